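"""Read-pair placement: a built-in exact-seed matcher and a SAM reader.

The matcher is a seed-and-verify aligner against the (typically synthetic)
reference: 16-mer exact seeds located through a sorted key array, followed
by full-length mismatch verification.  It exists so the counting pipeline
can run self-contained on simulated reads; aligned SAM input is the
production route and goes through pysam.

Both routes produce the same pair table: one row per input pair with
columns ``chrom`` ('*' when unplaced), ``start``, ``end`` (leftmost /
rightmost mapped base, half-open), ``orientation`` and ``mapq``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._seqarr import CODE, kmer_codes, revcomp_rows, seq_to_u8
from .genome import Genome
from .simulate import ReadPairBatch

PAIR_COLUMNS = ["chrom", "start", "end", "orientation", "mapq"]


class SeedMatcher:
    """Exact-seed, mismatch-verified placement of reads on a genome."""

    def __init__(self, genome: Genome, k: int = 16, max_mismatch_frac: float = 0.1):
        self.k = k
        self.max_mismatch_frac = max_mismatch_frac
        self.chrom_names = genome.names
        parts: list[np.ndarray] = []
        offsets: list[int] = []
        gap = np.full(k, ord("N"), dtype=np.uint8)
        cursor = 0
        for _, seq in genome.chromosomes:
            offsets.append(cursor)
            parts.append(seq_to_u8(seq))
            cursor += len(seq)
            parts.append(gap)
            cursor += k
        self._offsets = np.array(offsets, dtype=np.int64)
        self._chrom_len = np.array([len(s) for _, s in genome.chromosomes], dtype=np.int64)
        concat = np.concatenate(parts + [np.full(256, ord("N"), np.uint8)])
        self._genome = concat
        codes = CODE[concat]
        keys, valid = kmer_codes(codes, k)
        idx = np.flatnonzero(valid)
        keys = keys[idx]
        order = np.argsort(keys, kind="stable")
        self._sorted_keys = keys[order]
        self._sorted_pos = idx[order]

    def _to_chrom(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ci = np.searchsorted(self._offsets, gpos, side="right") - 1
        return ci, gpos - self._offsets[ci]

    def locate(self, reads: np.ndarray, lens: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Global positions (-1 if unplaced) and mapping qualities.

        Tries an exact seed at read offset 0, then at offset k for reads
        long enough; candidates are verified over the full read length with
        a mismatch budget of ``max(2, max_mismatch_frac * len)``.
        """
        n, w = reads.shape
        pos = np.full(n, -1, dtype=np.int64)
        mapq = np.zeros(n, dtype=np.int32)
        if n == 0:
            return pos, mapq
        codes = CODE[reads]
        powers = (4 ** np.arange(self.k - 1, -1, -1)).astype(np.uint64)
        pending = np.flatnonzero(lens >= self.k)
        for offset in (0, self.k):
            if len(pending) == 0:
                break
            use = pending[lens[pending] >= offset + self.k]
            if len(use) == 0:
                break
            win = codes[use, offset : offset + self.k]
            good = ~(win == 255).any(axis=1)
            use = use[good]
            if len(use) == 0:
                continue
            keys = (win[good].astype(np.uint64) * powers[None, :]).sum(axis=1)
            lo = np.searchsorted(self._sorted_keys, keys, side="left")
            hi = np.searchsorted(self._sorted_keys, keys, side="right")
            hit = hi > lo
            unique = hit & (hi - lo == 1)
            cand_rows = use[unique]
            cand_pos = self._sorted_pos[lo[unique]] - offset
            ok = self._verify(reads, lens, cand_rows, cand_pos)
            placed = cand_rows[ok]
            pos[placed] = cand_pos[ok]
            mapq[placed] = 60
            # ambiguous seeds: verify up to 8 candidates, keep a unique best
            multi_rows = use[hit & ~unique]
            multi_lo, multi_hi = lo[hit & ~unique], hi[hit & ~unique]
            for r, a, b in zip(multi_rows, multi_lo, multi_hi):
                cands = self._sorted_pos[a : min(b, a + 8)] - offset
                best, best_mm, ties = -1, 1 << 30, 0
                for c in cands:
                    if c < 0:
                        continue
                    mm = self._mismatches(reads[r], int(lens[r]), int(c))
                    if mm < best_mm:
                        best, best_mm, ties = int(c), mm, 1
                    elif mm == best_mm:
                        ties += 1
                if best >= 0 and best_mm <= max(2, int(self.max_mismatch_frac * lens[r])):
                    pos[r] = best
                    mapq[r] = 30 if ties == 1 else 0
            pending = pending[pos[pending] < 0]
        return pos, mapq

    def _mismatches(self, read: np.ndarray, l: int, gpos: int) -> int:
        ref = self._genome[gpos : gpos + l]
        return int((ref != read[:l]).sum())

    def _verify(self, reads, lens, rows, gpos) -> np.ndarray:
        if len(rows) == 0:
            return np.zeros(0, dtype=bool)
        w = reads.shape[1]
        gpos = np.asarray(gpos)
        valid = gpos >= 0
        take = np.clip(gpos[:, None], 0, None) + np.arange(w)[None, :]
        ref = self._genome[take]
        mism = (ref != reads[rows]) & (np.arange(w)[None, :] < lens[rows][:, None])
        mm = mism.sum(axis=1)
        budget = np.maximum(2, (self.max_mismatch_frac * lens[rows]).astype(int))
        return valid & (mm <= budget)

    def match_pairs(self, batch: ReadPairBatch) -> pd.DataFrame:
        """Place every pair of a batch; one output row per input pair."""
        p1, q1 = self.locate(batch.r1, batch.lens)
        r2rc = revcomp_rows(batch.r2, batch.lens)
        p2, q2 = self.locate(r2rc, batch.lens)

        n = batch.n
        lens = batch.lens.astype(np.int64)
        ok = (p1 >= 0) & (p2 >= 0)
        ci1 = np.full(n, -1, dtype=np.int64)
        loc1 = np.zeros(n, dtype=np.int64)
        ci2 = np.full(n, -2, dtype=np.int64)
        loc2 = np.zeros(n, dtype=np.int64)
        if ok.any():
            ci1[ok], loc1[ok] = self._to_chrom(p1[ok])
            ci2[ok], loc2[ok] = self._to_chrom(p2[ok])
        proper = ok & (ci1 == ci2)
        start = np.minimum(loc1, loc2)
        end = np.maximum(loc1 + lens, loc2 + lens)
        chrom = np.where(
            proper, np.array(self.chrom_names, dtype=object)[np.clip(ci1, 0, None)], "*"
        )
        return pd.DataFrame(
            {
                "chrom": chrom,
                "start": np.where(proper, start, 0),
                "end": np.where(proper, end, 0),
                "orientation": "FR",
                "mapq": np.where(proper, np.minimum(q1, q2), 0).astype(np.int32),
            }
        )


def pairs_from_sam(path) -> pd.DataFrame:
    """Collapse a (text) SAM file into one row per read pair.

    Mates are joined by query name; a pair is placed when both mates map to
    the same reference.  Secondary and supplementary alignments are
    ignored.  Unplaced pairs get chrom '*' and mapq 0.
    """
    import pysam

    pending: dict[str, tuple] = {}
    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            info = (
                rec.reference_name if not rec.is_unmapped else None,
                rec.reference_start if not rec.is_unmapped else 0,
                rec.reference_end if not rec.is_unmapped else 0,
                "R" if rec.is_reverse else "F",
                rec.mapping_quality,
            )
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = info
                continue
            c1, s1, e1, o1, q1 = mate
            c2, s2, e2, o2, q2 = info
            if c1 is None or c2 is None or c1 != c2:
                rows.append(("*", 0, 0, o1 + o2, 0))
            else:
                first, second = ((s1, e1, o1), (s2, e2, o2))
                if s2 < s1:
                    first, second = second, first
                rows.append(
                    (c1, min(s1, s2), max(e1, e2), first[2] + second[2], min(q1, q2))
                )
    for name, (c, s, e, o, q) in pending.items():
        rows.append(("*", 0, 0, o, 0))  # unmated reads are unassignable
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)
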