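"""Genome representation, GATC site scanning and fragment maps.

A Dam methyltransferase fusion marks adenines inside GATC motifs, and the
sequencing library is built from restriction fragments whose boundaries are
GATC sites.  The inter-site fragment is therefore the unit of measurement of
the whole assay; this module builds the per-chromosome fragment map that the
simulator and the counting pipeline share.

Coordinates are 0-based, half-open throughout.  Fragment boundaries are
placed at the motif start position, so that fragment length equals the
distance between consecutive motif starts and fragments tile each chromosome
exactly.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from typing import Iterable, Sequence

import numpy as np

GATC = "GATC"

_ALLOWED = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# NmCas9 protospacer-adjacent motif, 3' of the spacer: NNNNGMTT with M = A/C.
# Literal N in the sequence never matches.
_PAM_FWD = re.compile(r"(?=([ACGT]{4}G[AC]TT))")
_PAM_REV = re.compile(r"(?=(AA[GT]C[ACGT]{4}))")  # reverse complement of NNNNGMTT

SPACER_LENGTHS = (22, 23, 24)


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_dna(seq: str) -> None:
    bad = set(seq) - _ALLOWED
    if bad:
        for i, ch in enumerate(seq):
            if ch in bad:
                raise ValueError(
                    f"non-DNA character {ch!r} at position {i}; "
                    "sequences must be uppercase over A/C/G/T/N"
                )


def scan_gatc(sequence: str) -> list[int]:
    """Return the ascending 0-based start positions of every GATC motif.

    GATC cannot overlap itself, so a simple ``str.find`` walk enumerates all
    occurrences.  Windows containing N never match.  Non-DNA characters raise
    ``ValueError`` naming the offending position.
    """
    _validate_dna(sequence)
    positions: list[int] = []
    i = sequence.find(GATC)
    while i != -1:
        positions.append(i)
        i = sequence.find(GATC, i + 4)
    return positions


@dataclasses.dataclass
class Genome:
    """An ordered collection of named chromosome sequences.

    Chromosome names must be unique, sequences non-empty and restricted to
    the uppercase alphabet {A, C, G, T, N}.
    """

    chromosomes: list[tuple[str, str]]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, seq in self.chromosomes:
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
            _validate_dna(seq)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes}

    def sequence(self, name: str) -> str:
        for n, seq in self.chromosomes:
            if n == name:
                return seq
        raise KeyError(f"unknown chromosome {name!r}")

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        from Bio import SeqIO

        records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise ValueError(f"no FASTA records found in {path}")
        return cls(records)

    def to_fasta(self, path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chromosomes:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclasses.dataclass
class FragmentMap:
    """Tiling of a genome into GATC restriction fragments.

    Fragments are half-open intervals whose interior contains no GATC motif
    start; every non-terminal fragment is bounded by two GATC sites.  The
    first and last fragment of each chromosome are flagged ``terminal``: they
    lack a methylatable site on one side and can never be amplified by the
    two-methylated-flanks chemistry.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: np.ndarray  # (n_chrom,)
    sites: dict[str, np.ndarray]  # per-chromosome ascending GATC starts

    frag_chrom: np.ndarray  # (n_frag,) chromosome index
    frag_start: np.ndarray  # (n_frag,)
    frag_end: np.ndarray  # (n_frag,)
    frag_terminal: np.ndarray  # (n_frag,) bool

    site_chrom: np.ndarray  # (n_sites,) chromosome index
    site_pos: np.ndarray  # (n_sites,) concatenated positions

    # adjacent same-chromosome site pairs; pair k flanks fragment pair_fragment[k]
    pair_fragment: np.ndarray
    pair_left_site: np.ndarray
    pair_right_site: np.ndarray

    def __post_init__(self) -> None:
        self._chrom_index = {n: i for i, n in enumerate(self.chrom_names)}
        # fragment index range per chromosome (fragments are stored in order)
        self._frag_lo = np.searchsorted(self.frag_chrom, np.arange(len(self.chrom_names)))
        self._frag_hi = np.searchsorted(
            self.frag_chrom, np.arange(len(self.chrom_names)), side="right"
        )
        self._site_lo = np.searchsorted(self.site_chrom, np.arange(len(self.chrom_names)))

    @property
    def n_fragments(self) -> int:
        return len(self.frag_start)

    @property
    def n_sites(self) -> int:
        return len(self.site_pos)

    @property
    def n_internal_gatc(self) -> np.ndarray:
        """Internal GATC count per fragment; zero by construction."""
        return np.zeros(self.n_fragments, dtype=np.int64)

    def chrom_index(self, name: str) -> int:
        try:
            return self._chrom_index[name]
        except KeyError:
            raise KeyError(f"chromosome {name!r} not in fragment map") from None

    def chrom_fragments(self, name: str) -> slice:
        ci = self.chrom_index(name)
        return slice(int(self._frag_lo[ci]), int(self._frag_hi[ci]))

    def fragment_at(self, chrom: str, pos: int) -> int:
        """Global index of the fragment containing base ``pos``."""
        ci = self.chrom_index(chrom)
        if not (0 <= pos < self.chrom_lengths[ci]):
            raise ValueError(f"position {pos} outside {chrom} [0, {self.chrom_lengths[ci]})")
        lo, hi = int(self._frag_lo[ci]), int(self._frag_hi[ci])
        j = int(np.searchsorted(self.frag_start[lo:hi], pos, side="right")) - 1
        return lo + j

    def site_index(self, chrom: str, pos: int) -> int:
        """Global index of the GATC site at ``pos``; error if not a site."""
        ci = self.chrom_index(chrom)
        s = self.sites[chrom]
        j = int(np.searchsorted(s, pos))
        if j >= len(s) or s[j] != pos:
            raise ValueError(f"{chrom}:{pos} is not a GATC site")
        return int(self._site_lo[ci]) + j

    def fragments_flanking_site(self, chrom: str, pos: int) -> tuple[int, int]:
        """(left, right) fragment indices around the GATC site at ``pos``.

        The left fragment ends at the site, the right fragment starts at it.
        """
        self.site_index(chrom, pos)  # validates
        lo, hi = self.chrom_fragments(chrom).start, self.chrom_fragments(chrom).stop
        right = lo + int(np.searchsorted(self.frag_start[lo:hi], pos))
        return right - 1, right

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": [self.chrom_names[c] for c in self.frag_chrom],
                "start": self.frag_start,
                "end": self.frag_end,
                "terminal": self.frag_terminal,
            }
        )


def build_fragment_map(genome: Genome) -> FragmentMap:
    """Cut every chromosome at its GATC motif starts and tile it in fragments.

    A chromosome with no GATC site yields a single terminal fragment (with a
    warning): it can carry no methylation signal.
    """
    chrom_names = tuple(genome.names)
    chrom_lengths = np.array([len(seq) for _, seq in genome.chromosomes], dtype=np.int64)

    sites: dict[str, np.ndarray] = {}
    fc, fs, fe, ft = [], [], [], []
    sc, sp = [], []
    pair_frag, pair_l, pair_r = [], [], []

    frag_offset = 0
    site_offset = 0
    for ci, (name, seq) in enumerate(genome.chromosomes):
        L = len(seq)
        s = np.asarray(scan_gatc(seq), dtype=np.int64)
        sites[name] = s
        if len(s) == 0:
            warnings.warn(f"chromosome {name!r} has no GATC site; single terminal fragment")
            fc.append(np.array([ci]))
            fs.append(np.array([0]))
            fe.append(np.array([L]))
            ft.append(np.array([True]))
            frag_offset += 1
            continue
        bounds = np.unique(np.concatenate([[0], s, [L]]))
        starts, ends = bounds[:-1], bounds[1:]
        left_is_site = np.isin(starts, s)
        right_is_site = np.isin(ends, s)
        terminal = ~(left_is_site & right_is_site)
        n = len(starts)
        fc.append(np.full(n, ci))
        fs.append(starts)
        fe.append(ends)
        ft.append(terminal)
        sc.append(np.full(len(s), ci))
        sp.append(s)
        # adjacent site pairs flank the non-terminal fragments
        nonterm = np.flatnonzero(~terminal)
        for j in nonterm:
            li = int(np.searchsorted(s, starts[j]))
            pair_frag.append(frag_offset + j)
            pair_l.append(site_offset + li)
            pair_r.append(site_offset + li + 1)
        frag_offset += n
        site_offset += len(s)

    return FragmentMap(
        chrom_names=chrom_names,
        chrom_lengths=chrom_lengths,
        sites=sites,
        frag_chrom=np.concatenate(fc).astype(np.int32),
        frag_start=np.concatenate(fs).astype(np.int64),
        frag_end=np.concatenate(fe).astype(np.int64),
        frag_terminal=np.concatenate(ft).astype(bool),
        site_chrom=(np.concatenate(sc).astype(np.int32) if sc else np.empty(0, np.int32)),
        site_pos=(np.concatenate(sp).astype(np.int64) if sp else np.empty(0, np.int64)),
        pair_fragment=np.asarray(pair_frag, dtype=np.int64),
        pair_left_site=np.asarray(pair_l, dtype=np.int64),
        pair_right_site=np.asarray(pair_r, dtype=np.int64),
    )


@dataclasses.dataclass(frozen=True)
class PamTarget:
    """A candidate NmCas9 guide target: spacer plus 3' NNNNGMTT PAM."""

    chrom: str
    strand: str  # '+' or '-'
    spacer_start: int  # 0-based half-open genome coordinates
    spacer_end: int
    spacer_len: int
    pam_seq: str  # strand-oriented 8-mer matching NNNNGMTT

    def __post_init__(self) -> None:
        if self.spacer_len not in SPACER_LENGTHS:
            raise ValueError(f"spacer length {self.spacer_len} outside {SPACER_LENGTHS}")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


def find_pam_targets(
    genome: Genome,
    region: tuple[str, int, int] | None = None,
    spacer_lengths: Sequence[int] = SPACER_LENGTHS,
) -> list[PamTarget]:
    """Enumerate NmCas9 guide targets (spacer + NNNNGMTT PAM) on both strands.

    Every PAM occurrence is reported once per requested spacer length, as
    long as spacer and PAM fit inside the searched region.  ``region`` is a
    (chrom, start, end) half-open interval; the default scans the whole
    genome.  Spacers containing N are skipped.
    """
    if region is not None:
        chrom, start, end = region
        L = genome.lengths.get(chrom)
        if L is None:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= start < end <= L):
            raise ValueError(f"region {chrom}:{start}-{end} outside [0, {L})")
        windows: Iterable[tuple[str, int, str]] = [(chrom, start, genome.sequence(chrom)[start:end])]
    else:
        windows = [(name, 0, seq) for name, seq in genome.chromosomes]

    targets: list[PamTarget] = []
    for chrom, offset, seq in windows:
        for m in _PAM_FWD.finditer(seq):
            p = m.start()  # PAM start within window, plus strand
            pam = m.group(1)
            for sl in spacer_lengths:
                if p - sl < 0:
                    continue
                spacer = seq[p - sl : p]
                if "N" in spacer:
                    continue
                targets.append(
                    PamTarget(chrom, "+", offset + p - sl, offset + p, sl, pam)
                )
        for m in _PAM_REV.finditer(seq):
            p = m.start()  # plus-strand coordinate of the 8-mer
            pam = reverse_complement(m.group(1))
            for sl in spacer_lengths:
                if p + 8 + sl > len(seq):
                    continue
                spacer = seq[p + 8 : p + 8 + sl]
                if "N" in spacer:
                    continue
                targets.append(
                    PamTarget(chrom, "-", offset + p + 8, offset + p + 8 + sl, sl, pam)
                )
    targets.sort(key=lambda t: (t.chrom, t.spacer_start, t.strand, t.spacer_len))
    return targets
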