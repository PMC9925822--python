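"""From placed read pairs to fragment counts, normalized tracks and peaks.

The unit of signal is the GATC restriction fragment.  Counting assigns each
properly placed pair to the fragment containing its leftmost mapped base;
the treatment / Dam-only comparison is a per-fragment one-sided Poisson
test with Benjamini-Hochberg correction, and significant fragments are
merged into peaks along the fragment tiling.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import FragmentMap

_Q_MIN = 1e-300


@dataclasses.dataclass
class FragmentCounts:
    """Deduplicated read-pair counts per fragment for one sample."""

    sample_id: str
    condition: str
    counts: np.ndarray  # (n_fragments,) int64
    unassigned: int
    total_pairs: int
    duplicates_removed: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("fragment counts must be non-negative")
        if int(self.counts.sum()) + self.unassigned != self.total_pairs - self.duplicates_removed:
            raise ValueError(
                "count bookkeeping violated: assigned + unassigned != total - duplicates"
            )

    @property
    def assigned(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self, fmap: FragmentMap) -> pd.DataFrame:
        df = fmap.to_dataframe()
        df["count"] = self.counts
        return df


def fragment_of_pairs(
    pairs: pd.DataFrame, fmap: FragmentMap, read_len: int = 151
) -> np.ndarray:
    """Fragment index per pair (-1 for unassignable pairs).

    A pair is assigned to the fragment containing its leftmost mapped base;
    pairs whose span overhangs that fragment's end by more than ``read_len``
    are treated as boundary-crossing artifacts and left unassigned.
    """
    chroms = pairs["chrom"].to_numpy()
    known = set(fmap.chrom_names) | {"*"}
    offenders = sorted(set(chroms) - known)
    if offenders:
        raise ValueError(f"alignment reference names not in fragment map: {offenders}")

    frag = np.full(len(pairs), -1, dtype=np.int64)
    starts = pairs["start"].to_numpy(dtype=np.int64)
    ends = pairs["end"].to_numpy(dtype=np.int64)
    for name in fmap.chrom_names:
        rows = np.flatnonzero(chroms == name)
        if len(rows) == 0:
            continue
        sl = fmap.chrom_fragments(name)
        fs = fmap.frag_start[sl]
        fe = fmap.frag_end[sl]
        L = int(fmap.chrom_lengths[fmap.chrom_index(name)])
        inb = (starts[rows] >= 0) & (starts[rows] < L)
        rows = rows[inb]
        j = np.searchsorted(fs, starts[rows], side="right") - 1
        ok = ends[rows] <= fe[j] + read_len
        frag[rows[ok]] = sl.start + j[ok]
    return frag


def assign_reads(
    pairs: pd.DataFrame,
    fmap: FragmentMap,
    min_mapq: int = 0,
    dedup: bool = True,
    read_len: int = 151,
    sample_id: str = "sample",
    condition: str = "unknown",
) -> FragmentCounts:
    """Count placed pairs per fragment, with optional duplicate collapsing.

    Duplicates are pairs with identical (chrom, start, end, orientation);
    with ``dedup`` each group contributes one pair.  Pairs below
    ``min_mapq``, unplaced pairs and boundary-crossing pairs are counted as
    unassigned.  Note the simulator's reads are end-anchored, so coordinate
    duplicates there are genuine distinct molecules: analysis of simulated
    batches should run with ``dedup=False``.
    """
    total = len(pairs)
    work = pairs
    duplicates = 0
    if dedup and total:
        placed = work[work["chrom"] != "*"]
        kept = placed.drop_duplicates(subset=["chrom", "start", "end", "orientation"])
        duplicates = len(placed) - len(kept)
        work = pd.concat([kept, work[work["chrom"] == "*"]], ignore_index=True)

    frag = fragment_of_pairs(work, fmap, read_len=read_len)
    frag[work["mapq"].to_numpy() < min_mapq] = -1
    counts = np.bincount(frag[frag >= 0], minlength=fmap.n_fragments).astype(np.int64)
    unassigned = int((frag < 0).sum())
    return FragmentCounts(
        sample_id=sample_id,
        condition=condition,
        counts=counts,
        unassigned=unassigned,
        total_pairs=total,
        duplicates_removed=duplicates,
    )


@dataclasses.dataclass
class NormalizedTrack:
    """Per-fragment log2 enrichment of treatment over the Dam-only control."""

    values: np.ndarray  # (n_fragments,) float
    mask: np.ndarray  # (n_fragments,) bool; True where leak-masked
    meta: dict

    def __post_init__(self) -> None:
        if not np.isfinite(self.values).all():
            raise ValueError("normalized track must be finite everywhere")


def normalize(
    treatment: FragmentCounts,
    dam_only: FragmentCounts,
    uninduced: FragmentCounts | None = None,
    pseudocount: float = 1.0,
    leak_cpm_factor: float = 5.0,
) -> NormalizedTrack:
    """Size-factor scaled log2 ratio of treatment over the Dam-only control.

    ``value_i = log2(((t_i + c) / s_t) / ((d_i + c) / s_d))`` with size
    factors the total assigned counts.  When an uninduced (Cas9-) sample is
    supplied, fragments whose uninduced CPM exceeds ``leak_cpm_factor``
    times the median fragment CPM are masked (value 0, flagged): leak
    signal marks Dam-independent artifacts and is treated as a blacklist
    rather than a denominator.
    """
    t = treatment.counts.astype(float)
    d = dam_only.counts.astype(float)
    if len(t) != len(d):
        raise ValueError("samples are on different fragment maps")
    s_t, s_d = t.sum(), d.sum()
    if s_t == 0 or s_d == 0:
        raise ValueError("zero total assigned counts in a sample")
    c = float(pseudocount)
    values = np.log2(((t + c) / s_t) / ((d + c) / s_d))
    mask = np.zeros(len(t), dtype=bool)
    meta = {
        "pseudocount": c,
        "size_factors": {"treatment": s_t, "dam_only": s_d},
        "control_samples": [dam_only.sample_id],
    }
    if uninduced is not None:
        u = uninduced.counts.astype(float)
        if len(u) != len(t):
            raise ValueError("uninduced sample on a different fragment map")
        s_u = u.sum()
        if s_u == 0:
            raise ValueError("zero total assigned counts in the uninduced sample")
        cpm = u / s_u * 1e6
        threshold = leak_cpm_factor * float(np.median(cpm))
        mask = cpm > threshold
        values = np.where(mask, 0.0, values)
        meta["control_samples"].append(uninduced.sample_id)
        meta["leak_cpm_threshold"] = threshold
    return NormalizedTrack(values=values, mask=mask, meta=meta)


@dataclasses.dataclass
class PeakSet:
    """Merged runs of significantly enriched fragments.

    ``df`` columns: chrom, start, end, score (-log10 q), n_fragments,
    max_log2fc.  Peaks are sorted and non-overlapping, and every boundary
    coincides with a fragment boundary.  Per-fragment test results are kept
    for calibration diagnostics.
    """

    df: pd.DataFrame
    params: dict
    fragment_q: np.ndarray | None = None
    fragment_tested: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.df)

    def intervals(self) -> list[tuple[str, int, int]]:
        return list(zip(self.df["chrom"], self.df["start"], self.df["end"]))

    def to_bed6(self) -> pd.DataFrame:
        out = self.df[["chrom", "start", "end"]].copy()
        out["name"] = [f"peak_{i}" for i in range(len(out))]
        out["score"] = np.minimum(1000, np.round(100 * self.df["score"]).astype(int))
        out["strand"] = "."
        return out


def call_peaks(
    treatment: FragmentCounts,
    dam_only: FragmentCounts,
    fmap: FragmentMap,
    fdr: float = 0.05,
    min_log2fc: float = 1.0,
    merge_gap_fragments: int = 2,
    pseudocount: float = 1.0,
    mu_floor: float = 0.5,
) -> PeakSet:
    """Fragment-level one-sided Poisson enrichment test, BH-corrected.

    Each non-terminal fragment's treatment count is tested against
    ``mu_i = max(d_i * s_t / s_d, mu_floor)``; fragments with q < fdr and
    log2 fold change >= ``min_log2fc`` are significant, and significant
    fragments separated by at most ``merge_gap_fragments`` non-significant
    fragments merge into one peak.  Peak score is the best -log10 q among
    members.
    """
    if not (0.0 < fdr < 1.0):
        raise ValueError(f"fdr must be in (0, 1), got {fdr}")
    t = treatment.counts.astype(float)
    d = dam_only.counts.astype(float)
    s_t, s_d = t.sum(), d.sum()
    if s_t == 0 or s_d == 0:
        raise ValueError("zero total assigned counts in a sample")

    tested = ~fmap.frag_terminal
    mu = np.maximum(d * (s_t / s_d), mu_floor)
    pvals = stats.poisson.sf(t[tested] - 1, mu[tested])  # P(X >= t)
    qvals = stats.false_discovery_control(pvals, method="bh")
    c = float(pseudocount)
    log2fc = np.log2(((t + c) / s_t) / ((d + c) / s_d))

    q_full = np.full(fmap.n_fragments, 1.0)
    q_full[tested] = qvals
    sig = tested & (q_full < fdr) & (log2fc >= min_log2fc)

    rows = []
    for name in fmap.chrom_names:
        sl = fmap.chrom_fragments(name)
        idx = np.flatnonzero(sig[sl]) + sl.start
        if len(idx) == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > merge_gap_fragments + 1)
        groups = np.split(idx, breaks + 1)
        for g in groups:
            first, last = int(g[0]), int(g[-1])
            score = float((-np.log10(np.maximum(q_full[g], _Q_MIN))).max())
            rows.append(
                {
                    "chrom": name,
                    "start": int(fmap.frag_start[first]),
                    "end": int(fmap.frag_end[last]),
                    "score": score,
                    "n_fragments": last - first + 1,
                    "max_log2fc": float(log2fc[g].max()),
                }
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "n_fragments", "max_log2fc"])
    params = {
        "fdr": fdr,
        "min_log2fc": min_log2fc,
        "merge_gap_fragments": merge_gap_fragments,
        "pseudocount": pseudocount,
        "mu_floor": mu_floor,
    }
    return PeakSet(df=df, params=params, fragment_q=q_full, fragment_tested=tested)


def _merge_intervals(intervals: Sequence[tuple[str, int, int]]):
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in intervals:
        by_chrom.setdefault(c, []).append((int(s), int(e)))
    merged = []
    for c in sorted(by_chrom):
        ivs = sorted(by_chrom[c])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s < cur_e:  # >= 1 bp overlap
                cur_e = max(cur_e, e)
            else:
                merged.append((c, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((c, cur_s, cur_e))
    return merged


def replicate_consensus(peaksets: Sequence[PeakSet], min_support: int) -> PeakSet:
    """Merged intervals supported by at least ``min_support`` replicate sets.

    Support is a 1 bp-overlap rule: a merged interval counts a replicate if
    any of that replicate's peaks overlaps it.
    """
    if len(peaksets) < 2:
        raise ValueError("need at least two peak sets for a consensus")
    if min_support > len(peaksets):
        raise ValueError(f"min_support {min_support} exceeds number of sets {len(peaksets)}")
    all_iv = [iv for ps in peaksets for iv in ps.intervals()]
    rows = []
    for c, s, e in _merge_intervals(all_iv):
        support = 0
        score = 0.0
        fc = -math.inf
        nf = 0
        for ps in peaksets:
            sub = ps.df[(ps.df["chrom"] == c) & (ps.df["start"] < e) & (ps.df["end"] > s)]
            if len(sub):
                support += 1
                score = max(score, float(sub["score"].max()))
                fc = max(fc, float(sub["max_log2fc"].max()))
                nf = max(nf, int(sub["n_fragments"].max()))
        if support >= min_support:
            rows.append(
                {"chrom": c, "start": s, "end": e, "score": score,
                 "n_fragments": nf, "max_log2fc": fc if math.isfinite(fc) else 0.0}
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "n_fragments", "max_log2fc"])
    return PeakSet(df=df, params={"min_support": min_support, "n_sets": len(peaksets)})


def query_gatc_qpcr(
    track: NormalizedTrack, fmap: FragmentMap, sites: Sequence[tuple[str, int]]
) -> pd.DataFrame:
    """Enrichment of the two fragments flanking each queried GATC site.

    The in-silico analogue of the DpnII-protection qPCR assay: a methylated
    site protects its flanking fragments from DpnII digestion, so primer
    pairs spanning either flank report the site's labeling.  Returns left
    and right fragment enrichment and their mean; sites falling in masked
    fragments are flagged and their mean is null (NaN).
    """
    rows = []
    for chrom, pos in sites:
        left, right = fmap.fragments_flanking_site(chrom, pos)
        masked = bool(track.mask[left] or track.mask[right])
        lv, rv = float(track.values[left]), float(track.values[right])
        rows.append(
            {
                "chrom": chrom,
                "pos": int(pos),
                "left_value": lv,
                "right_value": rv,
                "mean_value": math.nan if masked else 0.5 * (lv + rv),
                "masked": masked,
            }
        )
    return pd.DataFrame(rows)
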