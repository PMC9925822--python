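"""Biological interpretation of peak sets.

Intra/inter-chromosomal classification, overlap of peaks with independent
region sets (e.g. 4C-identified viewpoint partners or chromatin-mark BEDs)
under a within-chromosome permutation null, shared-peak fractions between
conditions, multi-scale domainograms, reciprocal-bait confirmation and
peak-to-gene annotation.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def _as_region_df(regions) -> pd.DataFrame:
    if isinstance(regions, pd.DataFrame):
        return regions
    return pd.DataFrame(regions, columns=["chrom", "start", "end", "name"][: len(regions[0])])


def _peak_intervals(peaks) -> pd.DataFrame:
    if hasattr(peaks, "df"):
        return peaks.df
    return _as_region_df(peaks)


def classify_peaks(peaks, bait: tuple[str, int, int]) -> dict:
    """Split peaks into intra- (bait chromosome) and inter-chromosomal.

    Returns counts that always sum to the total number of peaks.
    """
    df = _peak_intervals(peaks)
    per_chrom = df.groupby("chrom").size().to_dict() if len(df) else {}
    intra = int(per_chrom.get(bait[0], 0))
    total = int(len(df))
    return {"intra": intra, "inter": total - intra, "per_chromosome": per_chrom, "total": total}


def _overlap_any(peak_s, peak_e, reg_s, reg_e) -> np.ndarray:
    """Boolean per peak: overlaps (>= 1 bp) any region. Arrays sorted by reg_s."""
    order = np.argsort(reg_s)
    rs, re_ = reg_s[order], reg_e[order]
    cummax_e = np.maximum.accumulate(re_)
    # candidate regions: start < peak_end; overlap iff max end among them > peak_start
    k = np.searchsorted(rs, peak_e, side="left")
    out = np.zeros(len(peak_s), dtype=bool)
    nz = k > 0
    out[nz] = cummax_e[k[nz] - 1] > peak_s[nz]
    return out


def _shuffle_starts(lengths: np.ndarray, chrom_len: int, rng) -> np.ndarray:
    """Uniform non-overlapping placement of intervals of given lengths."""
    lengths = rng.permutation(lengths)
    free = chrom_len - int(lengths.sum())
    if free < 0:
        raise ValueError("intervals do not fit in the chromosome")
    gaps = np.sort(rng.integers(0, free + 1, size=len(lengths)))
    starts = gaps + np.concatenate([[0], np.cumsum(lengths[:-1])])
    return starts, lengths


def overlap_with_regions(
    peaks,
    regions,
    chrom_lengths: Mapping[str, int],
    slop: int = 0,
    n_perm: int = 1000,
    seed=None,
) -> dict:
    """Observed peak/region overlap against a within-chromosome shuffle null.

    The null preserves each peak's chromosome, length and the non-overlap
    of the set, randomizing only positions; the permutation p-value is
    ``(1 + #{perm >= observed}) / (n_perm + 1)``.  Regions are extended by
    ``slop`` bp on both sides before testing.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pdf = _peak_intervals(peaks)
    rdf = _as_region_df(regions)
    bad = sorted(set(rdf["chrom"]) - set(chrom_lengths))
    if bad:
        raise ValueError(f"region chromosomes absent from genome: {bad}")
    bad = sorted(set(pdf["chrom"]) - set(chrom_lengths))
    if bad:
        raise ValueError(f"peak chromosomes absent from genome: {bad}")
    rng = np.random.default_rng(seed)

    n_peaks = len(pdf)
    if n_peaks == 0:
        return {"n_overlapping": 0, "fraction": 0.0, "perm_p": 1.0, "n_perm": n_perm}

    reg_by_chrom = {
        c: (
            np.maximum(g["start"].to_numpy() - slop, 0),
            g["end"].to_numpy() + slop,
        )
        for c, g in rdf.groupby("chrom")
    }

    def count_overlaps(peaks_by_chrom) -> int:
        total = 0
        for c, (ps, pe) in peaks_by_chrom.items():
            if c not in reg_by_chrom:
                continue
            rs, re_ = reg_by_chrom[c]
            total += int(_overlap_any(ps, pe, rs, re_).sum())
        return total

    obs_by_chrom = {
        c: (g["start"].to_numpy(np.int64), g["end"].to_numpy(np.int64))
        for c, g in pdf.groupby("chrom")
    }
    observed = count_overlaps(obs_by_chrom)

    lengths_by_chrom = {c: (e - s) for c, (s, e) in obs_by_chrom.items()}
    exceed = 0
    for _ in range(n_perm):
        perm = {}
        for c, lens in lengths_by_chrom.items():
            starts, plens = _shuffle_starts(lens, int(chrom_lengths[c]), rng)
            perm[c] = (starts, starts + plens)
        if count_overlaps(perm) >= observed:
            exceed += 1
    return {
        "n_overlapping": observed,
        "fraction": observed / n_peaks,
        "perm_p": (1 + exceed) / (n_perm + 1),
        "n_perm": n_perm,
    }


def shared_fraction(peaks_a, peaks_b) -> float:
    """Fraction of merged unique peaks (A union B) present in both sets."""
    from .counts import _merge_intervals

    a = _peak_intervals(peaks_a)
    b = _peak_intervals(peaks_b)
    all_iv = [(c, int(s), int(e)) for df in (a, b) for c, s, e in zip(df["chrom"], df["start"], df["end"])]
    if not all_iv:
        return 0.0
    merged = _merge_intervals(all_iv)
    shared = 0
    for c, s, e in merged:
        in_a = ((a["chrom"] == c) & (a["start"] < e) & (a["end"] > s)).any()
        in_b = ((b["chrom"] == c) & (b["start"] < e) & (b["end"] > s)).any()
        shared += bool(in_a and in_b)
    return shared / len(merged)


@dataclasses.dataclass
class Domainogram:
    """Multi-scale windowed means of a per-fragment signal.

    ``matrix[s, i]`` is the mean signal over a window of ``scales[s]``
    fragments centred on fragment ``i``; the scale-1 row reproduces the
    input exactly.
    """

    matrix: np.ndarray  # (n_scales, n_fragments)
    scales: list[int]
    chromosome: str


def domainogram(
    signal: np.ndarray,
    scales: Sequence[int],
    chromosome: str = "",
    padding: str = "clip",
) -> Domainogram:
    """Windowed means of ``signal`` at every requested (odd) scale.

    ``padding='clip'`` truncates windows symmetrically at the edges (the
    window stays centred and shrinks); ``padding='cyclic'`` wraps around,
    which preserves the row mean exactly at every scale.
    """
    scales = list(scales)
    if any(s < 1 or s % 2 == 0 for s in scales if s != 1):
        raise ValueError("scales must be odd positive integers")
    if sorted(scales) != scales:
        raise ValueError("scales must be ascending")
    x = np.asarray(signal, dtype=float)
    n = len(x)
    out = np.empty((len(scales), n))
    for si, s in enumerate(scales):
        h = s // 2
        if s == 1:  # identity row, bit-exact
            out[si] = x
            continue
        if padding == "cyclic":
            if h == 0:
                out[si] = x
            else:
                ext = np.concatenate([x[-h:], x, x[:h]])
                c = np.concatenate([[0.0], np.cumsum(ext)])
                out[si] = (c[s:] - c[:-s]) / s
        elif padding == "clip":
            c = np.concatenate([[0.0], np.cumsum(x)])
            i = np.arange(n)
            half = np.minimum(h, np.minimum(i, n - 1 - i))
            lo, hi = i - half, i + half + 1
            out[si] = (c[hi] - c[lo]) / (hi - lo)
        else:
            raise ValueError(f"unknown padding {padding!r}")
    return Domainogram(matrix=out, scales=scales, chromosome=chromosome)


def reciprocal_check(
    reciprocal_peaks, original_bait: tuple[str, int, int], slop: int = 0
) -> dict:
    """Does any peak from a reciprocal experiment hit the original bait?

    Confirmed iff a reciprocal peak overlaps the slop-extended original
    bait; ``best_overlap`` is the largest overlap in bp.
    """
    chrom, start, end = original_bait
    s, e = start - slop, end + slop
    df = _peak_intervals(reciprocal_peaks)
    best = 0
    for _, row in df[df["chrom"] == chrom].iterrows():
        ov = min(int(row["end"]), e) - max(int(row["start"]), s)
        best = max(best, ov)
    return {"confirmed": best > 0, "best_overlap": max(best, 0)}


def annotate_peaks(peaks, tss: pd.DataFrame, max_distance: int) -> pd.DataFrame:
    """Nearest-TSS annotation of each peak by midpoint distance.

    Distance is peak midpoint minus TSS midpoint (signed); exact ties go to
    the lexicographically smaller gene name.  Peaks farther than
    ``max_distance`` from every TSS are left unannotated (gene = None).
    """
    tss = _as_region_df(tss)
    if "name" not in tss:
        raise ValueError("tss regions must carry gene names")
    pdf = _peak_intervals(peaks)
    out = []
    by_chrom = {}
    for c, g in tss.groupby("chrom"):
        mids = ((g["start"].to_numpy(np.int64) + g["end"].to_numpy(np.int64)) // 2)
        names = g["name"].to_numpy()
        order = np.lexsort((names, mids))
        by_chrom[c] = (mids[order], names[order])
    for _, row in pdf.iterrows():
        pm = (int(row["start"]) + int(row["end"])) // 2
        gene, dist = None, None
        if row["chrom"] in by_chrom:
            mids, names = by_chrom[row["chrom"]]
            j = int(np.searchsorted(mids, pm))
            cand = [k for k in (j - 1, j) if 0 <= k < len(mids)]
            best_abs = None
            for k in cand:
                a = abs(pm - int(mids[k]))
                if best_abs is None or a < best_abs:
                    best_abs = a
            if best_abs is not None and best_abs <= max_distance:
                # all entries at exactly best_abs compete; lexicographic tie-break
                lo = int(np.searchsorted(mids, pm - best_abs, side="left"))
                hi = int(np.searchsorted(mids, pm + best_abs, side="right"))
                ties = [
                    (str(names[k]), int(pm - mids[k]))
                    for k in range(lo, hi)
                    if abs(pm - int(mids[k])) == best_abs
                ]
                gene, dist = min(ties, key=lambda t: t[0])
        out.append(
            {"chrom": row["chrom"], "start": int(row["start"]), "end": int(row["end"]),
             "gene": gene, "distance": dist}
        )
    return pd.DataFrame(out, columns=["chrom", "start", "end", "gene", "distance"])


def intersect_gene_lists(
    peak_genes: Sequence[str], de_genes: Sequence[str], universe: Sequence[str]
) -> dict:
    """Overlap of peak-annotated genes with a differential-expression list.

    Hypergeometric enrichment: drawing ``len(de in universe)`` genes from a
    universe of all annotatable genes, the p-value is the upper tail of the
    observed intersection size.
    """
    uni = set(universe)
    pg = set(peak_genes) & uni
    de = set(de_genes) & uni
    inter = sorted(pg & de)
    M, K, n, k = len(uni), len(pg), len(de), len(inter)
    p = float(stats.hypergeom.sf(k - 1, M, K, n)) if k > 0 else 1.0
    return {"intersection": inter, "n_intersection": k, "p_value": min(p, 1.0),
            "n_peak_genes": K, "n_de_genes": n, "n_universe": M}
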