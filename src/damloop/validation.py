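"""Orthogonal-validation arithmetic: 3C-qPCR, ddCt expression and DNA-FISH.

These are the quantifications used to confirm chromatin interactions seen
by sequencing: restriction-digestion efficiency QC, BAC-normalized 3C
relative interaction frequencies, 2^-ddCt expression fold changes, FISH
colocalization frequencies with Wilson intervals, and the two-proportion
sample-size calculation used to power a colocalization comparison.

Tabular inputs are plain DataFrames.  Ct tables carry columns
``sample, target, replicate, ct``; band tables ``site, intensity`` and
optionally ``replicate``; spot tables
``field_of_view, nucleus, channel, x, y, z`` with channels ``probeA`` /
``probeB`` and coordinates in micrometres.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from statsmodels.stats.proportion import proportion_confint


def _mean_ct(ct: pd.DataFrame, sample: str, target: str) -> tuple[float, float, int]:
    sub = ct[(ct["sample"] == sample) & (ct["target"] == target)]
    if len(sub) == 0:
        raise ValueError(f"no Ct records for sample={sample!r}, target={target!r}")
    vals = sub["ct"].to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError("Ct values must be positive")
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return float(vals.mean()), sd, len(vals)


def digestion_efficiency(
    ct: pd.DataFrame,
    site: str,
    control_site: str,
    digested_sample: str = "digested",
    undigested_sample: str = "undigested",
    qc_threshold: float = 80.0,
) -> dict:
    """Percent digestion at a restriction site from a ddCt comparison.

    ``efficiency% = 100 - 100 / 2^ddCt`` with
    ``ddCt = (Ct_dig - Ct_undig)_site - (Ct_dig - Ct_undig)_control``.
    Samples passing the QC threshold (default 80%) are usable for 3C.
    """
    d_site = _mean_ct(ct, digested_sample, site)[0] - _mean_ct(ct, undigested_sample, site)[0]
    d_ctrl = (
        _mean_ct(ct, digested_sample, control_site)[0]
        - _mean_ct(ct, undigested_sample, control_site)[0]
    )
    ddct = d_site - d_ctrl
    pct = 100.0 - 100.0 / 2.0**ddct
    return {"percent_digested": pct, "ddct": ddct, "passed": pct >= qc_threshold}


def band_table_from_ct(ct: pd.DataFrame, efficiency: float = 2.0) -> pd.DataFrame:
    """Convert a 3C-qPCR Ct table to equivalent band intensities.

    Template amount scales as ``E^(-Ct)``; this makes gel densitometry and
    qPCR interchangeable inputs for the interaction-frequency ratio.
    """
    if not (1.0 < efficiency <= 2.0):
        raise ValueError("amplification efficiency must be in (1, 2]")
    out = ct.rename(columns={"target": "site"}).copy()
    out["intensity"] = efficiency ** (-out.pop("ct").astype(float))
    return out


def interaction_frequency_3c(
    bands: pd.DataFrame,
    bac: pd.DataFrame,
    sites: Sequence[str],
    reference_site: str,
) -> pd.DataFrame:
    """BAC-normalized relative interaction frequency per assayed site.

    ``IF = (S_site / S_ref) / (B_site / B_ref)``: the sample ratio corrects
    for template amount via the internal reference site, and the BAC
    control library (equimolar digested/ligated BAC DNA) corrects per-site
    amplification bias.  With replicates, the ratio is computed per
    replicate and summarized as mean and SD.
    """

    def _per_rep(df: pd.DataFrame, label: str) -> pd.DataFrame:
        d = df.copy()
        if "replicate" not in d:
            d["replicate"] = 1
        if (d["intensity"] < 0).any():
            raise ValueError(f"negative intensities in {label} table")
        return d

    s_df = _per_rep(bands, "sample")
    b_df = _per_rep(bac, "BAC")

    def _ratio(df: pd.DataFrame, site: str, label: str) -> np.ndarray:
        vals = []
        for rep, g in df.groupby("replicate"):
            ref = g.loc[g["site"] == reference_site, "intensity"]
            tgt = g.loc[g["site"] == site, "intensity"]
            if len(ref) == 0 or len(tgt) == 0:
                raise ValueError(f"site {site!r} or reference missing from {label} table")
            if float(ref.mean()) == 0:
                raise ValueError(f"zero reference intensity in {label} table")
            vals.append(float(tgt.mean()) / float(ref.mean()))
        return np.array(vals)

    rows = []
    for site in sites:
        s_ratio = _ratio(s_df, site, "sample")
        b_ratio = _ratio(b_df, site, "BAC")
        if (b_ratio == 0).any():
            raise ValueError(f"zero BAC intensity at site {site!r}")
        b_mean = float(b_ratio.mean())
        ifs = s_ratio / b_mean
        rows.append(
            {
                "site": site,
                "interaction_frequency": float(ifs.mean()),
                "sd": float(ifs.std(ddof=1)) if len(ifs) > 1 else 0.0,
                "n_replicates": len(ifs),
            }
        )
    return pd.DataFrame(rows)


def ddct_expression(
    ct: pd.DataFrame,
    gene: str,
    sample: str,
    calibrator_sample: str,
    reference_gene: str = "GAPDH",
) -> dict:
    """Relative expression fold change by the 2^-ddCt method.

    Replicate Cts are averaged before differencing; the SD of ddCt is
    propagated from the four replicate SDs in quadrature and mapped to the
    fold-change scale.  ``fold = 2^-ddCt`` with
    ``ddCt = (Ct_gene - Ct_ref)_sample - (Ct_gene - Ct_ref)_calibrator``.
    """
    parts = []
    sds = []
    for s in (sample, calibrator_sample):
        for g in (gene, reference_gene):
            m, sd, _ = _mean_ct(ct, s, g)
            parts.append(m)
            sds.append(sd)
    ddct = (parts[0] - parts[1]) - (parts[2] - parts[3])
    sd_ddct = math.sqrt(sum(s**2 for s in sds))
    fold = 2.0**-ddct
    return {
        "fold_change": fold,
        "ddct": ddct,
        "sd_ddct": sd_ddct,
        "fold_sd": math.log(2.0) * fold * sd_ddct,
    }


def colocalization_frequency(spots: pd.DataFrame, distance_threshold: float = 1.0) -> dict:
    """FISH colocalization frequency per field of view, with Wilson CIs.

    A probeA spot is colocalized iff some probeB spot in the same nucleus
    lies within the Euclidean distance threshold (micrometres).  Nuclei
    with no probeA spot contribute nothing to the denominator.  Returns the
    per-field table and the pooled estimate with its Wilson 95% CI.
    """
    if len(spots) == 0:
        raise ValueError("empty spot table")
    if distance_threshold < 0:
        raise ValueError("distance threshold must be non-negative")
    nid, nuclei = pd.factorize(
        pd.Series(list(zip(spots["field_of_view"], spots["nucleus"])))
    )
    xyz = spots[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.isfinite(xyz).all():
        raise ValueError("spot coordinates must be finite")
    is_a = (spots["channel"] == "probeA").to_numpy()
    is_b = (spots["channel"] == "probeB").to_numpy()
    rows = []
    for k, (fov, nuc) in enumerate(nuclei):
        in_nuc = nid == k
        a = xyz[in_nuc & is_a]
        b = xyz[in_nuc & is_b]
        if len(a) == 0:
            continue
        if len(b) == 0:
            hits = 0
        else:
            hits = int((cdist(a, b).min(axis=1) <= distance_threshold).sum())
        rows.append({"field_of_view": fov, "nucleus": nuc, "n_a": len(a), "n_coloc": hits})
    if not rows:
        raise ValueError("no probeA spots in any nucleus")
    per_nuc = pd.DataFrame(rows)
    per_field = (
        per_nuc.groupby("field_of_view")[["n_a", "n_coloc"]].sum().reset_index()
    )
    per_field["frequency"] = per_field["n_coloc"] / per_field["n_a"]
    ci = per_field.apply(
        lambda r: proportion_confint(r["n_coloc"], r["n_a"], alpha=0.05, method="wilson"),
        axis=1,
    )
    per_field["ci_low"] = [c[0] for c in ci]
    per_field["ci_high"] = [c[1] for c in ci]
    total_hits = int(per_field["n_coloc"].sum())
    total_spots = int(per_field["n_a"].sum())
    lo, hi = proportion_confint(total_hits, total_spots, alpha=0.05, method="wilson")
    return {
        "per_field": per_field,
        "pooled_frequency": total_hits / total_spots,
        "pooled_ci": (float(lo), float(hi)),
        "n_spots": total_spots,
    }


def simulate_nuclei(
    n_nuclei: int,
    coloc_prob: float,
    spot_noise_sd: float = 0.25,
    nucleus_radius: float = 5.0,
    nuclei_per_field: int = 20,
    seed=None,
) -> pd.DataFrame:
    """Synthetic two-probe FISH spot table with planted colocalization.

    Each nucleus holds one probeA spot uniform in a sphere; with
    probability ``coloc_prob`` the probeB spot sits at the probeA position
    plus isotropic Gaussian noise (a colocalized pair), otherwise it is an
    independent uniform draw.  Deterministic given the seed.
    """
    if not (0.0 <= coloc_prob <= 1.0):
        raise ValueError("coloc_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)

    def _uniform_sphere(n):
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = nucleus_radius * rng.random(n) ** (1.0 / 3.0)
        return v * r[:, None]

    a = _uniform_sphere(n_nuclei)
    coloc = rng.random(n_nuclei) < coloc_prob
    b = _uniform_sphere(n_nuclei)
    b[coloc] = a[coloc] + rng.normal(0.0, spot_noise_sd, size=(int(coloc.sum()), 3))
    rows = []
    for i in range(n_nuclei):
        fov = i // nuclei_per_field
        for channel, xyz in (("probeA", a[i]), ("probeB", b[i])):
            rows.append(
                {
                    "field_of_view": fov,
                    "nucleus": i,
                    "channel": channel,
                    "x": xyz[0],
                    "y": xyz[1],
                    "z": xyz[2],
                }
            )
    return pd.DataFrame(rows)


def power_sample_size(
    p1: float, p2: float, alpha: float = 0.05, power: float = 0.8
) -> int:
    """Per-group sample size for a two-proportion comparison (z approximation).

    ``n = ceil((z_{1-a/2} sqrt(2 pbar qbar) + z_{1-b} sqrt(p1 q1 + p2 q2))^2
    / (p1 - p2)^2)`` with ``pbar`` the mean of the two proportions.
    """
    if not (0.0 < p2 < p1 < 1.0):
        if p1 == p2:
            raise ValueError("p1 == p2 gives an infinite sample size")
        raise ValueError("require 0 < p2 < p1 < 1")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    pbar = (p1 + p2) / 2
    num = (z_a * math.sqrt(2 * pbar * (1 - pbar)) + z_b * math.sqrt(p1 * (1 - p1) + p2 * (1 - p2))) ** 2
    return math.ceil(num / (p1 - p2) ** 2)


def two_proportion_power_mc(
    p1: float, p2: float, n: int, alpha: float = 0.05, n_trials: int = 10_000, seed=None
) -> float:
    """Monte-Carlo power of the pooled two-proportion z-test at size n."""
    rng = np.random.default_rng(seed)
    x1 = rng.binomial(n, p1, size=n_trials)
    x2 = rng.binomial(n, p2, size=n_trials)
    phat1, phat2 = x1 / n, x2 / n
    pool = (x1 + x2) / (2 * n)
    se = np.sqrt(pool * (1 - pool) * 2 / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (phat1 - phat2) / se, 0.0)
    crit = stats.norm.ppf(1 - alpha / 2)
    return float((np.abs(z) > crit).mean())


def validate_3c_primers(
    primers: pd.DataFrame,
    max_site_distance: int = 150,
    min_fragment: int = 70,
    max_fragment: int = 250,
) -> pd.DataFrame:
    """Check 3C primers against the standard design constraints.

    Primers must sit within ``max_site_distance`` bp of their restriction
    site and yield a ligated bait-target amplicon of at least
    ``min_fragment`` and under ``max_fragment`` bp.  Expects columns
    ``name, distance_to_site, fragment_length``.
    """
    out = primers.copy()
    out["distance_ok"] = out["distance_to_site"] <= max_site_distance
    out["length_ok"] = (out["fragment_length"] >= min_fragment) & (
        out["fragment_length"] < max_fragment
    )
    out["valid"] = out["distance_ok"] & out["length_ok"]
    return out
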