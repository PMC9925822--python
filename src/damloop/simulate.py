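"""Generative model of the CRISPR-targeted DamID assay.

The simulator reproduces the assay end to end: a synthetic genome with
controlled GATC density, a bait locus engaged by the guide-targeted
dCas9-Dam fusion, planted contact partners with known per-cell contact
probabilities, condition-specific adenine methylation, the
DpnI -> adaptor -> DpnII fragment-selection chemistry, and paired-end read
generation from the amplified fragment library.

Three experimental conditions are modelled:

* ``gRNA+Cas9+`` (treatment): the fusion is induced and targeted; GATC sites
  are methylated with probability ``p_max * exp(-d / decay_length)`` where
  ``d`` is the distance to the nearest engaged anchor (bait midpoint, or a
  partner midpoint in cells where that partner's contact fired), on top of
  an untargeted background component.
* ``gRNA-Cas9+`` (Dam-only control): untargeted, accessibility-weighted
  background labeling only, scaled to a configured expected number of
  methylated sites per cell.
* ``Cas9-`` (uninduced control): residual leak methylation at a small
  constant per-site rate.

A fragment is amplifiable in a cell iff it is non-terminal and both of its
flanking GATC sites are methylated: DpnI only cuts methylated GATC (freeing
adaptor-ligatable ends) and DpnII destroys every fragment still containing
an unmethylated site.
"""

from __future__ import annotations

import dataclasses
import gzip
import re
import warnings
from typing import Sequence

import numpy as np

from ._seqarr import CODE, seq_to_u8, u8_to_str
from .genome import GATC, Genome, FragmentMap, scan_gatc

TREATMENT = "gRNA+Cas9+"
DAM_ONLY = "gRNA-Cas9+"
UNINDUCED = "Cas9-"
CONDITIONS = (TREATMENT, DAM_ONLY, UNINDUCED)

_CONDITION_ALIASES = {
    "grna+cas9+": TREATMENT,
    "treatment": TREATMENT,
    "grna-cas9+": DAM_ONLY,
    "dam_only": DAM_ONLY,
    "dam-only": DAM_ONLY,
    "cas9-": UNINDUCED,
    "uninduced": UNINDUCED,
}


def normalize_condition(condition: str) -> str:
    key = condition.strip().lower().replace("−", "-")
    if key not in _CONDITION_ALIASES:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    return _CONDITION_ALIASES[key]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# synthetic genome


def simulate_genome(
    n_chrom: int,
    lengths: int | Sequence[int],
    gatc_spacing_mean: float = 256.0,
    seed=None,
) -> Genome:
    """Random genome with GATC motifs planted at controlled mean spacing.

    Inter-site gaps are 3 + Geometric, giving the requested mean distance
    between consecutive motif starts with a hard minimum of 4 bp (motifs
    cannot overlap).  Accidental GATC occurrences in the random background
    are disrupted so that the realized site set is exactly the planted one.
    Deterministic for a given seed.
    """
    if gatc_spacing_mean < 4:
        raise ValueError(f"infeasible GATC spacing {gatc_spacing_mean}; minimum is 4 bp")
    rng = _rng(seed)
    if np.isscalar(lengths):
        lengths = [int(lengths)] * n_chrom
    lengths = [int(x) for x in lengths]
    if len(lengths) != n_chrom:
        raise ValueError("lengths must match n_chrom")

    p_gap = 1.0 / (gatc_spacing_mean - 3.0) if gatc_spacing_mean > 4 else 1.0
    chroms: list[tuple[str, str]] = []
    for ci, L in enumerate(lengths):
        # planted motif start positions
        pos: list[int] = []
        cur = 0
        while True:
            gap = 3 + (rng.geometric(p_gap) if p_gap < 1.0 else 1)
            cur += int(gap)
            if cur > L - 4:
                break
            pos.append(cur)
        arr = DECODE_BASES[rng.integers(0, 4, size=L)]
        # disrupt accidental motifs (mutating can create new ones; iterate)
        seq = u8_to_str(arr)
        acc = scan_gatc(seq)
        while acc:
            for p in acc:
                arr[p + 1] = DECODE_BASES[rng.choice([1, 2, 3])]  # A -> C/G/T
            seq = u8_to_str(arr)
            acc = scan_gatc(seq)
        motif = np.frombuffer(GATC.encode(), dtype=np.uint8)
        for p in pos:
            arr[p : p + 4] = motif
        chroms.append((f"chr{ci + 1}", u8_to_str(arr)))
    return Genome(chroms)


DECODE_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# contact model and methylation


@dataclasses.dataclass(frozen=True)
class Partner:
    """A planted contact partner locus with a per-cell contact probability."""

    chrom: str
    start: int
    end: int
    contact_prob: float

    def __post_init__(self) -> None:
        if not (0.0 < self.contact_prob <= 1.0):
            raise ValueError(f"contact_prob must be in (0, 1], got {self.contact_prob}")
        if self.end <= self.start:
            raise ValueError("partner interval must be non-empty")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclasses.dataclass
class ContactModel:
    """Ground truth for the simulated assay.

    Parameters
    ----------
    bait : (chrom, start, end)
        Locus the guide RNA targets; engaged in every treatment cell.
    partners : list of Partner
        Planted contact loci; each fires independently per cell.
    decay_length : float
        Exponential length scale (bp) of the methylation kernel around an
        engaged anchor.
    p_max : float
        Peak per-site methylation probability at zero distance.
    leak_rate : float
        Per-site methylation probability in the uninduced (Cas9-) condition.
    background_total : float
        Expected number of background-methylated sites per cell genome-wide
        (untargeted Dam activity); distributed over sites proportionally to
        ``background_weights``.
    background_weights : per-fragment non-negative accessibility weights,
        or None for uniform.
    """

    bait: tuple[str, int, int]
    partners: list[Partner] = dataclasses.field(default_factory=list)
    decay_length: float = 1500.0
    p_max: float = 0.8
    leak_rate: float = 0.005
    background_total: float = 300.0
    background_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")
        if not (0.0 < self.p_max <= 1.0):
            raise ValueError("p_max must be in (0, 1]")
        if self.leak_rate < 0:
            raise ValueError("leak_rate must be non-negative")
        self.partners = [p if isinstance(p, Partner) else Partner(*p) for p in self.partners]

    @property
    def bait_midpoint(self) -> int:
        return (self.bait[1] + self.bait[2]) // 2


@dataclasses.dataclass
class MethylationState:
    """Per-cell boolean methylation flags over exactly the map's GATC sites."""

    flags: np.ndarray  # (n_cells, n_sites) bool
    condition: str
    partner_active: np.ndarray | None = None  # (n_cells, n_partners) bool

    @property
    def n_cells(self) -> int:
        return self.flags.shape[0]


def _site_flank_fragments(fmap: FragmentMap) -> tuple[np.ndarray, np.ndarray]:
    """(left, right) fragment index of each site; left == right at pos 0."""
    left = np.empty(fmap.n_sites, dtype=np.int64)
    right = np.empty(fmap.n_sites, dtype=np.int64)
    for name in fmap.chrom_names:
        ci = fmap.chrom_index(name)
        sl = fmap.chrom_fragments(name)
        smask = fmap.site_chrom == ci
        pos = fmap.site_pos[smask]
        r = sl.start + np.searchsorted(fmap.frag_start[sl], pos)
        l = np.where(r > sl.start, r - 1, r)
        left[smask] = l
        right[smask] = r
    return left, right


def background_site_probabilities(model: ContactModel, fmap: FragmentMap) -> np.ndarray:
    """Per-site background methylation probability for the Dam-only control.

    Proportional to the accessibility weight of the site's flanking
    fragments, scaled so the genome-wide expected number of methylated sites
    equals ``background_total``.
    """
    if fmap.n_sites == 0:
        return np.empty(0)
    w = model.background_weights
    if w is None:
        site_w = np.ones(fmap.n_sites)
    else:
        w = np.asarray(w, dtype=float)
        if len(w) != fmap.n_fragments:
            raise ValueError("background_weights must have one entry per fragment")
        if (w < 0).any():
            raise ValueError("background_weights must be non-negative")
        left, right = _site_flank_fragments(fmap)
        site_w = 0.5 * (w[left] + w[right])
    total = site_w.sum()
    if total == 0:
        return np.zeros(fmap.n_sites)
    return np.clip(model.background_total * site_w / total, 0.0, 0.999)


def site_methylation_probabilities(
    model: ContactModel,
    fmap: FragmentMap,
    condition: str,
    partner_active: Sequence[bool] | None = None,
) -> np.ndarray:
    """Analytic per-site methylation probability for one cell class.

    For the treatment condition, ``partner_active`` flags which planted
    partners are in contact in this cell (default: none).  The bait anchor
    is always engaged.  Anchored and background components combine as
    independent methylation opportunities.
    """
    condition = normalize_condition(condition)
    if condition == UNINDUCED:
        return np.full(fmap.n_sites, model.leak_rate)
    q = background_site_probabilities(model, fmap)
    if condition == DAM_ONLY:
        return q

    anchors = [(model.bait[0], model.bait_midpoint)]
    if partner_active is not None:
        for active, p in zip(partner_active, model.partners):
            if active:
                anchors.append((p.chrom, p.midpoint))
    d = np.full(fmap.n_sites, np.inf)
    for chrom, mid in anchors:
        ci = fmap.chrom_index(chrom)
        mask = fmap.site_chrom == ci
        d[mask] = np.minimum(d[mask], np.abs(fmap.site_pos[mask] - mid))
    p_anchor = model.p_max * np.exp(-d / model.decay_length)
    return 1.0 - (1.0 - p_anchor) * (1.0 - q)


def _check_bait(model: ContactModel, fmap: FragmentMap) -> None:
    ci = fmap.chrom_index(model.bait[0])
    pos = fmap.site_pos[fmap.site_chrom == ci]
    if len(pos) == 0 or np.abs(pos - model.bait_midpoint).min() > 2 * model.decay_length:
        warnings.warn(
            "bait has no GATC site within 2 decay lengths; it cannot be labeled"
        )


def simulate_methylation(
    model: ContactModel,
    fmap: FragmentMap,
    condition: str,
    n_cells: int,
    seed=None,
) -> MethylationState:
    """Realize per-cell methylation flags for one condition.

    Cells are independent.  In the treatment condition each partner's
    contact fires per cell with its ``contact_prob``; within a cell, sites
    are methylated independently given the engaged anchor set.
    """
    condition = normalize_condition(condition)
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = _rng(seed)
    n_sites = fmap.n_sites
    flags = np.zeros((n_cells, n_sites), dtype=bool)
    partner_active = None

    if condition == TREATMENT:
        _check_bait(model, fmap)
        P = len(model.partners)
        probs = np.array([p.contact_prob for p in model.partners])
        partner_active = rng.random((n_cells, P)) < probs[None, :] if P else np.zeros(
            (n_cells, 0), dtype=bool
        )
        patterns, inverse = np.unique(partner_active, axis=0, return_inverse=True)
        for k, pat in enumerate(patterns):
            idx = np.flatnonzero(inverse == k)
            p_site = site_methylation_probabilities(model, fmap, condition, pat)
            _fill_bernoulli(flags, idx, p_site, rng)
    else:
        p_site = site_methylation_probabilities(model, fmap, condition)
        _fill_bernoulli(flags, np.arange(n_cells), p_site, rng)
    return MethylationState(flags=flags, condition=condition, partner_active=partner_active)


def _fill_bernoulli(flags, rows, p_site, rng, chunk_floats: int = 5_000_000) -> None:
    n_sites = flags.shape[1]
    step = max(1, chunk_floats // max(1, n_sites))
    for i in range(0, len(rows), step):
        block = rows[i : i + step]
        flags[block, :] = rng.random((len(block), n_sites)) < p_site[None, :]


def select_amplifiable_fragments(
    state: MethylationState, fmap: FragmentMap
) -> list[np.ndarray]:
    """Fragments surviving DpnI -> adaptor -> DpnII selection, per cell.

    A fragment survives iff it is non-terminal and both flanking GATC sites
    are methylated; inter-site fragments contain no internal GATC, so DpnII
    destruction reduces to exactly this rule.
    """
    if state.flags.shape[1] != fmap.n_sites:
        raise ValueError("methylation state does not match the fragment map")
    amp = state.flags[:, fmap.pair_left_site] & state.flags[:, fmap.pair_right_site]
    return [fmap.pair_fragment[row] for row in amp]


def library_from_state(state: MethylationState, fmap: FragmentMap) -> np.ndarray:
    """Per-fragment molecule counts summed over cells (library multiset)."""
    amp = state.flags[:, fmap.pair_left_site] & state.flags[:, fmap.pair_right_site]
    m = np.zeros(fmap.n_fragments, dtype=np.int64)
    m[fmap.pair_fragment] = amp.sum(axis=0)
    return m


def simulate_library(
    model: ContactModel,
    fmap: FragmentMap,
    condition: str,
    n_cells: int,
    seed=None,
) -> np.ndarray:
    """Per-fragment molecule counts, sampled from the exact marginal law.

    Equivalent in distribution (marginally per fragment) to running
    ``simulate_methylation`` + ``select_amplifiable_fragments`` and summing
    over cells, but scales to the large cell numbers of a real induction:
    cells are partitioned by partner-activation pattern (multinomial) and
    each fragment's count is binomial within a pattern class.
    """
    condition = normalize_condition(condition)
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = _rng(seed)
    m = np.zeros(fmap.n_fragments, dtype=np.int64)
    if fmap.n_sites == 0:
        return m

    def pair_prob(p_site: np.ndarray) -> np.ndarray:
        return p_site[fmap.pair_left_site] * p_site[fmap.pair_right_site]

    if condition == TREATMENT:
        _check_bait(model, fmap)
        P = len(model.partners)
        if P > 16:
            raise ValueError("class enumeration supports at most 16 partners")
        probs = np.array([p.contact_prob for p in model.partners])
        n_classes = 1 << P
        class_p = np.empty(n_classes)
        for k in range(n_classes):
            bits = [(k >> j) & 1 for j in range(P)]
            class_p[k] = np.prod(np.where(bits, probs, 1.0 - probs)) if P else 1.0
        n_k = rng.multinomial(n_cells, class_p)
        counts = np.zeros(len(fmap.pair_fragment), dtype=np.int64)
        for k in np.flatnonzero(n_k):
            pat = [(k >> j) & 1 for j in range(P)]
            p_site = site_methylation_probabilities(model, fmap, condition, pat)
            counts += rng.binomial(int(n_k[k]), pair_prob(p_site))
        m[fmap.pair_fragment] = counts
    else:
        p_site = site_methylation_probabilities(model, fmap, condition)
        m[fmap.pair_fragment] = rng.binomial(n_cells, pair_prob(p_site))
    return m


# ---------------------------------------------------------------------------
# read generation


@dataclasses.dataclass
class ReadPairBatch:
    """Paired-end reads stored as padded byte matrices.

    R1 is the fragment 5' end read on the forward strand; R2 is the reverse
    complement of the fragment 3' end.  Fragments shorter than the read
    length yield truncated reads; ``lens`` holds the valid length per pair.
    ``truth_fragment`` carries the source fragment's global index for
    diagnostics (-1 if unknown).
    """

    r1: np.ndarray  # (n, read_len) uint8 ASCII, zero padded
    r2: np.ndarray
    lens: np.ndarray  # (n,) int32
    truth_fragment: np.ndarray  # (n,) int64
    read_len: int = 151

    @property
    def n(self) -> int:
        return len(self.lens)

    def write_fastq(self, path_r1, path_r2) -> None:
        for path, mat in ((path_r1, self.r1), (path_r2, self.r2)):
            opener = gzip.open if str(path).endswith(".gz") else open
            with opener(path, "wt") as fh:
                for i in range(self.n):
                    l = int(self.lens[i])
                    seq = mat[i, :l].tobytes().decode("ascii")
                    fh.write(f"@pair{i}:frag{int(self.truth_fragment[i])}\n{seq}\n+\n{'I' * l}\n")

    @classmethod
    def from_fastq(cls, path_r1, path_r2, read_len: int = 151) -> "ReadPairBatch":
        import pysam

        seqs1, seqs2, names = [], [], []
        with pysam.FastxFile(str(path_r1)) as fh:
            for rec in fh:
                seqs1.append(rec.sequence.upper())
                names.append(rec.name)
        with pysam.FastxFile(str(path_r2)) as fh:
            seqs2 = [rec.sequence.upper() for rec in fh]
        if len(seqs1) != len(seqs2):
            raise ValueError("R1/R2 FASTQ files differ in record count")
        n = len(seqs1)
        lens = np.array([len(s) for s in seqs1], dtype=np.int32)
        r1 = np.zeros((n, read_len), dtype=np.uint8)
        r2 = np.zeros((n, read_len), dtype=np.uint8)
        for i, (a, b) in enumerate(zip(seqs1, seqs2)):
            r1[i, : len(a)] = seq_to_u8(a)[:read_len]
            r2[i, : len(b)] = seq_to_u8(b)[:read_len]
        truth = np.full(n, -1, dtype=np.int64)
        pat = re.compile(r"frag(\d+)$")
        for i, name in enumerate(names):
            mm = pat.search(name)
            if mm:
                truth[i] = int(mm.group(1))
        return cls(r1=r1, r2=r2, lens=lens, truth_fragment=truth, read_len=read_len)


def generate_reads(
    library: np.ndarray,
    genome: Genome,
    fmap: FragmentMap,
    read_len: int = 151,
    paired: bool = True,
    error_rate: float = 0.0,
    amplification_dispersion: float = 0.0,
    depth: int = 30,
    seed=None,
) -> ReadPairBatch:
    """Paired-end reads from an amplified fragment library.

    ``library`` gives the molecule count per fragment.  Each molecule is
    amplified by an independent log-normal factor (sigma =
    ``amplification_dispersion``, unit mean); a fragment's read-pair count
    is its amplified mass scaled so the mean over represented fragments
    equals ``depth``.  With zero dispersion and uniform molecule counts
    every amplifiable fragment therefore appears in exactly ``depth`` pairs.
    Substitution errors are applied at ``error_rate`` per base.
    """
    if not paired:
        raise ValueError("only paired-end generation is supported")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = _rng(seed)
    library = np.asarray(library)
    occupied = np.flatnonzero(library > 0)
    if len(occupied) == 0:
        warnings.warn("empty library; returning an empty read batch")
        empty = np.zeros((0, read_len), dtype=np.uint8)
        return ReadPairBatch(empty, empty.copy(), np.zeros(0, np.int32), np.zeros(0, np.int64), read_len)

    mols = library[occupied].astype(np.int64)
    if amplification_dispersion > 0:
        sigma = float(amplification_dispersion)
        draws = rng.lognormal(-0.5 * sigma**2, sigma, size=int(mols.sum()))
        owner = np.repeat(np.arange(len(occupied)), mols)
        w = np.bincount(owner, weights=draws, minlength=len(occupied))
    else:
        w = mols.astype(float)
    copies = np.maximum(1, np.rint(depth * w / w.mean()).astype(np.int64))

    chrom_u8 = [seq_to_u8(seq) for _, seq in genome.chromosomes]
    n_occ = len(occupied)
    tmpl1 = np.zeros((n_occ, read_len), dtype=np.uint8)
    tmpl2 = np.zeros((n_occ, read_len), dtype=np.uint8)
    tlen = np.empty(n_occ, dtype=np.int32)
    comp = np.arange(256, dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp[a] = b
    for j, f in enumerate(occupied):
        ci = int(fmap.frag_chrom[f])
        s, e = int(fmap.frag_start[f]), int(fmap.frag_end[f])
        l = min(e - s, read_len)
        tlen[j] = l
        tmpl1[j, :l] = chrom_u8[ci][s : s + l]
        tmpl2[j, :l] = comp[chrom_u8[ci][e - l : e]][::-1]

    r1 = np.repeat(tmpl1, copies, axis=0)
    r2 = np.repeat(tmpl2, copies, axis=0)
    lens = np.repeat(tlen, copies)
    truth = np.repeat(occupied, copies)

    if error_rate > 0:
        for mat in (r1, r2):
            _inject_errors(mat, lens, error_rate, rng)
    return ReadPairBatch(r1=r1, r2=r2, lens=lens.astype(np.int32), truth_fragment=truth, read_len=read_len)


def _inject_errors(mat: np.ndarray, lens: np.ndarray, rate: float, rng) -> None:
    """Uniform substitution errors over the valid bases of a read matrix."""
    cum = np.concatenate([[0], np.cumsum(lens, dtype=np.int64)])
    total = int(cum[-1])
    k = rng.binomial(total, rate)
    if k == 0:
        return
    flat = rng.integers(0, total, size=k)
    rows = np.searchsorted(cum, flat, side="right") - 1
    offs = flat - cum[rows]
    cur = mat[rows, offs]
    code = CODE[cur]
    ok = code != 255  # skip N or padding (padding never sampled)
    shift = rng.integers(1, 4, size=k)
    newc = (code[ok] + shift[ok]) % 4
    mat[rows[ok], offs[ok]] = DECODE_BASES[newc]
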