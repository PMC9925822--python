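# Methods

This note documents the generative model behind `damloop.simulate`, the
statistical procedures in `damloop.counts`, the numerical conventions used
throughout, and what the synthetic benchmarks do and do not demonstrate.

## Coordinates and the fragment map

All internal coordinates are 0-based, half-open; BED output keeps that
convention. Fragment boundaries are placed at GATC **motif starts**, so a
fragment's length is the distance between consecutive motif starts and the
fragments tile each chromosome exactly (no gaps, no overlaps). The true
enzymes cut at a fixed offset inside GATC; since every fragment is bounded
by whole motifs, any consistent offset convention yields the same fragment
identities, and the motif-start convention keeps the tiling invariant
trivial to verify. Chromosome-end fragments are flagged `terminal` and
excluded from amplifiable sets: they lack a methylatable site on one side.
Motifs overlapping N never match; fragments may contain N.

## Labeling model

Methylation is simulated per cell over exactly the GATC sites of the
fragment map.

- **Treatment (`gRNA+Cas9+`).** The bait anchor is engaged in every cell.
  Each planted partner fires independently per cell with its
  `contact_prob`. Given the engaged anchor set, a site at distance `d`
  from the nearest anchor midpoint (same chromosome; anchors on other
  chromosomes do not contribute) is methylated with probability
  `p_max · exp(−d/λ)`, combined with the background component as two
  independent methylation opportunities. The kernel is a modeling choice:
  the assay's own literature reports no measured labeling radius, and an
  exponential is the minimal monotone-local model with a single length
  scale. Defaults: `λ = 1500 bp`, `p_max = 0.8`. Keeping `p_max < 1`
  reflects the deliberately short induction window of the assay — longer
  Dam exposure saturates labeling, so the defaults represent a
  non-saturating pulse. Both parameters are configuration knobs, and the
  benchmark conclusions should be read as holding for this kernel family
  rather than one "true" value.
- **Dam-only control (`gRNA−Cas9+`).** Untargeted, accessibility-weighted
  background labeling: per-site probability proportional to the mean
  accessibility weight of the flanking fragments (uniform by default; a
  user BED can up-weight open chromatin), scaled so the genome-wide
  expected number of methylated sites per cell equals `background_total`
  (default 300 on the 1.5 Mb default genome, i.e. ≈5% of sites). The
  treatment condition includes the same background.
- **Uninduced control (`Cas9−`).** Constant per-site leak rate
  `ε = 0.005`, modeling residual fusion expression without induction.

Cells are independent; `n_cells` counts independent chromosome copies (no
homolog pairing). Two sampling routes are provided and property-tested
against each other and against the closed-form expectation:
`simulate_methylation` realizes per-cell site flags (used for
chemistry-level tests), while `simulate_library` draws per-fragment
molecule counts from the exact marginal law (multinomial over
partner-activation patterns, binomial within a pattern). The aggregated
route ignores the within-cell correlation between *adjacent* fragments
that share a site; per-fragment marginals — the quantity every downstream
statistic consumes — are exact. Default `n_cells = 100,000`, chosen so
background fragment occupancy is deep (mean ≈ 250 molecules per fragment),
the regime a real induction of millions of cells operates in; at shallow
occupancy the fragment-presence granularity, not sequencing noise, would
dominate the counts.

## Library chemistry and reads

A fragment is amplifiable in a cell iff it is non-terminal and **both**
flanking GATC sites are methylated. This is exactly the
DpnI→adaptor→DpnII selection: DpnI cuts only methylated GATC, producing
adaptor-ligatable ends; DpnII then destroys any fragment still containing
an unmethylated site; since inter-site fragments contain no internal GATC,
survival reduces to the two-flanks rule. The test suite verifies this
equivalence against a literal digestion simulation on hundreds of random
methylation patterns.

Amplification noise is per molecule: each library molecule receives an
independent log-normal amplification factor (σ = `amplification_dispersion`,
unit mean), and a fragment's read-pair count is its summed amplified mass
scaled so the mean over represented fragments equals `depth` (default 30).
With many molecules per fragment the per-molecule noise averages out,
which is what keeps the downstream Poisson test honest; a single
per-fragment noise factor would instead inject irreducible
overdispersion.

Reads are paired-end 151 bp, sonication-free: R1 is the fragment 5′ end on
the forward strand, R2 the reverse complement of the 3′ end, truncated for
fragments shorter than the read length; substitution errors at
`error_rate = 0.001`. FASTQ headers carry the source fragment index for
diagnostics. Because read coordinates are end-anchored, coordinate-level
duplicates in simulated data are genuine distinct molecules — the analysis
of simulated batches therefore runs with `dedup=False`, while the SAM
route (real libraries, sonicated ends) defaults to standard paired-end
coordinate deduplication.

## Read placement and counting

The built-in matcher is a seed-and-verify aligner: exact 16-mer seeds at
read offsets 0 and 16 located in a sorted key array, full-length mismatch
verification with a budget of `max(2, 0.1·len)`, mapq 60 for unique seeds.
It exists so the pipeline is self-contained on synthetic genomes; aligned
SAM is the production input. A properly placed pair is assigned to the
fragment containing its leftmost mapped base; pairs overhanging that
fragment's end by more than one read length are counted unassigned, as are
pairs below `min_mapq`. The bookkeeping identity
`assigned + unassigned = total − duplicates` is asserted exactly.

## Normalization and peak calling

The signal track is `log2(((t_i+c)/s_t)/((d_i+c)/s_d))` with size factors
`s` the total assigned counts and pseudocount `c = 1` count. The
uninduced control is used as a **mask**, not a denominator: fragments
whose uninduced CPM exceeds 5× the median fragment CPM are flagged and
zeroed, treating Dam-independent signal as a blacklist and avoiding the
instability of double ratios. Note the count-scale pseudocount makes
size-factor invariance exact only in the `c → 0` limit; the residual
deviation is O(c/count) and the tests pin both the exact (c = 0) and the
bounded-approximation (c = 1) statements.

Peaks: per non-terminal fragment, a one-sided Poisson test of `t_i`
against `μ_i = max(d_i·s_t/s_d, μ_floor)` with `μ_floor = 0.5` (guards
empty control fragments), Benjamini–Hochberg across all tested fragments,
significance at `q < 0.05` **and** `log2FC ≥ 1`, and merging of
significant fragments separated by ≤ 2 non-significant fragments. Peak
score is the best −log10 q among members (q floored at 1e−300; BED scores
capped at 1000). The caller is deliberately explicit and fully specified
rather than delegating to an external peak caller with unstated
parameters. Replicate consensus keeps merged intervals supported by ≥ 2
of 3 replicates under a 1 bp-overlap rule.

## Interpretation statistics

The permutation null for peak/region overlap shuffles peak start positions
uniformly **within their own chromosome**, preserving lengths and
non-overlap (free-space placement, exact). Preserving chromosome
assignment matters because inter-chromosomal excess is precisely the
biological claim such overlaps support; a genome-wide shuffle would
destroy it. `perm_p = (1 + #{perm ≥ obs})/(n_perm + 1)`.

Domainogram windows are odd-sized and symmetric, truncated symmetrically
at chromosome edges (clip mode) or wrapped (cyclic mode, which conserves
the row mean exactly); the scale-1 row is the input, bit-exact.
Nearest-TSS annotation breaks exact distance ties lexicographically —
determinism over biological nuance. Gene-list enrichment is a
hypergeometric upper tail against the annotatable-gene universe.

## Validation arithmetic

Digestion QC: `efficiency% = 100 − 100/2^ΔΔCt`, pass at ≥ 80%. 3C:
`IF = (S_site/S_ref)/(B_site/B_ref)`; the internal reference cancels
template amount (exactly — asserted as a whole-library scaling invariance)
and the BAC control library cancels per-primer amplification bias;
equimolar BAC mixing is assumed. Ct tables convert to intensities via
`E^(−Ct)` with E fixed at 2.0 unless supplied. Expression:
`fold = 2^−ΔΔCt`, replicate Cts averaged before differencing, SDs
propagated in quadrature. FISH: a probeA spot colocalizes if a probeB
spot in the same nucleus lies within τ (default 1.0 µm — a declared
approximation to the signal-overlap criterion used with imaging data);
frequencies come with Wilson 95% intervals. The synthetic nucleus
generator plants colocalization with probability p (coincident up to
isotropic Gaussian noise, 0.25 µm) inside a 5 µm-radius nucleus, so the
measured frequency includes a small chance-overlap excess (≈0.006 at the
defaults). The power calculator is the standard two-proportion
z-approximation, cross-checked by Monte-Carlo power simulation of the
pooled z-test.

## Benchmark scales

The default benchmark (three 500 kb chromosomes, GATC spacing 256 bp,
five partners, depth 30, three replicates, ten seeds) runs the full
read-level pipeline in a few minutes on one CPU. Reciprocal-bait
simulations use a reduced geometry (three 200 kb chromosomes, 50,000
cells, one replicate) since each partner×seed combination is an
independent end-to-end run; the contact geometry is scaled
proportionally. Null calibration uses background-vs-background library
pairs through the identical read-level path.

## What the synthetic data does not show

The simulator emulates the assay's chemistry and its controls, not the
full complexity of real chromatin: no TAD structure or distance-dependent
polymer background, no accessibility bias unless supplied, no homolog
pairing, no adaptor read-through or quality decay, no mappability
structure beyond what a random genome provides, and an assumed (if
configurable) labeling kernel. Passing benchmarks therefore demonstrate
that the pipeline's logic and statistics are correct and calibrated under
the stated generative model — not that any particular biological dataset
will behave as cleanly. Reported peak counts from real libraries depend
on caller parameters and sequencing depth and are not reproduced here.
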