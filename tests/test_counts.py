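"""Read assignment, normalization, peak calling and consensus."""

import numpy as np
import pandas as pd
import pytest

from damloop import (
    FragmentCounts,
    SeedMatcher,
    assign_reads,
    call_peaks,
    fragment_of_pairs,
    generate_reads,
    normalize,
    pairs_from_sam,
    query_gatc_qpcr,
    replicate_consensus,
)
from damloop.counts import PeakSet


def _counts(fmap, values, sample="s", condition="c"):
    values = np.asarray(values, dtype=np.int64)
    return FragmentCounts(
        sample_id=sample,
        condition=condition,
        counts=values,
        unassigned=0,
        total_pairs=int(values.sum()),
        duplicates_removed=0,
    )


class TestAssignReads:
    def test_duplicates_collapse_to_one(self, small_fmap):
        pairs = pd.DataFrame(
            {
                "chrom": ["chr1"] * 10,
                "start": [1000] * 10,
                "end": [1300] * 10,
                "orientation": ["FR"] * 10,
                "mapq": [60] * 10,
            }
        )
        fc = assign_reads(pairs, small_fmap, dedup=True)
        assert fc.assigned == 1
        assert fc.duplicates_removed == 9
        assert fc.total_pairs == 10

    def test_empty_input(self, small_fmap):
        pairs = pd.DataFrame(columns=["chrom", "start", "end", "orientation", "mapq"])
        fc = assign_reads(pairs, small_fmap)
        assert fc.assigned == 0 and fc.unassigned == 0 and fc.total_pairs == 0

    def test_unknown_reference_rejected(self, small_fmap):
        pairs = pd.DataFrame(
            {"chrom": ["chrZ"], "start": [0], "end": [100], "orientation": ["FR"], "mapq": [60]}
        )
        with pytest.raises(ValueError, match="chrZ"):
            assign_reads(pairs, small_fmap)

    def test_boundary_crossing_pairs_unassigned(self, small_genome, small_fmap):
        # a pair spanning far past its fragment's end is an artifact
        f = int(np.flatnonzero(~small_fmap.frag_terminal)[0])
        s = int(small_fmap.frag_start[f])
        e = int(small_fmap.frag_end[f])
        pairs = pd.DataFrame(
            {
                "chrom": [small_fmap.chrom_names[small_fmap.frag_chrom[f]]] * 2,
                "start": [s, s],
                "end": [e + 10, e + 500],
                "orientation": ["FR", "FR"],
                "mapq": [60, 60],
            }
        )
        fc = assign_reads(pairs, small_fmap, read_len=151, dedup=False)
        assert fc.counts[f] == 1
        assert fc.unassigned == 1

    def test_count_conservation_invariant(self, small_genome, small_fmap, rng):
        lib = np.zeros(small_fmap.n_fragments, dtype=np.int64)
        lib[~small_fmap.frag_terminal] = rng.integers(0, 3, (~small_fmap.frag_terminal).sum())
        batch = generate_reads(lib, small_genome, small_fmap, depth=3, error_rate=0.005, seed=5)
        pairs = SeedMatcher(small_genome).match_pairs(batch)
        fc = assign_reads(pairs, small_fmap, min_mapq=10, dedup=False)
        assert fc.assigned + fc.unassigned == fc.total_pairs - fc.duplicates_removed

    def test_simulated_reads_assigned_to_true_fragment(self, small_genome, small_fmap):
        lib = np.zeros(small_fmap.n_fragments, dtype=np.int64)
        lib[~small_fmap.frag_terminal] = 1
        batch = generate_reads(lib, small_genome, small_fmap, depth=3, seed=6)
        pairs = SeedMatcher(small_genome).match_pairs(batch)
        frag = fragment_of_pairs(pairs, small_fmap)
        ok = frag >= 0
        assert (frag[ok] == batch.truth_fragment[ok]).mean() >= 0.99


SAM_TEMPLATE = """\
@HD\tVN:1.6\tSO:unsorted
@SQ\tSN:{chrom}\tLN:{length}
p1\t99\t{chrom}\t{s1}\t60\t50M\t=\t{s2}\t100\t{seq}\t*
p1\t147\t{chrom}\t{s2}\t60\t50M\t=\t{s1}\t-100\t{seq}\t*
lonely\t99\t{chrom}\t{s1}\t60\t50M\t=\t{s2}\t100\t{seq}\t*
"""


def test_sam_pair_reading(tmp_path, small_genome, small_fmap):
    f = int(np.flatnonzero(~small_fmap.frag_terminal)[2])
    chrom = small_fmap.chrom_names[small_fmap.frag_chrom[f]]
    s = int(small_fmap.frag_start[f])
    seq = small_genome.sequence(chrom)[s : s + 50]
    sam = SAM_TEMPLATE.format(
        chrom=chrom, length=len(small_genome.sequence(chrom)), s1=s + 1, s2=s + 51, seq=seq
    )
    path = tmp_path / "reads.sam"
    path.write_text(sam)
    pairs = pairs_from_sam(path)
    assert len(pairs) == 2  # one proper pair + one unmated read
    placed = pairs[pairs["chrom"] != "*"]
    assert len(placed) == 1
    assert int(placed["start"].iloc[0]) == s
    fc = assign_reads(pairs, small_fmap, dedup=True)
    assert fc.counts[f] == 1
    assert fc.unassigned == 1


class TestNormalize:
    def test_identity_when_treatment_equals_control(self, small_fmap, rng):
        v = rng.integers(1, 50, small_fmap.n_fragments)
        track = normalize(_counts(small_fmap, v), _counts(small_fmap, v))
        assert np.allclose(track.values, 0.0)

    def test_global_scaling_invariance(self, small_fmap, rng):
        # the size-factor normalization itself is exactly scale invariant
        t = rng.integers(1, 50, small_fmap.n_fragments)
        d = rng.integers(1, 50, small_fmap.n_fragments)
        a = normalize(_counts(small_fmap, t), _counts(small_fmap, d), pseudocount=0.0)
        b = normalize(_counts(small_fmap, 10 * t), _counts(small_fmap, d), pseudocount=0.0)
        assert np.allclose(a.values, b.values)
        # with the default pseudocount the deviation is O(c / count)
        a1 = normalize(_counts(small_fmap, 100 * t), _counts(small_fmap, 100 * d))
        b1 = normalize(_counts(small_fmap, 1000 * t), _counts(small_fmap, 100 * d))
        assert np.abs(a1.values - b1.values).max() < 0.02

    def test_antisymmetry(self, small_fmap, rng):
        t = rng.integers(0, 50, small_fmap.n_fragments)
        d = rng.integers(0, 50, small_fmap.n_fragments)
        a = normalize(_counts(small_fmap, t), _counts(small_fmap, d))
        b = normalize(_counts(small_fmap, d), _counts(small_fmap, t))
        assert np.allclose(a.values, -b.values)

    def test_five_fragment_worked_example(self):
        # expected values computed independently from the formula:
        # log2(((t+1)/36) / ((d+1)/9))
        t = [10, 0, 5, 20, 1]
        d = [1, 0, 5, 2, 1]
        expected = [0.459431618637297, -2.0, -2.0, 0.807354922057604, -2.0]

        class TinyMap:
            n_fragments = 5

        track = normalize(
            _counts(TinyMap, np.array(t)), _counts(TinyMap, np.array(d)), pseudocount=1.0
        )
        assert np.allclose(track.values, expected)

    def test_zero_total_rejected(self, small_fmap):
        z = np.zeros(small_fmap.n_fragments, dtype=np.int64)
        o = np.ones(small_fmap.n_fragments, dtype=np.int64)
        with pytest.raises(ValueError, match="zero total"):
            normalize(_counts(small_fmap, z), _counts(small_fmap, o))

    def test_uninduced_leak_masking(self, small_fmap):
        n = small_fmap.n_fragments
        t = np.full(n, 10, dtype=np.int64)
        d = np.full(n, 5, dtype=np.int64)
        u = np.zeros(n, dtype=np.int64)
        u[3] = 1000  # a leaky fragment
        track = normalize(_counts(small_fmap, t), _counts(small_fmap, d), _counts(small_fmap, u))
        assert track.mask[3]
        assert track.values[3] == 0.0
        assert not track.mask[4]


class TestCallPeaks:
    def test_extreme_single_fragment_enrichment(self, small_fmap):
        n = small_fmap.n_fragments
        t = np.full(n, 2, dtype=np.int64)
        d = np.full(n, 2, dtype=np.int64)
        f = int(np.flatnonzero(~small_fmap.frag_terminal)[10])
        t[f] = 100
        peaks = call_peaks(_counts(small_fmap, t), _counts(small_fmap, d), small_fmap)
        assert len(peaks) == 1
        row = peaks.df.iloc[0]
        assert row["start"] == small_fmap.frag_start[f]
        assert row["end"] == small_fmap.frag_end[f]
        assert row["score"] > 10

    def test_identical_samples_yield_no_peaks(self, small_fmap, rng):
        v = rng.integers(0, 40, small_fmap.n_fragments)
        peaks = call_peaks(_counts(small_fmap, v), _counts(small_fmap, v), small_fmap, fdr=0.5)
        assert len(peaks) == 0

    def test_merging_across_small_gaps(self, small_fmap):
        n = small_fmap.n_fragments
        t = np.full(n, 2, dtype=np.int64)
        d = np.full(n, 2, dtype=np.int64)
        idx = np.flatnonzero(~small_fmap.frag_terminal)
        a, b = int(idx[5]), int(idx[5]) + 3  # two enriched fragments, gap of 2
        t[a] = 200
        t[b] = 200
        peaks = call_peaks(_counts(small_fmap, t), _counts(small_fmap, d), small_fmap,
                           merge_gap_fragments=2)
        assert len(peaks) == 1
        assert peaks.df.iloc[0]["n_fragments"] == 4
        peaks2 = call_peaks(_counts(small_fmap, t), _counts(small_fmap, d), small_fmap,
                            merge_gap_fragments=1)
        assert len(peaks2) == 2

    def test_peak_boundaries_on_fragment_boundaries(self, small_fmap, rng):
        n = small_fmap.n_fragments
        t = rng.poisson(20, n).astype(np.int64)
        d = rng.poisson(20, n).astype(np.int64)
        t[40:45] += 300
        peaks = call_peaks(_counts(small_fmap, t), _counts(small_fmap, d), small_fmap)
        starts = set(small_fmap.frag_start.tolist())
        ends = set(small_fmap.frag_end.tolist())
        for _, row in peaks.df.iterrows():
            assert row["start"] in starts and row["end"] in ends

    def test_invalid_fdr_rejected(self, small_fmap):
        v = np.ones(small_fmap.n_fragments, dtype=np.int64)
        with pytest.raises(ValueError, match="fdr"):
            call_peaks(_counts(small_fmap, v), _counts(small_fmap, v), small_fmap, fdr=1.5)


def _peakset(intervals):
    df = pd.DataFrame(
        [
            {"chrom": c, "start": s, "end": e, "score": 5.0, "n_fragments": 1, "max_log2fc": 2.0}
            for c, s, e in intervals
        ],
        columns=["chrom", "start", "end", "score", "n_fragments", "max_log2fc"],
    )
    return PeakSet(df=df, params={})


class TestReplicateConsensus:
    def test_identical_sets(self):
        ivs = [("chr1", 100, 200), ("chr2", 50, 80)]
        cons = replicate_consensus([_peakset(ivs)] * 3, min_support=3)
        assert cons.df[["chrom", "start", "end"]].values.tolist() == [
            list(x) for x in ivs
        ]

    def test_disjoint_sets_empty(self):
        a = _peakset([("chr1", 0, 100)])
        b = _peakset([("chr1", 200, 300)])
        assert len(replicate_consensus([a, b], min_support=2)) == 0

    def test_min_support_bounds(self):
        a = _peakset([("chr1", 0, 100)])
        with pytest.raises(ValueError, match="min_support"):
            replicate_consensus([a, a], min_support=3)

    def test_matches_brute_force_sweep(self, rng):
        def brute(sets, min_support, span=2000):
            # base-level occupancy union, then per-merged-interval support
            cover = np.zeros(span, dtype=bool)
            for s in sets:
                for _, r in s.df.iterrows():
                    cover[r["start"] : r["end"]] = True
            out = []
            i = 0
            while i < span:
                if cover[i]:
                    j = i
                    while j < span and cover[j]:
                        j += 1
                    support = sum(
                        any(r["start"] < j and r["end"] > i for _, r in s.df.iterrows())
                        for s in sets
                    )
                    if support >= min_support:
                        out.append((i, j))
                    i = j
                else:
                    i += 1
            return out

        for trial in range(20):
            sets = []
            for _ in range(3):
                starts = rng.integers(0, 1900, 5)
                ivs = [("chr1", int(s), int(s + rng.integers(20, 120))) for s in starts]
                sets.append(_peakset(ivs))
            cons = replicate_consensus(sets, min_support=2)
            got = [(int(r["start"]), int(r["end"])) for _, r in cons.df.iterrows()]
            assert got == brute(sets, 2)


class TestQpcrQuery:
    def test_flanking_fragments_and_mean(self, small_fmap):
        from damloop.counts import NormalizedTrack

        values = np.arange(small_fmap.n_fragments, dtype=float)
        track = NormalizedTrack(values=values, mask=np.zeros(small_fmap.n_fragments, bool), meta={})
        pos = int(small_fmap.sites["chr1"][4])
        out = query_gatc_qpcr(track, small_fmap, [("chr1", pos)])
        left, right = small_fmap.fragments_flanking_site("chr1", pos)
        assert out.iloc[0]["left_value"] == values[left]
        assert out.iloc[0]["right_value"] == values[right]
        assert out.iloc[0]["mean_value"] == (values[left] + values[right]) / 2
        assert not out.iloc[0]["masked"]

    def test_masked_site_flagged_null(self, small_fmap):
        from damloop.counts import NormalizedTrack

        mask = np.zeros(small_fmap.n_fragments, dtype=bool)
        pos = int(small_fmap.sites["chr1"][4])
        left, _ = small_fmap.fragments_flanking_site("chr1", pos)
        mask[left] = True
        track = NormalizedTrack(
            values=np.zeros(small_fmap.n_fragments), mask=mask, meta={}
        )
        out = query_gatc_qpcr(track, small_fmap, [("chr1", pos)])
        assert out.iloc[0]["masked"]
        assert np.isnan(out.iloc[0]["mean_value"])

    def test_non_site_rejected(self, small_fmap):
        from damloop.counts import NormalizedTrack

        track = NormalizedTrack(
            values=np.zeros(small_fmap.n_fragments),
            mask=np.zeros(small_fmap.n_fragments, bool),
            meta={},
        )
        with pytest.raises(ValueError, match="not a GATC site"):
            query_gatc_qpcr(track, small_fmap, [("chr1", 1)])
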