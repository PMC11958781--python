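"""Consensus building, RPKM quantification, the fold rule and annotation."""

import math

import numpy as np
import pytest

from succer.core import FragmentIndex, GeneModel, Region, SignalTrack
from succer.ders import (
    DERConfig,
    GAIN,
    LOSS,
    MetaProfile,
    RPKMMatrix,
    annotate_feature,
    build_consensus,
    call_ders,
    der_center_profile,
    distance_summary,
    meta_profile,
    quantify_regions,
)
from succer.ders import DER


def naive_fold_rule(mean_ctrl, mean_case, tau=2.0, eps=0.5):
    """Independent per-region reimplementation of the GAIN/LOSS rule."""
    ratio = (mean_case + eps) / (mean_ctrl + eps)
    if ratio > tau:
        return GAIN
    if 1 / ratio > tau:
        return LOSS
    return None


def make_matrix(values, groups=None):
    values = np.asarray(values, dtype=float)
    n, s = values.shape
    samples = [f"s{j}" for j in range(s)]
    groups = groups or {
        f"s{j}": ("ctrl" if j < s // 2 else "case") for j in range(s)
    }
    regions = [Region("chr1", 1000 * i, 1000 * i + 500, name=f"r{i}")
               for i in range(n)]
    return RPKMMatrix(regions, samples, values, groups)


class TestConsensus:
    def test_identical_peak_sets_reproduce_themselves(self):
        peaks = [Region("chr1", 0, 100), Region("chr1", 500, 700)]
        consensus, prov = build_consensus({"a": peaks, "b": peaks})
        assert [(r.start, r.end) for r in consensus] == [(0, 100), (500, 700)]
        assert all(samples == ["a", "b"] for samples in prov.values())

    def test_disjoint_sets_concatenate(self):
        consensus, prov = build_consensus({
            "a": [Region("chr1", 0, 100)],
            "b": [Region("chr1", 500, 700)],
        })
        assert len(consensus) == 2
        assert prov[consensus[0].name] == ["a"]
        assert prov[consensus[1].name] == ["b"]

    def test_overlapping_peaks_merge(self):
        consensus, _ = build_consensus({
            "a": [Region("chr1", 0, 100)],
            "b": [Region("chr1", 50, 150)],
        })
        assert [(r.start, r.end) for r in consensus] == [(0, 150)]

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError, match="no peaks"):
            build_consensus({"a": []})


class TestQuantification:
    def test_rpkm_formula(self):
        region = Region("chr1", 0, 1000, name="r0")
        frags = [Region("chr1", 10, 110)] * 50 + [
            Region("chr1", 5000, 5100)
        ] * 999_950
        index = FragmentIndex(frags)
        matrix = quantify_regions(
            [region], {"s": index}, {"s": "ctrl", "t": "case"}
        )
        assert matrix.values[0, 0] == pytest.approx(50.0)

    def test_zero_fragments_give_zero_rpkm(self):
        region = Region("chr1", 0, 1000, name="r0")
        index = FragmentIndex([Region("chr1", 5000, 5100)])
        matrix = quantify_regions([region], {"s": index}, {"s": "ctrl"})
        assert matrix.values[0, 0] == 0.0

    def test_track_mode_takes_region_mean(self):
        track = SignalTrack([(Region("chr1", 0, 2000), 7.5)])
        matrix = quantify_regions(
            [Region("chr1", 100, 600, name="r0")], {"s": track},
            {"s": "ctrl"}, mode="track",
        )
        assert matrix.values[0, 0] == pytest.approx(7.5)

    def test_rpkm_invariant_under_doubling(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 9000, size=500)
        frags = [Region("chr1", int(s), int(s) + 100) for s in starts]
        region = Region("chr1", 2000, 2600, name="r0")
        single = quantify_regions([region], {"s": FragmentIndex(frags)},
                                  {"s": "ctrl"})
        doubled = quantify_regions([region], {"s": FragmentIndex(frags * 2)},
                                   {"s": "ctrl"})
        assert single.values[0, 0] == pytest.approx(
            doubled.values[0, 0], abs=1e-9
        )

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="library size 0"):
            quantify_regions(
                [Region("chr1", 0, 100, name="r0")],
                {"s": FragmentIndex([])}, {"s": "ctrl"},
            )


class TestFoldRule:
    def test_gain_with_pseudocount_arithmetic(self):
        matrix = make_matrix([[4.0, 4.0, 10.0, 10.0]])
        (der,) = call_ders(matrix)
        assert der.der_class == GAIN
        assert der.log2fc == pytest.approx(math.log2(10.5 / 4.5))

    def test_equal_means_call_nothing(self):
        assert call_ders(make_matrix([[5.0, 5.0, 5.0, 5.0]])) == []

    def test_pseudocount_handles_zero_signal(self):
        matrix = make_matrix([[3.0, 3.0, 0.0, 0.0]])
        (der,) = call_ders(matrix)
        assert der.der_class == LOSS
        assert der.log2fc == pytest.approx(math.log2(0.5 / 3.5))

    def test_matches_naive_rule_on_random_matrices(self):
        rng = np.random.default_rng(12)
        for _ in range(500):
            values = rng.gamma(1.0, 5.0, size=(6, 4))
            values[rng.random(size=values.shape) < 0.2] = 0.0
            matrix = make_matrix(values)
            called = {d.der_id: d.der_class for d in call_ders(matrix)}
            ctrl, case = matrix.group_means()
            for i, reg in enumerate(matrix.regions):
                assert called.get(reg.name) == naive_fold_rule(ctrl[i], case[i])

    def test_swapping_groups_swaps_classes(self):
        rng = np.random.default_rng(4)
        values = rng.gamma(1.0, 5.0, size=(20, 4))
        fwd = make_matrix(values)
        rev = make_matrix(values, groups={
            "s0": "case", "s1": "case", "s2": "ctrl", "s3": "ctrl"
        })
        flip = {GAIN: LOSS, LOSS: GAIN}
        fwd_calls = {d.der_id: d.der_class for d in call_ders(fwd)}
        rev_calls = {d.der_id: flip[d.der_class] for d in call_ders(rev)}
        assert fwd_calls == rev_calls

    def test_raising_threshold_never_adds_ders(self):
        rng = np.random.default_rng(8)
        values = rng.gamma(1.0, 5.0, size=(50, 4))
        matrix = make_matrix(values)
        previous = None
        for tau in (1.5, 2.0, 3.0, 5.0):
            ids = {d.der_id for d in call_ders(matrix, DERConfig(tau))}
            if previous is not None:
                assert ids <= previous
            previous = ids

    def test_sorted_by_absolute_fold_change_within_class(self):
        matrix = make_matrix([
            [1.0, 1.0, 10.0, 10.0],
            [1.0, 1.0, 100.0, 100.0],
            [50.0, 50.0, 1.0, 1.0],
        ])
        ders = call_ders(matrix)
        assert [d.der_class for d in ders] == [GAIN, GAIN, LOSS]
        assert abs(ders[0].log2fc) >= abs(ders[1].log2fc)

    def test_missing_group_rejected(self):
        matrix = make_matrix([[1.0, 2.0]], groups={"s0": "ctrl", "s1": "ctrl"})
        with pytest.raises(ValueError, match="group"):
            call_ders(matrix)


class TestAnnotation:
    def test_midpoint_at_tss_is_promoter(self, toy_genes):
        label, dist = annotate_feature(Region("chr1", 50, 150), toy_genes)
        assert label == "promoter-TSS"
        assert dist == 0.0

    def test_far_region_is_intergenic(self, toy_genes):
        label, dist = annotate_feature(Region("chr1", 5900, 6100), toy_genes)
        assert label == "intergenic"
        assert abs(dist) > 1000

    def test_intron_by_containment(self):
        gene = GeneModel("g", "chr1", "+", 1000, 2000, [(1000, 1200)])
        label, _ = annotate_feature(Region("chr1", 1400, 1600), [gene])
        assert label == "intron"
        # midpoint 1100 is 100 bp downstream of the TSS: just outside the
        # half-open promoter window [tss-1000, tss+100), so exon wins
        label, _ = annotate_feature(Region("chr1", 1000, 1200), [gene])
        assert label == "exon"
        # one bp earlier the midpoint (1099) is still promoter-proximal
        label, _ = annotate_feature(Region("chr1", 999, 1200), [gene])
        assert label == "promoter-TSS"

    def test_minus_strand_distance_sign(self):
        gene = GeneModel("g", "chr1", "-", 1000, 2000)
        # midpoint 500 bp beyond tx_end: downstream in genome = upstream of gene
        _, dist = annotate_feature(Region("chr1", 2450, 2550), [gene])
        assert dist == pytest.approx(1999 - 2500)  # negative = upstream

    def test_empty_gene_set_gives_intergenic_inf(self):
        label, dist = annotate_feature(Region("chr1", 0, 10), [])
        assert label == "intergenic"
        assert math.isinf(dist)

    def test_distance_summary_all_at_tss(self, toy_genes):
        ders = [
            DER(Region("chr1", 50, 150), 1, 5, 2.0, GAIN, "promoter-TSS", 0.0)
        ]
        dist_df, chrom_df = distance_summary(ders)
        row = dist_df.iloc[0]
        assert row["0-1kb"] == 1.0
        assert row["1-10kb"] == 0.0
        assert chrom_df["count"].sum() == 1

    def test_distance_summary_empty(self):
        dist_df, chrom_df = distance_summary([])
        assert dist_df.empty and chrom_df.empty


class TestProfiles:
    def test_constant_track_gives_flat_profiles(self):
        track = SignalTrack([(Region("chr1", 0, 50_000), 3.0)])
        genes = [GeneModel("g", "chr1", "+", 10_000, 14_000)]
        prof = meta_profile(track, genes)
        assert np.allclose(prof.values, 3.0)
        ders = [DER(Region("chr1", 20_000, 20_400, summit=200), 1, 5, 2, GAIN)]
        cprof = der_center_profile(track, ders)
        assert np.allclose(cprof.values, 3.0)

    def test_signal_at_tss_lands_in_first_body_bin(self):
        genes = [GeneModel("g", "chr1", "+", 10_000, 12_000)]
        track = SignalTrack([(Region("chr1", 10_000, 10_020), 1.0)])
        prof = meta_profile(track, genes)
        n_up = 2000 // 20
        assert prof.values[n_up] == pytest.approx(1.0)
        assert prof.values[:n_up].sum() == 0.0
        assert prof.values[n_up + 1:].sum() == 0.0

    def test_minus_strand_profile_is_reversed(self):
        plus = GeneModel("gp", "chr1", "+", 10_000, 12_000)
        minus = GeneModel("gm", "chr1", "-", 10_000, 12_000)
        track = SignalTrack([(Region("chr1", 9_000, 10_000), 2.0)])
        p_plus = meta_profile(track, [plus])
        p_minus = meta_profile(track, [minus])
        assert np.allclose(p_plus.values, p_minus.values[::-1])

    def test_short_genes_skipped_with_count(self):
        track = SignalTrack([(Region("chr1", 0, 10_000), 1.0)])
        genes = [
            GeneModel("ok", "chr1", "+", 2_000, 4_000),
            GeneModel("tiny", "chr1", "+", 5_000, 5_050),
        ]
        prof = meta_profile(track, genes)
        assert prof.n_used == 1
        assert prof.n_skipped == 1

    def test_der_center_profile_peaks_at_summit(self):
        center = 20_000
        track = SignalTrack([(Region("chr1", center - 100, center + 100), 5.0)])
        ders = [DER(Region("chr1", center - 200, center + 200, summit=200),
                    1, 5, 2, GAIN)]
        prof = der_center_profile(track, ders)
        peak_pos = prof.positions[np.argmax(prof.values)]
        assert abs(peak_pos) <= 200
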