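"""PWM scanning against a naive oracle, enrichment, profiles and targets."""

import math

import numpy as np
import pytest

from succer.core import ExpressionRecord, GeneModel, GenomeAssets, Region, \
    reverse_complement
from succer.ders import DER, GAIN
from succer.motifs import (
    PWM,
    identify_detfs,
    motif_enrichment,
    occurrence_profile,
    scan_pwm,
    summit_windows,
    tf_targets,
)
from succer.motifs import MotifEnrichmentResult, SummitWindow


def naive_scan(sequence: str, pwm: PWM, threshold_frac: float = 0.8):
    """Per-position, per-strand rescoring oracle (no vectorization), including
    the same best-score collapse of overlapping same-strand hits."""
    seq = sequence.upper()
    L = pwm.length
    threshold = threshold_frac * pwm.max_score
    lo = {b: pwm.log_odds[i] for i, b in enumerate("ACGT")}
    raw = []
    for strand in "+-":
        for i in range(len(seq) - L + 1):
            window = seq[i : i + L]
            if strand == "-":
                window = reverse_complement(window)
            score = sum(
                lo[c][j] if c in lo else 0.0 for j, c in enumerate(window)
            )
            if score >= threshold:
                raw.append((i, strand, score))
    kept = []
    for i, strand, score in sorted(raw, key=lambda t: (-t[2], t[0], t[1])):
        if not any(s == strand and abs(k - i) < L for k, s, _ in kept):
            kept.append((i, strand, score))
    return sorted(kept)


class TestScan:
    def test_point_mass_motif_score_follows_formula(self):
        # counts of 1 on the consensus base per position (consensus ACGT);
        # ACGT is reverse-complement palindromic, so both strands hit
        pwm = PWM.from_counts("m", "TF", np.eye(4))
        hits = scan_pwm("ACGT", pwm)
        assert sorted(h.strand for h in hits) == ["+", "-"]
        expected = 4 * math.log2((1.01 / 1.04) / 0.25)
        for hit in hits:
            assert hit.score == pytest.approx(expected)
        assert expected == pytest.approx(7.83, abs=0.02)

    def test_reverse_complement_sequence_gives_mirror_hits(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        pwm = PWM.from_consensus("m", "TF", "TGACTCA")
        fwd = scan_pwm(seq, pwm, threshold_frac=0.7)
        rev = scan_pwm(reverse_complement(seq), pwm, threshold_frac=0.7)
        assert len(fwd) == len(rev)
        assert sorted(round(h.score, 9) for h in fwd) == sorted(
            round(h.score, 9) for h in rev
        )

    def test_sequence_shorter_than_motif_yields_no_hits(self):
        pwm = PWM.from_consensus("m", "TF", "ACGTACGT")
        assert scan_pwm("ACG", pwm) == []

    def test_n_bases_score_as_background(self):
        pwm = PWM.from_consensus("m", "TF", "ACGT")
        # N contributes 0; three strong positions of ~2 bits miss an 0.8
        # threshold of ~8 bits, so no hit
        assert scan_pwm("ANGT", pwm) == []

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_naive_rescoring_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGTN"), size=400,
                                 p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        counts = rng.integers(0, 20, size=(4, 6)).astype(float)
        pwm = PWM.from_counts(f"m{seed}", "TF", counts)
        ours = sorted((h.offset, h.strand, round(h.score, 9))
                      for h in scan_pwm(seq, pwm, 0.7))
        oracle = [(i, s, round(sc, 9)) for i, s, sc in naive_scan(seq, pwm, 0.7)]
        assert ours == oracle


class TestSummitWindows:
    def _assets(self, n=10_000):
        return GenomeAssets({"chr1": n}, {"chr1": "A" * n})

    def test_window_centered_on_summit(self):
        der = DER(Region("chr1", 900, 1100, summit=100), 1, 5, 2.0, GAIN)
        (w,), skipped = summit_windows([der], self._assets())
        assert (w.start, w.end) == (800, 1200)
        assert skipped == 0

    def test_window_clipped_at_chromosome_start(self):
        der = DER(Region("chr1", 0, 100, summit=50), 1, 5, 2.0, GAIN)
        (w,), _ = summit_windows([der], self._assets())
        assert (w.start, w.end) == (0, 250)

    def test_midpoint_used_when_no_summit(self):
        der = DER(Region("chr1", 1000, 1400), 1, 5, 2.0, GAIN)
        (w,), _ = summit_windows([der], self._assets())
        assert (w.start, w.end) == (1000, 1400)


def make_window(i, seq, kind="t"):
    return SummitWindow(f"{kind}{i}", "chr1", 0, len(seq), len(seq) // 2, seq)


class TestEnrichment:
    def test_closed_form_tail(self):
        planted = "TGACTCA"
        pwm = PWM.from_consensus("m", "TF", planted)
        targets = [make_window(i, "CC" * 20 + planted + "CC" * 20)
                   for i in range(10)]
        bg = [make_window(i, "CC" * 100, "b") for i in range(100)]
        (res,) = motif_enrichment(targets, bg, [pwm])
        # k=10/10 against the floored background rate p0 = 1/(2*100)
        assert res.k == 10 and res.k_bg == 0
        assert res.p == pytest.approx((1 / 200) ** 10)

    def test_no_enrichment_when_rates_match(self):
        planted = "TGACTCA"
        pwm = PWM.from_consensus("m", "TF", planted)
        with_hit = "CC" * 20 + planted + "CC" * 20
        targets = [make_window(i, with_hit if i < 5 else "CC" * 47)
                   for i in range(10)]
        bg = [make_window(i, with_hit if i < 50 else "CC" * 47, "b")
              for i in range(100)]
        (res,) = motif_enrichment(targets, bg, [pwm])
        assert res.p >= 0.5

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="empty PWM library"):
            motif_enrichment([make_window(0, "ACGT" * 10)],
                             [make_window(0, "ACGT" * 10, "b")], [])

    def test_reverse_complementing_windows_preserves_counts(self):
        rng = np.random.default_rng(6)
        pwm = PWM.from_consensus("m", "TF", "TGACTCA")
        targets = [
            make_window(i, "".join(rng.choice(list("ACGT"), size=120)))
            for i in range(30)
        ]
        bg = [
            make_window(i, "".join(rng.choice(list("ACGT"), size=120)), "b")
            for i in range(60)
        ]
        rc_targets = [make_window(i, reverse_complement(w.sequence))
                      for i, w in enumerate(targets)]
        rc_bg = [make_window(i, reverse_complement(w.sequence), "b")
                 for i, w in enumerate(bg)]
        (fwd,) = motif_enrichment(targets, bg, [pwm], threshold_frac=0.7)
        (rev,) = motif_enrichment(rc_targets, rc_bg, [pwm], threshold_frac=0.7)
        assert (fwd.k, fwd.k_bg, fwd.p) == (rev.k, rev.k_bg, rev.p)


class TestDETF:
    def _enr(self, p):
        return [MotifEnrichmentResult("m", "TF1", 8, 10, 5, 100, p)]

    def test_enriched_and_upregulated_is_up_detf(self):
        expr = [ExpressionRecord("g1", 2.0, 8.0, 2.0, True)]
        detfs, _ = identify_detfs(self._enr(1e-5), [], expr, {"TF1": "g1"})
        (d,) = detfs
        assert d.direction == "up"
        assert d.expression_level == pytest.approx(math.log2(9.0))

    def test_not_significant_tf_is_not_detf(self):
        expr = [ExpressionRecord("g1", 2.0, 8.0, 2.0, False)]
        detfs, _ = identify_detfs(self._enr(1e-5), [], expr, {"TF1": "g1"})
        assert detfs == []

    def test_downregulated_tf_cannot_be_up_detf(self):
        expr = [ExpressionRecord("g1", 8.0, 2.0, -2.0, True)]
        detfs, _ = identify_detfs(self._enr(1e-5), [], expr, {"TF1": "g1"})
        assert detfs == []

    def test_unmappable_tf_counted(self):
        expr = [ExpressionRecord("g1", 2.0, 8.0, 2.0, True)]
        detfs, n_unmapped = identify_detfs(self._enr(1e-5), [], expr, {})
        assert detfs == [] and n_unmapped == 1


class TestOccurrenceProfile:
    def _setup(self, offsets):
        """One DER per offset; motif planted at summit+offset."""
        motif = "TGACTCA"
        chrom_len = 4000 * len(offsets)
        seq = bytearray(b"C" * chrom_len)
        ders = []
        for i, off in enumerate(offsets):
            summit = 4000 * i + 2000
            start = summit + off - (len(motif) - 1) // 2
            seq[start : start + len(motif)] = motif.encode()
            ders.append(
                DER(Region("chr1", summit - 500, summit + 500, summit=500),
                    1, 5, 2.0, GAIN)
            )
        assets = GenomeAssets({"chr1": chrom_len}, {"chr1": seq.decode()})
        return PWM.from_consensus("m", "TF", motif), ders, assets

    def test_hits_at_summit_fill_the_zero_bin(self):
        pwm, ders, assets = self._setup([0] * 5)
        prof = occurrence_profile(pwm, ders, assets)
        nonzero = np.nonzero(prof.density)[0]
        assert list(prof.edges[nonzero]) == [0.0]

    def test_conservation_identity(self):
        pwm, ders, assets = self._setup([-120, -10, 0, 35, 200, 480])
        prof = occurrence_profile(pwm, ders, assets)
        assert prof.density.sum() * 10 * prof.n_windows == pytest.approx(
            prof.total_hits
        )
        assert prof.total_hits == 6

    def test_no_hits_gives_zero_profile(self):
        pwm, ders, assets = self._setup([])
        ders = [DER(Region("chr1", 0, 1000, summit=500), 1, 5, 2.0, GAIN)]
        assets = GenomeAssets({"chr1": 1000}, {"chr1": "C" * 1000})
        prof = occurrence_profile(pwm, ders, assets)
        assert prof.density.sum() == 0.0


class TestTargets:
    def _genome_with_promoter_hits(self, distances):
        """One gene per distance; motif midpoint planted exactly ``distance``
        bp upstream of each TSS."""
        motif = "TGACTCA"
        chrom_len = 20_000 * len(distances)
        seq = bytearray(b"C" * chrom_len)
        genes, expr = [], []
        for i, dist in enumerate(distances):
            tss = 20_000 * i + 10_000
            mid = tss - dist
            start = mid - (len(motif) - 1) // 2
            seq[start : start + len(motif)] = motif.encode()
            gid = f"g{i}"
            genes.append(GeneModel(gid, "chr1", "+", tss, tss + 2_000))
            expr.append(ExpressionRecord(gid, 2.0, 8.0, 2.0 + i, True))
        assets = GenomeAssets({"chr1": chrom_len}, {"chr1": seq.decode()})
        return PWM.from_consensus("m", "TF", motif), genes, assets, expr

    def test_two_kb_boundary_half_open(self):
        pwm, genes, assets, expr = self._genome_with_promoter_hits(
            [1999, 2001, 500]
        )
        targets = tf_targets(pwm, genes, assets, expr)
        assert {g for g, _ in targets} == {"g0", "g2"}

    def test_sorted_by_absolute_fold_change_descending(self):
        pwm, genes, assets, expr = self._genome_with_promoter_hits([100, 200])
        targets = tf_targets(pwm, genes, assets, expr)
        assert [g for g, _ in targets] == ["g1", "g0"]

    def test_non_deg_genes_excluded(self):
        pwm, genes, assets, expr = self._genome_with_promoter_hits([100])
        expr[0].significant = False
        assert tf_targets(pwm, genes, assets, expr) == []
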