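"""PWM building, exact score thresholds, scanning, footprint scoring."""

import itertools

import numpy as np
import pytest

from conegrn.config import PipelineConfig
from conegrn.errors import PipelineError
from conegrn.genome import GenomicInterval, SignalTrack
from conegrn.motifs import (
    build_pwm,
    footprint_score,
    revcomp,
    scan_peak,
    score_tail_probability,
    score_threshold,
)


def enumeration_tail(pwm, threshold):
    """Brute-force P(score >= threshold) over all 4^L background words."""
    L = len(pwm)
    tail = 0.0
    for word in itertools.product(range(4), repeat=L):
        s = 0.0
        pr = 1.0
        for i, b in enumerate(word):
            s += pwm.log_odds[i, b]
            pr *= pwm.background[b]
        if round(s, 9) >= threshold - 1e-7:
            tail += pr
    return tail


class TestBuildPWM:
    def test_uniform_gives_zero_log_odds(self):
        pwm = build_pwm(np.full((4, 4), 5.0))
        assert np.allclose(pwm.log_odds, 0.0)

    def test_pure_column_log_odds(self):
        pwm = build_pwm([[10, 0, 0, 0]], pseudocount=0)
        assert pwm.log_odds[0, 0] == pytest.approx(2.0)

    def test_rows_sum_to_one(self):
        pwm = build_pwm(np.random.default_rng(0).integers(0, 30, (6, 4)))
        assert np.allclose(pwm.matrix.sum(axis=1), 1.0)

    def test_zero_row_without_pseudocount_rejected(self):
        with pytest.raises(PipelineError, match="zero-column"):
            build_pwm([[0, 0, 0, 0]], pseudocount=0)


class TestScoreThreshold:
    def test_length_one_enumeration(self):
        pwm = build_pwm([[10, 0, 0, 0]], pseudocount=0)
        # scores: A=2, others -inf; P(score >= 2) = 0.25
        assert score_threshold(pwm, 0.25) == pytest.approx(2.0)

    def test_near_one_p_keeps_almost_everything(self):
        pwm = build_pwm(np.random.default_rng(3).integers(1, 20, (4, 4)))
        thr = score_threshold(pwm, 0.999999)
        tail = enumeration_tail(pwm, thr)
        assert tail <= 0.999999
        # minimality: including the minimum score would exceed p
        assert enumeration_tail(pwm, pwm.min_score) > 0.999999

    @pytest.mark.parametrize("length,seed", [(4, 0), (5, 1), (6, 2), (7, 3), (8, 4)])
    def test_dp_tail_matches_enumeration(self, length, seed):
        rng = np.random.default_rng(seed)
        pwm = build_pwm(rng.integers(0, 25, (length, 4)), pseudocount=1)
        for p in (0.2, 0.01, 1e-3):
            thr = score_threshold(pwm, p)
            tail = enumeration_tail(pwm, thr)
            assert tail == pytest.approx(score_tail_probability(pwm, thr), abs=1e-9)
            assert tail <= p + 1e-12

    def test_monotone_in_p(self):
        pwm = build_pwm(np.random.default_rng(7).integers(0, 25, (8, 4)))
        thrs = [score_threshold(pwm, p) for p in (1e-4, 1e-3, 1e-2, 0.1)]
        assert all(a >= b - 1e-12 for a, b in zip(thrs, thrs[1:]))

    def test_unreachable_p_warns(self):
        pwm = build_pwm([[10, 0, 0, 0]], pseudocount=0)
        with pytest.warns(UserWarning, match="unreachable"):
            thr = score_threshold(pwm, 1e-6)
        assert thr > pwm.max_score


class TestScan:
    def setup_method(self):
        rng = np.random.default_rng(11)
        self.pwm = build_pwm(rng.integers(0, 30, (6, 4)), pseudocount=1)
        self.consensus = "".join(
            "ACGT"[i] for i in self.pwm.log_odds.argmax(axis=1)
        )

    def test_consensus_hit_forward(self):
        hits = scan_peak(self.pwm, self.consensus, self.pwm.max_score - 1e-9)
        assert any(h.strand == "+" and h.site.start == 0 for h in hits)

    def test_revcomp_hit_minus_strand(self):
        hits = scan_peak(self.pwm, revcomp(self.consensus), self.pwm.max_score - 1e-9)
        assert any(h.strand == "-" and h.site.start == 0 for h in hits)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(5)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)])
        thr = score_threshold(self.pwm, 0.05)
        fwd = scan_peak(self.pwm, seq, thr)
        rev = scan_peak(self.pwm, revcomp(seq), thr)
        n = len(seq)
        L = len(self.pwm)
        mirrored = {
            (n - h.site.end, "-" if h.strand == "+" else "+", round(h.score, 9))
            for h in fwd
        }
        observed = {(h.site.start, h.strand, round(h.score, 9)) for h in rev}
        assert mirrored == observed

    def test_windows_with_n_skipped(self):
        seq = "N" * 10
        assert scan_peak(self.pwm, seq, -100.0) == []

    def test_genomic_frame(self):
        peak = GenomicInterval("chr3", 1000, 1000 + len(self.consensus))
        hits = scan_peak(
            self.pwm, self.consensus, self.pwm.max_score - 1e-9, peak, "pk"
        )
        assert hits[0].site.start == 1000
        assert hits[0].peak_id == "pk"


def flat_track(value, chrom="c", start=0, end=200):
    return SignalTrack(
        [GenomicInterval(chrom, i, i + 1) for i in range(start, end)],
        [value] * (end - start),
    )


class TestFootprint:
    def test_protected_site_passes(self):
        cfg = PipelineConfig()
        site = GenomicInterval("c", 90, 100)
        ivs = [GenomicInterval("c", i, i + 1) for i in range(0, 200)]
        vals = [0.2 if 90 <= i < 100 else 0.3 for i in range(0, 200)]
        fp = footprint_score(SignalTrack(ivs, vals), site, cfg)
        assert fp.passes
        assert fp.s_left == pytest.approx(0.3)
        assert fp.s_center == pytest.approx(0.2)

    def test_flat_track_fails(self):
        fp = footprint_score(flat_track(0.3), GenomicInterval("c", 90, 100))
        assert fp.s_left - fp.s_center == pytest.approx(0.0)
        assert not fp.passes

    def test_boundary_is_strict(self):
        # flank - center exactly 0.05 must fail
        site = GenomicInterval("c", 90, 100)
        ivs = [GenomicInterval("c", i, i + 1) for i in range(0, 200)]
        vals = [0.25 if 90 <= i < 100 else 0.30 for i in range(0, 200)]
        fp = footprint_score(SignalTrack(ivs, vals), site)
        assert fp.s_left - fp.s_center == pytest.approx(0.05)
        assert not fp.passes

    def test_site_at_chromosome_edge_rejected(self):
        # left flank truncates to nothing at the chromosome start
        with pytest.warns(UserWarning, match="truncated"):
            with pytest.raises(PipelineError, match="bad-site"):
                footprint_score(flat_track(0.3), GenomicInterval("c", 0, 10))


class TestPredictBindingSites:
    def _inputs(self):
        rng = np.random.default_rng(21)
        pwm = build_pwm(rng.integers(0, 40, (8, 4)), pseudocount=1, motif_id="M0")
        consensus = "".join("ACGT"[i] for i in pwm.log_odds.argmax(axis=1))
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        seq = seq[:96] + consensus + seq[104:]
        peak = GenomicInterval("chr1", 5000, 5200)
        from conegrn.synthetic import generate_insertion_profile

        site = GenomicInterval("chr1", 5096, 5104)
        track = generate_insertion_profile(site, True, depth=100, seed=0)
        return pwm, peak, seq, track

    def test_lowly_expressed_tf_emits_nothing(self):
        from conegrn.motifs import predict_binding_sites

        pwm, peak, seq, track = self._inputs()
        out = predict_binding_sites(
            {"Cone": {"tf1": 0.09}}, {"M0": pwm}, {"tf1": "M0"},
            {"pk": peak}, {"pk": seq}, {"Cone": track},
        )
        assert out["Cone"] == []

    def test_expressed_tf_with_protected_site_emitted(self):
        from conegrn.motifs import predict_binding_sites

        pwm, peak, seq, track = self._inputs()
        out = predict_binding_sites(
            {"Cone": {"tf1": 2.0}}, {"M0": pwm}, {"tf1": "M0"},
            {"pk": peak}, {"pk": seq}, {"Cone": track},
        )
        assert any(h.site.start == 5096 for _, h, fp in out["Cone"] if fp.passes)

    def test_tf_without_motif_warns_and_skips(self):
        from conegrn.motifs import predict_binding_sites

        pwm, peak, seq, track = self._inputs()
        with pytest.warns(UserWarning, match="no-motif"):
            out = predict_binding_sites(
                {"Cone": {"tf2": 2.0}}, {"M0": pwm}, {},
                {"pk": peak}, {"pk": seq}, {"Cone": track},
            )
        assert out["Cone"] == []
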