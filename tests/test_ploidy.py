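"""Ploidy classifier: normalisation, peak detection, exceeding rates and
the diagnostic rule cascade."""

from __future__ import annotations

import numpy as np
import pytest

from ploidyrisk.exceptions import InadequateSampleError
from ploidyrisk.nuclei import NucleusRecord, SampleSimConfig, Stemline, simulate_sample
from ploidyrisk.ploidy import (DIHistogram, classify_ploidy, detect_peaks,
                               diploid_peak_cv, exceeding_rate, normalize_to_c)


def records_with_controls(epi_iods, ctrl_iod=100.0, n_ctrl=40, sid="s1"):
    recs = [NucleusRecord(sid, ctrl_iod, "lymphocyte") for _ in range(n_ctrl)]
    recs += [NucleusRecord(sid, float(x), "epithelial") for x in epi_iods]
    return recs


def hist_from(c_values, sid="h"):
    return DIHistogram(sid, np.asarray(c_values, float), 40, 1.0)


class TestNormalizeToC:
    def test_identity_scale(self):
        h = normalize_to_c(records_with_controls([100.0] * 10))
        assert np.allclose(h.c_values, 2.0)
        assert h.n_controls_used == 40

    def test_linearity(self):
        h = normalize_to_c(records_with_controls([150.0] * 10))
        assert np.allclose(h.c_values, 3.0)

    def test_excludes_artifacts_debris_controls(self):
        recs = records_with_controls([100.0] * 5)
        recs.append(NucleusRecord("s1", 100.0, "epithelial", "cut"))
        recs.append(NucleusRecord("s1", 30.0, "debris"))
        h = normalize_to_c(recs)
        assert len(h.c_values) == 5

    def test_too_few_controls(self):
        with pytest.raises(InadequateSampleError, match="control"):
            normalize_to_c(records_with_controls([100.0] * 10, n_ctrl=10))

    def test_nonpositive_iod_rejected(self):
        recs = records_with_controls([100.0, 0.0])
        with pytest.raises(ValueError, match="positive"):
            normalize_to_c(recs)

    def test_simulated_aneuploid_mode_lands_at_3c(self):
        cfg = SampleSimConfig(seed=21, n_total=2000,
                              stemlines=[Stemline(1.5, 1.0)])
        h = normalize_to_c(simulate_sample(cfg))
        peaks = detect_peaks(h)
        main = max(peaks, key=lambda p: p.fraction)
        assert abs(main.mode_c - 3.0) < 0.05


class TestDetectPeaks:
    def test_single_tight_cluster(self):
        rng = np.random.default_rng(0)
        peaks = detect_peaks(hist_from(rng.normal(2.0, 0.03, 500)))
        assert len(peaks) == 1
        assert abs(peaks[0].mode_c - 2.0) < 0.05
        assert peaks[0].fraction >= 0.9

    def test_two_stemlines_recovered_with_fractions(self):
        cfg = SampleSimConfig(seed=13, n_total=3000,
                              stemlines=[Stemline(1.0, 0.6), Stemline(1.5, 0.4)])
        h = normalize_to_c(simulate_sample(cfg))
        peaks = detect_peaks(h)
        big = [p for p in peaks if p.fraction > 0.10]
        assert len(big) == 2
        assert abs(big[0].mode_c - 2.0) < 0.05 and abs(big[1].mode_c - 3.0) < 0.05
        # generating fractions 0.6/0.4 carry G2+S away from G1: compare
        # against the G1 share of each stemline (0.9 of its fraction)
        assert abs(big[0].fraction - 0.54) < 0.05
        assert abs(big[1].fraction - 0.36) < 0.05

    @pytest.mark.parametrize("seed", range(5))
    def test_uniform_histogram_has_no_supra_threshold_peak(self, seed):
        rng = np.random.default_rng(seed)
        peaks = detect_peaks(hist_from(rng.uniform(1.0, 5.0, 500)))
        assert peaks == []

    def test_degenerate_identical_values(self):
        peaks = detect_peaks(hist_from([2.0] * 400))
        assert len(peaks) == 1
        assert peaks[0].fraction == 1.0 and peaks[0].cv_pct == 0.0

    def test_empty_histogram_raises(self):
        with pytest.raises(ValueError, match="empty"):
            detect_peaks(hist_from([]))


class TestExceedingRate:
    def test_brute_force_agreement(self):
        rng = np.random.default_rng(3)
        c = rng.uniform(0.5, 10.0, 777)
        h = hist_from(c)
        for thr in (2.0, 5.0, 9.0):
            assert exceeding_rate(h, thr) == np.sum(c > thr) / len(c)

    def test_examples(self):
        assert exceeding_rate(hist_from([2.0] * 50), 5.0) == 0.0
        c = [2.0] * 395 + [6.0] * 5
        assert exceeding_rate(hist_from(c), 5.0) == pytest.approx(0.0125)
        assert exceeding_rate(hist_from([2.0, 6.0]), 9.0) == 0.0

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            exceeding_rate(hist_from([2.0]), 0.0)


class TestDiploidPeakCV:
    def test_identical_values_zero_cv(self):
        h = hist_from([2.0] * 400)
        assert diploid_peak_cv(h, detect_peaks(h)) == (0.0, False)

    def test_simulated_cv_recovered(self):
        cfg = SampleSimConfig(seed=17, n_total=1000, diploid_cv_pct=2.0)
        h = normalize_to_c(simulate_sample(cfg))
        cv, fallback = diploid_peak_cv(h, detect_peaks(h))
        assert not fallback
        assert 1.5 < cv < 2.5

    def test_fallback_to_largest_peak_when_no_diploid(self):
        rng = np.random.default_rng(1)
        h = hist_from(rng.normal(3.0, 0.06, 500))  # DI 1.5 only
        cv, fallback = diploid_peak_cv(h, detect_peaks(h))
        assert fallback and cv > 0


class TestClassifyPloidy:
    """The four canonical outcomes of the rule cascade."""

    def test_diploid(self):
        cfg = SampleSimConfig(seed=31, n_total=1200)
        d = classify_ploidy(normalize_to_c(simulate_sample(cfg)))
        assert d.label == "diploid" and d.qc_pass

    def test_aneuploid_by_abnormal_stemline(self):
        cfg = SampleSimConfig(seed=32, n_total=1200,
                              stemlines=[Stemline(1.0, 0.55), Stemline(1.5, 0.45)])
        d = classify_ploidy(normalize_to_c(simulate_sample(cfg)))
        assert d.label == "aneuploid"
        assert "abnormal_stemline_peak" in d.reasons

    def test_aneuploid_by_5c_rate(self):
        cfg = SampleSimConfig(seed=33, n_total=1200, five_c_excess_fraction=0.02)
        d = classify_ploidy(normalize_to_c(simulate_sample(cfg)))
        assert d.label == "aneuploid"
        assert "five_c_rate_gt_1pct" in d.reasons

    def test_tetraploid(self):
        cfg = SampleSimConfig(seed=34, n_total=1200,
                              stemlines=[Stemline(1.0, 0.8, 0.02, 0.02),
                                         Stemline(2.0, 0.2, 0.01, 0.01)])
        d = classify_ploidy(normalize_to_c(simulate_sample(cfg)))
        assert d.label == "tetraploid"
        assert d.five_c_exceeding_rate <= 0.01

    def test_inadequate_below_300_nuclei(self):
        cfg = SampleSimConfig(seed=35, n_total=400)  # ~240 epithelial
        d = classify_ploidy(normalize_to_c(simulate_sample(cfg)))
        assert d.label == "inadequate" and not d.qc_pass
        assert "too_few_epithelial_nuclei" in d.reasons

    def test_inadequate_when_cv_exceeds_5pct(self):
        rng = np.random.default_rng(5)
        d = classify_ploidy(hist_from(rng.normal(2.0, 0.25, 400)))
        assert d.label == "inadequate"
        assert "diploid_peak_cv_gt_5pct" in d.reasons
        assert d.diploid_peak_cv_pct > 5.0

    def test_nine_c_rate_never_exceeds_five_c_rate(self):
        rng = np.random.default_rng(8)
        d = classify_ploidy(hist_from(np.concatenate([
            rng.normal(2.0, 0.04, 350), rng.uniform(5.5, 10.5, 30)])))
        assert d.nine_c_exceeding_rate <= d.five_c_exceeding_rate
        assert d.label == "aneuploid"


class TestThresholdTies:
    """Strict inequalities: ties fall to the less abnormal side."""

    def _peaky(self, n2, n4=0, n_over5=0):
        rng = np.random.default_rng(42)
        parts = [rng.normal(2.0, 0.02, n2)]
        if n4:
            parts.append(rng.normal(4.0, 0.02, n4))
        if n_over5:
            parts.append(np.full(n_over5, 6.0))
        return hist_from(np.concatenate(parts))

    def test_exactly_1pct_over_5c_is_not_aneuploid(self):
        d = classify_ploidy(self._peaky(396, n_over5=4))  # 4/400 = 1%
        assert d.five_c_exceeding_rate == pytest.approx(0.01)
        assert d.label == "diploid"

    def test_just_over_1pct_is_aneuploid(self):
        d = classify_ploidy(self._peaky(395, n_over5=5))  # 5/400 = 1.25%
        assert d.label == "aneuploid"

    def test_exactly_10pct_4c_band_is_diploid(self):
        d = classify_ploidy(self._peaky(360, n4=40))  # 40/400 = 10%
        assert d.four_c_fraction == pytest.approx(0.10)
        assert d.label == "diploid"

    def test_just_over_10pct_4c_peak_is_tetraploid(self):
        d = classify_ploidy(self._peaky(355, n4=45))  # 45/400 = 11.25%
        assert d.label == "tetraploid"


class TestInvariants:
    def test_determinism(self):
        records = simulate_sample(SampleSimConfig(seed=51, n_total=1200))
        a = classify_ploidy(normalize_to_c(records))
        b = classify_ploidy(normalize_to_c(records))
        assert a.label == b.label and a.reasons == b.reasons
        assert a.five_c_exceeding_rate == b.five_c_exceeding_rate

    @pytest.mark.parametrize("k", [0.25, 3.0, 17.0])
    @pytest.mark.parametrize("seed, expect", [(61, "diploid"), (62, "aneuploid")])
    def test_scale_invariance(self, k, seed, expect):
        stem = ([Stemline(1.0, 1.0)] if expect == "diploid"
                else [Stemline(1.0, 0.6), Stemline(1.4, 0.4)])
        records = simulate_sample(SampleSimConfig(seed=seed, n_total=1200,
                                                  stemlines=stem))
        scaled = [NucleusRecord(r.sample_id, r.iod * k, r.cls, r.artifact,
                                r.truth_component) for r in records]
        d0 = classify_ploidy(normalize_to_c(records))
        dk = classify_ploidy(normalize_to_c(scaled))
        assert d0.label == expect
        assert dk.label == d0.label
        assert np.allclose(
            np.sort(normalize_to_c(records).c_values),
            np.sort(normalize_to_c(scaled).c_values), rtol=1e-9)

    def test_raising_nuclei_above_5c_is_monotone_toward_aneuploid(self):
        rng = np.random.default_rng(9)
        base = rng.normal(2.0, 0.04, 400)
        labels = []
        for n_up in (0, 5, 20, 80):
            c = base.copy()
            c[:n_up] = 6.0
            labels.append(classify_ploidy(hist_from(c)).label)
        assert labels[0] == "diploid"
        # once aneuploid by the 5c rule, adding more >5c nuclei never reverts
        first = next(i for i, lab in enumerate(labels) if lab == "aneuploid")
        assert all(lab == "aneuploid" for lab in labels[first:])

    def test_four_c_band_matches_brute_force(self):
        rng = np.random.default_rng(10)
        c = rng.uniform(1.0, 6.0, 900)
        d = classify_ploidy(hist_from(c))
        assert d.four_c_fraction == np.sum((c >= 3.6) & (c <= 4.4)) / len(c)
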