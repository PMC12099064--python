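"""Feature computation, Beta-naive-Bayes training/scoring, and calls."""

import math

import numpy as np
import pytest

from msipipe import (
    AlleleSpectrum,
    MarkerFeatures,
    MsiModel,
    SampleSpectra,
    SimulationConfig,
    classify,
    compute_features,
    fit_model,
    load_model,
    msi_score,
    save_model,
    simulate_cohort,
)
from msipipe.classifier import MSI_H, MSS, BetaParams, _shrink
from msipipe.errors import ModelIOError, ScoringError, TrainingError


def _sample(panel, marker_counts):
    spectra = {
        m.name: AlleleSpectrum(m.name, marker_counts.get(m.name, {}))
        for m in panel
    }
    return SampleSpectra("s", spectra)


# ---------------------------------------------------------------------------
# independent oracle for the naive-Bayes score


def beta_logpdf(x, a, b):
    """Beta log-density from first principles (lgamma form)."""
    return (
        math.lgamma(a + b)
        - math.lgamma(a)
        - math.lgamma(b)
        + (a - 1) * math.log(x)
        + (b - 1) * math.log(1 - x)
    )


def oracle_score(features, model):
    """Term-by-term sum of Beta log-density differences."""
    total = model.prior_log_odds
    for f in features:
        for feat, value in (("del", f.del_freq), ("bias", f.allelic_bias)):
            for cls, sign in ((MSI_H, +1), (MSS, -1)):
                n = model.n_per_class[cls]
                x = (value * n + 0.5) / (n + 1)
                p = model.params[f.marker][cls][feat]
                total += sign * beta_logpdf(x, p.alpha, p.beta)
    return total


def toy_model(n=20):
    """Two-marker model: del_freq separates classes, bias terms identical."""
    mss_del = BetaParams(2, 38)
    msih_del = BetaParams(10, 10)
    bias = BetaParams(3, 3)
    params = {
        m: {MSS: {"del": mss_del, "bias": bias},
            MSI_H: {"del": msih_del, "bias": bias}}
        for m in ("M1", "M2")
    }
    return MsiModel(params=params, n_per_class={MSS: n, MSI_H: n})


class TestFeatures:
    @pytest.mark.parametrize(
        "counts,ref,del_freq,bias",
        [
            ({20: 90, 18: 10}, 20, 0.10, 1.0),
            ({20: 100}, 20, 0.0, 0.0),
            ({20: 50, 19: 25, 18: 25}, 20, 0.5, 0.5),
        ],
    )
    def test_feature_arithmetic(self, toy_panel, counts, ref, del_freq, bias):
        sample = _sample(toy_panel, {"TOY1": counts})
        (f,) = compute_features(sample, toy_panel)
        assert f.marker == "TOY1"
        assert f.del_freq == pytest.approx(del_freq)
        assert f.allelic_bias == pytest.approx(bias)

    def test_modal_reference_absorbs_germline_shift(self, toy_panel):
        # modal length 19 is within 1 unit of the panel reference 20
        sample = _sample(toy_panel, {"TOY1": {19: 100}})
        (f,) = compute_features(sample, toy_panel)
        assert f.del_freq == 0.0

    def test_panel_reference_keeps_somatic_deletion(self, toy_panel):
        # modal length 17 is 3 units off: the panel reference applies
        sample = _sample(toy_panel, {"TOY1": {17: 60, 20: 40}})
        (f,) = compute_features(sample, toy_panel)
        assert f.del_freq == pytest.approx(0.6)

    def test_zero_depth_markers_omitted(self, toy_panel):
        sample = _sample(toy_panel, {"TOY1": {20: 10}})
        feats = compute_features(sample, toy_panel)
        assert [f.marker for f in feats] == ["TOY1"]

    def test_bias_zero_iff_no_deletions(self):
        with pytest.raises(ValueError):
            MarkerFeatures("M", del_freq=0.2, allelic_bias=0.0)
        with pytest.raises(ValueError):
            MarkerFeatures("M", del_freq=0.0, allelic_bias=0.3)


class TestTraining:
    def test_requires_both_classes(self, toy_panel):
        sample = _sample(toy_panel, {"TOY1": {20: 50}, "TOY2": {15: 50}})
        with pytest.raises(TrainingError):
            fit_model([(sample, MSS)] * 6, toy_panel)

    def test_requires_minimum_per_class(self, toy_panel):
        sample = _sample(toy_panel, {"TOY1": {20: 50}, "TOY2": {15: 50}})
        cohort = [(sample, MSS)] * 4 + [(sample, MSI_H)] * 6
        with pytest.raises(TrainingError, match="MSS"):
            fit_model(cohort, toy_panel)

    def test_marker_absent_everywhere_is_an_error(self, toy_panel):
        sample = _sample(toy_panel, {"TOY1": {20: 50}})  # TOY2 never seen
        cohort = [(sample, MSS)] * 6 + [(sample, MSI_H)] * 6
        with pytest.raises(TrainingError, match="TOY2"):
            fit_model(cohort, toy_panel)

    def test_identical_classes_score_prior(self, toy_panel):
        rng = np.random.default_rng(4)
        samples = [
            _sample(
                toy_panel,
                {
                    "TOY1": {20: 90 + i, 19: 10},
                    "TOY2": {15: 80 + i, 14: 20},
                },
            )
            for i in range(6)
        ]
        cohort = [(s, MSS) for s in samples] + [(s, MSI_H) for s in samples]
        model = fit_model(cohort, toy_panel, prior_log_odds=1.5)
        feats = compute_features(samples[0], toy_panel)
        assert msi_score(feats, model) == pytest.approx(1.5)

    def test_fitted_means_recover_simulator_class_means(self, panel):
        config = SimulationConfig(seed=9, n_mss=20, n_msih=20, depth_mean=500)
        samples, truths = simulate_cohort(config, panel)
        labels = {t.sample_id: t.true_class for t in truths}
        cohort = [(s, labels[s.sample_id]) for s in samples]
        model = fit_model(cohort, panel)

        feats_by_class = {MSS: [], MSI_H: []}
        for s in samples:
            for f in compute_features(s, panel):
                feats_by_class[labels[s.sample_id]].append(
                    (f.marker, f.del_freq)
                )
        for cls in (MSS, MSI_H):
            n = model.n_per_class[cls]
            for marker in panel.names:
                empirical = np.mean(
                    [_shrink(v, n) for m, v in feats_by_class[cls] if m == marker]
                )
                fitted = model.params[marker][cls]["del"].mean
                assert abs(fitted - empirical) < 0.05


class TestScoring:
    def test_score_matches_independent_oracle(self):
        model = toy_model()
        features = [
            MarkerFeatures("M1", del_freq=0.4, allelic_bias=0.5),
            MarkerFeatures("M2", del_freq=0.5, allelic_bias=0.5),
        ]
        assert msi_score(features, model) == pytest.approx(
            oracle_score(features, model), rel=1e-12
        )

    def test_identical_bias_terms_cancel(self):
        # the bias conditionals of toy_model are equal across classes, so
        # changing the bias value must not move the score
        model = toy_model()
        base = [MarkerFeatures("M1", 0.4, 0.5)]
        other = [MarkerFeatures("M1", 0.4, 0.9)]
        assert msi_score(base, model) == pytest.approx(
            msi_score(other, model), rel=1e-12
        )

    def test_label_swap_negates_score(self):
        model = toy_model()
        swapped = MsiModel(
            params={
                m: {MSS: per[MSI_H], MSI_H: per[MSS]}
                for m, per in model.params.items()
            },
            n_per_class=dict(model.n_per_class),
        )
        features = [MarkerFeatures("M1", 0.3, 0.7)]
        assert msi_score(features, swapped) == pytest.approx(
            -msi_score(features, model), rel=1e-12
        )

    def test_monotone_in_del_freq_on_toy_model(self):
        # Beta(10,10) vs Beta(2,38): the density ratio increases over the
        # grid, so the score must be non-decreasing in del_freq
        model = toy_model()
        grid = np.linspace(0.01, 0.7, 40)
        scores = [
            msi_score([MarkerFeatures("M1", x, 0.5)], model) for x in grid
        ]
        assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_unknown_marker_rejected(self):
        model = toy_model()
        with pytest.raises(ScoringError):
            msi_score([MarkerFeatures("M9", 0.4, 0.5)], model)


class TestClassify:
    def test_clear_positive_call(self):
        r = classify(6.0, qc=True)
        assert (r.call, r.needs_repeat) == ("MSI-H", False)

    def test_clear_negative_call(self):
        r = classify(-7.2, qc=True)
        assert (r.call, r.needs_repeat) == ("MSS", False)

    def test_conflicting_repeat_is_uncertain_with_score_zero(self):
        r = classify(3.0, qc=True, repeat_score=-2.0)
        assert r.call == "uncertain"
        assert r.msi_score == 0.0
        assert r.needs_repeat

    def test_confirming_repeat_calls_by_sign(self):
        r = classify(-3.0, qc=True, repeat_score=-1.0)
        assert r.call == "MSS"
        assert r.msi_score == -3.0

    def test_qc_failure_dominates(self):
        assert classify(25.0, qc=False).call == "fail"

    def test_in_band_without_repeat_is_provisional(self):
        r = classify(2.0, qc=True)
        assert r.call == "MSI-H"
        assert r.needs_repeat

    def test_score_zero_without_repeat_is_uncertain(self):
        r = classify(0.0, qc=True)
        assert r.call == "uncertain"
        assert r.needs_repeat

    def test_band_zero_disables_repeats(self):
        r = classify(0.5, qc=True, band=0.0)
        assert (r.call, r.needs_repeat) == ("MSI-H", False)

    def test_call_sign_invariant(self):
        for score in (-8.0, -2.0, 0.0, 2.0, 8.0):
            r = classify(score, qc=True)
            if r.call == "MSI-H":
                assert r.msi_score > 0
            elif r.call == "MSS":
                assert r.msi_score < 0
            elif r.call == "uncertain":
                assert r.msi_score == 0.0


class TestModelIO:
    def test_round_trip_preserves_scores(self, tmp_path):
        model = toy_model()
        path = tmp_path / "model.json"
        save_model(model, path)
        again = load_model(path)
        features = [MarkerFeatures("M1", 0.37, 0.81)]
        assert msi_score(features, again) == pytest.approx(
            msi_score(features, model), abs=1e-9
        )

    def test_truncated_file_rejected(self, tmp_path):
        path = tmp_path / "trunc.json"
        save_model(toy_model(), path)
        path.write_text(path.read_text()[: 40])
        with pytest.raises(ModelIOError):
            load_model(path)

    def test_schema_mismatch_rejected(self, tmp_path):
        path = tmp_path / "old.json"
        path.write_text('{"schema": "something-else", "params": {}}')
        with pytest.raises(ModelIOError, match="schema"):
            load_model(path)

    def test_model_missing_marker_fails_at_scoring(self, toy_panel):
        model = toy_model()  # knows M1/M2 only
        sample = _sample(toy_panel, {"TOY1": {20: 10}})
        feats = compute_features(sample, toy_panel)
        with pytest.raises(ScoringError, match="TOY1"):
            msi_score(feats, model)
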