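"""Stage collapsing, agreement statistics, sleep metrics, Bland-Altman, PCA."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score, f1_score

from sonosleep.hypnogram import Hypnogram, STAGES
from sonosleep.scoring import (
    ConfusionMatrix,
    agreement_metrics,
    bland_altman,
    collapse,
    confusion,
    get_scheme,
    pca_embed,
    sleep_metrics,
)

from util import pairwise_agreement


def hyp(stages, lights_off=0):
    return Hypnogram(np.array(stages, dtype=object), 30.0, lights_off)


class TestCollapse:
    @pytest.mark.parametrize(
        "stage,scheme,expected",
        [
            ("N2", "three", "NREM"),
            ("REM", "two", "Sleep"),
            ("N1", "four", "Light"),
            ("N3", "four", "Deep"),
            ("W", "two", "W"),
        ],
    )
    def test_mappings(self, stage, scheme, expected):
        h = hyp([stage, stage])
        assert collapse(h, scheme).stages[0] == expected

    def test_five_is_identity(self):
        h = hyp(["W", "N1", "N2", "N3", "REM"])
        assert list(collapse(h, "five").stages) == list(h.stages)

    def test_length_and_lights_off_preserved(self):
        h = hyp(["W"] * 7 + ["N2"] * 3, lights_off=2)
        c = collapse(h, 3)
        assert len(c) == 10 and c.lights_off_index == 2

    def test_commutes_with_confusion(self, rng):
        truth = hyp(rng.choice(STAGES, size=200))
        pred = hyp(rng.choice(STAGES, size=200))
        direct = confusion(pred, truth, "three")
        pre = confusion(collapse(pred, "three"), collapse(truth, "three"), "three")
        assert np.array_equal(direct.counts, pre.counts)


class TestConfusion:
    def test_perfect_prediction_diagonal(self, rng):
        h = hyp(rng.choice(STAGES, size=100))
        cm = confusion(h, h, "five")
        assert cm.counts.sum() == 100
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))

    def test_enumerated_three_stage_counts(self):
        truth = hyp(["W", "W", "REM", "N2"])
        pred = hyp(["W", "N2", "REM", "N2"])
        cm = confusion(pred, truth, "three")
        classes = cm.classes
        w, nrem, rem = classes.index("W"), classes.index("NREM"), classes.index("REM")
        assert cm.counts[w, w] == 1
        assert cm.counts[w, nrem] == 1
        assert cm.counts[rem, rem] == 1
        assert cm.counts[nrem, nrem] == 1
        assert cm.counts.sum() == 4

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(hyp(["W"]), hyp(["W", "W"]))


class TestAgreementMetrics:
    def test_perfect_agreement_all_ones(self, rng):
        h = hyp(rng.choice(STAGES, size=60))
        m = agreement_metrics(confusion(h, h, "five"))
        for key in ("accuracy", "cohen_kappa", "macro_f1",
                    "mean_per_class_sensitivity"):
            assert m[key] == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        cm = ConfusionMatrix(np.array([[40, 10], [20, 30]]), ("a", "b"))
        m = agreement_metrics(cm)
        assert m["accuracy"] == pytest.approx(0.70, abs=1e-12)
        assert m["cohen_kappa"] == pytest.approx(0.40, abs=1e-12)
        assert m["mean_per_class_sensitivity"] == pytest.approx(0.70, abs=1e-12)

    def test_chance_level_outer_product_kappa_zero(self):
        row = np.array([30, 50, 20])
        col = np.array([10, 60, 30])
        counts = np.outer(row, col)  # prediction independent of truth
        m = agreement_metrics(ConfusionMatrix(counts, ("x", "y", "z")))
        assert m["cohen_kappa"] == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_marginal_kappa_absent(self):
        counts = np.array([[5, 0], [0, 0]])
        assert agreement_metrics(ConfusionMatrix(counts, ("a", "b")))[
            "cohen_kappa"
        ] is None

    def test_matches_pairwise_recomputation_and_sklearn(self, rng):
        scheme = get_scheme("three")
        for _ in range(30):
            n = int(rng.integers(20, 120))
            truth = rng.choice(STAGES, size=n)
            pred = rng.choice(STAGES, size=n)
            m = agreement_metrics(confusion(hyp(pred), hyp(truth), scheme))
            t3 = [scheme.mapping[s] for s in truth]
            p3 = [scheme.mapping[s] for s in pred]
            ref = pairwise_agreement(t3, p3, scheme.classes)
            for key, val in ref.items():
                if val is None:
                    assert m[key] is None
                else:
                    assert m[key] == pytest.approx(val, abs=1e-9), key
            assert m["cohen_kappa"] == pytest.approx(
                cohen_kappa_score(t3, p3), abs=1e-9
            )
            assert m["macro_f1"] == pytest.approx(
                f1_score(t3, p3, labels=list(scheme.classes), average="macro",
                         zero_division=0.0),
                abs=1e-9,
            )

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            agreement_metrics(ConfusionMatrix(np.zeros((2, 2), int), ("a", "b")))


class TestSleepMetrics:
    def test_worked_eight_epoch_night(self):
        h = hyp(["W", "W", "N1", "N2", "N3", "REM", "W", "N2"], lights_off=0)
        m = sleep_metrics(h)
        assert m.tst == pytest.approx(2.5)
        assert m.sol == pytest.approx(1.0)
        assert m.waso == pytest.approx(0.5)
        assert m.rem_latency == pytest.approx(1.5)
        assert m.se == pytest.approx(62.5)

    def test_all_wake_night_degenerate(self):
        m = sleep_metrics(hyp(["W"] * 10))
        assert m.tst == 0.0 and m.se == 0.0
        assert m.sol is None and m.waso is None and m.rem_latency is None

    def test_all_sleep_night(self):
        m = sleep_metrics(hyp(["N2"] * 8))
        assert m.tst == pytest.approx(4.0)
        assert m.se == pytest.approx(100.0)
        assert m.sol == 0.0 and m.waso == 0.0
        assert m.rem_latency is None

    def test_conservation_and_portions_on_random_nights(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 300))
            h = hyp(rng.choice(STAGES, size=n))
            m = sleep_metrics(h)
            wake_min = np.sum(np.asarray(h.stages) == "W") * 0.5
            assert m.tst + wake_min == pytest.approx(m.recording_minutes, abs=1e-9)
            assert sum(m.portions.values()) == pytest.approx(100.0, abs=1e-6)
            assert 0.0 <= m.se <= 100.0

    def test_lights_off_shifts_onset_latency(self):
        h = hyp(["W", "W", "W", "N2", "N2"], lights_off=1)
        assert sleep_metrics(h).sol == pytest.approx(1.0)

    def test_works_on_collapsed_scheme(self):
        h = collapse(hyp(["W", "N1", "N3", "REM"]), "three")
        m = sleep_metrics(h)
        assert m.tst == pytest.approx(1.5)
        assert m.rem_latency == pytest.approx(1.0)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.lists(st.sampled_from(STAGES), min_size=1, max_size=120))
def test_sleep_time_conservation_property(stages):
    """TST + wake time equals recording time for every possible hypnogram."""
    m = sleep_metrics(hyp(stages))
    wake_min = stages.count("W") * 0.5
    assert m.tst + wake_min == pytest.approx(len(stages) * 0.5, abs=1e-9)
    assert sum(m.portions.values()) == pytest.approx(100.0, abs=1e-6)


class TestBlandAltman:
    def test_identical_pairs_all_zero(self):
        r = bland_altman([(5.0, 5.0), (7.0, 7.0), (9.0, 9.0)])
        assert r.mean_diff == 0.0 and r.sd_diff == 0.0
        assert r.loa_low == 0.0 and r.loa_high == 0.0

    def test_hand_computed_small_sample(self):
        r = bland_altman([(0.0, 1.0), (0.0, 2.0), (0.0, 3.0)])
        assert r.mean_diff == pytest.approx(2.0)
        assert r.sd_diff == pytest.approx(1.0)
        assert r.loa_low == pytest.approx(0.04)
        assert r.loa_high == pytest.approx(3.96)
        # 95% CI of the mean from t(2): 2 +/- 4.3027 / sqrt(3)
        half = 4.302652729911275 / math.sqrt(3)
        assert r.ci_low == pytest.approx(2.0 - half, abs=1e-6)
        assert r.ci_high == pytest.approx(2.0 + half, abs=1e-6)

    def test_swapping_roles_negates(self, rng):
        pairs = [(float(a), float(b)) for a, b in rng.normal(5, 2, size=(10, 2))]
        fwd = bland_altman(pairs)
        rev = bland_altman([(b, a) for a, b in pairs])
        assert rev.mean_diff == pytest.approx(-fwd.mean_diff)
        assert rev.loa_low == pytest.approx(-fwd.loa_high)
        assert rev.loa_high == pytest.approx(-fwd.loa_low)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([(1.0, 2.0)])


class TestPCAEmbed:
    def test_planar_data_fully_explained(self, rng):
        basis = rng.standard_normal((2, 8))
        coeffs = rng.standard_normal((50, 2))
        x = coeffs @ basis
        coords, ev = pca_embed(x, 2)
        assert coords.shape == (50, 2)
        assert ev.sum() == pytest.approx(1.0, abs=1e-9)

    def test_explained_variance_sorted(self, rng):
        x = rng.standard_normal((100, 4, 6))  # time-steps get averaged
        _, ev = pca_embed(x, 2)
        assert ev[0] >= ev[1] >= 0.0
        assert ev.sum() <= 1.0 + 1e-12

    def test_isotropic_cloud_balanced(self):
        x = np.random.default_rng(5).standard_normal((1000, 6))
        _, ev = pca_embed(x, 2)
        assert abs(ev[0] - ev[1]) < 0.05

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pca_embed(np.zeros((1, 5)), 2)
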