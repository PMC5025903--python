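import numpy as np
import pytest

import synergait as sg
from synergait.errors import DegenerateSynergyError, InvalidParameterError
from synergait.synergy import (
    SynergySet,
    circular_xcorr_max,
    match_synergies,
    match_synergies_bruteforce,
    select_model_order,
)

from conftest import FAST_NMF


class TestNormalizeUnit:
    def test_three_four_five_column(self):
        W = np.array([[3.0], [4.0], [0.0]])
        H = np.ones((1, 100))
        out = sg.normalize_unit(SynergySet(["a", "b", "c"], W, H))
        assert np.allclose(out.W[:, 0], [0.6, 0.8, 0.0])
        assert np.allclose(out.H, 5.0)

    def test_identity_on_unit_columns(self, template):
        out = sg.normalize_unit(template)
        assert np.allclose(out.W, template.W)
        assert np.allclose(out.H, template.H)

    def test_product_invariance(self, rng):
        W = rng.uniform(0.1, 2, size=(6, 3))
        H = rng.uniform(0, 1, size=(3, 200))
        s = SynergySet([f"m{i}" for i in range(6)], W, H)
        out = sg.normalize_unit(s)
        assert np.max(np.abs(out.W @ out.H - W @ H)) < 1e-9
        assert np.allclose(np.linalg.norm(out.W, axis=0), 1.0, atol=1e-9)

    def test_zero_column_raises(self):
        W = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(DegenerateSynergyError):
            sg.normalize_unit(SynergySet(["a", "b"], W, np.ones((2, 100))))


class TestMatchSynergies:
    def test_recovers_shuffle(self, template):
        perm = [2, 0, 3, 1]
        shuffled = SynergySet(
            template.muscle_names, template.W[:, perm], template.H[perm, :]
        )
        matched, _, cosines = match_synergies(shuffled, template)
        assert matched.labels == list(template.labels)
        assert np.allclose(matched.W, template.W)
        assert np.allclose(cosines, 1.0)

    def test_scaling_does_not_change_assignment(self, template):
        scaled = SynergySet(template.muscle_names, template.W * 2.0, template.H)
        matched, _, cosines = match_synergies(scaled, template)
        assert np.allclose(cosines, 1.0)

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("j_cand", [3, 4])
    def test_equals_bruteforce_oracle(self, template, seed, j_cand):
        rng = np.random.default_rng(seed)
        cand = SynergySet(
            template.muscle_names,
            rng.uniform(0.01, 1, size=(8, j_cand)),
            rng.uniform(0, 1, size=(j_cand, 100)),
        )
        _, assignment, _ = match_synergies(cand, template)
        oracle = match_synergies_bruteforce(cand, template)
        assert np.array_equal(assignment, oracle)

    def test_muscle_mismatch_raises(self, template):
        other = SynergySet(["x"] * 0 + [f"m{i}" for i in range(8)], template.W, template.H)
        with pytest.raises(InvalidParameterError):
            match_synergies(other, template)


class TestAverageGroup:
    def test_identical_sets_average_to_input(self, template):
        out = sg.average_group([template, template, template], template)
        assert np.allclose(out.W, template.W, atol=1e-12)
        assert np.allclose(out.mean_profiles(), template.mean_profiles(), atol=1e-9)

    def test_two_onehot_columns_average_to_diagonal(self):
        muscles = ["a", "b"]
        ref = SynergySet(muscles, np.array([[1.0], [1.0]]) / np.sqrt(2), np.ones((1, 100)))
        s1 = SynergySet(muscles, np.array([[1.0], [0.0]]), np.ones((1, 100)))
        s2 = SynergySet(muscles, np.array([[0.0], [1.0]]), np.ones((1, 100)))
        out = sg.average_group([s1, s2], ref)
        assert np.allclose(out.W[:, 0], [1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_mean_of_perturbed_copies_close_to_truth(self, template, rng):
        sets = []
        for _ in range(13):
            W = np.clip(template.W + rng.normal(0, 0.05, template.W.shape), 0, None)
            sets.append(SynergySet(template.muscle_names, W, template.H.copy()))
        out = sg.average_group(sets, template)
        # clipping at zero biases zero entries upward by ~sd/sqrt(2*pi);
        # entries stay within a few hundredths of the template
        assert np.max(np.abs(out.W - template.W)) < 0.06
        assert np.mean(np.abs(out.W - template.W)) < 0.02


class TestCircularXcorr:
    def test_identical_profiles(self, template):
        r, lag = circular_xcorr_max(template.H[0], template.H[0])
        assert r == pytest.approx(1.0)
        assert lag == 0

    @pytest.mark.parametrize("shift", [5, -7, 49, -50])
    def test_circular_shift_construction(self, template, shift):
        a = template.H[1]
        b = np.roll(a, shift)
        r, lag = circular_xcorr_max(a, b)
        assert r == pytest.approx(1.0)
        assert lag == shift

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_bruteforce_all_lags(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.uniform(size=100), rng.uniform(size=100)
        r, lag = circular_xcorr_max(a, b)
        ac, bc = a - a.mean(), b - b.mean()
        denom = np.linalg.norm(ac) * np.linalg.norm(bc)
        best = max(
            ((float(sum(ac[t] * bc[(t + l) % 100] for t in range(100)) / denom), l)
             for l in range(-50, 50)),
            key=lambda p: (p[0], -abs(p[1])),
        )
        assert r == pytest.approx(best[0], abs=1e-12)
        assert abs(lag) == abs(best[1]) or r == pytest.approx(best[0])


class TestCompareConditions:
    def test_self_comparison(self, template):
        cmp = sg.compare_conditions(template, template)
        assert np.allclose(cmp.similarity, 1.0)
        assert np.allclose(cmp.correlation, 1.0)
        assert np.all(cmp.lag == 0)

    def test_shifted_profiles_report_lag(self, template):
        shifted = SynergySet(
            template.muscle_names, template.W.copy(),
            np.vstack([np.roll(h, 5) for h in template.H]), list(template.labels),
        )
        cmp = sg.compare_conditions(template, shifted)
        assert np.allclose(cmp.correlation, 1.0)
        assert np.all(np.abs(cmp.lag) == 5)


class TestModelOrderSelection:
    def test_rank_one_matrix_selects_one(self, rng):
        M = np.outer(rng.uniform(0.1, 1, 8), rng.uniform(0.1, 1, 200))
        assert select_model_order(M, seed=0, n_restarts=3, max_iter=300, tol=1e-6) == 1

    def test_healthy_subject_selects_four(self, template):
        sub = sg.make_healthy_cohort(template, n_subjects=1, config=sg.SynthConfig(seed=5))[0]
        j = select_model_order(sub.concatenated(), seed=0, n_restarts=4, max_iter=250, tol=1e-5)
        assert j == 4

    def test_merged_patient_selects_three(self, template):
        pat = sg.make_stroke_patient(
            template, merge_pairs=[("WA", "LD")], config=sg.SynthConfig(seed=6)
        )
        j = select_model_order(pat.concatenated(), seed=0, n_restarts=4, max_iter=250, tol=1e-5)
        assert j == 3

    def test_jmax_exhausted_warns(self, template):
        M = template.W @ template.H  # needs 4 synergies, but cap at 1
        with pytest.warns(RuntimeWarning):
            j = select_model_order(M, j_max=1, seed=0, n_restarts=2, max_iter=100)
        assert j == 1


class TestModelResultsApi:
    def test_fit_reports_vaf_and_summary(self, template):
        sub = sg.make_healthy_cohort(template, n_subjects=1, config=sg.SynthConfig(seed=9))[0]
        res = sg.GaitSynergyModel(sub).fit(n_synergies=4, seed=0, **FAST_NMF)
        assert res.vaf_total > 0.95
        text = res.summary()
        assert "total VAF" in text and "GM" in text
        matched = res.match_to(template)
        assert matched.synergies.labels == list(template.labels)

    def test_json_roundtrip(self, template):
        back = SynergySet.from_json(template.to_json())
        assert back.muscle_names == template.muscle_names
        assert np.allclose(back.W, template.W)
        assert np.allclose(back.H, template.H)
        assert back.labels == template.labels
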