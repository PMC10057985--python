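import numpy as np
import pytest

from nirtrace.errors import GridError, ParameterError
from nirtrace.models import (fit_simca, is_separable, residual_ratio,
                             simca_classify, simca_model_distance)
from nirtrace.preprocess import fit_pipeline, apply_pipeline
from nirtrace.split import MCCVPlan, mccv_splits
from nirtrace.synthetic import default_scenario

from conftest import make_set


def two_class_set(rng, n_per=20, p=30, shift=6.0):
    a = rng.normal(size=(2 * n_per, p))
    a[n_per:] += shift
    labels = ["A"] * n_per + ["B"] * n_per
    return make_set(a, labels=labels)


class TestFitting:
    def test_submodel_per_class_and_orthonormal_loadings(self, rng):
        m = fit_simca(two_class_set(rng))
        assert set(m.submodels) == {"A", "B"}
        for sub in m.submodels.values():
            gram = sub.loadings.T @ sub.loadings
            assert np.abs(gram - np.eye(sub.k)).max() < 1e-8
            assert sub.s0_sq >= 0

    def test_class_center_sample_accepted(self, rng):
        s = two_class_set(rng)
        m = fit_simca(s)
        sub = m.submodels["A"]
        r = residual_ratio(sub, make_set(sub.center, labels=["A"]))
        assert r[0] == pytest.approx(0.0, abs=1e-18)

    def test_fixed_k_on_rank2_data_recovers_noise_variance(self, rng):
        n, p, sigma = 100, 40, 0.05
        scores = rng.normal(size=(n, 2)) * [3.0, 1.5]
        basis = np.linalg.qr(rng.normal(size=(p, 2)))[0]
        a = scores @ basis.T + rng.normal(0, sigma, size=(n, p))
        s = make_set(a, labels=["A"] * n)
        m = fit_simca(s, k_rule=2)
        assert m.submodels["A"].s0_sq == pytest.approx(sigma**2, rel=0.15)

    def test_tiny_class_rejected(self, rng):
        s = make_set(rng.normal(size=(5, 8)), labels=["A"] * 3 + ["B"] * 2)
        with pytest.raises(ParameterError):
            fit_simca(s)

    def test_self_acceptance_rate_on_simulated_members(self, rng):
        s = two_class_set(rng, n_per=30, p=50)
        m = fit_simca(s)
        for sub in m.submodels.values():
            nsim = 2000
            scores = rng.normal(size=(nsim, sub.k)) * np.sqrt(sub.score_variances)
            eps = rng.normal(0, np.sqrt(sub.s0_sq), size=(nsim, 50))
            X = sub.center + scores @ sub.loadings.T + eps
            rate = np.mean(residual_ratio(sub, X) <= sub.f_limit)
            assert rate >= 0.93


class TestClassification:
    def test_center_sample_assigned_and_member_of_own_class_only(self, rng):
        s = two_class_set(rng, shift=10.0)
        m = fit_simca(s)
        probe = make_set(m.submodels["A"].center, labels=["A"])
        assigned, membership, _ = simca_classify(m, probe)
        assert assigned[0] == "A"
        assert membership["A"][0] and not membership["B"][0]

    def test_tie_breaks_to_first_sorted_label(self, rng):
        a = rng.normal(size=(40, 20))
        s = make_set(np.vstack([a, a]),
                     labels=["A"] * 40 + ["B"] * 40)
        # identical class data -> identical models -> all ratios tie
        m = fit_simca(s)
        probe = make_set(rng.normal(size=(5, 20)), labels=["A"] * 5,
                         prefix="p")
        assigned, _, ratios = simca_classify(m, probe)
        assert np.allclose(ratios[:, 0], ratios[:, 1])
        assert np.all(assigned == "A")

    def test_separable_synthetic_test_accuracy_perfect(self):
        s, _ = default_scenario("tiny", "strong").generate(seed=3)
        plan = MCCVPlan(s.n_samples, n_repeats=1, seed=3)
        (tr, te), = mccv_splits(s.labels, plan)
        pipe, train = fit_pipeline(["snv"], s.subset(tr))
        test = apply_pipeline(pipe, s.subset(te))
        assigned, _, _ = simca_classify(fit_simca(train), test)
        assert np.mean(assigned == test.labels) == 1.0

    def test_grid_mismatch(self, rng):
        m = fit_simca(two_class_set(rng))
        with pytest.raises(GridError):
            simca_classify(m, make_set(rng.normal(size=(2, 31)),
                                       labels=["A", "B"]))


class TestModelDistance:
    def test_identical_data_gives_unit_distance(self, rng):
        a = rng.normal(size=(25, 15))
        s = make_set(a, labels=["A"] * 25)
        sub = fit_simca(s).submodels["A"]
        assert simca_model_distance(sub, sub, s, s) == 1.0

    def test_symmetry(self, rng):
        s = two_class_set(rng)
        m = fit_simca(s)
        ia = np.flatnonzero(s.labels == "A")
        ib = np.flatnonzero(s.labels == "B")
        d1 = simca_model_distance(m.submodels["A"], m.submodels["B"],
                                  s.subset(ia), s.subset(ib))
        d2 = simca_model_distance(m.submodels["B"], m.submodels["A"],
                                  s.subset(ib), s.subset(ia))
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_separability_flag_threshold(self):
        assert not is_separable(3.0)
        assert is_separable(3.0001)

    def test_distance_monotone_in_class_separation(self):
        dists = []
        for sep in ("weak", "moderate", "strong"):
            s, _ = default_scenario("tiny", sep).generate(seed=1)
            pipe, t = fit_pipeline(["snv"], s)
            m = fit_simca(t)
            ia = np.flatnonzero(t.labels == "nonZJ")
            ib = np.flatnonzero(t.labels == "ZJ")
            dists.append(simca_model_distance(
                m.submodels["nonZJ"], m.submodels["ZJ"],
                t.subset(ia), t.subset(ib)))
        assert dists[0] < dists[1] < dists[2]
        assert is_separable(dists[2])
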