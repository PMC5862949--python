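import numpy as np
import pytest

from mirsig import bccp, simulate
from mirsig.bccp import (BCCPModel, classify_cohort, compound_covariate, fit,
                         loocv, posterior)
from tests.conftest import make_matrix


def separable_panel(rng, n_per_class=3, n_genes=10, shift=5.0, noise=0.1):
    values = rng.normal(8, noise, size=(n_genes, 2 * n_per_class))
    values[:, :n_per_class] += shift
    m = make_matrix(values, ["high"] * n_per_class + ["low"] * n_per_class)
    labels = {s: m.sample_condition[s] for s in m.sample_ids}
    return m, labels


class TestFit:
    def test_hand_worked_four_sample_two_gene_model(self):
        """c_j, class means, and pooled s^2 match the arithmetic done
        directly (standardize, pooled t, weighted sum) in this test."""
        values = np.array([[1.0, 2.0, 3.0, 4.0],
                           [4.0, 3.0, 2.0, 1.0]])
        m = make_matrix(values, ["high", "high", "low", "low"])
        labels = {s: c for s, c in m.sample_condition.items()}
        model = fit(m, labels, ["g0", "g1"])

        # oracle arithmetic, independent of the implementation path
        x = (values - values.mean(axis=1, keepdims=True)) \
            / values.std(axis=1, ddof=1, keepdims=True)
        t = np.empty(2)
        for i in range(2):
            h, lo = x[i, :2], x[i, 2:]
            sp2 = (h.var(ddof=1) + lo.var(ddof=1)) / 2
            t[i] = (h.mean() - lo.mean()) / np.sqrt(sp2 * (0.5 + 0.5))
        c = t @ x
        np.testing.assert_allclose(compound_covariate(
            model, m, internal_standardization=False), c, atol=1e-10)
        assert model.m_high == pytest.approx(c[:2].mean(), abs=1e-10)
        assert model.m_low == pytest.approx(c[2:].mean(), abs=1e-10)
        s2 = (c[:2].var(ddof=1) + c[2:].var(ddof=1)) / 2
        assert model.s2 == pytest.approx(s2, abs=1e-10)

    def test_separated_classes_put_training_posteriors_on_correct_side(self, rng):
        m, labels = separable_panel(rng)
        model = fit(m, labels, m.gene_ids)
        assert model.m_high != model.m_low
        p = bccp.posterior_from_expression(model, m,
                                           internal_standardization=False)
        for s, prob in zip(m.sample_ids, p):
            assert (prob > 0.5) == (labels[s] == "high")

    def test_label_swap_maps_posterior_to_complement(self, rng):
        m, labels = separable_panel(rng, shift=1.0, noise=1.0)
        swapped = {s: ("high" if v == "low" else "low")
                   for s, v in labels.items()}
        model = fit(m, labels, m.gene_ids)
        model_sw = fit(m, swapped, m.gene_ids)
        assert model_sw.m_high == pytest.approx(-model.m_low, abs=1e-10)
        c = compound_covariate(model, m, internal_standardization=False)
        c_sw = compound_covariate(model_sw, m, internal_standardization=False)
        np.testing.assert_allclose(
            posterior(model_sw, c_sw), 1 - posterior(model, c), atol=1e-10)

    def test_single_class_rejected(self, rng):
        values = rng.normal(size=(5, 4))
        m = make_matrix(values, ["high"] * 4)
        with pytest.raises(ValueError, match="classes"):
            fit(m, {s: "high" for s in m.sample_ids}, m.gene_ids)

    def test_missing_signature_genes_dropped(self, rng):
        m, labels = separable_panel(rng)
        model = fit(m, labels, m.gene_ids + ["ABSENT1", "ABSENT2"])
        assert model.genes == m.gene_ids

    def test_json_roundtrip(self, rng, tmp_path):
        m, labels = separable_panel(rng)
        model = fit(m, labels, m.gene_ids)
        model.to_json(tmp_path / "m.json")
        back = BCCPModel.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(back.weights, model.weights)
        assert back.m_high == model.m_high and back.s2 == model.s2


class TestPosterior:
    def _model(self, m_high=1.0, m_low=-1.0, s2=1.0, prior=0.5):
        return BCCPModel(genes=["g"], weights=np.ones(1),
                         train_mean=np.zeros(1), train_sd=np.ones(1),
                         m_high=m_high, m_low=m_low, s2=s2, prior_high=prior)

    def test_midpoint_is_half_under_equal_priors(self):
        model = self._model(m_high=2.0, m_low=-4.0)
        assert posterior(model, -1.0) == pytest.approx(0.5, abs=1e-12)

    def test_closed_form_logistic_value(self):
        # equal priors, m=+-1, s2=1, c=1 -> 1 / (1 + e^-2)
        model = self._model()
        assert posterior(model, 1.0) == pytest.approx(1 / (1 + np.exp(-2)),
                                                      abs=1e-9)

    def test_matches_two_gaussian_logistic_for_random_parameters(self, rng):
        """Posterior equals the closed-form logistic reduction of the
        Gaussian Bayes rule over random parameter draws."""
        for _ in range(200):
            m_high, m_low = sorted(rng.normal(scale=3, size=2))[::-1]
            s2 = rng.uniform(0.1, 4.0)
            prior = rng.uniform(0.05, 0.95)
            c = rng.normal(scale=5)
            model = self._model(m_high, m_low, s2, prior)
            a = (m_high - m_low) / s2
            b = (m_low ** 2 - m_high ** 2) / (2 * s2) \
                + np.log(prior / (1 - prior))
            expected = 1.0 / (1.0 + np.exp(-(a * c + b)))
            assert posterior(model, c) == pytest.approx(expected, rel=1e-9,
                                                        abs=1e-12)

    def test_strictly_increasing_in_c(self):
        model = self._model()
        grid = np.linspace(-5, 5, 101)
        p = posterior(model, grid)
        assert np.all(np.diff(p) > 0)

    def test_extreme_covariate_is_numerically_stable(self):
        model = self._model()
        assert posterior(model, 1e4) == pytest.approx(1.0)
        assert posterior(model, -1e4) == pytest.approx(0.0, abs=1e-12)


class TestLOOCV:
    def test_deterministic(self, rng):
        m, labels = separable_panel(rng, shift=0.5, noise=1.0)
        r1, calls1 = loocv(m, labels, m.gene_ids)
        r2, calls2 = loocv(m, labels, m.gene_ids)
        assert r1 == r2
        assert calls1.equals(calls2)

    def test_zero_error_on_separable_classes(self):
        """Class shift 3x noise sd, 6+6 samples, 50 genes: LOOCV error 0 in
        (essentially) every run."""
        zero = 0
        for k in range(20):
            rng = np.random.default_rng(4200 + k)
            m, labels = separable_panel(rng, n_per_class=6, n_genes=50,
                                        shift=1.5, noise=0.5)
            rate, _ = loocv(m, labels, m.gene_ids)
            zero += rate == 0
        assert zero >= 19

    def test_permutation_null_centers_at_half(self):
        rng = np.random.default_rng(77)
        m, _ = separable_panel(rng, n_per_class=6, n_genes=30, shift=0.0,
                               noise=1.0)
        rates = []
        for _ in range(100):
            perm = rng.permutation(["high"] * 6 + ["low"] * 6)
            labels = dict(zip(m.sample_ids, perm))
            rate, _ = loocv(m, labels, m.gene_ids)
            rates.append(rate)
        assert abs(np.mean(rates) - 0.5) <= 0.1


class TestClassifyCohort:
    def _fit_study(self, seed=0, n_patients=150):
        design = simulate.CohortDesign(
            n_patients=n_patients, n_genes=300, n_signature_genes=100,
            delta_sig=1.0, noise_sd=0.5, seed=seed)
        panel, labels = simulate.generate_labeled_panel(design, 8, 8)
        model = fit(panel, labels, design.signature_genes)
        cohort, _, truth = simulate.generate_cohort(design)
        return model, cohort, truth

    def test_labels_consistent_with_cutoffs(self):
        model, cohort, _ = self._fit_study()
        res = classify_cohort(model, cohort)
        for _, row in res.table.iterrows():
            if row["p_high"] > 0.7:
                assert row["label"] == "high"
            elif row["p_high"] < 0.3:
                assert row["label"] == "low"
            else:
                assert row["label"] == "undetermined"

    def test_strong_separation_leaves_few_undetermined(self):
        model, cohort, _ = self._fit_study(seed=1)
        res = classify_cohort(model, cohort)
        undet = (res.table["label"] == "undetermined").mean()
        assert undet < 0.05

    def test_planted_subtype_recovered(self):
        model, cohort, truth = self._fit_study(seed=2)
        res = classify_cohort(model, cohort)
        det = res.table[res.table["label"] != "undetermined"]
        agree = (det["label"] == det["patient"].map(truth["subtype"])).mean()
        assert agree >= 0.9

    def test_degenerate_cutoffs_yield_no_undetermined(self):
        model, cohort, _ = self._fit_study(seed=3)
        res = classify_cohort(model, cohort, high_cut=0.5, low_cut=0.5)
        assert (res.table["label"] != "undetermined").all()

    def test_platform_mismatch_rejected(self, rng):
        model, cohort, _ = self._fit_study(seed=4)
        other = make_matrix(rng.normal(size=(4, 5)), ["x"] * 5)
        with pytest.raises(ValueError, match="platform"):
            classify_cohort(model, other)
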