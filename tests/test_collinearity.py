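import warnings

import numpy as np
import pandas as pd
import pytest

from bacaba import collinearity, datasets, synthetic
from bacaba.datatypes import ValidityError


def _means_frame(rng, n=30, p=5, names=None):
    names = names or [f"T{i+1}" for i in range(p)]
    return pd.DataFrame(rng.normal(0, 1, size=(n, p)), columns=names)


class TestCorrelationMatrix:
    def test_proportional_traits_correlate_perfectly(self, rng):
        df = _means_frame(rng, p=2)
        df["T2"] = 3.0 * df["T1"] + 1.0
        R = collinearity.correlation_matrix(df)
        assert R.loc["T1", "T2"] == pytest.approx(1.0)

    def test_negated_trait_correlates_minus_one(self, rng):
        df = _means_frame(rng, p=2)
        df["T2"] = -df["T1"]
        assert collinearity.correlation_matrix(df).loc["T1", "T2"] == pytest.approx(-1.0)

    def test_independent_traits_near_zero(self, rng):
        R = collinearity.correlation_matrix(_means_frame(rng, n=2000, p=4))
        off = R.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_zero_variance_trait_named(self, rng):
        df = _means_frame(rng, p=3)
        df["T2"] = 7.0
        with pytest.raises(ValidityError, match="T2"):
            collinearity.correlation_matrix(df)


class TestDiagnose:
    def test_identity_matrix_is_weak(self):
        R = pd.DataFrame(np.eye(8), columns=list("ABCDEFGH"), index=list("ABCDEFGH"))
        d = collinearity.diagnose(R)
        assert d.condition_number == pytest.approx(1.0)
        np.testing.assert_allclose(d.vif, 1.0)
        assert d.severity == "weak"

    def test_published_condition_index_pairing(self):
        # printed largest eigenvalue 5.483 and singular value 0.0503 give the
        # printed condition index of 46.60 only under sigma1/sigmaj
        ci = np.sqrt(5.483) / 0.0503
        assert abs(ci - 46.60) < 0.1
        # the lambda-ratio convention would give a wildly different number
        assert abs(5.483 / 0.0503**2 - 46.60) > 100

    def test_eigenvalue_sum_equals_trait_count(self, rng):
        for p in (4, 6, 8):
            R = collinearity.correlation_matrix(_means_frame(rng, n=25, p=p))
            d = collinearity.diagnose(R)
            assert d.eigenvalues.sum() == pytest.approx(p, abs=1e-9)

    def test_published_spectra_sum_to_trait_count(self):
        assert sum(datasets.reference_eigenvalues("eight_traits")) == pytest.approx(8.000, abs=5e-3)
        assert sum(datasets.reference_eigenvalues("six_traits")) == pytest.approx(6.001, abs=5e-3)

    def test_eigen_reconstruction(self, rng):
        R = collinearity.correlation_matrix(_means_frame(rng, n=20, p=6))
        d = collinearity.diagnose(R)
        back = d.eigenvectors @ np.diag(d.eigenvalues) @ d.eigenvectors.T
        np.testing.assert_allclose(back, d.R, atol=1e-8)

    def test_vif_matches_regression_oracle(self, rng):
        means = _means_frame(rng, n=40, p=6)
        means["T2"] += 0.8 * means["T1"]  # induce some collinearity
        R = collinearity.correlation_matrix(means)
        d = collinearity.diagnose(R)
        Z = (means - means.mean()) / means.std(ddof=1)
        for j, t in enumerate(means.columns):
            X = Z.drop(columns=[t]).to_numpy()
            y = Z[t].to_numpy()
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r2 = 1 - ((y - X @ beta) ** 2).sum() / (y**2).sum()
            assert d.vif[j] == pytest.approx(1.0 / (1.0 - r2), rel=1e-8)

    def test_non_symmetric_rejected(self):
        R = pd.DataFrame([[1.0, 0.5], [0.2, 1.0]], columns=["A", "B"], index=["A", "B"])
        with pytest.raises(ValidityError):
            collinearity.diagnose(R)


class TestOffenders:
    def test_planted_ratio_trait_flagged(self, study_table):
        table, _, _ = study_table  # PY derived from PM/FM
        R = collinearity.correlation_matrix(table.genotype_means())
        d = collinearity.diagnose(R)
        offenders = collinearity.identify_offenders(d, n_small=2)
        assert set(offenders) & {"FM", "PM", "PY"}

    def test_tie_breaks_with_warning(self):
        # exactly tied loadings in the smallest eigenvector resolve to the
        # first trait, with a warning
        lam = np.array([1.5, 0.5])
        vec = np.array([[np.sqrt(0.5), np.sqrt(0.5)], [np.sqrt(0.5), np.sqrt(0.5)]])
        with pytest.warns(UserWarning, match="tied"):
            out = collinearity.identify_offenders_from(lam, vec, ("A", "B"), 1)
        assert out == ("A",)

    def test_range_error(self):
        R = pd.DataFrame(np.eye(3), columns=list("ABC"), index=list("ABC"))
        d = collinearity.diagnose(R)
        with pytest.raises(ValidityError):
            collinearity.identify_offenders(d, n_small=4)


class TestIterativeExclusion:
    def test_derived_ratio_pathology_is_removed(self, study_table):
        table, _, _ = study_table
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            trail = collinearity.screen_table(table)
        assert trail.passed
        removed = {s.excluded for s in trail.steps}
        assert removed and removed & {"FM", "PM", "PY"}
        assert trail.final.condition_number < 100
        assert trail.final.vif.max() <= 10

    def test_independent_traits_keep_everything(self, rng):
        means = _means_frame(rng, n=200, p=5)
        trail = collinearity.iterative_exclusion(means)
        assert trail.steps == () and len(trail.retained) == 5

    def test_published_reduced_spectrum_passes_gate(self):
        lam = datasets.reference_eigenvalues("six_traits")
        cn = max(lam) / min(lam)
        assert cn == pytest.approx(3.852 / 0.053, rel=1e-12)
        assert cn < 100
        assert collinearity.classify_cn(cn) == "weak"

    def test_exclusion_reduces_condition_number_on_planted_fixture(self):
        # monotone CN decrease along the trail, checked over planted-ratio
        # synthetic populations
        drops = 0
        for seed in range(10):
            cfg = synthetic.study_design_config(seed=seed, derive_py=True)
            table, _ = synthetic.simulate_population(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                trail = collinearity.screen_table(table)
            cns = [s.cn_before for s in trail.steps] + [trail.final.condition_number]
            assert all(b < a for a, b in zip(cns, cns[1:]))
            drops += len(trail.steps)
        assert drops >= 10  # at least one exclusion per planted population
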