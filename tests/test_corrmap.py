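"""Age-partial correlation machinery and Fisher r-to-z comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sleepspec import (build_corrmap, fisher_compare, normal_two_tailed_p,
                       partial_corr, residualize)
from sleepspec.corrmap import dimorphism_test
from sleepspec.exceptions import AlignmentError, ValidationError
from sleepspec.synthcohort import CohortSpec, PlantedEffect, generate_cohort, null_spec
from tests.conftest import random_spectra


def oracle_partial_corr(x, y, c):
    """Independent two-regression oracle: correlate OLS residuals."""
    rx = x - np.polyval(np.polyfit(c, x, 1), c)
    ry = y - np.polyval(np.polyfit(c, y, 1), c)
    r, _ = stats.pearsonr(rx, ry)
    n = len(x)
    t = r * np.sqrt((n - 3) / (1 - r ** 2))
    p = 2 * stats.t.sf(abs(t), n - 3)
    return r, p


class TestPartialCorr:
    def test_orthogonal_covariate_reduces_to_pearson(self, rng):
        # covariate made exactly orthogonal to 1, x and y by Gram-Schmidt
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        q, _ = np.linalg.qr(np.column_stack([np.ones(50), x, y]))
        c = rng.normal(size=50)
        c = c - q @ (q.T @ c)
        r, p, n = partial_corr(x, y, c)
        r_plain, _ = stats.pearsonr(x, y)
        assert r == pytest.approx(r_plain, abs=1e-12)

    def test_matches_two_regression_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            c = rng.normal(size=12)
            r, p, n = partial_corr(x, y, c)
            ro, po = oracle_partial_corr(x, y, c)
            assert r == pytest.approx(ro, abs=1e-12)
            assert p == pytest.approx(po, abs=1e-12)

    def test_covariate_equal_to_y_is_undefined(self, rng):
        c = rng.normal(size=30)
        x = rng.normal(size=30)
        r, p, n = partial_corr(x, c.copy(), c)
        assert np.isnan(r) and np.isnan(p)

    def test_nan_triples_dropped(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        c = rng.normal(size=20)
        x2 = x.copy()
        x2[0] = np.nan
        r_full, _, n_full = partial_corr(x, y, c)
        r_drop, _, n_drop = partial_corr(x2, y, c)
        assert n_drop == 19
        ro, _ = oracle_partial_corr(x[1:], y[1:], c[1:])
        assert r_drop == pytest.approx(ro, abs=1e-12)

    def test_too_few_triples(self, rng):
        with pytest.raises(ValidationError, match=">= 5"):
            partial_corr(np.ones(4), np.ones(4), np.ones(4))

    @settings(derandomize=True, max_examples=30)
    @given(ax=st.floats(0.1, 5), bx=st.floats(-5, 5),
           ay=st.floats(0.1, 5), by=st.floats(-5, 5),
           ac=st.floats(0.1, 5), bc=st.floats(-5, 5))
    def test_affine_invariance(self, ax, bx, ay, by, ac, bc):
        rng = np.random.default_rng(99)
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        c = rng.normal(size=25)
        r0, p0, _ = partial_corr(x, y, c)
        r1, p1, _ = partial_corr(ax * x + bx, ay * y + by, ac * c + bc)
        assert r1 == pytest.approx(r0, abs=1e-9)
        assert p1 == pytest.approx(p0, abs=1e-9)


class TestResidualize:
    def test_constant_covariate_centers(self, rng):
        v = rng.normal(size=10)
        out = residualize(v, np.full(10, 2.0))
        assert np.allclose(out, v - v.mean())

    def test_orthogonal_to_covariate(self, rng):
        v = rng.normal(size=40)
        c = rng.normal(size=40)
        out = residualize(v, c)
        assert abs(out @ c) < 1e-9
        assert abs(out.sum()) < 1e-9

    def test_residual_correlation_equals_partial(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        c = rng.normal(size=30)
        r, _, _ = partial_corr(x, y, c)
        rr, _ = stats.pearsonr(residualize(x, c), residualize(y, c))
        assert rr == pytest.approx(r, abs=1e-12)


class TestBuildCorrmap:
    def _cohort(self, seed=3, rho=0.45):
        spec = CohortSpec(
            n_female=68, n_male=83, states=("REM",), electrode_failures={},
            planted=[PlantedEffect("REM", 18.0, 19.0, ["Fz"], "F", rho)],
            seed=seed)
        return generate_cohort(spec)

    def test_planted_effect_recovered(self):
        rs = []
        for seed in range(25):
            spectra, subjects, res, _ = self._cohort(seed=seed)
            cm = build_corrmap(spectra["REM"], res, subjects, "F")
            ei = cm.electrodes.index("Fz")
            bi = int(np.argmin(np.abs(cm.bins - 18.75)))
            rs.append(cm.r[ei, bi])
        # mean of 25 cohort estimates: se ~ 0.1/sqrt(25) = 0.02
        assert np.mean(rs) == pytest.approx(0.45, abs=0.06)

    def test_male_cells_null(self):
        rs = []
        for seed in range(10):
            spectra, subjects, res, _ = self._cohort(seed=100 + seed)
            cm = build_corrmap(spectra["REM"], res, subjects, "M")
            ei = cm.electrodes.index("Fz")
            bi = int(np.argmin(np.abs(cm.bins - 18.75)))
            rs.append(cm.r[ei, bi])
        assert abs(np.mean(rs)) < 0.1

    def test_null_false_positive_rate(self):
        # grid-wide p<0.05 fraction over repeated null cohorts ~ alpha
        fracs = []
        elecs = ["F3", "Fz", "F4", "C3", "Cz", "C4"]
        for seed in range(200):
            spec = null_spec(n_female=30, n_male=5, electrodes=elecs,
                             seed=5000 + seed)
            spectra, subjects, res, _ = generate_cohort(spec)
            cm = build_corrmap(spectra["REM"], res, subjects, "F")
            fracs.append(np.mean(cm.p < 0.05))
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.01)

    def test_missing_electrode_reduces_n(self, rng):
        spectra, subjects, res, _ = self._cohort(seed=7)
        table = spectra["REM"]
        fz = table.electrodes.index("Fz")
        table.values[0, fz] = np.nan  # subject s001 is female
        cm = build_corrmap(table, res, subjects, "F")
        assert cm.n[fz, 0] == 67
        assert cm.n[table.electrodes.index("Cz"), 0] == 68

    def test_unknown_subject_is_alignment_error(self, rng):
        spectra, subjects, res, _ = self._cohort(seed=8)
        spectra["REM"].subjects[0] = "ghost"
        with pytest.raises(AlignmentError, match="ghost"):
            build_corrmap(spectra["REM"], res, subjects, "F")

    def test_sparse_electrode_marked_missing(self, rng):
        table = random_spectra(rng, n_subjects=8)
        table.values[:6, 0] = np.nan  # only 2 subjects left on F3
        import pandas as pd
        subjects = pd.DataFrame({
            "subject_id": table.subjects, "sex": "F",
            "age": rng.uniform(20, 60, 8), "raven_raw": 20.0,
            "cft_raw": np.nan, "device_id": "d"})
        res = pd.DataFrame({"subject_id": table.subjects,
                            "res": rng.normal(20, 5, 8)})
        cm = build_corrmap(table, res, subjects, "F")
        assert np.isnan(cm.r[0]).all()
        assert not np.isnan(cm.r[1]).any()


class TestFisher:
    def test_equal_r_is_zero(self):
        z, p = fisher_compare(0.4, 50, 0.4, 60)
        assert z == 0 and p == pytest.approx(1.0)

    def test_antisymmetry(self):
        z1, p1 = fisher_compare(0.5, 40, 0.2, 55)
        z2, p2 = fisher_compare(0.2, 55, 0.5, 40)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    @pytest.mark.parametrize("z,expected", [
        (0.0, 1.0), (2.22, 0.0264), (2.43, 0.0151), (1.92, 0.0549)])
    def test_two_tailed_p_values(self, z, expected):
        assert round(normal_two_tailed_p(z), 4) == expected

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValidationError):
            fisher_compare(1.0, 40, 0.2, 40)
        with pytest.raises(ValidationError):
            fisher_compare(0.5, 5, 0.2, 40)

    def test_p_uniform_under_equal_correlations(self, rng):
        # 2000 pairs of cohorts with the same true rho; Fisher p ~ U(0,1)
        rho, n1, n2, reps = 0.3, 40, 55, 2000

        def sample_r(n):
            x = rng.normal(size=(reps, n))
            y = rho * x + np.sqrt(1 - rho ** 2) * rng.normal(size=(reps, n))
            x = x - x.mean(axis=1, keepdims=True)
            y = y - y.mean(axis=1, keepdims=True)
            return (x * y).sum(axis=1) / np.sqrt(
                (x ** 2).sum(axis=1) * (y ** 2).sum(axis=1))

        r1, r2 = sample_r(n1), sample_r(n2)
        se = np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
        z = (np.arctanh(r1) - np.arctanh(r2)) / se
        p = 2 * stats.norm.sf(np.abs(z))
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_dimorphism_test_on_cohort(self):
        spec = CohortSpec(
            n_female=68, n_male=83, states=("REM",), electrode_failures={},
            planted=[PlantedEffect("REM", 18.0, 19.0, ["Fz"], "F", 0.55)],
            seed=11)
        spectra, subjects, res, _ = generate_cohort(spec)
        f = build_corrmap(spectra["REM"], res, subjects, "F")
        m = build_corrmap(spectra["REM"], res, subjects, "M")
        d = dimorphism_test(f, m, "Fz", 18.75)
        assert d.n_female == 68 and d.n_male == 83
        zo, po = fisher_compare(d.r_female, 68, d.r_male, 83)
        assert d.z == pytest.approx(zo) and d.p == pytest.approx(po)
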