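import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wayfarer import ssa
from wayfarer.errors import (
    ConfigurationError,
    DataError,
    RankDeficiencyError,
    SeparationError,
)
from wayfarer.tracks import STAGE_ACTIVE, STAGE_LOCAL, STAGE_RESIDENT


# ---------------------------------------------------------------------------
# helpers / oracles
# ---------------------------------------------------------------------------

def clr_frame(strata):
    """Build (X, info) from [(case_covs, [control_covs...]), ...]."""
    rows, sids, cases = [], [], []
    for sid, (case, controls) in enumerate(strata):
        rows.append(case)
        sids.append(sid)
        cases.append(1)
        for c in controls:
            rows.append(c)
            sids.append(sid)
            cases.append(0)
    arr = np.asarray(rows, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    X = pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])
    info = pd.DataFrame({"stratum_id": sids, "is_case": cases,
                         "individual": "a", "stage": STAGE_RESIDENT})
    return X, info


def conditional_loglik(beta, X, info):
    """Independent likelihood oracle: direct per-stratum evaluation."""
    beta = np.atleast_1d(beta)
    ll = 0.0
    for _, grp in pd.concat([X, info], axis=1).groupby("stratum_id"):
        eta = grp[X.columns].to_numpy() @ beta
        ll += eta[grp["is_case"].to_numpy() == 1][0] - np.log(np.exp(eta).sum())
    return ll


def grid_search_mle(X, info, lo=-4.0, hi=4.0):
    """Brute-force likelihood maximisation on a refining grid."""
    p = X.shape[1]
    centre = np.zeros(p)
    width = hi - lo
    for _ in range(8):
        axes = [np.linspace(c - width / 2, c + width / 2, 11) for c in centre]
        best, best_ll = None, -np.inf
        for point in itertools.product(*axes):
            ll = conditional_loglik(np.array(point), X, info)
            if ll > best_ll:
                best, best_ll = np.array(point), ll
        centre = best
        width /= 5.0
    return centre


def simulate_strata(rng, n_strata, beta, n_controls=20):
    """Candidate-choice simulation: one case drawn ~ exp(beta'x) among
    iid normal candidate covariates."""
    p = len(beta)
    out = []
    for _ in range(n_strata):
        xs = rng.normal(size=(n_controls + 1, p))
        probs = np.exp(xs @ beta)
        probs /= probs.sum()
        k = rng.choice(n_controls + 1, p=probs)
        case = xs[k]
        controls = np.delete(xs, k, axis=0)
        out.append((case, controls))
    return out


# ---------------------------------------------------------------------------
# distribution fitting
# ---------------------------------------------------------------------------

class TestFitStepDistributions:
    @staticmethod
    def steps_frame(lengths, angles, individual="a", stage=STAGE_ACTIVE):
        return pd.DataFrame(
            {"individual": individual, "stage": stage,
             "length": lengths, "turn_angle": angles}
        )

    def test_gamma_mle_recovery(self):
        rng = np.random.default_rng(11)
        steps = self.steps_frame(
            rng.gamma(2.0, 50.0, 5000), rng.vonmises(0.0, 2.0, 5000)
        )
        d = ssa.fit_step_distributions(steps)
        k, s = d.gamma[("a", STAGE_ACTIVE)]
        assert abs(k - 2.0) / 2.0 < 0.10
        assert abs(s - 50.0) / 50.0 < 0.10

    def test_vonmises_kappa_recovery(self):
        rng = np.random.default_rng(11)
        steps = self.steps_frame(
            rng.gamma(2.0, 50.0, 5000), rng.vonmises(0.0, 2.0, 5000)
        )
        d = ssa.fit_step_distributions(steps)
        _, kappa = d.vonmises[("a", STAGE_ACTIVE)]
        assert abs(kappa - 2.0) / 2.0 < 0.10

    def test_uniform_angles_small_kappa(self):
        rng = np.random.default_rng(12)
        steps = self.steps_frame(
            rng.gamma(2.0, 50.0, 3000), rng.uniform(-np.pi, np.pi, 3000)
        )
        d = ssa.fit_step_distributions(steps)
        assert d.vonmises[("a", STAGE_ACTIVE)][1] < 0.1

    def test_small_key_falls_back_to_pooled(self):
        rng = np.random.default_rng(13)
        big = self.steps_frame(rng.gamma(2, 50, 200), rng.vonmises(0, 1, 200), "a")
        small = self.steps_frame(rng.gamma(2, 50, 5), rng.vonmises(0, 1, 5), "b")
        d = ssa.fit_step_distributions(pd.concat([big, small], ignore_index=True))
        assert ("b", STAGE_ACTIVE) in d.fallback_keys
        gp, _ = d.params_for("b", STAGE_ACTIVE)
        assert gp == d.gamma[(None, STAGE_ACTIVE)]

    def test_degenerate_lengths_rejected(self):
        steps = self.steps_frame(np.full(50, 25.0), np.zeros(50))
        with pytest.raises(DataError, match="degenerate"):
            ssa.fit_step_distributions(steps)


# ---------------------------------------------------------------------------
# alternative steps
# ---------------------------------------------------------------------------

def observed_step(x=1500.0, y=1500.0, xe=1560.0, ye=1500.0, has_angle=True):
    return pd.Series(
        dict(
            individual="a", stage=STAGE_ACTIVE,
            x_start=x, y_start=y, x_end=xe, y_end=ye,
            length=float(np.hypot(xe - x, ye - y)),
            bearing=float(np.arctan2(xe - x, ye - y)),
            turn_angle=0.1 if has_angle else np.nan,
            has_angle=has_angle,
        )
    )


@pytest.fixture
def simple_dists():
    return ssa.StepDistributions(
        gamma={("a", STAGE_ACTIVE): (2.0, 40.0)},
        vonmises={("a", STAGE_ACTIVE): (0.0, 1.5)},
    )


class TestGenerateAlternatives:
    def test_stratum_size_and_single_case(self, uniform_stack, simple_dists):
        out = ssa.generate_alternatives(
            observed_step(), simple_dists, uniform_stack,
            m=20, rng=np.random.default_rng(1),
        )
        assert len(out) == 21
        assert out["is_case"].sum() == 1
        assert out.loc[0, "is_case"] == 1

    def test_bad_m_rejected(self, uniform_stack, simple_dists):
        with pytest.raises(ConfigurationError):
            ssa.generate_alternatives(
                observed_step(), simple_dists, uniform_stack, m=0
            )

    def test_concentration_limit_clusters_near_observed(self, uniform_stack):
        dists = ssa.StepDistributions(
            gamma={("a", STAGE_ACTIVE): (1e6, 60.0 / 1e6)},  # tight around 60
            vonmises={("a", STAGE_ACTIVE): (0.0, 1e6)},
        )
        step = observed_step()
        prev_bearing = step["bearing"] - step["turn_angle"]
        out = ssa.generate_alternatives(
            step, dists, uniform_stack, m=50, rng=np.random.default_rng(2)
        )
        alts = out[out["is_case"] == 0]
        expect_x = step["x_start"] + 60.0 * np.sin(prev_bearing)
        expect_y = step["y_start"] + 60.0 * np.cos(prev_bearing)
        # all alternatives land within a metre of the kernel's mode
        assert np.hypot(
            alts["x_end"] - expect_x, alts["y_end"] - expect_y
        ).max() < 1.0

    def test_sampled_lengths_match_fitted_gamma(self, uniform_stack, simple_dists):
        rng = np.random.default_rng(13)
        step = observed_step()
        lengths = []
        for _ in range(500):
            out = ssa.generate_alternatives(
                step, simple_dists, uniform_stack, m=20, rng=rng
            )
            alts = out[out["is_case"] == 0]
            lengths.append(
                np.hypot(
                    alts["x_end"] - step["x_start"], alts["y_end"] - step["y_start"]
                )
            )
        sample = np.concatenate(lengths)
        ref = np.random.default_rng(14).gamma(2.0, 40.0, sample.size)
        p = stats.ks_2samp(sample, ref).pvalue
        assert p > 0.01

    def test_no_prev_bearing_uses_uniform_directions(self, uniform_stack, simple_dists):
        rng = np.random.default_rng(3)
        step = observed_step(has_angle=False)
        out = ssa.generate_alternatives(step, simple_dists, uniform_stack, m=400, rng=rng)
        alts = out[out["is_case"] == 0]
        b = np.arctan2(alts["x_end"] - step["x_start"], alts["y_end"] - step["y_start"])
        # Rayleigh test of circular uniformity (normal approx, large n)
        r = np.hypot(np.cos(b).sum(), np.sin(b).sum()) / len(b)
        z = len(b) * r**2
        assert np.exp(-z) > 0.01
        assert out["length_only"].all()


# ---------------------------------------------------------------------------
# post-hoc habitat filter
# ---------------------------------------------------------------------------

def strata_frame(rows):
    """rows: (stratum_id, is_case, cover)"""
    return pd.DataFrame(
        {
            "stratum_id": [r[0] for r in rows],
            "is_case": [r[1] for r in rows],
            "cover": [r[2] for r in rows],
            "road": 0, "water": 0, "tri": 0.0,
            "individual": "a", "stage": STAGE_ACTIVE,
        }
    )


class TestPosthocFilter:
    def test_untouched_when_absent(self):
        df = strata_frame([(0, 1, "scrub"), (0, 0, "glade"), (0, 0, "scrub")])
        out = ssa.filter_habitat_posthoc(df)
        assert len(out) == 3

    def test_case_in_dropped_class_removes_stratum(self):
        df = strata_frame(
            [(0, 1, "bare_soil"), (0, 0, "scrub"),
             (1, 1, "scrub"), (1, 0, "glade")]
        )
        out = ssa.filter_habitat_posthoc(df)
        assert set(out["stratum_id"]) == {1}
        assert out.attrs["posthoc_counts"]["strata_case_dropped"] == 1

    def test_alternatives_removed_stratum_kept(self):
        rows = [(0, 1, "scrub")] + [(0, 0, "black_cotton")] * 3 + [(0, 0, "glade")] * 17
        out = ssa.filter_habitat_posthoc(strata_frame(rows))
        assert len(out) == 18  # case + 17 clean alternatives

    def test_stratum_reduced_below_two_removed(self):
        rows = [(0, 1, "scrub"), (0, 0, "black_cotton"), (1, 1, "scrub"), (1, 0, "glade")]
        out = ssa.filter_habitat_posthoc(strata_frame(rows))
        assert set(out["stratum_id"]) == {1}
        assert out.attrs["posthoc_counts"]["strata_too_small"] == 1


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def design_strata(stages=(STAGE_RESIDENT, STAGE_LOCAL, STAGE_ACTIVE)):
    rng = np.random.default_rng(0)
    rows = []
    sid = 0
    for stage in stages:
        for _ in range(4):
            for j in range(3):
                rows.append(
                    dict(
                        stratum_id=sid, is_case=int(j == 0), stage=stage,
                        individual="a",
                        road=int(rng.random() < 0.3),
                        water=int(rng.random() < 0.2),
                        cover=rng.choice(["scrub", "glade", "riverine", "bare_soil"]),
                        tri=float(rng.gamma(2, 1)),
                    )
                )
            sid += 1
    return pd.DataFrame(rows)


class TestBuildDesign:
    def test_within_stage_column_count(self):
        X, _ = ssa.build_design(design_strata(), "within_stage")
        # 2 binary + 3 cover dummies + tri = 6 covariates x 3 stages
        assert X.shape[1] == 18

    def test_vs_resident_column_count(self):
        X, _ = ssa.build_design(design_strata(), "vs_resident")
        assert X.shape[1] == 18  # 6 main + 6 x 2 transient stages

    def test_two_level_column_count(self):
        X, _ = ssa.build_design(design_strata(), "two_level")
        assert X.shape[1] == 12  # 6 main + 6 transient interactions

    def test_unknown_variant(self):
        with pytest.raises(ConfigurationError, match="variant"):
            ssa.build_design(design_strata(), "bogus")

    def test_tri_standardized(self):
        X, _ = ssa.build_design(design_strata(), "two_level")
        tri_cols = [c for c in X.columns if c.startswith("tri_z")]
        assert tri_cols
        assert abs(X["tri_z"].mean()) < 1e-9


# ---------------------------------------------------------------------------
# conditional logistic regression
# ---------------------------------------------------------------------------

class TestFitClr:
    def test_closed_form_ln2(self):
        X, info = clr_frame([(1.0, [0.0, 0.0]), (0.0, [1.0, 0.0])])
        fit = ssa.fit_clr(X, info)
        assert fit.beta.iloc[0] == pytest.approx(np.log(2), abs=1e-6)
        assert fit.converged

    def test_stratum_constant_covariate_rejected(self):
        X, info = clr_frame([(1.0, [1.0, 1.0]), (2.0, [2.0, 2.0])])
        with pytest.raises(RankDeficiencyError, match="x0"):
            ssa.fit_clr(X, info)

    @pytest.mark.parametrize("seed", [0, 3, 6])
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        strata = simulate_strata(rng, 3, np.array([0.7, -0.4]), n_controls=8)
        X, info = clr_frame(strata)
        fit = ssa.fit_clr(X, info)
        oracle = grid_search_mle(X, info)
        np.testing.assert_allclose(fit.beta.to_numpy(), oracle, atol=1e-3)

    def test_separation_divergence_detected(self):
        # covariate always 1 for the case, 0 for every control; forcing the
        # iteration on (score tolerance 0) drives beta past the bound
        strata = [(np.array([1.0]), np.zeros((3, 1))) for _ in range(10)]
        X, info = clr_frame(strata)
        with pytest.raises(SeparationError):
            ssa.fit_clr(X, info, tol_score=0.0, tol_loglik=0.0)

    def test_quasi_separation_flagged_at_convergence(self):
        strata = [(np.array([1.0]), np.zeros((3, 1))) for _ in range(10)]
        X, info = clr_frame(strata)
        fit = ssa.fit_clr(X, info)
        assert fit.separation_suspect
        assert abs(fit.beta.iloc[0]) > 15

    def test_invariant_to_stratum_constant_shift(self):
        rng = np.random.default_rng(5)
        strata = simulate_strata(rng, 50, np.array([0.5]), n_controls=5)
        X, info = clr_frame(strata)
        fit1 = ssa.fit_clr(X, info)
        shifts = info["stratum_id"].map(
            {s: rng.normal() * 10 for s in info["stratum_id"].unique()}
        )
        X2 = X.add(shifts, axis=0)
        fit2 = ssa.fit_clr(X2, info)
        np.testing.assert_allclose(
            fit1.beta.to_numpy(), fit2.beta.to_numpy(), atol=1e-6
        )

    def test_loglik_increases_monotonically(self):
        rng = np.random.default_rng(6)
        strata = simulate_strata(rng, 100, np.array([0.8, -0.5]))
        X, info = clr_frame(strata)
        lls = []
        for it in range(1, 7):
            fit = ssa.fit_clr(X, info, max_iter=it, tol_score=0.0, tol_loglik=0.0)
            lls.append(fit.loglik)
        assert all(b >= a - 1e-12 for a, b in zip(lls, lls[1:]))

    def test_score_zero_at_optimum(self):
        rng = np.random.default_rng(7)
        strata = simulate_strata(rng, 200, np.array([0.3]))
        X, info = clr_frame(strata)
        fit = ssa.fit_clr(X, info)
        assert fit.score_norm < 1e-6

    def test_consistency_with_planted_beta(self):
        rng = np.random.default_rng(8)
        strata = simulate_strata(rng, 5000, np.array([0.8, -0.5]))
        X, info = clr_frame(strata)
        fit = ssa.fit_clr(X, info)
        np.testing.assert_allclose(
            fit.beta.to_numpy(), [0.8, -0.5], atol=0.08
        )

    def test_multiple_cases_per_stratum_rejected(self):
        X = pd.DataFrame({"x0": [1.0, 0.0, 1.0]})
        info = pd.DataFrame(
            {"stratum_id": [0, 0, 0], "is_case": [1, 0, 1],
             "individual": "a", "stage": STAGE_RESIDENT}
        )
        with pytest.raises(DataError, match="exactly one case"):
            ssa.fit_clr(X, info)


class TestRssReport:
    @staticmethod
    def fit_with(beta, se):
        names = [f"b{i}" for i in range(len(beta))]
        return ssa.SelectionFit(
            beta=pd.Series(beta, index=names),
            cov=pd.DataFrame(np.diag(np.square(se)), index=names, columns=names),
            loglik=0.0, n_strata=1, n_steps=2, n_iter=1,
            converged=True, score_norm=0.0,
        )

    def test_zero_beta_unit_rss(self):
        tab = ssa.rss_report(self.fit_with([0.0], [0.2]))
        assert tab["rss"].iloc[0] == 1.0
        assert tab["rss_lo"].iloc[0] < 1.0 < tab["rss_hi"].iloc[0]

    def test_rss_exponentiates(self):
        tab = ssa.rss_report(self.fit_with([np.log(1.166)], [0.05]))
        assert tab["rss"].iloc[0] == pytest.approx(1.166)

    def test_ci_arithmetic(self):
        tab = ssa.rss_report(self.fit_with([-0.3], [0.05]))
        z = stats.norm.ppf(0.975)
        assert tab["rss_lo"].iloc[0] == pytest.approx(np.exp(-0.3 - z * 0.05))
        assert tab["rss_hi"].iloc[0] == pytest.approx(np.exp(-0.3 + z * 0.05))

    def test_stars(self):
        tab = ssa.rss_report(self.fit_with([1.0, 0.01], [0.1, 1.0]))
        assert tab["stars"].tolist() == ["***", ""]
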