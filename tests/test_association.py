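import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from arsmr.association import (
    association_scan,
    build_design,
    fit_null_model,
    test_variant,
)
from arsmr.errors import DegenerateInputError, NumericalError, ValidationError
from arsmr.synthetic_cohort import SimulationConfig, build_cluster_matrices, simulate_cohort


def _plain_frame(rng, n, extra=None):
    df = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
    if extra:
        df = df.assign(**extra)
    return df


def _household_kernel(labels):
    labels = np.asarray(labels)
    return (labels[:, None] == labels[None, :]).astype(float)


# ------------------------------------------------------------------ null fit

def test_gaussian_zero_components_equals_ols(rng):
    n = 200
    df = _plain_frame(rng, n)
    df["y"] = 1.0 + 0.5 * df.x1 - 0.2 * df.x2 + rng.normal(0, 1, n)
    kernels = {"household": _household_kernel(rng.integers(0, 40, n))}
    fit = fit_null_model(
        df,
        "y",
        covariates=("x1", "x2"),
        cluster_matrices=kernels,
        family="gaussian",
        fixed_variance_components={"household": 0.0},
    )
    X, _ = build_design(df, ("x1", "x2"))
    beta_ols, *_ = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)
    np.testing.assert_allclose(fit.beta.to_numpy(), beta_ols, rtol=1e-6)
    assert fit.variance_components["household"] == 0.0
    assert "household" in fit.boundary_components


def test_gaussian_reml_recovers_variance_components(rng):
    n = 600
    labels = np.repeat(np.arange(n // 3), 3)
    u = rng.normal(0, np.sqrt(1.0), n // 3)[labels // 1]
    df = _plain_frame(rng, n)
    df["y"] = 2.0 + u + rng.normal(0, 1, n)
    fit = fit_null_model(
        df,
        "y",
        covariates=("x1", "x2"),
        cluster_matrices={"household": _household_kernel(labels)},
        family="gaussian",
    )
    assert fit.variance_components["household"] == pytest.approx(1.0, abs=0.4)
    assert fit.variance_components["residual"] == pytest.approx(1.0, abs=0.3)


def test_binomial_intercept_is_logit_prevalence(rng):
    n = 800
    y = (rng.uniform(size=n) < 0.3).astype(float)
    df = pd.DataFrame({"y": y})
    fit = fit_null_model(df, "y", covariates=(), family="binomial")
    assert fit.beta["intercept"] == pytest.approx(logit(y.mean()), abs=1e-8)


def test_constant_trait_rejected(rng):
    df = _plain_frame(rng, 50, extra={"y": np.ones(50)})
    with pytest.raises(DegenerateInputError):
        fit_null_model(df, "y", covariates=("x1",), family="gaussian")


def test_missing_trait_values_rejected(rng):
    df = _plain_frame(rng, 50, extra={"y": np.r_[np.nan, np.ones(49)]})
    with pytest.raises(ValidationError):
        fit_null_model(df, "y", covariates=(), family="gaussian")


def test_rank_deficient_design_rejected(rng):
    df = _plain_frame(rng, 60)
    df["x2"] = 2.0 * df["x1"]
    df["y"] = rng.normal(size=60)
    with pytest.raises(NumericalError):
        fit_null_model(df, "y", covariates=("x1", "x2"), family="gaussian")


# -------------------------------------------------------------- variant test

def test_gaussian_truth_recovery(rng):
    n = 5000
    g = rng.binomial(2, 0.3, n).astype(float)
    df = pd.DataFrame({"y": 0.5 * g + rng.normal(0, 0.1, n)})
    fit = fit_null_model(df, "y", covariates=(), family="gaussian")
    res = test_variant(fit, g, rsid="rsX")
    assert res.beta_gy == pytest.approx(0.5, abs=3 * res.se_gy)
    assert res.se_gy > 0 and res.p < 1e-10


def test_monomorphic_dosage_rejected(rng):
    df = pd.DataFrame({"y": rng.normal(size=100)})
    fit = fit_null_model(df, "y", covariates=(), family="gaussian")
    with pytest.raises(DegenerateInputError):
        test_variant(fit, np.zeros(100))


def test_collinear_dosage_rejected(rng):
    n = 100
    df = _plain_frame(rng, n)
    df["y"] = rng.normal(size=n)
    fit = fit_null_model(df, "y", covariates=("x1", "x2"), family="gaussian")
    with pytest.raises(NumericalError):
        test_variant(fit, 3.0 * df["x1"].to_numpy())


def test_binary_logodds_scale_duplication(rng):
    # doubling the cohort by duplication: same log-odds beta, se / sqrt(2)
    n = 1500
    g = rng.binomial(2, 0.4, n).astype(float)
    y = (rng.uniform(size=n) < expit(-1.0 + 0.4 * g)).astype(float)
    df = pd.DataFrame({"y": y})
    fit1 = fit_null_model(df, "y", covariates=(), family="binomial")
    r1 = test_variant(fit1, g)
    df2 = pd.concat([df, df], ignore_index=True)
    fit2 = fit_null_model(df2, "y", covariates=(), family="binomial")
    r2 = test_variant(fit2, np.concatenate([g, g]))
    assert r2.beta_gy == pytest.approx(r1.beta_gy, abs=1e-6)
    assert r2.se_gy == pytest.approx(r1.se_gy / np.sqrt(2), rel=1e-3)


def test_type_i_error_null_binomial():
    rng = np.random.default_rng(2024)
    n, reps, alpha = 400, 1000, 0.05
    rejections = 0
    for _ in range(reps):
        g = rng.binomial(2, 0.3, n).astype(float)
        y = (rng.uniform(size=n) < 0.3).astype(float)
        if y.std() == 0 or g.std() == 0:
            continue
        fit = fit_null_model(pd.DataFrame({"y": y}), "y", covariates=(), family="binomial")
        rejections += test_variant(fit, g).p < alpha
    rate = rejections / reps
    assert 0.035 <= rate <= 0.065  # binomial CI for 1000 replicates


def test_gaussian_mixed_model_ci_coverage():
    # 95% +/- 2% coverage of the generative slope with household clustering
    rng = np.random.default_rng(7)
    n, reps = 240, 500
    labels = np.repeat(np.arange(n // 4), 4)
    K = _household_kernel(labels)
    covered = 0
    for _ in range(reps):
        g = rng.binomial(2, 0.35, n).astype(float)
        u = rng.normal(0, np.sqrt(0.5), n // 4)[labels]
        y = 0.3 * g + u + rng.normal(0, 1, n)
        fit = fit_null_model(
            pd.DataFrame({"y": y}),
            "y",
            covariates=(),
            cluster_matrices={"household": K},
            family="gaussian",
        )
        r = test_variant(fit, g)
        covered += abs(r.beta_gy - 0.3) <= 1.96 * r.se_gy
    assert covered / reps == pytest.approx(0.95, abs=0.02)


def test_binomial_pql_with_clusters_recovers_effect():
    rng = np.random.default_rng(33)
    n = 400
    labels = np.repeat(np.arange(n // 4), 4)
    K = _household_kernel(labels)
    g = rng.binomial(2, 0.4, n).astype(float)
    u = rng.normal(0, np.sqrt(0.4), n // 4)[labels]
    y = (rng.uniform(size=n) < expit(-0.5 + 0.6 * g + u)).astype(float)
    fit = fit_null_model(
        pd.DataFrame({"y": y}),
        "y",
        covariates=(),
        cluster_matrices={"household": K},
        family="binomial",
    )
    r = test_variant(fit, g)
    assert r.beta_gy == pytest.approx(0.6, abs=3.5 * r.se_gy)


# ---------------------------------------------------------------------- scan

@pytest.fixture(scope="module")
def scan_setup(instruments, ref_model):
    cfg = SimulationConfig(n_participants=900, seed=17, asthma_missing_rate=0.0)
    cohort, _, _ = simulate_cohort(cfg, ref=ref_model, instruments=instruments, build_clusters=False)
    return cohort


def test_scan_cartesian_count(scan_setup, instruments, rng):
    cohort = scan_setup.copy()
    traits = {}
    for k in range(7):
        col = f"t{k}"
        cohort[col] = rng.binomial(1, 0.3, len(cohort)).astype(float)
        traits[col] = (col, "binomial")
    strata = {
        "a": np.arange(len(cohort)) < 450,
        "b": np.arange(len(cohort)) >= 450,
    }
    table = association_scan(cohort, instruments, traits, strata=strata)
    assert len(table) == 3 * 7 * 2
    assert (table["status"] == "ok").all()


def test_scan_zero_case_stratum_error_coded(scan_setup, instruments):
    cohort = scan_setup.copy()
    cohort["flat"] = 0.0
    table = association_scan(cohort, instruments, {"flat": ("flat", "binomial")})
    assert len(table) == 3
    assert table["status"].str.startswith("null_fit_error").all()


def test_scan_deterministic(scan_setup, instruments, rng):
    cohort = scan_setup.copy()
    cohort["t"] = rng.binomial(1, 0.25, len(cohort)).astype(float)
    t1 = association_scan(cohort, instruments, {"t": ("t", "binomial")})
    t2 = association_scan(cohort, instruments, {"t": ("t", "binomial")})
    pd.testing.assert_frame_equal(t1, t2)
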