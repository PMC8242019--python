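import json

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from arsmr.errors import FeasibilityError, ValidationError
from arsmr.synthetic_cohort import (
    DEFAULT_MAF,
    SimulationConfig,
    build_cluster_matrices,
    dosages_from_vcf,
    partner_maf_for_ld,
    simulate_cohort,
    simulate_haplotypes,
    write_cluster_triplets,
    write_truth,
    write_vcf,
)


# ----------------------------------------------------------------- haplotypes

def test_haplotypes_linkage_equilibrium():
    hap = simulate_haplotypes(0.4, 0.3, 0.0, 10**6, rng=11)
    h = hap.haplotypes
    r = np.corrcoef(h[:, 0], h[:, 1])[0, 1]
    assert abs(r) < 0.005


def test_haplotypes_complete_ld_no_repulsion():
    hap = simulate_haplotypes(0.3, 0.3, 1.0, 50_000, rng=3)
    assert hap.counts["Ab"] == 0
    assert hap.counts["aB"] == 0
    assert hap.frequencies["Ab"] == pytest.approx(0.0, abs=1e-12)


def test_haplotypes_default_ld_calibration():
    hap = simulate_haplotypes(DEFAULT_MAF[0], DEFAULT_MAF[1], 0.87, 10**6, rng=5)
    assert hap.realized_dprime() == pytest.approx(0.87, abs=0.01)
    assert hap.realized_r2() == pytest.approx(0.28, abs=0.01)


def test_haplotypes_infeasible_dprime():
    with pytest.raises(FeasibilityError, match=r"\[0, 1\]"):
        simulate_haplotypes(0.3, 0.3, 1.2, 100)


def test_partner_maf_solver_roundtrip():
    q = partner_maf_for_ld(0.45, 0.87, 0.28)
    assert 0 < q < 0.45
    # plugging the solved MAF back yields the target r^2 exactly
    from arsmr.synthetic_cohort import dprime_r2

    assert dprime_r2(0.45, q, 0.87) == pytest.approx(0.28, abs=1e-9)


def test_partner_maf_solver_infeasible():
    with pytest.raises(FeasibilityError):
        partner_maf_for_ld(0.5, 0.1, 0.9)  # weak D' cannot give high r^2


# --------------------------------------------------------------------- cohort

@pytest.fixture(scope="module")
def big_cohort(instruments, ref_model):
    # frozen seed: the 2-MC-SE recovery checks are individually ~95% events
    cfg = SimulationConfig(n_participants=200_000, seed=13, metabolite_noise_sd=(3.0, 3.0))
    cohort, _, truth = simulate_cohort(
        cfg, ref=ref_model, instruments=instruments, build_clusters=False
    )
    return cohort, truth


def test_metabolites_sum_to_100_exactly(big_cohort):
    cohort, _ = big_cohort
    total = cohort["pct_iAs"] + cohort["pct_MMA"] + cohort["pct_DMA"]
    np.testing.assert_array_equal(total.to_numpy(), np.full(len(cohort), 100.0))


def test_dosages_in_range(big_cohort):
    cohort, _ = big_cohort
    for rsid in ("rs9527", "rs11191527", "rs61735836"):
        d = cohort[f"dosage_{rsid}"]
        assert d.between(0, 2).all()


def _marginal_slope_and_se(y, g):
    g = g - g.mean()
    beta = float(g @ y / (g @ g))
    resid = y - y.mean() - beta * g
    se = float(np.sqrt(resid @ resid / (len(y) - 2) / (g @ g)))
    return beta, se


def test_marginal_regressions_recover_published_betas(big_cohort, instruments):
    cohort, _ = big_cohort
    for met in ("iAs", "MMA"):
        published = instruments.beta_vector(met)
        for k, rsid in enumerate(instruments.rsids):
            beta, se = _marginal_slope_and_se(
                cohort[f"pct_{met}"].to_numpy(), cohort[f"dosage_{rsid}"].to_numpy()
            )
            assert beta == pytest.approx(published[k], abs=2 * se), (met, rsid)


def test_marginal_dma_betas_match_compositional_closure(big_cohort, instruments):
    # %DMA is generated by closure, so its per-variant slope equals the
    # negated sum of the %iAs and %MMA slopes (within 0.04 of the published
    # values, the bundled table's own closure error)
    cohort, _ = big_cohort
    implied = -(instruments.beta_vector("iAs") + instruments.beta_vector("MMA"))
    for k, rsid in enumerate(instruments.rsids):
        beta, se = _marginal_slope_and_se(
            cohort["pct_DMA"].to_numpy(), cohort[f"dosage_{rsid}"].to_numpy()
        )
        assert beta == pytest.approx(implied[k], abs=2 * se)
        assert beta == pytest.approx(instruments.beta_vector("DMA")[k], abs=0.05 + 2 * se)


def test_homozygote_contrast_doubles_per_allele_beta(big_cohort):
    cohort, _ = big_cohort
    d = cohort["dosage_rs61735836"]
    hi = cohort.loc[d == 2, "pct_iAs"]
    lo = cohort.loc[d == 0, "pct_iAs"]
    diff = hi.mean() - lo.mean()
    se = np.sqrt(hi.var() / len(hi) + lo.var() / len(lo))
    assert diff == pytest.approx(5.42, abs=3 * se)  # 2 x 2.71


def test_null_prevalence_matches_baseline(instruments, ref_model):
    cfg = SimulationConfig(n_participants=20_000, seed=9, asthma_missing_rate=0.0)
    cohort, _, truth = simulate_cohort(
        cfg, ref=ref_model, instruments=instruments, build_clusters=False
    )
    for trait, baseline in cfg.baseline_logodds.items():
        p = expit(baseline)
        se = np.sqrt(p * (1 - p) / cfg.n_participants)
        assert truth["trait_prevalence"][trait] == pytest.approx(p, abs=3 * se)


def test_simplex_resampling_failure_raises(instruments, ref_model):
    cfg = SimulationConfig(
        n_participants=200,
        seed=1,
        metabolite_noise_sd=(500.0, 500.0),
        max_simplex_resample=20,
    )
    with pytest.raises(FeasibilityError, match="noise too large"):
        simulate_cohort(cfg, ref=ref_model, instruments=instruments, build_clusters=False)


def test_determinism_same_seed(instruments, ref_model):
    cfg = SimulationConfig(n_participants=500, seed=77)
    a, _, ta = simulate_cohort(cfg, ref=ref_model, instruments=instruments, build_clusters=False)
    b, _, tb = simulate_cohort(cfg, ref=ref_model, instruments=instruments, build_clusters=False)
    pd.testing.assert_frame_equal(a, b)
    assert ta == tb


def test_truth_round_trip_byte_identical(tmp_path, instruments, ref_model):
    cfg = SimulationConfig(n_participants=300, seed=5)
    *_, truth = simulate_cohort(cfg, ref=ref_model, instruments=instruments, build_clusters=False)
    p1, p2 = tmp_path / "t1.json", tmp_path / "t2.json"
    write_truth(truth, str(p1))
    write_truth(json.loads(p1.read_text()), str(p2))
    assert p1.read_bytes() == p2.read_bytes()


def test_missing_injection_counts(instruments, ref_model):
    cfg = SimulationConfig(
        n_participants=2000, seed=2, n_smoking_nonresponse=13, n_diet_nonresponse=11
    )
    cohort, *_ = simulate_cohort(cfg, ref=ref_model, instruments=instruments, build_clusters=False)
    assert (~cohort["smoking_answered"]).sum() == 13
    assert cohort["grain_servings"].isna().sum() == 11


def test_config_validation():
    with pytest.raises(ValidationError):
        SimulationConfig(n_participants=0)
    with pytest.raises(FeasibilityError):
        SimulationConfig(target_dprime=1.5)
    with pytest.raises(ValidationError):
        SimulationConfig(frac_high_rice=1.2)


# ------------------------------------------------------------------- clusters

def _mini_cohort(household, sibling_of):
    n = len(household)
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "household_id": household,
            "block_group_id": np.zeros(n, dtype=int),
            "sibling_of": sibling_of,
        }
    )


def test_singleton_households_identity():
    c = _mini_cohort(np.arange(6), np.full(6, -1))
    m = build_cluster_matrices(c)
    np.testing.assert_array_equal(m.household, np.eye(6))
    np.testing.assert_array_equal(m.kinship, np.eye(6))


def test_single_sibling_pair_kinship():
    c = _mini_cohort(np.array([0, 0, 1, 2]), np.array([-1, 0, -1, -1]))
    m = build_cluster_matrices(c)
    off = m.kinship - np.diag(np.diag(m.kinship))
    assert (off == 0.5).sum() == 2
    assert m.kinship[0, 1] == 0.5 and m.kinship[1, 0] == 0.5


def test_household_of_three_has_six_offdiagonal_ones():
    # brute-force pair count: 3 members -> 3 * 2 ordered pairs
    c = _mini_cohort(np.array([7, 7, 7, 1, 2]), np.full(5, -1))
    m = build_cluster_matrices(c)
    off = m.household - np.diag(np.diag(m.household))
    assert off.sum() == 6


def test_dangling_sibling_reference_rejected():
    c = _mini_cohort(np.array([0, 1]), np.array([-1, 99]))
    with pytest.raises(ValidationError):
        build_cluster_matrices(c)


def test_simulated_cluster_matrices_valid(instruments, ref_model):
    cfg = SimulationConfig(n_participants=120, seed=8, sibling_pair_fraction=0.2)
    cohort, clusters, _ = simulate_cohort(cfg, ref=ref_model, instruments=instruments)
    for mat in (clusters.kinship, clusters.household, clusters.block_group):
        np.testing.assert_array_equal(mat, mat.T)
        assert np.linalg.eigvalsh(mat).min() >= -1e-8
    assert (np.diag(clusters.kinship) == 1.0).all()
    n_pairs = int(round(0.2 * 120 / 2))
    assert (clusters.kinship == 0.5).sum() == 2 * n_pairs


# ------------------------------------------------------------------------- io

def test_vcf_round_trip(tmp_path, instruments, ref_model):
    cfg = SimulationConfig(n_participants=50, seed=4)
    cohort, *_ = simulate_cohort(cfg, ref=ref_model, instruments=instruments, build_clusters=False)
    path = tmp_path / "variants.vcf"
    write_vcf(cohort, instruments, str(path))
    dosages = dosages_from_vcf(str(path), instruments.rsids)
    for rsid in instruments.rsids:
        np.testing.assert_allclose(
            dosages[f"dosage_{rsid}"], cohort[f"dosage_{rsid}"], atol=1e-6
        )


def test_cluster_triplet_writer(tmp_path, instruments, ref_model):
    cfg = SimulationConfig(n_participants=30, seed=4)
    _, clusters, _ = simulate_cohort(cfg, ref=ref_model, instruments=instruments)
    path = tmp_path / "clusters.tsv"
    write_cluster_triplets(clusters, str(path))
    trip = pd.read_csv(path, sep="\t")
    assert set(trip["matrix"]) == {"kinship", "household", "block_group"}
    kin = trip[trip["matrix"] == "kinship"]
    diag = kin[kin["i"] == kin["j"]]
    assert len(diag) == 30 and (diag["value"] == 1.0).all()
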