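"""Preprocessing, EWAS, cis-CSCE discovery and enrichment tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lfsmo.methylome import (
    GenotypeMatrix,
    MethylationDataset,
    cscce_anova,
    discover_cscce,
    ewas,
    feature_enrichment,
    locus_group_test,
    pca_outlier_trim,
    residualize,
)


def _dataset(beta, cov=None, pos_step=25_000):
    beta = pd.DataFrame(
        beta,
        index=[f"cg{i:05d}" for i in range(beta.shape[0])],
        columns=[f"s{j:03d}" for j in range(beta.shape[1])],
    )
    annot = pd.DataFrame(
        {"chrom": "chr1", "pos": 10_000 + pos_step * np.arange(len(beta))},
        index=beta.index,
    )
    if cov is None:
        cov = pd.DataFrame(index=beta.columns)
    else:
        cov = pd.DataFrame(cov, index=beta.columns)
    return MethylationDataset(beta, annot, cov)


def test_beta_range_enforced():
    with pytest.raises(ValueError):
        _dataset(np.full((3, 4), 1.5))


# ---------------------------------------------------------------------------
# PCA trimming


def test_planted_outlier_is_removed():
    rng = np.random.default_rng(0)
    beta = np.clip(rng.normal(0.5, 0.02, size=(50, 100)), 0, 1)
    beta[:, 17] += 0.3  # large coherent displacement -> dominates PC1
    ds = _dataset(np.clip(beta, 0, 1))
    kept, removed = pca_outlier_trim(ds)
    assert removed == ["s017"]
    assert kept.n_samples == 99


def test_homogeneous_samples_all_kept():
    rng = np.random.default_rng(1)
    ds = _dataset(np.clip(rng.normal(0.5, 0.01, size=(40, 60)), 0, 1))
    kept, removed = pca_outlier_trim(ds)
    assert removed == []


def test_trimming_is_per_cohort():
    rng = np.random.default_rng(2)
    beta = np.clip(rng.normal(0.5, 0.02, size=(50, 80)), 0, 1)
    beta[:, 5] += 0.3  # outlier inside cohort A only
    cov = {"cohort": ["A"] * 40 + ["B"] * 40}
    ds = _dataset(np.clip(beta, 0, 1), cov)
    _, removed = pca_outlier_trim(ds)
    assert removed == ["s005"]
    # cohort B membership is unaffected by the cohort A outlier
    ds_b = _dataset(np.clip(beta[:, 40:], 0, 1), {"cohort": ["B"] * 40})
    _, removed_b = pca_outlier_trim(ds_b)
    assert removed_b == []


# ---------------------------------------------------------------------------
# residualization


def test_known_covariate_effect_removed_exactly():
    rng = np.random.default_rng(3)
    group = np.repeat([0, 1], 30)
    beta = np.clip(0.4 + 0.1 * group + rng.normal(0, 0.02, size=(20, 60)), 0, 1)
    ds = _dataset(beta, {"group": group.astype(float)})
    out = residualize(ds, ["group"], n_latent=0)
    means = out.beta.T.groupby(group).mean()
    assert np.allclose(means.iloc[0], means.iloc[1], atol=1e-10)
    # per-probe means preserved
    assert np.allclose(out.beta.mean(axis=1), ds.beta.mean(axis=1), atol=1e-12)


def test_residualize_idempotent_without_latent_factors():
    rng = np.random.default_rng(4)
    group = np.repeat([0, 1], 25)
    beta = np.clip(0.4 + 0.08 * group + rng.normal(0, 0.03, size=(15, 50)), 0, 1)
    ds = _dataset(beta, {"group": group.astype(float)})
    once = residualize(ds, ["group"], n_latent=0)
    twice = residualize(once, ["group"], n_latent=0)
    assert np.allclose(once.beta, twice.beta, atol=1e-10)


def test_latent_factors_absorb_batch_variance():
    rng = np.random.default_rng(5)
    n_probes, n_samples = 200, 90
    batch = rng.integers(0, 2, n_samples)
    load = rng.normal(0, 1, n_probes)
    noise = rng.normal(0, 0.02, size=(n_probes, n_samples))
    beta = np.clip(0.5 + 0.08 * np.outer(load, batch - 0.5) + noise, 0, 1)
    ds = _dataset(beta, {"age": rng.uniform(1, 60, n_samples)})

    def batch_var_frac(mat):
        centered = mat - mat.mean(axis=1, keepdims=True)
        fitted = np.outer(
            (centered[:, batch == 1].mean(axis=1) - centered[:, batch == 0].mean(axis=1)),
            batch - batch.mean(),
        )
        return (fitted ** 2).sum() / (centered ** 2).sum()

    before = batch_var_frac(ds.beta.to_numpy())
    out = residualize(ds, ["age"], n_latent=5)
    after = batch_var_frac(out.beta.to_numpy())
    assert before > 0.3
    assert after < 0.01


def test_collinear_covariates_warn():
    rng = np.random.default_rng(6)
    beta = np.clip(rng.normal(0.5, 0.02, (10, 30)), 0, 1)
    x = rng.normal(size=30)
    ds = _dataset(beta, {"x1": x, "x2": 2 * x})
    with pytest.warns(UserWarning, match="collinear"):
        residualize(ds, ["x1", "x2"], n_latent=0)


# ---------------------------------------------------------------------------
# EWAS


def _three_cohort_ds(rng, n_probes=200, planted=(), delta=0.15):
    sizes = {"discovery": 50, "internal": 60, "external": 70}
    cols, cohort, status = [], [], []
    for c, n in sizes.items():
        for i in range(n):
            cols.append(f"{c[:3]}{i:03d}")
            cohort.append(c)
            status.append(i % 2)
    status = np.array(status)
    beta = np.clip(rng.normal(0.4, 0.05, size=(n_probes, len(cols))), 0, 1)
    for p in planted:
        beta[p] = np.clip(beta[p] + delta * status, 0, 1)
    ds = _dataset(beta, None)
    ds.sample_covariates["cohort"] = cohort
    ds.sample_covariates["cancer_status"] = status
    ds.beta.columns = cols
    ds.sample_covariates.index = cols
    return ds


def test_planted_probe_validates_and_permutation_destroys_it():
    rng = np.random.default_rng(7)
    ds = _three_cohort_ds(rng, planted=(3, 11))
    res = ewas(ds, cohorts=("discovery", "internal", "external"))
    assert set(res.validated_probes) == {"cg00003", "cg00011"}
    assert (res.discovery_effect().loc[res.validated_probes] > 0).all()
    # permuted outcome: planted probes no longer validate
    perm = ds.sample_covariates.copy()
    perm["cancer_status"] = rng.permutation(perm["cancer_status"].to_numpy())
    ds_perm = MethylationDataset(ds.beta, ds.probe_annot, perm)
    res_perm = ewas(ds_perm, cohorts=("discovery", "internal", "external"))
    assert "cg00003" not in res_perm.validated_probes


def test_constant_outcome_rejected():
    rng = np.random.default_rng(8)
    ds = _three_cohort_ds(rng, n_probes=10)
    ds.sample_covariates["cancer_status"] = 1
    with pytest.raises(ValueError, match="constant"):
        ewas(ds)


# ---------------------------------------------------------------------------
# cis-CSCE discovery


def _geno_for(ds, snps):
    """snps: dict snp_id -> (pos, dosage array over ds samples)."""
    annot = pd.DataFrame(
        {"chrom": "chr1", "pos": [v[0] for v in snps.values()]},
        index=pd.Index(snps.keys(), name="snp_id"),
    )
    mat = pd.DataFrame(
        {s: {sid: snps[sid][1][j] for sid in snps} for j, s in enumerate(ds.beta.columns)}
    ).T.T
    mat = pd.DataFrame(
        np.array([snps[sid][1] for sid in snps], dtype=float),
        index=annot.index, columns=ds.beta.columns,
    )
    return GenotypeMatrix(mat, annot)


def test_spearman_identical_under_134_and_012_codings():
    rng = np.random.default_rng(9)
    for _ in range(50):
        g = rng.integers(0, 3, size=47).astype(float)
        y = rng.normal(0.5, 0.1, size=47)
        if len(np.unique(g)) == 1:
            continue
        coded = pd.Series(g).replace({0: 1, 1: 3, 2: 4}).to_numpy()
        rho_raw = stats.spearmanr(g, y).statistic
        rho_coded = stats.spearmanr(coded, y).statistic
        assert rho_raw == rho_coded  # exact, not approximate


def test_strongest_snp_by_absolute_rho():
    rng = np.random.default_rng(10)
    n = 47
    g1 = rng.integers(0, 3, n).astype(float)
    g2 = rng.integers(0, 3, n).astype(float)
    beta_row = np.clip(0.5 - 0.12 * g2 + 0.04 * g1 + rng.normal(0, 0.02, n), 0, 1)
    beta = np.vstack([beta_row, np.full(n, 0.5)])
    ds = _dataset(beta, {"cohort": ["discovery"] * n,
                         "cancer_status": rng.integers(0, 2, n)})
    res_ewas = ewas(ds, cohorts=("discovery",))
    geno = _geno_for(ds, {"snp_pos": (12_000, g1), "snp_neg": (14_000, g2)})
    out = discover_cscce(res_ewas, ds, geno, probes=["cg00000"], fdr_cut=1.0)
    rec = out.records.iloc[0]
    assert rec["snp_id"] == "snp_neg"
    assert rec["rho"] < -0.5
    assert rec["allele_direction"] == "alt_decreases_meth"
    assert abs(rec["distance"]) <= 10_000


def test_cis_window_is_inclusive_and_bounds_distance():
    rng = np.random.default_rng(11)
    n = 40
    g = rng.integers(0, 3, n).astype(float)
    beta = np.clip(0.4 + 0.1 * g + rng.normal(0, 0.02, (1, n)), 0, 1)
    ds = _dataset(beta, {"cohort": ["discovery"] * n,
                         "cancer_status": rng.integers(0, 2, n)})
    res_ewas = ewas(ds, cohorts=("discovery",))
    # probe at 10_000: one SNP exactly at the window edge, one just outside
    geno = _geno_for(ds, {"edge": (20_000, g), "outside": (20_001, g)})
    out = discover_cscce(res_ewas, ds, geno, probes=["cg00000"], fdr_cut=1.0)
    assert list(out.records["snp_id"]) == ["edge"]
    assert out.records["distance"].iloc[0] == 10_000


def test_probe_without_cis_snp_is_counted_not_crashed():
    rng = np.random.default_rng(12)
    n = 30
    beta = np.clip(rng.normal(0.5, 0.03, (2, n)), 0, 1)
    ds = _dataset(beta, {"cohort": ["discovery"] * n,
                         "cancer_status": rng.integers(0, 2, n)})
    res_ewas = ewas(ds, cohorts=("discovery",))
    g = rng.integers(0, 3, n).astype(float)
    geno = _geno_for(ds, {"far": (500_000, g)})
    out = discover_cscce(res_ewas, ds, geno, probes=["cg00000", "cg00001"])
    assert out.n_no_cis_snp == 2 and len(out.records) == 0


def test_planted_meqtl_recovered_at_overlap_scale():
    """Per-allele shift 0.1, n=47, MAF 0.3: |rho| >= 0.4 in most seeds."""
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        n = 47
        g = rng.binomial(2, 0.3, n).astype(float)
        beta = np.clip(0.4 + 0.1 * g + rng.normal(0, 0.05, (1, n)), 0, 1)
        ds = _dataset(beta, {"cohort": ["discovery"] * n,
                             "cancer_status": rng.integers(0, 2, n)})
        res_ewas = ewas(ds, cohorts=("discovery",))
        geno = _geno_for(ds, {"snp": (12_000, g)})
        out = discover_cscce(res_ewas, ds, geno, probes=["cg00000"], fdr_cut=1.0)
        hits += abs(out.records["rho"].iloc[0]) >= 0.4
    assert hits >= 16  # >= 80% of seeds


def test_cis_stage_controls_fdr_under_global_null():
    """With no genotype-methylation coupling, BH at 0.05 keeps the mean
    false-discovery proportion (and per-seed discovery rate) below level."""
    n_seeds, n_probes, n = 200, 60, 47
    total_fdp = 0.0
    seeds_with_discovery = 0
    for seed in range(n_seeds):
        rng = np.random.default_rng(10_000 + seed)
        beta = np.clip(rng.normal(0.5, 0.05, size=(n_probes, n)), 0, 1)
        ds = _dataset(beta, {"cohort": ["discovery"] * n,
                             "cancer_status": rng.integers(0, 2, n)})
        res_ewas = ewas(ds, cohorts=("discovery",))
        snps = {
            f"s{i}": (int(ds.probe_annot["pos"].iloc[i]) + 500,
                      rng.binomial(2, 0.3, n).astype(float))
            for i in range(n_probes)
        }
        geno = _geno_for(ds, snps)
        out = discover_cscce(res_ewas, ds, geno, probes=list(ds.beta.index),
                             fdr_cut=0.05)
        k = len(out.records)
        total_fdp += k / max(k, 1) if k else 0.0
        seeds_with_discovery += k > 0
    assert total_fdp / n_seeds <= 0.08  # expected <= 0.05 plus Monte-Carlo slack
    assert seeds_with_discovery / n_seeds <= 0.10


# ---------------------------------------------------------------------------
# ANOVA by cancer type


def test_anova_identical_groups_and_two_level_t_equivalence():
    rng = np.random.default_rng(13)
    n = 40
    beta = np.clip(rng.normal(0.5, 0.05, (2, n)), 0, 1)
    types = np.array(["A", "B"] * (n // 2))
    ds = _dataset(beta, {"cancer_type": types})
    records = pd.DataFrame({"probe_id": ["cg00000", "cg00001"]})
    out = cscce_anova(records, ds)
    # two-level one-way ANOVA F equals the squared pooled-variance t
    y = ds.beta.loc["cg00000"]
    t = stats.ttest_ind(y[types == "A"], y[types == "B"]).statistic
    assert out.loc[out.probe_id == "cg00000", "F"].iloc[0] == pytest.approx(t**2)
    # equal group values -> F = 0
    beta_eq = np.tile(np.linspace(0.3, 0.7, n // 2), 2)[None, :]
    ds_eq = _dataset(np.clip(beta_eq, 0, 1), {"cancer_type": np.repeat(["A", "B"], n // 2)})
    out_eq = cscce_anova(pd.DataFrame({"probe_id": ["cg00000"]}), ds_eq)
    assert out_eq["F"].iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_anova_detects_type_specific_shift():
    rng = np.random.default_rng(14)
    types = np.repeat(["A", "B", "C"], 20)
    beta = np.clip(0.5 + 0.1 * (types == "C") + rng.normal(0, 0.04, 60), 0, 1)[None, :]
    ds = _dataset(beta, {"cancer_type": types})
    out = cscce_anova(pd.DataFrame({"probe_id": ["cg00000"]}), ds)
    assert out["p"].iloc[0] < 0.05


def test_anova_drops_singleton_levels():
    rng = np.random.default_rng(15)
    types = np.array(["A"] * 10 + ["B"] * 10 + ["rare"])
    beta = np.clip(rng.normal(0.5, 0.05, (1, 21)), 0, 1)
    ds = _dataset(beta, {"cancer_type": types})
    with pytest.warns(UserWarning, match="singleton"):
        cscce_anova(pd.DataFrame({"probe_id": ["cg00000"]}), ds)


# ---------------------------------------------------------------------------
# feature enrichment + single-locus tests


def _signal(rng, probes, features, samples, boost=None):
    cols = pd.MultiIndex.from_product([features, samples])
    mat = rng.lognormal(0, 0.3, size=(len(probes), len(cols)))
    sig = pd.DataFrame(mat, index=probes, columns=cols)
    if boost:
        feat, subset, factor = boost
        idx = pd.IndexSlice
        sig.loc[subset, idx[feat, :]] = sig.loc[subset, idx[feat, :]].to_numpy() * factor
    return sig


def test_planted_signal_enrichment_attains_signrank_bound():
    rng = np.random.default_rng(16)
    probes = [f"cg{i:05d}" for i in range(300)]
    samples = [f"sm{i}" for i in range(12)]
    target = probes[:20]
    sig = _signal(rng, probes, ["H3K4me1", "DNase"], samples,
                  boost=("H3K4me1", target, 2.0))
    out = feature_enrichment(target, probes, sig, n_baseline=5000, seed=1)
    row = out[out.feature == "H3K4me1"].iloc[0]
    assert row["p"] <= 2.0 ** -(len(samples) - 1)
    assert row["cohen_d"] > 1
    null_row = out[out.feature == "DNase"].iloc[0]
    assert abs(null_row["cohen_d"]) < 1


def test_enrichment_effect_sign_flips_when_sets_swap():
    rng = np.random.default_rng(17)
    probes = [f"cg{i:05d}" for i in range(200)]
    samples = [f"sm{i}" for i in range(10)]
    half_a, half_b = probes[:100], probes[100:]
    sig = _signal(rng, probes, ["mark"], samples, boost=("mark", half_a, 1.8))
    d_a = feature_enrichment(half_a, half_b, sig, n_baseline=4000, seed=2)["cohen_d"][0]
    d_b = feature_enrichment(half_b, half_a, sig, n_baseline=4000, seed=2)["cohen_d"][0]
    assert d_a > 0 > d_b


def test_enrichment_requires_enough_samples():
    rng = np.random.default_rng(18)
    probes = [f"cg{i:05d}" for i in range(50)]
    sig = _signal(rng, probes, ["mark"], ["sm0", "sm1"])
    with pytest.raises(ValueError, match="paired samples"):
        feature_enrichment(probes[:5], probes, sig, n_baseline=100, seed=0)


def test_locus_test_invariant_to_monotone_transform():
    rng = np.random.default_rng(19)
    values = pd.Series(rng.normal(0.5, 0.1, 60),
                       index=[f"sm{i}" for i in range(60)])
    groups = {"lfs": list(values.index[:30]), "hbc": list(values.index[30:])}
    p1 = locus_group_test(values, groups)["p"][0]
    p2 = locus_group_test(np.exp(values * 7), groups)["p"][0]
    assert p1 == p2


def test_locus_test_detects_shift_and_handles_ties():
    rng = np.random.default_rng(20)
    base = rng.normal(0, 1, 30)
    shifted = rng.normal(1, 1, 30)
    values = pd.Series(np.concatenate([base, shifted]),
                       index=[f"sm{i}" for i in range(60)])
    groups = {"a": [f"sm{i}" for i in range(30)], "b": [f"sm{i}" for i in range(30, 60)]}
    assert locus_group_test(values, groups)["p"][0] < 0.05
    tied = pd.Series(1.0, index=values.index)
    with pytest.warns(UserWarning, match="tied"):
        out = locus_group_test(tied, groups)
    assert out["p"][0] == 1.0


def test_locus_test_rejects_overlapping_groups():
    values = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
    with pytest.raises(ValueError, match="disjoint"):
        locus_group_test(values, {"g1": ["a", "b"], "g2": ["b", "c"]})
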