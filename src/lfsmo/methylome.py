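"""Methylation preprocessing, three-cohort EWAS and cis-CSCE discovery.

The analysis views peripheral-blood methylation as a proxy for the
constitutional (germline) epigenome.  A *cancer-associated secondary
constitutional epimutation* (cis-CSCE) is a CpG probe that is

1. associated with cancer status in a discovery cohort and replicated in
   two validation cohorts (the triple-cohort EWAS gate), and
2. associated, by Spearman correlation, with the genotype of a SNP
   within a fixed cis window (+/-10 kb) of the CpG.

Genotypes are coded additively as 1 (hom-ref), 3 (het), 4 (hom-alt); the
unusual spacing is irrelevant for a rank correlation and is preserved
only for fidelity to the published coding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_qvalues, rng_from_seed

__all__ = [
    "MethylationDataset",
    "GenotypeMatrix",
    "EwasResult",
    "CsceResult",
    "EpimutationAnalysis",
    "pca_outlier_trim",
    "residualize",
    "ewas",
    "wilcoxon_probe_test",
    "discover_cscce",
    "cscce_anova",
    "feature_enrichment",
    "locus_group_test",
]

#: additive genotype coding used for the cis association scan
ADDITIVE_CODE = {0: 1, 1: 3, 2: 4}


# ---------------------------------------------------------------------------
# containers


class MethylationDataset:
    """Beta matrix (probes x samples) with probe annotation and covariates.

    Parameters
    ----------
    beta : DataFrame
        Probes as rows, samples as columns, values in [0, 1] unless
        ``assume_residualized`` is set (residualized values may leave the
        unit interval).
    probe_annot : DataFrame indexed by probe_id
        Must carry ``chrom`` and ``pos`` (1-based CpG coordinate);
        ``gene``, ``region_class`` and ``context`` are optional.
    sample_covariates : DataFrame indexed by sample_id
    """

    def __init__(self, beta, probe_annot, sample_covariates, assume_residualized=False):
        beta = pd.DataFrame(beta)
        if beta.index.duplicated().any():
            raise ValueError("duplicate probe IDs in beta matrix")
        if beta.columns.duplicated().any():
            raise ValueError("duplicate sample IDs in beta matrix")
        if not assume_residualized:
            vals = beta.to_numpy()
            if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
                raise ValueError("beta values must lie in [0, 1]")
        missing = beta.index.difference(probe_annot.index)
        if len(missing):
            raise ValueError(f"{len(missing)} probes missing from probe_annot")
        missing = beta.columns.difference(sample_covariates.index)
        if len(missing):
            raise ValueError(f"{len(missing)} samples missing from sample_covariates")
        self.beta = beta
        self.probe_annot = probe_annot.loc[beta.index]
        self.sample_covariates = sample_covariates.loc[beta.columns]
        self.assume_residualized = assume_residualized

    @property
    def n_probes(self):
        return self.beta.shape[0]

    @property
    def n_samples(self):
        return self.beta.shape[1]

    def subset(self, samples=None, probes=None) -> "MethylationDataset":
        beta = self.beta
        if probes is not None:
            beta = beta.loc[list(probes)]
        if samples is not None:
            beta = beta[list(samples)]
        return MethylationDataset(
            beta, self.probe_annot, self.sample_covariates,
            assume_residualized=self.assume_residualized,
        )

    def cohorts(self) -> list[str]:
        if "cohort" in self.sample_covariates:
            return list(pd.unique(self.sample_covariates["cohort"]))
        return []


class GenotypeMatrix:
    """SNP x sample genotype dosages {0, 1, 2}, NaN for missing calls."""

    def __init__(self, genotypes, snp_annot):
        genotypes = pd.DataFrame(genotypes, dtype=float)
        ok = np.isin(genotypes.to_numpy(), [0.0, 1.0, 2.0]) | np.isnan(genotypes.to_numpy())
        if not ok.all():
            raise ValueError("genotype dosages must be 0, 1, 2 or missing")
        missing = genotypes.index.difference(snp_annot.index)
        if len(missing):
            raise ValueError(f"{len(missing)} SNPs missing from snp_annot")
        self.genotypes = genotypes
        self.snp_annot = snp_annot.loc[genotypes.index]

    def additive_code(self) -> pd.DataFrame:
        """The published 1/3/4 coding; rank-equivalent to 0/1/2."""
        return self.genotypes.replace(ADDITIVE_CODE)

    @property
    def samples(self):
        return list(self.genotypes.columns)


# ---------------------------------------------------------------------------
# preprocessing


def pca_outlier_trim(ds: MethylationDataset, k_sd: float = 3.0):
    """Remove samples beyond ``k_sd`` SDs of the mean on PC1 or PC2.

    PCA treats samples as observations; trimming is performed per cohort
    independently (a ``cohort`` covariate column, if absent the whole
    dataset is one cohort).  Returns ``(kept_dataset, removed_ids)``.
    """
    cov = ds.sample_covariates
    groups = (
        cov.groupby("cohort").groups.items()
        if "cohort" in cov
        else [("all", cov.index)]
    )
    removed: list[str] = []
    for _name, ids in groups:
        ids = list(ids)
        if len(ids) < 3:
            raise ValueError("pca_outlier_trim requires at least 3 samples per cohort")
        X = ds.beta[ids].to_numpy().T  # samples x probes
        Xc = X - X.mean(axis=0)
        if not np.any(Xc):
            raise ValueError("degenerate (constant) beta matrix")
        # two leading PCs via SVD; deterministic up to sign, which does not
        # affect a symmetric mean +/- k.sd window
        _u, s, vt = np.linalg.svd(Xc, full_matrices=False)
        scores = Xc @ vt[:2].T
        mu = scores.mean(axis=0)
        sd = scores.std(axis=0, ddof=1)
        sd[sd == 0] = np.inf
        bad = (np.abs(scores - mu) > k_sd * sd).any(axis=1)
        removed.extend(np.asarray(ids)[bad])
    kept = [s for s in ds.beta.columns if s not in set(removed)]
    return ds.subset(samples=kept), removed


def _design_matrix(cov: pd.DataFrame, names: list[str]) -> np.ndarray:
    cols = [np.ones(len(cov))]
    for name in names:
        x = cov[name]
        if x.dtype == bool or x.dtype == object or isinstance(x.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(x, drop_first=True).to_numpy(dtype=float)
            if dummies.size:
                cols.append(dummies)
        else:
            cols.append(np.asarray(x, dtype=float)[:, None])
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("collinear covariates in residualization design; using pseudoinverse")
    return X


def residualize(
    ds: MethylationDataset, known_covariates: list[str], n_latent: int = 10
) -> MethylationDataset:
    """Remove known covariate effects and latent variance components.

    Per-probe linear regression on the listed covariates, followed by
    removal of the top ``n_latent`` singular-vector components of the
    residual matrix (a factor-analysis stand-in for hidden confounders;
    the interface is pluggable so a heavier factor model can be swapped
    in).  Output is re-centered to the original per-probe means; values
    may leave [0, 1] slightly, hence ``assume_residualized``.
    """
    Y = ds.beta.to_numpy().T  # samples x probes
    mean = Y.mean(axis=0, keepdims=True)
    X = _design_matrix(ds.sample_covariates, list(known_covariates))
    beta_hat = np.linalg.pinv(X) @ Y
    R = Y - X @ beta_hat
    if n_latent > 0:
        k = min(n_latent, min(R.shape) - 1)
        u, s, vt = np.linalg.svd(R, full_matrices=False)
        R = R - (u[:, :k] * s[:k]) @ vt[:k]
    out = pd.DataFrame((R + mean).T, index=ds.beta.index, columns=ds.beta.columns)
    return MethylationDataset(
        out, ds.probe_annot, ds.sample_covariates, assume_residualized=True
    )


# ---------------------------------------------------------------------------
# EWAS


def wilcoxon_probe_test(cases: np.ndarray, controls: np.ndarray):
    """Vectorized two-sided Wilcoxon rank-sum test, one row per probe."""
    res = stats.mannwhitneyu(
        cases, controls, axis=1, alternative="two-sided", method="asymptotic"
    )
    return res.statistic, res.pvalue


@dataclass
class EwasResult:
    """Per-probe association with a binary outcome across cohorts."""

    table: pd.DataFrame  # stat_/p_/q_/sig_ columns per cohort + effect_ columns
    cohorts: tuple[str, ...]
    outcome: str
    fdr_cut: float

    @property
    def validated(self) -> pd.Series:
        sig = self.table[[f"sig_{c}" for c in self.cohorts]]
        return sig.all(axis=1)

    @property
    def validated_probes(self) -> list[str]:
        return list(self.table.index[self.validated])

    def discovery_effect(self) -> pd.Series:
        """Mean beta difference (outcome=1 minus outcome=0), first cohort."""
        return self.table[f"effect_{self.cohorts[0]}"]

    def summary(self) -> str:
        lines = [f"EWAS of {self.outcome!r} (BH FDR < {self.fdr_cut})"]
        for c in self.cohorts:
            lines.append(f"  {c}: {int(self.table[f'sig_{c}'].sum())} significant probes")
        lines.append(f"  validated in all cohorts: {int(self.validated.sum())}")
        return "\n".join(lines)


def ewas(
    ds: MethylationDataset,
    outcome: str = "cancer_status",
    test=None,
    fdr_cut: float = 0.1,
    cohorts: tuple[str, ...] | None = None,
) -> EwasResult:
    """Per-cohort EWAS of a binary outcome with BH correction per cohort.

    A probe is *validated* when q < ``fdr_cut`` in every cohort.  The
    per-probe test is pluggable (default: two-sided Wilcoxon rank-sum).
    """
    test = test or wilcoxon_probe_test
    cov = ds.sample_covariates
    if cohorts is None:
        cohorts = tuple(pd.unique(cov["cohort"])) if "cohort" in cov else ("all",)
    table = pd.DataFrame(index=ds.beta.index)
    for c in cohorts:
        ids = cov.index[cov["cohort"] == c] if "cohort" in cov else cov.index
        if not len(ids):
            raise ValueError(f"cohort {c!r} has no samples")
        y = cov.loc[ids, outcome].astype(int)
        if y.nunique() < 2:
            raise ValueError(f"outcome {outcome!r} is constant in cohort {c!r}")
        B = ds.beta[list(ids)].to_numpy()
        cases, controls = B[:, (y == 1).to_numpy()], B[:, (y == 0).to_numpy()]
        stat, p = test(cases, controls)
        q = bh_qvalues(p)
        table[f"stat_{c}"] = stat
        table[f"p_{c}"] = p
        table[f"q_{c}"] = q
        table[f"sig_{c}"] = q < fdr_cut
        table[f"effect_{c}"] = cases.mean(axis=1) - controls.mean(axis=1)
    return EwasResult(table=table, cohorts=tuple(cohorts), outcome=outcome, fdr_cut=fdr_cut)


# ---------------------------------------------------------------------------
# cis-CSCE discovery


@dataclass
class CsceResult:
    """cis-CSCE records: one (probe, strongest cis-SNP) pair per probe."""

    records: pd.DataFrame
    n_probes_tested: int
    n_no_cis_snp: int
    window: int
    fdr_cut: float

    def summary(self) -> str:
        n = len(self.records)
        hypo = int((self.records["risk_direction"] == "hypomethylation_risk").sum()) if n else 0
        up = int((self.records["allele_direction"] == "alt_increases_meth").sum()) if n else 0
        return (
            f"cis-CSCE discovery (window +/-{self.window} bp, BH FDR < {self.fdr_cut})\n"
            f"  probes tested: {self.n_probes_tested}"
            f" (no cis-SNP: {self.n_no_cis_snp})\n"
            f"  significant cis-CSCE: {n}\n"
            f"  alt allele increases methylation: {up}\n"
            f"  hypomethylation-risk: {hypo}"
        )


def _spearman(x: np.ndarray, y: np.ndarray):
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def discover_cscce(
    ewas_result: EwasResult,
    ds: MethylationDataset,
    geno: GenotypeMatrix,
    window: int = 10_000,
    fdr_cut: float = 0.05,
    min_pairs: int = 10,
    probes: list[str] | None = None,
) -> CsceResult:
    """Identify cis-CSCE among EWAS-validated probes.

    For each validated probe, every SNP within ``window`` bases (inclusive)
    of the CpG is tested by Spearman correlation between beta values and
    additive genotype codes over samples carrying both data types
    (pairwise-complete for missing genotypes; pairs with fewer than
    ``min_pairs`` complete observations are skipped).  The strongest SNP
    per probe (max |rho|, then smallest p, smallest |distance|,
    lexicographic SNP ID) represents the probe; BH correction runs over
    the retained per-probe p-values.
    """
    candidates = probes if probes is not None else ewas_result.validated_probes
    shared = [s for s in ds.beta.columns if s in set(geno.samples)]
    if not shared:
        raise ValueError("no samples shared between methylation and genotypes")
    code = geno.additive_code()[shared]
    beta = ds.beta[shared]
    annot = ds.probe_annot
    snps = geno.snp_annot
    effect = ewas_result.discovery_effect()

    rows, n_no_snp = [], 0
    for pid in candidates:
        chrom, pos = annot.at[pid, "chrom"], annot.at[pid, "pos"]
        near = snps[(snps["chrom"] == chrom) & (np.abs(snps["pos"] - pos) <= window)]
        if near.empty:
            n_no_snp += 1
            continue
        y = beta.loc[pid].to_numpy(dtype=float)
        best = None
        for sid, srow in near.iterrows():
            g = code.loc[sid].to_numpy(dtype=float)
            ok = ~np.isnan(g) & ~np.isnan(y)
            if ok.sum() < min_pairs or np.all(g[ok] == g[ok][0]):
                continue
            rho, p = _spearman(g[ok], y[ok])
            if np.isnan(rho):
                continue
            dist = int(srow["pos"] - pos)
            key = (-abs(rho), p, abs(dist), str(sid))
            if best is None or key < best[0]:
                best = (key, sid, rho, p, dist)
        if best is None:
            n_no_snp += 1
            continue
        _, sid, rho, p, dist = best
        rows.append(
            {
                "probe_id": pid,
                "snp_id": sid,
                "distance": dist,
                "rho": rho,
                "p_cs": p,
                "allele_direction": (
                    "alt_increases_meth" if rho > 0 else "alt_decreases_meth"
                ),
                "risk_direction": (
                    "hypomethylation_risk" if effect.get(pid, 0.0) < 0
                    else "hypermethylation_risk"
                ),
            }
        )
    records = pd.DataFrame(
        rows,
        columns=["probe_id", "snp_id", "distance", "rho", "p_cs",
                 "allele_direction", "risk_direction"],
    )
    if len(records):
        records["q_cs"] = bh_qvalues(records["p_cs"])
        records = records[records["q_cs"] < fdr_cut].reset_index(drop=True)
    else:
        records["q_cs"] = pd.Series(dtype=float)
    return CsceResult(
        records=records,
        n_probes_tested=len(candidates),
        n_no_cis_snp=n_no_snp,
        window=window,
        fdr_cut=fdr_cut,
    )


def cscce_anova(
    cscce: CsceResult | pd.DataFrame,
    ds: MethylationDataset,
    cancer_type: str = "cancer_type",
    min_per_level: int = 2,
) -> pd.DataFrame:
    """One-way ANOVA of beta by cancer type per cis-CSCE probe, with BH q."""
    records = cscce.records if isinstance(cscce, CsceResult) else cscce
    cov = ds.sample_covariates
    counts = cov[cancer_type].value_counts()
    levels = counts[counts >= min_per_level].index
    dropped = counts[counts < min_per_level]
    if len(dropped):
        warnings.warn(f"dropping singleton cancer-type levels: {list(dropped.index)}")
    if len(levels) < 2:
        raise ValueError("need at least two cancer-type levels with enough samples")
    keep = cov.index[cov[cancer_type].isin(levels)]
    rows = []
    for pid in records["probe_id"]:
        y = ds.beta.loc[pid, keep]
        groups = [y[cov.loc[keep, cancer_type] == lvl].to_numpy() for lvl in levels]
        f, p = stats.f_oneway(*groups)
        rows.append({"probe_id": pid, "F": float(f), "p": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_qvalues(out["p"])
    return out


# ---------------------------------------------------------------------------
# feature enrichment / single-locus tests


def feature_enrichment(
    cscce_probes,
    all_probes,
    signal: pd.DataFrame,
    n_baseline: int = 100_000,
    seed=0,
) -> pd.DataFrame:
    """Genomic-feature enrichment of a probe set against a resampled baseline.

    ``signal`` is indexed by probe with MultiIndex columns
    ``(feature, sample)`` holding the average signal of that feature at
    the probe's locus in that sample.  ``n_baseline`` probes are sampled
    with replacement from ``all_probes`` to form the baseline; for each
    feature, per-sample baseline means are compared with per-sample
    means over the cis-CSCE probes by a paired Wilcoxon signed-rank
    test, with effect size Cohen's d_z = mean(diff)/sd(diff).
    """
    rng = rng_from_seed(seed)
    cscce_probes = list(cscce_probes)
    all_probes = np.asarray(list(all_probes))
    baseline = rng.choice(all_probes, size=n_baseline, replace=True)
    features = signal.columns.get_level_values(0).unique()
    rows = []
    for feat in features:
        sub = signal[feat]
        n_samples = sub.shape[1]
        if n_samples < 5:
            raise ValueError(f"feature {feat!r}: need >=5 paired samples")
        base_mean = sub.loc[baseline].mean(axis=0)
        set_mean = sub.loc[cscce_probes].mean(axis=0)
        diff = (set_mean - base_mean).to_numpy(dtype=float)
        if np.allclose(diff, 0):
            p, d = 1.0, 0.0
        else:
            p = float(stats.wilcoxon(set_mean, base_mean, alternative="two-sided").pvalue)
            sd = diff.std(ddof=1)
            d = float(diff.mean() / sd) if sd > 0 else np.inf * np.sign(diff.mean())
        rows.append({"feature": feat, "p": p, "cohen_d": d, "n_samples": n_samples})
    return pd.DataFrame(rows)


def locus_group_test(values: pd.Series, groups: dict[str, list[str]]) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests of one locus across groups."""
    names = list(groups)
    seen: set[str] = set()
    for n in names:
        if not groups[n]:
            raise ValueError(f"group {n!r} is empty")
        dup = seen & set(groups[n])
        if dup:
            raise ValueError(f"groups are not disjoint: {sorted(dup)}")
        seen |= set(groups[n])
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            x = values.loc[groups[a]].to_numpy(dtype=float)
            y = values.loc[groups[b]].to_numpy(dtype=float)
            if len(np.unique(np.concatenate([x, y]))) == 1:
                warnings.warn(f"all values tied for {a} vs {b}; p = 1")
                stat, p = np.nan, 1.0
            else:
                res = stats.mannwhitneyu(x, y, alternative="two-sided")
                stat, p = float(res.statistic), float(res.pvalue)
            rows.append({"group_a": a, "group_b": b, "statistic": stat, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model-style front end


class EpimutationAnalysis:
    """Three-cohort EWAS + cis-CSCE discovery as one fitted model.

    Parameters mirror the published thresholds: EWAS FDR 0.1, cis-CSCE
    FDR 0.05, cis window 10 kb.
    """

    def __init__(
        self,
        dataset: MethylationDataset,
        genotypes: GenotypeMatrix | None = None,
        outcome: str = "cancer_status",
        test=None,
        fdr_ewas: float = 0.1,
        fdr_cscce: float = 0.05,
        window: int = 10_000,
        cohorts: tuple[str, ...] | None = None,
    ):
        self.dataset = dataset
        self.genotypes = genotypes
        self.outcome = outcome
        self.test = test
        self.fdr_ewas = fdr_ewas
        self.fdr_cscce = fdr_cscce
        self.window = window
        self.cohorts = cohorts

    def fit(self) -> "EpimutationResults":
        ew = ewas(
            self.dataset, outcome=self.outcome, test=self.test,
            fdr_cut=self.fdr_ewas, cohorts=self.cohorts,
        )
        cs = None
        if self.genotypes is not None:
            cs = discover_cscce(
                ew, self.dataset, self.genotypes,
                window=self.window, fdr_cut=self.fdr_cscce,
            )
        return EpimutationResults(model=self, ewas=ew, cscce=cs)


@dataclass
class EpimutationResults:
    model: EpimutationAnalysis
    ewas: EwasResult
    cscce: CsceResult | None = None
    extras: dict = field(default_factory=dict)

    def summary(self) -> str:
        parts = [self.ewas.summary()]
        if self.cscce is not None:
            parts.append(self.cscce.summary())
        return "\n".join(parts)
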