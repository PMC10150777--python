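"""Small-variant QC, tiered five-class classification and cohort comparisons.

The classification schema combines three axes:

* ACMG-style pathogenicity (P / LP / VUS / LB / B), taken from an
  upstream annotation engine and adjusted here only by the null-variant
  rule (null variants in loss-of-function-mechanism genes become LP);
* a four-tier gene prioritization (1 = autosomal dominant cancer
  predisposition genes, 2 = autosomal recessive CPGs, 3 = recurrently
  somatically mutated cancer genes, 4 = everything else);
* family co-segregation, coded as the ACMG PP1 (found in all affected
  members) and BS4 (found in no affected member) evidence items.

Variant classes: 1-4 are P/LP variants in tier 1-4 genes (class 4 needs
an explicit literature-support allow-list); class 5 is a
cancer-segregating VUS in a tier 1-3 gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_qvalues
from .cohort import Family

__all__ = [
    "QC_BOUNDS",
    "apply_qc_filters",
    "apply_population_filter",
    "code_segregation",
    "finalize_pathogenicity",
    "assign_class",
    "classify_variants",
    "per_patient_burden",
    "compare_burden",
    "pathway_enrichment",
    "survival_groups",
    "SurvivalGroups",
]

#: (metric, pass-predicate description) -- pass conditions exactly as the
#: short-read artifact filter set prescribes
QC_BOUNDS = {
    "read_pos_pct": lambda v: (v >= 10) & (v <= 90),
    "strandedness_pct": lambda v: (v >= 1) & (v <= 99),
    "dist_to_3prime": lambda v: v > 20,
    "homopolymer_len": lambda v: v < 5,
    "mapq_diff": lambda v: v < 30,
    "read_len_diff": lambda v: v < 25,
    "mmqs_diff": lambda v: v < 100,
    "alt_reads": lambda v: v >= 5,
}

NULL_CONSEQUENCES = {
    "nonsense",
    "frameshift_del",
    "frameshift_ins",
    "splice_canonical",
    "initiation_codon",
    "exon_deletion",
}

AF_COLUMNS = ["af_gnomad", "af_exac", "af_1kgp"]


def apply_qc_filters(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a variant table into passing and failing records.

    A record passes iff every QC metric satisfies its bound; the failed
    table carries a ``failed_filters`` column naming each violated
    filter.  A missing metric fails conservatively with the label
    ``missing_metric``.
    """
    df = records.copy()
    fail_labels = pd.Series([[] for _ in range(len(df))], index=df.index, dtype=object)
    for metric, pred in QC_BOUNDS.items():
        if metric not in df:
            raise ValueError(f"missing QC column: {metric}")
        v = pd.to_numeric(df[metric], errors="coerce")
        missing = v.isna()
        bad = ~pred(v.fillna(np.inf)) & ~missing
        for i in df.index[bad]:
            fail_labels[i] = fail_labels[i] + [metric]
        for i in df.index[missing]:
            if "missing_metric" not in fail_labels[i]:
                fail_labels[i] = fail_labels[i] + ["missing_metric"]
    failed_mask = fail_labels.map(len) > 0
    failed = df[failed_mask].copy()
    failed["failed_filters"] = fail_labels[failed_mask].map(",".join)
    return df[~failed_mask].copy(), failed


def apply_population_filter(
    records: pd.DataFrame, af_threshold: float = 0.01
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split into rare and common records.

    Common iff any population AF is strictly greater than the threshold
    (a variant at exactly 0.01 is retained); missing AF counts as 0
    (absent from the database).
    """
    df = records
    afs = df.reindex(columns=AF_COLUMNS).apply(pd.to_numeric, errors="coerce")
    if (afs < 0).any().any():
        raise ValueError("negative allele frequency")
    common = (afs.fillna(0.0) > af_threshold).any(axis=1)
    return df[~common].copy(), df[common].copy()


@dataclass(frozen=True)
class Segregation:
    pp1: int
    bs4: int
    label: str  # cancer_segregating | unaffected_segregating | shared | unknown


def code_segregation(family: Family, carriers: set[str]) -> Segregation:
    """PP1/BS4 co-segregation coding for one variant in one family.

    * all sequenced affected members carry it  -> (1, 0, cancer_segregating)
    * no sequenced affected member carries it  -> (0, 1, unaffected_segregating
      if an unaffected member carries it, else unknown)
    * carried by some but not all affected     -> (0, 0, shared)
    * singleton sample or no affected members  -> (0, 0, unknown)
    """
    unknown_ids = set(carriers) - set(family.members)
    if unknown_ids:
        raise ValueError(f"carriers not in family {family.family_id}: {sorted(unknown_ids)}")
    if family.is_singleton:
        return Segregation(0, 0, "unknown")
    affected = family.affected
    if not affected:
        return Segregation(0, 0, "unknown")
    carrying_affected = affected & set(carriers)
    if carrying_affected == affected:
        return Segregation(1, 0, "cancer_segregating")
    if not carrying_affected:
        label = "unaffected_segregating" if set(carriers) & family.unaffected else "unknown"
        return Segregation(0, 1, label)
    return Segregation(0, 0, "shared")


def finalize_pathogenicity(
    base_pathogenicity, consequence, gene: str, lof_mechanism_genes: set[str]
) -> str:
    """Apply the null-variant override to an upstream pathogenicity call.

    Null variants (nonsense, frameshift, canonical splice, initiation
    codon, exon deletion) in genes where loss of function is an
    established disease mechanism are upgraded to LP; calls are never
    downgraded and P/LP calls are untouched.
    """
    has_base = isinstance(base_pathogenicity, str) and base_pathogenicity != ""
    has_cons = isinstance(consequence, str) and consequence != ""
    if not has_base and not has_cons:
        raise ValueError("both base_pathogenicity and consequence are missing")
    base = base_pathogenicity if has_base else "VUS"
    if base in ("P", "LP"):
        return base
    if has_cons and consequence in NULL_CONSEQUENCES and gene in lof_mechanism_genes:
        return "LP"
    return base


def assign_class(
    final_pathogenicity: str,
    tier: int,
    segregation_label: str,
    gene: str,
    class4_support: set[str],
):
    """Map (pathogenicity, tier, segregation) to variant class 1-5 or None."""
    if final_pathogenicity in ("P", "LP"):
        if tier in (1, 2, 3):
            return tier
        if tier == 4 and gene in class4_support:
            return 4
        return None
    if (
        final_pathogenicity == "VUS"
        and tier in (1, 2, 3)
        and segregation_label == "cancer_segregating"
    ):
        return 5
    return None


def classify_variants(
    records: pd.DataFrame,
    families: list[Family],
    tiers: pd.DataFrame,
    lof_mechanism_genes: set[str],
    class4_support: set[str] | None = None,
) -> pd.DataFrame:
    """Full classification of a rare, QC-passing variant table.

    Adds columns: ``tier``, ``final_pathogenicity``, ``pp1``, ``bs4``,
    ``segregation``, ``variant_class``.  Carriers of a variant are all
    samples sharing (chrom, pos, ref, alt); segregation is coded within
    each carrier's own family.  Genes absent from tiers 1-3 default to
    tier 4.  Idempotent: a pure function of its inputs.
    """
    class4_support = class4_support or set()
    tier_of = dict(zip(tiers["gene"], tiers["tier"]))
    fam_of: dict[str, Family] = {}
    for fam in families:
        for m in fam.members:
            fam_of[m] = fam

    df = records.copy()
    df["tier"] = df["gene"].map(lambda g: tier_of.get(g, 4)).astype(int)
    df["final_pathogenicity"] = [
        finalize_pathogenicity(bp, cons, g, lof_mechanism_genes)
        for bp, cons, g in zip(df["base_pathogenicity"], df["consequence"], df["gene"])
    ]
    key = df[["chrom", "pos", "ref", "alt"]].astype(str).agg(":".join, axis=1)
    carriers_of = df.groupby(key)["sample_id"].agg(set)
    pp1, bs4, labels = [], [], []
    for k, sample in zip(key, df["sample_id"]):
        fam = fam_of.get(sample)
        if fam is None:
            seg = Segregation(0, 0, "unknown")
        else:
            seg = code_segregation(fam, carriers_of[k] & set(fam.members))
        pp1.append(seg.pp1)
        bs4.append(seg.bs4)
        labels.append(seg.label)
    df["pp1"], df["bs4"], df["segregation"] = pp1, bs4, labels
    df["variant_class"] = [
        assign_class(fp, t, lab, g, class4_support)
        for fp, t, lab, g in zip(
            df["final_pathogenicity"], df["tier"], df["segregation"], df["gene"]
        )
    ]
    return df


def per_patient_burden(
    classified: pd.DataFrame,
    sample_ids: list[str],
    exclude_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Per-sample counts of class 1-2, 1-3, 4 and 5 variants.

    ``exclude_genes`` removes e.g. TP53 itself (an inherent bias in any
    cohort comparison) or WNT-pathway genes before counting.
    """
    df = classified
    if exclude_genes:
        df = df[~df["gene"].isin(set(exclude_genes))]
    df = df[df["variant_class"].notna()]
    out = pd.DataFrame(
        0, index=pd.Index(sample_ids, name="sample_id"),
        columns=["class1_2", "class1_3", "class4", "class5"],
    )
    for sample, cls in zip(df["sample_id"], df["variant_class"]):
        if sample not in out.index:
            continue
        if cls in (1, 2):
            out.at[sample, "class1_2"] += 1
        if cls in (1, 2, 3):
            out.at[sample, "class1_3"] += 1
        elif cls == 4:
            out.at[sample, "class4"] += 1
        elif cls == 5:
            out.at[sample, "class5"] += 1
    return out


def compare_burden(
    counts_a,
    counts_b,
    test: str = "fisher_prevalence",
) -> tuple[float, float]:
    """Compare per-sample variant counts between two disjoint groups.

    ``fisher_prevalence`` dichotomizes each sample into carrier
    (count >= 1) vs non-carrier and applies a two-sided Fisher exact
    test; ``wilcoxon_count`` applies a two-sided Wilcoxon rank-sum test
    to the counts themselves.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if test == "fisher_prevalence":
        table = [
            [int((a >= 1).sum()), int((a < 1).sum())],
            [int((b >= 1).sum()), int((b < 1).sum())],
        ]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return float(odds), float(p)
    if test == "wilcoxon_count":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def pathway_enrichment(
    classified: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    background: set[str],
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Fisher enrichment of P/LP-mutated genes in each gene set, with BH q.

    Also reports ``freq``: the fraction of patients carrying at least one
    P/LP variant in the set (requires ``sample_ids``).
    """
    plp = classified[classified["final_pathogenicity"].isin(["P", "LP"])]
    mutated = set(plp["gene"]) & background
    rows = []
    import warnings as _warnings

    for name, genes in gene_sets.items():
        gs = set(genes)
        outside = gs - background
        if outside:
            _warnings.warn(
                f"gene set {name!r}: {len(outside)} genes absent from background; intersecting"
            )
            gs = gs & background
        if not gs:
            raise ValueError(f"gene set {name!r} is empty after intersection")
        a = len(mutated & gs)
        b = len(mutated - gs)
        c = len(gs - mutated)
        d = len(background - gs - mutated)
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        freq = np.nan
        if sample_ids is not None:
            hit = plp[plp["gene"].isin(gs)].groupby("sample_id").size()
            freq = float(
                sum(1 for s in sample_ids if hit.get(s, 0) >= 1) / max(len(sample_ids), 1)
            )
        rows.append(
            {"gene_set": name, "n_mutated_in_set": a, "odds_ratio": float(odds),
             "p": float(p), "freq": freq}
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_qvalues(out["p"])
    return out


@dataclass
class SurvivalGroups:
    """Class-based survival grouping with KM curves and a log-rank p."""

    labels: pd.Series  # sample_id -> wnt_modifier | class1_3 | neither
    dual_members: list[str]
    km_tables: dict[str, pd.DataFrame]
    logrank_p: float | None

    def summary(self) -> str:
        counts = self.labels.value_counts()
        lines = ["survival groups:"]
        for g in ("class1_3", "wnt_modifier", "neither"):
            lines.append(f"  {g}: {int(counts.get(g, 0))}")
        if self.dual_members:
            lines.append(f"  dual membership: {', '.join(self.dual_members)}")
        if self.logrank_p is not None:
            lines.append(f"  log-rank p = {self.logrank_p:.3g}")
        return "\n".join(lines)


def survival_groups(
    samples: pd.DataFrame,
    classified: pd.DataFrame,
    wnt_genes: set[str],
    dual_assignment: str = "class1_3",
) -> SurvivalGroups:
    """Assign each sample to a survival group and compare the groups.

    Groups: ``class1_3`` (>= 1 class 1-3 variant), ``wnt_modifier``
    (P/LP variant in a WNT-signaling gene), ``neither``.  A sample
    qualifying for both is assigned per ``dual_assignment`` ("class1_3",
    the risk-dominant default, or "wnt_modifier") and reported in
    ``dual_members``.  Kaplan-Meier curves and a log-rank test run over
    samples with survival data.
    """
    if dual_assignment not in ("class1_3", "wnt_modifier"):
        raise ValueError("dual_assignment must be 'class1_3' or 'wnt_modifier'")
    surv = samples.dropna(subset=["surv_time"])
    if (surv["surv_time"] <= 0).any():
        bad = surv.loc[surv["surv_time"] <= 0, "sample_id"].iloc[0]
        raise ValueError(f"non-positive follow-up time for sample {bad}")
    cls13 = set(
        classified.loc[classified["variant_class"].isin([1, 2, 3]), "sample_id"]
    )
    wnt = set(
        classified.loc[
            classified["final_pathogenicity"].isin(["P", "LP"])
            & classified["gene"].isin(set(wnt_genes)),
            "sample_id",
        ]
    )
    dual = sorted(cls13 & wnt)
    labels = {}
    for s in samples["sample_id"]:
        in13, inw = s in cls13, s in wnt
        if in13 and inw:
            labels[s] = dual_assignment
        elif inw:
            labels[s] = "wnt_modifier"
        elif in13:
            labels[s] = "class1_3"
        else:
            labels[s] = "neither"
    labels = pd.Series(labels, name="group")

    km_tables: dict[str, pd.DataFrame] = {}
    logrank_p = None
    if len(surv):
        from lifelines import KaplanMeierFitter
        from lifelines.statistics import multivariate_logrank_test

        surv = surv.assign(group=labels.loc[surv["sample_id"]].to_numpy())
        for g, grp in surv.groupby("group"):
            kmf = KaplanMeierFitter()
            kmf.fit(grp["surv_time"], grp["surv_event"].astype(int))
            km_tables[g] = kmf.survival_function_.rename(columns={"KM_estimate": "survival"})
        if surv["group"].nunique() >= 2:
            res = multivariate_logrank_test(
                surv["surv_time"], surv["group"], surv["surv_event"].astype(int)
            )
            logrank_p = float(res.p_value)
    return SurvivalGroups(
        labels=labels, dual_members=dual, km_tables=km_tables, logrank_p=logrank_p
    )
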