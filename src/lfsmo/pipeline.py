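"""Pipeline orchestration: run every stage from files on disk.

Stages run in dependency order (variants -> SV/CNV -> methylome ->
cis-CSCE -> risk); stages whose inputs are absent are skipped with a
notice in the manifest.  A provenance manifest records the seed,
thresholds, input checksums and per-stage record counts so reported
fractions are auditable.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import io as lio
from . import methylome as meth
from . import risk as risk_mod
from . import sv as sv_mod
from . import variants as var_mod

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full pipeline run.

    Threshold defaults are the published operating points: population AF
    0.01, EWAS FDR 0.1, cis-CSCE FDR 0.05, cis window 10 kb, PoN support
    3, annotation score 3, PCA trim at 3 SD, k = 3 clusters.
    """

    out_dir: str
    vcf: str | None = None
    variant_annot: str | None = None
    ped: str | None = None
    tiers: str | None = None
    gmt: str | None = None
    class4_support: str | None = None
    sv_caller_a: str | None = None
    sv_caller_b: str | None = None
    pon_dir: str | None = None
    cnv_caller_a: str | None = None
    cnv_caller_b: str | None = None
    exclusion_bed: str | None = None
    beta: str | None = None
    probe_annot: str | None = None
    sample_covariates: str | None = None
    genotypes: str | None = None
    exclude_genes: tuple[str, ...] = ()
    af_threshold: float = 0.01
    fdr_ewas: float = 0.1
    fdr_cscce: float = 0.05
    cis_window: int = 10_000
    min_pon_support: int = 3
    min_annot_score: int = 3
    k_sd: float = 3.0
    k_clusters: int = 3
    embed: str = "pca"
    cv_repeats: int = 5
    rf_trees: int = 300
    seed: int = 0

    def validate(self):
        for name in ("af_threshold", "fdr_ewas", "fdr_cscce", "cis_window",
                     "min_pon_support", "min_annot_score", "k_sd", "k_clusters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class StageLog:
    name: str
    status: str = "ok"
    counts: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    note: str = ""


def _log(msg):
    print(f"[lfsmo] {msg}", file=sys.stderr)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all runnable stages; returns the provenance manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "stages": [],
        "inputs": {},
    }
    for name, path in asdict(config).items():
        if isinstance(path, str) and name != "out_dir" and Path(path).is_file():
            manifest["inputs"][name] = lio.sha256_of(path)

    samples = families = None
    if config.ped:
        samples, families = lio.read_ped(config.ped)

    classified = None
    wnt_genes: set[str] = set()
    gene_sets = lio.read_gmt(config.gmt) if config.gmt else {}
    wnt_genes = set(gene_sets.get("WNT_SIGNALING", []))

    # ---- variants ---------------------------------------------------------
    if config.vcf and config.tiers and samples is not None:
        stage = StageLog("variants")
        try:
            records = lio.read_vcf(config.vcf, config.variant_annot)
            stage.counts["records_in"] = len(records)
            passed, failed = var_mod.apply_qc_filters(records)
            stage.counts["qc_pass"] = len(passed)
            stage.counts["qc_fail"] = len(failed)
            rare, common = var_mod.apply_population_filter(passed, config.af_threshold)
            stage.counts["rare"] = len(rare)
            stage.counts["common"] = len(common)
            tiers = lio.read_gene_tiers(config.tiers)
            lof = set(tiers.loc[tiers["tier"].isin([1, 2]), "gene"])
            support = set()
            if config.class4_support:
                support = {
                    g.strip()
                    for g in Path(config.class4_support).read_text().splitlines()
                    if g.strip()
                }
            classified = var_mod.classify_variants(rare, families, tiers, lof, support)
            classified.to_csv(out / "classified_variants.tsv", sep="\t", index=False)
            failed.to_csv(out / "qc_failed_variants.tsv", sep="\t", index=False)
            if "has_wgs" in samples:
                wgs_ids = list(samples.loc[samples["has_wgs"].astype(bool), "sample_id"])
            else:
                wgs_ids = list(samples["sample_id"])
            burden = var_mod.per_patient_burden(
                classified, wgs_ids, exclude_genes=set(config.exclude_genes)
            )
            burden.to_csv(out / "per_sample_burden.tsv", sep="\t")
            stage.counts["classified"] = int(classified["variant_class"].notna().sum())
            stage.outputs = ["classified_variants.tsv", "per_sample_burden.tsv"]
            if gene_sets:
                background = set(tiers["gene"])
                enr = var_mod.pathway_enrichment(
                    classified, gene_sets, background, sample_ids=wgs_ids
                )
                enr.to_csv(out / "pathway_enrichment.tsv", sep="\t", index=False)
                stage.outputs.append("pathway_enrichment.tsv")
            if wnt_genes and "surv_time" in samples:
                sg = var_mod.survival_groups(
                    samples[samples["sample_id"].isin(wgs_ids)], classified, wnt_genes
                )
                sg.labels.to_csv(out / "survival_groups.tsv", sep="\t", header=["group"])
                stage.counts["logrank_p"] = sg.logrank_p
                stage.outputs.append("survival_groups.tsv")
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage variants failed: {exc}") from exc
        manifest["stages"].append(asdict(stage))
        _log(f"variants: {stage.counts}")
    else:
        manifest["stages"].append(
            asdict(StageLog("variants", status="skipped", note="inputs missing"))
        )
        _log("variants: skipped (inputs missing)")

    # ---- SV consensus -----------------------------------------------------
    if config.sv_caller_a and config.sv_caller_b:
        stage = StageLog("sv_consensus")
        try:
            a = pd.read_csv(config.sv_caller_a, sep="\t")
            b = pd.read_csv(config.sv_caller_b, sep="\t")
            pon = {}
            if config.pon_dir:
                for f in sorted(Path(config.pon_dir).glob("*.tsv")):
                    pon[f.stem] = pd.read_csv(f, sep="\t")
            pieces = []
            for sample in sorted(set(a["sample_id"]) & set(b["sample_id"])):
                cons = sv_mod.merge_callsets(
                    a[a["sample_id"] == sample], b[b["sample_id"] == sample]
                )
                cons = sv_mod.filter_pon(cons, pon, min_support=config.min_pon_support)
                cons = sv_mod.filter_annotation(cons, min_score=config.min_annot_score)
                pieces.append(cons)
            consensus = (
                pd.concat(pieces, ignore_index=True) if pieces else sv_mod._empty_consensus()
            )
            consensus.to_csv(out / "sv_consensus.tsv", sep="\t", index=False)
            passing = consensus[consensus["filter_status"] == "pass"]
            lio.write_bed(
                passing, out / "sv_consensus_pass.bed",
                extra_cols=["svtype", "sample_id"],
            )
            stage.counts = {
                "calls_a": len(a), "calls_b": len(b),
                "consensus": len(consensus), "pass": len(passing),
            }
            stage.outputs = ["sv_consensus.tsv", "sv_consensus_pass.bed"]
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage sv_consensus failed: {exc}") from exc
        manifest["stages"].append(asdict(stage))
        _log(f"sv_consensus: {stage.counts}")
    else:
        manifest["stages"].append(
            asdict(StageLog("sv_consensus", status="skipped", note="inputs missing"))
        )

    # ---- CNV --------------------------------------------------------------
    if config.cnv_caller_a and config.cnv_caller_b:
        stage = StageLog("cnv")
        try:
            a = pd.read_csv(config.cnv_caller_a, sep="\t")
            b = pd.read_csv(config.cnv_caller_b, sep="\t")
            excl = lio.read_bed(config.exclusion_bed) if config.exclusion_bed else None
            cnv = sv_mod.intersect_cnv(a, b, exclusion=excl)
            cnv.to_csv(out / "cnv_consensus.tsv", sep="\t", index=False)
            stage.counts = {"calls_a": len(a), "calls_b": len(b), "consensus": len(cnv)}
            stage.outputs = ["cnv_consensus.tsv"]
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage cnv failed: {exc}") from exc
        manifest["stages"].append(asdict(stage))
        _log(f"cnv: {stage.counts}")
    else:
        manifest["stages"].append(
            asdict(StageLog("cnv", status="skipped", note="inputs missing"))
        )

    # ---- methylome + cis-CSCE --------------------------------------------
    cscce = None
    ds = None
    if config.beta and config.probe_annot and config.sample_covariates:
        stage = StageLog("cscce")
        try:
            ds = meth.MethylationDataset(
                lio.read_matrix(config.beta),
                pd.read_csv(config.probe_annot, sep="\t", index_col=0),
                pd.read_csv(config.sample_covariates, sep="\t", index_col=0),
            )
            ds, removed = meth.pca_outlier_trim(ds, k_sd=config.k_sd)
            stage.counts["pca_outliers_removed"] = len(removed)
            geno = None
            if config.genotypes:
                raw = pd.read_csv(config.genotypes, sep="\t", index_col=0)
                snp_annot = raw[["chrom", "pos"]]
                geno = meth.GenotypeMatrix(raw.drop(columns=["chrom", "pos"]), snp_annot)
            model = meth.EpimutationAnalysis(
                ds, genotypes=geno,
                fdr_ewas=config.fdr_ewas, fdr_cscce=config.fdr_cscce,
                window=config.cis_window,
            )
            res = model.fit()
            res.ewas.table.to_csv(out / "ewas.tsv", sep="\t")
            stage.counts["validated_probes"] = int(res.ewas.validated.sum())
            stage.outputs = ["ewas.tsv"]
            if res.cscce is not None:
                res.cscce.records.to_csv(out / "cscce.tsv", sep="\t", index=False)
                stage.counts["cscce"] = len(res.cscce.records)
                stage.outputs.append("cscce.tsv")
                cscce = res.cscce
            (out / "epimutation_summary.txt").write_text(res.summary() + "\n")
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage cscce failed: {exc}") from exc
        manifest["stages"].append(asdict(stage))
        _log(f"cscce: {stage.counts}")
    else:
        manifest["stages"].append(
            asdict(StageLog("cscce", status="skipped", note="methylation inputs missing"))
        )
        _log("cscce: skipped (methylation inputs missing)")

    # ---- risk -------------------------------------------------------------
    if cscce is not None and len(cscce.records) >= 2 and ds is not None:
        stage = StageLog("risk")
        try:
            probes = list(cscce.records["probe_id"])
            cov = ds.sample_covariates
            X = ds.beta.loc[probes].T
            y = cov["cancer_status"].astype(int)
            splits = {}
            for role, cohort in (("train", "external"), ("validation", "internal"),
                                 ("test", "discovery")):
                ids = cov.index[cov["cohort"] == cohort]
                splits[role] = (X.loc[ids], y.loc[ids])
            model = risk_mod.CancerRiskModel(
                splits["train"], splits["validation"], splits["test"],
                cv_repeats=config.cv_repeats, n_estimators=config.rf_trees,
                n_bootstrap=500,
            )
            report = model.fit(seed=config.seed)
            (out / "risk_report.json").write_text(json.dumps(report.to_dict(), indent=1))
            clus = risk_mod.embed_and_cluster(
                X, k=config.k_clusters, embed=config.embed, seed=config.seed,
                cancer_status=y,
            )
            clus.labels.to_csv(out / "clusters.tsv", sep="\t", header=["cluster"])
            stage.counts = {
                "auroc_test": report.auroc["test"],
                "chi2_p": clus.chi2_p,
            }
            stage.outputs = ["risk_report.json", "clusters.tsv"]
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage risk failed: {exc}") from exc
        manifest["stages"].append(asdict(stage))
        _log(f"risk: {stage.counts}")
    else:
        manifest["stages"].append(
            asdict(StageLog("risk", status="skipped", note="no cis-CSCE available"))
        )

    manifest["outputs"] = {
        f.name: lio.sha256_of(f) for f in sorted(out.iterdir()) if f.is_file()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
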