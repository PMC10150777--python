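"""Synthetic LFS-like cohort generator.

Emulates the statistical structure the downstream analysis assumes so
every stage is testable without access-controlled patient data:

* families with affected / unaffected members, a majority of families
  segregating a deleterious TP53 allele;
* an annotated small-variant table in which a minority of samples carry
  planted class 1-5 variants (tiered gene lists are generated alongside);
* dual-caller SV callsets holding the same true events under two caller
  labels with breakpoints jittered by N(0, sv_jitter_sd), plus
  caller-private false positives and recurrent panel-of-normals artifacts;
* CNV callsets from two read-depth-style callers with partial overlaps
  and an exclusion-region list;
* a methylation beta matrix over three cohorts (discovery / internal /
  external validation) with batch structure, planted cis-meQTLs
  (SNP -> methylation within +/-10 kb) of which a subset additionally
  carries a methylation -> cancer effect (the planted cis-CSCE);
* right-censored survival times whose hazard depends on the planted
  risk group.

Everything is drawn from one ``numpy`` Generator seeded by
``SimConfig.seed``; the same seed yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import SAMPLE_COLUMNS, Family, families_from_samples
from .methylome import GenotypeMatrix, MethylationDataset

__all__ = ["SimConfig", "SimConfigError", "SimulatedCohort", "simulate_cohort"]

_BASES = np.array(list("ACGT"))

#: consequence vocabulary for background (mostly inert) variants
_BG_CONSEQUENCES = ["synonymous", "missense", "inframe_indel", "other"]
_NULL_CONSEQUENCES = ["nonsense", "frameshift_del", "frameshift_ins", "splice_canonical"]
_CANCER_TYPES = ["breast", "CNS", "ACC", "RMS", "osteosarcoma"]


class SimConfigError(ValueError):
    """A SimConfig field is out of range; the message names the field."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the cohort the analysis was designed around: 47
    sequenced families (~84 genomes), methylation cohorts of 88 / 122 /
    142 samples with a 47-sample WGS overlap, per-allele meQTL shift of
    0.1 beta units and a cancer-associated shift of 0.15 beta units.
    """

    n_families: int = 47
    family_size_range: tuple[int, int] = (1, 6)
    frac_tp53_variant: float = 0.74
    frac_cancer_given_variant: float = 0.79
    frac_cancer_given_wildtype: float = 0.35
    # methylation / meQTL structure
    n_probes: int = 2000
    n_cis_snps_per_probe: int = 3
    n_planted_meqtl: int = 40
    n_planted_csce: int = 25
    meqtl_effect: float = 0.10
    cancer_effect: float = 0.15
    noise_sd: float = 0.05
    frac_hypomethylation_risk: float = 0.75
    batch_effect: float = 0.3
    cohort_sizes: tuple[int, int, int] = (88, 122, 142)
    n_overlap: int = 47
    cis_window: int = 10_000
    # small variants
    n_planted_class_variants: tuple[int, int, int, int, int] = (2, 3, 5, 3, 3)
    n_planted_wnt: int = 2
    n_background_variants: int = 25
    # SV / CNV
    n_sv_true: int = 5
    n_sv_fp: int = 3
    sv_jitter_sd: float = 30.0
    n_pon_controls: int = 10
    n_cnv_true: int = 4
    # survival
    censor_rate: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        proportions = [
            "frac_tp53_variant",
            "frac_cancer_given_variant",
            "frac_cancer_given_wildtype",
            "frac_hypomethylation_risk",
            "censor_rate",
        ]
        for name in proportions:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("meqtl_effect", "cancer_effect", "noise_sd"):
            v = getattr(self, name)
            if v < 0 or v > 1:
                raise SimConfigError(f"{name} must be in [0, 1], got {v}")
        counts = [
            "n_families",
            "n_probes",
            "n_cis_snps_per_probe",
            "n_overlap",
            "cis_window",
            "n_background_variants",
            "n_sv_true",
            "n_sv_fp",
            "n_pon_controls",
            "n_cnv_true",
            "n_planted_wnt",
        ]
        for name in counts:
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be non-negative")
        lo, hi = self.family_size_range
        if not (1 <= lo <= hi):
            raise SimConfigError(f"family_size_range must satisfy 1 <= lo <= hi, got {lo, hi}")
        if len(self.n_planted_class_variants) != 5:
            raise SimConfigError("n_planted_class_variants must have 5 entries (classes 1-5)")
        if any(k < 0 for k in self.n_planted_class_variants):
            raise SimConfigError("n_planted_class_variants entries must be non-negative")
        if self.n_planted_meqtl + self.n_planted_csce > self.n_probes:
            raise SimConfigError("n_planted_meqtl + n_planted_csce exceeds n_probes")
        if (self.n_planted_meqtl or self.n_planted_csce) and not self.n_cis_snps_per_probe:
            raise SimConfigError(
                "n_cis_snps_per_probe must be positive when meQTL/CSCE probes are planted"
            )
        if any(s <= 0 for s in self.cohort_sizes):
            raise SimConfigError("cohort_sizes must be positive")
        if self.n_overlap > self.cohort_sizes[0]:
            raise SimConfigError("n_overlap cannot exceed the discovery cohort size")
        if self.sv_jitter_sd < 0:
            raise SimConfigError("sv_jitter_sd must be non-negative")


@dataclass
class SimulatedCohort:
    """Bundle of everything :func:`simulate_cohort` produces."""

    config: SimConfig
    samples: pd.DataFrame  # WGS + methylation sample sheet
    families: list[Family]
    variants: pd.DataFrame
    gene_tiers: pd.DataFrame  # columns gene, tier, provenance
    gene_sets: dict[str, list[str]]
    class4_support: set[str]
    lof_mechanism_genes: set[str]
    sv_callsets: dict[str, pd.DataFrame]
    cnv_callsets: dict[str, pd.DataFrame]
    pon: dict[str, pd.DataFrame]
    exclusion_regions: pd.DataFrame
    methylation: MethylationDataset
    genotypes: GenotypeMatrix
    truth: dict = field(default_factory=dict)

    @property
    def wgs_samples(self) -> list[str]:
        return list(self.samples.loc[self.samples["has_wgs"], "sample_id"])


# ---------------------------------------------------------------------------
# gene universe


def _make_gene_tiers(rng: np.random.Generator) -> pd.DataFrame:
    """Synthetic tiered gene lists with the real tier sizes (60/29/489)."""
    rows = []
    for tier, n, label in [
        (1, 60, "autosomal_dominant_CPG"),
        (2, 29, "autosomal_recessive_CPG"),
        (3, 489, "somatic_cancer_gene"),
        (4, 600, "other_gene"),
    ]:
        for i in range(n):
            rows.append({"gene": f"G{tier}_{i:04d}", "tier": tier, "provenance": label})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# families


def _simulate_samples(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    sid = 0
    lo, hi = cfg.family_size_range
    sizes = np.arange(lo, hi + 1)
    # geometric weighting: most families contribute a single genome, as in
    # real sequencing cohorts where relatives are often unavailable
    weights = 0.45 ** (sizes - lo)
    weights = weights / weights.sum()
    for f in range(cfg.n_families):
        fid = f"F{f + 1:03d}"
        size = int(rng.choice(sizes, p=weights))
        tp53 = "variant" if rng.random() < cfg.frac_tp53_variant else "wildtype"
        ids = [f"S{sid + i + 1:04d}" for i in range(size)]
        sid += size
        father = ids[1] if size >= 2 else None
        mother = ids[2] if size >= 3 else None
        for i, s in enumerate(ids):
            is_proband = i == 0
            is_parent = i in (1, 2)
            if tp53 == "variant":
                carrier = is_proband or rng.random() < 0.5
            else:
                carrier = False
            if is_proband:
                affected = True
            elif carrier:
                affected = rng.random() < cfg.frac_cancer_given_variant
            else:
                affected = rng.random() < cfg.frac_cancer_given_wildtype
            rows.append(
                {
                    "family_id": fid,
                    "sample_id": s,
                    "father": father if (not is_parent and size >= 2 and i != 1) else None,
                    "mother": mother if (not is_parent and size >= 3 and i != 2) else None,
                    "sex": rng.choice(["M", "F"]),
                    "affected": bool(affected),
                    "tp53_status": tp53 if carrier or tp53 == "wildtype" else "wildtype",
                    "onset_age_months": float(rng.uniform(6, 500)) if affected else np.nan,
                    "surv_time": np.nan,
                    "surv_event": 0,
                    "has_wgs": True,
                    "has_methylation": False,
                    "cohort": None,
                }
            )
    df = pd.DataFrame(rows)
    df.loc[df["father"].isna(), "father"] = None
    df.loc[df["mother"].isna(), "mother"] = None
    return df


# ---------------------------------------------------------------------------
# small variants


def _gene_locus(gene: str, rng: np.random.Generator) -> tuple[str, int]:
    chrom = f"chr{int(rng.integers(1, 23))}"
    start = int(rng.integers(1_000_000, 200_000_000))
    return chrom, start

def _passing_qc(rng: np.random.Generator) -> dict:
    return {
        "read_pos_pct": float(rng.uniform(25, 75)),
        "strandedness_pct": float(rng.uniform(25, 75)),
        "dist_to_3prime": float(rng.uniform(30, 120)),
        "homopolymer_len": int(rng.integers(0, 4)),
        "mapq_diff": float(rng.uniform(0, 15)),
        "read_len_diff": float(rng.uniform(0, 12)),
        "mmqs_diff": float(rng.uniform(0, 60)),
        "alt_reads": int(rng.integers(8, 40)),
    }


_QC_FAIL_VALUES = {
    "read_pos_pct": 95.0,
    "strandedness_pct": 0.5,
    "dist_to_3prime": 10.0,
    "homopolymer_len": 7,
    "mapq_diff": 45.0,
    "read_len_diff": 30.0,
    "mmqs_diff": 150.0,
    "alt_reads": 3,
}


def _simulate_variants(
    cfg: SimConfig,
    rng: np.random.Generator,
    samples: pd.DataFrame,
    tiers: pd.DataFrame,
    truth: dict,
) -> tuple[pd.DataFrame, dict[str, list[str]], set[str], set[str]]:
    tier_genes = {t: list(tiers.loc[tiers["tier"] == t, "gene"]) for t in (1, 2, 3, 4)}
    lof_genes = set(tier_genes[1]) | set(tier_genes[2])
    wnt_genes = list(rng.choice(tier_genes[3], size=10, replace=False)) + list(
        rng.choice(tier_genes[4], size=5, replace=False)
    )
    gene_sets = {"WNT_SIGNALING": sorted(wnt_genes)}
    # a few decoy pathway sets over the tier-3/4 universe
    pool = np.array(tier_genes[3] + tier_genes[4])
    for i in range(6):
        gene_sets[f"HALLMARK_SET_{i + 1}"] = sorted(rng.choice(pool, size=40, replace=False))

    loci: dict[str, tuple[str, int]] = {}

    def locus(gene):
        if gene not in loci:
            loci[gene] = _gene_locus(gene, rng)
        return loci[gene]

    rows: list[dict] = []
    var_counter = [0]

    def add_variant(gene, sample_ids, consequence, base_path, afs=None, qc_fail=None):
        chrom, start = locus(gene)
        var_counter[0] += 1
        pos = start + var_counter[0] * 37
        ref = str(rng.choice(_BASES))
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        afs = afs or {}
        for s in sample_ids:
            qc = _passing_qc(rng)
            if qc_fail:
                qc[qc_fail] = _QC_FAIL_VALUES[qc_fail]
            rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "sample_id": s,
                    "gene": gene,
                    "consequence": consequence,
                    "domain": None,
                    "af_gnomad": afs.get("gnomad", np.nan),
                    "af_exac": afs.get("exac", np.nan),
                    "af_1kgp": afs.get("1kgp", np.nan),
                    "base_pathogenicity": base_path,
                    "genotype": "het",
                    "vaf": float(rng.uniform(0.35, 0.6)),
                    **qc,
                }
            )
        return f"{chrom}:{pos}:{ref}:{alt}"

    wgs_ids = list(samples["sample_id"])
    affected = samples.set_index("sample_id")["affected"]
    affected_ids = [s for s in wgs_ids if affected[s]]
    # carriers of planted class variants are distinct samples
    carrier_pool = list(rng.permutation(affected_ids))
    class4_support: set[str] = set()
    truth["class_variants"] = []
    truth["wnt_carriers"] = []

    for cls_index, n_cls in enumerate(cfg.n_planted_class_variants):
        cls = cls_index + 1
        for j in range(n_cls):
            if cls <= 4:
                if not carrier_pool:
                    raise SimConfigError(
                        "n_planted_class_variants exceeds available affected carriers"
                    )
                carriers = [carrier_pool.pop()]
                tier = cls if cls <= 3 else 4
                gene = str(rng.choice(tier_genes[tier]))
                if cls == 4:
                    class4_support.add(gene)
                # one planted record per run exercises the null-variant upgrade
                if cls == 2 and j == 0:
                    consequence, base = "nonsense", "VUS"
                else:
                    consequence = str(rng.choice(["missense", "nonsense", "frameshift_del"]))
                    base = str(rng.choice(["P", "LP"]))
                    if consequence == "missense" and gene in lof_genes and base == "LP":
                        base = "P"  # missense VUS would not upgrade; keep base P/LP explicit
            else:  # class 5: cancer-segregating VUS in a tier 1-3 gene
                fam_sizes = samples.groupby("family_id")["sample_id"].count()
                multi = [
                    f
                    for f in fam_sizes[fam_sizes >= 2].index
                    if affected[samples.loc[samples.family_id == f, "sample_id"]].sum() >= 2
                ]
                if not multi:
                    fid = fam_sizes.idxmax()
                    members = samples.loc[samples.family_id == fid, "sample_id"]
                    samples.loc[samples.sample_id.isin(members.iloc[:2]), "affected"] = True
                    multi = [fid]
                fid = str(rng.choice(multi))
                members = samples.loc[samples.family_id == fid]
                carriers = list(members.loc[members["affected"].astype(bool), "sample_id"])
                gene = str(rng.choice(tier_genes[int(rng.integers(1, 4))]))
                consequence, base = "missense", "VUS"
            key = add_variant(gene, carriers, consequence, base)
            truth["class_variants"].append(
                {
                    "class": cls,
                    "gene": gene,
                    "variant": key,
                    "carriers": list(carriers),
                    "consequence": consequence,
                    "base_pathogenicity": base,
                }
            )

    # protective WNT-pathway P/LP variants in cancer-free variant-TP53 samples
    free_pool = [
        s
        for s in wgs_ids
        if not affected[s]
        and samples.set_index("sample_id").loc[s, "tp53_status"] == "variant"
    ] or [s for s in wgs_ids if not affected[s]]
    for j in range(min(cfg.n_planted_wnt, len(free_pool))):
        carrier = free_pool[j]
        gene = str(rng.choice(gene_sets["WNT_SIGNALING"]))
        key = add_variant(gene, [carrier], "nonsense", "LP")
        truth["wnt_carriers"].append({"gene": gene, "variant": key, "carriers": [carrier]})

    # background variants: benign/common/QC-failing noise
    qc_filters = list(_QC_FAIL_VALUES)
    for s in wgs_ids:
        for _ in range(cfg.n_background_variants):
            gene = str(rng.choice(tier_genes[4] if rng.random() < 0.8 else tier_genes[3]))
            consequence = str(rng.choice(_BG_CONSEQUENCES, p=[0.5, 0.35, 0.05, 0.1]))
            base = str(rng.choice(["B", "LB", "VUS"], p=[0.45, 0.35, 0.2]))
            afs = {}
            if rng.random() < 0.4:  # common in at least one population database
                afs[str(rng.choice(["gnomad", "exac", "1kgp"]))] = float(rng.uniform(0.02, 0.5))
            elif rng.random() < 0.7:
                afs["gnomad"] = float(rng.uniform(0, 0.009))
            qc_fail = str(rng.choice(qc_filters)) if rng.random() < 0.15 else None
            add_variant(gene, [s], consequence, base, afs=afs, qc_fail=qc_fail)

    variants = pd.DataFrame(rows)
    return variants, gene_sets, class4_support, lof_genes


# ---------------------------------------------------------------------------
# SV / CNV


def _simulate_svs(
    cfg: SimConfig, rng: np.random.Generator, wgs_ids: list[str], truth: dict
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    def jitter(x):
        return max(1, int(round(x + rng.normal(0, cfg.sv_jitter_sd))))

    calls_a, calls_b = [], []
    truth["sv_events"] = []
    truth["sv_artifacts"] = []
    artifact_templates = []
    # recurrent technical artifacts shared with the panel of normals
    for i in range(3):
        start = int(rng.integers(5_000_000, 50_000_000))
        artifact_templates.append(
            {"chrom": "chr2", "start": start, "end": start + int(rng.integers(2000, 8000)),
             "svtype": "DEL"}
        )
    for s in wgs_ids:
        for _ in range(cfg.n_sv_true):
            chrom = f"chr{int(rng.integers(1, 23))}"
            length = int(10 ** rng.uniform(2.8, 5.3))
            start = int(rng.integers(1_000_000, 200_000_000))
            svtype = str(rng.choice(["DEL", "DUP", "INV"]))
            ev = {"chrom": chrom, "start": start, "end": start + length, "svtype": svtype,
                  "sample_id": s}
            truth["sv_events"].append(ev)
            score = int(rng.integers(3, 6))
            for calls in (calls_a, calls_b):
                calls.append(
                    {**ev, "start": jitter(start), "end": jitter(start + length),
                     "annot_score": score, "popdb_hit": False}
                )
        # caller-private false positives, far apart by construction
        for calls, offset in ((calls_a, 0), (calls_b, 500_000_000)):
            for _ in range(cfg.n_sv_fp):
                start = int(rng.integers(1_000_000, 200_000_000)) + offset
                calls.append(
                    {"chrom": f"chrFP{int(rng.integers(1, 23))}", "start": start,
                     "end": start + int(10 ** rng.uniform(2.8, 4.5)), "svtype": "DEL",
                     "sample_id": s, "annot_score": int(rng.integers(0, 6)),
                     "popdb_hit": bool(rng.random() < 0.3)}
                )
        # one shared artifact per sample (present in both callers and the PoN)
        art = artifact_templates[int(rng.integers(0, len(artifact_templates)))]
        truth["sv_artifacts"].append({**art, "sample_id": s})
        for calls in (calls_a, calls_b):
            calls.append(
                {**art, "start": jitter(art["start"]), "end": jitter(art["end"]),
                 "sample_id": s, "annot_score": 4, "popdb_hit": False}
            )

    pon = {}
    for c in range(cfg.n_pon_controls):
        ctrl = f"CTRL{c + 1:03d}"
        rows = []
        for art in artifact_templates:
            if c < 5:  # each artifact recurs in >= 3 controls
                rows.append(
                    {**art, "start": jitter(art["start"]), "end": jitter(art["end"]),
                     "sample_id": ctrl, "annot_score": np.nan, "popdb_hit": False}
                )
        for _ in range(4):
            start = int(rng.integers(1_000_000, 200_000_000))
            rows.append(
                {"chrom": f"chr{int(rng.integers(1, 23))}", "start": start,
                 "end": start + int(10 ** rng.uniform(2.8, 4.5)),
                 "svtype": str(rng.choice(["DEL", "DUP", "INV"])), "sample_id": ctrl,
                 "annot_score": np.nan, "popdb_hit": False}
            )
        pon[ctrl] = pd.DataFrame(rows)

    a = pd.DataFrame(calls_a).assign(caller="caller_a")
    b = pd.DataFrame(calls_b).assign(caller="caller_b")
    return {"caller_a": a, "caller_b": b}, pon


def _simulate_cnvs(
    cfg: SimConfig, rng: np.random.Generator, wgs_ids: list[str], truth: dict
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    rows_a, rows_b = [], []
    truth["cnv_events"] = []
    for s in wgs_ids:
        for _ in range(cfg.n_cnv_true):
            chrom = f"chr{int(rng.integers(1, 23))}"
            start = int(rng.integers(1_000_000, 200_000_000))
            length = int(10 ** rng.uniform(3.5, 5.5))
            state = str(rng.choice(["loss", "gain"]))
            truth["cnv_events"].append(
                {"chrom": chrom, "start": start, "end": start + length, "state": state,
                 "sample_id": s}
            )
            pad_a = int(rng.integers(0, length // 10 + 1))
            pad_b = int(rng.integers(0, length // 10 + 1))
            rows_a.append({"chrom": chrom, "start": start - pad_a, "end": start + length,
                           "state": state, "sample_id": s})
            rows_b.append({"chrom": chrom, "start": start, "end": start + length + pad_b,
                           "state": state, "sample_id": s})
        # caller-private calls
        for rows in (rows_a, rows_b):
            start = int(rng.integers(1_000_000, 200_000_000))
            rows.append({"chrom": f"chr{int(rng.integers(1, 23))}", "start": start,
                         "end": start + 5000, "state": "loss", "sample_id": s})
    exclusion = pd.DataFrame(
        {"chrom": [f"chr{c}" for c in range(1, 23)],
         "start": [220_000_000] * 22, "end": [230_000_000] * 22}
    )
    return (
        {"caller_a": pd.DataFrame(rows_a).assign(caller="caller_a"),
         "caller_b": pd.DataFrame(rows_b).assign(caller="caller_b")},
        exclusion,
    )


# ---------------------------------------------------------------------------
# methylation + genotypes


def _simulate_methylation(
    cfg: SimConfig, rng: np.random.Generator, samples: pd.DataFrame, truth: dict
) -> tuple[MethylationDataset, GenotypeMatrix, pd.DataFrame]:
    n_probes = cfg.n_probes
    sizes = cfg.cohort_sizes
    cohorts = ["discovery", "internal", "external"]
    rates = {"discovery": 0.70, "internal": 0.63, "external": 0.60}

    wgs_ids = list(samples["sample_id"])
    overlap = wgs_ids[: cfg.n_overlap]
    affected = samples.set_index("sample_id")["affected"]

    meth_ids, covar_rows = [], []
    m = 0
    for cohort, size in zip(cohorts, sizes):
        ids = []
        if cohort == "discovery":
            ids.extend(overlap)
        while len(ids) < size:
            m += 1
            ids.append(f"M{m:04d}")
        for s in ids:
            cancer = bool(affected[s]) if s in affected.index else bool(
                rng.random() < rates[cohort]
            )
            covar_rows.append(
                {
                    "sample_id": s,
                    "cohort": cohort,
                    "cancer_status": int(cancer),
                    "cancer_type": str(rng.choice(_CANCER_TYPES)) if cancer else "none",
                    "treatment_before_draw": bool(
                        cohort != "discovery" and rng.random() < 0.23
                    ),
                    "age_at_draw": float(rng.uniform(1, 60)),
                    "sex": str(rng.choice(["M", "F"])),
                    "batch": f"{cohort}_b{int(rng.integers(1, 3))}",
                    "array": "450k" if cohort == "discovery" else "EPIC",
                }
            )
        meth_ids.extend(ids)
    covars = pd.DataFrame(covar_rows).set_index("sample_id")
    n_samples = len(meth_ids)

    # probe annotation: probes spaced so cis windows never overlap
    spacing = max(2 * cfg.cis_window + 5000, 25_000)
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    probe_pos = 10_000 + spacing * np.arange(n_probes)
    probe_annot = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": "chr1",
            "pos": probe_pos,
            "gene": [
                f"G3_{int(rng.integers(0, 489)):04d}" if rng.random() < 0.3 else "intergenic"
                for _ in range(n_probes)
            ],
            "region_class": rng.choice(
                ["island", "shore", "shelf", "open_sea"], size=n_probes, p=[0.3, 0.2, 0.1, 0.4]
            ),
            "context": rng.choice(
                ["promoter", "body", "intergenic"], size=n_probes, p=[0.3, 0.4, 0.3]
            ),
        }
    ).set_index("probe_id")

    # cis-SNPs and genotypes (dosages latent for every methylation sample;
    # the exposed matrix is restricted to the WGS-methylation overlap)
    snp_rows, dosage_rows = [], []
    for i, pid in enumerate(probe_ids):
        for k in range(cfg.n_cis_snps_per_probe):
            offset = int(rng.integers(-cfg.cis_window, cfg.cis_window + 1))
            maf = float(rng.uniform(0.1, 0.4))
            snp_rows.append(
                {"snp_id": f"rs_{pid}_{k}", "chrom": "chr1",
                 "pos": int(probe_pos[i]) + offset, "maf": maf, "probe_of_origin": pid}
            )
            dosage_rows.append(rng.binomial(2, maf, size=n_samples))
    snp_annot = (
        pd.DataFrame(snp_rows).set_index("snp_id")
        if snp_rows
        else pd.DataFrame(columns=["chrom", "pos", "maf", "probe_of_origin"],
                          index=pd.Index([], name="snp_id"))
    )
    dosages = pd.DataFrame(
        np.array(dosage_rows) if dosage_rows else np.empty((0, n_samples)),
        index=snp_annot.index, columns=meth_ids,
    )

    # plant meQTL-only probes and CSCE probes (meQTL + cancer effect)
    planted = rng.choice(n_probes, size=cfg.n_planted_meqtl + cfg.n_planted_csce, replace=False)
    meqtl_probes = [probe_ids[i] for i in planted[: cfg.n_planted_meqtl]]
    csce_probes = [probe_ids[i] for i in planted[cfg.n_planted_meqtl:]]
    causal_snp, meqtl_sign, csce_sign = {}, {}, {}
    for pid in meqtl_probes + csce_probes:
        k = int(rng.integers(0, cfg.n_cis_snps_per_probe))
        causal_snp[pid] = f"rs_{pid}_{k}"
        meqtl_sign[pid] = int(rng.choice([-1, 1]))
    for pid in csce_probes:
        csce_sign[pid] = -1 if rng.random() < cfg.frac_hypomethylation_risk else 1

    base = np.where(
        rng.random(n_probes) < 0.6, rng.uniform(0.05, 0.30, n_probes),
        rng.uniform(0.70, 0.95, n_probes),
    )
    pos_of = {p: i for i, p in enumerate(probe_ids)}
    for pid in meqtl_probes + csce_probes:
        base[pos_of[pid]] = rng.uniform(0.35, 0.5)

    cancer = covars["cancer_status"].to_numpy()[None, :]
    mean = np.repeat(base[:, None], n_samples, axis=1)
    for pid in meqtl_probes + csce_probes:
        d = dosages.loc[causal_snp[pid]].to_numpy()
        mean[pos_of[pid]] += meqtl_sign[pid] * cfg.meqtl_effect * d
    for pid in csce_probes:
        mean[pos_of[pid]] += csce_sign[pid] * cfg.cancer_effect * cancer[0]

    mean = np.clip(mean, 0.02, 0.98)
    eta = logit(mean)
    # batch shifts on a fixed 20% of probes, on the logit scale
    batch_mask = rng.random(n_probes) < 0.2
    batch_codes = pd.factorize(covars["batch"])[0]
    eta += np.where(batch_mask[:, None], cfg.batch_effect * (batch_codes % 2)[None, :], 0.0)
    sigma = cfg.noise_sd / np.clip(base * (1 - base), 0.05, None)
    eta += rng.normal(0, 1, size=(n_probes, n_samples)) * sigma[:, None]
    beta = np.clip(expit(eta), 1e-6, 1 - 1e-6)

    ds = MethylationDataset(
        beta=pd.DataFrame(beta, index=probe_ids, columns=meth_ids),
        probe_annot=probe_annot,
        sample_covariates=covars,
    )
    geno = GenotypeMatrix(
        genotypes=dosages[overlap].astype(float),
        snp_annot=snp_annot.drop(columns=["maf", "probe_of_origin"]),
    )
    truth["meqtl_probes"] = meqtl_probes
    truth["csce_probes"] = csce_probes
    truth["causal_snp"] = causal_snp
    truth["meqtl_sign"] = meqtl_sign
    truth["csce_sign"] = csce_sign
    truth["overlap_samples"] = overlap

    meth_flags = samples["sample_id"].isin(overlap)
    samples = samples.copy()
    samples.loc[meth_flags, "has_methylation"] = True
    samples.loc[meth_flags, "cohort"] = "discovery"
    extra = covars.loc[~covars.index.isin(samples["sample_id"])]
    extra_rows = pd.DataFrame(
        {
            "family_id": [f"FM{i:04d}" for i in range(len(extra))],
            "sample_id": extra.index,
            "father": None,
            "mother": None,
            "sex": extra["sex"].to_numpy(),
            "affected": extra["cancer_status"].astype(bool).to_numpy(),
            "tp53_status": "variant",
            "onset_age_months": np.nan,
            "surv_time": np.nan,
            "surv_event": 0,
            "has_wgs": False,
            "has_methylation": True,
            "cohort": extra["cohort"].to_numpy(),
        }
    )
    samples = pd.concat([samples, extra_rows], ignore_index=True)
    return ds, geno, samples


# ---------------------------------------------------------------------------
# survival


def _simulate_survival(
    cfg: SimConfig, rng: np.random.Generator, samples: pd.DataFrame, truth: dict
) -> pd.DataFrame:
    class13_carriers = {
        c
        for v in truth["class_variants"]
        if v["class"] <= 3
        for c in v["carriers"]
    }
    wnt_carriers = {c for v in truth["wnt_carriers"] for c in v["carriers"]}
    base_rate = 1.0 / 150.0  # months^-1
    mult = np.ones(len(samples))
    ids = samples["sample_id"].to_numpy()
    mult[np.isin(ids, list(class13_carriers))] = 2.0
    mult[np.isin(ids, list(wnt_carriers))] = 0.5
    t = rng.exponential(1.0 / (base_rate * mult))
    censored = rng.random(len(samples)) < cfg.censor_rate
    obs = np.where(censored, t * rng.random(len(samples)), t)
    samples = samples.copy()
    samples["surv_time"] = np.round(obs, 2)
    samples["surv_event"] = (~censored).astype(int)
    truth["risk_multiplier"] = dict(zip(ids, mult[: len(ids)].tolist()))
    return samples


# ---------------------------------------------------------------------------


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort; see the module docstring.

    Returns a :class:`SimulatedCohort` whose ``truth`` ledger lists every
    planted meQTL probe, CSCE probe (with its causal SNP and effect
    signs), class-1..5 variant with its carriers, WNT-pathway protective
    carriers, true SV/CNV events and PoN artifacts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth: dict = {"seed": config.seed}

    tiers = _make_gene_tiers(rng)
    samples = _simulate_samples(config, rng)
    variants, gene_sets, class4_support, lof_genes = _simulate_variants(
        config, rng, samples, tiers, truth
    )
    sv_callsets, pon = _simulate_svs(config, rng, list(samples["sample_id"]), truth)
    cnv_callsets, exclusion = _simulate_cnvs(config, rng, list(samples["sample_id"]), truth)
    methylation, genotypes, samples = _simulate_methylation(config, rng, samples, truth)
    samples = _simulate_survival(config, rng, samples, truth)

    wgs = samples.loc[samples["has_wgs"], SAMPLE_COLUMNS + ["has_wgs"]]
    families = families_from_samples(wgs)
    return SimulatedCohort(
        config=config,
        samples=samples,
        families=families,
        variants=variants,
        gene_tiers=tiers,
        gene_sets=gene_sets,
        class4_support=class4_support,
        lof_mechanism_genes=lof_genes,
        sv_callsets=sv_callsets,
        cnv_callsets=cnv_callsets,
        pon=pon,
        exclusion_regions=exclusion,
        methylation=methylation,
        genotypes=genotypes,
        truth=truth,
    )


def config_to_dict(config: SimConfig) -> dict:
    return dataclasses.asdict(config)
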