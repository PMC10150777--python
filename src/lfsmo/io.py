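"""Readers and writers for the interchange formats.

Coordinate conventions: variants and SV/CNV tables are 1-based inclusive
(VCF convention) in memory; BED files on disk are 0-based half-open and
converted at this boundary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import SAMPLE_COLUMNS, families_from_samples

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_ped",
    "read_ped",
    "read_gene_tiers",
    "read_gmt",
    "write_gmt",
    "read_bed",
    "write_bed",
    "read_matrix",
    "write_matrix",
    "write_cohort",
    "sha256_of",
]

ANNOT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "sample_id", "gene", "consequence", "domain",
    "af_gnomad", "af_exac", "af_1kgp", "base_pathogenicity", "vaf",
    "read_pos_pct", "strandedness_pct", "dist_to_3prime", "homopolymer_len",
    "mapq_diff", "read_len_diff", "mmqs_diff", "alt_reads",
]


# ---------------------------------------------------------------------------
# VCF + annotation sidecar


def write_vcf(variants: pd.DataFrame, path, annot_path=None) -> None:
    """Write a per-sample variant table as a multi-sample VCF v4.2.

    One VCF line per unique (chrom, pos, ref, alt); carriers get GT 0/1
    (het), 1/1 (hom_alt) or 1 (hemi), everyone else 0/0.  Annotation and
    QC fields go to a sidecar TSV (``annot_path``) keyed by
    (chrom, pos, ref, alt, sample_id).
    """
    path = Path(path)
    samples = sorted(variants["sample_id"].unique())
    gt_map = {"het": "0/1", "hom_alt": "1/1", "hemi": "1"}
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]

    def chrom_key(c):
        c = str(c).removeprefix("chr")
        return (0, int(c)) if c.isdigit() else (1, c)

    for chrom in sorted(variants["chrom"].unique(), key=chrom_key):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    grouped = variants.groupby(["chrom", "pos", "ref", "alt"], sort=False)
    keys = sorted(grouped.groups, key=lambda k: (chrom_key(k[0]), k[1], k[2], k[3]))
    for key in keys:
        chrom, pos, ref, alt = key
        grp = grouped.get_group(key)
        gts = dict(zip(grp["sample_id"], grp.get("genotype", "het")))
        cols = [gt_map.get(gts.get(s), "0/0") if s in gts else "0/0" for s in samples]
        lines.append(
            f"{chrom}\t{int(pos)}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(cols)
        )
    path.write_text("\n".join(lines) + "\n")
    if annot_path is not None:
        cols = [c for c in ANNOT_COLUMNS if c in variants.columns]
        variants[cols].to_csv(annot_path, sep="\t", index=False)


def read_vcf(path, annot_path=None) -> pd.DataFrame:
    """Read a VCF into a per-sample-allele variant table.

    Multi-allelic sites decompose into one record per alternate allele;
    coordinates stay 1-based.  A sidecar annotation TSV, when given, is
    joined on (chrom, pos, ref, alt, sample_id).
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        if "GT" not in vcf.header.formats:
            raise ValueError("VCF has no GT format field")
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            alts = rec.alts or ()
            for ai, alt in enumerate(alts, start=1):
                for sample in rec.samples:
                    gt = rec.samples[sample].get("GT")
                    if gt is None or all(g is None for g in gt):
                        continue
                    calls = [g for g in gt if g is not None]
                    n_alt = sum(1 for g in calls if g == ai)
                    if n_alt == 0:
                        continue
                    if len(calls) == 1:
                        genotype = "hemi"
                    elif n_alt == len(calls):
                        genotype = "hom_alt"
                    else:
                        genotype = "het"
                    rows.append(
                        {"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
                         "alt": alt, "sample_id": sample, "genotype": genotype}
                    )
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "sample_id", "genotype"])
    if annot_path is not None:
        annot = pd.read_csv(annot_path, sep="\t")
        df = df.merge(annot, on=["chrom", "pos", "ref", "alt", "sample_id"], how="left")
    return df


# ---------------------------------------------------------------------------
# PED-like sample sheet


def write_ped(samples: pd.DataFrame, path) -> None:
    cols = [c for c in SAMPLE_COLUMNS + ["has_wgs", "has_methylation", "cohort"]
            if c in samples.columns]
    out = samples[cols].copy()
    for c in ("father", "mother"):
        out[c] = out[c].fillna("0")
    out.to_csv(path, sep="\t", index=False)


def read_ped(path):
    """Read a PED-like sample sheet; returns (samples, families)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "family_id": str,
                                            "father": str, "mother": str})
    required = {"family_id", "sample_id", "affected"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    for c in ("father", "mother"):
        if c in df:
            df[c] = df[c].replace({"0": None, "nan": None})
        else:
            df[c] = None
    df["affected"] = df["affected"].astype(bool)
    families = families_from_samples(df)
    return df, families


# ---------------------------------------------------------------------------
# gene lists / sets


def read_gene_tiers(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"gene {dup!r} assigned to more than one tier")
    return df


def read_gmt(path) -> dict[str, list[str]]:
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = parts[2:]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    lines = [f"{name}\tna\t" + "\t".join(genes) for name, genes in gene_sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED (0-based half-open on disk <-> 1-based inclusive in memory)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError("BED needs >= 3 columns")
    out = df.iloc[:, :3].copy()
    out.columns = ["chrom", "start", "end"]
    out["start"] = out["start"].astype(int) + 1
    out["end"] = out["end"].astype(int)
    if (out["end"] < out["start"] - 1).any():
        raise ValueError("malformed BED interval")
    return out


def write_bed(intervals: pd.DataFrame, path, extra_cols: list[str] | None = None) -> None:
    out = intervals.copy()
    out["start"] = out["start"].astype(int) - 1
    cols = ["chrom", "start", "end"] + (extra_cols or [])
    out[cols].to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# matrices


def write_matrix(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# cohort bundle


def write_cohort(cohort, outdir) -> dict[str, str]:
    """Serialize a SimulatedCohort to plain-text files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def p(name):
        paths[name] = str(outdir / name)
        return outdir / name

    write_vcf(cohort.variants, p("variants.vcf"), p("variants_annot.tsv"))
    write_ped(cohort.samples, p("samples.ped.tsv"))
    cohort.gene_tiers.to_csv(p("gene_tiers.tsv"), sep="\t", index=False)
    write_gmt(cohort.gene_sets, p("gene_sets.gmt"))
    for caller, df in cohort.sv_callsets.items():
        df.to_csv(p(f"sv_{caller}.tsv"), sep="\t", index=False)
    for caller, df in cohort.cnv_callsets.items():
        df.to_csv(p(f"cnv_{caller}.tsv"), sep="\t", index=False)
    pon_dir = outdir / "pon"
    pon_dir.mkdir(exist_ok=True)
    for ctrl, df in cohort.pon.items():
        df.to_csv(pon_dir / f"{ctrl}.tsv", sep="\t", index=False)
    paths["pon"] = str(pon_dir)
    write_bed(cohort.exclusion_regions, p("exclusion.bed"))
    write_matrix(cohort.methylation.beta, p("beta.tsv"), index_label="probe_id")
    cohort.methylation.probe_annot.to_csv(p("probe_annot.tsv"), sep="\t")
    cohort.methylation.sample_covariates.to_csv(p("sample_covariates.tsv"), sep="\t")
    geno = cohort.genotypes.snp_annot.join(cohort.genotypes.genotypes)
    geno.to_csv(p("genotypes.tsv"), sep="\t")
    with open(p("class4_support.txt"), "w") as fh:
        fh.write("\n".join(sorted(cohort.class4_support)) + "\n")
    with open(p("truth.json"), "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True, default=_jsonify)
    with open(p("sim_config.json"), "w") as fh:
        json.dump(dataclasses.asdict(cohort.config), fh, indent=1)
    return paths


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (set, tuple)):
        return sorted(x) if isinstance(x, set) else list(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
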