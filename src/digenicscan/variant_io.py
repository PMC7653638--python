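"""Readers and writers for the formats the pipeline touches.

VCF is read through cyvcf2 and normalized: multiallelic sites are split
into one biallelic record per alternate allele, with each sample's genotype
recoded as the dosage of that focal allele (other alternates count as
reference — downstream logic is carrier/non-carrier). Phase separators are
accepted but phase is discarded; origin is always re-derived by
transmission. The simulator's VCF writer lives here too and emits a fixed,
date-free header so identical runs are byte-identical.
"""
from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from cyvcf2 import VCF

from .classify import PREDICTORS, AnnotationProfile
from .digenic import CandidatePair
from .records import (
    MISSING,
    GeneSetCollection,
    GenotypeTable,
    InputError,
    ParseError,
    Pedigree,
    PedigreeMember,
    ValidationError,
    VariantRecord,
)

# annotation TSV <-> predictor-name mapping (column order is the file contract)
ANNOTATION_COLUMNS = (
    "variant_id",
    "gene",
    "region_class",
    "af_global",
    "af_popmax",
    "cadd_phred",
    "sift_score",
    "polyphen2_score",
    "lrt_pred",
    "mutationtaster_pred",
    "gerp_rs",
    "phylop_score",
)
_PREDICTOR_COLUMNS = {
    "CADD": "cadd_phred",
    "SIFT": "sift_score",
    "PolyPhen2": "polyphen2_score",
    "LRT": "lrt_pred",
    "MutationTaster": "mutationtaster_pred",
    "GERP++": "gerp_rs",
    "PhyloP": "phylop_score",
}
_CATEGORICAL_COLUMNS = {"lrt_pred", "mutationtaster_pred"}

REPORT_COLUMNS = (
    "rank",
    "gene_a",
    "variant_a",
    "origin_a",
    "gene_b",
    "variant_b",
    "origin_b",
    "shared_affected_count",
    "genesets",
    "score",
)


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], GenotypeTable]:
    """Read a multi-sample VCF into normalized biallelic records.

    Multiallelic sites become one record per alternate allele with genotypes
    recoded against that allele; record order is preserved. A genotype with
    any missing allele maps to MISSING. Gene and region class are taken
    from the GENE / REGION INFO keys when present (a side annotation table
    overrides them downstream). Parse failures name the failing record
    index (underlying readers do not expose file line numbers).
    """
    path = str(path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise InputError(f"VCF {path} has no sample columns")
    records: list[VariantRecord] = []
    rows: list[list[int]] = []
    seen: set[str] = set()
    try:
        for idx, site in enumerate(vcf):
            alts = site.ALT or []
            if not alts:
                continue
            genotypes = site.genotypes  # [[a0, a1, phased], ...]
            for alt_index, alt in enumerate(alts, start=1):
                rec = VariantRecord(
                    chrom=site.CHROM,
                    pos=site.POS,
                    ref=site.REF,
                    alt=alt,
                    gene=site.INFO.get("GENE") or "",
                    region_class=site.INFO.get("REGION") or "other",
                )
                if rec.variant_id in seen:
                    raise ParseError(
                        f"duplicate variant {rec.variant_id} at record {idx} of {path}"
                    )
                seen.add(rec.variant_id)
                row = []
                for gt in genotypes:
                    alleles = [a for a in gt[:-1]]  # last entry is the phase flag
                    if any(a < 0 for a in alleles) or not alleles:
                        row.append(MISSING)
                    else:
                        row.append(sum(1 for a in alleles if a == alt_index))
                records.append(rec)
                rows.append(row)
    except (ParseError, ValidationError):
        raise
    except Exception as exc:
        raise ParseError(
            f"malformed VCF record ~#{len(records)} in {path}: {exc}"
        ) from exc
    matrix = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    return records, GenotypeTable([r.variant_id for r in records], samples, matrix)


def write_vcf(
    path: str | Path,
    records: Sequence[VariantRecord],
    genotypes: GenotypeTable,
) -> None:
    """Write biallelic records as VCF v4.2 with a fixed, date-free header."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    lines = [
        "##fileformat=VCFv4.2",
        "##source=digenicscan",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=REGION,Number=1,Type=String,Description="Region class">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    chroms = []
    for r in records:
        if r.chrom not in chroms:
            chroms.append(r.chrom)
    for c in chroms:
        lines.append(f"##contig=<ID={c}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(genotypes.sample_ids)
    )
    for rec in records:
        info = f"GENE={rec.gene};REGION={rec.region_class}" if rec.gene else f"REGION={rec.region_class}"
        gts = "\t".join(gt_strings[int(g)] for g in genotypes.row(rec.variant_id))
        lines.append(
            f"{rec.chrom}\t{rec.pos}\t{rec.variant_id}\t{rec.ref}\t{rec.alt}"
            f"\t.\tPASS\t{info}\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a 6-column PED file (0 = missing parent, phenotype 2 = affected)."""
    members = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(
                    f"{path}:{lineno}: PED needs 6 columns, got {len(fields)}"
                )
            _family, sid, father, mother, sex, phenotype = fields[:6]
            try:
                sex_code = int(sex)
            except ValueError:
                sex_code = 0
            members.append(
                PedigreeMember(
                    sample_id=sid,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=sex_code,
                    affected=phenotype == "2",
                )
            )
    return Pedigree(members)


def write_pedigree(path: str | Path, ped: Pedigree, family_id: str = "FAM1") -> None:
    lines = [
        "\t".join(
            (
                family_id,
                m.sample_id,
                m.father_id or "0",
                m.mother_id or "0",
                str(m.sex),
                "2" if m.affected else "1",
            )
        )
        for m in ped.members
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_geneset(path: str | Path) -> GeneSetCollection:
    """Read GMT: one set per line — name, description, then gene symbols."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = frozenset(g for g in fields[2:] if g)
            sets[name] = genes
    return GeneSetCollection(sets)


def write_geneset(path: str | Path, sets: GeneSetCollection) -> None:
    lines = [
        name + "\tna\t" + "\t".join(sorted(genes))
        for name, genes in sorted(sets.sets.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return "" if math.isnan(value) else repr(value)
    return str(value)


def read_annotations(
    path: str | Path,
) -> tuple[dict[str, AnnotationProfile], dict[str, str], dict[str, str]]:
    """Read the annotation TSV.

    Returns (profiles by variant_id, gene by variant_id, region_class by
    variant_id). Empty cells are missing values.
    """
    profiles: dict[str, AnnotationProfile] = {}
    genes: dict[str, str] = {}
    regions: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing_cols = set(ANNOTATION_COLUMNS) - set(reader.fieldnames or ())
        if missing_cols:
            raise ParseError(
                f"{path}: annotation TSV missing column(s) {sorted(missing_cols)}"
            )
        for lineno, row in enumerate(reader, start=2):
            vid = row["variant_id"]
            if vid in profiles:
                raise ParseError(f"{path}:{lineno}: duplicate variant_id {vid!r}")
            values = {}
            for predictor, column in _PREDICTOR_COLUMNS.items():
                cell = row[column].strip()
                if cell == "":
                    continue
                values[predictor] = cell if column in _CATEGORICAL_COLUMNS else float(cell)
            try:
                profiles[vid] = AnnotationProfile(
                    variant_id=vid,
                    af_global=float(row["af_global"]) if row["af_global"].strip() else None,
                    af_popmax=float(row["af_popmax"]) if row["af_popmax"].strip() else None,
                    predictor_values=values,
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            genes[vid] = row["gene"]
            regions[vid] = row["region_class"]
    return profiles, genes, regions


def write_annotations(
    path: str | Path,
    records: Sequence[VariantRecord],
    profiles: Mapping[str, AnnotationProfile],
) -> None:
    lines = ["\t".join(ANNOTATION_COLUMNS)]
    for rec in records:
        p = profiles[rec.variant_id]
        cells = [
            rec.variant_id,
            rec.gene,
            rec.region_class,
            _cell(p.af_global),
            _cell(p.af_popmax),
        ]
        for predictor in PREDICTORS:
            cells.append(_cell(p.predictor_values.get(predictor)))
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def _pair_row(rank: int, p: CandidatePair) -> dict:
    return {
        "rank": rank,
        "gene_a": p.gene_a,
        "variant_a": p.variant_a,
        "origin_a": p.origin_a,
        "gene_b": p.gene_b,
        "variant_b": p.variant_b,
        "origin_b": p.origin_b,
        "shared_affected_count": len(p.shared_affected),
        "genesets": ";".join(p.genesets),
        "score": p.score,
    }


def write_report(
    pairs: Sequence[CandidatePair], path: str | Path, format: str = "tsv"
) -> None:
    """Write ranked candidate pairs as TSV (fixed column order) or JSON."""
    if format == "tsv":
        lines = ["\t".join(REPORT_COLUMNS)]
        for rank, p in enumerate(pairs, start=1):
            row = _pair_row(rank, p)
            lines.append("\t".join(_cell(row[c]) for c in REPORT_COLUMNS))
        Path(path).write_text("\n".join(lines) + "\n")
    elif format == "json":
        payload = [
            {**_pair_row(rank, p), "shared_affected": sorted(p.shared_affected)}
            for rank, p in enumerate(pairs, start=1)
        ]
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> list[CandidatePair]:
    """Re-read a report (TSV or JSON by extension) into CandidatePair objects."""
    path = Path(path)
    pairs = []
    if path.suffix == ".json":
        for row in json.loads(path.read_text()):
            pairs.append(
                CandidatePair(
                    variant_a=row["variant_a"],
                    variant_b=row["variant_b"],
                    gene_a=row["gene_a"],
                    gene_b=row["gene_b"],
                    shared_affected=frozenset(row["shared_affected"]),
                    genesets=tuple(row["genesets"].split(";")) if row["genesets"] else (),
                    score=float(row["score"]),
                )
            )
    else:
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                pairs.append(
                    CandidatePair(
                        variant_a=row["variant_a"],
                        variant_b=row["variant_b"],
                        gene_a=row["gene_a"],
                        gene_b=row["gene_b"],
                        # TSV stores only the count; keep a non-empty sentinel set
                        shared_affected=frozenset(
                            f"affected_{i}" for i in range(int(row["shared_affected_count"]))
                        ),
                        genesets=tuple(row["genesets"].split(";")) if row["genesets"] else (),
                        score=float(row["score"]),
                    )
                )
    return pairs
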