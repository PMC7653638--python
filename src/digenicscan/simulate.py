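"""Synthetic family-exome generator with a planted trans digenic pair.

The generator emulates the data the segregation scan expects but cannot
obtain: a two-parent / two-affected-children quartet, thousands of unlinked
background coding variants whose population allele frequencies follow a
rare-skewed Beta(0.2, 6) spectrum truncated to [1e-5, 0.5], Mendelian
transmission from founder genotypes drawn in Hardy-Weinberg proportions,
seven noisy in-silico predictor annotations, and one planted causal pair:
a rare deleterious variant carried het by the mother and a second one in a
different gene of the same pathway carried het by the father, with both
affected children inheriting both (trans configuration). Affection status
is fully penetrant for double carriers; carrier parents are labeled
unaffected. Identical configurations (including seed) produce
byte-identical output files.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .classify import PREDICTORS, AnnotationProfile
from .digenic import CandidatePair
from .records import (
    MISSING,
    ConfigError,
    GeneSetCollection,
    GenotypeTable,
    Pedigree,
    ValidationError,
    VariantRecord,
    quartet_pedigree,
)

_BASES = ("A", "C", "G", "T")

# raw-score sampling windows per predictor, clear of the default cutoffs
_SCORE_WINDOWS = {
    "CADD": ((20.5, 45.0), (0.0, 15.0)),
    "SIFT": ((0.0, 0.04), (0.10, 1.0)),
    "PolyPhen2": ((0.50, 1.0), (0.0, 0.40)),
    "GERP++": ((2.2, 6.0), (-3.0, 1.5)),
    "PhyloP": ((1.7, 7.0), (-2.0, 1.2)),
}
_CATEGORICAL_CALLS = {
    "LRT": (("D",), ("N", "U")),
    "MutationTaster": (("A", "D"), ("N", "P")),
}


@dataclass
class SimConfig:
    """Generator parameters; defaults are the study-like conditions."""

    n_background: int = 5000
    af_alpha: float = 0.2
    af_beta: float = 6.0
    af_min: float = 1e-5
    af_max: float = 0.5
    p_predictor_sensitivity: float = 0.9
    p_predictor_false_damaging: float = 0.1
    p_missing_call: float = 0.05
    genotype_error_rate: float = 0.0
    seed: int = 0
    n_genes: int = 1000
    pathway_size: int = 20
    pathway_name: str = "INSULIN_IGF1_PATHWAY"
    exonic_frac: float = 0.85
    splicing_frac: float = 0.05
    planted_af_max: float = 0.002
    n_transmission_violations: int = 0
    plant_pair: bool = True
    pedigree: Pedigree = field(default_factory=quartet_pedigree)

    def __post_init__(self) -> None:
        for name in (
            "p_predictor_sensitivity",
            "p_predictor_false_damaging",
            "p_missing_call",
            "genotype_error_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_background < 0:
            raise ConfigError("n_background must be >= 0")
        if self.af_alpha <= 0 or self.af_beta <= 0:
            raise ConfigError("Beta spectrum parameters must be positive")
        if not (0 <= self.af_min <= self.af_max <= 1):
            raise ConfigError("need 0 <= af_min <= af_max <= 1")
        if self.exonic_frac + self.splicing_frac > 1.0 + 1e-12:
            raise ConfigError("exonic_frac + splicing_frac must be <= 1")
        if self.n_genes < 2:
            raise ConfigError("need at least 2 genes")
        if self.pathway_size < 2 or self.pathway_size > self.n_genes:
            raise ConfigError("pathway_size must be in [2, n_genes]")


@dataclass
class SimTruth:
    """What the generator planted, for recovery scoring."""

    maternal_variant: str | None
    paternal_variant: str | None
    maternal_gene: str | None
    paternal_gene: str | None
    planted_afs: dict[str, float] = field(default_factory=dict)
    true_afs: dict[str, float] = field(default_factory=dict)
    transmission_violations: list[str] = field(default_factory=list)

    @property
    def gene_pair(self) -> frozenset[str] | None:
        if self.maternal_gene is None:
            return None
        return frozenset({self.maternal_gene, self.paternal_gene})

    def to_json(self) -> str:
        payload = {
            "maternal_variant": self.maternal_variant,
            "paternal_variant": self.paternal_variant,
            "maternal_gene": self.maternal_gene,
            "paternal_gene": self.paternal_gene,
            "planted_afs": self.planted_afs,
            "transmission_violations": self.transmission_violations,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        return cls(
            maternal_variant=d["maternal_variant"],
            paternal_variant=d["paternal_variant"],
            maternal_gene=d["maternal_gene"],
            paternal_gene=d["paternal_gene"],
            planted_afs=d.get("planted_afs", {}),
            transmission_violations=d.get("transmission_violations", []),
        )


@dataclass
class SimCohort:
    """Everything one simulated family run produces."""

    records: list[VariantRecord]
    genotypes: GenotypeTable
    profiles: dict[str, AnnotationProfile]
    pedigree: Pedigree
    genesets: GeneSetCollection
    truth: SimTruth
    config: SimConfig


def _gene_catalog(cfg: SimConfig) -> list[str]:
    return [f"GENE{i:04d}" for i in range(cfg.n_genes)]


def _gene_locus(gene_index: int) -> tuple[str, int]:
    """Deterministic chromosome and base position for a synthetic gene."""
    chrom = str(gene_index % 22 + 1)
    base = (gene_index // 22 + 1) * 100_000
    return chrom, base


def sample_af_spectrum(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Rare-skewed Beta allele frequencies, rejection-truncated to the window.

    A degenerate window (af_min == af_max) short-circuits to that constant,
    so fixed-frequency configurations are expressible.
    """
    if cfg.af_min == cfg.af_max:
        return np.full(n, cfg.af_min)
    afs = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        draw = rng.beta(cfg.af_alpha, cfg.af_beta, size=todo.size)
        ok = (draw >= cfg.af_min) & (draw <= cfg.af_max)
        afs[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return afs


def _make_records(
    cfg: SimConfig,
    rng: np.random.Generator,
    gene_indices: np.ndarray,
    regions: Sequence[str],
    gene_variant_counter: dict[int, int],
    catalog: list[str],
) -> list[VariantRecord]:
    records = []
    for gi, region in zip(gene_indices, regions):
        gi = int(gi)
        chrom, base = _gene_locus(gi)
        offset = gene_variant_counter.get(gi, 0)
        gene_variant_counter[gi] = offset + 1
        ref_i = int(rng.integers(4))
        alt_i = (ref_i + int(rng.integers(1, 4))) % 4
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=base + offset * 50 + 1,
                ref=_BASES[ref_i],
                alt=_BASES[alt_i],
                gene=catalog[gi],
                region_class=region,
            )
        )
    return records


def simulate_founders(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[VariantRecord], dict[str, np.ndarray], np.ndarray]:
    """Background variants with founder genotypes in Hardy-Weinberg proportions.

    Returns (records, founder genotype arrays keyed by sample id, true AFs);
    each founder genotype is the sum of two Bernoulli(AF) alleles.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    catalog = _gene_catalog(cfg)
    n = cfg.n_background
    afs = sample_af_spectrum(cfg, rng, n)
    gene_indices = rng.integers(0, cfg.n_genes, size=n)
    other_frac = 1.0 - cfg.exonic_frac - cfg.splicing_frac
    regions = rng.choice(
        ["exonic", "splicing", "other"],
        size=n,
        p=[cfg.exonic_frac, cfg.splicing_frac, max(other_frac, 0.0)],
    )
    counter: dict[int, int] = {}
    records = _make_records(cfg, rng, gene_indices, regions, counter, catalog)
    founder_gts = {
        f.sample_id: rng.binomial(2, afs).astype(np.int8)
        for f in cfg.pedigree.founders()
    }
    return records, founder_gts, afs


def transmit(
    ped: Pedigree,
    founder_genotypes: dict[str, np.ndarray],
    records: Sequence[VariantRecord],
    rng: np.random.Generator,
) -> GenotypeTable:
    """Mendelian transmission: each non-founder draws one allele per parent,
    uniformly from that parent's two alleles, independently across variants."""
    n = len(records)
    codes: dict[str, np.ndarray] = {}
    for sid, g in founder_genotypes.items():
        if len(g) != n:
            raise ValidationError("founder genotypes do not match record count")
        codes[sid] = np.asarray(g, dtype=np.int8)
    pending = [m for m in ped.members if m.sample_id not in codes]
    while pending:
        progressed = False
        remaining = []
        for m in pending:
            if m.father_id is None or m.mother_id is None:
                raise ValidationError(
                    f"non-founder {m.sample_id} needs both parents for transmission"
                )
            if m.father_id in codes and m.mother_id in codes:
                pf = codes[m.father_id] / 2.0  # P(transmit alt) = dosage / 2
                pm = codes[m.mother_id] / 2.0
                codes[m.sample_id] = (
                    rng.binomial(1, pf) + rng.binomial(1, pm)
                ).astype(np.int8)
                progressed = True
            else:
                remaining.append(m)
        if not progressed:
            raise ValidationError("pedigree transmission order cannot be resolved")
        pending = remaining
    sample_ids = ped.sample_ids
    matrix = np.stack([codes[s] for s in sample_ids], axis=1) if n else np.empty(
        (0, len(sample_ids)), dtype=np.int8
    )
    return GenotypeTable([r.variant_id for r in records], sample_ids, matrix)


def plant_digenic(
    records: list[VariantRecord],
    genotypes: GenotypeTable,
    ped: Pedigree,
    cfg: SimConfig,
    rng: np.random.Generator,
    pathway_genes: Sequence[str],
) -> tuple[list[VariantRecord], GenotypeTable, SimTruth]:
    """Add the causal trans pair: one rare het variant per parent, in two
    distinct pathway genes, inherited by every affected child; unaffected
    children carry at most one of the two."""
    if len(pathway_genes) < 2:
        raise ConfigError("plant_digenic needs a gene set with >= 2 genes")
    affected = [m.sample_id for m in ped.affected()]
    if not affected:
        raise ConfigError("plant_digenic needs >= 1 affected child")
    founders = ped.founders()
    mothers = [f for f in founders if f.sex == 2]
    fathers = [f for f in founders if f.sex == 1]
    if not mothers or not fathers:
        raise ConfigError("plant_digenic needs a mother and a father founder")
    mother, father = mothers[0].sample_id, fathers[0].sample_id

    catalog = _gene_catalog(cfg)
    gene_index = {g: i for i, g in enumerate(catalog)}
    gene_a, gene_b = [str(g) for g in rng.choice(pathway_genes, size=2, replace=False)]
    planted_afs = rng.uniform(cfg.af_min, cfg.planted_af_max, size=2)

    counter: dict[int, int] = {}
    for r in records:  # continue position numbering within each gene
        gi = gene_index.get(r.gene)
        if gi is not None:
            counter[gi] = counter.get(gi, 0) + 1
    planted_records = _make_records(
        cfg,
        rng,
        np.array([gene_index[gene_a], gene_index[gene_b]]),
        ["exonic", "exonic"],
        counter,
        catalog,
    )
    rec_a, rec_b = planted_records

    sample_ids = genotypes.sample_ids
    col = {s: j for j, s in enumerate(sample_ids)}
    new_rows = np.zeros((2, len(sample_ids)), dtype=np.int8)
    new_rows[0, col[mother]] = 1  # maternal variant: mother het, father hom-ref
    new_rows[1, col[father]] = 1
    for child in affected:
        new_rows[0, col[child]] = 1
        new_rows[1, col[child]] = 1
    unaffected_children = [
        m.sample_id for m in ped.nonfounders() if not m.affected
    ]
    for child in unaffected_children:
        inherit = rng.integers(2, size=2)  # independent 50/50 from each carrier
        if inherit.sum() == 2:
            inherit[int(rng.integers(2))] = 0  # at most one of the pair
        new_rows[0, col[child]] = inherit[0]
        new_rows[1, col[child]] = inherit[1]

    all_records = list(records) + planted_records
    matrix = np.vstack([genotypes.matrix, new_rows])
    table = GenotypeTable([r.variant_id for r in all_records], sample_ids, matrix)
    truth = SimTruth(
        maternal_variant=rec_a.variant_id,
        paternal_variant=rec_b.variant_id,
        maternal_gene=gene_a,
        paternal_gene=gene_b,
        planted_afs={
            rec_a.variant_id: float(planted_afs[0]),
            rec_b.variant_id: float(planted_afs[1]),
        },
    )
    return all_records, table, truth


def inject_transmission_violations(
    records: Sequence[VariantRecord],
    genotypes: GenotypeTable,
    ped: Pedigree,
    truth: SimTruth,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> GenotypeTable:
    """Force ``n_transmission_violations`` background variants into a de novo
    configuration (all affected children het, both parents hom-ref)."""
    if cfg.n_transmission_violations == 0:
        return genotypes
    planted = {truth.maternal_variant, truth.paternal_variant}
    eligible = [i for i, r in enumerate(records) if r.variant_id not in planted]
    chosen = rng.choice(eligible, size=cfg.n_transmission_violations, replace=False)
    matrix = genotypes.matrix.copy()
    col = {s: j for j, s in enumerate(genotypes.sample_ids)}
    for i in sorted(int(c) for c in chosen):
        matrix[i, :] = 0
        for m in ped.affected():
            matrix[i, col[m.sample_id]] = 1
        truth.transmission_violations.append(records[i].variant_id)
    return GenotypeTable(genotypes.variant_ids, genotypes.sample_ids, matrix)


def apply_genotype_errors(
    genotypes: GenotypeTable, rate: float, rng: np.random.Generator
) -> GenotypeTable:
    """Flip or drop each genotype independently with probability ``rate``."""
    if rate == 0:
        return genotypes
    matrix = genotypes.matrix.copy()
    hit = rng.random(matrix.shape) < rate
    replacements = np.array([0, 1, 2, MISSING], dtype=np.int8)
    noise = replacements[rng.integers(0, 4, size=matrix.shape)]
    matrix[hit] = noise[hit]
    return GenotypeTable(genotypes.variant_ids, genotypes.sample_ids, matrix)


def annotate_synthetic(
    records: Sequence[VariantRecord],
    truth: SimTruth,
    cfg: SimConfig,
    rng: np.random.Generator,
    true_afs: dict[str, float],
) -> dict[str, AnnotationProfile]:
    """Noisy seven-predictor annotations plus true allele frequencies.

    Causal variants draw damaging calls with p_predictor_sensitivity,
    background with p_predictor_false_damaging; every call is independently
    missing with p_missing_call. Raw scores are drawn from windows on the
    damaging or benign side of each predictor's conventional cutoff.
    """
    causal = {truth.maternal_variant, truth.paternal_variant}
    n = len(records)
    k = len(PREDICTORS)
    missing = rng.random((n, k)) < cfg.p_missing_call
    p_dam = np.array(
        [
            cfg.p_predictor_sensitivity
            if r.variant_id in causal
            else cfg.p_predictor_false_damaging
            for r in records
        ]
    )
    damaging = rng.random((n, k)) < p_dam[:, None]
    uniforms = rng.random((n, k))
    cat_picks = rng.integers(0, 2, size=(n, k))

    profiles: dict[str, AnnotationProfile] = {}
    for i, rec in enumerate(records):
        values = {}
        for j, name in enumerate(PREDICTORS):
            if missing[i, j]:
                continue
            if name in _CATEGORICAL_CALLS:
                side = _CATEGORICAL_CALLS[name][0 if damaging[i, j] else 1]
                values[name] = side[cat_picks[i, j] % len(side)]
            else:
                lo, hi = _SCORE_WINDOWS[name][0 if damaging[i, j] else 1]
                values[name] = float(lo + (hi - lo) * uniforms[i, j])
        af = true_afs[rec.variant_id]
        profiles[rec.variant_id] = AnnotationProfile(
            variant_id=rec.variant_id,
            af_global=float(af),
            af_popmax=float(min(af * (1.0 + 4.0 * uniforms[i, 0]), cfg.af_max)),
            predictor_values=values,
        )
    return profiles


def simulate_cohort(cfg: SimConfig) -> SimCohort:
    """Run the full generator: founders, transmission, planting, annotation."""
    rng = np.random.default_rng(cfg.seed)
    catalog = _gene_catalog(cfg)
    pathway = sorted(
        str(g) for g in rng.choice(catalog, size=cfg.pathway_size, replace=False)
    )
    records, founder_gts, afs = simulate_founders(cfg, rng)
    genotypes = transmit(cfg.pedigree, founder_gts, records, rng)
    true_afs = {r.variant_id: float(a) for r, a in zip(records, afs)}
    if cfg.plant_pair:
        records, genotypes, truth = plant_digenic(
            records, genotypes, cfg.pedigree, cfg, rng, pathway
        )
        true_afs.update(truth.planted_afs)
    else:
        truth = SimTruth(None, None, None, None)
    genotypes = inject_transmission_violations(
        records, genotypes, cfg.pedigree, truth, cfg, rng
    )
    genotypes = apply_genotype_errors(genotypes, cfg.genotype_error_rate, rng)
    profiles = annotate_synthetic(records, truth, cfg, rng, true_afs)
    truth.true_afs = true_afs

    # sort records (and genotype rows) by genomic coordinate for VCF output
    order = sorted(
        range(len(records)), key=lambda i: (int(records[i].chrom), records[i].pos)
    )
    records = [records[i] for i in order]
    genotypes = GenotypeTable(
        [r.variant_id for r in records],
        genotypes.sample_ids,
        genotypes.matrix[order],
    )
    genesets = GeneSetCollection({cfg.pathway_name: frozenset(pathway)})
    return SimCohort(records, genotypes, profiles, cfg.pedigree, genesets, truth, cfg)


def write_cohort(cohort: SimCohort, outdir: str | Path) -> dict[str, Path]:
    """Emit cohort.vcf, family.ped, annotations.tsv, genesets.gmt, truth.json."""
    from . import variant_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "ped": outdir / "family.ped",
        "annotations": outdir / "annotations.tsv",
        "genesets": outdir / "genesets.gmt",
        "truth": outdir / "truth.json",
    }
    variant_io.write_vcf(paths["vcf"], cohort.records, cohort.genotypes)
    variant_io.write_pedigree(paths["ped"], cohort.pedigree)
    variant_io.write_annotations(paths["annotations"], cohort.records, cohort.profiles)
    variant_io.write_geneset(paths["genesets"], cohort.genesets)
    paths["truth"].write_text(cohort.truth.to_json() + "\n")
    return paths


def evaluate_recovery(
    truth: SimTruth, pairs: Sequence[CandidatePair]
) -> tuple[int, float, int]:
    """(recall, precision, n_candidates) for the planted gene pair.

    Recall is 1 iff the planted (gene_a, gene_b) pair appears among the
    candidates; precision is 1/n when present among n pairs, else 0.
    """
    n = len(pairs)
    target = truth.gene_pair
    hit = target is not None and any(p.gene_pair == target for p in pairs)
    recall = 1 if hit else 0
    precision = (1.0 / n) if (hit and n) else 0.0
    return recall, precision, n
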