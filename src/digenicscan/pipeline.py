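"""End-to-end scan orchestration and the variant funnel.

Stage order is fixed — region, rarity, deleteriousness, shared-monoallelic
segregation, trans pairing, gene-set restriction, ranking — so funnel
counts are comparable across runs; the final pair set itself is
order-invariant. Funnel counts are asserted non-increasing across the
variant-level stages at run time.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

from . import classify, digenic, segregation, variant_io
from .classify import AnnotationProfile, DeleteriousnessCall
from .config import PipelineConfig, dump_config, load_config
from .digenic import CandidatePair
from .records import (
    ConsistencyError,
    GeneSetCollection,
    GenotypeTable,
    Pedigree,
    VariantRecord,
)
from .simulate import SimTruth, evaluate_recovery

logger = logging.getLogger(__name__)

VARIANT_STAGES = ("input", "region", "rarity", "deleterious", "shared_monoallelic")
PAIR_STAGES = ("pairs_trans", "pairs_geneset")


@dataclass
class StageCounts:
    """Ordered per-stage survivor counts (variants, then pairs)."""

    counts: dict[str, int] = field(default_factory=dict)

    def record(self, stage: str, count: int) -> None:
        previous = list(self.counts.values())[-1] if self.counts else None
        self.counts[stage] = count
        if stage in VARIANT_STAGES and previous is not None and count > previous:
            raise AssertionError(
                f"funnel violated at {stage}: {count} > previous {previous}"
            )
        logger.info("stage=%s survivors=%d", stage, count)

    def __getitem__(self, stage: str) -> int:
        return self.counts[stage]

    def as_list(self) -> list[tuple[str, int]]:
        return list(self.counts.items())


@dataclass
class ScanResult:
    pairs: list[CandidatePair]
    counts: StageCounts
    deleterious_calls: dict[str, DeleteriousnessCall]
    segregation: list[segregation.SegregationResult]


def scan_in_memory(
    records: Sequence[VariantRecord],
    genotypes: GenotypeTable,
    ped: Pedigree,
    profiles: Mapping[str, AnnotationProfile],
    genesets: GeneSetCollection,
    cfg: PipelineConfig | None = None,
) -> ScanResult:
    """Run the full prioritization on in-memory inputs.

    Variants without an annotation profile are treated as novel and
    uninformative: they pass rarity but cannot win the deleteriousness vote.
    """
    cfg = cfg or PipelineConfig()
    counts = StageCounts()
    counts.record("input", len(records))

    surv = [r for r in records if classify.region_pass(r)]
    counts.record("region", len(surv))

    def profile_of(vid: str) -> AnnotationProfile:
        return profiles.get(vid) or AnnotationProfile(variant_id=vid)

    surv = [
        r
        for r in surv
        if classify.rarity_pass(
            profile_of(r.variant_id), cfg.rarity_max_af, cfg.rarity_use_popmax
        )
    ]
    counts.record("rarity", len(surv))

    calls = {
        r.variant_id: classify.classify_deleterious(
            profile_of(r.variant_id), cfg.vote_thresholds, cfg.vote_min_informative
        )
        for r in surv
    }
    surv = [r for r in surv if calls[r.variant_id].verdict]
    counts.record("deleterious", len(surv))

    shared = segregation.shared_monoallelic_scan(
        surv,
        genotypes,
        ped,
        allow_other_parent_carrier=cfg.seg_allow_other_parent_carrier,
        chromosomes=cfg.seg_chromosomes,
    )
    counts.record("shared_monoallelic", len(shared))

    gene_of = {r.variant_id: r.gene for r in records}
    maternal = [s for s in shared if s.origin == segregation.MATERNAL]
    paternal = [s for s in shared if s.origin == segregation.PATERNAL]
    all_affected = frozenset(m.sample_id for m in ped.affected())
    pairs = digenic.pair_trans(
        maternal,
        paternal,
        gene_of,
        all_affected,
        require_all_affected=cfg.digenic_require_all_affected,
    )
    counts.record("pairs_trans", len(pairs))

    pairs = digenic.geneset_restrict(pairs, genesets, cfg.digenic_geneset_mode)
    counts.record("pairs_geneset", len(pairs))

    pairs = digenic.rank_pairs(pairs, calls, {p: profile_of(p) for p in gene_of})
    return ScanResult(pairs, counts, calls, shared)


def _check_consistency(
    genotypes: GenotypeTable,
    ped: Pedigree,
    profiles: Mapping[str, AnnotationProfile],
    records: Sequence[VariantRecord],
    max_missing_frac: float,
) -> None:
    vcf_samples = set(genotypes.sample_ids)
    ped_samples = set(ped.sample_ids)
    if vcf_samples != ped_samples:
        raise ConsistencyError(
            f"sample mismatch between VCF and PED: "
            f"VCF-only={sorted(vcf_samples - ped_samples)}, "
            f"PED-only={sorted(ped_samples - vcf_samples)}"
        )
    if records:
        missing = sum(1 for r in records if r.variant_id not in profiles)
        frac = missing / len(records)
        if frac > max_missing_frac:
            raise ConsistencyError(
                f"{missing}/{len(records)} variants ({frac:.1%}) lack annotation "
                f"(limit {max_missing_frac:.0%})"
            )


def run_scan(
    vcf_path: str | Path,
    ped_path: str | Path,
    annotations_path: str | Path,
    genesets_path: str | Path,
    outdir: str | Path,
    config_path: str | Path | None = None,
    **config_overrides,
) -> ScanResult:
    """File-based scan: ingest, run, write report + funnel + resolved config.

    Writes report.tsv, report.json, funnel.json and config.resolved.toml
    under ``outdir``. The annotation TSV is authoritative for gene and
    region class when it disagrees with VCF INFO keys. Zero pairs is a
    normal outcome, not an error.
    """
    cfg = load_config(config_path, **config_overrides)
    records, genotypes = variant_io.read_vcf(vcf_path)
    ped = variant_io.read_pedigree(ped_path)
    profiles, genes, regions = variant_io.read_annotations(annotations_path)
    genesets = variant_io.read_geneset(genesets_path)
    _check_consistency(
        genotypes, ped, profiles, records, cfg.pipeline_max_missing_annotation_frac
    )
    records = [
        replace(
            r,
            gene=genes.get(r.variant_id, r.gene),
            region_class=regions.get(r.variant_id, r.region_class),
        )
        for r in records
    ]
    result = scan_in_memory(records, genotypes, ped, profiles, genesets, cfg)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    variant_io.write_report(result.pairs, outdir / "report.tsv", "tsv")
    variant_io.write_report(result.pairs, outdir / "report.json", "json")
    (outdir / "funnel.json").write_text(
        json.dumps(
            {"stages": [{"stage": s, "count": c} for s, c in result.counts.as_list()]},
            indent=2,
        )
        + "\n"
    )
    (outdir / "config.resolved.toml").write_text(dump_config(cfg))
    return result


def run_evaluate(
    truth_path: str | Path, report_path: str | Path, out_path: str | Path
) -> dict:
    """Score a report against simulator truth; writes a metrics JSON."""
    truth = SimTruth.from_json(Path(truth_path).read_text())
    pairs = variant_io.read_report(report_path)
    recall, precision, n = evaluate_recovery(truth, pairs)
    metrics = {"recall": recall, "precision": precision, "n_candidates": n}
    Path(out_path).write_text(json.dumps(metrics, indent=2, sort_keys=True) + "\n")
    return metrics
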