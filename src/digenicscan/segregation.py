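"""Pedigree segregation scans: de novo, recessive, shared monoallelic.

Parental origin is always re-derived by transmission (carrier parent vs
hom-ref parent), never taken from VCF phase separators. A MISSING genotype
in any member a pattern needs disqualifies the variant for that pattern —
no imputation. Non-autosomal variants are excluded by default (with a
logged count); the hemizygous X transmission model is out of scope.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .records import (
    MISSING,
    DigenicScanError,
    GenotypeTable,
    Pedigree,
    VariantRecord,
)

logger = logging.getLogger(__name__)

MATERNAL = "maternal"
PATERNAL = "paternal"
AMBIGUOUS = "ambiguous"
NOT_APPLICABLE = "n/a"

DE_NOVO = "de_novo"
HOM_RECESSIVE = "hom_recessive"
COMPHET_PARTNER = "comphet_partner"
SHARED_MONOALLELIC = "shared_monoallelic"


class ContractViolation(DigenicScanError):
    """A caller broke an operation precondition."""


@dataclass(frozen=True)
class SegregationResult:
    variant_id: str
    pattern: str
    origin: str  # maternal / paternal / ambiguous / n/a
    affected_carriers: frozenset[str]


def _autosomal_records(
    records: Sequence[VariantRecord], chromosomes: str
) -> list[VariantRecord]:
    if chromosomes == "all":
        return list(records)
    kept = [r for r in records if r.is_autosomal()]
    dropped = len(records) - len(kept)
    if dropped:
        logger.info("segregation: excluded %d non-autosomal variant(s)", dropped)
    return kept


def _phaseable_affected(ped: Pedigree, genotypes: GenotypeTable) -> list[str]:
    """Affected members whose parents are both present and genotyped."""
    usable = []
    for m in ped.affected():
        if (
            m.father_id is not None
            and m.mother_id is not None
            and m.father_id in genotypes.sample_ids
            and m.mother_id in genotypes.sample_ids
        ):
            usable.append(m.sample_id)
        else:
            logger.warning(
                "segregation: affected member %s lacks two genotyped parents; "
                "skipped in trio-based scans",
                m.sample_id,
            )
    return usable


def phase_by_transmission(
    variant_id: str,
    genotypes: GenotypeTable,
    ped: Pedigree,
    child: str,
    allow_other_parent_carrier: bool = False,
) -> str:
    """Parental origin of a heterozygous child's alternate allele.

    Maternal iff the mother carries the allele and the father is hom-ref
    (strict mode); the converse for paternal. Both parents carriers, or
    neither, is ambiguous — the latter is de-novo-like and flagged in the
    log as a possible genotyping error. In permissive mode the non-carrier
    parent's genotype is ignored (MISSING or het does not disqualify), but
    two carrier parents remain ambiguous.
    """
    if genotypes.code(variant_id, child) != 1:
        raise ContractViolation(
            f"phase_by_transmission requires a heterozygous child; "
            f"{child} has code {genotypes.code(variant_id, child)} at {variant_id}"
        )
    member = ped.member(child)
    if member.father_id is None or member.mother_id is None:
        raise ContractViolation(f"child {child} lacks two pedigree parents")
    gf = genotypes.code(variant_id, member.father_id)
    gm = genotypes.code(variant_id, member.mother_id)
    mother_carrier = gm >= 1
    father_carrier = gf >= 1
    if allow_other_parent_carrier:
        if mother_carrier and not father_carrier:
            return MATERNAL
        if father_carrier and not mother_carrier:
            return PATERNAL
        return AMBIGUOUS
    if gf == MISSING or gm == MISSING:
        return AMBIGUOUS
    if mother_carrier and gf == 0:
        return MATERNAL
    if father_carrier and gm == 0:
        return PATERNAL
    if not mother_carrier and not father_carrier:
        logger.debug(
            "phase: %s het in %s but absent in both parents "
            "(possible de novo or genotyping error)",
            variant_id,
            child,
        )
    return AMBIGUOUS


def de_novo_scan(
    records: Sequence[VariantRecord],
    genotypes: GenotypeTable,
    ped: Pedigree,
    chromosomes: str = "autosomes",
) -> list[SegregationResult]:
    """Variants carried by every affected child whose parents are hom-ref."""
    children = _phaseable_affected(ped, genotypes)
    if not children:
        return []
    out = []
    for rec in _autosomal_records(records, chromosomes):
        vid = rec.variant_id
        ok = True
        for child in children:
            member = ped.member(child)
            gc = genotypes.code(vid, child)
            gf = genotypes.code(vid, member.father_id)
            gm = genotypes.code(vid, member.mother_id)
            if MISSING in (gc, gf, gm) or gc < 1 or gf != 0 or gm != 0:
                ok = False
                break
        if ok:
            out.append(
                SegregationResult(vid, DE_NOVO, NOT_APPLICABLE, frozenset(children))
            )
    return out


def _hom_recessive(
    records: Sequence[VariantRecord],
    genotypes: GenotypeTable,
    ped: Pedigree,
    children: list[str],
) -> list[SegregationResult]:
    out = []
    for rec in records:
        vid = rec.variant_id
        ok = True
        for child in children:
            member = ped.member(child)
            if (
                genotypes.code(vid, child) != 2
                or genotypes.code(vid, member.father_id) != 1
                or genotypes.code(vid, member.mother_id) != 1
            ):
                ok = False
                break
        if ok:
            out.append(
                SegregationResult(
                    vid, HOM_RECESSIVE, NOT_APPLICABLE, frozenset(children)
                )
            )
    return out


def _comphet(
    records: Sequence[VariantRecord],
    genotypes: GenotypeTable,
    ped: Pedigree,
    children: list[str],
) -> list[SegregationResult]:
    """Two variants in one gene, one per parental chromosome, in all affecteds.

    A pair is rejected when any unaffected member carries both variants
    (standard recessive filtering); origin is resolved per variant by
    transmission and must agree across the affected children.
    """
    by_gene: dict[str, list[tuple[str, str]]] = {}
    for rec in records:
        vid = rec.variant_id
        origins = set()
        usable = True
        for child in children:
            if genotypes.code(vid, child) != 1:
                usable = False
                break
            origins.add(phase_by_transmission(vid, genotypes, ped, child))
        if not usable or len(origins) != 1:
            continue
        origin = origins.pop()
        if origin == AMBIGUOUS:
            continue
        by_gene.setdefault(rec.gene, []).append((vid, origin))
    unaffected = [m.sample_id for m in ped.unaffected()]
    results: dict[str, SegregationResult] = {}
    for gene, entries in by_gene.items():
        maternal = [v for v, o in entries if o == MATERNAL]
        paternal = [v for v, o in entries if o == PATERNAL]
        for vm in maternal:
            for vp in paternal:
                carried_both = any(
                    genotypes.code(vm, u) >= 1 and genotypes.code(vp, u) >= 1
                    for u in unaffected
                )
                if carried_both:
                    continue
                results.setdefault(
                    vm,
                    SegregationResult(vm, COMPHET_PARTNER, MATERNAL, frozenset(children)),
                )
                results.setdefault(
                    vp,
                    SegregationResult(vp, COMPHET_PARTNER, PATERNAL, frozenset(children)),
                )
    return [results[v] for v in sorted(results)]


def recessive_scan(
    records: Sequence[VariantRecord],
    genotypes: GenotypeTable,
    ped: Pedigree,
    chromosomes: str = "autosomes",
) -> list[SegregationResult]:
    """Autosomal recessive patterns: homozygous and compound heterozygous."""
    children = _phaseable_affected(ped, genotypes)
    if not children:
        return []
    recs = _autosomal_records(records, chromosomes)
    return _hom_recessive(recs, genotypes, ped, children) + _comphet(
        recs, genotypes, ped, children
    )


def shared_monoallelic_scan(
    records: Sequence[VariantRecord],
    genotypes: GenotypeTable,
    ped: Pedigree,
    allow_other_parent_carrier: bool = False,
    chromosomes: str = "autosomes",
) -> list[SegregationResult]:
    """Variants heterozygous in every affected member with one unambiguous,
    shared parental origin (carrier in exactly one parent)."""
    children = _phaseable_affected(ped, genotypes)
    if not children or len(children) < len(ped.affected()):
        # the pattern requires phase for EVERY affected member
        return []
    out = []
    for rec in _autosomal_records(records, chromosomes):
        vid = rec.variant_id
        if any(genotypes.code(vid, c) != 1 for c in children):
            continue
        origins = {
            phase_by_transmission(vid, genotypes, ped, c, allow_other_parent_carrier)
            for c in children
        }
        if len(origins) == 1 and (origin := origins.pop()) != AMBIGUOUS:
            out.append(
                SegregationResult(vid, SHARED_MONOALLELIC, origin, frozenset(children))
            )
    return out
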