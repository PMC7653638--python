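"""Trans digenic pairing, gene-set restriction, and ranking.

A candidate pair joins one maternal-origin and one paternal-origin shared
monoallelic variant in DISTINCT genes, both carried by the affected members
— the two-locus, one-allele-from-each-parent architecture. Same-gene
cross-parental pairs are compound heterozygotes and belong to the recessive
scan, not here.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .classify import AnnotationProfile, DeleteriousnessCall
from .records import ConfigError, DigenicScanError, GeneSetCollection
from .segregation import AMBIGUOUS, MATERNAL, PATERNAL, ContractViolation, SegregationResult


@dataclass(frozen=True)
class CandidatePair:
    """One trans digenic candidate: variant_a maternal, variant_b paternal."""

    variant_a: str
    variant_b: str
    gene_a: str
    gene_b: str
    shared_affected: frozenset[str]
    genesets: tuple[str, ...] = ()
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise DigenicScanError(
                f"digenic pair genes must differ, got {self.gene_a} twice"
            )
        if not self.shared_affected:
            raise DigenicScanError("digenic pair must share >= 1 affected carrier")

    @property
    def origin_a(self) -> str:
        return MATERNAL

    @property
    def origin_b(self) -> str:
        return PATERNAL

    @property
    def gene_pair(self) -> frozenset[str]:
        return frozenset({self.gene_a, self.gene_b})

    def sort_key(self) -> tuple[str, str, str, str]:
        return (self.gene_a, self.gene_b, self.variant_a, self.variant_b)


def pair_trans(
    maternal: Sequence[SegregationResult],
    paternal: Sequence[SegregationResult],
    gene_of: Mapping[str, str],
    all_affected: frozenset[str],
    require_all_affected: bool = True,
) -> list[CandidatePair]:
    """Cartesian pairing of maternal x paternal candidates in distinct genes.

    ``gene_of`` maps variant_id -> gene symbol. shared_affected is the
    intersection of the two variants' affected carriers; with
    ``require_all_affected`` it must equal the full affected set. Output is
    deterministic: sorted by (gene_a, gene_b, variant_a, variant_b).
    """
    for res, want in ((maternal, MATERNAL), (paternal, PATERNAL)):
        for r in res:
            if r.origin != want:
                raise ContractViolation(
                    f"{r.variant_id}: expected {want} origin, got {r.origin!r}"
                )
    pairs = []
    for rm in maternal:
        for rp in paternal:
            gene_a, gene_b = gene_of[rm.variant_id], gene_of[rp.variant_id]
            if gene_a == gene_b:
                continue  # compound het territory
            shared = rm.affected_carriers & rp.affected_carriers
            if not shared:
                continue
            if require_all_affected and shared != all_affected:
                continue
            pairs.append(
                CandidatePair(
                    variant_a=rm.variant_id,
                    variant_b=rp.variant_id,
                    gene_a=gene_a,
                    gene_b=gene_b,
                    shared_affected=frozenset(shared),
                )
            )
    return sorted(pairs, key=CandidatePair.sort_key)


def geneset_restrict(
    pairs: Sequence[CandidatePair],
    sets: GeneSetCollection,
    mode: str = "both_in_same_set",
) -> list[CandidatePair]:
    """Keep pairs by gene-set membership; tags the sets holding both genes.

    ``both_in_same_set``: the two genes co-occur in at least one set.
    ``either``: at least one gene appears in at least one set.
    ``off``: identity.
    """
    if mode == "off":
        return list(pairs)
    if mode not in ("both_in_same_set", "either"):
        raise ConfigError(f"unknown geneset mode {mode!r}")
    if len(sets) == 0:
        raise ConfigError(f"geneset mode {mode!r} requires a non-empty collection")
    out = []
    for p in pairs:
        both = sets.sets_containing_all([p.gene_a, p.gene_b])
        keep = bool(both) if mode == "both_in_same_set" else bool(
            sets.sets_containing_any([p.gene_a, p.gene_b])
        )
        if keep:
            out.append(replace(p, genesets=tuple(both)))
    return out


def _variant_score(
    variant_id: str,
    dels: Mapping[str, DeleteriousnessCall],
    profiles: Mapping[str, AnnotationProfile],
) -> float:
    try:
        call = dels[variant_id]
        profile = profiles[variant_id]
    except KeyError as exc:
        raise DigenicScanError(
            f"missing deleteriousness call or annotation for {variant_id}"
        ) from exc
    vote_frac = call.n_damaging / call.n_informative if call.n_informative else 0.0
    af = profile.af_global if profile.af_global is not None else 0.0
    return vote_frac * (1.0 - af)


def rank_pairs(
    pairs: Sequence[CandidatePair],
    dels: Mapping[str, DeleteriousnessCall],
    profiles: Mapping[str, AnnotationProfile],
) -> list[CandidatePair]:
    """Score and sort pairs; a convenience ordering, not part of the model.

    score = mean over the pair's two variants of
    (damaging fraction of informative predictors) x (1 - global AF, missing
    AF as 0); descending, ties broken lexicographically.
    """
    scored = [
        replace(
            p,
            score=0.5
            * (
                _variant_score(p.variant_a, dels, profiles)
                + _variant_score(p.variant_b, dels, profiles)
            ),
        )
        for p in pairs
    ]
    return sorted(scored, key=lambda p: (-p.score, p.sort_key()))
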