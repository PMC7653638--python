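"""Per-variant rarity and ensemble-deleteriousness classification.

A variant passes the rarity filter when it is novel (no population frequency
on record) or its minor allele frequency is strictly below the cutoff
(default 0.01). Deleteriousness is decided by a majority vote over up to
seven in-silico predictors (CADD, SIFT, PolyPhen2, LRT, MutationTaster,
GERP++, PhyloP): a variant is deleterious iff strictly more than half of the
informative (non-missing) predictor calls are damaging, and at least
``min_informative`` predictors were informative at all. Ties and sparsely
annotated variants are conservatively NOT deleterious.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping

from .config import DEFAULT_THRESHOLDS
from .records import ConfigError, ValidationError, VariantRecord

PREDICTORS = ("CADD", "SIFT", "PolyPhen2", "LRT", "MutationTaster", "GERP++", "PhyloP")
CATEGORICAL_PREDICTORS = frozenset({"LRT", "MutationTaster"})
LOWER_IS_DAMAGING = frozenset({"SIFT"})

DAMAGING = "damaging"
BENIGN = "benign"
MISSING_CALL = "missing"


@dataclass(frozen=True)
class AnnotationProfile:
    """Population frequencies plus raw predictor values for one variant."""

    variant_id: str
    af_global: float | None = None
    af_popmax: float | None = None
    predictor_values: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, af in (("af_global", self.af_global), ("af_popmax", self.af_popmax)):
            if af is not None and not (0.0 <= af <= 1.0):
                raise ValidationError(
                    f"{label} out of [0, 1] for {self.variant_id}: {af}"
                )
        unknown = set(self.predictor_values) - set(PREDICTORS)
        if unknown:
            raise ValidationError(
                f"unknown predictor(s) for {self.variant_id}: {sorted(unknown)}"
            )


@dataclass(frozen=True)
class DeleteriousnessCall:
    variant_id: str
    per_predictor: Mapping[str, str]
    n_damaging: int
    n_informative: int
    verdict: bool
    insufficient_evidence: bool = False


def _is_absent(value: Any) -> bool:
    if value is None or value == "":
        return True
    return isinstance(value, float) and math.isnan(value)


def rarity_pass(
    profile: AnnotationProfile, max_af: float = 0.01, use_popmax: bool = False
) -> bool:
    """True iff the variant is novel or rarer than ``max_af`` (strict)."""
    if not (0.0 < max_af <= 1.0):
        raise ConfigError(f"max_af must be in (0, 1], got {max_af}")
    af = profile.af_popmax if use_popmax else profile.af_global
    return af is None or af < max_af


def predictor_call(
    name: str, value: Any, thresholds: Mapping[str, Any] | None = None
) -> str:
    """Map one predictor's raw score or categorical call to a tri-state call."""
    thresholds = thresholds if thresholds is not None else DEFAULT_THRESHOLDS
    if name not in PREDICTORS:
        raise ConfigError(f"unknown predictor {name!r}")
    if _is_absent(value):
        return MISSING_CALL
    cutoff = thresholds.get(name, DEFAULT_THRESHOLDS[name])
    if name in CATEGORICAL_PREDICTORS:
        return DAMAGING if str(value) in set(cutoff) else BENIGN
    score = float(value)
    if name in LOWER_IS_DAMAGING:
        return DAMAGING if score <= cutoff else BENIGN
    return DAMAGING if score >= cutoff else BENIGN


def call_predictors(
    profile: AnnotationProfile, thresholds: Mapping[str, Any] | None = None
) -> dict[str, str]:
    """Tri-state calls for all seven predictors (absent raw value -> missing)."""
    return {
        name: predictor_call(name, profile.predictor_values.get(name), thresholds)
        for name in PREDICTORS
    }


def majority_vote(
    calls: Mapping[str, str], min_informative: int = 4
) -> DeleteriousnessCall:
    """Strict-majority verdict over informative calls.

    Missing calls never count toward either side; an exact tie is not a
    majority. Fewer than ``min_informative`` informative calls yields a
    false verdict flagged as insufficient evidence.
    """
    unknown = set(calls) - set(PREDICTORS)
    if unknown:
        raise ConfigError(f"unknown predictor(s) in calls: {sorted(unknown)}")
    n_damaging = sum(1 for c in calls.values() if c == DAMAGING)
    n_informative = sum(1 for c in calls.values() if c != MISSING_CALL)
    insufficient = n_informative < min_informative
    verdict = (not insufficient) and n_damaging * 2 > n_informative
    return DeleteriousnessCall(
        variant_id="",
        per_predictor=dict(calls),
        n_damaging=n_damaging,
        n_informative=n_informative,
        verdict=verdict,
        insufficient_evidence=insufficient,
    )


def classify_deleterious(
    profile: AnnotationProfile,
    thresholds: Mapping[str, Any] | None = None,
    min_informative: int = 4,
) -> DeleteriousnessCall:
    """Full rule for one variant: threshold each predictor, then vote."""
    call = majority_vote(call_predictors(profile, thresholds), min_informative)
    return DeleteriousnessCall(
        variant_id=profile.variant_id,
        per_predictor=call.per_predictor,
        n_damaging=call.n_damaging,
        n_informative=call.n_informative,
        verdict=call.verdict,
        insufficient_evidence=call.insufficient_evidence,
    )


def region_pass(record: VariantRecord) -> bool:
    """Keep coding variants and those near exon-intron junctions."""
    if record.region_class not in ("exonic", "splicing", "other"):
        raise ValidationError(
            f"unknown region_class {record.region_class!r} for {record.variant_id}"
        )
    return record.region_class in ("exonic", "splicing")
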