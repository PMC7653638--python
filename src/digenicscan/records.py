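"""Core in-memory records: variants, genotype matrix, pedigree, gene sets.

Genotype codes are unphased alt-allele dosages against a single alternate
allele: 0 = hom-ref, 1 = het, 2 = hom-alt, MISSING = -1. Multiallelic sites
are split upstream into one record per alternate allele, so every record is
biallelic by construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

MISSING: int = -1
GENOTYPE_CODES = frozenset({0, 1, 2, MISSING})

REGION_CLASSES = ("exonic", "splicing", "other")


class DigenicScanError(Exception):
    """Base class for all package errors."""


class ParseError(DigenicScanError):
    """Malformed input file."""


class InputError(DigenicScanError):
    """Structurally valid file that violates a precondition (e.g. no samples)."""


class ValidationError(DigenicScanError):
    """In-memory record violating an invariant."""


class ConsistencyError(DigenicScanError):
    """Mutually inconsistent inputs (e.g. VCF samples not in pedigree)."""


class ConfigError(DigenicScanError):
    """Invalid configuration value."""


@dataclass(frozen=True)
class VariantRecord:
    """One normalized biallelic site.

    Coordinates are 1-based inclusive (VCF convention). ``variant_id`` is the
    canonical key ``chrom:pos:ref:alt`` after multiallelic splitting.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    region_class: str = "other"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(
                f"ref and alt alleles identical at {self.chrom}:{self.pos}"
            )

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def is_autosomal(self) -> bool:
        label = self.chrom.lower().removeprefix("chr")
        return label.isdigit() and 1 <= int(label) <= 22


class GenotypeTable:
    """Dense (variant x sample) matrix of genotype codes.

    Backed by an int8 numpy array; rows follow the variant order given at
    construction, columns the sample order.
    """

    def __init__(
        self,
        variant_ids: Sequence[str],
        sample_ids: Sequence[str],
        matrix: np.ndarray,
    ) -> None:
        matrix = np.asarray(matrix, dtype=np.int8)
        if matrix.shape != (len(variant_ids), len(sample_ids)):
            raise ValidationError(
                f"genotype matrix shape {matrix.shape} does not match "
                f"{len(variant_ids)} variants x {len(sample_ids)} samples"
            )
        bad = set(np.unique(matrix)) - GENOTYPE_CODES
        if bad:
            raise ValidationError(f"invalid genotype codes {sorted(bad)}")
        if len(set(variant_ids)) != len(variant_ids):
            raise ValidationError("duplicate variant_id in genotype table")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValidationError("duplicate sample_id in genotype table")
        self.variant_ids = list(variant_ids)
        self.sample_ids = list(sample_ids)
        self.matrix = matrix
        self._vidx = {v: i for i, v in enumerate(self.variant_ids)}
        self._sidx = {s: j for j, s in enumerate(self.sample_ids)}

    def code(self, variant_id: str, sample_id: str) -> int:
        return int(self.matrix[self._vidx[variant_id], self._sidx[sample_id]])

    def row(self, variant_id: str) -> np.ndarray:
        return self.matrix[self._vidx[variant_id]]

    def sample_column(self, sample_id: str) -> np.ndarray:
        return self.matrix[:, self._sidx[sample_id]]

    def has_variant(self, variant_id: str) -> bool:
        return variant_id in self._vidx

    def subset(self, variant_ids: Sequence[str]) -> "GenotypeTable":
        rows = [self._vidx[v] for v in variant_ids]
        return GenotypeTable(variant_ids, self.sample_ids, self.matrix[rows])

    def as_dict(self) -> dict[tuple[str, str], int]:
        return {
            (v, s): int(self.matrix[i, j])
            for v, i in self._vidx.items()
            for s, j in self._sidx.items()
        }


@dataclass(frozen=True)
class PedigreeMember:
    sample_id: str
    father_id: str | None
    mother_id: str | None
    sex: int  # 1 male, 2 female, 0 unknown
    affected: bool


@dataclass
class Pedigree:
    """Family members with parental links and affection status.

    Parental references must resolve to members (or be absent for founders)
    and the parent graph must be acyclic; both are checked at construction.
    """

    members: list[PedigreeMember]

    def __post_init__(self) -> None:
        ids = [m.sample_id for m in self.members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample id(s): {dupes}")
        known = set(ids)
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in known:
                    raise ValidationError(
                        f"{m.sample_id} references unknown parent {pid!r}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parents = {
            m.sample_id: [p for p in (m.father_id, m.mother_id) if p is not None]
            for m in self.members
        }
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(node: str, stack: list[str]) -> None:
            if state.get(node) == 1:
                return
            if state.get(node) == 0:
                raise ValidationError(
                    f"pedigree contains an ancestry cycle through {node!r}"
                )
            state[node] = 0
            for p in parents[node]:
                visit(p, stack + [node])
            state[node] = 1

        for sid in parents:
            visit(sid, [])

    def member(self, sample_id: str) -> PedigreeMember:
        for m in self.members:
            if m.sample_id == sample_id:
                return m
        raise KeyError(sample_id)

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.members]

    def affected(self) -> list[PedigreeMember]:
        return [m for m in self.members if m.affected]

    def unaffected(self) -> list[PedigreeMember]:
        return [m for m in self.members if not m.affected]

    def founders(self) -> list[PedigreeMember]:
        return [m for m in self.members if m.father_id is None and m.mother_id is None]

    def nonfounders(self) -> list[PedigreeMember]:
        return [m for m in self.members if m.father_id or m.mother_id]

    def has_both_parents(self, sample_id: str) -> bool:
        m = self.member(sample_id)
        return m.father_id is not None and m.mother_id is not None


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): set_name -> set of gene symbols."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if any(not g for g in genes):
                raise ValidationError(f"empty gene symbol in set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def sets_containing_all(self, genes: Iterable[str]) -> list[str]:
        wanted = set(genes)
        return sorted(n for n, s in self.sets.items() if wanted <= s)

    def sets_containing_any(self, genes: Iterable[str]) -> list[str]:
        wanted = set(genes)
        return sorted(n for n, s in self.sets.items() if wanted & s)


def quartet_pedigree(
    father: str = "father",
    mother: str = "mother",
    children: Sequence[str] = ("proband", "sibling"),
    children_affected: Sequence[bool] = (True, True),
) -> Pedigree:
    """Two founders plus children of both; the study's family structure."""
    members = [
        PedigreeMember(father, None, None, 1, False),
        PedigreeMember(mother, None, None, 2, False),
    ]
    for child, aff in zip(children, children_affected):
        members.append(PedigreeMember(child, father, mother, 2, aff))
    return Pedigree(members)
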