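"""Shared fixtures: the two-variant kindred configuration and file writers.

The kindred fixture encodes the family's printed genotype configuration:
a maternally transmitted FGFR1 missense variant (het in mother and both
affected sisters, absent in father; gnomAD-scale AF 0.00039) and a
paternally transmitted KLB variant (the mirror image; AF 0.002), both
called damaging by all seven predictors, with one gene set holding both
genes.
"""
from __future__ import annotations

import numpy as np
import pytest

from digenicscan import (
    AnnotationProfile,
    GeneSetCollection,
    GenotypeTable,
    VariantRecord,
    quartet_pedigree,
)
from digenicscan import variant_io

ALL_DAMAGING = {
    "CADD": 29.0,
    "SIFT": 0.0,
    "PolyPhen2": 0.98,
    "LRT": "D",
    "MutationTaster": "D",
    "GERP++": 4.5,
    "PhyloP": 2.5,
}


@pytest.fixture
def kindred():
    """In-memory records, genotypes, pedigree, profiles, gene sets."""
    ped = quartet_pedigree()  # father, mother, proband, sibling
    fgfr1 = VariantRecord("8", 39099, "G", "A", gene="FGFR1", region_class="exonic")
    klb = VariantRecord("4", 123, "C", "A", gene="KLB", region_class="exonic")
    records = [klb, fgfr1]  # coordinate order: chr4 before chr8
    #                         father mother proband sibling
    matrix = np.array(
        [
            [1, 0, 1, 1],  # KLB: paternal
            [0, 1, 1, 1],  # FGFR1: maternal
        ],
        dtype=np.int8,
    )
    genotypes = GenotypeTable([r.variant_id for r in records], ped.sample_ids, matrix)
    profiles = {
        fgfr1.variant_id: AnnotationProfile(
            fgfr1.variant_id, af_global=0.00039, af_popmax=0.00045,
            predictor_values=dict(ALL_DAMAGING),
        ),
        klb.variant_id: AnnotationProfile(
            klb.variant_id, af_global=0.002, af_popmax=0.02,
            predictor_values=dict(ALL_DAMAGING),
        ),
    }
    genesets = GeneSetCollection({"FGF21_PATHWAY": frozenset({"FGFR1", "KLB"})})
    return {
        "records": records,
        "genotypes": genotypes,
        "pedigree": ped,
        "profiles": profiles,
        "genesets": genesets,
        "fgfr1": fgfr1,
        "klb": klb,
    }


@pytest.fixture
def kindred_files(kindred, tmp_path):
    """The same kindred written out as VCF / PED / TSV / GMT."""
    paths = {
        "vcf": tmp_path / "kindred.vcf",
        "ped": tmp_path / "kindred.ped",
        "annotations": tmp_path / "kindred.tsv",
        "genesets": tmp_path / "kindred.gmt",
        "outdir": tmp_path / "out",
    }
    variant_io.write_vcf(paths["vcf"], kindred["records"], kindred["genotypes"])
    variant_io.write_pedigree(paths["ped"], kindred["pedigree"])
    variant_io.write_annotations(
        paths["annotations"], kindred["records"], kindred["profiles"]
    )
    variant_io.write_geneset(paths["genesets"], kindred["genesets"])
    return paths
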