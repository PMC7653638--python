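"""Independent brute-force reference for the full prioritization.

Re-implements every predicate naively and in one place — region and rarity
checks, predictor thresholding, majority vote, per-child transmission
phasing, the shared-monoallelic rule, distinct-gene trans pairing and
gene-set membership — without calling any pipeline predicate, so pipeline
results can be checked against an implementation that shares no logic with
them. Deliberately quadratic over variant pairs; intended for instances of
at most a few hundred variants.
"""
from __future__ import annotations

MISSING = -1

_NUMERIC_CUTOFFS = {
    "CADD": 20.0,
    "PolyPhen2": 0.446,
    "GERP++": 2.0,
    "PhyloP": 1.5,
}


def _damaging(name, value):
    if value is None or value == "":
        return None
    if name == "SIFT":
        return float(value) <= 0.05
    if name == "LRT":
        return str(value) == "D"
    if name == "MutationTaster":
        return str(value) in ("A", "D")
    return float(value) >= _NUMERIC_CUTOFFS[name]


def _autosomal(chrom):
    label = str(chrom).lower().removeprefix("chr")
    return label.isdigit() and 1 <= int(label) <= 22


def naive_pair_set(
    records,
    genotypes,
    ped,
    profiles,
    genesets,
    max_af=0.01,
    use_popmax=False,
    min_informative=4,
    geneset_mode="both_in_same_set",
):
    """All trans digenic candidate pairs as a set of (variant_a, variant_b)."""
    affected = [m for m in ped.members if m.affected]
    eligible = {}  # variant_id -> (gene, origin)
    for rec in records:
        vid = rec.variant_id
        if not _autosomal(rec.chrom):
            continue
        if rec.region_class not in ("exonic", "splicing"):
            continue
        prof = profiles.get(vid)
        af = None
        if prof is not None:
            af = prof.af_popmax if use_popmax else prof.af_global
        if af is not None and af >= max_af:
            continue
        n_dam = n_inf = 0
        values = prof.predictor_values if prof is not None else {}
        for name in ("CADD", "SIFT", "PolyPhen2", "LRT", "MutationTaster", "GERP++", "PhyloP"):
            call = _damaging(name, values.get(name))
            if call is None:
                continue
            n_inf += 1
            n_dam += int(call)
        if n_inf < min_informative or 2 * n_dam <= n_inf:
            continue
        origins = set()
        ok = True
        for child in affected:
            if child.father_id is None or child.mother_id is None:
                ok = False
                break
            gc = genotypes.code(vid, child.sample_id)
            gf = genotypes.code(vid, child.father_id)
            gm = genotypes.code(vid, child.mother_id)
            if gc != 1 or gf == MISSING or gm == MISSING:
                ok = False
                break
            if gm >= 1 and gf == 0:
                origins.add("maternal")
            elif gf >= 1 and gm == 0:
                origins.add("paternal")
            else:
                ok = False
                break
        if not ok or len(origins) != 1:
            continue
        eligible[vid] = (rec.gene, origins.pop())

    pairs = set()
    for va, (ga, oa) in eligible.items():
        if oa != "maternal":
            continue
        for vb, (gb, ob) in eligible.items():
            if ob != "paternal" or ga == gb:
                continue
            if geneset_mode == "both_in_same_set":
                if not any(ga in s and gb in s for s in genesets.sets.values()):
                    continue
            elif geneset_mode == "either":
                if not any(ga in s or gb in s for s in genesets.sets.values()):
                    continue
            pairs.add((va, vb))
    return pairs


def naive_de_novo(records, genotypes, ped):
    """Variant ids where all affected children are carriers of an allele
    absent from both hom-ref parents (complete trio data required)."""
    affected = [m for m in ped.members if m.affected]
    out = set()
    for rec in records:
        if not _autosomal(rec.chrom):
            continue
        vid = rec.variant_id
        ok = bool(affected)
        for child in affected:
            if child.father_id is None or child.mother_id is None:
                ok = False
                break
            gc = genotypes.code(vid, child.sample_id)
            gf = genotypes.code(vid, child.father_id)
            gm = genotypes.code(vid, child.mother_id)
            if gc < 1 or gf != 0 or gm != 0:
                ok = False
                break
        if ok:
            out.add(vid)
    return out


def naive_shared_monoallelic(records, genotypes, ped):
    """Variant ids het in every affected with one shared unambiguous origin."""
    out = {}
    affected = [m for m in ped.members if m.affected]
    for rec in records:
        if not _autosomal(rec.chrom):
            continue
        vid = rec.variant_id
        origins = set()
        ok = bool(affected)
        for child in affected:
            if child.father_id is None or child.mother_id is None:
                ok = False
                break
            gc = genotypes.code(vid, child.sample_id)
            gf = genotypes.code(vid, child.father_id)
            gm = genotypes.code(vid, child.mother_id)
            if gc != 1 or gf == MISSING or gm == MISSING:
                ok = False
                break
            if gm >= 1 and gf == 0:
                origins.add("maternal")
            elif gf >= 1 and gm == 0:
                origins.add("paternal")
            else:
                ok = False
                break
        if ok and len(origins) == 1:
            out[vid] = origins.pop()
    return out
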