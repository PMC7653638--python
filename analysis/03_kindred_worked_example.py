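#!/usr/bin/env python
"""The kindred worked example: two variants, one trans digenic pair.

Encodes the family's genotype configuration directly — an FGFR1 missense
variant heterozygous in the mother and both affected sisters (global AF
0.00039), and a KLB variant heterozygous in the father and both sisters
(global AF 0.002), each called damaging by all seven predictors, with one
gene set covering the FGF21 receptor-complex genes — and runs the full
file-based pipeline on it. Outputs land in results/kindred/.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "scripts"))
from acceptance import kindred_pair_count  # reuses the fixture builder

OUT = Path(__file__).resolve().parent.parent / "results" / "kindred"

def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    n = kindred_pair_count(OUT)
    report = (OUT / "out" / "report.tsv").read_text()
    print(report.rstrip())
    print(f"\ncandidate pairs: {n} (expected exactly 1: FGFR1 maternal x KLB paternal)")

if __name__ == "__main__":
    main()
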