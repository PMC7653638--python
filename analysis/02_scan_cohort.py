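#!/usr/bin/env python
"""Run the prioritization scan on the simulated quartet from step 01.

Reports the per-stage survivor funnel (input -> region -> rarity ->
deleterious -> shared monoallelic -> trans pairs -> gene-set pairs) and
scores the report against the simulator's planted truth. Outputs land in
results/scan/.
"""
import json
from pathlib import Path

from digenicscan import run_evaluate, run_scan

BASE = Path(__file__).resolve().parent.parent / "results"

def main() -> None:
    sim, out = BASE / "sim", BASE / "scan"
    if not (sim / "cohort.vcf").exists():
        raise SystemExit("run analysis/01_simulate_quartet.py first")
    result = run_scan(
        sim / "cohort.vcf", sim / "family.ped", sim / "annotations.tsv",
        sim / "genesets.gmt", out,
    )
    print("variant funnel:")
    for stage, count in result.counts.as_list():
        print(f"  {stage:<20}{count}")
    metrics = run_evaluate(sim / "truth.json", out / "report.json", out / "metrics.json")
    print("recovery vs planted truth:", json.dumps(metrics))

if __name__ == "__main__":
    main()
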