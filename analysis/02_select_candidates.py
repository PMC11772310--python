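#!/usr/bin/env python
"""Run both candidate-selection cascades over the simulated fixture.

Strategy A (bait co-expression -> specificity -> oxidase keywords) should
recover the three planted cytochrome P450s; strategy B (cultivar enrichment
-> specificity -> "dehydrogenase") should return the planted SDR plus the
conserved NAD(P)H-complex fragment that a curator would then discard.
Reports are written to results/selection/.
"""

import json
import sys
from pathlib import Path

from lupin_miner import coexsel, io

BASE = Path(__file__).resolve().parent.parent / "results"
IN = BASE / "simulated"
OUT = BASE / "selection"


def main() -> None:
    if not (IN / "expression.tsv").exists():
        print("run 01_simulate.py first", file=sys.stderr)
        return 1
    OUT.mkdir(parents=True, exist_ok=True)
    matrix = coexsel.ExpressionMatrix.from_tsv(IN / "expression.tsv", IN / "samples.tsv")
    tables = io.read_blast_tables(IN / "blast.tsv")
    annotations = io.read_annotations(IN / "annotations.tsv")
    cfg = coexsel.SelectionConfig()

    for name, fn in (
        ("oxidase", coexsel.select_oxidase_candidates),
        ("dehydrogenase", coexsel.select_dehydrogenase_candidates),
    ):
        report = fn(matrix, tables, annotations, cfg)
        (OUT / f"{name}_report.json").write_text(json.dumps(report.to_dict(), indent=2))
        print(f"strategy {name}:")
        for stage, n in report.stage_counts:
            print(f"  {stage:24s} {n}")
        print(f"  -> {', '.join(report.candidate_ids) or '(none)'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
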