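#!/usr/bin/env python
"""Generate the synthetic study inputs.

Writes the two-cultivar expression fixture (5000 transcripts, 8 bitter + 5
sweet organ samples, planted pathway module around the LDC bait), the
per-transcript BLAST hit tables and annotations, and the ground-truth record,
all under results/simulated/.
"""

import sys
from pathlib import Path

from lupin_miner import io, synthgen

SEED = 20240
OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = synthgen.default_study_spec(SEED, n_transcripts=5000)
    matrix, annotations, truth = synthgen.gen_expression(spec)
    classes = {t: truth.planted_class.get(t, "general") for t in matrix.transcript_ids}
    tables = synthgen.gen_blast_tables(classes, seed=SEED)

    matrix.to_tsv(OUT / "expression.tsv", OUT / "samples.tsv")
    io.write_blast_tables(tables, OUT / "blast.tsv")
    io.write_annotations(annotations, OUT / "annotations.tsv")
    io.write_truth(truth, OUT / "truth.json")

    print(f"wrote {len(matrix.transcript_ids)} transcripts x "
          f"{len(matrix.samples)} samples to {OUT}")
    print(f"planted candidates: {', '.join(truth.planted_candidate_ids)}")


if __name__ == "__main__":
    sys.exit(main())
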