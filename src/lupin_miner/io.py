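"""Readers and writers for the plain-text exchange formats.

Expression matrices travel as TSV (transcript id column + one column per
sample) with a companion sample-metadata TSV; BLAST hits use the standard
12-column tabular layout (qseqid sseqid pident length mismatch gapopen qstart
qend sstart send evalue bitscore); annotations are two-column TSV; truth
records are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .coexsel import BlastHitTable

BLAST_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


def write_blast_tables(
    tables: Mapping[str, BlastHitTable], path: str | Path
) -> None:
    """Write hit tables as one concatenated 12-column tabular file.

    Alignment geometry columns not carried by :class:`BlastHitTable` are
    filled with plausible values derived from percent identity.
    """
    frames = []
    for tid, t in tables.items():
        n = len(t)
        length = np.full(n, 300)
        mismatch = np.round(length * (1 - t.pident / 100.0)).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "qseqid": tid,
                    "sseqid": t.sseqid,
                    "pident": np.round(t.pident, 3),
                    "length": length,
                    "mismatch": mismatch,
                    "gapopen": 0,
                    "qstart": 1,
                    "qend": length,
                    "sstart": 1,
                    "send": length,
                    "evalue": t.evalue,
                    "bitscore": np.round(t.bitscore, 1),
                }
            )
        )
    out = pd.concat(frames) if frames else pd.DataFrame(columns=BLAST_COLUMNS)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_blast_tables(path: str | Path) -> dict[str, BlastHitTable]:
    """Read a (possibly concatenated) 12-column tabular file, grouped by
    query id, each group re-ranked by descending bit score."""
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST_COLUMNS)
    tables: dict[str, BlastHitTable] = {}
    for qid, grp in df.groupby("qseqid", sort=False):
        tables[str(qid)] = BlastHitTable(
            query_id=str(qid),
            sseqid=grp["sseqid"].to_numpy(dtype=object),
            pident=grp["pident"].to_numpy(dtype=float),
            bitscore=grp["bitscore"].to_numpy(dtype=float),
            evalue=grp["evalue"].to_numpy(dtype=float),
        ).ensure_ranked()
    return tables


def write_annotations(annotations: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"transcript_id": list(annotations), "description": list(annotations.values())}
    ).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["transcript_id"].astype(str), df["description"].astype(str)))


def write_truth(truth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
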