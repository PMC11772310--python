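"""Shared fixtures: a small handcrafted selection fixture with known outcome."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lupin_miner.coexsel import BlastHitTable, ExpressionMatrix, SelectionConfig


def make_hit_table(query_id: str, pidents: list[float]) -> BlastHitTable:
    n = len(pidents)
    return BlastHitTable(
        query_id=query_id,
        sseqid=np.array([f"s{j}" for j in range(n)], dtype=object),
        pident=np.array(pidents, dtype=float),
        bitscore=np.linspace(500, 100, n),
        evalue=np.logspace(-50, -5, n),
    )


@pytest.fixture
def small_fixture():
    """Six transcripts over 4+3 samples with a fully hand-computable outcome.

    - OX1: tracks the bait, specific, oxidase annotation  -> strategy A hit
    - DECOY: tracks the bait, conserved (general)         -> rejected at specificity
    - SDR: moderate PCC, bitter-enriched, specific, 'dehydrogenase' -> strategy B hit
    - HOUSE: background housekeeping gene
    - LOW: below the TPM floor in the reference sample
    """
    samples = [
        "Oskar_young_leaf",
        "Oskar_stem",
        "Oskar_root",
        "Oskar_flower",
        "Tanjil_young_leaf",
        "Tanjil_stem",
        "Tanjil_root",
    ]
    meta = pd.DataFrame(
        {
            "sample": samples,
            "cultivar": ["Oskar"] * 4 + ["Tanjil"] * 3,
            "organ": ["young_leaf", "stem", "root", "flower"] * 1
            + ["young_leaf", "stem", "root"],
        }
    ).set_index("sample")
    rows = {
        "LDC": [200.0, 60.0, 10.0, 45.0, 5.0, 2.0, 1.0],
        "OX1": [400.0, 120.0, 20.0, 90.0, 8.0, 3.0, 2.0],  # 2x bait: PCC 1
        "DECOY": [210.0, 65.0, 12.0, 47.0, 6.0, 2.0, 1.0],  # tracks bait
        "SDR": [80.0, 70.0, 60.0, 75.0, 4.0, 3.0, 2.0],  # bitter-enriched, low PCC
        "HOUSE": [50.0, 55.0, 52.0, 49.0, 51.0, 53.0, 50.0],
        "LOW": [5.0, 900.0, 900.0, 900.0, 1.0, 1.0, 1.0],
    }
    values = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    matrix = ExpressionMatrix(values=values, meta=meta).validate()
    tables = {
        "OX1": make_hit_table("OX1", [65.0] * 12 + [90.0] * 18),  # specific
        "DECOY": make_hit_table("DECOY", [95.0] * 30),  # general
        "SDR": make_hit_table("SDR", [50.0] * 15 + [85.0] * 15),  # specific
        "HOUSE": make_hit_table("HOUSE", [92.0] * 30),
        "LOW": make_hit_table("LOW", [40.0] * 30),
    }
    annotations = {
        "LDC": "lysine decarboxylase",
        "OX1": "cytochrome P450 family 71 protein",
        "DECOY": "polyphenol oxidase, conserved",
        "SDR": "short-chain dehydrogenase/reductase family",
        "HOUSE": "60S ribosomal protein",
        "LOW": "cytochrome P450 family 94 protein",
    }
    cfg = SelectionConfig()
    return matrix, tables, annotations, cfg
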