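"""Independent reference implementations used only by the tests.

These deliberately avoid the library's vectorized code paths: plain-Python
loops over scalars, applied transcript-by-transcript, so they can act as
oracles for the production implementations.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def pearson_brute(x, y) -> float:
    """Direct evaluation of sum((x-mx)(y-my)) / sqrt(sum sq * sum sq)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x)
    dy = sum((b - my) ** 2 for b in y)
    return num / math.sqrt(dx * dy)


def gaussian_area(amplitude: float, sigma: float) -> float:
    return amplitude * sigma * math.sqrt(2.0 * math.pi)


def _is_specific(table, top_n, id_threshold, min_specific_hits) -> bool:
    if table is None or len(table) == 0:
        return True
    window = list(table.pident[: min(top_n, len(table))])
    count = sum(1 for p in window if p < id_threshold)
    return count >= min_specific_hits


def _keyword_hit(desc, keywords) -> bool:
    if desc is None:
        return False
    return any(kw.lower() in desc.lower() for kw in keywords)


def strategy_a_oracle(matrix, tables, annotations, cfg) -> set[str]:
    """Transcript-by-transcript re-application of the four oxidase-cascade rules."""
    samples = cfg.resolve_pcc_samples(matrix)
    bait = [float(matrix.values.loc[cfg.bait_id, s]) for s in samples]
    out = set()
    for tid in matrix.values.index:
        if tid == cfg.bait_id:
            continue
        if float(matrix.values.loc[tid, cfg.reference_sample]) < cfg.tpm_min:
            continue
        prof = [float(matrix.values.loc[tid, s]) for s in samples]
        if len(set(prof)) == 1 or len(set(bait)) == 1:
            continue
        if not pearson_brute(bait, prof) > cfg.pcc_min:
            continue
        if not _is_specific(
            tables.get(tid), cfg.top_n, cfg.id_threshold, cfg.min_specific_hits
        ):
            continue
        if not _keyword_hit(annotations.get(tid), cfg.keywords_oxidase):
            continue
        out.add(tid)
    return out


def strategy_b_oracle(matrix, tables, annotations, cfg) -> set[str]:
    """Transcript-by-transcript re-application of the dehydrogenase-cascade rules."""
    low_cv, high_cv, organ, max_ratio = cfg.ratio_rule
    low_samples = matrix.samples_of(low_cv, organ)
    high_samples = matrix.samples_of(high_cv, organ)
    out = set()
    for tid in matrix.values.index:
        if float(matrix.values.loc[tid, cfg.reference_sample]) < cfg.tpm_min:
            continue
        num = sum(float(matrix.values.loc[tid, s]) for s in low_samples) / len(low_samples)
        den = sum(float(matrix.values.loc[tid, s]) for s in high_samples) / len(high_samples)
        if den == 0:
            ratio = 0.0 if num == 0 else float("inf")
        else:
            ratio = num / den
        if ratio > max_ratio:
            continue
        if not _is_specific(
            tables.get(tid), cfg.top_n, cfg.id_threshold, cfg.min_specific_hits
        ):
            continue
        if not _keyword_hit(annotations.get(tid), cfg.keywords_dehydrogenase):
            continue
        out.add(tid)
    return out


def random_small_fixture(seed: int, n_transcripts: int = 50):
    """A 50-transcript, two-cultivar fixture built independently of the
    package's generator: random log-normal expression, random hit tables,
    random annotations drawn from a vocabulary that straddles the keyword
    lists."""
    from lupin_miner.coexsel import BlastHitTable, ExpressionMatrix

    rng = np.random.default_rng(seed)
    organs_b = ["young_leaf", "stem", "root", "flower"]
    organs_s = ["young_leaf", "stem", "root"]
    samples = [f"Oskar_{o}" for o in organs_b] + [f"Tanjil_{o}" for o in organs_s]
    meta = pd.DataFrame(
        {
            "sample": samples,
            "cultivar": ["Oskar"] * len(organs_b) + ["Tanjil"] * len(organs_s),
            "organ": organs_b + organs_s,
        }
    ).set_index("sample")
    ids = ["LDC"] + [f"g{i}" for i in range(1, n_transcripts)]
    values = pd.DataFrame(
        rng.lognormal(2.2, 1.0, size=(n_transcripts, len(samples))),
        index=ids,
        columns=samples,
    )
    # make a few transcripts track the bait so the PCC stage has survivors
    bait = values.loc["LDC"].to_numpy()
    for tid in rng.choice(ids[1:], size=8, replace=False):
        noise = rng.normal(0, 0.15 * bait.std(), size=len(samples))
        values.loc[tid] = np.abs(bait * rng.uniform(0.5, 2.0) + noise)
    vocab = [
        "cytochrome P450 monooxygenase",
        "flavin-containing monooxygenase",
        "polyphenol oxidase",
        "short-chain dehydrogenase/reductase",
        "alcohol dehydrogenase",
        "ribosomal protein S9",
        "tubulin alpha chain",
        "MYB transcription factor",
    ]
    annotations = {tid: vocab[int(rng.integers(len(vocab)))] for tid in ids}
    tables = {}
    for tid in ids:
        n = int(rng.integers(5, 45))
        tables[tid] = BlastHitTable(
            query_id=tid,
            sseqid=np.array([f"s{j}" for j in range(n)], dtype=object),
            pident=rng.uniform(30, 100, size=n),
            bitscore=np.sort(rng.uniform(50, 800, size=n))[::-1].copy(),
            evalue=rng.uniform(1e-50, 1e-3, size=n),
        )
    matrix = ExpressionMatrix(values=values, meta=meta).validate()
    return matrix, tables, annotations
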