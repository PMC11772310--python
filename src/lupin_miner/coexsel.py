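"""Bait-gene co-expression candidate selection over a two-cultivar TPM matrix.

Two cascades prioritize biosynthetic gene candidates:

* **Strategy A (oxidases)** — expression floor in the reference sample ->
  Pearson correlation to the bait above a threshold -> lineage-specificity
  from BLAST percent-identity profiles -> oxidative-enzyme keyword match.
* **Strategy B (dehydrogenases)** — expression floor -> bitter-over-sweet
  cultivar enrichment in leaves -> lineage specificity -> "dehydrogenase"
  keyword match.

The specificity rule labels a transcript *specific* when at least
``min_specific_hits`` of its first ``top_n`` BLAST hits fall strictly below
``id_threshold`` percent identity — i.e. the gene has no close homologues
outside the alkaloid-producing lineage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ZeroVarianceError

log = logging.getLogger(__name__)

DEFAULT_OXIDASE_KEYWORDS = (
    "cytochrome",
    "P450",
    "oxidase",
    "oxygenase",
    "monooxygenase",
    "peroxidase",
    "dioxygenase",
)


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Transcripts x samples TPM values plus per-sample cultivar/organ labels."""

    values: pd.DataFrame  # index: transcript id, columns: sample id
    meta: pd.DataFrame  # index: sample id; columns: cultivar, organ

    def validate(self) -> "ExpressionMatrix":
        if self.values.columns.duplicated().any():
            raise ValueError("sample ids must be unique")
        if len(self.values) and (self.values.to_numpy() < 0).any():
            raise ValueError("TPM values must be >= 0")
        missing = set(self.values.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"metadata missing for samples: {sorted(missing)}")
        return self

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, cultivar: str | None = None, organ: str | None = None) -> list[str]:
        m = self.meta.loc[list(self.values.columns)]
        keep = pd.Series(True, index=m.index)
        if cultivar is not None:
            keep &= m["cultivar"] == cultivar
        if organ is not None:
            keep &= m["organ"] == organ
        return list(m.index[keep])

    def mean_tpm(self, transcript_id: str, cultivar: str, organ: str) -> float:
        """Arithmetic mean TPM over all replicates of (cultivar, organ)."""
        cols = self.samples_of(cultivar, organ)
        if not cols:
            raise ConfigError(f"no sample for cultivar={cultivar!r}, organ={organ!r}")
        return float(self.values.loc[transcript_id, cols].mean())

    # -- TSV round trip -----------------------------------------------------

    def to_tsv(self, expr_path: str | Path, meta_path: str | Path) -> None:
        self.values.rename_axis("transcript_id").to_csv(expr_path, sep="\t")
        self.meta.rename_axis("sample").to_csv(meta_path, sep="\t")

    @classmethod
    def from_tsv(cls, expr_path: str | Path, meta_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(values=values, meta=meta).validate()


@dataclass
class BlastHitTable:
    """Ranked BLAST hits for one query transcript.

    Rows are kept in BLAST's native ranking: descending bit score, ties broken
    by ascending e-value then subject id. :meth:`ensure_ranked` restores that
    order for tables read from unsorted files.
    """

    query_id: str
    sseqid: np.ndarray
    pident: np.ndarray
    bitscore: np.ndarray
    evalue: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.pident)
        if not (len(self.sseqid) == len(self.bitscore) == len(self.evalue) == n):
            raise ValueError("hit table columns must have equal length")
        if n and (np.min(self.pident) < 0 or np.max(self.pident) > 100):
            raise ValueError("percent identity must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.pident)

    def ensure_ranked(self) -> "BlastHitTable":
        order = np.lexsort((self.sseqid, self.evalue, -self.bitscore))
        return BlastHitTable(
            query_id=self.query_id,
            sseqid=self.sseqid[order],
            pident=self.pident[order],
            bitscore=self.bitscore[order],
            evalue=self.evalue[order],
        )


@dataclass
class SelectionConfig:
    """Thresholds of the two selection cascades; defaults are the published values."""

    tpm_min: float = 10.0
    reference_sample: str = "Oskar_young_leaf"
    bait_id: str = "LDC"
    pcc_min: float = 0.9
    pcc_cultivar: str | None = "Oskar"  # None -> all samples
    pcc_samples: tuple[str, ...] | None = None  # explicit override
    top_n: int = 30
    id_threshold: float = 70.0
    min_specific_hits: int = 10
    keywords_oxidase: tuple[str, ...] = DEFAULT_OXIDASE_KEYWORDS
    keywords_dehydrogenase: tuple[str, ...] = ("dehydrogenase",)
    # (numerator/low-QA cultivar, denominator/high-QA cultivar, organ, max ratio)
    ratio_rule: tuple[str, str, str, float] = ("Tanjil", "Oskar", "young_leaf", 1.0)

    def __post_init__(self) -> None:
        if not 0 < self.pcc_min <= 1:
            raise ConfigError("pcc_min must lie in (0, 1]")
        if not 0 < self.id_threshold <= 100:
            raise ConfigError("id_threshold must lie in (0, 100]")
        if self.min_specific_hits > self.top_n:
            raise ConfigError("min_specific_hits cannot exceed top_n")

    def resolve_pcc_samples(self, matrix: ExpressionMatrix) -> list[str]:
        if self.pcc_samples is not None:
            return list(self.pcc_samples)
        if self.pcc_cultivar is not None:
            return matrix.samples_of(cultivar=self.pcc_cultivar)
        return matrix.samples

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "tpm_min": self.tpm_min,
            "reference_sample": self.reference_sample,
            "bait_id": self.bait_id,
            "pcc_min": self.pcc_min,
            "pcc_cultivar": self.pcc_cultivar,
            "pcc_samples": list(self.pcc_samples) if self.pcc_samples else None,
            "top_n": self.top_n,
            "id_threshold": self.id_threshold,
            "min_specific_hits": self.min_specific_hits,
            "keywords_oxidase": list(self.keywords_oxidase),
            "keywords_dehydrogenase": list(self.keywords_dehydrogenase),
            "ratio_rule": list(self.ratio_rule),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SelectionConfig":
        doc = yaml.safe_load(Path(path).read_text())
        kwargs = dict(doc)
        for key in ("keywords_oxidase", "keywords_dehydrogenase", "pcc_samples"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(kwargs[key])
        if kwargs.get("ratio_rule") is not None:
            kwargs["ratio_rule"] = tuple(kwargs["ratio_rule"])
        return cls(**kwargs)


@dataclass
class CandidateReport:
    """Survivors of a cascade plus per-stage bookkeeping.

    ``stage_counts`` is ordered from the full input down to the final keyword
    stage; the counts are monotone nonincreasing by construction.
    """

    strategy: str
    stage_counts: list[tuple[str, int]]
    candidates: list[dict]
    dropped_zero_variance: int = 0
    no_hit_ids: list[str] = field(default_factory=list)

    @property
    def candidate_ids(self) -> list[str]:
        return [c["transcript_id"] for c in self.candidates]

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "stage_counts": [[s, n] for s, n in self.stage_counts],
            "candidates": self.candidates,
            "dropped_zero_variance": self.dropped_zero_variance,
            "no_hit_ids": self.no_hit_ids,
        }


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------


def filter_min_expression(
    matrix: ExpressionMatrix, sample: str, tpm_min: float
) -> set[str]:
    """Transcripts whose TPM in ``sample`` is at or above the floor.

    The published rule removes "< floor", so values exactly at the floor stay.
    """
    if sample not in matrix.values.columns:
        raise KeyError(f"sample {sample!r} not in matrix")
    col = matrix.values[sample]
    return set(col.index[col >= tpm_min])


def pcc(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation of two expression profiles."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("vectors must have equal length")
    if len(xa) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise ZeroVarianceError("correlation undefined for a constant vector")
    r = float(np.corrcoef(xa, ya)[0, 1])
    return min(1.0, max(-1.0, r))


def coexpression_candidates(
    matrix: ExpressionMatrix,
    bait: str,
    samples: Sequence[str],
    pcc_min: float,
) -> list[tuple[str, float]]:
    """All transcripts whose PCC to the bait over ``samples`` strictly exceeds
    ``pcc_min``, sorted by descending PCC (ties broken lexicographically).

    The bait is excluded from its own ranking; constant transcripts are
    dropped (their correlation is undefined) with a logged count.
    """
    if bait not in matrix.values.index:
        raise KeyError(f"bait {bait!r} not in matrix")
    if len(samples) < 3:
        raise ValueError("need at least 3 samples for correlation")
    sub = matrix.values.loc[:, list(samples)].to_numpy(dtype=float)
    ids = matrix.values.index.to_numpy()
    bait_vec = matrix.values.loc[bait, list(samples)].to_numpy(dtype=float)
    bc = bait_vec - bait_vec.mean()
    nb = np.linalg.norm(bc)
    if nb == 0:
        raise ZeroVarianceError("bait profile constant over the chosen samples")
    centred = sub - sub.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    zero_var = norms == 0
    n_dropped = int(zero_var.sum()) - (1 if zero_var[ids == bait].any() else 0)
    if n_dropped > 0:
        log.info("dropped %d zero-variance transcripts before correlation", n_dropped)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centred @ bc) / (norms * nb)
    r = np.clip(r, -1.0, 1.0)
    keep = (~zero_var) & (ids != bait) & (r > pcc_min)
    out = [(str(tid), float(rv)) for tid, rv in zip(ids[keep], r[keep])]
    out.sort(key=lambda item: (-item[1], item[0]))
    return out


def specificity_classify(
    table: BlastHitTable | None,
    top_n: int = 30,
    id_threshold: float = 70.0,
    min_specific_hits: int = 10,
) -> tuple[str, int]:
    """Lineage-specificity verdict from the first ``top_n`` ranked hits.

    Counts hits with percent identity strictly below ``id_threshold``; the
    transcript is *specific* when that count reaches ``min_specific_hits``.
    A missing or empty table classifies as specific — absence of homologues is
    the strongest form of the criterion (callers log these separately).
    """
    if table is None or len(table) == 0:
        return "specific", 0
    window = table.pident[: min(top_n, len(table))]
    count = int(np.sum(window < id_threshold))
    verdict = "specific" if count >= min_specific_hits else "general"
    return verdict, count


def keyword_filter(
    annotations: Mapping[str, str],
    ids: Iterable[str],
    keywords: Sequence[str],
) -> dict[str, str]:
    """Case-insensitive substring keyword screen over functional annotations.

    Returns surviving id -> first matching keyword. Transcripts without an
    annotation are treated as non-matches and logged.
    """
    if not keywords:
        raise ConfigError("keyword list must not be empty")
    lowered = [(kw, kw.lower()) for kw in keywords]
    out: dict[str, str] = {}
    for tid in ids:
        desc = annotations.get(tid)
        if desc is None:
            log.info("transcript %s has no annotation; treated as non-match", tid)
            continue
        dl = desc.lower()
        for kw, kwl in lowered:
            if kwl in dl:
                out[tid] = kw
                break
    return out


def cultivar_ratio(
    matrix: ExpressionMatrix, transcript_id: str, organ: str, high_cv: str, low_cv: str
) -> float:
    """Low-cultivar over high-cultivar mean TPM in one organ.

    0/0 is treated as ratio 0 (absent everywhere survives downstream); a
    positive numerator over a zero denominator maps to +inf.
    """
    num = matrix.mean_tpm(transcript_id, low_cv, organ)
    den = matrix.mean_tpm(transcript_id, high_cv, organ)
    if den == 0:
        return 0.0 if num == 0 else float("inf")
    return num / den


def cultivar_ratio_filter(
    matrix: ExpressionMatrix,
    ids: Iterable[str],
    organ: str,
    high_cv: str,
    low_cv: str,
    max_ratio: float = 1.0,
) -> set[str]:
    """Keep transcripts not enriched in the low-alkaloid cultivar.

    A transcript survives when mean TPM(low)/mean TPM(high) for ``organ`` is
    at most ``max_ratio`` (the published rule removes only ratios > 1).
    """
    for cv in (high_cv, low_cv):
        if not matrix.samples_of(cv, organ):
            raise ConfigError(f"organ {organ!r} absent for cultivar {cv!r}")
    return {
        tid
        for tid in ids
        if cultivar_ratio(matrix, tid, organ, high_cv, low_cv) <= max_ratio
    }


# ---------------------------------------------------------------------------
# Cascades
# ---------------------------------------------------------------------------


def _empty_report(strategy: str, stages: Sequence[str]) -> CandidateReport:
    return CandidateReport(
        strategy=strategy, stage_counts=[(s, 0) for s in stages], candidates=[]
    )


def _specificity_stage(
    ids: Iterable[str],
    blast_tables: Mapping[str, BlastHitTable],
    config: SelectionConfig,
) -> tuple[dict[str, int], list[str]]:
    """Apply the specificity classifier; returns surviving id -> supporting
    count and the ids that had no hit table at all."""
    survivors: dict[str, int] = {}
    no_hits: list[str] = []
    for tid in ids:
        table = blast_tables.get(tid)
        if table is None or len(table) == 0:
            no_hits.append(tid)
        verdict, count = specificity_classify(
            table, config.top_n, config.id_threshold, config.min_specific_hits
        )
        if verdict == "specific":
            survivors[tid] = count
    return survivors, no_hits


def select_oxidase_candidates(
    matrix: ExpressionMatrix,
    blast_tables: Mapping[str, BlastHitTable],
    annotations: Mapping[str, str],
    config: SelectionConfig,
) -> CandidateReport:
    """Strategy A: expression floor -> bait PCC -> specificity -> oxidase keywords."""
    stages = ["input", "tpm_floor", "pcc", "specificity", "keyword_oxidase"]
    if len(matrix.values) == 0:
        return _empty_report("oxidase", stages)

    floor_ids = filter_min_expression(matrix, config.reference_sample, config.tpm_min)
    samples = config.resolve_pcc_samples(matrix)
    ranked = coexpression_candidates(matrix, config.bait_id, samples, config.pcc_min)
    pcc_by_id = {tid: r for tid, r in ranked if tid in floor_ids}
    spec_counts, no_hits = _specificity_stage(pcc_by_id, blast_tables, config)
    matched = keyword_filter(annotations, spec_counts, config.keywords_oxidase)

    candidates = [
        {
            "transcript_id": tid,
            "pcc": pcc_by_id[tid],
            "specificity_count": spec_counts[tid],
            "matched_keyword": matched[tid],
        }
        for tid in sorted(matched, key=lambda t: (-pcc_by_id[t], t))
    ]
    counts = [
        ("input", len(matrix.values)),
        ("tpm_floor", len(floor_ids)),
        ("pcc", len(pcc_by_id)),
        ("specificity", len(spec_counts)),
        ("keyword_oxidase", len(candidates)),
    ]
    return CandidateReport(
        strategy="oxidase",
        stage_counts=counts,
        candidates=candidates,
        no_hit_ids=no_hits,
    )


def select_dehydrogenase_candidates(
    matrix: ExpressionMatrix,
    blast_tables: Mapping[str, BlastHitTable],
    annotations: Mapping[str, str],
    config: SelectionConfig,
) -> CandidateReport:
    """Strategy B: expression floor -> cultivar enrichment -> specificity ->
    "dehydrogenase" keyword. Survivors are meant for downstream manual
    curation (conserved housekeeping fragments are flagged, not auto-removed).
    """
    stages = ["input", "tpm_floor", "cultivar_ratio", "specificity", "keyword_dehydrogenase"]
    if len(matrix.values) == 0:
        return _empty_report("dehydrogenase", stages)

    low_cv, high_cv, organ, max_ratio = config.ratio_rule
    floor_ids = filter_min_expression(matrix, config.reference_sample, config.tpm_min)
    ratio_ids = cultivar_ratio_filter(
        matrix, floor_ids, organ, high_cv=high_cv, low_cv=low_cv, max_ratio=max_ratio
    )
    spec_counts, no_hits = _specificity_stage(ratio_ids, blast_tables, config)
    matched = keyword_filter(annotations, spec_counts, config.keywords_dehydrogenase)

    ratios = {
        tid: cultivar_ratio(matrix, tid, organ, high_cv, low_cv) for tid in matched
    }
    candidates = [
        {
            "transcript_id": tid,
            "cultivar_ratio": ratios[tid],
            "specificity_count": spec_counts[tid],
            "matched_keyword": matched[tid],
        }
        for tid in sorted(matched, key=lambda t: (ratios[t], t))
    ]
    counts = [
        ("input", len(matrix.values)),
        ("tpm_floor", len(floor_ids)),
        ("cultivar_ratio", len(ratio_ids)),
        ("specificity", len(spec_counts)),
        ("keyword_dehydrogenase", len(candidates)),
    ]
    return CandidateReport(
        strategy="dehydrogenase",
        stage_counts=counts,
        candidates=candidates,
        no_hit_ids=no_hits,
    )
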