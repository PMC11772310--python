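"""Ground-truth-annotated synthetic inputs for the selection and quantification pipelines.

Three generators emulate the statistical structure of the study data:

* :func:`gen_expression` — a transcripts x samples TPM matrix for a bitter
  (high-alkaloid) and a sweet (low-alkaloid) cultivar, with a co-expressed
  pathway module planted around a lysine-decarboxylase bait gene at exact
  target Pearson correlations, plus log-normal background transcripts
  rejection-sampled below a correlation cap.
* :func:`gen_blast_table` — 12-column BLAST-style hit tables whose percent
  identity distribution realizes a chosen lineage-specificity class.
* :func:`gen_ms_run` — centroided LC-MS/GC-MS acquisitions with Gaussian
  analyte elution profiles, an internal standard, blank-matched contaminant
  features, and optionally split enantiomer pairs.

Every generator is driven by one explicit integer seed and is bit-reproducible.
Units: time in minutes, m/z in Thomson, intensity in arbitrary counts, TPM
unitless (each sample sums to 1e6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chromquant import MsRun, Scan
from .coexsel import BlastHitTable, ExpressionMatrix
from .errors import GenerationError

_SQRT2PI = math.sqrt(2.0 * math.pi)

DEFAULT_BITTER_ORGANS = (
    "young_leaf",
    "mature_leaf",
    "stem",
    "root",
    "flower",
    "pod",
    "immature_seed",
    "mature_seed",
)
DEFAULT_SWEET_ORGANS = ("young_leaf", "stem", "root", "flower", "immature_seed")

# Bait (LDC) expression template: strongly biosynthetic in bitter leaves and
# pods, near-silent in the sweet cultivar whose pathway is down-regulated.
_DEFAULT_BAIT_PROFILE: dict[tuple[str, str], float] = {
    ("Oskar", "young_leaf"): 220.0,
    ("Oskar", "mature_leaf"): 130.0,
    ("Oskar", "stem"): 60.0,
    ("Oskar", "root"): 8.0,
    ("Oskar", "flower"): 45.0,
    ("Oskar", "pod"): 90.0,
    ("Oskar", "immature_seed"): 30.0,
    ("Oskar", "mature_seed"): 2.0,
    ("Tanjil", "young_leaf"): 6.0,
    ("Tanjil", "stem"): 2.0,
    ("Tanjil", "root"): 1.0,
    ("Tanjil", "flower"): 3.0,
    ("Tanjil", "immature_seed"): 1.0,
}

# Background annotation vocabulary deliberately free of the oxidase keyword
# list except through the conserved dehydrogenase entries, which exercise the
# specificity filter's exclusion path.
_BACKGROUND_ANNOTATIONS = (
    "60S ribosomal protein L7",
    "tubulin beta chain",
    "heat shock protein 70",
    "serine/threonine protein kinase",
    "ABC transporter B family member",
    "pentatricopeptide repeat-containing protein",
    "alcohol dehydrogenase class-3",
    "photosystem II protein D1",
    "ubiquitin-conjugating enzyme E2",
    "aquaporin PIP2-1",
    "histone H3.2",
    "MYB-related transcription factor",
    "chlorophyll a-b binding protein",
    "glutathione S-transferase U17",
    "expansin-A4",
    "sucrose synthase 2",
    "actin-depolymerizing factor",
    "malate dehydrogenase, cytosolic",
)


# ---------------------------------------------------------------------------
# Specs and truth record
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedGene:
    """One transcript planted into the synthetic matrix with known truth.

    ``sweet_scale`` sets the sweet-cultivar expression as a fraction of the
    matching bitter organ value; values <= 1 make the gene bitter-enriched
    (surviving the cultivar-ratio filter), values > 1 make it sweet-enriched.
    """

    transcript_id: str
    target_pcc: float
    specificity: str  # "specific" | "general"
    annotation: str
    sweet_scale: float = 0.1

    def __post_init__(self) -> None:
        if not -1.0 <= self.target_pcc <= 1.0:
            raise GenerationError(f"target PCC {self.target_pcc} outside [-1, 1]")
        if self.specificity not in ("specific", "general"):
            raise GenerationError(f"unknown specificity class {self.specificity!r}")


@dataclass
class ExpressionSimSpec:
    """Parameters of the synthetic two-cultivar expression matrix."""

    n_transcripts: int = 5000
    cultivars: tuple[str, str] = ("Oskar", "Tanjil")  # (bitter, sweet)
    organs_bitter: tuple[str, ...] = DEFAULT_BITTER_ORGANS
    organs_sweet: tuple[str, ...] = DEFAULT_SWEET_ORGANS
    bait_id: str = "LDC"
    bait_profile: Mapping[tuple[str, str], float] | None = None
    planted: tuple[PlantedGene, ...] = ()
    background_correlation_cap: float = 0.8
    reference_organ: str = "young_leaf"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < len(self.planted) + 1:
            raise GenerationError(
                "n_transcripts must cover every planted gene plus the bait"
            )
        if not self.background_correlation_cap < 0.9:
            raise GenerationError("background_correlation_cap must be < 0.9")

    def resolved_bait_profile(self) -> dict[tuple[str, str], float]:
        if self.bait_profile is not None:
            return dict(self.bait_profile)
        return dict(_DEFAULT_BAIT_PROFILE)


@dataclass(frozen=True)
class Analyte:
    """A simulated chromatographic analyte with a Gaussian elution profile.

    When ``enantiomer_split`` is given as (f_target, f_antipode) summing to 1,
    the amplitude is divided over two peaks at ``rt`` and
    ``rt + enantiomer_rt_offset`` sharing the same m/z channel.
    """

    name: str
    mz: float
    rt: float
    sigma: float
    amplitude: float
    enantiomer_split: tuple[float, float] | None = None
    enantiomer_rt_offset: float = 0.8

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise GenerationError("analyte amplitude must be >= 0")
        if self.sigma <= 0:
            raise GenerationError("analyte sigma must be > 0")
        if self.enantiomer_split is not None:
            f1, f2 = self.enantiomer_split
            if not (0 <= f1 <= 1 and 0 <= f2 <= 1):
                raise GenerationError("enantiomer fractions must lie in [0, 1]")
            if abs(f1 + f2 - 1.0) > 1e-9:
                raise GenerationError("enantiomer fractions must sum to 1")


@dataclass
class ChromSimSpec:
    """Parameters of a simulated centroided LC-MS/GC-MS acquisition."""

    analytes: tuple[Analyte, ...] = ()
    noise_sd: float = 0.0  # additive counts noise per centroid
    scan_interval: float = 0.01  # min
    run_length: float = 12.0  # min
    mz_jitter_sd: float = 0.0  # Th
    amplitude_cv: float = 0.0  # multiplicative log-normal amplitude noise
    blank_features: tuple[tuple[float, float, float], ...] = ()  # (mz, rt, amp)
    blank_sigma: float = 0.05  # shared elution width of blank features, min
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scan_interval <= 0:
            raise GenerationError("scan_interval must be > 0")
        for a in self.analytes:
            if not 0 <= a.rt <= self.run_length:
                raise GenerationError(f"analyte {a.name} elutes outside the run")
        for mz, rt, amp in self.blank_features:
            if not 0 <= rt <= self.run_length:
                raise GenerationError("blank feature elutes outside the run")
            if amp < 0:
                raise GenerationError("blank feature amplitude must be >= 0")


@dataclass
class TruthRecord:
    """Ground truth accompanying every generated artefact."""

    planted_candidate_ids: list[str] = field(default_factory=list)
    planted_pcc: dict[str, float] = field(default_factory=dict)
    planted_class: dict[str, str] = field(default_factory=dict)
    planted_annotation: dict[str, str] = field(default_factory=dict)
    analyte_truth: dict[str, dict] = field(default_factory=dict)
    overlapping_analytes: list[str] = field(default_factory=list)

    def validate(self) -> "TruthRecord":
        for name, info in self.analyte_truth.items():
            fr = info.get("enantiomer_fractions")
            if fr is not None:
                if not all(0 <= f <= 1 for f in fr):
                    raise GenerationError(f"{name}: enantiomer fractions outside [0,1]")
                if abs(sum(fr) - 1.0) > 1e-9:
                    raise GenerationError(f"{name}: enantiomer fractions must sum to 1")
        return self

    def to_dict(self) -> dict:
        return {
            "planted_candidate_ids": self.planted_candidate_ids,
            "planted_pcc": self.planted_pcc,
            "planted_class": self.planted_class,
            "planted_annotation": self.planted_annotation,
            "analyte_truth": self.analyte_truth,
            "overlapping_analytes": self.overlapping_analytes,
        }


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------


def tpm_from_counts(counts: Sequence[float], lengths: Sequence[float]) -> np.ndarray:
    """Transcripts-per-million from read counts and effective lengths.

    TPM_i = 1e6 * (c_i / l_i) / sum_j (c_j / l_j); the output sums to 1e6.
    """
    c = np.asarray(counts, dtype=float)
    l = np.asarray(lengths, dtype=float)
    if c.shape != l.shape:
        raise ValueError("counts and lengths must have equal length")
    if np.any(l <= 0):
        raise ValueError("effective lengths must be > 0")
    if np.any(c < 0):
        raise ValueError("counts must be >= 0")
    rate = c / l
    total = rate.sum()
    if total <= 0:
        raise ZeroDivisionError("all counts are zero; TPM normalization undefined")
    return 1e6 * rate / total


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


def _exact_corr_profile(
    bait: np.ndarray, rho: float, rng: np.random.Generator, ref_idx: int, floor: float
) -> np.ndarray:
    """Build a non-negative profile whose Pearson correlation with ``bait`` is
    exactly ``rho``: combine the unit-centred bait direction with an orthogonal
    unit residual as rho*x + sqrt(1-rho^2)*z, then map affinely (positive
    slope) into TPM space. Redraws the residual until the reference sample
    clears ``floor`` (so planted genes always pass the expression filter)."""
    xc = bait - bait.mean()
    nx = np.linalg.norm(xc)
    if nx == 0:
        raise GenerationError("bait profile has zero variance over these samples")
    xhat = xc / nx
    mean = bait.mean()
    for _ in range(200):
        if abs(rho) == 1.0:
            yc = math.copysign(1.0, rho) * xhat
        else:
            z = rng.standard_normal(len(bait))
            zc = z - z.mean()
            zo = zc - (zc @ xhat) * xhat
            nz = np.linalg.norm(zo)
            if nz < 1e-9:
                continue
            yc = rho * xhat + math.sqrt(1.0 - rho * rho) * (zo / nz)
        # positive-slope affine map: keep bait-like scale but stay positive
        lo = yc.min()
        beta = nx
        if lo < 0:
            beta = min(beta, 0.95 * (mean - 1.0) / (-lo))
        if beta <= 0:
            continue
        prof = mean + beta * yc
        if prof[ref_idx] >= floor and prof.min() >= 0:
            return prof
    raise GenerationError("could not realize the target PCC with a positive profile")


def gen_expression(
    spec: ExpressionSimSpec,
) -> tuple[ExpressionMatrix, dict[str, str], TruthRecord]:
    """Generate the two-cultivar TPM matrix, annotations and truth record.

    Planted genes hit their target PCC to the bait exactly (computed over the
    bitter-cultivar samples); background transcripts are log-normal draws
    rejection-sampled until every |PCC| stays below the correlation cap.
    """
    rng = np.random.default_rng(spec.seed)
    bitter, sweet = spec.cultivars
    samples = [f"{bitter}_{o}" for o in spec.organs_bitter] + [
        f"{sweet}_{o}" for o in spec.organs_sweet
    ]
    meta = pd.DataFrame(
        {
            "sample": samples,
            "cultivar": [bitter] * len(spec.organs_bitter)
            + [sweet] * len(spec.organs_sweet),
            "organ": list(spec.organs_bitter) + list(spec.organs_sweet),
        }
    ).set_index("sample")

    profile = spec.resolved_bait_profile()
    bait_row = np.array(
        [
            profile.get((meta.loc[s, "cultivar"], meta.loc[s, "organ"]), 0.0)
            for s in samples
        ]
    )
    n_bitter = len(spec.organs_bitter)
    bitter_cols = np.arange(n_bitter)
    ref_idx = list(spec.organs_bitter).index(spec.reference_organ)

    ids: list[str] = [spec.bait_id]
    rows: list[np.ndarray] = [bait_row]

    # planted genes: exact-PCC bitter block + scaled sweet block
    for g in spec.planted:
        bitter_part = _exact_corr_profile(
            bait_row[bitter_cols], g.target_pcc, rng, ref_idx, floor=12.0
        )
        sweet_part = np.array(
            [
                g.sweet_scale
                * bitter_part[list(spec.organs_bitter).index(o)]
                * rng.uniform(0.7, 1.0)
                for o in spec.organs_sweet
            ]
        )
        ids.append(g.transcript_id)
        rows.append(np.concatenate([bitter_part, sweet_part]))

    # background transcripts: log-normal, rejection-sampled under the PCC cap
    n_bg = spec.n_transcripts - 1 - len(spec.planted)
    if n_bg > 0:
        vals = rng.lognormal(mean=1.8, sigma=1.1, size=(n_bg, len(samples)))
        xb = bait_row[bitter_cols]
        xc = xb - xb.mean()
        nx = np.linalg.norm(xc)
        for _ in range(200):
            sub = vals[:, bitter_cols]
            subc = sub - sub.mean(axis=1, keepdims=True)
            norms = np.linalg.norm(subc, axis=1)
            norms[norms == 0] = np.inf  # constant rows: undefined PCC, redraw
            r = (subc @ xc) / (norms * nx)
            bad = (np.abs(r) >= spec.background_correlation_cap) | ~np.isfinite(r)
            bad |= norms == np.inf
            if not bad.any():
                break
            vals[bad] = rng.lognormal(
                mean=1.8, sigma=1.1, size=(int(bad.sum()), len(samples))
            )
        else:
            raise GenerationError("background rejection sampling did not converge")
        for i in range(n_bg):
            ids.append(f"LOC{100000 + i}")
            rows.append(vals[i])

    values = pd.DataFrame(np.vstack(rows), index=ids, columns=samples)
    matrix = ExpressionMatrix(values=values, meta=meta).validate()

    annotations = {spec.bait_id: "lysine decarboxylase"}
    for g in spec.planted:
        annotations[g.transcript_id] = g.annotation
    bg_ids = ids[1 + len(spec.planted) :]
    if bg_ids:
        choices = rng.choice(len(_BACKGROUND_ANNOTATIONS), size=len(bg_ids))
        for tid, ci in zip(bg_ids, choices):
            annotations[tid] = _BACKGROUND_ANNOTATIONS[int(ci)]

    truth = TruthRecord(
        planted_candidate_ids=[g.transcript_id for g in spec.planted],
        planted_pcc={g.transcript_id: g.target_pcc for g in spec.planted},
        planted_class={g.transcript_id: g.specificity for g in spec.planted},
        planted_annotation={g.transcript_id: g.annotation for g in spec.planted},
    ).validate()
    return matrix, annotations, truth


def default_study_spec(seed: int, n_transcripts: int = 5000) -> ExpressionSimSpec:
    """The canonical selection fixture: three lineage-specific oxidases
    strongly co-expressed with the bait, one short-chain
    dehydrogenase/reductase, one conserved NAD(P)H-complex fragment that
    shares the dehydrogenase keyword, and one conserved high-PCC oxidase decoy
    that the specificity filter must reject."""
    planted = (
        PlantedGene("CYP76E36", 0.97, "specific", "cytochrome P450 family 76 subfamily E"),
        PlantedGene("CYP71A168", 0.97, "specific", "cytochrome P450 71A, putative monooxygenase"),
        PlantedGene("CYP71D189", 0.97, "specific", "cytochrome P450 family 71 subfamily D"),
        PlantedGene(
            "SDR1",
            0.62,
            "specific",
            "(−)-isopiperitenol/(−)-carveol dehydrogenase, short-chain dehydrogenase/reductase",
        ),
        PlantedGene(
            "CRR3_FRAGMENT",
            0.55,
            "specific",
            "NAD(P)H dehydrogenase complex subunit CRR3, fragment",
        ),
        PlantedGene("CONSERVED_OXIDASE_DECOY", 0.97, "general", "polyphenol oxidase, conserved"),
    )
    return ExpressionSimSpec(n_transcripts=n_transcripts, planted=planted, seed=seed)


# ---------------------------------------------------------------------------
# BLAST-style hit tables
# ---------------------------------------------------------------------------


def gen_blast_table(
    specificity_class: str,
    top_n: int = 30,
    seed: int | np.random.Generator = 0,
    query_id: str = "query",
) -> BlastHitTable:
    """Generate one ranked hit table realizing a lineage-specificity class.

    ``"specific"`` tables place >= 10 of the first 30 hits below 70 %ID;
    ``"general"`` tables place at most 9 there. Rows are sorted by descending
    bit score.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if specificity_class not in ("specific", "general"):
        raise ValueError(f"unknown specificity class {specificity_class!r}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    window = min(top_n, 30)
    if specificity_class == "specific":
        n_low = int(rng.integers(12, max(13, window - 3)))
    else:
        n_low = int(rng.integers(0, 6))
    n_low = min(n_low, window)
    pident = rng.uniform(72.0, 98.0, size=top_n)
    low_pos = rng.choice(window, size=n_low, replace=False)
    pident[low_pos] = rng.uniform(35.0, 68.0, size=n_low)
    if top_n > 30:
        pident[30:] = rng.uniform(35.0, 98.0, size=top_n - 30)
    bitscore = np.sort(rng.uniform(80.0, 900.0, size=top_n))[::-1].copy()
    evalue = np.power(10.0, -bitscore / 10.0)
    sseqid = np.array([f"sp{i:05d}" for i in rng.integers(0, 99999, size=top_n)])
    return BlastHitTable(
        query_id=query_id,
        sseqid=sseqid,
        pident=pident,
        bitscore=bitscore,
        evalue=evalue,
    )


def gen_blast_tables(
    classes: Mapping[str, str], top_n: int = 30, seed: int = 0
) -> dict[str, BlastHitTable]:
    """Generate one hit table per transcript id, deterministically."""
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    return {
        tid: gen_blast_table(cls, top_n=top_n, seed=rng, query_id=tid)
        for tid, cls in classes.items()
    }


# ---------------------------------------------------------------------------
# Chromatographic runs
# ---------------------------------------------------------------------------


def _expand_components(
    spec: ChromSimSpec, rng: np.random.Generator
) -> tuple[list[tuple[str, float, float, float, float]], dict[str, dict], list[str]]:
    """Resolve analytes into elution components (name, mz, rt, sigma, amp),
    applying enantiomer splits and multiplicative amplitude noise. Returns the
    components, the per-analyte truth dict, and any (mz, rt) collisions."""
    components: list[tuple[str, float, float, float, float]] = []
    truth: dict[str, dict] = {}
    seen: dict[tuple[float, float], str] = {}
    overlaps: list[str] = []
    for a in spec.analytes:
        amp = a.amplitude
        if spec.amplitude_cv > 0:
            amp *= float(np.exp(rng.normal(0.0, spec.amplitude_cv)))
        entry: dict = {"rt": a.rt, "mz": a.mz, "enantiomer_fractions": None}
        if a.enantiomer_split is None:
            components.append((a.name, a.mz, a.rt, a.sigma, amp))
            entry["area"] = amp * a.sigma * _SQRT2PI
        else:
            f1, f2 = a.enantiomer_split
            rt2 = a.rt + a.enantiomer_rt_offset
            components.append((f"{a.name}_target", a.mz, a.rt, a.sigma, amp * f1))
            components.append((f"{a.name}_antipode", a.mz, rt2, a.sigma, amp * f2))
            entry["enantiomer_fractions"] = (f1, f2)
            entry["area"] = amp * a.sigma * _SQRT2PI
            entry["component_areas"] = {
                f"{a.name}_target": amp * f1 * a.sigma * _SQRT2PI,
                f"{a.name}_antipode": amp * f2 * a.sigma * _SQRT2PI,
            }
        key = (round(a.mz, 6), round(a.rt, 6))
        if key in seen:
            overlaps.append(f"{seen[key]}|{a.name}")
        seen[key] = a.name
        truth[a.name] = entry
    return components, truth, overlaps


def _build_run(
    components: Sequence[tuple[str, float, float, float, float]],
    spec: ChromSimSpec,
    rng: np.random.Generator,
    label: str,
) -> MsRun:
    times = np.arange(0.0, spec.run_length + 1e-9, spec.scan_interval)
    n = len(times)
    per_scan_mz: list[list[float]] = [[] for _ in range(n)]
    per_scan_i: list[list[float]] = [[] for _ in range(n)]
    for _name, mz, rt, sigma, amp in components:
        prof = amp * np.exp(-0.5 * ((times - rt) / sigma) ** 2)
        if spec.noise_sd > 0:
            mask = np.ones(n, dtype=bool)  # noisy channels carry a full baseline
            prof = prof + rng.normal(0.0, spec.noise_sd, size=n)
        else:
            mask = prof >= max(amp, 1.0) * 1e-9
        prof = np.clip(prof, 0.0, None)
        mzs = (
            mz + rng.normal(0.0, spec.mz_jitter_sd, size=n)
            if spec.mz_jitter_sd > 0
            else np.full(n, mz)
        )
        for i in np.nonzero(mask)[0]:
            per_scan_mz[i].append(mzs[i])
            per_scan_i[i].append(prof[i])
    scans = [
        Scan(
            time=float(times[i]),
            mz=np.array(per_scan_mz[i]),
            intensity=np.array(per_scan_i[i]),
        )
        for i in range(n)
    ]
    return MsRun(scans=scans, label=label).validate()


def gen_ms_run(spec: ChromSimSpec) -> tuple[MsRun, MsRun, TruthRecord]:
    """Simulate a sample run, its matched blank, and the ground truth.

    Each analyte contributes a Gaussian elution profile of true area
    amplitude * sigma * sqrt(2*pi) at its m/z; blank features (column bleed,
    solvent artefacts) appear in both the sample and the blank; the blank
    carries nothing else beyond noise.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_sample, rng_blank = (np.random.default_rng(s) for s in ss.spawn(2))
    components, analyte_truth, overlaps = _expand_components(spec, rng_sample)
    blank_components = [
        (f"blank_{j}", mz, rt, spec.blank_sigma, amp)
        for j, (mz, rt, amp) in enumerate(spec.blank_features)
    ]
    sample = _build_run(components + blank_components, spec, rng_sample, "sample")
    blank = _build_run(blank_components, spec, rng_blank, "blank")
    for j, (mz, rt, amp) in enumerate(spec.blank_features):
        analyte_truth[f"blank_{j}"] = {
            "rt": rt,
            "mz": mz,
            "area": amp * spec.blank_sigma * _SQRT2PI,
            "enantiomer_fractions": None,
            "is_blank": True,
        }
    truth = TruthRecord(
        analyte_truth=analyte_truth, overlapping_analytes=overlaps
    ).validate()
    return sample, blank, truth
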