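"""nCounter-style count normalization.

The chain mirrors the standard nSolver workflow for hybridization-count
panels and is applied jointly to all lanes (primary tumours and their
matched nodal metastases are always normalized together):

1. *Background thresholding*: each lane's background is estimated from
   its own negative-control probes as mean + ``background_sd_multiplier``
   standard deviations (sample SD, n-1 denominator); every non-negative
   probe count below that threshold is replaced by the threshold (floor
   semantics — no subtraction — so downstream logs stay positive).
2. *Housekeeping selection*: candidate housekeeping probes are ranked by
   the coefficient of variation of their log2 counts across lanes; the
   ``n_housekeeping`` most stable are kept as normalizers.
3. *Global-mean scaling*: each lane is scaled so the geometric mean of
   its normalizer probes (positive controls plus selected housekeeping)
   equals the across-lane geometric mean of those per-lane means.
   An arithmetic-mean variant is available via ``global_mean_stat``.
4. *Low-expression filtering*: endogenous genes whose mean log2 count
   across lanes falls below ``min_log2_mean_count`` are removed.

Counts are floored at ``log_floor`` before every log2 so an all-zero
lane (background threshold 0) cannot produce -inf.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import SampleCounts

__all__ = [
    "NormalizationParams",
    "CountMatrix",
    "NormalizationResult",
    "build_count_matrix",
    "background_threshold",
    "select_housekeeping",
    "global_mean_normalize",
    "filter_low_expression",
    "normalize_counts",
]


@dataclass(frozen=True)
class NormalizationParams:
    """Tunable knobs of the normalization chain.

    background_sd_multiplier
        SD multiplier in the background threshold (default 2, i.e.
        mean + 2 SD of the negative controls).
    n_housekeeping
        Number of most-stable housekeeping probes used as normalizers
        alongside the positive controls (default 4).
    min_log2_mean_count
        Low-expression cutoff: genes with mean log2 count (strictly)
        below this are excluded (default 6, i.e. ~64 counts).
    log_floor
        Counts are floored at this value before any log2 (default 1).
    global_mean_stat
        "geometric" (default, scale-equivariant) or "arithmetic" lane
        summary of the normalizer probes.
    low_expression_stat
        "mean_log2" (default: mean of log2 counts) or "log2_mean"
        (log2 of the mean count) for the low-expression rule.
    """

    background_sd_multiplier: float = 2.0
    n_housekeeping: int = 4
    min_log2_mean_count: float = 6.0
    log_floor: float = 1.0
    global_mean_stat: str = "geometric"
    low_expression_stat: str = "mean_log2"

    def __post_init__(self) -> None:
        if self.background_sd_multiplier < 0:
            raise ValidationError("background_sd_multiplier must be >= 0")
        if self.n_housekeeping < 1:
            raise ValidationError("n_housekeeping must be >= 1")
        if self.global_mean_stat not in ("geometric", "arithmetic"):
            raise ValidationError("global_mean_stat must be geometric|arithmetic")
        if self.low_expression_stat not in ("mean_log2", "log2_mean"):
            raise ValidationError("low_expression_stat must be mean_log2|log2_mean")


@dataclass
class CountMatrix:
    """Probe x sample count matrix with code-class and sample annotation.

    values
        DataFrame, probes (rows) x sample ids (columns), non-negative.
    code_class
        Series mapping probe name -> code class, aligned with values.
    samples
        DataFrame indexed by sample_id with columns patient_id, tissue.
    stage
        One of {"raw", "thresholded", "normalized"}.
    """

    values: pd.DataFrame
    code_class: pd.Series
    samples: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.code_class.index):
            raise ValidationError("values and code_class must share the probe index")
        if list(self.values.columns) != list(self.samples.index):
            raise ValidationError("values columns must match samples index")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")

    def probes_of_class(self, code_class: str) -> list[str]:
        return list(self.code_class.index[self.code_class == code_class])

    def endogenous(self) -> pd.DataFrame:
        return self.values.loc[self.probes_of_class("Endogenous")]


def build_count_matrix(samples: list[SampleCounts]) -> CountMatrix:
    """Assemble annotated :class:`SampleCounts` into a raw CountMatrix.

    All samples must share the same probe set (one codeset).
    """
    if not samples:
        raise ValidationError("no samples provided")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample ids")
    ref = samples[0]
    probe_names = [p.name for p in ref.probes]
    classes = pd.Series(
        {p.name: p.code_class for p in ref.probes}, name="code_class"
    ).loc[probe_names]
    columns = {}
    for s in samples:
        if [p.name for p in s.probes] != probe_names:
            raise ValidationError(
                f"sample {s.sample_id!r}: probe set differs from {ref.sample_id!r}"
            )
        columns[s.sample_id] = [float(p.count) for p in s.probes]
    values = pd.DataFrame(columns, index=probe_names)
    annot = pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in samples],
            "tissue": [s.tissue for s in samples],
        },
        index=pd.Index(ids, name="sample_id"),
    )
    for s in samples:
        if not any(p.code_class == "Negative" for p in s.probes):
            raise ValidationError(f"sample {s.sample_id!r}: no Negative probes")
        if not any(p.code_class == "Positive" for p in s.probes):
            raise ValidationError(f"sample {s.sample_id!r}: no Positive probes")
    return CountMatrix(values=values, code_class=classes, samples=annot, stage="raw")


def background_threshold(
    matrix: CountMatrix, params: NormalizationParams = NormalizationParams()
) -> tuple[CountMatrix, pd.Series]:
    """Floor each lane's non-negative-control counts at its background.

    The threshold for lane *s* is mean + multiplier * SD (sample SD,
    n-1 denominator) of the lane's negative-control counts; counts below
    it are replaced by it, counts at or above it are untouched.  Negative
    control probes themselves are left unchanged.  Idempotent.

    Returns the thresholded matrix (stage="thresholded") and the
    per-lane thresholds.
    """
    neg = matrix.probes_of_class("Negative")
    if len(neg) < 2:
        raise ValidationError(
            f"need >= 2 Negative probes to estimate background SD, got {len(neg)}"
        )
    negatives = matrix.values.loc[neg]
    thresholds = negatives.mean(axis=0) + params.background_sd_multiplier * negatives.std(
        axis=0, ddof=1
    )
    thresholds.name = "background_threshold"
    values = matrix.values.copy()
    non_neg = matrix.code_class != "Negative"
    values.loc[non_neg] = values.loc[non_neg].clip(lower=thresholds, axis=1)
    out = CountMatrix(
        values=values,
        code_class=matrix.code_class,
        samples=matrix.samples,
        stage="thresholded",
    )
    return out, thresholds


def _log2_floored(values: pd.DataFrame | pd.Series, floor: float):
    return np.log2(values.clip(lower=floor))


def select_housekeeping(
    matrix: CountMatrix,
    candidates: list[str] | None = None,
    k: int = 4,
    log_floor: float = 1.0,
) -> list[str]:
    """Rank housekeeping candidates by stability and return the top ``k``.

    Stability is the coefficient of variation (SD over mean, n-1 SD) of
    log2 counts across lanes; lower is more stable.  Ties break
    lexicographically by probe name.
    """
    if candidates is None:
        candidates = matrix.probes_of_class("Housekeeping")
    if len(candidates) < k:
        raise ValidationError(
            f"need at least k={k} housekeeping candidates, got {len(candidates)}"
        )
    missing = [c for c in candidates if c not in matrix.values.index]
    if missing:
        raise ValidationError(f"housekeeping candidates not in matrix: {missing}")
    logged = _log2_floored(matrix.values.loc[candidates], log_floor)
    mean = logged.mean(axis=1)
    sd = logged.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = (sd / mean.abs()).fillna(np.inf)
    cv[sd == 0] = 0.0  # constant probes are perfectly stable even at mean 0
    order = sorted(candidates, key=lambda name: (cv[name], name))
    return order[:k]


def global_mean_normalize(
    matrix: CountMatrix,
    normalizer_probes: list[str],
    params: NormalizationParams = NormalizationParams(),
) -> tuple[CountMatrix, pd.Series]:
    """Scale every lane to the common global mean of the normalizer probes.

    With the geometric statistic, lane *s* gets factor
    ``f_s = G / g_s`` where ``g_s`` is the geometric mean of the
    normalizer counts in *s* and ``G`` the geometric mean of the
    ``g_s`` over lanes.  Multiplying one lane's whole probe table by a
    constant therefore leaves its normalized values unchanged.
    """
    missing = [p for p in normalizer_probes if p not in matrix.values.index]
    if missing:
        raise ValidationError(f"normalizer probes not in matrix: {missing}")
    if not normalizer_probes:
        raise ValidationError("no normalizer probes given")
    block = matrix.values.loc[normalizer_probes]
    if (block.to_numpy() <= 0).any():
        raise ValidationError(
            "normalizer probe counts must be > 0 in every lane; "
            "apply background thresholding (or a log floor) first"
        )
    if params.global_mean_stat == "geometric":
        lane_means = np.exp(np.log(block).mean(axis=0))
        grand = float(np.exp(np.log(lane_means).mean()))
    else:
        lane_means = block.mean(axis=0)
        grand = float(lane_means.mean())
    factors = grand / lane_means
    factors.name = "scale_factor"
    out = CountMatrix(
        values=matrix.values.mul(factors, axis=1),
        code_class=matrix.code_class,
        samples=matrix.samples,
        stage="normalized",
    )
    return out, factors


def filter_low_expression(
    matrix: CountMatrix, params: NormalizationParams = NormalizationParams()
) -> tuple[CountMatrix, list[str]]:
    """Drop low-expression endogenous genes from a normalized matrix.

    A gene is excluded iff its mean log2 count across all lanes is
    strictly below ``min_log2_mean_count`` (or, with
    ``low_expression_stat="log2_mean"``, iff log2 of its mean count is).
    Control probes are dropped from the output: after normalization the
    analysis proceeds on endogenous genes only.

    Returns the restricted matrix and the excluded gene names in matrix
    order.
    """
    if matrix.stage != "normalized":
        raise ValidationError("filter_low_expression expects a normalized matrix")
    endo = matrix.endogenous()
    if params.low_expression_stat == "mean_log2":
        stat = _log2_floored(endo, params.log_floor).mean(axis=1)
    else:
        stat = np.log2(endo.mean(axis=1).clip(lower=params.log_floor))
    keep = stat >= params.min_log2_mean_count
    excluded = list(endo.index[~keep])
    retained = endo.loc[keep]
    if retained.empty:
        warnings.warn("all endogenous genes fell below the expression cutoff")
    out = CountMatrix(
        values=retained,
        code_class=matrix.code_class.loc[retained.index],
        samples=matrix.samples,
        stage="normalized",
    )
    return out, excluded


@dataclass
class NormalizationResult:
    """Everything the normalization chain produced."""

    matrix: CountMatrix
    thresholds: pd.Series
    scale_factors: pd.Series
    housekeeping: list[str]
    excluded_genes: list[str]
    params: NormalizationParams = field(default_factory=NormalizationParams)


def normalize_counts(
    samples: list[SampleCounts], params: NormalizationParams = NormalizationParams()
) -> NormalizationResult:
    """Run the full chain: threshold, pick housekeeping, scale, filter."""
    raw = build_count_matrix(samples)
    thresholded, thresholds = background_threshold(raw, params)
    housekeeping = select_housekeeping(
        thresholded, k=params.n_housekeeping, log_floor=params.log_floor
    )
    normalizers = thresholded.probes_of_class("Positive") + housekeeping
    # threshold 0 lanes can leave zero counts; floor them for the scaling step
    floored = replace(
        thresholded, values=thresholded.values.clip(lower=params.log_floor)
    )
    normalized, factors = global_mean_normalize(floored, normalizers, params)
    filtered, excluded = filter_low_expression(normalized, params)
    return NormalizationResult(
        matrix=filtered,
        thresholds=thresholds,
        scale_factors=factors,
        housekeeping=housekeeping,
        excluded_genes=excluded,
        params=params,
    )
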