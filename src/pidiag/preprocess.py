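"""Two-colour normalization, per-gene scaling and pre-filtering.

The normalization follows the classic intensity-dependent Lowess scheme
for dye-swap arrays: per array, a locally weighted linear regression
(tricube weights, 35% span, two robustness iterations) of the log-ratio
M = log2(experimental / control) on the mean log2 intensity
A = (log2 experimental + log2 control) / 2 is fitted and subtracted, so
any smooth dye bias in M-vs-A is removed.  The control channel is
floored at a small constant before forming the ratio, which caps the
ratios of near-background spots.

Downstream, every gene is divided by the median of its measurements
across all samples ("per-gene median scaling"), and three pre-filter
rules remove genes that are (1) too dim to trust, (2) mostly flagged
absent by the scanner, or (3) flat across the whole time course.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .containers import (
    MEDIAN_SCALED,
    RATIO,
    RAW_TWO_CHANNEL,
    ExpressionMatrix,
    check_meta,
)
from .errors import AlignmentError, DataError

logger = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    """Tunables for normalization and filtering.

    lowess_span
        Fraction of the data used by each local fit.
    control_floor
        Minimum control-channel value used as the ratio denominator.
    raw_floor / raw_floor_timepoints
        A gene is removed when its mean raw signal falls below
        ``raw_floor`` at ``raw_floor_timepoints`` or more time points.
    absent_frac
        A gene is removed when flagged absent in more than this fraction
        of its measurements.
    flat_band
        Closed interval of normalized signal; a gene whose per-day mean
        stays inside it at every time point is removed as unresponsive.
    """

    lowess_span: float = 0.35
    control_floor: float = 10.0
    raw_floor: float = 50.0
    raw_floor_timepoints: int = 5
    absent_frac: float = 0.5
    flat_band: tuple[float, float] = (0.8, 1.2)

    def __post_init__(self) -> None:
        if not 0 < self.lowess_span <= 1:
            raise DataError("lowess_span must lie in (0, 1]")
        if self.control_floor <= 0 or self.raw_floor < 0:
            raise DataError("floors must be positive")
        lo, hi = self.flat_band
        if not lo < hi:
            if lo != hi:  # allow the degenerate (c, c) band used to disable rule 3
                raise DataError("flat_band lower bound must not exceed the upper")


def floored_ratio(experimental, control, control_floor: float = 10.0):
    """Experimental/control ratio with the control channel floored."""
    return np.asarray(experimental, float) / np.maximum(
        np.asarray(control, float), control_floor
    )


def _array_channels(meta: pd.DataFrame) -> pd.DataFrame:
    """One row per array with its experimental and control channel ids."""
    rows = []
    for array_id, grp in meta.groupby("array_id", sort=False):
        trt = grp.set_index("treatment")["sample_id"]
        if "minus_P" not in trt.index or "plus_P" not in trt.index or len(grp) != 2:
            raise AlignmentError(
                f"array {array_id!r} must carry exactly one treated (minus_P) "
                "and one control (plus_P) channel"
            )
        day = grp["day"].iloc[0]
        rows.append(
            {
                "array_id": array_id,
                "experimental": trt["minus_P"],
                "control": trt["plus_P"],
                "day": day,
            }
        )
    return pd.DataFrame(rows)


def lowess_normalize(
    matrix: ExpressionMatrix, meta: pd.DataFrame, params: PreprocessParams | None = None
) -> ExpressionMatrix:
    """Lowess-normalize a raw two-channel matrix into per-array ratios.

    Per array, the experimental/control ratio (control floored at
    ``params.control_floor``) is corrected by subtracting the Lowess
    trend of log-ratio versus mean log-intensity.  Output columns are
    array ids; values are strictly positive ratios.
    """
    params = params or PreprocessParams()
    matrix.require_kind(RAW_TWO_CHANNEL)
    check_meta(meta, ("sample_id", "array_id", "treatment", "day"))
    missing = set(meta["sample_id"]) - set(matrix.samples)
    if missing:
        raise AlignmentError(f"metadata channels absent from matrix: {sorted(missing)[:5]}")

    arrays = _array_channels(meta[meta["sample_id"].isin(matrix.samples)])
    eps = 1e-12
    out = {}
    for row in arrays.itertuples(index=False):
        exp = np.maximum(matrix.data[row.experimental].to_numpy(float), eps)
        ctrl = np.maximum(matrix.data[row.control].to_numpy(float), eps)
        m = np.log2(floored_ratio(exp, ctrl, params.control_floor))
        a = 0.5 * (np.log2(exp) + np.log2(ctrl))
        span = a.max() - a.min()
        if span == 0 or np.ptp(m) == 0:
            # degenerate geometry: the trend is just the constant level
            trend = np.full_like(m, m.mean())
        else:
            trend = _sm_lowess(
                m,
                a,
                frac=params.lowess_span,
                it=2,
                delta=0.005 * span,
                return_sorted=False,
            )
        out[row.array_id] = np.exp2(m - trend)
    data = pd.DataFrame(out, index=matrix.genes)
    return ExpressionMatrix(data=data, kind=RATIO)


def median_scale(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each gene by the median of its measurements in all samples.

    Genes whose median is not finite and positive (e.g. all zeros) are
    reported via logging and dropped.
    """
    med = matrix.data.median(axis=1)
    bad = ~np.isfinite(med) | (med <= 0)
    if bad.any():
        dropped = matrix.genes[bad].tolist()
        logger.warning(
            "median_scale: dropping %d degenerate gene(s) with non-positive "
            "median, e.g. %s",
            len(dropped),
            dropped[:5],
        )
    data = matrix.data.loc[~bad].div(med[~bad], axis=0)
    return matrix.with_data(data, kind=MEDIAN_SCALED)


def _day_of_columns(columns: pd.Index, meta: pd.DataFrame) -> pd.Series:
    """Map matrix columns to sampling days via channel or array ids."""
    by_channel = meta.set_index("sample_id")["day"]
    by_array = meta.drop_duplicates("array_id").set_index("array_id")["day"]
    days = {}
    for col in columns:
        if col in by_channel.index:
            days[col] = by_channel[col]
        elif col in by_array.index:
            days[col] = by_array[col]
        else:
            raise DataError(f"column {col!r} has no day assignment in the metadata")
    out = pd.Series(days)
    if out.isna().any() or (out == ".").any():
        raise DataError("metadata is missing day assignments for some columns")
    return out.astype(int)


def _per_day_means(data: pd.DataFrame, days: pd.Series) -> pd.DataFrame:
    return data.T.groupby(days).mean().T


def prefilter(
    matrix: ExpressionMatrix,
    raw: ExpressionMatrix,
    flags: pd.DataFrame,
    meta: pd.DataFrame,
    params: PreprocessParams | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Apply the three pre-filter rules and report which fired per gene.

    Rule 1: mean raw signal (across replicates and treatments within each
    time point) below ``raw_floor`` at ``raw_floor_timepoints`` or more
    time points.  Rule 2: flagged absent in more than ``absent_frac`` of
    measurements.  Rule 3: per-day mean normalized signal inside
    ``flat_band`` at every time point.

    ``matrix`` must be median-scaled; ``raw`` is the aligned raw matrix.
    Returns the surviving genes and a per-removed-gene report with
    boolean columns ``rule1``/``rule2``/``rule3``.
    """
    params = params or PreprocessParams()
    matrix.require_kind(MEDIAN_SCALED)
    if not raw.genes.equals(matrix.genes):
        raise AlignmentError("raw matrix genes do not match the scaled matrix")

    raw_days = _day_of_columns(raw.samples, meta)
    norm_days = _day_of_columns(matrix.samples, meta)

    raw_day_means = _per_day_means(raw.data, raw_days)
    rule1 = (raw_day_means < params.raw_floor).sum(axis=1) >= params.raw_floor_timepoints

    if flags is None:
        rule2 = pd.Series(False, index=matrix.genes)
    else:
        if not flags.index.equals(matrix.genes):
            raise AlignmentError("flag table genes do not match the matrix")
        rule2 = flags.mean(axis=1) > params.absent_frac

    lo, hi = params.flat_band
    norm_day_means = _per_day_means(matrix.data, norm_days)
    if lo == hi:
        rule3 = pd.Series(False, index=matrix.genes)
    else:
        rule3 = ((norm_day_means >= lo) & (norm_day_means <= hi)).all(axis=1)

    removed = rule1 | rule2 | rule3
    report = pd.DataFrame(
        {"gene_id": matrix.genes, "rule1": rule1, "rule2": rule2, "rule3": rule3}
    ).loc[removed.to_numpy()]
    survivors = matrix.with_data(matrix.data.loc[~removed])
    return survivors, report.reset_index(drop=True)
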