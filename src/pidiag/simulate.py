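"""Seeded, truth-annotated synthetic datasets.

The generator emulates the statistical structure of a dye-swap
time-course nutrient-withdrawal experiment: at each of seven sampling
days (relative to phosphate withdrawal, with re-supply after 28 d) three
biological replicates of a minus-Pi (treated) and a plus-Pi (control)
plant are sampled; each treated/control pair is co-hybridised on two
arrays with dye orientations reversed.  The default design therefore
yields 42 biological samples, 42 arrays and 84 labelled sample-channels.

Responsive genes are planted with one of a small pool of temporal
response patterns (seven-symbol strings over ``↑ ↓ -``, one symbol per
day); the treated-channel expectation is the control expectation
multiplied (``↑``) or divided (``↓``) by ``effect_fold`` at the flagged
days only.  Noise is additive Gaussian on the log2 scale (log-normal on
the raw scale), which keeps signals positive and matches the standard
microarray error model.

A companion one-colour "field" generator produces labelled test sets in
which deficient-class samples shift every diagnostic gene by a chosen
attenuation of its planted effect, mimicking the weaker, steady-state
response of field-grown material.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import ONE_COLOUR, RAW_TWO_CHANNEL, ExpressionMatrix
from .errors import InvalidDesignError, WrongValueKindError

UP, DOWN, FLAT = "↑", "↓", "-"

DEFAULT_DAYS = (0, 1, 3, 7, 17, 29, 31)

#: Default pool of planted response patterns (one symbol per day).  These
#: are two-arrow analogues of the early/mid/late induction and
#: repression clusters seen after Pi withdrawal, balanced between up-
#: and down-regulation (real Pi-withdrawal responses split roughly
#: evenly between the two directions).  Each pattern has at least two
#: flagged days so a planted gene can satisfy the ">1.5-fold at two or
#: more time points" calling rule.
DEFAULT_PATTERNS = (
    "- - - - ↑ ↑ -",   # late induction, persists one day after re-supply
    "- - ↑ ↑ - - -",   # transient early induction
    "- - - ↑ ↑ - -",   # mid-course induction
    "- - - - ↓ ↓ -",   # late repression
    "- - ↓ ↓ - - -",   # transient early repression
    "- - - ↓ ↓ - -",   # mid-course repression
)

#: Status-tracking patterns: response at every deficiency day, the
#: idealisation of a diagnostic marker whose expression follows leaf P
#: status itself (which diverges from controls within a day of
#: withdrawal and re-converges after re-supply).  Used by the
#: marker-selection and classification benchmarks, where "a planted
#: fold-f diagnostic gene" means a gene with a fold-f separation between
#: the deficient and replete classes.
STATUS_PATTERNS = (
    "- ↑ ↑ ↑ ↑ ↑ -",
    "- ↓ ↓ ↓ ↓ ↓ -",
)


def parse_pattern(pattern: str) -> tuple[str, ...]:
    """Split a pattern string into its per-day symbols."""
    symbols = tuple(pattern.split())
    bad = [s for s in symbols if s not in (UP, DOWN, FLAT)]
    if bad:
        raise InvalidDesignError(f"unknown pattern symbols: {bad}")
    return symbols


def format_pattern(symbols: Sequence[str]) -> str:
    return " ".join(symbols)


@dataclass
class SimDesign:
    """Design of a synthetic dye-swap time-course experiment."""

    days: tuple[int, ...] = DEFAULT_DAYS
    replicates: int = 3
    dye_swap: bool = True
    n_genes: int = 5000
    frac_responsive: float = 0.1
    effect_fold: float = 2.0
    noise_sd: float = 0.2
    dye_bias: tuple[float, ...] = ()
    frac_absent: float = 0.02
    frac_low_signal: float = 0.05
    patterns: tuple[str, ...] = DEFAULT_PATTERNS
    seed: int = 0

    def __post_init__(self) -> None:
        self.days = tuple(int(d) for d in self.days)
        if any(b >= a for a, b in zip(self.days[1:], self.days[:-1])):
            raise InvalidDesignError("days must be strictly increasing")
        if not self.days:
            raise InvalidDesignError("at least one sampling day is required")
        if self.n_genes <= 0 or self.replicates <= 0:
            raise InvalidDesignError("n_genes and replicates must be positive")
        if self.effect_fold <= 1:
            raise InvalidDesignError("effect_fold must exceed 1")
        for name in ("frac_responsive", "frac_absent", "frac_low_signal"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidDesignError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise InvalidDesignError("noise_sd must be nonnegative")
        for p in self.patterns:
            if len(parse_pattern(p)) != len(self.days):
                raise InvalidDesignError(
                    f"pattern {p!r} has {len(parse_pattern(p))} symbols "
                    f"for {len(self.days)} days"
                )

    @property
    def n_samples(self) -> int:
        return len(self.days) * 2 * self.replicates

    @property
    def n_channels(self) -> int:
        return self.n_samples * (2 if self.dye_swap else 1)


# log2 baseline ranges: bright genes sit well above the raw-signal filter
# floor of 50, low-signal genes well below it even with noise.
_BRIGHT_LO, _BRIGHT_HI = 7.0, 13.0
_DIM_LO, _DIM_HI = 3.0, 5.0


def _deficient_day_mask(days: Sequence[int]) -> np.ndarray:
    """Days on which a minus-Pi plant is physiologically deficient.

    The first day (sampled two hours after withdrawal) and the final day
    (after re-supply) count as replete; everything in between is the
    deficiency period.
    """
    days = np.asarray(days)
    return (days > days[0]) & (days < days[-1])


def _pattern_effects(symbols: Sequence[str], log2_fold: float) -> np.ndarray:
    return np.array(
        [log2_fold if s == UP else -log2_fold if s == DOWN else 0.0 for s in symbols]
    )


def _gene_direction(symbols: Sequence[str], days: Sequence[int]) -> int:
    """Response direction during the deficiency period (+1 up, -1 down, 0 none)."""
    mask = _deficient_day_mask(days)
    for s, m in zip(symbols, mask):
        if m and s != FLAT:
            return 1 if s == UP else -1
    return 0


def generate_timecourse(
    design: SimDesign,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate a dye-swap time-course experiment.

    Returns
    -------
    matrix
        Raw two-channel :class:`ExpressionMatrix` (genes x labelled
        sample-channels) with absent flags.
    meta
        Sample metadata, one row per labelled sample-channel.
    truth
        Per-gene truth table: ``gene_id``, ``pattern``, ``is_diagnostic``,
        ``planted_fold``.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_genes
    genes = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")

    n_resp = int(round(design.frac_responsive * n))
    responsive = np.sort(rng.choice(n, size=n_resp, replace=False))
    resp_mask = np.zeros(n, dtype=bool)
    resp_mask[responsive] = True

    n_dim = int(round(design.frac_low_signal * n))
    nonresp = np.flatnonzero(~resp_mask)
    n_dim = min(n_dim, nonresp.size)
    dim = np.sort(rng.choice(nonresp, size=n_dim, replace=False))
    dim_mask = np.zeros(n, dtype=bool)
    dim_mask[dim] = True

    baseline = rng.uniform(_BRIGHT_LO, _BRIGHT_HI, size=n)
    baseline[dim_mask] = rng.uniform(_DIM_LO, _DIM_HI, size=int(dim_mask.sum()))

    pool = [parse_pattern(p) for p in design.patterns]
    pattern_idx = rng.integers(0, len(pool), size=n_resp)
    log2_fold = float(np.log2(design.effect_fold))
    n_days = len(design.days)

    # per-gene, per-day additive log2 effect applied to the treated channel
    effects = np.zeros((n, n_days))
    patterns = np.array([format_pattern([FLAT] * n_days)] * n, dtype=object)
    for gi, pi in zip(responsive, pattern_idx):
        effects[gi] = _pattern_effects(pool[pi], log2_fold)
        patterns[gi] = format_pattern(pool[pi])

    diagnostic = np.array(
        [
            resp_mask[g] and _gene_direction(parse_pattern(patterns[g]), design.days) != 0
            for g in range(n)
        ]
    )
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "pattern": patterns,
            "is_diagnostic": diagnostic,
            "planted_fold": np.where(resp_mask, design.effect_fold, 1.0),
        }
    ).set_index("gene_id", drop=False)

    orientations = ("fwd", "rev") if design.dye_swap else ("fwd",)
    columns, meta_rows, col_values = [], [], []
    for di, day in enumerate(design.days):
        for rep in range(1, design.replicates + 1):
            for orient in orientations:
                array_id = f"a_d{day}_r{rep}_{orient}"
                # fwd: treated on Cy5; rev: treated on Cy3
                for treatment in ("minus_P", "plus_P"):
                    if orient == "fwd":
                        dye = "Cy5" if treatment == "minus_P" else "Cy3"
                    else:
                        dye = "Cy3" if treatment == "minus_P" else "Cy5"
                    mu = baseline.copy()
                    if treatment == "minus_P":
                        mu = mu + effects[:, di]
                    noise = (
                        rng.normal(0.0, design.noise_sd, size=n)
                        if design.noise_sd > 0
                        else 0.0
                    )
                    col_values.append(np.exp2(mu + noise))
                    channel_id = f"{array_id}_{dye}"
                    columns.append(channel_id)
                    meta_rows.append(
                        {
                            "sample_id": channel_id,
                            "biological_id": f"d{day}_r{rep}_{treatment}",
                            "array_id": array_id,
                            "treatment": treatment,
                            "day": day,
                            "replicate": rep,
                            "dye": dye,
                            "dataset": "timecourse",
                            "label": ".",
                        }
                    )
    values = np.column_stack(col_values)
    data = pd.DataFrame(values, index=genes, columns=columns)
    flags = pd.DataFrame(
        rng.random(values.shape) < design.frac_absent, index=genes, columns=columns
    )
    meta = pd.DataFrame(meta_rows)
    matrix = ExpressionMatrix(data=data, kind=RAW_TWO_CHANNEL, flags=flags)
    if any(c != 0 for c in design.dye_bias):
        matrix = inject_dye_bias(matrix, meta, design.dye_bias)
    return matrix, meta, truth


def generate_field_set(
    truth: pd.DataFrame,
    n_per_class: int = 15,
    attenuation: float = 1.0,
    noise_sd: float = 0.25,
    seed: int = 0,
    days: Sequence[int] = DEFAULT_DAYS,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a one-colour fertilised/unfertilised field test set.

    Deficient-class (unfertilised) samples express every diagnostic gene
    shifted by ``attenuation * log2(planted_fold)`` in the gene's
    response direction; fertilised samples sit at baseline.  Baselines
    are drawn afresh (a field dataset is a separate hybridisation batch),
    which is immaterial downstream because field data are median-scaled
    within their own dataset before classification.
    """
    if n_per_class < 1:
        raise InvalidDesignError("n_per_class must be at least 1")
    if not (0 < attenuation <= 1):
        raise InvalidDesignError("attenuation must lie in (0, 1]")
    if not truth["is_diagnostic"].any():
        raise InvalidDesignError("truth table contains no diagnostic gene")

    rng = np.random.default_rng(seed)
    genes = truth.index
    n = len(genes)
    baseline = rng.uniform(_BRIGHT_LO, _BRIGHT_HI, size=n)
    direction = np.array(
        [
            _gene_direction(parse_pattern(p), days) if d else 0
            for p, d in zip(truth["pattern"], truth["is_diagnostic"])
        ]
    )
    shift = attenuation * direction * np.log2(truth["planted_fold"].to_numpy(float))

    cols, meta_rows, col_values = [], [], []
    for treatment, label in (("fertilised", "replete"), ("unfertilised", "deficient")):
        for i in range(1, n_per_class + 1):
            mu = baseline + (shift if label == "deficient" else 0.0)
            noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
            col_values.append(np.exp2(mu + noise))
            sid = f"field_{treatment}_{i:02d}"
            cols.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "biological_id": sid,
                    "array_id": sid,
                    "treatment": treatment,
                    "day": ".",
                    "replicate": i,
                    "dye": "Cy3",
                    "dataset": "field",
                    "label": label,
                }
            )
    data = pd.DataFrame(np.column_stack(col_values), index=genes, columns=cols)
    matrix = ExpressionMatrix(data=data, kind=ONE_COLOUR)
    return matrix, pd.DataFrame(meta_rows)


def inject_dye_bias(
    matrix: ExpressionMatrix, meta: pd.DataFrame, coefficients: Sequence[float]
) -> ExpressionMatrix:
    """Add a smooth intensity-dependent dye bias to a two-channel matrix.

    ``coefficients`` are polynomial coefficients ``(c1, c2, ...)`` in the
    *centred* mean log2 intensity A; the log-ratio log2(Cy5/Cy3) of each
    array gains ``sum_j c_j (A - mean(A))**j``, split symmetrically
    between the two channels so A itself is unchanged.  Zero (or empty)
    coefficients return the input unchanged.  The distortion is exactly
    the kind of artefact intensity-dependent Lowess normalization is
    meant to remove, making this the natural test fixture for it.
    """
    matrix.require_kind(RAW_TWO_CHANNEL)
    coefficients = tuple(coefficients)
    if not coefficients or all(c == 0 for c in coefficients):
        return matrix

    data = matrix.data.copy()
    by_array = meta.groupby("array_id", sort=False)
    for array_id, grp in by_array:
        dyes = grp.set_index("dye")["sample_id"]
        if "Cy3" not in dyes.index or "Cy5" not in dyes.index:
            raise WrongValueKindError(
                f"array {array_id!r} lacks a Cy3/Cy5 channel pair; "
                "dye bias applies to two-channel data only"
            )
        cy3, cy5 = dyes["Cy3"], dyes["Cy5"]
        a = 0.5 * (np.log2(data[cy3]) + np.log2(data[cy5]))
        ac = a - a.mean()
        bias = np.zeros_like(ac)
        for j, c in enumerate(coefficients, start=1):
            bias = bias + c * ac**j
        data[cy5] = data[cy5] * np.exp2(bias / 2.0)
        data[cy3] = data[cy3] * np.exp2(-bias / 2.0)
    return matrix.with_data(data)
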