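"""In-memory containers shared across the pipeline.

Expression data travel as a :class:`pandas.DataFrame` with genes in rows
and sample-channels (or arrays, or one-colour samples) in columns,
wrapped in :class:`ExpressionMatrix` to carry a *value-kind* tag and the
per-cell absent flags that two-colour scanners emit.  Sample metadata is
a plain DataFrame with one row per labelled sample-channel (see
:data:`META_COLUMNS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import pandas as pd

from .errors import DataError, WrongValueKindError

# value-kind tags
RAW_TWO_CHANNEL = "raw_two_channel"  # per-channel raw intensities, dye-swap design
ONE_COLOUR = "one_colour"            # per-sample processed signals
RATIO = "ratio"                      # treated/control per array, lowess-corrected
MEDIAN_SCALED = "median_scaled"      # per-gene median = 1
LOG2 = "log2"                        # log2 of median-scaled signals

#: required columns of a sample-metadata table; one row per sample-channel.
META_COLUMNS = (
    "sample_id",     # labelled sample-channel id (matrix column)
    "biological_id", # underlying biological sample (42 in the default design)
    "array_id",      # hybridisation; two channels share an array
    "treatment",     # plus_P | minus_P (or fertilised | unfertilised)
    "day",           # days relative to Pi withdrawal; "." for field samples
    "replicate",
    "dye",           # Cy3 | Cy5
    "dataset",       # timecourse | field | ...
    "label",         # replete | deficient | "."
)


@dataclass
class ExpressionMatrix:
    """Gene x sample grid of nonnegative signals.

    Parameters
    ----------
    data
        DataFrame indexed by gene id, one column per sample-channel.
    kind
        One of the value-kind tags defined in this module.
    flags
        Optional boolean DataFrame aligned to ``data``; ``True`` marks a
        measurement flagged *absent* by the scanner.
    """

    data: pd.DataFrame
    kind: str
    flags: Optional[pd.DataFrame] = field(default=None)

    def __post_init__(self) -> None:
        if self.flags is not None:
            if not self.flags.index.equals(self.data.index) or not (
                self.flags.columns.equals(self.data.columns)
            ):
                raise DataError("absent-flag table is not aligned to the data")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def require_kind(self, *kinds: str) -> None:
        if self.kind not in kinds:
            raise WrongValueKindError(
                f"expected a matrix of kind {' or '.join(kinds)}, got {self.kind!r}"
            )

    def with_data(self, data: pd.DataFrame, kind: Optional[str] = None) -> "ExpressionMatrix":
        flags = self.flags
        if flags is not None:
            flags = flags.reindex(index=data.index, columns=data.columns)
        return replace(self, data=data, kind=kind or self.kind, flags=flags)


def check_meta(meta: pd.DataFrame, required: tuple[str, ...] = META_COLUMNS) -> None:
    """Raise :class:`DataError` unless ``meta`` has the required columns."""
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise DataError(f"sample metadata is missing columns: {missing}")
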