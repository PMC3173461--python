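"""Tab-separated file dialects.

All tables are UTF-8 TSV with a header row and ``.`` for missing values.
Expression matrices put the gene id in the first column.  Files written
by the CLI open with ``#``-prefixed provenance comment lines (package
version, seed, parameter hash); readers skip comment lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .containers import ExpressionMatrix

NA = "."


def provenance_lines(seed: Optional[int], params: Optional[dict] = None) -> list[str]:
    digest = hashlib.md5(
        json.dumps(params or {}, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return [f"# pidiag v{__version__} seed={seed} params_hash={digest}"]


def _write(df: pd.DataFrame, path: str | Path, header_lines: list[str], index: bool) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", na_rep=NA, index=index)


def write_expression(
    matrix: ExpressionMatrix | pd.DataFrame,
    path: str | Path,
    header_lines: list[str] | None = None,
) -> None:
    df = matrix.data if isinstance(matrix, ExpressionMatrix) else matrix
    df = df.rename_axis("gene_id")
    _write(df, path, header_lines or [], index=True)


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", index_col=0, na_values=NA, encoding="utf-8"
    )
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return df


def write_table(
    df: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None
) -> None:
    _write(df, path, header_lines or [], index=False)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", na_values=NA, encoding="utf-8", **kwargs
    )


def write_flags(flags: pd.DataFrame, path: str | Path, header_lines=None) -> None:
    _write(
        flags.astype(int).rename_axis("gene_id"), path, header_lines or [], index=True
    )


def read_flags(path: str | Path) -> pd.DataFrame:
    return read_expression(path).astype(bool)
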