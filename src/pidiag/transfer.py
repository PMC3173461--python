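"""Cross-platform transfer of a diagnostic gene set.

A classifier built on one platform (species) can be projected onto
another through an ortholog mapping table of (source_gene_id,
target_gene_id) records, e.g. from translated-BLAST hits.  Sources with
several candidate targets resolve to their first record (map-file
order); several sources collapsing onto one target are averaged on the
log2 scale when expression is projected.  The mapped features then feed
an SVM trained on a labelled reference matrix of the *target* platform —
what labelled target-platform data to train on is an explicit input, not
something this module guesses.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import pandas as pd

from .classify import KernelSpec, predict_margins, train_svm
from .errors import AlignmentError, DataError, NoMappableFeaturesError


class MappingReport(NamedTuple):
    n_sources: int
    n_mapped: int
    unmapped_sources: list[str]
    collapsed_targets: dict[str, list[str]]  # target -> sources (where >1)


def _resolve_map(mapping: pd.DataFrame) -> pd.DataFrame:
    for col in ("source", "target"):
        if col not in mapping.columns:
            raise DataError("ortholog map needs 'source' and 'target' columns")
    m = mapping[["source", "target"]].astype(str)
    if (m == "").any().any() or m.isna().any().any():
        raise DataError("ortholog map contains empty identifiers")
    # one-to-many: keep the first record per source (map-file order)
    return m.drop_duplicates(subset="source", keep="first")


def map_features(
    diagnostic: Sequence[str], mapping: pd.DataFrame
) -> tuple[list[str], MappingReport]:
    """Project a diagnostic gene set through an ortholog map.

    Returns the distinct target features (first-appearance order) and a
    report of unmapped sources and many-to-one collapses.
    """
    if mapping.empty:
        raise DataError("ortholog map is empty")
    resolved = _resolve_map(mapping).set_index("source")["target"]
    diagnostic = list(diagnostic)
    targets: list[str] = []
    per_target: dict[str, list[str]] = {}
    unmapped = []
    for g in diagnostic:
        if g in resolved.index:
            t = resolved[g]
            per_target.setdefault(t, []).append(g)
            if t not in targets:
                targets.append(t)
        else:
            unmapped.append(g)
    if not targets:
        raise NoMappableFeaturesError("no diagnostic gene maps to the target platform")
    report = MappingReport(
        n_sources=len(diagnostic),
        n_mapped=len(targets),
        unmapped_sources=unmapped,
        collapsed_targets={t: s for t, s in per_target.items() if len(s) > 1},
    )
    return targets, report


def project_expression(
    features: pd.DataFrame, mapping: pd.DataFrame
) -> pd.DataFrame:
    """Rename a log2 feature table (genes x samples) into target space.

    Sources sharing a target are collapsed by the arithmetic mean of
    their log2 signals.
    """
    resolved = _resolve_map(mapping).set_index("source")["target"]
    keep = features.index.intersection(resolved.index)
    if keep.empty:
        raise NoMappableFeaturesError("no feature row appears in the ortholog map")
    sub = features.loc[keep]
    target_of = resolved.reindex(keep)
    out = sub.groupby(target_of.to_numpy()).mean()
    out.index.name = features.index.name
    return out


def cross_platform_classify(
    mapped_features: Sequence[str],
    reference_features: pd.DataFrame,
    reference_labels: pd.Series,
    test_features: pd.DataFrame,
    spec: KernelSpec,
    C: float = 1.0,
) -> pd.DataFrame:
    """Train on the target-platform reference, classify target samples.

    Both matrices are genes x samples on the log2 scale and must contain
    every mapped feature; margins follow the deficient = +1 convention.
    """
    mapped = list(mapped_features)
    for name, table in (("reference", reference_features), ("test", test_features)):
        missing = [g for g in mapped if g not in table.index]
        if missing:
            raise AlignmentError(
                f"{name} matrix lacks {len(missing)} mapped feature(s), "
                f"e.g. {missing[:5]}"
            )
    model = train_svm(reference_features.loc[mapped], reference_labels, spec, C=C)
    return predict_margins(model, test_features.loc[mapped])
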