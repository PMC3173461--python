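"""Class prediction of Pi status from expression profiles.

The training set treats the two-colour time-course data as one-colour:
each of the 84 labelled sample-channels becomes a training sample whose
features are log2 median-scaled signals.  Channels are labelled *Pi
replete* when they come from plants supplied with Pi throughout, or were
sampled on the first day (two hours after withdrawal, before any
physiological response) or the last day (after re-supply); minus-Pi
channels from the intervening days are *Pi deficient*.  Class coding is
deficient = +1, replete = -1, so a positive SVM margin reads
"this sample looks Pi deficient".

Candidate marker genes are ranked by the Golub signal-to-noise score
``s(g) = (mu_deficient - mu_replete) / (sd_deficient + sd_replete)`` and
a size-k diagnostic set takes the ceil(k/2) most positive and floor(k/2)
most negative scores (the original balanced practice).  The soft-margin
SVM dual is solved by libsvm (via scikit-learn); margins are recomputed
from the stored support coefficients with this module's own kernel
functions, which keeps the trained model a small, serialisable,
solver-independent artifact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .containers import ExpressionMatrix, check_meta
from .errors import (
    AlignmentError,
    ConvergenceError,
    DataError,
    DomainError,
)

DEFICIENT, REPLETE = "deficient", "replete"
CLASS_CODE = {DEFICIENT: +1, REPLETE: -1}

KERNEL_NAMES = ("poly1", "poly2", "poly3", "rbf")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and parameters.

    ``poly_dot`` is the polynomial dot-product kernel
    (scale * u.v + offset)^degree.  The default offset of 1
    (inhomogeneous kernel) is deliberate: with features median-centred
    within each dataset, the two classes of a balanced test set sit near
    +x and -x, and an even-degree *homogeneous* kernel satisfies
    k(u, -x) = k(u, x) — it cannot tell the classes apart at all.  The
    constant offset restores the odd (linear) terms, and ``scale``
    (defaulting at training time to 1 / (n_features * var(X)), the
    conventional gamma heuristic) keeps the dot product on the same
    O(1) footing as the offset regardless of gene-set size.  Set
    ``offset=0`` for the homogeneous variant.  ``rbf`` is
    exp(-gamma ||u - v||^2); a gamma of None likewise defers to
    1 / (n_features * var(X)).
    """

    family: str
    degree: Optional[int] = None
    gamma: Optional[float] = None
    offset: float = 1.0  # constant inside the polynomial; 0 = homogeneous
    scale: Optional[float] = None  # dot-product prefactor; None = set at training

    def __post_init__(self) -> None:
        if self.family == "poly_dot":
            if self.degree not in (1, 2, 3):
                raise DomainError("polynomial degree must be 1, 2 or 3")
            if self.gamma is not None:
                raise DomainError("gamma applies to the rbf kernel only")
        elif self.family == "rbf":
            if self.degree is not None:
                raise DomainError("degree applies to the polynomial kernel only")
            if self.gamma is not None and self.gamma <= 0:
                raise DomainError("gamma must be positive")
        else:
            raise DomainError(f"unknown kernel family {self.family!r}")

    @classmethod
    def from_name(cls, name: str) -> "KernelSpec":
        if name.startswith("poly") and name[4:].isdigit():
            return cls(family="poly_dot", degree=int(name[4:]))
        if name == "rbf":
            return cls(family="rbf")
        raise DomainError(f"unknown kernel name {name!r}; expected one of {KERNEL_NAMES}")

    @property
    def name(self) -> str:
        return f"poly{self.degree}" if self.family == "poly_dot" else "rbf"


def kernel_value(u: Sequence[float], v: Sequence[float], spec: KernelSpec) -> float:
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if u.shape != v.shape:
        raise AlignmentError("kernel arguments must have equal length")
    return float(kernel_matrix(u[None, :], v[None, :], spec)[0, 0])


def kernel_matrix(u: np.ndarray, v: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Gram matrix K[i, j] = k(u_i, v_j) for row-vector stacks u, v."""
    if u.shape[1] != v.shape[1]:
        raise AlignmentError("kernel arguments must have equal length")
    if spec.family == "poly_dot":
        scale = 1.0 if spec.scale is None else spec.scale
        return (scale * (u @ v.T) + spec.offset) ** spec.degree
    gamma = spec.gamma
    if gamma is None:
        raise DomainError("rbf kernel needs a concrete gamma at evaluation time")
    sq = (
        (u**2).sum(axis=1)[:, None] + (v**2).sum(axis=1)[None, :] - 2.0 * (u @ v.T)
    )
    return np.exp(-gamma * np.maximum(sq, 0.0))


def build_training_labels(
    meta: pd.DataFrame, replete_days: Optional[tuple[int, int]] = None
) -> pd.Series:
    """Label every sample-channel as replete or deficient.

    Channels from plus-Pi plants are always replete; minus-Pi channels
    are replete on the first and last sampling day (before the response
    develops / after re-supply) and deficient in between.
    """
    check_meta(meta, ("sample_id", "treatment", "day"))
    if meta[["treatment", "day"]].isna().any().any():
        raise DataError("every sample needs a treatment and a day")
    days = meta["day"].astype(int)
    if replete_days is None:
        replete_days = (int(days.min()), int(days.max()))
    replete = (meta["treatment"] == "plus_P") | days.isin(replete_days)
    labels = pd.Series(
        np.where(replete, REPLETE, DEFICIENT),
        index=pd.Index(meta["sample_id"], name="sample_id"),
        name="label",
    )
    return labels


def training_features(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Log2 of median-scaled signals, the feature representation used
    throughout classification (genes x samples)."""
    from .preprocess import median_scale

    scaled = median_scale(matrix)
    return np.log2(scaled.data)


def golub_scores(features: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Golub signal-to-noise score per gene.

    ``features`` is genes x samples on the log2 scale; ``labels`` maps
    sample id to replete/deficient.  Denominators are floored at
    1e-9 x the mean pooled sd to guard zero-variance genes.
    """
    labels = labels.reindex(features.columns)
    if labels.isna().any():
        raise DataError("every feature column needs a class label")
    classes = set(labels)
    if classes != {DEFICIENT, REPLETE}:
        raise DataError(f"need both classes in the training set, got {sorted(classes)}")
    dcols = labels.index[labels == DEFICIENT]
    rcols = labels.index[labels == REPLETE]
    if len(dcols) < 2 or len(rcols) < 2:
        raise DataError("each class needs at least 2 samples")
    mu_d = features[dcols].mean(axis=1)
    mu_r = features[rcols].mean(axis=1)
    sd = features[dcols].std(axis=1, ddof=1) + features[rcols].std(axis=1, ddof=1)
    eps = 1e-9 * float(sd.mean())
    if eps <= 0:
        eps = 1e-12
    return ((mu_d - mu_r) / sd.clip(lower=eps)).rename("golub_score")


def select_diagnostic(scores: pd.Series, k: int, balanced: bool = True) -> list[str]:
    """Pick the k-gene diagnostic set from Golub scores.

    Balanced selection (default) takes the ceil(k/2) most positive and
    floor(k/2) most negative scores; if one side runs short the other
    tops up.  ``balanced=False`` ranks purely by |score|.  Ties break on
    gene id, so the output is deterministic.
    """
    if k <= 0:
        raise DomainError("k must be positive")
    if k > len(scores):
        raise DomainError(f"k={k} exceeds the {len(scores)} scored genes")
    s = scores.sort_index()  # lexicographic tie-break baseline
    if not balanced:
        order = s.abs().sort_values(ascending=False, kind="stable")
        return list(order.index[:k])
    pos = s.sort_values(ascending=False, kind="stable")
    neg = s.sort_values(ascending=True, kind="stable")
    n_pos = min(int(np.ceil(k / 2)), len(s))
    n_neg = k - n_pos
    top = list(pos.index[:n_pos])
    chosen = set(top)
    bottom = [g for g in neg.index if g not in chosen][:n_neg]
    if len(bottom) < n_neg:  # degenerate: fewer genes than k/2 on a side
        extra = [g for g in pos.index if g not in chosen and g not in bottom]
        bottom += extra[: n_neg - len(bottom)]
    return top + bottom


@dataclass
class SVMModel:
    """A trained soft-margin kernel SVM in explicit dual form."""

    kernel: KernelSpec
    genes: list[str]
    support_ids: list[str]
    support_vectors: np.ndarray  # n_sv x n_genes
    dual_coef: np.ndarray        # alpha_i * y_i
    bias: float
    C: float
    class_code: dict = field(default_factory=lambda: dict(CLASS_CODE))

    def decision_function(self, features: pd.DataFrame) -> pd.Series:
        """Margins for a genes x samples feature table."""
        missing = [g for g in self.genes if g not in features.index]
        if missing:
            raise AlignmentError(
                f"test data lack {len(missing)} model gene(s), e.g. {missing[:5]}"
            )
        x = features.loc[self.genes].to_numpy(float).T  # samples x genes
        k = kernel_matrix(self.support_vectors, x, self.kernel)
        margins = self.dual_coef @ k + self.bias
        return pd.Series(margins, index=features.columns, name="margin")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kernel": {
                "family": self.kernel.family,
                "degree": self.kernel.degree,
                "gamma": self.kernel.gamma,
                "offset": self.kernel.offset,
                "scale": self.kernel.scale,
            },
            "genes": self.genes,
            "support_ids": self.support_ids,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "bias": self.bias,
            "C": self.C,
            "class_code": self.class_code,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SVMModel":
        d = json.loads(Path(path).read_text())
        return cls(
            kernel=KernelSpec(**d["kernel"]),
            genes=d["genes"],
            support_ids=d["support_ids"],
            support_vectors=np.asarray(d["support_vectors"], float),
            dual_coef=np.asarray(d["dual_coef"], float),
            bias=float(d["bias"]),
            C=float(d["C"]),
            class_code=d["class_code"],
        )


def train_svm(
    features: pd.DataFrame,
    labels: pd.Series,
    spec: KernelSpec,
    C: float = 1.0,
    tol: float = 1e-4,
) -> SVMModel:
    """Solve the soft-margin dual on a genes x samples feature table.

    The decision function is f(x) = sum_i alpha_i y_i k(x_i, x) + b with
    deficient coded +1.  Dual feasibility (0 <= alpha <= C, sum alpha_i
    y_i = 0) is asserted on the returned model.
    """
    labels = labels.reindex(features.columns)
    if labels.isna().any():
        raise DataError("every training column needs a class label")
    y = labels.map(CLASS_CODE)
    if y.isna().any() or len(set(y)) < 2:
        raise DataError("training data must contain both classes")
    x = features.to_numpy(float).T  # samples x genes
    if not np.all(np.isfinite(x)):
        raise DataError("training features must be finite")

    var = float(x.var())
    default_gamma = 1.0 / (x.shape[1] * var) if var > 0 else 1.0 / x.shape[1]
    if spec.family == "poly_dot":
        scale = default_gamma if spec.scale is None else spec.scale
        clf = SVC(
            kernel="poly", degree=spec.degree, gamma=scale, coef0=spec.offset,
            C=C, tol=tol, cache_size=512,
        )
        eff_spec = KernelSpec(
            family="poly_dot", degree=spec.degree, offset=spec.offset, scale=scale
        )
    else:
        gamma = default_gamma if spec.gamma is None else spec.gamma
        clf = SVC(kernel="rbf", gamma=gamma, C=C, tol=tol, cache_size=512)
        eff_spec = KernelSpec(family="rbf", gamma=gamma)
    clf.fit(x, y.to_numpy(int))
    if clf.fit_status_ != 0:
        raise ConvergenceError("libsvm reported a failed optimisation")

    dual = clf.dual_coef_[0]
    if abs(dual.sum()) > 1e-6 * max(1.0, np.abs(dual).sum()):
        raise ConvergenceError("dual equality constraint violated beyond tolerance")
    return SVMModel(
        kernel=eff_spec,
        genes=list(features.index),
        support_ids=[features.columns[i] for i in clf.support_],
        support_vectors=x[clf.support_],
        dual_coef=dual,
        bias=float(clf.intercept_[0]),
        C=C,
    )


def predict_margins(model: SVMModel, features: pd.DataFrame) -> pd.DataFrame:
    """Margins and predicted classes for a genes x samples feature table."""
    margins = model.decision_function(features)
    return pd.DataFrame(
        {
            "sample_id": margins.index,
            "margin": margins.to_numpy(),
            "predicted": np.where(margins.to_numpy() > 0, DEFICIENT, REPLETE),
        }
    ).reset_index(drop=True)


def percent_correct(
    n_plus_pred_minus: int,
    n_minus_pred_plus: int,
    n_plus_pred_plus: int,
    n_minus_pred_minus: int,
) -> float:
    """Percent of samples classified into their actual class, 1 decimal."""
    counts = (n_plus_pred_minus, n_minus_pred_plus, n_plus_pred_plus, n_minus_pred_minus)
    if any(c < 0 for c in counts):
        raise DomainError("confusion counts must be nonnegative")
    total = sum(counts)
    if total == 0:
        raise DomainError("confusion counts sum to zero")
    return round(100.0 * (n_plus_pred_plus + n_minus_pred_minus) / total, 1)


def evaluate_grid(
    train_features: pd.DataFrame,
    train_labels: pd.Series,
    test_features: pd.DataFrame,
    test_labels: pd.Series,
    sizes: Sequence[int],
    kernels: Sequence[str | KernelSpec] = KERNEL_NAMES,
    C: float = 1.0,
) -> pd.DataFrame:
    """Confusion grid over (kernel, gene-set size) cells.

    For each size k: rank genes on the training set by Golub score,
    select the balanced top-k, train each kernel on the selected
    features, predict the test set, and tabulate confusion counts.
    Here "+P" is the replete class and "-P" the deficient class, so
    e.g. ``n_plusP_pred_minusP`` counts replete samples called deficient.
    """
    shared = train_features.index.intersection(test_features.index)
    if len(shared) < len(train_features.index):
        raise AlignmentError("train and test sets must share the gene universe")
    specs = [k if isinstance(k, KernelSpec) else KernelSpec.from_name(k) for k in kernels]
    for k in sizes:
        if k > len(train_features.index):
            raise DomainError(f"gene-set size {k} exceeds the universe")
    scores = golub_scores(train_features, train_labels)
    actual = test_labels.reindex(test_features.columns)
    rows = []
    for k in sizes:
        chosen = select_diagnostic(scores, k)
        sub_train = train_features.loc[chosen]
        sub_test = test_features.loc[chosen]
        for spec in specs:
            model = train_svm(sub_train, train_labels, spec, C=C)
            pred = predict_margins(model, sub_test).set_index("sample_id")["predicted"]
            a = actual.to_numpy()
            p = pred.reindex(actual.index).to_numpy()
            n_pm = int(((a == REPLETE) & (p == DEFICIENT)).sum())
            n_mp = int(((a == DEFICIENT) & (p == REPLETE)).sum())
            n_pp = int(((a == REPLETE) & (p == REPLETE)).sum())
            n_mm = int(((a == DEFICIENT) & (p == DEFICIENT)).sum())
            rows.append(
                {
                    "kernel": spec.name,
                    "n_genes": k,
                    "n_plusP_pred_minusP": n_pm,
                    "n_minusP_pred_plusP": n_mp,
                    "n_plusP_pred_plusP": n_pp,
                    "n_minusP_pred_minusP": n_mm,
                    "percent_correct": percent_correct(n_pm, n_mp, n_pp, n_mm),
                }
            )
    return pd.DataFrame(rows)
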