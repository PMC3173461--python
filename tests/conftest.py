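"""Shared fixtures and independent oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from pidiag.classify import kernel_matrix


def make_meta(days, replicates=1, dye_swap=False):
    """Minimal channel-level metadata for hand-built fixtures."""
    rows = []
    orientations = ("fwd", "rev") if dye_swap else ("fwd",)
    for day in days:
        for rep in range(1, replicates + 1):
            for orient in orientations:
                array_id = f"a_d{day}_r{rep}_{orient}"
                for trt in ("minus_P", "plus_P"):
                    if orient == "fwd":
                        dye = "Cy5" if trt == "minus_P" else "Cy3"
                    else:
                        dye = "Cy3" if trt == "minus_P" else "Cy5"
                    rows.append(
                        {
                            "sample_id": f"{array_id}_{dye}",
                            "biological_id": f"d{day}_r{rep}_{trt}",
                            "array_id": array_id,
                            "treatment": trt,
                            "day": day,
                            "replicate": rep,
                            "dye": dye,
                            "dataset": "timecourse",
                            "label": ".",
                        }
                    )
    return pd.DataFrame(rows)


def svm_margins_bruteforce(x, y, C, spec, x_eval):
    """Independent soft-margin SVM oracle: solve the dual QP numerically.

    Maximises sum(a) - 1/2 a' (K * yy') a subject to 0 <= a <= C and
    a.y = 0 with SLSQP (no libsvm involved), recovers the bias from the
    free support vectors, and returns margins at ``x_eval``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    k = kernel_matrix(x, x, spec)
    q = k * np.outer(y, y)
    n = len(y)

    def neg_dual(a):
        return 0.5 * a @ q @ a - a.sum()

    def grad(a):
        return q @ a - 1.0

    res = minimize(
        neg_dual,
        np.full(n, min(C, 1.0) / 2),
        jac=grad,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    assert res.success, res.message
    a = res.x
    g = (a * y) @ k
    v = y - g
    eps = 1e-6 * max(C, 1.0)
    # KKT interval for the bias; free SVs collapse it to a point
    lower = ((y > 0) & (a < C - eps)) | ((y < 0) & (a > eps))
    upper = ((y > 0) & (a > eps)) | ((y < 0) & (a < C - eps))
    assert lower.any() and upper.any()
    b = float((v[lower].max() + v[upper].min()) / 2.0)
    return (a * y) @ kernel_matrix(x, np.asarray(x_eval, float), spec) + b


@pytest.fixture(scope="session")
def small_timecourse():
    """A 400-gene default-design simulation shared across tests."""
    from pidiag import SimDesign, generate_timecourse

    design = SimDesign(n_genes=400, seed=3)
    matrix, meta, truth = generate_timecourse(design)
    return design, matrix, meta, truth
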