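"""Published reference numbers used as pipeline inputs.

Two small tables from the original potato Pi-status field evaluation
travel with the package: the confusion-count grid of the kernel x
gene-set-size sweep (counts only; the percent column is *recomputed* by
:func:`pidiag.classify.percent_correct`), and the field-trial summary
statistics (mean, SEM, n per treatment) that feed the summary-statistic
Welch t-test.  They are inputs in the same sense a printed primer
sequence is: data to run the method on, not expected outputs baked into
the code.
"""

from __future__ import annotations

import pandas as pd

#: Confusion counts of the published field evaluation: per kernel and
#: diagnostic-set size, (replete samples predicted deficient, deficient
#: predicted replete, replete predicted replete, deficient predicted
#: deficient) over 15 + 15 field samples, plus the published percent
#: correct for cross-checking the arithmetic.
FIELD_EVALUATION_GRID = pd.DataFrame(
    [
        ("poly1", 25, 5, 7, 10, 8, 60.0),
        ("poly2", 25, 3, 9, 12, 6, 60.0),
        ("poly3", 25, 2, 7, 13, 8, 70.0),
        ("rbf", 25, 2, 7, 13, 8, 70.0),
        ("poly1", 50, 6, 2, 9, 13, 73.3),
        ("poly2", 50, 0, 3, 15, 12, 90.0),
        ("poly3", 50, 0, 4, 15, 11, 86.7),
        ("rbf", 50, 0, 4, 15, 11, 86.7),
        ("poly1", 100, 7, 0, 8, 15, 76.7),
        ("poly2", 100, 0, 3, 15, 12, 90.0),
        ("poly3", 100, 0, 3, 15, 12, 90.0),
        ("rbf", 100, 2, 3, 13, 12, 83.3),
        ("poly1", 200, 0, 0, 15, 15, 100.0),
        ("poly2", 200, 0, 0, 15, 15, 100.0),
        ("poly3", 200, 0, 0, 15, 15, 100.0),
        ("rbf", 200, 0, 0, 15, 15, 100.0),
        ("poly1", 250, 2, 0, 13, 15, 93.3),
        ("poly2", 250, 1, 0, 14, 15, 96.7),
        ("poly3", 250, 1, 0, 14, 15, 96.7),
        ("rbf", 250, 1, 0, 14, 15, 96.7),
        ("poly1", 1000, 3, 0, 12, 15, 90.0),
        ("poly2", 1000, 2, 0, 13, 15, 93.3),
        ("poly3", 1000, 2, 0, 13, 15, 93.3),
        ("rbf", 1000, 2, 0, 13, 15, 93.3),
        ("poly1", 8663, 4, 0, 11, 15, 86.7),
        ("poly2", 8663, 2, 1, 13, 14, 90.0),
        ("poly3", 8663, 2, 2, 13, 13, 86.7),
        ("rbf", 8663, 2, 2, 13, 13, 86.7),
        ("poly1", 28946, 2, 2, 13, 13, 86.7),
        ("poly2", 28946, 3, 1, 12, 14, 86.7),
        ("poly3", 28946, 5, 2, 10, 13, 76.7),
        ("rbf", 28946, 5, 2, 10, 13, 76.7),
        ("poly1", 42094, 2, 9, 13, 6, 63.3),
        ("poly2", 42094, 0, 15, 15, 0, 50.0),
        ("poly3", 42094, 0, 15, 15, 0, 50.0),
        ("rbf", 42094, 0, 14, 15, 1, 53.3),
    ],
    columns=[
        "kernel",
        "n_genes",
        "n_plusP_pred_minusP",
        "n_minusP_pred_plusP",
        "n_plusP_pred_plusP",
        "n_minusP_pred_minusP",
        "published_percent_correct",
    ],
)

#: Field-trial shoot summary statistics: (mean, sem, n) per treatment.
#: Unfertilised plots carry n = 6, fertilised plots n = 3.
FIELD_TRIAL_SUMMARY = {
    "shoot_biomass_g_dw": {"unfertilised": (147.60, 15.90, 6), "fertilised": (218.20, 5.40, 3)},
    "shoot_P_mg_g_dw": {"unfertilised": (1.98, 0.10, 6), "fertilised": (5.13, 0.65, 3)},
    "shoot_N_mg_g_dw": {"unfertilised": (20.93, 1.07, 6), "fertilised": (24.36, 3.25, 3)},
    "shoot_K_mg_g_dw": {"unfertilised": (60.67, 1.33, 6), "fertilised": (45.87, 4.67, 3)},
    "tuber_yield_t_ha": {"unfertilised": (34.93, 3.00, 6), "fertilised": (47.16, 2.20, 3)},
}
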