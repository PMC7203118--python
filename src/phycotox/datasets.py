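"""Bundled reference dataset: published herbicide toxicity thresholds.

EC10/EC50 (four-parameter logistic fits) and NEC (Bayesian threshold model,
growth endpoint only) values, with 95 % intervals, for the marine
cryptophyte *Rhodomonas salina* exposed to ten herbicides — seven PSII
inhibitors (diuron the reference), the ALS inhibitor imazapic, the ACCase
inhibitor haloxyfop and the synthetic auxin 2,4-D. Concentrations in
µg L⁻¹; censored thresholds carry the maximum tested concentration and
``censored=True``. Used for worked examples and for the derived summary
statistics (relative potencies, endpoint EC50 ratios and the
endpoint-sensitivity regression).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["load_threshold_table", "psii_ec50_pairs", "REFERENCE_HERBICIDE"]

REFERENCE_HERBICIDE = "diuron"

# herbicide, endpoint, metric, value, lo, hi, censored
_ROWS = [
    ("diuron", "sgr", "ec50", 6.27, 6.02, 6.54, False),
    ("diuron", "sgr", "ec10", 1.94, 1.75, 2.14, False),
    ("diuron", "sgr", "nec", 1.68, 1.53, 1.90, False),
    ("diuron", "yield", "ec50", 1.71, 1.63, 1.80, False),
    ("diuron", "yield", "ec10", 0.43, 0.38, 0.48, False),
    ("metribuzin", "sgr", "ec50", 13.4, 12.3, 14.5, False),
    ("metribuzin", "sgr", "ec10", 2.66, 2.21, 3.18, False),
    ("metribuzin", "sgr", "nec", 2.21, 1.97, 2.82, False),
    ("metribuzin", "yield", "ec50", 2.95, 2.72, 3.18, False),
    ("metribuzin", "yield", "ec10", 0.60, 0.50, 0.71, False),
    ("hexazinone", "sgr", "ec50", 8.50, 7.99, 9.06, False),
    ("hexazinone", "sgr", "ec10", 3.96, 3.40, 4.57, False),
    ("hexazinone", "sgr", "nec", 4.58, 4.34, 4.78, False),
    ("hexazinone", "yield", "ec50", 5.85, 5.61, 6.09, False),
    ("hexazinone", "yield", "ec10", 1.81, 1.63, 1.99, False),
    ("bromacil", "sgr", "ec50", 19.3, 17.7, 21.0, False),
    ("bromacil", "sgr", "ec10", 4.89, 4.01, 5.91, False),
    ("bromacil", "sgr", "nec", 5.53, 4.33, 6.44, False),
    ("bromacil", "yield", "ec50", 3.56, 3.19, 3.98, False),
    ("bromacil", "yield", "ec10", 0.59, 0.45, 0.75, False),
    ("tebuthiuron", "sgr", "ec50", 112.0, 106.0, 119.0, False),
    ("tebuthiuron", "sgr", "ec10", 27.5, 24.2, 31.2, False),
    ("tebuthiuron", "sgr", "nec", 22.7, 20.3, 25.2, False),
    ("tebuthiuron", "yield", "ec50", 16.0, 15.1, 17.0, False),
    ("tebuthiuron", "yield", "ec10", 2.66, 2.31, 3.06, False),
    ("simazine", "sgr", "ec50", 184.0, 173.0, 195.0, False),
    ("simazine", "sgr", "ec10", 38.4, 33.0, 44.2, False),
    ("simazine", "sgr", "nec", 48.0, 44.0, 51.0, False),
    ("simazine", "yield", "ec50", 59.2, 56.7, 61.8, False),
    ("simazine", "yield", "ec10", 9.28, 8.41, 10.2, False),
    ("propazine", "sgr", "ec50", 188.0, 177.0, 201.0, False),
    ("propazine", "sgr", "ec10", 42.0, 37.1, 47.3, False),
    ("propazine", "sgr", "nec", 27.8, 24.2, 31.1, False),
    ("propazine", "yield", "ec50", 39.5, 37.1, 42.1, False),
    ("propazine", "yield", "ec10", 5.85, 4.90, 6.91, False),
    ("imazapic", "sgr", "ec50", 790000.0, 760000.0, 825000.0, False),
    ("imazapic", "sgr", "ec10", 410000.0, 362000.0, 462000.0, False),
    ("imazapic", "sgr", "nec", 363000.0, 341000.0, 386000.0, False),
    ("imazapic", "yield", "ec50", 790000.0, np.nan, np.nan, True),
    ("imazapic", "yield", "ec10", 790000.0, np.nan, np.nan, True),
    ("haloxyfop", "sgr", "ec50", 3700.0, np.nan, np.nan, True),
    ("haloxyfop", "sgr", "ec10", 3700.0, np.nan, np.nan, True),
    ("haloxyfop", "sgr", "nec", 3700.0, np.nan, np.nan, True),
    ("haloxyfop", "yield", "ec50", 3700.0, np.nan, np.nan, True),
    ("haloxyfop", "yield", "ec10", 3700.0, np.nan, np.nan, True),
    ("2,4-D", "sgr", "ec50", 279000.0, np.nan, np.nan, True),
    ("2,4-D", "sgr", "ec10", 279000.0, np.nan, np.nan, True),
    ("2,4-D", "sgr", "nec", 279000.0, np.nan, np.nan, True),
    ("2,4-D", "yield", "ec50", 279000.0, np.nan, np.nan, True),
    ("2,4-D", "yield", "ec10", 279000.0, np.nan, np.nan, True),
]

PSII_HERBICIDES = ("diuron", "metribuzin", "hexazinone", "bromacil",
                   "tebuthiuron", "simazine", "propazine")


def load_threshold_table() -> pd.DataFrame:
    """Tidy threshold table: herbicide, endpoint, metric, value, lo, hi, censored."""
    return pd.DataFrame(
        _ROWS,
        columns=["herbicide", "endpoint", "metric", "value", "ci_low",
                 "ci_high", "censored"],
    )


def psii_ec50_pairs() -> pd.DataFrame:
    """Uncensored EC50 pairs (ec50_sgr, ec50_yield) for the PSII herbicides."""
    t = load_threshold_table()
    ec50 = t[(t["metric"] == "ec50") & ~t["censored"]]
    wide = ec50.pivot(index="herbicide", columns="endpoint", values="value")
    wide = wide.loc[[h for h in PSII_HERBICIDES if h in wide.index]]
    return (wide.rename(columns={"sgr": "ec50_sgr", "yield": "ec50_yield"})
            .reset_index())
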