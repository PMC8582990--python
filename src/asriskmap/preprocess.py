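"""Data preparation for spatial mapping of well concentrations.

Four steps precede any interpolation: re-centering planar coordinates on the
sampling centroid (keeps magnitudes small for the numerics), a log10
transform of the strongly right-skewed concentrations, a normality check of
the transformed values, and a concentration-ordered round-robin split into k
near-equal sets for cross-validation.  The ordered split deliberately
stratifies by magnitude so each fold sees the full concentration range —
a plain random split can put most extreme wells into a single fold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.diagnostic import lilliefors

SET_LABELS = "ABCDEFGHIJ"


def recenter(wells: pd.DataFrame, origin: tuple[float, float]) -> pd.DataFrame:
    """Shift coordinates to a new origin: (x, y) -> (x - ox, y - oy).

    Concentrations and all other columns are unchanged.
    """
    out = wells.copy()
    out["x"] = out["x"] - origin[0]
    out["y"] = out["y"] - origin[1]
    return out


def log_transform(concentrations) -> np.ndarray:
    """Elementwise log10; inverse is 10**(.).

    Raises on non-positive input (censored wells must already carry their
    substitution value, which is positive).
    """
    c = np.asarray(concentrations, dtype=float)
    if np.any(c <= 0):
        raise ValueError("log transform requires strictly positive concentrations")
    return np.log10(c)


def normality_pvalue(values, test: str = "lilliefors") -> float:
    """p-value of a composite normality test (mean and variance estimated).

    Default is the Kolmogorov-Smirnov test with the Lilliefors correction;
    the test is location-scale invariant.  Requires n >= 20 and non-constant
    input.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 20:
        raise ValueError("normality test requires n >= 20")
    if np.ptp(x) == 0:
        raise ValueError("normality test undefined for constant input")
    if test != "lilliefors":
        raise ValueError(f"unknown normality test {test!r}")
    _, pvalue = lilliefors(x, dist="norm")
    return float(pvalue)


def ordered_split(wells: pd.DataFrame, k: int = 3) -> pd.Series:
    """Concentration-ordered round-robin assignment to ``k`` sets.

    Wells sorted by descending concentration (ties broken by well_id) are
    dealt in turn to sets A, B, C, ...; set sizes differ by at most one and
    every set spans the full concentration range.  Returns a Series mapping
    well_id -> set label.
    """
    if k < 1 or len(wells) < k:
        raise ValueError(f"need at least k={k} wells")
    if k > len(SET_LABELS):
        raise ValueError(f"at most {len(SET_LABELS)} sets supported")
    order = wells.sort_values(
        ["conc_ugL", "well_id"], ascending=[False, True], kind="mergesort"
    )
    labels = [SET_LABELS[i % k] for i in range(len(order))]
    return pd.Series(labels, index=pd.Index(order["well_id"], name="well_id"), name="set")


def split_summary(wells: pd.DataFrame, split: pd.Series) -> pd.DataFrame:
    """Per-set descriptive statistics (count, mean, median, sd, skew, range)
    in the layout of a survey summary table."""
    merged = wells.merge(split.rename("set"), left_on="well_id", right_index=True)
    g = merged.groupby("set")["conc_ugL"]
    return pd.DataFrame(
        {
            "n_wells": g.size(),
            "mean": g.mean(),
            "median": g.median(),
            "sd": g.std(),
            "skewness": g.skew(),
            "min": g.min(),
            "max": g.max(),
        }
    )
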