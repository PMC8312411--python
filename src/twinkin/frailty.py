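"""Deficit-accumulation frailty index (FI).

The FI of Rockwood's deficit-accumulation model is the proportion of health
deficits an individual endorses out of those assessed (44 items here): a
person with five deficits scores 5/44 = 0.11.  Individuals missing more than
a fixed fraction of items (default 20%) are excluded.  For respondents with
some (but tolerable) missingness two denominators are in use in the
literature: the count of non-missing items (standard Rockwood practice,
the default) or the fixed full item count (``fixed44``-style replication).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import Cohort

DEFAULT_N_ITEMS = 44
DEFAULT_MAX_MISSING = 0.20


def compute_fi(items, max_missing_fraction: float = DEFAULT_MAX_MISSING,
               denominator: str = "nonmissing") -> np.ndarray:
    """Frailty index per individual from a deficit matrix.

    Parameters
    ----------
    items
        Array-like of shape ``(n_individuals, n_items)`` with entries in
        {0, 1, nan}; nan marks a missing item.
    max_missing_fraction
        Individuals whose missing-item fraction strictly exceeds this are
        excluded (FI returned as nan).
    denominator
        ``"nonmissing"`` divides by the count of answered items;
        ``"fixed"`` divides by the full item count regardless of missingness
        (missing items then count as non-deficits).

    Returns
    -------
    ndarray of FI values in [0, 1]; nan where excluded.
    """
    x = np.asarray(items, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] < 1:
        raise ValueError("empty item vector")
    if denominator not in ("nonmissing", "fixed"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    valid = ~np.isnan(x)
    if not np.all((x[valid] == 0) | (x[valid] == 1)):
        raise ValueError("deficit items must be 0, 1 or missing")
    n_items = x.shape[1]
    n_missing = n_items - valid.sum(axis=1)
    endorsed = np.nansum(x, axis=1)
    if denominator == "fixed":
        fi = endorsed / n_items
    else:
        denom = valid.sum(axis=1).astype(float)
        fi = np.divide(endorsed, denom, out=np.full(len(x), np.nan), where=denom > 0)
    excluded = n_missing / n_items > max_missing_fraction
    fi[excluded] = np.nan
    return fi


def sqrt_transform(fi) -> np.ndarray:
    """Square-root transform of the FI (normalising transform for its right skew)."""
    x = np.asarray(fi, dtype=float)
    if np.any(x[~np.isnan(x)] < 0):
        raise ValueError("FI values must be non-negative")
    return np.sqrt(x)


def item_columns(cohort: Cohort, prefix: str = "item") -> list[str]:
    """Deficit item base names present in a cohort (``item01`` ... ``itemNN``)."""
    names = sorted({c[:-2] for c in cohort.frame.columns
                    if c.startswith(prefix) and c.endswith("_1")})
    return names


def add_fi_to_cohort(cohort: Cohort, fi_name: str = "FI", prefix: str = "item",
                     max_missing_fraction: float = DEFAULT_MAX_MISSING,
                     denominator: str = "nonmissing") -> Cohort:
    """Compute the FI from a cohort's deficit-item columns and attach it.

    Adds ``<fi_name>_1`` / ``<fi_name>_2`` columns; excluded or absent twins
    get nan.
    """
    items = item_columns(cohort, prefix)
    if not items:
        raise ValueError(f"cohort has no deficit columns with prefix {prefix!r}")
    frame = cohort.frame.copy()
    for suf in ("_1", "_2"):
        mat = frame[[c + suf for c in items]].to_numpy(dtype=float)
        fi = compute_fi(mat, max_missing_fraction, denominator)
        present = frame[f"present{suf[-1]}"].to_numpy(dtype=bool)
        fi[~present] = np.nan
        frame[fi_name + suf] = fi
    names = cohort.phenotype_names + ([fi_name] if fi_name not in cohort.phenotype_names else [])
    return Cohort(frame, names)


def fi_descriptives(fi: np.ndarray) -> dict:
    """Median/IQR summary of an FI distribution (descriptive-table style)."""
    x = np.asarray(fi, dtype=float)
    x = x[~np.isnan(x)]
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"n": int(x.size), "median": float(med), "iqr": (float(q1), float(q3)),
            "mean": float(x.mean()), "skewness": float(pd.Series(x).skew())}
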