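"""Group-level descriptive and inferential summaries of ROH calls.

Per-category counts with two-group Student t-tests and HI/LI fold
ratios, and the decomposition of each individual's F_ROH into the
percentage contributed by every length category.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .detection import CATEGORY_LABELS, ROHSet


def two_sample_t(x, y, equal_var: bool = True) -> tuple[float, float]:
    """Two-sample t-test (pooled variance by default; Welch optional).

    Degenerate zero-variance inputs: equal means give (0, 1), unequal
    means give (inf-signed t, 0.0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        warnings.warn("zero variance with unequal means: degenerate t-test")
        return float(np.sign(np.mean(x) - np.mean(y)) * np.inf), 0.0
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def _group_arrays(values: pd.Series, groups: pd.Series
                  ) -> tuple[list[str], dict[str, np.ndarray]]:
    labels = list(dict.fromkeys(groups))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    arrays = {}
    for lab in labels:
        v = values[groups[groups == lab].index].to_numpy(dtype=float)
        if len(v) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 individuals")
        arrays[lab] = v
    return labels, arrays


def _sem(v: np.ndarray) -> float:
    return float(np.std(v, ddof=1) / np.sqrt(len(v)))


def category_count_table(roh: ROHSet, groups: pd.Series,
                         equal_var: bool = True) -> pd.DataFrame:
    """Per length category: group means +/- SEM of per-individual ROH
    counts, Student t-test p, and fold ratio (first group / second group;
    NaN when the second group's mean is 0).

    `groups`: Series mapping individual id -> group label (two labels).
    Individuals without ROH contribute zero counts.
    """
    individuals = list(groups.index)
    counts = (roh.frame.groupby(["individual", "category"]).size()
              .unstack(fill_value=0)
              .reindex(index=individuals, columns=list(CATEGORY_LABELS),
                       fill_value=0))
    rows = []
    for cat in list(CATEGORY_LABELS) + ["total"]:
        values = counts.sum(axis=1) if cat == "total" else counts[cat]
        labels, arr = _group_arrays(values, groups)
        a, b = arr[labels[0]], arr[labels[1]]
        if a.var() == 0 == b.var() and a.mean() == b.mean() == 0:
            t, p = 0.0, 1.0
        else:
            t, p = two_sample_t(a, b, equal_var=equal_var)
        rows.append({
            "category": cat,
            f"mean_{labels[0]}": a.mean(), f"sem_{labels[0]}": _sem(a),
            f"mean_{labels[1]}": b.mean(), f"sem_{labels[1]}": _sem(b),
            "n_" + labels[0]: len(a), "n_" + labels[1]: len(b),
            "t": t, "p_value": p,
            "fold": a.mean() / b.mean() if b.mean() > 0 else np.nan})
    return pd.DataFrame(rows)


def froh_decomposition(froh_table: pd.DataFrame, groups: pd.Series | None = None
                       ) -> pd.DataFrame:
    """Percentage of F_ROH_total contributed by each length category.

    `froh_table` is the output of `f_roh_by_category` (category columns
    plus F_ROH_total).  Returns per-individual percentages (rows sum to
    100); with `groups`, appends group mean +/- SEM rows and per-category
    t-test p-values.
    """
    cats = list(CATEGORY_LABELS)
    total = froh_table["F_ROH_total"]
    zero = total == 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} individual(s) with "
                      "F_ROH_total = 0 from the decomposition")
    tab = froh_table.loc[~zero]
    pct = tab[cats].div(tab["F_ROH_total"], axis=0) * 100.0
    if groups is None:
        return pct
    groups = groups.loc[groups.index.intersection(pct.index)]
    labels, _ = _group_arrays(pct[cats[0]], groups)
    rows = []
    for cat in cats:
        _, arr = _group_arrays(pct[cat], groups)
        a, b = arr[labels[0]], arr[labels[1]]
        t, p = two_sample_t(a, b)
        rows.append({"category": cat,
                     f"mean_{labels[0]}": a.mean(), f"sem_{labels[0]}": _sem(a),
                     f"mean_{labels[1]}": b.mean(), f"sem_{labels[1]}": _sem(b),
                     "t": t, "p_value": p})
    out = pd.DataFrame(rows)
    out.attrs["per_individual"] = pct
    return out


def length_summary(roh: ROHSet, groups: pd.Series,
                   by: str = "category") -> pd.DataFrame:
    """Mean/min/max segment length (Mb) per group, by length category or
    chromosome."""
    if by not in ("category", "chrom"):
        raise ValueError("by must be 'category' or 'chrom'")
    f = roh.frame.copy()
    f["group"] = f["individual"].map(groups)
    f["length_mb"] = f["length_bp"] / 1e6
    out = (f.groupby(["group", by])["length_mb"]
           .agg(["count", "mean", "min", "max",
                 ("sem", lambda v: np.std(v, ddof=1) / np.sqrt(len(v))
                  if len(v) > 1 else np.nan)])
           .reset_index())
    return out
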