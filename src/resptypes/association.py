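"""Spearman screen of fingerprint components against country indices.

Each response type's per-country proportion is rank-correlated with each of
the five country indices.  Following the study's flagging convention, a cell
is *moderate* when |r| > 0.3 and *significant* when p <= 0.05; no
multiple-testing adjustment is applied by default (a Benjamini-Hochberg
option exists for sensitivity analyses).
"""

from __future__ import annotations

from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

R_THRESHOLD = 0.3
P_THRESHOLD = 0.05
_EXACT_MAX_N = 9


def spearman(x, y, method: str = "approx") -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p value.

    r is the Pearson correlation of average-ranked values (ties receive
    average ranks).  ``method="approx"`` (default) uses the t-distribution
    approximation with n - 2 degrees of freedom; ``method="exact"``
    enumerates all permutations of one argument (n <= 9 only) and reports
    the fraction with |r| at least as large as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector has no rank correlation")
    if method == "approx":
        res = stats.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    if n > _EXACT_MAX_N:
        raise ValueError(f"exact permutation p limited to n <= {_EXACT_MAX_N}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()

    def r_of(perm_ry: np.ndarray) -> np.ndarray:
        ry_c = perm_ry - perm_ry.mean(axis=-1, keepdims=True)
        num = (rx_c * ry_c).sum(axis=-1)
        den = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=-1))
        return num / den

    r_obs = float(r_of(ry))
    perms = np.array(list(permutations(ry)))
    r_all = r_of(perms)
    p = float((np.abs(r_all) >= abs(r_obs) - 1e-12).sum() / factorial(n))
    return r_obs, p


def correlate_fingerprints(
    fingerprints: pd.DataFrame,
    index_table: pd.DataFrame,
    r_threshold: float = R_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Screen every (response type, index) pair over matched countries.

    Countries are inner-joined case-insensitively; at least 5 matches are
    required.  Returns a long-form table with one row per (type, index):
    r, p, ``moderate`` (|r| > r_threshold), ``significant`` (p <= p_threshold,
    or BH-adjusted p when ``adjust="bh"``), and the number of countries used.
    """
    common = fingerprints.index.intersection(index_table.index)
    if len(common) < 5:
        raise ValueError(
            f"only {len(common)} countries matched between fingerprints and "
            "index table; need at least 5"
        )
    fp = fingerprints.loc[common]
    idx = index_table.loc[common]
    rows = []
    for type_id in fp.columns:
        for index_name in idx.columns:
            r, p = spearman(fp[type_id].to_numpy(), idx[index_name].to_numpy())
            rows.append(
                {
                    "type_id": int(type_id),
                    "index": index_name,
                    "r": r,
                    "p": p,
                    "n_countries": len(common),
                }
            )
    out = pd.DataFrame(rows)
    if adjust == "bh":
        out["p_adjusted"] = multipletests(out["p"], method="fdr_bh")[1]
        p_for_flag = out["p_adjusted"]
    elif adjust is None:
        p_for_flag = out["p"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    out["moderate"] = out["r"].abs() > r_threshold
    out["significant"] = p_for_flag <= p_threshold
    return out


def flag_cells(
    cells: pd.DataFrame,
    r_threshold: float = R_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """(Re)compute moderate/significant flags on a long-form (r, p) table."""
    out = cells.copy()
    out["moderate"] = out["r"].abs() > r_threshold
    out["significant"] = out["p"] <= p_threshold
    return out


def table3_long(table3: pd.DataFrame) -> pd.DataFrame:
    """Reshape the packaged wide Spearman-screen table into long form."""
    rows = []
    index_names = sorted({c.rsplit("_", 1)[0] for c in table3.columns})
    for type_id, row in table3.iterrows():
        for name in index_names:
            rows.append(
                {
                    "type_id": int(type_id),
                    "index": name,
                    "r": row[f"{name}_r"],
                    "p": row[f"{name}_p"],
                }
            )
    return pd.DataFrame(rows)
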