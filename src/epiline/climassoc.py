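"""Climate association of an epiallele across accessions.

Accessions are grouped by the element's presence and methylation
(methylated / unmethylated / deletion, with methylation set to 0 when the
element is absent), and each of the 19 bioclimatic variables at two epochs
(present and last interglacial, LIG) is tested for rank association with
methylation, expression and senescence measures.  Spearman correlations use
exact permutation p-values at very small n and the t-approximation
otherwise; two-group comparisons use the Wilcoxon rank-sum test with an
exhaustive exact null for small samples, and epoch shifts within a group
use the paired signed-rank test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationResult",
    "assign_groups",
    "spearman",
    "wilcoxon_groups",
    "climate_scan",
    "epoch_shift_tests",
    "BIOCLIM_VARS",
]

BIOCLIM_VARS = tuple(f"bio{i}" for i in range(1, 20))

GROUPS = ("methylated", "unmethylated", "deletion")


@dataclass
class AssociationResult:
    x_name: str
    y_name: str
    rho: float
    p_value: float
    n: int
    method: str  # "exact" or "t-approx"


def assign_groups(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Group accessions by NMR19-4 status; returns (table, counts).

    Rules: element at 4.45 Mb present and methylated -> methylated;
    present and unmethylated -> unmethylated; absent -> deletion (whatever
    the 16.75 Mb copy does).  Accepts either a precomputed ``category``
    column (five-way classification) or a ``group`` column; otherwise
    derives the group from ``presence_4`` and ``meth_total``.
    """
    out = table.copy()
    if "category" in out.columns:
        mapping = {
            "NMR19-4m": "methylated",
            "NMR19-4m/16m": "methylated",
            "NMR19-4u": "unmethylated",
            "NMR19-16u": "deletion",
            "deletion": "deletion",
        }
        unknown = set(out["category"]) - set(mapping)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        out["group"] = out["category"].map(mapping)
    elif "group" in out.columns:
        unknown = set(out["group"]) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}")
    elif {"presence_4", "meth_total"} <= set(out.columns):
        present = out["presence_4"].astype(bool)
        meth = out["meth_total"].fillna(0) >= 0.2
        out["group"] = np.where(~present, "deletion", np.where(meth, "methylated", "unmethylated"))
    else:
        raise ValueError("need a 'category', 'group' or presence_4/meth_total columns")
    counts = {g: int((out["group"] == g).sum()) for g in GROUPS}
    return out, counts


# ---------------------------------------------------------------------------
# Rank statistics


def _average_ranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    x_name: str = "x",
    y_name: str = "y",
    exact_max_n: int = 10,
) -> AssociationResult:
    """Spearman rank correlation with pairwise deletion of missing values.

    rho is the Pearson correlation of average ranks (ties averaged).  The
    p-value is exact (full permutation enumeration) for n <= exact_max_n
    and the usual t-approximation above that.  Constant inputs are
    undefined and raise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: Spearman correlation undefined")
    rx, ry = _average_ranks(x), _average_ranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        p = _exact_spearman_p(rx, ry, rho)
        method = "exact"
    else:
        # t-approximation on n-2 degrees of freedom
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1 - rho**2))
            p = float(2 * stats.t.sf(abs(t), n - 2))
        method = "t-approx"
    return AssociationResult(x_name, y_name, rho, p, n, method)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p over all n! orderings of one rank vector."""
    n = rx.size
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    target = abs(rho_obs) - 1e-12
    hits = total = 0
    chunk: list[tuple[int, ...]] = []
    perms = itertools.permutations(range(n))
    while True:
        chunk = list(itertools.islice(perms, 200_000))
        if not chunk:
            break
        mat = ry_c[np.array(chunk)]
        rhos = (mat @ rx_c) / denom
        hits += int((np.abs(rhos) >= target).sum())
        total += len(chunk)
    return hits / total


def wilcoxon_groups(
    values,
    groups=None,
    paired: bool = False,
    exact_max_n: int = 20,
) -> tuple[float, str | None]:
    """Two-sided Wilcoxon test; returns (p, flag).

    Unpaired (rank-sum): ``values`` with a two-level ``groups`` vector.
    The null distribution is exhaustively enumerated (all assignments of
    the tied-average ranks to the groups) for combined n <= exact_max_n,
    and normal-approximated with tie correction above.  Paired
    (signed-rank, e.g. present vs LIG within one group): ``values`` is a
    pair of equal-length vectors; all-zero differences are degenerate and
    return p = 1 with a flag.
    """
    if paired:
        a, b = (np.asarray(v, float) for v in values)
        if a.size != b.size or a.size == 0:
            raise ValueError("paired vectors must be non-empty and equal length")
        diff = a - b
        if np.all(diff == 0):
            return 1.0, "degenerate: all paired differences are zero"
        res = stats.wilcoxon(a, b, alternative="two-sided", zero_method="wilcox")
        return float(res.pvalue), None

    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("need exactly two groups")
    ga = values[groups == labels[0]]
    gb = values[groups == labels[1]]
    if ga.size == 0 or gb.size == 0:
        raise ValueError("a group is empty")
    n = ga.size + gb.size
    ranks = _average_ranks(np.concatenate([ga, gb]))
    w_obs = float(ranks[: ga.size].sum())
    expect = ga.size * (n + 1) / 2.0
    if n <= exact_max_n:
        idx = np.array(list(itertools.combinations(range(n), ga.size)))
        sums = ranks[idx].sum(axis=1)
        p = float(np.mean(np.abs(sums - expect) >= abs(w_obs - expect) - 1e-12))
        return p, None
    res = stats.mannwhitneyu(ga, gb, alternative="two-sided", method="asymptotic")
    return float(res.pvalue), None


# ---------------------------------------------------------------------------
# The climate scan


MEASURES = ("meth_total", "meth_CG", "meth_CHG", "meth_CHH", "pph_expression", "chlorophyll")


def climate_scan(
    table: pd.DataFrame,
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Associate every bioclim variable (two epochs) with each measure.

    For each of the 19 variables and both epochs, Spearman correlations
    against total and per-context methylation, expression and chlorophyll.
    A variable counts as "associated" in an epoch when its p-value against
    *total methylation* is below ``alpha`` (raw p-values by default; an
    optional Benjamini-Hochberg mode adjusts within epoch).

    Returns the full result table and a summary:
    ``{"present": {"n_associated", "variables"}, "lig": {...}}``.
    """
    rows = []
    for epoch, suffix in (("present", ""), ("lig", "_lig")):
        for var in BIOCLIM_VARS:
            col = f"{var}{suffix}"
            if col not in table.columns:
                raise ValueError(f"missing climate column {col!r}")
            for measure in MEASURES:
                if measure not in table.columns:
                    continue
                res = spearman(table[measure], table[col], measure, var)
                rows.append(
                    {
                        "epoch": epoch,
                        "variable": var,
                        "measure": measure,
                        "rho": res.rho,
                        "p_value": res.p_value,
                        "n": res.n,
                    }
                )
    results = pd.DataFrame(rows)
    summary: dict[str, dict] = {}
    for epoch in ("present", "lig"):
        sub = results[(results["epoch"] == epoch) & (results["measure"] == "meth_total")].copy()
        pvals = sub["p_value"].to_numpy()
        if bh_correction:
            pvals = _benjamini_hochberg(pvals)
            sub["p_adjusted"] = pvals
        flagged = sub[pvals < alpha]
        summary[epoch] = {
            "n_associated": int(len(flagged)),
            "variables": list(flagged["variable"]),
        }
    return results, summary


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj


def epoch_shift_tests(table: pd.DataFrame, variable: str = "bio9") -> pd.DataFrame:
    """Paired present-vs-LIG comparison of one climate variable per group.

    For each methylation group, the variable's present and LIG values of
    the same accessions are compared with the Wilcoxon signed-rank test;
    reports medians, the shift and p.
    """
    col_now, col_lig = variable, f"{variable}_lig"
    rows = []
    for group, sub in table.groupby("group"):
        now = sub[col_now].to_numpy(float)
        lig = sub[col_lig].to_numpy(float)
        p, flag = wilcoxon_groups((now, lig), paired=True)
        rows.append(
            {
                "group": group,
                "n": len(sub),
                "median_present": float(np.median(now)),
                "median_lig": float(np.median(lig)),
                "median_shift": float(np.median(now - lig)),
                "p_value": p,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)
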