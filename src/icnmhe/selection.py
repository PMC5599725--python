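"""Statistical treatment of the performance grid.

Covers four questions about the cross-validated grid: do the classifier
families differ (paired t-tests over networks after averaging across
thresholds); which experimental factors drive performance (three-factor
fixed-effects factorial ANOVA with all two-way interactions); which networks
are stably predictive (the fraction of a network's 27 threshold x classifier
cells whose accuracy exceeds a cut, default 85%); and which thresholds are
best for a network (all co-optimal cells under an accuracy-then-sensitivity-
then-specificity ordering).
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "METRICS",
    "pairwise_classifier_tests",
    "factorial_anova",
    "stability_probability",
    "select_representative",
    "best_thresholds",
]

METRICS = ("acc", "sen", "spe")


def _require_columns(grid: pd.DataFrame) -> None:
    missing = {"icn", "threshold", "classifier", *METRICS} - set(grid.columns)
    if missing:
        raise ValueError(f"grid is missing columns: {sorted(missing)}")


def pairwise_classifier_tests(grid: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests between classifier families, per metric.

    Performance is first averaged over thresholds within each (network,
    classifier); each classifier pair is then compared with a two-sided paired
    t-test across networks. An all-zero difference vector is flagged degenerate
    and reported as p = 1.
    """
    _require_columns(grid)
    if grid["icn"].nunique() < 2:
        raise ValueError("need at least 2 networks for paired tests")
    avg = grid.groupby(["icn", "classifier"], sort=True)[list(METRICS)].mean()
    classifiers = sorted(grid["classifier"].unique())
    rows = []
    for metric in METRICS:
        wide = avg[metric].unstack("classifier")
        for a, b in itertools.combinations(classifiers, 2):
            diff = (wide[a] - wide[b]).to_numpy()
            degenerate = bool(np.var(diff) == 0)
            if degenerate:
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(wide[a], wide[b])
            rows.append(
                {
                    "metric": metric,
                    "classifier_a": a,
                    "classifier_b": b,
                    "t": float(t),
                    "p": float(p),
                    "df": len(diff) - 1,
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)


def _check_complete(grid: pd.DataFrame) -> None:
    levels = [sorted(grid[c].unique()) for c in ("threshold", "classifier", "icn")]
    expected = set(itertools.product(*levels))
    observed = set(zip(grid["threshold"], grid["classifier"], grid["icn"]))
    missing = expected - observed
    if missing:
        raise ValueError(
            f"incomplete factorial grid; {len(missing)} missing cells, e.g. "
            f"{sorted(missing)[:5]}"
        )


def factorial_anova(grid: pd.DataFrame, metric: str = "acc") -> pd.DataFrame:
    """Fixed-effects factorial ANOVA of a metric on threshold, classifier and
    network, with all two-way interactions.

    With one observation per cell the residual is the three-way interaction.
    Returns a frame with columns term, df, F, p (terms THR, CLS, ICN, THR:CLS,
    THR:ICN, CLS:ICN, Residual). A constant metric is reported as no-effect
    (F = 0, p = 1).
    """
    _require_columns(grid)
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    _check_complete(grid)
    data = grid.rename(columns={"threshold": "THR", "classifier": "CLS", "icn": "ICN"}).copy()
    data["y"] = data[metric]
    if np.allclose(data["y"].var(), 0.0):
        levels = {c: data[c].nunique() for c in ("THR", "CLS", "ICN")}
        terms = _df_table(levels)
        terms["F"] = 0.0
        terms["p"] = 1.0
        return terms
    formula = (
        "y ~ C(THR) + C(CLS) + C(ICN) + C(THR):C(CLS) + C(THR):C(ICN) + C(CLS):C(ICN)"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.ols(formula, data=data).fit()
        table = sm.stats.anova_lm(fit, typ=2)
    rename = {
        "C(THR)": "THR",
        "C(CLS)": "CLS",
        "C(ICN)": "ICN",
        "C(THR):C(CLS)": "THR:CLS",
        "C(THR):C(ICN)": "THR:ICN",
        "C(CLS):C(ICN)": "CLS:ICN",
    }
    out = table.rename(index=rename).reset_index().rename(
        columns={"index": "term", "PR(>F)": "p"}
    )
    out["df"] = out["df"].astype(int)
    return out[["term", "df", "F", "p"]]


def _df_table(levels: dict[str, int]) -> pd.DataFrame:
    l_thr, l_cls, l_icn = levels["THR"], levels["CLS"], levels["ICN"]
    rows = [
        ("THR", l_thr - 1),
        ("CLS", l_cls - 1),
        ("ICN", l_icn - 1),
        ("THR:CLS", (l_thr - 1) * (l_cls - 1)),
        ("THR:ICN", (l_thr - 1) * (l_icn - 1)),
        ("CLS:ICN", (l_cls - 1) * (l_icn - 1)),
        ("Residual", (l_thr - 1) * (l_cls - 1) * (l_icn - 1)),
    ]
    return pd.DataFrame(rows, columns=["term", "df"])


def stability_probability(grid: pd.DataFrame, acc_cut: float = 85.0) -> pd.DataFrame:
    """Per network, the percentage of threshold x classifier cells with
    accuracy strictly above ``acc_cut``, to one decimal."""
    _require_columns(grid)
    _check_complete(grid)
    n_cells = grid["threshold"].nunique() * grid["classifier"].nunique()

    def prob(sub: pd.DataFrame) -> float:
        return round(100.0 * (sub["acc"] > acc_cut).sum() / n_cells, 1)

    out = (
        grid.groupby("icn", sort=True)
        .apply(prob, include_groups=False)
        .rename("probability")
        .reset_index()
    )
    out["n_cells"] = n_cells
    return out.sort_values("probability", ascending=False, kind="stable").reset_index(drop=True)


def select_representative(stability: pd.DataFrame, p_cut: float = 70.0) -> list[str]:
    """Networks whose stability probability is >= ``p_cut`` percent, sorted by
    probability descending. An empty selection is valid (warned)."""
    sel = stability[stability["probability"] >= p_cut]
    sel = sel.sort_values("probability", ascending=False, kind="stable")
    if sel.empty:
        warnings.warn(f"no network reaches the {p_cut}% stability cut")
    return sel["icn"].tolist()


def best_thresholds(grid: pd.DataFrame, icn: str) -> tuple[list[float], dict[str, float]]:
    """All co-optimal thresholds for a network and the achieved metrics.

    Cells are ordered by accuracy, ties broken by sensitivity then specificity;
    every threshold achieving the optimum (under any classifier) is returned.
    """
    _require_columns(grid)
    sub = grid[grid["icn"] == icn]
    if sub.empty:
        raise ValueError(f"network {icn!r} not present in grid")
    key = list(zip(sub["acc"], sub["sen"], sub["spe"]))
    best = max(key)
    hit = sub[[k == best for k in key]]
    thresholds = sorted(hit["threshold"].unique())
    return thresholds, {"acc": best[0], "sen": best[1], "spe": best[2]}
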