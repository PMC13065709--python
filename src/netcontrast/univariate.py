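"""Mass-univariate mixed-model condition contrasts with FDR correction.

Per node (or per global metric), fits ``value ~ condition + age`` with
random intercepts for dataset and for participant nested within dataset,
and reports the age-adjusted fear-minus-neutral contrast.  Node-level
p-values for a local metric are Benjamini–Hochberg adjusted across all
nodes of that metric.

Sign convention: the contrast is fear − neutral, so a negative estimate
means the metric is lower in the fear condition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger("netcontrast")

__all__ = [
    "NodeContrastResult",
    "GlobalContrastResult",
    "fit_node_contrast",
    "fdr_adjust",
    "run_mass_univariate",
    "fit_global_contrast",
]


@dataclass
class NodeContrastResult:
    node_id: int
    b: float
    se: float
    t: float
    df: float
    p: float
    p_fdr: float = np.nan
    converged: bool = True
    fallback: bool = False


@dataclass
class GlobalContrastResult:
    metric: str
    mean_diff: float
    b: float
    se: float
    t: float
    df: float
    p: float
    converged: bool = True


def _check_long_table(df: pd.DataFrame) -> None:
    counts = df.groupby("participant_id")["condition"].nunique()
    if (counts < 2).any():
        who = counts.index[counts < 2][0]
        raise ValueError(f"participant {who!r} lacks one condition")


def _fit_mixed(sub: pd.DataFrame) -> tuple[float, float, bool, bool]:
    """Fit the nested mixed model on one node's long table.

    Returns ``(b, se, converged, fallback)`` where ``b`` is the
    fear − neutral fixed effect adjusted for age.  On a singular or
    non-convergent nested fit, falls back to a participant-only random
    intercept.
    """
    sub = sub.copy()
    sub["cond"] = (sub["condition"] == "fear").astype(float)
    # a constant covariate is collinear with the intercept and inestimable
    formula = ("value ~ cond + age" if sub["age"].nunique() > 1
               else "value ~ cond")

    def _try(groups: str, nested: bool):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            md = sm.MixedLM.from_formula(
                formula,
                groups=groups,
                re_formula="1",
                vc_formula=(
                    {"participant": "0 + C(participant_id)"} if nested else None
                ),
                data=sub,
            )
            try:
                fit = md.fit(reml=True, maxiter=200)
            except np.linalg.LinAlgError:
                fit = md.fit(reml=True, method="powell", maxiter=500)
        b = float(fit.params["cond"])
        se = float(fit.bse["cond"])
        ok = bool(fit.converged) and np.isfinite(se) and se > 0
        return b, se, ok

    if sub["dataset_id"].nunique() > 1:
        # nested structure: dataset random intercept plus a
        # participant-within-dataset variance component
        try:
            b, se, ok = _try("dataset_id", nested=True)
            if ok:
                return b, se, True, False
        except (np.linalg.LinAlgError, ValueError):
            pass
        logger.warning("nested mixed model singular; "
                       "falling back to participant-only random intercept")
    try:
        b, se, ok = _try("participant_id", nested=False)
        return b, se, ok, True
    except (np.linalg.LinAlgError, ValueError):
        return np.nan, np.nan, False, True


def fit_node_contrast(table: pd.DataFrame, node: int) -> NodeContrastResult:
    """Age-adjusted fear − neutral contrast for one node.

    ``table`` is long format with columns participant_id, dataset_id,
    condition, age, node_id, value.  The t reference uses
    ``df = n_participants − 1`` (the paired-design convention).
    """
    sub = table[table["node_id"] == node]
    if sub.empty:
        raise ValueError(f"node {node} absent from table")
    _check_long_table(sub)
    b, se, converged, fallback = _fit_mixed(sub)
    n_part = sub["participant_id"].nunique()
    df = float(n_part - 1)
    if not np.isfinite(b) or not np.isfinite(se) or se <= 0:
        return NodeContrastResult(node, np.nan, np.nan, np.nan, df, np.nan,
                                  converged=False, fallback=fallback)
    t = b / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return NodeContrastResult(node, b, se, t, df, p,
                              converged=converged, fallback=fallback)


def fdr_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment; NaNs pass through untouched."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.sum() == 0:
        return out
    vals = p[mask]
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    out[mask] = multipletests(vals, method="fdr_bh")[1]
    return out


def run_mass_univariate(table: pd.DataFrame) -> pd.DataFrame:
    """Contrast every node in the long table; FDR across all its nodes.

    Returns one row per node with columns node_id, b, se, t, df, p, p_fdr,
    converged, fallback.  Per-node failures yield NaN statistics but do
    not abort the run.
    """
    nodes = np.sort(table["node_id"].unique())
    results = []
    for node in nodes:
        try:
            results.append(fit_node_contrast(table, int(node)))
        except ValueError as exc:  # malformed node data: record, continue
            logger.warning("node %s failed: %s", node, exc)
            results.append(
                NodeContrastResult(int(node), np.nan, np.nan, np.nan,
                                   np.nan, np.nan, converged=False)
            )
    df = pd.DataFrame(
        {
            "node_id": [r.node_id for r in results],
            "b": [r.b for r in results],
            "se": [r.se for r in results],
            "t": [r.t for r in results],
            "df": [r.df for r in results],
            "p": [r.p for r in results],
            "converged": [r.converged for r in results],
            "fallback": [r.fallback for r in results],
        }
    )
    df["p_fdr"] = fdr_adjust(df["p"].to_numpy())
    return df


def fit_global_contrast(table: pd.DataFrame, metric: str) -> GlobalContrastResult:
    """Mixed-model contrast for a scalar global metric (e_global or q)."""
    if metric not in ("e_global", "q"):
        raise ValueError(f"unknown global metric {metric!r}")
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise ValueError(f"metric {metric!r} absent from table")
    _check_long_table(sub)
    b, se, converged, _ = _fit_mixed(sub)
    pivot = sub.pivot_table(index="participant_id", columns="condition",
                            values="value")
    mean_diff = float((pivot["fear"] - pivot["neutral"]).mean())
    n_part = sub["participant_id"].nunique()
    df = float(n_part - 1)
    if not np.isfinite(b) or not np.isfinite(se) or se <= 0:
        return GlobalContrastResult(metric, mean_diff, np.nan, np.nan,
                                    np.nan, df, np.nan, converged=False)
    t = b / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return GlobalContrastResult(metric, mean_diff, b, se, t, df, p,
                                converged=converged)


def attach_node_labels(results: pd.DataFrame, node_table) -> pd.DataFrame:
    """Join hemisphere/region/network labels for a Table-2-shaped CSV."""
    labels = node_table.table.rename(columns={"parcel_name": "region"})
    merged = results.merge(labels, on="node_id")
    cols = ["hemisphere", "region", "network", "node_id",
            "b", "se", "t", "df", "p", "p_fdr"]
    return merged[cols]
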