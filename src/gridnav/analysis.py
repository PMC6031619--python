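"""Cohort-level relationships between the fitted hybrid weight and the
navigation indices, plus parameter-recovery reporting for simulated cohorts.

The headline behavioural result this mirrors: subjects whose choices are
better explained by the model-based controller (larger omega) take shortest
paths more often (I_PATH up), waste fewer steps (I_STEPS up) and repeat
learned routes less (I_ROUTE down).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class UndefinedCorrelationError(ValueError):
    """A correlation is undefined (zero variance in one of the inputs)."""


class SubjectMatchError(ValueError):
    """Subject identifiers of two tables do not line up."""


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its two-tailed t-test (df = n - 2)."""

    pair: tuple[str, str]
    r: float
    n: int
    t: float
    p: float


def pearson_with_test(x, y, pair: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Pearson r with the standard t statistic ``r sqrt((n-2)/(1-r^2))``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.var(x) == 0 or np.var(y) == 0:
        raise UndefinedCorrelationError(f"zero variance in pair {pair}")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    n = len(x)
    t = r * np.sqrt((n - 2) / max(1.0 - r * r, np.finfo(float).tiny))
    return CorrelationResult(pair=pair, r=r, n=n, t=float(t), p=float(res.pvalue))


def _check_match(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    if set(a["subject_id"]) != set(b["subject_id"]):
        raise SubjectMatchError("subject identifiers do not match between tables")
    merged = a.merge(b, on="subject_id", validate="one_to_one")
    if len(merged) < 3:
        raise ValueError("need at least 3 matched subjects")
    return merged


def omega_index_report(
    omegas: pd.DataFrame,
    indices_avg: pd.DataFrame,
    fig_dir=None,
) -> pd.DataFrame:
    """Correlate phase-averaged omega with each phase-averaged index.

    ``omegas`` needs columns ``subject_id`` and ``omega_mean`` (as produced
    by :func:`gridnav.fitting.omega_summary`); ``indices_avg`` needs
    ``subject_id`` plus ``i_path``, ``i_steps``, ``i_route``.  Optionally
    writes one scatter panel per index to ``fig_dir``.

    No multiple-testing correction is applied; p-values are raw two-tailed.
    """
    merged = _check_match(
        omegas[["subject_id", "omega_mean"]], indices_avg
    )
    rows = []
    for index_name in ("i_path", "i_steps", "i_route"):
        res = pearson_with_test(
            merged["omega_mean"], merged[index_name], pair=("omega", index_name)
        )
        rows.append(
            {
                "index": index_name,
                "r": res.r,
                "n": res.n,
                "t": res.t,
                "p": res.p,
            }
        )
        if fig_dir is not None:
            _scatter_panel(merged, index_name, res, fig_dir)
    return pd.DataFrame(rows)


def _scatter_panel(merged: pd.DataFrame, index_name: str, res, fig_dir) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(merged["omega_mean"], merged[index_name], s=25, alpha=0.8)
    b, a = np.polyfit(merged["omega_mean"], merged[index_name], 1)
    xs = np.linspace(merged["omega_mean"].min(), merged["omega_mean"].max(), 50)
    ax.plot(xs, a + b * xs, color="crimson")
    ax.set_xlabel("fitted ω (phase-averaged)")
    ax.set_ylabel(index_name.upper())
    ax.set_title(f"r({res.n - 2}) = {res.r:.2f}, p = {res.p:.2g}")
    fig.tight_layout()
    fig.savefig(Path(fig_dir) / f"omega_vs_{index_name}.png", dpi=120)
    plt.close(fig)


def recovery_report(truth: pd.DataFrame, fits: pd.DataFrame) -> pd.DataFrame:
    """True-versus-fitted agreement per parameter of a simulated cohort.

    ``fits`` is the per-subject x phase table from
    :func:`gridnav.fitting.fit_cohort`; fitted values are phase-averaged
    before comparison.  Reports Pearson r, bias (fitted - true) and RMSE
    per free parameter; the headline metric is omega recovery.
    """
    hy = fits[fits["model"] == "hybrid"]
    if hy.empty:
        raise ValueError("recovery requires hybrid fits")
    avg = hy.groupby("subject_id")[["alpha", "beta", "lam", "omega"]].mean()
    merged = _check_match(truth, avg.reset_index())
    rows = []
    for name in ("alpha", "beta", "lam", "omega"):
        true = merged[f"{name}_x"].to_numpy()
        fitted = merged[f"{name}_y"].to_numpy()
        try:
            r = pearson_with_test(true, fitted, pair=(name, f"{name}_hat")).r
        except UndefinedCorrelationError:
            r = float("nan")
        rows.append(
            {
                "parameter": name,
                "r": r,
                "bias": float(np.mean(fitted - true)),
                "rmse": float(np.sqrt(np.mean((fitted - true) ** 2))),
                "n": len(merged),
            }
        )
    return pd.DataFrame(rows)
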