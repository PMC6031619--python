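"""Fitting the learning models to choice logs.

Each subject x phase slice is fitted separately by penalised maximum
likelihood (MAP): the softmax choice log-likelihood of the replayed log plus
weakly-informative priors — Beta(1.2, 1.2) on alpha, lambda and omega,
Gamma(shape 2, scale 3) on beta — maximised by box-constrained L-BFGS-B from
Latin-hypercube starting points.  Priors can be switched off for pure ML, and
an optional empirical-Bayes pass re-estimates the prior hyperparameters from
the cohort's MAP estimates and refits once.

Three model variants share one replay engine:

* ``model_free``  — omega fixed at 0; free (alpha, beta, lam), k = 3
* ``model_based`` — omega fixed at 1; free (beta,), k = 1 (planning values
  need no learning, so the replay reduces to a static softmax)
* ``hybrid``      — free (alpha, beta, lam, omega), k = 4

By default the model-free tables are re-initialised at each phase start,
matching the per-phase independence of the fitted parameters; a carry-over
switch replays earlier phases first to warm-start the tables instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import betaln
from scipy.stats import qmc

from ._replay import replay_logprobs
from .maze import AgentState, DIR_INDEX, Maze, PHASES, legal_actions
from .rl import ModelParams, value_iteration_all

MODELS = ("model_free", "model_based", "hybrid")

#: Free parameters and their box constraints per model variant.
FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "model_free": ("alpha", "beta", "lam"),
    "model_based": ("beta",),
    "hybrid": ("alpha", "beta", "lam", "omega"),
}

_UNIT_EPS = 1e-4


class CorruptLogError(ValueError):
    """A choice record contradicts the environment's movement rules."""


class FitError(RuntimeError):
    """No optimisation restart converged; carries per-restart diagnostics."""

    def __init__(self, message: str, diagnostics: list):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class Priors:
    """Hyperparameters of the MAP priors.

    ``alpha``, ``lam``, ``omega`` hold Beta(a, b); ``beta`` holds
    Gamma(shape, scale).
    """

    alpha: tuple[float, float] = (1.2, 1.2)
    lam: tuple[float, float] = (1.2, 1.2)
    omega: tuple[float, float] = (1.2, 1.2)
    beta: tuple[float, float] = (2.0, 3.0)


@dataclass(frozen=True)
class FitConfig:
    n_restarts: int = 10
    use_priors: bool = True
    priors: Priors = field(default_factory=Priors)
    seed: int = 0
    beta_max: float = 30.0
    carry_over: bool = False
    gamma: float = 0.1
    ftol: float = 1e-8


@dataclass
class FitResult:
    subject_id: str
    phase: str
    model: str
    params: ModelParams
    neg_log_likelihood: float
    n_choices: int
    aic: float
    bic: float
    n_restarts: int
    n_converged: int
    best_objective: float

    @property
    def k(self) -> int:
        return len(FREE_PARAMS[self.model])

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "phase": self.phase,
            "model": self.model,
            "alpha": self.params.alpha,
            "beta": self.params.beta,
            "lam": self.params.lam,
            "omega": self.params.omega,
            "nll": self.neg_log_likelihood,
            "n_choices": self.n_choices,
            "aic": self.aic,
            "bic": self.bic,
            "n_restarts": self.n_restarts,
            "n_converged": self.n_converged,
        }


class ReplayData:
    """A validated, array-packed slice of a choice log ready for replay."""

    def __init__(self, log: pd.DataFrame, maze: Maze):
        log = log.loc[~log["truncated"]].reset_index(drop=True)
        if log.empty:
            raise ValueError("empty log slice")
        self.n = len(log)
        self.maze = maze
        self.room = (
            log["room_row"].to_numpy(np.int64) * maze.n_cols
            + log["room_col"].to_numpy(np.int64)
        )
        self.act = np.array([DIR_INDEX[a] for a in log["chosen"]], dtype=np.int64)
        self.avail = np.zeros((self.n, 4), dtype=bool)
        for i, s in enumerate(log["available"]):
            for d in s:
                self.avail[i, DIR_INDEX[d]] = True
        self.reward = log["reward"].to_numpy(np.float64)
        self.context = log["leg_context"].to_numpy(np.int64)
        trial = log["trial"].to_numpy()
        phase = log["phase"].to_numpy()
        self.new_leg = np.zeros(self.n, dtype=bool)
        self.new_leg[0] = True
        self.new_leg[1:] = (
            (trial[1:] != trial[:-1])
            | (self.context[1:] != self.context[:-1])
            | (phase[1:] != phase[:-1])
        )
        self.phase = phase
        self._validate(log)

    def _validate(self, log: pd.DataFrame) -> None:
        maze = self.maze
        for i in range(self.n):
            room = maze.index_room(self.room[i])
            entry = log["entry_dir"].iloc[i] or None
            legal = set(legal_actions(maze, AgentState(room, entry)))
            recorded = set(log["available"].iloc[i])
            if recorded != legal:
                raise CorruptLogError(
                    f"row {i}: recorded actions {recorded} != legal {legal} "
                    f"at {room} (entry {entry})"
                )
            if log["chosen"].iloc[i] not in recorded:
                raise CorruptLogError(f"row {i}: chosen action not available")
        # exactly one reward, on the final step of each leg
        leg_id = np.cumsum(self.new_leg)
        for leg in np.unique(leg_id):
            r = self.reward[leg_id == leg]
            if r.sum() != 1 or r[-1] != 1:
                raise CorruptLogError(
                    f"leg {leg}: expected exactly one terminal reward"
                )

    def uniform_loglik(self) -> float:
        """Log-likelihood of the beta = 0 (uniform) policy — an upper NLL bound."""
        return float(-np.log(self.avail.sum(axis=1)).sum())


def step_logprobs(
    data: ReplayData,
    model: str,
    params: ModelParams,
    q_mb: np.ndarray,
    q_mf0: np.ndarray | None = None,
) -> np.ndarray:
    """Per-choice log probabilities under a model variant.

    ``q_mf0``, when given, is consumed as the starting model-free tables and
    mutated in place (used to chain phases under carry-over).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if model == "model_based":
        # no learning: a static softmax over the planning values
        vals = params.beta * q_mb[data.context, data.room, :]
        vals = np.where(data.avail, vals, -np.inf)
        m = vals.max(axis=1)
        lse = m + np.log(np.exp(vals - m[:, None]).sum(axis=1))
        return vals[np.arange(data.n), data.act] - lse
    omega = 0.0 if model == "model_free" else params.omega
    if q_mf0 is None:
        q_mf0 = np.zeros_like(q_mb)
    return replay_logprobs(
        data.room,
        data.act,
        data.avail,
        data.reward,
        data.context,
        data.new_leg,
        q_mb,
        params.alpha,
        params.beta,
        params.lam,
        omega,
        q_mf0,
    )


def choice_loglik(
    log: pd.DataFrame | ReplayData,
    model: str,
    params: ModelParams,
    maze: Maze,
    q_mb: np.ndarray | None = None,
    q_mf0: np.ndarray | None = None,
) -> float:
    """Total choice log-likelihood (nats) of a log slice under a model."""
    data = log if isinstance(log, ReplayData) else ReplayData(log, maze)
    if q_mb is None:
        q_mb, _ = value_iteration_all(maze, gamma=params.gamma)
    return float(step_logprobs(data, model, params, q_mb, q_mf0).sum())


def _log_prior(theta: dict[str, float], priors: Priors) -> float:
    lp = 0.0
    for name in ("alpha", "lam", "omega"):
        if name in theta:
            a, b = getattr(priors, name)
            x = theta[name]
            lp += (a - 1) * math.log(x) + (b - 1) * math.log1p(-x) - betaln(a, b)
    if "beta" in theta:
        shape, scale = priors.beta
        x = theta["beta"]
        lp += (
            (shape - 1) * math.log(x)
            - x / scale
            - math.lgamma(shape)
            - shape * math.log(scale)
        )
    return lp


def _bounds(model: str, config: FitConfig) -> list[tuple[float, float]]:
    out = []
    for name in FREE_PARAMS[model]:
        if name == "beta":
            out.append((1e-3, config.beta_max))
        else:
            out.append((_UNIT_EPS, 1.0 - _UNIT_EPS))
    return out


def _warm_start(
    full_data: ReplayData | None,
    phase: str,
    params: ModelParams,
    model: str,
    q_mb: np.ndarray,
) -> np.ndarray | None:
    """Model-free tables after replaying the phases preceding ``phase``."""
    if full_data is None:
        return None
    q_mf = np.zeros_like(q_mb)
    for prev in PHASES[: PHASES.index(phase)]:
        mask = full_data.phase == prev
        if not mask.any():
            continue
        sub = _slice_data(full_data, mask)
        replay_logprobs(
            sub.room,
            sub.act,
            sub.avail,
            sub.reward,
            sub.context,
            sub.new_leg,
            q_mb,
            params.alpha,
            params.beta,
            params.lam,
            0.0 if model == "model_free" else params.omega,
            q_mf,
        )
    return q_mf


def _slice_data(data: ReplayData, mask: np.ndarray) -> ReplayData:
    out = ReplayData.__new__(ReplayData)
    out.maze = data.maze
    out.n = int(mask.sum())
    for name in ("room", "act", "avail", "reward", "context", "new_leg", "phase"):
        setattr(out, name, getattr(data, name)[mask])
    out.new_leg = out.new_leg.copy()
    out.new_leg[0] = True
    return out


def fit_subject_phase(
    log: pd.DataFrame | ReplayData,
    model: str,
    maze: Maze,
    config: FitConfig = FitConfig(),
    q_mb: np.ndarray | None = None,
    subject_id: str = "",
    phase: str = "",
    full_log: pd.DataFrame | ReplayData | None = None,
) -> FitResult:
    """MAP fit of one model to one subject-phase slice.

    Multi-start L-BFGS-B; the best restart wins.  AIC/BIC are computed from
    the pure (unpenalised) negative log-likelihood at the MAP estimate.
    ``full_log`` is only consulted under ``config.carry_over`` to warm-start
    the model-free tables from the preceding phases.
    """
    data = log if isinstance(log, ReplayData) else ReplayData(log, maze)
    if data.n < 10:
        raise ValueError(f"need >= 10 choices to fit, got {data.n}")
    if q_mb is None:
        q_mb, _ = value_iteration_all(maze, gamma=config.gamma)
    full_data = None
    if config.carry_over and full_log is not None:
        full_data = (
            full_log
            if isinstance(full_log, ReplayData)
            else ReplayData(full_log, maze)
        )
    names = FREE_PARAMS[model]
    bounds = _bounds(model, config)

    def objective(x: np.ndarray) -> float:
        theta = dict(zip(names, x))
        params = ModelParams(
            alpha=theta.get("alpha", 0.5),
            beta=theta["beta"],
            lam=theta.get("lam", 0.5),
            omega=theta.get("omega", 0.5),
            gamma=config.gamma,
        )
        q_mf0 = _warm_start(full_data, phase, params, model, q_mb)
        nll = -float(step_logprobs(data, model, params, q_mb, q_mf0).sum())
        if config.use_priors:
            nll -= _log_prior(theta, config.priors)
        return nll

    sampler = qmc.LatinHypercube(d=len(names), seed=config.seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = lo + sampler.random(config.n_restarts) * (hi - lo)
    best, diagnostics, n_conv = None, [], 0
    for x0 in starts:
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": config.ftol, "maxiter": 500},
        )
        diagnostics.append((res.success, res.fun, res.message))
        n_conv += bool(res.success)
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError(f"no restart converged for {subject_id}/{phase}/{model}", diagnostics)
    theta = dict(zip(names, best.x))
    params = ModelParams(
        alpha=theta.get("alpha", 0.5),
        beta=theta["beta"],
        lam=theta.get("lam", 0.5),
        omega={"model_free": 0.0, "model_based": 1.0}.get(model, theta.get("omega", 0.5)),
        gamma=config.gamma,
    )
    q_mf0 = _warm_start(full_data, phase, params, model, q_mb)
    nll = -float(step_logprobs(data, model, params, q_mb, q_mf0).sum())
    k = len(names)
    return FitResult(
        subject_id=subject_id,
        phase=phase,
        model=model,
        params=params,
        neg_log_likelihood=nll,
        n_choices=data.n,
        aic=2 * k + 2 * nll,
        bic=k * math.log(data.n) + 2 * nll,
        n_restarts=config.n_restarts,
        n_converged=n_conv,
        best_objective=float(best.fun),
    )


def fit_cohort(
    log: pd.DataFrame,
    models,
    maze: Maze,
    config: FitConfig = FitConfig(),
) -> pd.DataFrame:
    """Fit one or more models to every subject x phase slice of a cohort log."""
    if isinstance(models, str):
        models = [models]
    q_mb, _ = value_iteration_all(maze, gamma=config.gamma)
    rows = []
    for subject, sub_log in log.groupby("subject_id", sort=False):
        full_data = ReplayData(sub_log, maze) if config.carry_over else None
        for phase in PHASES:
            slice_df = sub_log[sub_log["phase"] == phase]
            if slice_df.empty:
                continue
            data = ReplayData(slice_df, maze)
            for model in models:
                fit = fit_subject_phase(
                    data,
                    model,
                    maze,
                    config,
                    q_mb=q_mb,
                    subject_id=subject,
                    phase=phase,
                    full_log=full_data,
                )
                rows.append(fit.to_dict())
    return pd.DataFrame(rows)


def omega_summary(fits: pd.DataFrame) -> pd.DataFrame:
    """Per-subject hybrid omega by phase plus the across-phase mean."""
    hy = fits[fits["model"] == "hybrid"]
    if hy.empty:
        raise ValueError("no hybrid fits in table")
    wide = hy.pivot(index="subject_id", columns="phase", values="omega")
    wide["omega_mean"] = wide.mean(axis=1)
    return wide.reset_index()


def compare_models(fits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Model comparison per subject x phase and cohort best-model counts.

    Delta AIC/BIC are relative to each slice's best model; ties break toward
    the model with fewer free parameters.
    """
    if set(fits["model"].unique()) != set(MODELS):
        missing = set(MODELS) - set(fits["model"].unique())
        raise ValueError(f"missing fits for models: {sorted(missing)}")
    k_of = {m: len(FREE_PARAMS[m]) for m in MODELS}
    rows = []
    for (subject, phase), group in fits.groupby(["subject_id", "phase"]):
        if set(group["model"]) != set(MODELS):
            raise ValueError(f"incomplete model set for {subject}/{phase}")
        g = group.copy()
        g["k"] = g["model"].map(k_of)
        best_aic = g.sort_values(["aic", "k"]).iloc[0]
        best_bic = g.sort_values(["bic", "k"]).iloc[0]
        for _, r in g.iterrows():
            rows.append(
                {
                    "subject_id": subject,
                    "phase": phase,
                    "model": r["model"],
                    "nll": r["nll"],
                    "aic": r["aic"],
                    "bic": r["bic"],
                    "delta_aic": r["aic"] - best_aic["aic"],
                    "delta_bic": r["bic"] - best_bic["bic"],
                    "best_aic": r["model"] == best_aic["model"],
                    "best_bic": r["model"] == best_bic["model"],
                }
            )
    table = pd.DataFrame(rows)
    counts = (
        table[table["best_bic"]]
        .groupby(["phase", "model"])
        .size()
        .rename("n_best_bic")
        .reset_index()
    )
    return table, counts


def empirical_bayes_refit(
    log: pd.DataFrame,
    model: str,
    maze: Maze,
    config: FitConfig = FitConfig(),
) -> tuple[pd.DataFrame, Priors]:
    """One empirical-Bayes pass: fit, moment-match priors, refit once.

    Beta hyperparameters come from matching the cohort mean/variance of each
    unit-interval parameter; Gamma hyperparameters from the mean/variance of
    beta.  Returns the refit table and the updated priors.
    """
    first = fit_cohort(log, model, maze, config)

    def beta_mm(x: np.ndarray) -> tuple[float, float]:
        m, v = float(np.mean(x)), float(np.var(x))
        v = max(v, 1e-4)
        common = max(m * (1 - m) / v - 1.0, 0.05)
        return max(m * common, 1.01), max((1 - m) * common, 1.01)

    def gamma_mm(x: np.ndarray) -> tuple[float, float]:
        m, v = float(np.mean(x)), float(np.var(x))
        v = max(v, 1e-4)
        return max(m * m / v, 0.5), max(v / m, 1e-3)

    kwargs = {}
    for name in FREE_PARAMS[model]:
        vals = first[name].to_numpy()
        kwargs[name] = gamma_mm(vals) if name == "beta" else beta_mm(vals)
    priors = replace(Priors(), **kwargs)
    refit = fit_cohort(log, model, maze, replace(config, priors=priors))
    return refit, priors


def write_fits(fits: pd.DataFrame, path) -> None:
    fits.to_csv(path, sep="\t", index=False)


def read_fits(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
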