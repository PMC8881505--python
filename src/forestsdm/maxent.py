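"""Presence-background maximum-entropy modelling, implemented from scratch.

The model is a Gibbs distribution over the background points,

    q(x) = exp(sum_j beta_j f_j(x)) / Z,   Z = sum_background exp(.),

fitted by minimising the L1-penalised negative mean presence log-density

    -(1/n) sum_presence eta(x_i) + log Z + sum_j lambda_j |beta_j|

with cyclic coordinate descent and soft-thresholding. At the optimum the
defining Maxent property holds feature-wise (KKT):

    |E_presence[f_j] - E_model[f_j]| <= lambda_j,

with equality for active features. Training gain is the mean log improvement
of q at presences over the uniform background distribution; per-variable
contributions are path attributions of the objective decrease, with
permutation importance available as an independent estimator.

This module exists (rather than delegating to an external Maxent binary)
because the analysis needs access to the fit path for gain attribution and
to the exact penalty weights for the KKT diagnostics.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import rankdata

from .errors import DataError, PipelineError

__all__ = [
    "Feature",
    "FeatureSet",
    "MaxentModel",
    "expand_features",
    "default_lambdas",
    "fit",
    "training_gain",
    "variable_contribution",
    "permutation_importance",
    "auc",
    "aicc",
    "tune",
    "cross_validated_auc",
    "kkt_residuals",
    "TuneResult",
]

# Published Maxent default per-class regularization parameters, interpolated
# over the number of presence records (hinge is constant).
_BETA_TABLES: dict[str, tuple[list[float], list[float]]] = {
    "linear": ([10, 30, 100], [1.0, 0.2, 0.05]),
    "quadratic": ([0, 10, 17, 30, 100], [1.3, 0.8, 0.5, 0.25, 0.05]),
    "hinge": ([0], [0.5]),
    "categorical": ([0, 10, 17], [0.65, 0.5, 0.25]),
}


def _class_beta(cls: str, n_presences: int) -> float:
    xs, ys = _BETA_TABLES[cls]
    return float(np.interp(n_presences, xs, ys))


@dataclass(frozen=True)
class Feature:
    """One basis function of the model, scaled to [0, 1] over the background."""

    name: str
    variable: str
    cls: str  # 'linear' | 'quadratic' | 'hinge' | 'categorical'
    lo: float = 0.0  # scaling constants (background min/max of the raw value)
    hi: float = 1.0
    knot: float = 0.0
    direction: int = 0  # hinge: +1 forward, -1 reverse
    level: str | None = None  # categorical indicator level

    def transform(self, x: np.ndarray) -> np.ndarray:
        # values are clamped to the background range [0, 1]: a presence point
        # outside the training range must not be linearly extrapolated
        if self.cls == "linear":
            return np.clip((np.asarray(x, dtype=float) - self.lo) / (self.hi - self.lo), 0.0, 1.0)
        if self.cls == "quadratic":
            return np.clip((np.asarray(x, dtype=float) ** 2 - self.lo) / (self.hi - self.lo), 0.0, 1.0)
        if self.cls == "hinge":
            x = np.asarray(x, dtype=float)
            if self.direction > 0:
                return np.clip((x - self.knot) / (self.hi - self.knot), 0.0, 1.0)
            return np.clip((self.knot - x) / (self.knot - self.lo), 0.0, 1.0)
        if self.cls == "categorical":
            return (np.asarray(x) == self.level).astype(float)
        raise DataError(f"unknown feature class {self.cls!r}")


@dataclass
class FeatureSet:
    """Ordered collection of features with their source variables."""

    features: list[Feature]

    def __len__(self) -> int:
        return len(self.features)

    @property
    def variables(self) -> list[str]:
        seen: list[str] = []
        for f in self.features:
            if f.variable not in seen:
                seen.append(f.variable)
        return seen

    def feature_variables(self) -> np.ndarray:
        return np.array([f.variable for f in self.features])

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        cols = [f.transform(table[f.variable].to_numpy()) for f in self.features]
        X = np.column_stack(cols) if cols else np.empty((len(table), 0))
        if not np.all(np.isfinite(X)):
            raise DataError("non-finite feature values after expansion")
        return X

    def to_dict(self) -> list[dict]:
        return [vars(f).copy() for f in self.features]

    @classmethod
    def from_dict(cls, items: list[dict]) -> "FeatureSet":
        return cls([Feature(**it) for it in items])


def expand_features(
    presences: pd.DataFrame,
    backgrounds: pd.DataFrame,
    quantitative: list[str],
    categorical: list[str] = (),
    classes: str = "LQH",
    n_hinge_knots: int = 50,
) -> tuple[np.ndarray, np.ndarray, FeatureSet]:
    """Expand raw variables into the model's feature basis.

    Scaling constants and hinge knots come from the background sample and are
    reused for presences. Quantitative variables that are constant over the
    background are excluded with a warning; categorical indicators are built
    for the levels observed in the background (a level absent from the
    background carries no density information and would be unbounded).
    """
    classes = set(classes.upper())
    if not classes <= {"L", "Q", "H"}:
        raise DataError("feature classes must be a subset of L/Q/H")
    features: list[Feature] = []
    for var in quantitative:
        xb = backgrounds[var].to_numpy(dtype=float)
        lo, hi = float(np.min(xb)), float(np.max(xb))
        if not np.isfinite([lo, hi]).all() or hi <= lo:
            warnings.warn(f"variable {var!r} is constant over the background; excluded")
            continue
        if "L" in classes:
            features.append(Feature(var, var, "linear", lo=lo, hi=hi))
        if "Q" in classes:
            x2 = xb**2
            lo2, hi2 = float(np.min(x2)), float(np.max(x2))
            if hi2 > lo2:
                features.append(Feature(f"{var}^2", var, "quadratic", lo=lo2, hi=hi2))
        if "H" in classes:
            qs = np.quantile(xb, (np.arange(n_hinge_knots) + 1) / (n_hinge_knots + 1))
            knots = np.unique(qs)
            for k in knots:
                if lo < k < hi:
                    features.append(
                        Feature(f"hinge+({var},{k:.6g})", var, "hinge", lo=lo, hi=hi, knot=float(k), direction=1)
                    )
            for k in knots:
                if lo < k < hi:
                    features.append(
                        Feature(f"hinge-({var},{k:.6g})", var, "hinge", lo=lo, hi=hi, knot=float(k), direction=-1)
                    )
    for var in categorical:
        levels = sorted(pd.unique(backgrounds[var].astype(str)))
        if len(levels) < 2:
            warnings.warn(f"categorical variable {var!r} has a single background level; excluded")
            continue
        for lev in levels:
            features.append(Feature(f"{var}={lev}", var, "categorical", level=lev))
    fs = FeatureSet(features)
    cat_cast = {v: backgrounds[v].astype(str) for v in categorical}
    bg = backgrounds.assign(**cat_cast) if categorical else backgrounds
    pr = presences.assign(**{v: presences[v].astype(str) for v in categorical}) if categorical else presences
    return fs.transform(pr), fs.transform(bg), fs


def default_lambdas(
    feature_set: FeatureSet, Xp: np.ndarray, rm: float = 1.0, sd_floor: float = 0.01
) -> np.ndarray:
    """Per-feature L1 weights: rm x beta_class(n) x sd_presence / sqrt(n).

    ``sd_floor`` keeps every weight strictly positive (features live on a
    [0, 1] scale) so a feature constant over presences cannot blow up.
    """
    n = Xp.shape[0]
    s = np.maximum(Xp.std(axis=0), sd_floor)
    betas = np.array([_class_beta(f.cls, n) for f in feature_set.features])
    return rm * betas * s / math.sqrt(max(n, 1))


@dataclass
class MaxentModel:
    """A fitted model: features, coefficients, penalties and fit summaries."""

    feature_set: FeatureSet
    beta: np.ndarray
    lambdas: np.ndarray
    rm: float
    log_z: float  # log sum_background exp(eta) at the optimum
    n_background: int
    n_presence: int
    gain: float
    classes: str = "LQH"
    converged: bool = True
    n_cycles: int = 0
    objective: float = float("nan")
    trace: dict[str, float] = field(default_factory=dict)  # variable -> summed objective decrease
    bg_eta_sorted: np.ndarray | None = None  # for cumulative output

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.beta))

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return X @ self.beta

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        """Raw output: q(x), normalised to sum to 1 over the background."""
        return np.exp(self.linear_predictor(X) - self.log_z)

    def predict_cumulative(self, X: np.ndarray) -> np.ndarray:
        """Percentage of background points scoring at or below each point."""
        if self.bg_eta_sorted is None:
            raise PipelineError("model was fitted without background score storage")
        eta = self.linear_predictor(X)
        ranks = np.searchsorted(self.bg_eta_sorted, eta, side="right")
        return 100.0 * ranks / len(self.bg_eta_sorted)

    def to_dict(self) -> dict:
        return {
            "features": self.feature_set.to_dict(),
            "beta": self.beta.tolist(),
            "lambdas": self.lambdas.tolist(),
            "rm": self.rm,
            "log_z": self.log_z,
            "n_background": self.n_background,
            "n_presence": self.n_presence,
            "gain": self.gain,
            "classes": self.classes,
            "converged": self.converged,
            "n_cycles": self.n_cycles,
            "objective": self.objective,
            "trace": self.trace,
            "bg_eta_sorted": None if self.bg_eta_sorted is None else self.bg_eta_sorted.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "MaxentModel":
        return cls(
            feature_set=FeatureSet.from_dict(d["features"]),
            beta=np.asarray(d["beta"], dtype=float),
            lambdas=np.asarray(d["lambdas"], dtype=float),
            rm=d["rm"],
            log_z=d["log_z"],
            n_background=d["n_background"],
            n_presence=d["n_presence"],
            gain=d["gain"],
            classes=d.get("classes", "LQH"),
            converged=d.get("converged", True),
            n_cycles=d.get("n_cycles", 0),
            objective=d.get("objective", float("nan")),
            trace=d.get("trace", {}),
            bg_eta_sorted=None
            if d.get("bg_eta_sorted") is None
            else np.asarray(d["bg_eta_sorted"], dtype=float),
        )

    @classmethod
    def from_json(cls, path) -> "MaxentModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _log_sum_exp(eta: np.ndarray) -> float:
    m = eta.max()
    return float(m + math.log(np.exp(eta - m).sum()))


@njit(cache=True)
def _sweep_kernel(cols, fmean, lambdas, beta, eta_b, mean_eta_p, log_z, obj, order, improvements):
    """One coordinate-descent pass (numba-compiled inner loop).

    ``cols`` is the background design transposed (J, N). Mutates ``beta``,
    ``eta_b`` and ``improvements`` in place; returns the updated scalar state
    (mean presence eta, log Z, objective).
    """
    N = eta_b.shape[0]
    for oi in range(order.shape[0]):
        j = order[oi]
        mx = eta_b[0]
        for i in range(1, N):
            if eta_b[i] > mx:
                mx = eta_b[i]
        s = 0.0
        e1 = 0.0
        e2 = 0.0
        for i in range(N):
            w = math.exp(eta_b[i] - mx)
            x = cols[j, i]
            s += w
            e1 += w * x
            e2 += w * x * x
        e1 /= s
        e2 /= s
        g = e1 - fmean[j]
        h = e2 - e1 * e1
        if h < 1e-12:
            h = 1e-12
        z = h * beta[j] - g
        az = abs(z) - lambdas[j]
        if az < 0.0:
            az = 0.0
        target = (az / h) if z > 0 else (-az / h)
        d = target - beta[j]
        if abs(d) < 1e-13:
            continue
        penalty_rest = obj + mean_eta_p - log_z
        for _ in range(40):
            nb = beta[j] + d
            mx2 = eta_b[0] + d * cols[j, 0]
            for i in range(1, N):
                v = eta_b[i] + d * cols[j, i]
                if v > mx2:
                    mx2 = v
            s2 = 0.0
            for i in range(N):
                s2 += math.exp(eta_b[i] + d * cols[j, i] - mx2)
            new_log_z = mx2 + math.log(s2)
            new_mean = mean_eta_p + d * fmean[j]
            new_obj = -new_mean + new_log_z + penalty_rest + lambdas[j] * (abs(nb) - abs(beta[j]))
            if new_obj <= obj + 1e-12:
                for i in range(N):
                    eta_b[i] += d * cols[j, i]
                beta[j] = nb
                log_z = new_log_z
                mean_eta_p = new_mean
                if obj - new_obj > 0.0:
                    improvements[j] += obj - new_obj
                obj = new_obj
                break
            d *= 0.5
            if abs(d) < 1e-14:
                break
    return mean_eta_p, log_z, obj


def _penalised_objective(Xb, fmean, lambdas, beta):
    eta = Xb @ beta
    return float(-(fmean @ beta) + _log_sum_exp(eta) + lambdas @ np.abs(beta))


def _newton_polish(Xb, fmean, lambdas, beta, active, max_iter=50, grad_tol=1e-11):
    """Equality-phase Newton solve restricted to the active (non-zero) set.

    Coordinate descent localises the solution but its terminal convergence on
    correlated features is slow; with the active set and signs fixed, the
    penalised objective is smooth and a few damped Newton steps reach the
    bound conditions to near machine precision. A coordinate whose step
    crosses zero is truncated there and dropped from the set; steps backtrack
    if they fail to decrease the objective.
    """
    active = list(active)
    obj = _penalised_objective(Xb, fmean, lambdas, beta)
    for _ in range(max_iter):
        if not active:
            break
        A = np.asarray(active)
        XA = Xb[:, A]
        eta = Xb @ beta
        w = np.exp(eta - eta.max())
        p = w / w.sum()
        ea = p @ XA
        grad = ea - fmean[A] + np.sign(beta[A]) * lambdas[A]
        if np.abs(grad).max() < grad_tol:
            break
        cov = XA.T @ (XA * p[:, None]) - np.outer(ea, ea)
        cov.flat[:: len(A) + 1] += 1e-12  # ridge for degenerate directions
        try:
            step = np.linalg.solve(cov, -grad)
        except np.linalg.LinAlgError:
            break
        # truncate at the first sign change; that coordinate leaves the set
        t_max, crosser = 1.0, None
        for i, j in enumerate(A):
            if step[i] != 0.0 and np.sign(beta[j] + step[i]) == -np.sign(beta[j]):
                t = -beta[j] / step[i]
                if t < t_max:
                    t_max, crosser = t, j
        old = beta[A].copy()
        accepted = False
        t = t_max
        for _bt in range(12):
            beta[A] = old + t * step
            if crosser is not None and t == t_max:
                beta[crosser] = 0.0
            new_obj = _penalised_objective(Xb, fmean, lambdas, beta)
            if new_obj <= obj + 1e-13:
                obj = new_obj
                accepted = True
                break
            t *= 0.5
        if not accepted:
            beta[A] = old
            break
        if crosser is not None and beta[crosser] == 0.0:
            active.remove(crosser)


def fit(
    Xp: np.ndarray,
    Xb: np.ndarray,
    feature_set: FeatureSet | None = None,
    lambdas: np.ndarray | None = None,
    rm: float = 1.0,
    max_cycles: int = 150,
    tol: float = 1e-7,
    classes: str = "LQH",
    path_seed: int | None = None,
    kkt_tol: float = 1e-7,
    kkt_active_tol: float = 5e-4,
    beta_max: float = 40.0,
) -> MaxentModel:
    """Fit by cyclic coordinate descent with soft-thresholding.

    Each coordinate takes a soft-thresholded Newton step on the penalised
    objective, backtracking until the true objective does not increase, so
    the objective is non-increasing across cycles by construction.
    Convergence is declared on the optimality conditions themselves:
    every inactive feature satisfies |E_pres[f] - E_model[f]| <= lambda + kkt_tol
    and every active feature matches its bound to 1e-4. ``path_seed``
    shuffles the coordinate order each cycle (seeded, hence reproducible),
    which removes the path-attribution bias toward whichever correlated
    feature happens to come first. ``beta_max`` is a separation guard: a
    presence-supported corner of feature space with zero background mass has
    no finite optimum, so the fit stops (flagged unconverged) once a
    coefficient passes it.
    """
    Xp = np.asarray(Xp, dtype=float)
    Xb = np.asarray(Xb, dtype=float)
    if not (np.all(np.isfinite(Xp)) and np.all(np.isfinite(Xb))):
        raise DataError("non-finite feature values")
    if rm <= 0:
        raise DataError("regularization multiplier must be positive")
    n, J = Xp.shape
    N = Xb.shape[0]
    if lambdas is None:
        if feature_set is None:
            raise DataError("either lambdas or a feature_set is required")
        lambdas = default_lambdas(feature_set, Xp, rm)
    lambdas = np.asarray(lambdas, dtype=float)

    var_of = (
        feature_set.feature_variables()
        if feature_set is not None
        else np.array([f"f{j}" for j in range(J)])
    )
    fmean = Xp.mean(axis=0) if n else np.zeros(J)
    beta = np.zeros(J)
    eta_b = np.zeros(N)
    mean_eta_p = 0.0
    log_z = math.log(N)
    obj = -mean_eta_p + log_z  # no penalty at beta = 0
    converged = False
    cycles_done = 0
    path_rng = np.random.default_rng(path_seed) if path_seed is not None else None
    cols = np.ascontiguousarray(Xb.T)  # (J, N) for fast row access in the kernel
    improvements = np.zeros(J)
    state = [mean_eta_p, log_z, obj]

    def sweep(indices: np.ndarray, shuffle: bool) -> None:
        order = path_rng.permutation(indices) if (path_rng is not None and shuffle) else indices
        state[0], state[1], state[2] = _sweep_kernel(
            cols, fmean, lambdas, beta, eta_b,
            state[0], state[1], state[2],
            np.ascontiguousarray(order, dtype=np.int64), improvements,
        )

    def kkt_ok() -> bool:
        w = np.exp(eta_b - eta_b.max())
        p = w / w.sum()
        grad = p @ Xb - fmean  # d/dbeta of the smooth part
        active = beta != 0
        # one-sided: no feature's expectation gap may exceed its penalty
        overshoot = np.abs(grad) - lambdas
        if len(overshoot) and overshoot.max() > kkt_tol:
            return False
        # active features must also sit on the bound (equality band)
        active_resid = np.abs(grad[active] + np.sign(beta[active]) * lambdas[active])
        return len(active_resid) == 0 or active_resid.max() <= kkt_active_tol

    separated = False
    # coordinate order is shuffled only over the early cycles, where nearly
    # all of the objective decrease (and hence the gain attribution) happens;
    # late polishing cycles run in fixed order, which converges much faster
    shuffle_cycles = 40
    all_idx = np.arange(J)
    while cycles_done < max_cycles and J > 0:
        before = state[2]
        sweep(all_idx, cycles_done < shuffle_cycles)
        cycles_done += 1
        if np.abs(beta).max() > beta_max:
            separated = True
            break
        if kkt_ok():
            converged = True
            break
        if before - state[2] < tol:
            break  # stalled: objective flat but bounds not met
        while cycles_done < max_cycles:
            active = np.flatnonzero(beta)
            if len(active) == 0:
                break
            before_inner = state[2]
            sweep(active, cycles_done < shuffle_cycles)
            cycles_done += 1
            if before_inner - state[2] < tol or np.abs(beta).max() > beta_max:
                break
    if J == 0:
        converged = True
    # terminal phase: Newton-solve the active set to put every active feature
    # exactly on its penalty bound, sweeping afterwards to admit any inactive
    # feature whose bound is now violated
    if not converged and not separated:
        for _ in range(8):
            active = np.flatnonzero(beta)
            if len(active):
                snapshot = beta.copy()
                _newton_polish(Xb, fmean, lambdas, beta, active.tolist())
                if np.abs(beta).max() > beta_max:
                    # separation direction: the Newton step runs away; revert
                    beta[:] = snapshot
                    separated = True
            eta_b = Xb @ beta
            state[0] = float(fmean @ beta)
            state[1] = _log_sum_exp(eta_b)
            state[2] = -state[0] + state[1] + float(lambdas @ np.abs(beta))
            if separated:
                break
            if kkt_ok():
                converged = True
                break
            sweep(all_idx, False)
            cycles_done += 1
            if np.abs(beta).max() > beta_max:
                separated = True
                break
    mean_eta_p, log_z, obj = state
    trace: dict[str, float] = {}
    for j in np.flatnonzero(improvements):
        key = str(var_of[j])
        trace[key] = trace.get(key, 0.0) + float(improvements[j])
    if separated:
        warnings.warn(
            "complete separation: a feature direction has presence support but no "
            f"background mass (|beta| > {beta_max}); fit stopped at the guard"
        )
    gain = mean_eta_p - log_z + math.log(N)
    return MaxentModel(
        feature_set=feature_set if feature_set is not None else FeatureSet([]),
        beta=beta,
        lambdas=lambdas,
        rm=rm,
        log_z=log_z,
        n_background=N,
        n_presence=n,
        gain=gain,
        classes=classes,
        converged=converged,
        n_cycles=cycles_done,
        objective=obj,
        trace=trace,
        bg_eta_sorted=np.sort(eta_b),
    )


def training_gain(model: MaxentModel, Xp: np.ndarray) -> float:
    """Mean log improvement of the model density over the uniform background."""
    Xp = np.asarray(Xp, dtype=float)
    return float(model.linear_predictor(Xp).mean() - model.log_z + math.log(model.n_background))


def kkt_residuals(model: MaxentModel, Xp: np.ndarray, Xb: np.ndarray) -> pd.DataFrame:
    """Per-feature |E_presence[f] - E_model[f]| with its penalty bound."""
    eta_b = np.asarray(Xb, dtype=float) @ model.beta
    w = np.exp(eta_b - eta_b.max())
    p = w / w.sum()
    e_model = p @ Xb
    e_pres = np.asarray(Xp, dtype=float).mean(axis=0)
    return pd.DataFrame(
        {
            "feature": [f.name for f in model.feature_set.features]
            if len(model.feature_set)
            else [f"f{j}" for j in range(len(model.beta))],
            "residual": np.abs(e_pres - e_model),
            "lambda": model.lambdas,
            "active": model.beta != 0,
        }
    )


def variable_contribution(model: MaxentModel) -> dict[str, float]:
    """Path attribution of training gain to input variables.

    Each variable's share is its summed positive objective decrease along the
    coordinate-descent path, normalised and scaled to the total gain; shares
    are non-negative and sum to the gain (all zero when the gain is zero).
    """
    if model.gain <= 0 or not model.trace:
        return {v: 0.0 for v in model.feature_set.variables}
    total = sum(max(v, 0.0) for v in model.trace.values())
    out = {v: 0.0 for v in model.feature_set.variables}
    if total <= 0:
        return out
    for var, imp in model.trace.items():
        out[var] = max(imp, 0.0) / total * model.gain
    return out


def permutation_importance(
    model: MaxentModel,
    presences: pd.DataFrame,
    backgrounds: pd.DataFrame,
    seed: int = 0,
    n_rep: int = 3,
) -> dict[str, float]:
    """Gain drop when one variable is permuted jointly across all points.

    An independent estimator of variable importance that does not rely on the
    fit path: the variable's values are shuffled over the pooled presence and
    background rows, features are re-expanded, and the decrease in training
    gain (with the background renormalised) is averaged over replicates.
    """
    rng = np.random.default_rng(seed)
    cat = [f.variable for f in model.feature_set.features if f.cls == "categorical"]
    pr = presences.assign(**{v: presences[v].astype(str) for v in cat}) if cat else presences
    bg = backgrounds.assign(**{v: backgrounds[v].astype(str) for v in cat}) if cat else backgrounds
    base = training_gain(model, model.feature_set.transform(pr))
    out: dict[str, float] = {}
    n_p = len(pr)
    for var in model.feature_set.variables:
        drops = []
        pooled = np.concatenate([pr[var].to_numpy(), bg[var].to_numpy()])
        for _ in range(n_rep):
            perm = rng.permutation(pooled)
            pr2 = pr.assign(**{var: perm[:n_p]})
            bg2 = bg.assign(**{var: perm[n_p:]})
            Xp2 = model.feature_set.transform(pr2)
            Xb2 = model.feature_set.transform(bg2)
            eta_b = Xb2 @ model.beta
            log_z = _log_sum_exp(eta_b)
            gain2 = float((Xp2 @ model.beta).mean() - log_z + math.log(len(bg2)))
            drops.append(base - gain2)
        out[var] = max(0.0, float(np.mean(drops)))
    return out


def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with tie correction."""
    sp = np.asarray(presence_scores, dtype=float)
    sb = np.asarray(background_scores, dtype=float)
    if len(sp) == 0 or len(sb) == 0:
        raise DataError("AUC needs at least one presence and one background score")
    ranks = rankdata(np.concatenate([sp, sb]))
    r_p = ranks[: len(sp)].sum()
    return float((r_p - len(sp) * (len(sp) + 1) / 2.0) / (len(sp) * len(sb)))


def aicc(model: MaxentModel, Xp: np.ndarray) -> float:
    """Small-sample AIC from standardised raw outputs at presences.

    ``k`` is the number of non-zero coefficients; returns NaN (model
    disqualified) when n <= k + 1.
    """
    n = np.asarray(Xp).shape[0]
    k = model.n_nonzero
    if n <= k + 1:
        return float("nan")
    ll = float(np.log(model.predict_raw(np.asarray(Xp, dtype=float))).sum())
    return 2.0 * k - 2.0 * ll + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class TuneResult:
    model: MaxentModel
    classes: str
    rm: float
    aicc: float
    report: pd.DataFrame  # one row per candidate: classes, rm, aicc, k, gain
    auc_train: float
    auc_test_folds: list[float]

    @property
    def auc_test_mean(self) -> float:
        return float(np.mean(self.auc_test_folds)) if self.auc_test_folds else float("nan")


def cross_validated_auc(
    presences: pd.DataFrame,
    backgrounds: pd.DataFrame,
    quantitative: list[str],
    categorical: list[str],
    classes: str,
    rm: float,
    n_folds: int = 6,
    seed: int = 0,
    n_hinge_knots: int = 50,
    tol: float = 1e-7,
) -> list[float]:
    """Test AUC per fold: random presence partition, full background reused."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Xp, Xb, fs = expand_features(
            presences, backgrounds, quantitative, categorical, classes, n_hinge_knots
        )
    n = Xp.shape[0]
    n_folds = min(n_folds, n)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    aucs = []
    for i, held in enumerate(folds):
        train = np.setdiff1d(order, held)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit(Xp[train], Xb, feature_set=fs, rm=rm, classes=classes, tol=tol, path_seed=seed + i)
        aucs.append(auc(m.linear_predictor(Xp[held]), m.linear_predictor(Xb)))
    return aucs


def tune(
    presences: pd.DataFrame,
    backgrounds: pd.DataFrame,
    quantitative: list[str],
    categorical: list[str] = (),
    feature_grid: tuple[str, ...] = ("L", "LQ", "H", "LQH"),
    rms: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0),
    n_hinge_knots: int = 50,
    n_folds: int = 6,
    seed: int = 0,
    tol: float = 1e-7,
) -> TuneResult:
    """AICc model selection over feature classes and regularization values.

    The lowest-AICc candidate wins; exact ties go to the larger multiplier
    (more parsimonious). The winner is refitted on all presences and its
    discrimination is reported as the 6-fold cross-validated test AUC.
    """
    rows = []
    fits: dict[tuple[str, float], tuple[MaxentModel, np.ndarray, np.ndarray]] = {}
    for classes in feature_grid:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Xp, Xb, fs = expand_features(
                presences, backgrounds, quantitative, categorical, classes, n_hinge_knots
            )
        for rm in rms:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = fit(Xp, Xb, feature_set=fs, rm=rm, classes=classes, tol=tol, path_seed=seed)
            score = aicc(m, Xp)
            fits[(classes, rm)] = (m, Xp, Xb)
            rows.append(
                {"classes": classes, "rm": rm, "aicc": score, "k": m.n_nonzero, "gain": m.gain}
            )
    report = pd.DataFrame(rows)
    valid = report[np.isfinite(report["aicc"])]
    if len(valid) == 0:
        raise PipelineError("all tuning candidates disqualified (AICc undefined)")
    best_aicc = valid["aicc"].min()
    ties = valid[valid["aicc"] == best_aicc].sort_values("rm", ascending=False)
    winner = ties.iloc[0]
    model, Xp, Xb = fits[(winner["classes"], float(winner["rm"]))]
    auc_train = auc(model.linear_predictor(Xp), model.linear_predictor(Xb))
    folds = cross_validated_auc(
        presences,
        backgrounds,
        quantitative,
        categorical,
        winner["classes"],
        float(winner["rm"]),
        n_folds=n_folds,
        seed=seed,
        n_hinge_knots=n_hinge_knots,
        tol=tol,
    )
    return TuneResult(
        model=model,
        classes=str(winner["classes"]),
        rm=float(winner["rm"]),
        aicc=float(best_aicc),
        report=report,
        auc_train=auc_train,
        auc_test_folds=folds,
    )
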