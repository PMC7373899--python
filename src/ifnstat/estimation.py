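"""Maximum-likelihood calibration: weighted least squares with a weak L2
prior, deterministic multi-start trust-region optimization (waterfall),
profile-likelihood identifiability, prediction profiles and BIC selection.

Parameters are handled on log10 scale throughout: optimization is unbounded
("no fixed borders"); the weak L2 prior, contributing 1 to the objective at
five decades from 1, supplies soft containment.  The prior is subtracted
before identifiability analysis so profiles are purely data-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .params import ParameterSet
from .simulate import Condition, compute_observables, simulate

PRIOR_SCALE = 5.0  # decades at which the L2 prior contributes 1
PLATEAU_TOL = 0.1  # -2logL tolerance for waterfall plateau grouping


def l2_prior(log10_params) -> float:
    """Weak L2 prior: contributes 1 per parameter five decades from 1."""
    x = np.asarray(log10_params, float)
    return float(np.sum((x / PRIOR_SCALE) ** 2))


def chi2_delta(level: float, df: int = 1) -> float:
    """Objective increase threshold for a confidence level."""
    return float(stats.chi2.ppf(level, df))


class LeastSquaresObjective:
    """-2 log L as a sum of squared residuals, with optional L2 prior.

    ``residual_fn(x) -> array`` holds the data part; the prior adds
    residuals x_i / 5.  ``jac`` (optional) is the analytic Jacobian of the
    data residuals and enables an analytic gradient.
    """

    def __init__(self, residual_fn, n_params: int, prior: bool = True,
                 jac=None, names=None):
        self._fn = residual_fn
        self.n_params = int(n_params)
        self.prior = prior
        self._jac = jac
        self.names = tuple(names) if names else tuple(
            f"p{i}" for i in range(n_params))

    def data_residuals(self, x):
        r = np.asarray(self._fn(np.asarray(x, float)), float)
        return np.where(np.isfinite(r), r, 1e8)

    def residuals(self, x):
        r = self.data_residuals(x)
        if self.prior:
            r = np.concatenate([r, np.asarray(x, float) / PRIOR_SCALE])
        return r

    def value(self, x) -> float:
        return float(np.sum(self.residuals(x) ** 2))

    def data_value(self, x) -> float:
        """Objective with the prior subtracted (identifiability analysis)."""
        return float(np.sum(self.data_residuals(x) ** 2))

    def jacobian(self, x):
        if self._jac is None:
            return None
        J = np.asarray(self._jac(np.asarray(x, float)), float)
        if self.prior:
            J = np.vstack([J, np.eye(self.n_params) / PRIOR_SCALE])
        return J

    def gradient(self, x):
        """Analytic gradient 2 J^T r, if a Jacobian was supplied."""
        J = self.jacobian(x)
        if J is None:
            return None
        return 2.0 * J.T @ self.residuals(x)

    def fixing(self, indices, values) -> "LeastSquaresObjective":
        """Reduced objective with coordinates pinned (for profiles)."""
        indices = np.atleast_1d(indices)
        values = np.atleast_1d(values).astype(float)
        free = np.array([i for i in range(self.n_params)
                         if i not in set(indices.tolist())], dtype=int)

        def embed(z):
            x = np.empty(self.n_params)
            x[free] = z
            x[indices] = values
            return x

        def fn(z):
            return self._fn(embed(z))

        sub = LeastSquaresObjective(fn, free.size, prior=False,
                                    names=[self.names[i] for i in free])
        # keep the prior over *all* coordinates, including pinned ones
        if self.prior:
            def resid_with_prior(z):
                r = sub.data_residuals(z)
                return np.concatenate([r, embed(z) / PRIOR_SCALE])
            sub.residuals = resid_with_prior  # type: ignore[method-assign]
            sub.value = lambda z: float(np.sum(resid_with_prior(z) ** 2))
        sub._embed = embed  # type: ignore[attr-defined]
        return sub


def ode_objective(dataset, network, base_params: ParameterSet, free_names,
                  conditions: dict, prior: bool = True, tol: str = "fit",
                  mode: str = "absolute") -> LeastSquaresObjective:
    """Objective for the ODE model against a scaled dataset.

    ``dataset`` rows: target (observable name), condition_id, time,
    estimate, sigma.  ``free_names`` are the optimized parameters (log10
    values in ``mode='absolute'``; log10 *shifts* from the base set in
    ``mode='shift'``, as used for cell-type ratio parameters).
    """
    free_names = list(free_names)
    conds = {cid: sub for cid, sub in dataset.groupby("condition_id")}
    unknown = set(conds) - set(conditions)
    if unknown:
        raise KeyError(f"no Condition supplied for {sorted(unknown)}")
    plan = []
    for cid, sub in conds.items():
        times = np.unique(np.r_[0.0, sub["time"].to_numpy(float)])
        idx = np.searchsorted(times, sub["time"].to_numpy(float))
        plan.append((conditions[cid], times, idx,
                     sub["target"].to_numpy(),
                     sub["estimate"].to_numpy(float),
                     sub["sigma"].to_numpy(float)))

    def residual_fn(x):
        if mode == "absolute":
            p = base_params.updated(dict(zip(free_names, x)),
                                    log10_scale=True)
        else:
            p = base_params.shifted(dict(zip(free_names, x)))
        out = []
        for cond, times, idx, targets, est, sig in plan:
            try:
                traj = simulate(network, p, cond, times, tol=tol)
                obs = compute_observables(traj, p, set(targets))
            except Exception as exc:  # solver failure -> +inf, flagged
                warnings.warn(f"simulation failed during fit: {exc}",
                              RuntimeWarning, stacklevel=2)
                out.append(np.full(len(targets), 1e8))
                continue
            sim = np.array([obs[t][i] for t, i in zip(targets, idx)])
            out.append((est - sim) / sig)
        return np.concatenate(out)

    return LeastSquaresObjective(residual_fn, len(free_names), prior=prior,
                                 names=free_names)


# ----------------------------------------------------------------- multistart

@dataclass
class FitResult:
    x: np.ndarray
    value: float
    success: bool
    start_index: int
    n_free: int
    names: tuple = ()


def _optimize(objective: LeastSquaresObjective, x0, max_nfev=None):
    jac = "2-point" if objective._jac is None else objective.jacobian
    res = least_squares(objective.residuals, np.asarray(x0, float),
                        jac=jac, method="trf", diff_step=1e-4,
                        max_nfev=max_nfev)
    return res.x, float(np.sum(res.fun ** 2)), bool(res.success)


def multistart(objective: LeastSquaresObjective, n_starts: int,
               start_box=(-5.0, 5.0), seed: int = 0,
               max_nfev=None) -> list:
    """Deterministic multi-start optimization; results sorted (waterfall).

    Starts are uniform in log10 over ``start_box`` per free parameter.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = start_box
    lo = np.broadcast_to(np.asarray(lo, float), (objective.n_params,))
    hi = np.broadcast_to(np.asarray(hi, float), (objective.n_params,))
    starts = rng.uniform(lo, hi, size=(n_starts, objective.n_params))
    results = []
    for i, x0 in enumerate(starts):
        try:
            x, val, ok = _optimize(objective, x0, max_nfev=max_nfev)
        except Exception as exc:
            warnings.warn(f"start {i} failed: {exc}", RuntimeWarning,
                          stacklevel=2)
            continue
        results.append(FitResult(x=x, value=val, success=ok, start_index=i,
                                 n_free=objective.n_params,
                                 names=objective.names))
    if not results:
        raise RuntimeError("all optimization starts failed")
    results.sort(key=lambda r: r.value)
    return results


def waterfall_groups(results, tol: float = PLATEAU_TOL):
    """Group sorted fit results into objective-value plateaus."""
    groups, current = [], [results[0]]
    for r in results[1:]:
        if r.value - current[-1].value <= tol:
            current.append(r)
        else:
            groups.append(current)
            current = [r]
    groups.append(current)
    return groups


# -------------------------------------------------------------------- profile

@dataclass
class ProfileCurve:
    name: str
    values: np.ndarray      # profiled parameter grid (log10)
    objective: np.ndarray   # re-optimized objective at each grid value
    ci: tuple               # (lower, upper), np.nan if open
    classification: str     # identifiable | open_left | open_right | open_both
    optimum_value: float = 0.0
    failed_points: list = field(default_factory=list)


def _profile_direction(objective, best_x, best_val, index, delta, direction,
                       step0, max_steps, box_decades):
    xs, fs = [], []
    step = step0
    x_nuis = np.delete(best_x, index)
    theta = best_x[index]
    prev_f = best_val
    failed = []
    for _ in range(max_steps):
        theta = theta + direction * step
        sub = objective.fixing([index], [theta])
        try:
            if sub.n_params == 0:
                f = sub.value(np.empty(0))
            else:
                x_nuis, f, _ = _optimize(sub, x_nuis)
        except Exception:
            failed.append(theta)
            continue
        xs.append(theta)
        fs.append(f)
        rise = f - prev_f
        prev_f = f
        target = delta / 5.0
        if rise > 1e-12:
            step = float(np.clip(step * target / rise, step0 / 10, 1.0))
        else:
            step = min(step * 2.0, 1.0)
        if f - best_val > delta * 1.2:
            # refine the threshold crossing by bisection
            lo_t = xs[-2] if len(xs) >= 2 else best_x[index]
            lo_f = fs[-2] if len(fs) >= 2 else best_val
            hi_t, hi_f = theta, f
            for _ in range(12):
                if abs(hi_t - lo_t) < max(step0 / 5, 1e-4):
                    break
                mid = 0.5 * (lo_t + hi_t)
                sub = objective.fixing([index], [mid])
                if sub.n_params == 0:
                    fm = sub.value(np.empty(0))
                else:
                    x_nuis, fm = _optimize(sub, x_nuis)[:2]
                xs.append(mid)
                fs.append(fm)
                if fm - best_val > delta:
                    hi_t, hi_f = mid, fm
                else:
                    lo_t, lo_f = mid, fm
            break
        if abs(theta - best_x[index]) > box_decades:
            break
    order = np.argsort(direction * np.asarray(xs))
    return np.asarray(xs)[order], np.asarray(fs)[order], failed


def _crossing(thetas, objs, best_theta, best_val, delta):
    """Interpolated parameter value where the profile crosses opt+delta."""
    thr = best_val + delta
    for i, f in enumerate(objs):
        if f >= thr:
            th_prev = thetas[i - 1] if i > 0 else best_theta
            f_prev = objs[i - 1] if i > 0 else best_val
            if f == f_prev:
                return thetas[i]
            w = (thr - f_prev) / (f - f_prev)
            return th_prev + w * (thetas[i] - th_prev)
    return None  # never crossed: open


def profile(objective: LeastSquaresObjective, best_fit: FitResult,
            index: int, delta: float | None = None, level: float = 0.95,
            step0: float = 0.05, max_steps: int = 80,
            box_decades: float = 5.0) -> ProfileCurve:
    """Profile likelihood of one parameter around the accepted optimum."""
    if delta is None:
        delta = chi2_delta(level)
    best_x = np.asarray(best_fit.x, float)
    best_val = objective.value(best_x)
    up_t, up_f, fail_u = _profile_direction(
        objective, best_x, best_val, index, delta, +1.0, step0, max_steps,
        box_decades)
    lo_t, lo_f, fail_l = _profile_direction(
        objective, best_x, best_val, index, delta, -1.0, step0, max_steps,
        box_decades)
    values = np.r_[lo_t[::-1], best_x[index], up_t]
    objs = np.r_[lo_f[::-1], best_val, up_f]
    hi = _crossing(up_t, up_f, best_x[index], best_val, delta)
    lo = _crossing(lo_t, lo_f, best_x[index], best_val, delta)
    cls = {(True, True): "identifiable", (False, True): "open_left",
           (True, False): "open_right", (False, False): "open_both"}[
        (lo is not None, hi is not None)]
    return ProfileCurve(name=objective.names[index], values=values,
                        objective=objs,
                        ci=(np.nan if lo is None else lo,
                            np.nan if hi is None else hi),
                        classification=cls, optimum_value=best_val,
                        failed_points=fail_l + fail_u)


def prediction_profile(objective: LeastSquaresObjective,
                       best_fit: FitResult, predictor,
                       delta: float | None = None, level: float = 0.68,
                       n_steps: int = 40, weight: float = 1e6):
    """Confidence interval for a scalar prediction via constrained profiles.

    The prediction is pinned by a stiff quadratic penalty and the objective
    re-optimized; the interval collects prediction values whose profiled
    objective stays within ``delta`` (default: chi2 quantile for the level)
    of the optimum.
    """
    if delta is None:
        delta = chi2_delta(level)
    best_x = np.asarray(best_fit.x, float)
    c0 = float(predictor(best_x))
    if not np.isfinite(c0):
        raise ValueError("predictor is non-finite at the best fit")
    best_val = objective.value(best_x)
    scale = max(abs(c0), 1e-8)

    def profiled(c, x_start):
        w = np.sqrt(weight * delta) / scale

        def resid(x):
            return np.concatenate([objective.residuals(x),
                                   [w * (predictor(x) - c)]])
        res = least_squares(resid, x_start, method="trf")
        pen = (w * (predictor(res.x) - c)) ** 2
        return float(np.sum(res.fun ** 2) - pen), res.x

    bounds = []
    for direction in (+1.0, -1.0):
        c, x_start = c0, best_x.copy()
        step = 0.05 * scale
        bound = c0
        for _ in range(n_steps):
            c = c + direction * step
            f, x_start = profiled(c, x_start)
            if f - best_val > delta:
                break
            bound = c
            rise = max(f - best_val, 1e-12)
            step = float(np.clip(step * (delta / 5.0) / rise,
                                 0.01 * scale, 0.5 * scale))
        bounds.append(bound)
    hi, lo = bounds
    return (min(lo, c0), max(hi, c0))


# ------------------------------------------------------------ model selection

def bic(value: float, k: int, n: int) -> float:
    """Bayesian information criterion with -2 log L = ``value``."""
    return k * np.log(n) + value


def compare_models(fits: dict, n_data: int):
    """Rank model variants by BIC (ascending); winner first.

    ``fits`` maps variant name -> FitResult (objective values must refer to
    the same dataset of ``n_data`` points).
    """
    if not fits:
        raise ValueError("no fits supplied")
    rows = [(name, r.value, r.n_free, bic(r.value, r.n_free, n_data))
            for name, r in fits.items()]
    rows.sort(key=lambda t: t[3])
    import pandas as pd
    df = pd.DataFrame(rows, columns=["variant", "objective", "k", "bic"])
    df["delta_bic"] = df["bic"] - df["bic"].iloc[0]
    return df
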