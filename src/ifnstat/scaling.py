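"""Combined scaling-and-error model for replicate quantitative measurements.

Immunoblot signals are assumed log-normal: for record i on gel g(i) measuring
the latent quantity x(c,t) of its (condition, time) cell,

    log y_i = log s_g(i) + log x_c(i),t(i) + eps_i,   eps ~ N(0, sigma^2).

Gel scaling factors and latent time-course values are estimated jointly by
generalized least squares in log space with the reference gel fixed to 1;
1-sigma confidence intervals come from the inverse curvature at the optimum
with sigma^2 estimated from the residual degrees of freedom (constant
variance in log space per target).

Also provided: molecules-per-cell estimation from spike-in calibrator curves
(linear-region regression and interpolation) and qRT-PCR normalization to
the geometric mean of the GAPDH/HPRT/TBP reference genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

REFERENCE_GENES = ("GAPDH", "HPRT", "TBP")


class DisconnectedGelsError(ValueError):
    def __init__(self, target, components):
        self.components = components
        super().__init__(
            f"scaling graph for target {target!r} is disconnected; "
            f"gel components: {components}")


@dataclass
class ScaledDataset:
    """Scaled estimates with 1-sigma CIs plus per-gel scaling factors."""

    estimates: pd.DataFrame  # target, condition_id, time, estimate, sigma,
    #                          n_replicates, reliable
    gel_factors: dict = field(default_factory=dict)
    sigma_log: dict = field(default_factory=dict)  # per-target noise SD


def _align_one(sub: pd.DataFrame, target: str, reference_gel: str | None):
    gels = list(dict.fromkeys(sub["gel"]))
    ref = reference_gel if reference_gel in gels else gels[0]
    cells = list(dict.fromkeys(zip(sub["condition_id"], sub["time"])))
    gi = {g: i for i, g in enumerate(gels)}
    ci = {c: i for i, c in enumerate(cells)}
    # connectivity of the gel graph through shared (condition, time) cells
    n = len(gels) + len(cells)
    adj = np.zeros((n, n), bool)
    for _, r in sub.iterrows():
        a, b = gi[r.gel], len(gels) + ci[(r.condition_id, r.time)]
        adj[a, b] = adj[b, a] = True
    ncomp, labels = connected_components(adj, directed=False)
    if ncomp > 1:
        comps = [[g for g in gels if labels[gi[g]] == k]
                 for k in range(ncomp)]
        raise DisconnectedGelsError(target, [c for c in comps if c])

    free_gels = [g for g in gels if g != ref]
    fgi = {g: i for i, g in enumerate(free_gels)}
    m, p = len(sub), len(free_gels) + len(cells)
    A = np.zeros((m, p))
    b = np.log(sub["signal"].to_numpy(float))
    for row, (_, r) in enumerate(sub.iterrows()):
        if r.gel != ref:
            A[row, fgi[r.gel]] = 1.0
        A[row, len(free_gels) + ci[(r.condition_id, r.time)]] = 1.0
    theta, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = b - A @ theta
    dof = max(m - p, 1)
    sigma2 = float(resid @ resid) / dof
    cov = np.linalg.pinv(A.T @ A) * sigma2
    counts = sub.groupby(["condition_id", "time"]).size()
    rows = []
    for (cond, time), k in zip(cells, range(len(cells))):
        j = len(free_gels) + ci[(cond, time)]
        log_x = theta[j]
        sd_log = float(np.sqrt(max(cov[j, j], 0.0)))
        nrep = int(counts.loc[(cond, time)])
        rows.append((target, cond, time, float(np.exp(log_x)),
                     float(np.exp(log_x)) * sd_log, nrep, nrep >= 2))
    est = pd.DataFrame(rows, columns=["target", "condition_id", "time",
                                      "estimate", "sigma", "n_replicates",
                                      "reliable"])
    factors = {ref: 1.0}
    factors.update({g: float(np.exp(theta[fgi[g]])) for g in free_gels})
    return est, factors, float(np.sqrt(sigma2))


def align_replicates(measurements: pd.DataFrame,
                     reference_gel: str | None = None) -> ScaledDataset:
    """Merge replicate measurements across gels into scaled estimates.

    ``measurements`` needs columns target, gel, condition_id, time, signal
    (signals strictly positive).  Each target is scaled independently; the
    reference gel's factor is fixed to 1 (default: first gel per target).
    """
    required = {"target", "gel", "condition_id", "time", "signal"}
    missing = required - set(measurements.columns)
    if missing:
        raise KeyError(f"missing columns: {sorted(missing)}")
    if (measurements["signal"] <= 0).any():
        raise ValueError("signals must be positive (log-normal model)")
    frames, factors, sigmas = [], {}, {}
    for target, sub in measurements.groupby("target", sort=False):
        est, fac, sd = _align_one(sub.reset_index(drop=True), target,
                                  reference_gel)
        frames.append(est)
        factors.update(fac)
        sigmas[target] = sd
    return ScaledDataset(estimates=pd.concat(frames, ignore_index=True),
                         gel_factors=factors, sigma_log=sigmas)


def borrow_sigma(dataset: ScaledDataset, donor_target: str) -> ScaledDataset:
    """Assign the donor target's log-noise SD to single-replicate targets.

    Used for single-replicate measurements (e.g. per-patient hepatocyte
    time courses), borrowing the signal variance of a densely replicated
    reference time course that is assumed constant after stimulation.
    """
    sd = dataset.sigma_log[donor_target]
    est = dataset.estimates.copy()
    mask = ~est["reliable"]
    est.loc[mask, "sigma"] = est.loc[mask, "estimate"] * sd
    est.loc[mask, "reliable"] = True
    return ScaledDataset(est, dict(dataset.gel_factors),
                         dict(dataset.sigma_log))


# --------------------------------------------------- molecules per cell

class ExtrapolationError(ValueError):
    pass


def estimate_molecules_per_cell(curve: dict) -> tuple[float, float]:
    """Interpolate a spike-in calibration curve to molecules per cell.

    ``curve`` carries strictly increasing calibrator ``amounts`` (molecule
    equivalents), their ``signals``, the ``endogenous_signal``, the number
    of ``cells_per_lysate`` and the ``lysate_fraction`` loaded.  The linear
    region is the contiguous spike subset (length >= 3) maximizing the R^2
    of a linear fit; the endogenous signal is interpolated within it.
    Returns (molecules_per_cell, SEM) with the SEM propagated from the
    residual scatter of the fit assuming log-normal signals.
    """
    amounts = np.asarray(curve["amounts"], float)
    signals = np.asarray(curve["signals"], float)
    if amounts.size < 3:
        raise ValueError("need at least 3 spike levels")
    if np.any(np.diff(amounts) <= 0):
        raise ValueError("amounts must be strictly increasing")
    best = None
    for i in range(amounts.size - 2):
        for j in range(i + 3, amounts.size + 1):
            x, y = amounts[i:j], signals[i:j]
            slope, icpt = np.polyfit(x, y, 1)
            pred = slope * x + icpt
            ss_res = np.sum((y - pred) ** 2)
            ss_tot = np.sum((y - y.mean()) ** 2)
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
            if best is None or r2 > best[0]:
                best = (r2, i, j, slope, icpt)
    _, i, j, slope, icpt = best
    lo, hi = signals[i:j].min(), signals[i:j].max()
    endo = float(curve["endogenous_signal"])
    if not lo <= endo <= hi:
        raise ExtrapolationError(
            f"endogenous signal {endo:.4g} outside fitted linear region "
            f"[{lo:.4g}, {hi:.4g}]; extrapolation refused")
    amount = (endo - icpt) / slope
    per_cell = amount / curve["lysate_fraction"] / curve["cells_per_lysate"]
    y = signals[i:j]
    pred = slope * amounts[i:j] + icpt
    resid_log = np.log(y) - np.log(np.maximum(pred, 1e-300))
    sem_log = float(np.std(resid_log, ddof=2) / np.sqrt(j - i)) if j - i > 2 \
        else 0.0
    return float(per_cell), float(per_cell * sem_log)


# ----------------------------------------------------------- qPCR

class MissingReferenceError(ValueError):
    pass


def normalize_qpcr(records: pd.DataFrame,
                   reference_genes=REFERENCE_GENES,
                   baseline_condition=None) -> pd.DataFrame:
    """Reference-gene-normalized fold changes from Cq records.

    expression = E^(-Cq); normalized = expression / geometric mean of the
    reference-gene expressions of the same sample; fold change = normalized /
    normalized at the baseline sample.  ``baseline_condition`` is a
    (condition_id, time) pair; default: time 0 of the first condition.
    Samples missing any reference gene are rejected.
    """
    req = {"gene", "condition_id", "time", "Cq", "efficiency"}
    if req - set(records.columns):
        raise KeyError(f"missing columns: {sorted(req - set(records.columns))}")
    if ((records["Cq"] <= 0) | (records["Cq"] > 50)).any():
        raise ValueError("Cq values must lie in (0, 50]")
    if ((records["efficiency"] <= 1) | (records["efficiency"] > 2)).any():
        raise ValueError("amplification efficiency must lie in (1, 2]")
    recs = records.copy()
    recs["expression"] = recs["efficiency"] ** (-recs["Cq"])
    rows = []
    for (cond, time), sub in recs.groupby(["condition_id", "time"],
                                          sort=False):
        refs = sub[sub["gene"].isin(reference_genes)]
        if set(refs["gene"]) != set(reference_genes):
            raise MissingReferenceError(
                f"sample ({cond}, {time}) lacks reference genes "
                f"{sorted(set(reference_genes) - set(refs['gene']))}")
        geo = float(np.exp(np.mean(np.log(refs["expression"]))))
        for _, r in sub[~sub["gene"].isin(reference_genes)].iterrows():
            rows.append((r.gene, cond, time, r.expression / geo))
    norm = pd.DataFrame(rows, columns=["gene", "condition_id", "time",
                                       "normalized"])
    if baseline_condition is None:
        first = norm.iloc[0]
        t0 = norm[norm["condition_id"] == first.condition_id]["time"].min()
        baseline_condition = (first.condition_id, t0)
    cond0, t0 = baseline_condition
    base = norm[(norm["condition_id"] == cond0) & (norm["time"] == t0)]
    base_map = base.set_index("gene")["normalized"]
    norm["fold_change"] = [
        r.normalized / base_map[r.gene] for _, r in norm.iterrows()]
    return norm
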