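"""End-to-end synthetic benchmark scenarios.

Two workflows exercised by the test suite and reusable in analyses:

* receptor-structure recovery: data generated under the dual
  (SOCS1 | SOCS1xUSP18) receptor-degradation structure are fit under all
  four structural variants and ranked by BIC;
* cell-type transfer recovery: data generated under a shifted parameter set
  (HepG2-like: 2 true ratio parameters; hepatocyte-like: 5) are fit with the
  elastic-net path over a candidate ratio set and the support selected by
  the modified BIC.

Both use deliberately small designs (few conditions, coarse time grids,
restricted candidate sets, few starts) so that a full recovery run takes
seconds to a couple of minutes; larger designs are plain function arguments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .celltype import fit_path, select
from .estimation import compare_models, multistart, ode_objective
from .network import build_network
from .params import estimated_names
from .simulate import Condition, compute_observables, simulate
from .synthetic import nominal_parameters, nominal_values

#: free parameters per receptor variant for structure recovery
VARIANT_FREE = {
    "SOCS1": ("VdegSOCS1", "Kmdeg", "KiUSP18", "deactRec"),
    "USP18": ("VdegUSP18", "Kmdeg", "KiUSP18", "deactRec"),
    "SOCS1xUSP18": ("VdegCoop", "Kmdeg", "KiUSP18", "deactRec"),
    "SOCS1_or_SOCS1xUSP18": ("VdegSOCS1", "VdegCoop", "Kmdeg", "KiUSP18",
                             "deactRec"),
}

#: start-box centers (log10) for the receptor-module parameters
_START_CENTER = {"VdegSOCS1": 0.3, "VdegUSP18": 0.5, "VdegCoop": 1.0,
                 "Kmdeg": 4.0, "KiUSP18": 4.0, "deactRec": 0.5}

#: candidate ratio parameters for the scaled-down cell-type scenarios
RATIO_CANDIDATES = ("STAT1mRNA0", "actSTAT2", "Rec0", "STAT2mRNA0",
                    "synthSTAT2mRNA", "degSOCS1mRNA", "dissISGF3",
                    "actSTAT1", "degSTATmRNA", "KiUSP18")


def _noisy_dataset(truth, cells, seed, noise, network):
    rng = np.random.default_rng(seed)
    rows, conds = [], {}
    for cond, times, names in cells:
        conds[cond.condition_id] = cond
        grid = np.unique(np.r_[0.0, times])
        traj = simulate(network, truth, cond, grid, tol="fit")
        obs = compute_observables(traj, truth, names)
        idx = np.searchsorted(grid, times)
        for name in names:
            for i, t in zip(idx, times):
                val = obs[name][i] * np.exp(rng.normal(0.0, noise))
                rows.append((name, cond.condition_id, t, val,
                             noise * max(val, 1e-9)))
    data = pd.DataFrame(rows, columns=["target", "condition_id", "time",
                                       "estimate", "sigma"])
    return data, conds


def structure_recovery_dataset(seed: int = 0, noise: float = 0.1):
    """Noisy measurements generated under the dual-degradation truth.

    Conditions: a 24-h high-dose time course, a restimulation after
    high-dose prestimulation, and a USP18-knockdown time course (the
    knockdown is what separates the degradation structures).
    """
    truth = nominal_parameters(verify=False)
    network = build_network()
    tc_times = [0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0]
    cells = [
        (Condition(prestim_dose=1400.0, condition_id="tc1400"), tc_times,
         ("pSTAT1_Cyt", "pSTAT2_Cyt", "USP18_Cyt")),
        (Condition(prestim_dose=1400.0, stim_dose=1400.0,
                   condition_id="restim"),
         [24.5, 25.0, 26.0, 28.0], ("pSTAT1_Nuc", "pSTAT2_Nuc")),
        (Condition(prestim_dose=1400.0, knockdown_factor=0.05,
                   condition_id="kd"), tc_times,
         ("pSTAT1_Cyt", "pSTAT2_Cyt", "USP18_Cyt")),
    ]
    return _noisy_dataset(truth, cells, seed, noise, network)


def run_structure_recovery(seed: int = 0, n_starts: int = 3,
                           noise: float = 0.1):
    """Fit all four receptor variants to one synthetic dataset and rank
    them by BIC.  Returns (ranking DataFrame, fits dict)."""
    data, conds = structure_recovery_dataset(seed, noise)
    fits = {}
    for variant, free in VARIANT_FREE.items():
        network = build_network(variant)
        vals = nominal_values()
        vals.setdefault("VdegUSP18", 3.0)
        base_names = estimated_names(variant)
        from .params import ParameterSet
        base = ParameterSet.from_dict({n: vals[n] for n in base_names},
                                      variant=variant)
        obj = ode_objective(data, network, base, list(free), conds,
                            prior=True, tol="fit")
        center = np.array([_START_CENTER[n] for n in free])
        results = multistart(obj, n_starts=n_starts,
                             start_box=(center - 1.0, center + 1.0),
                             seed=seed)
        fits[variant] = results[0]
    return compare_models(fits, len(data)), fits


_CELLTYPE_OBS = ("pSTAT1_Cyt", "pSTAT2_Cyt", "pSTAT2_Nuc", "tSTAT2_Cyt",
                 "mRNA_STAT1", "mRNA_STAT2", "mRNA_SOCS1", "USP18_Cyt")


def celltype_dataset(truth_shifts: dict, seed: int = 0,
                     noise: float = 0.04):
    """Synthetic cell-type data: control model shifted by the true ratio
    parameters, observed under two conditions with replicate-averaged
    noise."""
    control = nominal_parameters(verify=False)
    truth = control.shifted(truth_shifts)
    network = build_network()
    cells = [
        (Condition(prestim_dose=1400.0, condition_id="tc1400"),
         [0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 24.0], _CELLTYPE_OBS),
        (Condition(prestim_dose=2.8, stim_dose=1400.0,
                   condition_id="restim2.8"),
         [4.0, 24.0, 24.5, 25.0, 26.0, 28.0],
         ("pSTAT1_Nuc", "pSTAT2_Nuc", "mRNA_STAT2", "mRNA_SOCS1")),
    ]
    data, conds = _noisy_dataset(truth, cells, seed, noise, network)
    return data, conds, network, control


def run_celltype_recovery(truth_shifts: dict, seed: int = 0,
                          n_lams: int = 9, n_starts: int = 1,
                          noise: float = 0.04):
    """Elastic-net path + modified-BIC selection on a cell-type scenario.

    The lambda grid is log-spaced over four decades centered where the
    penalty of an order-of-magnitude difference matches the chi-square
    scale of the data (n/2).
    """
    data, conds, network, control = celltype_dataset(truth_shifts, seed,
                                                     noise)
    obj = ode_objective(data, network, control, RATIO_CANDIDATES, conds,
                        prior=False, tol="fit", mode="shift")
    lam_c = len(data) / 2.0
    grid = np.geomspace(lam_c / 100.0, lam_c * 100.0, n_lams)
    path = fit_path(obj, grid, n_starts=n_starts, seed=seed)
    sel = select(path, obj, n_data=len(data))
    return sel, path
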