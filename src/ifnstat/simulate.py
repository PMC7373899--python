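"""Steady-state transform, compiled ODE right-hand sides and simulation.

Doses are clamped inputs: extracellular IFNα (pM) enters the rate equations
as a piecewise-constant input changed only by dosing/washout events, and the
integrator is stopped and restarted at every event.  Roferon (IFNα-2a) is
handled through an equipotency factor on the ligand-binding term (608 pM
Roferon ≡ 1,400 pM research-grade IFNα).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .network import DERIVED_PARAMS, ReactionNetwork, build_network
from .params import FIXED_CONSTANTS, GENES, ParameterSet

#: dose (pM) of each ligand producing equal receptor activation
EQUIPOTENCY = {"IFNa": 1.0, "Roferon": 1400.0 / 608.0}

#: solver settings: (rtol, atol)
TOLS = {"acceptance": (1e-8, 1e-10), "fit": (1e-6, 1e-8)}


class SteadyStateError(ValueError):
    pass


class SimulationError(RuntimeError):
    pass


@dataclass
class Condition:
    """One experimental condition (doses, perturbations, overrides)."""

    prestim_dose: float = 0.0
    stim_dose: float = 0.0
    stim_time: float = 24.0
    ligand: str = "IFNa"
    washout: tuple | None = None  # (t_remove, t_readd)
    knockdown_factor: float = 1.0
    overexpression: bool = False
    inhibitor_mode: bool = False
    ratio_vector: dict = field(default_factory=dict)   # log10 shifts
    abundance_overrides: dict = field(default_factory=dict)  # molecules/cell
    condition_id: str = ""

    def __post_init__(self):
        if self.prestim_dose < 0 or self.stim_dose < 0:
            raise ValueError("doses must be >= 0")
        if self.ligand not in EQUIPOTENCY:
            raise ValueError(f"unknown ligand {self.ligand!r}")
        if not 0.0 <= self.knockdown_factor <= 1.0:
            raise ValueError("knockdown_factor must lie in [0, 1]")
        if self.washout is not None:
            w = tuple(self.washout)
            if len(w) != 2 or not w[0] < w[1]:
                raise ValueError("washout times must be strictly increasing")
            self.washout = w


@dataclass
class Trajectory:
    t: np.ndarray
    x: np.ndarray  # species x time, natural scale
    network: ReactionNetwork
    condition: Condition
    min_state: float = 0.0

    def state(self, name: str) -> np.ndarray:
        return self.x[self.network.species_index[name]]


# ---------------------------------------------------------------- RHS codegen

_RHS_CACHE: dict = {}


def compiled_rhs(network: ReactionNetwork):
    """Generate and JIT-compile the mass-balance right-hand side."""
    key = (network.variant, tuple(sorted(network.chains.items())))
    if key in _RHS_CACHE:
        return _RHS_CACHE[key]
    sp_names = [s.name for s in network.species]
    rt_names = network.runtime_names()
    lines = ["def _rhs(t, y, rt, IFN, KD, OE):"]
    for i, name in enumerate(sp_names):
        lines.append(f"    {name} = y[{i}]")
    for j, name in enumerate(rt_names):
        lines.append(f"    {name} = rt[{j}]")
    terms = {name: [] for name in sp_names}
    for k, rxn in enumerate(network.reactions):
        lines.append(f"    r{k} = {rxn.rate}")
        for name, nu in rxn.reactants:
            terms[name].append(f"-{nu}.0*r{k}")
        for name, nu in rxn.products:
            terms[name].append(f"+{nu}.0*r{k}")
    lines.append(f"    dy = np.empty({len(sp_names)})")
    for i, name in enumerate(sp_names):
        expr = "".join(terms[name]) or "0.0"
        lines.append(f"    dy[{i}] = {expr.lstrip('+')}")
    lines.append("    return dy")
    ns = {"np": np}
    exec("\n".join(lines), ns)
    fn = njit(ns["_rhs"])
    _RHS_CACHE[key] = fn
    return fn


# ------------------------------------------------------- steady-state transform

def _effective_naturals(params: ParameterSet, condition: Condition | None
                        ) -> dict:
    nat = params.as_dict(natural=True)
    nat.update(FIXED_CONSTANTS)
    if condition is not None:
        for name, delta in condition.ratio_vector.items():
            nat[name] *= 10.0 ** delta
        ov = condition.abundance_overrides
        for prot, pname in (("STAT1", "totSTAT1"), ("STAT2", "totSTAT2"),
                            ("IRF9", "totIRF9")):
            if prot in ov:
                nat[pname] = float(ov[prot])
        if "USP18" in ov:
            # synthUSP18 is the abundance parameter for USP18
            nat["synthUSP18"] = (float(ov["USP18"]) * nat["degUSP18"]
                                 / nat["USP18mRNA0"])
        unknown = set(ov) - {"STAT1", "STAT2", "IRF9", "USP18"}
        if unknown:
            raise KeyError(f"unknown abundance overrides: {sorted(unknown)}")
        if condition.inhibitor_mode:
            nat["synthUSP18"] = nat["synthUSP18_inh"]
            nat["synthUSP18mRNA"] = nat["synthUSP18mRNA_inh"]
    return nat


def steady_state(params: ParameterSet, network: ReactionNetwork,
                 condition: Condition | None = None):
    """Resting state of the unstimulated system plus derived rates.

    Basal synthesis rates (receptor, all seven transcripts), the translation
    rates of SOCS1/SOCS3/IRF2 and the degradation rates of the STAT1/STAT2/
    IRF9 monomers are fixed so that the IFN=0 system is an exact fixed point
    at the specified basal abundances.  Returns ``(x0, rt, derived)``.
    """
    nat = _effective_naturals(params, condition)
    d = {}
    d["synthRec"] = nat["degRec"] * nat["Rec0"]
    mrna0 = {g: nat[f"{g}mRNA0"] for g in GENES}
    degm = {g: nat["degSTATmRNA"] if g in ("STAT1", "STAT2")
            else nat[f"deg{g}mRNA"] for g in GENES}
    for g in GENES:
        d[f"tcrb{g}"] = mrna0[g] * degm[g]
    if condition is not None and condition.inhibitor_mode:
        d["tcrbUSP18"] = nat["synthUSP18mRNAbasal_inh"]
        mrna0["USP18"] = d["tcrbUSP18"] / degm["USP18"]
    for g, pname in (("SOCS1", "synthSOCS1p"), ("SOCS3", "synthSOCS3p"),
                     ("IRF2", "synthIRF2p")):
        d[pname] = nat[f"{g}_0"] * nat[f"deg{g}"] / mrna0[g]
    # cytoplasm/nucleus split of the monomer pools
    x0 = np.zeros(network.n_species)
    idx = network.species_index
    mono = {}
    for g, tot_name, imp in (("STAT1", "totSTAT1", "impSTAT1"),
                             ("STAT2", "totSTAT2", "impSTAT2"),
                             ("IRF9", "totIRF9", "impIRF9")):
        ratio = nat[imp] / nat["expMono"]
        cyt = nat[tot_name] / (1.0 + ratio)
        mono[g] = (cyt, nat[tot_name] - cyt)
        d[f"deg{g}"] = nat[f"synth{g}"] * mrna0[g] / cyt
    bad = [k for k, v in d.items() if not np.isfinite(v) or v < 0]
    if bad:
        raise SteadyStateError(
            f"steady-state transform produced invalid rates: {bad}")
    x0[idx["Rec"]] = nat["Rec0"]
    x0[idx["STAT1c"]], x0[idx["STAT1n"]] = mono["STAT1"]
    x0[idx["STAT2c"]], x0[idx["STAT2n"]] = mono["STAT2"]
    x0[idx["IRF9c"]], x0[idx["IRF9n"]] = mono["IRF9"]
    tl_rate = {"STAT1": nat["synthSTAT1"], "STAT2": nat["synthSTAT2"],
               "IRF9": nat["synthIRF9"], "USP18": nat["synthUSP18"],
               "SOCS1": d["synthSOCS1p"], "SOCS3": d["synthSOCS3p"],
               "IRF2": d["synthIRF2p"]}
    for g in GENES:
        x0[idx[f"{g}mRNA"]] = mrna0[g]
        length = network.chains[g]
        flux = tl_rate[g] * mrna0[g]
        for i in range(1, length + 1):
            x0[idx[f"{g}chain{i}"]] = flux * nat[f"delay{g}"] / length
    x0[idx["USP18"]] = (nat["synthUSP18"] * mrna0["USP18"]
                        / nat["degUSP18"])
    x0[idx["SOCS1"]] = nat["SOCS1_0"]
    x0[idx["SOCS3"]] = nat["SOCS3_0"]
    x0[idx["IRF2"]] = nat["IRF2_0"]
    rt = np.array([nat[n] if n in nat else d[n]
                   for n in network.runtime_names()])
    bad_x = [s.name for s, v in zip(network.species, x0)
             if not np.isfinite(v) or v < 0]
    if bad_x or not np.all(np.isfinite(rt)):
        raise SteadyStateError(
            f"steady state invalid for species {bad_x or '(rates)'}")
    return x0, rt, d


def apply_steady_state(params: ParameterSet, network: ReactionNetwork
                       ) -> dict:
    """Derived basal rates that close the steady state (name -> value)."""
    _, _, derived = steady_state(params, network)
    return derived


# ------------------------------------------------------------------ simulation

def _segments(condition: Condition, t_end: float) -> list:
    pot = EQUIPOTENCY[condition.ligand]
    events = [(0.0, "pre")]
    if condition.washout is not None:
        events += [(condition.washout[0], "off"),
                   (condition.washout[1], "on")]
    events.append((condition.stim_time, "stim"))
    events = sorted((t, a) for t, a in events if t < t_end)
    segs = []
    level = 0.0
    for (t, action), t_next in zip(
            events, [t for t, _ in events[1:]] + [t_end]):
        if action == "pre":
            level += condition.prestim_dose * pot
        elif action == "off":
            level = 0.0
        elif action == "on":
            level = condition.prestim_dose * pot
        elif action == "stim":
            level += condition.stim_dose * pot
        if t_next > t:
            segs.append((t, t_next, level))
    return segs


def simulate(network: ReactionNetwork, params: ParameterSet,
             condition: Condition, t_grid, tol: str = "acceptance"
             ) -> Trajectory:
    """Integrate one condition over ``t_grid`` (hours, must start at 0).

    The t=0 state is the steady state of the unstimulated system (after
    applying the condition's ratio shifts and abundance overrides); dosing
    events are discontinuous input changes with stop-and-restart integration.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be increasing and start at 0")
    x0, rt, _ = steady_state(params, network, condition)
    rhs = compiled_rhs(network)
    rtol, atol = TOLS[tol]
    kd = condition.knockdown_factor
    oe = 1.0 if condition.overexpression else 0.0
    out = np.empty((network.n_species, t_grid.size))
    out[:, 0] = x0
    y = x0.copy()
    for (ta, tb, ifn) in _segments(condition, t_grid[-1]):
        mask = (t_grid > ta) & (t_grid <= tb)
        t_eval = np.unique(np.append(t_grid[mask], tb))
        sol = solve_ivp(lambda t, y_: rhs(t, y_, rt, ifn, kd, oe),
                        (ta, tb), y, method="LSODA", rtol=rtol, atol=atol,
                        t_eval=t_eval)
        if not sol.success:
            raise SimulationError(
                f"solver failed ({sol.message}) for condition "
                f"{condition.condition_id or condition} near t={sol.t[-1] if sol.t.size else ta:.3f} h")
        out[:, mask] = sol.y[:, np.isin(t_eval, t_grid[mask])]
        y = sol.y[:, -1]
    traj = Trajectory(t=t_grid, x=out, network=network, condition=condition,
                      min_state=float(out.min()))
    if traj.min_state < -10.0 * atol:
        warnings.warn(f"negative state {traj.min_state:.3e} beyond solver "
                      "tolerance", RuntimeWarning, stacklevel=2)
    return traj


# ------------------------------------------------------------------ observables

_PSTAT1_C = (("pSTAT1dimc", 2), ("pSTAT1pSTAT2c", 1), ("ISGF3c", 1))
_PSTAT2_C = (("pSTAT1pSTAT2c", 1), ("ISGF3c", 1))
_PSTAT1_N = (("pSTAT1dimn", 2), ("pSTAT1pSTAT2n", 1), ("ISGF3n", 1))
_PSTAT2_N = (("pSTAT1pSTAT2n", 1), ("ISGF3n", 1))

OBSERVABLES = {
    "pSTAT1_Cyt": (_PSTAT1_C, "scale_pSTAT1_Cyt", "offset_pSTAT1_Cyt"),
    "pSTAT2_Cyt": (_PSTAT2_C, "scale_pSTAT2_Cyt", "offset_pSTAT2_Cyt"),
    "pSTAT1_Nuc": (_PSTAT1_N, "scale_pSTAT1_Nuc", None),
    "pSTAT2_Nuc": (_PSTAT2_N, "scale_pSTAT2_Nuc", None),
    "tSTAT1_Cyt": ((("STAT1c", 1),) + _PSTAT1_C, "scale_tSTAT1_Cyt", None),
    "tSTAT2_Cyt": ((("STAT2c", 1),) + _PSTAT2_C, "scale_tSTAT2_Cyt", None),
    "IRF9_Cyt": ((("IRF9c", 1), ("ISGF3c", 1)), "scale_IRF9_Cyt", None),
    "USP18_Cyt": ((("USP18", 1),), "scale_USP18_Cyt", None),
    # unscaled summaries used for predictions and the antiviral response
    "tSTAT1_Nuc": ((("STAT1n", 1),) + _PSTAT1_N, None, None),
    "tSTAT2_Nuc": ((("STAT2n", 1),) + _PSTAT2_N, None, None),
    "OccGASbs": ((("OccGASbs", 1),), None, None),
    "OccISREbs": ((("OccISREbs", 1),), None, None),
    "Occ_total": ((("OccGASbs", 1), ("OccISREbs", 1)), None, None),
}
for _g in GENES:
    OBSERVABLES[f"mRNA_{_g}"] = (((f"{_g}mRNA", 1),), f"scale_mRNA_{_g}",
                                 None)


def compute_observables(traj: Trajectory, params: ParameterSet,
                        names=None) -> dict:
    """Observable time courses: scale x (weighted state sum) + offset."""
    names = list(OBSERVABLES) if names is None else list(names)
    out = {}
    for name in names:
        if name not in OBSERVABLES:
            raise KeyError(f"unmapped observable {name!r}")
        parts, scale, offset = OBSERVABLES[name]
        y = np.zeros(traj.t.size)
        for sp, w in parts:
            y += w * traj.state(sp)
        s = params.natural(scale) if scale else 1.0
        o = params.natural(offset) if offset else 0.0
        out[name] = s * y + o
    return out
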