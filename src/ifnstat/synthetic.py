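"""Synthetic ground truth and data generators for the analysis pipeline.

The nominal parameter set is the package's calibrated "true" cell state.  It
was obtained by a deterministic least-squares fit of the receptor/activation
parameters against the canonical 1-hour dose-response anchors (half-maximal
STAT1 phosphorylation at 2.8 pM, ~10% STAT2 phosphorylation at 2.8 pM, >=99%
of maximum at 1,400 pM, response peaks 30 min after a saturating dose) and by
direct calibration of the feedback arms to reproduce dose-dependent
hypersensitization (relative antiviral response > 1 after a low prestimulation
dose) and desensitization (response << 1 after a high dose).
``nominal_parameters`` re-verifies the anchors by simulation and fails loudly
if they do not hold.

Generators emulate the study's measurement processes: multi-gel immunoblots
with gel-specific multiplicative scaling factors and log-normal noise,
qRT-PCR Cq values referenced to three housekeeping genes, spike-in calibrator
curves for molecules-per-cell estimation, and log-normal plasma IFNα levels
for the virtual patient cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .network import build_network
from .params import GENES, ParameterSet, estimated_names
from .simulate import Condition, compute_observables, simulate

#: frozen nominal ("true") natural-scale parameter values for Huh7.5-like
#: synthetic cells; see module docstring for how they were calibrated
NOMINAL = dict(
    # receptor module
    BindIFN=0.98853, KiSOCS=600.0, deactRec=2.7929, degRec=0.05,
    VdegSOCS1=2.0, VdegCoop=12.0, Kmdeg=1.2e4,
    # lumped phosphorylation/dimerization
    actSTAT1=2.6453e-10, actSTAT2=1.0e-13, KiUSP18=2.0e4,
    # complexes and shuttling
    formISGF3=1.0e-4, impComplex=3.9853, dissDimHet=1.5, dissISGF3=0.35,
    impSTAT1=0.15, impSTAT2=0.15, impIRF9=0.25, expMono=1.0,
    # promoter occupancy
    actGAS=6.0e-6, actISREhet=8.0e-5, actISREISGF3=1.0e-3, decayOcc=1.0,
    # transcription
    synthSTAT1mRNA=5.0, synthSTAT2mRNA=15.0, synthIRF9mRNA=6.0,
    synthIRF2mRNA=12.0, synthUSP18mRNA=16.0, synthSOCS1mRNA=36.0,
    synthSOCS3mRNA=45.0,
    degSTATmRNA=0.25, degIRF9mRNA=0.3, degIRF2mRNA=0.6, degUSP18mRNA=0.4,
    degSOCS1mRNA=1.2, degSOCS3mRNA=1.5,
    KiIRF2=5.0e3, KmIRF9occ=0.01,
    # translation
    synthSTAT1=3.5e4, synthSTAT2=3.0e3, synthIRF9=450.0, synthUSP18=250.0,
    delaySTAT1=2.0, delaySTAT2=2.0, delayIRF9=3.0, delayIRF2=1.0,
    delayUSP18=2.0, delaySOCS1=0.8, delaySOCS3=0.5,
    # feedback-protein degradation
    degUSP18=0.25, degSOCS1=0.7, degSOCS3=1.0, degIRF2=0.2,
    # overexpression / siRNA condition parameters
    synthUSP18mRNAbasal_OE=12.0, synthUSP18_inh=250.0,
    synthUSP18mRNAbasal_inh=0.02, synthUSP18mRNA_inh=0.8,
    # initial abundances (molecules/cell; mRNAs in arbitrary units)
    Rec0=2000.0, totSTAT1=7.0e5, totSTAT2=5.0e4, totIRF9=3.0e3,
    SOCS1_0=500.0, SOCS3_0=200.0, IRF2_0=1000.0,
    STAT1mRNA0=1.0, STAT2mRNA0=1.0, IRF9mRNA0=1.0, USP18mRNA0=1.0,
    SOCS1mRNA0=1.0,
)

#: cell-type ratio scenarios (log10 shifts vs the control model).  The
#: HepG2-like truth alters the basal STAT1-mRNA level (basal synthesis) and
#: the lumped STAT1/STAT2 phosphorylation-association rate; the hepatocyte
#: (PHH)-like truth alters the receptor amount, basal and induced STAT2-mRNA
#: synthesis, SOCS1-mRNA degradation and nuclear ISGF3 dissociation.
HEPG2_TRUTH = {"STAT1mRNA0": 0.5, "actSTAT2": -0.5}
PHH_TRUTH = {"Rec0": -0.4, "STAT2mRNA0": 0.4, "synthSTAT2mRNA": 0.5,
             "degSOCS1mRNA": -0.4, "dissISGF3": 0.5}

#: anchor tolerances for the frozen nominal set
ANCHOR_TOL = {"R1_low": (0.50, 0.05), "R2_low": (0.10, 0.05),
              "R1_sat": (1.00, 0.01)}


class AnchorError(RuntimeError):
    """The nominal set no longer reproduces its dose-response anchors."""


def nominal_values() -> dict:
    """Natural-scale nominal values including unit scalings/offsets."""
    vals = dict(NOMINAL)
    for n in estimated_names():
        if n.startswith("scale_"):
            vals[n] = 1.0
        elif n.startswith("offset_"):
            vals[n] = 1e-3
    return vals


def anchor_ratios(params: ParameterSet, network=None) -> dict:
    """Simulated 1-h dose-response anchor ratios of the parameter set."""
    network = network or build_network()
    t = np.arange(0.0, 1.05, 0.05)
    resp = {}
    for dose in (2.8, 1400.0, 2800.0):
        tr = simulate(network, params, Condition(prestim_dose=dose), t,
                      tol="fit")
        obs = compute_observables(tr, params, ["pSTAT1_Cyt", "pSTAT2_Cyt"])
        off1 = params.natural("offset_pSTAT1_Cyt")
        off2 = params.natural("offset_pSTAT2_Cyt")
        resp[dose] = (obs["pSTAT1_Cyt"][-1] - off1,
                      obs["pSTAT2_Cyt"][-1] - off2)
    return {"R1_low": resp[2.8][0] / resp[2800.0][0],
            "R2_low": resp[2.8][1] / resp[2800.0][1],
            "R1_sat": resp[1400.0][0] / resp[2800.0][0]}


@lru_cache(maxsize=4)
def _nominal_cached(verify: bool) -> ParameterSet:
    params = ParameterSet.from_dict(nominal_values())
    if verify:
        ratios = anchor_ratios(params)
        bad = {k: ratios[k] for k, (target, tol) in ANCHOR_TOL.items()
               if abs(ratios[k] - target) > tol
               and not (k == "R1_sat" and ratios[k] >= target - tol)}
        if bad:
            raise AnchorError(f"anchor residuals out of tolerance: {bad}")
    return params


def nominal_parameters(seed: int = 0, verify: bool = True) -> ParameterSet:
    """The deterministic nominal truth (independent of ``seed``).

    With ``verify`` the dose-response anchors are re-simulated and an
    :class:`AnchorError` is raised if any falls outside its tolerance.
    """
    del seed  # the calibration is deterministic; kept for API symmetry
    return _nominal_cached(verify)


# -------------------------------------------------------------------- design

@dataclass
class DesignCell:
    condition: Condition
    times: tuple
    observables: tuple


@dataclass
class SyntheticDesign:
    """Experimental design: conditions x time grids x observable panels."""

    cells: list = field(default_factory=list)
    replicates: int = 2
    gels_per_target: int = 2

    @property
    def n_points(self) -> int:
        return sum(len(c.times) * len(c.observables) for c in self.cells)


_BLOT_PANEL = ("pSTAT1_Cyt", "pSTAT2_Cyt", "pSTAT1_Nuc", "pSTAT2_Nuc",
               "tSTAT1_Cyt", "tSTAT2_Cyt", "IRF9_Cyt", "USP18_Cyt")
_QPCR_PANEL = tuple(f"mRNA_{g}" for g in GENES)

DOSE_PANEL = (0.0, 0.28, 2.8, 8.4, 28.0, 140.0, 280.0, 1400.0, 2800.0)


def default_design(scale: str = "small") -> SyntheticDesign:
    """Emulates the shape of the study design (dose panel, prestimulation/
    stimulation at 24 h, knockdown and overexpression conditions).

    ``small`` keeps a reduced condition/time grid for fast test runs;
    ``full`` covers the complete dose panel.
    """
    times_tc = ((0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0) if scale == "small"
                else tuple(np.r_[np.arange(0, 4.1, 0.5),
                                 (6.0, 8.0, 12.0, 16.0, 20.0, 24.0)]))
    times_restim = (24.0, 24.5, 25.0, 26.0, 28.0)
    doses = (0.0, 2.8, 28.0, 1400.0) if scale == "small" else DOSE_PANEL
    cells = []
    for dose in doses:
        cells.append(DesignCell(
            Condition(prestim_dose=dose, condition_id=f"tc_{dose:g}"),
            times_tc, _BLOT_PANEL))
    for pre in (0.0, 2.8, 1400.0):
        cells.append(DesignCell(
            Condition(prestim_dose=pre, stim_dose=1400.0,
                      condition_id=f"restim_{pre:g}"),
            times_restim, ("pSTAT1_Nuc", "pSTAT2_Nuc")))
    cells.append(DesignCell(
        Condition(prestim_dose=1400.0, stim_dose=1400.0,
                  knockdown_factor=0.05, condition_id="usp18_kd"),
        times_tc, ("pSTAT1_Cyt", "pSTAT2_Cyt", "USP18_Cyt", "tSTAT1_Cyt")))
    cells.append(DesignCell(
        Condition(prestim_dose=0.0, stim_dose=1400.0, overexpression=True,
                  condition_id="usp18_oe"),
        times_restim, ("pSTAT1_Cyt", "pSTAT2_Cyt", "USP18_Cyt")))
    return SyntheticDesign(cells=cells)


def qpcr_design(scale: str = "small") -> SyntheticDesign:
    times = (0.0, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)
    doses = (0.0, 2.8, 28.0, 1400.0)
    cells = [DesignCell(Condition(prestim_dose=d, condition_id=f"tc_{d:g}"),
                        times, _QPCR_PANEL) for d in doses]
    return SyntheticDesign(cells=cells)


# ----------------------------------------------------------------- generators

def _simulate_design(design: SyntheticDesign, truth: ParameterSet, network):
    rows = []
    for cell in design.cells:
        tmax = max(cell.times)
        grid = np.unique(np.r_[0.0, cell.times])
        traj = simulate(network, truth, cell.condition, grid, tol="fit")
        obs = compute_observables(traj, truth, cell.observables)
        tidx = np.searchsorted(grid, cell.times)
        for name in cell.observables:
            for k, t in zip(tidx, cell.times):
                rows.append((name, cell.condition.condition_id, t,
                             obs[name][k]))
    return pd.DataFrame(rows, columns=["target", "condition_id", "time",
                                       "truth"])


def generate_blots(design: SyntheticDesign, truth: ParameterSet,
                   noise_sd_log: float = 0.2, seed: int = 0,
                   gel_sd_log: float = 0.5, floor: float = 1e-9,
                   network=None):
    """Noisy multi-gel immunoblot measurements from the true trajectories.

    signal = gel_factor x max(observable, floor) x exp(eps) with
    eps ~ N(0, noise_sd_log^2); the floor is a detection background keeping
    signals positive (log-normal model).  Gel factors are log-normal around
    1 with the first gel per target fixed at 1 (the scaling reference).
    Returns ``(measurements, gel_factors)``.
    """
    if noise_sd_log < 0:
        raise ValueError("noise_sd_log must be >= 0")
    network = network or build_network(truth.variant)
    rng = np.random.default_rng(seed)
    base = _simulate_design(design, truth, network)
    rows, factors = [], {}
    for target, sub in base.groupby("target", sort=False):
        for rep in range(design.replicates):
            gel = f"{target}_gel{rep % design.gels_per_target}"
            if gel not in factors:
                factors[gel] = (1.0 if gel.endswith("gel0") else
                                float(np.exp(rng.normal(0.0, gel_sd_log))))
            eps = rng.normal(0.0, noise_sd_log, len(sub))
            for (_, r), e in zip(sub.iterrows(), eps):
                rows.append((target, gel, r.condition_id, r.time,
                             factors[gel] * max(r.truth, floor)
                             * np.exp(e)))
    meas = pd.DataFrame(rows, columns=["target", "gel", "condition_id",
                                       "time", "signal"])
    return meas, factors


def generate_qpcr(design: SyntheticDesign, truth: ParameterSet,
                  noise_sd_cq: float = 0.3, efficiency: float = 2.0,
                  seed: int = 0, network=None) -> pd.DataFrame:
    """Cq records for target genes plus GAPDH/HPRT/TBP reference genes.

    Expression E^(-Cq) is proportional to transcript abundance; reference
    genes are constant in truth.  A per-sample pipetting offset shifts all
    Cq values of the sample alike (removed by reference normalization).
    """
    network = network or build_network(truth.variant)
    rng = np.random.default_rng(seed)
    base = _simulate_design(design, truth, network)
    rows = []
    for (cond, time), sub in base.groupby(["condition_id", "time"],
                                          sort=False):
        sample_shift = rng.normal(0.0, 0.5)
        for _, r in sub.iterrows():
            gene = r.target.replace("mRNA_", "")
            cq = (-np.log(max(r.truth, 1e-12)) / np.log(efficiency) + 25.0
                  + sample_shift + rng.normal(0.0, noise_sd_cq))
            rows.append((gene, cond, time, cq, efficiency))
        for ref in ("GAPDH", "HPRT", "TBP"):
            cq = 20.0 + sample_shift + rng.normal(0.0, noise_sd_cq)
            rows.append((ref, cond, time, cq, efficiency))
    return pd.DataFrame(rows, columns=["gene", "condition_id", "time", "Cq",
                                       "efficiency"])


def generate_calibration(truth_abundances: dict, spikes=None,
                         cells_per_lysate: float = 1.0e5,
                         lysate_fraction: float = 1.0,
                         noise_sd_log: float = 0.1, seed: int = 0):
    """Spike-in calibrator curves for molecules-per-cell estimation.

    Returns a dict protein -> CalibrationCurve-like record with strictly
    increasing spiked amounts (molecule equivalents), noisy signals and the
    endogenous-sample signal.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for prot, per_cell in truth_abundances.items():
        total = per_cell * cells_per_lysate * lysate_fraction
        sp = (np.geomspace(total / 30.0, total * 30.0, 7) if spikes is None
              else np.asarray(spikes, float))
        gain = np.exp(rng.normal(0.0, 0.3))
        signals = gain * sp * np.exp(rng.normal(0.0, noise_sd_log, sp.size))
        endo = gain * total * np.exp(rng.normal(0.0, noise_sd_log))
        out[prot] = {"amounts": sp, "signals": signals,
                     "endogenous_signal": float(endo),
                     "cells_per_lysate": cells_per_lysate,
                     "lysate_fraction": lysate_fraction}
    return out


def lognormal_moments(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given natural-scale moments."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    v = sd ** 2
    mu = np.log(mean ** 2 / np.sqrt(mean ** 2 + v))
    sigma = np.sqrt(np.log(1.0 + v / mean ** 2))
    return float(mu), float(sigma)


def generate_cohort_plasma(n: int, mean: float = 0.0440, sd: float = 0.0362,
                           seed: int = 0) -> np.ndarray:
    """Plasma IFNα concentrations (pM), moment-matched log-normal."""
    mu, sigma = lognormal_moments(mean, sd)
    rng = np.random.default_rng(seed)
    return rng.lognormal(mu, sigma, size=int(n))


# --------------------------------------------------- knockdown calibration

def usp18_reduction(network, params: ParameterSet, knockdown_factor: float,
                    dose: float = 1400.0, t_end: float = 24.0) -> float:
    """Percent reduction of USP18 protein at ``t_end`` h of stimulation in
    siRNA-treated cells relative to the unperturbed simulation."""
    t = np.arange(0.0, t_end + 1e-9, 0.25)
    out = {}
    for kd in (1.0, knockdown_factor):
        traj = simulate(network, params,
                        Condition(prestim_dose=dose, knockdown_factor=kd),
                        t, tol="fit")
        out[kd] = compute_observables(traj, params,
                                      ["USP18_Cyt"])["USP18_Cyt"][-1]
    return 100.0 * (1.0 - out[knockdown_factor] / out[1.0])


def calibrate_knockdown(network, params: ParameterSet,
                        target_percent: float = 94.5,
                        dose: float = 1400.0, t_end: float = 24.0,
                        tol_pp: float = 0.1) -> tuple[float, float]:
    """Root-find the siRNA mRNA-synthesis scaling factor reproducing a
    measured knockdown efficiency.

    Bisects the knockdown factor (log10 scale) until the simulated USP18
    protein reduction at ``t_end`` matches ``target_percent`` within
    ``tol_pp`` percentage points.  Returns (factor, achieved_percent).
    """
    from scipy.optimize import brentq

    def f(log10_k):
        return usp18_reduction(network, params, 10.0 ** log10_k, dose,
                               t_end) - target_percent

    lo, hi = -5.0, 0.0
    if f(lo) < 0:
        raise ValueError("target reduction unreachable even at full "
                         "silencing")
    root = brentq(f, lo, hi, xtol=1e-4)
    k = 10.0 ** root
    achieved = usp18_reduction(network, params, k, dose, t_end)
    if abs(achieved - target_percent) > tol_pp:
        raise RuntimeError(f"knockdown calibration missed target: "
                           f"{achieved:.3f}% vs {target_percent}%")
    return k, achieved
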