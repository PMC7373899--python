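"""Steady state, event handling, conservation and observables."""

import numpy as np
import pytest

from ifnstat.network import STAT1_MOIETY, build_network
from ifnstat.params import ParameterSet
from ifnstat.simulate import (Condition, apply_steady_state,
                              compute_observables, simulate, steady_state)
from ifnstat.synthetic import nominal_values


def test_unstimulated_fixed_point_long_horizon(network, nominal):
    t = np.array([0.0, 10.0, 100.0, 1000.0])
    traj = simulate(network, nominal, Condition(), t)
    x0 = traj.x[:, 0]
    rel = np.abs(traj.x - x0[:, None]) / np.maximum(x0[:, None], 1e-12)
    assert rel.max() < 1e-6


def test_simple_turnover_balance(network, nominal):
    derived = apply_steady_state(nominal, network)
    nat = nominal.as_dict()
    # basal transcription = degradation rate x basal mRNA level
    assert derived["tcrbUSP18"] == pytest.approx(
        nat["degUSP18mRNA"] * nat["USP18mRNA0"], rel=1e-12)
    assert derived["synthRec"] == pytest.approx(
        nat["degRec"] * nat["Rec0"], rel=1e-12)


def test_doubling_initial_doubles_implied_synthesis(network, nominal):
    d1 = apply_steady_state(nominal, network)
    d2 = apply_steady_state(nominal.updated(
        {"SOCS1_0": 2 * nominal.natural("SOCS1_0")}), network)
    assert d2["synthSOCS1p"] == pytest.approx(2 * d1["synthSOCS1p"],
                                              rel=1e-12)


def test_event_splitting_equivalence(network, nominal):
    cond = Condition(prestim_dose=2.8, stim_dose=1400.0)
    t_full = np.r_[np.arange(0.0, 24.0, 1.0), np.arange(24.0, 28.01, 0.25)]
    traj = simulate(network, nominal, cond, t_full)
    # manual split: prestimulation only, then restart from the 24h state
    t_pre = np.arange(0.0, 24.01, 1.0)
    pre = simulate(network, nominal, Condition(prestim_dose=2.8), t_pre)
    from ifnstat.simulate import TOLS, compiled_rhs, steady_state as ss
    from scipy.integrate import solve_ivp
    _, rt, _ = ss(nominal, network, cond)
    rhs = compiled_rhs(network)
    rtol, atol = TOLS["acceptance"]
    seg = solve_ivp(lambda t, y: rhs(t, y, rt, 2.8 + 1400.0, 1.0, 0.0),
                    (24.0, 28.0), pre.x[:, -1], method="LSODA",
                    rtol=rtol, atol=atol,
                    t_eval=np.arange(24.0, 28.01, 0.25))
    joined = np.c_[pre.x[:, :-1], seg.y]
    scale = np.maximum(np.abs(traj.x), 1e-9 * traj.x.max())
    assert np.max(np.abs(traj.x - joined) / scale) < 1e-6


def test_moiety_conservation_without_turnover(network, nominal):
    # silence every synthesis and degradation rate; the STAT1 moiety
    # (stoichiometry-weighted) must be conserved under fixed IFN
    tiny = {n: 1e-30 for n in
            ("degRec", "degUSP18", "degSOCS1", "degSOCS3", "degIRF2",
             "synthSTAT1", "synthSTAT2", "synthIRF9", "synthUSP18",
             "degSTATmRNA", "degIRF9mRNA", "degIRF2mRNA", "degUSP18mRNA",
             "degSOCS1mRNA", "degSOCS3mRNA",
             "synthSTAT1mRNA", "synthSTAT2mRNA", "synthIRF9mRNA",
             "synthIRF2mRNA", "synthUSP18mRNA", "synthSOCS1mRNA",
             "synthSOCS3mRNA")}
    p = nominal.updated(tiny)
    traj = simulate(network, p, Condition(prestim_dose=1400.0),
                    np.arange(0.0, 8.01, 0.5))
    w = network.conserved_moiety(STAT1_MOIETY)
    # oracle: the weight vector lies in the left null space of S for the
    # turnover-free reaction subset
    S = network.stoichiometry_matrix()
    keep = [j for j, r in enumerate(network.reactions)
            if not (r.name.startswith(("deg", "synth", "tcr", "tl_",
                                       "chain_")))]
    assert np.allclose(w @ S[:, keep], 0.0)
    total = w @ traj.x
    assert np.max(np.abs(total - total[0]) / total[0]) < 1e-8


def test_nonnegative_states(network, nominal):
    for pre, stim in ((0.0, 1400.0), (1400.0, 1400.0), (2.8, 1400.0)):
        traj = simulate(network, nominal,
                        Condition(prestim_dose=pre, stim_dose=stim),
                        np.arange(0.0, 28.01, 0.25))
        assert traj.min_state > -1e-9


def test_roferon_equipotency(network, nominal):
    t = np.arange(0.0, 4.01, 0.25)
    a = simulate(network, nominal, Condition(prestim_dose=1400.0), t)
    b = simulate(network, nominal,
                 Condition(prestim_dose=608.0, ligand="Roferon"), t)
    assert np.allclose(a.x, b.x, rtol=1e-8, atol=1e-8)


def test_washout_restores_baseline_dynamics(network, nominal):
    cond = Condition(prestim_dose=1400.0, stim_dose=1400.0,
                     washout=(20.5, 24.0))
    traj = simulate(network, nominal, cond, np.arange(0.0, 28.01, 0.5))
    # ligand off at 20.5h: active receptor decays before re-addition
    arec = traj.state("aRecIFN")
    t = traj.t
    assert arec[t == 23.5] < arec[t == 20.0]
    assert arec[t == 25.0] > arec[t == 23.5]


def test_condition_validation():
    with pytest.raises(ValueError):
        Condition(prestim_dose=-1.0)
    with pytest.raises(ValueError):
        Condition(washout=(24.0, 20.0))
    with pytest.raises(ValueError):
        Condition(knockdown_factor=1.5)
    with pytest.raises(ValueError):
        Condition(ligand="IFNg")


def test_steady_state_rejects_impossible_configuration(network, nominal):
    from ifnstat.simulate import SteadyStateError
    bad = nominal.updated({"degUSP18": np.nan}, log10_scale=True)
    with pytest.raises(SteadyStateError):
        steady_state(bad, network)


# ------------------------------------------------------------- observables

def test_identity_observable_mapping(network, nominal):
    traj = simulate(network, nominal, Condition(prestim_dose=28.0),
                    np.arange(0.0, 8.01, 0.5))
    p1 = nominal.updated({"scale_mRNA_STAT1": 1.0})
    obs = compute_observables(traj, p1, ["mRNA_STAT1"])
    assert np.allclose(obs["mRNA_STAT1"], traj.state("STAT1mRNA"))


def test_tstat1_cyt_matches_steady_state_share(network, nominal):
    x0, _, _ = steady_state(nominal, network)
    traj = simulate(network, nominal, Condition(), np.array([0.0, 1.0]))
    obs = compute_observables(traj, nominal, ["tSTAT1_Cyt"])
    nat = nominal.as_dict()
    cyt_share = nat["totSTAT1"] / (1.0 + nat["impSTAT1"] / nat["expMono"])
    assert obs["tSTAT1_Cyt"][0] == pytest.approx(
        nat["scale_tSTAT1_Cyt"] * cyt_share, rel=1e-9)


def test_scale_linearity(network, nominal):
    traj = simulate(network, nominal, Condition(prestim_dose=1400.0),
                    np.arange(0.0, 2.01, 0.25))
    lo = compute_observables(traj, nominal, ["pSTAT1_Cyt"])["pSTAT1_Cyt"]
    doubled = nominal.updated(
        {"scale_pSTAT1_Cyt": 2 * nominal.natural("scale_pSTAT1_Cyt")})
    hi = compute_observables(traj, doubled, ["pSTAT1_Cyt"])["pSTAT1_Cyt"]
    off = nominal.natural("offset_pSTAT1_Cyt")
    assert np.allclose(hi - off, 2 * (lo - off), rtol=1e-12)


def test_unmapped_observable_rejected(network, nominal):
    traj = simulate(network, nominal, Condition(), np.array([0.0, 1.0]))
    with pytest.raises(KeyError):
        compute_observables(traj, nominal, ["pSTAT5_Cyt"])


# ------------------------------------------------------ sensitization pattern

def test_desensitization_and_hypersensitization_direction(network, nominal):
    """1-h nuclear pSTAT2 response: smaller after high-dose prestimulation,
    larger after low-dose prestimulation (refractoriness vs priming)."""
    t = np.r_[np.arange(0.0, 24.0, 0.5), np.arange(24.0, 25.01, 0.25)]
    resp = {}
    for pre in (0.0, 2.8, 1400.0):
        cond = Condition(prestim_dose=pre, stim_dose=1400.0)
        traj = simulate(network, nominal, cond, t)
        o = compute_observables(traj, nominal, ["pSTAT2_Nuc"])["pSTAT2_Nuc"]
        i24, i25 = np.searchsorted(t, 24.0), np.searchsorted(t, 25.0)
        resp[pre] = o[i25] - o[i24]
    assert resp[1400.0] < resp[0.0]
    assert resp[2.8] > resp[0.0]


def test_sbml_round_trip(tmp_path, network, nominal):
    from ifnstat.sbml import read_sbml, write_sbml
    path = tmp_path / "model.xml"
    write_sbml(network, nominal, path)
    net2, p2, n_sp, n_rx = read_sbml(path)
    assert (n_sp, n_rx) == (network.n_species, network.n_reactions)
    t = np.arange(0.0, 8.01, 0.5)
    a = simulate(network, nominal, Condition(prestim_dose=1400.0), t)
    b = simulate(net2, p2, Condition(prestim_dose=1400.0), t)
    assert np.max(np.abs(a.x - b.x)) <= 1e-8 * max(1.0, np.abs(a.x).max())
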