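"""Scaling/error model, calibration curves, qPCR normalization."""

import numpy as np
import pandas as pd
import pytest

from ifnstat.scaling import (DisconnectedGelsError, ExtrapolationError,
                             MissingReferenceError, align_replicates,
                             estimate_molecules_per_cell, normalize_qpcr)


def _frame(rows):
    return pd.DataFrame(rows, columns=["target", "gel", "condition_id",
                                       "time", "signal"])


def test_single_gel_is_identity():
    rows = [("x", "g0", "c", t, v) for t, v in
            [(0.0, 1.0), (1.0, 2.5), (2.0, 7.0)]]
    ds = align_replicates(_frame(rows))
    assert ds.gel_factors == {"g0": 1.0}
    assert np.allclose(ds.estimates["estimate"], [1.0, 2.5, 7.0])


def test_two_gel_factor_recovered_exactly():
    truth = {0.0: 1.0, 1.0: 3.0, 2.0: 0.5}
    rows = [("x", "g0", "c", t, v) for t, v in truth.items()]
    rows += [("x", "g1", "c", t, 2.0 * v) for t, v in truth.items()]
    ds = align_replicates(_frame(rows))
    assert ds.gel_factors["g1"] == pytest.approx(2.0, rel=1e-12)
    est = ds.estimates.set_index("time")["estimate"]
    for t, v in truth.items():
        assert est.loc[t] == pytest.approx(v, rel=1e-12)


def test_gel_equivariance():
    rng = np.random.default_rng(0)
    rows = []
    for g, fac in (("g0", 1.0), ("g1", 1.7)):
        for t in range(5):
            rows.append(("x", g, "c", float(t),
                         fac * (t + 1.0) * np.exp(rng.normal(0, 0.1))))
    base = align_replicates(_frame(rows))
    scaled = [(tg, g, c, t, s * (3.0 if g == "g1" else 1.0))
              for tg, g, c, t, s in rows]
    ds = align_replicates(_frame(scaled))
    assert ds.gel_factors["g1"] == pytest.approx(
        3.0 * base.gel_factors["g1"], rel=1e-9)
    assert np.allclose(ds.estimates["estimate"],
                       base.estimates["estimate"], rtol=1e-9)


def test_ci_width_shrinks_with_replicates():
    """Mean CI width ~ 1/sqrt(N): log-log slope -0.5 +/- 0.1."""
    rng = np.random.default_rng(42)
    widths = []
    for n_rep in (2, 4, 8):
        reps = []
        for mc in range(40):
            rows = []
            for g, fac in (("g0", 1.0), ("g1", 2.0)):
                for t in range(4):
                    for _ in range(n_rep):
                        rows.append(("x", g, "c", float(t),
                                     fac * (t + 1.0)
                                     * np.exp(rng.normal(0, 0.2))))
            ds = align_replicates(_frame(rows))
            reps.append(ds.estimates["sigma"].mean())
        widths.append(np.mean(reps))
    slope = np.polyfit(np.log([2, 4, 8]), np.log(widths), 1)[0]
    assert slope == pytest.approx(-0.5, abs=0.1)


def test_disconnected_gels_reported():
    rows = [("x", "g0", "a", 0.0, 1.0), ("x", "g0", "a", 1.0, 2.0),
            ("x", "g1", "b", 0.0, 5.0), ("x", "g1", "b", 1.0, 6.0)]
    with pytest.raises(DisconnectedGelsError) as err:
        align_replicates(_frame(rows))
    assert len(err.value.components) == 2


def test_nonpositive_signal_rejected():
    with pytest.raises(ValueError, match="positive"):
        align_replicates(_frame([("x", "g0", "c", 0.0, 0.0)]))


def test_single_replicate_flagged_unreliable():
    rows = [("x", "g0", "c", 0.0, 1.0), ("x", "g0", "c", 1.0, 2.0),
            ("x", "g0", "c", 2.0, 3.0)]
    ds = align_replicates(_frame(rows))
    assert not ds.estimates["reliable"].any()


# ------------------------------------------------- molecules per cell

def _curve(amounts, signals, endo, cells=1e5, fraction=1.0):
    return {"amounts": np.asarray(amounts, float),
            "signals": np.asarray(signals, float),
            "endogenous_signal": endo, "cells_per_lysate": cells,
            "lysate_fraction": fraction}


def test_noiseless_interpolation_exact():
    amounts = np.array([1e4, 1e5, 1e6, 1e7])
    curve = _curve(amounts, 2.0 * amounts, endo=2.0 * 1e5, cells=1.0)
    est, sem = estimate_molecules_per_cell(curve)
    assert est == pytest.approx(1e5, rel=1e-9)
    assert sem == pytest.approx(0.0, abs=1e-9)


def test_doubling_cells_halves_estimate():
    amounts = np.array([1e4, 1e5, 1e6, 1e7])
    c1 = _curve(amounts, 3.0 * amounts, endo=3e5, cells=1e5)
    c2 = _curve(amounts, 3.0 * amounts, endo=3e5, cells=2e5)
    assert estimate_molecules_per_cell(c1)[0] == pytest.approx(
        2 * estimate_molecules_per_cell(c2)[0], rel=1e-12)


def test_extrapolation_refused():
    amounts = np.array([1e4, 1e5, 1e6])
    curve = _curve(amounts, 2.0 * amounts, endo=2e8)
    with pytest.raises(ExtrapolationError):
        estimate_molecules_per_cell(curve)


def test_stat2_truth_recovered_within_twofold():
    from ifnstat.synthetic import generate_calibration
    curves = generate_calibration({"STAT2": 5.0e4}, seed=3)
    est, _ = estimate_molecules_per_cell(curves["STAT2"])
    assert 2.5e4 <= est <= 1.0e5


# --------------------------------------------------------------- qPCR

def _qpcr(rows):
    return pd.DataFrame(rows, columns=["gene", "condition_id", "time",
                                       "Cq", "efficiency"])


def _sample(cond, time, target_cq, ref_cq=20.0, eff=2.0):
    rows = [("MX1", cond, time, target_cq, eff)]
    rows += [(g, cond, time, ref_cq, eff) for g in ("GAPDH", "HPRT", "TBP")]
    return rows


def test_one_cycle_doubling():
    rows = _sample("c", 0.0, 25.0) + _sample("c", 1.0, 24.0)
    out = normalize_qpcr(_qpcr(rows), baseline_condition=("c", 0.0))
    fc = out.set_index("time")["fold_change"]
    assert fc.loc[1.0] == pytest.approx(2.0, rel=1e-12)


def test_global_shift_invariance():
    rows = _sample("c", 0.0, 25.0) + _sample("c", 1.0, 24.0)
    shifted = _sample("c", 0.0, 26.0, ref_cq=21.0) + \
        _sample("c", 1.0, 25.0, ref_cq=21.0)
    a = normalize_qpcr(_qpcr(rows), baseline_condition=("c", 0.0))
    b = normalize_qpcr(_qpcr(shifted), baseline_condition=("c", 0.0))
    assert np.allclose(a["fold_change"], b["fold_change"], rtol=1e-12)


def test_missing_reference_rejected():
    rows = [("MX1", "c", 0.0, 25.0, 2.0), ("GAPDH", "c", 0.0, 20.0, 2.0),
            ("HPRT", "c", 0.0, 20.0, 2.0)]
    with pytest.raises(MissingReferenceError):
        normalize_qpcr(_qpcr(rows))


def test_cq_bounds_validated():
    rows = [("MX1", "c", 0.0, 55.0, 2.0)]
    with pytest.raises(ValueError, match="Cq"):
        normalize_qpcr(_qpcr(rows))


def test_generator_round_trip_fold_changes(network, nominal):
    """Noise-free Cq records reproduce the simulated fold changes."""
    from ifnstat.synthetic import generate_qpcr, qpcr_design
    q = generate_qpcr(qpcr_design(), nominal, noise_sd_cq=0.0, seed=0)
    out = normalize_qpcr(q, baseline_condition=("tc_0", 0.0))
    from ifnstat.simulate import Condition, compute_observables, simulate
    t = np.array([0.0, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0])
    traj = simulate(network, nominal, Condition(prestim_dose=1400.0), t)
    truth = compute_observables(traj, nominal, ["mRNA_USP18"])["mRNA_USP18"]
    got = out[(out["gene"] == "USP18")
              & (out["condition_id"] == "tc_1400")].sort_values("time")
    assert np.allclose(got["fold_change"], truth / truth[0], rtol=1e-4)
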