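"""Virtual cohort sampling, antiviral-response metrics, thresholds."""

import numpy as np
import pytest

from ifnstat.cohort import (DEFAULT_COHORT_CONFIG, ThresholdResult,
                            antiviral_response, desensitization_threshold,
                            sample_cohort, spearman)
from ifnstat.synthetic import lognormal_moments


def test_default_cohort_has_114_patients():
    cohort = sample_cohort(seed=0)
    assert len(cohort) == 114
    assert (cohort[["STAT1", "STAT2", "IRF9", "USP18",
                    "plasma_ifn"]] > 0).all().all()


def test_zero_variance_config_degenerates_to_means():
    cfg = {"n": 5, "IFN": (0.05, 0.0), "STAT1": (4e5, 0.0),
           "STAT2": (4e4, 0.0), "IRF9": (3e4, 0.0), "USP18": (1e4, 0.0)}
    cohort = sample_cohort(cfg, seed=1)
    assert np.allclose(cohort["plasma_ifn"], 0.05)
    assert np.allclose(cohort["STAT1"], 4e5)


def test_moment_matched_lognormal_mean_exact():
    mu, sigma = lognormal_moments(0.0440, 0.0362)
    analytic_mean = np.exp(mu + sigma ** 2 / 2.0)
    assert analytic_mean == pytest.approx(0.0440, abs=1e-12)
    analytic_var = (np.exp(sigma ** 2) - 1) * np.exp(2 * mu + sigma ** 2)
    assert np.sqrt(analytic_var) == pytest.approx(0.0362, abs=1e-12)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        lognormal_moments(-1.0, 0.1)
    with pytest.raises(ValueError):
        sample_cohort(n=0)


def test_reproducible_under_seed():
    a = sample_cohort(seed=7)
    b = sample_cohort(seed=7)
    assert a.equals(b)
    assert not a.equals(sample_cohort(seed=8))


def test_response_trivial_identities(network, nominal):
    # no stimulation: absolute response is exactly zero (self-subtraction)
    resp = antiviral_response(network, nominal, None, prestim_dose=10.0,
                              stim_dose=0.0)
    assert resp.absolute == 0.0
    assert np.isnan(resp.relative)
    # no prestimulation: relative response is exactly one (self-ratio)
    resp = antiviral_response(network, nominal, None, prestim_dose=0.0,
                              stim_dose=608.0)
    assert resp.relative == 1.0
    assert resp.absolute > 0.0


def test_hyper_and_desensitization_directions(network, nominal):
    lo = antiviral_response(network, nominal, None, prestim_dose=1.2,
                            stim_dose=608.0)
    hi = antiviral_response(network, nominal, None, prestim_dose=608.0,
                            stim_dose=608.0)
    assert lo.relative > 1.0
    assert hi.relative < 1.0


def test_threshold_bisection_matches_grid_oracle(network, nominal):
    res = desensitization_threshold(network, nominal, None, stim_dose=608.0,
                                    dose_range=(0.5, 200.0), n_grid=7)
    assert res.converged
    # dense-grid oracle around the located crossing
    grid = np.geomspace(res.threshold / 2.0, res.threshold * 2.0, 17)
    rel = np.array([antiviral_response(network, nominal, None, d, 608.0)
                    .relative for d in grid])
    sign_flip = grid[np.argmax(rel < 1.0)]
    assert res.threshold == pytest.approx(sign_flip, rel=0.12)
    # bracket property: >= 1 just below, < 1 just above
    below = antiviral_response(network, nominal, None,
                               res.threshold / 1.05, 608.0).relative
    above = antiviral_response(network, nominal, None,
                               res.threshold * 1.05, 608.0).relative
    assert below >= 1.0 > above


def test_no_threshold_reported_when_absent(network, nominal):
    res = desensitization_threshold(network, nominal, None, stim_dose=608.0,
                                    dose_range=(1e-4, 1e-3), n_grid=3)
    assert not res.converged and np.isnan(res.threshold)
    assert "no threshold" in res.note


def test_usp18_abundance_lowers_threshold(network, nominal):
    """Cells with more basal USP18 tolerate less prestimulation before
    desensitizing (anti-correlation direction)."""
    base_usp18 = (nominal.natural("synthUSP18")
                  * nominal.natural("USP18mRNA0")
                  / nominal.natural("degUSP18"))
    lo = desensitization_threshold(
        network, nominal, {"STAT1": 7e5, "STAT2": 5e4, "IRF9": 3e3,
                           "USP18": base_usp18}, 608.0,
        dose_range=(0.1, 200.0), n_grid=7)
    hi = desensitization_threshold(
        network, nominal, {"STAT1": 7e5, "STAT2": 5e4, "IRF9": 3e3,
                           "USP18": 10 * base_usp18}, 608.0,
        dose_range=(0.1, 200.0), n_grid=7)
    assert lo.converged and hi.converged
    assert hi.threshold < lo.threshold


def test_spearman_oracle_cases():
    x = np.arange(10.0)
    assert spearman(x, x)[0] == pytest.approx(1.0)
    assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)
    x5, y5 = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
    d2 = sum((a - b) ** 2 for a, b in zip(x5, y5))
    brute = 1.0 - 6.0 * d2 / (5 * (5 ** 2 - 1))  # classic rank formula
    r, p = spearman(x5, y5)
    assert r == pytest.approx(brute) == pytest.approx(0.8)
    r_const, p_const = spearman([1, 1, 1, 1], [1, 2, 3, 4])
    assert np.isnan(r_const) and np.isnan(p_const)
    with pytest.raises(ValueError):
        spearman([1, 2], [1, 2])
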