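"""Sampling experiments that validate the statistical cores.

These are full studies (many simulated experiments run through the actual
estimators) used both by the test suite and by scripts that reproduce the
package's calibration claims: confidence-interval coverage, likelihood-ratio
type-I error, and end-to-end recovery of nick densities from rendered gel
lanes.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .fluctuation import FluctuationExperiment, estimate_m, lrt_rates
from .gelquant import (
    embedded_ribos,
    fit_calibration,
    quantify_lane,
)
from .simulate import SimConfig, render_gel_lane, simulate_fluctuation_counts, simulate_lane_fragments

__all__ = ["ci_coverage", "lrt_type1_rate", "gel_recovery_error"]


def ci_coverage(
    m_true: float = 2.0,
    n_cultures: int = 30,
    n_reps: int = 1000,
    epsilon: float = 1.0,
    Nt: int = 1_000_000_000,
    seed: int = 0,
) -> float:
    """Fraction of simulated experiments whose 95% profile CI covers m_true."""
    rng = np.random.default_rng(seed)
    cfg = SimConfig(seed=seed, n_cultures=n_cultures, m_true=m_true, epsilon=epsilon, Nt=Nt)
    covered = 0
    for _ in range(n_reps):
        counts = simulate_fluctuation_counts(cfg, rng)
        exp = FluctuationExperiment(counts=tuple(counts), epsilon=epsilon, Nt=Nt)
        fit = estimate_m(exp)
        covered += fit.ci_low <= m_true <= fit.ci_high
    return covered / n_reps


def lrt_type1_rate(
    m_true: float = 2.0,
    n_cultures: int = 20,
    n_pairs: int = 1000,
    epsilon: float = 1.0,
    Nt: int = 1_000_000_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection fraction of the rate LRT on pairs simulated under a shared rate."""
    rng = np.random.default_rng(seed)
    cfg = SimConfig(seed=seed, n_cultures=n_cultures, m_true=m_true, epsilon=epsilon, Nt=Nt)
    rejected = 0
    for _ in range(n_pairs):
        c1 = simulate_fluctuation_counts(cfg, rng)
        c2 = simulate_fluctuation_counts(cfg, rng)
        e1 = FluctuationExperiment(counts=tuple(c1), epsilon=epsilon, Nt=Nt)
        e2 = FluctuationExperiment(counts=tuple(c2), epsilon=epsilon, Nt=Nt)
        _, p = lrt_rates(e1, e2)
        rejected += p < alpha
    return rejected / n_pairs


def gel_recovery_error(
    rho_wt: float = 1e-5,
    rho_mut: float = 6e-5,
    seed: int = 0,
    ladder_sizes: tuple[float, ...] = (48500, 20000, 10000, 5000, 2000, 1000),
    n_wt_lanes: int = 2,
) -> tuple[float, float]:
    """One end-to-end gel experiment: render, calibrate, quantify, difference.

    Simulates wild-type (RER-proficient-like, low nick density) and mutant
    (high nick density) lanes plus ladder lanes, runs the full densitometry
    pipeline with the *fitted* calibration, and returns
    (estimated n_ribo, ground truth (rho_mut - rho_wt) * G).
    """
    rng = np.random.default_rng(seed)
    cfg = SimConfig(seed=seed)
    marker = [
        render_gel_lane(np.asarray(ladder_sizes, dtype=float), cfg, rng,
                        label=f"M{i}", uniform_mass=True)
        for i in range(2)
    ]
    calib = fit_calibration(marker, ladder_sizes)
    wt_cfg = replace(cfg, rho=rho_wt)
    mut_cfg = replace(cfg, rho=rho_mut)
    N_wt = []
    for i in range(n_wt_lanes):
        lane = render_gel_lane(simulate_lane_fragments(wt_cfg, rng), wt_cfg, rng, label=f"wt{i}")
        N_wt.append(quantify_lane(lane, calib).breakpoints)
    mut_lane = render_gel_lane(
        simulate_lane_fragments(mut_cfg, rng), mut_cfg, rng, label="mut"
    )
    N_mut = quantify_lane(mut_lane, calib).breakpoints
    truth = (rho_mut - rho_wt) * cfg.G
    return embedded_ribos(N_mut, N_wt), truth
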