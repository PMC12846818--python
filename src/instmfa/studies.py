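"""Replicate validation studies on the synthetic fixtures.

Each study regenerates noisy datasets from a fixture's ground truth,
re-estimates fluxes, and summarizes estimator performance: relative error
of the recovered free fluxes, detection behavior for a structurally zero
flux (the gluconeogenic PEPCK direction of the mixotrophic preset), and
empirical coverage of the 95% profile-likelihood confidence intervals.

Pool sizes are treated as known (measured) in these studies, which keeps
the estimation problem to the free net and exchange fluxes; a joint
flux-plus-pool fit is exercised separately in the test suite.
"""

from __future__ import annotations

import numpy as np

from .fitting import fit
from .fixtures import generate_dataset, make_fixture, simulate_truth
from .uncertainty import profile_confidence_interval

__all__ = ["recovery_study", "structural_zero_study", "coverage_study"]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(2 * n)[::2] % (2**31 - 1)


def recovery_study(
    n_reps: int = 50,
    n_starts: int = 20,
    noise_sd: float = 0.005,
    seed: int = 0,
    min_flux: float = 1.0,
) -> dict:
    """Parameter recovery on the mixotrophic preset.

    Returns the pooled median relative error of recovered fluxes (truth
    above ``min_flux``) and the error of the glyoxylate-shunt partition
    fraction, across ``n_reps`` independent noisy datasets.
    """
    fx = make_fixture("mini_chlamy_mixo")
    truth = simulate_truth(fx)
    seeds = _child_seeds(seed, n_reps)
    rel_errors: list[float] = []
    shunt_errors: list[float] = []
    true_shunt = fx.flux_map.net["ICL"] / (fx.flux_map.net["ICL"] + fx.flux_map.net["IDH"])
    for rep in range(n_reps):
        s = int(seeds[rep])
        ds = generate_dataset(fx, noise_sd=noise_sd, seed=s, truth=truth)
        fr = fit(
            fx.network, ds, fixed=fx.fit_fixed, n_starts=n_starts, seed=s + 1,
            fixed_pools=fx.pools, fit_pool_ids=[], n_local=6,
            max_nfev_start=10, max_nfev_polish=60,
            polish_restarts=3, restart_tol=1e-6,
        )
        for r, t in fx.flux_map.net.items():
            if abs(t) >= min_flux and r not in fx.fit_fixed:
                rel_errors.append(abs(fr.flux_map.net[r] - t) / abs(t))
        icl, idh = fr.flux_map.net["ICL"], fr.flux_map.net["IDH"]
        shunt_errors.append(abs(icl / (icl + idh) - true_shunt))
    return dict(
        n_reps=n_reps,
        n_starts=n_starts,
        noise_sd=noise_sd,
        median_relative_error=float(np.median(rel_errors)),
        median_shunt_partition_error=float(np.median(shunt_errors)),
        max_shunt_partition_error=float(np.max(shunt_errors)),
        shunt_within_0p1_fraction=float(np.mean(np.array(shunt_errors) <= 0.1)),
        true_shunt_partition=true_shunt,
    )


def structural_zero_study(n_reps: int = 20, seed: int = 0, alpha: float = 0.05) -> dict:
    """Zero-flux detection: with a true gluconeogenic (PEPCK) flux of 0 in
    the mixotrophic preset, how often does the 95% profile CI include 0?"""
    fx = make_fixture("mini_chlamy_mixo")
    truth = simulate_truth(fx)
    seeds = _child_seeds(seed, n_reps)
    included = 0
    estimates = []
    for rep in range(n_reps):
        s = int(seeds[rep])
        ds = generate_dataset(fx, seed=s, truth=truth)
        fr = fit(
            fx.network, ds, fixed=fx.fit_fixed, n_starts=6, seed=s + 1,
            fixed_pools=fx.pools, fit_pool_ids=[], n_local=4,
            max_nfev_start=10, max_nfev_polish=60,
            polish_restarts=3, restart_tol=1e-6,
        )
        ci = profile_confidence_interval(
            fr, fx.network, ds, "PCK", alpha=alpha, max_nfev=60, sides="lower"
        )
        estimates.append(fr.flux_map.net["PCK"])
        # PEPCK is bounded below by 0, so the CI includes 0 exactly when the
        # profiled lower edge reaches the bound
        included += ci.lower <= 1e-6
    return dict(
        n_reps=n_reps,
        inclusion_fraction=included / n_reps,
        median_estimate=float(np.median(estimates)),
    )


def coverage_study(
    n_reps: int = 50,
    seed: int = 0,
    reactions: tuple[str, ...] = ("ICL", "SDH"),
    alpha: float = 0.05,
) -> dict:
    """Empirical coverage of 95% profile CIs on the small TCA/glyoxylate
    cycle (pooled across the profiled reactions)."""
    fx = make_fixture("toy_tca_glyox")
    truth = simulate_truth(fx)
    seeds = _child_seeds(seed, n_reps)
    covered = 0
    total = 0
    for rep in range(n_reps):
        s = int(seeds[rep])
        ds = generate_dataset(fx, seed=s, truth=truth)
        fr = fit(
            fx.network, ds, fixed=fx.fit_fixed, n_starts=6, seed=s + 1,
            fixed_pools=fx.pools, fit_pool_ids=[], n_local=3,
        )
        for rxn in reactions:
            ci = profile_confidence_interval(fr, fx.network, ds, rxn, alpha=alpha, max_nfev=60)
            tol = max(1e-3 * abs(ci.point), 1e-6)
            covered += ci.contains(fx.flux_map.net[rxn], tol=tol)
            total += 1
    return dict(
        n_reps=n_reps,
        reactions=list(reactions),
        n_intervals=total,
        coverage=covered / total,
    )
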