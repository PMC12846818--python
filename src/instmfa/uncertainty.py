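"""Profile-likelihood ("parameter continuation") confidence intervals.

For one reaction's net flux, the profile walks the flux away from its
best-fit value, re-optimizing every other free parameter at each step,
until the SSR exceeds ``SSR_min + chi2_{1,1-alpha}`` (3.84 at alpha=0.05).
The crossing is then located by bisection.  A direction is declared
unbounded when the walked flux exceeds ten times the largest substrate
uptake flux without crossing the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.stats import chi2

from .fitting import FitResult, MIDDataset, _Objective, _run_start
from .network import Network, NetworkError, free_flux_parameterization

__all__ = ["ConfidenceInterval", "profile_confidence_interval", "flux_point_estimate"]

UNBOUNDED = math.inf


@dataclass
class ConfidenceInterval:
    reaction: str
    lower: float  # -inf when unbounded below
    upper: float  # +inf when unbounded above
    alpha: float
    ssr_threshold: float
    point: float  # best-fit net flux
    #: (flux value, SSR) pairs visited during continuation, for plotting
    trace: list = None

    @property
    def bounded(self) -> bool:
        return math.isfinite(self.lower) and math.isfinite(self.upper)

    def contains(self, value: float, tol: float = 0.0) -> bool:
        return self.lower - tol <= value <= self.upper + tol


def flux_point_estimate(ci: ConfidenceInterval) -> float:
    """Interval midpoint (the CI-median flux reported on flux maps);
    NaN sentinel when either direction is unbounded."""
    if not ci.bounded:
        return math.nan
    return 0.5 * (ci.lower + ci.upper)


def _flux_range(net: Network, fixed, reaction: str) -> tuple[float, float]:
    """Admissible [min, max] of one net flux over the bounded polytope."""
    basis = free_flux_parameterization(net, fixed)
    j = basis.rxn_ids.index(reaction)
    lb = np.array([r.bounds[0] for r in net.reactions])
    ub = np.array([r.bounds[1] for r in net.reactions])
    k = basis.n_free_net
    out = []
    for sgn in (1.0, -1.0):
        c = sgn * basis.N[j]
        if k == 0 or np.allclose(basis.N[j], 0.0):
            out.append(basis.v0[j])
            continue
        res = linprog(
            c,
            A_ub=np.vstack([basis.N, -basis.N]),
            b_ub=np.concatenate([ub - basis.v0, basis.v0 - lb]),
            bounds=[(None, None)] * k,
            method="highs",
        )
        if res.status == 3:
            out.append(sgn * -UNBOUNDED)
        elif res.success:
            out.append(basis.v0[j] + float(basis.N[j] @ res.x))
        else:
            raise NetworkError(f"cannot bound flux {reaction}")
    lo, hi = sorted(out)
    return lo, hi


def _constrained_ssr(
    obj: _Objective,
    net: Network,
    reaction: str,
    value: float,
    warm: np.ndarray,
    max_nfev: int = 120,
) -> tuple[float, np.ndarray]:
    """Minimal SSR with the target net flux pinned at ``value``; all other
    free parameters re-optimized from the warm start."""
    fixed = dict(obj.basis.fixed)
    fixed[reaction] = value
    basis_c = free_flux_parameterization(net, fixed)
    obj_c = _Objective(
        basis_c,
        obj.data,
        obj.tracer,
        obj.fixed_pools,
        obj.fitted_pool_ids,
        obj.method,
        obj.grid_points,
        obj.drop_m0,
        censor_sd=obj.censor_sd,
    )
    # project the warm-start flux map onto the constrained affine space
    fm, pools = obj.split(warm)
    v_prev = np.array([fm.net[r] for r in basis_c.rxn_ids])
    theta = basis_c.N.T @ (v_prev - basis_c.v0)
    nb_full = obj.basis.n_params
    betas = warm[obj.basis.n_free_net : nb_full]
    logpools = warm[nb_full:]
    x0 = np.concatenate([theta, betas, logpools])
    lo, hi = obj_c.bounds()
    res = _run_start(obj_c, x0, lo, hi, max_nfev)
    for _ in range(3):  # restart until descent stalls (fresh trust region)
        prev = 2.0 * res.cost
        res2 = _run_start(obj_c, res.x, lo, hi, max_nfev)
        if not np.isfinite(res2.cost):
            break
        res = res2
        if prev - 2.0 * res.cost <= 1e-6 * max(prev, 1.0):
            break
    ssr = obj_c.data_ssr(res.x)
    # map solution back to the unconstrained parameterization for warm reuse
    fm_c, _ = obj_c.split(res.x)
    v_c = np.array([fm_c.net[r] for r in obj.basis.rxn_ids])
    theta_full = obj.basis.N.T @ (v_c - obj.basis.v0)
    nb_c = basis_c.n_params
    warm_next = np.concatenate(
        [theta_full, res.x[basis_c.n_free_net : nb_c], res.x[nb_c:]]
    )
    return float(ssr), warm_next


def profile_confidence_interval(
    fit: FitResult,
    net: Network,
    data: MIDDataset,
    reaction: str,
    alpha: float = 0.05,
    max_nfev: int = 120,
    sides: str = "both",
) -> ConfidenceInterval:
    """Parameter-continuation CI for one reaction's net flux.

    ``sides`` may be ``"both"``, ``"lower"`` or ``"upper"``; a side that is
    not profiled is reported as the best-fit value itself."""
    if fit.objective is None:
        raise ValueError("FitResult lacks its objective; re-run fit()")
    obj = fit.objective
    if reaction not in fit.flux_map.net:
        raise KeyError(reaction)
    v_hat = fit.flux_map.net[reaction]
    threshold = fit.ssr + chi2.ppf(1.0 - alpha, 1)
    trace: list[tuple[float, float]] = [(v_hat, fit.ssr)]
    rng_lo, rng_hi = _flux_range(net, obj.basis.fixed, reaction)
    if abs(rng_hi - rng_lo) < 1e-12:
        return ConfidenceInterval(
            reaction, v_hat, v_hat, alpha, threshold, v_hat, trace
        )

    uptakes = [
        abs(fit.flux_map.net[r.id])
        for r in net.reactions
        if any(net.metabolites[m].role == "source" for m in r.reactants)
    ]
    v_cap = 10.0 * max(max(uptakes, default=0.0), 1.0)
    bisect_tol = max(1e-3 * abs(v_hat), 1e-6)

    def profile_dir(sgn: float) -> float:
        limit = rng_hi if sgn > 0 else rng_lo
        step = max(0.05 * abs(v_hat), 0.01)
        warm = fit.params.copy()
        prev_val = v_hat
        prev_ssr = fit.ssr
        while True:
            val = prev_val + sgn * step
            clipped = False
            if sgn > 0 and val >= limit:
                val, clipped = limit, True
            if sgn < 0 and val <= limit:
                val, clipped = limit, True
            try:
                ssr, warm_new = _constrained_ssr(obj, net, reaction, val, warm, max_nfev)
            except Exception:
                step *= 0.5  # non-converged continuation step: retry smaller
                if step < bisect_tol:
                    return val
                continue
            trace.append((val, ssr))
            if ssr > threshold:
                # bracket [prev_val, val]; bisection to tolerance
                a, b = prev_val, val
                wa = warm
                while abs(b - a) > bisect_tol:
                    mid = 0.5 * (a + b)
                    s_m, w_m = _constrained_ssr(obj, net, reaction, mid, wa, max_nfev)
                    trace.append((mid, s_m))
                    if s_m > threshold:
                        b = mid
                    else:
                        a, wa = mid, w_m
                return 0.5 * (a + b)
            warm, prev_val, prev_ssr = warm_new, val, ssr
            if clipped:
                return val  # profile truncated at the admissible range edge
            if abs(val) > v_cap:
                return sgn * UNBOUNDED
            step *= 1.6  # accelerate while clearly below the threshold

    upper = profile_dir(+1.0) if sides in ("both", "upper") else v_hat
    lower = profile_dir(-1.0) if sides in ("both", "lower") else v_hat
    trace.sort(key=lambda p: p[0])
    return ConfidenceInterval(reaction, lower, upper, alpha, threshold, v_hat, trace)
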