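"""Flux and pool-size estimation from MID time courses.

The objective is the variance-weighted sum of squared residuals over all
scalar mass-isotopomer measurements.  Because each observed MID sums to 1,
its M+0 entry is redundant and is dropped from the objective (and from the
degrees of freedom), avoiding double counting.

Free parameters are (i) the coordinates of the steady-state flux polytope
(:class:`~instmfa.network.FluxBasis`), (ii) one bounded exchange coordinate
``beta`` per reversible reaction, and (iii) log10 pool sizes unless fixed.
Each optimization start draws the free coordinates uniformly inside the
bounded parameter space (randomized initial points in the flux solution
space); the minimal-SSR start is polished further and returned.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erf
from scipy.stats import chi2

from .emu import EMU, decompose
from .network import (
    FluxBasis,
    FluxMap,
    Network,
    apply_flux_vector,
    free_flux_parameterization,
)
from .simulate import MIDTrajectory, TracerProtocol, simulate_transient

__all__ = [
    "Observation",
    "MIDDataset",
    "FitResult",
    "weighted_ssr",
    "fit",
    "goodness_of_fit",
]

BOUND_PENALTY = 1.0e4
DEFAULT_POOL_BOUNDS = (1.0e-4, 1.0e2)  # umol/gDW


@dataclass(frozen=True)
class Observation:
    metabolite: str
    atoms: tuple[int, ...]  # measured fragment, 1-based carbon indices
    time_s: float
    mid: np.ndarray
    sd: np.ndarray

    @property
    def emu(self) -> EMU:
        return EMU(self.metabolite, self.atoms)


@dataclass
class MIDDataset:
    observations: list[Observation]
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.observations:
            raise ValueError("empty MID dataset")
        for o in self.observations:
            if len(o.mid) != len(o.atoms) + 1 or len(o.sd) != len(o.mid):
                raise ValueError(f"MID/SD length mismatch for {o.metabolite} t={o.time_s}")
            if np.any(o.sd <= 0):
                raise ValueError(f"non-positive SD for {o.metabolite} t={o.time_s}")
            if abs(float(np.sum(o.mid)) - 1.0) > 0.02:
                raise ValueError(
                    f"observed MID of {o.metabolite} at t={o.time_s} does not sum to 1 "
                    "within measurement slack (0.02)"
                )

    def times(self) -> np.ndarray:
        t = np.unique([o.time_s for o in self.observations])
        if t[0] != 0.0:
            t = np.concatenate([[0.0], t])
        return t

    def target_emus(self) -> list[EMU]:
        return sorted({o.emu for o in self.observations})

    def n_scalar_measurements(self, drop_m0: bool = True) -> int:
        return sum(len(o.mid) - (1 if drop_m0 else 0) for o in self.observations)


def weighted_ssr(sim: MIDTrajectory, data: MIDDataset, drop_m0: bool = True) -> float:
    """Sum over scalar measurements of ((sim - obs) / SD)^2."""
    total = 0.0
    for o in data.observations:
        s = sim.mid_at(o.emu, o.time_s)
        lo = 1 if drop_m0 else 0
        total += float(np.sum(((s[lo:] - o.mid[lo:]) / o.sd[lo:]) ** 2))
    return total


@dataclass
class StartRecord:
    ssr: float
    converged: bool
    nfev: int
    message: str


@dataclass
class FitResult:
    flux_map: FluxMap
    pool_sizes: dict[str, float]
    ssr: float
    dof: int
    n_starts: int
    starts: list[StartRecord]
    seed: int
    params: np.ndarray
    basis: FluxBasis
    fitted_pool_ids: list[str]
    identifiable: bool
    jac: np.ndarray | None = None
    objective: "_Objective | None" = None


def censored_mid_expectation(mid: np.ndarray, raw_sd: float) -> np.ndarray:
    """Expected recorded MID after the measurement post-processing.

    Recorded fractions are clipped at 0 and renormalized; for Gaussian
    channel noise of scale ``raw_sd`` the expected clipped value is the
    censored-Gaussian mean ``m Phi(m/sd) + sd phi(m/sd)``, which is biased
    upward where the true fraction is near 0.  Mapping model predictions
    through the same expectation keeps the weighted objective centred on
    the data (otherwise structurally-zero channels pull the fit)."""
    if raw_sd <= 0:
        return mid
    z = mid / raw_sd
    phi = np.exp(-0.5 * z**2) / math.sqrt(2.0 * math.pi)
    Phi = 0.5 * (1.0 + erf(z / math.sqrt(2.0)))
    e = mid * Phi + raw_sd * phi
    return e / e.sum()


class _Objective:
    """Residual vector for least squares; reusable by profile continuation."""

    def __init__(
        self,
        basis: FluxBasis,
        data: MIDDataset,
        tracer: TracerProtocol,
        fixed_pools: Mapping[str, float],
        fitted_pool_ids: Sequence[str],
        method: str = "fast",
        grid_points: int = 96,
        drop_m0: bool = True,
        censor_sd: float | None = None,
    ):
        self.basis = basis
        self.data = data
        self.tracer = tracer
        self.fixed_pools = dict(fixed_pools)
        self.fitted_pool_ids = list(fitted_pool_ids)
        self.method = method
        self.grid_points = grid_points
        self.drop_m0 = drop_m0
        self.censor_sd = censor_sd or 0.0
        self.emunet = decompose(basis.network, data.target_emus())
        self.times = data.times()
        self.targets = data.target_emus()
        if method == "fast":
            from .simulate import FastSimulator

            self._fast = FastSimulator(self.emunet, tracer, self.times, grid_points)
        else:
            self._fast = None
        needed = {e.metabolite for e in self.emunet.emus}
        missing = needed - set(self.fixed_pools) - set(self.fitted_pool_ids)
        if missing:
            raise ValueError(f"no pool size (fixed or fitted) for: {sorted(missing)}")

    @property
    def n_params(self) -> int:
        return self.basis.n_params + len(self.fitted_pool_ids)

    def split(self, x: np.ndarray) -> tuple[FluxMap, dict[str, float]]:
        nb = self.basis.n_params
        fm = apply_flux_vector(self.basis, x[:nb], check_bounds=False)
        pools = dict(self.fixed_pools)
        for pid, lp in zip(self.fitted_pool_ids, x[nb:]):
            pools[pid] = 10.0**lp
        return fm, pools

    def bounds(self, pool_bounds=DEFAULT_POOL_BOUNDS) -> tuple[np.ndarray, np.ndarray]:
        k = self.basis.n_free_net
        lo = list(self.basis.theta_bounds[:, 0])
        hi = list(self.basis.theta_bounds[:, 1])
        lo += [0.0] * len(self.basis.exchange_ids)
        hi += [0.9999] * len(self.basis.exchange_ids)
        lo += [np.log10(pool_bounds[0])] * len(self.fitted_pool_ids)
        hi += [np.log10(pool_bounds[1])] * len(self.fitted_pool_ids)
        return np.array(lo), np.array(hi)

    def simulate(self, x: np.ndarray) -> MIDTrajectory:
        fm, pools = self.split(x)
        if self._fast is not None:
            return self._fast.run(fm, pools, extract=self.targets)
        return simulate_transient(
            self.emunet,
            fm,
            pools,
            self.tracer,
            self.times,
            method=self.method,
            grid_points=self.grid_points,
        )

    def residuals(self, x: np.ndarray) -> np.ndarray:
        fm, pools = self.split(x)
        res: list[np.ndarray] = []
        try:
            traj = self.simulate(x)
        except Exception:
            # infeasible corner (e.g. vanishing throughput): large flat residual
            n = self.data.n_scalar_measurements(self.drop_m0)
            return np.full(n + len(self.basis.rxn_ids), 1e3)
        lo = 1 if self.drop_m0 else 0
        for o in self.data.observations:
            s = censored_mid_expectation(traj.mid_at(o.emu, o.time_s), self.censor_sd)
            res.append((s[lo:] - o.mid[lo:]) / o.sd[lo:])
        # hinge penalties keep the optimizer inside the flux bound polytope
        pen = np.zeros(len(self.basis.rxn_ids))
        for i, (rid, r) in enumerate(zip(self.basis.rxn_ids, self.basis.network.reactions)):
            v = fm.net[rid]
            lb, ub = r.bounds
            if v < lb:
                pen[i] = BOUND_PENALTY * (lb - v)
            elif v > ub:
                pen[i] = BOUND_PENALTY * (v - ub)
        res.append(pen)
        return np.concatenate(res)

    def data_ssr(self, x: np.ndarray) -> float:
        traj = self.simulate(x)
        lo = 1 if self.drop_m0 else 0
        total = 0.0
        for o in self.data.observations:
            s = censored_mid_expectation(traj.mid_at(o.emu, o.time_s), self.censor_sd)
            total += float(np.sum(((s[lo:] - o.mid[lo:]) / o.sd[lo:]) ** 2))
        return total


def _run_start(obj: _Objective, x0, lo, hi, max_nfev):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return least_squares(
            obj.residuals,
            np.clip(x0, lo, hi),
            bounds=(lo, hi),
            method="trf",
            x_scale="jac",
            ftol=1e-8,
            xtol=1e-10,
            gtol=1e-10,
            max_nfev=max_nfev,
        )


def fit(
    net: Network,
    data: MIDDataset,
    fixed: Mapping[str, float] | None = None,
    n_starts: int = 20,
    seed: int = 0,
    *,
    tracer: TracerProtocol | None = None,
    fixed_pools: Mapping[str, float] | None = None,
    fit_pool_ids: Sequence[str] | None = None,
    pool_bounds: tuple[float, float] = DEFAULT_POOL_BOUNDS,
    censor_sd: float | str | None = "auto",
    sim_method: str = "fast",
    grid_points: int = 96,
    n_local: int = 6,
    max_nfev_start: int = 15,
    max_nfev_polish: int = 120,
    polish_restarts: int = 5,
    restart_tol: float = 1e-8,
) -> FitResult:
    """Estimate fluxes (and pool sizes) by multi-start weighted least squares.

    ``fixed`` pins net fluxes (measured uptakes, biomass demands);
    ``fixed_pools`` pins pool sizes; remaining pools needed by the EMU
    system are fitted as log10 parameters within ``pool_bounds`` unless
    ``fit_pool_ids`` narrows the list.  Deterministic for a given ``seed``.

    Multi-start strategy: every start's objective is evaluated at its
    random initial point, the ``n_local`` most promising starts are locally
    optimized, and the minimal-SSR solution is polished to convergence.

    ``censor_sd`` is the raw per-channel noise scale of the measurement
    post-processing (clip at 0, renormalize); predictions are mapped through
    the matching censored-Gaussian expectation before the residuals are
    formed.  ``"auto"`` reads it from ``data.metadata['noise_sd']``.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    data.validate()
    if tracer is None:
        tracer = data.metadata.get("tracer")
    if tracer is None:
        raise ValueError("a TracerProtocol is required (argument or data.metadata['tracer'])")
    basis = free_flux_parameterization(net, fixed)
    fixed_pools = dict(fixed_pools or {})
    probe = decompose(net, data.target_emus())
    needed = sorted({e.metabolite for e in probe.emus})
    if fit_pool_ids is None:
        fit_pool_ids = [m for m in needed if m not in fixed_pools]
    if censor_sd == "auto":
        censor_sd = float(data.metadata.get("noise_sd") or 0.0)
    obj = _Objective(
        basis, data, tracer, fixed_pools, fit_pool_ids, sim_method, grid_points,
        censor_sd=censor_sd,
    )
    if obj.n_params == 0:
        # fully determined system: nothing to optimize, evaluate directly
        x0 = np.zeros(0)
        fm, pools = obj.split(x0)
        ssr = obj.data_ssr(x0)
        return FitResult(
            flux_map=fm,
            pool_sizes=pools,
            ssr=float(ssr),
            dof=data.n_scalar_measurements(),
            n_starts=n_starts,
            starts=[StartRecord(float(ssr), True, 1, "determined")],
            seed=seed,
            params=x0,
            basis=basis,
            fitted_pool_ids=[],
            identifiable=True,
            jac=np.zeros((data.n_scalar_measurements(), 0)),
            objective=obj,
        )
    lo, hi = obj.bounds(pool_bounds)
    rng = np.random.default_rng(seed)
    span_lo = np.where(np.isfinite(lo), lo, -1e3)
    span_hi = np.where(np.isfinite(hi), hi, 1e3)
    x0s = rng.uniform(span_lo, span_hi, size=(n_starts, obj.n_params))

    # score every start at its initial point, then optimize the best few
    ssr0 = np.empty(n_starts)
    for s in range(n_starts):
        try:
            ssr0[s] = float(np.sum(obj.residuals(x0s[s]) ** 2))
        except Exception:
            ssr0[s] = np.inf
    order = np.argsort(ssr0)
    chosen = set(order[: max(1, min(n_local, n_starts))].tolist())
    records: list[StartRecord] = []
    best = None
    for s in range(n_starts):
        if s not in chosen:
            records.append(StartRecord(float(ssr0[s]), False, 1, "screened"))
            continue
        try:
            res = _run_start(obj, x0s[s], lo, hi, max_nfev_start)
        except Exception as exc:  # pragma: no cover - defensive
            records.append(StartRecord(np.inf, False, 0, str(exc)))
            continue
        ssr = 2.0 * res.cost
        records.append(StartRecord(float(ssr), bool(res.success), int(res.nfev), "optimized"))
        if best is None or ssr < best[0]:
            best = (ssr, res)
    if best is None:
        raise RuntimeError("no optimization start converged")
    # polish with restarts: a fresh trust region often resumes fast descent
    res = _run_start(obj, best[1].x, lo, hi, max_nfev_polish)
    for _ in range(polish_restarts):
        prev = 2.0 * res.cost
        res2 = _run_start(obj, res.x, lo, hi, max_nfev_polish)
        if not np.isfinite(res2.cost):
            break
        res = res2
        if prev - 2.0 * res.cost <= restart_tol * max(prev, 1.0):
            break
    fm, pools = obj.split(res.x)
    ssr = obj.data_ssr(res.x)
    dof = data.n_scalar_measurements() - obj.n_params
    sv = np.linalg.svd(res.jac[: data.n_scalar_measurements()], compute_uv=False)
    identifiable = bool(sv.min() > 1e-8 * max(sv.max(), 1.0))
    if not identifiable:
        warnings.warn(
            "parameter Hessian is rank-deficient at the optimum; some fluxes "
            "are structurally unidentifiable",
            RuntimeWarning,
        )
    return FitResult(
        flux_map=fm,
        pool_sizes=pools,
        ssr=float(ssr),
        dof=int(dof),
        n_starts=n_starts,
        starts=records,
        seed=seed,
        params=res.x.copy(),
        basis=basis,
        fitted_pool_ids=list(fit_pool_ids),
        identifiable=identifiable,
        jac=np.asarray(res.jac),
        objective=obj,
    )


def goodness_of_fit(ssr: float, dof: int, alpha: float = 0.05) -> str:
    """Chi-square acceptance test: ``accept`` iff SSR lies inside the
    [alpha/2, 1-alpha/2] quantiles of chi2(dof)."""
    if dof < 1:
        raise ValueError("dof must be >= 1")
    lo = chi2.ppf(alpha / 2.0, dof)
    hi = chi2.ppf(1.0 - alpha / 2.0, dof)
    if ssr < lo:
        return "reject-low"
    if ssr > hi:
        return "reject-high"
    return "accept"
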