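"""Brute-force full-isotopomer simulator (test oracle).

Integrates the complete 2^n isotopomer balance of every balanced,
carbon-bearing metabolite and marginalizes to MIDs.  Exponential in network
carbon content, so guarded to <= 20 total balanced carbons; used only to
cross-check the EMU simulator on small fixtures, never in fitting.

Isotopomer indexing: bit ``a-1`` of the state index corresponds to carbon
``a`` (1-based), set when the carbon is 13C.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .emu import EMU
from .network import FluxMap, Network
from .simulate import (
    SECONDS_PER_HOUR,
    MIDTrajectory,
    SimulationError,
    TracerProtocol,
    _validate_times,
)

__all__ = ["isotopomer_oracle"]

MAX_TOTAL_CARBONS = 20


def _source_isotopomers(n: int, e: float) -> np.ndarray:
    """Independent-atom isotopomer distribution of a source molecule."""
    x = np.zeros(2**n)
    for s in range(2**n):
        k = bin(s).count("1")
        x[s] = e**k * (1 - e) ** (n - k)
    return x


def _marginal(x: np.ndarray, n: int, positions: Sequence[int]) -> np.ndarray:
    """Marginal isotopomer distribution over a subset of carbons (1-based)."""
    t = x.reshape((2,) * n, order="F")  # axis a-1 <-> carbon a
    keep = [p - 1 for p in positions]
    drop = tuple(ax for ax in range(n) if ax not in keep)
    m = t.sum(axis=drop) if drop else t
    # reorder axes to the order given in `positions`
    current = [ax for ax in range(n) if ax in keep]
    perm = [current.index(p - 1) for p in positions]
    m = np.transpose(m, perm)
    return m.ravel(order="F")


def isotopomer_oracle(
    net: Network,
    flux: FluxMap,
    pools: Mapping[str, float],
    tracer: TracerProtocol,
    times: Sequence[float],
    targets: Sequence[EMU] | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> MIDTrajectory:
    """Simulate full isotopomer dynamics and return target-EMU MIDs."""
    times = _validate_times(times)
    mets = [
        m for m in net.metabolites.values() if m.role == "balanced" and m.n_carbons > 0
    ]
    total_c = sum(m.n_carbons for m in mets)
    if total_c > MAX_TOTAL_CARBONS:
        raise SimulationError(
            f"isotopomer state space too large ({total_c} carbons > {MAX_TOTAL_CARBONS})"
        )
    met_ids = [m.id for m in mets]
    n_c = {m.id: m.n_carbons for m in mets}
    offsets: dict[str, int] = {}
    off = 0
    for m in mets:
        offsets[m.id] = off
        off += 2**m.n_carbons
    dim = off

    for m in mets:
        if pools.get(m.id, 0.0) <= 0:
            raise SimulationError(f"non-positive pool size for {m.id}")

    # production terms: (product met, rate_per_s, mapping) where mapping is a
    # list over reactant occurrences of (source met | None for boundary,
    # source positions (1-based), product positions (1-based))
    terms = []
    consumption = {m.id: 0.0 for m in mets}
    for rxn in net.reactions:
        for direction in (1, -1):
            if direction < 0 and not rxn.reversible:
                continue
            v = flux.forward(rxn) if direction > 0 else flux.backward(rxn)
            if v <= 0:
                continue
            reac_mets = rxn.reactants if direction > 0 else rxn.products
            prod_mets = rxn.products if direction > 0 else rxn.reactants
            for m_id in reac_mets:
                if m_id in consumption:
                    consumption[m_id] += v
            for amap in rxn.atom_maps:
                r_atoms = amap.reactant_atoms if direction > 0 else amap.product_atoms
                p_atoms = amap.product_atoms if direction > 0 else amap.reactant_atoms
                letter_src = {
                    letter: (occ, pos + 1)
                    for occ, atoms in enumerate(r_atoms)
                    for pos, letter in enumerate(atoms)
                }
                for pmet, patoms in zip(prod_mets, p_atoms):
                    if pmet not in consumption:  # sink/source product: not balanced
                        continue
                    by_occ: dict[int, tuple[list[int], list[int]]] = {}
                    for ppos, letter in enumerate(patoms, start=1):
                        occ, spos = letter_src[letter]
                        by_occ.setdefault(occ, ([], []))[0].append(spos)
                        by_occ[occ][1].append(ppos)
                    mapping = []
                    for occ in sorted(by_occ):
                        spos, ppos = by_occ[occ]
                        src_met = reac_mets[occ]
                        src = src_met if src_met in consumption else ("boundary", src_met)
                        mapping.append((src, tuple(spos), tuple(ppos)))
                    rate = amap.weight * v / SECONDS_PER_HOUR
                    terms.append((pmet, rate, mapping))

    def _outer(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        # joint distribution with b's bits appended above a's (column-major)
        return (a[:, None] * b[None, :]).ravel(order="F")

    def product_dist(state: np.ndarray, t: float, mapping) -> np.ndarray:
        dist = np.ones(1)
        placed: list[int] = []
        for src, spos, ppos in mapping:
            if isinstance(src, tuple):  # boundary source: independent atoms,
                e = float(tracer.enrichment(src[1], t))  # any marginal is binomial
                part = _source_isotopomers(len(spos), e)
            else:
                x = state[offsets[src] : offsets[src] + 2 ** n_c[src]]
                tot = x.sum()
                part = _marginal(x / tot if tot > 0 else x, n_c[src], spos)
            dist = _outer(dist, part)
            placed.extend(ppos)
        # dist is indexed by bits in `placed` order; permute to product order
        tensor = dist.reshape((2,) * len(placed), order="F")
        tensor = np.transpose(tensor, axes=list(np.argsort(placed)))
        return tensor.ravel(order="F")

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        for pmet, rate, mapping in terms:
            dist = product_dist(y, t, mapping)
            o = offsets[pmet]
            dy[o : o + dist.size] += (rate / pools[pmet]) * dist
        for m_id in met_ids:
            o = offsets[m_id]
            w = 2 ** n_c[m_id]
            dy[o : o + w] -= (consumption[m_id] / (SECONDS_PER_HOUR * pools[m_id])) * y[
                o : o + w
            ]
        return dy

    y0 = np.zeros(dim)
    for m_id in met_ids:
        y0[offsets[m_id]] = 1.0  # all-12C isotopomer

    T = float(times[-1])
    if T == 0:
        Y = y0[None, :]
    else:
        sol = solve_ivp(
            rhs, (0.0, T), y0, method="BDF", rtol=rtol, atol=atol, t_eval=times
        )
        if not sol.success:
            raise SimulationError(f"oracle integration failed: {sol.message}")
        Y = sol.y.T

    if targets is None:
        targets = [
            EMU(m.id, tuple(range(1, m.n_carbons + 1))) for m in mets
        ]
    mids: dict[EMU, np.ndarray] = {}
    for emu in targets:
        n = n_c[emu.metabolite]
        o = offsets[emu.metabolite]
        res = np.zeros((len(times), emu.size + 1))
        for ti in range(len(times)):
            x = Y[ti, o : o + 2**n]
            tot = x.sum()
            marg = _marginal(x / tot if tot > 0 else x, n, emu.atoms)
            for s in range(marg.size):
                res[ti, bin(s).count("1")] += marg[s]
        res = np.clip(res, 0.0, None)
        res /= res.sum(axis=1, keepdims=True)
        mids[emu] = res
    return MIDTrajectory(np.asarray(times, dtype=float), mids)
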