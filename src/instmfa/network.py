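"""Atom-mapped, compartmented metabolic networks and the admissible flux space.

A network is a set of carbon-balanced reactions with per-carbon atom
transition maps (letter strings, one letter per carbon, 1-based positions
in string order).  Metabolite roles are inferred from topology: a species
that is never produced is a *source* (boundary substrate whose labeling is
imposed by the tracer protocol), one that is never consumed is a *sink*
(biomass or excretion efflux), everything else is *balanced* and subject to
the steady-state constraint ``S . v_net = 0``.

Fluxes are expressed in umol * gDW^-1 * h^-1 throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import linprog

__all__ = [
    "Metabolite",
    "AtomMap",
    "AtomMappedReaction",
    "Network",
    "FluxMap",
    "FluxBasis",
    "NetworkError",
    "parse_network",
    "serialize_network",
    "stoichiometric_matrix",
    "free_flux_parameterization",
    "apply_flux_vector",
    "params_from_flux_map",
]

COMPARTMENTS = {
    "c": "cytosol",
    "p": "chloroplast",
    "m": "mitochondrion",
    "x": "extracellular",
}

#: default net-flux bounds when a row leaves the bounds column empty
DEFAULT_IRREV_BOUNDS = (0.0, 1.0e4)
DEFAULT_REV_BOUNDS = (-1.0e4, 1.0e4)

#: exchange-flux transform cap: x_exch = beta/(1-beta), beta in [0, BETA_MAX]
BETA_MAX = 0.9999


class NetworkError(ValueError):
    """Raised for malformed network definitions or infeasible flux constraints."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str
    n_carbons: int
    role: str = "balanced"  # balanced | source | sink

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS.values():
            raise NetworkError(f"unknown compartment {self.compartment!r} for {self.id}")
        if self.n_carbons < 0:
            raise NetworkError(f"negative carbon count for {self.id}")
        if self.role not in ("balanced", "source", "sink"):
            raise NetworkError(f"unknown role {self.role!r} for {self.id}")


@dataclass(frozen=True)
class AtomMap:
    """One atom-transition alternative for a reaction.

    ``reactant_atoms``/``product_atoms`` hold one letter string per molecule
    occurrence, in the order the occurrences appear in the equation.  Every
    reactant letter must appear exactly once among the products and vice
    versa (carbon conservation).  ``weight`` is the fraction of flux routed
    through this alternative; alternatives of one reaction sum to 1 (used to
    encode molecular symmetry, e.g. succinate/fumarate scrambling).
    """

    reactant_atoms: tuple[str, ...]
    product_atoms: tuple[str, ...]
    weight: float = 1.0

    def validate(self, rxn_id: str) -> None:
        r_letters = "".join(self.reactant_atoms)
        p_letters = "".join(self.product_atoms)
        if sorted(r_letters) != sorted(p_letters):
            raise NetworkError(
                f"reaction {rxn_id}: atom map not carbon-conserving "
                f"({r_letters!r} -> {p_letters!r})"
            )
        for side in (r_letters, p_letters):
            if len(set(side)) != len(side):
                raise NetworkError(f"reaction {rxn_id}: repeated atom letter in {side!r}")
        if not (0.0 < self.weight <= 1.0):
            raise NetworkError(f"reaction {rxn_id}: atom-map weight {self.weight} not in (0,1]")

    def reversed(self) -> "AtomMap":
        return AtomMap(self.product_atoms, self.reactant_atoms, self.weight)


@dataclass(frozen=True)
class AtomMappedReaction:
    """A reaction with occurrence-expanded stoichiometry and atom maps.

    ``reactants``/``products`` list one metabolite id per molecule occurrence
    (a stoichiometric coefficient of 2 appears as two occurrences, each with
    its own atom string in every atom map).
    """

    id: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    atom_maps: tuple[AtomMap, ...]
    reversible: bool = False
    bounds: tuple[float, float] = DEFAULT_IRREV_BOUNDS
    notes: str = ""

    def validate(self, metabolites: Mapping[str, Metabolite]) -> None:
        lo, hi = self.bounds
        if lo > hi:
            raise NetworkError(f"reaction {self.id}: lower bound exceeds upper bound")
        if not self.reversible and lo < 0:
            raise NetworkError(f"reaction {self.id}: irreversible but lower bound < 0")
        if not self.atom_maps:
            raise NetworkError(f"reaction {self.id}: no atom map")
        wsum = sum(m.weight for m in self.atom_maps)
        if abs(wsum - 1.0) > 1e-9:
            raise NetworkError(
                f"reaction {self.id}: atom-map weights sum to {wsum}, expected 1"
            )
        for am in self.atom_maps:
            am.validate(self.id)
            if len(am.reactant_atoms) != len(self.reactants) or len(
                am.product_atoms
            ) != len(self.products):
                raise NetworkError(f"reaction {self.id}: atom map arity mismatch")
            for met_id, atoms in zip(
                self.reactants + self.products, am.reactant_atoms + am.product_atoms
            ):
                met = metabolites[met_id]
                if len(atoms) != met.n_carbons:
                    raise NetworkError(
                        f"reaction {self.id}: atom string {atoms!r} length != "
                        f"{met.n_carbons} carbons of {met_id}"
                    )


@dataclass
class Network:
    metabolites: dict[str, Metabolite]
    reactions: list[AtomMappedReaction]
    #: source metabolite id -> fractional 13C atom enrichment as a function of
    #: time (seconds); used by the tracer protocol as a boundary condition
    tracer_inputs: dict[str, Callable[[float], float]] = field(default_factory=dict)

    def reaction(self, rxn_id: str) -> AtomMappedReaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def balanced_metabolites(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if m.role == "balanced"]

    def validate(self) -> None:
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkError(f"duplicate reaction id(s): {dup}")
        for r in self.reactions:
            r.validate(self.metabolites)
        produced: set[str] = set()
        consumed: set[str] = set()
        for r in self.reactions:
            consumed.update(r.reactants)
            produced.update(r.products)
            if r.reversible:
                consumed.update(r.products)
                produced.update(r.reactants)
        for m in self.metabolites.values():
            if m.role == "balanced":
                if m.id not in produced or m.id not in consumed:
                    raise NetworkError(
                        f"balanced metabolite {m.id} lacks a producing or consuming reaction"
                    )
        for src in self.tracer_inputs:
            if src not in self.metabolites:
                raise NetworkError(f"tracer input on unknown metabolite {src}")
            if self.metabolites[src].role != "source":
                raise NetworkError(f"tracer input on non-source metabolite {src}")


@dataclass
class FluxMap:
    """Net fluxes per reaction and exchange fluxes per reversible reaction."""

    net: dict[str, float]
    exchange: dict[str, float] = field(default_factory=dict)

    def forward(self, rxn: AtomMappedReaction) -> float:
        v = self.net[rxn.id]
        e = self.exchange.get(rxn.id, 0.0) if rxn.reversible else 0.0
        return max(v, 0.0) + e

    def backward(self, rxn: AtomMappedReaction) -> float:
        if not rxn.reversible:
            return 0.0
        v = self.net[rxn.id]
        return max(-v, 0.0) + self.exchange.get(rxn.id, 0.0)

    def scaled(self, factor: float) -> "FluxMap":
        return FluxMap(
            {k: v * factor for k, v in self.net.items()},
            {k: v * factor for k, v in self.exchange.items()},
        )


# ---------------------------------------------------------------------------
# parsing / serialization
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(
    r"^\s*(?:(\d+)\s+)?([A-Za-z0-9_]+)\.([a-z]+)\s*(?:\(([a-zA-Z]*)\))?\s*$"
)


def _parse_side(side: str, rxn_id: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    mets: list[str] = []
    atoms: list[str] = []
    for term in side.split("+"):
        m = _TERM_RE.match(term)
        if not m:
            raise NetworkError(f"reaction {rxn_id}: cannot parse term {term.strip()!r}")
        coef_s, name, cmpt, atom_s = m.groups()
        coef = int(coef_s) if coef_s else 1
        atom_s = atom_s or ""
        if coef != 1 and atom_s:
            raise NetworkError(
                f"reaction {rxn_id}: coefficient {coef} on carbon-bearing {name}.{cmpt}; "
                "repeat the term once per occurrence with its own atom string"
            )
        if cmpt not in COMPARTMENTS:
            raise NetworkError(f"reaction {rxn_id}: unknown compartment suffix {cmpt!r}")
        for _ in range(coef):
            mets.append(f"{name}.{cmpt}")
            atoms.append(atom_s)
    return tuple(mets), tuple(atoms)


def parse_network(text: str) -> Network:
    """Parse the pipe-delimited network dialect into a validated :class:`Network`.

    Columns: ``id | equation | reversibility | bounds | notes``.  Alternative
    atom maps are additional rows sharing the ``id`` with ``weight=`` in the
    notes column.  Blank lines and lines starting with ``#`` are ignored.
    """
    rxns: dict[str, dict] = {}
    order: list[str] = []
    met_carbons: dict[str, int] = {}
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = [c.strip() for c in line.split("|")]
        if len(cols) < 3:
            raise NetworkError(f"row has fewer than 3 columns: {line!r}")
        cols += [""] * (5 - len(cols))
        rxn_id, equation, rev_s, bounds_s, notes = cols[:5]
        if "->" not in equation:
            raise NetworkError(f"reaction {rxn_id}: missing '->' in equation")
        lhs, rhs = equation.split("->", 1)
        reactants, r_atoms = _parse_side(lhs, rxn_id)
        products, p_atoms = _parse_side(rhs, rxn_id)
        weight = 1.0
        wm = re.search(r"weight\s*=\s*([0-9.eE+-]+)", notes)
        if wm:
            weight = float(wm.group(1))
        amap = AtomMap(r_atoms, p_atoms, weight)
        if rxn_id in rxns:
            # continuation row: an alternative atom map for the same reaction
            entry = rxns[rxn_id]
            if not wm and not re.search(r"weight\s*=", entry["notes"] or ""):
                raise NetworkError(f"duplicate reaction id(s): ['{rxn_id}']")
            if (reactants, products) != (entry["reactants"], entry["products"]):
                raise NetworkError(
                    f"reaction {rxn_id}: alternative map row changes the equation"
                )
            entry["atom_maps"].append(amap)
            continue
        if rev_s not in ("rev", "irrev"):
            raise NetworkError(f"reaction {rxn_id}: reversibility must be rev|irrev")
        reversible = rev_s == "rev"
        if bounds_s:
            try:
                lo_s, hi_s = bounds_s.split(",")
                bounds = (float(lo_s), float(hi_s))
            except ValueError as exc:
                raise NetworkError(f"reaction {rxn_id}: bad bounds {bounds_s!r}") from exc
        else:
            bounds = DEFAULT_REV_BOUNDS if reversible else DEFAULT_IRREV_BOUNDS
        rxns[rxn_id] = dict(
            reactants=reactants,
            products=products,
            atom_maps=[amap],
            reversible=reversible,
            bounds=bounds,
            notes=notes,
        )
        order.append(rxn_id)
        for met_id, atoms in zip(reactants + products, r_atoms + p_atoms):
            n = len(atoms)
            if met_id in met_carbons and met_carbons[met_id] != n:
                raise NetworkError(
                    f"metabolite {met_id}: inconsistent carbon count "
                    f"({met_carbons[met_id]} vs {n})"
                )
            met_carbons.setdefault(met_id, n)

    reactions = [AtomMappedReaction(id=i, atom_maps=tuple(rxns[i].pop("atom_maps")), **rxns[i]) for i in order]
    produced: set[str] = set()
    consumed: set[str] = set()
    for r in reactions:
        consumed.update(r.reactants)
        produced.update(r.products)
        if r.reversible:
            consumed.update(r.products)
            produced.update(r.reactants)
    metabolites: dict[str, Metabolite] = {}
    for met_id, n in met_carbons.items():
        cmpt = COMPARTMENTS[met_id.rsplit(".", 1)[1]]
        if met_id not in produced:
            role = "source"
        elif met_id not in consumed:
            role = "sink"
        else:
            role = "balanced"
        metabolites[met_id] = Metabolite(met_id, cmpt, n, role)
    net = Network(metabolites, reactions)
    net.validate()
    return net


def serialize_network(net: Network) -> str:
    """Write the pipe-delimited dialect; ``parse_network`` round-trips it."""
    lines = []
    for r in net.reactions:
        for k, am in enumerate(r.atom_maps):
            lhs = " + ".join(
                f"{m} ({a})" for m, a in zip(r.reactants, am.reactant_atoms)
            )
            rhs = " + ".join(
                f"{m} ({a})" for m, a in zip(r.products, am.product_atoms)
            )
            rev = "rev" if r.reversible else "irrev"
            bounds = f"{r.bounds[0]:g},{r.bounds[1]:g}"
            if len(r.atom_maps) > 1:
                notes = f"weight={am.weight:g}"
            elif k == 0:
                notes = r.notes
            lines.append(f"{r.id} | {lhs} -> {rhs} | {rev} | {bounds} | {notes}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# stoichiometry and flux-space parameterization
# ---------------------------------------------------------------------------


def stoichiometric_matrix(net: Network) -> tuple[np.ndarray, list[str], list[str]]:
    """Net stoichiometric matrix over balanced metabolites.

    Returns ``(S, met_ids, rxn_ids)`` with ``S[i, j]`` the net coefficient of
    balanced metabolite ``i`` in reaction ``j`` (source/sink rows excluded).
    """
    mets = net.balanced_metabolites()
    rxn_ids = net.reaction_ids
    idx = {m: i for i, m in enumerate(mets)}
    S = np.zeros((len(mets), len(rxn_ids)))
    for j, r in enumerate(net.reactions):
        for m in r.reactants:
            if m in idx:
                S[idx[m], j] -= 1.0
        for m in r.products:
            if m in idx:
                S[idx[m], j] += 1.0
    return S, mets, rxn_ids


@dataclass
class FluxBasis:
    """Affine parameterization of the steady-state flux polytope.

    Net fluxes: ``v = v0 + N @ theta`` with ``N`` an orthonormal null-space
    basis of the stacked constraints (steady state plus fixed fluxes), so the
    map ``theta -> v -> theta`` is the identity.  Exchange fluxes of
    reversible reactions are separate parameters on [0, inf), handled through
    the bounded transform ``x = beta / (1 - beta)`` with ``beta`` in
    ``[0, BETA_MAX]``.
    """

    network: Network
    v0: np.ndarray
    N: np.ndarray
    rxn_ids: list[str]
    exchange_ids: list[str]
    fixed: dict[str, float]
    #: per-free-net-parameter [lo, hi] box (tightest axis-aligned box around
    #: the bounded polytope, found by linear programming)
    theta_bounds: np.ndarray

    @property
    def n_free_net(self) -> int:
        return self.N.shape[1]

    @property
    def n_params(self) -> int:
        return self.n_free_net + len(self.exchange_ids)


def free_flux_parameterization(
    net: Network, fixed: Mapping[str, float] | None = None
) -> FluxBasis:
    """Parameterize the admissible flux space given fixed flux assignments."""
    fixed = dict(fixed or {})
    S, _, rxn_ids = stoichiometric_matrix(net)
    n = len(rxn_ids)
    rows = [S]
    rhs = [np.zeros(S.shape[0])]
    for rid, val in fixed.items():
        row = np.zeros(n)
        row[rxn_ids.index(rid)] = 1.0
        rows.append(row[None, :])
        rhs.append(np.array([val]))
    A = np.vstack(rows)
    b = np.concatenate(rhs)
    v0, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = A @ v0 - b
    if np.max(np.abs(resid)) > 1e-6 * max(1.0, np.max(np.abs(b)) if b.size else 1.0):
        raise NetworkError("fixed fluxes are inconsistent with steady state (no solution)")
    N = null_space(A)
    lb = np.array([r.bounds[0] for r in net.reactions])
    ub = np.array([r.bounds[1] for r in net.reactions])
    if np.any(v0 < lb - 1e-6) or np.any(v0 > ub + 1e-6):
        # shift the particular solution into the bounded polytope if possible
        v0 = _feasible_point(v0, N, lb, ub)
    k = N.shape[1]
    theta_bounds = np.zeros((k, 2))
    for i in range(k):
        for sgn, col in ((1.0, 0), (-1.0, 1)):
            c = sgn * np.eye(k)[i]
            res = linprog(
                c,
                A_ub=np.vstack([N, -N]),
                b_ub=np.concatenate([ub - v0, v0 - lb]),
                bounds=[(None, None)] * k,
                method="highs",
            )
            if res.status == 3:  # unbounded direction
                theta_bounds[i, col] = sgn * -1e6
            elif not res.success:
                raise NetworkError("network has zero admissible flux space")
            else:
                theta_bounds[i, col] = sgn * res.fun
    theta_bounds = np.sort(theta_bounds, axis=1)
    exch = [r.id for r in net.reactions if r.reversible]
    return FluxBasis(net, v0, N, rxn_ids, exch, fixed, theta_bounds)


def _feasible_point(v0: np.ndarray, N: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    """Project the particular solution toward the bounded polytope (Chebyshev-ish)."""
    k = N.shape[1]
    if k == 0:
        return v0
    # minimize sum of bound violations via LP on (theta, slack)
    n = len(v0)
    c = np.concatenate([np.zeros(k), np.ones(2 * n)])
    A_ub = np.block(
        [
            [N, -np.eye(n), np.zeros((n, n))],
            [-N, np.zeros((n, n)), -np.eye(n)],
        ]
    )
    b_ub = np.concatenate([ub - v0, v0 - lb])
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=[(None, None)] * k + [(0, None)] * (2 * n),
        method="highs",
    )
    if res.success and res.fun < 1e-6:
        return v0 + N @ res.x[:k]
    return v0


def beta_to_exchange(beta: float) -> float:
    beta = min(max(beta, 0.0), BETA_MAX)
    return beta / (1.0 - beta)


def exchange_to_beta(x: float) -> float:
    if x < 0:
        raise NetworkError("exchange flux must be >= 0")
    return min(x / (1.0 + x), BETA_MAX)


def apply_flux_vector(
    basis: FluxBasis, params: Sequence[float], check_bounds: bool = True, tol: float = 1e-9
) -> FluxMap:
    """Map a free-parameter vector (net thetas then exchange betas) to a FluxMap."""
    params = np.asarray(params, dtype=float)
    k = basis.n_free_net
    if params.size != basis.n_params:
        raise NetworkError(
            f"expected {basis.n_params} parameters, got {params.size}"
        )
    v = basis.v0 + basis.N @ params[:k]
    if check_bounds:
        for rid, val, r in zip(basis.rxn_ids, v, basis.network.reactions):
            lo, hi = r.bounds
            if val < lo - tol or val > hi + tol:
                raise NetworkError(
                    f"flux bound violated for reaction {rid}: {val:.6g} outside [{lo:g}, {hi:g}]"
                )
    net = {rid: float(val) for rid, val in zip(basis.rxn_ids, v)}
    exchange = {
        rid: beta_to_exchange(float(b))
        for rid, b in zip(basis.exchange_ids, params[k:])
    }
    return FluxMap(net, exchange)


def params_from_flux_map(basis: FluxBasis, fm: FluxMap) -> np.ndarray:
    """Inverse of :func:`apply_flux_vector` (identity round trip on the polytope)."""
    v = np.array([fm.net[rid] for rid in basis.rxn_ids])
    theta = basis.N.T @ (v - basis.v0)
    betas = [exchange_to_beta(fm.exchange.get(rid, 0.0)) for rid in basis.exchange_ids]
    return np.concatenate([theta, betas])


def merge_metabolites(net: Network, mapping: Mapping[str, str]) -> Network:
    """Merge duplicated display pools into single modeled pools.

    ``mapping`` sends alias metabolite ids to their canonical id (e.g.
    compartmented duplicates drawn twice on a flux map but representing one
    pool in the model).  Atom maps are unaffected; carbon counts must match.
    """
    for alias, target in mapping.items():
        if net.metabolites[alias].n_carbons != net.metabolites[target].n_carbons:
            raise NetworkError(f"cannot merge {alias} into {target}: carbon counts differ")

    def rename(ids: tuple[str, ...]) -> tuple[str, ...]:
        return tuple(mapping.get(m, m) for m in ids)

    reactions = [
        AtomMappedReaction(
            r.id, rename(r.reactants), rename(r.products), r.atom_maps,
            r.reversible, r.bounds, r.notes,
        )
        for r in net.reactions
    ]
    produced: set[str] = set()
    consumed: set[str] = set()
    for r in reactions:
        consumed.update(r.reactants)
        produced.update(r.products)
        if r.reversible:
            consumed.update(r.products)
            produced.update(r.reactants)
    metabolites = {}
    for m in net.metabolites.values():
        if m.id in mapping:
            continue
        role = m.role
        if m.id in produced and m.id in consumed:
            role = "balanced"
        metabolites[m.id] = Metabolite(m.id, m.compartment, m.n_carbons, role)
    merged = Network(metabolites, reactions, dict(net.tracer_inputs))
    merged.validate()
    return merged


def steady_state_residual(net: Network, fm: FluxMap) -> float:
    """Max-norm of S . v_net over balanced metabolites (diagnostic)."""
    S, _, rxn_ids = stoichiometric_matrix(net)
    v = np.array([fm.net[r] for r in rxn_ids])
    if S.size == 0:
        return 0.0
    return float(np.max(np.abs(S @ v)))
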