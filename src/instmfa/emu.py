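"""Elementary metabolite unit (EMU) decomposition.

An EMU is a subset of one metabolite's carbon atoms.  The mass isotopomer
distribution (MID) of any EMU can be balanced using only EMUs of equal or
smaller size, which turns the exponentially large isotopomer balance into a
cascade of small linear systems, solved stratum by stratum (size 1, 2, ...).

``decompose`` traces the measured target fragments backward through every
atom map (both directions for reversible reactions) and returns the minimal
closed EMU network.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .network import AtomMappedReaction, Network, NetworkError

__all__ = ["EMU", "EMUReaction", "EMUNetwork", "decompose", "convolve_mids"]


@dataclass(frozen=True, order=True)
class EMU:
    metabolite: str
    atoms: tuple[int, ...]  # sorted, 1-based carbon indices

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(sorted(self.atoms)))

    @property
    def size(self) -> int:
        return len(self.atoms)

    def __str__(self) -> str:  # e.g. "SUC.m{1,2}"
        return f"{self.metabolite}{{{','.join(map(str, self.atoms))}}}"


@dataclass(frozen=True)
class EMUReaction:
    """One production route for ``product``: flux ``(rxn_id, direction)``
    carrying the (possibly condensed) reactant EMUs, scaled by the atom-map
    ``weight``.  ``direction`` is ``+1`` (forward) or ``-1`` (backward)."""

    product: EMU
    reactants: tuple[EMU, ...]
    rxn_id: str
    direction: int
    weight: float

    def __post_init__(self) -> None:
        if sum(e.size for e in self.reactants) != self.product.size:
            raise NetworkError(
                f"EMU reaction size mismatch for {self.product}: "
                f"{[str(e) for e in self.reactants]}"
            )


@dataclass
class EMUNetwork:
    network: Network
    targets: tuple[EMU, ...]
    emus: list[EMU]  # state EMUs (balanced metabolites), stratified by size
    boundary: list[EMU]  # EMUs on source metabolites (tracer boundary)
    reactions: list[EMUReaction]

    def strata(self) -> dict[int, list[EMU]]:
        out: dict[int, list[EMU]] = {}
        for e in self.emus:
            out.setdefault(e.size, []).append(e)
        return {k: sorted(v) for k, v in sorted(out.items())}

    def producing(self, emu: EMU) -> list[EMUReaction]:
        return [r for r in self.reactions if r.product == emu]

    def export_table(self) -> str:
        """Tabular adjacency listing for inspection / golden-file tests."""
        lines = ["product\treactants\tflux\tdirection\tweight"]
        key = lambda r: (r.product.size, str(r.product), r.rxn_id, r.direction, str(r.reactants))
        for r in sorted(self.reactions, key=key):
            reac = " + ".join(str(e) for e in r.reactants)
            d = "fwd" if r.direction > 0 else "bwd"
            lines.append(f"{r.product}\t{reac}\t{r.rxn_id}\t{d}\t{r.weight:g}")
        return "\n".join(lines) + "\n"


def _directions(rxn: AtomMappedReaction):
    yield 1, rxn.reactants, rxn.products, rxn.atom_maps
    if rxn.reversible:
        yield -1, rxn.products, rxn.reactants, tuple(m.reversed() for m in rxn.atom_maps)


def decompose(net: Network, targets: Iterable[EMU]) -> EMUNetwork:
    """Backward-trace ``targets`` to the minimal closed EMU network."""
    targets = tuple(targets)
    for t in targets:
        if t.metabolite not in net.metabolites:
            raise NetworkError(f"target on unknown metabolite {t.metabolite}")
        met = net.metabolites[t.metabolite]
        if met.n_carbons == 0:
            raise NetworkError(f"target on carbon-free metabolite {t.metabolite}")
        if not t.atoms or min(t.atoms) < 1 or max(t.atoms) > met.n_carbons:
            raise NetworkError(f"target atoms out of range for {t}")

    state: set[EMU] = set()
    boundary: set[EMU] = set()
    reactions: list[EMUReaction] = []
    queue: deque[EMU] = deque()

    def enqueue(e: EMU) -> None:
        role = net.metabolites[e.metabolite].role
        if role == "source":
            boundary.add(e)
        elif e not in state:
            state.add(e)
            queue.append(e)

    for t in targets:
        enqueue(t)

    while queue:
        emu = queue.popleft()
        produced = False
        for rxn in net.reactions:
            for direction, reac_mets, prod_mets, maps in _directions(rxn):
                for amap in maps:
                    r_atoms = amap.reactant_atoms
                    p_atoms = amap.product_atoms
                    # letter -> (reactant occurrence, 1-based atom position)
                    letter_src = {
                        letter: (occ, pos + 1)
                        for occ, atoms in enumerate(r_atoms)
                        for pos, letter in enumerate(atoms)
                    }
                    for occ, (pmet, patoms) in enumerate(zip(prod_mets, p_atoms)):
                        if pmet != emu.metabolite:
                            continue
                        by_reactant: dict[int, list[int]] = {}
                        for a in emu.atoms:
                            src_occ, src_pos = letter_src[patoms[a - 1]]
                            by_reactant.setdefault(src_occ, []).append(src_pos)
                        reac_emus = tuple(
                            EMU(reac_mets[src_occ], tuple(sorted(pos_list)))
                            for src_occ, pos_list in sorted(by_reactant.items())
                        )
                        er = EMUReaction(emu, reac_emus, rxn.id, direction, amap.weight)
                        reactions.append(er)
                        produced = True
                        for re_ in reac_emus:
                            enqueue(re_)
        if not produced:
            raise NetworkError(f"EMU {emu} has no producing reaction (unreachable)")

    emus = sorted(state, key=lambda e: (e.size, e.metabolite, e.atoms))
    return EMUNetwork(net, targets, emus, sorted(boundary), reactions)


def convolve_mids(a: Sequence[float], b: Sequence[float]) -> np.ndarray:
    """Condensation rule: the MID of a joined EMU is the convolution of parts.

    Both inputs must be valid MIDs (nonnegative, summing to 1 within 1e-9);
    the output has length ``len(a) + len(b) - 1`` and sums to 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("MID entries must be nonnegative")
    for v in (a, b):
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"MID does not sum to 1 (sum={v.sum()!r})")
    return np.convolve(a, b)
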