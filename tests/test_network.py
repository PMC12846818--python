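"""Atom-mapped network parsing, stoichiometry, and flux-space parameterization."""

import numpy as np
import pytest

from instmfa.network import (
    FluxMap,
    NetworkError,
    apply_flux_vector,
    free_flux_parameterization,
    params_from_flux_map,
    parse_network,
    serialize_network,
    steady_state_residual,
    stoichiometric_matrix,
)

ICL_ROW = "ICL | ICIT.m (abcdef) -> SUC.m (abcd) + GLX.m (ef) | irrev | |"
CHAIN = """
v1 | A.x (a) -> B.c (a) | irrev | |
v2 | B.c (a) -> C.x (a) | irrev | |
"""
DIAMOND = """
vin | S.x (a) -> A.c (a) | irrev | |
vb  | A.c (a) -> B.c (a) | irrev | |
vc  | A.c (a) -> C.c (a) | irrev | |
vbd | B.c (a) -> D.c (a) | irrev | |
vcd | C.c (a) -> D.c (a) | irrev | |
vout| D.c (a) -> P.x (a) | irrev | |
"""


def _nullity_by_elimination(S):
    """Independent Gaussian-elimination rank oracle."""
    A = np.array(S, dtype=float)
    rank = 0
    rows, cols = A.shape
    for c in range(cols):
        piv = None
        for r in range(rank, rows):
            if abs(A[r, c]) > 1e-10:
                piv = r
                break
        if piv is None:
            continue
        A[[rank, piv]] = A[[piv, rank]]
        A[rank] = A[rank] / A[rank, c]
        for r in range(rows):
            if r != rank and abs(A[r, c]) > 1e-12:
                A[r] -= A[r, c] * A[rank]
        rank += 1
    return cols - rank


class TestParsing:
    def test_isocitrate_lyase_row_carbon_bookkeeping(self):
        net = parse_network(ICL_ROW)
        assert len(net.reactions) == 1
        assert len(net.metabolites) == 3
        carbons = {m.id: m.n_carbons for m in net.metabolites.values()}
        assert carbons == {"ICIT.m": 6, "SUC.m": 4, "GLX.m": 2}

    def test_unassigned_atom_rejected(self):
        with pytest.raises(NetworkError, match="conserving"):
            parse_network("r1 | A.c (abc) -> B.c (ab) | irrev | |")

    def test_alternative_map_weights(self):
        ok = """
s | A.c (ab) -> B.c (ab) | irrev | | weight=0.5
s | A.c (ab) -> B.c (ba) | irrev | | weight=0.5
x | X.x (ab) -> A.c (ab) | irrev | |
y | B.c (ab) -> Y.x (ab) | irrev | |
"""
        net = parse_network(ok)
        assert len(net.reaction("s").atom_maps) == 2
        bad = ok.replace("weight=0.5", "weight=0.6")
        with pytest.raises(NetworkError, match="weights sum"):
            parse_network(bad)

    def test_duplicate_reaction_id(self):
        text = "r | A.x (a) -> B.c (a) | irrev | |\nr | A.x (a) -> B.c (a) | irrev | |\n"
        with pytest.raises(NetworkError, match="duplicate"):
            parse_network(text + "s | B.c (a) -> C.x (a) | irrev | |")

    def test_unknown_compartment(self):
        with pytest.raises(NetworkError, match="compartment"):
            parse_network("r | A.q (a) -> B.c (a) | irrev | |")

    def test_inconsistent_carbon_count(self):
        text = """
r1 | A.x (ab) -> B.c (ab) | irrev | |
r2 | B.c (abc) -> C.x (abc) | irrev | |
"""
        with pytest.raises(NetworkError, match="carbon count"):
            parse_network(text)

    def test_roles_inferred_from_topology(self):
        net = parse_network(CHAIN)
        roles = {m.id: m.role for m in net.metabolites.values()}
        assert roles == {"A.x": "source", "B.c": "balanced", "C.x": "sink"}

    def test_roundtrip_is_stable(self, toy, mini_mixo):
        for net in (toy.network, mini_mixo.network):
            text1 = serialize_network(net)
            net2 = parse_network(text1)
            assert serialize_network(net2) == text1
            assert net2.reaction_ids == net.reaction_ids
            assert {m.id for m in net2.metabolites.values()} == {
                m.id for m in net.metabolites.values()
            }


class TestStoichiometry:
    def test_linear_chain_row(self):
        S, mets, rxns = stoichiometric_matrix(parse_network(CHAIN))
        assert mets == ["B.c"]
        assert S.tolist() == [[1.0, -1.0]]

    def test_icl_column(self, toy):
        S, mets, rxns = stoichiometric_matrix(toy.network)
        j = rxns.index("ICL")
        col = {m: S[i, j] for i, m in enumerate(mets) if S[i, j] != 0}
        assert col == {"CIT.m": -1.0, "SUC.m": 1.0, "GLX.m": 1.0}

    def test_nullity_matches_elimination_oracle(self, toy):
        for text, n_fixed in ((DIAMOND, 1), (None, 0)):
            net = parse_network(text) if text else toy.network
            S, _, rxns = stoichiometric_matrix(net)
            basis = free_flux_parameterization(net)
            assert basis.n_free_net == _nullity_by_elimination(S)


class TestFluxBasis:
    def test_chain_fully_determined(self):
        net = parse_network(CHAIN)
        basis = free_flux_parameterization(net, fixed={"v1": 10.0})
        assert basis.n_free_net == 0
        fm = apply_flux_vector(basis, [])
        assert fm.net == pytest.approx({"v1": 10.0, "v2": 10.0})

    def test_diamond_one_free_branch_split(self):
        net = parse_network(DIAMOND)
        basis = free_flux_parameterization(net, fixed={"vin": 10.0})
        assert basis.n_free_net == 1
        target = FluxMap(dict(vin=10.0, vb=3.0, vc=7.0, vbd=3.0, vcd=7.0, vout=10.0))
        params = params_from_flux_map(basis, target)
        fm = apply_flux_vector(basis, params)
        assert fm.net["vb"] == pytest.approx(3.0, abs=1e-9)
        assert fm.net["vc"] == pytest.approx(7.0, abs=1e-9)
        assert steady_state_residual(net, fm) < 1e-10

    def test_random_params_satisfy_steady_state(self):
        net = parse_network(DIAMOND)
        basis = free_flux_parameterization(net, fixed={"vin": 10.0})
        rng = np.random.default_rng(0)
        for _ in range(20):
            theta = rng.uniform(basis.theta_bounds[:, 0], basis.theta_bounds[:, 1])
            fm = apply_flux_vector(basis, theta, check_bounds=False)
            assert steady_state_residual(net, fm) < 1e-10

    def test_roundtrip_params_identity(self, toy):
        basis = free_flux_parameterization(toy.network, fixed=toy.fit_fixed)
        p = params_from_flux_map(basis, toy.flux_map)
        fm = apply_flux_vector(basis, p)
        for r in toy.network.reaction_ids:
            assert fm.net[r] == pytest.approx(toy.flux_map.net[r], abs=1e-8)
        p2 = params_from_flux_map(basis, fm)
        assert np.allclose(p, p2, atol=1e-10)

    def test_bound_violation_names_reaction(self):
        net = parse_network(DIAMOND)
        basis = free_flux_parameterization(net, fixed={"vin": 10.0})
        theta_bad = basis.theta_bounds[:, 1] + 5.0
        with pytest.raises(NetworkError, match="v[bc]"):
            apply_flux_vector(basis, theta_bad)

    def test_inconsistent_fixed_fluxes(self):
        net = parse_network(CHAIN)
        with pytest.raises(NetworkError, match="inconsistent"):
            free_flux_parameterization(net, fixed={"v1": 10.0, "v2": 3.0})

    def test_ground_truth_satisfies_bounds_and_balance(self, toy, mini_auto, mini_mixo):
        for fx in (toy, mini_auto, mini_mixo):
            scale = max(abs(v) for v in fx.flux_map.net.values())
            assert steady_state_residual(fx.network, fx.flux_map) < 1e-8 * scale


class TestMergeMetabolites:
    def test_display_duplicates_collapse_to_one_pool(self):
        from instmfa.network import merge_metabolites

        text = """
v1 | A.x (a) -> P.c (a) | irrev | |
v2 | P.c (a) -> B.x (a) | irrev | |
v3 | A.x (a) -> P2.c (a) | irrev | |
v4 | P2.c (a) -> C.x (a) | irrev | |
"""
        net = parse_network(text)
        merged = merge_metabolites(net, {"P2.c": "P.c"})
        assert "P2.c" not in merged.metabolites
        assert merged.reaction("v3").products == ("P.c",)
        S, mets, _ = stoichiometric_matrix(merged)
        assert mets == ["P.c"]
        assert S.tolist() == [[1.0, -1.0, 1.0, -1.0]]

    def test_carbon_mismatch_rejected(self):
        from instmfa.network import merge_metabolites

        text = """
v1 | A.x (a) -> P.c (a) | irrev | |
v2 | P.c (a) -> B.x (a) | irrev | |
v3 | A2.x (ab) -> Q.c (ab) | irrev | |
v4 | Q.c (ab) -> C.x (ab) | irrev | |
"""
        net = parse_network(text)
        with pytest.raises(NetworkError, match="carbon counts"):
            merge_metabolites(net, {"Q.c": "P.c"})
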