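"""Transient labeling simulation: closed forms, invariants, oracle agreement."""

import numpy as np
import pytest

from instmfa.emu import EMU, decompose
from instmfa.fixtures import make_fixture, succinate_cap_fixture
from instmfa.network import FluxMap, parse_network
from instmfa.oracle import isotopomer_oracle
from instmfa.simulate import (
    DEFAULT_SAMPLING_TIMES,
    SimulationError,
    TracerProtocol,
    positional_enrichment,
    simulate_isotopic_steady_state,
    simulate_transient,
)

SINGLE_POOL = """
vin  | S.x (a) -> B.c (a) | irrev | |
vout | B.c (a) -> P.x (a) | irrev | |
"""


def _single_pool_setup(v=10.0, c=5.0, e=0.5):
    net = parse_network(SINGLE_POOL)
    emunet = decompose(net, [EMU("B.c", (1,))])
    fm = FluxMap(dict(vin=v, vout=v))
    tracer = TracerProtocol.step("S.x", post=e)
    return net, emunet, fm, {"B.c": c}, tracer


class TestClosedForms:
    def test_single_pool_washout(self):
        # enrichment(t) = e*(1 - exp(-(v/c) t)), t in hours here (v, c units)
        net, emunet, fm, pools, tracer = _single_pool_setup()
        times = (0.0, 60.0, 300.0, 900.0, 3600.0, 18000.0)
        traj = simulate_transient(emunet, fm, pools, tracer, times, rtol=1e-10, atol=1e-12)
        enr = traj.mids[EMU("B.c", (1,))][:, 1]
        t_h = np.asarray(times) / 3600.0
        expected = 0.5 * (1.0 - np.exp(-(10.0 / 5.0) * t_h))
        assert np.max(np.abs(enr - expected)) < 1e-8

    def test_t0_state_is_unlabeled(self, toy):
        em = decompose(toy.network, toy.target_emus())
        traj = simulate_transient(em, toy.flux_map, toy.pools, toy.tracer, (0.0, 30.0))
        for e, m in traj.mids.items():
            assert m[0, 0] == pytest.approx(1.0, abs=1e-12)
            assert np.all(m[0, 1:] < 1e-12)

    def test_steady_state_matches_long_transient(self):
        net, emunet, fm, pools, tracer = _single_pool_setup()
        ss = simulate_isotopic_steady_state(emunet, fm, None, tracer)
        assert ss[EMU("B.c", (1,))][1] == pytest.approx(0.5, abs=1e-12)

    def test_steady_state_matches_toy_transient_limit(self, toy):
        em = decompose(toy.network, toy.target_emus())
        ss = simulate_isotopic_steady_state(em, toy.flux_map, None, toy.tracer)
        traj = simulate_transient(
            em, toy.flux_map, toy.pools, toy.tracer, (0.0, 40000.0), rtol=1e-10, atol=1e-12
        )
        for e in em.emus:
            assert np.max(np.abs(ss[e] - traj.mids[e][-1])) < 1e-6

    def test_linear_chain_shares_steady_state(self):
        net = parse_network(
            """
v1 | A.x (a) -> B.c (a) | irrev | |
v2 | B.c (a) -> C.c (a) | irrev | |
v3 | C.c (a) -> D.x (a) | irrev | |
"""
        )
        em = decompose(net, [EMU("B.c", (1,)), EMU("C.c", (1,))])
        ss = simulate_isotopic_steady_state(
            em, FluxMap(dict(v1=5, v2=5, v3=5)), None, TracerProtocol.step("A.x", post=0.8)
        )
        assert np.allclose(ss[EMU("B.c", (1,))], ss[EMU("C.c", (1,))], atol=1e-12)


class TestInvariants:
    @pytest.mark.parametrize("method", ["bdf", "fast"])
    def test_mids_sum_to_one(self, toy, method):
        em = decompose(toy.network, toy.target_emus())
        traj = simulate_transient(
            em, toy.flux_map, toy.pools, toy.tracer, DEFAULT_SAMPLING_TIMES, method=method
        )
        for e, m in traj.mids.items():
            assert np.all(m >= 0)
            assert np.max(np.abs(m.sum(axis=1) - 1.0)) < 1e-9

    def test_monotone_enrichment_on_acyclic_chain(self):
        fx = make_fixture("linear3")
        em = decompose(fx.network, fx.target_emus())
        traj = simulate_transient(em, fx.flux_map, fx.pools, fx.tracer, DEFAULT_SAMPLING_TIMES)
        for e in em.emus:
            enr = traj.enrichment(e)
            assert np.all(np.diff(enr) > -1e-10)

    def test_timescale_invariance(self, toy):
        em = decompose(toy.network, toy.target_emus())
        t1 = simulate_transient(em, toy.flux_map, toy.pools, toy.tracer, DEFAULT_SAMPLING_TIMES)
        fm2 = toy.flux_map.scaled(2.0)
        pools2 = {k: 2 * v for k, v in toy.pools.items()}
        t2 = simulate_transient(em, fm2, pools2, toy.tracer, DEFAULT_SAMPLING_TIMES)
        for e in em.emus:
            assert np.max(np.abs(t1.mids[e] - t2.mids[e])) < 1e-7

    def test_succinate_capped_at_m2(self):
        fx = succinate_cap_fixture()
        em = decompose(fx.network, fx.target_emus())
        traj = simulate_transient(
            em, fx.flux_map, fx.pools, fx.tracer, DEFAULT_SAMPLING_TIMES, rtol=1e-10, atol=1e-12
        )
        suc = traj.mids[EMU("SUC.m", (1, 2, 3, 4))]
        assert suc[:, 3:].max() < 1e-9

    def test_fast_path_tracks_stiff_reference(self, mini_mixo):
        em = decompose(mini_mixo.network, mini_mixo.target_emus())
        ref = simulate_transient(
            em, mini_mixo.flux_map, mini_mixo.pools, mini_mixo.tracer, DEFAULT_SAMPLING_TIMES
        )
        fast = simulate_transient(
            em, mini_mixo.flux_map, mini_mixo.pools, mini_mixo.tracer,
            DEFAULT_SAMPLING_TIMES, method="fast",
        )
        dev = max(np.max(np.abs(ref.mids[e] - fast.mids[e])) for e in em.emus)
        assert dev < 5e-3

    def test_errors(self, toy):
        em = decompose(toy.network, toy.target_emus())
        bad_pools = dict(toy.pools, **{"CIT.m": 0.0})
        with pytest.raises(SimulationError, match="pool"):
            simulate_transient(em, toy.flux_map, bad_pools, toy.tracer, (0.0, 10.0))
        with pytest.raises(SimulationError, match="times"):
            simulate_transient(em, toy.flux_map, toy.pools, toy.tracer, (30.0, 10.0))


class TestOracleEquivalence:
    def test_single_pool_oracle_identity(self):
        net, emunet, fm, pools, tracer = _single_pool_setup()
        times = (0.0, 100.0, 1000.0)
        traj = simulate_transient(emunet, fm, pools, tracer, times, rtol=1e-10, atol=1e-12)
        orc = isotopomer_oracle(net, fm, pools, tracer, times)
        assert np.max(np.abs(traj.mids[EMU("B.c", (1,))] - orc.mids[EMU("B.c", (1,))])) < 1e-9

    def test_condensation_fixture_matches_oracle(self):
        text = """
va | AX.x (ab) -> A.c (ab) | irrev | |
vb | BX.x (a) -> B.c (a) | irrev | |
vc | A.c (ab) + B.c (c) -> C.c (abc) | irrev | |
vd | C.c (abc) -> D.x (abc) | irrev | |
"""
        net = parse_network(text)
        fm = FluxMap(dict(va=4.0, vb=4.0, vc=4.0, vd=4.0))
        pools = {"A.c": 0.05, "B.c": 0.02, "C.c": 0.2}
        tracer = TracerProtocol.step("AX.x", post=0.7).add("BX.x", post=0.3)
        em = decompose(net, [EMU("C.c", (1, 2, 3))])
        traj = simulate_transient(em, fm, pools, tracer, DEFAULT_SAMPLING_TIMES, rtol=1e-10, atol=1e-12)
        orc = isotopomer_oracle(net, fm, pools, tracer, DEFAULT_SAMPLING_TIMES, targets=list(em.emus))
        dev = max(np.max(np.abs(traj.mids[e] - orc.mids[e])) for e in em.emus)
        assert dev < 1e-8

    def test_oracle_state_space_guard(self, mini_mixo):
        with pytest.raises(SimulationError, match="state space"):
            isotopomer_oracle(
                mini_mixo.network, mini_mixo.flux_map, mini_mixo.pools,
                mini_mixo.tracer, (0.0, 10.0),
            )


class TestPositionalEnrichment:
    def test_single_pool_equals_overall(self):
        net, emunet, fm, pools, tracer = _single_pool_setup()
        traj = simulate_transient(emunet, fm, pools, tracer, (0.0, 600.0, 3600.0))
        pe = positional_enrichment(traj, "B.c", 1)
        assert np.allclose(pe, traj.enrichment(EMU("B.c", (1,))))

    def test_unlabeled_position_stays_zero(self):
        text = """
v1 | L.x (a) + U.x (b) -> AB.c (ab) | irrev | |
v2 | AB.c (ab) -> P.x (ab) | irrev | |
"""
        net = parse_network(text)
        em = decompose(net, [EMU("AB.c", (1,)), EMU("AB.c", (2,))])
        tracer = TracerProtocol.step("L.x", post=0.9).add("U.x", post=0.0)
        traj = simulate_transient(
            em, FluxMap(dict(v1=5, v2=5)), {"AB.c": 0.1}, tracer, (0.0, 600.0, 3600.0)
        )
        assert positional_enrichment(traj, "AB.c", 1)[-1] > 0.8
        assert positional_enrichment(traj, "AB.c", 2).max() < 1e-9

    def test_atom_average_identity(self, toy):
        # mean over single-atom enrichments x n == sum_k k*M+k of the full MID
        targets = [EMU("SUC.m", (i,)) for i in range(1, 5)] + [EMU("SUC.m", (1, 2, 3, 4))]
        em = decompose(toy.network, targets)
        traj = simulate_transient(
            em, toy.flux_map, toy.pools, toy.tracer, DEFAULT_SAMPLING_TIMES, rtol=1e-10, atol=1e-12
        )
        single_sum = sum(positional_enrichment(traj, "SUC.m", i) for i in range(1, 5))
        full = traj.mids[EMU("SUC.m", (1, 2, 3, 4))]
        weighted = (full * np.arange(5)).sum(axis=1)
        assert np.max(np.abs(single_sum - weighted)) < 1e-7

    def test_untraced_atom_errors(self):
        net, emunet, fm, pools, tracer = _single_pool_setup()
        traj = simulate_transient(emunet, fm, pools, tracer, (0.0, 10.0))
        with pytest.raises(KeyError):
            positional_enrichment(traj, "B.c", 2)


class TestTracer:
    def test_equilibration_lag_slows_step(self):
        net, emunet, fm, pools, _ = _single_pool_setup()
        instant = TracerProtocol.step("S.x", post=0.5)
        lagged = TracerProtocol.step("S.x", post=0.5, tau_s=120.0)
        t_i = simulate_transient(emunet, fm, pools, instant, (0.0, 120.0, 600.0))
        t_l = simulate_transient(emunet, fm, pools, lagged, (0.0, 120.0, 600.0))
        e = EMU("B.c", (1,))
        assert t_l.mids[e][1, 1] < t_i.mids[e][1, 1]

    def test_boundary_mid_is_binomial(self):
        tracer = TracerProtocol.step("S.x", post=0.4)
        mid = tracer.boundary_mid(EMU("S.x", (1, 2)), 10.0)
        assert np.allclose(mid, [0.36, 0.48, 0.16])
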