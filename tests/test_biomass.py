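"""Growth conversions, biomass demands, and derived flux metrics."""

import math

import pytest

from instmfa.biomass import (
    BiomassComposition,
    GrowthSpec,
    biomass_demand_fluxes,
    branch_partition_fraction,
    carbon_conversion_loss,
    doubling_from_growth_rate,
    growth_rate_from_doubling,
    provenance_fraction,
    rescale_flux_map,
    respiration_fraction,
    turnover_fraction,
)
from instmfa.network import FluxMap, parse_network, steady_state_residual


class TestGrowth:
    def test_mixotrophic_doubling_time_gives_0062(self):
        mu = growth_rate_from_doubling(11.1)
        assert float(f"{mu:.2g}") == 0.062

    def test_ln2_doubling_gives_unit_rate(self):
        assert growth_rate_from_doubling(math.log(2)) == pytest.approx(1.0)

    def test_roundtrip(self):
        mu = 0.0731
        assert growth_rate_from_doubling(doubling_from_growth_rate(mu)) == pytest.approx(mu)

    def test_invalid_doubling_time(self):
        with pytest.raises(ValueError):
            growth_rate_from_doubling(0.0)

    def test_growth_spec_tolerates_printed_rounding(self):
        # ln2/14.6 = 0.0475 vs a printed 0.048: inside the 2% slack
        GrowthSpec(14.6, 0.048).validate()
        with pytest.raises(ValueError, match="inconsistent"):
            GrowthSpec(14.6, 0.055).validate()


class TestBiomassDemands:
    def test_zero_fraction_zero_demand(self):
        comp = BiomassComposition({"protein": 0.0, "starch": 0.0})
        assert biomass_demand_fluxes(comp, 0.05) == {}

    def test_demands_scale_with_growth_rate(self):
        comp = BiomassComposition({"protein": 0.6, "starch": 0.05})
        d1 = biomass_demand_fluxes(comp, 0.05)
        d2 = biomass_demand_fluxes(comp, 0.10)
        for k in d1:
            assert d2[k] == pytest.approx(2.0 * d1[k])

    def test_hand_computed_single_macromolecule(self):
        comp = BiomassComposition(
            {"glyco": 0.5}, monomer_tables={"glyco": {"unit": 1000.0}}
        )
        d = biomass_demand_fluxes(comp, 0.06)
        assert d["unit"] == pytest.approx(30.0)

    def test_missing_monomer_table(self):
        comp = BiomassComposition({"mystery": 0.2}, monomer_tables={})
        with pytest.raises(ValueError, match="monomer table"):
            biomass_demand_fluxes(comp, 0.05)

    def test_fraction_validation(self):
        with pytest.raises(ValueError, match="sum"):
            BiomassComposition({"protein": 0.8, "starch": 0.4}).validate()


class TestRescaling:
    def test_identity_and_doubling(self, toy):
        fm = toy.flux_map
        same = rescale_flux_map(fm, 0.05, 0.05)
        assert same.net == pytest.approx(fm.net)
        double = rescale_flux_map(fm, 0.03, 0.06)
        for r, v in fm.net.items():
            assert double.net[r] == pytest.approx(2.0 * v)

    def test_ratios_invariant_and_balance_preserved(self, toy):
        scaled = rescale_flux_map(toy.flux_map, 0.048, 0.062)
        a, b = "ICL", "IDH"
        assert scaled.net[a] / scaled.net[b] == pytest.approx(
            toy.flux_map.net[a] / toy.flux_map.net[b]
        )
        assert steady_state_residual(toy.network, scaled) < 1e-9


class TestPartitionProvenance:
    def test_fifty_fifty_isocitrate_partition(self):
        net = parse_network(
            """
in  | X.x (abcdef) -> ICIT.m (abcdef) | irrev | |
IDH | ICIT.m (abcdef) -> A.x (abcdef) | irrev | |
ICL | ICIT.m (abcdef) -> B.x (abcd) + C.x (ef) | irrev | |
"""
        )
        fm = FluxMap({"in": 10.0, "IDH": 5.0, "ICL": 5.0})
        assert branch_partition_fraction(fm, net, "ICIT.m", "ICL") == pytest.approx(0.5)
        assert branch_partition_fraction(fm, net, "ICIT.m", "IDH") == pytest.approx(0.5)

    def test_single_consumer_and_hand_sum(self, toy):
        fm, net = toy.flux_map, toy.network
        # CIT consumed by IDH, ICL, DCIT: fractions sum to 1
        fr = [branch_partition_fraction(fm, net, "CIT.m", b) for b in ("IDH", "ICL", "DCIT")]
        assert sum(fr) == pytest.approx(1.0)
        assert fr[0] == pytest.approx(2.0 / 5.0)
        # GLX has a single consumer
        assert branch_partition_fraction(fm, net, "GLX.m", "MS") == pytest.approx(1.0)

    def test_partition_errors(self, toy):
        with pytest.raises(ValueError, match="consume"):
            branch_partition_fraction(toy.flux_map, toy.network, "CIT.m", "ACS")

    def test_provenance_examples(self, toy):
        fm, net = toy.flux_map, toy.network
        # acetyl-CoA comes entirely from acetate in the toy cycle
        assert provenance_fraction(fm, net, "ACA.m", ["ACS"]) == pytest.approx(1.0)
        # 97/3 split
        net2 = parse_network(
            """
a | A.x (ab) -> ACA.m (ab) | irrev | |
b | B.x (ab) -> ACA.m (ab) | irrev | |
c | ACA.m (ab) -> P.x (ab) | irrev | |
"""
        )
        fm2 = FluxMap(dict(a=9.7, b=0.3, c=10.0))
        assert provenance_fraction(fm2, net2, "ACA.m", ["a"]) == pytest.approx(0.97)
        assert provenance_fraction(fm2, net2, "ACA.m", ["a"]) + provenance_fraction(
            fm2, net2, "ACA.m", ["b"]
        ) == pytest.approx(1.0)

    def test_provenance_zero_influx(self, toy):
        fm = FluxMap({r: 0.0 for r in toy.network.reaction_ids})
        with pytest.raises(ValueError, match="influx"):
            provenance_fraction(fm, toy.network, "ACA.m", ["ACS"])


class TestRespiration:
    def _simple_net(self, extra=""):
        return parse_network(
            """
fix | G.x (a) -> C3.c (a) | irrev | |
dec | C3.c (a) -> CO2.c (a) | irrev | |
out | CO2.c (a) -> CO2X.x (a) | irrev | |
bm  | C3.c (a) -> BM.x (a) | irrev | |
"""
            + extra
        )

    def test_hand_carbon_bookkeeping(self):
        net = self._simple_net()
        fm = FluxMap(dict(fix=13.6, dec=3.6, out=3.6, bm=10.0))
        assert respiration_fraction(fm, net) == pytest.approx(0.36)

    def test_no_decarboxylation_gives_zero(self):
        net = self._simple_net()
        fm = FluxMap(dict(fix=10.0, dec=0.0, out=0.0, bm=10.0))
        assert respiration_fraction(fm, net) == pytest.approx(0.0)

    def test_non_co2_reaction_leaves_value_unchanged(self):
        net = self._simple_net("iso | C3.c (a) -> C3B.c (a) | rev | |\nsink | C3B.c (a) -> BM2.x (a) | irrev | |")
        fm = FluxMap(dict(fix=13.6, dec=3.6, out=3.6, bm=8.0, iso=2.0, sink=2.0))
        base = respiration_fraction(
            FluxMap(dict(fix=13.6, dec=3.6, out=3.6, bm=8.0, iso=0.0, sink=0.0)), net
        )
        assert respiration_fraction(fm, net) == pytest.approx(3.6 / (8.0 + 2.0))
        assert base == pytest.approx(3.6 / 8.0)

    def test_toy_fixture_value(self, toy):
        # IDH releases 2 CO2 per turn; biomass = ASP (4C) + GLU (6C) sinks
        val = respiration_fraction(toy.flux_map, toy.network)
        expected = (2 * 2.0) / (3.0 * 4 + 1.0 * 6)
        assert val == pytest.approx(expected)


class TestTurnoverAndCarbonLoss:
    def test_turnover_examples(self):
        assert turnover_fraction(100.0, 0.0) == 0.0
        assert turnover_fraction(100.0, 53.0) == pytest.approx(0.53)
        syn, frac = 30.0, turnover_fraction(30.0, 16.0)
        assert syn * (1 - frac) == pytest.approx(14.0)  # net accumulation
        with pytest.raises(ValueError):
            turnover_fraction(0.0, 1.0)
        with pytest.warns(UserWarning):
            turnover_fraction(10.0, 12.0)

    def test_pyruvate_to_acetyl_coa_loses_a_third(self):
        loss = carbon_conversion_loss(3, 2)
        assert loss == pytest.approx(100.0 / 3.0)
        assert round(loss) == 33

    def test_carbon_loss_examples(self):
        assert carbon_conversion_loss(4, 4) == 0.0
        assert carbon_conversion_loss(6, 3) == pytest.approx(50.0)
        with pytest.raises(ValueError):
            carbon_conversion_loss(2, 3)
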