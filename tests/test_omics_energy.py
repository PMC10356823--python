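"""Coverage/TPM conventions, donor energy attribution, taxon shares."""

import numpy as np
import pandas as pd
import pytest

from plumeomics import omics_energy
from plumeomics.geochem import CatabolicReaction, EnergyLandscape
from plumeomics.omics_energy import (acceptor_adjusted_contribution,
                                     compute_tpm, donor_energy_contribution,
                                     normalize_coverage,
                                     taxon_function_contribution)


class TestNormalizeCoverage:
    def test_reference_dataset_size_unchanged(self):
        assert normalize_coverage(30.0, 1e8) == 30.0

    def test_half_dataset_doubles(self):
        assert normalize_coverage(30.0, 5e7) == 60.0

    def test_double_dataset_halves(self):
        assert normalize_coverage(30.0, 2e8) == 15.0

    def test_zero_dataset_rejected(self):
        with pytest.raises(omics_energy.ParameterError):
            normalize_coverage(30.0, 0)


class TestComputeTpm:
    def test_single_gene_gets_million(self):
        assert compute_tpm([7], [500])[0] == pytest.approx(1e6)

    def test_length_normalization_ratio(self):
        tpm = compute_tpm([10, 10], [1000, 2000])
        assert tpm[0] / tpm[1] == pytest.approx(2.0)

    def test_sums_to_million(self):
        rng = np.random.default_rng(0)
        tpm = compute_tpm(rng.integers(0, 500, 50), rng.integers(300, 3000, 50))
        assert tpm.sum() == pytest.approx(1e6, abs=1e-3)

    def test_all_zero_counts_warns(self):
        with pytest.warns(UserWarning):
            tpm = compute_tpm([0, 0], [100, 100])
        assert np.all(tpm == 0)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(omics_energy.ParameterError):
            compute_tpm([1], [0])


def _landscape(delta_gs: dict[str, float], aerobic: dict[str, bool] | None = None):
    rows = [{"reaction": rid, "donor": rid.split("_")[0], "aerobic":
             (aerobic or {}).get(rid, True), "delta_g": dg,
             "energy_density": max(0.0, -dg), "percent_yield": 0.0}
            for rid, dg in delta_gs.items()]
    table = pd.DataFrame(rows)
    return EnergyLandscape(temperature=3.0, table=table,
                           total_energy=float(table["energy_density"].sum()),
                           biomass=0.0, biomass_yield=1e4)


def _reaction(rid, aerobic=True):
    donor = rid.split("_")[0]
    return CatabolicReaction(id=rid, donor=donor, acceptor="O2" if aerobic
                             else "NO3-", stoichiometry={donor: -1},
                             delta_g0={2.0: -1.0, 121.0: -1.0}, aerobic=aerobic)


def _weights(rows):
    return pd.DataFrame(rows, columns=["mag", "gene", "function", "count",
                                       "length", "coverage", "tpm"])


class TestDonorContribution:
    def test_single_donor_gets_everything(self):
        w = _weights([("m1", "g1", "sulfide_O2", 10, 900, 5.0, 100.0)])
        scape = _landscape({"sulfide_O2": -100.0, "methane_O2": -200.0})
        contrib = donor_energy_contribution(
            w, scape, [_reaction("sulfide_O2"), _reaction("methane_O2")])
        assert contrib.percents["sulfide"] == 100.0

    def test_free_energy_weighting(self):
        # equal coverage, dG -100 vs -50 -> 66.7% / 33.3%
        w = _weights([("m1", "g1", "sulfide_O2", 1, 900, 5.0, 0.0),
                      ("m1", "g2", "methane_O2", 1, 900, 5.0, 0.0)])
        scape = _landscape({"sulfide_O2": -100.0, "methane_O2": -50.0})
        contrib = donor_energy_contribution(
            w, scape, [_reaction("sulfide_O2"), _reaction("methane_O2")])
        assert contrib.percents["sulfide"] == pytest.approx(100 * 2 / 3, abs=0.05)
        assert contrib.percents["methane"] == pytest.approx(100 / 3, abs=0.05)

    def test_endergonic_reaction_contributes_nothing(self):
        w = _weights([("m1", "g1", "sulfide_O2", 1, 900, 50.0, 0.0),
                      ("m1", "g2", "methane_O2", 1, 900, 1.0, 0.0)])
        scape = _landscape({"sulfide_O2": +10.0, "methane_O2": -50.0})
        contrib = donor_energy_contribution(
            w, scape, [_reaction("sulfide_O2"), _reaction("methane_O2")])
        assert contrib.percents.get("sulfide", 0.0) == 0.0
        assert contrib.percents["methane"] == 100.0

    def test_unmapped_function_reported_not_fatal(self):
        w = _weights([("m1", "g1", "mystery", 1, 900, 5.0, 0.0),
                      ("m1", "g2", "methane_O2", 1, 900, 5.0, 0.0)])
        scape = _landscape({"methane_O2": -50.0})
        contrib = donor_energy_contribution(w, scape, [_reaction("methane_O2")])
        assert contrib.skipped_functions == ["mystery"]

    def test_invariant_to_uniform_weight_rescaling(self):
        w = _weights([("m1", "g1", "sulfide_O2", 1, 900, 5.0, 0.0),
                      ("m1", "g2", "methane_O2", 1, 900, 2.0, 0.0)])
        scaled = w.assign(coverage=w["coverage"] * 7.5)
        scape = _landscape({"sulfide_O2": -80.0, "methane_O2": -50.0})
        rxns = [_reaction("sulfide_O2"), _reaction("methane_O2")]
        c1 = donor_energy_contribution(w, scape, rxns).percents
        c2 = donor_energy_contribution(scaled, scape, rxns).percents
        pd.testing.assert_series_equal(c1, c2)

    def test_marker_map_routes_genes_to_reactions(self):
        w = _weights([("m1", "g1", "sqr", 1, 900, 5.0, 0.0)])
        scape = _landscape({"sulfide_O2": -100.0, "sulfide_NO3": -90.0})
        rxns = [_reaction("sulfide_O2"), _reaction("sulfide_NO3", aerobic=False)]
        contrib = donor_energy_contribution(w, scape, rxns)
        assert contrib.percents["sulfide"] == 100.0
        assert not contrib.skipped_functions


class TestAcceptorAdjustment:
    def _setup(self):
        w = _weights([("m1", "g1", "sulfide_O2", 1, 900, 5.0, 0.0),
                      ("m1", "g2", "sulfide_NO3", 1, 900, 5.0, 0.0),
                      ("m1", "g3", "methane_O2", 1, 900, 5.0, 0.0)])
        aerobic = {"sulfide_O2": True, "sulfide_NO3": False, "methane_O2": True}
        scape = _landscape({"sulfide_O2": -100.0, "sulfide_NO3": -100.0,
                            "methane_O2": -100.0}, aerobic)
        rxns = [_reaction("sulfide_O2"), _reaction("sulfide_NO3", aerobic=False),
                _reaction("methane_O2")]
        return w, scape, rxns

    def test_rho_one_is_aerobic_only(self):
        w, scape, rxns = self._setup()
        adj = acceptor_adjusted_contribution(w, scape, scape, rxns, rho=1.0)
        o2_only = donor_energy_contribution(
            w[w["function"].str.endswith("_O2")], scape,
            [r for r in rxns if r.aerobic])
        pd.testing.assert_series_equal(adj.percents, o2_only.percents)

    def test_rho_zero_is_nitrate_only(self):
        w, scape, rxns = self._setup()
        adj = acceptor_adjusted_contribution(w, scape, scape, rxns, rho=0.0)
        assert adj.percents["sulfide"] == 100.0

    def test_rho_half_symmetric_variants_average(self):
        # every donor has O2 and NO3 variants with identical dG and weights,
        # so the rho = 0.5 attribution equals the mean of the two extremes
        w = _weights([("m1", "g1", "sulfide_O2", 1, 900, 3.0, 0.0),
                      ("m1", "g2", "sulfide_NO3", 1, 900, 3.0, 0.0),
                      ("m1", "g3", "methane_O2", 1, 900, 1.0, 0.0),
                      ("m1", "g4", "methane_NO3", 1, 900, 1.0, 0.0)])
        aerobic = {"sulfide_O2": True, "sulfide_NO3": False,
                   "methane_O2": True, "methane_NO3": False}
        scape = _landscape({r: -100.0 for r in aerobic}, aerobic)
        rxns = [_reaction(r, aerobic=a) for r, a in aerobic.items()]
        half = acceptor_adjusted_contribution(w, scape, scape, rxns, rho=0.5)
        full = acceptor_adjusted_contribution(w, scape, scape, rxns, rho=1.0)
        none = acceptor_adjusted_contribution(w, scape, scape, rxns, rho=0.0)
        expected = (full.percents + none.percents) / 2
        pd.testing.assert_series_equal(half.percents, expected)
        assert half.percents["sulfide"] == pytest.approx(75.0)

    def test_rho_out_of_range(self):
        w, scape, rxns = self._setup()
        with pytest.raises(omics_energy.ParameterError):
            acceptor_adjusted_contribution(w, scape, scape, rxns, rho=1.5)


class TestTaxonContribution:
    def test_single_taxon_holds_all(self):
        w = _weights([("m1", "g1", "soxB", 1, 900, 5.0, 0.0)])
        out = taxon_function_contribution(w, {"m1": "SUP05"}, "soxB")
        assert out["share"].iloc[0] == 1.0 and out["flagged"].iloc[0]

    def test_four_equal_taxa_all_flagged(self):
        w = _weights([(f"m{i}", f"g{i}", "soxB", 1, 900, 5.0, 0.0)
                      for i in range(4)])
        taxonomy = {f"m{i}": f"t{i}" for i in range(4)}
        out = taxon_function_contribution(w, taxonomy, "soxB")
        assert np.allclose(out["share"], 0.25)
        assert out["flagged"].all()

    def test_exactly_ten_percent_not_flagged(self):
        w = _weights([("m1", "g1", "soxB", 1, 900, 1.0, 0.0),
                      ("m2", "g2", "soxB", 1, 900, 9.0, 0.0)])
        out = taxon_function_contribution(w, {"m1": "rare", "m2": "common"},
                                          "soxB")
        rare = out[out["taxon"] == "rare"].iloc[0]
        assert rare["share"] == pytest.approx(0.10)
        assert not rare["flagged"]  # strict > 10%

    def test_shares_sum_to_one(self):
        rng = np.random.default_rng(1)
        w = _weights([(f"m{i}", f"g{i}", "soxB", 1, 900,
                       float(rng.uniform(1, 20)), 0.0) for i in range(10)])
        taxonomy = {f"m{i}": f"t{i % 3}" for i in range(10)}
        out = taxon_function_contribution(w, taxonomy, "soxB")
        assert out["share"].sum() == pytest.approx(1.0)

    def test_absent_function_warns_empty(self):
        w = _weights([("m1", "g1", "soxB", 1, 900, 5.0, 0.0)])
        with pytest.warns(UserWarning):
            out = taxon_function_contribution(w, {}, "nirK")
        assert out.empty


def test_metagenome_and_metatranscriptome_share_code_path():
    w = _weights([("m1", "g1", "sulfide_O2", 1, 900, 5.0, 80.0),
                  ("m1", "g2", "methane_O2", 1, 900, 5.0, 20.0)])
    scape = _landscape({"sulfide_O2": -50.0, "methane_O2": -50.0})
    rxns = [_reaction("sulfide_O2"), _reaction("methane_O2")]
    dna = donor_energy_contribution(w, scape, rxns, basis="metagenome")
    rna = donor_energy_contribution(w, scape, rxns, basis="metatranscriptome")
    assert dna.percents["sulfide"] == pytest.approx(50.0)
    assert rna.percents["sulfide"] == pytest.approx(80.0)
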