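"""Simulator tests: determinism, closed-form kinetics, replication rules
and sequencing noise."""

import numpy as np
import pytest

from uvmut import simulate as sim
from uvmut.errors import ConfigurationError

from .conftest import make_template

# variable region with isolated TC sites only (TC separated by purines)
TC_VAR = ("GA" + "TCGA" * 12 + "TCG")


@pytest.fixture(scope="module")
def tc_template():
    t = make_template(TC_VAR)
    assert all(s.site_type == "TC" for s in sim.replicable_sites(t))
    return t


def fresh_sim(template, n, lesion=None, seed=0):
    return sim._ArmSimulator(
        template, n, lesion or sim.LesionModel(), np.random.default_rng(seed)
    )


class TestIrradiate:
    def test_zero_dose_is_identity(self, tc_template):
        s = fresh_sim(tc_template, 500)
        s.irradiate("UVB", 0.0)
        assert not s.dimer.any()

    def test_unknown_wavelength_rejected(self, tc_template):
        s = fresh_sim(tc_template, 10)
        with pytest.raises(ConfigurationError):
            s.irradiate("UVA", 1.0)

    def test_block_fraction_matches_site_wise_product_formula(self, templates, lesion):
        n = 10000
        for t in templates[:2]:
            s = fresh_sim(t, n, lesion, seed=3)
            s.irradiate("UVB", 10.0)
            blocked = s.dimer.any(axis=1).mean()
            expected = sim.expected_block_fraction(t, 10.0, "UVB", lesion)
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(blocked - expected) < 3 * se

    def test_calibrated_block_fraction_is_about_half_at_10kj(self, templates, lesion):
        n = 4000
        fractions = []
        for t in templates:
            s = fresh_sim(t, n, lesion, seed=4)
            s.irradiate("UVB", 10.0)
            fractions.append(s.dimer.any(axis=1).mean())
        se = np.sqrt(0.25 / (n * len(templates)))
        assert abs(np.mean(fractions) - 0.5) < 4 * se

    def test_uvc_tenfold_potency(self, templates, lesion):
        t = templates[0]
        n = 20000
        a = fresh_sim(t, n, lesion, seed=5)
        a.irradiate("UVB", 10.0)
        b = fresh_sim(t, n, lesion, seed=6)
        b.irradiate("UVC", 1.0)
        fa, fb = a.dimer.any(axis=1).mean(), b.dimer.any(axis=1).mean()
        se = np.sqrt(2 * 0.25 / n)
        assert abs(fa - fb) < 3 * se

    def test_no_overlapping_dimers(self, templates, lesion):
        t = max(templates, key=lambda x: len(sim.replicable_sites(x)))
        s = fresh_sim(t, 3000, lesion, seed=7)
        s.irradiate("UVC", 50.0)  # saturating dose
        assert s.dimer.any()
        for i in np.nonzero(s.overlap_next)[0]:
            assert not (s.dimer[:, i] & s.dimer[:, i + 1]).any()

    def test_photoreversion_probability_matches_closed_form(self, tc_template, lesion):
        s = fresh_sim(tc_template, 5000, lesion, seed=8)
        s.irradiate("UVB", 10.0)
        before = s.dimer.copy()
        n_before = int(before.sum())
        dose = 1.0
        s.irradiate("UVC", dose)
        p_rev = sim.reversion_probability(dose, "UVC", lesion)
        p_form = sim.formation_probability(dose, "UVC", lesion)
        # a previously-dimerised site is dimerised now iff it survived
        # reversion or reverted and immediately re-formed
        expected = (1 - p_rev) + p_rev * p_form
        still = s.dimer[before].mean()
        se = np.sqrt(expected * (1 - expected) / n_before)
        assert abs(still - expected) < 3 * se


class TestIncubate:
    def test_zero_hours_is_identity(self, tc_template):
        s = fresh_sim(tc_template, 100)
        s.irradiate("UVB", 10.0)
        s.incubate(0.0)
        assert not s.deam3.any()

    def test_half_life_definition_probability_one_half(self, tc_template):
        lesion = sim.LesionModel(t_half_3prime=2.0)
        s = fresh_sim(tc_template, 5000, lesion, seed=9)
        s.irradiate("UVB", 10.0)
        dimers = int(s.dimer.sum())
        s.incubate(2.0)
        frac = s.deam3[s.dimer].mean()
        se = np.sqrt(0.25 / dimers)
        assert abs(frac - 0.5) < 3 * se

    def test_deamination_fraction_matches_closed_form(self, tc_template):
        lesion = sim.LesionModel(t_half_3prime=8.0)
        s = fresh_sim(tc_template, 10000, lesion, seed=10)
        s.irradiate("UVC", 30.0)  # near-saturating: ~1e4 dimerised TC sites
        dimers = int(s.dimer.sum())
        assert dimers > 10000
        s.incubate(48.0)
        expected = sim.deamination_probability(48.0, 8.0)
        frac = s.deam3[s.dimer].mean()
        se = np.sqrt(expected * (1 - expected) / dimers)
        assert abs(frac - expected) < 3 * se

    def test_monomeric_cytosines_never_deaminate(self, tc_template):
        s = fresh_sim(tc_template, 1000)
        s.incubate(1000.0)  # no irradiation: no dimers
        assert not s.deam3.any() and not s.deam5.any()

    def test_double_deamination_of_cc_dimers_is_suppressed(self):
        cc_var = ("GA" + "CCGA" * 12 + "CCG")
        t = make_template(cc_var)
        lesion = sim.LesionModel()
        s = fresh_sim(t, 10000, lesion, seed=11)
        s.irradiate("UVC", 30.0)
        s.incubate(48.0)
        both = (s.deam5 & s.deam3 & s.dimer).sum()
        single = ((s.deam5 ^ s.deam3) & s.dimer).sum()
        assert single > 0
        assert both < 0.1 * single

    def test_three_prime_slot_deaminates_first_in_cc_dimers(self):
        cc_var = ("GA" + "CCGA" * 12 + "CCG")
        t = make_template(cc_var)
        s = fresh_sim(t, 8000, sim.LesionModel(), seed=12)
        s.irradiate("UVC", 30.0)
        s.incubate(24.0)
        assert s.deam3.sum() > 3 * s.deam5.sum()


class TestUdgAndReplication:
    def test_monomerised_uracil_becomes_abasic_but_5mc_does_not(self):
        cc_var = "GA" + "TCGA" * 6 + "TCGG" + "TCGA" * 5 + "TCG"
        t = make_template(cc_var)
        lesion = sim.LesionModel(t_half_3prime=0.01)  # deaminate everything fast
        s = fresh_sim(t, 2000, lesion, seed=13)
        s.methylate()
        s.irradiate("UVB", 10.0)
        s.incubate(48.0)
        s.irradiate("UVC", 50.0)  # revert most dimers
        deam_mono = s.deam3 & ~s.dimer
        s.udg()
        # uracils (non-CpG) are excised; 5mC-derived thymines are untouched
        assert (s.abasic3[deam_mono & ~s.cpg3[None, :]]).all()
        if (deam_mono & s.cpg3[None, :]).any():
            assert not s.abasic3[deam_mono & s.cpg3[None, :]].any()

    def test_lesion_free_replication_reproduces_reference(self, tc_template):
        lesion = sim.LesionModel(polymerase_error_rate=0.0)
        s = fresh_sim(tc_template, 50, lesion)
        full, products = s.replicate("poldelta")
        assert full.all()
        ref = np.frombuffer(tc_template.product_reference.encode(), dtype=np.uint8)
        assert (products == ref).all()

    def test_tt_dimer_bypass_is_error_free(self):
        tt_var = ("GA" + "TTGA" * 12 + "TTG")
        t = make_template(tt_var)
        lesion = sim.LesionModel(polymerase_error_rate=0.0)
        s = fresh_sim(t, 2000, lesion, seed=14)
        s.irradiate("UVB", 10.0)
        assert s.dimer.any()
        full, products = s.replicate("poldelta_tls")
        ref = np.frombuffer(t.product_reference.encode(), dtype=np.uint8)
        assert full.all()
        assert (products == ref).all()

    def test_cc_dimer_with_certain_misinsertion_yields_tandem_aa(self):
        cc_var = ("GA" + "CCGA" * 12 + "CCG")
        t = make_template(cc_var)
        lesion = sim.LesionModel(
            p_mis_tc=1.0, p_mis_other=1.0, polymerase_error_rate=0.0
        )
        s = fresh_sim(t, 500, lesion, seed=15)
        s.irradiate("UVB", 10.0)
        dimer_any = s.dimer.any(axis=1)
        full, products = s.replicate("poldelta_tls")
        ref = np.frombuffer(t.product_reference.encode(), dtype=np.uint8)
        # every dimerised CC site reads AA (GG>AA on the extending strand)
        for k, site in enumerate(s.sites):
            rows = np.nonzero(s.dimer[:, k])[0]
            c3 = site.read_positions[0] - 1
            assert (products[rows, c3] == ord("A")).all()
            assert (products[rows, c3 + 1] == ord("A")).all()
        # undimerised molecules replicate faithfully
        clean = np.nonzero(~dimer_any)[0]
        assert (products[clean] == ref).all()

    def test_poldelta_blocks_at_dimers_and_abasic_sites(self, tc_template, lesion):
        s = fresh_sim(tc_template, 2000, lesion, seed=16)
        s.irradiate("UVB", 10.0)
        blocked = s.dimer.any(axis=1)
        full, _ = s.replicate("poldelta")
        assert (full == ~blocked).all()

    def test_unknown_mode_rejected(self, tc_template):
        with pytest.raises(ConfigurationError):
            fresh_sim(tc_template, 10).replicate("polgamma")


class TestSequencing:
    def test_zero_noise_reads_equal_products(self, templates):
        t = templates[0]
        model = sim.SequencingModel(
            substitution_rate=0.0, homopolymer_indel_rate=0.0, contaminant_fraction=0.0
        )
        ref = np.frombuffer(t.product_reference.encode(), dtype=np.uint8)
        products = np.tile(ref, (20, 1))
        reads = sim.sequence_reads(products, t, model, np.random.default_rng(0))
        assert len(reads) == 20
        assert all(r.bases == t.product_reference for r in reads)

    def test_substitution_rate_recovered_within_3_se(self, templates):
        t = templates[0]
        rate = 0.002
        model = sim.SequencingModel(
            substitution_rate=rate, homopolymer_indel_rate=0.0, contaminant_fraction=0.0
        )
        ref = np.frombuffer(t.product_reference.encode(), dtype=np.uint8)
        n = 14000  # ~1e6 sequenced bases
        products = np.tile(ref, (n, 1))
        reads = sim.sequence_reads(products, t, model, np.random.default_rng(1))
        mism = sum(
            sum(a != b for a, b in zip(r.bases, t.product_reference)) for r in reads
        )
        total = n * len(t.product_reference)
        se = np.sqrt(rate * (1 - rate) / total)
        assert abs(mism / total - rate) < 3 * se

    def test_homopolymer_indels_only_change_run_lengths(self, templates):
        t = templates[4]  # homopolymer-containing template
        model = sim.SequencingModel(
            substitution_rate=0.0, homopolymer_indel_rate=1.0, contaminant_fraction=0.0
        )
        ref = np.frombuffer(t.product_reference.encode(), dtype=np.uint8)
        reads = sim.sequence_reads(
            np.tile(ref, (50, 1)), t, model, np.random.default_rng(2)
        )
        assert any(len(r.bases) != 73 for r in reads)
        for r in reads:
            assert abs(len(r.bases) - 73) <= 1


class TestProtocol:
    def test_byte_identical_reads_under_fixed_seed(self, templates, lesion):
        arms = {"first_hit_only:poldelta_tls": [
            ("irradiate", "UVB", 10.0), ("replicate", "poldelta_tls")]}
        cfg = sim.SimulationConfig(n_molecules=300, seed=77, lesion=lesion, arms=arms)
        a = sim.run_protocol(cfg, templates)["first_hit_only:poldelta_tls"]
        b = sim.run_protocol(cfg, templates)["first_hit_only:poldelta_tls"]
        assert [(r.read_id, r.bases) for r in a.reads] == [
            (r.read_id, r.bases) for r in b.reads
        ]
        assert a.ledger.equals(b.ledger)

    def test_different_seeds_differ(self, templates, lesion):
        arms = {"first_hit_only:poldelta_tls": [
            ("irradiate", "UVB", 10.0), ("replicate", "poldelta_tls")]}
        a = sim.run_protocol(
            sim.SimulationConfig(n_molecules=300, seed=1, lesion=lesion, arms=arms),
            templates,
        )["first_hit_only:poldelta_tls"]
        b = sim.run_protocol(
            sim.SimulationConfig(n_molecules=300, seed=2, lesion=lesion, arms=arms),
            templates,
        )["first_hit_only:poldelta_tls"]
        assert [r.bases for r in a.reads] != [r.bases for r in b.reads]

    def test_ledger_counts_match_read_mutations_without_noise(self, templates, lesion):
        cfg = sim.SimulationConfig(
            n_molecules=500, seed=21, lesion=lesion,
            sequencing=sim.SequencingModel(
                substitution_rate=0.0, homopolymer_indel_rate=0.0,
                contaminant_fraction=0.0,
            ),
            arms={"first_hit_only:poldelta_tls": [
                ("irradiate", "UVB", 10.0), ("replicate", "poldelta_tls")]},
        )
        res = sim.run_protocol(cfg, templates)["first_hit_only:poldelta_tls"]
        by_id = {t.template_id: t for t in templates}
        observed: dict[tuple, int] = {}
        for r in res.reads:
            tid = r.read_id.split(":")[-3]
            ref = by_id[tid].product_reference
            for i, (a, b) in enumerate(zip(r.bases, ref)):
                if a != b:
                    observed[(tid, i + 1, a)] = observed.get((tid, i + 1, a), 0) + 1
        ledgered = {
            (row.template_id, row.read_pos, row.obs_base): row.count
            for row in res.ledger.itertuples()
        }
        assert observed == ledgered

    def test_undefined_arm_rejected(self):
        with pytest.raises(ConfigurationError, match="undefined"):
            sim.standard_arms(["nonexistent_arm"])

    def test_missing_replicate_step_rejected(self, templates, lesion):
        cfg = sim.SimulationConfig(
            n_molecules=10, seed=0, lesion=lesion,
            arms={"broken": [("irradiate", "UVB", 1.0)]},
        )
        with pytest.raises(ConfigurationError, match="replicate"):
            sim.run_protocol(cfg, templates)
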