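"""96-class spectrum construction, cosine similarity, signature
normalisation and substitution fractions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uvmut.errors import DataError
from uvmut.frequency import misincorporation_frequency, aggregation_view
from uvmut.spectrum import (
    SPECTRUM_CLASSES,
    SignatureVector,
    build_spectrum,
    class_label,
    class_substitution,
    class_triplet,
    cosine_similarity,
    fraction_by_substitution,
    normalize_signature,
)

from .test_frequency import pileup_with_substitutions


def spectrum_from_subs(templates, subs_by_template, n_reads=100):
    """Build a spectrum from raw (unsubtracted) planted substitutions."""
    by_id = {t.template_id: t for t in templates}
    fts = []
    for t in templates:
        pc = pileup_with_substitutions(t, n_reads, subs_by_template.get(t.template_id, {}))
        ft = misincorporation_frequency(pc, template_id=t.template_id)
        fts.append(aggregation_view(ft, t.layout))
    return build_spectrum(fts, by_id, templates[0].layout)


class TestBuildSpectrum:
    def test_class_layout_is_96_substitution_major(self):
        assert len(SPECTRUM_CLASSES) == 96
        assert SPECTRUM_CLASSES[0] == "A[C>A]A"
        assert SPECTRUM_CLASSES[-1] == "T[T>G]T"
        assert len(set(SPECTRUM_CLASSES)) == 96

    def test_single_site_mean_uses_triplet_occurrence_count(self, templates):
        t = templates[0]
        # find an aggregation-region position and plant a 2% substitution
        pos = 40
        ref = t.product_reference
        refbase = ref[pos - 1]
        obs = "A" if refbase != "A" else "G"
        spec = spectrum_from_subs(
            [t], {t.template_id: {0: (pos, obs), 1: (pos, obs)}}, n_reads=100
        )
        from uvmut.amplicon import pyrimidine_centered_class

        triplet, sub, strand = pyrimidine_centered_class(ref, pos, obs)
        label = class_label(triplet, sub)
        row = spec.table.loc[label]
        # the mean is taken over the sites of the matching strand orientation
        n_orient = row["n_pyr"] if strand == "pyrimidine" else row["n_pur"]
        assert row["combined_mean"] == pytest.approx(2.0 / n_orient)
        other = spec.table.drop(label)
        assert other["combined_mean"].sum() == 0.0

    def test_all_zero_frequencies_give_all_zero_spectrum(self, templates):
        spec = spectrum_from_subs(templates, {})
        assert spec.total_mass == 0.0
        assert (spec.table["sd"] == 0).all()

    def test_n_sites_sum_to_pooled_aggregation_length(self, templates):
        spec = spectrum_from_subs(templates, {})
        # each position contributes to the 3 classes of its triplet
        assert spec.table["n_sites"].sum() == 3 * 350
        per_triplet = spec.table.groupby(
            [class_triplet(c) for c in spec.table.index]
        )["n_sites"].mean()
        assert per_triplet.sum() == 350

    def test_combined_mean_is_sum_of_strand_components(self, bundle):
        spec = bundle.analyses["two_hit_complete:poldelta_tls"].spectrum
        assert np.allclose(
            spec.table["combined_mean"],
            spec.table["pyr_mean"] + spec.table["pur_mean"],
        )
        assert (spec.table["combined_mean"] >= 0).all()

    def test_tls_mutations_land_on_the_purine_strand_component(self, bundle):
        # A-rule misinsertions are read as G>A on the extending strand, so
        # virtually no C>T is seen on the pyrimidine component
        spec = bundle.analyses["first_hit_only:poldelta_tls"].spectrum
        ct = [c for c in spec.table.index if class_substitution(c) == "C>T"]
        pur = spec.table.loc[ct, "pur_mean"].sum()
        pyr = spec.table.loc[ct, "pyr_mean"].sum()
        assert pur > 10 * pyr


class TestCosineSimilarity:
    def test_identity_and_disjoint_and_half_sqrt2(self):
        a = np.zeros(96)
        a[0] = a[1] = 1.0
        b = np.zeros(96)
        b[0] = 1.0
        c = np.zeros(96)
        c[5] = 2.0
        assert cosine_similarity(a, a) == pytest.approx(1.0)
        assert cosine_similarity(a, c) == pytest.approx(0.0)
        assert cosine_similarity(a, b) == pytest.approx(1 / np.sqrt(2), abs=1e-4)

    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_scale_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        a, b = rng.random(96), rng.random(96)
        assert cosine_similarity(a, b) == pytest.approx(cosine_similarity(b, a))
        assert cosine_similarity(a * scale, b) == pytest.approx(
            cosine_similarity(a, b)
        )
        assert 0.0 <= cosine_similarity(a, b) <= 1.0

    def test_zero_vector_refused(self):
        with pytest.raises(DataError, match="zero"):
            cosine_similarity(np.zeros(96), np.ones(96))


class TestSignatureNormalization:
    @staticmethod
    def two_class_signature(w1=0.6, w2=0.4):
        w = pd.Series(0.0, index=SPECTRUM_CLASSES)
        w["A[C>A]A"] = w1  # triplet ACA
        w["A[C>A]C"] = w2  # triplet ACC
        return SignatureVector(weights=w, label="toy")

    def test_uniform_genome_frequencies_change_nothing(self):
        sig = self.two_class_signature()
        freqs = {class_triplet(c): 1 / 32 for c in SPECTRUM_CLASSES}
        out = normalize_signature(sig, freqs)
        assert np.allclose(out.vector(), sig.vector())
        assert out.normalization == "genome-normalized"

    def test_two_class_worked_example(self):
        # weights (0.6, 0.4) over triplets with genome frequencies (0.3, 0.1)
        # -> (2, 4) -> rescaled (1/3, 2/3)
        sig = self.two_class_signature()
        freqs = {class_triplet(c): 1.0 for c in SPECTRUM_CLASSES}
        freqs["ACA"] = 0.3
        freqs["ACC"] = 0.1
        out = normalize_signature(sig, freqs)
        assert out.weights["A[C>A]A"] == pytest.approx(1 / 3)
        assert out.weights["A[C>A]C"] == pytest.approx(2 / 3)

    def test_doubling_a_triplet_frequency_halves_its_relative_weight(self):
        sig = self.two_class_signature(0.5, 0.5)
        base = {class_triplet(c): 1.0 for c in SPECTRUM_CLASSES}
        doubled = dict(base)
        doubled["ACA"] = 2.0
        out = normalize_signature(sig, doubled)
        assert out.weights["A[C>A]A"] / out.weights["A[C>A]C"] == pytest.approx(0.5)

    def test_nonpositive_frequency_refused(self):
        sig = self.two_class_signature()
        freqs = {class_triplet(c): 1.0 for c in SPECTRUM_CLASSES}
        freqs["ACA"] = 0.0
        with pytest.raises(DataError, match="positive"):
            normalize_signature(sig, freqs)


class TestFractionBySubstitution:
    def test_pure_ct_spectrum(self, templates):
        t = templates[0]
        # plant substitutions that all map to C>T classes
        subs = {}
        i = 0
        for pos in range(22, 72):
            refbase = t.product_reference[pos - 1]
            if refbase == "G":
                subs[i] = (pos, "A")  # read G>A == template-centric C>T
                i += 1
        spec = spectrum_from_subs([t], {t.template_id: subs})
        fr = fraction_by_substitution(spec)
        assert fr["C>T"] == pytest.approx(1.0)

    def test_equal_mass_gives_one_sixth_each(self):
        from uvmut.spectrum import MutSpectrum96

        table = pd.DataFrame(
            {
                "pyr_mean": 1.0,
                "pur_mean": 0.0,
                "combined_mean": 1.0,
                "sd": 0.0,
                "n_sites": 1,
            },
            index=pd.Index(SPECTRUM_CLASSES, name="class"),
        )
        fr = fraction_by_substitution(MutSpectrum96(table=table))
        for v in fr.values():
            assert v == pytest.approx(1 / 6)

    def test_zero_mass_refused(self, templates):
        spec = spectrum_from_subs(templates[:1], {})
        with pytest.raises(DataError, match="zero"):
            fraction_by_substitution(spec)
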