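import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dfppi import (
    ApaacConfig,
    GroupAlphabet,
    PropertyTable,
    RegionScheme,
    apaac_vector,
    apaacplus_vector,
    circle_trace,
    ctd_region_vector,
    enumerate_partitions,
    fvector,
    handcrafted_vector,
    ld_vector,
    split_regions,
)
from dfppi.descriptors import DEFAULT_GROUPS

import oracles

SEQ_LETTERS = st.sampled_from("ACDEFGHIKLMNPQRSTVWY")
seq_strategy = st.text(alphabet=SEQ_LETTERS, min_size=8, max_size=200)


@pytest.fixture(scope="module")
def props():
    return PropertyTable.default()


@pytest.fixture(scope="module")
def raw_props():
    from importlib import resources

    path = resources.files("dfppi").joinpath("data/apaac_properties.tsv")
    return oracles.load_raw_properties(str(path))


class TestRegions:
    def test_quarter_window_on_length_100(self, random_sequence):
        seq = random_sequence(100)
        regions = split_regions(seq)
        assert regions[0] == seq[0:25]  # residues 1..25

    def test_shifted_threequarter_window_on_length_100(self, random_sequence):
        seq = random_sequence(100)
        scheme = RegionScheme()
        # the (0.125, 0.875) window is the 9th region in the default scheme
        assert scheme.regions[8] == (0.125, 0.875)
        assert split_regions(seq, scheme)[8] == seq[12:87]  # residues 13..87

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=50, max_value=500), st.randoms())
    def test_threequarter_regions_cover_sequence(self, L, pyrandom):
        seq = "".join(pyrandom.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(L))
        regions = split_regions(seq)
        starts = [0, L // 8, L // 4]
        covered = set()
        for s, r in zip(starts, regions[7:]):
            covered.update(range(s, s + len(r)))
        assert covered == set(range(L))

    def test_too_short_sequence_names_minimum(self):
        with pytest.raises(ValueError, match="8"):
            split_regions("ACDEFGH")

    def test_all_regions_non_empty_at_minimum_length(self, random_sequence):
        assert all(len(r) >= 1 for r in split_regions(random_sequence(8)))


class TestCtd:
    def test_homopolymer(self):
        v = ctd_region_vector("A" * 20)  # A is in group 1
        np.testing.assert_allclose(v[:7], [1, 0, 0, 0, 0, 0, 0])
        np.testing.assert_allclose(v[7:28], 0)
        np.testing.assert_allclose(v[28:33], [0.05, 0.25, 0.50, 0.75, 1.00])
        np.testing.assert_allclose(v[33:], 0)

    def test_single_residue(self):
        v = ctd_region_vector("C")  # group 7
        np.testing.assert_allclose(v[:7], [0, 0, 0, 0, 0, 0, 1])
        np.testing.assert_allclose(v[7:28], 0)
        np.testing.assert_allclose(v[28 + 6 * 5 : 28 + 7 * 5], [1, 1, 1, 1, 1])

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            ctd_region_vector("")

    def test_matches_brute_force(self, random_sequence, rng):
        for _ in range(50):
            region = random_sequence(int(rng.integers(1, 80)))
            np.testing.assert_allclose(
                ctd_region_vector(region), oracles.brute_ctd(region), atol=1e-12
            )

    @settings(max_examples=50, deadline=None)
    @given(seq_strategy)
    def test_composition_sums_to_one_and_ranges(self, seq):
        v = ctd_region_vector(seq)
        assert abs(v[:7].sum() - 1) < 1e-12
        assert np.all((v[7:28] >= 0) & (v[7:28] <= 1))
        assert np.all((v[28:] >= 0) & (v[28:] <= 1))


class TestLd:
    def test_dimension_and_oracle(self, random_sequence, rng):
        for _ in range(50):
            seq = random_sequence(int(rng.integers(8, 300)))
            v = ld_vector(seq)
            assert v.dim == 630
            np.testing.assert_allclose(v.values, oracles.brute_ld(seq), atol=1e-12)

    def test_homopolymer_has_no_transitions(self):
        v = ld_vector("G" * 40).values.reshape(10, 63)
        np.testing.assert_allclose(v[:, 7:28], 0)

    def test_nonstandard_residues_are_stripped(self, random_sequence):
        seq = random_sequence(60)
        noisy = seq[:30] + "XXBZ" + seq[30:]
        np.testing.assert_allclose(ld_vector(noisy).values, ld_vector(seq).values)


class TestPartitions:
    def test_exactly_35_assignments(self):
        assert len(enumerate_partitions()) == 35

    def test_first_assignment_is_lexicographic(self):
        first = enumerate_partitions()[0]
        assert {g for g, c in first.items() if c == 0} == {1, 2, 3, 4}
        assert first[5] == 1 and first[6] == 2 and first[7] == 3

    def test_each_is_a_4_1_1_1_partition(self):
        seen = set()
        for a in enumerate_partitions():
            assert set(a) == {1, 2, 3, 4, 5, 6, 7}
            sizes = sorted(list(a.values()).count(c) for c in range(4))
            assert sizes == [1, 1, 1, 4]
            seen.add(frozenset(g for g, c in a.items() if c == 0))
        assert len(seen) == 35  # distinct G0 quadruples


class TestCircleTrace:
    def test_two_residue_hand_example(self):
        # both residues in class G0: angles pi/6 and pi/3
        assignment = enumerate_partitions()[0]  # group 1 (A) in G0
        pts = circle_trace("AA", assignment)
        np.testing.assert_allclose(pts[:, 0], [0.8660, 0.5000], atol=5e-5)

    def test_all_points_on_unit_circle(self, random_sequence):
        pts = circle_trace(random_sequence(200), enumerate_partitions()[17])
        np.testing.assert_allclose(np.hypot(pts[:, 0], pts[:, 1]), 1.0, atol=1e-12)

    def test_class_g2_points_stay_in_third_quadrant_sector(self):
        # choose an assignment that puts group 6 (D/E) alone in class G2
        assignment = next(a for a in enumerate_partitions() if a[6] == 2)
        pts = circle_trace("DEDED", assignment)
        angles = np.arctan2(pts[:, 1], pts[:, 0]) % (2 * np.pi)
        assert np.all((angles >= np.pi) & (angles < 1.5 * np.pi))


class TestFvector:
    def test_dimension(self, random_sequence):
        assert fvector(random_sequence(77)).dim == 140

    def test_two_residue_hand_example(self):
        vals = fvector("AA").values
        assert vals[0] == pytest.approx(0.6830, abs=5e-5)
        assert vals[1] == pytest.approx(0.0670, abs=5e-5)

    def test_matches_brute_force(self, random_sequence, rng):
        for _ in range(50):
            seq = random_sequence(int(rng.integers(1, 150)))
            np.testing.assert_allclose(
                fvector(seq).values, oracles.brute_fvector(seq), atol=1e-9
            )

    @settings(max_examples=30, deadline=None)
    @given(seq_strategy)
    def test_mean_and_dispersion_ranges(self, seq):
        vals = fvector(seq).values.reshape(35, 4)
        assert np.all((vals[:, 0] >= -1) & (vals[:, 0] <= 1))
        assert np.all((vals[:, 2] >= -1) & (vals[:, 2] <= 1))
        assert np.all(vals[:, 1] >= 0) and np.all(vals[:, 3] >= 0)


class TestApaac:
    def test_dimensions(self, random_sequence, props):
        seq = random_sequence(120)
        assert apaac_vector(seq, ApaacConfig(), props).dim == 80
        assert apaacplus_vector(seq, ApaacConfig(), props).dim == 140
        assert apaacplus_vector(seq, ApaacConfig(lam=5), props).dim == 40

    def test_zero_weights_reduce_to_composition(self, random_sequence, props):
        seq = random_sequence(100)
        v = apaacplus_vector(seq, ApaacConfig(w1=0.0, w2=0.0), props).values
        counts = np.array([seq.count(aa) for aa in "ACDEFGHIKLMNPQRSTVWY"])
        np.testing.assert_allclose(v[:20], counts / counts.sum(), atol=1e-12)
        np.testing.assert_allclose(v[20:], 0)

    def test_matches_brute_force(self, random_sequence, rng, props, raw_props):
        h1, h2 = raw_props
        for _ in range(20):
            seq = random_sequence(int(rng.integers(31, 200)))
            np.testing.assert_allclose(
                apaac_vector(seq, ApaacConfig(), props).values,
                oracles.brute_apaacplus(seq, h1, h2, plus=False),
                atol=1e-9,
            )
            np.testing.assert_allclose(
                apaacplus_vector(seq, ApaacConfig(), props).values,
                oracles.brute_apaacplus(seq, h1, h2, plus=True),
                atol=1e-9,
            )

    def test_short_sequence_triplet_terms_vanish(self, random_sequence, props, raw_props):
        h1, h2 = raw_props
        seq = random_sequence(45)
        v = apaacplus_vector(seq, ApaacConfig(), props).values
        # upsilon terms live at indices 80..139, ordered (h1,h2) per lag k=1..30;
        # lags with L-2k <= 0 (2k >= 45, i.e. k >= 23) must be exactly 0
        ups = v[80:].reshape(30, 2)
        assert np.all(ups[22:] == 0)
        np.testing.assert_allclose(v, oracles.brute_apaacplus(seq, h1, h2), atol=1e-9)

    def test_w2_zero_matches_apaac_prefix(self, random_sequence, props):
        seq = random_sequence(90)
        plus = apaacplus_vector(seq, ApaacConfig(w2=0.0), props).values
        base = apaac_vector(seq, ApaacConfig(), props).values
        np.testing.assert_allclose(plus[:80], base, atol=1e-12)
        np.testing.assert_allclose(plus[80:], 0)

    def test_frequency_block_invariant(self, random_sequence, props):
        # sum of the first 20 entries times the normalizer equals the raw
        # frequency mass (= 1), i.e. scaling is exactly the shared denominator
        seq = random_sequence(100)
        cfg = ApaacConfig()
        v = apaacplus_vector(seq, cfg, props).values
        ratio = v[:20].sum() / 1.0
        w_mass = v[20:].sum()
        assert ratio + w_mass == pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_nonstandard_stripping(self, random_sequence, props):
        seq = random_sequence(80)
        noisy = "XX" + seq[:40] + "B" + seq[40:]
        np.testing.assert_allclose(
            apaacplus_vector(noisy, ApaacConfig(), props).values,
            apaacplus_vector(seq, ApaacConfig(), props).values,
            atol=1e-12,
        )

    def test_all_nonstandard_rejected(self, props):
        with pytest.raises(ValueError):
            apaacplus_vector("XXXXXXXX", ApaacConfig(), props)


class TestPropertyTable:
    def test_standardization(self, props):
        for h in (props.h1, props.h2):
            assert h.mean() == pytest.approx(0.0, abs=1e-12)
            assert h.std() == pytest.approx(1.0, abs=1e-12)


class TestHandcrafted:
    def test_total_dimension_and_slices(self, random_sequence):
        seq = random_sequence(130)
        v = handcrafted_vector(seq)
        assert v.dim == 910
        np.testing.assert_allclose(v.values[:630], ld_vector(seq).values)
        np.testing.assert_allclose(v.values[630:770], fvector(seq).values)
        np.testing.assert_allclose(v.values[770:], apaacplus_vector(seq).values)

    def test_deterministic(self, random_sequence):
        seq = random_sequence(64)
        np.testing.assert_array_equal(
            handcrafted_vector(seq).values, handcrafted_vector(seq).values
        )


class TestGroupAlphabet:
    def test_default_covers_20_residues_in_7_groups(self):
        ga = GroupAlphabet()
        assert set(ga.mapping) == set("ACDEFGHIKLMNPQRSTVWY")
        assert set(ga.mapping.values()) == set(range(1, 8))

    def test_incomplete_alphabet_rejected(self):
        bad = {k: v for k, v in DEFAULT_GROUPS.items() if k != "A"}
        with pytest.raises(ValueError, match="A"):
            GroupAlphabet(bad)
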