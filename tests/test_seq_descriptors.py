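"""Sequence descriptors against hand calculations and brute-force
substring-counting oracles."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import protdesc.seq_descriptors as sd
from protdesc.core import (CANONICAL_ORDER, PhysicochemicalProperty,
                           ProteinRecord)

from conftest import make_record

AA = CANONICAL_ORDER


def _cell(i_aa: str, j_aa: str) -> int:
    """Row-major 20x20 cell index for an amino-acid couple."""
    return AA.index(i_aa) * 20 + AA.index(j_aa)


def brute_pair_counts(seq: str, gap: int = 1) -> Counter:
    """Independent substring-counting oracle: occurrences of each ordered
    couple at distance ``gap``."""
    return Counter((seq[i], seq[i + gap]) for i in range(len(seq) - gap))


class TestAac:
    def test_homopolymer(self):
        v = np.asarray(sd.aac(ProteinRecord("r", "AAAA")))
        assert v[AA.index("A")] == 1.0 and v.sum() == 1.0

    def test_hand_count(self):
        v = np.asarray(sd.aac(ProteinRecord("r", "ACDC")))
        assert v[AA.index("A")] == pytest.approx(0.25)
        assert v[AA.index("C")] == pytest.approx(0.5)
        assert v[AA.index("D")] == pytest.approx(0.25)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet=AA, min_size=1, max_size=60),
           st.randoms(use_true_random=False))
    def test_sums_to_one_and_permutation_invariant(self, seq, rnd):
        v = np.asarray(sd.aac(ProteinRecord("r", seq)))
        assert v.sum() == pytest.approx(1.0)
        shuffled = list(seq)
        rnd.shuffle(shuffled)
        w = np.asarray(sd.aac(ProteinRecord("r", "".join(shuffled))))
        np.testing.assert_allclose(v, w)


class TestTwoGram:
    def test_triple_a(self):
        v = np.asarray(sd.two_gram(ProteinRecord("r", "AAA")))
        assert v[_cell("A", "A")] == pytest.approx(2 / 3)
        assert v.sum() == pytest.approx(2 / 3)

    def test_order_sensitivity(self):
        a = np.asarray(sd.two_gram(ProteinRecord("r", "ACDC")))
        b = np.asarray(sd.two_gram(ProteinRecord("r", "CADC")))
        assert not np.allclose(a, b)

    def test_brute_force_oracle_on_random_sequences(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 51))
            seq = make_record(rng, n).sequence
            got = np.asarray(sd.two_gram(ProteinRecord("r", seq)))
            expected = np.zeros(400)
            for (a, b), c in brute_pair_counts(seq).items():
                expected[_cell(a, b)] = c / n
            np.testing.assert_allclose(got, expected, atol=1e-12)
            assert got.sum() == pytest.approx((n - 1) / n)


class TestQrc:
    def test_dimension(self, rng, prop):
        assert len(sd.qrc(make_record(rng, 30), prop)) == 1200

    def test_homopolymer_order_one(self, simple_prop):
        # index(A) = 1; each of the 3 neighbour pairs contributes 1+1,
        # normalized by N-m = 3
        v = np.asarray(sd.qrc(ProteinRecord("r", "AAAA"), simple_prop))
        assert v[_cell("A", "A")] == pytest.approx(2.0)

    def test_absent_couples_are_zero(self, simple_prop):
        v = np.asarray(sd.qrc(ProteinRecord("r", "AAAA"), simple_prop))
        mask = np.ones(1200, dtype=bool)
        for m in range(3):
            mask[400 * m + _cell("A", "A")] = False
        assert np.all(v[mask] == 0)

    def test_brute_force_oracle(self, rng, simple_prop):
        vals = simple_prop.vector()
        for _ in range(30):
            n = int(rng.integers(5, 40))
            seq = make_record(rng, n).sequence
            got = np.asarray(sd.qrc(ProteinRecord("r", seq), simple_prop))
            expected = np.zeros(1200)
            for m in (1, 2, 3):
                for (a, b), c in brute_pair_counts(seq, gap=m).items():
                    contrib = c * (vals[AA.index(a)] + vals[AA.index(b)])
                    expected[400 * (m - 1) + _cell(a, b)] = contrib / (n - m)
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_too_short_rejected(self, prop):
        with pytest.raises(ValueError):
            sd.qrc(ProteinRecord("r", "ACD"), prop)


class TestAutocovariance:
    def test_dimension_and_composition_head(self, rng, prop):
        rec = make_record(rng, 50)
        v = np.asarray(sd.autocovariance(rec, prop))
        assert len(v) == 40
        np.testing.assert_allclose(v[:20], np.asarray(sd.aac(rec)))

    def test_centered_property_zeroes_the_tail(self):
        # C and D carry +/-5 so mu = 0; the sequence avoids them, so every
        # residue carries exactly the mean and all lag terms vanish
        vals = {a: 0.0 for a in AA}
        vals["C"], vals["D"] = 5.0, -5.0
        d = PhysicochemicalProperty(id="c", values=vals)
        rec = ProteinRecord("r", "AG" * 30)
        v = np.asarray(sd.autocovariance(rec, d))
        np.testing.assert_allclose(v[20:], 0.0, atol=1e-12)

    def test_lag_terms_against_direct_formula(self, rng, simple_prop):
        n = 45
        rec = make_record(rng, n)
        mu, sigma = 10.5, 33.25  # stats of the positional scale
        x = simple_prop.vector()[rec.indices()] - mu
        v = np.asarray(sd.autocovariance(rec, simple_prop))
        for lag in range(1, 21):
            expected = (x[:n - lag] * x[lag:]).sum() / (sigma * (n - lag))
            assert v[19 + lag] == pytest.approx(expected, abs=1e-12)

    def test_degenerate_property_rejected(self, rng):
        flat = PhysicochemicalProperty(id="f", values={a: 2.0 for a in AA})
        with pytest.raises(ValueError):
            sd.autocovariance(make_record(rng, 50), flat)

    def test_short_sequence_rejected(self, rng, prop):
        with pytest.raises(ValueError):
            sd.autocovariance(make_record(rng, 20), prop, m=20)


class TestAaindexloc:
    def test_dimension(self, rng, prop):
        assert len(sd.aaindexloc(make_record(rng, 40), prop)) == 65

    def test_weighted_block_for_homopolymer(self, simple_prop):
        v = np.asarray(sd.aaindexloc(ProteinRecord("r", "AAAA"),
                                     simple_prop))
        weighted = v[20:40]
        assert weighted[AA.index("A")] == pytest.approx(1.0)  # 1.0 * index(A)
        assert np.all(weighted[1:] == 0)

    def test_grouping_block_sums_to_one(self, rng, prop):
        v = np.asarray(sd.aaindexloc(make_record(rng, 33), prop))
        assert v[40:].sum() == pytest.approx(1.0)

    def test_degenerate_scale_rejected(self, rng):
        d = PhysicochemicalProperty(
            id="d", values={a: float(i % 3) + 10 for i, a in enumerate(AA)})
        with pytest.raises(ValueError):
            sd.aaindexloc(make_record(rng, 30), d)


class TestGlobalEncoding:
    def test_ten_partitions(self):
        parts = sd.ge_partitions()
        assert len(parts) == 10
        seen = set()
        for first, second in parts:
            assert len(first) == 3 and len(second) == 3
            assert set(first) | set(second) == set(range(6))
            seen.add(frozenset({frozenset(first), frozenset(second)}))
        assert len(seen) == 10  # all distinct as unordered partitions

    def test_default_depth_dimension(self, rng):
        assert len(sd.global_encoding(make_record(rng, 30))) == 40

    def test_frequencies_sum_to_one(self, rng):
        v = np.asarray(sd.global_encoding(make_record(rng, 30)))
        by_partition = v.reshape(10, 4)
        np.testing.assert_allclose(by_partition[:, 0] + by_partition[:, 1],
                                   1.0)

    def test_homopolymer_characteristic_sequence(self):
        # A belongs to the first class, which is always in the first subset
        v = np.asarray(sd.global_encoding(ProteinRecord("r", "AAAA")))
        by_partition = v.reshape(10, 4)
        np.testing.assert_allclose(by_partition[:, 1], 1.0)  # all ones
        np.testing.assert_allclose(by_partition[:, 2:], 0.0)  # no switches

    def test_depth_two_triples_dimension(self, rng):
        assert len(sd.global_encoding(make_record(rng, 30), depth=2)) == 120


class TestP2g:
    def test_dimension(self, rng, prop):
        assert len(sd.p2g(make_record(rng, 25), prop)) == 800

    def test_two_residue_hand_case(self, simple_prop):
        v = np.asarray(sd.p2g(ProteinRecord("r", "AA"), simple_prop))
        cell = _cell("A", "A")
        assert v[2 * cell] == pytest.approx(1.0)
        assert v[2 * cell + 1] == pytest.approx(1.0)

    def test_brute_force_oracle(self, rng, simple_prop):
        vals = simple_prop.vector()
        for _ in range(200):
            n = int(rng.integers(2, 51))
            seq = make_record(rng, n).sequence
            got = np.asarray(sd.p2g(ProteinRecord("r", seq), simple_prop))
            expected = np.zeros(800)
            for (a, b), c in brute_pair_counts(seq).items():
                cell = _cell(a, b)
                expected[2 * cell] = c * vals[AA.index(a)] / (n - 1)
                expected[2 * cell + 1] = c * vals[AA.index(b)] / (n - 1)
            np.testing.assert_allclose(got, expected, atol=1e-12)


class TestNgram:
    @pytest.mark.parametrize("alphabet,dim", [
        ("A1", 400), ("A2", 225), ("A3", 512), ("A4", 125), ("A5", 64)])
    def test_dimensions(self, rng, alphabet, dim):
        assert len(sd.ngram(make_record(rng, 30), alphabet)) == dim

    def test_a1_equals_two_gram(self, rng):
        rec = make_record(rng, 40)
        got = np.asarray(sd.ngram(rec, "A1"))
        base = np.asarray(sd.two_gram(rec))
        # A1 lists the amino acids in its own order; compare as multisets
        # via the permutation induced by the alphabet definition
        perm = np.array([sd.NG_ALPHABETS["A1"].index(a) for a in AA])
        remap = (perm[:, None] * 20 + perm[None, :]).ravel()
        np.testing.assert_allclose(got[remap], base, atol=1e-15)

    def test_hand_translation_under_a3(self):
        # L and V both fall in the first A3 group
        v = np.asarray(sd.ngram(ProteinRecord("r", "LVI"), "A3"))
        assert v[0] == pytest.approx(1 / 3)  # the (0,0,0) triple
        assert v.sum() == pytest.approx(1 / 3)

    def test_brute_force_oracle_all_alphabets(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 51))
            seq = make_record(rng, n).sequence
            for alphabet, groups in sd.NG_ALPHABETS.items():
                order = sd.NG_ORDER[alphabet]
                a = len(groups)
                lookup = {aa: g for g, mem in enumerate(groups)
                          for aa in mem}
                trans = [lookup[aa] for aa in seq]
                expected = np.zeros(a ** order)
                for i in range(len(trans) - order + 1):
                    idx = 0
                    for sym in trans[i:i + order]:
                        idx = idx * a + sym
                    expected[idx] += 1 / n
                got = np.asarray(sd.ngram(ProteinRecord("r", seq), alphabet))
                np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_groups_partition_the_alphabet(self):
        for groups in sd.NG_ALPHABETS.values():
            assert sorted("".join(groups)) == sorted(AA)


class TestSac:
    def test_block_structure_length_50(self):
        seq = "A" * 20 + "C" * 10 + "D" * 20
        v = np.asarray(sd.sac(ProteinRecord("r", seq)))
        assert len(v) == 60
        assert v[AA.index("A")] == 1.0
        assert v[20 + AA.index("C")] == 1.0
        assert v[40 + AA.index("D")] == 1.0

    def test_each_nonempty_block_sums_to_one(self, rng):
        v = np.asarray(sd.sac(make_record(rng, 50)))
        for lo in (0, 20, 40):
            assert v[lo:lo + 20].sum() == pytest.approx(1.0)

    def test_short_sequence_middle_block_zero(self, rng):
        v = np.asarray(sd.sac(make_record(rng, 30)))
        assert v[20:40].sum() == 0.0
        assert v[:20].sum() == pytest.approx(1.0)


class TestDiscreteWavelet:
    def test_dimension(self, rng, prop):
        assert len(sd.discrete_wavelet(make_record(rng, 60), prop)) == 52

    def test_constant_profile_has_no_detail(self, rng):
        d = PhysicochemicalProperty(id="c", values={a: 3.0 for a in AA})
        v = np.asarray(sd.discrete_wavelet(make_record(rng, 60), d))
        per_level = v.reshape(4, 13)
        detail_stats = per_level[:, 9:]
        np.testing.assert_allclose(detail_stats, 0.0, atol=1e-9)

    def test_scaling_by_positive_constant(self, rng, prop):
        rec = make_record(rng, 60)
        base = np.asarray(sd.discrete_wavelet(rec, prop))
        tripled = PhysicochemicalProperty(
            id="x3", values={a: 3.0 * v for a, v in prop.values.items()})
        got = np.asarray(sd.discrete_wavelet(rec, tripled))
        np.testing.assert_allclose(got, 3.0 * base, atol=1e-9)

    def test_short_sequence_rejected(self, rng, prop):
        with pytest.raises(ValueError):
            sd.discrete_wavelet(make_record(rng, 10), prop)


class TestFiniteness:
    def test_all_descriptors_finite_on_random_sequences(self, rng, prop):
        for _ in range(20):
            rec = make_record(rng, int(rng.integers(45, 120)))
            outputs = [
                sd.aac(rec), sd.two_gram(rec), sd.qrc(rec, prop),
                sd.autocovariance(rec, prop), sd.aaindexloc(rec, prop),
                sd.global_encoding(rec), sd.p2g(rec, prop),
                sd.ngram(rec, "A3"), sd.sac(rec),
                sd.discrete_wavelet(rec, prop),
            ]
            for out in outputs:
                assert np.all(np.isfinite(np.asarray(out)))
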