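"""Pairwise distance corrections against oracles and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodegap import (
    DistanceMatrix,
    DistanceModelSpec,
    MultipleAlignment,
    build_distance_matrix,
    distance_histogram,
    gtr_distance,
    k2p_distance,
    p_distance,
    pair_counts,
    tn93_distance,
)
from barcodegap.distances import NoOverlapError

K2P_SPOT = 0.1701811651403471  # -1/2 ln[(1-2*0.1-0.05) sqrt(1-2*0.05)]


def _tn93_reference(p1, p2, q, freqs):
    """Independent transliteration of the Tamura-Nei closed form (no shared code)."""
    pa, pc, pg, pt = freqs
    pr, py = pa + pg, pc + pt
    k1 = 2 * pa * pg / pr
    k2 = 2 * pt * pc / py
    k3 = 2 * (pr * py - pa * pg * py / pr - pt * pc * pr / py)
    return (
        -k1 * math.log(1 - p1 / k1 - q / (2 * pr))
        - k2 * math.log(1 - p2 / k2 - q / (2 * py))
        - k3 * math.log(1 - q / (2 * pr * py))
    )


def _oracle_pair(seed=42, L=400):
    """Deterministic gapped pair; ape's dist.dna values are frozen below."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    s1 = rng.choice(4, size=L, p=[0.3, 0.2, 0.3, 0.2])
    s2 = s1.copy()
    mut = rng.random(L) < 0.12
    s2[mut] = rng.choice(4, size=mut.sum())
    a, b = bases[s1], bases[s2]
    a[rng.choice(L, 12, replace=False)] = "-"
    b[rng.choice(L, 12, replace=False)] = "-"
    return "".join(a), "".join(b)


class TestPairCounts:
    def test_transversion_counting(self):
        c = pair_counts("ACGT", "ACGA")
        assert c.n_valid == 4 and c.n_diff == 1
        assert c.q == pytest.approx(0.25)  # T<->A is a transversion
        assert c.p1 == c.p2 == 0

    def test_pairwise_deletion(self):
        c = pair_counts("AC-T", "AGTT")
        assert c.n_valid == 3 and c.n_diff == 1
        assert p_distance(c) == pytest.approx(1 / 3)

    def test_identical(self):
        c = pair_counts("ACGTACGT", "ACGTACGT")
        assert c.n_diff == 0 and c.p1 == c.p2 == c.q == 0

    def test_no_overlap_raises(self):
        with pytest.raises(NoOverlapError):
            pair_counts("AC--", "--GT")

    def test_class_proportions_sum_to_p(self):
        s1, s2 = _oracle_pair()
        c = pair_counts(s1, s2)
        assert c.p1 + c.p2 + c.q == pytest.approx(c.n_diff / c.n_valid)

    def test_fmat_and_freqs_consistent(self):
        s1, s2 = _oracle_pair()
        c = pair_counts(s1, s2)
        assert c.fmat.sum() == pytest.approx(1.0)
        assert sum(c.base_freqs) == pytest.approx(1.0)
        np.testing.assert_allclose(
            (c.fmat.sum(axis=1) + c.fmat.sum(axis=0)) / 2, c.base_freqs
        )

    def test_p_distance_brute_force(self):
        s1, s2 = _oracle_pair(seed=7)
        both = [
            (x, y) for x, y in zip(s1, s2) if x in "ACGT" and y in "ACGT"
        ]
        expected = sum(x != y for x, y in both) / len(both)
        assert p_distance(pair_counts(s1, s2)) == pytest.approx(expected)


class TestK2P:
    def test_spot_value(self):
        # closed form at P = 0.1, Q = 0.05
        from barcodegap.distances import _k2p_kernel

        assert float(_k2p_kernel(0.1, 0.05)) == pytest.approx(K2P_SPOT, abs=1e-9)

    def test_zero(self):
        c = pair_counts("ACGT", "ACGT")
        assert k2p_distance(c) == 0

    def test_saturation_is_nan(self):
        from barcodegap.distances import _k2p_kernel

        assert math.isnan(float(_k2p_kernel(0.3, 0.45)))

    def test_gamma_limit_recovers_uncorrected(self):
        from barcodegap.distances import _k2p_kernel

        plain = float(_k2p_kernel(0.1, 0.05))
        gamma = float(_k2p_kernel(0.1, 0.05, alpha=1e6))
        assert abs(gamma - plain) < 1e-6

    def test_invariant_sites_adjustment(self):
        # with I set, P and Q rescale by 1/(1-I) and the result by (1-I)
        from barcodegap.distances import _k2p_kernel

        I = 0.3
        direct = (1 - I) * float(_k2p_kernel(0.1 / (1 - I), 0.05 / (1 - I)))
        assert float(_k2p_kernel(0.1, 0.05, p_inv=I)) == pytest.approx(direct)

    def test_matches_ape_k80(self):
        # frozen from ape::dist.dna(model="K80", pairwise.deletion=TRUE)
        s1, s2 = _oracle_pair()
        assert k2p_distance(pair_counts(s1, s2)) == pytest.approx(
            0.1148076135, abs=1e-9
        )


class TestTN93:
    def test_reduces_to_k2p_at_equal_freqs(self):
        from barcodegap.distances import _tn93_kernel

        d = float(_tn93_kernel(0.05, 0.05, 0.05, np.array([0.25] * 4)))
        assert d == pytest.approx(K2P_SPOT, abs=1e-12)

    def test_zero(self):
        c = pair_counts("ACGTACGT", "ACGTACGT")
        assert tn93_distance(c) == 0

    def test_independent_transliteration(self):
        s1, s2 = _oracle_pair()
        c = pair_counts(s1, s2)
        expected = _tn93_reference(c.p1, c.p2, c.q, c.base_freqs)
        assert tn93_distance(c) == pytest.approx(expected, abs=1e-12)

    def test_close_to_ape_tn93(self):
        # frozen from ape::dist.dna(model="TN93", pairwise.deletion=TRUE);
        # ape estimates base frequencies from each sequence's full sites while
        # we use the pair's shared sites, hence the loose tolerance.
        s1, s2 = _oracle_pair()
        assert tn93_distance(pair_counts(s1, s2)) == pytest.approx(
            0.1150804026, abs=1e-4
        )

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_random_pairs_match_reference(self, seed):
        s1, s2 = _oracle_pair(seed=seed, L=300)
        c = pair_counts(s1, s2)
        expected = _tn93_reference(c.p1, c.p2, c.q, c.base_freqs)
        assert tn93_distance(c) == pytest.approx(expected, abs=1e-12)


class TestGTR:
    def test_no_differences_gives_zero(self):
        c = pair_counts("ACGTACGTACGT", "ACGTACGTACGT")
        assert gtr_distance(c) == pytest.approx(0.0, abs=1e-12)

    def test_converges_on_jc_simulation(self):
        # two tips at true distance 0.1 under equal rates, length 1e5
        rng = np.random.default_rng(5)
        L = 100_000
        t = 0.1
        # JC transition probability for half the path each side
        same = 0.25 + 0.75 * math.exp(-4 * (t / 2) / 3)
        anc = rng.integers(0, 4, size=L)
        def evolve(s):
            stay = rng.random(L) < same
            shift = rng.integers(1, 4, size=L)
            return np.where(stay, s, (s + shift) % 4)
        bases = np.array(list("ACGT"))
        s1 = "".join(bases[evolve(anc)])
        s2 = "".join(bases[evolve(anc)])
        est = gtr_distance(pair_counts(s1, s2))
        assert abs(est - 0.1) < 0.01

    def test_saturated_fmat_undefined(self):
        # anti-diagonal divergence matrix: eigenvalues of Pi^-1 F not all positive
        f = np.zeros((4, 4))
        f[0, 3] = f[3, 0] = f[1, 2] = f[2, 1] = 0.25
        from barcodegap.distances import _gtr_kernel

        assert math.isnan(float(_gtr_kernel(f)))


class TestDistanceMatrix:
    def test_identical_sequences_zero_matrix(self):
        aln = MultipleAlignment.from_records([("a", "ACGT"), ("b", "ACGT")])
        dm = build_distance_matrix(aln, "k2p")
        assert np.allclose(dm.d, 0)
        assert dm.defined.all()

    def test_hand_computed_p_distances(self):
        aln = MultipleAlignment.from_records(
            [("a", "ACGTACGT"), ("b", "ACGTACGA"), ("c", "TCGTACGA")]
        )
        dm = build_distance_matrix(aln, "p")
        assert dm.d[0, 1] == pytest.approx(1 / 8)
        assert dm.d[0, 2] == pytest.approx(2 / 8)
        assert dm.d[1, 2] == pytest.approx(1 / 8)

    def test_matches_per_pair_functions(self, clean_dataset):
        aln = clean_dataset.alignment.subset(clean_dataset.alignment.ids[:8])
        for model, fn in [
            ("p", p_distance),
            ("k2p", k2p_distance),
            ("tn93", tn93_distance),
            ("gtr", gtr_distance),
        ]:
            dm = build_distance_matrix(aln, model)
            for i in range(3):
                for j in range(i + 1, 6):
                    c = pair_counts(aln.rows[i], aln.rows[j])
                    assert dm.d[i, j] == pytest.approx(fn(c), abs=1e-10), model

    def test_symmetric_zero_diagonal(self, clean_dataset):
        for model in ("p", "k2p", "tn93", "gtr"):
            dm = build_distance_matrix(clean_dataset.alignment, model)
            assert np.allclose(np.diagonal(dm.d), 0)
            dd = np.where(dm.defined, dm.d, 0)
            assert np.allclose(dd, dd.T)

    def test_correction_inflates_p(self, clean_dataset):
        dp = build_distance_matrix(clean_dataset.alignment, "p")
        for model in ("k2p", "tn93"):
            dc = build_distance_matrix(clean_dataset.alignment, model)
            both = dp.defined & dc.defined
            assert np.all(dc.d[both] >= dp.d[both] - 1e-12)

    def test_saturated_pair_flagged_not_raised(self):
        # one pair beyond the K2P domain plus a normal pair
        aln = MultipleAlignment.from_records(
            [("a", "AAAAAAAAGGGGGGGGGGGG"), ("b", "GGGGGGGGAAAAAAAACCCC"),
             ("c", "AAAAAAAAGGGGGGGGGGGG")]
        )
        dm = build_distance_matrix(aln, "k2p")
        assert not dm.defined[0, 1]
        assert np.isnan(dm.d[0, 1])
        assert dm.defined[0, 2]

    def test_no_overlap_pair_flagged(self):
        aln = MultipleAlignment.from_records(
            [("a", "ACGT----"), ("b", "----ACGT"), ("c", "ACGTACGT")]
        )
        dm = build_distance_matrix(aln, "p")
        assert not dm.defined[0, 1]
        assert dm.defined[0, 2] and dm.defined[1, 2]

    def test_global_frequency_mode_runs(self, clean_dataset):
        spec = DistanceModelSpec("tn93", frequency_mode="global")
        dm = build_distance_matrix(clean_dataset.alignment, spec)
        assert dm.defined.all()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            DistanceModelSpec("jc69")
        with pytest.raises(ValueError):
            DistanceModelSpec("k2p", alpha=-1)
        with pytest.raises(ValueError):
            DistanceModelSpec("k2p", p_inv=1.0)


class TestHistogram:
    def test_toy_bins(self):
        ids = ("a", "b", "c")
        d = np.array([[0, 0.01, 0.02], [0.01, 0, 0.30], [0.02, 0.30, 0]])
        dm = DistanceMatrix(ids, d, np.ones((3, 3), bool))
        h = distance_histogram(dm, 0.1)
        as_dict = dict(zip(h["bin_left"].round(10), h["count"]))
        assert as_dict == {0.0: 2, 0.3: 1}

    def test_all_zero_single_bin(self):
        ids = tuple("abcd")
        dm = DistanceMatrix(ids, np.zeros((4, 4)), np.ones((4, 4), bool))
        h = distance_histogram(dm, 0.05)
        assert len(h) == 1 and h["count"].iloc[0] == 6

    def test_conservation(self, clean_dataset):
        from barcodegap import build_distance_matrix

        dm = build_distance_matrix(clean_dataset.alignment, "k2p")
        h = distance_histogram(dm, 0.013)
        assert h["count"].sum() == len(dm.condensed())
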