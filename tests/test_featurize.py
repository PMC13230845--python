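"""Interaction-tensor channels against explicit loop oracles."""

import numpy as np
import pytest

from duplexmap import (FeaturizerConfig, PairRecord, RnaSequence, S_MATRIX,
                       build_tensor, compatibility_channel, helix_run_channels,
                       pair_identity_channels, positional_channel,
                       structural_channel)
from duplexmap.featurize import PAIR_ID_NAMES, ablation_mask
from duplexmap.seq_io import BASE_INDEX, LengthPolicy, one_hot, pad_or_truncate


def windowed_mean_oracle(C, k, anti=False):
    """Brute-force helix-run: mean of C over the (anti-)diagonal window,
    out-of-bounds cells contributing 0."""
    Lp, Lm = C.shape
    out = np.zeros_like(C, dtype=float)
    half = k // 2
    for i in range(Lp):
        for j in range(Lm):
            acc = 0.0
            for t in range(k):
                r = i + t - half
                c = j - (t - half) if anti else j + t - half
                if 0 <= r < Lp and 0 <= c < Lm:
                    acc += C[r, c]
            out[i, j] = acc / k
    return out


class TestPairIdentity:
    def test_single_channel_lights_up(self):
        P, M = one_hot("C"), one_hot("G")
        B = pair_identity_channels(P, M)
        assert B[6, 0, 0] == 1.0  # channel 4*C + G = 4*1 + 2
        assert B.sum() == 1.0
        assert PAIR_ID_NAMES[6] == "CG"

    def test_padded_rows_are_zero_and_sums_partition(self):
        P = one_hot(pad_or_truncate("ACG", 5))
        M = one_hot(pad_or_truncate("UU", 4))
        B = pair_identity_channels(P, M)
        sums = B.sum(axis=0)
        assert (sums[3:, :] == 0).all()      # padded piRNA rows
        assert (sums[:, 2:] == 0).all()      # padded site columns
        assert (sums[:3, :2] == 1).all()     # non-padded cells partition


class TestCompatibility:
    @pytest.mark.parametrize("p,m,expected", [
        ("A", "U", 1.0), ("U", "A", 1.0), ("G", "C", 1.0), ("C", "G", 1.0),
        ("G", "U", 0.6), ("U", "G", 0.6),
        ("C", "A", 0.0), ("A", "A", 0.0), ("G", "G", 0.0),
    ])
    def test_pair_weights(self, p, m, expected):
        C = compatibility_channel(one_hot(p), one_hot(m))
        assert C[0, 0] == pytest.approx(expected)

    def test_linear_functional_of_pair_identity(self, rng):
        """C[i,j] == sum_ab S[a,b] * B_ab[i,j] exactly, everywhere."""
        bases = list("ACGU-")
        p = "".join(rng.choice(bases, size=9))
        m = "".join(rng.choice(bases, size=12))
        P, M = one_hot(p), one_hot(m)
        B = pair_identity_channels(P, M)
        C = compatibility_channel(P, M)
        recon = np.einsum("ab,abij->ij", S_MATRIX,
                          B.reshape(4, 4, *C.shape))
        np.testing.assert_array_equal(C, recon.astype(np.float32))

    def test_padding_contributes_zero(self):
        C = compatibility_channel(one_hot("A-"), one_hot("U-"))
        assert C[0, 0] == 1.0
        assert C[1, :].sum() == 0.0 and C[:, 1].sum() == 0.0

    def test_clip_applies_to_soft_encodings(self):
        # a soft (non-one-hot) row can push the matmul above 1
        P = np.array([[0.0, 0.0, 2.0, 0.0]], dtype=np.float32)
        M = one_hot("C")
        assert compatibility_channel(P, M)[0, 0] == 1.0


class TestHelixRuns:
    def test_all_ones_interior_and_corner(self):
        C = np.ones((21, 31), dtype=np.float32)
        Hd, Ha = helix_run_channels(C, 7)
        assert Hd[10, 15] == pytest.approx(1.0)
        assert Hd[0, 0] == pytest.approx(4 / 7)

    def test_zero_grid_stays_zero(self):
        Hd, Ha = helix_run_channels(np.zeros((8, 9), dtype=np.float32), 7)
        assert not Hd.any() and not Ha.any()

    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_matches_windowed_mean_oracle(self, k, rng):
        C = rng.random((10, 13)).astype(np.float32)
        Hd, Ha = helix_run_channels(C, k)
        np.testing.assert_allclose(Hd, windowed_mean_oracle(C, k), atol=1e-6)
        np.testing.assert_allclose(Ha, windowed_mean_oracle(C, k, anti=True),
                                   atol=1e-6)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            helix_run_channels(np.ones((4, 4), dtype=np.float32), 4)

    def test_antidiagonal_detects_antiparallel_run(self):
        # perfect anti-diagonal line of compatibility
        C = np.zeros((7, 7), dtype=np.float32)
        for t in range(7):
            C[t, 6 - t] = 1.0
        Hd, Ha = helix_run_channels(C, 7)
        assert Ha[3, 3] == pytest.approx(1.0)
        assert Hd[3, 3] == pytest.approx(1 / 7)


class TestPositional:
    def test_values(self):
        D = positional_channel(21, 31)
        assert D[0, 0] == 0.0
        assert D[20, 0] == pytest.approx(1.0)
        assert D[10, 15] == pytest.approx(0.0)
        assert D.min() >= 0.0 and D.max() <= 1.0

    def test_degenerate_length_rejected(self):
        with pytest.raises(ValueError):
            positional_channel(1, 31)


class TestStructural:
    def test_outer_product(self):
        A = structural_channel(np.array([0, 1]), np.array([1, 0]))
        assert A.tolist() == [[0, 0], [1, 0]]

    def test_all_accessible(self):
        A = structural_channel(np.ones(3), np.ones(4))
        assert (A == 1).all()


class TestBuildTensor:
    @pytest.mark.parametrize("mask,channels", [
        (None, 21),
        (("Base16",), 16),
        (tuple(g for g in ("C", "Hdiag", "Hanti", "Delta", "A")), 5),
    ])
    def test_shapes_follow_channel_mask(self, mask, channels, pair_record):
        fcfg = FeaturizerConfig() if mask is None else FeaturizerConfig(
            channel_mask=mask)
        X = build_tensor(pair_record, LengthPolicy(21, 31), fcfg)
        assert X.shape == (channels, 21, 31)

    def test_bounded_and_blockwise_binary(self, pair_record):
        X = build_tensor(pair_record, LengthPolicy(21, 31))
        assert X.min() >= 0.0 and X.max() <= 1.0
        assert set(np.unique(X[:16])) <= {0.0, 1.0}   # pair identity
        assert set(np.unique(X[20])) <= {0.0, 1.0}    # structural

    def test_determinism(self, pair_record):
        X1 = build_tensor(pair_record, LengthPolicy(21, 31))
        X2 = build_tensor(pair_record, LengthPolicy(21, 31))
        assert np.array_equal(X1, X2)

    def test_structural_channel_zero_on_padding(self):
        rec = PairRecord(RnaSequence("ACGUA"), RnaSequence("GGGAAAUCCC"), 1)
        X = build_tensor(rec, LengthPolicy(8, 12))
        assert X[20, 5:, :].sum() == 0.0  # padded piRNA rows inaccessible
        assert X[20, :, 10:].sum() == 0.0

    def test_ablation_mode_names(self):
        assert ablation_mask("full") == ("Base16", "C", "Hdiag", "Hanti",
                                         "Delta", "A")
        assert ablation_mask("full-Base16") == ("C", "Hdiag", "Hanti",
                                                "Delta", "A")
        assert ablation_mask("only-C") == ("C",)
        with pytest.raises(ValueError):
            ablation_mask("only-Q")
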