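"""Multi-channel interaction tensor construction.

Each piRNA/site pair maps to a Ch x L_p x L_m tensor whose channels are,
in canonical order:

* 16 pair-identity channels B[a,b][i,j] = P[i,a] * M[j,b] — piRNA base is
  the major index, channel index 4a + b over A,C,G,U;
* C — pairing compatibility clip_[0,1](P . S . M^T), with Watson-Crick
  pairs weighted 1, the G-U wobble 0.6, everything else 0;
* H_diag, H_anti — helix-run channels: the compatibility map convolved
  (cross-correlated) with a k x k identity kernel and its horizontal flip,
  zero "same" padding, normalized by k, so contiguous diagonal /
  anti-diagonal stretches of pairable bases light up;
* Delta — relative-position channel |i/(L_p-1) - j/(L_m-1)| over the full
  fixed grid, padded cells included;
* A — structural accessibility, the outer product of the two Nussinov
  unpairedness vectors (padded positions are inaccessible, u = 0).

Channel groups can be ablated: the tensor then contains only the selected
groups, in canonical order, and the model input width follows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import correlate2d

from .seq_io import (RNA_ALPHABET, LengthPolicy, PairRecord, one_hot,
                     pad_or_truncate)
from .structure import StructureCache, StructureConfig, unpaired_cached

#: wobble (G-U) compatibility weight
WOBBLE_WEIGHT = 0.6

#: 4x4 compatibility table in base order A,C,G,U
S_MATRIX = np.array([
    [0.0, 0.0, 0.0, 1.0],
    [0.0, 0.0, 1.0, 0.0],
    [0.0, 1.0, 0.0, WOBBLE_WEIGHT],
    [1.0, 0.0, WOBBLE_WEIGHT, 0.0],
], dtype=np.float32)

CHANNEL_GROUPS = ("Base16", "C", "Hdiag", "Hanti", "Delta", "A")
GROUP_SIZES = {"Base16": 16, "C": 1, "Hdiag": 1, "Hanti": 1, "Delta": 1, "A": 1}

PAIR_ID_NAMES = tuple(a + b for a in RNA_ALPHABET for b in RNA_ALPHABET)


@dataclass(frozen=True)
class FeaturizerConfig:
    """Helix-run kernel size and the set of channel groups to emit."""

    k: int = 7
    channel_mask: tuple[str, ...] = CHANNEL_GROUPS

    def __post_init__(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("helix-run kernel size k must be odd and >= 1")
        if not self.channel_mask:
            raise ValueError("channel_mask must be non-empty")
        unknown = set(self.channel_mask) - set(CHANNEL_GROUPS)
        if unknown:
            raise ValueError(f"unknown channel group(s): {sorted(unknown)}")
        # canonical order regardless of how the mask was given
        object.__setattr__(self, "channel_mask",
                           tuple(g for g in CHANNEL_GROUPS if g in self.channel_mask))

    @property
    def n_channels(self) -> int:
        return sum(GROUP_SIZES[g] for g in self.channel_mask)

    def channel_names(self) -> list[str]:
        names: list[str] = []
        for g in self.channel_mask:
            names.extend(PAIR_ID_NAMES if g == "Base16" else [g])
        return names


def pair_identity_channels(P: np.ndarray, M: np.ndarray) -> np.ndarray:
    """16 x L_p x L_m binary block; channel 4a + b holds B_{a,b}."""
    B = np.einsum("ia,jb->abij", P, M)
    return B.reshape(16, P.shape[0], M.shape[0]).astype(np.float32)


def compatibility_channel(P: np.ndarray, M: np.ndarray,
                          S: np.ndarray = S_MATRIX) -> np.ndarray:
    """clip_[0,1](P . S . M^T); zero wherever either position is padding."""
    return np.clip(P @ S @ M.T, 0.0, 1.0).astype(np.float32)


def helix_run_channels(C: np.ndarray, k: int = 7) -> tuple[np.ndarray, np.ndarray]:
    """Diagonal and anti-diagonal run detectors, same shape as C.

    Cross-correlation with the k x k identity kernel (and its horizontal
    flip), zero padding floor(k/2), normalized by k.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError("k must be odd and >= 1")
    K = np.eye(k, dtype=np.float32)
    H_diag = correlate2d(C, K, mode="same", boundary="fill") / k
    H_anti = correlate2d(C, K[:, ::-1], mode="same", boundary="fill") / k
    return H_diag.astype(np.float32), H_anti.astype(np.float32)


def positional_channel(L_p: int, L_m: int) -> np.ndarray:
    """Delta[i,j] = |i/(L_p-1) - j/(L_m-1)| on the full fixed grid."""
    if L_p < 2 or L_m < 2:
        raise ValueError("positional channel requires L_p >= 2 and L_m >= 2")
    i = np.arange(L_p, dtype=np.float32)[:, None] / (L_p - 1)
    j = np.arange(L_m, dtype=np.float32)[None, :] / (L_m - 1)
    return np.abs(i - j).astype(np.float32)


def structural_channel(u_p: np.ndarray, u_m: np.ndarray) -> np.ndarray:
    """Outer product of the two unpairedness vectors."""
    return np.outer(u_p, u_m).astype(np.float32)


def _padded_unpaired(bases: str, L: int, scfg: StructureConfig,
                     cache: StructureCache | None) -> np.ndarray:
    """Unpairedness of the cleaned, unpadded sequence, zero-extended to L."""
    u = unpaired_cached(bases[:L], cache, scfg).astype(np.float32)
    if len(u) < L:
        u = np.concatenate([u, np.zeros(L - len(u), dtype=np.float32)])
    return u


def build_tensor(rec: PairRecord, policy: LengthPolicy,
                 fcfg: FeaturizerConfig = FeaturizerConfig(),
                 scfg: StructureConfig = StructureConfig(),
                 cache: StructureCache | None = None) -> np.ndarray:
    """Full featurization of one pair: Ch x L_p x L_m float32 in [0, 1]."""
    p_pad = pad_or_truncate(rec.pirna, policy.L_p)
    m_pad = pad_or_truncate(rec.site, policy.L_m)
    P = one_hot(p_pad)
    M = one_hot(m_pad)

    parts: list[np.ndarray] = []
    mask = set(fcfg.channel_mask)
    need_C = bool({"C", "Hdiag", "Hanti"} & mask)

    if "Base16" in mask:
        parts.append(pair_identity_channels(P, M))
    if need_C:
        C = compatibility_channel(P, M)
        if "C" in mask:
            parts.append(C[None])
        if {"Hdiag", "Hanti"} & mask:
            H_diag, H_anti = helix_run_channels(C, fcfg.k)
            if "Hdiag" in mask:
                parts.append(H_diag[None])
            if "Hanti" in mask:
                parts.append(H_anti[None])
    if "Delta" in mask:
        parts.append(positional_channel(policy.L_p, policy.L_m)[None])
    if "A" in mask:
        u_p = _padded_unpaired(rec.pirna.bases, policy.L_p, scfg, cache)
        u_m = _padded_unpaired(rec.site.bases, policy.L_m, scfg, cache)
        parts.append(structural_channel(u_p, u_m)[None])
    return np.concatenate(parts, axis=0)


def featurize_records(records: Sequence[PairRecord], policy: LengthPolicy,
                      fcfg: FeaturizerConfig = FeaturizerConfig(),
                      scfg: StructureConfig = StructureConfig(),
                      cache: StructureCache | None = None) -> np.ndarray:
    """Stack tensors for a whole dataset: N x Ch x L_p x L_m float32."""
    X = np.empty((len(records), fcfg.n_channels, policy.L_p, policy.L_m),
                 dtype=np.float32)
    for n, rec in enumerate(records):
        X[n] = build_tensor(rec, policy, fcfg, scfg, cache)
    if cache is not None:
        cache.save()
    return X


def write_tensors(path, X: np.ndarray, records: Sequence[PairRecord],
                  policy: LengthPolicy, fcfg: FeaturizerConfig) -> None:
    """Persist featurized tensors with channel names and the length policy."""
    import h5py

    labels = np.array([-1 if r.label is None else r.label for r in records],
                      dtype=np.int8)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("tensors", data=X, compression="gzip")
        fh.create_dataset("labels", data=labels)
        fh.create_dataset("ids", data=np.array([r.id for r in records], dtype="S"))
        fh.attrs["channel_names"] = ",".join(fcfg.channel_names())
        fh.attrs["channel_mask"] = ",".join(fcfg.channel_mask)
        fh.attrs["k"] = fcfg.k
        fh.attrs["L_p"] = policy.L_p
        fh.attrs["L_m"] = policy.L_m


def ablation_mask(mode: str) -> tuple[str, ...]:
    """Map an ablation mode name to a channel mask.

    Modes: ``full``, ``full-<G>`` (leave one group out) and ``only-<G>``
    for G in Base16, C, Hdiag, Hanti, Delta, A.  ``only-Runs`` is not a
    mode; the two run channels ablate individually.
    """
    mode = mode.strip()
    if mode == "full":
        return CHANNEL_GROUPS
    for sep in ("-", "−", "–"):  # ascii hyphen, minus sign, en dash
        for prefix, build in (("full" + sep, "drop"), ("only" + sep, "keep")):
            if mode.startswith(prefix):
                g = mode[len(prefix):]
                if g in CHANNEL_GROUPS:
                    if build == "drop":
                        return tuple(x for x in CHANNEL_GROUPS if x != g)
                    return (g,)
    raise ValueError(f"unknown ablation mode: {mode!r}")
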