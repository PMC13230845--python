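"""Nussinov maximum base-pairing DP and unpairedness masks.

The structural channel of the interaction tensor needs to know which
positions of each RNA are likely occupied by intramolecular pairing and
therefore unavailable for binding a second RNA.  A Nussinov-style dynamic
program maximizes the number of non-crossing canonical pairs (A-U, G-C and,
optionally, the G-U wobble) subject to a minimum loop length, and a
deterministic traceback marks each position paired (0) or unpaired (1).

This is an accessibility prior, not a thermodynamic structure prediction:
it is cheap, deterministic, and cacheable, which is what the featurizer
needs when folding tens of thousands of short sequences.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass

import numpy as np

from .seq_io import RnaSequence

logger = logging.getLogger(__name__)

_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU_PAIRS = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class StructureConfig:
    """Folding options.

    l_min: minimum loop length — a pair (i, j) is allowed only when
        j - i > l_min, i.e. at least l_min unpaired bases sit between the
        partners.  Default 3.
    allow_gu: whether G-U wobble pairs count in the fold.  Default True,
        consistent with the wobble-aware compatibility channel.
    """

    l_min: int = 3
    allow_gu: bool = True

    def __post_init__(self) -> None:
        if self.l_min < 0:
            raise ValueError("l_min must be >= 0")


def can_pair(a: str, b: str, allow_gu: bool = True) -> bool:
    if (a, b) in _WC_PAIRS:
        return True
    return allow_gu and (a, b) in _GU_PAIRS


def nussinov_unpaired(seq: RnaSequence | str,
                      cfg: StructureConfig = StructureConfig()) -> np.ndarray:
    """Binary unpairedness vector: 1 = predicted unpaired, 0 = paired.

    Fills N(i, j) = max(N(i+1, j), N(i, j-1),
                        N(i+1, j-1) + 1 if (i, j) can pair and j - i > l_min,
                        max_t N(i, t) + N(t+1, j)),
    then runs a deterministic traceback preferring, in order: j unpaired,
    pair (i, j), bifurcation at the smallest split point t.
    """
    bases = seq.bases if isinstance(seq, RnaSequence) else seq
    L = len(bases)
    lmin, gu = cfg.l_min, cfg.allow_gu
    u = np.ones(L, dtype=np.int8)
    if L == 0:
        return u

    pairable = [[can_pair(bases[i], bases[j], gu) for j in range(L)]
                for i in range(L)]
    N = [[0] * L for _ in range(L)]
    for span in range(lmin + 1, L):
        for i in range(L - span):
            j = i + span
            best = max(N[i + 1][j], N[i][j - 1])
            if pairable[i][j]:
                best = max(best, (N[i + 1][j - 1] if i + 1 <= j - 1 else 0) + 1)
            row_i = N[i]
            for t in range(i + 1, j):
                v = row_i[t] + N[t + 1][j]
                if v > best:
                    best = v
            N[i][j] = best

    # traceback
    stack = [(0, L - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or N[i][j] == 0:
            continue
        if N[i][j] == N[i][j - 1]:
            stack.append((i, j - 1))
        elif pairable[i][j] and j - i > lmin and N[i][j] == N[i + 1][j - 1] + 1:
            u[i] = 0
            u[j] = 0
            stack.append((i + 1, j - 1))
        else:
            # t = i is the "i unpaired" case (N[i][i] = 0 + N[i+1][j])
            for t in range(i, j):
                if N[i][t] + N[t + 1][j] == N[i][j]:
                    stack.append((i, t))
                    stack.append((t + 1, j))
                    break
    return u


def max_pair_count(seq: RnaSequence | str,
                   cfg: StructureConfig = StructureConfig()) -> int:
    """The DP optimum N(0, L-1) (number of pairs in the best structure)."""
    u = nussinov_unpaired(seq, cfg)
    return int((u == 0).sum()) // 2


class StructureCache:
    """Persistent key-value store of unpairedness vectors.

    A single JSON file maps a content hash of (sequence, l_min, allow_gu)
    to the 0/1 mask string.  Corrupted entries are recomputed and
    overwritten with a logged warning.
    """

    def __init__(self, path):
        self.path = str(path)
        self._store: dict[str, str] = {}
        self._dirty = False
        if os.path.exists(self.path):
            try:
                with open(self.path) as fh:
                    data = json.load(fh)
                if isinstance(data, dict):
                    self._store = {str(k): str(v) for k, v in data.items()}
            except (json.JSONDecodeError, OSError) as exc:
                logger.warning("unreadable structure cache %s (%s); starting fresh",
                               self.path, exc)

    @staticmethod
    def key(bases: str, cfg: StructureConfig) -> str:
        payload = f"{bases}|{cfg.l_min}|{int(cfg.allow_gu)}"
        return hashlib.sha1(payload.encode()).hexdigest()

    def get(self, bases: str, cfg: StructureConfig) -> np.ndarray | None:
        raw = self._store.get(self.key(bases, cfg))
        if raw is None:
            return None
        if len(raw) != len(bases) or set(raw) - {"0", "1"}:
            logger.warning("corrupted cache entry for %r; recomputing", bases)
            return None
        return np.array([int(c) for c in raw], dtype=np.int8)

    def put(self, bases: str, cfg: StructureConfig, u: np.ndarray) -> None:
        self._store[self.key(bases, cfg)] = "".join(str(int(x)) for x in u)
        self._dirty = True

    def save(self) -> None:
        if not self._dirty:
            return
        tmp = self.path + ".tmp"
        with open(tmp, "w") as fh:
            json.dump(self._store, fh)
        os.replace(tmp, self.path)
        self._dirty = False

    def __len__(self) -> int:
        return len(self._store)


def unpaired_cached(seq: RnaSequence | str,
                    cache: StructureCache | None,
                    cfg: StructureConfig = StructureConfig()) -> np.ndarray:
    """Cached wrapper around :func:`nussinov_unpaired` (byte-identical results)."""
    bases = seq.bases if isinstance(seq, RnaSequence) else seq
    if cache is not None:
        hit = cache.get(bases, cfg)
        if hit is not None:
            return hit
    u = nussinov_unpaired(bases, cfg)
    if cache is not None:
        cache.put(bases, cfg, u)
    return u
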