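"""Sequence cleaning, encoding, length policy and pair-table I/O.

The toolkit works on pairs of a short guide RNA (a piRNA, ~21 nt) and a
candidate mRNA target-site window (~31 nt).  Sequences are cleaned to the
RNA alphabet {A, C, G, U} (DNA ``T`` is mapped to ``U``), right-padded or
truncated to a fixed length policy, and one-hot encoded in the column order
A=0, C=1, G=2, U=3.  Padded positions encode to the all-zero row so they
contribute nothing to the pair-identity or compatibility channels downstream.

All coordinates are 0-based.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

RNA_ALPHABET = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(RNA_ALPHABET)}
#: padding sentinel; deliberately outside the alphabet so one_hot maps it to 0
PAD = "-"


class SequenceError(ValueError):
    """Raised when a sequence cannot be cleaned to {A,C,G,U}."""


@dataclass(frozen=True)
class RnaSequence:
    """A cleaned RNA sequence over {A,C,G,U}."""

    bases: str
    id: str = ""

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise SequenceError("empty sequence")
        for pos, ch in enumerate(self.bases):
            if ch not in BASE_INDEX:
                raise SequenceError(
                    f"invalid base {ch!r} at position {pos} in sequence {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def gc_fraction(self) -> float:
        n_gc = sum(1 for b in self.bases if b in "GC")
        return n_gc / len(self.bases)


@dataclass(frozen=True)
class PairRecord:
    """One labeled (or unlabeled, in prediction mode) piRNA / target-site pair."""

    pirna: RnaSequence
    site: RnaSequence
    label: int | None = None
    id: str = ""

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass(frozen=True)
class LengthPolicy:
    """Fixed grid lengths: L_p for the piRNA axis, L_m for the site axis.

    Both must be >= 2 because the positional channel normalizes by L - 1.
    """

    L_p: int
    L_m: int

    def __post_init__(self) -> None:
        if self.L_p < 2 or self.L_m < 2:
            raise ValueError("length policy requires L_p >= 2 and L_m >= 2")


@dataclass
class DatasetStats:
    """Per-class descriptive statistics (lengths and GC content)."""

    label: int
    n: int
    mean_pirna_len: float
    mean_site_len: float
    mean_pirna_gc: float
    mean_site_gc: float


def clean_sequence(raw: str, id: str = "") -> RnaSequence:
    """Uppercase, map T->U, and validate against {A,C,G,U}.

    Ambiguity codes (N, R, ...) are rejected with the position of the first
    offending character rather than coerced.
    """
    s = raw.strip().upper().replace("T", "U")
    if not s:
        raise SequenceError("empty sequence after stripping whitespace")
    for pos, ch in enumerate(s):
        if ch not in BASE_INDEX:
            raise SequenceError(
                f"invalid character {ch!r} at position {pos} in sequence {id!r}"
            )
    return RnaSequence(bases=s, id=id)


def fit_length_policy(records: Sequence[PairRecord],
                      L_p: int | None = None,
                      L_m: int | None = None) -> LengthPolicy:
    """Maximum cleaned lengths observed in the dataset, overridable per axis."""
    if not records:
        raise ValueError("cannot fit a length policy on an empty collection")
    if L_p is None:
        L_p = max(len(r.pirna) for r in records)
    if L_m is None:
        L_m = max(len(r.site) for r in records)
    return LengthPolicy(L_p=L_p, L_m=L_m)


def pad_or_truncate(seq: RnaSequence | str, L: int) -> str:
    """Right-pad with the sentinel or truncate to the 5' prefix, to length L."""
    if L < 1:
        raise ValueError("target length must be >= 1")
    bases = seq.bases if isinstance(seq, RnaSequence) else seq
    if len(bases) >= L:
        return bases[:L]
    return bases + PAD * (L - len(bases))


def one_hot(padded: str, L: int | None = None) -> np.ndarray:
    """L x 4 one-hot matrix (columns A,C,G,U); sentinel rows are all zero."""
    if L is not None and len(padded) != L:
        raise ValueError(f"expected length {L}, got {len(padded)}")
    out = np.zeros((len(padded), 4), dtype=np.float32)
    for i, ch in enumerate(padded):
        j = BASE_INDEX.get(ch)
        if j is not None:
            out[i, j] = 1.0
    return out


# ---------------------------------------------------------------------------
# pair tables
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("pirna_seq", "site_seq")
OPTIONAL_COLUMNS = ("label", "id")


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_pairs(path, site_fasta=None) -> list[PairRecord]:
    """Read labeled pairs from a delimited table, or from two FASTA files.

    Delimited mode (default): a header row with columns ``pirna_seq``,
    ``site_seq`` and optional ``label`` / ``id``; comma or tab delimiter is
    auto-detected from the header line.

    FASTA-pair mode (``site_fasta`` given): ``path`` holds the piRNA records
    and ``site_fasta`` the site records, paired by record order; the result
    carries no labels (prediction mode).
    """
    if site_fasta is not None:
        return _read_fasta_pairs(path, site_fasta)

    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise ValueError(f"empty pair table: {path}")
        delim = _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        cols = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in cols]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        records: list[PairRecord] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                rid = (row.get("id") or f"pair{lineno - 2}").strip()
                pirna = clean_sequence(row["pirna_seq"])
                site = clean_sequence(row["site_seq"])
                raw_label = (row.get("label") or "").strip()
                label = int(raw_label) if raw_label != "" else None
                records.append(PairRecord(pirna=pirna, site=site,
                                          label=label, id=rid))
            except (SequenceError, ValueError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}: unreadable row at line {lineno}: {exc}")
    if not records:
        raise ValueError(f"no records in pair table: {path}")
    return records


def _read_fasta_pairs(pirna_fasta, site_fasta) -> list[PairRecord]:
    from Bio import SeqIO

    pirnas = list(SeqIO.parse(str(pirna_fasta), "fasta"))
    sites = list(SeqIO.parse(str(site_fasta), "fasta"))
    if len(pirnas) != len(sites):
        raise ValueError(
            f"FASTA files differ in record count: {len(pirnas)} vs {len(sites)}"
        )
    records = []
    for i, (p, m) in enumerate(zip(pirnas, sites)):
        rid = p.id or f"pair{i}"
        records.append(PairRecord(
            pirna=clean_sequence(str(p.seq), id=p.id),
            site=clean_sequence(str(m.seq), id=m.id),
            label=None, id=rid))
    return records


def write_pairs(records: Iterable[PairRecord], path, delimiter: str = "\t") -> None:
    """Write records as a delimited pair table (round-trips with read_pairs)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["id", "pirna_seq", "site_seq", "label"])
        for r in records:
            writer.writerow([r.id, r.pirna.bases, r.site.bases,
                             "" if r.label is None else r.label])


def describe_dataset(records: Sequence[PairRecord]) -> dict[int, DatasetStats]:
    """Per-class n, mean lengths and mean GC fraction on cleaned sequences."""
    if any(r.label is None for r in records):
        raise ValueError("describe_dataset requires labeled records")
    out: dict[int, DatasetStats] = {}
    for label in sorted({r.label for r in records}):
        sub = [r for r in records if r.label == label]
        out[label] = DatasetStats(
            label=label,
            n=len(sub),
            mean_pirna_len=float(np.mean([len(r.pirna) for r in sub])),
            mean_site_len=float(np.mean([len(r.site) for r in sub])),
            mean_pirna_gc=float(np.mean([r.pirna.gc_fraction for r in sub])),
            mean_site_gc=float(np.mean([r.site.gc_fraction for r in sub])),
        )
    return out
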