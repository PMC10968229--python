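"""Readers, writers and validation for CAID-style benchmark files.

Two file dialects are supported, both plain text or gzip-compressed:

* **Reference channel files** — FASTA-like three-line records::

      >P12345
      MKVLAT...
      0011100...

  The third line assigns one character per residue: ``1`` (positive for the
  channel), ``0`` (negative) or ``-`` (unknown / not assessed).  Two channels
  exist: LINKER (is the residue inside a disordered flexible linker?) and
  DISORDER (is the residue intrinsically disordered?).

* **Prediction files** — one block per protein: a ``>`` header followed by one
  tab-separated line per residue with the 1-based residue index, the amino
  acid letter, a propensity in [0, 1] and an optional binary call.  The binary
  column is parsed and retained but all downstream metrics binarize the
  propensities themselves.

Residue indices are 1-based on disk and 0-based in memory.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class ParseError(ValueError):
    """Raised when a reference or prediction file violates the dialect."""


class Channel(str, Enum):
    LINKER = "linker"
    DISORDER = "disorder"


class ResidueLabel(IntEnum):
    """Merged per-residue ground truth.

    ``DL`` residues are, by definition, also disordered: any computation of
    disorder content must count both ``DL`` and ``DISORDERED_OTHER``.
    """

    UNKNOWN = -1
    ORDERED = 0
    DISORDERED_OTHER = 1
    DL = 2


#: raw channel encoding: 1 / 0 / -1 (for "-")
RAW_UNKNOWN = -1


@dataclass(frozen=True)
class RawRecord:
    """One protein from a single reference channel, as read from disk."""

    protein_id: str
    sequence: str
    labels: np.ndarray  # int8 over {1, 0, -1}

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequence):
            raise ParseError(
                f"{self.protein_id}: label line length {len(self.labels)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class ReferenceEntry:
    """One protein with merged per-residue ground truth labels."""

    protein_id: str
    sequence: str
    residue_labels: np.ndarray  # int8 over ResidueLabel values

    def __post_init__(self) -> None:
        if len(self.residue_labels) != len(self.sequence):
            raise ValueError(
                f"{self.protein_id}: {len(self.residue_labels)} labels for "
                f"{len(self.sequence)} residues"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def has_dl(self) -> bool:
        return bool(np.any(self.residue_labels == ResidueLabel.DL))


@dataclass
class PredictionSet:
    """Per-residue propensities of one method, keyed by protein id.

    Proteins absent from ``scores`` were not predicted by the method and
    count against its coverage.
    """

    method_name: str
    scores: dict[str, np.ndarray] = field(default_factory=dict)
    binary: dict[str, np.ndarray] = field(default_factory=dict)

    def predicts(self, protein_id: str) -> bool:
        return protein_id in self.scores


@dataclass
class Dataset:
    """A merged reference plus the prediction sets under evaluation."""

    entries: list[ReferenceEntry]
    predictions: list[PredictionSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.protein_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate protein ids in reference")
        known = set(ids)
        for p in self.predictions:
            extra = set(p.scores) - known
            if extra:
                raise ValueError(
                    f"{p.method_name}: predictions for unknown proteins {sorted(extra)[:5]}"
                )

    @property
    def protein_ids(self) -> list[str]:
        return [e.protein_id for e in self.entries]

    @property
    def method_names(self) -> list[str]:
        return [p.method_name for p in self.predictions]

    def entry(self, protein_id: str) -> ReferenceEntry:
        for e in self.entries:
            if e.protein_id == protein_id:
                return e
        raise KeyError(protein_id)


# ---------------------------------------------------------------------------
# low-level text access
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, mode)
    elif path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _iter_nonempty(lines: Iterable[str]) -> Iterator[str]:
    for line in lines:
        line = line.rstrip("\n").rstrip("\r")
        if line.strip():
            yield line


# ---------------------------------------------------------------------------
# reference channels
# ---------------------------------------------------------------------------

_RAW_MAP = {"1": 1, "0": 0, "-": RAW_UNKNOWN}


def read_reference(path: str | Path, channel: Channel | str = Channel.LINKER) -> list[RawRecord]:
    """Read one reference channel file into raw {1, 0, unknown} records.

    Records are three lines each (header, sequence, labels); order on disk is
    preserved.  Raises :class:`ParseError` on length mismatches or duplicate
    protein ids.
    """
    channel = Channel(channel)
    records: list[RawRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        lines = list(_iter_nonempty(fh))
    i = 0
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">"):
            raise ParseError(f"{path}: expected '>' header, got {header[:30]!r}")
        protein_id = header[1:].split()[0]
        if protein_id in seen:
            raise ParseError(f"{path}: duplicate protein id {protein_id}")
        seen.add(protein_id)
        if i + 2 >= len(lines):
            raise ParseError(f"{path}: truncated record for {protein_id}")
        sequence, label_line = lines[i + 1], lines[i + 2]
        try:
            labels = np.array([_RAW_MAP[c] for c in label_line], dtype=np.int8)
        except KeyError as exc:
            raise ParseError(
                f"{protein_id}: invalid label character {exc.args[0]!r} "
                f"(channel {channel.value})"
            ) from None
        records.append(RawRecord(protein_id, sequence, labels))
        i += 3
    return records


def write_reference(records: Sequence[RawRecord], path: str | Path) -> None:
    """Write raw channel records in the three-line dialect (gzip if ``*.gz``)."""
    rev = {1: "1", 0: "0", RAW_UNKNOWN: "-"}
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n{rec.sequence}\n")
            fh.write("".join(rev[int(v)] for v in rec.labels) + "\n")


def merge_channels(
    linker: Sequence[RawRecord],
    disorder: Sequence[RawRecord] | None,
) -> list[ReferenceEntry]:
    """Resolve the linker and disorder channels into merged residue labels.

    Per residue: linker=1 -> DL; linker=0, disorder=1 -> DISORDERED_OTHER;
    linker=0, disorder=0 -> ORDERED; "-" in either channel -> UNKNOWN.  A
    residue with linker=1 but disorder=0 is kept as DL (the linker annotation
    is the evaluation's ground truth) and the inconsistency is logged.

    ``disorder=None`` treats every non-DL residue as ordered; scenarios that
    need the other-disordered class will then have no negatives.
    """
    by_id = {r.protein_id: r for r in disorder} if disorder is not None else None
    if by_id is not None:
        linker_ids = {r.protein_id for r in linker}
        if set(by_id) != linker_ids:
            only_l = sorted(linker_ids - set(by_id))
            only_d = sorted(set(by_id) - linker_ids)
            raise ParseError(
                f"channel protein sets differ (linker-only: {only_l[:5]}, "
                f"disorder-only: {only_d[:5]})"
            )
    entries = []
    for lrec in linker:
        if by_id is None:
            dis = np.zeros(len(lrec.sequence), dtype=np.int8)
        else:
            drec = by_id[lrec.protein_id]
            if len(drec.labels) != len(lrec.labels):
                raise ParseError(f"{lrec.protein_id}: channel lengths differ")
            if drec.sequence != lrec.sequence:
                raise ParseError(f"{lrec.protein_id}: channel sequences differ")
            dis = drec.labels
        lnk = lrec.labels
        out = np.full(len(lnk), int(ResidueLabel.ORDERED), dtype=np.int8)
        out[dis == 1] = int(ResidueLabel.DISORDERED_OTHER)
        out[lnk == 1] = int(ResidueLabel.DL)
        out[(lnk == RAW_UNKNOWN) | (dis == RAW_UNKNOWN)] = int(ResidueLabel.UNKNOWN)
        n_conflict = int(np.sum((lnk == 1) & (dis == 0)))
        if n_conflict:
            logger.warning(
                "%s: %d residue(s) annotated as linker but not disordered; kept as DL",
                lrec.protein_id,
                n_conflict,
            )
        entries.append(ReferenceEntry(lrec.protein_id, lrec.sequence, out))
    return entries


def channel_records(entries: Sequence[ReferenceEntry], channel: Channel | str) -> list[RawRecord]:
    """Project merged entries back onto one raw channel (inverse of merge)."""
    channel = Channel(channel)
    out = []
    for e in entries:
        lab = e.residue_labels
        if channel is Channel.LINKER:
            raw = (lab == ResidueLabel.DL).astype(np.int8)
        else:
            raw = ((lab == ResidueLabel.DL) | (lab == ResidueLabel.DISORDERED_OTHER)).astype(np.int8)
        raw[lab == ResidueLabel.UNKNOWN] = RAW_UNKNOWN
        out.append(RawRecord(e.protein_id, e.sequence, raw))
    return out


# ---------------------------------------------------------------------------
# predictions
# ---------------------------------------------------------------------------

def read_predictions(
    path: str | Path,
    method_name: str | None = None,
    reference: Sequence[ReferenceEntry] | None = None,
) -> PredictionSet:
    """Read one method's CAID-style prediction file.

    Residue indices must be contiguous 1..L; propensities must lie in [0, 1];
    with a ``reference``, residue letters and lengths are validated against
    it.  Errors name the protein and the 1-based position.
    """
    path = Path(path)
    if method_name is None:
        method_name = path.name.split(".")[0]
    ref_by_id = {e.protein_id: e for e in reference} if reference is not None else None

    scores: dict[str, np.ndarray] = {}
    binary: dict[str, np.ndarray] = {}
    cur_id: str | None = None
    cur_scores: list[float] = []
    cur_binary: list[int] = []
    cur_has_binary = False

    def flush() -> None:
        nonlocal cur_id, cur_scores, cur_binary, cur_has_binary
        if cur_id is None:
            return
        if ref_by_id is not None:
            ref = ref_by_id.get(cur_id)
            if ref is None:
                raise ParseError(f"{path}: predicted protein {cur_id} not in reference")
            if len(cur_scores) != ref.length:
                raise ParseError(
                    f"{cur_id}: {len(cur_scores)} predicted residues, reference has {ref.length}"
                )
        if cur_id in scores:
            raise ParseError(f"{path}: duplicate prediction block for {cur_id}")
        scores[cur_id] = np.asarray(cur_scores, dtype=np.float64)
        if cur_has_binary:
            binary[cur_id] = np.asarray(cur_binary, dtype=np.int8)
        cur_id, cur_scores, cur_binary, cur_has_binary = None, [], [], False

    with _open_text(path) as fh:
        for line in _iter_nonempty(fh):
            if line.startswith(">"):
                flush()
                cur_id = line[1:].split()[0]
                continue
            if cur_id is None:
                raise ParseError(f"{path}: residue line before any '>' header")
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"{cur_id}: malformed residue line {line!r}")
            idx = int(parts[0])
            if idx != len(cur_scores) + 1:
                raise ParseError(
                    f"{cur_id}: non-contiguous residue index {idx} at position "
                    f"{len(cur_scores) + 1}"
                )
            aa, prop = parts[1], float(parts[2])
            if not 0.0 <= prop <= 1.0:
                raise ParseError(f"{cur_id}: propensity {prop} outside [0, 1] at position {idx}")
            if ref_by_id is not None:
                ref = ref_by_id.get(cur_id)
                if ref is not None and idx <= ref.length and ref.sequence[idx - 1] != aa:
                    raise ParseError(
                        f"{cur_id}: residue letter {aa!r} at position {idx} does not "
                        f"match reference {ref.sequence[idx - 1]!r}"
                    )
            cur_scores.append(prop)
            if len(parts) >= 4:
                cur_has_binary = True
                cur_binary.append(int(parts[3]))
            else:
                cur_binary.append(0)
    flush()
    return PredictionSet(method_name, scores, binary)


def write_predictions(
    predset: PredictionSet,
    path: str | Path,
    reference: Sequence[ReferenceEntry],
) -> None:
    """Write a prediction set in the CAID tab-separated dialect."""
    ref_by_id = {e.protein_id: e for e in reference}
    with _open_text(Path(path), "wt") as fh:
        for pid in ref_by_id:
            if pid not in predset.scores:
                continue
            fh.write(f">{pid}\n")
            seq = ref_by_id[pid].sequence
            vals = predset.scores[pid]
            calls = predset.binary.get(pid)
            for i, v in enumerate(vals):
                if calls is not None:
                    fh.write(f"{i + 1}\t{seq[i]}\t{v:.3f}\t{int(calls[i])}\n")
                else:
                    fh.write(f"{i + 1}\t{seq[i]}\t{v:.3f}\n")


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def coverage(predset: PredictionSet, entries: Sequence[ReferenceEntry]) -> float:
    """Fraction of reference proteins with a complete score vector.

    A protein with a partial (wrong-length) score vector counts as
    unpredicted: mixing residue subsets across methods would make the
    comparisons incommensurable.
    """
    if not entries:
        raise ValueError("empty reference")
    n_ok = sum(
        1
        for e in entries
        if e.protein_id in predset.scores and len(predset.scores[e.protein_id]) == e.length
    )
    return n_ok / len(entries)


def filter_by_coverage(dataset: Dataset, threshold: float = 0.9) -> Dataset:
    """Drop methods whose coverage is strictly below ``threshold``.

    A method at exactly the threshold is retained (the rule excludes methods
    *below* 90%).  Removed method names are logged.
    """
    kept, removed = [], []
    for p in dataset.predictions:
        if coverage(p, dataset.entries) >= threshold:
            kept.append(p)
        else:
            removed.append(p.method_name)
    if removed:
        logger.info("coverage filter removed %d method(s): %s", len(removed), ", ".join(removed))
    return Dataset(entries=dataset.entries, predictions=kept)
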