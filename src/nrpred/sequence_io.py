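"""Reading, validating and writing protein sequence data and predictions.

FASTA dialect: ``>`` headers, arbitrary line wrapping, ``;`` comment lines
ignored.  Class labels for training files can come from a ``|``-delimited
final header field (``>Q12345|NR1``) or from a sidecar two-column TSV.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO

from .errors import (
    DuplicateIdentifierError,
    InputError,
    TooShortError,
)

logger = logging.getLogger(__name__)

#: The 20 canonical one-letter amino acid codes, alphabetical; this ordering
#: indexes every composition vector in the package.
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Recognised class tags: seven nuclear-receptor subfamilies plus the
#: non-receptor background class.  Synthetic fixtures may extend the NR range.
LABEL_PATTERN = re.compile(r"^(NR\d+|NONNR)$")

#: Minimum validated sequence length.  The Fourier block needs 10 distinct
#: non-constant frequency components of an L-point transform, so L >= 21.
DEFAULT_MIN_LENGTH = 21


@dataclass(frozen=True)
class ProteinRecord:
    """One identified amino acid sequence with an optional class label."""

    identifier: str
    sequence: str
    label: Optional[str] = None


@dataclass(frozen=True)
class PredictionResult:
    """Two-level prediction for one query."""

    identifier: str
    level1_label: str
    level1_membership: float
    level2_label: Optional[str] = None
    level2_membership: Optional[float] = None


def _split_header_label(token: str) -> tuple[str, Optional[str]]:
    """Split a ``|``-delimited trailing class tag off a header token."""
    if "|" in token:
        head, _, tail = token.rpartition("|")
        if LABEL_PATTERN.match(tail):
            return head, tail
    return token, None


def read_fasta(path) -> list[ProteinRecord]:
    """Read a (multi-)FASTA file into a list of :class:`ProteinRecord`.

    The header text up to the first whitespace becomes the identifier; a
    trailing ``|LABEL`` field on that token, when it matches a known class
    tag, is stripped off and stored as the record label.

    Raises
    ------
    InputError
        If the file is unreadable or contains no entries.
    DuplicateIdentifierError
        If two entries share an identifier.
    """
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise InputError(f"cannot read FASTA file {path!r}: {exc}") from exc
    # drop ';' comment lines before handing the text to the parser
    cleaned = "\n".join(
        line for line in text.splitlines() if not line.startswith(";")
    )
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(io.StringIO(cleaned), "fasta"):
        identifier, label = _split_header_label(entry.id)
        if identifier in seen:
            raise DuplicateIdentifierError(
                f"duplicate identifier {identifier!r} in {path!r}"
            )
        seen.add(identifier)
        records.append(ProteinRecord(identifier, str(entry.seq), label))
    if not records:
        raise InputError(f"no FASTA entries found in {path!r}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path) -> None:
    """Write records to FASTA; labels are appended as ``|LABEL`` header fields."""
    try:
        with open(path, "w") as handle:
            for rec in records:
                header = rec.identifier
                if rec.label is not None:
                    header = f"{header}|{rec.label}"
                handle.write(f">{header}\n")
                for start in range(0, len(rec.sequence), 60):
                    handle.write(rec.sequence[start : start + 60] + "\n")
    except OSError as exc:
        raise InputError(f"cannot write FASTA file {path!r}: {exc}") from exc


def read_label_table(path) -> dict[str, str]:
    """Read a two-column (identifier, label) TSV into a mapping."""
    mapping: dict[str, str] = {}
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise InputError(f"cannot read label table {path!r}: {exc}") from exc
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise InputError(f"{path!r}:{lineno}: expected two tab-separated columns")
        mapping[parts[0].strip()] = parts[1].strip()
    if not mapping:
        raise InputError(f"no label rows found in {path!r}")
    return mapping


def apply_labels(
    records: Sequence[ProteinRecord], labels: Mapping[str, str]
) -> list[ProteinRecord]:
    """Attach labels from a mapping; identifiers missing from it keep their label."""
    return [
        replace(rec, label=labels.get(rec.identifier, rec.label)) for rec in records
    ]


def validate_record(
    record: ProteinRecord, min_length: int = DEFAULT_MIN_LENGTH
) -> ProteinRecord:
    """Return a cleaned record: upper-cased, non-canonical residues removed.

    Characters outside the 20-letter alphabet (X, B, Z, U, ``*``, gaps, ...)
    are removed — every descriptor is defined only over the native residue
    types — and a warning with counts is logged.  Idempotent.

    Raises
    ------
    TooShortError
        If the cleaned sequence is shorter than ``min_length``.
    """
    upper = record.sequence.upper()
    kept = [c for c in upper if c in CANONICAL_RESIDUES]
    n_removed = len(upper) - len(kept)
    if n_removed:
        logger.warning(
            "%s: removed %d non-canonical character(s)", record.identifier, n_removed
        )
    cleaned = "".join(kept)
    if len(cleaned) < min_length:
        raise TooShortError(
            f"{record.identifier}: validated length {len(cleaned)} < "
            f"minimum {min_length}"
        )
    return replace(record, sequence=cleaned)


def validate_records(
    records: Iterable[ProteinRecord], min_length: int = DEFAULT_MIN_LENGTH
) -> tuple[list[ProteinRecord], list[tuple[ProteinRecord, TooShortError]]]:
    """Validate a batch, collecting rejects instead of aborting."""
    kept: list[ProteinRecord] = []
    rejected: list[tuple[ProteinRecord, TooShortError]] = []
    for rec in records:
        try:
            kept.append(validate_record(rec, min_length))
        except TooShortError as exc:
            logger.warning("rejected record: %s", exc)
            rejected.append((rec, exc))
    return kept, rejected


def write_predictions(results: Sequence[PredictionResult], path) -> None:
    """Write prediction results as a TSV table, one row per query in order."""
    if not results:
        raise InputError("no prediction results to write")
    try:
        with open(path, "w") as handle:
            handle.write(
                "identifier\tlevel1_label\tlevel1_membership\t"
                "level2_label\tlevel2_membership\n"
            )
            for res in results:
                l2 = res.level2_label if res.level2_label is not None else ""
                l2m = (
                    f"{res.level2_membership:.6f}"
                    if res.level2_membership is not None
                    else ""
                )
                handle.write(
                    f"{res.identifier}\t{res.level1_label}\t"
                    f"{res.level1_membership:.6f}\t{l2}\t{l2m}\n"
                )
    except OSError as exc:
        raise InputError(f"cannot write predictions to {path!r}: {exc}") from exc
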