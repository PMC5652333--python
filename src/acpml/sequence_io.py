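"""Reading, validating, normalising and writing peptide sequences.

Peptides are short (typically 5-50 residue) sequences over the 20 standard
amino acids. Input arrives as FASTA; records whose sequences contain
non-standard residues (ambiguity codes B/J/O/U/X/Z, gaps, digits, ...) are
collected into a rejection list with a reason rather than silently dropped,
so curation counts stay reproducible.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, TextIO, Union

logger = logging.getLogger("acpml")

#: The 20 standard amino acids, alphabetical one-letter order. This order is
#: frozen: every feature block indexes into it.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

Source = Union[str, Path, TextIO]


class FastaParseError(ValueError):
    """Structurally malformed FASTA (e.g. sequence data before any header)."""


class SequenceError(ValueError):
    """A sequence that fails validation; ``str(err)`` is the reason."""


@dataclass(frozen=True)
class Peptide:
    """A validated peptide: identifier, uppercase sequence, optional label.

    ``label`` is 1 for an anticancer peptide (ACP), 0 for non-ACP, ``None``
    when unknown (query peptides).
    """

    id: str
    seq: str
    label: Optional[int] = None

    def __len__(self) -> int:
        return len(self.seq)

    def with_label(self, label: Optional[int]) -> "Peptide":
        return Peptide(self.id, self.seq, label)


@dataclass(frozen=True)
class RejectedRecord:
    """A FASTA record that failed sequence validation."""

    id: str
    seq: str
    reason: str


def validate_sequence(raw: str) -> str:
    """Normalise ``raw`` to uppercase and check it against the 20-letter
    standard alphabet.

    Returns the normalised sequence or raises :class:`SequenceError` naming
    the first offending character and its 1-based position. Whitespace is
    stripped from both ends first; an empty result is rejected.
    """
    seq = raw.strip().upper()
    if not seq:
        raise SequenceError("empty sequence")
    for pos, char in enumerate(seq, start=1):
        if char not in _AA_SET:
            raise SequenceError(
                f"non-standard residue {char!r} at position {pos}"
            )
    return seq


def _as_text_stream(source: Source) -> TextIO:
    if isinstance(source, io.TextIOBase):
        return source
    if hasattr(source, "read"):  # file-like duck type
        return source  # type: ignore[return-value]
    path = Path(source)
    if path.exists():
        return path.open()
    if isinstance(source, str) and (source.startswith(">") or "\n" in source):
        return io.StringIO(source)
    raise FileNotFoundError(f"no such FASTA file: {source}")


def read_fasta(source: Source) -> tuple[list[Peptide], list[RejectedRecord]]:
    """Parse FASTA text into validated peptides.

    ``source`` may be a path, an open text stream, or FASTA text itself.
    Multi-line sequence bodies are concatenated; case is normalised to
    upper. Returns ``(accepted, rejected)``; every record in the input ends
    up in exactly one of the two lists.

    Raises :class:`FastaParseError` if sequence data precedes any header,
    naming the offending line number.
    """
    stream = _as_text_stream(source)
    accepted: list[Peptide] = []
    rejected: list[RejectedRecord] = []
    header: Optional[str] = None
    chunks: list[str] = []

    def flush() -> None:
        assert header is not None
        raw = "".join(chunks)
        try:
            accepted.append(Peptide(header, validate_sequence(raw)))
        except SequenceError as err:
            rejected.append(RejectedRecord(header, raw.strip().upper(), str(err)))

    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                flush()
            header = line[1:].strip()
            chunks = []
        else:
            if header is None:
                raise FastaParseError(
                    f"line {lineno}: sequence data before any '>' header"
                )
            chunks.append(line)
    if header is not None:
        flush()
    return accepted, rejected


def write_fasta(peptides: Iterable[Peptide], sink: Source) -> None:
    """Write peptides as FASTA, one sequence line per record.

    Duplicate identifiers are written as-is with a logged warning — the
    original records may legitimately share a name and merging would change
    curation counts.
    """
    peptides = list(peptides)
    seen: set[str] = set()
    for p in peptides:
        if p.id in seen:
            logger.warning("duplicate FASTA id written: %s", p.id)
        seen.add(p.id)
    own = not hasattr(sink, "write")
    stream = Path(sink).open("w") if own else sink  # type: ignore[arg-type]
    try:
        for p in peptides:
            stream.write(f">{p.id}\n{p.seq}\n")
    finally:
        if own:
            stream.close()


def write_rejection_report(
    rejected: Iterable[RejectedRecord], sink: Source
) -> None:
    """Write a TSV rejection report: id, reason."""
    own = not hasattr(sink, "write")
    stream = Path(sink).open("w") if own else sink  # type: ignore[arg-type]
    try:
        stream.write("id\treason\n")
        for rec in rejected:
            stream.write(f"{rec.id}\t{rec.reason}\n")
    finally:
        if own:
            stream.close()


def read_labels(source: Source) -> dict[str, int]:
    """Read a two-column TSV (id, label) into a mapping. A header row with
    the literal column names ``id``/``label`` is tolerated."""
    stream = _as_text_stream(source)
    labels: dict[str, int] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"labels line {lineno}: expected 2 columns")
        if lineno == 1 and fields[1].lower() == "label":
            continue
        labels[fields[0]] = int(fields[1])
    return labels


def write_labels(peptides: Iterable[Peptide], sink: Source) -> None:
    """Write a TSV of peptide ids and their binary labels."""
    own = not hasattr(sink, "write")
    stream = Path(sink).open("w") if own else sink  # type: ignore[arg-type]
    try:
        stream.write("id\tlabel\n")
        for p in peptides:
            if p.label is None:
                raise ValueError(f"peptide {p.id} has no label")
            stream.write(f"{p.id}\t{p.label}\n")
    finally:
        if own:
            stream.close()


def attach_labels(
    peptides: Iterable[Peptide], labels: dict[str, int]
) -> list[Peptide]:
    """Return peptides with labels looked up by id; missing id is an error."""
    out = []
    for p in peptides:
        if p.id not in labels:
            raise KeyError(f"no label for peptide {p.id}")
        out.append(p.with_label(int(labels[p.id])))
    return out
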