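"""Reading, validating and cleaning biological sequence corpora.

Sequences are treated as boundary-free character streams over a fixed
alphabet (DNA or protein).  Cleaning maps non-standard residue letters to a
single unknown-marker character so that downstream vocabularies stay closed,
and gap characters can be stripped from pre-aligned inputs.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

#: Characters accepted as alignment gaps (ASCII hyphen and en-dash).
GAP_CHARS = ("-", "–")

#: Single marker used for any non-standard residue after cleaning.
UNKNOWN_CHAR = "?"

DNA_CHARS = "ACGT"
PROTEIN_CHARS = "ACDEFGHIKLMNPQRSTVWY"

# Non-standard letters mapped to the unknown marker at cleaning time.
DNA_AMBIGUOUS = set("BDHKMNRSVWY")
PROTEIN_AMBIGUOUS = set("BJOUXZ")


class CorpusError(ValueError):
    """Raised for malformed input files or invalid corpora."""


@dataclass(frozen=True)
class Alphabet:
    """A fixed residue alphabet.

    Parameters
    ----------
    kind:
        Either ``"DNA"`` or ``"protein"``.
    characters:
        Ordered tuple of allowed uppercase characters.
    """

    kind: str
    characters: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("DNA", "protein"):
            raise ValueError(f"unknown alphabet kind {self.kind!r}")
        if len(set(self.characters)) != len(self.characters):
            raise ValueError("alphabet characters must be unique")
        expected = 4 if self.kind == "DNA" else 20
        if len(self.characters) != expected:
            raise ValueError(
                f"{self.kind} alphabet must have {expected} characters, "
                f"got {len(self.characters)}"
            )
        for c in self.characters:
            if len(c) != 1 or not c.isupper():
                raise ValueError(f"invalid alphabet character {c!r}")

    def __contains__(self, ch: str) -> bool:
        return ch in self.characters

    @property
    def ambiguous(self) -> set[str]:
        return DNA_AMBIGUOUS if self.kind == "DNA" else PROTEIN_AMBIGUOUS


DNA = Alphabet("DNA", tuple(DNA_CHARS))
PROTEIN = Alphabet("protein", tuple(PROTEIN_CHARS))


@dataclass
class SeqRecord:
    """One identified sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")


@dataclass
class Corpus:
    """An ordered collection of sequence records over one alphabet."""

    records: list[SeqRecord] = field(default_factory=list)
    alphabet: Alphabet | None = None

    @property
    def N(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SeqRecord]:
        return iter(self.records)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> Corpus:
    """Read a FASTA file into a :class:`Corpus`.

    Sequences are uppercased on read; record order is preserved.  Multi-line
    and single-line sequence dialects are both accepted and blank lines are
    ignored.  Plain-gzip files (``.gz``) are decompressed transparently.

    Raises
    ------
    CorpusError
        If the file is empty, has content before the first ``>`` header, or
        contains a record with an empty sequence (the offending header line
        number is reported).
    """
    path = Path(path)
    header_lines: list[int] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                header_lines.append(lineno)
            elif not header_lines:
                raise CorpusError(
                    f"{path}: line {lineno}: sequence data before first '>' header"
                )
    if not header_lines:
        raise CorpusError(f"{path}: no FASTA records found")

    records: list[SeqRecord] = []
    with _open_text(path) as handle:
        for idx, (title, seq) in enumerate(SimpleFastaParser(handle)):
            rec_id = title.split()[0] if title.split() else ""
            if not rec_id:
                raise CorpusError(
                    f"{path}: line {header_lines[idx]}: record with empty header"
                )
            if not seq:
                raise CorpusError(
                    f"{path}: line {header_lines[idx]}: record {rec_id!r} "
                    "has an empty sequence"
                )
            records.append(SeqRecord(rec_id, seq.upper()))
    return Corpus(records=records)


def write_fasta(corpus: Corpus, path: str | Path, width: int = 60) -> None:
    """Write a corpus to FASTA, wrapping sequence lines at ``width``."""
    with open(path, "wt") as handle:
        for rec in corpus.records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def strip_gaps(corpus: Corpus) -> Corpus:
    """Remove gap characters from every sequence.

    Both the ASCII hyphen ``-`` and the typographic en-dash are removed.
    Records whose sequence becomes empty are dropped with a logged warning.
    Idempotent.
    """
    table = str.maketrans({g: None for g in GAP_CHARS})
    records = []
    for rec in corpus.records:
        seq = rec.sequence.translate(table)
        if not seq:
            logger.warning("record %r became empty after gap stripping; dropped", rec.id)
            continue
        records.append(SeqRecord(rec.id, seq))
    return Corpus(records=records, alphabet=corpus.alphabet)


def detect_alphabet(corpus: Corpus) -> Alphabet:
    """Infer the alphabet of a corpus from its observed characters.

    Returns :data:`DNA` when every character is one of A, C, G, T; otherwise
    :data:`PROTEIN` when every character is a standard amino-acid letter (the
    unknown marker is always permitted).  Note that a DNA sequence containing
    IUPAC ambiguity codes may legitimately look like protein under this rule;
    pass an explicit alphabet to :func:`clean` to override.

    Raises
    ------
    CorpusError
        If the corpus is empty, or characters outside both alphabets are
        present (the offending characters are listed).
    """
    if corpus.N == 0:
        raise CorpusError("cannot detect alphabet of an empty corpus")
    observed: set[str] = set()
    for rec in corpus.records:
        observed.update(rec.sequence)
    observed.discard(UNKNOWN_CHAR)
    if observed <= set(DNA_CHARS):
        return DNA
    if observed <= set(PROTEIN_CHARS):
        return PROTEIN
    bad = sorted(observed - set(PROTEIN_CHARS) - set(DNA_CHARS))
    raise CorpusError(
        "characters outside both the DNA and protein alphabets: "
        + ", ".join(repr(c) for c in bad)
    )


def clean(corpus: Corpus, alphabet: Alphabet | None = None) -> Corpus:
    """Uppercase sequences and map non-standard residues to the unknown marker.

    Recognised ambiguity codes (IUPAC DNA codes; B, J, O, U, X, Z for
    proteins) become :data:`UNKNOWN_CHAR`; anything else raises.  When no
    alphabet is given it is detected after substitution of nothing, i.e. from
    the standard characters present.
    """
    if alphabet is None:
        # Detect from characters that are unambiguous under either alphabet.
        probe = Corpus(
            records=[
                SeqRecord(r.id, "".join(c for c in r.sequence.upper() if c not in
                                        (DNA_AMBIGUOUS | PROTEIN_AMBIGUOUS)) or "A")
                for r in corpus.records
            ]
        )
        alphabet = detect_alphabet(probe)
    allowed = set(alphabet.characters)
    mapped = alphabet.ambiguous
    records = []
    for rec in corpus.records:
        out = []
        for c in rec.sequence.upper():
            if c in allowed or c == UNKNOWN_CHAR:
                out.append(c)
            elif c in mapped:
                out.append(UNKNOWN_CHAR)
            else:
                raise CorpusError(
                    f"record {rec.id!r}: character {c!r} is not a {alphabet.kind} "
                    "residue or recognised ambiguity code"
                )
        records.append(SeqRecord(rec.id, "".join(out)))
    return Corpus(records=records, alphabet=alphabet)


def from_sequences(
    sequences: Iterable[str],
    alphabet: Alphabet | None = None,
    ids: Sequence[str] | None = None,
) -> Corpus:
    """Build a corpus from raw strings (convenience constructor)."""
    seqs = list(sequences)
    if ids is None:
        ids = [f"seq{i}" for i in range(len(seqs))]
    return Corpus(
        records=[SeqRecord(i, s.upper()) for i, s in zip(ids, seqs)],
        alphabet=alphabet,
    )
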