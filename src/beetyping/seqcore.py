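"""DNA alphabet, IUPAC semantics, FASTA I/O and translation QC.

All coordinates in this package are 1-based and inclusive on the top (plus)
strand, matching the convention used for the 658-bp Folmer barcoding frame
("position 99", "position 421", ...).  Sequences are uppercase DNA over the
full IUPAC alphabet; RNA ('U') is rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.Data.IUPACData import ambiguous_dna_complement, ambiguous_dna_values
from Bio.Seq import Seq
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "DnaRecord",
    "SequenceError",
    "IUPAC_EXPANSION",
    "IUPAC_COMPLEMENT",
    "CONCRETE_BASES",
    "expansion",
    "iupac_match",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "TranslationQC",
    "translation_qc",
]

#: concrete, unambiguous DNA bases
CONCRETE_BASES = frozenset("ACGT")

#: IUPAC code -> set of concrete bases it denotes (M={A,C}, N={A,C,G,T}, ...)
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items() if code != "X"
}

#: IUPAC complement table (M<->K, R<->Y, W<->W, ...)
IUPAC_COMPLEMENT: dict[str, str] = {
    k: v for k, v in ambiguous_dna_complement.items() if k != "X"
}

_VALID = frozenset(IUPAC_EXPANSION)


class SequenceError(ValueError):
    """Raised for invalid DNA alphabets, duplicate ids or malformed records."""


def _validate(seq: str, *, allow_gap: bool = False) -> str:
    """Uppercase ``seq`` and verify every character is a valid IUPAC DNA code.

    Reports the 1-based position of the first offending character.
    """
    up = seq.upper()
    allowed = _VALID | ({"-"} if allow_gap else set())
    for i, ch in enumerate(up):
        if ch not in allowed:
            raise SequenceError(
                f"invalid DNA character {ch!r} at position {i + 1}"
                + (" (RNA 'U' is not accepted)" if ch == "U" else "")
            )
    return up


@dataclass
class DnaRecord:
    """A named DNA sequence (uppercase IUPAC, 5'->3').

    Alignment gaps ('-') are tolerated so aligned inputs can be carried; any
    operation that needs a physical molecule (PCR, digestion) enforces
    concreteness itself.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        if not self.seq:
            raise SequenceError(f"record {self.id!r}: sequence must be non-empty")
        self.seq = _validate(self.seq, allow_gap=True)

    def __len__(self) -> int:
        return len(self.seq)

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos``."""
        return self.seq[pos - 1]


def expansion(code: str) -> frozenset[str]:
    """Set of concrete bases denoted by a single IUPAC code."""
    try:
        return IUPAC_EXPANSION[code.upper()]
    except KeyError:
        raise SequenceError(f"invalid IUPAC code {code!r}") from None


def iupac_match(template_base: str, code: str) -> bool:
    """True iff the concrete ``template_base`` is within ``expansion(code)``.

    The template base must be concrete (A/C/G/T); degenerate template bases
    are an error because physical templates are unambiguous molecules.
    """
    b = template_base.upper()
    if b not in CONCRETE_BASES:
        raise SequenceError(
            f"template base {template_base!r} is not concrete (A/C/G/T expected)"
        )
    return b in expansion(code)


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet (involution)."""
    up = _validate(seq)
    return "".join(IUPAC_COMPLEMENT[ch] for ch in reversed(up))


def read_fasta(path) -> list[DnaRecord]:
    """Read a multi-FASTA file into a list of :class:`DnaRecord`.

    Lowercase input is normalized to uppercase.  Duplicate ids are an error;
    an empty file yields an empty list with a warning.
    """
    records: list[DnaRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(DnaRecord(id=rec.id, seq=str(rec.seq), description=desc))
    if not records:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    return records


def write_fasta(records, path) -> None:
    """Write records as FASTA wrapped at 70 columns, preserving order."""
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(bio)


@dataclass
class TranslationQC:
    """Result of translating a barcode sequence for quality control."""

    protein: str
    has_stop: bool
    has_gap: bool
    frame: int
    frame_heuristic: bool = field(default=False)


def _translate_frame(seq: str, frame: int, table: int) -> tuple[str, bool]:
    sub = seq[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    protein = str(Seq(sub).translate(table=table))
    # a stop as the final codon is the natural end, internal stops are the QC failure
    internal = protein[:-1] if protein.endswith("*") else protein
    return protein, "*" in internal


def translation_qc(seq: str, frame: int | None = None, code_table: int = 5) -> TranslationQC:
    """Translate ``seq`` and report stop codons and gaps.

    Uses the invertebrate mitochondrial genetic code (NCBI table 5) by
    default, appropriate for insect COX1.  When ``frame`` is None the frame
    with the fewest internal stops is chosen and flagged as heuristic.
    """
    up = _validate(seq, allow_gap=True)
    has_gap = "-" in up
    ungapped = up.replace("-", "")
    if frame is not None:
        if frame not in (0, 1, 2):
            raise ValueError("frame must be 0, 1 or 2")
        if len(ungapped) - frame < 3:
            raise SequenceError("sequence too short to translate in this frame")
        protein, has_stop = _translate_frame(ungapped, frame, code_table)
        return TranslationQC(protein, has_stop, has_gap, frame)
    best: TranslationQC | None = None
    best_stops = None
    for f in (0, 1, 2):
        if len(ungapped) - f < 3:
            continue
        protein, has_stop = _translate_frame(ungapped, f, code_table)
        internal = protein[:-1] if protein.endswith("*") else protein
        n_stops = internal.count("*")
        if best is None or n_stops < best_stops:
            best = TranslationQC(protein, has_stop, has_gap, f, frame_heuristic=True)
            best_stops = n_stops
    if best is None:
        raise SequenceError("sequence too short to translate in any frame")
    return best
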