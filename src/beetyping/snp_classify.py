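"""SNP calling in the Folmer frame, haplogroup assignment, RFLP decision matrix.

The subspecies key rests on three diagnostic positions of the 658-bp Folmer
barcoding frame of COX1:

* position 99  (A -> G): separates the carnica/carpatica branch,
* position 448 (A -> G): carnica within that branch,
* position 421 (C -> T or C -> A): the two *A. m. mellifera* haplogroups
  (H1 and H2 respectively).

A sequence carrying none of the variant alleles is consistent with
*A. m. caucasica*, which is identified by exclusion.  Because absolute allele
identities at 448 are stated only as "G/A", the key is stored as reference
base (caucasica-type background) versus variant base, and the packaged
fixtures define the orientation explicitly (variant assumed G).

The RFLP decision matrix is the gel-side analogue of the same key: four
PCR-RFLP assays, each cutting in a specific haplotype set.  The HspAI-cut /
MspI-uncut pattern is called carpatica but flagged, because a minority of
carnica specimens share the carpatica COX1 sequence and cannot be excluded.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

from .seqcore import CONCRETE_BASES, DnaRecord

__all__ = [
    "DiagnosticSNP",
    "SnpTable",
    "SnpRow",
    "DecisionMatrix",
    "ClassificationResult",
    "FOLMER_LENGTH",
    "default_key",
    "call_snps",
    "assign_haplogroup",
    "load_decision_matrix",
    "rflp_classify",
]

FOLMER_LENGTH = 658

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class DiagnosticSNP:
    """A diagnostic position in the Folmer frame with labelled alleles."""

    folmer_pos: int
    alleles: tuple[tuple[str, str], ...]  # (label, base) pairs

    def __post_init__(self) -> None:
        if not 1 <= self.folmer_pos <= FOLMER_LENGTH:
            raise ValueError(f"position {self.folmer_pos} outside the Folmer frame")
        bases = {b for _, b in self.alleles}
        if len(bases) < 2:
            raise ValueError("a diagnostic SNP needs at least two distinct bases")

    def allele(self, label: str) -> str:
        for lab, base in self.alleles:
            if lab == label:
                return base
        raise KeyError(label)


def default_key() -> list[DiagnosticSNP]:
    """The packaged three-position subspecies key."""
    return [
        DiagnosticSNP(99, (("reference", "A"), ("carnica_carpatica", "G"))),
        DiagnosticSNP(421, (("reference", "C"), ("mellifera_H1", "T"), ("mellifera_H2", "A"))),
        DiagnosticSNP(448, (("reference", "A"), ("carnica", "G"))),
    ]


@dataclass
class SnpRow:
    folmer_pos: int
    alleles: dict[str, str]  # record id -> base
    kind: str  # "transition" | "transversion" | "mixed"
    flagged: bool = False  # gaps or ambiguity present in the column


@dataclass
class SnpTable:
    rows: list[SnpRow] = field(default_factory=list)

    @property
    def positions(self) -> list[int]:
        return [r.folmer_pos for r in self.rows]

    def __len__(self) -> int:
        return len(self.rows)


def _classify_pair(bases: set[str]) -> str:
    if bases <= _PURINES or bases <= _PYRIMIDINES:
        return "transition"
    if len(bases) == 2:
        return "transversion"
    return "mixed"


def call_snps(records: list[DnaRecord], frame_offset: int = 1) -> SnpTable:
    """Report every polymorphic column of an equal-length alignment.

    ``frame_offset`` maps alignment column 1 to a Folmer-frame position
    (offset 1 for sequences already trimmed to the 658-bp frame).  Columns
    containing gaps or ambiguity codes are reported but flagged.
    """
    if len(records) < 2:
        raise ValueError("need at least two records to call SNPs")
    n = len(records[0].seq)
    for r in records:
        if len(r.seq) != n:
            raise ValueError(
                "records differ in length; align (or trim) them before SNP calling"
            )
    table = SnpTable()
    for col in range(n):
        observed = {r.id: r.seq[col] for r in records}
        symbols = set(observed.values())
        concrete = {b for b in symbols if b in CONCRETE_BASES}
        # a column is reported when it shows real variation (>= 2 concrete
        # bases) or possible variation obscured by gaps/ambiguity
        if len(symbols) < 2 or not concrete:
            continue
        flagged = bool(symbols - CONCRETE_BASES)
        kind = _classify_pair(concrete) if len(concrete) >= 2 else "ambiguous"
        table.rows.append(SnpRow(col + frame_offset, observed, kind, flagged))
    return table


def assign_haplogroup(folmer_seq: DnaRecord, key: list[DiagnosticSNP] | None = None) -> str:
    """Apply the sequence key to a Folmer-frame sequence.

    Bases incompatible with every key allele (including N) yield
    ``"unknown haplotype"``; missing data is never silently coerced.
    """
    if key is None:
        key = default_key()
    by_pos = {snp.folmer_pos: snp for snp in key}
    for pos in by_pos:
        if len(folmer_seq.seq) < pos:
            raise ValueError(
                f"sequence {folmer_seq.id!r} shorter than key position {pos}"
            )

    def base_at(pos: int) -> str:
        return folmer_seq.base(pos)

    b99 = base_at(99)
    snp99, snp421, snp448 = by_pos[99], by_pos[421], by_pos[448]
    if b99 == snp99.allele("carnica_carpatica"):
        b448 = base_at(448)
        if b448 == snp448.allele("carnica"):
            return "carnica"
        if b448 == snp448.allele("reference"):
            return "carpatica"
        return "unknown haplotype"
    if b99 != snp99.allele("reference"):
        return "unknown haplotype"
    b421 = base_at(421)
    if b421 == snp421.allele("mellifera_H1"):
        return "mellifera_H1"
    if b421 == snp421.allele("mellifera_H2"):
        return "mellifera_H2"
    if b421 != snp421.allele("reference"):
        return "unknown haplotype"
    b448 = base_at(448)
    if b448 != snp448.allele("reference"):
        return "unknown haplotype"
    return "caucasica-consistent"


@dataclass
class DecisionMatrix:
    """Expected cut/uncut pattern per haplotype for the packaged assays."""

    assays: list[str]  # enzyme names, one per assay
    expected: dict[str, dict[str, str]]  # haplotype -> {enzyme: cut|uncut}
    aliases: dict[str, str] = field(default_factory=dict)  # primer pair -> enzyme

    def normalize(self, name: str) -> str:
        if name in self.assays:
            return name
        if name in self.aliases:
            return self.aliases[name]
        raise KeyError(
            f"unknown assay {name!r}; known: {self.assays + sorted(self.aliases)}"
        )


_PAIR_ALIASES = {"AmEu1": "AluI", "AmEu2": "HinfI", "AmCarp": "HspAI", "AmCar": "MspI"}


def load_decision_matrix(path=None) -> DecisionMatrix:
    if path is None:
        fh = resources.files("beetyping.data").joinpath("decision_matrix.tsv").open()
    else:
        fh = open(path)
    with fh:
        reader = csv.DictReader(fh, delimiter="\t")
        assays = [c for c in reader.fieldnames if c != "haplotype"]
        expected = {
            row["haplotype"]: {a: row[a] for a in assays} for row in reader
        }
    return DecisionMatrix(assays, expected, dict(_PAIR_ALIASES))


@dataclass
class ClassificationResult:
    call: str
    confidence_note: str  # unique | carnica_carpatica_ambiguous | inconsistent | caucasica_by_exclusion
    partial: bool = False


def rflp_classify(
    observed: dict[str, str], matrix: DecisionMatrix | None = None
) -> ClassificationResult:
    """Turn an observed cut/uncut pattern into a subspecies call.

    ``observed`` maps assay names (enzyme or primer-pair names) to "cut" or
    "uncut".  Patterns matching no matrix row are reported as inconsistent,
    never coerced to the nearest row.  Partial patterns are classified against
    the observed assays only and flagged partial (a unique call then means
    "unique among the assays provided").
    """
    if matrix is None:
        matrix = load_decision_matrix()
    norm: dict[str, str] = {}
    for name, state in observed.items():
        if state not in ("cut", "uncut"):
            raise ValueError(f"assay {name!r}: state must be 'cut' or 'uncut'")
        norm[matrix.normalize(name)] = state
    partial = set(norm) != set(matrix.assays)

    matching = [
        hap
        for hap, exp in matrix.expected.items()
        if all(exp[a] == s for a, s in norm.items())
    ]
    if not matching:
        return ClassificationResult("inconsistent", "inconsistent", partial)
    if not partial and all(s == "uncut" for s in norm.values()):
        return ClassificationResult("caucasica", "caucasica_by_exclusion", partial)
    if norm.get("HspAI") == "cut" and norm.get("MspI") == "uncut":
        # a minority of carnica specimens carry the carpatica COX1 sequence
        return ClassificationResult(
            "carpatica (carnica not excluded)", "carnica_carpatica_ambiguous", partial
        )
    if len(matching) == 1:
        return ClassificationResult(matching[0], "unique", partial)
    return ClassificationResult("|".join(sorted(matching)), "inconsistent", partial)
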