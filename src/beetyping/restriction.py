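"""Restriction-enzyme model and digestion simulator.

Recognition sites may contain IUPAC degeneracy (HinfI = GANTC) and are
scanned on both strands.  Only top-strand cut positions define fragments:
agarose electrophoresis reads double-stranded fragment length, so overhang
geometry is irrelevant to the reported patterns.  Digests are complete (every
site is cut) and templates are linear.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources

from .seqcore import CONCRETE_BASES, SequenceError, expansion, reverse_complement

__all__ = [
    "Enzyme",
    "DigestResult",
    "UnknownEnzymeError",
    "builtin_enzymes",
    "resolve_enzyme",
    "find_sites",
    "digest",
    "gel_resolvable",
]


@dataclass(frozen=True)
class Enzyme:
    """A restriction endonuclease.

    ``cut_offset`` is the 0-based position within the recognition site after
    which the top strand is cleaved (AluI AG^CT has offset 2).
    """

    name: str
    site: str
    cut_offset: int
    isoschizomers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.site) < 4:
            raise ValueError(f"{self.name}: recognition site must be >= 4 bp")
        if not 0 <= self.cut_offset <= len(self.site):
            raise ValueError(f"{self.name}: cut offset outside the site")


@dataclass
class DigestResult:
    """Fragments produced by a complete digest of a linear sequence."""

    enzyme: str
    cut_positions: list[int]  # 1-based: cleavage after this top-strand base
    fragment_lengths: list[int] = field(default_factory=list)  # descending

    @property
    def cut(self) -> bool:
        return bool(self.cut_positions)


class UnknownEnzymeError(KeyError):
    pass


def _load_builtin() -> dict[str, Enzyme]:
    table: dict[str, Enzyme] = {}
    path = resources.files("beetyping.data").joinpath("enzymes.tsv")
    with path.open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            iso = tuple(x for x in (row["isoschizomers"] or "").split(",") if x)
            table[row["name"]] = Enzyme(
                row["name"], row["site"], int(row["cut_offset"]), iso
            )
    return table


_BUILTIN: dict[str, Enzyme] | None = None

#: enzymes whose activity depends on substrate methylation; they resolve as
#: isoschizomers but in-silico digestion does not model the requirement
_METHYLATION_DEPENDENT = frozenset({"GlaI"})


def builtin_enzymes() -> dict[str, Enzyme]:
    """Packaged enzyme table (AluI, HinfI, HspAI, MspI, DraI)."""
    global _BUILTIN
    if _BUILTIN is None:
        _BUILTIN = _load_builtin()
    return dict(_BUILTIN)


def resolve_enzyme(name: str) -> Enzyme:
    """Resolve an enzyme or isoschizomer name to its canonical record.

    HpaII resolves to the MspI record (both CCGG), AluBI to AluI, and so on.
    Methylation-dependent isoschizomers (GlaI) resolve with a warning because
    their cutting depends on substrate methylation, which is not modeled.
    """
    table = builtin_enzymes()
    key = name.strip()
    lower = {n.lower(): n for n in table}
    if key.lower() in lower:
        return table[lower[key.lower()]]
    for enz in table.values():
        for iso in enz.isoschizomers:
            if iso.lower() == key.lower():
                if iso in _METHYLATION_DEPENDENT:
                    warnings.warn(
                        f"{iso} is methylation-dependent; treating it as a plain "
                        f"{enz.name} isoschizomer ({enz.site})",
                        stacklevel=2,
                    )
                return enz
    known = sorted(table) + sorted(i for e in table.values() for i in e.isoschizomers)
    raise UnknownEnzymeError(f"unknown enzyme {name!r}; known: {', '.join(known)}")


def _matches(seq: str, start0: int, pattern: str) -> bool:
    """Degenerate pattern match of ``pattern`` against seq at 0-based start."""
    for k, code in enumerate(pattern):
        if seq[start0 + k] not in expansion(code):
            return False
    return True


def find_sites(seq: str, enzyme: Enzyme) -> list[int]:
    """1-based start positions of recognition sites on either strand.

    The top strand is scanned for the site and for its reverse complement;
    palindromic matches are deduplicated.  The input must be concrete DNA.
    """
    up = seq.upper()
    bad = set(up) - CONCRETE_BASES
    if bad:
        raise SequenceError(f"sequence must be concrete DNA; found {sorted(bad)}")
    fwd = enzyme.site.upper()
    rev = reverse_complement(fwd)
    L = len(fwd)
    hits: set[int] = set()
    for s0 in range(len(up) - L + 1):
        if _matches(up, s0, fwd) or _matches(up, s0, rev):
            hits.add(s0 + 1)
    return sorted(hits)


def _cut_positions(seq: str, enzyme: Enzyme) -> list[int]:
    up = seq.upper()
    fwd = enzyme.site.upper()
    rev = reverse_complement(fwd)
    L = len(fwd)
    cuts: set[int] = set()
    for s0 in range(len(up) - L + 1):
        if _matches(up, s0, fwd):
            cut = s0 + enzyme.cut_offset  # 1-based "after this base"
        elif _matches(up, s0, rev):
            # site recognized on the bottom strand: the top-strand cleavage
            # mirrors the offset within the site
            cut = s0 + (L - enzyme.cut_offset)
        else:
            continue
        if 1 <= cut <= len(up) - 1:
            cuts.add(cut)
    return sorted(cuts)


def digest(seq: str, enzyme: Enzyme) -> DigestResult:
    """Complete digest of a linear concrete sequence.

    Fragment lengths are reported in descending order (gel convention) and
    always sum to the input length.
    """
    if set(seq.upper()) - CONCRETE_BASES:
        raise SequenceError("digest requires concrete DNA (A/C/G/T only)")
    cuts = _cut_positions(seq, enzyme)
    bounds = [0] + cuts + [len(seq)]
    fragments = sorted(
        (b - a for a, b in zip(bounds, bounds[1:])), reverse=True
    )
    return DigestResult(enzyme.name, cuts, fragments)


def gel_resolvable(
    fragments: list[int], min_fragment: int = 20, min_delta: int = 15
) -> tuple[bool, list[str]]:
    """Can all fragments be told apart on a 3% agarose gel?

    True iff every fragment is at least ``min_fragment`` bp and every pair of
    distinct fragment lengths differs by at least ``min_delta`` bp.  The
    defaults are conservative settings for 3% agarose, below the ~28-30 bp
    primer-sized fragments these assays produce; both are configurable.
    """
    if not fragments:
        raise ValueError("fragments must be non-empty")
    report: list[str] = []
    for f in fragments:
        if f < min_fragment:
            report.append(f"fragment {f} bp below visibility threshold {min_fragment} bp")
    distinct = sorted(set(fragments))
    for a, b in zip(distinct, distinct[1:]):
        if b - a < min_delta:
            report.append(f"fragments {b} and {a} bp differ by {b - a} < {min_delta} bp")
    return (not report), report
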