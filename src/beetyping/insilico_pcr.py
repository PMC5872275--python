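"""Virtual PCR: degenerate primer annealing and primer-overwrite amplification.

The central mechanical fact of mutagenic-primer (dCAPS) PCR is that primer
sequences *overwrite* the template at the product ends: after the first
cycles, every product molecule carries the primer bases verbatim, so a
deliberate mismatch near a primer 3' end appears in the product and can
complete a restriction site together with a nearby template SNP.  ``amplify``
therefore builds each product as

    resolved(forward primer) + template interior + revcomp(resolved(reverse primer))

where "resolved" replaces degenerate primer codes by the template base when
compatible (the polymerase copies the template wherever the primer pool
contains a complementary oligo) and by the lexicographically smallest
expansion otherwise.

No 3'-clamp rule is enforced when scoring primer hits: mutagenic primers
anneal and prime despite non-complementary 3'-terminal bases, so hits are
ranked purely by total mismatch count (default tolerance 3).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

from .seqcore import (
    CONCRETE_BASES,
    DnaRecord,
    SequenceError,
    expansion,
    reverse_complement,
)

__all__ = [
    "Primer",
    "PrimerHit",
    "Amplicon",
    "NestedResult",
    "find_primer_sites",
    "amplify",
    "nested_amplify",
    "load_primers",
    "DEFAULT_MAX_MISMATCH",
    "DEFAULT_SIZE_RANGE",
]

DEFAULT_MAX_MISMATCH = 3
DEFAULT_SIZE_RANGE = (100, 1000)


@dataclass(frozen=True)
class Primer:
    """A directional oligo, possibly degenerate and possibly mutagenic.

    ``mutated_positions`` are 1-based positions *within the primer* carrying
    deliberate substitutions relative to the template.  Mutagenic primers
    carry one or two such substitutions, confined to the 3'-terminal half.
    """

    name: str
    seq: str
    direction: str  # "forward" | "reverse"
    mutagenic: bool = False
    mutated_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.seq) < 15:
            raise ValueError(f"primer {self.name}: length must be >= 15 nt")
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"primer {self.name}: direction must be forward/reverse")
        object.__setattr__(self, "seq", self.seq.upper())
        for ch in self.seq:
            expansion(ch)  # validates the alphabet
        if self.mutagenic:
            n = len(self.mutated_positions)
            if n not in (1, 2):
                raise ValueError(
                    f"primer {self.name}: mutagenic primers carry 1 or 2 substitutions"
                )
            half = len(self.seq) / 2
            for p in self.mutated_positions:
                if not 1 <= p <= len(self.seq):
                    raise ValueError(f"primer {self.name}: position {p} outside primer")
                if p <= half:
                    raise ValueError(
                        f"primer {self.name}: substitution at {p} not in the 3'-terminal half"
                    )
        elif self.mutated_positions:
            raise ValueError(f"primer {self.name}: non-mutagenic primer with substitutions")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PrimerHit:
    """A primer footprint on a template, in 1-based template coordinates."""

    template_id: str
    primer: str
    start: int
    end: int
    strand: str  # "+" | "-"
    mismatches: int
    mismatch_positions: tuple[int, ...] = ()  # template coordinates


@dataclass
class Amplicon:
    """A concrete PCR product with its defining primer footprints."""

    template_id: str
    fwd_hit: PrimerHit
    rev_hit: PrimerHit
    product_seq: str

    @property
    def length(self) -> int:
        return len(self.product_seq)

    @property
    def start(self) -> int:
        """Leftmost template coordinate covered by the product."""
        return min(self.fwd_hit.start, self.rev_hit.start)

    @property
    def end(self) -> int:
        return max(self.fwd_hit.end, self.rev_hit.end)


@dataclass
class NestedResult:
    """Outcome of two-step (nested) amplification."""

    amplicons: list[Amplicon]
    outer_failed: bool = False


def _check_concrete(template: DnaRecord) -> None:
    if set(template.seq) - CONCRETE_BASES:
        raise SequenceError(
            f"template {template.id!r} must be concrete DNA (A/C/G/T)"
        )


def find_primer_sites(
    template: DnaRecord, primer: Primer, max_mismatch: int = DEFAULT_MAX_MISMATCH
) -> list[PrimerHit]:
    """All footprints of ``primer`` on either strand of ``template``.

    A primer position matches when the template base lies in the IUPAC
    expansion of the primer code; a footprint is reported when the number of
    non-matching positions is at most ``max_mismatch``.  Hits are sorted by
    (mismatches, start).  A primer longer than the template yields no hits.
    """
    _check_concrete(template)
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    seq = template.seq
    L = len(primer)
    hits: list[PrimerHit] = []
    for strand, probe in (("+", primer.seq), ("-", reverse_complement(primer.seq))):
        for s0 in range(len(seq) - L + 1):
            mis: list[int] = []
            for k in range(L):
                if seq[s0 + k] not in expansion(probe[k]):
                    mis.append(s0 + k + 1)
                    if len(mis) > max_mismatch:
                        break
            if len(mis) <= max_mismatch:
                hits.append(
                    PrimerHit(
                        template.id, primer.name, s0 + 1, s0 + L, strand,
                        len(mis), tuple(mis),
                    )
                )
    hits.sort(key=lambda h: (h.mismatches, h.start, h.strand))
    return hits


def _resolve(probe: str, segment: str) -> str:
    """Concrete primer sequence as it appears in the product.

    ``probe`` is the primer written in product (top-strand) orientation and
    ``segment`` the template top strand under its footprint.  Degenerate codes
    resolve to the template base when compatible, else to the smallest base in
    the expansion; concrete primer bases always win (overwrite rule).
    """
    out = []
    for code, tbase in zip(probe, segment):
        exp = expansion(code)
        if len(exp) == 1:
            out.append(next(iter(exp)))
        elif tbase in exp:
            out.append(tbase)
        else:
            out.append(min(exp))
    return "".join(out)


def amplify(
    template: DnaRecord,
    fwd: Primer,
    rev: Primer,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
) -> list[Amplicon]:
    """Enumerate all products of a primer pair within ``size_range``.

    Every plus-strand hit of one primer is paired with every downstream
    minus-strand hit of the other; both product orientations are generated,
    ambiguity is surfaced rather than hidden.  Products are reported 5'->3'
    starting with the forward primer.
    """
    if size_range[0] > size_range[1]:
        raise ValueError("size_range min must be <= max")
    fwd_hits = find_primer_sites(template, fwd, max_mismatch)
    rev_hits = find_primer_sites(template, rev, max_mismatch)
    seq = template.seq
    products: list[Amplicon] = []

    def emit(left: PrimerHit, right: PrimerHit, minus: bool):
        # left/right in ascending template coordinates
        if right.start - left.end - 1 < 0:
            return  # overlapping footprints
        interior = seq[left.end:right.start - 1]
        length = (right.end - left.start) + 1
        if not size_range[0] <= length <= size_range[1]:
            return
        # resolve primers against the template top strand under the footprints
        if not minus:
            p5 = _resolve(fwd.seq, seq[left.start - 1:left.end])
            p3 = _resolve(
                reverse_complement(rev.seq), seq[right.start - 1:right.end]
            )
            product = p5 + interior + p3
            products.append(Amplicon(template.id, left, right, product))
        else:
            # forward primer sits on the minus strand (right footprint); the
            # product top strand is the reverse complement of the template span
            p3 = _resolve(rev.seq, seq[left.start - 1:left.end])
            p5 = _resolve(
                reverse_complement(fwd.seq), seq[right.start - 1:right.end]
            )
            span = p3 + interior + p5
            products.append(
                Amplicon(template.id, right, left, reverse_complement(span))
            )

    for fh in (h for h in fwd_hits if h.strand == "+"):
        for rh in (h for h in rev_hits if h.strand == "-" and h.start > fh.end):
            emit(fh, rh, minus=False)
    for rh in (h for h in rev_hits if h.strand == "+"):
        for fh in (h for h in fwd_hits if h.strand == "-" and h.start > rh.end):
            emit(rh, fh, minus=True)

    products.sort(key=lambda a: (a.start, a.length))
    return products


def nested_amplify(
    template: DnaRecord,
    outer_pair: tuple[Primer, Primer],
    inner_pair: tuple[Primer, Primer],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
    outer_size_range: tuple[int, int] = (100, 5000),
) -> NestedResult:
    """Two-step PCR: amplify with the outer pair, re-amplify each product.

    Mirrors the degraded-template rescue protocol in which a long, highly
    specific first-round product serves as template for the subspecies assays.
    """
    outer = amplify(template, *outer_pair, max_mismatch, outer_size_range)
    if not outer:
        return NestedResult([], outer_failed=True)
    inner: list[Amplicon] = []
    for i, amp in enumerate(outer):
        t = DnaRecord(id=f"{template.id}|outer{i + 1}", seq=amp.product_seq)
        inner.extend(amplify(t, *inner_pair, max_mismatch, size_range))
    return NestedResult(inner)


def load_primers(path=None) -> dict[str, Primer]:
    """Load primers from a TSV (name, seq, direction, mutagenic, positions).

    With no path, returns the packaged primer set: the universal barcoding
    pair (LepF1/LepR1), the cytochrome-b pair, and the eight subspecies
    identification primers including the four mutagenic ones.
    """
    if path is None:
        fh = resources.files("beetyping.data").joinpath("primers.tsv").open()
    else:
        fh = open(path)
    primers: dict[str, Primer] = {}
    with fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            pos = tuple(
                int(x) for x in (row.get("mutated_positions") or "").split(",") if x
            )
            primers[row["name"]] = Primer(
                row["name"], row["seq"], row["direction"],
                mutagenic=row["mutagenic"] == "1", mutated_positions=pos,
            )
    return primers
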