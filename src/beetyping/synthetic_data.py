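"""Seeded generator of 658-bp Folmer-frame haplotype fixtures.

The generator builds five synthetic haplotypes (mellifera_H1, mellifera_H2,
carpatica, carnica, caucasica) on a shared AT-rich random background.  It
implants, at fixed frame offsets,

* the footprints of the four subspecies primer pairs (with each mutagenic
  primer's deliberate substitution *reverted* to a template-consistent base,
  so the substitution enters products only via primer overwrite),
* the three diagnostic alleles (positions 99, 421 and 448), and
* the restriction-site context around each diagnostic allele, placed so that
  the enzyme cuts the target haplotype's product into exactly the published
  fragment lengths (107+32, 122+28, 111+30, 118+30) and leaves every
  non-target product uncut at its full length (139/150/141/148).

Every candidate background is validated by running the real pipeline
(virtual PCR -> digestion -> RFLP classification) over all 20 assay x
haplotype cells and rejection-sampled until no stray recognition site occurs
in any product; the generator is therefore itself an end-to-end exercise of
the digestion engine.  Fixtures emulate the combinatorial structure of the
published assays, not the true GenBank sequences.

mellifera_H1 additionally diverges from the shared background by a set of
C<->T transitions plus one A->G and one T->A substitution (default eight
transitions, one of which completes the AluI site), placed outside every
amplicon so intra-subspecies variability can be emulated without disturbing
the assays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assay_design import AssayDefinition, load_assays, validate_assay
from .insilico_pcr import amplify
from .restriction import digest
from .seqcore import DnaRecord, reverse_complement
from .snp_classify import (
    FOLMER_LENGTH,
    assign_haplogroup,
    load_decision_matrix,
    rflp_classify,
)

__all__ = [
    "FixtureSpec",
    "FixtureSet",
    "GenerationError",
    "generate_fixtures",
    "mutate",
    "write_fixtures",
    "DEFAULT_SEED",
    "HAPLOTYPES",
]

DEFAULT_SEED = 20180127
HAPLOTYPES = ("mellifera_H1", "mellifera_H2", "carpatica", "carnica", "caucasica")

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


class GenerationError(RuntimeError):
    pass


@dataclass
class FixtureSpec:
    """Study conditions for the fixture generator."""

    seed: int = DEFAULT_SEED
    gc_content: float = 0.30  # bee COX1 is AT-rich
    h1_transitions: int = 8  # C<->T transitions private to mellifera_H1
    #: uncut product length per assay (AmEu1, AmEu2, AmCarp, AmCar)
    product_lengths: tuple[int, ...] = (139, 150, 141, 148)
    size_range: tuple[int, int] = (120, 160)
    max_retries: int = 500

    def __post_init__(self) -> None:
        # positions 34 (AluI completer) and 421 (H1 key allele) are both
        # C->T transitions and count toward the total
        if self.h1_transitions < 2:
            raise ValueError("mellifera_H1 carries at least two C->T transitions")
        lo, hi = self.size_range
        for L in self.product_lengths:
            if not lo <= L <= hi:
                warnings.warn(
                    f"product length {L} bp outside the gel-friendly range [{lo}, {hi}]"
                )


@dataclass
class FixtureSet:
    records: dict[str, DnaRecord]
    assays: dict[str, AssayDefinition]
    expected: dict[str, dict[str, list[int]]]  # assay -> haplotype -> fragments
    validation_table: pd.DataFrame
    protected_positions: frozenset[int]
    seed: int

    def record_list(self) -> list[DnaRecord]:
        return [self.records[h] for h in HAPLOTYPES]


# ---------------------------------------------------------------------------
# fixed frame layout (1-based, inclusive, plus strand of the Folmer frame)
#
# Each amplicon is anchored so that the digest of its product reproduces the
# published fragment split; the context bases were solved from the enzyme
# recognition sequences and the primer-overwrite rule (see docs/methods.md).
# ---------------------------------------------------------------------------


def _layout(assays: dict[str, AssayDefinition]) -> tuple[dict[int, str], dict[str, dict[int, str]]]:
    """(shared fixed bases, per-haplotype allele overrides)."""
    p = {name: a for name, a in assays.items()}
    fixed: dict[int, str] = {}

    def put(start: int, seq: str, revert: dict[int, str] | None = None) -> None:
        for i, ch in enumerate(seq):
            fixed[start + i] = ch
        for pos, base in (revert or {}).items():
            fixed[pos] = base

    # AmEu1 amplicon (AluI), plus orientation, Folmer 1-139
    put(1, p["AmEu1"].fwd.seq)
    rc_eu1r = reverse_complement(p["AmEu1"].rev.seq)
    put(108, rc_eu1r, revert={108: "A"})  # mutagenic 3' base reverted
    put(31, "AGC")  # AluI site 31-34 completed by T at 34 in mellifera_H1
    fixed[34] = "C"

    # AmCarp amplicon (HspAI), plus orientation, Folmer 70-210
    put(70, p["AmCarp"].fwd.seq)
    put(178, reverse_complement(p["AmCarp"].rev.seq), revert={178: "A"})
    fixed[99] = "A"  # diagnostic: G in carnica/carpatica completes GCGC
    put(100, "CGC")

    # AmCar amplicon (MspI), plus orientation, Folmer 328-475
    amcar_f = p["AmCar"].fwd.seq.replace("M", "A").replace("Y", "T")
    put(328, amcar_f, revert={359: "A"})
    put(457, reverse_complement(p["AmCar"].rev.seq))
    put(445, "CCG")  # MspI site 445-448 completed by G at 448 in carnica
    fixed[448] = "A"

    # AmEu2 amplicon (HinfI), minus orientation, Folmer 396-545
    put(396, p["AmEu2"].rev.seq)
    put(515, reverse_complement(p["AmEu2"].fwd.seq), revert={515: "C"})
    fixed[420] = "G"  # HinfI site on the product strand, completed by the
    fixed[421] = "C"  # 421 A allele (product-strand T) in mellifera_H2
    fixed[422] = "T"
    fixed[423] = "T"
    fixed[424] = "C"

    overrides = {
        "caucasica": {},
        "carpatica": {99: "G"},
        "carnica": {99: "G", 448: "G"},
        "mellifera_H2": {421: "A"},
        "mellifera_H1": {421: "T", 34: "T"},
    }
    return fixed, overrides


#: Folmer spans covered by the four amplicons; mellifera_H1's background
#: divergence is confined to the complement of these spans
_AMPLICON_SPANS = ((1, 139), (70, 210), (328, 475), (396, 545))


def _free_positions() -> list[int]:
    covered = set()
    for a, b in _AMPLICON_SPANS:
        covered.update(range(a, b + 1))
    return [i for i in range(1, FOLMER_LENGTH + 1) if i not in covered]


def _expected_patterns(assays: dict[str, AssayDefinition]) -> dict[str, dict[str, list[int]]]:
    out: dict[str, dict[str, list[int]]] = {}
    for name, a in assays.items():
        out[name] = {
            h: (list(a.cut_fragments) if h in a.targets else [a.uncut_length])
            for h in HAPLOTYPES
        }
    return out


def _validate(
    records: dict[str, DnaRecord],
    assays: dict[str, AssayDefinition],
    expected: dict[str, dict[str, list[int]]],
    size_range: tuple[int, int],
) -> pd.DataFrame | None:
    """All 20 assay x haplotype cells, or None when any cell deviates."""
    matrix = load_decision_matrix()
    rows = []
    observed_by_hap: dict[str, dict[str, str]] = {h: {} for h in HAPLOTYPES}
    for name, assay in assays.items():
        for hap in HAPLOTYPES:
            amps = amplify(records[hap], assay.fwd, assay.rev, 3, size_range)
            if len(amps) != 1:
                return None
            res = digest(amps[0].product_seq, assay.enzyme)
            if res.fragment_lengths != expected[name][hap]:
                return None
            observed_by_hap[hap][assay.enzyme.name] = "cut" if res.cut else "uncut"
            rows.append(
                {
                    "assay": name,
                    "enzyme": assay.enzyme.name,
                    "haplotype": hap,
                    "product_bp": amps[0].length,
                    "fragments": ",".join(map(str, res.fragment_lengths)),
                    "cut": res.cut,
                }
            )
    # the gel key and the sequence key must close the loop on every fixture
    for hap in HAPLOTYPES:
        call = rflp_classify(observed_by_hap[hap], matrix)
        if hap == "carpatica":
            if call.confidence_note != "carnica_carpatica_ambiguous":
                return None
        elif hap == "caucasica":
            if call.confidence_note != "caucasica_by_exclusion":
                return None
        elif call.call != hap:
            return None
        seq_label = assign_haplogroup(records[hap])
        if hap == "caucasica":
            if seq_label != "caucasica-consistent":
                return None
        elif seq_label != hap:
            return None
    return pd.DataFrame(rows)


def generate_fixtures(spec: FixtureSpec | int | None = None) -> FixtureSet:
    """Build the five validated fixture haplotypes and the packaged assays.

    Deterministic in ``spec.seed``; the random background is resampled until
    every assay reproduces its published fragment pattern on every haplotype
    and both classification keys return each fixture's own label.
    """
    if spec is None:
        spec = FixtureSpec()
    elif isinstance(spec, int):
        spec = FixtureSpec(seed=spec)
    assays = load_assays()
    for a, L in zip(("AmEu1", "AmEu2", "AmCarp", "AmCar"), spec.product_lengths):
        if assays[a].uncut_length != L:
            raise GenerationError(
                f"assay {a}: configured product length {L} does not match the "
                f"packaged assay ({assays[a].uncut_length} bp)"
            )
    fixed, overrides = _layout(assays)
    expected = _expected_patterns(assays)
    free = _free_positions()
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    bases = np.array(list("ACGT"))
    n_extra = spec.h1_transitions - 2  # 34 and 421 are transitions already

    last_failure = "no attempt"
    for _ in range(spec.max_retries):
        bg = rng.choice(bases, size=FOLMER_LENGTH, p=probs)
        template = {i + 1: bg[i] for i in range(FOLMER_LENGTH)}
        template.update(fixed)

        h1_extra = rng.choice(free, size=n_extra + 2, replace=False)
        h1_over = dict(overrides["mellifera_H1"])
        for pos in h1_extra[:n_extra]:
            template[int(pos)] = "C"
            h1_over[int(pos)] = "T"
        template[int(h1_extra[n_extra])] = "A"
        h1_over[int(h1_extra[n_extra])] = "G"
        template[int(h1_extra[n_extra + 1])] = "T"
        h1_over[int(h1_extra[n_extra + 1])] = "A"

        records: dict[str, DnaRecord] = {}
        for hap in HAPLOTYPES:
            over = h1_over if hap == "mellifera_H1" else overrides[hap]
            seq = "".join(
                over.get(i, template[i]) for i in range(1, FOLMER_LENGTH + 1)
            )
            records[hap] = DnaRecord(
                hap, seq, description=f"synthetic Folmer-frame haplotype ({hap})"
            )

        table = _validate(records, assays, expected, spec.size_range)
        if table is not None:
            protected = frozenset(fixed) | frozenset(
                {99, 421, 448, 34} | {int(x) for x in h1_extra}
            )
            return FixtureSet(records, assays, expected, table, protected, spec.seed)
        last_failure = "a product deviated from its expected fragment pattern"

    raise GenerationError(
        f"no valid background after {spec.max_retries} draws: {last_failure}"
    )


def mutate(
    record: DnaRecord,
    n_transitions: int,
    n_transversions: int,
    seed: int | None = None,
    protected_positions: frozenset[int] | set[int] = frozenset(),
) -> DnaRecord:
    """Introduce exact substitution counts at uniformly drawn free positions.

    Used to emulate intra-subspecies variability on top of a fixture without
    touching primer footprints or diagnostic sites.  Reproducible by seed.
    """
    if n_transitions < 0 or n_transversions < 0:
        raise ValueError("substitution counts must be >= 0")
    total = n_transitions + n_transversions
    if total == 0:
        return DnaRecord(record.id, record.seq, record.description)
    candidates = [
        i for i in range(1, len(record.seq) + 1) if i not in protected_positions
    ]
    if len(candidates) < total:
        raise ValueError(
            f"only {len(candidates)} unprotected positions for {total} substitutions"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=total, replace=False)
    seq = list(record.seq)
    for k, pos in enumerate(chosen):
        base = seq[pos - 1]
        if k < n_transitions:
            seq[pos - 1] = _TRANSITION[base]
        else:
            options = _TRANSVERSIONS[base]
            seq[pos - 1] = options[int(rng.integers(len(options)))]
    return DnaRecord(record.id, "".join(seq), record.description)


def write_fixtures(fixtures: FixtureSet, outdir) -> None:
    """Write FASTA fixtures, the assay config and the expected-pattern table."""
    from pathlib import Path

    from .seqcore import write_fasta

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(fixtures.record_list(), out / "haplotypes.fasta")
    fixtures.validation_table.to_csv(out / "expected_patterns.tsv", sep="\t", index=False)
    rows = []
    for name, a in fixtures.assays.items():
        rows.append(
            {
                "assay": name,
                "fwd_primer": a.fwd.name,
                "fwd_seq": a.fwd.seq,
                "rev_primer": a.rev.name,
                "rev_seq": a.rev.seq,
                "enzyme": a.enzyme.name,
                "targets": ",".join(a.targets),
            }
        )
    pd.DataFrame(rows).to_csv(out / "assays.tsv", sep="\t", index=False)
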