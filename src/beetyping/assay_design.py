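"""Mutagenic-primer (dCAPS) PCR-RFLP assay design.

Given aligned haplotypes and a diagnostic SNP, search the primer x enzyme
space for an assay whose PCR product is cleaved in exactly the haplotypes
carrying one allele.  A candidate places a primer so that its 3' end lies
just upstream of the SNP (within site-length - 1 bases); up to two deliberate
substitutions in the primer's 3'-terminal half then complete a restriction
recognition site *together with the template allele* at the SNP.  Because the
site must be finished by the template, the substitutions never fall on the
SNP position itself - otherwise the assay would cut every allele.

Every candidate is validated by full re-simulation (virtual amplification
with primer overwrite, then digestion) on every haplotype, scanning the whole
product on both strands so that a stray recognition site elsewhere in a
non-target product disqualifies the design: primers alone are never
allele-specific, the restriction pattern is the diagnostic readout.

Results are ranked by (number of substitutions, product length, enzyme name),
a deterministic order; the search itself is exhaustive within the configured
primer-length windows, so on small inputs it is complete.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

from .insilico_pcr import Primer, amplify, load_primers
from .restriction import Enzyme, builtin_enzymes, digest, find_sites
from .seqcore import DnaRecord, expansion, reverse_complement
from .snp_classify import DiagnosticSNP

__all__ = [
    "AssayDefinition",
    "AssayDesignResult",
    "DesignReport",
    "design_assay",
    "validate_assay",
    "load_assays",
    "DEFAULT_SIZE_RANGE",
]

DEFAULT_SIZE_RANGE = (120, 160)
MUTAGENIC_LENGTHS = range(28, 34)  # generated mutagenic primers, nt
OPPOSITE_LENGTHS = range(18, 21)  # generated non-mutagenic opposite primers, nt


@dataclass
class AssayDefinition:
    """A named, ready-to-run PCR-RFLP assay (primer pair + enzyme)."""

    name: str
    fwd: Primer
    rev: Primer
    enzyme: Enzyme
    targets: tuple[str, ...]
    cut_fragments: tuple[int, ...] = ()
    uncut_length: int | None = None


@dataclass
class AssayDesignResult:
    fwd: Primer
    rev: Primer
    enzyme: Enzyme
    target_haplotypes: frozenset[str]
    predicted_patterns: dict[str, list[int]]
    n_substitutions: int
    product_len: int
    strand: str = "+"  # orientation of the mutagenic primer relative to input


@dataclass
class DesignReport:
    """Ranked designs plus per-enzyme failure diagnostics."""

    results: list[AssayDesignResult] = field(default_factory=list)
    failure_reasons: dict[str, str] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    def __getitem__(self, i):
        return self.results[i]


def load_assays(path=None) -> dict[str, AssayDefinition]:
    """Packaged subspecies assays (primer pair, enzyme, expected patterns)."""
    primers = load_primers()
    enzymes = builtin_enzymes()
    if path is None:
        fh = resources.files("beetyping.data").joinpath("assays.tsv").open()
    else:
        fh = open(path)
    assays: dict[str, AssayDefinition] = {}
    with fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            assays[row["assay"]] = AssayDefinition(
                row["assay"],
                primers[row["fwd_primer"]],
                primers[row["rev_primer"]],
                enzymes[row["enzyme"]],
                tuple(row["targets"].split(",")),
                tuple(int(x) for x in row["cut_fragments"].split(",")),
                int(row["uncut_length"]),
            )
    return assays


def validate_assay(
    assay: AssayDefinition,
    haplotypes: list[DnaRecord],
    max_mismatch: int = 3,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
) -> dict[str, dict]:
    """Run amplify + digest per haplotype; the machine analogue of a gel table.

    Haplotypes on which a primer fails to anneal (no product) are marked
    ``no_product``.
    """
    out: dict[str, dict] = {}
    for hap in haplotypes:
        amps = amplify(hap, assay.fwd, assay.rev, max_mismatch, size_range)
        if not amps:
            out[hap.id] = {"fragments": [], "cut": False, "no_product": True}
            continue
        res = digest(amps[0].product_seq, assay.enzyme)
        out[hap.id] = {
            "fragments": res.fragment_lengths,
            "cut": res.cut,
            "no_product": False,
            "n_products": len(amps),
        }
    return out


def _snp_alleles(haplotypes: list[DnaRecord], pos: int) -> dict[str, str]:
    return {h.id: h.base(pos) for h in haplotypes}


def _design_one_strand(
    haplotypes: list[DnaRecord],
    pos: int,
    enzyme: Enzyme,
    size_range: tuple[int, int],
    max_subs: int,
    max_mismatch: int,
    strand: str,
) -> tuple[list[AssayDesignResult], str | None]:
    """Designs with the mutagenic primer 5' of the SNP on the given strand."""
    alleles = _snp_alleles(haplotypes, pos)
    distinct = sorted(set(alleles.values()))
    site = enzyme.site.upper()
    sL = len(site)
    n = len(haplotypes[0].seq)
    results: list[AssayDesignResult] = []
    reason = None

    # candidate site windows overlapping the SNP with a discriminating code
    windows = []
    for w in range(max(1, pos - sL + 1), pos + 1):
        if w + sL - 1 > n:
            continue
        code = site[pos - w]
        matching = {a for a in distinct if a in expansion(code)}
        if matching and matching != set(distinct):
            windows.append((w, matching))
    if not windows:
        return [], "no site placement discriminates the alleles at the SNP"

    for w, target_alleles in windows:
        targets = frozenset(h for h, a in alleles.items() if a in target_alleles)
        # a target haplotype supplies the template under the primer
        t_hap = next(h for h in haplotypes if h.id in sorted(targets))
        for end in range(max(w, pos - sL + 1), pos):  # primer 3' end, < SNP
            for L in MUTAGENIC_LENGTHS:
                start = end - L + 1
                if start < 1 or w < start:
                    continue
                # required substitutions: primer-covered site positions where
                # the template disagrees with the recognition sequence
                subs: list[tuple[int, str]] = []
                feasible = True
                for k in range(sL):
                    gpos = w + k
                    if gpos == pos:
                        continue
                    code = site[k]
                    tb = t_hap.base(gpos)
                    if gpos <= end:
                        if tb not in expansion(code):
                            subs.append((gpos, min(expansion(code))))
                    else:
                        if tb not in expansion(code):
                            feasible = False  # template side cannot complete the site
                            break
                if not feasible or not subs or len(subs) > max_subs:
                    if feasible and not subs:
                        reason = reason or "site pre-exists without mutagenesis (CAPS, not dCAPS)"
                    continue
                half = L / 2
                if any((g - start + 1) <= half for g, _ in subs):
                    continue
                primer_seq = list(t_hap.seq[start - 1:end])
                for gpos, base in subs:
                    primer_seq[gpos - start] = base
                mut_positions = tuple(sorted(g - start + 1 for g, _ in subs))
                fwd = Primer(
                    f"dcaps_{enzyme.name}_{pos}{strand}", "".join(primer_seq),
                    "forward", mutagenic=True, mutated_positions=mut_positions,
                )
                res = _pair_and_validate(
                    haplotypes, t_hap, fwd, enzyme, w, sL, start,
                    targets, size_range, max_subs, max_mismatch, strand,
                )
                if res is not None:
                    results.append(res)
                elif reason is None:
                    reason = "no opposite primer placement validated"
    return results, reason


def _mismatches(probe: str, segment: str) -> int:
    return sum(1 for c, b in zip(probe, segment) if b not in expansion(c))


def _pair_and_validate(
    haplotypes, t_hap, fwd, enzyme, w, sL, start,
    targets, size_range, max_subs, max_mismatch, strand,
) -> AssayDesignResult | None:
    n = len(t_hap.seq)
    fwd_len = len(fwd)
    end = start + fwd_len - 1
    for plen in range(size_range[0], size_range[1] + 1):
        for olen in OPPOSITE_LENGTHS:
            r_end = start + plen - 1
            r_start = r_end - olen + 1
            if r_end > n or r_start <= w + sL - 1:
                continue
            rev_site = t_hap.seq[r_start - 1:r_end]
            rev = Primer(fwd.name + "_r", reverse_complement(rev_site), "reverse")
            # cheap screen: construct the would-be product per haplotype and
            # check annealing + allele-specific cutting before paying for the
            # full both-strand amplification scan
            ok = True
            for hap in haplotypes:
                if _mismatches(fwd.seq, hap.seq[start - 1:end]) > max_mismatch:
                    ok = False
                    break
                if _mismatches(rev_site, hap.seq[r_start - 1:r_end]) > max_mismatch:
                    ok = False
                    break
                product = fwd.seq + hap.seq[end:r_start - 1] + rev_site
                if bool(find_sites(product, enzyme)) != (hap.id in targets):
                    ok = False
                    break
            if not ok:
                continue
            # authoritative validation: virtual PCR + digest on every haplotype
            patterns: dict[str, list[int]] = {}
            for hap in haplotypes:
                amps = amplify(hap, fwd, rev, max_mismatch, size_range)
                if len(amps) != 1:
                    ok = False
                    break
                dig = digest(amps[0].product_seq, enzyme)
                patterns[hap.id] = dig.fragment_lengths
                if dig.cut != (hap.id in targets):
                    ok = False
                    break
            if ok:
                return AssayDesignResult(
                    fwd, rev, enzyme, targets, patterns,
                    len(fwd.mutated_positions), plen, strand,
                )
    return None


def design_assay(
    haplotypes: list[DnaRecord],
    snp: DiagnosticSNP,
    enzymes: list[Enzyme] | None = None,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
    max_subs: int = 2,
    max_mismatch: int = 3,
) -> DesignReport:
    """Search for allele-specific PCR-RFLP assays at a diagnostic SNP.

    Both orientations are explored (the reverse orientation by designing on
    the reverse-complemented haplotypes with the SNP position mirrored and
    swapping the resulting primer roles).  Every returned design has been
    re-simulated on every haplotype; ranking is deterministic.
    """
    if enzymes is None:
        enzymes = list(builtin_enzymes().values())
    lengths = {len(h.seq) for h in haplotypes}
    if len(lengths) != 1:
        raise ValueError("haplotypes must be pre-aligned to equal length")
    pos = snp.folmer_pos
    alleles = _snp_alleles(haplotypes, pos)
    if len(set(alleles.values())) < 2:
        raise ValueError(f"not polymorphic: all haplotypes share {alleles!r} at {pos}")

    n = next(iter(lengths))
    rc_haps = [DnaRecord(h.id, reverse_complement(h.seq), h.description) for h in haplotypes]
    rc_pos = n - pos + 1

    report = DesignReport()
    for enzyme in enzymes:
        found: list[AssayDesignResult] = []
        reasons = []
        plus, r1 = _design_one_strand(
            haplotypes, pos, enzyme, size_range, max_subs, max_mismatch, "+"
        )
        found.extend(plus)
        minus, r2 = _design_one_strand(
            rc_haps, rc_pos, enzyme, size_range, max_subs, max_mismatch, "-"
        )
        for r in minus:
            # map back: the design's coordinates live on the reverse strand;
            # primers and patterns are already strand-agnostic deliverables
            found.append(r)
        for r in (r1, r2):
            if r:
                reasons.append(r)
        if not found:
            report.failure_reasons[enzyme.name] = (
                "; ".join(sorted(set(reasons))) or "no candidate satisfied the constraints"
            )
        report.results.extend(found)

    report.results.sort(
        key=lambda r: (r.n_substitutions, r.product_len, r.enzyme.name, r.fwd.seq)
    )
    # drop exact duplicates (same primers + enzyme)
    seen = set()
    unique = []
    for r in report.results:
        key = (r.fwd.seq, r.rev.seq, r.enzyme.name)
        if key not in seen:
            seen.add(key)
            unique.append(r)
    report.results = unique
    return report
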