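# beetyping

Molecular identification of honey-bee (*Apis mellifera*) subspecies from the
COX1 barcoding region — as an in-silico toolkit.

Beekeeping programs that maintain pure breeding lines (*A. m. mellifera*,
*A. m. carpatica*, *A. m. carnica*, *A. m. caucasica*) need a fast,
sequencing-free way to verify the subspecies of a colony.  The 658-bp Folmer
fragment of the mitochondrial *COX1* gene carries a small set of diagnostic
SNPs — an A/G substitution at position 99 (the carnica/carpatica branch), a
G/A substitution at position 448 (carnica), and C→T / C→A substitutions at
position 421 marking the two *A. m. mellifera* haplogroups — but none of
these naturally creates a restriction-site difference.  The trick is
**mutagenic-primer PCR-RFLP (dCAPS)**: a primer carrying one or two
deliberate mismatches near its 3′ end overwrites the product so that,
*together with one allele of the nearby SNP*, a restriction recognition site
appears in the amplicon of that allele only.  Cut vs. uncut on a 3% agarose
gel then reads out the subspecies, with no sequencer involved.

`beetyping` implements the complete workflow:

* **`seqcore`** – IUPAC DNA alphabet, FASTA I/O, reverse complement,
  translation QC under the invertebrate mitochondrial code (stop codons,
  gaps).
* **`insilico_pcr`** – degenerate-primer annealing with mismatch tolerance
  and virtual amplification with the primer-overwrite rule; nested (two-step)
  PCR for degraded templates.
* **`restriction`** – enzyme model over degenerate recognition sites (AluI,
  HinfI, HspAI, MspI, DraI packaged, with isoschizomer resolution such as
  HpaII→MspI), complete-digest simulation and gel-resolvability checks.
* **`assay_design`** – the dCAPS designer: exhaustive, deterministic search
  over enzyme × primer-anchor × substitution space, every candidate validated
  by re-simulation on every haplotype.
* **`snp_classify`** – SNP calling in the Folmer frame, the three-position
  sequence key, and the RFLP decision matrix (including the documented
  carnica/carpatica ambiguity and caucasica-by-exclusion).
* **`phylo`** – Kimura 2-parameter distances (with saturation handling),
  neighbor joining, bootstrap supports, Newick I/O, group variability means.
* **`synthetic_data`** – a seeded generator of five validated 658-bp
  haplotypes that reproduce the full published fragment table without any
  download.
* **`cli`** – `beetyping simulate | amplify | digest | design | classify |
  typing | tree`.

## Worked example

```python
from beetyping import generate_fixtures, validate_assay, rflp_classify

fx = generate_fixtures()                       # seeded, validated fixtures
table = validate_assay(fx.assays["AmCarp"], fx.record_list())
for hap, row in table.items():
    print(f"{hap:14s} {'/'.join(map(str, row['fragments'])):8s} "
          f"{'cut' if row['cut'] else 'uncut'}")
```

```
mellifera_H1   141      uncut
mellifera_H2   141      uncut
carpatica      111/30   cut
carnica        111/30   cut
caucasica      141      uncut
```

The AmCarp-f/AmCarp-r amplicon (141 bp) is cleaved by HspAI into 111 + 30 bp
for carpatica and carnica — the haplotypes carrying G at Folmer position
99 — and left intact for everything else.  The gel pattern feeds the
decision matrix:

```python
call = rflp_classify({"AluI": "uncut", "HinfI": "uncut",
                      "HspAI": "cut", "MspI": "uncut"})
print(call.call, "|", call.confidence_note)
```

```
carpatica (carnica not excluded) | carnica_carpatica_ambiguous
```

The ambiguity flag is deliberate: a minority of carnica specimens share the
carpatica COX1 sequence, so an HspAI-cut / MspI-uncut gel can never fully
exclude carnica.

The same works from the shell:

```bash
beetyping simulate --seed 7 --out fixtures/
beetyping classify fixtures/observed_patterns.tsv --out calls.tsv
beetyping tree fixtures/haplotypes.fasta --reps 500 --seed 7 --out tree.nwk
```

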