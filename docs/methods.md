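# Methods

## The typing model

The toolkit treats honey-bee subspecies identification as deterministic
genotyping over the 658-bp Folmer frame of mitochondrial *COX1*.  All
coordinates are 1-based, inclusive, on the plus strand of that frame.  Three
diagnostic positions carry the signal:

| position | reference (caucasica-type) | variant | meaning |
|---|---|---|---|
| 99  | A | G | carnica + carpatica branch |
| 421 | C | T / A | *A. m. mellifera* haplogroup 1 / haplogroup 2 |
| 448 | A | G | carnica within the 99-G branch |

Two redundant keys read this signal: the **sequence key**
(`snp_classify.assign_haplogroup`) inspects the bases directly, and the
**gel key** (`rflp_classify`) reads the cut/uncut pattern of four PCR-RFLP
assays (AluI, HinfI, HspAI, MspI).  A caucasica-type sequence carries no
variant and no cuttable product: it is identified by exclusion, and the
toolkit says so explicitly (`caucasica_by_exclusion`).  Because a minority
of carnica mitochondria are sequence-identical to carpatica, the
HspAI-cut/MspI-uncut pattern is reported as "carpatica (carnica not
excluded)" with an ambiguity flag rather than as a clean call.  Patterns
matching no matrix row are `inconsistent`, never coerced to the nearest row.

Because published sources state the 448 polymorphism only as "G/A", the key
stores reference-vs-variant pairs relative to the caucasica background and
the packaged fixtures fix the orientation (carnica = G, completing CCGG);
this is an explicit assumption, not data.

## Virtual PCR and the primer-overwrite rule

`insilico_pcr.amplify` models the single mechanical fact that makes dCAPS
work: after the first cycles every product molecule carries the primer
sequences verbatim at its ends.  A product is

    resolved(fwd) + template interior + revcomp(resolved(rev))

Degenerate primer codes resolve to the template base when compatible (the
polymerase copies the template wherever the primer pool complements it) and
to the lexicographically smallest expansion otherwise.  Annealing tolerates
`max_mismatch` incompatibilities anywhere in the footprint — deliberately
**without** a 3′-clamp rule, because mutagenic primers prime despite
non-complementary 3′ termini; the default tolerance is 3.  All hit pairs in
the size window are enumerated, on both orientations; ambiguity is surfaced,
not hidden.  Two-step (nested) amplification re-amplifies each outer product
and is how degraded templates are rescued: damage under an outer-primer
footprint is *restored* by primer overwrite, letting inner primers anneal on
the first-round product when they cannot on the template.

## Digestion

`restriction.digest` performs a complete digest of linear DNA.  Recognition
sites (IUPAC-degenerate) are scanned on both strands; only top-strand cut
positions define fragments, because agarose electrophoresis reads
double-stranded length and overhang geometry is invisible.  Fragment lengths
always sum to the input length and are reported descending (gel
convention).  Isoschizomers resolve to their canonical record; GlaI resolves
with a warning since its methylation dependence is not modeled.
`gel_resolvable` applies two configurable thresholds for 3% agarose
(minimum visible fragment 20 bp, minimum separable difference 15 bp —
conservative values chosen below the ~28-30 bp primer-sized fragments these
assays produce).

## The dCAPS designer

`assay_design.design_assay` searches, per enzyme and strand, over site
windows overlapping the SNP, primer 3′-end anchors within (site length − 1)
bases of the SNP, and mutagenic primer lengths of 28-33 nt (opposite primer
18-20 nt, matching the published assay dimensions).  Constraints:

* the site base over the SNP must match the target allele and mismatch every
  other allele (otherwise the window cannot discriminate);
* substitutions fall only in the primer's 3′-terminal half, never on the SNP
  itself (the template allele must complete the site), and number at most 2;
* at least one substitution is required — a site that pre-exists is a plain
  CAPS marker, not a design product;
* the whole product of every non-target haplotype must be site-free on both
  strands (primers alone are never allele-specific).

Every surviving candidate is validated by full re-simulation
(amplify → digest on every haplotype, requiring exactly one product each)
before being returned.  Ranking is (substitution count, product length,
enzyme name, primer sequence) — fully deterministic.  A fast screen by
direct product construction precedes the authoritative amplify-based
validation purely for speed; only re-simulated designs are ever reported.

## Synthetic fixtures

`synthetic_data.generate_fixtures` builds five 658-bp haplotypes on a shared
seeded background (default GC content 0.30, reflecting the AT-rich insect
mitochondrial genome) and implants, at fixed offsets, the four primer-pair
footprints, the three diagnostic alleles, and a restriction-site context per
assay.  Geometry (plus-strand Folmer coordinates):

| assay | amplicon | orientation | site | cut after | fragments |
|---|---|---|---|---|---|
| AmEu1 / AluI  | 1-139   | + | AGCT at 31-34, T(34) in H1 only    | 32 | 107 + 32 |
| AmCarp / HspAI| 70-210  | + | GCGC at 99-102, G(99) in carn/carp | 30 | 111 + 30 |
| AmCar / MspI  | 328-475 | + | CCGG at 445-448, G(448) in carnica | 118 | 118 + 30 |
| AmEu2 / HinfI | 396-545 | − | GANTC on the product strand, completed by the 421-A allele (H2) | 122 | 122 + 28 |

With the published primer sequences, a recognition site completed exactly at
the primer-overwrite junction cannot yield these printed splits (for the
AluI assay the junction bases are fixed to G,C by the primer, forcing a
108/31 split); the generator therefore places each site wholly in the
amplicon interior, completed by the diagnostic allele, at the offset that
produces the published split exactly.  Mutagenic primer positions are still
*reverted* on the template (the substitution enters products only through
overwrite), so the overwrite machinery is exercised on every amplification.
The AmEu2 amplicon is placed on the minus strand so that the same physical
421 allele drives both mellifera assays without colliding with the AluI site
context.

mellifera_H1 additionally diverges by eight C↔T transitions (two of which
are the 421 key and the AluI completer), one A→G and one T→A substitution;
the free-zone substitutions are confined to frame regions outside every
amplicon so intra-subspecies variability can be emulated (`mutate`) without
disturbing any assay.

Each candidate background is validated by running the real pipeline over all
20 assay × haplotype cells — exact fragment-length equality, exactly one
product per reaction, zero recognition sites in non-target products — plus
both classification keys returning each fixture's own label, and is
rejection-sampled until all constraints hold (typically within a handful of
draws; hard limit 500).  Fixtures reproduce the combinatorial structure of
the assays, **not** the real GenBank sequences: passing tests demonstrate the
correctness of the simulation and classification machinery, not properties
of real bee populations.  In particular the fixture frame cannot nest all
four amplicons inside the long AmCarp-f/AmCar-r fragment as real templates
do; nested-PCR rescue is exercised on a purpose-built degraded-template
fixture instead.

## Distances and trees

K2P distances use the standard two-parameter form
d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q) with P/Q the transition/transversion
proportions among retained sites.  Pairwise deletion of gap/ambiguous sites
is the default; complete deletion is available by flag.  Saturated pairs
(non-positive logarithm argument) raise an error rather than receiving an
arbitrary large distance; `mean_group_distance` excludes and counts them.
Within-group variability is reported as the mean pairwise K2P distance over
unordered pairs (an alternative convention uses p-distances; the choice is
documented here because published "variability" figures do not state
theirs).

Neighbor joining uses the standard Q-criterion agglomeration with two
documented numerical choices: ties broken by the lexicographically smallest
pair of labels (internal nodes labelled by their smallest descendant leaf),
and negative branch-length estimates clamped to zero.  Bootstrap resamples
alignment columns with replacement, rebuilds the NJ tree per replicate
(saturated replicates are skipped and counted) and reports, per internal
bipartition of the original tree, the integer percentage of replicates
containing it.  Supports are invariant to input taxon order for a fixed
seed because replicate rows are drawn in label-sorted order.

## Problem sizes and defaults

Unit and acceptance tests run on 300-bp design instances, 658-bp fixtures,
5-8-taxon trees and 200-instance oracle sweeps; the whole suite completes in
well under a minute.  Key defaults: `max_mismatch = 3`; assay size window
120-160 bp (general PCR window 100-1000 bp); bootstrap 500 replicates with
pairwise deletion; fixture seed 20180127.  The translation QC defaults to
NCBI genetic code table 5 (invertebrate mitochondrial); when no frame is
given, the frame with fewest internal stops is chosen and flagged as a
heuristic, since the Folmer amplicon's frame offset depends on upstream
trimming.

## Known limitations

* No thermodynamics: melting temperature, secondary structure and
  primer-dimer effects are not modeled; annealing is a pure mismatch count.
* Complete digestion only; no partial-digest kinetics, star activity or
  methylation sensitivity (GlaI warns).
* Linear templates only.
* The NJ/bootstrap machinery is for barcoding-scale alignments, not for
  large phylogenomic inference.
* Classification is a deterministic table lookup; no population-frequency
  estimation is attempted.
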