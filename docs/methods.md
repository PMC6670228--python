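# Methods

## Scope and model

`gliadkit` implements the computational side of a guide-design and
mutation-screen workflow for the wheat α- and γ-gliadin families: sequence
annotation, epitope-based subgroup classification, protospacer evaluation,
locus-scale edit simulation, and screen summary statistics, exercised on a
synthetic family generator. Wet-lab stages (transformation, gel
electrophoresis chemistry, qPCR copy-number assays) are out of scope; the
gel readout enters only as an abstraction (binned protein masses).

## Coordinates and conventions

DNA intervals are 0-based half-open; protein positions are 1-based
inclusive. Translation is always frame 0 from the first base (inputs are
ATG-anchored intronless CDS; there is no ORF search). A pseudogene is a
sequence whose translation contains `*` anywhere before the final codon.

## Epitope catalogue

Coeliac-disease epitopes are canonical 9-mer cores shipped as an editable
TSV (`data/epitopes.tsv`), stored in genomically encoded Q-form. Registry
listings give deamidated (E-substituted) forms; scanning with
`qe_equivalence=True` treats Q and E as equal and recovers those matches.
The default scan is on the genomic form because the pipeline operates on
gene-derived sequences; deamidation is physiological, not genomic.
Pseudogene proteins are scanned over their pre-stop residues only.

## Domain segmentation

The signal peptide is the first 20 residues by default (a configured
length; gliadin signal peptides are ~20 aa but the exact value is not
critical to any downstream logic). The repetitive/epitope region spans
from the first to the last epitope hit. Because the hit span generally
starts after the signal peptide, an `upstream` segment is emitted between
the two so the segmentation remains contiguous and covers every residue up
to the first stop — this fourth segment name is a deliberate extension of
the three-domain scheme, which cannot otherwise be both contiguous and
hit-anchored.

## Subgroup classification

Genes are grouped by exact epitope signature — the ordered
(epitope, count) tuple restricted to the repetitive region. Pseudogenes
are excluded by default (guide design focused on full-length genes).
Subgenome assignment is a majority vote over members carrying a genome
label, with threshold 0.6: below it the subgroup is `ambiguous` — the
safer call, since real γ-gliadin subgroups correlate poorly with a single
subgenome. In generated data the labels are planted, so recovery is exact.

## Guide matching

SpCas9 conventions: NGG PAM immediately 3′ of the protospacer on the
matched strand, blunt cut 3 bp 5′ of the PAM. The stored guides target the
antisense strand of the coding sequence, so their matches appear as
CCN + reverse-complement(protospacer) on the stored strand. Protospacer
lengths 19 and 20 are both accepted (the shipped guide set mixes both).
Coverage counting uses 100% identity; off-target scanning defaults to
≤ 3 mismatches with a flag for hits whose PAM-proximal 12 nt are
mismatch-free. IUPAC degenerate codes in the query are matched as set
membership, which also serves the degenerate cloning primers.

Hairpin and cross-dimer screens are exact-complement run lengths
(defaults: stem ≥ 8 with loop ≥ 3 flags a hairpin; an antiparallel
Watson–Crick run ≥ 10 flags a cross-dimer). They stand in for
thermodynamic folding and duplex tools and carry no energy model; the
thresholds are configuration.

## Synthetic families (the stated world)

A subgroup's prototype protein is
`signal peptide + upstream scaffold + epitope block + downstream scaffold`,
where the block concatenates the planted epitope copies with a 2-residue
linker. Scaffolds and the signal peptide contain no Q or E, so they can
never collide with the Gln-rich catalogue peptides under either scan mode;
they are stylised (repeat-structured but not wheat codon usage — a
declared non-goal). Proteins are reverse-translated with a seeded uniform
choice among synonymous codons: paralogs share proteins but differ in DNA.
Pseudogenisation substitutes one random internal codon with a stop.

Defaults: α = 100 copies (published range 60–150), 90% pseudogenes, five
subgroups (2×A, 2×B, 1×D); γ = 40 copies, six subgroups with the repeated
γ4c epitope at 1..6 copies across them (so a guide inside that epitope
cuts 1–6 times per gene); ω = 16 copies. The γ/ω pseudogene fractions
(0.5) and intergenic spacer range (50–300 bp uniform) are not published
and are fixed here as assumptions. Genome labels are planted on all genes
by default (`labeled_fraction=1.0`), emulating fully anchored
diploid-relative information; lower fractions model sparser anchoring.

Guide-target embedding inserts a codon-multiple cassette
(protospacer + PAM + frame padding chosen to avoid stop codons) at a
codon boundary of the requested region class, reverse-complemented by
default. Embedding verifies the motif count afterwards and refuses to
create a premature stop in an intact gene.

## Edit simulation

Cuts on an allele are resolved left-to-right: each adjacent pair excises
its segment with `p_segment_deletion` (consuming both cuts; fully
contained genes are `deleted`, the two flanking cut genes `fusion` when
the cuts lie in different genes, an in-gene excision otherwise), and every
unconsumed cut re-ligates perfectly (`p_perfect_repair`, default 0.2) or
acquires an indel (deletion 1–10 nt with probability 0.7, else insertion
1–3 nt; all invented defaults, config-exposed). Consequences are
frame-logic calls verifiable by re-annotating the edited allele.

The gel proxy maps each intact protein to `round(110 Da × residues /
500 Da)`; any monotone mass proxy suffices for presence/absence logic.
A grain is a genotype of 3 subgenome loci × 2 alleles edited
independently (no chimerism, no post-meiotic activity — one genotype per
grain, since the gel readout cannot resolve chimerism either). Band
intensity is only coarsely represented as bin counts, so "potential
changes" here capture count shifts but not smear/position effects.

### Analytic check configuration

For the closed-form consistency check the policy is restricted to 1-nt
deletions with no segment deletion, so every fired, imperfectly repaired
cut is a frameshift knockout and

P(grain changed) = 1 − (1 − e·(1 − p_perfect))^S

for S independent target sites per grain. The reduced genotype (3 genes
per locus, one locus per subgenome, S = 18) keeps 200 replicates of a
117-plant × 8-grain screen within seconds; the method-of-moments inversion
of the same formula recovers the generating efficiency. This restriction
exists to make the independent closed form exact, not to ease the test.

## Screening statistics

Percentages are rounded half-up (printed tables use display rounding;
raw values are kept in the DataFrame). The heterogeneity test is the
uncorrected Pearson χ² on the 2×k successes/failures table with df = k−1
— the default convention when only "chi-square" is specified. On the
shipped grain tables this gives p ≈ 0.011 for *any* changes and ≈ 0.088
for *clear* changes: the same significant/non-significant dichotomy as the
originally reported p = 0.015 / 0.097, whose exact values cannot be
reproduced because the tested table (plants vs grains) and any correction
were not specified; this implementation states its method exactly rather
than tuning to the printed numbers. An expected cell below 1 sets a
warning flag instead of blocking the test. Rates printed truncated at the
source (e.g. 14/360 → "3.88%") are reported here rounded half-up (3.89),
with comparisons carried out at a 0.02-point tolerance.

## Known limitations

- No microhomology-aware repair, base-editor outcomes, or expression
  compensation; indel sizes are a simple two-component distribution.
- No thermodynamic folding or genome-indexed off-target search; the
  heuristics bound complement runs only.
- Scaffold sequences are epitope-free by construction, so classification
  difficulty is lower than in real alignments where epitope variants shade
  into each other; a green subgroup-recovery test establishes correctness
  of the grouping logic, not robustness to real sequence noise.
- ω-gliadin/γ-locus interleaving (cuts in a targeted family deleting
  untargeted neighbours) is supported by the locus model but off by
  default.
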