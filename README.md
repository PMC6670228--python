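# gliadkit

Toolkit for designing CRISPR/Cas9 guides against the wheat gliadin
multigene families and for quantifying the resulting mutation screens.

## The problem

Wheat gluten contains gliadin storage proteins whose Gln/Pro-rich 9-mer
epitopes (e.g. DQ2.5-glia-γ4c) trigger coeliac disease. The α- and
γ-gliadins are encoded by large tandem-arrayed families — on the order of
60–150 α copies and ~40 γ copies across the A, B and D subgenomes of
hexaploid bread wheat, with a high pseudogene fraction (~90% for α). A
single sgRNA therefore has to hit a *conserved* site shared by as many
family members as possible, and the phenotypic readout of a mutation
screen is a gel profile, not a genotype.

`gliadkit` models this workflow end to end:

- **synthetic** — seeded generator of gliadin-like families: intronless
  coding sequences (signal peptide + epitope-bearing repetitive block +
  scaffold), discrete subgroups tied to subgenomes, premature-stop
  pseudogenes, tandem loci with random spacers, and protospacer/PAM
  cassette embedding so guide-coverage scenarios can be stated exactly.
- **annotation** — frame-0 translation, pseudogene calling ('*' before the
  terminal codon), exact 9-mer epitope scanning (optionally treating Q≡E to
  match deamidated registry peptides), domain segmentation.
- **classification** — epitope-signature subgroups and majority-vote
  subgenome assignment (threshold 0.6, else `ambiguous`).
- **guides** — protospacer matching on both strands with IUPAC degenerate
  codes, NGG PAM, blunt cut 3 bp 5′ of the PAM; per-subgroup coverage
  matrices at 100% identity; mismatch-annotated off-target scans; hairpin
  and cross-dimer heuristics.
- **editsim** — multiplexed cut/repair simulation on tandem loci
  (segment deletions between co-occurring cuts, small indels, perfect
  repair), frame-logic consequence calls, and a binned-mass protein
  profile emulating a one-dimensional gel ("clear" = band gained/lost,
  "potential" = intensity/count change only).
- **stats** — screen percentage tables (half-up rounding) and the
  uncorrected Pearson χ² heterogeneity test on 2×k construct tables,
  df = k−1.

## Worked example

```python
from gliadkit import demo
from gliadkit.annotation import default_catalogue
from gliadkit.classification import classify
from gliadkit.guides import coverage_matrix, load_guides

genes = demo.alpha_guide_demo(seed=7)          # 40 intact α-like genes
groups = classify(genes, default_catalogue().subset("alpha"))
cov = coverage_matrix(
    [g for g in load_guides() if g.name.startswith("sgRNA_alpha")],
    groups, {g.id: g for g in genes},
)
print(cov.table)
```

prints

```
                sg1  sg2  sg3  sg4  sg5
sgRNA_alpha87     0    5    0    0    0
sgRNA_alpha213   11   10    8    6    5
sgRNA_alpha324   11    0    8    0    5
```

Five subgroups are recovered (two per A and B subgenome plus one D).
`sgRNA_alpha213` reaches every subgroup; `sgRNA_alpha324` misses both
B-genome subgroups (`sg2`, `sg4`); `sgRNA_alpha87` only hits part of one
B subgroup — the coverage pattern the guide set was designed around.

On the screening side:

```python
from gliadkit.stats import load_screen_counts, heterogeneity_chi2
counts = load_screen_counts()
res = heterogeneity_chi2([c.grains_any for c in counts],
                         [c.grains_tested for c in counts])
print(round(res.statistic, 2), round(res.p_value, 3))   # 11.14 0.011
```

i.e. the four constructs differ significantly in the fraction of grains
with *any* profile change (p < 0.05), but not for *clear* changes alone
(p ≈ 0.088).

## Command line

```
gliadkit run --seed 7 --outdir out/        # generate → … → stats
gliadkit generate --family gamma --seed 3 --out-prefix out/gamma
gliadkit stats --out-prefix out/published
```

Every run writes an `artifact_manifest.json` of content hashes; identical
seed and options give identical hashes.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the main computation from scratch — the shipped count tables
through `stats`, a seeded synthetic α family through classification and
guide coverage, the γ repeat-count cut series, and a Monte-Carlo edit
screen — and writes the JSON target map.

See `docs/methods.md` for the model details, parameter defaults, and known
limitations.
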