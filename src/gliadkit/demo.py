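"""Seeded demonstration datasets wiring the pipeline stages together.

These builders encode the published coverage statements as a generated
world: which guides hit which subgroups, how often the repeated gamma
epitope is targeted, and a reduced hexaploid genotype for the Monte-Carlo
screen. They are first-class library code (the acceptance checks and the
CLI demo both run on them), not test fixtures.
"""

from __future__ import annotations

from .annotation import GliadinGene, default_catalogue
from .editsim import LocusModel, RepairPolicy
from .guides import GuideCandidate, load_guides
from .synthetic import (
    FamilySpec,
    default_alpha_subgroups,
    default_gamma_subgroups,
    embed_guide_targets,
    generate_family,
    generate_locus,
)


def _guide(name: str) -> GuideCandidate:
    return next(g for g in load_guides() if g.name == name)


def alpha_guide_demo(seed: int = 7, n_copies: int = 40) -> list[GliadinGene]:
    """Alpha family (5 subgroups, no pseudogenes) with guides planted per
    the published coverage pattern.

    sgRNA_alpha213 is embedded in every gene (covers all five subgroups);
    sgRNA_alpha324 is withheld from both B-genome subgroups; sgRNA_alpha87
    is embedded in only half the members of one B subgroup.
    """
    spec = FamilySpec(
        family="alpha",
        n_copies_total=n_copies,
        pseudogene_fraction=0.0,
        subgroup_defs=default_alpha_subgroups(),
        seed=seed,
    )
    genes = generate_family(spec)
    catalogue = default_catalogue().subset("alpha")

    genes = embed_guide_targets(
        genes, [_guide("sgRNA_alpha213").protospacer], "epitope_upstream",
        rc=True, catalogue=catalogue,
    )
    non_b = [i for i, g in enumerate(genes) if not g.subgroup.startswith("alpha-B")]
    genes = embed_guide_targets(
        genes, [_guide("sgRNA_alpha324").protospacer], "epitope_downstream",
        rc=True, indices=non_b, catalogue=catalogue,
    )
    b1 = [i for i, g in enumerate(genes) if g.subgroup == "alpha-B1"]
    genes = embed_guide_targets(
        genes, [_guide("sgRNA_alpha87").protospacer], "post_signal_peptide",
        rc=True, indices=b1[: max(1, len(b1) // 2)], catalogue=catalogue,
    )
    return genes


def gamma_cut_series(seed: int = 11) -> list[tuple[int, GliadinGene]]:
    """Six intact gamma genes carrying k = 1..6 copies of the repeated-
    epitope guide's target motif (the guide inside the most abundant gamma
    epitope cuts once per repeat)."""
    spec = FamilySpec(
        family="gamma",
        n_copies_total=6,
        pseudogene_fraction=0.0,
        subgroup_defs=default_gamma_subgroups(),
        seed=seed,
    )
    genes = generate_family(spec)
    catalogue = default_catalogue().subset("gamma")
    motif = _guide("sgRNA_gamma272").protospacer
    out = []
    for k, gene in enumerate(genes, start=1):
        (embedded,) = embed_guide_targets(
            [gene], [motif], "epitope_internal", rc=True, copies=k,
            catalogue=catalogue,
        )
        out.append((k, embedded))
    return out


def screen_genotype(
    seed: int = 3, genes_per_locus: int = 3
) -> list[LocusModel]:
    """Reduced hexaploid alpha genotype: one locus per subgenome, each with
    ``genes_per_locus`` intact genes carrying exactly one guide target site.

    Per grain (two alleles per locus) this yields
    3 * genes_per_locus * 2 independent target sites.
    """
    catalogue = default_catalogue().subset("alpha")
    motif = _guide("sgRNA_alpha213").protospacer
    loci = []
    subgroups = default_alpha_subgroups()
    for k, genome in enumerate(("A", "B", "D")):
        spec = FamilySpec(
            family="alpha",
            n_copies_total=genes_per_locus,
            pseudogene_fraction=0.0,
            subgroup_defs=subgroups[: min(genes_per_locus, len(subgroups))],
            seed=seed + 101 * k,
        )
        genes = generate_family(spec)
        genes = embed_guide_targets(
            genes, [motif], "epitope_upstream", rc=True, catalogue=catalogue
        )
        loci.append(
            generate_locus(
                genes,
                spacer_len_range=(50, 150),
                seed=seed + 101 * k + 1,
                locus_id=f"Gli-2_{genome}",
                genome=genome,
            )
        )
    return loci


def analytic_policy(p_perfect_repair: float = 0.2) -> RepairPolicy:
    """Repair policy under which the per-grain change probability has a
    closed form: no segment deletions and every indel a 1-nt deletion, so
    each fired-and-imperfectly-repaired cut is a frameshift knockout."""
    return RepairPolicy(
        p_segment_deletion=0.0,
        p_perfect_repair=p_perfect_repair,
        p_deletion=1.0,
        deletion_sizes=(1,),
        insertion_sizes=(1,),
    )
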