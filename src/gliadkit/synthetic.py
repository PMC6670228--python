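"""Seeded generator of gliadin-like gene families and tandem loci.

Emulates the statistical structure of the wheat alpha/gamma-gliadin
families: intronless coding sequences built from a signal peptide, a
scaffold, and a repetitive block of planted CD epitope copies; discrete
protein subgroups tied to the A/B/D subgenomes; a high pseudogene fraction
(premature in-frame stops); and tandem loci with random intergenic spacers.

Scaffold and signal-peptide templates deliberately contain no Q or E, so
they can never collide with catalogue epitopes (all canonical cores are
Gln-rich) under either the genomic or the deamidation-equivalent scan mode.
Proteins are reverse-translated with seeded uniform choice among synonymous
codons, so DNA copies differ while proteins stay subgroup-identical.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .annotation import (
    DEFAULT_SIGNAL_PEPTIDE_LEN,
    EpitopeCatalogue,
    GliadinGene,
    default_catalogue,
    scan_epitopes,
    segment_domains,
)
from .editsim import LocusModel

_STOP_CODONS = ("TAA", "TAG", "TGA")
_FAMILIES = ("alpha", "gamma", "omega")
_GENOMES = ("A", "B", "D")

# aa -> tuple of synonymous codons, standard genetic code
_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _CODONS.setdefault(_aa, ())
    _CODONS[_aa] += (_codon,)

#: 20-residue gliadin-style secretion signal (Q/E-free variant)
DEFAULT_SIGNAL_PEPTIDE = "MKTFLILALLAIVATTATTA"

# Q/E-free non-epitope scaffolds, split as (upstream, downstream) of the
# planted epitope block. Stylised: repeat structure, not wheat codon usage.
_SCAFFOLDS = {
    "alpha": (
        "VRVPVPHLHPKNPSHHHPHNHVPL",
        "VLHHHNIAHGRSHVLHHSTYHLLHNLCCHHLWHIPNHSHCHAIHNVVHAII"
        "LHHHHKHHHHPSSHVSFHHPLHHYPLGHGSFRPSHHNPHAHGSVHP",
    ),
    "gamma": (
        "NIHVDPSGHVHWLHLSKNPSHHHPH",
        "FLHPHHPFPHHPHHPYPHHPHSIIHSLHHLNPCKNFLLHHCNHVSLVSSLV"
        "SIILPRSDCHVMHHHCCHHLAHIPHHLHCAAIHSVVHSIIMHHH",
    ),
    "omega": (
        "ARHLNPSNKVLHSHHHPHVHHHPH",
        "FPHHHHHPFPSHHPYLHLHNPCKNILLHHCSPVAMPHRLARSHMLHHSSCH"
        "VMHHHCCHHLHHIPHHPHCAAIHSVVHAIIMHHH",
    ),
}

#: linker inserted between planted epitope copies (Q/E-free)
_EPITOPE_LINKER = "SG"

IUPAC_DNA = frozenset("ACGT")


@dataclass(frozen=True)
class SubgroupDef:
    """One protein subgroup: a genome of origin plus an epitope signature.

    ``epitope_variants`` is an ordered list of (epitope name, 9-mer peptide,
    copies); the prototype protein carries exactly that block between the
    scaffold halves.
    """

    label: str
    genome: str
    epitope_variants: tuple[tuple[str, str, int], ...]
    signal_peptide: str = DEFAULT_SIGNAL_PEPTIDE
    scaffold: tuple[str, str] = _SCAFFOLDS["alpha"]

    def __post_init__(self) -> None:
        if self.genome not in _GENOMES:
            raise ValueError(f"SubgroupDef.genome: invalid genome {self.genome!r}")
        for name, pep, copies in self.epitope_variants:
            if len(pep) != 9:
                raise ValueError(
                    f"SubgroupDef.epitope_variants: peptide for {name!r} must "
                    f"be a 9-mer, got {len(pep)}"
                )
            if copies < 0:
                raise ValueError(
                    f"SubgroupDef.epitope_variants: negative copies for {name!r}"
                )

    def prototype_protein(self) -> str:
        """Full-length protein shared by all intact members of the subgroup."""
        block = _EPITOPE_LINKER.join(
            pep for name, pep, copies in self.epitope_variants for _ in range(copies)
        )
        up, down = self.scaffold
        return self.signal_peptide + up + block + down


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one gliadin family to generate."""

    family: str
    n_copies_total: int
    pseudogene_fraction: float
    subgroup_defs: tuple[SubgroupDef, ...]
    loci_per_genome: int = 1
    seed: int = 0
    labeled_fraction: float = 1.0  # fraction of genes carrying a genome label

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"FamilySpec.family: invalid family {self.family!r}")
        if self.n_copies_total <= 0:
            raise ValueError("FamilySpec.n_copies_total: must be positive")
        if not 0.0 <= self.pseudogene_fraction <= 1.0:
            raise ValueError("FamilySpec.pseudogene_fraction: must be in [0, 1]")
        if not self.subgroup_defs:
            raise ValueError("FamilySpec.subgroup_defs: at least one subgroup")
        if self.n_copies_total < len(self.subgroup_defs):
            raise ValueError(
                "FamilySpec.n_copies_total: fewer copies than subgroups"
            )
        if self.loci_per_genome <= 0:
            raise ValueError("FamilySpec.loci_per_genome: must be positive")
        if not 0.0 <= self.labeled_fraction <= 1.0:
            raise ValueError("FamilySpec.labeled_fraction: must be in [0, 1]")


@dataclass
class FamilyPlan:
    """Generator ground truth for one family draw."""

    subgroup_of: dict[str, str] = field(default_factory=dict)
    genome_of: dict[str, str] = field(default_factory=dict)
    pseudogene: dict[str, bool] = field(default_factory=dict)


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        choices = _CODONS[aa]
        codons.append(choices[rng.integers(len(choices))])
    return "".join(codons)


def generate_family(
    spec: FamilySpec, return_plan: bool = False
) -> list[GliadinGene] | tuple[list[GliadinGene], FamilyPlan]:
    """Draw a seeded gliadin-like family.

    Every gene is a synonymous-codon re-encoding of its subgroup's prototype
    protein plus a terminal stop; genes flagged as pseudogenes receive one
    random internal sense->stop codon substitution. The first
    ``len(subgroup_defs)`` genes cover each subgroup once, the remainder are
    assigned uniformly at random.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_copies_total
    defs = spec.subgroup_defs
    sub_idx = np.concatenate(
        [np.arange(len(defs)), rng.integers(0, len(defs), size=n - len(defs))]
    )
    pseudo = rng.random(n) < spec.pseudogene_fraction
    labeled = rng.random(n) < spec.labeled_fraction

    genes: list[GliadinGene] = []
    plan = FamilyPlan()
    for i in range(n):
        sg = defs[int(sub_idx[i])]
        protein = sg.prototype_protein()
        dna = _reverse_translate(protein, rng) + _STOP_CODONS[rng.integers(3)]
        if pseudo[i]:
            # one random internal sense codon becomes a stop ("early stop
            # codons at various places"); keep the start codon intact
            codon_pos = int(rng.integers(1, len(protein)))
            stop = _STOP_CODONS[rng.integers(3)]
            dna = dna[: 3 * codon_pos] + stop + dna[3 * codon_pos + 3 :]
        gene_id = f"{spec.family}_{i:04d}"
        gene = GliadinGene(
            id=gene_id,
            family=spec.family,
            dna=dna,
            genome_label=sg.genome if labeled[i] else "unknown",
            subgroup=sg.label,
        )
        genes.append(gene)
        plan.subgroup_of[gene_id] = sg.label
        plan.genome_of[gene_id] = sg.genome
        plan.pseudogene[gene_id] = bool(pseudo[i])
    if return_plan:
        return genes, plan
    return genes


def generate_locus(
    genes: list[GliadinGene],
    spacer_len_range: tuple[int, int] = (50, 300),
    seed: int = 0,
    locus_id: str = "locus",
    genome: str = "A",
) -> LocusModel:
    """Place genes in order on one strand with random intergenic spacers.

    Spacers (uniform length within ``spacer_len_range``, random ACGT) occur
    between consecutive genes only; coordinates are 0-based half-open and the
    concatenated sequence is reconstructible from the intervals.
    """
    if not genes:
        raise ValueError("generate_locus: empty gene list")
    lo, hi = spacer_len_range
    if lo < 0 or hi < lo:
        raise ValueError("generate_locus: invalid spacer length range")
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    intervals: list[tuple[str, int, int]] = []
    cursor = 0
    for k, gene in enumerate(genes):
        if k > 0:
            spacer_len = int(rng.integers(lo, hi + 1))
            spacer = "".join("ACGT"[b] for b in rng.integers(0, 4, size=spacer_len))
            parts.append(spacer)
            cursor += spacer_len
        parts.append(gene.dna)
        intervals.append((gene.id, cursor, cursor + len(gene.dna)))
        cursor += len(gene.dna)
    return LocusModel(
        locus_id=locus_id,
        genome=genome,
        sequence="".join(parts),
        gene_intervals=tuple(intervals),
        family=genes[0].family,
    )


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _build_cassette(motif: str, rc: bool) -> str:
    """Codon-multiple insert containing the protospacer plus a PAM.

    With ``rc`` the guide will match the antisense strand (the shipped
    guides target the complementary strand of the stored coding sequence):
    the coding strand carries CCN + reverse-complement(motif). Otherwise it
    carries motif + NGG. Pad bases are chosen so no in-frame stop codon is
    created; raises if every variant collides with a stop.
    """
    body = _revcomp(motif) if rc else motif
    for n_base in "ACGT":
        core = ("CC" + n_base + body) if rc else (body + n_base + "GG")
        pad_len = (-len(core)) % 3
        for pad in itertools.product("ACGT", repeat=pad_len):
            cassette = core + "".join(pad)
            codons = [cassette[i : i + 3] for i in range(0, len(cassette), 3)]
            if any(c in _STOP_CODONS for c in codons):
                continue
            return cassette
    raise ValueError(
        f"motif {motif!r} cannot be embedded without creating a stop codon"
    )


def _insertion_offset(
    gene: GliadinGene, region: str, catalogue: EpitopeCatalogue
) -> int:
    """Codon-aligned DNA offset for a region class."""
    hits = scan_epitopes(gene.mature_protein, catalogue, gene_id=gene.id)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        dmap = segment_domains(gene.protein, hits, gene_id=gene.id)
    rep = dmap.region("repetitive")
    if region == "post_signal_peptide" or rep is None:
        return 3 * DEFAULT_SIGNAL_PEPTIDE_LEN
    if region == "epitope_upstream":
        return 3 * (rep.start - 1)
    if region == "epitope_internal":
        mid = rep.start - 1 + (rep.end - rep.start + 1) // 2
        return 3 * mid
    if region == "epitope_downstream":
        return 3 * rep.end
    raise ValueError(f"unknown region class {region!r}")


def _count_occurrences(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        start = haystack.find(needle, start)
        if start == -1:
            return count
        count += 1
        start += 1


def embed_guide_targets(
    genes: list[GliadinGene],
    guide_motifs: list[str],
    placement: str = "epitope_upstream",
    rc: bool = True,
    copies: int = 1,
    indices: list[int] | None = None,
    catalogue: EpitopeCatalogue | None = None,
) -> list[GliadinGene]:
    """Return copies of ``genes`` with protospacer+PAM cassettes planted.

    Each selected gene receives each motif exactly ``copies`` times at the
    requested region class, reverse-complemented when ``rc`` so the guide
    matches the antisense strand (as the printed protospacers do). Reading
    frame outside the cassette is preserved; embedding that would force a
    premature stop raises.
    """
    for motif in guide_motifs:
        if not 17 <= len(motif) <= 23 or set(motif) - IUPAC_DNA:
            raise ValueError(f"motif {motif!r} must be ACGT of length 17-23")
    if copies < 0:
        raise ValueError("copies must be >= 0")
    catalogue = catalogue or default_catalogue()
    selected = set(range(len(genes))) if indices is None else set(indices)

    out: list[GliadinGene] = []
    for i, gene in enumerate(genes):
        if i not in selected or copies == 0 or not guide_motifs:
            out.append(dataclasses.replace(gene))
            continue
        new = dataclasses.replace(gene)
        for motif in guide_motifs:
            cassette = _build_cassette(motif, rc)
            offset = _insertion_offset(new, placement, catalogue)
            insert = cassette * copies
            new.dna = new.dna[:offset] + insert + new.dna[offset:]
            new.refresh()
            searched = _revcomp(motif) if rc else motif
            found = _count_occurrences(new.dna, searched)
            if found != copies:
                raise ValueError(
                    f"gene {gene.id}: motif {motif!r} occurs {found} times "
                    f"after embedding, expected {copies}"
                )
            if not gene.is_pseudogene and new.is_pseudogene:
                raise ValueError(
                    f"gene {gene.id}: embedding {motif!r} created a premature stop"
                )
        out.append(new)
    return out


# ---------------------------------------------------------------------------
# Default family specifications (the stated world of the analysis)
# ---------------------------------------------------------------------------

def _variants(*items: tuple[str, int]) -> tuple[tuple[str, str, int], ...]:
    cat = {e.name: e.peptide for e in default_catalogue()}
    return tuple((name, cat[name], copies) for name, copies in items)


def default_alpha_subgroups() -> tuple[SubgroupDef, ...]:
    """Five alpha subgroups: two A, two B, one D (the unique-variant group)."""
    sc = _SCAFFOLDS["alpha"]
    return (
        SubgroupDef("alpha-A1", "A", _variants(("DQ2.5-glia-a1a", 2), ("DQ2.5-glia-a2", 1)), scaffold=sc),
        SubgroupDef("alpha-A2", "A", _variants(("DQ2.5-glia-a1a", 1), ("DQ2.5-glia-a1b", 1), ("DQ2.5-glia-a3", 1)), scaffold=sc),
        SubgroupDef("alpha-B1", "B", _variants(("DQ2.5-glia-a3", 1)), scaffold=sc),
        SubgroupDef("alpha-B2", "B", _variants(("DQ2.5-glia-a2", 2)), scaffold=sc),
        SubgroupDef("alpha-D1", "D", _variants(("DQ2.5-glia-a1a", 2), ("DQ2.5-glia-a1b", 1), ("DQ2.5-glia-a2", 1), ("DQ2.5-glia-a3", 1)), scaffold=sc),
    )


def default_gamma_subgroups() -> tuple[SubgroupDef, ...]:
    """Six gamma subgroups; g4c copy number runs 1..6 across them, so a guide
    inside that epitope cuts between one and six times per gene."""
    sc = _SCAFFOLDS["gamma"]
    return (
        SubgroupDef("gamma-B1", "B", _variants(("DQ2.5-glia-g3", 1), ("DQ2.5-glia-g4c", 1)), scaffold=sc),
        SubgroupDef("gamma-A1", "A", _variants(("DQ2.5-glia-g1", 1), ("DQ2.5-glia-g4c", 2)), scaffold=sc),
        SubgroupDef("gamma-A2", "A", _variants(("DQ2.5-glia-g2", 1), ("DQ2.5-glia-g4c", 3)), scaffold=sc),
        SubgroupDef("gamma-BD1", "B", _variants(("DQ2.5-glia-g4a", 1), ("DQ2.5-glia-g4c", 4)), scaffold=sc),
        SubgroupDef("gamma-BD2", "D", _variants(("DQ2.5-glia-g4b", 1), ("DQ2.5-glia-g4c", 5)), scaffold=sc),
        SubgroupDef("gamma-BD3", "D", _variants(("DQ2.5-glia-g5", 1), ("DQ2.5-glia-g4c", 6)), scaffold=sc),
    )


def default_omega_subgroups() -> tuple[SubgroupDef, ...]:
    sc = _SCAFFOLDS["omega"]
    return (
        SubgroupDef("omega-A1", "A", _variants(("DQ2.5-glia-w1", 2)), scaffold=sc),
        SubgroupDef("omega-B1", "B", _variants(("DQ2.5-glia-w2", 1)), scaffold=sc),
        SubgroupDef("omega-D1", "D", _variants(("DQ2.5-glia-w1", 1), ("DQ2.5-glia-w2", 1)), scaffold=sc),
    )


def default_alpha_spec(
    n_copies_total: int = 100, pseudogene_fraction: float = 0.9, seed: int = 7
) -> FamilySpec:
    """Alpha family defaults: 60-150 copies (100 chosen), 90% pseudogenes."""
    return FamilySpec(
        family="alpha",
        n_copies_total=n_copies_total,
        pseudogene_fraction=pseudogene_fraction,
        subgroup_defs=default_alpha_subgroups(),
        seed=seed,
    )


def default_gamma_spec(
    n_copies_total: int = 40, pseudogene_fraction: float = 0.5, seed: int = 11
) -> FamilySpec:
    """Gamma family defaults: ~40 copies; pseudogene fraction is not
    published for gamma, 0.5 is an assumption (documented)."""
    return FamilySpec(
        family="gamma",
        n_copies_total=n_copies_total,
        pseudogene_fraction=pseudogene_fraction,
        subgroup_defs=default_gamma_subgroups(),
        seed=seed,
    )


def default_omega_spec(
    n_copies_total: int = 16, pseudogene_fraction: float = 0.5, seed: int = 13
) -> FamilySpec:
    return FamilySpec(
        family="omega",
        n_copies_total=n_copies_total,
        pseudogene_fraction=pseudogene_fraction,
        subgroup_defs=default_omega_subgroups(),
        seed=seed,
    )
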