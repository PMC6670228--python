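"""Annotation of gliadin coding sequences.

Gliadin genes are intronless, so a coding sequence translates directly in
frame 0 from the ATG. A large share of gene copies in the tandem arrays are
pseudogenes carrying an in-frame premature stop codon; these are still
epitope-bearing at the DNA level but produce no full-length protein.

Coordinate conventions (used package-wide): DNA intervals are 0-based
half-open; protein positions are 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from Bio.Seq import Seq

STOP = "*"
_DNA_ALPHABET = frozenset("ACGT")

#: celiac-disease epitope cores are 9-mers by registry convention
EPITOPE_LENGTH = 9

#: default signal peptide length in residues (gliadins carry a short
#: N-terminal secretion signal; the exact length varies by a residue or two)
DEFAULT_SIGNAL_PEPTIDE_LEN = 20


class AnnotationWarning(UserWarning):
    """Non-fatal irregularity met while annotating a sequence."""


def translate_cds(dna: str) -> str:
    """Translate an intronless coding sequence in frame 0.

    Uses the standard genetic code; internal and terminal stop codons are
    retained as ``*``. A trailing incomplete codon is ignored with a warning.

    Raises
    ------
    ValueError
        If the sequence is shorter than one codon or contains a non-ACGT
        character (the position of the first offender is reported).
    """
    if len(dna) < 3:
        raise ValueError(f"coding sequence shorter than one codon (len={len(dna)})")
    for pos, base in enumerate(dna):
        if base not in _DNA_ALPHABET:
            raise ValueError(f"non-ACGT character {base!r} at position {pos}")
    tail = len(dna) % 3
    if tail:
        warnings.warn(
            f"trailing incomplete codon of {tail} nt ignored", AnnotationWarning,
            stacklevel=2,
        )
        dna = dna[: len(dna) - tail]
    return str(Seq(dna).translate(table=1))


def call_pseudogene(protein: str) -> bool:
    """True iff the protein carries a premature (non-terminal) stop.

    A stop as the very last symbol is the normal terminator and does not
    make a pseudogene. Proteins with no stop at all are full-length reading
    frames (e.g. a fragment); a warning flags the missing terminator.
    """
    if not protein:
        raise ValueError("empty protein")
    if STOP not in protein:
        warnings.warn("no terminal stop in protein", AnnotationWarning, stacklevel=2)
        return False
    return STOP in protein[:-1]


@dataclass(frozen=True)
class CatalogueEntry:
    name: str
    peptide: str
    families: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.peptide) != EPITOPE_LENGTH:
            raise ValueError(
                f"epitope {self.name!r}: peptide must be a 9-mer, got "
                f"{len(self.peptide)}"
            )


@dataclass(frozen=True)
class EpitopeCatalogue:
    """Catalogue of canonical CD epitope cores (9-mer peptides).

    Peptides are stored in genomically encoded Q-form; tissue
    transglutaminase deamidation (Q->E) is handled at scan time via
    ``qe_equivalence``.
    """

    entries: tuple[CatalogueEntry, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("duplicate epitope names in catalogue")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def subset(self, family: str) -> "EpitopeCatalogue":
        return EpitopeCatalogue(
            tuple(e for e in self.entries if family in e.families)
        )

    @classmethod
    def from_tsv(cls, path) -> "EpitopeCatalogue":
        entries = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {c: i for i, c in enumerate(header)}
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                entries.append(
                    CatalogueEntry(
                        name=fields[idx["name"]],
                        peptide=fields[idx["peptide"]],
                        families=frozenset(fields[idx["families"]].split(",")),
                    )
                )
        return cls(tuple(entries))


def default_catalogue() -> EpitopeCatalogue:
    """Catalogue shipped with the package (editable data, not a constant)."""
    ref = resources.files("gliadkit.data").joinpath("epitopes.tsv")
    with resources.as_file(ref) as path:
        return EpitopeCatalogue.from_tsv(path)


@dataclass(frozen=True)
class EpitopeHit:
    gene_id: str
    epitope_name: str
    position: int  # 1-based position of the first residue in the protein


def scan_epitopes(
    protein: str,
    catalogue: EpitopeCatalogue,
    qe_equivalence: bool = False,
    gene_id: str = "",
) -> list[EpitopeHit]:
    """Locate every exact 9-mer epitope occurrence in a protein.

    Overlapping hits are reported. With ``qe_equivalence`` Q and E compare
    equal, so deamidated registry peptides match their genomic Q-form.
    Hits are sorted by position, then by catalogue order.
    """
    if len(catalogue) == 0:
        raise ValueError("empty epitope catalogue")

    def canon(s: str) -> str:
        return s.replace("E", "Q") if qe_equivalence else s

    target = canon(protein)
    hits: list[EpitopeHit] = []
    for order, entry in enumerate(catalogue):
        pep = canon(entry.peptide)
        start = target.find(pep)
        while start != -1:
            hits.append(EpitopeHit(gene_id, entry.name, start + 1))
            start = target.find(pep, start + 1)
    hits.sort(key=lambda h: (h.position, catalogue.names().index(h.epitope_name)))
    return hits


@dataclass(frozen=True)
class DomainSegment:
    name: str  # signal_peptide | upstream | repetitive | downstream
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive


@dataclass(frozen=True)
class DomainMap:
    gene_id: str
    segments: tuple[DomainSegment, ...]
    truncated: bool = False  # segmented only up to the first stop

    def region(self, name: str) -> DomainSegment | None:
        for seg in self.segments:
            if seg.name == name:
                return seg
        return None


def segment_domains(
    protein: str,
    hits: Sequence[EpitopeHit],
    signal_peptide_len: int = DEFAULT_SIGNAL_PEPTIDE_LEN,
    gene_id: str = "",
) -> DomainMap:
    """Partition a protein into signal peptide / repetitive epitope region /
    downstream domain.

    The repetitive region spans from the first to the last epitope hit
    (inclusive of the final hit's 9 residues). Pseudogene proteins are
    segmented up to the first stop only. Segments are contiguous and cover
    residues 1..first-stop; a gap between the signal peptide and the first
    hit is emitted as an ``upstream`` segment so coverage stays contiguous.
    """
    stop_at = protein.find(STOP)
    length = len(protein) if stop_at == -1 else stop_at
    truncated = 0 <= stop_at < len(protein) - 1
    if length == 0:
        raise ValueError("protein has no residues before the first stop")

    if length <= signal_peptide_len:
        warnings.warn(
            "protein shorter than the signal peptide length; single segment",
            AnnotationWarning,
            stacklevel=2,
        )
        return DomainMap(
            gene_id, (DomainSegment("signal_peptide", 1, length),), truncated
        )

    segs = [DomainSegment("signal_peptide", 1, signal_peptide_len)]
    usable = [h for h in hits if h.position + EPITOPE_LENGTH - 1 <= length]
    if not usable:
        segs.append(DomainSegment("downstream", signal_peptide_len + 1, length))
        return DomainMap(gene_id, tuple(segs), truncated)

    first = min(h.position for h in usable)
    last = max(h.position + EPITOPE_LENGTH - 1 for h in usable)
    first = max(first, signal_peptide_len + 1)
    if first > signal_peptide_len + 1:
        segs.append(DomainSegment("upstream", signal_peptide_len + 1, first - 1))
    segs.append(DomainSegment("repetitive", first, min(last, length)))
    if last < length:
        segs.append(DomainSegment("downstream", last + 1, length))
    return DomainMap(gene_id, tuple(segs), truncated)


@dataclass
class GliadinGene:
    """One intronless gliadin coding sequence with its derived annotation."""

    id: str
    family: str  # alpha | gamma | omega | unknown
    dna: str
    species: str = "synthetic"
    genome_label: str = "unknown"  # A | B | D | unknown
    locus: str | None = None
    subgroup: str | None = None  # generator ground truth when available
    protein: str = field(default="", repr=False)
    is_pseudogene: bool = False

    def __post_init__(self) -> None:
        if not self.dna:
            raise ValueError(f"gene {self.id}: empty coding sequence")
        if not self.protein:
            self.refresh()

    def refresh(self) -> None:
        """(Re)derive protein and pseudogene status from the DNA."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", AnnotationWarning)
            self.protein = translate_cds(self.dna)
            self.is_pseudogene = call_pseudogene(self.protein)

    @property
    def mature_protein(self) -> str:
        """Residues up to (excluding) the first stop."""
        stop = self.protein.find(STOP)
        return self.protein if stop == -1 else self.protein[:stop]


def annotate_genes(
    genes: Iterable[GliadinGene],
    catalogue: EpitopeCatalogue,
    qe_equivalence: bool = False,
    signal_peptide_len: int = DEFAULT_SIGNAL_PEPTIDE_LEN,
) -> tuple[dict[str, list[EpitopeHit]], dict[str, DomainMap]]:
    """Scan epitopes and segment domains for a set of genes.

    Returns (hits per gene id, domain map per gene id). Pseudogenes are
    scanned over their pre-stop residues only, matching how the protein
    would present.
    """
    hits_by_gene: dict[str, list[EpitopeHit]] = {}
    domains_by_gene: dict[str, DomainMap] = {}
    for gene in genes:
        hits = scan_epitopes(
            gene.mature_protein, catalogue, qe_equivalence, gene_id=gene.id
        )
        hits_by_gene[gene.id] = hits
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", AnnotationWarning)
            domains_by_gene[gene.id] = segment_domains(
                gene.protein, hits, signal_peptide_len, gene_id=gene.id
            )
    return hits_by_gene, domains_by_gene
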