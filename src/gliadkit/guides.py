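"""sgRNA protospacer discovery and evaluation against gliadin gene sets.

A guide targets any site where its protospacer matches the DNA (on either
strand) immediately 5' of an SpCas9 NGG PAM; the blunt cut falls 3 bp 5' of
the PAM. Family-wide coverage is evaluated at 100% protospacer identity.
IUPAC degenerate codes in the query are honoured, which also covers the
degenerate cloning primers used to pull gliadin genes out of genomic DNA.

Secondary-structure (hairpin) and cross-dimer screens are exact-complement
run heuristics standing in for thermodynamic folding tools; their
thresholds are configuration, not science.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .annotation import DomainMap, GliadinGene

IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "R": frozenset("AG"), "Y": frozenset("CT"),
    "M": frozenset("AC"), "K": frozenset("GT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C", "R": "Y", "Y": "R", "M": "K",
    "K": "M", "S": "S", "W": "W", "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}

#: PAM-proximal protospacer positions that dominate Cas9 specificity
SEED_LENGTH = 12


def revcomp(seq: str) -> str:
    """Reverse complement honouring IUPAC degenerate codes."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class GuideCandidate:
    name: str
    protospacer: str
    targets_antisense: bool = True
    region_class: str = "epitope_upstream"
    anchor_column: int = 0

    def __post_init__(self) -> None:
        if not 17 <= len(self.protospacer) <= 23:
            raise ValueError(
                f"guide {self.name}: protospacer length {len(self.protospacer)} "
                "outside 17-23"
            )
        bad = set(self.protospacer) - set(IUPAC)
        if bad:
            raise ValueError(f"guide {self.name}: invalid characters {bad}")


@dataclass(frozen=True)
class GuideMatch:
    guide_name: str
    gene_id: str
    start: int  # 0-based half-open protospacer interval on the coding strand
    end: int
    strand: str  # '+' or '-'
    mismatches: int
    pam: str  # 3-mer on the matched strand
    cut_index: int  # between-base index on the coding strand
    seed_clean: bool = True  # PAM-proximal 12 nt mismatch-free

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _mismatch_positions(pattern: str, window: str) -> list[int] | None:
    """Positions (pattern coords) where window violates the IUPAC pattern."""
    out = []
    for j, (p, w) in enumerate(zip(pattern, window)):
        if w not in IUPAC[p]:
            if w not in "ACGT":
                return None  # ambiguous target base never matches
            out.append(j)
    return out


def match_guide(
    guide: GuideCandidate | str,
    gene: GliadinGene | str,
    max_mismatch: int = 0,
    require_pam: bool = True,
) -> list[GuideMatch]:
    """All placements of a protospacer on both strands of a coding sequence.

    Mismatches are counted over the protospacer only (never the PAM) against
    the query's IUPAC sets. A '+' match needs NGG immediately 3' on the
    coding strand; a '-' match is an occurrence of the reverse-complemented
    query with the PAM on the antisense strand (CCN immediately 5' on the
    coding strand). The blunt cut index lies 3 bp 5' of the PAM on the
    matched strand, reported in coding-strand coordinates.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    query = guide.protospacer if isinstance(guide, GuideCandidate) else guide
    name = guide.name if isinstance(guide, GuideCandidate) else "query"
    seq = gene.dna if isinstance(gene, GliadinGene) else gene
    gene_id = gene.id if isinstance(gene, GliadinGene) else ""
    L = len(query)
    rc_query = revcomp(query)
    matches: list[GuideMatch] = []
    for i in range(len(seq) - L + 1):
        window = seq[i : i + L]
        # sense placement
        mm = _mismatch_positions(query, window)
        if mm is not None and len(mm) <= max_mismatch:
            pam = seq[i + L : i + L + 3]
            if not require_pam or (len(pam) == 3 and pam[1:] == "GG"):
                matches.append(GuideMatch(
                    name, gene_id, i, i + L, "+", len(mm), pam, i + L - 3,
                    seed_clean=all(j < L - SEED_LENGTH for j in mm),
                ))
        # antisense placement: coding strand carries revcomp(query)
        mm = _mismatch_positions(rc_query, window)
        if mm is not None and len(mm) <= max_mismatch:
            pam_coding = seq[max(i - 3, 0) : i]
            pam = revcomp(pam_coding)
            if not require_pam or (len(pam) == 3 and pam[1:] == "GG"):
                # pattern position j is protospacer position L-1-j
                guide_pos = [L - 1 - j for j in mm]
                matches.append(GuideMatch(
                    name, gene_id, i, i + L, "-", len(mm), pam, i + 3,
                    seed_clean=all(p < L - SEED_LENGTH for p in guide_pos),
                ))
    matches.sort(key=lambda m: (m.start, m.strand))
    return matches


def predict_cut_sites(
    guide: GuideCandidate | str, gene: GliadinGene | str
) -> list[int]:
    """Cut indices from perfect, PAM-adjacent placements (one per match)."""
    return [m.cut_index for m in match_guide(guide, gene, 0, True)]


@dataclass
class CoverageMatrix:
    """Perfect-match gene coverage of guides across subgroups."""

    table: pd.DataFrame  # rows: guides, cols: subgroup labels, int cells
    subgroup_sizes: dict[str, int]
    per_guide_totals: dict[str, int] = field(default_factory=dict)
    covers_all: dict[str, bool] = field(default_factory=dict)


def coverage_matrix(
    guides: Sequence[GuideCandidate],
    subgroups,  # Sequence[classification.Subgroup]
    genes_by_id: dict[str, GliadinGene],
) -> CoverageMatrix:
    """Count, per guide and subgroup, member genes with >= 1 perfect match."""
    labels = [sg.label for sg in subgroups]
    data = {}
    totals = {}
    covers = {}
    for g in guides:
        row = []
        total = 0
        for sg in subgroups:
            hit = 0
            for gid in sg.member_ids:
                if match_guide(g, genes_by_id[gid], 0, True):
                    hit += 1
            row.append(hit)
            total += hit
        data[g.name] = row
        totals[g.name] = total
        covers[g.name] = all(c > 0 for c in row)
    table = pd.DataFrame.from_dict(data, orient="index", columns=labels)
    sizes = {sg.label: len(sg.member_ids) for sg in subgroups}
    return CoverageMatrix(table, sizes, totals, covers)


def off_target_scan(
    guide: GuideCandidate | str,
    background: Iterable[GliadinGene],
    max_mismatch: int = 3,
) -> list[GuideMatch]:
    """PAM-required matches with <= max_mismatch substitutions over a
    background set; ``seed_clean`` flags hits whose PAM-proximal 12 nt are
    mismatch-free (the dangerous kind)."""
    background = list(background)
    if not background:
        raise ValueError("off_target_scan: empty background")
    hits: list[GuideMatch] = []
    for gene in background:
        hits.extend(match_guide(guide, gene, max_mismatch, True))
    return hits


def hairpin_flag(
    protospacer: str, min_stem: int = 8, min_loop: int = 3
) -> tuple[int, bool]:
    """Longest self-complementary stem with a >= min_loop separation.

    Returns (max stem length, flagged). A stem is an exact reverse-
    complement pairing between two non-overlapping substrings of the
    protospacer separated by at least ``min_loop`` bases.
    """
    if min_loop < 3:
        raise ValueError("min_loop must be >= 3")
    s = protospacer
    n = len(s)
    best = 0
    for length in range(n // 2, 0, -1):
        if length <= best:
            break
        for i in range(n - length + 1):
            stem = s[i : i + length]
            target = revcomp(stem)
            j = s.find(target, i + length + min_loop)
            if j != -1:
                best = length
                break
    return best, best >= min_stem


def cross_dimer_flag(
    a: str, b: str, min_run: int = 10
) -> tuple[int, bool]:
    """Longest contiguous antiparallel Watson-Crick run between two oligos.

    Equivalent to the longest common substring of ``a`` and revcomp(``b``);
    symmetric in its arguments.
    """
    rb = revcomp(b)
    best = 0
    prev = [0] * (len(rb) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(rb) + 1)
        for j in range(1, len(rb) + 1):
            if a[i - 1] == rb[j - 1]:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best, best >= min_run


def find_conserved_windows(
    genes: Sequence[GliadinGene],
    k: int = 23,
    min_fraction: float = 0.5,
    region: str | None = None,
    domains: dict[str, DomainMap] | None = None,
) -> list[tuple[str, float, str]]:
    """k-mers shared by at least ``min_fraction`` of the genes.

    Scans both strands; the fraction is over distinct genes containing the
    window. With ``region`` (a DomainMap segment name) and ``domains``,
    scanning is restricted to the DNA encoding that protein segment.
    Returns (window, fraction, region label) sorted by fraction descending.
    """
    if k < 20:
        raise ValueError("k must be >= 20 (protospacer + PAM)")
    if not genes:
        return []
    shortest = min(len(g.dna) for g in genes)
    if k > shortest:
        raise ValueError(f"k={k} exceeds shortest gene length {shortest}")
    counts: dict[str, int] = {}
    for gene in genes:
        seq = gene.dna
        if region and domains:
            seg = domains[gene.id].region(region)
            if seg is None:
                continue
            seq = seq[3 * (seg.start - 1) : 3 * seg.end]
        seen = set()
        for strand_seq in (seq, revcomp(seq)):
            for i in range(len(strand_seq) - k + 1):
                seen.add(strand_seq[i : i + k])
        for w in seen:
            counts[w] = counts.get(w, 0) + 1
    n = len(genes)
    label = region or "any"
    out = [
        (w, c / n, label) for w, c in counts.items() if c / n >= min_fraction
    ]
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def load_guides() -> list[GuideCandidate]:
    """The six published protospacers shipped with the package."""
    ref = resources.files("gliadkit.data").joinpath("guides.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return [
        GuideCandidate(
            name=r["name"],
            protospacer=r["protospacer"],
            targets_antisense=bool(r["targets_antisense"]),
            region_class=r["region_class"],
            anchor_column=int(r["anchor_column"]),
        )
        for r in df.to_dict("records")
    ]


def guides_for_family(family: str) -> list[GuideCandidate]:
    prefix = {"alpha": "sgRNA_alpha", "gamma": "sgRNA_gamma"}[family]
    return [g for g in load_guides() if g.name.startswith(prefix)]


def load_primers() -> dict[str, str]:
    """Degenerate cloning primers shipped with the package."""
    ref = resources.files("gliadkit.data").joinpath("primers.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return {r["name"]: r["sequence"] for r in df.to_dict("records")}
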