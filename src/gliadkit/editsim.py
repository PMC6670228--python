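"""Simulation of multiplexed Cas9 editing on tandem gliadin loci.

Cuts predicted from guide/PAM matches are resolved left-to-right: an
adjacent pair of co-occurring cuts may excise the intervening segment
(deleting fully contained genes and fusing the two flanking cut genes),
and remaining cuts re-ligate perfectly or acquire a small indel. Per-gene
consequences follow reading-frame logic: a net length change not divisible
by 3 is a frameshift knockout; an in-frame change introducing a stop is a
nonsense knockout; otherwise an in-frame edit.

The phenotypic readout emulates a one-dimensional gel: intact proteins are
binned by approximate mass (110 Da per residue); a bin gained or lost is a
"clear" profile change, bin-count-only differences are "potential" changes.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation import (
    AnnotationWarning,
    EpitopeCatalogue,
    GliadinGene,
    call_pseudogene,
    default_catalogue,
    scan_epitopes,
    translate_cds,
)
from .guides import GuideCandidate, match_guide
from .stats import ScreeningCounts

RESIDUE_MASS_DA = 110.0
DEFAULT_BIN_WIDTH_DA = 500.0


@dataclass(frozen=True)
class LocusModel:
    """A tandem array of genes on one strand of one subgenome."""

    locus_id: str
    genome: str
    sequence: str
    gene_intervals: tuple[tuple[str, int, int], ...]  # (gene_id, start, end)
    family: str = "unknown"
    allele_count: int = 2

    def __post_init__(self) -> None:
        prev_end = 0
        for gid, start, end in self.gene_intervals:
            if not 0 <= start < end <= len(self.sequence):
                raise ValueError(f"locus {self.locus_id}: interval of {gid} out of bounds")
            if start < prev_end:
                raise ValueError(f"locus {self.locus_id}: intervals overlap at {gid}")
            prev_end = end

    def gene_dna(self, gene_id: str) -> str:
        for gid, start, end in self.gene_intervals:
            if gid == gene_id:
                return self.sequence[start:end]
        raise KeyError(gene_id)


@dataclass
class RepairPolicy:
    """NHEJ-style repair model for resolved double-strand breaks.

    All defaults are conventional modelling choices, exposed as
    configuration: cut pairs excise their segment with
    ``p_segment_deletion``; single cuts re-ligate perfectly with
    ``p_perfect_repair`` or acquire an indel (deletion of 1-10 nt with
    probability ``p_deletion``, else insertion of 1-3 random nt).
    """

    p_segment_deletion: float = 0.1
    p_perfect_repair: float = 0.2
    p_deletion: float = 0.7
    deletion_sizes: tuple[int, ...] = tuple(range(1, 11))
    insertion_sizes: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self) -> None:
        for name in ("p_segment_deletion", "p_perfect_repair", "p_deletion"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"RepairPolicy.{name}: must be in [0, 1]")
        if not self.deletion_sizes or not self.insertion_sizes:
            raise ValueError("RepairPolicy: empty indel size distribution")


@dataclass
class EditOutcome:
    """Result of resolving one allele's cuts."""

    allele_id: str
    edited_sequence: str
    consequences: dict[str, str]  # gene_id -> consequence enum
    edited_gene_dna: dict[str, str | None]  # None for deleted genes
    epitope_delta: dict[str, int] = field(default_factory=dict)
    events: list[tuple] = field(default_factory=list)


CONSEQUENCES = (
    "unchanged", "inframe_edit", "frameshift_ko", "nonsense_ko", "deleted",
    "fusion",
)


def classify_consequence(before_dna: str, after_dna: str) -> str:
    """Frame-logic consequence of editing one coding sequence."""
    if before_dna == after_dna:
        return "unchanged"
    if (len(after_dna) - len(before_dna)) % 3 != 0:
        return "frameshift_ko"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", AnnotationWarning)
        before_pseudo = call_pseudogene(translate_cds(before_dna))
        after_pseudo = (
            call_pseudogene(translate_cds(after_dna)) if len(after_dna) >= 3 else True
        )
    if after_pseudo and not before_pseudo:
        return "nonsense_ko"
    return "inframe_edit"


def _draw_single_repair(cut: int, policy: RepairPolicy, rng: np.random.Generator):
    """None (perfect religation) or a ('del'|'ins', ...) event at the cut."""
    if rng.random() < policy.p_perfect_repair:
        return None
    if rng.random() < policy.p_deletion:
        size = int(policy.deletion_sizes[rng.integers(len(policy.deletion_sizes))])
        return ("del", cut, cut + size)
    size = int(policy.insertion_sizes[rng.integers(len(policy.insertion_sizes))])
    ins = "".join("ACGT"[b] for b in rng.integers(0, 4, size=size))
    return ("ins", cut, ins)


def apply_cuts(
    locus: LocusModel,
    cuts: Sequence[int],
    policy: RepairPolicy,
    rng: np.random.Generator,
    allele_id: str = "allele",
    annotate: bool = True,
    catalogue: EpitopeCatalogue | None = None,
) -> EditOutcome:
    """Resolve a set of simultaneous cuts on one allele of a locus.

    Cuts are processed left-to-right: each adjacent pair excises the
    intervening segment with ``policy.p_segment_deletion`` (consuming both
    cuts); unconsumed cuts re-ligate perfectly or acquire an indel.
    Intergenic cuts are legal. With ``annotate`` the change in epitope count
    per gene is computed by re-scanning the edited translation.
    """
    n = len(locus.sequence)
    cuts = sorted(set(int(c) for c in cuts))
    if cuts and not (0 <= cuts[0] and cuts[-1] <= n):
        raise ValueError("cut index out of bounds")

    events: list[tuple] = []
    i = 0
    while i < len(cuts):
        if i + 1 < len(cuts) and rng.random() < policy.p_segment_deletion:
            events.append(("segdel", cuts[i], cuts[i + 1]))
            i += 2
            continue
        ev = _draw_single_repair(cuts[i], policy, rng)
        if ev is not None:
            events.append(ev)
        i += 1

    # clip deletions and normalise event bounds
    dels = []
    inss = []
    for ev in events:
        if ev[0] in ("del", "segdel"):
            dels.append((ev[0], ev[1], min(ev[2], n)))
        else:
            inss.append(ev)

    # build the edited sequence (apply right-to-left)
    seq = locus.sequence
    ordered = sorted(dels + inss, key=lambda e: e[1], reverse=True)
    for ev in ordered:
        if ev[0] in ("del", "segdel"):
            seq = seq[: ev[1]] + seq[ev[2] :]
        else:
            seq = seq[: ev[1]] + ev[2] + seq[ev[1] :]

    consequences: dict[str, str] = {}
    edited_dna: dict[str, str | None] = {}
    intervals = locus.gene_intervals

    def containing_gene(pos: int) -> str | None:
        for gid, gs, ge in intervals:
            if gs <= pos < ge:
                return gid
        return None

    fused: set[str] = set()
    deleted: set[str] = set()
    for ev in dels:
        if ev[0] != "segdel":
            continue
        a, b = ev[1], ev[2]
        for gid, gs, ge in intervals:
            if a <= gs and ge <= b:
                deleted.add(gid)
        ga, gb = containing_gene(a), containing_gene(b)
        if ga is not None and gb is not None and ga != gb:
            fused.update((ga, gb))

    for gid, gs, ge in intervals:
        if gid in deleted:
            consequences[gid] = "deleted"
            edited_dna[gid] = None
            continue
        if gid in fused:
            consequences[gid] = "fusion"
            edited_dna[gid] = None
            continue
        # reconstruct this gene's local edited sequence
        local = locus.sequence[gs:ge]
        touched = False
        local_events = []
        for ev in dels:
            o_start, o_end = max(ev[1], gs), min(ev[2], ge)
            if o_start < o_end:
                local_events.append(("del", o_start - gs, o_end - gs))
                touched = True
        for ev in inss:
            if gs < ev[1] < ge:
                local_events.append(("ins", ev[1] - gs, ev[2]))
                touched = True
        if not touched:
            consequences[gid] = "unchanged"
            edited_dna[gid] = local
            continue
        for ev in sorted(local_events, key=lambda e: e[1], reverse=True):
            if ev[0] == "del":
                local = local[: ev[1]] + local[ev[2] :]
            else:
                local = local[: ev[1]] + ev[2] + local[ev[1] :]
        edited_dna[gid] = local
        consequences[gid] = (
            classify_consequence(locus.sequence[gs:ge], local)
            if local
            else "deleted"
        )

    outcome = EditOutcome(
        allele_id=allele_id,
        edited_sequence=seq,
        consequences=consequences,
        edited_gene_dna=edited_dna,
        events=events,
    )

    if annotate:
        catalogue = catalogue or default_catalogue()
        for gid, gs, ge in intervals:
            before = _epitope_count(locus.sequence[gs:ge], catalogue)
            after_dna = edited_dna[gid]
            after = (
                _epitope_count(after_dna, catalogue)
                if after_dna and len(after_dna) >= 3
                else 0
            )
            outcome.epitope_delta[gid] = after - before
    return outcome


def _epitope_count(dna: str, catalogue: EpitopeCatalogue) -> int:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", AnnotationWarning)
        protein = translate_cds(dna)
    stop = protein.find("*")
    mature = protein if stop == -1 else protein[:stop]
    return len(scan_epitopes(mature, catalogue))


# ---------------------------------------------------------------------------
# Protein profile (gel readout proxy)
# ---------------------------------------------------------------------------

def mass_bin(residues: int, bin_width: float = DEFAULT_BIN_WIDTH_DA) -> int:
    return round(RESIDUE_MASS_DA * residues / bin_width)


def predict_profile(
    genes: Iterable[GliadinGene], bin_width: float = DEFAULT_BIN_WIDTH_DA
) -> Counter:
    """Multiset of (family, mass bin) over intact (non-pseudogene) proteins."""
    profile: Counter = Counter()
    for gene in genes:
        if gene.is_pseudogene:
            continue
        profile[(gene.family, mass_bin(len(gene.mature_protein), bin_width))] += 1
    return profile


def profile_diff(wild_type: Mapping, edited: Mapping) -> str:
    """'none' | 'potential_change' (bin counts only) | 'clear_change' (bin
    gained or lost)."""
    wt = {k: v for k, v in wild_type.items() if v}
    ed = {k: v for k, v in edited.items() if v}
    if wt == ed:
        return "none"
    if set(wt) != set(ed):
        return "clear_change"
    return "potential_change"


# ---------------------------------------------------------------------------
# Monte-Carlo screen
# ---------------------------------------------------------------------------

def _locus_wt_entries(locus: LocusModel) -> dict[str, tuple | None]:
    """gene_id -> (family, bin) for intact genes, None for pseudogenes."""
    entries: dict[str, tuple | None] = {}
    for gid, gs, ge in locus.gene_intervals:
        dna = locus.sequence[gs:ge]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", AnnotationWarning)
            protein = translate_cds(dna)
            pseudo = call_pseudogene(protein)
        if pseudo:
            entries[gid] = None
        else:
            stop = protein.find("*")
            mature = protein if stop == -1 else protein[:stop]
            entries[gid] = (locus.family, mass_bin(len(mature)))
    return entries


def _edited_entry(locus: LocusModel, consequence: str, dna: str | None) -> tuple | None:
    if consequence in ("deleted", "fusion", "frameshift_ko", "nonsense_ko"):
        return None
    if dna is None or len(dna) < 3:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", AnnotationWarning)
        protein = translate_cds(dna)
        if call_pseudogene(protein):
            return None
    stop = protein.find("*")
    mature = protein if stop == -1 else protein[:stop]
    return (locus.family, mass_bin(len(mature)))


def locus_cut_sites(locus: LocusModel, guides: Sequence[GuideCandidate]) -> list[int]:
    """All perfect PAM-adjacent cut indices of a guide set on a locus."""
    sites: set[int] = set()
    for g in guides:
        for m in match_guide(g, locus.sequence, 0, True):
            sites.add(m.cut_index)
    return sorted(sites)


def simulate_screen(
    constructs: Mapping[str, Sequence[GuideCandidate]],
    loci: Sequence[LocusModel],
    efficiency: float,
    n_plants: Mapping[str, int] | int,
    grains_per_plant: int = 8,
    policy: RepairPolicy | None = None,
    seed: int = 0,
) -> list[ScreeningCounts]:
    """Monte-Carlo screen over constructs, plants and grains.

    Each grain carries ``allele_count`` independent alleles of every locus;
    every predicted cut site fires independently with ``efficiency`` and the
    fired cuts resolve under ``policy``. A grain counts as changed when its
    binned protein profile differs from wild type; a plant counts when any
    of its grains does. One genotype per grain (no chimerism).
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must be in [0, 1]")
    policy = policy or RepairPolicy()
    rng = np.random.default_rng(seed)

    wt_entries = {locus.locus_id: _locus_wt_entries(locus) for locus in loci}
    wt_profile: Counter = Counter()
    for locus in loci:
        for entry in wt_entries[locus.locus_id].values():
            if entry is not None:
                wt_profile[entry] += locus.allele_count

    sites_by_construct = {
        name: [(locus, locus_cut_sites(locus, guides)) for locus in loci]
        for name, guides in constructs.items()
    }

    results: list[ScreeningCounts] = []
    for name in constructs:
        plants = n_plants[name] if isinstance(n_plants, Mapping) else int(n_plants)
        plant_clear = plant_any = grain_clear = grain_any = 0
        locus_sites = sites_by_construct[name]
        for _ in range(plants):
            saw_clear = saw_any = False
            for _ in range(grains_per_plant):
                profile = wt_profile.copy()
                touched = False
                for locus, sites in locus_sites:
                    if not sites:
                        continue
                    site_arr = np.asarray(sites)
                    for _allele in range(locus.allele_count):
                        fired = site_arr[rng.random(len(site_arr)) < efficiency]
                        if fired.size == 0:
                            continue
                        outcome = apply_cuts(
                            locus, fired.tolist(), policy, rng, annotate=False
                        )
                        entries = wt_entries[locus.locus_id]
                        for gid, cons in outcome.consequences.items():
                            if cons == "unchanged":
                                continue
                            touched = True
                            before = entries[gid]
                            after = _edited_entry(
                                locus, cons, outcome.edited_gene_dna[gid]
                            )
                            if before is not None:
                                profile[before] -= 1
                            if after is not None:
                                profile[after] += 1
                diff = profile_diff(wt_profile, profile) if touched else "none"
                if diff == "clear_change":
                    grain_clear += 1
                    grain_any += 1
                    saw_clear = saw_any = True
                elif diff == "potential_change":
                    grain_any += 1
                    saw_any = True
            plant_clear += saw_clear
            plant_any += saw_any
        results.append(
            ScreeningCounts(
                construct=name,
                regenerated=plants,
                expressing=plants,
                low_copy=0,
                plants_tested=plants,
                grains_tested=plants * grains_per_plant,
                plants_clear=plant_clear,
                grains_clear=grain_clear,
                plants_any=plant_any,
                grains_any=grain_any,
            )
        )
    return results


def efficiency_from_change_fraction(
    changed_fraction: float, n_sites: int, p_perfect_repair: float
) -> float:
    """Method-of-moments inversion of the per-grain change probability.

    Valid for the analytic policy (no segment deletions, every indel a
    frameshift): P(grain changed) = 1 - (1 - e*(1-p_perfect))^S for S
    independent target sites per grain, hence
    e = (1 - (1-f)^(1/S)) / (1 - p_perfect).
    """
    if not 0.0 <= changed_fraction < 1.0:
        raise ValueError("changed_fraction must be in [0, 1)")
    if p_perfect_repair >= 1.0:
        raise ValueError("p_perfect_repair must be < 1")
    return (1.0 - (1.0 - changed_fraction) ** (1.0 / n_sites)) / (
        1.0 - p_perfect_repair
    )
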