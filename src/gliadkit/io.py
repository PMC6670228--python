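"""Standard-format input/output: FASTA gene sets, locus manifests, reports.

FASTA headers are pipe-delimited: ``id|family|genome|subgroup|pseudogene``
(``pseudo``/``intact``); the locus manifest is a TSV with 0-based half-open
coordinates.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import GliadinGene
from .editsim import LocusModel


def write_fasta(genes: Iterable[GliadinGene], path: str | Path) -> None:
    records = []
    for g in genes:
        header = "|".join([
            g.id,
            g.family,
            g.genome_label,
            g.subgroup or "NA",
            "pseudo" if g.is_pseudogene else "intact",
        ])
        records.append(SeqRecord(Seq(g.dna), id=header, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[GliadinGene]:
    genes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.id.split("|")
        gene_id = fields[0]
        family = fields[1] if len(fields) > 1 else "unknown"
        genome = fields[2] if len(fields) > 2 else "unknown"
        subgroup = fields[3] if len(fields) > 3 and fields[3] != "NA" else None
        genes.append(
            GliadinGene(
                id=gene_id,
                family=family,
                dna=str(rec.seq).upper(),
                genome_label=genome,
                subgroup=subgroup,
            )
        )
    return genes


def write_locus_manifest(loci: Sequence[LocusModel], path: str | Path) -> None:
    rows = [
        {
            "locus": locus.locus_id,
            "gene_id": gid,
            "start": start,
            "end": end,
            "strand": "+",
        }
        for locus in loci
        for gid, start, end in locus.gene_intervals
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_locus_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_hits_tsv(hits_by_gene: dict, path: str | Path) -> None:
    rows = [
        {"gene_id": h.gene_id, "epitope_name": h.epitope_name, "position": h.position}
        for hits in hits_by_gene.values()
        for h in hits
    ]
    pd.DataFrame(rows, columns=["gene_id", "epitope_name", "position"]).to_csv(
        path, sep="\t", index=False
    )


def write_domains_tsv(domains_by_gene: dict, path: str | Path) -> None:
    rows = [
        {"gene_id": dm.gene_id, "domain": seg.name, "start": seg.start, "end": seg.end}
        for dm in domains_by_gene.values()
        for seg in dm.segments
    ]
    pd.DataFrame(rows, columns=["gene_id", "domain", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


def write_subgroups_tsv(subgroups, path: str | Path) -> None:
    rows = [
        {
            "label": sg.label,
            "signature": ";".join(f"{n}x{c}" for n, c in sg.signature) or ".",
            "n_members": len(sg.member_ids),
            "genome": sg.genome_assignment,
            "support": sg.support,
        }
        for sg in subgroups
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_membership_tsv(subgroups, path: str | Path) -> None:
    rows = [
        {"gene_id": gid, "subgroup": sg.label}
        for sg in subgroups
        for gid in sg.member_ids
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_matches_tsv(matches, path: str | Path) -> None:
    rows = [
        {
            "guide": m.guide_name,
            "gene_id": m.gene_id,
            "start": m.start,
            "end": m.end,
            "strand": m.strand,
            "mismatches": m.mismatches,
            "pam": m.pam,
            "cut_index": m.cut_index,
            "seed_clean": m.seed_clean,
        }
        for m in matches
    ]
    pd.DataFrame(
        rows,
        columns=[
            "guide", "gene_id", "start", "end", "strand", "mismatches", "pam",
            "cut_index", "seed_clean",
        ],
    ).to_csv(path, sep="\t", index=False)
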