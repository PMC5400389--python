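"""Reading and writing the package's plain-text formats.

FASTA goes through Biopython; tables are pandas TSV.  Aligned ortholog
pairs live in paired FASTA files carrying two records per gene, focal
sequence first (record ids ``<gene>|focal`` and ``<gene>|ortholog``, or
simply consecutive records).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .divergence import CodonAlignmentPair
from .scan import SequenceRecord


def read_fasta(
    path: str | Path,
    families: Mapping[str, str] | None = None,
    region_label: str = "cds_intron_containing",
) -> list[SequenceRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fam = families.get(rec.id, "") if families else ""
        out.append(
            SequenceRecord(
                gene_id=rec.id,
                seq=str(rec.seq).upper(),
                family_id=fam,
                region_label=region_label,
            )
        )
    return out


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.seq), id=r.gene_id, description="") for r in records),
        str(path),
        "fasta",
    )


def read_pairs_fasta(path: str | Path) -> list[CodonAlignmentPair]:
    """Aligned FASTA with two records per gene, focal first."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2:
        raise ValueError(f"{path}: odd number of records in paired FASTA")
    pairs = []
    for i in range(0, len(records), 2):
        focal, orth = records[i], records[i + 1]
        gene = focal.id.split("|")[0]
        pairs.append(
            CodonAlignmentPair(
                gene_id=gene,
                focal=str(focal.seq).upper(),
                ortholog=str(orth.seq).upper(),
            )
        )
    return pairs


def write_pairs_fasta(pairs: Sequence[CodonAlignmentPair], path: str | Path) -> None:
    recs = []
    for p in pairs:
        recs.append(SeqRecord(Seq(p.focal), id=f"{p.gene_id}|focal", description=""))
        recs.append(SeqRecord(Seq(p.ortholog), id=f"{p.gene_id}|ortholog", description=""))
    SeqIO.write(recs, str(path), "fasta")


def read_families_tsv(path: str | Path) -> dict[str, str]:
    """``gene_id<TAB>family_id`` mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "family_id"], comment="#")
    return dict(zip(df.gene_id.astype(str), df.family_id.astype(str)))


def write_families_tsv(families: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(families):
            fh.write(f"{g}\t{families[g]}\n")


def write_bed(
    occurrences: Iterable[tuple[str, int, int, str]], path: str | Path
) -> None:
    """BED of motif occurrences: chrom=gene_id, 0-based half-open."""
    with open(path, "w") as fh:
        for gene, start, end, name in occurrences:
            fh.write(f"{gene}\t{start}\t{end}\t{name}\n")


def write_stats_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
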