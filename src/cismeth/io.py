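"""Readers and writers for the package's on-disk formats.

Gene models travel as GTF (1-based inclusive on disk, converted to 0-based
half-open on read, via gffutils), CpG islands as 3-column BED, the probe
manifest / matrices / clinical table as tab-separated text.
"""

from __future__ import annotations

import os
from typing import Sequence

import gffutils
import pandas as pd

from .annotation import GeneModel, Transcript


def write_gtf(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            span_start = min(t.span[0] for t in gene.transcripts)
            span_end = max(t.span[1] for t in gene.transcripts)
            attrs = f'gene_id "{gene.gene_id}"; gene_type "{gene.gene_type}";'
            fh.write(
                f"{gene.chrom}\tcismeth\tgene\t{span_start + 1}\t{span_end}\t.\t"
                f"{gene.strand}\t.\t{attrs}\n"
            )
            for t in gene.transcripts:
                tattrs = attrs + f' transcript_id "{t.transcript_id}";'
                s, e = t.span
                fh.write(
                    f"{gene.chrom}\tcismeth\ttranscript\t{s + 1}\t{e}\t.\t"
                    f"{gene.strand}\t.\t{tattrs}\n"
                )
                for es, ee in t.exons:
                    fh.write(
                        f"{gene.chrom}\tcismeth\texon\t{es + 1}\t{ee}\t.\t"
                        f"{gene.strand}\t.\t{tattrs}\n"
                    )


def read_gtf(path) -> list[GeneModel]:
    """Load gene models from a GTF with gene/transcript/exon features."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        transcripts = []
        for t in db.children(g, featuretype="transcript"):
            exons = tuple(
                sorted(
                    (e.start - 1, e.end)
                    for e in db.children(t, featuretype="exon")
                )
            )
            transcripts.append(Transcript(t.attributes["transcript_id"][0], exons))
        gene_type = g.attributes.get("gene_type", ["protein_coding"])[0]
        genes.append(
            GeneModel(
                gene_id=g.attributes["gene_id"][0],
                chrom=g.seqid,
                strand=g.strand,
                transcripts=tuple(sorted(transcripts, key=lambda t: t.transcript_id)),
                gene_type=gene_type,
            )
        )
    return sorted(genes, key=lambda g: g.gene_id)


def write_bed(intervals: pd.DataFrame, path) -> None:
    intervals[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end"], usecols=[0, 1, 2]
    )


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_matrix(df: pd.DataFrame, path) -> None:
    """Matrix with an index column (probe/gene ids) and sample-id header."""
    df.to_csv(path, sep="\t", index=True)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return str(path)
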