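"""Gene-model handling and per-probe genomic annotation.

Coordinates are 0-based half-open everywhere inside the package; GTF input is
converted on read (see :mod:`cismeth.io`). Each gene's transcription start
site (TSS) is the strand-aware 5' end of the transcript with the largest
summed exon length. Probes are annotated relative to a target gene with

* a signed distance to the TSS (negative = upstream, strand-aware),
* a CpG-island relation (island / shore 0-2 kb / shelf 2-4 kb / open sea),
* a gene-body component of the TSS-selected transcript (first exon,
  first intron, other exon, other intron, intergenic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CGI_CATEGORIES = ("island", "shore", "shelf", "open_sea")
COMPONENT_CATEGORIES = (
    "first_exon",
    "first_intron",
    "other_exon",
    "other_intron",
    "intergenic",
)

SHORE_BP = 2000
SHELF_BP = 4000


@dataclass(frozen=True)
class Transcript:
    """A transcript as a sorted tuple of non-overlapping exon intervals."""

    transcript_id: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError(
                    f"transcript {self.transcript_id}: empty exon [{start},{end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exon_length(self) -> int:
        return sum(end - start for start, end in self.exons)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[Transcript, ...]
    gene_type: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


def select_tss(gene: GeneModel) -> tuple[int, Transcript]:
    """Return the TSS coordinate and the transcript that defines it.

    The transcript with the maximal summed exon length wins. Ties are broken
    by the more 5' start (strand-aware), then lexicographic transcript id,
    so the choice is deterministic.
    """
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id} has no transcripts")

    def rank(t: Transcript):
        start, end = t.span
        five_prime = start if gene.strand == "+" else -(end - 1)
        return (-t.exon_length, five_prime, t.transcript_id)

    best = min(gene.transcripts, key=rank)
    start, end = best.span
    tss = start if gene.strand == "+" else end - 1
    return tss, best


def signed_distance(pos, tss: int, strand: str):
    """Signed bp distance from TSS; negative means upstream of the gene."""
    raw = np.asarray(pos) - tss
    return raw if strand == "+" else -raw


def collect_cis_probes(
    gene: GeneModel, probes: pd.DataFrame, window_bp: int
) -> pd.DataFrame:
    """All probes on the gene's chromosome with |pos - tss| <= window_bp.

    Returns a frame with probe_id, pos and the strand-aware signed distance.
    The window boundary is inclusive. A probe may pair with many genes.
    """
    tss, _ = select_tss(gene)
    sub = probes.loc[probes["chrom"] == gene.chrom, ["probe_id", "pos"]]
    raw = sub["pos"].to_numpy() - tss
    keep = np.abs(raw) <= window_bp
    out = sub.loc[keep].copy()
    out["signed_distance"] = signed_distance(out["pos"].to_numpy(), tss, gene.strand)
    return out.reset_index(drop=True)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals into a sorted list."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def cgi_relation(
    positions: Sequence[int] | np.ndarray,
    islands: Sequence[tuple[int, int]],
) -> np.ndarray:
    """Classify positions against CpG islands on one chromosome.

    Distance is measured from the probe position to the nearest island base
    (BED half-open: bases start..end-1). 0 < d <= 2000 is shore, 2000 < d <=
    4000 is shelf, anything farther is open sea.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if len(islands) == 0:
        return np.full(pos.shape, "open_sea", dtype=object)
    merged = merge_intervals(islands)
    starts = np.array([s for s, _ in merged], dtype=np.int64)
    ends = np.array([e for _, e in merged], dtype=np.int64)

    idx = np.searchsorted(starts, pos, side="right") - 1
    prev = np.clip(idx, 0, len(starts) - 1)
    inside = (idx >= 0) & (pos < ends[prev])

    # distance to the previous island's last base and the next island's first
    d_prev = np.where(idx >= 0, pos - (ends[prev] - 1), np.iinfo(np.int64).max)
    nxt = np.clip(idx + 1, 0, len(starts) - 1)
    d_next = np.where(idx + 1 < len(starts), starts[nxt] - pos, np.iinfo(np.int64).max)
    dist = np.minimum(d_prev, d_next)
    dist[inside] = 0

    out = np.full(pos.shape, "open_sea", dtype=object)
    out[dist <= SHELF_BP] = "shelf"
    out[dist <= SHORE_BP] = "shore"
    out[inside] = "island"
    return out


def gene_component(
    positions: Sequence[int] | np.ndarray,
    gene: GeneModel,
    transcript: Transcript | None = None,
) -> np.ndarray:
    """Label positions by gene-body component of the TSS-selected transcript.

    "First" exon/intron are the 5'-most in strand order; positions outside
    the transcript span are intergenic. Single-exon transcripts have no
    introns.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if transcript is None:
        _, transcript = select_tss(gene)
    exons = transcript.exons
    n_ex = len(exons)
    bounds = np.array([b for exon in exons for b in exon], dtype=np.int64)
    idx = np.searchsorted(bounds, pos, side="right")

    out = np.full(pos.shape, "intergenic", dtype=object)
    in_exon = idx % 2 == 1
    exon_rank = idx // 2  # coordinate order
    intron_rank = idx // 2 - 1
    in_intron = (~in_exon) & (idx > 0) & (idx < 2 * n_ex)

    first_exon_coord = 0 if gene.strand == "+" else n_ex - 1
    first_intron_coord = 0 if gene.strand == "+" else n_ex - 2

    out[in_exon & (exon_rank == first_exon_coord)] = "first_exon"
    out[in_exon & (exon_rank != first_exon_coord)] = "other_exon"
    if n_ex > 1:
        out[in_intron & (intron_rank == first_intron_coord)] = "first_intron"
        out[in_intron & (intron_rank != first_intron_coord)] = "other_intron"
    return out


def annotate_probes(
    genes: Sequence[GeneModel],
    probes: pd.DataFrame,
    cgis: pd.DataFrame,
    window_bp: int = 1_000_000,
    chrom_blocklist: Sequence[str] = (),
) -> pd.DataFrame:
    """Build the per-(gene, probe) annotation table for all cis pairings.

    Genes on blocklisted chromosomes (e.g. sex chromosomes) are skipped.
    Returns columns: gene_id, probe_id, pos, signed_distance, cgi_relation,
    component.
    """
    islands_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, grp in cgis.groupby("chrom"):
        islands_by_chrom[chrom] = merge_intervals(
            zip(grp["start"].astype(int), grp["end"].astype(int))
        )
    frames = []
    for gene in genes:
        if gene.chrom in chrom_blocklist:
            continue
        cis = collect_cis_probes(gene, probes, window_bp)
        if cis.empty:
            continue
        pos = cis["pos"].to_numpy()
        cis.insert(0, "gene_id", gene.gene_id)
        cis["cgi_relation"] = cgi_relation(pos, islands_by_chrom.get(gene.chrom, []))
        cis["component"] = gene_component(pos, gene)
        frames.append(cis)
    if not frames:
        return pd.DataFrame(
            columns=[
                "gene_id",
                "probe_id",
                "pos",
                "signed_distance",
                "cgi_relation",
                "component",
            ]
        )
    return pd.concat(frames, ignore_index=True)
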