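"""TSS selection, cis-probe collection, CGI banding and gene components."""

import numpy as np
import pandas as pd
import pytest

from cismeth import (
    GeneModel,
    Transcript,
    cgi_relation,
    collect_cis_probes,
    gene_component,
    select_tss,
)


def make_gene(strand="+", exon_sets=None, gene_id="G1", chrom="chr1"):
    exon_sets = exon_sets or {"t1": ((100, 200), (300, 500))}
    transcripts = tuple(
        Transcript(tid, tuple(exons)) for tid, exons in exon_sets.items()
    )
    return GeneModel(gene_id, chrom, strand, transcripts)


class TestSelectTss:
    def test_single_transcript_plus_strand(self):
        tss, _ = select_tss(make_gene())
        assert tss == 100

    def test_longest_exon_sum_wins(self):
        gene = make_gene(
            exon_sets={
                "t1": ((100, 300), (400, 600)),          # 400 bp of exon
                "t2": ((50, 350), (400, 700)),           # 600 bp of exon
            }
        )
        tss, tr = select_tss(gene)
        assert tr.transcript_id == "t2"
        assert tss == 50

    def test_minus_strand_tss_is_last_base(self):
        gene = make_gene(strand="-", exon_sets={"t1": ((100, 500),)})
        tss, _ = select_tss(gene)
        assert tss == 499

    def test_tie_break_five_prime_then_id(self):
        gene = make_gene(
            exon_sets={"t2": ((100, 300),), "t1": ((150, 350),)}
        )
        tss, tr = select_tss(gene)
        assert (tss, tr.transcript_id) == (100, "t2")
        # equal starts too: lexicographic id decides
        gene2 = make_gene(exon_sets={"tb": ((100, 300),), "ta": ((100, 300),)})
        assert select_tss(gene2)[1].transcript_id == "ta"

    def test_no_transcripts_raises_with_gene_name(self):
        gene = GeneModel("G9", "chr1", "+", ())
        with pytest.raises(ValueError, match="G9"):
            select_tss(gene)


class TestCollectCisProbes:
    def manifest(self, positions, chrom="chr1"):
        return pd.DataFrame(
            {
                "probe_id": [f"cg{i}" for i in range(len(positions))],
                "chrom": chrom,
                "pos": positions,
            }
        )

    def test_probe_at_tss_distance_zero(self):
        gene = make_gene(exon_sets={"t1": ((2_000_000, 2_000_500),)})
        out = collect_cis_probes(gene, self.manifest([2_000_000]), 1_000_000)
        assert out["signed_distance"].tolist() == [0]

    def test_sign_convention_upstream_negative(self):
        gene = make_gene(exon_sets={"t1": ((2_000_000, 2_000_500),)})
        out = collect_cis_probes(gene, self.manifest([1_997_500]), 1_000_000)
        assert out["signed_distance"].tolist() == [-2500]
        # on the minus strand the same probe is downstream
        gene_m = make_gene(strand="-", exon_sets={"t1": ((1_999_501, 2_000_001),)})
        out_m = collect_cis_probes(gene_m, self.manifest([1_997_500]), 1_000_000)
        assert out_m["signed_distance"].tolist() == [2500]

    def test_window_boundary_inclusive_and_chromosome_match(self):
        gene = make_gene(exon_sets={"t1": ((2_000_000, 2_000_500),)})
        m = self.manifest([1_000_000, 999_999, 3_000_000, 3_000_001])
        out = collect_cis_probes(gene, m, 1_000_000)
        assert set(out["probe_id"]) == {"cg0", "cg2"}
        other = self.manifest([2_000_000], chrom="chr2")
        assert collect_cis_probes(gene, other, 1_000_000).empty

    def test_matches_exhaustive_pairwise_scan(self, rng):
        tss = 5_000_000
        gene = make_gene(exon_sets={"t1": ((tss, tss + 1000),)})
        pos = rng.integers(3_000_000, 7_000_000, size=1000)
        m = self.manifest(pos)
        out = collect_cis_probes(gene, m, 1_000_000)
        expected = {
            f"cg{i}" for i, p in enumerate(pos) if abs(int(p) - tss) <= 1_000_000
        }
        assert set(out["probe_id"]) == expected


def brute_force_cgi(pos, islands):
    best = np.inf
    for s, e in islands:
        if s <= pos < e:
            return "island"
        best = min(best, s - pos if pos < s else pos - (e - 1))
    if best <= 2000:
        return "shore"
    if best <= 4000:
        return "shelf"
    return "open_sea"


class TestCgiRelation:
    islands = [(10_000, 11_000), (30_000, 30_500)]

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (10_500, "island"),
            (10_999, "island"),
            (11_000, "shore"),       # first base past the island, gap 1
            (12_499, "shore"),       # gap 1500
            (13_999, "shelf"),       # gap 3000
            (15_999, "open_sea"),    # gap 5000
            (8_500, "shore"),
            (6_500, "shelf"),
        ],
    )
    def test_banding(self, pos, expected):
        assert cgi_relation([pos], self.islands)[0] == expected

    def test_agrees_with_brute_force_on_random_probes(self, rng):
        islands = []
        cursor = 0
        for _ in range(20):
            cursor += int(rng.integers(2_000, 20_000))
            islands.append((cursor, cursor + int(rng.integers(200, 2_000))))
            cursor = islands[-1][1]
        pos = rng.integers(0, cursor + 10_000, size=500)
        got = cgi_relation(pos, islands)
        expected = [brute_force_cgi(int(p), islands) for p in pos]
        assert got.tolist() == expected

    def test_no_islands_everything_open_sea(self):
        assert set(cgi_relation([1, 100, 10_000], [])) == {"open_sea"}


def painted_component_oracle(gene):
    """Base-by-base painting of the TSS transcript, strand-aware."""
    _, tr = select_tss(gene)
    span = tr.span
    paint = {}
    exons = list(tr.exons) if gene.strand == "+" else list(tr.exons)[::-1]
    for rank, (s, e) in enumerate(exons):
        label = "first_exon" if rank == 0 else "other_exon"
        for p in range(s, e):
            paint[p] = label
    introns = []
    coord = list(tr.exons)
    for (s1, e1), (s2, e2) in zip(coord, coord[1:]):
        introns.append((e1, s2))
    if gene.strand == "-":
        introns = introns[::-1]
    for rank, (s, e) in enumerate(introns):
        label = "first_intron" if rank == 0 else "other_intron"
        for p in range(s, e):
            paint[p] = label

    def classify(p):
        if p < span[0] or p >= span[1]:
            return "intergenic"
        return paint[p]

    return classify


class TestGeneComponent:
    def test_first_exon_and_intron_plus_strand(self):
        gene = make_gene(exon_sets={"t1": ((100, 200), (300, 500), (600, 700))})
        got = gene_component([150, 250, 400, 550, 650, 50, 800], gene)
        assert got.tolist() == [
            "first_exon", "first_intron", "other_exon",
            "other_intron", "other_exon", "intergenic", "intergenic",
        ]

    def test_minus_strand_first_is_rightmost(self):
        gene = make_gene(
            strand="-", exon_sets={"t1": ((100, 200), (300, 500), (600, 700))}
        )
        got = gene_component([650, 550, 400, 250, 150], gene)
        assert got.tolist() == [
            "first_exon", "first_intron", "other_exon",
            "other_intron", "other_exon",
        ]

    def test_single_exon_has_no_introns(self):
        gene = make_gene(exon_sets={"t1": ((100, 500),)})
        got = gene_component([300, 50, 600], gene)
        assert got.tolist() == ["first_exon", "intergenic", "intergenic"]

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_painted_array_oracle(self, rng, strand):
        exons = []
        cursor = 1_000
        for _ in range(int(rng.integers(2, 6))):
            cursor += int(rng.integers(50, 500))
            exons.append((cursor, cursor + int(rng.integers(50, 800))))
            cursor = exons[-1][1]
        gene = make_gene(strand=strand, exon_sets={"t1": tuple(exons)})
        oracle = painted_component_oracle(gene)
        pos = rng.integers(0, cursor + 2_000, size=200)
        got = gene_component(pos, gene)
        assert got.tolist() == [oracle(int(p)) for p in pos]


class TestStrandSymmetry:
    def test_mirroring_flips_distances_and_preserves_labels(self, rng):
        L = 10_000_000
        exons = ((4_000_000, 4_000_800), (4_001_500, 4_003_000), (4_004_000, 4_005_000))
        gene = make_gene(strand="+", exon_sets={"t1": exons})
        islands = [(3_995_000, 3_996_000), (4_002_000, 4_002_300)]
        pos = rng.integers(3_900_000, 4_100_000, size=300)

        mirror = lambda p: L - 1 - p  # noqa: E731
        m_exons = tuple(sorted((mirror(e - 1), mirror(s - 1)) for s, e in exons))
        gene_m = make_gene(strand="-", exon_sets={"t1": m_exons})
        m_islands = [(mirror(e - 1), mirror(s - 1)) for s, e in islands]
        m_pos = np.array([mirror(int(p)) for p in pos])

        tss, _ = select_tss(gene)
        tss_m, _ = select_tss(gene_m)
        assert tss_m == mirror(tss)

        d = pos - tss
        d_m = -(m_pos - tss_m)
        np.testing.assert_array_equal(d, d_m)

        assert cgi_relation(pos, islands).tolist() == cgi_relation(
            m_pos, m_islands
        ).tolist()
        assert gene_component(pos, gene).tolist() == gene_component(
            m_pos, gene_m
        ).tolist()
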