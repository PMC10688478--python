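"""Interval algebra, gene models and file round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cistromix.core import (
    DomainError,
    GeneModel,
    GenomicInterval,
    ParameterError,
    ParseError,
    Peak,
    merge_within,
    read_bed,
    read_gtf,
    read_peaks_bed,
    signed_distance_to_tss,
    write_bed,
    write_gtf,
    write_peaks_bed,
)


def occupancy_union(intervals, gap):
    """Per-bp occupancy oracle for merge_within (single chromosome).

    Marks occupied base pairs, extracts maximal runs, then joins runs whose
    separation is <= gap; for gap 0 this is the classical union of
    overlapping/adjacent intervals.
    """
    if not intervals:
        return []
    hi = max(iv.end for iv in intervals) + 1
    occ = np.zeros(hi, dtype=bool)
    for iv in intervals:
        occ[iv.start : iv.end] = True
    runs = []
    in_run = False
    for pos in range(hi):
        if occ[pos] and not in_run:
            runs.append([pos, pos + 1])
            in_run = True
        elif occ[pos]:
            runs[-1][1] = pos + 1
        else:
            in_run = False
    out = []
    for s, e in runs:
        if out and s - out[-1][1] <= gap:
            out[-1][1] = e
        else:
            out.append([s, e])
    return [tuple(r) for r in out]


class TestGenomicInterval:
    def test_invariants_enforced(self):
        with pytest.raises(ParameterError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ParameterError):
            GenomicInterval("", 0, 10)
        with pytest.raises(ParameterError):
            GenomicInterval("chr1", -1, 10)

    def test_center_and_overlap(self):
        a = GenomicInterval("chr1", 100, 300)
        assert a.center == 200
        assert a.overlaps(GenomicInterval("chr1", 299, 400))
        assert not a.overlaps(GenomicInterval("chr1", 300, 400))
        assert not a.overlaps(GenomicInterval("chr2", 100, 300))


class TestMergeWithin:
    def test_gap_bridges_small_separation(self):
        ivs = [GenomicInterval("chr1", 100, 300), GenomicInterval("chr1", 350, 500)]
        assert merge_within(ivs, 200) == [GenomicInterval("chr1", 100, 500)]

    def test_large_separation_unchanged(self):
        ivs = [GenomicInterval("chr1", 100, 300), GenomicInterval("chr1", 600, 700)]
        assert merge_within(ivs, 200) == ivs

    def test_negative_gap_rejected(self):
        with pytest.raises(ParameterError):
            merge_within([GenomicInterval("chr1", 0, 10)], -1)

    def test_chromosomes_kept_separate(self):
        ivs = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr2", 50, 150)]
        assert len(merge_within(ivs, 1000)) == 2

    def test_matches_occupancy_oracle_gap0(self, rng):
        for _ in range(50):
            ivs = [
                GenomicInterval("c", int(s), int(s) + int(l))
                for s, l in zip(
                    rng.integers(0, 2000, 30), rng.integers(1, 200, 30)
                )
            ]
            got = [(iv.start, iv.end) for iv in merge_within(ivs, 0)]
            assert got == occupancy_union(ivs, 0)

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.tuples(st.integers(0, 3000), st.integers(1, 300)),
            min_size=1,
            max_size=25,
        ),
        st.integers(0, 300),
    )
    def test_idempotent_and_monotone(self, raw, gap):
        ivs = [GenomicInterval("c", s, s + l) for s, l in raw]
        once = merge_within(ivs, gap)
        assert merge_within(once, gap) == once
        # output count is non-increasing in gap
        assert len(merge_within(ivs, gap + 50)) <= len(once)
        # coverage bounds (gap > 0 may also cover the bridged gaps)
        covered = sum(len(iv) for iv in once)
        assert covered >= max(len(iv) for iv in ivs)
        assert covered <= sum(len(iv) for iv in ivs) + gap * (len(ivs) - 1)
        # pairwise separation exceeds gap
        for a, b in zip(once, once[1:]):
            assert b.start - a.end > gap


class TestSignedDistance:
    @pytest.mark.parametrize(
        "point,strand,expected",
        [(9500, "+", -500), (9500, "-", 500), (10000, "+", 0), (10000, "-", 0)],
    )
    def test_sign_convention(self, point, strand, expected):
        exons = [GenomicInterval("chr1", 10000, 10500, strand)]
        gene = GeneModel(
            "g", "G", "chr1", strand,
            tss=10000 if strand == "+" else 10500,
            tts=10500 if strand == "+" else 10000,
            exons=exons,
        )
        if strand == "-":
            # recompute for the minus-strand TSS at 10500
            expected = gene.tss - point
        assert signed_distance_to_tss(point, gene) == expected

    def test_chromosome_mismatch(self):
        gene = GeneModel(
            "g", "G", "chr1", "+", 0, 100,
            [GenomicInterval("chr1", 0, 100, "+")],
        )
        with pytest.raises(DomainError):
            signed_distance_to_tss(5, gene, chrom="chr2")


class TestGeneModel:
    def _gene(self, strand):
        exons = [
            GenomicInterval("chr1", 1000, 1200, strand),
            GenomicInterval("chr1", 2000, 2300, strand),
            GenomicInterval("chr1", 5000, 5400, strand),
        ]
        tss = 1000 if strand == "+" else 5400
        tts = 5400 if strand == "+" else 1000
        return GeneModel("g", "G", "chr1", strand, tss, tts, exons)

    def test_intron_numbering_follows_transcription(self):
        plus = self._gene("+")
        minus = self._gene("-")
        assert plus.intron_index(1500) == 1
        assert plus.intron_index(3000) == 2
        assert minus.intron_index(1500) == 2
        assert minus.intron_index(3000) == 1
        assert plus.intron_index(1100) is None  # exonic

    def test_tss_consistency_enforced(self):
        with pytest.raises(ParameterError):
            GeneModel(
                "g", "G", "chr1", "+", 999, 5400,
                [GenomicInterval("chr1", 1000, 1200, "+")],
            )


class TestIO:
    def test_bed_round_trip(self, tmp_path):
        ivs = [
            GenomicInterval("chr1", 100, 500),
            GenomicInterval("chr2", 0, 7, "-"),
        ]
        path = tmp_path / "x.bed"
        write_bed(path, ivs)
        assert read_bed(path) == ivs

    def test_bed_parse_error_names_line(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t100\t500\nchr1\tnope\t10\n")
        with pytest.raises(ParseError, match=":2:"):
            read_bed(path)

    def test_peaks_bed_round_trip(self, tmp_path):
        peaks = [
            Peak(GenomicInterval("chr1", 100, 500), summit=321, score=50,
                 fold_enrichment=8.5, fdr=1e-6, replicate_support=3,
                 source="s1"),
        ]
        path = tmp_path / "p.bed"
        write_peaks_bed(path, peaks)
        back = read_peaks_bed(path)
        assert back[0].interval == peaks[0].interval
        assert back[0].summit == 321
        assert back[0].fold_enrichment == 8.5
        assert back[0].replicate_support == 3

    def test_gtf_minus_strand_tss(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        attrs = 'gene_id "g1"; transcript_id "t1"; gene_name "Foo";'
        gtf.write_text(
            f"chr1\tsrc\texon\t101\t200\t.\t-\t.\t{attrs}\n"
            f"chr1\tsrc\texon\t501\t700\t.\t-\t.\t{attrs}\n"
        )
        (gene,) = read_gtf(gtf)
        assert gene.tss == 700  # max end coordinate on minus strand
        assert gene.tts == 100
        assert gene.symbol == "Foo"
        assert [(e.start, e.end) for e in gene.exons] == [(100, 200), (500, 700)]

    def test_gtf_canonical_transcript_by_extent(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        lines = []
        for tx, (s, e) in {"t1": (101, 300), "t2": (101, 900)}.items():
            lines.append(
                f'chr1\tsrc\texon\t{s}\t{e}\t.\t+\t.\tgene_id "g1"; '
                f'transcript_id "{tx}";\n'
            )
        gtf.write_text("".join(lines))
        (gene,) = read_gtf(gtf)
        assert gene.exons[0].end == 900  # t2 has the larger extent

    def test_gtf_round_trip_counts(self, tmp_path, default_sim):
        path = tmp_path / "sim.gtf"
        write_gtf(path, default_sim.genes[:10])
        back = read_gtf(path)
        assert len(back) == 10
        for orig, rt in zip(sorted(default_sim.genes[:10], key=lambda g: g.gene_id), back):
            assert len(rt.introns()) == len(rt.exons) - 1
            assert rt.tss == orig.tss and rt.strand == orig.strand

    def test_gtf_malformed_line(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text("chr1\tsrc\texon\t1\t100\n")
        with pytest.raises(ParseError, match=":1:"):
            read_gtf(path)
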