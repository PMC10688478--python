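"""IUPAC scanning and motif analytics, checked against brute-force oracles."""

import numpy as np
import pytest

from cistromix.core import DictGenome, GenomicInterval, ParameterError, Peak
from cistromix.motifs import (
    BUILTIN_MOTIFS,
    IUPAC_CLASSES,
    IupacMotif,
    cooccurrence_venn,
    density_profile,
    flag_overlapping_pairs,
    iupac_match,
    pair_distances,
    presence_table,
    read_motifs,
    reverse_complement,
    scan_sequence,
)

ERE = next(m for m in BUILTIN_MOTIFS if m.name == "ERE")
NR5A = next(m for m in BUILTIN_MOTIFS if m.name == "NR5A")


def brute_force_hits(seq, motifs):
    """Per-position oracle: check every window on both strands directly."""
    comp = str.maketrans("ACGTN", "TGCAN")
    hits = []
    for motif in motifs:
        m = len(motif.consensus)
        for i in range(len(seq) - m + 1):
            window = seq[i : i + m]
            if all(
                b in IUPAC_CLASSES[c] or (c == "N" and b == "N")
                for c, b in zip(motif.consensus, window)
            ):
                hits.append((motif.name, i, "+"))
            rc = window.translate(comp)[::-1]
            if all(
                b in IUPAC_CLASSES[c] or (c == "N" and b == "N")
                for c, b in zip(motif.consensus, rc)
            ):
                hits.append((motif.name, i, "-"))
    return sorted(hits, key=lambda h: (h[1], h[0], h[2]))


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestIupacMatch:
    @pytest.mark.parametrize(
        "consensus,seq,expected",
        [
            ("GGTCASNBTGAC", "GGTCACCGTGAC", True),  # S->C, N->C, B->G
            ("GGTCASNBTGAC", "GGTCAAATGACC", False),  # A not in S={C,G}
            ("CYDTGACCTTGA", "CCATGACCTTGA", True),  # Y->C, D->A
            ("NNNN", "ACGN", True),  # N in seq matches only N consensus
            ("ACGT", "ACGN", False),
        ],
    )
    def test_examples(self, consensus, seq, expected):
        assert iupac_match(consensus, seq) is expected

    def test_length_mismatch(self):
        with pytest.raises(ParameterError):
            iupac_match("ACGT", "ACG")

    def test_mismatch_budget(self):
        assert not iupac_match("GGTCASNBTGAC", "GGTCAACGTGAC")
        assert iupac_match("GGTCASNBTGAC", "GGTCAACGTGAC", max_mismatches=1)

    def test_motif_validation(self):
        with pytest.raises(ParameterError):
            IupacMotif("bad", "ACZ")
        with pytest.raises(ParameterError):
            IupacMotif("short", "ACG")


class TestScanSequence:
    def test_reverse_complement_hit(self):
        seq = reverse_complement("GGTCACCGTGAC")
        hits = scan_sequence(seq, [ERE])
        assert [(h.strand, h.start) for h in hits] == [("-", 0)]

    def test_two_forward_hits(self):
        seq = "GGTCACCGTGAC" + "A" * 20 + "GGTCACCGTGAC"
        hits = [h for h in scan_sequence(seq, [ERE]) if h.strand == "+"]
        assert [h.start for h in hits] == [0, 32]

    def test_strand_symmetry(self, rng):
        seq = random_seq(rng, 500)
        fwd = scan_sequence(seq, BUILTIN_MOTIFS)
        rev = scan_sequence(reverse_complement(seq), BUILTIN_MOTIFS)
        mirrored = sorted(
            (h.motif, len(seq) - h.end, {"+": "-", "-": "+"}[h.strand])
            for h in fwd
        )
        assert mirrored == sorted((h.motif, h.start, h.strand) for h in rev)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            seq = random_seq(rng, 1000)
            got = sorted(
                (h.motif, h.start, h.strand)
                for h in scan_sequence(seq, BUILTIN_MOTIFS)
            )
            assert got == brute_force_hits(seq, BUILTIN_MOTIFS)

    def test_offset_shifts_coordinates(self):
        hits = scan_sequence("GGTCACCGTGAC", [ERE], offset=1000)
        assert hits[0].start == 1000
        assert hits[0].midpoint == 1006


class TestPresenceAndVenn:
    def test_presence_of_planted_motif(self):
        seq = "T" * 50 + "GGTCACCGTGAC" + "T" * 50
        genome = DictGenome({"chr1": seq})
        peak = Peak(GenomicInterval("chr1", 0, len(seq)))
        rows, fractions, skipped = presence_table([peak], genome)
        assert rows == [{"ERE": True, "NR5A": False, "GATA": False}]
        assert fractions["ERE"] == 1.0 and skipped == 0

    def test_out_of_bounds_peak_skipped_with_warning(self):
        genome = DictGenome({"chr1": "ACGT" * 100})
        good = Peak(GenomicInterval("chr1", 0, 50))
        bad = Peak(GenomicInterval("chr1", 350, 500))
        with pytest.warns(UserWarning):
            rows, _, skipped = presence_table([good, bad], genome)
        assert len(rows) == 1 and skipped == 1

    def test_empty_peak_list(self):
        rows, fractions, _ = presence_table([], DictGenome({"c": "ACGT"}))
        assert rows == [] and fractions == {"ERE": None, "NR5A": None, "GATA": None}

    def test_venn_partitions(self):
        table = [
            {"ERE": True, "NR5A": False, "GATA": False},
            {"ERE": True, "NR5A": True, "GATA": False},
            {"ERE": False, "NR5A": False, "GATA": False},
        ]
        venn = cooccurrence_venn(table)
        assert venn["ERE_only"] == 1 and venn["ERE+NR5A"] == 1 and venn["none"] == 1
        assert sum(venn.values()) == len(table)

    def test_all_false_counts_none(self):
        venn = cooccurrence_venn([{"ERE": False, "NR5A": False, "GATA": False}] * 7)
        assert venn["none"] == 7 and sum(venn.values()) == 7


class TestPairDistances:
    def _hits(self, pairs):
        from cistromix.motifs import MotifHit

        out = []
        for peak_pairs in pairs:
            hits = []
            for name, mid in peak_pairs:
                length = 12 if name in ("ERE", "NR5A") else 8
                hits.append(MotifHit(name, mid - length // 2, "+", "A" * length))
            out.append(hits)
        return out

    def test_signed_distances(self):
        hits = self._hits([[("ERE", 105), ("NR5A", 155)], [("ERE", 100), ("NR5A", 290)]])
        res = pair_distances(hits, "ERE", "NR5A")
        assert res.distances == [50, 190]
        assert res.histogram_distances == [50, 190]
        assert res.fraction_within == 0.5

    def test_missing_motif_excluded(self):
        hits = self._hits([[("ERE", 100)], [("ERE", 100), ("NR5A", 160)]])
        res = pair_distances(hits, "ERE", "NR5A")
        assert res.excluded_peaks == 1 and res.distances == [60]

    def test_closest_pair_chosen(self):
        hits = self._hits([[("ERE", 100), ("NR5A", 500), ("NR5A", 130)]])
        assert pair_distances(hits, "ERE", "NR5A").distances == [30]


class TestOverlapFlags:
    def _hit(self, name, start, length):
        from cistromix.motifs import MotifHit

        return MotifHit(name, start, "+", "A" * length)

    @pytest.mark.parametrize(
        "nr5a_start,expected",
        [(108, True), (121, True), (130, False)],  # overlap, gap 9, gap 18
    )
    def test_gap_rule(self, nr5a_start, expected):
        hits = [[self._hit("ERE", 100, 12), self._hit("NR5A", nr5a_start, 12)]]
        assert flag_overlapping_pairs(hits, "ERE", "NR5A", 10) == [expected]

    def test_half_site_artifact_regression(self):
        """An NR5A match whose flanks complete an ERE must be flagged.

        The NR5A element starts with C-Y-D-TGACC; preceding it with GGTCA
        yields GGTCA|CCT|TGAC, a valid ERE, so a single physical element
        matches both consensi at overlapping positions.
        """
        seq = "TTTTT" + "GGTCA" + "CCTTGACCTTGA" + "TTTTT"
        hits = scan_sequence(seq, BUILTIN_MOTIFS)
        motifs_found = {h.motif for h in hits}
        assert {"ERE", "NR5A"} <= motifs_found
        assert flag_overlapping_pairs([hits], "NR5A", "ERE", 10) == [True]


class TestDensityProfile:
    def test_central_mode_and_conservation(self):
        seqs = {}
        peaks = []
        half = 1500
        for i in range(5):
            chrom = f"c{i}"
            seq = list("A" * 4000)
            center = 2000
            seq[center - 6 : center + 6] = list("GGTCACCGTGAC")
            seqs[chrom] = "".join(seq)
            peaks.append(Peak(GenomicInterval(chrom, center - 100, center + 100)))
        genome = DictGenome(seqs)
        prof = density_profile(peaks, ERE, genome, halfwidth=half, bin_width=50)
        assert prof.counts.sum() == 5
        central = (0 + half) // 50
        assert prof.counts.argmax() == central
        # conservation: density * bin * n_peaks == total hits
        assert prof.density.sum() * 50 * 5 == pytest.approx(prof.counts.sum())

    def test_absent_motif_zero_profile(self):
        genome = DictGenome({"c": "A" * 4000})
        peaks = [Peak(GenomicInterval("c", 1900, 2100))]
        prof = density_profile(peaks, ERE, genome)
        assert prof.counts.sum() == 0 and prof.density.sum() == 0

    def test_clipping_accounted(self):
        genome = DictGenome({"c": "A" * 2000})
        peaks = [Peak(GenomicInterval("c", 100, 300))]
        prof = density_profile(peaks, ERE, genome)
        assert prof.clipped_peaks == 1


def test_read_motifs(tmp_path):
    path = tmp_path / "motifs.tsv"
    path.write_text("ERE\tGGTCASNBTGAC\n# comment\nGATA\tBNWGATAA\n")
    motifs = read_motifs(path)
    assert [m.name for m in motifs] == ["ERE", "GATA"]
    bad = tmp_path / "bad.tsv"
    bad.write_text("onlyname\n")
    from cistromix.core import ParseError

    with pytest.raises(ParseError, match=":1:"):
        read_motifs(bad)
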