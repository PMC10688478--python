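"""Synthetic-data generator: determinism, ground truth and recoverability."""

import numpy as np
import pytest

from cistromix.core import ParameterError
from cistromix.motifs import BUILTIN_MOTIFS, IUPAC_CLASSES, scan_sequence
from cistromix.peaks import CallerConfig, call_peaks, consensus_peaks
from cistromix.simulate import (
    SimConfig,
    fixture_tables,
    generate_expression,
    generate_genome,
    simulate,
    simulate_read_tracks,
    write_simulation,
)


class TestConfig:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ParameterError):
            SimConfig(seed=1, motif_class_probs={"ERE_only": 0.5, "none": 0.4})

    def test_fractions_validated(self):
        with pytest.raises(ParameterError):
            SimConfig(seed=1, dual_bound_fraction=1.5)


class TestGenerateGenome:
    def test_deterministic(self):
        cfg = SimConfig(seed=42, n_chroms=1, chrom_length=200_000, n_genes=8)
        s1, g1 = generate_genome(cfg)
        s2, g2 = generate_genome(cfg)
        assert all(np.array_equal(s1[c], s2[c]) for c in s1)
        assert [g.tss for g in g1] == [g.tss for g in g2]

    def test_gene_structure(self):
        cfg = SimConfig(seed=7, n_chroms=1, chrom_length=300_000, n_genes=10)
        _, genes = generate_genome(cfg)
        assert len(genes) == 10
        for g in genes:
            assert len(g.exons) >= 2
            assert len(g.introns()) == len(g.exons) - 1
        # genes do not overlap
        spans = sorted((g.span.start, g.span.end) for g in genes)
        assert all(b[0] >= a[1] for a, b in zip(spans, spans[1:]))

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ParameterError):
            generate_genome(SimConfig(seed=1, n_chroms=1, chrom_length=50_000, n_genes=40))

    def test_background_motif_rate_matches_degeneracy(self):
        """Scan raw random DNA: hit count ~ Poisson with the analytic rate."""
        cfg = SimConfig(seed=99, n_chroms=2, chrom_length=1_000_000, n_genes=2)
        seqs, _ = generate_genome(cfg)
        for motif in BUILTIN_MOTIFS:
            degeneracy = np.prod([len(IUPAC_CLASSES[c]) for c in motif.consensus])
            m = len(motif.consensus)
            n_pos = sum(len(s) - m + 1 for s in seqs.values())
            expected = 2 * n_pos * degeneracy / 4.0**m  # both strands
            observed = sum(
                len(scan_sequence(s.tobytes().decode(), [motif]))
                for s in seqs.values()
            )
            assert abs(observed - expected) <= 5 * np.sqrt(expected) + 3, motif.name


class TestGroundTruth:
    def test_simulation_deterministic(self):
        a = simulate(SimConfig(seed=5))
        b = simulate(SimConfig(seed=5))
        assert a.truth.to_json() == b.truth.to_json()
        assert [len(r) for r in a.replicate_peaks] == [len(r) for r in b.replicate_peaks]
        assert a.genome.fetch("chr1", 0, 5000) == b.genome.fetch("chr1", 0, 5000)

    def test_planted_class_fractions_recovered(self, default_sim):
        """Per-site presence over consensus peaks matches the planted mix."""
        sim = default_sim
        cons = consensus_peaks(sim.replicate_peaks)
        site_by_pos = {
            (s.chrom, s.center): s.motif_class for s in sim.truth.sites
        }
        matched = 0
        for p in cons:
            for (chrom, center), cls in site_by_pos.items():
                if chrom == p.chrom and abs(p.interval.center - center) <= 150:
                    hits = scan_sequence(
                        sim.genome.fetch(chrom, p.interval.start, p.interval.end),
                        BUILTIN_MOTIFS,
                    )
                    present = {h.motif for h in hits}
                    from cistromix.simulate import _CLASS_MOTIFS

                    assert present == set(_CLASS_MOTIFS[cls]), (cls, present)
                    matched += 1
                    break
        assert matched >= 180  # ~97% of 200 sites survive consensus

    def test_noise_free_limit_consensus_equals_truth(self):
        cfg = SimConfig(
            seed=3,
            replicate_detection_prob=1.0,
            noise_peaks_per_replicate=0,
        )
        sim = simulate(cfg)
        cons = consensus_peaks(sim.replicate_peaks)
        assert len(cons) == cfg.n_true_sites
        centers = {(p.chrom, p.interval.center) for p in cons}
        for s in sim.truth.sites:
            assert any(
                c == s.chrom and abs(x - s.center) <= 30 for c, x in centers
            )

    def test_pair_offset_recovered(self, default_sim):
        """ERE-NR5A planted offset appears as the modal pair distance."""
        from cistromix.motifs import pair_distances

        sim = default_sim
        hits = []
        for s in sim.truth.sites:
            if "ERE" in s.motif_class.replace("ERE_only", "ERE") and "NR5A" in s.motif_class:
                seq = sim.genome.fetch(s.chrom, s.center - 100, s.center + 100)
                hits.append(scan_sequence(seq, BUILTIN_MOTIFS, offset=s.center - 100))
        res = pair_distances(hits, "ERE", "NR5A")
        assert res.distances
        values, counts = np.unique(res.distances, return_counts=True)
        assert abs(values[counts.argmax()]) == sim.config.planted_pair_offset

    def test_dual_fraction_planted(self, default_sim):
        truth = default_sim.truth
        frac = sum(s.dual for s in truth.sites) / len(truth.sites)
        p = default_sim.config.dual_bound_fraction
        assert abs(frac - p) <= 2.576 * np.sqrt(p * (1 - p) / len(truth.sites))


class TestGenerateExpression:
    def test_noise_free_recovery_is_exact(self):
        from cistromix.integrate import essential_genes, filter_degs

        cfg = SimConfig(seed=11, nb_dispersion=0.0)
        rng = np.random.default_rng(cfg.seed)
        _, genes = generate_genome(cfg, rng)
        bound = {g.gene_id for g in genes[:100]}
        records, direct_truth, essential_truth = generate_expression(
            genes, bound, cfg, rng
        )
        degs = filter_degs(records)
        planted_degs = set(direct_truth) | {
            r.gene_id
            for r in records
            if r.gene_id not in direct_truth and abs(r.log2fc) > 0.4 and r.fdr < 0.05
        }
        assert set(g for g in degs.gene_ids) == planted_degs
        # essential cascade: precision and recall 1 in the noise-free limit
        ess = set(essential_genes(records).gene_id)
        assert ess == essential_truth

    def test_recall_degrades_with_dispersion(self):
        from cistromix.integrate import filter_degs

        recalls = []
        for disp in (0.0, 0.4):
            cfg = SimConfig(seed=21, nb_dispersion=disp)
            rng = np.random.default_rng(cfg.seed)
            _, genes = generate_genome(cfg, rng)
            bound = {g.gene_id for g in genes[:100]}
            records, direct_truth, _ = generate_expression(genes, bound, cfg, rng)
            degs = filter_degs(records).gene_ids
            planted = set(direct_truth)
            recalls.append(len(degs & planted) / len(planted))
        assert recalls[0] == 1.0
        assert recalls[1] < recalls[0]


class TestReadTracks:
    def test_caller_recovers_planted_sites(self):
        cfg = SimConfig(seed=31, n_chroms=1, chrom_length=1_200_000, n_genes=50,
                        n_true_sites=40, n_bound_genes=20, n_degs=30, n_essential=5)
        sim = simulate(cfg)
        chip, inp = simulate_read_tracks(sim, reads_per_site=80)
        peaks = call_peaks(chip, inp, CallerConfig())
        centers = np.array([p.summit for p in peaks])
        recalled = sum(
            np.abs(centers - s.center).min() <= 300 for s in sim.truth.sites
        )
        assert recalled / len(sim.truth.sites) >= 0.95


class TestOutputs:
    def test_write_simulation_files(self, tmp_path, default_sim):
        paths = write_simulation(default_sim, tmp_path)
        import json
        from cistromix.core import FastaGenome, read_gtf, read_peaks_bed

        genes = read_gtf(paths["gtf"])
        assert len(genes) == default_sim.config.n_genes
        rep1 = read_peaks_bed(paths["replicate_1"])
        assert len(rep1) == len(default_sim.replicate_peaks[0])
        fa = FastaGenome(paths["genome"])
        assert fa.fetch("chr1", 100, 200) == default_sim.genome.fetch("chr1", 100, 200)
        truth = json.load(open(paths["ground_truth"]))
        assert len(truth["sites"]) == default_sim.config.n_true_sites

    def test_fixture_tables_shape(self):
        t1, t2 = fixture_tables()
        assert len(t1) == 14
        assert t2.gene.nunique() == 28
        assert t1.set_index("gene").loc["Bhmt"].binding_site == "Intergenic"
        assert (t2[t2.gene == "Fkbp5"].NR5A == "x3").all()
        assert len(t2[t2.gene == "Fkbp5"]) == 2
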