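"""Self-contained synthetic data with known ground truth for every stage.

The generator emulates the study design the pipeline targets: a small
multi-chromosome genome with multi-exon genes, a set of true binding sites
carrying planted ERE/NR5A/GATA motif combinations, three replicate peak
sets with per-replicate detection dropout and noise peaks, a partner-factor
cistrome overlapping a controlled fraction of true sites, open-chromatin
and cross-species bound-gene sets, and a knockout-vs-wild-type DE table
with planted direct targets and negative-binomial count noise.

Default parameters mirror the headline fractions of the study conditions:
84% of sites carry at least one of the three motifs (class mix as printed
in the motif Venn), 36% of sites are dual-bound by the partner factor, 30%
of DEGs are direct targets, 69% of bound genes lie in open chromatin and
38% of bound genes are conserved.  Everything is deterministic given the
seed (one integer RNG stream, no locale-dependent I/O).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import AnnotationConfig, GeneIndex, classify_peak
from .core import (
    DictGenome,
    GeneModel,
    GenomicInterval,
    ParameterError,
    Peak,
    write_fasta,
    write_gtf,
    write_peaks_bed,
)
from .integrate import DERecord
from .motifs import BUILTIN_MOTIFS, scan_sequence
from .peaks import CoverageTrack

__all__ = [
    "SimConfig",
    "GroundTruthSite",
    "GroundTruth",
    "Simulation",
    "simulate",
    "generate_genome",
    "plant_cistrome",
    "generate_expression",
    "simulate_read_tracks",
    "write_simulation",
    "fixture_tables",
]

_DEFAULT_CLASS_PROBS = {
    "ERE_only": 0.246,
    "NR5A_only": 0.153,
    "GATA_only": 0.064,
    "ERE+NR5A": 0.224,
    "ERE+GATA": 0.138,
    "NR5A+GATA": 0.010,
    "triple": 0.007,
    "none": 0.158,
}


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic data.

    The seed is mandatory; all other defaults are the conditions the
    pipeline is meant to recover (see module docstring).
    """

    seed: int
    n_chroms: int = 3
    chrom_length: int = 1_500_000
    n_genes: int = 240
    n_true_sites: int = 200
    n_bound_genes: int = 100
    intron1_site_fraction: float = 0.36
    min_site_separation: int = 3_000
    peak_width: int = 200
    n_replicates: int = 3
    replicate_detection_prob: float = 0.9
    noise_peaks_per_replicate: int = 30
    motif_class_probs: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_PROBS)
    )
    planted_pair_offset: int = 60
    dual_bound_fraction: float = 0.36
    partner_only_peaks: int = 80
    partner_jitter: int = 50
    direct_target_fraction: float = 0.30
    n_degs: int = 120
    deg_up_fraction: float = 0.49
    effect_size_log2fc_mean: float = 1.0
    effect_size_log2fc_sd: float = 0.4
    min_effect_log2fc: float = 0.55
    nb_dispersion: float = 0.05
    n_essential: int = 10
    n_wt: int = 5
    n_ko: int = 4
    counts_per_fpkm: float = 20.0
    conservation_fraction: float = 0.38
    open_chromatin_fraction: float = 0.69

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ParameterError("seed is mandatory")
        total = sum(self.motif_class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"motif class probabilities sum to {total}, not 1")
        for name in (
            "replicate_detection_prob",
            "dual_bound_fraction",
            "direct_target_fraction",
            "conservation_fraction",
            "open_chromatin_fraction",
            "deg_up_fraction",
            "intron1_site_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1], got {v}")


@dataclass
class GroundTruthSite:
    chrom: str
    center: int
    motif_class: str
    dual: bool
    gene_id: str | None  # nearest gene when deliberately placed near one
    feature: str | None  # summit category at generation time


@dataclass
class GroundTruth:
    sites: list[GroundTruthSite]
    bound_genes: set[str]
    direct_targets: dict[str, float]  # gene_id -> planted log2fc
    essential_genes: set[str]
    conserved_genes: set[str]
    open_genes: set[str]

    def to_json(self) -> dict:
        return {
            "sites": [
                {
                    "chrom": s.chrom,
                    "center": s.center,
                    "motif_class": s.motif_class,
                    "dual": s.dual,
                    "gene_id": s.gene_id,
                    "feature": s.feature,
                }
                for s in self.sites
            ],
            "bound_genes": sorted(self.bound_genes),
            "direct_targets": dict(sorted(self.direct_targets.items())),
            "essential_genes": sorted(self.essential_genes),
            "conserved_genes": sorted(self.conserved_genes),
            "open_genes": sorted(self.open_genes),
        }


@dataclass
class Simulation:
    """Everything the generator produced, in memory."""

    config: SimConfig
    genome: DictGenome
    genes: list[GeneModel]
    replicate_peaks: list[list[Peak]]
    partner_peaks: list[Peak]
    de_table: list[DERecord]
    human_bound: dict[str, str]  # upper-case symbol -> feature category
    truth: GroundTruth


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def generate_genome(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, np.ndarray], list[GeneModel]]:
    """I.i.d. uniform ACGT chromosomes with non-overlapping multi-exon genes.

    Returns mutable uint8 sequence arrays (so motifs can be planted later)
    and the gene models.  Deterministic given the config seed.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    seqs = {
        f"chr{i + 1}": _random_dna(rng, cfg.chrom_length)
        for i in range(cfg.n_chroms)
    }
    genes: list[GeneModel] = []
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1
    gene_no = 0
    for ci, chrom in enumerate(sorted(seqs)):
        cursor = 10_000
        for _ in range(per_chrom[ci]):
            gene_no += 1
            n_exons = int(rng.integers(3, 6))
            exon_lens = rng.integers(200, 400, size=n_exons)
            intron_lens = rng.integers(2_000, 4_000, size=n_exons - 1)
            span = int(exon_lens.sum() + intron_lens.sum())
            if cursor + span + 10_000 > cfg.chrom_length:
                raise ParameterError(
                    "infeasible gene packing: increase chrom_length or "
                    "decrease n_genes"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            pos = cursor
            for k in range(n_exons):
                exons.append(
                    GenomicInterval(chrom, pos, pos + int(exon_lens[k]), strand)
                )
                pos += int(exon_lens[k])
                if k < n_exons - 1:
                    pos += int(intron_lens[k])
            gid = f"gene{gene_no:04d}"
            genes.append(
                GeneModel(
                    gene_id=gid,
                    symbol=f"Sg{gene_no:04d}",
                    chrom=chrom,
                    strand=strand,
                    tss=exons[0].start if strand == "+" else exons[-1].end,
                    tts=exons[-1].end if strand == "+" else exons[0].start,
                    exons=exons,
                )
            )
            cursor = pos + int(rng.integers(4_000, 9_000))
    return seqs, genes


def _instantiate(consensus: str, rng: np.random.Generator) -> str:
    from .motifs import IUPAC_CLASSES

    return "".join(
        c if len(IUPAC_CLASSES[c]) == 1 else IUPAC_CLASSES[c][rng.integers(len(IUPAC_CLASSES[c]))]
        for c in consensus
    )


def _write_seq(seqs: dict[str, np.ndarray], chrom: str, start: int, s: str) -> None:
    seqs[chrom][start : start + len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)


_CLASS_MOTIFS = {
    "ERE_only": ("ERE",),
    "NR5A_only": ("NR5A",),
    "GATA_only": ("GATA",),
    "ERE+NR5A": ("ERE", "NR5A"),
    "ERE+GATA": ("ERE", "GATA"),
    "NR5A+GATA": ("NR5A", "GATA"),
    "triple": ("ERE", "NR5A", "GATA"),
    "none": (),
}


def _plant_motifs(
    seqs: dict[str, np.ndarray],
    chrom: str,
    center: int,
    motif_class: str,
    pair_offset: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Write the class's motif instances around ``center``.

    The ERE midpoint sits at the site center; when ERE and NR5A co-occur
    the NR5A midpoint is placed ``pair_offset`` bp downstream of the ERE
    midpoint.  Returns the planted (start, end) spans.
    """
    present = _CLASS_MOTIFS[motif_class]
    by_name = {m.name: m for m in BUILTIN_MOTIFS}
    spans: list[tuple[int, int]] = []
    if "ERE" in present:
        s = _instantiate(by_name["ERE"].consensus, rng)
        start = center - len(s) // 2
        _write_seq(seqs, chrom, start, s)
        spans.append((start, start + len(s)))
    if "NR5A" in present:
        s = _instantiate(by_name["NR5A"].consensus, rng)
        mid = center + pair_offset if "ERE" in present else center
        start = mid - len(s) // 2
        _write_seq(seqs, chrom, start, s)
        spans.append((start, start + len(s)))
    if "GATA" in present:
        s = _instantiate(by_name["GATA"].consensus, rng)
        mid = center - 40 if len(present) > 1 else center
        start = mid - len(s) // 2
        _write_seq(seqs, chrom, start, s)
        spans.append((start, start + len(s)))
    return spans


def _scrub_region(
    seqs: dict[str, np.ndarray],
    chrom: str,
    start: int,
    end: int,
    protected: list[tuple[int, int]],
    rng: np.random.Generator,
    max_rounds: int = 12,
) -> None:
    """Mutate away incidental motif matches in a window, sparing planted spans."""
    start = max(0, start)
    end = min(len(seqs[chrom]), end)
    for _ in range(max_rounds):
        region = seqs[chrom][start:end].tobytes().decode()
        dirty = False
        for hit in scan_sequence(region, BUILTIN_MOTIFS, offset=start):
            if any(hit.start >= ps and hit.end <= pe for ps, pe in protected):
                continue
            free = [
                p
                for p in range(hit.start, hit.end)
                if not any(ps <= p < pe for ps, pe in protected)
            ]
            if not free:
                continue
            pos = free[len(free) // 2]
            old = seqs[chrom][pos]
            choices = [b for b in _BASES if b != old]
            seqs[chrom][pos] = choices[rng.integers(3)]
            dirty = True
        if not dirty:
            return


def plant_cistrome(
    seqs: dict[str, np.ndarray],
    genes: list[GeneModel],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[GroundTruthSite], list[list[Peak]], list[Peak]]:
    """Plant true sites, replicate peak sets and the partner cistrome.

    True sites are >= ``min_site_separation`` apart; a configurable fraction
    sits in intron 1 of its linked gene, the rest of the gene-linked sites
    upstream of the TSS within the bound-gene window, and the remainder in
    deep intergenic space.  Each replicate observes each true site with the
    detection probability and adds motif-free noise peaks; the partner
    cistrome covers ``dual_bound_fraction`` of true sites plus its own
    unique peaks.
    """
    index = GeneIndex(genes)
    chrom_names = sorted(seqs)
    half = cfg.peak_width // 2
    taken: list[tuple[str, int]] = []

    def is_free(chrom: str, pos: int, sep: int) -> bool:
        return all(
            c != chrom or abs(p - pos) >= sep for c, p in taken
        )

    # --- gene-linked sites (these genes become the planted bound genes)
    acfg = AnnotationConfig()
    eligible = [g for g in genes]
    rng.shuffle(eligible)
    n_intron1 = round(cfg.intron1_site_fraction * cfg.n_bound_genes)
    sites: list[GroundTruthSite] = []
    bound_genes: set[str] = set()
    gi = 0
    while len(bound_genes) < cfg.n_bound_genes and gi < len(eligible):
        gene = eligible[gi]
        gi += 1
        want_intron1 = len(bound_genes) < n_intron1
        placed = None
        for _ in range(20):
            if want_intron1:
                introns = gene.introns()
                intron1 = (
                    introns[0] if gene.strand == "+" else introns[-1]
                )
                # stay within +2 kb of the TSS so the windowed bound rule holds
                lo = intron1.start + 20
                hi = min(intron1.end - 20, gene.tss + 1_900) if gene.strand == "+" else intron1.end - 20
                if gene.strand == "-":
                    lo = max(intron1.start + 20, gene.tss - 1_900)
                if hi - lo < 40:
                    break
                pos = int(rng.integers(lo, hi))
            else:
                offset = int(rng.integers(2_500, 40_000))
                pos = gene.tss - offset if gene.strand == "+" else gene.tss + offset
            if pos < 2_000 or pos > cfg.chrom_length - 2_000:
                continue
            if not is_free(gene.chrom, pos, cfg.min_site_separation):
                continue
            nearest = index.nearest(gene.chrom, pos)
            if nearest is not None and nearest.gene_id == gene.gene_id:
                placed = pos
                break
        if placed is None:
            continue
        taken.append((gene.chrom, placed))
        sites.append(
            GroundTruthSite(gene.chrom, placed, "", False, gene.gene_id, None)
        )
        bound_genes.add(gene.gene_id)
    if len(bound_genes) < cfg.n_bound_genes:
        raise ParameterError(
            f"could only place {len(bound_genes)} of {cfg.n_bound_genes} "
            "gene-linked sites; loosen the packing parameters"
        )

    # --- remaining sites: deep intergenic (outside every bound window)
    while len(sites) < cfg.n_true_sites:
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        pos = int(rng.integers(2_000, cfg.chrom_length - 2_000))
        if not is_free(chrom, pos, cfg.min_site_separation):
            continue
        nearest = index.nearest(chrom, pos)
        if nearest is not None:
            from .core import signed_distance_to_tss

            d = signed_distance_to_tss(pos, nearest)
            # 100 bp margin so summit jitter cannot cross the window edge
            if (
                -acfg.bound_window_upstream - 100
                <= d
                <= acfg.bound_window_downstream + 100
            ):
                continue  # would create an unplanned bound gene
        taken.append((chrom, pos))
        sites.append(GroundTruthSite(chrom, pos, "", False, None, None))

    # --- motif classes and dual flags
    classes = list(cfg.motif_class_probs)
    probs = np.array([cfg.motif_class_probs[c] for c in classes])
    drawn = rng.choice(len(classes), size=len(sites), p=probs)
    dual = rng.random(len(sites)) < cfg.dual_bound_fraction
    protected_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in seqs}
    for site, cls_i, is_dual in zip(sites, drawn, dual):
        site.motif_class = classes[cls_i]
        site.dual = bool(is_dual)
        spans = _plant_motifs(
            seqs, site.chrom, site.center, site.motif_class,
            cfg.planted_pair_offset, rng,
        )
        protected_by_chrom[site.chrom].extend(spans)

    # --- noise-peak and partner-only positions (motif-free, off-site)
    def free_position(sep: int) -> tuple[str, int]:
        while True:
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            pos = int(rng.integers(2_000, cfg.chrom_length - 2_000))
            if is_free(chrom, pos, sep):
                return chrom, pos

    noise_centers: list[list[tuple[str, int]]] = []
    for _ in range(cfg.n_replicates):
        rep_noise = []
        for _ in range(cfg.noise_peaks_per_replicate):
            chrom, pos = free_position(1_000)
            rep_noise.append((chrom, pos))
        noise_centers.append(rep_noise)
    partner_only = [free_position(1_000) for _ in range(cfg.partner_only_peaks)]

    # --- scrub incidental motif matches inside every scanned window
    for site in sites:
        _scrub_region(
            seqs, site.chrom, site.center - half - 60, site.center + half + 60,
            protected_by_chrom[site.chrom], rng,
        )
    for rep_noise in noise_centers:
        for chrom, pos in rep_noise:
            _scrub_region(
                seqs, chrom, pos - half - 60, pos + half + 60,
                protected_by_chrom[chrom], rng,
            )

    # --- replicate peak sets
    def make_peak(chrom: str, center: int, source: str) -> Peak:
        jitter = int(rng.integers(-20, 21))
        start = center + jitter - half
        return Peak(
            interval=GenomicInterval(chrom, start, start + cfg.peak_width),
            summit=center + jitter,
            score=float(rng.integers(30, 120)),
            fold_enrichment=float(5 + rng.random() * 15),
            fdr=float(10 ** -rng.uniform(4, 12)),
            source=source,
        )

    replicate_peaks: list[list[Peak]] = []
    for rep in range(cfg.n_replicates):
        peaks = [
            make_peak(s.chrom, s.center, f"rep{rep + 1}_site")
            for s in sites
            if rng.random() < cfg.replicate_detection_prob
        ]
        peaks.extend(
            make_peak(chrom, pos, f"rep{rep + 1}_noise")
            for chrom, pos in noise_centers[rep]
        )
        peaks.sort(key=lambda p: (p.chrom, p.interval.start))
        replicate_peaks.append(peaks)

    # --- partner cistrome
    partner_peaks = [
        make_peak(
            s.chrom,
            s.center + int(rng.integers(-cfg.partner_jitter, cfg.partner_jitter + 1)),
            "partner_dual",
        )
        for s in sites
        if s.dual
    ]
    partner_peaks.extend(
        make_peak(chrom, pos, "partner_only") for chrom, pos in partner_only
    )
    partner_peaks.sort(key=lambda p: (p.chrom, p.interval.start))

    # --- record each site's summit feature category (generation-time truth)
    genome = DictGenome({c: seqs[c].tobytes().decode() for c in seqs})
    index2 = GeneIndex(genes)
    for site in sites:
        probe = Peak(
            interval=GenomicInterval(site.chrom, site.center - half, site.center + half),
            summit=site.center,
        )
        site.feature = classify_peak(probe, index2, acfg).category
    return sites, replicate_peaks, partner_peaks


def generate_expression(
    genes: list[GeneModel],
    bound_genes: set[str],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[DERecord], dict[str, float], set[str]]:
    """DE table with planted direct targets and essential genes.

    Baselines are log-normal FPKMs; planted DEGs shift one group by a drawn
    log2FC (sign split per ``deg_up_fraction``); replicate counts are
    gamma-Poisson (negative binomial) with the configured dispersion; the
    per-gene p-value is a two-sample Welch test on log2 counts with BH
    correction.  ``n_essential`` of the downregulated bound targets are
    forced to the near-absent knockout / expressed wild-type regime.
    Returns (records, planted log2FC per direct target, essential set).
    """
    from scipy import stats as sps
    from statsmodels.stats.multitest import multipletests

    n_direct = round(cfg.direct_target_fraction * cfg.n_degs)
    bound_sorted = sorted(bound_genes)
    if n_direct > len(bound_sorted):
        raise ParameterError("direct targets exceed available bound genes")
    rng.shuffle(bound_sorted)
    direct = bound_sorted[:n_direct]
    unbound = [g.gene_id for g in genes if g.gene_id not in bound_genes]
    rng.shuffle(unbound)
    indirect = unbound[: cfg.n_degs - n_direct]
    deg_ids = direct + indirect

    baseline = {
        g.gene_id: float(np.exp(rng.normal(1.2, 1.0))) for g in genes
    }
    planted_fc: dict[str, float] = {}
    for gid in deg_ids:
        mag = max(
            cfg.min_effect_log2fc,
            float(rng.normal(cfg.effect_size_log2fc_mean, cfg.effect_size_log2fc_sd)),
        )
        sign = 1.0 if rng.random() < cfg.deg_up_fraction else -1.0
        planted_fc[gid] = sign * mag
        baseline[gid] = max(baseline[gid], 3.0)

    # essential genes: near-absent KO, expressed WT, large negative log2FC
    down_direct = [g for g in direct if planted_fc[g] < 0]
    if len(down_direct) < cfg.n_essential:
        # flip enough up-regulated direct targets to meet the quota
        for g in direct:
            if len(down_direct) >= cfg.n_essential:
                break
            if planted_fc[g] > 0:
                planted_fc[g] = -planted_fc[g]
                down_direct.append(g)
    forced = set(down_direct[: cfg.n_essential])
    for gid in forced:
        wt = float(rng.uniform(5.0, 40.0))
        ko = float(rng.uniform(0.1, 1.0))
        baseline[gid] = wt
        planted_fc[gid] = float(np.log2(ko / wt))
    # ground-truth essential = every gene whose planted group means satisfy
    # the cascade (the forced set guarantees at least n_essential of them)
    essential = set()
    for gid, fc in planted_fc.items():
        wt_mean = baseline[gid]
        ko_mean = wt_mean * 2.0 ** fc
        if ko_mean < 2.0 and wt_mean >= 2.0 and wt_mean >= 2.0 * ko_mean:
            essential.add(gid)

    def group_counts(mean_fpkm: float, n: int) -> np.ndarray:
        mean = mean_fpkm * cfg.counts_per_fpkm
        if cfg.nb_dispersion <= 0:
            return np.full(n, mean)
        shape = 1.0 / cfg.nb_dispersion
        lam = rng.gamma(shape, mean / shape, size=n)
        return rng.poisson(lam).astype(float)

    records: list[DERecord] = []
    pvals: list[float] = []
    for g in genes:
        gid = g.gene_id
        fc = planted_fc.get(gid, 0.0)
        wt_mean = baseline[gid]
        ko_mean = wt_mean * 2.0 ** fc if gid in planted_fc else wt_mean
        wt_counts = group_counts(wt_mean, cfg.n_wt)
        ko_counts = group_counts(ko_mean, cfg.n_ko)
        wt_fpkm = float(wt_counts.mean() / cfg.counts_per_fpkm)
        ko_fpkm = float(ko_counts.mean() / cfg.counts_per_fpkm)
        log2fc = float(np.log2((ko_fpkm + 0.05) / (wt_fpkm + 0.05)))
        # two-group comparison by normal approximation on log2 counts
        lw = np.log2(wt_counts + 1.0)
        lk = np.log2(ko_counts + 1.0)
        se = float(
            np.sqrt(lw.var(ddof=1) / cfg.n_wt + lk.var(ddof=1) / cfg.n_ko)
        )
        if se == 0.0:
            p = 0.0 if abs(lw.mean() - lk.mean()) > 1e-12 else 1.0
        else:
            z = (lw.mean() - lk.mean()) / se
            p = float(2.0 * sps.norm.sf(abs(z)))
        pvals.append(p)
        records.append(
            DERecord(
                gene_id=gid,
                symbol=g.symbol,
                fpkm_wt=wt_fpkm,
                fpkm_ko=ko_fpkm,
                log2fc=log2fc,
                pvalue=p,
                fdr=1.0,
            )
        )
    qvals = multipletests(pvals, method="fdr_bh")[1]
    for rec, q in zip(records, qvals):
        rec.fdr = float(q)
    direct_truth = {gid: planted_fc[gid] for gid in direct}
    return records, direct_truth, essential


def simulate(cfg: SimConfig) -> Simulation:
    """Run the whole generator; one RNG stream drives every draw."""
    rng = np.random.default_rng(cfg.seed)
    seqs, genes = generate_genome(cfg, rng)
    sites, replicate_peaks, partner_peaks = plant_cistrome(seqs, genes, cfg, rng)
    bound = {s.gene_id for s in sites if s.gene_id is not None}
    de_table, direct_truth, essential = generate_expression(genes, bound, cfg, rng)

    # open-chromatin and cross-species bound-gene sets over the bound genes
    symbols = {g.gene_id: g.symbol for g in genes}
    bound_sorted = sorted(bound)
    n_open = round(cfg.open_chromatin_fraction * len(bound_sorted))
    open_idx = rng.choice(len(bound_sorted), size=n_open, replace=False)
    open_genes = {bound_sorted[i] for i in open_idx}
    extra = [g.gene_id for g in genes if g.gene_id not in bound]
    open_genes |= set(extra[:30])

    n_cons = round(cfg.conservation_fraction * len(bound_sorted))
    cons_idx = rng.choice(len(bound_sorted), size=n_cons, replace=False)
    conserved = {bound_sorted[i] for i in cons_idx}
    feature_by_gene = {
        s.gene_id: s.feature for s in sites if s.gene_id is not None
    }
    human_bound = {
        symbols[gid].upper(): feature_by_gene.get(gid) or "intergenic"
        for gid in conserved
    }
    # a few human-only bound genes that must not count as conserved
    for gid in extra[30:45]:
        human_bound[symbols[gid].upper()] = "intron"

    truth = GroundTruth(
        sites=sites,
        bound_genes=bound,
        direct_targets=direct_truth,
        essential_genes=essential,
        conserved_genes=conserved,
        open_genes=open_genes,
    )
    genome = DictGenome({c: seqs[c].tobytes().decode() for c in sorted(seqs)})
    return Simulation(
        config=cfg,
        genome=genome,
        genes=genes,
        replicate_peaks=replicate_peaks,
        partner_peaks=partner_peaks,
        de_table=de_table,
        human_bound=human_bound,
        truth=truth,
    )


def simulate_read_tracks(
    sim: Simulation,
    reads_per_site: int = 60,
    background_reads_per_kb: float = 10.0,
    seed: int | None = None,
) -> tuple[CoverageTrack, CoverageTrack]:
    """ChIP/input read tracks: uniform background with Poisson-enriched sites.

    ChIP reads pile up normally (sd 40 bp) around each true site on top of a
    uniform background; the input is uniform at the same background rate.
    """
    rng = np.random.default_rng(
        sim.config.seed + 7_777 if seed is None else seed
    )
    lengths = sim.genome.chroms()
    chip: dict[str, list[np.ndarray]] = {c: [] for c in lengths}
    inp: dict[str, np.ndarray] = {}
    for chrom, n in lengths.items():
        n_bg = rng.poisson(background_reads_per_kb * n / 1000)
        chip[chrom].append(rng.integers(0, n, size=n_bg))
        inp[chrom] = rng.integers(0, n, size=rng.poisson(background_reads_per_kb * n / 1000))
    for site in sim.truth.sites:
        k = rng.poisson(reads_per_site)
        pos = np.clip(
            np.round(rng.normal(site.center, 40.0, size=k)).astype(np.int64),
            0,
            lengths[site.chrom] - 1,
        )
        chip[site.chrom].append(pos)
    chip_track = CoverageTrack(
        {c: np.concatenate(v) for c, v in chip.items()}, dict(lengths)
    )
    input_track = CoverageTrack(inp, dict(lengths))
    return chip_track, input_track


def write_simulation(sim: Simulation, outdir) -> dict[str, str]:
    """Write FASTA, GTF, peak BEDs, DE TSV, gene sets and ground truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    seqs = {c: sim.genome.fetch(c, 0, n) for c, n in sim.genome.chroms().items()}
    write_fasta(out / "genome.fa", seqs)
    paths["genome"] = str(out / "genome.fa")
    write_gtf(out / "genes.gtf", sim.genes)
    paths["gtf"] = str(out / "genes.gtf")
    for i, peaks in enumerate(sim.replicate_peaks, 1):
        p = out / f"replicate_{i}.peaks.bed"
        write_peaks_bed(p, peaks)
        paths[f"replicate_{i}"] = str(p)
    write_peaks_bed(out / "partner.peaks.bed", sim.partner_peaks)
    paths["partner"] = str(out / "partner.peaks.bed")
    de = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "symbol": r.symbol,
                "fpkm_wt": r.fpkm_wt,
                "fpkm_ko": r.fpkm_ko,
                "log2fc": r.log2fc,
                "pvalue": r.pvalue,
                "fdr": r.fdr,
            }
            for r in sim.de_table
        ]
    )
    de.to_csv(out / "expression.tsv", sep="\t", index=False)
    paths["expression"] = str(out / "expression.tsv")
    with open(out / "open_chromatin_genes.txt", "w") as fh:
        fh.writelines(g + "\n" for g in sorted(sim.truth.open_genes))
    paths["open_genes"] = str(out / "open_chromatin_genes.txt")
    pd.DataFrame(
        [{"symbol": s, "feature": f} for s, f in sorted(sim.human_bound.items())]
    ).to_csv(out / "human_bound_genes.tsv", sep="\t", index=False)
    paths["human_bound"] = str(out / "human_bound_genes.tsv")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(sim.truth.to_json(), fh, indent=1, sort_keys=True)
    paths["ground_truth"] = str(out / "ground_truth.json")
    return paths


def fixture_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Packaged per-gene fixture tables for the two reporting cascades.

    The first table lists the factor-dependent ("essential") genes with
    their printed log2FC, group FPKMs and binding-site label; the second
    lists the strongly downregulated dual-bound genes with per-site
    location, TSS distance (kb) and ERE/NR5A marks.  The ``fdr`` columns
    are synthetic placeholders consistent with the significance bounds the
    source tables state (FDR < 1e-4 and FDR < 0.05 respectively); the
    tables print no per-gene FDR.
    """
    from importlib.resources import files

    data = files("cistromix") / "data"
    t1 = pd.read_csv(str(data / "table1_dependent_genes.tsv"), sep="\t")
    t2 = pd.read_csv(str(data / "table2_dual_bound_genes.tsv"), sep="\t")
    return t1, t2


def table1_inputs() -> tuple[list[DERecord], dict[str, str]]:
    """Fixture table 1 as (DE records, per-gene binding-site labels)."""
    t1, _ = fixture_tables()
    records = [
        DERecord(
            gene_id=row.gene,
            symbol=row.gene,
            fpkm_wt=row.fpkm_wt,
            fpkm_ko=row.fpkm_ko,
            log2fc=row.log2fc,
            pvalue=row.fdr,
            fdr=row.fdr,
        )
        for row in t1.itertuples()
    ]
    sites = {
        row.gene: row.binding_site
        for row in t1.itertuples()
        if row.binding_site != "-"
    }
    return records, sites


def table2_inputs() -> tuple[list[DERecord], dict[str, list]]:
    """Fixture table 2 as (DE records, per-gene dual binding sites)."""
    from .integrate import BindingSite, parse_mark

    _, t2 = fixture_tables()
    records = []
    sites: dict[str, list] = {}
    for gene, grp in t2.groupby("gene", sort=False):
        first = grp.iloc[0]
        records.append(
            DERecord(
                gene_id=gene,
                symbol=gene,
                fpkm_wt=1.0,
                fpkm_ko=1.0,
                log2fc=float(first.log2fc),
                pvalue=float(first.fdr),
                fdr=float(first.fdr),
            )
        )
        sites[gene] = [
            BindingSite(
                location=row.location,
                tss_kb=float(row.tss_kb),
                ere_count=parse_mark(str(row.ERE)),
                nr5a_count=parse_mark(str(row.NR5A)),
                dual=True,
            )
            for row in grp.itertuples()
        ]
    return records, sites
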