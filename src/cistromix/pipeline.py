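"""End-to-end orchestration: from replicate peak sets and a DE table to a
headline-statistics report.

``run_pipeline`` wires the stages together: consensus construction, motif
presence/co-occurrence, feature annotation, bound-gene sets, DEG filtering
and direct-target calling, the essentiality and strong-downregulation
cascades, dual-cistrome comparison, open-chromatin overlap and
cross-species conservation.  The report echoes every threshold used, and
each fraction is reported next to its numerator and denominator.
"""

from __future__ import annotations

import json
import time
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .annotate import (
    AnnotationConfig,
    GeneIndex,
    annotation_table,
    bound_genes,
    classify_peak,
    classify_relative,
)
from .compare import (
    classify_dual_sites,
    conservation_overlap,
    open_chromatin_gene_overlap,
    overlap_cistromes,
)
from .core import GeneModel, Peak
from .integrate import (
    BindingSite,
    DEGConfig,
    DERecord,
    direct_targets,
    essential_genes,
    filter_degs,
    strong_down_dual_bound,
)
from .motifs import (
    BUILTIN_MOTIFS,
    _peak_hits,
    cooccurrence_venn,
    flag_overlapping_pairs,
    pair_distances,
)
from .peaks import consensus_peaks

logger = logging.getLogger("cistromix")

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Nested stage configurations plus consensus parameters."""

    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    deg: DEGConfig = field(default_factory=DEGConfig)
    consensus_min_support: int = 2
    consensus_merge_gap: int = 200
    dual_max_center_distance: int = 200
    motif_flank: int = 0
    pair_window: int = 200
    pair_within: int = 100
    artifact_max_gap: int = 10


def _feature_label(ann) -> str:
    if ann.category == "intron" and ann.intron_index is not None:
        return f"intron {ann.intron_index}"
    return ann.category


def run_pipeline(
    replicate_peaks: list[list[Peak]],
    genes: list[GeneModel],
    genome,
    de_table: list[DERecord],
    partner_peaks: list[Peak] | None = None,
    open_genes: set[str] | None = None,
    species_b_bound: dict[str, str] | None = None,
    cfg: PipelineConfig | None = None,
) -> dict:
    """Run every stage and return the report dictionary."""
    cfg = cfg or PipelineConfig()
    t0 = time.time()
    index = GeneIndex(genes)
    symbols = {g.gene_id: g.symbol for g in genes}

    # 1. consensus peaks across replicates
    consensus = consensus_peaks(
        replicate_peaks, cfg.consensus_min_support, cfg.consensus_merge_gap
    )
    logger.info("consensus: %d peaks from %d replicates", len(consensus), len(replicate_peaks))

    # 2. motif hits, presence and co-occurrence (rows stay peak-aligned)
    hits_per_peak = []
    scanned_mask = []
    for p in consensus:
        try:
            hits_per_peak.append(_peak_hits(p, genome, BUILTIN_MOTIFS, cfg.motif_flank))
            scanned_mask.append(True)
        except Exception:
            hits_per_peak.append([])
            scanned_mask.append(False)
    rows = [
        {m.name: any(h.motif == m.name for h in hits) for m in BUILTIN_MOTIFS}
        for hits in hits_per_peak
    ]
    skipped = scanned_mask.count(False)
    scanned_rows = [r for r, ok in zip(rows, scanned_mask) if ok]
    venn = cooccurrence_venn(scanned_rows)
    n_scanned = len(scanned_rows)
    fractions = {
        m.name: (
            sum(r[m.name] for r in scanned_rows) / n_scanned if n_scanned else None
        )
        for m in BUILTIN_MOTIFS
    }
    any_motif = n_scanned - venn["none"]

    # 3. annotation, feature distribution, bound genes
    ann_df = annotation_table(consensus, genes, cfg.annotation)
    feature_counts = ann_df["category"].value_counts().to_dict()
    bound = bound_genes(consensus, index, cfg.annotation)
    logger.info("bound genes: %d", len(bound))

    # per-gene site bookkeeping for the cascades
    anns = [classify_peak(p, index, cfg.annotation) for p in consensus]
    artifact_flags = flag_overlapping_pairs(
        hits_per_peak, "NR5A", "ERE", cfg.artifact_max_gap
    )

    # 4. DEG filtering and direct targets
    degs = filter_degs(de_table, cfg.deg)
    site_ann_by_gene: dict[str, list] = {}
    for p, ann, hits in zip(consensus, anns, hits_per_peak):
        if ann.nearest_gene is None:
            continue
        has_ere = any(h.motif == "ERE" for h in hits)
        site_ann_by_gene.setdefault(ann.nearest_gene, []).append((ann, has_ere))
    targets = direct_targets(degs, bound, site_ann_by_gene)

    # 5. essentiality cascade
    label_by_gene = {
        gid: _feature_label(pairs[0][0]) for gid, pairs in site_ann_by_gene.items()
    }
    essential_df = essential_genes(de_table, label_by_gene, cfg.deg)

    # 6. dual cistrome comparison
    report_dual: dict = {}
    sites_by_gene: dict[str, list[BindingSite]] = {}
    strong_df = pd.DataFrame()
    if partner_peaks is not None:
        shared, a_only, _b_only = overlap_cistromes(
            consensus, partner_peaks, cfg.dual_max_center_distance
        )
        shared_idx = {id(s.erb_peak): s for s in shared}
        peak_pos = {id(p): i for i, p in enumerate(consensus)}
        shared_presence = [rows[peak_pos[id(s.erb_peak)]] for s in shared]
        shared_flags = [artifact_flags[peak_pos[id(s.erb_peak)]] for s in shared]
        dual_counts, dual_counts_excl = classify_dual_sites(
            shared, shared_presence, shared_flags
        )
        # ERE-NR5A spacing within dual-motif co-bound sites
        both_hits = [
            hits
            for p, hits, row in zip(consensus, hits_per_peak, rows)
            if id(p) in shared_idx and row.get("ERE") and row.get("NR5A")
        ]
        spacing = pair_distances(
            both_hits, "ERE", "NR5A", cfg.pair_window, cfg.pair_within
        )
        dual_gene_ids = set()
        for s in shared:
            ann = classify_peak(s.erb_peak, index, cfg.annotation)
            if ann.nearest_gene is not None:
                dual_gene_ids.add(ann.nearest_gene)
        # per-gene binding-site records for the strong-downregulation cascade
        gene_by_id = {g.gene_id: g for g in genes}
        for p, ann, hits in zip(consensus, anns, hits_per_peak):
            if ann.nearest_gene is None:
                continue
            gene = gene_by_id[ann.nearest_gene]
            rel = classify_relative(p, gene, index, cfg.annotation)
            sites_by_gene.setdefault(ann.nearest_gene, []).append(
                BindingSite(
                    location=_feature_label(rel),
                    tss_kb=round((ann.signed_tss_distance or 0) / 1000, 1),
                    ere_count=sum(h.motif == "ERE" for h in hits),
                    nr5a_count=sum(h.motif == "NR5A" for h in hits),
                    dual=id(p) in shared_idx,
                )
            )
        strong_df = strong_down_dual_bound(de_table, sites_by_gene, cfg.deg)
        report_dual = {
            "n_dual_sites": len(shared),
            "dual_fraction": len(shared) / len(consensus) if consensus else 0.0,
            "dual_motif_classes": dual_counts,
            "dual_motif_classes_excluding_artifacts": dual_counts_excl,
            "n_artifact_flagged": int(sum(shared_flags)),
            "pair_distance_n": len(spacing.distances),
            "pair_distance_within_100bp_fraction": spacing.fraction_within,
            "strong_down_dual_genes": sorted(strong_df["gene"].unique().tolist()),
            "n_strong_down_dual_genes": int(strong_df["gene"].nunique()),
        }

    # 7. open chromatin and conservation
    report_open: dict = {}
    if open_genes is not None:
        frac = open_chromatin_gene_overlap(bound, open_genes)
        report_open = {
            "n_bound_genes_in_open_chromatin": len(bound & open_genes),
            "open_chromatin_fraction": frac,
        }
    report_cons: dict = {}
    if species_b_bound is not None:
        bound_features = {
            symbols[gid]: _feature_label(pairs[0][0])
            for gid, pairs in site_ann_by_gene.items()
            if gid in bound
        }
        _, cons_summary = conservation_overlap(bound_features, species_b_bound)
        report_cons = {
            "conservation_n_genes": cons_summary["n_genes"],
            "conservation_n_shared": cons_summary["n_shared"],
            "conservation_fraction": cons_summary["shared_fraction"],
        }

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "thresholds": {
            "consensus_min_support": cfg.consensus_min_support,
            "consensus_merge_gap": cfg.consensus_merge_gap,
            "dual_max_center_distance": cfg.dual_max_center_distance,
            **{f"deg_{k}": v for k, v in asdict(cfg.deg).items()},
            **{f"annotation_{k}": v for k, v in asdict(cfg.annotation).items()},
        },
        "n_consensus_peaks": len(consensus),
        "n_peaks_scanned": n_scanned,
        "n_peaks_unscannable": skipped,
        "feature_counts": feature_counts,
        "feature_fractions": {
            k: v / len(consensus) for k, v in feature_counts.items()
        },
        "motif_fractions": fractions,
        "motif_venn": venn,
        "any_motif_count": any_motif,
        "any_motif_fraction": any_motif / n_scanned if n_scanned else None,
        "n_bound_genes": len(bound),
        "n_degs": len(degs.degs),
        "n_degs_up": len(degs.up),
        "n_degs_down": len(degs.down),
        "n_direct_targets": targets.n_targets,
        "direct_target_fraction": targets.fraction_of_degs,
        "direct_targets_up": targets.n_up,
        "direct_targets_down": targets.n_down,
        "direct_target_ere_fraction": targets.ere_fraction,
        "n_essential_genes": int(len(essential_df)),
        "essential_genes": essential_df["gene"].tolist(),
        **report_dual,
        **report_open,
        **report_cons,
    }
    logger.info("pipeline finished in %.2f s", time.time() - t0)
    # attach the tabular outputs for callers that want them
    report["_tables"] = {
        "annotations": ann_df,
        "essential": essential_df,
        "strong_down_dual": strong_df,
    }
    return report


def write_report(report: dict, outdir) -> str:
    """Write the JSON report (tables as sibling TSVs) and return its path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tables = report.pop("_tables", {})
    for name, df in tables.items():
        if isinstance(df, pd.DataFrame) and len(df):
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    path = out / "report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return str(path)
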