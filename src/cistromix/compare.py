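"""Dual transcription-factor cistrome comparison and conservation.

Two peak sets are overlapped by peak-center distance (default 200 bp,
matching the assay's ~200-nt peak size) with greedy one-to-one pairing, the
co-bound loci are partitioned by ERE/NR5A motif content (with the half-site
overlap artifact flagged separately), bound-gene sets are intersected with
open-chromatin gene sets, and bound genes are compared across species via an
ortholog symbol map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .core import FeatureAnnotation, ParameterError, Peak

__all__ = [
    "DualSite",
    "ConservationRecord",
    "overlap_cistromes",
    "classify_dual_sites",
    "open_chromatin_gene_overlap",
    "conservation_overlap",
    "read_ortholog_map",
]


@dataclass
class DualSite:
    """A locus co-bound by both factors (paired by center distance)."""

    erb_peak: Peak
    partner_peak: Peak
    center_distance: int
    motif_class: str = "unclassified"  # NR5A_only | ERE_only | both | neither
    overlap_artifact_flag: bool = False


def overlap_cistromes(
    a: list[Peak], b: list[Peak], max_center_distance: int = 200
) -> tuple[list[DualSite], list[Peak], list[Peak]]:
    """Pair peaks of two cistromes whose centers are within a distance.

    Greedy one-to-one pairing by increasing center distance (ties: leftmost
    partner peak); unpaired peaks are returned as a-only / b-only, so
    ``len(shared) + len(a_only) == len(a)``.
    """
    if max_center_distance < 0:
        raise ParameterError("max_center_distance must be >= 0")
    candidates: list[tuple[int, int, int, int]] = []  # (dist, b_center, ai, bi)
    b_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for j, pb in enumerate(b):
        b_by_chrom.setdefault(pb.chrom, []).append((pb.interval.center, j))
    for chrom in b_by_chrom:
        b_by_chrom[chrom].sort()
    import bisect

    for i, pa in enumerate(a):
        row = b_by_chrom.get(pa.chrom, [])
        ca = pa.interval.center
        lo = bisect.bisect_left(row, (ca - max_center_distance, -1))
        for cb, j in row[lo:]:
            if cb - ca > max_center_distance:
                break
            candidates.append((abs(cb - ca), cb, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    shared: list[DualSite] = []
    for dist, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        shared.append(
            DualSite(
                erb_peak=a[i],
                partner_peak=b[j],
                center_distance=b[j].interval.center - a[i].interval.center,
            )
        )
    a_only = [p for i, p in enumerate(a) if i not in used_a]
    b_only = [p for j, p in enumerate(b) if j not in used_b]
    return shared, a_only, b_only


def classify_dual_sites(
    shared: list[DualSite],
    presence: list[dict[str, bool]],
    artifact_flags: list[bool] | None = None,
) -> tuple[dict[str, int], dict[str, int]]:
    """Partition co-bound sites into 4 ERE/NR5A motif classes.

    ``presence`` holds per-site motif booleans for the first factor's peak
    sequence; ``artifact_flags`` marks sites where an NR5A match overlaps
    (or nearly overlaps) an ERE match, i.e. possibly one physical element.
    Returns (counts, counts excluding flagged sites); each site's
    ``motif_class`` and ``overlap_artifact_flag`` are filled in place.
    """
    if len(presence) != len(shared):
        raise ParameterError("presence rows must match shared sites")
    if artifact_flags is None:
        artifact_flags = [False] * len(shared)
    counts = {"NR5A_only": 0, "ERE_only": 0, "both": 0, "neither": 0}
    counts_excl = dict(counts)
    for site, row, flagged in zip(shared, presence, artifact_flags):
        has_ere, has_nr5a = row.get("ERE", False), row.get("NR5A", False)
        if has_ere and has_nr5a:
            cls = "both"
        elif has_nr5a:
            cls = "NR5A_only"
        elif has_ere:
            cls = "ERE_only"
        else:
            cls = "neither"
        site.motif_class = cls
        site.overlap_artifact_flag = bool(flagged)
        counts[cls] += 1
        if not flagged:
            counts_excl[cls] += 1
    return counts, counts_excl


def open_chromatin_gene_overlap(
    bound_genes: set[str], open_genes: set[str]
) -> float:
    """Fraction of bound genes that also lie in open-chromatin regions."""
    if not bound_genes:
        warnings.warn("empty bound-gene set: overlap fraction is 0", stacklevel=2)
        return 0.0
    return len(bound_genes & open_genes) / len(bound_genes)


@dataclass
class ConservationRecord:
    """Cross-species binding comparison for one gene/ortholog pair."""

    gene: str
    ortholog: str
    bound_in_a: bool
    bound_in_b: bool
    feature_a: str | None
    feature_b: str | None
    conserved_feature: bool


def read_ortholog_map(path) -> dict[str, str]:
    """Two-column TSV of species-A symbol to species-B symbol."""
    from .core import ParseError

    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            out[parts[0]] = parts[1]
    return out


def conservation_overlap(
    bound_a: dict[str, str],
    bound_b: dict[str, str],
    ortholog_map: dict[str, str] | None = None,
    strict_intron: bool = False,
) -> tuple[list[ConservationRecord], dict[str, float | int]]:
    """Compare bound genes (with feature categories) between two species.

    ``bound_a``/``bound_b`` map gene symbol to the feature category of its
    (best) binding site.  Without an ortholog map, symbols are matched
    case-insensitively, mirroring symbol-level cross-species comparison.
    Feature conservation compares categories only (any intron matches any
    intron) unless ``strict_intron`` labels like "intron 1" must be equal.

    Returns the per-gene records and a summary with the shared-gene
    fraction and per-feature conservation counts.
    """
    if ortholog_map is not None and not ortholog_map:
        raise ParameterError("empty ortholog map")
    if ortholog_map is None:
        b_upper = {sym.upper(): sym for sym in bound_b}
        pairs = [(sym, b_upper.get(sym.upper(), sym.upper())) for sym in bound_a]
        dropped = 0
    else:
        # keep only one-to-one pairs
        targets: dict[str, int] = {}
        for v in ortholog_map.values():
            targets[v] = targets.get(v, 0) + 1
        pairs = []
        dropped = 0
        for sym in bound_a:
            ortho = ortholog_map.get(sym)
            if ortho is None or targets.get(ortho, 0) > 1:
                dropped += 1
                continue
            pairs.append((sym, ortho))

    def _norm(feature: str | None) -> str | None:
        if feature is None:
            return None
        if not strict_intron and feature.startswith("intron"):
            return "intron"
        return feature

    records: list[ConservationRecord] = []
    for gene, ortho in sorted(pairs):
        fa = bound_a.get(gene)
        fb = bound_b.get(ortho)
        bound_both = fb is not None
        records.append(
            ConservationRecord(
                gene=gene,
                ortholog=ortho,
                bound_in_a=True,
                bound_in_b=bound_both,
                feature_a=fa,
                feature_b=fb,
                conserved_feature=bound_both and _norm(fa) == _norm(fb),
            )
        )
    n = len(records)
    shared = sum(r.bound_in_b for r in records)
    per_feature: dict[str, int] = {}
    for r in records:
        if r.conserved_feature:
            key = _norm(r.feature_a) or "unknown"
            per_feature[key] = per_feature.get(key, 0) + 1
    summary: dict[str, float | int] = {
        "n_genes": n,
        "n_shared": shared,
        "shared_fraction": shared / n if n else 0.0,
        "n_conserved_feature": sum(r.conserved_feature for r in records),
        "n_promoter_conserved": per_feature.get("promoter", 0),
        "dropped_pairs": dropped,
    }
    return records, summary


def conservation_table(records: list[ConservationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "ortholog": r.ortholog,
                "bound_in_a": r.bound_in_a,
                "bound_in_b": r.bound_in_b,
                "feature_a": r.feature_a,
                "feature_b": r.feature_b,
                "conserved_feature": r.conserved_feature,
            }
            for r in records
        ]
    )
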