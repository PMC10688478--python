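"""Differential-expression filtering and cistrome-transcriptome integration.

Three cascades operate on a per-gene DE summary table (group-average FPKMs,
log2 fold change of knockout vs wild type, BH FDR):

* DEG filter: FDR < 0.05, |log2FC| > 0.4, FPKM > 1 in at least one group.
* Essentiality filter: transcripts near absent in the knockout (FPKM < 2)
  but expressed (>= 2 FPKM and >= 2-fold higher) in wild type, at high
  confidence (FDR < 1e-4) -- genes that appear to require the factor for
  their expression.
* Strong-downregulation + dual-binding filter: log2FC < -0.9, FDR < 0.05,
  and at least one binding site co-bound by the partner factor.

All printed inequalities are strict exactly as typeset; "at least 2-fold"
and "> 1 FPKM" are >= 2 and > 1.  A generic hypergeometric gene-set
enrichment (BH-corrected) stands in for web-service ontology tools.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import FeatureAnnotation, ParameterError

__all__ = [
    "DERecord",
    "DEGConfig",
    "BindingSite",
    "DEGResult",
    "filter_degs",
    "DirectTargetSummary",
    "direct_targets",
    "essential_genes",
    "strong_down_dual_bound",
    "geneset_enrichment",
    "nr5a_mark",
    "parse_mark",
    "read_de_table",
    "read_gmt",
]


@dataclass
class DERecord:
    """Per-gene differential-expression summary (knockout vs wild type)."""

    gene_id: str
    symbol: str
    fpkm_wt: float
    fpkm_ko: float
    log2fc: float
    pvalue: float
    fdr: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.fpkm_wt) and math.isfinite(self.fpkm_ko)):
            raise ParameterError(f"{self.gene_id}: FPKMs must be finite")
        if self.fpkm_wt < 0 or self.fpkm_ko < 0:
            raise ParameterError(f"{self.gene_id}: FPKMs must be >= 0")
        if not (0.0 <= self.fdr <= 1.0):
            raise ParameterError(f"{self.gene_id}: fdr must be in [0, 1]")


@dataclass
class DEGConfig:
    """Thresholds for the three integration cascades (strict as typeset)."""

    fdr_max: float = 0.05
    min_abs_log2fc: float = 0.4
    min_fpkm_any_group: float = 1.0
    essential_ko_max_fpkm: float = 2.0
    essential_min_wt_fpkm: float = 2.0
    essential_min_fold: float = 2.0
    essential_fdr_max: float = 1e-4
    strong_down_log2fc: float = -0.9

    def __post_init__(self) -> None:
        for name in (
            "fdr_max",
            "min_abs_log2fc",
            "min_fpkm_any_group",
            "essential_ko_max_fpkm",
            "essential_min_wt_fpkm",
            "essential_min_fold",
            "essential_fdr_max",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")


@dataclass
class BindingSite:
    """A gene-linked binding site as used by the reporting cascades.

    ``location`` is a gene-relative label ("intron 2", "intergenic",
    "upstream gene", ...); ``tss_kb`` the signed TSS distance in kb (one
    decimal); motif counts are numbers of ERE / NR5A matches in the bound
    sequence; ``dual`` marks co-binding by the partner factor.
    """

    location: str
    tss_kb: float
    ere_count: int = 0
    nr5a_count: int = 0
    dual: bool = False


def nr5a_mark(count: int) -> str:
    """Serialize a motif count to the +/-/x2/x3 table notation."""
    if count <= 0:
        return "-"
    if count == 1:
        return "+"
    return f"×{count}"


def parse_mark(mark: str) -> int:
    """Inverse of :func:`nr5a_mark` (accepts 'x2' as well as '×2')."""
    mark = mark.strip()
    if mark in ("-", ""):
        return 0
    if mark == "+":
        return 1
    if mark[0] in ("×", "x", "X"):
        return int(mark[1:])
    raise ParameterError(f"cannot parse motif mark {mark!r}")


@dataclass
class DEGResult:
    """Outcome of the DEG filter, partitioned by regulation direction."""

    up: list[DERecord]
    down: list[DERecord]
    excluded_records: int = 0

    @property
    def degs(self) -> list[DERecord]:
        return self.up + self.down

    @property
    def gene_ids(self) -> set[str]:
        return {r.gene_id for r in self.degs}


def filter_degs(table: list[DERecord], cfg: DEGConfig | None = None) -> DEGResult:
    """Keep genes with fdr < 0.05, |log2fc| > 0.4, max group FPKM > 1."""
    cfg = cfg or DEGConfig()
    up, down, bad = [], [], 0
    for rec in table:
        try:
            keep = (
                rec.fdr < cfg.fdr_max
                and abs(rec.log2fc) > cfg.min_abs_log2fc
                and max(rec.fpkm_wt, rec.fpkm_ko) > cfg.min_fpkm_any_group
            )
        except TypeError:
            bad += 1
            continue
        if keep:
            (up if rec.log2fc > 0 else down).append(rec)
    if bad:
        warnings.warn(f"{bad} DE records with missing fields excluded", stacklevel=2)
    return DEGResult(up, down, bad)


@dataclass
class DirectTargetSummary:
    """Intersection of the DEG set with the bound-gene set, with breakdown."""

    targets: set[str]
    n_targets: int
    fraction_of_degs: float
    n_up: int
    n_down: int
    ere_fraction: float | None = None
    promoter_bound: set[str] = field(default_factory=set)
    intron_breakdown: dict[int, int] = field(default_factory=dict)


def direct_targets(
    degs: DEGResult,
    bound: set[str],
    site_annotations: dict[str, list[tuple[FeatureAnnotation, bool]]] | None = None,
) -> DirectTargetSummary:
    """Genes both differentially expressed and bound (nearest-TSS).

    ``site_annotations`` optionally maps each bound gene to its sites as
    (feature annotation, has_ERE) pairs, enabling the ERE fraction,
    promoter-bound subset and intron breakdown of the summary.
    """
    deg_ids = degs.gene_ids
    if deg_ids and bound and not (deg_ids & bound):
        warnings.warn(
            "DEG and bound gene sets are disjoint: check identifier spaces",
            stacklevel=2,
        )
    targets = deg_ids & bound
    n_up = sum(1 for r in degs.up if r.gene_id in targets)
    n_down = sum(1 for r in degs.down if r.gene_id in targets)
    ere_fraction = None
    promoter_bound: set[str] = set()
    intron_breakdown: dict[int, int] = {}
    if site_annotations is not None:
        sites = [
            (ann, has_ere)
            for gene in sorted(targets)
            for ann, has_ere in site_annotations.get(gene, [])
        ]
        if sites:
            ere_fraction = sum(has_ere for _, has_ere in sites) / len(sites)
        for gene in sorted(targets):
            for ann, _ in site_annotations.get(gene, []):
                if ann.category == "promoter":
                    promoter_bound.add(gene)
                elif ann.category == "intron" and ann.intron_index is not None:
                    intron_breakdown[ann.intron_index] = (
                        intron_breakdown.get(ann.intron_index, 0) + 1
                    )
    return DirectTargetSummary(
        targets=targets,
        n_targets=len(targets),
        fraction_of_degs=len(targets) / len(deg_ids) if deg_ids else 0.0,
        n_up=n_up,
        n_down=n_down,
        ere_fraction=ere_fraction,
        promoter_bound=promoter_bound,
        intron_breakdown=dict(sorted(intron_breakdown.items())),
    )


def essential_genes(
    table: list[DERecord],
    sites_by_gene: dict[str, str] | None = None,
    cfg: DEGConfig | None = None,
) -> pd.DataFrame:
    """Genes whose expression appears to depend on the factor.

    Kept iff fpkm_ko < 2, fpkm_wt >= 2, fpkm_wt >= 2 x fpkm_ko and
    fdr < 1e-4 (a zero knockout FPKM reduces the fold condition to the
    wild-type floor).  The output joins each gene with its binding-site
    label ("-" when unbound), sorted by log2fc ascending.
    """
    cfg = cfg or DEGConfig()
    sites_by_gene = sites_by_gene or {}
    rows = []
    for rec in table:
        fold_ok = rec.fpkm_wt >= cfg.essential_min_fold * rec.fpkm_ko
        if (
            rec.fpkm_ko < cfg.essential_ko_max_fpkm
            and rec.fpkm_wt >= cfg.essential_min_wt_fpkm
            and fold_ok
            and rec.fdr < cfg.essential_fdr_max
        ):
            rows.append(
                {
                    "gene": rec.symbol,
                    "gene_id": rec.gene_id,
                    "log2fc": rec.log2fc,
                    "fpkm_ko": rec.fpkm_ko,
                    "fpkm_wt": rec.fpkm_wt,
                    "binding_site": sites_by_gene.get(rec.gene_id)
                    or sites_by_gene.get(rec.symbol)
                    or "-",
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["gene", "gene_id", "log2fc", "fpkm_ko", "fpkm_wt", "binding_site"],
    )
    return df.sort_values(["log2fc", "gene"], kind="stable").reset_index(drop=True)


def strong_down_dual_bound(
    table: list[DERecord],
    sites_by_gene: dict[str, list[BindingSite]],
    cfg: DEGConfig | None = None,
) -> pd.DataFrame:
    """Strongly downregulated genes with at least one dual-bound site.

    Kept iff log2fc < -0.9 (strict), fdr < 0.05 and the gene carries >= 1
    site co-bound by the partner factor.  One output row per site of each
    kept gene, with gene-relative location, TSS distance (kb, one decimal)
    and ERE / NR5A marks in the +/-/x2/x3 notation.
    """
    cfg = cfg or DEGConfig()
    rows = []
    for rec in sorted(table, key=lambda r: (r.log2fc, r.symbol)):
        sites = sites_by_gene.get(rec.gene_id) or sites_by_gene.get(rec.symbol) or []
        if not (
            rec.log2fc < cfg.strong_down_log2fc
            and rec.fdr < cfg.fdr_max
            and any(s.dual for s in sites)
        ):
            continue
        dual_sites = [s for s in sites if s.dual]
        for i, site in enumerate(dual_sites, 1):
            rows.append(
                {
                    "gene": rec.symbol,
                    "gene_id": rec.gene_id,
                    "log2fc": rec.log2fc,
                    "site_index": i if len(dual_sites) > 1 else 0,
                    "location": site.location,
                    "tss_kb": round(site.tss_kb, 1),
                    "ERE": nr5a_mark(site.ere_count),
                    "NR5A": nr5a_mark(site.nr5a_count),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "gene_id",
            "log2fc",
            "site_index",
            "location",
            "tss_kb",
            "ERE",
            "NR5A",
        ],
    )


def geneset_enrichment(
    query: set[str],
    universe: set[str],
    collections: dict[str, set[str]],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    ``p`` is the upper tail P(X >= overlap) with the term intersected with
    the universe; q-values are BH across terms.
    """
    if not universe:
        raise ParameterError("empty universe")
    if not query <= universe:
        raise ParameterError("query must be a subset of the universe")
    M, n = len(universe), len(query)
    rows = []
    for term in sorted(collections):
        members = collections[term] & universe
        overlap = members & query
        k = len(overlap)
        p = stats.hypergeom.sf(k - 1, M, len(members), n) if k > 0 else 1.0
        rows.append(
            {
                "term": term,
                "term_size": len(members),
                "overlap": k,
                "pvalue": min(1.0, float(p)),
                "genes": ",".join(sorted(overlap)),
            }
        )
    df = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "pvalue", "genes"])
    if len(df):
        df["qvalue"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    else:
        df["qvalue"] = []
    return df


DE_COLUMNS = ["gene_id", "symbol", "fpkm_wt", "fpkm_ko", "log2fc", "pvalue", "fdr"]


def read_de_table(path) -> list[DERecord]:
    """Read a TSV DE table with the required header columns."""
    df = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise ParameterError(f"{path}: missing DE columns {sorted(missing)}")
    records, bad = [], 0
    for _, row in df.iterrows():
        if row[DE_COLUMNS].isna().any():
            bad += 1
            continue
        records.append(
            DERecord(
                gene_id=str(row["gene_id"]),
                symbol=str(row["symbol"]),
                fpkm_wt=float(row["fpkm_wt"]),
                fpkm_ko=float(row["fpkm_ko"]),
                log2fc=float(row["log2fc"]),
                pvalue=float(row["pvalue"]),
                fdr=float(row["fdr"]),
            )
        )
    if bad:
        warnings.warn(f"{path}: {bad} records with missing fields dropped", stacklevel=2)
    return records


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection (term TAB description TAB genes...)."""
    from .core import ParseError

    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 GMT columns")
            out[parts[0]] = {g for g in parts[2:] if g}
    return out
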