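"""Windowed-Poisson ChIP peak calling against input, and cross-replicate
consensus construction.

The caller slides a fixed window along each chromosome, tests the ChIP read
count in each window against a library-size-scaled input expectation with an
upper-tail Poisson test, applies Benjamini-Hochberg correction across all
windows, and keeps windows that clear both the q-value cutoff and a minimum
fold enrichment.  Retained windows are merged into peaks.  This is a
deliberate simplification of production callers: scaling is a plain library
ratio (no local-lambda background), and there is no duplicate filtering or
fragment-length model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GenomicInterval, ParameterError, Peak, merge_within

__all__ = ["CoverageTrack", "CallerConfig", "call_peaks", "consensus_peaks"]


@dataclass
class CoverageTrack:
    """Read 5'-positions per chromosome, plus chromosome lengths."""

    positions: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            if chrom not in self.chrom_lengths:
                raise ParameterError(f"no length for chromosome {chrom!r}")
            n = self.chrom_lengths[chrom]
            if pos.size and (pos.min() < 0 or pos.max() >= n):
                raise ParameterError(f"read positions outside {chrom} bounds")
            self.positions[chrom] = np.sort(pos)

    @property
    def library_size(self) -> int:
        return int(sum(p.size for p in self.positions.values()))

    @classmethod
    def from_bed(cls, path, chrom_lengths: dict[str, int]) -> "CoverageTrack":
        """Build from a BED of read intervals (5' end = start)."""
        from .core import read_bed

        pos: dict[str, list[int]] = {}
        for iv in read_bed(path):
            pos.setdefault(iv.chrom, []).append(iv.start)
        return cls(
            {c: np.array(v, dtype=np.int64) for c, v in pos.items()},
            dict(chrom_lengths),
        )


@dataclass
class CallerConfig:
    """Peak-caller thresholds.

    The q-value cutoff (0.001) and minimum fold enrichment over input (4x)
    are the two published gates; window/step default to the 200-nt peak-size
    vocabulary of the assay.
    """

    window: int = 200
    step: int = 50
    fdr_cutoff: float = 0.001
    min_fold: float = 4.0
    pseudocount: float = 0.5
    merge_gap: int = 200

    def __post_init__(self) -> None:
        if not (self.window >= self.step > 0):
            raise ParameterError("require window >= step > 0")
        if not (0.0 < self.fdr_cutoff < 1.0):
            raise ParameterError("fdr_cutoff must be in (0, 1)")
        if self.min_fold <= 0:
            raise ParameterError("min_fold must be > 0")
        if self.pseudocount <= 0:
            raise ParameterError("pseudocount must be > 0")
        if self.merge_gap < 0:
            raise ParameterError("merge_gap must be >= 0")


def _window_counts(pos: np.ndarray, starts: np.ndarray, window: int) -> np.ndarray:
    return np.searchsorted(pos, starts + window, side="left") - np.searchsorted(
        pos, starts, side="left"
    )


def call_peaks(
    chip: CoverageTrack, input_: CoverageTrack, cfg: CallerConfig | None = None
) -> list[Peak]:
    """Call enriched peaks from a ChIP track against an input track.

    For each sliding window, ``k`` = ChIP reads and ``lam`` is the largest
    of the pseudocount, the library-ratio-scaled input count, and the
    genome-wide expected ChIP count per window (the background floor keeps
    stochastic input dropout from producing spurious calls, as in
    local-background callers); p = P(Poisson(lam) >= k); windows are BH-
    corrected together, gated on q < fdr_cutoff AND k/lam > min_fold, then
    merged (edge gap <= merge_gap) into peaks.  The summit is the per-bp
    ChIP coverage maximum inside the peak; fold/fdr of a merged peak are the
    best (max fold, min q) of its constituent windows.
    """
    cfg = cfg or CallerConfig()
    if input_.library_size == 0:
        raise ParameterError("input track has zero library size")
    if chip.library_size == 0:
        warnings.warn("empty ChIP track: no peaks called", stacklevel=2)
        return []
    ratio = chip.library_size / input_.library_size
    genome_size = sum(chip.chrom_lengths.values())
    background = chip.library_size * cfg.window / genome_size

    chroms = sorted(chip.positions)
    all_k: list[np.ndarray] = []
    all_lam: list[np.ndarray] = []
    all_starts: list[np.ndarray] = []
    for chrom in chroms:
        n = chip.chrom_lengths[chrom]
        if n < cfg.window:
            starts = np.array([0], dtype=np.int64)
        else:
            starts = np.arange(0, n - cfg.window + 1, cfg.step, dtype=np.int64)
        k = _window_counts(chip.positions[chrom], starts, cfg.window)
        in_pos = input_.positions.get(chrom, np.empty(0, dtype=np.int64))
        lam = np.maximum(
            max(cfg.pseudocount, background),
            _window_counts(in_pos, starts, cfg.window) * ratio,
        )
        all_k.append(k)
        all_lam.append(lam)
        all_starts.append(starts)

    k = np.concatenate(all_k)
    lam = np.concatenate(all_lam)
    # upper tail P(X >= k) = sf(k - 1)
    pvals = stats.poisson.sf(k - 1, lam)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    fold = k / lam
    keep = (qvals < cfg.fdr_cutoff) & (fold > cfg.min_fold)

    peaks: list[Peak] = []
    offset = 0
    for chrom, starts in zip(chroms, all_starts):
        sel = keep[offset : offset + starts.size]
        if sel.any():
            win_ivs = [
                GenomicInterval(chrom, int(s), int(s) + cfg.window)
                for s in starts[sel]
            ]
            merged = merge_within(win_ivs, cfg.merge_gap)
            ws = starts[sel]
            wq = qvals[offset : offset + starts.size][sel]
            wf = fold[offset : offset + starts.size][sel]
            pos = chip.positions[chrom]
            for iv in merged:
                inside = (ws >= iv.start) & (ws + cfg.window <= iv.end)
                reads = pos[np.searchsorted(pos, iv.start) : np.searchsorted(pos, iv.end)]
                if reads.size:
                    per_bp = np.bincount(reads - iv.start, minlength=len(iv))
                    summit = iv.start + int(per_bp.argmax())
                    score = float(reads.size)
                else:  # pragma: no cover - retained window implies reads
                    summit, score = iv.center, 0.0
                peaks.append(
                    Peak(
                        interval=iv,
                        summit=summit,
                        score=score,
                        fold_enrichment=float(wf[inside].max()),
                        fdr=float(wq[inside].min()),
                        replicate_support=0,
                    )
                )
        offset += starts.size
    return peaks


def consensus_peaks(
    replicates: list[list[Peak]], min_support: int = 2, merge_gap: int = 200
) -> list[Peak]:
    """Cross-replicate consensus by single-linkage center clustering.

    Pooled peaks link when their centers are within ``merge_gap``; a cluster
    is kept when it draws on at least ``min_support`` distinct replicates.
    The consensus interval is the union of member intervals; its summit is
    the member summit closest to the consensus center, and score/fold/fdr
    are the best of the members.
    """
    if not replicates:
        raise ParameterError("need at least one replicate")
    if min_support > len(replicates):
        warnings.warn(
            f"min_support={min_support} exceeds replicate count "
            f"{len(replicates)}: empty consensus",
            stacklevel=2,
        )
        return []

    tagged = [
        (p.interval.chrom, p.interval.center, rep_i, p)
        for rep_i, peaks in enumerate(replicates)
        for p in peaks
    ]
    tagged.sort(key=lambda t: (t[0], t[1]))
    out: list[Peak] = []
    cluster: list[tuple[int, Peak]] = []

    def flush() -> None:
        if not cluster:
            return
        support = len({rep for rep, _ in cluster})
        if support >= min_support:
            members = [p for _, p in cluster]
            start = min(p.interval.start for p in members)
            end = max(p.interval.end for p in members)
            iv = GenomicInterval(members[0].interval.chrom, start, end)
            summit = min(
                (p.summit for p in members), key=lambda s: (abs(s - iv.center), s)
            )
            out.append(
                Peak(
                    interval=iv,
                    summit=summit,
                    score=max(p.score for p in members),
                    fold_enrichment=max(p.fold_enrichment for p in members),
                    fdr=min(p.fdr for p in members),
                    replicate_support=support,
                )
            )

    prev_chrom, prev_center = None, None
    for chrom, center, rep_i, peak in tagged:
        if (
            prev_chrom != chrom
            or prev_center is None
            or center - prev_center > merge_gap
        ):
            flush()
            cluster = []
        cluster.append((rep_i, peak))
        prev_chrom, prev_center = chrom, center
    flush()
    return out
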