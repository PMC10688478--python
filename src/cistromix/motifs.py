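"""IUPAC consensus motif scanning and motif-level analytics.

Scanning is exact full-consensus IUPAC matching (optionally allowing a fixed
number of mismatches), on both strands, reporting minus-strand hits in
plus-strand coordinates.  Built-in motifs are the estrogen response element
(ERE), the NR5A nuclear-receptor element bound by SF-1/LRH-1, and the GATA
pioneer-factor element.

A structural caveat drives one analytic here: the reverse complement of the
ERE half-site GGTCA (TGACC) sits inside the NR5A consensus, so an NR5A match
can be extended into an ERE match by flanking bases.  ``flag_overlapping_pairs``
marks peaks where ERE and NR5A matches overlap or fall within a small gap so
co-occurrence statistics can be recomputed without such artifacts.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np

from .core import DomainError, ParameterError, Peak

__all__ = [
    "IUPAC_CLASSES",
    "IupacMotif",
    "MotifHit",
    "BUILTIN_MOTIFS",
    "reverse_complement",
    "iupac_match",
    "scan_sequence",
    "presence_table",
    "cooccurrence_venn",
    "pair_distances",
    "flag_overlapping_pairs",
    "density_profile",
    "read_motifs",
]

IUPAC_CLASSES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly degenerate IUPAC) DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IupacMotif:
    """A named IUPAC consensus of length >= 4."""

    name: str
    consensus: str

    def __post_init__(self) -> None:
        if len(self.consensus) < 4:
            raise ParameterError(f"motif {self.name!r}: consensus too short")
        bad = set(self.consensus.upper()) - set(IUPAC_CLASSES)
        if bad:
            raise ParameterError(
                f"motif {self.name!r}: invalid IUPAC letters {sorted(bad)}"
            )
        object.__setattr__(self, "consensus", self.consensus.upper())

    def __len__(self) -> int:
        return len(self.consensus)


BUILTIN_MOTIFS = (
    IupacMotif("ERE", "GGTCASNBTGAC"),
    IupacMotif("NR5A", "CYDTGACCTTGA"),
    IupacMotif("GATA", "BNWGATAA"),
)


def iupac_match(consensus: str, seq: str, max_mismatches: int = 0) -> bool:
    """True iff ``seq`` satisfies ``consensus`` position by position.

    A sequence base matches when it lies in the IUPAC class of the consensus
    letter; an ``N`` in the sequence matches only an ``N`` consensus letter.
    ``max_mismatches`` positions may violate this (default 0 = exact).
    """
    consensus = consensus.upper()
    seq = seq.upper()
    if len(consensus) != len(seq):
        raise ParameterError(
            f"length mismatch: consensus {len(consensus)} vs seq {len(seq)}"
        )
    mismatches = 0
    for c, s in zip(consensus, seq):
        if c not in IUPAC_CLASSES:
            raise ParameterError(f"invalid IUPAC letter {c!r} in consensus")
        if s in IUPAC_CLASSES[c] or (c == "N" and s == "N"):
            continue
        mismatches += 1
        if mismatches > max_mismatches:
            return False
    return True


@dataclass(frozen=True)
class MotifHit:
    """A strand-aware motif match; ``start`` is in plus-strand coordinates
    and ``matched_seq`` is the plus-strand window (its reverse complement
    satisfies the consensus for minus-strand hits)."""

    motif: str
    start: int
    strand: str
    matched_seq: str

    @property
    def end(self) -> int:
        return self.start + len(self.matched_seq)

    @property
    def midpoint(self) -> int:
        return self.start + len(self.matched_seq) // 2


def _class_pattern(consensus: str) -> str:
    parts = []
    for c in consensus:
        cls = IUPAC_CLASSES[c]
        parts.append(f"[{cls}N]" if c == "N" else f"[{cls}]")
    return "".join(parts)


def scan_sequence(
    seq: str,
    motifs=BUILTIN_MOTIFS,
    offset: int = 0,
    max_mismatches: int = 0,
) -> list[MotifHit]:
    """All hits of ``motifs`` in ``seq`` on both strands, sorted by start.

    Minus-strand hits are windows whose reverse complement satisfies the
    consensus, reported at their plus-strand position.  ``offset`` shifts
    reported starts into genomic coordinates.
    """
    seq = seq.upper()
    hits: list[MotifHit] = []
    for motif in motifs:
        m = len(motif)
        if m > len(seq):
            continue
        if max_mismatches == 0:
            for strand, cons in (("+", motif.consensus), ("-", reverse_complement(motif.consensus))):
                pat = re.compile(f"(?=({_class_pattern(cons)}))")
                for match in pat.finditer(seq):
                    hits.append(
                        MotifHit(motif.name, match.start() + offset, strand, match.group(1))
                    )
        else:
            rc_cons = reverse_complement(motif.consensus)
            for i in range(len(seq) - m + 1):
                window = seq[i : i + m]
                if iupac_match(motif.consensus, window, max_mismatches):
                    hits.append(MotifHit(motif.name, i + offset, "+", window))
                if iupac_match(rc_cons, window, max_mismatches):
                    hits.append(MotifHit(motif.name, i + offset, "-", window))
    hits.sort(key=lambda h: (h.start, h.motif, h.strand))
    return hits


def _peak_hits(
    peak: Peak, genome, motifs, flank: int, max_mismatches: int = 0
) -> list[MotifHit]:
    start = peak.interval.start - flank
    end = peak.interval.end + flank
    seq = genome.fetch(peak.chrom, start, end)
    return scan_sequence(seq, motifs, offset=start, max_mismatches=max_mismatches)


def presence_table(
    peaks: list[Peak],
    genome,
    motifs=BUILTIN_MOTIFS,
    flank: int = 0,
    max_mismatches: int = 0,
) -> tuple[list[dict[str, bool]], dict[str, float | None], int]:
    """Per-peak motif presence booleans plus summary fractions.

    Returns ``(rows, fractions, n_skipped)``: one ``{motif: bool}`` row per
    scannable peak, the fraction of peaks containing each motif (``None``
    when no peak could be scanned), and the number of peaks skipped because
    their scan region fell outside the genome.
    """
    rows: list[dict[str, bool]] = []
    skipped = 0
    for peak in peaks:
        try:
            hits = _peak_hits(peak, genome, motifs, flank, max_mismatches)
        except DomainError as exc:
            warnings.warn(f"skipping unscannable peak: {exc}", stacklevel=2)
            skipped += 1
            continue
        present = {h.motif for h in hits}
        rows.append({m.name: m.name in present for m in motifs})
    if rows:
        fractions = {
            m.name: sum(r[m.name] for r in rows) / len(rows) for m in motifs
        }
    else:
        fractions = {m.name: None for m in motifs}
    return rows, fractions, skipped


def cooccurrence_venn(
    table: list[dict[str, bool]],
    motifs: tuple[str, str, str] = ("ERE", "NR5A", "GATA"),
) -> dict[str, int]:
    """Counts of the 8 presence classes of three motifs over a peak set.

    Keys: ``{a}_only``, ``{b}_only``, ``{c}_only``, ``{a}+{b}``, ``{a}+{c}``,
    ``{b}+{c}``, ``triple``, ``none``; values partition ``len(table)``.
    """
    a, b, c = motifs
    keys = [
        f"{a}_only", f"{b}_only", f"{c}_only",
        f"{a}+{b}", f"{a}+{c}", f"{b}+{c}", "triple", "none",
    ]
    counts = dict.fromkeys(keys, 0)
    for row in table:
        pattern = (row[a], row[b], row[c])
        idx = {
            (True, False, False): f"{a}_only",
            (False, True, False): f"{b}_only",
            (False, False, True): f"{c}_only",
            (True, True, False): f"{a}+{b}",
            (True, False, True): f"{a}+{c}",
            (False, True, True): f"{b}+{c}",
            (True, True, True): "triple",
            (False, False, False): "none",
        }[pattern]
        counts[idx] += 1
    return counts


@dataclass
class PairDistanceResult:
    """Signed closest-pair distances (b midpoint - a midpoint) per peak."""

    distances: list[int]  # one per peak containing both motifs
    histogram_distances: list[int]  # truncated to |d| <= window
    fraction_within: float | None  # fraction of all pairs with |d| <= within
    excluded_peaks: int  # peaks lacking one of the motifs


def pair_distances(
    hits_per_peak: list[list[MotifHit]],
    a: str,
    b: str,
    window: int = 200,
    within: int = 100,
) -> PairDistanceResult:
    """Closest-pair signed midpoint distance between two motifs per peak.

    For each peak with at least one hit of both motifs, reports the signed
    distance ``b.midpoint - a.midpoint`` of the closest (a, b) pair.  The
    histogram view truncates to ``|d| <= window``; ``fraction_within`` is
    the share of all reported pairs with ``|d| <= within``.
    """
    distances: list[int] = []
    excluded = 0
    for hits in hits_per_peak:
        a_mid = [h.midpoint for h in hits if h.motif == a]
        b_mid = [h.midpoint for h in hits if h.motif == b]
        if not a_mid or not b_mid:
            excluded += 1
            continue
        best = min(
            (bm - am for am in a_mid for bm in b_mid), key=lambda d: (abs(d), d)
        )
        distances.append(best)
    hist = [d for d in distances if abs(d) <= window]
    frac = (
        sum(abs(d) <= within for d in distances) / len(distances)
        if distances
        else None
    )
    return PairDistanceResult(distances, hist, frac, excluded)


def flag_overlapping_pairs(
    hits_per_peak: list[list[MotifHit]], a: str, b: str, max_gap: int = 10
) -> list[bool]:
    """Per-peak flag: some a-hit and b-hit overlap or lie within ``max_gap``.

    Encodes the half-site artifact guard: an NR5A match that directly or
    nearly abuts an ERE match may be one physical element read twice.
    """
    flags: list[bool] = []
    for hits in hits_per_peak:
        a_iv = [(h.start, h.end) for h in hits if h.motif == a]
        b_iv = [(h.start, h.end) for h in hits if h.motif == b]
        flagged = False
        for s1, e1 in a_iv:
            for s2, e2 in b_iv:
                gap = max(s1, s2) - min(e1, e2)  # negative when overlapping
                if gap <= max_gap:
                    flagged = True
                    break
            if flagged:
                break
        flags.append(flagged)
    return flags


@dataclass
class DensityProfile:
    """Motif-hit density around peak centers, in hits per peak per bp."""

    bin_edges: np.ndarray  # length n_bins + 1, relative to peak center
    counts: np.ndarray  # raw hit counts per bin
    density: np.ndarray  # counts / (n_peaks * bin width)
    n_peaks: int
    clipped_peaks: int


def density_profile(
    peaks: list[Peak],
    motif: IupacMotif,
    genome,
    halfwidth: int = 1500,
    bin_width: int = 50,
) -> DensityProfile:
    """Histogram of motif-hit midpoints relative to peak centers.

    Bins cover ``[-halfwidth, +halfwidth)``; flanks running off chromosome
    ends are clipped (and counted in ``clipped_peaks``).
    """
    if halfwidth <= 0 or bin_width <= 0 or halfwidth % bin_width:
        raise ParameterError("halfwidth must be a positive multiple of bin_width")
    edges = np.arange(-halfwidth, halfwidth + 1, bin_width)
    counts = np.zeros(edges.size - 1, dtype=np.int64)
    clipped = 0
    for peak in peaks:
        center = peak.interval.center
        want_start, want_end = center - halfwidth, center + halfwidth
        seq, got_start = genome.fetch_clipped(peak.chrom, want_start, want_end)
        if got_start != want_start or got_start + len(seq) != want_end:
            clipped += 1
        for hit in scan_sequence(seq, [motif], offset=got_start):
            rel = hit.midpoint - center
            if -halfwidth <= rel < halfwidth:
                counts[(rel + halfwidth) // bin_width] += 1
    n_peaks = len(peaks)
    density = (
        counts / (n_peaks * bin_width) if n_peaks else counts.astype(float)
    )
    return DensityProfile(edges, counts, density, n_peaks, clipped)


def read_motifs(path) -> list[IupacMotif]:
    """Read a two-column (name TAB consensus) motif definition file."""
    from .core import ParseError

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected name<TAB>consensus")
            try:
                out.append(IupacMotif(parts[0], parts[1]))
            except ParameterError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out
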