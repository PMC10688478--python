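# Methods

This note documents the models and procedures implemented in `cistromix`,
the defaults they ship with, the synthetic data they are validated on, and
the design choices made where the design was genuinely open.

## Coordinates and data model

All internal coordinates are 0-based half-open. BED is read as-is; GTF
(1-based inclusive) is converted on read. A gene is reduced to one
canonical transcript — the one with the greatest genomic exonic extent,
ties broken by smallest transcript id — because intron numbering ("intron
1", "intron 2") is only well-defined relative to a single transcript.
Introns are the gaps between consecutive exons, numbered 1..n in the
direction of transcription. 5'/3'UTR categories exist only when the GTF
carries CDS records; otherwise exonic summits are labeled `exon`.

## Peak calling

The caller is a deliberately simple windowed-Poisson test, not a
reimplementation of a production caller. Sliding windows (200 bp, step
50 bp — matching the ~200-nt peak-size scale of the assay) are tested
with an upper-tail Poisson p-value for the ChIP count against

```
lambda = max(pseudocount, background, input_count * N_chip / N_input)
background = N_chip * window / genome_size
```

BH correction runs across all windows of all chromosomes jointly; windows
pass only with q < 0.001 **and** fold enrichment k/lambda > 4 (the two
published-style gates). Passing windows are merged (edge gap ≤ 200 bp);
the merged peak's summit is the per-bp coverage maximum (leftmost tie),
and its fold/q are the best of its constituent windows.

*Why the background floor.* With lambda taken only from the scaled input,
windows where the input count stochastically drops to zero receive
lambda = pseudocount and pass both gates even on null data (~0.7% of
windows in a flat Poisson(5) simulation — far above the nominal q < 0.001
control). Flooring lambda at the genome-wide expected ChIP count per
window, as local-background callers do, restores the intended null
behavior: on a seeded 10,000-window null simulation the retained fraction
is ≤ the FDR cutoff and typically exactly zero. Simplifications stated:
plain library-ratio scaling, no local (peak-proximal) lambda, no duplicate
filtering, no fragment-length model, no IDR.

Consensus across biological replicates clusters pooled peaks by single
linkage on peak centers (link if centers within 200 bp) and keeps clusters
supported by ≥ 2 distinct replicates. Center-linkage mirrors the 200-nt
co-binding rule; the within-replicate merge uses edge gaps. With detection
probability p per replicate, expected recall of a true site is
P(Binom(3, p) ≥ 2) — 0.972 at p = 0.9 — which the test suite verifies to
±0.03 over 20 seeded draws.

## Motif scanning

Scanning is exact IUPAC-consensus matching (an optional max-mismatch
integer is available but defaults to 0): deterministic and auditable, with
no position-weight scoring and no background-model enrichment p-values.
An `N` in the sequence matches only an `N` consensus letter. Minus-strand
hits are windows whose reverse complement satisfies the consensus,
reported at plus-strand coordinates. The scanner is regex-based for speed
and is checked against a per-position brute-force oracle in the tests.

Distances between motifs are midpoint differences, with the midpoint at
start + floor(length/2); the distance anchor is otherwise arbitrary and
this choice is pinned by unit tests. Presence calls scan the peak interval
itself (flank 0); density profiles scan ±1500 bp around peak centers in
50-bp bins, normalized to hits per peak per bp.

The ERE/NR5A half-site artifact: the reverse complement of the ERE
half-site GGTCA (TGACC) occurs inside the NR5A consensus, so flanking
bases can extend an NR5A match into a full ERE match. Peaks where an ERE
and an NR5A hit overlap or sit within 10 bp are flagged, and co-occurrence
statistics can be recomputed with flagged peaks excluded; a regression
test encodes the construction `GGTCA + CCTTGACCTTGA`.

## Annotation

Classification is by summit position (a point rule gives the single-label
output a genomic-distribution figure needs) with precedence
promoter > 5'UTR > exon > 3'UTR > TTS > intron > intergenic — the
convention of summit-based annotators. The promoter is −1 kb…+100 bp of
the TSS in transcription direction; the TTS flank is ±1 kb. The bound-gene
window is −50 kb…+2 kb of the TSS (inclusive), *and* the gene must be the
peak's nearest-TSS gene, so one peak never marks several genes bound.
Nearest-TSS ties break to the lexicographically smaller symbol.

Gene-relative labels for reporting tables: a summit inside a feature of
the reported gene keeps that feature label; a summit inside a *different*
gene's span within 300 kb of the reported gene is labeled "upstream gene"
or "downstream gene" by its transcription-direction side; anything else is
"intergenic". The 300 kb cutoff is configurable and was chosen to cover
the largest distances such tables print (~260 kb).

Feature-distribution enrichment compares observed summit counts to the
genomic base-pair fraction of each category (computed with the same
precedence, via an explicit per-bp label array — appropriate for the
megabase-scale genomes this package simulates and analyzes), using a
two-sided exact binomial test, BH-corrected across categories.

## Expression integration

Inequalities are strict exactly as typeset: FDR < 0.05, |log2FC| > 0.4,
FPKM > 1 in at least one group for DEGs; KO FPKM < 2, WT FPKM ≥ 2,
WT ≥ 2 × KO (so a zero KO reduces to the WT floor), FDR < 10⁻⁴ for the
dependency cascade; log2FC < −0.9 for the strong-downregulation cascade.
Boundary semantics are pinned by unit tests. The DE model itself
(negative-binomial GLM fitting) is out of scope: tables arrive precomputed
or from the simulator. NR5A/ERE multiplicity is carried as an integer and
serialized to the +/−/×2/×3 notation.

The packaged fixture tables encode the per-gene printed values of the two
reporting cascades (14 dependency rows; 28 genes / 32 site rows). They
print no per-gene FDR, so the fixtures carry synthetic placeholder `fdr`
columns (10⁻⁵ and 0.01) consistent with the significance bounds their
legends state; the loader docstring says so.

Gene-set enrichment is a hypergeometric upper tail on the overlap of a
query with each term (intersected with the universe), BH across terms — a
generic stand-in for web-service ontology tools.

## Dual-cistrome comparison

"Co-bound within the ~200-nt peak size" is operationalized as peak-center
distance ≤ 200 bp: merged peak widths vary, centers give a reproducible
rule. Pairing is greedy one-to-one by increasing center distance (ties to
the leftmost partner peak) to prevent double counting where peaks cluster;
this makes shared counts symmetric between the two directions. Co-bound
sites are partitioned into ERE-only / NR5A-only / both / neither from the
first factor's peak sequence, with a second partition excluding
artifact-flagged sites (only the "both" class can shrink).

Conservation compares bound genes across species by case-insensitive
symbol identity (or an explicit one-to-one ortholog map; many-to-many
pairs are dropped and counted). Feature conservation is category-level —
any intron matches any intron, following the biological claim being
tested — with an optional strict mode requiring equal intron numbers.

## Synthetic data

The generator emulates the study design end to end, and its defaults *are*
the study conditions:

| parameter | default | meaning |
|---|---|---|
| genome | 3 × 1.5 Mb, uniform ACGT | small but large enough for ≥3 kb site separation |
| genes | 240, 3–5 exons, both strands | non-overlapping, 2–4 kb introns |
| true sites | 200, ≥3 kb apart | 100 gene-linked (36% in intron 1, rest ≤40 kb upstream), 100 deep intergenic |
| motif class mix | ERE-only .246, NR5A-only .153, GATA-only .064, ERE+NR5A .224, ERE+GATA .138, NR5A+GATA .010, triple .007, none .158 | matches the printed co-occurrence Venn; the 82 sites the Venn leaves unassigned are split 50/32 between NR5A+GATA and triple (a choice made once) |
| replicates | 3, detection 0.9, 30 noise peaks each | noise at motif-free positions ≥1 kb from sites |
| ERE–NR5A pair offset | +60 bp | planted midpoint spacing |
| dual-bound fraction | 0.36 | partner peak within ±50 bp of the site |
| DE table | 120 DEGs of 240 genes, 49% up, log2FC ≥ 0.55, NB dispersion 0.05, 5 vs 4 replicates | 30% of DEGs drawn from bound genes |
| dependency genes | ≥10 forced (KO 0.1–1 FPKM, WT 5–40) | truth = all genes whose planted means satisfy the cascade |
| open chromatin / conservation | 0.69 / 0.38 of bound genes | sampled independently of detection |

Motif instances are concrete draws from the degenerate consensus written
into the sequence; every scanned window (true-site and noise-peak regions
±160 bp) is then scrubbed of *incidental* matches by point mutations that
spare planted spans, so presence calls reflect the planted classes
exactly. Flanking DNA outside scan windows is left untouched (its chance
motif content matches the analytic IUPAC-degeneracy rate, which a test
verifies). Synthetic p-values come from a deliberately simple two-group
normal-approximation z-test on log2 counts, not an NB GLM: ground-truth
labels, not p-value calibration, drive validation. At dispersion 0 the
pipeline recovers planted DEGs and dependency genes exactly; recall
degrades monotonically with dispersion (tested).

What the generator does **not** emulate: mappability and GC structure,
duplicate reads and fragment-length effects, correlated replicate noise,
shrunken fold-change estimates, alternative TSS isoforms, and real
ortholog structure. Passing recovery tests therefore demonstrates the
correctness of the integration logic under controlled conditions, not
performance on real libraries.

Determinism: one `numpy.random.Generator` stream seeded from `SimConfig.
seed` drives every draw; outputs are byte-identical across runs, and the
end-to-end report is byte-identical given the same seed and config (timing
goes to the log, not the report).

## Problem sizes and validation

The shipped validation uses 200 sites × 3 replicates, a 4.5 Mb genome and
240 genes — large enough that every recovered headline fraction is tested
against the binomial 99% CI of its planted value, and small enough that
the full suite runs in seconds. Replicate-consensus recall is compared to
the closed-form binomial expectation over 20 seeds; the peak caller is
validated on a 10,000-window null and on fold-10 planted enrichment
(≥95% recall, against a 5×-depth input so lambda is estimated stably).

## Known limitations

* The caller's ratio scaling has no local lambda; broad enriched domains
  would inflate the background floor.
* Exact-match scanning gives no partial/degenerate-hit credit, so motif
  fractions are not comparable to scanners that count half or putative
  motifs; with `max_mismatches > 0` the scanner falls back to a slower
  per-position path.
* Genomic expected fractions use per-bp arrays; for gigabase genomes an
  interval-arithmetic implementation would be preferable.
* `essential`-cascade output on noisy data is threshold-sensitive near the
  KO < 2 FPKM boundary; the cascade is a filter, not a test with
  controlled error rates.
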