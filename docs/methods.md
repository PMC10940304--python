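# Methods

This note documents the models, conventions, and numerical choices behind
`zfscan`, and what the synthetic-data tests do and do not demonstrate.

## Domain detection and typing

The scanner matches the metal-coordinating skeleton
`C-X(2,4)-C-X(12)-H[-X(3,5)-H]` by a left-to-right greedy walk: the
leftmost first cysteine wins, the smallest Cys–Cys gap is tried first, and
scanning resumes after the accepted finger's last coordinating residue, so
accepted fingers never overlap. The classic F/L anchor positions of the
textbook C2H2 pattern are *not* required: degraded (M-type) fingers
routinely lose them, and requiring them would discard exactly the fingers
the classification is about.

The QALGGH window is the minimum-Hamming 6-mer within the 13 residues
ending at (and including) the first histidine, leftmost on ties. This
treats the QALGGH histidine as the first skeleton histidine, consistent
with the Q-type template `X2-C-X2-C-X7-QALGGH-X3-H`, and tolerates the
spacing variation of M-type fingers without enumerating it. Degradation is
the Hamming distance to `QALGGH` (0–6). Typing: Q ⇔ degradation 0 with the
second His present; Mk ⇔ degradation k ∈ 1–5 with the second His present;
D ⇔ second His absent (searched 3–5 residues after the first His). A
skeleton match whose best window is degraded at all six positions is
outside the Q/M/D scheme; it is rejected and logged rather than typed
(Z-type subtyping, which depends on unspecified Cys–His spacing ranges, is
out of scope).

Domain coordinates are 0-based half-open in memory, spanning first Cys to
last coordinating residue; output tables print 1-based inclusive
coordinates, the bioinformatics-table convention.

## Architecture classification and naming

Linkers are counted strictly between the last coordinating residue of one
finger and the first Cys of the next; *tandem* means linker ≤ 11 residues.
Proteins with ≥ 3 fingers and ≥ 1 tandem pair are `t1` (3 fingers) or `t2`
(≥ 4); otherwise the count alone fixes `1i`/`2i`/`3i`/`4i`/…  The type
suffix is `Q`, `M`, or `D` when all fingers share a category and `Mx`
otherwise. Two specific conventions:

* a two-finger protein with tandem spacing stays `2i-*` (no tandem
  two-finger class exists in the scheme); such genes are reported via a
  warning so users can inspect them;
* an all-D protein gets suffix `D` (e.g. `1i-D`), the natural extension of
  the scheme to a case the original subgroup lists never name.

Systematic names are `<prefix>.<subgroup>.<NN>` with ordinals assigned by
(chromosome, start) within each subgroup; the prefix defaults to `C2H2`
and is configurable per species. The family summary table is data-driven —
the number of subgroups is whatever the data contain.

## Physicochemistry

All five quantities follow the ProtParam conventions: average (not
monoisotopic) residue masses plus one water; pI by ~200-step bisection on
the Henderson–Hasselbalch net charge with the Bjellqvist pKa set
(side chains D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0;
C-terminus 3.55; N-terminus residue-specific around 7.5), converged to
|charge| < 1e-4; GRAVY as the mean Kyte–Doolittle hydropathy; instability
as (10/L)·Σ DIWV(xᵢ, xᵢ₊₁) with the Guruprasad dipeptide table (unstable
strictly above 40.00); aliphatic index X(A) + 2.9·X(V) + 3.9·(X(I)+X(L))
in mole percent. The DIWV and Kyte–Doolittle tables are the published ones
shipped with Biopython; the arithmetic is implemented here and
cross-checked in tests both against direct table arithmetic and against
Biopython's `ProteinAnalysis`. Unknown residues (`X`) raise by default;
with the documented fallback they contribute the mean residue mass to MW
and are excluded from the GRAVY/aliphatic denominators.

## Phylogeny

Distances are uncorrected p-distances with pairwise gap deletion (family
alignments are gap-rich; complete deletion would discard most columns);
a substitution correction can be plugged in by supplying a different
matrix. Neighbor joining is the Saitou–Nei agglomeration with the
Q-criterion; ties resolve to the first minimum in row-major order, making
the tree deterministic. Negative limb lengths are clamped to zero with the
deficit moved to the sibling limb, preserving the pair's path length. The
result is an unrooted tree (trifurcating root). Bootstrap support
resamples alignment columns with replacement (seeded NumPy generator),
rebuilds the NJ tree per replicate, and scores each internal bipartition
of the full-data tree by the fraction of replicates containing it.

The replicate default is 500; the literature this scheme follows quotes
both 500 and 1000 in different places, so the count is an explicit flag
(`--bootstrap`) rather than a silently resolved constant.

## Ka/Ks and divergence dating

Recently duplicated pairs are mutual nearest neighbours in protein
p-distance — "most similar proteins" is a distance statement, so no tree
topology is consulted. CDS pairs are codon-aligned by back-translating the
protein alignment (gap → `---`), with translation verified codon-by-codon.

Ka/Ks is Nei–Gojobori (1986) counting with Jukes–Cantor correction
d = −¾·ln(1 − 4p/3), undefined (NaN) at p ≥ ¾. Conventions:

* per-position site fractions: each of the three possible point mutations
  is synonymous, nonsynonymous, or — if it creates a stop codon —
  *neither*; a codon's S + N therefore equals 3 minus one third per
  stop-adjacent change;
* observed differences average, with equal weight, over all minimal
  mutational pathways between the two codons, skipping pathways through
  stop codons; if every pathway is blocked (possible only for some 2–3
  difference pairs) all pathways are used as a documented fallback;
* codons containing `N` or a gap are skipped entirely.

Divergence time is T = Ks/(2λ)·10⁻⁶ million years, λ defaulting to
6.5 × 10⁻⁹ synonymous substitutions per site per generation
(configurable). Selection calls: Ka/Ks < 1 purifying, = 1 neutral, > 1
positive, undefined when Ks is 0 or the correction diverges. The number of
pairs analysed is a user choice (`--max-pairs`); no "most recent" cutoff
is baked in.

## Promoter cis-element scanning

Promoters are the 2000 bases upstream of the annotated gene span
(strand-aware; minus-strand promoters are reverse-complemented so all
coordinates are 5′→3′ relative to transcription), truncated with a flag at
contig edges — a gene flush against the edge yields an empty flagged
promoter, not an error. The gene span, not the start codon, anchors the
extraction.

Motifs are IUPAC consensus strings in a user-replaceable three-column TSV
(`motif_id`, `consensus`, `stimulus`). Matching is exact-consensus on both
strands, leftmost-greedy non-overlapping per motif and strand; a
palindromic motif counts once (sense) per locus. Because consensus tables
differ between prediction services and their internal matrices are not
published, absolute counts are a function of the supplied table; the
bundled default covers the classic hormone- and stress-response elements
(ABRE, AuxRR, TGA, CGTCA/TGACG, GARE, P-box, TATC-box, TCA, SARE, DRE,
MBS, LTR, TC-rich repeats) and makes no claim of equivalence to any
external service.

## Expression

Input is an FPKM table and (optionally) a DE table; upstream read
processing is consumed, not reproduced. Filtering removes genes whose
arithmetic, unweighted mean FPKM across all samples is strictly below 1
(a mean of exactly 1 is kept); the filter operates on raw FPKM and the
log₂(FPKM+1) transform is applied afterwards, an order the API enforces.
DE summaries count FDR < 0.05 rows as up (log₂FC > 0) or down (< 0);
significant rows with log₂FC exactly 0 count as neither and are logged.
Stage specificity is computed on raw FPKM as max-group-mean over
total-mean, with the first maximum winning deterministically. Heatmap-style
output orders genes by complete-linkage clustering on correlation distance
of the transformed rows — a conventional choice, stated here because the
ordering is otherwise arbitrary.

## Synthetic data: what it shows and what it does not

The generator plants known structure so recovery can be asserted exactly:

* **Proteome** — fingers are built from the skeleton templates with the
  planned types, spacings, and linkers; filler sequence (termini, linkers,
  X-spacers) is drawn from an alphabet containing no C or H, so a spurious
  skeleton match is impossible, and no Q/A/L/G, so the planted QALGGH
  window is always the unique best window. Default family: 40 genes, 10
  subgroups (6+4 single-finger, 6+4+4 two-finger, 3+4 three-finger
  dispersed, 3 four-finger dispersed, 3 t1, 3 t2).
* **Genome/promoters** — promoter background is drawn from {A, C} only.
  Every motif in the default table has at least one fixed G/T (so the
  sense strand of background cannot match) and at least one fixed A/C (so
  the antisense strand cannot either); the generator additionally verifies
  each built promoter by re-scanning and re-draws placements on any
  junction artefact, so planted counts are exact by construction. Genes
  alternate strand, half are intronless (intron lengths ≥ 31 bp), and one
  gene sits 500 bp from a contig start to exercise promoter truncation.
* **CDS pairs** — the ancestor uses only `xC[TC]` codons
  (Ala/Pro/Ser/Thr families), which have exactly S = 1 and N = 2 NG86
  sites; synonymous mutations toggle the third base T↔C, nonsynonymous
  mutations swap the first base within the families (never through a
  stop), at most one mutation per codon. Substitution counts are drawn
  binomially from the Jukes–Cantor-inverted target proportions, so the
  estimator mean matches the target over seeds while individual pairs vary.
* **Pseudo-MSA** — one random ancestor per subgroup, each member a few
  point mutations away: equal-length, gap-free, with clean clade signal.
* **Expression/DE** — low genes have every value below 1; stage-specific
  genes peak in RS; the DE table plants exactly 6 up- and 8 down-regulated
  significant leaf/drought genes.

These data are deliberately *clean*: no spurious near-matches, no gapped
alignments, no codon-usage or isochore realism, no overdispersed counts.
Passing the recovery tests therefore shows the algorithms implement their
stated rules exactly; it does not show robustness to the ambiguities of
real genomes (fragmented annotations, degenerate fingers at the rejection
boundary, promoter elements overlapping repeats), which is why every
convention above is documented and the thresholds are parameters.

## Problem sizes and numerics

Defaults used by the test-suite and the reproduction script: 40-gene
family; 100-replicate bootstrap in the demo (500 default elsewhere); 50
random additive matrices of 5–8 taxa against a brute-force least-squares
topology oracle (all 15–10,395 unrooted topologies enumerated); 200 random
codon-pair alignments against exhaustive pathway enumeration (tolerance
1e-12); 20 CDS pairs of 300 codons at Ks 0.1/Ka 0.02 (mean within 3·SE);
100 random proteins for the pI grid-search comparison (grid step 0.001,
tolerance 1e-3). The pI bisection runs a fixed 200 iterations (interval
width 14·2⁻²⁰⁰), far past the 1e-4 charge tolerance; NJ tie-breaks,
stage-specificity argmax, and duplicate-pair tie-breaks are all
deterministic first-minimum/lexicographic rules; all stochastic components
take explicit integer seeds, and pipeline outputs embed version, seed, and
parameters in a header comment so reruns are byte-identical.
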