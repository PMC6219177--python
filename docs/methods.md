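# Methods

## Scope and data model

svbench evaluates somatic SV call sets against a known truth set and
characterizes their errors. SVs live in VCF v4.1 coordinates: 1-based
positions with inclusive END (interval arithmetic is half-open internally and
converted at the boundary). The END of a parsed record resolves as INFO/END,
else `POS + len(REF) − 1`, else POS. Supported SV types are DEL, DUP, INS,
INV, CNV, and BND; `SVTYPE=MSK` rows in a truth VCF are not variants but
masked regions defining the held-out testing set. Records whose FILTER is
neither PASS nor "." are dropped during preprocessing ("." is treated as
passing — the common dialect of truth VCFs); records with types outside the
controlled vocabulary are excluded with a warning rather than coerced,
since scoring is type-blind anyway and coercion risks misclassification.

Break-end handling: a MATEID pointing at a missing record synthesizes the
partner from the surviving breakend ALT's adjacency; IDs are re-assigned to
be globally unique; and same-chromosome BND mate pairs whose ALT geometry is
one of the canonical adjacency patterns are rewritten as one typed record
(t[p[ / ]p]t → DEL, ]p]t / t[p[ → DUP, matching t]p] or [p[t orientations →
INV). Only these canonical cases convert — anything else stays BND, where
the ensemble module's BND filter excludes it. Mate chains longer than two
records, and cross-chromosome mates carrying non-BND types, are rejected as
irreparable.

Train/test allocation: an SV is a testing-set SV iff ≥ 50% of its [POS, END]
region overlaps the union of mask regions (union, so overlapping masks are
not double-counted; the rule is therefore invariant to splitting or
reordering masks).

## Scoring

Two similarity schemes:

* **Region overlap** — Jaccard coefficient of the inclusive regions. The
  default qualification threshold is any positive overlap (j > 0). Records
  with a single breakpoint (POS == END, e.g. insertions) are 1-bp regions
  under this scheme, which is a poor fit; the library emits a warning and the
  closeness scheme is the default everywhere.
* **Breakpoint closeness** — `c′ = 1 − Δ/f` per breakpoint for `Δ ≤ f`,
  combined as the geometric mean over the start and end breakpoints.
  Single-breakpoint records are compared on the start breakpoint alone.
  Exactly one breakpoint within `f` ⇒ a *partial match*: excluded from the
  matching and from all TP/FP/FN counts.

The default flank is `f = 100` bp, the stringency at which breakpoint
predictions are close enough for downstream validation while tolerating
alignment-scale imprecision; it is a parameter everywhere it appears.

**Matching.** Qualifying (call, known) pairs form a bipartite graph; the
final assignment is the one-to-one matching that maximizes total similarity,
computed per chromosome by the Hungarian algorithm on the dense similarity
matrix (rows/columns restricted to records with at least one qualifying
edge). Tie preferences — same SVTYPE, then same train/test subset, then
earlier genomic order — are implemented as bonuses of 1e-9/5e-10/1e-13,
i.e. below the 1e-9 tolerance at which two similarities are considered
equal, so they can only select among genuinely co-optimal matchings. A
maximum-weight (rather than best-edge-restricted) matching is used because
restricting each SV to its best partners first can provably forfeit the
optimal assignment; the test suite checks equality with brute-force
enumeration on random small instances.

An unmatched call with at least one qualifying or partial edge is annotated
*partial* (it points at a truth SV that a closer call claimed); likewise an
unmatched known. Remaining unmatched calls are FPs and unmatched knowns are
FNs. Mated breakpoints are annotated separately; an FP whose mate is TP or
partial is upgraded to partial, and each mate pair then counts once, with
the group status being the best of its members (TP > partial > FP/FN).

**Scoped scores.** `precision = nTP/(nTP+nFP)`, `recall = nTP/(nTP+nFN)`,
`F = 2PR/(P+R)`, all defined as 0 when their denominator is 0, partial
matches excluded. Scope filters known-side SVs by subset label. Unmatched
calls carry no subset, so when mask regions are available an FP is
attributed to the test scope by the same ≥ 50% overlap rule used for truth
allocation; without masks FPs count in every scope. This attribution rule is
a design choice — nothing in the scoring semantics ties a spurious call to
either leaderboard scope.

## Ensembles

Calls from the top-k submissions (ordered best-first by overall F after
excluding BND calls) are compared pairwise across submissions only, with the
breakpoint-length distance `d = max(|Δstart|, |Δend|, |ΔL|)` (L = inclusive
length). This max-form combination is a deliberate choice: it incorporates
both breakpoint displacement and predicted-length disagreement, and `d < f`
then implies every component is within `f`, keeping the threshold semantics
of the closeness scheme. It is isolated in one function
(`breakpoint_length_distance`) so an alternative combination rule can be
swapped in.

* *Baseline*: connected components of the `d < f` graph. Components whose
  median pairwise distance exceeds `f` are refined by iteratively removing
  the member with the greatest median distance to the others (ties drop the
  later call in genomic order) until the median falls to `f` or one member
  remains.
* *Conservative*: pairs additionally need ≥ 1 bp region overlap. Pairs are
  processed from least to most distant (ties ordered by genomic position,
  then submission rank); a pair of two unassigned calls seeds a set; a pair
  with one assigned call adds the other iff its submission is not already
  covered and its median distance to the members is ≤ f; pairs between two
  assigned calls are discarded.

Sets covering ≤ k/2 distinct submissions are removed (strict majority), and
each survivor becomes one consensus call at the member-wise median start and
end — the lower median for even counts, preserving integer coordinates. The
library takes an ordered list of call sets; using only each team's best
submission (baseline) versus all submissions (conservative) is the caller's
selection, since team identity is submission metadata, not call-set content.

## Spike-in simulation

The generator emulates the study conditions end to end: a uniform-composition
pseudo-random reference (default GC 0.5), error-free paired reads at uniform
coverage with known placements (read length 100 bp, fragment length
300 ± 30 bp, coverage 30× in the standard configuration), and truth events of
the four simple SV classes at subclonal allele fractions 0.5 / 0.33 / 0.2.
Because reads are error-free and placements known, the local-assembly and
re-alignment stages of read-level spike-in are replaced by slicing the
reference over the plan interval; the contig-quality criteria reduce to
requiring the interval to exceed twice the mean fragment length. Emitted SAM
records are the true placements — no aligner runs anywhere.

A spike-in plan names an assembly interval, an SV type, a VAF, and type
parameters (middle fraction rearranged for DEL/DUP/INV, default 0.5; extra
tandem copies for DUP; the inserted sequence for INS). The contig over the
interval is rearranged (delete the middle span / tandem-duplicate it /
reverse-complement it / insert at the midpoint), and coverage is regenerated
over the rearranged contig at

```
C_f = VAF · C_o · (L_f / L_o),   pairs = round(C_f · L_f / (2 · read_len)).
```

Spiking is a replacement: each original pair whose fragment lies inside the
plan interval is removed with probability VAF, and the new contig-derived
pairs are added. The replacement model makes the depth consequences of each
type emerge from one mechanism — deleted spans drain to `(1 − VAF) · C_o`,
duplicated spans gain the extra copy's coverage, insertions add reads, and
inversions (L_f = L_o) leave depth unchanged — while reads wholly outside
the plan interval are untouched, so depth outside all plan intervals is
bitwise identical before and after. Reads crossing a junction are placed at
the reference location of their majority segment with the remainder
soft-clipped (reads majority-inside an inverted span flip strand; reads
entirely within inserted sequence are emitted unmapped), giving downstream
feature extraction realistic breakpoint signal. VAF is honored in
expectation, not exactly per locus; read counts are rounded to whole pairs,
and the per-spike ledger (input − removed + simulated = output) is exposed
for auditing.

Synthetic submissions derive from a truth set by (i) dropping each truth SV
with probability `fn_rate`, (ii) shifting each breakpoint by rounded
Gaussian jitter (`jitter_sd`, default regimes 10–15 bp, well inside the
100 bp flank), and (iii) placing `fp_count` spurious calls with
truth-resampled lengths uniformly outside the truth regions *plus a 100 bp
margin* — without the margin a nominal FP can fall within the flank of a
single-breakpoint truth insertion and match it, contradicting its label.

What the generator does **not** emulate: sequencing errors, base-quality
structure, coverage bias, repeats or low-complexity tracts, alignment
ambiguity, translocations, or complex rearrangements. Tests passing on this
data therefore validate the benchmarking machinery — scoring, aggregation,
accounting — not the difficulty of calling SVs in real genomes, where
alignment artifacts dominate the error profile.

## Error profiling

A breakpoint may inherit several annotations from the SVs it belongs to;
one label is kept with priority TP > FN > FP (favoring detection, then
recall). True-negative regions are rejection-sampled: lengths log-normal
with the natural-log mean/SD of the truth SV lengths; the start must avoid
the gap/repeat exclusion regions; the region must overlap neither truth nor
called SVs. Sampling aborts with a constraint-density error after
1000 × n_min attempts.

Per-breakpoint variables: *bridging reads* (primary alignments whose aligned
span contains the ±1 bp window — deliberately no split-read/CIGAR
requirement, and secondary/supplementary records are skipped so pairs are
not double-counted); *germline INDEL distance* (nearest INDEL parsed from
the germline VCF, where an INDEL is any allele pair of unequal length);
*nucleotide entropy* (−Σ p_x log₂ p_x over A/C/G/T, case-insensitive,
0·log 0 = 0, on the ±50 bp reference window truncated at contig ends);
*strand bias* (forward-strand proportion of reads overlapping the position;
0.5 when no read does). Further covariates (coverage, mapping quality, …)
are accepted as precomputed pass-through columns, not recomputed.

Univariate association: Pearson correlation between each variable and the
per-breakpoint proportion of teams with an FN/FP there; designated count and
distance variables are log10-transformed first, with zeros mapped to −1
rather than logged; transformation happens per breakpoint, before
correlating. Categorical variables are tested by likelihood ratio in a
binomial GLM (logit link) of the error proportion on the category — chosen
as the simplest model linking a categorical predictor to a proportion.
Zero-variance variables are reported with missing statistics.

Multivariate: random forests (500 trees, √p features per split, seeded)
separating FN from TP and FP from TN breakpoints. Variable importance is
permutation importance — the mean decrease in accuracy when the variable is
scrambled (10 repeats) — and model accuracy is the out-of-bag estimate. The
directional effect is the sign of the median shift of the variable in
erroneous vs. correct breakpoints, nulled when the two-sided Mann-Whitney P
exceeds 0.01 or the variable is categorical. Classes with fewer than 2
members raise an insufficient-data error; classes above a configurable size
guard (default 10 000) are refused rather than fitted.

## Leaderboard analyses

Submissions rank by overall F (ties: precision, then team id). The
within-team variance is the within-team sum of squares of F as a percentage
of the total sum of squares — a shift-invariant measure of how much of the
spread is parameter tuning within teams.

The overfitting-artifact resampling draws truth subsets of sizes 100–1000
and splits them into train/test at fractions 0.80–0.95, scoring each
submission on both sides of each split and reporting the median
F_train − F_test (median over replicates per submission, then median over
submissions). Each submission is matched against the full truth set once;
replicates only partition the matched/unmatched labels, so a submission that
reproduces the truth exactly has ΔF ≡ 0, and spurious calls — which no
subset can claim — count against both sides. The positive, training-fraction-
increasing gap that emerges for imperfect submissions is purely a
small-testing-set artifact: no fitting happens anywhere in the loop.

## Problem sizes and numerical choices

The test suite and the acceptance script run on deliberately desk-scale
configurations chosen to estimate each quantity with comfortable margins:
a 60 kb reference at 30× (9 000 read pairs) for spike-in depth accounting,
truth sets of 200–1000 SVs on 5–10 Mb coordinate spaces for scoring and
ensembles, 20 replicates per cell on a 300-SV total for the resampling grid,
and 150 breakpoints per class for the forests. Similarity ties are resolved
at an absolute tolerance of 1e-9; medians of even-sized integer sets use the
lower median; all randomness flows from explicit integer seeds
(`numpy.random.default_rng`), and fixed seeds give byte-identical FASTA, SAM,
and VCF outputs.

## Known limitations

* BND→typed conversion covers only canonical same-chromosome adjacencies;
  exotic breakend geometries stay BND and are invisible to the ensemble.
* The overlap scheme treats insertions as 1-bp regions (warned at runtime);
  closeness is the appropriate scheme for single-breakpoint events.
* FP attribution to train/test scopes via mask overlap is a convention, not
  a ground truth.
* The simulator's uniform, error-free reads make breakpoint features
  (entropy, strand bias) much cleaner than in real data; forests trained on
  them demonstrate the pipeline, not realistic error structure.
* Coverage inside a plan interval dips below C_o for deletion spikes at
  sub-unit VAF (the replaced reads are resimulated at C_f over the shorter
  contig); depth semantics are exact over the deleted span itself and
  outside the interval.
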