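# svbench

Benchmarking machinery for **somatic structural-variant (SV) calling**: a
read-level SV spike-in simulator with truth-set emission, two SV scoring
schemes with optimal call↔truth matching, majority-vote ensemble aggregation
of call sets, and FN/FP error profiling with random forests. It is written for
method developers and benchmark organizers who need to score SV call sets
against a simulated ground truth, merge submissions into consensus calls, and
characterize where callers fail — entirely on synthetic, desk-scale data.

## What it computes

**Scoring.** A called SV is compared to a known SV either by

* *region overlap* — the Jaccard coefficient `j = |A ∩ B| / |A ∪ B]` of the
  two genomic regions (1-based, inclusive), or
* *breakpoint closeness* — per breakpoint, the distance `Δ` between called
  and known positions is converted to a relative closeness `c′ = 1 − Δ/f`
  whenever `Δ ≤ f` (flank parameter, default `f = 100` bp); the overall
  similarity is the geometric mean `c = √(c′_start · c′_end)`. If only one
  breakpoint falls within the flank, the pair is a **partial match**:
  ineligible for matching, but shielding both records from the FP/FN counts.

Ambiguities are resolved by a one-to-one matching that maximizes total
similarity (Hungarian algorithm), with exact ties broken by same SVTYPE, then
same train/test subset, then genomic order. Matched records are TPs; the rest
are FPs (called side) or FNs (known side), and

```
precision = nTP / (nTP + nFP),  recall = nTP / (nTP + nFN),
F = 2 · precision · recall / (precision + recall)
```

with partial matches excluded from all three. Mated break-end (BND) pairs are
annotated per breakpoint, then counted as a single SV. Truth SVs with ≥ 50%
of their region inside masked (`SVTYPE=MSK`) regions form the held-out
testing set; scores can be scoped to train, test, or all.

**Ensembles.** Calls from the top-k submissions are merged when their
breakpoint-length distance `d = max(|Δstart|, |Δend|, |ΔL|)` is below `f`,
either by connected components with median-distance refinement (*baseline*)
or by guilt-by-association growth requiring ≥ 1 bp overlap and one call per
submission per set (*conservative*). Sets covering ≤ k/2 submissions are
discarded (majority vote); survivors are collapsed to the median start/end.

**Simulation.** A pseudo-random reference is generated, error-free paired
reads are placed uniformly at coverage `C_o` with known alignments (SAM
output needs no aligner), and DEL/DUP/INV/INS events are planted by
rearranging the local contig and resimulating coverage over it at
`C_f = VAF · C_o · (L_f / L_o)`, where `L_o`/`L_f` are the original and
rearranged contig lengths. Deletions drain depth over the deleted span to
`(1 − VAF) · C_o`, duplications/insertions add reads, inversions leave depth
unchanged, and junction-spanning reads are soft-clipped at the breakpoints.
Synthetic "submissions" derive from the truth by breakpoint jitter, dropout
(FN), and spurious calls (FP).

**Error profiling.** Breakpoints are labeled TP/FN/FP (priority TP > FN > FP)
or sampled as true negatives (log-normal lengths matched to the truth,
avoiding gaps/repeats, truth, and called SVs); four genomic variables are
computed per breakpoint (bridging reads, germline-INDEL distance, ±50 bp
nucleotide entropy, strand bias); associations are measured univariately
(Pearson on log10-transformed values; binomial GLM for categoricals) and
multivariately (random forests with permutation importance and Mann-Whitney
directional effects).

## Worked example

```python
import svbench as sb

contigs = {"chr1": 5_000_000}
truth = sb.random_truth(200, contigs, seed=7)                       # 200 planted SVs
masks = sb.random_masks(contigs, fraction=0.1, region_len=50_000, seed=8)
truth = sb.assign_train_test(truth, masks)                          # ≥50% masked → test
calls = sb.perturb_callset(truth, jitter_sd=10, fn_rate=0.15,
                           fp_count=20, seed=9, contigs=contigs)    # a noisy "submission"

match = sb.match_calls(calls, truth, scheme="closeness", f=100, masks=masks)
for scope in ("all", "train", "test"):
    r = sb.score(match, scope)
    print(f"{scope:5s} nTP={r.n_tp:3d} nFP={r.n_fp:2d} nFN={r.n_fn:2d} "
          f"precision={r.precision:.3f} recall={r.recall:.3f} F={r.f_score:.3f}")
```

prints

```
all   nTP=170 nFP=20 nFN=30 precision=0.895 recall=0.850 F=0.872
train nTP=151 nFP=19 nFN=29 precision=0.888 recall=0.839 F=0.863
test  nTP= 19 nFP= 1 nFN= 1 precision=0.950 recall=0.950 F=0.950
```

The submission was built with a 15% dropout rate and 20 spurious calls, and
the measured recall (0.850) and FP count (20) recover exactly that; the 10 bp
breakpoint jitter stays well inside the 100 bp flank, so no true call is
lost. Aggregating five dropout-free submissions with independent FPs removes
every spurious call by majority vote:

```python
subs = [sb.perturb_callset(truth, jitter_sd=10, fn_rate=0.0, fp_count=20,
                           seed=s, contigs=contigs) for s in (11, 12, 13, 14, 15)]
consensus = sb.ensemble_records(sb.build_ensemble(subs, k=5, mode="baseline", f=100))
print(sb.score(sb.match_calls(consensus, truth, f=100)).f_score)   # 1.000
```

The same operations are exposed on the command line: `svbench simulate`
(reference + spiked reads + truth VCF from a plan file), `svbench perturb`,
`svbench score`, `svbench ensemble`, `svbench leaderboard`, and
`svbench overfit` (see `svbench --help`).

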