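"""Characterization of false-negative and false-positive breakpoints.

Breakpoints inherit TP/FN/FP annotations from scoring (resolved with priority
TP > FN > FP when a position carries several), true-negative control regions
are rejection-sampled from the genome with log-normal lengths matched to the
truth set, and four per-breakpoint genomic variables are computed:

* **bridging reads** — reads whose aligned span contains the ±1 bp window
  around the breakpoint (no split-alignment requirement);
* **germline INDEL distance** — distance to the nearest germline INDEL;
* **nucleotide entropy** — Shannon entropy (bits) of the ±50 bp reference
  window over {A, C, G, T}, case-insensitive;
* **strand bias** — proportion of breakpoint-overlapping reads on the
  forward strand.

Additional covariates (coverage, mapping quality, ...) are accepted as
precomputed pass-through columns.  Univariate association uses Pearson
correlation on (optionally log10-transformed) values against per-breakpoint
team error proportions, with a binomial GLM for categorical variables;
multivariate importance uses random forests with permutation (mean decrease
in accuracy) importance and Mann-Whitney directional effects.
"""

from __future__ import annotations

import bisect
import math
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .model import SVRecord

__all__ = [
    "InsufficientDataError",
    "resolve_breakpoint_labels",
    "sample_true_negatives",
    "sequence_entropy",
    "compute_features",
    "compute_feature_table",
    "breakpoints_of",
    "univariate_association",
    "fit_error_forests",
]

LABEL_PRIORITY = ("TP", "FN", "FP")


class InsufficientDataError(ValueError):
    """Raised when a class is too small (or too large) to model reliably."""


def breakpoints_of(rec: SVRecord) -> list[tuple[str, int]]:
    """The breakpoint positions of a record (one for single-breakpoint SVs)."""
    if rec.is_single_breakpoint:
        return [(rec.chrom, rec.pos)]
    return [(rec.chrom, rec.pos), (rec.chrom, rec.end)]


def resolve_breakpoint_labels(
    annotations: Sequence[tuple[tuple[str, int], str]],
) -> dict[tuple[str, int], str]:
    """Collapse multiple per-breakpoint annotations with priority TP > FN > FP."""
    rank = {label: i for i, label in enumerate(LABEL_PRIORITY)}
    resolved: dict[tuple[str, int], str] = {}
    for bp, label in annotations:
        if label not in rank:
            raise ValueError(f"unknown breakpoint annotation {label!r}")
        best = resolved.get(bp)
        if best is None or rank[label] < rank[best]:
            resolved[bp] = label
    return resolved


# --------------------------------------------------------------------------
# True-negative sampling
# --------------------------------------------------------------------------

def _contig_lengths(genome: Union[dict[str, str], dict[str, int]]) -> dict[str, int]:
    return {chrom: (len(seq) if isinstance(seq, str) else int(seq))
            for chrom, seq in genome.items()}


def _build_tree(records: Sequence[SVRecord]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for rec in records:
        trees.setdefault(rec.chrom, IntervalTree()).addi(rec.pos, rec.end + 1)
    return trees


def sample_true_negatives(
    truth: Sequence[SVRecord],
    calls: Sequence[SVRecord],
    genome: Union[dict[str, str], dict[str, int]],
    excluded: Sequence[tuple[str, int, int]] = (),
    n_min: int = 100,
    seed: int = 0,
    max_attempts_factor: int = 1000,
) -> list[tuple[str, int, int]]:
    """Sample ≥ n_min true-negative regions satisfying all four criteria.

    Lengths are drawn from a log-normal distribution whose natural-log mean
    and standard deviation match the logged truth SV lengths; a region is
    accepted when its start is outside the gap/repeat exclusion regions and
    it overlaps neither the truth set nor the submission's calls.
    """
    if not truth:
        raise ValueError("cannot fit the length distribution: empty truth set")
    rng = np.random.default_rng(seed)
    contigs = _contig_lengths(genome)
    log_lengths = np.log([rec.length for rec in truth])
    mu, sd = float(log_lengths.mean()), float(log_lengths.std())

    truth_tree = _build_tree(truth)
    call_tree = _build_tree(calls)
    excl_tree: dict[str, IntervalTree] = {}
    for chrom, start, end in excluded:
        excl_tree.setdefault(chrom, IntervalTree()).addi(start, end + 1)

    names = sorted(contigs)
    weights = np.array([contigs[c] for c in names], dtype=float)
    weights /= weights.sum()
    regions: list[tuple[str, int, int]] = []
    cap = max_attempts_factor * n_min
    attempts = 0
    while len(regions) < n_min:
        attempts += 1
        if attempts > cap:
            raise RuntimeError(
                f"true-negative sampling accepted only {len(regions)}/{n_min} regions "
                f"in {cap} attempts; exclusion constraints are too dense"
            )
        chrom = names[int(rng.choice(len(names), p=weights))]
        length = max(1, int(round(rng.lognormal(mu, sd))))
        glen = contigs[chrom]
        if length > glen:
            continue
        start = int(rng.integers(1, glen - length + 2))
        end = start + length - 1
        if chrom in excl_tree and excl_tree[chrom].overlap(start, start + 1):
            continue
        if chrom in truth_tree and truth_tree[chrom].overlap(start, end + 1):
            continue
        if chrom in call_tree and call_tree[chrom].overlap(start, end + 1):
            continue
        regions.append((chrom, start, end))
    return regions


# --------------------------------------------------------------------------
# Genomic variables
# --------------------------------------------------------------------------

def sequence_entropy(seq: str) -> float:
    """Shannon entropy (bits) of the A/C/G/T composition, case-insensitive."""
    seq = seq.upper()
    counts = np.array([seq.count(b) for b in "ACGT"], dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _indel_positions(germline_indels: Union[str, Sequence[tuple[str, int]]]) -> dict[str, list[int]]:
    """Sorted germline INDEL positions per chromosome from a VCF or a list."""
    positions: dict[str, list[int]] = {}
    if isinstance(germline_indels, str):
        with pysam.VariantFile(germline_indels) as vf:
            for rec in vf:
                ref = rec.ref or ""
                alts = rec.alts or ()
                if any(len(alt) != len(ref) for alt in alts if alt and not alt.startswith("<")):
                    positions.setdefault(rec.chrom, []).append(rec.pos)
    else:
        for chrom, pos in germline_indels:
            positions.setdefault(chrom, []).append(pos)
    for chrom in positions:
        positions[chrom].sort()
    return positions


def _nearest_distance(sorted_positions: list[int], pos: int) -> float:
    if not sorted_positions:
        return math.inf
    i = bisect.bisect_left(sorted_positions, pos)
    best = math.inf
    if i < len(sorted_positions):
        best = min(best, abs(sorted_positions[i] - pos))
    if i > 0:
        best = min(best, abs(sorted_positions[i - 1] - pos))
    return float(best)


class AlignmentSpans:
    """Per-chromosome aligned-read spans, loadable from SAM/BAM or a read set.

    Plain SAM files carry no index, so alignments are scanned once into
    start/end/strand arrays; breakpoint queries are then vectorized.
    """

    def __init__(self, spans: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._spans = spans

    @classmethod
    def from_alignments(cls, alignments) -> "AlignmentSpans":
        if isinstance(alignments, cls):
            return alignments
        buckets: dict[str, list[tuple[int, int, bool]]] = {}
        if hasattr(alignments, "pairs"):  # a spike_sim.ReadSet
            from .spike_sim import _cigar_aligned_length

            for pair in alignments.pairs:
                for mate in (pair.mate1, pair.mate2):
                    if mate.pos is None:
                        continue
                    end = mate.pos + _cigar_aligned_length(mate.cigar) - 1
                    buckets.setdefault(pair.chrom, []).append(
                        (mate.pos, end, mate.strand == "-"))
        else:
            own = isinstance(alignments, str)
            bam = pysam.AlignmentFile(alignments) if own else alignments
            try:
                for read in bam.fetch(until_eof=True):
                    if read.is_unmapped or read.is_secondary or read.is_supplementary:
                        continue
                    buckets.setdefault(read.reference_name, []).append(
                        (read.reference_start + 1, read.reference_end, read.is_reverse))
            finally:
                if own:
                    bam.close()
        spans = {}
        for chrom, items in buckets.items():
            items.sort()
            arr = np.array(items, dtype=np.int64)
            spans[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2].astype(bool))
        return cls(spans)

    def bridging_reads(self, chrom: str, pos: int) -> int:
        """Reads whose aligned span contains the ±1 bp window around pos."""
        if chrom not in self._spans:
            return 0
        starts, ends, _rev = self._spans[chrom]
        return int(((starts <= max(1, pos - 1)) & (ends >= pos + 1)).sum())

    def strand_bias(self, chrom: str, pos: int) -> float:
        """Forward-strand proportion of reads overlapping pos (0.5 if none)."""
        if chrom not in self._spans:
            return 0.5
        starts, ends, rev = self._spans[chrom]
        over = (starts <= pos) & (ends >= pos)
        n = int(over.sum())
        return float((~rev[over]).sum() / n) if n else 0.5


def _entropy_window(reference: Union[str, dict[str, str]], chrom: str, pos: int,
                    flank: int) -> str:
    if isinstance(reference, dict):
        seq = reference.get(chrom)
        if seq is None:
            raise ValueError(f"breakpoint contig {chrom!r} absent from reference")
        if pos < 1 or pos > len(seq):
            raise ValueError(f"breakpoint {chrom}:{pos} outside contig (length {len(seq)})")
        return seq[max(0, pos - 1 - flank): min(len(seq), pos + flank)]
    from pyfaidx import Fasta

    fasta = Fasta(reference)
    if chrom not in fasta:
        raise ValueError(f"breakpoint contig {chrom!r} absent from reference")
    contig_len = len(fasta[chrom])
    if pos < 1 or pos > contig_len:
        raise ValueError(f"breakpoint {chrom}:{pos} outside contig (length {contig_len})")
    return str(fasta[chrom][max(0, pos - 1 - flank): min(contig_len, pos + flank)])


def compute_features(
    breakpoint: tuple[str, int],
    alignments,
    germline_indels: Union[str, Sequence[tuple[str, int]], dict[str, list[int]]],
    reference: Union[str, dict[str, str]],
    entropy_flank: int = 50,
) -> dict[str, float]:
    """The four per-breakpoint genomic variables at one position.

    Bridging reads are primary alignments whose aligned span contains the
    breakpoint ± 1 bp window; strand bias is the forward-strand proportion of
    reads overlapping the breakpoint itself; entropy is computed on the
    reference ± 50 bp window (truncated at contig ends).  ``alignments`` may
    be a SAM/BAM path, an open AlignmentFile, a simulated read set, or a
    preloaded :class:`AlignmentSpans`.
    """
    chrom, pos = breakpoint
    spans = AlignmentSpans.from_alignments(alignments)
    window = _entropy_window(reference, chrom, pos, entropy_flank)
    if isinstance(germline_indels, dict):
        indels = germline_indels
    else:
        indels = _indel_positions(germline_indels)
    return {
        "bridging_reads": float(spans.bridging_reads(chrom, pos)),
        "germline_indel_distance": _nearest_distance(indels.get(chrom, []), pos),
        "nucleotide_entropy": sequence_entropy(window),
        "strand_bias": spans.strand_bias(chrom, pos),
    }


def compute_feature_table(
    breakpoints: Sequence[tuple[str, int]],
    labels: Sequence[str],
    alignments,
    germline_indels: Union[str, Sequence[tuple[str, int]]],
    reference: Union[str, dict[str, str]],
    passthrough: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Feature rows for many breakpoints, with labels and optional covariates."""
    if len(breakpoints) != len(labels):
        raise ValueError("breakpoints and labels must have equal length")
    spans = AlignmentSpans.from_alignments(alignments)
    indels = _indel_positions(germline_indels) if not isinstance(germline_indels, dict) else germline_indels
    rows = []
    for (chrom, pos), label in zip(breakpoints, labels):
        feats = compute_features((chrom, pos), spans, indels, reference)
        feats.update({"chrom": chrom, "pos": pos, "label": label})
        rows.append(feats)
    table = pd.DataFrame(rows)
    table = table[["chrom", "pos", "label", "bridging_reads", "germline_indel_distance",
                   "nucleotide_entropy", "strand_bias"]]
    if passthrough is not None:
        table = pd.concat([table.reset_index(drop=True), passthrough.reset_index(drop=True)], axis=1)
    return table


# --------------------------------------------------------------------------
# Univariate association
# --------------------------------------------------------------------------

def log10_with_zero_rule(values: np.ndarray) -> np.ndarray:
    """log10 transform with zeros mapped to −1 instead of logged."""
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, -1.0)
    mask = values > 0
    out[mask] = np.log10(values[mask])
    return out


def univariate_association(
    features: pd.DataFrame,
    error_rates: Sequence[float],
    log_vars: Sequence[str] = ("bridging_reads", "germline_indel_distance"),
    categorical_vars: Sequence[str] = (),
    variables: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-variable association with the per-breakpoint error proportion.

    Continuous variables: Pearson r (on log10-transformed values for the
    designated variables, zeros → −1) and its P value.  Categorical
    variables: likelihood-ratio P of the variable in a binomial GLM of the
    error proportion.  Zero-variance variables are reported with missing
    statistics.
    """
    rates = np.asarray(error_rates, dtype=float)
    if len(rates) != len(features):
        raise ValueError("error_rates must align with the feature rows")
    if len(features) < 3:
        raise ValueError("univariate association requires at least 3 breakpoints")
    if variables is None:
        variables = [c for c in features.columns if c not in ("chrom", "pos", "label")]
    rows = []
    for var in variables:
        if var in categorical_vars:
            stat, p = _binomial_glm_p(features[var], rates)
            rows.append({"variable": var, "kind": "categorical", "statistic": stat, "p_value": p})
            continue
        values = features[var].to_numpy(dtype=float)
        finite = np.isfinite(values)
        values = np.where(finite, values, np.nanmax(values[finite]) if finite.any() else 0.0)
        if var in log_vars:
            values = log10_with_zero_rule(values)
        if np.ptp(values) == 0 or np.ptp(rates) == 0:
            rows.append({"variable": var, "kind": "continuous",
                         "statistic": np.nan, "p_value": np.nan})
            continue
        r, p = stats.pearsonr(values, rates)
        rows.append({"variable": var, "kind": "continuous", "statistic": float(r),
                     "p_value": float(p)})
    return pd.DataFrame(rows)


def _binomial_glm_p(categories: pd.Series, rates: np.ndarray) -> tuple[float, float]:
    import statsmodels.api as sm

    design = pd.get_dummies(categories.astype("category"), drop_first=True, dtype=float)
    if design.shape[1] == 0:  # single category: no effect testable
        return np.nan, np.nan
    y = np.clip(rates, 1e-9, 1 - 1e-9)
    full = sm.GLM(y, sm.add_constant(design), family=sm.families.Binomial()).fit()
    null = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial()).fit()
    lr = 2 * (full.llf - null.llf)
    df = design.shape[1]
    p = float(stats.chi2.sf(max(lr, 0.0), df))
    return float(lr), p


# --------------------------------------------------------------------------
# Random forests
# --------------------------------------------------------------------------

_TARGETS = {
    "FN_vs_TP": ("FN", "TP"),
    "FP_vs_TN": ("FP", "TN"),
}


def fit_error_forests(
    features: pd.DataFrame,
    target: str = "FN_vs_TP",
    seed: int = 0,
    n_trees: int = 500,
    n_permutations: int = 10,
    max_class_size: int = 10_000,
    direction_alpha: float = 0.01,
) -> tuple[pd.DataFrame, float]:
    """Random-forest variable importance for one error class.

    Fits a forest separating the error class (FN or FP) from its reference
    class (TP or TN), returning per-variable permutation importance (mean
    decrease in accuracy), the directional effect (sign of the location shift
    of the variable in erroneous vs. correct breakpoints; 0 when the
    two-sided Mann-Whitney P exceeds ``direction_alpha`` or the variable is
    categorical), and the out-of-bag model accuracy.
    """
    if target not in _TARGETS:
        raise ValueError(f"target must be one of {sorted(_TARGETS)}, got {target!r}")
    err_label, ref_label = _TARGETS[target]
    subset = features[features["label"].isin((err_label, ref_label))]
    counts = subset["label"].value_counts()
    for label in (err_label, ref_label):
        n = int(counts.get(label, 0))
        if n < 2:
            raise InsufficientDataError(
                f"insufficient data: class {label} has {n} breakpoint(s); "
                f"at least 2 are required to fit a model"
            )
        if n > max_class_size:
            raise InsufficientDataError(
                f"class {label} has {n} breakpoints, exceeding the {max_class_size} "
                f"guard against non-converging models"
            )

    drop = [c for c in ("chrom", "pos", "label") if c in subset.columns]
    x_raw = subset.drop(columns=drop)
    categorical = [c for c in x_raw.columns if not pd.api.types.is_numeric_dtype(x_raw[c])]
    x = x_raw.copy()
    for col in categorical:
        x[col] = x[col].astype("category").cat.codes
    x = x.to_numpy(dtype=float)
    y = (subset["label"] == err_label).to_numpy()

    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(x, y)
    accuracy = float(forest.oob_score_)
    perm = permutation_importance(
        forest, x, y, scoring="accuracy", n_repeats=n_permutations, random_state=seed,
    )

    rows = []
    for i, var in enumerate(x_raw.columns):
        direction = 0
        if var not in categorical:
            err_vals = x_raw.loc[subset["label"] == err_label, var].to_numpy(dtype=float)
            ref_vals = x_raw.loc[subset["label"] == ref_label, var].to_numpy(dtype=float)
            if np.ptp(np.concatenate([err_vals, ref_vals])) > 0:
                _u, p = stats.mannwhitneyu(err_vals, ref_vals, alternative="two-sided")
                if p <= direction_alpha:
                    shift = np.median(err_vals) - np.median(ref_vals)
                    if shift == 0:
                        shift = err_vals.mean() - ref_vals.mean()
                    direction = int(np.sign(shift))
        rows.append({
            "variable": var,
            "importance": float(perm.importances_mean[i]),
            "direction": direction,
            "model_accuracy": accuracy,
        })
    table = pd.DataFrame(rows).sort_values("importance", ascending=False).reset_index(drop=True)
    return table, accuracy
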