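"""Scoring of called SV sets against known (truth) SV sets.

Two similarity schemes are supported:

* **overlap** — Jaccard coefficient j of the two inclusive genomic regions;
  any j above the threshold (default: any positive overlap) qualifies.
* **closeness** — per-breakpoint relative closeness c' = 1 − Δ/f for
  breakpoint distance Δ within a flank f (default 100 bp); the overall
  similarity c is the geometric mean of the start and end c' values.  A pair
  with exactly one breakpoint inside the flank is a *partial* match: it never
  enters the matching but shields both records from being counted as FP/FN.

Ambiguity between qualifying pairs is resolved by a global maximum-weight
one-to-one matching (Hungarian algorithm).  Exact similarity ties are broken
by preferring pairs with the same SVTYPE, then the same train/test subset,
then earlier genomic order — implemented as infinitesimal bonuses (1e-9
scale) that cannot reorder genuinely different similarities above the 1e-9
reproducibility tolerance.

Matched records are TPs; unmatched calls/knowns with no qualifying or partial
similarity are FPs/FNs; the rest are partial matches, excluded from all
counts.  Mated breakpoints (BND pairs) are annotated separately, an FP mate
is upgraded to partial when its partner is TP or partial, and each mate pair
then counts as one SV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .model import MaskSet, SVRecord, assign_train_test

__all__ = [
    "SimilarityEdge",
    "ScoreReport",
    "MatchResult",
    "jaccard_similarity",
    "breakpoint_closeness",
    "match_calls",
    "score",
]

# similarity comparisons are reproducible to this absolute tolerance
SIM_TOL = 1e-9

_TYPE_BONUS = 1e-9
_SUBSET_BONUS = 5e-10
_ORDER_BONUS = 1e-13


@dataclass(frozen=True)
class SimilarityEdge:
    """A qualifying or partial similarity between one call and one known SV."""

    called_id: str
    known_id: str
    similarity: float
    partial_only: bool = False


@dataclass(frozen=True)
class ScoreReport:
    """TP/FP/FN counts and the derived precision/recall/F-score."""

    n_tp: int
    n_fp: int
    n_fn: int
    n_partial: int
    precision: float
    recall: float
    f_score: float
    subset_scope: str = "all"

    @classmethod
    def from_counts(cls, n_tp: int, n_fp: int, n_fn: int, n_partial: int = 0,
                    subset_scope: str = "all") -> "ScoreReport":
        precision = n_tp / (n_tp + n_fp) if (n_tp + n_fp) else 0.0
        recall = n_tp / (n_tp + n_fn) if (n_tp + n_fn) else 0.0
        f = (2 * precision * recall / (precision + recall)
             if (precision + recall) else 0.0)
        return cls(n_tp, n_fp, n_fn, n_partial, precision, recall, f, subset_scope)


def jaccard_similarity(region_a: tuple[str, int, int], region_b: tuple[str, int, int]) -> float:
    """Jaccard coefficient of two 1-based inclusive regions (0 across chromosomes)."""
    chrom_a, pos_a, end_a = region_a
    chrom_b, pos_b, end_b = region_b
    if chrom_a != chrom_b:
        return 0.0
    inter = min(end_a, end_b) - max(pos_a, pos_b) + 1
    if inter <= 0:
        return 0.0
    union = (end_a - pos_a + 1) + (end_b - pos_b + 1) - inter
    return inter / union


def breakpoint_closeness(called: SVRecord, known: SVRecord, f: float = 100.0) -> tuple[float, bool]:
    """Overall closeness c and a partial-match flag for one call/known pair.

    Returns ``(c, False)`` when both breakpoints are within the flank f
    (c is the geometric mean of the per-breakpoint closenesses), ``(0.0,
    True)`` when exactly one is, and ``(0.0, False)`` otherwise.  Records with
    a single breakpoint (pos == end, e.g. insertions or break-ends) are
    compared on the start breakpoint alone.
    """
    if f <= 0:
        raise ValueError(f"flank f must be positive, got {f}")
    if called.chrom != known.chrom:
        return 0.0, False
    d_start = abs(called.pos - known.pos)
    if called.is_single_breakpoint or known.is_single_breakpoint:
        if d_start <= f:
            return 1.0 - d_start / f, False
        return 0.0, False
    d_end = abs(called.end - known.end)
    ok_start, ok_end = d_start <= f, d_end <= f
    if ok_start and ok_end:
        return math.sqrt((1.0 - d_start / f) * (1.0 - d_end / f)), False
    if ok_start or ok_end:
        return 0.0, True
    return 0.0, False


@dataclass
class MatchResult:
    """One-to-one call↔truth assignment with per-SV annotations.

    ``called_status`` / ``known_status`` map record ids to one of
    ``TP``/``FP``/``partial`` and ``TP``/``FN``/``partial`` respectively.
    Counts exposed by :meth:`score` are per mated-breakpoint group (a BND
    mate pair counts once).
    """

    pairs: list[tuple[str, str, float]]
    called_status: dict[str, str]
    known_status: dict[str, str]
    called: list[SVRecord] = field(repr=False, default_factory=list)
    known: list[SVRecord] = field(repr=False, default_factory=list)
    called_subset: dict[str, str] = field(default_factory=dict)
    scheme: str = "closeness"
    f: float = 100.0
    j_min: float = 0.0

    @property
    def total_similarity(self) -> float:
        return sum(s for _, _, s in self.pairs)

    def matched_known(self, called_id: str) -> Optional[str]:
        for cid, kid, _ in self.pairs:
            if cid == called_id:
                return kid
        return None

    def annotations(self) -> pd.DataFrame:
        """Per-SV annotation table (id, side, status, matched_id, similarity)."""
        sim = {cid: (kid, s) for cid, kid, s in self.pairs}
        sim_k = {kid: (cid, s) for cid, kid, s in self.pairs}
        rows = []
        for rec in self.called:
            kid, s = sim.get(rec.id, (None, np.nan))
            rows.append((rec.id, "called", self.called_status[rec.id], kid, s))
        for rec in self.known:
            cid, s = sim_k.get(rec.id, (None, np.nan))
            rows.append((rec.id, "known", self.known_status[rec.id], cid, s))
        return pd.DataFrame(rows, columns=["id", "side", "status", "matched_id", "similarity"])


def _mate_groups(records: Sequence[SVRecord]) -> list[list[str]]:
    """Group record ids so each BND mate pair forms one group."""
    by_id = {rec.id: rec for rec in records}
    seen: set[str] = set()
    groups: list[list[str]] = []
    for rec in records:
        if rec.id in seen:
            continue
        group = [rec.id]
        seen.add(rec.id)
        mate = by_id.get(rec.mate_id) if rec.mate_id else None
        if mate is not None and mate.id not in seen and mate.mate_id == rec.id:
            group.append(mate.id)
            seen.add(mate.id)
        groups.append(group)
    return groups


def _similarity_matrices(
    called: list[SVRecord],
    known: list[SVRecord],
    scheme: str,
    f: float,
    j_min: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense (similarity, qualifying, partial) matrices for same-chromosome records."""
    pos_c = np.array([r.pos for r in called], dtype=float)[:, None]
    end_c = np.array([r.end for r in called], dtype=float)[:, None]
    pos_k = np.array([r.pos for r in known], dtype=float)[None, :]
    end_k = np.array([r.end for r in known], dtype=float)[None, :]
    if scheme == "closeness":
        ds = np.abs(pos_c - pos_k)
        de = np.abs(end_c - end_k)
        single = (np.array([r.is_single_breakpoint for r in called])[:, None]
                  | np.array([r.is_single_breakpoint for r in known])[None, :])
        ok_s, ok_e = ds <= f, de <= f
        cs = np.clip(1.0 - ds / f, 0.0, None)
        ce = np.clip(1.0 - de / f, 0.0, None)
        sim = np.where(single, np.where(ok_s, cs, 0.0),
                       np.where(ok_s & ok_e, np.sqrt(cs * ce), 0.0))
        qualify = np.where(single, ok_s, ok_s & ok_e)
        partial = (~single) & (ok_s ^ ok_e)
    elif scheme == "overlap":
        inter = np.minimum(end_c, end_k) - np.maximum(pos_c, pos_k) + 1
        union = (end_c - pos_c + 1) + (end_k - pos_k + 1) - np.clip(inter, 0, None)
        sim = np.where(inter > 0, np.clip(inter, 0, None) / union, 0.0)
        qualify = sim > j_min
        partial = np.zeros_like(qualify)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return sim, qualify, partial


def match_calls(
    called: Sequence[SVRecord],
    known: Sequence[SVRecord],
    scheme: str = "closeness",
    f: float = 100.0,
    j_min: float = 0.0,
    masks: Optional[MaskSet] = None,
) -> MatchResult:
    """Optimally match called SVs to known SVs and annotate TP/FP/FN/partial.

    The matching maximizes total similarity over all qualifying pairs subject
    to the one-to-one constraint; ties are broken by SVTYPE, subset, then
    genomic order.  When ``masks`` is given, unmatched calls (FPs) are
    attributed to the test scope by the same ≥50% mask-overlap rule used for
    truth allocation, enabling scoped score reports.
    """
    called = list(called)
    known = list(known)
    if scheme == "closeness" and f <= 0:
        raise ValueError(f"flank f must be positive, got {f}")
    for side, records in (("called", called), ("known", known)):
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate {side} record IDs: {dup}")
    if scheme == "overlap" and any(r.is_single_breakpoint for r in called + known):
        import warnings

        warnings.warn(
            "overlap scheme treats single-breakpoint records (e.g. insertions) "
            "as 1-bp regions; breakpoint-closeness scoring is better suited",
            stacklevel=2,
        )

    subset_rank = {"train": 0.0, "test": 1.0, "unassigned": 2.0}
    pairs: list[tuple[str, str, float]] = []
    has_edge_c = {r.id: False for r in called}
    has_edge_k = {r.id: False for r in known}
    matched_c: set[str] = set()
    matched_k: set[str] = set()

    chroms = sorted({r.chrom for r in called} & {r.chrom for r in known})
    for chrom in chroms:
        sub_c = [r for r in called if r.chrom == chrom]
        sub_k = [r for r in known if r.chrom == chrom]
        sim, qualify, partial = _similarity_matrices(sub_c, sub_k, scheme, f, j_min)
        any_edge = qualify | partial
        for i, rec in enumerate(sub_c):
            if any_edge[i].any():
                has_edge_c[rec.id] = True
        for j, rec in enumerate(sub_k):
            if any_edge[:, j].any():
                has_edge_k[rec.id] = True
        if not qualify.any():
            continue
        # restrict the assignment problem to records with a qualifying edge
        rows = np.flatnonzero(qualify.any(axis=1))
        cols = np.flatnonzero(qualify.any(axis=0))
        sub_sim = sim[np.ix_(rows, cols)]
        sub_q = qualify[np.ix_(rows, cols)]
        types_c = np.array([sub_c[i].svtype for i in rows])[:, None]
        types_k = np.array([sub_k[j].svtype for j in cols])[None, :]
        ss_c = np.array([subset_rank.get(sub_c[i].subset, 2.0) for i in rows])[:, None]
        ss_k = np.array([subset_rank.get(sub_k[j].subset, 2.0) for j in cols])[None, :]
        order = np.arange(len(rows))[:, None] + np.arange(len(cols))[None, :]
        weights = np.where(
            sub_q,
            sub_sim
            + _TYPE_BONUS * (types_c == types_k)
            + _SUBSET_BONUS * (ss_c == ss_k)
            - _ORDER_BONUS * order,
            0.0,
        )
        ri, ci = linear_sum_assignment(weights, maximize=True)
        for i, j in zip(ri, ci):
            if sub_q[i, j]:
                rec_c, rec_k = sub_c[rows[i]], sub_k[cols[j]]
                pairs.append((rec_c.id, rec_k.id, float(sub_sim[i, j])))
                matched_c.add(rec_c.id)
                matched_k.add(rec_k.id)

    called_status = {}
    for rec in called:
        if rec.id in matched_c:
            called_status[rec.id] = "TP"
        elif has_edge_c[rec.id]:
            called_status[rec.id] = "partial"
        else:
            called_status[rec.id] = "FP"
    known_status = {}
    for rec in known:
        if rec.id in matched_k:
            known_status[rec.id] = "TP"
        elif has_edge_k[rec.id]:
            known_status[rec.id] = "partial"
        else:
            known_status[rec.id] = "FN"

    # mated breakpoints: a FP whose mate is TP or partial becomes partial
    by_id = {r.id: r for r in called}
    for rec in called:
        mate = by_id.get(rec.mate_id) if rec.mate_id else None
        if mate is None:
            continue
        if called_status[rec.id] == "FP" and called_status[mate.id] in ("TP", "partial"):
            called_status[rec.id] = "partial"

    called_subset: dict[str, str] = {}
    if masks is not None:
        for rec in assign_train_test(called, masks):
            called_subset[rec.id] = rec.subset

    return MatchResult(
        pairs=pairs,
        called_status=called_status,
        known_status=known_status,
        called=called,
        known=known,
        called_subset=called_subset,
        scheme=scheme,
        f=f,
        j_min=j_min,
    )


def _group_status(statuses: list[str], absent: str) -> str:
    if "TP" in statuses:
        return "TP"
    if "partial" in statuses:
        return "partial"
    return absent


def score(match: MatchResult, scope: str = "all") -> ScoreReport:
    """Precision/recall/F over a subset scope, counting each mate pair once.

    ``scope`` filters known-side SVs by their train/test label; unmatched
    calls (FPs) are filtered by their mask-derived subset when the matching
    was built with masks, and are otherwise counted in every scope.  Partial
    matches are excluded from all counts.
    """
    if scope not in ("train", "test", "all"):
        raise ValueError(f"scope must be train/test/all, got {scope!r}")
    known_by_id = {r.id: r for r in match.known}
    n_tp = n_fn = n_fp = n_partial = 0
    for group in _mate_groups(match.known):
        if scope != "all" and not any(known_by_id[i].subset == scope for i in group):
            continue
        status = _group_status([match.known_status[i] for i in group], "FN")
        if status == "TP":
            n_tp += 1
        elif status == "FN":
            n_fn += 1
        else:
            n_partial += 1
    for group in _mate_groups(match.called):
        status = _group_status([match.called_status[i] for i in group], "FP")
        if status == "partial":
            n_partial += 1
        elif status == "FP":
            if scope != "all" and match.called_subset:
                if not any(match.called_subset.get(i) == scope for i in group):
                    continue
            n_fp += 1
    return ScoreReport.from_counts(n_tp, n_fp, n_fn, n_partial, subset_scope=scope)
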