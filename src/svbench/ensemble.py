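"""Consensus ("wisdom of the crowds") aggregation of SV calls across submissions.

Calls from the top-k submissions (ranked best-first by the caller) are merged
into consensus SVs.  Break-end (BND) calls are excluded up front.  Pairwise
breakpoint-length distances are computed only between calls from different
submissions; pairs closer than the flank threshold f are "sufficiently
similar".  Two set-construction modes are provided:

* **baseline** — connected components of the similarity graph, refined by
  iteratively dropping the member with the greatest median distance to the
  others until the median intra-set pairwise distance falls to ≤ f (or one
  member remains).
* **conservative** — guilt-by-association growth over similarity pairs sorted
  from least to most distant, with the added constraints that paired calls
  overlap by ≥ 1 bp and that no set contains two calls from the same
  submission; a candidate joins an existing set only if its median distance
  to the members is ≤ f.

Sets supported by ≤ k/2 distinct submissions are discarded (majority vote);
each surviving set is aggregated to a single consensus call at the median
start/end (lower median for even counts, keeping integer coordinates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .model import SVRecord
from .scoring import match_calls, score

__all__ = [
    "EnsembleSet",
    "breakpoint_length_distance",
    "build_ensemble",
    "ensemble_records",
    "ensemble_sweep",
]


def breakpoint_length_distance(a: SVRecord, b: SVRecord) -> float:
    """Breakpoint-length distance: max of start/end breakpoint distances and
    the difference in SV length (inclusive length end − pos + 1).

    Calls on different chromosomes are never similar (distance +inf).
    """
    if a.chrom != b.chrom:
        return math.inf
    return float(max(abs(a.pos - b.pos), abs(a.end - b.end), abs(a.length - b.length)))


@dataclass
class EnsembleSet:
    """A group of mutually similar calls and its consensus coordinates."""

    members: list[tuple[int, SVRecord]]  # (submission index, call)
    consensus: tuple[str, int, int]
    n_submissions_covered: int

    @property
    def consensus_svtype(self) -> str:
        types = sorted(rec.svtype for _, rec in self.members)
        return max(set(types), key=lambda t: (types.count(t), t))


def _lower_median(values: Sequence[int]) -> int:
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def _median_distance_to_others(members: list[tuple[int, SVRecord]], idx: int) -> float:
    rec = members[idx][1]
    dists = [breakpoint_length_distance(rec, other[1])
             for j, other in enumerate(members) if j != idx]
    return float(np.median(dists)) if dists else 0.0


def _median_intra_set_distance(members: list[tuple[int, SVRecord]]) -> float:
    dists = [
        breakpoint_length_distance(members[i][1], members[j][1])
        for i in range(len(members))
        for j in range(i + 1, len(members))
    ]
    return float(np.median(dists)) if dists else 0.0


def _genomic_key(item: tuple[int, SVRecord]) -> tuple:
    sub, rec = item
    return (rec.chrom, rec.pos, rec.end, sub)


def _refine_baseline_set(members: list[tuple[int, SVRecord]], f: float) -> list[tuple[int, SVRecord]]:
    members = sorted(members, key=_genomic_key)
    while len(members) > 1 and _median_intra_set_distance(members) > f:
        med = [_median_distance_to_others(members, i) for i in range(len(members))]
        worst = max(med)
        # tie on the greatest median distance: drop the later call in genomic order
        drop = max(i for i, m in enumerate(med) if m == worst)
        members.pop(drop)
    return members


def _similar_pairs(
    calls: list[tuple[int, SVRecord]],
    f: float,
    require_overlap: bool,
) -> list[tuple[float, int, int]]:
    """(distance, i, j) for inter-submission pairs with d < f (and overlap if asked)."""
    by_chrom: dict[str, list[int]] = {}
    for idx, (_sub, rec) in enumerate(calls):
        by_chrom.setdefault(rec.chrom, []).append(idx)
    pairs: list[tuple[float, int, int]] = []
    for idxs in by_chrom.values():
        pos = np.array([calls[i][1].pos for i in idxs])
        end = np.array([calls[i][1].end for i in idxs])
        length = end - pos + 1
        sub = np.array([calls[i][0] for i in idxs])
        d = np.maximum(
            np.abs(pos[:, None] - pos[None, :]),
            np.maximum(np.abs(end[:, None] - end[None, :]),
                       np.abs(length[:, None] - length[None, :])),
        ).astype(float)
        ok = (d < f) & (sub[:, None] != sub[None, :])
        if require_overlap:
            inter = np.minimum(end[:, None], end[None, :]) - np.maximum(pos[:, None], pos[None, :]) + 1
            ok &= inter >= 1
        ii, jj = np.nonzero(np.triu(ok, k=1))
        for a, b in zip(ii, jj):
            pairs.append((float(d[a, b]), idxs[a], idxs[b]))
    return pairs


def build_ensemble(
    submissions: Sequence[Sequence[SVRecord]],
    k: int,
    mode: str = "baseline",
    f: float = 100.0,
) -> list[EnsembleSet]:
    """Merge the top-k call sets into consensus calls.

    ``submissions`` must already be ordered best-first (by overall F-score
    after BND exclusion); for baseline mode the list should hold one (best)
    submission per team, while conservative mode may include several
    submissions per team.  Returns consensus sets sorted by (chrom, start).
    """
    if k < 2:
        raise ValueError(f"ensemble requires k >= 2 submissions, got k={k}")
    if k > len(submissions):
        raise ValueError(f"k={k} exceeds the {len(submissions)} available submissions")
    if mode not in ("baseline", "conservative"):
        raise ValueError(f"mode must be baseline or conservative, got {mode!r}")

    calls: list[tuple[int, SVRecord]] = []
    for sub_idx, records in enumerate(submissions[:k]):
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.end, r.id)):
            if rec.svtype == "BND":
                continue
            calls.append((sub_idx, rec))

    pairs = _similar_pairs(calls, f, require_overlap=(mode == "conservative"))

    sets: list[list[tuple[int, SVRecord]]] = []
    if mode == "baseline":
        graph = nx.Graph()
        graph.add_nodes_from(range(len(calls)))
        graph.add_edges_from((i, j) for _d, i, j in pairs)
        for component in nx.connected_components(graph):
            members = [calls[i] for i in sorted(component)]
            members = _refine_baseline_set(members, f)
            if members:
                sets.append(members)
    else:
        pairs.sort(key=lambda p: (p[0],) + _genomic_key(calls[p[1]]) + _genomic_key(calls[p[2]]))
        assigned: dict[int, int] = {}  # call index -> set index
        for _d, i, j in pairs:
            in_i, in_j = i in assigned, j in assigned
            if not in_i and not in_j:
                assigned[i] = assigned[j] = len(sets)
                sets.append([calls[i], calls[j]])
            elif in_i != in_j:
                set_idx = assigned[i] if in_i else assigned[j]
                cand = j if in_i else i
                members = sets[set_idx]
                covered = {sub for sub, _rec in members}
                if calls[cand][0] in covered:
                    continue
                med = float(np.median([
                    breakpoint_length_distance(calls[cand][1], rec) for _s, rec in members
                ]))
                if med <= f:
                    members.append(calls[cand])
                    assigned[cand] = set_idx
            # both endpoints already in sets: the pair is no longer considered

    out: list[EnsembleSet] = []
    for members in sets:
        covered = {sub for sub, _rec in members}
        if len(covered) <= k / 2:
            continue
        members = sorted(members, key=_genomic_key)
        chrom = members[0][1].chrom
        start = _lower_median([rec.pos for _s, rec in members])
        end = _lower_median([rec.end for _s, rec in members])
        out.append(EnsembleSet(members=members, consensus=(chrom, start, end),
                               n_submissions_covered=len(covered)))
    out.sort(key=lambda s: s.consensus)
    return out


def ensemble_records(sets: Sequence[EnsembleSet], id_prefix: str = "ens") -> list[SVRecord]:
    """Materialize consensus sets as SV records (for scoring or VCF output)."""
    out = []
    for i, ens in enumerate(sets):
        chrom, start, end = ens.consensus
        out.append(SVRecord(id=f"{id_prefix}{i + 1}", chrom=chrom, pos=start, end=end,
                            svtype=ens.consensus_svtype))
    return out


def _strip_bnd(records: Sequence[SVRecord]) -> list[SVRecord]:
    return [r for r in records if r.svtype != "BND"]


def ensemble_sweep(
    submissions: Sequence[Sequence[SVRecord]],
    truth: Sequence[SVRecord],
    mode: str = "baseline",
    f: float = 100.0,
    scheme: str = "closeness",
    ks: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Score ensembles of the top k submissions for k = 2..N against a truth set.

    Submissions are first re-ordered by overall F-score computed after BND
    exclusion; each row compares the k-ensemble with the kth-ranked
    individual submission.
    """
    stripped = [_strip_bnd(records) for records in submissions]
    scored = []
    for idx, records in enumerate(stripped):
        rep = score(match_calls(records, truth, scheme=scheme, f=f))
        scored.append((rep.f_score, -idx, idx, rep))
    scored.sort(reverse=True)
    order = [idx for _f, _tie, idx, _rep in scored]
    ordered = [stripped[idx] for idx in order]
    reports = {rank: rep for rank, (_f, _tie, _idx, rep) in enumerate(scored)}

    rows = []
    for k in (ks if ks is not None else range(2, len(ordered) + 1)):
        sets = build_ensemble(ordered, k=k, mode=mode, f=f)
        ens_rep = score(match_calls(ensemble_records(sets), truth, scheme=scheme, f=f))
        indiv = reports[k - 1]
        rows.append({
            "k": k,
            "mode": mode,
            "ensemble_precision": ens_rep.precision,
            "ensemble_recall": ens_rep.recall,
            "ensemble_f": ens_rep.f_score,
            "individual_precision": indiv.precision,
            "individual_recall": indiv.recall,
            "individual_f": indiv.f_score,
        })
    return pd.DataFrame(rows)
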