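"""Read-level SV spike-in simulation and synthetic benchmark data generation.

The simulator emulates tumor spike-in at the read level: a pseudo-random
reference is built, error-free paired reads are simulated at uniform coverage
with known placements (so the emitted SAM needs no external aligner), and
DEL/DUP/INV/INS events are planted by rearranging the local contig and
regenerating coverage over it.

The rearranged-contig coverage follows ``C_f = VAF · C_o · (L_f / L_o)``
where ``C_o`` is the original coverage and ``L_o``/``L_f`` the original and
rearranged contig lengths.  Spiking replaces a VAF-scaled fraction of the
original read pairs whose fragments fall inside the plan interval with
``round(C_f · L_f / (2 · read_len))`` new pairs simulated from the rearranged
contig: deletions therefore lose depth over the deleted span (down to
``(1 − VAF) · C_o``), duplications and insertions gain reads, and inversions
leave depth unchanged.  Reads crossing a junction are soft-clipped at the
junction in their reference alignment, producing realistic breakpoint signal
for downstream feature extraction.

Synthetic "submissions" are derived from a truth set by breakpoint jitter,
dropout (false negatives), and spurious calls (false positives).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pysam
from intervaltree import IntervalTree

from .model import MaskSet, SVRecord

__all__ = [
    "SpikePlan",
    "ReadMate",
    "ReadPair",
    "ReadSet",
    "generate_reference",
    "write_fasta",
    "simulate_reads",
    "write_sam",
    "rearrange_contig",
    "spike_sv",
    "spike_all",
    "perturb_callset",
    "random_truth",
    "random_masks",
    "read_plan_file",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# --------------------------------------------------------------------------
# Plans and read containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikePlan:
    """One SV spike-in: where, what type, at which allele fraction.

    ``start``/``end`` delimit the 1-based inclusive *assembly interval* (the
    local contig); the event itself acts on the middle of that interval —
    a ``fraction``-sized span for DEL/DUP/INV, the midpoint for INS.
    """

    chrom: str
    start: int
    end: int
    svtype: str
    vaf: float
    fraction: float = 0.5      # middle fraction rearranged (DEL/DUP/INV)
    copies: int = 1            # extra tandem copies (DUP)
    insert_seq: Optional[str] = None  # inserted sequence (INS)

    def __post_init__(self) -> None:
        if self.svtype not in ("DEL", "DUP", "INV", "INS"):
            raise ValueError(f"unsupported spike-in SV type {self.svtype!r}")
        if not 0.0 < self.vaf <= 1.0:
            raise ValueError(f"VAF must be in (0, 1], got {self.vaf}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid plan interval {self.chrom}:{self.start}-{self.end}")
        if self.svtype in ("DEL", "DUP", "INV") and not 0.0 < self.fraction < 1.0:
            raise ValueError(f"{self.svtype} fraction must be in (0, 1), got {self.fraction}")
        if self.svtype == "INS" and not self.insert_seq:
            raise ValueError("INS plan requires insert_seq")
        if self.svtype == "DUP" and self.copies < 1:
            raise ValueError("DUP requires at least one extra copy")

    @property
    def interval_length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ReadMate:
    """One aligned mate: SAM conventions (SEQ in reference-forward orientation)."""

    pos: Optional[int]  # 1-based leftmost aligned position; None = unmapped
    strand: str         # '+' or '-'
    seq: str
    cigar: str


@dataclass
class ReadPair:
    name: str
    chrom: str
    mate1: ReadMate
    mate2: ReadMate
    fragment_start: int    # 1-based; source-contig coordinates for variant reads
    fragment_length: int
    origin: str = "background"  # background | variant


@dataclass
class ReadSet:
    """Simulated paired reads plus the parameters they were generated under."""

    pairs: list[ReadPair]
    read_len: int
    coverage: float
    contigs: dict[str, int]
    fragment_mean: float = 300.0
    fragment_sd: float = 30.0
    spiked_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    ledger: dict = field(default_factory=dict)

    def depth(self, chrom: str, start: int, end: int) -> float:
        """Mean aligned-base depth over [start, end] (1-based inclusive; clips ignored)."""
        span = np.zeros(end - start + 1, dtype=np.int64)
        for pair in self.pairs:
            if pair.chrom != chrom:
                continue
            for mate in (pair.mate1, pair.mate2):
                if mate.pos is None:
                    continue
                aligned = _cigar_aligned_length(mate.cigar)
                lo = max(mate.pos, start)
                hi = min(mate.pos + aligned - 1, end)
                if lo <= hi:
                    span[lo - start: hi - start + 1] += 1
        return float(span.mean())


def _cigar_aligned_length(cigar: str) -> int:
    total = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in "MDN=X":
                total += int(num)
            num = ""
    return total


# --------------------------------------------------------------------------
# Reference and background reads
# --------------------------------------------------------------------------

def generate_reference(length: int, gc: float = 0.5, seed: int = 0, name: str = "chr1") -> dict[str, str]:
    """Deterministic pseudo-random reference sequence with the given GC content."""
    if length <= 0:
        raise ValueError(f"reference length must be positive, got {length}")
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)
    return {name: bases.tobytes().decode()}


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _as_seq_dict(reference: Union[str, dict[str, str]]) -> dict[str, str]:
    if isinstance(reference, dict):
        return reference
    return {"chr1": reference}


def simulate_reads(
    reference: Union[str, dict[str, str]],
    coverage: float,
    read_len: int = 100,
    fragment_mean: float = 300.0,
    fragment_sd: float = 30.0,
    seed: int = 0,
) -> ReadSet:
    """Error-free paired reads uniformly placed over the reference.

    Pair count per contig is ``round(coverage · G / (2 · read_len))``, giving
    mean depth within rounding of the nominal coverage.  Mate 1 is the
    forward-strand read at the fragment start; mate 2 is the reverse-strand
    read at the fragment end.
    """
    if coverage <= 0:
        raise ValueError(f"coverage must be positive, got {coverage}")
    seqs = _as_seq_dict(reference)
    rng = np.random.default_rng(seed)
    pairs: list[ReadPair] = []
    for chrom, seq in seqs.items():
        glen = len(seq)
        n_pairs = round(coverage * glen / (2 * read_len))
        if fragment_sd > 0:
            flens = np.rint(rng.normal(fragment_mean, fragment_sd, size=n_pairs)).astype(int)
        else:
            flens = np.full(n_pairs, int(round(fragment_mean)))
        flens = np.clip(flens, 2 * read_len, glen)
        starts = rng.integers(1, glen - flens + 2)  # 1-based fragment starts
        for i in range(n_pairs):
            start, flen = int(starts[i]), int(flens[i])
            frag = seq[start - 1: start - 1 + flen]
            pairs.append(ReadPair(
                name=f"bg_{chrom}_{i + 1}",
                chrom=chrom,
                mate1=ReadMate(pos=start, strand="+", seq=frag[:read_len], cigar=f"{read_len}M"),
                mate2=ReadMate(pos=start + flen - read_len, strand="-",
                               seq=frag[-read_len:], cigar=f"{read_len}M"),
                fragment_start=start,
                fragment_length=flen,
            ))
    return ReadSet(
        pairs=pairs,
        read_len=read_len,
        coverage=coverage,
        contigs={c: len(s) for c, s in seqs.items()},
        fragment_mean=fragment_mean,
        fragment_sd=fragment_sd,
    )


def write_sam(readset: ReadSet, path: str) -> None:
    """Emit the read set as a coordinate-sorted SAM file (true placements)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": length} for chrom, length in sorted(readset.contigs.items())],
    }
    tid = {chrom: i for i, (chrom, _l) in enumerate(sorted(readset.contigs.items()))}
    segments = []
    for pair in readset.pairs:
        for idx, (mate, other) in enumerate(((pair.mate1, pair.mate2), (pair.mate2, pair.mate1))):
            flag = 0x1
            if mate.pos is not None and other.pos is not None:
                flag |= 0x2
            if mate.pos is None:
                flag |= 0x4
            if other.pos is None:
                flag |= 0x8
            if mate.strand == "-":
                flag |= 0x10
            if other.strand == "-":
                flag |= 0x20
            flag |= 0x40 if idx == 0 else 0x80
            sort_pos = mate.pos if mate.pos is not None else (other.pos or 1)
            segments.append((pair.chrom, sort_pos, pair.name, idx, flag, mate, other))
    segments.sort(key=lambda s: (s[0], s[1], s[2], s[3]))
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for chrom, sort_pos, name, _idx, flag, mate, other in segments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = name
            seg.flag = flag
            seg.reference_id = tid[chrom]
            seg.reference_start = sort_pos - 1
            seg.mapping_quality = 0 if mate.pos is None else 60
            if mate.pos is not None:
                seg.cigarstring = mate.cigar
            seg.next_reference_id = tid[chrom]
            seg.next_reference_start = (other.pos or sort_pos) - 1
            if mate.pos is not None and other.pos is not None:
                lo = min(mate.pos, other.pos)
                hi = max(mate.pos + _cigar_aligned_length(mate.cigar),
                         other.pos + _cigar_aligned_length(other.cigar))
                tlen = hi - lo
                seg.template_length = tlen if mate.pos <= other.pos else -tlen
            seg.query_sequence = mate.seq
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(mate.seq))
            out.write(seg)


# --------------------------------------------------------------------------
# Contig rearrangement
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class _Segment:
    ref_off: Optional[int]  # 0-based offset within the plan interval; None = inserted sequence
    length: int
    strand: str             # '+' or '-' (reverse-complemented span)


def _middle_span(interval_len: int, fraction: float) -> tuple[int, int]:
    span_len = max(1, round(fraction * interval_len))
    off = (interval_len - span_len) // 2
    return off, span_len


def rearrange_contig(contig: str, plan: SpikePlan) -> tuple[str, list[_Segment], list[int]]:
    """Apply the planned rearrangement to a contig.

    Returns the rearranged sequence, the piecewise map from rearranged-contig
    coordinates back to interval offsets (for read placement), and the exact
    junction offsets in rearranged-contig coordinates.
    """
    n = len(contig)
    if n != plan.interval_length:
        raise ValueError(
            f"contig length {n} does not span the plan interval ({plan.interval_length} bp)"
        )
    if plan.svtype == "DEL":
        off, span = _middle_span(n, plan.fraction)
        if span >= n:
            raise ValueError("deletion would remove the entire contig")
        seq = contig[:off] + contig[off + span:]
        segments = [_Segment(0, off, "+"), _Segment(off + span, n - off - span, "+")]
        junctions = [off]
    elif plan.svtype == "DUP":
        off, span = _middle_span(n, plan.fraction)
        span_end = off + span
        seq = contig[:span_end] + contig[off:span_end] * plan.copies + contig[span_end:]
        segments = [_Segment(0, span_end, "+")]
        junctions = []
        cursor = span_end
        for _c in range(plan.copies):
            junctions.append(cursor)
            segments.append(_Segment(off, span, "+"))
            cursor += span
        junctions.append(cursor)
        segments.append(_Segment(span_end, n - span_end, "+"))
    elif plan.svtype == "INV":
        off, span = _middle_span(n, plan.fraction)
        seq = contig[:off] + revcomp(contig[off:off + span]) + contig[off + span:]
        segments = [_Segment(0, off, "+"), _Segment(off, span, "-"),
                    _Segment(off + span, n - off - span, "+")]
        junctions = [off, off + span]
    elif plan.svtype == "INS":
        mid = n // 2
        ins = plan.insert_seq or ""
        seq = contig[:mid] + ins + contig[mid:]
        segments = [_Segment(0, mid, "+"), _Segment(None, len(ins), "+"),
                    _Segment(mid, n - mid, "+")]
        junctions = [mid, mid + len(ins)]
    else:  # pragma: no cover - guarded by SpikePlan
        raise ValueError(plan.svtype)
    segments = [s for s in segments if s.length > 0]
    return seq, segments, junctions


def truth_record(plan: SpikePlan, sv_id: str) -> SVRecord:
    """Reference-coordinate truth record for a spike-in plan (exact breakpoints)."""
    n = plan.interval_length
    if plan.svtype in ("DEL", "DUP", "INV"):
        off, span = _middle_span(n, plan.fraction)
        pos = plan.start + off
        end = pos + span - 1
    else:  # INS: single breakpoint at the base preceding the insertion
        mid = n // 2
        pos = end = plan.start + mid - 1
    return SVRecord(id=sv_id, chrom=plan.chrom, pos=pos, end=end,
                    svtype=plan.svtype, vaf=plan.vaf)


# --------------------------------------------------------------------------
# Spiking
# --------------------------------------------------------------------------

def _place_mate(
    x: int,
    read_len: int,
    contig_strand: str,
    new_seq: str,
    segments: list[_Segment],
    interval_start: int,
) -> ReadMate:
    """Map a read at rearranged-contig offset x to its reference alignment."""
    read_seq = new_seq[x: x + read_len]
    # segment layout in rearranged-contig coordinates
    best = None  # (overlap, seg_start, segment)
    cursor = 0
    for seg in segments:
        s0, s1 = cursor, cursor + seg.length
        cursor = s1
        if seg.ref_off is None:
            continue
        overlap = min(s1, x + read_len) - max(s0, x)
        if overlap > 0 and (best is None or overlap > best[0]):
            best = (overlap, s0, seg)
    if best is None:
        return ReadMate(pos=None, strand=contig_strand, seq=read_seq, cigar="*")
    _overlap, s0, seg = best
    u = max(s0, x)
    v = min(s0 + seg.length, x + read_len)
    m = v - u
    left_clip, right_clip = u - x, x + read_len - v
    if seg.strand == "+":
        ref_pos = interval_start + seg.ref_off + (u - s0)
        strand = contig_strand
        seq, lc, rc = read_seq, left_clip, right_clip
    else:
        ref_pos = interval_start + seg.ref_off + seg.length - (v - s0)
        strand = "-" if contig_strand == "+" else "+"
        seq, lc, rc = revcomp(read_seq), right_clip, left_clip
    cigar = (f"{lc}S" if lc else "") + f"{m}M" + (f"{rc}S" if rc else "")
    return ReadMate(pos=ref_pos, strand=strand, seq=seq, cigar=cigar)


def spike_sv(
    reads: ReadSet,
    reference: Union[str, dict[str, str]],
    plan: SpikePlan,
    seed: int = 0,
    sv_id: Optional[str] = None,
) -> tuple[ReadSet, SVRecord]:
    """Plant one SV into a read set, returning the tumor read set and truth record.

    The local contig is the reference slice over the plan interval (valid for
    error-free reads, replacing the assembly step).  Original pairs whose
    fragments lie inside the interval are each removed with probability VAF
    and ``round(C_f · L_f / (2 · read_len))`` replacement pairs are simulated
    from the rearranged contig, where ``C_f = VAF · C_o · (L_f / L_o)``.
    The returned read set's ``ledger`` records the read-count balance.
    """
    seqs = _as_seq_dict(reference)
    if plan.chrom not in seqs:
        raise ValueError(f"plan chromosome {plan.chrom!r} not in reference")
    seq = seqs[plan.chrom]
    if plan.end > len(seq):
        raise ValueError(f"plan interval {plan.start}-{plan.end} outside contig of length {len(seq)}")
    if plan.interval_length <= 2 * reads.fragment_mean:
        raise ValueError(
            f"plan interval ({plan.interval_length} bp) must exceed twice the "
            f"fragment mean ({reads.fragment_mean} bp)"
        )
    for chrom, lo, hi in reads.spiked_intervals:
        if chrom == plan.chrom and not (plan.end < lo or plan.start > hi):
            raise ValueError(
                f"plan interval {plan.chrom}:{plan.start}-{plan.end} overlaps a prior "
                f"spike at {chrom}:{lo}-{hi}"
            )

    rng = np.random.default_rng(seed)
    contig = seq[plan.start - 1: plan.end]
    new_seq, segments, _junctions = rearrange_contig(contig, plan)
    l_o, l_f = len(contig), len(new_seq)
    c_f = plan.vaf * reads.coverage * (l_f / l_o)
    n_new = round(c_f * l_f / (2 * reads.read_len))

    # replacement: each interval-contained background pair is dropped with prob VAF
    kept: list[ReadPair] = []
    n_removed = 0
    for pair in reads.pairs:
        inside = (
            pair.origin == "background"
            and pair.chrom == plan.chrom
            and pair.fragment_start >= plan.start
            and pair.fragment_start + pair.fragment_length - 1 <= plan.end
        )
        if inside and rng.random() < plan.vaf:
            n_removed += 1
        else:
            kept.append(pair)

    new_pairs: list[ReadPair] = []
    if n_new > 0:
        if reads.fragment_sd > 0:
            flens = np.rint(rng.normal(reads.fragment_mean, reads.fragment_sd, size=n_new)).astype(int)
        else:
            flens = np.full(n_new, int(round(reads.fragment_mean)))
        flens = np.clip(flens, 2 * reads.read_len, l_f)
        starts = rng.integers(0, l_f - flens + 1)  # 0-based contig offsets
        for i in range(n_new):
            x, flen = int(starts[i]), int(flens[i])
            mate1 = _place_mate(x, reads.read_len, "+", new_seq, segments, plan.start)
            mate2 = _place_mate(x + flen - reads.read_len, reads.read_len, "-",
                                new_seq, segments, plan.start)
            new_pairs.append(ReadPair(
                name=f"spk_{plan.chrom}_{plan.start}_{i + 1}",
                chrom=plan.chrom,
                mate1=mate1,
                mate2=mate2,
                fragment_start=x + 1,
                fragment_length=flen,
                origin="variant",
            ))

    tumor = ReadSet(
        pairs=kept + new_pairs,
        read_len=reads.read_len,
        coverage=reads.coverage,
        contigs=dict(reads.contigs),
        fragment_mean=reads.fragment_mean,
        fragment_sd=reads.fragment_sd,
        spiked_intervals=reads.spiked_intervals + [(plan.chrom, plan.start, plan.end)],
        ledger={
            "n_input": len(reads.pairs),
            "n_removed": n_removed,
            "n_simulated": len(new_pairs),
            "n_output": len(kept) + len(new_pairs),
            "c_f": c_f,
            "l_o": l_o,
            "l_f": l_f,
        },
    )
    truth = truth_record(plan, sv_id or f"truth_{plan.chrom}_{plan.start}")
    return tumor, truth


def spike_all(
    reads: ReadSet,
    reference: Union[str, dict[str, str]],
    plans: Sequence[SpikePlan],
    seed: int = 0,
) -> tuple[ReadSet, list[SVRecord]]:
    """Apply several non-overlapping spike-in plans sequentially."""
    for i, a in enumerate(plans):
        for b in plans[i + 1:]:
            if a.chrom == b.chrom and not (a.end < b.start or a.start > b.end):
                raise ValueError(
                    f"plan intervals overlap: {a.chrom}:{a.start}-{a.end} and "
                    f"{b.chrom}:{b.start}-{b.end}"
                )
    rng = np.random.default_rng(seed)
    truths: list[SVRecord] = []
    current = reads
    for i, plan in enumerate(plans):
        current, truth = spike_sv(current, reference, plan,
                                  seed=int(rng.integers(0, 2**31 - 1)),
                                  sv_id=f"truth{i + 1}")
        truths.append(truth)
    return current, truths


# --------------------------------------------------------------------------
# Synthetic truth sets and submissions
# --------------------------------------------------------------------------

def random_truth(
    n: int,
    contigs: dict[str, int],
    seed: int = 0,
    log_mean: float = math.log(1000.0),
    log_sd: float = 0.6,
    svtypes: Sequence[str] = ("DEL", "DUP", "INV", "INS"),
    vafs: Sequence[float] = (0.5, 0.33, 0.2),
) -> list[SVRecord]:
    """Non-overlapping random truth SVs with log-normal lengths.

    Lengths follow the >100 bp regime typical of somatic SVs (log-normal,
    median 1 kb by default); insertions are single-breakpoint records; VAFs
    cycle through the subclonal fractions 0.5/0.33/0.2.
    """
    rng = np.random.default_rng(seed)
    trees = {chrom: IntervalTree() for chrom in contigs}
    names = sorted(contigs)
    weights = np.array([contigs[c] for c in names], dtype=float)
    weights /= weights.sum()
    out: list[SVRecord] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 1000 * n:
            raise RuntimeError(f"could not place {n} non-overlapping SVs (placed {len(out)})")
        chrom = names[int(rng.choice(len(names), p=weights))]
        svtype = svtypes[int(rng.integers(len(svtypes)))]
        length = 1 if svtype == "INS" else max(101, int(round(rng.lognormal(log_mean, log_sd))))
        if length >= contigs[chrom]:
            continue
        pos = int(rng.integers(1, contigs[chrom] - length + 2))
        end = pos + length - 1
        if trees[chrom].overlap(pos, end + 1):
            continue
        trees[chrom].addi(pos, end + 1)
        out.append(SVRecord(
            id=f"truth{len(out) + 1}", chrom=chrom, pos=pos, end=end, svtype=svtype,
            vaf=float(vafs[len(out) % len(vafs)]),
        ))
    out.sort(key=lambda r: (r.chrom, r.pos))
    for i, rec in enumerate(out):
        rec.id = f"truth{i + 1}"
    return out


def random_masks(
    contigs: dict[str, int],
    fraction: float = 0.1,
    region_len: int = 50_000,
    seed: int = 0,
) -> MaskSet:
    """Random non-overlapping mask regions covering ~`fraction` of the genome."""
    rng = np.random.default_rng(seed)
    regions: list[tuple[str, int, int]] = []
    for chrom, glen in sorted(contigs.items()):
        target = int(fraction * glen)
        rlen = min(region_len, max(1, glen // 4))
        tree = IntervalTree()
        covered = 0
        attempts = 0
        while covered < target and attempts < 10_000:
            attempts += 1
            start = int(rng.integers(1, max(2, glen - rlen + 2)))
            end = min(start + rlen - 1, glen)
            if tree.overlap(start, end + 1):
                continue
            tree.addi(start, end + 1)
            regions.append((chrom, start, end))
            covered += end - start + 1
    return MaskSet(sorted(regions))


def perturb_callset(
    truth: Sequence[SVRecord],
    jitter_sd: float = 0.0,
    fn_rate: float = 0.0,
    fp_count: int = 0,
    seed: int = 0,
    contigs: Optional[dict[str, int]] = None,
    fp_exclusion_flank: float = 100.0,
) -> list[SVRecord]:
    """Derive a synthetic submission from a truth set.

    Each truth SV is retained with probability ``1 − fn_rate`` and its
    breakpoints shifted by rounded Gaussian jitter; ``fp_count`` spurious
    calls with truth-like lengths are placed uniformly outside the truth
    regions.  Placement additionally avoids ``fp_exclusion_flank`` bp around
    each truth region so a "false positive" cannot sit within the default
    scoring flank of a truth breakpoint (which would make it a true call).
    """
    if not 0.0 <= fn_rate <= 1.0:
        raise ValueError(f"fn_rate must be in [0, 1], got {fn_rate}")
    if jitter_sd < 0 or fp_count < 0:
        raise ValueError("jitter_sd and fp_count must be non-negative")
    rng = np.random.default_rng(seed)
    truth = list(truth)
    if contigs is None:
        contigs = {}
        for rec in truth:
            contigs[rec.chrom] = max(contigs.get(rec.chrom, 0), rec.end + 10_000)

    calls: list[SVRecord] = []
    for rec in truth:
        if rng.random() < fn_rate:
            continue
        jit = (int(round(rng.normal(0, jitter_sd))) if jitter_sd > 0 else 0,
               int(round(rng.normal(0, jitter_sd))) if jitter_sd > 0 else 0)
        pos = max(1, rec.pos + jit[0])
        end = pos if rec.is_single_breakpoint else max(pos, rec.end + jit[1])
        calls.append(replace(rec, id=f"call{len(calls) + 1}", pos=pos, end=end,
                             subset="unassigned", vaf=None))

    trees: dict[str, IntervalTree] = {}
    margin = int(fp_exclusion_flank)
    for rec in truth:
        trees.setdefault(rec.chrom, IntervalTree()).addi(
            max(1, rec.pos - margin), rec.end + 1 + margin)
    lengths = [rec.length for rec in truth] or [1000]
    names = sorted(contigs)
    weights = np.array([contigs[c] for c in names], dtype=float)
    weights /= weights.sum()
    placed = 0
    attempts = 0
    while placed < fp_count:
        attempts += 1
        if attempts > 1000 * max(1, fp_count):
            raise RuntimeError("could not place the requested false-positive calls")
        chrom = names[int(rng.choice(len(names), p=weights))]
        length = int(lengths[int(rng.integers(len(lengths)))])
        if length >= contigs[chrom]:
            continue
        pos = int(rng.integers(1, contigs[chrom] - length + 2))
        end = pos + length - 1
        if chrom in trees and trees[chrom].overlap(pos, end + 1):
            continue
        placed += 1
        calls.append(SVRecord(id=f"call{len(calls) + 1}", chrom=chrom, pos=pos, end=end,
                              svtype="DEL"))
    calls.sort(key=lambda r: (r.chrom, r.pos))
    for i, rec in enumerate(calls):
        rec.id = f"call{i + 1}"
    return calls


def read_plan_file(path: str) -> list[SpikePlan]:
    """Read spike-in plans, one per line: ``chrom start end svtype vaf [param]``.

    The optional parameter is the rearranged middle fraction for DEL/INV,
    the extra copy count for DUP, and the inserted sequence for INS.
    """
    plans: list[SpikePlan] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected 'chrom start end svtype vaf [param]'")
            chrom, start, end, svtype, vaf = fields[:5]
            kwargs = {}
            if len(fields) > 5:
                param = fields[5]
                if svtype in ("DEL", "INV"):
                    kwargs["fraction"] = float(param)
                elif svtype == "DUP":
                    if "." in param:
                        kwargs["fraction"] = float(param)
                    else:
                        kwargs["copies"] = int(param)
                elif svtype == "INS":
                    kwargs["insert_seq"] = param
            if svtype == "INS" and "insert_seq" not in kwargs:
                raise ValueError(f"{path}:{lineno}: INS plan requires an insert sequence")
            plans.append(SpikePlan(chrom=chrom, start=int(start), end=int(end),
                                   svtype=svtype, vaf=float(vaf), **kwargs))
    return plans
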