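"""Structural-variant data model, VCF I/O, preprocessing, and train/test allocation.

The public coordinate convention is the VCF one: 1-based positions with an
inclusive END.  Interval arithmetic is done half-open internally and converted
at the boundary.

SVs are represented by :class:`SVRecord`.  Break-end (BND) records carry their
breakend ALT string so that mate synthesis and BND→typed conversion can use
the VCFv4.1 adjacency semantics.  Rows with ``SVTYPE=MSK`` inside a truth VCF
do not describe variants: they define the masked (held-out) genomic regions
used to allocate truth SVs to the testing set.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pysam

KNOWN_SVTYPES = {"CNV", "DEL", "DUP", "INS", "INV", "BND"}
_ALL_TYPES = KNOWN_SVTYPES | {"MSK"}

__all__ = [
    "SVRecord",
    "MaskSet",
    "VCFParseError",
    "PreprocessError",
    "parse_sv_vcf",
    "write_sv_vcf",
    "read_mask_bed",
    "preprocess_vcf",
    "assign_train_test",
    "mask_overlap_fraction",
]


class VCFParseError(ValueError):
    """Raised when a VCF row cannot be interpreted as an SV record."""


class PreprocessError(ValueError):
    """Raised for irreparable record collections (mate cycles, bad mate geometry)."""


@dataclass
class SVRecord:
    """One called or known structural variant.

    ``pos`` and ``end`` are 1-based inclusive breakpoints.  For BND and
    insertion-style single-breakpoint records ``end == pos``.
    """

    id: str
    chrom: str
    pos: int
    end: int
    svtype: str
    mate_id: Optional[str] = None
    event: Optional[str] = None
    filter_pass: bool = True
    subset: str = "unassigned"  # train | test | unassigned
    ref: str = "N"
    alt: Optional[str] = None
    vaf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VCFParseError(f"record {self.id}: POS must be >= 1, got {self.pos}")
        if self.svtype != "BND" and self.end < self.pos:
            raise VCFParseError(
                f"record {self.id}: END {self.end} < POS {self.pos} for non-BND record"
            )

    @property
    def length(self) -> int:
        """Span in bp under inclusive coordinates (1 for single-breakpoint records)."""
        return self.end - self.pos + 1

    @property
    def is_single_breakpoint(self) -> bool:
        return self.end == self.pos


@dataclass
class MaskSet:
    """Masked genomic regions (1-based inclusive) defining the testing set."""

    regions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.regions:
            if start > end or start < 1:
                raise ValueError(f"invalid mask interval {chrom}:{start}-{end}")

    def merged(self) -> dict[str, list[tuple[int, int]]]:
        """Per-chromosome union of mask intervals, sorted and non-overlapping."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.regions:
            by_chrom.setdefault(chrom, []).append((start, end))
        merged: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            out: list[tuple[int, int]] = []
            for start, end in ivals:
                if out and start <= out[-1][1] + 1:
                    out[-1] = (out[-1][0], max(out[-1][1], end))
                else:
                    out.append((start, end))
            merged[chrom] = out
        return merged


# --------------------------------------------------------------------------
# VCF parsing / writing
# --------------------------------------------------------------------------

def _record_filter_pass(rec: "pysam.VariantRecord") -> bool:
    # "." (no filter applied) is treated as passing, like PASS.
    keys = list(rec.filter.keys())
    return not keys or keys == ["PASS"]


def parse_sv_vcf(path: str) -> tuple[list[SVRecord], MaskSet]:
    """Parse a VCF v4.1 file into SV records and a mask set.

    END resolution order: ``INFO/END`` → ``POS + len(REF) − 1`` → ``POS``
    (pysam's ``stop`` implements exactly this chain).  Rows whose FILTER is
    neither PASS nor "." are kept but flagged ``filter_pass=False``; rows with
    ``SVTYPE=MSK`` are routed to the returned :class:`MaskSet`.
    """
    records: list[SVRecord] = []
    masks: list[tuple[str, int, int]] = []
    with pysam.VariantFile(str(path)) as vf:
        it = iter(vf)
        row = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                break
            except Exception as exc:  # htslib parse failure
                raise VCFParseError(f"{path}: malformed VCF record #{row + 1}: {exc}") from exc
            row += 1
            try:
                records_or_mask = _convert_pysam_record(rec, row)
            except VCFParseError:
                raise
            except Exception as exc:
                raise VCFParseError(f"{path}: record #{row}: {exc}") from exc
            if isinstance(records_or_mask, tuple):
                masks.append(records_or_mask)
            elif records_or_mask is not None:
                records.append(records_or_mask)
    return records, MaskSet(masks)


_BREAKEND_RE = re.compile(
    r"^(?P<t1>[A-Za-z.]*)(?P<b1>[\[\]])(?P<chrom>[^\[\]:]+):(?P<pos>\d+)(?P<b2>[\[\]])(?P<t2>[A-Za-z.]*)$"
)


def _info_get(rec: "pysam.VariantRecord", key: str):
    # pysam raises on keys absent from the header; treat those as unset
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def _convert_pysam_record(rec: "pysam.VariantRecord", row: int):
    if rec.pos < 1:
        raise VCFParseError(f"record #{row} ({rec.id}): non-positive POS {rec.pos}")
    svtype = _info_get(rec, "SVTYPE")
    alt = rec.alts[0] if rec.alts else None
    if svtype is None:
        if alt and _BREAKEND_RE.match(alt):
            svtype = "BND"
        elif alt and alt.startswith("<") and alt.endswith(">"):
            svtype = alt[1:-1]
        else:
            raise VCFParseError(f"record #{row} ({rec.id}): cannot determine SVTYPE")
    svtype = str(svtype)
    pos = rec.pos
    end = rec.stop  # INFO/END, else pos + rlen - 1, else pos (1-based inclusive)
    if svtype == "MSK":
        return (rec.chrom, pos, max(end, pos))
    if svtype == "BND":
        end = pos
    mate = _info_get(rec, "MATEID")
    if isinstance(mate, tuple):
        mate = mate[0]
    event = _info_get(rec, "EVENT")
    vaf = _info_get(rec, "VAF")
    if isinstance(vaf, tuple):
        vaf = vaf[0]
    return SVRecord(
        id=rec.id or f"row{row}",
        chrom=rec.chrom,
        pos=pos,
        end=max(end, pos) if svtype != "BND" else pos,
        svtype=svtype,
        mate_id=str(mate) if mate is not None else None,
        event=str(event) if event is not None else None,
        filter_pass=_record_filter_pass(rec),
        ref=rec.ref or "N",
        alt=alt,
        vaf=float(vaf) if vaf is not None else None,
    )


def _build_header(
    records: Sequence[SVRecord],
    masks: Optional[MaskSet],
    contigs: Optional[dict[str, int]],
) -> "pysam.VariantHeader":
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.1')
    header.add_meta("INFO", items=[("ID", "SVTYPE"), ("Number", "1"), ("Type", "String"),
                                   ("Description", "Type of structural variant")])
    header.add_meta("INFO", items=[("ID", "END"), ("Number", "1"), ("Type", "Integer"),
                                   ("Description", "End position of the variant")])
    header.add_meta("INFO", items=[("ID", "MATEID"), ("Number", "1"), ("Type", "String"),
                                   ("Description", "ID of mate breakend")])
    header.add_meta("INFO", items=[("ID", "EVENT"), ("Number", "1"), ("Type", "String"),
                                   ("Description", "ID of event associated to breakend")])
    header.add_meta("INFO", items=[("ID", "VAF"), ("Number", "1"), ("Type", "Float"),
                                   ("Description", "Variant allele fraction of the spiked variant")])
    header.add_meta("INFO", items=[("ID", "SUPP"), ("Number", "1"), ("Type", "Integer"),
                                   ("Description", "Number of distinct submissions supporting an ensemble call")])
    header.add_meta("FILTER", items=[("ID", "LowQual"), ("Description", "Failed caller quality filter")])
    if contigs is None:
        contigs = {}
        for rec in records:
            contigs[rec.chrom] = max(contigs.get(rec.chrom, 0), rec.end, rec.pos)
        if masks is not None:
            for chrom, _start, end in masks.regions:
                contigs[chrom] = max(contigs.get(chrom, 0), end)
        contigs = {c: length + 1000 for c, length in contigs.items()}
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    return header


def write_sv_vcf(
    records: Sequence[SVRecord],
    path: str,
    masks: Optional[MaskSet] = None,
    contigs: Optional[dict[str, int]] = None,
    supp: Optional[dict[str, int]] = None,
) -> None:
    """Write SV records (and optional mask rows) as an uncompressed VCF v4.1 file."""
    header = _build_header(records, masks, contigs)
    rows: list[tuple[str, int, SVRecord | tuple]] = []
    for rec in records:
        rows.append((rec.chrom, rec.pos, rec))
    if masks is not None:
        for i, (chrom, start, end) in enumerate(masks.regions):
            rows.append((chrom, start, ("MSK", f"msk{i + 1}", chrom, start, end)))
    rows.sort(key=lambda r: (r[0], r[1]))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for _chrom, _pos, item in rows:
            if isinstance(item, SVRecord):
                vrec = out.new_record(
                    contig=item.chrom,
                    start=item.pos - 1,
                    stop=item.end,
                    alleles=(item.ref, item.alt or f"<{item.svtype}>"),
                    id=item.id,
                )
                vrec.info["SVTYPE"] = item.svtype
                if item.mate_id is not None:
                    vrec.info["MATEID"] = item.mate_id
                if item.event is not None:
                    vrec.info["EVENT"] = item.event
                if item.vaf is not None:
                    vrec.info["VAF"] = item.vaf
                if supp and item.id in supp:
                    vrec.info["SUPP"] = supp[item.id]
                if not item.filter_pass:
                    vrec.filter.add("LowQual")
                else:
                    vrec.filter.add("PASS")
            else:
                _tag, mid, chrom, start, end = item
                vrec = out.new_record(
                    contig=chrom, start=start - 1, stop=end,
                    alleles=("N", "<MSK>"), id=mid,
                )
                vrec.info["SVTYPE"] = "MSK"
                vrec.filter.add("PASS")
            out.write(vrec)


def read_mask_bed(path: str) -> MaskSet:
    """Read mask regions from a BED file (0-based half-open → 1-based inclusive)."""
    regions: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"BED line with fewer than 3 columns: {line!r}")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            regions.append((chrom, start + 1, end))
    return MaskSet(regions)


# --------------------------------------------------------------------------
# Preprocessing
# --------------------------------------------------------------------------

def _parse_breakend(alt: str) -> Optional[tuple[str, int, str]]:
    """Decompose a breakend ALT into (mate_chrom, mate_pos, orientation).

    Orientations follow the four VCFv4.1 adjacency classes:
    ``right_after`` t[p[, ``left_before`` ]p]t, ``left_after`` t]p],
    ``right_before`` [p[t.
    """
    m = _BREAKEND_RE.match(alt)
    if not m or m.group("b1") != m.group("b2"):
        return None
    bracket = m.group("b1")
    t_before, t_after = m.group("t1"), m.group("t2")
    if bracket == "[":
        orient = "right_after" if t_before else "right_before"
    else:
        orient = "left_before" if t_after else "left_after"
    return m.group("chrom"), int(m.group("pos")), orient


_RECIPROCAL = {
    "right_after": "left_before",
    "left_before": "right_after",
    "left_after": "left_after",
    "right_before": "right_before",
}


def _breakend_alt(orient: str, t: str, chrom: str, pos: int) -> str:
    if orient == "right_after":
        return f"{t}[{chrom}:{pos}["
    if orient == "left_before":
        return f"]{chrom}:{pos}]{t}"
    if orient == "left_after":
        return f"{t}]{chrom}:{pos}]"
    return f"[{chrom}:{pos}[{t}"


def preprocess_vcf(records: Iterable[SVRecord]) -> list[SVRecord]:
    """Normalize a parsed record collection for scoring.

    Removes filter-failing records, drops records with SV types outside the
    controlled vocabulary (with a warning), repairs MATEID pairs by
    synthesizing missing partners from the breakend ALT, re-assigns globally
    unique IDs, and rewrites same-chromosome BND mate pairs with canonical
    DEL/DUP/INV adjacency geometry as single typed records.  Unconvertible
    BNDs are retained as BND.
    """
    kept: list[SVRecord] = []
    for rec in records:
        if not rec.filter_pass:
            continue
        if rec.svtype not in KNOWN_SVTYPES:
            warnings.warn(
                f"record {rec.id}: invalid SVTYPE {rec.svtype!r}; excluded from scoring",
                stacklevel=2,
            )
            continue
        kept.append(replace(rec))

    # duplicated input ids get disambiguated before mate resolution; an
    # ambiguous mate reference is left pointing at the first occurrence
    by_id: dict[str, SVRecord] = {}
    for rec in kept:
        rid = rec.id
        n = 1
        while rid in by_id:
            n += 1
            rid = f"{rec.id}.{n}"
        rec.id = rid
        by_id[rid] = rec

    # mate-pair validation and repair
    synthesized: list[SVRecord] = []
    for rec in list(by_id.values()):
        if rec.mate_id is None:
            continue
        mate = by_id.get(rec.mate_id)
        if mate is not None:
            if mate.mate_id is not None and mate.mate_id not in (rec.id, rec.mate_id):
                if by_id.get(mate.mate_id) is not rec:
                    raise PreprocessError(
                        f"MATEID cycle of length > 2 involving {rec.id} -> {rec.mate_id} -> {mate.mate_id}"
                    )
            if mate.chrom != rec.chrom and (rec.svtype != "BND" or mate.svtype != "BND"):
                raise PreprocessError(
                    f"mate pair {rec.id}/{mate.id} spans chromosomes but is not BND-typed"
                )
            if mate.mate_id is None:
                mate.mate_id = rec.id
            continue
        # synthesize the missing partner from this record's breakend ALT
        be = _parse_breakend(rec.alt or "")
        if be is None:
            warnings.warn(
                f"record {rec.id}: MATEID {rec.mate_id} unresolvable (no breakend ALT); dropping mate link",
                stacklevel=2,
            )
            rec.mate_id = None
            continue
        mchrom, mpos, orient = be
        if mchrom != rec.chrom and rec.svtype != "BND":
            raise PreprocessError(
                f"record {rec.id}: mate on different chromosome with non-BND type {rec.svtype}"
            )
        partner = SVRecord(
            id=rec.mate_id,
            chrom=mchrom,
            pos=mpos,
            end=mpos,
            svtype="BND",
            mate_id=rec.id,
            event=rec.event,
            alt=_breakend_alt(_RECIPROCAL[orient], "N", rec.chrom, rec.pos),
        )
        synthesized.append(partner)
        by_id[partner.id] = partner
    kept.extend(synthesized)

    # globally unique sequential ids
    id_map = {rec.id: f"sv{i + 1}" for i, rec in enumerate(kept)}
    for rec in kept:
        rec.id = id_map[rec.id]
        if rec.mate_id is not None:
            rec.mate_id = id_map.get(rec.mate_id, rec.mate_id)

    return _convert_bnd_pairs(kept)


_BND_PAIR_TYPES = {
    ("right_after", "left_before"): "DEL",
    ("left_before", "right_after"): "DUP",
    ("left_after", "left_after"): "INV",
    ("right_before", "right_before"): "INV",
}


def _convert_bnd_pairs(records: list[SVRecord]) -> list[SVRecord]:
    by_id = {rec.id: rec for rec in records}
    consumed: set[str] = set()
    out: list[SVRecord] = []
    for rec in records:
        if rec.id in consumed:
            continue
        if rec.svtype != "BND" or rec.mate_id is None:
            out.append(rec)
            continue
        mate = by_id.get(rec.mate_id)
        if mate is None or mate.svtype != "BND" or mate.chrom != rec.chrom:
            out.append(rec)
            continue
        lo, hi = (rec, mate) if rec.pos <= mate.pos else (mate, rec)
        be_lo = _parse_breakend(lo.alt or "")
        be_hi = _parse_breakend(hi.alt or "")
        svtype = None
        if be_lo and be_hi:
            svtype = _BND_PAIR_TYPES.get((be_lo[2], be_hi[2]))
        if svtype is None:
            out.append(rec)  # unconvertible geometry stays BND
            continue
        consumed.add(rec.id)
        consumed.add(mate.id)
        out.append(
            SVRecord(
                id=lo.id,
                chrom=lo.chrom,
                pos=lo.pos,
                end=hi.pos,
                svtype=svtype,
                event=lo.event or hi.event,
                subset=lo.subset,
            )
        )
    return out


# --------------------------------------------------------------------------
# Train/test allocation
# --------------------------------------------------------------------------

def mask_overlap_fraction(rec: SVRecord, merged: dict[str, list[tuple[int, int]]]) -> float:
    """Fraction of the record's [pos, end] covered by the union of mask regions."""
    ivals = merged.get(rec.chrom)
    if not ivals:
        return 0.0
    covered = 0
    for start, end in ivals:
        if end < rec.pos:
            continue
        if start > rec.end:
            break
        covered += min(end, rec.end) - max(start, rec.pos) + 1
    return covered / rec.length


def assign_train_test(records: Iterable[SVRecord], masks: MaskSet) -> list[SVRecord]:
    """Allocate each SV to the testing set iff ≥50% of its region is masked."""
    merged = masks.merged()
    out = []
    for rec in records:
        frac = mask_overlap_fraction(rec, merged)
        out.append(replace(rec, subset="test" if frac >= 0.5 else "train"))
    return out
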