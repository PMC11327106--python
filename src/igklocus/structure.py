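"""Structural genotyping: insertion SV, gene conversion, inversions.

The insertion SV is genotyped from coverage of its payload footprint
on the SV-inclusive reference — an assembly either aligns across the
payload (present) or skips it with a deletion (deleted).  The gene
conversion is genotyped by comparing the haplotype's acceptor-window
sequence to the proximal donor and to the distal reference: identity
to the donor exceeding identity to the acceptor by a margin marks the
converted haplotype.  Inversions are detected from orientation flips
among alignment records of a single contig.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .alignio import (
    DEL,
    MATCH,
    MISMATCH,
    AlignmentRecord,
    extract_target_span,
)
from .errors import ValidationError
from .locus import GenomicInterval, SvDefinition

PRESENT, SV_DELETED, NO_CALL = "present", "deleted", "no-call"
REFERENCE, CONVERTED = "reference", "converted"


@dataclass
class InversionCall:
    breakpoint_left: int
    breakpoint_right: int
    evidence: int  # number of contigs/reads showing the flip


@dataclass
class StructureGenotype:
    sample: str
    haplotype_id: str
    sv_calls: dict[str, str] = field(default_factory=dict)
    conversion_state: str = NO_CALL
    conversion_identity_donor: float = float("nan")
    conversion_identity_reference: float = float("nan")
    inversion_calls: list[InversionCall] = field(default_factory=list)


def _base_covered_fraction(records, interval: GenomicInterval) -> float:
    """Fraction of interval covered by aligned bases (=/X ops only)."""
    s, e = interval.start, interval.end
    covered = 0
    for rec in records:
        if rec.target_start >= e or rec.target_end <= s:
            continue
        for op, n, tpos, _q in rec.walk():
            if op in (MATCH, MISMATCH):
                covered += max(0, min(tpos + n, e) - max(tpos, s))
    return covered / interval.length()


def _span_covered(records, start: int, end: int) -> bool:
    return any(
        rec.target_start <= start and rec.target_end >= end for rec in records
    ) or _merged_span_covers(records, start, end)


def _merged_span_covers(records, start, end) -> bool:
    spans = sorted((r.target_start, r.target_end) for r in records)
    cursor = start
    for s, e in spans:
        if s > cursor:
            return False
        cursor = max(cursor, e)
        if cursor >= end:
            return True
    return cursor >= end


def genotype_sv(
    records: list[AlignmentRecord],
    sv: SvDefinition,
    min_covered_fraction: float = 0.9,
    max_deleted_fraction: float = 0.1,
    flank: int = 500,
) -> str:
    """Genotype an insertion SV from payload-footprint coverage.

    present: >= min_covered_fraction of the payload is covered by
    aligned bases; deleted: <= max_deleted_fraction covered while both
    flanks are aligned (so absence is observed, not missing data);
    otherwise no-call.
    """
    if sv.kind != "insertion":
        raise ValidationError(f"genotype_sv expects an insertion SV, got {sv.kind}")
    frac = _base_covered_fraction(records, sv.anchor)
    if frac >= min_covered_fraction:
        return PRESENT
    left_ok = _span_covered(
        records, max(0, sv.anchor.start - flank), sv.anchor.start
    )
    right_ok = _span_covered(records, sv.anchor.end, sv.anchor.end + flank)
    if frac <= max_deleted_fraction and left_ok and right_ok:
        return SV_DELETED
    return NO_CALL


def _identity(a: str, b: str) -> float:
    if not a and not b:
        return 1.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def genotype_conversion(
    records: list[AlignmentRecord],
    hap_seq: str,
    window: GenomicInterval,
    donor_seq: str,
    acceptor_ref_seq: str,
    margin: float = 0.002,
    min_aligned_fraction: float = 0.8,
) -> tuple[str, float, float]:
    """Genotype the gene-conversion haplotype by donor-vs-acceptor identity.

    Extracts the haplotype sequence over the acceptor window, computes
    identity to the proximal donor (I_p) and to the distal reference
    (I_d); converted iff I_p - I_d > margin, reference iff
    I_d - I_p > margin, else no-call.  Returns (state, I_p, I_d).
    """
    overlapping = [
        r
        for r in records
        if r.target_start < window.end and r.target_end > window.start
    ]
    best_seq, best_cov = "", 0
    for rec in overlapping:
        seq, cov = extract_target_span(rec, hap_seq, window.start, window.end)
        if cov > best_cov:
            best_seq, best_cov = seq, cov
    if best_cov < min_aligned_fraction * window.length():
        return NO_CALL, float("nan"), float("nan")
    i_p = _identity(best_seq, donor_seq)
    i_d = _identity(best_seq, acceptor_ref_seq)
    if i_p - i_d > margin:
        return CONVERTED, i_p, i_d
    if i_d - i_p > margin:
        return REFERENCE, i_p, i_d
    return NO_CALL, i_p, i_d


def detect_inversion(
    records: list[AlignmentRecord], merge_tolerance: int = 100
) -> list[InversionCall]:
    """Call inversions from orientation flips within single contigs.

    A contig aligning in >= 2 records of opposite orientation, with the
    flipped segment adjacent/nested within the locus, yields a call
    whose breakpoints are the facing ends of the flipped segment.
    Calls with breakpoints within the merge tolerance are pooled and
    their supporting contigs counted as evidence.
    """
    by_query: dict[str, list[AlignmentRecord]] = {}
    for r in records:
        by_query.setdefault(r.query_id, []).append(r)

    raw: list[tuple[int, int, str]] = []
    for qid, recs in by_query.items():
        orientations = {r.orientation for r in recs}
        if len(orientations) < 2:
            continue
        recs = sorted(recs, key=lambda r: r.target_start)
        n_fwd = sum(r.orientation == "forward" for r in recs)
        n_rev = len(recs) - n_fwd
        minority = "reverse" if n_rev <= n_fwd else "forward"
        for r in recs:
            if r.orientation == minority:
                raw.append((r.target_start, r.target_end, qid))

    calls: list[dict] = []
    for left, right, qid in sorted(raw):
        for c in calls:
            if (
                abs(c["left"] - left) <= merge_tolerance
                and abs(c["right"] - right) <= merge_tolerance
            ):
                c["support"].add(qid)
                break
        else:
            calls.append({"left": left, "right": right, "support": {qid}})
    return [
        InversionCall(c["left"], c["right"], len(c["support"])) for c in calls
    ]


def genotype_structure(
    records: list[AlignmentRecord],
    hap_seq: str,
    locus,
    reference: str,
    sample: str,
    hap_id: str,
    conversion_margin: float = 0.002,
    min_covered_fraction: float = 0.9,
    max_deleted_fraction: float = 0.1,
) -> StructureGenotype:
    """All structural genotypes for one haplotype."""
    from .simulate import donor_interval

    out = StructureGenotype(sample=sample, haplotype_id=hap_id)
    for sv in locus.sv_definitions:
        if sv.kind == "insertion":
            out.sv_calls[sv.sv_id] = genotype_sv(
                records,
                sv,
                min_covered_fraction=min_covered_fraction,
                max_deleted_fraction=max_deleted_fraction,
            )
    if locus.conversion_window is not None:
        win = locus.conversion_window
        donor = donor_interval(locus)
        state, i_p, i_d = genotype_conversion(
            records,
            hap_seq,
            win,
            reference[donor.start : donor.end],
            reference[win.start : win.end],
            margin=conversion_margin,
        )
        out.conversion_state = state
        out.conversion_identity_donor = i_p
        out.conversion_identity_reference = i_d
    out.inversion_calls = detect_inversion(records)
    return out
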