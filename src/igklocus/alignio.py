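"""Alignment records, CIGAR handling, and PAF/SAM input.

The pipeline consumes pairwise alignments of haplotype assemblies (or
long reads) to a reference.  Records keep an explicit op list with
match/mismatch distinguished (``=``/``X``), plus insertions (``I``) and
deletions (``D``) relative to the query, so downstream SNV calling and
feature extraction never need to re-align.  Plain ``M`` ops from SAM
input are resolved to ``=``/``X`` against the provided sequences.

Convention: ops are listed in target order.  For a reverse-orientation
record the aligned query segment in target orientation is the reverse
complement of the forward-strand query slice [query_start, query_end).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ValidationError

MATCH, MISMATCH, INS, DEL = "=", "X", "I", "D"
_CONSUMES_TARGET = {MATCH: True, MISMATCH: True, INS: False, DEL: True}
_CONSUMES_QUERY = {MATCH: True, MISMATCH: True, INS: True, DEL: False}

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def cigar_to_ops(cg: str) -> list[tuple[str, int]]:
    ops = [(op, int(n)) for n, op in _CIGAR_RE.findall(cg)]
    if sum(n for _, n in ops) == 0 or "".join(
        f"{n}{op}" for op, n in ops
    ) != cg:
        raise ValidationError(f"malformed CIGAR {cg!r}")
    return ops


def ops_to_cigar(ops: list[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in ops)


@dataclass
class AlignmentRecord:
    query_id: str
    query_length: int
    query_start: int  # forward-strand query coordinates, half-open
    query_end: int
    target_id: str
    target_length: int
    target_start: int
    target_end: int
    orientation: str  # "forward" | "reverse"
    ops: list[tuple[str, int]] = field(default_factory=list)

    def validate(self) -> None:
        tlen = sum(n for op, n in self.ops if _CONSUMES_TARGET[op])
        qlen = sum(n for op, n in self.ops if _CONSUMES_QUERY[op])
        tpos, qpos = self.target_start, 0
        for op, n in self.ops:
            if n <= 0:
                raise ValidationError(
                    f"{self.query_id}: non-positive op length at target {tpos}"
                )
            if _CONSUMES_TARGET[op]:
                tpos += n
            if _CONSUMES_QUERY[op]:
                qpos += n
        if tlen != self.target_end - self.target_start:
            raise ValidationError(
                f"{self.query_id}: CIGAR target length {tlen} != span "
                f"{self.target_end - self.target_start} "
                f"(first inconsistency at target {self.target_start + tlen})"
            )
        if qlen != self.query_end - self.query_start:
            raise ValidationError(
                f"{self.query_id}: CIGAR query length {qlen} != span "
                f"{self.query_end - self.query_start}"
            )

    def aligned_query(self, query_seq: str) -> str:
        """Query segment oriented along the target."""
        seg = query_seq[self.query_start : self.query_end]
        return revcomp(seg) if self.orientation == "reverse" else seg

    def n_matches(self) -> int:
        return sum(n for op, n in self.ops if op == MATCH)

    def walk(self):
        """Yield (op, length, target_pos, query_offset) per op.

        query_offset indexes into the target-oriented aligned query
        segment (see :meth:`aligned_query`).
        """
        tpos, qoff = self.target_start, 0
        for op, n in self.ops:
            yield op, n, tpos, qoff
            if _CONSUMES_TARGET[op]:
                tpos += n
            if _CONSUMES_QUERY[op]:
                qoff += n


def make_record(
    query_id: str,
    query_length: int,
    query_start: int,
    target_id: str,
    target_length: int,
    target_start: int,
    orientation: str,
    ops: list[tuple[str, int]],
) -> AlignmentRecord:
    """Build a record with end coordinates derived from the op list."""
    tspan = sum(n for op, n in ops if _CONSUMES_TARGET[op])
    qspan = sum(n for op, n in ops if _CONSUMES_QUERY[op])
    rec = AlignmentRecord(
        query_id=query_id,
        query_length=query_length,
        query_start=query_start,
        query_end=query_start + qspan,
        target_id=target_id,
        target_length=target_length,
        target_start=target_start,
        target_end=target_start + tspan,
        orientation=orientation,
        ops=ops,
    )
    rec.validate()
    return rec


def compress_ops(expanded: str) -> list[tuple[str, int]]:
    """Run-length encode a string of per-column op codes."""
    ops: list[tuple[str, int]] = []
    for ch in expanded:
        if ops and ops[-1][0] == ch:
            ops[-1] = (ch, ops[-1][1] + 1)
        else:
            ops.append((ch, 1))
    return ops


def ops_from_sequences(query_seg: str, target_seg: str) -> list[tuple[str, int]]:
    """Gapless =/X op list for two equal-length sequences."""
    if len(query_seg) != len(target_seg):
        raise ValidationError("gapless op derivation requires equal lengths")
    ops: list[tuple[str, int]] = []
    run_op, run_len = None, 0
    for q, t in zip(query_seg, target_seg):
        op = MATCH if q == t else MISMATCH
        if op == run_op:
            run_len += 1
        else:
            if run_op is not None:
                ops.append((run_op, run_len))
            run_op, run_len = op, 1
    if run_op is not None:
        ops.append((run_op, run_len))
    return ops


# ---------------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------------

def write_paf(records: list[AlignmentRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            aln_len = sum(n for _, n in r.ops)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.query_id,
                        r.query_length,
                        r.query_start,
                        r.query_end,
                        "+" if r.orientation == "forward" else "-",
                        r.target_id,
                        r.target_length,
                        r.target_start,
                        r.target_end,
                        r.n_matches(),
                        aln_len,
                        60,
                        "cg:Z:" + ops_to_cigar(r.ops),
                    )
                )
                + "\n"
            )


def read_paf(path) -> list[AlignmentRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ValidationError(f"{path}: row {lineno}: short PAF row")
            cg = None
            for tag in fields[12:]:
                if tag.startswith("cg:Z:"):
                    cg = tag[5:]
            if cg is None:
                raise ValidationError(f"{path}: row {lineno}: missing cg:Z tag")
            rec = AlignmentRecord(
                query_id=fields[0],
                query_length=int(fields[1]),
                query_start=int(fields[2]),
                query_end=int(fields[3]),
                orientation="forward" if fields[4] == "+" else "reverse",
                target_id=fields[5],
                target_length=int(fields[6]),
                target_start=int(fields[7]),
                target_end=int(fields[8]),
                ops=cigar_to_ops(cg),
            )
            rec.validate()
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# SAM (text or BAM, via pysam)
# ---------------------------------------------------------------------------

def read_sam(path, reference: dict[str, str] | None = None) -> list[AlignmentRecord]:
    """Read alignments from SAM/BAM, resolving M ops to =/X.

    ``reference`` maps target name to sequence; required only when the
    file uses plain M ops.
    """
    import pysam

    records = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            ops = _sam_ops(aln, reference)
            qlen = aln.infer_read_length() or len(aln.query_sequence or "")
            qspan = sum(n for op, n in ops if _CONSUMES_QUERY[op])
            # SAM stores the query in target orientation; recover
            # forward-strand coordinates for the record contract
            clip_left = (
                aln.cigartuples[0][1]
                if aln.cigartuples[0][0] in (4, 5)
                else 0
            )
            if aln.is_reverse:
                qstart = qlen - clip_left - qspan
            else:
                qstart = clip_left
            rec = AlignmentRecord(
                query_id=aln.query_name,
                query_length=qlen,
                query_start=qstart,
                query_end=qstart + qspan,
                target_id=aln.reference_name,
                target_length=fh.get_reference_length(aln.reference_name),
                target_start=aln.reference_start,
                target_end=aln.reference_end,
                orientation="reverse" if aln.is_reverse else "forward",
                ops=ops,
            )
            rec.validate()
            records.append(rec)
    return records


def _sam_ops(aln, reference) -> list[tuple[str, int]]:
    code = {0: "M", 1: INS, 2: DEL, 7: MATCH, 8: MISMATCH}
    ops: list[tuple[str, int]] = []
    tpos = aln.reference_start
    qpos = 0
    qseq = aln.query_alignment_sequence  # target-oriented, clips removed
    for c, n in aln.cigartuples:
        if c in (4, 5):  # clips
            continue
        if c not in code:
            raise ValidationError(f"{aln.query_name}: unsupported CIGAR op {c}")
        op = code[c]
        if op == "M":
            if reference is None or qseq is None:
                raise ValidationError(
                    f"{aln.query_name}: M ops need reference and query sequences"
                )
            tseg = reference[aln.reference_name][tpos : tpos + n]
            ops.extend(ops_from_sequences(qseq[qpos : qpos + n], tseg))
            tpos += n
            qpos += n
            continue
        ops.append((op, n))
        if _CONSUMES_TARGET[op]:
            tpos += n
        if _CONSUMES_QUERY[op]:
            qpos += n
    return compress_ops("".join(op * n for op, n in ops))


def load_alignments(path, reference: dict[str, str] | None = None):
    """Auto-detect PAF vs SAM/BAM by extension."""
    s = str(path)
    if s.endswith(".paf"):
        return read_paf(path)
    if s.endswith((".sam", ".bam", ".cram")):
        return read_sam(path, reference)
    raise ValidationError(f"cannot detect alignment format of {path}")


# ---------------------------------------------------------------------------
# Span queries
# ---------------------------------------------------------------------------

def covered_intervals(records, target_id: str) -> list[tuple[int, int]]:
    """Merged target intervals covered by any record."""
    spans = sorted(
        (r.target_start, r.target_end) for r in records if r.target_id == target_id
    )
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def covered_fraction(records, target_id: str, start: int, end: int) -> float:
    cov = 0
    for s, e in covered_intervals(records, target_id):
        cov += max(0, min(e, end) - max(s, start))
    return cov / (end - start)


def extract_target_span(
    rec: AlignmentRecord, query_seq: str, t_from: int, t_to: int
) -> tuple[str, int]:
    """Query bases aligned to target [t_from, t_to) within one record.

    Insertions internal to the span are preserved; deletions contribute
    nothing.  Returns (sequence, covered_target_bases) where coverage
    counts aligned bases only (deletion ops span but do not cover).
    """
    qseg = rec.aligned_query(query_seq)
    parts: list[str] = []
    covered = 0
    for op, n, tpos, qoff in rec.walk():
        if op == INS:
            if t_from < tpos <= t_to and parts:
                parts.append(qseg[qoff : qoff + n])
            continue
        lo, hi = max(tpos, t_from), min(tpos + n, t_to)
        if lo >= hi:
            if tpos >= t_to:
                break
            continue
        if op in (MATCH, MISMATCH):
            covered += hi - lo
            parts.append(qseg[qoff + (lo - tpos) : qoff + (hi - tpos)])
    return "".join(parts), covered
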