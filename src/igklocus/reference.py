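"""Reference editing with bidirectional coordinate liftover.

A custom locus reference is produced from a base assembly by a small
set of edits — splicing in a structural-variant payload, replacing a
span, or N-masking a gap — while keeping a ledger that maps positions
between the base and the edited ("custom") coordinate systems.  This
mirrors the common practice of building an SV-inclusive reference so
that haplotypes carrying the insertion align contiguously and its
absence genotypes as a deletion.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

DELETED = "deleted"


@dataclass(frozen=True)
class ReferenceEdit:
    """One edit on the base sequence.

    op is one of:
      - ``insert``: payload spliced in before position ``start``
        (requires start == end, payload non-empty)
      - ``replace``: base span [start, end) replaced by payload
      - ``n_mask``: base span [start, end) overwritten with N
        (length preserved; payload must be empty)
    """

    op: str
    contig: str
    start: int
    end: int
    payload: str = ""

    def __post_init__(self) -> None:
        if self.op not in ("insert", "replace", "n_mask"):
            raise ValidationError(f"unknown edit op {self.op!r}")
        if self.start < 0 or self.end < self.start:
            raise ValidationError(f"bad edit span {self.start}-{self.end}")
        if self.op == "insert":
            if self.start != self.end:
                raise ValidationError("insert edit requires start == end")
            if not self.payload:
                raise ValidationError("insert edit requires a payload")
        elif self.op == "replace":
            if self.start == self.end:
                raise ValidationError("replace edit requires a non-empty span")
        elif self.op == "n_mask" and self.payload:
            raise ValidationError("n_mask edit takes no payload")

    @property
    def span_length(self) -> int:
        return self.end - self.start

    @property
    def new_length(self) -> int:
        if self.op == "n_mask":
            return self.span_length
        return len(self.payload)

    @property
    def delta(self) -> int:
        """Length change introduced by this edit."""
        return self.new_length - self.span_length


class EditLedger:
    """Sorted edit list supporting liftover in both directions."""

    def __init__(self, edits: list[ReferenceEdit], base_length: int):
        self.edits = sorted(edits, key=lambda e: (e.start, e.end))
        self.base_length = base_length
        for a, b in zip(self.edits, self.edits[1:]):
            # touching is fine; true overlap (or two inserts at one point)
            # makes the result order-dependent
            if b.start < a.end or (a.start == b.start and a.end == b.end == a.start):
                raise ValidationError(
                    f"overlapping edits: {a.op}@{a.start}-{a.end} and "
                    f"{b.op}@{b.start}-{b.end}"
                )
        for e in self.edits:
            if e.end > base_length:
                raise ValidationError(
                    f"edit {e.op}@{e.start}-{e.end} exceeds base length {base_length}"
                )
        # cumulative coordinate shift in effect after each edit
        self._cum = []
        shift = 0
        for e in self.edits:
            shift += e.delta
            self._cum.append(shift)

    @property
    def custom_length(self) -> int:
        return self.base_length + (self._cum[-1] if self._cum else 0)

    def liftover(self, pos: int, direction: str) -> int | str:
        """Map a position between coordinate systems.

        Returns the mapped position, or ``"deleted"`` for positions
        inside a replaced base span (to_custom) or inside spliced-in
        payload (to_base).  Monotone non-decreasing outside edits.
        """
        if direction == "to_custom":
            if not (0 <= pos < self.base_length):
                raise ValidationError(f"position {pos} outside base [0,{self.base_length})")
            shift = 0
            for e, cum in zip(self.edits, self._cum):
                if pos < e.start:
                    break
                if pos < e.end and e.op == "replace":
                    return DELETED
                if pos < e.end:  # n_mask keeps coordinates
                    break
                shift = cum
            return pos + shift
        if direction == "to_base":
            if not (0 <= pos < self.custom_length):
                raise ValidationError(
                    f"position {pos} outside custom [0,{self.custom_length})"
                )
            shift = 0
            for e, cum in zip(self.edits, self._cum):
                new_start = e.start + shift
                if pos < new_start:
                    break
                if pos < new_start + e.new_length:
                    if e.op == "n_mask":
                        break  # masked but coordinate-preserving
                    return DELETED
                shift = cum
            return pos - shift
        raise ValidationError(f"unknown liftover direction {direction!r}")

    def lift_interval(self, start: int, end: int, direction: str):
        """Lift both bounds; None if either falls in deleted material."""
        a = self.liftover(start, direction)
        b = self.liftover(end - 1, direction)
        if a == DELETED or b == DELETED:
            return None
        return a, b + 1

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#op\tcontig\tstart\tend\tpayload\n")
            for e in self.edits:
                fh.write(
                    f"{e.op}\t{e.contig}\t{e.start}\t{e.end}\t{e.payload or '.'}\n"
                )

    @classmethod
    def from_tsv(cls, path, base_length: int) -> "EditLedger":
        edits = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                op, contig, start, end, payload = line.rstrip("\n").split("\t")
                edits.append(
                    ReferenceEdit(
                        op, contig, int(start), int(end),
                        "" if payload == "." else payload,
                    )
                )
        return cls(edits, base_length)


def build_custom_reference(
    base: str, edits: list[ReferenceEdit]
) -> tuple[str, EditLedger]:
    """Apply edits to a base sequence.

    Edits are applied in descending coordinate order so the result is
    independent of the listing order.  Output length obeys
    len(base) + sum(insert payloads) + sum(replacement - replaced).
    """
    ledger = EditLedger(edits, len(base))
    seq = base
    for e in sorted(ledger.edits, key=lambda e: e.start, reverse=True):
        if e.op == "n_mask":
            new = "N" * e.span_length
        else:
            new = e.payload
        seq = seq[: e.start] + new + seq[e.end :]
    if len(seq) != ledger.custom_length:
        raise AssertionError("length bookkeeping violated")  # pragma: no cover
    return seq, ledger
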