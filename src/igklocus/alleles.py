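"""Germline allele extraction, classification and support metrics.

Per gene and haplotype, the coding-exon sequence is lifted out of the
assembly-to-reference alignment, strand-normalized, and matched against
a germline database (headers ``GENE*NN``).  Exact matches take the
database label; everything else is a novel allele labelled
``GENE_N<k>``, reported with its nearest known allele, the edit
distance to it (substitutions and indels each weight 1), and the
coding consequence of the differences.  Long-read support for an
allele is summarized as the number of reads fully spanning its exon
footprint on the haplotype, and the subset doing so with 100%
identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .alignio import DEL, INS, MATCH, MISMATCH, AlignmentRecord, extract_target_span
from .errors import ValidationError
from .locus import GeneAnnotation
from .alignio import revcomp

CALLED, DELETED, UNRESOLVED = "called", "deleted", "unresolved"


@dataclass
class AlleleExtract:
    state: str  # called | deleted | unresolved
    sequence: str = ""
    truncated: bool = False
    reason: str = ""


@dataclass
class AlleleCall:
    sample: str
    haplotype_id: str
    gene_name: str
    state: str
    allele_label: str = ""
    sequence: str = ""
    nearest_known: str = ""
    distance_nt: int = 0
    effect: str = ""
    tie: bool = False
    has_indel: bool = False
    fully_spanning_reads: int = -1
    fully_spanning_reads_100pct: int = -1


@dataclass
class ReadSupport:
    fully_spanning_reads: int
    fully_spanning_reads_100pct: int

    def __post_init__(self) -> None:
        if not 0 <= self.fully_spanning_reads_100pct <= self.fully_spanning_reads:
            raise ValidationError("read-support counts out of order")


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def extract_allele(
    records: list[AlignmentRecord],
    hap_seq: str,
    gene: GeneAnnotation,
    masks: list[tuple[int, int]] | None = None,
) -> AlleleExtract:
    """Exon sequence of one gene from one haplotype's alignment.

    Strand-normalized.  Zero aligned bases over the exon footprint ->
    deleted (the gene is structurally absent); footprint overlapping a
    declared unresolved mask -> unresolved; footprint only partially
    inside the alignment span (contig truncation) -> unresolved with
    the truncation flag.  Indels internal to the exon are preserved in
    the extracted sequence.
    """
    iv = gene.exon
    if masks:
        for s, e in masks:
            if s < iv.end and iv.start < e:
                return AlleleExtract(UNRESOLVED, reason="masked")
    overlapping = [
        r for r in records if r.target_start < iv.end and r.target_end > iv.start
    ]
    if not overlapping:
        return AlleleExtract(DELETED, reason="no alignment over exon")
    best = max(
        overlapping,
        key=lambda r: min(r.target_end, iv.end) - max(r.target_start, iv.start),
    )
    span_cov = (min(best.target_end, iv.end) - max(best.target_start, iv.start)) / iv.length()
    seq, base_cov = extract_target_span(best, hap_seq, iv.start, iv.end)
    if span_cov < 1.0:
        return AlleleExtract(UNRESOLVED, truncated=True, reason="exon truncated at contig end")
    if base_cov == 0:
        return AlleleExtract(DELETED, reason="exon deleted in alignment")
    if gene.strand == "-":
        seq = revcomp(seq)
    return AlleleExtract(CALLED, sequence=seq)


# ---------------------------------------------------------------------------
# database matching
# ---------------------------------------------------------------------------

def match_allele(
    seq: str, db: dict[str, dict[str, str]], gene_name: str
) -> dict:
    """Match an exon sequence against the germline database.

    Returns a dict with keys allele_label (known label or "" when
    novel), nearest_known, distance_nt, tie, has_indel.  Deterministic
    under permutation of the database (ties break to the
    lexicographically first label).
    """
    alleles = db.get(gene_name)
    if not alleles:
        return {"state": UNRESOLVED, "reason": f"no database alleles for {gene_name}"}
    for label in sorted(alleles):
        if alleles[label] == seq:
            return {
                "state": CALLED,
                "allele_label": f"{gene_name}{label}",
                "nearest_known": f"{gene_name}{label}",
                "distance_nt": 0,
                "tie": False,
                "has_indel": False,
            }
    best_label, best_dist = None, None
    tie = False
    for label in sorted(alleles):
        d = edlib.align(seq, alleles[label], task="distance")["editDistance"]
        if best_dist is None or d < best_dist:
            best_label, best_dist, tie = label, d, False
        elif d == best_dist:
            tie = True
    return {
        "state": CALLED,
        "allele_label": "",  # assigned cohort-wide, see assign_novel_labels
        "nearest_known": f"{gene_name}{best_label}",
        "distance_nt": int(best_dist),
        "tie": tie,
        "has_indel": len(seq) != len(alleles[best_label]),
    }


def assign_novel_labels(calls: list[AlleleCall]) -> None:
    """Label novel alleles ``GENE_N<k>`` cohort-wide, in place.

    k is ordered by observation count (descending), then by sequence
    lexicographically, so labelling is deterministic.
    """
    by_gene: dict[str, dict[str, int]] = {}
    for c in calls:
        if c.state == CALLED and not c.allele_label:
            by_gene.setdefault(c.gene_name, {}).setdefault(c.sequence, 0)
            by_gene[c.gene_name][c.sequence] += 1
    labels: dict[tuple[str, str], str] = {}
    for gene, counts in by_gene.items():
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        for k, (seq, _n) in enumerate(ordered, 1):
            labels[(gene, seq)] = f"{gene}_N{k}"
    for c in calls:
        if c.state == CALLED and not c.allele_label:
            c.allele_label = labels[(c.gene_name, c.sequence)]


# ---------------------------------------------------------------------------
# coding consequence
# ---------------------------------------------------------------------------

def classify_effect(
    novel_seq: str, nearest_seq: str, reading_frame_offset: int = 0
) -> tuple[str, bool]:
    """Coding consequence of a novel allele vs its nearest known one.

    Net length change not divisible by 3 -> frameshift.  Otherwise the
    two translations are compared: any amino-acid difference (including
    an in-frame indel) -> nonsynonymous, else synonymous_only.
    Returns (effect, ambiguous) where ambiguous flags N-containing
    codons that were skipped in the comparison.
    """
    if (len(novel_seq) - len(nearest_seq)) % 3 != 0:
        return "frameshift", False
    ambiguous = False

    def codons(s):
        s = s[reading_frame_offset:]
        return [s[i : i + 3] for i in range(0, len(s) - len(s) % 3, 3)]

    ca, cb = codons(novel_seq), codons(nearest_seq)
    if len(ca) != len(cb):
        return "nonsynonymous", False  # in-frame indel changes the protein
    for a, b in zip(ca, cb):
        if "N" in a or "N" in b:
            ambiguous = True
            continue
        if str(Seq(a).translate()) != str(Seq(b).translate()):
            return "nonsynonymous", ambiguous
    return "synonymous_only", ambiguous


# ---------------------------------------------------------------------------
# read support and assembly accuracy
# ---------------------------------------------------------------------------

def read_support(
    footprint: tuple[int, int], read_records: list[AlignmentRecord]
) -> ReadSupport:
    """Spanning-read counts for an allele footprint on its haplotype.

    A read counts as fully spanning when its alignment covers the whole
    footprint; the 100% subset additionally has no mismatch or indel op
    inside the footprint.
    """
    s, e = footprint
    spanning = perfect = 0
    for rec in read_records:
        if rec.target_start > s or rec.target_end < e:
            continue
        spanning += 1
        clean = True
        for op, n, tpos, _q in rec.walk():
            if op == MISMATCH or op == DEL:
                if tpos < e and tpos + n > s:
                    clean = False
                    break
            elif op == INS and s < tpos < e:
                clean = False
                break
        if clean:
            perfect += 1
    return ReadSupport(spanning, perfect)


def assembly_accuracy(
    hap_lengths: dict[str, int],
    read_records: list[AlignmentRecord],
    mismatch_fraction_threshold: float = 0.25,
) -> tuple[float, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Percent accuracy of a diploid assembly from read alignments.

    A position is flagged when more than the threshold fraction of
    covering reads mismatch the assembly there (mismatch or deletion
    ops).  accuracy = (diploid length - flagged positions) / diploid
    length * 100.  Zero-coverage positions are excluded from flagging
    but included in the length; they are returned for inspection.
    """
    cov = {h: np.zeros(n, dtype=np.int32) for h, n in hap_lengths.items()}
    mism = {h: np.zeros(n, dtype=np.int32) for h, n in hap_lengths.items()}
    for rec in read_records:
        if rec.target_id not in cov:
            continue
        c, m = cov[rec.target_id], mism[rec.target_id]
        for op, n, tpos, _q in rec.walk():
            if op in (MATCH, MISMATCH, DEL):
                c[tpos : tpos + n] += 1
                if op != MATCH:
                    m[tpos : tpos + n] += 1
    total = sum(hap_lengths.values())
    flagged = 0
    flagged_pos = {}
    zero_cov = {}
    for h in hap_lengths:
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(cov[h] > 0, mism[h] / np.maximum(cov[h], 1), 0.0)
        f = frac > mismatch_fraction_threshold
        flagged += int(f.sum())
        flagged_pos[h] = np.nonzero(f)[0]
        zero_cov[h] = np.nonzero(cov[h] == 0)[0]
    return (total - flagged) / total * 100.0, flagged_pos, zero_cov


# ---------------------------------------------------------------------------
# cohort-level tables
# ---------------------------------------------------------------------------

def calls_to_frame(calls: list[AlleleCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": c.sample,
                "haplotype": c.haplotype_id,
                "gene": c.gene_name,
                "state": c.state,
                "allele_label": c.allele_label,
                "nearest_known": c.nearest_known,
                "distance_nt": c.distance_nt,
                "effect": c.effect,
                "fully_spanning_reads": c.fully_spanning_reads,
                "fully_spanning_reads_100pct": c.fully_spanning_reads_100pct,
            }
            for c in calls
        ]
    )


def heterozygosity_table(
    calls: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Percent of individuals heterozygous per gene per population.

    A sample is heterozygous at a gene iff its two haplotype states or
    labels differ; a deleted gene counts as a distinct allele state; a
    sample with an unresolved haplotype is excluded from that gene's
    denominator.
    """
    pop = metadata.set_index("sample")["population"]
    rows = []
    for gene, sub in calls.groupby("gene"):
        for sample, pair in sub.groupby("sample"):
            if len(pair) != 2:
                raise ValidationError(f"{sample}/{gene}: expected 2 haplotype calls")
            states = pair["state"].tolist()
            if UNRESOLVED in states:
                continue
            labels = [
                row["allele_label"] if row["state"] == CALLED else DELETED
                for _, row in pair.iterrows()
            ]
            rows.append(
                {
                    "gene": gene,
                    "population": pop[sample],
                    "sample": sample,
                    "het": labels[0] != labels[1],
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["gene", "population", "pct_heterozygous", "n"])
    out = (
        df.groupby(["gene", "population"])["het"]
        .agg(pct_heterozygous=lambda s: 100.0 * s.mean(), n="size")
        .reset_index()
    )
    return out


def call_alleles_for_haplotype(
    records: list[AlignmentRecord],
    hap_seq: str,
    locus,
    db: dict[str, dict[str, str]],
    sample: str,
    hap_id: str,
    masks: list[tuple[int, int]] | None = None,
    genes: list[str] | None = None,
) -> list[AlleleCall]:
    """Extract and match every gene of the locus on one haplotype."""
    out = []
    for g in locus.genes:
        if genes is not None and g.gene_name not in genes:
            continue
        ext = extract_allele(records, hap_seq, g, masks)
        call = AlleleCall(
            sample=sample, haplotype_id=hap_id, gene_name=g.gene_name, state=ext.state
        )
        if ext.state == CALLED:
            m = match_allele(ext.sequence, db, g.gene_name)
            call.state = m["state"]
            if m["state"] == CALLED:
                call.sequence = ext.sequence
                call.allele_label = m["allele_label"]
                call.nearest_known = m["nearest_known"]
                call.distance_nt = m["distance_nt"]
                call.tie = m["tie"]
                call.has_indel = m["has_indel"]
                if call.distance_nt > 0:
                    nearest_seq = db[g.gene_name][
                        m["nearest_known"].removeprefix(g.gene_name)
                    ]
                    call.effect, _amb = classify_effect(ext.sequence, nearest_seq)
                else:
                    call.effect = "exact"
        out.append(call)
    return out
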