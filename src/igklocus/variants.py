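"""Assembly-based diploid SNV genotyping.

SNVs are read directly off haplotype-to-reference alignments (mismatch
columns), not from a read pileup: the assemblies are consensus
sequences, so every mismatch op is a call.  Per-sample haplotype calls
are merged into a cohort matrix with explicit per-haplotype
missingness, multiallelic positions split into biallelic rows, an
alternate-allele-count filter, per-site gene-feature annotation, and
position-level intersection with external SNV catalogs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignio import DEL, INS, MATCH, MISMATCH, AlignmentRecord
from .errors import ValidationError
from .locus import GenomicInterval, LocusMap

MISSING = -1


@dataclass(frozen=True)
class SnvCall:
    position: int
    ref_base: str
    alt_base: str
    haplotype_id: str

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base or len(self.ref_base) != 1 or len(
            self.alt_base
        ) != 1:
            raise ValidationError(
                f"bad SNV {self.ref_base}>{self.alt_base} at {self.position}"
            )


@dataclass
class HaplotypeCalls:
    """SNV calls plus missingness bookkeeping for one haplotype."""

    haplotype_id: str
    calls: list[SnvCall]
    missing: list[tuple[int, int]]  # intervals with no =/X coverage
    inconsistent: set[int] = field(default_factory=set)

    def is_missing(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.missing)


def call_snvs(
    records: list[AlignmentRecord],
    query_seq: str,
    reference: str,
    regions: list[GenomicInterval],
) -> HaplotypeCalls:
    """Call SNVs for one haplotype within the analysis regions.

    One call per mismatch column; indel columns yield no SNV.  Region
    positions covered by no record (or only by deletion ops) form the
    missing set.  Overlapping records that disagree on a base mark the
    position assembly-inconsistent.
    """
    if not records:
        raise ValidationError("no alignment records for haplotype")
    hap_id = records[0].query_id
    region_arr = sorted((r.start, r.end) for r in regions)

    per_record: list[dict[int, str]] = []
    covered: list[list[tuple[int, int]]] = []
    for rec in records:
        rec.validate()
        qseg = rec.aligned_query(query_seq)
        calls: dict[int, str] = {}
        spans: list[tuple[int, int]] = []
        for op, n, tpos, qoff in rec.walk():
            if op in (MATCH, MISMATCH):
                if spans and spans[-1][1] == tpos:
                    spans[-1] = (spans[-1][0], tpos + n)
                else:
                    spans.append((tpos, tpos + n))
            if op == MISMATCH:
                for k in range(n):
                    p = tpos + k
                    if _in_regions(p, region_arr):
                        alt = qseg[qoff + k]
                        ref = reference[p]
                        if alt != ref:
                            calls[p] = alt
                        else:
                            raise ValidationError(
                                f"{hap_id}: mismatch op at {p} but bases agree "
                                "(inconsistent op-length bookkeeping)"
                            )
        per_record.append(calls)
        covered.append(spans)

    # consensus across (possibly overlapping) records
    final: dict[int, str] = {}
    inconsistent: set[int] = set()
    all_pos = set().union(*per_record) if per_record else set()
    for p in all_pos:
        seen: set[str] = set()
        for calls, spans in zip(per_record, covered):
            if p in calls:
                seen.add(calls[p])
            elif any(s <= p < e for s, e in spans):
                seen.add(reference[p])  # this record says reference
        if len(seen) == 1:
            final[p] = seen.pop()
        else:
            inconsistent.add(p)

    merged_cov = _merge_spans([s for spans in covered for s in spans])
    missing = []
    for rs, re_ in region_arr:
        missing.extend(_subtract(rs, re_, merged_cov))
    return HaplotypeCalls(
        haplotype_id=hap_id,
        calls=[
            SnvCall(p, reference[p], b, hap_id) for p, b in sorted(final.items())
        ],
        missing=missing,
        inconsistent=inconsistent,
    )


def _in_regions(pos, region_arr) -> bool:
    return any(s <= pos < e for s, e in region_arr)


def _merge_spans(spans):
    merged = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _subtract(start, end, covered):
    out = []
    cursor = start
    for s, e in covered:
        if e <= cursor or s >= end:
            continue
        if s > cursor:
            out.append((cursor, min(s, end)))
        cursor = max(cursor, e)
        if cursor >= end:
            break
    if cursor < end:
        out.append((cursor, end))
    return out


# ---------------------------------------------------------------------------
# cohort matrix
# ---------------------------------------------------------------------------

class CohortGenotypes:
    """Multi-sample biallelic SNV matrix with haplotype-level calls.

    ``sites`` is a DataFrame with columns (pos, ref, alt, feature);
    ``hap_gt`` an int8 matrix haplotypes x sites with values 0, 1 or
    -1 (missing).  AC/AN are derived, never stored stale.
    """

    def __init__(self, sites: pd.DataFrame, hap_gt: np.ndarray,
                 hap_ids: list[str], sample_map: dict[str, tuple[str, str]],
                 contig: str = "ref"):
        if hap_gt.shape != (len(hap_ids), len(sites)):
            raise ValidationError("genotype matrix shape mismatch")
        self.sites = sites.reset_index(drop=True)
        self.hap_gt = hap_gt.astype(np.int8)
        self.hap_ids = list(hap_ids)
        self.sample_map = dict(sample_map)
        self.contig = contig
        self._hap_index = {h: i for i, h in enumerate(self.hap_ids)}

    @property
    def samples(self) -> list[str]:
        return list(self.sample_map)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def ac(self) -> np.ndarray:
        return (self.hap_gt == 1).sum(axis=0)

    @property
    def an(self) -> np.ndarray:
        return (self.hap_gt != MISSING).sum(axis=0)

    def dosage(self) -> pd.DataFrame:
        """Samples x sites alternate-allele dosage; missing haplotypes
        contribute NaN halves (dosage of the called haplotype only)."""
        rows = {}
        for s, (h1, h2) in self.sample_map.items():
            g1 = self.hap_gt[self._hap_index[h1]].astype(float)
            g2 = self.hap_gt[self._hap_index[h2]].astype(float)
            g1[g1 == MISSING] = np.nan
            g2[g2 == MISSING] = np.nan
            rows[s] = g1 + g2
        return pd.DataFrame.from_dict(rows, orient="index")

    def genotype_strings(self) -> pd.DataFrame:
        sym = {0: "0", 1: "1", MISSING: "."}
        rows = {}
        for s, (h1, h2) in self.sample_map.items():
            g1 = self.hap_gt[self._hap_index[h1]]
            g2 = self.hap_gt[self._hap_index[h2]]
            rows[s] = [f"{sym[int(a)]}|{sym[int(b)]}" for a, b in zip(g1, g2)]
        return pd.DataFrame.from_dict(rows, orient="index")

    def subset_sites(self, mask) -> "CohortGenotypes":
        mask = np.asarray(mask)
        idx = np.nonzero(mask)[0] if mask.dtype == bool else mask
        return CohortGenotypes(
            self.sites.iloc[idx],
            self.hap_gt[:, idx],
            self.hap_ids,
            self.sample_map,
            self.contig,
        )

    def restrict(self, interval: GenomicInterval) -> "CohortGenotypes":
        pos = self.sites["pos"].to_numpy()
        return self.subset_sites((pos >= interval.start) & (pos < interval.end))

    def reorder_samples(self, order: list[str]) -> "CohortGenotypes":
        sample_map = {s: self.sample_map[s] for s in order}
        return CohortGenotypes(
            self.sites, self.hap_gt, self.hap_ids, sample_map, self.contig
        )

    def equals(self, other: "CohortGenotypes") -> bool:
        return (
            self.sites[["pos", "ref", "alt"]].equals(
                other.sites[["pos", "ref", "alt"]]
            )
            and self.hap_ids == other.hap_ids
            and np.array_equal(self.hap_gt, other.hap_gt)
        )


def merge_cohort(
    hap_calls: dict[str, HaplotypeCalls],
    sample_map: dict[str, tuple[str, str]],
    contig: str = "ref",
) -> CohortGenotypes:
    """Merge per-haplotype calls into a biallelic cohort matrix.

    Sites are the union of (pos, ref, alt) triples — a position with
    two alternate bases yields two biallelic rows.  A haplotype is 1 at
    its own (pos, alt), 0 at covered sites it does not carry, and
    missing where it has no aligned base or an inconsistent one.
    """
    for sample, haps in sample_map.items():
        if len(haps) != 2:
            raise ValidationError(f"sample {sample}: expected 2 haplotypes, got {len(haps)}")
        for h in haps:
            if h not in hap_calls:
                raise ValidationError(f"sample {sample}: no calls for haplotype {h}")

    triples = sorted(
        {(c.position, c.ref_base, c.alt_base) for hc in hap_calls.values() for c in hc.calls}
    )
    sites = pd.DataFrame(triples, columns=["pos", "ref", "alt"])
    sites["feature"] = "intergenic"
    hap_ids = [h for haps in sample_map.values() for h in haps]
    gt = np.zeros((len(hap_ids), len(triples)), dtype=np.int8)
    site_index = {t: j for j, t in enumerate(triples)}
    pos_arr = sites["pos"].to_numpy()
    for i, h in enumerate(hap_ids):
        hc = hap_calls[h]
        for c in hc.calls:
            gt[i, site_index[(c.position, c.ref_base, c.alt_base)]] = 1
        if hc.missing:
            miss = np.zeros(len(triples), dtype=bool)
            for s, e in hc.missing:
                miss |= (pos_arr >= s) & (pos_arr < e)
            gt[i, miss] = MISSING
        for p in hc.inconsistent:
            gt[i, pos_arr == p] = MISSING
    return CohortGenotypes(sites, gt, hap_ids, sample_map, contig)


def implied_maf_floor(n_haplotypes: int, min_ac_exclusive: int = 1) -> float:
    """Smallest MAF retained by an AC > min_ac_exclusive filter, in %."""
    return (min_ac_exclusive + 1) / n_haplotypes * 100.0


def filter_by_mac(
    cohort: CohortGenotypes, min_ac_exclusive: int = 1
) -> tuple[CohortGenotypes, float]:
    """Keep sites with alternate allele count strictly above the bound.

    Returns the filtered cohort and the implied MAF floor in percent
    (computed over the full haplotype complement).
    """
    if cohort.n_sites == 0:
        raise ValidationError("empty cohort")
    keep = cohort.ac > min_ac_exclusive
    floor = implied_maf_floor(len(cohort.hap_ids), min_ac_exclusive)
    return cohort.subset_sites(keep), floor


def annotate_features(cohort: CohortGenotypes, locus: LocusMap) -> CohortGenotypes:
    """Label each site with its gene feature, else 'intergenic'."""
    feats = []
    for g in locus.genes:
        for tag, iv in g.features.items():
            feats.append((iv.start, iv.end, tag))
    feats.sort()
    for (s1, e1, t1), (s2, e2, t2) in zip(feats, feats[1:]):
        if s2 < e1:
            raise ValidationError(
                f"overlapping features {t1}@{s1}-{e1} and {t2}@{s2}-{e2}"
            )
    starts = np.array([f[0] for f in feats])
    ends = np.array([f[1] for f in feats])
    labels = [f[2] for f in feats]
    out = []
    for p in cohort.sites["pos"].to_numpy():
        i = np.searchsorted(starts, p, side="right") - 1
        if i >= 0 and p < ends[i]:
            out.append(labels[i])
        else:
            out.append("intergenic")
    sites = cohort.sites.copy()
    sites["feature"] = out
    return CohortGenotypes(
        sites, cohort.hap_gt, cohort.hap_ids, cohort.sample_map, cohort.contig
    )


def intersect_catalog(
    cohort: CohortGenotypes,
    catalog_sites,
    by_allele: bool = False,
    coordinate_mismatch: bool = False,
) -> dict[str, set]:
    """Partition SNV sites against an external catalog.

    Position-level matching by default (the catalog comparison the
    analysis calls for); allele-aware matching compares (pos, alt)
    pairs.  Both inputs must already be in the same coordinate system.
    """
    if coordinate_mismatch:
        raise ValidationError("catalog is in a different coordinate system; lift over first")
    if by_allele:
        ours = set(zip(cohort.sites["pos"].tolist(), cohort.sites["alt"].tolist()))
        theirs = {(p, a) for p, a in catalog_sites}
    else:
        ours = set(cohort.sites["pos"].tolist())
        theirs = {p if isinstance(p, (int, np.integer)) else p[0] for p in catalog_sites}
    return {
        "unique_to_cohort": ours - theirs,
        "shared": ours & theirs,
        "unique_to_catalog": theirs - ours,
    }
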