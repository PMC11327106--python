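"""Synthetic diploid cohort generator with a truth ledger.

Generates haplotype sequences for a two-region segmental-duplication
locus by editing the SV-inclusive custom reference, in this order per
haplotype:

1. draw one germline allele per gene from population-specific
   frequencies and write its exon substitutions into the sequence;
2. draw the gene-conversion state; converted haplotypes have the
   acceptor window in the distal region overwritten with the proximal
   donor sequence (so paralog-divergent positions inside the window
   surface as apparent SNVs against the distal reference — the
   density signature of the conversion);
3. draw the insertion-SV state; "deleted" haplotypes lose the payload
   and the gene it carries;
4. draw a rare inversion, which reverse-complements the span between
   the two anchor-gene midpoints (emitted as orientation-flipped
   alignment records);
5. scatter additional SNVs as a Poisson process with per-region
   densities and per-feature multipliers, avoiding edited positions.

Every edit is recorded in a :class:`TruthSet` so that downstream
calls can be scored for exact recovery.  Truth alignments are emitted
as op lists (PAF with a cg:Z CIGAR on disk) that are consistent with
all edits.  One fixed seed yields byte-identical outputs; haplotype
substreams are derived from a counter so cohorts are reproducible
under resizing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignio import AlignmentRecord, DEL, MATCH, MISMATCH, make_record, revcomp
from .errors import ValidationError
from .locus import GenomicInterval, LocusMap

BASES = np.frombuffer(b"ACGT", dtype="S1")

# default cohort composition: 36 samples across five ancestry groups
DEFAULT_POPULATIONS = {"AFR": 8, "EAS": 7, "SAS": 10, "EUR": 10, "AMR": 1}

# deletion-allele frequency of the insertion SV per population
DEFAULT_SV_DELETION_FREQ = {
    "AFR": 0.50,
    "EAS": 0.786,
    "SAS": 0.90,
    "EUR": 0.85,
    "AMR": 0.50,
}

DEFAULT_CONVERSION_FREQ = {
    "AFR": 0.25,
    "EAS": 0.50,
    "SAS": 0.50,
    "EUR": 0.50,
    "AMR": 0.50,
}


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort."""

    seed: int = 0
    n_samples: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_POPULATIONS)
    )
    snv_density_proximal: float = 5e-4  # substitutions per bp per haplotype
    snv_density_distal: float = 1e-3
    feature_density_multipliers: dict[str, float] = field(
        default_factory=lambda: {
            "V-exon": 2.0,
            "L-Part1": 2.0,
            "intron": 1.5,
            "RSS": 1.0,
        }
    )
    n_alleles_per_gene: int = 3
    allele_max_substitutions: int = 8  # novel alleles sit 1-8 nt from nearest
    allele_frequencies: dict | None = None  # gene -> pop -> vector; else Dirichlet
    conversion_freq: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONVERSION_FREQ)
    )
    sv_deletion_freq: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SV_DELETION_FREQ)
    )
    inversion_freq: float = 0.014  # roughly one haplotype per 72
    read_length_mean: float = 10_000.0
    read_length_sd_frac: float = 0.1
    read_error_rate: float = 0.001
    coverage: float = 30.0

    def validate(self, locus: LocusMap | None = None) -> None:
        for name, p in [
            ("inversion_freq", self.inversion_freq),
            ("read_error_rate", self.read_error_rate),
            *[(f"conversion_freq[{k}]", v) for k, v in self.conversion_freq.items()],
            *[(f"sv_deletion_freq[{k}]", v) for k, v in self.sv_deletion_freq.items()],
        ]:
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name}={p} outside [0,1]")
        if self.snv_density_proximal < 0 or self.snv_density_distal < 0:
            raise ValidationError("SNV densities must be >= 0")
        if self.n_alleles_per_gene < 1:
            raise ValidationError("need >= 1 allele per functional gene")
        if locus is not None and locus.conversion_window is not None:
            for sv in locus.sv_definitions:
                if sv.kind == "insertion" and sv.anchor.overlaps(
                    locus.conversion_window
                ):
                    raise ValidationError(
                        f"conversion window overlaps SV anchor {sv.sv_id}"
                    )

    def sample_sheet(self) -> list[tuple[str, str]]:
        """Stable (sample, population) listing."""
        out = []
        i = 0
        for pop, n in self.n_samples.items():
            for _ in range(n):
                i += 1
                out.append((f"S{i:03d}", pop))
        return out


@dataclass
class HaplotypeTruth:
    sample: str
    hap_id: str
    population: str
    alleles: dict[str, str]  # gene -> allele label or "deleted"
    snvs: list[tuple[int, str, str, str]]  # (pos, ref, alt, source)
    sv_states: dict[str, str]
    conversion_state: str  # "reference" | "converted"
    inversion_state: bool
    deleted_spans: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class SimulatedHaplotype:
    hap_id: str
    seq: str
    records: list[AlignmentRecord]
    truth: HaplotypeTruth


@dataclass
class Cohort:
    locus: LocusMap
    reference: str
    contig: str
    haplotypes: list[SimulatedHaplotype]
    germline_db: dict[str, dict[str, str]]  # gene -> label -> exon seq
    metadata: "object"  # pandas DataFrame: sample, population, subpopulation, sex
    config: SimConfig

    def sample_map(self) -> dict[str, tuple[str, str]]:
        out: dict[str, list[str]] = {}
        for h in self.haplotypes:
            out.setdefault(h.truth.sample, []).append(h.hap_id)
        return {s: tuple(v) for s, v in out.items()}

    def truth_set(self) -> list[HaplotypeTruth]:
        return [h.truth for h in self.haplotypes]


# ---------------------------------------------------------------------------
# germline allele database
# ---------------------------------------------------------------------------

def reference_exon(gene, reference: str) -> str:
    """Strand-normalized reference exon sequence for a gene."""
    iv = gene.exon
    seq = reference[iv.start : iv.end]
    return revcomp(seq) if gene.strand == "-" else seq


def conversion_coupled_genes(locus: LocusMap) -> list[str]:
    """Distal genes whose exon lies inside the conversion acceptor window."""
    win = locus.conversion_window
    if win is None:
        return []
    return [
        g.gene_name
        for g in locus.genes
        if g.region_tag == "distal" and win.contains_interval(g.exon)
    ]


def donor_interval(locus: LocusMap) -> GenomicInterval:
    """Proximal interval paralogous to the conversion acceptor window.

    Assumes the two regions are coordinate-aligned copies (true of the
    packaged fixture and of real segmental duplications up to indels).
    """
    win = locus.conversion_window
    shift = locus.proximal.start - locus.distal.start
    return GenomicInterval(win.contig, win.start + shift, win.end + shift)


def simulate_germline_db(
    locus: LocusMap, reference: str, config: SimConfig
) -> dict[str, dict[str, str]]:
    """Build a synthetic germline allele database.

    ``*01`` equals the strand-normalized reference exon for every gene.
    For genes inside the conversion acceptor window, ``*02`` is the
    proximal paralog's reference exon (the conversion allele).  All
    other alleles are the reference exon with 1-8 random substitutions.
    """
    config.validate(locus)
    rng = np.random.default_rng([config.seed, 999_979])
    coupled = set(conversion_coupled_genes(locus))
    db: dict[str, dict[str, str]] = {}
    for gene in locus.genes:
        ref_exon = reference_exon(gene, reference)
        alleles = {"*01": ref_exon}
        if gene.gene_name in coupled:
            mate = locus.paralog_of(gene.gene_name)
            donor_exon = reference_exon(locus.gene(mate), reference)
            if donor_exon == ref_exon:
                raise ValidationError(
                    f"{gene.gene_name}: paralog exons identical; conversion "
                    "allele would be indistinguishable"
                )
            alleles["*02"] = donor_exon
        else:
            seen = {ref_exon}
            k = 2
            while len(alleles) < config.n_alleles_per_gene:
                n_subs = int(rng.integers(1, config.allele_max_substitutions + 1))
                seq = _mutate(ref_exon, n_subs, rng)
                if seq in seen:
                    continue
                seen.add(seq)
                alleles[f"*{k:02d}"] = seq
                k += 1
        db[gene.gene_name] = alleles
    return db


def _mutate(seq: str, n_subs: int, rng) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    pos = rng.choice(len(arr), size=min(n_subs, len(arr)), replace=False)
    for p in pos:
        choices = BASES[BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode()


def write_germline_db(db: dict[str, dict[str, str]], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(db):
            for label in sorted(db[gene]):
                fh.write(f">{gene}{label}\n")
                _write_wrapped(fh, db[gene][label])


def read_germline_db(path) -> dict[str, dict[str, str]]:
    db: dict[str, dict[str, str]] = {}
    for name, seq in iter_fasta(path):
        if "*" not in name:
            raise ValidationError(f"germline header {name!r} lacks GENE*NN form")
        gene, num = name.rsplit("*", 1)
        db.setdefault(gene, {})[f"*{num}"] = seq
    return db


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(
    locus: LocusMap,
    reference: str,
    config: SimConfig,
    germline_db: dict[str, dict[str, str]] | None = None,
    contig: str | None = None,
) -> Cohort:
    import pandas as pd

    config.validate(locus)
    if germline_db is None:
        germline_db = simulate_germline_db(locus, reference, config)
    contig = contig or locus.proximal.contig

    ref_arr = np.frombuffer(reference.encode(), dtype="S1")
    coupled = conversion_coupled_genes(locus)
    donor = donor_interval(locus) if locus.conversion_window is not None else None
    allele_edits = _allele_edit_table(locus, reference, germline_db)
    freqs = _allele_frequency_table(locus, germline_db, config, coupled)
    density_intervals = _density_intervals(locus, config)
    insertion_svs = [sv for sv in locus.sv_definitions if sv.kind == "insertion"]
    inversions = [sv for sv in locus.sv_definitions if sv.kind == "inversion"]

    sheet = config.sample_sheet()
    haplotypes: list[SimulatedHaplotype] = []
    meta_rows = []
    hap_counter = 0
    meta_rng = np.random.default_rng([config.seed, 999_961])
    for sample, pop in sheet:
        meta_rows.append(
            {
                "sample": sample,
                "population": pop,
                "subpopulation": f"{pop}{int(meta_rng.integers(1, 4))}",
                "sex": str(meta_rng.choice(["F", "M"])),
            }
        )
        for h in (1, 2):
            hap_id = f"{sample}_h{h}"
            rng = np.random.default_rng([config.seed, hap_counter])
            hap_counter += 1
            haplotypes.append(
                _simulate_haplotype(
                    hap_id, sample, pop, locus, ref_arr, config,
                    germline_db, allele_edits, freqs, coupled, donor,
                    insertion_svs, inversions, density_intervals,
                    contig, rng,
                )
            )
    return Cohort(
        locus=locus,
        reference=reference,
        contig=contig,
        haplotypes=haplotypes,
        germline_db=germline_db,
        metadata=pd.DataFrame(meta_rows),
        config=config,
    )


def _allele_edit_table(locus, reference, db):
    """Per (gene, label): genomic substitutions relative to the reference."""
    table: dict[tuple[str, str], list[tuple[int, bytes]]] = {}
    for gene in locus.genes:
        ref_exon = reference_exon(gene, reference)
        iv = gene.exon
        for label, seq in db[gene.gene_name].items():
            if len(seq) != len(ref_exon):
                raise ValidationError(
                    f"{gene.gene_name}{label}: simulator plants substitutions "
                    "only; allele length must match the reference exon"
                )
            edits = []
            for j, (a, b) in enumerate(zip(ref_exon, seq)):
                if a == b:
                    continue
                if gene.strand == "+":
                    gpos, base = iv.start + j, b
                else:
                    gpos, base = iv.end - 1 - j, revcomp(b)
                edits.append((gpos, base.encode()))
            table[(gene.gene_name, label)] = edits
    return table


def _allele_frequency_table(locus, db, config, coupled):
    """gene -> pop -> (labels, probability vector)."""
    rng = np.random.default_rng([config.seed, 999_983])
    out: dict[str, dict[str, tuple[list[str], np.ndarray]]] = {}
    pops = list(config.n_samples)
    for gene in locus.genes:
        if gene.gene_name in coupled:
            continue  # allele is determined by the conversion state
        labels = sorted(db[gene.gene_name])
        out[gene.gene_name] = {}
        for pop in pops:
            if config.allele_frequencies is not None:
                vec = np.asarray(
                    config.allele_frequencies[gene.gene_name][pop], dtype=float
                )
            else:
                vec = rng.dirichlet(np.ones(len(labels)))
            if len(vec) != len(labels) or abs(vec.sum() - 1) > 1e-9:
                raise ValidationError(
                    f"bad allele frequency vector for {gene.gene_name}/{pop}"
                )
            out[gene.gene_name][pop] = (labels, vec)
    return out


def _density_intervals(locus, config):
    """(start, end, rate, region_tag) candidate intervals for SNV placement."""
    out = []
    for tag, base in (
        ("proximal", config.snv_density_proximal),
        ("distal", config.snv_density_distal),
    ):
        region = locus.region(tag)
        cuts = [(region.start, region.end, 1.0)]
        featured = []
        for g in locus.genes:
            if g.region_tag != tag:
                continue
            for ftag, iv in g.features.items():
                mult = config.feature_density_multipliers.get(ftag, 1.0)
                featured.append((iv.start, iv.end, mult))
        featured.sort()
        # intergenic gaps between features keep the base rate
        pieces = []
        cursor = region.start
        for s, e, m in featured:
            if s > cursor:
                pieces.append((cursor, s, 1.0))
            pieces.append((s, e, m))
            cursor = max(cursor, e)
        if cursor < region.end:
            pieces.append((cursor, region.end, 1.0))
        out.extend((s, e, base * m, tag) for s, e, m in pieces)
    return out


def _simulate_haplotype(
    hap_id, sample, pop, locus, ref_arr, config, db, allele_edits, freqs,
    coupled, donor, insertion_svs, inversions, density_intervals, contig, rng,
):
    hap = ref_arr.copy()
    truth_alleles: dict[str, str] = {}
    source = {}  # pos -> edit source tag

    # 1. germline alleles
    for gene_name, pop_freqs in freqs.items():
        labels, vec = pop_freqs[pop]
        label = labels[rng.choice(len(labels), p=vec)]
        truth_alleles[gene_name] = label
        for gpos, base in allele_edits[(gene_name, label)]:
            hap[gpos] = base
            source[gpos] = "allele"

    # 2. gene conversion
    conversion_state = "reference"
    if locus.conversion_window is not None:
        if rng.random() < config.conversion_freq.get(pop, 0.0):
            conversion_state = "converted"
            win = locus.conversion_window
            hap[win.start : win.end] = ref_arr[donor.start : donor.end]
            for p in range(win.start, win.end):
                if hap[p] != ref_arr[p]:
                    source.setdefault(p, "conversion")
        for g in coupled:
            truth_alleles[g] = "*02" if conversion_state == "converted" else "*01"

    # 3. insertion SV state
    sv_states: dict[str, str] = {}
    deleted_spans: list[tuple[int, int]] = []
    for sv in insertion_svs:
        if rng.random() < config.sv_deletion_freq.get(pop, 0.0):
            sv_states[sv.sv_id] = "deleted"
            deleted_spans.append((sv.anchor.start, sv.anchor.end))
            for g in sv.carried_genes:
                truth_alleles[g] = "deleted"
        else:
            sv_states[sv.sv_id] = "present"
            for g in sv.carried_genes:
                if g not in truth_alleles:  # uncoupled carried gene
                    labels = sorted(db[g])
                    truth_alleles[g] = labels[rng.choice(len(labels))]

    # 4. inversion
    inversion_state = False
    inv_span = None
    if inversions and rng.random() < config.inversion_freq:
        inversion_state = True
        anchor = inversions[0].anchor
        inv_span = (anchor.start, anchor.end)

    # 5. scattered SNVs
    deleted_mask = np.zeros(len(hap), dtype=bool)
    for s, e in deleted_spans:
        deleted_mask[s:e] = True
    for s, e, rate, _tag in density_intervals:
        if rate <= 0:
            continue
        n = rng.poisson(rate * (e - s))
        if n == 0:
            continue
        pos = rng.choice(e - s, size=min(n, e - s), replace=False) + s
        for p in sorted(pos):
            if deleted_mask[p] or hap[p] != ref_arr[p] or hap[p] == b"N":
                continue  # already edited / deleted / masked
            choices = BASES[BASES != hap[p]]
            hap[p] = rng.choice(choices)
            source[p] = "snv"

    # truth alleles reflect the effective exon: scattered SNVs hitting an
    # exon turn the drawn allele into a novel one (or, rarely, another
    # known allele), exactly as the caller should report it
    for gene in locus.genes:
        name = gene.gene_name
        if truth_alleles.get(name) == "deleted":
            continue
        eff = _exon_from_array(hap, gene)
        for label, seq in db[name].items():
            if seq == eff:
                truth_alleles[name] = label
                break
        else:
            truth_alleles[name] = f"novel:{eff}"

    # truth SNV list: every surviving difference from the reference
    diff = np.nonzero((hap != ref_arr) & ~deleted_mask)[0]
    snvs = [
        (
            int(p),
            ref_arr[p].decode(),
            hap[p].decode(),
            source.get(int(p), "snv"),
        )
        for p in diff
    ]

    seq, records = _emit_alignment(
        hap, ref_arr, deleted_spans, inv_span, hap_id, contig
    )
    truth = HaplotypeTruth(
        sample=sample,
        hap_id=hap_id,
        population=pop,
        alleles=truth_alleles,
        snvs=snvs,
        sv_states=sv_states,
        conversion_state=conversion_state
        if locus.conversion_window is not None
        else "reference",
        inversion_state=inversion_state,
        deleted_spans=deleted_spans,
    )
    return SimulatedHaplotype(hap_id=hap_id, seq=seq, records=records, truth=truth)


def _emit_alignment(hap, ref_arr, deleted_spans, inv_span, hap_id, contig):
    """Haplotype sequence + truth alignment records from the edit plan."""
    L = len(ref_arr)
    kept = _subtract_spans([(0, L)], deleted_spans)
    if inv_span is None:
        parts = [("forward", kept)]
    else:
        s, e = inv_span
        parts = [
            ("forward", _clip_spans(kept, 0, s)),
            ("reverse", _clip_spans(kept, s, e)),
            ("forward", _clip_spans(kept, e, L)),
        ]
    parts = [(ori, spans) for ori, spans in parts if spans]

    chunks: list[str] = []
    records: list[AlignmentRecord] = []
    qpos = 0
    plan = []  # (orientation, spans, qstart)
    for ori, spans in parts:
        seg = "".join(hap[s:e].tobytes().decode() for s, e in spans)
        if ori == "reverse":
            seg = revcomp(seg)
        plan.append((ori, spans, qpos, seg))
        chunks.append(seg)
        qpos += len(seg)
    seq = "".join(chunks)

    for ori, spans, qstart, seg in plan:
        ops: list[tuple[str, int]] = []
        prev_end = None
        for s, e in spans:
            if prev_end is not None and s > prev_end:
                ops.append((DEL, s - prev_end))
            ops.extend(_diff_ops(hap[s:e], ref_arr[s:e]))
            prev_end = e
        records.append(
            make_record(
                query_id=hap_id,
                query_length=len(seq),
                query_start=qstart,
                target_id=contig,
                target_length=L,
                target_start=spans[0][0],
                orientation=ori,
                ops=ops,
            )
        )
    return seq, records


def _exon_from_array(hap, gene) -> str:
    iv = gene.exon
    seq = hap[iv.start : iv.end].tobytes().decode()
    return revcomp(seq) if gene.strand == "-" else seq


def _diff_ops(hap_slice, ref_slice) -> list[tuple[str, int]]:
    """Run-length =/X ops from two equal-length byte arrays."""
    n = len(hap_slice)
    mism = np.nonzero(hap_slice != ref_slice)[0]
    ops: list[tuple[str, int]] = []
    cursor = 0
    for p in mism:
        p = int(p)
        if p > cursor:
            ops.append((MATCH, p - cursor))
        if ops and ops[-1][0] == MISMATCH:
            ops[-1] = (MISMATCH, ops[-1][1] + 1)
        else:
            ops.append((MISMATCH, 1))
        cursor = p + 1
    if cursor < n:
        ops.append((MATCH, n - cursor))
    return ops


def _subtract_spans(spans, holes):
    out = list(spans)
    for hs, he in sorted(holes):
        new = []
        for s, e in out:
            if he <= s or hs >= e:
                new.append((s, e))
                continue
            if s < hs:
                new.append((s, hs))
            if he < e:
                new.append((he, e))
        out = new
    return out


def _clip_spans(spans, lo, hi):
    out = []
    for s, e in spans:
        a, b = max(s, lo), min(e, hi)
        if a < b:
            out.append((a, b))
    return out


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------

def simulate_reads(
    hap_seq: str,
    config: SimConfig,
    rng=None,
    hap_id: str = "hap",
):
    """Simulate error-bearing long reads from one haplotype.

    Returns (reads, records): reads as (read_id, sequence) pairs and
    truth alignments of each read to the haplotype.  Fragment lengths
    follow a normal law around the configured mean; substitution errors
    are i.i.d. per base at the configured rate.
    """
    if config.coverage <= 0:
        raise ValidationError("coverage must be > 0")
    if rng is None:
        rng = np.random.default_rng([config.seed, 999_941])
    L = len(hap_seq)
    mean_len = config.read_length_mean
    if mean_len > L:
        warnings.warn(
            f"{hap_id}: read length {mean_len:.0f} exceeds haplotype length {L}; "
            "emitting one full-length read"
        )
        lengths = [L]
    else:
        n_reads = max(1, int(round(config.coverage * L / mean_len)))
        lengths = np.clip(
            rng.normal(mean_len, config.read_length_sd_frac * mean_len, n_reads),
            50,
            L,
        ).astype(int)
    hap_arr = np.frombuffer(hap_seq.encode(), dtype="S1")
    reads, records = [], []
    for i, rlen in enumerate(lengths):
        rlen = int(rlen)
        start = int(rng.integers(0, L - rlen + 1))
        frag = hap_arr[start : start + rlen].copy()
        n_err = rng.binomial(rlen, config.read_error_rate)
        err_pos = (
            rng.choice(rlen, size=n_err, replace=False) if n_err else np.empty(0, int)
        )
        for p in err_pos:
            choices = BASES[BASES != frag[p]]
            frag[p] = rng.choice(choices)
        read_id = f"{hap_id}_r{i:05d}"
        reads.append((read_id, frag.tobytes().decode()))
        ops = _diff_ops(frag, hap_arr[start : start + rlen])
        records.append(
            make_record(
                query_id=read_id,
                query_length=rlen,
                query_start=0,
                target_id=hap_id,
                target_length=L,
                target_start=start,
                orientation="forward",
                ops=ops,
            )
        )
    return reads, records


# ---------------------------------------------------------------------------
# plain-text IO
# ---------------------------------------------------------------------------

def _write_wrapped(fh, seq: str, width: int = 80) -> None:
    for i in range(0, len(seq), width):
        fh.write(seq[i : i + width] + "\n")


def write_fasta(entries, path) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            _write_wrapped(fh, seq)


def iter_fasta(path):
    name, parts = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    yield name, "".join(parts)
                name, parts = line[1:].split()[0], []
            elif line:
                parts.append(line)
    if name is not None:
        yield name, "".join(parts)


def read_fasta(path) -> dict[str, str]:
    return dict(iter_fasta(path))


def write_truth_set(cohort: Cohort, path, snv_path=None) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#sample\thaplotype\tpopulation\tconversion_state\tinversion_state"
            "\tsv_states\talleles\n"
        )
        for h in cohort.haplotypes:
            t = h.truth
            svs = ";".join(f"{k}={v}" for k, v in sorted(t.sv_states.items()))
            alleles = ";".join(f"{k}={v}" for k, v in sorted(t.alleles.items()))
            fh.write(
                f"{t.sample}\t{t.hap_id}\t{t.population}\t{t.conversion_state}"
                f"\t{int(t.inversion_state)}\t{svs or '.'}\t{alleles or '.'}\n"
            )
    if snv_path is not None:
        with open(snv_path, "w") as fh:
            fh.write("#haplotype\tpos\tref\talt\tsource\n")
            for h in cohort.haplotypes:
                for pos, ref, alt, src in h.truth.snvs:
                    fh.write(f"{h.hap_id}\t{pos}\t{ref}\t{alt}\t{src}\n")


def write_metadata(cohort: Cohort, path) -> None:
    cohort.metadata.to_csv(path, sep="\t", index=False)
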