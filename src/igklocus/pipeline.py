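"""End-to-end drivers tying the analysis stages together.

Given haplotype sequences with alignments to the custom reference (in
memory or from files), run: SNV calling and cohort merge -> feature
annotation -> allele extraction and matching -> structural genotyping
-> population statistics.  The same functions serve the CLI, the
analysis scripts and the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import alleles as al
from . import popgen, structure, variants
from .locus import LocusMap
from .simulate import Cohort


@dataclass
class PipelineResult:
    cohort_genotypes: variants.CohortGenotypes
    filtered_genotypes: variants.CohortGenotypes
    maf_floor_percent: float
    allele_calls: list[al.AlleleCall]
    structure_genotypes: list[structure.StructureGenotype]
    hap_calls: dict[str, variants.HaplotypeCalls] = field(default_factory=dict)

    def allele_frame(self) -> pd.DataFrame:
        return al.calls_to_frame(self.allele_calls)

    def structure_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.structure_genotypes:
            row = {
                "sample": g.sample,
                "haplotype": g.haplotype_id,
                "conversion_state": g.conversion_state,
                "n_inversions": len(g.inversion_calls),
            }
            row.update(g.sv_calls)
            rows.append(row)
        return pd.DataFrame(rows)


def run_pipeline(
    cohort: Cohort,
    min_ac_exclusive: int = 1,
    conversion_margin: float = 0.002,
    annotate: bool = True,
) -> PipelineResult:
    """Full genotyping pass over an in-memory cohort."""
    locus = cohort.locus
    regions = [locus.proximal, locus.distal]
    hap_calls: dict[str, variants.HaplotypeCalls] = {}
    allele_calls: list[al.AlleleCall] = []
    struct_calls: list[structure.StructureGenotype] = []

    for hap in cohort.haplotypes:
        hc = variants.call_snvs(hap.records, hap.seq, cohort.reference, regions)
        hap_calls[hap.hap_id] = hc
        allele_calls.extend(
            al.call_alleles_for_haplotype(
                hap.records,
                hap.seq,
                locus,
                cohort.germline_db,
                sample=hap.truth.sample,
                hap_id=hap.hap_id,
            )
        )
        struct_calls.append(
            structure.genotype_structure(
                hap.records,
                hap.seq,
                locus,
                cohort.reference,
                sample=hap.truth.sample,
                hap_id=hap.hap_id,
                conversion_margin=conversion_margin,
            )
        )
    al.assign_novel_labels(allele_calls)

    merged = variants.merge_cohort(hap_calls, cohort.sample_map(), cohort.contig)
    if annotate:
        merged = variants.annotate_features(merged, locus)
    if merged.n_sites:
        filtered, floor = variants.filter_by_mac(merged, min_ac_exclusive)
    else:  # a monomorphic cohort has nothing to filter
        filtered = merged
        floor = variants.implied_maf_floor(len(merged.hap_ids), min_ac_exclusive)
    return PipelineResult(
        cohort_genotypes=merged,
        filtered_genotypes=filtered,
        maf_floor_percent=floor,
        allele_calls=allele_calls,
        structure_genotypes=struct_calls,
        hap_calls=hap_calls,
    )


def population_summary(result: PipelineResult, cohort: Cohort) -> dict:
    """Density, heterozygosity, skew and clustering summaries."""
    # density tracks use the unfiltered matrix: the generator plants
    # linkage-free per-haplotype SNVs, so frequency filtering strips
    # exactly the private variation the density statistic measures
    locus = cohort.locus
    merged = result.cohort_genotypes
    track_p = popgen.windowed_density(merged, locus.proximal)
    track_d = popgen.windowed_density(merged, locus.distal)
    diff, wilcoxon_p, degenerate = popgen.density_contrast(track_p, track_d)

    calls_df = result.allele_frame()
    het = al.heterozygosity_table(calls_df, cohort.metadata)
    freq_tables = popgen.build_freq_tables(calls_df, cohort.metadata)
    skew = popgen.allele_freq_skew(freq_tables)
    return {
        "track_proximal": track_p,
        "track_distal": track_d,
        "density_diff": diff,
        "density_wilcoxon_p": wilcoxon_p,
        "density_degenerate": degenerate,
        "heterozygosity": het,
        "freq_tables": freq_tables,
        "allele_skew": skew,
    }


def truth_genotype_matrix(cohort: Cohort) -> variants.CohortGenotypes:
    """Expected cohort matrix built directly from the truth ledger.

    Sites are the union of planted differences; a haplotype is missing
    at positions inside its deleted spans.
    """
    import numpy as np

    triples = sorted(
        {
            (pos, ref, alt)
            for hap in cohort.haplotypes
            for pos, ref, alt, _src in hap.truth.snvs
        }
    )
    sites = pd.DataFrame(triples, columns=["pos", "ref", "alt"])
    sites["feature"] = "intergenic"
    hap_ids = [h.hap_id for h in cohort.haplotypes]
    gt = np.zeros((len(hap_ids), len(triples)), dtype=np.int8)
    index = {t: j for j, t in enumerate(triples)}
    pos_arr = sites["pos"].to_numpy() if len(sites) else np.array([], dtype=int)
    for i, hap in enumerate(cohort.haplotypes):
        for pos, ref, alt, _src in hap.truth.snvs:
            gt[i, index[(pos, ref, alt)]] = 1
        for s, e in hap.truth.deleted_spans:
            gt[i, (pos_arr >= s) & (pos_arr < e)] = variants.MISSING
    return variants.CohortGenotypes(
        sites, gt, hap_ids, cohort.sample_map(), cohort.contig
    )


def score_against_truth(result: PipelineResult, cohort: Cohort) -> dict:
    """Recovery metrics against the simulator's truth ledger.

    Percentages over: planted allele labels (deleted is a label),
    haplotype-level SNV genotype entries, SV states, conversion states.
    """
    truth_by_hap = {h.hap_id: h.truth for h in cohort.haplotypes}

    call_lookup = {
        (c.haplotype_id, c.gene_name): c for c in result.allele_calls
    }
    n_alleles = n_alleles_ok = 0
    for hap_id, truth in truth_by_hap.items():
        for gene, expected in truth.alleles.items():
            call = call_lookup[(hap_id, gene)]
            n_alleles += 1
            if expected == "deleted":
                n_alleles_ok += call.state == "deleted"
            elif expected.startswith("novel:"):
                n_alleles_ok += (
                    call.state == "called"
                    and call.distance_nt > 0
                    and call.sequence == expected.removeprefix("novel:")
                )
            else:
                n_alleles_ok += (
                    call.state == "called"
                    and call.distance_nt == 0
                    and call.allele_label.removeprefix(gene) == expected
                )

    truth_matrix = truth_genotype_matrix(cohort)
    obs = result.cohort_genotypes
    same_sites = truth_matrix.sites[["pos", "ref", "alt"]].equals(
        obs.sites[["pos", "ref", "alt"]]
    )
    if same_sites and truth_matrix.hap_ids == obs.hap_ids:
        import numpy as np

        total = truth_matrix.hap_gt.size
        agree = int((truth_matrix.hap_gt == obs.hap_gt).sum())
        snv_pct = 100.0 * agree / total if total else 100.0
    else:
        snv_pct = 0.0

    n_sv = n_sv_ok = n_conv = n_conv_ok = 0
    for g in result.structure_genotypes:
        truth = truth_by_hap[g.haplotype_id]
        for sv_id, expected in truth.sv_states.items():
            n_sv += 1
            n_sv_ok += g.sv_calls.get(sv_id) == expected
        n_conv += 1
        n_conv_ok += g.conversion_state == truth.conversion_state

    return {
        "allele_recovery_pct": 100.0 * n_alleles_ok / n_alleles,
        "snv_genotype_concordance_pct": snv_pct,
        "snv_sites_identical": bool(same_sites),
        "sv_genotype_accuracy_pct": 100.0 * n_sv_ok / n_sv if n_sv else 100.0,
        "conversion_genotype_accuracy_pct": 100.0 * n_conv_ok / n_conv,
    }
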