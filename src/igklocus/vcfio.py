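"""VCF 4.2 emission and ingestion for the cohort genotype matrix.

Output is biallelic rows only, 1-based positions, phased haplotype
genotypes (the assemblies are haplotype-resolved), with INFO keys AC,
AN and FEAT.  Reading goes through pysam so any spec-conforming VCF
round-trips.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .variants import MISSING, CohortGenotypes

_HEADER = """\
##fileformat=VCFv4.2
##source=igklocus
##contig=<ID={contig},length={length}>
##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count over called haplotypes">
##INFO=<ID=AN,Number=1,Type=Integer,Description="Number of called haplotypes">
##INFO=<ID=FEAT,Number=1,Type=String,Description="Gene feature annotation">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased haplotype genotype">
"""


def write_vcf(cohort: CohortGenotypes, path, contig_length: int) -> None:
    sym = {0: "0", 1: "1", MISSING: "."}
    samples = cohort.samples
    with open(path, "w") as fh:
        fh.write(_HEADER.format(contig=cohort.contig, length=contig_length))
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        ac, an = cohort.ac, cohort.an
        idx = {h: i for i, h in enumerate(cohort.hap_ids)}
        for j, row in cohort.sites.iterrows():
            gts = []
            for s in samples:
                h1, h2 = cohort.sample_map[s]
                gts.append(
                    f"{sym[int(cohort.hap_gt[idx[h1], j])]}|"
                    f"{sym[int(cohort.hap_gt[idx[h2], j])]}"
                )
            info = f"AC={ac[j]};AN={an[j]};FEAT={row['feature']}"
            fh.write(
                f"{cohort.contig}\t{row['pos'] + 1}\t.\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t{info}\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path, sample_map: dict[str, tuple[str, str]] | None = None) -> CohortGenotypes:
    """Read a biallelic SNV VCF into a cohort matrix.

    If no sample->haplotype naming is given, haplotypes are named
    ``<sample>_h1`` / ``<sample>_h2``.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if sample_map is None:
            sample_map = {s: (f"{s}_h1", f"{s}_h2") for s in samples}
        contig = None
        rows = []
        gt_rows = []
        for rec in vf:
            if contig is None:
                contig = rec.chrom
            if len(rec.alts or ()) != 1:
                raise ValidationError(
                    f"{path}: row at {rec.pos} is not biallelic"
                )
            rows.append(
                {
                    "pos": rec.pos - 1,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "feature": rec.info.get("FEAT", "intergenic"),
                }
            )
            col = []
            for s in samples:
                a, b = rec.samples[s]["GT"]
                col.append(
                    (
                        MISSING if a is None else int(a),
                        MISSING if b is None else int(b),
                    )
                )
            gt_rows.append(col)

    sites = pd.DataFrame(rows, columns=["pos", "ref", "alt", "feature"])
    hap_ids = [h for s in samples for h in sample_map[s]]
    gt = np.full((len(hap_ids), len(sites)), 0, dtype=np.int8)
    for j, col in enumerate(gt_rows):
        for i, (a, b) in enumerate(col):
            gt[2 * i, j] = a
            gt[2 * i + 1, j] = b
    return CohortGenotypes(
        sites, gt, hap_ids, {s: sample_map[s] for s in samples}, contig or "ref"
    )
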