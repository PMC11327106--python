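"""Population statistics: windowed SNV density and the
proximal-vs-distal contrast (paired Wilcoxon); conversion-haplotype
density signature over the acceptor window; per-gene allele-frequency
skew (chi-square + BH FDR); PCA and IBS clustering of the distal
region.

Reads results/data, results/variants and results/structure outputs;
writes tables under results/popgen/.

Usage: python analysis/05_population_stats.py
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from igklocus import popgen
from igklocus.locus import load_locus
from igklocus.vcfio import read_vcf


def main():
    data = Path("results/data")
    out = Path("results/popgen")
    out.mkdir(parents=True, exist_ok=True)

    locus = load_locus(data / "locus.tsv")
    cohort = read_vcf(Path("results/variants/cohort.vcf"))
    filtered = read_vcf(Path("results/variants/cohort.mac_filtered.vcf"))
    metadata = pd.read_csv(data / "metadata.tsv", sep="\t")
    calls = pd.read_csv(Path("results/alleles/allele_calls.tsv"), sep="\t")
    struct = pd.read_csv(
        Path("results/structure/structure_genotypes.tsv"), sep="\t"
    )

    # density contrast on the unfiltered matrix (the generator plants
    # linkage-free private SNVs; see docs/methods.md)
    track_p = popgen.windowed_density(cohort, locus.proximal)
    track_d = popgen.windowed_density(cohort, locus.distal)
    diff, p_wilcoxon, _ = popgen.density_contrast(track_p, track_d)
    diff.rename("distal_minus_proximal").to_csv(
        out / "density_contrast.tsv", sep="\t"
    )
    print(f"mean density difference (distal - proximal): {diff.mean():.3e}; "
          f"paired Wilcoxon p = {p_wilcoxon:.3g}")

    # conversion carriers vs non-carriers over the acceptor window
    win = locus.conversion_window
    conv_dosage = struct.groupby("sample")["converted"].sum()
    dens_win = {
        s: popgen.snv_density(cohort, s, win) for s in cohort.samples
    }
    dens = pd.DataFrame({"window_density": dens_win, "conversion_dosage": conv_dosage})
    dens.to_csv(out / "conversion_window_density.tsv", sep="\t")
    by_group = dens.groupby("conversion_dosage")["window_density"].mean()
    print("mean acceptor-window density by conversion dosage:")
    print(by_group.round(6).to_string())

    # allele-frequency skew across populations
    tables = popgen.build_freq_tables(calls, metadata)
    skew = popgen.allele_freq_skew(tables)
    skew.to_csv(out / "allele_skew.tsv", sep="\t", index=False)
    sig = skew[skew["significant"] == True]  # noqa: E712
    print(f"{int(skew['testable'].sum())} genes testable; "
          f"{len(sig)} with significant skew (BH FDR < 0.05): "
          f"{sorted(sig['gene'])}")

    # PCA and IBS clustering of the distal region (filtered sites)
    distal = filtered.restrict(locus.distal)
    coords, evals = popgen.pca_genotypes(distal)
    coords.to_csv(out / "pca_distal.tsv", sep="\t")
    dis, _Z, clusters = popgen.ibs_cluster(distal, k=3)
    dis.to_csv(out / "ibs_dissimilarity_distal.tsv", sep="\t")
    clusters.rename("cluster").to_csv(out / "ibs_clusters.tsv", sep="\t")
    conv_by_cluster = dens["conversion_dosage"].groupby(clusters).mean()
    print("mean conversion dosage by IBS cluster:")
    print(conv_by_cluster.round(2).to_string())


if __name__ == "__main__":
    main()
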