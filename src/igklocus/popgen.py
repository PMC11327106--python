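"""Population-level statistics over cohort genotypes and allele calls.

SNV density per sample over an interval is the diploid-normalized
alternate-allele count, density = sum(dosage) / (2 * length); tracks of
10 Kbp windows along a region feed the proximal-vs-distal contrast
(paired Wilcoxon) and the conversion-haplotype density signature.
Allele-frequency skew between populations is tested per gene with a
chi-square on the population x allele haplotype-count table and
Benjamini-Hochberg FDR across genes; two-group contrasts (AFR vs
non-AFR) use Fisher's exact test.  PCA uses allele-frequency-scaled
dosages; identity-by-state dissimilarity feeds average-linkage
hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .locus import GenomicInterval
from .variants import MISSING, CohortGenotypes


@dataclass
class DensityTrack:
    windows: list[GenomicInterval]
    values: pd.DataFrame  # samples x windows, alt alleles per bp (diploid)

    def mean_per_sample(self) -> pd.Series:
        return self.values.mean(axis=1)


def snv_density(
    cohort: CohortGenotypes, sample: str, interval: GenomicInterval
) -> float:
    """Alternate alleles of one sample in the interval per diploid bp."""
    if interval.length() <= 0:
        raise ValidationError("zero-length interval")
    sub = cohort.restrict(interval)
    dosage = sub.dosage().loc[sample].fillna(0.0)
    return float(dosage.sum()) / (interval.length() * 2)


def windowed_density(
    cohort: CohortGenotypes, region: GenomicInterval, window_size: int = 10_000
) -> DensityTrack:
    """Half-open tiling of the region; the final partial window is
    normalized by its true length."""
    if window_size <= 0:
        raise ValidationError("window_size must be > 0")
    windows = []
    s = region.start
    while s < region.end:
        e = min(s + window_size, region.end)
        windows.append(GenomicInterval(region.contig, s, e))
        s = e
    pos = cohort.sites["pos"].to_numpy()
    dosage = cohort.dosage().fillna(0.0)
    cols = {}
    for j, w in enumerate(windows):
        mask = (pos >= w.start) & (pos < w.end)
        cols[j] = dosage.loc[:, mask].sum(axis=1) / (w.length() * 2)
    values = pd.DataFrame(cols)
    return DensityTrack(windows=windows, values=values)


def density_contrast(
    track_proximal: DensityTrack, track_distal: DensityTrack
) -> tuple[pd.Series, float, bool]:
    """Per-sample (mean distal - mean proximal) window density, with a
    two-sided paired Wilcoxon signed-rank p-value.

    Exact when n <= 25 without ties/zeros (scipy's automatic policy),
    normal approximation with tie correction otherwise.  All-zero
    differences return p = 1 with the degenerate flag set.
    """
    mp = track_proximal.mean_per_sample()
    md = track_distal.mean_per_sample()
    if not mp.index.equals(md.index):
        raise ValidationError("tracks cover different samples")
    diff = md - mp
    if (diff == 0).all():
        return diff, 1.0, True
    res = stats.wilcoxon(diff.to_numpy(), alternative="two-sided")
    return diff, float(res.pvalue), False


# ---------------------------------------------------------------------------
# allele frequency tables and skew tests
# ---------------------------------------------------------------------------

def build_freq_tables(
    calls: pd.DataFrame, metadata: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Per gene: population x allele haplotype-count table.

    A structurally deleted gene is an allele category ("deleted");
    unresolved haplotypes are dropped from the denominators.
    """
    pop = metadata.set_index("sample")["population"]
    out = {}
    for gene, sub in calls.groupby("gene"):
        sub = sub[sub["state"] != "unresolved"].copy()
        if sub.empty:
            continue
        sub["category"] = np.where(
            sub["state"] == "deleted", "deleted", sub["allele_label"]
        )
        sub["population"] = sub["sample"].map(pop)
        out[gene] = (
            sub.groupby(["population", "category"]).size().unstack(fill_value=0)
        )
    return out


def freq_table_frequencies(table: pd.DataFrame) -> pd.DataFrame:
    """Row-normalized frequencies; rows sum to 1 over called haplotypes."""
    denom = table.sum(axis=1)
    return table.div(denom, axis=0)


def allele_freq_skew(
    freq_tables: dict[str, pd.DataFrame], fdr_alpha: float = 0.05
) -> pd.DataFrame:
    """Chi-square allele-frequency skew per gene, BH-adjusted.

    No continuity correction and no expected-count guard (tables are
    small by design); min_expected is reported so validity can be
    judged.  Genes with a single allele category are untestable and
    excluded from the FDR family.
    """
    rows = []
    for gene, table in freq_tables.items():
        table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
        if table.shape[0] < 2 or table.shape[1] < 2:
            rows.append(
                {
                    "gene": gene,
                    "testable": False,
                    "chi2": np.nan,
                    "dof": 0,
                    "p": np.nan,
                    "min_expected": np.nan,
                }
            )
            continue
        chi2, p, dof, expected = stats.chi2_contingency(
            table.to_numpy(), correction=False
        )
        rows.append(
            {
                "gene": gene,
                "testable": True,
                "chi2": float(chi2),
                "dof": int(dof),
                "p": float(p),
                "min_expected": float(expected.min()),
            }
        )
    df = pd.DataFrame(rows).set_index("gene")
    df["p_adj"] = np.nan
    testable = df["testable"]
    if testable.any():
        df.loc[testable, "p_adj"] = bh_adjust(df.loc[testable, "p"].to_numpy())
    df["significant"] = df["p_adj"] < fdr_alpha
    return df.reset_index()


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(pvalues, method="fdr_bh")[1]


def fisher_group_test(
    states: np.ndarray, in_group: np.ndarray
) -> tuple[float, float, bool]:
    """Two-sided Fisher's exact test of a binary haplotype state
    between a group and its complement.

    Returns (odds_ratio, p, degenerate); a zero margin yields p = 1
    with the degenerate flag.
    """
    states = np.asarray(states, dtype=bool)
    in_group = np.asarray(in_group, dtype=bool)
    table = np.array(
        [
            [int((states & in_group).sum()), int((~states & in_group).sum())],
            [int((states & ~in_group).sum()), int((~states & ~in_group).sum())],
        ]
    )
    return fisher_exact_2x2(table)


def fisher_exact_2x2(table: np.ndarray) -> tuple[float, float, bool]:
    table = np.asarray(table)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), 1.0, True
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p), False


# ---------------------------------------------------------------------------
# PCA and IBS clustering
# ---------------------------------------------------------------------------

def pca_genotypes(
    cohort: CohortGenotypes, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample coordinates on the top eigenvectors of the genotype
    covariance.

    Dosages are centered at 2*p and scaled by sqrt(p*(1-p)) per site
    (allele-frequency variance scaling); missing dosages are imputed
    with the site mean.  Sign convention: each eigenvector's
    largest-magnitude loading is positive.  Returns (coords, eigenvalues).
    """
    if len(cohort.samples) < 2:
        raise ValidationError("PCA needs >= 2 samples")
    D = cohort.dosage()
    p = D.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValidationError("no polymorphic sites for PCA")
    D = D.loc[:, poly]
    p = p[poly]
    X = (D - 2 * p) / np.sqrt(p * (1 - p))
    X = X.fillna(0.0).to_numpy()
    grm = X @ X.T / X.shape[1]
    evals, evecs = np.linalg.eigh(grm)
    order = np.argsort(evals)[::-1][:n_components]
    coords = evecs[:, order]
    evals = evals[order]
    for k in range(coords.shape[1]):
        if coords[np.argmax(np.abs(coords[:, k])), k] < 0:
            coords[:, k] = -coords[:, k]
    return (
        pd.DataFrame(
            coords,
            index=list(D.index),
            columns=[f"EV{k + 1}" for k in range(coords.shape[1])],
        ),
        evals,
    )


def ibs_dissimilarity(cohort: CohortGenotypes) -> tuple[pd.DataFrame, list]:
    """1 - mean identity-by-state over sites called in both samples.

    Per-site IBS = 1 - |dosage_i - dosage_j| / 2.  Pairs with no
    jointly called site are NaN and returned in the flagged list.
    """
    D = cohort.dosage().to_numpy(dtype=float)
    samples = cohort.samples
    n = len(samples)
    out = np.zeros((n, n))
    flagged = []
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(D[i]) & ~np.isnan(D[j])
            if not both.any():
                out[i, j] = out[j, i] = np.nan
                flagged.append((samples[i], samples[j]))
                continue
            ibs = 1.0 - np.abs(D[i, both] - D[j, both]) / 2.0
            out[i, j] = out[j, i] = 1.0 - ibs.mean()
    return pd.DataFrame(out, index=samples, columns=samples), flagged


def ibs_cluster(
    cohort: CohortGenotypes, k: int
) -> tuple[pd.DataFrame, np.ndarray, pd.Series]:
    """Average-linkage hierarchical clustering on IBS dissimilarity.

    Returns (dissimilarity matrix, linkage, cluster labels).  Samples
    are processed in sorted label order so ties resolve
    deterministically.
    """
    if len(cohort.samples) < 2:
        raise ValidationError("clustering needs >= 2 samples")
    order = sorted(cohort.samples)
    dis, flagged = ibs_dissimilarity(cohort.reorder_samples(order))
    if flagged:
        raise ValidationError(f"pairs with no jointly called site: {flagged}")
    Z = hierarchy.linkage(squareform(dis.to_numpy(), checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return dis, Z, pd.Series(labels, index=order, name="cluster")
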