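"""Sm-site-stratified enrichment statistics for RIP-seq contrasts.

The fidelity path consumes externally computed per-gene log2 fold-changes and
adjusted p-values (e.g. a DESeq2 Wald test exported as TSV); a simplified
internal route (median-of-ratios size factors + pseudocounted mean ratio)
supports simulation-only workflows and carries no per-gene test.

Enrichment is classified with the study-wide thresholds log2(fold-change)
> 0.6 and adjusted p < 0.05 (i.e. > 1.5-fold).  Gene strata (Absent /
Noncanonical / Canonical Sm-site) are compared with one-sided two-sample
Wilcoxon rank-sum tests using the normal approximation with tie and
continuity corrections, Benjamini-Hochberg corrected across the pairs of one
call; ECDF coordinates are emitted for plotting cumulative-distribution
shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "LfcTable",
    "StrataTestResult",
    "DensityTable",
    "size_factors",
    "simple_lfc",
    "classify_enrichment",
    "stratified_cdf_test",
    "kendall_tau",
    "site_density",
    "candidate_intersection",
    "bh_adjust",
    "read_counts_tsv",
    "read_lfc_tsv",
]


@dataclass
class CountMatrix:
    """Gene x sample counts plus a sample -> condition design."""

    counts: pd.DataFrame  # index gene_id, columns sample ids, ints >= 0
    conditions: dict[str, str]  # sample -> condition label

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition labels: {sorted(missing)}")

    def samples_of(self, condition: str) -> list[str]:
        out = [s for s in self.counts.columns if self.conditions[s] == condition]
        if not out:
            raise ValueError(f"no samples with condition {condition!r}")
        return out


@dataclass
class LfcTable:
    """Per-gene log2 fold-change and (optional) adjusted p-value."""

    table: pd.DataFrame  # index gene_id, columns lfc [, padj]

    def __post_init__(self) -> None:
        if "lfc" not in self.table.columns:
            raise ValueError("LfcTable requires an 'lfc' column")
        if "padj" in self.table.columns:
            p = self.table["padj"].dropna()
            if ((p < 0) | (p > 1)).any():
                raise ValueError("padj outside [0, 1]")

    @property
    def has_padj(self) -> bool:
        return "padj" in self.table.columns and self.table["padj"].notna().any()


def read_counts_tsv(counts_path, design_path) -> CountMatrix:
    """Counts TSV (gene_id x samples) with a sidecar design TSV (sample, condition)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t")
    conditions = dict(zip(design["sample"], design["condition"]))
    return CountMatrix(counts, conditions)


def read_lfc_tsv(path) -> LfcTable:
    df = pd.read_csv(path, sep="\t")
    df = df.set_index("gene_id")
    return LfcTable(df)


def size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios normalization factors (one per sample).

    For genes with positive counts in every sample, each sample's factor is
    the median of count / geometric-mean ratios.
    """
    counts = m.counts.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in all samples; "
            "add a pseudocount or filter samples"
        )
    sub = counts[positive]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=m.counts.columns, name="size_factor")


def simple_lfc(
    m: CountMatrix, contrast: tuple[str, str], pseudocount: float = 0.5
) -> LfcTable:
    """Normalized log2 fold-change of condition A over condition B.

    A deliberately simple stand-in for a count-model fit: normalized condition
    means with a symmetric pseudocount; no per-gene test, so ``padj`` is
    absent.
    """
    cond_a, cond_b = contrast
    sf = size_factors(m)
    norm = m.counts / sf
    mean_a = norm[m.samples_of(cond_a)].mean(axis=1)
    mean_b = norm[m.samples_of(cond_b)].mean(axis=1)
    lfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    return LfcTable(pd.DataFrame({"lfc": lfc}))


def classify_enrichment(
    t: LfcTable, up: float = 0.6, down: float = -0.6, alpha: float = 0.05
) -> pd.Series:
    """Classify genes as enriched / depleted / neither.

    Enriched: lfc > ``up`` and padj < ``alpha``; depleted: lfc < ``down`` and
    padj < ``alpha``.  Requires adjusted p-values (import an external table
    for tested fold-changes).
    """
    if not t.has_padj:
        raise ValueError(
            "classification requires adjusted p-values; import an external "
            "(gene_id, lfc, padj) table"
        )
    lfc = t.table["lfc"]
    padj = t.table["padj"]
    cls = pd.Series("neither", index=t.table.index, name="class")
    cls[(lfc > up) & (padj < alpha)] = "enriched"
    cls[(lfc < down) & (padj < alpha)] = "depleted"
    return cls


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, >= raw p)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class StrataTestResult:
    """One ordered stratum comparison: Wilcoxon rank-sum with BH correction."""

    contrast: str
    stratum_a: str
    stratum_b: str
    n_a: int
    n_b: int
    statistic: float
    alternative: str
    p: float
    padj: float = float("nan")
    ecdf: pd.DataFrame | None = field(default=None, repr=False)


def _ecdf_frame(values: np.ndarray, label: str) -> pd.DataFrame:
    x = np.sort(values)
    y = np.arange(1, x.size + 1) / x.size
    return pd.DataFrame({"stratum": label, "lfc": x, "ecdf": y})


def stratified_cdf_test(
    t: LfcTable,
    strata: Mapping[str, str],
    pairs: Sequence[tuple[str, str]],
    alternative: str = "greater",
    contrast: str = "",
) -> list[StrataTestResult]:
    """Compare log2 fold-change distributions between gene strata.

    For each ordered pair (A, B), a one-sided two-sample Wilcoxon rank-sum
    test of A's lfc values against B's (normal approximation with tie and
    continuity corrections; the statistic is the Mann-Whitney U of stratum A).
    BH correction is applied across the supplied pairs.  Each result carries
    ECDF coordinates of both strata for plotting.
    """
    if alternative not in ("greater", "less"):
        raise ValueError(f"alternative must be 'greater' or 'less': {alternative!r}")
    labels = pd.Series({g: strata[g] for g in t.table.index if g in strata})
    groups = {
        lab: t.table.loc[idx, "lfc"].to_numpy()
        for lab, idx in labels.groupby(labels).groups.items()
    }
    results = []
    for a, b in pairs:
        for lab in (a, b):
            if lab not in groups or groups[lab].size == 0:
                raise ValueError(f"empty stratum: {lab!r}")
        xa, xb = groups[a], groups[b]
        if xa.size < 2 or xb.size < 2:
            raise ValueError(f"stratum too small for {a} vs {b} (n >= 2 required)")
        stat, p = stats.mannwhitneyu(
            xa, xb, alternative=alternative, use_continuity=True, method="asymptotic"
        )
        results.append(
            StrataTestResult(
                contrast=contrast,
                stratum_a=a,
                stratum_b=b,
                n_a=xa.size,
                n_b=xb.size,
                statistic=float(stat),
                alternative=alternative,
                p=float(p),
                ecdf=pd.concat([_ecdf_frame(xa, a), _ecdf_frame(xb, b)]),
            )
        )
    padj = bh_adjust([r.p for r in results])
    for r, q in zip(results, padj):
        r.padj = float(q)
    return results


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Kendall tau-b rank correlation with normal-approximation p-value.

    Used for rank-order comparisons such as per-gene Sm-site frequency
    against transcript or 3'UTR length.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("kendall_tau requires n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("tau undefined for a constant vector")
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass
class DensityTable:
    """Region -> (site count, total region length, sites per million bases)."""

    table: pd.DataFrame  # index region, columns sites, length_nt, per_mb


def site_density(
    summaries: Sequence,
    motif_class: str = "canonical",
    regions: Sequence = None,
) -> DensityTable:
    """Sm-site density per mRNA region in sites per million bases.

    Pools site counts and region lengths across genes: density = total sites
    / total length x 1e6 for each region.
    """
    from smsite.annotation_io import Region

    if regions is None:
        regions = (Region.FIVE_UTR, Region.CDS, Region.THREE_UTR)
    length_attr = {
        Region.FIVE_UTR: "utr5_length",
        Region.CDS: "cds_length",
        Region.THREE_UTR: "utr3_length",
        Region.NONCODING: "transcript_length",
    }
    rows = []
    for region in regions:
        sites = sum(
            s.region_counts.get((motif_class, region), 0) for s in summaries
        )
        length = sum(getattr(s, length_attr[region]) for s in summaries)
        if length == 0:
            raise ValueError(f"zero total length for region {region}")
        rows.append(
            {
                "region": str(region),
                "sites": sites,
                "length_nt": length,
                "per_mb": sites / length * 1e6,
            }
        )
    return DensityTable(pd.DataFrame(rows).set_index("region"))


def candidate_intersection(
    tables: Mapping[str, LfcTable],
    ambiguous: set[str] | None = None,
) -> pd.DataFrame:
    """Genes classified enriched in every comparison and genomically unambiguous.

    Mirrors a multi-way RIP candidate funnel: ATP-induced enrichment,
    enrichment over the input library, and Sm-protein association must all
    hold, and genes mapping to more than one genome are excluded.  Ordered by
    descending minimum lfc across the comparisons.
    """
    ambiguous = ambiguous or set()
    if not tables:
        raise ValueError("no comparisons supplied")
    enriched_sets = []
    for name, t in tables.items():
        cls = classify_enrichment(t)
        enriched_sets.append(set(cls.index[cls == "enriched"]))
    candidates = set.intersection(*enriched_sets) - ambiguous
    rows = []
    for g in candidates:
        lfcs = {name: float(t.table.loc[g, "lfc"]) for name, t in tables.items()}
        rows.append({"gene_id": g, "min_lfc": min(lfcs.values()), **lfcs})
    df = pd.DataFrame(rows, columns=["gene_id", "min_lfc", *tables])
    if not df.empty:
        df = df.sort_values(
            ["min_lfc", "gene_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return df
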