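"""TPM normalization, pairwise differential expression and profile classes.

The stage design has four groups (larvae, nymphs, adult females, adult
males), giving C(4,2) = 6 pairwise comparisons. A gene's *profile class* is
the subset of comparisons in which it is called significant (FDR-adjusted
p <= 0.05 and fold change >= +/-2), so with four groups there are
2^6 - 1 = 63 possible non-empty classes. A gene is flagged as differential
in a particular stage/sex only when all three of its comparisons against
the other groups are significant with a consistent direction.

Fold changes come from group-mean TPM with a pseudocount of 1. The default
test (``method="moderated"``) is a moderated t-test against the composite
null |effect| <= log2(fold cutoff), computed on log2 median-of-ratios
normalized counts: per-gene pooled variances are shrunk toward a common
prior fitted empirically across genes (scaled inverse-chi-square,
Smyth-style moment matching), which restores power at 3 replicates per
group the same way limma/DESeq2-type engines do, and the threshold null
mirrors DESeq2's lfcThreshold mode so that genes whose true change is
below the biological cutoff are not flagged on sampling noise alone.
Median-of-ratios size factors (rather than TPM column sums) remove the
compositional bias that strong stage-biased genes induce on the rest of
the transcriptome. A plain Welch t-test of the point null on log2(TPM+1)
is available via ``method="welch"``; it is simpler but underpowered and
anticonservative at this design scale. Neither attempts to reproduce a
count-model engine's p-values numerically; the (log2fc, p, q) contract is
what is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests


@dataclass
class ExpressionMatrix:
    """Raw counts with the sample->group mapping and gene lengths.

    ``counts`` is genes x samples (non-negative integers), ``groups`` maps
    sample_id -> group label, ``lengths`` maps gene_id -> length in nt.
    """

    counts: pd.DataFrame
    groups: pd.Series
    lengths: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = self.counts.index.difference(self.lengths.index)
        if len(missing):
            raise ValueError(f"genes without a length: {list(missing[:5])}")
        if (self.lengths.loc[self.counts.index] <= 0).any():
            raise ValueError("gene lengths must be positive")
        unmapped = self.counts.columns.difference(self.groups.index)
        if len(unmapped):
            raise ValueError(f"samples without a group: {list(unmapped[:5])}")
        self.groups = self.groups.loc[self.counts.columns]
        self.lengths = self.lengths.loc[self.counts.index]

    @property
    def group_order(self) -> list[str]:
        """Group labels in first-appearance (sample sheet) order."""
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def samples_of(self, group: str) -> list[str]:
        cols = [s for s in self.counts.columns if self.groups[s] == group]
        if not cols:
            raise ValueError(f"unknown group {group!r}")
        return cols


def compute_tpm(em: ExpressionMatrix) -> pd.DataFrame:
    """Transcripts per million: each sample column sums to 1e6.

    rate_g = count_g / (length_g / 1000); TPM_g = rate_g / sum(rate) * 1e6.
    An all-zero sample yields an all-zero column.
    """
    kb = em.lengths.to_numpy(dtype=float) / 1000.0
    rate = em.counts.to_numpy(dtype=float) / kb[:, None]
    colsum = rate.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = np.where(colsum > 0, rate / colsum * 1e6, 0.0)
    return pd.DataFrame(tpm, index=em.counts.index, columns=em.counts.columns)


def group_mean_tpm(em: ExpressionMatrix, tpm: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-group mean TPM (genes x groups, groups in sample-sheet order)."""
    tpm = compute_tpm(em) if tpm is None else tpm
    return pd.DataFrame(
        {g: tpm[em.samples_of(g)].mean(axis=1) for g in em.group_order})


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def comparison_label(x: str, y: str) -> str:
    return f"{x}_vs_{y}"


def canonical_comparisons(groups: list[str]) -> list[tuple[str, str]]:
    """All group pairs in the canonical (combinations) order."""
    return list(combinations(groups, 2))


def _welch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t-test p-values; zero-variance rows handled explicitly."""
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    p = np.ones(a.shape[0])
    ok = se2 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1[ok] - m2[ok]) / np.sqrt(se2[ok])
        df = se2[ok] ** 2 / (
            (v1[ok] / n1) ** 2 / (n1 - 1) + (v2[ok] / n2) ** 2 / (n2 - 1))
        p[ok] = 2.0 * stats.t.sf(np.abs(t), df)
    # no within-group variability at all: certain if the means differ
    degenerate = ~ok
    p[degenerate] = np.where(m1[degenerate] == m2[degenerate], 1.0, 0.0)
    return p


def _fit_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Fit a scaled inverse-chi-square prior (d0, s0^2) to sample variances.

    Moment matching on log variances: for s^2 ~ s0^2 * F(d, d0), the
    statistic e = log(s^2) - digamma(d/2) + log(d/2) has variance
    trigamma(d/2) + trigamma(d0/2) and mean
    log(s0^2) - digamma(d0/2) + log(d0/2). Genes with zero variance are
    excluded from the fit. Returns (d0, s0sq); d0 = inf when the observed
    spread is no wider than sampling noise alone.
    """
    from scipy.special import digamma, polygamma

    ls2 = np.log(s2[s2 > 0])
    if ls2.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    e = ls2 - digamma(d / 2.0) + np.log(d / 2.0)
    excess = float(np.var(e, ddof=1)) - float(polygamma(1, d / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(np.mean(e)))
    # invert trigamma (monotone decreasing) by Newton's method
    y = excess
    x = 0.5 + 1.0 / y
    for _ in range(100):
        step = -(float(polygamma(1, x)) - y) / float(polygamma(2, x))
        x_new = max(x + step, 1e-8)
        if abs(x_new - x) < 1e-10 * x:
            x = x_new
            break
        x = x_new
    d0 = 2.0 * x
    s0sq = float(np.exp(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


def _moderated_t(a: np.ndarray, b: np.ndarray,
                 lfc_null: float = 0.0) -> np.ndarray:
    """Row-wise moderated t-test p-values (empirical-Bayes pooled variance).

    Per-gene pooled within-group variances (d = n1+n2-2 df) are squeezed
    toward the fitted prior: s2_mod = (d0*s0^2 + d*s2) / (d0 + d); the t
    statistic then has d + d0 degrees of freedom. With ``lfc_null`` > 0 the
    null hypothesis is the composite |mean difference| <= lfc_null and the
    p-value is the upper tail of t = (|diff| - lfc_null) / se.
    """
    n1, n2 = a.shape[1], b.shape[1]
    d = n1 + n2 - 2
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d
    d0, s0sq = _fit_variance_prior(s2, d)
    if np.isinf(d0):
        s2_mod = np.full_like(s2, s0sq)
        df = np.inf
    else:
        s2_mod = (d0 * s0sq + d * s2) / (d0 + d)
        df = d0 + d
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    p = np.ones(a.shape[0])
    ok = se > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        if lfc_null > 0:
            t = (np.abs(diff[ok]) - lfc_null) / se[ok]
            p[ok] = stats.t.sf(t, df) if not np.isinf(df) else stats.norm.sf(t)
        else:
            t = diff[ok] / se[ok]
            p[ok] = (2.0 * stats.t.sf(np.abs(t), df) if not np.isinf(df)
                     else 2.0 * stats.norm.sf(np.abs(t)))
    degenerate = ~ok
    p[degenerate] = np.where(np.abs(diff[degenerate]) <= lfc_null, 1.0, 0.0)
    return p


def size_factors(counts: pd.DataFrame) -> np.ndarray:
    """Median-of-ratios library size factors (one per sample).

    Each sample's factor is the median across genes of its count divided by
    that gene's geometric-mean count; genes with a zero anywhere are
    excluded from the reference, as is conventional for count models. Falls
    back to relative library totals when no gene is zero-free.
    """
    x = counts.to_numpy(dtype=float)
    allpos = (x > 0).all(axis=1)
    if allpos.sum() >= 1:
        logx = np.log(x[allpos])
        ratios = logx - logx.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(ratios, axis=0))
    else:
        totals = x.sum(axis=0)
        totals[totals == 0] = 1.0
        sf = totals / np.exp(np.mean(np.log(totals)))
    return sf


def pairwise_de(em: ExpressionMatrix, group_x: str, group_y: str,
                tpm: pd.DataFrame | None = None, pseudocount: float = 1.0,
                method: str = "moderated",
                lfc_null: float | None = None) -> pd.DataFrame:
    """Differential expression between two groups.

    log2fc = log2((mean TPM_X + c) / (mean TPM_Y + c)) with pseudocount
    c = 1 (positive = higher in ``group_x``). With the default
    ``method="moderated"``, p-values come from a variance-moderated t-test
    of the composite null |effect| <= ``lfc_null`` (default log2(2),
    matching the downstream fold-change cutoff) on log2 size-factor
    normalized counts; ``method="welch"`` runs a plain Welch t-test of the
    point null on log2(TPM+1). q-values are Benjamini-Hochberg across all
    genes of the comparison.
    """
    tpm = compute_tpm(em) if tpm is None else tpm
    sx, sy = em.samples_of(group_x), em.samples_of(group_y)
    if len(sx) < 2 or len(sy) < 2:
        raise ValueError("each group needs >= 2 samples for testing")
    mx = tpm[sx].mean(axis=1).to_numpy()
    my = tpm[sy].mean(axis=1).to_numpy()
    log2fc = np.log2((mx + pseudocount) / (my + pseudocount))
    ix = [tpm.columns.get_loc(s) for s in sx]
    iy = [tpm.columns.get_loc(s) for s in sy]
    if method == "moderated":
        if lfc_null is None:
            lfc_null = float(np.log2(2.0))
        sf = size_factors(em.counts)
        lognorm = np.log2(em.counts.to_numpy(dtype=float) / sf[None, :] + 1.0)
        pvalue = _moderated_t(lognorm[:, ix], lognorm[:, iy], lfc_null=lfc_null)
    elif method == "welch":
        logtpm = np.log2(tpm.to_numpy() + 1.0)
        pvalue = _welch(logtpm[:, ix], logtpm[:, iy])
    else:
        raise ValueError(f"unknown DE method {method!r}")
    return pd.DataFrame({
        "gene_id": tpm.index,
        "comparison": comparison_label(group_x, group_y),
        "log2fc": log2fc,
        "pvalue": pvalue,
        "qvalue": bh_adjust(pvalue),
    })


def all_pairwise_de(em: ExpressionMatrix, tpm: pd.DataFrame | None = None,
                    method: str = "moderated",
                    lfc_null: float | None = None) -> pd.DataFrame:
    """Run all C(k,2) pairwise comparisons in canonical group order."""
    tpm = compute_tpm(em) if tpm is None else tpm
    frames = [pairwise_de(em, x, y, tpm=tpm, method=method, lfc_null=lfc_null)
              for x, y in canonical_comparisons(em.group_order)]
    return pd.concat(frames, ignore_index=True)


def assign_profiles(de: pd.DataFrame, groups: list[str], alpha: float = 0.05,
                    fc_cutoff: float = 2.0,
                    stage_means: pd.DataFrame | None = None) -> pd.DataFrame:
    """Signed per-comparison calls, profile (Venn) class and stage flags.

    A call is +1 when the first-named group is significantly higher
    (q <= alpha and log2fc >= log2(fc_cutoff)), -1 for the second group,
    0 otherwise. The ``venn_class`` is the "+"-joined subset of comparisons
    with a nonzero call, in canonical order (empty string = not a DEG).
    ``flag_<group>`` is true when all comparisons involving that group are
    significant with the group on the same side.
    """
    comps = canonical_comparisons(groups)
    labels = [comparison_label(x, y) for x, y in comps]
    missing = set(labels) - set(de["comparison"].unique())
    if missing:
        raise ValueError(f"missing comparisons: {sorted(missing)}")
    lfc_min = np.log2(fc_cutoff)

    wide_fc = de.pivot(index="gene_id", columns="comparison", values="log2fc")
    wide_q = de.pivot(index="gene_id", columns="comparison", values="qvalue")
    calls = pd.DataFrame(0, index=wide_fc.index, columns=labels, dtype=int)
    for lab in labels:
        sig = (wide_q[lab] <= alpha) & (wide_fc[lab].abs() >= lfc_min)
        calls[lab] = np.where(sig, np.sign(wide_fc[lab]).astype(int), 0)

    venn = calls.apply(
        lambda row: "+".join(lab for lab in labels if row[lab] != 0), axis=1)

    out = pd.DataFrame(index=calls.index)
    if stage_means is not None:
        for g in groups:
            out[f"tpm_mean_{g}"] = stage_means[g]
    for lab in labels:
        out[f"call_{lab}"] = calls[lab]
    out["venn_class"] = venn
    for g in groups:
        oriented = []
        for (x, y), lab in zip(comps, labels):
            if g == x:
                oriented.append(calls[lab])
            elif g == y:
                oriented.append(-calls[lab])
        oriented = pd.concat(oriented, axis=1)
        out[f"flag_{g}"] = (oriented != 0).all(axis=1) & (
            (oriented > 0).all(axis=1) | (oriented < 0).all(axis=1))
    return out


def stage_profiles(em: ExpressionMatrix, alpha: float = 0.05,
                   fc_cutoff: float = 2.0,
                   method: str = "moderated") -> pd.DataFrame:
    """Full pipeline: TPM -> all pairwise DE -> profile table."""
    tpm = compute_tpm(em)
    de = all_pairwise_de(em, tpm=tpm, method=method,
                         lfc_null=float(np.log2(fc_cutoff)))
    means = group_mean_tpm(em, tpm=tpm)
    return assign_profiles(de, em.group_order, alpha=alpha,
                           fc_cutoff=fc_cutoff, stage_means=means)


def enumerate_profile_classes(groups: list[str]) -> list[str]:
    """All 2^C(k,2) - 1 non-empty profile-class labels, canonical order."""
    labels = [comparison_label(x, y) for x, y in canonical_comparisons(groups)]
    classes = []
    for mask in range(1, 2 ** len(labels)):
        classes.append("+".join(lab for i, lab in enumerate(labels)
                                if mask >> i & 1))
    return classes


def venn_counts(profiles: pd.DataFrame, groups: list[str]) -> pd.Series:
    """DEG count per possible profile class (all classes, zeros included)."""
    classes = enumerate_profile_classes(groups)
    observed = profiles.loc[profiles["venn_class"] != "", "venn_class"]
    counts = observed.value_counts()
    return pd.Series([int(counts.get(c, 0)) for c in classes],
                     index=pd.Index(classes, name="venn_class"), name="n_genes")


def count_fold_threshold(de: pd.DataFrame, group_x: str, group_y: str,
                         fold: float = 50.0, alpha: float = 0.05) -> int:
    """Genes significantly > ``fold``-fold higher in X than in Y (strict).

    Accepts the comparison in either orientation; the stored log2fc is
    negated when (Y, X) is the canonical direction. An empty DE table
    counts zero.
    """
    if de.empty:
        return 0
    lab_fwd = comparison_label(group_x, group_y)
    lab_rev = comparison_label(group_y, group_x)
    if (de["comparison"] == lab_fwd).any():
        sub, sign = de[de["comparison"] == lab_fwd], 1.0
    elif (de["comparison"] == lab_rev).any():
        sub, sign = de[de["comparison"] == lab_rev], -1.0
    else:
        raise ValueError(f"comparison {lab_fwd} not in DE table")
    return int(((sub["qvalue"] <= alpha)
                & (sign * sub["log2fc"] > np.log2(fold))).sum())


def pca_scores(tpm: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-level PCA on gene-standardized TPM.

    Each gene row is centered and scaled to unit variance (equal weight per
    gene); zero-variance genes are dropped. Returns per-sample component
    scores and the explained-variance fractions (non-increasing, sum <= 1).
    """
    if tpm.shape[1] < 2:
        raise ValueError("PCA needs >= 2 samples")
    x = tpm.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    keep = sd > 0
    z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    n_comp = min(tpm.shape[1] - 1, int(keep.sum()))
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(z.T)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (pd.DataFrame(scores, index=tpm.columns, columns=cols),
            pca.explained_variance_ratio_)


def hclust_order(matrix: pd.DataFrame, k: int) -> tuple[list, pd.Series]:
    """Complete-linkage Euclidean clustering of rows, as used for heatmaps.

    Returns the dendrogram leaf order (row labels) and cluster labels 1..k,
    with clusters renumbered by first appearance in input order.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 rows to cluster")
    if k > matrix.shape[0]:
        raise ValueError("k exceeds the number of rows")
    z = hierarchy.linkage(matrix.to_numpy(dtype=float), method="complete",
                          metric="euclidean")
    order = [matrix.index[i] for i in hierarchy.leaves_list(z)]
    raw = hierarchy.fcluster(z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    for lab in raw:
        relabel.setdefault(int(lab), len(relabel) + 1)
    labels = pd.Series([relabel[int(v)] for v in raw], index=matrix.index,
                       name="cluster")
    return order, labels
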