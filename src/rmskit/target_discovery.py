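"""Fusion-unique developmental target discovery screen.

Reproduces, on expression matrices, the screen design that surfaces
targets uniquely induced by a fusion transcription factor relative to
its wild-type counterpart: quantile normalization, per-gene Welch
two-sample t-tests of each injected condition against the control,
intersection of the up-regulated signatures, restriction of the
fusion-unique set to genes with a human ortholog, and ranking by linear
fold change.  A PCA embedding of the samples accompanies the screen.

The screen operates on log2-scale intensity matrices (genes x samples)
with three conditions -- a fluorophore-only control, the wild-type
factor and the fusion (GFP / PAX3 / PAX3-FOXO1 in the motivating
design), each in technical triplicate.  Technical replicates are
treated as independent samples by the test, mirroring that design; this
is anti-conservative with respect to biological variation.

Significance defaults to an unadjusted two-sided p < 0.05 with a
positive log2 fold change; a Benjamini-Hochberg option is available but
off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionStudy",
    "WelchResult",
    "SignatureSets",
    "DiscoveryResult",
    "read_expression_study",
    "quantile_normalize",
    "welch_t_test",
    "differential_expression",
    "call_upregulated",
    "intersect_signatures",
    "filter_orthologs",
    "rank_candidates",
    "pca_embed",
    "discover",
]


@dataclass
class ExpressionStudy:
    """A genes x samples log2 expression matrix with sample annotations.

    values
        DataFrame of log2 intensities, index = gene ids, columns =
        sample ids.
    sample_conditions
        Series mapping sample id -> condition label.
    replicate_index
        Series mapping sample id -> replicate number within condition.
    """

    values: pd.DataFrame
    sample_conditions: pd.Series
    replicate_index: pd.Series

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        missing = set(self.values.columns) - set(self.sample_conditions.index)
        if missing:
            raise ValueError(f"samples without condition labels: {sorted(missing)}")
        counts = self.sample_conditions.loc[list(self.values.columns)].value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"conditions with fewer than 2 samples: {small}")

    def condition_columns(self, condition: str) -> list[str]:
        cols = [
            s
            for s in self.values.columns
            if self.sample_conditions.loc[s] == condition
        ]
        if not cols:
            raise ValueError(f"condition {condition!r} absent from study")
        return cols


def read_expression_study(
    matrix_tsv: str | Path, samples_tsv: str | Path
) -> ExpressionStudy:
    """Load a study from a TSV matrix and a sample sheet.

    The matrix has gene ids in the first column and sample ids as the
    header; the sample sheet has columns sample_id, condition,
    replicate_index.
    """
    values = pd.read_csv(matrix_tsv, sep="\t", index_col=0)
    sheet = pd.read_csv(samples_tsv, sep="\t").set_index("sample_id")
    return ExpressionStudy(
        values=values,
        sample_conditions=sheet["condition"],
        replicate_index=sheet["replicate_index"],
    )


def quantile_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Force every sample column onto the cross-sample rank-mean distribution.

    Each column's sorted values are replaced by the mean of the sorted
    columns; ties within a column receive the average of the rank means
    they span.  Gene and sample labels are preserved.
    """
    x = study.values.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("quantile normalization requires >= 2 samples")
    rank_means = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = sps.rankdata(x[:, j], method="average") - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (rank_means[lo] + rank_means[hi])
    values = pd.DataFrame(out, index=study.values.index, columns=study.values.columns)
    return ExpressionStudy(
        values=values,
        sample_conditions=study.sample_conditions,
        replicate_index=study.replicate_index,
    )


@dataclass(frozen=True)
class WelchResult:
    t_stat: float
    welch_df: float
    p_value: float
    degenerate: bool = False


def welch_t_test(group_a: Iterable[float], group_b: Iterable[float]) -> WelchResult:
    """Welch unequal-variance two-sample t-test (two-sided).

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b) with
    Welch-Satterthwaite degrees of freedom.  When both groups have zero
    variance the statistic is undefined: equal means yield t=0, p=1 and
    the ``degenerate`` flag; unequal means yield p=0 with the flag.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return WelchResult(0.0, df, 1.0, degenerate=True)
        t = np.inf if a.mean() > b.mean() else -np.inf
        return WelchResult(float(t), df, 0.0, degenerate=True)
    res = sps.ttest_ind(a, b, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def differential_expression(
    study: ExpressionStudy, treated: str, control: str
) -> pd.DataFrame:
    """Per-gene Welch test of ``treated`` vs ``control`` samples.

    Returns a DataFrame indexed by gene id with columns log2fc
    (mean(treated) - mean(control)), t_stat, welch_df, p_value and
    degenerate.  Genes whose variance is zero in both groups are flagged
    degenerate (p=1 when means are equal, mirroring a constant gene).
    """
    ta = study.values[study.condition_columns(treated)].to_numpy(dtype=float)
    co = study.values[study.condition_columns(control)].to_numpy(dtype=float)
    log2fc = ta.mean(axis=1) - co.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant genes trigger a harmless precision warning inside scipy
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(ta, co, axis=1, equal_var=False)
        t = np.array(res.statistic, dtype=float)
        p = np.array(res.pvalue, dtype=float)
        df = np.array(res.df, dtype=float)
    both_flat = (ta.var(axis=1, ddof=1) == 0) & (co.var(axis=1, ddof=1) == 0)
    fallback_df = float(ta.shape[1] + co.shape[1] - 2)
    equal = both_flat & (log2fc == 0)
    unequal = both_flat & (log2fc != 0)
    t[equal], p[equal], df[equal] = 0.0, 1.0, fallback_df
    t[unequal] = np.where(log2fc[unequal] > 0, np.inf, -np.inf)
    p[unequal], df[unequal] = 0.0, fallback_df
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t_stat": t,
            "welch_df": df,
            "p_value": p,
            "degenerate": both_flat,
        },
        index=study.values.index.rename("gene_id"),
    )


def call_upregulated(
    stats: pd.DataFrame,
    alpha: float = 0.05,
    min_log2fc: float = 0.0,
    bh: bool = False,
) -> set[str]:
    """Genes significantly up-regulated: p < alpha and log2fc > min_log2fc.

    With ``bh=True`` the p-values are Benjamini-Hochberg adjusted before
    thresholding (off by default).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if stats.empty:
        return set()
    p = stats["p_value"].to_numpy(dtype=float)
    if bh:
        p = multipletests(p, method="fdr_bh")[1]
    keep = (p < alpha) & (stats["log2fc"].to_numpy() > min_log2fc)
    return set(stats.index[keep])


@dataclass
class SignatureSets:
    """Up-regulated signatures for two conditions and their overlap."""

    up_factor_a: set[str]
    up_factor_b: set[str]
    shared: set[str]
    unique_b: set[str]


def intersect_signatures(up_a: set[str], up_b: set[str]) -> SignatureSets:
    """Shared and condition-b-unique up-regulated gene sets."""
    up_a, up_b = set(up_a), set(up_b)
    return SignatureSets(
        up_factor_a=up_a,
        up_factor_b=up_b,
        shared=up_a & up_b,
        unique_b=up_b - up_a,
    )


def filter_orthologs(
    genes: Iterable[str], ortholog_map: pd.DataFrame
) -> dict[str, str]:
    """Restrict a gene set to genes with a human ortholog.

    ``ortholog_map`` has columns organism_gene and human_gene with unique
    organism-gene keys; one-to-many mappings are rejected rather than
    resolved.  Returns {organism gene -> human symbol} for retained genes.
    """
    if ortholog_map.duplicated("organism_gene").any():
        dups = ortholog_map.loc[
            ortholog_map.duplicated("organism_gene"), "organism_gene"
        ].tolist()
        raise ValueError(f"duplicate organism-gene keys in ortholog map: {dups[:5]}")
    lookup = dict(
        zip(ortholog_map["organism_gene"], ortholog_map["human_gene"])
    )
    return {g: lookup[g] for g in genes if g in lookup}


def rank_candidates(
    genes: Iterable[str],
    stats: pd.DataFrame,
    orthologs: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Rank candidate genes by descending linear fold change.

    Fold change is 2**log2fc (linear scale, as "21-fold" is reported in
    the field).  Ties are broken by ascending p-value, then lexicographic
    gene id, so the ranking is fully deterministic.  Every gene must have
    a statistics row; a missing row is an error.
    """
    genes = sorted(genes)
    missing = [g for g in genes if g not in stats.index]
    if missing:
        raise ValueError(f"genes without statistics: {missing[:5]}")
    sub = stats.loc[genes]
    out = pd.DataFrame(
        {
            "gene_id": genes,
            "fold_change": np.exp2(sub["log2fc"].to_numpy(dtype=float)),
            "p_value": sub["p_value"].to_numpy(dtype=float),
            "human_ortholog": [
                orthologs.get(g, "") if orthologs else "" for g in genes
            ],
        }
    )
    out = out.sort_values(
        ["fold_change", "p_value", "gene_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return out


def pca_embed(
    study: ExpressionStudy, n_components: int = 3
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA embedding of the samples on the gene-centered matrix.

    Returns (scores, variance_fractions): scores is samples x components
    (columns PC1..PCk), variance_fractions the fraction of total
    variance each component explains (non-increasing, summing to <= 1).
    """
    x = study.values.to_numpy(dtype=float).T  # samples x genes
    max_comp = min(x.shape[1], x.shape[0] - 1)
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds min(genes, samples-1)={max_comp}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=study.values.columns, columns=cols),
        pca.explained_variance_ratio_,
    )


@dataclass
class DiscoveryResult:
    """Output of the end-to-end discovery screen."""

    candidates: pd.DataFrame
    signatures: SignatureSets
    pca_scores: pd.DataFrame
    pca_variance: np.ndarray
    de_a: pd.DataFrame
    de_b: pd.DataFrame
    normalized: ExpressionStudy = field(repr=False, default=None)


def discover(
    study: ExpressionStudy,
    ortholog_map: pd.DataFrame,
    alpha: float = 0.05,
    min_log2fc: float = 0.0,
    control: str = "gfp",
    factor_a: str = "pax3",
    factor_b: str = "pax3_foxo1",
    bh: bool = False,
    normalize: bool = True,
    n_components: int = 3,
) -> DiscoveryResult:
    """Run the full screen: normalize, test, intersect, filter, rank.

    The candidate list contains the ``factor_b``-unique up-regulated
    genes that have a human ortholog, ordered by descending linear fold
    change versus the control.
    """
    norm = quantile_normalize(study) if normalize else study
    de_a = differential_expression(norm, factor_a, control)
    de_b = differential_expression(norm, factor_b, control)
    up_a = call_upregulated(de_a, alpha=alpha, min_log2fc=min_log2fc, bh=bh)
    up_b = call_upregulated(de_b, alpha=alpha, min_log2fc=min_log2fc, bh=bh)
    signatures = intersect_signatures(up_a, up_b)
    orthologs = filter_orthologs(signatures.unique_b, ortholog_map)
    candidates = rank_candidates(orthologs.keys(), de_b, orthologs)
    scores, variance = pca_embed(norm, n_components=n_components)
    return DiscoveryResult(
        candidates=candidates,
        signatures=signatures,
        pca_scores=scores,
        pca_variance=variance,
        de_a=de_a,
        de_b=de_b,
        normalized=norm,
    )
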