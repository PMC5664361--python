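"""Profile similarity vs gene co-expression and protein-protein interaction."""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress, pearsonr, rankdata, ranksums

from .core_io import PPITable, ValidationError
from .profiles import ProfileSet
from .similarity import LogisticFit, fit_logistic, pairwise_similarity_matrix

__all__ = [
    "CoexpressionResult",
    "PPIComparison",
    "quantile_normalize",
    "preprocess_expression",
    "coexpression_vs_profile",
    "ppi_profile_comparison",
]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common rank-mean distribution.

    Each column's sorted values are replaced by the across-column mean of
    sorted values; ties receive the mean of their rank-slots. Idempotent.
    """
    values = matrix.to_numpy(dtype=float)
    sorted_cols = np.sort(values, axis=0)
    if (sorted_cols == sorted_cols[:, :1]).all():
        # columns already share one distribution: averaging identical values
        # can round; use the common column directly so the op is idempotent
        mean_sorted = sorted_cols[:, 0]
    else:
        mean_sorted = sorted_cols.mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")  # 1-based, ties averaged
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = (mean_sorted[lo] + mean_sorted[hi]) / 2.0
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def preprocess_expression(
    matrix: pd.DataFrame,
    sample_keep_prob: float = 0.10,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Natural-log transform, quantile-normalize, then keep each sample column
    independently with probability ``sample_keep_prob``.

    Raises on non-positive intensities (log undefined). At least one column
    is always retained.
    """
    values = matrix.to_numpy(dtype=float)
    if np.any(values <= 0):
        raise ValidationError("expression matrix has non-positive values; cannot log")
    logged = pd.DataFrame(np.log(values), index=matrix.index, columns=matrix.columns)
    normed = quantile_normalize(logged)
    if sample_keep_prob >= 1.0:
        return normed
    rng = np.random.default_rng(seed)
    keep = rng.random(normed.shape[1]) < sample_keep_prob
    if not keep.any():
        keep[rng.integers(0, len(keep))] = True
    return normed.loc[:, keep]


@dataclass
class CoexpressionResult:
    records: pd.DataFrame  # gene1, gene2, d_pp, r_ge
    pearson_r: float
    pearson_p: float
    linear_slope: float
    linear_intercept: float
    logistic_fit: LogisticFit
    binned_medians: pd.DataFrame  # bin_low, bin_high, median_r_ge, n_pairs
    n_selected: int
    n_dropped: int


def coexpression_vs_profile(
    expression: pd.DataFrame,
    gene_to_object: Mapping[str, str],
    profiles: ProfileSet,
    n_genes: int = 500,
    seed: int | None = 0,
    bin_width: float = 0.1,
) -> CoexpressionResult:
    """Relate profile similarity to expression correlation over random genes.

    ``n_genes`` genes are drawn (without replacement) among genes having both
    an expression row and a profiled object; all unordered pairs are formed;
    each pair carries d_PP of the containing objects and the Pearson
    correlation r_GE of the two expression rows. Genes lacking either source
    are dropped and counted.
    """
    object_index = {o: i for i, o in enumerate(profiles.object_ids)}
    eligible = sorted(
        g
        for g in expression.index
        if g in gene_to_object and gene_to_object[g] in object_index
    )
    n_dropped = len(expression.index) - len(eligible)
    if len(eligible) < 2:
        raise ValidationError("fewer than 2 genes with both expression and profile")
    rng = np.random.default_rng(seed)
    if n_genes < len(eligible):
        selected = sorted(rng.choice(eligible, size=n_genes, replace=False))
    else:
        selected = eligible

    expr = expression.loc[selected].to_numpy(dtype=float)
    # centered rows -> all pairwise Pearson correlations in one product
    centered = expr - expr.mean(axis=1, keepdims=True)
    denom = np.sqrt(np.sum(centered**2, axis=1))
    denom[denom == 0] = np.nan
    corr = (centered @ centered.T) / np.outer(denom, denom)

    rows = np.array([object_index[gene_to_object[g]] for g in selected])
    sim = pairwise_similarity_matrix(profiles.matrix[rows])

    i_idx, j_idx = np.triu_indices(len(selected), k=1)
    records = pd.DataFrame(
        {
            "gene1": [selected[i] for i in i_idx],
            "gene2": [selected[j] for j in j_idx],
            "d_pp": sim[i_idx, j_idx],
            "r_ge": corr[i_idx, j_idx],
        }
    ).dropna(subset=["r_ge"])

    if len(records) >= 2 and records["d_pp"].nunique() > 1:
        r, p = pearsonr(records["d_pp"], records["r_ge"])
        lin = linregress(records["d_pp"], records["r_ge"])
        slope, intercept = float(lin.slope), float(lin.intercept)
    else:
        r = p = slope = intercept = float("nan")
    logit = fit_logistic(records["d_pp"], records["r_ge"])

    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    bins = np.clip(np.digitize(records["d_pp"], edges, right=False) - 1, 0, len(edges) - 2)
    med_rows = []
    for b in range(len(edges) - 1):
        mask = bins == b
        if mask.any():
            med_rows.append(
                {
                    "bin_low": edges[b],
                    "bin_high": edges[b + 1],
                    "median_r_ge": float(records["r_ge"][mask].median()),
                    "n_pairs": int(mask.sum()),
                }
            )
    return CoexpressionResult(
        records=records,
        pearson_r=float(r),
        pearson_p=float(p),
        linear_slope=slope,
        linear_intercept=intercept,
        logistic_fit=logit,
        binned_medians=pd.DataFrame(med_rows),
        n_selected=len(selected),
        n_dropped=n_dropped,
    )


@dataclass
class PPIComparison:
    median_interacting: float
    median_non_interacting: float
    wilcoxon_p: float
    n_interacting: int
    n_non_interacting: int
    background_subsampled: bool
    d_pp_interacting: np.ndarray
    d_pp_non_interacting: np.ndarray


def ppi_profile_comparison(
    ppi: PPITable,
    gene_to_object: Mapping[str, str],
    profiles: ProfileSet,
    experimental_only: bool = True,
    drop_same_object: bool = False,
    max_background_pairs: int = 1_000_000,
    seed: int | None = 0,
) -> PPIComparison:
    """Compare d_PP of interacting vs non-interacting mapped gene pairs.

    The non-interacting background is every unordered pair of mapped genes
    not reported interacting, enumerated exhaustively up to
    ``max_background_pairs`` and uniformly subsampled beyond that. Two genes
    in the same object score d_PP = 1 and are retained unless
    ``drop_same_object``. Significance: two-sided Wilcoxon rank-sum.
    """
    object_index = {o: i for i, o in enumerate(profiles.object_ids)}
    sim = pairwise_similarity_matrix(profiles.matrix)

    def pair_dpp(g1: str, g2: str) -> float | None:
        o1, o2 = gene_to_object.get(g1), gene_to_object.get(g2)
        if o1 is None or o2 is None or o1 not in object_index or o2 not in object_index:
            return None
        if o1 == o2:
            return None if drop_same_object else 1.0
        return float(sim[object_index[o1], object_index[o2]])

    pairs = ppi.experimental_pairs() if experimental_only else list(ppi.pairs)
    interacting_set: set[tuple[str, str]] = set()
    d_int: list[float] = []
    for g1, g2 in sorted(pairs):
        d = pair_dpp(g1, g2)
        if d is not None:
            interacting_set.add((g1, g2) if g1 < g2 else (g2, g1))
            d_int.append(d)
    if not d_int:
        raise ValidationError("no interacting pair maps to profiled objects")

    mapped_genes = sorted(
        g for g, o in gene_to_object.items() if o in object_index
    )
    n = len(mapped_genes)
    total_pairs = n * (n - 1) // 2
    subsampled = total_pairs > max_background_pairs
    rng = np.random.default_rng(seed)
    d_non: list[float] = []
    if not subsampled:
        for g1, g2 in itertools.combinations(mapped_genes, 2):
            key = (g1, g2)
            if key in interacting_set:
                continue
            d = pair_dpp(g1, g2)
            if d is not None:
                d_non.append(d)
    else:
        target = max_background_pairs
        while len(d_non) < target:
            i = int(rng.integers(0, n))
            j = int(rng.integers(0, n - 1))
            if j >= i:
                j += 1
            g1, g2 = sorted((mapped_genes[i], mapped_genes[j]))
            if (g1, g2) in interacting_set:
                continue
            d = pair_dpp(g1, g2)
            if d is not None:
                d_non.append(d)

    arr_int = np.array(d_int)
    arr_non = np.array(d_non)
    p = float(ranksums(arr_int, arr_non).pvalue)
    return PPIComparison(
        median_interacting=float(np.median(arr_int)),
        median_non_interacting=float(np.median(arr_non)),
        wilcoxon_p=p,
        n_interacting=len(arr_int),
        n_non_interacting=len(arr_non),
        background_subsampled=subsampled,
        d_pp_interacting=arr_int,
        d_pp_non_interacting=arr_non,
    )
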