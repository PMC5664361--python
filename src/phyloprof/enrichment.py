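"""Identical-profile enrichment within pathways.

The core statistic: the fraction F_pw of identical profile pairs among a
pathway's gene objects, the analogous fraction F_all that additionally
compares each pathway object against every object outside the pathway, their
ratio E = F_pw / F_all, empirical p-values from uniform redraws of gene
objects, and Benjamini-Hochberg multiple-testing correction.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core_io import ValidationError
from .profiles import ProfileSet

__all__ = [
    "EnrichmentResult",
    "fraction_identical_within",
    "fraction_identical_overall",
    "enrichment_score",
    "permutation_pvalue",
    "bh_adjust",
    "enrichment_scan",
]


@dataclass
class EnrichmentResult:
    pathway_id: str
    n_f: int
    f_pw: float | None
    f_all: float | None
    enrichment: float | None
    p_empirical: float | None
    p_adjusted: float | None
    n_draws: int
    testable: bool
    mean_random_e: float | None = None


def _profile_codes(profiles: np.ndarray) -> np.ndarray:
    """Map profile rows to integer codes; equal rows share a code."""
    _, codes = np.unique(profiles, axis=0, return_inverse=True)
    return codes.astype(np.int64)


def _identical_pairs(counts: np.ndarray) -> float:
    return float(np.sum(counts * (counts - 1) // 2))


def fraction_identical_within(pathway_profiles: np.ndarray) -> float | None:
    """Fraction of unordered profile pairs within the pathway that are identical.

    Returns None (undefined) when fewer than 2 profiles are given; callers
    must exclude such pathways from testing rather than treat this as 0.
    """
    n = len(pathway_profiles)
    if n < 2:
        return None
    codes = _profile_codes(np.asarray(pathway_profiles))
    counts = np.bincount(codes)
    return _identical_pairs(counts) / (n * (n - 1) / 2)


def fraction_identical_overall(
    pathway_profiles: np.ndarray, outside_profiles: np.ndarray
) -> float | None:
    """Fraction of identical pairs over within-pathway pairs plus every
    (pathway, outside) cross pair; outside-outside pairs are never compared.

    Undefined (None) when there are no comparable pairs at all.
    """
    inside = np.asarray(pathway_profiles)
    outside = np.asarray(outside_profiles)
    n_f, n_out = len(inside), len(outside)
    denom = n_f * (n_f - 1) / 2 + n_f * n_out
    if denom == 0:
        return None
    if n_out == 0:
        return fraction_identical_within(inside)
    codes = _profile_codes(np.vstack([inside, outside]))
    in_counts = np.bincount(codes[:n_f], minlength=codes.max() + 1)
    out_counts = np.bincount(codes[n_f:], minlength=codes.max() + 1)
    within = _identical_pairs(in_counts)
    cross = float(np.sum(in_counts * out_counts))
    return (within + cross) / denom


def enrichment_score(f_pw: float | None, f_all: float | None) -> float | None:
    """E = F_pw / F_all; None when either input is undefined or F_all = 0."""
    if f_pw is None or f_all is None or f_all == 0.0:
        return None
    return f_pw / f_all


def _null_enrichments(
    codes: np.ndarray,
    n_f: int,
    n_draws: int,
    rng: np.random.Generator,
    chunk: int = 512,
) -> np.ndarray:
    """E_r for ``n_draws`` uniform without-replacement draws of n_f objects
    from the full pool; undefined draws yield NaN."""
    n_total = len(codes)
    k = codes.max() + 1
    total_counts = np.bincount(codes, minlength=k).astype(np.int64)
    denom_within = n_f * (n_f - 1) / 2
    denom_all = denom_within + n_f * (n_total - n_f)
    out = np.empty(n_draws, dtype=float)
    pos = 0
    while pos < n_draws:
        m = min(chunk, n_draws - pos)
        # vectorised sampling without replacement: rank random keys per row
        keys = rng.random((m, n_total))
        picks = np.argpartition(keys, n_f - 1, axis=1)[:, :n_f]
        picked_codes = codes[picks]
        flat = (np.arange(m)[:, None] * k + picked_codes).ravel()
        in_counts = np.bincount(flat, minlength=m * k).reshape(m, k)
        within = np.sum(in_counts * (in_counts - 1) // 2, axis=1).astype(float)
        cross = np.sum(in_counts * (total_counts[None, :] - in_counts), axis=1).astype(float)
        f_pw = within / denom_within if denom_within > 0 else np.full(m, np.nan)
        f_all = (within + cross) / denom_all if denom_all > 0 else np.full(m, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            e_r = np.where(f_all > 0, f_pw / f_all, np.nan)
        out[pos : pos + m] = e_r
        pos += m
    return out


def permutation_pvalue(
    observed_e: float | None,
    all_object_profiles: np.ndarray,
    n_f: int,
    n_draws: int = 10_000,
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[float | None, float | None]:
    """Empirical p-value of the enrichment score under uniform object redraws.

    Each draw samples ``n_f`` objects without replacement from the full pool
    and recomputes E_r against the complementary outside set;
    p = (#draws with E_r >= observed_e) / n_draws. Draws with undefined E_r
    (F_all = 0) count as non-exceeding. Returns (p, mean defined E_r);
    p is None when ``observed_e`` is undefined.
    """
    pool = np.asarray(all_object_profiles)
    if n_f > len(pool):
        raise ValidationError(f"n_f={n_f} exceeds pool size {len(pool)}")
    if n_f < 2 or n_draws < 1:
        return None, None
    rng = np.random.default_rng(seed)
    e_r = _null_enrichments(_profile_codes(pool), n_f, n_draws, rng)
    mean_e_r = float(np.nanmean(e_r)) if np.any(np.isfinite(e_r)) else None
    if observed_e is None:
        return None, mean_e_r
    exceed = np.sum(e_r[np.isfinite(e_r)] >= observed_e)
    return float(exceed / n_draws), mean_e_r


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pathway_seed(root_seed: int, pathway_id: str) -> np.random.SeedSequence:
    """Stable per-pathway child seed independent of scan order."""
    digest = hashlib.sha256(pathway_id.encode("utf-8")).digest()
    return np.random.SeedSequence([root_seed, int.from_bytes(digest[:8], "big")])


def enrichment_scan(
    memberships: Mapping[str, set[str] | Sequence[str]],
    profiles: ProfileSet,
    n_draws: int = 10_000,
    seed: int = 0,
    include_untestable_in_bh: bool = False,
) -> pd.DataFrame:
    """Run the full enrichment test over every pathway at one level.

    ``memberships`` maps pathway id -> member object ids; ``profiles`` is the
    full object universe the permutation null draws from. Pathways with
    n_f < 2 (or with undefined E) appear in the output flagged untestable and
    are excluded from the BH family unless ``include_untestable_in_bh``.
    Rows are sorted by adjusted p then enrichment descending.
    """
    index = {o: i for i, o in enumerate(profiles.object_ids)}
    results: list[EnrichmentResult] = []
    for pathway_id in sorted(memberships):
        member_ids = sorted(set(memberships[pathway_id]))
        unknown = [o for o in member_ids if o not in index]
        if unknown:
            raise ValidationError(
                f"pathway {pathway_id!r} references unknown objects {unknown[:5]}"
            )
        rows = np.array([index[o] for o in member_ids], dtype=int)
        mask = np.zeros(len(profiles.object_ids), dtype=bool)
        mask[rows] = True
        inside = profiles.matrix[mask]
        outside = profiles.matrix[~mask]
        f_pw = fraction_identical_within(inside)
        f_all = fraction_identical_overall(inside, outside)
        e = enrichment_score(f_pw, f_all)
        p, mean_e_r = permutation_pvalue(
            e,
            profiles.matrix,
            n_f=len(rows),
            n_draws=n_draws,
            seed=_pathway_seed(seed, pathway_id),
        )
        results.append(
            EnrichmentResult(
                pathway_id=pathway_id,
                n_f=len(rows),
                f_pw=f_pw,
                f_all=f_all,
                enrichment=e,
                p_empirical=p,
                p_adjusted=None,
                n_draws=n_draws,
                testable=p is not None,
                mean_random_e=mean_e_r,
            )
        )

    in_family = [
        r for r in results if r.testable or (include_untestable_in_bh and r.p_empirical is not None)
    ]
    if in_family:
        adjusted = bh_adjust([r.p_empirical for r in in_family])
        for r, padj in zip(in_family, adjusted):
            r.p_adjusted = float(padj)

    df = pd.DataFrame(
        {
            "pathway": [r.pathway_id for r in results],
            "n_f": [r.n_f for r in results],
            "f_pw": [_nan(r.f_pw) for r in results],
            "f_all": [_nan(r.f_all) for r in results],
            "enrichment": [_nan(r.enrichment) for r in results],
            "p_empirical": [_nan(r.p_empirical) for r in results],
            "p_adjusted": [_nan(r.p_adjusted) for r in results],
            "p_display": [_display_p(r) for r in results],
            "mean_random_e": [_nan(r.mean_random_e) for r in results],
            "n_draws": [r.n_draws for r in results],
            "testable": [r.testable for r in results],
        }
    )
    df = df.sort_values(
        ["p_adjusted", "enrichment"],
        ascending=[True, False],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    return df


def _nan(x: float | None) -> float:
    return math.nan if x is None else x


def _display_p(r: EnrichmentResult) -> str:
    """Human-readable p with a reporting floor of 1/n_draws for zero counts."""
    if r.p_empirical is None:
        return "NA"
    if r.p_empirical == 0.0:
        return f"<{1.0 / r.n_draws:g}"
    return f"{r.p_empirical:g}"
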