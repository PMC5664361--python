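"""Pairwise profile similarity d_PP, pathway-agreement A_PW, random object-pair
sampling and the logistic relationship fit."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core_io import ValidationError
from .profiles import ProfileSet

__all__ = [
    "LogisticFit",
    "profile_similarity",
    "pairwise_similarity_matrix",
    "pathway_agreement",
    "sample_pairs",
    "fit_logistic",
    "logistic",
]


@dataclass
class LogisticFit:
    """Fit of response = 1 / (1 + exp(-a * (x - b)))."""

    a: float | None
    b: float | None
    converged: bool
    rss: float | None
    n: int
    message: str = ""


def profile_similarity(pp1: np.ndarray, pp2: np.ndarray) -> float:
    """Jaccard similarity of two presence bit vectors: |AND| / |OR|."""
    p1 = np.asarray(pp1, dtype=bool)
    p2 = np.asarray(pp2, dtype=bool)
    if p1.shape != p2.shape:
        raise ValidationError(f"profile length mismatch: {p1.shape} vs {p2.shape}")
    union = np.sum(p1 | p2)
    if union == 0:
        raise ValidationError("both profiles are all-zero")
    return float(np.sum(p1 & p2) / union)


def pairwise_similarity_matrix(matrix: np.ndarray) -> np.ndarray:
    """Dense Jaccard similarity for all row pairs of a 0/1 matrix."""
    m = np.asarray(matrix, dtype=np.int64)
    inter = m @ m.T
    sizes = m.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / union, np.nan)
    return sim


def pathway_agreement(
    pw1: set[str] | frozenset[str],
    pw2: set[str] | frozenset[str],
    mode: str = "overlap",
) -> float | None:
    """Agreement of two pathway-id sets.

    ``"overlap"`` (default) divides the intersection by the smaller set size;
    ``"jaccard"`` divides by the union size. Returns None when either set is
    empty (such pairs are excluded from downstream fits).
    """
    if not pw1 or not pw2:
        return None
    inter = len(set(pw1) & set(pw2))
    if mode == "overlap":
        return inter / min(len(pw1), len(pw2))
    if mode == "jaccard":
        return inter / len(set(pw1) | set(pw2))
    raise ValueError("mode must be 'overlap' or 'jaccard'")


def sample_pairs(
    profiles: ProfileSet,
    pathway_sets: Mapping[str, set[str] | frozenset[str]],
    n_pairs: int = 100_000,
    seed: int | None = 0,
    agreement_mode: str = "overlap",
) -> pd.DataFrame:
    """Draw unordered distinct object pairs uniformly (with replacement across
    draws) among annotated objects; each record carries d_PP and A_PW.

    Objects with an empty pathway set are excluded before sampling.
    """
    eligible = [
        o for o in profiles.object_ids if pathway_sets.get(o)
    ]
    if len(eligible) < 2:
        raise ValidationError("need >= 2 objects with pathway annotation")
    sub = profiles.subset(eligible)
    rng = np.random.default_rng(seed)
    n = len(sub.object_ids)
    first = rng.integers(0, n, size=n_pairs)
    # second index drawn uniformly from the remaining n-1 objects
    second = rng.integers(0, n - 1, size=n_pairs)
    second = np.where(second >= first, second + 1, second)
    sim = pairwise_similarity_matrix(sub.matrix)
    d_pp = sim[first, second]
    records = {
        "g1": [sub.object_ids[i] for i in first],
        "g2": [sub.object_ids[j] for j in second],
        "d_pp": d_pp,
        "a_pw": [
            pathway_agreement(
                pathway_sets[sub.object_ids[i]],
                pathway_sets[sub.object_ids[j]],
                mode=agreement_mode,
            )
            for i, j in zip(first, second)
        ],
        "n1": [len(pathway_sets[sub.object_ids[i]]) for i in first],
        "n2": [len(pathway_sets[sub.object_ids[j]]) for j in second],
    }
    return pd.DataFrame(records)


def logistic(x: np.ndarray, a: float, b: float) -> np.ndarray:
    z = np.clip(-a * (np.asarray(x, dtype=float) - b), -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(z))


_INIT_A = (1.0, -1.0, 5.0, -5.0, 20.0, -20.0)
_INIT_B = (0.25, 0.5, 0.75)


def fit_logistic(
    x: Sequence[float], y: Sequence[float], min_records: int = 10
) -> LogisticFit:
    """Least-squares fit of y = 1/(1+exp(-a*(x-b))) with a multi-start grid.

    Records with undefined (NaN) response are dropped. Degenerate inputs
    (constant x, constant y, too few records) yield ``converged=False`` with
    parameters withheld.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < min_records:
        return LogisticFit(None, None, False, None, n, "too few records")
    if np.ptp(x) == 0:
        return LogisticFit(None, None, False, None, n, "constant predictor")
    if np.ptp(y) == 0:
        return LogisticFit(None, None, False, None, n, "constant response (b unidentifiable)")

    best: LogisticFit | None = None
    for a0 in _INIT_A:
        for b0 in _INIT_B:
            res = least_squares(
                lambda p: logistic(x, p[0], p[1]) - y,
                x0=np.array([a0, b0]),
                method="lm",
                max_nfev=2000,
            )
            if not res.success:
                continue
            rss = float(2.0 * res.cost)
            if best is None or rss < best.rss:  # type: ignore[operator]
                best = LogisticFit(
                    a=float(res.x[0]),
                    b=float(res.x[1]),
                    converged=True,
                    rss=rss,
                    n=n,
                    message="ok",
                )
    if best is None:
        return LogisticFit(None, None, False, None, n, "optimizer failed from all starts")
    return best
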