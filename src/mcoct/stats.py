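"""Statistical comparisons used in the study's analysis.

Group differences in lesion burden (e.g. HRF volumes of eyes with vs
without focal RPE damage) are tested with the two-sided Mann-Whitney U
test; ordinal agreement between two graders on the K-category band-damage
pattern scale is summarized with weighted kappa.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = [
    "SampleSplit",
    "mann_whitney_u",
    "weighted_kappa",
    "percentage",
    "group_summary",
]


@dataclass
class SampleSplit:
    """Two value collections to compare (with labels and units)."""

    x: np.ndarray
    y: np.ndarray
    labels: tuple[str, str] = ("group 1", "group 2")
    unit: str = ""


def mann_whitney_u(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    U is computed from rank sums with midranks for ties.  ``mode="exact"``
    enumerates the permutation null (valid only without ties);
    ``"approx"`` uses the normal approximation with tie-corrected variance
    and continuity correction; ``"auto"`` picks exact when both samples
    have at most 10 observations and there are no ties.

    Returns ``(U, p)`` with U the statistic of the first sample.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if mode == "auto":
        mode = "exact" if (max(x.size, y.size) <= 10 and not has_ties) else "approx"
    if mode == "exact" and has_ties:
        raise ValueError("exact mode requires tie-free data")
    if mode not in ("exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    method = "exact" if mode == "exact" else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def weighted_kappa(
    rater_a,
    rater_b,
    *,
    n_categories: int | None = None,
    weights="linear",
) -> float:
    """Weighted Cohen's kappa for two raters on an ordinal K-category scale.

    ``kappa = 1 - sum(w * o) / sum(w * e)`` with observed proportions ``o``,
    chance-expected proportions ``e`` from the marginals, and disagreement
    weights ``w`` (``"linear"``: |i-j|, ``"quadratic"``: (i-j)^2, or an
    explicit K×K matrix).  Raises on degenerate marginals (every item in a
    single category by both raters), where chance disagreement is zero and
    kappa undefined.
    """
    a = np.asarray(rater_a, dtype=np.int64)
    b = np.asarray(rater_b, dtype=np.int64)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("raters must grade the same non-empty item set")
    cats = np.unique(np.concatenate([a, b]))
    lo = cats.min()
    k = n_categories if n_categories is not None else int(cats.max() - lo + 1)
    ai, bi = a - lo, b - lo
    if np.any((ai < 0) | (ai >= k) | (bi < 0) | (bi >= k)):
        raise ValueError("grades outside the stated category range")
    o = np.zeros((k, k))
    np.add.at(o, (ai, bi), 1.0)
    o /= a.size
    e = np.outer(o.sum(axis=1), o.sum(axis=0))
    if isinstance(weights, str):
        i, j = np.indices((k, k))
        if weights == "linear":
            w = np.abs(i - j).astype(np.float64)
        elif weights == "quadratic":
            w = ((i - j) ** 2).astype(np.float64)
        else:
            raise ValueError(f"unknown weight scheme {weights!r}")
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (k, k):
            raise ValueError(f"weight matrix must be {k}x{k}")
    expected_disagreement = float(np.sum(w * e))
    if expected_disagreement == 0.0:
        raise ValueError(
            "kappa undefined: degenerate marginals (no chance disagreement)"
        )
    return float(1.0 - np.sum(w * o) / expected_disagreement)


def percentage(k: int, n: int) -> float:
    """Share of ``k`` out of ``n`` as a percentage."""
    if n <= 0:
        raise ValueError("n must be positive")
    return 100.0 * k / n


def group_summary(values, label: str = "", unit: str = "") -> dict:
    """Mean, SD, range and n of one group, for the analysis report."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty group")
    return {
        "label": label,
        "unit": unit,
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "min": float(v.min()),
        "max": float(v.max()),
    }


def exact_mw_pvalue_bound(n1: int, n2: int) -> float:
    """Smallest attainable two-sided exact p, ``2 / C(n1+n2, n1)`` (extreme ordering)."""
    return 2.0 / comb(n1 + n2, n1)
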