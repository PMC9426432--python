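"""Cross-condition significance screening for ensemble outputs.

The screen applied to each reaction/metabolite across temperature
conditions combines three gates, all of which must pass:

* Kruskal–Wallis test, p ≤ α (tie-corrected H, chi-square approximation
  with k−1 degrees of freedom);
* rank-based effect size ε² = H/(n_total − 1) at least ``eps_min``
  (default 0.36, a conventional "large effect" threshold — with large
  ensembles the p-value alone is always tiny, so the effect-size gate does
  the real work);
* every pairwise two-sided Wilcoxon rank-sum p ≤ α after Holm adjustment.

Items whose condition distributions are element-wise identical are
reported as ND (no difference) rather than not-significant.

Small-sample pairwise p-values are exact permutation probabilities
computed over all assignments of the pooled values (midranks, so ties are
handled); larger samples use the normal approximation with tie correction
and continuity correction, matching standard statistical practice.  The
two-sided exact p is P(|W − E[W]| ≥ |w_obs − E[W]|) under the permutation
null, which reduces to the usual doubled-tail probability when there are
no ties.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConditionComparison",
    "kruskal_wallis",
    "epsilon_squared",
    "pairwise_wilcoxon",
    "significance_screen",
    "rms_scale",
    "compare_conditions",
]

log = logging.getLogger(__name__)

ALPHA = 0.05
EPSILON2_MIN = 0.36
#: exact permutation enumeration is used when C(n1+n2, n1) is at most this
EXACT_LIMIT = 200_000


@dataclass
class ConditionComparison:
    """Screen result for one item (reaction or metabolite)."""

    item_id: str
    H: float
    p: float
    epsilon2: float
    pairwise_p: dict[tuple[str, str], float]
    verdict: str  # significant | not_significant | ND


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and chi-square p over ≥2 groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        # scipy raises on all-identical data; by continuity H = 0 there
        return 0.0, 1.0
    H, p = scipy.stats.kruskal(*arrays)
    return float(H), float(p)


def epsilon_squared(H: float, n_total: int) -> float:
    """Rank-based effect size for the Kruskal–Wallis statistic: H/(n−1)."""
    if n_total < 2:
        raise ValueError("n_total must be >= 2")
    return H / (n_total - 1)


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for the Wilcoxon rank-sum test.

    Enumerates all C(n1+n2, n1) assignments of the pooled midranks to the
    first group; p = P(|W − E[W]| >= |w_obs − E[W]|).
    """
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    n1 = len(x)
    n = len(pooled)
    w_obs = ranks[:n1].sum()
    mean_w = n1 * (n + 1) / 2.0
    dev_obs = abs(w_obs - mean_w)
    count = 0
    total = 0
    for idx in combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mean_w) >= dev_obs - 1e-12:
            count += 1
    return count / total


def _asymptotic_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Normal approximation with tie and continuity corrections."""
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


def _ranksum_p(x: np.ndarray, y: np.ndarray, method: str = "auto") -> float:
    if np.array_equal(np.sort(x), np.sort(y)):
        return 1.0
    if method == "exact":
        return _exact_ranksum_p(x, y)
    if method == "asymptotic":
        return _asymptotic_ranksum_p(x, y)
    if method != "auto":
        raise ValueError(f"unknown method {method!r}")
    if math.comb(len(x) + len(y), len(x)) <= EXACT_LIMIT:
        return _exact_ranksum_p(x, y)
    return _asymptotic_ranksum_p(x, y)


def pairwise_wilcoxon(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    correction: str = "holm",
    method: str = "auto",
) -> dict[tuple[str, str], float]:
    """Pairwise two-sided rank-sum tests with multiplicity adjustment.

    ``correction`` is ``holm`` (default), ``bonferroni`` or ``none``.
    Groups may be a mapping (labels preserved) or a sequence (labels are
    positional indices as strings).
    """
    if not isinstance(groups, Mapping):
        groups = {str(i): g for i, g in enumerate(groups)}
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    pairs = list(combinations(labels, 2))
    raw = [_ranksum_p(arrays[a], arrays[b], method=method) for a, b in pairs]
    if correction == "none":
        adjusted = raw
    elif correction in ("holm", "bonferroni"):
        adjusted = multipletests(raw, method=correction)[1]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return {pair: float(p) for pair, p in zip(pairs, adjusted)}


def _identical_distributions(arrays: Sequence[np.ndarray]) -> bool:
    first = np.sort(arrays[0])
    return all(
        a.size == first.size and np.array_equal(np.sort(a), first)
        for a in arrays[1:]
    )


def significance_screen(
    groups: Mapping[str, Sequence[float]],
    alpha: float = ALPHA,
    eps_min: float = EPSILON2_MIN,
    correction: str = "holm",
    item_id: str = "",
) -> ConditionComparison:
    """Full cross-condition screen for one item.

    Verdict is ``significant`` iff the Kruskal–Wallis p ≤ α AND ε² ≥
    eps_min AND every adjusted pairwise p ≤ α; ``ND`` when the condition
    distributions are element-wise identical.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if _identical_distributions(arrays):
        return ConditionComparison(
            item_id=item_id, H=0.0, p=1.0, epsilon2=0.0, pairwise_p={}, verdict="ND"
        )
    H, p = kruskal_wallis(arrays)
    n_total = sum(a.size for a in arrays)
    eps2 = epsilon_squared(H, n_total)
    pw = pairwise_wilcoxon(groups, correction=correction)
    significant = (
        p <= alpha and eps2 >= eps_min and all(v <= alpha for v in pw.values())
    )
    return ConditionComparison(
        item_id=item_id,
        H=H,
        p=p,
        epsilon2=eps2,
        pairwise_p=pw,
        verdict="significant" if significant else "not_significant",
    )


def rms_scale(values: Sequence[float]) -> tuple[np.ndarray, bool]:
    """Divide each value by the root mean square across conditions.

    Returns (scaled values, all_zero flag); an all-zero input cannot be
    scaled and comes back unchanged with the flag set.
    """
    v = np.asarray(values, dtype=float)
    rms = math.sqrt(float(np.mean(v**2)))
    if rms == 0.0:
        return np.zeros_like(v), True
    return v / rms, False


def compare_conditions(
    matrices: Mapping[str, pd.DataFrame],
    alpha: float = ALPHA,
    eps_min: float = EPSILON2_MIN,
    correction: str = "holm",
) -> pd.DataFrame:
    """Screen every shared column across per-condition ensemble matrices.

    Returns a tidy report: one row per item with H, p, ε², adjusted
    pairwise p-values and the verdict.
    """
    names = list(matrices)
    if len(names) < 2:
        raise ValueError("need at least two conditions")
    common = set.intersection(*(set(m.columns) for m in matrices.values()))
    rows = []
    for item in sorted(common):
        groups = {name: matrices[name][item].dropna().to_numpy() for name in names}
        if any(g.size == 0 for g in groups.values()):
            continue
        cmp = significance_screen(
            groups, alpha=alpha, eps_min=eps_min, correction=correction, item_id=item
        )
        row = {
            "item": item,
            "H": cmp.H,
            "p": cmp.p,
            "epsilon2": cmp.epsilon2,
            "verdict": cmp.verdict,
        }
        for (a, b), pv in cmp.pairwise_p.items():
            row[f"p_{a}_vs_{b}"] = pv
        rows.append(row)
    return pd.DataFrame(rows)
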