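"""Co-occurrence, abundance and rank-based distribution statistics.

Survey day is the base unit of co-occurrence: sharks and a water-user group
"co-occur" when both are observed at the same beach within the same survey
day.  Cross-shore distance distributions are compared with rank-based tests
(the distances are heavily skewed), with exact permutation p-values for tiny
samples and tie-corrected asymptotics otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CooccurrenceSummary",
    "cooccurrence_rate",
    "relative_abundance",
    "max_density",
    "RankTestResult",
    "rank_tests",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "dunn_posthoc",
    "compact_letter_display",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal rounding with ties away from zero, the convention used for
    reported percentages (so 96.666… -> 97, 78.38 -> 78.4)."""
    factor = 10.0 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass
class CooccurrenceSummary:
    """Days with both groups present over eligible days, plus mean abundance
    of each group on the days they co-occurred."""

    n_cooccurrence_days: int
    n_eligible_days: int
    mean_abundance_a: float
    mean_abundance_b: float
    group_a: str = "shark"
    group_b: str = ""

    @property
    def rate(self) -> float:
        return self.n_cooccurrence_days / self.n_eligible_days

    def percent(self, decimals: int = 0) -> float:
        return round_half_up(100.0 * self.rate, decimals)


def cooccurrence_rate(survey_day_table: pd.DataFrame, group_a: str, group_b: str,
                      beaches=None, eligible=None) -> CooccurrenceSummary:
    """Proportion of eligible survey days on which both groups were observed.

    ``beaches`` restricts to a beach subset; ``eligible`` is an optional
    boolean mask (aligned to the table) for explicit day-eligibility rules,
    since which days enter the denominator is an analysis choice.
    """
    t = survey_day_table
    if beaches is not None:
        t = t[t["beach"].isin(beaches)]
    if eligible is not None:
        mask = np.asarray(eligible, dtype=bool)
        if len(mask) != len(t):
            raise ValueError("eligibility mask length does not match the filtered table")
        t = t[mask]
    if len(t) == 0:
        raise ValueError("no eligible survey days after filtering")
    both = (t[group_a] > 0) & (t[group_b] > 0)
    co = t[both]
    return CooccurrenceSummary(
        n_cooccurrence_days=int(both.sum()),
        n_eligible_days=int(len(t)),
        mean_abundance_a=float(co[group_a].mean()) if len(co) else float("nan"),
        mean_abundance_b=float(co[group_b].mean()) if len(co) else float("nan"),
        group_a=group_a, group_b=group_b,
    )


def relative_abundance(survey_day_table: pd.DataFrame, groups,
                       beaches=None) -> pd.DataFrame:
    """Per-group mean count per survey and its share of all groups.

    Counts are summed across surveys, averaged by the number of surveys
    flown (empty-beach surveys stay in the denominator), then normalised to
    proportions.
    """
    t = survey_day_table
    if beaches is not None:
        t = t[t["beach"].isin(beaches)]
    n_surveys = int(t["n_surveys"].sum())
    if n_surveys == 0:
        raise ValueError("zero surveys flown")
    means = {g: float(t[g].sum()) / n_surveys for g in groups}
    total = sum(means.values())
    out = pd.DataFrame({
        "group": list(groups),
        "mean_per_survey": [means[g] for g in groups],
        "proportion": [means[g] / total if total > 0 else float("nan") for g in groups],
    })
    return out


def max_density(survey_day_table: pd.DataFrame, surveyed_area_ha: float,
                beach=None) -> float:
    """Maximum daily count of confirmed individual sharks per hectare surveyed."""
    if surveyed_area_ha <= 0:
        raise ValueError("surveyed area must be positive")
    t = survey_day_table
    if beach is not None:
        t = t[t["beach"] == beach]
    if len(t) == 0:
        return 0.0
    return float(t["shark_distinct"].max()) / surveyed_area_ha


# ---------------------------------------------------------------------------
# rank-based tests

@dataclass
class RankTestResult:
    """Result of one rank test (or one post-hoc pair)."""

    test: str
    groups: tuple
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    method: str = "asymptotic"


def _tie_term(all_values: np.ndarray) -> float:
    _, counts = np.unique(all_values, return_counts=True)
    return float(np.sum(counts**3 - counts))


def wilcoxon_rank_sum(a, b, method: str = "auto") -> RankTestResult:
    """Two-sided two-sample Wilcoxon rank-sum test.

    W is the rank sum of the first sample.  method 'exact' enumerates every
    assignment of the pooled values to the two samples (feasible for small
    n); 'asymptotic' uses the tie-corrected normal approximation with
    continuity correction; 'auto' picks exact when both samples have at
    most 10 values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    W = float(ranks[: len(a)].sum())
    n1, n2 = len(a), len(b)
    N = n1 + n2
    if method == "auto":
        method = "exact" if max(n1, n2) <= 10 else "asymptotic"
    if method == "exact":
        mu = n1 * (N + 1) / 2.0
        obs_dev = abs(W - mu)
        count = 0
        total = 0
        for idx in itertools.combinations(range(N), n1):
            w = ranks[list(idx)].sum()
            total += 1
            if abs(w - mu) >= obs_dev - 1e-9:
                count += 1
        p = count / total
    else:
        mu = n1 * (N + 1) / 2.0
        tie = _tie_term(pooled)
        var = n1 * n2 / 12.0 * ((N + 1) - tie / (N * (N - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = (abs(W - mu) - 0.5) / math.sqrt(var)
            p = 2 * sps.norm.sf(max(z, 0.0))
        p = min(p, 1.0)
    return RankTestResult("wilcoxon", ("a", "b"), W, p, method=method)


def _kw_statistic(values: np.ndarray, labels: np.ndarray) -> float:
    ranks = sps.rankdata(values)
    N = len(values)
    H = 0.0
    for g in np.unique(labels):
        r = ranks[labels == g]
        H += r.sum() ** 2 / len(r)
    H = 12.0 / (N * (N + 1)) * H - 3 * (N + 1)
    tie = _tie_term(values)
    correction = 1.0 - tie / (N**3 - N)
    if correction > 0:
        H /= correction
    return H


def kruskal_wallis(samples: dict, method: str = "auto") -> RankTestResult:
    """Tie-corrected Kruskal-Wallis H across k groups.

    'exact' enumerates all distinct assignments of pooled values to the
    group sizes; 'asymptotic' refers H to chi-squared with k-1 df.
    """
    names = list(samples)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(samples[g], dtype=float) for g in names]
    for g, arr in zip(names, arrays):
        if len(arr) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    values = np.concatenate(arrays)
    labels = np.concatenate([np.full(len(arr), i) for i, arr in enumerate(arrays)])
    N = len(values)
    if np.ptp(values) == 0:
        return RankTestResult("kruskal", tuple(names), 0.0, 1.0, method="degenerate")
    H = _kw_statistic(values, labels)
    if method == "auto":
        method = "exact" if N <= 10 else "asymptotic"
    if method == "exact":
        sizes = [len(arr) for arr in arrays]
        count = 0
        total = 0
        for perm_labels in _group_assignments(N, sizes):
            h = _kw_statistic(values, perm_labels)
            total += 1
            if h >= H - 1e-9:
                count += 1
        p = count / total
    else:
        p = float(sps.chi2.sf(H, len(names) - 1))
    return RankTestResult("kruskal", tuple(names), H, p, method=method)


def _group_assignments(N: int, sizes: list[int]):
    """Yield every assignment of N items to groups of the given sizes."""
    def rec(remaining: tuple, sizes_left: list[int], labels: dict, g: int):
        if not sizes_left:
            lab = np.empty(N, dtype=int)
            for i, v in labels.items():
                lab[i] = v
            yield lab
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            new = dict(labels)
            for i in combo:
                new[i] = g
            rest = tuple(i for i in remaining if i not in set(combo))
            yield from rec(rest, sizes_left[1:], new, g + 1)
    yield from rec(tuple(range(N)), sizes, {}, 0)


def dunn_posthoc(samples: dict, alpha: float = 0.05) -> list[RankTestResult]:
    """Dunn's pairwise z-tests on pooled ranks with Bonferroni adjustment.

    z_ij = (mean rank_i - mean rank_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)),
    with T the tie correction sum(t^3 - t)/(12(N-1)); the Bonferroni family
    is all m = k(k-1)/2 pairs.
    """
    names = list(samples)
    arrays = [np.asarray(samples[g], dtype=float) for g in names]
    values = np.concatenate(arrays)
    labels = np.concatenate([np.full(len(arr), i) for i, arr in enumerate(arrays)])
    N = len(values)
    ranks = sps.rankdata(values)
    mean_ranks = {i: ranks[labels == i].mean() for i in range(len(names))}
    ns = {i: (labels == i).sum() for i in range(len(names))}
    T = _tie_term(values) / (12.0 * (N - 1))
    m = len(names) * (len(names) - 1) // 2
    out = []
    for i, j in itertools.combinations(range(len(names)), 2):
        se = math.sqrt((N * (N + 1) / 12.0 - T) * (1.0 / ns[i] + 1.0 / ns[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2 * sps.norm.sf(abs(z))
        out.append(RankTestResult("dunn", (names[i], names[j]), z, p,
                                  p_adjusted=min(1.0, m * p)))
    return out


def compact_letter_display(names, pairs: list[RankTestResult],
                           alpha: float = 0.05) -> dict[str, str]:
    """Letters such that two groups share a letter iff not significantly different.

    Insert-and-absorb algorithm on the non-significance graph; letters are
    assigned in group order so the display is deterministic.
    """
    names = list(names)
    differ = {frozenset(r.groups) for r in pairs
              if (r.p_adjusted if r.p_adjusted is not None else r.p_value) < alpha}
    letters: list[set] = []
    for g in names:
        placed = False
        for group_set in letters:
            if all(frozenset((g, other)) not in differ for other in group_set):
                group_set.add(g)
                placed = True
        if not placed:
            letters.append({g})
    # absorb subsets
    letters = [s for i, s in enumerate(letters)
               if not any(s < t for j, t in enumerate(letters) if i != j)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in names}
    for letter, s in zip(alphabet, letters):
        for g in sorted(s, key=names.index):
            out[g] += letter
    return out


def rank_tests(samples: dict, alpha: float = 0.05, method: str = "auto") -> dict:
    """Omnibus + post-hoc comparison of cross-shore distance distributions.

    Returns a dict with the Kruskal-Wallis omnibus result, Dunn pairwise
    results (Bonferroni-adjusted), a compact letter display, and — when
    exactly two groups are given — the Wilcoxon rank-sum result.
    """
    names = list(samples)
    omnibus = kruskal_wallis(samples, method=method)
    pairs = dunn_posthoc(samples, alpha=alpha) if len(names) > 2 else []
    result = {
        "kruskal": omnibus,
        "dunn": pairs,
        "letters": compact_letter_display(names, pairs, alpha) if pairs else None,
    }
    if len(names) == 2:
        result["wilcoxon"] = wilcoxon_rank_sum(samples[names[0]], samples[names[1]],
                                               method=method)
    return result
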