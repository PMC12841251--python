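"""Group-comparison statistics and compact-letter-display annotation.

Two pipelines mirror how crustacean flavor tables are annotated:

* :func:`kruskal_groups` — Kruskal–Wallis omnibus test (tie-corrected),
  then pairwise two-sided rank-sum tests with Benjamini–Hochberg correction
  across the pairs of one variable (nucleotide-style data).
* :func:`anova_duncan` — one-way ANOVA followed by Duncan's multiple range
  test with studentized-range least significant ranges (amino-acid-style
  data).

Both end in a compact letter display: groups sharing a lowercase letter are
not significantly different at alpha.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "benjamini_hochberg",
    "kruskal_groups",
    "anova_duncan",
    "compact_letter_display",
]


@dataclass
class GroupComparison:
    """Omnibus statistic, BH-corrected pairwise table and letters for one variable."""

    variable_id: str
    method: str
    omnibus_stat: float
    omnibus_p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, raw_p, q, significant
    letters: dict[str, str]
    group_means: dict[str, float] = field(default_factory=dict)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, in input order.

    Adjusted values are monotone non-decreasing in the rank of the raw
    p-value and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _validate_groups(values_by_group: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(values_by_group) < 2:
        raise ValueError("need at least two groups")
    arrays = {}
    for g, vals in values_by_group.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        arrays[g] = arr
    return arrays


def _letters_from_pairwise(
    groups: list[str],
    arrays: Mapping[str, np.ndarray],
    pairwise: pd.DataFrame,
    alpha: float,
    omnibus_gate_open: bool,
) -> dict[str, str]:
    order = sorted(groups, key=lambda g: -float(np.mean(arrays[g])))
    k = len(order)
    sig = np.zeros((k, k), dtype=bool)
    if omnibus_gate_open:
        idx = {g: i for i, g in enumerate(order)}
        for row in pairwise.itertuples():
            if row.significant:
                i, j = idx[row.group_a], idx[row.group_b]
                sig[i, j] = sig[j, i] = True
    return compact_letter_display(order, sig)


def kruskal_groups(
    values_by_group: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    omnibus_gate: bool = True,
    variable_id: str = "",
) -> GroupComparison:
    """Kruskal–Wallis omnibus + BH-corrected pairwise rank-sum letters.

    Pairwise two-sided Mann–Whitney (Wilcoxon rank-sum) p-values use the
    exact null distribution when samples are small and tie-free, the
    tie-corrected normal approximation otherwise. The BH family is the set
    of pairwise comparisons within this one variable. When ``omnibus_gate``
    is set (default) and the omnibus p >= alpha, all groups share one letter
    regardless of the pairwise results.
    """
    arrays = _validate_groups(values_by_group)
    groups = list(arrays)
    if np.ptp(np.concatenate(list(arrays.values()))) == 0:
        # every observation identical: KW is undefined (all ranks tied)
        stat, p_omni = 0.0, 1.0
    else:
        stat, p_omni = sps.kruskal(*arrays.values())

    rows = []
    for a, b in itertools.combinations(groups, 2):
        xa, xb = arrays[a], arrays[b]
        pooled = np.concatenate([xa, xb])
        exact_ok = len(pooled) <= 30 and len(np.unique(pooled)) == len(pooled)
        if np.ptp(pooled) == 0:
            raw_p = 1.0
        else:
            res = sps.mannwhitneyu(
                xa, xb, alternative="two-sided", method="exact" if exact_ok else "asymptotic"
            )
            raw_p = float(res.pvalue)
        rows.append({"group_a": a, "group_b": b, "raw_p": raw_p})
    pairwise = pd.DataFrame(rows)
    pairwise["q"] = benjamini_hochberg(pairwise["raw_p"].to_numpy())
    pairwise["significant"] = pairwise["q"] < alpha

    letters = _letters_from_pairwise(
        groups, arrays, pairwise, alpha, omnibus_gate_open=(not omnibus_gate) or p_omni < alpha
    )
    return GroupComparison(
        variable_id=variable_id,
        method="kruskal-bh",
        omnibus_stat=float(stat),
        omnibus_p=float(p_omni),
        pairwise=pairwise,
        letters=letters,
        group_means={g: float(np.mean(v)) for g, v in arrays.items()},
    )


def _duncan_significance(
    means: Sequence[float], mse: float, df_error: int, n_harmonic: float, alpha: float
) -> np.ndarray:
    """Pairwise significance matrix of Duncan's multiple range test.

    Means must be sorted descending. A pair spanning ``p`` ordered means is
    significant when its difference exceeds the least significant range
    ``R_p = q(1 - alpha_p; p, df) * sqrt(MSE / n)`` with the Duncan
    protection level ``alpha_p = 1 - (1 - alpha)^(p - 1)``, and no enclosing
    span has already been declared non-significant (the standard containment
    rule of stepwise range procedures).
    """
    m = np.asarray(means, dtype=float)
    k = m.size
    if np.any(np.diff(m) > 1e-12):
        raise ValueError("means must be sorted in descending order")
    se = np.sqrt(mse / n_harmonic)
    lsr = np.full(k + 1, np.nan)
    for p in range(2, k + 1):
        alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
        q_crit = sps.studentized_range.ppf(1.0 - alpha_p, p, df_error)
        lsr[p] = q_crit * se
    sig = np.zeros((k, k), dtype=bool)
    # widest spans first so the containment rule can cascade inwards
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            exceeds = (m[i] - m[j]) > lsr[span] if se > 0 else m[i] != m[j]
            contained_ns = any(
                not sig[a, b]
                for a in range(0, i + 1)
                for b in range(j, k)
                if (b - a + 1) > span
            )
            sig[i, j] = sig[j, i] = exceeds and not contained_ns
    return sig


def anova_duncan(
    values_by_group: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    variable_id: str = "",
) -> GroupComparison:
    """One-way ANOVA followed by Duncan's multiple range test.

    Homoscedasticity is assumed, not tested. Unequal group sizes use the
    harmonic mean n in the least significant ranges. The pairwise table
    reports no per-pair p-values (Duncan is a range procedure); its
    ``significant`` column and the letters carry the grouping.
    """
    arrays = _validate_groups(values_by_group)
    groups = list(arrays)
    values = list(arrays.values())
    n_total = sum(len(v) for v in values)
    k = len(groups)
    df_error = n_total - k
    grand = np.mean(np.concatenate(values))
    sse = sum(float(np.sum((v - np.mean(v)) ** 2)) for v in values)
    mse = sse / df_error
    if mse == 0:
        if len({float(np.mean(v)) for v in values}) > 1:
            warnings.warn(
                "zero within-group variance with distinct means; letters are "
                "based on mean equality only"
            )
        f_stat, p_omni = (np.inf, 0.0) if len({float(np.mean(v)) for v in values}) > 1 else (0.0, 1.0)
    else:
        f_stat, p_omni = sps.f_oneway(*values)

    order = sorted(groups, key=lambda g: -float(np.mean(arrays[g])))
    means_sorted = [float(np.mean(arrays[g])) for g in order]
    n_harm = k / sum(1.0 / len(arrays[g]) for g in order)
    sig_sorted = _duncan_significance(means_sorted, mse, df_error, n_harm, alpha)
    letters = compact_letter_display(order, sig_sorted)

    idx = {g: i for i, g in enumerate(order)}
    rows = [
        {
            "group_a": a,
            "group_b": b,
            "raw_p": np.nan,
            "q": np.nan,
            "significant": bool(sig_sorted[idx[a], idx[b]]),
        }
        for a, b in itertools.combinations(groups, 2)
    ]
    return GroupComparison(
        variable_id=variable_id,
        method="anova-duncan",
        omnibus_stat=float(f_stat),
        omnibus_p=float(p_omni),
        pairwise=pd.DataFrame(rows),
        letters=letters,
        group_means={g: float(np.mean(v)) for g, v in arrays.items()},
    )


def compact_letter_display(
    groups: Sequence[str], significant: np.ndarray
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``groups`` must be ordered (conventionally by descending mean) so the
    letters come out in 'a', 'b', ... order along that ranking;
    ``significant[i, j]`` is True when groups i and j differ. Two groups
    share at least one letter iff their pair is non-significant. The letter
    set is kept small by absorbing redundant columns but minimality is not
    guaranteed in general.
    """
    sig = np.asarray(significant, dtype=bool)
    k = len(groups)
    if sig.shape != (k, k):
        raise ValueError("significance matrix shape must match the group list")
    if not np.array_equal(sig, sig.T):
        raise ValueError("significance matrix must be symmetric")
    if np.any(np.diag(sig)):
        raise ValueError("diagonal of the significance matrix must be False")

    columns: list[set[int]] = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if not sig[i, j]:
            continue
        for col in [c for c in columns if i in c and j in c]:
            columns.remove(col)
            for split in (col - {i}, col - {j}):
                if split and not any(split <= other for other in columns):
                    columns = [c for c in columns if not c <= split] + [split]
    # order columns by the first (best-ranked) group they contain
    columns.sort(key=lambda c: (min(c), sorted(c)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for pos, col in enumerate(columns):
        letter = alphabet[pos % 26] * (pos // 26 + 1)
        for i in sorted(col):
            letters[groups[i]] += letter
    return letters
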