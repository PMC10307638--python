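"""Ancestral genome-content statistics and group comparisons.

Reconciliation output is aggregated into one profile per ancestral node:
a proteome size (families whose corrected copy number clears the presence
threshold) and duplication/loss/origination counts normalised by that
size.  Clades of ancestors are then compared against the median of a
reference ancestor group with a two-sided one-sample Wilcoxon signed-rank
test — exact for small samples, normal approximation with continuity
correction beyond — and deliberately without any multiple-testing
correction, so individual p-values stay interpretable as reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, norm, rankdata

from .reconcile import THETA_PRESENT, ReconciliationSummary, SpeciesTree

EVENT_CLASSES = ("duplication", "loss", "origination")


class StatsError(ValueError):
    pass


@dataclass
class AncestorProfile:
    node_id: str
    proteome_size: int
    copy_sum: float                    # sum of corrected copies (alternative size)
    counts: dict[str, float]           # event class -> expected count
    rates: dict[str, float]            # event class -> count / proteome size


def copy_table(summaries: list[ReconciliationSummary], stree: SpeciesTree,
               corrected: bool = True) -> pd.DataFrame:
    """Families x branches table of (corrected) expected copy numbers."""
    rows = {}
    for s in summaries:
        values = s.corrected_copies if corrected else s.expected["copies"]
        rows[s.family_id] = values
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=stree.branch_names)


def event_table(summaries: list[ReconciliationSummary], stree: SpeciesTree,
                event_class: str) -> pd.DataFrame:
    key = {"duplication": "duplication", "loss": "loss",
           "origination": "origination"}[event_class]
    rows = {s.family_id: s.expected[key] for s in summaries}
    return pd.DataFrame.from_dict(rows, orient="index", columns=stree.branch_names)


def proteome_size(copies: pd.DataFrame, node_id: str,
                  theta_present: float = THETA_PRESENT) -> int:
    """Number of families with copy number above the presence threshold."""
    if node_id not in copies.columns:
        raise StatsError(f"unknown node {node_id!r}")
    return int((copies[node_id] > theta_present).sum())


def normalized_event_rates(node_id: str, counts: dict[str, float],
                           size: int, copy_sum: float = np.nan) -> AncestorProfile:
    if size <= 0:
        raise StatsError(f"proteome size of node {node_id!r} is zero")
    rates = {k: v / size for k, v in counts.items()}
    return AncestorProfile(node_id, size, copy_sum, dict(counts), rates)


def build_profiles(summaries: list[ReconciliationSummary], stree: SpeciesTree,
                   theta_present: float = THETA_PRESENT,
                   internal_only: bool = True) -> list[AncestorProfile]:
    copies = copy_table(summaries, stree)
    events = {cls: event_table(summaries, stree, cls) for cls in EVENT_CLASSES}
    profiles = []
    for idx, name in enumerate(stree.branch_names):
        if internal_only and stree.children[idx] is None:
            continue
        size = proteome_size(copies, name, theta_present)
        if size == 0:
            continue
        counts = {cls: float(events[cls][name].sum()) for cls in EVENT_CLASSES}
        profiles.append(normalized_event_rates(
            name, counts, size, float(copies[name].sum())))
    return profiles


# -- one-sample Wilcoxon signed-rank vs a reference scalar -----------------

def _exact_signed_rank_p(d: np.ndarray) -> float:
    """Two-sided exact p by dynamic programming over the signed-rank null
    (all 2^n sign assignments equally likely), with midranks for ties."""
    n = len(d)
    ranks = rankdata(np.abs(d))
    doubled = np.rint(2 * ranks).astype(int)  # integers even with midranks
    w_obs = int(np.rint(2 * ranks[d > 0].sum()))
    total = doubled.sum()
    # distribution of the doubled positive-rank sum
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled:
        new = dist.copy()
        new[r:] += dist[: total + 1 - r]
        dist = new / 2.0
    p_le = dist[: w_obs + 1].sum()
    p_ge = dist[w_obs:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _approx_signed_rank_p(d: np.ndarray) -> float:
    n = len(d)
    ranks = rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts ** 3 - tie_counts).sum() / 48.0
    if var <= 0:
        return 1.0
    diff = w - mean
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


def wilcoxon_vs_reference(values, reference: float, exact_max_n: int = 25) -> float:
    """Two-sided one-sample Wilcoxon signed-rank p-value of ``values``
    against a reference scalar.  Exact ties with the reference are
    dropped; at least three informative values are required.
    """
    d = np.asarray(values, dtype=float) - float(reference)
    d = d[d != 0]
    if len(d) < 3:
        raise StatsError("insufficient ancestors for a signed-rank test (n < 3)")
    if len(d) <= exact_max_n:
        return _exact_signed_rank_p(d)
    return _approx_signed_rank_p(d)


def mann_whitney_vs_group(values, reference_values) -> float:
    """Two-sample alternative (Mann-Whitney U), available behind a flag."""
    return float(mannwhitneyu(values, reference_values,
                              alternative="two-sided").pvalue)


def significance_stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def group_report(profiles: list[AncestorProfile], groups: dict[str, str],
                 reference_group: str, two_sample: bool = False) -> pd.DataFrame:
    """Median/IQR and Wilcoxon p-value per (group, event class), each
    non-reference group tested against the reference-group median.

    No multiple-comparison correction is applied.
    """
    by_group: dict[str, list[AncestorProfile]] = {}
    for p in profiles:
        g = groups.get(p.node_id)
        if g is not None:
            by_group.setdefault(g, []).append(p)
    if reference_group not in by_group or not by_group[reference_group]:
        raise StatsError(f"reference group {reference_group!r} is empty")
    rows = []
    for cls in EVENT_CLASSES:
        ref_values = np.array([p.rates[cls] for p in by_group[reference_group]])
        ref_median = float(np.median(ref_values))
        for group, members in sorted(by_group.items()):
            vals = np.array([p.rates[cls] for p in members])
            if group == reference_group:
                pval = np.nan
            else:
                try:
                    if two_sample:
                        pval = mann_whitney_vs_group(vals, ref_values)
                    else:
                        pval = wilcoxon_vs_reference(vals, ref_median)
                except StatsError:
                    pval = np.nan
            q1, q3 = np.percentile(vals, [25, 75])
            rows.append({
                "group": group,
                "event_class": cls,
                "n": len(vals),
                "median": float(np.median(vals)),
                "iqr_low": float(q1),
                "iqr_high": float(q3),
                "reference_median": ref_median,
                "p_value": pval,
                "stars": "" if np.isnan(pval) else significance_stars(pval),
            })
    return pd.DataFrame(rows)
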