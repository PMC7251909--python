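"""Frequency feature selection (FFS): consensus over seeded selection runs.

A feature that keeps being picked across independently seeded selection
runs is more likely to carry real signal than one that appears once.  FFS
counts, for each feature, the number of the r seeded runs whose selected
subset contains it, and retains only features with count >= t, the
frequency threshold.  The surviving sets from the linear- and RBF-kernel
fitness runs are finally unioned into one panel.
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass
class FrequencyTable:
    """Per-feature occurrence counts across r seeded selection runs.

    Features absent from every subset are simply absent from the map
    (an implied count of 0); every stored count lies in [1, r].
    """

    counts: dict
    r: int

    def __post_init__(self) -> None:
        bad = {f: c for f, c in self.counts.items() if not 1 <= c <= self.r}
        if bad:
            raise ValueError(f"counts outside [1, r={self.r}]: {bad}")


def count_occurrences(subsets) -> FrequencyTable:
    """Count how many of the given feature subsets contain each feature."""
    subsets = [set(s) for s in subsets]
    if not subsets:
        raise ValueError("need at least one selection subset")
    counts: dict = {}
    for subset in subsets:
        for feature in subset:
            counts[feature] = counts.get(feature, 0) + 1
    return FrequencyTable(counts, len(subsets))


def select_by_threshold(table: FrequencyTable, t: int) -> set:
    """Features occurring in at least *t* of the r subsets.

    t = 1 returns the union of the subsets, t = r their intersection, and
    the selection shrinks monotonically as t grows.
    """
    if not 1 <= t <= table.r:
        raise ValueError(f"threshold t={t} outside [1, r={table.r}]")
    return {f for f, c in table.counts.items() if c >= t}


def combine_kernels(linear_set, rbf_set, order=None) -> list:
    """Union of the per-kernel survivor sets, in deterministic order.

    If *order* (e.g. the SNP ids of the source matrix) is given, the output
    follows that column order; otherwise it is sorted lexicographically.
    """
    union = set(linear_set) | set(rbf_set)
    if order is not None:
        rank = {f: i for i, f in enumerate(order)}
        return sorted(union, key=lambda f: rank[f])
    return sorted(union)
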