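"""Information-gain ranking of SNPs and automatic elbow cut-point selection.

Each SNP column is treated as an unordered categorical variable over the
genotype codes {0, 1, 2}.  Its information gain is the entropy of the breed
label distribution minus the expected entropy after conditioning on the
genotype value, in bits.  Ranked gains form a steeply decaying curve, and a
knee-point heuristic picks how many top-ranked SNPs to retain.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import GenotypeMatrix

_SORT_TOL = 1e-9


@dataclass
class IGRanking:
    """SNPs ordered by descending information gain with an elbow cut.

    ``snp_ids[:cut_index]`` is the retained panel.
    """

    snp_ids: list
    ig_values: np.ndarray
    cut_index: int

    def __post_init__(self) -> None:
        self.ig_values = np.asarray(self.ig_values, dtype=float)
        if np.any(np.diff(self.ig_values) > _SORT_TOL):
            raise ValueError("ig_values must be non-increasing")
        if not 1 <= self.cut_index <= len(self.snp_ids):
            raise ValueError(f"cut_index {self.cut_index} outside [1, n]")

    @property
    def retained_ids(self) -> list:
        return self.snp_ids[: self.cut_index]


def entropy(labels) -> float:
    """Shannon entropy of a categorical sequence, in bits (0*log0 = 0)."""
    arr = np.asarray(labels)
    if arr.size == 0:
        raise ValueError("entropy of an empty sequence is undefined")
    _, counts = np.unique(arr, return_counts=True)
    p = counts / arr.size
    return float(-(p * np.log2(p)).sum())


def information_gain(column, labels) -> float:
    """Information gain of one categorical feature about the labels, in bits.

    IG = E(T) - sum_v (|T_v| / |T|) * E(T_v), where T_v is the subset of
    samples at which the feature takes value v.  Always in [0, E(T)].
    """
    col = np.asarray(column)
    y = np.asarray(labels)
    if col.shape != y.shape or col.ndim != 1:
        raise ValueError(
            f"column and labels must be equal-length 1-D sequences "
            f"({col.shape} vs {y.shape})"
        )
    total = entropy(y)
    n = col.size
    conditional = 0.0
    covered = 0
    for v in np.unique(col):
        sub = y[col == v]
        covered += sub.size
        conditional += sub.size / n * entropy(sub)
    assert covered == n, "genotype groups must partition the sample set"
    return max(total - conditional, 0.0)


def rank_features(G: GenotypeMatrix) -> IGRanking:
    """Score every SNP by information gain and rank in descending order.

    Requires an imputed matrix (no -1 entries).  Ties are broken by the
    original column index so the ranking is stable and reproducible.
    """
    if (G.values == -1).any():
        raise ValueError("matrix contains missing codes; run impute_mode first")
    codes = G.values
    m, n = codes.shape
    y = np.asarray(G.labels)
    classes, yi = np.unique(y, return_inverse=True)
    k = classes.size
    onehot = np.zeros((m, k))
    onehot[np.arange(m), yi] = 1.0
    total = entropy(y)

    conditional = np.zeros(n)
    covered = np.zeros(n)
    for v in (0, 1, 2):
        member = codes == v  # m x n
        cnt = member.T.astype(float) @ onehot  # n x k class counts within group v
        n_v = cnt.sum(axis=1)
        covered += n_v
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n_v[:, None] > 0, cnt / np.maximum(n_v, 1)[:, None], 0.0)
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        e_v = -plogp.sum(axis=1)
        conditional += np.where(n_v > 0, n_v / m * e_v, 0.0)
    assert np.all(covered == m), "genotype groups must partition the sample set"

    ig = np.clip(total - conditional, 0.0, None)
    order = np.argsort(-ig, kind="stable")
    ig_sorted = ig[order]
    cut = elbow_cutpoint(ig_sorted) if n >= 2 else 1
    return IGRanking([G.snp_ids[i] for i in order], ig_sorted, cut)


def elbow_cutpoint(ig_values) -> int:
    """Knee of a sorted, non-increasing score curve, as a 1-based count.

    The curve points (i, v_i) are compared against the straight chord
    joining (1, v_1) to (n, v_n); the retained count k is the index of the
    point farthest from that chord (maximum perpendicular distance, i.e.
    maximum |v_i - chord(i)| since the chord angle is fixed).  Ties break
    toward the smallest index, so a perfectly linear or constant curve
    yields k = 1.  Scale-invariant in the score values.
    """
    v = np.asarray(ig_values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-D sequence of length >= 2")
    if np.any(np.diff(v) > _SORT_TOL):
        raise ValueError("ig_values must be sorted non-increasing")
    n = v.size
    x = np.arange(n, dtype=float)
    chord = v[0] + (v[-1] - v[0]) * x / (n - 1)
    distance = np.abs(v - chord)
    return int(np.argmax(distance)) + 1
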