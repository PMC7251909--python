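"""End-to-end selection methods, comparison framework, and evaluation stats.

Orchestrates the experimental design: an outer stratified 80:20 split, r
randomly-seeded inner sub-splits of the training set, per-sub-split
information-gain ranking with an elbow cut, an optional GA refinement
driven by SVM cross-validation fitness (per kernel), an optional frequency
consensus (FFS) across the r runs, and a final tune-refit-test evaluation.

Methods
-------
``ALL``          no selection; every SNP enters the classifier.
``IG``           elbow-retained SNPs, unioned over the r sub-splits.
``IG+FFS``       elbow-retained SNPs filtered by frequency threshold.
``IG+GA``        conventional-GA refinement of the elbow panel, per kernel.
``IG+mGA``       the same with the asymmetric (modified) mutation.
``IG+GA+FFS``    conventional GA followed by frequency consensus.
``IG+mGA+FFS``   modified GA followed by frequency consensus — the headline
                 hybrid, which typically yields the smallest panel.

Also provides the evaluation statistics used for method comparison: a
one-way ANOVA computed from per-method summary statistics, percentage
arithmetic, minor allele frequency, and a leave-one-SNP-out accuracy scan.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import ffs as _ffs
from .ga_select import GAConfig, evolve
from .genotype_io import GenotypeMatrix, make_seeded_splits, stratified_split
from .info_gain import rank_features
from .svm_fitness import final_evaluate, subset_fitness

METHODS = ("ALL", "IG", "IG+FFS", "IG+GA", "IG+GA+FFS", "IG+mGA", "IG+mGA+FFS")

_GA_METHODS = {"IG+GA", "IG+GA+FFS", "IG+mGA", "IG+mGA+FFS"}
_FFS_METHODS = {"IG+FFS", "IG+GA+FFS", "IG+mGA+FFS"}


@dataclass
class PipelineConfig:
    """Knobs of the experimental framework.

    The outer and inner splits both default to an 80:20 ratio; r = 10 inner
    sub-splits feed the frequency consensus, whose threshold defaults to
    t = 9.  GA hyperparameters live in ``ga`` (its mode and seed are set
    per run).  The ``fitness_*`` grids control the SVM grid searched inside
    the GA fitness; the ``final_*`` grids control the last tune-and-test
    stage.  ``None`` means the full 13 x 21 powers-of-ten grid.
    """

    outer_fraction: float = 0.2
    r: int = 10
    inner_fraction: float = 0.2
    threshold: int = 9
    kernels: tuple = ("linear", "rbf")
    ga: GAConfig = field(default_factory=lambda: GAConfig(p_mutation=0.9))
    fitness_folds: int = 5
    fitness_c_grid: tuple | None = None
    fitness_gamma_grid: tuple | None = None
    final_folds: int = 5
    final_c_grid: tuple | None = None
    final_gamma_grid: tuple | None = None
    pool_kernel_counts: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.threshold <= self.r:
            raise ValueError(f"threshold {self.threshold} outside [1, r={self.r}]")
        bad = [k for k in self.kernels if k not in ("linear", "rbf")]
        if bad:
            raise ValueError(f"unknown kernels {bad}")


@dataclass
class MethodResult:
    """Selected panels and test accuracies of one method at one outer seed."""

    method: str
    selected_linear: set
    selected_rbf: set
    final_selected: list
    test_accuracy_linear: float
    test_accuracy_rbf: float
    outer_seed: int
    per_run_subsets: dict = field(default_factory=dict, repr=False)

    def accuracy(self, kernel: str) -> float:
        return {"linear": self.test_accuracy_linear, "rbf": self.test_accuracy_rbf}[kernel]

    def selected(self, kernel: str) -> set:
        return {"linear": self.selected_linear, "rbf": self.selected_rbf}[kernel]


@dataclass
class RunReport:
    """Aggregate of a multi-seed, multi-method comparison."""

    results: dict                 # method -> list[MethodResult], one per outer seed
    summary: pd.DataFrame         # per method/kernel mean +- std counts & accuracies
    anova: dict                   # kernel -> ANOVA table dict
    outer_seeds: tuple
    n_snps: int


def _inner_seed0(outer_seed: int) -> int:
    # distinct, reproducible inner seed block per outer seed, kept < 2**31
    return (outer_seed * 1009 + 1) % (2**31 - 1)


def run_method(
    G: GenotypeMatrix, method: str, cfg: PipelineConfig, outer_seed: int
) -> MethodResult:
    """Execute one selection method end to end for one outer seed.

    The matrix must already be imputed.  Every random stage is keyed off
    (outer seed, inner seed, kernel), so reruns are bit-reproducible.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if (G.values == -1).any():
        raise ValueError("matrix contains missing codes; run impute_mode first")
    if len(set(G.labels)) < 2:
        raise ValueError("need at least 2 distinct breed labels")

    train, test = stratified_split(G, cfg.outer_fraction, outer_seed)
    eval_kw = dict(
        folds=cfg.final_folds, C_grid=cfg.final_c_grid, gamma_grid=cfg.final_gamma_grid
    )

    def evaluate(ids, kernel: str) -> float:
        if not ids:
            return float("nan")
        return final_evaluate(ids, train, test, kind=kernel, seed=outer_seed, **eval_kw)

    if method == "ALL":
        accs = {k: evaluate(G.snp_ids, k) for k in cfg.kernels}
        return MethodResult(
            method, set(G.snp_ids), set(G.snp_ids), list(G.snp_ids),
            accs.get("linear", float("nan")), accs.get("rbf", float("nan")),
            outer_seed,
        )

    splits = make_seeded_splits(
        train, cfg.r, cfg.inner_fraction, seed0=_inner_seed0(outer_seed)
    )
    per_kernel_subsets: dict = {k: [] for k in cfg.kernels}
    for split in splits:
        try:
            sub_train = train.subset_samples(split.train_indices)
            ranking = rank_features(sub_train)
            retained = ranking.retained_ids
            if method in ("IG", "IG+FFS"):
                for kernel in cfg.kernels:
                    per_kernel_subsets[kernel].append(set(retained))
                continue
            retained_idx = [train.snp_index(s) for s in retained]
            X_sub = sub_train.values[:, retained_idx].astype(float)
            y_sub = np.asarray(sub_train.labels)
            mode = "modified" if method.startswith("IG+mGA") else "conventional"
            for k_off, kernel in enumerate(cfg.kernels):
                ga_cfg = replace(cfg.ga, mode=mode, seed=split.seed * 4 + k_off)

                def fitness(mask, _kernel=kernel):
                    return subset_fitness(
                        mask, X_sub, y_sub, kind=_kernel,
                        folds=cfg.fitness_folds, seed=split.seed,
                        C_grid=cfg.fitness_c_grid, gamma_grid=cfg.fitness_gamma_grid,
                    )

                result = evolve(len(retained), ga_cfg, fitness)
                chosen = {retained[i] for i in np.flatnonzero(result.best.mask)}
                per_kernel_subsets[kernel].append(chosen)
        except Exception as exc:
            raise RuntimeError(
                f"method {method!r} failed at outer seed {outer_seed}, "
                f"inner seed {split.seed}"
            ) from exc

    if method in _FFS_METHODS:
        if cfg.pool_kernel_counts:
            pooled = [s for subsets in per_kernel_subsets.values() for s in subsets]
            table = _ffs.count_occurrences(pooled)
            t = min(cfg.threshold, table.r)
            survivors = {k: _ffs.select_by_threshold(table, t) for k in cfg.kernels}
        else:
            survivors = {
                k: _ffs.select_by_threshold(
                    _ffs.count_occurrences(per_kernel_subsets[k]), cfg.threshold
                )
                for k in cfg.kernels
            }
        final = _ffs.combine_kernels(
            survivors.get("linear", set()), survivors.get("rbf", set()),
            order=G.snp_ids,
        )
        accs = {k: evaluate(final, k) for k in cfg.kernels}
        sel_lin = survivors.get("linear", set())
        sel_rbf = survivors.get("rbf", set())
    else:
        survivors = {
            k: set().union(*per_kernel_subsets[k]) for k in cfg.kernels
        }
        accs = {k: evaluate(sorted(survivors[k]), k) for k in cfg.kernels}
        sel_lin = survivors.get("linear", set())
        sel_rbf = survivors.get("rbf", set())
        final = _ffs.combine_kernels(sel_lin, sel_rbf, order=G.snp_ids)

    return MethodResult(
        method, sel_lin, sel_rbf, final,
        accs.get("linear", float("nan")), accs.get("rbf", float("nan")),
        outer_seed, per_run_subsets=per_kernel_subsets,
    )


def compare_all(
    G: GenotypeMatrix,
    cfg: PipelineConfig,
    methods=METHODS,
    outer_seeds=tuple(range(1, 11)),
) -> RunReport:
    """Run every method over the same outer seeds and tabulate the outcome.

    The summary mirrors the usual method-comparison table: per method and
    kernel, the mean +- std selected-panel size, its percentage of all
    SNPs, and the mean +- std test accuracy (in percent).  When every
    method has >= 2 seeds, a one-way ANOVA across methods is attached per
    kernel.
    """
    outer_seeds = tuple(outer_seeds)
    results = {
        m: [run_method(G, m, cfg, s) for s in outer_seeds] for m in methods
    }
    rows = []
    for m in methods:
        for kernel in cfg.kernels:
            sizes = [len(res.selected(kernel)) for res in results[m]]
            accs = [100.0 * res.accuracy(kernel) for res in results[m]]
            mean_size = float(np.mean(sizes))
            rows.append(
                {
                    "method": m,
                    "kernel": kernel,
                    "n_selected_mean": round(mean_size, 2),
                    "n_selected_std": round(float(np.std(sizes, ddof=1)), 2)
                    if len(sizes) > 1 else 0.0,
                    "percent_of_total": percent_of_total(mean_size, G.n_snps),
                    "accuracy_mean": round(float(np.nanmean(accs)), 2),
                    "accuracy_std": round(float(np.nanstd(accs, ddof=1)), 2)
                    if len(accs) > 1 else 0.0,
                }
            )
    summary = pd.DataFrame(rows)

    anova: dict = {}
    if len(outer_seeds) >= 2:
        for kernel in cfg.kernels:
            means, stds, ns = [], [], []
            for m in methods:
                accs = [100.0 * res.accuracy(kernel) for res in results[m]]
                accs = [a for a in accs if not math.isnan(a)]
                if len(accs) < 2:
                    break
                means.append(float(np.mean(accs)))
                stds.append(float(np.std(accs, ddof=1)))
                ns.append(len(accs))
            else:
                anova[kernel] = anova_oneway_from_summary(means, stds, ns)
    return RunReport(results, summary, anova, outer_seeds, G.n_snps)


# ---------------------------------------------------------------------------
# evaluation statistics
# ---------------------------------------------------------------------------

def anova_oneway_from_summary(means, stds, n_per_group) -> dict:
    """One-way ANOVA reconstructed from per-group means, SDs, and sizes.

    SS_between = sum n_i (xbar_i - xbar)^2, SS_within = sum (n_i - 1) s_i^2,
    F = MS_between / MS_within with (k - 1, N - k) degrees of freedom; the
    p-value comes from the F distribution's survival function.  Identical to
    an ANOVA on the raw observations whenever the summaries describe them.
    """
    means = np.asarray(means, dtype=float)
    stds = np.asarray(stds, dtype=float)
    ns = np.asarray(n_per_group, dtype=int)
    if not (means.size == stds.size == ns.size):
        raise ValueError("means, stds, and n_per_group must have equal length")
    if means.size < 2:
        raise ValueError("need at least two groups")
    if (ns < 2).any():
        raise ValueError("every group needs n >= 2")
    N = int(ns.sum())
    k = means.size
    grand = float((ns * means).sum() / N)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * stds**2).sum())
    df_between = k - 1
    df_within = N - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        # degenerate: no within-group variance
        F = float("inf") if ms_between > 0 else 0.0
    else:
        F = ms_between / ms_within
    p = float(stats.f.sf(F, df_between, df_within)) if np.isfinite(F) else 0.0
    return {
        "SS_between": ss_between,
        "SS_within": ss_within,
        "SS_total": ss_between + ss_within,
        "df_between": df_between,
        "df_within": df_within,
        "MS_between": ms_between,
        "MS_within": ms_within,
        "F": F,
        "p": p,
    }


def percent_of_total(k, n: int) -> float:
    """100 * k / n rounded to 2 decimals (k may be a fractional mean)."""
    if n <= 0:
        raise ValueError(f"total must be positive, got {n}")
    return round(100.0 * k / n, 2)


def compute_maf(column) -> float:
    """Minor allele frequency of an imputed additive-coded column.

    The alternate-allele frequency is p = mean(code) / 2; the MAF is the
    frequency of the rarer allele, min(p, 1 - p), in [0, 0.5].
    """
    col = np.asarray(column)
    if (col == -1).any():
        raise ValueError("column contains missing codes; impute first")
    p = float(col.mean()) / 2.0
    return min(p, 1.0 - p)


def leave_one_out_scan(
    selected,
    train: GenotypeMatrix,
    test: GenotypeMatrix,
    kind: str = "linear",
    folds: int = 5,
    seed: int = 0,
    C_grid=None,
    gamma_grid=None,
):
    """Re-evaluate the panel with each SNP left out in turn.

    Returns (baseline accuracy of the full panel, list of records
    ``{snp_id, maf, accuracy_without}``).  The MAF is computed on the
    training samples.  Low-MAF SNPs whose removal drops accuracy flag
    variants that carry breed signal despite being rare.
    """
    ids = list(selected)
    if len(ids) < 2:
        raise ValueError("need at least 2 selected SNPs to scan")
    kw = dict(kind=kind, folds=folds, seed=seed, C_grid=C_grid, gamma_grid=gamma_grid)
    baseline = final_evaluate(ids, train, test, **kw)
    records = []
    for snp in ids:
        rest = [s for s in ids if s != snp]
        records.append(
            {
                "snp_id": snp,
                "maf": compute_maf(train.column(snp)),
                "accuracy_without": final_evaluate(rest, train, test, **kw),
            }
        )
    return baseline, records
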