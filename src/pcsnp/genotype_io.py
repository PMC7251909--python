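"""Reading, validation, imputation, and partitioning of coded genotype matrices.

The data model is a samples x SNPs matrix in additive coding: each entry is
the count of the alternate allele (0, 1, or 2), with -1 marking a missing
genotype call.  Every sample carries a breed label.  This is the
post-quality-control representation produced by PLINK's ``--recode A``
export, so the tool starts at the coded matrix rather than at raw variant
calls.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_CODES = (-1, 0, 1, 2)

#: Leading metadata columns of a PLINK .raw-style export, in canonical order.
PLINK_META_COLS = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


class GenotypeValidationError(ValueError):
    """A genotype table violates the coding contract."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs genotype matrix with breed labels.

    Parameters
    ----------
    values
        Integer matrix of shape (m, n) with entries in {-1, 0, 1, 2}.
    sample_ids
        m sample identifiers.
    snp_ids
        n unique SNP identifiers (column order is meaningful).
    labels
        m breed names, one per sample.
    """

    values: np.ndarray
    sample_ids: list = field(default_factory=list)
    snp_ids: list = field(default_factory=list)
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise GenotypeValidationError(f"values must be 2-D, got ndim={arr.ndim}")
        bad = ~np.isin(arr, VALID_CODES)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeValidationError(
                f"invalid genotype code {arr[i, j]!r} at sample row {i}, SNP column {j}"
            )
        self.values = arr.astype(np.int8)
        self.sample_ids = list(self.sample_ids)
        self.snp_ids = list(self.snp_ids)
        self.labels = list(self.labels)
        m, n = self.values.shape
        if len(self.sample_ids) != m or len(self.labels) != m:
            raise GenotypeValidationError(
                f"{m} rows but {len(self.sample_ids)} sample ids / {len(self.labels)} labels"
            )
        if len(self.snp_ids) != n:
            raise GenotypeValidationError(f"{n} columns but {len(self.snp_ids)} SNP ids")
        if len(set(self.snp_ids)) != n:
            seen: set = set()
            dup = next(s for s in self.snp_ids if s in seen or seen.add(s))
            raise GenotypeValidationError(f"duplicate SNP id {dup!r}")

    # -- convenience ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int((self.values == -1).sum())

    @property
    def breeds(self) -> list:
        """Distinct breed labels in sorted order."""
        return sorted(set(self.labels))

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP id {snp_id!r}") from None

    def column(self, snp_id: str) -> np.ndarray:
        return self.values[:, self.snp_index(snp_id)]

    def subset_samples(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            self.values[idx],
            [self.sample_ids[i] for i in idx],
            list(self.snp_ids),
            [self.labels[i] for i in idx],
        )

    def subset_snps(self, snp_ids: Iterable[str]) -> "GenotypeMatrix":
        ids = list(snp_ids)
        idx = [self.snp_index(s) for s in ids]
        return GenotypeMatrix(
            self.values[:, idx], list(self.sample_ids), ids, list(self.labels)
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.snp_ids)
        df.insert(0, "breed", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df


@dataclass
class SplitSpec:
    """One stratified train/test partition of a sample index range."""

    seed: int
    train_indices: np.ndarray
    test_indices: np.ndarray
    fraction: float


# ---------------------------------------------------------------------------
# loading / writing
# ---------------------------------------------------------------------------

def _read_header_fields(path: Path, sep: str) -> list:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    return header.split() if sep is None else header.split(sep)


def load_genotype_table(
    path, dialect: str = "csv", label_col: str | None = None
) -> GenotypeMatrix:
    """Load a delimited genotype table into a :class:`GenotypeMatrix`.

    Dialects
    --------
    ``csv`` / ``tsv``
        One row per sample with columns ``sample_id``, ``breed`` (or
        *label_col*), then one column per SNP with codes in {-1, 0, 1, 2}.
    ``plink_raw``
        Whitespace-separated PLINK ``--recode A`` style table.  Leading
        metadata columns (FID/IID/PAT/MAT/SEX/PHENOTYPE) precede the SNP
        columns; ``NA`` maps to -1.  The breed label defaults to ``FID``
        and the sample id to ``IID``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect in ("csv", "tsv"):
        sep = "," if dialect == "csv" else "\t"
        fields = _read_header_fields(path, sep)
        if len(set(fields)) != len(fields):
            seen: set = set()
            dup = next(f for f in fields if f in seen or seen.add(f))
            raise GenotypeValidationError(f"duplicate SNP id {dup!r} in header")
        df = pd.read_csv(path, sep=sep)
        label_col = label_col or "breed"
        for col in ("sample_id", label_col):
            if col not in df.columns:
                raise GenotypeValidationError(f"required column {col!r} missing")
        meta = ["sample_id", label_col]
        snp_cols = [c for c in df.columns if c not in meta]
        sample_ids = df["sample_id"].astype(str).tolist()
        labels = df[label_col].astype(str).tolist()
    elif dialect == "plink_raw":
        fields = _read_header_fields(path, None)
        if len(set(fields)) != len(fields):
            seen = set()
            dup = next(f for f in fields if f in seen or seen.add(f))
            raise GenotypeValidationError(f"duplicate SNP id {dup!r} in header")
        df = pd.read_csv(path, sep=r"\s+")
        n_meta = 0
        for c in df.columns:
            if c in PLINK_META_COLS:
                n_meta += 1
            else:
                break
        if n_meta == 0:
            raise GenotypeValidationError("plink_raw table lacks metadata columns")
        label_col = label_col or "FID"
        snp_cols = list(df.columns[n_meta:])
        sample_ids = (
            df["IID"].astype(str).tolist() if "IID" in df.columns
            else [str(i) for i in range(len(df))]
        )
        labels = df[label_col].astype(str).tolist()
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    raw = df[snp_cols]
    # NA (plink) and empty cells become -1 before integer validation.
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    values = numeric.to_numpy(dtype=float)
    values = np.where(np.isnan(values), -1.0, values)
    if not np.isin(values, VALID_CODES).all():
        bad = ~np.isin(values, VALID_CODES)
        i, j = np.argwhere(bad)[0]
        raise GenotypeValidationError(
            f"invalid genotype code {raw.iloc[i, j]!r} at sample "
            f"{sample_ids[i]!r}, SNP {snp_cols[j]!r}"
        )
    G = GenotypeMatrix(values.astype(np.int8), sample_ids, snp_cols, labels)
    if G.n_missing:
        logger.info("loaded %s: %d missing genotype calls", path.name, G.n_missing)
    return G


def write_genotype_table(G: GenotypeMatrix, path, dialect: str = "csv") -> None:
    """Write *G* so that :func:`load_genotype_table` round-trips it exactly."""
    path = Path(path)
    if dialect in ("csv", "tsv"):
        sep = "," if dialect == "csv" else "\t"
        G.to_frame().to_csv(path, sep=sep, index=False)
    elif dialect == "plink_raw":
        df = pd.DataFrame(G.values, columns=G.snp_ids).astype(object)
        df = df.where(df != -1, "NA")
        df.insert(0, "PHENOTYPE", -9)
        df.insert(0, "SEX", 0)
        df.insert(0, "MAT", 0)
        df.insert(0, "PAT", 0)
        df.insert(0, "IID", G.sample_ids)
        df.insert(0, "FID", G.labels)
        df.to_csv(path, sep=" ", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_mode(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace every missing call with its SNP column's most frequent code.

    Single-imputation by column mode.  Ties between candidate modes are
    broken toward the smallest genotype code so the result is deterministic.
    Idempotent; entries other than -1 are never touched.
    """
    values = G.values.copy()
    for j in np.flatnonzero((values == -1).any(axis=0)):
        col = values[:, j]
        observed = col[col != -1]
        if observed.size == 0:
            raise GenotypeValidationError(
                f"SNP {G.snp_ids[j]!r} is entirely missing; mode undefined"
            )
        counts = np.bincount(observed, minlength=3)
        mode = int(np.argmax(counts))  # argmax takes the smallest code on ties
        col[col == -1] = mode
    return GenotypeMatrix(values, list(G.sample_ids), list(G.snp_ids), list(G.labels))


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

def _stratified_indices(
    labels: Sequence[str], fraction: float, seed: int, on_singleton: str = "error"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-breed random partition; test size per breed = round(fraction * size)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if on_singleton not in ("error", "train"):
        raise ValueError(f"on_singleton must be 'error' or 'train', got {on_singleton!r}")
    rng = np.random.default_rng(seed)
    arr = np.asarray(labels)
    test: list = []
    for breed in np.unique(arr):
        idx = np.flatnonzero(arr == breed)
        if idx.size < 2:
            if on_singleton == "error":
                raise ValueError(
                    f"breed {breed!r} has {idx.size} sample(s); need >= 2 "
                    "(or pass on_singleton='train')"
                )
            logger.warning("breed %r has a single sample; placed in train", breed)
            continue
        n_test = int(np.floor(fraction * idx.size + 0.5))
        n_test = min(n_test, idx.size - 1)
        perm = rng.permutation(idx)
        test.extend(perm[:n_test].tolist())
    test_idx = np.array(sorted(test), dtype=int)
    train_idx = np.setdiff1d(np.arange(arr.size), test_idx)
    return train_idx, test_idx


def stratified_split(
    G: GenotypeMatrix,
    test_fraction: float,
    seed: int,
    on_singleton: str = "error",
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Split samples into train/test, stratified by breed.

    Per breed, round(test_fraction * breed size) samples go to the test set
    (never the whole breed), so an 80:20 request on 10 samples of one breed
    yields exactly 8 train / 2 test.  Deterministic for a fixed seed.
    """
    train_idx, test_idx = _stratified_indices(G.labels, test_fraction, seed, on_singleton)
    return G.subset_samples(train_idx), G.subset_samples(test_idx)


def make_seeded_splits(
    G_train: GenotypeMatrix,
    r: int,
    fraction: float = 0.2,
    seed0: int = 0,
    on_singleton: str = "error",
) -> list[SplitSpec]:
    """Build *r* randomly-seeded stratified sub-splits of a training set.

    Seeds are seed0, seed0+1, ..., seed0+r-1 so an entire experiment is
    reproducible from a single integer.
    """
    if r < 1:
        raise ValueError(f"r must be >= 1, got {r}")
    specs = []
    for i in range(r):
        seed = seed0 + i
        train_idx, test_idx = _stratified_indices(
            G_train.labels, fraction, seed, on_singleton
        )
        specs.append(SplitSpec(seed, train_idx, test_idx, fraction))
    return specs
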