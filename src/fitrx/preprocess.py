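"""Standardization, sequence tensorization, SMOTE rebalancing and
leakage-safe stratified folds.

The compact representation is an N x 18 matrix (15 lap splits, pull-ups,
sit-ups, shuttle time). Augmentation operates on this compact matrix in
standardized units; tensorization to the N x 15 x 4 sequence happens last
so the replicated scalar channels stay exactly constant across time steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .cohort import N_LAPS, FitnessRecord

N_FEATURES = 18  # 15 laps + pull-ups + sit-ups + shuttle
COMPACT_COLUMNS = [f"lap_{i:02d}" for i in range(1, N_LAPS + 1)] + [
    "pull_ups",
    "sit_ups",
    "shuttle_s",
]


def read_cohort_csv_compact(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a cohort CSV directly into the compact matrix + label codes."""
    from .cohort import read_cohort_csv

    return records_to_compact(read_cohort_csv(path))


def records_to_compact(records: Sequence[FitnessRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Stack records into the compact N x 18 matrix and the label vector."""
    X = np.array(
        [list(r.lap_times) + [r.pull_ups, r.sit_ups, r.shuttle_time] for r in records],
        dtype=float,
    )
    y = np.array([int(r.category) for r in records], dtype=int)
    return X, y


@dataclass(frozen=True)
class StandardizationStats:
    mean: np.ndarray
    sd: np.ndarray


def standardize(
    X: np.ndarray, stats: StandardizationStats | None = None
) -> tuple[np.ndarray, StandardizationStats]:
    """Column-wise z-scoring.

    When `stats` is supplied (validation/test data) they are applied
    unchanged — never refit — which is what keeps fold evaluation honest.
    """
    X = np.asarray(X, dtype=float)
    if stats is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        zero = np.nonzero(sd == 0)[0]
        if zero.size:
            names = [COMPACT_COLUMNS[i] if i < len(COMPACT_COLUMNS) else str(i) for i in zero]
            raise ValueError(f"zero-variance column(s) when fitting stats: {names}")
        stats = StandardizationStats(mean=mean, sd=sd)
    return (X - stats.mean) / stats.sd, stats


@dataclass
class AugmentedSet:
    """Training matrix after rebalancing, with synthetic-row provenance."""

    X: np.ndarray
    y: np.ndarray
    synthetic: np.ndarray          # bool mask over rows of X
    parent_a: np.ndarray           # index into the input X, -1 for originals
    parent_b: np.ndarray
    interp_u: np.ndarray           # interpolation factor, NaN for originals


def smote_oversample(
    X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 42
) -> AugmentedSet:
    """SMOTE: oversample every minority class to the majority count.

    Each synthetic row is x_i + u * (x_j - x_i) with u ~ U[0,1], where x_j
    is one of x_i's k nearest same-class neighbors (Euclidean metric, ties
    by lowest index). Originals are preserved verbatim and flagged. k is
    clipped to class size - 1 (with a warning) so tiny classes still run;
    a class with fewer than 2 members is an error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k < 1:
        raise ValueError("k must be >= 1")
    classes, counts = np.unique(y, return_counts=True)
    majority = counts.max()
    rng = np.random.default_rng(seed)

    xs = [X]
    ys = [y]
    pa = [np.full(len(y), -1)]
    pb = [np.full(len(y), -1)]
    us = [np.full(len(y), np.nan)]
    for cls, cnt in zip(classes, counts):
        need = majority - cnt
        if need == 0:
            continue
        if cnt < 2:
            raise ValueError(
                f"class {cls} has {cnt} member(s); SMOTE needs >= 2 — lower k or merge classes"
            )
        idx = np.nonzero(y == cls)[0]
        k_eff = min(k, cnt - 1)
        if k_eff < k:
            warnings.warn(
                f"SMOTE k clipped from {k} to {k_eff} for class {cls} (size {cnt})",
                stacklevel=2,
            )
        nn = NearestNeighbors(n_neighbors=k_eff + 1, metric="euclidean")
        nn.fit(X[idx])
        _, neigh = nn.kneighbors(X[idx])  # first column is self (or a tie)
        # drop self-reference deterministically: remove own position, keep order
        neighbors = np.empty((cnt, k_eff), dtype=int)
        for r in range(cnt):
            row = [c for c in neigh[r] if c != r][:k_eff]
            while len(row) < k_eff:  # duplicates collapsed by exact ties
                row.append(row[-1])
            neighbors[r] = row
        src = rng.integers(0, cnt, size=need)
        pick = rng.integers(0, k_eff, size=need)
        u = rng.uniform(0.0, 1.0, size=need)
        a = idx[src]
        b = idx[neighbors[src, pick]]
        xs.append(X[a] + u[:, None] * (X[b] - X[a]))
        ys.append(np.full(need, cls, dtype=y.dtype))
        pa.append(a)
        pb.append(b)
        us.append(u)

    Xo = np.vstack(xs)
    yo = np.concatenate(ys)
    return AugmentedSet(
        X=Xo,
        y=yo,
        synthetic=np.concatenate([np.zeros(len(y), bool), np.ones(len(yo) - len(y), bool)]),
        parent_a=np.concatenate(pa),
        parent_b=np.concatenate(pb),
        interp_u=np.concatenate(us),
    )


def inject_noise(X: np.ndarray, sigma: float = 0.1, seed: int = 42) -> np.ndarray:
    """Add zero-mean Gaussian noise (SD sigma, standardized units).

    Applied on the compact 18-column representation *before* tensorization
    so the scalar-replication invariant stays exact.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    X = np.asarray(X, dtype=float)
    if sigma == 0:
        return X.copy()
    rng = np.random.default_rng(seed)
    return X + rng.normal(0.0, sigma, size=X.shape)


def tensorize(X: np.ndarray) -> np.ndarray:
    """Compact N x 18 -> sequence tensor N x 15 x 4.

    Channel 0 carries the lap series; channels 1-3 are pull-ups, sit-ups
    and shuttle time replicated across all 15 time steps.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValueError(f"expected N x {N_FEATURES} matrix, got {X.shape}")
    n = X.shape[0]
    out = np.empty((n, N_LAPS, 4), dtype=float)
    out[:, :, 0] = X[:, :N_LAPS]
    for c in range(3):
        out[:, :, c + 1] = X[:, N_LAPS + c, None]
    return out


def detensorize(T: np.ndarray) -> np.ndarray:
    """Inverse of tensorize (takes the scalar channels at t=0)."""
    T = np.asarray(T, dtype=float)
    if T.ndim != 3 or T.shape[1:] != (N_LAPS, 4):
        raise ValueError(f"expected N x {N_LAPS} x 4 tensor, got {T.shape}")
    return np.hstack([T[:, :, 0], T[:, 0, 1:]])


@dataclass
class Fold:
    """One cross-validation fold with its leakage-safe augmented training set.

    X_train is in standardized units (stats fit on this fold's original
    training rows only); validation rows are standardized with the same
    stats and are always original subjects.
    """

    train_idx: np.ndarray
    val_idx: np.ndarray
    stats: StandardizationStats
    X_train: np.ndarray
    y_train: np.ndarray
    synthetic: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray
    manifest: pd.DataFrame = field(repr=False, default=None)


@dataclass
class FoldPlan:
    folds: list[Fold]
    n_folds: int
    seed: int

    def manifest_frame(self) -> pd.DataFrame:
        return pd.concat([f.manifest for f in self.folds], ignore_index=True)

    def write_manifest_csv(self, path) -> None:
        self.manifest_frame().to_csv(path, index=False)


def make_folds(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 5,
    smote_k: int = 5,
    noise_sigma: float = 0.1,
    seed: int = 42,
    augment: bool = True,
) -> FoldPlan:
    """Stratified K-fold plan with augmentation confined to training splits.

    Per fold: standardization stats are fit on the fold's original training
    rows, SMOTE rebalances the standardized training subset to the majority
    count, Gaussian noise is added to all (original + synthetic) training
    rows, and the manifest records the provenance of every row. Validation
    sets partition the original subjects and never contain synthetic rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members; needs >= n_folds={n_folds}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = []
    for fold_no, (tr, va) in enumerate(skf.split(X, y)):
        Xtr_std, stats = standardize(X[tr])
        Xva_std, _ = standardize(X[va], stats)
        if augment:
            aug = smote_oversample(Xtr_std, y[tr], k=smote_k, seed=seed + 1000 + fold_no)
            Xa = inject_noise(aug.X, sigma=noise_sigma, seed=seed + 2000 + fold_no)
            ya, synth = aug.y, aug.synthetic
            manifest = pd.DataFrame(
                {
                    "row_id": np.arange(len(ya)),
                    "fold": fold_no,
                    "origin": np.where(synth, "synthetic", "original"),
                    "parent_a": aug.parent_a,
                    "parent_b": aug.parent_b,
                    "u": aug.interp_u,
                }
            )
        else:
            Xa, ya = Xtr_std, y[tr]
            synth = np.zeros(len(ya), bool)
            manifest = pd.DataFrame(
                {
                    "row_id": np.arange(len(ya)),
                    "fold": fold_no,
                    "origin": "original",
                    "parent_a": -1,
                    "parent_b": -1,
                    "u": np.nan,
                }
            )
        folds.append(
            Fold(
                train_idx=tr,
                val_idx=va,
                stats=stats,
                X_train=Xa,
                y_train=ya,
                synthetic=synth,
                X_val=Xva_std,
                y_val=y[va],
                manifest=manifest,
            )
        )
    return FoldPlan(folds=folds, n_folds=n_folds, seed=seed)
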