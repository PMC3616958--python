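"""Random-forest regression of pathway scores on tag-locus copy numbers.

Each pathway's per-sample score vector is fit as a non-linear function of the
log2 copy-number alterations of the tag-loci.  A forest of regression trees
is grown, each tree on a small subsample drawn without replacement; every
split picks the best of M randomly chosen predictors.  A locus's importance
in a tree is the increase of the tree's held-out prediction error when the
locus column is permuted among the held-out samples.  Per locus, the mean
importance over trees is normalized by its standard error.

All per-column randomness (predictor subsets at splits, held-out column
permutations) is keyed by a hash of the locus id, so reordering predictor
columns permutes the output records identically.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from pwcnaqtl.io_model import CopyNumberMatrix, ValidationError
from pwcnaqtl.tagloci import TagLocusSet

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_PERM_SALT = np.uint64(0xD1B54A32D192ED03)


def _splitmix64(x):
    """Vectorized splitmix64 finalizer on uint64 (wraparound intended)."""
    with np.errstate(over="ignore"):
        z = np.asarray(x, dtype=np.uint64) + _GOLDEN
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        return z ^ (z >> np.uint64(31))


_MASK64 = (1 << 64) - 1


def _splitmix64_int(x: int) -> int:
    """Scalar splitmix64 on Python ints (cheaper than numpy scalars)."""
    z = (x + 0x9E3779B97F4A7C15) & _MASK64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return z ^ (z >> 31)


def _column_keys(locus_ids) -> np.ndarray:
    keys = np.empty(len(locus_ids), dtype=np.uint64)
    for i, lid in enumerate(locus_ids):
        digest = hashlib.blake2b(str(lid).encode(), digest_size=8).digest()
        keys[i] = int.from_bytes(digest, "little")
    return keys


@dataclass(frozen=True)
class ForestParams:
    """Forest hyperparameters.

    ``mtry`` (predictors tried per split) defaults to ceil(sqrt(#tag-loci));
    ``samples_per_tree`` defaults to ceil(sqrt(#samples)), drawn WITHOUT
    replacement, so most samples of each tree are held out for the
    permutation-importance estimate.
    """

    n_trees: int = 1000
    mtry: int | None = None
    samples_per_tree: int | None = None
    min_node_size: int = 5
    seed: int = 0

    def resolve(self, n_features: int, n_samples: int) -> tuple[int, int, int]:
        if self.n_trees < 2:
            raise ValidationError(
                "n_trees must be >= 2 (standard error over trees undefined for N=1)"
            )
        m = self.mtry if self.mtry is not None else math.ceil(math.sqrt(n_features))
        if not 1 <= m <= n_features:
            raise ValidationError(f"mtry must be in [1, {n_features}], got {m}")
        k = (
            self.samples_per_tree
            if self.samples_per_tree is not None
            else math.ceil(math.sqrt(n_samples))
        )
        if not 2 <= k <= n_samples:
            raise ValidationError(f"samples_per_tree must be in [2, {n_samples}], got {k}")
        if n_samples - k < 2:
            raise ValidationError(
                "fewer than 2 held-out samples per tree; use more samples or a "
                "smaller samples_per_tree"
            )
        if self.min_node_size < 1:
            raise ValidationError("min_node_size must be >= 1")
        return self.n_trees, m, k

    def with_seed(self, seed: int) -> "ForestParams":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class ImportanceRecord:
    locus: str
    pathway: str
    importance: float  # mean held-out permutation importance over trees
    sigma: float  # standard error of the importance over trees
    ibar: float  # normalized importance: importance / sigma


class _Tree:
    """CART regression tree stored as flat arrays; -1 feature marks a leaf."""

    __slots__ = ("feature", "thresh", "left", "right", "value")

    def __init__(self) -> None:
        self.feature: list[int] = []
        self.thresh: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.value: list[float] = []

    def _new_node(self) -> int:
        self.feature.append(-1)
        self.thresh.append(0.0)
        self.left.append(-1)
        self.right.append(-1)
        self.value.append(0.0)
        return len(self.feature) - 1

    def used_features(self) -> list[int]:
        return sorted({f for f in self.feature if f >= 0})


def _build_tree(
    X: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    min_leaf: int,
    mtry: int,
    col_keys: np.ndarray,
    tree_key: np.uint64,
) -> _Tree:
    tree = _Tree()
    n_features = X.shape[1]

    def grow(sample_idx: np.ndarray) -> int:
        nid = tree._new_node()
        ys = y[sample_idx]
        tree.value[nid] = float(ys.mean())
        n = len(sample_idx)
        if n < 2 * min_leaf or np.ptp(ys) == 0.0:
            return nid
        node_key = _splitmix64_int((int(tree_key) + (nid + 1) * 0x9E3779B97F4A7C15) & _MASK64)
        prio = _splitmix64(col_keys ^ np.uint64(node_key))
        if mtry < n_features:
            feats = np.argpartition(prio, mtry - 1)[:mtry]
        else:
            feats = np.arange(n_features)
        Xn = X[sample_idx][:, feats]
        order = np.argsort(Xn, axis=0, kind="stable")
        Xs = np.take_along_axis(Xn, order, axis=0)
        Ys = ys[order]
        c1 = np.cumsum(Ys, axis=0)
        c2 = np.cumsum(Ys * Ys, axis=0)
        t1, t2 = c1[-1], c2[-1]
        s = np.arange(min_leaf, n - min_leaf + 1)  # left-child sizes
        if len(s) == 0:
            return nid
        sizes = s[:, None].astype(float)
        left_sse = c2[s - 1] - c1[s - 1] ** 2 / sizes
        right_sse = (t2 - c2[s - 1]) - (t1 - c1[s - 1]) ** 2 / (n - sizes)
        cost = left_sse + right_sse
        valid = Xs[s] > Xs[s - 1]  # split only between distinct values
        cost = np.where(valid, cost, np.inf)
        best = cost.min()
        if not np.isfinite(best):
            return nid
        ties = np.argwhere(cost == best)
        # deterministic, column-order-invariant tie-break: feature priority, then split
        si, fi = min(ties, key=lambda t: (int(prio[feats[t[1]]]), int(t[0])))
        f_local = int(fi)
        split = int(s[si])
        feature = int(feats[f_local])
        thr = float(0.5 * (Xs[split - 1, f_local] + Xs[split, f_local]))
        go_left = X[sample_idx, feature] <= thr
        left_id = grow(sample_idx[go_left])
        right_id = grow(sample_idx[~go_left])
        tree.feature[nid] = feature
        tree.thresh[nid] = thr
        tree.left[nid] = left_id
        tree.right[nid] = right_id
        return nid

    grow(np.sort(idx))
    return tree


def _predict(
    tree: _Tree,
    X: np.ndarray,
    override_feature: int = -1,
    override_column: np.ndarray | None = None,
) -> np.ndarray:
    """Predict for all rows; optionally substitute one feature's column."""
    out = np.empty(X.shape[0])
    stack = [(0, np.arange(X.shape[0]))]
    while stack:
        nid, rows = stack.pop()
        f = tree.feature[nid]
        if f < 0:
            out[rows] = tree.value[nid]
            continue
        col = override_column[rows] if f == override_feature else X[rows, f]
        go_left = col <= tree.thresh[nid]
        stack.append((tree.left[nid], rows[go_left]))
        stack.append((tree.right[nid], rows[~go_left]))
    return out


def build_design(
    CN: CopyNumberMatrix, tags: TagLocusSet, sample_ids: list[str] | None = None
) -> pd.DataFrame:
    """Sample x tag-locus design matrix of log2 copy-number alterations.

    Columns are the representative loci in the tag set's (genomic) order.
    ``sample_ids`` fixes the row order (e.g. the pathway-score columns);
    a sample-set mismatch is an error.
    """
    missing = [r for r in tags.rep_ids if r not in CN.values.index]
    if missing:
        raise ValidationError(f"representative loci absent from copy-number matrix: {missing[:10]}")
    if sample_ids is None:
        sample_ids = CN.sample_ids
    else:
        diff = set(sample_ids) ^ set(CN.sample_ids)
        if diff:
            raise ValidationError(
                f"sample sets of copy-number matrix and scores differ: {sorted(diff)[:10]}"
            )
    lg2 = CN.lg2()
    design = lg2.loc[tags.rep_ids, sample_ids].T
    design.index.name = "sample"
    return design


def fit_importance(
    A_p: pd.Series | np.ndarray,
    X: pd.DataFrame,
    params: ForestParams,
    pathway: str = "",
) -> list[ImportanceRecord]:
    """Held-out permutation importance of every design column for one pathway.

    Grows ``params.n_trees`` regression trees, each on a without-replacement
    subsample; per tree, each used locus is permuted among the held-out
    samples (permutation keyed by locus id and tree) and the increase in
    held-out mean squared error is that locus's contribution.  Loci unused by
    a tree contribute exactly zero for that tree.
    """
    y = np.asarray(A_p, dtype=float)
    Xv = X.to_numpy(dtype=float)
    n_samples, n_features = Xv.shape
    if len(y) != n_samples:
        raise ValidationError("score vector and design matrix are not sample-aligned")
    if n_samples < 10:
        raise ValidationError("fit_importance needs >= 10 samples")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(Xv)):
        raise ValidationError("non-finite values in scores or design")
    n_trees, mtry, k = params.resolve(n_features, n_samples)
    col_keys = _column_keys(X.columns)
    rng = np.random.default_rng(params.seed)
    tree_keys = rng.integers(0, 2**63, size=n_trees, dtype=np.int64).astype(np.uint64)
    subsamples = rng.permuted(
        np.tile(np.arange(n_samples), (n_trees, 1)), axis=1
    )[:, :k]
    contrib = np.zeros((n_trees, n_features))
    all_idx = np.arange(n_samples)
    in_mask = np.zeros(n_samples, dtype=bool)
    for t in range(n_trees):
        in_idx = subsamples[t]
        in_mask[:] = False
        in_mask[in_idx] = True
        held = all_idx[~in_mask]
        tree = _build_tree(
            Xv, y, in_idx, params.min_node_size, mtry, col_keys, tree_keys[t]
        )
        Xh = Xv[held]
        yh = y[held]
        base_err = float(np.mean((yh - _predict(tree, Xh)) ** 2))
        held_u64 = held.astype(np.uint64)
        for f in tree.used_features():
            pk = np.uint64(
                _splitmix64_int(int(col_keys[f]) ^ int(tree_keys[t]) ^ int(_PERM_SALT))
            )
            keys = _splitmix64(held_u64 ^ pk)
            permuted = Xh[np.argsort(keys, kind="stable"), f]
            pred = _predict(tree, Xh, override_feature=f, override_column=permuted)
            contrib[t, f] = float(np.mean((yh - pred) ** 2)) - base_err
    imp = contrib.mean(axis=0)
    se = contrib.std(axis=0, ddof=1) / math.sqrt(n_trees)
    bad = (se == 0) & (imp != 0)
    if bad.any():
        raise ValidationError(
            f"zero standard error with nonzero importance for: {list(X.columns[bad])[:5]}"
        )
    with np.errstate(invalid="ignore"):
        ibar = np.where(se > 0, imp / np.where(se > 0, se, 1.0), 0.0)
    return [
        ImportanceRecord(
            locus=str(col),
            pathway=pathway,
            importance=float(imp[j]),
            sigma=float(se[j]),
            ibar=float(ibar[j]),
        )
        for j, col in enumerate(X.columns)
    ]


def importance_frame(records: list[ImportanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus": [r.locus for r in records],
            "pathway": [r.pathway for r in records],
            "importance": [r.importance for r in records],
            "sigma": [r.sigma for r in records],
            "ibar": [r.ibar for r in records],
        }
    )
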