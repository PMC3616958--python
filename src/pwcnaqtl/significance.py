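"""Permutation null distributions, Z-test p-values and BH FDR control.

The null is built by permuting the per-sample pathway scores and,
independently, the sample rows of the design matrix (jointly across columns,
preserving inter-locus correlation), then re-running the forest importance
fit.  Normalized importances from the permuted fits form the null; observed
values are converted to one-sided upper-tail p-values by a Z-test against the
null mean and standard deviation, and corrected by Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pwcnaqtl.association import ForestParams, fit_importance
from pwcnaqtl.io_model import ValidationError

MIN_PERM_POOLED = 20
MIN_PERM_PER_LOCUS = 100

_P_FLOOR = float(np.nextafter(0.0, 1.0))


@dataclass
class NullModel:
    pathway: str
    pooling: str  # "pooled" or "per_locus"
    samples: np.ndarray | dict[str, np.ndarray]
    mu0: float | dict[str, float]
    s0: float | dict[str, float]
    n_permutations: int


def permutation_null(
    A_p: pd.Series | np.ndarray,
    X: pd.DataFrame,
    params: ForestParams,
    n_perm: int = 100,
    seed: int = 0,
    pooling: Literal["pooled", "per_locus"] = "pooled",
    pathway: str = "",
) -> NullModel:
    """Null distribution of normalized importance under joint randomization.

    Per permutation, the score vector's sample order and the design matrix's
    sample rows are permuted independently and ``fit_importance`` is rerun
    with a permutation-specific derived seed.  With ``pooling="pooled"`` all
    resulting normalized importances form one null; ``per_locus`` keeps one
    null per design column.
    """
    minimum = MIN_PERM_POOLED if pooling == "pooled" else MIN_PERM_PER_LOCUS
    if n_perm < minimum:
        raise ValidationError(
            f"n_perm={n_perm} below the enforced minimum {minimum} for {pooling} pooling"
        )
    y = np.asarray(A_p, dtype=float)
    n = len(y)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_perm)
    per_perm: list[np.ndarray] = []
    for child in children:
        rng = np.random.default_rng(child)
        yp = y[rng.permutation(n)]
        Xp = pd.DataFrame(
            X.to_numpy()[rng.permutation(n), :], columns=X.columns
        )
        derived_seed = int(child.generate_state(1, dtype=np.uint64)[0] % (2**63))
        records = fit_importance(yp, Xp, params.with_seed(derived_seed), pathway=pathway)
        per_perm.append(np.array([r.ibar for r in records]))
    stacked = np.vstack(per_perm)  # (n_perm, n_loci)
    if pooling == "pooled":
        flat = stacked.ravel()
        s0 = float(flat.std(ddof=1))
        if s0 == 0:
            raise ValidationError("null variance zero")
        return NullModel(pathway, "pooled", flat, float(flat.mean()), s0, n_perm)
    mus, sds, samp = {}, {}, {}
    for j, col in enumerate(X.columns):
        v = stacked[:, j]
        sd = float(v.std(ddof=1))
        if sd == 0:
            raise ValidationError(f"null variance zero for locus {col!r}")
        mus[str(col)] = float(v.mean())
        sds[str(col)] = sd
        samp[str(col)] = v
    return NullModel(pathway, "per_locus", samp, mus, sds, n_perm)


def z_pvalue(ibar: float, null: NullModel, locus: str | None = None) -> float:
    """One-sided upper-tail Z-test p-value of an observed normalized importance."""
    if not np.isfinite(ibar):
        raise ValidationError("non-finite normalized importance")
    if null.pooling == "pooled":
        mu0, s0 = null.mu0, null.s0
    else:
        if locus is None:
            raise ValidationError("per-locus null requires a locus id")
        mu0, s0 = null.mu0[locus], null.s0[locus]
    p = float(stats.norm.sf((ibar - mu0) / s0))
    return max(p, _P_FLOOR)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def association_table(
    importance: pd.DataFrame,
    nulls: dict[str, NullModel],
    alpha: float = 0.05,
    fdr_groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Attach p-values, q-values and significance flags to importance records.

    ``importance`` is the long-format frame (locus, pathway, importance,
    sigma, ibar); ``nulls`` maps pathway name to its NullModel.  When
    ``fdr_groups`` is given (aligned with ``importance`` rows), BH runs
    within each group (e.g. over-/under-expressed directions) separately.
    """
    df = importance.copy()
    pvals = np.empty(len(df))
    for i, row in enumerate(df.itertuples(index=False)):
        null = nulls[row.pathway]
        pvals[i] = z_pvalue(row.ibar, null, locus=row.locus)
    df["p"] = pvals
    q = np.empty(len(df))
    if fdr_groups is None:
        q[:] = bh_fdr(pvals)
    else:
        groups = np.asarray(fdr_groups)
        for g in pd.unique(groups):
            mask = groups == g
            q[mask] = bh_fdr(pvals[mask])
    df["q"] = q
    df["significant"] = df["q"] < alpha
    return df
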