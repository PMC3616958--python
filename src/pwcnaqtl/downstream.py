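"""Post-association summaries.

Alteration-frequency profiles over tag-loci, per-locus counts of
significantly associated pathways, chromosome-by-chromosome pathway-sharing
matrices, Fisher over-representation of driver genes in pathways, and a
per-gene differential-expression table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from pwcnaqtl.io_model import (
    CopyNumberMatrix,
    ExpressionMatrix,
    PathwayCollection,
    ValidationError,
)
from pwcnaqtl.significance import bh_fdr
from pwcnaqtl.tagloci import TagLocusSet

logger = logging.getLogger(__name__)


def alteration_frequency(
    CN: CopyNumberMatrix, tags: TagLocusSet, threshold: float = 1.5
) -> pd.Series:
    """Per tag-locus, the fraction of samples with |log2 CNA| strictly above
    ``threshold`` at the representative locus."""
    lg2 = CN.lg2()
    missing = [r for r in tags.rep_ids if r not in lg2.index]
    if missing:
        raise ValidationError(f"representatives absent from copy-number matrix: {missing[:10]}")
    sub = lg2.loc[tags.rep_ids]
    freq = (sub.abs() > threshold).mean(axis=1)
    freq.index.name = "tag_locus"
    freq.name = "alteration_frequency"
    return freq


def pathway_counts(assoc: pd.DataFrame, tags: TagLocusSet | None = None) -> pd.Series:
    """Distinct significantly associated pathways per tag-locus.

    Loci with no significant pathway are reported as 0; when ``tags`` is
    given, every tag-locus appears in the output.
    """
    if "significant" not in assoc.columns:
        raise ValidationError("association table lacks significance flags")
    sig = assoc[assoc["significant"]]
    counts = sig.groupby("locus")["pathway"].nunique()
    if tags is not None:
        counts = counts.reindex(tags.rep_ids, fill_value=0)
    else:
        counts = counts.reindex(pd.unique(assoc["locus"]), fill_value=0)
    counts.index.name = "tag_locus"
    counts.name = "n_pathways"
    return counts.astype(int)


@dataclass
class SharingMatrix:
    """Symmetric chromosome x chromosome counts of shared pathways."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts.to_numpy()
        if not np.array_equal(c, c.T):
            raise ValidationError("sharing matrix must be symmetric")
        diag = np.diag(c)
        if np.any(c > np.minimum.outer(diag, diag)):
            raise ValidationError("off-diagonal sharing exceeds a diagonal entry")


def chromosome_sharing(
    assoc: pd.DataFrame,
    tags: TagLocusSet,
    direction: Literal["over", "under"] | None = None,
) -> SharingMatrix:
    """counts[c1][c2] = number of distinct pathways significantly associated
    with at least one tag-locus on c1 AND at least one on c2.

    ``direction`` restricts to pathways of that expression direction (the
    association table must carry a ``direction`` column in that case).
    """
    sig = assoc[assoc["significant"]]
    if direction is not None:
        if "direction" not in sig.columns:
            raise ValidationError("association table lacks a direction column")
        sig = sig[sig["direction"] == direction]
    chrom_by_rep = {t.rep: t.chrom for t in tags}
    unresolved = sorted(set(sig["locus"]) - set(chrom_by_rep))
    if unresolved:
        raise ValidationError(f"loci not resolvable to a chromosome: {unresolved[:10]}")
    chroms = sorted({t.chrom for t in tags})
    on_chrom: dict[str, set[str]] = {c: set() for c in chroms}
    for row in sig.itertuples(index=False):
        on_chrom[chrom_by_rep[row.locus]].add(row.pathway)
    mat = pd.DataFrame(0, index=chroms, columns=chroms, dtype=int)
    for c1 in chroms:
        for c2 in chroms:
            mat.loc[c1, c2] = len(on_chrom[c1] & on_chrom[c2])
    return SharingMatrix(mat)


def fisher_over_representation(
    overlap: int, set_size: int, draw_size: int, universe: int
) -> float:
    """One-sided over-representation p: P[X >= overlap] for
    X ~ Hypergeom(universe, set_size, draw_size)."""
    if not (0 <= overlap <= min(set_size, draw_size)):
        raise ValidationError("impossible 2x2 table")
    return float(stats.hypergeom.sf(overlap - 1, universe, set_size, draw_size))


@dataclass(frozen=True)
class EnrichmentRecord:
    pathway: str
    overlap: int
    pathway_size: int
    driver_count: int
    universe_size: int
    p: float


def driver_enrichment(
    pathways: PathwayCollection,
    drivers: Iterable[str],
    universe: Iterable[str],
) -> list[EnrichmentRecord]:
    """Fisher one-sided over-representation of driver genes in each pathway.

    Pathway memberships and the driver list are intersected with the
    universe; pathways empty after intersection are skipped with a warning.
    Records are sorted by p ascending, ties by pathway name.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty gene universe")
    drv = set(drivers) & uni
    if set(drivers) - uni:
        logger.warning(
            "%d driver gene(s) outside the universe ignored", len(set(drivers) - uni)
        )
    records: list[EnrichmentRecord] = []
    for p in pathways:
        members = set(p.genes) & uni
        if not members:
            logger.warning("pathway %s empty after universe intersection; skipped", p.name)
            continue
        overlap = len(members & drv)
        pval = fisher_over_representation(overlap, len(members), len(drv), len(uni))
        records.append(
            EnrichmentRecord(p.name, overlap, len(members), len(drv), len(uni), pval)
        )
    records.sort(key=lambda r: (r.p, r.pathway))
    return records


def differential_expression(
    E: ExpressionMatrix, equal_var: bool = False
) -> pd.DataFrame:
    """Per-gene two-sided t-test (Welch by default) with BH q-values.

    Genes with zero variance in both classes and equal means get t = 0,
    p = 1 and are flagged in the ``degenerate`` column.
    """
    dis, ctl = E.disease_samples, E.control_samples
    if len(dis) < 2 or len(ctl) < 2:
        raise ValidationError("each class needs >= 2 samples for the t-test")
    Xd = E.values[dis].to_numpy()
    Xc = E.values[ctl].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(Xd, Xc, axis=1, equal_var=equal_var)
    degenerate = ~np.isfinite(t)
    same_mean = np.isclose(Xd.mean(axis=1), Xc.mean(axis=1))
    t = np.where(degenerate & same_mean, 0.0, t)
    p = np.where(degenerate & same_mean, 1.0, p)
    if np.any(degenerate & ~same_mean):
        # zero variance but distinct means: infinitely strong evidence
        diff_sign = np.sign(Xd.mean(axis=1) - Xc.mean(axis=1))
        t = np.where(degenerate & ~same_mean, diff_sign * np.inf, t)
        p = np.where(degenerate & ~same_mean, np.nextafter(0.0, 1.0), p)
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    out = pd.DataFrame(
        {"t": t, "p": p, "q": bh_fdr(p), "degenerate": degenerate},
        index=pd.Index(E.gene_ids, name="gene"),
    )
    return out
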