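"""Gene ranking, enrichment scores and leading-edge extraction.

Genes are ranked by a signal-to-noise metric between disease and control
samples; each pathway gets a weighted Kolmogorov-Smirnov-style running-sum
enrichment score (ES).  Pathways are classified by ES sign alone, and the
leading edge is the set of pathway members at or before the running-sum
extremum (at or after it for negative ES — the mirrored convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from pwcnaqtl.io_model import ExpressionMatrix, PathwayCollection, ValidationError

logger = logging.getLogger(__name__)

OVER = "over"
UNDER = "under"


@dataclass
class RankedGeneList:
    """Genes ordered most-disease-up first, with the ranking metric values."""

    genes: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.metric):
            raise ValidationError("genes and metric length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("ranked gene list has duplicate genes")
        if np.any(np.diff(self.metric) > 0):
            raise ValidationError("metric must be non-increasing along the ranking")

    def __len__(self) -> int:
        return len(self.genes)

    def rank_of(self, gene: str) -> int:
        return self.genes.index(gene)


@dataclass
class ESResult:
    pathway: str
    es: float
    running: np.ndarray
    argmax_rank: int  # 0-based rank of running-sum maximum (earliest tie)
    argmin_rank: int  # 0-based rank of running-sum minimum (earliest tie)
    hit_ranks: np.ndarray  # sorted 0-based ranks of set members


@dataclass
class LeadingEdgeSet:
    pathway: str
    sign: str  # "over" (ES > 0) or "under" (ES < 0)
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.sign not in (OVER, UNDER):
            raise ValidationError(f"invalid sign {self.sign!r}")
        if not self.genes:
            raise ValidationError(f"empty leading edge for {self.pathway!r}")


def rank_genes(E: ExpressionMatrix, sigma_floor: float = 0.2) -> RankedGeneList:
    """Rank genes by descending signal-to-noise ratio.

    metric = (mu_disease - mu_control) / (sigma_disease + sigma_control),
    with each class standard deviation floored at ``sigma_floor * |mu|`` of
    that class.  Ties are broken by lexicographic gene id.
    """
    dis, ctl = E.disease_samples, E.control_samples
    if len(dis) < 2 or len(ctl) < 2:
        raise ValidationError("each class needs >= 2 samples for ranking")
    Xd = E.values[dis].to_numpy()
    Xc = E.values[ctl].to_numpy()
    mu_d, mu_c = Xd.mean(axis=1), Xc.mean(axis=1)
    sd_d = np.maximum(Xd.std(axis=1, ddof=1), sigma_floor * np.abs(mu_d))
    sd_c = np.maximum(Xc.std(axis=1, ddof=1), sigma_floor * np.abs(mu_c))
    denom = sd_d + sd_c
    if (denom == 0).any():
        bad = [g for g, d in zip(E.gene_ids, denom) if d == 0]
        raise ValidationError(f"zero signal-to-noise denominator for genes: {bad[:10]}")
    metric = (mu_d - mu_c) / denom
    order = sorted(range(len(metric)), key=lambda i: (-metric[i], E.gene_ids[i]))
    return RankedGeneList(
        [E.gene_ids[i] for i in order], np.asarray([metric[i] for i in order])
    )


def enrichment_score(
    ranked: RankedGeneList, gene_set, weight_exponent: float = 1.0, pathway: str = ""
) -> ESResult:
    """Weighted running-sum enrichment score of a gene set on a ranked list.

    Hits increment the running sum by |metric|^weight_exponent normalized by
    the total over hits; misses decrement by 1/(N - N_H).  ES is the
    running-sum value of maximal absolute deviation from zero, ties resolved
    toward the earliest rank.
    """
    members = set(gene_set)
    N = len(ranked)
    is_hit = np.fromiter((g in members for g in ranked.genes), bool, count=N)
    n_hit = int(is_hit.sum())
    if n_hit == 0:
        raise ValidationError(f"empty intersection between ranked list and set {pathway!r}")
    if n_hit == N:
        raise ValidationError(
            f"gene set {pathway!r} covers the entire ranked list (miss denominator zero)"
        )
    weights = np.abs(ranked.metric) ** weight_exponent
    hit_total = weights[is_hit].sum()
    if hit_total == 0:
        # all hit metrics are exactly zero: fall back to equal hit weights
        step_hit = np.where(is_hit, 1.0 / n_hit, 0.0)
    else:
        step_hit = np.where(is_hit, weights / hit_total, 0.0)
    step = np.where(is_hit, step_hit, -1.0 / (N - n_hit))
    running = np.cumsum(step)
    argmax = int(np.argmax(running))
    argmin = int(np.argmin(running))
    # extremum of |running|, earliest rank on ties
    es = running[argmax] if abs(running[argmax]) >= abs(running[argmin]) else running[argmin]
    if abs(running[argmax]) == abs(running[argmin]):
        es = running[min(argmax, argmin)]
    return ESResult(
        pathway=pathway,
        es=float(es),
        running=running,
        argmax_rank=argmax,
        argmin_rank=argmin,
        hit_ranks=np.flatnonzero(is_hit),
    )


def leading_edge(es: ESResult, ranked: RankedGeneList) -> LeadingEdgeSet:
    """Extract the leading-edge genes of an enrichment result.

    Positive ES: set members at ranks <= the running-sum argmax (inclusive).
    Negative ES: set members at ranks >= the running-sum argmin (inclusive).
    """
    if es.es == 0:
        raise ValidationError(f"degenerate enrichment (ES = 0) for {es.pathway!r}")
    if es.es > 0:
        ranks = es.hit_ranks[es.hit_ranks <= es.argmax_rank]
        sign = OVER
    else:
        ranks = es.hit_ranks[es.hit_ranks >= es.argmin_rank]
        sign = UNDER
    genes = tuple(ranked.genes[r] for r in ranks)
    return LeadingEdgeSet(pathway=es.pathway, sign=sign, genes=genes)


def gsea_all(
    E: ExpressionMatrix,
    pathways: PathwayCollection,
    weight_exponent: float = 1.0,
    sigma_floor: float = 0.2,
) -> tuple[RankedGeneList, list[ESResult], list[LeadingEdgeSet]]:
    """Rank genes once and score every pathway; skip degenerate pathways.

    Pathways with no gene in the ranked list or with ES exactly zero are
    skipped with a warning.
    """
    ranked = rank_genes(E, sigma_floor=sigma_floor)
    present = set(ranked.genes)
    results: list[ESResult] = []
    edges: list[LeadingEdgeSet] = []
    for p in pathways:
        members = [g for g in p.genes if g in present]
        if not members:
            logger.warning("pathway %s: no member genes in expression matrix; skipped", p.name)
            continue
        if len(members) == len(ranked):
            logger.warning("pathway %s: covers the whole ranked list; skipped", p.name)
            continue
        res = enrichment_score(ranked, members, weight_exponent, pathway=p.name)
        if res.es == 0:
            logger.warning("pathway %s: ES exactly zero; skipped", p.name)
            continue
        results.append(res)
        edges.append(leading_edge(res, ranked))
    return ranked, results, edges
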