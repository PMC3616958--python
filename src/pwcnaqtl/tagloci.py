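"""Tag-locus detection and gene assignment.

Copy numbers of nearby loci are highly correlated, so each chromosome is
reduced to representative "tag" loci by a greedy left-to-right scan: a region
starts at the first unassigned locus (its representative) and extends while
the Pearson correlation criterion holds strictly.  Correlations are computed
on log2 copy-number ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from pwcnaqtl.io_model import CopyNumberMatrix, GeneAnnotation, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class TagLocus:
    rep: str  # representative locus id (first member)
    members: list[str]
    chrom: str
    span: tuple[int, int]  # (min pos, max pos + 1), half-open
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members or self.members[0] != self.rep:
            raise ValidationError("representative must be the first member")
        if self.span[0] >= self.span[1]:
            raise ValidationError("empty tag-locus span")


@dataclass
class TagLocusSet:
    tags: list[TagLocus]

    def __post_init__(self) -> None:
        reps = [t.rep for t in self.tags]
        if len(set(reps)) != len(reps):
            raise ValidationError("duplicate representative loci")
        self._by_rep = {t.rep: t for t in self.tags}

    def __len__(self) -> int:
        return len(self.tags)

    def __iter__(self):
        return iter(self.tags)

    def __getitem__(self, rep: str) -> TagLocus:
        return self._by_rep[rep]

    @property
    def rep_ids(self) -> list[str]:
        return [t.rep for t in self.tags]

    def chromosome_of(self, rep: str) -> str:
        return self._by_rep[rep].chrom


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; NaN when either vector is constant."""
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return float("nan")
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def detect_tag_loci(
    CN: CopyNumberMatrix,
    r_threshold: float = 0.95,
    mode: Literal["seed", "chain"] = "seed",
) -> TagLocusSet:
    """Greedy reduction of loci to tag-locus regions.

    mode="seed" (default): a candidate joins the region when its correlation
    with the region's seed locus exceeds ``r_threshold`` (strictly).
    mode="chain": the candidate is compared with the previous locus instead.
    Regions never cross chromosome boundaries; constant locus vectors become
    singleton regions with a warning.  The scan partitions the loci.
    """
    if CN.values.shape[1] < 2:
        raise ValidationError("tag-locus detection needs >= 2 samples")
    if mode not in ("seed", "chain"):
        raise ValueError(f"unknown mode {mode!r}")
    lg2 = CN.lg2().to_numpy()
    locus_ids = CN.locus_ids
    chroms = CN.coords["chrom"].astype(str).to_numpy()
    pos = CN.coords["pos"].to_numpy()
    tags: list[TagLocus] = []
    n_constant = 0
    i, m = 0, len(locus_ids)
    while i < m:
        seed_vec = lg2[i]
        members = [i]
        if np.std(seed_vec) == 0.0:
            n_constant += 1
        else:
            j = i + 1
            prev_vec = seed_vec
            while j < m and chroms[j] == chroms[i]:
                cand = lg2[j]
                ref = seed_vec if mode == "seed" else prev_vec
                r = _pearson(ref, cand)
                if np.isnan(r):
                    n_constant += 1
                    break
                if not (r > r_threshold):
                    break
                members.append(j)
                prev_vec = cand
                j += 1
        lo = int(min(pos[k] for k in members))
        hi = int(max(pos[k] for k in members)) + 1
        tags.append(
            TagLocus(
                rep=locus_ids[i],
                members=[locus_ids[k] for k in members],
                chrom=str(chroms[i]),
                span=(lo, hi),
            )
        )
        i = members[-1] + 1
    if n_constant:
        logger.warning(
            "%d constant locus vector(s): correlation undefined, singleton regions", n_constant
        )
    return TagLocusSet(tags)


def assign_genes(
    tags: TagLocusSet, annotation: GeneAnnotation, flank: int = 0
) -> TagLocusSet:
    """Assign genes to tag-loci by half-open interval overlap with the span.

    The span may be extended by ``flank`` bp on each side.  A gene may be
    assigned to multiple regions.  Annotation chromosomes absent from the
    locus set are an error.
    """
    locus_chroms = {t.chrom for t in tags}
    unmatched = sorted(annotation.chromosomes - locus_chroms)
    if unmatched:
        raise ValidationError(
            f"annotation chromosomes not present among loci: {unmatched}"
        )
    rec = annotation.records
    out: list[TagLocus] = []
    for t in tags:
        lo = t.span[0] - flank
        hi = t.span[1] + flank
        sel = rec[
            (rec["chrom"].astype(str) == t.chrom)
            & (rec["start"] < hi)
            & (rec["end"] > lo)
        ]
        out.append(
            TagLocus(
                rep=t.rep,
                members=list(t.members),
                chrom=t.chrom,
                span=t.span,
                genes=list(sel["gene"]),
            )
        )
    return TagLocusSet(out)
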