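"""Synthetic expression + copy-number cohorts with recorded ground truth.

Copy-number loci come in consecutive blocks sharing a single latent factor,
with loadings solved in closed form from the target within-block correlation.
Chromosome-scale signature events (amplifications/deletions in a fraction of
samples) can be overlaid.  Planted locus-to-pathway effects couple the
expression of a pathway's genes to the log2 copy-number alteration of the
block's first locus (the representative consumed downstream).

One global seed drives a splittable per-component stream, so adding
components does not perturb earlier draws.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pwcnaqtl.io_model import (
    CONTROL,
    DISEASE,
    CopyNumberMatrix,
    ExpressionMatrix,
    GeneAnnotation,
    Pathway,
    PathwayCollection,
    ValidationError,
)

_LOCUS_SPACING = 100_000
_GENE_LENGTH = 20_000


@dataclass(frozen=True)
class PlantedEffect:
    block: int  # global block index (in genomic order)
    pathway: int  # pathway index
    beta: float  # change in a pathway gene's expression per unit lg2 CNA


@dataclass(frozen=True)
class SignatureEvent:
    chromosome: int  # 0-based chromosome index
    sign: int  # +1 amplification, -1 deletion
    fraction: float  # fraction of disease samples altered
    magnitude: float  # shift in lg2 units


@dataclass
class SyntheticConfig:
    n_disease: int = 60
    n_control: int = 15
    n_chromosomes: int = 4
    loci_per_chromosome: int = 20
    block_size: int = 4
    within_block_r: float = 0.99
    n_pathways: int = 10
    genes_per_pathway: int = 10
    n_background_genes: int = 100
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    expression_noise_sd: float = 0.3
    cn_noise_sd: float = 0.5  # sd of each locus's lg2 copy-number signal
    baseline_range: tuple[float, float] = (5.0, 9.0)
    signature_events: list[SignatureEvent] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_disease",
            "n_control",
            "n_chromosomes",
            "loci_per_chromosome",
            "block_size",
            "n_pathways",
            "genes_per_pathway",
            "n_background_genes",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 < self.within_block_r < 1:
            raise ValidationError("within_block_r must lie strictly in (0, 1)")
        self.planted_effects = [
            PlantedEffect(**e) if isinstance(e, dict) else e for e in self.planted_effects
        ]
        self.signature_events = [
            SignatureEvent(**e) if isinstance(e, dict) else e for e in self.signature_events
        ]
        n_blocks = self.n_chromosomes * self._blocks_per_chromosome()
        for e in self.planted_effects:
            if not 0 <= e.block < n_blocks:
                raise ValidationError(f"planted block index {e.block} out of range")
            if not 0 <= e.pathway < self.n_pathways:
                raise ValidationError(f"planted pathway index {e.pathway} out of range")
        for s in self.signature_events:
            if not 0 <= s.chromosome < self.n_chromosomes:
                raise ValidationError(f"signature chromosome {s.chromosome} out of range")
            if s.sign not in (-1, 1):
                raise ValidationError("signature sign must be +1 or -1")
            if not 0 < s.fraction <= 1:
                raise ValidationError("signature fraction must lie in (0, 1]")

    def _blocks_per_chromosome(self) -> int:
        return -(-self.loci_per_chromosome // self.block_size)  # ceil division


@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix
    copy_number: CopyNumberMatrix
    pathways: PathwayCollection
    annotation: GeneAnnotation
    truth: dict

    def truth_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)


def _block_layout(config: SyntheticConfig) -> list[dict]:
    """Genomic block layout: chromosome, locus ids, positions."""
    blocks = []
    bpc = config._blocks_per_chromosome()
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        for b in range(bpc):
            lo = b * config.block_size
            hi = min(lo + config.block_size, config.loci_per_chromosome)
            if lo >= hi:
                continue
            loci = [f"L{c + 1}_{k + 1}" for k in range(lo, hi)]
            positions = [(k + 1) * _LOCUS_SPACING for k in range(lo, hi)]
            blocks.append(
                {
                    "index": len(blocks),
                    "chrom": chrom,
                    "chrom_index": c,
                    "loci": loci,
                    "positions": positions,
                }
            )
    return blocks


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a paired expression/copy-number dataset with known truth.

    Within a block, each locus's lg2 copy number is
    ``cn_noise_sd * (sqrt(r) * z_block + sqrt(1 - r) * noise)``, so the
    expected correlation between any two loci of the block is exactly
    ``within_block_r``; loci of different blocks are independent (before
    signature events).  Disease expression of a pathway's genes adds
    ``beta * lg2CNA(block representative)`` for every planted effect;
    controls carry baseline plus noise only.
    """
    root = np.random.SeedSequence(config.seed)
    rng_cn, rng_sig, rng_expr, rng_genes = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    n_dis, n_ctl = config.n_disease, config.n_control
    disease_ids = [f"D{j + 1}" for j in range(n_dis)]
    control_ids = [f"C{j + 1}" for j in range(n_ctl)]
    blocks = _block_layout(config)
    r = config.within_block_r

    # --- copy number (disease samples only) -------------------------------
    locus_ids: list[str] = []
    chrom_col: list[str] = []
    pos_col: list[int] = []
    lg2_rows: list[np.ndarray] = []
    block_rep_lg2: list[np.ndarray] = []
    for blk in blocks:
        z = rng_cn.standard_normal(n_dis)
        rows = []
        for lid, p in zip(blk["loci"], blk["positions"]):
            eps = rng_cn.standard_normal(n_dis)
            rows.append(config.cn_noise_sd * (np.sqrt(r) * z + np.sqrt(1 - r) * eps))
            locus_ids.append(lid)
            chrom_col.append(blk["chrom"])
            pos_col.append(p)
        lg2_rows.extend(rows)
        block_rep_lg2.append(rows[0])
    lg2 = np.vstack(lg2_rows)

    for ev in config.signature_events:
        n_alt = max(1, round(ev.fraction * n_dis))
        altered = rng_sig.permutation(n_dis)[:n_alt]
        on_chrom = [i for i, c in enumerate(chrom_col) if c == f"chr{ev.chromosome + 1}"]
        lg2[np.ix_(on_chrom, altered)] += ev.sign * ev.magnitude
    # representatives are views into lg2? rebuild after signature shifts
    rep_index = {}
    offset = 0
    for blk in blocks:
        rep_index[blk["index"]] = offset
        offset += len(blk["loci"])
    block_rep_lg2 = [lg2[rep_index[b["index"]]] for b in blocks]

    cn_values = pd.DataFrame(
        np.exp2(lg2), index=pd.Index(locus_ids, name="locus_id"), columns=disease_ids
    )
    coords = pd.DataFrame(
        {"chrom": chrom_col, "pos": pos_col}, index=cn_values.index
    )
    copy_number = CopyNumberMatrix(cn_values, coords)

    # --- pathways and gene annotation --------------------------------------
    pathway_genes = [
        [f"P{p + 1}G{g + 1}" for g in range(config.genes_per_pathway)]
        for p in range(config.n_pathways)
    ]
    background = [f"BG{g + 1}" for g in range(config.n_background_genes)]
    all_genes = [g for genes in pathway_genes for g in genes] + background
    pathways = PathwayCollection(
        [
            Pathway(f"PW{p + 1}", f"synthetic pathway {p + 1}", tuple(genes))
            for p, genes in enumerate(pathway_genes)
        ]
    )
    max_pos = (config.loci_per_chromosome + 1) * _LOCUS_SPACING
    ann_chrom = [
        f"chr{rng_genes.integers(1, config.n_chromosomes + 1)}" for _ in all_genes
    ]
    ann_start = rng_genes.integers(0, max_pos, size=len(all_genes))
    annotation = GeneAnnotation(
        pd.DataFrame(
            {
                "gene": all_genes,
                "chrom": ann_chrom,
                "start": ann_start,
                "end": ann_start + _GENE_LENGTH,
            }
        )
    )

    # --- expression ---------------------------------------------------------
    lo, hi = config.baseline_range
    baseline = rng_expr.uniform(lo, hi, size=len(all_genes))
    n_total = n_dis + n_ctl
    values = baseline[:, None] + rng_expr.standard_normal(
        (len(all_genes), n_total)
    ) * config.expression_noise_sd
    gene_index = {g: i for i, g in enumerate(all_genes)}
    for eff in config.planted_effects:
        rep = block_rep_lg2[eff.block]  # length n_dis
        for g in pathway_genes[eff.pathway]:
            values[gene_index[g], :n_dis] += eff.beta * rep
    values = np.clip(values, 0.0, None)
    expression = ExpressionMatrix(
        pd.DataFrame(
            values,
            index=pd.Index(all_genes, name="gene"),
            columns=disease_ids + control_ids,
        ),
        labels={**{s: DISEASE for s in disease_ids}, **{s: CONTROL for s in control_ids}},
    )

    truth = {
        "seed": config.seed,
        "blocks": [
            {
                "index": b["index"],
                "chrom": b["chrom"],
                "representative": b["loci"][0],
                "members": b["loci"],
            }
            for b in blocks
        ],
        "planted_effects": [
            {
                "block": e.block,
                "representative": blocks[e.block]["loci"][0],
                "pathway": pathways.names[e.pathway],
                "beta": e.beta,
            }
            for e in config.planted_effects
        ],
        "signature_events": [asdict(s) for s in config.signature_events],
    }
    return SyntheticDataset(expression, copy_number, pathways, annotation, truth)
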