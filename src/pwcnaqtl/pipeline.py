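"""End-to-end orchestration: simulate/ingest -> GSEA -> score -> tag-loci ->
associate -> test -> report, from one config, with a provenance manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from pwcnaqtl import __version__, downstream, gsea, io_model, scoring
from pwcnaqtl.association import (
    ForestParams,
    build_design,
    fit_importance,
    importance_frame,
)
from pwcnaqtl.io_model import ValidationError
from pwcnaqtl.significance import association_table, permutation_null
from pwcnaqtl.synthetic_data import SyntheticConfig, generate_dataset
from pwcnaqtl.tagloci import assign_genes, detect_tag_loci

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration; exactly one of ``inputs``/``synthetic`` is set."""

    seed: int = 0
    outdir: str = "pwcnaqtl_run"
    inputs: dict[str, str] | None = None  # paths: expression, labels, copy_number,
    # gene_sets, optionally annotation, drivers
    synthetic: SyntheticConfig | None = None
    gsea_weight_exponent: float = 1.0
    gsea_sigma_floor: float = 0.2
    scoring_mode: str = "ratio_of_sums"
    scoring_epsilon: float | None = None
    tag_r_threshold: float = 0.95
    tag_mode: str = "seed"
    gene_flank: int = 0
    forest: ForestParams = field(default_factory=ForestParams)
    n_perm: int = 100
    null_pooling: str = "pooled"
    alpha: float = 0.05
    fdr_pooling: str = "per_direction"  # or "pooled"
    cna_threshold: float = 1.5
    filter_max_zero_frac: float = 0.10

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synthetic is None):
            raise ValidationError("exactly one of inputs/synthetic must be configured")
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticConfig(**self.synthetic)
        if isinstance(self.forest, dict):
            self.forest = ForestParams(**self.forest)
        if self.fdr_pooling not in ("per_direction", "pooled"):
            raise ValidationError(f"unknown fdr_pooling {self.fdr_pooling!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        return d


def _derived_seed(*parts) -> int:
    h = hashlib.blake2b(repr(parts).encode(), digest_size=8).digest()
    return int.from_bytes(h, "little") % (2**63)


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages, writing intermediate TSVs and a manifest JSON.

    Returns a bundle with all in-memory stage outputs.  Identical config and
    seed produce byte-identical association tables.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {
            "pwcnaqtl": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }
    bundle: dict[str, Any] = {"manifest": manifest, "outdir": outdir}

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(
                f"stage {name!r} failed: {exc}; replay with "
                f"`pwcnaqtl {name} ...` on the artifacts in {outdir}"
            ) from exc
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
        return result

    # --- ingest / simulate --------------------------------------------------
    def _load():
        if config.synthetic is not None:
            ds = generate_dataset(config.synthetic)
            io_model.write_expression(ds.expression, outdir / "expression.tsv")
            io_model.write_labels(ds.expression.labels, outdir / "labels.tsv")
            io_model.write_copy_number(ds.copy_number, outdir / "copy_number.tsv")
            io_model.write_gene_sets(ds.pathways, outdir / "pathways.gmt")
            io_model.write_annotation(ds.annotation, outdir / "annotation.bed")
            ds.truth_json(outdir / "truth.json")
            return ds.expression, ds.copy_number, ds.pathways, ds.annotation, None, ds.truth
        paths = config.inputs
        labels = io_model.read_labels(paths["labels"]) if "labels" in paths else None
        expr = io_model.read_expression(paths["expression"], labels)
        cn = io_model.read_copy_number(paths["copy_number"])
        pws = io_model.read_gene_sets(paths["gene_sets"])
        ann = (
            io_model.read_annotation(paths["annotation"])
            if "annotation" in paths
            else None
        )
        drivers = (
            io_model.read_driver_genes(paths["drivers"]) if "drivers" in paths else None
        )
        return expr, cn, pws, ann, drivers, None

    expression, copy_number, pathways, annotation, drivers, truth = stage("ingest", _load)
    bundle["truth"] = truth

    # --- preprocess ----------------------------------------------------------
    expression = stage(
        "filter", lambda: io_model.filter_low_signal(expression, config.filter_max_zero_frac)
    )
    manifest["stages"]["filter"]["n_genes"] = len(expression.gene_ids)

    # --- GSEA -----------------------------------------------------------------
    def _gsea():
        return gsea.gsea_all(
            expression,
            pathways,
            weight_exponent=config.gsea_weight_exponent,
            sigma_floor=config.gsea_sigma_floor,
        )

    ranked, es_results, edges = stage("gsea", _gsea)
    bundle["ranked"] = ranked
    bundle["es_results"] = es_results
    bundle["leading_edges"] = edges
    le_df = pd.DataFrame(
        {
            "pathway": [e.pathway for e in edges],
            "es": [r.es for r in es_results],
            "sign": [e.sign for e in edges],
            "leading_edge": [";".join(e.genes) for e in edges],
        }
    )
    le_df.to_csv(outdir / "leading_edges.tsv", sep="\t", index=False)
    manifest["stages"]["gsea"]["n_pathways"] = len(edges)

    # --- scoring ---------------------------------------------------------------
    def _score():
        baseline = scoring.control_baseline(expression)
        return scoring.pathway_scores(
            expression,
            edges,
            baseline,
            mode=config.scoring_mode,
            epsilon=config.scoring_epsilon,
        )

    scores = stage("score", _score)
    scores.to_csv(outdir / "pathway_scores.tsv", sep="\t", float_format="%.17g")
    bundle["scores"] = scores

    # --- tag loci ----------------------------------------------------------------
    def _tags():
        t = detect_tag_loci(copy_number, config.tag_r_threshold, config.tag_mode)
        if annotation is not None:
            t = assign_genes(t, annotation, flank=config.gene_flank)
        return t

    tags = stage("tagloci", _tags)
    bundle["tags"] = tags
    pd.DataFrame(
        {
            "tag_locus": [t.rep for t in tags],
            "chrom": [t.chrom for t in tags],
            "start": [t.span[0] for t in tags],
            "end": [t.span[1] for t in tags],
            "n_members": [len(t.members) for t in tags],
            "members": [";".join(t.members) for t in tags],
            "genes": [";".join(t.genes) for t in tags],
        }
    ).to_csv(outdir / "tag_loci.tsv", sep="\t", index=False)
    manifest["stages"]["tagloci"]["n_tags"] = len(tags)

    # --- association ----------------------------------------------------------------
    design = build_design(copy_number, tags, sample_ids=list(scores.columns))
    direction_of = {e.pathway: e.sign for e in edges}

    def _associate():
        frames = []
        for pw in scores.index:
            seed = _derived_seed(config.seed, pw, "fit")
            records = fit_importance(
                scores.loc[pw], design, config.forest.with_seed(seed), pathway=pw
            )
            frames.append(importance_frame(records))
        return pd.concat(frames, ignore_index=True)

    importances = stage("associate", _associate)
    importances.to_csv(outdir / "importance.tsv", sep="\t", index=False, float_format="%.17g")
    bundle["importances"] = importances

    # --- significance ----------------------------------------------------------------
    def _test():
        nulls = {}
        for pw in scores.index:
            nulls[pw] = permutation_null(
                scores.loc[pw],
                design,
                config.forest,
                n_perm=config.n_perm,
                seed=_derived_seed(config.seed, pw, "null"),
                pooling=config.null_pooling,
                pathway=pw,
            )
        directions = importances["pathway"].map(direction_of)
        table = association_table(
            importances,
            nulls,
            alpha=config.alpha,
            fdr_groups=directions if config.fdr_pooling == "per_direction" else None,
        )
        table["direction"] = directions
        return nulls, table

    nulls, assoc = stage("test", _test)
    assoc.to_csv(outdir / "associations.tsv", sep="\t", index=False, float_format="%.17g")
    bundle["nulls"] = nulls
    bundle["associations"] = assoc
    manifest["stages"]["test"]["n_significant"] = int(assoc["significant"].sum())

    # --- downstream report --------------------------------------------------------------
    def _report():
        out = {}
        out["frequency"] = downstream.alteration_frequency(
            copy_number, tags, threshold=config.cna_threshold
        )
        out["frequency"].to_csv(outdir / "alteration_frequency.tsv", sep="\t")
        out["pathway_counts"] = downstream.pathway_counts(assoc, tags)
        out["pathway_counts"].to_csv(outdir / "pathway_counts.tsv", sep="\t")
        for direction in ("over", "under"):
            sharing = downstream.chromosome_sharing(assoc, tags, direction)
            sharing.counts.to_csv(outdir / f"sharing_{direction}.tsv", sep="\t")
            out[f"sharing_{direction}"] = sharing
        out["de"] = downstream.differential_expression(expression)
        out["de"].to_csv(outdir / "differential_expression.tsv", sep="\t")
        if drivers:
            records = downstream.driver_enrichment(pathways, drivers, expression.gene_ids)
            enr = pd.DataFrame([asdict(r) for r in records])
            enr.to_csv(outdir / "driver_enrichment.tsv", sep="\t", index=False)
            out["enrichment"] = records
        return out

    bundle["report"] = stage("report", _report)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return bundle
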