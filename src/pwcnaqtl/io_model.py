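"""Domain types, file readers/writers and expression preprocessing filters.

Coordinates are 0-based half-open throughout.  Tabular formats are plain TSV;
gene sets use GMT (name, description, member genes, tab-separated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DISEASE = "disease"
CONTROL = "control"
_VALID_LABELS = frozenset({DISEASE, CONTROL})


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Domain-type invariant violated."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of nonnegative log-scale intensities.

    ``values`` is indexed by gene id (rows) and sample id (columns);
    ``labels`` maps each sample id to ``"disease"`` or ``"control"``.
    """

    values: pd.DataFrame
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.values.shape[0] == 0:
            raise ValidationError("expression matrix has no genes")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {list(dups)[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValidationError(f"duplicate sample ids: {list(dups)[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("expression values must be finite")
        if (arr < 0).any():
            raise ValidationError("expression values must be nonnegative (log-scale)")
        if self.labels is not None:
            unknown = set(self.labels) - set(self.values.columns)
            if unknown:
                raise ValidationError(f"labels for unknown samples: {sorted(unknown)}")
            bad = {s: c for s, c in self.labels.items() if c not in _VALID_LABELS}
            if bad:
                raise ValidationError(f"invalid class labels: {bad}")
            classes = set(self.labels.values())
            if classes and classes != _VALID_LABELS:
                raise ValidationError(
                    "labels must include at least one disease and one control sample"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def _samples_of(self, cls: str) -> list[str]:
        if self.labels is None:
            raise ValidationError("expression matrix has no class labels")
        return [s for s in self.values.columns if self.labels.get(s) == cls]

    @property
    def disease_samples(self) -> list[str]:
        return self._samples_of(DISEASE)

    @property
    def control_samples(self) -> list[str]:
        return self._samples_of(CONTROL)


@dataclass
class CopyNumberMatrix:
    """Locus x sample matrix of copy-number ratios (1.0 = diploid-normal).

    ``coords`` carries one row per locus with ``chrom`` and 0-based ``pos``
    columns, index-aligned with ``values``.  Loci are kept sorted by
    (chromosome, position).
    """

    values: pd.DataFrame
    coords: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate locus ids")
        if list(self.values.index) != list(self.coords.index):
            raise ValidationError("values and coords must share locus index")
        for col in ("chrom", "pos"):
            if col not in self.coords.columns:
                raise ValidationError(f"coords missing column {col!r}")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)) or (arr <= 0).any():
            raise ValidationError(
                "copy-number ratios must be finite and strictly positive; "
                "use clamp_epsilon when reading to clamp nonpositive values"
            )
        order = self.coords.sort_values(["chrom", "pos"], kind="stable").index
        if not order.equals(self.coords.index):
            logger.warning("copy-number loci were not coordinate-sorted; sorting")
            self.coords = self.coords.loc[order]
            self.values = self.values.loc[order]

    @property
    def locus_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def lg2(self) -> pd.DataFrame:
        """Log2-transformed copy-number ratios (the modeling scale)."""
        return np.log2(self.values)


@dataclass(frozen=True)
class Pathway:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"pathway {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"pathway {self.name!r} has duplicate genes")


@dataclass
class PathwayCollection:
    pathways: list[Pathway] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [p.name for p in self.pathways]
        if len(set(names)) != len(names):
            dups = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate pathway names: {dups}")
        self._by_name = {p.name: p for p in self.pathways}

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __getitem__(self, name: str) -> Pathway:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.pathways]

    def subset(self, names: Sequence[str]) -> "PathwayCollection":
        return PathwayCollection([self._by_name[n] for n in names])


@dataclass
class GeneAnnotation:
    """Gene intervals: columns gene, chrom, start, end (0-based half-open)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"gene", "chrom", "start", "end"}
        missing = need - set(self.records.columns)
        if missing:
            raise ValidationError(f"annotation missing columns: {sorted(missing)}")
        if len(self.records) == 0:
            raise ValidationError("annotation is empty")
        bad = self.records[self.records["start"] >= self.records["end"]]
        if len(bad):
            raise ValidationError(
                f"annotation intervals with start >= end: {list(bad['gene'])[:5]}"
            )
        if self.records.duplicated(["gene", "chrom", "start", "end"]).any():
            raise ValidationError("duplicate (gene, location) records")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def chromosomes(self) -> set[str]:
        return set(self.records["chrom"].astype(str))


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> PathwayCollection:
    """Read a GMT file: one pathway per line, ``name<TAB>desc<TAB>genes...``.

    Duplicate genes within a set are deduplicated (first occurrence kept)
    with a logged warning; duplicate pathway names are an error.
    """
    pathways: list[Pathway] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate pathway name {name!r}")
            seen.add(name)
            uniq = list(dict.fromkeys(genes))
            if len(uniq) != len(genes):
                logger.warning(
                    "pathway %s: %d duplicate gene(s) removed", name, len(genes) - len(uniq)
                )
            if not uniq:
                raise ParseError(f"{path}: line {lineno}: pathway {name!r} has no genes")
            pathways.append(Pathway(name, desc, tuple(uniq)))
    return PathwayCollection(pathways)


def write_gene_sets(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in collection:
            fh.write("\t".join([p.name, p.description, *p.genes]) + "\n")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def _read_numeric_tsv(path: str | Path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.shape[0] == 0:
        raise ParseError(f"{path}: no {what}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad_rows = df.index[coerced.isna() & df[col].notna()]
            row = bad_rows[0] if len(bad_rows) else df.index[df[col].isna()][0]
            raise ParseError(
                f"{path}: non-numeric value at row {row!r}, column {col!r}"
            )
    return df


def read_expression(
    path: str | Path, labels: Mapping[str, str] | None = None
) -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene ids, header sample ids)."""
    df = _read_numeric_tsv(path, "genes")
    return ExpressionMatrix(df.astype(float), dict(labels) if labels else None)


def write_expression(E: ExpressionMatrix, path: str | Path) -> None:
    E.values.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


def read_labels(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``sample<TAB>class`` with class in {disease, control}."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 fields")
            sample, cls = parts
            if cls not in _VALID_LABELS:
                raise ParseError(f"{path}: line {lineno}: unknown class {cls!r}")
            out[sample] = cls
    return out


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, cls in labels.items():
            fh.write(f"{sample}\t{cls}\n")


def filter_low_signal(E: ExpressionMatrix, max_zero_frac: float = 0.10) -> ExpressionMatrix:
    """Drop genes whose fraction of zero values is strictly above the cutoff.

    The default removes rows with more than 10% zero (log-transformed)
    expression values across all samples.
    """
    frac_zero = (E.values == 0).mean(axis=1)
    keep = frac_zero <= max_zero_frac
    if not keep.any():
        raise ValidationError("empty matrix after filtering")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_low_signal: removed %d of %d genes", n_drop, len(keep))
    return ExpressionMatrix(E.values.loc[keep], dict(E.labels) if E.labels else None)


def collapse_probesets(
    E: ExpressionMatrix, probe_gene_map: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene.

    For each gene the probe with the highest mean intensity over disease
    samples is kept (over all samples when no labels are attached); ties are
    broken by the lexicographically smallest probe id.
    """
    unmapped = [p for p in E.values.index if p not in probe_gene_map]
    if unmapped:
        raise ValidationError(f"unmapped probes: {unmapped[:10]}")
    cols = E.disease_samples if E.labels is not None else E.sample_ids
    means = E.values[cols].mean(axis=1)
    best: dict[str, str] = {}
    for probe in E.values.index:
        gene = probe_gene_map[probe]
        cur = best.get(gene)
        if (
            cur is None
            or means[probe] > means[cur]
            or (means[probe] == means[cur] and probe < cur)
        ):
            best[gene] = probe
    genes = list(dict.fromkeys(probe_gene_map[p] for p in E.values.index))
    chosen = [best[g] for g in genes]
    out = E.values.loc[chosen].copy()
    out.index = pd.Index(genes, name="gene")
    return ExpressionMatrix(out, dict(E.labels) if E.labels else None)


# ---------------------------------------------------------------------------
# Copy number
# ---------------------------------------------------------------------------


def read_copy_number(
    path: str | Path, clamp_epsilon: float | None = None
) -> CopyNumberMatrix:
    """Read a locus x sample TSV with leading columns locus_id, chrom, pos.

    Ratios must be strictly positive (1.0 = diploid).  Values <= 0 are an
    error unless ``clamp_epsilon`` is given, in which case they are clamped
    to that epsilon with a warning (log2 is applied downstream).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    for col in ("locus_id", "chrom", "pos"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    df = df.set_index("locus_id")
    coords = df[["chrom", "pos"]].copy()
    coords["pos"] = coords["pos"].astype(int)
    values = df.drop(columns=["chrom", "pos"]).astype(float)
    if values.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns")
    arr = values.to_numpy()
    if (arr <= 0).any():
        if clamp_epsilon is None:
            n_bad = int((arr <= 0).sum())
            raise ParseError(
                f"{path}: {n_bad} copy-number value(s) <= 0; pass clamp_epsilon "
                "to clamp them to a small positive ratio"
            )
        logger.warning(
            "clamping %d nonpositive copy-number value(s) to %g",
            int((arr <= 0).sum()),
            clamp_epsilon,
        )
        values = values.clip(lower=clamp_epsilon)
    return CopyNumberMatrix(values, coords)


def write_copy_number(CN: CopyNumberMatrix, path: str | Path) -> None:
    out = pd.concat([CN.coords, CN.values], axis=1)
    out.to_csv(path, sep="\t", index_label="locus_id", float_format="%.17g")


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------


def read_annotation(path: str | Path, one_based: bool = False) -> GeneAnnotation:
    """Read gene intervals from BED4 (chrom, start, end, gene; no header).

    BED is taken as 0-based half-open.  Pass ``one_based=True`` for 1-based
    inclusive tabular annotation; starts are shifted down by one.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene"],
        dtype={"chrom": str, "gene": str},
        comment="#",
    )
    if df[["start", "end"]].isna().any().any():
        raise ParseError(f"{path}: missing coordinates")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if one_based:
        df["start"] -= 1
    return GeneAnnotation(df[["gene", "chrom", "start", "end"]])


def write_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    annotation.records[["chrom", "start", "end", "gene"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_driver_genes(path: str | Path) -> list[str]:
    """Plain one-gene-per-line driver list; blank lines and # comments skipped."""
    genes: list[str] = []
    with open(path) as fh:
        for raw in fh:
            g = raw.strip()
            if g and not g.startswith("#"):
                genes.append(g)
    return list(dict.fromkeys(genes))
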