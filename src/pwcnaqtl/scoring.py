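"""Per-sample pathway expression fold-change scores.

A pathway's score in a disease sample is the log2 ratio of the summed
expression of its leading-edge genes in that sample to the summed control
baseline of the same genes (ratio of sums, not sum of ratios).
"""

from __future__ import annotations

from typing import Iterable, Literal

import numpy as np
import pandas as pd

from pwcnaqtl.gsea import LeadingEdgeSet
from pwcnaqtl.io_model import ExpressionMatrix, ValidationError


def control_baseline(E: ExpressionMatrix) -> pd.Series:
    """Mean expression per gene over the control samples."""
    controls = E.control_samples
    if not controls:
        raise ValidationError("no control samples for baseline")
    return E.values[controls].mean(axis=1)


def pathway_scores(
    E: ExpressionMatrix,
    leading_edges: Iterable[LeadingEdgeSet],
    baseline: pd.Series | None = None,
    mode: Literal["ratio_of_sums", "sum_of_ratios"] = "ratio_of_sums",
    epsilon: float | None = None,
) -> pd.DataFrame:
    """Pathway x disease-sample matrix of log2 fold-change scores.

    ``ratio_of_sums`` (default): score = log2(sum_i E_ij / sum_i baseline_i)
    over the leading-edge genes i of the pathway.  ``sum_of_ratios`` is an
    alternative reading (mean of per-gene log2 ratios) kept for sensitivity
    analysis.  Zero numerators/denominators are an error unless ``epsilon``
    is given, in which case they are clamped.
    """
    if baseline is None:
        baseline = control_baseline(E)
    missing_base = set(E.gene_ids) - set(baseline.index)
    if missing_base:
        raise ValidationError(f"baseline missing genes: {sorted(missing_base)[:10]}")
    disease = E.disease_samples
    rows: list[np.ndarray] = []
    names: list[str] = []
    for le in leading_edges:
        genes = list(le.genes)
        absent = [g for g in genes if g not in E.values.index]
        if absent:
            raise ValidationError(
                f"pathway {le.pathway!r}: leading-edge genes absent from matrix: {absent[:10]}"
            )
        sub = E.values.loc[genes, disease].to_numpy(dtype=float)
        base = baseline.loc[genes].to_numpy(dtype=float)
        if mode == "ratio_of_sums":
            num = sub.sum(axis=0)
            den = base.sum()
            if den <= 0:
                if epsilon is None:
                    raise ValidationError(
                        f"pathway {le.pathway!r}: zero baseline denominator "
                        "(pass epsilon to clamp)"
                    )
                den = max(den, epsilon)
            if (num <= 0).any():
                if epsilon is None:
                    bad = [s for s, v in zip(disease, num) if v <= 0]
                    raise ValidationError(
                        f"pathway {le.pathway!r}: zero numerator in sample(s) "
                        f"{bad[:5]} (pass epsilon to clamp)"
                    )
                num = np.maximum(num, epsilon)
            rows.append(np.log2(num / den))
        elif mode == "sum_of_ratios":
            if epsilon is not None:
                sub = np.maximum(sub, epsilon)
                base = np.maximum(base, epsilon)
            if (base <= 0).any() or (sub <= 0).any():
                raise ValidationError(
                    f"pathway {le.pathway!r}: nonpositive expression in "
                    "sum_of_ratios mode (pass epsilon to clamp)"
                )
            rows.append(np.log2(sub / base[:, None]).mean(axis=0))
        else:
            raise ValueError(f"unknown mode {mode!r}")
        names.append(le.pathway)
    return pd.DataFrame(rows, index=pd.Index(names, name="pathway"), columns=disease)
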