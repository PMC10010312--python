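"""Expression filtering and normalization.

The canonical normalized layer is produced in three fixed steps:

1. ``v = log2(1 + count)`` per cell of the matrix;
2. per-sample upper-quartile scaling: each sample's values are divided by
   that sample's 75th percentile of v over genes with v > 0 and multiplied
   by the global mean of those 75th percentiles, so the output scale is
   comparable across samples;
3. per-gene median centering across samples, so every gene's median is 0.

Scaling precedes centering: centering first and rescaling per sample
afterwards would destroy the zero-median property the normalized layer
guarantees. Percentiles use the linear-interpolation definition.
"""

from __future__ import annotations

import numpy as np

from .containers import COUNTS, LOG_NORMALIZED, ExpressionMatrix, FilterReport


def _require_counts(m: ExpressionMatrix, op: str) -> None:
    if m.layer != COUNTS:
        raise ValueError(f"{op} requires a counts-layer matrix, got {m.layer!r}")


def filter_min_expression(
    m: ExpressionMatrix, min_count: int = 10, min_samples: int = 5
) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep genes with at least ``min_count`` reads in at least
    ``min_samples`` samples; samples are unchanged."""
    _require_counts(m, "filter_min_expression")
    keep = (m.values >= min_count).sum(axis=1) >= min_samples
    kept_genes = [g for g, k in zip(m.gene_ids, keep) if k]
    removed = [g for g, k in zip(m.gene_ids, keep) if not k]
    out = ExpressionMatrix(kept_genes, list(m.sample_ids), m.values[keep], m.layer)
    report = FilterReport(m.n_genes, len(kept_genes), removed)
    return out, report


def restrict_gene_universe(
    m: ExpressionMatrix, allowed_genes: list[str]
) -> tuple[ExpressionMatrix, FilterReport]:
    """Intersect matrix genes with an allowed list (e.g. protein-coding),
    preserving matrix order."""
    if not allowed_genes:
        raise ValueError("allowed_genes must be non-empty")
    allowed = {str(g) for g in allowed_genes}
    keep = np.array([g in allowed for g in m.gene_ids], dtype=bool)
    if not keep.any():
        raise ValueError("no matrix gene is in the allowed gene universe")
    kept_genes = [g for g, k in zip(m.gene_ids, keep) if k]
    removed = [g for g, k in zip(m.gene_ids, keep) if not k]
    out = ExpressionMatrix(kept_genes, list(m.sample_ids), m.values[keep], m.layer)
    return out, FilterReport(m.n_genes, len(kept_genes), removed)


def normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(1+x) transform, per-sample upper-quartile scaling, per-gene
    median centering. Rejects samples whose counts are all zero (their
    upper quartile is undefined)."""
    _require_counts(m, "normalize")
    if m.n_samples < 2:
        raise ValueError("normalize requires at least 2 samples")
    v = np.log2(1.0 + m.values)

    uq = np.empty(m.n_samples)
    for j, sample in enumerate(m.sample_ids):
        pos = v[:, j][v[:, j] > 0]
        if pos.size == 0:
            raise ValueError(f"sample {sample!r} has all-zero counts; upper quartile undefined")
        uq[j] = np.percentile(pos, 75, method="linear")
    v = v * (uq.mean() / uq)

    v = v - np.median(v, axis=1, keepdims=True)
    return ExpressionMatrix(list(m.gene_ids), list(m.sample_ids), v, LOG_NORMALIZED)
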