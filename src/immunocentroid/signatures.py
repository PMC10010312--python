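"""Immune gene-set signature scoring, group statistics and enrichment.

A signature score is the unweighted mean of the normalized expression of
the set's genes present in the matrix (the mean-of-genes convention used
for immune cell-type signatures in tumor profiling). Group comparisons use
the two-sided Wilcoxon rank-sum test (exact when both groups are small and
untied, normal approximation with tie correction otherwise) alongside a
pooled-variance t statistic. Overrepresentation analysis is a one-sided
hypergeometric upper-tail test with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import LOG_NORMALIZED, ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

EXACT_WILCOXON_MAX_N = 10


def default_immune_collection() -> GeneSetCollection:
    """The packaged default marker collection: 28 singleton immune marker
    sets plus one 12-gene type I interferon module."""
    path = resources.files("immunocentroid").joinpath("data/immune_markers.gmt")
    with resources.as_file(path) as p:
        return GeneSetCollection.read_gmt(p)


@dataclass
class SignatureScores:
    """Signatures x samples score matrix."""

    signature_names: list[str]
    sample_ids: list[str]
    scores: np.ndarray
    #: per-set fraction of genes absent from the scored matrix
    dropped_gene_fraction: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.signature_names), len(self.sample_ids)):
            raise ValueError("score matrix shape inconsistent with names")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("signature scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.signature_names, columns=self.sample_ids)

    def row(self, name: str) -> np.ndarray:
        return self.scores[self.signature_names.index(name)]


@dataclass
class GroupComparison:
    """Two-group statistics for one signature (positive t = higher in the
    first/responder group)."""

    signature_name: str
    wilcoxon_statistic: float
    wilcoxon_p: float
    t_statistic: float
    mean_difference: float
    display: bool  # p < 0.05 display convention


@dataclass
class EnrichmentResult:
    set_name: str
    overlap_count: int
    set_size: int
    query_size: int
    universe_size: int
    p_hypergeometric: float
    p_adjusted: float


def score_signatures(
    norm: ExpressionMatrix, collection: GeneSetCollection
) -> SignatureScores:
    """Mean normalized expression of each set's genes per sample.

    Genes absent from the matrix are dropped from their set (the drop
    fraction is logged); sets with no gene present are dropped entirely
    with a warning. Raises if no set overlaps the matrix at all.
    """
    if norm.layer != LOG_NORMALIZED:
        raise ValueError("score_signatures requires the log_normalized layer")
    index = {g: i for i, g in enumerate(norm.gene_ids)}
    names: list[str] = []
    rows: list[np.ndarray] = []
    dropped: dict[str, float] = {}
    for name, genes in collection.sets.items():
        present = [index[g] for g in genes if g in index]
        frac_dropped = 1.0 - len(present) / len(genes)
        if not present:
            warnings.warn(f"signature {name!r} has no gene in the matrix; dropped")
            continue
        if frac_dropped > 0:
            logger.info("signature %s: %.0f%% of genes absent, scored on the rest",
                        name, 100 * frac_dropped)
        dropped[name] = frac_dropped
        names.append(name)
        rows.append(norm.values[present].mean(axis=0))
    if not names:
        raise ValueError("no signature has any gene present in the matrix")
    return SignatureScores(names, list(norm.sample_ids), np.vstack(rows), dropped)


def _wilcoxon(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum test. Exact enumeration when both groups are
    <= 10 with no ties; normal approximation with tie correction otherwise.
    Returns (rank-sum W of the first group, p)."""
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    small = len(x) <= EXACT_WILCOXON_MAX_N and len(y) <= EXACT_WILCOXON_MAX_N
    method = "exact" if (small and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic) + len(x) * (len(x) + 1) / 2.0  # U -> rank-sum W
    return w, float(res.pvalue)


def pooled_t_statistic(x: np.ndarray, y: np.ndarray, s0: float = 0.0) -> float:
    """Two-sample pooled-variance t with an additive offset s0 in the
    denominator: t = (mean_x - mean_y) / (s_p sqrt(1/n1 + 1/n2) + s0)."""
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    diff = x.mean() - y.mean()
    df = n1 + n2 - 2
    if df <= 0:
        sp = 0.0
    else:
        sp = np.sqrt(((n1 - 1) * x.var(ddof=1 if n1 > 1 else 0)
                      + (n2 - 1) * y.var(ddof=1 if n2 > 1 else 0)) / df)
    denom = sp * np.sqrt(1.0 / n1 + 1.0 / n2) + s0
    if denom == 0.0:
        return 0.0 if diff == 0 else np.sign(diff) * np.inf
    return float(diff / denom)


def compare_groups(
    scores: SignatureScores, labels: np.ndarray | pd.Series
) -> list[GroupComparison]:
    """Per-signature responder vs non-responder comparison.

    ``labels`` is boolean per sample (True = responder / first group).
    Sign convention: positive t and mean difference mean higher in
    responders.
    """
    if isinstance(labels, pd.Series):
        labels = labels.reindex(scores.sample_ids).to_numpy()
    labels = np.asarray(labels, dtype=bool)
    if labels.shape != (len(scores.sample_ids),):
        raise ValueError("labels must align with the score matrix samples")
    if labels.all() or not labels.any():
        raise ValueError("both groups must be non-empty")
    out = []
    for i, name in enumerate(scores.signature_names):
        x = scores.scores[i, labels]
        y = scores.scores[i, ~labels]
        w, p = _wilcoxon(x, y)
        t = pooled_t_statistic(x, y)
        out.append(
            GroupComparison(
                signature_name=name,
                wilcoxon_statistic=w,
                wilcoxon_p=p,
                t_statistic=t,
                mean_difference=float(x.mean() - y.mean()),
                display=p < 0.05,
            )
        )
    return out


def comparisons_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "signature": [c.signature_name for c in comparisons],
            "wilcoxon_statistic": [c.wilcoxon_statistic for c in comparisons],
            "wilcoxon_p": [c.wilcoxon_p for c in comparisons],
            "t_statistic": [c.t_statistic for c in comparisons],
            "mean_difference": [c.mean_difference for c in comparisons],
            "display": [c.display for c in comparisons],
        }
    )


def teff_myeloid_scatter(
    scores: SignatureScores,
    teff_name: str,
    myeloid_name: str,
    response: pd.Series | None = None,
) -> pd.DataFrame:
    """Quadrant labels from the T-effector and myeloid inflammation scores.

    Each sample is called HIGH on a signature when its score is >= the
    cohort median of that signature (ties HIGH, deterministically).
    Returns the scatter table: sample, both scores, optional response,
    and quadrant in {Teff_HIGH/Myeloid_HIGH, Teff_HIGH/Myeloid_LOW,
    Teff_LOW/Myeloid_HIGH, Teff_LOW/Myeloid_LOW}.
    """
    for name in (teff_name, myeloid_name):
        if name not in scores.signature_names:
            raise KeyError(f"signature {name!r} not in score matrix")
    teff = scores.row(teff_name)
    mye = scores.row(myeloid_name)
    teff_hi = teff >= np.median(teff)
    mye_hi = mye >= np.median(mye)
    quadrant = [
        f"Teff_{'HIGH' if t else 'LOW'}/Myeloid_{'HIGH' if m else 'LOW'}"
        for t, m in zip(teff_hi, mye_hi)
    ]
    table = pd.DataFrame(
        {
            "sample_id": scores.sample_ids,
            "teff_score": teff,
            "myeloid_score": mye,
            "quadrant": quadrant,
        }
    )
    if response is not None:
        table["response"] = response.reindex(scores.sample_ids).to_numpy()
    return table


def overrepresentation(
    query_genes: list[str],
    collection: GeneSetCollection,
    universe: list[str],
) -> list[EnrichmentResult]:
    """Hypergeometric overrepresentation of a query gene list in each set.

    Per set: overlap k, set size within the universe K, query size n,
    universe size N; one-sided upper-tail p = P(X >= k); BH adjustment
    across sets. Query genes outside the universe are dropped with a
    warning.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    uni = {str(g) for g in universe}
    query = []
    seen = set()
    for g in query_genes:
        g = str(g)
        if g in seen:
            continue
        seen.add(g)
        if g not in uni:
            warnings.warn(f"query gene {g!r} not in universe; dropped")
            continue
        query.append(g)
    n = len(query)
    N = len(uni)
    qset = set(query)
    results = []
    for name, genes in collection.sets.items():
        in_uni = [g for g in genes if g in uni]
        K = len(in_uni)
        k = len(qset & set(in_uni))
        # P(X >= k) under Hypergeometric(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(
                set_name=name,
                overlap_count=k,
                set_size=K,
                query_size=n,
                universe_size=N,
                p_hypergeometric=min(1.0, p),
                p_adjusted=np.nan,
            )
        )
    raw = [r.p_hypergeometric for r in results]
    if raw:
        adj = multipletests(raw, method="fdr_bh")[1]
        for r, a in zip(results, adj):
            r.p_adjusted = float(a)
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set": [r.set_name for r in results],
            "overlap": [r.overlap_count for r in results],
            "set_size": [r.set_size for r in results],
            "query_size": [r.query_size for r in results],
            "universe_size": [r.universe_size for r in results],
            "p_hypergeometric": [r.p_hypergeometric for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
        }
    )
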