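"""Nearest-centroid classifiers for treatment response and tumor subtype.

The de novo response classifier follows the classification-to-nearest-
centroids recipe: a label-free candidate filter keeps genes that are both
highly expressed (across-sample median above a quantile of all gene
medians) and highly variable (variance above a quantile of all gene
variances); inside each leave-one-out fold, genes are ranked by the
two-class pooled-variance t statistic and the top m/2 up- and m/2
down-regulated candidates are kept; class centroids (per-gene class means)
with pooled within-class SDs are fitted on the fold's training samples and
the held-out sample is predicted by minimal standardized distance

    d_k(x) = sum_g ((x_g - c_kg) / (s_g + s0))^2 .

The gene count m is chosen to maximize LOOCV accuracy (ties toward the
smallest m) and the final model refits selection and centroids on all
samples. All tie-breaks are deterministic: gene ranking by larger |t| then
lexicographic gene ID; class prediction ties toward the first listed class.

The subtype classifier fits centroids for the ccA/ccB intrinsic subtypes
of clear-cell renal carcinoma on a fixed 34-gene list with a stratified
2/3 - 1/3 train/test split, median-centering genes on the training split.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .containers import LOG_NORMALIZED, ExpressionMatrix

STANDARDIZED = "standardized"
EUCLIDEAN = "euclidean"


@dataclass
class CandidateFilterParams:
    """Label-free candidate gene filter thresholds.

    A gene passes when its across-sample median is at or above the
    ``median_percentile`` quantile of all gene medians AND its variance is
    at or above the ``variance_percentile`` quantile of all gene variances.
    """

    median_percentile: float = 0.25
    variance_percentile: float = 0.70

    def __post_init__(self) -> None:
        for name, v in (("median_percentile", self.median_percentile),
                        ("variance_percentile", self.variance_percentile)):
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")


@dataclass
class CentroidModel:
    """A fitted nearest-centroid model.

    centroids has shape (n_classes, n_genes) over ``selected_genes``;
    pooled_sd is the per-gene pooled within-class SD. ``center_offsets``,
    when present, is subtracted from incoming expression rows before
    distance computation (used by the subtype classifier, which centers on
    its training split). cv_trace holds (n_genes, cv_accuracy) pairs.
    """

    selected_genes: list[str]
    class_labels: list[str]
    centroids: np.ndarray
    pooled_sd: np.ndarray
    s0: float = 0.0
    distance_kind: str = STANDARDIZED
    cv_trace: list[tuple[int, float]] = field(default_factory=list)
    center_offsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.pooled_sd = np.asarray(self.pooled_sd, dtype=float)
        if self.centroids.shape != (len(self.class_labels), len(self.selected_genes)):
            raise ValueError("centroid matrix shape inconsistent with labels/genes")
        if self.pooled_sd.shape != (len(self.selected_genes),):
            raise ValueError("pooled_sd length inconsistent with selected genes")
        if self.distance_kind not in (STANDARDIZED, EUCLIDEAN):
            raise ValueError(f"unknown distance kind {self.distance_kind!r}")
        if self.s0 < 0:
            raise ValueError("s0 must be non-negative")
        if self.distance_kind == STANDARDIZED and np.any(self.pooled_sd + self.s0 <= 0):
            raise ValueError("pooled_sd + s0 must be positive for standardized distance")

    @property
    def chosen_n_genes(self) -> int:
        return len(self.selected_genes)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "selected_genes": self.selected_genes,
            "class_labels": self.class_labels,
            "centroids": self.centroids.tolist(),
            "pooled_sd": self.pooled_sd.tolist(),
            "s0": self.s0,
            "distance_kind": self.distance_kind,
            "cv_trace": [[int(m), float(a)] for m, a in self.cv_trace],
            "center_offsets": None if self.center_offsets is None
            else np.asarray(self.center_offsets).tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CentroidModel":
        d = json.loads(Path(path).read_text())
        return cls(
            selected_genes=list(d["selected_genes"]),
            class_labels=list(d["class_labels"]),
            centroids=np.array(d["centroids"], dtype=float),
            pooled_sd=np.array(d["pooled_sd"], dtype=float),
            s0=float(d["s0"]),
            distance_kind=str(d["distance_kind"]),
            cv_trace=[(int(m), float(a)) for m, a in d.get("cv_trace", [])],
            center_offsets=None if d.get("center_offsets") is None
            else np.array(d["center_offsets"], dtype=float),
        )


def _require_norm(norm: ExpressionMatrix, op: str) -> None:
    if norm.layer != LOG_NORMALIZED:
        raise ValueError(f"{op} requires the log_normalized layer")


def select_candidates(
    norm: ExpressionMatrix, params: CandidateFilterParams = CandidateFilterParams()
) -> list[str]:
    """Label-free high-expression / high-variance candidate filter."""
    _require_norm(norm, "select_candidates")
    if norm.n_samples < 2:
        raise ValueError("select_candidates requires at least 2 samples")
    med = np.median(norm.values, axis=1)
    var = np.var(norm.values, axis=1, ddof=1)
    med_cut = np.quantile(med, params.median_percentile)
    var_cut = np.quantile(var, params.variance_percentile)
    keep = (med >= med_cut) & (var >= var_cut)
    return [g for g, k in zip(norm.gene_ids, keep) if k]


def _as_binary_labels(
    labels: np.ndarray | pd.Series | list, sample_ids: list[str]
) -> np.ndarray:
    """Boolean vector aligned to sample order; True = first class."""
    if isinstance(labels, pd.Series):
        labels = labels.reindex(sample_ids)
        if labels.isna().any():
            missing = [s for s, v in labels.items() if pd.isna(v)]
            raise ValueError(f"labels missing for samples: {missing}")
        labels = labels.to_numpy()
    arr = np.asarray(labels)
    if arr.dtype != bool:
        uniq = sorted(set(arr.tolist()))
        if len(uniq) != 2:
            raise ValueError(f"need exactly 2 label values, got {uniq}")
        arr = arr == uniq[0]
    if arr.shape != (len(sample_ids),):
        raise ValueError("label vector length must match the sample count")
    return arr


def gene_t_statistics(
    norm: ExpressionMatrix,
    labels: np.ndarray | pd.Series,
    s0: float = 0.0,
) -> pd.Series:
    """Per-gene two-sample pooled-variance t statistics.

    Denominator is s_p * sqrt(1/n1 + 1/n2) + s0. Positive values mean
    higher expression in the first class (True labels, e.g. CR/PR).
    """
    _require_norm(norm, "gene_t_statistics")
    mask = _as_binary_labels(labels, norm.sample_ids)
    n1, n2 = int(mask.sum()), int((~mask).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"both classes need >= 2 samples, got {n1} and {n2}")
    x = norm.values[:, mask]
    y = norm.values[:, ~mask]
    diff = x.mean(axis=1) - y.mean(axis=1)
    sp = np.sqrt(((n1 - 1) * x.var(axis=1, ddof=1) + (n2 - 1) * y.var(axis=1, ddof=1))
                 / (n1 + n2 - 2))
    denom = sp * np.sqrt(1.0 / n1 + 1.0 / n2) + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / denom, 0.0)
    return pd.Series(t, index=norm.gene_ids, name="t")


def _rank_genes(t: pd.Series) -> tuple[list[str], list[str]]:
    """Genes ordered most-positive-first and most-negative-first, ties by
    larger |t| then lexicographic gene ID."""
    frame = pd.DataFrame({"t": t, "abs_t": t.abs(), "gene": t.index})
    up = frame.sort_values(["t", "abs_t", "gene"], ascending=[False, False, True])
    down = frame.sort_values(["t", "abs_t", "gene"], ascending=[True, False, True])
    return list(up["gene"]), list(down["gene"])


def select_top_genes(t: pd.Series, m: int, balanced: bool = True) -> list[str]:
    """Top-m gene selection from a t-statistic ranking.

    Balanced mode (default) takes m/2 most-positive and m/2 most-negative
    genes; unbalanced mode takes the top m by |t|. Deterministic tie-breaks
    (larger |t|, then lexicographic gene ID).
    """
    if m <= 0:
        raise ValueError("m must be positive")
    if m > len(t):
        raise ValueError(f"m={m} exceeds the {len(t)} available genes")
    if balanced:
        if m % 2:
            raise ValueError("balanced selection requires an even m")
        up, down = _rank_genes(t)
        chosen = up[: m // 2]
        chosen_set = set(chosen)
        for g in down:
            if len(chosen) == m:
                break
            if g not in chosen_set:
                chosen.append(g)
                chosen_set.add(g)
        return chosen
    frame = pd.DataFrame({"abs_t": t.abs(), "gene": t.index})
    ranked = frame.sort_values(["abs_t", "gene"], ascending=[False, True])
    return list(ranked["gene"][:m])


def _pooled_within_class_sd(values: np.ndarray, class_masks: list[np.ndarray]) -> np.ndarray:
    """sqrt of pooled within-class variance per gene; 0 when df <= 0."""
    n = values.shape[1]
    k = len(class_masks)
    ss = np.zeros(values.shape[0])
    for mask in class_masks:
        sub = values[:, mask]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = n - k
    if df <= 0:
        return np.zeros(values.shape[0])
    return np.sqrt(ss / df)


def _resolve_s0(pooled_sd: np.ndarray, s0: float) -> float:
    """s0 fallback: when s0 = 0 and any pooled SD is 0, use the median of
    the positive pooled SDs (1.0 when none are positive) so distances stay
    finite."""
    if s0 > 0 or np.all(pooled_sd > 0):
        return s0
    positive = pooled_sd[pooled_sd > 0]
    return float(np.median(positive)) if positive.size else 1.0


def fit_centroids(
    norm: ExpressionMatrix,
    labels: np.ndarray | pd.Series,
    genes: list[str],
    distance_kind: str = STANDARDIZED,
    s0: float = 0.0,
    class_labels: list[str] | None = None,
    center_offsets: np.ndarray | None = None,
) -> CentroidModel:
    """Per-class per-gene mean centroids with pooled within-class SDs.

    ``labels`` may be any two-or-more-class categorical vector aligned with
    the samples; ``class_labels`` fixes the class order (first class wins
    prediction ties), defaulting to order of first appearance.
    """
    sub = norm.subset_genes(genes)
    if isinstance(labels, pd.Series):
        labels = labels.reindex(sub.sample_ids)
        if labels.isna().any():
            raise ValueError("labels missing for some samples")
        labels = labels.to_numpy()
    labels = np.asarray([str(v) for v in labels])
    if labels.shape != (sub.n_samples,):
        raise ValueError("label vector length must match the sample count")
    if class_labels is None:
        class_labels = list(dict.fromkeys(labels.tolist()))
    masks = []
    for cls in class_labels:
        mask = labels == cls
        if not mask.any():
            raise ValueError(f"class {cls!r} has no samples")
        masks.append(mask)
    values = sub.values
    if center_offsets is not None:
        values = values - np.asarray(center_offsets, dtype=float)[:, None]
    centroids = np.vstack([values[:, m].mean(axis=1) for m in masks])
    pooled_sd = _pooled_within_class_sd(values, masks)
    return CentroidModel(
        selected_genes=list(sub.gene_ids),
        class_labels=list(class_labels),
        centroids=centroids,
        pooled_sd=pooled_sd,
        s0=_resolve_s0(pooled_sd, s0) if distance_kind == STANDARDIZED else s0,
        distance_kind=distance_kind,
        center_offsets=None if center_offsets is None
        else np.asarray(center_offsets, dtype=float),
    )


def predict(model: CentroidModel, norm: ExpressionMatrix) -> pd.DataFrame:
    """Classify samples by minimal (standardized) distance to centroids.

    Returns a DataFrame indexed by sample with the predicted class and one
    distance column per class. Ties go to the first class in
    ``model.class_labels``.
    """
    index = {g: i for i, g in enumerate(norm.gene_ids)}
    missing = [g for g in model.selected_genes if g not in index]
    if missing:
        raise KeyError(f"model genes absent from matrix: {missing}")
    rows = [index[g] for g in model.selected_genes]
    x = norm.values[rows, :]  # genes x samples
    if not np.all(np.isfinite(x)):
        raise ValueError("expression values must be finite")
    if model.center_offsets is not None:
        x = x - model.center_offsets[:, None]
    if model.distance_kind == STANDARDIZED:
        scale = model.pooled_sd + model.s0
    else:
        scale = np.ones(len(model.selected_genes))
    # distances: classes x samples
    d = np.stack([
        (((x - c[:, None]) / scale[:, None]) ** 2).sum(axis=0)
        for c in model.centroids
    ])
    winner = np.argmin(d, axis=0)  # first minimal index -> first listed class
    out = pd.DataFrame(
        {"predicted_class": [model.class_labels[k] for k in winner]},
        index=pd.Index(norm.sample_ids, name="sample_id"),
    )
    for k, cls in enumerate(model.class_labels):
        out[f"distance_{cls}"] = d[k]
    return out


def _loocv_accuracy_fast(
    norm: ExpressionMatrix,
    mask: np.ndarray,
    candidates: list[str],
    gene_grid: list[int],
    reselect_in_folds: bool,
    t_full: pd.Series,
) -> dict[int, float] | None:
    """Vectorized LOOCV for the default configuration (standardized
    distance, s0 = 0, balanced selection).

    Per fold the centroids and pooled SDs do not depend on the gene count
    m, and the balanced selections at increasing m are prefixes of the
    up-/down-rankings, so each class distance is a prefix sum of per-gene
    standardized squared deviations. Exactly reproduces the naive
    per-(fold, m) refit. Returns None when a fold has a zero pooled SD
    (the naive path then applies its s0 fallback).
    """
    cand = norm.subset_genes(candidates)
    values = cand.values  # genes x samples
    gene_arr = np.array(cand.gene_ids)
    n = cand.n_samples
    correct = {m: 0 for m in gene_grid}
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        tr = values[:, keep]
        tr_mask = mask[keep]
        n1, n2 = int(tr_mask.sum()), int((~tr_mask).sum())
        x1, x2 = tr[:, tr_mask], tr[:, ~tr_mask]
        m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
        ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
        sd = np.sqrt(ss / (n1 + n2 - 2))
        if np.any(sd == 0):
            return None
        if reselect_in_folds:
            sp = sd  # pooled SD doubles as the t denominator scale
            t = (m1 - m2) / (sp * np.sqrt(1.0 / n1 + 1.0 / n2))
        else:
            t = t_full.to_numpy()
        order_up = np.lexsort((gene_arr, -t))
        order_dn = np.lexsort((gene_arr, t))
        x = values[:, i]
        contrib = ((x - np.stack([m1, m2])) / sd) ** 2  # classes x genes
        cum_up = np.concatenate(
            [np.zeros((2, 1)), np.cumsum(contrib[:, order_up], axis=1)], axis=1
        )
        cum_dn = np.concatenate(
            [np.zeros((2, 1)), np.cumsum(contrib[:, order_dn], axis=1)], axis=1
        )
        truth_idx = 0 if mask[i] else 1
        for m in gene_grid:
            h = m // 2
            d = cum_up[:, h] + cum_dn[:, h]
            if int(np.argmin(d)) == truth_idx:
                correct[m] += 1
    return {m: c / n for m, c in correct.items()}


def _loocv_accuracy(
    norm: ExpressionMatrix,
    mask: np.ndarray,
    class_labels: list[str],
    candidates: list[str],
    gene_grid: list[int],
    distance_kind: str,
    s0: float,
    balanced: bool,
    reselect_in_folds: bool,
    t_full: pd.Series,
) -> dict[int, float]:
    """Held-out accuracy per grid value; selection recomputed inside each
    fold (default) so held-out samples never inform gene ranking."""
    if (distance_kind == STANDARDIZED and s0 == 0.0 and balanced
            and all(m % 2 == 0 for m in gene_grid)):
        fast = _loocv_accuracy_fast(
            norm, mask, candidates, gene_grid, reselect_in_folds, t_full
        )
        if fast is not None:
            return fast
    n = norm.n_samples
    cand_matrix = norm.subset_genes(candidates)
    labels_str = np.where(mask, class_labels[0], class_labels[1])
    correct = {m: 0 for m in gene_grid}
    for i in range(n):
        train_idx = [j for j in range(n) if j != i]
        train = cand_matrix.subset_samples([cand_matrix.sample_ids[j] for j in train_idx])
        train_mask = mask[train_idx]
        if reselect_in_folds:
            t = gene_t_statistics(train, train_mask, s0=0.0)
        else:
            t = t_full
        for m in gene_grid:
            genes = select_top_genes(t, m, balanced=balanced)
            model = fit_centroids(
                train, labels_str[train_idx], genes,
                distance_kind=distance_kind, s0=s0, class_labels=class_labels,
            )
            held = norm.subset_samples([norm.sample_ids[i]]).subset_genes(genes)
            pred = predict(model, held)["predicted_class"].iloc[0]
            if pred == labels_str[i]:
                correct[m] += 1
    return {m: c / n for m, c in correct.items()}


def train_response_classifier(
    norm: ExpressionMatrix,
    labels: np.ndarray | pd.Series,
    params: CandidateFilterParams = CandidateFilterParams(),
    gene_grid: list[int] | None = None,
    distance_kind: str = STANDARDIZED,
    s0: float = 0.0,
    balanced: bool = True,
    reselect_in_folds: bool = True,
    class_labels: tuple[str, str] = ("CR/PR", "SD/PD"),
) -> CentroidModel:
    """Train the cross-validated nearest-centroid response classifier.

    Candidate filtering runs once on the full matrix (it is label-free);
    the per-fold t-ranking and top-m/2-up / m/2-down selection run inside
    each leave-one-out fold. The returned model is refitted on all samples
    at the LOOCV-best gene count (ties toward the smallest count) and
    carries the full cv_trace.
    """
    _require_norm(norm, "train_response_classifier")
    mask = _as_binary_labels(labels, norm.sample_ids)
    if mask.sum() < 3 or (~mask).sum() < 3:
        raise ValueError("each response class needs at least 3 samples")
    if gene_grid is None:
        gene_grid = list(range(4, 101, 2))
    if not gene_grid:
        raise ValueError("gene_grid must be non-empty")

    candidates = select_candidates(norm, params)
    if len(candidates) < 2:
        raise ValueError("candidate filter left fewer than 2 genes")
    grid = sorted(set(int(m) for m in gene_grid))
    usable = [m for m in grid if m <= len(candidates)]
    if len(usable) < len(grid):
        warnings.warn(
            f"gene grid truncated to m <= {len(candidates)} (candidate count)"
        )
    if not usable:
        raise ValueError("no grid value fits within the candidate gene count")

    cand_matrix = norm.subset_genes(candidates)
    t_full = gene_t_statistics(cand_matrix, mask, s0=0.0)
    acc = _loocv_accuracy(
        norm, mask, list(class_labels), candidates, usable,
        distance_kind, s0, balanced, reselect_in_folds, t_full,
    )
    best_m = max(usable, key=lambda m: (acc[m], -m))
    final_genes = select_top_genes(t_full, best_m, balanced=balanced)
    labels_str = np.where(mask, class_labels[0], class_labels[1])
    model = fit_centroids(
        norm, labels_str, final_genes,
        distance_kind=distance_kind, s0=s0, class_labels=list(class_labels),
    )
    model.cv_trace = [(m, acc[m]) for m in usable]
    return model


def train_subtype_classifier(
    norm: ExpressionMatrix,
    subtype_labels: pd.Series,
    gene_list: list[str],
    test_size: float = 1 / 3,
    seed: int = 0,
    max_retries: int = 20,
    distance_kind: str = STANDARDIZED,
    s0: float = 0.0,
) -> tuple[CentroidModel, float]:
    """Centroid subtype classifier with a stratified 2/3 - 1/3 split.

    Genes are restricted to ``gene_list`` (all must be present) and
    median-centered on the training split; the centering offsets are stored
    on the model so test (and future) samples are centered identically.
    Returns the fitted model and the held-out accuracy.
    """
    _require_norm(norm, "train_subtype_classifier")
    missing = [g for g in gene_list if g not in set(norm.gene_ids)]
    if missing:
        raise KeyError(f"subtype gene list absent from matrix: {missing}")
    labels = subtype_labels.reindex(norm.sample_ids)
    if labels.isna().any():
        raise ValueError("subtype labels missing for some samples")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least two subtypes")

    samples = np.array(norm.sample_ids)
    split = None
    for attempt in range(max_retries):
        try:
            tr, te = train_test_split(
                samples, test_size=test_size, random_state=seed + attempt,
                stratify=labels.to_numpy(),
            )
        except ValueError:
            tr, te = train_test_split(
                samples, test_size=test_size, random_state=seed + attempt
            )
        if set(labels[tr]) == set(classes) and len(te) > 0:
            split = (list(tr), list(te))
            break
    if split is None:
        raise ValueError(
            f"could not produce a split containing every subtype in {max_retries} tries"
        )
    train_ids, test_ids = split
    train = norm.subset_samples(train_ids).subset_genes(gene_list)
    offsets = np.median(train.values, axis=1)
    model = fit_centroids(
        train, labels[train_ids], gene_list,
        distance_kind=distance_kind, s0=s0, class_labels=classes,
        center_offsets=offsets,
    )
    test = norm.subset_samples(test_ids)
    pred = predict(model, test)["predicted_class"]
    accuracy = float((pred.to_numpy() == labels[test_ids].to_numpy()).mean())
    return model, accuracy


# ---------------------------------------------------------------------------
# Model / Results presentation layer
# ---------------------------------------------------------------------------


class CentroidResults:
    """Fitted-model results: centroids, CV trace, and a summary table."""

    def __init__(self, model: CentroidModel, model_spec: object | None = None,
                 extra: dict | None = None) -> None:
        self.model = model
        self.model_spec = model_spec
        self.extra = dict(extra or {})

    @property
    def selected_genes(self) -> list[str]:
        return self.model.selected_genes

    @property
    def cv_trace(self) -> pd.DataFrame:
        return pd.DataFrame(self.model.cv_trace, columns=["n_genes", "cv_accuracy"])

    @property
    def cv_accuracy(self) -> float | None:
        trace = dict(self.model.cv_trace)
        return trace.get(self.model.chosen_n_genes)

    def predict(self, norm: ExpressionMatrix) -> pd.DataFrame:
        return predict(self.model, norm)

    def centroid_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.model.centroids.T,
            index=self.model.selected_genes,
            columns=self.model.class_labels,
        )

    def summary(self) -> str:
        lines = [
            "Nearest-centroid classifier",
            "=" * 46,
            f"classes:          {' vs '.join(self.model.class_labels)}",
            f"selected genes:   {self.model.chosen_n_genes}",
            f"distance:         {self.model.distance_kind} (s0 = {self.model.s0:.4g})",
        ]
        if self.cv_accuracy is not None:
            lines.append(f"LOOCV accuracy:   {self.cv_accuracy:.3f} at m = "
                         f"{self.model.chosen_n_genes}")
        for key, val in self.extra.items():
            lines.append(f"{key + ':':<18}{val}")
        up = self.centroid_frame()
        direction = up[self.model.class_labels[0]] - up[self.model.class_labels[1]]
        top = direction.abs().sort_values(ascending=False).head(10).index
        lines.append("top genes (|centroid difference|):")
        for g in top:
            lines.append(f"  {g:<14}{direction[g]:+.3f}")
        return "\n".join(lines)


class NearestCentroidResponse:
    """Treatment-response nearest-centroid model (CR/PR vs SD/PD).

    Construct from a normalized expression matrix and per-sample response
    labels; ``fit()`` runs candidate filtering, in-fold gene selection,
    LOOCV gene-count choice, and the final refit, returning a
    :class:`CentroidResults`.
    """

    def __init__(
        self,
        norm: ExpressionMatrix,
        labels: np.ndarray | pd.Series,
        params: CandidateFilterParams = CandidateFilterParams(),
        gene_grid: list[int] | None = None,
        distance_kind: str = STANDARDIZED,
        s0: float = 0.0,
        balanced: bool = True,
        reselect_in_folds: bool = True,
    ) -> None:
        self.norm = norm
        self.labels = labels
        self.params = params
        self.gene_grid = gene_grid
        self.distance_kind = distance_kind
        self.s0 = s0
        self.balanced = balanced
        self.reselect_in_folds = reselect_in_folds

    @classmethod
    def from_clinical(cls, norm: ExpressionMatrix, clinical, **kwargs
                      ) -> "NearestCentroidResponse":
        """Build from a ClinicalTable, using evaluable samples only."""
        labels = clinical.responder_labels()
        keep = [s for s in norm.sample_ids if s in labels.index]
        return cls(norm.subset_samples(keep), labels.loc[keep], **kwargs)

    def fit(self) -> CentroidResults:
        model = train_response_classifier(
            self.norm, self.labels, params=self.params, gene_grid=self.gene_grid,
            distance_kind=self.distance_kind, s0=self.s0, balanced=self.balanced,
            reselect_in_folds=self.reselect_in_folds,
        )
        return CentroidResults(model, model_spec=self)


class SubtypeCentroid:
    """ccA/ccB-style subtype centroid model on a fixed gene list."""

    def __init__(self, norm: ExpressionMatrix, subtype_labels: pd.Series,
                 gene_list: list[str], test_size: float = 1 / 3) -> None:
        self.norm = norm
        self.subtype_labels = subtype_labels
        self.gene_list = list(gene_list)
        self.test_size = test_size

    def fit(self, seed: int = 0) -> CentroidResults:
        model, accuracy = train_subtype_classifier(
            self.norm, self.subtype_labels, self.gene_list,
            test_size=self.test_size, seed=seed,
        )
        return CentroidResults(model, model_spec=self,
                               extra={"test accuracy": f"{accuracy:.3f}"})
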