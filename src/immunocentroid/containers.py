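"""Core data containers and their text serializations.

Expression data travel as a gene x sample matrix with an explicit layer tag
so downstream stages can enforce "counts in, log-normalized out" contracts.
Clinical data are a per-sample table with best response, a clinical-benefit
flag, and right-censored OS/PFS endpoints. Gene sets use the GMT dialect
(tab-separated: name, description, genes...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

COUNTS = "counts"
LOG_NORMALIZED = "log_normalized"

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD", "NA")
RESPONDER_CLASSES = ("CR/PR", "SD/PD")


@dataclass
class ExpressionMatrix:
    """Gene x sample numeric matrix with a layer tag.

    Parameters
    ----------
    gene_ids : ordered unique gene identifiers (rows).
    sample_ids : ordered unique sample identifiers (columns).
    values : 2-D array of shape (n_genes, n_samples).
    layer : ``"counts"`` (non-negative integers) or ``"log_normalized"``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    layer: str = COUNTS

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if self.layer not in (COUNTS, LOG_NORMALIZED):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.layer == COUNTS:
            if np.any(self.values < 0) or np.any(self.values != np.round(self.values)):
                raise ValueError("counts layer requires non-negative integer values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, layer: str = COUNTS) -> "ExpressionMatrix":
        return cls(
            gene_ids=list(frame.index.astype(str)),
            sample_ids=list(frame.columns.astype(str)),
            values=frame.to_numpy(dtype=float),
            layer=layer,
        )

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        """Row subset in the given order; raises on missing genes."""
        genes = [str(g) for g in genes]
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(genes, list(self.sample_ids), self.values[rows], self.layer)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = [str(s) for s in samples]
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing}")
        cols = [index[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), samples, self.values[:, cols], self.layer)

    def write_tsv(self, path: str | Path) -> None:
        """Tab-separated text: first column ``gene_id``, one column per sample."""
        frame = self.to_frame()
        frame.index.name = "gene_id"
        frame.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, layer: str = COUNTS) -> "ExpressionMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(frame, layer=layer)


@dataclass
class FilterReport:
    """Bookkeeping for a gene-filtering step."""

    n_genes_in: int
    n_genes_out: int
    removed_gene_ids: list[str]

    def __post_init__(self) -> None:
        if self.n_genes_out + len(self.removed_gene_ids) != self.n_genes_in:
            raise ValueError("filter report does not balance: in != out + removed")

    def to_dict(self) -> dict:
        return {
            "n_genes_in": self.n_genes_in,
            "n_genes_out": self.n_genes_out,
            "removed_gene_ids": list(self.removed_gene_ids),
        }


CLINICAL_COLUMNS = [
    "sample_id",
    "best_response",
    "clinical_benefit",
    "os_months",
    "os_event",
    "pfs_months",
    "pfs_event",
]


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations.

    ``best_response`` takes RECIST-style categories CR/PR/SD/PD plus "NA" for
    non-evaluable patients. ``clinical_benefit`` marks CR, PR, or stable
    disease lasting at least six months. OS/PFS are right-censored times in
    months with boolean event indicators (True = event observed).
    Extra columns are carried along as covariates.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in clinical table")
        df["best_response"] = df["best_response"].fillna("NA").astype(str)
        bad = set(df["best_response"]) - set(RESPONSE_CATEGORIES)
        if bad:
            raise ValueError(f"unknown best_response categories: {sorted(bad)}")
        for col in ("os_months", "pfs_months"):
            df[col] = df[col].astype(float)
            if (df[col] < 0).any():
                raise ValueError(f"negative times in {col}")
        for col in ("os_event", "pfs_event"):
            df[col] = df[col].astype(bool)
        benefit = df["clinical_benefit"]
        known = benefit.notna()
        df.loc[known, "clinical_benefit"] = benefit[known].astype(bool)
        # benefit implies disease control: CR, PR or SD
        viol = df.loc[known & benefit.fillna(False).astype(bool), "best_response"]
        bad_rows = viol[~viol.isin(["CR", "PR", "SD"])]
        if len(bad_rows):
            raise ValueError(
                "clinical_benefit=True requires best_response in {CR, PR, SD}; "
                f"violated for responses {sorted(set(bad_rows))}"
            )
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def responder_labels(self) -> pd.Series:
        """CR/PR vs SD/PD labels indexed by sample, NA samples dropped."""
        df = self.data.set_index("sample_id")
        resp = df["best_response"]
        labels = resp[resp != "NA"].map(
            lambda r: RESPONDER_CLASSES[0] if r in ("CR", "PR") else RESPONDER_CLASSES[1]
        )
        return labels

    def covariate_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in CLINICAL_COLUMNS]

    def write_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out["os_event"] = out["os_event"].astype(int)
        out["pfs_event"] = out["pfs_event"].astype(int)
        if out["clinical_benefit"].notna().all():
            out["clinical_benefit"] = out["clinical_benefit"].astype(bool).astype(int)
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ClinicalTable":
        df = pd.read_csv(path, dtype={"sample_id": str})
        if "clinical_benefit" in df.columns and df["clinical_benefit"].notna().all():
            df["clinical_benefit"] = df["clinical_benefit"].astype(float).astype(bool)
        return cls(df)


class GeneSetCollection:
    """Named gene lists with optional provenance notes.

    Duplicate genes within a set are collapsed (first occurrence kept);
    empty sets are rejected.
    """

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        provenance: Mapping[str, str] | None = None,
    ) -> None:
        self.sets: dict[str, list[str]] = {}
        for name, genes in sets.items():
            seen: dict[str, None] = {}
            for g in genes:
                seen.setdefault(str(g))
            if not seen:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[str(name)] = list(seen)
        self.provenance = {str(k): str(v) for k, v in (provenance or {}).items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, genes in self.sets.items():
                desc = self.provenance.get(name, "na")
                fh.write("\t".join([name, desc, *genes]) + "\n")

    @classmethod
    def read_gmt(cls, path: str | Path) -> "GeneSetCollection":
        sets: dict[str, list[str]] = {}
        prov: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"malformed GMT line (need name, desc, >=1 gene): {line!r}")
                name, desc, *genes = parts
                sets[name] = [g for g in genes if g]
                prov[name] = desc
        return cls(sets, prov)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene identifier per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
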