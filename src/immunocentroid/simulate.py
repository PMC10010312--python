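"""Synthetic RNA-seq cohort generator.

Emulates the statistical structure the downstream analysis assumes: a small
immunotherapy cohort (~35 patients, ~37% responders) with negative-binomial
counts, a handful of planted gene programs elevated (or depleted) in
responders, best-response categories split to realistic CR:PR and SD:PD
proportions, and exponential (optionally Weibull) survival whose hazard
depends on an immune-high flag.

Counts for gene g, sample i are NB with mean mu_g (times 2**effect for
program genes in responders) and variance mu + dispersion * mu**2; per-gene
baseline means are log-normal. Censoring is an independent exponential time
whose rate is chosen so the expected censored fraction at baseline equals
``censoring_rate``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import COUNTS, ClinicalTable, ExpressionMatrix

#: CR:PR split among responders and SD:PD split among non-responders,
#: matching a ~35-patient IL2 cohort (1 CR : 12 PR; 6 SD : 16 PD).
DEFAULT_CR_FRACTION = 1 / 13
DEFAULT_SD_FRACTION = 6 / 22
#: fraction of SD patients whose stable disease lasts >= 6 months and hence
#: counts as clinical benefit (2 of 6 in the emulated cohort).
DEFAULT_SD_BENEFIT_FRACTION = 2 / 6


@dataclass
class SurvivalSpec:
    """Baseline survival model for the simulated cohort.

    baseline_median_months applies to immune-low samples; immune-high
    samples get hazard multiplied by exp(log_hazard_ratio). ``shape`` = 1
    is exponential; other positive values give a Weibull with that shape
    under proportional hazards.
    """

    baseline_median_months: float = 60.0
    log_hazard_ratio_immune_high: float = math.log(2.0)
    censoring_rate: float = 0.3
    shape: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_median_months <= 0:
            raise ValueError("baseline_median_months must be positive")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.shape <= 0:
            raise ValueError("Weibull shape must be positive")


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort.

    program_specs is a list of (name, n_genes, log2 effect in responders);
    program gene lists are disjoint and drawn from the gene universe. The
    first program defines the immune-high flag (top half of samples by mean
    log2(1+count) over its genes).
    """

    n_samples: int = 35
    n_genes: int = 2000
    responder_fraction: float = 0.37
    program_specs: list[tuple[str, int, float]] = field(
        default_factory=lambda: [("immune", 40, 1.0)]
    )
    baseline_log_mean: tuple[float, float] = (4.0, 1.2)
    #: NB dispersion alpha (var = mu + alpha mu^2); 0.16 corresponds to the
    #: conventional biological CV of 0.4 for human clinical RNA-seq cohorts.
    dispersion: float = 0.16
    #: program genes are drawn from genes whose baseline mean is at or above
    #: this quantile of the universe -- immune programs live among expressed
    #: genes, not in the near-zero tail.
    program_expression_quantile: float = 0.5
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    cr_fraction: float = DEFAULT_CR_FRACTION
    sd_fraction: float = DEFAULT_SD_FRACTION
    sd_benefit_fraction: float = DEFAULT_SD_BENEFIT_FRACTION
    pfs_scale: float = 1 / 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0:
            raise ValueError("n_samples and n_genes must be positive")
        if not 0.0 < self.responder_fraction < 1.0:
            raise ValueError("responder_fraction must lie in (0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        names = [name for name, _, _ in self.program_specs]
        if len(set(names)) != len(names):
            raise ValueError("program names must be unique")
        total = sum(n for _, n, _ in self.program_specs)
        if total > self.n_genes:
            raise ValueError(
                f"programs need {total} genes but the universe has only {self.n_genes}"
            )
        for name, n, _ in self.program_specs:
            if n <= 0:
                raise ValueError(f"program {name!r} must contain at least one gene")
        if isinstance(self.survival, (tuple, list)):
            self.survival = SurvivalSpec(*self.survival)

    @property
    def program_names(self) -> list[str]:
        return [name for name, _, _ in self.program_specs]


@dataclass
class SimTruth:
    """Planted ground truth of a simulated cohort, for recovery tests."""

    responder_labels: np.ndarray  # boolean per sample
    program_genes: dict[str, list[str]]
    realized_effects: dict[str, float]
    immune_high_flag: np.ndarray  # boolean per sample

    def __post_init__(self) -> None:
        self.responder_labels = np.asarray(self.responder_labels, dtype=bool)
        self.immune_high_flag = np.asarray(self.immune_high_flag, dtype=bool)
        if self.responder_labels.shape != self.immune_high_flag.shape:
            raise ValueError("label vectors must have equal length")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "responder_labels": self.responder_labels.astype(int).tolist(),
            "program_genes": self.program_genes,
            "realized_effects": self.realized_effects,
            "immune_high_flag": self.immune_high_flag.astype(int).tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            responder_labels=np.array(payload["responder_labels"], dtype=bool),
            program_genes={k: list(v) for k, v in payload["program_genes"].items()},
            realized_effects={k: float(v) for k, v in payload["realized_effects"].items()},
            immune_high_flag=np.array(payload["immune_high_flag"], dtype=bool),
        )


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draw parameterized by mean and dispersion alpha (var = mu + alpha mu^2)."""
    size = 1.0 / dispersion  # numpy's n parameter
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _survival_times(
    rng: np.random.Generator,
    spec: SurvivalSpec,
    immune_high: np.ndarray,
    median_months: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Event/censoring draw under a proportional-hazards Weibull.

    S(t) = exp(-(t/scale)^shape * exp(lhr * x)); shape 1 is exponential.
    Returns (observed time, event indicator).
    """
    n = len(immune_high)
    scale = median_months / math.log(2.0) ** (1.0 / spec.shape)
    hr = np.exp(spec.log_hazard_ratio_immune_high * immune_high.astype(float))
    # T = scale * (E / hr)^(1/shape) with E ~ Exp(1)
    event_t = scale * (rng.exponential(1.0, size=n) / hr) ** (1.0 / spec.shape)
    if spec.censoring_rate == 0.0:
        return event_t, np.ones(n, dtype=bool)
    # exponential censoring with P(C < T) = censoring_rate at baseline
    base_rate = math.log(2.0) / median_months
    cens_rate = base_rate * spec.censoring_rate / (1.0 - spec.censoring_rate)
    cens_t = rng.exponential(1.0 / cens_rate, size=n)
    observed = np.minimum(event_t, cens_t)
    event = event_t <= cens_t
    return observed, event


def _assign_responses(
    responders: np.ndarray, config: SimConfig
) -> tuple[list[str], np.ndarray]:
    """Deterministic best-response and benefit assignment given labels.

    Within each arm, categories are assigned by sample order: the first
    round(n * fraction) responders are CR (rest PR), the first
    round(n * sd_fraction) non-responders are SD (rest PD); the first
    round(n_SD * sd_benefit_fraction) SD patients carry clinical benefit.
    """
    n = len(responders)
    response = [""] * n
    resp_idx = np.flatnonzero(responders)
    nonresp_idx = np.flatnonzero(~responders)
    n_cr = int(round(len(resp_idx) * config.cr_fraction))
    n_sd = int(round(len(nonresp_idx) * config.sd_fraction))
    for j, i in enumerate(resp_idx):
        response[i] = "CR" if j < n_cr else "PR"
    for j, i in enumerate(nonresp_idx):
        response[i] = "SD" if j < n_sd else "PD"
    benefit = responders.copy()
    sd_idx = [i for i in nonresp_idx if response[i] == "SD"]
    n_sd_benefit = int(round(len(sd_idx) * config.sd_benefit_fraction))
    for i in sd_idx[:n_sd_benefit]:
        benefit[i] = True
    return response, benefit


def simulate_cohort(config: SimConfig) -> tuple[ExpressionMatrix, ClinicalTable, SimTruth]:
    """Generate one paired expression + clinical cohort.

    Returns a counts-layer ExpressionMatrix, a ClinicalTable, and the
    planted SimTruth. Identical configs (including seed) give identical
    outputs.
    """
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genes

    gene_ids = [f"G{i:05d}" for i in range(g)]
    sample_ids = [f"S{i:03d}" for i in range(n)]

    log_mu, log_sigma = config.baseline_log_mean
    base_mean = np.exp(rng.normal(log_mu, log_sigma, size=g))

    # disjoint program gene lists drawn without replacement from the
    # adequately-expressed part of the universe
    total_program = sum(spec[1] for spec in config.program_specs)
    cut = np.quantile(base_mean, config.program_expression_quantile)
    eligible = np.flatnonzero(base_mean >= cut)
    if len(eligible) < total_program:
        raise ValueError(
            f"programs need {total_program} genes but only {len(eligible)} are "
            f"at or above the expression quantile {config.program_expression_quantile}"
        )
    pool = rng.choice(eligible, size=total_program, replace=False)
    program_genes: dict[str, list[str]] = {}
    program_rows: dict[str, np.ndarray] = {}
    offset = 0
    for name, size, _ in config.program_specs:
        rows = np.sort(pool[offset : offset + size])
        program_rows[name] = rows
        program_genes[name] = [gene_ids[i] for i in rows]
        offset += size

    n_resp = max(1, min(n - 1, int(round(n * config.responder_fraction))))
    responders = np.zeros(n, dtype=bool)
    responders[rng.choice(n, size=n_resp, replace=False)] = True

    mean = np.tile(base_mean[:, None], (1, n))
    effects = {name: float(eff) for name, _, eff in config.program_specs}
    for name, rows in program_rows.items():
        mean[np.ix_(rows, responders)] *= 2.0 ** effects[name]

    counts = _nb_counts(rng, mean, config.dispersion)
    matrix = ExpressionMatrix(gene_ids, sample_ids, counts.astype(float), COUNTS)

    # immune-high flag: top half of samples by mean log2(1+count) over the
    # first program's genes (the planted immune program score)
    first = config.program_names[0]
    score = np.log2(1.0 + counts[program_rows[first], :]).mean(axis=0)
    order = np.argsort(-score, kind="stable")
    immune_high = np.zeros(n, dtype=bool)
    immune_high[order[: n // 2 + n % 2]] = True

    response, benefit = _assign_responses(responders, config)
    os_t, os_e = _survival_times(rng, config.survival, immune_high,
                                 config.survival.baseline_median_months)
    pfs_t, pfs_e = _survival_times(rng, config.survival, immune_high,
                                   config.survival.baseline_median_months * config.pfs_scale)

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "best_response": response,
                "clinical_benefit": benefit,
                "os_months": np.round(os_t, 4),
                "os_event": os_e,
                "pfs_months": np.round(pfs_t, 4),
                "pfs_event": pfs_e,
                "immune_high": immune_high.astype(int),
            }
        )
    )
    truth = SimTruth(
        responder_labels=responders,
        program_genes=program_genes,
        realized_effects=effects,
        immune_high_flag=immune_high,
    )
    return matrix, clinical, truth


def default_contrasting_configs(
    seed_il2: int = 0, seed_pd1: int = 1
) -> tuple[SimConfig, SimConfig]:
    """Default paired cohorts: effector program elevated in responders of
    both, myeloid program elevated in IL2-like responders but depleted in
    anti-PD-1-like responders."""
    il2 = SimConfig(
        program_specs=[("teff", 8, 1.0), ("myeloid", 6, 1.0)],
        seed=seed_il2,
    )
    pd1 = SimConfig(
        program_specs=[("teff", 8, 1.0), ("myeloid", 6, -1.0)],
        seed=seed_pd1,
    )
    return il2, pd1


def simulate_contrasting_cohorts(
    config_il2: SimConfig, config_pd1: SimConfig
) -> tuple[
    tuple[ExpressionMatrix, ClinicalTable, SimTruth],
    tuple[ExpressionMatrix, ClinicalTable, SimTruth],
]:
    """Generate an IL2-like and an anti-PD-1-like cohort sharing a myeloid
    program whose responder association flips sign between them."""
    shared = set(config_il2.program_names) & set(config_pd1.program_names)
    if "myeloid" not in shared:
        raise ValueError(
            "both configs must define a shared 'myeloid' program; "
            f"shared programs: {sorted(shared)}"
        )
    return simulate_cohort(config_il2), simulate_cohort(config_pd1)
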