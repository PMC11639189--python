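"""Synthetic multiple-myeloma cohort generator.

Emulates the statistical design the signature pipeline assumes: a cohort of
CD138+ tumor expression profiles (log2 scale) in which a small set of
"driver" genes is recurrently mutated, mutation status shifts the mean
expression of a hidden target-gene set, age/gender covariates exist,
survival follows a proportional-hazards model linked to a latent risk score,
binary treatment response follows a logistic model on the same score, and
(optionally) paired whole-bone-marrow profiles are exact two-component
mixtures of tumor and microenvironment expression with known fractions.

Everything is seeded: the same :class:`CohortConfig` always yields
byte-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "ConfigurationError",
    "DriverSpec",
    "SurvivalSpec",
    "ResponseSpec",
    "MixingSpec",
    "CohortConfig",
    "PairedBoneMarrow",
    "SyntheticCohort",
    "generate_cohort",
    "generate_survival",
    "generate_paired_bone_marrow",
    "write_cohort",
]

NONSYNONYMOUS_CLASSES = ("missense", "missense_splice", "stop_gain", "frameshift")

# Relative frequencies of somatic variant classes among non-synonymous calls;
# missense dominates exome call sets.
_NONSYN_CLASS_PROBS = {
    "missense": 0.75,
    "stop_gain": 0.12,
    "frameshift": 0.08,
    "missense_splice": 0.05,
}
# Synonymous calls added per driver as a fraction of its non-synonymous calls,
# so selection-ratio statistics are computable on generated tables.
_SYNONYMOUS_FRACTION = 0.3
# Shape of the gamma distribution of per-target effect magnitudes: shape < 1
# gives the many-weak/few-strong target profile typical of differential
# expression downstream of a driver mutation.
_EFFECT_SHAPE = 0.5


class ConfigurationError(ValueError):
    """Raised when a cohort configuration is internally inconsistent."""


@dataclass(frozen=True)
class DriverSpec:
    """One recurrently mutated driver gene and its transcriptomic footprint.

    Parameters
    ----------
    gene : str
        Gene symbol used in the mutation table and expression matrix.
    frequency : float
        Fraction of samples carrying a non-synonymous mutation.
    n_targets : int
        Number of hidden target genes whose mean expression shifts in
        mutated samples.
    effect : float
        Mean effect magnitude in units of the expression noise SD.
        Per-gene magnitudes are gamma-distributed (shape 0.5) around this
        mean: a perturbed pathway typically has many weakly and few
        strongly responding targets.
    sign_mix : float
        Probability that a target gene is up-regulated (the rest are
        down-regulated).
    """

    gene: str
    frequency: float = 0.15
    n_targets: int = 50
    effect: float = 2.0
    sign_mix: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.frequency <= 1.0):
            raise ConfigurationError(f"driver frequency must be in (0,1]: {self.frequency}")
        if not (0.0 <= self.sign_mix <= 1.0):
            raise ConfigurationError(f"sign_mix must be in [0,1]: {self.sign_mix}")
        if self.n_targets < 1:
            raise ConfigurationError("n_targets must be >= 1")
        if self.effect < 0:
            raise ConfigurationError("effect must be >= 0")


@dataclass(frozen=True)
class SurvivalSpec:
    """Proportional-hazards survival generator parameters.

    Event times are exponential with rate ``baseline_hazard *
    exp(log_hr * score)``; censoring times are independent exponentials
    calibrated so the expected censored fraction equals ``censoring``.
    """

    baseline_hazard: float = 0.02
    log_hr: float = math.log(2.0)
    censoring: float = 0.2

    def __post_init__(self) -> None:
        if self.baseline_hazard < 0:
            raise ConfigurationError("baseline hazard must be >= 0")
        if not (0.0 <= self.censoring <= 1.0):
            raise ConfigurationError("censoring fraction must be in [0,1]")


@dataclass(frozen=True)
class ResponseSpec:
    """Logistic treatment-response generator: logit P(responder) =
    logit(base_rate) + log_odds * score."""

    log_odds: float = -1.0
    base_rate: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.base_rate < 1.0):
            raise ConfigurationError("base_rate must be in (0,1)")


@dataclass(frozen=True)
class MixingSpec:
    """Tumor-fraction range for paired whole-bone-marrow mixtures."""

    p_range: tuple[float, float] = (0.2, 0.8)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.p_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ConfigurationError(f"mixing fractions must satisfy 0 <= lo <= hi < 1: {self.p_range}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    n_samples: int = 500
    n_genes: int = 1000
    drivers: tuple[DriverSpec, ...] = (DriverSpec("TP53"),)
    noise_sd: float = 1.0
    age_range: tuple[float, float] = (40.0, 80.0)
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    response: ResponseSpec = field(default_factory=ResponseSpec)
    mixing: MixingSpec = field(default_factory=MixingSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 20:
            raise ConfigurationError("n_samples must be >= 20")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        names = [d.gene for d in self.drivers]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate driver gene names")
        needed = len(self.drivers) + sum(d.n_targets for d in self.drivers)
        if needed > self.n_genes:
            raise ConfigurationError(
                f"drivers plus disjoint target sets need {needed} genes, have {self.n_genes}"
            )


@dataclass
class PairedBoneMarrow:
    """Matched whole-bone-marrow / CD138+ profiles with known ground truth."""

    e_wbm: pd.DataFrame
    e_mm: pd.DataFrame
    p_mm: pd.Series
    time_profile: pd.DataFrame
    proportions: pd.DataFrame


@dataclass
class SyntheticCohort:
    expression: pd.DataFrame  # genes x samples, log2 scale
    mutations: pd.DataFrame  # sample_id, gene, variant_class
    clinical: pd.DataFrame  # sample_id-indexed covariates + outcomes
    truth: dict
    config: CohortConfig
    paired: PairedBoneMarrow | None = None


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(1, n + 1)]


def _gene_ids(config: CohortConfig) -> list[str]:
    driver_names = [d.gene for d in config.drivers]
    n_fill = config.n_genes - len(driver_names)
    fillers = [f"G{i:05d}" for i in range(1, n_fill + 1)]
    return driver_names + fillers


def generate_survival(
    linear_score: np.ndarray, spec: SurvivalSpec, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Draw (time, event) pairs from a proportional-hazards model.

    The log hazard is ``log(baseline_hazard) + log_hr * score``. Censoring
    times are independent exponentials whose rate is calibrated (by root
    finding) so that the expected fraction of censored records matches
    ``spec.censoring``.
    """
    score = np.asarray(linear_score, dtype=float)
    if not np.all(np.isfinite(score)):
        raise ValueError("scores must be finite")
    if spec.baseline_hazard < 0:
        raise ConfigurationError("baseline hazard must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rates = spec.baseline_hazard * np.exp(spec.log_hr * score)
    event_times = rng.exponential(1.0 / rates)

    if spec.censoring <= 0.0:
        time, event = event_times, np.ones_like(event_times, dtype=int)
    elif spec.censoring >= 1.0:
        # Fully administratively censored cohort: no events observed.
        time, event = event_times, np.zeros_like(event_times, dtype=int)
    else:

        def censored_fraction(mu: float) -> float:
            return float(np.mean(mu / (mu + rates))) - spec.censoring

        mean_rate = float(np.mean(rates))
        mu = brentq(censored_fraction, mean_rate * 1e-9, mean_rate * 1e9)
        censor_times = rng.exponential(1.0 / mu, size=score.shape)
        event = (event_times <= censor_times).astype(int)
        time = np.minimum(event_times, censor_times)
    return pd.DataFrame({"time": time, "event": event})


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort per the configuration.

    Mutated samples have the mean expression of their driver's target genes
    shifted by the per-gene true effect; the per-driver truth (target sets,
    signed effects, mutated sample lists) is stored for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    samples = _sample_ids(config.n_samples)
    genes = _gene_ids(config)

    gene_means = rng.normal(8.0, 2.0, size=config.n_genes)
    expr = gene_means[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, config.n_samples)
    )

    age = rng.uniform(*config.age_range, size=config.n_samples)
    gender = rng.integers(0, 2, size=config.n_samples)

    driver_names = [d.gene for d in config.drivers]
    non_driver_idx = np.arange(len(driver_names), config.n_genes)
    pool = rng.permutation(non_driver_idx)
    pool_pos = 0

    gene_arr = np.asarray(genes)
    mut_rows: list[tuple[str, str, str]] = []
    truth: dict = {"drivers": {}}
    classes = list(_NONSYN_CLASS_PROBS)
    class_p = np.array([_NONSYN_CLASS_PROBS[c] for c in classes])

    for driver in config.drivers:
        n_mut = max(1, int(round(driver.frequency * config.n_samples)))
        mutated_idx = rng.choice(config.n_samples, size=n_mut, replace=False)
        mutated_idx.sort()

        target_idx = pool[pool_pos : pool_pos + driver.n_targets]
        pool_pos += driver.n_targets

        magnitudes = rng.gamma(_EFFECT_SHAPE, driver.effect / _EFFECT_SHAPE, size=driver.n_targets)
        signs = np.where(rng.random(driver.n_targets) < driver.sign_mix, 1.0, -1.0)
        effects = signs * magnitudes  # in noise-SD units
        expr[np.ix_(target_idx, mutated_idx)] += (effects * config.noise_sd)[:, None]

        for si in mutated_idx:
            vclass = classes[rng.choice(len(classes), p=class_p)]
            mut_rows.append((samples[si], driver.gene, vclass))
        n_syn = int(round(_SYNONYMOUS_FRACTION * n_mut))
        if n_syn:
            syn_idx = rng.choice(config.n_samples, size=n_syn, replace=False)
            for si in syn_idx:
                mut_rows.append((samples[si], driver.gene, "synonymous"))

        truth["drivers"][driver.gene] = {
            "target_genes": gene_arr[target_idx].tolist(),
            "effects": effects.tolist(),
            "mutated_samples": [samples[i] for i in mutated_idx],
        }

    # Latent risk score: standardized, sign-corrected mean target expression
    # of the first driver. It is what a perfect signature would recover.
    first = config.drivers[0]
    tinfo = truth["drivers"][first.gene]
    t_idx = [genes.index(g) for g in tinfo["target_genes"]]
    t_signs = np.sign(np.asarray(tinfo["effects"]))
    raw = (t_signs[:, None] * (expr[t_idx, :] - expr[t_idx, :].mean(axis=1, keepdims=True))).mean(
        axis=0
    )
    sd_raw = raw.std(ddof=0)
    risk = (raw - raw.mean()) / sd_raw if sd_raw > 0 else np.zeros_like(raw)
    truth["risk_score"] = dict(zip(samples, risk.tolist()))

    surv = generate_survival(risk, config.survival, rng)

    p_resp = expit(logit(config.response.base_rate) + config.response.log_odds * risk)
    responder = (rng.random(config.n_samples) < p_resp).astype(int)
    resp_code = np.where(
        responder == 1,
        rng.choice(["CR", "PR", "MR"], size=config.n_samples),
        rng.choice(["NC", "PD"], size=config.n_samples),
    )

    clinical = pd.DataFrame(
        {
            "age": age,
            "gender": gender,
            "time": surv["time"].to_numpy(),
            "event": surv["event"].to_numpy(),
            "response": responder,
            "response_code": resp_code,
            "arm": "bortezomib",
        },
        index=pd.Index(samples, name="sample_id"),
    )

    expression = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=samples)
    mutations = pd.DataFrame(mut_rows, columns=["sample_id", "gene", "variant_class"])
    return SyntheticCohort(
        expression=expression,
        mutations=mutations,
        clinical=clinical,
        truth=truth,
        config=config,
    )


# Immune compartment used for paired bone-marrow mixtures. Granulocyte
# abundance is generated to decrease with the latent risk score, mirroring
# the kind of tumor-microenvironment shift the downstream analysis looks for.
_PLASMA_CATALOGS = ("Plasma cells", "B cells memory", "MM plasma cells", "PlasmaMemory")
_IMMUNE_CELLS = ("Granulocytes", "Macrophages", "T cells CD4", "T cells CD8", "NK cells", "Monocytes")
_IMMUNE_BASE_WEIGHTS = np.array([0.30, 0.15, 0.20, 0.15, 0.10, 0.10])


def generate_paired_bone_marrow(
    cohort: SyntheticCohort, config: CohortConfig | None = None
) -> SyntheticCohort:
    """Augment a cohort with paired whole-bone-marrow mixtures.

    The WBM profile is the exact convex combination
    ``E_wbm = p * E_mm + (1 - p) * E_time`` of the tumor (CD138+) profile and
    a generated microenvironment profile; optional measurement noise
    (``mixing.noise_sd``) is added afterwards. A cell-proportion matrix with
    plasma catalogs summing to ``p`` per sample is generated alongside.
    """
    config = config or cohort.config
    lo, hi = config.mixing.p_range
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    samples = cohort.expression.columns
    genes = cohort.expression.index
    n_s, n_g = len(samples), len(genes)

    p = rng.uniform(lo, hi, size=n_s)
    time_means = rng.normal(8.0, 2.0, size=n_g)
    e_time = time_means[:, None] + rng.normal(0.0, config.noise_sd, size=(n_g, n_s))

    e_mm = cohort.expression.to_numpy()
    e_wbm = p[None, :] * e_mm + (1.0 - p)[None, :] * e_time
    if config.mixing.noise_sd > 0:
        e_wbm = e_wbm + rng.normal(0.0, config.mixing.noise_sd, size=e_wbm.shape)

    risk = np.array([cohort.truth["risk_score"][s] for s in samples])
    weights = np.tile(_IMMUNE_BASE_WEIGHTS, (n_s, 1)).astype(float)
    weights[:, 0] *= np.exp(-0.5 * risk)  # granulocytes shrink with risk
    weights *= rng.lognormal(0.0, 0.15, size=weights.shape)
    weights /= weights.sum(axis=1, keepdims=True)
    immune = (1.0 - p)[:, None] * weights

    plasma_split = rng.dirichlet(np.ones(len(_PLASMA_CATALOGS)), size=n_s)
    plasma = p[:, None] * plasma_split

    proportions = pd.DataFrame(
        np.hstack([plasma, immune]),
        index=pd.Index(samples, name="sample_id"),
        columns=list(_PLASMA_CATALOGS) + list(_IMMUNE_CELLS),
    )

    cohort.paired = PairedBoneMarrow(
        e_wbm=pd.DataFrame(e_wbm, index=genes, columns=samples),
        e_mm=cohort.expression,
        p_mm=pd.Series(p, index=samples, name="p_mm"),
        time_profile=pd.DataFrame(e_time, index=genes, columns=samples),
        proportions=proportions,
    )
    return cohort


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write the standard tab-delimited cohort file set plus a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.expression.to_csv(outdir / "expression.tsv", sep="\t")
    cohort.mutations.to_csv(outdir / "mutations.tsv", sep="\t", index=False)
    cohort.clinical.to_csv(outdir / "clinical.tsv", sep="\t")
    truth = dict(cohort.truth)
    truth["config"] = asdict(cohort.config)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    if cohort.paired is not None:
        cohort.paired.e_wbm.to_csv(outdir / "expression_wbm.tsv", sep="\t")
        cohort.paired.proportions.to_csv(outdir / "cell_proportions.tsv", sep="\t")
        cohort.paired.p_mm.to_frame().to_csv(outdir / "tumor_fraction.tsv", sep="\t")
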