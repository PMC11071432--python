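"""Synthetic multi-site, multi-batch TMT-style cohort generator.

Emulates the statistical structure of a large multi-center brain TMT
proteome: batches nested within contributing sites, protein-specific
additive batch offsets on the log2 scale, planted sex-, race-, and
diagnosis-linked marker proteins, an age trend, a latent neuropathology
variable that drives both the ordinal CERAD/Braak scores and the
AD-marker effects, an APOE-ε4-specific peptide row with bimodal
carrier/non-carrier signal, rare global-shift outlier samples, and
intensity-dependent (MNAR) missingness.

Everything planted is recorded in :class:`GroundTruth` so parameter-recovery
tests can compare estimates against the generative draw.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .containers import AbundanceMatrix, SampleMetadata, METADATA_COLUMNS
from .errors import ConfigError

#: Reserved row id for the APOE ε4 allele-specific tryptic peptide signal.
APOE4_PEPTIDE_ID = "APOE4|LGADMEDVR"

_SITE_NAMES = ("Emory", "Mayo", "MountSinai", "Rush")
_RACES = ("AfricanAmerican", "LatinoAmerican", "NHW", "other")
_RACE_PROBS = (0.30, 0.20, 0.48, 0.02)
_DIAGNOSES = ("AD", "control", "other")
_DIAG_PROBS = (0.55, 0.35, 0.10)

# CERAD (0-3) and Braak (0-6) cutpoints on the latent pathology axis, which
# is scaled so controls average 0 and AD cases average 1.
_CERAD_CUTS = (0.2, 0.5, 0.8)
_BRAAK_CUTS = (-0.1, 0.15, 0.35, 0.55, 0.75, 0.95)


@dataclass
class SimulationConfig:
    """Parameters of the generative model.

    Sizes default to a desk-scale cohort that keeps the study's shape
    (≈15 samples per batch, batches nested in 4 sites); the
    :meth:`dlpfc_like` and :meth:`stg_like` presets carry the full cohort
    dimensions.  Effect sizes are in log2-abundance units.
    """

    n_proteins: int = 400
    n_samples: int = 240
    n_batches: int = 16
    n_sites: int = 4
    batch_sd: float = 0.3          # SD of per-protein, per-batch additive offsets
    site_sd: float = 0.0           # site-level offsets; 0 = batch-only structure
    noise_sd: float = 0.3          # residual log2 SD
    n_sex_markers: int = 10
    n_ad_markers: int = 10
    n_race_markers: int = 10
    effect_size_sex: float = 1.0
    effect_size_ad: float = 0.5
    effect_size_race: float = 0.5
    apoe4_carrier_freq: float = 0.35
    apoe4_log2_separation: float = 3.0   # ≥ 8-fold linear separation at default
    genotype_error_rate: float = 0.02
    n_outliers: int = 2
    outlier_shift: float = 3.0     # log2 units added to every protein of an outlier
    missing_rate_target: float = 0.15
    mnar_steepness: float = 1.0    # 0 → missing completely at random
    age_slope_sd: float = 0.01     # log2 units per year
    replicate_frac: float = 0.05   # fraction of samples that are donor replicates
    seed: int = 0

    @classmethod
    def dlpfc_like(cls, **overrides: Any) -> "SimulationConfig":
        """Frontal-cortex-shaped cohort: 1105 samples, 72 batches, 4 sites."""
        base = dict(n_samples=1105, n_batches=72, n_sites=4, n_proteins=2000)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def stg_like(cls, **overrides: Any) -> "SimulationConfig":
        """Temporal-cortex-shaped cohort: 280 samples, 19 batches, 2 sites."""
        base = dict(n_samples=280, n_batches=19, n_sites=2, n_proteins=2000)
        base.update(overrides)
        return cls(**base)

    def validate(self) -> None:
        counts = ("n_proteins", "n_samples", "n_batches", "n_sites",
                  "n_sex_markers", "n_ad_markers", "n_race_markers", "n_outliers")
        for name in counts:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_samples < self.n_batches:
            raise ConfigError(
                f"n_samples ({self.n_samples}) must be >= n_batches ({self.n_batches})")
        if self.n_batches < self.n_sites:
            raise ConfigError(
                f"n_batches ({self.n_batches}) must be >= n_sites ({self.n_sites})")
        for name in ("apoe4_carrier_freq", "genotype_error_rate", "replicate_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.missing_rate_target < 1.0:
            raise ConfigError(
                f"missing_rate_target must be in [0, 1), got {self.missing_rate_target}")
        for name in ("batch_sd", "site_sd", "noise_sd", "age_slope_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_sex_markers + self.n_ad_markers + self.n_race_markers > self.n_proteins:
            raise ConfigError("marker counts sum exceeds n_proteins")
        if self.n_outliers > self.n_samples:
            raise ConfigError("n_outliers exceeds n_samples")


@dataclass
class GroundTruth:
    """Ledger of everything the simulator planted."""

    protein_means: dict[str, float]
    batch_offsets: pd.DataFrame            # proteins × batches, log2 units
    trait_effects: pd.DataFrame            # columns: protein_id, factor, effect
    age_slopes: dict[str, float]
    outlier_samples: list[str]
    generating_apoe: dict[str, str]
    recorded_apoe: dict[str, str]
    latent_pathology: dict[str, float]
    sex_markers: list[str]
    ad_markers: list[str]
    race_markers: list[str]
    missingness: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        payload = {
            "protein_means": self.protein_means,
            "batch_offsets": self.batch_offsets.to_dict(),
            "trait_effects": self.trait_effects.to_dict(orient="records"),
            "age_slopes": self.age_slopes,
            "outlier_samples": self.outlier_samples,
            "generating_apoe": self.generating_apoe,
            "recorded_apoe": self.recorded_apoe,
            "latent_pathology": self.latent_pathology,
            "sex_markers": self.sex_markers,
            "ad_markers": self.ad_markers,
            "race_markers": self.race_markers,
            "missingness": self.missingness,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _batch_site_layout(cfg: SimulationConfig) -> tuple[list[str], list[str], dict[str, str]]:
    """Batch labels, their site assignment (nested), and names."""
    sites = [_SITE_NAMES[i % len(_SITE_NAMES)] + (str(i // len(_SITE_NAMES) + 1) if i >= len(_SITE_NAMES) else "")
             for i in range(cfg.n_sites)]
    batch_names = [f"b{i + 1:02d}" for i in range(cfg.n_batches)]
    batch_site = {b: sites[i % cfg.n_sites] for i, b in enumerate(batch_names)}
    return batch_names, sites, batch_site


def simulate_cohort(config: SimulationConfig) -> tuple[AbundanceMatrix, SampleMetadata, GroundTruth]:
    """Draw one cohort from the generative model.

    Per protein p and sample j the log2 abundance is

        mu_p + b[batch(j), p] + sum_f beta[p, f] * x[j, f]
             + gamma_p * (age_j - 75) + eps,    eps ~ N(0, noise_sd),

    outlier samples get ``outlier_shift`` added to every protein, and the
    reserved APOE4 peptide row is bimodal: carriers at a high mode,
    non-carriers ``apoe4_log2_separation`` log2 units below it.  The
    returned matrix is on the linear intensity scale (2**log2), fully
    observed; apply :func:`apply_missingness` afterwards.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    protein_ids = [f"P{i + 1:05d}|G{i + 1}" for i in range(config.n_proteins)]
    sample_ids = [f"S{j + 1:04d}" for j in range(config.n_samples)]
    batch_names, _, batch_site = _batch_site_layout(config)

    # --- sample structure -------------------------------------------------
    batch_of = np.array([batch_names[j % config.n_batches] for j in range(config.n_samples)])
    site_of = np.array([batch_site[b] for b in batch_of])

    n_rep = int(round(config.replicate_frac * config.n_samples))
    n_ind = config.n_samples - n_rep
    individual = [f"I{j + 1:04d}" for j in range(n_ind)]
    if n_rep > 0:
        donors = rng.choice(n_ind, size=n_rep, replace=False)
        individual += [f"I{d + 1:04d}" for d in donors]
    individual = np.array(individual)

    sex = rng.choice(["female", "male"], size=config.n_samples)
    race = rng.choice(_RACES, size=config.n_samples, p=_RACE_PROBS)
    diagnosis = rng.choice(_DIAGNOSES, size=config.n_samples, p=_DIAG_PROBS)
    age = np.clip(rng.normal(75.0, 8.0, size=config.n_samples), 55.0, 100.0).round(1)

    diag_base = np.select([diagnosis == "AD", diagnosis == "other"], [1.0, 0.5], default=0.0)
    latent = diag_base + rng.normal(0.0, 0.25, size=config.n_samples)
    cerad = np.digitize(latent, _CERAD_CUTS)                  # 0..3
    braak = np.digitize(latent, _BRAAK_CUTS)                  # 0..6

    # APOE genotypes: the generating genotype drives the peptide signal; the
    # recorded genotype carries symmetric carrier<->non-carrier errors.
    carrier = rng.random(config.n_samples) < config.apoe4_carrier_freq
    gen_pairs = np.where(
        carrier,
        rng.choice(["e3/e4", "e4/e4", "e2/e4"], size=config.n_samples, p=[0.80, 0.15, 0.05]),
        rng.choice(["e3/e3", "e2/e3", "e2/e2"], size=config.n_samples, p=[0.75, 0.20, 0.05]),
    )
    flip = rng.random(config.n_samples) < config.genotype_error_rate
    rec_pairs = np.where(flip, np.where(carrier, "e3/e3", "e3/e4"), gen_pairs)

    # replicate samples must agree with their donor on every trait
    first_row: dict[str, int] = {}
    for j, ind in enumerate(individual):
        if ind in first_row:
            k = first_row[ind]
            sex[j], race[j], diagnosis[j], age[j] = sex[k], race[k], diagnosis[k], age[k]
            latent[j], cerad[j], braak[j] = latent[k], cerad[k], braak[k]
            carrier[j], gen_pairs[j], rec_pairs[j] = carrier[k], gen_pairs[k], rec_pairs[k]
        else:
            first_row[ind] = j

    # --- protein-level parameters ----------------------------------------
    mu = rng.normal(20.0, 1.5, size=config.n_proteins)
    batch_off = rng.normal(0.0, config.batch_sd, size=(config.n_proteins, config.n_batches))
    site_names = sorted(set(batch_site.values()))
    site_off = rng.normal(0.0, config.site_sd, size=(config.n_proteins, len(site_names)))
    gamma = rng.normal(0.0, config.age_slope_sd, size=config.n_proteins)

    order = rng.permutation(config.n_proteins)
    sex_idx = order[:config.n_sex_markers]
    ad_idx = order[config.n_sex_markers:config.n_sex_markers + config.n_ad_markers]
    race_idx = order[config.n_sex_markers + config.n_ad_markers:
                     config.n_sex_markers + config.n_ad_markers + config.n_race_markers]

    # signed effects so markers go both up and down, as real sex/race/AD
    # markers do (X- vs Y-linked proteins, etc.)
    sign = lambda k: rng.choice([-1.0, 1.0], size=k)  # noqa: E731
    beta_sex = config.effect_size_sex * sign(len(sex_idx))
    beta_ad = config.effect_size_ad * sign(len(ad_idx))
    beta_race = config.effect_size_race * sign(len(race_idx))

    x_sex = (sex == "female").astype(float)
    x_race = (race == _RACES[0]).astype(float)   # African American indicator

    # --- assemble log2 matrix (proteins × samples) ------------------------
    batch_col = np.array([batch_names.index(b) for b in batch_of])
    site_col = np.array([site_names.index(s) for s in site_of])
    log2 = (mu[:, None]
            + batch_off[:, batch_col]
            + site_off[:, site_col]
            + gamma[:, None] * (age[None, :] - 75.0)
            + rng.normal(0.0, config.noise_sd, size=(config.n_proteins, config.n_samples)))
    log2[sex_idx] += beta_sex[:, None] * x_sex[None, :]
    log2[race_idx] += beta_race[:, None] * x_race[None, :]
    # AD markers scale with the latent pathology axis (E=0 in controls, 1 in
    # AD), so the AD-vs-control mean gap equals effect_size_ad while CERAD
    # and Braak trends are monotone in the same signal.
    log2[ad_idx] += beta_ad[:, None] * latent[None, :]

    # APOE4-specific peptide row.  Heterozygous carriers sit at the high
    # mode, e4/e4 homozygotes one log2 unit above it (allele dose), and
    # non-carriers at a low background mode `apoe4_log2_separation` below
    # the heterozygote mode (residual chemical noise / isotope impurity).
    apoe_mu = 18.0
    hom = gen_pairs == "e4/e4"
    apoe_row = np.where(carrier, apoe_mu + np.where(hom, 1.0, 0.0),
                        apoe_mu - config.apoe4_log2_separation)
    apoe_row = apoe_row + rng.normal(0.0, config.noise_sd, size=config.n_samples)

    outlier_ids: list[str] = []
    if config.n_outliers > 0:
        out_idx = rng.choice(config.n_samples, size=config.n_outliers, replace=False)
        log2[:, out_idx] += config.outlier_shift
        apoe_row[out_idx] += config.outlier_shift
        outlier_ids = sorted(sample_ids[j] for j in out_idx)

    all_ids = protein_ids + [APOE4_PEPTIDE_ID]
    full = np.vstack([log2, apoe_row[None, :]])
    matrix = AbundanceMatrix(
        pd.DataFrame(np.exp2(full), index=all_ids, columns=sample_ids), stage="raw")

    meta = pd.DataFrame({
        "individual_id": individual,
        "batch": batch_of,
        "site": site_of,
        "sex": sex,
        "race": race,
        "diagnosis": diagnosis,
        "age": age,
        "cerad": cerad,
        "braak": braak,
        "apoe": rec_pairs,
    }, index=pd.Index(sample_ids, name="sample_id"))[list(METADATA_COLUMNS)]
    metadata = SampleMetadata(meta)

    effects = []
    for ids, idx, betas, factor in (
            (protein_ids, sex_idx, beta_sex, "sex"),
            (protein_ids, ad_idx, beta_ad, "diagnosis"),
            (protein_ids, race_idx, beta_race, "race")):
        for i, b in zip(idx, betas):
            effects.append({"protein_id": ids[i], "factor": factor, "effect": float(b)})
    truth = GroundTruth(
        protein_means={pid: float(m) for pid, m in zip(protein_ids, mu)},
        batch_offsets=pd.DataFrame(batch_off, index=protein_ids, columns=batch_names),
        trait_effects=pd.DataFrame(effects, columns=["protein_id", "factor", "effect"]),
        age_slopes={pid: float(g) for pid, g in zip(protein_ids, gamma)},
        outlier_samples=outlier_ids,
        generating_apoe={s: g for s, g in zip(sample_ids, gen_pairs)},
        recorded_apoe={s: r for s, r in zip(sample_ids, rec_pairs)},
        latent_pathology={s: float(v) for s, v in zip(sample_ids, latent)},
        sex_markers=[protein_ids[i] for i in sex_idx],
        ad_markers=[protein_ids[i] for i in ad_idx],
        race_markers=[protein_ids[i] for i in race_idx],
    )
    return matrix, metadata, truth


def apply_missingness(matrix: AbundanceMatrix, config: SimulationConfig,
                      truth: GroundTruth | None = None) -> AbundanceMatrix:
    """Introduce intensity-dependent missingness into a raw matrix.

    The per-entry missingness probability is logistic in the negative
    standardized log2 intensity, ``p = expit(a - s * z)`` with
    ``s = mnar_steepness``; the intercept ``a`` is solved so the expected
    missing fraction equals ``missing_rate_target``.  ``s = 0`` reduces to
    missing-completely-at-random at exactly the target rate.
    """
    config.validate()
    if matrix.stage != "raw":
        raise ConfigError(f"apply_missingness expects a raw-stage matrix, got {matrix.stage!r}")
    target = config.missing_rate_target
    if target == 0.0:
        return matrix.copy()

    values = matrix.values
    log2v = np.log2(values)
    z = (log2v - log2v.mean()) / max(log2v.std(), 1e-12)
    s = config.mnar_steepness

    def mean_p(a: float) -> float:
        return float(expit(a - s * z).mean())

    a = brentq(lambda a: mean_p(a) - target, -60.0, 60.0, xtol=1e-10)
    p = expit(a - s * z)
    rng = np.random.default_rng([config.seed, 0x5EED])
    out = values.copy()
    out[rng.random(values.shape) < p] = np.nan
    # The reserved APOE4 peptide row keeps its background signal: reporter-ion
    # chemical noise is always measured, so absence there is not MNAR dropout.
    if APOE4_PEPTIDE_ID in matrix.data.index:
        i = matrix.data.index.get_loc(APOE4_PEPTIDE_ID)
        out[i] = values[i]
    if truth is not None:
        truth.missingness = {"intercept": float(a), "steepness": float(s), "target": float(target)}
    return matrix.with_values(out, stage="raw")
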