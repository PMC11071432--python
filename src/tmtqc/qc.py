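"""Core QC: missingness filter, loading normalization, log2 transform,
iterative PCA outlier removal, and per-protein batch regression.

The pipeline order is the standard one for multi-batch TMT protein
reports: drop proteins quantified in too few samples, divide each sample's
intensities by its total to correct loading differences, log2 transform,
iteratively remove samples that are extreme on the leading principal
components, then regress the processing-batch effect out of every protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, SampleMetadata, QCReport, QCStep
from .errors import ConfigError, QCError

logger = logging.getLogger(__name__)


@dataclass
class QCConfig:
    """Tunables of the QC pipeline.

    ``max_missing_frac``: a protein is removed only when its missing
    fraction is *strictly greater* than this (0.5 by default — a protein
    missing in exactly half the samples is retained).
    ``outlier_sd_threshold`` / ``outlier_pcs``: a sample is an outlier when
    its score on any of the leading ``outlier_pcs`` components lies more
    than ``outlier_sd_threshold`` standard deviations from that component's
    mean (defaults 4 SD on PC1–PC2).
    """

    max_missing_frac: float = 0.5
    outlier_sd_threshold: float = 4.0
    outlier_pcs: int = 2
    max_outlier_rounds: int = 30
    batch_factor: str = "batch"
    pca_impute: str = "protein_mean"   # imputation used only inside PCA/MDS

    def validate(self) -> None:
        if not 0.0 < self.max_missing_frac <= 1.0:
            raise ConfigError(f"max_missing_frac must be in (0, 1], got {self.max_missing_frac}")
        if self.outlier_sd_threshold <= 0:
            raise ConfigError(f"outlier_sd_threshold must be > 0, got {self.outlier_sd_threshold}")
        if self.outlier_pcs < 1:
            raise ConfigError(f"outlier_pcs must be >= 1, got {self.outlier_pcs}")
        if self.max_outlier_rounds < 1:
            raise ConfigError(f"max_outlier_rounds must be >= 1, got {self.max_outlier_rounds}")
        if self.pca_impute != "protein_mean":
            raise ConfigError(f"unknown pca_impute rule {self.pca_impute!r}")


def filter_missing(matrix: AbundanceMatrix, config: QCConfig | None = None) -> tuple[AbundanceMatrix, QCStep]:
    """Drop proteins missing in more than ``max_missing_frac`` of samples.

    The boundary is inclusive on the retained side: with the 0.5 default a
    protein missing in exactly 50% of samples stays.
    """
    config = config or QCConfig()
    config.validate()
    if matrix.n_proteins == 0 or matrix.n_samples == 0:
        raise QCError("cannot filter an empty matrix")
    frac = np.mean(matrix.missing_mask(), axis=1)
    keep = frac <= config.max_missing_frac
    kept_ids = [pid for pid, k in zip(matrix.protein_ids, keep) if k]
    out = matrix.subset_proteins(kept_ids)
    step = QCStep(
        name="filter_missing",
        params={"max_missing_frac": config.max_missing_frac},
        n_proteins_before=matrix.n_proteins, n_proteins_after=out.n_proteins,
        n_samples_before=matrix.n_samples, n_samples_after=out.n_samples,
        details={"n_removed": int((~keep).sum())},
    )
    return out, step


def normalize_sample_loading(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Divide each observed value by its sample's total observed abundance.

    Corrects for unequal protein loading across TMT channels; observed
    column sums become exactly 1 and missing entries stay missing.
    """
    if matrix.stage != "raw":
        raise QCError(f"normalize_sample_loading expects raw stage, got {matrix.stage!r}")
    values = matrix.values
    totals = np.nansum(values, axis=0)
    dead = [s for s, t in zip(matrix.sample_ids, totals) if not t > 0]
    if dead:
        raise QCError(f"samples with zero observed total abundance: {dead}")
    return matrix.with_values(values / totals[None, :], stage="ratio")


def log2_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Elementwise log2 of a ratio-stage matrix."""
    if matrix.stage != "ratio":
        raise QCError(f"log2_transform expects ratio stage, got {matrix.stage!r}")
    values = matrix.values
    if np.nanmin(values, initial=np.inf) <= 0:
        raise QCError("log2_transform requires strictly positive observed values")
    return matrix.with_values(np.log2(values), stage="log2")


def _imputed_centered(matrix: AbundanceMatrix) -> np.ndarray:
    """Protein-centered grid with per-protein mean imputation (PCA/MDS only)."""
    values = matrix.values.copy()
    row_mean = np.nanmean(values, axis=1)
    idx = np.where(np.isnan(values))
    values[idx] = row_mean[idx[0]]
    return values - values.mean(axis=1, keepdims=True)


def pca_scores(matrix: AbundanceMatrix, n_components: int = 2) -> pd.DataFrame:
    """Sample scores on the leading principal components.

    Proteins are mean-centered (not variance-scaled); missing entries are
    mean-imputed for the decomposition only.  The sign of each component is
    fixed so its largest-magnitude protein loading is positive, making
    scores reproducible across linear-algebra backends.
    """
    if matrix.stage not in ("log2", "batch_corrected"):
        raise QCError(f"pca_scores expects log2 or batch_corrected stage, got {matrix.stage!r}")
    if matrix.n_samples < 3:
        raise QCError("pca_scores requires at least 3 samples")
    max_rank = min(matrix.n_samples, matrix.n_proteins)
    if n_components > max_rank:
        raise QCError(f"requested {n_components} components but rank is at most {max_rank}")
    centered = _imputed_centered(matrix)            # proteins × samples
    # SVD of samples × proteins: scores = U * s, loadings are V rows
    u, s, vt = np.linalg.svd(centered.T, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components]
    for k in range(n_components):
        if loadings[k, np.argmax(np.abs(loadings[k]))] < 0:
            scores[:, k] = -scores[:, k]
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return pd.DataFrame(scores, index=matrix.sample_ids, columns=cols)


def detect_outliers_iterative(matrix: AbundanceMatrix, config: QCConfig | None = None
                              ) -> tuple[AbundanceMatrix, QCStep]:
    """Iteratively remove samples extreme on the leading principal components.

    Each round recomputes PCA on the remaining samples, flags every sample
    whose score on any tested component is more than
    ``outlier_sd_threshold`` population SDs from the component mean,
    removes all flagged samples together, and repeats until a round flags
    none (or ``max_outlier_rounds`` is hit, which is recorded as a warning).
    """
    config = config or QCConfig()
    config.validate()
    if matrix.stage != "log2":
        raise QCError(f"detect_outliers_iterative expects log2 stage, got {matrix.stage!r}")
    current = matrix
    rounds: list[dict] = []
    hit_cap = False
    for rnd in range(1, config.max_outlier_rounds + 1):
        if current.n_samples < 4:
            break
        n_pcs = min(config.outlier_pcs, min(current.n_samples, current.n_proteins) - 1)
        scores = pca_scores(current, n_components=n_pcs)
        arr = scores.to_numpy()
        mean = arr.mean(axis=0)
        sd = arr.std(axis=0)            # population SD, n denominator
        flagged: dict[str, str] = {}
        for k in range(n_pcs):
            if sd[k] == 0:
                continue
            z = np.abs(arr[:, k] - mean[k]) / sd[k]
            for sid in scores.index[z > config.outlier_sd_threshold]:
                flagged.setdefault(sid, f"PC{k + 1}")
        if not flagged:
            break
        if len(flagged) >= current.n_samples:
            raise QCError("outlier loop would remove every remaining sample")
        rounds.append({"round": rnd, "removed": sorted(flagged),
                       "component": {s: c for s, c in sorted(flagged.items())}})
        keep = [s for s in current.sample_ids if s not in flagged]
        current = current.subset_samples(keep)
    else:
        hit_cap = True
        logger.warning("outlier removal stopped at max_outlier_rounds=%d", config.max_outlier_rounds)
    step = QCStep(
        name="detect_outliers_iterative",
        params={"outlier_sd_threshold": config.outlier_sd_threshold,
                "outlier_pcs": config.outlier_pcs,
                "max_outlier_rounds": config.max_outlier_rounds},
        n_proteins_before=matrix.n_proteins, n_proteins_after=current.n_proteins,
        n_samples_before=matrix.n_samples, n_samples_after=current.n_samples,
        details={"rounds": rounds, "n_rounds": len(rounds), "hit_max_rounds": hit_cap},
    )
    return current, step


def regress_batch(matrix: AbundanceMatrix, metadata: SampleMetadata,
                  config: QCConfig | None = None) -> tuple[AbundanceMatrix, QCStep]:
    """Regress the processing-batch effect out of every protein.

    Per protein, an ordinary-least-squares fit of log2 abundance on batch
    as a categorical factor (equivalent, for a single factor, to the batch
    means on observed entries) is removed and the protein's grand mean over
    observed values is restored, so the corrected matrix stays on the log2
    scale and per-batch means are equalized.  Proteins observed in a single
    batch, and batches with fewer than 2 samples, are passed through and
    flagged.
    """
    config = config or QCConfig()
    config.validate()
    if matrix.stage != "log2":
        raise QCError(f"regress_batch expects log2 stage, got {matrix.stage!r}")
    meta = metadata.aligned_to(matrix)
    if meta.df[config.batch_factor].isna().any():
        bad = meta.df.index[meta.df[config.batch_factor].isna()].tolist()
        raise QCError(f"samples without a {config.batch_factor!r} label: {bad}")
    batches = meta.df[config.batch_factor].to_numpy()
    levels, batch_idx = np.unique(batches, return_inverse=True)
    n_levels = len(levels)

    small = [str(b) for b, c in zip(*np.unique(batches, return_counts=True)) if c < 2]
    if small:
        logger.warning("batches with fewer than 2 samples (correction may be unstable): %s", small)

    values = matrix.values
    observed = ~np.isnan(values)
    corrected = values.copy()
    single_batch: list[str] = []
    if n_levels > 1:
        # vectorized per-protein batch means over observed entries
        ohe = np.eye(n_levels)[batch_idx]                       # samples × levels
        counts = observed.astype(float) @ ohe                    # proteins × levels
        sums = np.where(observed, values, 0.0) @ ohe
        with np.errstate(invalid="ignore", divide="ignore"):
            bmeans = sums / counts                               # NaN where batch unobserved
        grand = np.nansum(values, axis=1) / observed.sum(axis=1)
        n_obs_batches = (counts > 0).sum(axis=1)
        fitted = bmeans[np.arange(matrix.n_proteins)[:, None], batch_idx[None, :]]
        adjusted = values - fitted + grand[:, None]
        estimable = n_obs_batches > 1
        corrected = np.where(estimable[:, None], adjusted, values)
        single_batch = [pid for pid, e in zip(matrix.protein_ids, estimable) if not e]
        if single_batch:
            logger.warning("%d proteins observed in a single batch passed through uncorrected",
                           len(single_batch))
    out = matrix.with_values(corrected, stage="batch_corrected")
    step = QCStep(
        name="regress_batch",
        params={"batch_factor": config.batch_factor, "n_batches": int(n_levels)},
        n_proteins_before=matrix.n_proteins, n_proteins_after=out.n_proteins,
        n_samples_before=matrix.n_samples, n_samples_after=out.n_samples,
        details={"proteins_passed_through": single_batch, "small_batches": small},
    )
    return out, step


def run_qc(matrix: AbundanceMatrix, metadata: SampleMetadata,
           config: QCConfig | None = None) -> tuple[AbundanceMatrix, QCReport]:
    """Full pipeline: filter → normalize → log2 → outlier removal → batch regression."""
    config = config or QCConfig()
    report = QCReport()
    filtered, step = filter_missing(matrix, config)
    report.add(step)
    log2m = log2_transform(normalize_sample_loading(filtered))
    cleaned, step = detect_outliers_iterative(log2m, config)
    report.add(step)
    corrected, step = regress_batch(cleaned, metadata, config)
    report.add(step)
    return corrected, report
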