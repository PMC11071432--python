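"""QC-assessment analytics: MDS embeddings and per-protein variance partitioning.

``mds_embed`` gives the classical (Torgerson) multidimensional scaling of
samples used to visualize batch/site structure before and after correction.
``variance_partition`` decomposes each protein's abundance variance into
fractions attributable to donor traits and batch, the standard mixed-model
diagnostic for whether a technical factor still shapes the data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import AbundanceMatrix, SampleMetadata
from .errors import QCError
from .qc import _imputed_centered

logger = logging.getLogger(__name__)

DEFAULT_FACTORS = ("age", "sex", "race", "diagnosis", "batch")

#: Factors modeled as a continuous fixed effect rather than a variance component.
CONTINUOUS_FACTORS = ("age",)


def mds_embed(matrix: AbundanceMatrix, n_dims: int = 2,
              color_by: pd.Series | None = None) -> pd.DataFrame:
    """Classical (Torgerson) MDS of samples on Euclidean profile distances.

    Missing entries are per-protein mean-imputed exactly as in
    :func:`tmtqc.qc.pca_scores`, so for complete data the embedding agrees
    with PCA sample scores up to sign.  Coordinates are sign-fixed so each
    dimension's largest-magnitude coordinate is positive.
    """
    if matrix.n_samples < 3:
        raise QCError("mds_embed requires at least 3 samples")
    if n_dims > matrix.n_samples:
        raise QCError(f"cannot embed {matrix.n_samples} samples in {n_dims} dimensions")
    centered = _imputed_centered(matrix)                 # proteins × samples
    x = centered.T
    sq = (x ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)     # squared distances
    np.fill_diagonal(d2, 0.0)
    n = d2.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_dims]
    coords = vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))
    for k in range(coords.shape[1]):
        if coords[np.argmax(np.abs(coords[:, k])), k] < 0:
            coords[:, k] = -coords[:, k]
    out = pd.DataFrame(coords, index=matrix.sample_ids,
                       columns=[f"dim{k + 1}" for k in range(n_dims)])
    if color_by is not None:
        out["color_by"] = color_by.reindex(out.index)
    return out


@dataclass
class VariancePartitionTable:
    """Per-protein variance fractions per factor plus residual.

    ``fractions`` is indexed by protein id with one column per factor and a
    ``residual`` column; rows sum to 1.  ``fallback`` flags proteins whose
    REML fit did not converge and fell back to the method-of-moments
    estimator; ``skipped`` lists proteins with too few complete samples.
    """

    fractions: pd.DataFrame
    fallback: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    @property
    def factors(self) -> list[str]:
        return [c for c in self.fractions.columns if c != "residual"]


def _aliased_pairs(meta: pd.DataFrame, cats: Sequence[str]) -> list[tuple[str, str]]:
    """Categorical factor pairs whose levels correspond one-to-one."""
    out = []
    for i, f in enumerate(cats):
        for g in cats[i + 1:]:
            tab = pd.crosstab(meta[f], meta[g]).to_numpy()
            if ((tab > 0).sum(axis=0) <= 1).all() and ((tab > 0).sum(axis=1) <= 1).all():
                out.append((f, g))
    return out


def _mom_components(y: np.ndarray, cat_levels: dict[str, np.ndarray]) -> dict[str, float]:
    """Method-of-moments variance components (no convergence issues).

    With a single categorical factor this is the exact one-way ANOVA
    (Henderson) estimator, which handles unbalanced groups; with several
    crossed factors it regresses off-diagonal cross-products of the
    centered response on same-level indicators (Haseman–Elston style).
    """
    if len(cat_levels) == 1:
        (f, lv), = cat_levels.items()
        levels, idx = np.unique(lv, return_inverse=True)
        n = len(y)
        counts = np.bincount(idx).astype(float)
        k = len(levels)
        gmeans = np.bincount(idx, weights=y) / counts
        ssw = float(np.sum((y - gmeans[idx]) ** 2))
        ssb = float(np.sum(counts * (gmeans - y.mean()) ** 2))
        msw = ssw / max(n - k, 1)
        denom = n - float(np.sum(counts ** 2)) / n
        s2b = max((ssb - (k - 1) * msw) / denom, 0.0) if denom > 0 else 0.0
        return {f: s2b, "__resid__": msw}
    r = y - y.mean()
    n = len(r)
    iu = np.triu_indices(n, k=1)
    prods = (r[:, None] * r[None, :])[iu]
    cols = []
    names = list(cat_levels)
    for f in names:
        lv = cat_levels[f]
        cols.append((lv[:, None] == lv[None, :])[iu].astype(float))
    if not cols:
        return {"__resid__": float(r @ r / max(n - 1, 1))}
    # intercept absorbs the O(1/n) bias that centering puts on every pair
    design = np.column_stack([np.ones(len(prods))] + cols)
    coef, *_ = np.linalg.lstsq(design, prods, rcond=None)
    comps = {f: max(float(c), 0.0) for f, c in zip(names, coef[1:])}
    total = float(r @ r) / max(n - 1, 1)
    comps["__resid__"] = max(total - sum(comps.values()), 0.0)
    return comps


def _reml_components(y: np.ndarray, cat_levels: dict[str, np.ndarray]) -> dict[str, float]:
    """REML variance components via a mixed model with crossed random intercepts."""
    data = pd.DataFrame({"y": y})
    vcf = {}
    for f, lv in cat_levels.items():
        data[f] = lv
        vcf[f] = f"0 + C({f})"
    data["__g__"] = 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula("y ~ 1", groups="__g__", vc_formula=vcf,
                                        re_formula="0", data=data)
        # Powell handles boundary (zero) variance components far more
        # reliably than gradient-based optimizers here.
        fit = model.fit(reml=True, method="powell", maxiter=300)
    if not fit.converged or np.any(~np.isfinite(list(fit.vcomp) + [fit.scale])):
        raise RuntimeError("REML did not converge")
    comps = {f: max(float(v), 0.0) for f, v in zip(model.exog_vc.names, fit.vcomp)}
    comps["__resid__"] = max(float(fit.scale), 0.0)
    return comps


def variance_partition(matrix: AbundanceMatrix, metadata: SampleMetadata,
                       factors: Sequence[str] = DEFAULT_FACTORS,
                       min_samples: int = 10,
                       method: str = "reml") -> VariancePartitionTable:
    """Per-protein fraction of abundance variance attributable to each factor.

    Categorical factors (sex, race, diagnosis, batch, ...) enter as random
    intercepts whose variance components are estimated by REML; continuous
    factors (age) enter as fixed effects whose contribution is the variance
    of the fitted term.  The reported fractions are each component divided
    by the total (components + fixed-term variance + residual), so rows sum
    to 1.  Non-convergent REML fits fall back to a method-of-moments
    estimator and are flagged; ``method="mom"`` forces the fallback path for
    every protein.
    """
    if method not in ("reml", "mom"):
        raise QCError(f"unknown variance_partition method {method!r}")
    meta = metadata.aligned_to(matrix).df
    missing_factors = [f for f in factors if f not in meta.columns]
    if missing_factors:
        raise QCError(f"factors absent from metadata: {missing_factors}")
    cont = [f for f in factors if f in CONTINUOUS_FACTORS]
    cats = [f for f in factors if f not in CONTINUOUS_FACTORS]
    for f, g in _aliased_pairs(meta.dropna(subset=cats) if cats else meta, cats):
        logger.warning("factors %r and %r are aliased (one-to-one levels); "
                       "their variance split is arbitrary", f, g)

    usable_cats = []
    for f in cats:
        if meta[f].dropna().nunique() < 2:
            logger.warning("factor %r has a single level and is excluded", f)
        else:
            usable_cats.append(f)

    rows = {}
    fallback: list[str] = []
    skipped: list[str] = []
    all_cols = cont + usable_cats
    values = matrix.values
    meta_cols = {f: meta[f].to_numpy() for f in all_cols}
    for i, pid in enumerate(matrix.protein_ids):
        y = values[i]
        mask = ~np.isnan(y)
        for f in all_cols:
            mask &= ~pd.isna(meta_cols[f])
        if mask.sum() < min_samples:
            skipped.append(pid)
            continue
        yy = y[mask].astype(float)
        age_var = 0.0
        if cont:
            # residualize the continuous fixed effects first; their share is
            # the variance of the fitted linear term
            xc = np.column_stack([np.ones(mask.sum())] +
                                 [meta_cols[f][mask].astype(float) for f in cont])
            coef, *_ = np.linalg.lstsq(xc, yy, rcond=None)
            fitted = xc[:, 1:] @ coef[1:]
            age_var = float(np.var(fitted))
            yy = yy - fitted
        cat_levels = {f: meta_cols[f][mask].astype(str) for f in usable_cats}
        comps = None
        if method == "reml" and cat_levels:
            try:
                comps = _reml_components(yy, cat_levels)
            except Exception:
                comps = None
        if comps is None:
            comps = _mom_components(yy, cat_levels)
            if method == "reml" and cat_levels:
                fallback.append(pid)
        total = sum(comps.values()) + age_var
        if total <= 0:
            row = {f: 0.0 for f in all_cols}
            row["residual"] = 1.0
        else:
            row = {f: comps.get(f, 0.0) / total for f in usable_cats}
            for f in cont:
                row[f] = age_var / total if len(cont) == 1 else np.nan
            row["residual"] = comps["__resid__"] / total
        rows[pid] = row
    frac = pd.DataFrame.from_dict(rows, orient="index")
    if not frac.empty:
        frac = frac[[*all_cols, "residual"]]
    if skipped:
        logger.warning("%d proteins skipped (fewer than %d complete samples)",
                       len(skipped), min_samples)
    return VariancePartitionTable(fractions=frac, fallback=fallback, skipped=skipped)


def rank_factor_proteins(table: VariancePartitionTable, factor: str,
                         top_n: int = 20) -> list[str]:
    """Proteins ordered by descending variance fraction for one factor.

    Ties break by protein id (lexicographic), so the ranking is total and
    reproducible.
    """
    if factor not in table.fractions.columns or factor == "residual":
        raise QCError(f"unknown factor {factor!r}; available: {table.factors}")
    df = table.fractions
    order = sorted(df.index, key=lambda pid: (-df.at[pid, factor], pid))
    return order[:min(top_n, len(order))]


def plot_mds(coords: pd.DataFrame, path: str, title: str = "MDS of samples") -> None:
    """Scatter of the first two MDS dimensions, colored by the color_by column."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    if "color_by" in coords:
        for level, grp in coords.groupby("color_by"):
            ax.scatter(grp["dim1"], grp["dim2"], s=12, label=str(level), alpha=0.7)
        ax.legend(fontsize=7)
    else:
        ax.scatter(coords["dim1"], coords["dim2"], s=12, alpha=0.7)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_variance_violin(table: VariancePartitionTable, path: str,
                         title: str = "Variance explained") -> None:
    """Violin plot of per-protein variance fractions by factor (percent scale)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table.fractions * 100.0
    cols = [c for c in df.columns]
    fig, ax = plt.subplots(figsize=(1.0 + len(cols), 4))
    ax.violinplot([df[c].dropna().to_numpy() for c in cols], showmedians=True)
    ax.set_xticks(range(1, len(cols) + 1), cols, rotation=45, ha="right")
    ax.set_ylabel("% variance explained")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
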