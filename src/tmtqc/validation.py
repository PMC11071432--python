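"""Technical-validation analyses.

Three checks that a harmonized brain TMT proteome behaves like the biology
says it must: AD-linked proteins differ by diagnosis (one-way ANOVA with
Benjamini–Hochberg correction), amyloid/tau proteins rise monotonically
with ordinal neuropathology scores (Jonckheere–Terpstra trend statistic
with a permutation p-value), and the APOE ε4 allele-specific peptide
signal (LGADMEDVR) reproduces the recorded APOE genotype ("proteotype"
concordance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceMatrix, SampleMetadata
from .errors import QCError

logger = logging.getLogger(__name__)


def differential_abundance(matrix: AbundanceMatrix, metadata: SampleMetadata,
                           group_col: str = "diagnosis",
                           protein_subset: list[str] | None = None,
                           min_per_group: int = 3) -> pd.DataFrame:
    """One-way ANOVA per protein across the levels of ``group_col``.

    Returns a table with F statistic, raw p, Benjamini–Hochberg adjusted p
    (across the tested set), and — when exactly two levels are present —
    the difference of group means (first level minus second, levels sorted).
    Proteins with fewer than ``min_per_group`` observed samples in ≥2
    groups are skipped and counted.
    """
    meta = metadata.aligned_to(matrix).df
    groups = meta[group_col]
    levels = sorted(groups.dropna().unique().tolist())
    if len(levels) < 2:
        raise QCError(f"group column {group_col!r} has fewer than 2 levels")
    ids = protein_subset if protein_subset is not None else matrix.protein_ids
    missing = [p for p in ids if p not in matrix.data.index]
    if missing:
        raise QCError(f"proteins absent from matrix: {missing}")

    rows = []
    n_skipped = 0
    for pid in ids:
        y = matrix.data.loc[pid]
        per_level = []
        for lv in levels:
            v = y[groups == lv].dropna().to_numpy()
            if len(v) >= min_per_group:
                per_level.append((lv, v))
        if len(per_level) < 2:
            n_skipped += 1
            continue
        arrays = [v for _, v in per_level]
        if np.ptp(np.concatenate(arrays)) == 0:
            f, p = 0.0, 1.0   # all values identical: no evidence of difference
        else:
            with np.errstate(invalid="ignore"):
                f, p = stats.f_oneway(*arrays)
            if np.isnan(f):
                f, p = 0.0, 1.0
        row = {"protein_id": pid, "F": float(f), "p": float(p)}
        if len(per_level) == 2:
            row["mean_diff"] = float(arrays[0].mean() - arrays[1].mean())
        rows.append(row)
    if n_skipped:
        logger.warning("%d proteins skipped (fewer than %d samples in 2+ groups)",
                       n_skipped, min_per_group)
    out = pd.DataFrame(rows).set_index("protein_id")
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out.attrs["n_skipped"] = n_skipped
    out.attrs["levels"] = levels
    return out.sort_values("p")


@dataclass
class TrendResult:
    """Ordinal trend of one protein across pathology stages."""

    protein_id: str
    stage_col: str
    stage_medians: dict[int, float]      # ordered stage -> median log2 abundance
    stage_n: dict[int, int]
    statistic: float                     # Jonckheere–Terpstra T
    z: float                             # standardized against the permutation null
    p_value: float                       # one-sided (increasing trend), permutation
    n_perm: int
    n_total: int


def _jt_statistic(values: np.ndarray, stages: np.ndarray) -> float:
    """Jonckheere–Terpstra T: sum of Mann–Whitney counts over ordered stage pairs."""
    levels = np.unique(stages)
    t = 0.0
    for a in range(len(levels)):
        for b in range(a + 1, len(levels)):
            x = values[stages == levels[a]]
            y = values[stages == levels[b]]
            t += np.sum(y[None, :] > x[:, None]) + 0.5 * np.sum(y[None, :] == x[:, None])
    return float(t)


def ordinal_trend(matrix: AbundanceMatrix, metadata: SampleMetadata,
                  protein_id: str, stage_col: str = "cerad",
                  n_perm: int = 2000, seed: int = 0,
                  dedupe_individuals: bool = True) -> TrendResult:
    """Jonckheere–Terpstra trend of a protein across an ordinal stage column.

    Rank-based (invariant to monotone transforms of abundance); the
    p-value comes from permuting stage labels ``n_perm`` times with the
    given seed, one-sided for an increasing trend.  Replicate tissues are
    reduced to the first sample per individual before testing, matching
    per-individual reporting.
    """
    if protein_id not in matrix.data.index:
        raise QCError(f"protein {protein_id!r} absent from matrix")
    if n_perm < 100:
        logger.warning("n_perm=%d is small; permutation p will be coarse", n_perm)
    meta = metadata.aligned_to(matrix)
    if dedupe_individuals:
        meta = meta.first_per_individual()
    y = matrix.data.loc[protein_id, meta.df.index]
    stage = pd.to_numeric(meta.df[stage_col], errors="coerce")
    mask = y.notna() & stage.notna()
    values = y[mask].to_numpy(dtype=float)
    stages = stage[mask].to_numpy(dtype=int)
    levels = np.unique(stages)
    if len(levels) < 2:
        raise QCError(f"stage column {stage_col!r} has fewer than 2 populated stages")

    t_obs = _jt_statistic(values, stages)
    rng = np.random.default_rng(seed)
    perm_t = np.empty(n_perm)
    for i in range(n_perm):
        perm_t[i] = _jt_statistic(values, rng.permutation(stages))
    sd = perm_t.std()
    z = (t_obs - perm_t.mean()) / sd if sd > 0 else 0.0
    p = (1.0 + np.sum(perm_t >= t_obs)) / (n_perm + 1.0)
    medians = {int(lv): float(np.median(values[stages == lv])) for lv in levels}
    counts = {int(lv): int(np.sum(stages == lv)) for lv in levels}
    return TrendResult(protein_id=protein_id, stage_col=stage_col,
                       stage_medians=medians, stage_n=counts,
                       statistic=t_obs, z=float(z), p_value=float(p),
                       n_perm=n_perm, n_total=int(mask.sum()))


@dataclass
class ProteotypeResult:
    """APOE ε4 carrier calls from the allele-specific peptide vs recorded genotype."""

    per_sample: pd.DataFrame             # log2 abundance, genotype pair, flags
    threshold: float                     # log2 decision threshold
    concordance: float                   # fraction of genotyped samples agreeing
    n_false_positive: int                # non-carriers called carrier
    n_false_negative: int
    false_positive_rate: float
    fold_change: float                   # linear-scale mean ratio, called carrier / non
    callable: bool = True
    component_means: tuple[float, float] = (np.nan, np.nan)
    notes: list[str] = field(default_factory=list)


def _em_two_gaussian(x: np.ndarray, max_iter: int = 200, tol: float = 1e-8
                     ) -> tuple[float, float, float]:
    """Equal-variance two-component Gaussian mixture by EM.

    Deterministic quantile-based initialization (component means at the
    10th and 90th percentiles); returns (low mean, high mean, sd).
    """
    m1, m2 = np.quantile(x, [0.1, 0.9])
    if m1 == m2:
        return float(m1), float(m2), 0.0
    sd = max(x.std() / 2.0, 1e-6)
    w = 0.5
    for _ in range(max_iter):
        d1 = stats.norm.pdf(x, m1, sd) * (1 - w)
        d2 = stats.norm.pdf(x, m2, sd) * w
        denom = d1 + d2
        denom[denom == 0] = 1e-300
        r = d2 / denom
        new_m1 = np.sum((1 - r) * x) / max(np.sum(1 - r), 1e-12)
        new_m2 = np.sum(r * x) / max(np.sum(r), 1e-12)
        var = (np.sum((1 - r) * (x - new_m1) ** 2) + np.sum(r * (x - new_m2) ** 2)) / len(x)
        new_sd = max(np.sqrt(var), 1e-9)
        new_w = float(np.mean(r))
        if abs(new_m1 - m1) < tol and abs(new_m2 - m2) < tol:
            m1, m2, sd, w = new_m1, new_m2, new_sd, new_w
            break
        m1, m2, sd, w = new_m1, new_m2, new_sd, new_w
    lo, hi = sorted((float(m1), float(m2)))
    return lo, hi, float(sd)


def call_apoe_proteotype(matrix: AbundanceMatrix, metadata: SampleMetadata,
                         peptide_row_id: str = "APOE4|LGADMEDVR",
                         threshold: float | None = None,
                         min_separation: float = 1.0,
                         dedupe_individuals: bool = True) -> ProteotypeResult:
    """Call ε4 carrier status from the allele-specific peptide and compare to genotype.

    A sample is a carrier-by-proteotype when its log2 peptide abundance
    exceeds a threshold — by default the midpoint between the two component
    means of an equal-variance Gaussian mixture fit by EM (deterministic
    quantile initialization); pass ``threshold`` to override.  Missing
    peptide intensities are floored at the row's minimum observed value
    (absence of the allele-specific signal is informative, not ignorable).
    A mixture separation below ``min_separation`` log2 units marks the
    result uncallable rather than silently thresholding noise.
    """
    if peptide_row_id not in matrix.data.index:
        raise QCError(f"peptide row {peptide_row_id!r} absent from matrix")
    meta = metadata.aligned_to(matrix)
    if dedupe_individuals:
        meta = meta.first_per_individual()
    y = matrix.data.loc[peptide_row_id, meta.df.index]
    if y.notna().any():
        y = y.fillna(float(y.min()))
    carrier_geno = meta.apoe_carrier()
    genotyped = carrier_geno.notna()
    if not genotyped.any():
        raise QCError("no sample has a recorded APOE genotype")

    x = y.to_numpy(dtype=float)
    if matrix.stage == "raw":
        x = np.log2(np.clip(x, 1e-12, None))
    notes: list[str] = []
    lo = hi = np.nan
    if threshold is None:
        lo, hi, _sd = _em_two_gaussian(x)
        thr = 0.5 * (lo + hi)
        callable_ = (hi - lo) >= min_separation
        if not callable_:
            notes.append(f"mixture separation {hi - lo:.3f} log2 units < {min_separation}; uncallable")
    else:
        thr = float(threshold)
        callable_ = True

    called = x > thr
    df = pd.DataFrame({
        "apoe4_log2_abundance": x,
        "recorded_apoe": meta.df["apoe"],
        "carrier_by_genotype": carrier_geno,
        "carrier_by_proteotype": called,
    }, index=meta.df.index)
    df["concordant"] = df["carrier_by_genotype"] == df["carrier_by_proteotype"]
    sub = df[genotyped.to_numpy()]
    n = len(sub)
    fp = int(((~sub["carrier_by_genotype"].astype(bool)) & sub["carrier_by_proteotype"]).sum())
    fn = int((sub["carrier_by_genotype"].astype(bool) & ~sub["carrier_by_proteotype"]).sum())
    concordance = 1.0 - (fp + fn) / n
    pos, neg = x[called], x[~called]
    if len(pos) and len(neg):
        fold = float(np.mean(np.exp2(pos)) / np.mean(np.exp2(neg)))
    else:
        fold = np.nan
        notes.append("one called group is empty; fold change undefined")
    return ProteotypeResult(per_sample=df, threshold=float(thr),
                            concordance=float(concordance),
                            n_false_positive=fp, n_false_negative=fn,
                            false_positive_rate=fp / n,
                            fold_change=fold, callable=callable_,
                            component_means=(float(lo), float(hi)), notes=notes)
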