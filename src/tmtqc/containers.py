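"""Core in-memory containers shared by every pipeline stage.

The central object is :class:`AbundanceMatrix`, a protein-group × sample
grid of reporter-ion-derived abundances with explicit missing entries and a
processing-stage tag, so each stage can assert what scale its input is on
(raw linear intensities, loading-normalized ratios, log2 ratios, or
batch-corrected log2 ratios).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, MetadataError

#: Allowed processing stages, in pipeline order.
STAGES = ("raw", "ratio", "log2", "batch_corrected")

#: Metadata columns the pipeline understands.  ``sample_id`` is the index.
METADATA_COLUMNS = (
    "individual_id",
    "batch",
    "site",
    "sex",
    "race",
    "diagnosis",
    "age",
    "cerad",
    "braak",
    "apoe",
)

_APOE_ALLELES = ("e2", "e3", "e4")


@dataclass
class AbundanceMatrix:
    """Protein groups in rows, samples in columns; NaN marks a missing value.

    Parameters
    ----------
    data
        DataFrame indexed by protein-group id (``accession|gene-symbol``
        strings) with one column per sample.  Values are nonnegative floats
        on the raw/ratio stages; any real number on log2 stages.
    stage
        One of :data:`STAGES`.
    """

    data: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise FormatError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if not self.data.index.is_unique:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate protein ids: {dups}")
        if not self.data.columns.is_unique:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        self.data = self.data.astype(float)
        values = self.data.to_numpy()
        if self.stage in ("raw", "ratio"):
            if np.nanmin(values, initial=np.inf) < 0:
                raise FormatError(f"negative values not allowed at stage {self.stage!r}")
        if self.stage == "ratio":
            sums = np.nansum(values, axis=0)
            observed = ~np.all(np.isnan(values), axis=0)
            if not np.allclose(sums[observed], 1.0, atol=1e-9):
                raise FormatError("ratio-stage column sums must equal 1 within 1e-9")

    @property
    def protein_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def n_proteins(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.data.to_numpy())

    def missing_fraction(self) -> float:
        return float(np.mean(self.missing_mask()))

    def subset_proteins(self, keep: Sequence[str]) -> "AbundanceMatrix":
        return AbundanceMatrix(self.data.loc[list(keep)].copy(), stage=self.stage)

    def subset_samples(self, keep: Sequence[str]) -> "AbundanceMatrix":
        return AbundanceMatrix(self.data[list(keep)].copy(), stage=self.stage)

    def with_values(self, values: np.ndarray, stage: str) -> "AbundanceMatrix":
        """Same ids, new grid and stage tag."""
        df = pd.DataFrame(values, index=self.data.index.copy(), columns=self.data.columns.copy())
        return AbundanceMatrix(df, stage=stage)

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.data.copy(), stage=self.stage)

    def equals(self, other: "AbundanceMatrix") -> bool:
        if self.stage != other.stage:
            return False
        if self.protein_ids != other.protein_ids or self.sample_ids != other.sample_ids:
            return False
        a, b = self.values, other.values
        return bool(np.array_equal(np.isnan(a), np.isnan(b)) and np.allclose(
            np.nan_to_num(a), np.nan_to_num(b), rtol=0, atol=0))


def parse_apoe(value: Any) -> str | None:
    """Normalize an APOE genotype string into a sorted ``"e2/e4"``-style pair.

    Accepts ``"e3/e4"``, ``"E4/E3"``, ``"ε3/ε4"``, ``"3/4"`` or ``"34"``;
    allele order is irrelevant (the genotype is an unordered pair).  Missing
    or empty input returns None.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip().lower().replace("ε", "e").replace("ε", "e")
    if text in ("", "na", "nan", "none", "unknown"):
        return None
    digits = [c for c in text if c in "234"]
    if len(digits) != 2:
        raise MetadataError(f"cannot parse APOE genotype {value!r}")
    alleles = sorted(f"e{d}" for d in digits)
    return "/".join(alleles)


def apoe_is_carrier(pair: str | None) -> bool | None:
    """True when the genotype pair contains an ε4 allele; None when unknown."""
    if pair is None:
        return None
    return "e4" in pair.split("/")


@dataclass
class SampleMetadata:
    """Per-sample traits driving regression, partitioning, and validation.

    ``df`` is indexed by sample_id and carries the columns in
    :data:`METADATA_COLUMNS`.  ``apoe`` holds normalized unordered pairs
    (see :func:`parse_apoe`); ``cerad`` is an ordinal plaque score and
    ``braak`` an ordinal 0–6 tangle stage.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.df.index.is_unique:
            dups = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise MetadataError(f"duplicate sample ids: {dups}")
        missing_cols = [c for c in METADATA_COLUMNS if c not in self.df.columns]
        if missing_cols:
            raise MetadataError(f"metadata missing required columns: {missing_cols}")
        # each batch must map to exactly one site
        pairs = self.df[["batch", "site"]].dropna().drop_duplicates()
        counts = pairs.groupby("batch", observed=True)["site"].nunique()
        crossed = counts[counts > 1].index.tolist()
        if crossed:
            raise MetadataError(f"batches mapped to more than one site: {crossed}")
        bad_braak = self._bad_ordinal("braak", range(0, 7))
        if bad_braak:
            raise MetadataError(
                f"braak values outside 0..6 for samples: {bad_braak}")
        bad_cerad = self._bad_ordinal("cerad", range(0, 5))
        if bad_cerad:
            raise MetadataError(
                f"cerad values outside the accepted 0..4 codings for samples: {bad_cerad}")

    def _bad_ordinal(self, col: str, allowed: Iterable[int]) -> list[str]:
        allowed = set(allowed)
        bad: list[str] = []
        for sid, v in self.df[col].items():
            if pd.isna(v):
                continue
            try:
                iv = int(v)
            except (TypeError, ValueError):
                bad.append(str(sid))
                continue
            if iv != float(v) or iv not in allowed:
                bad.append(str(sid))
        return bad

    @property
    def sample_ids(self) -> list[str]:
        return self.df.index.tolist()

    def subset(self, keep: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.df.loc[list(keep)].copy())

    def aligned_to(self, matrix: AbundanceMatrix) -> "SampleMetadata":
        """Metadata rows reordered to the matrix's samples; unmatched is an error."""
        unmatched = [s for s in matrix.sample_ids if s not in self.df.index]
        if unmatched:
            raise MetadataError(f"samples absent from metadata: {unmatched}")
        return self.subset(matrix.sample_ids)

    def apoe_carrier(self) -> pd.Series:
        """Boolean ε4-carrier flag per sample (None where genotype unknown)."""
        return self.df["apoe"].map(apoe_is_carrier)

    def first_per_individual(self) -> "SampleMetadata":
        """Keep the first sample (in current row order) per individual.

        Replicate tissues from one donor share ``individual_id``; analyses
        reported per unique individual use this documented selector.
        """
        keep = ~self.df["individual_id"].duplicated()
        return SampleMetadata(self.df[keep].copy())


@dataclass
class QCStep:
    """One auditable record of a QC operation."""

    name: str
    params: dict[str, Any]
    n_proteins_before: int
    n_proteins_after: int
    n_samples_before: int
    n_samples_after: int
    details: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "params": self.params,
            "n_proteins_before": self.n_proteins_before,
            "n_proteins_after": self.n_proteins_after,
            "n_samples_before": self.n_samples_before,
            "n_samples_after": self.n_samples_after,
            "details": self.details,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "QCStep":
        return cls(**d)


@dataclass
class QCReport:
    """Ordered record of every QC step applied to a dataset."""

    steps: list[QCStep] = field(default_factory=list)
    schema_version: int = 1

    def add(self, step: QCStep) -> None:
        if self.steps:
            last = self.steps[-1]
            if (step.n_proteins_before > last.n_proteins_after
                    or step.n_samples_before > last.n_samples_after):
                raise ValueError(
                    f"step {step.name!r} starts from more proteins/samples than the previous step ended with")
        self.steps.append(step)

    def removed_samples(self) -> list[str]:
        out: list[str] = []
        for step in self.steps:
            for rnd in step.details.get("rounds", []):
                out.extend(rnd["removed"])
        return out

    def to_dict(self) -> dict[str, Any]:
        return {"schema_version": self.schema_version,
                "steps": [s.to_dict() for s in self.steps]}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "QCReport":
        return cls(steps=[QCStep.from_dict(s) for s in d["steps"]],
                   schema_version=d.get("schema_version", 1))
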