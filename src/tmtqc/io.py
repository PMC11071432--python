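"""Readers and writers for abundance matrices, metadata, and QC reports.

Formats are deliberately plain: tab-separated matrices (proteins in rows,
samples in columns — the convention of search-engine protein reports), CSV
metadata, and JSON QC reports with a schema version.  Writers prepend a
provenance comment line; readers never silently coerce — every cell that is
dropped or reinterpreted is counted and logged.
"""

from __future__ import annotations

import json
import logging
from importlib.metadata import version, PackageNotFoundError
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, SampleMetadata, QCReport, METADATA_COLUMNS, parse_apoe
from .errors import FormatError, MetadataError

logger = logging.getLogger(__name__)

DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "nan", "N/A")


def _tool_version() -> str:
    try:
        return version("tmtqc")
    except PackageNotFoundError:  # pragma: no cover - not installed
        return "unknown"


def read_abundance(path: str | Path,
                   missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
                   zero_as_missing: bool = True,
                   stage: str = "raw") -> AbundanceMatrix:
    """Read a tab-delimited protein × sample abundance table.

    The first column holds protein-group ids; every other column is one
    sample.  Cells matching ``missing_tokens`` become missing; literal 0
    intensities are treated as missing when ``zero_as_missing`` (the default
    for reporter-ion reports, where absence is encoded as 0 and would
    otherwise break the log2 transform).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, comment="#",
                     na_values=list(missing_tokens), keep_default_na=False,
                     dtype=str)
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path.name}: duplicate sample ids {dups}")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path.name}: duplicate protein ids {dups}")
    try:
        values = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path.name}: non-numeric abundance cell ({exc})") from exc
    neg = values.lt(0) if stage in ("raw", "ratio") else pd.DataFrame(False, index=values.index, columns=values.columns)
    if neg.any().any():
        prot = values.index[neg.any(axis=1)][0]
        col = values.columns[neg.loc[prot].to_numpy().nonzero()[0][0]]
        raise FormatError(f"{path.name}: negative value at protein {prot!r}, sample {col!r}")
    if zero_as_missing:
        n_zero = int(values.eq(0).sum().sum())
        if n_zero:
            logger.warning("%s: %d zero-intensity cells treated as missing", path.name, n_zero)
            values = values.replace(0.0, np.nan)
    df.index.name = "protein_id"
    return AbundanceMatrix(values, stage=stage)


def write_abundance(matrix: AbundanceMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# tmtqc v{_tool_version()} abundance matrix; stage={matrix.stage}\n")
        df = matrix.data.copy()
        df.index.name = "protein_id"
        df.to_csv(fh, sep="\t", na_rep="NA", lineterminator="\n")


# columns accepted in input CSVs, mapped onto the canonical names
_METADATA_ALIASES = {
    "sampleid": "sample_id", "sample": "sample_id", "specimenid": "sample_id",
    "individualid": "individual_id", "individual": "individual_id", "projid": "individual_id",
    "plex": "batch", "tmt_batch": "batch",
    "center": "site", "cohort": "site",
    "msex": "sex", "gender": "sex",
    "ethnicity": "race",
    "dx": "diagnosis", "dcfdx": "diagnosis",
    "age_death": "age", "ageatdeath": "age",
    "ceradsc": "cerad", "cerad_score": "cerad",
    "braaksc": "braak", "braak_stage": "braak",
    "apoe_genotype": "apoe", "apoe4": "apoe",
}


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a sample-metadata CSV into canonical columns.

    Header names are matched case-insensitively against a documented alias
    table; APOE genotypes are normalized into unordered allele pairs.
    Unknown Braak/CERAD codes raise a validation error listing the samples.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype=str)
    rename = {}
    for col in df.columns:
        key = col.strip().lower().replace(" ", "_")
        rename[col] = _METADATA_ALIASES.get(key.replace("_", ""), _METADATA_ALIASES.get(key, key))
    df = df.rename(columns=rename)
    if "sample_id" not in df.columns:
        raise MetadataError(f"{path.name}: no sample_id column found")
    df = df.set_index("sample_id")
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    bad_apoe: list[str] = []
    parsed = []
    for sid, raw in df["apoe"].items():
        try:
            parsed.append(parse_apoe(raw))
        except MetadataError:
            bad_apoe.append(str(sid))
            parsed.append(None)
    if bad_apoe:
        raise MetadataError(f"{path.name}: unparseable APOE genotypes for samples {bad_apoe}")
    df["apoe"] = parsed
    for col in ("age", "cerad", "braak"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return SampleMetadata(df[list(METADATA_COLUMNS)])


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# tmtqc v{_tool_version()} sample metadata\n")
        df = metadata.df.copy()
        df.index.name = "sample_id"
        df.to_csv(fh, lineterminator="\n")


def write_report(report: QCReport, path: str | Path) -> None:
    """Serialize a QC report as versioned JSON."""
    payload = report.to_dict()
    payload["tool_version"] = _tool_version()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=_json_default)
        fh.write("\n")


def read_report(path: str | Path) -> QCReport:
    with open(path) as fh:
        return QCReport.from_dict(json.load(fh))


def _json_default(obj: object) -> object:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
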