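"""Cohort input: Ct tables and sample metadata.

Files are comma- or tab-separated with a header row; the delimiter is
auto-detected. Ct cells holding the literal string ``undetermined`` are kept
as missing replicates (NaN) and handled downstream.
"""

from __future__ import annotations

import csv
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    UNDETERMINED,
    Role,
    RunConfig,
    SampleMeta,
    Subtype,
)
from .errors import ConfigError, InputFormatError, ValidationError

logger = logging.getLogger(__name__)

CT_COLUMNS = ("sample_id", "assay_id", "replicate", "ct")
META_COLUMNS = ("sample_id", "subtype", "role")


@dataclass
class CtTable:
    """Long-format cycle-threshold records.

    ``df`` has columns sample_id, assay_id, assay_class, replicate, ct; a
    NaN ct is an undetermined well. ``unknown_assays`` lists assay ids that
    matched neither panel nor reference in the run configuration.
    """

    df: pd.DataFrame
    unknown_assays: tuple[str, ...] = ()
    flagged: tuple[tuple[str, str], ...] = field(default=())
    # flagged: (sample_id, assay_id) pairs with no usable replicate at all

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.df["sample_id"].unique())

    @property
    def assay_ids(self) -> list[str]:
        return sorted(self.df["assay_id"].unique())


def _read_delimited(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"{what} file not found: {path}")
    try:
        # sep=None + python engine sniffs comma vs tab from the header line
        df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                         skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{what} file is empty: {path}") from None
    except csv.Error as exc:
        raise ValidationError(
            f"{what} file {path} is not a delimited table: {exc}"
        ) from None
    if df.empty:
        raise ValidationError(f"{what} file has no data rows: {path}")
    df.columns = [c.strip() for c in df.columns]
    return df


def read_ct_table(path: str | Path, config: RunConfig) -> CtTable:
    """Load and validate a long-format Ct file.

    Raises InputFormatError for missing columns, ValidationError for
    duplicate (sample, assay, replicate) keys or unparseable cells. Unknown
    assays load with a warning; sample x assay cells whose replicates are all
    undetermined are flagged, not fatal.
    """
    df = _read_delimited(path, "Ct table")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(
            f"Ct table {path} is missing required columns: {missing}"
        )
    df = df[list(CT_COLUMNS)].copy()
    for col in ("sample_id", "assay_id"):
        df[col] = df[col].str.strip()

    try:
        df["replicate"] = df["replicate"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-integer replicate value in {path}: {exc}")
    if (df["replicate"] < 1).any():
        bad = df.loc[df["replicate"] < 1].iloc[0]
        raise ValidationError(
            f"replicate numbers must be >= 1; got {bad['replicate']} for "
            f"({bad['sample_id']}, {bad['assay_id']})"
        )

    dup = df.duplicated(subset=["sample_id", "assay_id", "replicate"])
    if dup.any():
        key = df.loc[dup, ["sample_id", "assay_id", "replicate"]].iloc[0]
        raise ValidationError(
            "duplicate Ct record for key "
            f"({key['sample_id']}, {key['assay_id']}, {key['replicate']})"
        )

    ct_raw = df["ct"].str.strip()
    is_undet = ct_raw.str.lower() == UNDETERMINED

    # builtin float() round-trips repr output exactly; pandas' own float
    # parsing can be off by an ulp, which would break the round-trip contract
    def _parse(cell: str) -> float:
        if pd.isna(cell):
            return math.nan
        try:
            return float(cell)
        except ValueError:
            return math.inf  # sentinel; rejected below

    ct = ct_raw.where(~is_undet).map(_parse)
    bad_cells = np.isinf(ct.to_numpy(dtype=float))
    if bad_cells.any():
        row = df.loc[bad_cells].iloc[0]
        raise ValidationError(
            f"unparseable ct value {row['ct']!r} for "
            f"({row['sample_id']}, {row['assay_id']}, {row['replicate']})"
        )
    if (ct.dropna() < 0).any():
        raise ValidationError(f"negative Ct values present in {path}")
    df["ct"] = ct

    df["assay_class"] = df["assay_id"].map(
        lambda a: (cls := config.assay_class(a)) and cls.value
    )
    unknown = tuple(sorted(df.loc[df["assay_class"].isna(), "assay_id"].unique()))
    if unknown:
        warnings.warn(
            f"Ct table contains assays outside the configured panels and "
            f"references: {list(unknown)}",
            stacklevel=2,
        )

    all_missing = (
        df.groupby(["sample_id", "assay_id"])["ct"]
        .apply(lambda s: s.isna().all())
    )
    flagged = tuple(all_missing.index[all_missing])
    for sample_id, assay_id in flagged:
        logger.warning(
            "all replicates undetermined for sample %s assay %s",
            sample_id, assay_id,
        )

    order = ["sample_id", "assay_id", "assay_class", "replicate", "ct"]
    return CtTable(df=df[order].reset_index(drop=True),
                   unknown_assays=unknown, flagged=flagged)


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    """Load and validate the sample metadata file."""
    df = _read_delimited(path, "metadata")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(
            f"metadata file {path} is missing required columns: {missing}"
        )
    samples: list[SampleMeta] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sample_id = str(row["sample_id"]).strip()
        if sample_id in seen:
            raise ValidationError(f"duplicate sample_id {sample_id!r}")
        seen.add(sample_id)
        try:
            subtype = Subtype(str(row["subtype"]).strip())
        except ValueError:
            raise ValidationError(
                f"unknown subtype {row['subtype']!r} for sample {sample_id!r}; "
                f"expected one of {[s.value for s in Subtype]}"
            ) from None
        try:
            role = Role(str(row["role"]).strip())
        except ValueError:
            raise ValidationError(
                f"unknown role {row['role']!r} for sample {sample_id!r}"
            ) from None
        samples.append(SampleMeta(sample_id=sample_id, subtype=subtype, role=role))

    if not any(s.role is Role.CALIBRATOR for s in samples):
        raise ConfigError("cohort contains no calibrator (normal) samples")

    counts = subtype_counts(samples)
    logger.info("loaded %d samples: %s", len(samples),
                {k.value: v for k, v in counts.items()})
    return samples


def subtype_counts(samples: list[SampleMeta]) -> dict[Subtype, int]:
    counts: dict[Subtype, int] = {s: 0 for s in Subtype}
    for s in samples:
        counts[s.subtype] += 1
    return counts


def metadata_frame(samples: list[SampleMeta]) -> pd.DataFrame:
    """Metadata as a DataFrame indexed by sample_id."""
    return pd.DataFrame(
        {
            "subtype": [s.subtype.value for s in samples],
            "role": [s.role.value for s in samples],
        },
        index=pd.Index([s.sample_id for s in samples], name="sample_id"),
    )


def write_ct_table(table: CtTable, path: str | Path) -> None:
    out = table.df.copy()
    # repr round-trips doubles exactly, keeping write->read lossless
    out["ct"] = out["ct"].map(
        lambda v: UNDETERMINED if pd.isna(v) else repr(float(v))
    )
    out.drop(columns=["assay_class"]).to_csv(path, index=False)


def write_metadata(samples: list[SampleMeta], path: str | Path) -> None:
    metadata_frame(samples).to_csv(path)
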