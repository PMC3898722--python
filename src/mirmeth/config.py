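"""Run configuration and sample metadata types.

The default panels are the nine DNMT3b-regulating microRNAs (normalized to
RNU66) and the nine methylation-sensitive biomarker genes (normalized to
beta-actin) used throughout the pipeline.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .errors import ConfigError, ValidationError

DEFAULT_MIR_PANEL = (
    "miR-29a",
    "miR-29b",
    "miR-29c",
    "miR-148a",
    "miR-148b",
    "miR-26a",
    "miR-26b",
    "miR-203",
    "miR-222",
)

DEFAULT_GENE_PANEL = (
    "CEACAM6",
    "CDH1",
    "CST6",
    "ESR1",
    "GNA11",
    "MUC1",
    "MYB",
    "TFF3",
    "SCNN1A",
)

UNDETERMINED = "undetermined"


class Subtype(str, enum.Enum):
    LUMINAL_A = "luminal_A"
    LUMINAL_B = "luminal_B"
    HER2_ENRICHED = "her2_enriched"
    BASAL_LIKE = "basal_like"
    NORMAL = "normal"


class Role(str, enum.Enum):
    TUMOR = "tumor"
    CALIBRATOR = "calibrator"


class AssayClass(str, enum.Enum):
    MIR = "mir"
    GENE = "gene"
    MIR_REFERENCE = "mir_reference"
    GENE_REFERENCE = "gene_reference"


TUMOR_SUBTYPES = (
    Subtype.LUMINAL_A,
    Subtype.LUMINAL_B,
    Subtype.HER2_ENRICHED,
    Subtype.BASAL_LIKE,
)


@dataclass(frozen=True)
class SampleMeta:
    """One cohort sample: identity, molecular subtype and analysis role."""

    sample_id: str
    subtype: Subtype
    role: Role

    def __post_init__(self) -> None:
        is_normal = self.subtype is Subtype.NORMAL
        is_calibrator = self.role is Role.CALIBRATOR
        if is_normal != is_calibrator:
            raise ValidationError(
                f"sample {self.sample_id!r}: role=calibrator is only valid for "
                f"subtype=normal (got subtype={self.subtype.value}, "
                f"role={self.role.value})"
            )


@dataclass
class RunConfig:
    """All tunable choices of a pipeline run.

    ``median_population`` selects which samples the per-assay binarization
    medians are computed over; ``rounding`` controls how diagnostic
    percentages are rounded to integers.
    """

    mir_panel: tuple[str, ...] = DEFAULT_MIR_PANEL
    gene_panel: tuple[str, ...] = DEFAULT_GENE_PANEL
    mir_reference: str = "RNU66"
    gene_reference: str = "ACTB"
    hypermethylator_gene_cutoff: int = 7
    mir_low_group_cutoff: int = 6
    median_population: str = "tumors_only"  # or "all_samples"
    rounding: str = "half_up"  # or "banker"
    t_test_variant: str = "student"  # or "welch"
    seed: int = 0

    def __post_init__(self) -> None:
        self.mir_panel = tuple(self.mir_panel)
        self.gene_panel = tuple(self.gene_panel)
        if not self.mir_panel or not self.gene_panel:
            raise ConfigError("mir_panel and gene_panel must be non-empty")
        panels = set(self.mir_panel) | set(self.gene_panel)
        if len(panels) != len(self.mir_panel) + len(self.gene_panel):
            raise ConfigError("mir_panel and gene_panel must be disjoint")
        if {self.mir_reference, self.gene_reference} & panels:
            raise ConfigError("reference assays must not appear in the panels")
        if not 0 <= self.hypermethylator_gene_cutoff <= len(self.gene_panel):
            raise ConfigError(
                "hypermethylator_gene_cutoff must lie in "
                f"[0, {len(self.gene_panel)}]"
            )
        if not 0 <= self.mir_low_group_cutoff <= len(self.mir_panel):
            raise ConfigError(
                f"mir_low_group_cutoff must lie in [0, {len(self.mir_panel)}]"
            )
        if self.median_population not in ("tumors_only", "all_samples"):
            raise ConfigError(
                "median_population must be 'tumors_only' or 'all_samples'"
            )
        if self.rounding not in ("half_up", "banker"):
            raise ConfigError("rounding must be 'half_up' or 'banker'")
        if self.t_test_variant not in ("student", "welch"):
            raise ConfigError("t_test_variant must be 'student' or 'welch'")

    @property
    def panel_assays(self) -> tuple[str, ...]:
        return self.mir_panel + self.gene_panel

    def assay_class(self, assay_id: str) -> AssayClass | None:
        """Classify an assay id, or None when it is unknown to this config."""
        if assay_id in self.mir_panel:
            return AssayClass.MIR
        if assay_id in self.gene_panel:
            return AssayClass.GENE
        if assay_id == self.mir_reference:
            return AssayClass.MIR_REFERENCE
        if assay_id == self.gene_reference:
            return AssayClass.GENE_REFERENCE
        return None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            return cls()
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        out = {f.name: getattr(self, f.name) for f in fields(self)}
        out["mir_panel"] = list(self.mir_panel)
        out["gene_panel"] = list(self.gene_panel)
        return out
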