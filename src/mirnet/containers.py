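"""Core in-memory containers shared across the pipeline stages.

All containers are thin, validated wrappers around :class:`pandas.DataFrame`.
Feature-by-sample matrices keep features on the rows (index = feature id) and
samples on the columns, mirroring the on-disk TSV layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("sham", "MI")
SPECIES = ("mouse", "rat", "human")


class MirnetError(ValueError):
    """Base class for validation failures raised by this package."""


class TransformState(str, Enum):
    """Where an expression matrix sits in the normalization chain.

    Transitions only move forward: linear -> log2p1 -> log2p1_quantile.
    """

    LINEAR = "linear"
    LOG2P1 = "log2p1"
    LOG2P1_QUANTILE = "log2p1_quantile"


_STATE_ORDER = {
    TransformState.LINEAR: 0,
    TransformState.LOG2P1: 1,
    TransformState.LOG2P1_QUANTILE: 2,
}


@dataclass(frozen=True)
class SampleDesign:
    """Sample sheet: one row per sequenced library.

    Columns: sample_id, condition in {sham, MI}, stage (e.g. 1D/1W/8W),
    replicate (integer). (condition, stage, replicate) must be unique.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "stage", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise MirnetError(f"design table missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            dupes = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise MirnetError(f"duplicate sample ids: {sorted(set(dupes))}")
        bad = set(self.table["condition"]) - set(CONDITIONS)
        if bad:
            raise MirnetError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")
        key = self.table[["condition", "stage", "replicate"]]
        if key.duplicated().any():
            raise MirnetError("(condition, stage, replicate) rows are not unique")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def stages(self) -> list[str]:
        """Stage labels in first-appearance order."""
        return list(dict.fromkeys(self.table["stage"]))

    def samples(self, condition: str | None = None, stage: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if condition is not None:
            mask &= self.table["condition"] == condition
        if stage is not None:
            mask &= self.table["stage"] == stage
        return list(self.table.loc[mask, "sample_id"])

    def require_stage(self, stage: str) -> None:
        if stage not in set(self.table["stage"]):
            raise MirnetError(f"stage {stage!r} absent from design (have {self.stages})")


@dataclass
class CountMatrix:
    """Raw integer read counts, features x samples.

    ``lengths`` (feature length in bases) is mandatory for the mRNA layer and
    forbidden for the miRNA layer, matching what FPKM vs RPM need.
    """

    counts: pd.DataFrame
    design: SampleDesign
    layer: str  # "mRNA" | "miRNA"
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.layer not in ("mRNA", "miRNA"):
            raise MirnetError(f"unknown layer {self.layer!r}")
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()]
            raise MirnetError(f"duplicate feature ids: {sorted(set(dupes))}")
        if list(self.counts.columns) != self.design.sample_ids:
            raise MirnetError("count matrix columns do not match the design sample ids")
        if (self.counts.values < 0).any():
            raise MirnetError("negative counts")
        if self.layer == "mRNA":
            if self.lengths is None:
                raise MirnetError("mRNA counts require feature lengths")
            if not self.lengths.index.equals(self.counts.index):
                raise MirnetError("length index does not match count matrix features")
            if (self.lengths <= 0).any():
                raise MirnetError("feature lengths must be positive")
        elif self.lengths is not None:
            raise MirnetError("miRNA counts do not carry feature lengths")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index


@dataclass
class ExpressionMatrix:
    """Normalized expression (FPKM or RPM), optionally log2(+1)/quantile-normalized."""

    values: pd.DataFrame
    design: SampleDesign
    layer: str
    transform_state: TransformState = TransformState.LINEAR

    def __post_init__(self) -> None:
        if list(self.values.columns) != self.design.sample_ids:
            raise MirnetError("expression columns do not match the design sample ids")

    def require_state(self, state: TransformState) -> None:
        if self.transform_state is not state:
            raise MirnetError(
                f"expected transform state {state.value!r}, got {self.transform_state.value!r}"
            )

    def advanced(self, values: pd.DataFrame, state: TransformState) -> "ExpressionMatrix":
        """Return a copy advanced to ``state`` (forward transitions only)."""
        if _STATE_ORDER[state] < _STATE_ORDER[self.transform_state]:
            raise MirnetError(
                f"transform state may only advance ({self.transform_state.value} -> {state.value})"
            )
        return ExpressionMatrix(values, self.design, self.layer, state)


DIRECTIONS = ("up", "down", "ns")


@dataclass
class DETable:
    """Per-feature, per-stage differential-expression calls.

    Columns: feature_id, stage, mean_sham, mean_mi, log2fc, fold_change,
    p_raw, p_adj, direction. Thresholds used for the calls ride along so a
    serialized table is self-describing.
    """

    records: pd.DataFrame
    alpha: float = 0.05
    fc_threshold: float = 2.0

    COLUMNS = (
        "feature_id",
        "stage",
        "mean_sham",
        "mean_mi",
        "log2fc",
        "fold_change",
        "p_raw",
        "p_adj",
        "direction",
    )

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.records.columns)
        if missing:
            raise MirnetError(f"DE table missing columns: {sorted(missing)}")
        if self.records[["feature_id", "stage"]].duplicated().any():
            raise MirnetError("duplicate (feature, stage) records in DE table")
        bad = set(self.records["direction"]) - set(DIRECTIONS)
        if bad:
            raise MirnetError(f"unknown DE directions: {sorted(bad)}")

    @property
    def stages(self) -> list[str]:
        return list(dict.fromkeys(self.records["stage"]))

    def slice(self, stage: str) -> pd.DataFrame:
        return self.records[self.records["stage"] == stage]

    def direction_of(self, feature_id: str, stage: str) -> str:
        sub = self.records[
            (self.records["feature_id"] == feature_id) & (self.records["stage"] == stage)
        ]
        if sub.empty:
            return "ns"
        return sub["direction"].iloc[0]

    def features_with_direction(self, stage: str, direction: str) -> set[str]:
        sub = self.slice(stage)
        return set(sub.loc[sub["direction"] == direction, "feature_id"])

    def de_features(self, stage: str | None = None) -> set[str]:
        """Features called up or down at ``stage`` (or at any stage)."""
        rec = self.records if stage is None else self.slice(stage)
        return set(rec.loc[rec["direction"] != "ns", "feature_id"])

    @staticmethod
    def concat(tables: Sequence["DETable"]) -> "DETable":
        if not tables:
            raise MirnetError("no DE tables to concatenate")
        alpha = tables[0].alpha
        fc = tables[0].fc_threshold
        return DETable(
            pd.concat([t.records for t in tables], ignore_index=True), alpha=alpha, fc_threshold=fc
        )


@dataclass
class TargetPredictionTable:
    """miRNA-family -> gene target predictions (TargetScan-style).

    One row per predicted family/gene site group with its weighted context++
    score percentile (wcsp, 0-100), seed-site count, per-species conservation
    flags of the site, and a site-level conserved/non-conserved flag used by
    the >=10-conserved-targets rule.
    """

    table: pd.DataFrame

    COLUMNS = (
        "family_id",
        "gene_id",
        "wcsp",
        "seed_sites",
        "conserved_mouse",
        "conserved_rat",
        "conserved_human",
        "conserved_site",
    )

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise MirnetError(f"prediction table missing columns: {sorted(missing)}")
        wcsp = self.table["wcsp"]
        if ((wcsp < 0) | (wcsp > 100)).any():
            raise MirnetError("wcsp outside [0, 100]")
        if (self.table["seed_sites"] < 0).any():
            raise MirnetError("negative seed-site counts")

    def for_family(self, family_id: str) -> pd.DataFrame:
        return self.table[self.table["family_id"] == family_id]

    def families(self) -> set[str]:
        return set(self.table["family_id"])


@dataclass
class FamilyRegistry:
    """miRNA -> family membership with family-level species conservation."""

    table: pd.DataFrame  # columns: mirna_id, family_id, conserved_mouse/rat/human

    COLUMNS = ("mirna_id", "family_id", "conserved_mouse", "conserved_rat", "conserved_human")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise MirnetError(f"family registry missing columns: {sorted(missing)}")
        if self.table["mirna_id"].duplicated().any():
            raise MirnetError("a miRNA may belong to only one family")

    def family_of(self, mirna_id: str) -> str:
        sub = self.table[self.table["mirna_id"] == mirna_id]
        if sub.empty:
            raise MirnetError(f"miRNA {mirna_id!r} absent from family registry")
        return sub["family_id"].iloc[0]

    def members(self, family_id: str) -> list[str]:
        return list(self.table.loc[self.table["family_id"] == family_id, "mirna_id"])

    def families(self) -> list[str]:
        return list(dict.fromkeys(self.table["family_id"]))

    def species_conservation(self, family_id: str) -> set[str]:
        """Species in which the family is conserved (all members agree)."""
        sub = self.table[self.table["family_id"] == family_id]
        if sub.empty:
            raise MirnetError(f"unknown family {family_id!r}")
        out = set()
        for sp in SPECIES:
            if sub[f"conserved_{sp}"].all():
                out.add(sp)
        return out


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise MirnetError(f"gene set {self.name!r} is empty")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            raise MirnetError("duplicate gene-set names in collection")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass
class GOAnnotationTable:
    """Flat gene -> GO term annotation (no term-tree propagation)."""

    table: pd.DataFrame  # columns: gene_id, term

    def __post_init__(self) -> None:
        missing = {"gene_id", "term"} - set(self.table.columns)
        if missing:
            raise MirnetError(f"GO table missing columns: {sorted(missing)}")

    def terms(self) -> list[str]:
        return list(dict.fromkeys(self.table["term"]))

    def genes_for(self, term: str) -> set[str]:
        return set(self.table.loc[self.table["term"] == term, "gene_id"])

    def has_term(self, term: str) -> bool:
        return term in set(self.table["term"])
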