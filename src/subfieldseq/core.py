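"""Shared domain types and validation for the subfield pipeline.

The analysis operates on gene-level count matrices from two sequencing
platforms (labelled ``A`` for the Illumina-like discovery platform and ``B``
for the Ion-Proton-like validation platform) together with a per-sample
design sheet describing animal, hippocampal region (CA1, CA3, DG), age
group, cognitive class and site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REGIONS = ("CA1", "CA3", "DG")
PLATFORMS = ("A", "B")
AGE_GROUPS = ("young", "aged")
COGNITIVE_CLASSES = ("young", "AU", "AI", "unassigned")

#: region pairs in canonical order; a contrast (R1, R2) is oriented
#: "level2 vs level1", i.e. positive log2FC means higher in R2.
REGION_PAIRS = (("CA1", "CA3"), ("CA1", "DG"), ("CA3", "DG"))

SAMPLESHEET_COLUMNS = (
    "sample_id",
    "animal_id",
    "region",
    "age_group",
    "cognitive_class",
    "platform",
    "site",
)


class PipelineError(Exception):
    """Base class for errors raised by this package."""


class ParseError(PipelineError):
    """Malformed on-disk input (names the offending line/column)."""


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer counts.

    Parameters
    ----------
    counts
        DataFrame with gene identifiers as the index and sample identifiers
        as columns; entries must be non-negative integers.
    platform
        ``"A"`` or ``"B"``.
    """

    counts: pd.DataFrame
    platform: str

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise PipelineError(f"unknown platform label {self.platform!r}")
        idx = self.counts.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise PipelineError(f"duplicate gene ids: {dups[:5]}")
        cols = self.counts.columns
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise PipelineError(f"duplicate sample ids: {dups[:5]}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise PipelineError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise PipelineError("counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(sample_ids)], self.platform)


def validate_samplesheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet DataFrame and return it.

    Enforces required columns, the closed region/age/class/platform
    vocabularies, unique sample ids, and uniqueness of each
    (animal, region, platform) combination.
    """
    missing = [c for c in SAMPLESHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ParseError(f"sample sheet missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"duplicate sample_id {dup!r}")
    for col, allowed in (
        ("region", REGIONS),
        ("age_group", AGE_GROUPS),
        ("cognitive_class", COGNITIVE_CLASSES),
        ("platform", PLATFORMS),
    ):
        bad = set(sheet[col].unique()) - set(allowed)
        if bad:
            raise ParseError(
                f"sample sheet column {col!r} has unknown value(s) {sorted(bad)}; "
                f"allowed: {allowed}"
            )
    key = sheet[["animal_id", "region", "platform"]]
    if key.duplicated().any():
        row = key[key.duplicated()].iloc[0]
        raise ParseError(
            "duplicate (animal_id, region, platform) combination: "
            f"{tuple(row)}"
        )
    return sheet.reset_index(drop=True)


@dataclass
class Contrast:
    """A two-group comparison on one factor of the design.

    ``factor`` is one of ``region``, ``age_group``, ``cognitive_class`` or
    ``cue_split``; the fitted log2 fold change is oriented ``level2`` vs
    ``level1`` (positive = higher in ``level2``).  ``subset`` optionally
    restricts the samples first (e.g. ``{"age_group": "aged"}`` so that the
    impaired/unimpaired comparison excludes young animals, avoiding age as a
    confound; ``{"region": "CA1"}`` for a within-region age contrast).
    """

    factor: str
    level1: str
    level2: str
    subset: dict = field(default_factory=dict)

    @property
    def name(self) -> str:
        parts = [f"{self.level2}_vs_{self.level1}"]
        for k in ("region",):
            if k in self.subset:
                parts.insert(0, str(self.subset[k]))
        return "_".join(parts)

    def select(self, sheet: pd.DataFrame) -> pd.DataFrame:
        """Rows of ``sheet`` participating in the contrast, with a
        ``__group__`` column equal to 0 for level1 and 1 for level2."""
        sub = sheet
        for col, val in self.subset.items():
            sub = sub[sub[col] == val]
        sub = sub[sub[self.factor].isin([self.level1, self.level2])].copy()
        sub["__group__"] = (sub[self.factor] == self.level2).astype(int)
        for level, grp in ((self.level1, 0), (self.level2, 1)):
            if (sub["__group__"] == grp).sum() < 2:
                raise PipelineError(
                    f"contrast {self.name}: level {level!r} has fewer than 2 samples"
                )
        return sub
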