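"""Readers and writers for the pipeline's on-disk formats.

Canonical formats are plain text: counts as TSV (genes as rows, first
column ``gene_id``, header row of sample ids) with MatrixMarket accepted
for interoperability; sample sheets and behavior records as CSV; all
result tables as TSV with fixed column order so outputs diff cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as spio
import yaml

from .core import CountMatrix, ParseError, validate_samplesheet

BEHAVIOR_COLUMNS = (
    ["animal_id", "age_group"]
    + [f"cue_block{i}" for i in range(1, 6)]
    + [f"spatial_block{i}" for i in range(1, 6)]
    + ["probe_goal_pct", "probe_opposite_pct"]
)


def read_counts(path, platform_label: str) -> CountMatrix:
    """Read a gene-level count matrix from TSV or MatrixMarket.

    TSV layout: header ``gene_id<TAB>sample1<TAB>...``; one gene per row.
    MatrixMarket (``.mtx``) requires sidecar files ``<stem>.genes.txt`` and
    ``<stem>.samples.txt`` holding one identifier per line.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        return _read_counts_mtx(path, platform_label)
    return _read_counts_tsv(path, platform_label)


def _read_counts_tsv(path: Path, platform_label: str) -> CountMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "gene_id":
            raise ParseError(
                f"{path}:1: malformed header (expected 'gene_id<TAB>sample...')"
            )
        sample_ids = header[1:]
        gene_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            gene_ids.append(parts[0])
            row = []
            for col, cell in enumerate(parts[1:], start=2):
                try:
                    value = int(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: column {col}: non-integer count {cell!r}"
                    ) from None
                if value < 0:
                    raise ParseError(
                        f"{path}:{lineno}: column {col}: negative count {value}"
                    )
                row.append(value)
            rows.append(row)
    counts = pd.DataFrame(
        np.asarray(rows, dtype=np.int64).reshape(len(gene_ids), len(sample_ids)),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=sample_ids,
    )
    return CountMatrix(counts, platform_label)


def _read_counts_mtx(path: Path, platform_label: str) -> CountMatrix:
    genes_path = path.with_name(path.stem + ".genes.txt")
    samples_path = path.with_name(path.stem + ".samples.txt")
    for sidecar in (genes_path, samples_path):
        if not sidecar.exists():
            raise ParseError(f"missing MatrixMarket sidecar id list: {sidecar}")
    matrix = spio.mmread(path)
    matrix = np.asarray(matrix.todense() if hasattr(matrix, "todense") else matrix)
    if not np.all(np.equal(np.mod(matrix, 1), 0)):
        raise ParseError(f"{path}: non-integer entries")
    gene_ids = genes_path.read_text().split()
    sample_ids = samples_path.read_text().split()
    if matrix.shape != (len(gene_ids), len(sample_ids)):
        raise ParseError(
            f"{path}: matrix shape {matrix.shape} does not match id lists "
            f"({len(gene_ids)} genes, {len(sample_ids)} samples)"
        )
    counts = pd.DataFrame(
        matrix.astype(np.int64),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=sample_ids,
    )
    return CountMatrix(counts, platform_label)


def write_counts(cm: CountMatrix, path) -> None:
    """Write a count matrix in the canonical TSV dialect (lossless
    round-trip with :func:`read_counts`)."""
    df = cm.counts.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_samplesheet(path) -> pd.DataFrame:
    """Read and validate a sample sheet CSV."""
    try:
        sheet = pd.read_csv(path, dtype=str)
    except Exception as exc:  # noqa: BLE001 - surfaced as a parse error
        raise ParseError(f"{path}: {exc}") from exc
    return validate_samplesheet(sheet)


def write_samplesheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index=False, lineterminator="\n")


def read_behavior(path) -> pd.DataFrame:
    """Read behavioral records (per-animal block path lengths and
    probe-trial quadrant percentages) from CSV."""
    df = pd.read_csv(path)
    missing = [c for c in BEHAVIOR_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: behavior file missing columns {missing}")
    if df["animal_id"].duplicated().any():
        dup = df.loc[df["animal_id"].duplicated(), "animal_id"].iloc[0]
        raise ParseError(f"{path}: duplicate animal_id {dup!r}")
    return df


def write_behavior(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def write_table(df: pd.DataFrame, path, comment: str | None = None) -> None:
    """Write a result table as TSV, optionally with a ``#`` header comment
    stating e.g. the contrast orientation."""
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    # keep_default_na off so tokens like the truth class "null" survive;
    # empty cells and the spellings pandas writes for NaN still parse as NA
    return pd.read_csv(
        path,
        sep="\t",
        comment="#",
        keep_default_na=False,
        na_values=["", "NA", "NaN", "nan"],
    )


@dataclass
class RunConfig:
    """Thresholds and paths for one pipeline run.

    The default alphas implement the staged design: a two-tailed seed cut-off
    of 0.01 on platform A, a direction-matched one-tailed 0.05 on platform B,
    hence a combined per-gene level of 0.01 x 0.05 = 0.0005 which also feeds
    the empirical FDR.  ``subfield_alpha`` is the BH-adjusted threshold for
    the pairwise subfield comparisons, and ``fc_filter`` the |average log2FC|
    cut applied before over-representation analysis.
    """

    seed_alpha: float = 0.01
    validate_alpha: float = 0.05
    combined_alpha: float = 0.0005
    subfield_alpha: float = 0.05
    fc_filter: float = 0.50
    min_detect_samples: int = 3
    rng_seed: int = 0
    outdir: str = "results"
    counts_a: str | None = None
    counts_b: str | None = None
    samplesheet: str | None = None
    behavior: str | None = None
    gmt: str | None = None
    simulate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("seed_alpha", "validate_alpha", "combined_alpha", "subfield_alpha"):
            value = getattr(self, name)
            if not 0 < value < 1:
                raise ValueError(f"{name} must be in (0, 1), got {value}")
        if self.fc_filter < 0:
            raise ValueError("fc_filter must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)
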