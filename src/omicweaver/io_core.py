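"""Core data containers and tabular IO.

The pipeline moves three expression modalities (DIA protein log-intensities,
RNA-seq counts, small-RNA counts) plus per-sample covariates through a chain
of analyses.  Everything downstream consumes the validated containers defined
here rather than raw frames, so format and invariant checking happens once,
at the boundary.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

MODALITIES = ("protein_log_intensity", "rna_counts", "mirna_counts", "mirna_log2fpkm")
COUNT_MODALITIES = ("rna_counts", "mirna_counts")
DX_LEVELS = ("CON", "MDD", "PTSD")
REGIONS = ("DLPFC", "sgPFC")
SEXES = ("M", "F")


class FormatError(ValueError):
    """Malformed input file (bad delimiter structure, duplicate ids, ...)."""


class ValidationError(ValueError):
    """Well-formed input violating a container invariant."""


@dataclasses.dataclass
class ExpressionMatrix:
    """Features x samples numeric matrix tagged with its modality.

    Count modalities (``rna_counts``, ``mirna_counts``) must hold nonnegative
    integers with no missing entries.  The protein log-intensity modality may
    contain missing values, flagged in ``missing_mask`` (True = missing); the
    stored value at a missing cell is NaN.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    modality: str
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FormatError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if self.modality in COUNT_MODALITIES:
            if np.isnan(self.values).any():
                raise ValidationError("count matrix contains missing values")
            if (self.values < 0).any():
                raise ValidationError("count matrix contains negative values")
            if not np.allclose(self.values, np.round(self.values)):
                raise ValidationError("count matrix contains fractional values")
            self.missing_mask = None
        elif self.modality == "protein_log_intensity":
            nan = np.isnan(self.values)
            if self.missing_mask is None:
                self.missing_mask = nan
            else:
                self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
                if self.missing_mask.shape != self.values.shape:
                    raise ValidationError("missing_mask shape mismatch")
                if (nan & ~self.missing_mask).any():
                    raise ValidationError("NaN value not flagged in missing_mask")
                self.values = np.where(self.missing_mask, np.nan, self.values)
        else:  # mirna_log2fpkm: derived, dense
            if np.isnan(self.values).any():
                raise ValidationError("log2fpkm matrix contains missing values")
            self.missing_mask = None

    # -- convenience ------------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def subset_features(self, keep: Sequence[str]) -> "ExpressionMatrix":
        keep = list(keep)
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [idx[f] for f in keep]
        return ExpressionMatrix(
            keep,
            list(self.sample_ids),
            self.values[rows],
            self.modality,
            None if self.missing_mask is None else self.missing_mask[rows],
        )

    def subset_samples(self, keep: Sequence[str]) -> "ExpressionMatrix":
        keep = list(keep)
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in keep]
        return ExpressionMatrix(
            list(self.feature_ids),
            keep,
            self.values[:, cols],
            self.modality,
            None if self.missing_mask is None else self.missing_mask[:, cols],
        )


@dataclasses.dataclass
class SampleTable:
    """Per-sample covariates: diagnosis, region, sex, age, ancestry, PMI, RIN."""

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "donor_id", "dx", "region", "sex", "age", "ancestry", "pmi", "rin")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"sample table missing required columns: {missing}")
        if df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id")
        for col, levels in (("dx", DX_LEVELS), ("region", REGIONS), ("sex", SEXES)):
            bad = set(df[col]) - set(levels)
            if bad:
                raise ValidationError(f"illegal {col} value(s): {sorted(bad)}")
        if (df["age"] < 0).any() or (df["pmi"] < 0).any():
            raise ValidationError("age and pmi must be nonnegative")
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def subset(self, sample_ids: Sequence[str]) -> "SampleTable":
        df = self.frame.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleTable(df)


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with optional descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


@dataclasses.dataclass
class TargetTable:
    """miRNA -> target predictions from external databases."""

    frame: pd.DataFrame  # columns mirna_id, target_id, source

    SOURCES = ("targetscan", "mirbase", "other")

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("mirna_id", "target_id", "source"):
            if col not in df.columns:
                raise FormatError(f"target table missing column {col!r}")
        bad = set(df["source"]) - set(self.SOURCES)
        if bad:
            raise ValidationError(f"illegal target source(s): {sorted(bad)}")
        df = df.drop_duplicates(subset=["mirna_id", "target_id", "source"])
        self.frame = df.reset_index(drop=True)


@dataclasses.dataclass
class PipelineConfig:
    """Per-stage parameter blocks; anything omitted falls back to stage defaults."""

    seed: int = 0
    outdir: str = "results"
    stages: dict = dataclasses.field(default_factory=dict)

    def stage(self, name: str) -> dict:
        return dict(self.stages.get(name, {}))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        seed = int(raw.pop("seed", 0))
        outdir = str(raw.pop("outdir", "results"))
        return cls(seed=seed, outdir=outdir, stages=raw)


# ---------------------------------------------------------------------------
# readers / writers


def _sep_for(path: str | Path) -> str:
    # Delimiter comes from the extension alone: deterministic, no sniffing.
    return "," if str(path).endswith(".csv") else "\t"


def read_expression_matrix(path: str | Path, modality: str) -> ExpressionMatrix:
    """Read a features x samples delimited matrix.

    First column holds feature ids, header row holds sample ids.  Empty cells
    or "NA" are treated as missing (protein modality only; counts reject them).
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, na_values=["NA", ""])
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate feature ids")
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    values = df.to_numpy(dtype=float)
    return ExpressionMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values, modality)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    df = m.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep=_sep_for(path), float_format="%.10g", na_rep="NA")


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"sample_id": str, "donor_id": str})
    return SampleTable(df)


def write_sample_table(s: SampleTable, path: str | Path) -> None:
    s.frame.to_csv(path, sep=_sep_for(path), index=False)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member1 <tab> member2 ..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(gs: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in gs.sets.items():
            desc = gs.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_target_table(path: str | Path) -> TargetTable:
    df = pd.read_csv(path, sep=_sep_for(path))
    return TargetTable(df)


def write_result_table(df: pd.DataFrame, path: str | Path) -> None:
    """All result tables share one TSV convention: fixed column order, 6 sig digits."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# alignment


def align_to_samples(
    m: ExpressionMatrix,
    s: SampleTable,
    filter: Callable[[pd.Series], bool] | None = None,
) -> tuple[ExpressionMatrix, SampleTable]:
    """Restrict matrix and table to their shared samples, in table row order.

    ``filter`` is an optional predicate applied to each sample-table row (a
    pandas Series); samples failing it are dropped from both outputs.
    """
    present = set(m.sample_ids)
    rows = s.frame[s.frame["sample_id"].isin(present)]
    if filter is not None:
        rows = rows[rows.apply(filter, axis=1)]
    kept = list(rows["sample_id"])
    if not kept:
        raise ValidationError("no samples shared between matrix and table after filtering")
    return m.subset_samples(kept), SampleTable(rows.reset_index(drop=True))
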