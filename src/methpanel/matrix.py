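"""Core containers and delimited-text I/O for methylation data.

The central object is :class:`BetaMatrix`, a samples x probes table of
methylation beta values (methylated signal / total signal, in [0, 1]) with
NaN for missing cells. Labels map samples to cancer-type classes; the probe
manifest records the genomic coordinate of each CpG cytosine (1-based,
forward strand, matching array-manifest convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "SampleLabels",
    "ProbeManifest",
    "ValidationError",
    "HarmonizationError",
    "HarmonizeResult",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_labels",
    "write_labels",
    "read_manifest",
    "write_manifest",
    "harmonize_to_panel",
]


class ValidationError(ValueError):
    """Input data violates a container invariant (range, uniqueness, shape)."""


class HarmonizationError(ValueError):
    """A matrix cannot be harmonized to a panel under the requested policy."""


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass(frozen=True)
class BetaMatrix:
    """Samples x probes matrix of beta values in [0, 1], NaN = missing.

    Wraps a float DataFrame with unique sample ids (index) and probe ids
    (columns). Construction validates the range invariant.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        if not isinstance(df, pd.DataFrame):
            raise ValidationError("BetaMatrix requires a DataFrame")
        _check_unique(df.index, "sample ids")
        _check_unique(df.columns, "probe ids")
        vals = df.to_numpy(dtype=float, copy=False)
        bad = np.nonzero((vals < 0) | (vals > 1))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValidationError(
                f"beta value out of [0,1] at sample {df.index[i]!r}, "
                f"probe {df.columns[j]!r}: {vals[i, j]}"
            )
        object.__setattr__(self, "data", df.astype(float))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        return BetaMatrix(self.data.loc[list(sample_ids)])

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(self.data.loc[:, list(probe_ids)])

    def values_for(self, probe_id: str) -> pd.Series:
        return self.data[probe_id]


@dataclass(frozen=True)
class SampleLabels:
    """Mapping sample_id -> class name (cancer type or merged cohort)."""

    mapping: pd.Series  # index = sample_id, values = class name

    def __post_init__(self):
        s = pd.Series(self.mapping)
        _check_unique(s.index, "sample ids in labels")
        if len(s) == 0:
            raise ValidationError("labels are empty")
        object.__setattr__(self, "mapping", s.astype(str))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.mapping.index)

    @property
    def classes(self) -> list[str]:
        """Class names in sorted (lexicographic) order."""
        return sorted(self.mapping.unique())

    def class_counts(self) -> pd.Series:
        return self.mapping.value_counts().sort_index()

    def subset(self, sample_ids) -> "SampleLabels":
        return SampleLabels(self.mapping.loc[list(sample_ids)])

    def for_samples(self, sample_ids) -> np.ndarray:
        return self.mapping.loc[list(sample_ids)].to_numpy()


@dataclass(frozen=True)
class ProbeManifest:
    """Genomic coordinates of CpG probes.

    ``position`` is the 1-based coordinate of the CpG cytosine on the
    forward strand (the array-manifest convention); count files in other
    dialects are normalized to this at parse time.
    """

    table: pd.DataFrame  # index = probe_id; columns chrom, position, strand

    def __post_init__(self):
        t = pd.DataFrame(self.table)
        _check_unique(t.index, "probe ids in manifest")
        missing = {"chrom", "position", "strand"} - set(t.columns)
        if missing:
            raise ValidationError(f"manifest missing columns: {sorted(missing)}")
        t = t[["chrom", "position", "strand"]].copy()
        t["position"] = t["position"].astype(int)
        if (t["position"] < 1).any():
            raise ValidationError("manifest positions must be >= 1")
        keys = t[["chrom", "position"]].apply(tuple, axis=1)
        if keys.duplicated().any():
            raise ValidationError("duplicate (chrom, position) in manifest")
        object.__setattr__(self, "table", t)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def coordinates(self, probe_ids=None) -> pd.DataFrame:
        t = self.table
        return t if probe_ids is None else t.loc[list(probe_ids)]


# ---------------------------------------------------------------------------
# Disk formats: TSV with header row; "NA" for missing beta values.
# ---------------------------------------------------------------------------

def read_beta_matrix(path, orientation: str = "samples_in_rows") -> BetaMatrix:
    """Read a beta matrix from a delimited text file.

    Parameters
    ----------
    path : str or Path
        TSV file with one header row and one id column.
    orientation : {"samples_in_rows", "probes_in_rows"}
        Layout of the file; ``probes_in_rows`` transposes after reading
        (array exports vary in orientation).
    """
    if orientation not in ("samples_in_rows", "probes_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""],
                     keep_default_na=True)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    if orientation == "probes_in_rows":
        df = df.T
    return BetaMatrix(df)


def write_beta_matrix(bm: BetaMatrix, path) -> None:
    """Write samples-in-rows TSV with ``NA`` for missing cells."""
    bm.data.to_csv(path, sep="\t", na_rep="NA", float_format="%.12g",
                   index_label="sample_id")


def read_labels(path) -> SampleLabels:
    """Read a two-column TSV (sample_id, class)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"label file {path} needs 2 columns")
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values,
                  name="class")
    return SampleLabels(s)


def write_labels(labels: SampleLabels, path) -> None:
    labels.mapping.rename("class").to_csv(path, sep="\t",
                                          index_label="sample_id")


def read_manifest(path) -> ProbeManifest:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    return ProbeManifest(df.set_index("probe_id"))


def write_manifest(manifest: ProbeManifest, path) -> None:
    manifest.table.to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# Panel harmonization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HarmonizeResult:
    """Harmonized matrix plus provenance of imputed cells."""

    matrix: BetaMatrix
    #: probes absent from the input platform, imputed for every sample
    missing_probes: list[str] = field(default_factory=list)
    #: boolean mask (samples x panel probes) of imputed cells
    imputed_mask: pd.DataFrame | None = None

    @property
    def n_imputed_cells(self) -> int:
        return int(self.imputed_mask.to_numpy().sum())


def harmonize_to_panel(bm: BetaMatrix, panel, impute: str = "training_mean",
                       impute_values=None, constant: float = 0.5
                       ) -> HarmonizeResult:
    """Restrict and reorder a beta matrix to a trained panel's probe list.

    Probes absent from ``bm`` (platform mismatch) and missing cells within
    present probes are filled according to ``impute``:

    - ``training_mean``: per-probe values from ``impute_values`` (a mapping
      probe_id -> mean stored in the trained model);
    - ``constant``: a single fill value;
    - ``fail``: raise if any panel probe is absent from ``bm``.
    """
    panel = list(panel)
    _check_unique(panel, "panel probes")
    have = set(bm.probe_ids)
    absent = [p for p in panel if p not in have]

    if impute == "fail":
        if absent:
            raise HarmonizationError(
                f"{len(absent)} panel probe(s) missing from input: {absent}")
        out = bm.data.loc[:, panel]
        mask = out.isna()
        if mask.to_numpy().any():
            raise HarmonizationError(
                "missing cells present under impute='fail'")
        return HarmonizeResult(BetaMatrix(out), [], mask)

    if impute == "training_mean":
        if impute_values is None:
            raise ValueError("impute='training_mean' requires impute_values")
        fill = pd.Series(impute_values, dtype=float)
        not_stored = [p for p in panel if p not in fill.index]
        if not_stored:
            raise HarmonizationError(
                f"no stored imputation value for: {not_stored[:5]}")
        fill = fill.loc[panel]
    elif impute == "constant":
        fill = pd.Series(constant, index=panel, dtype=float)
    else:
        raise ValueError(f"unknown imputation policy {impute!r}")

    out = bm.data.reindex(columns=panel)
    mask = out.isna()
    out = out.fillna(fill)
    if absent:
        warnings.warn(
            f"imputed {len(absent)} probe(s) absent from input platform",
            stacklevel=2)
    return HarmonizeResult(BetaMatrix(out), absent, mask)
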