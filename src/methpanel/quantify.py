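"""Targeted bisulfite sequencing counts -> classifier-ready beta values.

Consumes the standard Bismark coverage format (chrom, start, end,
%methylation, methylated count, unmethylated count), normalizes
coordinates to the manifest convention (1-based forward-strand CpG
cytosine), optionally merges the two symmetric strands of each CpG, and
computes beta = M / (M + U) for every panel probe with sufficient
coverage. Probes below the coverage floor come out missing, to be imputed
downstream during panel harmonization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import BetaMatrix, ProbeManifest

__all__ = [
    "QuantConfig",
    "CoverageParseError",
    "read_coverage_file",
    "write_coverage_file",
    "merge_strands",
    "counts_to_beta",
]

_COLUMNS = ["chrom", "position", "strand",
            "count_methylated", "count_unmethylated"]


class CoverageParseError(ValueError):
    """A coverage file row is malformed; the message carries the line."""


@dataclass(frozen=True)
class QuantConfig:
    #: minimum merged coverage for a probe to receive a beta value
    min_coverage: int = 10
    strand_mode: str = "merge_cpg"  # or "forward_only"
    coordinate_dialect: str = "one_based_inclusive"  # or zero_based_half_open

    def __post_init__(self):
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if self.strand_mode not in ("merge_cpg", "forward_only"):
            raise ValueError(f"unknown strand_mode {self.strand_mode!r}")
        if self.coordinate_dialect not in ("one_based_inclusive",
                                           "zero_based_half_open"):
            raise ValueError(
                f"unknown dialect {self.coordinate_dialect!r}")


def read_coverage_file(path, dialect: str = "one_based_inclusive"
                       ) -> pd.DataFrame:
    """Parse a Bismark ``.cov`` file into a counts table.

    Returns a frame with columns chrom, position (1-based cytosine),
    strand (always "."; the format does not carry strand),
    count_methylated, count_unmethylated. Malformed or negative-count
    rows raise :class:`CoverageParseError` naming the line number.
    """
    if dialect not in ("one_based_inclusive", "zero_based_half_open"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise CoverageParseError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, "
                    f"got {len(parts)}")
            chrom, start, _end, _pct, m, u = parts
            try:
                start = int(start)
                m = int(m)
                u = int(u)
            except ValueError as exc:
                raise CoverageParseError(
                    f"{path}:{lineno}: unparseable field: {exc}") from exc
            if m < 0 or u < 0:
                raise CoverageParseError(
                    f"{path}:{lineno}: negative count")
            pos = start + 1 if dialect == "zero_based_half_open" else start
            if pos < 1:
                raise CoverageParseError(
                    f"{path}:{lineno}: position < 1 after normalization")
            records.append((chrom, pos, ".", m, u))
    return pd.DataFrame(records, columns=_COLUMNS)


def write_coverage_file(mc: pd.DataFrame, path,
                        dialect: str = "one_based_inclusive") -> None:
    """Write counts in Bismark coverage format."""
    with open(path, "w") as fh:
        for row in mc.itertuples(index=False):
            m, u = int(row.count_methylated), int(row.count_unmethylated)
            total = m + u
            pct = 100.0 * m / total if total else 0.0
            pos = int(row.position)
            start = pos - 1 if dialect == "zero_based_half_open" else pos
            end = pos if dialect == "zero_based_half_open" else pos
            fh.write(f"{row.chrom}\t{start}\t{end}\t{pct:g}\t{m}\t{u}\n")


def merge_strands(mc: pd.DataFrame, manifest: ProbeManifest) -> pd.DataFrame:
    """Collapse the two strands of each CpG onto the forward cytosine.

    A record at position pos+1 of a manifest CpG at pos is the
    reverse-strand cytosine of the same dinucleotide; its counts are
    added to the forward position. Idempotent, and conserves the total
    read count.
    """
    coords = manifest.coordinates()
    forward = set(zip(coords["chrom"], coords["position"]))
    out = mc.copy()
    pos = out["position"].to_numpy().copy()
    chroms = out["chrom"].to_numpy()
    for i in range(len(out)):
        key = (chroms[i], pos[i] - 1)
        if (chroms[i], pos[i]) not in forward and key in forward:
            pos[i] -= 1
    out["position"] = pos
    out["strand"] = "."
    grouped = (out.groupby(["chrom", "position"], as_index=False, sort=False)
               .agg({"strand": "first", "count_methylated": "sum",
                     "count_unmethylated": "sum"}))
    return grouped[_COLUMNS]


def counts_to_beta(mc: pd.DataFrame, manifest: ProbeManifest, panel,
                   cfg: QuantConfig = QuantConfig(),
                   sample_id: str = "sample"):
    """Quantify one sample's panel beta vector from its counts.

    Returns ``(BetaMatrix, qc)`` where the matrix has a single row and
    exactly the panel's probes (missing where coverage < min_coverage or
    no record exists) and ``qc`` reports per-probe coverage.
    """
    panel = list(panel)
    dup = mc.duplicated(subset=["chrom", "position"], keep=False)
    if dup.any():
        warnings.warn(f"{int(dup.sum())} duplicate coverage records summed "
                      "(multi-lane merge?)", stacklevel=2)
    if cfg.strand_mode == "merge_cpg":
        mc = merge_strands(mc, manifest)  # also sums duplicate positions
    else:
        coords = manifest.coordinates()
        forward = set(zip(coords["chrom"], coords["position"]))
        keep = [(c, p) in forward
                for c, p in zip(mc["chrom"], mc["position"])]
        mc = (mc.loc[keep]
              .groupby(["chrom", "position"], as_index=False, sort=False)
              .agg({"strand": "first", "count_methylated": "sum",
                    "count_unmethylated": "sum"}))[_COLUMNS]

    lookup = {(c, p): (m, u) for c, p, m, u in zip(
        mc["chrom"], mc["position"],
        mc["count_methylated"], mc["count_unmethylated"])}
    coords = manifest.coordinates(panel)
    beta = np.full(len(panel), np.nan)
    coverage = np.zeros(len(panel), dtype=int)
    n_hit = 0
    for i, (chrom, p) in enumerate(zip(coords["chrom"], coords["position"])):
        rec = lookup.get((chrom, int(p)))
        if rec is None:
            continue
        n_hit += 1
        m, u = rec
        coverage[i] = m + u
        if m + u >= cfg.min_coverage:
            beta[i] = m / (m + u)
    if n_hit == 0:
        raise ValueError("no coverage record overlaps any panel probe")
    bm = BetaMatrix(pd.DataFrame([beta], index=[sample_id], columns=panel))
    qc = pd.DataFrame({"coverage": coverage,
                       "quantified": ~np.isnan(beta)},
                      index=pd.Index(panel, name="probe_id"))
    return bm, qc
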