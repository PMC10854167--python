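"""CpG context and gene-region annotation of panel probes.

Each probe is assigned exactly one CpG-content context — Island (inside a
CpG island), Shore (within 2 kb of an island edge), Shelf (2-4 kb), Open
Sea (beyond) — following the Illumina 450K convention, and one functional
gene region with the priority TSS200 > TSS1500 > 5'UTR > FirstExon >
3'UTR > Body, Intergenic when no gene is hit. Upstream distances are
measured strand-aware from the transcription start site.

Interval files arrive as BED (0-based half-open) and are converted to
1-based inclusive coordinates at this module's boundary; all internal
arithmetic is 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ProbeManifest

__all__ = [
    "AnnotationTracks",
    "read_cgi_bed",
    "read_gene_models",
    "classify_cpg_context",
    "classify_gene_region",
    "annotate_probes",
    "summarize_panel_annotation",
    "CONTEXTS",
    "REGIONS",
]

CONTEXTS = ["Island", "Shore", "Shelf", "OpenSea"]
REGIONS = ["TSS200", "TSS1500", "5'UTR", "FirstExon", "Body", "3'UTR",
           "Intergenic"]
_REGION_PRIORITY = ["TSS200", "TSS1500", "5'UTR", "FirstExon", "3'UTR",
                    "Body"]

SHORE_BP = 2000
SHELF_BP = 4000


@dataclass(frozen=True)
class AnnotationTracks:
    """CGI intervals and simplified gene models, 1-based inclusive.

    ``cgi``: columns chrom, start, end (start <= end).
    ``genes``: columns gene, chrom, strand, tss and optional interval
    pairs ``utr5_start/utr5_end``, ``first_exon_start/first_exon_end``,
    ``body_start/body_end``, ``utr3_start/utr3_end`` (NaN = absent).
    """

    cgi: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self):
        cgi = pd.DataFrame(self.cgi)
        if len(cgi) and (cgi["start"] > cgi["end"]).any():
            raise ValueError("CGI interval with start > end")
        if len(cgi) and (cgi["start"] < 1).any():
            raise ValueError("CGI interval with start < 1")
        object.__setattr__(self, "cgi", cgi)
        object.__setattr__(self, "genes", pd.DataFrame(self.genes))


def read_cgi_bed(path) -> pd.DataFrame:
    """Read CGI intervals from BED; convert to 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={0: str})
    out = df.copy()
    out["start"] = df["start"].astype(int) + 1
    out["end"] = df["end"].astype(int)
    return out


def read_gene_models(path) -> pd.DataFrame:
    """Read the simplified gene-model TSV (header row expected)."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str,
                                              "strand": str})


def _cgi_distance(position: int, intervals: pd.DataFrame) -> int:
    """0 when inside an interval, else bp to the nearest interval edge."""
    starts = intervals["start"].to_numpy()
    ends = intervals["end"].to_numpy()
    inside = (starts <= position) & (position <= ends)
    if inside.any():
        return 0
    gaps = np.where(position < starts, starts - position, position - ends)
    return int(gaps.min())


def classify_cpg_context(chrom: str, position: int,
                         tracks: AnnotationTracks) -> str:
    """Island / Shore / Shelf / OpenSea by distance to the nearest CGI.

    Boundary distances are inclusive toward the nearer category (a probe
    exactly 2000 bp out is Shore, exactly 4000 bp is Shelf).
    """
    sub = tracks.cgi[tracks.cgi["chrom"] == chrom]
    if sub.empty:
        warnings.warn(f"chromosome {chrom!r} absent from CGI track",
                      stacklevel=2)
        return "OpenSea"
    d = _cgi_distance(int(position), sub)
    if d == 0:
        return "Island"
    if d <= SHORE_BP:
        return "Shore"
    if d <= SHELF_BP:
        return "Shelf"
    return "OpenSea"


def _in_interval(position, row, prefix) -> bool:
    s, e = row.get(f"{prefix}_start"), row.get(f"{prefix}_end")
    if pd.isna(s) or pd.isna(e):
        return False
    return int(s) <= position <= int(e)


def _gene_region(position: int, row: pd.Series) -> str | None:
    """Region of one gene hit, or None when the position misses the gene."""
    tss = int(row["tss"])
    upstream = tss - position if row["strand"] == "+" else position - tss
    hits = set()
    if 1 <= upstream <= 200:
        hits.add("TSS200")
    elif 201 <= upstream <= 1500:
        hits.add("TSS1500")
    for prefix, name in (("utr5", "5'UTR"), ("first_exon", "FirstExon"),
                         ("utr3", "3'UTR"), ("body", "Body")):
        if _in_interval(position, row, prefix):
            hits.add(name)
    for name in _REGION_PRIORITY:
        if name in hits:
            return name
    return None


def classify_gene_region(chrom: str, position: int,
                         tracks: AnnotationTracks) -> str:
    """Highest-priority functional region over all genes hit."""
    position = int(position)
    sub = tracks.genes[tracks.genes["chrom"] == chrom]
    best = len(_REGION_PRIORITY)
    for _, row in sub.iterrows():
        region = _gene_region(position, row)
        if region is not None:
            best = min(best, _REGION_PRIORITY.index(region))
    return _REGION_PRIORITY[best] if best < len(_REGION_PRIORITY) \
        else "Intergenic"


def annotate_probes(probe_ids, manifest: ProbeManifest,
                    tracks: AnnotationTracks) -> pd.DataFrame:
    """Per-probe context, region and chromosome."""
    coords = manifest.coordinates(list(probe_ids))
    rows = []
    for pid, row in coords.iterrows():
        chrom, pos = row["chrom"], int(row["position"])
        rows.append({
            "probe_id": pid,
            "chrom": chrom,
            "context": classify_cpg_context(chrom, pos, tracks),
            "region": classify_gene_region(chrom, pos, tracks),
        })
    return pd.DataFrame(rows).set_index("probe_id")


def summarize_panel_annotation(panel, manifest: ProbeManifest,
                               tracks: AnnotationTracks) -> dict:
    """Fractions per context and region, counts per chromosome.

    Fractions within each categorization sum to 1; chromosome counts sum
    to the panel size.
    """
    ann = annotate_probes(panel, manifest, tracks)
    n = len(ann)
    context = (ann["context"].value_counts()
               .reindex(CONTEXTS, fill_value=0) / n)
    region = (ann["region"].value_counts()
              .reindex(REGIONS, fill_value=0) / n)
    chrom = ann["chrom"].value_counts().sort_index()
    return {"context_fraction": context, "region_fraction": region,
            "chrom_counts": chrom, "table": ann}
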