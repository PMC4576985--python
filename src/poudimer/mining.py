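"""Ranked-peak element mining with nearest-TSS annotation.

ChIP-Seq peaks, ranked by fold enrichment, are mined for exact MORE /
MORE+1 / PORE / Sox/Oct element occurrences: the top fraction of peaks
(default 5%) is selected, each peak's sequence scanned on both strands,
and every element annotated with the nearest transcription start site
within 100 kb of the element midpoint.

Coordinates are 0-based half-open (BED convention) throughout; sequence
sources may be a plain ``{chrom: sequence}`` mapping or a
``pyfaidx.Fasta`` handle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .motifs import MotifDefinition, default_motif_set, scan_sequence

__all__ = [
    "PeakRecord",
    "TssRecord",
    "AnnotatedHit",
    "PeakMotifReport",
    "mine_peaks",
    "nearest_tss",
    "read_peaks_bed",
    "write_peaks_bed",
    "read_tss_table",
    "write_tss_table",
    "TSS_MAX_DISTANCE",
]

#: an element is assigned to a gene only if its TSS lies within this many bp
TSS_MAX_DISTANCE = 100_000


@dataclass(frozen=True)
class PeakRecord:
    chrom: str
    start: int
    end: int
    fold_enrichment: float
    rank: int  # 1-based, by descending enrichment
    name: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("peak requires 0 <= start < end")
        if self.rank < 1:
            raise ValueError("rank is 1-based")


@dataclass(frozen=True)
class TssRecord:
    gene: str
    chrom: str
    pos: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("pos must be >= 0")


@dataclass(frozen=True)
class AnnotatedHit:
    """A motif hit in genome coordinates with its nearest-gene assignment."""

    peak_rank: int
    chrom: str
    start: int  # genomic, 0-based
    end: int
    strand: str
    element_class: str
    subtype: str
    matched: str
    nearest_gene: str | None
    distance_bp: int | None


@dataclass(frozen=True)
class PeakMotifReport:
    """Mining result: per-peak hits and per-subtype summary counts."""

    peaks: Sequence[PeakRecord]
    hits: Sequence[AnnotatedHit]
    top_fraction: float

    @property
    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for h in self.hits:
            out[h.element_class] = out.get(h.element_class, 0) + 1
        return out

    @property
    def subtype_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for h in self.hits:
            out[h.subtype] = out.get(h.subtype, 0) + 1
        return out

    def hits_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "peak_rank": h.peak_rank,
                    "chrom": h.chrom,
                    "start": h.start,
                    "end": h.end,
                    "strand": h.strand,
                    "element_class": h.element_class,
                    "subtype": h.subtype,
                    "matched": h.matched,
                    "nearest_gene": h.nearest_gene,
                    "distance_bp": h.distance_bp,
                }
                for h in self.hits
            ]
        )

    def summary(self) -> dict:
        return {
            "n_peaks_mined": len(self.peaks),
            "top_fraction": self.top_fraction,
            "n_hits": len(self.hits),
            "class_counts": self.class_counts,
            "subtype_counts": self.subtype_counts,
        }


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Plus-strand sequence from a dict-like or pyfaidx.Fasta source."""
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} missing from sequence source")
    record = genome[chrom]
    if isinstance(record, str):
        if end > len(record):
            raise IndexError(f"peak {chrom}:{start}-{end} outside sequence bounds")
        return record[start:end]
    # pyfaidx-style record
    if end > len(record):
        raise IndexError(f"peak {chrom}:{start}-{end} outside sequence bounds")
    return str(record[start:end])


def nearest_tss(
    chrom: str,
    pos: int,
    tss: Sequence[TssRecord],
    max_distance: int = TSS_MAX_DISTANCE,
) -> tuple[str | None, int | None]:
    """Gene with the TSS closest to ``pos`` on ``chrom``; (None, None) if
    none lies within ``max_distance`` bp.  Absolute distance; ties go to the
    alphabetically first gene."""
    candidates = [(abs(t.pos - pos), t.gene) for t in tss if t.chrom == chrom]
    if not candidates:
        return None, None
    dist, gene = min(candidates)
    if dist > max_distance:
        return None, None
    return gene, dist


def mine_peaks(
    peaks: Sequence[PeakRecord],
    genome: Mapping[str, object],
    tss: Sequence[TssRecord],
    top_fraction: float = 0.05,
    motifs: Sequence[MotifDefinition] | None = None,
) -> PeakMotifReport:
    """Mine the top fraction of peaks (by fold enrichment) for elements.

    Selects ``ceil(top_fraction * n)`` peaks by descending fold enrichment,
    scans each peak's sequence with the full element grammar (or a custom
    ``motifs`` set) on both strands, and annotates every hit with the
    nearest TSS within 100 kb of the element midpoint.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    motifs = tuple(motifs) if motifs is not None else default_motif_set()
    n_top = math.ceil(top_fraction * len(peaks))
    selected = sorted(peaks, key=lambda p: (-p.fold_enrichment, p.rank))[:n_top]

    annotated: list[AnnotatedHit] = []
    for peak in selected:
        seq = _fetch(genome, peak.chrom, peak.start, peak.end)
        for hit in scan_sequence(seq, motifs, seq_id=peak.chrom):
            g_start = peak.start + hit.start
            g_end = peak.start + hit.end
            midpoint = (g_start + g_end) // 2
            gene, dist = nearest_tss(peak.chrom, midpoint, tss)
            annotated.append(
                AnnotatedHit(
                    peak_rank=peak.rank,
                    chrom=peak.chrom,
                    start=g_start,
                    end=g_end,
                    strand=hit.strand,
                    element_class=hit.element_class,
                    subtype=hit.subtype,
                    matched=hit.matched,
                    nearest_gene=gene,
                    distance_bp=dist,
                )
            )
    annotated.sort(key=lambda h: (h.peak_rank, h.start, h.subtype))
    return PeakMotifReport(tuple(selected), tuple(annotated), top_fraction)


# ---------------------------------------------------------------------------
# I/O — BED peaks (score column = fold enrichment) and TSS tables


def read_peaks_bed(path) -> list[PeakRecord]:
    """BED with columns chrom, start, end[, name, score]; score = fold
    enrichment.  Ranks are assigned by descending enrichment."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = ["chrom", "start", "end", "name", "score"][: df.shape[1]]
    if "score" not in df.columns:
        df["score"] = 0.0
    if "name" not in df.columns:
        df["name"] = ""
    df = df.sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)
    return [
        PeakRecord(r.chrom, int(r.start), int(r.end), float(r.score), i + 1, str(r.name))
        for i, r in df.iterrows()
    ]


def write_peaks_bed(peaks: Sequence[PeakRecord], path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "name": [p.name or f"peak_{p.rank}" for p in peaks],
            "score": [p.fold_enrichment for p in peaks],
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_tss_table(path) -> list[TssRecord]:
    """TSV with columns gene, chrom, pos[, strand] (header required)."""
    df = pd.read_csv(path, sep="\t")
    strands = df["strand"] if "strand" in df.columns else ["+"] * len(df)
    return [
        TssRecord(str(g), str(c), int(p), str(s))
        for g, c, p, s in zip(df["gene"], df["chrom"], df["pos"], strands)
    ]


def write_tss_table(tss: Sequence[TssRecord], path) -> None:
    pd.DataFrame(
        {
            "gene": [t.gene for t in tss],
            "chrom": [t.chrom for t in tss],
            "pos": [t.pos for t in tss],
            "strand": [t.strand for t in tss],
        }
    ).to_csv(path, sep="\t", index=False)
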