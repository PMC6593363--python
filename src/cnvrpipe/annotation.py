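"""Overlap annotation of CNVRs against genes and genomic feature tracks.

A CNVR is associated with a gene when it overlaps the gene's span
extended by a configurable flank on both sides (default 5 Mb, clipped
to the chromosome).  Hits inside the gene body are further classified
against sub-features — CDS, UTR, exon, and intron (introns derived from
exon gaps) — and flank-only hits are labelled upstream/downstream
relative to the gene's strand.  Each record carries a combined label of
the form "<component> <category>" (e.g. ``"cds del"``) so the report
database can be searched by overlap type.

BED-like tracks (QTL, assembly gap, repeat, segmental duplication) are
annotated by plain >= 1-bp overlap; a gap that contains a CNVR boundary
additionally gets a ``boundary_in_gap`` caveat flag, since depth
anomalies at assembly gaps can masquerade as CNV breakpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .core_io import CNVR, GeneTrack

__all__ = ["OverlapRecord", "annotate_genes", "annotate_tracks", "records_to_frame"]


@dataclass
class OverlapRecord:
    cnvr_id: str
    feature_id: str
    feature_kind: str  # gene|CDS|UTR|exon|intron|upstream|downstream|QTL|gap|repeat|segdup
    overlap_bp: int
    overlap_label: str
    boundary_in_gap: bool = False


def _ov(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def _union_bp(intervals: list[tuple[int, int]], region: tuple[int, int]) -> int:
    """Total bases of ``region`` covered by the union of ``intervals``."""
    clipped = sorted(
        (max(s, region[0]), min(e, region[1]))
        for s, e in intervals
        if _ov((s, e), region) > 0
    )
    total, last_end = 0, 0
    for s, e in clipped:
        s = max(s, last_end + 1)
        if e >= s:
            total += e - s + 1
            last_end = max(last_end, e)
    return total


def annotate_genes(
    cnvrs: list[CNVR],
    gene_track: GeneTrack,
    flank: int = 5_000_000,
    chrom_lengths: dict[str, int] | None = None,
) -> list[OverlapRecord]:
    """Overlap CNVRs with flanked genes and classify per sub-feature."""
    records: list[OverlapRecord] = []
    for cnvr in cnvrs:
        cat = (cnvr.category or "").lower()
        region = (cnvr.start, cnvr.end)
        for gene in gene_track.genes:
            if gene.chrom != cnvr.chrom:
                continue
            fstart = max(1, gene.start - flank)
            fend = gene.end + flank
            if chrom_lengths and gene.chrom in chrom_lengths:
                fend = min(fend, chrom_lengths[gene.chrom])
            if _ov(region, (fstart, fend)) < 1:
                continue
            body_ov = _ov(region, (gene.start, gene.end))
            if body_ov >= 1:
                records.append(
                    OverlapRecord(
                        cnvr.cnvr_id, gene.gene_id, "gene", body_ov, f"gene {cat}"
                    )
                )
                components = {
                    "exon": [iv for t in gene.transcripts for iv in t.exons],
                    "CDS": [iv for t in gene.transcripts for iv in t.cds],
                    "UTR": [
                        iv for t in gene.transcripts for iv in t.utr5 + t.utr3
                    ],
                    "intron": [iv for t in gene.transcripts for iv in t.introns],
                }
                for kind, intervals in components.items():
                    bp = _union_bp(intervals, region)
                    if bp >= 1:
                        records.append(
                            OverlapRecord(
                                cnvr.cnvr_id,
                                gene.gene_id,
                                kind,
                                bp,
                                f"{kind.lower()} {cat}",
                            )
                        )
            else:
                # flank-only hit: orient by strand
                left_ov = _ov(region, (fstart, gene.start - 1))
                right_ov = _ov(region, (gene.end + 1, fend))
                if gene.strand == "+":
                    sides = (("upstream", left_ov), ("downstream", right_ov))
                elif gene.strand == "-":
                    sides = (("downstream", left_ov), ("upstream", right_ov))
                else:
                    warnings.warn(
                        f"gene {gene.gene_id} is strandless; labelling flanks "
                        "left/right",
                        stacklevel=2,
                    )
                    sides = (("left_flank", left_ov), ("right_flank", right_ov))
                for kind, bp in sides:
                    if bp >= 1:
                        records.append(
                            OverlapRecord(
                                cnvr.cnvr_id,
                                gene.gene_id,
                                kind,
                                bp,
                                f"{kind.lower()} {cat}",
                            )
                        )
    records.sort(key=lambda r: (r.cnvr_id, r.feature_kind, r.feature_id))
    return records


def annotate_tracks(
    cnvrs: list[CNVR], tracks: list[pd.DataFrame]
) -> list[OverlapRecord]:
    """Annotate CNVRs against BED-like tracks by >= 1-bp overlap.

    Tracks come from :func:`cnvrpipe.core_io.read_track` (columns chrom,
    start, end, feature_id, kind).  The record set is a pure function of
    the inputs: track order does not affect it.
    """
    feats: list[tuple[str, int, int, str, str]] = []
    for tr in tracks:
        for _, f in tr.iterrows():
            feats.append(
                (f["chrom"], int(f["start"]), int(f["end"]), f["feature_id"], f["kind"])
            )
    feats.sort()
    records: list[OverlapRecord] = []
    for cnvr in cnvrs:
        cat = (cnvr.category or "").lower()
        for chrom, s, e, fid, kind in feats:
            if chrom != cnvr.chrom:
                continue
            bp = _ov((cnvr.start, cnvr.end), (s, e))
            if bp < 1:
                continue
            boundary_in_gap = kind == "gap" and (
                s <= cnvr.start <= e or s <= cnvr.end <= e
            )
            records.append(
                OverlapRecord(
                    cnvr.cnvr_id,
                    fid,
                    kind,
                    bp,
                    f"{kind.lower()} {cat}",
                    boundary_in_gap=boundary_in_gap,
                )
            )
    records.sort(key=lambda r: (r.cnvr_id, r.feature_kind, r.feature_id))
    return records


def records_to_frame(records: list[OverlapRecord]) -> pd.DataFrame:
    cols = [
        "cnvr_id",
        "feature_id",
        "feature_kind",
        "overlap_bp",
        "overlap_label",
        "boundary_in_gap",
    ]
    if not records:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([r.__dict__ for r in records])[cols]
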