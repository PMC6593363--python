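"""Domain types, coordinate conventions, and readers/writers.

Coordinate convention
---------------------
All genomic intervals are 1-based inclusive: an interval ``[start, end]``
has length ``end - start + 1``.  A 1,000-bp window grid tiles each
chromosome as ``[(i-1)*WL + 1, i*WL]``.  BED-style 0-based half-open
coordinates are converted at I/O boundaries only (:func:`to_bed`,
:func:`from_bed`).

Copy-number genotypes are small integers 0..8 with 2 the diploid
reference; the undetermined genotype ``CN_`` (produced by the CN2
correction) is encoded as :data:`CN_UNKNOWN` (-1) in memory and as the
string ``"CN_"`` on disk.
"""

from __future__ import annotations

import csv
import os
import tempfile
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CN_UNKNOWN",
    "FormatError",
    "RecordError",
    "GenomeLayout",
    "ReadCountMatrix",
    "CNVCall",
    "CNVR",
    "PipelineConfig",
    "GeneModel",
    "Transcript",
    "GeneTrack",
    "cn_to_str",
    "str_to_cn",
    "to_bed",
    "from_bed",
    "read_cnv_calls",
    "write_cnv_calls",
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_meta",
    "write_sample_meta",
    "read_features_gff3",
    "read_track",
    "write_cnvr_table",
    "read_cnvr_table",
    "write_genotype_matrix",
    "read_genotype_matrix",
]

#: In-memory encoding of the undetermined genotype ``CN_``.
CN_UNKNOWN = -1


class FormatError(ValueError):
    """A file violates its format contract (missing column, bad layout)."""


class RecordError(ValueError):
    """A single record violates its value contract (bad coordinate, bad CN)."""


def cn_to_str(cn: int) -> str:
    return "CN_" if cn == CN_UNKNOWN else f"CN{cn}"


def str_to_cn(s: str) -> int:
    s = s.strip()
    if s in ("CN_", "_"):
        return CN_UNKNOWN
    if s.startswith("CN"):
        s = s[2:]
    return int(s)


def to_bed(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def from_bed(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """A fixed window grid over named chromosomes.

    Windows on each chromosome are the 1-based inclusive intervals
    ``[(i-1)*WL + 1, i*WL]``; if the chromosome length is not a multiple
    of the window length a trailing partial window is retained and
    flagged (it is excluded from CNV calling downstream).
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    window_length: int = 1000

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise FormatError("chrom_names and chrom_lengths differ in length")
        if self.window_length <= 0:
            raise FormatError("window_length must be positive")
        if any(l <= 0 for l in self.chrom_lengths):
            raise FormatError("chromosome lengths must be positive")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @property
    def genome_size(self) -> int:
        return int(sum(self.chrom_lengths))

    def n_windows(self, chrom: str) -> int:
        length = self.lengths[chrom]
        return -(-length // self.window_length)  # ceil division

    @property
    def total_windows(self) -> int:
        return sum(self.n_windows(c) for c in self.chrom_names)

    def windows(self) -> pd.DataFrame:
        """Window table: chrom, start, end, partial (one row per window)."""
        wl = self.window_length
        rows = []
        for chrom, length in zip(self.chrom_names, self.chrom_lengths):
            n = self.n_windows(chrom)
            starts = np.arange(n, dtype=np.int64) * wl + 1
            ends = np.minimum(starts + wl - 1, length)
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": ends,
                        "partial": ends - starts + 1 != wl,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class ReadCountMatrix:
    """Windows x samples read counts on a fixed :class:`GenomeLayout`.

    ``counts`` is a ``(n_windows, n_samples)`` array; integer for raw
    counts, floating-point after normalisation.  Row order matches
    ``layout.windows()``.
    """

    layout: GenomeLayout
    sample_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = tuple(self.sample_ids)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be 2-D (windows x samples)")
        if self.counts.shape != (self.layout.total_windows, len(self.sample_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match layout "
                f"({self.layout.total_windows} windows x {len(self.sample_ids)} samples)"
            )
        if (self.counts < 0).any():
            raise RecordError("negative read count")

    @property
    def windows(self) -> pd.DataFrame:
        return self.layout.windows()

    def subset_samples(self, sample_ids: Sequence[str]) -> "ReadCountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ReadCountMatrix(self.layout, tuple(sample_ids), self.counts[:, idx])


@dataclass
class CNVCall:
    """One per-sample CNV: an interval plus an integer copy-number genotype.

    ``cn`` is in {0, 1, 3, ..., 8}; CN2 is the reference state and never
    a call.  Caller-produced calls snap to window boundaries and span at
    least three windows.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    cn: int
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise RecordError(
                f"start > end for call {self.chrom}:{self.start}-{self.end}"
            )
        if self.cn == 2:
            raise RecordError("CN2 is the reference genotype, not a CNV")
        if not (0 <= self.cn <= 8):
            raise RecordError(f"copy number {self.cn} outside 0..8")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass
class CNVR:
    """A CNV region: the span of a cluster of reciprocally overlapping CNVs.

    ``genotypes`` maps every cohort sample to an integer genotype
    (0..8, with 2 the provisional reference default) or
    :data:`CN_UNKNOWN` after the CN2 correction.
    """

    cnvr_id: str
    chrom: str
    start: int
    end: int
    members: list[CNVCall] = field(default_factory=list)
    category: str | None = None  # DEL | AMP | MIX
    genotypes: dict[str, int] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def member_samples(self) -> set[str]:
        return {c.sample_id for c in self.members}

    @property
    def n_samples(self) -> int:
        """Samples in which the CNVR was detected (non-CN2, non-CN_)."""
        return sum(1 for g in self.genotypes.values() if g not in (2, CN_UNKNOWN))

    def genotype_counts(self) -> Counter:
        return Counter(self.genotypes.values())


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds of the whole pipeline; defaults follow the study design."""

    window_length: int = 1000          # bp per read-count window
    min_adjacent_windows: int = 3      # windows a CNV must span
    reciprocal_overlap: float = 0.50   # pairwise RO for CNVR merging
    iqr_multiplier: float = 1.5        # QC fence half-width in IQRs
    k_mad: float = 6.0                 # PCA outlier distance, in robust SDs
    hwe_alpha: float = 1e-5            # HWE chi-square significance floor
    alpha: float = 1e-3                # per-window depth significance
    gene_flank: int = 5_000_000        # bp flank counted as part of a gene
    min_samples_per_cnvr: int = 2      # singleton CNVR filter
    report_length_min: int = 1_000     # default database length filter (bp)
    report_length_max: int = 3_000_000
    report_min_samples: int = 2
    samples_per_genotype_plot: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.reciprocal_overlap <= 1):
            raise FormatError("reciprocal_overlap must be in (0, 1]")
        for name in (
            "window_length",
            "min_adjacent_windows",
            "iqr_multiplier",
            "hwe_alpha",
            "alpha",
            "gene_flank",
            "min_samples_per_cnvr",
            "report_length_min",
            "report_length_max",
            "report_min_samples",
            "samples_per_genotype_plot",
        ):
            if getattr(self, name) <= 0:
                raise FormatError(f"{name} must be strictly positive")


# ---------------------------------------------------------------------------
# Gene annotation types
# ---------------------------------------------------------------------------


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons of this transcript."""
        exons = sorted(self.exons)
        out = []
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out


@dataclass
class GeneModel:
    gene_id: str
    name: str
    chrom: str
    start: int
    end: int
    strand: str  # '+', '-' or '.'
    transcripts: list[Transcript] = field(default_factory=list)


@dataclass
class GeneTrack:
    """Genes with resolved transcript structure, plus orphan features."""

    genes: list[GeneModel] = field(default_factory=list)
    orphans: list[tuple[str, str, int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# CNV call tables
# ---------------------------------------------------------------------------

_CALL_COLUMNS = ("chrom", "start", "end", "sample", "cn")


def read_cnv_calls(path: str | os.PathLike, dataset_id: str = "") -> list[CNVCall]:
    """Read a BED-like TSV of per-sample CNV calls (1-based inclusive).

    Required header columns: chrom, start, end, sample, cn.  Rows with
    cn=2 are rejected (CN2 is the reference, not a CNV); coordinate and
    genotype errors carry the offending line number.
    """
    calls: list[CNVCall] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, expected header")
        missing = [c for c in _CALL_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                start, end = int(row["start"]), int(row["end"])
                cn = str_to_cn(row["cn"])
            except ValueError as exc:
                raise RecordError(f"{path}:{lineno}: {exc}") from exc
            try:
                calls.append(
                    CNVCall(
                        sample_id=row["sample"],
                        chrom=row["chrom"],
                        start=start,
                        end=end,
                        cn=cn,
                        dataset_id=dataset_id,
                    )
                )
            except RecordError as exc:
                raise RecordError(f"{path}:{lineno}: {exc}") from exc
    return calls


def write_cnv_calls(calls: Iterable[CNVCall], path: str | os.PathLike) -> None:
    with _atomic_open(path) as fh:
        fh.write("chrom\tstart\tend\tsample\tcn\n")
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.sample_id}\t{c.cn}\n")


# ---------------------------------------------------------------------------
# Read-count matrices
# ---------------------------------------------------------------------------


def read_count_matrix(path: str | os.PathLike) -> ReadCountMatrix:
    """Read a window read-count TSV: chrom, start, end, then one column per sample.

    The window length is inferred as the modal window size; chromosome
    lengths as the maximum window end per chromosome.  Overlapping or
    duplicated windows are a format error.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column(s): {col}")
    sample_ids = tuple(c for c in df.columns if c not in ("chrom", "start", "end"))
    if not sample_ids:
        raise FormatError(f"{path}: no sample columns")
    sizes = (df["end"] - df["start"] + 1).to_numpy()
    wl = int(pd.Series(sizes).mode().iloc[0])
    for chrom, grp in df.groupby("chrom", sort=False):
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] <= g["end"].to_numpy()[:-1]).any():
            raise FormatError(f"{path}: overlapping or duplicated windows on {chrom}")
    chroms = list(dict.fromkeys(df["chrom"]))
    lengths = tuple(int(df.loc[df["chrom"] == c, "end"].max()) for c in chroms)
    layout = GenomeLayout(tuple(chroms), lengths, window_length=wl)
    expected = layout.windows()
    got = df[["chrom", "start", "end"]].reset_index(drop=True)
    if not expected[["chrom", "start", "end"]].equals(
        got.astype({"start": np.int64, "end": np.int64})
    ):
        raise FormatError(f"{path}: windows do not tile the inferred layout")
    counts = df[list(sample_ids)].to_numpy()
    if (counts < 0).any():
        raise RecordError(f"{path}: negative read count")
    return ReadCountMatrix(layout, sample_ids, counts)


def write_count_matrix(matrix: ReadCountMatrix, path: str | os.PathLike) -> None:
    df = matrix.windows[["chrom", "start", "end"]].copy()
    for j, s in enumerate(matrix.sample_ids):
        df[s] = matrix.counts[:, j]
    with _atomic_open(path) as fh:
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

_META_COLUMNS = ("sample_id", "breed", "dataset_id", "coverage")


def read_sample_meta(path: str | os.PathLike) -> pd.DataFrame:
    """Read sample metadata CSV: sample_id, breed, dataset_id, coverage."""
    df = pd.read_csv(path)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise RecordError(f"{path}: duplicate sample_id {dup!r}")
    if (df["breed"].astype(str).str.len() == 0).any():
        raise RecordError(f"{path}: empty breed code")
    return df


def write_sample_meta(meta: pd.DataFrame, path: str | os.PathLike) -> None:
    with _atomic_open(path) as fh:
        meta.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------


def read_features_gff3(path: str | os.PathLike) -> GeneTrack:
    """Parse a GFF3 into gene models with resolved transcript structure.

    Introns are derived as the gaps between consecutive exons of each
    transcript.  Exons or CDS without a resolvable parent transcript are
    kept as orphans with a warning (no intron derivation for them).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    track = GeneTrack()
    transcript_kinds = {"mRNA", "transcript"}
    sub_kinds = {
        "exon": "exons",
        "CDS": "cds",
        "five_prime_UTR": "utr5",
        "three_prime_UTR": "utr3",
    }
    seen_sub_ids: set[str] = set()
    for gene in db.features_of_type("gene"):
        name = gene.attributes.get("Name", [gene.id])[0]
        model = GeneModel(
            gene_id=gene.id,
            name=name,
            chrom=gene.seqid,
            start=gene.start,
            end=gene.end,
            strand=gene.strand or ".",
        )
        for tx in db.children(gene, level=1):
            if tx.featuretype not in transcript_kinds:
                continue
            t = Transcript(transcript_id=tx.id)
            for child in db.children(tx, level=1):
                attr = sub_kinds.get(child.featuretype)
                if attr is None:
                    continue
                getattr(t, attr).append((child.start, child.end))
                seen_sub_ids.add(_feature_key(child))
            model.transcripts.append(t)
        track.genes.append(model)
    # Orphan sub-features: exon/CDS/UTR with no transcript parent
    for kind in sub_kinds:
        for feat in db.features_of_type(kind):
            if _feature_key(feat) in seen_sub_ids:
                continue
            warnings.warn(
                f"{kind} at {feat.seqid}:{feat.start}-{feat.end} has no parent "
                "transcript; kept without intron derivation",
                stacklevel=2,
            )
            track.orphans.append((kind, feat.seqid, feat.start, feat.end))
    return track


def _feature_key(feat) -> str:
    return f"{feat.featuretype}:{feat.seqid}:{feat.start}:{feat.end}:{feat.id}"


# ---------------------------------------------------------------------------
# BED-like annotation tracks (QTL / gap / repeat / segdup)
# ---------------------------------------------------------------------------


def read_track(path: str | os.PathLike, kind: str) -> pd.DataFrame:
    """Read a BED-like TSV annotation track (1-based inclusive, with header).

    Required columns chrom, start, end; an optional ``name`` column
    supplies feature identifiers.  Returns a frame with columns
    chrom, start, end, feature_id, kind.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("chrom", "start", "end") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    out = df[["chrom", "start", "end"]].copy()
    if "name" in df.columns:
        out["feature_id"] = df["name"].astype(str)
    else:
        out["feature_id"] = [f"{kind}_{i + 1}" for i in range(len(df))]
    out["kind"] = kind
    if (out["start"] > out["end"]).any():
        bad = out.loc[out["start"] > out["end"]].index[0]
        raise RecordError(f"{path}: start > end at data row {bad + 1}")
    return out


# ---------------------------------------------------------------------------
# CNVR tables and genotype matrices
# ---------------------------------------------------------------------------

_CN_COLS = [f"CN{i}" for i in range(9)] + ["CN_"]


def write_cnvr_table(cnvrs: Sequence[CNVR], path: str | os.PathLike) -> None:
    """Write one CSV row per CNVR, ordered by (chrom, start, end).

    ``n_samples`` counts samples with a non-CN2, non-CN_ genotype; the
    per-genotype columns count every genotype class including CN2 and CN_.
    """
    rows = []
    for r in sorted(cnvrs, key=lambda r: (r.chrom, r.start, r.end)):
        counts = r.genotype_counts()
        row = {
            "cnvr_id": r.cnvr_id,
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "length": r.length,
            "category": r.category or "",
            "n_samples": r.n_samples,
        }
        for i in range(9):
            row[f"CN{i}"] = counts.get(i, 0)
        row["CN_"] = counts.get(CN_UNKNOWN, 0)
        rows.append(row)
    header = ["cnvr_id", "chrom", "start", "end", "length", "category", "n_samples"]
    header += _CN_COLS
    with _atomic_open(path) as fh:
        writer = csv.DictWriter(fh, fieldnames=header, quoting=csv.QUOTE_MINIMAL)
        writer.writeheader()
        writer.writerows(rows)


def read_cnvr_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def write_genotype_matrix(gm: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a CNVRs x samples genotype matrix as CSV with CN-string cells."""
    out = gm.map(cn_to_str)
    out.index.name = "cnvr_id"
    with _atomic_open(path) as fh:
        out.to_csv(fh)


def read_genotype_matrix(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="cnvr_id")
    return df.map(str_to_cn)


# ---------------------------------------------------------------------------


class _atomic_open:
    """Write to a temp file in the target directory, rename on success."""

    def __init__(self, path: str | os.PathLike):
        self.path = os.fspath(path)

    def __enter__(self):
        d = os.path.dirname(self.path) or "."
        fd, self.tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
        self.fh = os.fdopen(fd, "w", newline="")
        return self.fh

    def __exit__(self, exc_type, exc, tb):
        self.fh.close()
        if exc_type is None:
            os.replace(self.tmp, self.path)
        else:
            os.unlink(self.tmp)
        return False
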