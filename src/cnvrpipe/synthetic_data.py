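"""Synthetic multi-breed cohorts with known CNV truth.

The generator emulates the signal structure of a multi-sample
whole-genome read-depth experiment:

* each CNV locus carries a deletion or duplication allele with a
  per-breed allele frequency; diploid genotypes are drawn under
  Hardy-Weinberg proportions (p^2, 2pq, q^2) within each breed;
* window read counts are Poisson with expectation
  ``lambda * CN/2 * batch_scale``, where ``lambda`` is the per-window
  mean depth (default 100 reads per 1-kb window) — windows partially
  covered by a CNV get a proportionally interpolated expectation;
* allele frequencies, where not given explicitly, are drawn from a
  rare-skewed neutral-spectrum density (proportional to 1/q), matching
  the strongly rare-shifted frequency spectra seen in real CNV cohorts;
* "problematic" samples of the two kinds that dominate real QC —
  low-coverage samples and batch outliers — can be planted with known
  labels so QC recall is measurable.

What it does not emulate: GC and mappability bias, segmental-duplication
depth artefacts, read-level errors.  Tests passing on these cohorts show
the pipeline's rules behave as specified, not that the caller would be
well calibrated on real alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import FormatError, GenomeLayout, ReadCountMatrix

__all__ = [
    "CNVLocusSpec",
    "simulate_cohort",
    "simulate_counts",
    "plant_problem_samples",
    "sfs_frequencies",
    "random_loci",
]


@dataclass
class CNVLocusSpec:
    """A polymorphic CNV locus with per-breed variant-allele frequencies.

    ``gain`` is the number of copies added per duplication allele
    (1 gives heterozygote CN3 / homozygote CN4; 3 models a high-amplification
    allele with homozygote CN8, as seen at the cattle KIT locus).
    """

    chrom: str
    start: int
    end: int
    variant: str  # "DEL" or "DUP"
    allele_frequency: dict[str, float] = field(default_factory=dict)
    gain: int = 1
    locus_id: str = ""

    def __post_init__(self) -> None:
        if self.variant not in ("DEL", "DUP"):
            raise FormatError(f"variant must be DEL or DUP, got {self.variant!r}")
        for breed, q in self.allele_frequency.items():
            if not (0.0 <= q <= 1.0):
                raise FormatError(
                    f"allele frequency {q} for breed {breed} outside [0, 1]"
                )
        if not self.locus_id:
            self.locus_id = f"{self.chrom}:{self.start}-{self.end}:{self.variant}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def cn_for_allele_count(self, k: int) -> int:
        """Diploid copy number for k variant alleles (k in 0..2)."""
        if self.variant == "DEL":
            return 2 - k
        return min(2 + self.gain * k, 8)


def sfs_frequencies(
    n: int, rng: np.random.Generator, q_min: float = 0.01, q_max: float = 0.4
) -> np.ndarray:
    """Draw allele frequencies from a density proportional to 1/q on [q_min, q_max].

    This is the neutral site-frequency-spectrum shape; most variants are
    rare, as observed for CNVs in outbred cohorts.
    """
    u = rng.random(n)
    return q_min * (q_max / q_min) ** u


def simulate_cohort(
    loci: list[CNVLocusSpec],
    breed_sizes: dict[str, int],
    seed: int,
    dataset_id: str = "ds1",
    coverage: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample diploid genotypes under per-breed HWE at every locus.

    Returns (meta, truth): sample metadata with breed/dataset/coverage,
    and a samples x loci table of true integer copy numbers.
    """
    for b, n in breed_sizes.items():
        if n < 1:
            raise FormatError(f"breed {b} has size {n} < 1")
    rng = np.random.default_rng(seed)
    sample_ids, breeds = [], []
    for breed, n in breed_sizes.items():
        for i in range(n):
            sample_ids.append(f"{breed}{i + 1:03d}")
            breeds.append(breed)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "breed": breeds,
            "dataset_id": dataset_id,
            "coverage": coverage,
        }
    )
    truth = pd.DataFrame(index=sample_ids, columns=[l.locus_id for l in loci], dtype=int)
    for locus in loci:
        cns = np.empty(len(sample_ids), dtype=int)
        for i, breed in enumerate(breeds):
            q = locus.allele_frequency.get(breed, 0.0)
            k = rng.binomial(2, q)
            cns[i] = locus.cn_for_allele_count(k)
        truth[locus.locus_id] = cns
    truth.index.name = "sample_id"
    return meta, truth


def _expected_depth(
    truth: pd.DataFrame,
    loci: list[CNVLocusSpec],
    layout: GenomeLayout,
    mean_depth_per_window: float,
) -> np.ndarray:
    """Per-(window, sample) expected counts; partial overlap interpolates."""
    windows = layout.windows()
    n_win, n_smp = len(windows), len(truth.index)
    lam = np.full((n_win, n_smp), mean_depth_per_window, dtype=float)
    w_chrom = windows["chrom"].to_numpy()
    w_start = windows["start"].to_numpy()
    w_end = windows["end"].to_numpy()
    w_len = (w_end - w_start + 1).astype(float)
    for locus in loci:
        mask = (w_chrom == locus.chrom) & (w_start <= locus.end) & (w_end >= locus.start)
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            continue
        ov = (
            np.minimum(w_end[idx], locus.end) - np.maximum(w_start[idx], locus.start) + 1
        )
        frac = ov / w_len[idx]
        cn = truth[locus.locus_id].to_numpy(dtype=float)
        # lam *= 1 + frac * (CN/2 - 1): full windows scale by CN/2
        lam[idx, :] *= 1.0 + np.outer(frac, cn / 2.0 - 1.0)
    return lam


def simulate_counts(
    truth: pd.DataFrame,
    loci: list[CNVLocusSpec],
    layout: GenomeLayout,
    seed: int,
    mean_depth_per_window: float = 100.0,
    batch_scale: dict[str, float] | None = None,
    meta: pd.DataFrame | None = None,
    noise: str = "poisson",
    overdispersion: float | None = None,
) -> ReadCountMatrix:
    """Window read counts for a cohort with known truth.

    ``noise="none"`` returns the exact expectations (the analytic
    noise-free mode used by caller-contract tests); ``"poisson"`` draws
    Poisson counts; with ``overdispersion`` r set, a negative binomial
    with that dispersion (variance lambda + lambda^2/r) is used instead.
    ``batch_scale`` multiplies every expectation of the samples of a
    dataset (requires ``meta`` to map samples to datasets).
    """
    if mean_depth_per_window <= 0:
        raise FormatError("mean_depth_per_window must be positive")
    rng = np.random.default_rng(seed)
    lam = _expected_depth(truth, loci, layout, mean_depth_per_window)
    if batch_scale:
        if meta is None:
            raise FormatError("batch_scale requires sample metadata")
        ds = meta.set_index("sample_id")["dataset_id"]
        scales = np.array([batch_scale.get(ds[s], 1.0) for s in truth.index])
        lam = lam * scales[np.newaxis, :]
    if noise == "none":
        counts = lam
    elif noise == "poisson":
        if overdispersion is not None:
            r = float(overdispersion)
            p = r / (r + lam)
            counts = rng.negative_binomial(r, p)
        else:
            counts = rng.poisson(lam)
    else:
        raise FormatError(f"unknown noise mode {noise!r}")
    return ReadCountMatrix(layout, tuple(truth.index), counts)


def plant_problem_samples(
    matrix: ReadCountMatrix,
    kind: str,
    samples: list[str],
    seed: int,
    multiplier: float = 0.3,
    window_fraction: float = 0.2,
    scale: float = 1.5,
) -> tuple[ReadCountMatrix, dict[str, str]]:
    """Degrade designated samples; returns (new matrix, truth labels).

    ``low_coverage``: binomial thinning of the sample's counts by
    ``multiplier`` (integer counts) or plain scaling (real-valued
    counts) — emulates a sample sequenced at a fraction of the cohort
    depth.  ``batch_outlier``: a random ``window_fraction`` of windows
    is systematically rescaled by ``scale`` — emulates platform or
    library-prep bias confined to one sample.
    """
    if kind not in ("low_coverage", "batch_outlier"):
        raise FormatError(f"unknown problem kind {kind!r}")
    rng = np.random.default_rng(seed)
    counts = matrix.counts.copy()
    integral = np.issubdtype(counts.dtype, np.integer)
    labels: dict[str, str] = {}
    for s in samples:
        j = matrix.sample_ids.index(s)
        if kind == "low_coverage":
            if integral:
                counts[:, j] = rng.binomial(counts[:, j], multiplier)
            else:
                counts[:, j] = counts[:, j] * multiplier
        else:
            n_win = counts.shape[0]
            sel = rng.choice(n_win, max(1, int(round(window_fraction * n_win))), replace=False)
            if integral:
                counts[sel, j] = rng.poisson(scale * counts[sel, j])
            else:
                counts[sel, j] = counts[sel, j] * scale
        labels[s] = kind
    return ReadCountMatrix(matrix.layout, matrix.sample_ids, counts), labels


def random_loci(
    layout: GenomeLayout,
    n_loci: int,
    breeds: list[str],
    seed: int,
    min_windows: int = 3,
    max_windows: int = 20,
    frac_del: float = 0.6,
    breed_specific_fraction: float = 0.0,
    q_min: float = 0.01,
    q_max: float = 0.4,
    min_gap_windows: int = 5,
) -> list[CNVLocusSpec]:
    """Place non-overlapping window-aligned CNV loci with SFS-drawn frequencies.

    A ``breed_specific_fraction`` of loci are polymorphic in one breed
    only (frequency 0 elsewhere); the rest share one frequency across
    breeds.  Loci are separated by at least ``min_gap_windows`` windows.
    """
    rng = np.random.default_rng(seed)
    wl = layout.window_length
    loci: list[CNVLocusSpec] = []
    cursor: dict[str, int] = {c: 0 for c in layout.chrom_names}  # next free window
    chrom_cycle = list(layout.chrom_names)
    ci = 0
    attempts = 0
    while len(loci) < n_loci and attempts < 50 * n_loci:
        attempts += 1
        chrom = chrom_cycle[ci % len(chrom_cycle)]
        ci += 1
        n_full = layout.lengths[chrom] // wl
        width = int(rng.integers(min_windows, max_windows + 1))
        w0 = cursor[chrom] + min_gap_windows
        if w0 + width > n_full:
            continue
        start = w0 * wl + 1
        end = (w0 + width) * wl
        cursor[chrom] = w0 + width
        variant = "DEL" if rng.random() < frac_del else "DUP"
        q = float(sfs_frequencies(1, rng, q_min, q_max)[0])
        if rng.random() < breed_specific_fraction and breeds:
            target = breeds[int(rng.integers(len(breeds)))]
            af = {b: (q if b == target else 0.0) for b in breeds}
        else:
            af = {b: q for b in breeds}
        loci.append(CNVLocusSpec(chrom, start, end, variant, af))
    if len(loci) < n_loci:
        raise FormatError(
            f"could not place {n_loci} loci on this layout (placed {len(loci)}); "
            "enlarge the genome or reduce locus sizes/gaps"
        )
    return loci
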