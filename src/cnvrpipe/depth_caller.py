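"""Multi-sample window read-depth CNV caller.

A deliberately simple caller with the external contract common to
window-based read-depth tools: counts on a fixed 1,000-bp grid are
normalised across samples, each window gets an integer copy-number
estimate (CN0..CN8, CN2 = diploid reference) with a per-window
significance flag, and a CNV is reported only when at least three
adjacent windows deviate in a consistent direction.  Call boundaries
snap to window boundaries, so every call has length >= 3 windows and a
multiple of the window length.

The per-window reference is the across-sample *median* of normalised
counts — robust to carriers, but windows where more than half the
cohort carries a variant will mis-reference (documented limitation).
Significance is a two-sided exact Poisson tail test of the observed
normalised count against the window reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import poisson

from .core_io import CNVCall, FormatError, GenomeLayout, ReadCountMatrix

__all__ = ["WindowCNMatrix", "normalize_counts", "estimate_window_cn", "segment_calls"]


@dataclass
class WindowCNMatrix:
    """Per-(window, sample) integer CN estimates and significance flags.

    ``masked`` marks windows excluded from calling (partial terminal
    windows and windows with zero reference depth); flags are always
    false there.  The estimate and the flag are otherwise independent:
    a window can round to CN1 yet be statistically unconvincing.
    """

    layout: GenomeLayout
    sample_ids: tuple[str, ...]
    cn: np.ndarray        # (n_windows, n_samples) int
    flag: np.ndarray      # (n_windows, n_samples) bool
    masked: np.ndarray    # (n_windows,) bool
    reference: np.ndarray  # (n_windows,) float, per-window lambda


def normalize_counts(
    matrix: ReadCountMatrix,
) -> tuple[ReadCountMatrix, dict[str, float], list[str]]:
    """Scale each sample so its total count equals the cohort mean total.

    Returns (normalised matrix, per-sample scaling factors, excluded
    samples).  Samples with zero total are excluded with a warning; the
    returned matrix drops their columns.
    """
    if len(matrix.sample_ids) < 2:
        raise FormatError("normalisation needs at least 2 samples")
    totals = matrix.counts.sum(axis=0).astype(float)
    zero = totals == 0
    excluded = [s for s, z in zip(matrix.sample_ids, zero) if z]
    if excluded:
        warnings.warn(
            f"excluding zero-total sample(s): {', '.join(excluded)}", stacklevel=2
        )
    keep = ~zero
    kept_ids = tuple(s for s, k in zip(matrix.sample_ids, keep) if k)
    counts = matrix.counts[:, keep].astype(float)
    totals = totals[keep]
    target = totals.mean()
    factors = {s: target / t for s, t in zip(kept_ids, totals)}
    normed = counts * (target / totals)[np.newaxis, :]
    return ReadCountMatrix(matrix.layout, kept_ids, normed), factors, excluded


def _round_toward_2(v: np.ndarray) -> np.ndarray:
    """Round to nearest integer; exact halves resolve toward 2."""
    v = np.asarray(v, dtype=float)
    up = np.floor(v + 0.5)    # half rounds up (used below 2)
    down = np.ceil(v - 0.5)   # half rounds down (used at/above 2)
    return np.where(v >= 2.0, down, up)


def estimate_window_cn(norm_matrix: ReadCountMatrix, alpha: float = 1e-3) -> WindowCNMatrix:
    """Integer CN estimate and significance flag per (window, sample).

    Per window the reference depth ``lambda_w`` is the across-sample
    median of normalised counts; the estimate is ``round(2 x /
    lambda_w)`` (halves toward 2) clipped to [0, 8].  The flag is true
    iff the estimate differs from 2 AND the two-sided exact Poisson tail
    probability of x under ``lambda_w`` is below ``alpha``.  Partial
    windows and windows with zero reference are masked.
    """
    x = norm_matrix.counts.astype(float)
    lam = np.median(x, axis=1)
    partial = norm_matrix.windows["partial"].to_numpy()
    masked = partial | (lam == 0)
    safe_lam = np.where(lam > 0, lam, 1.0)
    v = 2.0 * x / safe_lam[:, None]
    cn = np.clip(_round_toward_2(v), 0, 8).astype(np.int8)
    # two-sided exact Poisson test: each side tested at alpha, i.e. flag when
    # min(P(X<=floor x), P(X>=ceil x)) < alpha
    lo = poisson.cdf(np.floor(x), safe_lam[:, None])
    hi = poisson.sf(np.ceil(x) - 1, safe_lam[:, None])
    p_tail = np.minimum(lo, hi)
    flag = (cn != 2) & (p_tail < alpha) & ~masked[:, None]
    cn[masked, :] = 2
    return WindowCNMatrix(
        layout=norm_matrix.layout,
        sample_ids=norm_matrix.sample_ids,
        cn=cn.astype(int),
        flag=flag,
        masked=masked,
        reference=lam,
    )


def segment_calls(
    wcn: WindowCNMatrix,
    min_adjacent_windows: int = 3,
    dataset_id: str = "",
) -> list[CNVCall]:
    """Merge runs of >= ``min_adjacent_windows`` flagged windows into CNV calls.

    A run must be direction-consistent (all window estimates below 2, or
    all above); a flagged gain window terminates a loss run and vice
    versa, so mixed adjacent events yield two abutting calls.  The call
    genotype is the median of the window estimates in the run, halves
    rounded toward 2.  Boundaries snap to window boundaries.
    """
    windows = wcn.layout.windows()
    w_chrom = windows["chrom"].to_numpy()
    w_start = windows["start"].to_numpy()
    w_end = windows["end"].to_numpy()
    calls: list[CNVCall] = []
    for j, sample in enumerate(wcn.sample_ids):
        # direction code: -1 loss, +1 gain, 0 not flagged
        d = np.where(wcn.flag[:, j], np.sign(wcn.cn[:, j] - 2), 0).astype(np.int8)
        for chrom in wcn.layout.chrom_names:
            sel = np.nonzero(w_chrom == chrom)[0]
            dc = d[sel]
            if not dc.any():
                continue
            # run-length encoding of constant stretches
            change = np.nonzero(np.diff(dc))[0] + 1
            bounds = np.concatenate(([0], change, [len(dc)]))
            for b0, b1 in zip(bounds[:-1], bounds[1:]):
                if dc[b0] == 0 or b1 - b0 < min_adjacent_windows:
                    continue
                run = sel[b0:b1]
                gt = int(_round_toward_2(np.median(wcn.cn[run, j])))
                calls.append(
                    CNVCall(
                        sample_id=sample,
                        chrom=chrom,
                        start=int(w_start[run[0]]),
                        end=int(w_end[run[-1]]),
                        cn=gt,
                        dataset_id=dataset_id,
                    )
                )
    calls.sort(key=lambda c: (c.chrom, c.start, c.end, c.sample_id))
    return calls
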