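"""Per-dataset sample quality control.

Problematic samples are identified before CNVR construction by two
deterministic rules and removed together with all their CNV calls:

* **PCA outliers** — principal components of the normalised window
  counts (samples as observations) summarise systematic depth
  structure; a sample is flagged when its Euclidean distance from the
  coordinate-wise median in (PC1, PC2) exceeds
  ``median(d) + k_mad * 1.4826 * MAD(d)``, i.e. ``k_mad`` robust
  standard deviations (the 1.4826 factor makes the MAD a consistent
  normal-scale estimate).  Default ``k_mad = 6``.
* **IQR outliers** — a sample whose DEL proportion (fraction of its
  calls with CN<2) or total CNV count lies more than 1.5 interquartile
  ranges outside [Q1, Q3] of its dataset is flagged.

QC is strictly per dataset: batch effects make cross-dataset read-depth
comparison unreliable, so cohorts from different datasets must be
flagged within their own group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core_io import CNVCall, FormatError, ReadCountMatrix

__all__ = ["QCReport", "pca_outliers", "iqr_outliers", "build_qc_report", "apply_qc"]

_MAD_SCALE = 1.4826  # consistency factor: MAD -> sigma under normality


@dataclass
class QCReport:
    """Per-sample QC metrics and flags; ``pass`` = no flag set."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: sample_id, dataset_id, total_cnvs, del_proportion,
    #          pc1, pc2, pca_outlier, del_prop_outlier, total_cnv_outlier,
    #          high_coverage_outlier, pass

    @property
    def failing_samples(self) -> list[str]:
        if self.table.empty:
            return []
        return self.table.loc[~self.table["pass"], "sample_id"].tolist()


def pca_outliers(
    norm_matrix: ReadCountMatrix, k_mad: float = 6.0
) -> tuple[np.ndarray, np.ndarray]:
    """Flag PCA outliers on normalised counts; returns (flags, pc_coords).

    Samples are observations, windows features (centred per window).
    With ``k_mad = inf`` nothing is ever flagged.
    """
    n = len(norm_matrix.sample_ids)
    if n < 3:
        raise FormatError("PCA outlier detection needs at least 3 samples")
    X = norm_matrix.counts.T.astype(float)  # samples x windows
    n_comp = 2
    if n - 1 < 2:
        n_comp = n - 1
        warnings.warn(f"fewer samples than components; using {n_comp}", stacklevel=2)
    pca = PCA(n_components=n_comp, svd_solver="full")
    pcs = pca.fit_transform(X)
    if pcs.shape[1] < 2:
        pcs = np.column_stack([pcs, np.zeros(n)])
    med = np.median(pcs[:, :2], axis=0)
    d = np.sqrt(((pcs[:, :2] - med) ** 2).sum(axis=1))
    mad = np.median(np.abs(d - np.median(d)))
    if not np.isfinite(k_mad):
        return np.zeros(n, dtype=bool), pcs[:, :2]
    # noise floor guards against float jitter when all distances are ~0
    eps = 1e-9 * max(1.0, float(np.abs(pcs[:, :2]).max()))
    threshold = np.median(d) + k_mad * _MAD_SCALE * mad + eps
    return d > threshold, pcs[:, :2]


def iqr_outliers(values: np.ndarray, multiplier: float = 1.5) -> np.ndarray:
    """Two-sided 1.5xIQR fence with type-7 (linear interpolation) quartiles."""
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise FormatError("IQR outlier detection needs at least 4 values")
    q1, q3 = np.percentile(values, [25, 75])  # numpy default is type-7
    iqr = q3 - q1
    return (values < q1 - multiplier * iqr) | (values > q3 + multiplier * iqr)


def build_qc_report(
    calls: list[CNVCall],
    meta: pd.DataFrame,
    norm_matrix: ReadCountMatrix | None = None,
    iqr_multiplier: float = 1.5,
    k_mad: float = 6.0,
    flag_high_coverage: bool = False,
) -> QCReport:
    """Compute all QC metrics and flags, grouped by dataset.

    ``norm_matrix`` enables the PCA rule (skipped when absent).  The
    optional high-coverage rule (off by default) applies the IQR fence
    to the metadata coverage field, upper side only.
    """
    by_sample: dict[str, list[CNVCall]] = {s: [] for s in meta["sample_id"]}
    for c in calls:
        if c.sample_id in by_sample:
            by_sample[c.sample_id].append(c)
    rows = []
    for _, m in meta.iterrows():
        s = m["sample_id"]
        mine = by_sample.get(s, [])
        total = len(mine)
        delp = (
            sum(1 for c in mine if c.cn < 2) / total if total else 0.0
        )
        rows.append(
            {
                "sample_id": s,
                "dataset_id": m["dataset_id"],
                "coverage": m.get("coverage", np.nan),
                "total_cnvs": total,
                "del_proportion": delp,
            }
        )
    table = pd.DataFrame(rows)
    table["pc1"] = np.nan
    table["pc2"] = np.nan
    table["pca_outlier"] = False
    table["del_prop_outlier"] = False
    table["total_cnv_outlier"] = False
    table["high_coverage_outlier"] = False
    for ds, grp in table.groupby("dataset_id", sort=False):
        idx = grp.index
        if len(idx) >= 4:
            table.loc[idx, "del_prop_outlier"] = iqr_outliers(
                grp["del_proportion"].to_numpy(), iqr_multiplier
            )
            table.loc[idx, "total_cnv_outlier"] = iqr_outliers(
                grp["total_cnvs"].to_numpy(), iqr_multiplier
            )
            if flag_high_coverage:
                cov = grp["coverage"].to_numpy(dtype=float)
                q1, q3 = np.percentile(cov, [25, 75])
                table.loc[idx, "high_coverage_outlier"] = cov > q3 + iqr_multiplier * (
                    q3 - q1
                )
        if norm_matrix is not None:
            ds_samples = grp["sample_id"].tolist()
            present = [s for s in ds_samples if s in norm_matrix.sample_ids]
            if len(present) >= 3:
                sub = norm_matrix.subset_samples(present)
                flags, pcs = pca_outliers(sub, k_mad=k_mad)
                pos = {s: i for i, s in enumerate(present)}
                for row_i, s in zip(idx, ds_samples):
                    if s in pos:
                        table.loc[row_i, ["pc1", "pc2"]] = pcs[pos[s]]
                        table.loc[row_i, "pca_outlier"] = bool(flags[pos[s]])
    flag_cols = [
        "pca_outlier",
        "del_prop_outlier",
        "total_cnv_outlier",
        "high_coverage_outlier",
    ]
    table["pass"] = ~table[flag_cols].any(axis=1)
    return QCReport(table=table)


def apply_qc(
    calls: list[CNVCall], meta: pd.DataFrame, report: QCReport
) -> tuple[list[CNVCall], pd.DataFrame, dict[str, int]]:
    """Drop every call from failing samples; returns (calls, meta, log).

    Idempotent: re-applying the same report changes nothing.
    """
    failing = set(report.failing_samples)
    kept = [c for c in calls if c.sample_id not in failing]
    new_meta = meta[~meta["sample_id"].isin(failing)].reset_index(drop=True)
    log = {
        "samples_removed": len(set(meta["sample_id"]) & failing),
        "calls_removed": len(calls) - len(kept),
    }
    return kept, new_meta, log
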