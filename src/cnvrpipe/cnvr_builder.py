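"""CNVR construction and genotype assignment.

CNVs from different samples are clustered into CNV regions (CNVRs) by
the 50% pairwise reciprocal-overlap criterion: two CNVs are linked when
the length of their intersection is at least half of *each* CNV's
length.  CNVRs are the connected components of this graph
(single-linkage closure), with span = [min member start, max member
end].  Clustering is genotype-agnostic, so deletion and amplification
calls can share a CNVR; regions seen in fewer than two distinct samples
are filtered out.

Per-sample CNVR genotypes follow the largest-aggregate-width rule: a
sample's member CNVs are grouped by copy-number class, class widths are
summed, and the class with the largest aggregate width wins; ties go to
the class closest to CN2, and a residual tie (e.g. CN1 vs CN3) to the
lower copy number.  Samples without a member CNV default to CN2, which
the CN2 correction then demotes to CN_ (undetermined) wherever the
sample carries a CNV in a different CNVR overlapping the test CNVR by
at least one base — such a sample cannot safely be called diploid
there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CN_UNKNOWN, CNVR, CNVCall, GenomeLayout, PipelineConfig

__all__ = [
    "reciprocal_overlap",
    "ro_satisfied",
    "cluster_cnvs",
    "categorize",
    "filter_singletons",
    "assign_genotypes",
    "cn2_correction",
    "genotype_matrix",
    "build_cnvrs",
    "merge_cnvr_sets",
]


def reciprocal_overlap(
    a: tuple[int, int], b: tuple[int, int]
) -> tuple[float, float]:
    """Overlap of two same-chromosome 1-based inclusive intervals as a
    fraction of each interval's length."""
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
    return ov / (a[1] - a[0] + 1), ov / (b[1] - b[0] + 1)


def ro_satisfied(a: CNVCall, b: CNVCall, threshold: float = 0.5) -> bool:
    """True iff both reciprocal-overlap fractions reach ``threshold``.

    Calls on different chromosomes never satisfy the criterion.
    """
    if a.chrom != b.chrom:
        return False
    fa, fb = reciprocal_overlap(a.interval, b.interval)
    return fa >= threshold and fb >= threshold


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_cnvs(
    calls: list[CNVCall],
    ro: float = 0.5,
    id_prefix: str = "cnvr",
) -> list[CNVR]:
    """Cluster CNVs into CNVRs by single-linkage reciprocal overlap.

    Sweep over start-sorted calls per chromosome: a qualifying pair must
    intersect, so only pairs whose intervals overlap are examined; the
    result equals brute-force all-pairs connected components.  Output is
    deterministically ordered by (chrom, start, end) and ids are
    assigned in that order.
    """
    n = len(calls)
    uf = _UnionFind(n)
    order = sorted(range(n), key=lambda i: (calls[i].chrom, calls[i].start, calls[i].end))
    for ii, i in enumerate(order):
        ci = calls[i]
        for j in order[ii + 1 :]:
            cj = calls[j]
            if cj.chrom != ci.chrom or cj.start > ci.end:
                break
            if ro_satisfied(ci, cj, ro):
                uf.union(i, j)
    groups: dict[int, list[CNVCall]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(calls[i])
    cnvrs = []
    for members in groups.values():
        cnvrs.append(
            CNVR(
                cnvr_id="",
                chrom=members[0].chrom,
                start=min(c.start for c in members),
                end=max(c.end for c in members),
                members=sorted(members, key=lambda c: (c.start, c.end, c.sample_id)),
            )
        )
    cnvrs.sort(key=lambda r: (r.chrom, r.start, r.end))
    for k, r in enumerate(cnvrs, start=1):
        r.cnvr_id = f"{id_prefix}_{k}"
    return cnvrs


def categorize(cnvr: CNVR) -> str:
    """DEL iff all member CNs are 0/1, AMP iff all >= 3, MIX otherwise."""
    if not cnvr.members:
        raise ValueError(f"CNVR {cnvr.cnvr_id} has no member CNVs")
    cns = {c.cn for c in cnvr.members}
    if cns <= {0, 1}:
        return "DEL"
    if all(cn >= 3 for cn in cns):
        return "AMP"
    return "MIX"


def filter_singletons(
    cnvrs: list[CNVR], min_samples: int = 2
) -> tuple[list[CNVR], int]:
    """Drop CNVRs whose members span fewer than ``min_samples`` distinct samples."""
    kept = [r for r in cnvrs if len(r.member_samples) >= min_samples]
    return kept, len(cnvrs) - len(kept)


def assign_genotypes(cnvr: CNVR, all_samples: list[str]) -> dict[str, int]:
    """Per-sample CNVR genotype by the largest-aggregate-width rule.

    Samples without a member CNV get the provisional reference CN2
    (subject to the later CN2 correction).
    """
    by_sample: dict[str, dict[int, int]] = {}
    for c in cnvr.members:
        by_sample.setdefault(c.sample_id, {}).setdefault(c.cn, 0)
        by_sample[c.sample_id][c.cn] += c.length
    genotypes: dict[str, int] = {}
    for s in all_samples:
        widths = by_sample.get(s)
        if not widths:
            genotypes[s] = 2
            continue
        # max aggregate width; tie -> closest to CN2; residual tie -> lower CN
        genotypes[s] = max(widths, key=lambda cn: (widths[cn], -abs(cn - 2), -cn))
    return genotypes


def cn2_correction(cnvrs: list[CNVR]) -> None:
    """Demote provisional CN2 to CN_ at CNVRs overlapped by the sample's CNVs.

    For each test CNVR and each sample whose genotype there is the
    provisional CN2: if the sample has a member CNV in *another* CNVR
    that overlaps the test CNVR by >= 1 bp, the genotype becomes CN_.
    Mutates ``cnvr.genotypes`` in place; idempotent.
    """
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(cnvrs):
        by_chrom.setdefault(r.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        idxs = sorted(idxs, key=lambda i: cnvrs[i].start)
        for a_pos, i in enumerate(idxs):
            ri = cnvrs[i]
            for j in idxs[a_pos + 1 :]:
                rj = cnvrs[j]
                if rj.start > ri.end:
                    break
                # ri and rj overlap by >= 1 bp
                for test, other in ((ri, rj), (rj, ri)):
                    for s in other.member_samples:
                        if test.genotypes.get(s) == 2 and s not in test.member_samples:
                            test.genotypes[s] = CN_UNKNOWN


def genotype_matrix(cnvrs: list[CNVR], all_samples: list[str]) -> pd.DataFrame:
    """CNVRs x samples integer genotype matrix (CN_ encoded as -1)."""
    data = {
        r.cnvr_id: [r.genotypes.get(s, 2) for s in all_samples] for r in cnvrs
    }
    gm = pd.DataFrame(data, index=all_samples).T
    gm.index.name = "cnvr_id"
    return gm.astype(int)


def build_cnvrs(
    calls: list[CNVCall],
    all_samples: list[str],
    config: PipelineConfig = PipelineConfig(),
    id_prefix: str = "cnvr",
) -> tuple[list[CNVR], pd.DataFrame, dict[str, int]]:
    """Full single-dataset CNVR pipeline stage.

    cluster -> singleton filter -> categorise -> genotype assignment ->
    CN2 correction; returns (CNVRs, genotype matrix, log).  The CN2
    correction runs on the retained (post-filter) CNVR set.
    """
    cnvrs = cluster_cnvs(calls, ro=config.reciprocal_overlap, id_prefix=id_prefix)
    n_before = len(cnvrs)
    cnvrs, n_removed = filter_singletons(cnvrs, config.min_samples_per_cnvr)
    for r in cnvrs:
        r.category = categorize(r)
        r.genotypes = assign_genotypes(r, all_samples)
    cn2_correction(cnvrs)
    gm = genotype_matrix(cnvrs, all_samples)
    log = {
        "cnvrs_clustered": n_before,
        "singletons_removed": n_removed,
        "cnvrs_kept": len(cnvrs),
    }
    return cnvrs, gm, log


@dataclass
class MergeSummary:
    n_regions: int
    total_bp: int
    pct_genome: float | None = None


def merge_cnvr_sets(
    sets: list[list[CNVR]],
    mode: str = "union",
    layout: GenomeLayout | None = None,
) -> tuple[pd.DataFrame, MergeSummary]:
    """Combine CNVR sets across datasets.

    ``union``: coalesce overlapping or bookended (end+1 == start)
    regions into a non-redundant set, reporting total bp covered and,
    given a layout, the percentage of the genome.  ``unique_coords``:
    deduplicate on exact (chrom, start, end), counting regions with
    identical coordinates across datasets once.
    """
    regions = [(r.chrom, r.start, r.end) for s in sets for r in s]
    if mode == "unique_coords":
        uniq = sorted(set(regions))
        df = pd.DataFrame(uniq, columns=["chrom", "start", "end"])
        total = int((df["end"] - df["start"] + 1).sum()) if len(df) else 0
        return df, MergeSummary(len(df), total)
    if mode != "union":
        raise ValueError(f"unknown merge mode {mode!r}")
    merged: list[list] = []
    for chrom, start, end in sorted(regions):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2] + 1:
            merged[-1][2] = max(merged[-1][2], end)
        else:
            merged.append([chrom, start, end])
    df = pd.DataFrame(merged, columns=["chrom", "start", "end"])
    total = int((df["end"] - df["start"] + 1).sum()) if len(df) else 0
    pct = 100.0 * total / layout.genome_size if layout is not None else None
    return df, MergeSummary(len(df), total, pct)
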