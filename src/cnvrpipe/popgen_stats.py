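"""Population-genetic characterisation of CNVR genotypes.

* **HWE test** — Pearson's chi-square goodness of fit of genotype
  proportions to Hardy-Weinberg expectations, restricted to diallelic
  autosomal CNVRs: genotype spectra within {CN0, CN1, CN2} (deletion
  side: minor-allele homozygote, heterozygote, reference homozygote) or
  within {CN2, CN3, CN4} (duplication side).  The allele frequency is
  estimated from the counts, expected counts are n*(q^2, 2pq, p^2), the
  statistic has 1 degree of freedom, and a CNVR is "in HWE" when
  p >= 1e-5.  Multi-allelic spectra are not testable (the allele
  combination behind, say, CN3 + CN0 is ambiguous) and are reported as
  non-qualifying.
* **Parity test** — individuals with even genotypes (CN0, CN2, CN4,
  CN6, CN8; homozygote-like) must be at least as many as those with odd
  genotypes (CN1, CN3, CN5, CN7; heterozygote-like); ties pass.
* **Sample clustering** — hierarchical clustering with the Spearman
  correlation distance (1 - rho over CNVRs genotyped in both samples;
  CN_ is missing and pairwise-excluded) and the ward.D2 agglomeration
  criterion.
* Set-level summaries: >= 1-bp overlap fractions between CNVR sets,
  breed-specific CNVRs, and per-chromosome density tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import chi2, rankdata

from .core_io import CN_UNKNOWN, CNVR, GenomeLayout
from .cnvr_builder import merge_cnvr_sets

__all__ = [
    "HWEResult",
    "hwe_test",
    "parity_test",
    "spearman_distance_matrix",
    "cluster_samples",
    "linkage_to_newick",
    "overlap_fraction",
    "breed_specific",
    "density_by_chromosome",
]

_DEL_SIDE = {0, 1, 2}
_DUP_SIDE = {2, 3, 4}
_EVEN = {0, 2, 4, 6, 8}


@dataclass
class HWEResult:
    cnvr_id: str
    qualifies: bool
    mapping: str | None = None  # "DEL-side" or "DUP-side"
    reason: str | None = None
    chi2: float | None = None
    p_value: float | None = None
    in_hwe: bool | None = None


def hwe_test(
    genotype_counts: dict[int, int],
    hwe_alpha: float = 1e-5,
    cnvr_id: str = "",
    continuity_correction: bool = False,
) -> HWEResult:
    """Chi-square HWE goodness-of-fit on a diallelic CNVR genotype spectrum.

    ``genotype_counts`` maps integer genotypes to sample counts (CN_
    must already be excluded).  Qualification requires the observed
    spectrum to lie within {CN0, CN1, CN2} or {CN2, CN3, CN4} with at
    least two genotype classes present.  No continuity correction by
    default; ``continuity_correction`` enables the Yates-style
    |obs-exp| - 0.5 adjustment.
    """
    observed = {g: c for g, c in genotype_counts.items() if c > 0}
    if CN_UNKNOWN in observed:
        raise ValueError("CN_ samples must be excluded before the HWE test")
    spectrum = set(observed)
    if len(spectrum) < 2:
        return HWEResult(cnvr_id, False, reason="monomorphic")
    if spectrum <= _DEL_SIDE:
        mapping, classes = "DEL-side", (0, 1, 2)  # (aa, Aa, AA)
    elif spectrum <= _DUP_SIDE:
        mapping, classes = "DUP-side", (4, 3, 2)
    else:
        return HWEResult(cnvr_id, False, reason="multi-allelic")
    n_aa = observed.get(classes[0], 0)
    n_het = observed.get(classes[1], 0)
    n_AA = observed.get(classes[2], 0)
    n = n_aa + n_het + n_AA
    q = (2 * n_aa + n_het) / (2 * n)
    p = 1.0 - q
    expected = np.array([n * q * q, 2 * n * p * q, n * p * p])
    obs = np.array([n_aa, n_het, n_AA], dtype=float)
    nonzero = expected > 0
    dev = np.abs(obs - expected)
    if continuity_correction:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev[nonzero] ** 2 / expected[nonzero]).sum())
    p_value = float(chi2.sf(stat, df=1))
    return HWEResult(
        cnvr_id,
        True,
        mapping=mapping,
        chi2=stat,
        p_value=p_value,
        in_hwe=p_value >= hwe_alpha,
    )


def parity_test(genotype_counts: dict[int, int]) -> bool | None:
    """Pass iff even-genotype individuals are at least as many as odd.

    CN_ must be excluded; with zero genotyped samples the test is not
    evaluated (None).
    """
    if CN_UNKNOWN in genotype_counts and genotype_counts[CN_UNKNOWN] > 0:
        raise ValueError("CN_ samples must be excluded before the parity test")
    total = sum(genotype_counts.values())
    if total == 0:
        return None
    even = sum(c for g, c in genotype_counts.items() if g in _EVEN)
    return even >= total - even


def spearman_distance_matrix(gm: pd.DataFrame) -> pd.DataFrame:
    """Pairwise 1 - Spearman rho between sample genotype vectors.

    ``gm`` is CNVRs x samples with CN_ as -1 (treated as missing and
    pairwise-excluded).  Average ranks break the pervasive integer
    ties.  Pairs sharing no genotyped CNVR, or with a zero-variance
    vector over the shared set, get the maximum distance 2 with a
    warning.
    """
    samples = list(gm.columns)
    vals = gm.to_numpy(dtype=float)
    vals[vals == CN_UNKNOWN] = np.nan
    n = len(samples)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = ~np.isnan(vals[:, i]) & ~np.isnan(vals[:, j])
            if mask.sum() < 2:
                warnings.warn(
                    f"samples {samples[i]} and {samples[j]} share "
                    f"{int(mask.sum())} genotyped CNVRs; distance set to 2",
                    stacklevel=2,
                )
                dist[i, j] = dist[j, i] = 2.0
                continue
            a, b = vals[mask, i], vals[mask, j]
            if a.std() == 0 or b.std() == 0:
                warnings.warn(
                    f"zero-variance genotype vector for pair "
                    f"({samples[i]}, {samples[j]}); distance set to 2",
                    stacklevel=2,
                )
                dist[i, j] = dist[j, i] = 2.0
                continue
            ra, rb = rankdata(a), rankdata(b)
            rho = np.corrcoef(ra, rb)[0, 1]
            dist[i, j] = dist[j, i] = 1.0 - rho
    return pd.DataFrame(dist, index=samples, columns=samples)


def cluster_samples(
    gm: pd.DataFrame, k: int | None = None
) -> tuple[np.ndarray, list[str], np.ndarray | None]:
    """Ward.D2 hierarchical clustering on the Spearman distance matrix.

    Samples are ordered by id before clustering so the result is
    deterministic in input order.  Returns (linkage matrix, ordered
    sample ids, flat labels at ``k`` clusters or None).
    """
    if gm.shape[1] < 2 or gm.shape[0] < 2:
        raise ValueError("clustering needs >= 2 samples and >= 2 CNVRs")
    gm = gm[sorted(gm.columns)]
    dist = spearman_distance_matrix(gm)
    condensed = squareform(dist.to_numpy(), checks=False)
    Z = linkage(condensed, method="ward")  # ward on dissimilarities == ward.D2
    labels = fcluster(Z, t=k, criterion="maxclust") if k else None
    return Z, list(gm.columns), labels


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialise a scipy linkage matrix as a Newick string."""
    tree = to_tree(Z)

    def rec(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = rec(node.left), rec(node.right)
        dl = node.dist - node.left.dist
        dr = node.dist - node.right.dist
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return rec(tree) + ";"


def overlap_fraction(set_a: list[CNVR], set_b: list[CNVR]) -> float | None:
    """Fraction of regions in A sharing >= 1 bp with any region in B.

    Asymmetric; an empty A is not evaluable (None).
    """
    if not set_a:
        return None
    b_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in set_b:
        b_by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for chrom in b_by_chrom:
        b_by_chrom[chrom].sort()
    hits = 0
    for r in set_a:
        for s, e in b_by_chrom.get(r.chrom, ()):
            if s > r.end:
                break
            if e >= r.start:
                hits += 1
                break
    return hits / len(set_a)


def breed_specific(
    gm: pd.DataFrame, meta: pd.DataFrame, min_carriers: int = 2
) -> dict[str, list[str]]:
    """CNVRs carried by >= ``min_carriers`` samples of one breed and none of any other.

    A carrier has a non-CN2, non-CN_ genotype.
    """
    breed_of = meta.set_index("sample_id")["breed"]
    carriers = (gm != 2) & (gm != CN_UNKNOWN)
    out: dict[str, list[str]] = {b: [] for b in breed_of.unique()}
    sample_breeds = np.array([breed_of.get(s) for s in gm.columns])
    carr = carriers.to_numpy()
    for row, cnvr_id in enumerate(gm.index):
        breeds_here = set(sample_breeds[carr[row]])
        if len(breeds_here) != 1:
            continue
        (b,) = breeds_here
        if carr[row].sum() >= min_carriers:
            out[b].append(cnvr_id)
    return out


def density_by_chromosome(
    cnvrs: list[CNVR], layout: GenomeLayout
) -> pd.DataFrame:
    """Per-chromosome CNVR counts, category split, and CNVRs per Mb."""
    known = set(layout.chrom_names)
    for r in cnvrs:
        if r.chrom not in known:
            raise ValueError(f"CNVR {r.cnvr_id} on unknown chromosome {r.chrom!r}")
    rows = []
    for chrom in layout.chrom_names:
        mine = [r for r in cnvrs if r.chrom == chrom]
        mb = layout.lengths[chrom] / 1e6
        row = {
            "chrom": chrom,
            "n_cnvrs": len(mine),
            "DEL": sum(1 for r in mine if r.category == "DEL"),
            "AMP": sum(1 for r in mine if r.category == "AMP"),
            "MIX": sum(1 for r in mine if r.category == "MIX"),
            "per_mb": len(mine) / mb,
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    _, summary = merge_cnvr_sets([cnvrs], mode="union", layout=layout)
    df.attrs["nonredundant_bp"] = summary.total_bp
    df.attrs["pct_genome"] = summary.pct_genome
    return df
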