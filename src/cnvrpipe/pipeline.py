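"""End-to-end orchestration, one dataset at a time.

Batch effects make read-depth signals incomparable across sequencing
datasets, so every stage up to CNVR construction runs within a single
dataset; cross-dataset combination happens only at the final
merge/summary step.  Mixing samples of different datasets into one
calling/QC group is refused unless explicitly overridden.

A run manifest (JSON) records the configuration hash, seed, and
per-artifact checksums so a rerun with the same config and seed can be
verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings

import pandas as pd

from . import annotation as ann
from . import cnvr_builder, depth_caller, popgen_stats, report_db, sample_qc
from .core_io import (
    CNVR,
    PipelineConfig,
    read_cnv_calls,
    read_count_matrix,
    read_features_gff3,
    read_sample_meta,
    read_track,
    write_cnv_calls,
    write_cnvr_table,
    write_genotype_matrix,
)

__all__ = ["run_pipeline", "run_dataset", "cnvrs_from_tables"]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def cnvrs_from_tables(cnvr_df: pd.DataFrame, gm: pd.DataFrame) -> list[CNVR]:
    """Rebuild span/category/genotype CNVR objects from serialized tables.

    Member CNVs are not recoverable from the tables; stages that only
    need spans, categories, and genotypes (stats, annotation, report)
    work from these.
    """
    out = []
    for row in cnvr_df.itertuples():
        r = CNVR(
            cnvr_id=row.cnvr_id,
            chrom=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            category=row.category or None,
        )
        if row.cnvr_id in gm.index:
            r.genotypes = gm.loc[row.cnvr_id].to_dict()
        out.append(r)
    return out


def compute_stats(
    cnvrs: list[CNVR],
    gm: pd.DataFrame,
    meta: pd.DataFrame,
    config: PipelineConfig,
) -> dict:
    """HWE, parity, breed-specific lists, and sample clustering for one dataset."""
    from .core_io import CN_UNKNOWN

    hwe_results: dict[str, popgen_stats.HWEResult] = {}
    parity_results: dict[str, bool | None] = {}
    for r in cnvrs:
        counts = {g: c for g, c in r.genotype_counts().items() if g != CN_UNKNOWN}
        hwe_results[r.cnvr_id] = popgen_stats.hwe_test(
            counts, hwe_alpha=config.hwe_alpha, cnvr_id=r.cnvr_id
        )
        parity_results[r.cnvr_id] = popgen_stats.parity_test(counts)
    newick = None
    if gm.shape[0] >= 2 and gm.shape[1] >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Z, labels, _ = popgen_stats.cluster_samples(gm)
        newick = popgen_stats.linkage_to_newick(Z, labels)
    return {
        "hwe": hwe_results,
        "parity": parity_results,
        "newick": newick,
        "breed_specific": popgen_stats.breed_specific(gm, meta),
    }


def run_dataset(
    dataset_id: str,
    outdir: str,
    meta: pd.DataFrame,
    counts_path: str | None = None,
    calls_path: str | None = None,
    config: PipelineConfig = PipelineConfig(),
    tracks: dict[str, str] | None = None,
    seed: int = 0,
    build_report: bool = True,
) -> dict:
    """Run call -> qc -> cnvrs -> stats -> annotate -> report for one dataset."""
    os.makedirs(outdir, exist_ok=True)
    artifacts: dict[str, str] = {}
    norm = None
    if counts_path:
        matrix = read_count_matrix(counts_path)
        norm, _, _ = depth_caller.normalize_counts(matrix)
        wcn = depth_caller.estimate_window_cn(norm, alpha=config.alpha)
        calls = depth_caller.segment_calls(
            wcn, config.min_adjacent_windows, dataset_id=dataset_id
        )
        calls_file = os.path.join(outdir, "calls.tsv")
        write_cnv_calls(calls, calls_file)
        artifacts["calls"] = calls_file
    elif calls_path:
        calls = read_cnv_calls(calls_path, dataset_id=dataset_id)
    else:
        raise ValueError(f"dataset {dataset_id}: needs counts or calls")

    report = sample_qc.build_qc_report(
        calls,
        meta,
        norm_matrix=norm,
        iqr_multiplier=config.iqr_multiplier,
        k_mad=config.k_mad,
    )
    qc_file = os.path.join(outdir, "qc_report.csv")
    report.table.to_csv(qc_file, index=False)
    artifacts["qc_report"] = qc_file
    calls, meta, qc_log = sample_qc.apply_qc(calls, meta, report)

    cnvrs, gm, build_log = cnvr_builder.build_cnvrs(
        calls, list(meta["sample_id"]), config, id_prefix=f"{dataset_id}_cnvr"
    )
    cnvr_file = os.path.join(outdir, "cnvrs.csv")
    write_cnvr_table(cnvrs, cnvr_file)
    gm_file = os.path.join(outdir, "genotypes.csv")
    write_genotype_matrix(gm, gm_file)
    artifacts["cnvrs"] = cnvr_file
    artifacts["genotypes"] = gm_file

    stats = compute_stats(cnvrs, gm, meta, config)
    hwe_rows = [
        {
            "cnvr_id": h.cnvr_id,
            "qualifies": h.qualifies,
            "mapping": h.mapping or "",
            "reason": h.reason or "",
            "chi2": h.chi2,
            "p_value": h.p_value,
            "in_hwe": h.in_hwe,
        }
        for h in stats["hwe"].values()
    ]
    hwe_file = os.path.join(outdir, "hwe.csv")
    pd.DataFrame(hwe_rows).to_csv(hwe_file, index=False)
    artifacts["hwe"] = hwe_file
    parity_file = os.path.join(outdir, "parity.csv")
    pd.DataFrame(
        [{"cnvr_id": k, "parity_pass": v} for k, v in stats["parity"].items()]
    ).to_csv(parity_file, index=False)
    artifacts["parity"] = parity_file
    if stats["newick"]:
        nwk_file = os.path.join(outdir, "dendrogram.nwk")
        with open(nwk_file, "w") as fh:
            fh.write(stats["newick"] + "\n")
        artifacts["dendrogram"] = nwk_file

    overlap_df = None
    if tracks:
        records = []
        if "genes" in tracks:
            gene_track = read_features_gff3(tracks["genes"])
            records.extend(
                ann.annotate_genes(cnvrs, gene_track, flank=config.gene_flank)
            )
        bed_tracks = [
            read_track(path, kind)
            for kind, path in tracks.items()
            if kind != "genes"
        ]
        if bed_tracks:
            records.extend(ann.annotate_tracks(cnvrs, bed_tracks))
        overlap_df = ann.records_to_frame(records)
        ov_file = os.path.join(outdir, "overlaps.csv")
        overlap_df.to_csv(ov_file, index=False)
        artifacts["overlaps"] = ov_file

    if build_report:
        db_dir = os.path.join(outdir, "db")
        report_db.build_database(
            cnvrs,
            gm,
            meta,
            overlaps=overlap_df,
            hwe=stats["hwe"],
            parity=stats["parity"],
            counts=norm,
            outdir=db_dir,
            seed=seed,
            length_min=config.report_length_min,
            length_max=config.report_length_max,
            min_samples=config.report_min_samples,
            per_genotype_plot=config.samples_per_genotype_plot,
            dataset_id=dataset_id,
        )
        artifacts["db_index"] = os.path.join(db_dir, "index.html")

    return {
        "dataset_id": dataset_id,
        "cnvrs": cnvrs,
        "artifacts": artifacts,
        "qc_log": qc_log,
        "build_log": build_log,
    }


def run_pipeline(config: dict, outdir: str, allow_combined: bool = False) -> dict:
    """Run every configured dataset, then the cross-dataset merge summary.

    ``config`` is a plain dict (typically loaded from JSON): keys
    ``seed``, ``pipeline`` (PipelineConfig overrides), ``tracks``, and
    ``datasets`` — a list of {id, meta, counts | calls}.
    """
    os.makedirs(outdir, exist_ok=True)
    seed = int(config.get("seed", 0))
    pconf = PipelineConfig(**config.get("pipeline", {}), rng_seed=seed)
    tracks = config.get("tracks")
    results = []
    for ds in config["datasets"]:
        meta = read_sample_meta(ds["meta"])
        foreign = meta[meta["dataset_id"] != ds["id"]]
        if len(foreign):
            if not allow_combined:
                raise ValueError(
                    f"dataset {ds['id']}: metadata contains samples of other "
                    f"datasets ({sorted(foreign['dataset_id'].unique())}); "
                    "combining datasets in one calling/QC group is refused "
                    "because batch effects corrupt cross-dataset read-depth "
                    "comparison (pass allow_combined=True to override)"
                )
            warnings.warn(
                f"dataset {ds['id']}: combining samples across datasets; "
                "batch effects may skew genotype distributions",
                stacklevel=2,
            )
        results.append(
            run_dataset(
                ds["id"],
                os.path.join(outdir, ds["id"]),
                meta,
                counts_path=ds.get("counts"),
                calls_path=ds.get("calls"),
                config=pconf,
                tracks=tracks,
                seed=seed,
                build_report=config.get("build_report", True),
            )
        )
    sets = [r["cnvrs"] for r in results]
    union_df, union_summary = cnvr_builder.merge_cnvr_sets(sets, mode="union")
    uniq_df, uniq_summary = cnvr_builder.merge_cnvr_sets(sets, mode="unique_coords")
    merged_file = os.path.join(outdir, "merged_cnvrs.csv")
    union_df.to_csv(merged_file, index=False)

    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        "datasets": {
            r["dataset_id"]: {
                "qc": r["qc_log"],
                "cnvrs": r["build_log"],
                "checksums": {k: _sha256(v) for k, v in r["artifacts"].items()},
            }
            for r in results
        },
        "merged": {
            "nonredundant_regions": union_summary.n_regions,
            "nonredundant_bp": union_summary.total_bp,
            "unique_coordinate_cnvrs": uniq_summary.n_regions,
        },
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
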