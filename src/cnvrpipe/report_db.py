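"""Static, self-contained HTML CNVR database.

``build_database`` writes an index page (filter panel, summary
statistics, searchable CNVR/gene/sample tables, CSV exports) and one
detail page per CNVR (summary, genotype and breed distributions,
overlapping features, HWE/parity results, genome-browser URL, and
per-genotype window-depth plots).  Everything is rendered at build time
into plain HTML + vanilla JavaScript, loads from disk with no network
access, and all numbers shown are also embedded as machine-readable
JSON so they can be audited against direct recomputation.

Depth support at a CNVR is visualised from the window count matrix (up
to three seeded-randomly chosen samples per observed genotype), which
serves the same purpose as read-alignment screenshots: visual
verification that the depth signal supports the called genotype.
"""

from __future__ import annotations

import html
import json
import os
import re
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CN_UNKNOWN, CNVR, ReadCountMatrix, cn_to_str, write_cnvr_table
from .popgen_stats import HWEResult

__all__ = ["build_database", "plot_genotype_coverage", "filter_cnvrs", "db_statistics"]

_NCBI_URL = (
    "https://www.ncbi.nlm.nih.gov/genome/gdv/browser/genome/"
    "?context=genome&acc=GCF_000003055.6&chr={chrom}&from={start}&to={end}"
)

_CSS = """
body{font-family:sans-serif;margin:1.5em;max-width:1100px}
table{border-collapse:collapse;margin:0.8em 0}
th,td{border:1px solid #aaa;padding:0.25em 0.6em;font-size:0.9em}
th{background:#eee}
.panel{border:1px solid #ccc;border-radius:6px;padding:0.8em 1em;margin:1em 0}
.bar{background:#4a7fb5;display:inline-block;height:0.9em;vertical-align:middle}
.cat-DEL{color:#b03030}.cat-AMP{color:#2060a0}.cat-MIX{color:#707020}
input{margin:0.2em}
"""


def filter_cnvrs(
    cnvrs: list[CNVR],
    length_min: int = 1_000,
    length_max: int = 3_000_000,
    min_samples: int = 2,
    exclude_samples_pattern: str | None = None,
) -> list[CNVR]:
    """Apply the database's default-style filters to a CNVR list.

    ``exclude_samples_pattern`` is a regular expression; samples
    matching it are ignored when counting carriers.
    """
    pat = re.compile(exclude_samples_pattern) if exclude_samples_pattern else None
    out = []
    for r in cnvrs:
        if not (length_min <= r.length <= length_max):
            continue
        carriers = [
            s
            for s, g in r.genotypes.items()
            if g not in (2, CN_UNKNOWN) and not (pat and pat.search(s))
        ]
        if len(carriers) >= min_samples:
            out.append(r)
    return out


def db_statistics(cnvrs: list[CNVR]) -> dict:
    """Summary statistics for a CNVR set (used by the Statistics panel)."""
    if not cnvrs:
        return {"n_cnvrs": 0, "by_category": {}, "total_bp": 0, "mean_length": 0.0}
    return {
        "n_cnvrs": len(cnvrs),
        "by_category": {
            cat: sum(1 for r in cnvrs if r.category == cat)
            for cat in ("DEL", "AMP", "MIX")
        },
        "total_bp": int(sum(r.length for r in cnvrs)),
        "mean_length": float(np.mean([r.length for r in cnvrs])),
    }


def plot_genotype_coverage(
    cnvr: CNVR,
    counts: ReadCountMatrix,
    outdir: str,
    per_genotype: int = 3,
    seed: int = 0,
    flank_windows: int = 10,
    gaps: pd.DataFrame | None = None,
) -> list[str]:
    """Window-depth plots for up to ``per_genotype`` samples per genotype.

    Sample selection is seeded sampling without replacement, derived
    from (seed, cnvr_id) so the choice is stable per CNVR across runs.
    Returns the written image paths (relative to ``outdir``).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    windows = counts.windows
    on_chrom = windows["chrom"] == cnvr.chrom
    lo = cnvr.start - flank_windows * counts.layout.window_length
    hi = cnvr.end + flank_windows * counts.layout.window_length
    sel = np.nonzero(on_chrom & (windows["end"] >= lo) & (windows["start"] <= hi))[0]
    if sel.size == 0:
        return []
    rng = np.random.default_rng([seed, zlib.crc32(cnvr.cnvr_id.encode())])
    by_genotype: dict[int, list[str]] = {}
    for s, g in sorted(cnvr.genotypes.items()):
        if g not in (2, CN_UNKNOWN) and s in counts.sample_ids:
            by_genotype.setdefault(g, []).append(s)
    paths = []
    mids = (windows["start"].to_numpy()[sel] + windows["end"].to_numpy()[sel]) / 2
    for g in sorted(by_genotype):
        samples = by_genotype[g]
        if len(samples) > per_genotype:
            chosen = list(rng.choice(samples, per_genotype, replace=False))
        else:
            chosen = samples
        for s in chosen:
            j = counts.sample_ids.index(s)
            fig, ax = plt.subplots(figsize=(6, 2.2))
            ax.plot(mids / 1e6, counts.counts[sel, j], lw=0.8, color="#333")
            ax.axvline(cnvr.start / 1e6, color="#b03030", ls="--", lw=0.8)
            ax.axvline(cnvr.end / 1e6, color="#b03030", ls="--", lw=0.8)
            if gaps is not None:
                for _, gap in gaps.iterrows():
                    if gap["chrom"] == cnvr.chrom and gap["end"] >= lo and gap["start"] <= hi:
                        ax.axvspan(
                            gap["start"] / 1e6, gap["end"] / 1e6, color="#ccc", alpha=0.5
                        )
            ax.set_xlabel(f"{cnvr.chrom} position (Mb)")
            ax.set_ylabel("depth")
            ax.set_title(f"{cnvr.cnvr_id} {cn_to_str(g)} {s}", fontsize=9)
            fname = f"img/{cnvr.cnvr_id}_CN{g}_{s}.png"
            fig.savefig(os.path.join(outdir, fname), dpi=80, bbox_inches="tight")
            plt.close(fig)
            paths.append(fname)
    return paths


def _esc(x) -> str:
    return html.escape(str(x))


def _page(title: str, body: str, depth: int = 0) -> str:
    return (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>{_esc(title)}</title><style>{_CSS}</style></head>"
        f"<body>{body}</body></html>"
    )


def _bar_table(counts: dict[str, int], caption: str) -> str:
    if not counts:
        return f"<p>No data for {_esc(caption)}.</p>"
    peak = max(counts.values())
    rows = "".join(
        f"<tr><td>{_esc(k)}</td><td>{v}</td>"
        f"<td><span class='bar' style='width:{120 * v / peak:.0f}px'></span></td></tr>"
        for k, v in counts.items()
    )
    return (
        f"<table><caption>{_esc(caption)}</caption>"
        f"<tr><th>class</th><th>n</th><th></th></tr>{rows}</table>"
    )


def build_database(
    cnvrs: list[CNVR],
    genotype_matrix: pd.DataFrame,
    meta: pd.DataFrame,
    overlaps: pd.DataFrame | None = None,
    hwe: dict[str, HWEResult] | None = None,
    parity: dict[str, bool | None] | None = None,
    counts: ReadCountMatrix | None = None,
    outdir: str = "cnvr_db",
    seed: int = 0,
    length_min: int = 1_000,
    length_max: int = 3_000_000,
    min_samples: int = 2,
    per_genotype_plot: int = 3,
    dataset_id: str = "",
) -> dict:
    """Write the full static database; returns a manifest of written files.

    Depth plots are generated only when ``counts`` is given.  The index
    embeds pre-filter and default-filter statistics as JSON (element id
    ``db-stats``) in addition to rendering them.
    """
    os.makedirs(outdir, exist_ok=True)
    os.makedirs(os.path.join(outdir, "cnvr"), exist_ok=True)
    os.makedirs(os.path.join(outdir, "csv"), exist_ok=True)
    os.makedirs(os.path.join(outdir, "img"), exist_ok=True)
    manifest: dict[str, list[str]] = {"pages": [], "images": [], "csv": []}
    hwe = hwe or {}
    parity = parity or {}
    overlaps = overlaps if overlaps is not None else pd.DataFrame(
        columns=["cnvr_id", "feature_id", "feature_kind", "overlap_bp", "overlap_label"]
    )
    breed_of = meta.set_index("sample_id")["breed"].to_dict()

    filtered = filter_cnvrs(cnvrs, length_min, length_max, min_samples)
    stats = {
        "prefilter": db_statistics(cnvrs),
        "default_filter": db_statistics(filtered),
        "filters": {
            "length_min": length_min,
            "length_max": length_max,
            "min_samples": min_samples,
        },
    }

    # ---- CSV exports -------------------------------------------------
    if cnvrs:
        write_cnvr_table(cnvrs, os.path.join(outdir, "csv", "cnvrs.csv"))
        manifest["csv"].append("csv/cnvrs.csv")
    if not overlaps.empty:
        overlaps.to_csv(os.path.join(outdir, "csv", "overlaps.csv"), index=False)
        manifest["csv"].append("csv/overlaps.csv")
    meta.to_csv(os.path.join(outdir, "csv", "samples.csv"), index=False)
    manifest["csv"].append("csv/samples.csv")

    # ---- detail pages ------------------------------------------------
    for r in cnvrs:
        imgs: list[str] = []
        if counts is not None:
            imgs = plot_genotype_coverage(
                r, counts, outdir, per_genotype=per_genotype_plot, seed=seed
            )
            manifest["images"].extend(imgs)
        gcounts = {
            cn_to_str(g): c
            for g, c in sorted(r.genotype_counts().items(), key=lambda t: t[0])
            if g != 2
        }
        carriers = [s for s, g in r.genotypes.items() if g not in (2, CN_UNKNOWN)]
        bcounts: dict[str, int] = {}
        for s in carriers:
            b = breed_of.get(s, "?")
            bcounts[b] = bcounts.get(b, 0) + 1
        h = hwe.get(r.cnvr_id)
        p = parity.get(r.cnvr_id)
        ov = overlaps[overlaps["cnvr_id"] == r.cnvr_id] if not overlaps.empty else overlaps
        ov_rows = "".join(
            f"<tr><td>{_esc(x.feature_id)}</td><td>{_esc(x.feature_kind)}</td>"
            f"<td>{x.overlap_bp}</td><td>{_esc(x.overlap_label)}</td></tr>"
            for x in ov.itertuples()
        )
        hwe_txt = (
            f"qualifies ({h.mapping}); &chi;&sup2;={h.chi2:.3f}, "
            f"P={h.p_value:.3g}, {'in HWE' if h.in_hwe else 'NOT in HWE'}"
            if h and h.qualifies
            else (f"not tested ({h.reason})" if h else "not tested")
        )
        parity_txt = {True: "pass", False: "fail", None: "not evaluated"}.get(p, "not evaluated")
        sample_rows = "".join(
            f"<tr><td>{_esc(s)}</td><td>{_esc(breed_of.get(s, '?'))}</td>"
            f"<td>{cn_to_str(r.genotypes[s])}</td></tr>"
            for s in sorted(carriers)
        )
        img_html = "".join(f"<img src='../{i}' alt='{_esc(i)}'>" for i in imgs)
        url = _NCBI_URL.format(chrom=r.chrom, start=r.start, end=r.end)
        body = f"""
<h1>{_esc(r.cnvr_id)}</h1>
<p><a href='../index.html'>&larr; index</a></p>
<div class='panel'><h2>Summary</h2>
<table>
<tr><th>location</th><td>{_esc(r.chrom)}:{r.start:,}&ndash;{r.end:,}</td></tr>
<tr><th>length</th><td>{r.length:,} bp</td></tr>
<tr><th>category</th><td class='cat-{r.category}'>{_esc(r.category)}</td></tr>
<tr><th>samples with CNV</th><td>{r.n_samples}</td></tr>
<tr><th>member CNVs</th><td>{len(r.members)}</td></tr>
<tr><th>genome browser</th><td><a href='{url}'>NCBI Genome Data Viewer</a></td></tr>
</table></div>
<div class='panel'><h2>Genotype distribution</h2>{_bar_table(gcounts, 'genotypes (carriers)')}</div>
<div class='panel'><h2>Breed distribution</h2>{_bar_table(bcounts, 'carrier breeds')}</div>
<div class='panel'><h2>Tests</h2><p>HWE: {hwe_txt}<br>Parity: {parity_txt}</p></div>
<div class='panel'><h2>Overlapping features</h2>
<table><tr><th>feature</th><th>kind</th><th>bp</th><th>label</th></tr>{ov_rows or ''}</table></div>
<div class='panel'><h2>Samples</h2>
<table><tr><th>sample</th><th>breed</th><th>genotype</th></tr>{sample_rows}</table></div>
<div class='panel'><h2>Read-depth support</h2>{img_html or '<p>No count matrix supplied; plots omitted.</p>'}</div>
"""
        page_path = os.path.join(outdir, "cnvr", f"{r.cnvr_id}.html")
        with open(page_path, "w") as fh:
            fh.write(_page(r.cnvr_id, body))
        manifest["pages"].append(f"cnvr/{r.cnvr_id}.html")

    # ---- index page --------------------------------------------------
    if cnvrs:
        table_rows = "".join(
            f"<tr data-len='{r.length}' data-ns='{r.n_samples}'>"
            f"<td><a href='cnvr/{_esc(r.cnvr_id)}.html'>{_esc(r.cnvr_id)}</a></td>"
            f"<td>{_esc(r.chrom)}</td><td>{r.start:,}</td><td>{r.end:,}</td>"
            f"<td>{r.length:,}</td><td class='cat-{r.category}'>{_esc(r.category)}</td>"
            f"<td>{r.n_samples}</td></tr>"
            for r in sorted(cnvrs, key=lambda r: (r.chrom, r.start, r.end))
        )
        cnvr_table = (
            "<input id='search' placeholder='search (e.g. cds del)' size='30'>"
            "<table id='cnvrs'><tr><th>CNVR</th><th>chrom</th><th>start</th>"
            "<th>end</th><th>length</th><th>category</th><th>samples</th></tr>"
            f"{table_rows}</table>"
        )
        zero_state = ""
    else:
        cnvr_table = ""
        zero_state = "<p><strong>No CNVRs to display.</strong></p>"
    pre, post = stats["prefilter"], stats["default_filter"]
    ds_label = f" &mdash; dataset {_esc(dataset_id)}" if dataset_id else ""
    ov_gene = (
        overlaps[overlaps["feature_kind"].isin(["gene", "CDS", "UTR", "exon", "intron"])]
        if not overlaps.empty
        else overlaps
    )
    gene_rows = "".join(
        f"<tr><td><a href='cnvr/{_esc(x.cnvr_id)}.html'>{_esc(x.cnvr_id)}</a></td>"
        f"<td>{_esc(x.feature_id)}</td><td>{_esc(x.feature_kind)}</td>"
        f"<td>{x.overlap_bp}</td><td>{_esc(x.overlap_label)}</td></tr>"
        for x in ov_gene.itertuples()
    )
    sample_rows = "".join(
        f"<tr><td>{_esc(m['sample_id'])}</td><td>{_esc(m['breed'])}</td>"
        f"<td>{_esc(m['dataset_id'])}</td><td>{m['coverage']}</td></tr>"
        for _, m in meta.iterrows()
    )
    body = f"""
<h1>CNVR database{ds_label}</h1>
{zero_state}
<script id='db-stats' type='application/json'>{json.dumps(stats)}</script>
<div class='panel'><h2>Filters</h2>
<p>Defaults: length {length_min:,}&ndash;{length_max:,} bp; detected in &ge; {min_samples} samples.
Sample exclusion accepts regular-expression matches.</p>
<label>min length <input id='fmin' type='number' value='{length_min}'></label>
<label>max length <input id='fmax' type='number' value='{length_max}'></label>
<label>min samples <input id='fns' type='number' value='{min_samples}'></label>
<button onclick='applyFilters()'>apply</button>
<span id='fcount'></span></div>
<div class='panel'><h2>Statistics</h2>
<table><tr><th></th><th>all CNVRs</th><th>default filters</th></tr>
<tr><td>CNVRs</td><td>{pre['n_cnvrs']}</td><td>{post['n_cnvrs']}</td></tr>
<tr><td>DEL</td><td>{pre['by_category'].get('DEL', 0)}</td><td>{post['by_category'].get('DEL', 0)}</td></tr>
<tr><td>AMP</td><td>{pre['by_category'].get('AMP', 0)}</td><td>{post['by_category'].get('AMP', 0)}</td></tr>
<tr><td>MIX</td><td>{pre['by_category'].get('MIX', 0)}</td><td>{post['by_category'].get('MIX', 0)}</td></tr>
<tr><td>total bp</td><td>{pre['total_bp']:,}</td><td>{post['total_bp']:,}</td></tr>
</table></div>
<div class='panel'><h2>CNVRs</h2>{cnvr_table}</div>
<div class='panel'><h2>Overlapping genes</h2>
<input id='gsearch' placeholder='search (e.g. cds del)' size='30'>
<table id='genes'><tr><th>CNVR</th><th>feature</th><th>kind</th><th>bp</th><th>label</th></tr>{gene_rows}</table></div>
<div class='panel'><h2>Samples</h2>
<table><tr><th>sample</th><th>breed</th><th>dataset</th><th>coverage</th></tr>{sample_rows}</table></div>
<div class='panel'><h2>Exports</h2><ul>
{''.join(f"<li><a href='{p}'>{p}</a></li>" for p in manifest['csv'])}
</ul><button onclick='exportNotes()'>save filters/favourites as text</button></div>
<script>
function applyFilters() {{
  var lo = +document.getElementById('fmin').value,
      hi = +document.getElementById('fmax').value,
      ns = +document.getElementById('fns').value, n = 0;
  document.querySelectorAll('#cnvrs tr[data-len]').forEach(function (tr) {{
    var ok = +tr.dataset.len >= lo && +tr.dataset.len <= hi && +tr.dataset.ns >= ns;
    tr.style.display = ok ? '' : 'none'; if (ok) n++;
  }});
  document.getElementById('fcount').textContent = n + ' CNVRs pass';
}}
function hookSearch(inputId, tableId) {{
  var inp = document.getElementById(inputId);
  if (!inp) return;
  inp.addEventListener('input', function () {{
    var q = inp.value.toLowerCase();
    document.querySelectorAll('#' + tableId + ' tr').forEach(function (tr, i) {{
      if (i === 0) return;
      tr.style.display = tr.textContent.toLowerCase().indexOf(q) >= 0 ? '' : 'none';
    }});
  }});
}}
hookSearch('search', 'cnvrs'); hookSearch('gsearch', 'genes');
function exportNotes() {{
  var txt = 'filters: min=' + document.getElementById('fmin').value +
            ' max=' + document.getElementById('fmax').value +
            ' min_samples=' + document.getElementById('fns').value + '\\n';
  var a = document.createElement('a');
  a.href = 'data:text/plain;charset=utf-8,' + encodeURIComponent(txt);
  a.download = 'cnvr_db_notes.txt'; a.click();
}}
</script>
"""
    with open(os.path.join(outdir, "index.html"), "w") as fh:
        fh.write(_page("CNVR database", body))
    manifest["pages"].insert(0, "index.html")
    manifest["stats"] = stats
    return manifest
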