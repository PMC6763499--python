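"""Static HTML report over a results bundle.

Renders the bundle's TSV tables into one self-contained HTML page with
sortable tables, an optional 2-D scatter of an embedding colored by the
top-autocorrelated signature, and a signature-similarity clustering
(average-linkage hierarchical clustering on 1 - |Spearman r| of per-cell
scores) so related signatures appear together.
"""

from __future__ import annotations

import base64
import io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats

__all__ = ["cluster_signatures", "render_report"]

_TABLE_FILES = [
    ("Signature autocorrelation", "autocorrelation.tsv"),
    ("Numeric meta-data autocorrelation", "metadata_numeric.tsv"),
    ("Categorical meta-data association", "metadata_categorical.tsv"),
    ("Differential signatures (1-vs-all)", "differential.tsv"),
    ("Latent component annotations", "lc_annotations.tsv"),
    ("Dropped signatures", "dropped_signatures.tsv"),
]

_SORT_JS = """
function sortTable(t, col) {
  var rows = Array.from(t.tBodies[0].rows);
  var asc = t.dataset.asc !== 'true';
  t.dataset.asc = asc;
  rows.sort(function(a, b) {
    var x = a.cells[col].innerText, y = b.cells[col].innerText;
    var nx = parseFloat(x), ny = parseFloat(y);
    if (!isNaN(nx) && !isNaN(ny)) return asc ? nx - ny : ny - nx;
    return asc ? x.localeCompare(y) : y.localeCompare(x);
  });
  rows.forEach(function(r) { t.tBodies[0].appendChild(r); });
}
document.querySelectorAll('table.sortable th').forEach(function(th, i) {
  th.onclick = function() {
    var t = th.closest('table');
    sortTable(t, Array.from(th.parentNode.cells).indexOf(th));
  };
});
"""


def cluster_signatures(scores: pd.DataFrame, cut: float = 0.5) -> pd.DataFrame:
    """Group signatures by the absolute correlation of their score profiles.

    Distance is 1 - |Spearman r| between per-cell score vectors; clusters
    come from cutting an average-linkage dendrogram at ``cut``.
    """
    if len(scores) < 2:
        return pd.DataFrame({"signature": scores.index, "cluster": [0] * len(scores)})
    r = scipy.stats.spearmanr(scores.to_numpy().T).statistic
    r = np.atleast_2d(r)
    dist = 1.0 - np.abs(r)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    condensed = scipy.spatial.distance.squareform(dist, checks=False)
    link = scipy.cluster.hierarchy.linkage(condensed, method="average")
    labels = scipy.cluster.hierarchy.fcluster(link, t=cut, criterion="distance")
    return pd.DataFrame({"signature": scores.index, "cluster": labels - 1})


def _scatter_png(embedding: pd.DataFrame, color: np.ndarray | None, title: str) -> str:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4), dpi=110)
    sc = ax.scatter(
        embedding.iloc[:, 0], embedding.iloc[:, 1],
        c=color, cmap="viridis", s=6, linewidths=0,
    )
    if color is not None:
        fig.colorbar(sc, ax=ax, shrink=0.8)
    ax.set_title(title)
    ax.set_xticks([]), ax.set_yticks([])
    buf = io.BytesIO()
    fig.savefig(buf, format="png", bbox_inches="tight")
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode()


def render_report(
    bundle_dir: str | Path,
    output: str | Path | None = None,
    embedding: str | Path | None = None,
) -> Path:
    """Render ``bundle.json`` and its TSVs into one static HTML file.

    ``embedding`` may point to a cells x 2 TSV (e.g. a t-SNE/UMAP layout);
    when given, a scatter colored by the top-ranked signature's scores is
    embedded.  Missing bundle files are listed, not fatal.
    """
    bundle_dir = Path(bundle_dir)
    index_path = bundle_dir / "bundle.json"
    if not index_path.exists():
        raise FileNotFoundError(f"no bundle.json in {bundle_dir}")
    index = json.loads(index_path.read_text())
    output = Path(output) if output else bundle_dir / "report.html"

    parts = [
        "<!doctype html><html><head><meta charset='utf-8'>",
        "<title>scsig results</title>",
        "<style>body{font-family:sans-serif;margin:2em}table{border-collapse:collapse}"
        "th,td{border:1px solid #ccc;padding:3px 8px;font-size:13px}"
        "th{cursor:pointer;background:#eee}</style></head><body>",
        f"<h1>scsig results</h1><p>version {index.get('version')} · "
        f"seed {index.get('seed')} · {index.get('n_cells')} cells × "
        f"{index.get('n_genes')} genes · K={index.get('k')}</p>",
    ]

    missing = []
    scores_path = bundle_dir / "scores.tsv"
    scores = None
    if scores_path.exists():
        scores = pd.read_csv(scores_path, sep="\t", index_col=0)
        if "signature" in scores.columns:
            scores = scores.drop(columns=["signature"])
    else:
        missing.append("scores.tsv")

    if embedding is not None and scores is not None:
        emb = pd.read_csv(embedding, sep="\t", index_col=0)
        auto_path = bundle_dir / "autocorrelation.tsv"
        color, title = None, "embedding"
        if auto_path.exists():
            auto = pd.read_csv(auto_path, sep="\t").sort_values("c_prime", ascending=False)
            top = auto.iloc[0]["signature"]
            if top in scores.index:
                color = scores.loc[top].to_numpy()
                title = f"top signature: {top}"
        png = _scatter_png(emb, color, title)
        parts.append(f"<h2>Embedding</h2><img src='data:image/png;base64,{png}'>")

    if scores is not None and len(scores) >= 2:
        clusters = cluster_signatures(scores)
        parts.append("<h2>Signature clusters</h2>")
        parts.append(
            clusters.to_html(index=False, classes="sortable", border=0)
        )

    for title, fname in _TABLE_FILES:
        path = bundle_dir / fname
        if not path.exists():
            if fname in index.get("files", []):
                missing.append(fname)
            continue
        df = pd.read_csv(path, sep="\t")
        parts.append(f"<h2>{title}</h2>")
        parts.append(df.to_html(index=False, classes="sortable", border=0, na_rep=""))

    if missing:
        parts.append("<h2>Missing files</h2><ul>")
        parts.extend(f"<li>{m}</li>" for m in missing)
        parts.append("</ul>")
    parts.append(f"<script>{_SORT_JS}</script></body></html>")
    output.write_text("\n".join(parts))
    return output
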