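"""The whole pipeline from files on disk, plus the static HTML report.

Writes a synthetic dataset in the tool's input formats (expression TSV,
GMT signatures, meta-data TSV), runs the configured analysis end to end,
and renders the results bundle to a single self-contained HTML page.
Equivalent CLI:  scsig simulate d/  &&  scsig run config.yaml  &&
scsig report out/
"""

import json
import tempfile
from pathlib import Path

from scsig import (
    PlantedSignature,
    RunConfig,
    SyntheticSpec,
    make_clustered_dataset,
    render_report,
    run,
    write_expression,
    write_metadata,
    write_signatures,
)

workdir = Path(tempfile.mkdtemp())
spec = SyntheticSpec(
    n_cells=300,
    n_genes=400,
    n_clusters=2,
    planted_signatures=[PlantedSignature("planted", 30, (0,), 1.5)],
    seed=4,
)
counts, meta, sigs = make_clustered_dataset(spec)
write_expression(counts, workdir / "counts.tsv")
write_metadata(meta, workdir / "meta.tsv")
write_signatures(sigs, workdir / "sigs.gmt")

config = RunConfig(
    expression=str(workdir / "counts.tsv"),
    signatures=str(workdir / "sigs.gmt"),
    metadata=str(workdir / "meta.tsv"),
    output_dir=str(workdir / "out"),
    n_backgrounds=100,
    n_permutations=100,
    differential_by="cluster",
    lc_annotate=True,
    seed=4,
)
index = run(config)
print("bundle files:", ", ".join(index["files"]))

report = render_report(workdir / "out")
print(f"report: {report} ({report.stat().st_size // 1024} kB, self-contained HTML)")
print(json.dumps({k: index[k] for k in ("n_cells", "n_genes", "k", "seed")}, indent=1))
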