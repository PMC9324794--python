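"""Reading a multilayer network from disk and writing detection results.

Writes two small TSV edge lists and a manifest to a temporary directory,
loads them back as a multilayer network, runs the detection and writes the
per-layer matchings, control paths and JSON summary.
"""

import json
import tempfile
from pathlib import Path

from copath import read_multilayer, run_copath, write_result

with tempfile.TemporaryDirectory() as tmp:
    d = Path(tmp)
    (d / "a.tsv").write_text("1\t2\n2\t3\n2\t4\n2\t5\n4\t5\n")
    (d / "b.tsv").write_text("1\t2\n2\t3\n4\t5\n")
    (d / "manifest.txt").write_text("a: a.tsv\nb: b.tsv\n")

    net = read_multilayer(d / "manifest.txt")
    print("layers:", net.layer_ids,
          "sizes:", [(l.n_nodes, l.n_edges) for l in net.layers])

    result = run_copath(net)
    files = write_result(result, d / "out")
    print("wrote:", sorted(Path(f).name for f in files))
    summary = json.loads((d / "out" / "summary.json").read_text())
    print(f"CV = {summary['cv']:.4f}, |chi| = {summary['chi_size']}")
    print("paths (layer a):", (d / "out" / "a.paths.txt").read_text().split())
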