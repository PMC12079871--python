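"""End-to-end run: panel CSV in, full report directory out.

Writes a synthetic panel to CSV, loads it back through the validating
reader, runs the complete analysis (descriptives, paired tests, transform,
network, centrality, bootstrap, stability, clinical-cutoff subgroups), and
exports every table plus GraphML and a JSON master report.

Equivalent shell usage:
    clpn simulate --n 1200 --seed 9 --out panel.csv
    clpn run --data panel.csv --out results/ --seed 9
"""

import tempfile
from pathlib import Path

from clpnet import (AnalysisConfig, default_nodes, default_spec,
                    generate_panel, load_panel, run_full_analysis,
                    write_panel)
from clpnet.pipeline import export_report

workdir = Path(tempfile.mkdtemp())
csv_path = workdir / "panel.csv"
write_panel(generate_panel(default_spec(1200, seed=9), seed=9), csv_path)

dataset = load_panel(csv_path, default_nodes())
config = AnalysisConfig(cv_folds=5, lambda_grid_size=30, n_boot=30,
                        n_drop_boot=10, drop_proportions=(0.1, 0.3),
                        seed=9)
report = run_full_analysis(dataset, config)

print(f"retained edges: {report.edge_summary['n_edges']} "
      f"({report.edge_summary['percent_positive']}% positive)")
if report.stability is not None:
    print(f"CS coefficients: { {k: round(v, 2) for k, v in report.stability.cs.items()} }")
if report.subgroups is not None:
    print(f"subgroups at cutoff {report.subgroups.cutoff:g}: "
          f"high n={report.subgroups.n_high}, low n={report.subgroups.n_low}")

manifest = export_report(report, workdir / "results")
print(f"\nwrote {len(manifest)} artifacts to {workdir / 'results'}:")
for name in sorted(manifest):
    print(f"  {name}")
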