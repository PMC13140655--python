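"""End-to-end run: synthetic cohort -> networks -> similarities -> stats.

Writes a small cohort to disk, runs the full pipeline from its manifest
and prints where each output landed.  (Three participants keep the demo
fast; the default study design uses twelve.)
"""

import json
import tempfile
from pathlib import Path

from breathnet import CohortSpec, PipelineConfig, generate_cohort, run_pipeline
from breathnet.io import write_cohort

workdir = Path(tempfile.mkdtemp(prefix="breathnet_demo_"))
cohort = generate_cohort(CohortSpec(n_participants=3, seed=8))
manifest = write_cohort(cohort, workdir / "cohort")

cfg = PipelineConfig(seed=9, output_dir=str(workdir / "out"))
result = run_pipeline(cfg, manifest_path=manifest)

print(f"{len(result.networks)} participant networks, "
      f"{len(result.group_networks)} group median networks, "
      f"{len(result.failures)} failures")
print("rest-exercise WJSI means:",
      result.similarity[["rest_ex_CTR", "rest_ex_HY1", "rest_ex_HY2"]]
      .mean().round(3).to_dict())
report = json.loads((workdir / "out" / "stats.json").read_text())
print("statistics sections:", sorted(report))
print("outputs under:", workdir / "out")
# The similarity table, rankings, group networks (CSV/JSON/GraphML) and
# the statistics report are all plain-text files under the output dir.
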