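"""Run the whole pipeline in one call and inspect the run directory.

Equivalent to `dfncpm run-all --simulate --seed 42 --out runs/demo` on the
command line; every stage writes its artifacts under the output directory.
"""

import dataclasses
import json
from pathlib import Path
from tempfile import mkdtemp

from dfncpm import ClassificationProtocol, MiningSpec, PipelineConfig, run_pipeline

cfg = PipelineConfig(
    seed=42,
    mining=MiningSpec(max_length=5),
    # 100 CV repeats in full runs; reduced here so the demo finishes fast
    protocol=ClassificationProtocol(cv_repeats=10, seed=42),
)
rundir = run_pipeline(cfg, Path(mkdtemp()) / "demo")

print("artifacts:")
for path in sorted(rundir.rglob("*")):
    if path.is_file():
        print("  ", path.relative_to(rundir))

dpm = json.loads((rundir / "patterns" / "dpm_result.json").read_text())
print("pattern partition:", dpm["venn"])
print((rundir / "summary.md").read_text())
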