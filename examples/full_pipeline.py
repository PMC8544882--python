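"""The whole measurement-to-inference chain in four stages.

simulate (synthetic raw tables) -> derive (skeletal/assay/morphometric
tables) -> analyze (ANOVA, contrasts, PCA, regressions) -> report
(Markdown rendering of the machine-readable outputs).

Equivalent shell commands:
    coralith simulate --outdir raw --seed 1
    coralith derive   --data-dir raw --outdir derived
    coralith analyze  --data-dir derived --outdir analysis --seed 1
    coralith report   --data-dir analysis --outdir analysis
"""

import tempfile
from pathlib import Path

from coralith import PipelineConfig, run_analysis, run_derive, run_report, run_simulate

with tempfile.TemporaryDirectory() as tmp:
    root = Path(tmp)
    run_simulate(PipelineConfig(outdir=str(root / "raw"), seed=1))
    run_derive(PipelineConfig(data_dir=str(root / "raw"), outdir=str(root / "derived")))
    run_analysis(PipelineConfig(data_dir=str(root / "derived"),
                                outdir=str(root / "analysis"), seed=1))
    run_report(PipelineConfig(data_dir=str(root / "analysis"),
                              outdir=str(root / "analysis")))
    print((root / "analysis" / "report.md").read_text())
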