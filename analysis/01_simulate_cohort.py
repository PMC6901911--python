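#!/usr/bin/env python
"""Simulate the study cohort: 117 subjects (98 group A + 19 group B) of
paired pseudo-T2W/pseudo-ADC volumes with contoured DIL and mirrored NT
masks, written as NIfTI files plus a subjects.csv manifest.

Output: results/pipeline/cohort/
"""

import json

from dilradiomics.pipeline import PipelineConfig, run_stage

if __name__ == "__main__":
    config = PipelineConfig(workdir="results/pipeline", seed=42)
    summary = run_stage("simulate", config)
    print("simulated cohort:", json.dumps(summary))
    print("volumes + masks under", f"{config.workdir}/cohort/")
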