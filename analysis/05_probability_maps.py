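#!/usr/bin/env python
"""Sliding-window (25x25) DIL probability maps for two held-out group-B
subjects: each window is harmonized, featurized, projected through the
frozen PLSC model and scored by the trained network; the thresholded
patch is compared with the true DIL contour by Dice.

Outputs: results/pipeline/{<subject>_probmap.nii.gz, dice_report.csv}
"""

import json

from dilradiomics.pipeline import PipelineConfig, run_stage

if __name__ == "__main__":
    config = PipelineConfig(workdir="results/pipeline", seed=42)
    summary = run_stage("map", config)
    print("probability maps:", json.dumps(summary, indent=2))
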