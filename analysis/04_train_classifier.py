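#!/usr/bin/env python
"""Train and validate the 8:5:1 MLP on the selected latent variables:
subject-level LOOCV (strategy 1, with CCF-vs-epoch stopping analysis)
followed by 100 stratified 67/33 splits (strategy 2) and the
train-on-A / test-on-B cross-cohort evaluation.

Outputs: results/pipeline/{ann_model.npz, ccf_curve.csv, metrics.csv,
train_summary.json, evaluate_summary.json}
"""

import json

from dilradiomics.pipeline import PipelineConfig, run_stage

if __name__ == "__main__":
    config = PipelineConfig(workdir="results/pipeline", seed=42)
    train = run_stage("train", config)
    print("strategy 1 (LOOCV):", json.dumps(train, indent=2))
    evaluate = run_stage("evaluate", config)
    print("strategy 2 + cross-cohort:", json.dumps(evaluate, indent=2))
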