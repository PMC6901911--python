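#!/usr/bin/env python
"""Harmonize every volume by its subject's NT-mask mean and extract the
168-feature radiomics descriptor per ROI per modality (468 rows:
117 subjects x {DIL, NT} x {T2W, ADC}).

Output: results/pipeline/features.csv (+ extraction settings sidecar)
"""

import json

from dilradiomics.pipeline import PipelineConfig, run_stage

if __name__ == "__main__":
    config = PipelineConfig(workdir="results/pipeline", seed=42)
    summary = run_stage("extract", config)
    print("extracted features:", json.dumps(summary))
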