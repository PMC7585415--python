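#!/usr/bin/env python
"""Generate the synthetic recording library.

Mechanism-mode TEVC-like recordings (60 s of 10 mM agonist, 500 Hz,
100 Hz low-pass, 20,000 channels) for wild type and the SU3/SU4/SU5
mutant combinations under the reference model III parameterization.
Traces and a batch manifest go to results/recordings/.
"""

import json
from pathlib import Path

from gabakin.io import write_json, write_trace
from gabakin.params import ModelVariant
from gabakin.scheme import build_scheme
from gabakin.synth import (
    REFERENCE_MULTIPLIERS,
    REFERENCE_PARAMS_III,
    RecordingConfig,
    generate_trace,
)

OUT = Path("results/recordings")
OUT.mkdir(parents=True, exist_ok=True)

CONSTRUCTS = ("CWT", "C3", "C4", "C5", "C34", "C35", "C45", "C345")
BASE_SEED = 20260930

manifest = []
for k, construct in enumerate(CONSTRUCTS):
    profile = REFERENCE_MULTIPLIERS.profile_for(construct)
    scheme = build_scheme(ModelVariant.III, REFERENCE_PARAMS_III, profile)
    config = RecordingConfig(seed=BASE_SEED + k)
    trace, truth = generate_trace(scheme, config)
    path = OUT / f"{construct}.tsv"
    write_trace(path, trace, {"construct": construct, "seed": config.seed})
    write_json(path.with_suffix(".truth.json"), truth)  # ground-truth sidecar
    manifest.append({"construct": construct, "file": path.name, "seed": config.seed,
                     "application_window_s": truth["application_window_s"]})
    peak = abs(trace.current).max()
    print(f"{construct:6s} -> {path.name}  (peak {peak:.0f} channel units)")

(OUT / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
print(f"\n{len(manifest)} recordings and manifest written to {OUT}/")
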