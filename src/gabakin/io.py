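"""Plain-text serialization: traces, model configs, reports.

Traces travel as two-column delimited text (time_s, current) with
``#key=value`` comment headers carrying provenance (config hash, seed).
Model definitions round-trip through YAML; calibration reports through
JSON.  No binary formats.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import yaml

from .params import (
    ConcertedFactors,
    ModelVariant,
    MutationProfile,
    RateParameters,
)
from .simulate import CurrentTrace
from .states import SubunitID


def run_hash(obj) -> str:
    """Short deterministic hash of any JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Traces

def write_trace(path: str | Path, trace: CurrentTrace, metadata: Dict | None = None) -> None:
    path = Path(path)
    lines = []
    meta = dict(metadata or {})
    meta.setdefault("n_channels", trace.n_channels)
    meta.setdefault("unitary_current", trace.unitary_current)
    for key in sorted(meta):
        lines.append(f"#{key}={meta[key]}")
    lines.append("time_s\tcurrent")
    for t, c in zip(trace.times, trace.current):
        lines.append(f"{t:.6f}\t{c:.8g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_trace(path: str | Path) -> Tuple[CurrentTrace, Dict[str, str]]:
    path = Path(path)
    meta: Dict[str, str] = {}
    times, current = [], []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, value = line[1:].partition("=")
                    meta[key] = value
                continue
            if line.startswith("time"):
                continue
            t, c = line.split("\t")
            times.append(float(t))
            current.append(float(c))
    if not times:
        raise ValueError(f"no samples in trace file {path}")
    return (
        CurrentTrace(
            times=np.asarray(times),
            current=np.asarray(current),
            n_channels=int(float(meta.get("n_channels", 0))),
            unitary_current=float(meta.get("unitary_current", -1.0)),
        ),
        meta,
    )


# ---------------------------------------------------------------------------
# Model configuration (YAML)

def model_config_dict(
    variant: ModelVariant,
    params: RateParameters,
    profile: MutationProfile,
    agonist_conc: float,
) -> Dict:
    return {
        "variant": variant.value,
        "agonist_conc_M": agonist_conc,
        "rates": asdict(params),
        "mutation": {
            "mutated": sorted(s.name for s in profile.mutated),
            "multipliers": {
                k: getattr(profile, k)
                for k in (
                    "c3_plus", "c3_minus", "c4_plus", "c4_minus",
                    "c5_plus", "c5_minus", "c34_plus", "c34_minus",
                )
            },
            "concerted_factors": {
                su.name: asdict(fac) for su, fac in profile.concerted_factors.items()
            },
        },
    }


def save_model_config(
    path: str | Path,
    variant: ModelVariant,
    params: RateParameters,
    profile: MutationProfile = MutationProfile(),
    agonist_conc: float = 0.01,
) -> None:
    cfg = model_config_dict(variant, params, profile, agonist_conc)
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True), encoding="utf-8")


def load_model_config(
    path: str | Path,
) -> Tuple[ModelVariant, RateParameters, MutationProfile, float]:
    cfg = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    variant = ModelVariant(cfg["variant"])
    params = RateParameters(**cfg["rates"])
    mut = cfg.get("mutation", {})
    profile = MutationProfile(
        mutated=frozenset(SubunitID[name] for name in mut.get("mutated", [])),
        concerted_factors={
            SubunitID[name]: ConcertedFactors(**fac)
            for name, fac in mut.get("concerted_factors", {}).items()
        },
        **mut.get("multipliers", {}),
    )
    return variant, params, profile, float(cfg.get("agonist_conc_M", 0.01))


# ---------------------------------------------------------------------------
# Reports

def observables_frame(observables: Dict[str, "DesensObservables"]):
    """Per-construct observables table (pandas DataFrame)."""
    import pandas as pd

    rows = []
    for construct, obs in observables.items():
        rows.append(
            {
                "construct": construct,
                "tau_fast_s": obs.tau_fast,
                "tau_slow_s": obs.tau_slow,
                "pct_A_fast": obs.pct_A_fast,
                "pct_I_res": obs.pct_I_res,
                "tau_w_s": obs.tau_w,
            }
        )
    return pd.DataFrame(rows)


def write_json(path: str | Path, payload: Dict) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_default) + "\n",
        encoding="utf-8",
    )
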