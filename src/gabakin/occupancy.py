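"""State-occupancy time courses and the kinetically favored pathway.

During a sustained agonist application the receptor population drains
from the active (conducting) states into the desensitized layer.  This
module reports the per-state occupancies over time and extracts the
dominant desensitization route as a greedy maximum-cumulative-flux walk
from the fully open state to the terminal all-desensitized state; the
cumulative flux of an edge is the integral of rate times source
occupancy over the application.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .scheme import KineticScheme
from .simulate import AgonistProtocol, OccupancyTrajectory, propagate
from .states import StateTag

#: Relative tolerance under which two competing edge fluxes count as tied.
TIE_RTOL = 1e-9


@dataclass
class PathwayReport:
    """Dominant desensitization pathway and its flux bookkeeping.

    ``steps`` lists the visited state labels from AO to the terminal
    state; where two outgoing edges tie (symmetric subunits), each step
    holds every co-dominant choice and the walk continues from the
    canonically first one.  ``edge_fluxes`` holds the cumulative flux of
    every desensitization-layer edge; ``peak_occupancy`` the maximum of
    each gated state's occupancy and its time.
    """

    steps: List[Tuple[str, ...]] = field(default_factory=list)
    edge_fluxes: Dict[Tuple[str, str], float] = field(default_factory=dict)
    peak_occupancy: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    @property
    def path_labels(self) -> List[str]:
        """The walked path, first co-dominant label at each step."""
        return [step[0] for step in self.steps]


def occupancy_timecourses(
    scheme: KineticScheme, protocol: AgonistProtocol = AgonistProtocol()
) -> Tuple[OccupancyTrajectory, np.ndarray]:
    """All gated-state occupancies plus the summed conducting occupancy.

    Returns the full trajectory (every state, one column per state, in
    scheme order) and the active-population trace — the summed occupancy
    of the conducting states, the quantity a macroscopic recording sees.
    """
    traj = propagate(scheme, protocol)
    active = traj.probabilities[:, scheme.conducting_mask].sum(axis=1)
    return traj, active


def _desens_edges(scheme: KineticScheme) -> List[Tuple[int, int]]:
    """Index pairs of desensitization-layer transitions (gated -> gated)."""
    out = []
    for tr in scheme.transitions:
        a, b = scheme.states[tr.source], scheme.states[tr.target]
        if a.tag is StateTag.GATED and b.tag is StateTag.GATED:
            out.append((tr.source, tr.target))
    return out


def dominant_pathway(
    scheme: KineticScheme,
    protocol: AgonistProtocol = AgonistProtocol(),
    traj: OccupancyTrajectory | None = None,
) -> PathwayReport:
    """Greedy maximum-cumulative-flux walk from AO to the terminal state.

    At each visited state the walk follows the outgoing desensitization
    edge (one more subunit desensitized) with the largest cumulative flux;
    exact ties — symmetric subunits — are reported as co-dominant rather
    than silently broken.  The walk ends when no outgoing desensitization
    edge carries flux.
    """
    if traj is None:
        traj = propagate(scheme, protocol)
    q = scheme.generator
    fluxes: Dict[Tuple[int, int], float] = {}
    for i, j in _desens_edges(scheme):
        fluxes[(i, j)] = float(
            np.trapezoid(q[i, j] * traj.probabilities[:, i], traj.times)
        )

    report = PathwayReport()
    for idx, state in enumerate(scheme.states):
        if state.tag is StateTag.GATED:
            col = traj.probabilities[:, idx]
            k = int(np.argmax(col))
            report.peak_occupancy[state.label] = (float(traj.times[k]), float(col[k]))
    report.edge_fluxes = {
        (scheme.states[i].label, scheme.states[j].label): f
        for (i, j), f in fluxes.items()
    }

    current = scheme.state_index("AO")
    report.steps.append((scheme.states[current].label,))
    visited = {current}
    while True:
        candidates = [
            (j, f)
            for (i, j), f in fluxes.items()
            if i == current
            and j not in visited
            and len(scheme.states[j].pattern) > len(scheme.states[current].pattern)
        ]
        if not candidates:
            break
        best_flux = max(f for _, f in candidates)
        if best_flux <= 0:
            break
        tied = sorted(
            j for j, f in candidates
            if abs(f - best_flux) <= TIE_RTOL * best_flux
        )
        report.steps.append(tuple(scheme.states[j].label for j in tied))
        current = tied[0]
        visited.add(current)
    return report


def occupancy_table(scheme: KineticScheme, traj: OccupancyTrajectory):
    """Time-by-state occupancy table (pandas DataFrame) for export."""
    import pandas as pd

    df = pd.DataFrame(traj.probabilities, columns=scheme.labels)
    df.insert(0, "time_s", traj.times)
    return df
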