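"""Master-equation propagation and macroscopic-current synthesis.

Occupancies evolve as dp/dt = p Q under the piecewise-constant generator
of an agonist protocol.  For a constant generator the propagation is exact
(matrix exponential, evaluated through the eigendecomposition of Q, with
an expm-stepping fallback for ill-conditioned eigenbases).  Macroscopic
current is conducting occupancy times channel count times unitary
current; finite-channel (binomial) noise is available for synthetic
recordings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy.linalg import expm

from .scheme import KineticScheme


@dataclass(frozen=True)
class AgonistProtocol:
    """Sequence of agonist-application segments.

    ``segments`` are (duration s, concentration molar) pairs applied in
    order, starting from the all-resting receptor.  ``exchange_tau`` > 0
    emulates finite solution exchange: at each segment boundary the
    concentration relaxes exponentially towards the new level instead of
    stepping.  The default is the study protocol, a 60 s ideal step of
    10 mM agonist sampled at 500 Hz (dt = 2 ms).
    """

    segments: Tuple[Tuple[float, float], ...] = ((60.0, 0.01),)
    exchange_tau: float = 0.0
    dt: float = 0.002

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        for dur, conc in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be positive")
            if conc < 0:
                raise ValueError("concentrations must be nonnegative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.exchange_tau < 0:
            raise ValueError("exchange_tau must be >= 0")

    @property
    def duration_total(self) -> float:
        return sum(dur for dur, _ in self.segments)


@dataclass
class OccupancyTrajectory:
    """Per-state occupancy probabilities on a common time grid."""

    times: np.ndarray
    probabilities: np.ndarray  # shape (n_times, n_states)
    labels: List[str] = field(default_factory=list)

    def state(self, label: str) -> np.ndarray:
        return self.probabilities[:, self.labels.index(label)]


@dataclass
class CurrentTrace:
    """Uniformly sampled macroscopic current (inward currents negative)."""

    times: np.ndarray
    current: np.ndarray
    n_channels: int = 0
    unitary_current: float = -1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.times.shape != self.current.shape:
            raise ValueError("times and current must have matching lengths")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0


def _eig_propagator(q: np.ndarray):
    """Return f(p0, times) -> occupancies, or None if Q is ill-conditioned."""
    lam, v = np.linalg.eig(q.T)
    cond = np.linalg.cond(v)
    if not np.isfinite(cond) or cond > 1e10:
        return None
    vinv = np.linalg.inv(v)

    def run(p0: np.ndarray, times: np.ndarray) -> np.ndarray:
        w = vinv @ p0  # spectral weights of the column vector p^T
        phases = np.exp(np.multiply.outer(times, lam))  # (n_t, n_s)
        out = np.real(phases * w @ v.T)
        return out

    return run


def _expm_step_run(q: np.ndarray, p0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Fallback: exact stepping with expm over the (near-uniform) grid."""
    out = np.empty((len(times), len(p0)))
    prev_t = times[0]
    p = p0 @ expm(q * prev_t) if prev_t > 0 else p0.copy()
    out[0] = p
    step_cache: dict[float, np.ndarray] = {}
    for k in range(1, len(times)):
        h = round(times[k] - prev_t, 12)
        if h not in step_cache:
            step_cache[h] = expm(q * h)
        p = p @ step_cache[h]
        out[k] = p
        prev_t = times[k]
    return out


def occupancies_at(
    scheme: KineticScheme,
    times: np.ndarray,
    p0: np.ndarray | None = None,
    agonist_conc: float | None = None,
) -> np.ndarray:
    """Occupancies at arbitrary times under a constant generator.

    Exact for any time grid (no discretization error); used both by
    :func:`propagate` and by the calibration fast path, which samples a
    non-uniform grid.
    """
    q = scheme.generator if agonist_conc is None else scheme.generator_at(agonist_conc)
    if not np.all(np.isfinite(q)):
        raise ValueError("generator contains non-finite entries")
    if p0 is None:
        p0 = np.zeros(scheme.n_states)
        p0[scheme.state_index("R")] = 1.0
    times = np.asarray(times, dtype=float)
    run = _eig_propagator(q)
    if run is not None:
        probs = run(p0, times)
    else:  # pragma: no cover - degenerate eigenbasis
        probs = _expm_step_run(q, p0, times)
    # Clip the tiny negative round-off without disturbing normalization.
    np.clip(probs, 0.0, None, out=probs)
    probs /= probs.sum(axis=1, keepdims=True)
    return probs


def propagate(scheme: KineticScheme, protocol: AgonistProtocol) -> OccupancyTrajectory:
    """Propagate the master equation from the all-resting state.

    The generator is rebuilt whenever the segment concentration changes.
    With ``exchange_tau`` > 0 the concentration approaches each segment's
    level exponentially and the generator is resampled every ``dt`` until
    the exchange has converged; the ideal-step branches are exact.
    """
    q_ref = scheme.generator
    if not np.all(np.isfinite(q_ref)):
        raise ValueError("generator contains non-finite entries")
    max_exit = float(np.max(-np.diag(q_ref)))
    if max_exit > 0 and protocol.dt > 1.0 / max_exit:
        warnings.warn(
            f"dt = {protocol.dt} s exceeds the fastest relaxation time "
            f"{1.0 / max_exit:.2e} s; sampled occupancies may miss fast transients",
            stacklevel=2,
        )

    dt = protocol.dt
    n_total = int(round(protocol.duration_total / dt))
    times = np.arange(n_total + 1) * dt
    probs = np.empty((n_total + 1, scheme.n_states))
    p = np.zeros(scheme.n_states)
    p[scheme.state_index("R")] = 1.0
    probs[0] = p

    k = 0  # index of the last filled row
    t_seg_start = 0.0
    conc_prev = 0.0
    for dur, conc in protocol.segments:
        k_end = int(round((t_seg_start + dur) / dt))
        if protocol.exchange_tau > 0 and conc != conc_prev:
            # Resample the concentration along the exponential approach.
            tau = protocol.exchange_tau
            n_exch = min(k_end - k, int(np.ceil(12.0 * tau / dt)))
            for i in range(n_exch):
                t_mid = (i + 0.5) * dt
                c_now = conc + (conc_prev - conc) * np.exp(-t_mid / tau)
                p = p @ expm(scheme.generator_at(c_now) * dt)
                probs[k + 1 + i] = p
            k += n_exch
        if k < k_end:
            sub_times = times[k : k_end + 1] - times[k]
            seg = occupancies_at(scheme, sub_times, p0=p, agonist_conc=conc)
            probs[k : k_end + 1] = seg
            p = probs[k_end]
        k = k_end
        t_seg_start += dur
        conc_prev = conc

    np.clip(probs, 0.0, None, out=probs)
    probs /= probs.sum(axis=1, keepdims=True)
    return OccupancyTrajectory(times=times, probabilities=probs, labels=scheme.labels)


def current_from_occupancy(
    traj: OccupancyTrajectory,
    scheme: KineticScheme,
    n_channels: int = 20_000,
    unitary_current: float = -1.0,
) -> CurrentTrace:
    """Deterministic macroscopic current: N * i * conducting occupancy."""
    if traj.probabilities.shape[1] != scheme.n_states:
        raise ValueError("trajectory and scheme disagree on the number of states")
    p_cond = traj.probabilities[:, scheme.conducting_mask].sum(axis=1)
    return CurrentTrace(
        times=traj.times,
        current=n_channels * unitary_current * p_cond,
        n_channels=n_channels,
        unitary_current=unitary_current,
    )


def sample_channel_noise(
    traj: OccupancyTrajectory,
    scheme: KineticScheme,
    n_channels: int = 20_000,
    seed: int = 0,
    unitary_current: float = -1.0,
) -> CurrentTrace:
    """Macroscopic current with finite-channel binomial noise.

    At each sample the number of conducting channels is drawn from
    Binomial(n_channels, conducting probability); draws are independent
    across samples, which matches the noise floor of a heavily low-pass
    filtered ensemble recording.  Reproducible for a fixed seed.
    """
    if traj.probabilities.shape[1] != scheme.n_states:
        raise ValueError("trajectory and scheme disagree on the number of states")
    p_cond = traj.probabilities[:, scheme.conducting_mask].sum(axis=1)
    p_cond = np.clip(p_cond, 0.0, 1.0)
    rng = np.random.default_rng(seed)
    counts = rng.binomial(n_channels, p_cond)
    return CurrentTrace(
        times=traj.times,
        current=counts * unitary_current,
        n_channels=n_channels,
        unitary_current=unitary_current,
    )
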