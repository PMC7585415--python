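"""Wild-type calibration, mutant-ratio fitting and combination prediction.

The study's workflow, re-expressed as explicit optimization: (1) fix the
binding/gating rates and calibrate the four wild-type desensitization
rates of a variant against the four wild-type observables (tau_fast,
tau_slow, %A_fast, %I_res — exactly as many constraints as parameters);
(2) with the wild-type rates frozen, fit each single mutant's rate
multipliers against that construct's observables; (3) combine the
single-mutant multipliers multiplicatively to predict the combination
constructs, which is where the model variants diverge (anti-synergy under
model I, synergy under models II/III).

The objective compares observables on transformed scales — log for time
constants, logit for the amplitude and residual-current fractions — so
that a given relative error counts equally everywhere.
"""

from __future__ import annotations

import importlib.resources
import itertools
import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .metrics import DesensObservables, fit_decay_arrays, weighted_tau
from .params import (
    ConcertedFactors,
    ModelVariant,
    MutationProfile,
    RateParameters,
    profile_from_multipliers,
)
from .scheme import build_scheme
from .simulate import occupancies_at
from .states import SubunitID

# ---------------------------------------------------------------------------
# Targets

_FIELDS = ("tau_fast", "tau_slow", "pct_A_fast", "pct_I_res")

#: Constructs decaying faster than this get zero weight on the
#: slow-component observables, which are unreliable for them.
FAST_CONSTRUCT_TAU = 0.3


@dataclass
class ObservableTargets:
    """Experimental observables of one construct, with per-observable weights.

    Missing observables are NaN and weighted zero.  For fast-desensitizing
    constructs (tau_fast < 0.3 s) the slow-component observables
    (tau_slow, %I_res) default to weight zero.
    """

    construct: str
    tau_fast: float
    tau_slow: float = float("nan")
    pct_A_fast: float = float("nan")
    pct_I_res: float = float("nan")
    weights: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.tau_fast):
            raise ValueError("tau_fast target is required")
        w = {f: 1.0 for f in _FIELDS}
        if self.tau_fast < FAST_CONSTRUCT_TAU:
            w["tau_slow"] = 0.0
            w["pct_I_res"] = 0.0
        for f in _FIELDS:
            if not np.isfinite(getattr(self, f)):
                w[f] = 0.0
        w.update(self.weights)
        self.weights = w

    @property
    def tau_w(self) -> float:
        return weighted_tau(self.tau_fast, self.tau_slow, self.pct_A_fast)


def observed_targets() -> Dict[str, ObservableTargets]:
    """The packaged table of measured observables per construct."""
    with importlib.resources.files("gabakin.data").joinpath(
        "observed_desensitization.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    out: Dict[str, ObservableTargets] = {}
    for _, row in df.iterrows():
        out[row["construct"]] = ObservableTargets(
            construct=row["construct"],
            tau_fast=row["tau_fast_s"],
            tau_slow=row["tau_slow_s"],
            pct_A_fast=row["pct_A_fast"],
            pct_I_res=row["pct_I_res"],
        )
    return out


def construct_subunits(construct: str) -> frozenset:
    """Mutated subunits of a construct label: 'C45' -> {SU4, SU5}."""
    m = re.fullmatch(r"C(WT|[1-5]{0,5})", construct)
    if m is None:
        raise ValueError(f"unrecognized construct label {construct!r}")
    if m.group(1) == "WT" or m.group(1) == "":
        return frozenset()
    return frozenset(SubunitID(int(d)) for d in m.group(1))


# ---------------------------------------------------------------------------
# Fast observable prediction

def _obs_grid(t_app: float, coarse: bool = False) -> Tuple[np.ndarray, np.ndarray]:
    """Two-tier sampling: dense over the first 2 s, strided beyond.

    sqrt(stride) weights make the strided tail carry the same least-squares
    mass as uniform 500 Hz sampling.  The ``coarse`` grid (3x fewer points)
    serves the grid-search experiments, where only loss *ordering* between
    coupling pairs matters.
    """
    dt_fine, dt_tail = (0.006, 0.06) if coarse else (0.002, 0.02)
    t_fine_end = min(2.0, t_app)
    fine = np.arange(0.0, t_fine_end, dt_fine)
    tail = np.arange(t_fine_end, t_app + 1e-9, dt_tail)
    times = np.concatenate([fine, tail])
    stride = dt_tail / dt_fine
    w = np.concatenate([np.ones(len(fine)), np.full(len(tail), math.sqrt(stride))])
    return times, w


def predict_observables(
    variant: ModelVariant,
    params: RateParameters,
    profile: MutationProfile = MutationProfile(),
    *,
    agonist_conc: float = 0.01,
    t_app: float = 60.0,
    warm_taus: Tuple[float, float] | None = None,
    warm_accept: float = 2.5e-2,
    coarse: bool = False,
) -> DesensObservables:
    """Forward-simulate one construct and fit its decay observables.

    Simulates the study protocol (ideal step of 10 mM agonist for 60 s from
    the all-resting receptor) and fits the conducting-occupancy decay.  The
    propagation is exact (constant-generator matrix exponential evaluated on
    the sampling grid), so the result is deterministic in the parameters.
    ``warm_taus`` seeds the inner decay fit; the full multi-start grid is
    used whenever the warm start fits poorly.
    """
    scheme = build_scheme(variant, params, profile, agonist_conc)
    times, w = _obs_grid(t_app, coarse)
    probs = occupancies_at(scheme, times, agonist_conc=agonist_conc)
    y = probs[:, scheme.conducting_mask].sum(axis=1)
    ipk = int(np.argmax(y))
    peak = float(y[ipk])
    if peak <= 0:
        raise RuntimeError("no conducting occupancy; nothing to fit")
    trel = times[ipk:] - times[ipk]
    ydec = y[ipk:]
    wdec = w[ipk:]

    fit = None
    if warm_taus is not None:
        try:
            fit = fit_decay_arrays(
                trel, ydec, wdec, init_taus=[warm_taus], n_grid=0, max_nfev=40
            )
        except RuntimeError:
            fit = None
        # The bi-exponential form never matches the multi-state decay
        # exactly; floors of ~1% rms are normal.  Only a clearly worse fit
        # signals that the warm start landed in the wrong basin.
        if fit is not None and fit.resnorm > warm_accept:
            fit = None
    if fit is None:
        fit = fit_decay_arrays(trel, ydec, wdec, n_grid=4, max_nfev=80)

    return DesensObservables(
        tau_fast=fit.tau_fast,
        tau_slow=fit.tau_slow,
        pct_A_fast=100.0 * fit.fast_share,
        pct_I_res=100.0 * y[-1] / peak,
        I_peak=peak,
        fit_quality=fit.resnorm,
        plateau=fit.plateau,
        mono=fit.mono,
    )


def predict_construct(
    variant: ModelVariant,
    params: RateParameters,
    profile: MutationProfile,
    **kwargs,
) -> DesensObservables:
    """Observables predicted for one construct under calibrated inputs."""
    return predict_observables(variant, params, profile, **kwargs)


# ---------------------------------------------------------------------------
# Objective pieces

def _logit(frac: float) -> float:
    # Fractions beyond [1%, 99%] are experimentally indistinguishable; the
    # clip keeps saturated predictions from dominating the loss.
    f = min(max(frac, 1e-2), 1 - 1e-2)
    return math.log(f / (1 - f))


def target_residuals(pred: DesensObservables, tgt: ObservableTargets) -> np.ndarray:
    """Weighted transformed residuals (log taus, logit fractions)."""
    w = tgt.weights
    out = []
    if w["tau_fast"]:
        out.append(w["tau_fast"] * math.log(pred.tau_fast / tgt.tau_fast))
    if w["tau_slow"]:
        out.append(w["tau_slow"] * math.log(pred.tau_slow / tgt.tau_slow))
    if w["pct_A_fast"]:
        out.append(
            w["pct_A_fast"]
            * (_logit(pred.pct_A_fast / 100.0) - _logit(tgt.pct_A_fast / 100.0))
        )
    if w["pct_I_res"]:
        out.append(
            w["pct_I_res"]
            * (_logit(pred.pct_I_res / 100.0) - _logit(tgt.pct_I_res / 100.0))
        )
    return np.asarray(out)


def n_constraints(tgt: ObservableTargets) -> int:
    return sum(1 for f in _FIELDS if tgt.weights[f] > 0)


def restrict_targets(
    tgt: ObservableTargets, fields: Sequence[str]
) -> ObservableTargets:
    """Copy of ``tgt`` with nonzero weight only on the listed observables."""
    w = {f: (tgt.weights[f] if f in fields else 0.0) for f in _FIELDS}
    return ObservableTargets(
        construct=tgt.construct,
        tau_fast=tgt.tau_fast,
        tau_slow=tgt.tau_slow,
        pct_A_fast=tgt.pct_A_fast,
        pct_I_res=tgt.pct_I_res,
        weights=w,
    )


# ---------------------------------------------------------------------------
# Ballpark initializers

def model_I_equilibrium_from_amplitude(fast_amplitude_fraction: float) -> float:
    """Invert A_fast/I_peak ~ 2 D (model I two-pathway approximation)."""
    if fast_amplitude_fraction < 0:
        raise ValueError("amplitude fraction must be nonnegative")
    return fast_amplitude_fraction / 2.0


def model_II_equilibrium_from_amplitude(fast_amplitude_fraction: float) -> float:
    """Positive root of D^2 = f (1 + 2 D) (model II amplitude relation)."""
    f = fast_amplitude_fraction
    if f < 0:
        raise ValueError("amplitude fraction must be nonnegative")
    return f + math.sqrt(f * f + f)


class BallparkRangeError(ValueError):
    """The closed-form inversion is outside its validity range."""


def _su3_init(targets: ObservableTargets) -> Tuple[float, float]:
    """Rough SU3 rates from the slow component (starting point only)."""
    tau_slow = targets.tau_slow if np.isfinite(targets.tau_slow) else 5 * targets.tau_fast
    share = targets.pct_A_fast / 100.0 if np.isfinite(targets.pct_A_fast) else 0.5
    d3 = max((1.0 - share) / 2.0, 0.05)
    d3_minus = 1.0 / (2.0 * tau_slow * (1.0 + d3))
    return d3 * d3_minus, d3_minus


def ballpark_init_model_I(targets: ObservableTargets) -> RateParameters:
    """Model I starting rates from the stated closed-form approximations.

    Reads the relaxation relations as rates: 1/tau_fast ~ 2 (delta+ +
    delta-) for the SU4/SU5 pair and A_fast/I_peak ~ 2 D for their
    equilibrium constant; SU3 is initialized from the slow component
    analogously.  Starting points only — calibration refines numerically.
    """
    share = targets.pct_A_fast / 100.0
    if not np.isfinite(share):
        raise BallparkRangeError("no amplitude fraction available")
    if share >= 0.5:
        raise BallparkRangeError(
            "A_fast/I_peak >= 0.5 puts the 2D approximation out of range"
        )
    d = model_I_equilibrium_from_amplitude(share)
    delta_minus = 1.0 / (2.0 * targets.tau_fast * (1.0 + d))
    delta_plus = max(d * delta_minus, 1e-6)
    d3_plus, d3_minus = _su3_init(targets)
    return RateParameters(
        delta_plus=delta_plus,
        delta_minus=delta_minus,
        delta3_plus=d3_plus,
        delta3_minus=d3_minus,
    )


def ballpark_init_model_II(targets: ObservableTargets) -> RateParameters:
    """Model II starting rates: D from the quadratic amplitude relation,
    delta+ from 1/tau_fast ~ 2 D delta+."""
    share = targets.pct_A_fast / 100.0
    if not np.isfinite(share):
        raise BallparkRangeError("no amplitude fraction available")
    if np.isfinite(targets.pct_I_res):
        share = share * (1.0 - targets.pct_I_res / 100.0)
    d = model_II_equilibrium_from_amplitude(share)
    if d <= 0:
        raise BallparkRangeError("no positive root for D")
    delta_plus = 1.0 / (2.0 * d * targets.tau_fast)
    delta_minus = delta_plus / d
    d3_plus, d3_minus = _su3_init(targets)
    return RateParameters(
        delta_plus=delta_plus,
        delta_minus=delta_minus,
        delta3_plus=d3_plus,
        delta3_minus=d3_minus,
    )


def _ballpark_concerted(targets: ObservableTargets) -> RateParameters:
    """Concerted-variant starting rates from a two-branch approximation."""
    share = targets.pct_A_fast / 100.0 if np.isfinite(targets.pct_A_fast) else 0.4
    res = targets.pct_I_res / 100.0 if np.isfinite(targets.pct_I_res) else 0.1
    tau_s = targets.tau_slow if np.isfinite(targets.tau_slow) else 5 * targets.tau_fast
    f = min(share * (1 - res), 0.9)
    d_f = f / max(1 - f, 0.05)
    d_s = max(1.0 / max(res, 1e-3) - 1.0 - d_f, 0.1)
    lam_f = 1.0 / targets.tau_fast
    cf_minus = lam_f / (1.0 + d_f)
    cf_plus = d_f * cf_minus
    lam_s = 1.0 / tau_s
    cs_minus = lam_s / (d_s / (1.0 + d_f) + 1.0)
    cs_plus = d_s * cs_minus
    return RateParameters(
        conc_fast_plus=cf_plus,
        conc_fast_minus=cf_minus,
        conc_slow_plus=cs_plus,
        conc_slow_minus=cs_minus,
    )


# ---------------------------------------------------------------------------
# Wild-type calibration

_SUBUNIT_FREE = ("delta_plus", "delta_minus", "delta3_plus", "delta3_minus")
_CONCERTED_FREE = (
    "conc_fast_plus", "conc_fast_minus", "conc_slow_plus", "conc_slow_minus"
)

#: Flag threshold on the total squared transformed loss of the WT fit.
WT_LOSS_THRESHOLD = 0.05


@dataclass
class CalibrationResult:
    """Outcome of a wild-type calibration (optionally plus mutant fits)."""

    variant: ModelVariant
    params: RateParameters
    loss: float
    converged: bool
    predictions: Dict[str, DesensObservables] = field(default_factory=dict)
    multipliers: "FittedMultipliers | None" = None


class _WarmCache:
    """Per-construct warm starts and resnorm floors for the inner decay fit.

    The warm-start acceptance threshold adapts to the construct's observed
    model-mismatch floor, so constructs whose decay is poorly captured by
    two exponentials do not fall back to the expensive multi-start grid on
    every objective evaluation.
    """

    def __init__(self, coarse: bool = False) -> None:
        self._taus: Dict[object, Tuple[float, float]] = {}
        self._floor: Dict[object, float] = {}
        self._coarse = coarse

    def predict(self, key, variant, params, profile, **kw) -> DesensObservables:
        floor = self._floor.get(key)
        accept = 2.5e-2 if floor is None else max(2.5e-2, 1.5 * floor)
        obs = predict_observables(
            variant, params, profile, warm_taus=self._taus.get(key),
            warm_accept=accept, coarse=self._coarse, **kw
        )
        self._taus[key] = (obs.tau_fast, obs.tau_slow)
        if np.isfinite(obs.fit_quality):
            self._floor[key] = min(floor, obs.fit_quality) if floor is not None else obs.fit_quality
        return obs


def _free_names(variant: ModelVariant) -> Tuple[str, ...]:
    return _CONCERTED_FREE if variant is ModelVariant.CONCERTED else _SUBUNIT_FREE


def _apply_free(params: RateParameters, names, log_rates) -> RateParameters:
    return params.evolve(**{n: float(np.exp(v)) for n, v in zip(names, log_rates)})


def calibrate_wt(
    variant: ModelVariant,
    targets: ObservableTargets,
    couplings: Tuple[float, float] | None = None,
    *,
    n_refine: int = 2,
    max_nfev: int = 200,
    coarse: bool = False,
) -> CalibrationResult:
    """Calibrate the four wild-type desensitization rates of a variant.

    Binding/gating stay at their defaults; the free parameters are
    (delta+, delta-, delta3+, delta3-) for the subunit variants and the
    four fast/slow entry/exit rates for CONCERTED.  For model III the
    couplings (gamma, epsilon) are fixed inputs, not fitted.  Deterministic
    multi-start: the ballpark initializer plus a fixed log-grid of
    perturbations; the best fit is returned, flagged ``converged=False``
    when the loss stays above threshold.
    """
    base = RateParameters()
    if couplings is not None:
        if variant is not ModelVariant.III:
            raise ValueError("couplings are a model III feature")
        base = base.evolve(
            gamma_coupling=float(couplings[0]), epsilon_coupling=float(couplings[1])
        )

    if variant is ModelVariant.CONCERTED:
        inits = [_ballpark_concerted(targets)]
    elif variant is ModelVariant.I:
        try:
            inits = [ballpark_init_model_I(targets)]
        except BallparkRangeError:
            inits = []
    else:
        try:
            inits = [ballpark_init_model_II(targets)]
        except BallparkRangeError:
            inits = []

    names = _free_names(variant)
    fallback = base if variant is ModelVariant.CONCERTED else RateParameters(
        delta_plus=0.1, delta_minus=0.2, delta3_plus=0.05, delta3_minus=0.01
    )
    if not inits:
        inits = [fallback]
    cache = _WarmCache(coarse)

    def residual(x: np.ndarray) -> np.ndarray:
        p = _apply_free(base, names, x)
        obs = cache.predict("wt", variant, p, MutationProfile())
        return target_residuals(obs, targets)

    # Deterministic coarse screen around the initializer(s), then refine the
    # best candidates.  The slow pair (SU3 / slow branch) is the least
    # constrained direction, and under model III couplings its rates sit
    # roughly 1/gamma below the uncoupled guess, so the screen spans those
    # scales explicitly.
    slow_scales = [(1.0, 1.0), (0.1, 1.0), (0.01, 0.1), (1e-3, 0.01)]
    fast_scales = [(1.0, 1.0), (2.5, 6.0), (0.5, 0.3)]
    if n_refine <= 1:  # reduced-effort screen for grid experiments
        slow_scales = [(1.0, 1.0), (0.01, 0.1)]
        fast_scales = [(1.0, 1.0), (2.5, 6.0)]
    if variant is ModelVariant.III and couplings is not None:
        g, e = max(couplings[0], 1.0), max(couplings[1], 1.0)
        slow_scales += [(1.0 / g, 1.0), (1.0 / g, 1.0 / e)]
    lo, hi = math.log(1e-6), math.log(50.0)
    candidates = []
    for init in inits:
        x_init = np.log([getattr(init, n) for n in names])
        for fs in fast_scales:
            for ss in slow_scales:
                x0 = x_init + np.log([fs[0], fs[1], ss[0], ss[1]])
                candidates.append(np.clip(x0, lo, hi))
    screened = sorted(
        (float(r @ r), tuple(x)) for x in candidates for r in [residual(x)]
    )
    # Refine the best screened candidates plus the untouched ballpark start
    # (the screen can prefer corner candidates the refiner cannot escape).
    refine = [x for _, x in screened[:n_refine]]
    ballpark = tuple(np.log([getattr(inits[0], n) for n in names]))
    if ballpark not in refine:
        refine.append(ballpark)

    best_x, best_cost = None, np.inf
    for x0 in refine:
        try:
            sol = least_squares(
                residual, np.asarray(x0), bounds=(lo, hi), diff_step=2e-2,
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=max_nfev,
            )
        except Exception:
            continue
        if sol.cost < best_cost:
            best_x, best_cost = sol.x, sol.cost
        if best_cost < 1e-10:
            break
    if best_x is None:
        raise RuntimeError(f"wild-type calibration failed for {variant}")

    params = _apply_free(base, names, best_x)
    loss = float(2 * best_cost)
    pred = cache.predict("wt", variant, params, MutationProfile())
    return CalibrationResult(
        variant=variant,
        params=params,
        loss=loss,
        converged=loss < WT_LOSS_THRESHOLD,
        predictions={"CWT": pred},
    )


# ---------------------------------------------------------------------------
# Mutation-ratio fitting

@dataclass
class FittedMultipliers:
    """Per-subunit mutation multipliers fitted on single mutants.

    ``c4`` and ``c5`` are constrained equal (the two constructs are
    statistically indistinguishable); for variant III the recovery
    multipliers of SU4/SU5 stay at 1.  ``concerted`` holds the
    per-subunit factor quadruples of the concerted variant.
    """

    c3: Tuple[float, float] = (1.0, 1.0)
    c4: Tuple[float, float] = (1.0, 1.0)
    c5: Tuple[float, float] = (1.0, 1.0)
    c34: Tuple[float, float] = (1.0, 1.0)
    concerted: Dict[SubunitID, ConcertedFactors] = field(default_factory=dict)

    def profile_for(self, construct: str) -> MutationProfile:
        """Mutation profile of a construct from the fitted multipliers."""
        mutated = construct_subunits(construct)
        return profile_from_multipliers(
            mutated, c3=self.c3, c4=self.c4, c5=self.c5, c34=self.c34,
            concerted=self.concerted,
        )


#: Weight of the parsimony prior on log-multipliers in every mutant fit.
#: Mutations are allowed order-of-magnitude rate changes (the prior is a
#: zero-mean Gaussian on log c with sd 1/0.15 ~ 6.7 log-units), but where
#: the data leave a multiplier unidentified — or identify it only up to a
#: flat likelihood tail — the fit settles on the smallest perturbation
#: consistent with the observables, the standard parsimony reading of a
#: point mutation's effect.
RIDGE_WEIGHT = 0.15


#: Gain-of-desensitization mutations increase the rates they touch; the
#: subunit-model multipliers are therefore searched on [1, 1000].  The
#: concerted variant's factor quadruples carry no stated directionality
#: and are searched on [1e-2, 1e3].
SUBUNIT_MULT_BOUNDS = (0.0, math.log(1e3))
CONCERTED_FACTOR_BOUNDS = (math.log(1e-2), math.log(1e3))


def _fit_log_params(
    residual,
    n_free: int,
    starts: Sequence[np.ndarray],
    bounds=SUBUNIT_MULT_BOUNDS,
    max_nfev: int = 150,
) -> np.ndarray:
    best_x, best_cost = None, np.inf
    for x0 in starts:
        try:
            sol = least_squares(
                residual, np.clip(x0, *bounds), bounds=bounds, diff_step=2e-2,
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=max_nfev,
            )
        except Exception:
            continue
        if sol.cost < best_cost:
            best_x, best_cost = sol.x, sol.cost
        if best_cost < 1e-10:
            break
    if best_x is None:
        raise RuntimeError("multiplier fit failed from every start")
    return best_x


def _screened_starts(
    residual, grids: Sequence[Sequence[float]], n_keep: int = 2
) -> List[np.ndarray]:
    """Deterministic coarse screen over a multiplier grid.

    Gradient-based refinement of the mutant fits can stall at the
    unperturbed start when the observables respond weakly there; screening
    a fixed log-grid of candidate multiplier vectors first makes the fit
    start from the right decade regardless of local gradient quality.
    """
    cands = [np.log(np.asarray(v, dtype=float)) for v in itertools.product(*grids)]
    scored = sorted(
        (float(r @ r), tuple(x)) for x in cands for r in [residual(np.asarray(x))]
    )
    return [np.asarray(x) for _, x in scored[:n_keep]]


#: Coarse screen decades for mutation multipliers (entry, recovery).
_ENTRY_GRID = (1.0, 3.0, 10.0, 30.0, 100.0, 300.0)
_RECOVERY_GRID = (1.0, 3.0, 10.0)


def fit_mutation_ratios(
    variant: ModelVariant,
    wt_result: CalibrationResult,
    mutant_targets: Mapping[str, ObservableTargets],
    *,
    fit_su45_to: str = "singles",
    fields: Sequence[str] | None = None,
    effort: str = "full",
    ridge_weight: float = RIDGE_WEIGHT,
    warm_cache: "_WarmCache | None" = None,
) -> FittedMultipliers:
    """Fit mutation multipliers on single mutants with wild-type frozen.

    ``fit_su45_to='singles'`` fits the shared SU4/SU5 multiplier against
    C4 and C5 jointly (simulation *a* of model I); ``'C45'`` fits it
    against the double mutant instead, after which the singles become the
    prediction (simulation *b*).  The SU3 fit (when C3 targets are given)
    additionally carries the c34 cross-multipliers for variants II-beta
    and III.  ``fields`` restricts the fit to a subset of observables —
    model I's single free multiplier is matched on the decay time
    constants, the axis on which that model is judged.  Underdetermined
    fits (more free multipliers than weighted constraints) get a weak
    ridge pulling log-multipliers towards 0.
    """
    params = wt_result.params
    cache = warm_cache if warm_cache is not None else _WarmCache()
    if fields is not None:
        mutant_targets = {
            c: restrict_targets(t, fields) for c, t in mutant_targets.items()
        }

    max_nfev = 150 if effort == "full" else 60

    if variant is ModelVariant.CONCERTED:
        return _fit_concerted_factors(
            wt_result, mutant_targets, cache, effort, ridge_weight
        )

    fitted = FittedMultipliers()

    # --- shared SU4/SU5 multiplier ---
    if fit_su45_to == "singles":
        su45_constructs = [c for c in ("C4", "C5") if c in mutant_targets]
    elif fit_su45_to in mutant_targets:
        su45_constructs = [fit_su45_to]
    else:
        su45_constructs = []
    if su45_constructs:
        entry_only = variant in (ModelVariant.I, ModelVariant.III)
        n_free = 1 if entry_only else 2
        ridge = ridge_weight

        def resid45(x: np.ndarray) -> np.ndarray:
            c_plus = float(np.exp(x[0]))
            c_minus = 1.0 if entry_only else float(np.exp(x[1]))
            out = []
            for c in su45_constructs:
                prof = profile_from_multipliers(
                    construct_subunits(c),
                    c4=(c_plus, c_minus), c5=(c_plus, c_minus),
                )
                obs = cache.predict(c, variant, params, prof)
                out.append(target_residuals(obs, mutant_targets[c]))
            if ridge:
                out.append(ridge * x)
            return np.concatenate(out)

        grids45 = [_ENTRY_GRID] + ([] if entry_only else [_RECOVERY_GRID])
        starts = _screened_starts(resid45, grids45, n_keep=2 if effort == "full" else 1)
        x = _fit_log_params(resid45, n_free, starts, max_nfev=max_nfev)
        c_plus = float(np.exp(x[0]))
        c_minus = 1.0 if entry_only else float(np.exp(x[1]))
        fitted.c4 = fitted.c5 = (c_plus, c_minus)

    # --- SU3 multiplier (and c34 cross-effect where licensed) ---
    if "C3" in mutant_targets:
        with_cross = variant in (ModelVariant.II_BETA, ModelVariant.III)
        entry_only = variant is ModelVariant.I
        n_free = 1 if entry_only else (4 if with_cross else 2)
        ridge = ridge_weight

        def resid3(x: np.ndarray) -> np.ndarray:
            e = np.exp(x)
            c3 = (float(e[0]), 1.0 if entry_only else float(e[1]))
            c34 = (float(e[2]), float(e[3])) if with_cross else (1.0, 1.0)
            prof = profile_from_multipliers(
                construct_subunits("C3"), c3=c3, c34=c34
            )
            obs = cache.predict("C3", variant, params, prof)
            out = [target_residuals(obs, mutant_targets["C3"])]
            if ridge:
                out.append(ridge * x)
            return np.concatenate(out)

        grids3: List[Sequence[float]] = [(1.0, 3.0, 10.0, 30.0)]
        if not entry_only:
            grids3.append(_RECOVERY_GRID)
        if with_cross:
            grids3 += [(1.0, 3.0, 10.0, 30.0), (1.0, 3.0)]
        starts = _screened_starts(resid3, grids3, n_keep=2 if effort == "full" else 1)
        x = _fit_log_params(resid3, n_free, starts, max_nfev=max_nfev)
        e = np.exp(x)
        fitted.c3 = (float(e[0]), 1.0 if entry_only else float(e[1]))
        if with_cross:
            fitted.c34 = (float(e[2]), float(e[3]))
    return fitted


def _fit_concerted_factors(
    wt_result: CalibrationResult,
    mutant_targets: Mapping[str, ObservableTargets],
    cache: _WarmCache,
    effort: str = "full",
    ridge_weight: float = RIDGE_WEIGHT,
) -> FittedMultipliers:
    """Per-mutant (gamma_f, epsilon_f, gamma_s, epsilon_s) factor fits.

    Single mutants rarely pin down all four factors (three weighted
    constraints is typical), so a weak ridge keeps the fit at the
    smallest perturbation consistent with the data — the natural reading
    of an energy-additive mutation model.
    """
    params = wt_result.params
    fitted = FittedMultipliers()
    # C4 and C5 are indistinguishable: fit both jointly with shared factors.
    joint = [c for c in ("C4", "C5") if c in mutant_targets]
    groups: List[Tuple[Tuple[str, ...], Tuple[SubunitID, ...]]] = []
    if joint:
        groups.append(
            (tuple(joint), tuple(next(iter(construct_subunits(c))) for c in joint))
        )
    if "C3" in mutant_targets:
        groups.append((("C3",), (SubunitID.SU3,)))

    for constructs, subunits in groups:
        ridge = ridge_weight

        def resid(x: np.ndarray) -> np.ndarray:
            fac = ConcertedFactors(*np.exp(x))
            out = []
            for c in constructs:
                su = construct_subunits(c)
                prof = profile_from_multipliers(
                    su, concerted={s: fac for s in su}
                )
                obs = cache.predict(c, ModelVariant.CONCERTED, params, prof)
                out.append(target_residuals(obs, mutant_targets[c]))
            out.append(ridge * x)
            return np.concatenate(out)

        conc_axis = (0.3, 1.0, 3.0, 10.0)
        starts = _screened_starts(
            resid, [conc_axis, (0.3, 1.0, 3.0), conc_axis, (0.3, 1.0, 3.0)],
            n_keep=2 if effort == "full" else 1,
        )
        x = _fit_log_params(
            resid, 4, starts,
            bounds=CONCERTED_FACTOR_BOUNDS,
            max_nfev=150 if effort == "full" else 60,
        )
        fac = ConcertedFactors(*np.exp(x))
        for su in subunits:
            fitted.concerted[su] = fac
    return fitted


# ---------------------------------------------------------------------------
# Full pipeline and model comparison

def run_full_calibration(
    variant: ModelVariant,
    targets: Mapping[str, ObservableTargets],
    *,
    couplings: Tuple[float, float] | None = None,
    fit_su45_to: str = "singles",
    predict: Iterable[str] = ("C3", "C4", "C5", "C34", "C35", "C45", "C345"),
    n_refine: int = 2,
    max_nfev: int = 200,
    effort: str = "full",
    ridge_weight: float = RIDGE_WEIGHT,
    coarse: bool = False,
) -> CalibrationResult:
    """Calibrate wild type, fit single-mutant ratios, predict combinations.

    For model I the mutant fits match the decay time constants only (that
    model cannot move the amplitude share, and the study quantifies its
    mutants kinetically); the other variants fit the full weighted
    observable vector.
    """
    result = calibrate_wt(
        variant, targets["CWT"], couplings, n_refine=n_refine,
        max_nfev=max_nfev, coarse=coarse,
    )
    mutants = {c: t for c, t in targets.items() if c != "CWT"}
    # Model I cannot reproduce the mutant amplitude shift, so its single
    # free multiplier is matched on the decay time constants alone.
    fields = ("tau_fast", "tau_slow") if variant is ModelVariant.I else None
    cache = _WarmCache(coarse)
    result.multipliers = fit_mutation_ratios(
        variant, result, mutants, fit_su45_to=fit_su45_to, fields=fields,
        effort=effort, ridge_weight=ridge_weight, warm_cache=cache,
    )
    for construct in predict:
        prof = result.multipliers.profile_for(construct)
        result.predictions[construct] = cache.predict(
            construct, variant, result.params, prof
        )
    return result


def total_loss(
    result: CalibrationResult, targets: Mapping[str, ObservableTargets]
) -> float:
    """Summed squared transformed residuals over every targeted construct."""
    loss = 0.0
    for construct, tgt in targets.items():
        if construct in result.predictions:
            r = target_residuals(result.predictions[construct], tgt)
            loss += float(r @ r)
    return loss


#: The coupling grid searched for model III.
COUPLING_GRID = (1.0, 10.0, 100.0, 1000.0)


def select_couplings(
    targets: Mapping[str, ObservableTargets],
    grid: Sequence[float] = COUPLING_GRID,
    *,
    effort: str = "fast",
) -> Tuple[Tuple[float, float], CalibrationResult, pd.DataFrame]:
    """Grid-search the model III couplings (gamma, epsilon).

    For each grid pair, runs the full calibration pipeline and scores the
    summed loss over all targeted constructs; returns the best pair, its
    calibration, and the full score table.  The default reduced-effort
    optimizer settings keep the 16-pair grid tractable; the loss ordering
    between coupling pairs is far coarser than the optimizer tolerance.
    """
    kw = (
        {"n_refine": 1, "max_nfev": 60, "coarse": True}
        if effort == "fast"
        else {}
    )
    # The grid compares pure goodness-of-fit between coupling pairs; the
    # parsimony prior on multipliers would let large couplings masquerade
    # as small multipliers, so it is disabled here.
    kw["ridge_weight"] = 0.0
    rows = []
    best = None
    for gamma, eps in itertools.product(grid, grid):
        res = run_full_calibration(
            ModelVariant.III, targets, couplings=(gamma, eps), **kw
        )
        loss = total_loss(res, targets)
        rows.append({"gamma": gamma, "epsilon": eps, "loss": loss})
        if best is None or loss < best[2]:
            best = ((gamma, eps), res, loss)
    table = pd.DataFrame(rows)
    return best[0], best[1], table


# Mutant-cycle flag thresholds.  fold1 = tau_fast(WT)/tau_fast(C4) is the
# acceleration bought by the first SU4/SU5 mutation, fold2 =
# tau_fast(C4)/tau_fast(C45) by the second.  Additive (independent) effects
# give fold2 ~ fold1; a model is flagged synergistic when the second
# mutation helps clearly more than the first, anti-synergistic when it
# helps clearly less.
SYNERGY_FOLD_RATIO = 1.25
ANTI_SYNERGY_FOLD_RATIO = 0.8


def model_comparison_report(
    results: Mapping[str, CalibrationResult],
    targets: Mapping[str, ObservableTargets],
) -> Tuple[pd.DataFrame, Dict[str, str]]:
    """Predicted-vs-observed table and qualitative synergy flags.

    The table holds, per (variant, construct), the predicted observables
    and the fold-error against the targets.  Flags classify each variant
    by a mutant-cycle comparison on the predicted tau_fast: additive
    effects make the second SU4/SU5 mutation buy the same fold-change as
    the first; 'synergy' means it buys clearly more, 'anti-synergy'
    clearly less.
    """
    rows = []
    flags: Dict[str, str] = {}
    for name, res in results.items():
        for construct, pred in res.predictions.items():
            row = {
                "variant": name,
                "construct": construct,
                "tau_fast_pred": pred.tau_fast,
                "tau_slow_pred": pred.tau_slow,
                "pct_A_fast_pred": pred.pct_A_fast,
                "pct_I_res_pred": pred.pct_I_res,
                "tau_w_pred": pred.tau_w,
            }
            if construct in targets:
                tgt = targets[construct]
                row["tau_fast_obs"] = tgt.tau_fast
                row["tau_fast_fold_error"] = pred.tau_fast / tgt.tau_fast
                if np.isfinite(tgt.tau_slow):
                    row["tau_slow_obs"] = tgt.tau_slow
                    row["tau_slow_fold_error"] = pred.tau_slow / tgt.tau_slow
            rows.append(row)
        needed = {"CWT", "C4", "C45"}
        if needed <= res.predictions.keys():
            fold1 = (
                res.predictions["CWT"].tau_fast / res.predictions["C4"].tau_fast
            )
            fold2 = (
                res.predictions["C4"].tau_fast / res.predictions["C45"].tau_fast
            )
            if fold2 >= SYNERGY_FOLD_RATIO * fold1:
                flags[name] = "synergy"
            elif fold2 <= ANTI_SYNERGY_FOLD_RATIO * fold1:
                flags[name] = "anti-synergy"
            else:
                flags[name] = "additive"
    return pd.DataFrame(rows), flags
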