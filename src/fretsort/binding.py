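"""Biosensor binding characterization: dose-response fits, occupancy, kinetics.

A c-di-GMP biosensor changes FRET upon ligand binding; depending on the
conformational change the response can increase or decrease with ligand.  The
dose response of permeabilized biosensor-expressing cells is described by an
allosteric sigmoidal (Hill) model

    E(c) = E0 + (E_inf - E0) * c**h / (K_D**h + c**h)

with the half-saturation constant reported directly as the dissociation
constant K_D and Hill coefficient h.  Relative in-vivo occupancy interpolates
a sample's efficiency linearly between apo and saturated reference strains.
Dissociation kinetics after ligand washout are modelled as a single
exponential relaxation of the FRET ratio with apparent rate k_off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize

from .errors import UnidentifiableFitError

#: Bounds for the Hill coefficient; the biosensors are single-site binders so
#: strong apparent cooperativity indicates a pathological fit.
HILL_BOUNDS = (0.3, 4.0)

#: Minimal |E_sat - E_apo| (response units) accepted for occupancy interpolation.
MIN_DYNAMIC_RANGE = 1.0


@dataclass(frozen=True)
class Titration:
    """Ligand titration: concentrations (nM) vs FRET response."""

    concentration: np.ndarray
    response: np.ndarray
    response_kind: str = "efficiency"  # or "ratio"

    def __post_init__(self) -> None:
        c = np.asarray(self.concentration, dtype=float)
        r = np.asarray(self.response, dtype=float)
        if c.shape != r.shape or c.ndim != 1:
            raise ValueError("concentration and response must be matching 1-D arrays")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        if self.response_kind not in ("efficiency", "ratio"):
            raise ValueError("response_kind must be 'efficiency' or 'ratio'")
        object.__setattr__(self, "concentration", c)
        object.__setattr__(self, "response", r)


@dataclass(frozen=True)
class BindingFit:
    """Hill-model parameters of a dose response."""

    K_D: float
    h: float
    E0: float
    E_inf: float
    direction: str  # "increasing" or "decreasing"
    stderr: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    def __post_init__(self) -> None:
        if not (self.K_D > 0 and self.h > 0):
            raise ValueError("K_D and h must be positive")

    def predict(self, concentration: np.ndarray) -> np.ndarray:
        return hill(np.asarray(concentration, float), self.K_D, self.h, self.E0, self.E_inf)


@dataclass(frozen=True)
class KineticsTrace:
    """Ratiometric FRET time series with ligand addition/removal events."""

    time: np.ndarray
    ratio: np.ndarray
    events: tuple = ()  # sequence of (time_min, kind, concentration_nM)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        r = np.asarray(self.ratio, dtype=float)
        if t.shape != r.shape or t.ndim != 1:
            raise ValueError("time and ratio must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        for ev in self.events:
            if ev[1] not in ("addition", "removal"):
                raise ValueError(f"unknown event kind {ev[1]!r}")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "ratio", r)


@dataclass(frozen=True)
class KineticsFit:
    """Single-exponential dissociation fit: R(t) = R_inf + (R0-R_inf)e^{-k t}."""

    k_off: float
    R0: float
    R_inf: float
    converged: bool = True
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.k_off < 0:
            raise ValueError("k_off must be >= 0")


class Occupancy(NamedTuple):
    value: float
    out_of_range: bool


def hill(c: np.ndarray, kd: float, h: float, e0: float, e_inf: float) -> np.ndarray:
    """Allosteric sigmoidal response; defined (=e0) at c = 0."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(c > 0, 1.0 / (1.0 + (kd / np.maximum(c, 1e-300)) ** h), 0.0)
    return e0 + (e_inf - e0) * frac


def fit_dose_response(data: Titration) -> BindingFit:
    """Fit the Hill model to a titration by bounded least squares.

    K_D is optimized on a log scale with multiple starts (the dose bracketing
    the half response, plus the geometric dose quartiles) to avoid the local
    minima of sigmoid fitting; the best-cost solution wins.
    """
    c, r = data.concentration, data.response
    if np.unique(c).size < 5:
        raise UnidentifiableFitError("need >= 5 distinct concentrations")
    span = float(np.ptp(r))
    if span <= 1e-12 * max(1.0, float(np.max(np.abs(r)))):
        raise UnidentifiableFitError("flat response; binding parameters undefined")

    pos = c[c > 0]
    e0_guess = float(r[np.argmin(c)])
    einf_guess = float(r[np.argmax(c)])
    half = 0.5 * (e0_guess + einf_guess)
    kd_starts = [float(pos[np.argmin(np.abs(r[c > 0] - half))])]
    kd_starts += list(np.exp(np.quantile(np.log(pos), [0.25, 0.5, 0.75])))

    def residuals(p: np.ndarray) -> np.ndarray:
        log_kd, h, e0, e_inf = p
        return hill(c, np.exp(log_kd), h, e0, e_inf) - r

    lo = [-np.inf, HILL_BOUNDS[0], -np.inf, -np.inf]
    hi = [np.inf, HILL_BOUNDS[1], np.inf, np.inf]
    best = None
    for kd0 in kd_starts:
        p0 = [np.log(kd0), 1.0, e0_guess, einf_guess]
        try:
            sol = optimize.least_squares(residuals, p0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise UnidentifiableFitError("dose-response fit failed from every start")

    log_kd, h, e0, e_inf = best.x
    kd = float(np.exp(log_kd))
    stderr = _stderr_from_jacobian(best, n_obs=len(r))
    # delta method: sd(K_D) = K_D * sd(log K_D)
    named = {
        "K_D": kd * stderr[0],
        "h": stderr[1],
        "E0": stderr[2],
        "E_inf": stderr[3],
    }
    return BindingFit(
        K_D=kd,
        h=float(h),
        E0=float(e0),
        E_inf=float(e_inf),
        direction="increasing" if e_inf > e0 else "decreasing",
        stderr=named,
        converged=bool(best.success),
    )


def _stderr_from_jacobian(sol, n_obs: int) -> np.ndarray:
    """Asymptotic parameter standard errors from a least_squares solution."""
    dof = max(n_obs - sol.x.size, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        jtj_inv = np.linalg.pinv(sol.jac.T @ sol.jac)
        return np.sqrt(np.maximum(np.diag(jtj_inv) * s2, 0.0))
    except np.linalg.LinAlgError:
        return np.full(sol.x.size, np.nan)


def occupancy(
    e_sample: float,
    e_apo_ref: float,
    e_sat_ref: float,
    min_dynamic_range: float = MIN_DYNAMIC_RANGE,
) -> Occupancy:
    """Relative biosensor occupancy by linear interpolation between references.

    The references are labelled by ligand state (apo vs saturated), not by
    magnitude, so the same formula serves FRET-increasing and -decreasing
    biosensors.  Values outside [0, 1] are returned unclamped with a flag.
    """
    dyn = e_sat_ref - e_apo_ref
    if abs(dyn) < min_dynamic_range:
        raise UnidentifiableFitError(
            f"reference dynamic range |{dyn:g}| below {min_dynamic_range:g}"
        )
    value = (e_sample - e_apo_ref) / dyn
    return Occupancy(value=float(value), out_of_range=not (0.0 <= value <= 1.0))


def fit_dissociation(trace: KineticsTrace, removal_event_index: int = 0) -> KineticsFit:
    """Fit a single-exponential decay to the segment after a removal event.

    The segment runs from the selected removal event up to the next event (or
    the end of the trace).  R0 is left free rather than pinned to the
    pre-removal plateau, since sub-saturating additions may not have fully
    equilibrated.
    """
    removals = [ev for ev in trace.events if ev[1] == "removal"]
    if removal_event_index >= len(removals):
        raise ValueError(
            f"trace has {len(removals)} removal events; index "
            f"{removal_event_index} out of range"
        )
    t0 = float(removals[removal_event_index][0])
    later = [float(ev[0]) for ev in trace.events if float(ev[0]) > t0]
    t_end = min(later) if later else np.inf
    mask = (trace.time > t0) & (trace.time <= t_end)
    t = trace.time[mask] - t0
    r = trace.ratio[mask]
    if len(t) < 6:
        raise ValueError(f"only {len(t)} points after removal; need >= 6")

    if np.ptp(r) <= 1e-12 * max(1.0, float(np.max(np.abs(r)))):
        return KineticsFit(
            k_off=0.0, R0=float(r[0]), R_inf=float(r[-1]),
            converged=True, flags=frozenset({"constant_trace"}),
        )

    r0_guess, rinf_guess = float(r[0]), float(r[-1])
    amp = r0_guess - rinf_guess
    # log-linear starting rate from the early half of the decay
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (r - rinf_guess) / amp if amp != 0 else np.full_like(r, np.nan)
    ok = np.isfinite(z) & (z > 0.05)
    if ok.sum() >= 2:
        k0 = max(-np.polyfit(t[ok], np.log(z[ok]), 1)[0], 1e-6)
    else:
        k0 = 1.0 / max(t[-1], 1e-6)

    def model(tt, k, r0, rinf):
        return rinf + (r0 - rinf) * np.exp(-k * tt)

    try:
        popt, _ = optimize.curve_fit(
            model, t, r, p0=[k0, r0_guess, rinf_guess],
            bounds=([0.0, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        converged = True
    except RuntimeError:
        popt, converged = [k0, r0_guess, rinf_guess], False
    return KineticsFit(
        k_off=float(popt[0]), R0=float(popt[1]), R_inf=float(popt[2]),
        converged=converged,
    )
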