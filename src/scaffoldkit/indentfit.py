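"""Fit elastic and viscoelastic parameters to ramp-and-hold indentation curves.

Workflow: detect the contact point on a raw recording, re-zero time/depth and
subtract the force baseline, split the trace into a loading ramp and a
constant-depth hold, then

* fit the Hertz relation to the loading segment (linear least squares in E),
* fit the three SLS parameters (E0, E_inf, tau) by bounded nonlinear least
  squares of the Lee–Radok forward model against the observed force over the
  loading and hold segments jointly.

The apparent Young's modulus from a loading-only Hertz fit of a viscoelastic
material falls between E_inf and E0; the joint fit separates the three
parameters using the relaxation transient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

from .mechanics import (
    DepthProtocol,
    ProbeSpec,
    SampleGeometry,
    SLSParams,
    bec_correction,
    lee_radok_force,
    _hertz_prefactor,
)

__all__ = [
    "IndentationCurve",
    "ElasticFit",
    "ViscoFit",
    "FitError",
    "ContactError",
    "detect_contact",
    "split_segments",
    "fit_elastic",
    "fit_sls",
    "goodness_of_fit",
]


class FitError(RuntimeError):
    """A fit could not be performed or produced an invalid result."""


class ContactError(RuntimeError):
    """No contact point could be identified on the curve."""


@dataclass(frozen=True)
class IndentationCurve:
    """A sampled indentation recording: time (s), depth (m), force (N).

    ``depth`` is probe travel; after :func:`detect_contact` it is true
    indentation depth with depth[0] = 0 at the contact point.
    """

    time: np.ndarray
    depth: np.ndarray
    force: np.ndarray
    probe: ProbeSpec
    geometry: SampleGeometry
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        d = np.asarray(self.depth, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if not (t.ndim == 1 and t.shape == d.shape == f.shape and t.size >= 2):
            raise ValueError("time, depth, force must be equal-length 1-D arrays (n >= 2)")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "depth", d)
        object.__setattr__(self, "force", f)

    def __len__(self) -> int:
        return self.time.size

    def slice(self, start: int, stop: int | None = None) -> "IndentationCurve":
        sl = np.s_[start:stop]
        return IndentationCurve(
            self.time[sl], self.depth[sl], self.force[sl],
            self.probe, self.geometry, self.label,
        )


@dataclass(frozen=True)
class ElasticFit:
    """Result of a Hertz fit on the loading segment."""

    young_modulus: float  # Pa
    r_squared: float
    n_points: int
    residual_norm: float  # N, L2 norm of residuals

    def __post_init__(self) -> None:
        if not (self.young_modulus > 0):
            raise ValueError("young_modulus must be > 0")


@dataclass(frozen=True)
class ViscoFit:
    """Result of an SLS (Lee–Radok) fit.

    ``diagnostics`` records initialization, identifiability warnings
    (``tau_identifiable``), and the fit window used.
    """

    params: SLSParams
    r_squared: float
    converged: bool
    iterations: int
    diagnostics: dict = field(default_factory=dict)


def goodness_of_fit(observed, predicted) -> float:
    """Coefficient of determination R^2 = 1 - SS_res/SS_tot."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length 1-D, n >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("zero-variance observations: R^2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def detect_contact(
    curve: IndentationCurve,
    force_threshold: float | None = None,
    baseline_window: float = 0.02,
) -> tuple[int, IndentationCurve]:
    """Locate the contact point and return (index, re-zeroed curve).

    The force baseline and its noise SD are estimated from the initial
    ``baseline_window`` fraction of the recording (assumed pre-contact).
    Contact is the first sample whose baseline-subtracted force exceeds the
    threshold (default 5x the baseline noise SD), walked back to the last
    baseline crossing.  If the initial window itself rises well beyond the
    threshold the recording is taken to start at contact (index 0,
    unchanged).  The returned curve starts at contact with time/depth
    re-zeroed and the baseline subtracted.
    """
    f = curve.force
    n = len(curve)
    nw = min(max(5, int(round(baseline_window * n))), n)
    baseline = float(np.median(f[:nw]))
    if force_threshold is None:
        sd = float(np.std(f[:nw]))
        force_threshold = 5.0 * sd if sd > 0 else 1e-12
    spread = float(f[:nw].max() - f[:nw].min())
    if spread > 3.0 * force_threshold and f[nw - 1] - f[0] > force_threshold:
        k, baseline = 0, 0.0  # no pre-contact plateau: already in contact
    else:
        above = np.nonzero(f - baseline > force_threshold)[0]
        if above.size == 0:
            raise ContactError("no contact detected: no sample exceeds the force threshold")
        k = int(above[0])
        # walk back to the last sample at or below baseline before the crossing
        while k > 0 and f[k - 1] - baseline > 0:
            k -= 1
        if k == 0:
            baseline = 0.0  # starts at contact; leave the trace untouched
    out = IndentationCurve(
        curve.time[k:] - curve.time[k],
        curve.depth[k:] - curve.depth[k],
        curve.force[k:] - baseline,
        curve.probe,
        curve.geometry,
        curve.label,
    )
    return k, out


def split_segments(
    curve: IndentationCurve,
    hold_tolerance: float = 0.005,
) -> tuple[IndentationCurve, IndentationCurve | None]:
    """Split a contact-corrected curve into (loading, hold).

    Hold samples sit within ``hold_tolerance`` (relative) of the maximal
    depth AND show a depth rate well below the ramp rate; a monotone ramp
    with no plateau yields ``hold=None``.
    """
    d = curve.depth
    t = curve.time
    dmax = float(d.max())
    if dmax <= 0:
        raise ValueError("curve has no positive indentation depth")
    near_max = d >= (1.0 - hold_tolerance) * dmax
    k = int(np.argmax(near_max))  # first sample within tolerance of max depth
    if k == len(curve) - 1:
        return curve, None
    # mean rate over the candidate plateau vs. the ramp rate
    ramp_rate = (d[k] - d[0]) / (t[k] - t[0]) if k > 0 else np.inf
    plateau_rate = (d[-1] - d[k]) / (t[-1] - t[k])
    if k > 0 and abs(plateau_rate) >= 0.5 * ramp_rate:
        return curve, None  # still ramping: no hold plateau
    return curve.slice(0, k + 1), curve.slice(k, None)


def fit_elastic(
    loading: IndentationCurve,
    probe: ProbeSpec | None = None,
    geometry: SampleGeometry | None = None,
) -> ElasticFit:
    """Least-squares Hertz fit of the loading segment.

    The model F = E * g(delta) is linear in E, with
    g = pref * f_BEC(delta) * delta^(3/2), so the optimum is closed-form:
    E = sum(g*F) / sum(g^2).
    """
    probe = probe or loading.probe
    geometry = geometry or loading.geometry
    if len(loading) < 10:
        raise FitError(f"need >= 10 loading samples, got {len(loading)}")
    d = np.clip(loading.depth, 0.0, None)
    g = _hertz_prefactor(probe, geometry) * bec_correction(d, probe, geometry) * d**1.5
    denom = float(np.sum(g * g))
    if denom == 0.0:
        raise FitError("loading segment has zero depth everywhere")
    e = float(np.sum(g * loading.force) / denom)
    if not (e > 0 and np.isfinite(e)):
        raise FitError(f"elastic fit returned nonpositive modulus E={e:.3g} Pa")
    pred = e * g
    r2 = goodness_of_fit(loading.force, pred)
    return ElasticFit(
        young_modulus=e,
        r_squared=r2,
        n_points=len(loading),
        residual_norm=float(np.linalg.norm(loading.force - pred)),
    )


def _initial_guess(
    curve: IndentationCurve,
    loading: IndentationCurve,
    hold: IndentationCurve,
) -> tuple[float, float, float]:
    """Heuristic (E0, E_inf, tau) start: E0 from an elastic fit to the early
    loading, E_inf from the final hold force via the Hertz inverse, tau from
    the time to half relaxation along the hold."""
    n20 = max(10, int(0.2 * len(loading)))
    try:
        e0 = fit_elastic(loading.slice(0, n20)).young_modulus
    except FitError:
        e0 = fit_elastic(loading).young_modulus
    d_end = float(hold.depth[-1])
    g_end = (
        _hertz_prefactor(curve.probe, curve.geometry)
        * bec_correction(d_end, curve.probe, curve.geometry)
        * d_end**1.5
    )
    einf = max(float(hold.force[-1]) / g_end, 1e-3 * e0) if g_end > 0 else 0.5 * e0
    einf = min(einf, e0)
    f0, f1 = float(hold.force[0]), float(hold.force[-1])
    half = 0.5 * (f0 + f1)
    below = np.nonzero(hold.force <= half)[0]
    hold_span = float(hold.time[-1] - hold.time[0])
    if f0 > f1 and below.size:
        tau = max(float(hold.time[below[0]] - hold.time[0]), 1e-3)
    else:
        tau = max(hold_span / 5.0, 1e-3)
    return e0, einf, tau


def fit_sls(
    curve: IndentationCurve,
    window: Literal["joint", "loading", "hold"] = "joint",
    hold_tolerance: float = 0.005,
    max_nfev: int = 200,
    bec_with_derivative: bool = False,
) -> ViscoFit:
    """Bounded nonlinear least-squares fit of the SLS Lee–Radok model.

    ``curve`` must be contact-corrected (depth 0 at the first sample) and
    contain both a loading ramp and a hold plateau.  The optimizer works on
    x = (E_inf, dE, tau) with dE = E0 - E_inf >= 0, which enforces
    E0 >= E_inf > 0 by construction.  Deterministic: identical input and
    configuration give an identical report.
    """
    loading, hold = split_segments(curve, hold_tolerance=hold_tolerance)
    if hold is None:
        raise FitError("no hold plateau found: a viscoelastic fit needs a relaxation segment")
    e0_i, einf_i, tau_i = _initial_guess(curve, loading, hold)
    de_i = max(e0_i - einf_i, 1e-3 * e0_i)

    protocol = DepthProtocol(curve.time, np.clip(curve.depth, 0.0, None))
    if window == "joint":
        mask = np.ones(len(curve), dtype=bool)
    elif window == "loading":
        mask = np.zeros(len(curve), dtype=bool)
        mask[: len(loading)] = True
    elif window == "hold":
        mask = np.zeros(len(curve), dtype=bool)
        mask[len(loading) - 1 :] = True
    else:
        raise ValueError(f"unknown fit window {window!r}")
    f_obs = curve.force

    def residuals(x: np.ndarray) -> np.ndarray:
        p = SLSParams(e0=x[0] + x[1], einf=x[0], tau=x[2])
        pred = lee_radok_force(
            protocol, p, curve.probe, curve.geometry,
            bec_with_derivative=bec_with_derivative,
        )
        return (pred - f_obs)[mask]

    x0 = np.array([einf_i, de_i, tau_i])
    scale = np.array([einf_i, max(de_i, 0.1 * einf_i), max(tau_i, 0.1)])
    res = least_squares(
        residuals,
        x0,
        bounds=([1e-6, 0.0, 1e-4], [np.inf, np.inf, 1e5]),
        x_scale=scale,
        max_nfev=max_nfev,
        method="trf",
        ftol=1e-12,
        xtol=1e-12,
        gtol=1e-12,
    )
    einf, de, tau = res.x
    params = SLSParams(e0=float(einf + de), einf=float(einf), tau=float(tau))
    pred_full = lee_radok_force(
        protocol, params, curve.probe, curve.geometry,
        bec_with_derivative=bec_with_derivative,
    )
    r2 = goodness_of_fit(f_obs[mask], pred_full[mask])

    hold_span = float(hold.time[-1] - hold.time[0])
    rel_amp = de / params.e0 if params.e0 > 0 else 0.0
    diagnostics: dict = {
        "window": window,
        "initial_guess": {"e0": e0_i, "einf": einf_i, "tau": tau_i},
        "n_loading": len(loading),
        "n_hold": len(hold),
        "relaxation_amplitude": float(rel_amp),
        "tau_identifiable": bool(rel_amp >= 0.01),
        "warnings": [],
    }
    if tau > hold_span / 2.0:
        diagnostics["warnings"].append(
            f"hold ({hold_span:.3g} s) is short relative to fitted tau ({tau:.3g} s)"
        )
    if not diagnostics["tau_identifiable"]:
        diagnostics["warnings"].append(
            "relaxation amplitude < 1% of E0: tau is not identifiable (material is "
            "effectively elastic)"
        )
    return ViscoFit(
        params=params,
        r_squared=r2,
        converged=bool(res.status > 0),
        iterations=int(res.nfev),
        diagnostics=diagnostics,
    )
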