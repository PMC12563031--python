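"""Contact mechanics for spherical indentation of soft, finite-thickness layers.

The forward models implemented here are the ones used to interpret
ramp-and-hold microindentation of hydrated collagen scaffolds with a
spherical probe:

* Hertzian contact of a rigid sphere on an (incompressible) elastic layer,
  with a multiplicative bottom-effect correction (BEC) that accounts for the
  stiffening caused by the rigid substrate beneath a thin sample,

      F(delta) = 4*sqrt(R)/(3*(1-nu^2)) * f_BEC(delta) * E * delta^(3/2)

* the standard linear solid (SLS) relaxation modulus

      E(t) = E_inf + (E0 - E_inf) * exp(-t/tau)

* the Lee–Radok hereditary integral, which generalizes the Hertz relation to
  linear viscoelastic materials for a monotonically loading depth history,

      F(t) = 4*sqrt(R)/(3*(1-nu^2)) *
             Integral_0^t f_BEC(delta(xi)) * E(t-xi) * d(delta^(3/2))/dxi dxi

All quantities are SI internally (m, s, Pa, N).  Unit conversion to
bench-friendly units (um, uN, kPa) happens at the I/O boundary, not here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "ProbeSpec",
    "SampleGeometry",
    "SLSParams",
    "DepthProtocol",
    "hertz_force",
    "bec_correction",
    "sls_relaxation_modulus",
    "lee_radok_force",
]

# Bottom-effect correction polynomials in chi = sqrt(R*delta)/h for an
# incompressible (nu = 0.5) layer on a rigid support.  "bonded": layer
# adheres to the substrate; "free": frictionless (non-bonded) contact.
_BEC_COEFFS = {
    "bonded": (1.133, 1.283, 0.769, 0.0975),
    "free": (0.884, 0.781, 0.386, 0.0048),
}


@dataclass(frozen=True)
class ProbeSpec:
    """Spherical indenter probe.

    Parameters
    ----------
    tip_radius : float
        Radius of the spherical tip in metres (R in the Hertz relation).
    cantilever_stiffness : float, optional
        Cantilever/actuator stiffness in N/m.  Metadata only; it does not
        enter the contact model (the instrument operates in
        displacement-control).
    """

    tip_radius: float
    cantilever_stiffness: float | None = None

    def __post_init__(self) -> None:
        if not (self.tip_radius > 0):
            raise ValueError(f"tip_radius must be > 0, got {self.tip_radius}")


@dataclass(frozen=True)
class SampleGeometry:
    """Sample thickness and Poisson's ratio.

    ``thickness=math.inf`` means a semi-infinite half-space (no bottom-effect
    correction).  ``bonded`` selects the bonded-layer BEC polynomial; set it
    to False for a layer resting freely on the substrate.
    """

    thickness: float = math.inf
    poisson_ratio: float = 0.5
    bonded: bool = True

    def __post_init__(self) -> None:
        if not (self.thickness > 0):
            raise ValueError(f"thickness must be > 0, got {self.thickness}")
        if not (0.0 <= self.poisson_ratio <= 0.5):
            raise ValueError(
                f"poisson_ratio must be in [0, 0.5], got {self.poisson_ratio}"
            )

    @property
    def semi_infinite(self) -> bool:
        return math.isinf(self.thickness)


@dataclass(frozen=True)
class SLSParams:
    """Standard-linear-solid parameters.

    e0
        Instantaneous Young's modulus E0 (Pa); response at t = 0.
    einf
        Long-term (equilibrium) Young's modulus E_inf (Pa); e0 >= einf > 0.
    tau
        Relaxation time in seconds.
    """

    e0: float
    einf: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.einf > 0):
            raise ValueError(f"einf must be > 0, got {self.einf}")
        if self.e0 < self.einf:
            raise ValueError(f"e0 ({self.e0}) must be >= einf ({self.einf})")
        if not (self.tau > 0):
            raise ValueError(f"tau must be > 0, got {self.tau}")


@dataclass(frozen=True)
class DepthProtocol:
    """Sampled indentation-depth history delta(t), with contact at t = 0.

    ``time`` must be strictly increasing and start at 0; ``depth`` must be
    nonnegative with depth[0] = 0 (time is initiated at the contact).
    A depth jump between consecutive samples is treated as a one-sample ramp
    (the limiting representation of a step).
    """

    time: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        d = np.asarray(self.depth, dtype=float)
        if t.ndim != 1 or t.shape != d.shape or t.size < 2:
            raise ValueError("time and depth must be 1-D arrays of equal length >= 2")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(d < 0):
            raise ValueError("depth must be nonnegative")
        if d[0] != 0:
            raise ValueError("depth must start at 0 (contact at t = 0)")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "depth", d)

    @classmethod
    def ramp_hold(
        cls,
        speed: float,
        max_depth: float,
        hold: float,
        sample_rate: float,
    ) -> "DepthProtocol":
        """Constant-rate ramp to ``max_depth`` (m) at ``speed`` (m/s),
        followed by a constant hold of ``hold`` seconds."""
        if min(speed, max_depth, hold, sample_rate) <= 0:
            raise ValueError("speed, max_depth, hold and sample_rate must be > 0")
        t_ramp = max_depth / speed
        n = int(round((t_ramp + hold) * sample_rate))
        t = np.arange(n + 1) / sample_rate
        d = np.minimum(t * speed, max_depth)
        return cls(t, d)

    @classmethod
    def step_hold(cls, depth: float, hold: float, sample_rate: float) -> "DepthProtocol":
        """Instantaneous step to ``depth`` then hold; the step is represented
        as a one-sample ramp over the first sampling interval."""
        if min(depth, hold, sample_rate) <= 0:
            raise ValueError("depth, hold and sample_rate must be > 0")
        n = int(round(hold * sample_rate))
        t = np.arange(n + 1) / sample_rate
        d = np.full(n + 1, depth)
        d[0] = 0.0
        return cls(t, d)


def _hertz_prefactor(probe: ProbeSpec, geometry: SampleGeometry) -> float:
    return 4.0 * math.sqrt(probe.tip_radius) / (3.0 * (1.0 - geometry.poisson_ratio**2))


def bec_correction(depth, probe: ProbeSpec, geometry: SampleGeometry):
    """Bottom-effect correction factor f_BEC(delta) >= 1.

    Evaluates the fourth-order polynomial in chi = sqrt(R*delta)/h for a
    layer of thickness h on a rigid support.  Returns 1 for a semi-infinite
    sample or at zero depth.  Accepts scalar or array depth.
    """
    d = np.asarray(depth, dtype=float)
    if np.any(d < 0):
        raise ValueError("depth must be nonnegative")
    if geometry.semi_infinite:
        out = np.ones_like(d)
        return float(out) if np.isscalar(depth) else out
    a1, a2, a3, a4 = _BEC_COEFFS["bonded" if geometry.bonded else "free"]
    chi = np.sqrt(probe.tip_radius * d) / geometry.thickness
    out = 1.0 + chi * (a1 + chi * (a2 + chi * (a3 + chi * a4)))
    return float(out) if np.isscalar(depth) else out


def hertz_force(depth, elastic_modulus: float, probe: ProbeSpec, geometry: SampleGeometry):
    """Hertz contact force (N) of a rigid sphere at indentation ``depth`` (m),
    including the bottom-effect correction for finite-thickness samples.

    F = 4*sqrt(R)/(3*(1-nu^2)) * f_BEC(delta) * E * delta^(3/2)
    """
    d = np.asarray(depth, dtype=float)
    if np.any(d < 0):
        raise ValueError("depth must be nonnegative")
    if not (elastic_modulus > 0):
        raise ValueError(f"elastic_modulus must be > 0, got {elastic_modulus}")
    f = (
        _hertz_prefactor(probe, geometry)
        * bec_correction(d, probe, geometry)
        * elastic_modulus
        * d**1.5
    )
    return float(f) if np.isscalar(depth) else f


def sls_relaxation_modulus(t, params: SLSParams):
    """SLS relaxation modulus E(t) = E_inf + (E0 - E_inf)*exp(-t/tau), Pa."""
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("t must be nonnegative")
    e = params.einf + (params.e0 - params.einf) * np.exp(-tt / params.tau)
    return float(e) if np.isscalar(t) else e


def lee_radok_force(
    protocol: DepthProtocol,
    params: SLSParams,
    probe: ProbeSpec,
    geometry: SampleGeometry,
    *,
    bec_with_derivative: bool = False,
) -> np.ndarray:
    """Force trace (N) of the Lee–Radok hereditary integral on ``protocol``.

    The integral is discretized interval-by-interval: the corrected
    d(delta^(3/2))/dxi rate is taken piecewise constant (its exact interval
    average), and the exponential SLS kernel is integrated exactly over each
    interval, so the elastic degenerate case E0 = E_inf is reproduced to
    machine precision and the scheme is second-order accurate in the grid
    spacing.

    By default the bottom-effect factor multiplies the depth-rate term with
    the instantaneous depth, f_BEC(delta(xi)) * d(delta^(3/2))/dxi.  With
    ``bec_with_derivative=True`` the integrand is d[f_BEC * delta^(3/2)]/dxi
    instead, which makes the elastic limit coincide with the corrected Hertz
    force also for finite-thickness samples.  The two forms are identical
    when the sample is semi-infinite.
    """
    t = protocol.time
    d = protocol.depth
    u = d**1.5
    dt = np.diff(t)

    if bec_with_derivative:
        v = bec_correction(d, probe, geometry) * u
        s = np.diff(v)  # interval increments of the corrected response
    else:
        d_mid = 0.5 * (d[:-1] + d[1:])
        s = bec_correction(d_mid, probe, geometry) * np.diff(u)

    einf, de, tau = params.einf, params.e0 - params.einf, params.tau

    # F_i = pref * (E_inf * A_i + dE * C_i) with
    # A_i = sum_{j<i} s_j  and  C_i = exp(-t_i/tau) * int_0^{t_i} e^{xi/tau} w dxi,
    # w piecewise-constant = s_j/dt_j.  C obeys the stable recursion
    # C_{i+1} = a_i C_i + w_i * tau * (1 - a_i),  a_i = exp(-dt_i/tau).
    a_elastic = np.concatenate(([0.0], np.cumsum(s)))
    if de == 0.0:
        c = np.zeros_like(a_elastic)
    else:
        w = s / dt
        a = np.exp(-dt / tau)
        drive = w * tau * (1.0 - a)
        if np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
            # uniform grid: C is a first-order IIR filter of the drive term
            c_tail = lfilter([1.0], [1.0, -a[0]], drive)
            c = np.concatenate(([0.0], c_tail))
        else:
            c = np.zeros(t.size)
            for i in range(dt.size):
                c[i + 1] = a[i] * c[i] + drive[i]
    return _hertz_prefactor(probe, geometry) * (einf * a_elastic + de * c)
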