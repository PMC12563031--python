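"""Shared fixtures and independent oracles.

The oracles deliberately use different numerics than the package (dense
trapezoidal quadrature, exhaustive threshold search) so agreement is a real
cross-check, not a tautology.
"""

from __future__ import annotations

import numpy as np
import pytest

from scaffoldkit.mechanics import (
    DepthProtocol,
    ProbeSpec,
    SampleGeometry,
    SLSParams,
    bec_correction,
    sls_relaxation_modulus,
)


def lee_radok_quadrature_oracle(
    protocol: DepthProtocol,
    params: SLSParams,
    probe: ProbeSpec,
    geometry: SampleGeometry,
    refine: int = 10,
) -> np.ndarray:
    """Brute-force hereditary integral on a ``refine``-times finer grid.

    Linearly interpolates the depth history onto the fine grid and evaluates
    the Stieltjes integral as a midpoint Riemann sum,
    F(t_i) = pref * sum_j fBEC(delta_mid,j) * E(t_i - xi_mid,j) * du_j,
    independently for every output time.  O(n^2), reference only.
    """
    t = protocol.time
    tf = np.linspace(t[0], t[-1], refine * (t.size - 1) + 1)
    df = np.interp(tf, t, protocol.depth)
    du = np.diff(df**1.5)
    xi_mid = 0.5 * (tf[:-1] + tf[1:])
    fbec = bec_correction(0.5 * (df[:-1] + df[1:]), probe, geometry)
    nu = geometry.poisson_ratio
    pref = 4.0 * np.sqrt(probe.tip_radius) / (3.0 * (1.0 - nu**2))
    out = np.zeros_like(t)
    for i, ti in enumerate(t):
        m = xi_mid < ti
        kernel = sls_relaxation_modulus(ti - xi_mid[m], params)
        out[i] = pref * np.sum(fbec[m] * kernel * du[m])
    return out


def isodata_fixed_points(data: np.ndarray) -> list[int]:
    """All integer thresholds T with round_half_up((mean(I<T)+mean(I>=T))/2) == T.

    Exhaustive search over the intensity lattice via histogram cumulative
    sums; the independent oracle for the Riddler–Calvard iteration.
    """
    flat = np.asarray(data).ravel()
    lo, hi = int(flat.min()), int(flat.max())
    counts = np.bincount(flat.astype(np.int64) - lo, minlength=hi - lo + 1)
    values = np.arange(lo, hi + 1, dtype=float)
    csum = np.cumsum(counts)
    wsum = np.cumsum(counts * values)
    fixed = []
    for t in range(lo + 1, hi + 1):
        n_low = csum[t - 1 - lo]
        n_high = csum[-1] - n_low
        if n_low == 0 or n_high == 0:
            continue
        mean_low = wsum[t - 1 - lo] / n_low
        mean_high = (wsum[-1] - wsum[t - 1 - lo]) / n_high
        if int(np.floor(0.5 * (mean_low + mean_high) + 0.5)) == t:
            fixed.append(t)
    return fixed


@pytest.fixture
def probe() -> ProbeSpec:
    return ProbeSpec(tip_radius=500e-6, cantilever_stiffness=12.0)


@pytest.fixture
def half_space() -> SampleGeometry:
    return SampleGeometry()


@pytest.fixture
def thin_layer() -> SampleGeometry:
    return SampleGeometry(thickness=1e-3)


@pytest.fixture
def sls_truth() -> SLSParams:
    return SLSParams(e0=30e3, einf=10e3, tau=5.0)
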