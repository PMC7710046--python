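"""Brute-force tip-lowering oracle, independent of the closed-form engine.

The tip surface (probe sphere capped by a tangent cone) is discretized along
its radial cross-section at fine lateral resolution.  For a tip axis at
lateral distance ``d`` from an atom centre, the tip is lowered until some
sampled surface point first touches the atom sphere; by axial symmetry the
contact happens in the plane containing the tip axis and the atom, so the
2-D cross-section suffices.

Tip cross-section height above the apex at radial offset s:

    f(s) = R - sqrt(R^2 - s^2)                      for s <= R*cos(alpha)
    f(s) = R*(1 - sin(alpha)) + (s - R*cos(alpha))/tan(alpha)   otherwise

A surface point at (s, f(s)) touches the atom sphere (radius r, centre
height z) from above when the apex is at

    h(s) = z + sqrt(r^2 - (s - d)^2) - f(s),   |s - d| <= r

and the first-contact apex height is max over s of h(s).
"""

import math

import numpy as np


def tip_profile(s: np.ndarray, R: float, alpha: float) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    s_t = R * math.cos(alpha)
    sphere = R - np.sqrt(np.maximum(R * R - s * s, 0.0))
    cone = R * (1.0 - math.sin(alpha)) + (s - s_t) / math.tan(alpha)
    return np.where(s <= s_t, sphere, cone)


def brute_collision_height(
    R: float,
    alpha: float,
    atom_z: float,
    atom_r: float,
    d: float,
    ds: float = 1e-4,
) -> float:
    """First-contact apex height for one atom by exhaustive surface sampling."""
    s_lo = max(0.0, d - atom_r)
    s_hi = d + atom_r
    n = max(3, int(math.ceil((s_hi - s_lo) / ds)) + 1)
    s = np.linspace(s_lo, s_hi, n)
    inside = np.abs(s - d) <= atom_r
    s = s[inside]
    lift = np.sqrt(np.maximum(atom_r**2 - (s - d) ** 2, 0.0))
    h = atom_z + lift - tip_profile(s, R, alpha)
    return float(h.max())


def brute_scan_cell(
    coords: np.ndarray,
    radii: np.ndarray,
    R: float,
    alpha: float,
    x: float,
    y: float,
    ds: float = 1e-4,
) -> float:
    """Stage-clamped brute-force height at one grid cell over many atoms."""
    best = 0.0
    for (ax, ay, az), ar in zip(coords, radii):
        d = math.hypot(x - ax, y - ay)
        best = max(best, brute_collision_height(R, alpha, az, ar, d, ds=ds))
    return best


def brute_scan_cell_vectorized(
    coords: np.ndarray,
    radii: np.ndarray,
    R: float,
    alpha: float,
    x: float,
    y: float,
    ds: float = 1e-4,
) -> float:
    """Same as brute_scan_cell; kept as an alias for clarity at call sites."""
    return brute_scan_cell(coords, radii, R, alpha, x, y, ds=ds)
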