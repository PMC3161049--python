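"""Sphere geometry and elementary osmotic bookkeeping.

Cells are treated as spheres throughout: measured diameters convert to
volumes as πd³/6, and the (fixed) membrane area is that of the sphere with
the isotonic volume.  All functions accept scalars or numpy arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "sphere_volume",
    "sphere_diameter",
    "sphere_area_from_volume",
    "water_volume",
    "osmoles",
]

_UM3_TO_L = 1e-15


def sphere_volume(diameter):
    """Volume (µm³) of a sphere of the given diameter (µm): πd³/6."""
    d = np.asarray(diameter, dtype=float)
    if np.any(d < 0):
        raise ValueError("diameter must be non-negative")
    v = np.pi * d**3 / 6.0
    return v.item() if np.isscalar(diameter) else v


def sphere_diameter(volume):
    """Diameter (µm) of the sphere with the given volume (µm³): (6V/π)^{1/3}."""
    v = np.asarray(volume, dtype=float)
    if np.any(v < 0):
        raise ValueError("volume must be non-negative")
    d = (6.0 * v / np.pi) ** (1.0 / 3.0)
    return d.item() if np.isscalar(volume) else d


def sphere_area_from_volume(volume):
    """Surface area (µm²) of the sphere with the given volume (µm³).

    A = (36π)^{1/3} V^{2/3}.
    """
    v = np.asarray(volume, dtype=float)
    if np.any(v < 0):
        raise ValueError("volume must be non-negative")
    a = (36.0 * np.pi) ** (1.0 / 3.0) * v ** (2.0 / 3.0)
    return a.item() if np.isscalar(volume) else a


def water_volume(cell_volume, V_b):
    """Osmotically active water volume: cell volume minus non-osmotic volume.

    Raises if any cell volume falls below V_b — that indicates a measurement
    or configuration inconsistency, not a physical state.
    """
    vc = np.asarray(cell_volume, dtype=float)
    vb = np.asarray(V_b, dtype=float)
    if np.any(vc < vb):
        raise ValueError(
            "cell volume below non-osmotic volume V_b; check measurements/config"
        )
    w = vc - vb
    return w.item() if np.isscalar(cell_volume) and np.isscalar(V_b) else w


def osmoles(M_iso, V_iso):
    """Intracellular osmoles N = M_iso · V_iso(in litres).

    Parameters are the isotonic osmolality (Osm/kg ≈ Osm/L) and the isotonic
    water volume in µm³; the µm³ → L factor is 1e-15.
    """
    m = np.asarray(M_iso, dtype=float)
    v = np.asarray(V_iso, dtype=float)
    if np.any(m < 0) or np.any(v < 0):
        raise ValueError("osmolality and water volume must be non-negative")
    n = m * v * _UM3_TO_L
    return n.item() if np.isscalar(M_iso) and np.isscalar(V_iso) else n
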