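"""Exact algebra of one-start helical symmetry.

A one-start helical filament is generated from a single asymmetric unit by
repeated application of a screw operator: rotate by the *twist* (degrees)
about the filament axis and translate by the *rise* (angstroms) along it.
The convention used throughout the package: the helical axis is ``z``, the
origin lies on the axis, and positive twist is a right-handed rotation.

Twist is normalized into ``(-180, 180]`` so that ``+180`` and ``-180``
denote the same operator; uromodulin-type filaments sit exactly at this
boundary (two subunits per turn), which is why the sign of the twist is
experimentally ill-determined there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "HelicalSymmetry",
    "PointSet",
    "FilamentModel",
    "normalize_twist",
    "enumerate_compatible_rises",
    "apply_symmetry",
    "pitch_and_units_per_turn",
    "axial_projection_period",
]


def normalize_twist(twist_degrees: float) -> float:
    """Map a twist angle onto the canonical interval ``(-180, 180]``."""
    t = math.fmod(float(twist_degrees), 360.0)
    if t > 180.0:
        t -= 360.0
    elif t <= -180.0:
        t += 360.0
    return t


@dataclass(frozen=True)
class HelicalSymmetry:
    """Screw operator of a one-start helix.

    Parameters
    ----------
    rise_angstrom:
        Axial translation per subunit, Å. Must be positive.
    twist_degrees:
        Rotation per subunit about the filament (z) axis, degrees.
        Normalized into ``(-180, 180]`` on construction; the sign encodes
        handedness (positive = right-handed under the package convention).
    """

    rise_angstrom: float
    twist_degrees: float

    def __post_init__(self) -> None:
        if not (self.rise_angstrom > 0):
            raise ValueError(f"rise must be > 0 Å, got {self.rise_angstrom}")
        object.__setattr__(
            self, "twist_degrees", normalize_twist(self.twist_degrees)
        )

    @property
    def twist_radians(self) -> float:
        return math.radians(self.twist_degrees)

    def rotation_matrix(self, k: int = 1) -> np.ndarray:
        """3x3 rotation matrix of ``k`` applications of the operator."""
        a = k * self.twist_radians
        c, s = math.cos(a), math.sin(a)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass
class PointSet:
    """Labeled 3D points with optional per-point mass (Da) and radius (Å).

    The light-weight carrier for asymmetric units, pseudo-atom models and
    coordinate selections. Coordinates are in Å.
    """

    coords: np.ndarray  # (N, 3)
    labels: Optional[Sequence[str]] = None
    masses: Optional[np.ndarray] = None
    radii: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.shape[-1] != 3:
            raise ValueError("coords must be (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.masses is not None:
            self.masses = np.asarray(self.masses, dtype=float)
            if self.masses.shape[0] != len(self):
                raise ValueError("masses length mismatch")
        if self.radii is not None:
            self.radii = np.asarray(self.radii, dtype=float)
            if np.any(self.radii < 0):
                raise ValueError("radii must be >= 0")

    def __len__(self) -> int:
        return self.coords.shape[0]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PointSet":
        new = self.coords @ rotation.T + translation
        return replace(self, coords=new)


@dataclass
class FilamentModel:
    """A filament as an asymmetric unit plus a helical operator.

    Subunit ``k`` occupies the asymmetric unit transformed by ``k``
    applications of the symmetry operator; ``n_subunits`` copies are taken
    symmetrically around ``k = 0``.
    """

    asymmetric_unit: PointSet
    symmetry: HelicalSymmetry
    n_subunits: int = 1

    def __post_init__(self) -> None:
        if self.n_subunits < 1:
            raise ValueError("n_subunits must be >= 1")

    def subunit_indices(self) -> range:
        half = self.n_subunits // 2
        return range(-half, self.n_subunits - half)

    def all_points(self) -> PointSet:
        """All subunits merged into a single point set."""
        parts = [apply_symmetry(self.asymmetric_unit, self.symmetry, k)
                 for k in self.subunit_indices()]
        coords = np.vstack([p.coords for p in parts])
        masses = (np.concatenate([p.masses for p in parts])
                  if self.asymmetric_unit.masses is not None else None)
        radii = (np.concatenate([p.radii for p in parts])
                 if self.asymmetric_unit.radii is not None else None)
        return PointSet(coords=coords, masses=masses, radii=radii)


def enumerate_compatible_rises(
    periodicity_angstrom: float, n_max: int
) -> list[float]:
    """Candidate rises compatible with an axial projection periodicity.

    If the projected density repeats every ``P`` Å along the axis, then any
    integer number ``n`` of subunits may span that repeat, giving candidate
    rises ``P/n`` for ``n = 1..n_max`` (descending). These seed the
    windowed twist/rise search.
    """
    if not (periodicity_angstrom > 0):
        raise ValueError(
            f"periodicity must be > 0 Å, got {periodicity_angstrom}"
        )
    if int(n_max) < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    return [periodicity_angstrom / n for n in range(1, int(n_max) + 1)]


def apply_symmetry(unit: PointSet, sym: HelicalSymmetry, k: int) -> PointSet:
    """Apply ``k`` copies of the screw operator (negative k = inverse)."""
    rot = sym.rotation_matrix(k)
    shift = np.array([0.0, 0.0, k * sym.rise_angstrom])
    return unit.transformed(rot, shift)


def pitch_and_units_per_turn(sym: HelicalSymmetry) -> tuple[float, float]:
    """Helical pitch (Å) and number of subunits per 360° turn.

    ``units_per_turn = 360 / |twist|`` and ``pitch = rise * units_per_turn``.
    A twist of zero has no finite pitch and is rejected.
    """
    if sym.twist_degrees == 0:
        raise ValueError("twist of 0° has no finite pitch")
    units = 360.0 / abs(sym.twist_degrees)
    return sym.rise_angstrom * units, units


def axial_projection_period(
    sym: HelicalSymmetry, tolerance_degrees: float = 1e-6
) -> tuple[float, bool]:
    """Smallest axial translation mapping the 2D projection onto itself.

    For a twist of ``360/m`` degrees (integer ``m``) the projected density
    repeats exactly every ``m * rise`` Å — e.g. two subunits per turn at
    180° twist gives a projection period of twice the rise. Returns
    ``(period, exact)``; when the twist is not commensurate with 360° within
    ``tolerance_degrees`` the helical pitch is returned with ``exact=False``.
    """
    pitch, units = pitch_and_units_per_turn(sym)
    m = round(units)
    if m >= 1 and abs(360.0 / m - abs(sym.twist_degrees)) <= tolerance_degrees:
        return m * sym.rise_angstrom, True
    return pitch, False


def export_pseudo_pdb(model: FilamentModel, path: str) -> None:
    """Write the filament as CA pseudo-atoms (one chain per subunit).

    Intended for visual inspection in a molecular viewer, not for
    refinement: every point becomes a carbon pseudo-atom.
    """
    import gemmi

    st = gemmi.Structure()
    st.name = "filament"
    mdl = gemmi.Model("1")
    chain_ids = (
        "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
    )
    for i, k in enumerate(model.subunit_indices()):
        unit = apply_symmetry(model.asymmetric_unit, model.symmetry, k)
        chain = gemmi.Chain(chain_ids[i % len(chain_ids)])
        for j, xyz in enumerate(unit.coords):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(j + 1, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*xyz)
            res.add_atom(atom)
            chain.add_residue(res)
        mdl.add_chain(chain)
    st.add_model(mdl)
    st.setup_entities()
    st.write_pdb(path)
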