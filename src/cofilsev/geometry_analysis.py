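"""Per-subunit geometric observables of a filament system.

The observables are the ones that distinguish bare from cofilin-decorated
actin and localise a decoration boundary:

* adjacent-subunit *twist* — rotation angle of the relative screw transform
  between consecutive subunits' inner-domain (SD3+SD4) Calpha sets;
* *flatness* dihedral ``phi`` — signed torsion over the four subdomain
  centers of mass, ordered (SD2, SD1, SD3, SD4), i.e. torsion about the
  SD1-SD3 axis separating the outer from the inner domain;
* *cleft distance* ``d`` — |COM(SD2) - COM(SD4)|;
* Calpha *contact counts* under a strict < cutoff (default 10 A);
* post-fit *RMSD* series against a reference frame or structure.

All angles are reported in degrees; twist as a magnitude in (0, 180].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from cofilsev.errors import (
    ConfigurationError,
    DomainError,
    InputError,
    StructuralError,
)
from cofilsev.filament_model import (
    ContactSpec,
    FilamentSystem,
    Subunit,
    center_of_mass,
    resolve_selection,
)


# -- low-level geometry ----------------------------------------------------

def signed_dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion angle (degrees) of four points, right-hand convention.

    Looking down the p1->p2 axis, a positive angle rotates the p0 projection
    clockwise onto the p3 projection (standard biomolecular torsion sign).
    """
    b1 = np.asarray(p1, float) - np.asarray(p0, float)
    b2 = np.asarray(p2, float) - np.asarray(p1, float)
    b3 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if norm_b2 == 0 or np.linalg.norm(n1) == 0 or np.linalg.norm(n2) == 0:
        raise DomainError("degenerate dihedral: collinear points")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / norm_b2))
    return float(np.degrees(np.arctan2(y, x)))


def rotation_angle(rotation: np.ndarray) -> float:
    """Rotation angle (degrees, in [0, 180]) of a 3x3 rotation matrix."""
    tr = float(np.trace(rotation))
    return float(np.degrees(np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))))


# -- result containers -----------------------------------------------------

@dataclass(frozen=True)
class SubunitGeometryRecord:
    """Internal conformation of one subunit in one frame."""

    position: int
    frame: int
    phi: float  # degrees, signed
    d: float    # Angstrom


@dataclass
class AngleProfile:
    """Per-position, per-frame values of an angular observable.

    ``values`` has shape (n_frames, n_positions); column order follows
    ``positions`` (sorted ascending).
    """

    name: str
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != self.positions.size:
            raise InputError("profile values do not match positions")
        order = np.argsort(self.positions)
        self.positions = self.positions[order]
        self.values = self.values[:, order]

    @property
    def n_frames(self) -> int:
        return int(self.values.shape[0])

    @property
    def position_mean(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def position_sd(self) -> np.ndarray:
        return self.values.std(axis=0)

    def to_frame(self) -> pd.DataFrame:
        frames, cols = np.meshgrid(
            np.arange(self.n_frames), np.arange(self.positions.size), indexing="ij"
        )
        return pd.DataFrame(
            {
                "frame": frames.ravel(),
                "position_n": self.positions[cols.ravel()],
                "value_deg": self.values.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, name: str = "angle") -> "AngleProfile":
        df = pd.read_csv(path)
        need = {"frame", "position_n", "value_deg"}
        if not need <= set(df.columns):
            raise InputError(f"profile CSV must have columns {sorted(need)}")
        pivot = df.pivot(index="frame", columns="position_n", values="value_deg")
        if pivot.isna().any().any():
            raise InputError("profile CSV is not a complete frame x position grid")
        return cls(name, pivot.columns.to_numpy(), pivot.to_numpy())


@dataclass
class ContactProfile:
    """Per-position, per-frame Calpha contact counts for one ContactSpec."""

    spec: ContactSpec
    positions: np.ndarray
    counts: np.ndarray  # (n_frames, n_positions), int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=int))
        if (self.counts < 0).any():
            raise InputError("negative contact counts")

    @property
    def n_frames(self) -> int:
        return int(self.counts.shape[0])

    @property
    def position_mean(self) -> np.ndarray:
        return self.counts.mean(axis=0)

    @property
    def position_sd(self) -> np.ndarray:
        return self.counts.std(axis=0)

    def to_frame(self) -> pd.DataFrame:
        frames, cols = np.meshgrid(
            np.arange(self.n_frames), np.arange(self.positions.size), indexing="ij"
        )
        return pd.DataFrame(
            {
                "frame": frames.ravel(),
                "position_n": self.positions[cols.ravel()],
                "n_contacts": self.counts.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class RmsdSeries:
    """Per-frame post-fit RMSD of a subunit-position selection."""

    selection: tuple[int, ...]
    reference: str
    values: np.ndarray  # (n_frames,), Angstrom

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": np.arange(len(self.values)), "rmsd_angstrom": self.values}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# -- helpers ---------------------------------------------------------------

def _frame_indices(system: FilamentSystem, frames: Sequence[int] | None) -> list[int]:
    if frames is None:
        return list(range(system.n_frames))
    idx = [int(f) for f in frames]
    bad = [f for f in idx if not 0 <= f < system.n_frames]
    if bad:
        raise InputError(f"frame indices out of range: {bad}")
    return idx


def _sel_coords(sub: Subunit, frame: int, name: str) -> np.ndarray:
    ids = resolve_selection(name, sub)
    return sub.coords[frame][sub.template.index_of(ids)]


def _actin_positions(system: FilamentSystem) -> list[int]:
    return [s.position for s in system.actins if s.template.kind == "actin"]


# -- observables -----------------------------------------------------------

def twist_profile(
    system: FilamentSystem,
    frames: Sequence[int] | None = None,
    method: str = "screw",
    core_selection: str = "inner",
) -> AngleProfile:
    """Adjacent-subunit twist magnitude per genetic-helix pair.

    For each consecutive pair (n, n+1) the value stored at position n is, in
    the default ``screw`` method, the rotation angle of the least-squares
    rigid transform taking subunit n+1's core (SD3+SD4) Calpha set onto
    subunit n's.  The ``projection`` method instead measures the azimuthal
    increment of subunit centroids about the filament's principal axis.
    """
    from cofilsev.boundary_builder import superpose

    pos = _actin_positions(system)
    if len(pos) < 2:
        raise InputError("twist profile needs at least two subunits")
    if method not in ("screw", "projection"):
        raise ConfigurationError(f"unknown twist method '{method}'")
    fidx = _frame_indices(system, frames)
    pairs = [n for n in pos[:-1] if n + 1 in pos]

    values = np.empty((len(fidx), len(pairs)))
    if method == "screw":
        for i, f in enumerate(fidx):
            for j, n in enumerate(pairs):
                a = _sel_coords(system.subunit(n), f, core_selection)
                b = _sel_coords(system.subunit(n + 1), f, core_selection)
                if a.shape != b.shape:
                    raise StructuralError(
                        f"pair ({n},{n + 1}): core selections differ in size"
                    )
                t = superpose(mobile=b, reference=a)
                values[i, j] = rotation_angle(t.rotation)
    else:
        for i, f in enumerate(fidx):
            coms = np.array(
                [center_of_mass(system.subunit(n).coords[f]) for n in pos]
            )
            az = _cylinder_azimuths(coms)
            for j, n in enumerate(pairs):
                k = pos.index(n)
                delta = (az[k + 1] - az[k] + 180.0) % 360.0 - 180.0
                values[i, j] = abs(delta)
    return AngleProfile("twist", np.array(pairs), values)


def _perp_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.eye(3)[np.argmin(np.abs(axis))]
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(axis, e1)


def _cylinder_azimuths(points: np.ndarray) -> np.ndarray:
    """Azimuths of points about a least-squares cylinder axis.

    The axis (direction + offset) is fitted by minimising the spread of
    point-to-axis distances, seeded by the principal component; on ideal
    helical data the fit is exact, so azimuth increments equal the true
    per-subunit rotation.
    """
    from scipy.optimize import least_squares

    c0 = points.mean(axis=0)
    centered = points - c0
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    a0 = vt[0]
    theta0, phi0 = np.arccos(np.clip(a0[2], -1, 1)), np.arctan2(a0[1], a0[0])

    def geometry(p):
        th, ph, off1, off2 = p
        axis = np.array(
            [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
        )
        e1, e2 = _perp_basis(axis)
        rel = points - (c0 + off1 * e1 + off2 * e2)
        rel_perp = rel - np.outer(rel @ axis, axis)
        return axis, e1, e2, rel_perp

    def residuals(p):
        radii = np.linalg.norm(geometry(p)[3], axis=1)
        return radii - radii.mean()

    fit = least_squares(
        residuals, x0=[theta0, phi0, 0.0, 0.0], xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    _, e1, e2, rel_perp = geometry(fit.x)
    return np.degrees(np.arctan2(rel_perp @ e2, rel_perp @ e1))


def flatness_and_cleft(
    system: FilamentSystem, frame: int, n: int
) -> SubunitGeometryRecord:
    """Flatness dihedral phi and cleft distance d of subunit ``n``.

    phi is the signed torsion over (COM(SD2), COM(SD1), COM(SD3), COM(SD4));
    d is the SD2-SD4 centroid distance (the nucleotide cleft).
    """
    sub = system.subunit(n)
    if sub.template.kind != "actin":
        raise DomainError(f"subunit {n} is not actin")
    coms = [
        center_of_mass(_sel_coords(sub, frame, sd))
        for sd in ("sd2", "sd1", "sd3", "sd4")
    ]
    phi = signed_dihedral(*coms)
    d = float(np.linalg.norm(coms[0] - coms[3]))
    return SubunitGeometryRecord(position=n, frame=frame, phi=phi, d=d)


def phi_profile(
    system: FilamentSystem, frames: Sequence[int] | None = None
) -> AngleProfile:
    """Per-subunit flatness dihedral as an :class:`AngleProfile`."""
    pos = _actin_positions(system)
    fidx = _frame_indices(system, frames)
    values = np.array(
        [[flatness_and_cleft(system, f, n).phi for n in pos] for f in fidx]
    )
    return AngleProfile("phi", np.array(pos), values)


def geometry_table(
    system: FilamentSystem, frames: Sequence[int] | None = None
) -> pd.DataFrame:
    """Long-form table of (frame, position_n, phi_deg, d_angstrom)."""
    rows = []
    for f in _frame_indices(system, frames):
        for n in _actin_positions(system):
            rec = flatness_and_cleft(system, f, n)
            rows.append((f, n, rec.phi, rec.d))
    return pd.DataFrame(rows, columns=["frame", "position_n", "phi_deg", "d_angstrom"])


def contact_count(
    system: FilamentSystem,
    frame: int,
    pair: tuple[int, int],
    spec: ContactSpec | None = None,
) -> int:
    """Number of Calpha pairs strictly closer than the cutoff.

    Pairs run over ``selection_a`` of the first subunit against
    ``selection_b`` of the second.
    """
    spec = spec or ContactSpec()
    a = _sel_coords(system.subunit(pair[0]), frame, spec.selection_a)
    b = _sel_coords(system.subunit(pair[1]), frame, spec.selection_b)
    return int(np.count_nonzero(cdist(a, b) < spec.cutoff))


def dloop_contact_profile(
    system: FilamentSystem,
    frames: Sequence[int] | None = None,
    spec: ContactSpec | None = None,
) -> ContactProfile:
    """D-loop contacts of each subunit with its pointed-end neighbor (n+2).

    By default counts the D-loop Calphas of subunit n against every Calpha of
    subunit n+2 under the 10 A cutoff; restrict ``spec.selection_b`` (e.g. to
    ``target_cleft``) for the narrower variant.
    """
    spec = spec or ContactSpec()
    pos = _actin_positions(system)
    if len(pos) < 3:
        raise InputError("D-loop contact profile needs at least three subunits")
    fidx = _frame_indices(system, frames)
    targets = [n for n in pos if n + 2 in pos]
    counts = np.array(
        [
            [contact_count(system, f, (n, n + 2), spec) for n in targets]
            for f in fidx
        ]
    )
    return ContactProfile(spec, np.array(targets), counts)


def interface_integrity(
    system: FilamentSystem, frame: int, cutoff: float = 10.0
) -> pd.DataFrame:
    """All-vs-all contact totals per longitudinal interface, with rupture flags.

    An interface (n, n+2) with zero Calpha pairs under the cutoff is flagged
    ruptured — the Calpha-level signature of a severed protofilament.
    """
    pos = _actin_positions(system)
    if len(pos) < 3:
        raise InputError("interface integrity needs at least three subunits")
    spec = ContactSpec(selection_a="all", selection_b="all", cutoff=cutoff)
    rows = []
    for n in pos:
        if n + 2 not in pos:
            continue
        c = contact_count(system, frame, (n, n + 2), spec)
        rows.append((n, n + 2, c, c == 0))
    return pd.DataFrame(
        rows, columns=["n_barbed", "n_pointed", "n_contacts", "ruptured"]
    )


def rmsd_series(
    system: FilamentSystem,
    selection: Iterable[int],
    reference: int | FilamentSystem = 0,
) -> RmsdSeries:
    """Post-superposition Calpha RMSD of selected subunits, per frame.

    ``reference`` is a frame index of ``system`` or an external system whose
    frame 0 supplies the reference coordinates for the same positions.
    """
    from cofilsev.boundary_builder import superpose

    sel = sorted(set(int(n) for n in selection))
    if not sel:
        raise InputError("empty position selection")
    subs = [system.subunit(n) for n in sel]
    if isinstance(reference, FilamentSystem):
        try:
            ref = np.concatenate([reference.subunit(n).coords[0] for n in sel])
        except Exception as exc:
            raise InputError(f"reference does not cover selection: {exc}") from exc
        ref_name = "external"
    else:
        if not 0 <= reference < system.n_frames:
            raise InputError(f"reference frame {reference} out of range")
        ref = np.concatenate([s.coords[reference] for s in subs])
        ref_name = f"frame {reference}"
    vals = np.empty(system.n_frames)
    for f in range(system.n_frames):
        mob = np.concatenate([s.coords[f] for s in subs])
        if mob.shape != ref.shape:
            raise InputError("selection/reference atom count mismatch")
        vals[f] = superpose(mobile=mob, reference=ref).rmsd_after
    return RmsdSeries(selection=tuple(sel), reference=ref_name, values=vals)


def per_position_stats(
    profile: AngleProfile | ContactProfile, last_k: int | None = None
) -> pd.DataFrame:
    """Mean and population SD over the trailing ``last_k`` frames per position.

    ``last_k=None`` uses half the frames (rounded up) — the analogue of
    summarising only the equilibrated tail of a trajectory.
    """
    data = profile.values if isinstance(profile, AngleProfile) else profile.counts
    nf = data.shape[0]
    if last_k is None:
        last_k = (nf + 1) // 2
    if last_k <= 0:
        raise ConfigurationError("last_k must be positive")
    if last_k > nf:
        raise ConfigurationError(f"last_k={last_k} exceeds {nf} frames")
    tail = data[nf - last_k:]
    return pd.DataFrame(
        {
            "position_n": profile.positions,
            "mean": tail.mean(axis=0),
            "sd": tail.std(axis=0),
        }
    )
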