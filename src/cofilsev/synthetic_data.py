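"""Synthetic filaments with prescribed geometry, standing in for MD ensembles.

The generator builds Calpha pseudo-subunits whose four subdomain clusters
are placed analytically so that the flatness dihedral phi and cleft distance
d measured by :mod:`cofilsev.geometry_analysis` equal the prescribed values
exactly, then stacks them on an ideal helix (per-subunit twist + rise, both
optionally position-dependent) and adds i.i.d. Gaussian coordinate noise per
frame to emulate thermal fluctuation statistics.  Cofilin placeholders are
compact pseudo-atom balls centered on the bridging site between SD2 of the
barbed-side and SD1 of the pointed-side bridged actin.

Geometry the generator emulates, and nothing more: helical symmetry,
position-dependent subunit conformation, D-loop protrusion/retraction
(present in bare-like templates, absent in cofilactin-like ones), bridging
occupancy, and per-frame Gaussian noise.  It makes no attempt at realistic
protein shape or dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from cofilsev.errors import ConfigurationError, GenerationError, TopologyError
from cofilsev.filament_model import (
    CofilinRecord,
    FilamentSystem,
    HelicalParams,
    ResidueSelections,
    Subunit,
    SubunitTemplate,
    center_of_mass,
)
from cofilsev.geometry_analysis import AngleProfile, signed_dihedral
from cofilsev.transition_fit import TransitionParams, evaluate_transition

# template construction constants (Angstrom)
_SD_OFFSET_R = 9.0       # lateral offset of SD2/SD4 from the SD1-SD3 axis
_SD_AXIAL_U = 3.0        # axial offset of SD2 above SD1 / SD4 below SD3
_RADIAL_RHO = 8.0        # subunit body offset from the filament axis
_MIN_AXIS_LEN = 6.0      # minimum SD1-SD3 separation before geometry fails
_CLUSTER_HALF = {        # uniform-box half-widths (x, y, z) per subdomain
    "sd1": (4.0, 4.0, 17.0),
    "sd2": (3.5, 3.5, 6.0),
    "sd3": (4.0, 4.0, 17.0),
    "sd4": (4.0, 4.0, 10.0),
}
_COFILIN_N_RESIDUES = 150
_COFILIN_RADIUS = 12.0

#: Generator defaults for the two canonical subunit conformations: flatness
#: asymptotes of the boundary transition model, representative cleft
#: distances, and D-loop extension (protruding for bare actin, retracted for
#: cofilactin, where cofilin displaces the D-loop contact).
BARE_CONFORMATION = {"phi": -9.0, "d": 25.0, "dloop_extension": 14.0}
COFILACTIN_CONFORMATION = {"phi": -28.9, "d": 23.0, "dloop_extension": 2.0}

#: Cryo-EM helical symmetries: per-subunit twist magnitude (deg) and rise (A).
BARE_HELICAL = HelicalParams(twist_per_subunit=167.0, rise_per_subunit=27.5)
COFILACTIN_HELICAL = HelicalParams(twist_per_subunit=162.0, rise_per_subunit=27.5)


@dataclass(frozen=True)
class NoiseModel:
    """Per-frame i.i.d. Gaussian coordinate noise."""

    coordinate_sd: float = 0.0  # Angstrom per Cartesian component
    n_frames: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coordinate_sd < 0:
            raise ConfigurationError("coordinate_sd must be non-negative")
        if self.n_frames < 1:
            raise ConfigurationError("n_frames must be at least 1")


def make_subunit_template(
    phi_target: float,
    d_target: float,
    seed: int = 0,
    dloop_extension: float = 14.0,
    conformation_label: str = "custom",
    selections: ResidueSelections | None = None,
) -> SubunitTemplate:
    """A 375-residue Calpha pseudo-subunit with exact phi and d.

    The four subdomain centroids are placed analytically: SD1 above SD3
    along the local (filament) z axis, SD2 offset laterally above SD1, and
    SD4 offset below SD3 at azimuth ``phi_target`` about the SD1-SD3 axis,
    with the axis length solved so the SD2-SD4 distance equals ``d_target``.
    Residues are scattered uniformly in boxes recentred on each centroid, so
    the measured dihedral and cleft distance equal the targets to machine
    precision.  D-loop residues (44-52) sit on a stalk extending toward the
    pointed end (+z) by ``dloop_extension``.
    """
    if abs(phi_target) >= 90.0:
        raise GenerationError("|phi_target| must be below 90 degrees")
    if d_target <= 0:
        raise GenerationError("d_target must be positive")
    sel = selections or ResidueSelections.default()
    phi_rad = np.radians(phi_target)
    arg = d_target**2 - 2.0 * _SD_OFFSET_R**2 * (1.0 - np.cos(phi_rad))
    min_span = _MIN_AXIS_LEN + 2.0 * _SD_AXIAL_U
    if arg <= min_span**2:
        raise GenerationError(
            f"d_target={d_target} too small for subdomain cluster geometry"
        )
    axis_len = float(np.sqrt(arg)) - 2.0 * _SD_AXIAL_U

    com_sd3 = np.array([_RADIAL_RHO, 0.0, 0.0])
    com_sd1 = com_sd3 + np.array([0.0, 0.0, axis_len])
    com_sd2 = com_sd1 + np.array([_SD_OFFSET_R, 0.0, _SD_AXIAL_U])
    com_sd4 = com_sd3 + np.array(
        [
            _SD_OFFSET_R * np.cos(phi_rad),
            _SD_OFFSET_R * np.sin(phi_rad),
            -_SD_AXIAL_U,
        ]
    )
    if abs(phi_target) > 1e-12:
        measured = signed_dihedral(com_sd2, com_sd1, com_sd3, com_sd4)
        if abs(measured - phi_target) > abs(measured + phi_target):
            com_sd4[1] = -com_sd4[1]  # flip chirality to match the convention

    rng = np.random.default_rng(seed)
    coords = np.empty((375, 3))

    def scatter(com: np.ndarray, ids: np.ndarray, half: tuple[float, float, float]) -> None:
        offsets = rng.uniform(-1.0, 1.0, size=(ids.size, 3)) * np.array(half)
        offsets -= offsets.mean(axis=0)
        coords[ids - 1] = com + offsets

    scatter(com_sd1, np.array(sorted(sel.sd1)), _CLUSTER_HALF["sd1"])
    scatter(com_sd3, np.array(sorted(sel.sd3)), _CLUSTER_HALF["sd3"])
    scatter(com_sd4, np.array(sorted(sel.sd4)), _CLUSTER_HALF["sd4"])

    # SD2: a scattered body plus the D-loop stalk, jointly recentred
    sd2_ids = np.array(sorted(sel.sd2))
    dloop_ids = np.array(sorted(sel.dloop))
    body_ids = np.array(sorted(sel.sd2 - sel.dloop))
    half = np.array(_CLUSTER_HALF["sd2"])
    offsets = np.empty((sd2_ids.size, 3))
    order = {rid: j for j, rid in enumerate(sd2_ids)}
    body_off = rng.uniform(-1.0, 1.0, size=(body_ids.size, 3)) * half
    for rid, off in zip(body_ids, body_off):
        offsets[order[rid]] = off
    stalk_t = np.linspace(0.0, 1.0, dloop_ids.size)
    jitter = rng.uniform(-0.5, 0.5, size=(dloop_ids.size, 2))
    for rid, t, (jx, jy) in zip(dloop_ids, stalk_t, jitter):
        offsets[order[rid]] = [2.0 + jx, jy, 6.0 + t * dloop_extension]
    offsets -= offsets.mean(axis=0)
    coords[sd2_ids - 1] = com_sd2 + offsets

    return SubunitTemplate(
        residue_ids=tuple(range(1, 376)),
        ca_coords=coords,
        kind="actin",
        conformation_label=conformation_label,
        selections=sel,
    )


def bare_template(seed: int = 0, **overrides) -> SubunitTemplate:
    """Bare-actin-like pseudo-subunit (flat, protruding D-loop)."""
    kw = {**BARE_CONFORMATION, **overrides}
    return make_subunit_template(
        kw["phi"], kw["d"], seed=seed,
        dloop_extension=kw["dloop_extension"], conformation_label="bare",
    )


def cofilactin_template(seed: int = 0, **overrides) -> SubunitTemplate:
    """Cofilactin-like pseudo-subunit (twisted, retracted D-loop)."""
    kw = {**COFILACTIN_CONFORMATION, **overrides}
    return make_subunit_template(
        kw["phi"], kw["d"], seed=seed,
        dloop_extension=kw["dloop_extension"], conformation_label="cofilactin",
    )


def _cofilin_template(seed: int) -> SubunitTemplate:
    rng = np.random.default_rng(seed)
    # uniform scatter in a ball, recentred so the centroid is exact
    pts = rng.normal(size=(_COFILIN_N_RESIDUES, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= _COFILIN_RADIUS * rng.uniform(0.0, 1.0, size=(_COFILIN_N_RESIDUES, 1)) ** (1 / 3)
    pts -= pts.mean(axis=0)
    return SubunitTemplate(
        residue_ids=tuple(range(1, _COFILIN_N_RESIDUES + 1)),
        ca_coords=pts,
        kind="cofilin",
        conformation_label="placeholder",
    )


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_filament(
    template_by_position: Mapping[int, SubunitTemplate],
    helical: HelicalParams = BARE_HELICAL,
    occupancy: set[int] | frozenset[int] = frozenset(),
    noise: NoiseModel | None = None,
    twist_by_position: Mapping[int, float] | None = None,
    periodic: bool = False,
) -> FilamentSystem:
    """Stack subunit templates on an ideal (possibly non-uniform) helix.

    Subunit n+1 is subunit n's template rotated by ``twist(n)`` about the
    filament (z) axis and raised by the per-subunit rise; ``twist(n)``
    defaults to the uniform helical value and may be overridden per position.
    Cofilins are placed for each key k in ``occupancy`` midway between
    SD2 of subunit k and SD1 of subunit k+2 (the periodic image when k+2 is
    one past the pointed end of a periodic system).  Frame f adds i.i.d.
    Gaussian noise from a seeded, frame-indexed stream.
    """
    noise = noise or NoiseModel()
    positions = sorted(template_by_position)
    if not positions:
        raise TopologyError("no subunit templates given")
    if positions != list(range(positions[0], positions[0] + len(positions))):
        raise TopologyError("template positions must be consecutive")
    p0, top = positions[0], positions[-1]

    def twist_at(n: int) -> float:
        if twist_by_position is not None and n in twist_by_position:
            return float(twist_by_position[n])
        return helical.twist_per_subunit

    # cumulative azimuth and rise per position, extended one past the end
    # so a periodic system can place its dangling cofilin's partner site
    azimuth: dict[int, float] = {p0: 0.0}
    for n in range(p0, top + 1):
        azimuth[n + 1] = azimuth[n] + twist_at(n)

    def placed(template: SubunitTemplate, n: int) -> np.ndarray:
        rot = _rot_z(azimuth[n])
        rise = np.array([0.0, 0.0, (n - p0) * helical.rise_per_subunit])
        return template.ca_coords @ rot.T + rise

    ideal_actin = {n: placed(template_by_position[n], n) for n in positions}

    cof_template_cache: dict[int, SubunitTemplate] = {}
    ideal_cof: dict[int, np.ndarray] = {}
    for k in sorted(occupancy):
        if k not in ideal_actin:
            raise TopologyError(f"occupancy key {k}: subunit absent")
        if k + 2 in ideal_actin:
            partner_template = template_by_position[k + 2]
            partner = ideal_actin[k + 2]
        elif periodic and k + 2 == top + 1:
            partner_template = template_by_position[p0]
            partner = placed(partner_template, top + 1)
        else:
            raise TopologyError(
                f"occupancy key {k}: pointed-side subunit {k + 2} absent"
            )
        sel_k = template_by_position[k].selections
        sd2_idx = template_by_position[k].index_of(sel_k.sd2)
        sd1_idx = partner_template.index_of(partner_template.selections.sd1)
        site = 0.5 * (
            center_of_mass(ideal_actin[k][sd2_idx])
            + center_of_mass(partner[sd1_idx])
        )
        tmpl = _cofilin_template(seed=noise.seed + 100_000 + k)
        cof_template_cache[k] = tmpl
        ideal_cof[k] = tmpl.ca_coords + site

    n_frames, sd = noise.n_frames, noise.coordinate_sd
    actins: list[Subunit] = []
    cofilins: dict[int, CofilinRecord] = {}

    def frames_for(ideal: np.ndarray, tag: int) -> np.ndarray:
        frames = np.empty((n_frames,) + ideal.shape)
        for f in range(n_frames):
            if sd == 0.0:
                frames[f] = ideal
            else:
                rng = np.random.default_rng([noise.seed, f, tag])
                frames[f] = ideal + rng.normal(0.0, sd, size=ideal.shape)
        return frames

    for n in positions:
        actins.append(
            Subunit(n, template_by_position[n], frames_for(ideal_actin[n], tag=n + 10_000))
        )
    for k, ideal in ideal_cof.items():
        cofilins[k] = CofilinRecord(
            k, cof_template_cache[k], frames_for(ideal, tag=k + 20_000)
        )
    return FilamentSystem(actins=actins, cofilins=cofilins, periodic=periodic)


def make_bare_filament(
    n_subunits: int = 18,
    helical: HelicalParams = BARE_HELICAL,
    noise: NoiseModel | None = None,
    seed: int = 0,
    start: int = 0,
) -> FilamentSystem:
    """Uniform bare-actin-like filament (no cofilins)."""
    tmpl = bare_template(seed=seed)
    return make_filament(
        {start + j: tmpl for j in range(n_subunits)}, helical=helical, noise=noise
    )


def make_cofilactin_filament(
    n_subunits: int = 11,
    helical: HelicalParams = COFILACTIN_HELICAL,
    noise: NoiseModel | None = None,
    seed: int = 0,
    start: int = 0,
    periodic: bool = True,
) -> FilamentSystem:
    """Fully decorated cofilactin filament.

    As one repeat of an effectively infinite (periodic) filament it carries
    ``n_subunits - 1`` cofilins keyed ``start .. start + n_subunits - 2``;
    the pointed-most cofilin bridges onto the periodic image.  With
    ``periodic=False`` only complete bridges are kept (``n_subunits - 2``).
    """
    tmpl = cofilactin_template(seed=seed)
    top = start + n_subunits - 1
    occupancy = set(range(start, top)) if periodic else set(range(start, top - 1))
    return make_filament(
        {start + j: tmpl for j in range(n_subunits)},
        helical=helical,
        occupancy=occupancy,
        noise=noise,
        periodic=periodic,
    )


def make_angle_profile(
    params: TransitionParams,
    positions: range | list[int],
    noise_sd: float = 0.0,
    n_frames: int = 1,
    seed: int = 0,
    name: str = "twist",
) -> AngleProfile:
    """Per-frame samples of the transition model plus Gaussian noise."""
    pos = np.array(sorted(int(n) for n in positions))
    if pos.size == 0:
        raise ConfigurationError("empty position range")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")
    truth = np.asarray(evaluate_transition(params, pos), dtype=float)
    rng = np.random.default_rng(seed)
    values = truth[None, :] + rng.normal(0.0, noise_sd, size=(n_frames, pos.size))
    return AngleProfile(name, pos, values)
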