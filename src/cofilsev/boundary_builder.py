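"""Boundary-model construction: superposition, splicing, replication, ablation.

A severing-boundary model is built by splicing a bare filament and a
cofilin-decorated (cofilactin) filament after rigid-body alignment:

* ``slow`` — the cofilin cluster ends at the *barbed* side of the boundary.
  Subunit i of the cofilactin structure is aligned onto subunit i of the
  bare structure by full-subunit Calpha superposition; the model keeps bare
  subunits i-8..i-1 and cofilactin subunits i..i+9 with the eight cofilins
  bridging wholly inside that segment.
* ``fast`` — the cluster ends at the *pointed* side.  The inner subdomains
  (SD3+SD4) of four subunits spanning i..i+3 from each input are pooled into
  one superposition; the model keeps cofilactin i-8..i+1 with its eight
  interior cofilins and bare i+2..i+9.  Because this construction leaves the
  interfacial D-loops short of their longitudinal partners, the output is
  flagged ``requires_relaxation``.
* ``fast_alt`` — the discarded alternative fast construction (interfacial
  subunit starts actin-like); provided for completeness.

Both spliced outputs contain 18 actins and (slow/fast) 8 cofilins with the
interfacial subunits i, i+1 each touching exactly one cofilin.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal

import numpy as np
from scipy.spatial.transform import Rotation

from cofilsev.errors import InputError, NumericalError, TopologyError
from cofilsev.filament_model import (
    BoundarySpec,
    CofilinRecord,
    FilamentSystem,
    Subunit,
    resolve_selection,
)

#: Maximum junction RMSD (A) for an input to count as periodic under
#: :func:`replicate_longitudinal`.
PERIODICITY_TOLERANCE = 0.5


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform ``x -> R x + t`` with its fit residual."""

    rotation: np.ndarray   # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd_after: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
            rmsd_after=0.0,
        )

    def power(self, k: int) -> "RigidTransform":
        out = RigidTransform(np.eye(3), np.zeros(3), 0.0)
        for _ in range(k):
            out = self.compose(out)
        return out


def superpose(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares optimal rigid superposition of ``mobile`` onto ``reference``.

    Kabsch superposition: returns the proper rotation and translation
    minimising the Calpha RMSD, together with the minimised RMSD.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape:
        raise InputError(f"point-count mismatch: {mob.shape} vs {ref.shape}")
    if mob.ndim != 2 or mob.shape[1] != 3 or mob.shape[0] < 3:
        raise InputError("superposition needs at least three 3-D points")
    cm, cr = mob.mean(axis=0), ref.mean(axis=0)
    mob_c, ref_c = mob - cm, ref - cr
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2 or np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise NumericalError("degenerate (collinear) point set")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    matrix = rot.as_matrix()
    # recompute the residual from coordinates: the optimiser's reported
    # residual loses precision to cancellation near zero
    rmsd = float(np.sqrt(np.mean(np.sum((mob_c @ matrix.T - ref_c) ** 2, axis=1))))
    return RigidTransform(
        rotation=matrix,
        translation=cr - matrix @ cm,
        rmsd_after=rmsd,
    )


def _transform_unit(unit, t: RigidTransform):
    coords = np.stack([t.apply(unit.coords[f]) for f in range(unit.coords.shape[0])])
    return replace(unit, coords=coords)


def _inner_coords(sub: Subunit, frame: int = 0) -> np.ndarray:
    ids = resolve_selection("inner", sub)
    return sub.coords[frame][sub.template.index_of(ids)]


def splice_boundary(
    bare: FilamentSystem,
    cofilactin: FilamentSystem,
    mode: Literal["slow", "fast", "fast_alt"],
) -> FilamentSystem:
    """Splice a bare and a cofilactin filament into a boundary model.

    Output positions run -8..9 with ``interfacial_index = 0``; the attached
    :class:`BoundarySpec` records the mode and the putative severing pairs.
    Alignment transforms are computed on frame 0 and applied to all frames.
    """
    if not cofilactin.cofilins:
        raise TopologyError("cofilactin input carries no cofilin occupancy")
    minima = {"slow": (9, 10), "fast": (10, 12), "fast_alt": (10, 9)}
    if mode not in minima:
        raise TopologyError(f"unknown splice mode '{mode}'")
    need_bare, need_cof = minima[mode]
    if len(bare.actins) < need_bare:
        raise TopologyError(
            f"{mode} splice needs at least {need_bare} bare subunits "
            f"(got {len(bare.actins)})"
        )
    if len(cofilactin.actins) < need_cof:
        raise TopologyError(
            f"{mode} splice needs at least {need_cof} cofilactin subunits "
            f"(got {len(cofilactin.actins)})"
        )
    bsubs, csubs = bare.actins, cofilactin.actins

    def shifted(sub: Subunit, new_pos: int) -> Subunit:
        return replace(sub, position=new_pos, coords=sub.coords.copy())

    actins: list[Subunit] = []
    cofilins: dict[int, CofilinRecord] = {}

    if mode == "slow":
        # cofilactin c0..c9 -> 0..9, aligned via full-subunit fit of c0 on b8
        t = superpose(mobile=csubs[0].coords[0], reference=bsubs[8].coords[0])
        for j, sub in enumerate(bsubs[:8]):
            actins.append(shifted(sub, -8 + j))
        for j, sub in enumerate(csubs[:10]):
            actins.append(shifted(_transform_unit(sub, t), j))
        kept = {s.position for s in csubs[:10]}
        offset = -csubs[0].position
        for k, rec in cofilactin.cofilins.items():
            if k in kept and k + 2 in kept:
                cofilins[k + offset] = CofilinRecord(
                    k + offset, rec.template, _transform_unit(rec, t).coords
                )
        counts = (8, 10)
        relax = False
    elif mode == "fast":
        # cofilactin c0..c9 -> -8..1; pooled inner-domain fit of bare b0..b3
        # onto cofilactin c8..c11 (the window spanning i..i+3)
        ref = np.concatenate([_inner_coords(s) for s in csubs[8:12]])
        mob = np.concatenate([_inner_coords(s) for s in bsubs[:4]])
        t = superpose(mobile=mob, reference=ref)
        for j, sub in enumerate(csubs[:10]):
            actins.append(shifted(sub, -8 + j))
        for j, sub in enumerate(bsubs[2:10]):
            actins.append(shifted(_transform_unit(sub, t), 2 + j))
        kept = {s.position for s in csubs[:10]}
        offset = -csubs[8].position
        for k, rec in cofilactin.cofilins.items():
            if k in kept and k + 2 in kept:
                cofilins[k + offset] = CofilinRecord(
                    k + offset, rec.template, rec.coords.copy()
                )
        counts = (8, 10)
        relax = True
    else:  # fast_alt
        # cofilactin c0..c7 -> -8..-1 via full-subunit fit of c8 on b0;
        # cofilins retained when both bridged positions exist in the output,
        # so the two topmost bridge into the bare segment.
        t = superpose(mobile=csubs[8].coords[0], reference=bsubs[0].coords[0])
        for j, sub in enumerate(csubs[:8]):
            actins.append(shifted(_transform_unit(sub, t), -8 + j))
        for j, sub in enumerate(bsubs[:10]):
            actins.append(shifted(sub, j))
        out_pos = {s.position for s in actins}
        offset = -csubs[8].position
        for k, rec in cofilactin.cofilins.items():
            nk = k + offset
            if nk in out_pos and nk + 2 in out_pos and nk < 0:
                cofilins[nk] = CofilinRecord(
                    nk, rec.template, _transform_unit(rec, t).coords
                )
        counts = (10, 8)
        relax = False

    spec = BoundarySpec(
        mode=mode,
        bare_count=counts[0],
        cofilactin_count=counts[1],
        cofilin_count=len(cofilins),
        interfacial_index=0,
        requires_relaxation=relax,
    )
    return FilamentSystem(
        actins=actins,
        cofilins=cofilins,
        periodic=False,
        interfacial_index=0,
        boundary=spec,
    )


def replicate_longitudinal(system: FilamentSystem, times: int) -> FilamentSystem:
    """Append ``times`` rigid copies of a periodic filament at its pointed end.

    The per-subunit screw transform is estimated from the first adjacent
    pair; the input must be periodic under it (every subunit predicted from
    subunit 0 to within :data:`PERIODICITY_TOLERANCE` RMSD).  Occupancy is
    replicated with keys shifted by one repeat per copy, so a fully
    decorated periodic cofilactin stays fully decorated across junctions —
    one repeat of an 11-subunit / 10-cofilin cofilactin yields the canonical
    22-subunit / 20-cofilin structure.
    """
    if times < 0:
        raise TopologyError("times must be non-negative")
    out = system.copy()
    if times == 0:
        return out
    subs = system.actins
    if len(subs) < 2:
        raise TopologyError("replication needs at least two subunits")
    n = len(subs)
    if any(s.template.n_residues != subs[0].template.n_residues for s in subs):
        raise TopologyError("non-periodic input: subunit residue counts differ")
    step = superpose(mobile=subs[0].coords[0], reference=subs[1].coords[0])
    for m, sub in enumerate(subs):
        pred = step.power(m).apply(subs[0].coords[0])
        rmsd = float(np.sqrt(np.mean(np.sum((pred - sub.coords[0]) ** 2, axis=1))))
        if rmsd > PERIODICITY_TOLERANCE:
            raise TopologyError(
                f"non-periodic input: subunit {sub.position} deviates "
                f"{rmsd:.2f} A from the helical prediction"
            )
    repeat = step.power(n)
    actins = list(out.actins)
    cofilins = dict(out.cofilins)
    for t in range(1, times + 1):
        t_rep = repeat.power(t)
        for sub in subs:
            actins.append(
                replace(_transform_unit(sub, t_rep), position=sub.position + t * n)
            )
        for k, rec in system.cofilins.items():
            nk = k + t * n
            cofilins[nk] = CofilinRecord(
                nk, rec.template, _transform_unit(rec, t_rep).coords
            )
    return FilamentSystem(
        actins=actins,
        cofilins=cofilins,
        periodic=system.periodic,
        interfacial_index=system.interfacial_index,
        boundary=system.boundary,
    )


def ablate_cofilins(system: FilamentSystem, keep: Iterable[int]) -> FilamentSystem:
    """Remove all cofilins except those keyed in ``keep``.

    Actin coordinates are untouched; the retained occupancy defines the
    surviving cofilin cluster(s) — e.g. ``{k, k+2}`` is a longitudinal pair,
    ``{k, k+1}`` a lateral one.
    """
    keep_set = {int(k) for k in keep}
    missing = keep_set - set(system.cofilins)
    if missing:
        raise TopologyError(f"keep references absent cofilins: {sorted(missing)}")
    out = system.copy()
    out.cofilins = {k: rec for k, rec in out.cofilins.items() if k in keep_set}
    return out


def cofilin_clusters(system: FilamentSystem) -> list[set[int]]:
    """Contiguous bound-cofilin clusters (keys within 2 are one cluster)."""
    keys = sorted(system.cofilins)
    clusters: list[set[int]] = []
    for k in keys:
        if clusters and k - max(clusters[-1]) <= 2:
            clusters[-1].add(k)
        else:
            clusters.append({k})
    return clusters
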