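"""Domain types and topology conventions for two-start helical actin filaments.

Indexing conventions used throughout the package:

* Subunit positions are consecutive integers along the genetic (single-start)
  helix.  The index increases toward the pointed end; "barbed side" means
  lower indices.
* With a genetic-helix twist near 167 deg, consecutive indices alternate
  between the two protofilaments, so longitudinal (same-strand) neighbors are
  ``n +/- 2`` and the lateral neighbor is ``n + 1``.
* A cofilin bridges two longitudinal actins and is keyed by the barbed-side
  member ``k`` of its bridged pair ``(k, k+2)``.
* Residue numbering is 1-based.  Units are Angstrom internally; the 1 nm
  contact cutoff is stored as 10 A.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping

import numpy as np

from cofilsev.errors import (
    ConfigurationError,
    DomainError,
    StructuralError,
    TopologyError,
)

N_ACTIN_RESIDUES = 375

#: Canonical four-subdomain partition of the 375-residue actin chain.
#: SD2 carries the DNase-I binding loop (D-loop); SD3+SD4 form the inner
#: domain that the filament's helical core is built from.
DEFAULT_SUBDOMAIN_RANGES: dict[str, tuple[tuple[int, int], ...]] = {
    "sd1": ((1, 32), (70, 137), (338, 375)),
    "sd2": ((33, 69),),
    "sd3": ((138, 180), (270, 337)),
    "sd4": ((181, 269),),
}

DEFAULT_DLOOP_RANGE: tuple[tuple[int, int], ...] = ((44, 52),)
DEFAULT_TARGET_CLEFT_RANGES: tuple[tuple[int, int], ...] = ((143, 148), (349, 351))

#: Contact cutoff, Angstrom (the field's conventional "< 1 nm" criterion).
DEFAULT_CONTACT_CUTOFF = 10.0


def _expand(ranges: Iterable[tuple[int, int]]) -> frozenset[int]:
    out: set[int] = set()
    for lo, hi in ranges:
        if lo > hi:
            raise ConfigurationError(f"empty residue range {lo}-{hi}")
        out.update(range(lo, hi + 1))
    return frozenset(out)


@dataclass(frozen=True)
class ResidueSelections:
    """Named residue-index sets (1-based, inclusive) on one actin subunit."""

    dloop: frozenset[int]
    target_cleft: frozenset[int]
    sd1: frozenset[int]
    sd2: frozenset[int]
    sd3: frozenset[int]
    sd4: frozenset[int]

    def __post_init__(self) -> None:
        for name in ("dloop", "target_cleft", "sd1", "sd2", "sd3", "sd4"):
            if not getattr(self, name):
                raise ConfigurationError(f"selection '{name}' is empty")
        sds = [self.sd1, self.sd2, self.sd3, self.sd4]
        union: set[int] = set()
        total = 0
        for s in sds:
            union.update(s)
            total += len(s)
        if total != len(union):
            raise ConfigurationError("subdomain selections overlap")
        if union != set(range(min(union), max(union) + 1)):
            raise ConfigurationError("subdomains do not cover a contiguous residue range")
        if not self.dloop <= self.sd2:
            raise ConfigurationError("D-loop must lie within subdomain 2")
        if min(union) < 1 or max(union) > N_ACTIN_RESIDUES:
            raise ConfigurationError(
                f"residue indices must lie in 1..{N_ACTIN_RESIDUES}"
            )

    @classmethod
    def default(cls) -> "ResidueSelections":
        return cls(
            dloop=_expand(DEFAULT_DLOOP_RANGE),
            target_cleft=_expand(DEFAULT_TARGET_CLEFT_RANGES),
            sd1=_expand(DEFAULT_SUBDOMAIN_RANGES["sd1"]),
            sd2=_expand(DEFAULT_SUBDOMAIN_RANGES["sd2"]),
            sd3=_expand(DEFAULT_SUBDOMAIN_RANGES["sd3"]),
            sd4=_expand(DEFAULT_SUBDOMAIN_RANGES["sd4"]),
        )

    @classmethod
    def from_ranges(cls, ranges: Mapping[str, Iterable[tuple[int, int]]]) -> "ResidueSelections":
        """Build selections from a mapping of name -> [(lo, hi), ...]."""
        merged = {
            "dloop": DEFAULT_DLOOP_RANGE,
            "target_cleft": DEFAULT_TARGET_CLEFT_RANGES,
            **DEFAULT_SUBDOMAIN_RANGES,
        }
        for name, rr in ranges.items():
            if name not in merged:
                raise ConfigurationError(f"unknown selection name '{name}'")
            merged[name] = tuple(tuple(r) for r in rr)  # type: ignore[assignment]
        return cls(**{k: _expand(v) for k, v in merged.items()})

    def named(self, name: str) -> frozenset[int]:
        derived = {
            "inner": self.sd3 | self.sd4,
            "outer": self.sd1 | self.sd2,
        }
        if name in derived:
            return frozenset(derived[name])
        if name in ("dloop", "target_cleft", "sd1", "sd2", "sd3", "sd4"):
            return getattr(self, name)
        raise ConfigurationError(f"unknown selection name '{name}'")


@dataclass(frozen=True)
class SubunitTemplate:
    """One subunit's reference Calpha coordinates with residue bookkeeping.

    ``ca_coords`` holds one (x, y, z) per residue in ``residue_ids`` order.
    Actin templates carry a full :class:`ResidueSelections`; cofilin
    placeholders have ``selections=None``.
    """

    residue_ids: tuple[int, ...]
    ca_coords: np.ndarray  # (n_res, 3), Angstrom
    kind: Literal["actin", "cofilin"]
    conformation_label: str = "custom"
    selections: ResidueSelections | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.ca_coords, dtype=float)
        object.__setattr__(self, "ca_coords", coords)
        if coords.shape != (len(self.residue_ids), 3):
            raise StructuralError(
                f"expected one coordinate per residue: {coords.shape} vs "
                f"{len(self.residue_ids)} residues"
            )
        if not np.isfinite(coords).all():
            raise StructuralError("non-finite template coordinates")
        if self.kind == "actin":
            sel = self.selections or ResidueSelections.default()
            object.__setattr__(self, "selections", sel)
            have = set(self.residue_ids)
            need = sel.sd1 | sel.sd2 | sel.sd3 | sel.sd4
            if not need <= have:
                missing = sorted(need - have)[:5]
                raise StructuralError(
                    f"actin template missing residues {missing}..."
                )

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def index_of(self, residue_ids: Iterable[int]) -> np.ndarray:
        """Array indices (into ``ca_coords``) of the given residue ids, sorted."""
        lookup = {rid: i for i, rid in enumerate(self.residue_ids)}
        try:
            return np.array([lookup[r] for r in sorted(residue_ids)], dtype=int)
        except KeyError as exc:
            raise StructuralError(f"residue {exc.args[0]} absent from subunit") from exc


@dataclass(frozen=True)
class HelicalParams:
    """Per-subunit helical symmetry: twist magnitude (deg) and rise (A)."""

    twist_per_subunit: float = 166.7
    rise_per_subunit: float = 27.5

    def __post_init__(self) -> None:
        if not 0.0 < self.twist_per_subunit <= 180.0:
            raise ConfigurationError("twist must be in (0, 180] degrees")
        if self.rise_per_subunit <= 0.0:
            raise ConfigurationError("rise must be positive")


@dataclass
class Subunit:
    """An actin subunit placed in the filament: position, template, frames."""

    position: int
    template: SubunitTemplate
    coords: np.ndarray  # (n_frames, n_res, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.shape[1:] != (self.template.n_residues, 3):
            raise StructuralError("subunit frames do not match template residue count")


@dataclass
class CofilinRecord:
    """A bound cofilin placeholder keyed by the barbed-side actin ``key``.

    Bridges actin positions ``(key, key + 2)``.
    """

    key: int
    template: SubunitTemplate
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]

    @property
    def bridged_pair(self) -> tuple[int, int]:
        return (self.key, self.key + 2)


@dataclass(frozen=True)
class BoundarySpec:
    """Description of a spliced bare/cofilactin boundary model."""

    mode: Literal["slow", "fast", "fast_alt"] | None
    bare_count: int
    cofilactin_count: int
    cofilin_count: int
    interfacial_index: int
    requires_relaxation: bool = False

    @property
    def putative_severing_pairs(self) -> list[tuple[int, int]]:
        return putative_severing_interface(self)


@dataclass(frozen=True)
class ContactSpec:
    """Which residue sets to count Calpha contacts between, and how."""

    selection_a: str = "dloop"
    selection_b: str = "all"
    cutoff: float = DEFAULT_CONTACT_CUTOFF
    partner_rule: Literal["longitudinal-pointed", "lateral", "explicit"] = (
        "longitudinal-pointed"
    )

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ConfigurationError("contact cutoff must be positive")


@dataclass
class FilamentSystem:
    """Ordered, polarity-aware filament: actin subunits plus bound cofilins.

    ``periodic`` marks a system that represents one repeat of an effectively
    infinite filament; in that case the pointed-most cofilin may bridge
    ``(n_max - 1, n_max + 1)`` where its pointed-side partner is the periodic
    image one repeat up.
    """

    actins: list[Subunit]
    cofilins: dict[int, CofilinRecord] = field(default_factory=dict)
    periodic: bool = False
    interfacial_index: int | None = None
    boundary: BoundarySpec | None = None

    def __post_init__(self) -> None:
        self.actins = sorted(self.actins, key=lambda s: s.position)
        self.validate()

    # -- structure queries -------------------------------------------------
    @property
    def positions(self) -> list[int]:
        return [s.position for s in self.actins]

    @property
    def n_frames(self) -> int:
        return int(self.actins[0].coords.shape[0]) if self.actins else 0

    def subunit(self, position: int) -> Subunit:
        for s in self.actins:
            if s.position == position:
                return s
        raise TopologyError(f"no subunit at position {position}")

    def has_position(self, position: int) -> bool:
        return any(s.position == position for s in self.actins)

    def cofilins_touching(self, position: int) -> list[CofilinRecord]:
        """Cofilin records whose bridged pair includes ``position``."""
        return [c for c in self.cofilins.values() if position in c.bridged_pair]

    def validate(self) -> None:
        if not self.actins:
            raise TopologyError("filament has no actin subunits")
        pos = self.positions
        if pos != list(range(pos[0], pos[0] + len(pos))):
            raise TopologyError(f"positions not consecutive: {pos}")
        nf = {int(s.coords.shape[0]) for s in self.actins}
        nf |= {int(c.coords.shape[0]) for c in self.cofilins.values()}
        if len(nf) > 1:
            raise TopologyError(f"inconsistent frame counts across subunits: {nf}")
        top = pos[-1]
        for k, rec in self.cofilins.items():
            if k != rec.key:
                raise TopologyError("cofilin record key mismatch")
            if not self.has_position(k):
                raise TopologyError(f"cofilin {k}: barbed-side actin absent")
            if not self.has_position(k + 2):
                # the single periodic-image dangler at the pointed end is legal
                if not (self.periodic and k + 2 == top + 1):
                    raise TopologyError(
                        f"cofilin {k}: pointed-side actin {k + 2} absent"
                    )

    def copy(self) -> "FilamentSystem":
        return FilamentSystem(
            actins=[replace(s, coords=s.coords.copy()) for s in self.actins],
            cofilins={
                k: CofilinRecord(k, c.template, c.coords.copy())
                for k, c in self.cofilins.items()
            },
            periodic=self.periodic,
            interfacial_index=self.interfacial_index,
            boundary=self.boundary,
        )


# -- topology operations ---------------------------------------------------

def resolve_selection(name: str, subunit: SubunitTemplate | Subunit) -> frozenset[int]:
    """Resolve a named residue selection on an actin subunit.

    ``"all"`` resolves to every residue of the subunit (any kind); the actin
    selections (``dloop``, ``target_cleft``, ``sd1..sd4``, ``inner``,
    ``outer``) require an actin template carrying them.
    """
    template = subunit.template if isinstance(subunit, Subunit) else subunit
    if name == "all":
        return frozenset(template.residue_ids)
    if template.kind != "actin" or template.selections is None:
        raise StructuralError(
            f"selection '{name}' requires an actin subunit (got {template.kind})"
        )
    resolved = template.selections.named(name)
    missing = resolved - set(template.residue_ids)
    if missing:
        raise StructuralError(
            f"selection '{name}' references residues absent from subunit: "
            f"{sorted(missing)[:5]}"
        )
    return resolved


def neighbor(
    system: FilamentSystem,
    n: int,
    rule: Literal["longitudinal-pointed", "longitudinal-barbed", "lateral"],
) -> int | None:
    """Neighbor position of subunit ``n`` under the genetic-helix convention.

    Longitudinal (same protofilament) neighbors are two genetic-helix steps
    away; the lateral neighbor is the next index.  Returns ``None`` when the
    neighbor falls outside the system.
    """
    if not system.has_position(n):
        raise TopologyError(f"position {n} not in system")
    offsets = {
        "longitudinal-pointed": 2,
        "longitudinal-barbed": -2,
        "lateral": 1,
    }
    if rule not in offsets:
        raise ConfigurationError(f"unknown neighbor rule '{rule}'")
    m = n + offsets[rule]
    return m if system.has_position(m) else None


def putative_severing_interface(spec: BoundarySpec) -> list[tuple[int, int]]:
    """Longitudinal interfaces most likely to sever for a boundary model.

    Severing is expected where bare-like subunits meet the interfacial
    subunits ``i``, ``i+1``: on their barbed side for a slow-severing boundary
    and on their pointed side for a fast-severing one.
    """
    if spec.mode is None:
        raise ConfigurationError("boundary mode is unset")
    i = spec.interfacial_index
    if spec.mode == "slow":
        return [(i - 2, i), (i - 1, i + 1)]
    if spec.mode in ("fast", "fast_alt"):
        return [(i, i + 2), (i + 1, i + 3)]
    raise ConfigurationError(f"unknown boundary mode '{spec.mode}'")


def center_of_mass(coords: np.ndarray) -> np.ndarray:
    """Uniform-weight centroid of a (n, 3) Calpha coordinate array."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] == 0:
        raise DomainError("centroid requires a non-empty (n, 3) array")
    return coords.mean(axis=0)
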