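"""Read/write filament systems as multi-model PDB files (via gemmi).

Layout convention: one chain per subunit.  Actin chains come first in
position order, then cofilin chains in key order, with chain IDs drawn from
``A-Z a-z 0-9``.  Frames map to ``MODEL``/``ENDMDL`` records.  Only Calpha
atoms are written (the whole package is a Calpha-level model); occupancy is
1.00 and B-factor 0.00.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from cofilsev.errors import FormatError, StructuralError
from cofilsev.filament_model import (
    CofilinRecord,
    FilamentSystem,
    ResidueSelections,
    Subunit,
    SubunitTemplate,
)

CHAIN_ID_POOL = string.ascii_uppercase + string.ascii_lowercase + string.digits

#: Auto chain classification: actin chains carry >= this many residues.
ACTIN_MIN_RESIDUES = 300
#: ... and cofilin placeholders fewer than this many.
COFILIN_MAX_RESIDUES = 200


@dataclass
class ChainMap:
    """chain id -> (subunit position or cofilin key, kind)."""

    chains: dict[str, tuple[int, str]] = field(default_factory=dict)
    periodic: bool = False
    interfacial_index: int | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "chains": {cid: list(v) for cid, v in self.chains.items()},
            "periodic": self.periodic,
            "interfacial_index": self.interfacial_index,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ChainMap":
        payload = json.loads(Path(path).read_text())
        return cls(
            chains={cid: (int(p), str(k)) for cid, (p, k) in payload["chains"].items()},
            periodic=bool(payload.get("periodic", False)),
            interfacial_index=payload.get("interfacial_index"),
        )


def default_chain_map(system: FilamentSystem) -> ChainMap:
    """The chain assignment :func:`write_system` uses for this system."""
    n_chains = len(system.actins) + len(system.cofilins)
    if n_chains > len(CHAIN_ID_POOL):
        raise FormatError(
            f"{n_chains} chains exceed the {len(CHAIN_ID_POOL)} single-character "
            "PDB chain IDs; split the system across files"
        )
    chains: dict[str, tuple[int, str]] = {}
    idx = 0
    for sub in system.actins:
        chains[CHAIN_ID_POOL[idx]] = (sub.position, "actin")
        idx += 1
    for key in sorted(system.cofilins):
        chains[CHAIN_ID_POOL[idx]] = (key, "cofilin")
        idx += 1
    return ChainMap(
        chains=chains,
        periodic=system.periodic,
        interfacial_index=system.interfacial_index,
    )


def write_system(system: FilamentSystem, path: str | Path) -> ChainMap:
    """Write a filament as a standard (multi-model) PDB file.

    Returns the :class:`ChainMap` used, so callers can persist it (the CLI
    writes it as a ``.chains.json`` sidecar) for lossless re-reading.
    """
    if not system.actins:
        raise FormatError("refusing to write an empty system")
    chain_map = default_chain_map(system)
    by_chain: list[tuple[str, Subunit | CofilinRecord]] = []
    it = iter(chain_map.chains.items())
    for sub in system.actins:
        cid, _ = next(it)
        by_chain.append((cid, sub))
    for key in sorted(system.cofilins):
        cid, _ = next(it)
        by_chain.append((cid, system.cofilins[key]))

    st = gemmi.Structure()
    st.name = "cofilsev filament"
    for f in range(system.n_frames):
        model = gemmi.Model(f + 1)
        for cid, unit in by_chain:
            chain = gemmi.Chain(cid)
            for r, rid in enumerate(unit.template.residue_ids):
                res = gemmi.Residue()
                res.name = "ALA"
                res.seqid = gemmi.SeqId(int(rid), " ")
                atom = gemmi.Atom()
                atom.name = "CA"
                atom.element = gemmi.Element("C")
                x, y, z = unit.coords[f, r]
                atom.pos = gemmi.Position(float(x), float(y), float(z))
                atom.occ = 1.0
                atom.b_iso = 0.0
                res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
    return chain_map


def _auto_chain_map(frames: dict[str, np.ndarray], order: list[str]) -> ChainMap:
    """Infer positions/kinds from chain sizes and geometry.

    Actin chains are identified by residue count (>= 300), cofilins by
    (< 200).  Actin positions are assigned by projecting chain centroids onto
    the filament's principal axis, oriented so that position increases with
    the chains' file order on average (our writer emits barbed -> pointed).
    Cofilin keys pick the bridged pair whose SD-level midpoint is nearest.
    """
    actin_ids = [c for c in order if len(frames[c]) >= ACTIN_MIN_RESIDUES]
    cof_ids = [c for c in order if len(frames[c]) < COFILIN_MAX_RESIDUES]
    odd = set(order) - set(actin_ids) - set(cof_ids)
    if odd:
        raise FormatError(
            f"chains {sorted(odd)} have ambiguous residue counts for auto mapping"
        )
    if not actin_ids:
        raise FormatError("no actin-sized chains found for auto mapping")
    coms = np.array([frames[c].mean(axis=0) for c in actin_ids])
    centered = coms - coms.mean(axis=0)
    if len(actin_ids) > 1:
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
        proj = centered @ axis
        if np.corrcoef(proj, np.arange(len(proj)))[0, 1] < 0:
            proj = -proj
    else:
        proj = np.zeros(1)
    rank = np.argsort(np.argsort(proj))
    chains: dict[str, tuple[int, str]] = {
        cid: (int(rank[j]), "actin") for j, cid in enumerate(actin_ids)
    }
    pos_of = {cid: int(rank[j]) for j, cid in enumerate(actin_ids)}
    com_of = {pos_of[c]: coms[j] for j, c in enumerate(actin_ids)}
    top = max(com_of)
    # candidate bridging sites: midpoints of complete (k, k+2) pairs, plus an
    # extrapolated site for k = top-1 whose partner is the periodic image
    sites: dict[int, np.ndarray] = {
        k: 0.5 * (com_of[k] + com_of[k + 2])
        for k in com_of
        if k + 2 in com_of
    }
    if top - 1 in com_of and top - 3 in com_of:
        sites[top - 1] = com_of[top - 1] + 0.5 * (com_of[top - 1] - com_of[top - 3])
    periodic = False
    for cid in cof_ids:
        ccom = frames[cid].mean(axis=0)
        if not sites:
            raise FormatError(f"cannot place cofilin chain {cid}: no bridged pair")
        best = min(sites, key=lambda k: float(np.linalg.norm(ccom - sites[k])))
        if any(v == (best, "cofilin") for v in chains.values()):
            raise FormatError(
                f"cofilin chains collide at bridging key {best} during auto mapping"
            )
        if best + 2 not in com_of:
            periodic = True
        chains[cid] = (best, "cofilin")
    return ChainMap(chains=chains, periodic=periodic)


def read_system(
    path: str | Path,
    chain_map: ChainMap | str = "auto",
    selections: ResidueSelections | None = None,
) -> FilamentSystem:
    """Read a (multi-model) PDB file as a :class:`FilamentSystem`.

    ``chain_map`` maps chains to subunit positions and kinds; ``"auto"``
    infers the mapping (see :func:`_auto_chain_map`).  Every residue must
    carry a Calpha atom; models must agree in atom content.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise FormatError(f"{path}: no models in file")

    per_frame: list[dict[str, np.ndarray]] = []
    resids: dict[str, list[int]] = {}
    order: list[str] = []
    for mi, model in enumerate(st):
        frame: dict[str, np.ndarray] = {}
        for chain in model:
            ids, xyz = [], []
            for res in chain:
                ca = res.find_atom("CA", "*")
                if ca is None:
                    raise StructuralError(
                        f"{path}: chain {chain.name} residue {res.seqid.num} "
                        "has no CA atom"
                    )
                ids.append(int(res.seqid.num))
                xyz.append([ca.pos.x, ca.pos.y, ca.pos.z])
            frame[chain.name] = np.array(xyz, dtype=float)
            if mi == 0:
                resids[chain.name] = ids
                order.append(chain.name)
            elif resids.get(chain.name) != ids:
                raise FormatError(
                    f"{path}: model {model.num} disagrees with model 1 in "
                    f"chain {chain.name}"
                )
        if mi > 0 and set(frame) != set(per_frame[0]):
            raise FormatError(f"{path}: models contain different chains")
        per_frame.append(frame)

    if chain_map == "auto":
        cmap = _auto_chain_map(per_frame[0], order)
    else:
        cmap = chain_map
        missing = set(order) - set(cmap.chains)
        if missing:
            raise FormatError(
                f"{path}: chains {sorted(missing)} absent from chain map"
            )

    actins: list[Subunit] = []
    cofilins: dict[int, CofilinRecord] = {}
    for cid in order:
        pos, kind = cmap.chains[cid]
        coords = np.stack([f[cid] for f in per_frame])
        template = SubunitTemplate(
            residue_ids=tuple(resids[cid]),
            ca_coords=coords[0],
            kind=kind,  # type: ignore[arg-type]
            selections=selections if kind == "actin" else None,
        )
        if kind == "actin":
            actins.append(Subunit(pos, template, coords))
        else:
            cofilins[pos] = CofilinRecord(pos, template, coords)

    return FilamentSystem(
        actins=actins,
        cofilins=cofilins,
        periodic=cmap.periodic,
        interfacial_index=cmap.interfacial_index,
    )
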