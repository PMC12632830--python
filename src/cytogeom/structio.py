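"""Structure I/O and chain-role annotation.

This module reads and writes macromolecular structures (PDB / mmCIF via
gemmi) and attaches the chain-role metadata the geometry engine needs:
which chain is the fixed receptor, which is the mobile receptor, which
chains are binders or scaffold, and which residue of each receptor is the
membrane-proximal anchor whose Cα defines the inter-receptor distance.

Conventions
-----------
* Author residue numbering is used throughout; insertion codes are appended
  to the residue number to form a composite string key (``"72"``, ``"72A"``).
  Integer residue selectors are accepted anywhere and normalised.
* Hydrogens are dropped on load by default; every distance computation in
  the toolkit uses heavy atoms only.
* Alternate locations resolve to the highest-occupancy conformer
  (tie broken toward altloc ``A``).
* Multi-model files use model 1 only (logged).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger("cytogeom")

__all__ = [
    "AtomRecord",
    "ChainRoleMap",
    "ComplexModel",
    "RoleResolutionError",
    "StructureFormatError",
    "SelectionError",
    "load_structure",
    "write_structure",
    "crop_by_proximity",
    "block_positions",
]

#: atoms retained when a residue is mutated to placeholder geometry
_BACKBONE_PLUS_CB = {"N", "CA", "C", "O", "CB"}

_HYDROGEN_ELEMENTS = {"H", "D"}


class StructureFormatError(ValueError):
    """File could not be parsed under the requested coordinate format."""


class RoleResolutionError(KeyError):
    """A chain-role entry does not resolve against the structure."""


class SelectionError(ValueError):
    """A residue/atom selection does not resolve against the structure."""


def reskey(residue: int | str) -> str:
    """Normalise a residue selector to the composite string key."""
    return str(residue).strip()


@dataclass(frozen=True)
class AtomRecord:
    """A single atom, author numbering, position in Å."""

    chain_id: str
    residue_index: str
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray
    is_heavy: bool = True


@dataclass(frozen=True)
class ChainRoleMap:
    """Assignment of structural roles to chains.

    ``membrane_anchor_fixed`` / ``membrane_anchor_mobile`` select the
    membrane-proximal terminal residue of each receptor chain, whose Cα is
    the reference point for the inter-receptor distance descriptor.
    """

    fixed_receptor: str
    mobile_receptor: str
    membrane_anchor_fixed: tuple[str, str]
    membrane_anchor_mobile: tuple[str, str]
    binders: tuple[str, ...] = ()
    scaffold: str | None = None

    def __post_init__(self) -> None:
        if self.fixed_receptor == self.mobile_receptor:
            raise ValueError("fixed_receptor and mobile_receptor must differ")
        object.__setattr__(self, "binders", tuple(self.binders))
        object.__setattr__(
            self,
            "membrane_anchor_fixed",
            (self.membrane_anchor_fixed[0], reskey(self.membrane_anchor_fixed[1])),
        )
        object.__setattr__(
            self,
            "membrane_anchor_mobile",
            (self.membrane_anchor_mobile[0], reskey(self.membrane_anchor_mobile[1])),
        )

    @property
    def receptor_chains(self) -> tuple[str, str]:
        return (self.fixed_receptor, self.mobile_receptor)

    def all_chains(self) -> tuple[str, ...]:
        chains = [self.fixed_receptor, self.mobile_receptor, *self.binders]
        if self.scaffold is not None:
            chains.append(self.scaffold)
        return tuple(chains)

    def to_dict(self) -> dict:
        return {
            "fixed_receptor": self.fixed_receptor,
            "mobile_receptor": self.mobile_receptor,
            "binders": list(self.binders),
            "scaffold": self.scaffold,
            "membrane_anchor_fixed": list(self.membrane_anchor_fixed),
            "membrane_anchor_mobile": list(self.membrane_anchor_mobile),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChainRoleMap":
        return cls(
            fixed_receptor=d["fixed_receptor"],
            mobile_receptor=d["mobile_receptor"],
            binders=tuple(d.get("binders") or ()),
            scaffold=d.get("scaffold"),
            membrane_anchor_fixed=tuple(d["membrane_anchor_fixed"]),
            membrane_anchor_mobile=tuple(d["membrane_anchor_mobile"]),
        )


@dataclass
class ComplexModel:
    """An atomic structure with chain roles and designability annotations.

    Atoms are stored column-wise in parallel arrays for fast geometry;
    :meth:`atoms` yields per-atom records when a row view is convenient.
    """

    chain_ids: np.ndarray          # object array of str
    residue_ids: np.ndarray        # object array of composite residue keys
    residue_names: np.ndarray      # object array of 3-letter codes
    atom_names: np.ndarray         # object array
    elements: np.ndarray           # object array
    coords: np.ndarray             # (n, 3) float64, Å
    roles: ChainRoleMap
    blocked_positions: set[tuple[str, str]] = field(default_factory=set)
    designable_extensions: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if not np.isfinite(self.coords).all():
            raise ValueError("atom positions must be finite")

    # -- basic views ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def copy(self) -> "ComplexModel":
        return ComplexModel(
            chain_ids=self.chain_ids.copy(),
            residue_ids=self.residue_ids.copy(),
            residue_names=self.residue_names.copy(),
            atom_names=self.atom_names.copy(),
            elements=self.elements.copy(),
            coords=self.coords.copy(),
            roles=self.roles,
            blocked_positions=set(self.blocked_positions),
            designable_extensions=set(self.designable_extensions),
        )

    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(self.n_atoms):
            yield AtomRecord(
                chain_id=self.chain_ids[i],
                residue_index=self.residue_ids[i],
                residue_name=self.residue_names[i],
                atom_name=self.atom_names[i],
                element=self.elements[i],
                position=self.coords[i],
            )

    def present_chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c, None)
        return list(seen)

    def chain_mask(self, chains: str | Iterable[str]) -> np.ndarray:
        if isinstance(chains, str):
            chains = {chains}
        chains = set(chains)
        return np.fromiter((c in chains for c in self.chain_ids), bool, self.n_atoms)

    def ca_mask(self) -> np.ndarray:
        return np.fromiter((a == "CA" for a in self.atom_names), bool, self.n_atoms)

    def subset(self, mask: np.ndarray) -> "ComplexModel":
        """New model with only atoms selected by ``mask`` (roles kept)."""
        kept = {(c, r) for c, r in zip(self.chain_ids[mask], self.residue_ids[mask])}
        return ComplexModel(
            chain_ids=self.chain_ids[mask],
            residue_ids=self.residue_ids[mask],
            residue_names=self.residue_names[mask],
            atom_names=self.atom_names[mask],
            elements=self.elements[mask],
            coords=self.coords[mask],
            roles=self.roles,
            blocked_positions={p for p in self.blocked_positions if p in kept},
            designable_extensions={p for p in self.designable_extensions if p in kept},
        )

    def residues_of_chain(self, chain: str) -> list[str]:
        """Residue keys of a chain, in atom order."""
        seen: dict[str, None] = {}
        for c, r in zip(self.chain_ids, self.residue_ids):
            if c == chain:
                seen.setdefault(r, None)
        return list(seen)

    def residue_set(self) -> set[tuple[str, str]]:
        return set(zip(self.chain_ids, self.residue_ids))

    def chain_ca_coords(self, chain: str) -> np.ndarray:
        m = self.chain_mask(chain) & self.ca_mask()
        return self.coords[m]

    def chain_ca_centroid(self, chain: str) -> np.ndarray:
        ca = self.chain_ca_coords(chain)
        if len(ca) == 0:
            raise RoleResolutionError(f"chain {chain!r} has no Cα atoms")
        return ca.mean(axis=0)

    def anchor_ca(self, which: str) -> np.ndarray:
        """Cα position of a membrane anchor; ``which`` is 'fixed' or 'mobile'."""
        sel = (
            self.roles.membrane_anchor_fixed
            if which == "fixed"
            else self.roles.membrane_anchor_mobile
        )
        chain, res = sel
        m = (
            self.chain_mask(chain)
            & self.ca_mask()
            & np.fromiter((r == res for r in self.residue_ids), bool, self.n_atoms)
        )
        n = int(m.sum())
        if n != 1:
            raise RoleResolutionError(
                f"membrane anchor ({chain}, {res}) resolves to {n} Cα atoms; need exactly 1"
            )
        return self.coords[m][0]

    def validate_roles(self) -> None:
        present = set(self.present_chains())
        for c in self.roles.all_chains():
            if c not in present:
                raise RoleResolutionError(
                    f"role chain {c!r} absent from structure (chains: {sorted(present)})"
                )
        self.anchor_ca("fixed")
        self.anchor_ca("mobile")
        missing = self.blocked_positions - self.residue_set()
        if missing:
            raise SelectionError(f"blocked positions absent from structure: {sorted(missing)}")


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------


def _coor_format(path: Path, format: str) -> gemmi.CoorFormat:
    if format == "pdb":
        return gemmi.CoorFormat.Pdb
    if format == "mmcif":
        return gemmi.CoorFormat.Mmcif
    if format == "auto":
        return gemmi.CoorFormat.Detect
    raise ValueError(f"unknown format {format!r}")


def load_structure(
    path: str | Path,
    roles: ChainRoleMap,
    format: str = "auto",
    keep_hydrogens: bool = False,
) -> ComplexModel:
    """Read a PDB/mmCIF file into a :class:`ComplexModel`.

    The first model of a multi-model file is used; alternate locations
    resolve to the highest-occupancy conformer (tie → altloc 'A');
    hydrogens are dropped unless ``keep_hydrogens``.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=_coor_format(path, format))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path} contains no coordinate model")
    if len(st) > 1:
        logger.info("%s has %d models; using model 1", path.name, len(st))
    model = st[0]

    chain_ids, res_ids, res_names, atom_names, elements, coords = [], [], [], [], [], []
    for chain in model:
        for residue in chain:
            # altloc resolution: keep highest occupancy per atom name
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None:
                    best[atom.name] = atom
                    continue
                key_new = (-atom.occ, atom.altloc or "A")
                key_old = (-prev.occ, prev.altloc or "A")
                if key_new < key_old:
                    best[atom.name] = atom
            rkey = f"{residue.seqid.num}{(residue.seqid.icode or '').strip()}"
            for atom in best.values():
                elem = atom.element.name or "X"
                if not keep_hydrogens and elem.upper() in _HYDROGEN_ELEMENTS:
                    continue
                chain_ids.append(chain.name)
                res_ids.append(rkey)
                res_names.append(residue.name)
                atom_names.append(atom.name)
                elements.append(elem)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])

    if not coords:
        raise StructureFormatError(f"{path} contains no (heavy) atoms")
    cm = ComplexModel(
        chain_ids=np.array(chain_ids, dtype=object),
        residue_ids=np.array(res_ids, dtype=object),
        residue_names=np.array(res_names, dtype=object),
        atom_names=np.array(atom_names, dtype=object),
        elements=np.array(elements, dtype=object),
        coords=np.array(coords, dtype=float),
        roles=roles,
    )
    cm.validate_roles()
    return cm


def _split_reskey(key: str) -> tuple[int, str]:
    i = len(key)
    while i > 0 and not key[i - 1].isdigit():
        i -= 1
    return int(key[:i]), key[i:]


def write_structure(model: ComplexModel, path: str | Path, format: str = "pdb") -> None:
    """Write a model to PDB or mmCIF; chain ids and coordinates preserved."""
    if model.n_atoms == 0:
        raise ValueError("cannot write an empty model")
    chains = model.present_chains()
    if format == "pdb" and len(chains) > 62:
        raise ValueError(
            f"{len(chains)} chains exceed the PDB single-character chain limit (62); "
            "write mmCIF instead"
        )
    st = gemmi.Structure()
    st.name = "cytogeom"
    gm = gemmi.Model("1")
    by_chain: dict[str, gemmi.Chain] = {}
    current: tuple[str, str] | None = None
    residue: gemmi.Residue | None = None
    for i in range(model.n_atoms):
        cid = model.chain_ids[i]
        if cid not in by_chain:
            by_chain[cid] = gemmi.Chain(cid)
        rid = model.residue_ids[i]
        if current != (cid, rid):
            res = gemmi.Residue()
            res.name = model.residue_names[i]
            num, icode = _split_reskey(rid)
            res.seqid = gemmi.SeqId(num, icode or " ")
            # gemmi copies on add; keep the stored reference
            residue = by_chain[cid].add_residue(res)
            current = (cid, rid)
        atom = gemmi.Atom()
        atom.name = model.atom_names[i]
        atom.element = gemmi.Element(model.elements[i])
        atom.occ = 1.0
        atom.b_iso = 0.0
        x, y, z = model.coords[i]
        atom.pos = gemmi.Position(x, y, z)
        residue.add_atom(atom)
    for chain in by_chain.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    path = Path(path)
    if format == "pdb":
        st.write_pdb(str(path))
    elif format == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------


def _normalize_selection(selection: Iterable[tuple[str, int | str]]) -> set[tuple[str, str]]:
    return {(c, reskey(r)) for c, r in selection}


def crop_by_proximity(
    model: ComplexModel,
    target: str,
    reference_selection: Iterable[tuple[str, int | str]],
    radius: float = 10.0,
) -> ComplexModel:
    """Keep only residues of ``target`` with any heavy atom within ``radius``
    Å of any heavy atom of ``reference_selection``; other chains untouched.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    sel = _normalize_selection(reference_selection)
    if not sel:
        raise SelectionError("reference_selection is empty")
    missing = sel - model.residue_set()
    if missing:
        raise SelectionError(f"reference residues absent: {sorted(missing)}")

    ref_mask = np.fromiter(
        ((c, r) in sel for c, r in zip(model.chain_ids, model.residue_ids)),
        bool,
        model.n_atoms,
    )
    tgt_mask = model.chain_mask(target)
    if not tgt_mask.any():
        raise RoleResolutionError(f"target chain {target!r} absent")

    tree = cKDTree(model.coords[ref_mask])
    dists, _ = tree.query(model.coords[tgt_mask], k=1)
    near_res = {
        (c, r)
        for c, r, d in zip(
            model.chain_ids[tgt_mask], model.residue_ids[tgt_mask], dists
        )
        if d <= radius
    }
    keep = np.fromiter(
        (
            (c != target) or ((c, r) in near_res)
            for c, r in zip(model.chain_ids, model.residue_ids)
        ),
        bool,
        model.n_atoms,
    )
    if not any(c == target for c in model.chain_ids[keep]):
        warnings.warn(
            f"crop_by_proximity removed every residue of chain {target!r}",
            stacklevel=2,
        )
    return model.subset(keep)


def block_positions(
    model: ComplexModel,
    selection: Iterable[tuple[str, int | str]],
    mode: str = "annotate",
    mutate_to: str = "GLU",
) -> ComplexModel:
    """Mark residues as non-designable / non-interacting.

    ``annotate`` records them in ``blocked_positions`` without touching
    coordinates. ``mutate`` additionally renames the residue and strips
    side-chain atoms beyond Cβ — placeholder geometry for interface
    blocking (e.g. glutamate walls), not a modeled side chain.
    """
    if mode not in ("annotate", "mutate"):
        raise ValueError(f"unknown mode {mode!r}")
    sel = _normalize_selection(selection)
    missing = sel - model.residue_set()
    if missing:
        raise SelectionError(f"positions to block absent: {sorted(missing)}")
    out = model.copy()
    out.blocked_positions |= sel
    if mode == "annotate":
        return out
    keep = np.ones(out.n_atoms, bool)
    for i in range(out.n_atoms):
        if (out.chain_ids[i], out.residue_ids[i]) in sel:
            out.residue_names[i] = mutate_to
            if out.atom_names[i] not in _BACKBONE_PLUS_CB:
                keep[i] = False
    return out.subset(keep)
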