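"""From accepted geometries to design inputs and back.

An accepted dimer geometry is turned into inputs for generative backbone
design: a contig specification per fusion orientation (binder A → scaffold
gap → binder B and the reverse), with the variable scaffold length range
derived from the Cα gap between the joined termini; and a redesign mask
listing positions whose sequence may change (the new scaffold and any
binder residue contacting it within a cutoff, default 5 Å) while receptor-
interface residues stay frozen.

Returned designs are validated geometrically: the receptors are
superposed back onto the design through the shared binder chains (Kabsch
least-squares fit) and any scaffold that clashes with them is rejected;
prediction score tables (pLDDT / PAE / RMSD / interface contact counts)
are thresholded, with the PAE comparison strict (< limit).

For homodimeric (C2) agonists the module places a second protomer by a
180° rotation about the symmetry axis, extends terminal helices with
ideal α-helical Cα geometry to provide fusion anchors, and verifies
two-fold symmetry by RMSD against the rotated partner.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .geomframe import (
    ClashParams,
    Frame,
    GeometrySample,
    RigidTransform,
    count_clashes_between,
    kabsch,
)
from .structio import ComplexModel, RoleResolutionError, SelectionError, reskey

logger = logging.getLogger("cytogeom")

__all__ = [
    "ContigSpec",
    "RedesignMask",
    "AlignBackResult",
    "C2Assembly",
    "SuperpositionError",
    "make_contig_specs",
    "redesign_mask",
    "align_back_filter",
    "filter_scores",
    "build_c2_assembly",
    "extend_terminus_helix",
    "check_c2_symmetry",
]

#: maximal Cα–Cα extension per residue (Å) used to convert a terminal gap
#: into a minimum scaffold length
MAX_RESIDUE_SPAN = 3.8

#: ideal α-helix Cα parameters
HELIX_RISE = 1.5        # Å per residue along the axis
HELIX_TWIST = 100.0     # degrees per residue about the axis
HELIX_RADIUS = 2.3      # Å, Cα distance from the axis


class SuperpositionError(ValueError):
    """Too few shared atoms (or degenerate geometry) for a rigid fit."""


# ---------------------------------------------------------------------------
# contig specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContigSpec:
    """A fixed-segment / variable-gap specification for backbone design.

    ``contig_string`` follows the conventional text grammar
    ``<chain><start>-<end>/<Lmin>-<Lmax>/<chain><start>-<end>``: two fixed
    binder segments joined by a scaffold whose length is free between
    Lmin and Lmax residues.
    """

    orientation: str                      # "A_then_B" or "B_then_A"
    binder_a_range: tuple[str, str, str]  # (chain, first residue, last residue)
    binder_b_range: tuple[str, str, str]
    scaffold_length_min: int
    scaffold_length_max: int
    gap_distance: float                   # Å between the joined termini Cα
    contig_string: str

    def __post_init__(self) -> None:
        if not (0 < self.scaffold_length_min <= self.scaffold_length_max):
            raise ValueError("need 0 < scaffold_length_min <= scaffold_length_max")


def _terminal_ca(model: ComplexModel, chain: str, which: str) -> tuple[str, np.ndarray]:
    """(residue key, Cα position) of a chain terminus; 'N' first, 'C' last."""
    residues = model.residues_of_chain(chain)
    if not residues:
        raise RoleResolutionError(f"chain {chain!r} absent")
    res = residues[0] if which == "N" else residues[-1]
    m = (
        model.chain_mask(chain)
        & model.ca_mask()
        & np.fromiter((r == res for r in model.residue_ids), bool, model.n_atoms)
    )
    if not m.any():
        raise SelectionError(f"terminal residue ({chain}, {res}) has no Cα atom")
    return res, model.coords[m][0]


def make_contig_specs(
    sample_model: ComplexModel,
    slack: int = 40,
    span_per_residue: float = MAX_RESIDUE_SPAN,
) -> list[ContigSpec]:
    """Contig specifications for both fusion orientations of a sampled
    geometry.

    For each orientation the scaffold gap is the Cα distance between the
    joined termini (first binder's C-terminus to second binder's
    N-terminus); the minimum scaffold length is ceil(gap / 3.8 Å)
    (clamped to ≥ 1) and the maximum adds ``slack`` residues.
    """
    binders = sample_model.roles.binders
    if len(binders) < 2:
        raise RoleResolutionError("contig specs need two binder chains")
    a, b = binders[0], binders[1]
    specs = []
    for orientation, first, second in (("A_then_B", a, b), ("B_then_A", b, a)):
        _, c_term = _terminal_ca(sample_model, first, "C")
        _, n_term = _terminal_ca(sample_model, second, "N")
        d = float(np.linalg.norm(c_term - n_term))
        lmin = max(1, math.ceil(d / span_per_residue))
        lmax = lmin + slack
        fa = (first, *_chain_span(sample_model, first))
        fb = (second, *_chain_span(sample_model, second))
        contig = (
            f"{fa[0]}{fa[1]}-{fa[2]}/{lmin}-{lmax}/{fb[0]}{fb[1]}-{fb[2]}"
        )
        specs.append(
            ContigSpec(
                orientation=orientation,
                binder_a_range=fa,
                binder_b_range=fb,
                scaffold_length_min=lmin,
                scaffold_length_max=lmax,
                gap_distance=d,
                contig_string=contig,
            )
        )
    return specs


def _chain_span(model: ComplexModel, chain: str) -> tuple[str, str]:
    residues = model.residues_of_chain(chain)
    return residues[0], residues[-1]


# ---------------------------------------------------------------------------
# redesign mask
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RedesignMask:
    designable: frozenset[tuple[str, str]]
    frozen_interface: frozenset[tuple[str, str]]
    cutoff: float = 5.0

    def __post_init__(self) -> None:
        if self.designable & self.frozen_interface:
            raise ValueError("designable and frozen_interface overlap")


def redesign_mask(
    model: ComplexModel,
    scaffold: str,
    interface_sets: Iterable[tuple[str, int | str]] = (),
    cutoff: float = 5.0,
) -> RedesignMask:
    """Positions eligible for sequence redesign after scaffold fusion.

    Designable = every scaffold residue plus any binder residue with a
    heavy atom within ``cutoff`` Å of a scaffold heavy atom, minus the
    receptor-interface residues and any blocked positions; the interface
    set is returned frozen.
    """
    if scaffold not in model.present_chains():
        raise RoleResolutionError(f"scaffold chain {scaffold!r} absent")
    interface = {(c, reskey(r)) for c, r in interface_sets}
    scaffold_res = {(scaffold, r) for r in model.residues_of_chain(scaffold)}

    sc_mask = model.chain_mask(scaffold)
    tree = cKDTree(model.coords[sc_mask])
    binder_chains = set(model.roles.binders)
    contact: set[tuple[str, str]] = set()
    if binder_chains:
        b_mask = model.chain_mask(binder_chains)
        dists, _ = tree.query(model.coords[b_mask], k=1)
        for c, r, d in zip(model.chain_ids[b_mask], model.residue_ids[b_mask], dists):
            if d <= cutoff:
                contact.add((c, r))

    designable = (scaffold_res | contact) - interface - model.blocked_positions
    return RedesignMask(
        designable=frozenset(designable),
        frozen_interface=frozenset(interface),
        cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# align-back clash filter
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignBackResult:
    passed: bool
    clash_pairs: int
    fit_rmsd: float


def align_back_filter(
    design: ComplexModel,
    native: ComplexModel,
    clash: ClashParams = ClashParams(),
    scaffold: str | None = None,
) -> AlignBackResult:
    """Superpose the native receptors onto a fused design and count
    receptor–scaffold clashes.

    The rigid fit uses the Cα atoms of the binder chains shared between
    the two models (matched by chain and residue key); the design fails
    when the clash-pair count exceeds ``clash.max_allowed_pairs``.
    """
    shared_binders = [c for c in native.roles.binders if c in design.present_chains()]
    if not shared_binders:
        raise SuperpositionError("no shared binder chains between design and native")

    def binder_ca(model: ComplexModel) -> dict[tuple[str, str], np.ndarray]:
        m = model.chain_mask(shared_binders) & model.ca_mask()
        return {
            (c, r): xyz
            for c, r, xyz in zip(model.chain_ids[m], model.residue_ids[m], model.coords[m])
        }

    ca_n, ca_d = binder_ca(native), binder_ca(design)
    keys = sorted(set(ca_n) & set(ca_d))
    if len(keys) < 3:
        raise SuperpositionError(f"only {len(keys)} shared binder Cα atoms; need >= 3")
    P = np.array([ca_n[k] for k in keys])
    Q = np.array([ca_d[k] for k in keys])
    R, t, rmsd = kabsch(P, Q)

    rec_mask = native.chain_mask(native.roles.receptor_chains)
    receptors = native.coords[rec_mask] @ R.T + t
    sc_chain = scaffold if scaffold is not None else design.roles.scaffold
    if sc_chain is None:
        raise RoleResolutionError("design has no scaffold chain annotated")
    scaffold_coords = design.coords[design.chain_mask(sc_chain)]
    pairs = count_clashes_between(receptors, scaffold_coords, clash.cutoff)
    return AlignBackResult(
        passed=pairs <= clash.max_allowed_pairs, clash_pairs=pairs, fit_rmsd=rmsd
    )


# ---------------------------------------------------------------------------
# score-table filtering
# ---------------------------------------------------------------------------


def filter_scores(
    table: pd.DataFrame,
    plddt_min: float = 85.0,
    pae_max: float = 10.0,
    rmsd_max: float = 2.0,
    min_contacts: int | None = None,
) -> list[str]:
    """Design ids passing the prediction-confidence thresholds.

    pLDDT and RMSD comparisons are inclusive (≥ / ≤); the PAE comparison
    is strict (<), so a design at exactly the PAE limit fails. Contact
    counts (interface residues within 5 Å) are checked only when
    ``min_contacts`` is given. Input row order is preserved.
    """
    required = {"design_id", "plddt", "pae", "rmsd_to_input"}
    if min_contacts is not None:
        required.add("contacts")
    missing = required - set(table.columns)
    if missing:
        raise KeyError(f"score table lacks columns: {sorted(missing)}")
    if len(table) == 0:
        return []
    keep = (
        (table["plddt"] >= plddt_min)
        & (table["pae"] < pae_max)
        & (table["rmsd_to_input"] <= rmsd_max)
    )
    if min_contacts is not None:
        keep &= table["contacts"] >= min_contacts
    return list(table.loc[keep, "design_id"])


# ---------------------------------------------------------------------------
# C2 assembly
# ---------------------------------------------------------------------------

_CHAIN_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


@dataclass(frozen=True)
class C2Assembly:
    model: ComplexModel
    protomer_a_chains: tuple[str, ...]
    protomer_b_chains: tuple[str, ...]
    chain_map: dict[str, str]
    inter_protomer_clashes: int


def _c2_rotation(axis: np.ndarray, origin: np.ndarray) -> RigidTransform:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    R = Rotation.from_rotvec(np.pi * axis).as_matrix()
    return RigidTransform(R, np.zeros(3), np.asarray(origin, float))


def build_c2_assembly(
    monomer: ComplexModel,
    frame: Frame,
    clash: ClashParams = ClashParams(),
) -> C2Assembly:
    """Duplicate a protomer by 180° rotation about the frame Z axis
    through the frame origin, remap the copy's chain ids, and report
    inter-protomer clashes (reported, never silently dropped)."""
    T = _c2_rotation(frame.z_axis, frame.origin)
    used = list(monomer.present_chains())
    chain_map: dict[str, str] = {}
    pool = [c for c in _CHAIN_ALPHABET if c not in used]
    for c in used:
        if not pool:
            raise ValueError("ran out of chain identifiers for the second protomer")
        chain_map[c] = pool.pop(0)

    copy = monomer.copy()
    copy.coords = T.apply(copy.coords)
    copy.chain_ids = np.array([chain_map[c] for c in copy.chain_ids], dtype=object)

    model = ComplexModel(
        chain_ids=np.concatenate([monomer.chain_ids, copy.chain_ids]),
        residue_ids=np.concatenate([monomer.residue_ids, copy.residue_ids]),
        residue_names=np.concatenate([monomer.residue_names, copy.residue_names]),
        atom_names=np.concatenate([monomer.atom_names, copy.atom_names]),
        elements=np.concatenate([monomer.elements, copy.elements]),
        coords=np.vstack([monomer.coords, copy.coords]),
        roles=monomer.roles,
        blocked_positions=set(monomer.blocked_positions),
        designable_extensions=set(monomer.designable_extensions),
    )
    pairs = count_clashes_between(monomer.coords, copy.coords, clash.cutoff)
    if pairs > clash.max_allowed_pairs:
        logger.warning(
            "C2 assembly has %d inter-protomer clash pairs at cutoff %.2f Å",
            pairs, clash.cutoff,
        )
    return C2Assembly(
        model=model,
        protomer_a_chains=tuple(used),
        protomer_b_chains=tuple(chain_map[c] for c in used),
        chain_map=chain_map,
        inter_protomer_clashes=pairs,
    )


def check_c2_symmetry(
    assembly: ComplexModel,
    axis: np.ndarray,
    protomer_a: Sequence[str],
    protomer_b: Sequence[str],
    tolerance: float = 1e-6,
    origin: np.ndarray | None = None,
) -> tuple[bool, float]:
    """Validate two-fold symmetry: Cα RMSD between protomer B and the
    180°-rotated protomer A (about ``axis`` through ``origin``)."""
    origin = np.zeros(3) if origin is None else np.asarray(origin, float)
    T = _c2_rotation(axis, origin)
    ca_a = np.vstack([assembly.chain_ca_coords(c) for c in protomer_a])
    ca_b = np.vstack([assembly.chain_ca_coords(c) for c in protomer_b])
    if ca_a.shape != ca_b.shape:
        raise ValueError(
            f"protomer Cα counts differ ({len(ca_a)} vs {len(ca_b)}); cannot pair atoms"
        )
    rot = T.apply(ca_a)
    rmsd = float(np.sqrt(np.mean(np.sum((rot - ca_b) ** 2, axis=1))))
    return rmsd <= tolerance, rmsd


# ---------------------------------------------------------------------------
# ideal-helix terminal extension
# ---------------------------------------------------------------------------


class TerminusError(ValueError):
    """Terminal segment too short or not helical enough to extend."""


def _fit_screw(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float, float]:
    """Fit the per-residue screw transform of an ordered Cα trace.

    Returns (axis unit vector, point on axis, twist angle rad, rise Å,
    fit residual Å). The screw is the rigid map sending points[:-1] onto
    points[1:]; its rotation axis is the local helix axis.
    """
    P, Q = points[:-1], points[1:]
    R, t, _ = kabsch(P, Q)
    residual = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    rotvec = Rotation.from_matrix(R).as_rotvec()
    theta = float(np.linalg.norm(rotvec))
    if theta < 1e-3:
        raise TerminusError("terminal segment is not helical (no local twist)")
    u = rotvec / theta
    rise = float(t @ u)
    # point on the axis: (I − R) c = t − (t·u) u, singular along u → lstsq
    t_perp = t - rise * u
    c, *_ = np.linalg.lstsq(np.eye(3) - R, t_perp, rcond=None)
    return u, c, theta, rise, residual


def extend_terminus_helix(
    model: ComplexModel,
    chain: str,
    terminus: str,
    n_residues: int = 10,
    fit_window: int = 7,
    max_fit_residual: float = 0.5,
    rise: float = HELIX_RISE,
    twist: float = HELIX_TWIST,
) -> ComplexModel:
    """Append ideal α-helical Cα residues continuing a terminal helix.

    The local helix axis is fitted from the terminal ``fit_window`` Cα
    atoms (≥ 4 required) via the per-residue screw transform; new Cα
    positions advance along that axis with the ideal 1.5 Å rise and 100°
    twist per residue. The added residues carry placeholder glycine
    names and are recorded as designable extensions.
    """
    if terminus not in ("N", "C"):
        raise ValueError("terminus must be 'N' or 'C'")
    if n_residues < 0:
        raise ValueError("n_residues must be >= 0")
    out = model.copy()
    if n_residues == 0:
        return out

    ca = model.chain_ca_coords(chain)
    residues = model.residues_of_chain(chain)
    if len(ca) < 4:
        raise TerminusError("need >= 4 consecutive Cα atoms to fit the helix axis")
    seg = ca[-min(fit_window, len(ca)):] if terminus == "C" else ca[: min(fit_window, len(ca))][::-1]
    u, c, theta, fitted_rise, residual = _fit_screw(seg)
    if residual > max_fit_residual:
        raise TerminusError(
            f"terminal segment deviates from a helix (screw-fit residual {residual:.2f} Å)"
        )

    step_angle = math.copysign(math.radians(twist), theta if theta > 0 else 1.0)
    step_rise = math.copysign(rise, fitted_rise if fitted_rise != 0 else 1.0)
    p0 = seg[-1]
    new_points = []
    for k in range(1, n_residues + 1):
        Rk = Rotation.from_rotvec(u * step_angle * k).as_matrix()
        new_points.append(Rk @ (p0 - c) + c + step_rise * k * u)
    new_points = np.array(new_points)

    last_num, _ = _split_num(residues[-1] if terminus == "C" else residues[0])
    if terminus == "C":
        new_keys = [str(last_num + k) for k in range(1, n_residues + 1)]
    else:
        new_keys = [str(last_num - k) for k in range(1, n_residues + 1)]

    if terminus == "N":
        # prepended residues must read outward-in so the chain stays ordered
        new_points = new_points[::-1]
        new_keys = new_keys[::-1]
    n_new = len(new_points)
    add = dict(
        chain_ids=np.array([chain] * n_new, dtype=object),
        residue_ids=np.array(new_keys, dtype=object),
        residue_names=np.array(["GLY"] * n_new, dtype=object),
        atom_names=np.array(["CA"] * n_new, dtype=object),
        elements=np.array(["C"] * n_new, dtype=object),
        coords=new_points,
    )
    if terminus == "C":
        order = (out, add)
    else:
        order = (add, out)

    def col(name):
        parts = []
        for src in order:
            parts.append(getattr(src, name) if isinstance(src, ComplexModel) else src[name])
        return np.concatenate(parts)

    result = ComplexModel(
        chain_ids=col("chain_ids"),
        residue_ids=col("residue_ids"),
        residue_names=col("residue_names"),
        atom_names=col("atom_names"),
        elements=col("elements"),
        coords=np.vstack(
            [src.coords if isinstance(src, ComplexModel) else src["coords"] for src in order]
        ),
        roles=out.roles,
        blocked_positions=set(out.blocked_positions),
        designable_extensions=set(out.designable_extensions)
        | {(chain, k) for k in new_keys},
    )
    return result


def _split_num(key: str) -> tuple[int, str]:
    i = len(key)
    while i > 0 and not key[i - 1].isdigit():
        i -= 1
    return int(key[:i]), key[i:]
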