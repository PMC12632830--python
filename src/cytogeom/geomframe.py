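"""Standardized membrane frame, rigid-body sampling and geometry descriptors.

The receptor dimer is placed in a membrane-anchored coordinate frame:

* origin — midpoint of the two receptor-chain Cα centroids;
* Z — unit vector from the midpoint of the two membrane-anchor Cα
  positions toward the origin (the membrane lies below, Z points away
  from it);
* X — component of the fixed→mobile inter-anchor vector orthogonal to Z;
* Y — Z × X (right-handed).

One receptor is held fixed and the mobile receptor (plus its binder) is
moved by rigid transforms sampled either from independent per-DOF
Gaussians centred on the native geometry or from a grid. Rotations
compose as Rz·Ry·Rx about the frame axes through a chosen rotation
center; translations are expressed in frame coordinates. Geometries
with heavy-atom clashes are rejected, and each survivor is summarised
by the descriptors that track signaling: inter-anchor (membrane-
proximal termini) distance, rotation about Z, and lateral deviation of
the mobile anchor in the membrane plane.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structio import ComplexModel, RoleResolutionError

logger = logging.getLogger("cytogeom")

__all__ = [
    "Frame",
    "RigidTransform",
    "SamplerConfig",
    "ClashParams",
    "DescriptorSet",
    "GeometrySample",
    "DegenerateFrameError",
    "NonRigidMotionError",
    "define_frame",
    "kabsch",
    "sample_transforms",
    "apply_transform",
    "count_clashes",
    "compute_descriptors",
    "run_geometry_scan",
    "select_diverse",
]

#: order of the six rigid degrees of freedom in sampler output
DOF_NAMES = ("rot_x", "rot_y", "rot_z", "trans_x", "trans_y", "trans_z")


class DegenerateFrameError(ValueError):
    """The anchor geometry does not define a usable frame."""


class NonRigidMotionError(ValueError):
    """A chain moved non-rigidly where a rigid motion was assumed."""


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-6:
        raise DegenerateFrameError(f"{what} vector has near-zero norm")
    return v / n


@dataclass(frozen=True)
class Frame:
    """Right-handed orthonormal frame; axes are world-space unit vectors."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        for a, b in itertools.combinations((self.x_axis, self.y_axis, self.z_axis), 2):
            if abs(a @ b) > 1e-8:
                raise ValueError("frame axes must be mutually orthogonal")
        for a in (self.x_axis, self.y_axis, self.z_axis):
            if abs(np.linalg.norm(a) - 1.0) > 1e-10:
                raise ValueError("frame axes must be unit vectors")
        if np.linalg.norm(np.cross(self.x_axis, self.y_axis) - self.z_axis) > 1e-8:
            raise ValueError("frame must be right-handed (x × y = z)")

    @property
    def basis(self) -> np.ndarray:
        """3×3 matrix with the axes as columns (frame→world rotation)."""
        return np.column_stack((self.x_axis, self.y_axis, self.z_axis))

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, float) - self.origin) @ self.basis

    def to_world(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.basis.T + self.origin


@dataclass(frozen=True)
class RigidTransform:
    """p → R·(p − c) + c + t with rotation R about ``rotation_center`` c."""

    rotation: np.ndarray
    translation: np.ndarray
    rotation_center: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, float).reshape(3, 3))
        object.__setattr__(self, "translation", np.asarray(self.translation, float).reshape(3))
        object.__setattr__(
            self, "rotation_center", np.asarray(self.rotation_center, float).reshape(3)
        )
        R = self.rotation
        if abs(np.linalg.det(R) - 1.0) > 1e-8 or np.abs(R @ R.T - np.eye(3)).max() > 1e-8:
            raise ValueError("rotation must be a proper orthonormal matrix")

    @classmethod
    def identity(cls, center: np.ndarray | None = None) -> "RigidTransform":
        c = np.zeros(3) if center is None else center
        return cls(np.eye(3), np.zeros(3), c)

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, float)
        return (p - self.rotation_center) @ self.rotation.T + self.rotation_center + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -(Rt @ self.translation), self.rotation_center)

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``first`` then ``self``."""
        # centered form p -> R p + b
        b1 = first.rotation_center - first.rotation @ first.rotation_center + first.translation
        b2 = self.rotation_center - self.rotation @ self.rotation_center + self.translation
        R = self.rotation @ first.rotation
        b = self.rotation @ b1 + b2
        c = first.rotation_center
        return RigidTransform(R, b - c + R @ c, c)


@dataclass(frozen=True)
class SamplerConfig:
    """Per-DOF sampling widths. Rotations in degrees, translations in Å.

    ``gaussian`` mode draws each DOF independently from N(0, σ); the
    distribution is centred on the native geometry. ``grid`` mode
    enumerates the Cartesian product of per-axis (min, max, step)
    specifications over the DOFs present in ``grid``, in the fixed axis
    order rot_z, rot_y, rot_x, trans_x, trans_y, trans_z with the last
    listed axis varying fastest.
    """

    sigma_rot_x: float = 0.0
    sigma_rot_y: float = 0.0
    sigma_rot_z: float = 0.0
    sigma_trans_x: float = 0.0
    sigma_trans_y: float = 0.0
    sigma_trans_z: float = 0.0
    n_samples: int = 1000
    seed: int = 0
    mode: str = "gaussian"
    grid: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sigmas = (
            self.sigma_rot_x, self.sigma_rot_y, self.sigma_rot_z,
            self.sigma_trans_x, self.sigma_trans_y, self.sigma_trans_z,
        )
        if any(s < 0 for s in sigmas):
            raise ValueError("sigmas must be non-negative")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.mode not in ("gaussian", "grid"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def sigmas(self) -> np.ndarray:
        return np.array(
            [
                self.sigma_rot_x, self.sigma_rot_y, self.sigma_rot_z,
                self.sigma_trans_x, self.sigma_trans_y, self.sigma_trans_z,
            ]
        )


@dataclass(frozen=True)
class ClashParams:
    """Hard-sphere clash criterion: inter-chain heavy-atom pairs closer
    than ``cutoff`` Å; a geometry passes if pairs ≤ ``max_allowed_pairs``."""

    cutoff: float = 3.0
    max_allowed_pairs: int = 0
    pair_scope: str = "inter_chain_all"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.pair_scope not in ("inter_chain_all", "receptor_vs_designed"):
            raise ValueError(f"unknown pair_scope {self.pair_scope!r}")


@dataclass(frozen=True)
class DescriptorSet:
    """Geometry descriptors of one sampled dimer configuration.

    ``termini_distance`` — Cα–Cα distance between the membrane anchors (Å);
    ``delta_distance`` — change vs. the native complex (Å);
    ``theta_z`` — rotation of the mobile receptor about the frame Z axis
    relative to native, degrees in (−180, 180];
    ``lateral_deviation`` — angle at the frame origin between the
    membrane-plane (XY) projections of the native and sampled
    mobile-anchor positions, degrees in [0, 180].
    """

    termini_distance: float
    delta_distance: float
    theta_z: float
    lateral_deviation: float

    def as_dict(self) -> dict[str, float]:
        return {
            "termini_distance": self.termini_distance,
            "delta_distance": self.delta_distance,
            "theta_z": self.theta_z,
            "lateral_deviation": self.lateral_deviation,
        }


@dataclass(frozen=True)
class GeometrySample:
    id: str
    transform: RigidTransform
    clash_pairs: int
    passed_clash: bool
    descriptors: DescriptorSet
    dof: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# frame construction
# ---------------------------------------------------------------------------


def define_frame(model: ComplexModel) -> Frame:
    """Build the standardized membrane frame from receptor centroids and
    membrane-proximal anchor Cα positions."""
    c_fixed = model.chain_ca_centroid(model.roles.fixed_receptor)
    c_mobile = model.chain_ca_centroid(model.roles.mobile_receptor)
    a_fixed = model.anchor_ca("fixed")
    a_mobile = model.anchor_ca("mobile")
    origin = (c_fixed + c_mobile) / 2.0
    anchor_mid = (a_fixed + a_mobile) / 2.0
    if np.linalg.norm(a_fixed - a_mobile) < 1e-6:
        raise DegenerateFrameError("membrane anchors coincide")
    z = _unit(origin - anchor_mid, "membrane normal (anchor-midpoint → origin)")
    d = a_mobile - a_fixed
    x_raw = d - (d @ z) * z
    if np.linalg.norm(x_raw) < 1e-6:
        raise DegenerateFrameError("inter-anchor vector is parallel to the membrane normal")
    x = x_raw / np.linalg.norm(x_raw)
    y = np.cross(z, x)
    return Frame(origin=origin, x_axis=x, y_axis=y, z_axis=z)


# ---------------------------------------------------------------------------
# rigid-transform sampling and application
# ---------------------------------------------------------------------------


def _transform_from_dof(dof: np.ndarray, frame: Frame, center: np.ndarray) -> RigidTransform:
    """Six DOFs (rot_x, rot_y, rot_z in degrees; trans in frame Å) → world
    transform. Rotation composes Rz·Ry·Rx about the frame axes."""
    B = frame.basis
    # extrinsic x-y-z about the frame axes == Rz·Ry·Rx in the frame basis
    R_frame = Rotation.from_euler("xyz", dof[:3], degrees=True).as_matrix()
    R_world = B @ R_frame @ B.T
    t_world = B @ dof[3:]
    return RigidTransform(R_world, t_world, center)


def sample_transforms(
    config: SamplerConfig, frame: Frame, mobile_center: np.ndarray
) -> tuple[list[RigidTransform], np.ndarray]:
    """Draw rigid transforms per the sampler configuration.

    Returns the transforms together with the (n, 6) matrix of drawn DOFs
    in the order ``DOF_NAMES``; deterministic given ``config.seed``.
    """
    mobile_center = np.asarray(mobile_center, float)
    if config.mode == "gaussian":
        rng = np.random.default_rng(config.seed)
        dofs = rng.normal(0.0, 1.0, size=(config.n_samples, 6)) * config.sigmas
    else:
        axes = []
        for name in ("rot_z", "rot_y", "rot_x", "trans_x", "trans_y", "trans_z"):
            if name not in config.grid:
                continue
            lo, hi, step = config.grid[name]
            if step == 0:
                raise ValueError(f"grid axis {name!r} has zero step")
            axes.append((name, np.arange(lo, hi + step * 0.5, step)))
        if not axes:
            raise ValueError("grid mode requires at least one grid axis")
        cols = {name: [] for name, _ in axes}
        for combo in itertools.product(*(vals for _, vals in axes)):
            for (name, _), v in zip(axes, combo):
                cols[name].append(v)
        n = len(next(iter(cols.values())))
        dofs = np.zeros((n, 6))
        for j, name in enumerate(DOF_NAMES):
            if name in cols:
                dofs[:, j] = cols[name]
    transforms = [_transform_from_dof(d, frame, mobile_center) for d in dofs]
    return transforms, dofs


def apply_transform(
    model: ComplexModel, transform: RigidTransform, chains: set[str] | list[str]
) -> ComplexModel:
    """Move the listed chains rigidly; every other atom is untouched."""
    chains = set(chains)
    if not chains:
        raise ValueError("empty chain set")
    present = set(model.present_chains())
    missing = chains - present
    if missing:
        raise RoleResolutionError(f"chains absent from structure: {sorted(missing)}")
    out = model.copy()
    mask = out.chain_mask(chains)
    out.coords[mask] = transform.apply(out.coords[mask])
    return out


# ---------------------------------------------------------------------------
# clash counting
# ---------------------------------------------------------------------------


def count_clashes(model: ComplexModel, params: ClashParams) -> int:
    """Number of heavy-atom pairs closer than the cutoff between chains in
    scope; intra-chain pairs are never counted."""
    if model.n_atoms == 0:
        raise ValueError("empty model")
    if params.pair_scope == "inter_chain_all":
        tree = cKDTree(model.coords)
        pairs = tree.query_pairs(params.cutoff, output_type="ndarray")
        if len(pairs) == 0:
            return 0
        strict = (
            np.linalg.norm(model.coords[pairs[:, 0]] - model.coords[pairs[:, 1]], axis=1)
            < params.cutoff
        )
        diff_chain = model.chain_ids[pairs[:, 0]] != model.chain_ids[pairs[:, 1]]
        return int(np.sum(strict & diff_chain))
    # receptor_vs_designed: receptor chains vs everything else
    rec_mask = model.chain_mask(model.roles.receptor_chains)
    other_mask = ~rec_mask
    return count_clashes_between(model.coords[rec_mask], model.coords[other_mask], params.cutoff)


def count_clashes_between(coords_a: np.ndarray, coords_b: np.ndarray, cutoff: float) -> int:
    """Heavy-atom pairs strictly closer than ``cutoff`` between two atom sets."""
    if len(coords_a) == 0 or len(coords_b) == 0:
        return 0
    tree = cKDTree(coords_b)
    n = 0
    for idxs, pa in zip(tree.query_ball_point(coords_a, cutoff), coords_a):
        if idxs:
            n += int(np.sum(np.linalg.norm(coords_b[idxs] - pa, axis=1) < cutoff))
    return n


# ---------------------------------------------------------------------------
# superposition and descriptors
# ---------------------------------------------------------------------------


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit P → Q.

    Returns (R, t, rmsd) with R a proper rotation minimising
    ‖R·P + t − Q‖; the classical SVD solution with determinant correction.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or len(P) < 3:
        raise ValueError("superposition needs two equal sets of >= 3 points")
    Pc, Qc = P.mean(0), Q.mean(0)
    H = (P - Pc).T @ (Q - Qc)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = Qc - R @ Pc
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return R, t, rmsd


def compute_descriptors(
    native: ComplexModel,
    sample_model: ComplexModel,
    frame: Frame,
    rigid_tol: float = 1e-3,
) -> DescriptorSet:
    """Descriptors of a sampled geometry relative to the native complex.

    The mobile receptor must have moved rigidly: its internal geometry is
    checked against the native chain (post-fit Cα RMSD ≤ ``rigid_tol`` Å).
    """
    mobile = native.roles.mobile_receptor
    P = native.chain_ca_coords(mobile)
    Q = sample_model.chain_ca_coords(mobile)
    if P.shape != Q.shape:
        raise NonRigidMotionError("mobile chain atom count differs between models")
    R, _, rmsd = kabsch(P, Q)
    if rmsd > rigid_tol:
        raise NonRigidMotionError(
            f"mobile chain deformed non-rigidly (post-fit RMSD {rmsd:.2e} Å > {rigid_tol} Å)"
        )

    a_fixed = sample_model.anchor_ca("fixed")
    a_mobile = sample_model.anchor_ca("mobile")
    termini = float(np.linalg.norm(a_fixed - a_mobile))
    native_termini = float(np.linalg.norm(native.anchor_ca("fixed") - native.anchor_ca("mobile")))

    B = frame.basis
    R_frame = B.T @ R @ B
    angles = Rotation.from_matrix(R_frame).as_euler("xyz", degrees=True)
    if abs(angles[1]) >= 89.0:
        warnings.warn(
            "mobile-receptor pitch near gimbal lock; theta_z extraction is ill-conditioned",
            stacklevel=2,
        )
    theta_z = float(angles[2])
    if theta_z <= -180.0:
        theta_z += 360.0

    p_native = frame.to_frame(native.anchor_ca("mobile"))[:2]
    p_sample = frame.to_frame(a_mobile)[:2]
    nn, ns = np.linalg.norm(p_native), np.linalg.norm(p_sample)
    if nn < 1e-9 or ns < 1e-9:
        lateral = 0.0
    else:
        cosang = np.clip(p_native @ p_sample / (nn * ns), -1.0, 1.0)
        lateral = float(np.degrees(np.arccos(cosang)))

    return DescriptorSet(
        termini_distance=termini,
        delta_distance=termini - native_termini,
        theta_z=theta_z,
        lateral_deviation=lateral,
    )


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------


def default_mobile_chains(model: ComplexModel) -> set[str]:
    """Chains moved together by default: the mobile receptor and, if two
    binders are annotated, the second (the one engaging the mobile receptor)."""
    chains = {model.roles.mobile_receptor}
    if len(model.roles.binders) >= 2:
        chains.add(model.roles.binders[1])
    return chains


def run_geometry_scan(
    native: ComplexModel,
    config: SamplerConfig,
    clash: ClashParams = ClashParams(),
    mobile_chains: set[str] | None = None,
    rotation_about: str = "mobile_center",
) -> list[GeometrySample]:
    """Sample rigid-body geometries of the mobile receptor and score each.

    ``rotation_about`` selects the rotation center: ``mobile_center``
    (the mobile receptor's Cα centroid — pure reorientation) or
    ``origin`` (the frame origin — orbital motion that changes lateral
    deviation). Deterministic given the configuration seed.
    """
    native.validate_roles()
    frame = define_frame(native)
    if rotation_about == "mobile_center":
        center = native.chain_ca_centroid(native.roles.mobile_receptor)
    elif rotation_about == "origin":
        center = frame.origin
    else:
        raise ValueError(f"unknown rotation_about {rotation_about!r}")
    chains = default_mobile_chains(native) if mobile_chains is None else set(mobile_chains)

    transforms, dofs = sample_transforms(config, frame, center)
    width = max(5, len(str(len(transforms) - 1)))
    samples: list[GeometrySample] = []
    n_pass = 0
    for i, (T, dof) in enumerate(zip(transforms, dofs)):
        moved = apply_transform(native, T, chains)
        pairs = count_clashes(moved, clash)
        passed = pairs <= clash.max_allowed_pairs
        n_pass += passed
        desc = compute_descriptors(native, moved, frame)
        samples.append(
            GeometrySample(
                id=f"s{i:0{width}d}",
                transform=T,
                clash_pairs=pairs,
                passed_clash=passed,
                descriptors=desc,
                dof=dict(zip(DOF_NAMES, (float(v) for v in dof))),
            )
        )
    logger.info(
        "geometry scan: %d sampled, %d passed clash filter (cutoff %.2f Å)",
        len(samples), n_pass, clash.cutoff,
    )
    return samples


# ---------------------------------------------------------------------------
# diversity selection
# ---------------------------------------------------------------------------

_DIVERSITY_KEYS = ("delta_distance", "theta_z", "lateral_deviation")


def _descriptor_matrix(samples: list[GeometrySample], weights: dict[str, float] | None) -> np.ndarray:
    X = np.array([[getattr(s.descriptors, k) for k in _DIVERSITY_KEYS] for s in samples])
    # scale each descriptor by its spread so Å and degrees are comparable
    scale = X.std(axis=0)
    scale[scale < 1e-12] = 1.0
    X = X / scale
    if weights:
        w = np.array([weights.get(k, 1.0) for k in _DIVERSITY_KEYS])
        X = X * w
    return X


def select_diverse(
    samples: list[GeometrySample],
    k: int,
    weights: dict[str, float] | None = None,
    seed: int = 0,
) -> list[GeometrySample]:
    """Greedy farthest-point subset of clash-passing samples in weighted
    descriptor space; the first pick is the sample nearest the native
    geometry (ties → lowest id). Deterministic; ``seed`` is accepted for
    interface symmetry but the greedy procedure draws no random numbers."""
    eligible = [s for s in samples if s.passed_clash]
    if k > len(eligible):
        raise ValueError(f"requested k={k} but only {len(eligible)} samples pass the clash filter")
    if k <= 0:
        raise ValueError("k must be positive")
    eligible = sorted(eligible, key=lambda s: s.id)
    X = _descriptor_matrix(eligible, weights)

    d_native = np.linalg.norm(X, axis=1)
    chosen = [int(np.argmin(d_native))]  # argmin is the lowest index among ties
    min_dist = np.linalg.norm(X - X[chosen[0]], axis=1)
    while len(chosen) < k:
        nxt = int(np.argmax(min_dist))
        chosen.append(nxt)
        min_dist = np.minimum(min_dist, np.linalg.norm(X - X[nxt], axis=1))
    return [eligible[i] for i in chosen]
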