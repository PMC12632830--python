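"""Synthetic fixtures: toy receptor complexes and ground-truth assay data.

Everything the toolkit needs for development and testing is generated
here as a pure function of a specification plus a seed — no structure
downloads or measured data required.

* :func:`make_toy_complex` builds a four-chain Cα-only model (two
  receptor stand-ins plus one binder each) whose chain centroids and
  membrane-anchor positions are realised exactly, so the standardized
  frame it induces is known in closed form.
* :func:`make_synthetic_curves` draws replicate dose-response
  measurements from known 4PL parameters under additive or
  multiplicative noise, emitting the ground truth alongside.
* :func:`make_geometry_benchmark` produces descriptor/activity pairs
  with a known generative relation (activity declining linearly with
  inter-anchor distance, collapsing beyond 90° lateral deviation, or
  null) for calibrating the correlation statistics.

Toy chains are ideal Cα helices (1.5 Å rise, 100° twist, 2.3 Å radius)
or random coils; side chains are deliberately absent — every geometric
contract in the toolkit is defined on heavy atoms and is exercised
fully by Cα traces, while full-atom realism is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .fusion import HELIX_RADIUS, HELIX_RISE, HELIX_TWIST
from .geomframe import DescriptorSet, GeometrySample, RigidTransform
from .signaling import DoseResponseData
from .structio import ChainRoleMap, ComplexModel

__all__ = [
    "ToyComplexSpec",
    "SyntheticCurveSpec",
    "make_toy_complex",
    "make_synthetic_curves",
    "make_geometry_benchmark",
    "preset_degenerate_anchors",
    "preset_clashing_binders",
    "preset_flat_curve",
]


@dataclass(frozen=True)
class ToyComplexSpec:
    """Geometry of a toy two-receptor complex.

    Chain layout: A = fixed receptor, B = mobile receptor, C = binder of
    A, D = binder of B. Centroids and anchors are realised exactly;
    anchors are the last residue of each receptor chain. Defaults place
    an ectodomain-sized pair ~30 Å apart with anchors near a membrane
    plane at z ≈ 8 Å below the centroids.
    """

    receptor_a_centroid: tuple[float, float, float] = (-15.0, 0.0, 30.0)
    receptor_b_centroid: tuple[float, float, float] = (15.0, 0.0, 30.0)
    anchor_a: tuple[float, float, float] = (-15.0, 0.0, 8.0)
    anchor_b: tuple[float, float, float] = (15.0, 0.0, 8.0)
    residues_per_chain: int = 24
    helix: bool = True
    binder_offset_a: tuple[float, float, float] = (-6.0, 10.0, 14.0)
    binder_offset_b: tuple[float, float, float] = (6.0, 10.0, 14.0)
    binder_residues: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if np.allclose(self.receptor_a_centroid, self.receptor_b_centroid):
            raise ValueError("receptor centroids must be distinct")
        if np.allclose(self.anchor_a, self.anchor_b):
            raise ValueError("anchors must be distinct")
        if self.helix and self.residues_per_chain < 4:
            raise ValueError("helix chains need >= 4 residues (axis undefined)")
        if self.residues_per_chain < 2 or self.binder_residues < 2:
            raise ValueError("chains need >= 2 residues")


def _helix_trace(n: int, rise: float = HELIX_RISE, twist: float = HELIX_TWIST,
                 radius: float = HELIX_RADIUS) -> np.ndarray:
    k = np.arange(n)
    ang = np.radians(twist) * k
    return np.column_stack((radius * np.cos(ang), radius * np.sin(ang), rise * k))


def _coil_trace(n: int, rng: np.random.Generator) -> np.ndarray:
    steps = rng.normal(size=(n - 1, 3))
    steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
    return np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])


def _place_chain(
    trace: np.ndarray,
    centroid: np.ndarray,
    anchor: np.ndarray | None,
    helix: bool = False,
) -> np.ndarray:
    """Place a Cα trace so its centroid lands on ``centroid`` and, if
    given, its last Cα exactly on ``anchor``.

    For helical traces the centroid→anchor distance is matched by
    rescaling the helix rise (the chain stays a perfect helix, only its
    pitch changes), then the chain is rigidly rotated and translated; the
    anchor constraint is thus exact. For coils the small residual is
    redistributed over the other atoms so both constraints stay exact."""
    pts = trace - trace.mean(axis=0)
    if anchor is not None:
        target_dir = np.asarray(anchor, float) - np.asarray(centroid, float)
        D = np.linalg.norm(target_dir)
        if helix:
            # trace axis is z; z is already centered, so scaling z keeps
            # the centroid at the origin
            radial = np.linalg.norm(pts[-1][:2])
            axial = abs(pts[-1][2])
            if D > radial and axial > 1e-9:
                pts = pts * np.array([1.0, 1.0, np.sqrt(D**2 - radial**2) / axial])
        R = _rotation_between(pts[-1], target_dir)
        pts = pts @ R.T
    pts = pts + centroid
    if anchor is not None:
        delta = np.asarray(anchor, float) - pts[-1]
        pts[-1] += delta
        pts[:-1] -= delta / (len(pts) - 1)
    return pts


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation sending direction a to direction b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite directions: rotate 180° about any perpendicular
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def make_toy_complex(spec: ToyComplexSpec = ToyComplexSpec()) -> ComplexModel:
    """Build the four-chain Cα-only toy complex described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.residues_per_chain

    def trace(length: int) -> np.ndarray:
        return _helix_trace(length) if spec.helix else _coil_trace(length, rng)

    ca = np.asarray(spec.receptor_a_centroid, float)
    cb = np.asarray(spec.receptor_b_centroid, float)
    chains = {
        "A": _place_chain(trace(n), ca, np.asarray(spec.anchor_a, float), spec.helix),
        "B": _place_chain(trace(n), cb, np.asarray(spec.anchor_b, float), spec.helix),
        "C": _place_chain(trace(spec.binder_residues), ca + spec.binder_offset_a, None),
        "D": _place_chain(trace(spec.binder_residues), cb + spec.binder_offset_b, None),
    }

    chain_ids, res_ids, coords = [], [], []
    for cid, pts in chains.items():
        for i, p in enumerate(pts, start=1):
            chain_ids.append(cid)
            res_ids.append(str(i))
            coords.append(p)
    n_atoms = len(coords)
    roles = ChainRoleMap(
        fixed_receptor="A",
        mobile_receptor="B",
        binders=("C", "D"),
        membrane_anchor_fixed=("A", str(n)),
        membrane_anchor_mobile=("B", str(n)),
    )
    model = ComplexModel(
        chain_ids=np.array(chain_ids, dtype=object),
        residue_ids=np.array(res_ids, dtype=object),
        residue_names=np.array(["ALA"] * n_atoms, dtype=object),
        atom_names=np.array(["CA"] * n_atoms, dtype=object),
        elements=np.array(["C"] * n_atoms, dtype=object),
        coords=np.array(coords, float),
        roles=roles,
    )
    model.validate_roles()
    return model


# ---------------------------------------------------------------------------
# synthetic dose-response data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCurveSpec:
    """Known-truth dose-response generator.

    ``params`` maps (ligand_id, readout) to 4PL truth dicts with keys
    bottom/top/ec50/hill. The default dose grid is 8 log-spaced points
    from 1 pM to 100 nM with triplicate wells, matching a typical pSTAT
    titration layout; noise is multiplicative with 5% CV.
    """

    params: Mapping[tuple[str, str], Mapping[str, float]] = field(
        default_factory=lambda: {
            ("wt", "pSTAT5"): {"bottom": 0.0, "top": 1000.0, "ec50": 1e-9, "hill": 1.0}
        }
    )
    doses: tuple[float, ...] = tuple(np.logspace(-12, -7, 8))
    replicates: int = 3
    noise: str = "multiplicative"
    cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be positive")
        if self.cv < 0:
            raise ValueError("CV must be non-negative")
        if self.noise not in ("additive", "multiplicative"):
            raise ValueError(f"unknown noise model {self.noise!r}")


def make_synthetic_curves(
    spec: SyntheticCurveSpec = SyntheticCurveSpec(),
) -> tuple[list[DoseResponseData], pd.DataFrame]:
    """Draw replicate responses from known 4PL truths; returns the data
    sets together with a ground-truth table for recovery tests."""
    rng = np.random.default_rng(spec.seed)
    doses = np.repeat(np.asarray(spec.doses, float), spec.replicates)
    datasets = []
    truth_rows = []
    for (ligand, readout), p in spec.params.items():
        clean = p["bottom"] + (p["top"] - p["bottom"]) / (
            1.0 + (p["ec50"] / doses) ** p["hill"]
        )
        if spec.cv == 0:
            resp = clean
        elif spec.noise == "multiplicative":
            resp = clean * (1.0 + rng.normal(0.0, spec.cv, size=clean.shape))
        else:
            resp = clean + rng.normal(0.0, spec.cv * p["top"], size=clean.shape)
        datasets.append(
            DoseResponseData(ligand_id=ligand, readout=readout, doses=doses, responses=resp)
        )
        truth_rows.append(
            {"ligand_id": ligand, "readout": readout, **{k: float(v) for k, v in p.items()}}
        )
    return datasets, pd.DataFrame(truth_rows)


def curves_to_tidy(datasets: list[DoseResponseData]) -> pd.DataFrame:
    rows = []
    for ds in datasets:
        for i, (d, r) in enumerate(zip(ds.doses, ds.responses)):
            rows.append(
                {
                    "ligand_id": ds.ligand_id,
                    "readout": ds.readout,
                    "dose_molar": d,
                    "replicate": i,
                    "response": r,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# geometry–activity benchmarks
# ---------------------------------------------------------------------------

#: descriptor sampling ranges spanning the regimes the scan explores
BENCH_DISTANCE_RANGE = (20.0, 80.0)
BENCH_NATIVE_DISTANCE = 50.0
BENCH_THETA_RANGE = (-180.0, 180.0)
BENCH_LATERAL_RANGE = (0.0, 180.0)


def make_geometry_benchmark(
    n_designs: int,
    relation: str = "distance_linear",
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[list[GeometrySample], pd.DataFrame]:
    """Descriptor sets plus activities with a known generative relation.

    ``distance_linear`` — activity declines linearly with the
    inter-anchor distance (high activity at compact geometries);
    ``lateral_threshold`` — activity collapses for lateral deviations
    ≥ 90°; ``null`` — activity independent of every descriptor.
    Gaussian noise of SD ``noise_sd`` is added in all modes.
    """
    if n_designs < 10:
        raise ValueError("n_designs must be >= 10")
    if relation not in ("distance_linear", "lateral_threshold", "null"):
        raise ValueError(f"unknown relation {relation!r}")
    rng = np.random.default_rng(seed)
    dist = rng.uniform(*BENCH_DISTANCE_RANGE, n_designs)
    theta = rng.uniform(*BENCH_THETA_RANGE, n_designs)
    lateral = rng.uniform(*BENCH_LATERAL_RANGE, n_designs)

    if relation == "distance_linear":
        base = (BENCH_DISTANCE_RANGE[1] - dist) / (
            BENCH_DISTANCE_RANGE[1] - BENCH_DISTANCE_RANGE[0]
        )
    elif relation == "lateral_threshold":
        base = np.where(lateral < 90.0, 1.0, 0.2)
    else:
        base = np.full(n_designs, 0.5)
    sd = noise_sd if relation != "null" else max(noise_sd, 0.1)
    activity = base + rng.normal(0.0, sd, n_designs)

    width = max(4, len(str(n_designs - 1)))
    samples = []
    rows = []
    for i in range(n_designs):
        sid = f"d{i:0{width}d}"
        samples.append(
            GeometrySample(
                id=sid,
                transform=RigidTransform.identity(),
                clash_pairs=0,
                passed_clash=True,
                descriptors=DescriptorSet(
                    termini_distance=float(dist[i]),
                    delta_distance=float(dist[i] - BENCH_NATIVE_DISTANCE),
                    theta_z=float(theta[i]),
                    lateral_deviation=float(lateral[i]),
                ),
            )
        )
        rows.append({"design_id": sid, "activity": float(activity[i])})
    return samples, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# error-path presets
# ---------------------------------------------------------------------------


def preset_degenerate_anchors() -> ToyComplexSpec:
    """Anchors stacked on the frame Z axis: the inter-anchor vector is
    parallel to the membrane normal, so frame construction must fail."""
    return ToyComplexSpec(
        receptor_a_centroid=(0.0, 0.0, 40.0),
        receptor_b_centroid=(0.0, 0.0, 20.0),
        anchor_a=(0.0, 0.0, 12.0),
        anchor_b=(0.0, 0.0, 4.0),
    )


def preset_clashing_binders() -> ToyComplexSpec:
    """Binders placed on top of the partner receptor so the native
    complex already fails the clash filter."""
    return ToyComplexSpec(
        binder_offset_a=(30.0, 0.0, 0.0),   # binder C sits on receptor B
        binder_offset_b=(-30.0, 0.0, 0.0),  # binder D sits on receptor A
    )


def preset_flat_curve() -> SyntheticCurveSpec:
    """A ligand with no dose response (top == bottom)."""
    return SyntheticCurveSpec(
        params={("dead", "pSTAT5"): {"bottom": 100.0, "top": 100.0, "ec50": 1e-9, "hill": 1.0}},
        cv=0.0,
    )
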