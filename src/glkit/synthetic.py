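"""Synthetic data with embedded ground truth for every pipeline stage.

Three generators:

* initial-velocity datasets on the experimental concentration grids, from a
  known mechanism's rate law plus a proportional/additive noise model;
* two-rigid-domain bead structures along a closing trajectory (known hinge
  rotation and mass-center separation);
* noisy scattering curves from any coordinate model (Debye forward model).

Every generator takes an explicit seed, routes all randomness through one
``numpy.random.default_rng`` and embeds its ground truth in the output
metadata so each downstream analysis has a closure test
(generate → analyze → recover truth).
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import kinetics_core as kc
from . import saxs
from .errors import AnalysisError, InputError
from .kinetics_fit import VelocityDataset
from .structure import DomainPartition, StructureModel

#: Fixed-substrate grids of the initial-velocity experiment (µM): the
#: varied-MgADP family used these D-glucose levels and vice versa.
FIG1_GLUCOSE_LEVELS = (30.0, 50.0, 100.0, 150.0, 200.0, 250.0, 500.0, 1000.0)
FIG1_MGADP_LEVELS = (10.0, 30.0, 50.0, 100.0, 300.0, 1000.0)

#: Kinetic constants reported for TlGK (µM; µmol·mg⁻¹·min⁻¹).  Ki_A is not
#: printed and is set equal to Km_A as an explicit stand-in; the product
#: inhibition constants are likewise stand-ins in the experimentally probed
#: concentration range (the supplementary values are not public).
TABLE1_PARAMS = kc.MechanismParams(
    Vmax=67.8, Km_A=8.6, Km_B=218.5, Ki_A=8.6,
    Ki_P=1000.0, Ki_Q=500.0, mechanism="ordered_bibi",
)


# ---------------------------------------------------------------------------
# initial-velocity data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VelocityDesign:
    """Factorial design of an initial-velocity experiment (µM levels)."""

    a_levels: Sequence[float] = FIG1_MGADP_LEVELS
    b_levels: Sequence[float] = FIG1_GLUCOSE_LEVELS
    p_levels: Sequence[float] = (0.0,)
    q_levels: Sequence[float] = (0.0,)
    replicates: int = 1
    noise_proportional: float = 0.0   # fractional sd of multiplicative noise
    noise_additive: float = 0.0       # sd in velocity units
    seed: int | None = None

    def __post_init__(self):
        for name in ("a_levels", "b_levels"):
            if any(not level > 0 for level in getattr(self, name)):
                raise InputError(f"{name} must all be > 0")
        for name in ("p_levels", "q_levels"):
            if any(level < 0 for level in getattr(self, name)):
                raise InputError(f"{name} must all be >= 0")
        if self.noise_proportional < 0 or self.noise_additive < 0:
            raise InputError("noise magnitudes must be >= 0")
        if (self.noise_proportional > 0 or self.noise_additive > 0) and self.seed is None:
            raise InputError("a seed is mandatory for noisy output")
        if self.replicates < 1:
            raise InputError("replicates must be >= 1")


def gen_velocity_data(design: VelocityDesign,
                      truth: kc.MechanismParams = TABLE1_PARAMS) -> VelocityDataset:
    """Initial-velocity dataset from a known mechanism.

    Product-free rows are evaluated with the closed-form forward law;
    rows with products use the numeric steady state of the matching
    4-state scheme (identical where both apply).  Noise model:
    v_obs = v·(1 + σ_prop·ε₁) + σ_add·ε₂ with independent standard
    normals, clipped at zero.
    """
    scheme = kc.ordered_bibi_scheme(truth) if truth.mechanism == "ordered_bibi" else None
    rows = []
    for a, b, p, q in itertools.product(design.a_levels, design.b_levels,
                                        design.p_levels, design.q_levels):
        state = kc.ConcentrationState(A=a, B=b, P=p, Q=q)
        if p == 0 and q == 0:
            if truth.mechanism == "ping_pong":
                v = kc.rate_ping_pong(truth, state)
            else:
                v = kc.rate_ordered_bibi(truth, state)
        else:
            if scheme is None:
                raise InputError(f"product-inhibition rows need an ordered_bibi truth, "
                                 f"not {truth.mechanism}")
            v = kc.steady_state_rate(scheme, state)
        for _ in range(design.replicates):
            rows.append({"A": a, "B": b, "P": p, "Q": q, "v": v})
    frame = pd.DataFrame(rows)
    noisy = design.noise_proportional > 0 or design.noise_additive > 0
    if noisy:
        rng = np.random.default_rng(design.seed)
        v = frame["v"].to_numpy()
        eps1 = rng.standard_normal(len(v))
        eps2 = rng.standard_normal(len(v))
        frame["v"] = np.clip(
            v * (1.0 + design.noise_proportional * eps1) + design.noise_additive * eps2,
            0.0, None)
        frame["sigma"] = np.sqrt((design.noise_proportional * v) ** 2
                                 + design.noise_additive ** 2).clip(min=1e-12)
    metadata = {
        "truth": dataclasses.asdict(truth),
        "design": dataclasses.asdict(design) | {
            "a_levels": list(design.a_levels), "b_levels": list(design.b_levels),
            "p_levels": list(design.p_levels), "q_levels": list(design.q_levels)},
        "seed": design.seed,
    }
    return VelocityDataset(frame, metadata=metadata)


def gen_inhibition_data(
    inhibitor: str,
    varied: str,
    inhibitor_levels: Sequence[float],
    varied_levels: Sequence[float] | None = None,
    co_level: float | None = None,
    truth: kc.MechanismParams = TABLE1_PARAMS,
    noise_proportional: float = 0.0,
    seed: int | None = None,
) -> VelocityDataset:
    """Product-inhibition design: one product varied over levels (including
    0) against one substrate, co-substrate fixed near its Km."""
    if varied not in ("A", "B") or inhibitor not in ("P", "Q"):
        raise InputError("varied must be A or B, inhibitor P or Q")
    km = truth.Km_A if varied == "A" else truth.Km_B
    if varied_levels is None:
        varied_levels = kc.reciprocal_grid(km)
    co = "B" if varied == "A" else "A"
    if co_level is None:
        co_level = truth.Km_B if co == "B" else truth.Km_A
    a_levels = varied_levels if varied == "A" else (co_level,)
    b_levels = varied_levels if varied == "B" else (co_level,)
    design = VelocityDesign(
        a_levels=tuple(a_levels), b_levels=tuple(b_levels),
        p_levels=tuple(inhibitor_levels) if inhibitor == "P" else (0.0,),
        q_levels=tuple(inhibitor_levels) if inhibitor == "Q" else (0.0,),
        noise_proportional=noise_proportional, seed=seed)
    data = gen_velocity_data(design, truth)
    data.metadata["varied"] = varied
    data.metadata["inhibitor"] = inhibitor
    return data


# ---------------------------------------------------------------------------
# two-domain bead structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoDomainSpec:
    """Geometry of a synthetic two-rigid-domain particle (Å, degrees).

    The open form places the small domain's center ``separation_open`` from
    the large domain's; the closed form rotates the small domain by
    ``hinge_angle_deg`` about its centroid and moves it in to
    ``separation_closed`` — a closing rotation-plus-translation with known
    ground truth.
    """

    n_large: int = 220
    n_small: int = 120
    radius_large: float = 16.0
    radius_small: float = 12.0
    separation_open: float = 30.0
    separation_closed: float = 26.5
    hinge_angle_deg: float = 12.0
    n_linker: int = 6
    jitter: float = 0.0
    seed: int = 0
    protein_like: bool = True   # element C beads (Z = 6); else unit mass

    def __post_init__(self):
        if not 0.0 <= self.hinge_angle_deg <= 90.0:
            raise InputError("hinge angle must be within [0, 90] degrees")
        if self.separation_open <= 0 or self.separation_closed <= 0:
            raise InputError("separations must be positive")
        if self.n_large < 4 or self.n_small < 4:
            raise InputError("need at least 4 beads per domain")
        if self.jitter < 0:
            raise InputError("jitter must be >= 0")


def _sphere_cloud(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    u = rng.random(n)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts = v * (radius * u[:, None] ** (1.0 / 3.0))
    return pts - pts.mean(axis=0)  # exact centroid at the origin


def sphere_bead_model(radius: float, spacing: float = 2.0) -> np.ndarray:
    """Deterministic solid-sphere bead model: cubic-lattice points inside a
    sphere of the given radius (Å).  Rg of the point set approaches the
    analytic √(3/5)·R as the spacing shrinks."""
    if not radius > 0 or not spacing > 0:
        raise InputError("radius and spacing must be positive")
    n = int(np.floor(radius / spacing))
    axis = np.arange(-n, n + 1) * spacing
    xx, yy, zz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= radius]
    return pts - pts.mean(axis=0)


def _rot_z(angle_deg: float) -> np.ndarray:
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _bead_model(points: np.ndarray, protein_like: bool) -> StructureModel:
    n = len(points)
    element = "C" if protein_like else "X"
    mass = 12.011 if protein_like else 1.0
    return StructureModel(
        chain=["A"] * n,
        resnum=np.arange(1, n + 1),
        resname=["ALA"] * n,
        atomname=["CA"] * n,
        element=[element] * n,
        mass=np.full(n, mass),
        xyz=points,
        occupancy=np.ones(n),
        altloc=[""] * n,
    )


def gen_two_domain_model(spec: TwoDomainSpec
                         ) -> tuple[StructureModel, StructureModel, dict]:
    """Open and closed conformers of a two-domain bead particle.

    Returns (open model, closed model, truth) where truth records the
    rotation matrix/angle, the translation, the two separations and the
    domain partition (bead residue ranges).  Raises if the closing motion
    drives the domains into overlap.
    """
    rng = np.random.default_rng(spec.seed)
    large = _sphere_cloud(rng, spec.n_large, spec.radius_large)
    small_local = _sphere_cloud(rng, spec.n_small, spec.radius_small)

    open_center = np.array([spec.separation_open, 0.0, 0.0])
    closed_center = np.array([spec.separation_closed, 0.0, 0.0])
    small_open = small_local + open_center
    rot = _rot_z(spec.hinge_angle_deg)
    small_closed = small_local @ rot.T + closed_center

    linker_pts = []
    if spec.n_linker > 0:
        # straight linker between domain surfaces in the open form; excluded
        # from both domains (hinge region)
        start = np.array([spec.radius_large, 0.0, 0.0])
        end = open_center - np.array([spec.radius_small, 0.0, 0.0])
        frac = np.linspace(0.1, 0.9, spec.n_linker)[:, None]
        linker_pts = start + frac * (end - start)

    if spec.jitter > 0:
        large = large + rng.normal(0.0, spec.jitter, large.shape)
        noise_small = rng.normal(0.0, spec.jitter, small_open.shape)
        small_open = small_open + noise_small
        small_closed = small_closed + rng.normal(0.0, spec.jitter, small_closed.shape)

    gap = (np.linalg.norm(small_closed[:, None, :] - large[None, :, :], axis=2)).min()
    if gap <= 0.5:
        raise AnalysisError(
            f"closed-form domains overlap (min bead gap {gap:.2f} Å); "
            "increase separation_closed or reduce the domain radii")

    def assemble(small_pts):
        parts = [large] + ([linker_pts] if spec.n_linker > 0 else []) + [small_pts]
        return _bead_model(np.vstack(parts), spec.protein_like)

    open_model = assemble(small_open)
    closed_model = assemble(small_closed)

    n_l, n_k = spec.n_large, spec.n_linker
    partition = DomainPartition({
        "large": [("A", 1, n_l)],
        "small": [("A", n_l + n_k + 1, n_l + n_k + spec.n_small)],
    })
    truth = {
        "rotation_deg": spec.hinge_angle_deg,
        "rotation_matrix": rot,
        "translation": closed_center - open_center,
        "separation_open": spec.separation_open,
        "separation_closed": spec.separation_closed,
        "partition": partition,
        "seed": spec.seed,
        "spec": dataclasses.asdict(spec),
    }
    return open_model, closed_model, truth


def gen_closing_trajectory(spec: TwoDomainSpec, n_frames: int = 5
                           ) -> tuple[list[StructureModel], dict]:
    """Monotone closing trajectory: angle and separation interpolated
    linearly from the open to the closed geometry over ``n_frames``."""
    if n_frames < 2:
        raise InputError("need at least 2 frames")
    frames = []
    angles = np.linspace(0.0, spec.hinge_angle_deg, n_frames)
    seps = np.linspace(spec.separation_open, spec.separation_closed, n_frames)
    for angle, sep in zip(angles, seps):
        frame_spec = dataclasses.replace(spec, hinge_angle_deg=float(angle),
                                         separation_closed=float(sep))
        _, closed, truth = gen_two_domain_model(frame_spec)
        frames.append(closed)
    return frames, {"angles_deg": angles.tolist(), "separations": seps.tolist(),
                    "partition": truth["partition"], "seed": spec.seed}


# ---------------------------------------------------------------------------
# scattering curves
# ---------------------------------------------------------------------------

def gen_saxs_curve(model, q: np.ndarray | None = None,
                   noise: float = 0.0, seed: int | None = None) -> saxs.ScatteringCurve:
    """Debye profile of a model with multiplicative Gaussian noise of
    fractional sd ``noise``; the σ column records the applied noise level."""
    if noise < 0:
        raise InputError("noise must be >= 0")
    if noise > 0 and seed is None:
        raise InputError("a seed is mandatory for noisy output")
    curve = saxs.debye_profile(model, q)
    if noise == 0:
        return curve
    rng = np.random.default_rng(seed)
    i_noisy = curve.I * (1.0 + noise * rng.standard_normal(curve.I.shape))
    sigma = np.clip(noise * np.abs(curve.I), 1e-12 * max(curve.I.max(), 1.0), None)
    return saxs.ScatteringCurve(curve.q, np.clip(i_noisy, 1e-12, None), sigma)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def write_manifest(path: str | Path, **entries) -> None:
    """Record ground truth and seeds next to generated artifacts."""

    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, DomainPartition):
            return obj.ranges
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        raise TypeError(f"unserializable {type(obj)}")

    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True, default=default))
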