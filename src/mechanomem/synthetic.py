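"""Synthetic fixtures with exact ground truth.

Three families of generators, each a pure function of (spec, seed):

* bead membranes on jittered hexagonal lattices with a prescribed
  deformation field and near-protein species enrichment;
* photobleaching traces drawn from a binomial subunit-labelling model with
  exponential bleach times and additive Gaussian noise;
* toy structures (rigid-transformed copies, kinked helices) with known
  transforms for the structural-comparison metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.spatial.transform import Rotation

from mechanomem.io_formats import (
    AtomModel,
    FrameSet,
    MembraneFrame,
    PROTEIN_SPECIES,
    Trace,
    wrap_coords,
)

DEFAULT_COMPOSITION = {"PE": 0.54, "PC": 0.32, "SM": 0.08, "CHOL": 0.06}


@dataclass(frozen=True)
class MembraneComposition:
    """Molar species fractions; defaults to PE:PC:SM:CHOL = 54:32:8:6."""

    fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")
        if any(v <= 0 for v in self.fractions.values()):
            raise ValueError("all fractions must be positive")

    @property
    def species(self) -> list[str]:
        return list(self.fractions)


@dataclass(frozen=True)
class GaussianBump:
    """One radial Gaussian component of a deformation field.

    ``amplitude`` is the signed z displacement (Angstrom) applied to beads of
    the given leaflet at the component centre; a positive amplitude on the
    lower leaflet moves beads toward the midplane (local thinning), as does a
    negative amplitude on the upper leaflet.
    """

    leaflet: Literal["upper", "lower"]
    amplitude: float
    center: tuple[float, float]
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class DeformationField:
    """Sum of Gaussian bumps: dz(x, y) = sum_i A_i exp(-r_i^2 / (2 s_i^2))."""

    components: tuple[GaussianBump, ...] = ()

    def evaluate(self, leaflet: str, xy: np.ndarray, box: np.ndarray) -> np.ndarray:
        """Signed z displacement at the given xy positions (minimum image)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        dz = np.zeros(len(xy))
        for comp in self.components:
            if comp.leaflet != leaflet:
                continue
            d = xy - np.asarray(comp.center)
            d -= np.round(d / box[:2]) * box[:2]
            r2 = np.sum(d * d, axis=1)
            dz += comp.amplitude * np.exp(-r2 / (2.0 * comp.sigma**2))
        return dz


@dataclass(frozen=True)
class ProteinFootprint:
    """Cylindrical exclusion zone emitted as rings of protein beads."""

    center: tuple[float, float]
    radius: float
    bead_spacing: float = 4.0


@dataclass(frozen=True)
class SyntheticMembraneSpec:
    box: tuple[float, float, float] = (400.0, 400.0, 120.0)
    area_per_lipid: float = 65.0
    leaflet_offset: float = 19.0       # |z| of the phosphate planes
    xy_jitter_sd: float = 0.8
    z_noise_sd: float = 0.8
    composition: MembraneComposition = field(default_factory=MembraneComposition)
    deformation: DeformationField = field(default_factory=DeformationField)
    footprint: ProteinFootprint | None = None
    shell_multipliers: dict[str, float] = field(default_factory=dict)
    shell_distance: float = 7.0
    cholesterol_depth: float = 5.0     # hydroxyl sits this far below the phosphate plane
    n_frames: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("frame count must be >= 1")
        if self.footprint is not None and self.footprint.radius >= min(self.box[:2]) / 2:
            raise ValueError("footprint radius must be < half the smaller box edge")
        if any(m < 0 for m in self.shell_multipliers.values()):
            raise ValueError("shell multipliers must be non-negative")


@dataclass
class MembraneGroundTruth:
    """Everything needed to score the leaflet-map and enrichment estimators."""

    seed: int
    leaflet_offset: float
    deformation: DeformationField
    species: list[str]
    leaflets: list[str]                 # per-lipid leaflet label
    bulk_ratio: dict[str, float]        # realized whole-membrane fractions
    shell_ratio: dict[str, float]       # realized fractions inside the shell
    shell_mask: np.ndarray              # per-lipid: inside enrichment shell
    footprint: ProteinFootprint | None
    cholesterol_depth: float

    def expected_thickness(self, leaflet: str, xy: np.ndarray,
                           box: np.ndarray) -> np.ndarray:
        """Noise-free |z - midplane| of phosphates at the given xy positions."""
        dz = self.deformation.evaluate(leaflet, xy, np.asarray(box))
        sign = 1.0 if leaflet == "upper" else -1.0
        return np.abs(sign * self.leaflet_offset + dz)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "leaflet_offset": self.leaflet_offset,
            "deformation": [
                {"leaflet": c.leaflet, "amplitude": c.amplitude,
                 "center": list(c.center), "sigma": c.sigma}
                for c in self.deformation.components
            ],
            "bulk_ratio": self.bulk_ratio,
            "shell_ratio": self.shell_ratio,
            "n_lipids": len(self.species),
            "footprint": None if self.footprint is None else {
                "center": list(self.footprint.center),
                "radius": self.footprint.radius,
            },
        }


def _hex_lattice(lx: float, ly: float, area_per_site: float) -> np.ndarray:
    """Hexagonal lattice covering [0, lx) x [0, ly) at the given site area."""
    a = math.sqrt(2.0 * area_per_site / math.sqrt(3.0))
    dy = a * math.sqrt(3.0) / 2.0
    nx = max(1, int(round(lx / a)))
    ny = max(1, int(round(ly / dy)))
    ax, ay = lx / nx, ly / ny
    pts = []
    for j in range(ny):
        xoff = 0.5 * ax if j % 2 else 0.0
        for i in range(nx):
            pts.append((i * ax + xoff, j * ay))
    return np.asarray(pts)


def _min_image_xy_dist(xy: np.ndarray, center: np.ndarray, box_xy: np.ndarray) -> np.ndarray:
    d = xy - center
    d -= np.round(d / box_xy) * box_xy
    return np.hypot(d[:, 0], d[:, 1])


def _footprint_beads(fp: ProteinFootprint, z_extent: float) -> np.ndarray:
    """Rings of beads on the footprint cylinder wall spanning +-z_extent."""
    n_ring = max(8, int(round(2.0 * math.pi * fp.radius / fp.bead_spacing)))
    angles = np.linspace(0.0, 2.0 * math.pi, n_ring, endpoint=False)
    n_z = max(2, math.ceil(2.0 * z_extent / fp.bead_spacing) + 1)
    zs = np.linspace(-z_extent, z_extent, n_z)
    ring = np.column_stack([
        fp.center[0] + fp.radius * np.cos(angles),
        fp.center[1] + fp.radius * np.sin(angles),
    ])
    return np.concatenate([
        np.column_stack([ring, np.full(n_ring, z)]) for z in zs
    ])


def build_membrane(spec: SyntheticMembraneSpec) -> tuple[FrameSet, MembraneGroundTruth]:
    """Generate membrane frames with known deformation/enrichment truth.

    Reference beads sit on jittered hexagonal lattices at z = +-z0 + dz(x, y)
    + noise; species are assigned multinomially from the composition, with
    shell multipliers renormalised inside the enrichment shell.  Frames are
    i.i.d. redraws of jitter and noise around the same base lattice; species
    labels and the lattice are fixed across frames.
    """
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    lattice = _hex_lattice(box[0], box[1], spec.area_per_lipid)

    fp = spec.footprint
    if fp is not None:
        center = np.asarray(fp.center)
        keep = _min_image_xy_dist(lattice, center, box[:2]) >= fp.radius
        lattice = lattice[keep]

    n_per_leaflet = len(lattice)
    base_xy = np.concatenate([lattice, lattice])       # upper then lower
    leaflets = ["upper"] * n_per_leaflet + ["lower"] * n_per_leaflet
    n_lipids = len(base_xy)

    # species assignment: shell multipliers renormalised inside the shell
    names = spec.composition.species
    base_p = np.array([spec.composition.fractions[s] for s in names])
    if fp is not None and spec.shell_multipliers:
        d_surface = _min_image_xy_dist(base_xy, np.asarray(fp.center), box[:2]) - fp.radius
        shell_mask = d_surface <= spec.shell_distance
        mult = np.array([spec.shell_multipliers.get(s, 1.0) for s in names])
        shell_p = base_p * mult
        if shell_p.sum() <= 0:
            raise ValueError("shell multipliers zero out the shell composition")
        shell_p = shell_p / shell_p.sum()
    else:
        shell_mask = np.zeros(n_lipids, dtype=bool)
        shell_p = base_p
    idx_bulk = rng.choice(len(names), size=n_lipids, p=base_p)
    idx_shell = rng.choice(len(names), size=n_lipids, p=shell_p)
    species_idx = np.where(shell_mask, idx_shell, idx_bulk)
    species = [names[i] for i in species_idx]

    is_chol = np.array([s == "CHOL" for s in species])
    bead_names = np.where(is_chol, "ROH", "PO4").astype(object)
    sign = np.where(np.array(leaflets) == "upper", 1.0, -1.0)
    ref_abs_z = np.where(is_chol,
                         spec.leaflet_offset - spec.cholesterol_depth,
                         spec.leaflet_offset)

    prot_xyz = None
    if fp is not None:
        prot_xyz = _footprint_beads(fp, spec.leaflet_offset)

    frames = []
    for f in range(spec.n_frames):
        xy = base_xy + rng.normal(0.0, spec.xy_jitter_sd, size=base_xy.shape)
        xy = np.mod(xy, box[:2])
        dz = np.empty(n_lipids)
        for leaflet in ("upper", "lower"):
            m = np.array(leaflets) == leaflet
            dz[m] = spec.deformation.evaluate(leaflet, xy[m], box)
        z = sign * ref_abs_z + dz + rng.normal(0.0, spec.z_noise_sd, size=n_lipids)
        z = z + box[2] / 2.0     # box-centred bilayer
        coords = np.column_stack([xy, z])
        sp = list(species)
        beads = list(bead_names)
        mol_ids = list(range(1, n_lipids + 1))
        if prot_xyz is not None:
            pz = prot_xyz.copy()
            pz[:, 2] += box[2] / 2.0
            coords = np.concatenate([coords, pz])
            sp += [PROTEIN_SPECIES] * len(prot_xyz)
            beads += ["BB"] * len(prot_xyz)
            mol_ids += [n_lipids + 1] * len(prot_xyz)
        frames.append(MembraneFrame(
            species=np.array(sp, dtype=object),
            mol_ids=np.array(mol_ids),
            bead_names=np.array(beads, dtype=object),
            coords=coords,
            box=box,
            time=float(f),
        ))

    counts_bulk = {s: species.count(s) for s in names}
    total = sum(counts_bulk.values())
    in_shell = [sp for sp, m in zip(species, shell_mask) if m]
    shell_total = len(in_shell)
    truth = MembraneGroundTruth(
        seed=spec.seed,
        leaflet_offset=spec.leaflet_offset,
        deformation=spec.deformation,
        species=species,
        leaflets=leaflets,
        bulk_ratio={s: counts_bulk[s] / total for s in names},
        shell_ratio={
            s: (in_shell.count(s) / shell_total if shell_total else float("nan"))
            for s in names
        },
        shell_mask=shell_mask,
        footprint=fp,
        cholesterol_depth=spec.cholesterol_depth,
    )
    return FrameSet(frames, composition=dict(spec.composition.fractions)), truth


# ---------------------------------------------------------------------------
# Photobleaching traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceSpec:
    n_traces: int = 100
    n_subunits: int = 2
    maturation_p: float = 0.8
    unit_intensity: float = 100.0
    noise_sd: float = 10.0
    mean_bleach_frames: float = 100.0
    trace_length: int = 400
    baseline: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.maturation_p <= 1.0:
            raise ValueError("maturation probability must be in [0, 1]")
        if self.n_subunits < 1:
            raise ValueError("subunit count must be >= 1")
        if self.trace_length <= 0:
            raise ValueError("trace length must be positive")


@dataclass
class TraceGroundTruth:
    seed: int
    n_subunits: int
    maturation_p: float
    k_true: list[int]                  # active fluorophores per trace
    step_frames: list[list[int]]       # sorted bleach frames per trace

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_subunits": self.n_subunits,
            "maturation_p": self.maturation_p,
            "k_true": self.k_true,
            "step_frames": self.step_frames,
        }


def _truncated_exponential(rng: np.random.Generator, mean: float, upper: float,
                           size: int) -> np.ndarray:
    u = rng.uniform(size=size)
    return -mean * np.log1p(-u * (1.0 - math.exp(-upper / mean)))


def make_traces(spec: TraceSpec) -> tuple[list[Trace], TraceGroundTruth]:
    """Photobleaching traces from the binomial subunit-labelling model.

    Per trace: k ~ Binomial(n, p) active fluorophores; k bleach times i.i.d.
    exponential (mean ``mean_bleach_frames``) truncated to the trace length;
    intensity = baseline + unit * (number still active) + Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    traces: list[Trace] = []
    k_true: list[int] = []
    step_frames: list[list[int]] = []
    T = spec.trace_length
    for i in range(spec.n_traces):
        k = int(rng.binomial(spec.n_subunits, spec.maturation_p))
        times = _truncated_exponential(rng, spec.mean_bleach_frames, T - 1, k)
        steps = sorted(int(np.clip(math.ceil(t), 1, T - 1)) for t in times)
        frames = np.arange(T)
        active = np.sum(frames[:, None] < np.asarray(steps)[None, :], axis=1) if k else np.zeros(T)
        intensity = spec.baseline + spec.unit_intensity * active
        if spec.noise_sd > 0:
            intensity = intensity + rng.normal(0.0, spec.noise_sd, size=T)
        traces.append(Trace(f"trace{i:05d}", intensity))
        k_true.append(k)
        step_frames.append(steps)
    truth = TraceGroundTruth(spec.seed, spec.n_subunits, spec.maturation_p,
                             k_true, step_frames)
    return traces, truth


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------

@dataclass
class TransformGroundTruth:
    rotation: np.ndarray           # 3x3
    translation: np.ndarray        # applied after rotation about the centroid
    angle_deg: float
    axis: np.ndarray

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "angle_deg": self.angle_deg,
            "axis": self.axis.tolist(),
        }


def make_rotated_copy(model: AtomModel, axis, angle_deg: float,
                      translation=(0.0, 0.0, 0.0)) -> tuple[AtomModel, TransformGroundTruth]:
    """Exact rigid-transformed copy: rotate about the centroid, then translate."""
    if len(model) == 0:
        raise ValueError("model is empty")
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("rotation axis must be non-zero")
    axis = axis / norm
    rot = Rotation.from_rotvec(axis * math.radians(angle_deg))
    R = rot.as_matrix()
    coords = model.coords
    centroid = coords.mean(axis=0)
    moved = (coords - centroid) @ R.T + centroid + np.asarray(translation, dtype=float)
    truth = TransformGroundTruth(R, np.asarray(translation, dtype=float),
                                 angle_deg, axis)
    return model.with_coords(moved), truth


def make_helix(n_res: int, rise: float = 1.5, twist: float = 100.0,
               radius: float = 2.3, kink: float = 0.0) -> np.ndarray:
    """Ideal alpha-helix CA trace along +z, optionally kinked at the midpoint.

    The kink tilts the C-terminal half about the x axis through the helix
    axis point at the split, by ``kink`` degrees.
    """
    if n_res < 8:
        raise ValueError("need at least 8 residues for axis fitting")
    i = np.arange(n_res)
    theta = np.radians(twist) * i
    coords = np.column_stack([
        radius * np.cos(theta),
        radius * np.sin(theta),
        rise * i,
    ])
    if kink != 0.0:
        mid = n_res // 2
        pivot = np.array([0.0, 0.0, rise * mid])
        R = Rotation.from_rotvec([math.radians(kink), 0.0, 0.0]).as_matrix()
        coords[mid:] = (coords[mid:] - pivot) @ R.T + pivot
    return coords
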