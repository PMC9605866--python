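"""Rigid-body comparison metrics between structural states.

Least-squares superposition (Kabsch with reflection correction), domain
rotation angles, helix bend geometry, centroid separations, and
solvent-accessible / buried interface surface areas (Shrake-Rupley with a
deterministic Fibonacci sphere).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import Align
from scipy.spatial import cKDTree

from mechanomem.io_formats import (
    AtomModel,
    EmptySelectionError,
    SelectionSpec,
    apply_selection,
)

# vdW radii (Angstrom); replaceable because the published areas' radii are
# unstated.
DEFAULT_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20,
}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M", "SEC": "U", "PYL": "O",
}


class DegenerateGeometryError(ValueError):
    """Too few or collinear points for a unique superposition."""


@dataclass
class SuperpositionResult:
    """Optimal rigid transform mapping the mobile set onto the reference."""

    rotation: np.ndarray       # 3x3 proper orthogonal
    translation: np.ndarray    # applied after rotation
    rmsd: float
    angle_deg: float           # arccos((trace(R) - 1) / 2)
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    @property
    def axis(self) -> np.ndarray:
        """Unit rotation axis (arbitrary for angle 0)."""
        R = self.rotation
        v = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        n = np.linalg.norm(v)
        return v / n if n > 1e-12 else np.array([0.0, 0.0, 1.0])


def superpose(reference: np.ndarray, mobile: np.ndarray) -> SuperpositionResult:
    """Kabsch least-squares superposition of correspondence-ordered sets.

    The SVD determinant sign is corrected so the returned rotation is always
    proper (no reflection).
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("inputs must be equal-shape (N, 3) arrays")
    n = len(ref)
    if n < 3:
        raise DegenerateGeometryError("need at least 3 paired points")
    ref_mean = ref.mean(axis=0)
    mob_mean = mob.mean(axis=0)
    ref_c = ref - ref_mean
    mob_c = mob - mob_mean
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2 or np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise DegenerateGeometryError("points are collinear")
    H = mob_c.T @ ref_c
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    moved = mob_c @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref_c) ** 2, axis=1))))
    cos_t = (np.trace(R) - 1.0) / 2.0
    angle = math.degrees(math.acos(min(1.0, max(-1.0, cos_t))))
    translation = ref_mean - R @ mob_mean
    return SuperpositionResult(R, translation, rmsd, angle, n)


# ---------------------------------------------------------------------------
# Atom pairing
# ---------------------------------------------------------------------------

def _residues(model: AtomModel) -> list[tuple[tuple, str]]:
    """Ordered unique residues [(chain, resnum, icode), resname] of a model."""
    seen: dict[tuple, str] = {}
    for a in model.atoms:
        seen.setdefault((a.chain, a.res_num, a.icode), a.res_name)
    return list(seen.items())


def pair_atoms(model_1: AtomModel, sel_1: SelectionSpec,
               model_2: AtomModel, sel_2: SelectionSpec,
               mode: str = "by-key", residue_offset: int = 0
               ) -> tuple[np.ndarray, np.ndarray, list[tuple]]:
    """Paired coordinate sets from two models.

    by-key
        Intersect on (residue number, insertion code, atom name);
        ``residue_offset`` is added to model-2 residue numbers first.
    by-alignment
        Global sequence alignment of the selections' residue sequences
        (match/mismatch/gap = 1/-1/-2), CA atoms of aligned columns only.

    Returns (coords_1, coords_2, pair keys).
    """
    a1 = apply_selection(model_1, sel_1)
    a2 = apply_selection(model_2, sel_2)
    if mode == "by-key":
        map2 = {(a.res_num + residue_offset, a.icode, a.atom_name): a for a in a2.atoms}
        pairs = [
            (a, map2[(a.res_num, a.icode, a.atom_name)])
            for a in a1.atoms
            if (a.res_num, a.icode, a.atom_name) in map2
        ]
    elif mode == "by-alignment":
        res1 = _residues(a1)
        res2 = _residues(a2)
        seq1 = "".join(_THREE_TO_ONE.get(r, "X") for _, r in res1)
        seq2 = "".join(_THREE_TO_ONE.get(r, "X") for _, r in res2)
        aligner = Align.PairwiseAligner(
            mode="global", match_score=1, mismatch_score=-1,
            open_gap_score=-2, extend_gap_score=-2,
        )
        aln = aligner.align(seq1, seq2)[0]
        ca1 = {(a.chain, a.res_num, a.icode): a for a in a1.atoms if a.atom_name == "CA"}
        ca2 = {(a.chain, a.res_num, a.icode): a for a in a2.atoms if a.atom_name == "CA"}
        pairs = []
        for (s1, e1), (s2, e2) in zip(*aln.aligned):
            for i, j in zip(range(s1, e1), range(s2, e2)):
                k1, k2 = res1[i][0], res2[j][0]
                if k1 in ca1 and k2 in ca2:
                    pairs.append((ca1[k1], ca2[k2]))
    else:
        raise ValueError(f"unknown pairing mode {mode!r}")
    if not pairs:
        raise EmptySelectionError("no atom pairs between the two selections")
    c1 = np.array([[p[0].x, p[0].y, p[0].z] for p in pairs])
    c2 = np.array([[p[1].x, p[1].y, p[1].z] for p in pairs])
    keys = [(p[0].key, p[1].key) for p in pairs]
    return c1, c2, keys


def domain_rotation(model_e: AtomModel, model_c: AtomModel,
                    anchor: SelectionSpec, moving: SelectionSpec,
                    mode: str = "by-key", residue_offset: int = 0) -> float:
    """Rotation angle (degrees) of the moving selection between two models.

    First superposes model_e onto model_c over the anchor pairs, then
    superposes the transformed moving selection onto its counterpart; the
    angle of that second rotation is returned.
    """
    a_e, a_c, _ = pair_atoms(model_e, anchor, model_c, anchor, mode, residue_offset)
    global_fit = superpose(a_c, a_e)
    m_e, m_c, _ = pair_atoms(model_e, moving, model_c, moving, mode, residue_offset)
    local_fit = superpose(m_c, global_fit.apply(m_e))
    return local_fit.angle_deg


# ---------------------------------------------------------------------------
# Helix geometry
# ---------------------------------------------------------------------------

@dataclass
class HelixGeometry:
    axis_n: np.ndarray
    axis_c: np.ndarray
    bend_deg: float
    centroid: np.ndarray
    axial_length: float


def _principal_axis(coords: np.ndarray, turn: int = 4) -> np.ndarray:
    """Dominant principal direction, oriented from first toward last point.

    Coordinates are first averaged over a sliding window of one helical turn
    (~3.6 residues) so that incomplete turns do not tilt the axis; short
    segments fall back to the raw points.
    """
    if len(coords) >= turn + 3:
        kernel = np.full(turn, 1.0 / turn)
        coords = np.column_stack([
            np.convolve(coords[:, k], kernel, mode="valid") for k in range(3)
        ])
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    if np.dot(axis, coords[-1] - coords[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _helix_axis(coords: np.ndarray) -> np.ndarray:
    """Helix axis from successive second-difference cross products.

    Second differences of an ideal helix point radially inward, so the cross
    product of two successive ones lies exactly along the axis, independent
    of segment length or phase.  Falls back to the principal direction for
    degenerate (straight-chain) input.
    """
    dd = np.diff(coords, n=2, axis=0)
    crosses = np.cross(dd[:-1], dd[1:])
    norms = np.linalg.norm(crosses, axis=1)
    good = norms > 1e-9
    if not good.any():
        return _principal_axis(coords)
    units = crosses[good] / norms[good, None]
    # align all samples with the first before averaging (sign ambiguity)
    units[units @ units[0] < 0] *= -1
    axis = units.mean(axis=0)
    axis /= np.linalg.norm(axis)
    if np.dot(axis, coords[-1] - coords[0]) < 0:
        axis = -axis
    return axis


def helix_geometry(coords: np.ndarray, split: int | None = None) -> HelixGeometry:
    """Two-half axis bend of an ordered CA trace.

    Each half's axis comes from :func:`_helix_axis` oriented N to C; the
    bend is the angle between the half axes.  ``split`` defaults to the
    midpoint CA.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (N, 3)")
    n = len(coords)
    if n < 8:
        raise ValueError("need at least 8 CA atoms")
    if split is None:
        split = n // 2
    if split < 4 or n - split < 4:
        raise ValueError("need at least 4 CA atoms in each half")
    axis_n = _helix_axis(coords[:split])
    axis_c = _helix_axis(coords[split:])
    cos_b = float(np.clip(np.dot(axis_n, axis_c), -1.0, 1.0))
    bend = math.degrees(math.acos(cos_b))
    full_axis = _principal_axis(coords)
    proj = coords @ full_axis
    return HelixGeometry(axis_n, axis_c, bend, coords.mean(axis=0),
                         float(proj.max() - proj.min()))


def centroid_distance(set_1: np.ndarray, set_2: np.ndarray) -> float:
    """Euclidean distance between arithmetic centroids."""
    c1 = np.asarray(set_1, dtype=float)
    c2 = np.asarray(set_2, dtype=float)
    if c1.size == 0 or c2.size == 0:
        raise ValueError("empty coordinate set")
    return float(np.linalg.norm(c1.reshape(-1, 3).mean(axis=0) -
                                c2.reshape(-1, 3).mean(axis=0)))


# ---------------------------------------------------------------------------
# Solvent-accessible surface area
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit sphere sampling (no RNG)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _atom_radii(model: AtomModel, radii: dict[str, float]) -> np.ndarray:
    missing = sorted({a.element for a in model.atoms if a.element not in radii})
    if missing:
        offenders = [a.key for a in model.atoms if a.element in missing][:5]
        raise ValueError(
            f"no vdW radius configured for element(s) {missing}; "
            f"offending atoms include {offenders}"
        )
    return np.array([radii[a.element] for a in model.atoms])


def sasa(model: AtomModel, probe: float = 1.4, points: int = 960,
         radii: dict[str, float] | None = None) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area.

    Per atom: area = 4 pi (r + probe)^2 times the fraction of deterministic
    Fibonacci-sphere sample points not inside any neighbour's probe-expanded
    sphere.  Returns (per-atom areas, total), in square Angstrom.
    """
    if radii is None:
        radii = DEFAULT_RADII
    if len(model) == 0:
        raise ValueError("empty model")
    r = _atom_radii(model, radii) + probe
    coords = model.coords
    sphere = fibonacci_sphere(points)
    tree = cKDTree(coords)
    r_max = r.max()
    areas = np.empty(len(model))
    neighbor_lists = tree.query_ball_point(coords, 2.0 * r_max)
    for i in range(len(model)):
        nbrs = [j for j in neighbor_lists[i]
                if j != i and np.linalg.norm(coords[j] - coords[i]) < r[i] + r[j]]
        pts = coords[i] + r[i] * sphere
        if nbrs:
            d2 = np.sum((pts[:, None, :] - coords[nbrs][None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < (r[nbrs] ** 2)[None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * math.pi * r[i] ** 2 * frac
    return areas, float(areas.sum())


@dataclass
class InterfaceArea:
    """SASA bookkeeping for a two-part complex.

    ``buried`` is sasa_A + sasa_B - sasa_AB; ``interface`` is buried / 2.
    Both conventions are reported because published numbers rarely state
    which was used.
    """

    sasa_a: float
    sasa_b: float
    sasa_ab: float
    probe: float
    points: int

    @property
    def buried(self) -> float:
        return self.sasa_a + self.sasa_b - self.sasa_ab

    @property
    def interface(self) -> float:
        return self.buried / 2.0

    def to_dict(self) -> dict:
        return {
            "sasa_A": self.sasa_a, "sasa_B": self.sasa_b, "sasa_AB": self.sasa_ab,
            "buried": self.buried, "interface": self.interface,
            "probe": self.probe, "points": self.points,
        }


def buried_interface_area(model: AtomModel, part_a: SelectionSpec,
                          part_b: SelectionSpec, probe: float = 1.4,
                          points: int = 960,
                          radii: dict[str, float] | None = None) -> InterfaceArea:
    """Buried SASA between two disjoint parts of a model."""
    sub_a = apply_selection(model, part_a)
    sub_b = apply_selection(model, part_b)
    keys_a = {a.key for a in sub_a.atoms}
    overlap = keys_a & {a.key for a in sub_b.atoms}
    if overlap:
        raise ValueError(f"selections overlap on {len(overlap)} atoms, "
                         f"e.g. {sorted(overlap)[:3]}")
    _, total_a = sasa(sub_a, probe, points, radii)
    _, total_b = sasa(sub_b, probe, points, radii)
    combined = AtomModel(sub_a.atoms + sub_b.atoms, model.model_id)
    _, total_ab = sasa(combined, probe, points, radii)
    return InterfaceArea(total_a, total_b, total_ab, probe, points)
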