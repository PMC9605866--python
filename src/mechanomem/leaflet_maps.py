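"""Per-leaflet membrane thickness and lipid density maps.

Thickness is the z distance of phospholipid phosphate beads from the bilayer
midplane, binned on a 2 Angstrom xy grid and averaged per bin over the frame
window (second half of the frame set by default).  The midplane is the mean
phosphate z of each frame, recomputed per frame.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from mechanomem.io_formats import FrameSet, MembraneFrame, write_grid

logger = logging.getLogger(__name__)


@dataclass
class ThicknessMap:
    """Binned mean |z_phosphate - z_midplane| for one leaflet.

    ``mean`` is NaN wherever ``count`` is zero (empty bins are missing, never
    zero: protein-occupied bins must not read as zero thickness).
    """

    leaflet: str
    bin_size: float
    origin: tuple[float, float]
    box: tuple[float, float]
    mean: np.ndarray            # (nx, ny)
    count: np.ndarray           # (nx, ny) int
    window: tuple[int, int]     # [first, last] frame indices used

    @property
    def n_samples(self) -> int:
        return int(self.count.sum())

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.mean.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.bin_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.bin_size
        return xs, ys

    def write(self, path) -> None:
        write_grid(path, self.mean, self.count, {
            "kind": "thickness",
            "leaflet": self.leaflet,
            "bin": self.bin_size,
            "origin": self.origin,
            "box": self.box,
            "window": self.window,
        })


@dataclass
class DensityMap:
    """Raw per-bin counts of one species' reference bead over the window."""

    species: str
    bin_size: float
    origin: tuple[float, float]
    box: tuple[float, float]
    count: np.ndarray
    window: tuple[int, int]

    @property
    def n_samples(self) -> int:
        return int(self.count.sum())

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.count.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.bin_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.bin_size
        return xs, ys

    def write(self, path) -> None:
        write_grid(path, self.count.astype(float), self.count, {
            "kind": "density",
            "species": self.species,
            "bin": self.bin_size,
            "origin": self.origin,
            "box": self.box,
            "window": self.window,
        })


@dataclass
class RadialProfile:
    """Thickness vs distance from the protein surface, annulus-averaged."""

    r_edges: np.ndarray         # strictly increasing, length n_bins + 1
    mean: np.ndarray            # per-annulus weighted mean thickness (NaN if empty)
    count: np.ndarray           # per-annulus sample count
    bulk: float                 # weighted mean beyond the bulk distance

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])


def compute_midplane(frame: MembraneFrame) -> float:
    """Global midplane: mean z over all phospholipid phosphate beads."""
    mask = frame.phosphate_mask()
    if not mask.any():
        raise ValueError("frame contains no phosphate beads")
    return float(frame.coords[mask, 2].mean())


def assign_leaflets(frame: MembraneFrame, z0: float) -> np.ndarray:
    """Leaflet label per reference bead ("upper"/"lower", "" for non-reference).

    A bead exactly at the midplane is assigned upper, with a warning.
    """
    labels = np.full(len(frame), "", dtype=object)
    ref = frame.reference_mask()
    z = frame.coords[:, 2]
    ties = ref & (z == z0)
    if ties.any():
        logger.warning("%d reference beads exactly at the midplane; assigned upper",
                       int(ties.sum()))
    labels[ref & (z >= z0)] = "upper"
    labels[ref & (z < z0)] = "lower"
    return labels


def _grid_shape(box: np.ndarray, bin_size: float) -> tuple[int, int]:
    return (max(1, math.ceil(box[0] / bin_size - 1e-9)),
            max(1, math.ceil(box[1] / bin_size - 1e-9)))


def _window_indices(frames: FrameSet, window: str) -> tuple[int, int]:
    n = len(frames)
    if window == "full":
        return 0, n - 1
    if window == "half":
        return n // 2, n - 1
    raise ValueError(f"unknown window {window!r}")


def thickness_map(frames: FrameSet, leaflet: str, bin_size: float = 2.0,
                  window: str = "half") -> ThicknessMap:
    """Mean per-bin |z_phosphate - midplane| for one leaflet over the window."""
    if leaflet not in ("upper", "lower"):
        raise ValueError(f"leaflet must be 'upper' or 'lower', got {leaflet!r}")
    first, last = _window_indices(frames, window)
    if last < first:
        raise ValueError("empty frame window")
    box = frames[first].box
    nx, ny = _grid_shape(box, bin_size)
    total = np.zeros((nx, ny))
    count = np.zeros((nx, ny), dtype=int)
    for frame in frames[first:last + 1]:
        z0 = compute_midplane(frame)
        labels = assign_leaflets(frame, z0)
        mask = frame.phosphate_mask() & (labels == leaflet)
        xy = frame.coords[mask, :2]
        thick = np.abs(frame.coords[mask, 2] - z0)
        ix = np.minimum((xy[:, 0] / bin_size).astype(int), nx - 1)
        iy = np.minimum((xy[:, 1] / bin_size).astype(int), ny - 1)
        np.add.at(total, (ix, iy), thick)
        np.add.at(count, (ix, iy), 1)
    mean = np.full((nx, ny), np.nan)
    occupied = count > 0
    mean[occupied] = total[occupied] / count[occupied]
    return ThicknessMap(leaflet, bin_size, (0.0, 0.0), (float(box[0]), float(box[1])),
                        mean, count, (first, last))


def density_map(frames: FrameSet, species: str, bin_size: float = 2.0,
                window: str = "half") -> DensityMap:
    """Per-bin counts of one species' reference bead over the window."""
    if frames.composition and species not in frames.composition:
        raise ValueError(f"species {species!r} not in composition declaration "
                         f"{sorted(frames.composition)}")
    first, last = _window_indices(frames, window)
    box = frames[first].box
    nx, ny = _grid_shape(box, bin_size)
    count = np.zeros((nx, ny), dtype=int)
    seen = False
    for frame in frames[first:last + 1]:
        mask = frame.reference_mask() & frame.mask_species(species)
        seen = seen or mask.any()
        xy = frame.coords[mask, :2]
        ix = np.minimum((xy[:, 0] / bin_size).astype(int), nx - 1)
        iy = np.minimum((xy[:, 1] / bin_size).astype(int), ny - 1)
        np.add.at(count, (ix, iy), 1)
    if not seen and not frames.composition:
        raise ValueError(f"species {species!r} absent from all frames")
    return DensityMap(species, bin_size, (0.0, 0.0), (float(box[0]), float(box[1])),
                      count, (first, last))


def radial_thickness_profile(tmap: ThicknessMap, center: tuple[float, float],
                             protein_radius: float, r_bin: float = 4.0,
                             bulk_distance: float | None = None) -> RadialProfile:
    """Annulus-averaged thickness vs distance from the protein surface.

    Grid bins are grouped by d = (minimum-image xy distance to ``center``)
    minus ``protein_radius``; bins with d < 0 (inside the footprint) are
    dropped.  Annulus means are count-weighted.  The bulk reference is the
    weighted mean over annuli beyond ``bulk_distance`` (defaults to 2/3 of
    the maximum distance).
    """
    xs, ys = tmap.bin_centers()
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    box = np.asarray(tmap.box)
    dx = gx - center[0]
    dy = gy - center[1]
    dx -= np.round(dx / box[0]) * box[0]
    dy -= np.round(dy / box[1]) * box[1]
    d = np.hypot(dx, dy) - protein_radius
    occ = tmap.count > 0
    keep = occ & (d >= 0)
    if not keep.any():
        raise ValueError("all occupied bins are inside the protein footprint")
    d_keep = d[keep]
    w = tmap.count[keep].astype(float)
    vals = tmap.mean[keep]
    d_max = d_keep.max()
    n_annuli = max(1, math.ceil(d_max / r_bin))
    edges = np.arange(n_annuli + 1) * r_bin
    idx = np.minimum((d_keep / r_bin).astype(int), n_annuli - 1)
    wsum = np.bincount(idx, weights=w, minlength=n_annuli)
    vsum = np.bincount(idx, weights=w * vals, minlength=n_annuli)
    mean = np.full(n_annuli, np.nan)
    occ_a = wsum > 0
    mean[occ_a] = vsum[occ_a] / wsum[occ_a]
    if bulk_distance is None:
        bulk_distance = 2.0 * d_max / 3.0
    bulk_sel = occ_a & (edges[:-1] >= bulk_distance)
    if not bulk_sel.any():
        bulk_sel = occ_a
    bulk = float(np.sum(vsum[bulk_sel]) / np.sum(wsum[bulk_sel]))
    return RadialProfile(edges, mean, wsum.astype(int), bulk)


@dataclass
class PropagationResult:
    distance: float
    converged: bool


def propagation_distance(profile: RadialProfile, tolerance: float) -> PropagationResult:
    """Smallest d* with |mean - bulk| < tolerance for every annulus beyond d*.

    Returns the outermost annulus edge flagged unconverged when the condition
    is never satisfied.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    dev = np.abs(profile.mean - profile.bulk)
    occupied = profile.count > 0
    violating = occupied & (dev >= tolerance)
    if not violating.any():
        return PropagationResult(0.0, True)
    last_bad = int(np.nonzero(violating)[0][-1])
    d_star = float(profile.r_edges[last_bad + 1])
    converged = last_bad + 1 < len(profile.mean)
    return PropagationResult(d_star, converged)


def fit_radial_gaussian(profile: RadialProfile,
                        offset: float = 0.0) -> tuple[float, float]:
    """Least-squares (amplitude, sigma) of a radial Gaussian deviation.

    Fits mean(d) = bulk + A exp(-(d + offset)^2 / (2 sigma^2)) on the annulus
    means; ``offset`` maps surface distances back to centre distances when
    the field is centred on the protein.  The returned amplitude is the
    signed thickness deviation at d = -offset.
    """
    occ = profile.count > 0
    r = profile.r_centers[occ] + offset
    y = profile.mean[occ] - profile.bulk
    if len(r) < 3:
        raise ValueError("too few occupied annuli to fit")
    a0 = y[np.argmax(np.abs(y))]
    s0 = max(profile.r_edges[-1] / 4.0, 1.0)

    def model(rr, a, s):
        return a * np.exp(-rr**2 / (2.0 * s**2))

    popt, _ = curve_fit(model, r, y, p0=[a0, s0],
                        sigma=1.0 / np.sqrt(profile.count[occ]), maxfev=10000)
    return float(popt[0]), float(abs(popt[1]))
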