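"""Lipid composition of the protein shell and the depletion-enrichment index.

A lipid is "in shell" in a frame when the minimum-image distance from its
reference bead to the nearest protein bead is at most the cutoff (7 Angstrom
by default).  The index for species L is its fractional abundance in the
shell divided by its fractional abundance in the whole membrane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from mechanomem.io_formats import FrameSet, PROTEIN_SPECIES


@dataclass
class ShellCounts:
    """Frame-averaged per-species bead counts in the shell and overall."""

    cutoff: float
    shell: dict[str, float]        # mean count within cutoff, per species
    total: dict[str, float]        # mean whole-membrane count, per species
    n_frames: int
    window: str = "full"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        for s, c in self.shell.items():
            if c > self.total.get(s, 0.0) + 1e-9:
                raise ValueError(f"shell count exceeds total for {s}")


@dataclass
class EnrichmentTable:
    """Shell ratio, bulk ratio and index per species.

    ``index[s]`` is NaN (and listed in ``undefined``) when the bulk ratio is
    zero.
    """

    shell_ratio: dict[str, float]
    bulk_ratio: dict[str, float]
    index: dict[str, float]
    cutoff: float
    n_frames: int
    window: str = "full"
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "species": {
                s: {
                    "shell_ratio": self.shell_ratio[s],
                    "bulk_ratio": self.bulk_ratio[s],
                    "index": self.index[s],
                }
                for s in self.index
            },
            "cutoff": self.cutoff,
            "n_frames": self.n_frames,
            "window": self.window,
            "undefined": self.undefined,
        }


def _shell_mask_frame(ref_xyz: np.ndarray, protein_xyz: np.ndarray,
                      box: np.ndarray, cutoff: float) -> np.ndarray:
    """True per reference bead within cutoff of any protein bead (periodic)."""
    tree = cKDTree(np.mod(protein_xyz, box), boxsize=box)
    d, _ = tree.query(np.mod(ref_xyz, box), k=1)
    return d <= cutoff


def shell_composition(frames: FrameSet, protein: np.ndarray | None = None,
                      cutoff: float = 7.0, window: str = "full") -> ShellCounts:
    """Per-species reference-bead counts within ``cutoff`` of the protein.

    ``protein`` is an (M, 3) coordinate set used for every frame; when None,
    protein beads are taken from each frame's "PROT" species.  Counts are
    averaged over the frames of the window.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sub = frames.window(window)
    if len(sub) == 0:
        raise ValueError("empty frame window")
    species_names = sorted({str(s) for s in sub[0].species if s != PROTEIN_SPECIES})
    shell_sum = {s: 0.0 for s in species_names}
    total_sum = {s: 0.0 for s in species_names}
    for frame in sub:
        if protein is None:
            prot_xyz = frame.coords[frame.mask_species(PROTEIN_SPECIES)]
        else:
            prot_xyz = np.asarray(protein, dtype=float)
        if len(prot_xyz) == 0:
            raise ValueError("empty protein coordinate set")
        ref = frame.reference_mask()
        in_shell = np.zeros(len(frame), dtype=bool)
        in_shell[ref] = _shell_mask_frame(frame.coords[ref], prot_xyz,
                                          frame.box, cutoff)
        for s in species_names:
            m = frame.mask_species(s) & ref
            total_sum[s] += int(m.sum())
            shell_sum[s] += int((m & in_shell).sum())
    n = len(sub)
    return ShellCounts(
        cutoff=cutoff,
        shell={s: shell_sum[s] / n for s in species_names},
        total={s: total_sum[s] / n for s in species_names},
        n_frames=n,
        window=window,
    )


def depletion_enrichment_index(shell: ShellCounts) -> EnrichmentTable:
    """index(L) = ratio(L)_shell / ratio(L)_bulk.

    ratio(L)_shell is species L's mean shell count as a fraction of the total
    mean shell count; ratio(L)_bulk likewise over the whole membrane.
    Frame averaging happens on counts before ratio formation.
    """
    total_bulk = sum(shell.total.values())
    if total_bulk <= 0:
        raise ValueError("no lipids in the membrane")
    total_shell = sum(shell.shell.values())
    shell_ratio = {}
    bulk_ratio = {}
    index = {}
    undefined = []
    for s in shell.total:
        bulk_ratio[s] = shell.total[s] / total_bulk
        shell_ratio[s] = shell.shell[s] / total_shell if total_shell > 0 else float("nan")
        if total_shell <= 0 or bulk_ratio[s] == 0:
            index[s] = float("nan")
            undefined.append(s)
        else:
            index[s] = shell_ratio[s] / bulk_ratio[s]
    return EnrichmentTable(shell_ratio, bulk_ratio, index, shell.cutoff,
                           shell.n_frames, shell.window, undefined)


def mean_of_ratio_index(frames: FrameSet, protein: np.ndarray | None = None,
                        cutoff: float = 7.0, window: str = "full") -> EnrichmentTable:
    """Alternative estimator: average per-frame indices instead of counts.

    Frames with an empty shell contribute nothing.  Provided because the
    averaging order is a modelling choice; the count-averaged
    :func:`depletion_enrichment_index` is the default.
    """
    sub = frames.window(window)
    per_frame: list[EnrichmentTable] = []
    for i in range(len(sub)):
        one = FrameSet([sub[i]], sub.composition)
        counts = shell_composition(one, protein, cutoff, "full")
        if sum(counts.shell.values()) > 0:
            per_frame.append(depletion_enrichment_index(counts))
    if not per_frame:
        raise ValueError("shell empty in every frame")
    species = per_frame[0].index.keys()
    index = {s: float(np.mean([t.index[s] for t in per_frame])) for s in species}
    shell_ratio = {s: float(np.mean([t.shell_ratio[s] for t in per_frame])) for s in species}
    bulk_ratio = per_frame[0].bulk_ratio
    return EnrichmentTable(shell_ratio, bulk_ratio, index, cutoff,
                           len(per_frame), window)
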