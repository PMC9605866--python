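"""Readers and writers for the text formats the pipeline touches.

Covers fixed-column PDB (with MODEL/ENDMDL blocks), concatenated GRO frame
files for bead membranes, delimited photobleaching trace tables, grid TSV
files with ``# key=value`` metadata headers, and a small selection language
for addressing subsets of atoms.

All coordinates are handled in Angstrom internally; GRO files (nm) are
converted at the boundary.
"""

from __future__ import annotations

import fnmatch
import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# Default reference-bead names: phosphate for phospholipids, hydroxyl for
# cholesterol.  Covers Martini bead naming and atomistic phosphorus naming.
PHOSPHATE_BEADS = frozenset({"PO4", "P", "P8"})
HYDROXYL_BEADS = frozenset({"ROH", "O3", "OH"})
CHOLESTEROL_SPECIES = frozenset({"CHOL", "CHL1", "ERG"})
PROTEIN_SPECIES = "PROT"


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


class EmptyInputError(ValueError):
    """File contained no usable records."""


class EmptySelectionError(ValueError):
    """A selection matched no atoms."""


# ---------------------------------------------------------------------------
# Atom models (PDB)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """A single atom record.

    Residue identity is the triple (chain, residue number, insertion code).
    """

    chain: str
    res_num: int
    icode: str
    res_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    b_factor: float = 0.0

    @property
    def key(self) -> tuple:
        return (self.chain, self.res_num, self.icode, self.atom_name)

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class AtomModel:
    """A parsed structure: one MODEL block of a PDB file."""

    atoms: list[Atom]
    model_id: int = 1

    def __post_init__(self) -> None:
        coords = self.coords
        if len(self.atoms) and not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates in model")
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise ValueError(f"duplicate atom key {dup} in model {self.model_id}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms]).reshape(-1, 3)

    def with_coords(self, coords: np.ndarray) -> "AtomModel":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            replace(a, x=float(c[0]), y=float(c[1]), z=float(c[2]))
            for a, c in zip(self.atoms, coords)
        ]
        return AtomModel(atoms, self.model_id)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)


_TWO_LETTER_ELEMENTS = frozenset({
    "FE", "ZN", "MG", "MN", "CA", "NA", "CL", "BR", "CU", "NI", "CO", "SE",
})


def _infer_element(atom_name: str, res_name: str) -> str:
    """Element from the atom-name column when the element column is absent.

    CA is calcium only when it is its own residue (ion); in amino acids it is
    an alpha carbon.
    """
    name = atom_name.strip()
    stripped = "".join(c for c in name if c.isalpha())
    if not stripped:
        raise ValueError(f"cannot infer element for atom name {atom_name!r}")
    two = stripped[:2].upper()
    if two in _TWO_LETTER_ELEMENTS and res_name.strip().upper() == two:
        return two.capitalize()
    return stripped[0].upper()


def _parse_pdb_atom_line(line: str, lineno: int) -> Atom:
    try:
        res_num = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_s = line[54:60].strip()
        b_s = line[60:66].strip()
        occupancy = float(occ_s) if occ_s else 1.0
        b_factor = float(b_s) if b_s else 0.0
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed PDB record at line {lineno}: {line.rstrip()!r}") from exc
    res_name = line[17:20].strip()
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _infer_element(line[12:16], res_name)
    else:
        element = element.capitalize()
    return Atom(
        chain=line[21].strip() or " ",
        res_num=res_num,
        icode=line[26].strip() if len(line) > 26 else "",
        res_name=res_name,
        atom_name=line[12:16].strip(),
        element=element,
        x=x, y=y, z=z,
        occupancy=occupancy,
        b_factor=b_factor,
    )


def _dedup_altloc(records: list[tuple[str, Atom]]) -> list[Atom]:
    """Keep the highest-occupancy alternate location per atom identity."""
    best: dict[tuple, tuple[int, str, Atom]] = {}
    order: list[tuple] = []
    for i, (altloc, atom) in enumerate(records):
        k = atom.key
        if k not in best:
            best[k] = (i, altloc, atom)
            order.append(k)
        else:
            _, _, prev = best[k]
            if atom.occupancy > prev.occupancy:
                best[k] = (best[k][0], altloc, atom)
    return [best[k][2] for k in order]


def read_pdb(path: str | Path) -> list[AtomModel]:
    """Parse a fixed-column PDB file into one :class:`AtomModel` per MODEL.

    Files without MODEL records yield a single model.  Alternate locations
    are reduced to the highest-occupancy copy; insertion codes are kept as
    part of residue identity.

    Raises
    ------
    ParseError
        On a malformed fixed-width record (message names the line number).
    EmptyInputError
        If the file holds no ATOM/HETATM records.
    """
    path = Path(path)
    models: list[AtomModel] = []
    records: list[tuple[str, Atom]] = []
    model_id = 1
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                try:
                    model_id = int(line[6:].split()[0])
                except (ValueError, IndexError):
                    model_id = len(models) + 1
                in_model = True
                records = []
            elif rec == "ENDMDL":
                models.append(AtomModel(_dedup_altloc(records), model_id))
                records = []
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                altloc = line[16] if len(line) > 16 else " "
                records.append((altloc, _parse_pdb_atom_line(line, lineno)))
    if records:
        models.append(AtomModel(_dedup_altloc(records), model_id if in_model else 1))
    if not models or all(len(m) == 0 for m in models):
        raise EmptyInputError(f"no ATOM/HETATM records in {path}")
    return models


def write_pdb(models: AtomModel | Sequence[AtomModel], path: str | Path) -> None:
    """Write one or more models as a fixed-column PDB file."""
    if isinstance(models, AtomModel):
        models = [models]
    multi = len(models) > 1
    with open(path, "w") as fh:
        for model in models:
            if multi:
                fh.write(f"MODEL {model.model_id:>8d}\n")
            for serial, a in enumerate(model.atoms, start=1):
                name = a.atom_name
                # column 13 is reserved for 2-letter element symbols
                name_field = f" {name:<3s}" if len(name) < 4 and len(a.element) < 2 else f"{name:<4s}"
                fh.write(
                    "ATOM  {serial:>5d} {name}{alt}{res:<3s} {chain}{resnum:>4d}{icode}"
                    "   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n".format(
                        serial=serial % 100000,
                        name=name_field,
                        alt=" ",
                        res=a.res_name[:3],
                        chain=(a.chain or " ")[:1],
                        resnum=a.res_num,
                        icode=(a.icode or " ")[:1],
                        x=a.x, y=a.y, z=a.z,
                        occ=a.occupancy, b=a.b_factor,
                        el=a.element.upper()[:2],
                    )
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Membrane frames (GRO)
# ---------------------------------------------------------------------------

def wrap_coords(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into the primary box [0, L) along each periodic axis."""
    coords = np.asarray(coords, dtype=float)
    box = np.asarray(box, dtype=float)
    wrapped = np.mod(coords, box)
    # float rounding can land exactly on the box edge for tiny negatives
    return np.where(wrapped >= box, wrapped - box, wrapped)


@dataclass
class MembraneFrame:
    """One time point of a bead membrane: species-labelled reference beads.

    Coordinates are in Angstrom, wrapped into [0, L) on construction.
    """

    species: np.ndarray       # str array, length N
    mol_ids: np.ndarray       # int array, length N
    bead_names: np.ndarray    # str array, length N
    coords: np.ndarray        # (N, 3) float, Angstrom
    box: np.ndarray           # (3,) float, Angstrom
    time: float = 0.0

    def __post_init__(self) -> None:
        self.species = np.asarray(self.species, dtype=object)
        self.mol_ids = np.asarray(self.mol_ids, dtype=int)
        self.bead_names = np.asarray(self.bead_names, dtype=object)
        self.box = np.asarray(self.box, dtype=float)
        coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates in frame")
        self.coords = wrap_coords(coords, self.box)

    def __len__(self) -> int:
        return len(self.mol_ids)

    def mask_species(self, species: str) -> np.ndarray:
        return np.asarray([s == species for s in self.species], dtype=bool)

    def reference_mask(
        self,
        phosphate_beads: frozenset[str] = PHOSPHATE_BEADS,
        hydroxyl_beads: frozenset[str] = HYDROXYL_BEADS,
    ) -> np.ndarray:
        """True for each particle that is a lipid reference bead."""
        names = self.bead_names
        ref = phosphate_beads | hydroxyl_beads
        is_ref = np.asarray([b in ref for b in names], dtype=bool)
        is_prot = self.mask_species(PROTEIN_SPECIES)
        return is_ref & ~is_prot

    def phosphate_mask(
        self, phosphate_beads: frozenset[str] = PHOSPHATE_BEADS
    ) -> np.ndarray:
        """True for phospholipid phosphate beads (cholesterol excluded)."""
        is_p = np.asarray([b in phosphate_beads for b in self.bead_names], dtype=bool)
        is_chol = np.asarray([s in CHOLESTEROL_SPECIES for s in self.species], dtype=bool)
        is_prot = self.mask_species(PROTEIN_SPECIES)
        return is_p & ~is_chol & ~is_prot


@dataclass
class FrameSet:
    """An ordered sequence of membrane frames sharing particle identity."""

    frames: list[MembraneFrame]
    composition: dict[str, float] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        if self.frames:
            n0 = len(self.frames[0])
            sp0 = list(self.frames[0].species)
            for i, f in enumerate(self.frames[1:], start=1):
                if len(f) != n0:
                    raise ValueError(f"frame {i} particle count {len(f)} != {n0}")
                if list(f.species) != sp0:
                    raise ValueError(f"frame {i} species labels differ from frame 0")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return FrameSet(self.frames[i], self.composition, self.source)
        return self.frames[i]

    def window(self, which: str = "half") -> "FrameSet":
        """Frame window selection: "half" keeps the second half, "full" all."""
        if which == "full":
            return self
        if which == "half":
            return self[len(self.frames) // 2:]
        raise ValueError(f"unknown window {which!r}")


def read_gro_frames(path: str | Path) -> FrameSet:
    """Read a concatenated multi-block GRO file into a :class:`FrameSet`.

    GRO positions (nm) are converted to Angstrom.  The residue-name field is
    taken as the species label and the residue number as molecule id.
    """
    path = Path(path)
    frames: list[MembraneFrame] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i].rstrip("\n")
        time = 0.0
        if "t=" in title:
            try:
                time = float(title.split("t=")[1].split()[0])
            except (ValueError, IndexError):
                pass
        if i + 1 >= n_lines:
            raise ParseError(f"truncated GRO block at line {i + 1}")
        try:
            count = int(lines[i + 1])
        except ValueError as exc:
            raise ParseError(f"bad particle count at line {i + 2}: {lines[i + 1]!r}") from exc
        body_start = i + 2
        body_end = body_start + count
        if body_end >= n_lines + 1 or body_end > n_lines:
            raise ParseError(
                f"GRO block starting at line {i + 1} declares {count} particles "
                f"but the file ends early"
            )
        species, mol_ids, beads, coords = [], [], [], []
        for j in range(body_start, body_end):
            line = lines[j]
            try:
                mol_ids.append(int(line[0:5]))
                species.append(line[5:10].strip())
                beads.append(line[10:15].strip())
                coords.append(
                    (float(line[20:28]), float(line[28:36]), float(line[36:44]))
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(f"malformed GRO particle line {j + 1}: {line.rstrip()!r}") from exc
        if body_end >= n_lines:
            raise ParseError(f"missing box line after GRO block at line {i + 1}")
        box_fields = lines[body_end].split()
        if len(box_fields) < 3:
            raise ParseError(f"malformed box line {body_end + 1}: {lines[body_end]!r}")
        box = np.array([float(v) for v in box_fields[:3]]) * 10.0
        frames.append(
            MembraneFrame(
                species=np.array(species, dtype=object),
                mol_ids=np.array(mol_ids),
                bead_names=np.array(beads, dtype=object),
                coords=np.array(coords) * 10.0,
                box=box,
                time=time,
            )
        )
        i = body_end + 1
    if not frames:
        raise EmptyInputError(f"no GRO blocks in {path}")
    return FrameSet(frames, source=str(path))


def write_gro_frames(frames: FrameSet | Iterable[MembraneFrame], path: str | Path,
                     title: str = "membrane frame") -> None:
    """Write frames as concatenated GRO blocks (Angstrom -> nm)."""
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"{title}, t= {frame.time:.3f}\n")
            fh.write(f"{len(frame)}\n")
            nm = frame.coords / 10.0
            for k in range(len(frame)):
                fh.write(
                    "{resid:>5d}{res:<5s}{bead:>5s}{serial:>5d}"
                    "{x:8.3f}{y:8.3f}{z:8.3f}\n".format(
                        resid=int(frame.mol_ids[k]) % 100000,
                        res=str(frame.species[k])[:5],
                        bead=str(frame.bead_names[k])[:5],
                        serial=(k + 1) % 100000,
                        x=nm[k, 0], y=nm[k, 1], z=nm[k, 2],
                    )
                )
            bx = frame.box / 10.0
            fh.write(f"{bx[0]:10.5f}{bx[1]:10.5f}{bx[2]:10.5f}\n")


# ---------------------------------------------------------------------------
# Photobleaching traces
# ---------------------------------------------------------------------------

@dataclass
class Trace:
    """A single-molecule fluorescence time series at uniform frame spacing."""

    trace_id: str
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError(f"trace {self.trace_id}: non-finite intensities")

    def __len__(self) -> int:
        return len(self.intensities)


def read_traces(path: str | Path) -> list[Trace]:
    """Read a delimited trace table (columns: trace id, frame, intensity).

    Traces are grouped by id and sorted by frame index; the frame index must
    be strictly increasing and uniformly spaced within each trace.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    expected = {"trace_id", "frame", "intensity"}
    if not expected.issubset(df.columns):
        raise ParseError(
            f"trace table must have columns {sorted(expected)}, got {list(df.columns)}"
        )
    if not pd.api.types.is_numeric_dtype(df["intensity"]):
        bad = df.loc[pd.to_numeric(df["intensity"], errors="coerce").isna()]
        raise ParseError(f"non-numeric intensity values, e.g. row {bad.index[0]}")
    traces = []
    for tid, grp in df.groupby("trace_id", sort=False):
        frames = grp["frame"].to_numpy()
        order = np.argsort(frames, kind="stable")
        frames = frames[order]
        diffs = np.diff(frames)
        if len(diffs) and (np.any(diffs <= 0)):
            raise ParseError(f"trace {tid}: frame index not strictly increasing")
        if len(diffs) > 1 and not np.all(diffs == diffs[0]):
            raise ParseError(f"trace {tid}: non-uniform frame spacing")
        traces.append(Trace(str(tid), grp["intensity"].to_numpy()[order]))
    if not traces:
        raise EmptyInputError(f"no traces in {path}")
    return traces


def write_traces(traces: Iterable[Trace], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("trace_id\tframe\tintensity\n")
        for t in traces:
            for frame, val in enumerate(t.intensities):
                fh.write(f"{t.trace_id}\t{frame}\t{val:.6g}\n")


# ---------------------------------------------------------------------------
# Grid files
# ---------------------------------------------------------------------------

def write_grid(path: str | Path, mean: np.ndarray, count: np.ndarray,
               meta: dict[str, object]) -> None:
    """Write a 2D grid as long-format TSV with ``# key=value`` header lines.

    Bins with zero count are written with an empty mean field, never as zero.
    """
    mean = np.asarray(mean, dtype=float)
    count = np.asarray(count, dtype=int)
    with open(path, "w") as fh:
        for key, val in meta.items():
            if isinstance(val, (tuple, list, np.ndarray)):
                val = " ".join(f"{v:g}" if isinstance(v, (int, float, np.floating)) else str(v) for v in val)
            fh.write(f"# {key}={val}\n")
        fh.write(f"# shape={mean.shape[0]} {mean.shape[1]}\n")
        fh.write("ix\tiy\tmean\tcount\n")
        for ix in range(mean.shape[0]):
            for iy in range(mean.shape[1]):
                m = "" if count[ix, iy] == 0 else f"{mean[ix, iy]:.6f}"
                fh.write(f"{ix}\t{iy}\t{m}\t{count[ix, iy]}\n")


def read_grid(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict[str, str]]:
    """Read a grid TSV written by :func:`write_grid`.

    Returns (mean, count, metadata); empty bins read back as NaN.
    """
    meta: dict[str, str] = {}
    body = io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("# "):
                key, _, val = line[2:].rstrip("\n").partition("=")
                meta[key] = val
            else:
                body.write(line)
    body.seek(0)
    if "shape" not in meta:
        raise ParseError(f"grid file {path} missing shape header")
    nx, ny = (int(v) for v in meta["shape"].split())
    df = pd.read_csv(body, sep="\t")
    mean = np.full((nx, ny), np.nan)
    count = np.zeros((nx, ny), dtype=int)
    mean[df["ix"], df["iy"]] = df["mean"]
    count[df["ix"], df["iy"]] = df["count"]
    return mean, count, meta


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionSpec:
    """Atom-subset specification: chains AND residue range AND name pattern.

    Any criterion left as None matches everything.  The atom-name pattern
    uses glob semantics ("C*" matches CA, CB but not N).
    """

    chains: frozenset[str] | None = None
    res_range: tuple[int, int] | None = None
    atom_pattern: str | None = None

    def __post_init__(self) -> None:
        if self.res_range is not None and self.res_range[0] > self.res_range[1]:
            raise ValueError(f"residue range start > end: {self.res_range}")
        if self.chains is not None:
            object.__setattr__(self, "chains", frozenset(self.chains))

    def matches(self, atom: Atom) -> bool:
        if self.chains is not None and atom.chain not in self.chains:
            return False
        if self.res_range is not None and not (
            self.res_range[0] <= atom.res_num <= self.res_range[1]
        ):
            return False
        if self.atom_pattern is not None and not fnmatch.fnmatchcase(
            atom.atom_name, self.atom_pattern
        ):
            return False
        return True

    def __str__(self) -> str:
        parts = []
        if self.chains is not None:
            parts.append("chain " + "+".join(sorted(self.chains)))
        if self.res_range is not None:
            parts.append(f"{self.res_range[0]}:{self.res_range[1]}")
        if self.atom_pattern is not None:
            parts.append(f"name {self.atom_pattern}")
        return ", ".join(parts) or "all"


def parse_selection(text: str) -> SelectionSpec:
    """Parse a selection string like ``"chain A+B, 74:459, name CA"``."""
    chains: frozenset[str] | None = None
    res_range: tuple[int, int] | None = None
    pattern: str | None = None
    for token in (t.strip() for t in text.split(",")):
        if not token:
            continue
        low = token.lower()
        if low.startswith("chain "):
            chains = frozenset(token[6:].strip().split("+"))
        elif low.startswith("name "):
            pattern = token[5:].strip()
        elif ":" in token:
            a, b = token.split(":", 1)
            res_range = (int(a), int(b))
        else:
            raise ValueError(f"cannot parse selection token {token!r}")
    return SelectionSpec(chains=chains, res_range=res_range, atom_pattern=pattern)


def apply_selection(model: AtomModel, spec: SelectionSpec) -> AtomModel:
    """Atoms of ``model`` matching ``spec``, ordered by (chain, residue, name).

    Raises :class:`EmptySelectionError` when nothing matches.
    """
    if len(model) == 0:
        raise EmptyInputError("cannot select from an empty model")
    picked = [a for a in model.atoms if spec.matches(a)]
    if not picked:
        raise EmptySelectionError(f"selection {spec} matched no atoms")
    picked.sort(key=lambda a: (a.chain, a.res_num, a.icode, a.atom_name))
    return AtomModel(picked, model.model_id)
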