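"""Regression metrics against deposited coordinate files.

These helpers drive the comparison metrics with selections read from a TOML
config (chains and residue ranges must come from the deposited files' own
annotations).  They are exercised only when the structure files are present
locally; nothing here downloads anything.
"""

from __future__ import annotations

import os
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from mechanomem import structure_compare as sc
from mechanomem.io_formats import AtomModel, SelectionSpec, apply_selection, read_pdb

DEFAULT_CONFIG = Path(__file__).resolve().parents[2] / "configs" / "deposited_models.toml"
STRUCTURE_DIR_ENV = "MECHANOMEM_STRUCTURE_DIR"


class StructuresUnavailable(RuntimeError):
    """Deposited structure files or their selection config are missing."""


@dataclass
class DepositedModels:
    expanded: AtomModel
    contracted: AtomModel
    cib3_complex: AtomModel
    config: dict


def _structure_dir() -> Path:
    env = os.environ.get(STRUCTURE_DIR_ENV)
    if env:
        return Path(env)
    return Path.cwd() / "data" / "structures"


def load_deposited(config_path: Path | str = DEFAULT_CONFIG) -> DepositedModels:
    """Load the three deposited models plus the selection config.

    Raises :class:`StructuresUnavailable` with an actionable message when the
    files are absent or the config's selections have not been filled in from
    the deposited annotations.
    """
    config_path = Path(config_path)
    if not config_path.exists():
        raise StructuresUnavailable(f"selection config {config_path} not found")
    with open(config_path, "rb") as fh:
        cfg = tomllib.load(fh)
    sdir = _structure_dir()
    paths = {k: sdir / v for k, v in cfg["files"].items()}
    missing = [str(p) for p in paths.values() if not p.exists()]
    if missing:
        raise StructuresUnavailable(
            "deposited coordinate files not found: " + ", ".join(missing)
            + f"; download them and place them in {sdir} (or set "
            + f"${STRUCTURE_DIR_ENV})"
        )
    if not cfg["calm1"]["chain"] or not cfg["anchor_protomer"]["chain"]:
        raise StructuresUnavailable(
            f"selections in {config_path} are unset; fill in the chain ids "
            "and residue ranges from the deposited files' annotations"
        )
    return DepositedModels(
        expanded=read_pdb(paths["expanded"])[0],
        contracted=read_pdb(paths["contracted"])[0],
        cib3_complex=read_pdb(paths["cib3_complex"])[0],
        config=cfg,
    )


def calm1_cib3_rmsd(models: DepositedModels) -> float:
    """CA RMSD of CALM-1 (expanded model) onto CIB3, paired by alignment."""
    cfg = models.config
    sel_calm = SelectionSpec(chains=frozenset({cfg["calm1"]["chain"]}),
                             atom_pattern="CA")
    sel_cib3 = SelectionSpec(chains=frozenset({cfg["cib3"]["chain"]}),
                             atom_pattern="CA")
    c1, c2, _ = sc.pair_atoms(models.cib3_complex, sel_cib3,
                              models.expanded, sel_calm, mode="by-alignment")
    return sc.superpose(c1, c2).rmsd


def half_complex_rotation(models: DepositedModels) -> float:
    """Rotation of one half-complex between the two states, anchored on the
    other pore-subunit protomer."""
    cfg = models.config
    anchor = SelectionSpec(chains=frozenset({cfg["anchor_protomer"]["chain"]}),
                           atom_pattern="CA")
    moving = SelectionSpec(chains=frozenset(cfg["moving_half"]["chains"]),
                           atom_pattern="CA")
    return sc.domain_rotation(models.expanded, models.contracted, anchor,
                              moving, mode="by-alignment")


def _helix_ca(model: AtomModel, chain: str, start: int, end: int) -> np.ndarray:
    sel = apply_selection(model, SelectionSpec(
        chains=frozenset({chain}), res_range=(start, end), atom_pattern="CA"))
    atoms = sorted(sel.atoms, key=lambda a: (a.res_num, a.icode))
    return np.array([[a.x, a.y, a.z] for a in atoms])


def tm10_bend_difference(models: DepositedModels) -> float:
    """TM10 bend angle, contracted minus expanded (degrees)."""
    cfg = models.config["tm10"]
    bends = {}
    for name, model in (("e", models.expanded), ("c", models.contracted)):
        ca = _helix_ca(model, cfg["chain"], cfg["res_start"], cfg["res_end"])
        bends[name] = sc.helix_geometry(ca).bend_deg
    return bends["c"] - bends["e"]


def h3_separation_difference(models: DepositedModels) -> float:
    """H3-H3 centroid separation, expanded minus contracted (Angstrom)."""
    cfg = models.config["h3"]
    seps = {}
    for name, model in (("e", models.expanded), ("c", models.contracted)):
        a = _helix_ca(model, cfg["chain_a"], cfg["res_start"], cfg["res_end"])
        b = _helix_ca(model, cfg["chain_b"], cfg["res_start"], cfg["res_end"])
        seps[name] = sc.centroid_distance(a, b)
    return seps["e"] - seps["c"]


def buried_areas(models: DepositedModels) -> dict[str, sc.InterfaceArea]:
    """Dimer-interface and CALM-1 interface buried SASA on the expanded model."""
    out = {}
    for key in ("dimer_interface", "calm1_interface"):
        cfg = models.config[key]
        out[key] = sc.buried_interface_area(
            models.expanded,
            SelectionSpec(chains=frozenset({cfg["chain_a"]})),
            SelectionSpec(chains=frozenset({cfg["chain_b"]})),
        )
    return out
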