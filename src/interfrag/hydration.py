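"""Interfacial water selection and hydration-shell classification.

A water is interfacial when its oxygen lies within ``d_max`` of heavy
atoms of *both* solute partners (target and ligand).  Retained waters
are classified by a single distance d_w = max(d_to_target, d_to_ligand):
Shell 1 holds the closest waters (d_w <= 3.5 A), Shell 2 the remaining
intermediate ones, and Shell 3 is their union -- it is always derived,
never stored.  The max convention makes "interfacial" and "Shell 3"
coincide exactly; a min convention is available for sensitivity checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from interfrag.structure_io import Atom, Residue

__all__ = [
    "ShellAssignment",
    "select_interfacial_waters",
    "assign_shells",
    "remove_clashing_waters",
]

SHELL1_CUTOFF_DEFAULT = 3.5


@dataclass
class ShellAssignment:
    """A retained interfacial water with its solute distances and shell."""

    water: Residue
    d_to_target: float
    d_to_ligand: float
    shell: int  # 1 or 2; Shell 3 = Shell 1 union Shell 2


def _water_oxygen(water: Residue) -> Optional[Atom]:
    for atom in water.atoms:
        if atom.element == "O":
            return atom
    return None


def _pooled_heavy_coords(residues: Sequence[Residue]) -> np.ndarray:
    blocks = [r.heavy_coords() for r in residues]
    blocks = [b for b in blocks if b.shape[0]]
    if not blocks:
        raise ValueError("no heavy atoms in solute residue list")
    return np.vstack(blocks)


def select_interfacial_waters(
    waters: Sequence[Residue],
    target: Sequence[Residue],
    ligand: Sequence[Residue],
    d_max: float,
) -> list[tuple[Residue, float, float]]:
    """Retain waters whose oxygen is within ``d_max`` of heavy atoms of
    both the target and the ligand.

    Returns ``(water, d_to_target, d_to_ligand)`` triples in input
    order.  Waters without an oxygen atom are dropped with a warning.
    """
    if not d_max > 0:
        raise ValueError("d_max must be positive")
    if not waters:
        return []
    t_coords = _pooled_heavy_coords(target)
    l_coords = _pooled_heavy_coords(ligand)
    out: list[tuple[Residue, float, float]] = []
    for water in waters:
        oxygen = _water_oxygen(water)
        if oxygen is None:
            warnings.warn(
                f"water {water.label} has no oxygen atom; dropped",
                stacklevel=2,
            )
            continue
        o = oxygen.xyz.reshape(1, 3)
        d_t = float(cdist(o, t_coords).min())
        d_l = float(cdist(o, l_coords).min())
        if d_t <= d_max and d_l <= d_max:
            out.append((water, d_t, d_l))
    return out


def assign_shells(
    retained: Sequence[tuple[Residue, float, float]],
    shell1_cutoff: float = SHELL1_CUTOFF_DEFAULT,
    convention: str = "max",
) -> list[ShellAssignment]:
    """Classify retained interfacial waters into Shells 1 and 2.

    The classification distance is ``max`` (default) or ``min`` of the
    two solute distances; Shell 1 if it is <= ``shell1_cutoff``, else
    Shell 2.  |Shell 1| + |Shell 2| always equals the retained count.
    """
    if convention not in ("max", "min"):
        raise ValueError("convention must be 'max' or 'min'")
    pick = max if convention == "max" else min
    out = []
    for water, d_t, d_l in retained:
        d_w = pick(d_t, d_l)
        out.append(
            ShellAssignment(
                water=water,
                d_to_target=d_t,
                d_to_ligand=d_l,
                shell=1 if d_w <= shell1_cutoff else 2,
            )
        )
    return out


def remove_clashing_waters(
    waters: Sequence[Residue],
    ligand: Sequence[Residue],
    d_min: float,
) -> list[Residue]:
    """Drop waters whose oxygen lies strictly closer than ``d_min`` to any
    ligand heavy atom (a water at exactly ``d_min`` is kept)."""
    if not d_min > 0:
        raise ValueError("d_min must be positive")
    if not waters:
        return []
    l_coords = _pooled_heavy_coords(ligand)
    out = []
    for water in waters:
        oxygen = _water_oxygen(water)
        if oxygen is None:
            out.append(water)  # cannot clash-test; dropped later at selection
            continue
        d = float(cdist(oxygen.xyz.reshape(1, 3), l_coords).min())
        if d >= d_min:
            out.append(water)
    return out
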