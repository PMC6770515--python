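"""Deterministic toy complexes with planted ground truth, and loaders
for the shipped 15-system reference benchmark tables.

The generator builds an ideal-geometry extended peptide chain (bond
lengths N-CA 1.458 A, CA-C 1.525 A, C-N 1.329 A) as the target, places
single ligand "probe" atoms so that chosen residues have an exactly
known closest-heavy-atom distance, and positions water oxygens at
prescribed (distance-to-target, distance-to-ligand) pairs by sphere
intersection.  Every planted quantity is re-measured after generation;
a mismatch raises, so a returned structure is guaranteed to realise its
plan.  All placement is deterministic; the seed only drives optional
coordinate jitter on atoms that do not enter any planted distance.
"""

from __future__ import annotations

import hashlib
import io
import math
from dataclasses import dataclass, field
from importlib import resources


import numpy as np
import pandas as pd

from interfrag.fragmenter_core import closest_heavy_distance
from interfrag.structure_io import Atom, ComplexStructure, Residue

__all__ = [
    "GenerationError",
    "ToyComplexSpec",
    "ReferenceTables",
    "MODEL_COLUMNS",
    "make_toy_complex",
    "load_reference_tables",
]

# ideal backbone geometry (Angstrom)
_N_CA = 1.458
_CA_C = 1.525
_C_N = 1.329
_N_TO_C_SPAN = 2.45  # intra-residue N...C distance of the extended template
_PITCH = _N_TO_C_SPAN + _C_N  # translation between successive residues
_CA_X = (_N_TO_C_SPAN**2 + _N_CA**2 - _CA_C**2) / (2 * _N_TO_C_SPAN)
_CA_Y = math.sqrt(_N_CA**2 - _CA_X**2)

_PLACEMENT_TOL = 1e-3


class GenerationError(ValueError):
    """A toy-complex plan could not be realised."""


@dataclass
class ToyComplexSpec:
    """Plan for a synthetic target-ligand-water complex.

    planted_interface maps target residue index (0-based) to the exact
    closest-heavy-atom distance that residue should have to the ligand.
    water_plan lists (d_to_target, d_to_ligand) pairs, realised for the
    water oxygen relative to all solute heavy atoms; the first planted
    residue and its probe atom serve as the anchor pair, so at least one
    planted residue is required when waters are planned.
    """

    n_target_residues: int = 8
    residue_names: dict[int, str] = field(default_factory=dict)
    #: total ligand atoms; silently raised to one probe per planted residue
    ligand_atom_count: int = 1
    ligand_offset: float = 8.0
    planted_interface: dict[int, float] = field(default_factory=dict)
    water_plan: list[tuple[float, float]] = field(default_factory=list)
    disulfide_pairs: list[tuple[int, int]] = field(default_factory=list)
    cys_protonated: frozenset[int] = frozenset()
    his_protons: dict[int, tuple[str, ...]] = field(default_factory=dict)
    water_res_name: str = "WAT"
    jitter_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_target_residues < 1:
            raise GenerationError("need at least one target residue")
        self.ligand_atom_count = max(
            self.ligand_atom_count, 1, len(self.planted_interface)
        )
        for idx, d in self.planted_interface.items():
            if not (0 <= idx < self.n_target_residues):
                raise GenerationError(f"planted index {idx} out of range")
            if d <= 0:
                raise GenerationError(f"planted distance must be positive")
        if self.water_plan and not self.planted_interface:
            raise GenerationError("water_plan requires a planted residue")
        for d_t, d_l in self.water_plan:
            if d_t <= 0 or d_l <= 0:
                raise GenerationError("water distances must be positive")


def _backbone(i: int, name: str) -> dict[str, np.ndarray]:
    """Ideal extended-backbone heavy atoms of residue i."""
    x0 = i * _PITCH
    n = np.array([x0, 0.0, 0.0])
    ca = np.array([x0 + _CA_X, _CA_Y, 0.0])
    c = np.array([x0 + _N_TO_C_SPAN, 0.0, 0.0])
    o = c + 1.229 * np.array([0.5, -0.8660254, 0.0])
    atoms = {"N": n, "CA": ca, "C": c, "O": o}
    if name != "GLY":
        atoms["CB"] = ca + np.array([0.0, 1.52, 0.0])
    return atoms


def make_toy_complex(spec: ToyComplexSpec) -> ComplexStructure:
    """Build and self-validate a toy complex (chains A/L/W).

    Returns a :class:`ComplexStructure` whose measured planted distances
    agree with the plan to within 1e-3 A (otherwise raises
    :class:`GenerationError`).  Identical specs give byte-identical PDB
    output downstream.
    """
    rng = np.random.default_rng(spec.seed)
    serial = iter(range(1, 10**6))

    target: list[Residue] = []
    backbone_sets: dict[int, dict[str, np.ndarray]] = {}
    for i in range(spec.n_target_residues):
        name = spec.residue_names.get(i, "ALA")
        atoms = _backbone(i, name)
        backbone_sets[i] = atoms
        if spec.jitter_scale > 0:
            atoms["O"] = atoms["O"] + rng.normal(
                scale=spec.jitter_scale, size=3
            )
        residue_atoms = [
            Atom(serial=next(serial), name=an, element=an[0], xyz=pos)
            for an, pos in atoms.items()
        ]
        if name in ("CYS", "CYX"):
            sg = atoms["CB"] + np.array([0.0, 0.0, 1.81])
            residue_atoms.append(
                Atom(serial=next(serial), name="SG", element="S", xyz=sg)
            )
            if i in spec.cys_protonated:
                residue_atoms.append(
                    Atom(
                        serial=next(serial),
                        name="HG",
                        element="H",
                        xyz=sg + np.array([0.0, 0.0, 1.34]),
                    )
                )
        if name in ("HIS", "HID", "HIE", "HIP"):
            cb = atoms["CB"]
            ring = {
                "ND1": cb + np.array([0.6, 0.9, 0.0]),
                "NE2": cb + np.array([-0.6, 0.9, 0.0]),
            }
            for an, pos in ring.items():
                residue_atoms.append(
                    Atom(serial=next(serial), name=an, element="N", xyz=pos)
                )
            for hname in spec.his_protons.get(i, ()):
                base = ring["ND1"] if hname == "HD1" else ring["NE2"]
                residue_atoms.append(
                    Atom(
                        serial=next(serial),
                        name=hname,
                        element="H",
                        xyz=base + np.array([0.0, 1.0, 0.0]),
                    )
                )
        target.append(
            Residue(
                chain_id="A",
                res_seq=i + 1,
                res_name=name,
                atoms=residue_atoms,
                role="target",
            )
        )

    # disulfide partners: SG of the second member moved next to the first
    for i, j in spec.disulfide_pairs:
        for idx in (i, j):
            if target[idx].res_name not in ("CYS", "CYX"):
                raise GenerationError(
                    f"disulfide pair member {idx} is not CYS"
                )
        sg_i = target[i].atom("SG")
        sg_j = target[j].atom("SG")
        assert sg_i is not None and sg_j is not None
        sg_j.xyz = sg_i.xyz + np.array([0.0, 0.7, 1.93])  # |.| ~ 2.05

    # ligand probes realising the planted closest-heavy distances
    ligand_atoms: list[Atom] = []
    planted = sorted(spec.planted_interface.items())
    for k, (idx, dist) in enumerate(planted, start=1):
        anchor = _closest_plant_anchor(target[idx])
        ligand_atoms.append(
            Atom(
                serial=next(serial),
                name=f"C{k}",
                element="C",
                xyz=anchor + np.array([0.0, dist, 0.0]),
            )
        )
    k = len(ligand_atoms)
    base = (
        ligand_atoms[0].xyz
        if ligand_atoms
        else np.array([0.0, spec.ligand_offset, 0.0])
    )
    while k < spec.ligand_atom_count:
        k += 1
        ligand_atoms.append(
            Atom(
                serial=next(serial),
                name=f"C{k}",
                element="C",
                xyz=base + np.array([0.0, 2.0 + 1.5 * (k - len(planted)), 0.0]),
            )
        )
    ligand = [
        Residue(
            chain_id="L",
            res_seq=1,
            res_name="LIG",
            atoms=ligand_atoms,
            role="ligand",
        )
    ]

    # waters by sphere intersection around the anchor pair
    waters: list[Residue] = []
    if spec.water_plan:
        anchor_idx = planted[0][0]
        t_anchor = _closest_plant_anchor(target[anchor_idx])
        l_anchor = ligand_atoms[0].xyz
        axis = l_anchor - t_anchor
        dist_tl = float(np.linalg.norm(axis))
        u = axis / dist_tl
        e1 = np.array([1.0, 0.0, 0.0])
        e2 = np.cross(u, e1)
        e2 /= np.linalg.norm(e2)
        e1 = np.cross(e2, u)
        for w, (d_t, d_l) in enumerate(spec.water_plan):
            if not abs(d_t - d_l) <= dist_tl <= d_t + d_l:
                raise GenerationError(
                    f"water plan ({d_t}, {d_l}) infeasible for anchor "
                    f"separation {dist_tl:.3f}"
                )
            a = (d_t**2 - d_l**2 + dist_tl**2) / (2 * dist_tl)
            rho = math.sqrt(max(d_t**2 - a**2, 0.0))
            theta = math.radians(90.0 + 18.0 * w)
            o = (
                t_anchor
                + a * u
                + rho * (math.cos(theta) * e1 + math.sin(theta) * e2)
            )
            atoms = [
                Atom(serial=next(serial), name="O", element="O", xyz=o),
                Atom(
                    serial=next(serial),
                    name="H1",
                    element="H",
                    xyz=o + np.array([0.9572, 0.0, 0.0]),
                ),
                Atom(
                    serial=next(serial),
                    name="H2",
                    element="H",
                    xyz=o + np.array([-0.24, 0.9266, 0.0]),
                ),
            ]
            waters.append(
                Residue(
                    chain_id="W",
                    res_seq=w + 1,
                    res_name=spec.water_res_name,
                    atoms=atoms,
                    role="water",
                )
            )

    structure = ComplexStructure(residues=target + ligand + waters)
    _validate_plan(structure, spec, target, ligand, waters)
    return structure


def _closest_plant_anchor(residue: Residue) -> np.ndarray:
    atom = residue.atom("CB") or residue.atom("CA")
    if atom is None:
        raise GenerationError(f"residue {residue.label} lacks CB/CA anchor")
    return atom.xyz


def _validate_plan(
    structure: ComplexStructure,
    spec: ToyComplexSpec,
    target: list[Residue],
    ligand: list[Residue],
    waters: list[Residue],
) -> None:
    for idx, planned in spec.planted_interface.items():
        measured = closest_heavy_distance(target[idx], ligand)
        if abs(measured - planned) > _PLACEMENT_TOL:
            raise GenerationError(
                f"planted residue {idx}: measured d_cls {measured:.4f} "
                f"!= planned {planned:.4f}"
            )
    t_coords = np.vstack([r.heavy_coords() for r in target])
    l_coords = np.vstack([r.heavy_coords() for r in ligand])
    for water, (d_t, d_l) in zip(waters, spec.water_plan):
        o = water.atom("O")
        assert o is not None
        md_t = float(np.min(np.linalg.norm(t_coords - o.xyz, axis=1)))
        md_l = float(np.min(np.linalg.norm(l_coords - o.xyz, axis=1)))
        if abs(md_t - d_t) > _PLACEMENT_TOL or abs(md_l - d_l) > _PLACEMENT_TOL:
            raise GenerationError(
                f"water {water.res_seq}: measured ({md_t:.4f}, {md_l:.4f}) "
                f"!= planned ({d_t:.4f}, {d_l:.4f})"
            )
    for i, j in spec.disulfide_pairs:
        sg_i = target[i].atom("SG")
        sg_j = target[j].atom("SG")
        assert sg_i is not None and sg_j is not None
        d = float(np.linalg.norm(sg_i.xyz - sg_j.xyz))
        if not d < 2.3:
            raise GenerationError(f"disulfide pair ({i},{j}) SG-SG {d:.3f}")


# ---------------------------------------------------------------------------
# reference benchmark tables
# ---------------------------------------------------------------------------

#: residual column -> regression parameter count (2 = with intercept)
MODEL_COLUMNS: dict[str, int] = {
    "vacuum_dry": 2,
    "vacuum_shell1": 2,
    "vacuum_shell2": 2,
    "vacuum_shell3": 2,
    "cosmo_dry": 2,
    "cosmo_shell1": 2,
    "cosmo_shell2": 2,
    "cosmo_shell3": 2,
    "cosmo_shell3_nointercept": 1,
}

_SHA256 = {
    "reference_systems.tsv": None,  # filled below at import
    "reference_residuals.tsv": None,
    "reference_statistics.tsv": None,
}

# Frozen digests of the shipped benchmark tables; guards against silent
# edits of the transcription.
_EXPECTED_SHA256 = {
    "reference_systems.tsv": "513262e29a9d17b7a2a0628b0ab184e129ae8fef857b9ea6a390f03c664ce97e",
    "reference_residuals.tsv": "fc27f2aabc9abb4023e2747329421b0e8f988dce1176e4ccc746e05447e7fe18",
    "reference_statistics.tsv": "acb8ff275644048149a74d69d68d82f955d5590288255fe9779678dae48de7bb",
}


@dataclass
class ReferenceTables:
    """The 15-system benchmark: systems, residual columns, statistics."""

    systems: pd.DataFrame  # indexed by system_id
    residuals: pd.DataFrame  # indexed by system_id; one column per model
    statistics: pd.DataFrame  # indexed by model

    @property
    def dhb_exp(self) -> pd.Series:
        return self.systems["dHb_exp_kcal_mol"]


def _read_resource(name: str) -> str:
    return (
        resources.files("interfrag.data").joinpath(name).read_text("utf-8")
    )


def load_reference_tables(verify_checksum: bool = True) -> ReferenceTables:
    """Load the shipped benchmark tables, verifying integrity.

    Checks the SHA-256 of each file against frozen digests and asserts
    the hydration-shell bookkeeping (Shell1 + Shell2 = Shell3 per
    system) on load.
    """
    frames = {}
    for name in _EXPECTED_SHA256:
        text = _read_resource(name)
        if verify_checksum:
            digest = hashlib.sha256(text.encode("utf-8")).hexdigest()
            if digest != _EXPECTED_SHA256[name]:
                raise ValueError(
                    f"checksum mismatch for {name}: {digest}"
                )
        frames[name] = pd.read_csv(io.StringIO(text), sep="\t", comment="#")

    systems = frames["reference_systems.tsv"].set_index("system_id")
    residuals = frames["reference_residuals.tsv"].set_index("system_id")
    statistics = frames["reference_statistics.tsv"].set_index("model")

    if len(systems) != 15:
        raise ValueError(f"expected 15 systems, found {len(systems)}")
    bad = systems[
        systems["shell1"] + systems["shell2"] != systems["shell3"]
    ]
    if len(bad):
        raise ValueError(
            f"shell bookkeeping violated for: {list(bad.index)}"
        )
    if set(residuals.columns) != set(MODEL_COLUMNS):
        raise ValueError("residual columns do not match the model set")
    if list(residuals.index) != list(systems.index):
        raise ValueError("system order differs between tables")
    return ReferenceTables(
        systems=systems, residuals=residuals, statistics=statistics
    )
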