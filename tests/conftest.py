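"""Shared builders and brute-force oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from interfrag.energetics import AtomParameters, ParameterTable, pair_energy
from interfrag.fixtures import ToyComplexSpec, make_toy_complex
from interfrag.structure_io import Atom, ComplexStructure, Residue

_serial = itertools.count(1)


def mk_atom(name: str, xyz, element: str | None = None) -> Atom:
    if element is None:
        element = name.lstrip("0123456789")[0]
    return Atom(serial=next(_serial), name=name, element=element, xyz=np.asarray(xyz, float))


def mk_res(chain: str, seq: int, name: str, atoms, role: str = "target") -> Residue:
    """atoms: list of (atom_name, xyz) or (atom_name, xyz, element)."""
    built = []
    for entry in atoms:
        if len(entry) == 2:
            built.append(mk_atom(entry[0], entry[1]))
        else:
            built.append(mk_atom(entry[0], entry[1], entry[2]))
    return Residue(chain_id=chain, res_seq=seq, res_name=name, atoms=built, role=role)


@pytest.fixture
def toy_spec() -> ToyComplexSpec:
    return ToyComplexSpec(
        n_target_residues=8,
        ligand_atom_count=3,
        planted_interface={1: 3.0, 4: 3.3},
        water_plan=[(3.2, 3.4), (4.2, 4.6)],
        seed=7,
    )


@pytest.fixture
def toy_structure(toy_spec) -> ComplexStructure:
    return make_toy_complex(toy_spec)


def random_complex(rng: np.random.Generator, n_target=5, n_lig_atoms=6, n_waters=10):
    """Random atom-cloud complex plus a matching random parameter table."""
    target = []
    entries = {}
    for i in range(n_target):
        atoms = []
        for k in range(4):
            # first atom always heavy so every residue has heavy atoms
            el = rng.choice(["C", "N", "O", "H"]) if k else "C"
            name = f"{el}{k+1}"
            atoms.append((name, rng.uniform(0, 10, size=3), el))
            entries[(f"R{i+1}", name)] = AtomParameters(
                q=float(rng.uniform(-0.8, 0.8)),
                r_star=float(rng.uniform(0.6, 2.0)),
                eps=float(rng.uniform(0.0, 0.3)),
            )
        target.append(mk_res("A", i + 1, f"R{i+1}", atoms))
    lig_atoms = []
    for k in range(n_lig_atoms):
        el = rng.choice(["C", "N", "O"])
        name = f"{el}{k+1}L"
        lig_atoms.append((name, rng.uniform(12, 20, size=3), el))
        entries[("LIG", name)] = AtomParameters(
            q=float(rng.uniform(-0.8, 0.8)),
            r_star=float(rng.uniform(0.6, 2.0)),
            eps=float(rng.uniform(0.0, 0.3)),
        )
    ligand = [mk_res("L", 1, "LIG", lig_atoms, role="ligand")]
    waters = [
        mk_res("W", w + 1, "WAT", [("O", rng.uniform(0, 20, size=3), "O")], role="water")
        for w in range(n_waters)
    ]
    return target, ligand, waters, ParameterTable(entries)


def brute_closest_heavy(res_a, others) -> float:
    best = np.inf
    for a in res_a.atoms:
        if not a.is_heavy:
            continue
        for other in others:
            for b in other.atoms:
                if not b.is_heavy:
                    continue
                best = min(best, float(np.linalg.norm(a.xyz - b.xyz)))
    return best


def brute_interfacial(waters, target, ligand, d_max):
    kept = []
    for w in waters:
        o = next((a for a in w.atoms if a.element == "O"), None)
        if o is None:
            continue
        d_t = min(
            float(np.linalg.norm(o.xyz - a.xyz))
            for r in target
            for a in r.atoms
            if a.is_heavy
        )
        d_l = min(
            float(np.linalg.norm(o.xyz - a.xyz))
            for r in ligand
            for a in r.atoms
            if a.is_heavy
        )
        if d_t <= d_max and d_l <= d_max:
            kept.append((w.key, d_t, d_l))
    return kept


def brute_einter(target_residue, ligand, params) -> float:
    total = 0.0
    for a in target_residue.atoms:
        pa = params.get(target_residue.res_name, a.name)
        for res in ligand:
            for b in res.atoms:
                pb = params.get(res.res_name, b.name)
                r = float(np.linalg.norm(a.xyz - b.xyz))
                total += pair_energy(pa, pb, r)
    return total
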