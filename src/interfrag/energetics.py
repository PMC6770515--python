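"""Per-residue target-ligand interaction energies (Lennard-Jones + Coulomb).

The screening energy for each extracted target residue is the pairwise
sum over its atoms i and all ligand atoms j::

    E_inter = sum_ij [ A_ij / r_ij^12 - B_ij / r_ij^6
                       + k_C * q_i * q_j / (eps_r * r_ij) ]

with Amber-style combining rules A_ij = eps_ij * R_ij^12,
B_ij = 2 * eps_ij * R_ij^6, R_ij = R_i + R_j (sum of vdW radii) and
eps_ij = sqrt(eps_i * eps_j) (geometric-mean well depth).  The Coulomb
constant k_C = 332.0636 kcal A mol^-1 e^-2 puts charges in elementary
units and distances in Angstrom.  No distance cutoff is applied: the
extracted interface is small enough for the full double sum.  Large
positive values flag target residues colliding with the ligand.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from interfrag.structure_io import Residue

__all__ = [
    "COULOMB_CONSTANT",
    "AtomParameters",
    "ParameterTable",
    "EinterRow",
    "EinterReport",
    "builtin_parameter_table",
    "combine_pair",
    "pair_energy",
    "residue_einter",
    "einter_report",
    "flag_clashes",
]

#: kcal * Angstrom / (mol * e^2); 1/(4 pi eps_0) in these units.
COULOMB_CONSTANT = 332.0636

DEFAULT_CLASH_THRESHOLD = 10.0  # kcal/mol

_WATER_ALIASES = {"HOH": "WAT", "SOL": "WAT", "H2O": "WAT"}


class AtomParameters(NamedTuple):
    """Non-bonded parameters of one atom type.

    q: partial charge (e); r_star: vdW radius R_i (A);
    eps: well depth (kcal/mol).
    """

    q: float
    r_star: float
    eps: float

    def validate(self) -> "AtomParameters":
        if self.eps < 0:
            raise ValueError("well depth eps must be non-negative")
        if self.r_star < 0:
            raise ValueError("vdW radius must be non-negative")
        return self


ZERO_PARAMETERS = AtomParameters(0.0, 0.0, 0.0)


class ParameterTable:
    """(res_name, atom_name) -> :class:`AtomParameters` lookup.

    Built from a TSV with header ``res_name  atom_name  q  r_star  eps``.
    Water residue-name dialects (HOH/SOL/H2O) alias to WAT.  The
    ``missing_policy`` decides what a failed lookup does: ``strict``
    raises, ``zero`` substitutes null parameters with a warning.
    """

    def __init__(self, entries: dict[tuple[str, str], AtomParameters]):
        self._entries = {
            (r.upper(), a.upper()): p.validate() for (r, a), p in entries.items()
        }

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, key: tuple[str, str]) -> bool:
        res, atom = key
        res = _WATER_ALIASES.get(res.upper(), res.upper())
        return (res, atom.upper()) in self._entries or (
            "ALL",
            atom.upper(),
        ) in self._entries

    def get(
        self, res_name: str, atom_name: str, missing_policy: str = "strict"
    ) -> AtomParameters:
        res = _WATER_ALIASES.get(res_name.upper(), res_name.upper())
        key = (res, atom_name.upper())
        if key in self._entries:
            return self._entries[key]
        # generic backbone entry shared by all standard residues
        fallback = ("ALL", atom_name.upper())
        if fallback in self._entries and res != "WAT":
            return self._entries[fallback]
        if missing_policy == "zero":
            warnings.warn(
                f"no parameters for ({res_name}, {atom_name}); "
                "using zero charge and vdW",
                stacklevel=2,
            )
            return ZERO_PARAMETERS
        raise KeyError(
            f"no non-bonded parameters for residue {res_name!r} "
            f"atom {atom_name!r}"
        )

    @classmethod
    def from_tsv(cls, text: str) -> "ParameterTable":
        df = pd.read_csv(io.StringIO(text), sep="\t", comment="#")
        required = {"res_name", "atom_name", "q", "r_star", "eps"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"parameter table needs columns {sorted(required)}, "
                f"got {list(df.columns)}"
            )
        entries = {
            (str(row.res_name), str(row.atom_name)): AtomParameters(
                float(row.q), float(row.r_star), float(row.eps)
            )
            for row in df.itertuples()
        }
        return cls(entries)

    @classmethod
    def from_file(cls, path) -> "ParameterTable":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_tsv(fh.read())


def builtin_parameter_table() -> ParameterTable:
    """Representative Amber-style parameters for peptide and water atoms.

    Covers backbone atoms of the 20 standard residues, the side chains
    most relevant to charge and disulfide logic, the ACE/NME caps and
    TIP3P-like water.  Intended for interface screening, not production
    force-field work; supply a full table for anything else.
    """
    text = (
        resources.files("interfrag.data")
        .joinpath("nonbonded_minimal.tsv")
        .read_text(encoding="utf-8")
    )
    return ParameterTable.from_tsv(text)


def combine_pair(
    p_i: AtomParameters, p_j: AtomParameters
) -> tuple[float, float, float, float]:
    """Amber combining rules: returns (A_ij, B_ij, eps_ij, R_ij)."""
    r_ij = p_i.r_star + p_j.r_star
    eps_ij = float(np.sqrt(p_i.eps * p_j.eps))
    a_ij = eps_ij * r_ij**12
    b_ij = 2.0 * eps_ij * r_ij**6
    return a_ij, b_ij, eps_ij, r_ij


def pair_energy(
    p_i: AtomParameters,
    p_j: AtomParameters,
    r_ij: float,
    relative_permittivity: float = 1.0,
) -> float:
    """LJ + Coulomb energy (kcal/mol) of one atom pair at distance r_ij."""
    if r_ij <= 0:
        raise ValueError("pair distance must be positive")
    a, b, _, _ = combine_pair(p_i, p_j)
    lj = a / r_ij**12 - b / r_ij**6
    coulomb = COULOMB_CONSTANT * p_i.q * p_j.q / (
        relative_permittivity * r_ij
    )
    return lj + coulomb


@dataclass
class EinterRow:
    """One target residue's interaction energy with the whole ligand."""

    residue_key: tuple[str, int, str]
    residue_label: str
    e_lj: float
    e_coulomb: float
    clash: bool = False

    @property
    def e_inter(self) -> float:
        return self.e_lj + self.e_coulomb


@dataclass
class EinterReport:
    """Per-residue energies plus column totals."""

    rows: list[EinterRow] = field(default_factory=list)
    clash_threshold: float = DEFAULT_CLASH_THRESHOLD

    @property
    def total_lj(self) -> float:
        return sum(r.e_lj for r in self.rows)

    @property
    def total_coulomb(self) -> float:
        return sum(r.e_coulomb for r in self.rows)

    @property
    def total(self) -> float:
        return self.total_lj + self.total_coulomb

    def to_dataframe(self) -> pd.DataFrame:
        records = [
            {
                "residue": r.residue_label,
                "E_LJ": r.e_lj,
                "E_Coulomb": r.e_coulomb,
                "E_inter": r.e_inter,
                "clash": r.clash,
            }
            for r in self.rows
        ]
        records.append(
            {
                "residue": "TOTAL",
                "E_LJ": self.total_lj,
                "E_Coulomb": self.total_coulomb,
                "E_inter": self.total,
                "clash": any(r.clash for r in self.rows),
            }
        )
        return pd.DataFrame.from_records(records)


def _gather(
    residues: Sequence[Residue],
    params: ParameterTable,
    include_hydrogens: bool,
    missing_policy: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    coords, q, r_star, eps = [], [], [], []
    for res in residues:
        for atom in res.atoms:
            if not include_hydrogens and not atom.is_heavy:
                continue
            p = params.get(res.res_name, atom.name, missing_policy)
            coords.append(atom.xyz)
            q.append(p.q)
            r_star.append(p.r_star)
            eps.append(p.eps)
    return (
        np.array(coords, dtype=float).reshape(-1, 3),
        np.array(q, dtype=float),
        np.array(r_star, dtype=float),
        np.array(eps, dtype=float),
    )


def residue_einter(
    target_residue: Residue,
    ligand: Sequence[Residue],
    params: ParameterTable,
    include_hydrogens: bool = True,
    missing_policy: str = "strict",
    relative_permittivity: float = 1.0,
) -> EinterRow:
    """Sum pair energies over all (target-residue atom, ligand atom) pairs."""
    tc, tq, tr, te = _gather(
        [target_residue], params, include_hydrogens, missing_policy
    )
    lc, lq, lr, le = _gather(ligand, params, include_hydrogens, missing_policy)
    if tc.shape[0] == 0 or lc.shape[0] == 0:
        return EinterRow(
            residue_key=target_residue.key,
            residue_label=target_residue.label,
            e_lj=0.0,
            e_coulomb=0.0,
        )
    r = cdist(tc, lc)
    if np.any(r == 0):
        raise ValueError(
            f"coincident atoms between {target_residue.label} and ligand"
        )
    eps_ij = np.sqrt(np.outer(te, le))
    r_ij = np.add.outer(tr, lr)
    a = eps_ij * r_ij**12
    b = 2.0 * eps_ij * r_ij**6
    e_lj = float(np.sum(a / r**12 - b / r**6))
    e_coulomb = float(
        COULOMB_CONSTANT
        * np.sum(np.outer(tq, lq) / r)
        / relative_permittivity
    )
    return EinterRow(
        residue_key=target_residue.key,
        residue_label=target_residue.label,
        e_lj=e_lj,
        e_coulomb=e_coulomb,
    )


def einter_report(
    target_residues: Sequence[Residue],
    ligand: Sequence[Residue],
    params: ParameterTable,
    include_hydrogens: bool = True,
    missing_policy: str = "strict",
    relative_permittivity: float = 1.0,
    clash_threshold: float = DEFAULT_CLASH_THRESHOLD,
) -> EinterReport:
    """Per-residue report over the extracted target residues (waters are
    never part of the target-ligand double sum)."""
    report = EinterReport(clash_threshold=clash_threshold)
    for res in target_residues:
        report.rows.append(
            residue_einter(
                res,
                ligand,
                params,
                include_hydrogens=include_hydrogens,
                missing_policy=missing_policy,
                relative_permittivity=relative_permittivity,
            )
        )
    flag_clashes(report, clash_threshold)
    return report


def flag_clashes(
    report: EinterReport, threshold: float = DEFAULT_CLASH_THRESHOLD
) -> list[EinterRow]:
    """Mark rows with E_inter above ``threshold`` (kcal/mol) and return
    them; large positive energies indicate steric collisions."""
    if not np.isfinite(threshold) and threshold < 0:
        raise ValueError("threshold must not be -inf")
    flagged = []
    for row in report.rows:
        row.clash = row.e_inter > threshold
        if row.clash:
            flagged.append(row)
    report.clash_threshold = threshold
    return flagged
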