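"""PDB coordinate I/O and MOPAC-style semi-empirical QM input writing.

The structure model is deliberately small: a complex is an ordered list of
residues (grouped by chain, sorted by residue id), each residue an ordered
list of atoms.  Residues are tagged with a role -- ``target``, ``ligand``
or ``water`` -- because every downstream step (fragment selection, shell
classification, interaction energies) is phrased in terms of that
three-way split.  Water detection is purely by residue name against a
configurable set; the default covers the common MD and crystallographic
dialects (WAT, SOL, H2O, HOH).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "DEFAULT_WATER_NAMES",
    "Atom",
    "Residue",
    "ComplexStructure",
    "QmInputSpec",
    "PdbParseError",
    "PdbIntegrityError",
    "parse_pdb",
    "write_pdb",
    "write_qm_input",
]

#: Residue names recognised as water molecules.
DEFAULT_WATER_NAMES = frozenset({"WAT", "SOL", "H2O", "HOH"})

_CHARGE_REMARK_RE = re.compile(r"TOTAL CHARGE:\s*([+-]?\d+)")


class PdbParseError(ValueError):
    """A coordinate record could not be parsed (message names the line)."""


class PdbIntegrityError(ValueError):
    """The file parses but violates structural uniqueness constraints."""


@dataclass
class Atom:
    """A single atom with Cartesian coordinates in Angstrom."""

    serial: int
    name: str
    element: str
    xyz: np.ndarray
    alt_loc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,):
            raise ValueError(f"atom {self.name}: xyz must be a 3-vector")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")
        self.element = self.element.upper()

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    def moved(self, xyz: np.ndarray) -> "Atom":
        return replace(self, xyz=np.asarray(xyz, dtype=float))


@dataclass
class Residue:
    """One residue: a named, ordered group of atoms on a chain."""

    chain_id: str
    res_seq: int
    res_name: str
    atoms: list[Atom]
    icode: str = ""
    role: str = "target"  # target | ligand | water

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.key}: no atoms")
        if self.role not in ("target", "ligand", "water"):
            raise ValueError(f"residue {self.key}: bad role {self.role!r}")

    @property
    def key(self) -> tuple[str, int, str]:
        """Unique residue identifier within a structure."""
        return (self.chain_id, self.res_seq, self.icode)

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.res_name}{self.res_seq}{self.icode}"

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_atom(self, name: str) -> bool:
        return self.atom(name) is not None

    def heavy_coords(self) -> np.ndarray:
        coords = [a.xyz for a in self.atoms if a.is_heavy]
        return np.array(coords, dtype=float).reshape(-1, 3)

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float).reshape(-1, 3)


@dataclass
class ComplexStructure:
    """A target-ligand(-water) complex as an ordered residue list.

    Residues are grouped by chain (chains in first-encounter order) and
    sorted by ``(res_seq, icode)`` within each chain.  ``total_charge``
    is the integer formal charge of the whole complex once assigned; it
    travels through PDB round trips via a REMARK line.
    """

    residues: list[Residue] = field(default_factory=list)
    remarks: list[str] = field(default_factory=list)
    total_charge: Optional[int] = None

    def chains(self) -> dict[str, list[Residue]]:
        out: dict[str, list[Residue]] = {}
        for res in self.residues:
            out.setdefault(res.chain_id, []).append(res)
        return out

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for res in self.residues:
            for atom in res.atoms:
                yield res, atom

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def by_role(self, role: str) -> list[Residue]:
        return [r for r in self.residues if r.role == role]


def _infer_element(atom_name: str) -> str:
    """Element from a PDB atom name (leading digits stripped, first letter).

    Sufficient for protein/water/organic-ligand atoms (CA -> C, SG -> S,
    1HB2 -> H); two-letter metals are not resolved and should carry an
    explicit element column.
    """
    stripped = atom_name.lstrip("0123456789")
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def parse_pdb(
    text: str,
    water_names: Iterable[str] = DEFAULT_WATER_NAMES,
) -> ComplexStructure:
    """Parse ATOM/HETATM records into a :class:`ComplexStructure`.

    ATOM and HETATM are treated identically.  Waters are recognised by
    residue name membership in ``water_names``.  Alternate locations are
    resolved by keeping the highest-occupancy copy of each atom (ties go
    to the first encountered).  REMARK lines are preserved, and a
    ``TOTAL CHARGE: <int>`` remark restores ``total_charge``.

    Raises
    ------
    PdbParseError
        Malformed coordinate field; the message names the line number.
    PdbIntegrityError
        Duplicate (chain, res_seq, icode, atom name, alt_loc).
    """
    water_set = {w.upper() for w in water_names}
    remarks: list[str] = []
    total_charge: Optional[int] = None
    # residue key -> (res_name, {atom name -> Atom})
    order: list[tuple[str, int, str]] = []
    res_names: dict[tuple[str, int, str], str] = {}
    res_atoms: dict[tuple[str, int, str], dict[str, Atom]] = {}
    seen: set[tuple[str, int, str, str, str]] = set()
    n_coord = 0

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "REMARK":
            remark = line[6:].strip()
            remarks.append(remark)
            m = _CHARGE_REMARK_RE.search(remark)
            if m:
                total_charge = int(m.group(1))
            continue
        if rec not in ("ATOM", "HETATM"):
            continue
        n_coord += 1
        try:
            serial = int(line[6:11])
            name = line[12:16].strip()
            alt_loc = line[16].strip()
            res_name = line[17:21].strip().upper()
            chain_id = line[21].strip()
            res_seq = int(line[22:26])
            icode = line[26].strip()
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            occ_field = line[54:60].strip()
            occupancy = float(occ_field) if occ_field else 1.0
            element = line[76:78].strip() if len(line) >= 77 else ""
        except (ValueError, IndexError) as exc:
            raise PdbParseError(
                f"line {lineno}: malformed coordinate record: {exc}"
            ) from None
        if not name:
            raise PdbParseError(f"line {lineno}: empty atom name")
        if not element:
            try:
                element = _infer_element(name)
            except ValueError as exc:
                raise PdbParseError(f"line {lineno}: {exc}") from None

        key = (chain_id, res_seq, icode)
        dup_key = (chain_id, res_seq, icode, name, alt_loc)
        if dup_key in seen:
            raise PdbIntegrityError(
                f"line {lineno}: duplicate atom {name!r} (alt_loc {alt_loc!r}) "
                f"in residue {chain_id}/{res_name}{res_seq}{icode}"
            )
        seen.add(dup_key)

        atom = Atom(
            serial=serial,
            name=name,
            element=element,
            xyz=np.array([x, y, z]),
            alt_loc=alt_loc,
            occupancy=occupancy,
        )
        if key not in res_atoms:
            order.append(key)
            res_names[key] = res_name
            res_atoms[key] = {}
        existing = res_atoms[key].get(name)
        if existing is None:
            res_atoms[key][name] = atom
        elif existing.alt_loc == atom.alt_loc:
            # identical alt_loc already rejected above; unreachable guard
            raise PdbIntegrityError(f"line {lineno}: duplicate atom {name!r}")
        elif atom.occupancy > existing.occupancy:
            res_atoms[key][name] = atom

    if n_coord == 0:
        raise PdbParseError("no ATOM/HETATM records found")

    # chains in first-encounter order; residues sorted by (res_seq, icode)
    chain_order: list[str] = []
    per_chain: dict[str, list[tuple[str, int, str]]] = {}
    for key in order:
        if key[0] not in per_chain:
            chain_order.append(key[0])
            per_chain[key[0]] = []
        per_chain[key[0]].append(key)

    residues: list[Residue] = []
    for chain_id in chain_order:
        for key in sorted(per_chain[chain_id], key=lambda k: (k[1], k[2])):
            res_name = res_names[key]
            role = "water" if res_name in water_set else "target"
            residues.append(
                Residue(
                    chain_id=key[0],
                    res_seq=key[1],
                    icode=key[2],
                    res_name=res_name,
                    atoms=list(res_atoms[key].values()),
                    role=role,
                )
            )
    return ComplexStructure(
        residues=residues, remarks=remarks, total_charge=total_charge
    )


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 and not name[:1].isdigit():
        return f" {name:<3}"
    return f"{name:<4}"


def write_pdb(
    structure: ComplexStructure, include_charge_remark: bool = False
) -> str:
    """Serialise a structure to PDB text (coordinates at 3 decimals).

    Records are written chain by chain in residue order with TER after
    each chain and END at the end.  With ``include_charge_remark`` the
    stored integer formal charge is written as a ``REMARK 250 TOTAL
    CHARGE: <int>`` line, which :func:`parse_pdb` reads back.
    """
    if structure.n_atoms == 0:
        raise ValueError("refusing to write a structure with no atoms")
    lines: list[str] = []
    for remark in structure.remarks:
        if _CHARGE_REMARK_RE.search(remark):
            continue  # rewritten below from total_charge
        lines.append(f"REMARK {remark}")
    if include_charge_remark:
        if structure.total_charge is None:
            raise ValueError("include_charge_remark requires total_charge")
        lines.append(f"REMARK 250 TOTAL CHARGE: {structure.total_charge:d}")

    serial = 0
    for chain_id, residues in structure.chains().items():
        for res in residues:
            record = "HETATM" if res.role in ("ligand", "water") else "ATOM"
            for atom in res.atoms:
                serial += 1
                x, y, z = atom.xyz
                lines.append(
                    f"{record:<6}{serial % 100000:>5} "
                    f"{_format_atom_name(atom.name, atom.element)}"
                    f"{atom.alt_loc or ' '}"
                    f"{res.res_name:<4}"
                    f"{chain_id:1}{res.res_seq:>4}{res.icode or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{atom.occupancy:6.2f}{0.0:6.2f}          "
                    f"{atom.element:>2}"
                )
        serial += 1
        lines.append(f"TER   {serial % 100000:>5}")
    lines.append("END")
    return "\n".join(lines) + "\n"


_FREEZE_MODES = ("none", "calpha", "heavy", "custom")


@dataclass
class QmInputSpec:
    """Settings for a MOPAC-style semi-empirical input file.

    Defaults follow the conventions used for PM7/Mozyme heats of
    formation on extracted interfaces: eigenvector-following geometry
    optimisation, MM peptide-bond correction (MMOK), PREC and GEO-OK to
    keep long runs alive, exit at gradient norm 1.0, and COSMO implicit
    water via ``eps`` = 78.3 when a solvent model is wanted (``eps``
    unset means vacuum).
    """

    keywords: Sequence[str] = ("PM7", "MOZYME", "EF", "PREC", "GEO-OK", "MMOK")
    total_charge: Optional[int] = None
    eps: Optional[float] = None
    gnorm: Optional[float] = 1.0
    freeze_mode: str = "none"
    frozen_atom_selector: Optional[Callable[[Atom, Residue], bool]] = None
    title: str = "interface complex"

    def __post_init__(self) -> None:
        if self.eps is not None and not self.eps > 1.0:
            raise ValueError("eps must exceed 1 (unset means vacuum)")
        if self.freeze_mode not in _FREEZE_MODES:
            raise ValueError(
                f"unknown freeze_mode {self.freeze_mode!r}; "
                f"expected one of {_FREEZE_MODES}"
            )
        if self.freeze_mode == "custom" and self.frozen_atom_selector is None:
            raise ValueError("freeze_mode='custom' needs frozen_atom_selector")

    def is_frozen(self, atom: Atom, residue: Residue) -> bool:
        if self.freeze_mode == "none":
            return False
        if self.freeze_mode == "calpha":
            return atom.name == "CA"
        if self.freeze_mode == "heavy":
            return atom.is_heavy
        assert self.frozen_atom_selector is not None
        return bool(self.frozen_atom_selector(atom, residue))


def write_qm_input(structure: ComplexStructure, spec: QmInputSpec) -> str:
    """Write a MOPAC-style input: keyword line, title, blank, atom lines.

    Atom lines carry the element, coordinates at 5 decimals and a 0/1
    optimisation flag per coordinate (0 = frozen).  The charge keyword is
    taken from the spec, falling back to the structure's stored charge.
    """
    charge = spec.total_charge
    if charge is None:
        charge = structure.total_charge
    if charge is None:
        raise ValueError("total charge unset on both structure and spec")

    tokens: list[str] = []
    for kw in spec.keywords:
        if kw not in tokens:
            tokens.append(kw)
    tokens.append(f"CHARGE={charge:d}")
    if spec.eps is not None:
        tokens.append(f"EPS={spec.eps:g}")
    if spec.gnorm is not None:
        tokens.append(f"GNORM={spec.gnorm:g}")

    lines = [" ".join(tokens), spec.title, ""]
    for res, atom in structure.iter_atoms():
        flag = 0 if spec.is_frozen(atom, res) else 1
        x, y, z = atom.xyz
        lines.append(
            f"{atom.element:<2} {x:12.5f} {flag} {y:12.5f} {flag} "
            f"{z:12.5f} {flag}"
        )
    return "\n".join(lines) + "\n"
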