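"""Interface extraction: fragment selection, growth, capping and charges.

A target residue enters the interface when its closest heavy atom lies
within ``d_TL`` of any ligand heavy atom.  Selected residues are grouped
into maximal contiguous runs per chain, optionally grown by ``n``
sequential neighbours on each side, single-residue gaps between runs are
bridged, and cysteines disulfide-bonded to selected cysteines are pulled
in.  Each run is then sealed into a chemically complete peptide: an
acetyl (ACE) cap replaces the preceding residue at a cut N-terminus, an
N-methylamide (NME) cap replaces the following residue at a cut
C-terminus, while true chain termini keep a protonated amino group or a
carboxylate anion.  Formal charges are assigned per residue at pH 7 with
explicit-proton logic for His/Cys/Asp/Glu.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from interfrag.structure_io import (
    DEFAULT_WATER_NAMES,
    Atom,
    ComplexStructure,
    Residue,
)

__all__ = [
    "STANDARD_AMINO_ACIDS",
    "SIDECHAIN_CHARGES_PH7",
    "FragmenterConfig",
    "Fragment",
    "InterfaceComplex",
    "partition_complex",
    "closest_heavy_distance",
    "select_interface_residues",
    "grow_fragments",
    "merge_single_gaps",
    "include_disulfide_partners",
    "find_disulfide_pairs",
    "cap_fragment",
    "residue_charge",
    "extract_interface",
    "methyl_hydrogens",
]

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL".split()
)

#: Side-chain formal charges at pH 7 for residues with fixed protonation.
#: CYS and HIS are handled by explicit-proton rules, not this table.
SIDECHAIN_CHARGES_PH7: dict[str, int] = {
    **{name: 0 for name in STANDARD_AMINO_ACIDS},
    "ASP": -1,
    "GLU": -1,
    "LYS": +1,
    "ARG": +1,
    # neutral capping groups
    "ACE": 0,
    "NME": 0,
    "NMA": 0,
}


@dataclass
class FragmenterConfig:
    """Tunable distances (Angstrom) and selectors of the extraction.

    d_tl: target-ligand closest-heavy-atom cutoff for residue selection.
    d_w: water-to-solute cutoff for retaining interfacial waters.
    n: number of sequential neighbours appended to each fragment end.
    d_max: maximal water-solute distance of the hydration editing step.
    d_min: minimal water-ligand distance below which a water clashes.
    ss_cutoff: SG-SG distance treated as a disulfide bridge.
    """

    d_tl: float = 3.5
    d_w: float = 5.0
    n: int = 0
    d_max: float = 5.0
    d_min: float = 1.75
    ss_cutoff: float = 2.3
    shell1_cutoff: float = 3.5
    ligand_chains: frozenset[str] = frozenset()
    water_names: frozenset[str] = DEFAULT_WATER_NAMES
    ligand_formal_charge: Optional[int] = None
    charge_table: Optional[Mapping[str, int]] = None
    clash_threshold: float = 10.0  # kcal/mol, E_inter flagging

    def __post_init__(self) -> None:
        for attr in ("d_tl", "d_w", "d_max", "d_min", "ss_cutoff"):
            if not getattr(self, attr) > 0:
                raise ValueError(f"{attr} must be positive")
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if not (self.d_min < self.d_w <= self.d_max):
            warnings.warn(
                "recommended ordering d_min < d_w <= d_max violated "
                f"(d_min={self.d_min}, d_w={self.d_w}, d_max={self.d_max})",
                stacklevel=2,
            )
        self.ligand_chains = frozenset(self.ligand_chains)
        self.water_names = frozenset(w.upper() for w in self.water_names)


@dataclass
class Fragment:
    """A contiguous capped target peptide.

    ``n_cap_atoms``/``c_cap_atoms`` hold the constructed cap atoms (the
    ACE/NME groups, or the hydrogens of a protonated free N-terminus;
    empty for an untouched carboxylate C-terminus).
    """

    chain_id: str
    residues: list[Residue]
    n_cap: str  # ACE | NH3_PLUS
    c_cap: str  # NME | COO_MINUS
    n_cap_atoms: list[Atom] = field(default_factory=list)
    c_cap_atoms: list[Atom] = field(default_factory=list)
    formal_charge: int = 0
    d_cls_per_residue: dict[tuple[str, int, str], float] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        seqs = [r.res_seq for r in self.residues]
        if seqs != list(range(seqs[0], seqs[0] + len(seqs))) and not all(
            s2 >= s1 for s1, s2 in zip(seqs, seqs[1:])
        ):
            raise ValueError("fragment residues must be contiguous and sorted")
        if self.n_cap not in ("ACE", "NH3_PLUS"):
            raise ValueError(f"bad n_cap {self.n_cap!r}")
        if self.c_cap not in ("NME", "COO_MINUS"):
            raise ValueError(f"bad c_cap {self.c_cap!r}")

    @property
    def first(self) -> Residue:
        return self.residues[0]

    @property
    def last(self) -> Residue:
        return self.residues[-1]

    def to_residues(self) -> list[Residue]:
        """Fragment as writable residues, caps materialised as ACE/NME."""
        out: list[Residue] = []
        if self.n_cap == "ACE":
            out.append(
                Residue(
                    chain_id=self.chain_id,
                    res_seq=self.first.res_seq - 1,
                    res_name="ACE",
                    atoms=list(self.n_cap_atoms),
                    role="target",
                )
            )
            out.extend(self.residues)
        else:
            # protonated amino group: hydrogens live on the first residue
            first = self.residues[0]
            out.append(
                Residue(
                    chain_id=first.chain_id,
                    res_seq=first.res_seq,
                    icode=first.icode,
                    res_name=first.res_name,
                    atoms=list(first.atoms) + list(self.n_cap_atoms),
                    role="target",
                )
            )
            out.extend(self.residues[1:])
        if self.c_cap == "NME":
            out.append(
                Residue(
                    chain_id=self.chain_id,
                    res_seq=self.last.res_seq + 1,
                    res_name="NME",
                    atoms=list(self.c_cap_atoms),
                    role="target",
                )
            )
        return out

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.to_residues())


@dataclass
class InterfaceComplex:
    """The extracted hydrated interface: fragments + ligand + waters."""

    fragments: list[Fragment]
    ligand: list[Residue]
    waters: list  # list[ShellAssignment]
    total_charge: int
    einter_report: Optional[object] = None  # EinterReport when computed

    def to_structure(self, with_waters: bool = True) -> ComplexStructure:
        residues: list[Residue] = []
        for frag in self.fragments:
            residues.extend(frag.to_residues())
        residues.extend(self.ligand)
        if with_waters:
            # Shell 1 first, then Shell 2 (stable within shells)
            ordered = sorted(
                self.waters, key=lambda sa: (sa.shell, sa.water.res_seq)
            )
            residues.extend(sa.water for sa in ordered)
        return ComplexStructure(residues=residues, total_charge=self.total_charge)

    def ligand_structure(self) -> ComplexStructure:
        return ComplexStructure(residues=list(self.ligand), total_charge=None)

    def fragments_structure(self) -> ComplexStructure:
        residues: list[Residue] = []
        charge = 0
        for frag in self.fragments:
            residues.extend(frag.to_residues())
            charge += frag.formal_charge
        return ComplexStructure(residues=residues, total_charge=charge)


# ---------------------------------------------------------------------------
# partitioning and geometric selection
# ---------------------------------------------------------------------------


def partition_complex(
    structure: ComplexStructure, config: FragmenterConfig
) -> tuple[list[Residue], list[Residue], list[Residue]]:
    """Split the complex into (target, ligand, water) residue lists.

    Waters are identified by residue name on any chain (name rule takes
    precedence over the ligand chain selector); ligand residues are the
    non-water residues on the configured ligand chains; everything else
    is target.  Roles on the returned residues are updated in place.
    """
    if not config.ligand_chains:
        raise ValueError("ligand_chains selector is empty")
    present = {r.chain_id for r in structure.residues}
    missing = config.ligand_chains - present
    if missing == config.ligand_chains:
        raise ValueError(
            f"no ligand chain of {sorted(config.ligand_chains)} present "
            f"(chains in structure: {sorted(present)})"
        )
    target: list[Residue] = []
    ligand: list[Residue] = []
    waters: list[Residue] = []
    for res in structure.residues:
        if res.res_name in config.water_names:
            res.role = "water"
            waters.append(res)
        elif res.chain_id in config.ligand_chains:
            res.role = "ligand"
            ligand.append(res)
        else:
            res.role = "target"
            target.append(res)
    if not ligand:
        raise ValueError("ligand selection is empty (only waters on chain?)")
    if not target:
        raise ValueError("target is empty after partitioning")
    return target, ligand, waters


def closest_heavy_distance(
    residue: Residue, others: Sequence[Residue]
) -> float:
    """Minimum heavy-atom Euclidean distance from ``residue`` to ``others``."""
    a = residue.heavy_coords()
    if a.shape[0] == 0:
        raise ValueError(f"residue {residue.label} has no heavy atoms")
    blocks = [o.heavy_coords() for o in others]
    b = np.vstack([blk for blk in blocks if blk.shape[0]]) if blocks else None
    if b is None or b.shape[0] == 0:
        raise ValueError("other residues contain no heavy atoms")
    return float(cdist(a, b).min())


def select_interface_residues(
    target: Sequence[Residue], ligand: Sequence[Residue], d_tl: float
) -> list[Residue]:
    """Target residues whose closest heavy atom is within ``d_tl`` of the
    ligand's heavy atoms.  Monotone in ``d_tl``."""
    if not target or not ligand:
        raise ValueError("target and ligand must be non-empty")
    return [
        res
        for res in target
        if closest_heavy_distance(res, ligand) <= d_tl
    ]


# ---------------------------------------------------------------------------
# run construction on the chain topology
# ---------------------------------------------------------------------------


def _chain_index(
    target: Sequence[Residue],
) -> dict[str, list[Residue]]:
    chains: dict[str, list[Residue]] = {}
    for res in target:
        chains.setdefault(res.chain_id, []).append(res)
    return chains


def _runs_to_residues(
    intervals: dict[str, list[tuple[int, int]]],
    chains: dict[str, list[Residue]],
) -> list[list[Residue]]:
    runs: list[list[Residue]] = []
    for chain_id in chains:
        for lo, hi in intervals.get(chain_id, []):
            runs.append(chains[chain_id][lo : hi + 1])
    return runs


def _residues_to_intervals(
    runs: Iterable[Sequence[Residue]],
    chains: dict[str, list[Residue]],
) -> dict[str, list[tuple[int, int]]]:
    pos: dict[tuple[str, int, str], int] = {}
    for chain_id, residues in chains.items():
        for i, res in enumerate(residues):
            pos[res.key] = i
    intervals: dict[str, list[tuple[int, int]]] = {}
    for run in runs:
        chain_id = run[0].chain_id
        intervals.setdefault(chain_id, []).append(
            (pos[run[0].key], pos[run[-1].key])
        )
    for chain_id in intervals:
        intervals[chain_id].sort()
    return intervals


def _merge_overlaps(
    intervals: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def grow_fragments(
    selected: Iterable[Residue], target: Sequence[Residue], n: int
) -> list[list[Residue]]:
    """Group selected residues into contiguous runs and grow each end by
    up to ``n`` sequential neighbours (clipped at chain termini).

    Sequence adjacency is positional within the chain's residue list
    (file order), so insertion-code neighbours count as sequential.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    chains = _chain_index(target)
    selected_keys = {res.key for res in selected}
    intervals: dict[str, list[tuple[int, int]]] = {}
    for chain_id, residues in chains.items():
        idx = [i for i, r in enumerate(residues) if r.key in selected_keys]
        if not idx:
            continue
        raw: list[tuple[int, int]] = []
        lo = prev = idx[0]
        for i in idx[1:]:
            if i == prev + 1:
                prev = i
            else:
                raw.append((lo, prev))
                lo = prev = i
        raw.append((lo, prev))
        grown = [
            (max(0, lo - n), min(len(residues) - 1, hi + n)) for lo, hi in raw
        ]
        intervals[chain_id] = _merge_overlaps(grown)
    return _runs_to_residues(intervals, chains)


def merge_single_gaps(
    runs: Iterable[Sequence[Residue]], target: Sequence[Residue]
) -> list[list[Residue]]:
    """Bridge runs on one chain separated by exactly one residue,
    including the connector.  Idempotent."""
    chains = _chain_index(target)
    intervals = _residues_to_intervals(runs, chains)
    for chain_id, ivals in intervals.items():
        changed = True
        while changed:
            changed = False
            out: list[tuple[int, int]] = []
            for lo, hi in ivals:
                if out and lo - out[-1][1] == 2:
                    out[-1] = (out[-1][0], hi)
                    changed = True
                else:
                    out.append((lo, hi))
            ivals = out
        intervals[chain_id] = ivals
    return _runs_to_residues(intervals, chains)


def find_disulfide_pairs(
    target: Sequence[Residue], ss_cutoff: float
) -> list[tuple[Residue, Residue]]:
    """Cysteine pairs whose SG atoms lie within ``ss_cutoff``."""
    cys = []
    for res in target:
        if res.res_name not in ("CYS", "CYX"):
            continue
        sg = res.atom("SG")
        if sg is None:
            warnings.warn(
                f"cysteine {res.label} lacks an SG atom; skipped in "
                "disulfide detection",
                stacklevel=2,
            )
            continue
        cys.append((res, sg.xyz))
    pairs = []
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            if np.linalg.norm(cys[i][1] - cys[j][1]) <= ss_cutoff:
                pairs.append((cys[i][0], cys[j][0]))
    return pairs


def include_disulfide_partners(
    runs: Iterable[Sequence[Residue]],
    target: Sequence[Residue],
    ss_cutoff: float,
) -> list[list[Residue]]:
    """Add disulfide partners of selected cysteines as runs, then re-merge
    single gaps.  Iterates to a fixed point; idempotent."""
    if not ss_cutoff > 0:
        raise ValueError("ss_cutoff must be positive")
    chains = _chain_index(target)
    pairs = find_disulfide_pairs(target, ss_cutoff)
    partner: dict[tuple[str, int, str], list[Residue]] = {}
    for a, b in pairs:
        partner.setdefault(a.key, []).append(b)
        partner.setdefault(b.key, []).append(a)

    current = [list(run) for run in runs]
    while True:
        member = {res.key for run in current for res in run}
        to_add = [
            p
            for key in member
            for p in partner.get(key, [])
            if p.key not in member
        ]
        if not to_add:
            break
        current.extend([[p] for p in to_add])
        current = merge_single_gaps(current, target)
    return merge_single_gaps(current, target)


# ---------------------------------------------------------------------------
# capping
# ---------------------------------------------------------------------------

_TETRAHEDRAL_DEG = 109.47
_CH_BOND = 1.09
_NH_BOND = 1.01


def methyl_hydrogens(
    carbon: np.ndarray,
    bonded: np.ndarray,
    reference: np.ndarray,
    bond_length: float = _CH_BOND,
    angle_deg: float = _TETRAHEDRAL_DEG,
) -> list[np.ndarray]:
    """Three staggered hydrogen positions on ``carbon``.

    Hydrogens sit at ``bond_length`` from ``carbon``, at ``angle_deg``
    from the carbon->bonded axis, staggered (dihedrals 60/180/300
    degrees) relative to the ``reference`` substituent on ``bonded``.
    Also used for the protonated amino group with an N-H bond length.
    """
    carbon = np.asarray(carbon, dtype=float)
    u = np.asarray(bonded, dtype=float) - carbon
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("carbon and bonded atom coincide")
    u = u / norm
    w = np.asarray(reference, dtype=float) - np.asarray(bonded, dtype=float)
    v = w - np.dot(w, u) * u
    vn = np.linalg.norm(v)
    if vn < 1e-8:
        # reference collinear with the bond: any perpendicular will do
        seed = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(seed, u)) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        v = seed - np.dot(seed, u) * u
        vn = np.linalg.norm(v)
    v = v / vn
    t = np.cross(u, v)
    alpha = math.radians(angle_deg)
    positions = []
    for phi_deg in (60.0, 180.0, 300.0):
        phi = math.radians(phi_deg)
        direction = math.cos(alpha) * u + math.sin(alpha) * (
            math.cos(phi) * v + math.sin(phi) * t
        )
        positions.append(carbon + bond_length * direction)
    return positions


def _require_atoms(res: Residue, names: Sequence[str]) -> dict[str, Atom]:
    out = {}
    for name in names:
        atom = res.atom(name)
        if atom is None and name == "CA":
            # an existing ACE/NME cap offers its methyl carbon instead
            atom = res.atom("CH3")
        if atom is None:
            raise ValueError(
                f"residue {res.label} lacks backbone atom {name!r} "
                "required for cap construction"
            )
        out[name] = atom
    return out


def cap_fragment(
    run: Sequence[Residue], target: Sequence[Residue]
) -> Fragment:
    """Seal a contiguous run into a capped peptide fragment.

    A cut N-terminus gets an acetyl group built from the preceding
    residue's C/O/CA (the CA becomes the methyl carbon and receives three
    constructed hydrogens); a cut C-terminus gets an N-methylamide from
    the following residue's N (+ amide H when present) and CA, again with
    three constructed hydrogens.  True chain termini are left as a
    protonated amino group (three hydrogens on the backbone N) or an
    unchanged carboxylate.
    """
    chains = _chain_index(target)
    chain = chains[run[0].chain_id]
    pos = {res.key: i for i, res in enumerate(chain)}
    i_first, i_last = pos[run[0].key], pos[run[-1].key]

    n_cap_atoms: list[Atom] = []
    if i_first > 0:
        prev = chain[i_first - 1]
        atoms = _require_atoms(prev, ("C", "O", "CA"))
        ch3 = atoms["CA"].xyz
        c = atoms["C"].xyz
        o = atoms["O"].xyz
        n_cap_atoms = [
            Atom(serial=0, name="CH3", element="C", xyz=ch3),
            Atom(serial=0, name="C", element="C", xyz=c),
            Atom(serial=0, name="O", element="O", xyz=o),
        ]
        for k, h in enumerate(methyl_hydrogens(ch3, c, o), start=1):
            n_cap_atoms.append(
                Atom(serial=0, name=f"HH3{k}", element="H", xyz=h)
            )
        n_cap = "ACE"
    else:
        first = run[0]
        atoms = _require_atoms(first, ("N", "CA", "C"))
        n_cap_atoms = [
            Atom(serial=0, name=f"H{k}", element="H", xyz=h)
            for k, h in enumerate(
                methyl_hydrogens(
                    atoms["N"].xyz,
                    atoms["CA"].xyz,
                    atoms["C"].xyz,
                    bond_length=_NH_BOND,
                ),
                start=1,
            )
        ]
        n_cap = "NH3_PLUS"

    c_cap_atoms: list[Atom] = []
    if i_last < len(chain) - 1:
        nxt = chain[i_last + 1]
        atoms = _require_atoms(nxt, ("N", "CA"))
        n_xyz = atoms["N"].xyz
        ch3 = atoms["CA"].xyz
        c_cap_atoms = [Atom(serial=0, name="N", element="N", xyz=n_xyz)]
        amide_h = nxt.atom("H") or nxt.atom("HN")
        if amide_h is not None:
            c_cap_atoms.append(
                Atom(serial=0, name="H", element="H", xyz=amide_h.xyz)
            )
        c_cap_atoms.append(Atom(serial=0, name="CH3", element="C", xyz=ch3))
        # staggered relative to the preceding carbonyl carbon of the run
        ref = _require_atoms(run[-1], ("C",))["C"].xyz
        for k, h in enumerate(methyl_hydrogens(ch3, n_xyz, ref), start=1):
            c_cap_atoms.append(
                Atom(serial=0, name=f"HH3{k}", element="H", xyz=h)
            )
        c_cap = "NME"
    else:
        c_cap = "COO_MINUS"

    return Fragment(
        chain_id=run[0].chain_id,
        residues=list(run),
        n_cap=n_cap,
        c_cap=c_cap,
        n_cap_atoms=n_cap_atoms,
        c_cap_atoms=c_cap_atoms,
    )


# ---------------------------------------------------------------------------
# formal charges at pH 7
# ---------------------------------------------------------------------------


def residue_charge(
    residue: Residue,
    in_disulfide: bool = False,
    is_free_n_terminus: bool = False,
    is_free_c_terminus: bool = False,
    charge_table: Optional[Mapping[str, int]] = None,
) -> int:
    """Formal charge of one residue at pH 7.

    Asp/Glu score -1 (0 when an explicit side-chain proton HD2/HE2 is
    present), Lys/Arg +1, Cys 0 when disulfide-bonded or carrying HG and
    -1 otherwise, His from its explicit ring protons (HD1 and HE2 -> +1,
    exactly one -> 0, none -> -1).  A free N-terminus adds +1 and a free
    C-terminus -1.  ``charge_table`` overrides or extends the side-chain
    table (e.g. for non-standard residues).
    """
    name = residue.res_name
    table = dict(SIDECHAIN_CHARGES_PH7)
    if charge_table:
        table.update(charge_table)

    if name in ("CYS", "CYX"):
        charge = 0 if (in_disulfide or residue.has_atom("HG")) else -1
    elif name in ("HIS", "HID", "HIE", "HIP"):
        protons = sum(residue.has_atom(h) for h in ("HD1", "HE2"))
        charge = {2: +1, 1: 0, 0: -1}[protons]
    elif name == "ASP" and residue.has_atom("HD2"):
        charge = 0
    elif name == "GLU" and residue.has_atom("HE2"):
        charge = 0
    elif name in table:
        charge = table[name]
    else:
        raise ValueError(
            f"no charge entry for residue {name!r} ({residue.label}); "
            "supply a charge_table"
        )
    if is_free_n_terminus:
        charge += 1
    if is_free_c_terminus:
        charge -= 1
    return charge


def _fragment_charge(
    frag: Fragment,
    disulfide_keys: set[tuple[str, int, str]],
    charge_table: Optional[Mapping[str, int]],
) -> int:
    total = 0
    for res in frag.residues:
        total += residue_charge(
            res,
            in_disulfide=res.key in disulfide_keys,
            is_free_n_terminus=(res is frag.first and frag.n_cap == "NH3_PLUS"),
            is_free_c_terminus=(res is frag.last and frag.c_cap == "COO_MINUS"),
            charge_table=charge_table,
        )
    return total


def _ligand_charge(
    ligand: Sequence[Residue], config: FragmenterConfig
) -> int:
    """Ligand formal charge: explicit override, or per-residue pH-7 rules
    for peptidic ligands (free termini on the first/last residue)."""
    if config.ligand_formal_charge is not None:
        return config.ligand_formal_charge
    known = config.charge_table or {}
    standard = all(
        r.res_name in STANDARD_AMINO_ACIDS
        or r.res_name in ("CYX", "HID", "HIE", "HIP")
        or r.res_name in known
        for r in ligand
    )
    if not standard:
        raise ValueError(
            "ligand contains non-amino-acid residues; set "
            "ligand_formal_charge or provide a charge_table"
        )
    total = 0
    for i, res in enumerate(ligand):
        total += residue_charge(
            res,
            is_free_n_terminus=(i == 0),
            is_free_c_terminus=(i == len(ligand) - 1),
            charge_table=config.charge_table,
        )
    return total


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def extract_interface(
    structure: ComplexStructure,
    config: FragmenterConfig,
    params: Optional[object] = None,
    compute_einter: bool = True,
) -> InterfaceComplex:
    """Run the full extraction pipeline on a complex.

    Stages: partition -> residue selection by ``d_tl`` -> growth by ``n``
    -> single-gap merging -> disulfide partner inclusion -> capping ->
    formal charges -> water clash removal, interfacial selection by
    ``d_w`` and shell classification -> per-residue interaction-energy
    report.  Deterministic for a fixed input.
    """
    from interfrag import energetics, hydration

    target, ligand, waters = partition_complex(structure, config)
    selected = select_interface_residues(target, ligand, config.d_tl)
    runs = grow_fragments(selected, target, config.n)
    runs = merge_single_gaps(runs, target)
    runs = include_disulfide_partners(runs, target, config.ss_cutoff)

    disulfide_keys = {
        res.key
        for pair in find_disulfide_pairs(target, config.ss_cutoff)
        for res in pair
    }
    fragments = []
    for run in runs:
        frag = cap_fragment(run, target)
        frag.formal_charge = _fragment_charge(
            frag, disulfide_keys, config.charge_table
        )
        frag.d_cls_per_residue = {
            res.key: closest_heavy_distance(res, ligand) for res in run
        }
        fragments.append(frag)

    kept_waters = hydration.remove_clashing_waters(waters, ligand, config.d_min)
    retained = hydration.select_interfacial_waters(
        kept_waters, target, ligand, config.d_w
    )
    shells = hydration.assign_shells(
        retained, shell1_cutoff=config.shell1_cutoff
    )

    total_charge = sum(f.formal_charge for f in fragments) + _ligand_charge(
        ligand, config
    )

    report = None
    if compute_einter:
        if params is None:
            params = energetics.builtin_parameter_table()
            policy = "zero"
        else:
            policy = "strict"
        fragment_residues = [res for frag in fragments for res in frag.residues]
        report = energetics.einter_report(
            fragment_residues,
            ligand,
            params,
            missing_policy=policy,
            clash_threshold=config.clash_threshold,
        )

    return InterfaceComplex(
        fragments=fragments,
        ligand=ligand,
        waters=shells,
        total_charge=total_charge,
        einter_report=report,
    )
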