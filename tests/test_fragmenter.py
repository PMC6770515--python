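"""Fragment selection, growth, merging, disulfides, capping and charges."""

import math
import warnings

import numpy as np
import pytest

from conftest import brute_closest_heavy, mk_res, random_complex
from interfrag.fixtures import ToyComplexSpec, make_toy_complex
from interfrag.fragmenter_core import (
    FragmenterConfig,
    cap_fragment,
    closest_heavy_distance,
    extract_interface,
    grow_fragments,
    include_disulfide_partners,
    merge_single_gaps,
    partition_complex,
    residue_charge,
    select_interface_residues,
)
from interfrag.structure_io import parse_pdb, write_pdb


def chain_of(n, chain="A", start=1):
    """n single-CA alanines spaced 4 A apart (contiguous backbone proxy)."""
    return [
        mk_res(chain, start + i, "ALA", [("CA", (4.0 * i, 0, 0), "C")])
        for i in range(n)
    ]


def runs_as_seqs(runs):
    return sorted(tuple(r.res_seq for r in run) for run in runs)


class TestPartition:
    def test_counts_match_generator(self, toy_structure):
        cfg = FragmenterConfig(ligand_chains={"L"})
        target, ligand, waters = partition_complex(toy_structure, cfg)
        assert (len(target), len(ligand), len(waters)) == (8, 1, 2)

    def test_all_water_structure_has_no_target(self):
        spec = ToyComplexSpec(n_target_residues=2, planted_interface={0: 3.0})
        s = make_toy_complex(spec)
        for res in s.residues:
            res.res_name = "SOL"
        cfg = FragmenterConfig(ligand_chains={"L"})
        with pytest.raises(ValueError):
            partition_complex(s, cfg)

    def test_water_name_takes_precedence_on_ligand_chain(self, toy_structure):
        lig = [r for r in toy_structure.residues if r.chain_id == "L"][0]
        extra = mk_res("L", 2, "HOH", [("O", (0, 30, 0), "O")])
        toy_structure.residues.append(extra)
        cfg = FragmenterConfig(ligand_chains={"L"})
        target, ligand, waters = partition_complex(toy_structure, cfg)
        assert extra in waters and extra not in ligand

    def test_empty_ligand_selector_rejected(self, toy_structure):
        with pytest.raises(ValueError):
            partition_complex(
                toy_structure, FragmenterConfig(ligand_chains=frozenset())
            )


class TestClosestHeavyDistance:
    def test_forced_geometry(self):
        a = mk_res("A", 1, "ALA", [("CA", (0, 0, 0), "C")])
        b = mk_res("L", 1, "LIG", [("C1", (3, 0, 0), "C")])
        assert closest_heavy_distance(a, [b]) == pytest.approx(3.0)
        assert closest_heavy_distance(b, [a]) == pytest.approx(3.0)

    def test_identity_is_zero(self):
        a = mk_res("A", 1, "ALA", [("CA", (1, 2, 3), "C")])
        assert closest_heavy_distance(a, [a]) == 0.0

    def test_hydrogens_ignored(self):
        a = mk_res("A", 1, "ALA", [("CA", (0, 0, 0), "C"), ("HA", (2.9, 0, 0), "H")])
        b = mk_res("L", 1, "LIG", [("C1", (3, 0, 0), "C")])
        assert closest_heavy_distance(a, [b]) == pytest.approx(3.0)

    def test_hydrogen_only_residue_rejected(self):
        h = mk_res("A", 1, "XXX", [("H1", (0, 0, 0), "H")])
        b = mk_res("L", 1, "LIG", [("C1", (3, 0, 0), "C")])
        with pytest.raises(ValueError):
            closest_heavy_distance(h, [b])

    def test_matches_brute_force_on_random_clouds(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            target, ligand, _, _ = random_complex(rng)
            for res in target:
                assert closest_heavy_distance(res, ligand) == pytest.approx(
                    brute_closest_heavy(res, ligand), abs=1e-12
                )


class TestSelection:
    @pytest.fixture
    def planted(self):
        spec = ToyComplexSpec(
            n_target_residues=9,
            ligand_atom_count=3,
            planted_interface={1: 3.0, 4: 4.0, 7: 6.0},
        )
        s = make_toy_complex(spec)
        cfg = FragmenterConfig(ligand_chains={"L"})
        return partition_complex(s, cfg)

    @pytest.mark.parametrize(
        "d_tl,expected",
        [(3.5, {2}), (4.5, {2, 5}), (math.inf, set(range(1, 10)))],
    )
    def test_threshold_selection(self, planted, d_tl, expected):
        target, ligand, _ = planted
        sel = select_interface_residues(target, ligand, d_tl)
        assert {r.res_seq for r in sel} == expected

    def test_monotone_in_d_tl(self, planted):
        target, ligand, _ = planted
        prev: set = set()
        for d_tl in (2.0, 3.5, 4.5, 6.5, 10.0):
            cur = {r.res_seq for r in select_interface_residues(target, ligand, d_tl)}
            assert prev <= cur
            prev = cur


class TestGrowAndMerge:
    def test_n0_keeps_contiguous_blocks(self):
        chain = chain_of(10)
        sel = [chain[i] for i in (2, 3, 7)]
        assert runs_as_seqs(grow_fragments(sel, chain, 0)) == [(3, 4), (8,)]

    def test_n1_adds_first_neighbours(self):
        chain = chain_of(10)
        sel = [chain[4]]
        assert runs_as_seqs(grow_fragments(sel, chain, 1)) == [(4, 5, 6)]

    def test_growth_clipped_at_terminus(self):
        chain = chain_of(10)
        sel = [chain[0]]
        assert runs_as_seqs(grow_fragments(sel, chain, 1)) == [(1, 2)]

    def test_growth_monotone_in_n(self):
        chain = chain_of(20)
        sel = [chain[i] for i in (3, 9, 15)]
        prev: set = set()
        for n in range(4):
            cur = {
                r.res_seq for run in grow_fragments(sel, chain, n) for r in run
            }
            assert prev <= cur
            prev = cur

    def test_single_gap_merged_with_connector(self):
        chain = chain_of(20)
        runs = [[chain[9], chain[10]], [chain[12], chain[13]]]
        assert runs_as_seqs(merge_single_gaps(runs, chain)) == [tuple(range(10, 15))]

    def test_double_gap_not_merged(self):
        chain = chain_of(20)
        runs = [[chain[9]], [chain[12]]]
        assert runs_as_seqs(merge_single_gaps(runs, chain)) == [(10,), (13,)]

    def test_merge_idempotent(self):
        chain = chain_of(20)
        runs = [[chain[0]], [chain[2]], [chain[4], chain[5]], [chain[9]]]
        once = merge_single_gaps(runs, chain)
        twice = merge_single_gaps(once, chain)
        assert runs_as_seqs(once) == runs_as_seqs(twice) == [(1, 2, 3, 4, 5, 6), (10,)]


class TestDisulfides:
    def make_ss_fixture(self, sg_gap=2.05):
        spec = ToyComplexSpec(
            n_target_residues=10,
            residue_names={1: "CYS", 7: "CYS"},
            planted_interface={1: 3.0},
            disulfide_pairs=[(1, 7)] if sg_gap <= 2.3 else [],
        )
        s = make_toy_complex(spec)
        target, _, _ = partition_complex(
            s, FragmenterConfig(ligand_chains={"L"})
        )
        if sg_gap > 2.3:  # separate the SG atoms explicitly
            target[7].atom("SG").xyz = target[1].atom("SG").xyz + np.array(
                [0.0, 0.0, sg_gap]
            )
        return target

    def test_partner_outside_selection_added(self):
        target = self.make_ss_fixture(2.05)
        runs = [[target[1]]]
        out = include_disulfide_partners(runs, target, ss_cutoff=2.3)
        assert runs_as_seqs(out) == [(2,), (8,)]

    def test_beyond_cutoff_not_added(self):
        target = self.make_ss_fixture(4.0)
        runs = [[target[1]]]
        out = include_disulfide_partners(runs, target, ss_cutoff=2.3)
        assert runs_as_seqs(out) == [(2,)]

    def test_idempotent_when_partner_already_selected(self):
        target = self.make_ss_fixture(2.05)
        runs = [[target[1]], [target[7]]]
        out = include_disulfide_partners(runs, target, ss_cutoff=2.3)
        assert runs_as_seqs(out) == runs_as_seqs(
            include_disulfide_partners(out, target, ss_cutoff=2.3)
        )

    def test_cys_without_sg_warns_and_skips(self):
        target = self.make_ss_fixture(2.05)
        target[7].atoms = [a for a in target[7].atoms if a.name != "SG"]
        with pytest.warns(UserWarning, match="SG"):
            out = include_disulfide_partners([[target[1]]], target, 2.3)
        assert runs_as_seqs(out) == [(2,)]


class TestCapping:
    @pytest.fixture
    def target(self):
        s = make_toy_complex(
            ToyComplexSpec(n_target_residues=10, planted_interface={5: 3.0})
        )
        target, _, _ = partition_complex(
            s, FragmenterConfig(ligand_chains={"L"})
        )
        return target

    def test_internal_run_gets_ace_and_nme(self, target):
        frag = cap_fragment(target[4:6], target)
        assert frag.n_cap == "ACE" and frag.c_cap == "NME"
        # ACE: CH3 + C + O + 3H; NME: N + CH3 + 3H (toy chain has no amide H)
        assert len(frag.n_cap_atoms) == 6
        assert len(frag.c_cap_atoms) == 5
        n_res_atoms = sum(len(r.atoms) for r in frag.residues)
        assert frag.n_atoms == n_res_atoms + 11

    def test_chain_start_gets_protonated_amine(self, target):
        frag = cap_fragment(target[0:2], target)
        assert frag.n_cap == "NH3_PLUS"
        assert [a.element for a in frag.n_cap_atoms] == ["H", "H", "H"]

    def test_chain_end_keeps_carboxylate(self, target):
        frag = cap_fragment(target[8:10], target)
        assert frag.c_cap == "COO_MINUS"
        assert frag.c_cap_atoms == []

    def test_constructed_hydrogen_geometry(self, target):
        frag = cap_fragment(target[4:6], target)
        prev = target[3]
        ch3, c = prev.atom("CA").xyz, prev.atom("C").xyz
        hydrogens = [a for a in frag.n_cap_atoms if a.element == "H"]
        assert len(hydrogens) == 3
        for h in hydrogens:
            bond = np.linalg.norm(h.xyz - ch3)
            assert bond == pytest.approx(1.09, abs=1e-6)
            v1 = h.xyz - ch3
            v2 = c - ch3
            angle = math.degrees(
                math.acos(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            )
            assert angle == pytest.approx(109.47, abs=1e-4)
        # staggered: all three H mutually separated
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(hydrogens[i].xyz - hydrogens[j].xyz) > 1.5

    def test_amine_hydrogen_geometry(self, target):
        frag = cap_fragment(target[0:2], target)
        n = target[0].atom("N").xyz
        ca = target[0].atom("CA").xyz
        for h in frag.n_cap_atoms:
            assert np.linalg.norm(h.xyz - n) == pytest.approx(1.01, abs=1e-6)
            v1, v2 = h.xyz - n, ca - n
            angle = math.degrees(
                math.acos(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            )
            assert angle == pytest.approx(109.47, abs=1e-4)

    def test_missing_backbone_atom_names_residue(self, target):
        target[3].atoms = [a for a in target[3].atoms if a.name != "O"]
        with pytest.raises(ValueError, match="ALA4"):
            cap_fragment(target[4:6], target)


class TestResidueCharge:
    @pytest.mark.parametrize(
        "name,atoms,kwargs,expected",
        [
            ("CYS", [("SG", (0, 0, 0), "S")], {"in_disulfide": True}, 0),
            ("CYS", [("SG", (0, 0, 0), "S")], {}, -1),
            ("CYS", [("SG", (0, 0, 0), "S"), ("HG", (0, 0, 1), "H")], {}, 0),
            ("ALA", [("CA", (0, 0, 0), "C")], {}, 0),
            ("GLU", [("CA", (0, 0, 0), "C")], {"is_free_c_terminus": True}, -2),
            ("GLU", [("CA", (0, 0, 0), "C"), ("HE2", (1, 0, 0), "H")], {}, 0),
            ("ASP", [("CA", (0, 0, 0), "C")], {}, -1),
            ("ASP", [("CA", (0, 0, 0), "C"), ("HD2", (1, 0, 0), "H")], {}, 0),
            ("LYS", [("NZ", (0, 0, 0), "N")], {}, 1),
            ("ARG", [("CZ", (0, 0, 0), "C")], {"is_free_n_terminus": True}, 2),
            (
                "HIS",
                [("HD1", (0, 0, 0), "H"), ("HE2", (1, 0, 0), "H")],
                {},
                1,
            ),
            ("HIS", [("HD1", (0, 0, 0), "H")], {}, 0),
            ("HIS", [("HE2", (0, 0, 0), "H")], {}, 0),
            ("HIS", [("CA", (0, 0, 0), "C")], {}, -1),
        ],
    )
    def test_ph7_rules(self, name, atoms, kwargs, expected):
        res = mk_res("A", 1, name, atoms)
        assert residue_charge(res, **kwargs) == expected

    def test_unknown_residue_needs_table(self):
        res = mk_res("A", 1, "XYZ", [("C1", (0, 0, 0), "C")])
        with pytest.raises(ValueError, match="XYZ"):
            residue_charge(res)
        assert residue_charge(res, charge_table={"XYZ": -2}) == -2


class TestExtractInterface:
    def test_fragments_equal_planted_interface(self, toy_structure):
        cfg = FragmenterConfig(ligand_chains={"L"}, ligand_formal_charge=0)
        iface = extract_interface(toy_structure, cfg, compute_einter=False)
        seqs = sorted(
            r.res_seq for f in iface.fragments for r in f.residues
        )
        assert seqs == [2, 5]  # planted at 3.0 and 3.3 <= d_tl 3.5

    def test_large_cutoff_takes_whole_chain(self, toy_structure):
        cfg = FragmenterConfig(
            d_tl=1000.0, ligand_chains={"L"}, ligand_formal_charge=0
        )
        iface = extract_interface(toy_structure, cfg, compute_einter=False)
        assert len(iface.fragments) == 1
        frag = iface.fragments[0]
        assert len(frag.residues) == 8
        assert frag.n_cap == "NH3_PLUS" and frag.c_cap == "COO_MINUS"
        # whole neutral chain as zwitterion: +1 - 1 = 0
        assert frag.formal_charge == 0

    def test_total_charge_consistency_and_remark(self):
        spec = ToyComplexSpec(
            n_target_residues=8,
            residue_names={1: "ASP", 4: "LYS"},
            planted_interface={1: 3.0, 4: 3.2},
        )
        s = make_toy_complex(spec)
        cfg = FragmenterConfig(ligand_chains={"L"}, ligand_formal_charge=0)
        iface = extract_interface(s, cfg, compute_einter=False)
        assert iface.total_charge == sum(
            f.formal_charge for f in iface.fragments
        )
        assert iface.total_charge == -1 + 1
        text = write_pdb(iface.to_structure(), include_charge_remark=True)
        assert parse_pdb(text).total_charge == iface.total_charge

    def test_rerun_on_own_output_is_stable(self, toy_structure):
        cfg = FragmenterConfig(ligand_chains={"L"}, ligand_formal_charge=0)
        iface = extract_interface(toy_structure, cfg, compute_einter=False)
        text = write_pdb(iface.to_structure(), include_charge_remark=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            iface2 = extract_interface(
                parse_pdb(text), cfg, compute_einter=False
            )
        keys1 = {r.key for f in iface.fragments for r in f.residues}
        keys2 = {r.key for f in iface2.fragments for r in f.residues}
        assert keys1 <= keys2  # caps may add flanking-residue atoms only

    def test_n0_membership_is_explained(self):
        """Every fragment residue is selected, a connector, or an SS partner."""
        spec = ToyComplexSpec(
            n_target_residues=12,
            residue_names={2: "CYS", 9: "CYS"},
            planted_interface={2: 3.0, 4: 3.2},
            disulfide_pairs=[(2, 9)],
        )
        s = make_toy_complex(spec)
        cfg = FragmenterConfig(ligand_chains={"L"}, ligand_formal_charge=0)
        iface = extract_interface(s, cfg, compute_einter=False)
        target, ligand, _ = partition_complex(s, cfg)
        selected = {
            r.res_seq
            for r in select_interface_residues(target, ligand, cfg.d_tl)
        }
        connectors = {4}  # gap between selected 3 and 5 (res_seq)
        ss_partners = {10}
        members = {r.res_seq for f in iface.fragments for r in f.residues}
        assert members <= selected | connectors | ss_partners
        assert selected <= members
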