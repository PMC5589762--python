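"""NOE restraint parsing, modification rules, violations and energies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from czbkit import (
    AtomRecord,
    AtomSelector,
    Ensemble,
    HarmonicTether,
    NOERestraint,
    RestraintSet,
    RestraintResolutionError,
    Structure,
    TwoWellPotential,
    ensemble_effective_distance,
    mean_ensemble_violation,
    pad_restraints,
    parse_restraints,
    parse_xplor_restraints,
    remap_aliphatic,
    remap_set,
    restraint_energy,
    structure_mean_violation,
    structure_violation,
    tether_energy,
    write_restraint_table,
)
from czbkit.synthgen import DecoySpec, make_decoy_ensemble


def pair_structure(r: float) -> Structure:
    """Two atoms separated by r along x."""
    return Structure(
        [
            AtomRecord("A", 1, "GLY", "CA", "C", (0.0, 0.0, 0.0)),
            AtomRecord("C", 1, "GLY", "CA", "C", (float(r), 0.0, 0.0)),
        ]
    )


def pair_restraint(bound: float) -> NOERestraint:
    return NOERestraint(("A", 1, "CA"), ("C", 1, "CA"), bound, interface=True)


class TestParsing:
    def test_table_parsed_in_file_order(self, toy, true_restraints, tmp_path):
        path = write_restraint_table(true_restraints, tmp_path / "r.tbl")
        back = parse_restraints(path, toy)
        assert len(back) == len(true_restraints)
        assert [r.pair for r in back] == [r.pair for r in true_restraints]

    def test_interface_flag_from_chain_membership(self, toy, tmp_path):
        a = next(a for a in toy.atoms if a.chain_id == "A")
        b = next(a for a in toy.atoms if a.chain_id == "B")
        c = next(a for a in toy.atoms if a.chain_id == "C")
        lines = [
            f"C {c.res_seq} {c.atom_name} A {a.res_seq} {a.atom_name} 5.0",
            f"A {a.res_seq} {a.atom_name} B {b.res_seq} {b.atom_name} 5.0",
        ]
        p = tmp_path / "r.tbl"
        p.write_text("\n".join(lines) + "\n")
        rset = parse_restraints(p, toy)
        assert rset[0].interface is True
        assert rset[1].interface is False

    def test_absent_atom_error_names_line(self, toy, tmp_path):
        p = tmp_path / "r.tbl"
        p.write_text("A 999 CA C 1 CA 5.0\n")
        with pytest.raises(RestraintResolutionError, match="line 1"):
            parse_restraints(p, toy)

    def test_xplor_assign_import_upper_is_d_plus_dplus(self, toy, tmp_path):
        a = next(a for a in toy.atoms if a.chain_id == "A")
        c = next(a for a in toy.atoms if a.chain_id == "C")
        p = tmp_path / "x.tbl"
        p.write_text(
            f"assign (segid C and resid {c.res_seq} and name {c.atom_name}) "
            f"(segid A and resid {a.res_seq} and name {a.atom_name}) "
            "4.0 2.2 1.5\n"
        )
        rset = parse_xplor_restraints(p, toy)
        assert rset[0].upper_bound == pytest.approx(5.5)
        assert rset[0].interface is True


class TestAliphaticRemap:
    @pytest.fixture
    def topo_with_h(self):
        """LEU with a methyl hydrogen + TYR ring carbon + backbone amide H."""
        atoms = [
            AtomRecord("C", 70, "LEU", "N", "N", (0, 0, 0)),
            AtomRecord("C", 70, "LEU", "H", "H", (0, -1, 0)),
            AtomRecord("C", 70, "LEU", "CD1", "C", (1, 0, 0)),
            AtomRecord("C", 70, "LEU", "HD11", "H", (1.5, 0.5, 0)),
            AtomRecord("B", 40, "TYR", "CZ", "C", (5, 0, 0)),
            AtomRecord("B", 40, "TYR", "OH", "O", (6, 0, 0)),
            AtomRecord("B", 40, "TYR", "HH", "H", (6.5, 0, 0)),
        ]
        return Structure(atoms)

    def test_methyl_hydrogen_remapped_to_carbon_plus_one_angstrom(self, topo_with_h):
        r = NOERestraint(("C", 70, "HD11"), ("B", 40, "CZ"), 4.0)
        out = remap_aliphatic(r, topo_with_h)
        assert out.atom_a == ("C", 70, "CD1")
        assert out.upper_bound == pytest.approx(5.0)
        assert out.remapped_aliphatic_a and not out.remapped_aliphatic_b

    def test_both_endpoints_aliphatic_adds_two_angstrom(self, topo_with_h):
        # HH is polar (on OH); use two methyl H's instead
        topo = Structure(
            list(topo_with_h.atoms)
            + [
                AtomRecord("B", 41, "ALA", "CB", "C", (8, 0, 0)),
                AtomRecord("B", 41, "ALA", "HB1", "H", (8.5, 0, 0)),
            ]
        )
        r = NOERestraint(("C", 70, "HD11"), ("B", 41, "HB1"), 4.0)
        out = remap_aliphatic(r, topo)
        assert out.atom_a == ("C", 70, "CD1")
        assert out.atom_b == ("B", 41, "CB")
        assert out.upper_bound == pytest.approx(6.0)

    def test_polar_hydrogens_untouched(self, topo_with_h):
        for key in (("C", 70, "H"), ("B", 40, "HH")):
            r = NOERestraint(key, ("C", 70, "CD1") if key[0] == "B" else ("B", 40, "CZ"), 4.0)
            out = remap_aliphatic(r, topo_with_h)
            assert out.atom_a == key
            assert out.upper_bound == pytest.approx(4.0)

    def test_methyl_ambiguity_collapses_to_loosest_bound(self, topo_with_h):
        topo = Structure(
            list(topo_with_h.atoms)
            + [AtomRecord("C", 70, "LEU", "HD12", "H", (1.5, -0.5, 0))]
        )
        rset = RestraintSet(
            [
                NOERestraint(("C", 70, "HD11"), ("B", 40, "CZ"), 4.0),
                NOERestraint(("C", 70, "HD12"), ("B", 40, "CZ"), 4.5),
            ]
        )
        out = remap_set(rset, topo)
        assert len(out) == 1
        assert out[0].upper_bound == pytest.approx(5.5)


class TestPadding:
    def test_pad_adds_to_every_bound_and_sets_flag(self):
        rset = RestraintSet([pair_restraint(4.0), pair_restraint(5.5)])
        out = pad_restraints(rset, 1.0)
        assert [r.upper_bound for r in out] == pytest.approx([5.0, 6.5])
        assert all(r.padded for r in out)

    def test_pad_zero_is_identity(self):
        rset = RestraintSet([pair_restraint(4.0)])
        out = pad_restraints(rset, 0.0)
        assert out[0].upper_bound == 4.0
        assert not out[0].padded

    def test_remap_then_pad_composes_to_two_angstrom(self):
        topo = Structure(
            [
                AtomRecord("C", 1, "ALA", "CB", "C", (0, 0, 0)),
                AtomRecord("C", 1, "ALA", "HB1", "H", (0.5, 0, 0)),
                AtomRecord("A", 2, "GLY", "CA", "C", (4, 0, 0)),
            ]
        )
        r = NOERestraint(("C", 1, "HB1"), ("A", 2, "CA"), 4.0)
        out = pad_restraints(RestraintSet([remap_aliphatic(r, topo)]), 1.0)
        assert out[0].upper_bound == pytest.approx(6.0)

    @given(
        a=st.floats(0.0, 3.0, allow_nan=False),
        b=st.floats(0.0, 3.0, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_padding_is_additive(self, a, b):
        rset = RestraintSet([pair_restraint(4.0)])
        seq = pad_restraints(pad_restraints(rset, a), b)
        once = pad_restraints(rset, a + b)
        assert seq[0].upper_bound == pytest.approx(once[0].upper_bound)


class TestViolations:
    @pytest.mark.parametrize(
        "r, bound, expected",
        [(5.0, 6.0, 0.0), (7.25, 6.0, 1.25), (6.0, 6.0, 0.0)],
    )
    def test_one_sided_violation(self, r, bound, expected):
        s = pair_structure(r)
        assert structure_violation(s, pair_restraint(bound)) == pytest.approx(expected)

    def test_effective_distance_single_member_is_identity(self):
        ens = Ensemble([pair_structure(4.0)])
        assert ensemble_effective_distance(ens, pair_restraint(6.0)) == pytest.approx(4.0)

    def test_effective_distance_two_members_matches_arithmetic_oracle(self):
        ens = Ensemble([pair_structure(4.0), pair_structure(8.0)])
        expected = ((4.0**-6 + 8.0**-6) / 2.0) ** (-1.0 / 6.0)
        got = ensemble_effective_distance(ens, pair_restraint(6.0))
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(4.478, abs=5e-4)

    def test_identical_members_give_that_distance(self):
        ens = Ensemble([pair_structure(5.0)] * 4)
        assert ensemble_effective_distance(ens, pair_restraint(6.0)) == pytest.approx(5.0)

    def test_coincident_atoms_raise_singularity(self):
        ens = Ensemble([pair_structure(0.0)])
        with pytest.raises(ZeroDivisionError):
            ensemble_effective_distance(ens, pair_restraint(6.0))

    @given(
        st.lists(st.floats(1.0, 20.0, allow_nan=False), min_size=1, max_size=12)
    )
    @settings(max_examples=100, deadline=None)
    def test_power_mean_inequality(self, distances):
        """r⁻⁶ average ≤ arithmetic mean, bracketed by min and max."""
        ens = Ensemble([pair_structure(r) for r in distances])
        eff = ensemble_effective_distance(ens, pair_restraint(6.0))
        assert min(distances) - 1e-9 <= eff <= max(distances) + 1e-9
        assert eff <= np.mean(distances) + 1e-9

    def test_mean_violation_zero_on_satisfying_ensemble(self, toy, true_restraints):
        ens = Ensemble([toy])
        assert mean_ensemble_violation(ens, true_restraints) == pytest.approx(0.0)

    def test_mean_violation_is_arithmetic_mean_over_restraints(self):
        ens = Ensemble([pair_structure(6.2)])
        rset = RestraintSet([pair_restraint(6.0), pair_restraint(6.2)])
        assert mean_ensemble_violation(ens, rset) == pytest.approx(0.1)

    def test_mean_violation_grows_with_perturbation(self, toy, true_restraints):
        means = []
        for sigma in (0.2, 1.0):
            ens, _ = make_decoy_ensemble(
                toy, DecoySpec(sigma_levels=(sigma,), members_per_level=8, seed=21)
            )
            means.append(
                np.mean(
                    [structure_mean_violation(m, true_restraints) for m in ens]
                )
            )
        assert means[1] > means[0]

    def test_padded_set_never_violates_more(self, toy, true_restraints):
        ens, _ = make_decoy_ensemble(
            toy, DecoySpec(sigma_levels=(1.5,), members_per_level=5, seed=3)
        )
        v_raw = mean_ensemble_violation(ens, true_restraints)
        v_pad = mean_ensemble_violation(ens, pad_restraints(true_restraints, 1.0))
        assert v_pad <= v_raw


class TestEnergies:
    def test_satisfied_restraints_have_zero_energy(self, toy, true_restraints):
        assert restraint_energy(toy, true_restraints) == pytest.approx(0.0)

    def test_outer_wall_step_plus_ramp(self):
        s = pair_structure(7.0)
        rset = RestraintSet([pair_restraint(6.0)])
        pot = TwoWellPotential(outer_step=1.0)
        assert restraint_energy(s, rset, pot) == pytest.approx(2.0)

    def test_inner_step_below_lower_edge(self):
        s = pair_structure(1.0)
        rset = RestraintSet([pair_restraint(6.0)])
        pot = TwoWellPotential(lower_edge=1.8, outer_step=1.0, inner_step=0.7)
        assert restraint_energy(s, rset, pot) == pytest.approx(0.7)

    def test_energy_nondecreasing_beyond_bound(self):
        pot = TwoWellPotential(outer_step=1.3)
        rs = np.linspace(6.0, 12.0, 200)
        es = pot.energy(rs, np.full_like(rs, 6.0))
        assert np.all(np.diff(es) >= -1e-12)

    def test_zero_energy_iff_zero_violation(self):
        rset = RestraintSet([pair_restraint(6.0)])
        pot = TwoWellPotential()
        for r in (2.0, 5.0, 6.0):
            s = pair_structure(r)
            assert (restraint_energy(s, rset, pot) == 0.0) == (
                structure_violation(s, rset[0]) == 0.0
            )

    def test_tether_zero_at_reference(self, toy, core_selector):
        tether = HarmonicTether.from_structure(toy, core_selector, 0.4)
        assert tether_energy(toy, tether) == pytest.approx(0.0)

    def test_tether_spring_constant_at_unit_displacement(self):
        s = pair_structure(4.0)
        tether = HarmonicTether([("A", 1, "CA")], np.zeros((1, 3)), 0.4)
        displaced = s.with_coords(s.coords + np.array([[1.0, 0, 0], [0, 0, 0]]))
        assert tether_energy(displaced, tether) == pytest.approx(0.4)
        doubled = s.with_coords(s.coords + np.array([[2.0, 0, 0], [0, 0, 0]]))
        assert tether_energy(doubled, tether) == pytest.approx(1.6)
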