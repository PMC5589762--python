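"""Interface contacts, SASA and buried-surface analysis."""

import numpy as np
import pytest

from czbkit import (
    AtomRecord,
    AtomSelector,
    ContractError,
    DecoySpec,
    Ensemble,
    RadiusError,
    Structure,
    average_contacts,
    buried_sasa,
    buried_sasa_ensemble,
    compute_sasa,
    count_contacts,
    export_heatmap,
    make_decoy_ensemble,
)
from czbkit.geometry import rotation_about_axis

GROUP_A = AtomSelector(chains=("A",))
GROUP_B = AtomSelector(chains=("B",))


def two_atoms(d, elem=("C", "C")):
    return Structure(
        [
            AtomRecord("A", 1, "GLY", "CA", elem[0], (0.0, 0.0, 0.0)),
            AtomRecord("B", 1, "GLY", "CA", elem[1], (float(d), 0.0, 0.0)),
        ]
    )


class TestContacts:
    @pytest.mark.parametrize("d, expected", [(5.99, 1), (6.0, 1), (6.01, 0)])
    def test_cutoff_is_inclusive_at_six_angstrom(self, d, expected):
        cc = count_contacts(two_atoms(d), GROUP_A, GROUP_B)
        assert cc.total == expected

    def test_hydrogens_never_count(self):
        s = two_atoms(3.0, elem=("C", "H"))
        assert count_contacts(s, GROUP_A, GROUP_B).total == 0

    def test_overlapping_groups_rejected(self, toy):
        with pytest.raises(ContractError):
            count_contacts(toy, AtomSelector(chains=("A",)), AtomSelector())

    def test_counts_match_brute_force_on_random_toys(self):
        """Per-residue counts equal an explicit all-pairs O(n²) oracle."""
        rng = np.random.default_rng(0)
        for trial in range(20):
            atoms = []
            for i in range(40):
                chain = "A" if i < 20 else "B"
                atoms.append(
                    AtomRecord(
                        chain, i // 4 + 1, "GLY", f"X{i}", "C",
                        tuple(rng.uniform(0, 15, 3)),
                    )
                )
            s = Structure(atoms)
            cc = count_contacts(s, GROUP_A, GROUP_B)
            # oracle
            total = 0
            per_a, per_b = {}, {}
            for ai in s.atoms:
                if ai.chain_id != "A":
                    continue
                for aj in s.atoms:
                    if aj.chain_id != "B":
                        continue
                    d = np.linalg.norm(np.array(ai.coord) - np.array(aj.coord))
                    if d <= 6.0:
                        total += 1
                        per_a[(ai.chain_id, ai.res_seq)] = per_a.get((ai.chain_id, ai.res_seq), 0) + 1
                        per_b[(aj.chain_id, aj.res_seq)] = per_b.get((aj.chain_id, aj.res_seq), 0) + 1
            assert cc.total == total
            assert cc.per_residue_a == per_a
            assert cc.per_residue_b == per_b

    def test_side_sums_equal_total(self, toy, core_selector, chaperone_selector):
        cc = count_contacts(toy, core_selector, chaperone_selector)
        assert sum(cc.per_residue_a.values()) == cc.total
        assert sum(cc.per_residue_b.values()) == cc.total

    def test_invariant_under_rigid_motion(self, toy, core_selector, chaperone_selector):
        rot = rotation_about_axis([1.0, 1.0, 0.0], 33.0)
        moved = toy.with_coords(toy.coords @ rot.T + np.array([3.0, -5.0, 2.0]))
        a = count_contacts(toy, core_selector, chaperone_selector)
        b = count_contacts(moved, core_selector, chaperone_selector)
        assert a.total == b.total
        assert a.per_residue_a == b.per_residue_a


class TestAverageContacts:
    def test_single_member_equals_count_contacts(self, toy, core_selector, chaperone_selector):
        prof = average_contacts(Ensemble([toy]), core_selector, chaperone_selector)
        cc = count_contacts(toy, core_selector, chaperone_selector)
        merged = {**cc.per_residue_a, **cc.per_residue_b}
        assert prof.per_residue == pytest.approx(merged)
        assert prof.totals == [cc.total]

    def test_mean_of_two_members(self):
        s1, s2 = two_atoms(5.0), two_atoms(7.0)
        prof = average_contacts(Ensemble([s1, s2]), GROUP_A, GROUP_B)
        assert prof.per_residue[("A", 1)] == pytest.approx(0.5)
        assert prof.mean_total == pytest.approx(0.5)

    def test_invariant_under_member_reordering(self, toy, core_selector, chaperone_selector):
        ens, _ = make_decoy_ensemble(
            toy, DecoySpec(sigma_levels=(0.6,), members_per_level=4, seed=9)
        )
        fwd = average_contacts(ens, core_selector, chaperone_selector)
        rev = average_contacts(
            Ensemble(list(reversed(ens.members))), core_selector, chaperone_selector
        )
        assert fwd.per_residue == pytest.approx(rev.per_residue)


class TestSasa:
    def test_single_sphere_analytic(self):
        s = Structure([AtomRecord("A", 1, "GLY", "CA", "C", (0, 0, 0))])
        res = compute_sasa(s)
        exact = 4 * np.pi * (1.7 + 1.4) ** 2
        assert res.total == pytest.approx(exact, rel=0.01)

    def test_far_atoms_additive(self):
        s = two_atoms(50.0)
        exact = 2 * 4 * np.pi * (1.7 + 1.4) ** 2
        assert compute_sasa(s).total == pytest.approx(exact, rel=1e-6)

    def test_fused_spheres_match_closed_form(self):
        """Two identical spheres at d < 2R lose spherical caps of height
        h = R − d/2 each; closed form 2·(4πR² − 2πRh)."""
        for d in (1.5, 2.5, 4.0):
            s = two_atoms(d)
            r_ext = 1.7 + 1.4
            h = r_ext - d / 2
            exact = 2 * (4 * np.pi * r_ext**2 - 2 * np.pi * r_ext * h)
            assert compute_sasa(s).total == pytest.approx(exact, rel=0.01)

    def test_missing_radius_names_element(self):
        s = Structure([AtomRecord("A", 1, "HEM", "FE", "FE", (0, 0, 0))])
        with pytest.raises(RadiusError, match="FE"):
            compute_sasa(s)

    def test_per_chain_totals_sum(self, toy):
        res = compute_sasa(toy, points=240)
        assert sum(res.per_chain.values()) == pytest.approx(res.total)


class TestBuriedSasa:
    def test_separated_chains_bury_nothing(self):
        s = two_atoms(50.0)
        assert buried_sasa(s, (("A",), ("B",))) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_under_partition_swap(self, toy):
        a = buried_sasa(toy, (("A", "B"), ("C",)), points=240)
        b = buried_sasa(toy, (("C",), ("A", "B")), points=240)
        assert a == pytest.approx(b, abs=1e-9)

    def test_docked_toy_matches_monte_carlo_oracle(self, toy):
        """Independent oracle: random-direction sphere sampling."""
        got = buried_sasa(toy, (("A", "B"), ("C",)))

        def mc_sasa(structure, n_pts=3000, seed=0):
            rng = np.random.default_rng(seed)
            heavy = [i for i, a in enumerate(structure.atoms) if a.is_heavy]
            coords = structure.coords[heavy]
            radii = np.array(
                [{"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}[structure.atoms[i].element] for i in heavy]
            ) + 1.4
            total = 0.0
            for n, i in enumerate(heavy):
                v = rng.normal(size=(n_pts, 3))
                v /= np.linalg.norm(v, axis=1, keepdims=True)
                pts = coords[n] + radii[n] * v
                d = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=2)
                d[:, n] = np.inf
                acc = np.all(d >= radii[None, :], axis=1)
                total += 4 * np.pi * radii[n] ** 2 * acc.mean()
            return total

        oracle = (
            mc_sasa(toy.drop_chains(["C"]))
            + mc_sasa(toy.drop_chains(["A", "B"]))
            - mc_sasa(toy)
        )
        assert got == pytest.approx(oracle, rel=0.03)

    def test_overlap_increases_monotonically_on_approach(self):
        values = []
        for d in (8.0, 6.0, 4.5, 3.0):
            values.append(buried_sasa(two_atoms(d), (("A",), ("B",))))
        assert all(b > a - 1e-9 for a, b in zip(values, values[1:]))

    def test_incomplete_partition_rejected(self, toy):
        with pytest.raises(ContractError):
            buried_sasa(toy, (("A",), ("C",)))

    def test_ensemble_statistics(self, toy):
        ens, _ = make_decoy_ensemble(
            toy, DecoySpec(sigma_levels=(0.5,), members_per_level=3, seed=2)
        )
        mean, sd, values = buried_sasa_ensemble(
            ens, (("A", "B"), ("C",)), points=240
        )
        assert mean == pytest.approx(values.mean())
        assert sd == pytest.approx(values.std(ddof=1))


class TestHeatmapExport:
    def test_bfactors_carry_profile_values(self, toy, core_selector, chaperone_selector, tmp_path):
        prof = average_contacts(Ensemble([toy]), core_selector, chaperone_selector)
        pdb_path, tsv_path = export_heatmap(toy, prof, tmp_path / "heat.pdb")
        from czbkit import read_structure_models

        back = read_structure_models(pdb_path).members[0]
        for atom in back.atoms:
            expected = prof.per_residue.get((atom.chain_id, atom.res_seq), 0.0)
            assert atom.bfactor == pytest.approx(expected, abs=5e-3)

    def test_tsv_covers_group_residues(self, toy, core_selector, chaperone_selector, tmp_path):
        import pandas as pd

        prof = average_contacts(Ensemble([toy]), core_selector, chaperone_selector)
        _, tsv_path = export_heatmap(toy, prof, tmp_path / "heat.pdb")
        df = pd.read_csv(tsv_path, sep="\t")
        assert len(df) == len(toy.residues())
        assert list(df.columns) == ["chain", "resseq", "resname", "avg_contacts"]

    def test_empty_profile_writes_zero_bfactors(self, toy, tmp_path):
        from czbkit import InterfaceProfile, read_structure_models

        prof = InterfaceProfile({}, [0])
        pdb_path, _ = export_heatmap(toy, prof, tmp_path / "zero.pdb")
        back = read_structure_models(pdb_path).members[0]
        assert all(a.bfactor == 0.0 for a in back.atoms)
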