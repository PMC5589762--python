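"""Monte Carlo sampler: energies, acceptance rules, replica exchange."""

import numpy as np
import pytest

from czbkit import (
    AtomRecord,
    AtomSelector,
    ConfigError,
    ContractError,
    EnergyModel,
    HarmonicTether,
    ReplicaState,
    SamplerConfig,
    Structure,
    attempt_swap,
    metropolis_accept,
    run_sampling,
    structure_mean_violation,
    swap_probability,
    total_energy,
)
from czbkit.sampler import DEFAULT_TEMPERATURES, EnergyDecomposition
from czbkit.synthgen import DecoySpec, make_decoy_ensemble


def single_atom(chain="X"):
    return Structure([AtomRecord(chain, 1, "ALA", "CA", "C", (0.0, 0.0, 0.0))])


class TestEnergyModel:
    def test_reference_toy_has_zero_energy(self, toy, true_restraints, core_selector):
        tether = HarmonicTether.from_structure(toy, core_selector, 0.4)
        model = EnergyModel(toy, true_restraints, tethers=[tether])
        e = total_energy(toy, model)
        assert e.restraint == pytest.approx(0.0)
        assert e.tether == pytest.approx(0.0)
        assert e.excluded_volume == pytest.approx(0.0)

    def test_soft_sphere_overlap_of_two_carbons(self):
        s = Structure(
            [
                AtomRecord("A", 1, "GLY", "CA", "C", (0.0, 0.0, 0.0)),
                AtomRecord("B", 1, "GLY", "CA", "C", (2.0, 0.0, 0.0)),
            ]
        )
        e = total_energy(s, EnergyModel(s))
        assert e.excluded_volume == pytest.approx((3.4 - 2.0) ** 2)

    def test_decomposition_sums_to_total(self, toy, true_restraints, core_selector):
        tether = HarmonicTether.from_structure(toy, core_selector, 0.4)
        model = EnergyModel(toy, true_restraints, tethers=[tether])
        rng = np.random.default_rng(0)
        perturbed = toy.with_coords(toy.coords + rng.normal(0, 0.4, toy.coords.shape))
        e = model.decompose(perturbed.coords)
        assert e.total == pytest.approx(e.restraint + e.tether + e.excluded_volume)

    def test_delta_matches_full_recomputation(self, toy, true_restraints):
        model = EnergyModel(toy, true_restraints)
        rng = np.random.default_rng(7)
        old = toy.coords
        moved = rng.choice(len(old), size=10, replace=False)
        new = old.copy()
        new[moved] += rng.normal(0, 0.5, (10, 3))
        d = model.delta(old, new, moved)
        full = model.decompose(new).total - model.decompose(old).total
        assert d.total == pytest.approx(full, abs=1e-8)


class TestMetropolis:
    def test_nonpositive_delta_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(-1.0, 0.5, rng) for _ in range(100))
        assert all(metropolis_accept(0.0, 0.5, rng) for _ in range(100))

    def test_acceptance_frequency_at_delta_equal_t(self):
        rng = np.random.default_rng(42)
        n = 100_000
        acc = sum(metropolis_accept(0.5, 0.5, rng) for _ in range(n))
        p = np.exp(-1.0)
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(acc - n * p) < 3 * sigma

    def test_cold_limit_rejects_positive_delta(self):
        rng = np.random.default_rng(0)
        assert not any(metropolis_accept(1.0, 1e-12, rng) for _ in range(50))


class TestSwap:
    def make_state(self, energy, t_index):
        return ReplicaState(
            coords=np.zeros((1, 3)),
            temperature=DEFAULT_TEMPERATURES[t_index],
            temperature_index=t_index,
            energy=EnergyDecomposition(restraint=energy),
            rng=np.random.default_rng(0),
        )

    def test_equal_energies_always_swap(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            si, sj = self.make_state(2.0, 0), self.make_state(2.0, 1)
            assert attempt_swap(si, sj, rng)

    def test_hot_replica_with_lower_energy_always_swaps(self):
        rng = np.random.default_rng(0)
        si, sj = self.make_state(5.0, 0), self.make_state(1.0, 1)
        assert swap_probability(5.0, 1.0, si.temperature, sj.temperature) == 1.0
        assert attempt_swap(si, sj, rng)
        assert si.temperature_index == 1 and sj.temperature_index == 0

    def test_non_adjacent_pair_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ContractError):
            attempt_swap(self.make_state(1.0, 0), self.make_state(1.0, 2), rng)

    def test_two_state_exchange_matches_boltzmann(self):
        """2-state system × 2 temperatures: occupancies follow exp(−E/T).

        The stationary distribution of the swap-augmented chain factorises
        into independent Boltzmann factors, so per-temperature occupancy of
        the excited state must match the analytic value within MC error.
        """
        e0, e1 = 0.0, 1.0
        temps = (0.5, 1.0)
        rng = np.random.default_rng(3)
        states = [0, 0]  # configuration per temperature slot
        counts = np.zeros((2, 2))
        n_steps = 40_000
        for step in range(n_steps):
            for t_idx in (0, 1):
                cur = states[t_idx]
                prop = 1 - cur
                delta = (e1 - e0) if prop == 1 else (e0 - e1)
                if metropolis_accept(delta, temps[t_idx], rng):
                    states[t_idx] = prop
            if step % 5 == 0:
                ei = e1 if states[0] else e0
                ej = e1 if states[1] else e0
                if rng.random() < swap_probability(ei, ej, temps[0], temps[1]):
                    states = [states[1], states[0]]
            counts[0, states[0]] += 1
            counts[1, states[1]] += 1
        for t_idx, t in enumerate(temps):
            z = 1.0 + np.exp(-(e1 - e0) / t)
            expected = np.exp(-(e1 - e0) / t) / z
            observed = counts[t_idx, 1] / n_steps
            assert observed == pytest.approx(expected, abs=0.02)


class TestRunSampling:
    def test_snapshot_bookkeeping(self, toy, true_restraints):
        cfg = SamplerConfig(
            temperatures=(0.48, 0.563, 0.658, 0.767),
            steps_per_replica=400,
            snapshot_interval=100,
            swap_interval=200,
            seed=5,
        )
        ens, log = run_sampling(toy, true_restraints, [], cfg)
        assert len(ens) == 4 * (400 // 100)
        assert set(ens.annotations) >= {
            "replica", "temperature", "step", "energy",
            "restraint_energy", "tether_energy", "excluded_volume",
        }

    def test_deterministic_under_seed(self, toy, true_restraints):
        cfg = SamplerConfig(
            temperatures=(0.48, 0.6),
            steps_per_replica=200,
            snapshot_interval=100,
            swap_interval=50,
            seed=9,
        )
        a, _ = run_sampling(toy, true_restraints, [], cfg)
        b, _ = run_sampling(toy, true_restraints, [], cfg)
        assert np.array_equal(a.coords_array(), b.coords_array())

    def test_snapshot_energies_audit_consistent(self, toy, true_restraints, core_selector):
        tether = HarmonicTether.from_structure(toy, core_selector, 0.4)
        cfg = SamplerConfig(
            temperatures=(0.48, 0.6),
            steps_per_replica=300,
            snapshot_interval=150,
            swap_interval=100,
            seed=2,
        )
        ens, _ = run_sampling(toy, true_restraints, [tether], cfg)
        model = EnergyModel(toy, true_restraints, tethers=[tether])
        for i, m in enumerate(ens.members):
            assert ens.annotations["energy"][i] == pytest.approx(
                model.decompose(m.coords).total, abs=1e-6
            )

    def test_zero_weight_move_set_rejected(self):
        with pytest.raises(ConfigError):
            SamplerConfig(move_weights={"pivot": 0.0, "jiggle": 0.0})

    def test_tethered_core_never_drifts(self, toy, true_restraints, core_selector):
        tether = HarmonicTether.from_structure(toy, core_selector, 0.4)
        cfg = SamplerConfig(
            temperatures=(0.48, 0.767),
            steps_per_replica=500,
            snapshot_interval=250,
            swap_interval=100,
            seed=4,
        )
        ens, _ = run_sampling(toy, true_restraints, [tether], cfg)
        idx = core_selector.indices(toy)
        for m in ens.members:
            disp = np.linalg.norm(m.coords[idx] - toy.coords[idx], axis=1).max()
            assert disp < 2.0

    def test_free_tethered_particle_variance(self):
        """Equilibrium variance of E = k·x² is T/(2k) per axis."""
        s = single_atom()
        tether = HarmonicTether([("X", 1, "CA")], np.zeros((1, 3)), 0.4)
        t = 0.5
        cfg = SamplerConfig(
            temperatures=(t,),
            steps_per_replica=150_000,
            snapshot_interval=50,
            swap_interval=10**9,
            move_weights={"jiggle": 1.0},
            max_translation=1.2,
            mobile_chains=("X",),
            seed=8,
        )
        ens, _ = run_sampling(s, None, [tether], cfg, ev_enabled=False)
        samples = ens.coords_array()[:, 0, :]
        var = samples.var()
        assert var == pytest.approx(t / (2 * 0.4), rel=0.08)

    def test_sampling_reduces_violations_from_randomized_start(
        self, toy, true_restraints, core_selector
    ):
        tether = HarmonicTether.from_structure(toy, core_selector, 0.4)
        for seed in (1, 2):
            dec, _ = make_decoy_ensemble(
                toy, DecoySpec(sigma_levels=(1.5,), members_per_level=1, seed=seed)
            )
            start = dec.members[0]
            v0 = structure_mean_violation(start, true_restraints)
            cfg = SamplerConfig(
                temperatures=(0.48, 0.563, 0.658),
                steps_per_replica=900,
                snapshot_interval=300,
                swap_interval=150,
                seed=seed,
            )
            ens, _ = run_sampling(start, true_restraints, [tether], cfg)
            cold = ens.subset(
                [i for i, r in enumerate(ens.annotations["replica"]) if r == 0]
            )
            v1 = np.mean(
                [structure_mean_violation(m, true_restraints) for m in cold.members]
            )
            assert v1 < v0
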