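"""The two-state generator: geometry, mixtures, energies, pseudo-MD."""

import numpy as np
import pytest

from conformens.core import Ensemble
from conformens.clustering import cluster_ensemble
from conformens.descriptors import ReferenceSet, aperture_angle, classify_by_reference
from conformens.filtering import mean_energy_filter
from conformens.geometry import kabsch_superpose, pairwise_rmsd_matrix
from conformens.synthetic import (
    EnergyModelSpec,
    PseudoMDSpec,
    SyntheticSpec,
    assign_energies,
    make_endpoints,
    pseudo_md_lambda_trace,
    sample_pseudo_md,
    sample_two_state_ensemble,
)


class TestMakeEndpoints:
    def test_aperture_matches_nominal_theta(self, tiny_spec):
        open_model, closed_model, regions = make_endpoints(tiny_spec)
        arm_a, hinge, arm_b = regions
        assert aperture_angle(open_model, arm_a, hinge, arm_b) == pytest.approx(
            tiny_spec.theta_open, abs=1.0
        )
        assert aperture_angle(closed_model, arm_a, hinge, arm_b) == pytest.approx(
            tiny_spec.theta_closed, abs=1.0
        )

    def test_atom_count_and_residue_numbering(self, tiny_spec):
        open_model, _, regions = make_endpoints(tiny_spec)
        assert open_model.n_atoms == tiny_spec.n_res
        assert regions[0].first_residue == 1
        assert regions[-1].last_residue == tiny_spec.n_res

    def test_endpoint_rmsd_monotone_in_angle_difference(self):
        rmsds = []
        for delta in (20.0, 40.0, 60.0):
            spec = SyntheticSpec(
                n_res=24, arm_len=10, theta_open=60.0 + delta, theta_closed=60.0
            )
            open_model, closed_model, _ = make_endpoints(spec)
            rmsds.append(
                kabsch_superpose(open_model.coords, closed_model.coords).rmsd
            )
        assert rmsds[0] < rmsds[1] < rmsds[2]

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(n_res=20, arm_len=10)  # no room for a hinge
        with pytest.raises(ValueError):
            SyntheticSpec(theta_open=50.0, theta_closed=60.0)


class TestSampleTwoStateEnsemble:
    def test_pure_open_noise_free_reproduces_endpoint(self, tiny_spec):
        spec = SyntheticSpec(
            **{
                **tiny_spec.__dict__,
                "mixture_weights": (1.0, 0.0),
                "state_sd": 0.0,
                "coord_noise_sd": 0.0,
                "n_models": 5,
            }
        )
        ensemble, truth = sample_two_state_ensemble(spec)
        open_model, _, _ = make_endpoints(spec)
        for model in ensemble:
            np.testing.assert_allclose(model.coords, open_model.coords, atol=1e-12)
        assert truth.state_labels == ["open"] * 5

    def test_model_count_and_determinism(self, tiny_spec):
        ens1, t1 = sample_two_state_ensemble(tiny_spec)
        ens2, _ = sample_two_state_ensemble(tiny_spec)
        assert ens1.n_models == tiny_spec.n_models
        np.testing.assert_array_equal(ens1.coords(), ens2.coords())
        other = SyntheticSpec(**{**tiny_spec.__dict__, "seed": tiny_spec.seed + 1})
        ens3, _ = sample_two_state_ensemble(other)
        assert not np.array_equal(ens1.coords(), ens3.coords())
        assert len(t1.lambda_values) == tiny_spec.n_models


class TestAssignEnergies:
    def test_well_minima_and_barrier(self):
        emodel = EnergyModelSpec(
            well_depth=700.0, barrier_height=60.0, asymmetry=0.0, energy_noise_sd=0.0
        )
        np.testing.assert_allclose(emodel.energy([0.0, 1.0]), [-700.0, -700.0])
        assert emodel.energy(0.5) == pytest.approx(-700.0 + 60.0)

    def test_noisy_table_matches_formula_oracle(self, tiny_spec):
        _, truth = sample_two_state_ensemble(tiny_spec)
        emodel = EnergyModelSpec()
        table = assign_energies(truth, emodel, seed=99)
        rng = np.random.default_rng(99)
        lam = truth.lambda_values
        expected = (
            -emodel.well_depth
            + 16.0 * emodel.barrier_height * lam**2 * (1 - lam) ** 2
            + emodel.asymmetry * lam
            + rng.normal(scale=emodel.energy_noise_sd, size=lam.shape)
        )
        np.testing.assert_allclose(
            table.for_models(truth.model_ids), expected, atol=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_filter_removes_barrier_region_models(self, tiny_spec, seed):
        """Among conformers between the wells, the filter discards the
        barrier region: kept models sit nearer the wells than removed ones.

        Conformers beyond the wells (λ outside [0, 1]) are excluded from the
        comparison: the quartic also rises steeply there, so over-extended
        models are removed too, but their |λ - 1/2| is large and would
        conflate the two effects.
        """
        spec = SyntheticSpec(
            **{**tiny_spec.__dict__, "state_sd": 0.2, "n_models": 500, "seed": 41 + seed}
        )
        _, truth = sample_two_state_ensemble(spec)
        emodel = EnergyModelSpec(barrier_height=60.0, energy_noise_sd=10.0)
        assert emodel.barrier_height >= 5 * emodel.energy_noise_sd
        table = assign_energies(truth, emodel, seed=42 + seed)
        result = mean_energy_filter(table, truth.model_ids)
        lam = dict(zip(truth.model_ids, truth.lambda_values))
        kept_dist = np.mean(
            [abs(lam[m] - 0.5) for m in result.kept_ids if 0 <= lam[m] <= 1]
        )
        removed_dist = np.mean(
            [abs(lam[m] - 0.5) for m in result.removed_ids if 0 <= lam[m] <= 1]
        )
        assert kept_dist > removed_dist


class TestPseudoMD:
    def test_deterministic_relaxation_without_noise(self):
        md = PseudoMDSpec(n_frames=200, kappa=0.8, sigma=0.0, mu=0.5, lambda0=1.1)
        lam = pseudo_md_lambda_trace(md)
        gaps = np.abs(lam - 0.5)
        assert (np.diff(gaps) <= 1e-12).all()
        assert lam[-1] == pytest.approx(0.5, abs=1e-3)

    def test_stationary_variance_matches_discrete_ou(self):
        md = PseudoMDSpec(
            n_frames=100_000, dt=0.05, kappa=1.0, mu=0.5, sigma=0.05, seed=12
        )
        lam = pseudo_md_lambda_trace(md)
        burn = lam[1000:]
        expected = md.sigma**2 * md.dt / (2 * md.kappa * md.dt - (md.kappa * md.dt) ** 2)
        assert burn.var() == pytest.approx(expected, rel=0.10)
        # walk stayed inside the reflection bounds for this gentle setting
        assert burn.min() > -0.2 and burn.max() < 1.2

    def test_same_seed_identical_trace_and_frames(self, tiny_spec):
        md = PseudoMDSpec(n_frames=50, seed=7)
        ens1, lam1 = sample_pseudo_md(tiny_spec, md)
        ens2, lam2 = sample_pseudo_md(tiny_spec, md)
        np.testing.assert_array_equal(lam1, lam2)
        np.testing.assert_array_equal(ens1.coords(), ens2.coords())

    def test_reflection_keeps_walk_in_bounds(self):
        md = PseudoMDSpec(n_frames=5000, dt=0.1, kappa=0.2, sigma=1.5, seed=3)
        lam = pseudo_md_lambda_trace(md)
        assert lam.min() >= -0.2 - 1e-12
        assert lam.max() <= 1.2 + 1e-12


def test_end_to_end_population_and_k_recovery(tiny_spec):
    """Filter → elbow → cut → classify on the generator's study conditions.

    k = 2 must be found for every seed; the mean recovered open fraction
    over the seed set must match the generating mixture weight.
    """
    open_fracs = []
    for seed in range(10):
        spec = SyntheticSpec(n_models=1000, seed=seed)
        ensemble, truth = sample_two_state_ensemble(spec)
        table = assign_energies(truth, EnergyModelSpec(), seed=seed + 1000)
        kept_ids = mean_energy_filter(table, ensemble.model_ids).kept_ids
        kept = ensemble.subset_models(kept_ids)
        matrix = pairwise_rmsd_matrix(kept)
        result = cluster_ensemble(matrix, table, k_max=8)
        assert result.k == 2
        open_model, closed_model, _ = make_endpoints(spec)
        refs = ReferenceSet([("open", open_model), ("closed", closed_model)])
        _, fractions = classify_by_reference(kept, refs)
        open_fracs.append(fractions.get("open-like", 0.0))
    assert np.mean(open_fracs) == pytest.approx(0.30, abs=0.03)
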