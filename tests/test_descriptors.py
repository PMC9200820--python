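"""Hinge descriptors, reference classification, ensemble spread."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conformens.core import Ensemble, RegionSpec
from conformens.descriptors import (
    NearestReferenceClassifier,
    ReferenceSet,
    aperture_angle,
    classify_by_reference,
    descriptor_series,
    ensemble_spread,
    interdomain_distance,
)
from conformens.geometry import kabsch_superpose
from conformens.synthetic import (
    SyntheticSpec,
    make_endpoints,
    sample_two_state_ensemble,
)

from helpers import ca_model


def _three_point_model(points):
    return ca_model(np.asarray(points, dtype=float), "toy")


R1 = RegionSpec("a", "A", 1, 1)
R2 = RegionSpec("h", "A", 2, 2)
R3 = RegionSpec("b", "A", 3, 3)


class TestApertureAngle:
    def test_right_angle(self):
        m = _three_point_model([[1, 0, 0], [0, 0, 0], [0, 1, 0]])
        assert aperture_angle(m, R1, R2, R3) == pytest.approx(90.0)

    def test_collinear_is_straight(self):
        m = _three_point_model([[-2, 0, 0], [0, 0, 0], [3, 0, 0]])
        assert aperture_angle(m, R1, R2, R3) == pytest.approx(180.0)

    def test_three_four_five_triangle(self):
        # vertices (0,0) (4,0) (0,3); right angle at origin
        at_right = _three_point_model([[4, 0, 0], [0, 0, 0], [0, 3, 0]])
        assert aperture_angle(at_right, R1, R2, R3) == pytest.approx(90.0)
        # hinge at the (4,0) vertex: angle = arccos(4/5)
        at_acute = _three_point_model([[0, 0, 0], [4, 0, 0], [0, 3, 0]])
        assert aperture_angle(at_acute, R1, R2, R3) == pytest.approx(
            np.degrees(np.arccos(0.8))
        )

    def test_coincident_centres_rejected(self):
        m = _three_point_model([[0, 0, 0], [0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError, match="undefined"):
            aperture_angle(m, R1, R2, R3)

    def test_invariant_under_rigid_motion(self, endpoints):
        open_model, _, regions = endpoints
        arm_a, hinge, arm_b = regions
        base = aperture_angle(open_model, arm_a, hinge, arm_b)
        rot = Rotation.from_euler("zyx", [20, 50, 80], degrees=True).as_matrix()
        moved = open_model.with_coords(open_model.coords @ rot.T + 7.0)
        assert aperture_angle(moved, arm_a, hinge, arm_b) == pytest.approx(
            base, abs=1e-9
        )


class TestInterdomainDistance:
    def test_single_atom_regions(self):
        m = _three_point_model([[0, 0, 0], [1, 1, 1], [3, 4, 0]])
        assert interdomain_distance(m, R1, R3) == pytest.approx(5.0)

    def test_identical_regions_give_zero(self):
        m = _three_point_model([[0, 0, 0], [1, 1, 1], [3, 4, 0]])
        assert interdomain_distance(m, R1, R1) == 0.0

    def test_monotone_in_morph_coordinate(self, tiny_spec):
        from conformens.synthetic import morph_coords

        open_model, closed_model, regions = make_endpoints(tiny_spec)
        arm_a, _, arm_b = regions
        lam = np.linspace(0.0, 1.0, 9)
        coords = morph_coords(open_model, closed_model, lam)
        distances = [
            interdomain_distance(open_model.with_coords(c), arm_a, arm_b)
            for c in coords
        ]
        assert (np.diff(distances) < 0).all()  # closing reduces the distance

    def test_empty_region_rejected(self):
        m = _three_point_model([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError, match="empty"):
            interdomain_distance(m, RegionSpec("x", "A", 9, 9), R1)


def test_descriptor_series_shapes(tiny_spec):
    spec = SyntheticSpec(**{**tiny_spec.__dict__, "n_models": 10})
    ensemble, _ = sample_two_state_ensemble(spec)
    _, _, regions = make_endpoints(spec)
    series = descriptor_series(ensemble, *regions)
    assert len(series.model_ids) == 10
    assert ((series.angle >= 0) & (series.angle <= 180)).all()
    assert (series.distance >= 0).all()
    df = series.to_dataframe(["x"] * 10)
    assert list(df.columns) == ["model_id", "angle_deg", "distance_A", "label"]


class TestClassifyByReference:
    def test_model_identical_to_reference(self, endpoints):
        open_model, closed_model, _ = endpoints
        refs = ReferenceSet([("open", open_model), ("closed", closed_model)])
        ens = Ensemble([open_model.with_coords(open_model.coords, "q")])
        labels, fractions = classify_by_reference(ens, refs)
        assert labels == ["open-like"]
        assert fractions == {"open-like": 1.0}

    def test_exact_tie_goes_to_first_reference(self, endpoints):
        # two references with identical coordinates: every RMSD ties exactly
        open_model, _, _ = endpoints
        twin = open_model.with_coords(open_model.coords, "twin")
        refs = ReferenceSet([("first", open_model), ("second", twin)])
        query = open_model.with_coords(open_model.coords + 0.5, "q")
        labels, _ = classify_by_reference(Ensemble([query]), refs)
        assert labels == ["first-like"]

    def test_intermediate_margin_creates_third_class(self, endpoints):
        open_model, closed_model, _ = endpoints
        midpoint = open_model.with_coords(
            (open_model.coords + closed_model.coords) / 2.0, "mid"
        )
        refs = ReferenceSet(
            [("open", open_model), ("closed", closed_model)],
            intermediate_margin=1.0,
        )
        labels, fractions = classify_by_reference(Ensemble([midpoint]), refs)
        assert labels == ["intermediate-like"]
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_low_noise_mixture_recovers_generating_states(self, tiny_spec):
        spec = SyntheticSpec(**{**tiny_spec.__dict__, "n_models": 400, "seed": 13})
        ensemble, truth = sample_two_state_ensemble(spec)
        open_model, closed_model, _ = make_endpoints(spec)
        refs = ReferenceSet([("open", open_model), ("closed", closed_model)])
        labels, fractions = classify_by_reference(ensemble, refs)
        # noise << separation: every model classified as its generating state
        assert labels == [f"{s}-like" for s in truth.state_labels]
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_open_fraction_monotone_in_mixture_weight(self, tiny_spec):
        recovered = []
        for w_open in (0.1, 0.3, 0.5, 0.7, 0.9):
            spec = SyntheticSpec(
                **{
                    **tiny_spec.__dict__,
                    "n_models": 300,
                    "seed": 29,
                    "mixture_weights": (w_open, 1.0 - w_open),
                }
            )
            ensemble, _ = sample_two_state_ensemble(spec)
            open_model, closed_model, _ = make_endpoints(spec)
            refs = ReferenceSet([("open", open_model), ("closed", closed_model)])
            _, fractions = classify_by_reference(ensemble, refs)
            recovered.append(fractions.get("open-like", 0.0))
        assert (np.diff(recovered) > 0).all()

    def test_topology_mismatch_rejected(self, endpoints):
        open_model, closed_model, _ = endpoints
        truncated = open_model.subset(np.arange(open_model.n_atoms) < 10)
        refs = ReferenceSet([("open", truncated)])
        with pytest.raises(ValueError, match="topology"):
            classify_by_reference(Ensemble([open_model]), refs)


class TestNearestReferenceClassifierEstimator:
    def test_sklearn_protocol(self, endpoints):
        from sklearn.base import clone

        open_model, closed_model, _ = endpoints
        clf = NearestReferenceClassifier(intermediate_margin=0.5)
        assert clone(clf).get_params() == {"intermediate_margin": 0.5}
        X = np.stack([open_model.coords, closed_model.coords])
        clf.fit(X, ["open", "closed"])
        assert list(clf.classes_) == ["open-like", "closed-like", "intermediate-like"]
        pred = clf.predict(open_model.coords[None])
        assert pred[0] == "open-like"


class TestEnsembleSpread:
    def test_single_model_is_zero(self, endpoints):
        open_model, _, _ = endpoints
        assert ensemble_spread(Ensemble([open_model])) == 0.0

    def test_two_models_equals_pairwise_rmsd(self, endpoints):
        open_model, closed_model, _ = endpoints
        expected = kabsch_superpose(open_model.coords, closed_model.coords).rmsd
        spread = ensemble_spread(Ensemble([open_model, closed_model]))
        assert spread == pytest.approx(expected, abs=1e-9)

    def test_matches_exhaustive_pairwise_max(self, tiny_spec):
        spec = SyntheticSpec(**{**tiny_spec.__dict__, "n_models": 20, "seed": 77})
        ensemble, _ = sample_two_state_ensemble(spec)
        coords = ensemble.coords()
        brute = max(
            kabsch_superpose(coords[i], coords[j]).rmsd
            for i in range(20)
            for j in range(i + 1, 20)
        )
        assert ensemble_spread(ensemble) == pytest.approx(brute, abs=1e-9)

    def test_range_to_reference_variant(self, tiny_spec):
        spec = SyntheticSpec(**{**tiny_spec.__dict__, "n_models": 10, "seed": 5})
        ensemble, _ = sample_two_state_ensemble(spec)
        open_model, _, _ = make_endpoints(spec)
        from conformens.geometry import rmsd_to_reference

        d = rmsd_to_reference(ensemble.coords(), open_model.coords)
        got = ensemble_spread(
            ensemble, method="range_to_reference", reference=open_model
        )
        assert got == pytest.approx(d.max() - d.min(), abs=1e-9)
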