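"""Hinge-geometry descriptors and reference-based conformer classification.

Hinge-bending proteins (adenylate kinase being the canonical example) open
and close two domains about a hinge.  Two scalar descriptors capture the
state of each conformer: the *aperture angle* subtended at the hinge
region's centre of geometry by the two domain centres, and the Euclidean
*inter-domain distance* between the domain centres.  Centres of geometry
use the unweighted Cα atoms of each region.

Conformers are classified against labelled reference structures (e.g. the
open and closed X-ray forms) by minimised backbone RMSD: each model takes
the label of its nearest reference, suffixed "-like"; an optional margin
assigns "intermediate-like" when the two best references are nearly
equidistant.  The ensemble's overall spread is its diameter, the maximum
pairwise backbone RMSD (ΔRMSD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .core import Ensemble, RegionSpec, StructureModel
from .geometry import pairwise_rmsd_matrix, rmsd_to_reference

__all__ = [
    "DescriptorSeries",
    "ReferenceSet",
    "NearestReferenceClassifier",
    "aperture_angle",
    "interdomain_distance",
    "descriptor_series",
    "classify_by_reference",
    "ensemble_spread",
]

INTERMEDIATE_LABEL = "intermediate-like"


def _region_center(model: StructureModel, region: RegionSpec) -> np.ndarray:
    """Unweighted centre of geometry of the region's Cα atoms.

    Falls back to all atoms of the region for models without Cα records.
    """
    mask = region.mask(model)
    if not mask.any():
        raise ValueError(f"region {region.name!r} is empty in model {model.model_id!r}")
    ca = mask & (model.atom_names.astype(str) == "CA")
    use = ca if ca.any() else mask
    return model.coords[use].mean(axis=0)


def aperture_angle(
    model: StructureModel,
    arm_a: RegionSpec,
    hinge: RegionSpec,
    arm_b: RegionSpec,
) -> float:
    """Opening angle (degrees) at the hinge between two domain centres.

    The angle at the hinge region's centre of geometry subtended by the
    centres of the two arm regions, computed as the arccos of the clamped
    normalised dot product; 180° means fully extended/collinear.
    """
    c_a = _region_center(model, arm_a)
    c_h = _region_center(model, hinge)
    c_b = _region_center(model, arm_b)
    v_a = c_a - c_h
    v_b = c_b - c_h
    n_a = np.linalg.norm(v_a)
    n_b = np.linalg.norm(v_b)
    if n_a < 1e-9 or n_b < 1e-9:
        raise ValueError("aperture angle undefined: arm centre coincides with hinge")
    cos = np.clip(np.dot(v_a, v_b) / (n_a * n_b), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def interdomain_distance(
    model: StructureModel, region_a: RegionSpec, region_b: RegionSpec
) -> float:
    """Euclidean distance (Å) between two regions' centres of geometry."""
    return float(
        np.linalg.norm(_region_center(model, region_a) - _region_center(model, region_b))
    )


@dataclass
class DescriptorSeries:
    """Per-model aperture angle (deg) and inter-domain distance (Å)."""

    model_ids: list[str]
    angle: np.ndarray
    distance: np.ndarray

    def __post_init__(self) -> None:
        self.angle = np.asarray(self.angle, dtype=float)
        self.distance = np.asarray(self.distance, dtype=float)
        n = len(self.model_ids)
        if self.angle.shape != (n,) or self.distance.shape != (n,):
            raise ValueError("angle/distance length must match model_ids")
        if np.any((self.angle < 0) | (self.angle > 180)) or np.any(self.distance < 0):
            raise ValueError("angles must lie in [0, 180] deg, distances >= 0")

    def to_dataframe(self, labels: Sequence[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "model_id": self.model_ids,
                "angle_deg": self.angle,
                "distance_A": self.distance,
            }
        )
        if labels is not None:
            df["label"] = list(labels)
        return df


def descriptor_series(
    ensemble: Ensemble,
    arm_a: RegionSpec,
    hinge: RegionSpec,
    arm_b: RegionSpec,
) -> DescriptorSeries:
    """Aperture angle and arm_a-arm_b distance for every model."""
    angles = []
    distances = []
    for model in ensemble:
        angles.append(aperture_angle(model, arm_a, hinge, arm_b))
        distances.append(interdomain_distance(model, arm_a, arm_b))
    return DescriptorSeries(ensemble.model_ids, np.array(angles), np.array(distances))


@dataclass
class ReferenceSet:
    """Labelled reference conformers plus the intermediate-class margin (Å)."""

    references: list[tuple[str, StructureModel]]
    intermediate_margin: float = 0.0

    def __post_init__(self) -> None:
        if not self.references:
            raise ValueError("at least one reference required")
        labels = [lab for lab, _ in self.references]
        if len(set(labels)) != len(labels):
            raise ValueError("reference labels must be unique")
        if self.intermediate_margin < 0:
            raise ValueError("intermediate_margin must be >= 0")


class NearestReferenceClassifier(ClassifierMixin, BaseEstimator):
    """Label conformations by their nearest reference structure (RMSD).

    scikit-learn style classifier over coordinate arrays.  ``fit(X, y)``
    takes reference coordinates ``(n_refs, n_atoms, 3)`` and their labels;
    ``predict(X)`` computes the minimised RMSD of each conformation to every
    reference and returns the nearest label suffixed ``"-like"``.  When the
    two smallest RMSDs differ by less than ``intermediate_margin`` Å the
    conformation is called ``"intermediate-like"`` instead.  Exact ties with
    margin 0 go to the reference listed first.

    Attributes
    ----------
    classes_ : ndarray of str
        The "-like" labels this classifier can emit.
    reference_coords_ : ndarray
    reference_labels_ : list of str
    """

    def __init__(self, intermediate_margin: float = 0.0) -> None:
        self.intermediate_margin = intermediate_margin

    def fit(self, X, y):
        coords = np.asarray(X, dtype=float)
        labels = [str(lab) for lab in y]
        if coords.ndim != 3 or coords.shape[0] != len(labels):
            raise ValueError("X must be (n_refs, n_atoms, 3) matching y")
        if len(set(labels)) != len(labels):
            raise ValueError("reference labels must be unique")
        if self.intermediate_margin < 0:
            raise ValueError("intermediate_margin must be >= 0")
        self.reference_coords_ = coords
        self.reference_labels_ = labels
        classes = [f"{lab}-like" for lab in labels]
        if self.intermediate_margin > 0:
            classes.append(INTERMEDIATE_LABEL)
        self.classes_ = np.array(classes, dtype=object)
        return self

    def rmsd_to_references(self, X) -> np.ndarray:
        """RMSD of each conformation to each reference, shape (n, n_refs)."""
        coords = np.asarray(X, dtype=float)
        if coords.ndim != 3 or coords.shape[1:] != self.reference_coords_.shape[1:]:
            raise ValueError(
                f"topology mismatch: expected (*, {self.reference_coords_.shape[1]}, 3)"
            )
        return np.column_stack(
            [rmsd_to_reference(coords, ref) for ref in self.reference_coords_]
        )

    def predict(self, X) -> np.ndarray:
        d = self.rmsd_to_references(X)
        nearest = np.argmin(d, axis=1)  # argmin takes the first on exact ties
        labels = np.array(
            [f"{self.reference_labels_[j]}-like" for j in nearest], dtype=object
        )
        if self.intermediate_margin > 0 and d.shape[1] >= 2:
            part = np.partition(d, 1, axis=1)
            ambiguous = (part[:, 1] - part[:, 0]) < self.intermediate_margin
            labels[ambiguous] = INTERMEDIATE_LABEL
        return labels


def classify_by_reference(
    ensemble: Ensemble,
    refs: ReferenceSet,
    selection_keys: Sequence | None = None,
) -> tuple[list[str], dict[str, float]]:
    """Classify every model against labelled references; report populations.

    The comparison uses the ensemble's shared atoms (extract the backbone
    beforehand for backbone-RMSD classification); all references must match
    that topology.  Returns per-model labels (ensemble order) and the
    population fraction of every emitted class (fractions sum to 1).
    """
    for lab, ref in refs.references:
        if ref.atom_keys != ensemble.atom_keys:
            raise ValueError(
                f"reference {lab!r} topology does not match the ensemble"
            )
    clf = NearestReferenceClassifier(refs.intermediate_margin).fit(
        np.stack([ref.coords for _, ref in refs.references]),
        [lab for lab, _ in refs.references],
    )
    labels = clf.predict(ensemble.coords()).tolist()
    n = len(labels)
    fractions = {
        cls: labels.count(cls) / n for cls in clf.classes_ if labels.count(cls)
    }
    return labels, fractions


def ensemble_spread(
    ensemble: Ensemble,
    method: str = "max_pairwise",
    reference: StructureModel | None = None,
) -> float:
    """ΔRMSD: the conformational spread of an ensemble, in Å.

    ``method="max_pairwise"`` (default) returns the ensemble diameter — the
    maximum entry of the pairwise minimised-RMSD matrix (0 for a single
    model).  ``method="range_to_reference"`` instead returns the range
    (max - min) of per-model RMSDs to *reference*.
    """
    if method == "max_pairwise":
        if ensemble.n_models < 2:
            return 0.0
        return float(pairwise_rmsd_matrix(ensemble).values.max())
    if method == "range_to_reference":
        if reference is None:
            raise ValueError("range_to_reference requires a reference model")
        d = rmsd_to_reference(ensemble.coords(), reference.coords)
        return float(d.max() - d.min())
    raise ValueError(f"unknown method {method!r}")
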