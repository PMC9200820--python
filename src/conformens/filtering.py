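"""Energy-based decoy triage.

Decoy sets produced by restraint-guided structure prediction are rescored by
an external coarse-grained force field; models whose energy is strictly
above the arithmetic mean of the set are discarded before clustering.  The
mean-energy rule is intentionally literal: ties with the threshold are kept,
and the filter is applied once (re-applying it to the kept subset recomputes
a lower mean and would remove more models — that is a property of the rule,
not a bug, and it is not done here).

A Pearson energy-vs-RMSD correlation is provided as the diagnostic used to
judge whether an energy function discriminates near-native from non-native
decoys.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Ensemble, EnergyTable, StructureModel
from .geometry import rmsd_to_reference

__all__ = ["FilterResult", "mean_energy_filter", "energy_rmsd_correlation"]


@dataclass
class FilterResult:
    """Outcome of the mean-energy filter: a disjoint kept/removed partition."""

    threshold: float
    kept_ids: list[str]
    removed_ids: list[str]

    @property
    def n_kept(self) -> int:
        return len(self.kept_ids)

    @property
    def n_removed(self) -> int:
        return len(self.removed_ids)

    def to_dataframe(self, energies: EnergyTable) -> pd.DataFrame:
        ids = self.kept_ids + self.removed_ids
        order = {m: i for i, m in enumerate(self.kept_ids)}
        order.update(
            {m: len(self.kept_ids) + i for i, m in enumerate(self.removed_ids)}
        )
        ids = sorted(ids, key=order.get)
        return pd.DataFrame(
            {
                "model_id": ids,
                "energy_kcal_mol": [energies[m] for m in ids],
                "kept": [m in set(self.kept_ids) for m in ids],
            }
        )


def mean_energy_filter(
    energies: EnergyTable, model_ids: Sequence[str]
) -> FilterResult:
    """Partition models at the arithmetic mean of their energies.

    The threshold is the mean energy of exactly the listed models (the caller
    controls the averaging population).  Models with energy strictly greater
    than the threshold are removed; models at or below it — including exact
    ties — are kept.  Input order is preserved in both lists.
    """
    model_ids = list(model_ids)
    if not model_ids:
        raise ValueError("model_ids must be non-empty")
    values = energies.for_models(model_ids)
    threshold = float(values.mean())
    kept = [m for m, e in zip(model_ids, values) if e <= threshold]
    removed = [m for m, e in zip(model_ids, values) if e > threshold]
    return FilterResult(threshold, kept, removed)


def energy_rmsd_correlation(
    energies: EnergyTable,
    reference: StructureModel,
    ensemble: Ensemble,
) -> float:
    """Pearson correlation between model energies and RMSD to a reference.

    RMSD is the minimised (Kabsch) RMSD of each model to *reference* over the
    ensemble's shared atoms; callers wanting backbone-only correlation should
    extract the backbone first.  A positive correlation indicates that the
    energy function ranks near-reference models lower in energy.
    """
    if ensemble.n_models < 3:
        raise ValueError("correlation needs at least 3 models")
    if reference.atom_keys != ensemble.atom_keys:
        raise ValueError("reference topology does not match ensemble")
    e = energies.for_models(ensemble.model_ids)
    r = rmsd_to_reference(ensemble.coords(), reference.coords)
    if np.ptp(e) == 0 or np.ptp(r) == 0:
        raise ValueError("correlation undefined: zero variance in energy or RMSD")
    return float(stats.pearsonr(e, r).statistic)
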