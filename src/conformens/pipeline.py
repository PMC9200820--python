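"""End-to-end orchestration of the ensemble-analysis stages.

One :func:`run_pipeline` call executes, in order: input loading (files or
the synthetic generator) → atom selection → mean-energy filtering →
pairwise RMSD → elbow-selected hierarchical clustering → lowest-energy
centroids → per-cluster alignment, RMSF and Cartesian PCA → projection of
the cluster and of the reference (MD or pseudo-MD) ensemble onto PC1 with
density overlap → hinge descriptors → reference classification with
population fractions → ΔRMSD spread.  Every stage writes its CSV into the
output directory and the run ends with a machine-readable ``summary.json``.

Any stage failure raises :class:`PipelineError` naming the stage.  Given
the same configuration and seed the run is fully deterministic, down to the
bytes of the summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import clustering, descriptors, filtering, geometry, io, motions, synthetic
from .core import Ensemble, EnergyTable, RegionSpec, StructureModel

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the failing stage."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input mode must be active: file mode (``models_path`` plus
    ``energies_path``; optional reference structures, region file and MD
    ensemble) or synthetic mode (``synthetic=True``; specs optional, seeded
    from ``seed``).
    """

    # file mode
    models_path: str | None = None
    energies_path: str | None = None
    references_paths: dict[str, str] = field(default_factory=dict)
    regions_path: str | None = None
    md_path: str | None = None

    # synthetic mode
    synthetic: bool = False
    synthetic_spec: synthetic.SyntheticSpec | None = None
    energy_model: synthetic.EnergyModelSpec | None = None
    pseudo_md: synthetic.PseudoMDSpec | None = None

    # analysis parameters
    selection: str = "backbone"
    linkage: str = "average"
    k_max: int = 10
    flatness_floor: float = clustering.FLATNESS_FLOOR
    intermediate_margin: float = 0.0
    seed: int = 0
    out_dir: str = "conformens_out"

    def validate(self) -> None:
        file_mode = self.models_path is not None
        if file_mode == self.synthetic:
            raise ValueError(
                "exactly one of models_path (file mode) or synthetic=True "
                "must be active"
            )
        if file_mode and self.energies_path is None:
            raise ValueError("file mode requires energies_path")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key, klass in (
            ("synthetic_spec", synthetic.SyntheticSpec),
            ("energy_model", synthetic.EnergyModelSpec),
            ("pseudo_md", synthetic.PseudoMDSpec),
        ):
            if isinstance(raw.get(key), dict):
                if key == "synthetic_spec" and "mixture_weights" in raw[key]:
                    raw[key]["mixture_weights"] = tuple(raw[key]["mixture_weights"])
                raw[key] = klass(**raw[key])
        return cls(**raw)


def _derive_seeds(seed: int) -> tuple[int, int, int]:
    """Three independent sub-seeds (< 2^31) from the single run seed."""
    ss = np.random.SeedSequence(seed)
    return tuple(int(s) % (2**31) for s in ss.generate_state(3))


def _load_inputs(config: RunConfig):
    """Returns (ensemble, energies, references, regions, md_ensemble, extra)."""
    if config.synthetic:
        seeds = _derive_seeds(config.seed)
        spec = config.synthetic_spec or synthetic.SyntheticSpec()
        spec = synthetic.SyntheticSpec(
            **{**spec.__dict__, "seed": seeds[0]}
        )
        emodel = config.energy_model or synthetic.EnergyModelSpec()
        mdspec = config.pseudo_md or synthetic.PseudoMDSpec()
        mdspec = synthetic.PseudoMDSpec(**{**mdspec.__dict__, "seed": seeds[2]})
        open_model, closed_model, regions = synthetic.make_endpoints(spec)
        ensemble, truth = synthetic.sample_two_state_ensemble(spec)
        energies = synthetic.assign_energies(truth, emodel, seed=seeds[1])
        md_ensemble, _ = synthetic.sample_pseudo_md(spec, mdspec)
        references = [("open", open_model), ("closed", closed_model)]
        return ensemble, energies, references, regions, md_ensemble, truth
    ensemble = io.read_pdb_models(config.models_path)
    energies = io.read_energy_table(config.energies_path)
    references = [
        (label, io.read_pdb_models(path).models[0])
        for label, path in config.references_paths.items()
    ]
    regions = (
        io.read_region_file(config.regions_path) if config.regions_path else None
    )
    md_ensemble = io.read_pdb_models(config.md_path) if config.md_path else None
    return ensemble, energies, references, regions, md_ensemble, None


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the summary dict (also on disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "selection": config.selection}

    with _stage("load"):
        ensemble, energies, references, regions, md_ensemble, truth = _load_inputs(
            config
        )
        summary["n_models"] = ensemble.n_models
        if truth is not None:
            truth.to_dataframe().to_csv(out / "ground_truth.csv", index=False)

    with _stage("extract"):
        work = io.extract_atoms(ensemble, config.selection)
        refs_work = [
            (label, _extract_model(model, config.selection))
            for label, model in references
        ]
        md_work = (
            io.extract_atoms(md_ensemble, config.selection)
            if md_ensemble is not None
            else None
        )

    with _stage("filter"):
        filt = filtering.mean_energy_filter(energies, work.model_ids)
        filt.to_dataframe(energies).to_csv(out / "filter.csv", index=False)
        if not filt.kept_ids:
            raise ValueError("no models survive the mean-energy filter")
        kept = work.subset_models(filt.kept_ids)
        summary["energy_threshold_kcal_mol"] = filt.threshold
        summary["n_kept"] = filt.n_kept
        summary["n_removed"] = filt.n_removed

    with _stage("pairwise_rmsd"):
        matrix = geometry.pairwise_rmsd_matrix(kept)
        matrix.to_csv(out / "rmsd_matrix.csv")

    with _stage("cluster"):
        result = clustering.cluster_ensemble(
            matrix,
            energies,
            k_max=min(config.k_max, matrix.n - 1),
            linkage=config.linkage,
            flatness_floor=config.flatness_floor,
        )
        result.to_dataframe(energies).to_csv(out / "clusters.csv", index=False)
        pd.DataFrame(
            {"k": np.arange(1, len(result.dispersion_curve) + 1),
             "W": result.dispersion_curve}
        ).to_csv(out / "dispersion.csv", index=False)
        summary["k"] = result.k
        summary["centroids"] = {
            str(c): {"model_id": mid, "energy_kcal_mol": energies[mid]}
            for c, mid in result.centroid_ids.items()
        }

    with _stage("cluster_analysis"):
        summary["clusters"] = {}
        for c in sorted(set(result.labels.values())):
            members = result.members(c)
            info: dict = {"n_members": len(members)}
            if len(members) >= 2:
                cluster_ens = kept.subset_models(members)
                aligned, _ = geometry.align_to_mean(cluster_ens)
                rmsf = geometry.rmsf_profile(aligned, selection="calpha")
                rmsf.to_csv(out / f"rmsf_cluster{c}.csv")
                info["max_rmsf_nm"] = float(rmsf.values.max())
                pc = motions.fit_cartesian_pca(aligned)
                frac = pc.variance_fraction
                info["pc1_variance_fraction"] = (
                    float(frac[0]) if np.isfinite(frac[0]) else None
                )
                proj = motions.project_models(pc, aligned, component=1)
                proj.to_dataframe().to_csv(
                    out / f"pc_scores_cluster{c}.csv", index=False
                )
                pd.DataFrame(
                    {
                        "component": np.arange(1, len(pc.variances) + 1),
                        "variance_A2": pc.variances,
                        "fraction": frac,
                    }
                ).to_csv(out / f"variances_cluster{c}.csv", index=False)
                if md_work is not None and md_work.n_models >= 5 and len(members) >= 5:
                    md_proj = motions.project_models(pc, md_work, component=1)
                    info["pc1_density_overlap_vs_md"] = motions.density_overlap(
                        proj, md_proj
                    )
            summary["clusters"][str(c)] = info

    with _stage("motions"):
        # collective motion of the whole kept ensemble: on a two-state set
        # PC1 is the open/closed mode, the axis on which the decoys and the
        # reference (MD) ensemble are compared
        if kept.n_models >= 5:
            aligned_all, _ = geometry.align_to_mean(kept)
            pc_all = motions.fit_cartesian_pca(aligned_all)
            frac = pc_all.variance_fraction
            summary["ensemble_pc1_variance_fraction"] = (
                float(frac[0]) if np.isfinite(frac[0]) else None
            )
            proj_all = motions.project_models(pc_all, aligned_all, component=1)
            proj_all.to_dataframe().to_csv(out / "pc_scores.csv", index=False)
            pd.DataFrame(
                {
                    "component": np.arange(1, len(pc_all.variances) + 1),
                    "variance_A2": pc_all.variances,
                    "fraction": frac,
                }
            ).to_csv(out / "variances.csv", index=False)
            if md_work is not None and md_work.n_models >= 5:
                md_proj = motions.project_models(pc_all, md_work, component=1)
                summary["ensemble_pc1_overlap_vs_md"] = motions.density_overlap(
                    proj_all, md_proj
                )

    with _stage("descriptors"):
        if regions is not None and len(regions) >= 3:
            arm_a, hinge, arm_b = regions[0], regions[1], regions[2]
            desc = descriptors.descriptor_series(kept, arm_a, hinge, arm_b)
        else:
            desc = None

    with _stage("classify"):
        labels = None
        if refs_work:
            refset = descriptors.ReferenceSet(
                refs_work, intermediate_margin=config.intermediate_margin
            )
            labels, fractions = descriptors.classify_by_reference(kept, refset)
            pd.DataFrame(
                {
                    "label": list(fractions),
                    "count": [int(round(f * kept.n_models)) for f in fractions.values()],
                    "fraction": list(fractions.values()),
                }
            ).to_csv(out / "populations.csv", index=False)
            summary["populations"] = fractions
        if desc is not None:
            desc.to_dataframe(labels).to_csv(out / "descriptors.csv", index=False)

    with _stage("spread"):
        summary["delta_rmsd_A"] = float(matrix.values.max())

    with _stage("summary"):
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
    return summary


def _extract_model(model: StructureModel, selection: str) -> StructureModel:
    ens = io.extract_atoms(Ensemble([model]), selection)
    return ens.models[0]
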