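"""Ground-truthed synthetic stand-ins for decoy sets and MD trajectories.

The generator builds a minimal hinge-bending test article: a Cα-only chain
of two straight arms (3.8 Å Cα spacing) joined at a short hinge segment,
with the arms subtending a configurable aperture angle at the hinge.  An
"open" and a "closed" endpoint differ only in that angle, and every
intermediate conformation is the linear Cartesian morph

    x(λ) = (1 - λ) · x_open + λ · x_closed

so the whole construction has exactly one collective degree of freedom — the
property the PCA and descriptor machinery is tested against.  A decoy set is
drawn as a two-component mixture over λ (λ ≈ 0 open, λ ≈ 1 closed) with
isotropic coordinate noise; scores from an external rescoring step are
emulated by a double-well energy

    E(λ) = -E0 + 16 h λ² (1 - λ)² + c λ + ε,   ε ~ N(0, σ_E²)

with minima at the two states and a barrier of height h at λ = 1/2.  A
pseudo-MD trajectory is a mean-reverting (discrete Ornstein-Uhlenbeck)
random walk on λ, reflected into [-0.2, 1.2] — slight over-opening beyond
the endpoints is allowed deliberately.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Ensemble, EnergyTable, RegionSpec, StructureModel

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "EnergyModelSpec",
    "PseudoMDSpec",
    "make_endpoints",
    "morph_coords",
    "sample_two_state_ensemble",
    "assign_energies",
    "pseudo_md_lambda_trace",
    "sample_pseudo_md",
]

CA_SPACING = 3.8  # Å, canonical consecutive-Cα distance

#: reflection bounds for the pseudo-MD morph coordinate
LAMBDA_BOUNDS = (-0.2, 1.2)


@dataclass
class SyntheticSpec:
    """Geometry and sampling parameters of the two-state test article.

    Defaults mirror a 1000-model decoy set over a strongly hinged chain:
    a 30 %/70 % open/closed mixture with tight per-state spread
    (``state_sd = 0.02`` on λ) and 0.2 Å isotropic coordinate noise, small
    against the multi-Å open/closed separation.
    """

    n_res: int = 60
    arm_len: int = 25
    theta_open: float = 120.0
    theta_closed: float = 60.0
    mixture_weights: tuple[float, float] = (0.3, 0.7)
    state_sd: float = 0.02
    coord_noise_sd: float = 0.2
    n_models: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_res < 6:
            raise ValueError("n_res must be >= 6")
        if self.n_res < 2 * self.arm_len + 2:
            raise ValueError("need n_res >= 2*arm_len + 2 (hinge of >= 2 residues)")
        if not (0 < self.theta_closed < self.theta_open <= 180):
            raise ValueError("need 0 < theta_closed < theta_open <= 180")
        w = self.mixture_weights
        if len(w) != 2 or w[0] < 0 or w[1] < 0 or abs(sum(w) - 1.0) > 1e-12:
            raise ValueError("mixture_weights must be two non-negatives summing to 1")
        if self.state_sd < 0 or self.coord_noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")

    @property
    def n_hinge(self) -> int:
        return self.n_res - 2 * self.arm_len


@dataclass
class GroundTruth:
    """Per-model generating state of a synthetic decoy set."""

    model_ids: list[str]
    lambda_values: np.ndarray
    state_labels: list[str]
    energies: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "model_id": self.model_ids,
                "lambda": self.lambda_values,
                "state": self.state_labels,
            }
        )
        if self.energies is not None:
            df["energy_kcal_mol"] = self.energies
        return df


@dataclass
class EnergyModelSpec:
    """Double-well energy stand-in for an external rescoring step.

    ``well_depth`` sets the overall scale (both minima at -well_depth when
    the asymmetry c = 0), ``barrier_height`` the barrier at λ = 1/2,
    ``asymmetry`` tilts the closed well by c kcal/mol, and
    ``energy_noise_sd`` adds Gaussian scoring noise.  The default scale is
    chosen so thresholds land in the hundreds of kcal/mol, the magnitude
    typical of coarse-grained decoy rescoring; the wells are symmetric by
    default (c = 0) so energy filtering treats the two states even-handedly.
    """

    well_depth: float = 700.0
    barrier_height: float = 60.0
    asymmetry: float = 0.0
    energy_noise_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.barrier_height < 0 or self.energy_noise_sd < 0:
            raise ValueError("barrier_height and energy_noise_sd must be >= 0")

    def energy(self, lam: np.ndarray) -> np.ndarray:
        """Noise-free E(λ) = -E0 + 16 h λ²(1-λ)² + c λ."""
        lam = np.asarray(lam, dtype=float)
        return (
            -self.well_depth
            + 16.0 * self.barrier_height * lam**2 * (1.0 - lam) ** 2
            + self.asymmetry * lam
        )


@dataclass
class PseudoMDSpec:
    """Mean-reverting random walk on the morph coordinate λ."""

    n_frames: int = 500
    dt: float = 0.05
    kappa: float = 1.0
    mu: float = 0.5
    sigma: float = 0.4
    seed: int = 0
    lambda0: float | None = None  # start of the walk; defaults to mu

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


def make_endpoints(
    spec: SyntheticSpec,
) -> tuple[StructureModel, StructureModel, list[RegionSpec]]:
    """Build the open and closed endpoint conformers plus their regions.

    Both arms lie in the xy-plane, symmetric about the x-axis, emanating
    from the hinge; the hinge residues sit on the z-axis centred on the
    origin so the hinge centre of geometry is exactly the origin and the
    aperture angle of an endpoint equals its nominal theta.
    """
    def chain(theta_deg: float) -> np.ndarray:
        half = np.radians(theta_deg) / 2.0
        u_a = np.array([np.cos(half), np.sin(half), 0.0])
        u_b = np.array([np.cos(half), -np.sin(half), 0.0])
        # arm residues from the far end inward, so the chain runs
        # arm_a -> hinge -> arm_b
        radii_in = CA_SPACING * np.arange(spec.arm_len, 0, -1)
        arm_a = radii_in[:, None] * u_a
        n_h = spec.n_hinge
        z = CA_SPACING * (np.arange(n_h) - (n_h - 1) / 2.0)
        hinge = np.column_stack([np.zeros(n_h), np.zeros(n_h), z])
        radii_out = CA_SPACING * np.arange(1, spec.arm_len + 1)
        arm_b = radii_out[:, None] * u_b
        return np.vstack([arm_a, hinge, arm_b])

    def model(coords: np.ndarray, model_id: str) -> StructureModel:
        n = spec.n_res
        return StructureModel(
            model_id,
            ["CA"] * n,
            ["ALA"] * n,
            np.arange(1, n + 1),
            ["A"] * n,
            coords,
        )

    open_model = model(chain(spec.theta_open), "open")
    closed_model = model(chain(spec.theta_closed), "closed")
    regions = [
        RegionSpec("arm_a", "A", 1, spec.arm_len),
        RegionSpec("hinge", "A", spec.arm_len + 1, spec.arm_len + spec.n_hinge),
        RegionSpec("arm_b", "A", spec.arm_len + spec.n_hinge + 1, spec.n_res),
    ]
    return open_model, closed_model, regions


def morph_coords(
    open_model: StructureModel, closed_model: StructureModel, lam: np.ndarray
) -> np.ndarray:
    """Linear Cartesian morph: (1-λ)·open + λ·closed, shape (len(λ), N, 3)."""
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    return (
        (1.0 - lam)[:, None, None] * open_model.coords[None]
        + lam[:, None, None] * closed_model.coords[None]
    )


def _model_ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def sample_two_state_ensemble(
    spec: SyntheticSpec,
) -> tuple[Ensemble, GroundTruth]:
    """Draw a decoy-set stand-in from the two-state mixture.

    Per model: the state (open/closed) is drawn from ``mixture_weights``,
    λ ~ N(0 or 1, state_sd), and the morph coordinates get isotropic
    Gaussian noise of ``coord_noise_sd`` Å per axis.  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    open_model, closed_model, _ = make_endpoints(spec)
    n = spec.n_models
    states = rng.choice(2, size=n, p=list(spec.mixture_weights))  # 0=open, 1=closed
    lam = rng.normal(loc=states.astype(float), scale=spec.state_sd)
    coords = morph_coords(open_model, closed_model, lam)
    coords += rng.normal(scale=spec.coord_noise_sd, size=coords.shape)
    ids = _model_ids("m", n)
    models = [
        open_model.with_coords(c, model_id=mid) for c, mid in zip(coords, ids)
    ]
    truth = GroundTruth(
        ids,
        lam,
        ["open" if s == 0 else "closed" for s in states],
    )
    return Ensemble(models), truth


def assign_energies(
    truth: GroundTruth, emodel: EnergyModelSpec, seed: int = 0
) -> EnergyTable:
    """Emulated rescoring: double-well energy of each model's true λ + noise.

    Fills ``truth.energies`` and returns the corresponding
    :class:`~conformens.core.EnergyTable` (kcal/mol).
    """
    rng = np.random.default_rng(seed)
    e = emodel.energy(truth.lambda_values)
    if emodel.energy_noise_sd > 0:
        e = e + rng.normal(scale=emodel.energy_noise_sd, size=e.shape)
    truth.energies = e
    return EnergyTable(dict(zip(truth.model_ids, e.astype(float))))


def _reflect(x: float, lo: float, hi: float) -> float:
    # fold x back into [lo, hi] (handles multiple crossings)
    span = hi - lo
    while x < lo or x > hi:
        if x < lo:
            x = 2 * lo - x
        else:
            x = 2 * hi - x
    return x


def pseudo_md_lambda_trace(md: PseudoMDSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """The reflected mean-reverting λ walk itself, without building frames.

    ``λ_{t+1} = λ_t + κ (μ - λ_t) dt + σ sqrt(dt) ξ_t`` started at
    ``lambda0`` (μ by default) and reflected into [-0.2, 1.2].
    """
    if rng is None:
        rng = np.random.default_rng(md.seed)
    lo, hi = LAMBDA_BOUNDS
    lam = np.empty(md.n_frames)
    x = float(md.mu if md.lambda0 is None else md.lambda0)
    sqrt_dt = np.sqrt(md.dt)
    noise = rng.normal(size=md.n_frames)
    for t in range(md.n_frames):
        x = x + md.kappa * (md.mu - x) * md.dt + md.sigma * sqrt_dt * noise[t]
        x = _reflect(x, lo, hi)
        lam[t] = x
    return lam


def sample_pseudo_md(
    spec: SyntheticSpec, md: PseudoMDSpec
) -> tuple[Ensemble, np.ndarray]:
    """Pseudo-MD reference trajectory on the morph coordinate.

    Frames are the morph coordinates of the reflected mean-reverting λ walk
    (see :func:`pseudo_md_lambda_trace`) plus the spec's coordinate jitter.
    Deterministic given ``md.seed``.
    """
    rng = np.random.default_rng(md.seed)
    open_model, closed_model, _ = make_endpoints(spec)
    lam = pseudo_md_lambda_trace(md, rng)
    coords = morph_coords(open_model, closed_model, lam)
    if spec.coord_noise_sd > 0:
        coords = coords + rng.normal(scale=spec.coord_noise_sd, size=coords.shape)
    ids = _model_ids("f", md.n_frames)
    models = [
        open_model.with_coords(c, model_id=mid) for c, mid in zip(coords, ids)
    ]
    return Ensemble(models), lam
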