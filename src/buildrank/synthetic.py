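"""Synthetic fixtures: density maps, model pairs, and feature→outcome tables.

Everything the test and evaluation machinery consumes can be generated here
with a known ground truth:

* density maps as sums of isotropic Gaussian blobs plus white noise — not a
  physical density simulation (no structure factors), but with controllable
  histogram statistics;
* built/deposited model pairs on a well-separated Cα path, where the true
  completeness is fixed by construction;
* per-variant feature→outcome tables whose outcomes follow known smooth
  response functions of the features plus Gaussian noise, emulating the
  empirical behaviour of model-building pipelines: completeness is high at
  good resolution and collapses beyond ~3.5 Å, R factors rise with
  resolution, and (for MR) a poor search model hurts.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .compare import Residue, StructureModel
from .maps import DensityMap
from .training import EXPERIMENTAL_FEATURES, MR_FEATURES, TrainingTable
from .variants import PipelineVariant, applicable_measures, default_registry

__all__ = [
    "make_synthetic_map",
    "ModelPair",
    "make_model_pair",
    "OutcomeGeneratorSpec",
    "SyntheticOutcomes",
    "make_outcome_table",
    "AMINO_ACIDS",
]

AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)


def make_synthetic_map(
    n_atoms: int = 20,
    cell_edge: float = 20.0,
    grid_shape: tuple[int, int, int] = (32, 32, 32),
    noise_sigma: float = 0.1,
    seed: int = 0,
    blob_sigma: float = 0.8,
    blob_height: float = 1.0,
) -> DensityMap:
    """Sum of Gaussian blobs at uniform-random positions plus white noise.

    ``blob_sigma`` is the blob width in angstroms; the cell is cubic with
    edge ``cell_edge``.  ``n_atoms=0, noise_sigma=0`` gives the constant
    zero map.
    """
    if n_atoms < 0:
        raise ValueError("n_atoms must be non-negative")
    if min(grid_shape) < 1:
        raise ValueError("grid_shape must be positive")
    rng = np.random.default_rng(seed)
    nx, ny, nz = grid_shape
    axes = [np.arange(n) * cell_edge / n for n in grid_shape]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    values = np.zeros(grid_shape, dtype=float)
    centers = rng.uniform(0.0, cell_edge, size=(n_atoms, 3))
    for cx, cy, cz in centers:
        d2 = (gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2
        values += blob_height * np.exp(-d2 / (2.0 * blob_sigma**2))
    if noise_sigma > 0:
        values += rng.normal(0.0, noise_sigma, size=grid_shape)
    return DensityMap(
        values=values,
        cell=(cell_edge, cell_edge, cell_edge, 90.0, 90.0, 90.0),
    )


@dataclass
class ModelPair:
    """A built/deposited model pair with its construction ground truth."""

    built: StructureModel
    deposited: StructureModel
    expected_completeness: float
    n_matched: int
    n_wrong_type: int


def make_model_pair(
    n_residues: int,
    match_fraction: float,
    wrong_type_fraction: float = 0.0,
    displacement: float = 0.3,
    seed: int = 0,
) -> ModelPair:
    """Deposited model plus a partial rebuild with known completeness.

    The deposited model places ``n_residues`` Cα atoms 3.8 Å apart along a
    gently jittered path (so no two Cα come within the 1 Å match cutoff of
    each other).  The built model reproduces ``round(match_fraction * n)``
    residues displaced by exactly ``displacement`` (must be below the match
    cutoff), gives ``round(wrong_type_fraction * n)`` residues the right
    position but a mutated residue type, and omits the rest.  True
    completeness is therefore ``n_matched / n_residues`` exactly.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be positive")
    for name, frac in (("match_fraction", match_fraction), ("wrong_type_fraction", wrong_type_fraction)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if match_fraction + wrong_type_fraction > 1.0 + 1e-12:
        raise ValueError("match_fraction + wrong_type_fraction must not exceed 1")
    if not 0.0 <= displacement < 1.0:
        raise ValueError("displacement must be in [0, 1) Å for matched residues")
    rng = np.random.default_rng(seed)
    spacing = 3.8
    # straight path along x with sub-angstrom perpendicular jitter: consecutive
    # Cα separations stay >= spacing in x, far beyond the match cutoff
    positions = np.zeros((n_residues, 3))
    positions[:, 0] = np.arange(n_residues) * spacing
    positions[:, 1] = rng.uniform(-0.3, 0.3, size=n_residues)
    positions[:, 2] = rng.uniform(-0.3, 0.3, size=n_residues)
    types = rng.choice(AMINO_ACIDS, size=n_residues)
    deposited = StructureModel(
        residues=[
            Residue("A", i + 1, "", types[i], tuple(positions[i]))
            for i in range(n_residues)
        ]
    )
    n_match = int(round(match_fraction * n_residues))
    n_wrong = int(round(wrong_type_fraction * n_residues))
    n_wrong = min(n_wrong, n_residues - n_match)
    order = rng.permutation(n_residues)
    match_idx = sorted(order[:n_match])
    wrong_idx = sorted(order[n_match : n_match + n_wrong])
    built_residues = []
    for i in match_idx:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = positions[i] + displacement * direction
        built_residues.append(Residue("A", int(i) + 1, "", types[i], tuple(pos)))
    for i in wrong_idx:
        mutated = rng.choice([aa for aa in AMINO_ACIDS if aa != types[i]])
        built_residues.append(Residue("A", int(i) + 1, "", mutated, tuple(positions[i])))
    built = StructureModel(residues=built_residues)
    return ModelPair(
        built=built,
        deposited=deposited,
        expected_completeness=n_match / n_residues,
        n_matched=n_match,
        n_wrong_type=n_wrong,
    )


ResponseFn = Callable[[pd.DataFrame], np.ndarray]


@dataclass
class OutcomeGeneratorSpec:
    """Generative conditions for synthetic feature→outcome tables.

    Resolution is uniform on [1.0, 4.0] Å; the map statistics derive from a
    latent map-quality variable that decays with resolution (so skew and
    r.m.s.d. carry secondary signal); MR sequence identity is uniform on
    [0.2, 1.0].  Outcome noise defaults to sigma = 0.05 for completeness
    and 0.02 for the R factors, reflecting that completeness is the harder
    target.  Custom per-(variant, measure) response functions can be
    supplied; otherwise smooth logistic-in-resolution responses with
    variant-specific midpoints are drawn reproducibly from the seed.
    """

    phasing_mode: str = "experimental"
    resolution_range: tuple[float, float] = (1.0, 4.0)
    seq_identity_range: tuple[float, float] = (0.2, 1.0)
    noise_sigma: dict[str, float] = field(
        default_factory=lambda: {"completeness": 0.05, "R_work": 0.02, "R_free": 0.02}
    )
    responses: Optional[dict[tuple[str, str], ResponseFn]] = None
    seed: int = 0


@dataclass
class SyntheticOutcomes:
    """Generated tables plus the noiseless truth for recovery tests."""

    features: pd.DataFrame
    tables: dict[tuple[str, str], TrainingTable]
    truth: dict[tuple[str, str], ResponseFn]
    registry: list[PipelineVariant]
    feature_columns: list[str]

    def truth_values(self, variant_id: str, measure: str) -> np.ndarray:
        return self.truth[(variant_id, measure)](self.features)


def _sample_features(spec: OutcomeGeneratorSpec, n: int, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = spec.resolution_range
    resolution = rng.uniform(lo, hi, size=n)
    # latent map quality in (0, 1): good at high resolution, noisy
    quality = expit((2.5 - resolution) / 0.5) + rng.normal(0.0, 0.08, size=n)
    quality = np.clip(quality, 0.0, 1.0)
    frame = pd.DataFrame(
        {
            "dataset_id": [f"synth-{i:05d}" for i in range(n)],
            "resolution": resolution,
            "rmsd": 0.20 + 0.15 * quality + rng.normal(0.0, 0.02, size=n),
            "skew": 0.02 + 0.30 * quality**2 + rng.normal(0.0, 0.03, size=n),
            "max_density": 2.0 + 8.0 * quality + rng.normal(0.0, 0.5, size=n),
            "min_density": -1.8 + 1.2 * quality + rng.normal(0.0, 0.2, size=n),
        }
    )
    if spec.phasing_mode == "MR":
        s_lo, s_hi = spec.seq_identity_range
        frame["sequence_identity"] = rng.uniform(s_lo, s_hi, size=n)
    return frame


def _default_responses(
    spec: OutcomeGeneratorSpec,
    registry: Sequence[PipelineVariant],
    rng: np.random.Generator,
) -> dict[tuple[str, str], ResponseFn]:
    responses: dict[tuple[str, str], ResponseFn] = {}
    for variant in registry:
        midpoint = rng.uniform(2.3, 3.1)
        steepness = rng.uniform(0.30, 0.50)
        top = rng.uniform(0.70, 0.88)
        skew_coeff = rng.uniform(0.05, 0.25)
        sid_coeff = rng.uniform(0.10, 0.30) if variant.phasing_mode == "MR" else 0.0
        rwork_rise = rng.uniform(0.08, 0.14)
        rfree_offset = rng.uniform(0.025, 0.045)

        def completeness(
            f: pd.DataFrame,
            midpoint=midpoint,
            steepness=steepness,
            top=top,
            skew_coeff=skew_coeff,
            sid_coeff=sid_coeff,
        ) -> np.ndarray:
            value = 0.05 + top * expit((midpoint - f["resolution"].to_numpy()) / steepness)
            value = value + skew_coeff * (f["skew"].to_numpy() - 0.15)
            if sid_coeff and "sequence_identity" in f.columns:
                value = value + sid_coeff * (f["sequence_identity"].to_numpy() - 0.6)
            return np.clip(value, 0.0, 1.0)

        def r_work(
            f: pd.DataFrame, midpoint=midpoint, rwork_rise=rwork_rise, skew_coeff=skew_coeff
        ) -> np.ndarray:
            value = 0.20 + rwork_rise * expit((f["resolution"].to_numpy() - midpoint) / 0.6)
            value = value - 0.4 * skew_coeff * (f["skew"].to_numpy() - 0.15)
            return np.clip(value, 0.05, 0.60)

        def r_free(f: pd.DataFrame, r_work=r_work, rfree_offset=rfree_offset) -> np.ndarray:
            return np.clip(r_work(f) + rfree_offset, 0.05, 0.65)

        cell_responses = {"completeness": completeness, "R_work": r_work, "R_free": r_free}
        for measure in applicable_measures(variant):
            responses[(variant.variant_id, measure)] = cell_responses[measure]
    return responses


def make_outcome_table(
    spec: OutcomeGeneratorSpec,
    n_datasets: int,
    registry: Optional[Sequence[PipelineVariant]] = None,
) -> SyntheticOutcomes:
    """Per-(variant, measure) training tables with known generative truth.

    Each applicable cell's outcome is ``response(features) + N(0, sigma)``,
    clamped to the measure's valid range ([0, 1] for completeness, (0, 1)
    for R factors).  The noiseless responses are returned alongside so
    recovery tests can compare against the truth.
    """
    if n_datasets < 2:
        raise ValueError("need at least 2 datasets")
    registry = list(registry) if registry is not None else default_registry(spec.phasing_mode)
    rng = np.random.default_rng(spec.seed)
    features = _sample_features(spec, n_datasets, rng)
    feature_columns = MR_FEATURES if spec.phasing_mode == "MR" else EXPERIMENTAL_FEATURES
    responses = dict(spec.responses) if spec.responses is not None else {}
    defaults = _default_responses(spec, registry, np.random.default_rng(spec.seed + 1))
    for key, fn in defaults.items():
        responses.setdefault(key, fn)
    tables: dict[tuple[str, str], TrainingTable] = {}
    truth: dict[tuple[str, str], ResponseFn] = {}
    for variant in registry:
        for measure in applicable_measures(variant):
            key = (variant.variant_id, measure)
            response = responses[key]
            sigma = spec.noise_sigma.get(measure, 0.0)
            outcome = response(features)
            if sigma > 0:
                outcome = outcome + rng.normal(0.0, sigma, size=n_datasets)
            if measure == "completeness":
                outcome = np.clip(outcome, 0.0, 1.0)
            else:
                outcome = np.clip(outcome, 1e-3, 0.999)
            frame = features.copy()
            frame["outcome"] = outcome
            tables[key] = TrainingTable(
                frame=frame[["dataset_id", *feature_columns, "outcome"]],
                feature_columns=list(feature_columns),
            )
            truth[key] = response
    return SyntheticOutcomes(
        features=features,
        tables=tables,
        truth=truth,
        registry=registry,
        feature_columns=list(feature_columns),
    )
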