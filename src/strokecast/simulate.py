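"""Synthetic MCAO cohort generator with known ground truth.

Emulates the structure of a transient middle-cerebral-artery-occlusion
(MCAO) mouse cohort: a toy mirror-symmetric brain atlas, stochastic lesion
masks grown from a striatal core into a cortical shell, per-animal
covariates (genotype, surgeon, occlusion time), and daily staircase
skilled-reaching records with a dynamic subacute phase and a stable
residual phase.

The generative assumptions mirror the empirical regularities the analysis
pipeline is designed to detect:

* lesions nucleate in the deep striatum-like core and reach cortex-like
  shell regions only at larger volumes (nested topology);
* expected lesion volume grows with occlusion time, while the *relative*
  spread of volumes shrinks (short occlusions are more heterogeneous);
* the acute motor deficit is a saturating (logistic) function of weighted
  damage across a small set of informative regions;
* most animals recover to a convex fraction of their acute deficit, but a
  severity-dependent minority secondarily deteriorates after the subacute
  phase — so early performance is the strongest predictor of late
  performance, while severe outcomes remain intrinsically ambiguous.

Everything is a pure function of the master seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import AtlasVolume, save_ontology
from .topography import LesionMask, region_lesion_percentages

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "Cohort",
    "build_toy_atlas",
    "simulate_lesion",
    "simulate_behavior",
    "simulate_cohort",
    "write_cohort",
]

#: expected lesion size as a fraction of the ipsilateral hemisphere, and the
#: relative (SD/mean) spread of that size, per occlusion time in minutes.
#: Longer occlusion -> larger but more homogeneous infarcts.
OCCLUSION_VOLUME_FRACTION = {30: 0.22, 45: 0.42, 60: 0.60}
OCCLUSION_RELATIVE_SD = {30: 0.85, 45: 0.35, 60: 0.22}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    The cohort has ``n_animals`` MCAO animals plus ``n_sham`` sham-operated
    animals. Noise SDs are on the deficit scale (deficit in [0, 1]);
    ``recovery_rate`` is per day.
    """

    master_seed: int = 0
    n_animals: int = 215
    n_sham: int = 15
    occlusion_minutes: int | Sequence[int] = 45
    atlas_shape: tuple[int, int, int] = (40, 32, 32)
    voxel_size_mm: float = 0.2
    n_regions: int = 60
    informative_region_ids: tuple[int, ...] | None = None  # default: chosen in simulate_cohort
    deficit_weights: tuple[float, ...] | None = None       # aligned with informative ids
    n_informative: int = 14
    recovery_rate: float = 0.22
    recovery_floor: float = 0.40
    recovery_gain: float = 0.25
    non_recovery_max: float = 0.35
    non_recovery_noise_sd: float = 0.03
    residual_noise_sd: float = 0.02
    acute_noise_sd: float = 0.035
    genotype_labels: tuple[str, ...] = tuple(f"Gt{i:02d}" for i in range(1, 16))
    surgeon_labels: tuple[str, ...] = ("A", "B")
    genotype_effect_sd: float = 0.15
    surgeon_effect_mm3: float = 3.0
    # lesion growth
    volume_rel_sd: float | None = None  # None -> occlusion-time calibration table
    lesion_side: str = "left"
    shell_penalty_mm: float = 1.2
    shell_penalty_jitter_sd: float = 1.4
    growth_noise_mm: float = 0.5
    growth_noise_smooth_vox: float = 1.5
    region_jitter_mm: float = 2.6
    severity_beta: tuple[float, float] = (3.5, 1.2)
    # deficit link (normalized logistic in weighted damage)
    deficit_max: float = 0.97
    damage_midpoint: float = 0.15
    damage_scale: float = 0.08
    # behavior
    pellets_presented: int = 20
    baseline_mean_pct: float = 65.0
    baseline_sd_pct: float = 8.0
    training_tau_days: float = 4.0
    daily_noise_sd: float = 0.03
    nonparetic_dip_fraction: float = 0.55
    nonparetic_recovery_rate: float = 0.35

    def __post_init__(self) -> None:
        if self.n_animals <= 0:
            raise ValueError("n_animals must be positive")
        if self.n_sham < 0:
            raise ValueError("n_sham must be non-negative")
        if self.n_regions < 20:
            raise ValueError("n_regions must be >= 20")
        if self.recovery_rate <= 0:
            raise ValueError("recovery_rate must be positive")
        for name in ("residual_noise_sd", "acute_noise_sd", "daily_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        occ = np.atleast_1d(np.asarray(self.occlusion_minutes))
        bad = set(occ.tolist()) - set(OCCLUSION_VOLUME_FRACTION)
        if bad:
            raise ValueError(f"occlusion_minutes must be in {sorted(OCCLUSION_VOLUME_FRACTION)}, got {bad}")

    def occlusion_per_animal(self) -> np.ndarray:
        occ = np.atleast_1d(np.asarray(self.occlusion_minutes, dtype=int))
        if occ.size == 1:
            return np.full(self.n_animals, int(occ[0]))
        if occ.size != self.n_animals:
            raise ValueError("occlusion_minutes must be a scalar or one value per MCAO animal")
        return occ

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


@dataclass
class GroundTruth:
    """Latent quantities of the simulated cohort, for parameter-recovery tests.

    ``per_animal`` columns: latent_severity (lesion-size driver in [0, 1]),
    acute_deficit (deficit level at stroke onset, [0, 1]), residual_deficit,
    true_subacute_pct / true_residual_pct (noise-free phase means of paretic
    performance as percent of baseline).
    """

    per_animal: pd.DataFrame
    informative_region_ids: tuple[int, ...]
    deficit_weights: pd.Series

    def to_json(self, path: str | Path) -> None:
        payload = {
            "informative_region_ids": [int(r) for r in self.informative_region_ids],
            "deficit_weights": {str(k): float(v) for k, v in self.deficit_weights.items()},
            "per_animal": json.loads(self.per_animal.to_json(orient="index")),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class Cohort:
    """A simulated cohort: atlas, masks, covariates and behavior records."""

    atlas: AtlasVolume
    covariates: pd.DataFrame         # indexed by animal_id
    masks: dict[str, LesionMask]
    behavior: pd.DataFrame           # long format: animal_id, day, side, retrieved, presented
    config: SimulationConfig

    @property
    def animal_ids(self) -> list[str]:
        return list(self.covariates.index)

    def mcao_ids(self) -> list[str]:
        return list(self.covariates.index[self.covariates["group"] == "mcao"])


# --------------------------------------------------------------------------
# toy atlas
# --------------------------------------------------------------------------

def _animal_rng(master_seed: int, index: int, stream: int = 0) -> np.random.Generator:
    """Stable per-animal random stream from (master_seed, animal index)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(stream, index))
    )


def build_toy_atlas(
    n_regions: int = 60,
    atlas_shape: tuple[int, int, int] = (40, 32, 32),
    voxel_size_mm: float = 0.2,
    seed: int = 0,
    core_depth_frac: float = 0.45,
) -> AtlasVolume:
    """Build a mirror-symmetric two-hemisphere toy brain atlas.

    The brain is an ellipsoid split at the midline of axis 0 (left = lower
    indices). Each hemisphere is divided into a deep "core" compartment
    (striatum-like, eroded interior) and a superficial "shell" compartment
    (cortex-like), each partitioned into Voronoi regions around randomly
    placed seeds. Region ids 1..n/2 are left-hemisphere, n/2+1..n their
    right mirror images.
    """
    if n_regions < 20:
        raise ValueError("n_regions must be >= 20")
    if n_regions % 2:
        raise ValueError("n_regions must be even (regions are mirrored per hemisphere)")
    shape = tuple(int(s) for s in atlas_shape)
    if len(shape) != 3 or min(shape) < 16:
        raise ValueError(f"atlas_shape must be 3 ints each >= 16, got {atlas_shape}")

    # ellipsoidal foreground, symmetric under flip of axis 0
    grids = np.indices(shape).astype(float)
    center = [(s - 1) / 2.0 for s in shape]
    semi = [0.45 * s for s in shape]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    fg = r2 <= 1.0
    if shape[0] % 2:  # odd first dim: carve the midline slice out (longitudinal fissure)
        fg[shape[0] // 2, :, :] = False

    mid = shape[0] // 2
    left = np.zeros(shape, dtype=bool)
    left[:mid] = True
    left_fg = fg & left

    # depth from brain surface separates deep core from superficial shell
    depth = ndimage.distance_transform_edt(fg)
    core_thresh = max(2.0, core_depth_frac * float(depth.max()))
    core = left_fg & (depth >= core_thresh)
    shell = left_fg & ~core

    k = n_regions // 2
    k_core = max(2, int(round(k / 3)))
    k_shell = k - k_core
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(99,)))

    labels = np.zeros(shape, dtype=np.int32)
    next_id = 1
    for compartment, n_parts in ((core, k_core), (shell, k_shell)):
        coords = np.argwhere(compartment)
        if len(coords) < n_parts:
            raise ValueError(
                f"atlas_shape {shape} too small to place {n_regions} regions "
                f"(compartment has {len(coords)} voxels for {n_parts} regions)"
            )
        seeds = coords[rng.choice(len(coords), size=n_parts, replace=False)]
        # nearest-seed (Voronoi) assignment with a few Lloyd relaxation
        # steps, so region sizes are roughly balanced within a compartment
        for _ in range(4):
            d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
            assign = d2.argmin(axis=1)
            for part in range(n_parts):
                members = coords[assign == part]
                if len(members) == 0:
                    continue
                centroid = members.mean(axis=0)
                seeds[part] = members[((members - centroid) ** 2).sum(axis=1).argmin()]
        d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        labels[tuple(coords.T)] = next_id + assign
        next_id += n_parts

    # right hemisphere: mirror of the left, ids offset by k
    flipped = np.flip(labels, axis=0)
    labels = np.where(flipped > 0, flipped + k, labels)

    rows = []
    for hemi, offset in (("L", 0), ("R", k)):
        for i in range(k):
            rid = offset + i + 1
            is_core = i < k_core
            cls = "core" if is_core else "shell"
            stem = "CP" if is_core else "CTX"
            j = i + 1 if is_core else i - k_core + 1
            rows.append(
                {
                    "region_id": rid,
                    "acronym": f"{stem}{j}-{hemi}",
                    "name": f"{'striatum-like core' if is_core else 'cortex-like shell'} region {j}, "
                            f"{'left' if hemi == 'L' else 'right'}",
                    "hemisphere": hemi,
                    "structure_class": cls,
                }
            )
    ontology = pd.DataFrame(rows).set_index("region_id")
    atlas = AtlasVolume(labels=labels, voxel_size_mm=voxel_size_mm, ontology=ontology)
    atlas.validate()
    return atlas


# --------------------------------------------------------------------------
# lesion growth
# --------------------------------------------------------------------------

def _growth_seed_voxel(atlas: AtlasVolume, side: str) -> tuple[int, int, int]:
    """Deterministic nucleation point: center of the deep core compartment."""
    hemi = atlas.hemisphere_mask(side)
    core_ids = atlas.ontology.index[
        (atlas.ontology["structure_class"] == "core")
        & (atlas.ontology["hemisphere"] == ("L" if side == "left" else "R"))
    ]
    core = np.isin(atlas.labels, core_ids) & hemi
    coords = np.argwhere(core)
    centroid = coords.mean(axis=0)
    best = coords[((coords - centroid) ** 2).sum(axis=1).argmin()]
    return tuple(int(c) for c in best)


def simulate_lesion(
    atlas: AtlasVolume,
    occlusion_minutes: int,
    latent_severity: float,
    seed: int | np.random.Generator = 0,
    *,
    animal_id: str = "sim",
    side: str = "left",
    shell_penalty_mm: float = 1.2,
    shell_penalty_jitter_sd: float = 1.4,
    growth_noise_mm: float = 0.5,
    growth_noise_smooth_vox: float = 1.5,
    region_jitter_mm: float = 2.6,
    volume_rel_sd: float | None = None,
    volume_scale: float = 1.0,
    volume_offset_mm3: float = 0.0,
) -> LesionMask:
    """Grow one stochastic lesion mask nucleated in the striatal core.

    The lesion is the connected set of lowest-cost voxels around the core
    nucleation point, where cost = Euclidean distance (mm) + a penalty for
    cortex-like shell voxels + a smooth random field + a per-region
    vulnerability offset. The target volume is ``latent_severity`` x an
    occlusion-time-dependent fraction of the hemisphere x lognormal noise
    whose relative SD shrinks with occlusion time.

    The shell penalty makes cortical voxels reachable only once the core
    neighbourhood is exhausted, giving the nested core-then-cortex topology
    of transient-occlusion infarcts; its per-animal lognormal jitter
    (``shell_penalty_jitter_sd``) makes some animals cortex-sparing and
    others cortex-heavy at the same volume. The per-animal, per-region
    offsets (``region_jitter_mm``, emulating collateral-flow variation
    between vascular territories) give individual regions partially
    independent involvement, so lesion topology carries information beyond
    total volume.
    """
    if not 0.0 <= latent_severity <= 1.0:
        raise ValueError("latent_severity must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    empty = LesionMask(mask=np.zeros(atlas.shape, dtype=bool), animal_id=animal_id)
    if latent_severity == 0.0:
        return empty

    hemi = atlas.hemisphere_mask(side) & (atlas.labels > 0)
    n_hemi = int(hemi.sum())
    f_mean = OCCLUSION_VOLUME_FRACTION[int(occlusion_minutes)]
    rel_sd = (
        OCCLUSION_RELATIVE_SD[int(occlusion_minutes)]
        if volume_rel_sd is None
        else float(volume_rel_sd)
    )
    sigma = np.sqrt(np.log1p(rel_sd**2))        # lognormal with mean 1, SD rel_sd
    noise = np.exp(rng.normal(-0.5 * sigma**2, sigma))
    frac = latent_severity * f_mean * noise * volume_scale
    target_n = int(round(frac * n_hemi + volume_offset_mm3 / atlas.voxel_volume_mm3))
    target_n = int(np.clip(target_n, 0, n_hemi))
    if target_n == 0:
        return empty

    vox_mm = float(atlas.voxel_size_mm) if np.isscalar(atlas.voxel_size_mm) else float(
        np.asarray(atlas.voxel_size_mm).mean()
    )
    seed_vox = _growth_seed_voxel(atlas, side)
    grids = np.indices(atlas.shape).astype(float)
    dist_mm = np.sqrt(sum((g - s) ** 2 for g, s in zip(grids, seed_vox))) * vox_mm

    shell_ids = atlas.ontology.index[atlas.ontology["structure_class"] == "shell"]
    is_shell = np.isin(atlas.labels, shell_ids)
    field = ndimage.gaussian_filter(rng.standard_normal(atlas.shape), growth_noise_smooth_vox)
    sd = field.std()
    if sd > 0:
        field = field / sd * growth_noise_mm
    penalty = shell_penalty_mm * np.exp(
        rng.normal(-0.5 * shell_penalty_jitter_sd**2, shell_penalty_jitter_sd)
    )
    region_offsets = rng.normal(0.0, region_jitter_mm, int(atlas.region_ids.max()) + 1)

    cost = dist_mm + penalty * is_shell + field + region_offsets[atlas.labels]
    cost[~hemi] = np.inf

    lesion = _grow_connected(cost, seed_vox, target_n)
    return LesionMask(mask=lesion, animal_id=animal_id)


def _grow_connected(cost: np.ndarray, seed_vox: tuple[int, int, int], target_n: int) -> np.ndarray:
    """Best-first connected accretion: repeatedly annex the cheapest voxel on
    the lesion frontier until target_n voxels are included. Guarantees a
    connected lesion of exactly the target size (unless the reachable
    domain is smaller)."""
    import heapq

    shape = cost.shape
    flat_cost = cost.ravel()
    strides = (shape[1] * shape[2], shape[2], 1)
    seed_flat = seed_vox[0] * strides[0] + seed_vox[1] * strides[1] + seed_vox[2]
    n_flat = flat_cost.size

    in_lesion = np.zeros(n_flat, dtype=bool)
    queued = np.zeros(n_flat, dtype=bool)
    heap = [(flat_cost[seed_flat], seed_flat)]
    queued[seed_flat] = True
    n_added = 0
    nbr_offsets = (-strides[0], strides[0], -strides[1], strides[1], -1, 1)
    while heap and n_added < target_n:
        c, idx = heapq.heappop(heap)
        if not np.isfinite(c):
            break
        in_lesion[idx] = True
        n_added += 1
        x = idx // strides[0]
        y = (idx % strides[0]) // strides[1]
        z = idx % strides[1]
        for off, coord, lim in zip(
            nbr_offsets, (x, x, y, y, z, z), (0, shape[0] - 1, 0, shape[1] - 1, 0, shape[2] - 1)
        ):
            if coord == lim:
                continue
            nb = idx + off
            if not queued[nb] and np.isfinite(flat_cost[nb]):
                queued[nb] = True
                heapq.heappush(heap, (flat_cost[nb], nb))
    return in_lesion.reshape(shape)


# --------------------------------------------------------------------------
# behavioral trajectories
# --------------------------------------------------------------------------

def damage_score(pct: pd.Series, weights: pd.Series) -> float:
    """Normalized weighted damage in [0, 1]: sum(w_r * pct_r/100) / sum(w_r)."""
    w = weights.reindex(pct.index, fill_value=0.0)
    total = float(weights.sum())
    if total <= 0:
        return 0.0
    return float((w * pct / 100.0).sum() / total)


def deficit_link(
    u: float | np.ndarray,
    deficit_max: float = 0.97,
    midpoint: float = 0.35,
    scale: float = 0.12,
) -> float | np.ndarray:
    """Acute deficit as a floor-anchored logistic of weighted damage u in [0, 1].

    The logistic is shifted and rescaled so that zero damage maps exactly to
    zero deficit (sham animals obey the same link) and full damage saturates
    near ``deficit_max``.
    """
    sig = lambda x: 1.0 / (1.0 + np.exp(-x))
    lo = sig(-midpoint / scale)
    hi = sig((1.0 - midpoint) / scale)
    raw = sig((np.asarray(u, dtype=float) - midpoint) / scale)
    out = deficit_max * (raw - lo) / (hi - lo)
    return float(out) if np.isscalar(u) else out


def _deficit_trajectory(days: np.ndarray, acute: float, residual: float, rate: float) -> np.ndarray:
    """Deficit relaxing exponentially from the acute level (at day 1, the MRI
    day) toward the residual level."""
    return residual + (acute - residual) * np.exp(-rate * (days - 1.0))


def simulate_behavior(
    region_pct: pd.Series,
    config: SimulationConfig,
    is_sham: bool,
    paretic_side: str = "right",
    seed: int | np.random.Generator = 0,
    *,
    animal_id: str = "sim",
    deficit_weights: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate daily staircase records for one animal.

    Training days -21..-1 ramp to an animal-specific plateau; post-stroke
    days 2..21 follow baseline x (1 - deficit(t)) on the paretic paw, with
    the deficit relaxing exponentially from the acute level (a noisy
    logistic in weighted regional damage) toward the residual level (a
    fixed fraction of the acute level plus noise). The non-paretic paw gets
    a smaller, fully transient dip. Daily pellet counts are binomial draws,
    so noise granularity is set by ``pellets_presented``. Sham animals go
    through the identical model with zero damage.

    Returns the long-format record and a dict of latent truths.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if paretic_side not in ("left", "right"):
        raise ValueError("paretic_side must be 'left' or 'right'")
    if deficit_weights is None:
        deficit_weights = pd.Series(dtype=float)

    u = 0.0 if is_sham else damage_score(region_pct, deficit_weights)
    d_link = deficit_link(u, config.deficit_max, config.damage_midpoint, config.damage_scale)
    acute = float(np.clip(d_link + rng.normal(0.0, config.acute_noise_sd), 0.0, 1.0))
    # recovery mixture: most animals recover to a convex fraction of the
    # acute deficit; with probability rising in severity (up to
    # non_recovery_max) an animal secondarily deteriorates after the
    # subacute phase and ends near its acute deficit. The branch is
    # invisible during the subacute window (both follow the same early
    # trajectory), which is what makes severe outcomes intrinsically hard
    # to predict from early measurements.
    non_recovered = (not is_sham) and rng.uniform() < config.non_recovery_max * acute**2
    recovered_level = acute * (config.recovery_floor + config.recovery_gain * acute)
    if non_recovered:
        residual = float(np.clip(acute + rng.normal(0.0, config.non_recovery_noise_sd), 0.0, 1.0))
    else:
        residual = float(
            np.clip(recovered_level + rng.normal(0.0, config.residual_noise_sd), 0.0, 1.0)
        )

    plateau = float(np.clip(rng.normal(config.baseline_mean_pct, config.baseline_sd_pct), 25.0, 95.0))
    train_days = np.arange(-21, 0)
    post_days = np.arange(2, 22)

    # shared early trajectory toward the recovered level; after day 6 the
    # deficit settles (twice as fast) onto the realized residual level, so a
    # secondary deterioration only shows after the subacute window
    t = post_days.astype(float)
    rho = config.recovery_rate
    early = _deficit_trajectory(t, acute, recovered_level, rho)
    d6 = recovered_level + (acute - recovered_level) * np.exp(-rho * 5.0)
    late = residual + (d6 - residual) * np.exp(-2.0 * rho * (t - 6.0))
    d_par = np.where(t <= 6.0, early, late)
    d_non = (
        config.nonparetic_dip_fraction
        * acute
        * np.exp(-config.nonparetic_recovery_rate * (post_days - 1.0))
    )

    truth = {
        "acute_deficit": acute,
        "residual_deficit": residual,
        "damage_score": u,
        "baseline_plateau_pct": plateau,
        "true_subacute_pct": float(100.0 * (1.0 - d_par[(post_days >= 2) & (post_days <= 6)].mean())),
        "true_residual_pct": float(100.0 * (1.0 - d_par[(post_days >= 12) & (post_days <= 21)].mean())),
    }

    n_pellets = config.pellets_presented
    rows = []
    ramp = 1.0 - np.exp(-(train_days + 22.0) / config.training_tau_days)
    for side in ("left", "right"):
        p_train = plateau / 100.0 * ramp
        d_post = d_par if side == paretic_side else d_non
        p_post = plateau / 100.0 * (1.0 - d_post)
        p_all = np.concatenate([p_train, p_post])
        days = np.concatenate([train_days, post_days])
        p_noisy = np.clip(p_all * np.exp(rng.normal(0.0, config.daily_noise_sd, p_all.size)), 0.0, 1.0)
        retrieved = rng.binomial(n_pellets, p_noisy)
        for d, r in zip(days, retrieved):
            rows.append((animal_id, int(d), side, int(r), n_pellets))

    record = pd.DataFrame(
        rows, columns=["animal_id", "day", "side", "pellets_retrieved", "pellets_presented"]
    )
    return record, truth


# --------------------------------------------------------------------------
# full cohort
# --------------------------------------------------------------------------

def default_informative_regions(atlas: AtlasVolume, side: str, n: int = 14) -> tuple[int, ...]:
    """Default ground-truth informative set: shell (cortex-like) regions of
    the lesioned hemisphere.

    Shell involvement at a given lesion volume is strongly modulated by the
    per-animal vulnerability jitter, so these regions carry topographic
    information beyond total volume — the property that makes the
    segmented-MRI predictor outperform plain lesion volume."""
    hemi = "L" if side == "left" else "R"
    ont = atlas.ontology
    shell = sorted(ont.index[(ont["hemisphere"] == hemi) & (ont["structure_class"] == "shell")])
    if len(shell) < n:
        raise ValueError(f"atlas has only {len(shell)} shell regions in hemisphere {hemi}, need {n}")
    # smallest regions first: their involvement is the most volume-independent
    sizes = atlas.region_voxel_counts()
    shell = sorted(shell, key=lambda r: (int(sizes[r]), int(r)))
    return tuple(sorted(int(r) for r in shell[:n]))


def default_deficit_weights(region_ids: Sequence[int]) -> pd.Series:
    """Equal unit weights over the informative regions: each contributes the
    same share of the deficit, so the importance ground truth is simply
    informative-vs-uninformative."""
    return pd.Series(1.0, index=list(region_ids))


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """Simulate a full cohort (n_animals MCAO + n_sham sham) with ground truth.

    Per-animal randomness comes from independent streams derived from
    (master_seed, animal index), so the cohort is bit-reproducible and
    stable under partial regeneration.
    """
    atlas = build_toy_atlas(
        n_regions=config.n_regions,
        atlas_shape=config.atlas_shape,
        voxel_size_mm=config.voxel_size_mm,
        seed=config.master_seed,
    )
    side = config.lesion_side
    paretic = "right" if side == "left" else "left"

    if config.informative_region_ids is None:
        info_ids = default_informative_regions(atlas, side, config.n_informative)
    else:
        info_ids = tuple(int(r) for r in config.informative_region_ids)
        unknown = set(info_ids) - set(int(r) for r in atlas.region_ids)
        if unknown:
            raise ValueError(f"informative_region_ids not in atlas: {sorted(unknown)}")
    if config.deficit_weights is None:
        weights = default_deficit_weights(info_ids)
    else:
        if len(config.deficit_weights) != len(info_ids):
            raise ValueError("deficit_weights must align with informative_region_ids")
        weights = pd.Series(list(config.deficit_weights), index=list(info_ids))
    if (weights < 0).any():
        raise ValueError("deficit_weights must be non-negative")

    # study-level effects: genotype scales volume multiplicatively, surgeon
    # adds a fixed mm^3 offset
    study_rng = np.random.default_rng(np.random.SeedSequence(entropy=config.master_seed, spawn_key=(1,)))
    genotype_factor = {
        g: float(np.exp(study_rng.normal(0.0, config.genotype_effect_sd)))
        for g in config.genotype_labels
    }
    occlusion = config.occlusion_per_animal()

    n_total = config.n_animals + config.n_sham
    ids = [f"M{i + 1:03d}" for i in range(n_total)]
    cov_rows, truth_rows, masks, behavior_frames = [], [], {}, []

    for i, animal in enumerate(ids):
        is_sham = i >= config.n_animals
        rng = _animal_rng(config.master_seed, i, stream=2)
        genotype = config.genotype_labels[i % len(config.genotype_labels)]
        surgeon = config.surgeon_labels[
            int(rng.integers(len(config.surgeon_labels)))
        ]
        occ = 45 if is_sham else int(occlusion[i])
        severity = 0.0 if is_sham else float(rng.beta(*config.severity_beta))
        offset = config.surgeon_effect_mm3 if surgeon == config.surgeon_labels[-1] else 0.0

        mask = simulate_lesion(
            atlas,
            occ,
            severity,
            rng,
            animal_id=animal,
            side=side,
            shell_penalty_mm=config.shell_penalty_mm,
            shell_penalty_jitter_sd=config.shell_penalty_jitter_sd,
            growth_noise_mm=config.growth_noise_mm,
            growth_noise_smooth_vox=config.growth_noise_smooth_vox,
            region_jitter_mm=config.region_jitter_mm,
            volume_rel_sd=config.volume_rel_sd,
            volume_scale=genotype_factor[genotype],
            volume_offset_mm3=0.0 if is_sham else offset,
        )
        masks[animal] = mask
        profile = region_lesion_percentages(mask, atlas)
        record, truth = simulate_behavior(
            profile.pct,
            config,
            is_sham=is_sham,
            paretic_side=paretic,
            seed=rng,
            animal_id=animal,
            deficit_weights=weights,
        )
        behavior_frames.append(record)
        cov_rows.append(
            {
                "animal_id": animal,
                "group": "sham" if is_sham else "mcao",
                "genotype": genotype,
                "surgeon": surgeon,
                "occlusion_minutes": occ,
                "paretic_side": paretic,
            }
        )
        truth_rows.append({"animal_id": animal, "latent_severity": severity, **truth})

    covariates = pd.DataFrame(cov_rows).set_index("animal_id")
    behavior = pd.concat(behavior_frames, ignore_index=True)
    per_animal = pd.DataFrame(truth_rows).set_index("animal_id")
    cohort = Cohort(atlas=atlas, covariates=covariates, masks=masks, behavior=behavior, config=config)
    truth = GroundTruth(per_animal=per_animal, informative_region_ids=info_ids, deficit_weights=weights)
    return cohort, truth


def write_cohort(cohort: Cohort, truth: GroundTruth, outdir: str | Path) -> None:
    """Write a cohort in its on-disk layout: NIfTI atlas + masks, CSV tables,
    ground-truth JSON and a config echo."""
    outdir = Path(outdir)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    cohort.atlas.to_nifti(outdir / "atlas_labels.nii.gz")
    save_ontology(cohort.atlas.ontology, outdir / "ontology.csv")
    for animal, mask in cohort.masks.items():
        mask.to_nifti(outdir / "masks" / f"{animal}.nii.gz", cohort.atlas)
    cohort.covariates.reset_index().to_csv(outdir / "covariates.csv", index=False)
    cohort.behavior.to_csv(outdir / "behavior.csv", index=False)
    truth.to_json(outdir / "ground_truth.json")
    with open(outdir / "config.json", "w") as fh:
        json.dump(cohort.config.to_dict(), fh, indent=1)
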