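"""Scenario configuration and the bleach/recover simulation runners.

A :class:`ScenarioConfig` fully determines one in silico TOCCSL experiment:
geometry, oligomer species, laser profile, bleach kinetics, timings,
colocalization rule, replicate counts and the master seed.  The runners
here produce compact post-bleach / post-recovery snapshots of the visible
molecules, which is all any downstream analysis consumes.

Seeding: every random stage draws from
``SeedSequence(master_seed, spawn_key=(stage_tag, run_index))`` so runs are
independent, replayable and stable under refactoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .bleaching import BleachModel, LaserProfile, apply_bleach_pulse
from .core import CellGeometry, ConfigurationError, MoleculeEnsemble, OligomerSpecies, init_ensemble
from .recovery import (
    AnalysisRegion,
    ColocalizationRule,
    RingAccumulator,
    analysis_region,
    fit_cubic_optimum,
    fit_density_profile,
)

__all__ = [
    "ScenarioConfig",
    "Snapshot",
    "default_bleach_dt",
    "default_t_rec_grid",
    "stage_rng",
    "bleach_snapshot",
    "recover",
    "optimize_recovery_time",
    "RecoveryOptimum",
]

# Stage tags for the seeding scheme; values are part of the reproducibility
# contract and must not be renumbered.
STAGES = {"init": 0, "bleach": 1, "recover": 2, "opt_init": 3, "opt_bleach": 4, "opt_recover": 5,
          "confirm_init": 6, "confirm_bleach": 7, "confirm_recover": 8, "bootstrap": 9}


def stage_rng(master_seed: int, stage: str, run_index: int = 0) -> np.random.Generator:
    """Independent generator for one (stage, run) pair of a scenario."""
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(STAGES[stage], run_index))
    )


def default_bleach_dt(profile_kind: str) -> float:
    """Default bleach time step: 2 ms for the uniform profile (sharp edge),
    10 ms for the diffraction-affected and ideal profiles."""
    return 0.002 if profile_kind == "uniform" else 0.01


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one in silico TOCCSL experiment."""

    species: tuple[OligomerSpecies, ...]
    geometry: CellGeometry = CellGeometry()
    profile: LaserProfile = LaserProfile()
    bleach: BleachModel = BleachModel()
    t_bleach: float = 4.0
    t_rec: float | str = "auto"
    rule: ColocalizationRule = ColocalizationRule()
    n_runs: int = 1000
    runs_per_point: int = 100
    confirm_runs: int = 300
    t_rec_grid: tuple[float, ...] | None = None
    seed: int = 1
    opt_metric: str = "molecules"  # metric maximized over t_rec: "molecules" or "events"
    region_source: str = "confirm"  # "confirm": dedicated runs; "pooled": the analysis runs
    n_boot: int = 10_000

    def __post_init__(self) -> None:
        if not self.species:
            raise ConfigurationError("at least one species is required")
        total = sum(s.fraction for s in self.species)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"species fractions must sum to 1, got {total}")
        if self.n_runs < 1:
            raise ConfigurationError(f"n_runs must be >= 1, got {self.n_runs}")
        if self.t_rec != "auto" and not (isinstance(self.t_rec, (int, float)) and self.t_rec >= 0):
            raise ConfigurationError(f"t_rec must be 'auto' or a nonnegative time, got {self.t_rec}")
        if self.opt_metric not in ("molecules", "events"):
            raise ConfigurationError(f"unknown opt_metric {self.opt_metric!r}")
        if self.region_source not in ("confirm", "pooled"):
            raise ConfigurationError(f"unknown region_source {self.region_source!r}")
        if self.t_bleach < 0:
            raise ConfigurationError(f"t_bleach must be >= 0, got {self.t_bleach}")

    @property
    def m_max(self) -> int:
        return max(s.m for s in self.species)

    @property
    def center(self) -> tuple[float, float]:
        return self.geometry.center


def default_t_rec_grid(config: ScenarioConfig) -> np.ndarray:
    """Recovery-time grid for the optimization, scaled diffusively.

    The reference grid spans 0.1-2.8 s for the fastest species at
    D = 0.5 um^2/s; for other mobilities the grid is scaled by ``0.5 / D``
    so that the recovered density pattern covers a comparable range
    (diffusion lengths scale as ``sqrt(D t)``).
    """
    D_ref = max(s.D for s in config.species if s.fraction > 0)
    if D_ref <= 0:
        raise ConfigurationError("automatic t_rec requires a diffusing species (D > 0)")
    scale = 0.5 / D_ref
    return np.round(np.arange(0.1, 2.81, 0.1) * scale, 9)


@dataclass
class Snapshot:
    """Visible molecules (n >= 1) of one run at one time point.

    Positions are in um on the periodic cell of side ``L``; ``D`` is the
    per-molecule diffusion coefficient needed to advance the recovery.
    """

    L: float
    t: float
    positions: np.ndarray
    n: np.ndarray
    m: np.ndarray
    D: np.ndarray

    @property
    def n_molecules(self) -> int:
        return self.positions.shape[0]

    def radii(self, center: tuple[float, float]) -> np.ndarray:
        return np.hypot(self.positions[:, 0] - center[0], self.positions[:, 1] - center[1])


def _snapshot_from_ensemble(ens: MoleculeEnsemble) -> Snapshot:
    vis = ens.n > 0
    return Snapshot(
        L=ens.L,
        t=ens.t,
        positions=ens.positions[vis].astype(np.float64),
        n=ens.n[vis].astype(np.int16),
        m=ens.m[vis].astype(np.int16),
        D=ens.D_per_molecule[vis],
    )


def bleach_snapshot(config: ScenarioConfig, run_index: int, stage_prefix: str = "") -> Snapshot:
    """Initialise one cell and apply the bleach pulse; return the visible rest."""
    rng_init = stage_rng(config.seed, stage_prefix + "init", run_index)
    ens = init_ensemble(config.geometry, config.species, config.bleach.weights_AB, rng_init)
    rng_bleach = stage_rng(config.seed, stage_prefix + "bleach", run_index)
    out = apply_bleach_pulse(ens, config.profile, config.bleach, config.t_bleach, rng_bleach)
    return _snapshot_from_ensemble(out)


def recover(snapshot: Snapshot, t_rec: float, rng: np.random.Generator) -> Snapshot:
    """Advance free diffusion for the recovery interval.

    No bleaching occurs during recovery, so the sum of per-step Gaussian
    increments collapses to a single Gaussian displacement with variance
    ``2 D t_rec`` per axis (wrapping commutes with summation on the torus);
    this is exact, not an approximation.
    """
    if t_rec < 0:
        raise ConfigurationError(f"t_rec must be >= 0, got {t_rec}")
    pos = snapshot.positions
    if t_rec > 0 and snapshot.n_molecules:
        disp = rng.standard_normal(pos.shape) * np.sqrt(2.0 * snapshot.D * t_rec)[:, None]
        pos = np.mod(pos + disp, snapshot.L)
    return Snapshot(
        L=snapshot.L,
        t=snapshot.t + t_rec,
        positions=pos,
        n=snapshot.n,
        m=snapshot.m,
        D=snapshot.D,
    )


def region_from_snapshots(
    snapshots: Sequence[Snapshot], config: ScenarioConfig
) -> tuple[AnalysisRegion, "np.ndarray"]:
    """Density profile over runs -> erf fit -> analysis region."""
    acc = RingAccumulator(config.profile.d_ap)
    for snap in snapshots:
        acc.add_radii(snap.radii(config.center))
    profile = acc.profile()
    fit = fit_density_profile(profile, d_edge=config.profile.d_edge)
    region = analysis_region(fit, config.rule.rho_crit, config.center)
    return region, profile


@dataclass
class RecoveryOptimum:
    """Result of the recovery-time optimization."""

    t_rec_opt: float
    region: AnalysisRegion | None
    grid: np.ndarray
    mean_counts: np.ndarray
    cubic_coeffs: np.ndarray
    at_boundary: bool


def optimize_recovery_time(
    config: ScenarioConfig,
    t_rec_grid=None,
    runs_per_point: int | None = None,
    confirm_runs: int | None = None,
    share_bleach: bool = True,
) -> RecoveryOptimum:
    """Find the recovery time that maximizes the analyzable molecule count.

    For each grid recovery time, ``runs_per_point`` post-bleach states are
    recovered, the pooled radial density profile is fitted, the analysis
    region derived, and the mean number of visible molecules (or detection
    events, per ``config.opt_metric``) inside the region recorded.  A cubic
    polynomial fit over the grid locates the optimum, restricted to the
    sampled interval.  With ``share_bleach`` (default) the same post-bleach
    states feed every grid point — the bleach phase is independent of
    ``t_rec``, so each point's estimate is unchanged and the pulse is only
    simulated once per run.  If ``confirm_runs > 0`` the analysis region at
    the optimum is re-determined from that many fresh runs.
    """
    grid = np.asarray(
        default_t_rec_grid(config) if t_rec_grid is None else t_rec_grid, dtype=float
    )
    if grid.size < 4:
        raise ConfigurationError("the recovery-time grid needs at least 4 points")
    runs_per_point = config.runs_per_point if runs_per_point is None else runs_per_point
    confirm_runs = config.confirm_runs if confirm_runs is None else confirm_runs

    from .recovery import detect_apparent_nmers  # local import; cheap

    n_grid = grid.size
    mean_counts = np.zeros(n_grid)
    degenerate = np.zeros(n_grid, dtype=bool)
    bleached = [
        bleach_snapshot(config, i, stage_prefix="opt_") for i in range(runs_per_point)
    ]
    for j, t_rec in enumerate(grid):
        acc = RingAccumulator(config.profile.d_ap)
        recovered = []
        for i in range(runs_per_point):
            snap = bleached[i] if share_bleach else bleach_snapshot(config, j * runs_per_point + i, "opt_")
            rec = recover(snap, t_rec, stage_rng(config.seed, "opt_recover", j * runs_per_point + i))
            acc.add_radii(rec.radii(config.center))
            recovered.append(rec)
        profile = acc.profile()
        fit = fit_density_profile(profile, d_edge=config.profile.d_edge)
        region = analysis_region(fit, config.rule.rho_crit, config.center)
        degenerate[j] = region.r_analysis <= 0.0
        if config.opt_metric == "molecules":
            counts = [
                int(np.sum(rec.radii(config.center) <= region.r_analysis)) for rec in recovered
            ]
        else:
            counts = [
                len(detect_apparent_nmers(rec, region, config.rule, config.m_max))
                for rec in recovered
            ]
        mean_counts[j] = np.mean(counts)

    # Grid points whose analysis region degenerated to radius 0 (recovered
    # density above the cutoff everywhere) carry no count information and
    # would drag the cubic's maximum; exclude them when enough points remain.
    valid = ~degenerate
    if valid.sum() >= 4:
        t_opt, coeffs, at_boundary = fit_cubic_optimum(grid[valid], mean_counts[valid])
    else:
        t_opt, coeffs, at_boundary = fit_cubic_optimum(grid, mean_counts)

    region_opt = None
    if confirm_runs > 0:
        confirmed = []
        for i in range(confirm_runs):
            snap = bleach_snapshot(config, i, stage_prefix="confirm_")
            confirmed.append(recover(snap, t_opt, stage_rng(config.seed, "confirm_recover", i)))
        region_opt, _ = region_from_snapshots(confirmed, config)

    return RecoveryOptimum(
        t_rec_opt=float(t_opt),
        region=region_opt,
        grid=grid,
        mean_counts=mean_counts,
        cubic_coeffs=coeffs,
        at_boundary=at_boundary,
    )
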