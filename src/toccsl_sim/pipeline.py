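"""End-to-end orchestration: simulate -> bleach -> recover -> detect -> fractions.

``run_scenario`` executes one full in silico TOCCSL experiment from a
:class:`~toccsl_sim.scenario.ScenarioConfig` and returns (and optionally
writes) the fraction table, analysis region, density profile, per-run
detection events and a machine-readable manifest.  Everything is
deterministic given the config's master seed.
"""

from __future__ import annotations

import sys
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bleaching import BleachModel, LaserProfile
from .core import CellGeometry, ConfigurationError, OligomerSpecies
from .recovery import AnalysisRegion, ColocalizationRule, DensityProfile, detect_apparent_nmers
from .scenario import (
    RecoveryOptimum,
    ScenarioConfig,
    Snapshot,
    bleach_snapshot,
    default_bleach_dt,
    optimize_recovery_time,
    recover,
    region_from_snapshots,
    stage_rng,
)
from .stats import FractionTable, apparent_fractions, bootstrap_ci

__all__ = [
    "ScenarioResult",
    "run_scenario",
    "analyze_snapshots",
    "standard_scenario",
    "PRESETS",
    "preset_scenarios",
    "config_to_dict",
    "config_from_dict",
    "save_manifest",
    "load_manifest",
]


def _log(msg: str, verbose: bool) -> None:
    if verbose:
        print(msg, file=sys.stderr, flush=True)


@dataclass
class ScenarioResult:
    """Bundle of everything one scenario produces."""

    config: ScenarioConfig
    t_rec_used: float
    region: AnalysisRegion
    density_profile: DensityProfile
    fractions: FractionTable
    events_per_run: list
    optimum: RecoveryOptimum | None = None

    @property
    def total_events(self) -> int:
        return self.fractions.total_events

    def events_frame(self) -> pd.DataFrame:
        rows = []
        for run_id, events in enumerate(self.events_per_run):
            for ev in events:
                rows.append(
                    {
                        "run_id": run_id,
                        "n": ev.n,
                        "coloc_flag": ev.coloc_flag,
                        "member_m_list": ";".join(str(m) for m in ev.member_m),
                        "x": round(ev.anchor[0], 4),
                        "y": round(ev.anchor[1], 4),
                    }
                )
        return pd.DataFrame(rows, columns=["run_id", "n", "coloc_flag", "member_m_list", "x", "y"])

    def density_frame(self) -> pd.DataFrame:
        p = self.density_profile
        return pd.DataFrame(
            {
                "r_outer_um": np.round(p.r_outer, 4),
                "mean_count": p.mean_count,
                "density_per_um2": p.density,
            }
        )

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.fractions.to_frame().to_csv(outdir / "fractions.tsv", sep="\t", index=False)
        self.events_frame().to_csv(outdir / "events.tsv", sep="\t", index=False)
        self.density_frame().to_csv(outdir / "density_profile.tsv", sep="\t", index=False)
        manifest = {
            "config": config_to_dict(self.config),
            "t_rec_used": float(self.t_rec_used),
            "r_analysis_um": float(self.region.r_analysis),
            "analysis_area_um2": float(self.region.area),
            "rho_crit_per_um2": float(self.region.rho_crit),
            "total_events": self.total_events,
            "version": __version__,
        }
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)


def analyze_snapshots(
    recovered: list[Snapshot],
    config: ScenarioConfig,
    region: AnalysisRegion | None = None,
    with_bootstrap: bool = True,
):
    """Detect events on post-recovery snapshots and compute fractions.

    If ``region`` is None it is determined from the pooled density profile
    of these very snapshots.
    """
    pooled_region, profile = region_from_snapshots(recovered, config)
    if region is None:
        region = pooled_region
    events_per_run = [
        detect_apparent_nmers(snap, region, config.rule, config.m_max) for snap in recovered
    ]
    fractions = apparent_fractions(events_per_run, config.m_max)
    if with_bootstrap and len(recovered) >= 2:
        ci_n, ci_true = bootstrap_ci(
            events_per_run,
            config.m_max,
            n_boot=config.n_boot,
            seed=stage_rng(config.seed, "bootstrap", 0),
        )
        fractions.ci_n = ci_n
        fractions.ci_true = ci_true
    return region, profile, events_per_run, fractions


def run_scenario(
    config: ScenarioConfig,
    outdir=None,
    verbose: bool = False,
    with_bootstrap: bool = True,
) -> ScenarioResult:
    """Run one complete in silico TOCCSL experiment.

    Resolves ``t_rec == "auto"`` through the recovery-time optimization,
    simulates ``n_runs`` independent bleach/recovery runs, determines the
    analysis region (from dedicated confirmation runs or, with
    ``region_source == "pooled"``, from the analysis runs themselves),
    detects apparent n-mers and pools them into fractions with bootstrap
    confidence intervals.  Deterministic for a fixed master seed.
    """
    optimum = None
    if config.t_rec == "auto":
        _log("optimizing recovery time ...", verbose)
        confirm = config.confirm_runs if config.region_source == "confirm" else 0
        optimum = optimize_recovery_time(config, confirm_runs=confirm)
        t_rec = optimum.t_rec_opt
        region = optimum.region
        _log(f"  t_rec_opt = {t_rec:.3f} s", verbose)
    else:
        t_rec = float(config.t_rec)
        region = None
        if config.region_source == "confirm" and config.confirm_runs > 0:
            _log(f"determining analysis region from {config.confirm_runs} runs ...", verbose)
            confirmed = [
                recover(
                    bleach_snapshot(config, i, "confirm_"),
                    t_rec,
                    stage_rng(config.seed, "confirm_recover", i),
                )
                for i in range(config.confirm_runs)
            ]
            region, _ = region_from_snapshots(confirmed, config)

    _log(f"simulating {config.n_runs} analysis runs ...", verbose)
    recovered = []
    for i in range(config.n_runs):
        snap = bleach_snapshot(config, i)
        recovered.append(recover(snap, t_rec, stage_rng(config.seed, "recover", i)))
        if verbose and (i + 1) % 50 == 0:
            _log(f"  run {i + 1}/{config.n_runs}", verbose)

    region, profile, events_per_run, fractions = analyze_snapshots(
        recovered, config, region=region, with_bootstrap=with_bootstrap
    )
    _log(
        f"r_analysis = {region.r_analysis:.3f} um, {fractions.total_events} events",
        verbose,
    )
    result = ScenarioResult(
        config=config,
        t_rec_used=t_rec,
        region=region,
        density_profile=profile,
        fractions=fractions,
        events_per_run=events_per_run,
        optimum=optimum,
    )
    if outdir is not None:
        result.write(outdir)
    return result


# ---------------------------------------------------------------------------
# Scenario factories and presets


def standard_scenario(
    profile_kind: str = "diffraction_affected",
    species=None,
    t_bleach: float = 4.0,
    t_rec="auto",
    D: float = 0.5,
    m: int = 2,
    **overrides,
) -> ScenarioConfig:
    """A scenario with the standard benchmark conditions.

    21 x 21 um^2 cell at 100 entities/um^2, 7 um aperture (1 um edge decay,
    sigma 0.5 um for the diffraction-affected profile), bleach kinetics
    alpha = 235/s, beta = 30/s, A = 0.782, colocalization threshold 300 nm
    with 20% accepted probability.  ``species`` defaults to a pure
    population of ``m``-mers with diffusion coefficient ``D``.
    """
    if species is None:
        label = {1: "monomer", 2: "dimer", 3: "trimer", 4: "tetramer"}.get(m, f"{m}-mer")
        species = (OligomerSpecies(label, m, D, 1.0),)
    dt = overrides.pop("dt", default_bleach_dt(profile_kind))
    return ScenarioConfig(
        species=tuple(species),
        profile=LaserProfile(kind=profile_kind),
        bleach=BleachModel(dt=dt),
        t_bleach=t_bleach,
        t_rec=t_rec,
        **overrides,
    )


def monomer_dimer_mixture(D1: float = 0.5, D2: float = 0.5) -> tuple[OligomerSpecies, ...]:
    """1:1 (by entity count) monomer/dimer mixture."""
    return (
        OligomerSpecies("monomer", 1, D1, 0.5),
        OligomerSpecies("dimer", 2, D2, 0.5),
    )


def _preset_tbleach_sweep(kind: str, **kw) -> list[ScenarioConfig]:
    return [
        standard_scenario(kind, t_bleach=tb, **kw)
        for tb in (0.3, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0)
    ]


def preset_scenarios(name: str, **overrides) -> list[ScenarioConfig]:
    """Instantiate a named experiment preset as a list of scenario configs."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return PRESETS[name](**overrides)


PRESETS = {
    # Photobleaching-time sweeps for a pure dimer population, one per profile.
    "tbleach_sweep_ideal": lambda **kw: _preset_tbleach_sweep("ideal", **kw),
    "tbleach_sweep_uniform": lambda **kw: _preset_tbleach_sweep("uniform", **kw),
    "tbleach_sweep_diffraction": lambda **kw: _preset_tbleach_sweep("diffraction_affected", **kw),
    # Recovery-time sweep at fixed bleach time (diffraction-affected profile).
    "trec_sweep_dimer": lambda **kw: [
        standard_scenario("diffraction_affected", t_rec=tr, **kw)
        for tr in np.round(np.arange(0.1, 2.81, 0.3), 3)
    ],
    # Mobility sweep for pure dimers.
    "mobility_sweep_dimer": lambda **kw: [
        standard_scenario("diffraction_affected", D=D, **kw)
        for D in (0.02, 0.05, 0.1, 0.2, 0.5)
    ],
    # Mobility-ratio sweeps for the 1:1 monomer/dimer mixture.
    "mixture_ratio_sweep_ideal": lambda **kw: [
        standard_scenario("ideal", species=monomer_dimer_mixture(0.5, 0.5 * r), **kw)
        for r in (0.1, 0.2, 0.3, 0.5, 0.7, 1.0)
    ],
    "mixture_ratio_sweep_diffraction": lambda **kw: [
        standard_scenario(
            "diffraction_affected", species=monomer_dimer_mixture(0.5, 0.5 * r), **kw
        )
        for r in (0.1, 0.2, 0.3, 0.5, 0.7, 1.0)
    ],
    # Pure and mixed tetramer populations at different mobilities.
    "tetramer_mobility": lambda **kw: [
        standard_scenario("diffraction_affected", m=4, D=D, **kw) for D in (0.02, 0.1, 0.5)
    ]
    + [
        standard_scenario(
            "diffraction_affected",
            species=(
                OligomerSpecies("tetramer_slow", 4, D1, 0.5),
                OligomerSpecies("tetramer_fast", 4, D2, 0.5),
            ),
            **kw,
        )
        for D1, D2 in ((0.02, 0.1), (0.1, 0.5))
    ],
}


# ---------------------------------------------------------------------------
# Manifest round-trip


def config_to_dict(config: ScenarioConfig) -> dict:
    d = {
        "species": [asdict(s) for s in config.species],
        "geometry": asdict(config.geometry),
        "profile": asdict(config.profile),
        "bleach": asdict(config.bleach),
        "t_bleach": config.t_bleach,
        "t_rec": config.t_rec,
        "rule": asdict(config.rule),
        "n_runs": config.n_runs,
        "runs_per_point": config.runs_per_point,
        "confirm_runs": config.confirm_runs,
        "t_rec_grid": list(config.t_rec_grid) if config.t_rec_grid is not None else None,
        "seed": config.seed,
        "opt_metric": config.opt_metric,
        "region_source": config.region_source,
        "n_boot": config.n_boot,
    }
    return d


def config_from_dict(d: dict) -> ScenarioConfig:
    d = dict(d)
    grid = d.pop("t_rec_grid", None)
    return ScenarioConfig(
        species=tuple(OligomerSpecies(**s) for s in d.pop("species")),
        geometry=CellGeometry(**d.pop("geometry")),
        profile=LaserProfile(**d.pop("profile")),
        bleach=BleachModel(**d.pop("bleach")),
        rule=ColocalizationRule(**d.pop("rule")),
        t_rec_grid=tuple(grid) if grid is not None else None,
        **d,
    )


def save_manifest(config: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"config": config_to_dict(config), "version": __version__}, fh, sort_keys=False)


def load_manifest(path) -> ScenarioConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data["config"])
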