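"""Post-recovery analysis: colocalization, detection, density profiles, analysis region.

After the bleach pulse and a recovery interval, unbleached molecules have
repopulated the photobleached area from outside.  In diffraction-limited
imaging, molecules closer than a threshold distance ``R`` cannot be told
apart, so groups of nearby molecules are detected as one "apparent n-mer"
whose fluorescent state is the sum over the group.  To bound the rate of
such random colocalizations, analysis is restricted to a central disk in
which the recovered molecule density stays below a cutoff density
``rho_crit`` derived from the accepted colocalization probability.  The
disk radius is obtained by fitting an erf-shaped recovery profile to
ring-binned radial densities and intersecting the fit with ``rho_crit``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, curve_fit
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.special import erf

from .core import ConfigurationError

__all__ = [
    "ColocalizationRule",
    "DetectionEvent",
    "DensityProfile",
    "DensityFit",
    "AnalysisRegion",
    "p_coloc",
    "rho_crit",
    "detect_apparent_nmers",
    "radial_density_profile",
    "RingAccumulator",
    "fit_density_profile",
    "analysis_region",
    "fit_cubic_optimum",
]

RING_SPACING = 0.01  # ring outer-radius spacing, um (10 nm)


@dataclass(frozen=True)
class ColocalizationRule:
    """Diffraction-limited grouping rule.

    ``R`` is the colocalization threshold distance (um): molecules with
    pairwise distance <= R are indistinguishable.  ``p_coloc_max`` is the
    largest accepted probability of a random colocalization, which sets the
    cutoff density via :func:`rho_crit`.  Events with summed fluorescent
    state above ``n_cap_factor * m_max`` are discarded.
    """

    R: float = 0.3
    p_coloc_max: float = 0.2
    n_cap_factor: int = 5

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ConfigurationError(f"threshold distance must be > 0, got {self.R}")
        if not 0.0 < self.p_coloc_max < 1.0:
            raise ConfigurationError(f"p_coloc_max must lie in (0, 1), got {self.p_coloc_max}")
        if self.n_cap_factor < 1:
            raise ConfigurationError("n_cap_factor must be >= 1")

    @property
    def rho_crit(self) -> float:
        return rho_crit(self.p_coloc_max, self.R)


def p_coloc(rho, R: float):
    """Probability that a randomly placed molecule has a neighbor within ``R``.

    For a 2D Poisson point field of density ``rho`` (molecules/um^2) the
    nearest-neighbor distance is Rayleigh distributed, giving
    ``1 - exp(-R**2 * pi * rho)``.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("density must be >= 0")
    out = 1.0 - np.exp(-(R**2) * np.pi * rho)
    return float(out) if out.ndim == 0 else out


def rho_crit(p_coloc_max: float, R: float) -> float:
    """Cutoff density at which the random-colocalization probability reaches
    ``p_coloc_max``; exact inverse of :func:`p_coloc`."""
    if not 0.0 < p_coloc_max < 1.0:
        raise ValueError(f"p_coloc_max must lie in (0, 1), got {p_coloc_max}")
    return float(-np.log(1.0 - p_coloc_max) / (R**2 * np.pi))


@dataclass(frozen=True)
class AnalysisRegion:
    """Central disk within which detections are accepted."""

    center: tuple[float, float]
    r_analysis: float
    rho_crit: float

    @property
    def area(self) -> float:
        return np.pi * self.r_analysis**2


@dataclass(frozen=True)
class DetectionEvent:
    """One apparent n-mer: a group of mutually colocalized visible molecules.

    ``n`` is the summed fluorescent state over the group, ``member_ids``
    index into the analyzed ensemble, ``member_m`` are the constituent true
    oligomeric states, and ``coloc_flag`` marks events grouping two or more
    molecules (random colocalizations).
    """

    n: int
    member_ids: tuple[int, ...]
    member_m: tuple[int, ...]
    member_n: tuple[int, ...]
    coloc_flag: bool
    anchor: tuple[float, float]

    @property
    def is_true_mmer(self) -> bool:
        """Single nonphotobleached molecule detected alone (n == m)."""
        return not self.coloc_flag and self.member_m[0] == self.n


def _ensemble_arrays(ensemble):
    """Positions / n / m from a MoleculeEnsemble or any snapshot-like object."""
    return (
        np.asarray(ensemble.positions, dtype=float),
        np.asarray(ensemble.n),
        np.asarray(ensemble.m),
    )


def detect_apparent_nmers(
    ensemble,
    region: AnalysisRegion,
    rule: ColocalizationRule,
    m_max: int | None = None,
) -> list[DetectionEvent]:
    """Group visible molecules into apparent n-mer detection events.

    Visible molecules (``n >= 1``) are linked whenever their pairwise
    distance is <= ``R`` and grouped into connected components
    (single-linkage), so chains of pairwise-close molecules form one event
    even when some members lie outside the analysis region.  An event is
    kept if at least one member lies inside the region
    (``distance to center <= r_analysis``) and its summed fluorescent state
    does not exceed ``n_cap_factor * m_max``.  Dark molecules (``n = 0``)
    never participate.  Each molecule belongs to at most one event.
    """
    pos, n, m = _ensemble_arrays(ensemble)
    if m_max is None:
        m_max = int(m.max()) if m.size else 1
    cap = rule.n_cap_factor * m_max

    vis = np.flatnonzero(n >= 1)
    if vis.size == 0:
        return []
    pos_v = pos[vis]
    center = np.asarray(region.center, dtype=float)
    r_center = np.hypot(pos_v[:, 0] - center[0], pos_v[:, 1] - center[1])

    # Any keepable event is confined to r_analysis + cap * R (a chain that
    # reaches farther must have more than cap members, hence n > cap), so
    # restricting the component search to a slightly larger disk is exact.
    buffer_r = region.r_analysis + (cap + 1) * rule.R
    cand = np.flatnonzero(r_center <= buffer_r)
    if cand.size == 0:
        return []
    pos_c = pos_v[cand]
    r_c = r_center[cand]

    tree = cKDTree(pos_c)
    pairs = tree.query_pairs(rule.R, output_type="ndarray")
    k = cand.size
    if pairs.size:
        data = np.ones(pairs.shape[0], dtype=np.int8)
        graph = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(k, k))
        n_comp, labels = connected_components(graph, directed=False)
    else:
        n_comp, labels = k, np.arange(k)

    inside = r_c <= region.r_analysis
    n_sum = np.bincount(labels, weights=n[vis[cand]], minlength=n_comp)
    any_inside = np.bincount(labels, weights=inside, minlength=n_comp) > 0
    keep = any_inside & (n_sum >= 1) & (n_sum <= cap)

    order = np.argsort(labels, kind="stable")
    bounds = np.searchsorted(labels[order], np.arange(n_comp + 1))
    events: list[DetectionEvent] = []
    for comp in np.flatnonzero(keep):
        members_c = order[bounds[comp] : bounds[comp + 1]]
        members = vis[cand[members_c]]
        inside_members = members_c[inside[members_c]]
        anchor_c = inside_members[0] if inside_members.size else members_c[0]
        events.append(
            DetectionEvent(
                n=int(n_sum[comp]),
                member_ids=tuple(int(i) for i in members),
                member_m=tuple(int(v) for v in m[members]),
                member_n=tuple(int(v) for v in n[members]),
                coloc_flag=members.size >= 2,
                anchor=(float(pos_c[anchor_c, 0]), float(pos_c[anchor_c, 1])),
            )
        )
    return events


@dataclass
class DensityProfile:
    """Ring-binned radial density of visible molecules around the aperture center.

    Rings have outer radii ``RING_SPACING, 2*RING_SPACING, ... , 1.5*d_ap``;
    a molecule at radius ``r`` falls in the ring whose half-open interval
    ``(r_outer - spacing, r_outer]`` contains it (the innermost ring is the
    full disk of radius ``RING_SPACING``).  ``mean_count`` is the average
    molecule count per ring over the contributing simulation runs.
    """

    d_ap: float
    r_outer: np.ndarray
    mean_count: np.ndarray
    n_runs: int

    @property
    def ring_area(self) -> np.ndarray:
        r_in = self.r_outer - RING_SPACING
        return np.pi * (self.r_outer**2 - r_in**2)

    @property
    def density(self) -> np.ndarray:
        return self.mean_count / self.ring_area


class RingAccumulator:
    """Streaming accumulation of ring counts over simulation runs."""

    def __init__(self, d_ap: float):
        self.d_ap = d_ap
        self.n_rings = int(round(1.5 * d_ap / RING_SPACING))
        self.counts = np.zeros(self.n_rings, dtype=np.int64)
        self.n_runs = 0

    def add_radii(self, radii: np.ndarray) -> None:
        """Add one run's visible-molecule radial distances (um)."""
        bins = np.ceil(np.asarray(radii, dtype=float) / RING_SPACING).astype(np.int64)
        bins[bins == 0] = 1  # r == 0 falls in the innermost disk
        bins = bins[bins <= self.n_rings]
        self.counts += np.bincount(bins - 1, minlength=self.n_rings)
        self.n_runs += 1

    def profile(self) -> DensityProfile:
        if self.n_runs == 0:
            raise ValueError("no runs accumulated")
        r_outer = RING_SPACING * np.arange(1, self.n_rings + 1)
        return DensityProfile(
            d_ap=self.d_ap,
            r_outer=r_outer,
            mean_count=self.counts / self.n_runs,
            n_runs=self.n_runs,
        )


def radial_density_profile(runs: Sequence, d_ap: float, center=None) -> DensityProfile:
    """Ring-binned radial density profile averaged over post-recovery runs.

    Counts molecules with fluorescent state ``0 < n <= m`` in concentric
    rings around the aperture center.
    """
    runs = list(runs)
    if not runs:
        raise ValueError("at least one run is required")
    acc = RingAccumulator(d_ap)
    for run in runs:
        pos, n, _ = _ensemble_arrays(run)
        if center is None:
            cx = cy = run.L / 2.0
        else:
            cx, cy = center
        vis = n >= 1
        radii = np.hypot(pos[vis, 0] - cx, pos[vis, 1] - cy)
        acc.add_radii(radii)
    return acc.profile()


def _recovery_profile(r, rho0, d_prime, tau):
    """Erf-shaped radial recovery profile of a photobleached disk."""
    return rho0 * (1.0 - 0.5 * erf((r + d_prime / 2.0) / tau) + 0.5 * erf((r - d_prime / 2.0) / tau))


@dataclass(frozen=True)
class DensityFit:
    """Fitted erf recovery profile: plateau density ``rho0`` (molecules/um^2),
    effective depleted width ``d_prime`` (um) and spread scale
    ``tau = sqrt(4 D' t')`` (um), fitted for ``r <= fit_r_max``."""

    rho0: float
    d_prime: float
    tau: float
    fit_r_max: float
    residual_norm: float

    def __call__(self, r):
        out = _recovery_profile(np.asarray(r, dtype=float), self.rho0, self.d_prime, self.tau)
        return float(out) if out.ndim == 0 else out


def fit_density_profile(
    profile: DensityProfile,
    fit_r_max: float | None = None,
    d_edge: float = 1.0,
) -> DensityFit:
    """Least-squares fit of the erf recovery profile to ring densities.

    The fit range defaults to ``r <= (d_ap + d_edge) / 2``.  Initial guesses:
    plateau from the outer end of the fit range, depleted width from the
    aperture side, spread from the 16-84% rise width of the data.
    """
    if fit_r_max is None:
        fit_r_max = (profile.d_ap + d_edge) / 2.0
    sel = profile.r_outer <= fit_r_max + 1e-12
    if sel.sum() < 4:
        raise ValueError("fit range contains fewer than 4 rings")
    r = profile.r_outer[sel]
    rho = profile.density[sel]

    rho0_0 = max(float(np.mean(rho[-max(len(rho) // 10, 3) :])), 1e-6)
    lo, hi = 0.16 * rho0_0, 0.84 * rho0_0
    r_lo = r[np.searchsorted(np.maximum.accumulate(rho), lo)] if np.any(rho >= lo) else r[0]
    r_hi = r[np.searchsorted(np.maximum.accumulate(rho), hi)] if np.any(rho >= hi) else r[-1]
    tau_0 = max(float(r_hi - r_lo), 0.05)
    p0 = (rho0_0, profile.d_ap, tau_0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _recovery_profile,
                r,
                rho,
                p0=p0,
                bounds=([0, 0, 1e-6], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
    except (RuntimeError, ValueError) as exc:
        raise RuntimeError(f"density-profile fit did not converge (initial guess {p0})") from exc
    resid = float(np.linalg.norm(_recovery_profile(r, *popt) - rho))
    return DensityFit(
        rho0=float(popt[0]),
        d_prime=float(popt[1]),
        tau=float(popt[2]),
        fit_r_max=float(fit_r_max),
        residual_norm=resid,
    )


def analysis_region(
    fit: DensityFit,
    rho_crit_value: float,
    center: tuple[float, float],
) -> AnalysisRegion:
    """Largest radius where the fitted density equals the cutoff density.

    The fitted erf profile is monotone increasing in ``r``, so the crossing
    is unique and found by bracketed root search.  If the fitted density
    never reaches the cutoff within the fit range the region is capped at
    the fit-range boundary (with a warning); if even the center exceeds the
    cutoff the region degenerates to radius 0 (with a warning).
    """
    lo, hi = 0.0, fit.fit_r_max
    if fit(hi) < rho_crit_value:
        warnings.warn(
            "fitted density stays below the cutoff within the fit range; "
            "capping the analysis region at the fit-range boundary",
            stacklevel=2,
        )
        r = hi
    elif fit(lo) > rho_crit_value:
        warnings.warn(
            "fitted density exceeds the cutoff everywhere; degenerate analysis region",
            stacklevel=2,
        )
        r = 0.0
    else:
        r = brentq(lambda x: fit(x) - rho_crit_value, lo, hi, xtol=1e-9)
    return AnalysisRegion(center=center, r_analysis=float(r), rho_crit=rho_crit_value)


def fit_cubic_optimum(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, bool]:
    """Position of the maximum of a cubic polynomial fit, restricted to the
    sampled interval.

    Returns ``(x_opt, coefficients, at_boundary)``; a maximum on the interval
    boundary raises a warning and sets the flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("cubic fit needs at least 4 grid points")
    coeffs = np.polyfit(x, y, 3)
    crit = np.roots(np.polyder(coeffs))
    crit = crit[np.isreal(crit)].real
    crit = crit[(crit >= x.min()) & (crit <= x.max())]
    candidates = np.concatenate([crit, [x.min(), x.max()]])
    values = np.polyval(coeffs, candidates)
    x_opt = float(candidates[np.argmax(values)])
    at_boundary = np.isclose(x_opt, x.min()) or np.isclose(x_opt, x.max())
    if at_boundary:
        warnings.warn(
            f"cubic fit maximum lies on the grid boundary (t = {x_opt}); "
            "consider extending the recovery-time grid",
            stacklevel=2,
        )
    return x_opt, coeffs, bool(at_boundary)
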