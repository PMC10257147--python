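"""Oligomer populations diffusing on a model membrane.

The simulation state is a :class:`MoleculeEnsemble`: point-like oligomer
entities on a square cell of side ``L`` (periodic boundaries), each with a
fixed oligomeric state ``m`` (number of subunits), a fluorescent state ``n``
(number of subunits with an active fluorophore, ``0 <= n <= m``) and, per
subunit, an assignment to one of the two components of the biexponential
photobleaching law.  Positions evolve by 2D Brownian motion: per time step
each coordinate takes an independent Gaussian step with variance
``2 * D * dt``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "OligomerSpecies",
    "CellGeometry",
    "MoleculeEnsemble",
    "ConfigurationError",
    "init_ensemble",
    "diffuse",
    "species_counts",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its contract."""


@dataclass(frozen=True)
class OligomerSpecies:
    """One oligomer population.

    Parameters
    ----------
    label:
        Human-readable name (e.g. ``"dimer"``).
    m:
        Oligomeric state, i.e. number of subunits per entity (``m >= 1``).
    D:
        Lateral diffusion coefficient in um^2/s (``D >= 0``).
    fraction:
        Mixture fraction of *entities* belonging to this species.
    """

    label: str
    m: int
    D: float
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ConfigurationError(f"oligomeric state m must be >= 1, got {self.m}")
        if self.D < 0:
            raise ConfigurationError(f"diffusion coefficient must be >= 0, got {self.D}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigurationError(f"fraction must lie in [0, 1], got {self.fraction}")


@dataclass(frozen=True)
class CellGeometry:
    """Square simulated membrane patch ("cell area").

    ``L`` is the side length in um and ``density`` the number of oligomer
    entities per um^2; the total entity count is ``round(density * L**2)``.
    """

    L: float = 21.0
    density: float = 100.0

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ConfigurationError(f"cell side length must be > 0, got {self.L}")
        if self.density <= 0:
            raise ConfigurationError(f"density must be > 0, got {self.density}")

    @property
    def n_molecules(self) -> int:
        return int(round(self.density * self.L * self.L))

    @property
    def center(self) -> tuple[float, float]:
        return (self.L / 2.0, self.L / 2.0)


def _validate_fractions(species: Sequence[OligomerSpecies]) -> None:
    total = sum(s.fraction for s in species)
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(
            f"species fractions must sum to 1 (got {total!r} over {len(species)} species)"
        )


def species_counts(n_total: int, species: Sequence[OligomerSpecies]) -> np.ndarray:
    """Deterministic entity counts per species (largest-remainder rounding).

    Guarantees ``counts.sum() == n_total`` so that e.g. a 1:1 monomer/dimer
    mixture is split exactly, independent of the RNG.
    """
    _validate_fractions(species)
    fractions = np.array([s.fraction for s in species], dtype=float)
    ideal = fractions * n_total
    counts = np.floor(ideal).astype(np.int64)
    remainder = n_total - counts.sum()
    if remainder > 0:
        order = np.argsort(-(ideal - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts


@dataclass
class MoleculeEnsemble:
    """State of all simulated molecules at time ``t``.

    Arrays are aligned on the molecule axis (length ``N``); subunit arrays
    have shape ``(N, m_max)`` with the trailing columns beyond each
    molecule's ``m`` permanently inactive (padding).

    Attributes
    ----------
    positions:
        ``(N, 2)`` coordinates in um, each in ``[0, L)``.
    species_index:
        Index into :attr:`species` per molecule.
    m:
        Oligomeric state per molecule (never changes).
    n:
        Fluorescent state per molecule; equals the number of set flags in
        :attr:`subunit_active` and is non-increasing over time.
    subunit_active:
        Boolean flag per subunit; cleared irreversibly by photobleaching.
    subunit_ibiex:
        Photobleaching component per subunit: 1 (fast, rate alpha) or
        2 (slow, rate beta); 0 marks padding columns.
    """

    L: float
    species: tuple[OligomerSpecies, ...]
    positions: np.ndarray
    species_index: np.ndarray
    m: np.ndarray
    n: np.ndarray
    subunit_active: np.ndarray
    subunit_ibiex: np.ndarray
    t: float = 0.0

    @property
    def n_molecules(self) -> int:
        return self.positions.shape[0]

    @property
    def m_max(self) -> int:
        """Largest oligomeric state among the initially assigned species."""
        return max(s.m for s in self.species)

    @property
    def D_per_molecule(self) -> np.ndarray:
        D_by_species = np.array([s.D for s in self.species], dtype=float)
        return D_by_species[self.species_index]

    def visible(self) -> np.ndarray:
        """Boolean mask of molecules with at least one active fluorophore."""
        return self.n > 0

    def copy(self) -> "MoleculeEnsemble":
        return MoleculeEnsemble(
            L=self.L,
            species=self.species,
            positions=self.positions.copy(),
            species_index=self.species_index.copy(),
            m=self.m.copy(),
            n=self.n.copy(),
            subunit_active=self.subunit_active.copy(),
            subunit_ibiex=self.subunit_ibiex.copy(),
            t=self.t,
        )

    def check_invariants(self) -> None:
        """Assert internal consistency (used by tests; O(N * m_max))."""
        assert np.all((self.positions >= 0.0) & (self.positions < self.L))
        assert np.array_equal(self.subunit_active.sum(axis=1), self.n)
        assert np.all((self.n >= 0) & (self.n <= self.m))
        cols = np.arange(self.subunit_active.shape[1])
        padding = cols[None, :] >= self.m[:, None]
        assert not np.any(self.subunit_active[padding])
        assert np.all(self.subunit_ibiex[padding] == 0)
        assert np.all(np.isin(self.subunit_ibiex[~padding], (1, 2)))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def init_ensemble(
    geometry: CellGeometry,
    species: Sequence[OligomerSpecies],
    weights_AB: tuple[float, float] = (0.782, 0.218),
    seed=None,
) -> MoleculeEnsemble:
    """Place molecules uniformly at random and initialise all states.

    Every molecule starts fully fluorescent (``n = m``); each subunit is
    independently assigned to the fast photobleaching component with
    probability ``A`` (else the slow one), where ``weights_AB = (A, B)``
    are the normalized weights of the biexponential bleach curve.
    """
    species = tuple(species)
    if not species:
        raise ConfigurationError("at least one species is required")
    A, B = weights_AB
    if abs(A + B - 1.0) > 1e-9 or A < 0 or B < 0:
        raise ConfigurationError(f"weights A and B must be >= 0 and sum to 1, got {weights_AB}")
    n_total = geometry.n_molecules
    if n_total <= 0:
        raise ConfigurationError("total molecule count must be positive")

    rng = _as_rng(seed)
    counts = species_counts(n_total, species)
    species_index = np.repeat(np.arange(len(species)), counts).astype(np.int32)
    m = np.array([s.m for s in species], dtype=np.int16)[species_index]
    m_max = int(m.max())

    positions = rng.uniform(0.0, geometry.L, size=(n_total, 2))
    cols = np.arange(m_max)
    subunit_active = cols[None, :] < m[:, None]
    ibiex = np.where(rng.random(size=(n_total, m_max)) < A, 1, 2).astype(np.uint8)
    ibiex[~subunit_active] = 0

    return MoleculeEnsemble(
        L=geometry.L,
        species=species,
        positions=positions,
        species_index=species_index,
        m=m,
        n=m.astype(np.int16).copy(),
        subunit_active=subunit_active,
        subunit_ibiex=ibiex,
        t=0.0,
    )


def _step_sigma(ensemble: MoleculeEnsemble, dt: float) -> np.ndarray:
    """Per-molecule Gaussian step std for one step of length ``dt``."""
    sigma_by_species = np.sqrt(2.0 * dt * np.array([s.D for s in ensemble.species]))
    return sigma_by_species[ensemble.species_index]


def diffuse_inplace(
    ensemble: MoleculeEnsemble,
    dt: float,
    n_steps: int,
    rng: np.random.Generator,
    subset: np.ndarray | None = None,
) -> None:
    """Advance Brownian motion in place; periodic wrap applied per step.

    ``subset`` (an index array) restricts position updates to a subgroup of
    molecules; time still advances for the whole ensemble, so callers using
    it must account for the remaining displacement themselves.
    """
    if dt <= 0:
        raise ConfigurationError(f"time step must be > 0, got {dt}")
    if n_steps < 0:
        raise ConfigurationError(f"number of steps must be >= 0, got {n_steps}")
    pos = ensemble.positions if subset is None else ensemble.positions[subset]
    sigma = _step_sigma(ensemble, dt)
    sigma = sigma if subset is None else sigma[subset]
    n = pos.shape[0]
    for _ in range(n_steps):
        steps = rng.standard_normal((n, 2))
        steps *= sigma[:, None]
        pos += steps
        np.mod(pos, ensemble.L, out=pos)
    if subset is not None:
        ensemble.positions[subset] = pos
    ensemble.t += n_steps * dt


def diffuse(ensemble: MoleculeEnsemble, dt: float, n_steps: int, seed=None) -> MoleculeEnsemble:
    """Return a copy of ``ensemble`` diffused for ``n_steps`` steps of ``dt``.

    Each coordinate of each molecule is incremented per step by an
    independent draw from N(0, 2 * D * dt); molecules leaving the cell
    re-enter on the opposite side.  Identity, ``m``, ``n`` and subunit
    states are unchanged.
    """
    out = ensemble.copy()
    diffuse_inplace(out, dt, n_steps, _as_rng(seed))
    return out
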