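"""Minimal metadynamics engine on toy energy surfaces.

Implements the biasing math of binding-pose metadynamics at desk scale:
an RMSD collective variable over a ligand atom selection, Gaussian hill
deposition along that CV, and overdamped (Euler-Maruyama) Langevin dynamics
on analytic potentials.  The engine generates multi-trial ensembles that
feed the stability-scoring module and lets the bias/free-energy arithmetic
be validated against closed forms; it makes no attempt at solvated or
membrane systems.

Units: Angstrom, kcal/mol, ps.  kB = 0.0019872041 kcal/(mol K).
Default hill parameters (height 0.05 kcal/mol, width 0.02 A, deposition
every 100 steps) follow the published binding-pose-metadynamics protocol;
a trial records 50 frames regardless of step count, preserving the
10 ns / 200 ps production-to-frame ratio in toy units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .structio import MolecularStructure, Trajectory, TrajectoryEnsemble, rmsd_fixed

__all__ = [
    "KB",
    "CVDefinition",
    "HillStore",
    "ToySystem",
    "cv_value",
    "bias_energy",
    "bias_force",
    "run_trial",
    "run_ensemble",
    "reconstruct_fes",
]

KB = 0.0019872041  # kcal/(mol K)
FRAMES_PER_TRIAL = 50


@dataclass
class CVDefinition:
    """RMSD collective variable: selected atoms vs their starting positions."""

    atom_selection: np.ndarray  # indices into the system coordinate array
    reference: np.ndarray  # (n_sel, 3) starting coordinates

    def __post_init__(self) -> None:
        self.atom_selection = np.asarray(self.atom_selection, dtype=int)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.atom_selection.size == 0:
            raise ValueError("CV atom selection must be non-empty")
        if self.reference.shape != (self.atom_selection.size, 3):
            raise ValueError("CV reference shape mismatch with selection")


@dataclass
class HillStore:
    """Deposited Gaussian hills along the CV, in deposition order."""

    height: float = 0.05  # kcal/mol
    width: float = 0.02  # Angstrom
    deposition_interval: int = 100  # steps
    centers: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("hill height and width must be positive")
        if self.deposition_interval < 1:
            raise ValueError("deposition interval must be >= 1")

    def add(self, center: float) -> None:
        self.centers.append(float(center))


@dataclass
class ToySystem:
    """Analytic-potential particle system for desk-scale trials.

    ``potential(coords)`` returns kcal/mol, ``gradient(coords)`` its
    derivative (same shape as coords).  ``mobile`` marks integrated atoms;
    frozen atoms keep their initial coordinates (a rigid receptor cage).
    """

    potential: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray]
    coords: np.ndarray
    temperature: float = 300.0  # K
    friction: float = 1.0  # 1/ps
    mobile: np.ndarray | None = None
    template: MolecularStructure | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("system coords must be (N, 3)")
        if self.mobile is None:
            self.mobile = np.arange(self.coords.shape[0])
        self.mobile = np.asarray(self.mobile, dtype=int)


def cv_value(cv: CVDefinition, coords: np.ndarray) -> float:
    """Current CV: fixed-correspondence RMSD of the selection vs reference."""
    coords = np.asarray(coords, dtype=float)
    if np.max(cv.atom_selection) >= coords.shape[0]:
        raise ValueError("CV selection exceeds coordinate array")
    return rmsd_fixed(coords[cv.atom_selection], cv.reference)


def bias_energy(store: HillStore, s: float | np.ndarray) -> float | np.ndarray:
    """Sum of deposited Gaussians at CV value(s) ``s``; 0 for an empty store."""
    s = np.asarray(s, dtype=float)
    if not store.centers:
        return float(0.0) if s.ndim == 0 else np.zeros_like(s)
    centers = np.asarray(store.centers)
    e = store.height * np.exp(
        -((s[..., None] - centers) ** 2) / (2.0 * store.width ** 2)
    ).sum(axis=-1)
    return float(e) if e.ndim == 0 else e


def bias_force(store: HillStore, cv: CVDefinition, coords: np.ndarray) -> np.ndarray:
    """Per-atom bias force −dE_bias/ds · ds/dx.

    The RMSD gradient is undefined at s = 0; by convention the force is zero
    there (and whenever the store is empty).
    """
    coords = np.asarray(coords, dtype=float)
    forces = np.zeros_like(coords)
    if not store.centers:
        return forces
    s = cv_value(cv, coords)
    if s <= 0.0:
        return forces
    centers = np.asarray(store.centers)
    # dE/ds of the Gaussian sum
    de_ds = float(np.sum(
        store.height * (-(s - centers) / store.width ** 2)
        * np.exp(-((s - centers) ** 2) / (2.0 * store.width ** 2))
    ))
    m = cv.atom_selection.size
    ds_dx = (coords[cv.atom_selection] - cv.reference) / (m * s)
    forces[cv.atom_selection] = -de_ds * ds_dx
    return forces


def _frame_interval(n_steps: int, frames: int = FRAMES_PER_TRIAL) -> int:
    return max(1, n_steps // frames)


def run_trial(system: ToySystem, cv: CVDefinition | None,
              hill_params: HillStore | None, n_steps: int, seed: int,
              dt: float = 0.01, frame_interval: int | None = None,
              ) -> tuple[Trajectory, HillStore]:
    """One overdamped-Langevin trial with optional metadynamics bias.

    Euler-Maruyama: dx = (F/γ) dt + sqrt(2 kB T dt / γ) ξ, with unit-mass
    mobility 1/γ.  Hills are deposited at the current CV every
    ``hill_params.deposition_interval`` steps; frames are recorded every
    ``frame_interval`` steps (default n_steps/50), frame 0 included.  The
    same seed reproduces the trajectory bit for bit.
    """
    if frame_interval is None:
        frame_interval = _frame_interval(n_steps)
    if n_steps < frame_interval:
        raise ValueError("n_steps must be >= frame_interval")
    store = HillStore(
        height=hill_params.height, width=hill_params.width,
        deposition_interval=hill_params.deposition_interval,
    ) if hill_params is not None else None
    rng = np.random.default_rng(seed)
    x = system.coords.copy()
    mob = system.mobile
    noise_scale = np.sqrt(2.0 * KB * system.temperature * dt / system.friction)
    frames = [x.copy()]
    times = [0.0]
    for step in range(1, n_steps + 1):
        f = -system.gradient(x)
        if store is not None and cv is not None:
            if (step - 1) % store.deposition_interval == 0:
                store.add(cv_value(cv, x))
            f = f + bias_force(store, cv, x)
        if not np.all(np.isfinite(f)):
            raise FloatingPointError(f"non-finite force at step {step}")
        x = x.copy()
        x[mob] += (f[mob] / system.friction) * dt
        x[mob] += noise_scale * rng.standard_normal((mob.size, 3))
        if step % frame_interval == 0:
            frames.append(x.copy())
            times.append(step * dt)
    traj = Trajectory(np.array(frames), np.array(times))
    return traj, store if store is not None else HillStore()


def run_ensemble(system: ToySystem, cv: CVDefinition | None,
                 hill_params: HillStore | None, n_steps: int,
                 n_trials: int = 10, seeds: list[int] | None = None,
                 dt: float = 0.01, frame_interval: int | None = None,
                 ) -> tuple[TrajectoryEnsemble, list[HillStore]]:
    """Independent repeated trials packaged for stability scoring.

    Default seed policy: trial i uses seed i.  Duplicate seeds are rejected
    (trials must be independent).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if seeds is None:
        seeds = list(range(n_trials))
    if len(seeds) != n_trials:
        raise ValueError("need one seed per trial")
    if len(set(seeds)) != len(seeds):
        raise ValueError("duplicate seeds across trials")
    trials = []
    stores = []
    for s in seeds:
        traj, store = run_trial(system, cv, hill_params, n_steps, seed=s,
                                dt=dt, frame_interval=frame_interval)
        trials.append(traj)
        stores.append(store)
    if system.template is None:
        raise ValueError("system.template required to package an ensemble")
    return TrajectoryEnsemble(trials, system.template), stores


def reconstruct_fes(store: HillStore, grid: np.ndarray,
                    average_last_frac: float | None = None) -> np.ndarray:
    """Free-energy estimate on a CV grid: F(s) = −E_bias(s), min-shifted to 0.

    Standard non-tempered estimator; meaningful only once the bias has
    roughly filled the sampled basins.  With ``average_last_frac`` the
    estimate is instead the time average of −E_bias over the final fraction
    of hill depositions, which damps the oscillation of the instantaneous
    bias around the converged surface.
    """
    if not store.centers:
        raise ValueError("empty hill store: nothing to reconstruct")
    grid = np.asarray(grid, dtype=float)
    if average_last_frac is None:
        f = -bias_energy(store, grid)
    else:
        if not 0.0 < average_last_frac <= 1.0:
            raise ValueError("average_last_frac must be in (0, 1]")
        centers = np.asarray(store.centers)
        contrib = store.height * np.exp(
            -((grid[None, :] - centers[:, None]) ** 2) / (2.0 * store.width ** 2))
        cumulative = np.cumsum(contrib, axis=0)
        start = min(len(centers) - 1,
                    int((1.0 - average_last_frac) * len(centers)))
        f = -cumulative[start:].mean(axis=0)
    return f - f.min()
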