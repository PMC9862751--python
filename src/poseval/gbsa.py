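"""Single-trajectory MM/GBSA-style binding free-energy estimation.

ΔG_bind = G(complex) − G(receptor) − G(ligand), with every G evaluated on
the same complex frame (no re-minimization of the separated species) as

    G = E_Coulomb + E_LJ + G_GB + γ·SASA

E_Coulomb is the bare pairwise Coulomb sum (332.0636·q_i·q_j/r_ij), E_LJ a
Lorentz–Berthelot 12-6 Lennard-Jones sum, G_GB the Still pairwise
generalized-Born polar solvation term over HCT/OBC effective radii, and the
nonpolar term a surface-tension γ times a Shrake–Rupley solvent-accessible
surface area computed on a deterministic Fibonacci sphere point set (results
are bit-stable).  Per-atom parameters (charge, LJ, GB radius/screening)
come from the sidecar CSV — no force field is bundled, so absolute values
are only as meaningful as the parameters supplied; the component
arithmetic, sign conventions and ΔΔG logic are the point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import MolecularStructure

__all__ = [
    "COULOMB_CONST",
    "EnergyBreakdown",
    "GBParams",
    "coulomb_energy",
    "lj_energy",
    "born_radii",
    "gb_polar_energy",
    "sasa",
    "free_energy",
    "delta_g_bind",
    "delta_delta_g",
]

COULOMB_CONST = 332.0636  # kcal·Å/(mol·e²)

# fallback vdW radii for SASA when no gb_radius is supplied
_VDW = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8,
        "F": 1.47, "Cl": 1.75, "Br": 1.85, "I": 1.98}


@dataclass
class EnergyBreakdown:
    e_coulomb: float
    e_lj: float
    g_gb: float
    g_sa: float

    @property
    def total(self) -> float:
        return self.e_coulomb + self.e_lj + self.g_gb + self.g_sa

    def __sub__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(
            self.e_coulomb - other.e_coulomb,
            self.e_lj - other.e_lj,
            self.g_gb - other.g_gb,
            self.g_sa - other.g_sa,
        )


@dataclass
class GBParams:
    """Generalized-Born / surface-area model parameters.

    ``gb_offset`` shrinks intrinsic radii before descreening integration
    (0 keeps an isolated atom's effective radius equal to its intrinsic
    radius).  OBC rescaling constants alpha/beta/gamma follow the standard
    second parameterization.
    """

    eps_in: float = 1.0
    eps_out: float = 78.5
    surface_tension: float = 0.0072  # kcal/(mol·Å²)
    probe_radius: float = 1.4  # Å
    sasa_points: int = 960
    gb_offset: float = 0.0  # Å
    obc_alpha: float = 1.0
    obc_beta: float = 0.8
    obc_gamma: float = 4.85

    def __post_init__(self) -> None:
        if not self.eps_out > self.eps_in >= 1.0:
            raise ValueError("require eps_out > eps_in >= 1")


def _require(structure: MolecularStructure, attrs: tuple[str, ...]) -> None:
    missing = [a.serial for a in structure.atoms
               if any(getattr(a, att) is None for att in attrs)]
    if missing:
        raise ValueError(f"atoms missing {attrs} parameters: serials {missing}")


def _pair_distances(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=-1))


def coulomb_energy(structure: MolecularStructure) -> float:
    """Pairwise Coulomb sum over all i<j, no cutoff (kcal/mol)."""
    _require(structure, ("charge",))
    q = np.array([a.charge for a in structure.atoms])
    if len(q) < 2:
        return 0.0
    r = _pair_distances(structure.coords)
    iu = np.triu_indices(len(q), k=1)
    return float(COULOMB_CONST * np.sum(q[iu[0]] * q[iu[1]] / r[iu]))


def lj_energy(structure: MolecularStructure) -> float:
    """12-6 Lennard-Jones sum with Lorentz–Berthelot mixing (kcal/mol)."""
    _require(structure, ("lj_sigma", "lj_epsilon"))
    sig = np.array([a.lj_sigma for a in structure.atoms])
    eps = np.array([a.lj_epsilon for a in structure.atoms])
    n = len(sig)
    if n < 2:
        return 0.0
    r = _pair_distances(structure.coords)
    iu = np.triu_indices(n, k=1)
    sij = 0.5 * (sig[iu[0]] + sig[iu[1]])
    eij = np.sqrt(eps[iu[0]] * eps[iu[1]])
    sr6 = (sij / r[iu]) ** 6
    return float(np.sum(4.0 * eij * (sr6 * sr6 - sr6)))


def born_radii(structure: MolecularStructure,
               params: GBParams | None = None) -> np.ndarray:
    """Effective Born radii via HCT pairwise descreening with OBC rescaling.

    An isolated atom's effective radius equals its intrinsic radius (with
    the default zero offset); burying an atom grows its effective radius.
    """
    params = params or GBParams()
    _require(structure, ("gb_radius", "gb_screen"))
    rho = np.array([a.gb_radius for a in structure.atoms]) - params.gb_offset
    scr = np.array([a.gb_screen for a in structure.atoms])
    if np.any(rho <= 0):
        raise ValueError("nonpositive intrinsic GB radius after offset")
    n = len(rho)
    coords = structure.coords
    integral = np.zeros(n)
    if n > 1:
        r = _pair_distances(coords)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                rij = r[i, j]
                srj = scr[j] * rho[j]
                if rij >= rho[i] + srj:
                    lij = rij - srj
                    uij = rij + srj
                elif rij > abs(rho[i] - srj):
                    lij = rho[i]
                    uij = rij + srj
                elif rho[i] < srj:
                    lij = srj - rij
                    uij = rij + srj
                else:
                    continue  # descreener fully inside atom i
                integral[i] += 0.5 * (
                    1.0 / lij - 1.0 / uij
                    + 0.25 * (rij - srj ** 2 / rij) * (1.0 / uij ** 2 - 1.0 / lij ** 2)
                    + 0.5 * np.log(lij / uij) / rij
                )
    psi = integral * rho
    arg = params.obc_alpha * psi - params.obc_beta * psi ** 2 + params.obc_gamma * psi ** 3
    inv_eff = 1.0 / rho - np.tanh(arg) / rho
    # guard: effective radius must stay positive and >= intrinsic behaviour
    inv_eff = np.clip(inv_eff, 1e-6, None)
    return 1.0 / inv_eff


def gb_polar_energy(structure: MolecularStructure, radii: np.ndarray,
                    params: GBParams | None = None) -> float:
    """Still's pairwise GB polar solvation energy (kcal/mol).

    −(k/2)·(1/eps_in − 1/eps_out)·Σ_ij q_i q_j / f_GB with
    f_GB = sqrt(r² + R_i R_j exp(−r²/(4 R_i R_j))); the i=j self terms give
    the Born limit for an isolated ion.
    """
    params = params or GBParams()
    _require(structure, ("charge",))
    q = np.array([a.charge for a in structure.atoms])
    radii = np.asarray(radii, dtype=float)
    r2 = _pair_distances(structure.coords) ** 2
    rirj = radii[:, None] * radii[None, :]
    f_gb = np.sqrt(r2 + rirj * np.exp(-r2 / (4.0 * rirj)))
    pref = -0.5 * COULOMB_CONST * (1.0 / params.eps_in - 1.0 / params.eps_out)
    return float(pref * np.sum(np.outer(q, q) / f_gb))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def sasa(structure: MolecularStructure, probe: float = 1.4,
         n_points: int = 960) -> tuple[np.ndarray, float]:
    """Shrake–Rupley solvent-accessible surface area.

    Each atom's solvent sphere (radius + probe) is sampled with a fixed
    Fibonacci point set; a point is exposed when outside every neighbor's
    solvent sphere.  Exactly coincident spheres count once (the lowest-index
    atom keeps the surface).  Returns (per-atom Å², total Å²).
    """
    radii = np.array([
        a.gb_radius if a.gb_radius is not None else _VDW.get(a.element, 1.7)
        for a in structure.atoms
    ])
    coords = structure.coords
    n = len(radii)
    solv = radii + probe
    unit = _fibonacci_sphere(n_points)
    areas = np.zeros(n)
    for i in range(n):
        pts = coords[i] + solv[i] * unit
        exposed = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            dij = np.linalg.norm(coords[i] - coords[j])
            if dij > solv[i] + solv[j]:
                continue
            if dij < 1e-9:  # coincident spheres: larger (or earlier) one wins
                if solv[j] > solv[i] or (solv[j] == solv[i] and j < i):
                    exposed[:] = False
                    break
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > solv[j] ** 2
        areas[i] = 4.0 * np.pi * solv[i] ** 2 * exposed.sum() / n_points
    return areas, float(areas.sum())


def free_energy(structure: MolecularStructure,
                params: GBParams | None = None) -> EnergyBreakdown:
    """Full G = E_Coulomb + E_LJ + G_GB + γ·SASA of one species."""
    params = params or GBParams()
    radii = born_radii(structure, params)
    _, total_sasa = sasa(structure, probe=params.probe_radius,
                         n_points=params.sasa_points)
    return EnergyBreakdown(
        e_coulomb=coulomb_energy(structure),
        e_lj=lj_energy(structure),
        g_gb=gb_polar_energy(structure, radii, params),
        g_sa=params.surface_tension * total_sasa,
    )


def delta_g_bind(complex: MolecularStructure,
                 params: GBParams | None = None,
                 ) -> tuple[float, dict[str, EnergyBreakdown]]:
    """Single-frame ΔG_bind = G(complex) − G(receptor) − G(ligand).

    Receptor and ligand geometries are extracted from the complex frame by
    role mask; more favorable binding is more negative.  Returns the value
    and the component breakdowns (including the per-component delta).
    """
    rec_idx = complex.indices(role="receptor")
    lig_idx = complex.indices(role="ligand")
    if len(rec_idx) == 0 or len(lig_idx) == 0:
        raise ValueError("complex must carry both receptor and ligand roles")
    if set(rec_idx) & set(lig_idx):
        raise ValueError("receptor/ligand selections overlap")
    g_cpx = free_energy(complex, params)
    g_rec = free_energy(complex.subset(rec_idx), params)
    g_lig = free_energy(complex.subset(lig_idx), params)
    delta = g_cpx - g_rec - g_lig
    return delta.total, {
        "complex": g_cpx, "receptor": g_rec, "ligand": g_lig, "delta": delta,
    }


def delta_delta_g(before: float, after: float) -> float:
    """ΔΔG = ΔG_bind(before) − ΔG_bind(after); positive means the later
    (post-MD) conformation binds more favorably."""
    return float(before - after)
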