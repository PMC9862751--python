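"""Deterministic synthetic fixtures for every analysis module.

These generators build miniature receptor-ligand systems with *planted*,
analytically known properties — interaction inventories, RMSD-drift
plateaus, hydrogen-bond persistence fractions, conformational basin
occupancies, assay threshold counts, dose-response IC50s — so each analysis
module can be validated closed-loop without external data.  Everything is
seed-deterministic: the same parameters produce byte-identical output.

The geometry is deliberately unphysical-but-clean: interaction units are
laid out on a lattice with >= 10 A between units so each planted contact is
the only one its detector can find, and atoms carry complete sidecar-style
parameters (charge, LJ, GB) so the energetics module needs no force field.
None of this emulates real protein geometry; what closed-loop tests show is
that the analysis arithmetic is correct, not that it is accurate on real
complexes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import triage
from .structio import (
    Atom,
    MolecularStructure,
    Trajectory,
    TrajectoryEnsemble,
)

__all__ = [
    "make_toy_complex",
    "make_drift_ensemble",
    "make_hb_ensemble",
    "make_basin_trajectory",
    "make_assay_table",
    "make_dose_response",
    "make_double_well",
]

UNIT_SPACING = 12.0  # A between planted interaction units
MAX_UNITS = 12

# per-element defaults for the sidecar parameters
_PARAMS = {
    "H": dict(charge=0.0, lj_sigma=2.5, lj_epsilon=0.03, gb_radius=1.2, gb_screen=0.85),
    "C": dict(charge=0.0, lj_sigma=3.4, lj_epsilon=0.10, gb_radius=1.7, gb_screen=0.72),
    "N": dict(charge=0.0, lj_sigma=3.25, lj_epsilon=0.17, gb_radius=1.55, gb_screen=0.79),
    "O": dict(charge=0.0, lj_sigma=3.0, lj_epsilon=0.21, gb_radius=1.5, gb_screen=0.85),
    "S": dict(charge=0.0, lj_sigma=3.6, lj_epsilon=0.25, gb_radius=1.8, gb_screen=0.96),
}


class _Builder:
    def __init__(self) -> None:
        self.atoms: list[Atom] = []
        self.roles: list[str] = []
        self.next_res = 1

    def add(self, role: str, name: str, element: str, res_name: str,
            res_id: int, xyz, charge: float | None = None) -> int:
        p = dict(_PARAMS[element])
        if charge is not None:
            p["charge"] = charge
        chain = "L" if role == "ligand" else "A"
        self.atoms.append(Atom(
            serial=len(self.atoms) + 1, name=name, element=element,
            res_name=res_name, res_id=res_id, chain=chain,
            xyz=np.asarray(xyz, dtype=float), **p,
        ))
        self.roles.append(role)
        return len(self.atoms) - 1

    def new_residue(self) -> int:
        r = self.next_res
        self.next_res += 1
        return r

    def build(self, title: str) -> MolecularStructure:
        return MolecularStructure(self.atoms, self.roles, title)


def _hexagon(center: np.ndarray, radius: float = 1.39) -> np.ndarray:
    """Planar hexagon in the xz-plane around ``center`` (normal along y)."""
    ang = np.arange(6) * np.pi / 3.0
    pts = np.zeros((6, 3))
    pts[:, 0] = radius * np.cos(ang)
    pts[:, 2] = radius * np.sin(ang)
    return pts + center


def make_toy_complex(n_hb: int = 1, n_pipi: int = 0, n_ionic: int = 0,
                     n_hydrophobic: int = 0, n_filler: int = 12,
                     seed: int = 0) -> tuple[MolecularStructure, dict]:
    """Toy receptor cage + ligand with an exactly planted interaction set.

    Each requested interaction occupies its own lattice slot (12 A apart)
    along x, with the ligand half at y=0 and the receptor half displaced
    toward +y at the detector's ideal geometry:

    * hydrogen bond — ligand O-H donor, receptor Ser O acceptor, linear,
      H...A = 2.0 A;
    * pi-pi stack  — parallel hexagons (ligand ring / receptor Phe ring),
      centroids 3.8 A apart, face to face;
    * ionic bridge — ligand ammonium N (charge +1) 3.0 A from a receptor
      Asp carboxylate O;
    * hydrophobic  — bare ligand C 4.0 A from a receptor Leu sidechain C.

    A four-atom receptor backbone anchor (Gly N/CA/C/O) and ``n_filler``
    inert receptor carbons complete the cage.  Returns the structure (roles
    and parameters attached) and the ring definitions for the pi-pi
    detector.  Raises when more units are requested than the toy ligand can
    carry.
    """
    n_units = n_hb + n_pipi + n_ionic + n_hydrophobic
    if n_units > MAX_UNITS:
        raise ValueError(
            f"{n_units} interaction units exceed the toy-ligand budget ({MAX_UNITS})"
        )
    del seed  # geometry is fully deterministic; accepted for API uniformity
    b = _Builder()
    ring_defs: dict[str, list[list[int]]] = {"ligand": [], "receptor": []}
    slot = 0

    def center() -> np.ndarray:
        nonlocal slot
        c = np.array([slot * UNIT_SPACING, 0.0, 0.0])
        slot += 1
        return c

    for _ in range(n_hb):
        c = center()
        r = b.new_residue()
        d = b.add("ligand", "O1", "O", "LIG", 1, c, charge=-0.40)
        b.add("ligand", "H1", "H", "LIG", 1, c + [0.0, 0.96, 0.0], charge=0.40)
        b.add("receptor", "OG", "O", "SER", r, c + [0.0, 2.96, 0.0], charge=-0.40)
        b.add("receptor", "CB", "C", "SER", r, c + [0.0, 4.36, 0.0], charge=0.10)
        del d
    for _ in range(n_pipi):
        c = center()
        r = b.new_residue()
        lig_ring = [b.add("ligand", f"C{i+1}", "C", "LIG", 1, xyz)
                    for i, xyz in enumerate(_hexagon(c))]
        rec_ring = [b.add("receptor", n, "C", "PHE", r, xyz)
                    for n, xyz in zip(("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
                                      _hexagon(c + [0.0, 3.8, 0.0]))]
        ring_defs["ligand"].append(lig_ring)
        ring_defs["receptor"].append(rec_ring)
    for _ in range(n_ionic):
        c = center()
        r = b.new_residue()
        b.add("ligand", "N1", "N", "LIG", 1, c, charge=1.0)
        b.add("receptor", "OD1", "O", "ASP", r, c + [0.0, 3.0, 0.0], charge=-1.0)
    for _ in range(n_hydrophobic):
        c = center()
        r = b.new_residue()
        b.add("ligand", "C9", "C", "LIG", 1, c)
        b.add("receptor", "CD1", "C", "LEU", r, c + [0.0, 4.0, 0.0])

    # receptor backbone anchors: one Gly quad per unit slot, 4.5 A below the
    # ligand plane (inside the 5 A binding-site radius, outside every
    # detector cutoff), plus one global quad — a well-conditioned alignment
    # set surrounding the ligand
    for k in range(max(slot, 1)):
        r = b.new_residue()
        p = np.array([k * UNIT_SPACING, -4.5, 0.0])
        b.add("receptor", "N", "N", "GLY", r, p)
        b.add("receptor", "CA", "C", "GLY", r, p + [1.5, 0.0, 0.0])
        b.add("receptor", "C", "C", "GLY", r, p + [0.0, 0.0, 1.5])
        b.add("receptor", "O", "O", "GLY", r, p + [0.0, 0.0, 2.7])
    r = b.new_residue()
    b.add("receptor", "N", "N", "GLY", r, [-8.0, 0.0, 0.0])
    b.add("receptor", "CA", "C", "GLY", r, [-8.0, 1.5, 0.0])
    b.add("receptor", "C", "C", "GLY", r, [-8.0, 0.0, 1.5])
    b.add("receptor", "O", "O", "GLY", r, [-9.5, 0.5, 0.8])
    # inert filler carbons, >= 6 A below the ligand plane
    for i in range(n_filler):
        rr = b.new_residue()
        b.add("receptor", "CB", "C", "ALA", rr,
              [2.0 * i - 4.0, -6.0 - 2.0 * (i % 3), 3.0])
    # guarantee the ligand has a heavy atom even with zero units requested
    if not any(role == "ligand" for role in b.roles):
        b.add("ligand", "C1", "C", "LIG", 1, [0.0, 0.0, 0.0])
    return b.build("toy-complex"), ring_defs


def _template_with_units(n_hb: int) -> tuple[MolecularStructure, dict]:
    return make_toy_complex(n_hb=n_hb, n_filler=6)


def make_drift_ensemble(plateau: float | list[float], n_trials: int = 10,
                        n_frames: int = 50, ramp_frac: float = 0.4,
                        timestep_ps: float = 200.0,
                        template: MolecularStructure | None = None,
                        ) -> TrajectoryEnsemble:
    """Ensemble whose ligand drifts along +x to an exact RMSD plateau.

    Every ligand atom is displaced by the same vector with a linear ramp to
    the plateau (held thereafter) while the receptor stays rigid, so the
    trial-averaged RMSD curve peaks at exactly ``mean(plateaus)``:
    the analytic PoseScore.  ``plateau`` may be per-trial.
    """
    if template is None:
        template, _ = _template_with_units(n_hb=1)
    plateaus = ([float(plateau)] * n_trials if np.isscalar(plateau)
                else [float(p) for p in plateau])
    if len(plateaus) != n_trials:
        raise ValueError("need one plateau per trial")
    if any(p < 0 for p in plateaus):
        raise ValueError("plateau must be non-negative")
    lig = template.indices(role="ligand")
    base = template.coords
    direction = np.array([1.0, 0.0, 0.0])
    ramp_end = max(1, int(round(ramp_frac * (n_frames - 1))))
    trials = []
    for p in plateaus:
        coords = np.repeat(base[None, :, :], n_frames, axis=0)
        for t in range(n_frames):
            d = p * min(1.0, t / ramp_end)
            coords[t, lig] = base[lig] + d * direction
        trials.append(Trajectory(coords, np.arange(n_frames) * timestep_ps))
    return TrajectoryEnsemble(trials, template)


def make_hb_ensemble(persistence: float, n_trials: int = 10, n_frames: int = 50,
                     window_frac: float = 0.2, n_hb: int = 1,
                     timestep_ps: float = 200.0) -> TrajectoryEnsemble:
    """Ensemble with an exactly programmed hydrogen-bond persistence.

    The starting pose carries ``n_hb`` planted hydrogen bonds.  Within the
    final ``window_frac`` of frames, the donor hydrogens are swung 90 deg
    out of line (breaking every reference bond) in exactly
    ``round((1 - persistence) * window)`` frames — the first frames of the
    window — so the persistence fraction is hit exactly on even windows.
    Ligand heavy atoms never move: the drift score of this ensemble is 0.
    """
    if not 0.0 <= persistence <= 1.0:
        raise ValueError("persistence must lie in [0, 1]")
    template, _ = _template_with_units(n_hb=n_hb)
    base = template.coords
    h_idx = [i for i, a in enumerate(template.atoms)
             if a.element == "H" and template.role_mask[i] == "ligand"]
    donor_of = {h: h - 1 for h in h_idx}  # builder places H right after its donor

    n_window = max(1, int(round(window_frac * n_frames)))
    n_break = int(round((1.0 - persistence) * n_window))
    broken_frames = set(range(n_frames - n_window, n_frames - n_window + n_break))

    coords = np.repeat(base[None, :, :], n_frames, axis=0)
    for t in broken_frames:
        for h in h_idx:
            d = donor_of[h]
            # swing H from +y to +x around its donor: D-H...A angle ~72 deg
            coords[t, h] = base[d] + np.array([0.96, 0.0, 0.0])
    traj = Trajectory(coords, np.arange(n_frames) * timestep_ps)
    trials = [Trajectory(coords.copy(), traj.timestamps.copy())
              for _ in range(n_trials)]
    return TrajectoryEnsemble(trials, template)


def make_basin_trajectory(n_frames: int = 100, major_frac: float = 0.8,
                          ligand_shift: float = 2.0, backbone_shift: float = 2.0,
                          jitter: float = 0.03, seed: int = 0,
                          major_is_shifted: bool = False,
                          timestep_ps: float = 100.0,
                          template: MolecularStructure | None = None,
                          ) -> TrajectoryEnsemble:
    """Two-basin trajectory with a planted majority conformer.

    Basin A is the starting conformation (frame 0 is always in it, like an
    unbiased run launched from the pose); basin B displaces the ligand by
    ``ligand_shift`` A (+x) and one backbone CA by ``backbone_shift`` A so
    the basins are separable on a backbone RMSD matrix.  A fraction
    ``major_frac`` of frames sits in the majority basin — basin A unless
    ``major_is_shifted`` — with basin membership assigned by a seeded
    permutation of frames 1..T-1.  Gaussian jitter of scale ``jitter`` A is
    added to every frame.
    """
    if template is None:
        template, _ = _template_with_units(n_hb=1)
    rng = np.random.default_rng(seed)
    base = template.coords
    lig = template.indices(role="ligand")
    ca = [i for i, a in enumerate(template.atoms)
          if a.name == "CA" and template.role_mask[i] == "receptor"]
    if not ca:
        raise ValueError("template lacks a receptor CA atom")

    shifted = base.copy()
    shifted[lig, 0] += ligand_shift
    shifted[ca[0], 0] += backbone_shift

    n_major = int(round(major_frac * n_frames))
    n_shifted = (min(n_major, n_frames - 1) if major_is_shifted
                 else n_frames - n_major)
    order = rng.permutation(n_frames - 1) + 1  # frame 0 stays in basin A
    in_shifted = set(order[:n_shifted].tolist())

    coords = np.empty((n_frames, base.shape[0], 3))
    for t in range(n_frames):
        frame = (shifted if t in in_shifted else base).copy()
        frame += jitter * rng.standard_normal(frame.shape)
        coords[t] = frame
    traj = Trajectory(coords, np.arange(n_frames) * timestep_ps)
    return TrajectoryEnsemble([traj], template)


def make_assay_table(n: int = 50, n_above: int = 20, threshold: float = 70.0,
                     seed: int = 0) -> pd.DataFrame:
    """Synthetic assay table with a controllable strict-threshold hit count.

    Exactly ``n_above`` compounds get inhibition in (threshold+2, 100] and
    the rest in [0, threshold-2), so ``count_hits`` at ``threshold`` must
    return ``n_above``.
    """
    if n_above > n:
        raise ValueError("n_above cannot exceed n")
    rng = np.random.default_rng(seed)
    hi = rng.uniform(threshold + 2.0, 100.0, size=n_above)
    lo = rng.uniform(0.0, max(threshold - 2.0, 0.0), size=n - n_above)
    inhibition = np.concatenate([hi, lo])
    rng.shuffle(inhibition)
    return pd.DataFrame({
        "compound_id": [f"SYN-{i:04d}" for i in range(n)],
        "vina_score": np.round(rng.uniform(-14.0, -9.0, size=n), 1),
        "inhibition_pct": np.round(inhibition, 1),
        "ic50_uM": np.nan,
    })


def make_dose_response(ic50_uM: float = 1.25, hill: float = 1.0,
                       bottom: float = 0.0, top: float = 100.0,
                       concentrations: np.ndarray | None = None,
                       noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Dose-response curve from an exact 4PL with optional Gaussian noise.

    Default concentrations: 8-point 3-fold dilution series from 30 uM,
    bracketing IC50s in the ~1 uM range.  ``noise_sd`` is in percent
    response.
    """
    if concentrations is None:
        concentrations = 30.0 / 3.0 ** np.arange(8)
    x = np.asarray(concentrations, dtype=float)
    y = triage.four_pl(x, bottom, top, np.log10(ic50_uM), hill)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=x.shape)
    return pd.DataFrame({"conc_uM": x, "response_pct": y})


def make_tethered_system(stiffness: float = 10.0, temperature: float = 300.0,
                         friction: float = 1.0,
                         template: MolecularStructure | None = None,
                         ) -> tuple["metadyn.ToySystem", "metadyn.CVDefinition"]:
    """Toy bound complex: ligand atoms tethered harmonically to their pose.

    Each ligand atom feels U = stiffness * |x - x0|^2 (kcal/mol/A^2 per
    atom) around its starting position while the receptor stays frozen — a
    caricature of a binding well whose depth is the tether stiffness.
    Stiffer tethers give smaller thermal RMSD excursions, so stability
    scores sharpen as the well deepens.  The CV is the ligand heavy-atom
    RMSD from the pose, matching the biased-simulation convention.
    """
    from . import metadyn

    if template is None:
        template, _ = _template_with_units(n_hb=1)
    lig = template.indices(role="ligand")
    lig_heavy = template.indices(role="ligand", heavy_only=True)
    x0 = template.coords

    def potential(x: np.ndarray) -> float:
        d = x[lig] - x0[lig]
        return float(stiffness * np.sum(d * d))

    def gradient(x: np.ndarray) -> np.ndarray:
        g = np.zeros_like(x)
        g[lig] = 2.0 * stiffness * (x[lig] - x0[lig])
        return g

    system = metadyn.ToySystem(
        potential=potential, gradient=gradient, coords=x0.copy(),
        temperature=temperature, friction=friction, mobile=lig,
        template=template,
    )
    cv = metadyn.CVDefinition(lig_heavy, x0[lig_heavy].copy())
    return system, cv


def make_double_well(barrier: float = 3.0, center: float = 1.0,
                     half_sep: float = 0.5, transverse_k: float = 50.0,
                     temperature: float = 300.0, friction: float = 1.0,
                     ) -> tuple["metadyn.ToySystem", "metadyn.CVDefinition", dict]:
    """Single-particle 1D double well for the metadynamics engine.

    The potential along x is quartic,

        U(x) = barrier * ((x - center)^2 - half_sep^2)^2 / half_sep^4,

    with minima at ``center +- half_sep`` (energy 0) and a saddle of height
    ``barrier`` at ``center``; stiff harmonics (``transverse_k``) pin y and
    z.  The particle starts in the inner well and the CV is the distance
    from the origin, so CV ~ x and the analytic free-energy barrier along
    the CV equals ``barrier`` up to a constant transverse term.

    Returns (system, cv, info) with the analytic well/saddle CV positions.
    """
    from . import metadyn

    a, b4 = center, half_sep ** 4

    def potential(x: np.ndarray) -> float:
        px = x[0, 0]
        return float(barrier * ((px - a) ** 2 - half_sep ** 2) ** 2 / b4
                     + transverse_k * (x[0, 1] ** 2 + x[0, 2] ** 2))

    def gradient(x: np.ndarray) -> np.ndarray:
        g = np.zeros_like(x)
        px = x[0, 0]
        g[0, 0] = barrier * 4.0 * (px - a) * ((px - a) ** 2 - half_sep ** 2) / b4
        g[0, 1] = 2.0 * transverse_k * x[0, 1]
        g[0, 2] = 2.0 * transverse_k * x[0, 2]
        return g

    start = np.array([[a - half_sep, 0.0, 0.0]])
    system = metadyn.ToySystem(
        potential=potential, gradient=gradient, coords=start,
        temperature=temperature, friction=friction,
    )
    cv = metadyn.CVDefinition(np.array([0]), np.zeros((1, 3)))
    info = {"inner_well": a - half_sep, "outer_well": a + half_sep,
            "saddle": a, "barrier": barrier}
    return system, cv, info
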