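"""BPMD-style pose-stability scoring from multi-trial trajectory ensembles.

A candidate pose is scored by running several short biased (or unbiased)
simulations from the same starting complex and watching how far the ligand
drifts and how well its initial hydrogen-bond network survives:

* ``PoseScore`` — the maximum of the trial-averaged ligand heavy-atom RMSD
  curve (Angstrom, relative to the starting pose after binding-site
  alignment).  Below 2 A the pose is called stable.
* ``PersScore`` — the fraction of the starting pose's hydrogen bonds still
  present over the final stretch of each trial, averaged over trials (0-1).
* ``CompScore`` — ``PoseScore - 5 * PersScore``; lower is more stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import interactions
from .structio import (
    BACKBONE_NAMES,
    MolecularStructure,
    TrajectoryEnsemble,
    kabsch_superpose,
    rmsd_fixed,
)

__all__ = [
    "BPMDResult",
    "ligand_rmsd_curve",
    "pose_score",
    "pers_score",
    "comp_score",
    "stability_call",
    "rank_by_compscore",
    "score_pose",
]

COMPSCORE_WEIGHT = 5.0
STABLE_THRESHOLD = 2.0  # Angstrom, strict: PoseScore < 2 is stable


@dataclass
class BPMDResult:
    """Stability scores of one pose from an n-trial ensemble."""

    pose_score: float
    pers_score: float
    comp_score: float
    rmsd_curve: np.ndarray
    timestamps: np.ndarray
    n_trials: int

    @property
    def stable(self) -> bool:
        return stability_call(self) == "stable"


def site_selection(template: MolecularStructure, radius: float = 5.0) -> np.ndarray:
    """Receptor backbone atoms within ``radius`` of any starting-pose ligand
    atom — the frame alignment set for the RMSD curve."""
    lig = template.indices(role="ligand")
    if len(lig) == 0:
        raise ValueError("template has no ligand atoms")
    coords = template.coords
    site = [
        i for i in template.indices(role="receptor")
        if template.atoms[i].name in BACKBONE_NAMES
        and np.min(np.linalg.norm(coords[lig] - coords[i], axis=1)) <= radius
    ]
    if len(site) < 3:
        # fall back to all receptor backbone so superposition stays posed
        site = [i for i in template.indices(role="receptor")
                if template.atoms[i].name in BACKBONE_NAMES]
    if len(site) < 3:
        raise ValueError("fewer than 3 receptor backbone atoms for site alignment")
    return np.array(site, dtype=int)


def ligand_rmsd_curve(ensemble: TrajectoryEnsemble,
                      ligand_sel: np.ndarray | None = None,
                      site_sel: np.ndarray | None = None,
                      site_radius: float = 5.0,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged ligand heavy-atom RMSD versus time.

    Every frame is first superposed onto frame 0 through the binding-site
    selection (receptor backbone within ``site_radius`` of the starting
    ligand), then the ligand heavy-atom RMSD against the frame-0 pose is
    taken at fixed correspondence.  Returns (timestamps ps, mean curve A).
    """
    template = ensemble.atom_template
    if ligand_sel is None:
        ligand_sel = template.indices(role="ligand", heavy_only=True)
    ligand_sel = np.asarray(ligand_sel, dtype=int)
    if len(ligand_sel) == 0:
        raise ValueError("empty ligand selection")
    if site_sel is None:
        site_sel = site_selection(template, radius=site_radius)
    site_sel = np.asarray(site_sel, dtype=int)

    curves = []
    for trial in ensemble.trials:
        ref_site = trial.coords[0][site_sel]
        ref_lig = trial.coords[0][ligand_sel]
        values = np.empty(trial.n_frames)
        for t in range(trial.n_frames):
            sup = kabsch_superpose(trial.coords[t][site_sel], ref_site)
            lig = sup.apply(trial.coords[t][ligand_sel])
            values[t] = rmsd_fixed(lig, ref_lig)
        curves.append(values)
    return ensemble.timestamps.copy(), np.mean(curves, axis=0)


def pose_score(curve: np.ndarray) -> float:
    """Maximum of the trial-averaged RMSD curve (Angstrom)."""
    curve = np.asarray(curve, dtype=float)
    if curve.size == 0:
        raise ValueError("empty RMSD curve")
    return float(np.max(curve))


def pers_score(ensemble: TrajectoryEnsemble,
               reference_hbs: list[interactions.InteractionRecord] | None = None,
               window_frac: float = 0.2,
               hb_kwargs: dict | None = None) -> float:
    """Hydrogen-bond persistence over the final ``window_frac`` of each trial.

    The reference bonds are those detected on the starting pose (frame 0 of
    trial 0) unless given.  For each trial, each reference (donor-H,
    acceptor) pair is re-evaluated geometrically in every window frame; the
    score is the surviving fraction of (bond x frame) observations, averaged
    over trials.  Defined as 0 when the starting pose has no hydrogen bonds.
    """
    if not 0.0 < window_frac <= 1.0:
        raise ValueError("window_frac must be in (0, 1]")
    hb_kwargs = hb_kwargs or {}
    template = ensemble.atom_template
    if reference_hbs is None:
        frame0 = template.with_coords(ensemble.trials[0].coords[0])
        reference_hbs = interactions.detect_hbonds(frame0, **hb_kwargs)
    reference_hbs = [r for r in reference_hbs if r.kind == "hb"]
    if not reference_hbs:
        return 0.0

    per_trial = []
    for trial in ensemble.trials:
        n_frames = trial.n_frames
        n_window = max(1, int(round(window_frac * n_frames)))
        window = range(n_frames - n_window, n_frames)
        kept = 0
        for t in window:
            frame = template.with_coords(trial.coords[t])
            found = interactions.detect_hbonds(frame, **hb_kwargs)
            found_keys = {(r.ligand_atoms, r.receptor_atoms) for r in found}
            kept += sum((r.ligand_atoms, r.receptor_atoms) in found_keys
                        for r in reference_hbs)
        per_trial.append(kept / (len(reference_hbs) * n_window))
    return float(np.mean(per_trial))


def comp_score(pose_score: float, pers_score: float,
               weight: float = COMPSCORE_WEIGHT) -> float:
    """Composite stability score: PoseScore − weight × PersScore.

    The weight of 5 makes a fully persistent hydrogen-bond network worth 5 A
    of positional credit; lower values mean a more stable pose.
    """
    if not 0.0 <= pers_score <= 1.0:
        raise ValueError("pers_score must lie in [0, 1]")
    return float(pose_score - weight * pers_score)


def stability_call(result: "BPMDResult | float", threshold: float = STABLE_THRESHOLD) -> str:
    """``stable`` iff PoseScore < threshold (strict), else ``unstable``."""
    ps = result.pose_score if isinstance(result, BPMDResult) else float(result)
    return "stable" if ps < threshold else "unstable"


def rank_by_compscore(results: list[tuple[str, BPMDResult]],
                      ) -> list[tuple[str, BPMDResult]]:
    """Ascending CompScore; ties broken by lower PoseScore, then pose id."""
    if not results:
        raise ValueError("no results to rank")
    return sorted(results, key=lambda pr: (pr[1].comp_score, pr[1].pose_score, pr[0]))


def score_pose(ensemble: TrajectoryEnsemble,
               window_frac: float = 0.2,
               site_radius: float = 5.0,
               weight: float = COMPSCORE_WEIGHT) -> BPMDResult:
    """Full stability scoring of one pose from its trial ensemble."""
    timestamps, curve = ligand_rmsd_curve(ensemble, site_radius=site_radius)
    ps = pose_score(curve)
    pers = pers_score(ensemble, window_frac=window_frac)
    return BPMDResult(
        pose_score=ps,
        pers_score=pers,
        comp_score=comp_score(ps, pers, weight=weight),
        rmsd_curve=curve,
        timestamps=timestamps,
        n_trials=ensemble.n_trials,
    )
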