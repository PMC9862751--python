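"""Pose-reliability decision procedure.

After a candidate pose has won the metadynamics stability ranking, an
unbiased simulation started from it is clustered and its representative
conformation compared back against the starting pose on three axes: how far
the ligand moved (heavy-atom RMSD after binding-site alignment), how much
the estimated binding free energy improved (ΔΔG = ΔG_before − ΔG_after),
and how the strong-interaction inventory (hydrogen bonds, pi-pi stacks,
ionic bridges) changed.  The classification:

* ``ambiguous`` — the ligand moved a lot (RMSD > 3 Å): the simulation found
  a different pose with no clear energetic winner; the method cannot decide.
* ``confirmed`` — the ligand barely moved (RMSD <= 1 Å) and the energy did
  not improve significantly: the starting pose survives as-is.
* ``refined``  — everything else: the relaxed representative pose is the
  more plausible binding mode.

Interaction-count changes are reported but deliberately not used as a
classification rule.  Thresholds are calibrated so the five benchmark
(RMSD, ΔΔG) pairs of the D3R screening study classify as one confirmed,
three refined, one ambiguous; all are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from . import gbsa, interactions, posescore, trajcluster
from .structio import MolecularStructure, TrajectoryEnsemble, kabsch_superpose, rmsd_fixed

__all__ = [
    "PoseComparison",
    "RMSD_CONFIRM",
    "RMSD_AMBIGUOUS",
    "DDG_SIGNIFICANT",
    "compare_poses",
    "classify",
    "run_pipeline",
]

RMSD_CONFIRM = 1.0  # Å: at or below, the pose is unchanged
RMSD_AMBIGUOUS = 3.0  # Å: strictly above, the motion is too large to call
DDG_SIGNIFICANT = 7.5  # kcal/mol: at or above, post-MD stabilization is significant


@dataclass
class PoseComparison:
    """Before/after comparison of a top-scored pose and the post-MD
    representative conformation."""

    rmsd_pre_post: float
    ddg: float | None = None
    strong_before: int = 0
    strong_after: int = 0
    verdict: str | None = None
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.rmsd_pre_post < 0:
            raise ValueError("rmsd must be non-negative")


def _strong_count(complex: MolecularStructure,
                  ring_defs: dict | None = None) -> int:
    records = interactions.detect_all(complex, ring_defs=ring_defs)
    return sum(r.kind in ("hb", "pipi", "ionic") for r in records)


def compare_poses(top_complex: MolecularStructure,
                  representative_complex: MolecularStructure,
                  dg_top: float | None = None,
                  dg_representative: float | None = None,
                  ring_defs: dict | None = None,
                  site_radius: float = 5.0) -> PoseComparison:
    """Align binding sites, then measure the ligand's displacement and the
    change in strong-interaction counts (and ΔΔG when energies are given).

    Both complexes must carry the same ligand atom set (names, in order).
    """
    lig_top = top_complex.indices(role="ligand", heavy_only=True)
    lig_rep = representative_complex.indices(role="ligand", heavy_only=True)
    names_top = [top_complex.atoms[i].name for i in lig_top]
    names_rep = [representative_complex.atoms[i].name for i in lig_rep]
    if names_top != names_rep:
        raise ValueError("ligand atom sets differ between the two complexes")

    site = posescore.site_selection(top_complex, radius=site_radius)
    sup = kabsch_superpose(representative_complex.coords[site],
                           top_complex.coords[site])
    moved = sup.apply(representative_complex.coords[lig_rep])
    rmsd = rmsd_fixed(moved, top_complex.coords[lig_top])

    ddg = None
    if dg_top is not None and dg_representative is not None:
        ddg = gbsa.delta_delta_g(dg_top, dg_representative)
    return PoseComparison(
        rmsd_pre_post=rmsd,
        ddg=ddg,
        strong_before=_strong_count(top_complex, ring_defs),
        strong_after=_strong_count(representative_complex, ring_defs),
    )


def classify(cmp: PoseComparison,
             rmsd_confirm: float = RMSD_CONFIRM,
             rmsd_ambiguous: float = RMSD_AMBIGUOUS,
             ddg_significant: float = DDG_SIGNIFICANT) -> str:
    """Assign the verdict and rationale; see module docstring for the rules.

    Boundary convention: an RMSD exactly at ``rmsd_ambiguous`` is still
    classifiable, one exactly at ``rmsd_confirm`` is still confirm-eligible.
    """
    rmsd = cmp.rmsd_pre_post
    ddg = cmp.ddg if cmp.ddg is not None else 0.0
    if rmsd > rmsd_ambiguous:
        cmp.verdict = "ambiguous"
        cmp.rationale = (
            f"ligand moved {rmsd:.2f} A (> {rmsd_ambiguous:g} A): alternative "
            f"pose found; ddG {ddg:+.2f} kcal/mol does not separate them"
        )
    elif rmsd <= rmsd_confirm and ddg < ddg_significant:
        cmp.verdict = "confirmed"
        cmp.rationale = (
            f"pose preserved (RMSD {rmsd:.2f} A <= {rmsd_confirm:g} A) with no "
            f"significant stabilization (ddG {ddg:+.2f} < {ddg_significant:g})"
        )
    else:
        cmp.verdict = "refined"
        cmp.rationale = (
            f"representative pose preferred: RMSD {rmsd:.2f} A and/or "
            f"significant stabilization (ddG {ddg:+.2f} kcal/mol)"
        )
    return cmp.verdict


@dataclass
class PipelineReport:
    """One row per ligand; failed stages leave an ``error`` and keep going."""

    rows: list[dict] = field(default_factory=list)


def run_pipeline(candidates: dict[str, list[interactions.PoseRecord]],
                 trajectory_provider: Callable[
                     [interactions.PoseRecord],
                     tuple[TrajectoryEnsemble, TrajectoryEnsemble]],
                 receptor_site: list[tuple[str, int, str]],
                 gb_params: gbsa.GBParams | None = None,
                 ring_defs: dict | None = None,
                 top_k: int = 3,
                 sim_threshold: float = 0.7,
                 cluster_cutoff: float = trajcluster.DEFAULT_CUTOFF,
                 ) -> PipelineReport:
    """End-to-end pose validation for a batch of ligands.

    For each ligand: fingerprint + cluster its candidate poses, keep the top
    ``top_k`` cluster representatives by docking score, stability-score each
    through its biased ensemble, take the best CompScore pose, extract the
    representative conformation of its unbiased trajectory, estimate both
    binding free energies, and classify.  ``trajectory_provider`` maps a
    pose to its (biased ensemble, unbiased trajectory) pair — from the toy
    engine or from files.
    """
    report = PipelineReport()
    for ligand_id, poses in candidates.items():
        try:
            for p in poses:
                if p.fingerprint is None:
                    p.fingerprint = interactions.build_sift(
                        p, receptor_site, ring_defs=ring_defs)
            clustering = interactions.cluster_poses(poses, sim_threshold)
            top = interactions.select_top_k(clustering.representatives, k=top_k)

            scored = []
            ensembles = {}
            for pose in top:
                biased, unbiased = trajectory_provider(pose)
                ensembles[pose.pose_id] = (pose, biased, unbiased)
                scored.append((pose.pose_id, posescore.score_pose(biased)))
            ranked = posescore.rank_by_compscore(scored)
            best_id, best_result = ranked[0]
            best_pose, _, unbiased = ensembles[best_id]

            rep_struct, rep_frame = trajcluster.representative_conformation(
                unbiased, cutoff=cluster_cutoff)
            dg_top, _ = gbsa.delta_g_bind(best_pose.structure, gb_params)
            dg_rep, _ = gbsa.delta_g_bind(rep_struct, gb_params)
            cmp = compare_poses(best_pose.structure, rep_struct,
                                dg_top=dg_top, dg_representative=dg_rep,
                                ring_defs=ring_defs)
            classify(cmp)
            report.rows.append({
                "ligand": ligand_id,
                "n_poses": clustering.n_poses,
                "n_clusters": clustering.n_clusters,
                "best_pose": best_id,
                "pose_score": best_result.pose_score,
                "pers_score": best_result.pers_score,
                "comp_score": best_result.comp_score,
                "stable": best_result.stable,
                "representative_frame": rep_frame,
                "dg_top": dg_top,
                "dg_representative": dg_rep,
                "ddg": cmp.ddg,
                "rmsd_pre_post": cmp.rmsd_pre_post,
                "strong_before": cmp.strong_before,
                "strong_after": cmp.strong_after,
                "verdict": cmp.verdict,
                "rationale": cmp.rationale,
                "error": None,
            })
        except Exception as exc:  # keep the batch going, record the failure
            report.rows.append({"ligand": ligand_id, "verdict": None,
                                "error": f"{type(exc).__name__}: {exc}"})
    return report
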