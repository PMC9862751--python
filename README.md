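# poseval

**poseval** is a toolkit for deciding whether a docked protein–ligand
binding pose is *real*: it scores candidate poses for dynamical stability
from repeated short simulations, removes redundant poses by interaction
fingerprints, estimates binding free energies with a generalized-Born /
surface-area model, and classifies how well a pose survives unbiased
molecular dynamics.  It also covers the screening-side bookkeeping of a
virtual-screening campaign — docking-score ranking with diversity picks,
radioligand-assay inhibition arithmetic, and IC50 determination by
four-parameter logistic fits.

It is aimed at computational chemists who have candidate poses (from
docking or induced-fit docking) and trajectory ensembles (from binding-pose
metadynamics or plain MD) and need reproducible, scriptable arithmetic for
the downstream decisions, without a commercial modelling suite.

## The scores

Given an ensemble of `n` independent trials started from the same pose,
with ligand heavy-atom RMSD measured against the starting pose after
binding-site alignment of every frame:

- **PoseScore** (Å) — the maximum of the trial-averaged RMSD curve.
  A pose with PoseScore < 2 Å is called *stable*.
- **PersScore** ∈ [0, 1] — the fraction of the starting pose's hydrogen
  bonds still intact over the final 20 % of each trial, averaged over
  trials (0 when the pose has no hydrogen bonds).
- **CompScore** = PoseScore − 5 · PersScore — the composite ranking score;
  lower is more stable.

After unbiased MD from the best-CompScore pose, the representative
conformation (the frame with the most neighbours in an RMSD-matrix
clustering) is compared back to the starting pose by ligand RMSD and by
ΔΔG = ΔG_bind(before) − ΔG_bind(after), where each single-frame

ΔG_bind = G(complex) − G(receptor) − G(ligand),
G = E_Coulomb + E_LJ + G_GB + γ·SASA.

The verdict is **confirmed** (pose unchanged: RMSD ≤ 1 Å and no
significant stabilization), **refined** (the relaxed pose is preferred), or
**ambiguous** (RMSD > 3 Å: the method cannot decide).

A small metadynamics engine (RMSD collective variable, Gaussian hill
deposition, overdamped Langevin dynamics on analytic surfaces) generates
desk-scale trial ensembles and validates the biasing and free-energy
arithmetic against closed forms.

## Worked example

Score a pose from a trial trajectory whose ligand drifts to a programmed
1.5 Å plateau while keeping its hydrogen bond:

```sh
poseval fixtures --kind drift_ensemble --out drift.pdb
poseval score drift.pdb
```

prints

```json
{
  "pose_score": 1.5,
  "pers_score": 1.0,
  "comp_score": -3.5,
  "stable": true,
  "n_trials": 1
}
```

— the ligand moved at most 1.5 Å from its pose (below the 2 Å stability
threshold), every reference hydrogen bond survived the end of the run, and
the composite score 1.5 − 5 × 1.0 = −3.5 ranks this pose as very stable.

Assay triage on the packaged 27-compound screening table:

```sh
poseval triage
```

```json
{ ">50%": 27, ">70%": 23, ">80%": 13, ">90%": 6,
  "lowest_ic50_uM": [0.97, 1.25, 1.41, 1.48, 1.49] }
```

— 27 compounds inhibit more than 50 % at 10 µM, 23 more than 70 %, 13 more
than 80 %, 6 more than 90 %, and the five most potent have IC50s between
0.97 and 1.49 µM.

The same operations are available as library calls
(`poseval.posescore.score_pose`, `poseval.triage.count_hits`,
`poseval.verdict.run_pipeline`, …); see `docs/methods.md` for the models
and conventions.

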