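# Methods

This note records the models poseval implements, the conventions and
defaults it chooses where the underlying procedures leave them open, and
what its synthetic validation does and does not demonstrate.

## Structures, RMSD, superposition

Structures are ordered atom lists with per-atom receptor/ligand/other
roles; coordinates are Ångström, residue numbering is 1-based, and atom
correspondence is always positional (no symmetry-corrected RMSD — the
toolkit is deterministic by construction, and symmetry equivalence is left
to the caller's atom ordering).  Multi-model PDB is the trajectory
interchange format; PDBQT partial charges (columns 71–76) are read into
the atom's `charge` field.  Hydrogens are kept on read and heavy-atom
selections are derived, because the drift score is defined over ligand
heavy atoms.  Rigid superposition uses the least-squares optimal proper
rotation (via `scipy.spatial.transform.Rotation.align_vectors`) and
requires ≥ 3 non-collinear points.

Docking grid boxes span the ligand's heavy-atom bounding box plus a
±10 Å pad per axis at 1 Å spacing.  The box center is the bounding-box
midpoint by default; "center of the ligand" is ambiguous, so the centroid
is offered as an alternative (`center="centroid"`).

## Interaction detection and fingerprints

All detectors are geometric, with cutoffs exposed as arguments:

| interaction | criterion (defaults) |
|---|---|
| hydrogen bond | H···A ≤ 2.8 Å, D–H···A ≥ 120°, H···A–X ≥ 90° for every heavy X bonded to the acceptor |
| π–π face-to-face | ring-centroid distance ≤ 4.4 Å, interplanar angle ≤ 30° |
| π–π edge-to-face | distance ≤ 5.5 Å, angle ∈ [60°, 120°] |
| ionic bridge | opposite formal charges within 4.0 Å |
| hydrophobic | nonpolar heavy atoms (C/S not bonded to N/O) within 4.5 Å, one record per residue |

Donor/acceptor typing is by element (N, O) with covalent bonds inferred
from distance (≤ 1.25 Å for D–H, ≤ 1.8 Å otherwise).  Aromatic rings must
be declared — there is no ring perception.  Formal charges come from
residue-name templates at pH 7 (Asp/Glu −, Lys/Arg/His⁺ +) on the receptor
and from sidecar partial charges (|q| ≥ 0.5 on N/O) on the ligand; no pKa
calculation is attempted.

The structural interaction fingerprint assigns 9 bits per binding-site
residue — any_contact, backbone, sidechain, polar, hydrophobic, hb_donor,
hb_acceptor, aromatic, charged — with `any_contact` the OR of the rest and
donor/acceptor from the residue's perspective.  Pose deduplication is
complete-linkage agglomeration at Tanimoto similarity ≥ 0.7 (two poses
share a cluster only if *every* pair in the cluster is that similar); the
linkage and threshold are not prescribed by the upstream procedure, so
both are configurable, and ties are broken by docking score then pose id.
Within a cluster the best-scoring (lowest) pose is retained, and the top
three cluster representatives go forward to stability scoring.

## Stability scores

Every frame is superposed onto frame 0 through the binding-site selection
— receptor backbone atoms within 5 Å of the starting ligand (radius
configurable; the upstream protocol aligns binding sites without naming an
atom set) — then the ligand heavy-atom RMSD against the frame-0 pose is
averaged across trials to give the drift curve.  PoseScore is the curve
maximum; the stability call is strict (`< 2 Å`).  PersScore re-evaluates
each frame-0 hydrogen bond geometrically over the final 20 % of each
trial's frames (the window fraction is configurable; the persistence
notion targets the end of the simulation) and is defined as 0 when the
starting pose has no hydrogen bonds, matching the published score tables
that print 0.00 in that case.  CompScore = PoseScore − 5·PersScore; the
weight 5 was verified against the published score table, where the linear
combination reproduces all rows except three cells that are internally
inconsistent (they are flagged by the regression suite, not fitted).
Ranking is by CompScore ascending with PoseScore, then pose id, as
tie-breaks.

## Toy metadynamics engine

The engine exists to generate trial ensembles at desk scale and to
validate the biasing math; it makes no attempt at solvated or membrane
systems.  The collective variable is the RMSD of a ligand atom selection
from its reference coordinates; its gradient is undefined at RMSD = 0, so
the bias force is zero there by convention.  Bias energy is the usual
non-tempered sum of Gaussians; hill defaults (height 0.05 kcal/mol, width
0.02 Å, deposition every 100 steps) follow the published binding-pose
metadynamics settings.  Dynamics is overdamped Euler–Maruyama Langevin
(unit mass, mobility 1/γ), chosen as the simplest integrator that is
correct for the analytic toy surfaces; each trial records 50 frames
regardless of step count, preserving the 10 ns / 200 ps
production-to-frame ratio in toy units.  Trials take seeds explicitly
(default: trial index) and identical seeds are rejected so ensembles are
genuinely independent; identical inputs and seed reproduce trajectories
bit for bit.

Free-energy surfaces are estimated as F(s) = −V_bias(s), min-shifted to
zero; an optional tail-average (mean of −V over the last fraction of
depositions) damps the well-known oscillation of the instantaneous
estimator.  Validation uses a quartic double well (wells at CV 0.5 and
1.5 Å, barrier at 1.0 Å): a 10⁵-step run at 300 K with 0.05 kcal/mol hills
recovers the barrier within 25 %, and the rare-event check uses a 7 kT
barrier so that unbiased escape within the 10⁴-step horizon is genuinely
rare — at lower barriers unbiased crossings are common enough that the
paired comparison measures noise rather than acceleration.

## Trajectory clustering

Frames are subsampled (every 10th, capped at 1000), pairwise-superposed on
the receptor backbone, and clustered on the RMSD matrix with a
deterministic leader algorithm: the frame with the most neighbours within
the cutoff seeds a cluster with those neighbours, the process repeats on
the remainder up to 10 clusters, and the overflow is labelled −1.  The
exact algorithm behind the reference implementation is unpublished; the
leader scheme was chosen because it directly realizes the stated selection
rule ("the structure with the largest number of neighbours").  The
neighbour cutoff defaults to 2.0 Å backbone RMSD and all tie-breaks
resolve to the lowest original frame index, so results are
order-deterministic.  Whether clustering should use receptor or complex
backbone is unspecified upstream; receptor backbone is the default and the
selection is an argument.

## GB/SA energetics

The proprietary solvation model and force field used upstream are not
reimplemented; poseval computes a generic single-frame MM/GBSA over
user-supplied per-atom parameters (sidecar CSV: charge, LJ σ/ε, GB
radius/screening).  Consequently **absolute ΔG_bind values are not
comparable to published tables** — only the component arithmetic, sign
convention (more favourable = more negative) and ΔΔG logic are.

- Coulomb: 332.0636·q_iq_j/r_ij over all pairs, no cutoff.
- Lennard-Jones: 12-6 with Lorentz–Berthelot mixing.
- GB: HCT pairwise-descreening integrals with OBC rescaling
  (α, β, γ = 1.0, 0.8, 4.85); the radius offset defaults to 0 so an
  isolated atom's effective radius equals its intrinsic radius exactly.
  Polar energy is Still's pairwise formula with
  f_GB = √(r² + R_iR_j·exp(−r²/4R_iR_j)), ε_in = 1, ε_out = 78.5,
  including self terms (the single-ion limit is the Born equation).
- Nonpolar: γ·SASA with γ = 0.0072 kcal/(mol·Å²), probe 1.4 Å.
  SASA is Shrake–Rupley over a deterministic Fibonacci-spiral point set
  (960 points/atom), so results are bit-stable; exactly coincident spheres
  count once.

Receptor and ligand free energies are evaluated on the geometries
extracted from the complex frame — the single-trajectory approximation,
with no re-minimization and no entropy term.

## Pose-reliability verdict

The comparison aligns the representative conformation onto the top-scored
complex through the binding-site backbone, measures ligand heavy-atom
RMSD, counts strong interactions (HB + π–π + ionic) on both sides, and
takes ΔΔG = ΔG_before − ΔG_after (positive = post-MD stabilization).
Classification: RMSD > 3 Å → ambiguous; else RMSD ≤ 1 Å *and*
ΔΔG < 7.5 kcal/mol → confirmed; else refined.  Boundary values stay in the
less drastic category (exactly 1.0 Å remains confirm-eligible, exactly
3.0 Å is not ambiguous).  The thresholds are calibrated so the five
benchmark (RMSD, ΔΔG) pairs shipped in `poseval/data/` classify as one
confirmed, three refined, one ambiguous; the ΔΔG significance default is
7.5 rather than 8.0 kcal/mol because one benchmark ligand described as
significantly stabilized has a printed ΔΔG of 7.90.  Interaction-count
changes are reported but deliberately not part of the rule — the source
procedure narrates them without one.  All three thresholds are arguments.

## Assay triage

Inhibition % = 100·(total − test)/(total − nonspecific) from raw counts;
"over X %" hit counting is a strict inequality, which reproduces every
published count (27/23/13/6 at 50/70/80/90 %).  IC50s come from 4PL fits
y = bottom + (top − bottom)/(1 + 10^((log₁₀IC50 − log₁₀x)·hill)) in
log-concentration space with bottom/top bounded to [−10, 110] % and the
Hill slope to (0.05, 20) — unconstrained fits are unstable on short
curves.  A response spanning < 1 % raises an error (unidentifiable IC50)
rather than returning an arbitrary fit.  Diversity selection takes the
top-300 compounds by ascending docking score and keeps the best-scoring
member of each supplied cluster; chemical-fingerprint clustering itself is
out of scope and labels are an input.

## Synthetic fixtures: what they show and what they don't

The generators plant analytically known properties: interaction units on a
12 Å lattice at ideal detector geometry (each planted contact is the only
one its detector can find — with the documented exception that stacked
rings also register as a hydrophobic contact, which is chemically true);
drift ensembles whose ligand translates rigidly to an exact RMSD plateau;
hydrogen-bond ensembles that break donors in an exact fraction of window
frames; two-basin trajectories with a seeded majority conformer separable
on the backbone RMSD matrix; assay tables with exact threshold counts; and
noiseless or Gaussian-noised 4PL curves.  Receptor "binding sites" are
Gly backbone quads placed 4.5 Å from each ligand unit so binding-site
alignment is well-conditioned.

Closed-loop tests over these fixtures demonstrate that the analysis
arithmetic is exact and self-consistent.  They do not demonstrate accuracy
on real complexes: the fixtures have no realistic protein geometry,
conformational strain, solvent, or parameter uncertainty, and the GB/SA
values are only as meaningful as the supplied parameters.  Problem sizes
throughout the validation suite (tens of atoms, 10-trial ensembles,
10⁴–10⁵-step toy runs, 100-frame clusterings) are chosen as the smallest
sizes at which each property is unambiguous.

## Known limitations

- No symmetry-corrected RMSD; atom correspondence is positional.
- No aromatic-ring or protonation-state perception; both are inputs.
- Non-tempered metadynamics only; no well-tempered variant, no explicit
  solvent or membranes.
- MM/GBSA is single-frame, entropy-free, and parameter-agnostic; absolute
  binding energies are not transferable claims.
- Water bridges and halogen bonds are not detected.
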