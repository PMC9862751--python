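"""Geometric protein-ligand interaction detection and interaction fingerprints.

Detects the strong interaction classes used for pose comparison — hydrogen
bonds, pi-pi stacking, ionic bridges — plus hydrophobic contacts, encodes
them per binding-site residue as a structural interaction fingerprint (SIFt),
and clusters docked poses by fingerprint Tanimoto similarity so that only one
representative per contact pattern survives.

All detectors are purely geometric: cutoff distances/angles are exposed as
keyword arguments, aromatic rings must be declared explicitly (no perception),
and formal charges come from residue-name templates at pH 7 or from per-atom
partial charges in the sidecar parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .structio import BACKBONE_NAMES, MolecularStructure

__all__ = [
    "InteractionRecord",
    "InteractionFingerprint",
    "PoseRecord",
    "PoseClustering",
    "detect_hbonds",
    "detect_pipi",
    "detect_ionic",
    "detect_hydrophobic",
    "detect_all",
    "build_sift",
    "tanimoto",
    "cluster_poses",
    "select_top_k",
]

# SIFt bit layout, one row of this per binding-site residue.
SIFT_BITS = (
    "any_contact", "backbone", "sidechain", "polar", "hydrophobic",
    "hb_donor", "hb_acceptor", "aromatic", "charged",
)

_NEG_RES = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_POS_RES = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIP": ("ND1", "NE2")}

_BOND_MAX = 1.8  # Angstrom, distance heuristic for covalent bonds
_DH_BOND_MAX = 1.25  # donor-hydrogen covalent bond


@dataclass
class InteractionRecord:
    """One detected interaction between the ligand and a receptor residue.

    ``direction`` is relative to the ligand: ``donor`` means the ligand
    donates the hydrogen.  ``geometry`` is (distance A, angle deg); the angle
    is 0 where not meaningful.
    """

    kind: str  # hb | pipi | ionic | hydrophobic
    ligand_atoms: tuple[int, ...]  # atom indices into the complex
    residue: tuple[str, int, str]  # (chain, res_id, res_name)
    direction: str = "n/a"
    distance: float = 0.0
    angle: float = 0.0
    receptor_atoms: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("hb", "pipi", "ionic", "hydrophobic"):
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        if self.distance <= 0:
            raise ValueError("interaction distance must be positive")


@dataclass
class InteractionFingerprint:
    """Per-residue interaction bit matrix for one pose."""

    residue_index: list[tuple[str, int, str]]
    bits: np.ndarray  # (n_residues, 9) in {0,1}

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.shape != (len(self.residue_index), len(SIFT_BITS)):
            raise ValueError("bit matrix shape mismatch")
        if not np.all((self.bits == 0) | (self.bits == 1)):
            raise ValueError("fingerprint bits must be 0/1")


@dataclass
class PoseRecord:
    """A scored candidate pose (docking/IFD-style score, lower is better)."""

    pose_id: str
    structure: MolecularStructure
    score: float
    fingerprint: InteractionFingerprint | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("pose score must be finite")


@dataclass
class PoseClustering:
    """Outcome of fingerprint clustering: Table-2-style pose/cluster counts."""

    n_poses: int
    n_clusters: int
    clusters: list[list[PoseRecord]]
    representatives: list[PoseRecord] = field(default_factory=list)


def _neighbors(coords: np.ndarray, i: int, max_dist: float) -> np.ndarray:
    d = np.linalg.norm(coords - coords[i], axis=1)
    d[i] = np.inf
    return np.flatnonzero(d <= max_dist)


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _residue_key(structure: MolecularStructure, i: int) -> tuple[str, int, str]:
    a = structure.atoms[i]
    return (a.chain, a.res_id, a.res_name)


def detect_hbonds(complex: MolecularStructure, d_ha_max: float = 2.8,
                  dha_min: float = 120.0, hax_min: float = 90.0,
                  ) -> list[InteractionRecord]:
    """Intermolecular hydrogen bonds by distance/angle criteria.

    Donor = N/O with a covalently bound H; acceptor = N/O.  A bond requires
    H...A <= ``d_ha_max``, D-H...A >= ``dha_min`` and, for every heavy atom X
    bound to the acceptor, H...A-X >= ``hax_min``.  Donors without hydrogens
    are skipped.  One record per (donor-H, acceptor) pair.
    """
    coords = complex.coords
    records: list[InteractionRecord] = []
    roles = complex.role_mask

    def polar_idx(role: str) -> list[int]:
        return [i for i in complex.indices(role=role)
                if complex.atoms[i].element in ("N", "O")]

    def hydrogens_of(i: int) -> list[int]:
        return [j for j in _neighbors(coords, i, _DH_BOND_MAX)
                if complex.atoms[j].element == "H" and roles[j] == roles[i]]

    def heavy_bonded(i: int) -> list[int]:
        return [j for j in _neighbors(coords, i, _BOND_MAX)
                if complex.atoms[j].is_heavy and roles[j] == roles[i]]

    for donor_role, acceptor_role in (("ligand", "receptor"), ("receptor", "ligand")):
        for d in polar_idx(donor_role):
            hs = hydrogens_of(d)
            for a in polar_idx(acceptor_role):
                for h in hs:
                    dist_ha = float(np.linalg.norm(coords[h] - coords[a]))
                    if dist_ha > d_ha_max:
                        continue
                    if _angle(coords[d], coords[h], coords[a]) < dha_min:
                        continue
                    if any(_angle(coords[h], coords[a], coords[x]) < hax_min
                           for x in heavy_bonded(a)):
                        continue
                    lig_side = d if donor_role == "ligand" else a
                    rec_side = a if donor_role == "ligand" else d
                    records.append(InteractionRecord(
                        kind="hb",
                        ligand_atoms=(lig_side, h) if donor_role == "ligand" else (lig_side,),
                        residue=_residue_key(complex, rec_side),
                        direction="donor" if donor_role == "ligand" else "acceptor",
                        distance=dist_ha,
                        angle=_angle(coords[d], coords[h], coords[a]),
                        receptor_atoms=(rec_side,),
                    ))
    return records


def _ring_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[2]


def detect_pipi(complex: MolecularStructure, ring_defs: dict[str, list[list[int]]],
                d_f2f: float = 4.4, d_e2f: float = 5.5) -> list[InteractionRecord]:
    """Pi-pi stacking between declared ligand and receptor rings.

    ``ring_defs`` maps role (``ligand``/``receptor``) to lists of ring atom
    index sets.  Face-to-face: centroid distance <= ``d_f2f`` and interplanar
    angle <= 30 deg; edge-to-face: distance <= ``d_e2f`` and angle in
    [60, 120] deg.
    """
    coords = complex.coords
    records = []
    for ring in ring_defs.get("ligand", []) + ring_defs.get("receptor", []):
        if len(ring) < 3:
            raise ValueError("ring definition needs at least 3 atoms")
    for lring in ring_defs.get("ligand", []):
        lc, ln = _ring_plane(coords[lring])
        for rring in ring_defs.get("receptor", []):
            rc, rn = _ring_plane(coords[rring])
            dist = float(np.linalg.norm(lc - rc))
            cosang = abs(float(np.dot(ln, rn)))
            ang = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
            kind = None
            if dist <= d_f2f and ang <= 30.0:
                kind = "face-to-face"
            elif dist <= d_e2f and 60.0 <= ang <= 120.0:
                kind = "edge-to-face"
            if kind:
                records.append(InteractionRecord(
                    kind="pipi",
                    ligand_atoms=tuple(lring),
                    residue=_residue_key(complex, rring[0]),
                    direction="n/a",
                    distance=dist,
                    angle=ang,
                    receptor_atoms=tuple(rring),
                ))
    return records


def _formal_charges(complex: MolecularStructure) -> dict[int, int]:
    """Formal charge assignment: residue templates for the receptor, sidecar
    partial charges (|q| >= 0.5 on N/O) for the ligand."""
    charges: dict[int, int] = {}
    have_any = False
    for i, a in enumerate(complex.atoms):
        role = complex.role_mask[i]
        if role == "receptor":
            if a.res_name in _NEG_RES and a.name in _NEG_RES[a.res_name]:
                charges[i] = -1
                have_any = True
            elif a.res_name in _POS_RES and a.name in _POS_RES[a.res_name]:
                charges[i] = +1
                have_any = True
        elif role == "ligand" and a.charge is not None:
            have_any = True
            if a.element in ("N", "O") and abs(a.charge) >= 0.5:
                charges[i] = int(np.sign(a.charge))
    if not have_any:
        raise ValueError(
            "no formal charge assignments available: need charged residue "
            "templates or per-atom charges on the ligand"
        )
    return charges


def detect_ionic(complex: MolecularStructure, d_max: float = 4.0,
                 ) -> list[InteractionRecord]:
    """Ionic bridges: opposite formal charges within ``d_max`` Angstrom."""
    coords = complex.coords
    charges = _formal_charges(complex)
    roles = complex.role_mask
    lig = [i for i in charges if roles[i] == "ligand"]
    rec = [i for i in charges if roles[i] == "receptor"]
    records = []
    for i in lig:
        for j in rec:
            if charges[i] * charges[j] >= 0:
                continue
            dist = float(np.linalg.norm(coords[i] - coords[j]))
            if dist <= d_max:
                records.append(InteractionRecord(
                    kind="ionic", ligand_atoms=(i,),
                    residue=_residue_key(complex, j),
                    distance=dist, receptor_atoms=(j,),
                ))
    return records


def detect_hydrophobic(complex: MolecularStructure, d_max: float = 4.5,
                       ) -> list[InteractionRecord]:
    """Hydrophobic contacts: one record per receptor residue with >= 1
    nonpolar heavy-atom pair (C/S not bonded to N/O) within ``d_max``."""
    coords = complex.coords
    roles = complex.role_mask

    def nonpolar(idx: np.ndarray) -> list[int]:
        out = []
        for i in idx:
            a = complex.atoms[i]
            if a.element not in ("C", "S"):
                continue
            bonded = _neighbors(coords, i, _BOND_MAX)
            if any(complex.atoms[j].element in ("N", "O") for j in bonded):
                continue
            out.append(i)
        return out

    lig_np = nonpolar(complex.indices(role="ligand", heavy_only=True))
    rec_np = nonpolar(complex.indices(role="receptor", heavy_only=True))
    best: dict[tuple[str, int, str], tuple[float, int, int]] = {}
    for i in lig_np:
        for j in rec_np:
            dist = float(np.linalg.norm(coords[i] - coords[j]))
            if dist > d_max:
                continue
            key = _residue_key(complex, j)
            if key not in best or dist < best[key][0]:
                best[key] = (dist, i, j)
    del roles
    return [
        InteractionRecord(kind="hydrophobic", ligand_atoms=(i,), residue=key,
                          distance=dist, receptor_atoms=(j,))
        for key, (dist, i, j) in sorted(best.items())
    ]


def detect_all(complex: MolecularStructure,
               ring_defs: dict[str, list[list[int]]] | None = None,
               include_ionic: bool = True) -> list[InteractionRecord]:
    """All detectors on one complex; ionic detection is skipped quietly when
    no charge assignment exists (``include_ionic=False`` to force-skip)."""
    records = detect_hbonds(complex)
    if ring_defs:
        records += detect_pipi(complex, ring_defs)
    if include_ionic:
        try:
            records += detect_ionic(complex)
        except ValueError:
            pass
    records += detect_hydrophobic(complex)
    return records


def build_sift(pose: PoseRecord, receptor_site: list[tuple[str, int, str]],
               ring_defs: dict[str, list[list[int]]] | None = None,
               contact_dist: float = 4.5) -> InteractionFingerprint:
    """Structural interaction fingerprint of one pose over a fixed site.

    ``receptor_site`` fixes the residue ordering (sorted by chain, res_id) so
    fingerprints of different poses are comparable.  Bits per residue follow
    :data:`SIFT_BITS`; ``any_contact`` is the OR of the rest.
    """
    if not receptor_site:
        raise ValueError("receptor_site must not be empty")
    site = sorted(set(receptor_site), key=lambda r: (r[0], r[1]))
    complex = pose.structure
    coords = complex.coords
    records = detect_all(complex, ring_defs=ring_defs)
    bit_of = {name: k for k, name in enumerate(SIFT_BITS)}
    bits = np.zeros((len(site), len(SIFT_BITS)), dtype=np.uint8)
    row = {key: k for k, key in enumerate(site)}

    # raw proximity contacts -> backbone/sidechain bits
    lig_idx = complex.indices(role="ligand", heavy_only=True)
    for j in complex.indices(role="receptor", heavy_only=True):
        key = _residue_key(complex, j)
        if key not in row:
            continue
        d = np.linalg.norm(coords[lig_idx] - coords[j], axis=1)
        if np.any(d <= contact_dist):
            which = "backbone" if complex.atoms[j].name in BACKBONE_NAMES else "sidechain"
            bits[row[key], bit_of[which]] = 1

    for rec in records:
        if rec.residue not in row:
            continue
        r = row[rec.residue]
        if rec.kind == "hb":
            bits[r, bit_of["polar"]] = 1
            # bit is from the residue's perspective: ligand donor => residue accepts
            if rec.direction == "donor":
                bits[r, bit_of["hb_acceptor"]] = 1
            else:
                bits[r, bit_of["hb_donor"]] = 1
        elif rec.kind == "pipi":
            bits[r, bit_of["aromatic"]] = 1
        elif rec.kind == "ionic":
            bits[r, bit_of["charged"]] = 1
            bits[r, bit_of["polar"]] = 1
        elif rec.kind == "hydrophobic":
            bits[r, bit_of["hydrophobic"]] = 1
    bits[:, bit_of["any_contact"]] = np.any(bits[:, 1:], axis=1)
    return InteractionFingerprint(site, bits)


def tanimoto(a: InteractionFingerprint, b: InteractionFingerprint) -> float:
    """Tanimoto similarity |a AND b| / |a OR b|; 1.0 when both are empty."""
    if a.residue_index != b.residue_index:
        raise ValueError("fingerprints cover different residue sets")
    inter = int(np.sum(a.bits & b.bits))
    union = int(np.sum(a.bits | b.bits))
    return 1.0 if union == 0 else inter / union


def cluster_poses(poses: list[PoseRecord], sim_threshold: float = 0.7,
                  ) -> PoseClustering:
    """Complete-linkage clustering of poses at fingerprint Tanimoto >= threshold.

    Within each cluster the best-scoring pose (lowest score, ties broken by
    pose_id) is kept as representative.  Requires fingerprints to be computed.
    """
    if not poses:
        raise ValueError("no poses to cluster")
    for p in poses:
        if p.fingerprint is None:
            raise ValueError(f"pose {p.pose_id}: fingerprint not computed")
    n = len(poses)
    if n == 1:
        return PoseClustering(1, 1, [list(poses)], list(poses))
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = 1.0 - tanimoto(poses[i].fingerprint,
                                                     poses[j].fingerprint)
    z = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(z, t=1.0 - sim_threshold, criterion="distance")
    clusters: dict[int, list[PoseRecord]] = {}
    for lab, pose in zip(labels, poses):
        clusters.setdefault(int(lab), []).append(pose)
    cluster_list = [sorted(c, key=lambda p: (p.score, p.pose_id))
                    for c in clusters.values()]
    cluster_list.sort(key=lambda c: (c[0].score, c[0].pose_id))
    reps = [c[0] for c in cluster_list]
    return PoseClustering(n, len(cluster_list), cluster_list, reps)


def select_top_k(representatives: list[PoseRecord], k: int = 3) -> list[PoseRecord]:
    """The k best-scoring representatives, score-ascending; fewer when fewer
    exist (some ligands simply produce < k non-redundant poses)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return sorted(representatives, key=lambda p: (p.score, p.pose_id))[:k]
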