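"""Core structural types and I/O.

Molecular structures are plain ordered atom lists with receptor/ligand role
labels; coordinates are in Angstrom throughout, residue numbering follows the
1-based PDB convention, and atom correspondence is always by file order (no
symmetry-corrected RMSD).  Supported formats are PDB v3.3 (ATOM/HETATM/
MODEL/ENDMDL), the AutoDock PDBQT dialect (partial charge in columns 71-76)
and plain XYZ; multi-model PDB doubles as the trajectory interchange format.

Per-atom energetics parameters (partial charge, Lennard-Jones sigma/epsilon,
generalized-Born radius and screening factor) travel in a sidecar CSV keyed
by atom serial, because force-field assignment is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "Atom",
    "MolecularStructure",
    "Trajectory",
    "TrajectoryEnsemble",
    "GridBox",
    "Superposition",
    "ParseError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_parameter_csv",
    "attach_parameters",
    "kabsch_superpose",
    "rmsd_fixed",
    "make_grid_box",
]

# Element symbols accepted on input (H..Og).
_ELEMENTS = frozenset(
    "H HE LI BE B C N O F NE NA MG AL SI P S CL AR K CA SC TI V CR MN FE CO NI "
    "CU ZN GA GE AS SE BR KR RB SR Y ZR NB MO TC RU RH PD AG CD IN SN SB TE I "
    "XE CS BA LA CE PR ND PM SM EU GD TB DY HO ER TM YB LU HF TA W RE OS IR PT "
    "AU HG TL PB BI PO AT RN FR RA AC TH PA U NP PU".split()
)

# AutoDock atom types -> element (PDBQT files carry AD types, not elements).
_AD_TYPES = {
    "A": "C", "C": "C", "N": "N", "NA": "N", "NS": "N", "OA": "O", "OS": "O",
    "SA": "S", "S": "S", "H": "H", "HD": "H", "HS": "H", "F": "F", "CL": "Cl",
    "BR": "Br", "I": "I", "P": "P", "MG": "Mg", "ZN": "Zn", "FE": "Fe",
    "MN": "Mn", "CA": "Ca",
}

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


class ParseError(ValueError):
    """Raised when a structure/trajectory file fails to parse; the message
    names the offending line or model."""


def _norm_element(symbol: str) -> str:
    s = symbol.strip()
    if not s:
        return ""
    return s[0].upper() + s[1:].lower()


@dataclass
class Atom:
    """One atom with optional per-atom energetics parameters.

    ``charge`` is the partial charge in e; ``lj_sigma``/``lj_epsilon`` the
    Lennard-Jones parameters in Angstrom and kcal/mol; ``gb_radius``/
    ``gb_screen`` the intrinsic generalized-Born radius (Angstrom) and the
    unitless descreening factor.
    """

    serial: int
    name: str
    element: str
    res_name: str
    res_id: int
    chain: str
    xyz: np.ndarray
    charge: float | None = None
    lj_sigma: float | None = None
    lj_epsilon: float | None = None
    gb_radius: float | None = None
    gb_screen: float | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.serial}: xyz must be a finite 3-vector")
        if _norm_element(self.element).upper() not in _ELEMENTS:
            raise ValueError(f"atom {self.serial}: unknown element {self.element!r}")
        self.element = _norm_element(self.element)
        if self.res_id < 1:
            raise ValueError(f"atom {self.serial}: res_id must be >= 1 (PDB convention)")

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class MolecularStructure:
    """Ordered atom list with per-atom receptor/ligand/other role labels."""

    atoms: list[Atom]
    role_mask: list[str] = field(default_factory=list)
    title: str = ""

    def __post_init__(self) -> None:
        if not self.role_mask:
            self.role_mask = ["other"] * len(self.atoms)
        if len(self.role_mask) != len(self.atoms):
            raise ValueError("role_mask length must match atom count")
        for r in self.role_mask:
            if r not in ("receptor", "ligand", "other"):
                raise ValueError(f"invalid role {r!r}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array, Angstrom."""
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "MolecularStructure":
        """Copy of the structure with replaced coordinates (same atoms/roles)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, xyz=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return MolecularStructure(atoms, list(self.role_mask), self.title)

    def indices(self, role: str | None = None, heavy_only: bool = False) -> np.ndarray:
        """Atom indices filtered by role and/or heavy-atom flag."""
        idx = []
        for i, a in enumerate(self.atoms):
            if role is not None and self.role_mask[i] != role:
                continue
            if heavy_only and not a.is_heavy:
                continue
            idx.append(i)
        return np.array(idx, dtype=int)

    def subset(self, indices: Iterable[int]) -> "MolecularStructure":
        indices = list(indices)
        return MolecularStructure(
            [self.atoms[i] for i in indices],
            [self.role_mask[i] for i in indices],
            self.title,
        )

    def assign_roles(self, ligand_res: set[str] | None = None) -> None:
        """Label atoms: HETATM-style ligand residues vs everything else.

        Atoms whose res_name is in ``ligand_res`` become ligand, the rest
        receptor.  Default ligand residue names: LIG, UNL, MOL.
        """
        ligand_res = ligand_res or {"LIG", "UNL", "MOL"}
        self.role_mask = [
            "ligand" if a.res_name in ligand_res else "receptor" for a in self.atoms
        ]


@dataclass
class Trajectory:
    """Frames of one simulation trial: (T, N, 3) coords + (T,) timestamps, ps."""

    coords: np.ndarray
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("trajectory coords must be (T, N, 3)")
        if self.timestamps.shape != (self.coords.shape[0],):
            raise ValueError("timestamps length must match frame count")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


@dataclass
class TrajectoryEnsemble:
    """Independent trials over an identical atom set (BPMD-style repeats)."""

    trials: list[Trajectory]
    atom_template: MolecularStructure

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError("ensemble needs at least one trial")
        n_atoms = len(self.atom_template)
        n_frames = self.trials[0].n_frames
        for i, t in enumerate(self.trials):
            if t.coords.shape[1] != n_atoms:
                raise ValueError(f"trial {i}: atom count mismatch with template")
            if t.n_frames != n_frames:
                raise ValueError(f"trial {i}: frame count mismatch")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def timestamps(self) -> np.ndarray:
        return self.trials[0].timestamps


@dataclass
class GridBox:
    """Docking grid box: center and edge lengths in Angstrom."""

    center: np.ndarray
    dims: np.ndarray
    spacing: float = 1.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.dims = np.asarray(self.dims, dtype=float)
        if np.any(self.dims <= 0) or self.spacing <= 0:
            raise ValueError("grid dims and spacing must be positive")


@dataclass
class Superposition:
    """Rigid-body fit: y ~ rotation @ x + translation, with post-fit RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not math.isclose(float(np.linalg.det(self.rotation)), 1.0, abs_tol=1e-6):
            raise ValueError("rotation must be proper (det = +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# readers / writers


def _parse_pdb_line(line: str, lineno: int, pdbqt: bool) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain = line[21].strip() or "A"
        res_id = int(line[22:26])
        xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
    except (ValueError, IndexError) as exc:
        raise ParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from None
    charge = None
    if pdbqt:
        try:
            charge = float(line[70:76])
        except (ValueError, IndexError):
            raise ParseError(f"line {lineno}: malformed PDBQT charge field") from None
        ad_type = line[77:79].strip().upper()
        element = _AD_TYPES.get(ad_type)
        if element is None:
            # fall back to the atom-name leading letters
            element = _guess_element(name)
    else:
        element = line[76:78].strip() if len(line) >= 77 else ""
        element = element or _guess_element(name)
    if _norm_element(element).upper() not in _ELEMENTS:
        raise ParseError(f"line {lineno}: unknown element {element!r}")
    try:
        return Atom(serial, name, element, res_name, res_id, chain, np.array(xyz),
                    charge=charge)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from None


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and _norm_element(stripped[:2]).upper() in _ELEMENTS:
        # two-letter only when the single letter is not itself an element
        if stripped[0].upper() not in _ELEMENTS or stripped[:2].upper() in (
            "CL", "BR", "MG", "ZN", "FE", "MN", "NA",
        ):
            return stripped[:2]
    return stripped[:1]


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    ext = path.suffix.lower().lstrip(".")
    if ext in ("pdb", "ent"):
        return "pdb"
    if ext in ("pdbqt", "xyz"):
        return ext
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def _read_pdb_models(path: Path, pdbqt: bool) -> list[list[Atom]]:
    models: list[list[Atom]] = []
    current: list[Atom] = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if current:
                    models.append(current)
                current = []
                in_model = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                current.append(_parse_pdb_line(line.rstrip("\n"), lineno, pdbqt))
    if current or not models:
        models.append(current)
    if not any(models):
        raise ParseError(f"{path.name}: no ATOM/HETATM records found")
    del in_model
    return [m for m in models if m]


def _read_xyz_models(path: Path) -> list[list[Atom]]:
    models: list[list[Atom]] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"line {i + 1}: expected atom count in XYZ header") from None
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ParseError(f"line {i + 1}: XYZ block truncated (wanted {n} atoms)")
        atoms = []
        for j, rec in enumerate(block):
            parts = rec.split()
            if len(parts) < 4:
                raise ParseError(f"line {i + 3 + j}: malformed XYZ atom record")
            el = parts[0]
            if _norm_element(el).upper() not in _ELEMENTS:
                raise ParseError(f"line {i + 3 + j}: unknown element {el!r}")
            try:
                xyz = np.array([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError:
                raise ParseError(f"line {i + 3 + j}: malformed XYZ coordinates") from None
            atoms.append(Atom(j + 1, el, el, "UNK", 1, "A", xyz))
        models.append(atoms)
        i += 2 + n
    if not models:
        raise ParseError(f"{path.name}: empty XYZ file")
    return models


def read_structure(path: str | Path, format: str | None = None) -> MolecularStructure:
    """Read a single structure (first model of a multi-model file).

    PDBQT partial charges land in ``Atom.charge``.  Raises :class:`ParseError`
    naming the offending line on malformed records or unknown elements.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt in ("pdb", "pdbqt"):
        atoms = _read_pdb_models(path, pdbqt=(fmt == "pdbqt"))[0]
    elif fmt == "xyz":
        atoms = _read_xyz_models(path)[0]
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    return MolecularStructure(atoms, title=path.stem)


def write_structure(structure: MolecularStructure, path: str | Path,
                    format: str | None = None) -> None:
    """Write a structure as PDB or XYZ (coordinates to 3 decimals)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        with open(path, "w") as fh:
            fh.writelines(_pdb_atom_lines(structure))
            fh.write("END\n")
    elif fmt == "xyz":
        with open(path, "w") as fh:
            fh.write(f"{len(structure)}\n{structure.title}\n")
            for a in structure.atoms:
                fh.write(f"{a.element:2s} {a.xyz[0]:12.3f} {a.xyz[1]:12.3f} {a.xyz[2]:12.3f}\n")
    else:
        raise ValueError(f"unsupported output format {fmt!r}")


def _pdb_atom_lines(structure: MolecularStructure) -> list[str]:
    lines = []
    for a, role in zip(structure.atoms, structure.role_mask):
        rec = "HETATM" if role == "ligand" else "ATOM  "
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"{rec}{a.serial:5d} {name:<4s}{a.res_name:>4s}{a.chain:>2s}{a.res_id:4d}    "
            f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}\n"
        )
    return lines


def read_trajectory(path: str | Path, format: str | None = None,
                    timestep_ps: float = 200.0) -> TrajectoryEnsemble:
    """Read a multi-model PDB or multi-block XYZ file as a single-trial ensemble.

    Timestamps are ``frame_index * timestep_ps``; the atom template comes from
    the first model.  An atom-count mismatch between models raises
    :class:`ParseError` naming the model index (1-based).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        models = _read_pdb_models(path, pdbqt=False)
    elif fmt == "xyz":
        models = _read_xyz_models(path)
    else:
        raise ValueError(f"unsupported trajectory format {fmt!r}")
    n0 = len(models[0])
    for i, m in enumerate(models):
        if len(m) != n0:
            raise ParseError(f"model {i + 1}: atom count {len(m)} != {n0} of model 1")
    coords = np.array([[a.xyz for a in m] for m in models])
    timestamps = np.arange(len(models)) * float(timestep_ps)
    template = MolecularStructure(models[0], title=path.stem)
    return TrajectoryEnsemble([Trajectory(coords, timestamps)], template)


def write_trajectory(ensemble_or_traj, template: MolecularStructure | None,
                     path: str | Path) -> None:
    """Write a trajectory (one trial) as a multi-model PDB."""
    if isinstance(ensemble_or_traj, TrajectoryEnsemble):
        traj = ensemble_or_traj.trials[0]
        template = ensemble_or_traj.atom_template
    else:
        traj = ensemble_or_traj
        if template is None:
            raise ValueError("template required when writing a bare Trajectory")
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            fh.write(f"MODEL {i + 1:8d}\n")
            fh.writelines(_pdb_atom_lines(template.with_coords(traj.coords[i])))
            fh.write("ENDMDL\n")
        fh.write("END\n")


_PARAM_COLS = ("charge", "lj_sigma", "lj_epsilon", "gb_radius", "gb_screen")


def read_parameter_csv(path: str | Path) -> pd.DataFrame:
    """Load a per-atom parameter sidecar CSV (serial-keyed)."""
    df = pd.read_csv(path)
    missing = {"serial", *_PARAM_COLS} - set(df.columns)
    if missing:
        raise ValueError(f"parameter CSV missing columns: {sorted(missing)}")
    return df


def attach_parameters(structure: MolecularStructure, params: pd.DataFrame) -> None:
    """Attach sidecar parameters to atoms in place, matching on serial."""
    table = params.set_index("serial")
    for a in structure.atoms:
        if a.serial not in table.index:
            raise ValueError(f"no parameters for atom serial {a.serial}")
        row = table.loc[a.serial]
        for col in _PARAM_COLS:
            setattr(a, col, float(row[col]))


def write_parameter_csv(structure: MolecularStructure, path: str | Path) -> None:
    rows = [
        {"serial": a.serial, **{c: getattr(a, c) for c in _PARAM_COLS}}
        for a in structure.atoms
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# geometry


def rmsd_fixed(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation at fixed atom correspondence (no fitting)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[1] != 3 or a.shape[0] == 0:
        raise ValueError("expected non-empty (N, 3) coordinate arrays")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: Sequence[float] | None = None) -> Superposition:
    """Least-squares optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation + translation minimizing the (weighted) RMSD,
    and the RMSD after the transform.  Requires >= 3 non-collinear points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile/reference must be matching (N, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    cm = (w[:, None] * mobile).sum(axis=0) / wsum
    cr = (w[:, None] * reference).sum(axis=0) / wsum
    x = mobile - cm
    y = reference - cr
    if np.linalg.matrix_rank(x, tol=1e-10) < 2:
        raise ValueError("degenerate point set (collinear or coincident)")
    rot, _ = Rotation.align_vectors(y, x, weights=w)
    R = rot.as_matrix()
    t = cr - R @ cm
    fitted = mobile @ R.T + t
    rmsd = float(np.sqrt(np.sum(w * np.sum((fitted - reference) ** 2, axis=1)) / wsum))
    return Superposition(R, t, rmsd)


def make_grid_box(ligand: MolecularStructure, pad: float = 10.0,
                  spacing: float = 1.0, center: str = "midpoint") -> GridBox:
    """Docking box around the ligand's heavy atoms.

    The box spans the per-axis heavy-atom extent plus ``pad`` on each side
    (the +-10 A augmentation convention).  ``center`` is the bounding-box
    midpoint by default, or ``"centroid"`` for the arithmetic mean position.
    """
    idx = ligand.indices(heavy_only=True)
    if len(idx) == 0:
        raise ValueError("ligand has no heavy atoms")
    xyz = ligand.coords[idx]
    lo = xyz.min(axis=0)
    hi = xyz.max(axis=0)
    if center == "midpoint":
        c = (lo + hi) / 2.0
    elif center == "centroid":
        c = xyz.mean(axis=0)
    else:
        raise ValueError("center must be 'midpoint' or 'centroid'")
    dims = (hi - lo) + 2.0 * pad
    return GridBox(c, dims, spacing)
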