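"""Residue-level features from predicted structure models.

Works on PDB-format models whose B-factor column carries a per-residue
confidence (pLDDT, 0-100), as produced by structure-prediction pipelines.
Features computed per residue:

- contacts: other residues whose alpha-carbon lies within 12 A of this
  residue's alpha-carbon;
- com_distance: distance from the alpha-carbon to the protein's
  atomic-mass-weighted center of mass;
- proximal variant counts: pathogenic / population variant counts summed
  over the nine spatially nearest residues;
- rsa / burial: Shrake-Rupley solvent accessibility normalized by the
  residue's theoretical maximum; buried means RSA < 20%;
- secondary structure: 3-state (H/E/C) assignment from backbone dihedral
  windows;
- plddt: the confidence from the CA B-factor.  Low-confidence residues are
  deliberately not excluded — confidence itself is informative.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

from .constants import (
    ATOMIC_MASSES,
    BURIED_RSA_THRESHOLD,
    DEFAULT_ATOMIC_MASS,
    DEFAULT_MAX_ASA,
    DEFAULT_VDW_RADIUS,
    MAX_ASA,
    VDW_RADII,
)

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "parse_pdb",
    "residue_contacts",
    "com_distance",
    "proximal_variant_counts",
    "shrake_rupley_sasa",
    "rsa",
    "secondary_structure",
    "residue_feature_table",
]


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: np.ndarray
    b_factor: float


@dataclass(frozen=True)
class Residue:
    index: int
    name: str
    atoms: tuple[Atom, ...]

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class StructureModel:
    residues: list[Residue]

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")
        for r in self.residues:
            if r.atom("CA") is None:
                raise ValueError(f"residue {r.index} lacks a CA atom")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def indices(self) -> np.ndarray:
        return np.array([r.index for r in self.residues])

    @property
    def ca_coords(self) -> np.ndarray:
        return np.array([r.atom("CA").coord for r in self.residues])

    @property
    def plddt(self) -> np.ndarray:
        return np.array([r.atom("CA").b_factor for r in self.residues])

    def all_atoms(self) -> tuple[np.ndarray, list[Atom]]:
        atoms = [a for r in self.residues for a in r.atoms]
        return np.array([a.coord for a in atoms]), atoms

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "StructureModel":
        """Rigid-body transformed copy (for invariance checks)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation)
        t = np.zeros(3) if translation is None else np.asarray(translation)
        residues = [
            Residue(
                r.index, r.name,
                tuple(Atom(a.name, a.element, R @ a.coord + t, a.b_factor)
                      for a in r.atoms),
            )
            for r in self.residues
        ]
        return StructureModel(residues)


def parse_pdb(source) -> StructureModel:
    """Parse PDB text (or a path/handle) into a :class:`StructureModel`.

    Only the first model is read; alternate locations other than ''/'A' are
    skipped; heteroatom records are ignored.  Residues without a CA atom
    are excluded with a warning (they cannot enter the geometry features).
    """
    if isinstance(source, str) and "\n" in source:
        handle = io.StringIO(source)
    elif hasattr(source, "read"):
        handle = source
    else:
        handle = open(source)

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", handle)
    models = list(structure)
    if not models:
        raise ValueError("no ATOM records found")
    model = models[0]

    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            hetflag, resseq, _ = res.id
            if hetflag.strip():
                continue
            atoms = []
            for atom in res.get_unpacked_list():
                if atom.get_altloc() not in (" ", "", "A"):
                    continue
                element = (atom.element or atom.get_name()[0]).strip().upper()
                atoms.append(
                    Atom(
                        atom.get_name(), element,
                        np.asarray(atom.get_coord(), dtype=float),
                        float(atom.get_bfactor()),
                    )
                )
            if not atoms:
                continue
            if not any(a.name == "CA" for a in atoms):
                warnings.warn(f"residue {resseq} has no CA; excluded from geometry")
                continue
            residues.append(Residue(int(resseq), res.get_resname().strip(), tuple(atoms)))
    if not residues:
        raise ValueError("no usable residues parsed")
    residues.sort(key=lambda r: r.index)
    return StructureModel(residues)


def residue_contacts(model: StructureModel, cutoff: float = 12.0) -> np.ndarray:
    """Number of other residues with CA within ``cutoff`` A (self excluded)."""
    ca = model.ca_coords
    d = cdist(ca, ca)
    return ((d <= cutoff).sum(axis=1) - 1).astype(int)


def com_distance(model: StructureModel) -> np.ndarray:
    """Distance from each CA to the mass-weighted center of all atoms."""
    coords, atoms = model.all_atoms()
    masses = []
    for a in atoms:
        m = ATOMIC_MASSES.get(a.element)
        if m is None:
            warnings.warn(f"unknown element {a.element!r}; using mass {DEFAULT_ATOMIC_MASS}")
            m = DEFAULT_ATOMIC_MASS
        masses.append(m)
    masses = np.asarray(masses)
    com = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    return np.linalg.norm(model.ca_coords - com, axis=1)


def proximal_variant_counts(
    model: StructureModel,
    variant_map: dict[int, tuple[int, int]],
    k: int = 9,
) -> np.ndarray:
    """Sum variant counts over each residue's ``k`` nearest residues.

    ``variant_map`` maps residue index -> (n_pathogenic, n_population);
    unmapped residues contribute zero.  Nearness is CA-CA distance, self
    excluded, ties broken by lower residue index.  When the chain has at
    most ``k`` other residues, all of them are used.  Returns an (n, 2)
    array of (pathogenic, population) sums.
    """
    if any(c < 0 for pair in variant_map.values() for c in pair):
        raise ValueError("variant counts must be non-negative")
    ca = model.ca_coords
    idx = model.indices
    counts = np.array([variant_map.get(int(i), (0, 0)) for i in idx], dtype=float)
    n = len(idx)
    out = np.zeros((n, 2))
    d = cdist(ca, ca)
    for i in range(n):
        others = np.delete(np.arange(n), i)
        order = np.lexsort((idx[others], d[i, others]))
        nearest = others[order[: min(k, n - 1)]]
        out[i] = counts[nearest].sum(axis=0)
    return out.astype(int)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def shrake_rupley_sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), Shrake-Rupley."""
    coords, atoms = model.all_atoms()
    radii = np.array(
        [VDW_RADII.get(a.element, DEFAULT_VDW_RADIUS) for a in atoms]
    ) + probe_radius
    sphere = _sphere_points(n_sphere_points)
    n_atoms = len(atoms)
    areas = np.zeros(n_atoms)
    d = cdist(coords, coords)
    for i in range(n_atoms):
        pts = coords[i] + radii[i] * sphere
        neighbors = np.where((d[i] < radii[i] + radii) & (np.arange(n_atoms) != i))[0]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbors:
            accessible &= np.linalg.norm(pts - coords[j], axis=1) >= radii[j]
            if not accessible.any():
                break
        areas[i] = 4 * np.pi * radii[i] ** 2 * accessible.mean()
    return areas


def rsa(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> tuple[np.ndarray, list[str]]:
    """Relative solvent accessibility and burial class per residue.

    Residue SASA divided by its theoretical maximum accessible area,
    clipped to [0, 1]; residues with RSA strictly below 20% are 'buried',
    otherwise 'exposed'.
    """
    atom_areas = shrake_rupley_sasa(model, probe_radius, n_sphere_points)
    values = np.zeros(model.n_residues)
    pos = 0
    for i, res in enumerate(model.residues):
        n_atoms = len(res.atoms)
        sasa = atom_areas[pos: pos + n_atoms].sum()
        pos += n_atoms
        values[i] = sasa / MAX_ASA.get(res.name, DEFAULT_MAX_ASA)
    values = np.clip(values, 0.0, 1.0)
    burial = [
        "buried" if v < BURIED_RSA_THRESHOLD else "exposed" for v in values
    ]
    return values, burial


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _ang_diff(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def secondary_structure(model: StructureModel) -> list[str]:
    """3-state secondary structure from backbone dihedral windows.

    H when (phi, psi) lies within 40 degrees of (-60, -45) for at least 4
    consecutive residues; E when within 45 degrees of (-120, 130) for at
    least 2 consecutive; C otherwise.  Residues missing backbone atoms (or
    chains shorter than 3) are C.
    """
    n = model.n_residues
    if n < 3:
        return ["C"] * n

    bb = []
    for r in model.residues:
        trio = tuple(r.atom(name) for name in ("N", "CA", "C"))
        bb.append(None if any(a is None for a in trio) else tuple(a.coord for a in trio))

    phi = [None] * n
    psi = [None] * n
    idx = model.indices
    for i in range(n):
        if bb[i] is None:
            continue
        if i > 0 and bb[i - 1] is not None and idx[i] == idx[i - 1] + 1:
            phi[i] = _dihedral(bb[i - 1][2], bb[i][0], bb[i][1], bb[i][2])
        if i < n - 1 and bb[i + 1] is not None and idx[i + 1] == idx[i] + 1:
            psi[i] = _dihedral(bb[i][0], bb[i][1], bb[i][2], bb[i + 1][0])

    def in_window(i: int, center: tuple[float, float], tol: float) -> bool:
        return (
            phi[i] is not None and psi[i] is not None
            and _ang_diff(phi[i], center[0]) <= tol
            and _ang_diff(psi[i], center[1]) <= tol
        )

    helix = [in_window(i, (-60.0, -45.0), 40.0) for i in range(n)]
    strand = [in_window(i, (-120.0, 130.0), 45.0) for i in range(n)]

    out = ["C"] * n

    def mark_runs(flags: list[bool], min_len: int, symbol: str) -> None:
        i = 0
        while i < n:
            if flags[i]:
                j = i
                while j < n and flags[j]:
                    j += 1
                if j - i >= min_len:
                    for t in range(i, j):
                        if out[t] == "C":
                            out[t] = symbol
                i = j
            else:
                i += 1

    mark_runs(helix, 4, "H")
    mark_runs(strand, 2, "E")
    return out


def residue_feature_table(
    model: StructureModel,
    variant_map: dict[int, tuple[int, int]] | None = None,
    protein_id: str = "protein",
    contact_cutoff: float = 12.0,
    k_proximal: int = 9,
) -> pd.DataFrame:
    """All residue features as a tidy table (one row per residue)."""
    prox = proximal_variant_counts(model, variant_map or {}, k=k_proximal)
    rsa_vals, burial = rsa(model)
    return pd.DataFrame(
        {
            "protein_id": protein_id,
            "residue_index": model.indices,
            "residue_name": [r.name for r in model.residues],
            "contacts": residue_contacts(model, cutoff=contact_cutoff),
            "com_distance": com_distance(model),
            "rsa": rsa_vals,
            "burial": burial,
            "n_proximal_pathogenic": prox[:, 0],
            "n_proximal_population": prox[:, 1],
            "secondary": secondary_structure(model),
            "plddt": model.plddt,
        }
    )
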