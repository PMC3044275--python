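"""Cα-trace geometry: ideal-helix construction, PDB I/O, octapeptide windows
and the 29-component geometric-invariant descriptor.

A helix fragment is represented only by its Cα coordinates.  Each 8-residue
sliding window is summarized by 29 scalars that are invariant under rotation
and translation: the end-to-end distance d(1,8), the area of the triangle
(Cα1, Cα5, Cα8), the five i→i+3 distances, four i→i+4 distances, signed
volumes of the five consecutive tetrahedra (i, i+1, i+2, i+3) and the four
handedness tetrahedra (i, i+1, i+2, i+4), the five tetrahedron edge-sum
perimeters, and four triangle areas (i, i+2, i+4).  Signed volumes flip sign
under mirror reflection and therefore encode helix handedness (positive for
a right-handed helix).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "CAlphaTrace",
    "HelixGeometryParams",
    "OctapeptideWindow",
    "InvariantVector",
    "INVARIANT_NAMES",
    "WINDOW_SIZE",
    "build_ideal_helix",
    "read_ca_trace",
    "write_ca_trace",
    "extract_octapeptides",
    "signed_tetra_volume",
    "triangle_area",
    "compute_invariants",
    "invariant_matrix",
]

WINDOW_SIZE = 8

#: Frozen order of the 29 invariant names.  1-based residue indices within
#: the octapeptide, matching the Cα1..Cα8 convention.
INVARIANT_NAMES: tuple[str, ...] = (
    ("d_1_8", "A_1_5_8")
    + tuple(f"d_{i}_{i + 3}" for i in range(1, 6))
    + tuple(f"d_{i}_{i + 4}" for i in range(1, 5))
    + tuple(f"vol_{i}_{i + 1}_{i + 2}_{i + 3}" for i in range(1, 6))
    + tuple(f"vol_{i}_{i + 1}_{i + 2}_{i + 4}" for i in range(1, 5))
    + tuple(f"perim_{i}_{i + 3}" for i in range(1, 6))
    + tuple(f"area_{i}_{i + 2}_{i + 4}" for i in range(1, 5))
)
assert len(INVARIANT_NAMES) == 29


@dataclass
class CAlphaTrace:
    """Ordered Cα coordinates of one chain (or synthetic helix).

    Parameters
    ----------
    coords : (n, 3) float array, Å
    sequence : one-letter amino-acid string of length n
    source_id : free-text origin tag (PDB id + chain, or a synthetic label)
    residue_index : 1-based residue ordinals; defaults to 1..n
    """

    coords: np.ndarray
    sequence: str
    source_id: str = "unknown"
    residue_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if len(self.sequence) != len(self.coords):
            raise ValueError(
                f"sequence length {len(self.sequence)} != coordinate count "
                f"{len(self.coords)}"
            )
        if self.residue_index is None:
            self.residue_index = np.arange(1, len(self.coords) + 1)
        else:
            self.residue_index = np.asarray(self.residue_index, dtype=int)
        if len(self) >= 2:
            d = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
            if np.any((d <= 2.0) | (d >= 4.5)):
                warnings.warn(
                    f"{self.source_id}: consecutive Cα–Cα distance outside "
                    "(2.0, 4.5) Å — trace may not be a valid backbone",
                    stacklevel=2,
                )

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class HelixGeometryParams:
    """Backbone torsions and bond geometry for ideal-helix construction.

    Defaults are the canonical right-handed α-helix torsions and textbook
    backbone bond lengths/angles.
    """

    phi: float = -63.0
    psi: float = -43.0
    omega: float = 180.0
    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329
    angle_n_ca_c: float = 111.2
    angle_ca_c_n: float = 116.2
    angle_c_n_ca: float = 121.7
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        for name in ("phi", "psi", "omega"):
            v = getattr(self, name)
            if not (-180.0 < v <= 180.0):
                raise ValueError(f"{name}={v} outside (-180, 180]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class OctapeptideWindow:
    """One 8-residue sliding window of a Cα trace (1-based ``start``)."""

    parent: CAlphaTrace
    start: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= len(self.parent) - WINDOW_SIZE + 1:
            raise ValueError(f"window start {self.start} out of range")

    @property
    def coords(self) -> np.ndarray:
        return self.parent.coords[self.start - 1 : self.start - 1 + WINDOW_SIZE]

    @property
    def sequence(self) -> str:
        return self.parent.sequence[self.start - 1 : self.start - 1 + WINDOW_SIZE]


@dataclass
class InvariantVector:
    """The 29 geometric invariants of one octapeptide window.

    ``values`` follows the frozen :data:`INVARIANT_NAMES` order.  Named
    slices expose the families used in downstream profile analysis.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (29,):
            raise ValueError("InvariantVector requires exactly 29 components")

    @property
    def d18(self) -> float:
        return float(self.values[0])

    @property
    def a158(self) -> float:
        return float(self.values[1])

    @property
    def d_i_i3(self) -> np.ndarray:
        return self.values[2:7]

    @property
    def d_i_i4(self) -> np.ndarray:
        return self.values[7:11]

    @property
    def vol_i_i3(self) -> np.ndarray:
        return self.values[11:16]

    @property
    def vol_i_i4(self) -> np.ndarray:
        return self.values[16:20]

    @property
    def perimeters(self) -> np.ndarray:
        return self.values[20:25]

    @property
    def areas_i_i2_i4(self) -> np.ndarray:
        return self.values[25:29]

    def to_dict(self) -> dict[str, float]:
        return dict(zip(INVARIANT_NAMES, map(float, self.values)))


# ---------------------------------------------------------------------------
# Elementary invariants


def signed_tetra_volume(p1, p2, p3, p4) -> float:
    """Signed tetrahedron volume ((p2−p1)×(p3−p1))·(p4−p1)/6 in Å³.

    The sign encodes chirality: mirror reflection negates it.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    return float(np.dot(np.cross(p2 - p1, p3 - p1), p4 - p1) / 6.0)


def triangle_area(p1, p2, p3) -> float:
    """Area of the triangle (p1, p2, p3) in Å²."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    return float(0.5 * np.linalg.norm(np.cross(p2 - p1, p3 - p1)))


# ---------------------------------------------------------------------------
# Ideal-helix construction


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Next atom d with |c−d| = bond, ∠(b,c,d) = angle, τ(a,b,c,d) = torsion."""
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.cos(tor) * np.sin(ang),
            bond * np.sin(tor) * np.sin(ang),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_ideal_helix(
    n_residues: int,
    params: HelixGeometryParams | None = None,
    sequence: str | None = None,
    seed: int | None = None,
    source_id: str = "ideal-helix",
) -> CAlphaTrace:
    """Construct a Cα trace from repeated (φ, ψ, ω) backbone torsions.

    The N–Cα–C backbone is grown residue by residue with the standard
    internal-coordinate (NeRF) construction; the Cα atoms are returned.
    Gaussian coordinate noise of ``params.noise_sigma`` Å is added when
    nonzero, seeded by ``seed``.
    """
    if n_residues < 4:
        raise ValueError("an ideal helix needs at least 4 residues")
    params = params or HelixGeometryParams()
    if sequence is None:
        sequence = "A" * n_residues
    if len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")

    n0 = np.zeros(3)
    ca0 = np.array([params.bond_n_ca, 0.0, 0.0])
    ang = np.deg2rad(params.angle_n_ca_c)
    c0 = ca0 + params.bond_ca_c * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])
    atoms = [n0, ca0, c0]
    for _ in range(1, n_residues):
        nn = _place_atom(atoms[-3], atoms[-2], atoms[-1],
                         params.bond_c_n, params.angle_ca_c_n, params.psi)
        can = _place_atom(atoms[-2], atoms[-1], nn,
                          params.bond_n_ca, params.angle_c_n_ca, params.omega)
        cn = _place_atom(atoms[-1], nn, can,
                         params.bond_ca_c, params.angle_n_ca_c, params.phi)
        atoms.extend([nn, can, cn])
    ca = np.array(atoms[1::3])

    if params.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        ca = ca + rng.normal(0.0, params.noise_sigma, size=ca.shape)
    return CAlphaTrace(coords=ca, sequence=sequence, source_id=source_id)


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)

_AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA1_TO_3 = {v: k for k, v in _AA3_TO_1.items()}


def read_ca_trace(path, chain: str) -> CAlphaTrace:
    """Read one chain's Cα trace from a PDB file.

    Alternate locations are resolved to the highest-occupancy conformer;
    residues lacking a Cα atom are skipped with a warning.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="occupancy")
    if chain not in set(atoms.chain_id):
        raise KeyError(f"chain {chain!r} not present in {path}")
    sel = atoms[atoms.chain_id == chain]
    coords, letters, res_ids = [], [], []
    for res_id in np.unique(sel.res_id):
        res = sel[sel.res_id == res_id]
        ca = res[res.atom_name == "CA"]
        if len(ca) == 0:
            warnings.warn(f"residue {res_id} in chain {chain} has no Cα; skipped",
                          stacklevel=2)
            continue
        coords.append(ca.coord[0])
        letters.append(_AA3_TO_1.get(str(res.res_name[0]), "X"))
        res_ids.append(int(res_id))
    return CAlphaTrace(
        coords=np.array(coords, dtype=float).reshape(-1, 3),
        sequence="".join(letters),
        source_id=f"{path}:{chain}",
        residue_index=np.array(res_ids, dtype=int),
    )


def write_ca_trace(trace: CAlphaTrace, path, chain: str = "A") -> None:
    """Write a Cα-only PDB file (one CA ATOM record per residue)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(trace)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(trace.coords, dtype=np.float32)
    arr.chain_id = np.full(n, chain)
    arr.res_id = np.asarray(trace.residue_index)
    arr.res_name = np.array([_AA1_TO_3.get(a, "UNK") for a in trace.sequence])
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.hetero = np.zeros(n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Windows and the 29-invariant descriptor


def extract_octapeptides(trace: CAlphaTrace) -> list[OctapeptideWindow]:
    """All 8-residue sliding windows (step 1) of the trace.

    Consecutive windows overlap in exactly 7 residues.  A trace shorter
    than 8 residues yields an empty list.
    """
    if len(trace) < WINDOW_SIZE:
        return []
    return [OctapeptideWindow(trace, s) for s in range(1, len(trace) - WINDOW_SIZE + 2)]


def compute_invariants(window: OctapeptideWindow | np.ndarray) -> InvariantVector:
    """Compute the 29 invariants of one octapeptide window.

    Accepts either an :class:`OctapeptideWindow` or a bare (8, 3) array.
    Duplicated coordinates produce zeros where geometry forces them and a
    warning, never an error.
    """
    p = window.coords if isinstance(window, OctapeptideWindow) else np.asarray(window, float)
    if p.shape != (WINDOW_SIZE, 3):
        raise ValueError("expected 8 Cα coordinates")
    if len(np.unique(p.round(6), axis=0)) < WINDOW_SIZE:
        warnings.warn("duplicated Cα coordinates in window; degenerate values set to 0",
                      stacklevel=2)

    v = np.empty(29)
    v[0] = np.linalg.norm(p[7] - p[0])                       # d_1_8
    v[1] = triangle_area(p[0], p[4], p[7])                   # A_1_5_8
    for i in range(5):                                       # d_i_i+3
        v[2 + i] = np.linalg.norm(p[i + 3] - p[i])
    for i in range(4):                                       # d_i_i+4
        v[7 + i] = np.linalg.norm(p[i + 4] - p[i])
    for i in range(5):                                       # vol (i..i+3)
        v[11 + i] = signed_tetra_volume(p[i], p[i + 1], p[i + 2], p[i + 3])
    for i in range(4):                                       # vol (i,i+1,i+2,i+4)
        v[16 + i] = signed_tetra_volume(p[i], p[i + 1], p[i + 2], p[i + 4])
    for i in range(5):                                       # tetrahedron perimeter
        quad = p[i : i + 4]
        perim = 0.0
        for a in range(4):
            for b in range(a + 1, 4):
                perim += np.linalg.norm(quad[a] - quad[b])
        v[20 + i] = perim
    for i in range(4):                                       # area (i, i+2, i+4)
        v[25 + i] = triangle_area(p[i], p[i + 2], p[i + 4])
    return InvariantVector(v)


def invariant_matrix(windows: Sequence[OctapeptideWindow] | Iterator) -> np.ndarray:
    """Stack :func:`compute_invariants` over windows into an (n, 29) matrix."""
    return np.array([compute_invariants(w).values for w in windows]).reshape(-1, 29)
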