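"""Synthetic helix corpus generator.

The analysis pipeline was designed for helices harvested from real protein
domains; no accession list of that corpus is distributable, so this module
generates a labeled stand-in with the statistical structure the analysis
assumes: five geometric subclasses (regular, extended, c-cap, kinked,
curved) realized as parametric deformations of an ideal α-helix, paired
with subclass-biased amino-acid sequences whose overall and positional
preferences follow the patterns the propensity analysis is meant to
recover.

Geometry defaults are chosen so the subclass signatures of the gross
invariants reproduce the expected ordering (extended d18 > regular d18 >
c-cap d18 > curved d18; kinked A158 largest); sequence enrichment factors
default to 2–4x for signature residues — strong enough for the classifier
to recover their weight signs, weak enough to keep the task non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .assembly import FLANK_WIDTH, HelixSegment, attach_flanks
from .geometry import (
    CAlphaTrace,
    HelixGeometryParams,
    build_ideal_helix,
    compute_invariants,
    extract_octapeptides,
)

__all__ = [
    "SUBCLASSES",
    "SubclassGeometrySpec",
    "SubclassSequenceProfile",
    "DatasetConfig",
    "SyntheticDataset",
    "DEFAULT_GEOMETRY_SPECS",
    "DEFAULT_SEQUENCE_PROFILES",
    "BACKGROUND_FREQUENCIES",
    "generate_geometry",
    "generate_sequence",
    "generate_dataset",
    "generate_window_dataset",
]

SUBCLASSES = ("regular", "extended", "c-cap", "kinked", "curved")

_AA = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Approximate natural amino-acid background frequencies (renormalized).
BACKGROUND_FREQUENCIES: dict[str, float] = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}
_total = sum(BACKGROUND_FREQUENCIES.values())
BACKGROUND_FREQUENCIES = {a: v / _total for a, v in BACKGROUND_FREQUENCIES.items()}


# ---------------------------------------------------------------------------
# Geometry generation


@dataclass
class SubclassGeometrySpec:
    """Parametric deformation of an ideal helix for one subclass.

    Exactly one deformation family is active per non-regular subclass:
    ``rise_scale`` (extended), ``kink_angle``/``kink_position`` (kinked),
    ``curvature`` (curved) or ``compress_count``/``compress_factor``
    (c-cap).  ``noise_sigma`` (Å) is isotropic Gaussian coordinate noise.
    """

    name: str
    phi: float = -63.0
    psi: float = -43.0
    rise_scale: float = 1.0
    kink_angle: float = 0.0        # degrees
    kink_position: int = 5         # 1-based residue where the axis bends
    kink_stretch: float = 1.2      # Å of local axial extension at the kink
    curvature: float = 0.0         # 1/Å, of the helix axis arc
    compress_count: int = 0        # residues compressed at the C-terminus
    compress_factor: float = 1.0   # radial scale for compressed residues
    compress_axial_factor: float = 0.9  # rise scale for compressed residues
    noise_sigma: float = 0.15

    def __post_init__(self) -> None:
        active = sum(
            [self.rise_scale != 1.0, self.kink_angle != 0.0,
             self.curvature != 0.0, self.compress_count > 0]
        )
        if active > 1:
            raise ValueError("at most one deformation family may be active")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


DEFAULT_GEOMETRY_SPECS: dict[str, SubclassGeometrySpec] = {
    "regular": SubclassGeometrySpec(name="regular"),
    "extended": SubclassGeometrySpec(name="extended", rise_scale=1.08),
    "c-cap": SubclassGeometrySpec(name="c-cap", compress_count=3,
                                  compress_factor=0.6),
    "kinked": SubclassGeometrySpec(name="kinked", kink_angle=25.0,
                                   kink_position=5),
    "curved": SubclassGeometrySpec(name="curved", curvature=0.08),
}


def _axis_frame(coords: np.ndarray) -> np.ndarray:
    """Rotate/translate so the helix axis is +z and passes through the origin.

    The axis direction comes from cross products of successive second
    differences (which are exactly radial for an ideal circular helix), the
    in-plane center from an algebraic circle fit, so an ideal helix ends up
    with uniform radius, twist and rise in the returned frame.
    """
    p = np.asarray(coords, float)
    b = p[:-2] - 2 * p[1:-1] + p[2:]
    w = np.cross(b[:-1], b[1:])
    w = w / np.linalg.norm(w, axis=1, keepdims=True)
    w = w * np.sign(w @ (p[-1] - p[0]))[:, None]
    z = w.mean(axis=0)
    z /= np.linalg.norm(z)
    x = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(x, z)) > 0.9:
        x = np.array([0.0, 1.0, 0.0])
    x = x - np.dot(x, z) * z
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    q = (p - p.mean(axis=0)) @ np.vstack([x, y, z]).T
    design = np.column_stack([2 * q[:, 0], 2 * q[:, 1], np.ones(len(q))])
    center = np.linalg.lstsq(design, q[:, 0] ** 2 + q[:, 1] ** 2, rcond=None)[0]
    q[:, 0] -= center[0]
    q[:, 1] -= center[1]
    return q


def _rotation(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def _apply_kink(p: np.ndarray, position: int, angle_deg: float,
                stretch: float = 1.2) -> np.ndarray:
    """Bend the helix axis at ``position`` (1-based Cα) with local extension.

    A proline-style kink both tilts the downstream axis and locally
    lengthens the backbone (the broken hydrogen bond lets the rise open
    up), so the C-terminal part is rotated by ``angle_deg`` about an axis
    through the kink Cα perpendicular to the helix axis and shifted by
    ``stretch`` Å along the axis (split over the two bonds flanking the
    kink).  Among the candidate bend directions the one giving the widest
    (Cα1, Cα5, Cα8)-style triangle while still extending the end-to-end
    distance is chosen, matching the extended-but-bent character of kinked
    helices.
    """
    d18_base = np.linalg.norm(p[-1] - p[0])

    def metrics(q):
        d = np.linalg.norm(q[-1] - q[0])
        area = 0.5 * np.linalg.norm(
            np.cross(q[len(q) // 2] - q[0], q[-1] - q[0]))
        return d, area

    pivot = p[position - 1].copy()
    best = None
    fallback = None
    for az in np.arange(0.0, 360.0, 22.5):
        bend_axis = np.array([np.cos(np.deg2rad(az)), np.sin(np.deg2rad(az)), 0.0])
        R = _rotation(bend_axis, np.deg2rad(angle_deg))
        q = p.copy()
        q[position - 1 :] = (q[position - 1 :] - pivot) @ R.T + pivot
        q[position - 1 :, 2] += stretch / 2
        q[position:, 2] += stretch / 2
        d, area = metrics(q)
        if fallback is None or d + area > fallback[0]:
            fallback = (d + area, q)
        if d >= d18_base + 0.3 and (best is None or area > best[0]):
            best = (area, q)
    return (best or fallback)[1]


def _apply_curvature(p: np.ndarray, curvature: float) -> np.ndarray:
    """Re-wind the helix around a circular-arc axis of radius 1/curvature.

    The cylindrical coordinates (radius, phase, axial position) of each Cα
    are read off in the straight-axis frame and re-laid along an arc in the
    xz-plane using the arc's local normal/binormal frame, so the local
    helical geometry is preserved while the axis bends.
    """
    r = 1.0 / curvature
    rho = np.hypot(p[:, 0], p[:, 1])
    theta = np.unwrap(np.arctan2(p[:, 1], p[:, 0]))
    z = p[:, 2] - p[:, 2].min()
    a = z / r
    centerline = np.column_stack([r * (1 - np.cos(a)), np.zeros_like(a), r * np.sin(a)])
    normal = np.column_stack([np.cos(a), np.zeros_like(a), -np.sin(a)])
    out = centerline + (rho * np.cos(theta))[:, None] * normal
    out[:, 1] += rho * np.sin(theta)
    return out


def _apply_compression(p: np.ndarray, count: int, factor: float,
                       axial_factor: float = 0.9) -> np.ndarray:
    """Compact the last ``count`` residues toward the helix axis.

    Radial distance is scaled down to ``factor`` (graded from 1 at the
    boundary) and the local rise to ``axial_factor``, producing the
    compact C-terminal cap."""
    q = p.copy()
    n = len(p)
    z_boundary = q[n - count - 1, 2]
    for j, i in enumerate(range(n - count, n)):
        t = (j + 1) / count
        f_r = 1.0 + (factor - 1.0) * t
        f_z = 1.0 + (axial_factor - 1.0) * t
        q[i, 0] *= f_r
        q[i, 1] *= f_r
        q[i, 2] = z_boundary + (q[i, 2] - z_boundary) * f_z
    return q


def generate_geometry(
    spec: SubclassGeometrySpec,
    length: int,
    seed: int | None = None,
    sequence: str | None = None,
) -> CAlphaTrace:
    """Generate one Cα trace of ``length`` residues for a geometry subclass."""
    if length < 8:
        raise ValueError("helix length must be >= 8")
    params = HelixGeometryParams(phi=spec.phi, psi=spec.psi, noise_sigma=0.0)
    base = build_ideal_helix(length, params, sequence=sequence,
                             source_id=f"synthetic:{spec.name}")
    p = _axis_frame(base.coords)
    if spec.rise_scale != 1.0:
        p = p * np.array([1.0, 1.0, spec.rise_scale])
    elif spec.kink_angle != 0.0:
        pos = min(max(spec.kink_position, 2), length - 1)
        p = _apply_kink(p, pos, spec.kink_angle, spec.kink_stretch)
    elif spec.curvature != 0.0:
        p = _apply_curvature(p, spec.curvature)
    elif spec.compress_count > 0:
        p = _apply_compression(p, min(spec.compress_count, length - 1),
                               spec.compress_factor, spec.compress_axial_factor)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        p = p + rng.normal(0.0, spec.noise_sigma, size=p.shape)
    return CAlphaTrace(coords=p, sequence=base.sequence,
                       source_id=f"synthetic:{spec.name}")


# ---------------------------------------------------------------------------
# Sequence generation


@dataclass
class SubclassSequenceProfile:
    """Sequence preferences of one subclass.

    ``overall_enrichment`` multiplies the background for interior residues;
    ``n_preferred``/``c_preferred`` list the favored residues per terminal
    position (N1..N4 and C4..C1), boosted by ``positional_boost`` over the
    background; flank profiles boost their preferred residues by
    ``flank_boost``.
    """

    name: str
    overall_enrichment: dict[str, float] = field(default_factory=dict)
    n_preferred: tuple = ((), (), (), ())
    c_preferred: tuple = ((), (), (), ())          # C4, C3, C2, C1 order
    flank_before_preferred: tuple = ()
    flank_before_disfavored: tuple = ()
    flank_after_preferred: tuple = ()
    flank_after_disfavored: tuple = ()
    positional_boost: float = 4.0
    flank_boost: float = 3.0

    def _distribution(self, enrich: Mapping[str, float]) -> np.ndarray:
        p = np.array([BACKGROUND_FREQUENCIES[a] * enrich.get(a, 1.0) for a in _AA])
        return p / p.sum()

    def interior_distribution(self) -> np.ndarray:
        return self._distribution(self.overall_enrichment)

    def positional_distribution(self, preferred: Sequence[str],
                                boost: float | None = None) -> np.ndarray:
        # position preferences act on top of the class composition, but a
        # preferred residue is never boosted below the plain-background
        # boost (otherwise an interior-depleted residue — Gly capping a
        # regular helix, say — would lose its stated position preference)
        boost = self.positional_boost if boost is None else boost
        enrich = dict(self.overall_enrichment)
        for a in preferred:
            enrich[a] = boost * max(1.0, enrich.get(a, 1.0))
        return self._distribution(enrich)

    def flank_distribution(self, preferred: Sequence[str],
                           disfavored: Sequence[str] = ()) -> np.ndarray:
        # flanks lie outside the helix: boost/deplete over the plain
        # background, without the helix-interior enrichment
        enrich = {a: self.flank_boost for a in preferred}
        enrich.update({a: 1.0 / self.flank_boost for a in disfavored})
        return self._distribution(enrich)


DEFAULT_SEQUENCE_PROFILES: dict[str, SubclassSequenceProfile] = {
    "regular": SubclassSequenceProfile(
        name="regular",
        overall_enrichment={"A": 2.0, "L": 2.0, "I": 1.8, "E": 1.6, "Q": 1.6,
                            "K": 1.4, "R": 1.4, "M": 1.4, "P": 0.3, "G": 0.4,
                            "F": 0.5, "W": 0.5, "Y": 0.5, "D": 0.7, "H": 0.6,
                            "C": 0.5, "N": 0.6, "S": 0.7, "T": 0.7},
        n_preferred=(("S", "T", "D", "N"), ("P",), ("E",), ("E", "Q")),
        c_preferred=(("A", "I", "L"), ("K", "A", "R", "E", "Q"),
                     ("L", "A", "Q", "K", "R"), ("G",)),
        flank_before_preferred=("G",),
        flank_before_disfavored=("A", "L", "I", "V", "M"),
        flank_after_preferred=("P",),
    ),
    "extended": SubclassSequenceProfile(
        name="extended",
        overall_enrichment={"L": 2.0, "M": 2.0, "A": 1.6, "F": 1.8, "Q": 1.3,
                            "P": 0.7, "G": 0.6},
        n_preferred=(("D", "N"), ("P", "A", "W", "E", "L"),
                     ("E", "A", "Q"), ("E", "L", "F", "Q")),
        c_preferred=(("L", "M", "A"), ("L", "Q", "K"), ("L", "Q", "K"),
                     ("L", "F", "Y", "Q", "M")),
    ),
    "c-cap": SubclassSequenceProfile(
        name="c-cap",
        overall_enrichment={"H": 2.5, "F": 1.8, "Y": 1.8, "L": 1.4, "A": 1.2,
                            "E": 1.2, "R": 1.3, "G": 1.3},
        n_preferred=(("D", "E", "A"), ("Q", "A", "E"), ("E", "W", "A", "L"),
                     ("L", "F", "I", "M")),
        c_preferred=(("L", "A", "R", "M"), ("K", "R", "E", "Q", "L"),
                     ("H", "Y", "F"), ("G",)),
    ),
    "kinked": SubclassSequenceProfile(
        name="kinked",
        overall_enrichment={"P": 3.0, "D": 2.0, "H": 2.0, "F": 2.0, "Y": 1.8,
                            "W": 1.8, "A": 0.7, "L": 0.7, "E": 0.8, "Q": 0.8,
                            "K": 0.8, "R": 0.8},
        n_preferred=(("P", "E"), ("E", "P", "D"), ("N", "H", "Y", "F"),
                     ("W", "A", "L", "F")),
        c_preferred=(("P",), ("E", "Q", "W"), ("L", "I", "F", "Y", "V"),
                     ("L", "M", "I", "A")),
    ),
    "curved": SubclassSequenceProfile(
        name="curved",
        overall_enrichment={"P": 3.0, "N": 2.0, "W": 2.5, "C": 2.0, "D": 2.0,
                            "H": 2.0, "A": 0.7, "L": 0.7, "E": 0.8, "K": 0.8,
                            "R": 0.8, "I": 0.7},
        n_preferred=(("Y", "F", "W"), ("E", "K", "R"),
                     ("H", "N", "Q", "K", "E"), ("N", "D", "H", "C", "G")),
        c_preferred=(("P",), ("P", "E"), ("H", "P", "W"),
                     ("F", "Y", "L", "W", "A")),
    ),
}


def _draw(rng: np.random.Generator, dist: np.ndarray, n: int = 1) -> str:
    return "".join(_AA[i] for i in rng.choice(len(_AA), size=n, p=dist))


def generate_sequence(
    profile: SubclassSequenceProfile,
    length: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[str, str, str]:
    """Sample (helix sequence, flank_before, flank_after) for a subclass.

    Positions 1..4 and the last four follow the positional multinomials;
    interior residues follow the overall-enriched background; flanks are
    4-residue draws from the flank profiles.
    """
    if length < 8:
        raise ValueError("helix length must be >= 8")
    rng = rng if rng is not None else np.random.default_rng(seed)
    chars = []
    for j in range(4):
        chars.append(_draw(rng, profile.positional_distribution(profile.n_preferred[j])))
    interior = length - 8
    if interior > 0:
        chars.append(_draw(rng, profile.interior_distribution(), interior))
    for j in range(4):
        chars.append(_draw(rng, profile.positional_distribution(profile.c_preferred[j])))
    bg = profile.flank_distribution(profile.flank_before_preferred,
                                    profile.flank_before_disfavored)
    ag = profile.flank_distribution(profile.flank_after_preferred,
                                    profile.flank_after_disfavored)
    return "".join(chars), _draw(rng, bg, FLANK_WIDTH), _draw(rng, ag, FLANK_WIDTH)


# ---------------------------------------------------------------------------
# Corpus assembly


#: Per-subclass fractions of generated helix counts.  The regular share is
#: chosen so that, after restricting to training lengths (8..15) under the
#: default length distribution, the positive (regular) fraction of the
#: classifier corpus is 0.62; the remainder splits in proportion to the
#: subclass mixing weights 5:5:2:1.
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "regular": 0.6885, "extended": 0.1198, "c-cap": 0.1198,
    "kinked": 0.0479, "curved": 0.0240,
}

#: Per-subclass helix-length bin probabilities (l == 8, 9..15, > 15),
#: following the coarse length distribution of the study corpus.
DEFAULT_LENGTH_BINS: dict[str, tuple[float, float, float]] = {
    "regular": (0.1441, 0.5960, 0.2598),
    "extended": (0.7274, 0.2724, 0.0002),
    "c-cap": (0.7904, 0.2095, 0.0001),
    "kinked": (0.9931, 0.0069, 0.0),
    "curved": (0.9302, 0.0698, 0.0),
}


@dataclass
class DatasetConfig:
    n_helices: int = 3000
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    length_bins: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_BINS))
    max_long_length: int = 22
    geometry_specs: dict[str, SubclassGeometrySpec] = field(
        default_factory=lambda: dict(DEFAULT_GEOMETRY_SPECS))
    sequence_profiles: dict[str, SubclassSequenceProfile] = field(
        default_factory=lambda: dict(DEFAULT_SEQUENCE_PROFILES))
    uniform_profiles: bool = False  # negative control: no sequence signal


@dataclass
class SyntheticDataset:
    """Labeled corpus: one trace + one flanked segment per helix."""

    traces: list[CAlphaTrace]
    segments: list[HelixSegment]
    labels: list[str]
    chain_sequences: list[str]

    def __len__(self) -> int:
        return len(self.labels)


def _sample_length(rng: np.random.Generator, bins: tuple[float, float, float],
                   max_long: int) -> int:
    b = rng.choice(3, p=np.array(bins) / np.sum(bins))
    if b == 0:
        return 8
    if b == 1:
        return int(rng.integers(9, 16))
    return int(rng.integers(16, max_long + 1))


def generate_dataset(config: DatasetConfig | None = None,
                     seed: int = 0,
                     out_dir: str | Path | None = None) -> SyntheticDataset:
    """Generate the full labeled corpus (geometry + sequences + flanks).

    Deterministic under ``seed``.  When ``out_dir`` is given, writes one
    Cα-only PDB per trace, a FASTA of helix sequences (flanks in the
    description line) and a tab-separated label manifest.
    """
    config = config or DatasetConfig()
    rng = np.random.default_rng(seed)
    names = sorted(config.class_proportions)
    props = np.array([config.class_proportions[s] for s in names], float)
    props = props / props.sum()
    counts = rng.multinomial(config.n_helices, props)

    traces, segments, labels, chains = [], [], [], []
    idx = 0
    for name, count in zip(names, counts):
        profile = config.sequence_profiles[name]
        if config.uniform_profiles:
            profile = SubclassSequenceProfile(name=name)
        spec = config.geometry_specs[name]
        for _ in range(count):
            length = _sample_length(rng, config.length_bins[name],
                                    config.max_long_length)
            seq, fb, fa = generate_sequence(profile, length, rng=rng)
            gseed = int(rng.integers(0, 2**31 - 1))
            trace = generate_geometry(spec, length, seed=gseed, sequence=seq)
            trace.source_id = f"synthetic:{name}:{idx}"
            chain = fb + seq + fa
            nwin = length - 7
            seg = HelixSegment(
                source_id=trace.source_id,
                start=FLANK_WIDTH + 1,
                end=FLANK_WIDTH + length,
                sequence=seq,
                subclass_labels=(name,) * nwin,
            )
            seg = attach_flanks(seg, chain)
            traces.append(trace)
            segments.append(seg)
            labels.append(name)
            chains.append(chain)
            idx += 1

    ds = SyntheticDataset(traces=traces, segments=segments, labels=labels,
                          chain_sequences=chains)
    if out_dir is not None:
        _write_dataset(ds, Path(out_dir))
    return ds


def _write_dataset(ds: SyntheticDataset, out_dir: Path) -> None:
    from .geometry import write_ca_trace

    out_dir.mkdir(parents=True, exist_ok=True)
    pdb_dir = out_dir / "pdb"
    pdb_dir.mkdir(exist_ok=True)
    with open(out_dir / "sequences.fasta", "w") as fa, \
         open(out_dir / "labels.tsv", "w") as tsv:
        tsv.write("helix_id\tsubclass\tlength\tflank_before\tflank_after\n")
        for i, (trace, seg, label) in enumerate(
                zip(ds.traces, ds.segments, ds.labels)):
            hid = f"helix{i:05d}"
            write_ca_trace(trace, pdb_dir / f"{hid}.pdb")
            fa.write(f">{hid} subclass={label} flank_before={seg.flank_before} "
                     f"flank_after={seg.flank_after}\n{seg.sequence}\n")
            tsv.write(f"{hid}\t{label}\t{seg.length}\t{seg.flank_before}\t"
                      f"{seg.flank_after}\n")


# ---------------------------------------------------------------------------
# Window-level dataset for mixture modeling


#: Mixture-study proportions: the five subclasses at their reported mixing
#: weights plus a sixth, geometrically distinct filler group (left-handed
#: mirrored helices) absorbing the remaining mass.
DEFAULT_WINDOW_PROPORTIONS: dict[str, float] = {
    "regular": 0.76, "extended": 0.05, "c-cap": 0.05,
    "kinked": 0.02, "curved": 0.01, "mirror": 0.11,
}


def generate_window_dataset(
    n: int,
    proportions: Mapping[str, float] | None = None,
    seed: int = 0,
    specs: Mapping[str, SubclassGeometrySpec] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate n labeled octapeptide windows and their invariant matrix.

    Each window is a length-8 helix of its subclass geometry (deformation at
    a fixed in-window position, so each subclass forms one conformational
    cluster).  The ``mirror`` label produces left-handed (reflected) regular
    windows.  Returns (X, labels) with X of shape (n, 29).
    """
    proportions = dict(proportions or DEFAULT_WINDOW_PROPORTIONS)
    specs = dict(specs or DEFAULT_GEOMETRY_SPECS)
    rng = np.random.default_rng(seed)
    names = sorted(proportions)
    p = np.array([proportions[s] for s in names], float)
    p = p / p.sum()
    counts = rng.multinomial(n, p)
    X = np.empty((n, 29))
    labels = np.empty(n, dtype=object)
    row = 0
    for name, count in zip(names, counts):
        spec = specs["regular"] if name == "mirror" else specs[name]
        for _ in range(count):
            gseed = int(rng.integers(0, 2**31 - 1))
            trace = generate_geometry(spec, 8, seed=gseed)
            coords = trace.coords
            if name == "mirror":
                coords = coords * np.array([-1.0, 1.0, 1.0])
            window = extract_octapeptides(
                CAlphaTrace(coords, trace.sequence, trace.source_id))[0]
            X[row] = compute_invariants(window).values
            labels[row] = name
            row += 1
    perm = rng.permutation(n)
    return X[perm], labels[perm]
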