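"""Ground-truth test structures and fluorophore labelling.

Structures are described in sample space, in nanometres, with a right-handed
coordinate system whose ``z = 0`` plane is the focal plane (+z toward the
objective).  Three pattern families are provided:

* axon segments — stacks of equidistant rings mimicking the periodic actin
  scaffold of axon initial segments (190 nm pitch, 300 nm radius by default);
* line patterns — arbitrary polylines labelled along their arc length;
* vesicles — spheres labelled uniformly over their surface.

Epitopes carry a local orthonormal triad (radial, tangential, axial) so that
rigid dye labels can be given geometrically meaningful dipole orientations
(radial or azimuthal with respect to the structure).

Labelling densities are interpreted as Poisson process rates: the number of
epitopes on a ring (or line, or sphere) is Poisson with mean density x
circumference (arc length, surface area), and positions are uniform.  This
reproduces the configured density in expectation while retaining the
stochasticity of a real immunolabelling reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AxonSegmentSpec",
    "LinePatternSpec",
    "VesicleSpec",
    "LabelingSpec",
    "EpitopeSet",
    "LabeledSet",
    "generate_axon_pattern",
    "generate_line_pattern",
    "generate_vesicle_pattern",
    "place_labels",
]

_UNIT_TOL = 1e-9


def _as_unit(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if abs(n - 1.0) > 1e-9:
        raise ValueError(f"{name} must be a unit vector (norm {n!r})")
    return v


@dataclass(frozen=True)
class AxonSegmentSpec:
    """A stack of equidistant rings along a common axis.

    ``axis_direction`` encodes the full pose of the segment: a segment lying
    in the focal plane has an in-plane axis; tilting the segment by 10 deg
    means rotating the axis 10 deg out of that plane.
    """

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    n_rings: int = 5
    ring_spacing: float = 190.0
    ring_radius: float = 300.0

    def __post_init__(self):
        _as_unit(self.axis_direction, "axis_direction")
        if self.ring_spacing <= 0:
            raise ValueError("ring_spacing must be > 0")
        if self.ring_radius <= 0:
            raise ValueError("ring_radius must be > 0")
        if self.n_rings < 1:
            raise ValueError("n_rings must be >= 1")


@dataclass(frozen=True)
class LinePatternSpec:
    """Polyline structures (vertex chains in nm, 2D or 3D)."""

    polylines: tuple = ()
    z_offset: float = 0.0

    def __post_init__(self):
        if len(self.polylines) == 0:
            raise ValueError("polylines must be non-empty")
        for pl in self.polylines:
            arr = np.asarray(pl, dtype=float)
            if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] not in (2, 3):
                raise ValueError("each polyline needs >= 2 vertices of dim 2 or 3")
            seg = np.diff(arr, axis=0)
            if np.any(np.linalg.norm(seg, axis=1) == 0):
                raise ValueError("consecutive polyline vertices must be distinct")

    def vertices3d(self) -> list[np.ndarray]:
        out = []
        for pl in self.polylines:
            arr = np.asarray(pl, dtype=float)
            if arr.shape[1] == 2:
                arr = np.column_stack([arr, np.full(len(arr), self.z_offset)])
            else:
                arr = arr.copy()
                arr[:, 2] += self.z_offset
            out.append(arr)
        return out


@dataclass(frozen=True)
class VesicleSpec:
    """Spherical vesicles labelled over their surface."""

    centers: tuple = ((0.0, 0.0, 0.0),)
    radius: float = 200.0
    surface_density: float = 100.0  # labels / um^2

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.surface_density < 0:
            raise ValueError("surface_density must be >= 0")


@dataclass(frozen=True)
class LabelingSpec:
    """How dyes attach to epitopes.

    linker_mode ``rigid`` draws one displacement direction per fluorophore
    and keeps it; ``flexible`` exposes a per-event re-orientation contract
    consumed by the photophysics layer.  dipole_mode decides the emission /
    absorption dipole: free rotation, or fixed along the epitope's radial or
    azimuthal triad vector, or a fixed custom unit vector.
    """

    linker_length: float = 0.0
    linker_mode: str = "rigid"  # rigid | flexible
    density: float = 50.0
    dipole_mode: str = "free_rotating"
    custom_dipole: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.linker_length < 0:
            raise ValueError("linker_length must be >= 0")
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if self.linker_mode not in ("rigid", "flexible"):
            raise ValueError(f"unknown linker_mode {self.linker_mode!r}")
        modes = ("free_rotating", "fixed_radial", "fixed_azimuthal", "fixed_custom")
        if self.dipole_mode not in modes:
            raise ValueError(f"unknown dipole_mode {self.dipole_mode!r}")
        if self.dipole_mode == "fixed_custom":
            if self.custom_dipole is None:
                raise ValueError("fixed_custom requires custom_dipole")
            _as_unit(self.custom_dipole, "custom_dipole")


@dataclass
class EpitopeSet:
    """Epitope positions with local orientation frames.

    ``triads[i]`` is a 3x3 matrix whose rows are the (radial, tangential,
    axial) unit vectors at epitope ``i``; all rows orthonormal.
    """

    positions: np.ndarray  # (N, 3) nm
    triads: np.ndarray  # (N, 3, 3)
    structure_id: np.ndarray  # (N,) int

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.triads = np.asarray(self.triads, dtype=float).reshape(-1, 3, 3)
        self.structure_id = np.asarray(self.structure_id, dtype=int).reshape(-1)
        n = len(self.positions)
        if len(self.triads) != n or len(self.structure_id) != n:
            raise ValueError("field lengths disagree")
        if n:
            gram = np.einsum("nij,nkj->nik", self.triads, self.triads)
            if not np.allclose(gram, np.eye(3), atol=1e-9):
                raise ValueError("triads must be orthonormal")

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def empty(cls) -> "EpitopeSet":
        return cls(np.empty((0, 3)), np.empty((0, 3, 3)), np.empty(0, dtype=int))

    @classmethod
    def concatenate(cls, sets: list["EpitopeSet"]) -> "EpitopeSet":
        sets = [s for s in sets if len(s)]
        if not sets:
            return cls.empty()
        return cls(
            np.concatenate([s.positions for s in sets]),
            np.concatenate([s.triads for s in sets]),
            np.concatenate([s.structure_id for s in sets]),
        )


@dataclass
class LabeledSet:
    """Fluorophore positions and dipole orientations after linker attachment."""

    positions: np.ndarray  # (N, 3) nm, post-linker (rigid) or epitope (flexible)
    dipoles: np.ndarray  # (N, 3) unit vectors; meaningful for fixed modes
    epitope_positions: np.ndarray  # (N, 3) nm
    structure_id: np.ndarray
    spec: LabelingSpec = field(default_factory=LabelingSpec)

    def __len__(self) -> int:
        return len(self.positions)


def _orthonormal_complement(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane perpendicular to ``axis``."""
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(helper, axis)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(helper, axis)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def generate_axon_pattern(
    segments,
    density: float,
    rng_seed,
) -> EpitopeSet:
    """Place epitopes uniformly on the ring circles of axon segments.

    ``density`` is in labels/um of ring circumference; per-ring counts are
    Poisson(density x 2 pi R).  Rings are centred symmetrically about the
    segment center along its axis.  The local triad is (outward radial,
    azimuthal tangent, segment axis).
    """
    if isinstance(segments, AxonSegmentSpec):
        segments = [segments]
    if len(segments) == 0:
        raise ValueError("segments must be non-empty")
    if density < 0:
        raise ValueError("density must be >= 0")
    rng = np.random.default_rng(rng_seed)
    parts = []
    for sid, seg in enumerate(segments):
        axis = _as_unit(seg.axis_direction, "axis_direction")
        center = np.asarray(seg.center, dtype=float)
        e1, e2 = _orthonormal_complement(axis)
        offsets = (np.arange(seg.n_rings) - (seg.n_rings - 1) / 2.0) * seg.ring_spacing
        mean = density * 2.0 * np.pi * seg.ring_radius / 1000.0  # density per um
        for off in offsets:
            n = rng.poisson(mean)
            if n == 0:
                continue
            ang = rng.uniform(0.0, 2.0 * np.pi, size=n)
            radial = np.outer(np.cos(ang), e1) + np.outer(np.sin(ang), e2)
            tangential = np.outer(-np.sin(ang), e1) + np.outer(np.cos(ang), e2)
            pos = center + off * axis + seg.ring_radius * radial
            triads = np.stack(
                [radial, tangential, np.broadcast_to(axis, radial.shape)], axis=1
            )
            parts.append(
                EpitopeSet(pos, triads, np.full(n, sid, dtype=int))
            )
    return EpitopeSet.concatenate(parts)


def generate_line_pattern(
    spec: LinePatternSpec,
    density: float,
    rng_seed,
) -> EpitopeSet:
    """Place epitopes along polylines as a Poisson process of rate ``density``.

    ``density`` is in labels/um of arc length.  The triad at an epitope is
    (in-plane normal, tangent, binormal ~ z).
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    rng = np.random.default_rng(rng_seed)
    parts = []
    zhat = np.array([0.0, 0.0, 1.0])
    for sid, verts in enumerate(spec.vertices3d()):
        seg_vec = np.diff(verts, axis=0)
        seg_len = np.linalg.norm(seg_vec, axis=1)
        total = seg_len.sum()
        n = rng.poisson(density * total / 1000.0)
        if n == 0:
            continue
        s = np.sort(rng.uniform(0.0, total, size=n))
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg_len) - 1)
        frac = (s - cum[idx]) / seg_len[idx]
        pos = verts[idx] + frac[:, None] * seg_vec[idx]
        tangent = seg_vec[idx] / seg_len[idx][:, None]
        normal = np.cross(tangent, zhat)
        nn = np.linalg.norm(normal, axis=1, keepdims=True)
        # vertical segments: fall back to x as the normal direction
        bad = nn[:, 0] < 1e-12
        if bad.any():
            normal[bad] = np.cross(tangent[bad], [0.0, 1.0, 0.0])
            nn = np.linalg.norm(normal, axis=1, keepdims=True)
        normal /= nn
        binormal = np.cross(normal, tangent)
        triads = np.stack([normal, tangent, binormal], axis=1)
        parts.append(EpitopeSet(pos, triads, np.full(n, sid, dtype=int)))
    return EpitopeSet.concatenate(parts)


def generate_vesicle_pattern(spec: VesicleSpec, rng_seed) -> EpitopeSet:
    """Place epitopes uniformly on sphere surfaces.

    Expected count per vesicle is surface_density x 4 pi R^2; the triad is
    (outward normal, tangent, second tangent).
    """
    rng = np.random.default_rng(rng_seed)
    area_um2 = 4.0 * np.pi * (spec.radius / 1000.0) ** 2
    mean = spec.surface_density * area_um2
    parts = []
    for sid, c in enumerate(spec.centers):
        c = np.asarray(c, dtype=float)
        n = rng.poisson(mean)
        if n == 0:
            continue
        v = rng.standard_normal((n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pos = c + spec.radius * v
        # tangent frame via Gram-Schmidt against a helper axis
        helper = np.where(
            np.abs(v[:, 2:3]) < 0.9,
            np.array([0.0, 0.0, 1.0]),
            np.array([0.0, 1.0, 0.0]),
        )
        t1 = np.cross(helper, v)
        t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
        t2 = np.cross(v, t1)
        triads = np.stack([v, t1, t2], axis=1)
        parts.append(EpitopeSet(pos, triads, np.full(n, sid, dtype=int)))
    return EpitopeSet.concatenate(parts)


def _uniform_sphere(rng, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def place_labels(epitopes: EpitopeSet, spec: LabelingSpec, rng_seed) -> LabeledSet:
    """Attach fluorophores to epitopes through the linker model.

    Rigid linkers displace the dye by exactly ``linker_length`` along one
    direction drawn uniformly on the sphere once per fluorophore.  Flexible
    linkers keep the stored position at the epitope; the per-event
    re-orientation is applied by the photophysics layer using the same spec.
    Dipoles follow ``dipole_mode`` using the epitope's local triad.
    """
    rng = np.random.default_rng(rng_seed)
    n = len(epitopes)
    epos = epitopes.positions
    if spec.linker_mode == "rigid" and spec.linker_length > 0 and n:
        disp = _uniform_sphere(rng, n) * spec.linker_length
        pos = epos + disp
    else:
        pos = epos.copy()

    if n == 0:
        dip = np.empty((0, 3))
    elif spec.dipole_mode == "fixed_radial":
        dip = epitopes.triads[:, 0, :].copy()
    elif spec.dipole_mode == "fixed_azimuthal":
        dip = epitopes.triads[:, 1, :].copy()
    elif spec.dipole_mode == "fixed_custom":
        dip = np.broadcast_to(np.asarray(spec.custom_dipole, float), (n, 3)).copy()
    else:  # free_rotating: direction is not fixed; store placeholders
        dip = _uniform_sphere(rng, n)

    return LabeledSet(
        positions=pos,
        dipoles=dip,
        epitope_positions=epos.copy(),
        structure_id=epitopes.structure_id.copy(),
        spec=spec,
    )
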