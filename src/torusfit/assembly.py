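"""Ring-oligomer assembly and disordered-tail ensembles.

A ring-forming dimer is propagated into a closed torus or an open partial
ring by repeated application of a single inter-dimer rigid transform, the
arrangement seen in crystals of ring-forming ribbon-helix-helix antitoxins
(eight dimers close a torus; arcs of 4-7 dimers model the solution species).
Disordered C-terminal tails are grown on each chain as self-avoiding
Calpha-trace random walks with fixed virtual bonds, giving a coil ensemble
over which scattering can be averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    DegenerateGeometryError,
    GrowthFailureError,
    InvalidArgumentError,
    ShapeMismatchError,
)

__all__ = [
    "BeadChain",
    "BeadModel",
    "RigidTransform",
    "OligomerModel",
    "TailSpec",
    "TailEnsemble",
    "kabsch_superpose",
    "infer_adjacent_transform",
    "build_partial_ring",
    "ring_layout",
    "ring_metrics",
    "estimate_ring_axis",
    "grow_tails",
]

MAX_DIMERS = 8  # a closed torus: eight dimers, sixteen chains


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class BeadChain:
    """One chain of a coarse-grained model: one bead per residue."""

    chain_id: str
    residue_index: np.ndarray
    coords: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InvalidArgumentError("coords must be (n, 3)")
        if self.residue_index.shape[0] != self.coords.shape[0]:
            raise InvalidArgumentError("one coordinate per residue index required")
        if self.residue_index.size > 1 and np.any(np.diff(self.residue_index) <= 0):
            raise InvalidArgumentError("residue indices must be strictly increasing")
        if self.weights is None:
            self.weights = np.ones(self.coords.shape[0])
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape[0] != self.coords.shape[0]:
                raise InvalidArgumentError("one weight per bead required")

    def __len__(self) -> int:
        return self.coords.shape[0]


@dataclass
class BeadModel:
    """An ordered collection of bead chains (e.g. the two chains of a dimer)."""

    chains: list[BeadChain]

    @property
    def coords(self) -> np.ndarray:
        return np.concatenate([c.coords for c in self.chains], axis=0)

    @property
    def weights(self) -> np.ndarray:
        return np.concatenate([c.weights for c in self.chains], axis=0)

    @property
    def n_beads(self) -> int:
        return sum(len(c) for c in self.chains)

    def transformed(self, t: "RigidTransform", chain_suffix: str = "") -> "BeadModel":
        return BeadModel([
            replace(c, chain_id=c.chain_id + chain_suffix, coords=t.apply(c.coords),
                    weights=c.weights.copy())
            for c in self.chains
        ])


@dataclass
class RigidTransform:
    """A proper rotation plus translation, ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise InvalidArgumentError("rotation must be 3x3, translation length 3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise InvalidArgumentError("rotation must be orthogonal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise InvalidArgumentError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def about_axis(cls, axis, angle_rad: float,
                   point=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Rotation by ``angle_rad`` about a line through ``point`` along ``axis``."""
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        point = np.asarray(point, dtype=float)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)
        return cls(R, point - R @ point)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def power(self, n: int) -> "RigidTransform":
        t = RigidTransform.identity()
        for _ in range(n):
            t = self.compose(t)
        return t

    @property
    def angle_deg(self) -> float:
        """Rotation angle in degrees, from the trace of the rotation."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class OligomerModel:
    """``k`` congruent dimers placed around (part of) a ring.

    ``ring_axis`` is stored as ``(point, unit direction)``; for models built
    by :func:`build_partial_ring` it is exact, otherwise it can be estimated
    with :func:`estimate_ring_axis`.
    """

    dimers: list[BeadModel]
    k: int
    closed: bool
    ring_axis: tuple[np.ndarray, np.ndarray] | None = None
    transform: RigidTransform | None = None

    @property
    def chains(self) -> list[BeadChain]:
        return [c for d in self.dimers for c in d.chains]

    @property
    def n_chains(self) -> int:
        return 2 * self.k

    @property
    def coords(self) -> np.ndarray:
        return np.concatenate([d.coords for d in self.dimers], axis=0)

    @property
    def weights(self) -> np.ndarray:
        return np.concatenate([d.weights for d in self.dimers], axis=0)


@dataclass
class TailSpec:
    """Geometry of the self-avoiding Calpha-trace tail walk.

    ``bond_length`` is the fixed virtual Calpha-Calpha bond (3.8 A);
    ``angle_limits`` bounds the virtual bond angle between consecutive
    bonds (degrees); ``clash_cutoff`` is the minimum allowed distance
    between non-bonded bead centres; ``max_attempts`` caps whole-chain
    restarts before growth is declared failed.
    """

    tail_length: int = 30
    bond_length: float = 3.8
    clash_cutoff: float = 4.0
    max_attempts: int = 500
    angle_limits: tuple[float, float] = (70.0, 150.0)
    step_attempts: int = 30

    def __post_init__(self):
        if self.tail_length < 0:
            raise InvalidArgumentError("tail_length must be >= 0")
        if self.bond_length <= 0:
            raise InvalidArgumentError("bond_length must be positive")
        if self.clash_cutoff < 0:
            raise InvalidArgumentError("clash_cutoff must be >= 0")


@dataclass
class TailEnsemble:
    """Conformer ensemble sharing a fixed core.

    ``core_coords``/``core_weights`` are identical in every conformer;
    ``conformers`` holds full coordinate sets (core beads first, then tail
    beads chain by chain in ``tail_slices`` order).
    """

    base_model: OligomerModel
    spec: TailSpec
    seed: int
    core_coords: np.ndarray
    core_weights: np.ndarray
    conformers: list[np.ndarray]
    weights: np.ndarray          # per-bead weights of a full conformer
    tail_slices: dict[str, slice] = field(default_factory=dict)

    @property
    def n_conformers(self) -> int:
        return len(self.conformers)


# --------------------------------------------------------------------------
# superposition
# --------------------------------------------------------------------------

def kabsch_superpose(A: np.ndarray, B: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares proper rigid superposition of ``A`` onto ``B``.

    Returns the transform ``x -> R x + t`` minimizing ``|R A + t - B|`` and
    the post-superposition RMSD.  Reflections are disallowed: the returned
    rotation always has determinant +1 (mirror-image inputs therefore keep
    a non-zero RMSD).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ShapeMismatchError("point sets must both be (n, 3) with equal n")
    if A.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 points")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12 * max(S[0], 1.0):
        raise DegenerateGeometryError("point set is rank-deficient (collinear)")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(A) - B) ** 2, axis=1))))
    return transform, rmsd


# --------------------------------------------------------------------------
# rings
# --------------------------------------------------------------------------

def infer_adjacent_transform(ring: OligomerModel) -> RigidTransform:
    """Recover the generating inter-dimer transform of a ring.

    Superposes dimer 0 onto dimer 1; all adjacent pairs of a ring built
    from a single transform are related by the same transform.
    """
    if ring.k < 2:
        raise InvalidArgumentError("need at least two dimers")
    a, b = ring.dimers[0].coords, ring.dimers[1].coords
    if a.shape != b.shape:
        raise ShapeMismatchError("dimers must have identical bead counts")
    transform, rmsd = kabsch_superpose(a, b)
    if rmsd > 1e-3:
        raise ShapeMismatchError(
            f"dimers are not congruent (superposition RMSD {rmsd:.3g} A)"
        )
    return transform


def build_partial_ring(dimer: BeadModel, transform: RigidTransform,
                       k: int) -> OligomerModel:
    """Place ``k`` copies of ``dimer``: copy ``j`` is ``transform^j(dimer)``.

    ``k = MAX_DIMERS`` with the torus-closing transform yields the closed
    ring (``closed`` is set when ``transform^k`` is the identity on the
    first dimer to within 1e-3 A).
    """
    if not 1 <= k <= MAX_DIMERS:
        raise InvalidArgumentError(f"k must be in [1, {MAX_DIMERS}]")
    dimers = []
    current = dimer
    for j in range(k):
        dimers.append(current.transformed(
            RigidTransform.identity(), chain_suffix="" if j == 0 else str(j)))
        current = current.transformed(transform)
    closure = transform.power(k)
    ref = dimer.coords
    gap = float(np.sqrt(np.mean(np.sum((closure.apply(ref) - ref) ** 2, axis=1))))
    closed = gap < 1e-3
    axis = None
    if k >= 3:
        axis = estimate_ring_axis_from_transform(transform)
    return OligomerModel(dimers=dimers, k=k, closed=closed, ring_axis=axis,
                         transform=transform)


def estimate_ring_axis_from_transform(
        t: RigidTransform) -> tuple[np.ndarray, np.ndarray]:
    """Axis (point, direction) of a screw-free rotational transform."""
    w, v = np.linalg.eig(t.rotation)
    direction = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    direction = direction / np.linalg.norm(direction)
    # fixed point: (I - R) p = t  restricted to the plane normal to the axis
    A = np.eye(3) - t.rotation
    point, *_ = np.linalg.lstsq(A, t.translation, rcond=None)
    # remove any component along the axis (pure rotation assumed)
    point = point - direction * np.dot(point, direction)
    return point, direction


def estimate_ring_axis(model: OligomerModel) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares ring axis from dimer centroids.

    The axis direction is the normal of the least-squares plane through the
    dimer centroids and the axis point is the centroid of centroids; exact
    for ideal closed rings.
    """
    if model.k < 3:
        raise DegenerateGeometryError("ring axis needs at least 3 dimers")
    centroids = np.array([d.coords.mean(axis=0) for d in model.dimers])
    centre = centroids.mean(axis=0)
    _, _, Vt = np.linalg.svd(centroids - centre)
    return centre, Vt[2] / np.linalg.norm(Vt[2])


def ring_metrics(model: OligomerModel, bead_radius: float = 1.9) -> dict:
    """Inner-hole and outer diameters of a ring model.

    ``hole_diameter = 2 * max(min_axial_distance - bead_radius, 0)`` and the
    outer diameter analogously with the maximum axial distance plus the
    bead radius.
    """
    if model.k < 3:
        raise DegenerateGeometryError("ring metrics need at least 3 dimers")
    point, direction = model.ring_axis if model.ring_axis is not None \
        else estimate_ring_axis(model)
    rel = model.coords - point
    radial = rel - np.outer(rel @ direction, direction)
    dist = np.linalg.norm(radial, axis=1)
    hole = max(2.0 * (float(dist.min()) - bead_radius), 0.0)
    outer = 2.0 * (float(dist.max()) + bead_radius)
    return {"hole_diameter": hole, "outer_diameter": outer}


def ring_layout(dimer: BeadModel, k: int, k_closed: int = MAX_DIMERS,
                clearance: float = 4.0) -> OligomerModel:
    """Place a centred dimer on the smallest ring with a clash-free seam.

    The dimer is translated radially (along +x) to radius ``R`` and the
    generating transform is a rotation by ``360/k_closed`` degrees about the
    global z axis.  ``R`` is the smallest radius (to 0.01 A, found by
    bisection) at which adjacent dimers keep all inter-dimer bead distances
    at or above ``clearance`` -- adjacent dimers then touch, mimicking a
    packed torus seam.  Deterministic for a given dimer.
    """
    if not 1 <= k <= k_closed:
        raise InvalidArgumentError(f"k must be in [1, {k_closed}]")
    step = RigidTransform.about_axis((0, 0, 1), 2.0 * np.pi / k_closed)
    base = dimer.coords

    def min_gap(R: float) -> float:
        shifted = base + np.array([R, 0.0, 0.0])
        rotated = step.apply(shifted)
        return float(cKDTree(shifted).query(rotated)[0].min())

    lo, hi = 0.0, 10.0
    while min_gap(hi) < clearance:
        lo, hi = hi, hi * 2.0
        if hi > 1e5:
            raise DegenerateGeometryError("could not find a clash-free ring radius")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_gap(mid) >= clearance:
            hi = mid
        else:
            lo = mid
        if hi - lo < 0.01:
            break
    R = hi
    placed = dimer.transformed(
        RigidTransform(np.eye(3), np.array([R, 0.0, 0.0])))
    return build_partial_ring(placed, step, k)


# --------------------------------------------------------------------------
# tails
# --------------------------------------------------------------------------

def _rotation_to_z(v: np.ndarray) -> np.ndarray:
    """Proper rotation taking the unit vector ``v`` to ``+z``."""
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(v, z))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def _grow_chain(
    rng: np.random.Generator,
    anchor: np.ndarray,
    prev: np.ndarray | None,
    n_beads: int,
    spec: TailSpec,
    obstacle_tree: cKDTree | None,
    extra_obstacles: list[np.ndarray],
    anchor_index: int | None = None,
    inside=None,
) -> np.ndarray | None:
    """Grow one self-avoiding chain; returns ``(n_beads, 3)`` or ``None``.

    Each new bead sits at ``bond_length`` from its predecessor with the
    virtual bond angle drawn uniformly from ``angle_limits`` (dihedral
    uniform on the circle), and is rejected if any non-bonded bead of the
    static obstacles, of ``extra_obstacles`` or of the chain itself lies
    closer than ``clash_cutoff`` (or if ``inside`` vetoes the position).
    The first grown bead is covalently bonded to the anchor, so the anchor
    bead (``anchor_index`` in the obstacle tree) is exempt from its clash
    check.
    """
    lo, hi = np.radians(spec.angle_limits)
    cutoff = spec.clash_cutoff
    grown = np.empty((n_beads, 3))
    extra = np.concatenate(extra_obstacles, axis=0) if extra_obstacles else None
    last = anchor
    direction = None
    if prev is not None:
        direction = anchor - prev
        direction = direction / np.linalg.norm(direction)
    for i in range(n_beads):
        placed = False
        for _ in range(spec.step_attempts):
            if direction is None:
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                cand = last + spec.bond_length * u
            else:
                # bond angle theta between previous and new bond
                theta = rng.uniform(lo, hi)
                phi = rng.uniform(0.0, 2.0 * np.pi)
                # new bond makes angle (pi - theta) with previous direction
                beta = np.pi - theta
                local = np.array([
                    np.sin(beta) * np.cos(phi),
                    np.sin(beta) * np.sin(phi),
                    np.cos(beta),
                ])
                cand = last + spec.bond_length * (_rotation_to_z(direction).T @ local)
            if inside is not None and not inside(cand):
                continue
            if obstacle_tree is not None:
                if i == 0 and anchor_index is not None:
                    # nearest obstacle may be the bonded anchor: take two
                    d, j = obstacle_tree.query(cand, k=2)
                    dmin = d[1] if j[0] == anchor_index else d[0]
                else:
                    dmin = obstacle_tree.query(
                        cand, distance_upper_bound=cutoff)[0]
                if dmin < cutoff:
                    continue
            if extra is not None and extra.size:
                if np.min(np.einsum("ij,ij->i", extra - cand, extra - cand)) \
                        < cutoff**2:
                    continue
            # self-clash: own beads except the directly bonded predecessor
            if i >= 2:
                prior = grown[:i - 1]
                d2 = np.einsum("ij,ij->i", prior - cand, prior - cand)
                if d2.min() < cutoff**2:
                    continue
            placed = True
            break
        if not placed:
            return None
        grown[i] = cand
        direction = (cand - last)
        direction = direction / np.linalg.norm(direction)
        last = cand
    return grown


def grow_tails(
    model: OligomerModel,
    spec: TailSpec,
    n_conformers: int,
    seed: int,
    terminal: str = "C",
) -> TailEnsemble:
    """Attach self-avoiding tail conformers to every chain of a model.

    Tails are anchored at each chain's last (C-terminal, default) or first
    core bead; the structured core is kept fixed and is identical across
    conformers.  Each conformer uses an independent random substream derived
    from ``(seed, conformer index)``, and a chain that dead-ends is
    restarted with fresh randomness up to ``spec.max_attempts`` times before
    :class:`GrowthFailureError` is raised.
    """
    if n_conformers < 1:
        raise InvalidArgumentError("n_conformers must be >= 1")
    if terminal not in ("C", "N"):
        raise InvalidArgumentError("terminal must be 'C' or 'N'")
    chains = model.chains
    core_coords = model.coords
    core_weights = model.weights
    n_core = core_coords.shape[0]
    L = spec.tail_length

    tail_slices = {}
    offset = n_core
    for c in chains:
        tail_slices[c.chain_id] = slice(offset, offset + L)
        offset += L
    full_weights = np.concatenate([core_weights, np.ones(len(chains) * L)])

    if L == 0:
        conformers = [core_coords.copy() for _ in range(n_conformers)]
        return TailEnsemble(base_model=model, spec=spec, seed=seed,
                            core_coords=core_coords, core_weights=core_weights,
                            conformers=conformers, weights=core_weights.copy(),
                            tail_slices={c.chain_id: slice(n_core, n_core)
                                         for c in chains})

    from . import _kernels

    chain_offsets = np.cumsum([0] + [len(c) for c in chains])
    anchors, prevs, anchor_idx = [], [], []
    for ichain, c in enumerate(chains):
        if len(c) < 2:
            raise InvalidArgumentError(
                f"chain {c.chain_id!r} needs >= 2 core beads to anchor a tail"
            )
        if terminal == "C":
            anchors.append(c.coords[-1])
            prevs.append(c.coords[-2])
            anchor_idx.append(int(chain_offsets[ichain + 1] - 1))
        else:
            anchors.append(c.coords[0])
            prevs.append(c.coords[1])
            anchor_idx.append(int(chain_offsets[ichain]))
    anchors = np.ascontiguousarray(anchors, dtype=float)
    prevs = np.ascontiguousarray(prevs, dtype=float)
    anchor_idx = np.asarray(anchor_idx, dtype=np.int64)
    core_contig = np.ascontiguousarray(core_coords)
    lo, hi = np.radians(spec.angle_limits)

    # a chain may dead-end because of tails grown before it, so failures
    # restart the whole conformer from a fresh substream; per-chain restart
    # budgets across all attempts stay within spec.max_attempts
    chain_restarts = 25
    conformer_attempts = max(1, spec.max_attempts // chain_restarts)
    conformers = []
    for ic in range(n_conformers):
        tails = None
        last_failed = -1
        for attempt in range(conformer_attempts):
            rng = np.random.default_rng([seed, ic, attempt])
            grown, failed = _kernels.grow_conformer(
                rng, core_contig, anchors, prevs, anchor_idx, L,
                spec.bond_length, spec.clash_cutoff, lo, hi,
                spec.step_attempts, chain_restarts,
            )
            if failed < 0:
                tails = grown
                break
            last_failed = failed
        if tails is None:
            raise GrowthFailureError(chains[last_failed].chain_id, ic,
                                     spec.max_attempts)
        conformers.append(np.concatenate([core_coords, tails], axis=0))
    return TailEnsemble(base_model=model, spec=spec, seed=seed,
                        core_coords=core_coords, core_weights=core_weights,
                        conformers=conformers, weights=full_weights,
                        tail_slices=tail_slices)


def grow_isolated_tail(spec: TailSpec, seed: int,
                       n_conformers: int = 1) -> list[np.ndarray]:
    """Self-avoiding walks from the origin with no core obstacles.

    Useful for studying the bare coil statistics of the tail model (e.g.
    the super-linear growth of the mean squared end-to-end distance that
    signals self-avoidance).
    """
    out = []
    for ic in range(n_conformers):
        rng = np.random.default_rng([seed, ic])
        tail = None
        for _ in range(spec.max_attempts):
            tail = _grow_chain(rng, np.zeros(3), None, spec.tail_length, spec,
                               None, [])
            if tail is not None:
                break
        if tail is None:
            raise GrowthFailureError("isolated", ic, spec.max_attempts)
        out.append(tail)
    return out
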