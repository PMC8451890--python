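"""Parametric airway-tree phantoms with analytic ground truth.

Builds recursive bifurcating trees at mouse-like dimensions (tracheal
diameter ~1.2 mm, per-generation scale ratio 0.75, length/diameter ~2),
rasterises them into binary voxel volumes, and optionally injects the
artifact classes real cast scans exhibit: thin touching-branch bridges,
annular-ligament-like spur nubs, closed loops, and trifurcations.

Conventions
-----------
* The trachea runs along +y from the origin; the lung extends toward -z,
  so the anatomical gravity vector constructed from the trachea and main
  bronchi points in -z and is non-trivial.
* Branches are capsules (cylinders with hemispherical caps) so the junction
  fill is smooth, except that exposed ends — terminal tips and the proximal
  tracheal stub — are cut flat at the true endpoint.  Ground-truth length is
  then exactly the node-to-node distance that the measurement stage defines.
* One seeded generator with per-branch substreams keyed by the branch label,
  so pruning one subtree never perturbs its siblings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .volume import BinaryMask

__all__ = [
    "TreeSpec",
    "BranchGeom",
    "AirwayTree",
    "ArtifactSpec",
    "build_tree",
    "rasterize_tree",
    "inject_artifacts",
]

ARTIFACT_KINDS = frozenset(
    {"touching_branches", "spur_nub", "closed_loop", "trifurcation"}
)


@dataclass(frozen=True)
class TreeSpec:
    """Parameters of a synthetic bifurcating airway tree.

    ``length_scale`` and ``diameter_scale`` are the generation-1 (trachea)
    values in mm; both decay geometrically by ``scale_ratio`` per
    generation.  ``daughter_asymmetry`` is the minor/major daughter diameter
    ratio in (0, 1]. ``curvature`` bows each branch as a circular arc with
    maximum sagitta ``curvature * length``.  ``prune_prob`` is the
    per-daughter probability that an entire subtree is absent.
    """

    generations: int = 6
    length_scale: float = 3.0
    diameter_scale: float = 1.2
    scale_ratio: float = 0.75
    branch_angle_mean: float = 33.0
    branch_angle_sd: float = 0.0
    daughter_asymmetry: float = 0.8
    curvature: float = 0.0
    prune_prob: float = 0.0
    seed: int = 0
    #: minimum surface clearance (mm) enforced between non-adjacent branches;
    #: candidate bifurcation planes are re-drawn until it holds, so phantoms
    #: do not self-touch unless artifacts are injected deliberately.
    min_clearance: float = 0.15

    def validate(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.length_scale <= 0 or self.diameter_scale <= 0 or self.scale_ratio <= 0:
            raise ValueError("scales must be positive")
        if not (0.0 < self.daughter_asymmetry <= 1.0):
            raise ValueError("daughter_asymmetry must be in (0, 1]")
        if not (0.0 <= self.prune_prob < 1.0):
            raise ValueError("prune_prob must be in [0, 1)")


@dataclass
class BranchGeom:
    """One branch: straight (or arc-bowed) segment with a diameter."""

    label: str
    start: np.ndarray  # mm
    end: np.ndarray    # mm
    diameter: float    # mm
    points: np.ndarray  # (N, 3) centerline polyline, mm
    parent: str | None

    @property
    def vector(self) -> np.ndarray:
        return self.end - self.start

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.vector))


@dataclass
class AirwayTree:
    """Resolved tree geometry plus its analytic ground-truth table."""

    spec: TreeSpec
    branches: dict[str, BranchGeom]
    ground_truth: pd.DataFrame = field(repr=False)

    def __getitem__(self, label: str) -> BranchGeom:
        return self.branches[label]


@dataclass(frozen=True)
class ArtifactSpec:
    """One injected defect.

    ``location`` is a branch label (``spur_nub``, ``trifurcation``) or a
    ``"labelA:labelB"`` pair (``touching_branches``, ``closed_loop``);
    ``magnitude`` is the feature size in micrometres (bridge/spur diameter,
    spur length).
    """

    kind: str
    location: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}")


def _branch_rng(seed: int, label: str) -> np.random.Generator:
    # substream keyed by the label digits: stable under pruning of siblings
    return np.random.default_rng([int(seed)] + [int(c) for c in label])


def _rotate_toward(d: np.ndarray, u: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate unit vector ``d`` by ``angle_deg`` toward perpendicular unit ``u``."""
    a = np.deg2rad(angle_deg)
    return np.cos(a) * d + np.sin(a) * u


def _perp_frame(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    n1 = np.cross(d, ref)
    n1 /= np.linalg.norm(n1)
    return n1, np.cross(d, n1)


def _arc_points(start: np.ndarray, end: np.ndarray, bow: np.ndarray, n: int = 17) -> np.ndarray:
    """Polyline from start to end bowed by the sagitta vector ``bow`` at midpoint."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    chord = start[None] * (1 - t) + end[None] * t
    return chord + np.sin(np.pi * t) * bow[None]


def _clearance(branches: dict[str, BranchGeom], parent_label: str,
               start: np.ndarray, end: np.ndarray, diameter: float,
               n: int = 24) -> float:
    """Smallest surface-to-surface distance from a candidate segment to any
    committed non-adjacent branch (adjacent = sharing the start node)."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    cand = start * (1 - t) + end * t
    best = np.inf
    for b in branches.values():
        if np.allclose(b.end, start) or np.allclose(b.start, start):
            continue  # parent or sibling: shares the bifurcation node
        other = b.start * (1 - t) + b.end * t
        d = np.linalg.norm(cand[:, None] - other[None, :], axis=2).min()
        best = min(best, d - (diameter + b.diameter) / 2.0)
    return best


def build_tree(spec: TreeSpec) -> AirwayTree:
    """Realise a :class:`TreeSpec` into geometry plus ground truth.

    The trachea is labelled "1"; each daughter appends "1" (major,
    larger diameter) or "2" (minor).  With ``prune_prob = 0`` the tree is
    complete: generation g holds 2**(g-1) branches.
    """
    spec.validate()
    branches: dict[str, BranchGeom] = {}

    trachea_dir = np.array([0.0, 1.0, 0.0])
    ld_ratio = spec.length_scale / spec.diameter_scale

    def grow(label: str, start: np.ndarray, direction: np.ndarray,
             diameter: float, parent: str | None) -> None:
        rng = _branch_rng(spec.seed, label)
        length = diameter * ld_ratio
        if parent is None:
            # the trachea is proportionally longer than bronchial branches;
            # a short tracheal stub is also numerically fragile under thinning
            length *= 1.5
        end = start + direction * length
        if spec.curvature > 0 and parent is not None:
            n1, n2 = _perp_frame(direction)
            phi = rng.uniform(0, 2 * np.pi)
            bow = (np.cos(phi) * n1 + np.sin(phi) * n2) * spec.curvature * length
            points = _arc_points(start, end, bow)
        else:
            points = np.array([start, end])
        branches[label] = BranchGeom(label, start.copy(), end, diameter, points, parent)
        gen = len(label)
        if gen >= spec.generations:
            return
        # bifurcation plane: perpendicular direction per daughter
        if parent is None:
            # first bifurcation: both bronchi dive toward -z (dorsal), opposite x;
            # the common pitch keeps the gravity construction well away from
            # its degenerate (bronchi parallel to trachea) configuration
            u_major = np.array([np.sin(np.deg2rad(55)), 0.0, -np.cos(np.deg2rad(55))])
            u_minor = np.array([-np.sin(np.deg2rad(55)), 0.0, -np.cos(np.deg2rad(55))])
            u_of_sign = {+1: u_major, -1: u_minor}
        else:
            u_of_sign = None
        d_major = diameter * spec.scale_ratio * 2.0 / (1.0 + spec.daughter_asymmetry)
        d_major = min(d_major, 0.95 * diameter)
        d_minor = d_major * spec.daughter_asymmetry
        for digit, sign, dia, share in (
            ("1", +1, d_major, 0.7),
            ("2", -1, d_minor, 1.0),
        ):
            child = label + digit
            crng = _branch_rng(spec.seed, child)
            if spec.prune_prob > 0 and crng.uniform() < spec.prune_prob:
                continue
            theta = spec.branch_angle_mean * share
            if spec.branch_angle_sd > 0:
                theta += crng.normal(0.0, spec.branch_angle_sd)
            theta = float(np.clip(theta, 5.0, 85.0))
            if u_of_sign is not None:
                grow(child, end, _rotate_toward(direction, u_of_sign[sign], theta),
                     dia, label)
                continue
            # bifurcation-plane azimuth alternates by generation with jitter so
            # subtrees interleave; candidates are re-drawn (deterministically,
            # from the child's substream) until the new branch keeps
            # min_clearance to every non-adjacent committed branch
            n1, n2 = _perp_frame(direction)
            length_child = dia * ld_ratio
            best: tuple[float, np.ndarray] | None = None
            for attempt in range(24):
                jitter = crng.uniform(-20.0, 20.0) if attempt == 0 else crng.uniform(-90.0, 90.0)
                phi = np.deg2rad(90.0 * (gen % 2) + jitter)
                u = sign * (np.cos(phi) * n1 + np.sin(phi) * n2)
                cdir = _rotate_toward(direction, u, theta)
                clear = _clearance(branches, label, end, end + cdir * length_child, dia)
                if best is None or clear > best[0]:
                    best = (clear, cdir)
                if clear >= spec.min_clearance:
                    break
            grow(child, end, best[1], dia, label)

    grow("1", np.zeros(3), trachea_dir, spec.diameter_scale, None)
    return AirwayTree(spec=spec, branches=branches, ground_truth=_ground_truth(branches))


def _gravity_from_geometry(branches: dict[str, BranchGeom]) -> np.ndarray | None:
    """Gravity unit vector from the trachea/main-bronchi plane, or None."""
    if "1" not in branches:
        return None
    t = branches["1"].vector
    t = t / np.linalg.norm(t)
    kids = [branches[k] for k in ("11", "12") if k in branches]
    if len(kids) < 2:
        return None
    units = [b.vector / np.linalg.norm(b.vector) for b in kids]
    b = (units[0] + units[1]) / 2.0
    g = b - (b @ t) * t
    norm = np.linalg.norm(g)
    if norm < 1e-12:
        return None
    g = g / norm
    return g if g @ b >= 0 else -g


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _ground_truth(branches: dict[str, BranchGeom]) -> pd.DataFrame:
    g = _gravity_from_geometry(branches)
    rows = []
    for label in sorted(branches):
        b = branches[label]
        angle = _angle_deg(branches[b.parent].vector, b.vector) if b.parent else np.nan
        grav = _angle_deg(b.vector, g) if g is not None else np.nan
        rows.append({
            "label": label,
            "generation": len(label),
            "x1": b.start[0], "y1": b.start[1], "z1": b.start[2],
            "x2": b.end[0], "y2": b.end[1], "z2": b.end[2],
            "length_mm": b.length,
            "diameter_mm": b.diameter,
            "branch_angle_deg": angle,
            "gravity_angle_deg": grav,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rasterisation

def _stamp_tube(values: np.ndarray, origin_mm: np.ndarray, spacing_mm: float,
                points: np.ndarray, radius_mm: float,
                flat_start: bool = False, flat_end: bool = False) -> None:
    """OR a capsule chain along ``points`` (mm) into ``values`` in place.

    ``flat_start``/``flat_end`` cut the respective cap flat at the endpoint
    plane (used for exposed ends so ground-truth length is exact).
    """
    lo = (points.min(axis=0) - radius_mm - 2 * spacing_mm - origin_mm) / spacing_mm
    hi = (points.max(axis=0) + radius_mm + 2 * spacing_mm - origin_mm) / spacing_mm
    lo = np.maximum(np.floor(lo).astype(int), 0)
    hi = np.minimum(np.ceil(hi).astype(int) + 1, values.shape)
    if np.any(lo >= hi):
        return
    idx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    pos = idx.reshape(3, -1).T * spacing_mm + origin_mm  # (M, 3) mm
    dmin = np.full(pos.shape[0], np.inf)
    for a, b in zip(points[:-1], points[1:]):
        ab = b - a
        denom = ab @ ab
        if denom < 1e-18:
            continue
        t = np.clip((pos - a) @ ab / denom, 0.0, 1.0)
        dmin = np.minimum(dmin, np.linalg.norm(pos - (a + t[:, None] * ab), axis=1))
    inside = dmin <= radius_mm
    if flat_start:
        d0 = points[1] - points[0]
        inside &= (pos - points[0]) @ d0 >= 0.0
    if flat_end:
        d1 = points[-1] - points[-2]
        inside &= (pos - points[-1]) @ d1 <= 0.0
    block = values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    np.logical_or(block, inside.reshape(block.shape), out=block)


def rasterize_tree(tree: AirwayTree, voxel_size: float, margin_mm: float = 0.3) -> BinaryMask:
    """Rasterise an :class:`AirwayTree` into a binary volume.

    ``voxel_size`` is in micrometres.  Emits a warning when the smallest
    branch diameter spans fewer than 4 voxels (measurements there fall below
    the workflow's accuracy).
    """
    spacing_mm = voxel_size / 1000.0
    if not tree.branches:
        return BinaryMask(values=np.zeros((1, 1, 1), bool), spacing=voxel_size,
                          provenance=[{"op": "rasterize", "voxel_size_um": voxel_size}])
    dmin = min(b.diameter for b in tree.branches.values())
    if dmin < 4 * spacing_mm:
        warnings.warn(
            f"smallest branch diameter {dmin:.3f} mm spans < 4 voxels at "
            f"{voxel_size} um; measurements will be below workflow accuracy",
            stacklevel=2,
        )
    pts = np.vstack([b.points for b in tree.branches.values()])
    rmax = max(b.diameter for b in tree.branches.values()) / 2.0
    lo = pts.min(axis=0) - rmax - margin_mm
    hi = pts.max(axis=0) + rmax + margin_mm
    shape = np.ceil((hi - lo) / spacing_mm).astype(int) + 1
    values = np.zeros(shape, dtype=bool)
    origin_mm = lo
    has_child = {b.parent for b in tree.branches.values() if b.parent}
    for label, b in tree.branches.items():
        _stamp_tube(
            values, origin_mm, spacing_mm, b.points, b.diameter / 2.0,
            flat_start=(b.parent is None),
            flat_end=(label not in has_child),
        )
    return BinaryMask(
        values=values, spacing=voxel_size, origin=origin_mm * 1000.0,
        provenance=[{"op": "rasterize", "voxel_size_um": voxel_size}],
    )


# ---------------------------------------------------------------------------
# artifact injection

def _closest_axis_points(a: BranchGeom, b: BranchGeom, min_gap: float = 0.0,
                         n: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Closest pair of mid-section axis points whose surfaces are at least
    ``min_gap`` (mm) apart — a bridge between overlapping surfaces (e.g. two
    siblings inside their junction lens) would change nothing."""
    # stay mid-branch: an attachment near a tip or a junction lets the
    # skeleton junction swallow the neighbouring feature
    ta = np.linspace(0.25, 0.75, n)[:, None]
    pa = a.start * (1 - ta) + a.end * ta
    pb = b.start * (1 - ta) + b.end * ta
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    gap = d - (a.diameter + b.diameter) / 2.0
    valid = gap >= min_gap
    if valid.any():
        d = np.where(valid, d, np.inf)
    i, j = np.unravel_index(int(d.argmin()), d.shape)
    return pa[i], pb[j]


def _point_branch_clearance(p: np.ndarray, b: BranchGeom) -> float:
    t = float(np.clip((p - b.start) @ b.vector / (b.length**2 + 1e-18), 0.0, 1.0))
    return float(np.linalg.norm(p - (b.start + t * b.vector)) - b.diameter / 2.0)


def inject_artifacts(mask: BinaryMask, tree: AirwayTree,
                     artifacts: list[ArtifactSpec]) -> BinaryMask:
    """Stamp artifact geometry into a rasterised phantom.

    * ``touching_branches`` — thin bridge (diameter = magnitude, intended to
      be below the opening bandwidth) between the closest surface points of
      the two branches named ``"A:B"``.
    * ``closed_loop`` — same construction with a thick bridge that survives
      opening, producing a genuine cycle.
    * ``spur_nub`` — short lateral protrusion of length = magnitude off the
      midpoint of the named branch (annular-ligament-like nub).
    * ``trifurcation`` — a third, smaller daughter stamped at the distal
      node of the named branch.
    """
    values = mask.values.copy()
    spacing_mm = mask.spacing / 1000.0
    origin_mm = np.asarray(mask.origin, float) / 1000.0
    for art in artifacts:
        mag_mm = art.magnitude / 1000.0
        if art.kind in ("touching_branches", "closed_loop"):
            la, lb = art.location.split(":")
            if la not in tree.branches or lb not in tree.branches:
                raise KeyError(f"artifact location {art.location!r} not in tree")
            pa, pb = _closest_axis_points(tree[la], tree[lb],
                                          min_gap=3.0 * spacing_mm)
            _stamp_tube(values, origin_mm, spacing_mm,
                        np.array([pa, pb]), mag_mm / 2.0)
        elif art.kind == "spur_nub":
            loc, _, frac = art.location.partition("@")
            if loc not in tree.branches:
                raise KeyError(f"artifact location {loc!r} not in tree")
            b = tree[loc]
            t_attach = float(frac) if frac else 0.5
            mid = b.start + t_attach * (b.end - b.start)
            d = b.vector / b.length
            n1, n2 = _perp_frame(d)
            # pick the lateral direction whose tip stays clearest of every
            # other branch, so the nub protrudes into background
            best_tip, best_clear = None, -np.inf
            for phi in np.linspace(0.0, 2 * np.pi, 12, endpoint=False):
                u = np.cos(phi) * n1 + np.sin(phi) * n2
                tip = mid + u * (b.diameter / 2.0 + mag_mm)
                clear = min(
                    (_point_branch_clearance(tip, other)
                     for lab, other in tree.branches.items() if lab != loc),
                    default=np.inf,
                )
                if clear > best_clear:
                    best_tip, best_clear = tip, clear
            _stamp_tube(values, origin_mm, spacing_mm,
                        np.array([mid, best_tip]),
                        max(mag_mm / 3.0, 1.6 * spacing_mm), flat_end=True)
        elif art.kind == "trifurcation":
            if art.location not in tree.branches:
                raise KeyError(f"artifact location {art.location!r} not in tree")
            parent = tree[art.location]
            d = parent.vector / parent.length
            kids = [tree[k] for k in (art.location + "1", art.location + "2")
                    if k in tree.branches]
            if len(kids) == 2:
                # the third daughter must leave the junction >= ~60 degrees
                # from the parent and both daughters or its tube merges with
                # a neighbour for over a millimetre before surfacing; the
                # normal of the daughters' plane is the widest-open direction
                d1 = kids[0].vector / kids[0].length
                d2 = kids[1].vector / kids[1].length
                nrm = np.cross(d1, d2)
                nrm /= max(np.linalg.norm(nrm), 1e-9)
                extra_dir = 0.3 * d + nrm
            else:
                u, v = _perp_frame(d)
                extra_dir = d + 0.8 * (0.6 * u + 0.8 * v)
            extra_dir /= np.linalg.norm(extra_dir)
            dia = (min(k.diameter for k in kids) if kids else parent.diameter) * 0.8
            # long enough to emerge from the junction zone by several radii,
            # otherwise thinning retracts the stub entirely
            sinang = np.sqrt(max(1.0 - (d @ extra_dir) ** 2, 1e-6))
            length = max(mag_mm, parent.diameter / (2.0 * sinang) + 2.0 * dia)
            # start slightly inside the parent so the skeleton junction sits
            # within the trifurcation-intermediate detection range
            start = parent.end - 0.3 * (parent.diameter / 2.0) * d
            tip = start + extra_dir * length
            _stamp_tube(values, origin_mm, spacing_mm,
                        np.array([start, tip]), dia / 2.0, flat_end=True)
    return mask.with_op(values, "inject_artifacts",
                        artifacts=[(a.kind, a.location, a.magnitude) for a in artifacts])
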