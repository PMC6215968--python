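"""Parametric curved-strand geometry.

Builds the idealised slab of atrial muscle (optionally flanked by
endocardial and/or epicardial conductive bath layers), bends it to a
prescribed interface curvature while preserving the endocardial arc
length, tags regions / boundaries / the stimulus node set, and places the
activation and electrogram probes on the endocardial interface.

Also provides closed-form synthetic activation fields used to unit-test
the conduction-velocity estimators.

Coordinates are in cm.  The *straight frame* ``(X, Y)`` has the muscle
occupying ``[0, lm] x [Y_min, Le]`` with the endocardial interface on the
line ``X = 0``; the endocardial bath sits at ``X < 0`` and the epicardial
bath at ``X > lm``.  The bottom strip ``Y <= 0`` is never bent, so the
stimulated region is identical across curvatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "StrandSpec",
    "TissueMesh",
    "ProbeSet",
    "GeometryError",
    "MUSCLE",
    "BATH_ENDO",
    "BATH_EPI",
    "bend",
    "unbend",
    "curvature",
    "build_straight_strand",
    "build_strand",
    "place_probes",
    "synthetic_activation",
]

MUSCLE, BATH_ENDO, BATH_EPI = 0, 1, 2
REGION_NAMES = {MUSCLE: "muscle", BATH_ENDO: "bath_endo", BATH_EPI: "bath_epi"}

#: straight-frame Y below which nodes belong to the stimulus region (cm)
STIMULUS_Y_CUTOFF = -0.02797


class GeometryError(ValueError):
    """Raised for inconsistent strand dimensions or a non-injective bend."""


@dataclass(frozen=True)
class StrandSpec:
    """Dimensions and discretisation of the bent-strand geometry.

    Lengths in cm, ``theta`` in radians.  ``theta = 0`` is the straight
    strand; ``theta in (0, pi]`` bends the region ``Y > 0`` onto an annulus
    whose endocardial radius is ``R0 = Le / theta``.  ``c = +1`` bends left
    (positive interface curvature), ``c = -1`` right (negative).
    """

    lm: float                   # muscle thickness
    L: float = 2.3              # total interface length
    Le: float = 2.0             # bent (endocardial) length, == Y_max
    lb_endo: float = 0.0        # endocardial bath thickness
    lb_epi: float = 0.0         # epicardial bath thickness
    theta: float = 0.0          # bend angle
    c: int = 1                  # bend direction
    hX: float = 0.0025          # transverse mesh size (25 um)
    hY: float = 0.005           # longitudinal mesh size (50 um)
    #: geometric coarsening ratio of bath columns away from the interface
    #: (1.0 = uniform grid, the default for the idealised experiments);
    #: when > 1, a boundary layer of >= 3 fine columns stays at hX
    bath_grading: float = 1.0

    def __post_init__(self):
        if not (self.L > self.Le > 0):
            raise GeometryError(f"need L > Le > 0, got L={self.L}, Le={self.Le}")
        if self.lm <= 0:
            raise GeometryError(f"muscle thickness must be positive, got {self.lm}")
        if self.hX <= 0 or self.hY <= 0:
            raise GeometryError("mesh sizes must be positive")
        if self.hX > self.lm + 1e-12:
            raise GeometryError(
                f"hX={self.hX} exceeds muscle thickness {self.lm}: "
                "fewer than one element across the muscle"
            )
        if self.lb_endo < 0 or self.lb_epi < 0:
            raise GeometryError("bath thicknesses must be >= 0")
        if self.bath_grading < 1.0:
            raise GeometryError("bath_grading must be >= 1")
        if not (0.0 <= self.theta <= np.pi):
            raise GeometryError(f"theta must lie in [0, pi], got {self.theta}")
        if self.c not in (-1, 1):
            raise GeometryError(f"bend direction c must be +-1, got {self.c}")
        if self.theta > 0:
            R0 = self.Le / self.theta
            # innermost radius across the full cross-section must stay positive
            X_inner = -self.lb_endo if self.c == 1 else -(self.lm + self.lb_epi)
            # R = R0 + c X; for c=+1 smallest at X=-lb_endo, for c=-1 at X=lm+lb_epi
            R_min = R0 - (self.lb_endo if self.c == 1 else self.lm + self.lb_epi)
            if R_min <= 0:
                side = "endocardial bath" if self.c == 1 else "muscle+epicardial bath"
                raise GeometryError(
                    f"bend radius R0={R0:.4g} cm too small for the {side} "
                    f"thickness: mapped radius {R_min:.4g} <= 0"
                )

    @property
    def Y_min(self) -> float:
        return self.Le - self.L

    @property
    def R0(self) -> float:
        if self.theta == 0:
            return np.inf
        return self.Le / self.theta

    @property
    def kappa(self) -> float:
        return curvature(self.theta, self.c, self.Le)

    def scaled(self, factor: float) -> "StrandSpec":
        """Same geometry at ``factor`` x coarser mesh (hX, hY scaled)."""
        hX = min(self.hX * factor, self.lm)  # keep >= 1 element across muscle
        return replace(self, hX=hX, hY=self.hY * factor)


def curvature(theta: float, c: int, Ymax: float) -> float:
    """Signed interface curvature kappa = c * theta / Ymax (1/cm); 0 when
    the strand is straight."""
    if theta == 0:
        return 0.0
    return c * theta / Ymax


def bend(points: np.ndarray, theta: float, c: int, Ymax: float) -> np.ndarray:
    """Map straight-frame points onto the bent configuration.

    Points with ``Y <= 0`` are unchanged; for ``Y > 0`` the strand is
    wrapped onto circles concentric with ``(-c R0, 0)``, preserving arc
    length along every longitudinal line ``X = const`` at its own radius
    ``R = R0 + c X`` and exactly on the interface ``X = 0``.  For
    ``c = +1`` (positive interface curvature) the bend is toward the
    endocardial bath side, which sits on the inside of the bend; the
    muscle lies at radii larger than R0, which is what slows the
    endocardial front.  ``theta = 0`` is the identity.
    """
    pts = np.asarray(points, dtype=float)
    if theta == 0:
        return pts.copy()
    out = pts.copy()
    X, Y = pts[..., 0], pts[..., 1]
    R0 = Ymax / theta
    R = R0 + c * X
    top = Y > 0
    if np.any(R[top] <= 0):
        worst = float(np.min(R[top]))
        raise GeometryError(
            f"bend not injective: radius R0 + cX reaches {worst:.4g} <= 0; "
            "reduce the bath/muscle thickness on the inside of the bend"
        )
    # wrap around the centre (-c R0, 0): continuous with the unbent strip,
    # orientation-preserving (det J = R theta / Ymax > 0)
    phi = theta * Y / Ymax
    out[..., 0] = np.where(top, c * (R * np.cos(phi) - R0), X)
    out[..., 1] = np.where(top, R * np.sin(phi), Y)
    return out


def unbend(points: np.ndarray, theta: float, c: int, Ymax: float) -> np.ndarray:
    """Inverse of :func:`bend` (exact for points in the image of the map)."""
    pts = np.asarray(points, dtype=float)
    if theta == 0:
        return pts.copy()
    out = pts.copy()
    x, y = pts[..., 0], pts[..., 1]
    R0 = Ymax / theta
    top = y > 0
    Rc = R0 + c * x      # R cos(phi)
    R = np.hypot(y, Rc)
    phi = np.arctan2(y, Rc)
    out[..., 0] = np.where(top, c * (R - R0), x)
    out[..., 1] = np.where(top, phi * Ymax / theta, y)
    return out


@dataclass
class TissueMesh:
    """Conforming structured triangulation of the (possibly bent) strand.

    ``nodes`` are bent coordinates; ``straight_nodes`` keep the pre-bend
    frame (used for fiber construction and the stimulus predicate).
    Triangles are counterclockwise.  ``edge_sets`` maps label ->
    ``(n_edges, 2)`` node-index pairs: ``interface_endo``/``interface_epi``
    (muscle-bath interfaces; tagged even when the bath is absent),
    ``muscle_exterior`` and ``bath_exterior``.
    """

    nodes: np.ndarray            # (N, 2)
    straight_nodes: np.ndarray   # (N, 2)
    triangles: np.ndarray        # (M, 3) int
    region: np.ndarray           # (M,) int, MUSCLE/BATH_ENDO/BATH_EPI
    edge_sets: dict[str, np.ndarray]
    stimulus_nodes: np.ndarray   # int indices
    spec: StrandSpec
    shape: tuple[int, int]       # (n_cols, n_rows) of the node grid

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    @property
    def muscle_elements(self) -> np.ndarray:
        return np.where(self.region == MUSCLE)[0]

    @property
    def muscle_nodes(self) -> np.ndarray:
        """Indices of nodes incident to at least one muscle element."""
        return np.unique(self.triangles[self.region == MUSCLE])

    @property
    def interface_nodes(self) -> np.ndarray:
        """Endocardial-interface node indices ordered by arc length."""
        edges = self.edge_sets["interface_endo"]
        idx = np.unique(edges)
        order = np.argsort(self.straight_nodes[idx, 1])
        return idx[order]

    def areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        a, b = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]
        return 0.5 * (a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])

    def centroids(self, frame: Literal["bent", "straight"] = "bent") -> np.ndarray:
        pts = self.nodes if frame == "bent" else self.straight_nodes
        return pts[self.triangles].mean(axis=1)


def _bath_offsets(lb: float, hX: float, grading: float) -> np.ndarray:
    """Cumulative column offsets (ascending, excluding 0) covering a bath
    of depth ``lb`` starting at the interface.

    Uniform when ``grading == 1``; otherwise a boundary layer of three
    fine columns at ``hX`` followed by geometrically growing widths, the
    last column truncated so the total depth is exact.
    """
    if grading == 1.0:
        nb = max(1, int(round(lb / hX)))
        return np.linspace(0.0, lb, nb + 1)[1:]
    widths, w, total = [], hX, 0.0
    k = 0
    while total < lb - 1e-12:
        if k >= 3:
            w = min(w * grading, lb - total)
        widths.append(min(w, lb - total))
        total += widths[-1]
        k += 1
    return np.cumsum(widths)


def _column_coords(spec: StrandSpec) -> tuple[np.ndarray, np.ndarray]:
    """Transverse node coordinates and per-element-column region labels."""
    nm = int(round(spec.lm / spec.hX))
    xs = [np.linspace(0.0, spec.lm, nm + 1)]
    reg = [np.full(nm, MUSCLE)]
    if spec.lb_endo > 0:
        off = _bath_offsets(spec.lb_endo, spec.hX, spec.bath_grading)
        xs.insert(0, -off[::-1])
        reg.insert(0, np.full(len(off), BATH_ENDO))
    if spec.lb_epi > 0:
        off = _bath_offsets(spec.lb_epi, spec.hX, spec.bath_grading)
        xs.append(spec.lm + off)
        reg.append(np.full(len(off), BATH_EPI))
    return np.concatenate(xs), np.concatenate(reg)


def build_straight_strand(spec: StrandSpec) -> TissueMesh:
    """Structured triangulation of the straight strand plus bath layers.

    Each ``hX x hY`` rectangle is split along its lower-left to upper-right
    diagonal into two counterclockwise triangles.  Baths conform with the
    muscle on the shared interface columns.
    """
    X, col_region = _column_coords(spec)
    ny = int(round(spec.L / spec.hY))
    Y = np.linspace(spec.Y_min, spec.Le, ny + 1)
    nx = len(X) - 1

    XX, YY = np.meshgrid(X, Y, indexing="ij")
    nodes = np.column_stack([XX.ravel(), YY.ravel()])

    def nid(i, j):  # column i, row j
        return i * (ny + 1) + j

    i_idx, j_idx = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    ll = nid(i_idx, j_idx).ravel()
    lr = nid(i_idx + 1, j_idx).ravel()
    ur = nid(i_idx + 1, j_idx + 1).ravel()
    ul = nid(i_idx, j_idx + 1).ravel()
    # diagonal ll -> ur
    tri = np.empty((2 * nx * ny, 3), dtype=np.int64)
    tri[0::2] = np.column_stack([ll, lr, ur])
    tri[1::2] = np.column_stack([ll, ur, ul])
    region = np.repeat(col_region, 2 * ny)

    # boundary / interface edge sets
    i_endo = int(np.argmin(np.abs(X - 0.0)))       # column at X = 0
    i_epi = int(np.argmin(np.abs(X - spec.lm)))    # column at X = lm
    rows = np.arange(ny)

    def column_edges(i):
        return np.column_stack([nid(i, rows), nid(i, rows + 1)])

    edge_sets: dict[str, np.ndarray] = {
        "interface_endo": column_edges(i_endo),
        "interface_epi": column_edges(i_epi),
    }
    muscle_ext, bath_ext = [], []
    cols = np.arange(nx)
    bottom = np.column_stack([nid(cols, 0), nid(cols + 1, 0)])
    top = np.column_stack([nid(cols, ny), nid(cols + 1, ny)])
    left = column_edges(0)
    right = column_edges(nx)
    for e_set, horiz in ((bottom, True), (top, True)):
        for i, e in zip(cols, e_set):
            (muscle_ext if col_region[i] == MUSCLE else bath_ext).append(e)
    (muscle_ext if spec.lb_endo == 0 else bath_ext).extend(left)
    (muscle_ext if spec.lb_epi == 0 else bath_ext).extend(right)
    edge_sets["muscle_exterior"] = np.asarray(muscle_ext, dtype=np.int64)
    edge_sets["bath_exterior"] = (
        np.asarray(bath_ext, dtype=np.int64).reshape(-1, 2)
    )

    muscle_col = (nodes[:, 0] >= -1e-12) & (nodes[:, 0] <= spec.lm + 1e-12)
    stim = np.where(muscle_col & (nodes[:, 1] < STIMULUS_Y_CUTOFF))[0]

    return TissueMesh(
        nodes=nodes.copy(),
        straight_nodes=nodes,
        triangles=tri,
        region=region,
        edge_sets=edge_sets,
        stimulus_nodes=stim,
        spec=spec,
        shape=(nx + 1, ny + 1),
    )


def build_strand(spec: StrandSpec) -> tuple[TissueMesh, "ProbeSet"]:
    """Build the straight strand, apply the bend, and place the probes."""
    mesh = build_straight_strand(spec)
    if spec.theta > 0:
        mesh.nodes = bend(mesh.straight_nodes, spec.theta, spec.c, spec.Le)
    probes = place_probes(mesh)
    return mesh, probes


# -- probes -----------------------------------------------------------------

#: straight-frame reference coordinates (cm) of the activation probes
X1_REF, X2_REF = (0.0, 1.0), (0.0, 1.5)
#: straight-frame reference coordinates (cm) of the electrogram probes
P1_REF, P2_REF = (0.0, 1.75), (0.0, 1.95)


@dataclass
class ProbeSet:
    """Activation probes ``x1, x2`` (5 mm apart along the interface) and
    electrogram probes ``p1, p2`` (2 mm apart), snapped to interface
    nodes."""

    node_x1: int
    node_x2: int
    node_p1: int
    node_p2: int
    x1: np.ndarray
    x2: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    snap_distance: float
    #: geodesic interface separations (cm), preserved under bending
    separation_x: float = 0.5
    separation_p: float = 0.2


def place_probes(mesh: TissueMesh) -> ProbeSet:
    """Snap the four reference probes to the nearest endocardial-interface
    mesh node (the default hY divides every probe offset, so the snap is
    lossless there)."""
    spec = mesh.spec
    iface = mesh.interface_nodes
    Y_iface = mesh.straight_nodes[iface, 1]
    ids, snap = [], 0.0
    for ref in (X1_REF, X2_REF, P1_REF, P2_REF):
        k = int(np.argmin(np.abs(Y_iface - ref[1])))
        d = abs(Y_iface[k] - ref[1])
        snap = max(snap, d)
        ids.append(int(iface[k]))
    if snap > spec.hY:
        raise GeometryError(
            f"probe snap distance {snap:.3g} cm exceeds hY={spec.hY}"
        )
    n1, n2, m1, m2 = ids
    return ProbeSet(
        node_x1=n1, node_x2=n2, node_p1=m1, node_p2=m2,
        x1=mesh.nodes[n1].copy(), x2=mesh.nodes[n2].copy(),
        p1=mesh.nodes[m1].copy(), p2=mesh.nodes[m2].copy(),
        snap_distance=float(snap),
    )


# -- synthetic activation fields (estimator test fixtures) ------------------

def synthetic_activation(
    mesh: TissueMesh,
    mode: Literal["planar", "radial"],
    speed: float,
    origin: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Closed-form per-node activation-time map (ms).

    ``planar``: a front translating in +y at ``speed`` (cm/ms) from
    ``y = origin[1]``; ``radial``: a circular front expanding from
    ``origin``.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    xy = mesh.nodes
    if mode == "planar":
        return (xy[:, 1] - origin[1]) / speed
    if mode == "radial":
        return np.hypot(xy[:, 0] - origin[0], xy[:, 1] - origin[1]) / speed
    raise ValueError(f"unknown mode {mode!r}")
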