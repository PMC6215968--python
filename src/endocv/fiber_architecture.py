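"""Per-element fiber directions on the muscle region.

Two constructions:

* :func:`strand_fibers` -- analytic tangents of the bent longitudinal
  lines of the parametric strand (exact, used for the idealised
  experiments);
* :func:`harmonic_fiber_field` -- the rule-based construction for
  arbitrary muscle meshes: solve a Laplace problem with unit Dirichlet
  data on two boundary sets and take the normalised gradient.

Fibers are unit 2-D vectors stored per muscle element (matching the
piecewise-constant conductivity tensors of the linear-element assembly);
they are never defined in the bath.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .strand_geometry import MUSCLE, TissueMesh

__all__ = ["FiberField", "strand_fibers", "harmonic_fiber_field"]


@dataclass
class FiberField:
    """Unit fiber vectors for the muscle elements of a mesh.

    ``vectors[k]`` is the fiber direction on element ``elements[k]``;
    ``potential`` carries the harmonic potential at muscle nodes when the
    field was built by :func:`harmonic_fiber_field` (else None).
    """

    elements: np.ndarray          # muscle element indices into mesh.triangles
    vectors: np.ndarray           # (n_muscle_elements, 2), unit norm
    potential: np.ndarray | None = None

    def __post_init__(self):
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("fiber vectors must have unit norm")

    def on_elements(self, mesh: TissueMesh) -> np.ndarray:
        """(n_elements, 2) array with fibers on muscle elements and NaN in
        the bath (for export)."""
        out = np.full((mesh.n_elements, 2), np.nan)
        out[self.elements] = self.vectors
        return out


def strand_fibers(mesh: TissueMesh) -> FiberField:
    """Fibers tangent to the bent longitudinal lines.

    In the straight frame the fibers are (0, 1); the bend maps the line
    ``X = const`` onto a circle of radius ``R0 + cX`` centred at
    ``(-c R0, 0)``, whose unit tangent at angle ``phi = theta Y / Ymax``
    is ``(-c sin phi, cos phi)``.  For the straight strand this reduces
    to (0, 1) everywhere.
    """
    spec = mesh.spec
    els = mesh.muscle_elements
    cen = mesh.centroids(frame="straight")[els]
    f = np.zeros((len(els), 2))
    if spec.theta == 0:
        f[:, 1] = 1.0
    else:
        phi = np.where(cen[:, 1] > 0, spec.theta * cen[:, 1] / spec.Le, 0.0)
        f[:, 0] = -spec.c * np.sin(phi)
        f[:, 1] = np.cos(phi)
    return FiberField(elements=els, vectors=f)


def _p1_gradients(nodes: np.ndarray, tris: np.ndarray):
    """Per-element P1 shape-function gradients and areas.

    Returns ``(grads, areas)`` with ``grads`` of shape (M, 3, 2):
    ``grads[k, a]`` is the gradient of the hat function of local vertex
    ``a`` on triangle ``k``.
    """
    p = nodes[tris]
    v0, v1, v2 = p[:, 0], p[:, 1], p[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    d = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]  # 2 * signed area
    if np.any(d <= 0):
        raise ValueError("degenerate or negatively oriented triangle")
    g = np.empty((len(tris), 3, 2))
    # grad of hat_a is perpendicular to the opposite edge / (2 area)
    for a, (b, c) in enumerate(((1, 2), (2, 0), (0, 1))):
        e = p[:, c] - p[:, b]
        g[:, a, 0] = -e[:, 1]
        g[:, a, 1] = e[:, 0]
    g /= d[:, None, None]
    return g, 0.5 * d


def harmonic_fiber_field(
    mesh: TissueMesh,
    gamma0: np.ndarray,
    gamma1: np.ndarray,
    grad_floor: float = 1e-10,
) -> FiberField:
    """Fibers from a harmonic potential on the muscle sub-mesh.

    Solves ``div grad(phi) = 0`` with ``phi = 0`` on the nodes of the edge
    set ``gamma0``, ``phi = 1`` on ``gamma1`` and zero normal flux on the
    rest of the muscle boundary, using linear elements; the fiber on each
    element is the normalised gradient of ``phi``.

    Raises if the two Dirichlet sets intersect or if the gradient
    magnitude falls below ``grad_floor`` anywhere (degenerate potential).
    """
    n0 = np.unique(np.asarray(gamma0))
    n1 = np.unique(np.asarray(gamma1))
    if n0.size == 0 or n1.size == 0:
        raise ValueError("gamma0 and gamma1 must be non-empty")
    if np.intersect1d(n0, n1).size:
        raise ValueError("gamma0 and gamma1 must be disjoint")

    els = mesh.muscle_elements
    tris = mesh.triangles[els]
    mnodes = np.unique(tris)
    local = -np.ones(mesh.n_nodes, dtype=np.int64)
    local[mnodes] = np.arange(len(mnodes))
    ltris = local[tris]

    grads, areas = _p1_gradients(mesh.nodes, tris)
    # isotropic stiffness: K_ab = area * grad_a . grad_b
    ke = np.einsum("kad,kbd,k->kab", grads, grads, areas)
    rows = np.repeat(ltris, 3, axis=1).ravel()
    cols = np.tile(ltris, (1, 3)).ravel()
    K = sp.csr_matrix(
        (ke.ravel(), (rows, cols)), shape=(len(mnodes), len(mnodes))
    )

    phi = np.zeros(len(mnodes))
    phi[local[n1]] = 1.0
    dir_mask = np.zeros(len(mnodes), dtype=bool)
    dir_mask[local[n0]] = True
    dir_mask[local[n1]] = True
    free = ~dir_mask
    rhs = -K[free][:, dir_mask] @ phi[dir_mask]
    phi[free] = spla.spsolve(K[free][:, free].tocsc(), rhs)

    g = np.einsum("kad,ka->kd", grads, phi[ltris])
    mag = np.linalg.norm(g, axis=1)
    bad = mag < grad_floor
    if bad.any():
        raise ValueError(
            f"degenerate harmonic potential: |grad phi| < {grad_floor} on "
            f"{bad.sum()} element(s), e.g. element {els[np.argmax(bad)]}"
        )
    return FiberField(elements=els, vectors=g / mag[:, None], potential=phi)
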