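"""Low-level finite-element kernel for linear quadrilaterals and hexahedra.

Everything is vectorized over elements and Gauss points; the reference-element
data (shape values, reference gradients, 2x2(x2) Gauss rule) is computed once
and the isoparametric mapping is precomputed per mesh.
"""

from __future__ import annotations

import numpy as np

_G = 1.0 / np.sqrt(3.0)

# quad node order: (-1,-1), (1,-1), (1,1), (-1,1)  (counter-clockwise)
_QUAD_NODES = np.array([[-1.0, -1.0], [1.0, -1.0], [1.0, 1.0], [-1.0, 1.0]])
# hex node order: bottom quad then top quad (VTK hexahedron)
_HEX_NODES = np.array(
    [[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
     [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], dtype=float
)


def gauss_points(dim: int) -> tuple[np.ndarray, np.ndarray]:
    """2-point tensor Gauss rule on [-1,1]^dim: (points (ngp,dim), weights (ngp,))."""
    pts1 = np.array([-_G, _G])
    if dim == 1:
        return pts1[:, None], np.ones(2)
    if dim == 2:
        g = np.array([[x, y] for y in pts1 for x in pts1])
        return g, np.ones(4)
    g = np.array([[x, y, z] for z in pts1 for y in pts1 for x in pts1])
    return g, np.ones(8)


def shape_functions(dim: int, xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear/trilinear shape values and reference gradients.

    Returns ``(N, dN)`` with shapes ``(npts, nn)`` and ``(npts, nn, dim)``.
    """
    xi = np.atleast_2d(xi)
    nodes = _QUAD_NODES if dim == 2 else _HEX_NODES
    nn = nodes.shape[0]
    npts = xi.shape[0]
    N = np.ones((npts, nn))
    dN = np.zeros((npts, nn, dim))
    for d in range(dim):
        fac = 0.5 * (1.0 + xi[:, None, d] * nodes[None, :, d])
        N *= fac
    for d in range(dim):
        term = np.ones((npts, nn))
        for e in range(dim):
            if e == d:
                term *= 0.5 * nodes[None, :, e]
            else:
                term *= 0.5 * (1.0 + xi[:, None, e] * nodes[None, :, e])
        dN[:, :, d] = term
    return N, dN


class ElementBasis:
    """Precomputed isoparametric data on the reference configuration.

    Attributes
    ----------
    N : (ngp, nn) shape values
    dN_dx : (E, ngp, nn, dim) physical shape gradients
    detJxW : (E, ngp) quadrature weights times Jacobian determinants
    """

    def __init__(self, node_coords: np.ndarray, elements: np.ndarray):
        dim = node_coords.shape[1]
        xi, w = gauss_points(dim)
        N, dN = shape_functions(dim, xi)
        coords = node_coords[elements]                      # (E, nn, dim)
        # J[e,g,i,j] = d x_i / d xi_j
        J = np.einsum("eni,gnj->egij", coords, dN)
        detJ = np.linalg.det(J)
        if np.any(detJ <= 0):
            raise ValueError("element with non-positive Jacobian determinant")
        Jinv = np.linalg.inv(J)
        self.dim = dim
        self.nn = elements.shape[1]
        self.ngp = len(w)
        self.N = N
        self.dN_dx = np.einsum("gnj,egji->egni", dN, Jinv)
        self.detJxW = detJ * w[None, :]
        # Gauss-point physical coordinates (reference configuration)
        self.gp_coords = np.einsum("gn,enj->egj", N, coords)

    def interpolate(self, nodal: np.ndarray, elements: np.ndarray) -> np.ndarray:
        """Scalar nodal field -> values at Gauss points, shape (E, ngp)."""
        return np.einsum("gn,en->eg", self.N, nodal[elements])

    def gradient(self, nodal: np.ndarray, elements: np.ndarray) -> np.ndarray:
        """Scalar nodal field -> gradients at Gauss points, shape (E, ngp, dim)."""
        return np.einsum("egni,en->egi", self.dN_dx, nodal[elements])


def element_jacobians(node_coords: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """det(J) at every Gauss point of every element, shape (E, ngp)."""
    dim = node_coords.shape[1]
    xi, _ = gauss_points(dim)
    _, dN = shape_functions(dim, xi)
    coords = node_coords[elements]
    J = np.einsum("eni,gnj->egij", coords, dN)
    return np.linalg.det(J)


def element_measures(node_coords: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """Area (2D) or volume (3D) per element by Gauss integration."""
    dim = node_coords.shape[1]
    _, w = gauss_points(dim)
    detJ = element_jacobians(node_coords, elements)
    return detJ @ w
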