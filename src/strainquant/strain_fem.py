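"""Linear triangular FE mesh on the dot grid and per-frame strain tensors.

The dot pattern on the reference frame is meshed by Delaunay triangulation.
On a linear (constant-strain) triangle the displacement gradient is
constant and follows directly from the element's shape functions: with
reference edge matrix ``D = [X2-X1, X3-X1]`` and displacement edge matrix
``d = [u2-u1, u3-u1]`` (columns), ``grad u = d @ inv(D)``.  The reported
strain is the infinitesimal (linear) tensor

    eps = 1/2 (grad u + grad u^T),

exact for any affine displacement field and accurate to O(strain^2) for
the few-percent membrane stretches of interest; a pure rotation by angle
theta leaks a spurious strain of order theta^2/2 (documented small-strain
artifact).  Nodal tensors are recovered by area-weighted averaging of the
incident element tensors, and the per-frame mean xx / yy strains are the
unweighted average over all nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay

from .tracking import DotTracks


@dataclass
class TriMesh:
    """Linear triangular mesh on the reference dot positions.

    ``nodes`` are reference (x, y) coordinates, ``elements`` index triples
    with counter-clockwise orientation (positive signed area in x-right /
    y-up convention), ``element_areas`` the triangle areas in px^2.
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_areas: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def node_areas(self) -> np.ndarray:
        """Per-node sum of incident element areas (px^2)."""
        out = np.zeros(self.n_nodes)
        for el, a in zip(self.elements, self.element_areas):
            out[el] += a
        return out


@dataclass
class StrainTrace:
    """Per-frame, per-node symmetric strain tensors and their spatial means.

    ``node_strain`` has shape (n_frames, n_nodes, 2, 2); ``mean_xx`` and
    ``mean_yy`` are the node-averaged E_xx(t) and E_yy(t) series;
    ``times`` are seconds from the frame rate.  Strain is identically zero
    at the reference frame.
    """

    node_strain: np.ndarray
    times: np.ndarray

    @property
    def mean_xx(self) -> np.ndarray:
        return self.node_strain[:, :, 0, 0].mean(axis=1)

    @property
    def mean_yy(self) -> np.ndarray:
        return self.node_strain[:, :, 1, 1].mean(axis=1)

    @property
    def mean_xy(self) -> np.ndarray:
        return self.node_strain[:, :, 0, 1].mean(axis=1)


def _signed_area2(nodes: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Twice the signed area of each triangle (positive = CCW)."""
    p = nodes[tri]
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    return a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]


def build_mesh(reference: np.ndarray) -> TriMesh:
    """Delaunay-triangulate the reference dot pattern.

    Elements are re-oriented counter-clockwise.  The square 3x3 grid is
    fully degenerate for Delaunay (every quad is co-circular); qhull's
    triangulation of the lexicographically sorted input is deterministic,
    and nodal strains for affine fields do not depend on the diagonal
    choice.

    Raises
    ------
    ValueError
        For fewer than 3 nodes or an all-collinear pattern.
    """
    nodes = np.asarray(reference, dtype=float).reshape(-1, 2)
    if nodes.shape[0] < 3:
        raise ValueError("need at least 3 nodes to build a mesh")
    try:
        tri = Delaunay(nodes)
    except Exception as exc:  # qhull raises its own error type
        raise ValueError(f"triangulation failed (collinear nodes?): {exc}") from exc
    if tri.simplices.size == 0:
        raise ValueError("all nodes collinear: no triangulation exists")
    elements = np.sort(tri.simplices, axis=1)  # deterministic node order
    area2 = _signed_area2(nodes, elements)
    flip = area2 < 0
    elements[flip] = elements[flip][:, [0, 2, 1]]
    area2 = np.abs(area2)
    if np.any(area2 == 0):
        raise ValueError("degenerate (zero-area) element in triangulation")
    order = np.lexsort((elements[:, 2], elements[:, 1], elements[:, 0]))
    return TriMesh(nodes=nodes, elements=elements[order], element_areas=area2[order] / 2)


def element_strain(
    mesh: TriMesh, element: int, displaced_nodes: np.ndarray
) -> np.ndarray:
    """Infinitesimal strain tensor of one element at a displaced state.

    ``displaced_nodes`` holds the current (x, y) coordinates of *all* mesh
    nodes; the element's constant displacement gradient is evaluated from
    its linear shape functions and symmetrised.
    """
    idx = mesh.elements[element]
    X = mesh.nodes[idx]
    x = np.asarray(displaced_nodes, dtype=float)[idx]
    if not np.all(np.isfinite(x)):
        raise ValueError("displaced nodes must be finite")
    D = np.column_stack((X[1] - X[0], X[2] - X[0]))
    if abs(np.linalg.det(D)) < 1e-300:
        raise ValueError(f"degenerate reference element {element}")
    u = x - X
    grad = np.column_stack((u[1] - u[0], u[2] - u[0])) @ np.linalg.inv(D)
    return 0.5 * (grad + grad.T)


def _all_element_strains(mesh: TriMesh, displaced: np.ndarray) -> np.ndarray:
    """Vectorised element strains for one frame, shape (n_elements, 2, 2)."""
    X = mesh.nodes[mesh.elements]          # (ne, 3, 2)
    u = displaced[mesh.elements] - X       # (ne, 3, 2)
    D = np.stack((X[:, 1] - X[:, 0], X[:, 2] - X[:, 0]), axis=-1)
    d = np.stack((u[:, 1] - u[:, 0], u[:, 2] - u[:, 0]), axis=-1)
    grad = d @ np.linalg.inv(D)
    return 0.5 * (grad + np.swapaxes(grad, -1, -2))


def node_strain(mesh: TriMesh, tracks: DotTracks, fps: float | None = None) -> StrainTrace:
    """Per-frame nodal strain tensors from tracked dot positions.

    Each node's tensor is the area-weighted average of the strains of its
    incident elements; the displacement field is measured relative to the
    tracks' reference frame, which must coincide with the mesh nodes.

    Raises
    ------
    ValueError
        If the track and mesh node counts differ.
    """
    if tracks.n_dots != mesh.n_nodes:
        raise ValueError(
            f"track count {tracks.n_dots} != mesh node count {mesh.n_nodes}"
        )
    n_frames = tracks.n_frames
    node_eps = np.zeros((n_frames, mesh.n_nodes, 2, 2))
    w = mesh.element_areas[:, None, None]
    weight_sum = mesh.node_areas
    for t in range(n_frames):
        eps = _all_element_strains(mesh, tracks.positions[t])  # (ne, 2, 2)
        acc = np.zeros((mesh.n_nodes, 2, 2))
        contrib = eps * w
        for corner in range(3):
            np.add.at(acc, mesh.elements[:, corner], contrib)
        node_eps[t] = acc / weight_sum[:, None, None]
    times = np.arange(n_frames, dtype=float)
    if fps is not None:
        times = times / fps
    return StrainTrace(node_strain=node_eps, times=times)


def strain_table(trace: StrainTrace, fps: float):
    """Mean strain series as a DataFrame (frame, t_s, Exx_mean, Eyy_mean, Exy_mean)."""
    import pandas as pd

    n = trace.node_strain.shape[0]
    return pd.DataFrame(
        {
            "frame": np.arange(n),
            "t_s": np.arange(n) / fps,
            "Exx_mean": trace.mean_xx,
            "Eyy_mean": trace.mean_yy,
            "Exy_mean": trace.mean_xy,
        }
    )
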