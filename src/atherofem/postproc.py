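"""Derived quantities and reporting: stenosis degree, lumen area, stresses.

The headline scalar is the stenosis degree — the percentage reduction of the
lumen cross-sectional area relative to the undeformed reference,
``100 (1 - A / A0)``.  Positive values mean a narrowing lumen; pure
pressurization dilates the lumen and gives negative values.
"""

from __future__ import annotations

import warnings

import numpy as np

from .geometry import Mesh


def polygon_area(points: np.ndarray) -> float:
    """Signed shoelace area of a closed polygon (CCW positive)."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def lumen_area(mesh: Mesh, u: np.ndarray, plane: int | None = None) -> float:
    """Deformed lumen cross-section area in µm².

    2D: shoelace area of the deformed inner-boundary polygon (stored CCW).
    3D: area of the inner-boundary ring on the axial node plane nearest the
    artery mid-length (where the lesion is seeded), projected to the
    cross-sectional plane.

    A self-intersecting (collapsed) boundary reports zero area — i.e. 100%
    stenosis — with a warning.
    """
    if mesh.dim == 3 and plane is None:
        plane = mesh.meta["n_z"] // 2
    loop = mesh.inner_loop(plane or 0)
    pts = mesh.node_coords[loop][:, :2] + u[loop][:, :2]
    if _self_intersects(pts):
        warnings.warn("deformed lumen boundary self-intersects; "
                      "reporting fully occluded lumen", RuntimeWarning)
        return 0.0
    area = polygon_area(pts)
    if area < 0.0:
        raise ValueError("lumen boundary lost its counter-clockwise orientation")
    return area


def _self_intersects(pts: np.ndarray) -> bool:
    try:
        from shapely.geometry import Polygon
        return not Polygon(pts).is_valid
    except Exception:  # pragma: no cover - shapely always present in practice
        return False


def principal_stresses(sigma: np.ndarray, reduce_cells: bool = True) -> np.ndarray:
    """Largest principal Cauchy stress per element [kPa].

    ``sigma`` is (E, ngp, 3, 3) symmetric; Gauss-point tensors are
    volume-averaged per element (equal weights on the 2-point rule) before
    the eigen-decomposition.
    """
    sigma = np.asarray(sigma, dtype=float)
    if reduce_cells and sigma.ndim == 4:
        sigma = sigma.mean(axis=1)
    return np.linalg.eigvalsh(sigma)[..., -1]


def min_principal_stresses(sigma: np.ndarray, reduce_cells: bool = True) -> np.ndarray:
    sigma = np.asarray(sigma, dtype=float)
    if reduce_cells and sigma.ndim == 4:
        sigma = sigma.mean(axis=1)
    return np.linalg.eigvalsh(sigma)[..., 0]


def stenosis_series(result) -> "pandas.DataFrame":  # noqa: F821
    """Scalar time series of one run as a DataFrame (CSV-ready).

    Columns: time, lumen_area_um2, stenosis_pct, min_c, max_phi, max_p1_kPa.
    """
    import pandas as pd
    return pd.DataFrame(result.series)


def write_series_csv(result, path) -> None:
    stenosis_series(result).to_csv(path, index=False)


def plot_stenosis(results, labels=None, path=None):
    """Stenosis-degree vs pseudo-time, one curve per run (comparison mode)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not isinstance(results, (list, tuple)):
        results = [results]
    labels = labels or [r.config.label for r in results]
    fig, ax = plt.subplots(figsize=(5.0, 3.5))
    for res, lab in zip(results, labels):
        ax.plot(res.series["time"], res.series["stenosis_pct"], label=lab)
    ax.set_xlabel("pseudo-time")
    ax.set_ylabel("stenosis degree [%]")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def annulus_front_metrics(mesh: Mesh, phi: np.ndarray, level: float = 0.5):
    """Front-position metrics of a lesion on the structured annulus.

    Returns a dict with the outermost/innermost radial positions of the
    phi = level contour (sub-element interpolation along each radial ray)
    and the angular half-width of the lesion on the ring nearest mid-wall.
    """
    n_r, n_c = mesh.meta["n_r"], mesh.meta["n_c"]
    radii = np.linalg.norm(mesh.node_coords[:n_c * (n_r + 1)].reshape(
        n_r + 1, n_c, 2)[:, 0, :], axis=1)
    grid = phi[:n_c * (n_r + 1)].reshape(n_r + 1, n_c)

    r_out_front, r_in_front = -np.inf, np.inf
    for j in range(n_c):
        col = grid[:, j]
        hot = col >= level
        if not hot.any():
            continue
        i_hi = int(np.max(np.nonzero(hot)[0]))
        if i_hi < n_r:
            t = (col[i_hi] - level) / (col[i_hi] - col[i_hi + 1])
            r_hi = radii[i_hi] + t * (radii[i_hi + 1] - radii[i_hi])
        else:
            r_hi = radii[-1]
        i_lo = int(np.min(np.nonzero(hot)[0]))
        if i_lo > 0:
            t = (col[i_lo] - level) / (col[i_lo] - col[i_lo - 1])
            r_lo = radii[i_lo] + t * (radii[i_lo - 1] - radii[i_lo])
        else:
            r_lo = radii[0]
        r_out_front = max(r_out_front, r_hi)
        r_in_front = min(r_in_front, r_lo)

    # angular half-width on the ring closest to the lesion's radial centroid
    if np.isfinite(r_out_front):
        r_center = 0.5 * (r_out_front + r_in_front)
        ring = int(np.argmin(np.abs(radii - r_center)))
        row = grid[ring]
        dtheta = 2.0 * np.pi / n_c
        hot = row >= level
        frac = 0.0
        for j in range(n_c):
            a, b = row[j], row[(j + 1) % n_c]
            if hot[j] and hot[(j + 1) % n_c]:
                frac += 1.0
            elif hot[j] != hot[(j + 1) % n_c] and a != b:
                frac += abs((a - level) / (a - b)) if hot[j] else \
                    abs((b - level) / (b - a))
        ang_halfwidth = 0.5 * frac * dtheta
    else:
        ang_halfwidth = 0.0
    return {
        "r_outer_front": float(r_out_front),
        "r_inner_front": float(r_in_front),
        "angular_halfwidth": float(ang_halfwidth),
    }


def lesion_stress_signature(sim, state, phi_hot: float = 0.5,
                            phi_cold: float = 0.1, rim_width: float | None = None):
    """(min principal stress inside the lesion, max principal in the healthy rim).

    The lesion is the element set with mean phi > ``phi_hot``; the rim is the
    healthy elements (mean phi < ``phi_cold``) whose centroid lies within
    ``rim_width`` (default 3 element sizes) of the lesion centroids.
    """
    mesh = sim.mesh
    sigma = sim.cauchy_stress_field(state)
    phi_gp = sim.basis.interpolate(state.phi, mesh.elements)
    phi_e = phi_gp.mean(axis=1)
    hot = phi_e > phi_hot
    cold = phi_e < phi_cold
    if not np.any(hot) or not np.any(cold):
        return np.nan, np.nan
    cent = sim.basis.gp_coords.mean(axis=1)
    if rim_width is None:
        rim_width = 3.0 * mesh.meta.get("h", 1.0)
    d = np.min(np.linalg.norm(cent[cold][:, None, :] - cent[hot][None, :, :],
                              axis=2), axis=1)
    rim = np.where(cold)[0][d <= rim_width]
    if rim.size == 0:
        return np.nan, np.nan
    p_min_core = float(np.min(min_principal_stresses(sigma)[hot]))
    p_max_rim = float(np.max(principal_stresses(sigma)[rim]))
    return p_min_core, p_max_rim
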