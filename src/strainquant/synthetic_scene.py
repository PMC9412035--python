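"""Ground-truth renderer: dot-grid movies under programmable deformations.

The scene emulates the experimental recording: a small fiducial dot grid
(default 3x3) on a membrane viewed by a fixed camera, deformed by a
time-periodic near-affine stretch.  The cyclic waveform is a raised
cosine,

    w(t) = 1/2 (1 - cos 2 pi f t),

so valleys sit at zero strain, like a pump that stretches from rest.  The
deformation applied to the reference dot positions X (about the grid
center c) is

    x(t) = R(theta w) (I + w G) (X - c) + c + v t,

with G collecting the equibiaxial/anisotropic (amp_xx, amp_yy) and shear
components, R a rotation and v a constant drift.  Dots are rendered as
anti-aliased filled disks (analytic pixel coverage), optionally blurred,
with seeded Gaussian pixel noise, so that sub-pixel motion moves image
centroids smoothly.  The renderer returns both the frames and the exact
continuous dot-center trajectories; :func:`analytic_strain` gives the
exact infinitesimal strain of the affine map as the oracle for the FE
stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .dot_imaging import FrameSequence


@dataclass
class SyntheticScene:
    """Parameters of a rendered dot-grid stretching scene.

    Amplitudes are dimensionless strains at cycle peak: ``amp_xx`` /
    ``amp_yy`` the normal stretches, ``shear`` the off-diagonal
    displacement-gradient component, ``rotation`` the peak rotation in
    radians.  ``drift`` is a constant (px/s) translation velocity.
    """

    grid_shape: tuple[int, int] = (3, 3)
    grid_spacing: float = 80.0
    dot_radius: float = 5.0
    amp_xx: float = 0.04
    amp_yy: float = 0.04
    shear: float = 0.0
    rotation: float = 0.0
    drift: tuple[float, float] = (0.0, 0.0)
    frequency: float = 1.0
    phase: float = 0.0
    image_shape: tuple[int, int] | None = None  # (h, w); derived if None
    background: float = 0.85
    dot_intensity: float = 0.10
    blur_sigma: float = 1.0
    noise_sigma: float = 0.02
    fps: float = 30.0
    duration: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amp_xx < 0 or self.amp_yy < 0:
            raise ValueError("strain amplitudes must be non-negative")
        if self.image_shape is None:
            span_x = (self.grid_shape[1] - 1) * self.grid_spacing
            span_y = (self.grid_shape[0] - 1) * self.grid_spacing
            margin = 8 * self.dot_radius + 0.5 * max(self.amp_xx, self.amp_yy) * max(span_x, span_y)
            self.image_shape = (
                int(np.ceil(span_y + 2 * margin)),
                int(np.ceil(span_x + 2 * margin)),
            )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))

    @property
    def grid(self) -> np.ndarray:
        """Reference dot centers (x, y), row-major, centered in the image."""
        ny, nx = self.grid_shape
        h, w = self.image_shape
        x0 = (w - 1 - (nx - 1) * self.grid_spacing) / 2
        y0 = (h - 1 - (ny - 1) * self.grid_spacing) / 2
        pts = [
            (x0 + j * self.grid_spacing, y0 + i * self.grid_spacing)
            for i in range(ny)
            for j in range(nx)
        ]
        return np.array(pts)

    @property
    def center(self) -> np.ndarray:
        return self.grid.mean(axis=0)

    def waveform(self, t: np.ndarray | float) -> np.ndarray | float:
        """Raised-cosine modulation in [0, 1]; 0 at rest, 1 at cycle peak."""
        return 0.5 * (1.0 - np.cos(2 * np.pi * self.frequency * np.asarray(t) + self.phase))

    def affine_at(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Deformation (A, b) mapping reference positions at time t: x = A(X-c)+c+b."""
        w = float(self.waveform(t))
        G = np.array([[self.amp_xx, self.shear], [self.shear, self.amp_yy]])
        th = self.rotation * w
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        A = R @ (np.eye(2) + w * G)
        b = np.asarray(self.drift, dtype=float) * t
        return A, b

    def true_tracks(self) -> np.ndarray:
        """Exact continuous dot-center trajectories, shape (n_frames, n_dots, 2)."""
        c = self.center
        X = self.grid
        out = np.empty((self.n_frames, X.shape[0], 2))
        for k in range(self.n_frames):
            A, b = self.affine_at(k / self.fps)
            out[k] = (X - c) @ A.T + c + b
        return out


def analytic_strain(scene: SyntheticScene, t: float) -> np.ndarray:
    """Exact infinitesimal strain tensor of the scene's affine map at time t.

    Returns sym(A(t)) - I, the oracle against which FE strains are checked.

    Raises
    ------
    ValueError
        If ``t`` lies outside the scene duration.
    """
    if not (0.0 <= t <= scene.duration):
        raise ValueError(f"t={t} outside scene duration [0, {scene.duration}]")
    A, _ = scene.affine_at(t)
    return 0.5 * (A + A.T) - np.eye(2)


def _render_dots(shape: tuple[int, int], centers: np.ndarray, radius: float) -> np.ndarray:
    """Anti-aliased coverage image of filled disks (1 inside, 0 outside).

    Per-pixel coverage is approximated analytically from the distance of
    the pixel center to the disk edge, clipped to a one-pixel transition
    band; this moves the image centroid smoothly under sub-pixel motion.
    """
    h, w = shape
    cov = np.zeros((h, w))
    pad = int(np.ceil(radius)) + 2
    for cx, cy in centers:
        x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
        y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.hypot(xx - cx, yy - cy)
        patch = np.clip(radius + 0.5 - d, 0.0, 1.0)
        cov[y0:y1, x0:x1] = np.maximum(cov[y0:y1, x0:x1], patch)
    return cov


def render_sequence(scene: SyntheticScene) -> tuple[FrameSequence, np.ndarray]:
    """Render the scene; returns (FrameSequence, ground-truth tracks).

    All stochastic rendering (pixel noise) comes from a generator seeded
    with ``scene.seed``, so identical scenes render bit-identically.

    Raises
    ------
    ValueError
        If any dot approaches the frame border (within 2 dot radii) under
        the peak deformation.
    """
    tracks = scene.true_tracks()
    h, w = scene.image_shape
    margin = 2 * scene.dot_radius
    if (
        tracks[..., 0].min() < margin
        or tracks[..., 0].max() > w - 1 - margin
        or tracks[..., 1].min() < margin
        or tracks[..., 1].max() > h - 1 - margin
    ):
        raise ValueError("dot leaves the frame under peak deformation")
    rng = np.random.default_rng(scene.seed)
    frames = np.empty((scene.n_frames, h, w))
    for k in range(scene.n_frames):
        cov = _render_dots((h, w), tracks[k], scene.dot_radius)
        img = scene.background + (scene.dot_intensity - scene.background) * cov
        if scene.blur_sigma > 0:
            img = gaussian_filter(img, scene.blur_sigma)
        if scene.noise_sigma > 0:
            img = img + rng.normal(0.0, scene.noise_sigma, size=img.shape)
        frames[k] = np.clip(img, 0.0, 1.0)
    return FrameSequence(frames=frames, fps=scene.fps), tracks


def truth_table(scene: SyntheticScene):
    """Ground-truth tracks and analytic strains as a tidy DataFrame."""
    import pandas as pd

    tracks = scene.true_tracks()
    rows = []
    for k in range(scene.n_frames):
        t = k / scene.fps
        eps = analytic_strain(scene, t)
        for d, (x, y) in enumerate(tracks[k]):
            rows.append((k, t, d, x, y, eps[0, 0], eps[1, 1], eps[0, 1]))
    return pd.DataFrame(
        rows, columns=["frame", "t_s", "dot_id", "x_px", "y_px", "Exx", "Eyy", "Exy"]
    )
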