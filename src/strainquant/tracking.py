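"""Link per-frame dot detections into labelled trajectories.

The first frame is the reference configuration; its detections (sorted
row-major) define the dot labels 0..n-1.  Each subsequent frame is matched
to the previous known positions by optimal one-to-one assignment
(Hungarian algorithm on squared displacements), which for a small grid is
cheap and immune to the swap errors greedy matching can make.  Frames with
missing detections are gap-filled by linear interpolation of the dot's
neighbouring observed positions; missing detections at the start or end of
the recording cannot be interpolated and are an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist, pdist

from .dot_imaging import DotSet


class TrackingError(ValueError):
    """Raised when detections cannot be linked into consistent tracks."""


@dataclass
class DotTracks:
    """Labelled dot trajectories.

    Attributes
    ----------
    positions : ndarray, shape (n_frames, n_dots, 2)
        Sub-pixel (x, y) position of each dot in each frame; no gaps.
    reference_frame : int
        Index of the frame defining the labels (row-major on that frame).
    """

    positions: np.ndarray
    reference_frame: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (n_frames, n_dots, 2)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain missing values after linking")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_dots(self) -> int:
        return self.positions.shape[1]

    @property
    def reference(self) -> np.ndarray:
        return self.positions[self.reference_frame]


def link_tracks(
    dotsets: Sequence[DotSet],
    expected_n: int = 9,
    max_disp: float | None = None,
) -> DotTracks:
    """Link DotSets into :class:`DotTracks` by optimal assignment.

    Parameters
    ----------
    dotsets : sequence of DotSet
        Per-frame detections; every frame needs at least one center and
        the first frame exactly ``expected_n``.
    expected_n : int
        Number of physical dots (nine for the standard grid).
    max_disp : float, optional
        Largest admissible frame-to-frame displacement in pixels.
        Defaults to 0.45 x the minimum inter-dot spacing on the reference
        frame, which rules out track swaps by construction.

    Raises
    ------
    TrackingError
        If the reference frame count is wrong, more than 30% of dots are
        unmatched in some frame, an optimal match exceeds ``max_disp``,
        or a dot is missing on the first/last frame (no extrapolation).
    """
    if len(dotsets) < 2:
        raise TrackingError("need at least two frames to track")
    ref = dotsets[0].centers
    if ref.shape[0] != expected_n:
        raise TrackingError(
            f"reference frame has {ref.shape[0]} dots, expected {expected_n}"
        )
    if any(len(ds) == 0 for ds in dotsets):
        raise TrackingError("every frame must contain at least one detection")
    if max_disp is None:
        max_disp = 0.45 * pdist(ref).min()

    n_frames = len(dotsets)
    pos = np.full((n_frames, expected_n, 2), np.nan)
    pos[0] = ref
    last_known = ref.copy()  # most recent observed position per dot

    for t in range(1, n_frames):
        det = dotsets[t].centers
        cost = cdist(last_known, det, metric="sqeuclidean")
        rows, cols = linear_sum_assignment(cost)
        disp = np.sqrt(cost[rows, cols])
        ok = disp <= max_disp
        if np.any(~ok) and det.shape[0] >= expected_n:
            raise TrackingError(
                f"frame {t}: optimal match displacement "
                f"{disp.max():.2f} px exceeds max_disp={max_disp:.2f} px"
            )
        rows, cols = rows[ok], cols[ok]
        n_missing = expected_n - rows.size
        if n_missing > 0.3 * expected_n:
            raise TrackingError(
                f"frame {t}: {n_missing}/{expected_n} dots unmatched"
            )
        pos[t, rows] = det[cols]
        last_known[rows] = det[cols]

    _fill_gaps(pos)
    return DotTracks(positions=pos, reference_frame=0)


def _fill_gaps(pos: np.ndarray) -> None:
    """Linearly interpolate interior NaN runs per dot, in place."""
    n_frames = pos.shape[0]
    t = np.arange(n_frames)
    for k in range(pos.shape[1]):
        missing = np.isnan(pos[:, k, 0])
        if not missing.any():
            continue
        if missing[0] or missing[-1]:
            raise TrackingError(
                f"dot {k}: missing detection on the first or last frame"
            )
        for d in range(2):
            pos[missing, k, d] = np.interp(
                t[missing], t[~missing], pos[~missing, k, d]
            )
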