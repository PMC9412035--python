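"""End-to-end analysis: frames -> tracks -> strains -> sample amplitudes."""

from __future__ import annotations

from typing import Literal

from .dot_imaging import FrameSequence, detect_sequence
from .tracking import DotTracks, link_tracks
from .strain_fem import StrainTrace, build_mesh, node_strain
from .cycle_analysis import (
    DEFAULT_PROMINENCE_FRAC,
    SampleStrainResult,
    find_cycles,
    sample_result,
)


def analyze_tracks(
    tracks: DotTracks,
    fps: float,
    loading_freq: float | None = None,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> tuple[SampleStrainResult, StrainTrace]:
    """Strain amplitudes from already-linked dot trajectories.

    Builds the FE mesh on the tracks' reference frame, computes the nodal
    strain trace and runs the peak analysis on the mean xx and yy series.
    """
    mesh = build_mesh(tracks.reference)
    trace = node_strain(mesh, tracks, fps=fps)
    pa_xx = find_cycles(trace.mean_xx, fps, loading_freq, prominence_frac)
    pa_yy = find_cycles(trace.mean_yy, fps, loading_freq, prominence_frac)
    return sample_result(pa_xx, pa_yy, fps, loading_freq), trace


def analyze_frames(
    seq: FrameSequence,
    loading_freq: float | None = None,
    polarity: Literal["dark-dots", "bright-dots"] = "dark-dots",
    expected_dots: int = 9,
    min_area: float = 5,
    max_area: float = 10_000,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    smooth_sigma: float = 1.5,
    roi: tuple[int, int, int, int] | None = None,
) -> tuple[SampleStrainResult, StrainTrace, DotTracks]:
    """Full pipeline on a frame sequence.

    Segments and localizes the fiducial dots in every frame, links them
    into trajectories, computes the FE strain trace and the per-sample
    amplitudes.  Returns (result, strain trace, tracks).
    """
    dotsets = detect_sequence(
        seq, polarity=polarity, min_area=min_area, max_area=max_area,
        smooth_sigma=smooth_sigma, roi=roi,
    )
    tracks = link_tracks(dotsets, expected_n=expected_dots)
    result, trace = analyze_tracks(
        tracks, seq.fps, loading_freq, prominence_frac
    )
    return result, trace, tracks
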