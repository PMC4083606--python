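"""Per-frame trajectory analysis, summaries and cross-degree comparisons.

For every trajectory frame the pipeline builds each helix's PCA frame, fits
the degree-m spline, discretises both splines at M common positions, spans
the rulings and records the interhelical distances at selected positions
together with the total ruled-surface area A. Frames are processed
independently (no state leaks between frames), so results are unaffected by
processing order.

Summaries follow common boxplot conventions: per-position five-number
summaries (true min/max whiskers, quartiles by linear interpolation between
order statistics) of d over time, the time-averaged area and its standard
deviation, and percent change of the time-averaged area between polynomial
degrees.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import HelixGeomError, ValidationError
from .spline import DEFAULT_DEGREES, compute_frame, evaluate_spline, fit_spline
from .structure_io import HelixTrace
from .surface import DEFAULT_M, build_rulings, default_positions, ruled_surface_area

__all__ = [
    "GeometryTimeSeries",
    "SummaryStats",
    "DegreeComparison",
    "analyze_trajectory",
    "summarize",
    "compare_degrees",
    "estimate_oscillation",
    "run_analysis",
]

logger = logging.getLogger("helixgeom")


@dataclass(frozen=True)
class GeometryTimeSeries:
    """Per-frame geometric quantities for one polynomial degree.

    ``distance_series`` is (frames, len(positions)) in Å; ``area_series``
    (Å²) and ``rss_series`` (Å², both helices summed) are per frame. Time
    stamps are optional metadata and never affect computation.
    """

    degree_m: int
    positions: tuple[int, ...]
    area_series: np.ndarray
    distance_series: np.ndarray
    rss_series: np.ndarray
    M: int = DEFAULT_M
    times_ns: np.ndarray | None = None
    skipped_frames: tuple[int, ...] = ()

    @property
    def n_frames(self) -> int:
        return len(self.area_series)


@dataclass(frozen=True)
class SummaryStats:
    """Boxplot five-number summaries of d per position, plus area statistics."""

    positions: tuple[int, ...]
    five_number: dict[int, tuple[float, float, float, float, float]]
    time_averaged_area: float
    area_sd: float

    def to_dict(self) -> dict:
        return {
            "positions": list(self.positions),
            "five_number": {
                str(pos): {
                    "min": v[0], "q1": v[1], "median": v[2], "q3": v[3], "max": v[4]
                }
                for pos, v in self.five_number.items()
            },
            "time_averaged_area": self.time_averaged_area,
            "area_sd": self.area_sd,
        }


@dataclass(frozen=True)
class DegreeComparison:
    """Percent change of time-averaged area relative to a reference degree."""

    reference_degree: int
    comparisons: tuple[tuple[int, float], ...]

    def to_dict(self) -> dict:
        return {
            "reference_degree": self.reference_degree,
            "percent_change": {str(m): pct for m, pct in self.comparisons},
        }


def _analyze_frame(
    pair: Sequence[HelixTrace], degree_m: int, M: int, positions: Sequence[int]
):
    trace1, trace2 = pair
    model1 = fit_spline(trace1, compute_frame(trace1), degree_m)
    model2 = fit_spline(trace2, compute_frame(trace2), degree_m)
    curve1 = evaluate_spline(model1, M)
    curve2 = evaluate_spline(model2, M)
    rulings = build_rulings(curve1, curve2)
    dists = rulings.distances[np.asarray(positions) - 1]
    area = ruled_surface_area(rulings).total_area
    rss = model1.rss + model2.rss
    return area, dists, rss, rulings.orientation_reversed


def analyze_trajectory(
    frames: Sequence[Sequence[HelixTrace]],
    degree_m: int,
    M: int = DEFAULT_M,
    positions: Sequence[int] | None = None,
    skip_bad_frames: bool = False,
    dt_ns: float | None = None,
) -> GeometryTimeSeries:
    """Run the full geometric analysis frame by frame.

    Each frame is a (helix1, helix2) trace pair. A per-frame failure aborts
    with the frame index and cause unless ``skip_bad_frames`` is set, in
    which case the frame is logged and recorded in ``skipped_frames``.
    """
    if len(frames) < 1:
        raise ValidationError("frames: need at least one frame")
    if positions is None:
        positions = default_positions(M)
    positions = tuple(int(p) for p in positions)
    for p in positions:
        if not 1 <= p <= M:
            raise ValidationError(f"position {p} out of range [1, {M}]")

    areas, dists, rsss, kept, skipped = [], [], [], [], []
    for t, pair in enumerate(frames):
        try:
            area, d, rss, reversed_ = _analyze_frame(pair, degree_m, M, positions)
        except HelixGeomError as exc:
            if skip_bad_frames:
                logger.warning("frame %d skipped: %s", t, exc)
                skipped.append(t)
                continue
            raise HelixGeomError(f"frame {t}: {exc}") from exc
        logger.debug(
            "frame %d: degree=%d M=%d orientation_reversed=%s area=%.6g",
            t, degree_m, M, reversed_, area,
        )
        areas.append(area)
        dists.append(d)
        rsss.append(rss)
        kept.append(t)
    if not areas:
        raise HelixGeomError("all frames failed analysis")
    times = None if dt_ns is None else np.asarray(kept, dtype=float) * dt_ns
    return GeometryTimeSeries(
        degree_m=degree_m,
        positions=positions,
        area_series=np.asarray(areas),
        distance_series=np.asarray(dists),
        rss_series=np.asarray(rsss),
        M=M,
        times_ns=times,
        skipped_frames=tuple(skipped),
    )


def summarize(series: GeometryTimeSeries) -> SummaryStats:
    """Five-number summary of d per position over time, plus area mean/sd.

    Whiskers are the true extremes; quartiles use linear interpolation
    between order statistics. area_sd is the sample standard deviation
    (ddof=1; zero for a single frame).
    """
    five = {}
    for j, pos in enumerate(series.positions):
        col = series.distance_series[:, j]
        q = np.percentile(col, [0, 25, 50, 75, 100])
        five[pos] = tuple(float(v) for v in q)
    areas = series.area_series
    sd = float(areas.std(ddof=1)) if len(areas) > 1 else 0.0
    return SummaryStats(
        positions=series.positions,
        five_number=five,
        time_averaged_area=float(areas.mean()),
        area_sd=sd,
    )


def compare_degrees(
    summaries: Mapping[int, SummaryStats], reference_degree: int
) -> DegreeComparison:
    """Percent change of time-averaged area of each degree vs the reference."""
    if reference_degree not in summaries:
        raise ValidationError(
            f"reference degree {reference_degree} not among {sorted(summaries)}"
        )
    ref = summaries[reference_degree].time_averaged_area
    comps = tuple(
        (m, 100.0 * (s.time_averaged_area - ref) / ref)
        for m, s in sorted(summaries.items())
    )
    return DegreeComparison(reference_degree=reference_degree, comparisons=comps)


def estimate_oscillation(values: Sequence[float]) -> tuple[float, float, float]:
    """Estimate (amplitude, period, mean) of a sinusoidal series by FFT.

    The period is reported in frames from the dominant non-DC Fourier mode;
    intended as a diagnostic for breathing-type trajectories.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValidationError("values: need at least 4 samples")
    mean = float(x.mean())
    spec = np.fft.rfft(x - mean)
    k = int(np.argmax(np.abs(spec[1:]))) + 1
    amplitude = 2.0 * float(np.abs(spec[k])) / len(x)
    period = len(x) / k
    return amplitude, float(period), mean


# ---------------------------------------------------------------------------
# batch driver used by the CLI

_UNIT_SCALE = {"angstrom": (1.0, 1.0), "nm": (0.1, 0.01)}  # (distance, area)


def _timeseries_frame(series: GeometryTimeSeries, dscale: float, ascale: float):
    data = {"frame": np.arange(series.n_frames)}
    if series.times_ns is not None:
        data["time_ns"] = series.times_ns
    data["area"] = series.area_series * ascale
    for j, pos in enumerate(series.positions):
        data[f"d_pos{pos}"] = series.distance_series[:, j] * dscale
    data["rss"] = series.rss_series * dscale**2
    return pd.DataFrame(data)


def run_analysis(
    frames: Sequence[Sequence[HelixTrace]],
    degrees: Sequence[int] = DEFAULT_DEGREES,
    M: int = DEFAULT_M,
    positions: Sequence[int] | None = None,
    out_dir: str | Path | None = None,
    units: str = "angstrom",
    reference_degree: int | None = None,
    skip_bad_frames: bool = False,
    dt_ns: float | None = None,
) -> tuple[dict[int, GeometryTimeSeries], dict[int, SummaryStats], DegreeComparison]:
    """Analyse one trajectory for several polynomial degrees and write outputs.

    Writes, when ``out_dir`` is given: ``timeseries_m{m}.csv`` (6 significant
    digits), ``timeseries_m{m}.json`` (full precision), ``summary_m{m}.json``
    and ``degree_comparison.json``. In-memory results are always in Å/Å²;
    the unit switch only rescales the written files.
    """
    if units not in _UNIT_SCALE:
        raise ValidationError(f"units: 'angstrom' or 'nm', got {units!r}")
    dscale, ascale = _UNIT_SCALE[units]
    all_series: dict[int, GeometryTimeSeries] = {}
    all_summaries: dict[int, SummaryStats] = {}
    for m in degrees:
        series = analyze_trajectory(
            frames, m, M=M, positions=positions,
            skip_bad_frames=skip_bad_frames, dt_ns=dt_ns,
        )
        all_series[m] = series
        all_summaries[m] = summarize(series)
    ref = reference_degree if reference_degree is not None else min(degrees)
    comparison = compare_degrees(all_summaries, ref)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for m, series in all_series.items():
            df = _timeseries_frame(series, dscale, ascale)
            df.to_csv(out_dir / f"timeseries_m{m}.csv", index=False,
                      float_format="%.6g")
            (out_dir / f"timeseries_m{m}.json").write_text(
                df.to_json(orient="columns", double_precision=15)
            )
            summary = all_summaries[m].to_dict()
            summary["units"] = units
            summary["M"] = series.M
            summary["degree_m"] = m
            summary["knots_K"] = 0
            if dscale != 1.0:
                summary["time_averaged_area"] *= ascale
                summary["area_sd"] *= ascale
                summary["five_number"] = {
                    pos: {k: v * dscale for k, v in fv.items()}
                    for pos, fv in summary["five_number"].items()
                }
            (out_dir / f"summary_m{m}.json").write_text(
                json.dumps(summary, indent=2)
            )
        (out_dir / "degree_comparison.json").write_text(
            json.dumps(comparison.to_dict(), indent=2)
        )
    return all_series, all_summaries, comparison
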