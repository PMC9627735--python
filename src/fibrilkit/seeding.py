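"""Highly seeded kinetics: initial slopes and relative elongation rates.

With abundant preformed seeds the early reaction is dominated by fibril-end
elongation, dM/dt ~ 2 k_plus m(0) P(0), so the initial slope of a
normalized seeded trace is directly proportional to k_plus.  Ratios of
slopes across conditions with the same seed preparation therefore estimate
relative elongation rates without knowing the seed number concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tht import AggregationTrace, _baseline_plateau, normalize_and_average, normalize_trace

__all__ = [
    "SeededSlopeResult",
    "initial_slope",
    "relative_elongation_rate",
    "seeded_slope_series",
]

DEFAULT_WINDOW_S = 20.0 * 60.0


@dataclass
class SeededSlopeResult:
    """Initial slope of one seeded trace (normalized units per second)."""

    slope: float
    slope_stderr: float
    window: tuple[float, float]
    r2: float
    n_points: int
    relative_k_plus: float | None = None
    relative_k_plus_stderr: float | None = None

    def summary(self) -> str:
        rel = (
            f"\n  relative k_plus : {self.relative_k_plus:.4f}"
            if self.relative_k_plus is not None
            else ""
        )
        return (
            "Seeded initial-slope fit\n"
            f"  slope  : {self.slope:.5g} +/- {self.slope_stderr:.2g} s^-1 "
            f"(normalized units)\n"
            f"  window : {self.window[0]:.0f}-{self.window[1]:.0f} s "
            f"({self.n_points} points)\n"
            f"  R2     : {self.r2:.5f}{rel}"
        )


def initial_slope(
    trace: AggregationTrace,
    window: float = DEFAULT_WINDOW_S,
    completion_cutoff: float = 0.20,
    normalize: bool = True,
    reference_span: tuple[float, float] | None = None,
) -> SeededSlopeResult:
    """Ordinary least-squares initial slope of a highly seeded trace.

    The fit uses the first ``window`` seconds of the normalized trace,
    excluding points beyond ``completion_cutoff`` (20%) completion so the
    early-time linear regime is preserved.  Requires a seeded-assay trace
    with at least 5 points in the window.

    ``reference_span`` = (baseline, amplitude) normalizes with a shared
    fluorescence calibration (e.g. from the uninhibited condition on the
    same plate) instead of the trace's own plateau — necessary when a
    strongly inhibited trace does not plateau within the observation
    window.
    """
    if trace.condition.assay != "seeded_tht":
        raise ValueError("initial_slope expects a seeded_tht trace")
    if reference_span is not None:
        base, span = reference_span
        if span <= 0:
            raise ValueError("reference amplitude must be positive")
        own_base = float(np.mean(trace.y[:3]))
        tr = AggregationTrace(
            t=trace.t, y=(trace.y - own_base) / span, condition=trace.condition
        )
    elif normalize:
        tr = normalize_trace(trace)
    else:
        tr = trace
    t0 = tr.t[0]
    sel = (tr.t - t0) <= window
    sel &= tr.y <= completion_cutoff
    n = int(np.sum(sel))
    if n < 5:
        raise ValueError(
            f"only {n} usable points in the first {window:.0f} s; need >= 5"
        )
    t, y = tr.t[sel] - t0, tr.y[sel]
    lin = stats.linregress(t, y)
    slope, stderr = float(lin.slope), float(lin.stderr)
    if slope < 0 and abs(slope) > 2 * stderr:
        warnings.warn(
            "significantly negative initial slope: no detectable seeded growth",
            RuntimeWarning,
        )
    return SeededSlopeResult(
        slope=max(slope, 0.0),
        slope_stderr=stderr,
        window=(float(t0), float(t0 + t[-1])),
        r2=float(lin.rvalue**2),
        n_points=n,
    )


def relative_elongation_rate(
    sample: SeededSlopeResult, reference: SeededSlopeResult
) -> SeededSlopeResult:
    """Relative elongation rate: sample slope / reference (0% inhibitor) slope.

    Valid when both traces share the seed preparation and substrate
    concentration.  The uncertainty on the ratio is propagated from the
    two linear-fit standard errors; the result is returned as a copy of
    ``sample`` with ``relative_k_plus`` filled in.
    """
    if reference.slope <= 0 or (
        reference.slope_stderr > 0 and reference.slope < 3 * reference.slope_stderr
    ):
        raise ValueError("reference slope is zero or indistinguishable from noise")
    ratio = sample.slope / reference.slope
    rel_err = np.sqrt(
        (sample.slope_stderr / max(sample.slope, 1e-300)) ** 2
        + (reference.slope_stderr / reference.slope) ** 2
    )
    return SeededSlopeResult(
        slope=sample.slope,
        slope_stderr=sample.slope_stderr,
        window=sample.window,
        r2=sample.r2,
        n_points=sample.n_points,
        relative_k_plus=float(ratio),
        relative_k_plus_stderr=float(ratio * rel_err),
    )


def seeded_slope_series(
    traces: list[AggregationTrace],
    window: float = DEFAULT_WINDOW_S,
    completion_cutoff: float = 0.20,
) -> dict[float, SeededSlopeResult]:
    """Initial slopes and relative elongation rates across a seeded dose series.

    Replicates are averaged per inhibitor ratio; every trace is normalized
    with the shared fluorescence amplitude of the 0% (uninhibited)
    condition, and slopes are expressed relative to that condition.
    The dataset must include a 0% ratio.
    """
    by_ratio: dict[float, list[AggregationTrace]] = {}
    for tr in traces:
        by_ratio.setdefault(tr.condition.ratio_percent, []).append(tr)
    if 0.0 not in by_ratio:
        raise ValueError("seeded series must include the 0% (uninhibited) condition")
    raw_avg = {r: normalize_and_average(v) for r, v in by_ratio.items()}
    # recover the shared amplitude from the raw 0% replicates (averaging
    # normalizes, so take baseline/plateau from one raw replicate)
    base0, plat0 = _baseline_plateau(by_ratio[0.0][0].y)
    span0 = plat0 - base0
    rescaled_by_ratio: dict[float, AggregationTrace] = {}
    for r, avg in raw_avg.items():
        # averaged traces are already normalized by their own plateau; undo
        # that with the ratio of their raw span to the 0% span
        own_base, own_plat = _baseline_plateau(by_ratio[r][0].y)
        scale = (own_plat - own_base) / span0
        rescaled_by_ratio[r] = AggregationTrace(
            t=avg.t, y=avg.y * scale, condition=avg.condition
        )
    # each trace keeps its own completion cutoff: truncating every condition
    # at the same converted fraction equalises the monomer-depletion bias of
    # the linear fit, so it cancels in slope ratios
    results = {
        r: initial_slope(tr, window, completion_cutoff, normalize=False)
        for r, tr in rescaled_by_ratio.items()
    }
    ref = results[0.0]
    return {
        r: (relative_elongation_rate(res, ref) if r != 0.0 else res)
        for r, res in results.items()
    }
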