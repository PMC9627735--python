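"""Analysis of aggregation traces from plate-reader assays.

Covers normalisation and replicate averaging of thioflavin-T (ThT)
fluorescence traces, sigmoidal descriptors (half time tau_1/2 and maximal
growth rate r_max), global fitting of dose series to the integrated rate
law with a single free microscopic rate constant, dose-response summaries,
and the relative-aggregation readout for amorphous (turbidity) assays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np
from scipy import optimize, stats

from .kinetics import KineticParameters, fibril_mass_closed_form

__all__ = [
    "TraceCondition",
    "AggregationTrace",
    "SigmoidFit",
    "SigmoidTransitionModel",
    "GlobalFitResult",
    "GlobalRateLawModel",
    "DoseResponseSummary",
    "normalize_trace",
    "normalize_and_average",
    "fit_sigmoid",
    "dose_response_summary",
    "global_fit",
    "relative_amorphous_aggregation",
    "FREE_PARAMETERS",
]

ASSAY_KINDS = ("tht", "seeded_tht", "amorphous")

#: Admissible choices for the single free rate constant of a global fit.
#: The combined constants sqrt(k_plus*k_n) and sqrt(k_plus*k_2) are what the
#: unseeded rate law actually identifies; k_n / k_2 / k_plus act through them.
FREE_PARAMETERS = ("k_n", "k_2", "k_plus", "sqrt_k_plus_k_n", "sqrt_k_plus_k_2")


@dataclass(frozen=True)
class TraceCondition:
    """Experimental condition metadata attached to one trace."""

    assay: str = "tht"
    substrate_M: float = 3e-6
    inhibitor: str = "none"
    ratio_percent: float = 0.0
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.assay not in ASSAY_KINDS:
            raise ValueError(f"assay must be one of {ASSAY_KINDS}, got {self.assay!r}")

    def key(self) -> tuple:
        """Condition identity ignoring the replicate id."""
        return (self.assay, self.substrate_M, self.inhibitor, self.ratio_percent)


@dataclass
class AggregationTrace:
    """One time series of a fibril-mass proxy signal.

    ``t`` in seconds, strictly increasing; ``y`` is ThT fluorescence (a.u.)
    or absorbance at 360 nm for amorphous assays.
    """

    t: np.ndarray
    y: np.ndarray
    condition: TraceCondition = field(default_factory=TraceCondition)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape or self.t.ndim != 1:
            raise ValueError("t and y must be 1-D arrays of equal length")
        if len(self.t) < 2 or np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("signal contains non-finite values")


def _baseline_plateau(
    y: np.ndarray, baseline_fraction: float = 0.05, plateau_fraction: float = 0.10
) -> tuple[float, float]:
    """Baseline and plateau levels of a rising trace.

    Plateau = mean of the final ``plateau_fraction`` of points; baseline =
    mean of the points before ``baseline_fraction`` completion (with the
    first few points as fallback when the rise starts immediately).
    """
    n = len(y)
    n_plat = max(2, int(round(plateau_fraction * n)))
    plateau = float(np.mean(y[-n_plat:]))
    y0 = float(np.min(y[: max(3, n // 10)]))
    span = plateau - y0
    if span <= 0:
        return y0, plateau
    completion = (y - y0) / span
    pre = np.nonzero(completion[: n - n_plat] < baseline_fraction)[0]
    if len(pre) >= 2:
        baseline = float(np.mean(y[pre]))
    else:
        baseline = float(np.mean(y[:3]))
    return baseline, plateau


def normalize_trace(
    trace: AggregationTrace,
    baseline_fraction: float = 0.05,
    plateau_fraction: float = 0.10,
) -> AggregationTrace:
    """Rescale a trace affinely so baseline -> 0 and plateau -> 1."""
    baseline, plateau = _baseline_plateau(trace.y, baseline_fraction, plateau_fraction)
    span = plateau - baseline
    if span <= 0:
        raise ValueError("trace has no rise above baseline; cannot normalize")
    return AggregationTrace(
        t=trace.t.copy(), y=(trace.y - baseline) / span, condition=trace.condition
    )


def normalize_and_average(
    traces: list[AggregationTrace],
    baseline_fraction: float = 0.05,
    plateau_fraction: float = 0.10,
    disagreement_sd: float = 0.15,
) -> AggregationTrace:
    """Normalize replicate traces and average them pointwise.

    Replicates must share the experimental condition (up to replicate id).
    Averaging is performed on the intersection of the time ranges with
    linear interpolation onto the first replicate's grid; no smoothing is
    applied.  Warns when replicates disagree (pointwise SD > 0.15 in
    normalized units).
    """
    if not traces:
        raise ValueError("need at least one trace")
    keys = {tr.condition.key() for tr in traces}
    if len(keys) > 1:
        raise ValueError(f"cannot average across mixed conditions: {sorted(keys)}")
    normed = [
        normalize_trace(tr, baseline_fraction, plateau_fraction) for tr in traces
    ]
    t_lo = max(tr.t[0] for tr in normed)
    t_hi = min(tr.t[-1] for tr in normed)
    if t_hi <= t_lo:
        raise ValueError("replicate time ranges do not overlap")
    grid = normed[0].t[(normed[0].t >= t_lo) & (normed[0].t <= t_hi)]
    ys = np.vstack([np.interp(grid, tr.t, tr.y) for tr in normed])
    if len(normed) > 1 and float(np.max(np.std(ys, axis=0, ddof=1))) > disagreement_sd:
        warnings.warn(
            "replicates disagree (pointwise SD exceeds "
            f"{disagreement_sd} normalized units)",
            RuntimeWarning,
        )
    cond = replace(traces[0].condition, replicate=0)
    return AggregationTrace(t=grid, y=ys.mean(axis=0), condition=cond)


# ---------------------------------------------------------------------------
# sigmoidal descriptor fit
# ---------------------------------------------------------------------------


def sigmoid(t, F0, A, r_max, tau_half):
    """F(t) = F0 + A / (1 + exp[r_max (tau_half - t)])."""
    return F0 + A / (1.0 + np.exp(np.clip(r_max * (tau_half - t), -700, 700)))


@dataclass
class SigmoidFit:
    """Results of a sigmoidal descriptor fit.

    ``r_max`` (s^-1) is the growth-rate parameter of the logistic; the curve
    passes through F0 + A/2 at t = tau_half (s) by construction.
    """

    F0: float
    A: float
    r_max: float
    tau_half: float
    residual_sse: float
    n_points: int = 0

    def predict(self, t: np.ndarray) -> np.ndarray:
        return sigmoid(np.asarray(t, dtype=float), self.F0, self.A, self.r_max, self.tau_half)

    def summary(self) -> str:
        h = 3600.0
        return (
            "Sigmoidal transition fit\n"
            f"  F0 (base value)      : {self.F0:.6g}\n"
            f"  A (amplitude)        : {self.A:.6g}\n"
            f"  r_max (growth rate)  : {self.r_max:.6g} s^-1  ({self.r_max * h:.4g} h^-1)\n"
            f"  tau_1/2 (half time)  : {self.tau_half:.6g} s  ({self.tau_half / h:.4g} h)\n"
            f"  SSE ({self.n_points} points)   : {self.residual_sse:.6g}"
        )


class SigmoidTransitionModel:
    """Sigmoidal model of one aggregation trace.

    Fits F(t) = F0 + A/(1 + exp[r_max(tau_half - t)]) by bounded
    least squares with data-driven starting values, falling back to a small
    deterministic multi-start if the first attempt does not converge.
    """

    def __init__(self, trace: AggregationTrace, min_snr: float = 5.0):
        self.trace = trace
        self.min_snr = min_snr

    def fit(self) -> SigmoidFit:
        t, y = self.trace.t, self.trace.y
        n = len(t)
        baseline, plateau = _baseline_plateau(y)
        span = plateau - baseline
        noise_sd = float(np.std(np.diff(y[: max(5, n // 10)]))) / np.sqrt(2.0)
        if span <= 0 or (noise_sd > 0 and span < self.min_snr * noise_sd):
            raise ValueError(
                "no transition: plateau does not rise above baseline noise"
            )
        # starting values: midpoint crossing and midpoint slope A*r/4
        yc = (y - baseline) / span
        tau0 = float(np.interp(0.5, np.clip(yc, 0, 1), t))
        dy = np.gradient(y, t)
        r0 = max(4.0 * float(np.max(dy)) / span, 1e-12)

        model = lmfit.Model(sigmoid)
        params = model.make_params(
            F0=dict(value=baseline),
            A=dict(value=span, min=1e-12 * max(abs(span), 1.0)),
            r_max=dict(value=r0, min=1e-12),
            tau_half=dict(value=tau0, min=t[0] - (t[-1] - t[0]), max=2 * t[-1]),
        )
        best = None
        starts = [(r0, tau0)] + [
            (r0 * fr, tau0 * ft)
            for fr in (0.3, 3.0)
            for ft in (0.7, 1.0, 1.3)
        ]
        for r_init, tau_init in starts:
            params["r_max"].value = r_init
            params["tau_half"].value = max(tau_init, t[0])
            try:
                res = model.fit(y, params, t=t)
            except Exception:
                continue
            if best is None or res.chisqr < best.chisqr:
                best = res
            if best.chisqr <= (noise_sd**2) * n * 4 and best.success:
                break
        if best is None or not best.success:
            raise RuntimeError(
                f"sigmoid fit failed after {len(starts)} starts; "
                "check that the trace shows a single sigmoidal transition"
            )
        v = best.params.valuesdict()
        return SigmoidFit(
            F0=v["F0"],
            A=v["A"],
            r_max=v["r_max"],
            tau_half=v["tau_half"],
            residual_sse=float(best.chisqr),
            n_points=n,
        )


def fit_sigmoid(trace: AggregationTrace) -> SigmoidFit:
    """Fit the sigmoidal descriptor to one trace (see SigmoidTransitionModel)."""
    return SigmoidTransitionModel(trace).fit()


# ---------------------------------------------------------------------------
# dose-response summaries
# ---------------------------------------------------------------------------


@dataclass
class DoseResponseSummary:
    """Trends of tau_1/2 and r_max across inhibitor molar ratios.

    tau_1/2 is summarised by a straight line in ratio, r_max by a
    mono-exponential decline r_max(ratio) = r0 * exp(-ratio / c0).
    """

    tau_slope: float
    tau_intercept: float
    tau_r2: float
    rmax_r0: float
    rmax_c0: float
    rmax_r2: float

    def summary(self) -> str:
        return (
            "Dose-response summary\n"
            f"  tau_1/2 vs ratio : slope {self.tau_slope:.6g} s/%, "
            f"intercept {self.tau_intercept:.6g} s, R2 {self.tau_r2:.4f}\n"
            f"  r_max vs ratio   : r0 {self.rmax_r0:.6g} s^-1, "
            f"decay scale {self.rmax_c0:.6g} %, R2 {self.rmax_r2:.4f}"
        )


def dose_response_summary(fits: dict[float, SigmoidFit]) -> DoseResponseSummary:
    """Summarise sigmoid fits across inhibitor ratios.

    Requires at least three ratios including the uninhibited (0) condition.
    """
    ratios = np.array(sorted(fits), dtype=float)
    if len(ratios) < 3 or 0.0 not in ratios:
        raise ValueError("need >= 3 inhibitor ratios including 0")
    tau = np.array([fits[r].tau_half for r in ratios])
    rmax = np.array([fits[r].r_max for r in ratios])

    lin = stats.linregress(ratios, tau)

    def expdecay(x, r0, c0):
        return r0 * np.exp(-x / c0)

    model = lmfit.Model(expdecay)
    c0_init = max(ratios[-1], 1.0)
    if rmax[-1] > 0 and rmax[0] > rmax[-1]:
        c0_init = ratios[-1] / max(np.log(rmax[0] / rmax[-1]), 1e-6)
    res = model.fit(
        rmax,
        model.make_params(
            r0=dict(value=float(rmax[0]), min=1e-15),
            c0=dict(value=float(c0_init), min=1e-9),
        ),
        x=ratios,
    )
    ss_tot = float(np.sum((rmax - rmax.mean()) ** 2))
    rmax_r2 = 1.0 - float(res.chisqr) / ss_tot if ss_tot > 0 else 1.0
    return DoseResponseSummary(
        tau_slope=float(lin.slope),
        tau_intercept=float(lin.intercept),
        tau_r2=float(lin.rvalue**2),
        rmax_r0=float(res.params["r0"].value),
        rmax_c0=float(res.params["c0"].value),
        rmax_r2=rmax_r2,
    )


# ---------------------------------------------------------------------------
# global rate-law fitting with a single free microscopic rate constant
# ---------------------------------------------------------------------------


def _lam2_kap2_scales(free_parameter: str, s: float) -> tuple[float, float]:
    # how a multiplicative change s of the free constant propagates to the
    # combined rates lambda^2 (k_plus*k_n) and kappa^2 (k_plus*k_2)
    if free_parameter in ("k_n", "sqrt_k_plus_k_n"):
        f = s if free_parameter == "k_n" else s**2
        return f, 1.0
    if free_parameter in ("k_2", "sqrt_k_plus_k_2"):
        f = s if free_parameter == "k_2" else s**2
        return 1.0, f
    if free_parameter == "k_plus":
        return s, s
    raise ValueError(f"free_parameter must be one of {FREE_PARAMETERS}")


@dataclass
class GlobalFitResult:
    """Outcome of a multi-trace rate-law fit with one free rate constant.

    ``per_condition_values`` maps inhibitor ratio (percent) to the fitted
    value of the free constant in that condition; ``per_condition_scale``
    holds the same information as the multiplicative factor relative to the
    uninhibited baseline.  ``chi2`` is the mean over traces of
    SSE/(N - p) on normalized traces — comparable across free-parameter
    choices within one dataset.
    """

    free_parameter: str
    baseline_params: KineticParameters
    per_condition_values: dict[float, float]
    per_condition_scale: dict[float, float]
    chi2: float
    n_traces: int
    baseline_sse: float = 0.0

    def summary(self) -> str:
        lines = [
            f"Global rate-law fit  (free parameter: {self.free_parameter})",
            f"  traces: {self.n_traces}   chi2: {self.chi2:.6g}",
            "  baseline (0%): "
            f"k_n={self.baseline_params.k_n:.4g}, "
            f"k_plus={self.baseline_params.k_plus:.4g}, "
            f"k_2={self.baseline_params.k_2:.4g} "
            f"(m0={self.baseline_params.m0:.3g} M)",
        ]
        for ratio in sorted(self.per_condition_values):
            lines.append(
                f"  ratio {ratio:6.1f}%: {self.free_parameter} = "
                f"{self.per_condition_values[ratio]:.6g}"
                f"   (x{self.per_condition_scale[ratio]:.4f} of baseline)"
            )
        return "\n".join(lines)


class GlobalRateLawModel:
    """Global fit of an unseeded dose series to the integrated rate law.

    The uninhibited (0% ratio) traces pin down the baseline combined rate
    constants sqrt(k_plus*k_n) and sqrt(k_plus*k_2) — the only combinations
    the unseeded rate law identifies.  Each inhibited condition is then
    refitted with a single free microscopic rate constant (k_n, k_2 or
    k_plus, or a combined constant), all others held at baseline.  The chi2
    of the resulting global fit discriminates which microscopic step the
    inhibitor acts on.

    Parameters
    ----------
    traces : list of AggregationTrace
        Normalized (or normalizable) unseeded ThT traces spanning inhibitor
        ratios; must include ratio 0.
    free_parameter : str
        One of ``FREE_PARAMETERS``.
    k_plus_ref : float
        Nominal elongation rate constant (M^-1 s^-1) used to convert
        combined rates into individual constants for reporting.
    """

    def __init__(
        self,
        traces: list[AggregationTrace],
        free_parameter: str = "k_2",
        k_plus_ref: float = 3e6,
        n_starts: int = 16,
        normalize: bool = True,
        seed: int = 0,
    ):
        if free_parameter not in FREE_PARAMETERS:
            raise ValueError(f"free_parameter must be one of {FREE_PARAMETERS}")
        if not traces:
            raise ValueError("no traces given")
        m0s = {tr.condition.substrate_M for tr in traces}
        if len(m0s) > 1:
            raise ValueError("all traces must share the substrate concentration m0")
        if not any(tr.condition.ratio_percent == 0 for tr in traces):
            raise ValueError("dataset must include a 0% (uninhibited) condition")
        self.free_parameter = free_parameter
        self.m0 = m0s.pop()
        self.k_plus_ref = k_plus_ref
        self.n_starts = n_starts
        self.seed = seed
        self.traces = [normalize_trace(tr) if normalize else tr for tr in traces]

    # -- model evaluation ---------------------------------------------------

    def _params_from_combined(self, lam2_prod: float, kap2_prod: float) -> KineticParameters:
        # lam2_prod = k_plus*k_n, kap2_prod = k_plus*k_2
        return KineticParameters(
            k_n=lam2_prod / self.k_plus_ref,
            k_plus=self.k_plus_ref,
            k_2=kap2_prod / self.k_plus_ref,
            m0=self.m0,
        )

    def _predict(self, lam2_prod, kap2_prod, t):
        return fibril_mass_closed_form(
            self._params_from_combined(lam2_prod, kap2_prod), t
        )

    # -- baseline fit -------------------------------------------------------

    def _fit_baseline(self) -> tuple[float, float, float, int]:
        traces0 = [tr for tr in self.traces if tr.condition.ratio_percent == 0]
        rng = np.random.default_rng(self.seed)

        def resid(logx):
            lam2, kap2 = 10.0 ** logx
            r = []
            for tr in traces0:
                r.append(self._predict(lam2, kap2, tr.t) - tr.y)
            return np.concatenate(r)

        # initial guess from the half time of the first baseline trace:
        # kappa ~ 4 / tau_half is a serviceable order-of-magnitude start
        tau0 = float(np.interp(0.5, np.clip(traces0[0].y, 0, 1), traces0[0].t))
        kap_guess = 4.0 / max(tau0, 1.0)
        kap2_guess = kap_guess**2 / (2.0 * self.m0**3)
        lam2_guess = kap2_guess * self.m0 * 1e-2  # lambda/kappa ~ 0.1
        x0 = np.log10([lam2_guess, kap2_guess])
        lo, hi = x0 - 4.0, x0 + 4.0
        best = None
        for i in range(self.n_starts):
            xi = x0 if i == 0 else rng.uniform(lo, hi)
            try:
                sol = optimize.least_squares(
                    resid, xi, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("baseline rate-law fit did not converge from any start")
        lam2, kap2 = 10.0 ** best.x
        sse = float(2.0 * best.cost)
        n_pts = sum(len(tr.t) for tr in traces0)
        return lam2, kap2, sse, n_pts

    # -- per-condition single-free-constant fits ----------------------------

    def _fit_condition(self, traces, lam2_0, kap2_0) -> tuple[float, float]:
        def resid(logs):
            fl, fk = _lam2_kap2_scales(self.free_parameter, 10.0 ** logs[0])
            r = []
            for tr in traces:
                r.append(self._predict(lam2_0 * fl, kap2_0 * fk, tr.t) - tr.y)
            return np.concatenate(r)

        best = None
        for s0 in (0.0, -1.0, -2.0, 1.0):
            sol = optimize.least_squares(
                resid, [s0], bounds=([-6.0], [6.0]), method="trf",
                xtol=1e-12, ftol=1e-12,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        return 10.0 ** best.x[0], float(2.0 * best.cost)

    def fit(self) -> GlobalFitResult:
        lam2_0, kap2_0, sse0, n0 = self._fit_baseline()
        baseline = self._params_from_combined(lam2_0, kap2_0)
        baseline_value = self._constant_value(baseline, 1.0)

        by_ratio: dict[float, list[AggregationTrace]] = {}
        for tr in self.traces:
            r = tr.condition.ratio_percent
            if r != 0:
                by_ratio.setdefault(r, []).append(tr)

        chi2_terms = [sse0 / max(n0 - 2, 1)]
        values: dict[float, float] = {}
        scales: dict[float, float] = {}
        for ratio, trs in sorted(by_ratio.items()):
            s, sse = self._fit_condition(trs, lam2_0, kap2_0)
            n_pts = sum(len(tr.t) for tr in trs)
            chi2_terms.append(sse / max(n_pts - 1, 1))
            scales[ratio] = float(s)
            values[ratio] = self._constant_value(baseline, s)
        return GlobalFitResult(
            free_parameter=self.free_parameter,
            baseline_params=baseline,
            per_condition_values=values,
            per_condition_scale=scales,
            chi2=float(np.mean(chi2_terms)),
            n_traces=len(self.traces),
            baseline_sse=sse0,
        )

    def _constant_value(self, baseline: KineticParameters, scale: float) -> float:
        fp = self.free_parameter
        if fp == "k_n":
            return baseline.k_n * scale
        if fp == "k_2":
            return baseline.k_2 * scale
        if fp == "k_plus":
            return baseline.k_plus * scale
        if fp == "sqrt_k_plus_k_n":
            return float(np.sqrt(baseline.k_plus * baseline.k_n)) * scale
        return float(np.sqrt(baseline.k_plus * baseline.k_2)) * scale


def global_fit(
    traces: list[AggregationTrace],
    free_parameter: str = "k_2",
    **kwargs,
) -> GlobalFitResult:
    """Globally fit a dose series with one free microscopic rate constant."""
    return GlobalRateLawModel(traces, free_parameter, **kwargs).fit()


# ---------------------------------------------------------------------------
# amorphous (turbidity) aggregation
# ---------------------------------------------------------------------------


def relative_amorphous_aggregation(
    sample: AggregationTrace, control: AggregationTrace
) -> float:
    """Percent aggregation of a sample relative to an uninhibited control.

    Both traces must be amorphous-assay (absorbance 360 nm) recordings at
    the same substrate concentration.  Returns
    100 * rise(sample) / rise(control) where rise = plateau - baseline,
    plateau = mean of the final 10% of points.
    """
    for tr, name in ((sample, "sample"), (control, "control")):
        if tr.condition.assay != "amorphous":
            raise ValueError(f"{name} trace is not an amorphous-assay recording")
    if sample.condition.substrate_M != control.condition.substrate_M:
        raise ValueError("sample and control substrate concentrations differ")

    def rise(tr: AggregationTrace) -> float:
        n = len(tr.y)
        base = float(np.mean(tr.y[: max(3, int(0.05 * n))]))
        plat = float(np.mean(tr.y[-max(2, int(0.10 * n)):]))
        return plat - base

    rise_c = rise(control)
    noise = float(np.std(np.diff(control.y[: max(5, len(control.y) // 10)])))
    if rise_c <= max(5.0 * noise, 0.0) or rise_c <= 0:
        raise ValueError("control trace shows no rise; relative aggregation undefined")
    return 100.0 * rise(sample) / rise_c
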