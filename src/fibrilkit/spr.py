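"""Surface plasmon resonance (SPR) binding-kinetics analysis.

Dissociation phases of a concentration series are fitted globally to a
biexponential decay with shared fast/slow rate constants (k_d1 >= k_d2)
and fast-phase fraction x; association phases are fitted per concentration
to a monoexponential approach with observed rate k_obs.  The association
rate constant k_a comes from linear regression of k_obs on analyte
concentration (k_obs = c k_a + k_d); the kinetic dissociation constant is
K_D = k_d2 / k_a, with the slow phase taken as the specific interaction.
A 1:1 Langmuir (hyperbolic) fit of the maximum response versus
concentration gives the steady-state K_D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy import stats

__all__ = [
    "Sensorgram",
    "DissociationFit",
    "AssociationFit",
    "AffinityResult",
    "DissociationModel",
    "AssociationModel",
    "SteadyStateAffinityModel",
    "fit_dissociation_global",
    "fit_association",
    "estimate_affinity_kinetic",
    "estimate_affinity_steady_state",
]


@dataclass
class Sensorgram:
    """SPR response versus time for one analyte concentration.

    ``t_inject_end`` marks the start of the dissociation phase (t1);
    ``masked_intervals`` lists (start, stop) spans excluded from all fits
    (buffer spikes).  Responses are assumed reference-subtracted and
    baseline-zeroed.
    """

    t: np.ndarray
    R: np.ndarray
    c: float
    t_inject_end: float
    masked_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.t.shape != self.R.shape or self.t.ndim != 1:
            raise ValueError("t and R must be 1-D arrays of equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not self.t[0] <= self.t_inject_end <= self.t[-1]:
            raise ValueError("t_inject_end must lie within the time range")

    def _unmasked(self) -> np.ndarray:
        keep = np.ones(len(self.t), dtype=bool)
        for a, b in self.masked_intervals:
            keep &= ~((self.t >= a) & (self.t <= b))
        return keep

    def association_window(self) -> tuple[np.ndarray, np.ndarray]:
        """Unmasked (t, R) of the association phase, t relative to injection."""
        sel = (self.t <= self.t_inject_end) & self._unmasked()
        return self.t[sel] - self.t[0], self.R[sel]

    def dissociation_window(self) -> tuple[np.ndarray, np.ndarray]:
        """Unmasked (t, R) of the dissociation phase, t relative to t1."""
        sel = (self.t >= self.t_inject_end) & self._unmasked()
        return self.t[sel] - self.t_inject_end, self.R[sel]


@dataclass
class DissociationFit:
    """Global biexponential dissociation fit.

    R(t) = R1 [x exp(-k_d1 (t - t1)) + (1 - x) exp(-k_d2 (t - t1))] with
    x, k_d1, k_d2 shared across concentrations and R1 per curve.
    ``monoexponential`` flags the degenerate fallback (k_d1 ~ k_d2 or
    x at a boundary), in which case k_d1 = k_d2.
    """

    R1: dict[float, float]
    x: float
    k_d1: float
    k_d2: float
    residual_sse: float = 0.0
    monoexponential: bool = False

    def predict(self, c: float, td: np.ndarray) -> np.ndarray:
        td = np.asarray(td, dtype=float)
        return self.R1[c] * (
            self.x * np.exp(-self.k_d1 * td)
            + (1.0 - self.x) * np.exp(-self.k_d2 * td)
        )

    def summary(self) -> str:
        kind = "monoexponential (degenerate)" if self.monoexponential else "biexponential"
        return (
            f"Global dissociation fit ({kind})\n"
            f"  k_d1 (fast) : {self.k_d1:.4g} s^-1\n"
            f"  k_d2 (slow) : {self.k_d2:.4g} s^-1\n"
            f"  x (fast fraction): {self.x:.4f}\n"
            f"  SSE         : {self.residual_sse:.5g}"
        )


@dataclass
class AssociationFit:
    """Monoexponential association fit R(t) = Rf + (R0 - Rf) exp(-k_obs t)."""

    R0: float
    Rf: float
    k_obs: float
    c: float
    residual_sse: float = 0.0

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.Rf + (self.R0 - self.Rf) * np.exp(-self.k_obs * t)


@dataclass
class AffinityResult:
    """Binding constants from kinetic and/or steady-state analysis.

    KD_kinetic = k_d2 / k_a by construction; ``k_d_intercept`` is the
    intercept of the k_obs regression, reported for diagnostics (it is
    related to secondary binding contributions, not used for K_D).
    """

    k_a: float | None = None
    k_d_intercept: float | None = None
    KD_kinetic: float | None = None
    KD_steady: float | None = None
    Rmax_steady: float | None = None
    KD_steady_ci: tuple[float, float] | None = None
    k_a_stderr: float | None = None

    def summary(self) -> str:
        lines = ["Affinity analysis"]
        if self.k_a is not None:
            lines.append(f"  k_a (association) : {self.k_a:.4g} M^-1 s^-1")
            lines.append(f"  k_obs intercept   : {self.k_d_intercept:.4g} s^-1")
            lines.append(
                f"  KD (kinetic)      : {self.KD_kinetic:.4g} M "
                f"({self.KD_kinetic * 1e6:.3g} umol/L)"
            )
        if self.KD_steady is not None:
            ci = (
                f"  [{self.KD_steady_ci[0] * 1e6:.3g}, {self.KD_steady_ci[1] * 1e6:.3g}]"
                if self.KD_steady_ci
                else ""
            )
            lines.append(
                f"  KD (steady state) : {self.KD_steady:.4g} M "
                f"({self.KD_steady * 1e6:.3g} umol/L){ci}"
            )
            lines.append(f"  Rmax (steady)     : {self.Rmax_steady:.4g} RU")
        return "\n".join(lines)


class DissociationModel:
    """Global biexponential model of the dissociation phases of >= 2 curves."""

    def __init__(self, sensorgrams: list[Sensorgram], degeneracy_ratio: float = 3.0):
        if len(sensorgrams) < 2:
            raise ValueError("global dissociation fit needs >= 2 concentrations")
        self.sensorgrams = sensorgrams
        self.degeneracy_ratio = degeneracy_ratio

    def _residual(self, params, biexp: bool):
        r = []
        kd1 = params["k_d1"].value
        kd2 = params["k_d2"].value if biexp else kd1
        x = params["x"].value if biexp else 1.0
        for i, sg in enumerate(self.sensorgrams):
            td, R = sg.dissociation_window()
            R1 = params[f"R1_{i}"].value
            pred = R1 * (x * np.exp(-kd1 * td) + (1 - x) * np.exp(-kd2 * td))
            r.append(pred - R)
        return np.concatenate(r)

    def _fit_once(self, biexp: bool):
        params = lmfit.Parameters()
        # initial decay scale from the first curve's early dissociation
        tds = [sg.dissociation_window() for sg in self.sensorgrams]
        span = max(td[0][-1] for td in tds)
        params.add("k_d1", value=10.0 / span, min=1e-8, max=10.0)
        if biexp:
            params.add("k_d2", value=0.1 / span, min=1e-10, max=10.0)
            params.add("x", value=0.5, min=0.0, max=1.0)
        for i, (td, R) in enumerate(tds):
            params.add(f"R1_{i}", value=float(R[0]), min=0.0)
        return lmfit.minimize(
            self._residual, params, kws={"biexp": biexp}, method="least_squares"
        )

    def fit(self) -> DissociationFit:
        res = self._fit_once(biexp=True)
        kd1, kd2 = res.params["k_d1"].value, res.params["k_d2"].value
        x = res.params["x"].value
        if kd1 < kd2:  # enforce fast/slow ordering
            kd1, kd2, x = kd2, kd1, 1.0 - x
        degenerate = (
            kd2 <= 0 or kd1 / max(kd2, 1e-300) < self.degeneracy_ratio
            or x < 1e-3 or x > 1 - 1e-3
        )
        if degenerate:
            warnings.warn(
                "biexponential dissociation is degenerate (phases not separable); "
                "collapsing to a monoexponential model",
                RuntimeWarning,
            )
            res = self._fit_once(biexp=False)
            kd1 = kd2 = res.params["k_d1"].value
            x = 1.0
        R1 = {
            sg.c: float(res.params[f"R1_{i}"].value)
            for i, sg in enumerate(self.sensorgrams)
        }
        return DissociationFit(
            R1=R1,
            x=float(x),
            k_d1=float(kd1),
            k_d2=float(kd2),
            residual_sse=float(res.chisqr),
            monoexponential=bool(degenerate),
        )


class AssociationModel:
    """Monoexponential model of one association phase."""

    def __init__(self, sensorgram: Sensorgram):
        self.sensorgram = sensorgram

    def fit(self) -> AssociationFit:
        t, R = self.sensorgram.association_window()
        if len(t) < 5:
            raise ValueError("too few association points")
        span = float(np.ptp(R))
        noise = float(np.std(np.diff(R))) / np.sqrt(2.0)
        if span <= max(5.0 * noise, 1e-12):
            raise ValueError("flat association response; nothing to fit")

        def model(t, R0, Rf, k_obs):
            return Rf + (R0 - Rf) * np.exp(-k_obs * t)

        m = lmfit.Model(model)
        k0 = 3.0 / max(t[-1], 1e-9)
        params = m.make_params(
            R0=dict(value=float(R[0])),
            Rf=dict(value=float(R[-1])),
            k_obs=dict(value=k0, min=1e-8, max=1e3),
        )
        best = None
        for kf in (1.0, 0.2, 5.0):
            params["k_obs"].value = k0 * kf
            res = m.fit(R, params, t=t)
            if best is None or res.chisqr < best.chisqr:
                best = res
        if not best.success:
            raise RuntimeError("association fit did not converge")
        v = best.params.valuesdict()
        return AssociationFit(
            R0=v["R0"], Rf=v["Rf"], k_obs=v["k_obs"],
            c=self.sensorgram.c, residual_sse=float(best.chisqr),
        )


def fit_dissociation_global(sensorgrams: list[Sensorgram]) -> DissociationFit:
    """Globally fit all dissociation phases to the shared biexponential."""
    return DissociationModel(sensorgrams).fit()


def fit_association(sensorgram: Sensorgram) -> AssociationFit:
    """Fit one association phase to the monoexponential approach."""
    return AssociationModel(sensorgram).fit()


def estimate_affinity_kinetic(
    assoc_fits: dict[float, AssociationFit] | list[AssociationFit],
    dissoc: DissociationFit,
) -> AffinityResult:
    """Kinetic affinity from the k_obs-versus-concentration regression.

    k_obs = c k_a + k_d: the slope is k_a and K_D = k_d2 / k_a with k_d2
    from the global dissociation fit.  Requires >= 4 concentrations
    spanning at least one decade.
    """
    fits = list(assoc_fits.values()) if isinstance(assoc_fits, dict) else list(assoc_fits)
    c = np.array([f.c for f in fits], dtype=float)
    kobs = np.array([f.k_obs for f in fits], dtype=float)
    if len(c) < 4:
        raise ValueError("need >= 4 concentrations for the k_obs regression")
    if c.max() / c.min() < 10.0:
        raise ValueError("concentration series must span at least one decade")
    lin = stats.linregress(c, kobs)
    if lin.slope <= 0:
        raise ValueError("k_obs does not increase with concentration; no binding signal")
    k_a = float(lin.slope)
    return AffinityResult(
        k_a=k_a,
        k_d_intercept=float(lin.intercept),
        KD_kinetic=dissoc.k_d2 / k_a,
        k_a_stderr=float(lin.stderr),
    )


class SteadyStateAffinityModel:
    """1:1 Langmuir fit of maximum binding response versus concentration."""

    def __init__(self, responses: dict[float, float]):
        if len(responses) < 4:
            raise ValueError("need >= 4 concentrations for the steady-state fit")
        self.c = np.array(sorted(responses), dtype=float)
        self.R = np.array([responses[c] for c in sorted(responses)], dtype=float)
        if np.any(self.R <= 0):
            raise ValueError("responses must be positive")

    def fit(self) -> AffinityResult:
        def langmuir(c, Rmax, KD):
            return Rmax * c / (KD + c)

        m = lmfit.Model(langmuir)
        res = m.fit(
            self.R,
            m.make_params(
                Rmax=dict(value=float(self.R.max() * 1.5), min=1e-9),
                KD=dict(value=float(np.median(self.c)), min=1e-12, max=1.0),
            ),
            c=self.c,
        )
        KD = float(res.params["KD"].value)
        KD_err = res.params["KD"].stderr
        ci = None
        if KD_err is not None and np.isfinite(KD_err):
            ci = (max(KD - 1.96 * KD_err, 0.0), KD + 1.96 * KD_err)
            if KD_err > KD:
                warnings.warn(
                    "steady-state K_D is poorly constrained (no clear saturation); "
                    "confidence interval is wide",
                    RuntimeWarning,
                )
        return AffinityResult(
            KD_steady=KD,
            Rmax_steady=float(res.params["Rmax"].value),
            KD_steady_ci=ci,
        )


def estimate_affinity_steady_state(responses: dict[float, float]) -> AffinityResult:
    """Steady-state affinity from maximum responses (1:1 Langmuir fit)."""
    return SteadyStateAffinityModel(responses).fit()
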