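"""pH-titration analysis: apparent pKa of a single-site protonation transition.

The observable (CD ellipticity or Trp fluorescence) is modelled as a
Henderson-Hasselbalch-type sigmoid in pH,

    S(pH) = S_acid + (S_base - S_acid) / (1 + 10^(n (pKa - pH))),

with an optional Hill coefficient n (fixed to 1 by default, appropriate
when a single residue titrates in the sampled range).  Confidence
intervals come from a seeded residual bootstrap, which behaves better than
asymptotic intervals at the small number of pH points typical of these
experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lmfit
import numpy as np

__all__ = ["TitrationCurve", "TitrationFit", "TitrationModel", "fit_pka"]


@dataclass
class TitrationCurve:
    """Signal versus pH series feeding the pKa fit."""

    pH: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.pH = np.asarray(self.pH, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.pH.shape != self.signal.shape or self.pH.ndim != 1:
            raise ValueError("pH and signal must be 1-D arrays of equal length")
        if len(self.pH) < 5:
            raise ValueError("need >= 5 pH points spanning the transition")
        if len(np.unique(self.pH)) != len(self.pH):
            raise ValueError("pH values must be distinct")
        if np.any(self.pH < 3) or np.any(self.pH > 11):
            raise ValueError("pH values must lie within 3-11")


@dataclass
class TitrationFit:
    """Apparent pKa and asymptotic signals of a single-site transition."""

    pKa: float
    S_acid: float
    S_base: float
    hill_n: float
    ci_pKa: tuple[float, float] | None
    residual_sse: float = 0.0

    def predict(self, pH: np.ndarray) -> np.ndarray:
        pH = np.asarray(pH, dtype=float)
        return self.S_acid + (self.S_base - self.S_acid) / (
            1.0 + 10.0 ** (self.hill_n * (self.pKa - pH))
        )

    def summary(self) -> str:
        ci = (
            f"  [{self.ci_pKa[0]:.3f}, {self.ci_pKa[1]:.3f}] (95% bootstrap)"
            if self.ci_pKa
            else "  (no CI computed)"
        )
        return (
            "Single-site titration fit\n"
            f"  apparent pKa : {self.pKa:.3f}{ci}\n"
            f"  S_acid       : {self.S_acid:.5g}\n"
            f"  S_base       : {self.S_base:.5g}\n"
            f"  Hill n       : {self.hill_n:.3f}\n"
            f"  SSE          : {self.residual_sse:.5g}"
        )


def _single_site(pH, pKa, S_acid, S_base, hill_n):
    return S_acid + (S_base - S_acid) / (1.0 + 10.0 ** (hill_n * (pKa - pH)))


class TitrationModel:
    """Single-site protonation model of one titration curve."""

    def __init__(self, curve: TitrationCurve, fix_hill: bool = True):
        self.curve = curve
        self.fix_hill = fix_hill

    def _fit_arrays(self, pH, signal) -> lmfit.model.ModelResult:
        span = float(signal.max() - signal.min())
        noise = float(np.std(np.diff(signal))) / np.sqrt(2.0)
        if span <= 0 or (noise > 0 and span < 4.0 * noise):
            raise ValueError("no transition detected within the sampled pH range")
        m = lmfit.Model(_single_site)
        order = np.argsort(pH)
        mid = 0.5 * (signal[order][0] + signal[order][-1])
        pKa0 = float(np.interp(0.0, (signal[order] - mid) * np.sign(signal[order][-1] - signal[order][0]), pH[order]))
        params = m.make_params(
            pKa=dict(value=pKa0, min=pH.min() - 2.0, max=pH.max() + 2.0),
            S_acid=dict(value=float(signal[order][0])),
            S_base=dict(value=float(signal[order][-1])),
            hill_n=dict(value=1.0, min=0.05, max=10.0, vary=not self.fix_hill),
        )
        res = m.fit(signal, params, pH=pH)
        if not res.success:
            raise RuntimeError("titration fit did not converge")
        return res

    def fit(self, n_boot: int = 200, seed: int = 0) -> TitrationFit:
        """Fit the curve; bootstrap the pKa CI with ``n_boot`` resamples (0 = skip)."""
        pH, signal = self.curve.pH, self.curve.signal
        res = self._fit_arrays(pH, signal)
        v = res.params.valuesdict()
        if not (pH.min() <= v["pKa"] <= pH.max()):
            warnings.warn(
                "fitted pKa lies outside the sampled pH range; "
                "the transition is not bracketed by the data",
                RuntimeWarning,
            )
        ci = None
        if n_boot > 0:
            rng = np.random.default_rng(seed)
            resid = signal - res.best_fit
            pkas = []
            for _ in range(n_boot):
                boot = res.best_fit + rng.choice(resid, size=len(resid), replace=True)
                try:
                    bres = self._fit_arrays(pH, boot)
                except Exception:
                    continue
                pkas.append(bres.params["pKa"].value)
            if len(pkas) >= max(20, n_boot // 4):
                lo, hi = np.percentile(pkas, [2.5, 97.5])
                ci = (float(lo), float(hi))
        return TitrationFit(
            pKa=float(v["pKa"]),
            S_acid=float(v["S_acid"]),
            S_base=float(v["S_base"]),
            hill_n=float(v["hill_n"]),
            ci_pKa=ci,
            residual_sse=float(res.chisqr),
        )


def fit_pka(
    curve: TitrationCurve,
    fix_hill: bool = True,
    n_boot: int = 200,
    seed: int = 0,
) -> TitrationFit:
    """Fit a titration curve to the single-site model and report apparent pKa."""
    return TitrationModel(curve, fix_hill=fix_hill).fit(n_boot=n_boot, seed=seed)
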