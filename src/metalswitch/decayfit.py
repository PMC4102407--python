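"""Autodegradation kinetics from band-intensity time series.

Relative protein content I(t) (normalized to the maximum) is fit on the log
scale by ordinary least squares, matching the log-linear presentation of
stability assays: ln I = ln I0 − k t, half-life t½ = ln2/k, with half-life
bounds from the fitted slope ± its standard error and a 95% confidence band
for the linear model.  Variants follow the calcium-blind ShhN_AAA
(E90A/E91A/E127A; putatively a constitutively active peptidase) versus the
additional catalytic knockout ShhN_AAAA (+E177A) assay design with time
points 0/3/6/18 h at low and neutral pH.
"""

from __future__ import annotations

import dataclasses
import io
import math

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import rank_sum_test

__all__ = [
    "DecaySeries",
    "DecayFit",
    "fit_decay",
    "compare_at_time",
    "halflife_contrast",
    "read_decay_tsv",
]

DEFAULT_FLOOR = 0.01  # detection floor on relative intensity


@dataclasses.dataclass
class DecaySeries:
    variant: str                    # e.g. "AAA" or "AAAA"
    ph_label: str                   # "low" (~5) or "neutral" (~7)
    observations: list              # (time_h, intensity, replicate_id)

    def __post_init__(self):
        times = {t for t, _, _ in self.observations}
        if len(times) < 2:
            raise ValueError("need at least two distinct time points")
        for t, i, _ in self.observations:
            if not (0.0 < i <= 1.0 + 1e-9):
                raise ValueError(
                    f"intensity {i} at t={t} outside (0, 1] — intensities "
                    "must be normalized to the maximum protein content")

    def at_time(self, t: float) -> np.ndarray:
        vals = [i for tt, i, _ in self.observations
                if math.isclose(tt, t, abs_tol=1e-9)]
        if not vals:
            raise KeyError(f"no observations at t={t} h "
                           f"for {self.variant}/{self.ph_label}")
        return np.array(vals)

    @property
    def times(self) -> np.ndarray:
        return np.array(sorted({t for t, _, _ in self.observations}))


@dataclasses.dataclass
class DecayFit:
    rate: float                     # k, 1/h
    rate_se: float
    half_life: float                # h (inf when k <= 0)
    half_life_bounds: tuple         # (ln2/(k+SE), ln2/(k-SE))
    intercept: float                # ln I0
    no_decay: bool
    n_points: int
    n_censored: int
    ci_band: pd.DataFrame | None = None   # t, fit, lo95, hi95 (log scale)


def fit_decay(d: DecaySeries, include_t0: bool = True,
              floor: float = DEFAULT_FLOOR) -> DecayFit:
    """Least-squares exponential-decay fit on log intensity vs time.

    Intensities below the detection ``floor`` are censored from the fit
    (near-vanished bands carry no reliable log signal) and counted.  The
    t = 0 normalization anchor is included by default.  A non-positive
    fitted rate flags ``no_decay`` with an infinite half-life.
    """
    pts = [(t, i) for t, i, _ in d.observations
           if (include_t0 or t > 0)]
    censored = [(t, i) for t, i in pts if i < floor]
    pts = [(t, i) for t, i in pts if i >= floor]
    times = sorted({t for t, _ in pts})
    if len(times) < 2:
        raise ValueError("fewer than two usable time points after censoring")
    t = np.array([p[0] for p in pts])
    y = np.log(np.array([p[1] for p in pts]))
    res = stats.linregress(t, y)
    k = -res.slope
    se = res.stderr if np.isfinite(res.stderr) else 0.0

    if k <= 0:
        half = float("inf")
        bounds = (math.log(2) / (k + se) if k + se > 0 else float("inf"),
                  float("inf"))
        no_decay = True
    else:
        half = math.log(2) / k
        hi = math.log(2) / (k - se) if k - se > 0 else float("inf")
        bounds = (math.log(2) / (k + se), hi)
        no_decay = False

    # 95% confidence band of the linear model on the log scale
    band = None
    n = len(t)
    if n > 2:
        dof = n - 2
        tcrit = stats.t.ppf(0.975, dof)
        resid = y - (res.intercept + res.slope * t)
        s2 = float(resid @ resid) / dof
        tgrid = np.linspace(t.min(), t.max(), 50)
        sxx = float(((t - t.mean()) ** 2).sum())
        sefit = np.sqrt(s2 * (1.0 / n + (tgrid - t.mean()) ** 2 / sxx))
        fit = res.intercept + res.slope * tgrid
        band = pd.DataFrame({"time_h": tgrid, "log_fit": fit,
                             "lo95": fit - tcrit * sefit,
                             "hi95": fit + tcrit * sefit})
    return DecayFit(rate=float(k), rate_se=float(se), half_life=half,
                    half_life_bounds=bounds, intercept=float(res.intercept),
                    no_decay=no_decay, n_points=n, n_censored=len(censored),
                    ci_band=band)


def compare_at_time(a: DecaySeries, b: DecaySeries, t: float):
    """Two-sided rank-sum test on replicate intensities at time ``t``."""
    return rank_sum_test(a.at_time(t), b.at_time(t),
                         alternative="two-sided")


def halflife_contrast(a: DecaySeries, b: DecaySeries, **fit_kwargs) -> dict:
    """Half-life ratio t½(a)/t½(b) with first-order error propagation."""
    fa, fb = fit_decay(a, **fit_kwargs), fit_decay(b, **fit_kwargs)
    if fa.no_decay or fb.no_decay:
        return {"ratio": float("nan"), "bounds": (float("nan"), float("nan")),
                "undefined": True, "fit_a": fa, "fit_b": fb}
    ratio = fa.half_life / fb.half_life          # = k_b / k_a
    rel = math.sqrt((fa.rate_se / fa.rate) ** 2 + (fb.rate_se / fb.rate) ** 2)
    se = ratio * rel
    return {"ratio": float(ratio), "bounds": (ratio - se, ratio + se),
            "undefined": False, "fit_a": fa, "fit_b": fb}


def read_decay_tsv(path_or_text) -> list:
    """Load decay series from a TSV with columns
    variant, pH, time_h, replicate, intensity; one series per
    (variant, pH) group."""
    if isinstance(path_or_text, str) and "\n" in path_or_text:
        df = pd.read_csv(io.StringIO(path_or_text), sep="\t")
    else:
        df = pd.read_csv(path_or_text, sep="\t")
    out = []
    for (variant, ph), grp in df.groupby(["variant", "pH"], sort=True):
        obs = [(float(r.time_h), float(r.intensity), str(r.replicate))
               for r in grp.itertuples()]
        out.append(DecaySeries(variant=str(variant), ph_label=str(ph),
                               observations=obs))
    return out
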