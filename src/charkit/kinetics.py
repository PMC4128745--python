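"""Phage infection kinetics: adsorption rate constants and one-step growth parameters.

The adsorption model is first-order loss of free phage onto a fixed excess of
host cells (Adams):

    P(t) = P0 * exp(-k * B * t)

with ``k`` the adsorption rate constant (ml/min) and ``B`` the host
concentration (cfu/ml).  A non-adsorbable residual fraction ``r`` generalizes
this to ``P(t)/P0 = r + (1 - r) * exp(-k B t)``.

One-step growth curves are summarized by the latent period (time from
adsorption to first progeny release) and the burst size (final free phage per
infected cell).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import DegenerateInputError, InvalidInputError, NoBurstError

__all__ = [
    "TiterSeries",
    "AdsorptionResult",
    "OneStepResult",
    "adsorption_fractions",
    "fit_adsorption_constant",
    "estimate_latent_period",
    "estimate_burst_size",
    "infected_cell_count",
]


@dataclass(frozen=True)
class TiterSeries:
    """Timestamped phage titers from a single assay.

    Parameters
    ----------
    time
        Sampling times in minutes, non-negative and strictly increasing
        within each replicate.
    titer
        Free-phage titers in pfu/ml, non-negative.
    replicate
        Integer replicate label per point (default: all zero).
    """

    time: np.ndarray
    titer: np.ndarray
    replicate: np.ndarray | None = None
    dilution_plated: float | None = None
    volume_plated_ml: float | None = None
    assay: str = ""
    phage_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        p = np.asarray(self.titer, dtype=float)
        if t.size == 0 or p.size == 0:
            raise InvalidInputError("titer series must be non-empty")
        if t.shape != p.shape:
            raise InvalidInputError("time and titer must have equal length")
        rep = (
            np.zeros(t.shape, dtype=int)
            if self.replicate is None
            else np.asarray(self.replicate, dtype=int)
        )
        if rep.shape != t.shape:
            raise InvalidInputError("replicate labels must match series length")
        if np.any(t < 0):
            raise InvalidInputError("times must be non-negative")
        if np.any(p < 0):
            raise InvalidInputError("titers must be non-negative")
        for r in np.unique(rep):
            tr = t[rep == r]
            if np.any(np.diff(tr) <= 0):
                raise InvalidInputError(
                    f"times must be strictly increasing within replicate {r}"
                )
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "titer", p)
        object.__setattr__(self, "replicate", rep)

    def __len__(self) -> int:
        return int(self.time.size)

    def mean_by_time(self) -> "TiterSeries":
        """Collapse replicates to the per-time mean titer."""
        times = np.unique(self.time)
        means = np.array([self.titer[self.time == t].mean() for t in times])
        return TiterSeries(times, means, assay=self.assay, phage_id=self.phage_id)


@dataclass
class AdsorptionResult:
    """Free-fraction curve and fitted adsorption parameters."""

    k: float  # ml/min
    residual_fraction: float
    fractions: np.ndarray  # P/P0, clamped to [0, 1] for reporting
    raw_fractions: np.ndarray  # unclamped ratios
    times: np.ndarray
    B: float | None = None
    p0: float | None = None
    fit_window: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)


@dataclass
class OneStepResult:
    latent_period_min: float
    burst_size: float
    baseline_titer: float
    plateau_titer: float
    infected_cells: float | None = None
    moi: float | None = None


def adsorption_fractions(series: TiterSeries, p0: float) -> AdsorptionResult:
    """Free-phage fraction P(t)/P0 at each sampled time.

    Fractions are clamped to [0, 1] for reporting (counting noise can push a
    ratio slightly above 1); the raw ratios are preserved on the result.
    """
    if p0 <= 0:
        raise InvalidInputError(f"p0 must be positive, got {p0}")
    raw = series.titer / float(p0)
    clamped = np.clip(raw, 0.0, 1.0)
    return AdsorptionResult(
        k=math.nan,
        residual_fraction=0.0,
        fractions=clamped,
        raw_fractions=raw,
        times=series.time.copy(),
        p0=float(p0),
    )


def _preplateau_window(fractions: np.ndarray, rel_drop: float = 0.05) -> np.ndarray:
    """Indices of the initial decaying window of a fraction curve.

    Includes points up to and including the first one whose relative drop from
    the previous sample is below ``rel_drop`` (the curve has flattened there).
    """
    idx = [0]
    for i in range(1, len(fractions)):
        idx.append(i)
        prev, cur = fractions[i - 1], fractions[i]
        if prev <= 0:
            break
        if (prev - cur) / prev < rel_drop:
            break
    return np.asarray(idx, dtype=int)


def fit_adsorption_constant(
    series: TiterSeries,
    B: float,
    p0: float,
    mode: str = "regression",
    allow_residual: bool = False,
    t_star: float | None = None,
) -> AdsorptionResult:
    """Estimate the adsorption rate constant k (ml/min).

    ``single_point`` evaluates Adams' formula k = ln(P0/P(t*)) / (B t*) at one
    time point (the last sampled time unless ``t_star`` is given).
    ``regression`` fits ln(P/P0) = -kBt by least squares with the intercept
    fixed at 0 over the pre-plateau window.  With ``allow_residual`` the full
    model P/P0 = r + (1-r) exp(-kBt) is fitted and the non-adsorbable residual
    fraction r is reported.
    """
    if B <= 0:
        raise InvalidInputError(f"host concentration B must be positive, got {B}")
    res = adsorption_fractions(series, p0)
    res.B = float(B)
    t = res.times
    frac = res.raw_fractions
    notes: list[str] = []

    if np.all(frac >= 1.0):
        notes.append("no net adsorption detected (all fractions >= 1); k set to 0")
        res.k = 0.0
        res.warnings = notes
        res.fit_window = np.arange(len(t))
        return res

    if mode == "single_point":
        ts = float(t[-1]) if t_star is None else float(t_star)
        if ts not in t:
            raise InvalidInputError(f"t_star={ts} is not a sampled time")
        f = float(frac[t == ts][0])
        if f <= 0:
            raise InvalidInputError("fraction at t_star is zero; cannot take log")
        res.k = max(0.0, math.log(1.0 / f) / (B * ts))
        res.fit_window = np.flatnonzero(t == ts)
    elif mode == "regression":
        window = _preplateau_window(np.clip(frac, 0.0, None))
        usable = window[(frac[window] > 0)]
        dropped = len(window) - len(usable)
        if dropped:
            notes.append(f"{dropped} zero-titer point(s) excluded from log fit")
        if len(usable) < 2:
            raise InvalidInputError(
                "regression mode needs at least 2 usable pre-plateau points"
            )
        tw, fw = t[usable], frac[usable]
        if allow_residual:
            # fit the decay rate kB (O(0.1)/min) rather than k itself
            # (O(1e-9) ml/min), which is far below curve_fit's step scale
            def model(tt, rate, r):
                return r + (1.0 - r) * np.exp(-rate * tt)

            rate0 = max(1e-6, -np.log(max(fw[-1], 1e-12)) / tw[-1])
            (rate_hat, r_hat), _ = curve_fit(
                model, tw, fw, p0=[rate0, 0.0],
                bounds=([0.0, 0.0], [np.inf, 1.0]), maxfev=10000,
            )
            res.k = float(rate_hat) / B
            res.residual_fraction = float(r_hat)
        else:
            y = np.log(fw)
            # least squares slope with intercept fixed at 0: ln f = -kB t
            slope = float(np.sum(tw * y) / np.sum(tw * tw))
            res.k = max(0.0, -slope / B)
        res.fit_window = usable
    else:
        raise InvalidInputError(f"unknown mode {mode!r}")

    res.warnings = notes
    return res


def estimate_latent_period(series: TiterSeries, rise_factor: float = 2.0) -> float:
    """Latent period: last sampled time before the titer first exceeds
    baseline_mean * rise_factor, with baseline_mean the mean of the first two
    samples."""
    s = series.mean_by_time()
    if len(s) < 4:
        raise InvalidInputError("latent-period estimation needs >= 4 time points")
    baseline = float(s.titer[:2].mean())
    threshold = baseline * rise_factor
    above = np.flatnonzero(s.titer > threshold)
    if above.size == 0:
        raise NoBurstError(
            f"no sample exceeds {rise_factor}x the baseline of {baseline:.3g} pfu/ml"
        )
    first = int(above[0])
    if first == 0:
        raise DegenerateInputError("first sample already above the rise threshold")
    return float(s.time[first - 1])


def estimate_burst_size(
    series: TiterSeries, infected_cells: float, plateau_n: int = 3
) -> float:
    """Burst size: mean of the final plateau titers over infected cells per ml.

    The plateau is the last ``plateau_n`` samples; if they vary by more than
    20% a warning is emitted and the last point alone is used.
    """
    if infected_cells <= 0:
        raise InvalidInputError(
            f"infected_cells must be positive, got {infected_cells}"
        )
    s = series.mean_by_time()
    tail = s.titer[-plateau_n:]
    lo, hi = tail.min(), tail.max()
    if lo <= 0 or (hi - lo) / hi > 0.20:
        warnings.warn(
            "no stable plateau in the last samples; using the final point",
            stacklevel=2,
        )
        plateau = float(s.titer[-1])
    else:
        plateau = float(tail.mean())
    return plateau / float(infected_cells)


def infected_cell_count(p_total: float, adsorbed_fraction: float) -> float:
    """Infected cells per ml under the single-hit assumption (low MOI).

    At MOI ~ 0.001 essentially every adsorbed phage hits a distinct cell, so
    infected cells = total phage * adsorbed fraction.
    """
    if not (0.0 <= adsorbed_fraction <= 1.0):
        raise InvalidInputError(
            f"adsorbed_fraction must lie in [0, 1], got {adsorbed_fraction}"
        )
    return float(p_total) * float(adsorbed_fraction)


def poisson_infected_fraction(moi_adsorbed: float) -> float:
    """Fraction of cells infected at least once: 1 - exp(-m).

    Optional multiple-infection correction; negligible at MOI << 1.
    """
    if moi_adsorbed < 0:
        raise InvalidInputError("adsorbed MOI must be non-negative")
    return 1.0 - math.exp(-moi_adsorbed)
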