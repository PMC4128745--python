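"""Appelmans serial-dilution broth assays.

The Appelmans method titrates phage lytic activity in liquid culture:
tenfold dilutions of a phage stock are inoculated with a fixed bacterial
concentration and culture turbidity (OD600) is read at 24 and 48 h.  The
endpoint is the most dilute tube that still suppresses growth below a
turbidity threshold; a phage is "stable" if it holds OD600 below 0.1 at
48 h down to a given minimum MOI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "DilutionPlan",
    "ODTable",
    "moi_for_dilution",
    "lysis_endpoint",
    "is_stable",
    "compare_conditions",
    "CONDITIONS",
]

CONDITIONS = ("phage_a", "phage_b", "mixture", "control")


@dataclass(frozen=True)
class DilutionPlan:
    """Serial tenfold dilution design for an Appelmans assay."""

    stock_titer: float = 1e9  # pfu/ml
    dilution_exponents: tuple[int, ...] = tuple(range(-2, -10, -1))
    bacteria: float = 1e5  # cfu/ml
    tube_volume_ml: float = 5.0

    def __post_init__(self) -> None:
        if self.stock_titer <= 0 or self.bacteria <= 0:
            raise InvalidInputError("stock titer and bacteria must be positive")
        exps = tuple(self.dilution_exponents)
        if any(e >= 0 for e in exps):
            raise InvalidInputError("dilution exponents must be negative")
        if any(b >= a for a, b in zip(exps, exps[1:])):
            # stored most-concentrated first
            raise InvalidInputError("dilution exponents must be strictly decreasing")
        object.__setattr__(self, "dilution_exponents", exps)

    def mois(self) -> dict[int, float]:
        return {e: moi_for_dilution(self, e) for e in self.dilution_exponents}


def moi_for_dilution(plan: DilutionPlan, exponent: int) -> float:
    """MOI of the tube at a given tenfold-dilution exponent."""
    if exponent not in plan.dilution_exponents:
        raise InvalidInputError(f"exponent {exponent} not in plan")
    return plan.stock_titer * 10.0 ** exponent / plan.bacteria


@dataclass
class ODTable:
    """Replicate OD600 readings per (condition, dilution exponent, time).

    Backed by a DataFrame with columns ``condition``, ``dilution_exponent``
    (NaN for the no-phage control), ``time_h``, ``replicate``, ``od600``.
    """

    data: pd.DataFrame = field(repr=False)

    REQUIRED = ("condition", "dilution_exponent", "time_h", "replicate", "od600")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise InvalidInputError(f"OD table missing columns: {missing}")
        if (self.data["od600"] < 0).any():
            raise InvalidInputError("OD600 readings must be non-negative")

    def mean_od(self, condition: str, time_h: float) -> pd.Series:
        """Replicate-mean OD indexed by dilution exponent (ascending |exp|)."""
        sub = self.data[
            (self.data["condition"] == condition) & (self.data["time_h"] == time_h)
        ]
        if sub.empty:
            raise InvalidInputError(
                f"no readings for condition={condition!r} at {time_h} h"
            )
        if condition == "control":
            return sub.groupby("time_h")["od600"].mean()
        g = sub.groupby("dilution_exponent")["od600"].mean()
        return g.sort_index(ascending=False)  # -2 first, most dilute last

    def exponents(self, condition: str, time_h: float) -> list[int]:
        return [int(e) for e in self.mean_od(condition, time_h).index]


def lysis_endpoint(
    od: ODTable, condition: str, time_h: float, threshold: float = 0.1
) -> int | None:
    """Most dilute exponent whose replicate-mean OD600 is below ``threshold``.

    Returns ``None`` if no tube is lysed.  Dilution tubes must form a
    contiguous series; a missing tube raises.
    """
    means = od.mean_od(condition, time_h)
    exps = np.array([int(e) for e in means.index])
    if len(exps) > 1 and not np.all(np.diff(exps) == -1):
        raise InvalidInputError("dilution series has missing tubes")
    lysed = [int(e) for e, v in means.items() if v < threshold]
    return min(lysed) if lysed else None


def is_stable(
    od: ODTable,
    condition: str,
    plan: DilutionPlan,
    min_moi: float = 0.01,
    time_h: float = 48,
    threshold: float = 0.1,
) -> bool:
    """Stability criterion: OD600 < threshold at ``time_h`` for every tube
    with MOI >= ``min_moi``."""
    means = od.mean_od(condition, time_h)
    mois = plan.mois()
    checked = False
    for e, v in means.items():
        if mois[int(e)] >= min_moi:
            checked = True
            if v >= threshold:
                return False
    if not checked:
        raise InvalidInputError("no tube at or above the minimum MOI")
    return True


def compare_conditions(od: ODTable, time_h: float) -> dict:
    """Per-dilution comparison of the phage mixture against the better single.

    Returns the signed OD difference mixture - min(phage_a, phage_b) at each
    dilution exponent, and the fraction of dilutions where the mixture OD is
    less than or equal to both singles.
    """
    for cond in ("phage_a", "phage_b", "mixture"):
        try:
            od.mean_od(cond, time_h)
        except InvalidInputError:
            raise InvalidInputError(f"condition {cond!r} missing at {time_h} h")
    a = od.mean_od("phage_a", time_h)
    b = od.mean_od("phage_b", time_h)
    m = od.mean_od("mixture", time_h)
    exps = sorted(set(a.index) & set(b.index) & set(m.index), reverse=True)
    if not exps:
        raise InvalidInputError("no common dilution exponents across conditions")
    diffs = {int(e): float(m[e] - min(a[e], b[e])) for e in exps}
    n_better = sum(m[e] <= min(a[e], b[e]) for e in exps)
    return {
        "time_h": time_h,
        "difference_by_exponent": diffs,
        "fraction_mixture_best": n_better / len(exps),
    }
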