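"""Host-range matrices and efficiency of plating (EOP).

Each (strain, phage) pair gets one categorical activity call:

* ``propagates``   — the phage forms plaques / amplifies on the strain,
* ``adsorbs_only`` — the phage attaches (parallel-streaks positive) but does
  not propagate,
* ``resistant``    — no detectable interaction.

EOP is the titer on a test strain divided by the titer on the propagation
host; it is defined only for propagating pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum

from .errors import InvalidInputError

__all__ = [
    "Call",
    "StrainRecord",
    "ActivityCall",
    "HostRangeMatrix",
    "eop",
    "summarize_host_range",
    "joint_activity",
]


class Call(str, Enum):
    PROPAGATES = "propagates"
    ADSORBS_ONLY = "adsorbs_only"
    RESISTANT = "resistant"


#: calls counted as "adsorbs" (parallel-streaks positive)
ACTIVE_CALLS = frozenset({Call.PROPAGATES, Call.ADSORBS_ONLY})


@dataclass(frozen=True)
class StrainRecord:
    strain_id: str
    species: str = ""
    rep_profile: int | None = None
    carbapenem_phenotype: str | None = None  # "R" or "S"
    oxa51: bool | None = None
    oxa23: bool | None = None


@dataclass(frozen=True)
class ActivityCall:
    strain_id: str
    phage_id: str
    call: Call
    eop: float | None = None

    def __post_init__(self) -> None:
        call = Call(self.call)
        object.__setattr__(self, "call", call)
        if self.eop is not None:
            if call is not Call.PROPAGATES:
                raise InvalidInputError(
                    "EOP may only accompany a 'propagates' call"
                )
            if self.eop < 0:
                raise InvalidInputError("EOP must be non-negative")


@dataclass
class HostRangeMatrix:
    """Complete strain x phage grid of activity calls."""

    strains: list[StrainRecord]
    calls: list[ActivityCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[tuple[str, str], ActivityCall] = {}
        for c in self.calls:
            key = (c.strain_id, c.phage_id)
            if key in self._index:
                raise InvalidInputError(f"duplicate call for {key}")
            self._index[key] = c

    @property
    def phage_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.calls:
            seen.setdefault(c.phage_id, None)
        return list(seen)

    def call_for(self, strain_id: str, phage_id: str) -> ActivityCall:
        try:
            return self._index[(strain_id, phage_id)]
        except KeyError:
            raise InvalidInputError(
                f"no activity call for strain {strain_id!r} x phage {phage_id!r}"
            ) from None


def eop(test_titer: float, host_titer: float) -> float:
    """Efficiency of plating: titer on the test strain over the host titer."""
    if host_titer <= 0:
        raise InvalidInputError(f"host titer must be positive, got {host_titer}")
    if test_titer < 0:
        raise InvalidInputError("test titer must be non-negative")
    return float(test_titer) / float(host_titer)


def _pct(count: int, n: int) -> float:
    """Percentage to 1 decimal, round-half-up (matches reporting convention)."""
    return float(
        (Decimal(100 * count) / Decimal(n)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


def summarize_host_range(
    matrix: HostRangeMatrix,
    phage_id: str,
    species_filter: str | None = None,
) -> dict:
    """Counts and percentages of strains a phage propagates on / adsorbs to.

    ``n_adsorbs`` counts both ``propagates`` and ``adsorbs_only`` calls
    (streak-positive).  Percentages are reported to 1 decimal place.
    """
    strains = [
        s
        for s in matrix.strains
        if species_filter is None or s.species == species_filter
    ]
    if not strains:
        raise InvalidInputError(
            f"no strains match species filter {species_filter!r}"
        )
    calls = [matrix.call_for(s.strain_id, phage_id) for s in strains]
    n = len(calls)
    n_prop = sum(c.call is Call.PROPAGATES for c in calls)
    n_ads = sum(c.call in ACTIVE_CALLS for c in calls)
    return {
        "phage_id": phage_id,
        "n": n,
        "n_propagates": n_prop,
        "n_adsorbs": n_ads,
        "pct_propagates": _pct(n_prop, n),
        "pct_adsorbs": _pct(n_ads, n),
    }


def joint_activity(
    matrix: HostRangeMatrix,
    phage_a: str,
    phage_b: str,
    species_filter: str | None = None,
) -> dict:
    """Partition strains by the joint calls of two phages.

    Returns ``both_propagate`` (both phages propagate), ``both_resistant``
    (complete resistance to both) and ``exactly_one_active`` (everything in
    between: at least one phage shows activity but not both propagate).
    The three counts always sum to n.
    """
    strains = [
        s
        for s in matrix.strains
        if species_filter is None or s.species == species_filter
    ]
    if not strains:
        raise InvalidInputError("empty strain filter")
    both_prop = both_res = middle = 0
    for s in strains:
        ca = matrix.call_for(s.strain_id, phage_a).call
        cb = matrix.call_for(s.strain_id, phage_b).call
        if ca is Call.PROPAGATES and cb is Call.PROPAGATES:
            both_prop += 1
        elif ca is Call.RESISTANT and cb is Call.RESISTANT:
            both_res += 1
        else:
            middle += 1
    return {
        "n": len(strains),
        "both_propagate": both_prop,
        "exactly_one_active": middle,
        "both_resistant": both_res,
    }
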