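"""Frequency of phage-resistant mutant cells from plating counts.

A saturating phage challenge (MOI ~100) is plated directly; surviving
colonies are resistant mutants.  The per-replicate frequency is
colonies / cells plated, and replicates are summarized by their mean and
sample standard deviation (n-1 denominator), the convention used for
reporting values such as 1.2±0.5e-7.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

from .errors import InvalidInputError

__all__ = ["ResistancePlating", "mutant_frequency"]


@dataclass(frozen=True)
class ResistancePlating:
    replicate: int
    colonies: int
    cells_plated: float  # culture cfu/ml x plated volume (ml)
    moi_challenge: float | None = None

    def __post_init__(self) -> None:
        if self.cells_plated <= 0:
            raise InvalidInputError(
                f"cells_plated must be positive, got {self.cells_plated}"
            )
        if self.colonies < 0:
            raise InvalidInputError("colony count must be non-negative")
        if self.colonies > self.cells_plated:
            raise InvalidInputError("more colonies than cells plated")

    @property
    def frequency(self) -> float:
        return self.colonies / self.cells_plated


def mutant_frequency(platings: list[ResistancePlating]) -> dict:
    """Mean and sample SD of per-replicate resistant-mutant frequencies.

    With a single replicate the SD is undefined and reported as ``None``.
    """
    if not platings:
        raise InvalidInputError("at least one plating is required")
    freqs = [p.frequency for p in platings]
    mean = statistics.fmean(freqs)
    sd = statistics.stdev(freqs) if len(freqs) > 1 else None
    return {"mean": mean, "sd": sd, "per_replicate": freqs}
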