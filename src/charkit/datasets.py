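"""Built-in example datasets.

The host-range panel here is a synthetic reconstruction: the published study
reported only aggregate counts for its 34-strain Acinetobacter panel (28
A. baumannii plus 4 A. pittii and 2 A. nosocomialis), not the per-strain
calls.  This module lays out one concrete strain x phage grid that is
consistent with every aggregate figure in that report:

* Acibel004 propagates on 21/28 A. baumannii strains and adsorbs (streak
  positive) on 25/28; Acibel007 propagates on 17/28 and adsorbs on 20/28.
* Both phages propagate on 15 strains; 2 strains are completely resistant to
  both; the remaining 11 show partial/one-sided activity.
* All 6 non-baumannii strains resist both phages, with Acibel004 retaining
  weak adsorption on 5 of them.

Per-strain identities and EOP values are synthetic placeholders; summaries
computed from the grid reproduce the aggregate numbers exactly.
"""

from __future__ import annotations

from .host_range import ActivityCall, Call, HostRangeMatrix, StrainRecord

__all__ = ["acinetobacter_panel", "PHAGE_A", "PHAGE_B"]

PHAGE_A = "Acibel004"
PHAGE_B = "Acibel007"

# (strain index, species, call for Acibel004, call for Acibel007)
_P, _A, _R = Call.PROPAGATES, Call.ADSORBS_ONLY, Call.RESISTANT

_GRID: list[tuple[str, Call, Call]] = (
    # 15 strains where both phages propagate
    [("A. baumannii", _P, _P)] * 15
    # 6 strains where only Acibel004 propagates: Acibel007 adsorbs on 3,
    # resists 3
    + [("A. baumannii", _P, _A)] * 3
    + [("A. baumannii", _P, _R)] * 3
    # 2 strains where only Acibel007 propagates: Acibel004 adsorbs on 1,
    # resists 1
    + [("A. baumannii", _A, _P)]
    + [("A. baumannii", _R, _P)]
    # 3 strains with no propagation but Acibel004 adsorption
    + [("A. baumannii", _A, _R)] * 3
    # 2 strains completely resistant to both phages
    + [("A. baumannii", _R, _R)] * 2
    # non-baumannii: resistant, Acibel004 weakly adsorbs on 5 of 6
    + [("A. pittii", _A, _R)] * 3
    + [("A. pittii", _R, _R)]
    + [("A. nosocomialis", _A, _R)] * 2
)

# Synthetic EOP placeholders spanning the reported ranges
# (Acibel004: 1.0 down to 1e-5; Acibel007: 6.25e-1 down to 6.25e-2).
_EOP_A = [1.0, 1e-1, 1e-2, 1e-3, 1e-4, 1e-5]
_EOP_B = [6.25e-1, 2.5e-1, 6.25e-2]


def acinetobacter_panel() -> HostRangeMatrix:
    """Synthetic 34-strain host-range matrix matching the published aggregates."""
    strains: list[StrainRecord] = []
    calls: list[ActivityCall] = []
    ia = ib = 0
    for i, (species, call_a, call_b) in enumerate(_GRID, start=1):
        sid = f"AB{i:03d}" if species == "A. baumannii" else f"NX{i:03d}"
        strains.append(StrainRecord(strain_id=sid, species=species))
        eop_a = eop_b = None
        if call_a is _P:
            eop_a = _EOP_A[ia % len(_EOP_A)]
            ia += 1
        if call_b is _P:
            eop_b = _EOP_B[ib % len(_EOP_B)]
            ib += 1
        calls.append(ActivityCall(sid, PHAGE_A, call_a, eop_a))
        calls.append(ActivityCall(sid, PHAGE_B, call_b, eop_b))
    return HostRangeMatrix(strains=strains, calls=calls)
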