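"""Synthetic assay-data generators with configurable ground truth.

Every analysis stage in the package has a generator here that reproduces the
statistical structure of the corresponding bench assay, so each estimator
can be validated by parameter recovery without laboratory data.  All
generators are pure functions of their parameters and seed.

Plating noise follows standard plaque/colony-assay practice: the expected
titer is scaled by an automatic tenfold dilution into the countable 30-300
range, a Poisson count is drawn, and the count is rescaled back to pfu/ml.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .appelmans import CONDITIONS, DilutionPlan, ODTable
from .errors import InvalidInputError, NumericalError
from .genotyping import GenomeRecord
from .kinetics import TiterSeries
from .resistance import ResistancePlating

__all__ = [
    "InfectionParams",
    "BrothParams",
    "PRESETS",
    "simulate_adsorption",
    "simulate_onestep",
    "simulate_resistance",
    "simulate_appelmans",
    "simulate_genomes",
]


@dataclass(frozen=True)
class InfectionParams:
    """Ground truth for adsorption / one-step growth generators.

    ``k`` in ml/min, ``latent`` and ``rise`` in minutes, ``B`` in cfu/ml,
    ``p0`` in pfu/ml.  ``residual_fraction`` is the non-adsorbable phage
    fraction.
    """

    k: float
    latent: float
    burst: float
    B: float = 1e8
    moi: float = 0.001
    residual_fraction: float = 0.0
    rise: float = 15.0
    adsorption_window_min: float = 8.0  # pre-resuspension adsorption time

    def __post_init__(self) -> None:
        if min(self.k, self.latent, self.burst, self.B, self.moi) < 0:
            raise InvalidInputError("infection parameters must be non-negative")
        if not 0 <= self.residual_fraction <= 1:
            raise InvalidInputError("residual fraction must lie in [0, 1]")
        if self.rise <= 0:
            raise InvalidInputError("rise duration must be positive")

    @property
    def p0(self) -> float:
        return self.moi * self.B

    def free_fraction(self, t: float) -> float:
        r = self.residual_fraction
        return r + (1.0 - r) * math.exp(-self.k * self.B * t)

    def adsorbed_fraction(self, t: float) -> float:
        return 1.0 - self.free_fraction(t)


#: Generator presets at the study's reported ground truths (B=1e8 cfu/ml,
#: MOI 0.001, 3-min one-step sampling grid).
PRESETS: dict[str, InfectionParams] = {
    "acibel004": InfectionParams(k=1.2e-9, latent=27.0, burst=125.0),
    "acibel007": InfectionParams(k=1.7e-9, latent=21.0, burst=145.0),
}


def _plate(rng: np.random.Generator, expected_titer: float) -> float:
    """Poisson plating at an auto-selected tenfold dilution (30-300 counts)."""
    if expected_titer <= 0:
        return 0.0
    # smallest tenfold scale keeping the expected count at or below 300
    e = max(0, math.ceil(math.log10(expected_titer / 300.0)))
    scale = 10.0 ** e
    return float(rng.poisson(expected_titer / scale)) * scale


def simulate_adsorption(
    params: InfectionParams,
    times: list[float] | np.ndarray = (3, 5, 8, 10, 15, 20),
    seed: int | None = None,
    noise: bool = True,
) -> TiterSeries:
    """Free-phage titer series from an adsorption assay.

    Expected titer p0 * (r + (1-r) exp(-kBt)); Poisson plating noise unless
    ``noise=False``.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise InvalidInputError("times must be non-empty")
    rng = np.random.default_rng(seed)
    expected = np.array([params.p0 * params.free_fraction(x) for x in t])
    if noise:
        titer = np.array([_plate(rng, e) for e in expected])
    else:
        titer = expected
    return TiterSeries(t, titer, assay="adsorption")


def simulate_onestep(
    params: InfectionParams,
    times: list[float] | np.ndarray | None = None,
    seed: int | None = None,
    noise: bool = True,
) -> TiterSeries:
    """One-step growth curve: baseline, linear rise after the latent period,
    then a plateau at baseline + burst * infected cells.

    Adsorption is allowed for ``params.adsorption_window_min`` before
    resuspension; the baseline counts one infective center per infected cell.
    """
    if times is None:
        times = np.arange(0.0, 90.0 + 1e-9, 3.0)
    t = np.asarray(times, dtype=float)
    infected = params.p0 * params.adsorbed_fraction(params.adsorption_window_min)
    if params.latent + params.rise > t[-1]:
        raise InvalidInputError("latent + rise must fall within the time grid")
    baseline = infected  # one plaque per infective center
    plateau = baseline + params.burst * infected
    expected = np.where(
        t <= params.latent,
        baseline,
        np.where(
            t >= params.latent + params.rise,
            plateau,
            baseline
            + params.burst * infected * (t - params.latent) / params.rise,
        ),
    )
    rng = np.random.default_rng(seed)
    titer = (
        np.array([_plate(rng, e) for e in expected]) if noise else expected
    )
    return TiterSeries(t, titer, assay="onestep")


def simulate_resistance(
    f: float,
    cells_plated: float,
    n_replicates: int = 3,
    seed: int | None = None,
) -> list[ResistancePlating]:
    """Resistant-colony counts: Poisson(f * cells_plated) per replicate."""
    if not 0 <= f <= 1:
        raise InvalidInputError("mutant frequency must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lam = f * cells_plated
    return [
        ResistancePlating(replicate=i, colonies=int(rng.poisson(lam)),
                          cells_plated=cells_plated)
        for i in range(n_replicates)
    ]


@dataclass(frozen=True)
class BrothParams:
    """Phenomenological broth-infection model parameters for one phage.

    Rates are per hour.  ``resistant_frequency`` is the *effective* initial
    fraction of cells resistant to the phage — it absorbs mutants arising
    during the 48 h incubation, so it is deliberately far above plating
    mutant frequencies.  ``od_per_cell`` converts live cells/ml to OD600.
    """

    growth_rate: float = 0.67  # /h
    carrying_capacity: float = 8.5e8  # cells/ml
    adsorption_k: float = 7.2e-8  # ml/h  (1.2e-9 ml/min * 60)
    burst: float = 125.0
    resistant_frequency: float = 1e-4
    od_per_cell: float = 1e-9

    def __post_init__(self) -> None:
        if min(self.growth_rate, self.carrying_capacity, self.adsorption_k,
               self.burst, self.od_per_cell) <= 0:
            raise InvalidInputError("broth parameters must be positive")
        if not 0 <= self.resistant_frequency <= 1:
            raise InvalidInputError("resistant frequency must lie in [0, 1]")


def _integrate_broth(
    pa: BrothParams | None,
    pb: BrothParams | None,
    n0: float,
    p0a: float,
    p0b: float,
    hours: float,
    dt: float = 0.01,
) -> dict[float, float]:
    """Deterministic mass-action broth dynamics; returns total cells/ml at
    each whole hour.

    Four host subpopulations by resistance genotype (sensitive, resistant to
    A, to B, to both; resistance loci independent) grow logistically toward a
    shared carrying capacity; each phage adsorbs to and lyses its susceptible
    subpopulations with burst release.  Multiplicative (exponential) Euler
    updates keep all state non-negative at the fixed step.
    """
    ref = pa or pb or BrothParams()  # host growth params shared across phages
    g = ref.growth_rate
    K = ref.carrying_capacity
    fa = pa.resistant_frequency if pa else 0.0
    fb = pb.resistant_frequency if pb else 0.0
    # subpopulations: index by (resistant to A, resistant to B)
    N = {
        (False, False): n0 * (1 - fa) * (1 - fb),
        (True, False): n0 * fa * (1 - fb),
        (False, True): n0 * (1 - fa) * fb,
        (True, True): n0 * fa * fb,
    }
    P = {"a": p0a, "b": p0b}
    out: dict[float, float] = {}
    steps = int(round(hours / dt))
    record = {int(round(h / dt)) for h in range(0, int(hours) + 1)}
    for step in range(steps + 1):
        if step in record:
            out[round(step * dt, 6)] = sum(N.values())
        tot = sum(N.values())
        logistic = g * (1.0 - tot / K)
        newN = {}
        for (ra, rb), cells in N.items():
            kill = 0.0
            if pa and not ra:
                kill += pa.adsorption_k * P["a"]
            if pb and not rb:
                kill += pb.adsorption_k * P["b"]
            newN[(ra, rb)] = cells * math.exp((logistic - kill) * dt)
        for tag, par in (("a", pa), ("b", pb)):
            if par is None:
                continue
            if tag == "a":
                susceptible = N[(False, False)] + N[(False, True)]
            else:
                susceptible = N[(False, False)] + N[(True, False)]
            rate = par.adsorption_k * susceptible * (par.burst - 1.0)
            # cap the per-step log-growth: once phage vastly outnumber hosts
            # the susceptible pool collapses within the next step anyway
            P[tag] = P[tag] * math.exp(min(rate * dt, 50.0))
        N = newN
        if not all(map(math.isfinite, N.values())) or not all(
            map(math.isfinite, P.values())
        ):
            raise NumericalError(
                f"broth integration diverged (n0={n0}, p0a={p0a}, p0b={p0b})"
            )
    return out


def simulate_appelmans(
    params_a: BrothParams,
    params_b: BrothParams,
    plan: DilutionPlan | None = None,
    hours: tuple[float, ...] = (24.0, 48.0),
    n_replicates: int = 3,
    read_noise_sd: float = 0.01,
    seed: int | None = None,
    dt: float = 0.01,
) -> ODTable:
    """OD600 table for an Appelmans assay: each phage alone, the mixture, and
    a no-phage control, across the dilution plan.

    Tube dynamics are deterministic mass-action (see ``_integrate_broth``);
    Gaussian read noise (sd ``read_noise_sd``) is added per replicate
    reading and ODs are floored at zero.
    """
    plan = plan or DilutionPlan()
    rng = np.random.default_rng(seed)
    od_per_cell = params_a.od_per_cell
    rows = []

    def record(condition, exponent, cells_at):
        for h in hours:
            od_true = od_per_cell * cells_at[h]
            for rep in range(n_replicates):
                od = max(0.0, od_true + rng.normal(0.0, read_noise_sd))
                rows.append(
                    {
                        "condition": condition,
                        "dilution_exponent": exponent,
                        "time_h": h,
                        "replicate": rep,
                        "od600": od,
                    }
                )

    horizon = max(hours)
    for exponent in plan.dilution_exponents:
        p0 = plan.stock_titer * 10.0 ** exponent
        traj = _integrate_broth(params_a, None, plan.bacteria, p0, 0.0,
                                horizon, dt)
        record("phage_a", exponent, traj)
        traj = _integrate_broth(None, params_b, plan.bacteria, 0.0, p0,
                                horizon, dt)
        record("phage_b", exponent, traj)
        # mixture: equal split of the same total phage dose
        traj = _integrate_broth(params_a, params_b, plan.bacteria,
                                p0 / 2.0, p0 / 2.0, horizon, dt)
        record("mixture", exponent, traj)
    traj = _integrate_broth(None, None, plan.bacteria, 0.0, 0.0, horizon, dt)
    record("control", float("nan"), traj)
    return ODTable(pd.DataFrame(rows))


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _motif_free_insert(
    rng: np.random.Generator, length: int, gc: float, motif: str = "GCGC"
) -> str:
    """Random insert guaranteed to contain no motif occurrence, padded with
    A-runs at both ends so no motif can form across an insertion junction
    either.  Used for clone edits so one insertion changes at most two bands
    of the restriction profile."""
    pad = "A" * (len(motif) - 1)
    core_len = max(0, length - 2 * len(pad))
    while True:
        core = _random_seq(rng, core_len, gc)
        if motif not in core:
            return pad + core + pad


def simulate_genomes(
    n: int,
    length: int = 10_000,
    gc: float = 0.5,
    site_density: float | None = None,
    clone_edits: list[tuple[int, int]] | None = None,
    seed: int | None = None,
) -> list[GenomeRecord]:
    """Random genomes with i.i.d. bases at a target GC content.

    ``site_density`` optionally plants extra GCGC sites at the given per-bp
    density (on top of chance occurrences).  ``clone_edits`` is a list of
    (parent index, insertion length) pairs; each appends a clone of the
    parent genome with one motif-free insertion at a random position, so the
    clone's restriction profile differs from its parent's in at most two
    bands.
    """
    if not 0 < gc < 1:
        raise InvalidInputError("gc must lie in (0, 1)")
    if length <= 0:
        raise InvalidInputError("length must be positive")
    rng = np.random.default_rng(seed)
    genomes = []
    for i in range(n):
        seq = _random_seq(rng, length, gc)
        if site_density is not None:
            n_sites = int(site_density * length)
            for pos in rng.integers(0, length - 4, size=n_sites):
                seq = seq[:pos] + "GCGC" + seq[pos + 4 :]
        genomes.append(GenomeRecord(id=f"G{i:03d}", sequence=seq))
    for parent_idx, ins_len in clone_edits or []:
        parent = genomes[parent_idx]
        insert = _motif_free_insert(rng, ins_len, gc)
        # avoid splitting an existing recognition site with the insertion
        while True:
            pos = int(rng.integers(0, len(parent) + 1))
            if "GCGC" not in parent.sequence[max(0, pos - 3) : pos + 3]:
                break
        seq = parent.sequence[:pos] + insert + parent.sequence[pos:]
        genomes.append(
            GenomeRecord(id=f"{parent.id}_clone{ins_len}", sequence=seq)
        )
    return genomes
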