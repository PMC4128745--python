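# Methods

This note documents the models, defaults and numerical choices behind each
analysis module, what the synthetic generators do and do not emulate, and
the design decisions taken where the underlying assay conventions leave
room.

## Adsorption kinetics

Free phage adsorbing to a large excess of host cells decay exponentially,
P(t) = P₀·e^(−kBt), where k (ml/min) is the second-order adsorption rate
constant and B (cfu/ml) the host concentration, assumed constant over the
short assay (≤ 20 min). Two estimators are provided:

* **single_point**: k = ln(P₀/P(t*)) / (B·t*) at one chosen time (default:
  the last sample). This is the classical one-point evaluation and is
  sensitive to the choice of t*.
* **regression** (default): least-squares slope of ln(P/P₀) against t with
  the intercept fixed at 0 (the curve starts at fraction 1 by
  construction). Natural logs are used throughout; 2.303·log₁₀ is
  equivalent.

The regression window covers the initial decay only: points are included up
to and including the first sample whose relative drop from its predecessor
is below 5%, after which the curve is considered flattened (residual
unadsorbed phage, depleted receptors). No standard window convention
exists; this rule is deterministic and matches how practitioners read the
linear range off the semilog plot. Zero-titer points cannot enter the log
fit and are excluded with a warning; a series whose fractions never fall
below 1 yields k = 0 with a warning rather than a negative constant.

With `allow_residual` the two-parameter model P/P₀ = r + (1−r)·e^(−kBt) is
fitted by `scipy.optimize.curve_fit`. The optimizer works on the decay rate
kB (order 0.1/min) rather than k itself (order 10⁻⁹ ml/min) because the
latter is far below the default finite-difference step scale; the result is
divided by B afterwards. Bounds are k ≥ 0, r ∈ [0, 1].

Reported fractions are clamped to [0, 1] (counting noise can push a ratio
slightly above 1); raw ratios are preserved on the result object.

## One-step growth

The latent period is detected as the last sampled time before the titer
first exceeds baseline × rise factor, with the baseline taken as the mean
of the first two post-resuspension samples and a default rise factor of
2.0. The assay defines the concept (interval between adsorption and first
progeny release) but no numeric rule; doubling is well above plating noise
at countable plaque numbers while still firing on the first rise sample.
On a 3-min grid this estimator is accurate to one sampling interval by
construction: it returns a value in [L−3, L] for a true latent period L.

Burst size = mean of the last 3 samples (the plateau) divided by infected
cells per ml. If the last 3 samples spread by more than 20% no plateau is
declared; the final sample is used alone and a warning emitted. Infected
cells are computed as total phage × adsorbed fraction under the single-hit
assumption, valid at MOI 0.001 where multiple infection is negligible; the
Poisson correction 1 − e^(−m) is available (`poisson_infected_fraction`)
but off by default.

## Host range and EOP

Activity calls are categorical: `propagates` (plaque formation /
amplification), `adsorbs_only` (streak-test positive without propagation),
`resistant`. "Adsorbs" in summaries counts the first two. EOP = test-strain
titer / host-strain titer, defined only for propagating pairs. Percentages
are rounded half-up to one decimal, the convention of the source reports.
The joint partition of two phages is {both propagate, both fully
resistant, everything else}; the three counts always sum to n.

`charkit.datasets.acinetobacter_panel()` is a synthetic reconstruction of a
34-strain panel: only aggregate counts were published, so the per-strain
grid is one concrete layout consistent with all of them (21/28 and 17/28
propagating, 25/28 and 20/28 adsorbing among A. baumannii, 15
both-propagate, 2 fully resistant, 6 non-baumannii strains resistant to
both). Per-strain identities and EOP values are placeholders.

## Resistant-mutant frequency

Frequency per replicate = colonies / cells plated; the denominator is the
number of cells plated (concentration × volume), not survivors, because
the challenge mixture is plated directly. Replicates are summarized by
mean and sample SD (n−1); a single replicate reports SD as null. The
generator draws colonies ~ Poisson(f·N) independently per replicate:
selection is applied at plating, so pre-existing-mutant jackpot
fluctuation (Luria–Delbrück) is deliberately out of model, and no
fluctuation-test rate estimation is attempted.

## Appelmans assays

A dilution plan maps tenfold dilution exponents to MOI:
stock·10^e / bacteria. The default plan (stock 10⁹ pfu/ml, exponents −2 to
−9, bacteria 10⁵ cfu/ml) spans MOI 100 down to 10⁻⁵. The lysis endpoint at
a time point is the most dilute tube whose replicate-mean OD600 is below
0.1 (the stability threshold, configurable); stability additionally
requires every tube at MOI ≥ 0.01 to be below threshold at 48 h. The
24 h and 48 h readings are treated as distinct tables with no
interpolation. Replicate SDs are carried for reporting only.

## Broth-infection generator

`simulate_appelmans` integrates a deliberately phenomenological mass-action
model per tube: four host subpopulations indexed by resistance genotype
(sensitive, resistant to phage A, to B, to both — loci independent) grow
logistically toward a shared carrying capacity; each phage adsorbs to its
susceptible subpopulations at rate k_ads·P and releases burst−1 net progeny
per infection. There is no latent-period delay and no debris/dead-cell
optical contribution: OD600 = od_per_cell × live cells + Gaussian read
noise (sd 0.01, small against reported assay SDs of 0.01–0.06). Updates
are multiplicative (exponential Euler, fixed step 0.01 h) so state stays
non-negative; the per-step phage log-growth is capped at 50 because once
phage vastly outnumber hosts the susceptible pool collapses on the next
step regardless.

Defaults: growth rate 0.67/h, carrying capacity 8.5×10⁸ cells/ml,
od_per_cell 10⁻⁹ (OD 0.85 at saturation), k_ads 7.2×10⁻⁸ ml/h (the
Acibel004 adsorption constant per hour), burst 125. `resistant_frequency`
(10⁻⁴) is an *effective* initial resistant fraction: in a deterministic
model it must absorb the mutants that would arise during 48 h of growth,
so it is orders of magnitude above plating mutant frequencies (~10⁻⁷) by
design.

What the model reproduces: the qualitative 24-h ordering control ≫ single
phages > mixture at every dilution, robustly against read noise, because
single-resistant subpopulations are visible by 24 h while double mutants
are not. Known limitation: by 48 h all resistant subpopulations saturate
at carrying capacity, so single-phage and mixture tubes converge — the
sustained 48-h mixture advantage seen in real broth assays (where
resistance arises stochastically and later) is not reproduced, and
generator-based mixture-vs-singles properties are therefore asserted at
24 h. Real OD tables are analyzed identically at both time points.

## fRFLP genotyping

Digestion finds all (possibly overlapping) occurrences of the recognition
motif on the forward strand — sufficient for the default HhaI site GCGC,
which is its own reverse complement — and cuts after `cut_offset` bases
(GCG^C → 3). Linear molecules give cuts+1 fragments summing to the genome
length; circular ones give one fragment per cut. Sites containing N never
match. The physical assay sizes only FAM-labelled fragments; the in silico
digest reports all fragments, a documented simplification.

Profile similarity is Dice band matching: each profile first discards
fragments shorter than 5% of its own longest fragment (the "noise floor",
interpreting gel noise reduction as a relative size cutoff), then
fragments are matched one-to-one greedily in ascending length order with a
1 bp tolerance; similarity = 2M/(n_a+n_b). The greedy two-pointer matching
is maximal for interval tolerances on sorted lists. This coefficient
stands in for unpublished gel-comparison software; tolerance and floor are
configurable. Distance = 1 − similarity feeds tree building.

Neighbor joining is the standard Saitou–Nei agglomeration on the
Q-criterion, implemented in-house so that tie-breaking is deterministic
(smallest Q, then lexicographic label pairs) and negative branch lengths
are clamped to zero; scikit-bio's implementation serves as an independent
cross-check in the test suite, and recovery of additive matrices from
known trees (n = 4, 5) is property-tested. Fewer than three taxa yield a
trivial tree.

Genome statistics: GC is computed over unambiguous bases (N excluded from
the denominator); coding percent is the covered fraction of the union of
1-based inclusive CDS intervals, strand-agnostic. Codon usage is counted
over concatenated CDS (trailing partial codons dropped with a warning),
scaled per 1000 codons, and compared at the codons decoded by supplied
tRNA anticodons under strict reverse complement (no wobble pairing).

## Plating-noise model

All titer generators draw Poisson counts at an automatically selected
tenfold dilution targeting the countable 30–300 range (standard plaque
assay practice) and rescale to pfu/ml. Consequences: relative noise is
roughly 6–18% per reading, and titers are quantized at the dilution scale.
The one-step generator models the rise linearly over a configurable 15-min
window between baseline (one infective center per infected cell) and
plateau (baseline + burst × infected); real rises are sigmoidal, which the
latent/burst estimators do not depend on.

## Problem sizes

Recovery tests and the acceptance script use 25 seeded replicates per
configuration (10–100 where the corresponding property dictates), 3–10 kb
synthetic genomes for digestion/clustering checks, and 100-genome
conservation sweeps — sizes chosen so the full suite exercises every
stochastic path while remaining desk-scale.

## Error handling conventions

Precondition violations raise `InvalidInputError` (or `SchemaError` for
malformed files, naming the column/row/record); degenerate analyses have
dedicated exceptions (`NoBurstError`, `DegenerateInputError`); recoverable
oddities (no plateau, excluded zero-titer points, dropped partial codons)
warn and proceed. CLI subcommands exit non-zero on any of these.
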