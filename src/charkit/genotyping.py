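"""In silico fRFLP genotyping and genome summary statistics.

Genomes are digested with a restriction enzyme (default HhaI, recognition
GCGC, cleaving GCG^C), fragment-length profiles are compared by a Dice
band-matching coefficient with a size tolerance and a noise floor, and the
resulting distance matrix (1 - similarity) is clustered with neighbor
joining.

The physical fRFLP assay sizes only fluorescently labelled fragments; the in
silico digest reports all fragments — a documented simplification.  The
band-matching coefficient here (greedy one-to-one matching in ascending
length order, Dice normalization) stands in for gel-comparison software
whose exact algorithm is unpublished.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "GenomeRecord",
    "Fingerprint",
    "DistanceMatrix",
    "digest",
    "fingerprint_similarity",
    "distance_matrix",
    "neighbor_joining",
    "genome_stats",
    "codon_usage_compare",
]

_VALID = set("ACGTN")
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    id: str
    sequence: str
    topology: str = "linear"  # or "circular"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise InvalidInputError(f"genome {self.id!r} is empty")
        bad = set(seq) - _VALID
        if bad:
            raise InvalidInputError(
                f"genome {self.id!r} contains non-ACGTN characters: {sorted(bad)}"
            )
        if self.topology not in ("linear", "circular"):
            raise InvalidInputError(f"unknown topology {self.topology!r}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Fingerprint:
    """Restriction-fragment length profile of one genome, descending order."""

    genome_id: str
    enzyme: str
    fragment_lengths: tuple[int, ...]
    noise_floor_applied: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "fragment_lengths",
            tuple(sorted(self.fragment_lengths, reverse=True)),
        )


def _find_sites(seq: str, motif: str) -> list[int]:
    """Start positions of all (possibly overlapping) motif occurrences."""
    sites, start = [], 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return sites
        sites.append(i)
        start = i + 1


def digest(
    genome: GenomeRecord,
    site: str = "GCGC",
    cut_offset: int = 3,
    enzyme: str = "HhaI",
) -> Fingerprint:
    """Fragment lengths from cutting at every motif occurrence.

    The default HhaI site GCGC is its own reverse complement, so scanning the
    forward strand finds every cut.  ``cut_offset`` is the position of the
    cut within the motif (GCG^C -> 3).  Occurrences containing N never match
    and are skipped.  Linear genomes yield cuts+1 fragments summing to the
    genome length; circular genomes yield one fragment per cut (or the whole
    genome if uncut).
    """
    motif = site.upper()
    if not motif:
        raise InvalidInputError("recognition motif must be non-empty")
    if not 0 <= cut_offset <= len(motif):
        raise InvalidInputError("cut_offset must lie within the motif")
    seq = genome.sequence
    cuts = sorted({s + cut_offset for s in _find_sites(seq, motif)})
    # drop cuts at the very ends of a linear molecule (zero-length fragments)
    n = len(seq)
    if genome.topology == "linear":
        bounds = [0] + [c for c in cuts if 0 < c < n] + [n]
        frags = [b - a for a, b in zip(bounds, bounds[1:])]
    else:
        if not cuts:
            frags = [n]
        else:
            frags = [b - a for a, b in zip(cuts, cuts[1:])]
            frags.append(n - cuts[-1] + cuts[0])
    return Fingerprint(genome.id, enzyme, tuple(frags))


def _noise_filter(lengths: tuple[int, ...], noise_frac: float) -> list[int]:
    if not lengths:
        return []
    floor = noise_frac * max(lengths)
    return sorted(l for l in lengths if l >= floor)


def fingerprint_similarity(
    a: Fingerprint,
    b: Fingerprint,
    tolerance_bp: int = 1,
    noise_frac: float = 0.05,
) -> float:
    """Dice band-matching similarity between two fragment profiles.

    Fragments shorter than ``noise_frac`` times the longest fragment of
    their own profile are discarded; remaining fragments are matched
    one-to-one greedily in ascending length order, two fragments matching
    when their lengths differ by at most ``tolerance_bp``.  Similarity is
    2M / (n_a + n_b) for M matched pairs.
    """
    if a.enzyme != b.enzyme:
        raise InvalidInputError(
            f"fingerprints from different enzymes: {a.enzyme!r} vs {b.enzyme!r}"
        )
    fa = _noise_filter(a.fragment_lengths, noise_frac)
    fb = _noise_filter(b.fragment_lengths, noise_frac)
    if not fa or not fb:
        warnings.warn("empty fingerprint after noise filtering", stacklevel=2)
        return 0.0
    i = j = m = 0
    while i < len(fa) and j < len(fb):
        d = fa[i] - fb[j]
        if abs(d) <= tolerance_bp:
            m += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return 2.0 * m / (len(fa) + len(fb))


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with zero diagonal, entries in [0, 1]."""

    labels: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise InvalidInputError("matrix shape must match label count")
        if not np.allclose(d, d.T, atol=1e-9):
            raise InvalidInputError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise InvalidInputError("distance matrix diagonal must be zero")
        if (d < 0).any():
            raise InvalidInputError("distances must be non-negative")
        self.values = d


def distance_matrix(
    fingerprints: list[Fingerprint],
    tolerance_bp: int = 1,
    noise_frac: float = 0.05,
) -> DistanceMatrix:
    """Pairwise band-matching distances (1 - Dice similarity)."""
    n = len(fingerprints)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = fingerprint_similarity(
                fingerprints[i], fingerprints[j], tolerance_bp, noise_frac
            )
            d[i, j] = d[j, i] = 1.0 - s
    return DistanceMatrix([f.genome_id for f in fingerprints], d)


def neighbor_joining(dm: DistanceMatrix) -> str:
    """Unrooted neighbor-joining tree (Saitou & Nei) in newick text.

    Q-criterion agglomeration with deterministic tie-breaking by label order;
    negative branch lengths are clamped to zero.  With fewer than three taxa
    a trivial tree is returned.
    """
    labels = list(dm.labels)
    d = dm.values.copy()
    n = len(labels)
    if n == 0:
        raise InvalidInputError("empty distance matrix")
    if n == 1:
        return f"({labels[0]}:0);"
    if n == 2:
        h = d[0, 1] / 2.0
        return f"({labels[0]}:{h:.6g},{labels[1]}:{h:.6g});"

    nodes = [f"{lab}" for lab in labels]  # newick strings under construction
    names = list(labels)  # tie-break keys
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                q = (m - 2) * sub[ii, jj] - r[ii] - r[jj]
                key = (q, *sorted((names[active[ii]], names[active[jj]])))
                if best is None or key < best[0]:
                    best = (key, ii, jj)
        _, ii, jj = best
        i, j = active[ii], active[jj]
        dij = sub[ii, jj]
        li = dij / 2.0 + (r[ii] - r[jj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = f"({nodes[i]}:{li:.6g},{nodes[j]}:{lj:.6g})"
        # distances from the new node u to every other active node
        du = {}
        for kk in active:
            if kk in (i, j):
                continue
            du[kk] = max((d[i, kk] + d[j, kk] - dij) / 2.0, 0.0)
        nodes.append(new)
        names.append(min(names[i], names[j]))
        u = len(nodes) - 1
        d = np.pad(d, ((0, 1), (0, 1)))
        for kk, val in du.items():
            d[u, kk] = d[kk, u] = val
        active = [a for a in active if a not in (i, j)] + [u]

    a, b, c = active
    la = max((d[a, b] + d[a, c] - d[b, c]) / 2.0, 0.0)
    lb = max((d[a, b] + d[b, c] - d[a, c]) / 2.0, 0.0)
    lc = max((d[a, c] + d[b, c] - d[a, b]) / 2.0, 0.0)
    return (
        f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g},{nodes[c]}:{lc:.6g});"
    )


def genome_stats(
    genome: GenomeRecord,
    cds_intervals: list[tuple[int, int]] | None = None,
) -> dict:
    """Length, G+C percent, and coding fraction of a genome.

    GC is computed over unambiguous bases only (N excluded from the
    denominator).  ``cds_intervals`` are 1-based inclusive coordinates;
    coding percent is the fraction of the genome covered by their union
    (strand-agnostic).
    """
    seq = genome.sequence
    counts = Counter(seq)
    acgt = sum(counts[b] for b in "ACGT")
    gc = 100.0 * (counts["G"] + counts["C"]) / acgt if acgt else 0.0
    out = {"length_bp": len(seq), "gc_percent": gc}
    if cds_intervals is not None:
        n = len(seq)
        covered = np.zeros(n, dtype=bool)
        for start, end in cds_intervals:
            if not (1 <= start <= end <= n):
                raise InvalidInputError(
                    f"CDS interval ({start}, {end}) outside genome bounds 1..{n}"
                )
            covered[start - 1 : end] = True
        out["coding_percent"] = 100.0 * covered.sum() / n
    return out


_RNA2DNA = str.maketrans("U", "T")


def anticodon_to_codon(anticodon: str) -> str:
    """Codon read by a tRNA anticodon: strict reverse complement, no wobble."""
    ac = anticodon.upper().translate(_RNA2DNA)
    if len(ac) != 3 or set(ac) - set("ACGT"):
        raise InvalidInputError(f"invalid anticodon {anticodon!r}")
    return revcomp(ac)


def codon_usage_compare(
    phage_cds: list[str],
    host_table: dict[str, float],
    trna_anticodons: list[str],
) -> dict:
    """Phage codon usage (per 1000 codons) versus a host codon-frequency table.

    CDS sequences are concatenated codon-wise; trailing partial codons are
    dropped with a warning.  Codons decoded by the supplied tRNA anticodons
    (strict reverse complement) are compared: for each, is the phage
    frequency higher than the host's?
    """
    if not phage_cds:
        raise InvalidInputError("empty CDS set")
    codons: Counter[str] = Counter()
    for cds in phage_cds:
        seq = cds.upper()
        if len(seq) % 3:
            warnings.warn(
                f"CDS length {len(seq)} not divisible by 3; trailing bases dropped",
                stacklevel=2,
            )
            seq = seq[: len(seq) - len(seq) % 3]
        codons.update(seq[i : i + 3] for i in range(0, len(seq), 3))
    total = sum(codons.values())
    if total == 0:
        raise InvalidInputError("no complete codons in CDS set")
    phage_freq = {c: 1000.0 * v / total for c, v in codons.items()}
    host = {c.upper().translate(_RNA2DNA): f for c, f in host_table.items()}

    matched = sorted({anticodon_to_codon(a) for a in trna_anticodons})
    comparison = []
    for codon in matched:
        pf = phage_freq.get(codon, 0.0)
        hf = host.get(codon, 0.0)
        comparison.append(
            {
                "codon": codon,
                "phage_freq": pf,
                "host_freq": hf,
                "higher_in_phage": pf > hf,
            }
        )
    return {
        "phage_table": phage_freq,
        "matched_codons": comparison,
        "n_matched": len(comparison),
        "n_higher_in_phage": sum(c["higher_in_phage"] for c in comparison),
    }
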