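"""Alignment summaries, haplotype collapsing, genetic distances, and
threshold-based species delimitation.

The species-count heuristic follows the barcoding convention used for
monogenean flatworms: haplotypes closer than a marker-specific divergence
cut-off (1% for nuclear ITS rDNA, 2% for mitochondrial COI) are treated
as conspecific, and the number of clusters of mutually-close haplotypes
estimates the number of species sampled.  Distances may be uncorrected
(p), Jukes-Cantor, or gamma-corrected Jukes-Cantor with a marker-specific
shape parameter (0.40 for ITS rDNA, 0.11 for COI by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .trees import DistanceMatrix

__all__ = [
    "SeqAlignment",
    "HaplotypeSet",
    "DistanceModel",
    "DelimitationConfig",
    "read_fasta_alignment",
    "alignment_stats",
    "collapse_haplotypes",
    "pairwise_distance",
    "distance_matrix",
    "delimit_species",
    "prune_similar",
    "calibrate_rate",
]

_UNAMBIGUOUS = frozenset("ACGT")

# gamma shape defaults per marker (ITS rDNA / COI)
GAMMA_SHAPE_ITS = 0.40
GAMMA_SHAPE_COI = 0.11

# delimitation divergence cut-offs per marker
THRESHOLD_ITS = 0.01
THRESHOLD_COI = 0.02


@dataclass
class SeqAlignment:
    """A rectangular DNA alignment over {A, C, G, T, -, N}."""

    labels: list[str]
    sequences: list[str]

    def __post_init__(self):
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences differ in count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate sequence labels")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        bad = set("".join(self.sequences)) - set("ACGT-N")
        if bad:
            raise ValueError(f"unexpected alignment characters: {sorted(bad)}")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def mask_codon_position(self, position: int) -> "SeqAlignment":
        """Drop one codon position (1, 2 or 3) from a protein-coding alignment."""
        if position not in (1, 2, 3):
            raise ValueError("codon position must be 1, 2 or 3")
        keep = [i for i in range(self.length) if i % 3 != position - 1]
        return SeqAlignment(
            list(self.labels), ["".join(s[i] for i in keep) for s in self.sequences]
        )


def read_fasta_alignment(path) -> SeqAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return SeqAlignment([r.id for r in records], [str(r.seq) for r in records])


def write_fasta(aln: SeqAlignment, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for label, seq in zip(aln.labels, aln.sequences):
            fh.write(f">{label}\n{seq}\n")


@dataclass
class HaplotypeSet:
    """Distinct sequences with multiplicities and member labels."""

    representatives: list[str]  # representative labels
    sequences: list[str]  # one per representative
    members: list[list[str]]  # input labels per haplotype

    @property
    def n_haplotypes(self) -> int:
        return len(self.representatives)

    @property
    def multiplicities(self) -> list[int]:
        return [len(m) for m in self.members]

    def to_alignment(self) -> SeqAlignment:
        return SeqAlignment(list(self.representatives), list(self.sequences))


@dataclass
class DistanceModel:
    """Distance correction: uncorrected p, Jukes-Cantor, or JC+Gamma."""

    kind: str = "p"  # "p" | "JC" | "JC+G"
    alpha: float | None = None

    def __post_init__(self):
        if self.kind not in ("p", "JC", "JC+G"):
            raise ValueError(f"unknown distance model {self.kind!r}")
        if self.kind == "JC+G":
            if self.alpha is None or self.alpha <= 0:
                raise ValueError("JC+G requires a gamma shape alpha > 0")


@dataclass
class DelimitationConfig:
    """Divergence threshold (as a fraction) and linkage rule."""

    threshold: float = THRESHOLD_ITS
    linkage: str = "single"  # "single" | "complete"

    def __post_init__(self):
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        if self.linkage not in ("single", "complete"):
            raise ValueError(f"unknown linkage rule {self.linkage!r}")


# ---------------------------------------------------------------------
# Alignment summaries
# ---------------------------------------------------------------------

def alignment_stats(aln: SeqAlignment) -> tuple[int, int, int]:
    """(alignment length, variable sites, parsimony-informative sites).

    A site is variable when it shows >= 2 distinct unambiguous states;
    parsimony-informative when >= 2 states each occur in >= 2 sequences.
    """
    if aln.n_sequences == 0:
        raise ValueError("empty alignment")
    n_var = n_pi = 0
    for col in zip(*aln.sequences):
        counts: dict[str, int] = {}
        for ch in col:
            if ch in _UNAMBIGUOUS:
                counts[ch] = counts.get(ch, 0) + 1
        if len(counts) >= 2:
            n_var += 1
            if sum(1 for c in counts.values() if c >= 2) >= 2:
                n_pi += 1
    return aln.length, n_var, n_pi


def collapse_haplotypes(aln: SeqAlignment) -> HaplotypeSet:
    """Merge identical sequences (case-insensitive) into haplotypes.

    The representative of each haplotype is the first label encountered
    in input order; member lists preserve input order.
    """
    groups: dict[str, list[str]] = {}
    for label, seq in zip(aln.labels, aln.sequences):
        groups.setdefault(seq, []).append(label)
    reps, seqs, members = [], [], []
    for seq, labels in groups.items():
        reps.append(labels[0])
        seqs.append(seq)
        members.append(labels)
    return HaplotypeSet(reps, seqs, members)


# ---------------------------------------------------------------------
# Pairwise distances
# ---------------------------------------------------------------------

def _p_distance(s1: str, s2: str) -> float:
    compared = mismatches = 0
    for a, b in zip(s1, s2):
        if a in _UNAMBIGUOUS and b in _UNAMBIGUOUS:
            compared += 1
            if a != b:
                mismatches += 1
    if compared == 0:
        raise ValueError("no comparable sites between sequences")
    return mismatches / compared


def pairwise_distance(s1: str, s2: str, model: DistanceModel | None = None) -> float:
    """Pairwise genetic distance with pairwise deletion of gaps and Ns.

    p: proportion of mismatching compared sites.
    JC: d = -(3/4) ln(1 - 4p/3).
    JC+G: d = (3 alpha / 4) [(1 - 4p/3)^(-1/alpha) - 1].
    """
    if len(s1) != len(s2):
        raise ValueError("sequences differ in length")
    model = model or DistanceModel("p")
    p = _p_distance(s1.upper(), s2.upper())
    if model.kind == "p":
        return p
    if p >= 0.75:
        raise ValueError(f"p-distance {p:.3f} >= 3/4: saturated under JC")
    if model.kind == "JC":
        return -0.75 * np.log1p(-4.0 * p / 3.0)
    a = model.alpha
    return 0.75 * a * ((1.0 - 4.0 * p / 3.0) ** (-1.0 / a) - 1.0)


def distance_matrix(aln: SeqAlignment, model: DistanceModel | None = None) -> DistanceMatrix:
    """All pairwise distances for an alignment, as a labeled matrix."""
    n = aln.n_sequences
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pairwise_distance(
                aln.sequences[i], aln.sequences[j], model
            )
    return DistanceMatrix(list(aln.labels), D)


# ---------------------------------------------------------------------
# Species delimitation and pruning
# ---------------------------------------------------------------------

def delimit_species(
    D: DistanceMatrix,
    cfg: DelimitationConfig | None = None,
    unit: str = "fraction",
) -> tuple[int, dict[str, int]]:
    """Count clusters of haplotypes closer than the divergence threshold.

    Under single linkage (default) two haplotypes are conspecific when a
    chain of pairwise distances < threshold connects them: the species
    count is the number of connected components of the d < threshold
    graph.  The threshold is a fraction; ``unit`` declares the scale of
    the matrix ("fraction" or "percent") and mismatched declarations
    raise.
    """
    cfg = cfg or DelimitationConfig()
    if unit == "fraction":
        values = D.values
    elif unit == "percent":
        values = D.values / 100.0
    else:
        raise ValueError(
            f"unit mismatch: matrix unit {unit!r} is neither 'fraction' nor "
            f"'percent' (threshold is a fraction)"
        )
    if D.n == 1:
        return 1, {D.labels[0]: 1}
    if cfg.linkage == "single":
        adj = values < cfg.threshold
        n_clusters, assignment = connected_components(adj, directed=False)
        assignment = assignment + 1
    else:
        Z = linkage(squareform(values, checks=False), method="complete")
        # fcluster merges at distance <= t; the rule is strict (< threshold)
        t = np.nextafter(cfg.threshold, 0.0)
        assignment = fcluster(Z, t=t, criterion="distance")
        n_clusters = len(set(assignment))
    return int(n_clusters), {lab: int(c) for lab, c in zip(D.labels, assignment)}


def prune_similar(
    haps: HaplotypeSet, D: DistanceMatrix, threshold: float = 0.01
) -> HaplotypeSet:
    """Greedy pruning of near-identical haplotypes for diversification input.

    Haplotypes are processed by decreasing multiplicity (ties broken by
    label order); one joins an existing representative when its distance
    to it is < threshold, otherwise it seeds a new cluster.  Returned
    haplotypes are the cluster seeds.
    """
    order = sorted(
        range(haps.n_haplotypes),
        key=lambda i: (-len(haps.members[i]), haps.representatives[i]),
    )
    rep_idx: list[int] = []
    for i in order:
        lab_i = haps.representatives[i]
        joined = False
        for j in rep_idx:
            if D[haps.representatives[j], lab_i] < threshold:
                joined = True
                break
        if not joined:
            rep_idx.append(i)
    rep_idx.sort(key=lambda i: haps.representatives[i])
    return HaplotypeSet(
        [haps.representatives[i] for i in rep_idx],
        [haps.sequences[i] for i in rep_idx],
        [list(haps.members[i]) for i in rep_idx],
    )


def calibrate_rate(d_lo: float, d_hi: float, T: float) -> tuple[float, float]:
    """Per-lineage substitution rate range (% per my) from a divergence range.

    A pairwise divergence d accumulated over T million years splits
    between the two diverging lineages, giving a per-lineage rate
    (d/2)/T; endpoints are rounded to one decimal.
    """
    if T <= 0:
        raise ValueError("calibration age T must be positive")
    if not 0 <= d_lo <= d_hi:
        raise ValueError("require 0 <= d_lo <= d_hi")
    return round(d_lo / 2.0 / T, 1), round(d_hi / 2.0 / T, 1)
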