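"""Three-allele distance phylogeny and molecular-clock dating.

Cloned Long, Short and Marine allele sequences are compared pairwise by
p-distance (mismatched aligned bases / aligned bases, gap and N columns
excluded) after global alignment.  The three pairwise distances imply a
three-taxon tree: the closest pair is sister, and terminal branch
lengths follow from the three-point formula
``b_X = (d_XY + d_XZ - d_YZ) / 2``, which reconstructs the input
distances exactly.  Given a per-lineage substitution rate
(substitutions/site/My) the split times are ``t = d / (2 rate)``.

No multiple-hit correction is applied: at p-distances near 0.02 the
correction is far below the alignment-choice uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

TAXA = ("Long", "Short", "Marine")


@dataclass(frozen=True)
class DistanceTriple:
    """Pairwise substitution rates among the Long, Short and Marine alleles."""

    d_LS: float
    d_SM: float
    d_LM: float

    def __post_init__(self):
        for name, d in (("d_LS", self.d_LS), ("d_SM", self.d_SM),
                        ("d_LM", self.d_LM)):
            if not 0 <= d <= 1:
                raise ValueError(f"{name}={d} outside [0, 1]")

    def between(self, a: str, b: str) -> float:
        pair = frozenset((a, b))
        return {frozenset(("Long", "Short")): self.d_LS,
                frozenset(("Short", "Marine")): self.d_SM,
                frozenset(("Long", "Marine")): self.d_LM}[pair]


@dataclass
class ThreeTaxonTree:
    sister: tuple[str, str]      # the pair with the smallest distance
    outgroup: str
    branches: dict[str, float]   # terminal branch length per taxon

    def newick(self) -> str:
        a, b = self.sister
        return (f"(({a}:{self.branches[a]:.6g},{b}:{self.branches[b]:.6g}):0,"
                f"{self.outgroup}:{self.branches[self.outgroup]:.6g});")

    def reconstructed_distance(self, a: str, b: str) -> float:
        return self.branches[a] + self.branches[b]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def substitution_rate(seq_a: str, seq_b: str) -> float:
    """p-distance between two sequences after global alignment.

    Mismatched aligned base pairs divided by aligned base pairs; columns
    containing a gap or an N are excluded from both numerator and
    denominator.  Symmetric in its arguments.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if not a or not b:
        raise ValueError("empty sequence")
    if a == b:
        return 0.0
    alignment = _make_aligner().align(a, b)[0]
    aligned = mismatches = 0
    col_a, col_b = alignment[0], alignment[1]
    for ca, cb in zip(col_a, col_b):
        if ca in "-N" or cb in "-N":
            continue
        aligned += 1
        if ca != cb:
            mismatches += 1
    if aligned == 0:
        raise ValueError("no aligned non-gap columns between the sequences")
    return mismatches / aligned


def distances_from_fasta(seqs: dict[str, str]) -> DistanceTriple:
    """Pairwise p-distances from a FASTA dict keyed Long / Short / Marine."""
    missing = set(TAXA) - set(seqs)
    if missing:
        raise ValueError(f"FASTA missing records: {sorted(missing)}")
    return DistanceTriple(
        d_LS=substitution_rate(seqs["Long"], seqs["Short"]),
        d_SM=substitution_rate(seqs["Short"], seqs["Marine"]),
        d_LM=substitution_rate(seqs["Long"], seqs["Marine"]))


def three_taxon_tree(d: DistanceTriple) -> ThreeTaxonTree:
    """Impute the three-taxon tree from a distance triple.

    The sister pair is the pair with the smallest pairwise distance
    (ties broken lexicographically by taxon names); terminal branches
    come from the three-point formula and negative implied branches are
    clamped to zero.
    """
    pairs = sorted(
        (("Long", "Short"), ("Long", "Marine"), ("Marine", "Short")),
        key=lambda p: (d.between(*p), p))
    sister = pairs[0]
    outgroup = next(t for t in TAXA if t not in sister)
    branches = {}
    for x in TAXA:
        y, z = (t for t in TAXA if t != x)
        b = (d.between(x, y) + d.between(x, z) - d.between(y, z)) / 2
        if b < -1e-12:
            import warnings
            warnings.warn(f"negative implied branch for {x}; clamped to 0")
        branches[x] = max(0.0, b)
    return ThreeTaxonTree(sister=sister, outgroup=outgroup, branches=branches)


def clock_dates(tree: ThreeTaxonTree, d: DistanceTriple,
                rate_per_lineage: float) -> dict[str, float]:
    """Divergence times (My) under a strict clock, t(X,Y) = d_XY / (2 rate).

    The sister split uses the sister-pair distance; the deeper split uses
    the mean of the two outgroup distances (their clock-implied times
    coincide only for exactly additive, ultrametric triples).
    """
    if rate_per_lineage <= 0:
        raise ValueError("rate must be positive")
    a, b = tree.sister
    d_sister = d.between(a, b)
    others = [d.between(tree.outgroup, t) for t in tree.sister]
    d_deep = sum(others) / 2
    return {
        "sister_split_mya": d_sister / (2 * rate_per_lineage),
        "deep_split_mya": d_deep / (2 * rate_per_lineage),
    }
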