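"""Synthetic genome cohorts with a planted species/subspecies hierarchy.

The generator draws a random ancestor at a configurable G+C content and
evolves it independently down a balanced hierarchy tree (species ->
subspecies -> strain by default) by per-branch substitutions (uniform over
the three alternative bases, i.e. Jukes-Cantor-like and composition
neutral), point indels with geometric lengths, and segment inversions.
Every run is fully reproducible from the seed and returns truth records:
the true tree, the planted partition at every level, and the expected
pairwise substitution fraction for each genome pair.

Under the uniform substitution model the probability that a site differs
between two leaves joined by branches with change probabilities p_1..p_m is

    E[mismatch] = 3/4 * (1 - prod_i (1 - 4 p_i / 3)),

which is what the truth record reports (indels and inversions do not enter:
they relocate sequence rather than change aligned identity).

The default hierarchy (3 species x 2 subspecies x 4 strains, 50 kb genomes)
is calibrated so that expected pairwise divergences map through the default
dDDH model onto the three diagnostic bands: ~0.019 within subspecies
(dDDH ~ 0.83, above the 0.80 band edge), ~0.0295 between subspecies of one
species (dDDH ~ 0.74, inside 0.72-0.78), and ~0.084 between species
(dDDH ~ 0.21, far below 0.60).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genomes import GenomeRecord
from .cluster import Partition

__all__ = [
    "Level",
    "SimConfig",
    "TruthRecord",
    "simulate_taxon_set",
    "evolve_sequence",
    "expected_mismatch_fraction",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class Level:
    """One hierarchy level: children per parent and the per-branch
    substitution probability applied on each child branch."""

    groups: int
    subst_p: float

    def __post_init__(self) -> None:
        if self.groups < 1:
            raise ValueError("each level needs >= 1 group per parent")
        if not 0.0 <= self.subst_p <= 1.0:
            raise ValueError("substitution probability must lie in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the last hierarchy level produces the strains."""

    seed: int = 0
    ancestor_length: int = 50_000
    gc: float = 0.50
    hierarchy: tuple[Level, ...] = (
        Level(3, 0.029),    # species branches
        Level(2, 0.00535),  # subspecies branches
        Level(4, 0.0096),   # strain branches
    )
    indel_rate: float = 1e-5        # point events per base per branch
    indel_mean_length: float = 3.0  # geometric mean indel length
    inversion_rate: float = 0.2     # expected inversions per branch
    inversion_length: tuple[int, int] = (500, 2000)

    def __post_init__(self) -> None:
        if self.ancestor_length <= 0:
            raise ValueError("ancestor_length must be positive")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must lie strictly inside (0, 1)")
        if not self.hierarchy:
            raise ValueError("hierarchy must have at least one level")
        if self.hierarchy[0].groups < 2:
            raise ValueError("need >= 2 terminal groups at the species level")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth accompanying a simulated cohort."""

    tree_newick: str
    partitions: tuple[Partition, ...]  # one per hierarchy level above strain
    expected_mismatch: dict[tuple[str, str], float]  # sorted-pair keyed

    def partition_at(self, level: int) -> Partition:
        return self.partitions[level]


def expected_mismatch_fraction(branch_ps: Sequence[float]) -> float:
    """Expected per-site mismatch between two leaves joined by these branches."""
    lam = 1.0
    for p in branch_ps:
        lam *= 1.0 - 4.0 * p / 3.0
    return 0.75 * (1.0 - lam)


def _rc(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def evolve_sequence(
    seq: str | np.ndarray,
    subst_p: float,
    indel_rate: float,
    indel_mean_len: float,
    inversions: float,
    rng: np.random.Generator,
    inversion_length: tuple[int, int] = (500, 2000),
    return_events: bool = False,
) -> str | np.ndarray | tuple:
    """One branch of evolution: substitutions, indels, inversions.

    Substitutions hit each position independently with probability
    ``subst_p`` and replace the base uniformly with one of the three
    alternatives (so at subst_p = 1 no position keeps its base).  Indel
    events occur as Poisson(indel_rate * length) point events, each an
    insertion or deletion with equal probability and geometric length of
    mean ``indel_mean_len``.  ``inversions`` is the expected (Poisson)
    number of segments to reverse-complement.  Accepts and returns either
    a string or an A/C/G/T code array; with ``return_events=True`` a ledger
    of (kind, position, length) tuples is returned alongside the sequence.
    """
    as_str = isinstance(seq, str)
    if as_str:
        codes = np.frombuffer(
            seq.translate(str.maketrans("ACGT", "\x00\x01\x02\x03")).encode(
                "latin1"
            ),
            dtype=np.uint8,
        ).copy()
    else:
        codes = np.asarray(seq, dtype=np.uint8).copy()

    events: list[tuple[str, int, int]] = []
    n = codes.size
    if subst_p > 0 and n:
        hits = np.flatnonzero(rng.random(n) < subst_p)
        if hits.size:
            shift = rng.integers(1, 4, size=hits.size).astype(np.uint8)
            codes[hits] = (codes[hits] + shift) % 4
            events.extend(("substitution", int(h), 1) for h in hits)

    if indel_rate > 0 and n:
        n_events = rng.poisson(indel_rate * n)
        for _ in range(n_events):
            pos = int(rng.integers(0, codes.size + 1))
            length = int(rng.geometric(1.0 / indel_mean_len))
            if rng.random() < 0.5:  # insertion of random sequence
                ins = rng.integers(0, 4, size=length).astype(np.uint8)
                codes = np.concatenate([codes[:pos], ins, codes[pos:]])
                events.append(("insertion", pos, length))
            else:
                deleted = min(length, codes.size - pos)
                codes = np.delete(codes, np.s_[pos : pos + length])
                events.append(("deletion", pos, deleted))

    if inversions > 0 and codes.size:
        lo, hi = inversion_length
        for _ in range(rng.poisson(inversions)):
            length = int(rng.integers(lo, hi + 1))
            length = min(length, codes.size)
            start = int(rng.integers(0, codes.size - length + 1))
            codes[start : start + length] = _rc(codes[start : start + length])
            events.append(("inversion", start, length))

    if as_str:
        result: str | np.ndarray = codes.tobytes().decode("latin1").translate(
            str.maketrans("\x00\x01\x02\x03", "ACGT")
        )
    else:
        result = codes
    return (result, events) if return_events else result


def _decode(codes: np.ndarray) -> str:
    return codes.tobytes().decode("latin1").translate(
        str.maketrans("\x00\x01\x02\x03", "ACGT")
    )


def simulate_taxon_set(
    config: SimConfig,
) -> tuple[list[GenomeRecord], TruthRecord]:
    """Simulate a genome cohort with planted hierarchical structure.

    Strain ids encode the path through the hierarchy ("t1-2-3" = species 1,
    subspecies 2, strain 3), so the planted partitions can be read off the
    labels as well as from the truth record.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    p_gc = config.gc / 2.0
    p_at = (1.0 - config.gc) / 2.0
    ancestor = rng.choice(
        4, size=config.ancestor_length, p=[p_at, p_gc, p_gc, p_at]
    ).astype(np.uint8)

    # evolve depth-first in deterministic order
    leaves: list[tuple[tuple[int, ...], np.ndarray]] = []
    newick_parts: list[str] = []

    def descend(codes: np.ndarray, path: tuple[int, ...], level: int) -> str:
        if level == len(config.hierarchy):
            sid = "t" + "-".join(str(i + 1) for i in path)
            leaves.append((path, codes))
            return sid
        lv = config.hierarchy[level]
        parts = []
        for child in range(lv.groups):
            child_codes = evolve_sequence(
                codes,
                lv.subst_p,
                config.indel_rate,
                config.indel_mean_length,
                config.inversion_rate,
                rng,
                config.inversion_length,
            )
            sub = descend(child_codes, path + (child,), level + 1)
            parts.append(f"{sub}:{lv.subst_p:g}")
        return "(" + ",".join(parts) + ")"

    newick = descend(ancestor, (), 0) + ";"

    genomes = [
        GenomeRecord("t" + "-".join(str(i + 1) for i in path), [("chr", _decode(c))])
        for path, c in leaves
    ]

    # planted partitions: one per level above the strain level
    partitions = []
    for level in range(len(config.hierarchy) - 1):
        groups: dict[tuple[int, ...], list[str]] = {}
        for path, _ in leaves:
            groups.setdefault(path[: level + 1], []).append(
                "t" + "-".join(str(i + 1) for i in path)
            )
        partitions.append(
            Partition.from_clusters([groups[k] for k in sorted(groups)])
        )

    # expected pairwise mismatch from the branch path between each leaf pair
    ps = [lv.subst_p for lv in config.hierarchy]
    expected: dict[tuple[str, str], float] = {}
    for (pa, _), (pb, _) in itertools.combinations(leaves, 2):
        split = 0
        while split < len(pa) and pa[split] == pb[split]:
            split += 1
        branch_ps = ps[split:] + ps[split:]  # both sides of the split
        ia = "t" + "-".join(str(i + 1) for i in pa)
        ib = "t" + "-".join(str(i + 1) for i in pb)
        key = tuple(sorted((ia, ib)))
        expected[key] = expected_mismatch_fraction(branch_ps)

    return genomes, TruthRecord(newick, tuple(partitions), expected)
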