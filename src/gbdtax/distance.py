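"""GBDP intergenomic distances, pairwise matrices and pseudo-bootstrap.

Given a trimmed (footprint-disjoint) HSP set between two genomes with
H = Σ HSP lengths, I = Σ identities and L = len_a + len_b, three distance
formulas are supported:

  coverage            d = 1 - 2H / L
  identities_per_hsp  d = 1 - I / H        ("formula 2"; default, the
                                            draft-genome recommendation)
  identities_per_total d = 1 - 2I / L

All distances are clamped to [0, 1].  With no HSPs at all the distance is 1
under every formula (no evidence of homology).

Pseudo-bootstrap support works by resampling HSPs (not alignment columns):
per replicate and pair, n = |HSPs| HSPs are drawn with replacement and the
distance recomputed.  Each (seed, replicate, pair) triple gets its own RNG
stream, so replicate matrices are reproducible and independent of the order
in which pairs are processed.
"""

from __future__ import annotations

import itertools
import warnings
import zlib
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .genomes import GenomeRecord
from .matching import HSPSet, MatchParams, find_hsps, greedy_with_trimming

__all__ = [
    "FORMULAS",
    "DistanceMatrix",
    "BootstrapSpec",
    "gbdp_distance",
    "pairwise_matrix",
    "bootstrap_matrices",
]

FormulaName = Literal["coverage", "identities_per_hsp", "identities_per_total"]

#: Formula aliases accepted wherever a formula name is expected.
FORMULAS: dict[str, FormulaName] = {
    "coverage": "coverage",
    "f1": "coverage",
    "identities_per_hsp": "identities_per_hsp",
    "f2": "identities_per_hsp",
    "formula2": "identities_per_hsp",
    "identities_per_total": "identities_per_total",
    "f3": "identities_per_total",
}


def resolve_formula(name: str) -> FormulaName:
    try:
        return FORMULAS[name]
    except KeyError:
        raise ValueError(
            f"unknown distance formula {name!r}; choose from {sorted(FORMULAS)}"
        ) from None


class DistanceMatrixError(ValueError):
    pass


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric labeled matrix of intergenomic distances in [0, 1]."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if v.shape != (n, n):
            raise DistanceMatrixError(
                f"matrix shape {v.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise DistanceMatrixError("duplicate labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise DistanceMatrixError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise DistanceMatrixError("diagonal is not zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise DistanceMatrixError("entries outside [0, 1]")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in matrix") from None

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices(len(self), k=1)
        return self.values[iu]

    def to_skbio(self):
        import skbio

        return skbio.DistanceMatrix(self.values, ids=list(self.labels))


@dataclass(frozen=True)
class BootstrapSpec:
    replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


def gbdp_distance(hsps: HSPSet, formula: str = "identities_per_hsp") -> float:
    """One intergenomic distance from a trimmed HSP set."""
    kind = resolve_formula(formula)
    if not hsps.is_footprint_disjoint():
        raise ValueError(
            "HSP set is not footprint-disjoint; run greedy_with_trimming first"
        )
    H = hsps.total_length
    I = hsps.total_identities
    L = hsps.len_a + hsps.len_b
    if kind == "coverage":
        return _clamp01(1.0 - 2.0 * H / L)
    if kind == "identities_per_total":
        return _clamp01(1.0 - 2.0 * I / L)
    if H == 0:
        warnings.warn(
            f"pair {hsps.pair}: no HSPs; identities_per_hsp distance set to 1"
        )
        return 1.0
    return _clamp01(1.0 - I / H)


HSPCache = Mapping[tuple[str, str], HSPSet]


def pairwise_hsp_sets(
    genomes: Sequence[GenomeRecord],
    params: MatchParams | None = None,
    trim_min_length: int | None = None,
) -> dict[tuple[str, str], HSPSet]:
    """Trimmed HSP sets for every unordered genome pair, keyed by sorted ids."""
    params = params or MatchParams()
    if trim_min_length is None:
        trim_min_length = params.min_length
    ids = [g.strain_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate strain ids in genome set")
    by_id = {g.strain_id: g for g in genomes}
    cache: dict[tuple[str, str], HSPSet] = {}
    for ia, ib in itertools.combinations(sorted(ids), 2):
        raw = find_hsps(by_id[ia], by_id[ib], params)
        cache[(ia, ib)] = greedy_with_trimming(
            raw, trim_min_length, (params.match, params.mismatch)
        )
    return cache


def matrix_from_cache(
    labels: Sequence[str],
    cache: HSPCache,
    formula: str = "identities_per_hsp",
) -> DistanceMatrix:
    n = len(labels)
    v = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        key = tuple(sorted((labels[i], labels[j])))
        v[i, j] = v[j, i] = gbdp_distance(cache[key], formula)
    return DistanceMatrix(tuple(labels), v)


def pairwise_matrix(
    genomes: Sequence[GenomeRecord],
    formula: str = "identities_per_hsp",
    params: MatchParams | None = None,
) -> tuple[DistanceMatrix, dict[tuple[str, str], HSPSet]]:
    """Full distance matrix plus the per-pair trimmed HSP cache.

    Each unordered pair is aligned once; label order follows the input
    genome order.
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    cache = pairwise_hsp_sets(genomes, params)
    labels = [g.strain_id for g in genomes]
    return matrix_from_cache(labels, cache, formula), cache


def _pair_rng(seed: int, replicate: int, pair: tuple[str, str]) -> np.random.Generator:
    """Stable per-(seed, replicate, pair) RNG stream."""
    tag = zlib.crc32("\x00".join(sorted(pair)).encode())
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(replicate), int(tag)])
    )


def resample_distance(
    hsps: HSPSet,
    formula: str,
    rng: np.random.Generator,
) -> float:
    """Distance after resampling n HSPs with replacement (one replicate)."""
    n = len(hsps.hsps)
    if n == 0:
        return 1.0
    idx = rng.integers(0, n, size=n)
    lengths = np.array([h.length for h in hsps.hsps])
    idents = np.array([h.identities for h in hsps.hsps])
    H = int(lengths[idx].sum())
    I = int(idents[idx].sum())
    L = hsps.len_a + hsps.len_b
    kind = resolve_formula(formula)
    if kind == "coverage":
        return _clamp01(1.0 - 2.0 * H / L)
    if kind == "identities_per_total":
        return _clamp01(1.0 - 2.0 * I / L)
    return 1.0 if H == 0 else _clamp01(1.0 - I / H)


def bootstrap_matrices(
    labels: Sequence[str],
    cache: HSPCache,
    formula: str = "identities_per_hsp",
    spec: BootstrapSpec | None = None,
) -> list[DistanceMatrix]:
    """Pseudo-bootstrap replicate distance matrices by HSP resampling."""
    spec = spec or BootstrapSpec()
    for i, j in itertools.combinations(sorted(labels), 2):
        if (i, j) not in cache:
            raise ValueError(f"HSP cache is missing pair ({i}, {j})")
    out = []
    n = len(labels)
    for rep in range(spec.replicates):
        v = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            key = tuple(sorted((labels[i], labels[j])))
            rng = _pair_rng(spec.seed, rep, key)
            v[i, j] = v[j, i] = resample_distance(cache[key], formula, rng)
        out.append(DistanceMatrix(tuple(labels), v))
    return out
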