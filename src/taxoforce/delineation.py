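"""Genus delineation by threshold-stable single-linkage clustering.

A similarity matrix (typically AAI, percent scale) is clustered at every
observed off-diagonal value: the partition at threshold ``t`` is the set of
connected components of the graph whose edges join genome pairs with
similarity ≥ t.  Because the partition only changes when ``t`` crosses an
observed value, the threshold axis decomposes into *stable intervals*, each
carrying one partition.  Candidate intervals are then scored against a
reference grouping (e.g. a phylogenomic tree's clades) and ranked; the
top-ranked interval is the proposed genus boundary.

The model front-end follows the statsmodels convention::

    model = GenusDelineation(matrix, reference=groups)
    res = model.fit()
    res.summary()
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "SimilarityMatrix",
    "Partition",
    "StableInterval",
    "CandidateEvaluation",
    "GenusDelineation",
    "DelineationResults",
    "cluster_at_threshold",
    "enumerate_stable_intervals",
    "adjusted_rand_index",
    "evaluate_candidates",
    "export_dendrogram",
]


@dataclass
class SimilarityMatrix:
    """Symmetric genome × genome matrix of a percent-scale relatedness index.

    Off-diagonal values are rounded to 2 decimals on construction, matching
    the precision of published AAI tables and preventing float noise from
    splitting stable intervals.  The diagonal is fixed at 100 and ignored.
    """

    genomes: list[str]
    values: np.ndarray
    index_kind: str = "AAI"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.genomes)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} genomes")
        if len(set(self.genomes)) != n:
            raise ValueError("duplicate genome labels")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("similarity matrix is not symmetric")
        v = np.round(v, 2)
        off = v[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < 0 or off.max() > 100):
            raise ValueError("off-diagonal similarities must lie in [0, 100]")
        np.fill_diagonal(v, 100.0)
        self.values = v

    @property
    def n(self) -> int:
        return len(self.genomes)

    def off_diagonal_values(self) -> np.ndarray:
        """Sorted distinct off-diagonal values."""
        mask = ~np.eye(self.n, dtype=bool)
        return np.unique(self.values[mask])


class Partition:
    """A clustering of genomes into disjoint blocks."""

    def __init__(self, blocks: Iterable[Iterable[str]]):
        self.blocks = [frozenset(b) for b in blocks]
        if any(not b for b in self.blocks):
            raise ValueError("empty block")
        all_genomes = [g for b in self.blocks for g in b]
        if len(all_genomes) != len(set(all_genomes)):
            raise ValueError("blocks are not disjoint")
        self._genomes = frozenset(all_genomes)

    @classmethod
    def from_labels(cls, genomes: Sequence[str], labels: Sequence[int]) -> "Partition":
        blocks: dict[int, set[str]] = {}
        for g, lab in zip(genomes, labels):
            blocks.setdefault(lab, set()).add(g)
        return cls(blocks.values())

    @classmethod
    def from_mapping(cls, mapping: dict[str, str]) -> "Partition":
        blocks: dict[str, set[str]] = {}
        for g, grp in mapping.items():
            blocks.setdefault(grp, set()).add(g)
        return cls(blocks.values())

    @property
    def genomes(self) -> frozenset:
        return self._genomes

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_singletons(self) -> int:
        return sum(1 for b in self.blocks if len(b) == 1)

    def labels_for(self, genomes: Sequence[str]) -> list[int]:
        lookup = {g: i for i, b in enumerate(self.blocks) for g in b}
        return [lookup[g] for g in genomes]

    def restrict(self, genomes: Iterable[str]) -> "Partition":
        keep = set(genomes)
        blocks = [b & keep for b in self.blocks if b & keep]
        return Partition(blocks)

    def same_block(self, a: str, b: str) -> bool:
        return any(a in blk and b in blk for blk in self.blocks)

    def __eq__(self, other) -> bool:
        return isinstance(other, Partition) and set(self.blocks) == set(other.blocks)

    def __hash__(self) -> int:
        return hash(frozenset(self.blocks))

    def __repr__(self) -> str:
        return f"Partition({self.n_blocks} blocks, {len(self._genomes)} genomes)"


@dataclass
class StableInterval:
    """A maximal threshold range over which the partition is unchanged.

    ``lower`` and ``upper`` are the observed matrix values bounding the
    stable run (display ``[lo–hi]``); ``prev_value`` is the largest observed
    value below the run (None for the first interval).  Any threshold ``t``
    with ``prev_value < t ≤ upper`` yields this partition under the edge
    rule S ≥ t, so the full validity range is :attr:`threshold_range`.
    """

    lower: float
    upper: float
    partition: Partition
    prev_value: float | None = None

    @property
    def n_clusters(self) -> int:
        return self.partition.n_blocks

    @property
    def width(self) -> float:
        return self.upper - self.lower

    @property
    def threshold_range(self) -> tuple[float, float]:
        """Half-open (lo, hi]: every threshold in it yields this partition."""
        lo = self.prev_value if self.prev_value is not None else 0.0
        return (lo, self.upper)

    def __repr__(self) -> str:
        return f"StableInterval([{self.lower:.2f}–{self.upper:.2f}], {self.n_clusters} clusters)"


@dataclass
class CandidateEvaluation:
    interval: StableInterval
    ari_vs_reference: float
    exact_match: bool
    n_singletons: int
    forbidden_merges: list[tuple[str, str]] = field(default_factory=list)
    rank: int = 0


def cluster_at_threshold(S: SimilarityMatrix, t: float) -> Partition:
    """Single-linkage partition at threshold ``t``: connected components of
    the graph with edges where similarity ≥ t."""
    if not (0 < t <= 100):
        raise ValueError(f"threshold {t} outside (0, 100]")
    n = S.n
    adj = (S.values >= t) & ~np.eye(n, dtype=bool)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return Partition.from_labels(S.genomes, labels)


def enumerate_stable_intervals(S: SimilarityMatrix) -> list[StableInterval]:
    """Enumerate all threshold-stable partitions of ``S``.

    The partition is evaluated at each distinct off-diagonal value; maximal
    runs of identical partitions are merged into one interval spanning the
    run's observed values.  Cluster counts are non-decreasing along the list.
    """
    if S.n < 2:
        return []
    values = S.off_diagonal_values()
    intervals: list[StableInterval] = []
    run_start = None
    run_prev = None
    prev_partition = None
    prev_value = None
    for v in values:
        part = cluster_at_threshold(S, float(v))
        if part != prev_partition:
            if prev_partition is not None:
                intervals.append(
                    StableInterval(
                        float(run_start), float(prev_value), prev_partition, run_prev
                    )
                )
            run_prev = float(prev_value) if prev_value is not None else None
            run_start = v
            prev_partition = part
        prev_value = v
    intervals.append(
        StableInterval(float(run_start), float(prev_value), prev_partition, run_prev)
    )
    return intervals


def adjusted_rand_index(p: Partition, q: Partition) -> float:
    """Adjusted Rand index between two partitions of the same genome set."""
    if p.genomes != q.genomes:
        raise ValueError("partitions cover different genome sets")
    genomes = sorted(p.genomes)
    if p == q:
        return 1.0
    return float(adjusted_rand_score(p.labels_for(genomes), q.labels_for(genomes)))


def evaluate_candidates(
    intervals: Sequence[StableInterval],
    reference: Partition,
    forbidden_merge_pairs: Sequence[tuple[str, str]] = (),
    max_singleton_fraction: float | None = None,
) -> list[CandidateEvaluation]:
    """Score stable intervals against a reference grouping and rank them.

    Ordering: ARI (desc), forbidden merges (asc), singleton count (asc),
    interval width (desc).  Evaluation is restricted to the genomes shared by
    the matrix and the reference; an empty intersection is an error.
    """
    if not intervals:
        return []
    matrix_genomes = intervals[0].partition.genomes
    common = matrix_genomes & reference.genomes
    if not common:
        raise ValueError("reference grouping shares no genomes with the matrix")
    ref = reference.restrict(common)

    evals: list[CandidateEvaluation] = []
    for iv in intervals:
        part = iv.partition.restrict(common)
        ari = adjusted_rand_index(part, ref)
        merges = [
            (a, b)
            for a, b in forbidden_merge_pairs
            if a in common and b in common and part.same_block(a, b)
        ]
        evals.append(
            CandidateEvaluation(
                interval=iv,
                ari_vs_reference=ari,
                exact_match=(part == ref),
                n_singletons=part.n_singletons,
                forbidden_merges=merges,
            )
        )
    order = sorted(
        range(len(evals)),
        key=lambda i: (
            -evals[i].ari_vs_reference,
            len(evals[i].forbidden_merges),
            evals[i].n_singletons,
            -evals[i].interval.width,
        ),
    )
    for rank, i in enumerate(order, start=1):
        evals[i].rank = rank
    if max_singleton_fraction is not None:
        n = len(common)
        for e in evals:
            if e.n_singletons / n > max_singleton_fraction and e.rank == 1:
                warnings.warn(
                    "rank-1 interval exceeds the singleton-fraction constraint"
                )
    return evals


def _single_linkage(S: SimilarityMatrix):
    D = 100.0 - S.values
    np.fill_diagonal(D, 0.0)
    return linkage(squareform(D, checks=False), method="single")


def cut_dendrogram(S: SimilarityMatrix, t: float) -> Partition:
    """Cut the single-linkage merge tree at distance 100 − t (test hook:
    must agree with :func:`cluster_at_threshold`)."""
    Z = _single_linkage(S)
    labels = fcluster(Z, t=100.0 - t, criterion="distance")
    return Partition.from_labels(S.genomes, labels)


def export_dendrogram(S: SimilarityMatrix) -> str:
    """Ultrametric newick string of the single-linkage merge tree.

    Node height is half the merge distance (100 − similarity)/2, so two
    genomes with similarity 80 sit at depth 10 each.  Cutting the tree at
    height (100 − t)/2 reproduces ``cluster_at_threshold(S, t)``.
    """
    if S.n < 2:
        raise ValueError("need at least 2 genomes for a dendrogram")
    Z = _single_linkage(S)
    n = S.n
    heights = {i: 0.0 for i in range(n)}
    newick = {i: S.genomes[i] for i in range(n)}
    for k, (a, b, dist, _) in enumerate(Z):
        a, b = int(a), int(b)
        h = dist / 2.0
        node = n + k
        la = h - heights[a]
        lb = h - heights[b]
        newick[node] = f"({newick[a]}:{la:.6g},{newick[b]}:{lb:.6g})"
        heights[node] = h
    return newick[n + len(Z) - 1] + ";"


class GenusDelineation:
    """Threshold-interval genus-delineation model for a similarity matrix.

    Parameters
    ----------
    similarity
        Symmetric percent-scale matrix (typically AAI).
    reference
        Reference grouping (e.g. phylogenomic clades) used to score candidate
        intervals; optional — without it :meth:`fit` only enumerates intervals.
    forbidden_pairs
        Genome pairs that must never be merged into one genus.
    max_singleton_fraction
        Soft constraint used to flag candidate partitions dominated by
        single-member groups.
    """

    def __init__(
        self,
        similarity: SimilarityMatrix,
        reference: Partition | None = None,
        forbidden_pairs: Sequence[tuple[str, str]] = (),
        max_singleton_fraction: float | None = None,
    ):
        if similarity.n < 2:
            raise ValueError("need at least 2 genomes")
        self.similarity = similarity
        self.reference = reference
        self.forbidden_pairs = list(forbidden_pairs)
        self.max_singleton_fraction = max_singleton_fraction

    def fit(self) -> "DelineationResults":
        intervals = enumerate_stable_intervals(self.similarity)
        evaluations = None
        if self.reference is not None:
            evaluations = evaluate_candidates(
                intervals,
                self.reference,
                forbidden_merge_pairs=self.forbidden_pairs,
                max_singleton_fraction=self.max_singleton_fraction,
            )
        return DelineationResults(self, intervals, evaluations)


class DelineationResults:
    """Fitted delineation: stable intervals and (optionally) their ranking."""

    def __init__(self, model, intervals, evaluations):
        self.model = model
        self.intervals = intervals
        self.evaluations = evaluations

    @property
    def optimal(self) -> CandidateEvaluation:
        if self.evaluations is None:
            raise ValueError("no reference grouping was supplied; nothing ranked")
        return min(self.evaluations, key=lambda e: e.rank)

    def partition_at(self, t: float) -> Partition:
        return cluster_at_threshold(self.model.similarity, t)

    def to_newick(self) -> str:
        return export_dendrogram(self.model.similarity)

    def summary(self) -> pd.DataFrame:
        """One row per stable interval: bounds, cluster count and, when a
        reference was supplied, the evaluation columns."""
        rows = []
        ev_by_iv = {}
        if self.evaluations is not None:
            ev_by_iv = {id(e.interval): e for e in self.evaluations}
        for iv in self.intervals:
            row = {
                "lower": iv.lower,
                "upper": iv.upper,
                "n_clusters": iv.n_clusters,
            }
            e = ev_by_iv.get(id(iv))
            if e is not None:
                row.update(
                    ari=e.ari_vs_reference,
                    n_singletons=e.n_singletons,
                    forbidden_merges=len(e.forbidden_merges),
                    rank=e.rank,
                    exact_match=e.exact_match,
                )
            rows.append(row)
        return pd.DataFrame(rows)
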