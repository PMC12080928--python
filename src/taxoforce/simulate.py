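"""Ground-truthed synthetic inputs for every analysis stage.

Three generators emulate the statistical structure the pipeline assumes:

* :func:`simulate_similarity_matrix` — symmetric AAI-like matrices with
  planted genus blocks: intra-genus values drawn from one percent range,
  inter-genus values from a lower one.  In separable scenarios the two
  ranges do not overlap, so a threshold gap exists and the planted partition
  is recoverable exactly.
* :func:`simulate_pangenome` — binary genome × CDS matrices with core genes
  (present everywhere), clade-driven accessory genes (phylogenetic forcing),
  habitat-driven genes present with a stated penetrance inside their habitat
  and a background rate elsewhere (environmental forcing), plus optional
  Bernoulli bit-flip noise on the core/clade columns.
* :func:`simulate_proteome_pair` — a proteome and a per-site-substituted
  copy at a target amino-acid identity, with exact-aligner hit tables, for
  testing AAI/POCP machinery.

Default configurations mirror the study design the pipeline targets: a
38-genome matrix split into 17 genus groups, and a 16-genome pangenome over
six habitats (six sponge, two coral, two flatworm, one eelgrass, four
seawater, one sediment isolate).

Reproducibility: one global integer seed feeds a named-substream scheme
(each generator draws from ``default_rng([seed, stream_id])``), so stages
are reproducible independently of each other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import HabitatDesign, HitRecord, PresenceAbsenceMatrix, ProteomeRecord
from .delineation import Partition, SimilarityMatrix

__all__ = [
    "MatrixSimConfig",
    "PangenomeSimConfig",
    "SimTruth",
    "simulate_similarity_matrix",
    "simulate_pangenome",
    "simulate_proteome_pair",
    "study_matrix_config",
    "study_pangenome_config",
    "study_habitat_design",
]

_STREAM_MATRIX = 11
_STREAM_PANGENOME = 13
_STREAM_PROTEOME = 17

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


@dataclass
class MatrixSimConfig:
    """Planted-genus similarity-matrix scenario.

    ``intra_range`` / ``inter_range`` are [lo, hi] percent bounds for
    within- and between-genus values; with ``separable`` (default) the
    ranges must not overlap, guaranteeing a clean threshold gap.
    ``distribution`` is ``"uniform"`` or ``("truncated_normal", mean, sd)``.
    """

    genus_sizes: Sequence[int]
    intra_range: tuple[float, float] = (85.0, 95.0)
    inter_range: tuple[float, float] = (60.0, 70.0)
    distribution: object = "uniform"
    seed: int = 0
    separable: bool = True

    def __post_init__(self):
        if not self.genus_sizes or any(s < 1 for s in self.genus_sizes):
            raise ValueError("genus sizes must all be ≥ 1")
        for lo, hi in (self.intra_range, self.inter_range):
            if not (0 <= lo <= hi <= 100):
                raise ValueError("ranges must satisfy 0 ≤ lo ≤ hi ≤ 100")
        if self.separable and self.inter_range[1] >= self.intra_range[0]:
            raise ValueError(
                "separable scenario requires inter_range.hi < intra_range.lo"
            )


@dataclass
class PangenomeSimConfig:
    """Planted pangenome scenario: core + clade (phylogenetic) + habitat genes."""

    habitat_assignment: dict[str, str]
    clade_structure: Sequence[Sequence[str]]
    n_core: int = 2000
    n_phylo_per_clade: int = 400
    n_habitat_genes_per_habitat: int = 100
    penetrance: float = 0.9
    background: float = 0.05
    noise_flip: float = 0.01
    seed: int = 0

    @property
    def n_genomes(self) -> int:
        return len(self.habitat_assignment)

    def __post_init__(self):
        if not self.habitat_assignment:
            raise ValueError("zero genomes")
        if not set(self.habitat_assignment.values()):
            raise ValueError("zero habitats")
        for p in (self.penetrance, self.background, self.noise_flip):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        genomes = set(self.habitat_assignment)
        for clade in self.clade_structure:
            unknown = set(clade) - genomes
            if unknown:
                raise ValueError(f"clade members not in the genome set: {unknown}")


@dataclass
class SimTruth:
    """Planted ground truth attached to a simulated dataset."""

    partition: Partition | None = None
    gap_interval: tuple[float, float] | None = None
    gene_labels: dict[str, str] = field(default_factory=dict)

    def genes_of(self, label_prefix: str) -> set[str]:
        return {g for g, lab in self.gene_labels.items() if lab.startswith(label_prefix)}


def _draw(rng: np.random.Generator, lo: float, hi: float, size: int, distribution) -> np.ndarray:
    if distribution == "uniform":
        vals = rng.uniform(lo, hi, size)
    elif isinstance(distribution, tuple) and distribution[0] == "truncated_normal":
        from scipy.stats import truncnorm

        _, mean, sd = distribution
        a, b = (lo - mean) / sd, (hi - mean) / sd
        vals = truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    return np.round(vals, 2)  # published AAI tables carry 2 decimals


def simulate_similarity_matrix(cfg: MatrixSimConfig) -> tuple[SimilarityMatrix, SimTruth]:
    """Symmetric percent matrix with planted genus blocks.

    The truth records the planted partition and, in separable scenarios, the
    exact gap ``(max drawn inter value, min drawn intra value)`` — the open
    threshold region with no observed values, inside which any cut recovers
    the planted partition.
    """
    rng = _rng(cfg.seed, _STREAM_MATRIX)
    sizes = list(cfg.genus_sizes)
    n = sum(sizes)
    genomes = [f"g{i + 1:03d}" for i in range(n)]
    genus_of = np.repeat(np.arange(len(sizes)), sizes)

    values = np.full((n, n), 100.0)
    iu = np.triu_indices(n, k=1)
    same = genus_of[iu[0]] == genus_of[iu[1]]
    intra = _draw(rng, *cfg.intra_range, int(same.sum()), cfg.distribution)
    inter = _draw(rng, *cfg.inter_range, int((~same).sum()), cfg.distribution)
    upper = np.empty(iu[0].size)
    upper[same] = intra
    upper[~same] = inter
    values[iu] = upper
    values[(iu[1], iu[0])] = upper

    matrix = SimilarityMatrix(genomes=genomes, values=values, index_kind="AAI")
    blocks = [
        {genomes[i] for i in range(n) if genus_of[i] == k} for k in range(len(sizes))
    ]
    gap = None
    if cfg.separable and intra.size and inter.size:
        gap = (float(inter.max()), float(intra.min()))
    truth = SimTruth(partition=Partition(blocks), gap_interval=gap)
    return matrix, truth


def simulate_pangenome(
    cfg: PangenomeSimConfig,
) -> tuple[PresenceAbsenceMatrix, HabitatDesign, SimTruth]:
    """Binary pangenome with planted core, clade-driven and habitat-driven genes.

    Habitat genes are Bernoulli(penetrance) inside their habitat's genomes
    and Bernoulli(background) elsewhere; core and clade columns are
    bit-flipped with probability ``noise_flip``.  Rows that end up all-zero
    are regenerated (with a warning); columns are labelled with their truth
    so recovery can be scored.
    """
    import pandas as pd

    rng = _rng(cfg.seed, _STREAM_PANGENOME)
    genomes = list(cfg.habitat_assignment)
    n = len(genomes)
    gidx = {g: i for i, g in enumerate(genomes)}
    habitats = list(dict.fromkeys(cfg.habitat_assignment.values()))

    cols: list[np.ndarray] = []
    labels: list[str] = []

    for k in range(cfg.n_core):
        cols.append(np.ones(n, dtype=np.int8))
        labels.append(f"core_{k + 1:05d}")
    for ci, clade in enumerate(cfg.clade_structure):
        member = np.zeros(n, dtype=np.int8)
        for g in clade:
            member[gidx[g]] = 1
        for k in range(cfg.n_phylo_per_clade):
            cols.append(member.copy())
            labels.append(f"phylo_c{ci + 1}_{k + 1:05d}")
    n_structural = len(cols)
    for h in habitats:
        inside = np.array(
            [cfg.habitat_assignment[g] == h for g in genomes], dtype=bool
        )
        for k in range(cfg.n_habitat_genes_per_habitat):
            col = np.where(
                inside,
                rng.random(n) < cfg.penetrance,
                rng.random(n) < cfg.background,
            ).astype(np.int8)
            cols.append(col)
            labels.append(f"hab_{h}_{k + 1:05d}")

    M = np.column_stack(cols) if cols else np.zeros((n, 0), dtype=np.int8)
    if cfg.noise_flip > 0 and n_structural:
        flips = rng.random((n, n_structural)) < cfg.noise_flip
        M[:, :n_structural] ^= flips.astype(np.int8)

    zero_rows = np.flatnonzero(M.sum(axis=1) == 0)
    if zero_rows.size:
        warnings.warn(f"regenerating {zero_rows.size} all-zero genome rows")
        for i in zero_rows:
            M[i, : min(1, M.shape[1])] = 1

    pa = PresenceAbsenceMatrix(pd.DataFrame(M, index=genomes, columns=labels))
    design = HabitatDesign(dict(cfg.habitat_assignment))
    truth = SimTruth(gene_labels=dict(zip(labels, labels)))
    # gene_labels maps column -> truth class prefix (core / phylo_cK / hab_H)
    truth.gene_labels = {
        lab: lab.rsplit("_", 1)[0] for lab in labels
    }
    return pa, design, truth


def simulate_proteome_pair(
    target_aai: float, n_proteins: int = 50, length: int = 300, seed: int = 0
) -> tuple[ProteomeRecord, ProteomeRecord, list[HitRecord], list[HitRecord]]:
    """A proteome and its per-site-substituted copy at a target identity.

    Each site of each protein of B differs from A with probability
    1 − target/100 (substitutions to a uniformly chosen different residue).
    The returned hit tables are exact: identity is counted directly from the
    mismatches, the bit score is proportional to the match count, and each
    protein hits only its ortholog.
    """
    if not (30 < target_aai <= 100):
        raise ValueError("target_aai must lie in (30, 100]")
    rng = _rng(seed, _STREAM_PROTEOME)
    sub_rate = 1.0 - target_aai / 100.0

    prots_a: dict[str, str] = {}
    prots_b: dict[str, str] = {}
    hits_ab: list[HitRecord] = []
    hits_ba: list[HitRecord] = []
    for k in range(n_proteins):
        a = rng.choice(_AA, size=length)
        b = a.copy()
        mutate = rng.random(length) < sub_rate
        if mutate.any():
            # substitute with a residue guaranteed different from the original
            shift = rng.integers(1, len(_AA), size=int(mutate.sum()))
            orig_idx = np.searchsorted(_AA, b[mutate])
            b[mutate] = _AA[(orig_idx + shift) % len(_AA)]
        pa_id, pb_id = f"a{k + 1:04d}", f"b{k + 1:04d}"
        prots_a[pa_id] = "".join(a)
        prots_b[pb_id] = "".join(b)
        matches = int((a == b).sum())
        pident = round(100.0 * matches / length, 4)
        common = dict(
            pident=pident,
            aln_length=length,
            mismatch=length - matches,
            gapopen=0,
            qstart=1,
            qend=length,
            sstart=1,
            send=length,
            evalue=1e-180,
            bitscore=round(2.0 * matches, 2),
        )
        hits_ab.append(HitRecord(query_id=pa_id, subject_id=pb_id, **common))
        hits_ba.append(HitRecord(query_id=pb_id, subject_id=pa_id, **common))

    return (
        ProteomeRecord("genomeA", prots_a),
        ProteomeRecord("genomeB", prots_b),
        hits_ab,
        hits_ba,
    )


def study_habitat_design() -> HabitatDesign:
    """The 16-genome, six-habitat layout of the target study: six sponge,
    two coral, two flatworm, one eelgrass, four seawater, one sediment
    isolate."""
    layout = (
        ["sponge"] * 6 + ["coral"] * 2 + ["flatworm"] * 2 + ["eelgrass"]
        + ["seawater"] * 4 + ["sediment"]
    )
    return HabitatDesign({f"g{i + 1:03d}": h for i, h in enumerate(layout)})


def study_matrix_config(seed: int = 0) -> MatrixSimConfig:
    """A 38-genome, 17-group scenario shaped like the family-level matrix:
    intra-genus AAI above ≈78.5%, inter-genus below ≈71.9%."""
    sizes = [8, 1, 1, 1, 1, 4, 5, 1, 1, 1, 2, 2, 1, 3, 1, 3, 2]
    assert sum(sizes) == 38 and len(sizes) == 17
    return MatrixSimConfig(
        genus_sizes=sizes,
        intra_range=(78.5, 95.0),
        inter_range=(60.0, 71.9),
        seed=seed,
    )


def study_pangenome_config(seed: int = 0) -> PangenomeSimConfig:
    """16 genomes over six habitats with a five-clade phylogenetic backbone
    and a few thousand CDS columns, sized like the study pangenome."""
    design = study_habitat_design()
    genomes = design.genomes
    clades = [genomes[0:5], genomes[5:9], genomes[9:12], genomes[12:14], genomes[14:16]]
    return PangenomeSimConfig(
        habitat_assignment=dict(design.assignment),
        clade_structure=clades,
        n_core=2000,
        n_phylo_per_clade=400,
        n_habitat_genes_per_habitat=100,
        penetrance=0.9,
        background=0.05,
        noise_flip=0.01,
        seed=seed,
    )
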