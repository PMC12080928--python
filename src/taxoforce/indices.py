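"""Genomic relatedness indices: AAI, POCP and OrthoANI-style ANI.

All three are computed from pairwise search results in BLAST tabular layout,
so production runs consume externally produced outfmt-6 files (BLASTP,
DIAMOND, usearch); the pipeline never shells out implicitly.  A built-in
exact aligner (edit-distance based, toy scale) backs the OrthoANI fragment
search and the test fixtures.

AAI: mean percent identity over reciprocal best hits (RBH) between two
proteomes.  POCP: 100·(C1+C2)/(T1+T2) where Ci counts proteins of genome i
with a qualifying hit in the other and Ti is its proteome size; the
qualifying filter is E < 1e-5, identity ≥ 50%, and (per the original POCP
definition) alignable region ≥ 50% of the query.  OrthoANI: genomes are cut
into consecutive 1020-bp fragments, fragments are searched both ways, and
the mean identity over reciprocal best fragment pairs is reported; the
95–96% ANI band together with 70% dDDH delimits species.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import edlib

from .io import GenomeRecord, HitRecord

__all__ = [
    "HitFilters",
    "RBHPair",
    "PairIndexResult",
    "SpeciesCall",
    "AAI_DEFAULT_FILTERS",
    "POCP_DEFAULT_FILTERS",
    "reciprocal_best_hits",
    "compute_aai",
    "compute_pocp",
    "orthoani",
    "species_call",
    "exact_align_hits",
    "fragment_genome",
]


@dataclass(frozen=True)
class HitFilters:
    """Hit-qualification filters; all are applied before best-hit selection.

    ``min_cov`` is the aligned fraction of the query protein and is only
    enforced when query lengths are available.
    """

    min_pident: float = 30.0
    min_cov: float = 0.7
    max_evalue: float = 1e-3


#: Two-way RBH filters for AAI (Kostas-lab calculator convention).
AAI_DEFAULT_FILTERS = HitFilters(min_pident=30.0, min_cov=0.7, max_evalue=1e-3)
#: POCP conserved-protein filters: E < 1e-5, identity ≥ 50%, coverage ≥ 50%.
POCP_DEFAULT_FILTERS = HitFilters(min_pident=50.0, min_cov=0.5, max_evalue=1e-5)


@dataclass(frozen=True)
class RBHPair:
    protein_a: str
    protein_b: str
    pident: float
    aln_length: int = 0
    qcov_a: float | None = None
    qcov_b: float | None = None


@dataclass
class PairIndexResult:
    """One index value for an unordered genome pair, with supporting counts."""

    genome_a: str
    genome_b: str
    index_kind: str
    value: float | None
    support: dict = field(default_factory=dict)
    sd: float | None = None
    flag: str | None = None


@dataclass
class SpeciesCall:
    genome_a: str
    genome_b: str
    ani_value: float
    ddh_value: float | None
    verdict: str  # same_species | different_species | ambiguous


def _passes(
    hit: HitRecord, filters: HitFilters, query_lengths: Mapping[str, int] | None
) -> bool:
    if hit.pident < filters.min_pident or hit.evalue > filters.max_evalue:
        return False
    if query_lengths is not None and hit.query_id in query_lengths:
        qlen = query_lengths[hit.query_id]
        cov = (hit.qend - hit.qstart + 1) / qlen if qlen else 0.0
        if cov < filters.min_cov:
            return False
    return True


def _best_hits(
    hits: Sequence[HitRecord], filters: HitFilters, query_lengths
) -> dict[str, HitRecord]:
    """Best subject per query: max bitscore, ties by lower evalue then
    lexicographic subject id (determinism across search backends)."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        if not _passes(h, filters, query_lengths):
            continue
        cur = best.get(h.query_id)
        if cur is None or (-h.bitscore, h.evalue, h.subject_id) < (
            -cur.bitscore,
            cur.evalue,
            cur.subject_id,
        ):
            best[h.query_id] = h
    return best


def reciprocal_best_hits(
    hits_ab: Sequence[HitRecord],
    hits_ba: Sequence[HitRecord],
    filters: HitFilters = AAI_DEFAULT_FILTERS,
    lengths_a: Mapping[str, int] | None = None,
    lengths_b: Mapping[str, int] | None = None,
) -> list[RBHPair]:
    """Reciprocal best hits between two protein sets.

    A pair (p, q) is returned iff q is p's top hit in ``hits_ab`` and p is
    q's top hit in ``hits_ba`` after filtering.  The reported identity is the
    A→B value.
    """
    best_ab = _best_hits(hits_ab, filters, lengths_a)
    best_ba = _best_hits(hits_ba, filters, lengths_b)
    pairs = []
    for p, hit in sorted(best_ab.items()):
        q = hit.subject_id
        back = best_ba.get(q)
        if back is not None and back.subject_id == p:
            qcov_a = (
                (hit.qend - hit.qstart + 1) / lengths_a[p]
                if lengths_a and p in lengths_a
                else None
            )
            qcov_b = (
                (back.qend - back.qstart + 1) / lengths_b[q]
                if lengths_b and q in lengths_b
                else None
            )
            pairs.append(
                RBHPair(
                    protein_a=p,
                    protein_b=q,
                    pident=hit.pident,
                    aln_length=hit.aln_length,
                    qcov_a=qcov_a,
                    qcov_b=qcov_b,
                )
            )
    return pairs


def compute_aai(
    rbh_pairs: Sequence[RBHPair], genome_a: str = "A", genome_b: str = "B"
) -> PairIndexResult:
    """Average amino-acid identity: unweighted mean identity over RBH pairs."""
    if not rbh_pairs:
        return PairIndexResult(
            genome_a, genome_b, "AAI", value=None, support={"n": 0}, flag="no_orthologs"
        )
    pidents = [p.pident for p in rbh_pairs]
    sd = statistics.stdev(pidents) if len(pidents) > 1 else None
    return PairIndexResult(
        genome_a,
        genome_b,
        "AAI",
        value=sum(pidents) / len(pidents),
        support={"n": len(pidents)},
        sd=sd,
    )


def compute_pocp(
    hits_ab: Sequence[HitRecord],
    hits_ba: Sequence[HitRecord],
    t1: int,
    t2: int,
    filters: HitFilters = POCP_DEFAULT_FILTERS,
    lengths_a: Mapping[str, int] | None = None,
    lengths_b: Mapping[str, int] | None = None,
    genome_a: str = "A",
    genome_b: str = "B",
) -> PairIndexResult:
    """Percentage of conserved proteins: 100·(C1+C2)/(T1+T2)."""
    if t1 + t2 == 0:
        raise ValueError("both proteomes are empty (T1 + T2 = 0)")
    c1 = len({h.query_id for h in hits_ab if _passes(h, filters, lengths_a)})
    c2 = len({h.query_id for h in hits_ba if _passes(h, filters, lengths_b)})
    value = 100.0 * (c1 + c2) / (t1 + t2)
    return PairIndexResult(
        genome_a,
        genome_b,
        "POCP",
        value=value,
        support={"C1": c1, "C2": c2, "T1": t1, "T2": t2},
    )


def fragment_genome(genome: GenomeRecord, fragment_length: int = 1020) -> dict[str, str]:
    """Cut each contig into consecutive non-overlapping fragments; the
    trailing remainder shorter than ``fragment_length`` is discarded."""
    frags: dict[str, str] = {}
    for ci, seq in enumerate(genome.sequences):
        for k in range(len(seq) // fragment_length):
            frags[f"{genome.genome_id}|c{ci}|f{k}"] = seq[
                k * fragment_length : (k + 1) * fragment_length
            ]
    return frags


def exact_align_hits(
    queries: Mapping[str, str], targets: Mapping[str, str], min_pident: float = 35.0
) -> list[HitRecord]:
    """Built-in exact aligner: global edit-distance alignment of every query
    against every target, reported as outfmt-6-style hits.

    Identity is 100·(L − edit_distance)/L with L the longer sequence; hits
    below ``min_pident`` are dropped (OrthoANI's published identity filter).
    Toy scale only — quadratic in the number of sequences.
    """
    hits = []
    for qid, q in queries.items():
        for sid, s in targets.items():
            L = max(len(q), len(s))
            if L == 0:
                continue
            dist = edlib.align(q, s, mode="NW", task="distance")["editDistance"]
            pident = 100.0 * (L - dist) / L
            if pident < min_pident:
                continue
            hits.append(
                HitRecord(
                    query_id=qid,
                    subject_id=sid,
                    pident=round(pident, 4),
                    aln_length=L,
                    mismatch=dist,
                    gapopen=0,
                    qstart=1,
                    qend=len(q),
                    sstart=1,
                    send=len(s),
                    evalue=0.0,
                    bitscore=round(2.0 * (L - dist), 2),
                )
            )
    return hits


def orthoani(
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
    aligner: Callable[[Mapping[str, str], Mapping[str, str]], list[HitRecord]] | None = None,
    fragment_length: int = 1020,
) -> PairIndexResult:
    """OrthoANI-style average nucleotide identity.

    Both genomes are fragmented, fragments are searched in both directions
    with ``aligner`` (default: the built-in exact aligner), and the mean
    identity over reciprocal best fragment pairs is reported.
    """
    if not genome_a.sequences or not genome_b.sequences:
        raise ValueError("empty assembly")
    if aligner is None:
        aligner = exact_align_hits
    frags_a = fragment_genome(genome_a, fragment_length)
    frags_b = fragment_genome(genome_b, fragment_length)
    if not frags_a or not frags_b:
        return PairIndexResult(
            genome_a.genome_id,
            genome_b.genome_id,
            "ANI",
            value=None,
            support={"n_fragments_a": len(frags_a), "n_fragments_b": len(frags_b)},
            flag="below_detection",
        )
    hits_ab = aligner(frags_a, frags_b)
    hits_ba = aligner(frags_b, frags_a)
    # fragment-level RBH with no additional identity/coverage gating beyond
    # what the aligner already applied
    open_filters = HitFilters(min_pident=0.0, min_cov=0.0, max_evalue=float("inf"))
    pairs = reciprocal_best_hits(hits_ab, hits_ba, filters=open_filters)
    if not pairs:
        return PairIndexResult(
            genome_a.genome_id,
            genome_b.genome_id,
            "ANI",
            value=None,
            support={"n_pairs": 0},
            flag="below_detection",
        )
    pidents = [p.pident for p in pairs]
    sd = statistics.stdev(pidents) if len(pidents) > 1 else None
    return PairIndexResult(
        genome_a.genome_id,
        genome_b.genome_id,
        "ANI",
        value=sum(pidents) / len(pidents),
        support={"n_pairs": len(pairs)},
        sd=sd,
    )


def species_call(
    ani: float,
    ddh: float | None = None,
    genome_a: str = "A",
    genome_b: str = "B",
) -> SpeciesCall:
    """Apply the species-delineation rule.

    ANI ≥ 96 (with dDDH ≥ 70 when available) → same species; ANI < 95 (with
    dDDH < 70 when available) → different species; the 95–96 ANI band or a
    conflict between the two indices → ambiguous.
    """
    if not (0 <= ani <= 100):
        raise ValueError(f"ANI {ani} outside [0, 100]")
    if ani >= 96:
        ani_verdict = "same_species"
    elif ani < 95:
        ani_verdict = "different_species"
    else:
        ani_verdict = "ambiguous"
    if ddh is None:
        verdict = ani_verdict
    else:
        ddh_verdict = "same_species" if ddh >= 70 else "different_species"
        if ani_verdict == "ambiguous" or ani_verdict != ddh_verdict:
            verdict = "ambiguous"
        else:
            verdict = ani_verdict
    return SpeciesCall(genome_a, genome_b, ani, ddh, verdict)
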