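"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from taxoforce import HabitatDesign, Partition, PresenceAbsenceMatrix, SimilarityMatrix


# ---------------------------------------------------------------- oracles


def brute_force_partition(S: SimilarityMatrix, t: float) -> Partition:
    """Transitive-closure oracle: repeatedly merge any two groups joined by
    an edge S ≥ t until a fixed point; independent of graph libraries."""
    groups = [{g} for g in S.genomes]
    idx = {g: i for i, g in enumerate(S.genomes)}
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(range(S.n), 2):
            if S.values[a, b] >= t:
                ga = next(grp for grp in groups if S.genomes[a] in grp)
                gb = next(grp for grp in groups if S.genomes[b] in grp)
                if ga is not gb:
                    groups.remove(gb)
                    ga |= gb
                    changed = True
    return Partition(groups)


def ari_formula(labels_a, labels_b) -> float:
    """Adjusted Rand index straight from the contingency-table formula."""
    from math import comb

    a_vals = sorted(set(labels_a))
    b_vals = sorted(set(labels_b))
    n = len(labels_a)
    table = np.zeros((len(a_vals), len(b_vals)), dtype=int)
    for la, lb in zip(labels_a, labels_b):
        table[a_vals.index(la), b_vals.index(lb)] += 1
    sum_ij = sum(comb(int(x), 2) for x in table.flat)
    sum_a = sum(comb(int(x), 2) for x in table.sum(axis=1))
    sum_b = sum(comb(int(x), 2) for x in table.sum(axis=0))
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    maximum = (sum_a + sum_b) / 2
    if maximum == expected:
        return 1.0
    return (sum_ij - expected) / (maximum - expected)


def cca_eigen_oracle(Y: np.ndarray, habitats: list[str]):
    """Independent CCA oracle via the generalized eigenproblem route.

    Builds the chi-square residual matrix, projects it onto the span of the
    weighted-centred habitat dummies with an orthonormal basis from QR, and
    takes eigenvalues of the projected cross-product with scipy's symmetric
    eigensolver — no SVD of the fitted matrix, no shared code with the
    implementation.
    """
    import scipy.linalg

    Y = np.asarray(Y, dtype=float)
    total = Y.sum()
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    E = np.outer(r, c)
    Q = (P - E) / np.sqrt(E)
    total_inertia = (Q**2).sum()

    hab_levels = list(dict.fromkeys(habitats))
    Z = np.zeros((len(habitats), len(hab_levels)))
    for i, h in enumerate(habitats):
        Z[i, hab_levels.index(h)] = 1.0
    Zc = Z - r @ Z
    X = np.sqrt(r)[:, None] * Zc
    Qmat, R = scipy.linalg.qr(X, mode="economic")
    rank = np.sum(np.abs(np.diag(R)) > 1e-9 * max(1.0, np.abs(R[0, 0])))
    basis = Qmat[:, :rank] if rank else np.zeros((X.shape[0], 0))
    M = basis.T @ Q @ Q.T @ basis
    eig = scipy.linalg.eigh(M, eigvals_only=True)[::-1]
    eig = eig[eig > 1e-10]
    return np.sort(eig)[::-1], float(total_inertia)


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def toy_matrix() -> SimilarityMatrix:
    """4 genomes: pairs (1,2)@95 and (3,4)@96, everything else 61."""
    v = np.full((4, 4), 61.0)
    v[0, 1] = v[1, 0] = 95.0
    v[2, 3] = v[3, 2] = 96.0
    np.fill_diagonal(v, 100.0)
    return SimilarityMatrix(["1", "2", "3", "4"], v)


@pytest.fixture
def small_pangenome():
    """5 genomes × 8 CDS with hand-built habitat-exclusive columns."""
    genomes = ["gA", "gB", "gC", "gD", "gE"]
    df = pd.DataFrame(
        {
            "ubiq": [1, 1, 1, 1, 1],
            "x_strict": [1, 1, 0, 0, 0],  # all of habitat x, nowhere else
            "x_partial": [1, 0, 0, 0, 0],  # one of habitat x, nowhere else
            "y_strict": [0, 0, 1, 1, 0],
            "mixed": [1, 0, 1, 0, 0],
            "z_only": [0, 0, 0, 0, 1],
            "noise1": [0, 1, 1, 0, 1],
            "noise2": [1, 0, 0, 1, 1],
        },
        index=genomes,
    )
    design = HabitatDesign({"gA": "x", "gB": "x", "gC": "y", "gD": "y", "gE": "z"})
    return PresenceAbsenceMatrix(df), design


def random_similarity(rng: np.random.Generator, n: int) -> SimilarityMatrix:
    v = np.round(rng.uniform(30, 100, size=(n, n)), 2)
    v = np.triu(v, k=1)
    v = v + v.T
    np.fill_diagonal(v, 100.0)
    return SimilarityMatrix([f"g{i}" for i in range(n)], v)
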