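"""Canonical (constrained) correspondence analysis of a binary pangenome.

The gene presence/absence matrix Y (genomes × CDS clusters) is treated as a
contingency table.  With P = Y / y₊₊, row masses r and column masses c, the
chi-square residual matrix is

    Q_ij = (P_ij − r_i c_j) / sqrt(r_i c_j),

whose squared Frobenius norm is the *total inertia* (the chi-square statistic
of Y divided by its grand total).  Habitat categories enter as indicator
(dummy) variables, weighted-centred with the row masses; Q is projected onto
their span by row-mass-weighted least squares and the fitted matrix is
decomposed by SVD.  Squared singular values are the constrained eigenvalues;
at most (number of habitats − 1) constrained axes exist.

The ratio constrained/total inertia is the *environmentally forced* fraction
of gene-content variation; its complement is attributed to phylogeny.  This
mirrors what ``vegan::cca(Y ~ habitat)`` computes.

Usage::

    model = PangenomeCCA(pa_matrix, habitat_design)
    res = model.fit()
    res.env_fraction, res.eigenvalues
    res.summary()
    null = model.permutation_test(n_permutations=99, seed=1)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .io import HabitatDesign, PresenceAbsenceMatrix

__all__ = ["PangenomeCCA", "CCAResults", "cca_fit", "variance_partition", "habitat_axis_correlation"]

_EIG_TOL = 1e-10


@dataclass
class _ChiSquareDecomposition:
    P: np.ndarray
    r: np.ndarray
    c: np.ndarray
    Q: np.ndarray

    @property
    def total_inertia(self) -> float:
        return float((self.Q**2).sum())


def _decompose(Y: np.ndarray) -> _ChiSquareDecomposition:
    total = Y.sum()
    if total <= 0:
        raise ValueError("matrix has zero grand total")
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    E = np.outer(r, c)
    Q = (P - E) / np.sqrt(E)
    return _ChiSquareDecomposition(P=P, r=r, c=c, Q=Q)


class PangenomeCCA:
    """CCA of gene presence/absence constrained by habitat categories.

    Parameters
    ----------
    pa
        Binary genome × CDS-cluster matrix.  All-zero columns are dropped
        with a warning (zero-mass columns have no chi-square contribution).
    design
        Habitat category per genome; must cover every genome in ``pa``.
    scaling
        ``"symmetric"`` (default) scales site and CDS scores by the fourth
        root of the eigenvalues, keeping magnitudes comparable across the two
        score sets; ``"sites"`` and ``"species"`` put the eigenvalue weight
        on one side only.  The choice is stamped into the results.
    """

    def __init__(
        self,
        pa: PresenceAbsenceMatrix,
        design: HabitatDesign,
        scaling: str = "symmetric",
    ):
        if scaling not in ("symmetric", "sites", "species"):
            raise ValueError(f"unknown scaling {scaling!r}")
        design.require_covering(pa.genomes)
        df = pa.df
        col_sums = df.to_numpy().sum(axis=0)
        if (col_sums == 0).any():
            dropped = [c for c, s in zip(df.columns, col_sums) if s == 0]
            warnings.warn(f"dropping {len(dropped)} all-zero CDS columns")
            df = df.loc[:, col_sums > 0]
        self.df = df
        self.design = design
        self.scaling = scaling
        self.habitats = [h for h in design.habitats if any(
            design.assignment[g] == h for g in df.index)]

    def _dummies(self) -> np.ndarray:
        Z = np.zeros((len(self.df.index), len(self.habitats)))
        for i, g in enumerate(self.df.index):
            Z[i, self.habitats.index(self.design.assignment[g])] = 1.0
        return Z

    def fit(self) -> "CCAResults":
        genomes = list(self.df.index)
        cds = list(self.df.columns)
        dec = _decompose(self.df.to_numpy(dtype=float))
        r, c, Q = dec.r, dec.c, dec.Q
        total_inertia = dec.total_inertia

        n_habitats = len(self.habitats)
        if n_habitats < 2:
            warnings.warn("single habitat: zero constrained axes")
            return CCAResults(
                model=self,
                genomes=genomes,
                cds=cds,
                eigenvalues=np.array([]),
                total_inertia=total_inertia,
                site_scores=pd.DataFrame(index=genomes),
                cds_scores=pd.DataFrame(index=cds),
                habitat_scores=pd.DataFrame(index=self.habitats),
                habitat_axis_r=pd.DataFrame(index=self.habitats),
                row_masses=r,
                col_masses=c,
            )

        Z = self._dummies()
        Zc = Z - r @ Z  # weighted centring removes the trivial CA axis
        X = np.sqrt(r)[:, None] * Zc
        # row-mass-weighted least squares of Q on the centred dummies,
        # as an orthogonal projection onto the numerical column span of X
        # (the centred dummies are exactly rank-deficient: rows sum to zero)
        Ux, sx, _ = np.linalg.svd(X, full_matrices=False)
        span = sx > sx[0] * 1e-9 if sx.size else np.zeros(0, bool)
        Ux = Ux[:, span]
        Qhat = Ux @ (Ux.T @ Q)

        U, s, Vt = np.linalg.svd(Qhat, full_matrices=False)
        lam = s**2
        keep = lam > max(_EIG_TOL, _EIG_TOL * (lam[0] if lam.size else 1.0))
        keep &= np.arange(lam.size) < n_habitats - 1
        U, s, Vt, lam = U[:, keep], s[keep], Vt[keep], lam[keep]
        k = lam.size  # ≤ n_habitats − 1; fewer if the design is rank-deficient

        # standard coordinates
        with np.errstate(divide="ignore", invalid="ignore"):
            site_std = U / np.sqrt(r)[:, None]
            cds_std = Vt.T / np.sqrt(c)[:, None]
        if self.scaling == "symmetric":
            site = site_std * lam**0.25
            cds_sc = cds_std * lam**0.25
        elif self.scaling == "sites":
            site = site_std * np.sqrt(lam)
            cds_sc = cds_std
        else:
            site = site_std
            cds_sc = cds_std * np.sqrt(lam)

        # habitat centroids of site scores (weighted by row masses), then fix
        # axis signs: largest-|centroid| habitat positive on each axis
        cent = np.zeros((n_habitats, k))
        for j, h in enumerate(self.habitats):
            idx = [i for i, g in enumerate(genomes) if self.design.assignment[g] == h]
            w = r[idx]
            cent[j] = (w[:, None] * site[idx]).sum(axis=0) / w.sum()
        for ax in range(k):
            jmax = int(np.argmax(np.abs(cent[:, ax])))
            if cent[jmax, ax] < 0:
                site[:, ax] *= -1
                cds_sc[:, ax] *= -1
                cent[:, ax] *= -1

        axes = [f"CCA{i + 1}" for i in range(k)]
        site_scores = pd.DataFrame(site, index=genomes, columns=axes)
        cds_scores = pd.DataFrame(cds_sc, index=cds, columns=axes)
        habitat_scores = pd.DataFrame(cent, index=self.habitats, columns=axes)

        # weighted Pearson correlation of each habitat indicator with each axis
        rmat = np.full((n_habitats, k), np.nan)
        for j in range(n_habitats):
            z = Z[:, j]
            zbar = r @ z
            zc = z - zbar
            vz = r @ zc**2
            if vz <= 0:
                continue  # constant indicator: correlation undefined
            for ax in range(k):
                x = site[:, ax]
                xc = x - r @ x
                vx = r @ xc**2
                if vx <= 0:
                    continue
                rmat[j, ax] = (r @ (zc * xc)) / np.sqrt(vz * vx)
        habitat_axis_r = pd.DataFrame(rmat, index=self.habitats, columns=axes)

        return CCAResults(
            model=self,
            genomes=genomes,
            cds=cds,
            eigenvalues=lam,
            total_inertia=total_inertia,
            site_scores=site_scores,
            cds_scores=cds_scores,
            habitat_scores=habitat_scores,
            habitat_axis_r=habitat_axis_r,
            row_masses=r,
            col_masses=c,
        )

    def permutation_test(
        self, n_permutations: int = 99, seed: int | np.random.Generator = 0
    ) -> np.ndarray:
        """Null distribution of env_fraction under habitat-label shuffling."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        genomes = list(self.df.index)
        labels = [self.design.assignment[g] for g in genomes]
        out = np.empty(n_permutations)
        pa = PresenceAbsenceMatrix(self.df)
        for i in range(n_permutations):
            perm = rng.permutation(len(labels))
            shuffled = HabitatDesign({g: labels[j] for g, j in zip(genomes, perm)})
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out[i] = PangenomeCCA(pa, shuffled, scaling=self.scaling).fit().env_fraction
        return out


class CCAResults:
    """Fitted CCA: eigenvalues, inertia decomposition and score tables."""

    def __init__(
        self,
        model,
        genomes,
        cds,
        eigenvalues,
        total_inertia,
        site_scores,
        cds_scores,
        habitat_scores,
        habitat_axis_r,
        row_masses,
        col_masses,
    ):
        self.model = model
        self.genomes = genomes
        self.cds = cds
        self.eigenvalues = np.asarray(eigenvalues)
        self.total_inertia = float(total_inertia)
        self.site_scores = site_scores
        self.cds_scores = cds_scores
        self.habitat_scores = habitat_scores
        self.habitat_axis_r = habitat_axis_r
        self.row_masses = row_masses
        self.col_masses = col_masses

    @property
    def n_axes(self) -> int:
        return self.eigenvalues.size

    @property
    def constrained_inertia(self) -> float:
        return float(self.eigenvalues.sum())

    @property
    def env_fraction(self) -> float:
        """Fraction of total inertia explained by habitat (environmental forcing)."""
        return self.constrained_inertia / self.total_inertia

    @property
    def phylo_fraction(self) -> float:
        """Residual fraction, attributed to phylogenetic forcing."""
        return 1.0 - self.env_fraction

    @property
    def axis_fractions(self) -> np.ndarray:
        return self.eigenvalues / self.total_inertia

    def variance_partition(self) -> tuple[float, float]:
        return self.env_fraction, self.phylo_fraction

    def summary(self) -> pd.DataFrame:
        """Per-axis eigenvalue table plus the inertia partition."""
        rows = [
            {
                "component": f"CCA{i + 1}",
                "eigenvalue": lam,
                "fraction_of_total": lam / self.total_inertia,
            }
            for i, lam in enumerate(self.eigenvalues)
        ]
        rows.append(
            {
                "component": "constrained (environmental)",
                "eigenvalue": self.constrained_inertia,
                "fraction_of_total": self.env_fraction,
            }
        )
        rows.append(
            {
                "component": "unconstrained (phylogenetic)",
                "eigenvalue": self.total_inertia - self.constrained_inertia,
                "fraction_of_total": self.phylo_fraction,
            }
        )
        return pd.DataFrame(rows)

    def plot_biplot(self, axes=(0, 1), ax=None):
        """Basic ordination biplot: genomes as points, habitat centroids as
        arrows, CDS as small markers."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        i, j = axes
        ax.scatter(
            self.cds_scores.iloc[:, i],
            self.cds_scores.iloc[:, j],
            s=4,
            marker="+",
            color="0.7",
            label="CDS",
        )
        ax.scatter(
            self.site_scores.iloc[:, i],
            self.site_scores.iloc[:, j],
            facecolors="none",
            edgecolors="C0",
            label="genomes",
        )
        for h, row in self.habitat_scores.iterrows():
            ax.annotate(
                h,
                (row.iloc[i], row.iloc[j]),
                color="C3",
            )
            ax.arrow(0, 0, row.iloc[i], row.iloc[j], color="C3", alpha=0.5)
        ax.axhline(0, lw=0.5, color="0.8")
        ax.axvline(0, lw=0.5, color="0.8")
        ax.set_xlabel(self.site_scores.columns[i])
        ax.set_ylabel(self.site_scores.columns[j])
        ax.legend(loc="best", fontsize="small")
        return ax


def cca_fit(
    Y: PresenceAbsenceMatrix, design: HabitatDesign, scaling: str = "symmetric"
) -> CCAResults:
    """Functional front-end: fit the habitat-constrained CCA in one call."""
    return PangenomeCCA(Y, design, scaling=scaling).fit()


def variance_partition(model: CCAResults) -> tuple[float, float]:
    """(environmental, phylogenetic) inertia fractions of a fitted model."""
    return model.variance_partition()


def habitat_axis_correlation(
    model: CCAResults, design: HabitatDesign | None = None
) -> pd.DataFrame:
    """Habitat-indicator vs axis-score weighted Pearson correlations.

    With no ``design`` the fit's own table is returned.  Supplying a design
    correlates *its* indicators against the fitted site scores without
    refitting — the basis of the label-permutation check, where shuffled
    indicators should correlate with the ordination more weakly than the
    true ones do.
    """
    if design is None:
        return model.habitat_axis_r
    design.require_covering(model.genomes)
    habitats = [h for h in design.habitats]
    r = model.row_masses
    site = model.site_scores.to_numpy()
    k = site.shape[1]
    out = np.full((len(habitats), k), np.nan)
    for j, h in enumerate(habitats):
        z = np.array([1.0 if design.assignment[g] == h else 0.0 for g in model.genomes])
        zc = z - r @ z
        vz = r @ zc**2
        if vz <= 0:
            continue
        for ax in range(k):
            x = site[:, ax]
            xc = x - r @ x
            vx = r @ xc**2
            if vx > 0:
                out[j, ax] = (r @ (zc * xc)) / np.sqrt(vz * vx)
    return pd.DataFrame(out, index=habitats, columns=model.site_scores.columns)
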