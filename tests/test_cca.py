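"""Constrained correspondence analysis: inertia, eigenvalues, scores."""

import numpy as np
import pandas as pd
import pytest

from taxoforce import HabitatDesign, PangenomeCCA, PresenceAbsenceMatrix, cca_fit

from conftest import cca_eigen_oracle


def _random_pa(rng, n, p):
    Y = rng.integers(0, 2, size=(n, p))
    Y[:, Y.sum(axis=0) == 0] = 1
    Y[Y.sum(axis=1) == 0, 0] = 1
    return PresenceAbsenceMatrix(
        pd.DataFrame(Y, index=[f"g{i}" for i in range(n)], columns=[f"c{j}" for j in range(p)])
    )


class TestAgainstEigenOracle:
    def test_eigenvalues_and_env_fraction_match_oracle(self):
        """50 random small matrices vs an independent generalized-eigenproblem
        solver, to 1e-8."""
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n = int(rng.integers(5, 12))
            p = int(rng.integers(8, 30))
            n_hab = int(rng.integers(2, min(5, n) + 1))
            pa = _random_pa(rng, n, p)
            habitats = [f"h{rng.integers(0, n_hab)}" for _ in range(n)]
            habitats[: n_hab] = [f"h{k}" for k in range(n_hab)]  # all levels present
            design = HabitatDesign(dict(zip(pa.genomes, habitats)))
            res = PangenomeCCA(pa, design).fit()
            eig_oracle, total_oracle = cca_eigen_oracle(pa.values, habitats)
            assert res.total_inertia == pytest.approx(total_oracle, abs=1e-10)
            assert res.eigenvalues == pytest.approx(eig_oracle, abs=1e-8)
            assert res.env_fraction == pytest.approx(
                eig_oracle.sum() / total_oracle, abs=1e-8
            )

    def test_total_inertia_is_chi_square_over_grand_total(self):
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(3)
        pa = _random_pa(rng, 6, 12)
        design = HabitatDesign({g: ("u" if i < 3 else "v") for i, g in enumerate(pa.genomes)})
        res = PangenomeCCA(pa, design).fit()
        chi2 = chi2_contingency(pa.values, correction=False)[0]
        assert res.total_inertia == pytest.approx(chi2 / pa.values.sum())


class TestAxisCountAndDegenerateDesigns:
    def test_six_habitats_give_exactly_five_axes(self):
        rng = np.random.default_rng(8)
        pa = _random_pa(rng, 16, 200)
        habitats = (
            ["sponge"] * 6 + ["coral"] * 2 + ["flatworm"] * 2 + ["eelgrass"]
            + ["seawater"] * 4 + ["sediment"]
        )
        design = HabitatDesign(dict(zip(pa.genomes, habitats)))
        res = PangenomeCCA(pa, design).fit()
        assert res.n_axes == 5

    def test_single_habitat_zero_axes_and_null_partition(self):
        rng = np.random.default_rng(4)
        pa = _random_pa(rng, 5, 10)
        design = HabitatDesign({g: "same" for g in pa.genomes})
        with pytest.warns(UserWarning, match="single habitat"):
            res = PangenomeCCA(pa, design).fit()
        assert res.n_axes == 0
        assert res.variance_partition() == (0.0, 1.0)

    def test_saturated_design_explains_everything(self):
        # habitats with identical rows inside, distinct across: env_fraction 1
        rows = {
            "h1": [1, 1, 0, 0, 1, 0],
            "h2": [0, 1, 1, 0, 0, 1],
            "h3": [1, 0, 1, 1, 0, 0],
        }
        data, habitats, genomes = [], [], []
        for h, row in rows.items():
            for k in range(2):
                genomes.append(f"{h}_g{k}")
                habitats.append(h)
                data.append(row)
        pa = PresenceAbsenceMatrix(
            pd.DataFrame(data, index=genomes, columns=[f"c{j}" for j in range(6)])
        )
        res = PangenomeCCA(pa, HabitatDesign(dict(zip(genomes, habitats)))).fit()
        assert res.env_fraction == pytest.approx(1.0)
        assert res.phylo_fraction == pytest.approx(0.0)

    def test_unconstrained_limit_recovers_full_inertia(self):
        # one dummy per genome: constrained space = everything (CA recovery)
        rng = np.random.default_rng(6)
        pa = _random_pa(rng, 6, 15)
        design = HabitatDesign({g: f"solo_{g}" for g in pa.genomes})
        res = PangenomeCCA(pa, design).fit()
        assert res.constrained_inertia == pytest.approx(res.total_inertia)


class TestInvariances:
    def test_eigenvalues_invariant_under_permutations(self):
        rng = np.random.default_rng(10)
        pa = _random_pa(rng, 8, 20)
        habitats = ["a", "a", "b", "b", "c", "c", "a", "b"]
        design = HabitatDesign(dict(zip(pa.genomes, habitats)))
        base = PangenomeCCA(pa, design).fit()

        row_perm = rng.permutation(8)
        col_perm = rng.permutation(20)
        df = pa.df.iloc[row_perm, col_perm]
        design_p = HabitatDesign({g: design.assignment[g] for g in df.index})
        perm = PangenomeCCA(PresenceAbsenceMatrix(df), design_p).fit()
        assert perm.eigenvalues == pytest.approx(base.eigenvalues, abs=1e-10)
        assert perm.env_fraction == pytest.approx(base.env_fraction)

    def test_axis_fractions_sum_to_env_fraction(self):
        rng = np.random.default_rng(12)
        pa = _random_pa(rng, 7, 18)
        design = HabitatDesign(
            dict(zip(pa.genomes, ["x", "x", "y", "y", "z", "z", "x"]))
        )
        res = cca_fit(pa, design)
        assert res.axis_fractions.sum() == pytest.approx(res.env_fraction)
        assert res.constrained_inertia <= res.total_inertia + 1e-12


class TestHabitatAxisCorrelation:
    def test_two_point_separation_gives_unit_correlation(self):
        # habitat u = one genome far out on axis 1
        df = pd.DataFrame(
            {
                "c1": [1, 0, 0, 0],
                "c2": [1, 0, 0, 0],
                "c3": [0, 1, 1, 1],
                "c4": [0, 1, 1, 1],
                "c5": [1, 1, 1, 1],
            },
            index=["g1", "g2", "g3", "g4"],
        )
        pa = PresenceAbsenceMatrix(df)
        design = HabitatDesign({"g1": "u", "g2": "v", "g3": "v", "g4": "v"})
        res = PangenomeCCA(pa, design).fit()
        assert abs(res.habitat_axis_r.loc["u", "CCA1"]) == pytest.approx(1.0)

    def test_orthogonal_indicator_has_zero_correlation(self):
        # habitat w's genomes carry the union pattern of u and v, so by the
        # u↔v exchange symmetry its indicator is orthogonal to the axis that
        # separates u from v
        df = pd.DataFrame(
            {
                "c1": [1, 1, 0, 0, 1, 1],
                "c2": [0, 0, 1, 1, 1, 1],
                "c3": [1, 1, 1, 1, 1, 1],
            },
            index=[f"g{i}" for i in range(6)],
        )
        pa = PresenceAbsenceMatrix(df)
        design = HabitatDesign(
            dict(zip(df.index, ["u", "u", "v", "v", "w", "w"]))
        )
        res = PangenomeCCA(pa, design).fit()
        r_w = res.habitat_axis_r.loc["w"].abs().to_numpy()
        assert r_w.min() < 1e-8

    def test_correlations_bounded_and_permutation_degrades_them(self):
        from taxoforce.simulate import (
            PangenomeSimConfig,
            simulate_pangenome,
            study_habitat_design,
        )

        design16 = study_habitat_design()
        cfg = PangenomeSimConfig(
            dict(design16.assignment),
            [],
            n_core=150,
            n_phylo_per_clade=0,
            n_habitat_genes_per_habitat=30,
            penetrance=1.0,
            background=0.0,
            noise_flip=0.0,
            seed=0,
        )
        pa, design, _ = simulate_pangenome(cfg)
        res = PangenomeCCA(pa, design).fit()
        r = res.habitat_axis_r.to_numpy()
        finite = np.isfinite(r)
        assert (np.abs(r[finite]) <= 1 + 1e-9).all()

        # permuted indicators correlate with the fixed ordination more
        # weakly than the planted ones in ≥95 of 100 replicates
        from taxoforce.cca import habitat_axis_correlation

        rng = np.random.default_rng(0)
        genomes = list(pa.genomes)
        labels = [design.assignment[g] for g in genomes]
        planted_mean = np.nanmean(np.abs(r))
        hits = 0
        reps = 100
        for _ in range(reps):
            shuffled = HabitatDesign(dict(zip(genomes, rng.permutation(labels))))
            r_perm = habitat_axis_correlation(res, shuffled).to_numpy()
            if np.nanmean(np.abs(r_perm)) < planted_mean:
                hits += 1
        assert hits >= 95


class TestScoresAndSummary:
    def test_axis_sign_convention_and_summary_table(self):
        rng = np.random.default_rng(14)
        pa = _random_pa(rng, 9, 25)
        design = HabitatDesign(
            dict(zip(pa.genomes, ["a", "a", "a", "b", "b", "b", "c", "c", "c"]))
        )
        res = PangenomeCCA(pa, design).fit()
        # per axis, the largest-|centroid| habitat is positive
        for ax in res.habitat_scores.columns:
            col = res.habitat_scores[ax]
            assert col.loc[col.abs().idxmax()] > 0
        df = res.summary()
        assert df["component"].iloc[-2] == "constrained (environmental)"
        assert df["fraction_of_total"].iloc[-2] == pytest.approx(res.env_fraction)
        assert df["fraction_of_total"].iloc[-1] == pytest.approx(res.phylo_fraction)
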