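"""Protein-evolution simulator: determinism, calibration, study dataset."""

import math

import numpy as np
import pytest

from evorate import seqio
from evorate.distance import distance_matrix, p_distance
from evorate.errors import ConfigError, EvorateError
from evorate.ratecomp import build_pair_table
from evorate.simulate import (
    LocusSpec,
    SimConfig,
    discrete_gamma_rates,
    expected_p,
    make_paper_like_dataset,
    path_distance,
    simulate,
    study_clade_map,
)


def _two_leaf_config(mu=0.1, length=2000, seed=0, **kw):
    tree = seqio.read_timetree("(A:50,B:50);")
    return SimConfig(
        tree=tree, loci=[LocusSpec("l1", length)], mu=mu, seed=seed, **kw
    )


class TestDeterminism:
    def test_same_seed_identical_output(self):
        r1 = simulate(_two_leaf_config(seed=7))
        r2 = simulate(_two_leaf_config(seed=7))
        assert seqio.fasta_string(r1.loci["l1"]) == seqio.fasta_string(r2.loci["l1"])

    def test_different_seed_differs(self):
        r1 = simulate(_two_leaf_config(seed=1))
        r2 = simulate(_two_leaf_config(seed=2))
        assert r1.loci["l1"].members != r2.loci["l1"].members

    def test_manifest_regenerates(self):
        cfg = _two_leaf_config(seed=4)
        r1 = simulate(cfg)
        manifest = cfg.manifest()
        tree = seqio.read_timetree(manifest["newick"])
        cfg2 = SimConfig(
            tree=tree,
            loci=[LocusSpec(*spec) for spec in manifest["loci"]],
            mu=manifest["mu"],
            branch_rate=manifest["branch_rate"],
            gamma_shape=manifest["gamma_shape"],
            gamma_categories=manifest["gamma_categories"],
            dropout=[tuple(d) for d in manifest["dropout"]],
            seed=manifest["seed"],
        )
        r2 = simulate(cfg2)
        assert r1.loci["l1"].members == r2.loci["l1"].members


class TestCalibration:
    def test_near_zero_rate_keeps_sequences_identical(self):
        res = simulate(_two_leaf_config(mu=1e-9, length=3000))
        a = res.loci["l1"].members["A"]
        b = res.loci["l1"].members["B"]
        identity = sum(x == y for x, y in zip(a, b)) / len(a)
        assert identity >= 0.999

    def test_empirical_p_matches_closed_form(self):
        """Observed p-distance within 3 binomial SE of the analytic value."""
        cfg = _two_leaf_config(mu=0.2314, length=20000, seed=12)
        res = simulate(cfg)
        d_path = path_distance(res, "A", "B", "l1")
        assert d_path == pytest.approx(0.2314, rel=1e-12)
        p_exp = (19 / 20) * (1 - math.exp(-(20 / 19) * d_path))
        p_obs, n = p_distance(
            res.loci["l1"].members["A"], res.loci["l1"].members["B"]
        )
        se = math.sqrt(p_exp * (1 - p_exp) / n)
        assert abs(p_obs - p_exp) < 3 * se

    def test_rate_linearity(self):
        """Doubling mu doubles expected branch distances; empirical
        Poisson-corrected distances track within Monte-Carlo error."""
        r1 = simulate(_two_leaf_config(mu=0.1, length=10000, seed=3))
        r2 = simulate(_two_leaf_config(mu=0.2, length=10000, seed=3))
        assert r2.branch_distance["A"] == pytest.approx(
            2 * r1.branch_distance["A"]
        )
        from evorate.distance import poisson_distance

        d1 = poisson_distance(
            p_distance(r1.loci["l1"].members["A"], r1.loci["l1"].members["B"])[0]
        )
        d2 = poisson_distance(
            p_distance(r2.loci["l1"].members["A"], r2.loci["l1"].members["B"])[0]
        )
        # Poisson correction removes multiple hits but not the 20-state
        # back-substitution structure exactly; allow generous MC tolerance
        assert d2 / d1 == pytest.approx(2.0, rel=0.15)

    def test_equilibrium_frequencies_at_leaves(self):
        res = simulate(_two_leaf_config(mu=1.0, length=20000, seed=8))
        seq = res.loci["l1"].members["B"]
        counts = np.array([seq.count(aa) for aa in seqio.AMINO_ACIDS])
        freqs = counts / counts.sum()
        # multinomial 3-sigma band around 1/20
        se = math.sqrt(0.05 * 0.95 / len(seq))
        assert np.all(np.abs(freqs - 0.05) < 3.5 * se)

    def test_branch_rate_multiplier_scales_distance(self):
        cfg = _two_leaf_config(branch_rate={"A": 2.0})
        res = simulate(cfg)
        assert res.branch_distance["A"] == pytest.approx(
            2 * res.branch_distance["B"]
        )


class TestExpectedP:
    def test_saturation_limit(self):
        res = simulate(_two_leaf_config(mu=1e6, length=10))
        assert expected_p(res, "A", "B", "l1") == pytest.approx(0.95, abs=1e-9)

    def test_closed_form_value(self):
        # path distance 0.1: p = 0.95 (1 - e^(-2/19))
        res = simulate(_two_leaf_config(mu=0.1, length=10))
        assert path_distance(res, "A", "B", "l1") == pytest.approx(0.1)
        assert expected_p(res, "A", "B", "l1") == pytest.approx(
            0.95 * (1 - math.exp(-0.1 * 20 / 19)), abs=1e-12
        )
        assert expected_p(res, "A", "B", "l1") == pytest.approx(0.0949, abs=5e-5)

    def test_gamma_averages_categories(self):
        res = simulate(_two_leaf_config(gamma_shape=0.5, length=10))
        rates = discrete_gamma_rates(0.5, 4)
        d = path_distance(res, "A", "B", "l1")
        manual = np.mean(0.95 * (1 - np.exp(-(20 / 19) * d * rates)))
        assert expected_p(res, "A", "B", "l1") == pytest.approx(manual, abs=1e-12)

    def test_unsupported_for_custom_matrix(self, rng):
        ex = np.ones((20, 20))
        np.fill_diagonal(ex, 0.0)
        freqs = np.full(20, 0.05)
        cfg = _two_leaf_config(exchangeability=ex, frequencies=freqs)
        res = simulate(cfg)
        with pytest.raises(EvorateError):
            expected_p(res, "A", "B", "l1")


class TestGammaDiscretization:
    def test_category_rates_average_to_one(self):
        for shape in (0.3, 1.0, 5.0):
            for k in (2, 4, 8):
                rates = discrete_gamma_rates(shape, k)
                assert len(rates) == k
                assert rates.mean() == pytest.approx(1.0, abs=1e-9)
                assert np.all(np.diff(rates) > 0)

    def test_invalid_parameters(self):
        with pytest.raises(ConfigError):
            discrete_gamma_rates(-1.0, 4)


class TestCustomMatrixModel:
    def test_uniform_exchangeability_matches_equal_rates_statistics(self):
        """The all-equal exchangeability matrix is the equal-rates model."""
        ex = np.ones((20, 20))
        np.fill_diagonal(ex, 0.0)
        freqs = np.full(20, 0.05)
        cfg = _two_leaf_config(
            mu=0.3, length=20000, seed=21, exchangeability=ex, frequencies=freqs
        )
        res = simulate(cfg)
        p_obs, n = p_distance(
            res.loci["l1"].members["A"], res.loci["l1"].members["B"]
        )
        p_exp = (19 / 20) * (1 - math.exp(-(20 / 19) * 0.3))
        se = math.sqrt(p_exp * (1 - p_exp) / n)
        assert abs(p_obs - p_exp) < 3 * se

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            _two_leaf_config(mu=-1).validate()
        with pytest.raises(ConfigError):
            cfg = _two_leaf_config()
            cfg.frequencies = np.full(20, 0.06)  # sums to 1.2
            cfg.exchangeability = np.ones((20, 20))
            cfg.validate()


class TestStudyDataset:
    def test_structure(self, study_dataset):
        assert len(study_dataset.loci) == 10
        # exactly one (locus, taxon) dropout
        sizes = {name: len(a.members) for name, a in study_dataset.loci.items()}
        assert sizes["CatSperZ"] == 14
        assert all(v == 15 for k, v in sizes.items() if k != "CatSperZ")
        total = sum(a.length for a in study_dataset.loci.values())
        assert total >= 2000

    def test_tree_calibration(self, study_dataset):
        tree = study_dataset.config.tree
        assert tree.root_age == pytest.approx(160)
        assert tree.mrca_age("marsupial1", "marsupial2") == pytest.approx(82)

    def test_rank_reversal_single_replicate(self, study_dataset):
        concat = seqio.concatenate(
            list(study_dataset.loci.values()),
            study_dataset.locus_order,
            "gap_fill",
        )
        dm = distance_matrix(concat)
        table = build_pair_table(dm, study_dataset.config.tree, study_clade_map())
        between = table[table["clade_a"] != table["clade_b"]]

        def clade_mean(clade, col):
            sel = between[
                (between["clade_a"] == clade) ^ (between["clade_b"] == clade)
            ]
            return sel[col].mean()

        clades = ["primates", "rodents", "Laurasiatherians", "Afrotherians",
                  "marsupials"]
        raw = {c: clade_mean(c, "d_raw") for c in clades}
        norm = {c: clade_mean(c, "d_norm") for c in clades}
        # raw: marsupials among the two most divergent clades
        assert sorted(raw, key=raw.get, reverse=True).index("marsupials") <= 1
        # normalized: marsupials less divergent than rodents
        assert norm["marsupials"] < norm["rodents"]

    def test_expected_p_predicts_reversal(self, study_dataset):
        """The analytic oracle itself orders raw vs normalized correctly."""
        res = study_dataset
        total_len = sum(a.length for a in res.loci.values())

        def exp_dist(a, b):
            return (
                sum(
                    expected_p(res, a, b, name) * res.loci[name].length
                    for name in res.loci
                )
                / total_len
            )

        tree = res.config.tree
        raw_marsupial = exp_dist("marsupial1", "primate1")
        raw_rodent = exp_dist("rodent1", "primate1")
        raw_afro = exp_dist("afrotherian1", "primate1")
        assert raw_marsupial > raw_afro  # ancient split: large raw distance
        norm_marsupial = raw_marsupial / (tree.mrca_age("marsupial1", "primate1") / 100)
        norm_rodent = raw_rodent / (tree.mrca_age("rodent1", "primate1") / 100)
        assert norm_marsupial < norm_rodent
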