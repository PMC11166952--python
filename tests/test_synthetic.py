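import numpy as np
import pandas as pd
import pytest

import mima
from mima.errors import ConfigurationError, DegenerateDesignError
from mima.synthetic import (
    CohortConfig,
    generate_cohort,
    generate_deg_table,
    generate_interactome,
    generate_pathways,
    pre_post_design,
)
from tests.conftest import hypergeom_tail_enum


def small_config(**kw):
    base = dict(
        n_genes=15,
        n_planted=3,
        cell_types=("PBMC",),
        n_microbes_per_rank={("bacteria", "genus"): 10},
        seed=5,
    )
    base.update(kw)
    return CohortConfig(**base)


class TestGenerateCohort:
    def test_seed_determinism_byte_identical(self):
        outs = []
        for _ in range(2):
            expr, mic, truth = generate_cohort(small_config())
            outs.append(
                expr["PBMC"].data.to_csv() + mic[("bacteria", "genus")].data.to_csv()
            )
        assert outs[0] == outs[1]

    def test_no_planting_gives_empty_truth(self):
        _, _, truth = generate_cohort(small_config(n_planted=0))
        assert truth.planted_pairs == []

    def test_planted_ids_exist_in_matrices(self):
        expr, mic, truth = generate_cohort(small_config())
        for p in truth.planted_pairs:
            assert p.gene in expr[p.cell_type].data.index
            assert p.microbe in mic[(p.domain, p.rank)].data.index

    def test_microbe_zero_fraction_and_nonnegativity(self):
        cfg = small_config(n_genes=5, zero_inflation=0.4, n_microbes_per_rank={("bacteria", "genus"): 200})
        _, mic, _ = generate_cohort(cfg)
        values = mic[("bacteria", "genus")].data.to_numpy()
        assert (values >= 0).all()
        assert abs((values == 0).mean() - 0.4) < 0.05  # rounding adds a few extra zeros

    @pytest.mark.parametrize(
        "kw, field",
        [
            (dict(n_crew=1), "n_crew"),
            (dict(n_timepoints=1), "n_timepoints"),
            (dict(zero_inflation=1.0), "zero_inflation"),
            (dict(n_planted=1000), "n_planted"),
            (dict(planted_cell_type="nope"), "planted_cell_type"),
        ],
    )
    def test_invalid_config_names_field(self, kw, field):
        with pytest.raises(ConfigurationError, match=field):
            generate_cohort(small_config(**kw))

    def test_marginal_contract_of_nonplanted_genes(self):
        # mean tracks the baseline window and within-crew spread tracks noise_sd
        cfg = small_config(n_genes=1200, n_planted=0, noise_sd=0.5, crew_sd=0.5, seed=2)
        expr, _, _ = generate_cohort(cfg)
        values = expr["PBMC"].data.to_numpy()
        lo, hi = cfg.baseline_range
        assert abs(values.mean() - (lo + hi) / 2) < 0.1
        per_crew = values.reshape(cfg.n_genes, cfg.n_crew, cfg.n_timepoints)
        within_var = per_crew.var(axis=2, ddof=1).mean()
        assert abs(within_var - cfg.noise_sd**2) < 0.01


class TestDegTable:
    def test_identical_groups_not_deg(self, tiny_expression):
        expr = tiny_expression
        expr.data.loc["g1"] = [4.0, 6.0, 4.0, 6.0]
        design = {"crew1_T1": "pre", "crew1_T2": "pre", "crew2_T1": "post", "crew2_T2": "post"}
        table = generate_deg_table(expr, design).set_index("gene")
        assert table.loc["g1", "log2fc"] == 0.0
        assert not table.loc["g1", "is_deg"]

    def test_doubling_gives_log2fc_one(self, tiny_expression):
        expr = tiny_expression
        expr.data.loc["g2"] = [3.0, 3.0, 6.0, 6.0]
        design = {"crew1_T1": "pre", "crew1_T2": "pre", "crew2_T1": "post", "crew2_T2": "post"}
        table = generate_deg_table(expr, design).set_index("gene")
        assert table.loc["g2", "log2fc"] == pytest.approx(1.0)

    def test_small_group_rejected(self, tiny_expression):
        with pytest.raises(DegenerateDesignError):
            generate_deg_table(
                tiny_expression,
                {"crew1_T1": "pre", "crew1_T2": "post", "crew2_T1": "post", "crew2_T2": "post"},
            )

    def test_null_calibration(self):
        # both groups from the same distribution: ~5% of raw p-values below 0.05
        cfg = small_config(n_genes=2000, n_planted=0, crew_sd=0.0, seed=9)
        expr, _, _ = generate_cohort(cfg)
        table = generate_deg_table(expr["PBMC"], pre_post_design(expr["PBMC"]))
        frac = (table["p"] < 0.05).mean()
        assert 0.04 <= frac <= 0.06


class TestInteractome:
    def test_reproducible_edge_count(self):
        a, _ = generate_interactome(30, 100, 0.03, seed=4)
        b, _ = generate_interactome(30, 100, 0.03, seed=4)
        assert {c: len(g) for c, g in a.gene_sets.items()} == {c: len(g) for c, g in b.gene_sets.items()}
        assert a.gene_sets == b.gene_sets

    def test_density_bounds_checked(self):
        with pytest.raises(ConfigurationError):
            generate_interactome(10, 50, 1.5, seed=0)

    def test_null_interactome_false_positive_rate(self):
        # with no planting, unadjusted hits track alpha
        degs = [f"gene_{i:05d}" for i in range(1, 41)]
        rates = []
        for seed in range(8):
            inter, _ = generate_interactome(100, 400, 0.05, seed=seed)
            table = mima.compound_enrichment(degs, inter)
            rates.append((table["p"] < 0.05).mean())
        assert 0.0 <= float(np.mean(rates)) <= 0.12

    def test_planted_compound_recovered_with_hypergeometric_oracle(self):
        degs = [f"gene_{i:05d}" for i in range(1, 31)]
        inter, planted = generate_interactome(
            100, 300, 0.05, deg_genes=degs, n_planted=2, planted_deg_fraction=0.9, seed=7
        )
        table = mima.compound_enrichment(degs, inter).set_index("compound")
        universal = mima.build_universal_gene_set(inter)
        degs_in = set(degs) & universal
        for cid in planted:
            assert table.loc[cid, "significant"]
            genes = inter.gene_sets[cid]
            expected = hypergeom_tail_enum(
                len(genes & degs_in), len(universal), len(genes), len(degs_in)
            )
            assert table.loc[cid, "p"] == pytest.approx(expected, abs=1e-12)


class TestPathways:
    def test_planted_top_k_has_positive_es(self):
        genes = [f"g{i}" for i in range(60)]
        ranking = mima.make_ranking(genes, np.linspace(2, -2, 60))
        collection, planted = generate_pathways(
            5, (5, 8), genes, ranking=list(ranking.index), n_planted=2, concordance=1.0, seed=1
        )
        results = {r.pathway: r for r in mima.preranked_gsea(ranking, collection, n_perm=200, seed=0)}
        for name in planted:
            assert results[name].es > 0

    def test_empty_collection_round_trips_to_empty_result(self):
        collection, _ = generate_pathways(0, (2, 3), ["a", "b", "c"], seed=0)
        assert len(collection) == 0
        ranking = mima.make_ranking(["a", "b", "c"], [1.0, 0.5, -1.0])
        assert mima.preranked_gsea(ranking, collection, n_perm=100, seed=0) == []

    def test_oversized_sets_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_pathways(3, (5, 10), ["a", "b", "c"], seed=0)

    def test_random_sets_nes_centered_near_zero(self):
        # an antisymmetric score profile, so random-set ES has no sign bias
        genes = [f"g{i}" for i in range(80)]
        ranking = mima.make_ranking(genes, np.linspace(2, -2, 80))
        collection, _ = generate_pathways(30, (5, 10), genes, seed=3)
        results = mima.preranked_gsea(ranking, collection, n_perm=200, seed=1)
        nes = np.array([r.nes for r in results if np.isfinite(r.nes)])
        assert abs(nes.mean()) < 0.35


def test_effect_size_monotone_recovery():
    """Planted-pair support recovery by the screen is monotone in effect size."""
    def power(effect, seeds=range(6)):
        hits = total = 0
        for s in seeds:
            cfg = small_config(effect_size=effect, noise_sd=0.5, seed=100 + s)
            expr, mic, truth = generate_cohort(cfg)
            degs = {ct: list(e.genes) for ct, e in expr.items()}
            cands = mima.run_screen_all(expr, mic, degs, mima.ScreenConfig(seed=s), transforms=("log",))
            found = {(c.cell_type, c.gene, c.microbe, c.domain, c.rank) for c in cands}
            hits += len(truth.pair_keys() & found)
            total += len(truth.pair_keys())
        return hits / total

    assert power(1.0) >= power(0.25)
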