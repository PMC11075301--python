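import json

import numpy as np
import pytest

from menkit.diversity import bray_curtis_matrix, dissimilarity_test
from menkit.errors import ConfigurationError
from menkit.synthetic import (
    SyntheticConfig,
    generate_counts,
    generate_pathway_table,
)


def null_config(seed, **kw):
    """Config with every treatment effect switched off."""
    defaults = dict(
        n_asv=80, n_blocks=4, block_size=10, months=(1, 2),
        samples_per_group_month=6, depth=5000,
        effect_richness=0.0, effect_dominance=0.0, effect_network=1.0,
        seed=seed,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestConfigValidation:
    def test_blocks_exceeding_asvs(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(n_asv=10, n_blocks=3, block_size=5).validate()

    def test_bad_rho(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(rho_within=1.0).validate()

    def test_bad_halflife(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(recovery_halflife=0).validate()


class TestGenerateCounts:
    def test_column_sums_equal_depth(self):
        table, _ = generate_counts(null_config(1))
        assert (table.counts.sum(axis=0) == 5000).all()

    def test_seed_reproducibility(self):
        t1, _ = generate_counts(null_config(3))
        t2, _ = generate_counts(null_config(3))
        np.testing.assert_array_equal(t1.counts, t2.counts)
        t3, _ = generate_counts(null_config(4))
        assert (t1.counts != t3.counts).any()

    def test_truth_covers_blocks_and_months(self):
        cfg = null_config(5)
        table, truth = generate_counts(cfg)
        blocks = set(truth.block_membership.values())
        assert blocks == {0, 1, 2, 3, 4}
        assert set(truth.effect_trajectory) == set(cfg.months)
        assert truth.latents.shape == (cfg.n_asv, table.n_samples)

    def test_null_model_type_i_rate(self):
        # no effects -> groups exchangeable -> PERMANOVA rejects ~5%
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            cfg = null_config(seed, months=(1,), n_asv=40, n_blocks=2, depth=2000)
            table, _ = generate_counts(cfg)
            dist = bray_curtis_matrix(table)
            labels = table.metadata["group"].to_numpy()
            res = dissimilarity_test(dist, labels, "adonis", n_perm=99, seed=seed)
            if res.p_value <= 0.05:
                hits += 1
        assert 0.02 <= hits / n_rep <= 0.08

    def test_no_planted_signal_when_rho_zero(self):
        cfg = null_config(7, rho_within=0.0, months=(1,),
                          samples_per_group_month=100, depth=20000)
        table, truth = generate_counts(cfg)
        within, between = _block_correlations(table, truth)
        assert abs(within - between) < 0.05

    def test_strong_blocks_detectable(self):
        cfg = null_config(8, rho_within=0.9, months=(1,),
                          samples_per_group_month=50, depth=20000)
        table, truth = generate_counts(cfg)
        within, between = _block_correlations(table, truth)
        assert within - between >= 0.4

    def test_monotone_recovery_of_block_correlation(self):
        cfg = SyntheticConfig(
            n_asv=100, n_blocks=5, block_size=10, rho_within=0.9,
            months=(1, 5, 14), samples_per_group_month=40, depth=20000,
            effect_richness=0.0, effect_dominance=0.0, effect_network=0.2,
            recovery_halflife=3.0, seed=9,
        )
        table, truth = generate_counts(cfg)
        gaps = []
        for month in cfg.months:
            w_a, _ = _block_correlations(table.subset(group="A", month=month), truth)
            w_c, _ = _block_correlations(table.subset(group="C", month=month), truth)
            gaps.append(w_c - w_a)
        assert gaps[0] > gaps[1] > gaps[2] - 0.05
        assert gaps[0] > 0.2

    def test_richness_effect_depletes_group_a(self):
        cfg = SyntheticConfig(
            n_asv=100, n_blocks=2, block_size=10, months=(1,),
            samples_per_group_month=20, depth=10000,
            effect_richness=0.4, effect_dominance=0.0, effect_network=1.0,
            seed=10,
        )
        table, _ = generate_counts(cfg)
        richness_a = (table.subset(group="A").counts > 0).sum(axis=0).mean()
        richness_c = (table.subset(group="C").counts > 0).sum(axis=0).mean()
        assert richness_a < richness_c - 10


def _block_correlations(table, truth):
    la = np.log10(table.counts + 1)
    ok = la.std(axis=1) > 0
    corr = np.corrcoef(la[ok])
    blocks = np.array(
        [truth.block_membership[a] for a, k in zip(table.asv_ids, ok) if k]
    )
    n = blocks.size
    iu, ju = np.triu_indices(n, k=1)
    same = (blocks[iu] == blocks[ju]) & (blocks[iu] > 0)
    vals = np.abs(corr[iu, ju])
    return vals[same].mean(), vals[~same].mean()


class TestGeneratePathwayTable:
    def test_shape_and_determinism(self):
        a = generate_pathway_table(30, 20, 5, 0.9, seed=1)
        b = generate_pathway_table(30, 20, 5, 0.9, seed=1)
        assert a.shape == (30, 20)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_zero_samples_errors(self):
        with pytest.raises(ConfigurationError):
            generate_pathway_table(10, 0, 2, 0.5, seed=0)

    def test_oversized_clique_errors(self):
        with pytest.raises(ConfigurationError):
            generate_pathway_table(5, 10, 6, 0.5, seed=0)

    def test_null_table_sparse_network(self):
        from menkit.funcnet import build_pathway_network

        table = generate_pathway_table(60, 100, 8, 0.0, seed=2)
        net = build_pathway_network(table, r_cut=0.8, p_cut=0.05)
        possible = 60 * 59 / 2
        assert net.number_of_edges() / possible <= 0.05

    def test_truth_json_round_trip(self, tmp_path):
        _, truth = generate_counts(null_config(11))
        path = tmp_path / "truth.json"
        truth.to_json(path)
        data = json.loads(path.read_text())
        assert data["block_membership"] == truth.block_membership
        assert len(data["latents"]["sample_ids"]) == truth.latents.shape[1]
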