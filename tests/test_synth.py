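import dataclasses

import numpy as np
import pandas as pd
import pytest

from limbphylo import conservation, divergence, synth
from limbphylo.normalize import LIMBS, STAGES

from conftest import SPECIES, TREE


def make_cfg(**kw) -> synth.SimConfig:
    base = dict(
        species_tree=TREE,
        n_core_orthologs=40,
        n_specific_per_species=5,
        stage_divergence_sd={"ridge": 0.1, "bud": 0.3, "paddle": 0.5},
        noise_sd=0.05,
        n_replicates=2,
        seq_depth=200_000,
        seed=1,
    )
    base.update(kw)
    return synth.SimConfig(**base)


class TestConfigValidation:
    def test_unknown_tai_shape(self):
        with pytest.raises(synth.ConfigError, match="tai_shape"):
            make_cfg(tai_shape="pear").validate()

    def test_invalid_stage_set(self):
        with pytest.raises(synth.ConfigError, match="stage"):
            make_cfg(stage_divergence_sd={"ridge": 0.1, "bud": 0.1}).validate()

    def test_non_positive_depth(self):
        with pytest.raises(synth.ConfigError, match="seq_depth"):
            make_cfg(seq_depth=0).validate()

    def test_negative_sd(self):
        with pytest.raises(synth.ConfigError):
            make_cfg(noise_sd=-1.0).validate()


class TestGenerateDataset:
    def test_dimensions(self, small_dataset, small_config):
        ds = small_dataset
        cfg = small_config
        assert ds.species == SPECIES
        for sp in ds.species:
            n_samples = 2 * 3 * cfg.n_replicates
            assert ds.counts[sp].shape[1] == n_samples
            assert ds.fpkm[sp].values.shape == ds.counts[sp].shape
            assert (ds.counts[sp].values >= 0).all()
            assert (ds.fpkm[sp].values.values >= 0).all()
        assert len(ds.core_groups()) == cfg.n_core_orthologs

    def test_core_in_every_species_specific_in_one(self, small_dataset):
        ds = small_dataset
        core = ds.core_groups()
        for sp in ds.species:
            assert core[sp].isin(ds.counts[sp].index).all()
        for sp in ds.species:
            spec = [g for g, ps in ds.truth["ps"][sp].items() if ps == 1]
            for other in ds.species:
                present = pd.Index(spec).isin(ds.counts[other].index)
                assert present.all() if other == sp else not present.any()

    def test_truth_covers_every_gene(self, small_dataset):
        ds = small_dataset
        for sp in ds.species:
            assert set(ds.truth["ps"][sp]) == set(ds.counts[sp].index)

    def test_zero_divergence_limit_gives_perfect_spearman(self):
        cfg = make_cfg(
            stage_divergence_sd={"ridge": 0.0, "bud": 0.0, "paddle": 0.0},
            noise_sd=0.0,
        )
        ds = synth.generate_dataset(cfg)
        core = ds.core_groups()
        for limb in LIMBS:
            for stage in STAGES:
                cols = {
                    sp: ds.fpkm[sp]
                    .values[f"{sp}_{limb}_{stage}_r1"]
                    .loc[core[sp]]
                    .values
                    for sp in ds.species
                }
                profiles = pd.DataFrame(cols, index=core.index)
                c = conservation.mean_pairwise_spearman(profiles)
                assert c == pytest.approx(1.0)

    def test_no_limb_effect_means_no_truth_flags(self):
        ds = synth.generate_dataset(make_cfg(limb_effect_genes=5, limb_effect_size=0.0))
        assert all(not v for v in ds.truth["limb_divergent"].values())

    def test_planted_genes_top_by_divergence_score_at_zero_noise(self):
        cfg = make_cfg(
            limb_effect_genes=4,
            limb_effect_size=6.0,
            noise_sd=0.0,
            stage_divergence_sd={"ridge": 0.0, "bud": 0.0, "paddle": 0.0},
        )
        ds = synth.generate_dataset(cfg)
        sp = "mouse"
        fore = ds.fpkm[sp].values[f"{sp}_fore_bud_r1"]
        hind = ds.fpkm[sp].values[f"{sp}_hind_bud_r1"]
        sc = divergence.score_within(fore, hind)
        top = set(sc.scores.nlargest(4).index)
        assert top == set(ds.truth["limb_divergent"][sp])

    def test_pairwise_homolog_counts_follow_clades(self):
        ds = synth.generate_dataset(make_cfg(n_specific_per_clade=10))
        hits = ds.homology

        def n(a, b):
            sub = hits[(hits.qspecies == a) & (hits.sspecies == b)]
            return sub["qseqid"].nunique()

        # closer pairs share more genes when clade-specific genes exist
        assert n("bat", "pig") > n("bat", "mouse") > n("bat", "opossum")
        # core-only pair count equals the core size
        assert n("pig", "opossum") == 40

    def test_no_homology_records_for_specific_genes(self, small_dataset):
        ds = small_dataset
        spec = {g for sp in ds.species for g, p in ds.truth["ps"][sp].items() if p == 1}
        assert not ds.homology["qseqid"].isin(spec).any()
        assert not ds.homology["sseqid"].isin(spec).any()

    def test_deterministic_given_seed(self):
        a = synth.generate_dataset(make_cfg(seed=9))
        b = synth.generate_dataset(make_cfg(seed=9))
        for sp in a.species:
            pd.testing.assert_frame_equal(a.counts[sp], b.counts[sp])
            pd.testing.assert_frame_equal(a.fpkm[sp].values, b.fpkm[sp].values)
        pd.testing.assert_frame_equal(a.homology, b.homology)

    def test_stage_divergence_ordering_over_seeds(self):
        # Monte-Carlo: mean pairwise Spearman strictly decreasing
        # ridge -> bud -> paddle in >= 95% of seeds
        ok = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = make_cfg(
                seed=seed,
                n_core_orthologs=120,
                stage_divergence_sd={"ridge": 0.1, "bud": 0.5, "paddle": 1.0},
                n_replicates=1,
            )
            ds = synth.generate_dataset(cfg)
            core = ds.core_groups()
            cs = {}
            for stage in STAGES:
                cols = {
                    sp: ds.fpkm[sp]
                    .values[f"{sp}_fore_{stage}_r1"]
                    .loc[core[sp]]
                    .values
                    for sp in ds.species
                }
                cs[stage] = conservation.mean_pairwise_spearman(
                    pd.DataFrame(cols, index=core.index)
                )
            if cs["ridge"] > cs["bud"] > cs["paddle"]:
                ok += 1
        assert ok >= 0.95 * n_seeds


class TestWriteDataset:
    def test_round_trip_identity(self, small_dataset, tmp_path):
        synth.write_dataset(small_dataset, tmp_path)
        back = synth.read_dataset(tmp_path)
        for sp in small_dataset.species:
            pd.testing.assert_frame_equal(
                back.counts[sp], small_dataset.counts[sp]
            )
            np.testing.assert_allclose(
                back.fpkm[sp].values.values,
                small_dataset.fpkm[sp].values.values,
                rtol=1e-5,
            )
        pd.testing.assert_frame_equal(back.homology, small_dataset.homology)
        assert back.truth["ps"] == small_dataset.truth["ps"]

    def test_empty_dataset_round_trips(self, tmp_path):
        cfg = make_cfg(n_core_orthologs=0, n_specific_per_species=0)
        ds = synth.generate_dataset(cfg)
        synth.write_dataset(ds, tmp_path)
        back = synth.read_dataset(tmp_path)
        for sp in back.species:
            assert back.counts[sp].empty
        assert back.homology.empty

    def test_manifest_row_counts(self, small_dataset, tmp_path):
        manifest = synth.write_dataset(small_dataset, tmp_path)
        for name, meta in manifest["files"].items():
            path = tmp_path / name
            assert path.exists()
            if name.endswith(".tsv"):
                n_rows = sum(1 for _ in open(path)) - 1  # header
                assert meta["rows"] == n_rows

    def test_fixed_seed_byte_identical_files(self, tmp_path):
        ds1 = synth.generate_dataset(make_cfg(seed=5))
        ds2 = synth.generate_dataset(make_cfg(seed=5))
        d1, d2 = tmp_path / "a", tmp_path / "b"
        synth.write_dataset(ds1, d1)
        synth.write_dataset(ds2, d2)
        assert synth.dataset_digest(d1) == synth.dataset_digest(d2)
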