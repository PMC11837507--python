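import dataclasses
import filecmp

import numpy as np
import pandas as pd
import pytest

from qsip15n.enrichment import DEFAULT_CONSTANTS
from qsip15n.simulate import (
    SimulationConfig,
    simulate_study,
    simulate_taxa,
    study_samples,
    true_centers,
)

SMALL = SimulationConfig(n_taxa=12, seed=5)


class TestConfig:
    def test_validate_rejects_bad_values(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_taxa=0).validate()
        with pytest.raises(ValueError):
            SimulationConfig(kernel_sd=0.0).validate()
        with pytest.raises(ValueError):
            SimulationConfig(eaf_zero_prob=1.5).validate()

    def test_design_arithmetic(self):
        metas = study_samples(SimulationConfig())
        assert len(metas) == 2 * 7 * 3
        assert sum(m.label == "unlabeled" for m in metas) == 14


class TestTaxa:
    def test_determinism(self):
        a = simulate_taxa(SMALL).taxa
        b = simulate_taxa(SMALL).taxa
        pd.testing.assert_frame_equal(a, b)

    def test_ranges_and_normalization(self):
        t = simulate_taxa(SimulationConfig(n_taxa=200, seed=1)).taxa
        assert t["gc"].between(0.25, 0.75).all()
        assert t["abundance"].sum() == pytest.approx(1.0)
        assert (t["eaf_lab"] >= 0).all() and (t["eaf_lab"] <= 0.6).all()
        assert (t["eaf_field"] >= 0).all()

    def test_degenerate_all_unenriched(self):
        cfg = dataclasses.replace(
            SMALL, eaf_zero_prob=1.0, field_intercept=0.0, field_noise_sd=0.0
        )
        t = simulate_taxa(cfg).taxa
        assert (t["eaf_lab"] == 0).all() and (t["eaf_field"] == 0).all()

    def test_field_map_exact_when_noiseless(self):
        cfg = dataclasses.replace(SMALL, field_noise_sd=0.0)
        t = simulate_taxa(cfg).taxa
        np.testing.assert_allclose(
            t["eaf_field"], 0.81 * t["eaf_lab"] + 0.01, atol=1e-12
        )

    def test_identity_map_makes_methods_agree(self):
        cfg = dataclasses.replace(
            SMALL, field_slope=1.0, field_intercept=0.0, field_noise_sd=0.0
        )
        t = simulate_taxa(cfg).taxa
        np.testing.assert_array_equal(t["eaf_lab"], t["eaf_field"])

    def test_true_centers_shift_with_enrichment(self):
        truth = simulate_taxa(SimulationConfig(n_taxa=50, seed=2))
        light = true_centers(truth, None)
        lab = true_centers(truth, "lab")
        enriched = truth.taxa["eaf_lab"].to_numpy() > 0
        assert (lab[enriched] > light[enriched]).all()
        np.testing.assert_allclose(lab[~enriched], light[~enriched], rtol=1e-12)
        # light centers follow the GC calibration line
        gc = truth.taxa["gc"].to_numpy()
        np.testing.assert_allclose(
            light, DEFAULT_CONSTANTS.gc_intercept + DEFAULT_CONSTANTS.gc_slope * gc
        )


class TestStudy:
    def test_determinism_and_structure(self):
        t1, m1, metas1, truth1 = simulate_study(SMALL)
        t2, m2, metas2, truth2 = simulate_study(SMALL)
        assert len(t1) == 42 and metas1 == metas2
        pd.testing.assert_frame_equal(m1.counts, m2.counts)
        pd.testing.assert_frame_equal(truth1.taxa, truth2.taxa)
        assert truth1.tube_offsets == truth2.tube_offsets
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.total_copies, b.total_copies)

    def test_different_seed_changes_data(self):
        _, m1, _, _ = simulate_study(SMALL)
        _, m2, _, _ = simulate_study(dataclasses.replace(SMALL, seed=6))
        assert not m1.counts.equals(m2.counts)

    def test_counts_respect_window_and_depth(self):
        tubes, matrix, _, truth = simulate_study(SMALL)
        lo, hi = truth.config.analysis_window
        for t in tubes:
            for fid, d in zip(t.fraction_ids, t.densities):
                col = matrix.counts[fid]
                if lo <= d <= hi:
                    assert col.sum() == truth.config.seq_depth
                else:
                    assert col.sum() == 0

    def test_infinite_depth_gives_exact_proportions(self):
        cfg = dataclasses.replace(SMALL, seq_depth=None)
        tubes, matrix, _, truth = simulate_study(cfg)
        lo, hi = cfg.analysis_window
        t = tubes[0]
        inside = [f for f, d in zip(t.fraction_ids, t.densities) if lo <= d <= hi]
        sums = matrix.counts[inside].sum(axis=0)
        np.testing.assert_allclose(sums[sums > 0], 1e6, rtol=1e-9)

    def test_files_byte_identical_across_runs(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_study(SMALL, out_dir=d1)
        simulate_study(SMALL, out_dir=d2)
        names = [p.name for p in d1.iterdir()]
        assert set(names) >= {
            "fractions.tsv", "counts.tsv", "taxonomy.tsv", "samples.tsv",
            "truth.tsv", "tube_offsets.tsv", "sim_config.tsv",
        }
        match, mismatch, errors = filecmp.cmpfiles(d1, d2, names, shallow=False)
        assert not mismatch and not errors

    def test_refuses_nonempty_dir_without_force(self, tmp_path):
        (tmp_path / "existing.txt").write_text("x")
        with pytest.raises(FileExistsError):
            simulate_study(SMALL, out_dir=tmp_path)
        simulate_study(SMALL, out_dir=tmp_path, force=True)
        assert (tmp_path / "fractions.tsv").exists()

    def test_written_files_round_trip_to_pipeline_inputs(self, tmp_path):
        from qsip15n import io as qio

        tubes, matrix, metas, _ = simulate_study(SMALL, out_dir=tmp_path)
        back_tubes = qio.read_fraction_table(tmp_path / "fractions.tsv")
        back = qio.read_taxon_counts(
            tmp_path / "counts.tsv", tmp_path / "taxonomy.tsv", back_tubes
        )
        back_metas = qio.read_sample_table(tmp_path / "samples.tsv")
        assert back_metas == metas
        assert back.shape == matrix.shape
        np.testing.assert_allclose(
            back.counts.to_numpy(), matrix.counts.to_numpy(), rtol=1e-9
        )

    def test_multiple_asvs_per_genus_conserve_counts(self):
        cfg = dataclasses.replace(SMALL, asvs_per_genus=3, seq_depth=None)
        _, m3, _, truth = simulate_study(cfg)
        assert m3.counts.shape[0] == 3 * cfg.n_taxa
        from qsip15n.filtering import aggregate_to_genus

        g = aggregate_to_genus(m3)
        assert len(g.genera) == cfg.n_taxa
        _, m1, _, _ = simulate_study(dataclasses.replace(cfg, asvs_per_genus=1))
        np.testing.assert_allclose(
            np.sort(g.counts.to_numpy().sum(axis=1)),
            np.sort(m1.counts.to_numpy().sum(axis=1)),
            rtol=1e-6,
        )

    def test_smoke_tiny(self):
        tubes, matrix, metas, _ = simulate_study(
            SimulationConfig(n_taxa=5, seq_depth=100, seed=3)
        )
        assert len(tubes) == 42 and matrix.counts.shape[0] == 5
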