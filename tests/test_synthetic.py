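"""Synthetic-spectrum generator: determinism, degenerate limits, templates
and the planted discriminant structure."""

import numpy as np
import pytest

from evspec.bands import sum_bands
from evspec.preprocess import preprocess_pipeline
from evspec.synthetic import (
    GeneratorConfig,
    albumin_reference_bands,
    default_config,
    default_group_templates,
    generate_dataset,
    generate_null_dataset,
)


class TestTemplates:
    def test_each_group_mirrors_assignment_table(self):
        templates = default_group_templates()
        teir = {b.center: b.assignment for b in templates["TEIR"]}
        assert teir[1743.0] == "CO stretching-phospholipid"
        sec = {b.center: b.assignment for b in templates["SEC"]}
        assert sec[977.0] == "O-P-O symmetric stretching of phospholipids"
        uc = {b.center for b in templates["UC"]}
        assert 1665.0 in uc
        # range rows appear at their midpoints
        assert 1562.5 in teir and 1384.0 in teir

    def test_albumin_reference_band_ordering(self):
        bands = {b.center: b.amplitude for b in albumin_reference_bands()}
        assert {1650.0, 1550.0, 1450.0, 1070.0} <= set(bands)
        assert bands[1650.0] > bands[1550.0] > bands[1450.0]
        assert all(950 <= c <= 1920 for c in bands)


class TestGenerateDataset:
    def test_seeded_determinism(self):
        cfg = default_config(seed=99, n_per_group=4)
        s1, t1 = generate_dataset(cfg)
        s2, t2 = generate_dataset(default_config(seed=99, n_per_group=4))
        np.testing.assert_array_equal(s1.intensities, s2.intensities)
        np.testing.assert_array_equal(t1.albumin_fraction, t2.albumin_fraction)
        s3, _ = generate_dataset(default_config(seed=100, n_per_group=4))
        assert not np.array_equal(s1.intensities, s3.intensities)

    def test_degenerate_config_reproduces_templates(self):
        cfg = default_config(seed=1, n_per_group=2)
        cfg.noise_sd = 0.0
        cfg.baseline_coeff_scale = 0.0
        cfg.contaminant_rate = 0.0
        cfg.albumin_fraction = {g: (0.0, 0.0) for g in cfg.groups}
        cfg.amplitude_jitter_cv = {g: 0.0 for g in cfg.groups}
        cfg.wavenumber_shift_sd = 0.0
        spectra, _ = generate_dataset(cfg)
        for g in cfg.groups:
            template = sum_bands(cfg.axis, cfg.group_templates[g])
            for row in spectra.intensities[spectra.labels == g]:
                np.testing.assert_allclose(row, template, atol=1e-12)

    def test_amplitude_linearity(self):
        cfg = default_config(seed=2, n_per_group=2)
        cfg.noise_sd = 0.0
        cfg.baseline_coeff_scale = 0.0
        cfg.contaminant_rate = 0.0
        cfg.albumin_fraction = {g: (0.0, 0.0) for g in cfg.groups}
        cfg.amplitude_jitter_cv = {g: 0.0 for g in cfg.groups}
        cfg.wavenumber_shift_sd = 0.0
        s1, _ = generate_dataset(cfg)
        cfg2 = default_config(seed=2, n_per_group=2)
        cfg2.noise_sd = 0.0
        cfg2.baseline_coeff_scale = 0.0
        cfg2.contaminant_rate = 0.0
        cfg2.albumin_fraction = {g: (0.0, 0.0) for g in cfg2.groups}
        cfg2.amplitude_jitter_cv = {g: 0.0 for g in cfg2.groups}
        cfg2.wavenumber_shift_sd = 0.0
        cfg2.group_templates = {
            g: [b.scaled(2.0) for b in bands] for g, bands in cfg2.group_templates.items()
        }
        s2, _ = generate_dataset(cfg2)
        np.testing.assert_allclose(s2.intensities, 2.0 * s1.intensities, rtol=1e-12)

    def test_row_counts_labels_and_finiteness(self, profile_draw):
        cfg, spectra, truth = profile_draw
        assert spectra.n == 3 * cfg.n_per_group
        assert np.all(np.isfinite(spectra.intensities))
        for g in cfg.groups:
            assert int((spectra.labels == g).sum()) == cfg.n_per_group
        assert truth.albumin_fraction.shape == (spectra.n,)
        assert 0 <= truth.is_contaminant.mean() < 0.3

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            default_config(seed=1, n_per_group=1)
        with pytest.raises(ValueError):
            GeneratorConfig(seed=1, noise_sd=-0.1)
        with pytest.raises(ValueError):
            GeneratorConfig(seed=1, albumin_fraction={"TEIR": (1.2, 0.1),
                                                      "UC": (0.3, 0.1),
                                                      "SEC": (0.2, 0.1)})

    def test_config_json_round_trip(self, tmp_path):
        cfg = default_config(seed=123, n_per_group=5)
        path = tmp_path / "cfg.json"
        cfg.to_json(path)
        back = GeneratorConfig.from_json(path)
        assert back.seed == 123 and back.n_per_group == 5
        s1, _ = generate_dataset(cfg)
        s2, _ = generate_dataset(back)
        np.testing.assert_array_equal(s1.intensities, s2.intensities)


class TestPlantedStructure:
    def test_max_group_difference_in_phosphate_window(self, profile_preprocessed):
        """The strongest between-group contrast sits at the O-P-O band."""
        pre = profile_preprocessed
        wn = pre.axis.values
        means = np.array(
            [pre.intensities[pre.labels == g].mean(axis=0) for g in ("TEIR", "UC", "SEC")]
        )
        w = wn[np.argmax(means.max(axis=0) - means.min(axis=0))]
        assert 967 <= w <= 982

    def test_planted_windows_dominate_between_group_variance(self, profile_preprocessed):
        pre = profile_preprocessed
        wn = pre.axis.values
        means = np.array(
            [pre.intensities[pre.labels == g].mean(axis=0) for g in ("TEIR", "UC", "SEC")]
        )
        v = means.var(axis=0)
        win = ((wn >= 967) & (wn <= 982)) | ((wn >= 1025) & (wn <= 1040))
        width = int(win.sum())
        planted = v[win].sum()
        for s in range(len(wn) - width):
            if not np.any(win[s:s + width]):
                assert v[s:s + width].sum() < planted


class TestNullGenerator:
    def test_groups_share_one_distribution(self):
        cfg = default_config(seed=42, n_per_group=30)
        cfg.axis_step = 8.0
        spectra, _ = generate_null_dataset(cfg)
        means = [spectra.intensities[spectra.labels == g].mean(axis=0)
                 for g in ("TEIR", "UC", "SEC")]
        spread = np.max(np.abs(means[0] - means[1]))
        within = spectra.intensities.std(axis=0).max()
        assert spread < within  # group means differ only by sampling noise

    def test_seeded_determinism(self):
        cfg = default_config(seed=7, n_per_group=3)
        a, _ = generate_null_dataset(cfg)
        b, _ = generate_null_dataset(default_config(seed=7, n_per_group=3))
        np.testing.assert_array_equal(a.intensities, b.intensities)
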