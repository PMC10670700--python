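"""Synthetic Vis-NIR dataset generator: forward model and calibration."""

import dataclasses

import numpy as np
import pytest

from gastronir.contents import MEASURED_COMPONENTS, summarize_by_origin
from gastronir.models import PLSCalibration
from gastronir.partition import spxy_split
from gastronir.simulate import (
    COMPONENT_BANDS,
    DEFAULT_ORIGINS,
    OriginSpec,
    SyntheticConfig,
    component_spectra,
    generate_dataset,
    sample_concentrations,
)

PUBLISHED_BATCHES = {
    "DJ": 25, "DAF": 40, "LS": 40, "PUA": 25, "LP": 25, "LJ": 5,
    "ZT": 5, "YC": 20, "WF": 5, "LY": 30, "DF": 20,
}


class TestComponentSpectra:
    def test_single_band_peaks_at_its_center(self):
        bands = dict(COMPONENT_BANDS)
        bands["GA"] = ((980.0, 30.0, 1.0),)
        cfg = SyntheticConfig(bands=bands)
        E = component_spectra(cfg)
        assert np.argmax(E[0]) == cfg.grid.index_of(980.0)

    def test_zero_weights_rejected(self):
        bands = dict(COMPONENT_BANDS)
        bands["GA"] = ((980.0, 30.0, 0.0),)
        with pytest.raises(ValueError, match="zero absorptivity"):
            component_spectra(SyntheticConfig(bands=bands))

    def test_components_pairwise_distinct(self):
        E = component_spectra(SyntheticConfig())
        unit = E / np.linalg.norm(E, axis=1, keepdims=True)
        cos = unit @ unit.T
        iu = np.triu_indices(len(E), k=1)
        assert cos[iu].max() < 0.999

    def test_band_outside_grid_rejected(self):
        bands = dict(COMPONENT_BANDS)
        bands["GA"] = ((3000.0, 30.0, 1.0),)
        with pytest.raises(ValueError, match="outside the grid"):
            SyntheticConfig(bands=bands)

    def test_gaussian_band_integral(self):
        # analytic oracle: integral of a*exp(-x^2/2w^2) = a*w*sqrt(2*pi)
        bands = dict(COMPONENT_BANDS)
        amp, width = 0.7, 30.0
        bands["GA"] = ((1400.0, width, amp),)
        cfg = SyntheticConfig(bands=bands)
        E = component_spectra(cfg)
        integral = E[0].sum() * cfg.grid.step_nm
        assert integral == pytest.approx(amp * width * np.sqrt(2 * np.pi),
                                         rel=0.01)


class TestSampleConcentrations:
    def test_large_sample_mean_recovers_origin_mean(self):
        dj = next(o for o in DEFAULT_ORIGINS if o.code == "DJ")
        cfg = SyntheticConfig(
            origins=(dataclasses.replace(dj, n_samples=5000),)
        )
        table, labels = sample_concentrations(cfg, seed=4)
        assert set(labels) == {"DJ"}
        ga = table.values_for("GA")
        assert ga.mean() == pytest.approx(4.7040, rel=0.02)

    def test_zero_within_cv_gives_identical_samples(self):
        cfg = SyntheticConfig(within_cv=0.0)
        table, labels = sample_concentrations(cfg, seed=1)
        frame = table.data.copy()
        frame["origin"] = labels
        for _, grp in frame.groupby("origin"):
            assert (grp[list(MEASURED_COMPONENTS)].nunique() == 1).all()

    def test_summary_recovers_configured_means(self):
        cfg = SyntheticConfig(
            origins=tuple(
                dataclasses.replace(o, n_samples=400) for o in DEFAULT_ORIGINS
            )
        )
        table, labels = sample_concentrations(cfg, seed=2)
        summary = summarize_by_origin(table, labels)
        for origin in cfg.origins:
            got = summary.origin_means.loc[origin.code, "GA"]
            assert got == pytest.approx(origin.component_means[0], rel=0.05)

    def test_all_concentrations_positive(self):
        table, _ = sample_concentrations(SyntheticConfig(within_cv=0.6), seed=3)
        assert (table.data[list(MEASURED_COMPONENTS)].to_numpy() > 0).all()


class TestGenerateDataset:
    def test_default_shape_and_replicates(self):
        cfg = SyntheticConfig()
        ds = generate_dataset(cfg, seed=0)
        assert cfg.n_samples == 240  # published batch structure
        assert ds.spectra.absorbance.shape == (240 * 3, 1050)
        assert len(ds.replicate_groups) == 240
        assert all(len(v) == 3 for v in ds.replicate_groups.values())
        counts = {c: ds.labels.count(c) for c in set(ds.labels)}
        assert counts == PUBLISHED_BATCHES
        averaged = ds.averaged()
        assert averaged.absorbance.shape == (240, 1050)

    def test_noiseless_config_is_exact_linear_mixture(self):
        cfg = SyntheticConfig().noiseless()
        ds = generate_dataset(cfg, seed=5)
        E = component_spectra(cfg)
        C = ds.contents.data[list(MEASURED_COMPONENTS)].to_numpy()
        resid = ds.spectra.absorbance - C @ E
        assert np.abs(resid).max() < 1e-12

    def test_deterministic_under_seed(self):
        cfg = SyntheticConfig().scaled(0.1)
        a = generate_dataset(cfg, seed=9)
        b = generate_dataset(cfg, seed=9)
        np.testing.assert_array_equal(a.spectra.absorbance, b.spectra.absorbance)
        assert (a.contents.data == b.contents.data).all().all()
        c = generate_dataset(cfg, seed=10)
        assert not np.array_equal(a.spectra.absorbance, c.spectra.absorbance)

    def test_noiseless_plsr_identifies_contents(self):
        # linear identifiability: PLSR recovers a mixture coefficient exactly
        cfg = SyntheticConfig().noiseless().scaled(0.5)
        ds = generate_dataset(cfg, seed=6)
        X = ds.spectra.absorbance
        y = ds.contents.values_for("GA")
        split = spxy_split(X, y, 0.25)
        tr, te = list(split.train_indices), list(split.test_indices)
        model = PLSCalibration(n_components=8).fit(X[tr], y[tr])
        pred = model.predict(X[te])
        r2 = 1 - np.sum((pred - y[te]) ** 2) / np.sum(
            (y[te] - y[te].mean()) ** 2
        )
        assert r2 >= 0.999

    def test_zero_separation_removes_origin_signal(self):
        from gastronir.models import KNNModel
        from gastronir.preprocessing import PreprocessConfig, apply_pipeline

        cfg = dataclasses.replace(SyntheticConfig().scaled(0.5), separation=0.0)
        ds = generate_dataset(cfg, seed=7)
        avg = ds.averaged()
        pre = apply_pipeline(avg, PreprocessConfig())
        codes = cfg.class_codes(avg.origin_labels)
        split = spxy_split(pre.absorbance, codes.astype(float), 0.25)
        tr, te = list(split.train_indices), list(split.test_indices)
        model = KNNModel(k=3).fit(pre.absorbance[tr], codes[tr])
        acc = np.mean(model.predict(pre.absorbance[te]) == codes[te])
        assert acc < 0.5  # collapses toward chance (1/11) without separation

    def test_invalid_origin_specs_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            OriginSpec("X", 5, (0.0, 1, 1, 1, 1, 1), (1, 1, 1))
        with pytest.raises(ValueError, match="n_samples"):
            OriginSpec("X", 0, (1, 1, 1, 1, 1, 1), (1, 1, 1))
        with pytest.raises(ValueError, match="replicates"):
            SyntheticConfig(replicates=0)
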