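import dataclasses
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from eggshell import (
    Dataset,
    ValidationError,
    apply_combat,
    batch_cv,
    cv_report,
    default_config,
    fit_combat,
    generate_dataset_with_truth,
    reduction_rate,
    summarize_colors,
)
from eggshell.batch_correction import _it_sol
from .conftest import make_table, random_dataset


def _mvn_dataset(rng, n, batches, shift=None, scale=None):
    """MVN colors split across batches with optional per-batch effects."""
    mean = np.array([80.0, -6.0, 10.0])
    cov = np.array([[16.0, 0.5, -2.0], [0.5, 2.0, 1.0], [-2.0, 1.0, 9.0]])
    colors = rng.multivariate_normal(mean, cov, size=n)
    obs = np.clip(rng.integers(1, 5, size=(n, 4)), 1, 4)
    batch = np.array([batches[i % len(batches)] for i in range(n)])
    for j, b in enumerate(batches):
        m = batch == b
        if scale is not None:
            colors[m] = (colors[m] - mean) * scale[j] + mean
        if shift is not None:
            colors[m] = colors[m] + shift[j]
    rows = [(batch[i], *colors[i], obs[i]) for i in range(n)]
    return Dataset(make_table(rows))


class TestFitApply:
    def test_no_batch_effect_leaves_data_nearly_unchanged(self, rng):
        """One distribution split arbitrarily into 2 batches: correction
        should be close to the identity."""
        ds = _mvn_dataset(rng, 600, ["B1", "B2"])
        corrected = apply_combat(fit_combat(ds), ds)
        sd = ds.colors.std(axis=0, ddof=1)
        rms = np.sqrt(((corrected.colors - ds.colors) ** 2).mean(axis=0))
        assert np.all(rms < 0.1 * sd)

    def test_known_shift_recovery(self, rng):
        ds = _mvn_dataset(rng, 600, ["B1", "B2"], shift=[(0, 0, 0), (0, 0, 10)])
        raw_means = ds.df.groupby("batch")["b"].mean()
        assert abs(raw_means["B2"] - raw_means["B1"]) > 9
        corrected = apply_combat(fit_combat(ds), ds)
        means = corrected.df.groupby("batch")["b"].mean()
        assert abs(means["B2"] - means["B1"]) < 0.5

    def test_eb_locations_shrink_toward_prior(self, rng):
        ds = _mvn_dataset(
            rng, 400, ["B1", "B2"], shift=[(1, 0.2, -0.5), (-1, -0.2, 0.5)]
        )
        model = fit_combat(ds)
        lo = np.minimum(model.gamma_hat, model.gamma_bar[:, None]) - 1e-12
        hi = np.maximum(model.gamma_hat, model.gamma_bar[:, None]) + 1e-12
        assert np.all(model.gamma_star >= lo) and np.all(model.gamma_star <= hi)

    def test_generator_ground_truth_recovered(self, calibrated):
        """Corrected values land within 0.5 RMS of the pre-effect colors."""
        _, ds, truth = calibrated
        corrected = apply_combat(fit_combat(ds), ds)
        clean = truth[["clean_L", "clean_a", "clean_b"]].to_numpy()
        rms = np.sqrt(((corrected.colors - clean) ** 2).mean(axis=0))
        assert np.all(rms < 0.5)

    def test_batch_medians_align(self, calibrated):
        _, ds, _ = calibrated
        corrected = apply_combat(fit_combat(ds), ds)
        med_raw = ds.df.groupby("batch")[["L", "a", "b"]].median()
        med_cor = corrected.df.groupby("batch")[["L", "a", "b"]].median()
        spread_raw = (med_raw - med_raw.median()).abs().max()
        spread_cor = (med_cor - med_cor.median()).abs().max()
        assert np.all(spread_cor.to_numpy() < spread_raw.to_numpy())

    def test_covariate_signal_preserved(self, calibrated):
        _, ds, _ = calibrated
        corrected = apply_combat(fit_combat(ds), ds)
        before = summarize_colors(ds).corr_with_aveobs
        after = summarize_colors(corrected).corr_with_aveobs
        assert np.all(np.sign(before) == np.sign(after))
        assert np.all((before - after).abs() < 0.05)

    def test_single_batch_rejected(self, rng):
        ds = _mvn_dataset(rng, 50, ["B1"])
        with pytest.raises(ValidationError, match="at least 2 batches"):
            fit_combat(ds)

    def test_singleton_batch_rejected(self, rng):
        ds = _mvn_dataset(rng, 51, ["B1", "B2", "B3"])
        keep = np.ones(51, dtype=bool)
        keep[np.flatnonzero(ds.df["batch"] == "B3")[1:]] = False
        ds = ds.subset(keep)
        with pytest.raises(ValidationError, match="size 1"):
            fit_combat(ds)

    def test_unseen_batch_rejected(self, rng):
        ds = _mvn_dataset(rng, 100, ["B1", "B2"])
        model = fit_combat(ds)
        other = _mvn_dataset(rng, 40, ["B9"])
        with pytest.raises(ValidationError, match="unseen batch"):
            apply_combat(model, other)

    def test_corrected_state_flag_and_labels_untouched(self, rng):
        ds = _mvn_dataset(rng, 80, ["B1", "B2"])
        corrected = apply_combat(fit_combat(ds), ds)
        assert corrected.state == "corrected"
        obs_cols = ["obs1", "obs2", "obs3", "obs4"]
        assert corrected.df[obs_cols].equals(ds.df[obs_cols])


class TestEBFallback:
    def test_single_feature_reduces_to_raw_location_scale(self, rng):
        """With one feature the MoM priors are degenerate: the adjustment
        falls back to the unshrunk per-batch estimates."""
        ds = _mvn_dataset(rng, 200, ["B1", "B2"], shift=[(0, 0, 0), (3, 0, 0)])
        model = fit_combat(ds, eb=False)
        assert np.allclose(model.gamma_star, model.gamma_hat)
        assert np.allclose(model.delta_star, model.delta_hat)

    def test_it_sol_fixed_point_is_posterior_consistent(self, rng):
        z = rng.normal(0.3, 1.2, size=(40, 3))
        g_hat = z.mean(axis=0)
        d_hat = z.var(axis=0, ddof=1)
        g_star, d_star = _it_sol(z, g_hat, d_hat, 0.0, 0.5, 3.0, 2.0)
        # at the fixed point the coupled update equations hold
        n = len(z)
        g_next = (0.5 * n * g_hat + d_star * 0.0) / (0.5 * n + d_star)
        assert np.allclose(g_next, g_star, rtol=1e-5)


class TestDiagnostics:
    def test_batch_cv_hand_example(self, rng):
        # batch means 10 and 20: SD 7.0711 over mean 15 -> 47.14%
        ds = _mvn_dataset(rng, 400, ["B1", "B2"])
        df = ds.df.copy()
        for c in ("L", "a", "b"):
            df[c] = np.where(df["batch"] == "B1", 10.0, 20.0)
        cv = batch_cv(Dataset(df))
        assert cv["L"] == pytest.approx(47.140452, abs=1e-4)

    def test_equal_batch_means_give_zero_cv(self, rng):
        ds = _mvn_dataset(rng, 100, ["B1", "B2"])
        df = ds.df.copy()
        for c in ("L", "a", "b"):
            df[c] = 42.0
        assert np.allclose(batch_cv(Dataset(df)), 0.0)

    @pytest.mark.parametrize(
        "before,after,expected",
        [(1.55, 0.35, 77.4), (8.40, 2.70, 67.9), (4.0, 4.0, 0.0)],
    )
    def test_reduction_rate(self, before, after, expected):
        assert reduction_rate(before, after) == pytest.approx(expected, abs=0.05)

    def test_reduction_rate_rejects_nonpositive_before(self):
        with pytest.raises(ValidationError):
            reduction_rate(0.0, 0.0)

    def test_cv_reduced_on_injected_batch_effects(self):
        """Correction lowers the batch-mean CV for every channel, across
        seeds, under survey-scale injected effects."""
        for seed in range(10):
            cfg = default_config(seed=seed)
            ds, _ = generate_dataset_with_truth(cfg, n_override=700)
            corrected = apply_combat(fit_combat(ds), ds)
            rep = cv_report(ds, corrected)
            assert np.all(
                rep["after_cv_percent"].to_numpy()
                <= rep["before_cv_percent"].to_numpy()
            )


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
class TestReferenceImplementation:
    def test_matches_sva_combat(self, tmp_path, rng):
        """Independent oracle: Bioconductor sva::ComBat on the same table."""
        cfg = default_config(seed=31)
        ds, _ = generate_dataset_with_truth(cfg, n_override=300)
        corrected = apply_combat(fit_combat(ds), ds)
        csv = tmp_path / "in.csv"
        ds.df[["batch", "L", "a", "b", "aveobs"]].to_csv(csv, index=False)
        script = tmp_path / "combat.R"
        script.write_text(
            'suppressMessages(library(sva))\n'
            f'd <- read.csv("{csv}")\n'
            'dat <- t(as.matrix(d[, c("L","a","b")]))\n'
            "mod <- model.matrix(~aveobs, data=d)\n"
            "out <- ComBat(dat=dat, batch=d$batch, mod=mod, par.prior=TRUE)\n"
            f'write.csv(t(out), "{tmp_path / "out.csv"}", row.names=FALSE)\n'
        )
        subprocess.run(
            ["Rscript", str(script)], check=True, capture_output=True
        )
        ref = pd.read_csv(tmp_path / "out.csv").to_numpy()
        assert np.abs(corrected.colors - ref).max() < 1e-3
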