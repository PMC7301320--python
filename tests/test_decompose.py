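import numpy as np
import pandas as pd
import pytest

from gonogopca.decompose import (
    CaseMatrix, SelectionRule, build_case_matrix, component_amplitude_map,
    covariance_pca, label_components, reconstitute, select_components,
    varimax_criterion, varimax_rotate,
)


def _case_matrix(data, montage, tag="go-placebo"):
    n = data.shape[0]
    meta = pd.DataFrame({
        "subject": np.arange(n) // 19, "block": 0,
        "channel": [montage.scalp_channels[i % 19] for i in range(n)],
    })
    times = -0.1 + np.arange(data.shape[1]) * 2 / 512.0
    return CaseMatrix(data=np.asarray(data, float), case_meta=meta,
                      times=times, tag=tag, montage=montage)


class TestCaseMatrix:
    def test_study_geometry_988_cases_218_variables(self, synthetic_averages):
        cm = build_case_matrix(synthetic_averages, "placebo", "go")
        assert cm.n_cases == 988           # 26 subjects x 2 blocks x 19 channels
        assert cm.n_variables == 218
        assert cm.case_to_variable_ratio == pytest.approx(4.53, abs=0.005)

    def test_single_subject_single_block_gives_19_rows(self, synthetic_averages):
        avg = synthetic_averages
        mask = ((avg.meta["subject"] == 0) & (avg.meta["block"] == 0)).to_numpy()
        from gonogopca.data import AverageSet
        sub = AverageSet(avg.data[mask], list(avg.channels), avg.times,
                         avg.sfreq, avg.meta.loc[mask].reset_index(drop=True),
                         avg.montage)
        cm = build_case_matrix(sub, "placebo", "go")
        assert cm.n_cases == 19

    def test_missing_cell_reported_by_key(self, synthetic_averages):
        avg = synthetic_averages
        drop = ~((avg.meta["subject"] == 3) & (avg.meta["block"] == 1)
                 & (avg.meta["drug"] == "placebo")
                 & (avg.meta["condition"] == "go")).to_numpy()
        from gonogopca.data import AverageSet
        sub = AverageSet(avg.data[drop], list(avg.channels), avg.times,
                         avg.sfreq, avg.meta.loc[drop].reset_index(drop=True),
                         avg.montage)
        with pytest.raises(ValueError, match=r"missing average cells.*3, 1"):
            build_case_matrix(sub, "placebo", "go")


class TestCovariancePca:
    def test_two_column_toy_eigenvalues(self, montage):
        """Columns with covariance [[2,1],[1,2]] have eigenvalues 3 and 1."""
        rng = np.random.default_rng(0)
        z = rng.normal(size=(20000, 2))
        root = np.linalg.cholesky(np.array([[2.0, 1.0], [1.0, 2.0]]))
        cm = _case_matrix(z @ root.T, montage)
        dec = covariance_pca(cm)
        assert dec.eigenvalues[0] == pytest.approx(3.0, rel=0.05)
        assert dec.eigenvalues[1] == pytest.approx(1.0, rel=0.05)

    def test_rank_one_data_carries_all_variance_in_first_factor(self, montage):
        t = np.linspace(0, 1, 50)
        shape = np.exp(-((t - 0.5) ** 2) / 0.01)
        scores = np.random.default_rng(1).normal(size=38)
        cm = _case_matrix(np.outer(scores, shape), montage)
        dec = covariance_pca(cm)
        assert dec.pct_variance[0] == pytest.approx(100.0, abs=1e-8)

    def test_keep_all_reconstruction_is_exact(self, montage):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(57, 30))
        dec = covariance_pca(_case_matrix(X, montage))
        recon = dec.scores @ dec.loadings.T + dec.column_means
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_zero_variance_column_guarded(self, montage):
        X = np.random.default_rng(3).normal(size=(40, 10))
        X[:, 4] = 1.23
        dec = covariance_pca(_case_matrix(X, montage))
        assert np.all(np.isfinite(dec.loadings))
        assert np.all(np.isfinite(dec.scores))

    def test_single_case_rejected(self, montage):
        with pytest.raises(ValueError, match="2 cases"):
            covariance_pca(_case_matrix(np.zeros((1, 10)), montage))


def _varimax_grid_search(L):
    """Brute-force oracle for a 2-factor rotation: scan all angles for the
    maximum of the Varimax criterion (on Kaiser-normalized loadings)."""
    h = np.sqrt((L ** 2).sum(axis=1, keepdims=True))
    Ln = L / h
    best_angle, best_val = 0.0, -np.inf
    for ang in np.linspace(0, np.pi / 2, 20001):
        c, s = np.cos(ang), np.sin(ang)
        R = np.array([[c, -s], [s, c]])
        val = varimax_criterion(Ln @ R)
        if val > best_val:
            best_angle, best_val = ang, val
    return best_angle, best_val


class TestVarimax:
    def _simple_loadings(self):
        t = np.linspace(0, 1, 60)
        f1 = 5.0 * np.exp(-((t - 0.3) ** 2) / 0.005)
        f2 = 3.0 * np.exp(-((t - 0.7) ** 2) / 0.005)
        return np.column_stack([f1, f2])

    def _toy_decomposition(self, L, montage):
        rng = np.random.default_rng(4)
        S = rng.normal(size=(500, 2))
        S = (S - S.mean(0)) / S.std(0, ddof=1)
        X = S @ L.T
        return covariance_pca(_case_matrix(X, montage))

    def test_mixed_factors_recovered_against_grid_search_oracle(self, montage):
        """PCA of data built from two localized factors is a rotated mix;
        Varimax undoes it, reaching the same criterion value as an
        exhaustive angle search and recovering the planted shapes."""
        L = self._simple_loadings()
        dec = self._toy_decomposition(L, montage)
        rot = varimax_rotate(dec)
        ang, oracle_val = _varimax_grid_search(dec.loadings[:, :2])
        h = np.sqrt((rot.loadings[:, :2] ** 2).sum(axis=1, keepdims=True))
        h[h < 1e-12] = 1.0
        achieved = varimax_criterion(rot.loadings[:, :2] / h)
        assert achieved >= oracle_val - 1e-6
        for k in range(2):
            planted = L[:, k]
            match = max(abs(np.corrcoef(planted, rot.loadings[:, j])[0, 1])
                        for j in range(2))
            assert match > 0.999

    def test_simple_structure_is_a_fixed_point(self, montage):
        L = self._simple_loadings()
        dec = self._toy_decomposition(L, montage)
        rot1 = varimax_rotate(dec)
        rot2 = varimax_rotate(rot1)
        for k in range(2):
            c = abs(np.dot(rot1.loadings[:, k], rot2.loadings[:, k])
                    / (np.linalg.norm(rot1.loadings[:, k])
                       * np.linalg.norm(rot2.loadings[:, k])))
            assert c > 1 - 1e-8

    def test_criterion_trace_non_decreasing(self, montage):
        X = np.random.default_rng(5).normal(size=(300, 40))
        rot = varimax_rotate(covariance_pca(_case_matrix(X, montage)))
        trace = rot.criterion_trace
        assert np.all(np.diff(trace) >= -1e-10)

    def test_rotation_matrix_orthonormal(self, montage):
        X = np.random.default_rng(6).normal(size=(200, 30))
        rot = varimax_rotate(covariance_pca(_case_matrix(X, montage)))
        R = rot.rotation
        assert np.linalg.norm(R.T @ R - np.eye(R.shape[1])) < 1e-8

    def test_communalities_preserved(self, montage):
        X = np.random.default_rng(7).normal(size=(200, 30))
        dec = covariance_pca(_case_matrix(X, montage))
        rot = varimax_rotate(dec)
        np.testing.assert_allclose((rot.loadings ** 2).sum(axis=1),
                                   (dec.loadings ** 2).sum(axis=1), rtol=1e-8)

    def test_percent_variance_total_preserved(self, montage):
        X = np.random.default_rng(8).normal(size=(200, 30))
        dec = covariance_pca(_case_matrix(X, montage))
        rot = varimax_rotate(dec)
        assert rot.pct_variance.sum() == pytest.approx(
            dec.pct_variance.sum(), abs=1e-6)

    def test_reconstruction_survives_rotation(self, montage):
        X = np.random.default_rng(9).normal(size=(100, 25))
        rot = varimax_rotate(covariance_pca(_case_matrix(X, montage)))
        recon = rot.scores @ rot.loadings.T + rot.column_means
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_peak_loadings_positive(self, montage):
        X = np.random.default_rng(10).normal(size=(100, 25))
        rot = varimax_rotate(covariance_pca(_case_matrix(X, montage)))
        peaks = rot.loadings[np.argmax(np.abs(rot.loadings), axis=0),
                             np.arange(rot.n_factors)]
        assert np.all(peaks >= 0)


class TestSelection:
    def _dec_with(self, montage, pct, labels=None):
        n = len(pct)
        dec = covariance_pca(_case_matrix(
            np.random.default_rng(11).normal(size=(60, n)), montage))
        dec.pct_variance = np.asarray(pct, float)
        if labels is not None:
            dec.labels = labels
        return dec

    def test_primary_floor_selects_in_variance_order(self, montage):
        dec = self._dec_with(montage, [40, 20, 15, 6, 3, 2.5, 1.9, 1.2, 0.4, 0.1])
        flags = select_components(dec, SelectionRule())
        assert flags.sum() == 6
        assert flags[:6].all() and not flags[6:].any()

    def test_fallback_selects_labelled_match_above_1_percent(self, montage):
        dec = self._dec_with(montage, [40, 1.4, 0.5],
                             labels=["P3b", "PN", "unknown"])
        flags = select_components(dec, SelectionRule(),
                                  reference_labels=["P3b", "PN"])
        assert flags[1]

    def test_fallback_does_not_select_below_1_percent(self, montage):
        dec = self._dec_with(montage, [40, 0.9, 0.5],
                             labels=["P3b", "PN", "unknown"])
        flags = select_components(dec, SelectionRule(),
                                  reference_labels=["P3b", "PN"])
        assert not flags[1]

    def test_fallback_floor_must_undercut_primary(self):
        with pytest.raises(ValueError):
            SelectionRule(primary_floor=1.0, fallback_floor=2.0)


class TestLabelling:
    def _planted_decomposition(self, montage, templates, labels, seed=12):
        """Noise-free case matrix from planted components with independent
        scores, then PCA + Varimax."""
        rng = np.random.default_rng(seed)
        times = -0.1 + np.arange(218) * 2 / 512.0
        cols = []
        for lab in labels:
            t = next(x for x in templates if x.label == lab)
            cols.append(t.temporal_shape(times))
        F = np.column_stack(cols)
        n_cases = 38 * 19
        chans = np.tile(np.arange(19), 38)
        # the signed amplitude already lives in the temporal shape; scores
        # carry subject spread times the (unsigned-max) topography weight
        S = np.column_stack([
            rng.normal(1.0, 0.3, size=n_cases)
            * next(x for x in templates if x.label == lab
                   ).topo_vector(montage.scalp_channels)[chans]
            for lab in labels])
        X = S @ F.T
        meta = pd.DataFrame({
            "subject": np.arange(n_cases) // 19, "block": 0,
            "channel": [montage.scalp_channels[c] for c in chans]})
        cm = CaseMatrix(X, meta, times, "go-placebo", montage)
        return varimax_rotate(covariance_pca(cm))

    def test_planted_components_label_themselves(self, montage, templates):
        dec = self._planted_decomposition(montage, templates,
                                          ["N1-1", "P3b", "SW2"])
        labels = label_components(dec, templates)
        assigned = {l for l in labels if l != "unknown"}
        assert assigned == {"N1-1", "P3b", "SW2"}

    def test_frontocentral_negativity_at_100ms_is_n1(self, montage, templates):
        dec = self._planted_decomposition(montage, templates, ["N1-1"])
        labels = label_components(dec, templates)
        i = int(np.argmax(dec.pct_variance))
        assert labels[i] == "N1-1"
        assert 70 <= dec.peak_latency_ms[i] <= 130

    def test_competing_factors_tie_broken_by_score_then_variance(
            self, montage, templates):
        """Two factors in the same latency window: the better-scoring one
        wins the label, the loser stays unknown."""
        dec = self._planted_decomposition(montage, templates, ["P3b", "SW1"])
        # force both peaks into the P3b window by labelling against a
        # library holding only P3b
        lib = tuple(t for t in templates if t.label == "P3b")
        windows = {"P3b": (0.0, 750.0)}
        labels = label_components(dec, lib, windows_ms=windows, min_score=-2.0)
        assert labels.count("P3b") == 1
        assert labels.count("unknown") >= 1


class TestAmplitudeMaps:
    def test_amplitude_is_score_times_peak_loading(self, montage):
        """score 2.0 at a peak loading of 3.0 uV -> 6.0 uV."""
        t = np.linspace(0, 1, 40)
        shape = 3.0 * np.exp(-((t - 0.5) ** 2) / 0.01)
        scores = np.full(38, 2.0)
        scores[19:] *= -1          # second subject mirrored to keep variance
        X = np.outer(scores, shape)
        dec = varimax_rotate(covariance_pca(_case_matrix(X, montage)))
        # restore raw (unstandardized) score scale by rescaling: use factor 0
        amap = component_amplitude_map(dec, 0)
        got = amap["amplitude_uv"].abs().max()
        assert got == pytest.approx(6.0, rel=0.03)

    def test_zero_scores_give_flat_zero_map(self, montage):
        X = np.tile(np.linspace(0, 1, 30), (38, 1))  # identical cases
        dec = varimax_rotate(covariance_pca(_case_matrix(X, montage)))
        amap = component_amplitude_map(dec, 0)
        np.testing.assert_allclose(amap["amplitude_uv"], 0.0, atol=1e-8)

    def test_unknown_site_rejected(self, montage):
        X = np.random.default_rng(13).normal(size=(38, 20))
        dec = varimax_rotate(covariance_pca(_case_matrix(X, montage)))
        with pytest.raises(ValueError, match="not in montage"):
            component_amplitude_map(dec, 0, sites=["Oz"])


class TestReconstitution:
    def test_all_factors_give_perfect_site_correlations(self, montage):
        X = np.random.default_rng(14).normal(size=(76, 30))
        dec = varimax_rotate(covariance_pca(_case_matrix(X, montage)))
        dec.selected = np.ones(dec.n_factors, dtype=bool)
        _, fit = reconstitute(dec, selected_only=True)
        assert (fit["r"] > 1 - 1e-9).all()

    def test_empty_selection_reconstitutes_column_means_only(self, montage):
        X = np.random.default_rng(15).normal(size=(76, 30))
        dec = varimax_rotate(covariance_pca(_case_matrix(X, montage)))
        dec.selected = np.zeros(dec.n_factors, dtype=bool)
        waves, _ = reconstitute(dec, selected_only=True)
        one = waves[waves["channel"] == montage.scalp_channels[0]]
        np.testing.assert_allclose(one["reconstituted_uv"].to_numpy(),
                                   dec.column_means, atol=1e-10)
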