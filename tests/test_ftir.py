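"""FTIR processing: windows, second derivative, band assignment, PCA."""

import numpy as np
import pytest

from mycofuel.ftir import (
    BAND_REFERENCE,
    FtirError,
    Spectrum,
    assign_bands,
    extract_window,
    find_bands,
    pca_window,
    resample,
    second_derivative,
)
from mycofuel.simulate import FtirSeriesConfig, gen_ftir_series


def _spec(wn, ab, label=""):
    return Spectrum(np.asarray(wn, float), np.asarray(ab, float), label)


class TestSpectrum:
    def test_descending_grid_flipped(self):
        s = _spec([3000, 2000, 1000], [1.0, 2.0, 3.0])
        assert s.wavenumbers[0] == 1000
        assert s.absorbance[0] == 3.0

    def test_non_monotone_rejected(self):
        with pytest.raises(FtirError, match="monotone"):
            _spec([1, 3, 2], [0, 0, 0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(FtirError, match="length"):
            _spec([1, 2], [0, 0, 0])


class TestWindow:
    def test_full_range_is_identity(self):
        wn = np.arange(400, 4001, 1.0)
        s = _spec(wn, np.sin(wn / 100))
        w = extract_window(s, 400, 4000)
        assert np.array_equal(w.wavenumbers, s.wavenumbers)
        assert np.array_equal(w.absorbance, s.absorbance)

    def test_inclusive_point_count(self):
        wn = np.arange(400, 4001, 1.0)
        s = _spec(wn, np.zeros_like(wn))
        assert len(extract_window(s, 2800, 3050)) == 251

    def test_no_overlap_raises(self):
        s = _spec(np.arange(400, 4001, 1.0), np.zeros(3601))
        with pytest.raises(FtirError, match="overlap"):
            extract_window(s, 5000, 6000)

    def test_processing_log_appended(self):
        s = _spec(np.arange(400, 500, 1.0), np.zeros(100))
        w = extract_window(s, 420, 480)
        assert any("window" in step for step in w.processing)


class TestSecondDerivative:
    def test_exact_on_quadratic(self):
        """Boxcar + central difference is exact for polynomials deg <= 2."""
        wn = np.arange(1000, 1400, 1.0)
        a, b, c = 3e-4, -0.1, 2.0
        d2 = second_derivative(_spec(wn, a * wn**2 + b * wn + c), 25)
        assert np.allclose(d2.absorbance, 2 * a, atol=1e-6)

    def test_zero_on_linear_baseline(self):
        wn = np.arange(1000, 1400, 2.0)
        d2 = second_derivative(_spec(wn, 0.5 - 1e-4 * wn), 25)
        assert np.allclose(d2.absorbance, 0.0, atol=1e-12)

    def test_gaussian_minimum_at_center(self):
        wn = np.arange(1600, 1900, 1.0)
        ab = 0.5 * np.exp(-0.5 * ((wn - 1745) / 10.0) ** 2)
        d2 = second_derivative(_spec(wn, ab), 25)
        center = d2.wavenumbers[np.argmin(d2.absorbance)]
        assert abs(center - 1745) <= 1.0

    def test_width_validation(self):
        s = _spec(np.arange(0, 100, 1.0), np.zeros(100))
        with pytest.raises(FtirError):
            second_derivative(s, 24)
        with pytest.raises(FtirError):
            second_derivative(s, 1)
        with pytest.raises(FtirError, match="points"):
            second_derivative(_spec(np.arange(10.0), np.zeros(10)), 25)

    def test_nonuniform_grid_resampled(self):
        rng = np.random.default_rng(0)
        wn = np.sort(rng.uniform(1000, 1400, 500))
        wn = np.unique(wn)
        a = 2e-4
        d2 = second_derivative(_spec(wn, a * wn**2), 25)
        # linear interpolation of a quadratic leaves O(h^2 f'') kinks, so
        # agreement is approximate, not exact as on a native uniform grid
        assert np.mean(d2.absorbance) == pytest.approx(2 * a, rel=0.05)
        assert np.allclose(d2.absorbance, 2 * a, rtol=0.25)
        assert "resample" in d2.processing


class TestFindAndAssign:
    def test_two_band_recovery(self):
        wn = np.arange(2700, 3100, 0.5)
        ab = (
            0.3 * np.exp(-0.5 * ((wn - 2852) / 9) ** 2)
            + 0.45 * np.exp(-0.5 * ((wn - 2922) / 9) ** 2)
        )
        d2 = second_derivative(_spec(wn, ab), 25)
        peaks = find_bands(d2, prominence=1e-5)
        for center in (2852, 2922):
            assert np.min(np.abs(peaks - center)) <= 2.0

    def test_flat_spectrum_no_bands(self):
        wn = np.arange(1000, 1400, 1.0)
        d2 = second_derivative(_spec(wn, np.full_like(wn, 0.3)), 25)
        assert find_bands(d2).size == 0

    def test_nearly_coincident_bands_merge(self):
        """Bands overlapping > 90 % resolve as a single component."""
        wn = np.arange(1600, 1900, 0.5)
        ab = (
            0.5 * np.exp(-0.5 * ((wn - 1744) / 12) ** 2)
            + 0.5 * np.exp(-0.5 * ((wn - 1746) / 12) ** 2)
        )
        d2 = second_derivative(_spec(wn, ab), 25)
        peaks = find_bands(d2, prominence=1e-5)
        assert len(peaks) == 1

    @pytest.mark.parametrize(
        "peak,mode_part,matched",
        [
            (1745.0, "C=O", True),
            (3008.0, "=C-H", True),
            (1250.0, "P=O", True),  # inside the ranged reference
            (2000.0, "unassigned", False),
        ],
    )
    def test_assignment(self, peak, mode_part, matched):
        (a,) = assign_bands([peak])
        assert a.matched is matched
        assert mode_part in a.mode

    def test_assignment_tolerance(self):
        (a,) = assign_bands([1745 + 4.0])
        assert a.matched
        (b,) = assign_bands([1745 + 4.5], tol=4.0)
        # 1749.5 is within tol of nothing (next ref is 1465)
        assert not b.matched


class TestPCA:
    def _latent_spectra(self, n=6, p=40, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        wn = np.linspace(2800, 3050, p)
        base = np.exp(-0.5 * ((wn - 2920) / 30) ** 2)
        levels = np.linspace(0.2, 1.0, n)
        out = []
        for i, lv in enumerate(levels):
            ab = lv * base + noise * rng.normal(size=p)
            out.append(Spectrum(wn, ab, label=f"s{i}"))
        return out

    def test_single_factor_dominates(self):
        res = pca_window(self._latent_spectra(noise=1e-6))
        assert res.explained_variance_ratio[0] > 0.99

    def test_loadings_orthonormal(self):
        res = pca_window(self._latent_spectra(noise=0.05))
        gram = res.loadings.T @ res.loadings
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_variance_fractions_valid(self):
        res = pca_window(self._latent_spectra(noise=0.05))
        r = res.explained_variance_ratio
        assert np.all(r >= 0)
        assert r.sum() <= 1 + 1e-9
        assert np.all(np.diff(r) <= 1e-12)

    def test_reconstruction_with_all_components(self):
        spectra = self._latent_spectra(noise=0.05)
        res = pca_window(spectra)
        X = np.vstack([s.absorbance for s in spectra])
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        err = np.linalg.norm(res.reconstruct_standardized() - Z)
        assert err < 1e-6

    def test_duplicate_spectra_get_identical_scores(self):
        spectra = self._latent_spectra(noise=0.05)
        spectra.append(
            Spectrum(
                spectra[0].wavenumbers.copy(),
                spectra[0].absorbance.copy(),
                label="dup",
            )
        )
        res = pca_window(spectra)
        assert np.allclose(res.scores[0], res.scores[-1], atol=1e-10)

    def test_matches_dense_eig_oracle(self):
        """Brute-force oracle: explicit correlation matrix + eigh on a
        20-variable toy window, cross-checked against scikit-learn."""
        spectra = self._latent_spectra(n=8, p=20, noise=0.1, seed=3)
        res = pca_window(spectra)

        X = np.vstack([s.absorbance for s in spectra])
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        corr = np.corrcoef(Z, rowvar=False)
        w = np.sort(np.linalg.eigvalsh(corr))[::-1]
        assert np.allclose(
            res.explained_variance_ratio, w / w.sum(), atol=1e-8
        )

        from sklearn.decomposition import PCA

        sk = PCA().fit(Z)
        k = min(len(sk.explained_variance_ratio_), 3)
        assert np.allclose(
            res.explained_variance_ratio[:k],
            sk.explained_variance_ratio_[:k],
            atol=1e-8,
        )
        for j in range(k):
            dot = abs(np.dot(sk.components_[j], res.loadings[:, j]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_zero_variance_variable_dropped(self):
        spectra = self._latent_spectra(noise=0.05)
        for s in spectra:
            s.absorbance[0] = 1.234  # constant across spectra
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pca_window(spectra)
        assert res.dropped_wavenumbers.size == 1

    def test_needs_three_spectra_and_common_grid(self):
        spectra = self._latent_spectra()
        with pytest.raises(FtirError, match="at least 3"):
            pca_window(spectra[:2])
        shifted = resample(
            spectra[0], np.linspace(2810, 3040, 33)
        )
        with pytest.raises(FtirError, match="common grid"):
            pca_window([shifted] + spectra[1:])

    def test_day1_separates_from_day6_7_along_pc1(self):
        """With lipid bands growing along the fermentation, the growth-phase
        day-1 spectrum sits apart from the lipid-accumulation days 6-7."""
        spectra, truth = gen_ftir_series(FtirSeriesConfig(seed=11))
        res = pca_window(spectra, lo=2800, hi=3050)
        scores = dict(zip(res.labels, res.scores[:, 0]))
        d1, d6, d7 = scores["day 1"], scores["day 6"], scores["day 7"]
        # sign-align so late days score positive
        sign = 1.0 if d7 >= d1 else -1.0
        assert sign * d6 > sign * d1
        assert sign * d7 > sign * d1
        # well separated: gap exceeds the within-late-phase spread
        late = [scores[f"day {d}"] for d in (6, 7, 8, 9, 10)]
        gap = sign * (min(late) - d1)
        assert gap > 5 * np.std(late)
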