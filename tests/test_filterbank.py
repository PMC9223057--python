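"""Filter-design unit tests: half-band SDP, factorization, selection."""

import numpy as np
import pytest
import pywt
from scipy.integrate import simpson

from somnowave.filterbank import (
    DesignSpec,
    HalfBandFilter,
    InfeasibleSpecError,
    design_filter_bank,
    design_halfband,
    frequency_variance,
    moment_residuals,
    orthogonality_residuals,
    select_min_duration,
    spectral_factorize,
    tf_product,
    time_variance,
    load_filter,
    save_filter,
)


def lattice_length4(theta: np.ndarray) -> np.ndarray:
    """One-parameter family of all length-4 orthonormal low-pass filters.

    Columns are filters; every member has unit energy, sum sqrt(2), and at
    least one vanishing moment.
    """
    c, s = np.cos(theta), np.sin(theta)
    h = np.stack([1 - c + s, 1 + c + s, 1 + c - s, 1 - c - s]) / (2 * np.sqrt(2))
    return h


class TestDesignSpec:
    def test_rejects_odd_or_tiny_lengths(self):
        with pytest.raises(InfeasibleSpecError):
            DesignSpec(length=7, vanishing_moments=1)
        with pytest.raises(InfeasibleSpecError):
            DesignSpec(length=4, vanishing_moments=3)
        with pytest.raises(InfeasibleSpecError):
            DesignSpec(length=4, vanishing_moments=0)


class TestHalfbandDesign:
    def test_haar_product_is_unique_solution(self):
        hb = design_halfband(DesignSpec(length=2, vanishing_moments=1))
        assert np.allclose(hb.coefficients, [0.5, 1.0, 0.5], atol=1e-9)

    def test_length18_has_35_taps_and_order6_zero_at_pi(self):
        hb = design_halfband(DesignSpec(length=18, vanishing_moments=3))
        p = hb.coefficients
        assert len(p) == 35
        w = np.linspace(0, np.pi, 2001)
        P = sum(c * np.exp(-1j * (n - 17) * w) for n, c in enumerate(p)).real
        # half-band structure: centre 1, even off-centre taps 0
        assert abs(p[17] - 1.0) < 1e-8
        assert max(abs(p[17 + 2 * k]) for k in range(1, 9)) < 1e-8
        assert P.min() > -1e-8
        # order-6 zero at pi: P ~ c (w - pi)^6 near pi
        eps = np.array([1e-2, 5e-3])
        vals = [
            float(sum(c * np.exp(-1j * (n - 17) * (np.pi - e)) for n, c in enumerate(p)).real)
            for e in eps
        ]
        ratio = vals[0] / vals[1]
        assert ratio == pytest.approx(2.0**6, rel=0.15)

    def test_halfband_objective_matches_length4_lattice_minimum(self):
        """Independent oracle: brute-force sweep of the lattice family."""
        hb = design_halfband(DesignSpec(length=4, vanishing_moments=1))
        theta = np.linspace(0, 2 * np.pi, 20001)
        H = lattice_length4(theta)  # 4 x n_theta
        w = np.linspace(0, np.pi, 2049)
        E = np.exp(-1j * np.outer(w, np.arange(4)))
        P = np.abs(E @ H) ** 2  # n_w x n_theta
        sw2 = simpson(w[:, None] ** 2 * P, x=w, axis=0) / simpson(P, x=w, axis=0)
        assert hb.objective_value == pytest.approx(sw2.min(), abs=1e-4)
        assert hb.objective_value <= frequency_variance(
            np.array(pywt.Wavelet("db2").dec_lo)
        ) + 1e-9

    def test_design_is_deterministic(self):
        a = design_halfband(DesignSpec(length=10, vanishing_moments=2))
        b = design_halfband(DesignSpec(length=10, vanishing_moments=2))
        assert np.abs(a.coefficients - b.coefficients).max() < 1e-6


class TestSpectralFactorization:
    def test_haar_product_has_single_factor(self):
        hb = HalfBandFilter(np.array([0.5, 1.0, 0.5]), 0.0)
        factors = spectral_factorize(hb)
        assert len(factors) == 1
        assert np.allclose(factors[0], np.sqrt(0.5) * np.ones(2), atol=1e-12)

    def test_factors_reproduce_product(self, bank18):
        hb = design_halfband(DesignSpec(length=18, vanishing_moments=3))
        p = hb.coefficients / hb.coefficients[17]
        for h in spectral_factorize(hb):
            assert np.abs(np.convolve(h, h[::-1]) - p).max() < 1e-8

    def test_db2_candidates_include_minimum_and_maximum_phase(self):
        db2 = np.array(pywt.Wavelet("db2").dec_lo)
        hb = HalfBandFilter(np.convolve(db2, db2[::-1]), 0.0)
        cands = spectral_factorize(hb)
        assert any(np.allclose(c, db2, atol=1e-8) for c in cands)
        assert any(np.allclose(c, db2[::-1], atol=1e-8) for c in cands)


class TestMinDurationSelection:
    def test_haar_duration(self):
        h = np.sqrt(0.5) * np.ones(2)
        bank = select_min_duration([h, h.copy()])
        assert bank.time_variance == pytest.approx(0.25, abs=1e-12)

    def test_duration_is_reversal_invariant_and_tie_broken(self):
        db2 = np.array(pywt.Wavelet("db2").dec_lo)
        assert time_variance(db2) == pytest.approx(time_variance(db2[::-1]), abs=1e-12)
        bank = select_min_duration([db2, db2[::-1]])
        # lexicographically smallest of the two tied sequences
        expected = min((tuple(db2), tuple(db2[::-1])))
        assert tuple(bank.lowpass) == pytest.approx(expected)

    def test_selection_matches_bruteforce(self):
        db2 = np.array(pywt.Wavelet("db2").dec_lo)
        hb = HalfBandFilter(np.convolve(db2, db2[::-1]), 0.0)
        cands = spectral_factorize(hb)
        bank = select_min_duration(cands)
        assert bank.time_variance == pytest.approx(
            min(time_variance(c) for c in cands), abs=1e-12
        )

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_min_duration([])


class TestDesignedBankInvariants:
    def test_orthogonality_and_moments(self, bank18):
        assert np.abs(orthogonality_residuals(bank18.lowpass)).max() < 1e-8
        assert np.abs(moment_residuals(bank18.lowpass, 3)).max() < 1e-6

    def test_highpass_is_alternating_flip(self, bank18):
        h, g = bank18.lowpass, bank18.highpass
        n = np.arange(18)
        assert np.allclose(g, (-1.0) ** n * h[::-1])

    def test_energy_and_sign_conventions(self, bank18):
        assert np.dot(bank18.lowpass, bank18.lowpass) == pytest.approx(1.0, abs=1e-12)
        assert bank18.lowpass.sum() == pytest.approx(np.sqrt(2.0), abs=1e-8)


class TestTFProduct:
    def test_haar_time_spread(self, haar_bank):
        assert np.sqrt(haar_bank.time_variance) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize(
        "length,moments,db", [(4, 1, "db2"), (6, 1, "db3"), (18, 3, "db9")]
    )
    def test_beats_daubechies_of_equal_length(self, length, moments, db, bank18, bank4):
        if length == 18:
            bank = bank18
        elif length == 4:
            bank = bank4
        else:
            bank = design_filter_bank(DesignSpec(length=length, vanishing_moments=moments))
        dbh = np.array(pywt.Wavelet(db).dec_lo)
        assert bank.tf_product <= tf_product(dbh) + 1e-9

    def test_quadrature_grid_convergence(self, bank18):
        a = tf_product(bank18.lowpass, 2049)
        b = tf_product(bank18.lowpass, 4097)
        assert abs(a - b) < 1e-6


class TestFilterIO:
    def test_text_roundtrip_preserves_coefficients(self, bank18, tmp_path):
        path = tmp_path / "filt.txt"
        save_filter(bank18, path, DesignSpec())
        back = load_filter(path)
        assert np.abs(back.lowpass - bank18.lowpass).max() < 1e-15
        assert (tmp_path / "filt.txt.json").exists()
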