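"""Competitive-binding theory: transfer matrix, free-ligand solve, PSF and
pixel resampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from cbscaffold import _tm
from cbscaffold.cbtheory import (
    LigandParams,
    SequenceRecord,
    apply_psf,
    free_concentrations,
    sequence_to_barcode,
    to_pixel_resolution,
    yoyo_binding_profile,
)

from .oracles import enumerate_lattice_coverage


def _random_weights(rng, L):
    return rng.random(L) * 3.0, rng.random(L) * 3.0


def _linear_zeroed(w, m):
    out = w.copy()
    out[max(0, len(w) - m + 1):] = 0.0
    return out


class TestTransferMatrix:
    @pytest.mark.parametrize("circular", [False, True])
    def test_matches_exhaustive_enumeration(self, circular):
        """Exact equilibrium marginals: the transfer-matrix coverage equals
        brute-force enumeration of all ligand configurations to 1e-10."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            L = int(rng.integers(8, 15))
            my, mn = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            wy, wn = _random_weights(rng, L)
            if circular:
                cy, cn, ny, nn = _tm.circular_coverage(wy, wn, my, mn)
            else:
                cy, cn, ny, nn = _tm.linear_coverage(
                    _linear_zeroed(wy, my), _linear_zeroed(wn, mn), my, mn
                )
            by, bn = enumerate_lattice_coverage(wy, wn, my, mn, circular)
            np.testing.assert_allclose(cy, by, atol=1e-10)
            np.testing.assert_allclose(cn, bn, atol=1e-10)
            assert abs(ny - by.sum() / my) < 1e-10
            assert abs(nn - bn.sum() / mn) < 1e-10

    def test_probability_bounds_random_sweep(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            L = int(rng.integers(10, 60))
            wy, wn = rng.random(L) * 50, rng.random(L) * 50
            cy, cn, *_ = _tm.circular_coverage(wy, wn, 4, 4)
            assert (cy >= -1e-12).all() and (cy <= 1 + 1e-12).all()
            assert (cn >= -1e-12).all() and (cn <= 1 + 1e-12).all()
            assert (cy + cn <= 1 + 1e-9).all()  # footprints exclude each other

    def test_monotone_in_ligand_concentration(self, params):
        seq = SequenceRecord("m", "ACGTTGCAGGTTACGCATCC" * 3, False)
        base = yoyo_binding_profile(seq, params, 0.01, 2.0).p_bound
        more_yoyo = yoyo_binding_profile(seq, params, 0.02, 2.0).p_bound
        more_net = yoyo_binding_profile(seq, params, 0.01, 4.0).p_bound
        assert (more_yoyo >= base - 1e-12).all()
        assert (more_net <= base + 1e-12).all()

    def test_netropsin_saturation_darkens_at_sequence(self, params):
        seq = SequenceRecord("at", "AT" * 30, False)
        p = yoyo_binding_profile(seq, params, 0.02, 1e6).p_bound
        assert p.max() < 1e-3

    def test_palindrome_gives_mirror_symmetric_profile(self, params):
        seq = SequenceRecord("pal", "ACGTGCATATGCACGT", False)
        assert seq.bases == "".join(
            {"A": "T", "C": "G", "G": "C", "T": "A"}[b] for b in reversed(seq.bases)
        )
        p = yoyo_binding_profile(seq, params, 0.02, 3.0).p_bound
        np.testing.assert_allclose(p, p[::-1], atol=1e-12)

    def test_short_linear_sequence_rejected(self, params):
        with pytest.raises(ValueError, match="footprint"):
            yoyo_binding_profile(SequenceRecord("s", "ACG", False), params, 0.01, 1.0)


class TestFreeConcentrations:
    def test_no_dna_binds_nothing(self):
        p = LigandParams(netropsin_constants={}, conc_dna=0.0)
        seq = SequenceRecord("s", "ACGTACGTACGT", False)
        assert free_concentrations(p, seq) == (p.conc_yoyo_total, p.conc_netropsin_total)

    def test_zero_constants_bind_nothing(self):
        p = LigandParams(K_yoyo=0.0, netropsin_constants={}, conc_dna=1.0)
        seq = SequenceRecord("s", "ACGTACGTACGT", False)
        assert free_concentrations(p, seq) == (p.conc_yoyo_total, p.conc_netropsin_total)

    def test_single_site_langmuir_closed_form(self):
        """One YOYO site on a footprint-length lattice: the solver must
        agree with the scalar Langmuir mass balance solved by bisection."""
        K, c_tot, c_dna = 5.0, 0.4, 2.0
        L = 4
        p = LigandParams(
            K_yoyo=K, netropsin_constants={}, conc_yoyo_total=c_tot,
            conc_netropsin_total=0.0, conc_dna=c_dna,
        )
        seq = SequenceRecord("s", "ACGT", False)

        def mass_balance(c):
            theta = K * c / (1 + K * c)  # single-site occupancy
            return c_tot - c - c_dna * theta / L

        expected = brentq(mass_balance, 0, c_tot, xtol=1e-14)
        got, _ = free_concentrations(p, seq)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_mass_balance_residual(self, params):
        seq = SequenceRecord("s", "ACGTTTAAGGCCGCGCATAT" * 20, False)
        cy, cn = free_concentrations(params, seq)
        from cbscaffold.cbtheory import _equilibrium

        _, _, n_y, n_n = _equilibrium(seq, params, cy, cn)
        bound = params.conc_dna * np.array([n_y, n_n]) / len(seq)
        tot = np.array([params.conc_yoyo_total, params.conc_netropsin_total])
        resid = np.abs(tot - np.array([cy, cn]) - bound) / tot
        assert resid.max() < 1e-9
        assert 0 <= cy <= params.conc_yoyo_total
        assert 0 <= cn <= params.conc_netropsin_total


class TestPSF:
    def test_zero_sigma_is_identity(self, rng):
        x = rng.random(100)
        np.testing.assert_array_equal(apply_psf(x, 0.0, circular=False), x)

    @pytest.mark.parametrize("circular", [False, True])
    def test_constant_profile_is_preserved(self, circular):
        x = np.full(200, 0.37)
        np.testing.assert_allclose(apply_psf(x, 15.0, circular), x, atol=1e-12)

    def test_circular_impulse_gives_gaussian_and_conserves_sum(self):
        x = np.zeros(400)
        x[200] = 1.0
        out = apply_psf(x, 10.0, circular=True)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        d = np.abs(np.arange(400) - 200)
        kern = np.exp(-0.5 * (d / 10.0) ** 2)
        np.testing.assert_allclose(out, kern / kern.sum(), atol=1e-12)

    def test_circular_mean_is_conserved_exactly(self, rng):
        x = rng.random(333)
        out = apply_psf(x, 25.0, circular=True)
        assert out.mean() == pytest.approx(x.mean(), abs=1e-12)


class TestPixelResampling:
    def test_unit_scale_is_identity(self, rng):
        x = rng.random(64)
        bc = to_pixel_resolution(x, 1.0)
        np.testing.assert_allclose(bc.values, x, atol=1e-12)

    def test_constant_input(self):
        bc = to_pixel_resolution(np.full(1000, 2.5), 10.0)
        assert bc.n_px == 100
        np.testing.assert_allclose(bc.values, 2.5, atol=1e-12)

    def test_ramp_block_average_oracle(self):
        x = np.arange(100, dtype=float)
        bc = to_pixel_resolution(x, 10.0, method="block")
        expected = x.reshape(10, 10).mean(axis=1)
        np.testing.assert_allclose(bc.values, expected, atol=1e-12)

    def test_shorter_than_one_pixel_errors(self):
        with pytest.raises(ValueError, match="shorter than one pixel"):
            to_pixel_resolution(np.ones(10), 100.0)


class TestSequenceToBarcode:
    def test_gc_homopolymer_brighter_than_at(self, params):
        gc = sequence_to_barcode(SequenceRecord("gc", "GC" * 5000, False), params)
        at = sequence_to_barcode(SequenceRecord("at", "AT" * 5000, False), params)
        assert gc.values.mean() > at.values.mean()

    def test_circular_rotation_rotates_barcode(self, params):
        bases = SequenceRecord("g", "ACGGTTCAAGCTTACCGGAT" * 100, True).bases
        rot_bp = 500  # one pixel at 100 bp/px... use bp_per_px dividing rotation
        a = sequence_to_barcode(SequenceRecord("a", bases, True), params,
                                sigma_bp=200, bp_per_px=100)
        b = sequence_to_barcode(
            SequenceRecord("b", bases[rot_bp:] + bases[:rot_bp], True), params,
            sigma_bp=200, bp_per_px=100,
        )
        np.testing.assert_allclose(b.values, np.roll(a.values, -rot_bp // 100),
                                   atol=1e-9)

    def test_circular_and_linear_agree_in_interior(self, params):
        rec = SequenceRecord("g", "ACGGTTCAAGCTTACCGGAT" * 600, False)
        lin = sequence_to_barcode(rec, params, sigma_bp=500, bp_per_px=100)
        circ = sequence_to_barcode(
            SequenceRecord("g", rec.bases, True), params, sigma_bp=500, bp_per_px=100
        )
        n = lin.n_px
        edge = 40  # pixels; > 2 * (5 sigma) away from the ends
        np.testing.assert_allclose(
            lin.values[edge : n - edge], circ.values[edge : n - edge], rtol=0.02
        )

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            SequenceRecord("n", "ACGTN", False)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    st.integers(min_value=10, max_value=30),
    st.floats(min_value=0.01, max_value=20.0),
    st.floats(min_value=0.01, max_value=20.0),
)
def test_coverage_probabilities_always_valid(L, wy_scale, wn_scale):
    """Coverage stays in [0, 1] for arbitrary admissible weights."""
    rng = np.random.default_rng(L)
    wy = rng.random(L) * wy_scale
    wn = rng.random(L) * wn_scale
    cy, cn, *_ = _tm.circular_coverage(wy, wn, 4, 4)
    assert (cy >= -1e-12).all() and (cy <= 1 + 1e-12).all()
    assert (cn >= -1e-12).all() and (cn <= 1 + 1e-12).all()
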