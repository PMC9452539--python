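import numpy as np
import pytest

import enhmom as em
from enhmom.moments import MOMENT_INDEX_ORDER, NumericStabilityError


def brute_force_raw(entries):
    """Independent double-loop oracle for origin-referenced moments."""
    d = entries.shape[0]
    out = []
    for j, k in MOMENT_INDEX_ORDER:
        total = 0.0
        for a in range(1, d + 1):
            for b in range(1, d + 1):
                total += a**j * b**k * entries[a - 1, b - 1]
        out.append(total)
    return np.array(out)


def brute_force_central(entries):
    d = entries.shape[0]
    m00 = entries.sum()
    a_bar = sum(a * entries[a - 1, b - 1] for a in range(1, d + 1)
                for b in range(1, d + 1)) / m00
    b_bar = sum(b * entries[a - 1, b - 1] for a in range(1, d + 1)
                for b in range(1, d + 1)) / m00
    out = []
    for j, k in MOMENT_INDEX_ORDER:
        total = 0.0
        for a in range(1, d + 1):
            for b in range(1, d + 1):
                total += (a - a_bar) ** j * (b - b_bar) ** k * entries[a - 1, b - 1]
        out.append(total)
    return np.array(out)


class TestEncode:
    def test_default_alphabetical_map(self):
        assert em.encode("ACGT").values.tolist() == [1, 2, 3, 4]
        assert em.encode("AAAA").values.tolist() == [1, 1, 1, 1]

    def test_custom_map_applied(self):
        series = em.encode("ACGT", {"A": 4, "C": 3, "G": 2, "T": 1})
        assert series.values.tolist() == [4, 3, 2, 1]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            em.encode("")


class TestReshape:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([1, 2, 3, 4, 1, 2, 3, 4, 1], [[1, 2, 3], [4, 1, 2], [3, 4, 1]]),
            ([1, 2, 3, 4, 1], [[1, 2, 3], [4, 1, 0], [0, 0, 0]]),
            ([1, 2, 3, 4], [[1, 2], [3, 4]]),
        ],
    )
    def test_row_major_fill_with_zero_padding(self, values, expected):
        m = em.reshape_to_square(np.array(values))
        assert m.entries.tolist() == expected

    def test_dimension_is_ceil_sqrt(self):
        assert em.reshape_to_square(np.ones(200)).dimension == 15
        assert em.reshape_to_square(np.ones(16)).dimension == 4
        assert em.reshape_to_square(np.ones(17)).dimension == 5

    def test_row_major_scan_inverts_the_reshape(self, rng):
        values = rng.integers(1, 5, size=137)
        m = em.reshape_to_square(values)
        assert m.entries.ravel()[:137].astype(int).tolist() == values.tolist()

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            em.reshape_to_square(np.array([]))


class TestRawCentralMoments:
    MAT = em.SquareMatrix(np.array([[1.0, 2.0], [3.0, 4.0]]))

    def test_frozen_examples(self):
        m = em.raw_moments(self.MAT).as_dict()
        assert m["raw_00"] == 10.0
        assert m["raw_10"] == 17.0
        assert m["raw_01"] == 16.0
        assert em.moments.centroid(self.MAT) == (1.7, 1.6)
        mu = em.central_moments(self.MAT).as_dict()
        assert mu["central_20"] == pytest.approx(2.1, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_integer_matrices(self, rng):
        for _ in range(100):
            entries = rng.integers(0, 10, size=(5, 5)).astype(float)
            if entries.sum() == 0:
                continue
            mat = em.SquareMatrix(entries)
            assert em.raw_moments(mat).values == pytest.approx(
                brute_force_raw(entries), abs=0
            )
            assert em.central_moments(mat).values == pytest.approx(
                brute_force_central(entries), abs=1e-9
            )

    def test_first_central_moments_vanish(self, rng):
        for _ in range(20):
            entries = rng.random((6, 6))
            mu = em.central_moments(em.SquareMatrix(entries)).as_dict()
            assert abs(mu["central_10"]) < 1e-9
            assert abs(mu["central_01"]) < 1e-9
            assert mu["central_00"] == pytest.approx(entries.sum())

    def test_all_zero_matrix_degenerates_to_zero_vectors(self, caplog):
        zero = em.SquareMatrix(np.zeros((4, 4)))
        assert em.raw_moments(zero).values.tolist() == [0.0] * 10
        assert em.central_moments(zero).values.tolist() == [0.0] * 10


class TestHahnBasis:
    def test_degree_zero_polynomial_is_constant(self):
        from enhmom.moments import _hahn_polynomial_row

        assert _hahn_polynomial_row(0, 10, 0.0, 0.0).tolist() == [1.0] * 10

    @pytest.mark.parametrize("N", [2, 4, 15, 16, 64])
    @pytest.mark.parametrize("xy", [0.0, 1.0])
    def test_weighted_rows_orthonormal(self, N, xy):
        basis = em.build_hahn_basis(
            em.HahnParams(N=N, x=xy, y=xy), max_degree=min(3, N - 1)
        )
        G = basis.table @ basis.table.T
        assert np.max(np.abs(G - np.eye(basis.max_degree + 1))) < 1e-8

    def test_degree_must_be_below_support(self):
        with pytest.raises(ValueError):
            em.build_hahn_basis(em.HahnParams(N=3), max_degree=3)

    @pytest.mark.parametrize("N", [2, 3, 5, 8])
    def test_complete_basis_transform_is_an_isometry(self, N, rng):
        entries = rng.random((N, N))
        mat = em.SquareMatrix(entries)
        basis = em.build_hahn_basis(em.HahnParams(N=N), max_degree=N - 1)
        spectrum = em.hahn_transform(mat, basis)
        back = em.inverse_hahn_transform(spectrum, basis)
        assert np.max(np.abs(back.entries - entries)) < 1e-8
        # energy conservation under the orthonormal transform
        assert np.sum(spectrum**2) == pytest.approx(np.sum(entries**2))


class TestHahnMoments:
    def test_zero_matrix_gives_zero_moments(self):
        basis = em.build_hahn_basis(em.HahnParams(N=4))
        vec = em.hahn_moments(em.SquareMatrix(np.zeros((4, 4))), basis)
        assert vec.values.tolist() == [0.0] * 10

    def test_linearity_in_the_input(self, rng):
        basis = em.build_hahn_basis(em.HahnParams(N=5))
        entries = rng.random((5, 5))
        one = em.hahn_moments(em.SquareMatrix(entries), basis).values
        three = em.hahn_moments(em.SquareMatrix(3.0 * entries), basis).values
        assert three == pytest.approx(3.0 * one)

    def test_dimension_mismatch_rejected(self):
        basis = em.build_hahn_basis(em.HahnParams(N=4))
        with pytest.raises(ValueError):
            em.hahn_moments(em.SquareMatrix(np.ones((5, 5))), basis)

    def test_spectrum_ordering_follows_eq_convention(self, rng):
        # H_uv must weight rows by degree v and columns by degree u
        entries = rng.random((6, 6))
        basis = em.build_hahn_basis(em.HahnParams(N=6))
        spectrum = em.hahn_transform(em.SquareMatrix(entries), basis)
        h_uv = float(basis.table[1] @ entries.T @ basis.table[2])
        assert spectrum[1, 2] == pytest.approx(h_uv)


class TestMomentBlock:
    def test_block_is_raw_central_hahn_concatenation(self, rng):
        entries = rng.random((5, 5))
        mat = em.SquareMatrix(entries)
        block = em.moment_block(mat)
        assert block.shape == (30,)
        assert block[:10] == pytest.approx(em.raw_moments(mat).values)
        assert block[10:20] == pytest.approx(em.central_moments(mat).values)

    def test_zero_matrix_gives_thirty_zeros(self):
        block = em.moment_block(em.SquareMatrix(np.zeros((4, 4))))
        assert block.tolist() == [0.0] * 30
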