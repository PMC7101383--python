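import math

import numpy as np
import pytest

from plastisize import (
    ClassGrid,
    ConcentrationGrid,
    InvalidGridError,
    InvalidParameterError,
    NoClassError,
    SizeClass,
    generate_synthetic_grids,
    linearise_classes,
    published_fit,
    risk_index,
    round_half_up,
    select_ingestible_class,
    total_plastic,
)
from plastisize.riskmap import (
    PLASTIC_SIZE_CLASSES,
    invert_linearisation,
    read_class_grid,
    read_concentration_grid,
    read_size_classes,
    write_grid,
    write_size_classes,
)


def plastic_grid(values, mask=None):
    return ClassGrid(
        values=np.asarray(values, float), n_classes=8, max_exponent=6.0, mask=mask,
        units_note="pieces km^-2",
    )


def zoo_grid(values, mask=None):
    return ClassGrid(
        values=np.asarray(values, float), n_classes=5, max_exponent=2.0, mask=mask,
        units_note="mg C m^-3",
    )


def conc(values, mask=None, units="u"):
    return ConcentrationGrid(values=np.asarray(values, float), mask=mask, units=units)


class TestLineariseClasses:
    def test_plastic_top_class_is_one_million(self):
        assert linearise_classes(plastic_grid([[8]])).values[0, 0] == pytest.approx(
            1_000_000.0
        )

    def test_zoo_top_class_is_one_hundred(self):
        assert linearise_classes(zoo_grid([[5]])).values[0, 0] == pytest.approx(100.0)

    def test_class_zero_maps_to_one(self):
        assert linearise_classes(plastic_grid([[0]])).values[0, 0] == 1.0
        assert linearise_classes(zoo_grid([[0]])).values[0, 0] == 1.0

    def test_strictly_increasing_in_class(self):
        values = linearise_classes(plastic_grid([list(range(9))])).values[0]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_mask_preserved(self):
        mask = np.array([[True, False]])
        out = linearise_classes(plastic_grid([[3, 4]], mask=mask))
        assert out.mask.tolist() == [[True, False]]

    def test_exactly_invertible(self):
        rng = np.random.default_rng(5)
        values = rng.integers(0, 9, size=(20, 30)).astype(float)
        mask = rng.random((20, 30)) < 0.1
        grid = plastic_grid(values, mask=mask)
        recovered = invert_linearisation(linearise_classes(grid), 8, 6.0)
        assert np.allclose(recovered[~mask], values[~mask], atol=1e-9)
        assert np.isnan(recovered[mask]).all()

    def test_invalid_class_value_names_cell(self):
        with pytest.raises(InvalidGridError, match=r"\(0, 1\)"):
            plastic_grid([[1, 9]])
        with pytest.raises(InvalidGridError, match=r"\(1, 0\)"):
            plastic_grid([[1, 2], [3.5, 0]])

    def test_masked_cells_exempt_from_range_check(self):
        grid = plastic_grid([[1, 99]], mask=np.array([[False, True]]))
        assert linearise_classes(grid).mask[0, 1]


class TestSelectIngestibleClass:
    def test_zooplankton_community_selects_smallest_class(self):
        selection = select_ingestible_class(published_fit(), 13.5)
        assert selection.size_class == SizeClass(0.33, 1.00)
        assert round_half_up(selection.buffer_mm, 2) == 0.14

    def test_tie_on_upper_bound_selects_that_class(self):
        from plastisize.allometry import AllometricFit

        # identity fit: prediction at 1.0 mm body is exactly 1.0 mm
        fit = AllometricFit(1.0, 0.0, 10, None, None, None, 1.0, math.inf, 0.0)
        selection = select_ingestible_class(fit, 1.0)
        assert selection.size_class == SizeClass(0.33, 1.00)
        assert selection.buffer_mm == pytest.approx(0.0, abs=1e-12)

    def test_88_6_mm_body_selects_third_class(self):
        selection = select_ingestible_class(published_fit(), 88.6)
        assert selection.predicted_mm == pytest.approx(5.0, abs=0.01)
        assert selection.size_class == SizeClass(4.76, 20.00)

    def test_unbounded_class_catches_large_predictions(self):
        selection = select_ingestible_class(published_fit(), 1_000_000.0)
        assert selection.size_class == SizeClass(20.00, None)
        assert selection.buffer_mm is None

    def test_no_class_error_without_unbounded_class(self):
        bounded = [SizeClass(0.33, 1.00), SizeClass(1.00, 4.76)]
        with pytest.raises(NoClassError):
            select_ingestible_class(published_fit(), 100_000.0, bounded)

    def test_monotone_in_body_length(self):
        uppers = []
        for body in (13.5, 88.6, 1000.0, 100_000.0):
            cls = select_ingestible_class(published_fit(), body).size_class
            uppers.append(math.inf if cls.upper_mm is None else cls.upper_mm)
        assert uppers == sorted(uppers)

    def test_accepts_bare_tuples(self):
        selection = select_ingestible_class(published_fit(), 13.5, [(0.0, 2.0)])
        assert selection.size_class == SizeClass(0.0, 2.0)

    def test_empty_classes(self):
        with pytest.raises(InvalidParameterError):
            select_ingestible_class(published_fit(), 13.5, [])


class TestTotalPlastic:
    def test_four_unit_grids_sum_to_four(self):
        grids = [conc(np.ones((3, 4))) for _ in range(4)]
        assert (total_plastic(grids).values == 4.0).all()

    def test_single_grid_identity(self):
        grid = conc([[1.0, 2.0]])
        out = total_plastic([grid])
        assert np.array_equal(out.values, grid.values)
        assert np.array_equal(out.mask, grid.mask)

    def test_matches_cellwise_oracle(self):
        rng = np.random.default_rng(12)
        grids = [
            conc(rng.uniform(0, 10, (5, 6)), mask=rng.random((5, 6)) < 0.2)
            for _ in range(4)
        ]
        out = total_plastic(grids)
        for r in range(5):
            for c in range(6):
                expected = sum(
                    0.0 if g.mask[r, c] else g.values[r, c] for g in grids
                )
                assert out.values[r, c] == pytest.approx(expected, abs=1e-12)

    def test_masked_only_when_all_inputs_masked(self):
        a = conc([[1.0, 1.0]], mask=np.array([[True, True]]))
        b = conc([[2.0, 2.0]], mask=np.array([[True, False]]))
        out = total_plastic([a, b])
        assert out.mask.tolist() == [[True, False]]
        assert out.values[0, 1] == 2.0

    def test_shape_mismatch(self):
        with pytest.raises(InvalidGridError):
            total_plastic([conc(np.ones((2, 2))), conc(np.ones((2, 3)))])

    def test_unit_mismatch(self):
        with pytest.raises(InvalidGridError):
            total_plastic([conc([[1.0]], units="a"), conc([[1.0]], units="b")])


class TestRiskIndex:
    def test_equal_grids_give_unit_risk(self):
        grid = conc([[2.0, 5.0], [7.0, 1.0]])
        out = risk_index(grid, conc(grid.values.copy()))
        assert np.allclose(out.values[~out.mask], 1.0)

    def test_hand_computed_2x2(self):
        plastic = conc([[10.0, 100.0], [1000.0, 0.0]], units="pieces km^-2")
        zoo = conc([[1.0, 10.0], [0.0, 100.0]], units="mg C m^-3")
        out = risk_index(plastic, zoo)
        assert out.values[0, 0] == 10.0
        assert out.values[0, 1] == 10.0
        assert out.mask[1, 0]  # zero zooplankton density -> masked
        assert out.values[1, 1] == 0.0
        assert not out.mask[1, 1]

    def test_homogeneity_in_plastic(self):
        rng = np.random.default_rng(3)
        plastic = conc(rng.uniform(0, 100, (6, 6)))
        zoo = conc(rng.uniform(0.1, 10, (6, 6)))
        base = risk_index(plastic, zoo)
        for k in (0.5, 3.0, 10.0):
            scaled = risk_index(conc(plastic.values * k), zoo)
            assert np.allclose(
                scaled.values[~scaled.mask], k * base.values[~base.mask]
            )

    def test_inverse_homogeneity_in_zooplankton(self):
        rng = np.random.default_rng(4)
        plastic = conc(rng.uniform(0, 100, (6, 6)))
        zoo = conc(rng.uniform(0.1, 10, (6, 6)))
        base = risk_index(plastic, zoo)
        scaled = risk_index(plastic, conc(zoo.values * 2.0))
        assert np.allclose(scaled.values[~scaled.mask], base.values[~base.mask] / 2.0)

    def test_input_masks_propagate(self):
        plastic = conc([[1.0, 1.0]], mask=np.array([[True, False]]))
        zoo = conc([[1.0, 1.0]], mask=np.array([[False, True]]))
        assert risk_index(plastic, zoo).mask.tolist() == [[True, True]]

    def test_shape_mismatch(self):
        with pytest.raises(InvalidGridError):
            risk_index(conc(np.ones((2, 2))), conc(np.ones((3, 2))))

    def test_no_infinities(self):
        out = risk_index(conc([[5.0]]), conc([[0.0]]))
        assert np.isfinite(out.values).all()


class TestSyntheticGrids:
    def test_deterministic(self):
        a_plastic, a_zoo = generate_synthetic_grids((8, 9), seed=6)
        b_plastic, b_zoo = generate_synthetic_grids((8, 9), seed=6)
        for a, b in zip(a_plastic, b_plastic):
            assert np.array_equal(a.values, b.values)
            assert np.array_equal(a.mask, b.mask)
        assert np.array_equal(a_zoo.values, b_zoo.values)

    def test_class_values_in_range(self):
        plastic, zoo = generate_synthetic_grids((30, 30), seed=1)
        for g in plastic:
            assert ((g.values >= 0) & (g.values <= 8)).all()
        assert ((zoo.values >= 0) & (zoo.values <= 5)).all()

    def test_about_ten_percent_masked(self):
        plastic, zoo = generate_synthetic_grids((100, 100), seed=2)
        for g in list(plastic) + [zoo]:
            assert 0.05 < g.mask.mean() < 0.15

    def test_one_grid_per_size_class(self):
        plastic, _ = generate_synthetic_grids((4, 4), seed=0)
        assert len(plastic) == len(PLASTIC_SIZE_CLASSES)

    def test_invalid_shape(self):
        with pytest.raises(InvalidParameterError):
            generate_synthetic_grids((0, 5), seed=0)

    def test_full_pipeline_smoke(self):
        plastic_grids, zoo = generate_synthetic_grids((12, 15), seed=9)
        selection = select_ingestible_class(published_fit(), 13.5)
        index = PLASTIC_SIZE_CLASSES.index(
            (selection.size_class.lower_mm, selection.size_class.upper_mm)
        )
        plastic_conc = [linearise_classes(g) for g in plastic_grids]
        risk = risk_index(plastic_conc[index], linearise_classes(zoo))
        assert risk.shape == (12, 15)
        assert (risk.values[~risk.mask] >= 0).all()
        total = total_plastic(plastic_conc)
        total_risk = risk_index(total, linearise_classes(zoo))
        ok = ~total_risk.mask & ~risk.mask
        assert (total_risk.values[ok] >= risk.values[ok]).all()


class TestGridIO:
    def test_concentration_roundtrip(self, tmp_path):
        rng = np.random.default_rng(7)
        grid = conc(rng.uniform(0, 1e6, (5, 8)), mask=rng.random((5, 8)) < 0.3)
        path = tmp_path / "grid.tsv"
        write_grid(grid, path)
        back = read_concentration_grid(path, units="u")
        assert np.array_equal(back.mask, grid.mask)
        assert np.allclose(back.values[~back.mask], grid.values[~grid.mask])

    def test_class_grid_roundtrip(self, tmp_path):
        plastic, _ = generate_synthetic_grids((6, 6), seed=3)
        path = tmp_path / "class.tsv"
        write_grid(plastic[0], path)
        back = read_class_grid(path, 8, 6.0)
        assert np.array_equal(back.mask, plastic[0].mask)
        assert np.array_equal(back.values[~back.mask], plastic[0].values[~plastic[0].mask])

    def test_na_marks_mask(self, tmp_path):
        path = tmp_path / "grid.tsv"
        path.write_text("1.0\tNA\n2.0\t3.0\n")
        back = read_concentration_grid(path)
        assert back.mask.tolist() == [[False, True], [False, False]]

    def test_ragged_rejected(self, tmp_path):
        path = tmp_path / "grid.tsv"
        path.write_text("1.0\t2.0\n3.0\n")
        with pytest.raises(InvalidGridError):
            read_concentration_grid(path)

    def test_size_class_table_roundtrip(self, tmp_path):
        classes = [SizeClass(*c) for c in PLASTIC_SIZE_CLASSES]
        path = tmp_path / "classes.csv"
        write_size_classes(classes, path)
        assert read_size_classes(path) == classes

    def test_size_class_table_bad_header(self, tmp_path):
        path = tmp_path / "classes.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(InvalidParameterError):
            read_size_classes(path)
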