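"""Pixel correlation, cell-type assignment, abundance, subsection preview."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import spottype as st
from conftest import grid_offset, unit_grid


def _stack(values, genes=None, grid=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    if grid is None:
        grid = st.GridSpec(0.0, 0.0, 1.0, values.shape[2], values.shape[1], 1.0)
    return st.DensityStack(values=values, genes=genes, grid=grid)


def pearson_bruteforce(expr, sig_row):
    """Definitional Pearson: covariance over the product of standard deviations."""
    ex, sx = np.mean(expr), np.std(expr)
    ey, sy = np.mean(sig_row), np.std(sig_row)
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.mean((expr - ex) * (sig_row - ey)) / (sx * sy))


class TestCorrelatePixel:
    def test_positive_affine_transform_gives_one(self):
        sig = np.array([1.0, 0.0, 2.0])
        assert st.correlate_pixel(2 * sig + 3, sig) == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        sig = np.array([1.0, 0.0, 2.0])
        assert st.correlate_pixel(-sig, sig) == pytest.approx(-1.0)

    def test_disjoint_indicator_vectors(self):
        # hand-computed Pearson of (1,0,0) vs (0,1,0) on 3-vectors
        assert st.correlate_pixel(
            np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])
        ) == pytest.approx(-0.5)

    def test_zero_variance_pixel_is_undefined(self):
        r = st.correlate_pixel(np.array([2.0, 2.0, 2.0]), np.array([1.0, 0.0, 0.0]))
        assert math.isnan(r)

    def test_zero_variance_signature_rejected(self):
        with pytest.raises(st.ValidationError, match="zero variance"):
            st.correlate_pixel(np.array([1.0, 0.0]), np.array([3.0, 3.0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(st.ValidationError):
            st.correlate_pixel(np.array([1.0, 0.0]), np.array([1.0, 0.0, 0.0]))

    @settings(max_examples=50, derandomize=True)
    @given(hst.integers(0, 2**31 - 1))
    def test_matches_definitional_formula(self, seed):
        rng = np.random.default_rng(seed)
        expr, sig = rng.normal(size=5), rng.normal(size=5)
        assert st.correlate_pixel(expr, sig) == pytest.approx(
            pearson_bruteforce(expr, sig), abs=1e-12
        )


class TestAssignCelltypes:
    SIG = st.SignatureMatrix(
        ["t0", "t1"], ["g0", "g1", "g2"],
        np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
    )

    def test_proportional_pixel_gets_its_type(self):
        # pixel (0,0) proportional to row 1 of the signatures, above threshold
        vals = np.zeros((3, 1, 2))
        vals[:, 0, 0] = [0.0, 4.0, 0.0]
        vals[:, 0, 1] = [4.0, 0.0, 0.0]
        ctmap = st.assign_celltypes(_stack(vals, genes=self.SIG.genes), self.SIG, 1.0)
        assert ctmap.labels.tolist() == [[1, 0]]

    def test_below_threshold_is_background_regardless_of_correlation(self):
        vals = np.zeros((3, 1, 1))
        vals[:, 0, 0] = [1.9, 0.0, 0.0]  # perfect match to t0 but total 1.9
        ctmap = st.assign_celltypes(_stack(vals, genes=self.SIG.genes), self.SIG, 2.0)
        assert ctmap.labels.tolist() == [[-1]]

    def test_equal_mixture_tie_breaks_to_lowest_index(self):
        vals = np.zeros((3, 1, 1))
        vals[:, 0, 0] = [2.0, 2.0, 0.0]  # equally correlated with both rows
        stack = _stack(vals, genes=self.SIG.genes)
        r0 = st.correlate_pixel(vals[:, 0, 0], self.SIG.values[0])
        r1 = st.correlate_pixel(vals[:, 0, 0], self.SIG.values[1])
        assert r0 == pytest.approx(r1)  # confirmed tie
        ctmap = st.assign_celltypes(stack, self.SIG, 0.0)
        assert ctmap.labels[0, 0] == 0

    def test_zero_variance_pixel_falls_to_background_above_threshold(self):
        vals = np.full((3, 1, 1), 5.0)  # constant expression vector
        ctmap = st.assign_celltypes(_stack(vals, genes=self.SIG.genes), self.SIG, 1.0)
        assert ctmap.labels[0, 0] == -1

    def test_gene_order_mismatch_rejected(self):
        vals = np.zeros((3, 1, 1))
        stack = _stack(vals, genes=["g1", "g0", "g2"])
        with pytest.raises(st.ValidationError, match="gene order"):
            st.assign_celltypes(stack, self.SIG, 0.0)

    def test_constant_signature_row_rejected_by_name(self):
        sig = st.SignatureMatrix(["flat", "ok"], ["g0", "g1"],
                                 np.array([[2.0, 2.0], [1.0, 0.0]]))
        stack = _stack(np.zeros((2, 1, 1)), genes=["g0", "g1"])
        with pytest.raises(st.ValidationError, match="flat"):
            st.assign_celltypes(stack, sig, 0.0)

    @settings(max_examples=20, derandomize=True)
    @given(hst.integers(0, 2**31 - 1))
    def test_vectorized_assigner_matches_per_pixel_loop(self, seed):
        """On random 8×8 stacks the vectorized path equals definitional
        Pearson + argmax computed pixel by pixel."""
        rng = np.random.default_rng(seed)
        G, K = 6, 4
        vals = rng.gamma(1.0, 1.0, size=(G, 8, 8))
        vals[:, 0, 0] = 3.0  # force one zero-variance pixel vector
        sig = st.SignatureMatrix(
            [f"t{k}" for k in range(K)], [f"g{i}" for i in range(G)],
            rng.uniform(0.0, 2.0, size=(K, G)),
        )
        threshold = float(np.median(vals.sum(axis=0)))
        ctmap = st.assign_celltypes(_stack(vals, genes=sig.genes), sig, threshold)
        for r in range(8):
            for c in range(8):
                expr = vals[:, r, c]
                if expr.sum() < threshold or np.ptp(expr) == 0:
                    expected = -1
                else:
                    corrs = [pearson_bruteforce(expr, sig.values[k]) for k in range(K)]
                    expected = int(np.argmax(corrs))
                assert ctmap.labels[r, c] == expected, (r, c)

    @settings(max_examples=10, derandomize=True)
    @given(hst.integers(0, 2**31 - 1))
    def test_threshold_monotonicity(self, seed):
        """Raising the threshold only grows the background; surviving
        foreground labels never change."""
        rng = np.random.default_rng(seed)
        vals = rng.gamma(1.0, 1.0, size=(4, 10, 10))
        sig = st.SignatureMatrix(["a", "b"], [f"g{i}" for i in range(4)],
                                 rng.uniform(0, 2, size=(2, 4)))
        stack = _stack(vals, genes=sig.genes)
        totals = vals.sum(axis=0)
        prev = None
        for thr in np.quantile(totals, [0.0, 0.3, 0.6, 0.9]):
            ctmap = st.assign_celltypes(stack, sig, float(thr))
            bg = ctmap.labels == -1
            if prev is not None:
                assert (prev["bg"] <= bg).all()  # background never shrinks
                still_fg = ~bg
                np.testing.assert_array_equal(
                    ctmap.labels[still_fg], prev["labels"][still_fg]
                )
            prev = {"bg": bg, "labels": ctmap.labels}

    def test_positive_rescaling_changes_no_foreground_label(self):
        rng = np.random.default_rng(7)
        vals = rng.gamma(1.0, 1.0, size=(5, 12, 12))
        sig = st.SignatureMatrix(["a", "b", "c"], [f"g{i}" for i in range(5)],
                                 rng.uniform(0, 2, size=(3, 5)))
        base = st.assign_celltypes(_stack(vals, genes=sig.genes), sig, 0.0)
        scaled = st.assign_celltypes(_stack(vals * 37.5, genes=sig.genes), sig, 0.0)
        np.testing.assert_array_equal(base.labels, scaled.labels)

    def test_cosine_measure_supported(self):
        vals = np.zeros((3, 1, 1))
        vals[:, 0, 0] = [4.0, 0.0, 0.0]
        ctmap = st.assign_celltypes(_stack(vals, genes=self.SIG.genes), self.SIG, 0.0,
                                    measure="cosine")
        assert ctmap.labels[0, 0] == 0
        with pytest.raises(st.ValidationError):
            st.assign_celltypes(_stack(vals, genes=self.SIG.genes), self.SIG, 0.0,
                                measure="spearman")


class TestQuantifyAbundance:
    def test_counts_and_fractions(self):
        ctmap = st.CellTypeMap(np.array([[0, 0], [1, -1]]), ["a", "b"])
        table = st.quantify_abundance(ctmap)
        assert table.set_index("celltype")["count"].to_dict() == {
            "a": 2, "b": 1, "background": 1}
        assert table.set_index("celltype")["fraction"]["a"] == pytest.approx(2 / 3)
        assert table.set_index("celltype")["fraction"]["b"] == pytest.approx(1 / 3)
        assert table["count"].sum() == 4  # counts cover the whole view

    def test_all_background_view(self):
        ctmap = st.CellTypeMap(np.full((3, 3), -1), ["a"])
        table = st.quantify_abundance(ctmap)
        assert (table["fraction"] == 0).all()
        assert table.set_index("celltype")["count"]["background"] == 9

    def test_single_pixel_view(self):
        ctmap = st.CellTypeMap(np.array([[0, 1], [1, -1]]), ["a", "b"])
        table = st.quantify_abundance(ctmap, st.ViewRect(0, 1, 1, 2))
        by = table.set_index("celltype")
        assert by["fraction"]["b"] == 1.0 and by["count"]["b"] == 1

    def test_empty_or_out_of_bounds_view_rejected(self):
        ctmap = st.CellTypeMap(np.zeros((2, 2), dtype=int), ["a"])
        with pytest.raises(st.ValidationError):
            st.ViewRect(1, 1, 0, 2)
        with pytest.raises(st.ValidationError):
            st.quantify_abundance(ctmap, st.ViewRect(0, 5, 0, 2))


class TestPreviewSubsection:
    def test_full_extent_preview_equals_full_run(self, toy_tissue, toy_params,
                                                 toy_signatures):
        _, spots, _ = toy_tissue
        grid = st.make_grid(spots, toy_params)
        full = st.run_kde(spots, toy_signatures.genes, toy_params, grid)
        full_map = st.assign_celltypes(full, toy_signatures, toy_params.threshold)
        stack, ctmap = st.preview_subsection(
            spots, toy_signatures, (150.0, 150.0), 10_000.0, toy_params)
        np.testing.assert_array_equal(stack.values, full.values)
        np.testing.assert_array_equal(ctmap.labels, full_map.labels)

    def test_interior_pixels_match_full_run_exactly(self, toy_tissue, toy_params,
                                                    toy_signatures):
        _, spots, _ = toy_tissue
        grid = st.make_grid(spots, toy_params)
        full = st.run_kde(spots, toy_signatures.genes, toy_params, grid)
        full_map = st.assign_celltypes(full, toy_signatures, toy_params.threshold)
        stack, ctmap = st.preview_subsection(
            spots, toy_signatures, (150.0, 150.0), 120.0, toy_params)
        r0, c0 = grid_offset(stack.grid, grid)
        H, W = stack.grid.height_px, stack.grid.width_px
        rad = math.ceil(2 * grid.bandwidth_px)
        inner = np.s_[rad : H - rad, rad : W - rad]
        np.testing.assert_array_equal(
            stack.values[(slice(None),) + inner],
            full.values[:, r0 + rad : r0 + H - rad, c0 + rad : c0 + W - rad],
        )
        np.testing.assert_array_equal(
            ctmap.labels[inner],
            full_map.labels[r0 + rad : r0 + H - rad, c0 + rad : c0 + W - rad],
        )

    def test_preview_keeps_full_run_resolution(self, toy_tissue, toy_params,
                                               toy_signatures):
        _, spots, _ = toy_tissue
        grid = st.make_grid(spots, toy_params)
        stack, _ = st.preview_subsection(
            spots, toy_signatures, (150.0, 150.0), 80.0, toy_params)
        assert stack.grid.scale == grid.scale
        assert stack.grid.bandwidth_px == grid.bandwidth_px
        assert stack.grid.width_px < grid.width_px

    def test_window_without_molecules_rejected(self, toy_tissue, toy_params,
                                               toy_signatures):
        _, spots, _ = toy_tissue
        with pytest.raises(st.ValidationError):
            st.preview_subsection(spots, toy_signatures, (10_000.0, 10_000.0), 5.0,
                                  toy_params)
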