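"""Expression ingestion, harmonisation and differential expression."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from xtalk.expression import (
    ExpressionDataset,
    ExpressionError,
    differential_expression,
    intersect_genes,
    read_expression,
    signature_genes,
)

from conftest import make_dataset


def _write_matrix(tmp_path, rows, header):
    path = tmp_path / "expr.tsv"
    lines = ["gene\t" + "\t".join(header)]
    for gene, vals in rows:
        lines.append(gene + "\t" + "\t".join(str(v) for v in vals))
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadExpression:
    def test_reads_matrix_with_states(self, tmp_path):
        path = _write_matrix(
            tmp_path,
            [("A", [1, 2, 3, 4]), ("B", [2, 2, 2, 2]), ("C", [0, 1, 0, 1])],
            ["s1", "s2", "s3", "s4"],
        )
        ds = read_expression(
            path, {"s1": "normal", "s2": "normal", "s3": "tumor", "s4": "tumor"}
        )
        assert len(ds.genes) == 3
        assert len(ds.samples) == 4
        assert list(ds.state_samples("tumor")) == ["s3", "s4"]

    def test_sample_missing_from_state_map_is_named(self, tmp_path):
        path = _write_matrix(tmp_path, [("A", [1, 2])], ["s1", "s2"])
        with pytest.raises(ExpressionError, match="s2"):
            read_expression(path, {"s1": "normal"})

    def test_duplicate_gene_rows_collapse_by_mean(self, tmp_path):
        path = _write_matrix(
            tmp_path, [("A", [1.0, 5.0]), ("A", [3.0, 7.0])], ["s1", "s2"]
        )
        ds = read_expression(path, {"s1": "normal", "s2": "tumor"})
        assert ds.values.loc["A", "s1"] == 2.0
        assert ds.values.loc["A", "s2"] == 6.0

    def test_non_numeric_cell_is_located(self, tmp_path):
        path = _write_matrix(tmp_path, [("A", [1, "oops"])], ["s1", "s2"])
        with pytest.raises(ExpressionError, match="s2"):
            read_expression(path, {"s1": "normal", "s2": "tumor"})


class TestIntersectGenes:
    def _ds(self, genes, did):
        samples = ["n1", "n2", "t1", "t2"]
        states = pd.Series(["normal", "normal", "tumor", "tumor"], index=samples)
        values = pd.DataFrame(
            np.arange(len(genes) * 4, dtype=float).reshape(len(genes), 4),
            index=genes,
            columns=samples,
        )
        return ExpressionDataset(did, values, states)

    def test_restricts_to_common_sorted_genes(self):
        out = intersect_genes([self._ds(["A", "B", "C"], "d1"), self._ds(["B", "C", "D"], "d2")])
        assert all(list(ds.genes) == ["B", "C"] for ds in out)

    def test_single_dataset_unchanged(self):
        (out,) = intersect_genes([self._ds(["B", "A"], "d1")])
        assert set(out.genes) == {"A", "B"}

    def test_disjoint_gene_sets_error(self):
        with pytest.raises(ExpressionError, match="empty"):
            intersect_genes([self._ds(["A"], "d1"), self._ds(["B"], "d2")])


class TestDifferentialExpression:
    def test_identical_states_give_zero_lfc_p_one(self):
        ds = make_dataset(n_genes=3, n_per_state=4, seed=1)
        ds.values.loc["G0"] = [5, 6, 7, 8, 5, 6, 7, 8]
        de = differential_expression(ds)
        assert de.loc["G0", "log2fc"] == 0
        assert de.loc["G0", "p_value"] == 1

    def test_exact_unit_shift(self):
        ds = make_dataset(n_genes=2, n_per_state=4, seed=2)
        normal = ds.state_samples("normal")
        tumor = ds.state_samples("tumor")
        ds.values.loc["G1", tumor] = ds.values.loc["G1", normal].to_numpy() + 1.0
        de = differential_expression(ds)
        assert de.loc["G1", "log2fc"] == pytest.approx(1.0, abs=1e-12)

    def test_welch_p_matches_hand_formula(self):
        # independent oracle: Welch statistic and Satterthwaite df from scratch
        from scipy.stats import t as tdist

        ds = make_dataset(n_genes=5, n_per_state=5, seed=3)
        de = differential_expression(ds)
        for g in ds.genes:
            x = ds.state_values("tumor").loc[g].to_numpy()
            y = ds.state_values("normal").loc[g].to_numpy()
            vx, vy = x.var(ddof=1), y.var(ddof=1)
            nx_, ny = len(x), len(y)
            se2 = vx / nx_ + vy / ny
            t = (x.mean() - y.mean()) / math.sqrt(se2)
            df = se2**2 / ((vx / nx_) ** 2 / (nx_ - 1) + (vy / ny) ** 2 / (ny - 1))
            p = 2 * tdist.sf(abs(t), df)
            assert de.loc[g, "p_value"] == pytest.approx(p, abs=1e-10)

    def test_single_sample_state_errors(self):
        ds = make_dataset(n_per_state=3)
        small = ExpressionDataset(
            "S", ds.values.iloc[:, [0, 3, 4, 5]], ds.states.iloc[[0, 3, 4, 5]]
        )
        with pytest.raises(ExpressionError, match="normal"):
            differential_expression(small)

    def test_column_order_invariance_and_label_swap(self):
        ds = make_dataset(seed=4)
        de = differential_expression(ds)
        shuffled = ExpressionDataset(
            ds.dataset_id, ds.values.iloc[:, ::-1], ds.states.iloc[::-1]
        )
        de2 = differential_expression(shuffled)
        pd.testing.assert_frame_equal(de, de2)
        flipped = ds.states.map({"normal": "tumor", "tumor": "normal"})
        de3 = differential_expression(ExpressionDataset(ds.dataset_id, ds.values, flipped))
        np.testing.assert_allclose(de3.log2fc, -de.log2fc, atol=1e-12)
        np.testing.assert_allclose(de3.p_value, de.p_value, atol=1e-12)


class TestSignatureGenes:
    def _tables(self, rows):
        # rows: gene -> [(lfc, p) per dataset]
        out = {}
        for d in range(3):
            out[f"d{d}"] = pd.DataFrame(
                {
                    "log2fc": {g: v[d][0] for g, v in rows.items()},
                    "p_value": {g: v[d][1] for g, v in rows.items()},
                }
            )
        return out

    def test_mean_lfc_boundary_is_inclusive_at_half(self):
        rows = {
            "JUST_UNDER": [(0.49, 0.001)] * 3,
            "AT_BOUND": [(0.5, 0.001)] * 3,
        }
        up, down = signature_genes(self._tables(rows))
        assert "JUST_UNDER" not in up | down
        assert "AT_BOUND" in up

    def test_direction_and_p_filter(self):
        rows = {
            "UP": [(1.0, 0.001), (1.0, 0.001), (1.0, 0.001)],
            "DOWN": [(-1.0, 0.001)] * 3,
            "ONE_BAD_P": [(2.0, 0.001), (2.0, 0.001), (-2.0, 0.5)],
        }
        up, down = signature_genes(self._tables(rows))
        assert up == {"UP"}
        assert down == {"DOWN"}

    def test_up_down_disjoint_within_pool(self):
        rows = {f"G{i}": [((-1) ** i * 0.8, 0.005)] * 3 for i in range(6)}
        up, down = signature_genes(self._tables(rows), gene_pool={f"G{i}" for i in range(6)})
        assert not up & down
        assert up | down <= {f"G{i}" for i in range(6)}

    def test_empty_pool_errors(self):
        rows = {"G": [(1.0, 0.001)] * 3}
        with pytest.raises(ExpressionError, match="pool"):
            signature_genes(self._tables(rows), gene_pool=set())


@given(shift=st.floats(-2, 2, allow_nan=False), seed=st.integers(0, 50))
def test_lfc_equals_planted_shift(shift, seed):
    """A constant tumor shift is recovered exactly as the log2FC."""
    ds = make_dataset(n_genes=2, n_per_state=4, seed=seed)
    tumor = ds.state_samples("tumor")
    normal = ds.state_samples("normal")
    ds.values.loc["G0", tumor] = ds.values.loc["G0", normal].to_numpy() + shift
    de = differential_expression(ds)
    assert de.loc["G0", "log2fc"] == pytest.approx(shift, abs=1e-9)
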