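import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regulon_coupler.io import (
    BindingScoreTable,
    ExpressionMatrix,
    GeneList,
    OrthologMap,
    ValidationError,
)
from regulon_coupler.panel import (
    PanelConfig,
    average_replicates,
    build_panel,
    top_k_genes,
)


def _table(dataset_id, scores, species="human", group=None):
    return BindingScoreTable(
        dataset_id=dataset_id,
        species=species,
        replicate_group=group or dataset_id,
        scores=pd.Series(scores),
    )


def _expr(genes, n_samples=4, value=1.0):
    return ExpressionMatrix(
        pd.DataFrame(
            np.full((len(genes), n_samples), value),
            index=genes,
            columns=[f"s{i}" for i in range(n_samples)],
        )
    )


class TestAverageReplicates:
    def test_hand_computed_mean(self):
        t1 = _table("r1", {"A": 10.0, "B": 2.0}, group="g")
        t2 = _table("r2", {"A": 6.0, "B": 4.0}, group="g")
        (merged,) = average_replicates([t1, t2])
        assert merged.scores["A"] == pytest.approx(8.0)
        assert merged.scores["B"] == pytest.approx(3.0)
        assert merged.replicate_group == "g"

    def test_singleton_group_unchanged(self):
        t = _table("solo", {"A": 1.0})
        (out,) = average_replicates([t])
        assert out is t

    def test_present_only_averaging(self):
        t1 = _table("r1", {"A": 10.0, "B": 6.0}, group="g")
        t2 = _table("r2", {"A": 6.0}, group="g")
        (merged,) = average_replicates([t1, t2])
        assert merged.scores["B"] == pytest.approx(6.0)

    def test_mixed_species_group_rejected(self):
        t1 = _table("r1", {"A": 1.0}, species="human", group="g")
        t2 = _table("r2", {"A": 2.0}, species="mouse", group="g")
        with pytest.raises(ValidationError, match="species"):
            average_replicates([t1, t2])

    def test_group_order_is_first_occurrence(self):
        tables = [
            _table("b1", {"A": 1.0}, group="g2"),
            _table("a1", {"A": 1.0}, group="g1"),
        ]
        assert [t.replicate_group for t in average_replicates(tables)] == ["g2", "g1"]


class TestTopK:
    def test_k_larger_than_table_returns_all(self):
        gl = top_k_genes(_table("d", {"A": 1.0, "B": 2.0}), 10)
        assert gl.symbols == ["B", "A"]

    def test_lexicographic_tie_break(self):
        gl = top_k_genes(_table("d", {"C": 4.0, "B": 5.0, "A": 5.0}), 2)
        assert gl.symbols == ["A", "B"]

    def test_exact_k_from_large_table(self):
        rng = np.random.default_rng(0)
        scores = {f"G{i:04d}": float(s) for i, s in enumerate(rng.normal(size=3000))}
        gl = top_k_genes(_table("d", scores), 100)
        assert len(gl) == 100
        kept = min(scores[g] for g in gl)
        dropped = max(v for g, v in scores.items() if g not in set(gl.symbols))
        assert kept >= dropped


class TestBuildPanel:
    def test_toy_membership_rule(self):
        lists = [
            GeneList(["A", "B", "C"], label="l1"),
            GeneList(["B", "C", "D"], label="l2"),
            GeneList(["C", "E"], label="l3"),
        ]
        expr = _expr(["A", "B", "C", "D", "E"])
        panel = build_panel(
            lists, ["human"] * 3, OrthologMap(), expr, GeneList([], label="none"),
            PanelConfig(top_k=10, min_list_membership=2),
        )
        assert panel.symbols == ["B", "C"]
        assert panel.counts["n_multi_list"] == 2
        assert panel.counts["n_canonical_added"] == 0

    def test_empty_canonical_equals_filtered_list(self):
        lists = [GeneList(["A", "B"], label="l1"), GeneList(["A", "B"], label="l2")]
        expr = _expr(["A", "B"])
        panel = build_panel(
            lists, ["human", "human"], OrthologMap(), expr, GeneList([]),
            PanelConfig(),
        )
        assert panel.symbols == ["A", "B"]
        assert panel.counts["n_final"] == panel.counts["n_after_filters"]

    def test_ortholog_corroboration_across_species(self):
        lists = [
            GeneList(["ABCA1"], label="human_ds"),
            GeneList(["mmAbc"], label="mouse_ds"),
        ]
        omap = OrthologMap({"mmAbc": "ABCA1"})
        panel = build_panel(
            lists, ["human", "mouse"], omap, _expr(["ABCA1"]), GeneList([]),
            PanelConfig(),
        )
        assert panel.symbols == ["ABCA1"]
        assert panel.provenance.loc["ABCA1", "n_lists"] == 2
        assert "MMABC" in panel.provenance.loc["ABCA1", "source_symbols"]

    def test_unmapped_multi_list_gene_counted_as_ortholog_drop(self):
        lists = [
            GeneList(["Mystery"], label="m1"),
            GeneList(["Mystery"], label="m2"),
        ]
        panel = build_panel(
            lists, ["mouse", "mouse"], OrthologMap(), _expr(["OTHER"]),
            GeneList([]), PanelConfig(),
        )
        assert panel.counts["n_dropped_no_ortholog"] == 1
        assert panel.counts["n_after_filters"] == 0

    def test_expression_presence_filter(self):
        lists = [GeneList(["A", "B"], label="l1"), GeneList(["A", "B"], label="l2")]
        # B observed in only 1/4 samples -> fails the 50% presence rule
        df = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [1.0, np.nan, np.nan, np.nan]],
            index=["A", "B"], columns=list("wxyz"),
        )
        panel = build_panel(
            lists, ["human", "human"], OrthologMap(), ExpressionMatrix(df),
            GeneList([]), PanelConfig(),
        )
        assert panel.symbols == ["A"]
        assert panel.counts["n_dropped_not_expressed"] == 1

    def test_canonical_absent_from_expression_retained_and_flagged(self):
        lists = [GeneList(["A"], label="l1"), GeneList(["A"], label="l2")]
        panel = build_panel(
            lists, ["human", "human"], OrthologMap(), _expr(["A"]),
            GeneList(["GHOST"], label="canon"), PanelConfig(),
        )
        assert panel.symbols == ["A", "GHOST"]
        assert not panel.provenance.loc["GHOST", "in_expression"]
        assert panel.provenance.loc["GHOST", "status"] == "canonical_added"

    def test_canonical_rescues_filtered_gene(self):
        lists = [GeneList(["A"], label="l1")]
        panel = build_panel(
            lists, ["human"], OrthologMap(), _expr(["A"]),
            GeneList(["A"], label="canon"), PanelConfig(min_list_membership=2),
        )
        assert panel.symbols == ["A"]
        assert panel.counts["n_canonical_added"] == 1

    def test_empty_list_collection_rejected(self):
        with pytest.raises(ValidationError):
            build_panel([], [], OrthologMap(), _expr(["A"]), GeneList([]), PanelConfig())

    def test_determinism_under_list_order(self):
        lists = [
            GeneList(["A", "B", "C"], label="l1"),
            GeneList(["C", "A"], label="l2"),
            GeneList(["B", "C"], label="l3"),
        ]
        expr = _expr(["A", "B", "C"])
        p1 = build_panel(lists, ["human"] * 3, OrthologMap(), expr, GeneList([]), PanelConfig())
        p2 = build_panel(
            lists[::-1], ["human"] * 3, OrthologMap(), expr, GeneList([]), PanelConfig()
        )
        assert p1.symbols == p2.symbols
        assert p1.counts == p2.counts

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_bookkeeping_identity_and_membership_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        pool = [f"G{i}" for i in range(20)]
        n_lists = rng.integers(1, 5)
        lists = [
            GeneList(
                list(rng.choice(pool, size=rng.integers(1, 12), replace=False)),
                label=f"l{i}",
            )
            for i in range(n_lists)
        ]
        expressed = list(rng.choice(pool, size=10, replace=False))
        expr = _expr(expressed)
        canonical = GeneList(list(rng.choice(pool, size=4, replace=False)), label="c")
        panels = []
        for mlm in (1, 2, 3):
            panel = build_panel(
                lists, ["human"] * n_lists, OrthologMap(), expr, canonical,
                PanelConfig(min_list_membership=mlm),
            )
            c = panel.counts
            assert c["n_final"] == c["n_after_filters"] + c["n_canonical_added"]
            assert c["n_multi_list"] == (
                c["n_dropped_no_ortholog"] + c["n_dropped_not_expressed"]
                + c["n_after_filters"]
            )
            assert len(set(panel.symbols)) == len(panel.symbols) == c["n_final"]
            panels.append(c["n_after_filters"])
        # raising the membership requirement never grows the pre-union panel
        assert panels[0] >= panels[1] >= panels[2]
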