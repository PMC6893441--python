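"""Consensus TF target-panel construction from ChIP-Seq binding scores.

The panel is built by the multi-dataset corroboration rule: take the
``top_k`` highest-scoring genes of each (replicate-averaged) binding-score
table, keep genes appearing in at least ``min_list_membership`` lists, map
non-human symbols through an ortholog table (unmapped symbols are counted
and dropped), drop genes not expressed in the accompanying expression
matrix, and finally union the survivors with a literature-derived canonical
target list whose members are exempt from every filter.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    BindingScoreTable,
    ExpressionMatrix,
    GeneList,
    OrthologMap,
    ValidationError,
    canonical_symbol,
)

__all__ = ["PanelConfig", "TargetPanel", "average_replicates", "top_k_genes", "build_panel"]

HUMAN = "human"


@dataclass
class PanelConfig:
    """Tunable parameters of the panel-building rule.

    top_k: genes taken from the top of each binding-score table.
    min_list_membership: minimum number of lists a gene must appear in
        (2 means genes seen in only one list are excluded).
    min_expressed_fraction: a gene counts as expressed when present in the
        expression matrix with at least this fraction of non-missing samples.
    """

    top_k: int = 100
    min_list_membership: int = 2
    min_expressed_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")
        if self.min_list_membership < 1:
            raise ValidationError("min_list_membership must be >= 1")
        if not 0.0 <= self.min_expressed_fraction <= 1.0:
            raise ValidationError("min_expressed_fraction must lie in [0, 1]")


@dataclass
class TargetPanel:
    """Final target gene list with per-gene provenance and bookkeeping.

    ``counts`` satisfies ``n_final = n_after_filters + n_canonical_added``
    where ``n_canonical_added`` counts canonical genes not already present.
    """

    symbols: list[str]
    provenance: pd.DataFrame
    counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def to_frame(self) -> pd.DataFrame:
        return self.provenance

    def final_frame(self) -> pd.DataFrame:
        """Provenance restricted to the final panel, in panel order."""
        return self.provenance.loc[self.symbols]


def average_replicates(tables: Sequence[BindingScoreTable]) -> list[BindingScoreTable]:
    """Collapse tables sharing a replicate_group into one averaged table.

    For each gene the score is the arithmetic mean over the replicates in
    which the gene is present (present-only averaging).  Groups appear in
    first-occurrence order; a group mixing species is an error.
    """
    groups: dict[str, list[BindingScoreTable]] = defaultdict(list)
    order: list[str] = []
    for t in tables:
        if t.replicate_group not in groups:
            order.append(t.replicate_group)
        groups[t.replicate_group].append(t)
    out = []
    for g in order:
        members = groups[g]
        species = {t.species for t in members}
        if len(species) > 1:
            raise ValidationError(
                f"replicate group {g!r} mixes species {sorted(species)}"
            )
        if len(members) == 1:
            out.append(members[0])
            continue
        merged = pd.concat([t.scores for t in members], axis=1)
        out.append(
            BindingScoreTable(
                dataset_id=g,
                species=members[0].species,
                replicate_group=g,
                scores=merged.mean(axis=1, skipna=True),
            )
        )
    return out


def top_k_genes(table: BindingScoreTable, k: int) -> GeneList:
    """The ``min(k, len(table))`` genes with the highest binding scores.

    Deterministic: sorted by descending score, ties broken by ascending
    symbol.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    df = table.scores.reset_index()
    df.columns = ["gene", "score"]
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    return GeneList(list(df["gene"].head(k)), label=table.dataset_id)


def build_panel(
    lists: Sequence[GeneList],
    species: Sequence[str],
    orthologs: OrthologMap,
    expr: ExpressionMatrix,
    canonical: GeneList,
    cfg: PanelConfig | None = None,
) -> TargetPanel:
    """Assemble the consensus target panel from per-dataset top-k lists.

    ``lists`` are the post-averaging top-k gene lists, with a parallel
    ``species`` entry each.  Non-human symbols are translated through
    ``orthologs`` before membership counting so a mouse and a human dataset
    can corroborate the same human gene; symbols without an ortholog retain
    their source symbol and, if they pass the membership filter, are dropped
    and counted as ortholog casualties.  Genes failing the
    expressed-in-``expr`` rule are dropped next, and the canonical list is
    unioned in last, exempt from all filters.
    """
    cfg = cfg or PanelConfig()
    if len(lists) == 0:
        raise ValidationError("build_panel: no gene lists supplied")
    if len(species) != len(lists):
        raise ValidationError("build_panel: species must parallel lists")

    # per-list mapping to human symbols; membership counted once per list
    membership: dict[str, set[str]] = defaultdict(set)  # symbol -> dataset labels
    unmappable: set[str] = set()
    source_of: dict[str, set[str]] = defaultdict(set)
    for glist, sp in zip(lists, species):
        label = glist.label
        is_human = sp.strip().lower() == HUMAN
        for sym in glist:
            if is_human:
                mapped = sym
            else:
                hit = orthologs.get(sym)
                if hit is None:
                    mapped = sym
                    unmappable.add(sym)
                else:
                    mapped = hit
                    source_of[mapped].add(sym)
            membership[mapped].add(label)

    def expressed(sym: str) -> bool:
        if sym not in expr:
            return False
        vals = expr.gene_values(sym)
        return np.isfinite(vals).mean() >= cfg.min_expressed_fraction

    multi = sorted(s for s, ds in membership.items() if len(ds) >= cfg.min_list_membership)
    status: dict[str, str] = {}
    kept: list[str] = []
    for sym in multi:
        if sym in unmappable:
            status[sym] = "dropped_no_ortholog"
        elif not expressed(sym):
            status[sym] = "dropped_not_expressed"
        else:
            status[sym] = "kept"
            kept.append(sym)

    n_multi = len(multi)
    n_no_orth = sum(1 for s in multi if status[s] == "dropped_no_ortholog")
    n_not_expr = sum(1 for s in multi if status[s] == "dropped_not_expressed")

    canonical_added = [canonical_symbol(s) for s in canonical if s not in set(kept)]
    final = kept + canonical_added

    # a canonical gene that was dropped by a filter is rescued by the union;
    # mark that on its existing provenance row instead of duplicating it
    multi_set = set(multi)
    for sym in canonical_added:
        if sym in multi_set:
            status[sym] += "+canonical_rescued"

    rows = []
    for sym in multi:
        rows.append(
            {
                "gene": sym,
                "status": status[sym],
                "n_lists": len(membership[sym]),
                "datasets": ";".join(sorted(membership[sym])),
                "source_symbols": ";".join(sorted(source_of.get(sym, ()))),
                "canonical": sym in canonical,
                "in_expression": sym in expr,
            }
        )
    for sym in canonical_added:
        if sym in multi_set:
            continue
        rows.append(
            {
                "gene": sym,
                "status": "canonical_added",
                "n_lists": len(membership.get(sym, ())),
                "datasets": ";".join(sorted(membership.get(sym, ()))),
                "source_symbols": "",
                "canonical": True,
                "in_expression": sym in expr,
            }
        )
    provenance = pd.DataFrame(
        rows,
        columns=[
            "gene", "status", "n_lists", "datasets",
            "source_symbols", "canonical", "in_expression",
        ],
    ).set_index("gene")

    counts = {
        "n_multi_list": n_multi,
        "n_dropped_no_ortholog": n_no_orth,
        "n_dropped_not_expressed": n_not_expr,
        "n_after_filters": len(kept),
        "n_canonical_added": len(canonical_added),
        "n_final": len(final),
    }
    return TargetPanel(symbols=final, provenance=provenance, counts=counts)
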