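"""Cohort-stratified TF-target correlation screen.

For each gene of a target panel, the screen computes the Pearson
correlation of its expression with the transcription factor's expression,
separately within two sample cohorts, adjusts the two-sided p-values with
Benjamini-Hochberg within each cohort, flags genes with ``q < fdr_level``,
and compares the per-cohort significant counts with a two-sided Fisher's
exact test on the 2x2 table [significant, not] x [cohort A, cohort B].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import (
    CohortAnnotation,
    ExpressionMatrix,
    ValidationError,
    canonical_symbol,
)
from .stats import bh_fdr, fisher_exact_2x2, pearson_rows

__all__ = ["ScreenResult", "run_screen", "volcano"]


@dataclass
class ScreenResult:
    """Per-gene, per-cohort correlation records plus count bookkeeping.

    records columns: gene, cohort, r, p, q, significant, n_used.
    ``counts`` maps cohort label -> number of significant genes;
    ``bh_threshold`` maps cohort label -> largest raw p among rejected
    genes (NaN when nothing was rejected), the constant line a volcano
    plot would draw for the BH cut.
    """

    records: pd.DataFrame
    fdr_level: float
    cohorts: list[str]
    counts: dict[str, int]
    n_tested: dict[str, int]
    skipped: list[str]
    fisher_odds_ratio: float
    fisher_p: float
    denominator: str
    bh_threshold: dict[str, float] = field(default_factory=dict)

    def summary(self) -> dict:
        """JSON-ready summary of the screen."""
        a, b = self.cohorts
        return {
            "cohorts": self.cohorts,
            "fdr_level": self.fdr_level,
            f"count_{a}": self.counts[a],
            f"count_{b}": self.counts[b],
            "n_tested": self.n_tested,
            "n_skipped": len(self.skipped),
            "denominator": self.denominator,
            "fisher_odds_ratio": self.fisher_odds_ratio,
            "fisher_p": self.fisher_p,
            "bh_threshold": self.bh_threshold,
        }


def run_screen(
    expr: ExpressionMatrix,
    ann: CohortAnnotation,
    tf_gene: str,
    panel: Iterable[str],
    fdr_level: float = 0.01,
    denominator: str = "tested",
    pooled_fdr: bool = False,
) -> ScreenResult:
    """Correlate ``tf_gene`` with every panel gene within each cohort.

    Panel genes absent from ``expr`` (or with fewer than three complete
    pairs in a cohort) are reported in ``skipped``, never silently dropped.
    ``denominator`` chooses the Fisher-table margin: ``"tested"`` (genes
    actually correlated, the default) or ``"panel"`` (the full panel size).
    ``pooled_fdr=True`` applies BH across both cohorts as one family
    instead of per cohort.
    """
    tf = canonical_symbol(tf_gene)
    if tf not in expr:
        raise ValidationError(f"TF gene {tf!r} absent from expression matrix")
    if denominator not in ("tested", "panel"):
        raise ValidationError("denominator must be 'tested' or 'panel'")

    cohorts = ann.cohorts
    if len(cohorts) != 2:
        raise ValidationError(
            f"screen requires exactly two cohorts, found {len(cohorts)}: {cohorts}"
        )

    panel_syms = [canonical_symbol(g) for g in panel]
    if not panel_syms:
        raise ValidationError("empty panel")
    present = [g for g in panel_syms if g in expr]
    skipped = [g for g in panel_syms if g not in expr]

    sample_index = {s: i for i, s in enumerate(expr.sample_ids)}
    per_cohort: dict[str, pd.DataFrame] = {}
    for label in cohorts:
        cols = [sample_index[s] for s in ann.samples(label) if s in sample_index]
        if len(cols) < 3:
            raise ValidationError(
                f"cohort {label!r} has {len(cols)} samples in the matrix (need >= 3)"
            )
        sub = expr.data.to_numpy()[:, cols]
        gene_pos = [expr.data.index.get_loc(g) for g in present]
        Y = sub[gene_pos, :]
        x = sub[expr.data.index.get_loc(tf), :]
        r, p, n_used = pearson_rows(x, Y)
        low_n = n_used < 3
        zero_var = np.isnan(r) & ~low_n
        if zero_var.any():
            gene = present[int(np.argmax(zero_var))]
            raise ValidationError(
                f"gene {gene!r} has zero variance in cohort {label!r}; correlation undefined"
            )
        per_cohort[label] = pd.DataFrame(
            {"gene": present, "cohort": label, "r": r, "p": p, "n_used": n_used}
        )[~low_n]
        skipped.extend(np.asarray(present)[low_n].tolist())

    if pooled_fdr:
        pooled = pd.concat(per_cohort.values(), ignore_index=True)
        pooled["q"] = bh_fdr(pooled["p"].to_numpy())
        frames = [pooled[pooled["cohort"] == label] for label in cohorts]
    else:
        frames = []
        for label in cohorts:
            df = per_cohort[label].copy()
            df["q"] = bh_fdr(df["p"].to_numpy())
            frames.append(df)

    records = pd.concat(frames, ignore_index=True)
    records["significant"] = records["q"] < fdr_level
    records = records[["gene", "cohort", "r", "p", "q", "significant", "n_used"]]

    counts, n_tested, bh_thr = {}, {}, {}
    for label in cohorts:
        sub = records[records["cohort"] == label]
        counts[label] = int(sub["significant"].sum())
        n_tested[label] = int(len(sub))
        rejected = sub.loc[sub["significant"], "p"]
        bh_thr[label] = float(rejected.max()) if len(rejected) else float("nan")

    a_lab, b_lab = cohorts
    denom = {
        label: (n_tested[label] if denominator == "tested" else len(panel_syms))
        for label in cohorts
    }
    odds, fp = fisher_exact_2x2(
        counts[a_lab], denom[a_lab] - counts[a_lab],
        counts[b_lab], denom[b_lab] - counts[b_lab],
    )

    return ScreenResult(
        records=records,
        fdr_level=fdr_level,
        cohorts=list(cohorts),
        counts=counts,
        n_tested=n_tested,
        skipped=sorted(set(skipped)),
        fisher_odds_ratio=odds,
        fisher_p=fp,
        denominator=denominator,
        bh_threshold=bh_thr,
    )


def volcano(result: ScreenResult, path: str, cohort: str | None = None) -> None:
    """Scatter of r against -log10(q) per cohort (optional plot output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [cohort] if cohort else result.cohorts
    fig, axes = plt.subplots(1, len(labels), figsize=(5 * len(labels), 4), squeeze=False)
    for ax, label in zip(axes[0], labels):
        sub = result.records[result.records["cohort"] == label]
        q = np.maximum(sub["q"].to_numpy(), 1e-300)
        ax.scatter(sub["r"], -np.log10(q), s=8,
                   c=np.where(sub["significant"], "crimson", "grey"))
        ax.axhline(-np.log10(result.fdr_level), ls=":", c="k", lw=0.8)
        ax.set_xlabel("Pearson r with TF")
        ax.set_ylabel("-log10 q")
        ax.set_title(label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
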