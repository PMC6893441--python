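"""Cross-cohort regulator comparison and receptor/corepressor ratio analysis.

Receptor and corepressor expression is compared between the two cohorts
with two-tailed Mann-Whitney U tests under Bonferroni correction.  The
receptor-to-corepressor "ratio" on log-scale data is the difference of log
expressions (the log of the linear ratio); per-sample ratio profiles can
then be correlated with target-gene expression within each cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    CohortAnnotation,
    ExpressionMatrix,
    ValidationError,
    canonical_symbol,
)
from .stats import bonferroni, mann_whitney_u, pearson_with_p

__all__ = [
    "RegulatorSet",
    "RatioProfile",
    "compare_regulators",
    "ratio_score",
    "ratio_target_correlation",
]


@dataclass
class RegulatorSet:
    """Genes grouped by regulatory role; the role sets must be disjoint."""

    receptors: tuple[str, ...] = ("NR1H3", "NR1H2", "ESR1", "PGR")
    corepressors: tuple[str, ...] = ("NCOR1", "NCOR2", "LCOR")
    coactivators: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.receptors = tuple(canonical_symbol(g) for g in self.receptors)
        self.corepressors = tuple(canonical_symbol(g) for g in self.corepressors)
        self.coactivators = tuple(canonical_symbol(g) for g in self.coactivators)
        roles = [set(self.receptors), set(self.corepressors), set(self.coactivators)]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = roles[i] & roles[j]
                if overlap:
                    raise ValidationError(f"regulator roles overlap on {sorted(overlap)}")

    @property
    def all_genes(self) -> list[str]:
        return list(self.receptors) + list(self.corepressors) + list(self.coactivators)

    def role_of(self, gene: str) -> str:
        g = canonical_symbol(gene)
        if g in self.receptors:
            return "receptor"
        if g in self.corepressors:
            return "corepressor"
        if g in self.coactivators:
            return "coactivator"
        raise KeyError(gene)


@dataclass
class RatioProfile:
    """Per-sample receptor-minus-corepressor log-expression score."""

    receptor: str
    corepressor: str
    scores: pd.Series  # index: sample_id; NaN where either gene is missing


def compare_regulators(
    expr: ExpressionMatrix,
    ann: CohortAnnotation,
    regs: RegulatorSet,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Mann-Whitney comparison of each regulator between the two cohorts.

    Returns one row per regulator with medians per cohort, U, raw and
    Bonferroni-adjusted p-values, and the direction of the shift.
    Regulators absent from the matrix get ``present=False`` rows with NaN
    statistics and do not enter the Bonferroni family (unless
    ``family_size`` overrides it).
    """
    cohorts = ann.cohorts
    if len(cohorts) != 2:
        raise ValidationError(f"exactly two cohorts required, found {cohorts}")
    a_lab, b_lab = cohorts

    common = [s for s in ann.labels.index if s in set(expr.sample_ids)]
    if not common:
        raise ValidationError("no overlap between annotation and expression samples")

    col_of = {s: i for i, s in enumerate(expr.sample_ids)}
    idx_a = [col_of[s] for s in ann.samples(a_lab) if s in col_of]
    idx_b = [col_of[s] for s in ann.samples(b_lab) if s in col_of]

    rows = []
    for gene in regs.all_genes:
        role = regs.role_of(gene)
        if gene not in expr:
            rows.append(
                dict(gene=gene, role=role, present=False,
                     **{f"median_{a_lab}": np.nan, f"median_{b_lab}": np.nan},
                     U=np.nan, p_raw=np.nan, p_adj=np.nan, direction="absent")
            )
            continue
        vals = expr.gene_values(gene)
        xa = vals[idx_a]
        xb = vals[idx_b]
        xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
        U, p = mann_whitney_u(xa, xb)
        med_a, med_b = float(np.median(xa)), float(np.median(xb))
        direction = (
            f"{a_lab}>{b_lab}" if med_a > med_b
            else f"{a_lab}<{b_lab}" if med_a < med_b else "equal"
        )
        rows.append(
            dict(gene=gene, role=role, present=True,
                 **{f"median_{a_lab}": med_a, f"median_{b_lab}": med_b},
                 U=U, p_raw=p, p_adj=np.nan, direction=direction)
        )
    out = pd.DataFrame(rows)
    tested = out["present"]
    m = family_size if family_size is not None else int(tested.sum())
    if tested.any():
        out.loc[tested, "p_adj"] = bonferroni(out.loc[tested, "p_raw"].to_numpy(), m=m)
    return out


def ratio_score(
    expr: ExpressionMatrix, receptor: str, corepressor: str
) -> RatioProfile:
    """Per-sample log-ratio score: log-expression(receptor) - log-expression(corepressor).

    Defined only where both genes are observed; other samples get NaN.
    On already-log-scale (possibly median-centered) matrices this is the
    log of the linear expression ratio and is invariant to adding a common
    constant to both genes.
    """
    rec, cor = canonical_symbol(receptor), canonical_symbol(corepressor)
    for g in (rec, cor):
        if g not in expr:
            raise ValidationError(f"gene {g!r} absent from expression matrix")
    score = expr.data.loc[rec] - expr.data.loc[cor]
    return RatioProfile(receptor=rec, corepressor=cor, scores=score)


def ratio_target_correlation(
    profile: RatioProfile,
    expr: ExpressionMatrix,
    target: str,
    ann: CohortAnnotation,
) -> pd.DataFrame:
    """Pearson correlation of a ratio profile with a target gene per cohort.

    Returns a frame indexed by cohort label with columns r, p, n_used.
    """
    tgt = canonical_symbol(target)
    if tgt not in expr:
        raise ValidationError(f"target gene {tgt!r} absent from expression matrix")
    y = expr.data.loc[tgt]
    rows = {}
    for label in ann.cohorts:
        samples = [s for s in ann.samples(label) if s in profile.scores.index]
        xs = profile.scores[samples].to_numpy()
        ys = y[samples].to_numpy()
        r, p = pearson_with_p(xs, ys)
        n_used = int((np.isfinite(xs) & np.isfinite(ys)).sum())
        rows[label] = dict(r=r, p=p, n_used=n_used)
    return pd.DataFrame.from_dict(rows, orient="index")
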