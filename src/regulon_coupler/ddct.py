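"""Relative quantification of qPCR data by the ddCt (2^-ddCt) method.

Replicate Ct values are averaged per (condition, gene) before
differencing; the target is normalised to a housekeeping gene within each
condition (dCt), conditions are contrasted against a reference condition
(ddCt), and the fold change is 2^-ddCt assuming perfect per-cycle doubling.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ValidationError, canonical_symbol

__all__ = ["CtTable", "read_ct_table", "ddct_fold_change", "ddct_table"]


@dataclass
class CtTable:
    """Long-format qPCR cycle-threshold measurements.

    ``data`` columns: sample_id, condition, gene, ct.  Ct values must be
    finite and positive.  ``housekeeping`` names the normaliser gene.
    """

    data: pd.DataFrame
    housekeeping: str

    def __post_init__(self) -> None:
        df = self.data.copy()
        required = ["sample_id", "condition", "gene", "ct"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"CtTable missing columns {missing}")
        df["gene"] = df["gene"].map(canonical_symbol)
        df["ct"] = df["ct"].astype(float)
        if not np.isfinite(df["ct"]).all() or (df["ct"] <= 0).any():
            raise ValidationError("Ct values must be finite and positive")
        self.data = df
        self.housekeeping = canonical_symbol(self.housekeeping)

    def mean_ct(self, condition: str, gene: str) -> float:
        """Replicate-averaged Ct for one (condition, gene) cell."""
        gene = canonical_symbol(gene)
        sel = self.data[
            (self.data["condition"] == condition) & (self.data["gene"] == gene)
        ]
        if sel.empty:
            raise ValidationError(f"no Ct value for condition {condition!r}, gene {gene!r}")
        return float(sel["ct"].mean())


def read_ct_table(
    path: str | os.PathLike, housekeeping: str, sep: str = "\t"
) -> CtTable:
    return CtTable(pd.read_csv(path, sep=sep), housekeeping=housekeeping)


def ddct_fold_change(
    table: CtTable, target: str, treated: str, reference: str
) -> float:
    """Fold change of ``target`` in ``treated`` relative to ``reference``.

    dCt = Ct_target - Ct_housekeeping per condition (replicates averaged
    first); ddCt = dCt_treated - dCt_reference; fold = 2^-ddCt.
    """
    dct_treated = table.mean_ct(treated, target) - table.mean_ct(treated, table.housekeeping)
    dct_reference = table.mean_ct(reference, target) - table.mean_ct(reference, table.housekeeping)
    ddct = dct_treated - dct_reference
    return float(2.0 ** (-ddct))


def ddct_table(table: CtTable, reference: str) -> pd.DataFrame:
    """Fold changes for every (gene, condition) pair against ``reference``.

    The housekeeping gene itself is excluded from the output.
    """
    genes = sorted(g for g in table.data["gene"].unique() if g != table.housekeeping)
    conditions = [c for c in table.data["condition"].unique() if c != reference]
    rows = []
    for gene in genes:
        for cond in conditions:
            rows.append(
                dict(gene=gene, condition=cond, reference=reference,
                     fold_change=ddct_fold_change(table, gene, cond, reference))
            )
    return pd.DataFrame(rows, columns=["gene", "condition", "reference", "fold_change"])
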