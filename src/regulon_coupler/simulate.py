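"""Synthetic two-cohort expression data with corepressor-modulated TF coupling.

The generator emulates the geometry of a two-subtype tumour expression
study: a small cohort A (81 samples) and a larger cohort B (234 samples),
one transcription factor (TF), three co-regulated corepressors, a block of
true TF target genes and a block of uncoupled decoys, on a log scale with
optional per-gene median centering.

Generative model, per sample j:

* TF log-expression        ``x_j ~ Normal(mu_tf[cohort], sigma_tf)``
* corepressor c            ``z_cj = mu_cor[cohort] + sigma_cor * (sqrt(rho)*s_j + sqrt(1-rho)*e_cj)``
  with a shared standard-normal factor ``s_j`` (pairwise correlation
  ``rho_cor`` between corepressors; their marginals stay
  Normal(mu_cor, sigma_cor))
* repression index         ``r_j = mean_c z_cj``
* coupling weight          ``w_j = 1 / (1 + exp(-kappa * (x_j - r_j - theta)))``
* true target i            ``y_ij = beta_i * w_j * x_j + Normal(0, sigma_y)``,
  ``beta_i ~ Uniform(beta_range)``
* decoy                    ``y_ij ~ Normal(0, sigma_y)``

The logistic weight is the simplest monotone map from the TF-to-corepressor
log-ratio to a coupling strength in [0, 1]: cohorts where corepressors
outweigh the TF sit on the flat low shoulder (targets decoupled), cohorts
where the TF dominates sit near 1 (targets strongly coupled).

A companion generator emits ChIP-Seq-style binding-score tables (seven
datasets in five replicate groups, two of them mouse), an ortholog map with
a configurable number of unmappable mouse genes, extra high-scoring genes
withheld from the expression matrix, and a canonical-target list, so the
whole panel-building pipeline can run without any external download.

All randomness flows through one seeded :func:`numpy.random.default_rng`
(PCG64) in a fixed draw order, so a given seed reproduces every artifact
bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    BindingScoreTable,
    CohortAnnotation,
    ExpressionMatrix,
    GeneList,
    OrthologMap,
    ValidationError,
    median_center,
    write_annotation,
    write_expression_matrix,
    write_gene_list,
    write_ortholog_map,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "simulate_cohorts",
    "simulate_binding_tables",
    "write_fixture",
]

COHORT_A = "ERneg"
COHORT_B = "ERpos"
TF_GENE = "NR1H3"
COREPRESSOR_GENES = ("NCOR1", "NCOR2", "LCOR")


@dataclass
class SyntheticConfig:
    """All generative-model parameters (log-expression units throughout).

    Defaults mirror the emulated study: cohort sizes 81 and 234, 135 true
    targets plus 865 decoys, a TF expressed slightly higher in cohort A and
    corepressors expressed much higher in cohort B, so cohort A is
    de-repressed (coupling weight near 1) and cohort B repressed (weight
    near 0, modulated by corepressor load).  Effect sizes were calibrated
    once so the default scenario reproduces the qualitative count asymmetry
    of the emulated study, not its exact counts.
    """

    n_A: int = 81
    n_B: int = 234
    n_targets: int = 135
    n_decoys: int = 865
    mu_tf_A: float = 1.2
    mu_tf_B: float = 0.8
    sigma_tf: float = 1.0
    mu_cor_A: float = 0.0
    mu_cor_B: float = 2.6
    sigma_cor: float = 1.0
    rho_cor: float = 0.9
    beta_range: tuple[float, float] = (0.15, 0.5)
    kappa: float = 4.0
    theta: float = 0.0
    sigma_y: float = 1.0
    seed: int = 0
    center: bool = True
    n_canonical: int = 24

    def __post_init__(self) -> None:
        if min(self.n_A, self.n_B) < 3:
            raise ValidationError("cohort sizes must be >= 3")
        if self.n_targets < 1 or self.n_decoys < 0:
            raise ValidationError("n_targets must be >= 1 and n_decoys >= 0")
        for name in ("sigma_tf", "sigma_cor", "sigma_y"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.rho_cor <= 1.0:
            raise ValidationError("rho_cor must lie in [0, 1]")
        lo, hi = self.beta_range
        if lo > hi:
            raise ValidationError("beta_range must be (low, high) with low <= high")
        if not 0 <= self.n_canonical <= self.n_targets:
            raise ValidationError("n_canonical must lie in [0, n_targets]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["beta_range"] = list(d["beta_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "beta_range" in d:
            d["beta_range"] = tuple(d["beta_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator actually did: per-gene coupling and per-sample weights."""

    is_target: pd.Series        # gene -> bool (decoys and regulators False)
    beta: pd.Series             # gene -> coupling magnitude (0 for decoys)
    coupling_weight: pd.Series  # sample -> w_j
    cohort: pd.Series           # sample -> label
    target_genes: list[str] = field(default_factory=list)
    canonical_genes: list[str] = field(default_factory=list)
    decoy_genes: list[str] = field(default_factory=list)


def _gene_names(cfg: SyntheticConfig) -> tuple[list[str], list[str]]:
    targets = [f"TG{i + 1:03d}" for i in range(cfg.n_targets)]
    decoys = [f"DC{i + 1:03d}" for i in range(cfg.n_decoys)]
    return targets, decoys


def simulate_cohorts(
    cfg: SyntheticConfig,
) -> tuple[ExpressionMatrix, CohortAnnotation, GroundTruth]:
    """Draw one synthetic two-cohort expression matrix.

    Row order: TF, the three corepressors, targets, decoys.  With
    ``cfg.center`` the matrix is per-gene median-centered over all samples
    (the convention of array-median-centered public expression extracts);
    centering shifts each gene by a constant and leaves within-cohort
    correlations and between-cohort rank statistics unchanged.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_A + cfg.n_B
    cohort = np.array([COHORT_A] * cfg.n_A + [COHORT_B] * cfg.n_B)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    mu_tf = np.where(cohort == COHORT_A, cfg.mu_tf_A, cfg.mu_tf_B)
    mu_cor = np.where(cohort == COHORT_A, cfg.mu_cor_A, cfg.mu_cor_B)

    # documented draw order: TF, shared corepressor factor, corepressor noise,
    # betas, target noise, decoy noise
    x = rng.normal(mu_tf, cfg.sigma_tf)
    shared = rng.normal(0.0, 1.0, size=n)
    eps = rng.normal(0.0, 1.0, size=(len(COREPRESSOR_GENES), n))
    z = mu_cor + cfg.sigma_cor * (
        np.sqrt(cfg.rho_cor) * shared + np.sqrt(1.0 - cfg.rho_cor) * eps
    )
    r = z.mean(axis=0)
    with np.errstate(over="ignore"):
        w = 1.0 / (1.0 + np.exp(-cfg.kappa * (x - r - cfg.theta)))

    betas = rng.uniform(*cfg.beta_range, size=cfg.n_targets)
    targets_mat = betas[:, None] * w[None, :] * x[None, :] + rng.normal(
        0.0, cfg.sigma_y, size=(cfg.n_targets, n)
    )
    decoys_mat = rng.normal(0.0, cfg.sigma_y, size=(cfg.n_decoys, n))

    target_names, decoy_names = _gene_names(cfg)
    genes = [TF_GENE, *COREPRESSOR_GENES, *target_names, *decoy_names]
    values = np.vstack([x[None, :], z, targets_mat, decoys_mat])
    mat = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=sample_ids))
    if cfg.center:
        mat = median_center(mat)

    ann = CohortAnnotation(pd.Series(cohort, index=sample_ids))
    beta_series = pd.Series(0.0, index=genes)
    beta_series[target_names] = betas
    is_target = pd.Series(False, index=genes)
    is_target[target_names] = True
    canonical = target_names[cfg.n_targets - cfg.n_canonical:]
    truth = GroundTruth(
        is_target=is_target,
        beta=beta_series,
        coupling_weight=pd.Series(w, index=sample_ids),
        cohort=pd.Series(cohort, index=sample_ids),
        target_genes=target_names,
        canonical_genes=canonical,
        decoy_genes=decoy_names,
    )
    return mat, ann, truth


# ---------------------------------------------------------------------------
# binding-score fixture


def simulate_binding_tables(
    cfg: SyntheticConfig,
    truth: GroundTruth,
    n_no_ortholog: int = 11,
    n_not_expressed: int = 26,
    top_k: int = 100,
) -> tuple[list[BindingScoreTable], OrthologMap, GeneList]:
    """Binding-score tables + ortholog map + canonical list for panel building.

    Seven datasets in five replicate groups (two mouse singletons, two
    duplicated human time-course groups, one human singleton).  By
    construction, running the default fixture through the panel builder
    with ``top_k`` and membership >= 2 yields:

    * the non-canonical true targets appearing in >= 2 post-averaging lists,
    * ``n_no_ortholog`` mouse-only genes without ortholog entries (dropped),
    * ``n_not_expressed`` human genes absent from the expression matrix
      (dropped),
    * the ``cfg.n_canonical`` canonical targets kept out of every top-k list
      (they only enter through the canonical union).

    Raises if the gene pools are too small for the requested geometry.
    """
    rng = np.random.default_rng(cfg.seed + 1)  # independent of the expression draw
    n_core = cfg.n_targets - cfg.n_canonical
    core = truth.target_genes[:n_core]
    if n_core < 1:
        raise ValidationError("no non-canonical targets to place in binding lists")

    nx_genes = [f"NX{i + 1:03d}" for i in range(n_not_expressed)]
    mmx_genes = [f"MMX{i + 1:03d}" for i in range(n_no_ortholog)]

    # candidates needing membership >= 2 via the three human lists
    candidates = core + nx_genes
    human_ids = ["crc_2h", "crc_48h", "adipocyte"]
    pairs = [(0, 1), (0, 2), (1, 2)]
    human_members: dict[str, list[str]] = {d: [] for d in human_ids}
    for i, gene in enumerate(candidates):
        for j in pairs[i % 3]:
            human_members[human_ids[j]].append(gene)
    for d, members in human_members.items():
        if len(members) > top_k:
            raise ValidationError(
                f"human list {d} needs {len(members)} slots but top_k={top_k}"
            )

    # mouse lists: the unmappable genes in both (membership 2), plus mapped
    # mouse aliases of some core targets for cross-species corroboration
    mouse_ids = ["mono_veh", "mono_gw"]
    n_alias = min(40, n_core // 2)
    alias_of = {f"MM{g}": g for g in core[: 2 * n_alias]}
    mouse_members = {
        "mono_veh": mmx_genes + [f"MM{g}" for g in core[:n_alias]],
        "mono_gw": mmx_genes + [f"MM{g}" for g in core[n_alias: 2 * n_alias]],
    }

    # single-list fillers (membership 1 -> excluded): human fillers come from
    # the decoy pool, mouse fillers are aliases of further decoys
    decoy_pool = list(truth.decoy_genes)
    fill_map: dict[str, str] = {}
    pool_pos = 0

    def take_decoys(k: int) -> list[str]:
        nonlocal pool_pos
        if pool_pos + k > len(decoy_pool):
            raise ValidationError("decoy pool exhausted while padding binding lists")
        out = decoy_pool[pool_pos: pool_pos + k]
        pool_pos += k
        return out

    for d in human_ids:
        pad = take_decoys(top_k - len(human_members[d]))
        human_members[d] = human_members[d] + pad
    for d in mouse_ids:
        pad = [f"MM{g}" for g in take_decoys(top_k - len(mouse_members[d]))]
        for alias in pad:
            fill_map[alias] = alias[2:]
        mouse_members[d] = mouse_members[d] + pad

    group_of = {
        "mono_veh": ("mono_veh", "mouse", 1),
        "mono_gw": ("mono_gw", "mouse", 1),
        "crc_2h": ("crc_2h", "human", 2),
        "crc_48h": ("crc_48h", "human", 2),
        "adipocyte": ("adipocyte", "human", 1),
    }
    tables: list[BindingScoreTable] = []
    for list_id, members in {**mouse_members, **human_members}.items():
        group, species, n_rep = group_of[list_id]
        # descending intended scores; low-scoring padding beyond the top-k
        base = np.linspace(100.0, 50.0, num=len(members))
        # low-scoring padding beyond the top-k; never selected, and (for the
        # mouse lists) deliberately left out of the ortholog map — they are
        # single-list genes, excluded by membership before the ortholog step
        extra = [f"LX{list_id.upper()}{i:03d}" for i in range(50)]
        extra_scores = np.linspace(5.0, 1.0, num=len(extra))
        for rep in range(n_rep):
            jitter = rng.normal(0.0, 0.5, size=len(members))
            scores = pd.Series(
                np.concatenate([base + jitter, extra_scores]),
                index=members + extra,
            )
            dataset_id = list_id if n_rep == 1 else f"{list_id}_r{rep + 1}"
            tables.append(
                BindingScoreTable(
                    dataset_id=dataset_id,
                    species=species,
                    replicate_group=group,
                    scores=scores,
                )
            )
    omap = OrthologMap({**alias_of, **fill_map})

    canonical = GeneList(truth.canonical_genes, label="canonical_targets")
    return tables, omap, canonical


def write_fixture(cfg: SyntheticConfig, outdir: str | os.PathLike) -> dict[str, str]:
    """Write the complete synthetic fixture to ``outdir``; returns the paths.

    Files: expression.tsv, annotation.tsv, manifest.tsv plus one score TSV
    per dataset, orthologs.tsv, canonical.txt, ground_truth.json.
    """
    os.makedirs(outdir, exist_ok=True)
    outdir = os.fspath(outdir)
    mat, ann, truth = simulate_cohorts(cfg)
    tables, omap, canonical = simulate_binding_tables(cfg, truth)

    paths = {
        "expression": os.path.join(outdir, "expression.tsv"),
        "annotation": os.path.join(outdir, "annotation.tsv"),
        "manifest": os.path.join(outdir, "manifest.tsv"),
        "orthologs": os.path.join(outdir, "orthologs.tsv"),
        "canonical": os.path.join(outdir, "canonical.txt"),
        "ground_truth": os.path.join(outdir, "ground_truth.json"),
    }
    write_expression_matrix(mat, paths["expression"])
    write_annotation(ann, paths["annotation"])
    write_ortholog_map(omap, paths["orthologs"])
    write_gene_list(canonical, paths["canonical"])

    rows = []
    for t in tables:
        fname = f"binding_{t.dataset_id}.tsv"
        t.scores.rename("score").rename_axis("gene").reset_index().to_csv(
            os.path.join(outdir, fname), sep="\t", index=False
        )
        rows.append(
            dict(dataset_id=t.dataset_id, species=t.species,
                 replicate_group=t.replicate_group, path=fname)
        )
    pd.DataFrame(rows).to_csv(paths["manifest"], sep="\t", index=False)

    gt = {
        "config": cfg.to_dict(),
        "target_genes": truth.target_genes,
        "canonical_genes": truth.canonical_genes,
        "beta": {g: float(truth.beta[g]) for g in truth.target_genes},
        "coupling_weight": {
            s: float(v) for s, v in truth.coupling_weight.items()
        },
    }
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(gt, fh, indent=1, sort_keys=True)
    return paths
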