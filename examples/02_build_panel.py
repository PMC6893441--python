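"""Build a consensus target panel from synthetic ChIP-Seq binding scores.

Seven binding-score tables (five replicate groups, two of them mouse) are
replicate-averaged; the top-100 genes of each averaged table are
corroborated across lists, translated through an ortholog map, filtered by
expression presence, and unioned with a canonical target list.
"""

from regulon_coupler import (
    PanelConfig,
    SyntheticConfig,
    average_replicates,
    build_panel,
    simulate_binding_tables,
    simulate_cohorts,
    top_k_genes,
)

cfg = SyntheticConfig(seed=1)
matrix, annotation, truth = simulate_cohorts(cfg)
tables, orthologs, canonical = simulate_binding_tables(cfg, truth)
print(f"{len(tables)} binding-score tables in "
      f"{len({t.replicate_group for t in tables})} replicate groups")

averaged = average_replicates(tables)
lists = [top_k_genes(t, 100) for t in averaged]
panel = build_panel(
    lists, [t.species for t in averaged], orthologs, matrix, canonical,
    PanelConfig(top_k=100, min_list_membership=2),
)
for key, value in panel.counts.items():
    print(f"{key:28s} {value}")

# Genes seen in only one top-100 list are discarded; multi-list genes are
# lost to missing orthologs or missing expression; the canonical targets
# join the panel unconditionally.  The final size is the filtered list
# plus the canonical additions.
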