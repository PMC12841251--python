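"""Threshold DEG calling and the set algebra behind shared/unique gene counts.

Builds a synthetic differential-expression table with 100 planted effects,
filters it at |log2FC| >= 1 and FDR <= 0.05, and shows the upset-style counts
plus directional consistency between two contrasts.
"""

import savor

table, planted = savor.gen_deg_table(n_genes=2000, n_de=100, seed=7)
res = savor.filter_degs(table, lfc_min=1.0, fdr_max=0.05)
print(f"kept {res.n_kept} DEGs ({res.n_up} up, {res.n_down} down); "
      f"{len(planted & set(res.table['gene_id']))}/100 planted genes recovered")

# shared/unique detected genes across three treatment groups
sets = {
    "ICE": set(table["gene_id"][:1500]),
    "LTA": set(table["gene_id"][300:1800]),
    "LT": set(table["gene_id"][600:2000]),
}
summary = savor.detected_gene_upset(sets)
print("detected in all groups:", summary.all_shared)
print("exclusive per group:", summary.exclusive)

# directional consistency of DEGs shared by two contrasts
other, _ = savor.gen_deg_table(n_genes=2000, n_de=100, seed=8)
shared = res.table["gene_id"].tolist()[:50]
consistent, opposing = savor.shared_deg_consistency(table, other, shared)
print(f"of {len(shared)} shared genes: {consistent} same-sign, {opposing} opposing")
# Same-sign fold changes across two preservation methods point to a common
# transcriptional response; opposing signs flag treatment-specific genes.
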