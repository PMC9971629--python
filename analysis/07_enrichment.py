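"""Term enrichment of the DE-lncRNA target genes.

Study set = genes that are cis or trans targets of DE lncRNAs; background =
all genes with at least one term annotation; per-term hypergeometric
upper-tail p with BH correction. Writes results/enrichment/enrichment.tsv.
The generator preferentially annotates genes near planted DE lncRNAs with
TERM_drought, so that term should rank at or near the top.
"""

from _common import RESULTS, SEED, load

from lncnet import de as de_mod, enrichment, targets
from lncnet.io import write_table
from lncnet.pipeline import identify_stage

dataset, config = load()
out = RESULTS / "enrichment"

lengths = {m.transcript_id: m.spliced_length for m in dataset.models}
fpkm = de_mod.compute_fpkm(dataset.counts, lengths)
lnc_ids, *_ = identify_stage(dataset.models, dataset.sequences, fpkm, config)
nb = de_mod.nb_test(dataset.counts, config=config)
de_lnc = de_mod.call_de(nb.loc[sorted(lnc_ids)], "lncRNA", config)
de_lnc_ids = sorted(de_lnc.index[de_lnc.status != "ns"])

by_id = {m.transcript_id: m for m in dataset.models}
gene_models = [m for m in dataset.models if m.class_code == "="]
cis_pairs = targets.cis_targets([by_id[t] for t in de_lnc_ids], gene_models, config=config)
trans_pairs = targets.trans_targets(
    {t: dataset.sequences[t] for t in de_lnc_ids},
    {m.transcript_id: dataset.sequences[m.transcript_id] for m in gene_models},
    config,
)
gene_of = {m.transcript_id: m.gene_id for m in gene_models}
study = {p.gene_id for p in cis_pairs} | {gene_of[p.gene_id] for p in trans_pairs}
background = set().union(*dataset.term_map.values())
study &= background

results = enrichment.enrich(study, background, dataset.term_map, config)
table = enrichment.enrichment_table(results, config.enrich_top_n)
write_table(table, out / "enrichment.tsv")

top = table.iloc[0]
print(f"seed {SEED}: study {len(study)} target genes / background {len(background)}")
print(f"  top term: {top.term_id} (k={top.k}/{top.K}, p={top.p_value:.2e}, "
      f"FDR={top.fdr:.2e})")
print(f"  TERM_drought rank: "
      f"{int(table.index[table.term_id == 'TERM_drought'][0]) + 1 if (table.term_id == 'TERM_drought').any() else 'absent'}")
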