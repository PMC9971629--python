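"""Build the lncRNA-miRNA-mRNA ceRNA network and score it against truth.

Shared-miRNA hypergeometric test over DE lncRNA x DE mRNA pairs, strict
shared-count > 3, p < 0.05, FDR < 0.1, positive lncRNA-mRNA correlation.
Writes results/cerna/ (triplets, nodes, edges, GraphML) and reports recall
and precision on the planted triplets vs decoys.
"""

from _common import RESULTS, SEED, load

from lncnet import cerna as cerna_mod, de as de_mod
from lncnet.io import write_network, write_table
from lncnet.mimicry import find_mres
from lncnet.pipeline import identify_stage

dataset, config = load()
out = RESULTS / "cerna"

lengths = {m.transcript_id: m.spliced_length for m in dataset.models}
fpkm = de_mod.compute_fpkm(dataset.counts, lengths)
lnc_ids, *_ = identify_stage(dataset.models, dataset.sequences, fpkm, config)
nb = de_mod.nb_test(dataset.counts, config=config)
mrna_ids = sorted(m.transcript_id for m in dataset.models if m.class_code == "=")
de_lnc = de_mod.call_de(nb.loc[sorted(lnc_ids)], "lncRNA", config)
de_mrna = de_mod.call_de(nb.loc[mrna_ids], "mRNA", config)

scan = {t: dataset.sequences[t] for t in sorted(lnc_ids) + mrna_ids}
catalog = find_mres(scan, dataset.mirnas, config)
triplets, graph = cerna_mod.build_network(
    catalog,
    sorted(de_lnc.index[de_lnc.status != "ns"]),
    sorted(de_mrna.index[de_mrna.status != "ns"]),
    fpkm,
    config,
)
table = cerna_mod.triplets_table(triplets)
write_table(table, out / "cerna_triplets.tsv")
write_network(graph, out, prefix="cerna")

truth = dataset.truth.triplets
planted = set(
    zip(truth.loc[~truth.is_decoy, "lncrna_id"], truth.loc[~truth.is_decoy, "mrna_id"])
)
decoys = set(
    zip(truth.loc[truth.is_decoy, "lncrna_id"], truth.loc[truth.is_decoy, "mrna_id"])
)
found = set(zip(table.lncrna_id, table.mrna_id))
recall = len(planted & found) / len(planted) if planted else float("nan")
precision = len(planted & found) / len(found) if found else float("nan")
print(f"seed {SEED}: {len(table)} retained triplets, "
      f"{graph.number_of_nodes()} nodes / {graph.number_of_edges()} edges")
print(f"  recall on planted triplets: {recall:.0%}; precision: {precision:.0%}")
print(f"  decoys (sharing <= {config.cerna_min_shared - 1}) retained: "
      f"{len(decoys & found)}/{len(decoys)}")
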