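"""Predict cis and trans targets of the differentially expressed lncRNAs.

cis: genes within 100 kb of the lncRNA span. trans: best normalised duplex
energy (ndG) over sliding complementarity windows, cutoff -1.0. Writes
results/targets/ and reports recovery of the planted trans pairs.
"""

import pandas as pd
from _common import RESULTS, SEED, load

from lncnet import de as de_mod, targets
from lncnet.io import write_table
from lncnet.pipeline import identify_stage

dataset, config = load()
out = RESULTS / "targets"

lengths = {m.transcript_id: m.spliced_length for m in dataset.models}
fpkm = de_mod.compute_fpkm(dataset.counts, lengths)
lnc_ids, *_ = identify_stage(dataset.models, dataset.sequences, fpkm, config)
nb = de_mod.nb_test(dataset.counts, config=config)
de_lnc = de_mod.call_de(nb.loc[sorted(lnc_ids)], "lncRNA", config)
de_lnc_ids = sorted(de_lnc.index[de_lnc.status != "ns"])

by_id = {m.transcript_id: m for m in dataset.models}
gene_models = [m for m in dataset.models if m.class_code == "="]
cis_pairs = targets.cis_targets(
    [by_id[t] for t in de_lnc_ids], gene_models, config=config
)
cis_df = pd.DataFrame(
    [(p.lncrna_id, p.gene_id, p.distance_bp) for p in cis_pairs],
    columns=["lncrna_id", "gene_id", "distance_bp"],
)
write_table(cis_df, out / "cis_targets.tsv")

trans_pairs = targets.trans_targets(
    {t: dataset.sequences[t] for t in de_lnc_ids},
    {m.transcript_id: dataset.sequences[m.transcript_id] for m in gene_models},
    config,
)
trans_df = pd.DataFrame(
    [(p.lncrna_id, p.gene_id, p.ndg, p.site[0], p.site[1]) for p in trans_pairs],
    columns=["lncrna_id", "gene_id", "ndg", "site_start", "site_end"],
)
write_table(trans_df, out / "trans_targets.tsv")

truth = dataset.truth.trans
planted = set(zip(truth.lncrna_id, truth.mrna_id))
found = set(zip(trans_df.lncrna_id, trans_df.gene_id))
print(f"seed {SEED}: {len(cis_df)} cis pairs for {len(de_lnc_ids)} DE lncRNAs "
      f"(median distance {cis_df.distance_bp.median():.0f} bp)")
print(f"  {len(trans_df)} trans pairs; planted complementarity recovered "
      f"{len(planted & found)}/{len(planted)}")
print(f"  spurious trans pairs: {len(found - planted)}")
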