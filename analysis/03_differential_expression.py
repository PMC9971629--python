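"""Differential expression DR vs CK for lncRNAs and mRNAs.

Median-of-ratios normalisation on the full count matrix, NB Wald tests,
then the study's calling rules (lncRNA: p < 0.05, mRNA: FDR < 0.05, both
with |log2FC| >= 1). Writes results/de/ and reports planted-effect recovery.
"""

from _common import RESULTS, SEED, load

from lncnet import de as de_mod
from lncnet.io import write_table
from lncnet.pipeline import identify_stage

dataset, config = load()
out = RESULTS / "de"

lengths = {m.transcript_id: m.spliced_length for m in dataset.models}
fpkm = de_mod.compute_fpkm(dataset.counts, lengths)
lnc_ids, *_ = identify_stage(dataset.models, dataset.sequences, fpkm, config)
mrna_ids = sorted(m.transcript_id for m in dataset.models if m.class_code == "=")

size_factors = de_mod.size_factors_median_ratio(dataset.counts)
nb = de_mod.nb_test(dataset.counts, size_factors, config)
de_lnc = de_mod.call_de(nb.loc[sorted(lnc_ids)], "lncRNA", config)
de_mrna = de_mod.call_de(nb.loc[mrna_ids], "mRNA", config)
for name, df in (("de_lncrna", de_lnc), ("de_mrna", de_mrna)):
    dump = df.copy()
    dump.insert(0, "feature_id", dump.index)
    write_table(dump, out / f"{name}.tsv")

truth = dataset.truth.de
called = set(de_lnc.index[de_lnc.status != "ns"]) | set(
    de_mrna.index[de_mrna.status != "ns"]
)
for lfc in (2.0, 4.0, 13.0):
    planted = set(truth.loc[truth.log2fc.abs() == lfc, "feature_id"])
    rec = len(planted & called) / len(planted) if planted else float("nan")
    print(f"  |log2FC|={lfc:g}: recovered {len(planted & called)}/{len(planted)} "
          f"({rec:.0%})")
null_feats = (
    set(dataset.counts.values.index) - set(truth.feature_id)
)
fp = len(null_feats & called)
print(f"seed {SEED}: {int((de_lnc.status != 'ns').sum())} DE lncRNAs "
      f"({int((de_lnc.status == 'up').sum())} up / "
      f"{int((de_lnc.status == 'down').sum())} down), "
      f"{int((de_mrna.status != 'ns').sum())} DE mRNAs")
print(f"  false positives among {len(null_feats)} null features: {fp}")
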