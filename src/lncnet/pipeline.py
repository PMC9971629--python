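"""End-to-end orchestration: simulate -> identify -> DE -> targets -> mimicry
-> ceRNA network -> enrichment, writing one TSV per stage.

Each stage is a thin wrapper over the corresponding module so the analysis
drivers, the CLI and the test suite all run the same code paths. The
coding-potential consensus runs the built-in ORF scorer at three
stringencies (100 / 110 / 120 codons) as the three-tool stand-in; externally
produced call tables can replace them via ``identify_stage(calls=...)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cerna as cerna_mod
from . import de as de_mod
from . import discovery, enrichment, io as lio, targets
from .config import RunConfig
from .mimicry import find_mres
from .simulate import SimulatedDataset, SimulationSpec, simulate_dataset, write_dataset
from .types import ExpressionMatrix, MRESite, TranscriptModel

STUB_TOOLS = (("orfscan_strict", 100), ("orfscan", 110), ("orfscan_lenient", 120))


@dataclass
class PipelineResult:
    lncrna_ids: set[str] = field(default_factory=set)
    lncrna_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    venn_tools: dict = field(default_factory=dict)
    venn_groups: tuple = ()
    summary: dict = field(default_factory=dict)
    fpkm: ExpressionMatrix | None = None
    de_lnc: pd.DataFrame = field(default_factory=pd.DataFrame)
    de_mrna: pd.DataFrame = field(default_factory=pd.DataFrame)
    cis: pd.DataFrame = field(default_factory=pd.DataFrame)
    trans: pd.DataFrame = field(default_factory=pd.DataFrame)
    mres: list[MRESite] = field(default_factory=list)
    triplets: pd.DataFrame = field(default_factory=pd.DataFrame)
    graph: object = None
    enrich: pd.DataFrame = field(default_factory=pd.DataFrame)


def stub_calls(
    sequences: dict[str, str], config: RunConfig
) -> list[discovery.CodingPotentialCall]:
    """Three-stringency ORF-scorer call table for the consensus step."""
    calls = []
    for tid in sorted(sequences):
        score = discovery.longest_orf_codons(sequences[tid])
        for tool, cutoff in STUB_TOOLS:
            calls.append(
                discovery.CodingPotentialCall(tid, tool, score < cutoff, float(score))
            )
    return calls


def identify_stage(
    models: list[TranscriptModel],
    sequences: dict[str, str],
    fpkm: ExpressionMatrix,
    config: RunConfig,
    calls: list[discovery.CodingPotentialCall] | None = None,
) -> tuple[set[str], pd.DataFrame, dict, pd.DataFrame]:
    """Basic screen + coding-potential consensus; returns the lncRNA id set,
    the per-lncRNA table, the tool Venn counts, and the screen log."""
    candidates, screen_log = discovery.basic_screen(models, fpkm, config)
    cand_seqs = {t.transcript_id: sequences[t.transcript_id] for t in candidates}
    if calls is None:
        calls = stub_calls(cand_seqs, config)
    else:
        cand_ids = set(cand_seqs)
        calls = [c for c in calls if c.transcript_id in cand_ids]
    tools = sorted({c.tool_name for c in calls})
    retained_ids, venn = discovery.consensus_noncoding(calls, tools)
    retained = [t for t in candidates if t.transcript_id in retained_ids]
    records = discovery.make_records(retained, fpkm)
    table = pd.DataFrame(
        [
            (r.transcript_id, r.category, r.length_nt, r.n_exons, r.max_fpkm)
            for r in records
        ],
        columns=["transcript_id", "category", "length_nt", "n_exons", "max_fpkm"],
    ).sort_values("transcript_id", ignore_index=True)
    return retained_ids, table, venn, screen_log


def run_all(
    spec: SimulationSpec | None = None,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
    dataset: SimulatedDataset | None = None,
) -> PipelineResult:
    """Run the whole analysis on a (simulated) dataset; write tables when
    ``outdir`` is given."""
    config = config or RunConfig()
    if dataset is None:
        spec = spec or SimulationSpec(rng_seed=config.rng_seed)
        dataset = simulate_dataset(spec)
    models = dataset.models
    seqs = dataset.sequences
    res = PipelineResult()

    lengths = {m.transcript_id: m.spliced_length for m in models}
    res.fpkm = de_mod.compute_fpkm(dataset.counts, lengths)

    # --- identification
    res.lncrna_ids, res.lncrna_table, res.venn_tools, screen_log = identify_stage(
        models, seqs, res.fpkm, config
    )
    records = discovery.make_records(
        [m for m in models if m.transcript_id in res.lncrna_ids], res.fpkm
    )
    res.summary = discovery.summarize_lncrnas(records) if records else {}
    lnc_fpkm = ExpressionMatrix(
        res.fpkm.values.loc[sorted(res.lncrna_ids)], dict(res.fpkm.groups), "fpkm"
    )
    res.venn_groups = discovery.group_presence_venn(lnc_fpkm, config)

    # --- differential expression (normalised on the full matrix)
    size_factors = de_mod.size_factors_median_ratio(dataset.counts)
    nb = de_mod.nb_test(dataset.counts, size_factors, config)
    mrna_ids = sorted(m.transcript_id for m in models if m.class_code == "=")
    res.de_lnc = de_mod.call_de(nb.loc[sorted(res.lncrna_ids)], "lncRNA", config)
    res.de_mrna = de_mod.call_de(nb.loc[mrna_ids], "mRNA", config)
    de_lnc_ids = sorted(res.de_lnc.index[res.de_lnc.status != "ns"])
    de_mrna_ids = sorted(res.de_mrna.index[res.de_mrna.status != "ns"])

    # --- target prediction for the DE lncRNAs
    by_id = {m.transcript_id: m for m in models}
    de_lnc_models = [by_id[t] for t in de_lnc_ids]
    gene_models = [m for m in models if m.class_code == "="]
    cis_pairs = targets.cis_targets(de_lnc_models, gene_models, config=config)
    res.cis = pd.DataFrame(
        [(p.lncrna_id, p.gene_id, p.distance_bp) for p in cis_pairs],
        columns=["lncrna_id", "gene_id", "distance_bp"],
    )
    trans_pairs = targets.trans_targets(
        {t: seqs[t] for t in de_lnc_ids},
        {m.transcript_id: seqs[m.transcript_id] for m in gene_models},
        config,
    )
    res.trans = pd.DataFrame(
        [(p.lncrna_id, p.gene_id, p.ndg, p.site[0], p.site[1]) for p in trans_pairs],
        columns=["lncrna_id", "gene_id", "ndg", "site_start", "site_end"],
    )

    # --- MRE scan over identified lncRNAs and all mRNAs
    scan_seqs = {t: seqs[t] for t in sorted(res.lncrna_ids)}
    scan_seqs.update({m.transcript_id: seqs[m.transcript_id] for m in gene_models})
    res.mres = find_mres(scan_seqs, dataset.mirnas, config)

    # --- ceRNA network
    triplets, graph = cerna_mod.build_network(
        res.mres, de_lnc_ids, de_mrna_ids, res.fpkm, config
    )
    res.triplets = cerna_mod.triplets_table(triplets)
    res.graph = graph

    # --- enrichment of DE-lncRNA target genes
    gene_of = {m.transcript_id: m.gene_id for m in gene_models}
    study = {gene_of[t] for t in res.trans.gene_id if t in gene_of}
    study |= set(res.cis.gene_id)
    background = set().union(*dataset.term_map.values()) if dataset.term_map else set()
    study &= background
    if study and background:
        enr = enrichment.enrich(study, background, dataset.term_map, config)
        res.enrich = enrichment.enrichment_table(enr)
    if outdir is not None:
        _write_results(res, screen_log, dataset, Path(outdir))
    return res


def _write_results(
    res: PipelineResult,
    screen_log: pd.DataFrame,
    dataset: SimulatedDataset,
    outdir: Path,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_dataset(dataset, outdir / "sim")
    lio.write_table(res.lncrna_table, outdir / "lncrna_table.tsv")
    lio.write_table(screen_log, outdir / "screen_log.tsv")
    venn = pd.DataFrame(
        sorted(("+".join(sorted(k)), v) for k, v in res.venn_tools.items()),
        columns=["tool_set", "n_transcripts"],
    )
    lio.write_table(venn, outdir / "venn_tools.tsv")
    shared, ck_only, dr_only = res.venn_groups
    gv = pd.DataFrame(
        [("shared", len(shared)), ("CK_only", len(ck_only)), ("DR_only", len(dr_only))],
        columns=["region", "n_lncrnas"],
    )
    lio.write_table(gv, outdir / "venn_groups.tsv")
    for name, series in res.summary.items():
        lio.write_table(
            series.rename("value").rename_axis("key").reset_index(),
            outdir / f"summary_{name}.tsv",
        )
    for name, df in (("de_lncrna", res.de_lnc), ("de_mrna", res.de_mrna)):
        out = df.copy()
        out.insert(0, "feature_id", out.index)
        lio.write_table(out, outdir / f"{name}.tsv")
    lio.write_table(res.cis, outdir / "cis_targets.tsv")
    lio.write_table(res.trans, outdir / "trans_targets.tsv")
    mre_df = pd.DataFrame(
        [
            (s.molecule_id, s.mirna_id, s.start, s.end, s.penalty_score, s.kind)
            for s in res.mres
        ],
        columns=["molecule_id", "mirna_id", "start", "end", "penalty_score", "kind"],
    ).sort_values(["molecule_id", "mirna_id", "start"], ignore_index=True)
    lio.write_table(mre_df, outdir / "mres.tsv")
    lio.write_table(res.triplets, outdir / "cerna_triplets.tsv")
    if res.graph is not None:
        lio.write_network(res.graph, outdir, prefix="cerna")
    lio.write_table(res.enrich, outdir / "enrichment.tsv")
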