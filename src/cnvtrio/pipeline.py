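"""End-to-end orchestration of the four filter layers.

Stages compose on disk through canonical TSVs, so running the subcommands
one at a time over intermediate files is bit-identical to a single
``run_pipeline`` call.  Every stage logs its input/output call counts to the
run log (stage name and counts only — no timestamps, so reruns under the
same configuration produce byte-identical output files), and call counts
are asserted non-increasing across filter stages.

Stage order: parse -> de novo / control filter -> replication + veto ->
merge -> knowledge-base annotation -> carrier permutation test ->
expression contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from . import stats as stats_mod
from .annotate import annotate_regions, dgv_novel_de_novo
from .expression import compare_expression, housekeeping_normalize
from .io_formats import (
    Pedigree,
    read_calls,
    read_calls_canonical,
    read_expression,
    read_knowledge_base,
    read_pedigree,
    read_regions,
    read_trace,
    write_calls_canonical,
    write_regions,
    write_trace,
)
from .replication import (
    attach_supporting_calls,
    filter_by_replication,
    merge_recurrent,
)
from .trio_filter import FilterTrace, classify_cohort

logger = logging.getLogger("cnvtrio")

DIALECT_OF = {
    "discovery": "xcnv",
    "rep_wes": "xcnv",
    "rep_array": "rawcnv",
    "rep_wgs": "svbed",
}


@dataclass
class PipelineConfig:
    """Inputs, matching thresholds, and output location for one run."""

    calls: dict[str, str]  # dataset -> call file in its dialect
    pedigree: str
    chd_bed: str
    dgv_bed: str
    genes_bed: str
    expressed_list: str
    expression: Optional[str] = None
    tissues: Optional[str] = None
    rho: float = 0.5  # de novo / control matching reciprocal overlap
    rho_rep: float = 0.25  # replication matching reciprocal overlap
    f_kb: float = 0.5  # knowledge-base one-way coverage fraction
    n_perm: int = 10_000
    seed: int = 0
    invert_criterion2: bool = False
    build: str = "unspecified"
    out_dir: str = "cnvtrio_out"

    def validate(self) -> None:
        for name, v in (("rho", self.rho), ("rho_rep", self.rho_rep),
                        ("f_kb", self.f_kb)):
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.n_perm < 1_000:
            raise ValueError("n_perm must be >= 1,000 for the test stage")


class StageError(RuntimeError):
    """A stage's contract was violated; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _out(config: PipelineConfig, name: str) -> str:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return str(out / name)


def stage_filter_denovo(config: PipelineConfig, pedigree: Pedigree) -> dict[str, int]:
    """Layer 1: parse discovery calls, certify de novo, drop control-matched.

    Writes ``denovo_calls.tsv`` (canonical) and ``trace_denovo.tsv``.
    """
    trace = FilterTrace()
    parsed = read_calls(
        config.calls["discovery"], DIALECT_OF["discovery"], "discovery", pedigree
    )
    for rej in parsed.rejected:
        trace.add(f"discovery:line{rej.lineno}", "parse", "drop", rej.reason)
    n_proband = sum(1 for c in parsed.calls if c.role == "proband")
    survivors, _verdicts = classify_cohort(
        parsed.calls, pedigree, rho=config.rho, cohort="discovery", trace=trace
    )
    trace.check_consistency()
    write_calls_canonical(survivors, _out(config, "denovo_calls.tsv"))
    write_trace(trace, _out(config, "trace_denovo.tsv"))
    return {
        "parsed_discovery": len(parsed.calls),
        "proband_calls": n_proband,
        "de_novo_survivors": len(survivors),
    }


def stage_replicate(config: PipelineConfig, pedigree: Pedigree) -> dict[str, int]:
    """Layer 2: replication support/veto matching, then recurrent-region merge.

    Reads ``denovo_calls.tsv``; writes ``regions_raw.tsv`` and
    ``trace_replicate.tsv``.
    """
    survivors = read_calls_canonical(_out(config, "denovo_calls.tsv"))
    replication = {}
    trace = FilterTrace()
    for dataset in ("rep_wes", "rep_array", "rep_wgs"):
        parsed = read_calls(
            config.calls[dataset], DIALECT_OF[dataset], dataset, pedigree
        )
        replication[dataset] = parsed.calls
    replicated, evidence = filter_by_replication(
        survivors, replication, config.rho_rep, trace
    )
    if len(replicated) > len(survivors):
        raise StageError("replicate", "call count increased across a filter stage")
    de_novo_ids = {c.call_id for c in survivors}
    merged_input = attach_supporting_calls(replicated, evidence, replication)
    regions = merge_recurrent(merged_input, evidence, de_novo_ids)
    n_members = sum(len(r.member_call_ids) for r in regions)
    if n_members != len(merged_input):
        raise StageError(
            "replicate",
            f"region partition lost calls: {n_members} != {len(merged_input)}",
        )
    write_regions(regions, _out(config, "regions_raw.tsv"))
    write_trace(trace, _out(config, "trace_replicate.tsv"))
    return {
        "de_novo_survivors": len(survivors),
        "replicated": len(replicated),
        "regions": len(regions),
    }


def stage_annotate(config: PipelineConfig) -> dict[str, int]:
    """Layer 3: gene mapping, relevance flags, and the novel de novo list.

    Reads ``regions_raw.tsv``; writes ``regions_annotated.tsv`` and
    ``dgv_novel.tsv``.
    """
    regions = read_regions(_out(config, "regions_raw.tsv"))
    kb = read_knowledge_base(
        config.chd_bed, config.dgv_bed, config.genes_bed, config.expressed_list
    )
    annotate_regions(regions, kb, config.f_kb, config.invert_criterion2)
    novel = dgv_novel_de_novo(regions, kb, config.f_kb)
    write_regions(regions, _out(config, "regions_annotated.tsv"))
    write_regions(novel, _out(config, "dgv_novel.tsv"))
    return {
        "regions": len(regions),
        "relevant": sum(1 for r in regions if r.relevant),
        "dgv_novel_de_novo": len(novel),
    }


def stage_test(config: PipelineConfig, pedigree: Pedigree) -> dict[str, int]:
    """Carrier-asymmetry permutation test per region.

    Null denominators are the discovery + WES-replication probands vs family
    controls of the supplied pedigree.  Reads ``regions_annotated.tsv``;
    writes ``regions.tsv`` (the final region table).
    """
    regions = read_regions(_out(config, "regions_annotated.tsv"))
    n_case = len(pedigree.probands("discovery")) + len(pedigree.probands("rep_wes"))
    n_control = len(pedigree.controls("discovery")) + len(
        pedigree.controls("rep_wes")
    )
    stats_mod.test_regions(
        regions, n_case, n_control, config.n_perm, config.seed
    )
    write_regions(regions, _out(config, "regions.tsv"))
    return {"regions_tested": len(regions)}


def stage_express(config: PipelineConfig, pedigree: Pedigree) -> dict[str, int]:
    """Layer 4: carrier vs non-carrier expression contrasts for region genes.

    Reads ``regions.tsv`` plus the FPKM matrix; writes ``contrasts.tsv``.
    Regions without genes in the matrix, or without both groups in a tissue,
    contribute no contrast.
    """
    header = (
        "gene\ttissue\tn_carrier\tn_noncarrier\tmean_fpkm_carrier\t"
        "mean_fpkm_noncarrier\tlog2_fold_change\tp_value\tmethod\n"
    )
    path = _out(config, "contrasts.tsv")
    if config.expression is None or config.tissues is None:
        with open(path, "w") as fh:
            fh.write("#" + header)
        return {"contrasts": 0}
    regions = read_regions(_out(config, "regions.tsv"))
    matrix = housekeeping_normalize(
        read_expression(config.expression, config.tissues)
    )
    # carrier sample ids are recoverable from the member call ids written by
    # the canonical call writer (call provenance is "<cohort>:<dialect>:<line>"),
    # so carriers are re-derived from the original discovery calls
    pedigree_calls = read_calls(
        config.calls["discovery"], DIALECT_OF["discovery"], "discovery", pedigree
    ).calls
    call_sample = {c.call_id: c.sample_id for c in pedigree_calls}
    contrasts = []
    for region in regions:
        carriers = sorted(
            {
                call_sample[cid]
                for cid in region.member_call_ids
                if cid in call_sample
            }
        )
        carriers = [s for s in carriers if s in set(matrix.samples)]
        if not carriers:
            continue
        tissues = sorted({matrix.tissue[s] for s in carriers})
        for gene in region.genes:
            if gene not in matrix.fpkm.index:
                continue
            for tissue in tissues:
                t_carriers = [s for s in carriers if matrix.tissue[s] == tissue]
                t_all = matrix.samples_of_tissue(tissue)
                if not t_carriers or len(t_carriers) == len(t_all):
                    continue
                contrasts.append(
                    compare_expression(gene, tissue, t_carriers, matrix)
                )
    with open(path, "w") as fh:
        fh.write("#" + header)
        for c in contrasts:
            p = "NA" if c.p_value is None else repr(float(c.p_value))
            fh.write(
                f"{c.gene}\t{c.tissue}\t{len(c.carrier_samples)}\t"
                f"{len(c.noncarrier_samples)}\t{repr(float(c.mean_fpkm_carrier))}\t"
                f"{repr(float(c.mean_fpkm_noncarrier))}\t"
                f"{repr(float(c.log2_fold_change))}\t{p}\t{c.method}\n"
            )
    return {"contrasts": len(contrasts)}


def run_pipeline(config: PipelineConfig) -> dict[str, int]:
    """Run every stage in order; returns the stage-count summary.

    Outputs under ``config.out_dir``: ``regions.tsv`` (final region table),
    ``dgv_novel.tsv``, ``contrasts.tsv``, ``trace.tsv`` (combined), and
    ``run.log`` (stage counts and the effective configuration).
    """
    config.validate()
    pedigree = read_pedigree(config.pedigree)
    counts: dict[str, int] = {}
    for stage_fn, needs_ped in (
        (stage_filter_denovo, True),
        (stage_replicate, True),
        (stage_annotate, False),
        (stage_test, True),
        (stage_express, True),
    ):
        stage_counts = stage_fn(config, pedigree) if needs_ped else stage_fn(config)
        logger.info("stage %s: %s", stage_fn.__name__, stage_counts)
        counts.update(stage_counts)

    if not (
        counts["proband_calls"]
        >= counts["de_novo_survivors"]
        >= counts["replicated"]
    ):
        raise StageError("pipeline", f"filter counts not monotone: {counts}")

    combined = FilterTrace()
    for name in ("trace_denovo.tsv", "trace_replicate.tsv"):
        combined.records.extend(read_trace(_out(config, name)).records)
    combined.check_consistency()
    write_trace(combined, _out(config, "trace.tsv"))

    with open(_out(config, "run.log"), "w") as fh:
        fh.write(f"# cnvtrio run (build tag: {config.build})\n")
        fh.write(
            f"# rho={config.rho} rho_rep={config.rho_rep} f_kb={config.f_kb} "
            f"n_perm={config.n_perm} seed={config.seed} "
            f"invert_criterion2={config.invert_criterion2}\n"
        )
        for k in sorted(counts):
            fh.write(f"{k}\t{counts[k]}\n")
    return counts
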