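"""Layer 2: cross-platform replication matching and recurrent-region merging.

Certified de novo discovery calls are checked against three independent
replication datasets (WES trios, SNP-array singletons, WGS trios).  A
replication *proband* call matching at reciprocal overlap >= rho_rep supports
the discovery call; a matching replication *control* call (family control or
unrelated array control) vetoes it — a variant seen in any healthy control is
treated as unrelated to disease.  Matching is type-agnostic because partial-
span and opposite-type calls at the same locus still mark it as copy-number
labile; the merged region records which types were observed.

Surviving calls plus their supporters are merged into recurrent regions by
single-linkage clustering at >= 1 bp overlap on the same chromosome, and
carriers are counted as distinct samples, never calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import (
    CnvCall,
    GenomicInterval,
    chrom_sort_key,
    reciprocal_overlap,
    union_span,
)
from .trio_filter import FilterTrace

REPLICATION_DATASETS = ("rep_wes", "rep_array", "rep_wgs")


@dataclass(frozen=True)
class ReplicationEvidence:
    """Supporting and vetoing replication calls for one discovery call or region."""

    rep_wes: tuple[str, ...] = ()
    rep_array: tuple[str, ...] = ()
    rep_wgs: tuple[str, ...] = ()
    veto: tuple[str, ...] = ()

    @property
    def supported(self) -> bool:
        """Supported: >= 1 replication proband hit in >= 1 dataset, zero vetoes."""
        return bool(self.rep_wes or self.rep_array or self.rep_wgs) and not self.veto

    def supporting(self, dataset: str) -> tuple[str, ...]:
        return getattr(self, dataset)

    def merge(self, other: "ReplicationEvidence") -> "ReplicationEvidence":
        def u(a: tuple[str, ...], b: tuple[str, ...]) -> tuple[str, ...]:
            return tuple(sorted(set(a) | set(b)))

        return ReplicationEvidence(
            u(self.rep_wes, other.rep_wes),
            u(self.rep_array, other.rep_array),
            u(self.rep_wgs, other.rep_wgs),
            u(self.veto, other.veto),
        )


@dataclass
class CnvRegion:
    """A merged recurrent CNV locus with carrier counts and annotation slots.

    ``interval`` is the union span of all member calls.  Flag/gene/p-value
    fields are filled by the annotation and statistics stages.
    """

    region_id: str
    interval: GenomicInterval
    member_call_ids: tuple[str, ...]
    cnv_types: tuple[str, ...]
    n_case_carriers: int
    n_control_carriers: int
    evidence: ReplicationEvidence = field(default_factory=ReplicationEvidence)
    de_novo: bool = False
    genes: tuple[str, ...] = ()
    expressed_gene: Optional[bool] = None
    novel_vs_chd: Optional[bool] = None
    absent_from_dgv: Optional[bool] = None
    relevant: Optional[bool] = None
    p_carrier: Optional[float] = None
    p_exact: Optional[float] = None
    n_perm: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_case_carriers < 0 or self.n_control_carriers < 0:
            raise ValueError(f"negative carrier count in region {self.region_id}")

    @property
    def supported(self) -> bool:
        return self.evidence.supported


def check_dataset_disjointness(
    discovery_calls: Iterable[CnvCall], replication_calls: Iterable[CnvCall]
) -> None:
    """Replication cohorts must be mutually exclusive from discovery samples."""
    disc = {c.sample_id for c in discovery_calls}
    for c in replication_calls:
        if c.sample_id in disc:
            raise ValueError(
                f"sample {c.sample_id} appears in both discovery and "
                f"replication cohort {c.cohort}: cohorts must be mutually exclusive"
            )


def match_replication(
    call: CnvCall,
    replication_calls: dict[str, list[CnvCall]],
    rho_rep: float = 0.25,
) -> ReplicationEvidence:
    """Match one discovery call against every replication dataset.

    ``replication_calls`` maps dataset name (rep_wes / rep_array / rep_wgs)
    to its full call list, probands and controls together; roles on the calls
    decide support vs veto.
    """
    if not 0.0 < rho_rep <= 1.0:
        raise ValueError(f"rho_rep must be in (0, 1], got {rho_rep}")
    supporting: dict[str, list[str]] = {d: [] for d in REPLICATION_DATASETS}
    veto: list[str] = []
    for dataset in REPLICATION_DATASETS:
        for rc in replication_calls.get(dataset, []):
            if reciprocal_overlap(call.interval, rc.interval) >= rho_rep:
                if rc.role == "proband":
                    supporting[dataset].append(rc.call_id)
                else:
                    veto.append(rc.call_id)
    return ReplicationEvidence(
        tuple(sorted(supporting["rep_wes"])),
        tuple(sorted(supporting["rep_array"])),
        tuple(sorted(supporting["rep_wgs"])),
        tuple(sorted(veto)),
    )


def filter_by_replication(
    calls: list[CnvCall],
    replication_calls: dict[str, list[CnvCall]],
    rho_rep: float = 0.25,
    trace: Optional[FilterTrace] = None,
) -> tuple[list[CnvCall], dict[str, ReplicationEvidence]]:
    """Keep discovery calls that are supported and not vetoed by replication data.

    Returns surviving calls and the evidence for every input call.  Vetoed
    calls and unsupported calls are traced with distinct reasons.
    """
    all_rep = [c for lst in replication_calls.values() for c in lst]
    check_dataset_disjointness(calls, all_rep)
    evidence: dict[str, ReplicationEvidence] = {}
    survivors: list[CnvCall] = []
    for call in sorted(calls, key=lambda c: c.call_id):
        ev = match_replication(call, replication_calls, rho_rep)
        evidence[call.call_id] = ev
        if ev.veto:
            if trace is not None:
                trace.add(
                    call.call_id, "replication", "drop",
                    "replication_control_hit", ev.veto,
                )
        elif not ev.supported:
            if trace is not None:
                trace.add(call.call_id, "replication", "drop", "not_replicated")
        else:
            if trace is not None:
                trace.add(
                    call.call_id, "replication", "pass", "replicated",
                    ev.rep_wes + ev.rep_array + ev.rep_wgs,
                )
            survivors.append(call)
    return survivors, evidence


def merge_recurrent(
    calls: list[CnvCall],
    evidence: Optional[dict[str, ReplicationEvidence]] = None,
    de_novo_call_ids: Optional[set[str]] = None,
) -> list[CnvRegion]:
    """Merge calls into recurrent regions by single-linkage >= 1 bp overlap.

    Input is typically the surviving discovery calls plus their supporting
    replication calls.  Regions are maximal: two regions on the same
    chromosome never overlap.  Region IDs derive from the sorted union-span
    coordinates, so the result is invariant to input order.
    """
    by_chrom: dict[str, list[CnvCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.interval.chrom, []).append(c)

    regions: list[CnvRegion] = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        chrom_calls = sorted(
            by_chrom[chrom], key=lambda c: (c.interval.start, c.interval.end, c.call_id)
        )
        # sweep: 1 bp-overlap connected components on sorted inclusive intervals
        cluster: list[CnvCall] = []
        max_end = -1
        for c in chrom_calls:
            if cluster and c.interval.start > max_end:
                regions.append(_build_region(cluster, evidence, de_novo_call_ids))
                cluster = []
                max_end = -1
            cluster.append(c)
            max_end = max(max_end, c.interval.end)
        if cluster:
            regions.append(_build_region(cluster, evidence, de_novo_call_ids))
    return regions


def _build_region(
    members: list[CnvCall],
    evidence: Optional[dict[str, ReplicationEvidence]],
    de_novo_call_ids: Optional[set[str]],
) -> CnvRegion:
    span = union_span([m.interval for m in members])
    case_samples = {m.sample_id for m in members if m.is_case}
    control_samples = {m.sample_id for m in members if not m.is_case}
    ev = ReplicationEvidence()
    if evidence is not None:
        for m in members:
            if m.call_id in evidence:
                ev = ev.merge(evidence[m.call_id])
    # supporting replication calls that are themselves members also carry
    # their sample into the case-carrier count via case_samples above
    de_novo = (
        any(m.call_id in de_novo_call_ids for m in members)
        if de_novo_call_ids is not None
        else False
    )
    return CnvRegion(
        region_id=str(span),
        interval=span,
        member_call_ids=tuple(sorted(m.call_id for m in members)),
        cnv_types=tuple(sorted({m.cnv_type for m in members})),
        n_case_carriers=len(case_samples),
        n_control_carriers=len(control_samples),
        evidence=ev,
        de_novo=de_novo,
    )


def attach_supporting_calls(
    survivors: list[CnvCall],
    evidence: dict[str, ReplicationEvidence],
    replication_calls: dict[str, list[CnvCall]],
) -> list[CnvCall]:
    """Surviving discovery calls plus every replication call that supports one."""
    by_id = {
        c.call_id: c for lst in replication_calls.values() for c in lst
    }
    out = list(survivors)
    seen = {c.call_id for c in survivors}
    for call in survivors:
        ev = evidence[call.call_id]
        for dataset in REPLICATION_DATASETS:
            for cid in ev.supporting(dataset):
                if cid not in seen:
                    out.append(by_id[cid])
                    seen.add(cid)
    return out
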