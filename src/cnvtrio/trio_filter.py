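"""Layer 1 of the discovery pipeline: de novo classification and control filtering.

A proband CNV call advances only if it is not inherited — no call in a
first-degree relative (parent or sibling) of the same family matches it at
reciprocal overlap >= rho — and not present in any independent family
control of the same dataset.  Matching is deliberately type-agnostic: an
overlapping parental duplication blocks certification of a proband deletion,
a conservative convention that treats any overlapping CNV at a locus as
evidence the locus is segregating in the family.

Probands whose family has no genotyped relative cannot be classified and are
excluded from the de novo channel (recorded in the trace, never silently
dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from intervaltree import IntervalTree

from .model import CnvCall, reciprocal_overlap

DE_NOVO = "de_novo"
INHERITED = "inherited"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class InheritanceVerdict:
    call_id: str
    verdict: str  # de_novo | inherited | unclassified
    matching_relative_calls: tuple[str, ...] = ()
    max_relative_overlap: float = 0.0

    def __post_init__(self) -> None:
        if self.verdict == INHERITED and not self.matching_relative_calls:
            raise ValueError("inherited verdict requires matching relative calls")


@dataclass(frozen=True)
class TraceRecord:
    """One filter decision: which stage saw the call and what it decided."""

    call_id: str
    stage: str
    decision: str  # pass | drop
    reason: str
    evidence: tuple[str, ...] = ()


@dataclass
class FilterTrace:
    """Ordered per-call provenance of every filter decision — the audit spine.

    Every proband call appears at every stage it reached; a call dropped at
    stage k appears at no later stage.
    """

    records: list[TraceRecord] = field(default_factory=list)

    def add(
        self,
        call_id: str,
        stage: str,
        decision: str,
        reason: str,
        evidence: Iterable[str] = (),
    ) -> None:
        if decision not in ("pass", "drop"):
            raise ValueError(f"decision must be pass or drop, got {decision!r}")
        self.records.append(
            TraceRecord(call_id, stage, decision, reason, tuple(evidence))
        )

    def stages_of(self, call_id: str) -> list[TraceRecord]:
        return [r for r in self.records if r.call_id == call_id]

    def terminal(self, call_id: str) -> Optional[TraceRecord]:
        recs = self.stages_of(call_id)
        return recs[-1] if recs else None

    def check_consistency(self) -> None:
        """Assert the drop-is-terminal invariant for every call in the trace."""
        dropped: set[str] = set()
        for r in self.records:
            if r.call_id in dropped:
                raise AssertionError(
                    f"call {r.call_id} appears at stage {r.stage} after being dropped"
                )
            if r.decision == "drop":
                dropped.add(r.call_id)


def _tree_index(calls: Iterable[CnvCall]) -> dict[str, IntervalTree]:
    """Per-chromosome interval index; tree coordinates are half-open [start, end+1)."""
    trees: dict[str, IntervalTree] = {}
    for c in calls:
        trees.setdefault(c.interval.chrom, IntervalTree()).addi(
            c.interval.start, c.interval.end + 1, c
        )
    return trees


def _matches(
    call: CnvCall, trees: dict[str, IntervalTree], rho: float
) -> list[tuple[float, CnvCall]]:
    """All indexed calls reaching reciprocal overlap >= rho with ``call``."""
    tree = trees.get(call.interval.chrom)
    if tree is None:
        return []
    hits = []
    for node in tree.overlap(call.interval.start, call.interval.end + 1):
        other: CnvCall = node.data
        ro = reciprocal_overlap(call.interval, other.interval)
        if ro >= rho:
            hits.append((ro, other))
    hits.sort(key=lambda t: (-t[0], t[1].call_id))
    return hits


def classify_inheritance(
    proband_call: CnvCall,
    relative_calls: list[CnvCall],
    rho: float = 0.5,
    has_genotyped_relatives: Optional[bool] = None,
) -> InheritanceVerdict:
    """Classify one proband call as de novo, inherited, or unclassified.

    ``relative_calls`` must be restricted to the proband's own family
    (parents and siblings).  A call is inherited iff any relative call on the
    same chromosome reaches reciprocal overlap >= rho, irrespective of
    DEL/DUP type.  ``has_genotyped_relatives`` distinguishes "relatives
    genotyped but call-free" (de novo) from "no relatives genotyped"
    (unclassified); when None it is inferred from the list being non-empty.
    """
    if not 0.0 < rho <= 1.0:
        raise ValueError(f"rho must be in (0, 1], got {rho}")
    for rc in relative_calls:
        if rc.family_id != proband_call.family_id:
            raise ValueError(
                f"relative call {rc.call_id} from family {rc.family_id} passed "
                f"for proband of family {proband_call.family_id}"
            )
        if rc.sample_id == proband_call.sample_id:
            raise ValueError(
                f"proband's own call {rc.call_id} passed as relative evidence"
            )
    if has_genotyped_relatives is None:
        has_genotyped_relatives = bool(relative_calls)
    if not has_genotyped_relatives:
        return InheritanceVerdict(proband_call.call_id, UNCLASSIFIED)

    best_ro = 0.0
    matching: list[tuple[float, str]] = []
    for rc in relative_calls:
        ro = reciprocal_overlap(proband_call.interval, rc.interval)
        best_ro = max(best_ro, ro)
        if ro >= rho:
            matching.append((ro, rc.call_id))
    if matching:
        matching.sort(key=lambda t: (-t[0], t[1]))
        return InheritanceVerdict(
            proband_call.call_id,
            INHERITED,
            tuple(cid for _, cid in matching),
            best_ro,
        )
    return InheritanceVerdict(proband_call.call_id, DE_NOVO, (), best_ro)


def filter_against_controls(
    proband_calls: list[CnvCall],
    control_calls: list[CnvCall],
    rho: float = 0.5,
    stage: str = "control_filter",
) -> tuple[list[CnvCall], list[TraceRecord]]:
    """Drop proband calls matched by any independent family control.

    ``control_calls`` are all non-proband samples of the same dataset,
    excluding the proband's own family (whose calls were already consumed by
    inheritance classification).  A call is dropped iff some control call
    reaches reciprocal overlap >= rho; the trace names the control evidence.
    """
    trees = _tree_index(control_calls)
    survivors: list[CnvCall] = []
    records: list[TraceRecord] = []
    for call in proband_calls:
        hits = _matches(call, trees, rho)
        if hits:
            records.append(
                TraceRecord(
                    call.call_id,
                    stage,
                    "drop",
                    "matched_independent_control",
                    tuple(h.call_id for _, h in hits),
                )
            )
        else:
            survivors.append(call)
            records.append(TraceRecord(call.call_id, stage, "pass", "no_control_match"))
    return survivors, records


def classify_cohort(
    calls: list[CnvCall],
    pedigree,
    rho: float = 0.5,
    cohort: str = "discovery",
    trace: Optional[FilterTrace] = None,
) -> tuple[list[CnvCall], dict[str, InheritanceVerdict]]:
    """Run layer 1 over a whole dataset: inheritance then control filtering.

    Returns the surviving (certified de novo) proband calls and the verdict
    for every proband call.  ``pedigree`` supplies family structure (see
    :class:`cnvtrio.io_formats.Pedigree`).
    """
    trace = trace if trace is not None else FilterTrace()
    cohort_calls = [c for c in calls if c.cohort == cohort]
    by_sample: dict[str, list[CnvCall]] = {}
    for c in cohort_calls:
        by_sample.setdefault(c.sample_id, []).append(c)

    proband_calls = sorted(
        (c for c in cohort_calls if c.role == "proband"),
        key=lambda c: c.call_id,
    )
    verdicts: dict[str, InheritanceVerdict] = {}
    de_novo_calls: list[CnvCall] = []
    for call in proband_calls:
        relatives = pedigree.relatives_of(call.sample_id)
        relative_calls = [
            rc for s in relatives for rc in by_sample.get(s, [])
        ]
        v = classify_inheritance(
            call, relative_calls, rho, has_genotyped_relatives=bool(relatives)
        )
        verdicts[call.call_id] = v
        if v.verdict == DE_NOVO:
            trace.add(call.call_id, "inheritance", "pass", "de_novo")
            de_novo_calls.append(call)
        elif v.verdict == INHERITED:
            trace.add(
                call.call_id,
                "inheritance",
                "drop",
                "inherited",
                v.matching_relative_calls,
            )
        else:
            trace.add(call.call_id, "inheritance", "drop", "no_genotyped_relatives")

    # independent family controls: every non-proband sample outside the
    # proband's own family, within the same dataset
    survivors: list[CnvCall] = []
    family_of = {c.call_id: c.family_id for c in de_novo_calls}
    control_calls_all = [c for c in cohort_calls if c.role != "proband"]
    trees = _tree_index(control_calls_all)
    for call in de_novo_calls:
        hits = [
            h
            for ro, h in _matches(call, trees, rho)
            if h.family_id != family_of[call.call_id]
        ]
        if hits:
            trace.add(
                call.call_id,
                "control_filter",
                "drop",
                "matched_independent_control",
                tuple(h.call_id for h in hits),
            )
        else:
            trace.add(call.call_id, "control_filter", "pass", "no_control_match")
            survivors.append(call)
    return survivors, verdicts
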