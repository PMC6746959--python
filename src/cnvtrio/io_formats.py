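"""Readers and writers for every on-disk format the pipeline touches.

Three CNV call dialects are supported, one per upstream caller family:

* ``xcnv``   — exome read-depth caller output (tab-separated; SAMPLE, CNV,
  INTERVAL required, trailing quality columns optional);
* ``rawcnv`` — array-intensity caller output (whitespace-separated tokens:
  region, ``numsnp=``, ``length=``, ``stateK,cn=N``, signal-file token,
  ``startsnp=``, ``endsnp=``);
* ``svbed``  — BED-like WGS structural-variant calls (chrom, 0-based start,
  end, sample, DEL/DUP, read-support fraction).  Calls with support below
  0.50 are rejected at parse time — the provenance filter applied to the
  upstream WGS calls.

All BED-style 0-based half-open coordinates are converted to the package's
1-based inclusive convention at this boundary.  Output tables are TSV with a
fixed, documented column order so runs diff bit-exactly.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .annotate import KnowledgeBase
from .expression import ExpressionMatrix
from .model import (
    COHORTS,
    CnvCall,
    GenomicInterval,
    chrom_sort_key,
    normalize_chrom,
)
from .replication import CnvRegion, ReplicationEvidence
from .trio_filter import FilterTrace, TraceRecord

logger = logging.getLogger("cnvtrio")

DIALECTS = ("xcnv", "rawcnv", "svbed")
DIALECT_PLATFORM = {"xcnv": "wes", "rawcnv": "array", "svbed": "wgs"}

#: minimum read-support fraction for a WGS call to be accepted
MIN_WGS_SUPPORT = 0.50


class DialectError(ValueError):
    """Unknown dialect name — a configuration error, not a data error."""


@dataclass(frozen=True)
class RejectedLine:
    lineno: int
    line: str
    reason: str


@dataclass
class ParsedCalls:
    """Parse result: accepted calls plus every rejected line with its reason."""

    calls: list[CnvCall]
    rejected: list[RejectedLine] = field(default_factory=list)

    def __iter__(self):
        return iter(self.calls)

    def __len__(self) -> int:
        return len(self.calls)


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PedMember:
    sample_id: str
    family_id: str
    father_id: str
    mother_id: str
    sex: str
    affected: bool
    dataset: str
    role: str


class Pedigree:
    """Family structure with roles and affection status across the datasets."""

    def __init__(self, members: list[PedMember]) -> None:
        self.members: dict[str, PedMember] = {}
        self.families: dict[str, list[str]] = {}
        for m in members:
            if m.sample_id in self.members:
                raise ValueError(f"duplicate sample_id {m.sample_id!r} in pedigree")
            if m.dataset not in COHORTS:
                raise ValueError(
                    f"unknown dataset {m.dataset!r} for sample {m.sample_id}"
                )
            self.members[m.sample_id] = m
            self.families.setdefault(m.family_id, []).append(m.sample_id)

    def role_of(self, sample_id: str) -> str:
        return self.members[sample_id].role

    def family_of(self, sample_id: str) -> str:
        return self.members[sample_id].family_id

    def dataset_of(self, sample_id: str) -> str:
        return self.members[sample_id].dataset

    def relatives_of(self, sample_id: str) -> list[str]:
        """Genotyped first-degree relatives (parents and siblings) of a proband."""
        m = self.members[sample_id]
        out = []
        for other_id in self.families[m.family_id]:
            if other_id == sample_id:
                continue
            if self.members[other_id].role in ("mother", "father", "sibling"):
                out.append(other_id)
        return sorted(out)

    def samples(self, dataset: Optional[str] = None) -> list[str]:
        return sorted(
            s for s, m in self.members.items()
            if dataset is None or m.dataset == dataset
        )

    def probands(self, dataset: str) -> list[str]:
        return [s for s in self.samples(dataset) if self.members[s].role == "proband"]

    def controls(self, dataset: str) -> list[str]:
        return [s for s in self.samples(dataset) if self.members[s].role != "proband"]


def read_pedigree(path: str) -> Pedigree:
    """Read a PED-like file: family, sample, father, mother, sex, affected(1/2), dataset.

    Roles are inferred from the parental-ID columns: samples named as a
    father/mother are parents; children (any nonzero parent ID) are probands
    if affected, else siblings; singletons are probands if affected, else
    unrelated controls.  A child referencing an absent parent keeps its role;
    the parent simply never appears among its genotyped relatives.
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise ValueError(
                    f"{path}:{lineno}: expected 7 pedigree columns, got {len(parts)}"
                )
            rows.append(parts)

    father_ids: dict[str, set[str]] = {}
    mother_ids: dict[str, set[str]] = {}
    for fam, _sid, fid, mid, _sex, _aff, _ds in rows:
        if fid != "0":
            father_ids.setdefault(fam, set()).add(fid)
        if mid != "0":
            mother_ids.setdefault(fam, set()).add(mid)
    fam_sizes: dict[str, int] = {}
    for fam, *_ in rows:
        fam_sizes[fam] = fam_sizes.get(fam, 0) + 1

    members = []
    for fam, sid, fid, mid, sex, aff, ds in rows:
        affected = aff == "2"
        if sid in father_ids.get(fam, set()):
            role = "father"
        elif sid in mother_ids.get(fam, set()):
            role = "mother"
        elif fid != "0" or mid != "0":
            role = "proband" if affected else "sibling"
        elif affected:
            role = "proband"
        else:
            role = "unrelated_control"
        if role == "proband" and not affected:
            raise ValueError(f"proband {sid} is not affected")
        members.append(PedMember(sid, fam, fid, mid, sex, affected, ds, role))
    return Pedigree(members)


def write_pedigree(ped: Pedigree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#family_id\tsample_id\tfather_id\tmother_id\tsex\taffected\tdataset\n")
        for sid in sorted(ped.members):
            m = ped.members[sid]
            fh.write(
                f"{m.family_id}\t{m.sample_id}\t{m.father_id}\t{m.mother_id}\t"
                f"{m.sex}\t{'2' if m.affected else '1'}\t{m.dataset}\n"
            )


# ---------------------------------------------------------------------------
# call dialects
# ---------------------------------------------------------------------------

def _call_context(sample_id: str, pedigree: Optional[Pedigree]) -> tuple[str, str]:
    """(family_id, role) for a sample, from the pedigree when available."""
    if pedigree is not None and sample_id in pedigree.members:
        return pedigree.family_of(sample_id), pedigree.role_of(sample_id)
    return sample_id, "unrelated_control"


def read_calls(
    path: str,
    dialect: str,
    cohort: str,
    pedigree: Optional[Pedigree] = None,
) -> ParsedCalls:
    """Parse one call file in the given dialect.

    Family and role context come from the pedigree; samples absent from it
    fall back to singleton unrelated controls.  Malformed records are
    rejected individually with their line numbers, never silently skipped,
    and the parse total always satisfies
    ``len(calls) + len(rejected) == number of non-header lines``.
    """
    if dialect not in DIALECTS:
        raise DialectError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if cohort not in COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}")
    platform = DIALECT_PLATFORM[dialect]
    parser = {"xcnv": _parse_xcnv, "rawcnv": _parse_rawcnv, "svbed": _parse_svbed}[
        dialect
    ]

    calls: list[CnvCall] = []
    rejected: list[RejectedLine] = []
    n_data_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#") or (dialect == "xcnv" and line.startswith("SAMPLE\t")):
                continue
            n_data_lines += 1
            try:
                sample_id, interval, cnv_type, quality, support = parser(line)
            except _Reject as exc:
                rejected.append(RejectedLine(lineno, line, str(exc)))
                continue
            except (ValueError, IndexError) as exc:
                rejected.append(RejectedLine(lineno, line, f"malformed: {exc}"))
                continue
            family_id, role = _call_context(sample_id, pedigree)
            calls.append(
                CnvCall(
                    call_id=f"{cohort}:{dialect}:{lineno:06d}",
                    sample_id=sample_id,
                    family_id=family_id,
                    role=role,
                    cohort=cohort,
                    platform=platform,
                    interval=interval,
                    cnv_type=cnv_type,
                    quality=quality,
                    support=support,
                )
            )
    if n_data_lines == 0:
        logger.warning("no records in %s (%s)", path, dialect)
    for r in rejected:
        logger.warning("%s:%d rejected (%s)", path, r.lineno, r.reason)
    assert len(calls) + len(rejected) == n_data_lines
    return ParsedCalls(calls, rejected)


class _Reject(ValueError):
    """Record-level rejection with a stable reason code."""


def _parse_xcnv(line: str):
    parts = line.split("\t")
    if len(parts) < 3:
        raise ValueError(f"need at least SAMPLE, CNV, INTERVAL; got {len(parts)} columns")
    sample, cnv, interval_s = parts[0], parts[1], parts[2]
    if cnv not in ("DEL", "DUP"):
        raise _Reject(f"unknown CNV state {cnv!r}")
    interval = GenomicInterval.from_string(interval_s)
    quality = None
    if len(parts) >= 9 and parts[8] not in ("", "NA"):
        quality = float(parts[8])  # Q_EXACT
    return sample, interval, cnv, quality, None


def _parse_rawcnv(line: str):
    parts = line.split()
    if len(parts) < 5:
        raise ValueError(f"need at least 5 whitespace tokens, got {len(parts)}")
    interval = GenomicInterval.from_string(parts[0])
    state_tok = next((p for p in parts if ",cn=" in p), None)
    if state_tok is None:
        raise _Reject("missing copy-number state token")
    cn = int(state_tok.split(",cn=")[1])
    if cn == 2:
        raise _Reject("cn=2 is the diploid state, not a CNV")
    cnv = "DEL" if cn <= 1 else "DUP"
    file_tok = next(
        (p for p in parts if "=" not in p and ":" not in p and "," not in p), None
    )
    if file_tok is None:
        raise ValueError("missing signal-file token")
    sample = os.path.splitext(os.path.basename(file_tok))[0]
    quality = None
    conf_tok = next((p for p in parts if p.startswith("conf=")), None)
    if conf_tok is not None:
        quality = float(conf_tok[5:])
    return sample, interval, cnv, quality, None


def _parse_svbed(line: str):
    parts = line.split("\t")
    if len(parts) < 6:
        raise ValueError(f"need 6 columns, got {len(parts)}")
    chrom, start0, end, sample, cnv, support = parts[:6]
    if cnv not in ("DEL", "DUP"):
        raise _Reject(f"unknown SV type {cnv!r}")
    frac = float(support)
    if not 0.0 <= frac <= 1.0:
        raise ValueError(f"support fraction {frac} outside [0, 1]")
    if frac < MIN_WGS_SUPPORT:
        raise _Reject(f"read support {frac:.3f} below {MIN_WGS_SUPPORT}")
    interval = GenomicInterval(normalize_chrom(chrom), int(start0) + 1, int(end))
    return sample, interval, cnv, None, f"{frac:.3f}"


def write_calls(calls: list[CnvCall], path: str, dialect: str) -> None:
    """Write calls in one of the three dialects (deterministic row order)."""
    if dialect not in DIALECTS:
        raise DialectError(f"unknown dialect {dialect!r}")
    ordered = sorted(
        calls,
        key=lambda c: (
            c.sample_id,
            chrom_sort_key(c.interval.chrom),
            c.interval.start,
            c.interval.end,
            c.cnv_type,
        ),
    )
    with open(path, "w") as fh:
        if dialect == "xcnv":
            fh.write(
                "SAMPLE\tCNV\tINTERVAL\tKB\tCHR\tMID_BP\tTARGETS\tNUM_TARG\tQ_EXACT\n"
            )
            for c in ordered:
                iv = c.interval
                kb = (iv.end - iv.start + 1) / 1000.0
                mid = (iv.start + iv.end) // 2
                q = "NA" if c.quality is None else repr(float(c.quality))
                fh.write(
                    f"{c.sample_id}\t{c.cnv_type}\t{iv}\t{kb:.2f}\t{iv.chrom}\t"
                    f"{mid}\tNA\tNA\t{q}\n"
                )
        elif dialect == "rawcnv":
            for c in ordered:
                iv = c.interval
                length = iv.end - iv.start + 1
                state = "state2,cn=1" if c.cnv_type == "DEL" else "state5,cn=3"
                conf = "" if c.quality is None else f" conf={repr(float(c.quality))}"
                fh.write(
                    f"{iv} numsnp=10 length={length} {state} "
                    f"{c.sample_id}.baf startsnp=rs0 endsnp=rs1{conf}\n"
                )
        else:  # svbed
            for c in ordered:
                iv = c.interval
                frac = c.support if c.support is not None else "1.000"
                fh.write(
                    f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{c.sample_id}\t"
                    f"{c.cnv_type}\t{frac}\n"
                )


# canonical TSV carrying every CnvCall field, for composing pipeline stages on disk

_CALL_COLUMNS = [
    "call_id", "sample_id", "family_id", "role", "cohort", "platform",
    "chrom", "start", "end", "cnv_type", "quality", "support",
]


def write_calls_canonical(calls: list[CnvCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_CALL_COLUMNS) + "\n")
        for c in sorted(calls, key=lambda c: c.call_id):
            fh.write(
                "\t".join(
                    [
                        c.call_id, c.sample_id, c.family_id, c.role, c.cohort,
                        c.platform, c.interval.chrom, str(c.interval.start),
                        str(c.interval.end), c.cnv_type,
                        "NA" if c.quality is None else repr(float(c.quality)),
                        "NA" if c.support is None else c.support,
                    ]
                )
                + "\n"
            )


def read_calls_canonical(path: str) -> list[CnvCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            calls.append(
                CnvCall(
                    call_id=p[0], sample_id=p[1], family_id=p[2], role=p[3],
                    cohort=p[4], platform=p[5],
                    interval=GenomicInterval(p[6], int(p[7]), int(p[8])),
                    cnv_type=p[9],
                    quality=None if p[10] == "NA" else float(p[10]),
                    support=None if p[11] == "NA" else p[11],
                )
            )
    return calls


# ---------------------------------------------------------------------------
# knowledge base, gene models, expression
# ---------------------------------------------------------------------------

def read_bed_intervals(path: str) -> list[tuple[GenomicInterval, Optional[str]]]:
    """BED records as 1-based inclusive intervals plus the optional name column."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            start0, end = int(parts[1]), int(parts[2])
            if end <= start0:
                raise ValueError(f"{path}:{lineno}: empty or inverted BED interval")
            iv = GenomicInterval(normalize_chrom(parts[0]), start0 + 1, end)
            name = parts[3] if len(parts) > 3 else None
            out.append((iv, name))
    return out


def read_knowledge_base(
    chd_bed: str, dgv_bed: str, genes_bed: str, expressed_list: str
) -> KnowledgeBase:
    """Load the flat knowledge bases: known disease loci, common-CNV catalogue,
    gene models (BED4), and the developmentally heart-expressed gene list."""
    chd = [iv for iv, _ in read_bed_intervals(chd_bed)]
    dgv = [iv for iv, _ in read_bed_intervals(dgv_bed)]
    gene_models: dict[str, GenomicInterval] = {}
    for iv, name in read_bed_intervals(genes_bed):
        if name is None:
            raise ValueError(f"gene model BED requires a name column: {genes_bed}")
        if name in gene_models:
            raise ValueError(f"duplicate gene symbol {name!r} in {genes_bed}")
        gene_models[name] = iv
    expressed: set[str] = set()
    with open(expressed_list) as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                expressed.add(sym)
    for sym in sorted(expressed - set(gene_models)):
        logger.warning(
            "expressed gene %s has no gene model; retained for symbol matching", sym
        )
    return KnowledgeBase(chd, dgv, expressed, gene_models)


def write_bed(records: list[tuple[GenomicInterval, Optional[str]]], path: str) -> None:
    with open(path, "w") as fh:
        for iv, name in records:
            row = f"{iv.chrom}\t{iv.start - 1}\t{iv.end}"
            if name is not None:
                row += f"\t{name}"
            fh.write(row + "\n")


def read_expression(path: str, tissue_path: str) -> ExpressionMatrix:
    """Read an FPKM TSV (first column gene, header of sample IDs) and the
    two-column sample-to-tissue map."""
    fpkm = pd.read_csv(path, sep="\t", index_col=0)
    if fpkm.isna().any().any():
        gene = fpkm.index[fpkm.isna().any(axis=1)][0]
        raise ValueError(f"missing FPKM cell at gene {gene!r} in {path}")
    neg = fpkm < 0
    if neg.any().any():
        gene = fpkm.index[neg.any(axis=1)][0]
        sample = fpkm.columns[neg.loc[gene].values.argmax()]
        raise ValueError(f"negative FPKM at gene {gene!r}, sample {sample!r} in {path}")
    tissue: dict[str, str] = {}
    with open(tissue_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            sample, tis = line.rstrip("\n").split("\t")
            tissue[sample] = tis
    return ExpressionMatrix(fpkm, tissue)


def write_expression(matrix: ExpressionMatrix, path: str, tissue_path: str) -> None:
    matrix.fpkm.to_csv(path, sep="\t", index_label="gene", float_format="%.6f")
    with open(tissue_path, "w") as fh:
        for s in matrix.samples:
            fh.write(f"{s}\t{matrix.tissue[s]}\n")


# ---------------------------------------------------------------------------
# canonical region and trace tables
# ---------------------------------------------------------------------------

_REGION_COLUMNS = [
    "region_id", "chrom", "start", "end", "cnv_types", "member_call_ids",
    "n_case_carriers", "n_control_carriers", "rep_wes_support",
    "rep_array_support", "rep_wgs_support", "veto", "supported", "de_novo",
    "genes", "expressed_gene", "novel_vs_chd", "absent_from_dgv", "relevant",
    "p_carrier", "p_exact", "n_perm", "seed",
]


def _fmt_list(items: tuple[str, ...]) -> str:
    return ",".join(items) if items else "."


def _parse_list(s: str) -> tuple[str, ...]:
    return tuple(s.split(",")) if s != "." else ()


def _fmt_opt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _parse_bool(s: str) -> Optional[bool]:
    return None if s == "NA" else s == "true"


def write_regions(regions: list[CnvRegion], path: str) -> None:
    """Write the canonical region table; rows sorted by locus, columns fixed."""
    ordered = sorted(
        regions,
        key=lambda r: (
            chrom_sort_key(r.interval.chrom),
            r.interval.start,
            r.interval.end,
            r.region_id,
        ),
    )
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_REGION_COLUMNS) + "\n")
        for r in ordered:
            ev = r.evidence
            fh.write(
                "\t".join(
                    [
                        r.region_id, r.interval.chrom, str(r.interval.start),
                        str(r.interval.end), _fmt_list(r.cnv_types),
                        _fmt_list(r.member_call_ids), str(r.n_case_carriers),
                        str(r.n_control_carriers), _fmt_list(ev.rep_wes),
                        _fmt_list(ev.rep_array), _fmt_list(ev.rep_wgs),
                        _fmt_list(ev.veto), _fmt_opt(ev.supported),
                        _fmt_opt(r.de_novo), _fmt_list(r.genes),
                        _fmt_opt(r.expressed_gene), _fmt_opt(r.novel_vs_chd),
                        _fmt_opt(r.absent_from_dgv), _fmt_opt(r.relevant),
                        _fmt_opt(r.p_carrier), _fmt_opt(r.p_exact),
                        _fmt_opt(r.n_perm), _fmt_opt(r.seed),
                    ]
                )
                + "\n"
            )


def read_regions(path: str) -> list[CnvRegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            if len(p) != len(_REGION_COLUMNS):
                raise ValueError(
                    f"region row has {len(p)} columns, expected {len(_REGION_COLUMNS)}"
                )
            regions.append(
                CnvRegion(
                    region_id=p[0],
                    interval=GenomicInterval(p[1], int(p[2]), int(p[3])),
                    cnv_types=_parse_list(p[4]),
                    member_call_ids=_parse_list(p[5]),
                    n_case_carriers=int(p[6]),
                    n_control_carriers=int(p[7]),
                    evidence=ReplicationEvidence(
                        _parse_list(p[8]), _parse_list(p[9]),
                        _parse_list(p[10]), _parse_list(p[11]),
                    ),
                    de_novo=bool(_parse_bool(p[13])),
                    genes=_parse_list(p[14]),
                    expressed_gene=_parse_bool(p[15]),
                    novel_vs_chd=_parse_bool(p[16]),
                    absent_from_dgv=_parse_bool(p[17]),
                    relevant=_parse_bool(p[18]),
                    p_carrier=None if p[19] == "NA" else float(p[19]),
                    p_exact=None if p[20] == "NA" else float(p[20]),
                    n_perm=None if p[21] == "NA" else int(p[21]),
                    seed=None if p[22] == "NA" else int(p[22]),
                )
            )
    return regions


def write_trace(trace: FilterTrace, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#call_id\tstage\tdecision\treason\tevidence\n")
        for r in trace.records:
            fh.write(
                f"{r.call_id}\t{r.stage}\t{r.decision}\t{r.reason}\t"
                f"{_fmt_list(r.evidence)}\n"
            )


def read_trace(path: str) -> FilterTrace:
    trace = FilterTrace()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            trace.records.append(TraceRecord(p[0], p[1], p[2], p[3], _parse_list(p[4])))
    return trace
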