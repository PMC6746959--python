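"""Synthetic multi-platform trio cohorts with known CNV ground truth.

The generator emulates the study design the pipeline is built for: a
discovery cohort of exome-sequenced family trios, a second independent
exome trio cohort, an array cohort of unrelated cases and controls, and a
small WGS trio cohort — all mutually exclusive in samples — carrying three
kinds of CNVs:

* **polymorphic loci**: population CNVs with fixed breakpoints, transmitted
  Mendelianly (each parental allele passed with probability 0.5).  These are
  the benign background the filters must remove.
* **background de novo events**: rare proband-only CNVs at random positions,
  one per proband at rate ``de_novo_rate``.
* **planted regions**: case-only recurrent loci with rostered carriers in
  each dataset and a named expression gene with a dosage effect — the
  signal the pipeline must recover.

Platform degradation is applied per dataset: calls are dropped with
probability 1 - sensitivity, breakpoints jittered with rounded Gaussian
noise, DEL/DUP flipped at the type-miscall rate, and false calls injected
at random positions.  Everything is deterministic under the master seed;
identical config + seed give byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .expression import DEFAULT_HOUSEKEEPING, ExpressionMatrix
from .io_formats import (
    Pedigree,
    PedMember,
    read_calls,
    write_bed,
    write_calls,
    write_expression,
    write_pedigree,
)
from .model import CnvCall, GenomicInterval, overlap_bp

# approximate human chromosome lengths (bp); enough genome to make chance
# overlap between independent random events rare
GENOME = {
    "chr1": 249_250_621, "chr2": 243_199_373, "chr3": 198_022_430,
    "chr4": 191_154_276, "chr5": 180_915_260, "chr6": 171_115_067,
    "chr7": 159_138_663, "chr8": 146_364_022, "chr9": 141_213_431,
    "chr10": 135_534_747, "chr11": 135_006_516, "chr12": 133_851_895,
    "chr13": 115_169_878, "chr14": 107_349_540, "chr15": 102_531_392,
    "chr16": 90_354_753, "chr17": 81_195_210, "chr18": 78_077_248,
    "chr19": 59_128_983, "chr20": 63_025_520, "chr21": 48_129_895,
    "chr22": 51_304_566,
}

DATASET_DIALECT = {
    "discovery": "xcnv",
    "rep_wes": "xcnv",
    "rep_array": "rawcnv",
    "rep_wgs": "svbed",
}


@dataclass(frozen=True)
class PlantedRegion:
    """A case-only recurrent CNV locus the pipeline should recover."""

    name: str
    interval: GenomicInterval
    cnv_type: str
    carriers: dict[str, int]  # dataset -> number of rostered case carriers
    gene: str
    dosage_effect: float  # expression multiplier per carried allele (0.5 = het DEL)
    tissue: str = "aorta"


@dataclass(frozen=True)
class PlatformParams:
    sensitivity: float = 0.95
    jitter_sd: float = 100.0  # bp, per breakpoint
    false_rate: float = 0.02  # probability of one false call per sample
    type_miscall: float = 0.02

    def validate(self) -> None:
        for p in (self.sensitivity, self.false_rate, self.type_miscall):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"platform probability {p} outside [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter sd must be >= 0")


def default_planted_regions() -> list[PlantedRegion]:
    """Five case-only recurrent regions, each tagged with a heart-expressed gene.

    Coordinates and gene symbols follow well-known CHD-associated loci so
    synthetic outputs read like real ones; carriers and effects are invented.
    """
    return [
        PlantedRegion(
            "P1", GenomicInterval("chr2", 109_363_161, 109_371_723), "DEL",
            {"discovery": 4, "rep_wes": 2, "rep_array": 0, "rep_wgs": 0},
            "RANBP2", 0.5, "aorta",
        ),
        PlantedRegion(
            "P2", GenomicInterval("chr2", 109_113_426, 109_287_320), "DEL",
            {"discovery": 3, "rep_wes": 2, "rep_array": 1, "rep_wgs": 0},
            "LIMS1", 0.5, "aorta",
        ),
        PlantedRegion(
            "P3", GenomicInterval("chr21", 38_461_093, 38_523_202), "DEL",
            {"discovery": 2, "rep_wes": 3, "rep_array": 0, "rep_wgs": 0},
            "TTC3", 0.5, "right_atrium",
        ),
        PlantedRegion(
            "P4", GenomicInterval("chr21", 30_400_216, 30_547_213), "DEL",
            {"discovery": 2, "rep_wes": 1, "rep_array": 1, "rep_wgs": 1},
            "MAP3K7CL", 0.5, "aorta",
        ),
        PlantedRegion(
            "P5", GenomicInterval("chr8", 11_534_468, 11_617_511), "DEL",
            {"discovery": 3, "rep_wes": 2, "rep_array": 0, "rep_wgs": 0},
            "GATA4", 0.5, "left_ventricle",
        ),
    ]


def default_platform_params() -> dict[str, PlatformParams]:
    return {
        "discovery": PlatformParams(0.95, 100.0, 0.02, 0.02),
        "rep_wes": PlatformParams(0.95, 100.0, 0.02, 0.02),
        "rep_array": PlatformParams(0.90, 500.0, 0.02, 0.02),
        "rep_wgs": PlatformParams(0.98, 50.0, 0.02, 0.02),
    }


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Cohort shapes are the scaled-down analogue of the study's four datasets
    (the full design is 760 + 1,712 trios, 1,860 array singletons, 33 WGS
    trios); the default 100/200/150/10 keeps a full pipeline run under a
    minute while preserving the case:control structure.
    """

    n_trios_discovery: int = 100
    n_trios_rep_wes: int = 200
    n_array_cases: int = 75
    n_array_controls: int = 75
    n_trios_rep_wgs: int = 10
    #: fraction of trio families with genotyped relatives (652/760 in the design)
    fraction_with_relatives: float = 0.86
    n_polymorphic_loci: int = 10
    polymorphic_freq_range: tuple[float, float] = (0.05, 0.30)
    polymorphic_len_range: tuple[int, int] = (20_000, 200_000)
    de_novo_rate: float = 0.05
    de_novo_len_range: tuple[int, int] = (10_000, 1_000_000)
    false_len_range: tuple[int, int] = (1_000, 1_000_000)
    planted_regions: list[PlantedRegion] = field(default_factory=default_planted_regions)
    platform_params: dict[str, PlatformParams] = field(
        default_factory=default_platform_params
    )
    expression_sigma_log2: float = 0.5
    expression_baseline_fpkm: float = 30.0
    n_expression_samples: int = 55
    master_seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.fraction_with_relatives <= 1.0:
            raise ValueError("fraction_with_relatives outside [0, 1]")
        if not 0.0 <= self.de_novo_rate <= 1.0:
            raise ValueError("de_novo_rate outside [0, 1]")
        lo, hi = self.polymorphic_freq_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("polymorphic_freq_range outside [0, 1]")
        if self.expression_sigma_log2 < 0:
            raise ValueError("expression noise sd must be >= 0")
        for params in self.platform_params.values():
            params.validate()
        for pr in self.planted_regions:
            if pr.cnv_type not in ("DEL", "DUP"):
                raise ValueError(f"planted region {pr.name}: bad type {pr.cnv_type}")
            if not 0 < pr.dosage_effect:
                raise ValueError(f"planted region {pr.name}: bad dosage effect")

    def noiseless(self) -> "SimulationConfig":
        """Copy with perfect detection: sensitivity 1, no jitter/false/miscalls."""
        perfect = {
            d: PlatformParams(1.0, 0.0, 0.0, 0.0) for d in self.platform_params
        }
        return replace(self, platform_params=perfect)


@dataclass(frozen=True)
class TrueEvent:
    """One true CNV of one sample, before platform degradation."""

    dataset: str
    sample_id: str
    interval: GenomicInterval
    cnv_type: str
    origin: str  # polymorphic:<locus> | de_novo | planted:<name>
    inherited_from: tuple[str, ...] = ()


CallKey = tuple[str, str, str, int, int, str]


def call_key(call: CnvCall) -> CallKey:
    iv = call.interval
    return (call.cohort, call.sample_id, iv.chrom, iv.start, iv.end, call.cnv_type)


@dataclass
class SimulationTruth:
    """Ground truth: every true event, every emitted call's origin, and the
    planted-region carrier rosters."""

    events: list[TrueEvent]
    emitted_origin: dict[CallKey, str]  # includes "false_positive"
    planted_rosters: dict[str, dict[str, list[str]]]  # region -> dataset -> samples
    polymorphic_loci: list[GenomicInterval]

    def origin_of(self, call: CnvCall) -> str:
        return self.emitted_origin[call_key(call)]

    def de_novo_keys(
        self, dataset: str, pedigree: Pedigree, require_relatives: bool = True
    ) -> set[CallKey]:
        """Keys of emitted proband calls that are truly de novo (background or
        planted), optionally restricted to probands with genotyped relatives."""
        out = set()
        for key, origin in self.emitted_origin.items():
            if key[0] != dataset:
                continue
            if not (origin == "de_novo" or origin.startswith("planted:")):
                continue
            sample = key[1]
            if pedigree.role_of(sample) != "proband":
                continue
            if require_relatives and not pedigree.relatives_of(sample):
                continue
            out.add(key)
        return out


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _random_interval(
    rng: np.random.Generator,
    len_range: tuple[int, int],
    avoid: list[GenomicInterval],
    max_tries: int = 1000,
) -> GenomicInterval:
    chroms = sorted(GENOME)
    weights = np.array([GENOME[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    log_lo, log_hi = math.log(len_range[0]), math.log(len_range[1])
    for _ in range(max_tries):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        length = int(round(math.exp(rng.uniform(log_lo, log_hi))))
        start = int(rng.integers(1, GENOME[chrom] - length))
        iv = GenomicInterval(chrom, start, start + length - 1)
        if all(overlap_bp(iv, a) == 0 for a in avoid):
            return iv
    raise RuntimeError("could not place a random interval away from avoided loci")


def _build_pedigree(config: SimulationConfig, rng: np.random.Generator) -> Pedigree:
    members: list[PedMember] = []

    def add_trio(prefix: str, i: int, dataset: str, with_relatives: bool) -> None:
        fam = f"{prefix}F{i:04d}"
        pro = f"{prefix}{i:04d}-01"
        if with_relatives:
            fa, mo = f"{prefix}{i:04d}-02", f"{prefix}{i:04d}-03"
            members.append(PedMember(pro, fam, fa, mo, "1", True, dataset, "proband"))
            members.append(PedMember(fa, fam, "0", "0", "1", False, dataset, "father"))
            members.append(PedMember(mo, fam, "0", "0", "2", False, dataset, "mother"))
        else:
            members.append(PedMember(pro, fam, "0", "0", "1", True, dataset, "proband"))

    for i in range(config.n_trios_discovery):
        add_trio("D", i, "discovery", rng.random() < config.fraction_with_relatives)
    for i in range(config.n_trios_rep_wes):
        add_trio("R", i, "rep_wes", rng.random() < config.fraction_with_relatives)
    for i in range(config.n_array_cases):
        sid = f"A{i:04d}"
        members.append(PedMember(sid, sid, "0", "0", "1", True, "rep_array", "proband"))
    for i in range(config.n_array_controls):
        sid = f"AC{i:04d}"
        members.append(
            PedMember(sid, sid, "0", "0", "2", False, "rep_array", "unrelated_control")
        )
    for i in range(config.n_trios_rep_wgs):
        add_trio("W", i, "rep_wgs", True)
    return Pedigree(members)


def _draw_polymorphic_loci(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[GenomicInterval], list[float]]:
    avoid = [pr.interval for pr in config.planted_regions]
    loci: list[GenomicInterval] = []
    freqs: list[float] = []
    lo, hi = config.polymorphic_freq_range
    for _ in range(config.n_polymorphic_loci):
        iv = _random_interval(rng, config.polymorphic_len_range, avoid + loci)
        loci.append(iv)
        freqs.append(float(rng.uniform(lo, hi)))
    return loci, freqs


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    pedigree: Pedigree
    calls: dict[str, list[CnvCall]]  # dataset -> emitted calls
    truth: SimulationTruth

    def all_calls(self) -> list[CnvCall]:
        return [c for d in sorted(self.calls) for c in self.calls[d]]


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate the four-dataset cohort in memory; see the module docstring."""
    config.validate()
    rng = np.random.default_rng(config.master_seed)
    pedigree = _build_pedigree(config, rng)
    loci, freqs = _draw_polymorphic_loci(config, rng)
    locus_types = ["DEL" if rng.random() < 0.5 else "DUP" for _ in loci]
    avoid_for_denovo = loci + [pr.interval for pr in config.planted_regions]

    events: list[TrueEvent] = []

    # polymorphic loci: Mendelian transmission within trios, marginal carrier
    # probability for singletons and relative-less probands
    datasets = ("discovery", "rep_wes", "rep_array", "rep_wgs")
    for dataset in datasets:
        fams: dict[str, list[str]] = {}
        for sid in pedigree.samples(dataset):
            fams.setdefault(pedigree.family_of(sid), []).append(sid)
        for fam in sorted(fams):
            sids = sorted(fams[fam])
            roles = {s: pedigree.role_of(s) for s in sids}
            parents = [s for s in sids if roles[s] in ("father", "mother")]
            children = [s for s in sids if roles[s] in ("proband", "sibling")]
            for li, (iv, q, t) in enumerate(zip(loci, freqs, locus_types)):
                carrier_parents = [p for p in parents if rng.random() < q]
                for p in carrier_parents:
                    events.append(
                        TrueEvent(dataset, p, iv, t, f"polymorphic:L{li}")
                    )
                for ch in children:
                    if parents:
                        transmitted = [
                            p for p in carrier_parents if rng.random() < 0.5
                        ]
                        if transmitted:
                            events.append(
                                TrueEvent(
                                    dataset, ch, iv, t, f"polymorphic:L{li}",
                                    tuple(transmitted),
                                )
                            )
                    elif rng.random() < q:
                        events.append(
                            TrueEvent(dataset, ch, iv, t, f"polymorphic:L{li}")
                        )

    # background de novo events, placed away from polymorphic and planted loci
    for dataset in datasets:
        for sid in pedigree.probands(dataset):
            if rng.random() < config.de_novo_rate:
                iv = _random_interval(rng, config.de_novo_len_range, avoid_for_denovo)
                t = "DEL" if rng.random() < 0.5 else "DUP"
                events.append(TrueEvent(dataset, sid, iv, t, "de_novo"))

    # planted case-only recurrent regions with rostered carriers
    rosters: dict[str, dict[str, list[str]]] = {}
    for pr in config.planted_regions:
        rosters[pr.name] = {}
        for dataset, n_carriers in sorted(pr.carriers.items()):
            probands = pedigree.probands(dataset)
            if n_carriers > len(probands):
                raise ValueError(
                    f"planted region {pr.name}: {n_carriers} carriers requested "
                    f"but only {len(probands)} probands in {dataset}"
                )
            chosen = sorted(
                rng.choice(probands, size=n_carriers, replace=False).tolist()
            )
            rosters[pr.name][dataset] = chosen
            for sid in chosen:
                events.append(
                    TrueEvent(dataset, sid, pr.interval, pr.cnv_type,
                              f"planted:{pr.name}")
                )

    # platform degradation and emission
    calls: dict[str, list[CnvCall]] = {d: [] for d in datasets}
    emitted_origin: dict[CallKey, str] = {}
    counter = 0
    order = sorted(
        range(len(events)),
        key=lambda i: (
            events[i].dataset, events[i].sample_id, events[i].interval.chrom,
            events[i].interval.start, events[i].interval.end, events[i].origin,
        ),
    )
    for i in order:
        ev = events[i]
        params = config.platform_params[ev.dataset]
        if rng.random() >= params.sensitivity:
            continue
        iv = _jitter(ev.interval, params.jitter_sd, rng)
        cnv_type = ev.cnv_type
        if rng.random() < params.type_miscall:
            cnv_type = "DUP" if cnv_type == "DEL" else "DEL"
        counter += 1
        call = _emit(
            pedigree, ev.dataset, ev.sample_id, iv, cnv_type, counter, rng,
            is_false=False,
        )
        calls[ev.dataset].append(call)
        emitted_origin[call_key(call)] = ev.origin

    # false calls
    for dataset in datasets:
        params = config.platform_params[dataset]
        if params.false_rate <= 0:
            continue
        for sid in pedigree.samples(dataset):
            if rng.random() < params.false_rate:
                iv = _random_interval(rng, config.false_len_range, [])
                t = "DEL" if rng.random() < 0.5 else "DUP"
                counter += 1
                call = _emit(pedigree, dataset, sid, iv, t, counter, rng, is_false=True)
                calls[dataset].append(call)
                emitted_origin[call_key(call)] = "false_positive"

    truth = SimulationTruth(events, emitted_origin, rosters, loci)
    return SimulatedCohort(config, pedigree, calls, truth)


def _jitter(
    iv: GenomicInterval, sd: float, rng: np.random.Generator
) -> GenomicInterval:
    if sd <= 0:
        return iv
    for _ in range(100):
        s = iv.start + int(round(rng.normal(0.0, sd)))
        e = iv.end + int(round(rng.normal(0.0, sd)))
        if 1 <= s <= e:
            return GenomicInterval(iv.chrom, s, e)
    return iv  # pathological sd vs length; keep the true breakpoints


def _emit(
    pedigree: Pedigree,
    dataset: str,
    sample_id: str,
    iv: GenomicInterval,
    cnv_type: str,
    counter: int,
    rng: np.random.Generator,
    is_false: bool,
) -> CnvCall:
    dialect = DATASET_DIALECT[dataset]
    quality: Optional[float] = None
    support: Optional[str] = None
    if dialect == "xcnv":
        quality = float(int(rng.integers(30, 100)))
    elif dialect == "rawcnv":
        quality = float(round(rng.uniform(10.0, 60.0), 3))
    else:
        # svbed read-support fraction: true calls always clear the 0.50 parse
        # filter; false calls draw a tail below it, so the filter is exercised
        lo = 0.35 if is_false else 0.50
        support = f"{rng.uniform(lo, 1.0):.3f}"
    return CnvCall(
        call_id=f"sim:{dataset}:{counter:06d}",
        sample_id=sample_id,
        family_id=pedigree.family_of(sample_id),
        role=pedigree.role_of(sample_id),
        cohort=dataset,
        platform={"xcnv": "wes", "rawcnv": "array", "svbed": "wgs"}[dialect],
        interval=iv,
        cnv_type=cnv_type,
        quality=quality,
        support=support,
    )


# ---------------------------------------------------------------------------
# on-disk cohort
# ---------------------------------------------------------------------------

def write_cohort(cohort: SimulatedCohort, out_dir: str) -> dict[str, str]:
    """Write the cohort in the dialects the pipeline reads; returns file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for dataset, dialect in DATASET_DIALECT.items():
        p = out / f"{dataset}.{dialect}"
        write_calls(cohort.calls[dataset], str(p), dialect)
        paths[dataset] = str(p)
    ped_path = out / "cohort.ped"
    write_pedigree(cohort.pedigree, str(ped_path))
    paths["pedigree"] = str(ped_path)
    truth_path = out / "truth.tsv"
    _write_truth(cohort.truth, str(truth_path))
    paths["truth"] = str(truth_path)
    return paths


def _write_truth(truth: SimulationTruth, path: str) -> None:
    """Two record types: true generating events, and emitted-call origins
    (post-jitter coordinates, including injected false positives)."""
    with open(path, "w") as fh:
        fh.write(
            "#record_type\tdataset\tsample_id\tchrom\tstart\tend\tcnv_type\torigin\n"
        )
        for ev in sorted(
            truth.events,
            key=lambda e: (e.dataset, e.sample_id, e.interval.chrom,
                           e.interval.start, e.interval.end, e.origin),
        ):
            fh.write(
                f"true_event\t{ev.dataset}\t{ev.sample_id}\t{ev.interval.chrom}\t"
                f"{ev.interval.start}\t{ev.interval.end}\t{ev.cnv_type}\t{ev.origin}\n"
            )
        for key in sorted(truth.emitted_origin):
            fh.write(
                f"emitted_call\t{key[0]}\t{key[1]}\t{key[2]}\t{key[3]}\t{key[4]}\t"
                f"{key[5]}\t{truth.emitted_origin[key]}\n"
            )


def load_cohort_calls(
    paths: dict[str, str], pedigree: Pedigree
) -> dict[str, list[CnvCall]]:
    """Read the written dialect files back; the reader is the source of truth
    for call IDs in the on-disk pipeline."""
    out = {}
    for dataset, dialect in DATASET_DIALECT.items():
        out[dataset] = read_calls(paths[dataset], dialect, dataset, pedigree).calls
    return out


# ---------------------------------------------------------------------------
# knowledge base + expression
# ---------------------------------------------------------------------------

HOUSEKEEPING_MODELS = {
    "G6PD": GenomicInterval("chr9", 133_759_606, 133_775_787),
    "ACTB": GenomicInterval("chr7", 5_566_779, 5_570_232),
}
HOUSEKEEPING_BASELINE = {"G6PD": 40.0, "ACTB": 250.0}


def simulate_knowledge_base(
    cohort: SimulatedCohort, out_dir: str, n_background_genes: int = 5
) -> dict[str, str]:
    """Write gene models, known-disease-locus and common-CNV BEDs, and the
    heart-expressed gene list consistent with the cohort's ground truth.

    The common-CNV catalogue is the polymorphic loci (the benign background),
    padded by 1 kb; known disease loci cover two of the planted regions so
    both directions of the novelty criterion are exercised.
    """
    config = cohort.config
    rng = np.random.default_rng(config.master_seed + 7)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    gene_records: list[tuple[GenomicInterval, Optional[str]]] = []
    for pr in config.planted_regions:
        gene_records.append((pr.interval, pr.gene))
    for sym, iv in sorted(HOUSEKEEPING_MODELS.items()):
        gene_records.append((iv, sym))
    avoid = [g for g, _ in gene_records] + cohort.truth.polymorphic_loci
    for i in range(n_background_genes):
        iv = _random_interval(rng, (20_000, 200_000), avoid)
        gene_records.append((iv, f"BG{i:03d}"))
        avoid.append(iv)

    dgv = [
        (GenomicInterval(iv.chrom, max(1, iv.start - 1000), iv.end + 1000), None)
        for iv in cohort.truth.polymorphic_loci
    ]
    chd_known = [
        (pr.interval, None) for pr in config.planted_regions[:2]
    ] or [(_random_interval(rng, (100_000, 1_000_000), []), None)]

    paths = {
        "genes_bed": str(out / "genes.bed"),
        "chd_bed": str(out / "chd_known.bed"),
        "dgv_bed": str(out / "dgv_common.bed"),
        "expressed_list": str(out / "heart_expressed.txt"),
    }
    write_bed(gene_records, paths["genes_bed"])
    write_bed(chd_known, paths["chd_bed"])
    write_bed(dgv, paths["dgv_bed"])
    with open(paths["expressed_list"], "w") as fh:
        for pr in config.planted_regions:
            fh.write(pr.gene + "\n")
    return paths


def simulate_expression(
    cohort: SimulatedCohort, out_dir: Optional[str] = None
) -> tuple[ExpressionMatrix, dict[str, list[str]]]:
    """Dosage-dependent FPKM for a cardiac-biopsy subset of discovery probands.

    Per sample and planted gene, log2 FPKM ~ Normal(log2(baseline *
    dosage^carrier), sigma); housekeeping genes sit at fixed baselines with a
    quarter of the noise.  Carriers of each planted region are forced into
    the region's tissue so every contrast has both groups.  Returns the
    matrix and the carrier roster restricted to expression samples.
    """
    config = cohort.config
    rng = np.random.default_rng(config.master_seed + 13)
    probands = cohort.pedigree.probands("discovery")
    carriers_by_region = {
        pr.name: [
            s for s in cohort.truth.planted_rosters[pr.name].get("discovery", [])
        ]
        for pr in config.planted_regions
    }
    forced = sorted({s for lst in carriers_by_region.values() for s in lst})
    rest = [s for s in probands if s not in forced]
    samples = forced + rest[: max(0, config.n_expression_samples - len(forced))]

    tissues = sorted({pr.tissue for pr in config.planted_regions}) or ["aorta"]
    tissue_of: dict[str, str] = {}
    for pr in config.planted_regions:
        for s in carriers_by_region[pr.name]:
            tissue_of.setdefault(s, pr.tissue)
    for j, s in enumerate(samples):
        tissue_of.setdefault(s, tissues[j % len(tissues)])

    genes = [pr.gene for pr in config.planted_regions] + sorted(HOUSEKEEPING_BASELINE)
    fpkm = {}
    sigma = config.expression_sigma_log2
    for s in samples:
        col = []
        for pr in config.planted_regions:
            carrier = s in carriers_by_region[pr.name]
            mu = math.log2(
                config.expression_baseline_fpkm
                * (pr.dosage_effect if carrier else 1.0)
            )
            col.append(2.0 ** rng.normal(mu, sigma))
        for hk in sorted(HOUSEKEEPING_BASELINE):
            mu = math.log2(HOUSEKEEPING_BASELINE[hk])
            col.append(2.0 ** rng.normal(mu, sigma / 4.0))
        fpkm[s] = col

    matrix = ExpressionMatrix(
        pd.DataFrame(fpkm, index=genes),
        {s: tissue_of[s] for s in samples},
        DEFAULT_HOUSEKEEPING,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_expression(
            matrix, str(out / "expression_fpkm.tsv"), str(out / "tissues.tsv")
        )
    expr_carriers = {
        name: [s for s in lst if s in set(samples)]
        for name, lst in carriers_by_region.items()
    }
    return matrix, expr_carriers
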