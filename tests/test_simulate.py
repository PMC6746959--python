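"""Generator contracts: reproducibility, Mendelian consistency, noiseless
limit, de novo rate, and dosage-dependent expression."""

import filecmp
import math

import numpy as np
import pytest

from cnvtrio.model import overlap_bp
from cnvtrio.simulate import (
    SimulationConfig,
    call_key,
    simulate_cohort,
    simulate_expression,
    simulate_knowledge_base,
    write_cohort,
)


def small_config(**kwargs):
    defaults = dict(
        n_trios_discovery=30, n_trios_rep_wes=40, n_array_cases=20,
        n_array_controls=20, n_trios_rep_wgs=5, n_polymorphic_loci=6,
        planted_regions=[], master_seed=21,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestDeterminismAndStructure:
    def test_identical_seed_gives_byte_identical_files(self, tmp_path):
        for d in ("a", "b"):
            cohort = simulate_cohort(SimulationConfig(master_seed=33))
            write_cohort(cohort, str(tmp_path / d))
            simulate_knowledge_base(cohort, str(tmp_path / d))
            simulate_expression(cohort, str(tmp_path / d))
        names = [
            "discovery.xcnv", "rep_wes.xcnv", "rep_array.rawcnv",
            "rep_wgs.svbed", "cohort.ped", "truth.tsv", "genes.bed",
            "chd_known.bed", "dgv_common.bed", "heart_expressed.txt",
            "expression_fpkm.tsv", "tissues.tsv",
        ]
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", names, shallow=False
        )
        assert mismatch == [] and errors == []

    def test_different_seed_changes_output(self):
        a = simulate_cohort(small_config(master_seed=1))
        b = simulate_cohort(small_config(master_seed=2))
        assert {call_key(c) for c in a.all_calls()} != {
            call_key(c) for c in b.all_calls()
        }

    def test_sample_ids_disjoint_across_datasets(self, default_cohort):
        ped = default_cohort.pedigree
        seen = {}
        for sid, m in ped.members.items():
            assert seen.setdefault(sid, m.dataset) == m.dataset
        datasets = {}
        for sid, m in ped.members.items():
            datasets.setdefault(m.dataset, set()).add(sid)
        all_ids = [s for ids in datasets.values() for s in ids]
        assert len(all_ids) == len(set(all_ids))

    def test_invalid_config_rejected_before_generation(self):
        with pytest.raises(ValueError):
            simulate_cohort(small_config(de_novo_rate=1.5))
        with pytest.raises(ValueError):
            simulate_cohort(small_config(fraction_with_relatives=-0.1))


class TestTruthContracts:
    def test_noiseless_emission_equals_truth(self, noiseless_cohort):
        emitted = {call_key(c) for c in noiseless_cohort.all_calls()}
        truth_keys = {
            (ev.dataset, ev.sample_id, ev.interval.chrom, ev.interval.start,
             ev.interval.end, ev.cnv_type)
            for ev in noiseless_cohort.truth.events
        }
        assert emitted == truth_keys
        assert all(
            origin != "false_positive"
            for origin in noiseless_cohort.truth.emitted_origin.values()
        )

    def test_mendelian_consistency(self, noiseless_cohort):
        """Every inherited proband call has a same-locus parental truth allele."""
        truth = noiseless_cohort.truth
        ped = noiseless_cohort.pedigree
        parent_events = {}
        for ev in truth.events:
            parent_events.setdefault((ev.dataset, ev.sample_id), []).append(ev)
        checked = 0
        for ev in truth.events:
            if not ev.origin.startswith("polymorphic"):
                continue
            if ped.role_of(ev.sample_id) != "proband":
                continue
            rels = ped.relatives_of(ev.sample_id)
            if not rels:
                continue
            assert ev.inherited_from, f"carrier proband without transmitting parent"
            for parent in ev.inherited_from:
                assert any(
                    pe.origin == ev.origin
                    and overlap_bp(pe.interval, ev.interval) > 0
                    for pe in parent_events.get((ev.dataset, parent), [])
                )
            checked += 1
        assert checked > 0

    def test_no_de_novo_and_no_planted_yields_no_de_novo_truth(self):
        cohort = simulate_cohort(small_config(de_novo_rate=0.0))
        assert cohort.truth.de_novo_keys("discovery", cohort.pedigree) == set()
        from cnvtrio.trio_filter import classify_cohort, DE_NOVO

        _, verdicts = classify_cohort(cohort.calls["discovery"], cohort.pedigree)
        # platform noise may fake isolated de novo calls, but with noise off none
        noiseless = simulate_cohort(small_config(de_novo_rate=0.0).noiseless())
        _, v2 = classify_cohort(noiseless.calls["discovery"], noiseless.pedigree)
        assert all(v.verdict != DE_NOVO for v in v2.values())

    def test_de_novo_count_binomial_expectation(self):
        config = small_config(
            n_trios_discovery=500, n_polymorphic_loci=0, de_novo_rate=0.1,
            master_seed=55,
        )
        cohort = simulate_cohort(config)
        n = sum(
            1 for ev in cohort.truth.events
            if ev.dataset == "discovery" and ev.origin == "de_novo"
        )
        assert abs(n - 50) <= 3 * math.sqrt(50)

    def test_planted_rosters_are_case_only_and_sized(self, default_cohort):
        ped = default_cohort.pedigree
        for pr in default_cohort.config.planted_regions:
            roster = default_cohort.truth.planted_rosters[pr.name]
            for dataset, n in pr.carriers.items():
                assert len(roster[dataset]) == n
                for sid in roster[dataset]:
                    assert ped.role_of(sid) == "proband"


class TestSimulatedExpression:
    def test_neutral_dosage_groups_match_in_expectation(self):
        from cnvtrio.simulate import PlantedRegion
        from cnvtrio.model import GenomicInterval

        config = SimulationConfig(
            master_seed=77,
            planted_regions=[
                PlantedRegion(
                    "P1", GenomicInterval("chr2", 109_363_161, 109_371_723),
                    "DEL", {"discovery": 10}, "RANBP2", 1.0, "aorta",
                )
            ],
        )
        cohort = simulate_cohort(config)
        matrix, carriers = simulate_expression(cohort)
        cs = carriers["P1"]
        ns = [s for s in matrix.samples if s not in cs]
        mc = np.log2(matrix.fpkm.loc["RANBP2", cs]).mean()
        mn = np.log2(matrix.fpkm.loc["RANBP2", ns]).mean()
        assert abs(mc - mn) < 0.5

    def test_zero_noise_halved_dosage_is_exactly_half(self):
        base = SimulationConfig(master_seed=78, expression_sigma_log2=0.0)
        cohort = simulate_cohort(base)
        matrix, carriers = simulate_expression(cohort)
        for pr in base.planted_regions:
            cs = carriers[pr.name]
            ns = [s for s in matrix.samples if s not in cs]
            assert matrix.fpkm.loc[pr.gene, cs].values == pytest.approx(
                base.expression_baseline_fpkm * 0.5
            )
            assert matrix.fpkm.loc[pr.gene, ns].values == pytest.approx(
                base.expression_baseline_fpkm
            )

    def test_expression_cohort_size(self, default_cohort):
        matrix, _ = simulate_expression(default_cohort)
        assert len(matrix.samples) == default_cohort.config.n_expression_samples
        assert {"G6PD", "ACTB"} <= set(matrix.genes)
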