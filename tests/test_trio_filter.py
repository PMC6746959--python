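"""De novo certification: examples, order invariance, rho monotonicity,
brute-force oracle, and exact recovery on a noiseless synthetic cohort."""

import numpy as np
import pytest

from conftest import make_call
from cnvtrio.model import reciprocal_overlap
from cnvtrio.simulate import call_key
from cnvtrio.trio_filter import (
    DE_NOVO,
    INHERITED,
    UNCLASSIFIED,
    classify_cohort,
    classify_inheritance,
    filter_against_controls,
)


def trio_calls(proband_iv=(1000, 2000), parent_ivs=()):
    proband = make_call(
        "p1", start=proband_iv[0], end=proband_iv[1], sample_id="C1", family_id="F1"
    )
    relatives = [
        make_call(
            f"r{i}", start=s, end=e, sample_id="M1", family_id="F1", role="mother",
            cnv_type="DUP",
        )
        for i, (s, e) in enumerate(parent_ivs)
    ]
    return proband, relatives


class TestClassifyInheritance:
    def test_no_relative_calls_but_genotyped_relatives_is_de_novo(self):
        proband, _ = trio_calls()
        v = classify_inheritance(proband, [], has_genotyped_relatives=True)
        assert v.verdict == DE_NOVO

    def test_identical_parental_interval_is_inherited(self):
        proband, rels = trio_calls(parent_ivs=[(1000, 2000)])
        v = classify_inheritance(proband, rels)
        assert v.verdict == INHERITED
        assert v.max_relative_overlap == 1.0
        assert v.matching_relative_calls == ("r0",)

    def test_opposite_type_still_blocks_de_novo(self):
        # relative calls are DUP; matching is type-agnostic
        proband, rels = trio_calls(parent_ivs=[(1100, 2100)])
        assert classify_inheritance(proband, rels).verdict == INHERITED

    def test_no_genotyped_relatives_is_unclassified(self):
        proband, _ = trio_calls()
        assert classify_inheritance(proband, []).verdict == UNCLASSIFIED

    def test_relative_from_other_family_is_contract_violation(self):
        proband, _ = trio_calls()
        alien = make_call("x", sample_id="M9", family_id="F9", role="mother")
        with pytest.raises(ValueError, match="family"):
            classify_inheritance(proband, [alien])

    def test_rho_monotonicity_on_random_families(self):
        """Raising rho only ever converts inherited -> de novo."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            start = int(rng.integers(1, 10_000))
            proband, _ = trio_calls((start, start + int(rng.integers(100, 5000))))
            rels = []
            for i in range(int(rng.integers(0, 4))):
                s = int(rng.integers(1, 12_000))
                rels.append(
                    make_call(f"r{i}", start=s, end=s + int(rng.integers(100, 5000)),
                              sample_id="M1", family_id="F1", role="mother")
                )
            verdicts = [
                classify_inheritance(proband, rels, rho,
                                     has_genotyped_relatives=True).verdict
                for rho in (0.1, 0.3, 0.5, 0.7, 0.9)
            ]
            seen_de_novo = False
            for v in verdicts:
                if v == DE_NOVO:
                    seen_de_novo = True
                assert not (seen_de_novo and v == INHERITED)


class TestControlFilter:
    def test_no_overlap_all_survive(self):
        probands = [make_call(f"p{i}", start=1000 * i + 1, end=1000 * i + 100)
                    for i in range(1, 4)]
        controls = [make_call("c1", chrom="chr9", sample_id="U1",
                              role="unrelated_control")]
        survivors, records = filter_against_controls(probands, controls)
        assert survivors == probands
        assert all(r.decision == "pass" for r in records)

    def test_identical_control_interval_drops_with_evidence(self):
        proband = make_call("p1")
        control = make_call("c1", sample_id="U1", family_id="U1",
                            role="unrelated_control")
        survivors, records = filter_against_controls([proband], [control])
        assert survivors == []
        (rec,) = records
        assert rec.decision == "drop" and rec.evidence == ("c1",)

    def test_planted_truth_table(self):
        """10 proband-unique calls plus 5 shared-with-control calls: 10 survive."""
        probands, controls = [], []
        for i in range(10):
            probands.append(make_call(f"u{i}", chrom="chr1", start=10_000 * (i + 1),
                                      end=10_000 * (i + 1) + 500, sample_id=f"P{i}"))
        for i in range(5):
            s = 10_000 * (i + 1)
            shared = make_call(f"s{i}", chrom="chr2", start=s, end=s + 500,
                               sample_id=f"P{i}")
            probands.append(shared)
            controls.append(make_call(f"ctl{i}", chrom="chr2", start=s, end=s + 500,
                                      sample_id=f"U{i}", role="unrelated_control"))
        survivors, _ = filter_against_controls(probands, controls)
        assert sorted(c.call_id for c in survivors) == [f"u{i}" for i in range(10)]


class TestCohortClassification:
    def _brute_force(self, calls, pedigree, rho):
        """All-pairs enumeration of layer 1 on a small cohort."""
        by_sample = {}
        for c in calls:
            by_sample.setdefault(c.sample_id, []).append(c)
        out = set()
        for c in calls:
            if c.role != "proband":
                continue
            rels = pedigree.relatives_of(c.sample_id)
            if not rels:
                continue
            rel_calls = [rc for s in rels for rc in by_sample.get(s, [])]
            if any(reciprocal_overlap(c.interval, rc.interval) >= rho
                   for rc in rel_calls):
                continue
            control_hit = any(
                reciprocal_overlap(c.interval, oc.interval) >= rho
                for oc in calls
                if oc.role != "proband" and oc.family_id != c.family_id
            )
            if not control_hit:
                out.add(c.call_id)
        return out

    def test_matches_brute_force_on_small_cohorts(self):
        from cnvtrio.simulate import SimulationConfig, simulate_cohort

        config = SimulationConfig(
            n_trios_discovery=6, n_trios_rep_wes=2, n_array_cases=2,
            n_array_controls=2, n_trios_rep_wgs=1, n_polymorphic_loci=3,
            planted_regions=[], master_seed=9,
        )
        cohort = simulate_cohort(config)
        calls = cohort.calls["discovery"]
        assert len(calls) <= 40
        survivors, _ = classify_cohort(calls, cohort.pedigree, rho=0.5)
        assert {c.call_id for c in survivors} == self._brute_force(
            calls, cohort.pedigree, 0.5
        )

    def test_order_invariance(self, default_cohort):
        calls = default_cohort.calls["discovery"]
        a, _ = classify_cohort(calls, default_cohort.pedigree)
        b, _ = classify_cohort(list(reversed(calls)), default_cohort.pedigree)
        assert {c.call_id for c in a} == {c.call_id for c in b}

    def test_noiseless_recovery_equals_truth(self, noiseless_cohort):
        """With perfect detection, the classified de novo set is exactly the
        generator's de novo truth (background + planted, relative-bearing
        probands)."""
        cohort = noiseless_cohort
        calls = cohort.calls["discovery"]
        survivors, verdicts = classify_cohort(calls, cohort.pedigree)
        by_id = {c.call_id: c for c in calls}
        classified = {
            call_key(by_id[cid])
            for cid, v in verdicts.items()
            if v.verdict == DE_NOVO
        }
        truth = cohort.truth.de_novo_keys("discovery", cohort.pedigree)
        assert classified == truth
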