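"""Replication matching and single-linkage region merging."""

import numpy as np
import pytest

from conftest import make_call
from cnvtrio.model import GenomicInterval, overlap_bp
from cnvtrio.replication import (
    check_dataset_disjointness,
    filter_by_replication,
    match_replication,
    merge_recurrent,
)


def rep_call(call_id, start, end, chrom="chr2", role="proband", cohort="rep_wes",
             sample_id=None, cnv_type="DUP"):
    platform = {"rep_wes": "wes", "rep_array": "array", "rep_wgs": "wgs"}[cohort]
    return make_call(
        call_id, chrom=chrom, start=start, end=end,
        sample_id=sample_id or f"S_{call_id}", role=role, cohort=cohort,
        platform=platform, cnv_type=cnv_type,
    )


class TestMatchReplication:
    def test_partial_opposite_type_supports_at_loose_rho(self):
        # discovery DEL vs replication DUP with reciprocal overlap ~0.268:
        # a supporting hit at rho_rep 0.25, no hit at 0.5
        disc = make_call("d1", chrom="chr2", start=109363161, end=109371723)
        rep = rep_call("r1", 109365376, 109389041)
        ev = match_replication(disc, {"rep_wes": [rep]}, rho_rep=0.25)
        assert ev.rep_wes == ("r1",) and ev.supported
        ev2 = match_replication(disc, {"rep_wes": [rep]}, rho_rep=0.5)
        assert not ev2.supported and ev2.rep_wes == ()

    def test_control_match_vetoes(self):
        disc = make_call("d1", start=1000, end=2000)
        ctl = rep_call("r1", 1000, 2000, chrom="chr1", role="unrelated_control",
                       cohort="rep_array")
        ev = match_replication(disc, {"rep_array": [ctl]})
        assert ev.veto == ("r1",) and not ev.supported

    def test_support_and_veto_together_is_not_supported(self):
        disc = make_call("d1", start=1000, end=2000)
        sup = rep_call("r1", 1000, 2000, chrom="chr1")
        ctl = rep_call("r2", 1000, 2000, chrom="chr1", role="mother",
                       cohort="rep_wes")
        ev = match_replication(disc, {"rep_wes": [sup, ctl]})
        assert ev.rep_wes == ("r1",) and ev.veto == ("r2",)
        assert not ev.supported

    def test_shared_sample_between_cohorts_is_fatal(self):
        disc = make_call("d1", sample_id="DUPSAMPLE")
        rep = rep_call("r1", 1, 10, sample_id="DUPSAMPLE")
        with pytest.raises(ValueError, match="mutually exclusive"):
            check_dataset_disjointness([disc], [rep])
        with pytest.raises(ValueError, match="mutually exclusive"):
            filter_by_replication([disc], {"rep_wes": [rep]})


class TestMergeRecurrent:
    def test_overlapping_discovery_and_replication_calls_form_one_region(self):
        # three discovery probands plus an array supporter at one locus
        calls = [
            make_call(f"d{i}", chrom="chr2", start=109113426, end=109287320,
                      sample_id=f"P{i}")
            for i in range(3)
        ]
        calls.append(
            rep_call("a1", 109173930, 109301074, cohort="rep_array",
                     cnv_type="DEL")
        )
        (region,) = merge_recurrent(calls)
        assert region.interval == GenomicInterval("chr2", 109113426, 109301074)
        assert region.n_case_carriers == 4
        assert region.n_control_carriers == 0

    def test_different_chromosomes_stay_separate(self):
        calls = [make_call("a", chrom="chr1"), make_call("b", chrom="chr2",
                                                         sample_id="S2")]
        assert len(merge_recurrent(calls)) == 2

    def test_transitive_chain_merges(self):
        a = make_call("a", start=100, end=200, sample_id="S1")
        b = make_call("b", start=180, end=300, sample_id="S2")
        c = make_call("c", start=290, end=400, sample_id="S3")
        assert overlap_bp(a.interval, c.interval) == 0
        (region,) = merge_recurrent([a, b, c])
        assert region.member_call_ids == ("a", "b", "c")

    def test_carriers_counted_as_samples_not_calls(self):
        calls = [
            make_call("a", start=100, end=200, sample_id="S1"),
            make_call("b", start=150, end=250, sample_id="S1"),
        ]
        (region,) = merge_recurrent(calls)
        assert region.n_case_carriers == 1

    def _random_calls(self, rng, n):
        calls = []
        for i in range(n):
            s = int(rng.integers(1, 5000))
            calls.append(
                make_call(f"c{i}", chrom=f"chr{1 + int(rng.integers(0, 2))}",
                          start=s, end=s + int(rng.integers(50, 2000)),
                          sample_id=f"S{i}")
            )
        return calls

    def test_partition_and_maximality_properties(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            calls = self._random_calls(rng, int(rng.integers(1, 30)))
            regions = merge_recurrent(calls)
            members = [cid for r in regions for cid in r.member_call_ids]
            assert sorted(members) == sorted(c.call_id for c in calls)
            by_chrom = {}
            for r in regions:
                by_chrom.setdefault(r.interval.chrom, []).append(r.interval)
            for ivs in by_chrom.values():
                ivs.sort(key=lambda iv: iv.start)
                for x, y in zip(ivs, ivs[1:]):
                    assert overlap_bp(x, y) == 0

    def test_order_invariance(self):
        rng = np.random.default_rng(8)
        calls = self._random_calls(rng, 25)
        ref = merge_recurrent(calls)
        perm = [calls[i] for i in rng.permutation(len(calls))]
        assert merge_recurrent(perm) == ref

    def test_matches_connected_components_oracle(self):
        """Regions equal connected components of the brute-force overlap graph."""
        rng = np.random.default_rng(17)
        for _ in range(30):
            calls = self._random_calls(rng, int(rng.integers(2, 16)))
            regions = merge_recurrent(calls)
            # brute force: BFS over the pairwise >= 1 bp overlap graph
            adj = {c.call_id: set() for c in calls}
            for x in calls:
                for y in calls:
                    if x.call_id != y.call_id and overlap_bp(x.interval,
                                                             y.interval) >= 1:
                        adj[x.call_id].add(y.call_id)
            seen, components = set(), []
            for c in calls:
                if c.call_id in seen:
                    continue
                stack, comp = [c.call_id], set()
                while stack:
                    u = stack.pop()
                    if u in comp:
                        continue
                    comp.add(u)
                    stack.extend(adj[u] - comp)
                seen |= comp
                components.append(frozenset(comp))
            assert {frozenset(r.member_call_ids) for r in regions} == set(components)
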