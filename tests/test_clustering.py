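import math

import numpy as np
import pytest

from conftest import mutate, random_sequence, records_from

from smorfscape.clustering import (
    ClusterParams,
    _hash_kmer,
    align_pair,
    cluster_bruteforce,
    cluster_linear,
    passes_thresholds,
    select_kmers,
)
from smorfscape.io import ProteinRecord


DEFAULTS = ClusterParams()


class TestSelectKmers:
    def test_too_short_sequence_has_no_kmers(self):
        r = ProteinRecord(id="a", sequence="ACDEFGHIK")  # length k-1
        assert select_kmers(r, DEFAULTS) == set()

    def test_length_k_gives_single_kmer(self):
        r = ProteinRecord(id="a", sequence="ACDEFGHIKL")
        kms = select_kmers(r, DEFAULTS)
        assert {km for km, _ in kms} == {"ACDEFGHIKL"}

    def test_matches_full_sort_oracle(self, rng):
        seq = random_sequence(rng, 40)  # ~30 distinct 10-mers, m=20
        r = ProteinRecord(id="a", sequence=seq)
        selected = select_kmers(r, DEFAULTS)
        all_kmers = {seq[i : i + 10] for i in range(len(seq) - 9)}
        oracle = sorted(
            (_hash_kmer(km, DEFAULTS.hash_seed), km) for km in all_kmers
        )[:20]
        assert selected == {(km, h) for h, km in oracle}

    def test_deterministic_across_calls(self, rng):
        r = ProteinRecord(id="a", sequence=random_sequence(rng, 80))
        assert select_kmers(r, DEFAULTS) == select_kmers(r, DEFAULTS)

    def test_seed_changes_selection(self, rng):
        r = ProteinRecord(id="a", sequence=random_sequence(rng, 80))
        other = ClusterParams(hash_seed=99)
        assert select_kmers(r, DEFAULTS) != select_kmers(r, other)


class TestAlignPair:
    def align(self, q, t, params=DEFAULTS):
        return align_pair(
            ProteinRecord(id="q", sequence=q),
            ProteinRecord(id="t", sequence=t),
            params,
        )

    def test_identical_sequences(self):
        res = self.align("ACDEFGHIK", "ACDEFGHIK")
        assert res.identity == 1.0
        assert res.coverage_query == 1.0
        assert res.coverage_target == 1.0

    def test_terminal_truncation_lowers_coverage_not_identity(self):
        res = self.align("ACDEFGHIK", "ACDEFGH")
        assert res.identity == 1.0
        assert res.coverage_query == pytest.approx(7 / 9)
        assert res.coverage_target == 1.0

    def test_disjoint_sequences_zero_identity(self):
        assert self.align("AAAA", "WWWW").identity == 0.0

    def test_symmetric_coverages_swap(self, rng):
        a, b = random_sequence(rng, 60), random_sequence(rng, 45)
        ab = self.align(a, b)
        ba = self.align(b, a)
        assert ab.coverage_query == pytest.approx(ba.coverage_target)
        assert ab.coverage_target == pytest.approx(ba.coverage_query)


class TestPassesThresholds:
    def make(self, identity, cq, ct):
        from smorfscape.clustering import PairwiseResult

        return PairwiseResult(identity=identity, coverage_query=cq,
                              coverage_target=ct, score=0)

    def test_one_coverage_below_bidirectional_fails(self):
        assert not passes_thresholds(self.make(0.9, 0.78, 1.0), DEFAULTS)

    def test_coverage_half_rescues_truncation(self):
        relaxed = ClusterParams(min_coverage=0.5)
        assert passes_thresholds(self.make(0.9, 0.78, 1.0), relaxed)

    def test_thresholds_are_inclusive(self):
        assert passes_thresholds(self.make(0.8, 0.8, 0.8), DEFAULTS)

    @pytest.mark.parametrize(
        "mode,cq,ct,expected",
        [("target", 0.2, 0.9, True), ("query", 0.9, 0.2, True),
         ("query", 0.2, 0.9, False)],
    )
    def test_one_sided_coverage_modes(self, mode, cq, ct, expected):
        params = ClusterParams(coverage_mode=mode)
        assert passes_thresholds(self.make(0.9, cq, ct), params) is expected


class TestClusterLinear:
    def test_exact_duplicates_form_one_cluster(self, rng):
        seq = random_sequence(rng, 60)
        recs = records_from({f"c{i}": seq for i in range(5)})
        cs = cluster_linear(recs, DEFAULTS)
        assert len(cs.clusters) == 1
        assert cs.clusters[0].size == 5
        assert cs.clusters[0].representative_id == "c0"

    def test_unrelated_sequences_stay_singletons(self, rng):
        recs = records_from(
            {"a": random_sequence(rng, 80), "b": random_sequence(rng, 80)}
        )
        linear = cluster_linear(recs, DEFAULTS)
        brute = cluster_bruteforce(recs, DEFAULTS)
        assert len(linear.clusters) == 2
        assert partition(linear) == partition(brute)

    def test_truncation_coclustering_matches_coverage_rule(self, rng):
        full = random_sequence(rng, 80)
        recs = records_from({"p": full, "p90": full[:72], "p50": full[:40]})
        cs = cluster_linear(recs, DEFAULTS)
        memb = cs.membership()
        assert memb["p90"] == memb["p"]  # 90% fragment joins
        assert memb["p50"] != memb["p"]  # 50% fragment stays out at default

    def test_duplicate_ids_rejected(self, rng):
        seq = random_sequence(rng, 60)
        recs = [ProteinRecord(id="a", sequence=seq)] * 2
        with pytest.raises(ValueError, match="duplicate"):
            cluster_linear(recs, DEFAULTS)

    def test_partition_property(self, rng):
        recs = records_from(
            {f"r{i}": random_sequence(rng, int(rng.integers(30, 100)))
             for i in range(40)}
        )
        cs = cluster_linear(recs, DEFAULTS)
        members = [m for c in cs.clusters for m in c.member_ids]
        assert sorted(members) == sorted(r.id for r in recs)
        assert sum(c.size for c in cs.clusters) == len(recs)

    def test_representative_is_longest_member(self, rng):
        anc = random_sequence(rng, 80)
        recs = records_from({"zlong": anc, "a90": anc[:72], "b90": anc[:73]})
        cs = cluster_linear(recs, DEFAULTS)
        assert len(cs.clusters) == 1
        assert cs.clusters[0].representative_id == "zlong"

    def test_order_independence(self, rng):
        anc = [random_sequence(rng, 70) for _ in range(5)]
        named = {}
        for i, a in enumerate(anc):
            for j in range(4):
                named[f"f{i}m{j}"] = mutate(rng, a, 0.02)
        recs = records_from(named)
        forward = cluster_linear(recs, DEFAULTS)
        backward = cluster_linear(list(reversed(recs)), DEFAULTS)
        assert partition(forward) == partition(backward)

    def test_mutated_copies_cocluster_at_5_percent(self, rng):
        hits = total = 0
        for i in range(20):
            anc = random_sequence(rng, int(rng.integers(60, 101)))
            named = {f"p{i}": anc}
            named.update({f"p{i}m{j}": mutate(rng, anc, 0.05) for j in range(5)})
            memb = cluster_linear(records_from(named), DEFAULTS).membership()
            hits += sum(memb[f"p{i}m{j}"] == memb[f"p{i}"] for j in range(5))
            total += 5
        assert hits / total >= 0.9

    def test_lower_coverage_never_splits_clusters(self, rng):
        full = random_sequence(rng, 90)
        recs = records_from({"p": full, "t85": full[:77], "t60": full[:54]})
        strict = cluster_linear(recs, DEFAULTS)
        relaxed = cluster_linear(recs, ClusterParams(min_coverage=0.5))
        # every strict cluster is contained in one relaxed cluster
        relaxed_memb = relaxed.membership()
        for cluster in strict.clusters:
            assert len({relaxed_memb[m] for m in cluster.member_ids}) == 1


class TestClusterBruteforce:
    def test_singleton_input(self, rng):
        recs = records_from({"a": random_sequence(rng, 50)})
        cs = cluster_bruteforce(recs, DEFAULTS)
        assert [c.member_ids for c in cs.clusters] == [["a"]]

    def test_duplicates_merge(self, rng):
        seq = random_sequence(rng, 50)
        cs = cluster_bruteforce(records_from({"a": seq, "b": seq}), DEFAULTS)
        assert len(cs.clusters) == 1

    def test_recovers_planted_partition(self, rng):
        named, planted = {}, {}
        for f in range(10):
            anc = random_sequence(rng, int(rng.integers(50, 90)))
            for j in range(5):
                rid = f"f{f}m{j}"
                named[rid] = mutate(rng, anc, 0.03)
                planted[rid] = f
        cs = cluster_bruteforce(records_from(named), DEFAULTS)
        got = {
            frozenset(c.member_ids) for c in cs.clusters
        }
        want = {
            frozenset(r for r, fam in planted.items() if fam == f)
            for f in range(10)
        }
        assert got == want


def partition(cluster_set):
    return {frozenset(c.member_ids) for c in cluster_set.clusters}


class TestOracleAgreement:
    def test_linear_equals_bruteforce_on_separated_families(self, rng):
        for trial in range(5):
            named = {}
            for f in range(6):
                anc = random_sequence(rng, int(rng.integers(60, 90)))
                named[f"t{trial}f{f}m0"] = anc
                for j in range(1, 5):
                    named[f"t{trial}f{f}m{j}"] = mutate(rng, anc, 0.02)
            for s in range(5):
                named[f"t{trial}noise{s}"] = random_sequence(rng, 70)
            recs = records_from(named)
            assert partition(cluster_linear(recs, DEFAULTS)) == partition(
                cluster_bruteforce(recs, DEFAULTS)
            )
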