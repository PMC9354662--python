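import itertools

import numpy as np
import pytest

from conftest import mutate, random_sequence, records_from

from smorfscape.annotation import (
    AnnotationDB,
    DBEntry,
    LineageTable,
    UNANNOTATED,
    UNRESOLVED,
    assign_annotation,
    build_db,
    knn,
    load_db,
    match_known_genes,
    normalize_taxon_to_family,
    save_db,
)
from smorfscape.clustering import ClusterParams, align_pair, passes_thresholds
from smorfscape.embedding import EmbedderSpec
from smorfscape.families import SmallProteinFamily
from smorfscape.io import ProteinRecord

SPEC = EmbedderSpec(dimension=32, seed=0)


def entry(eid, vector, ecs=(), taxon=None, name="protein"):
    return DBEntry(
        id=eid, sequence="ACDEFGHIKL", vector=np.asarray(vector, dtype=float),
        ec_numbers=list(ecs), taxon=taxon, protein_name=name,
    )


def toy_db(entries):
    return AnnotationDB(entries=entries, embedder=EmbedderSpec(dimension=len(entries[0].vector)))


class TestBuildDB:
    def make_source(self, rng):
        recs = []
        anc = random_sequence(rng, 60)
        recs.append(ProteinRecord(
            id="a1", sequence=anc,
            description="Catalase EC=1.11.1.6 OS=Escherichia coli OX=562"))
        recs.append(ProteinRecord(
            id="a2", sequence=mutate(rng, anc, 0.01),
            description="Catalase-like protein OS=Escherichia coli OX=562",
            taxon="Escherichia coli"))
        recs.append(ProteinRecord(
            id="u1", sequence=random_sequence(rng, 50),
            description="Uncharacterized protein OS=uncultured bacterium"))
        recs.append(ProteinRecord(
            id="l1", sequence=random_sequence(rng, 101),
            description="Long protein EC=2.7.7.7 OS=Escherichia coli OX=562"))
        recs.append(ProteinRecord(
            id="b1", sequence=random_sequence(rng, 55),
            description="Kinase EC=2.7.13.3 OS=Bacillus subtilis OX=1423"))
        return recs

    def test_filters_and_dedup_preference(self, rng):
        db = build_db(self.make_source(rng), SPEC)
        ids = {e.id for e in db.entries}
        assert "u1" not in ids  # uncharacterized dropped
        assert "l1" not in ids  # too long
        assert "a1" in ids and "a2" not in ids  # EC-bearing member survives dedup
        assert "b1" in ids

    def test_no_redundant_pair_survives(self, rng):
        db = build_db(self.make_source(rng), SPEC)
        params = ClusterParams()
        for e1, e2 in itertools.combinations(db.entries, 2):
            res = align_pair(
                ProteinRecord(id=e1.id, sequence=e1.sequence),
                ProteinRecord(id=e2.id, sequence=e2.sequence),
                params,
            )
            assert not passes_thresholds(res, params)

    def test_empty_survivor_set_rejected(self, rng):
        only_decoys = [
            ProteinRecord(id="u1", sequence=random_sequence(rng, 40),
                          description="Uncharacterized protein")
        ]
        with pytest.raises(ValueError, match="survive"):
            build_db(only_decoys, SPEC)

    def test_roundtrip_through_disk(self, rng, tmp_path):
        db = build_db(self.make_source(rng), SPEC)
        save_db(db, tmp_path / "db")
        back = load_db(tmp_path / "db")
        assert [e.id for e in back.entries] == [e.id for e in db.entries]
        assert np.array_equal(back.vectors, db.vectors)
        assert [e.ec_numbers for e in back.entries] == [
            e.ec_numbers for e in db.entries
        ]


class TestKNN:
    def test_exact_hit_first_at_distance_zero(self):
        db = toy_db([entry("a", [0, 0]), entry("b", [1, 0]), entry("c", [0, 2])])
        hits = knn(db, np.array([1.0, 0.0]), k=2)
        assert hits[0][0].id == "b" and hits[0][1] == 0.0

    def test_k_larger_than_db_returns_all(self):
        db = toy_db([entry("a", [0, 0]), entry("b", [1, 0])])
        assert len(knn(db, np.array([0.0, 0.0]), k=7)) == 2

    def test_distance_ties_break_by_id(self):
        db = toy_db([entry("z", [1, 0]), entry("a", [-1, 0])])
        hits = knn(db, np.array([0.0, 0.0]), k=2)
        assert [h[0].id for h in hits] == ["a", "z"]

    def test_dimension_mismatch_rejected(self):
        db = toy_db([entry("a", [0, 0])])
        with pytest.raises(ValueError, match="mismatch"):
            knn(db, np.array([0.0, 0.0, 0.0]), k=1)

    def test_agrees_with_linear_scan(self, rng):
        vectors = rng.standard_normal((200, 8))
        db = toy_db([entry(f"e{i:03d}", vectors[i]) for i in range(200)])
        q = rng.standard_normal(8)
        hits = knn(db, q, k=10)
        oracle = sorted(
            ((np.linalg.norm(vectors[i] - q), f"e{i:03d}") for i in range(200))
        )[:10]
        assert [(h[0].id, pytest.approx(h[1])) for h in hits] == [
            (eid, pytest.approx(d)) for d, eid in oracle
        ]


def neighbors_from_labels(labels):
    """Neighbor list at ascending distances; None means no EC annotation."""
    out = []
    for i, lab in enumerate(labels):
        ecs = [lab] if lab else []
        out.append((entry(f"n{i:02d}", [0, 0], ecs=ecs), 0.1 * (i + 1)))
    return out


def oracle_assign(labels):
    """Independent rule evaluator: unique mode wins; tie -> first-seen tied
    label; no labels -> UNANNOTATED."""
    labeled = [l for l in labels if l]
    if not labeled:
        return UNANNOTATED, 0
    counts = {}
    for l in labeled:
        counts[l] = counts.get(l, 0) + 1
    top = max(counts.values())
    tied = [l for l in labeled if counts[l] == top]
    return tied[0], top


class TestAssignAnnotation:
    def test_modal_label_wins(self):
        nb = neighbors_from_labels(["1.11.1.6", "1.11.1.6", "2.7.7.7"])
        a = assign_annotation("f", nb, "EC")
        assert (a.label, a.support) == ("1.11.1.6", 2)

    def test_tie_broken_by_nearest(self):
        nb = neighbors_from_labels(["a", "b"])
        assert assign_annotation("f", nb, "EC").label == "a"

    def test_no_labeled_neighbor_is_unannotated(self):
        nb = neighbors_from_labels([None, None, None])
        a = assign_annotation("f", nb, "EC")
        assert (a.label, a.support) == (UNANNOTATED, 0)

    def test_taxonomy_field_reads_taxon(self):
        nb = [(entry("n0", [0, 0], taxon="Escherichia coli"), 0.1)]
        assert assign_annotation("f", nb, "taxonomy").label == "Escherichia coli"

    def test_unknown_field_rejected(self):
        with pytest.raises(ValueError):
            assign_annotation("f", [], "GO")

    def test_matches_enumeration_oracle(self):
        labels3 = ["a", "b", "c", None]
        for n in range(0, 6):
            for combo in itertools.product(labels3, repeat=n):
                got = assign_annotation("f", neighbors_from_labels(combo), "EC")
                want_label, want_support = oracle_assign(combo)
                assert (got.label, got.support) == (want_label, want_support), combo

    def test_permuting_same_label_neighbors_is_invariant(self):
        base = ["a", "a", "b"]
        results = {
            assign_annotation("f", neighbors_from_labels(p), "EC").label
            for p in itertools.permutations(base)
        }
        assert results == {"a"}


class TestNormalizeTaxon:
    def lineage(self):
        return LineageTable({
            "Blautia producta": ("species", "Blautia"),
            "Blautia": ("genus", "Lachnospiraceae"),
            "Lachnospiraceae": ("family", "Bacteria"),
            "Bacteria": ("superkingdom", None),
        })

    def test_species_resolves_to_family(self):
        assert (
            normalize_taxon_to_family("Blautia producta", self.lineage())
            == "Lachnospiraceae"
        )

    def test_family_rank_resolves_to_itself(self):
        assert (
            normalize_taxon_to_family("Lachnospiraceae", self.lineage())
            == "Lachnospiraceae"
        )

    def test_absent_taxon_unresolved(self):
        assert normalize_taxon_to_family("Martian microbe", self.lineage()) == UNRESOLVED

    def test_lineage_without_family_rank_unresolved(self):
        assert normalize_taxon_to_family("Bacteria", self.lineage()) == UNRESOLVED


class TestMatchKnownGenes:
    def family_of(self, rng, seq, size, fid):
        members = records_from({f"{fid}m{j}": seq for j in range(size)})
        return SmallProteinFamily(
            family_id=fid, representative=members[0], members=members
        )

    def test_identical_gene_reports_family_size(self, rng):
        seq = random_sequence(rng, 60)
        fams = {"s1": [self.family_of(rng, seq, 12, "f0")]}
        gene = ProteinRecord(id="senS", sequence=seq)
        rows = match_known_genes(fams, [gene])
        assert rows == [{"gene_id": "senS", "sample_id": "s1", "copy_number": 12}]

    def test_unrelated_gene_reports_zero(self, rng):
        fams = {"s1": [self.family_of(rng, random_sequence(rng, 60), 5, "f0")]}
        gene = ProteinRecord(id="agrD", sequence=random_sequence(rng, 60))
        assert match_known_genes(fams, [gene])[0]["copy_number"] == 0

    def test_three_substitution_variant_still_matches(self, rng):
        seq = random_sequence(rng, 50)
        variant = list(seq)
        for pos in (5, 20, 40):
            variant[pos] = "W" if seq[pos] != "W" else "Y"
        fams = {"s1": [self.family_of(rng, "".join(variant), 6, "f0")]}
        gene = ProteinRecord(id="senS", sequence=seq)
        assert match_known_genes(fams, [gene])[0]["copy_number"] == 6


class TestExternalAnnotationImport:
    def test_importer_parses_ec_and_taxon(self, tmp_path):
        from smorfscape.annotation import read_external_annotations_tsv
        from smorfscape.io import write_tsv_table

        rows = [
            {"query": "f1", "ec": "1.11.1.6;2.7.7.7", "taxon": "Escherichia coli"},
            {"query": "f2", "ec": "", "taxon": ""},
        ]
        p = tmp_path / "ext.tsv"
        write_tsv_table(rows, p)
        ann = read_external_annotations_tsv(p)
        assert ann["f1"]["ec_numbers"] == ["1.11.1.6", "2.7.7.7"]
        assert ann["f1"]["taxon"] == "Escherichia coli"
        assert ann["f2"] == {"ec_numbers": [], "taxon": None}
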