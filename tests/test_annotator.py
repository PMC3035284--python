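"""The value hierarchy and attribute assignment."""

import itertools

import pytest

from metannot.annotator import (
    HIERARCHY,
    EvidenceBundle,
    MappingTables,
    annotate,
    annotation_header_fields,
    assign_common_name,
    assign_ec,
    assign_gene_symbol,
    assign_go,
    assign_role,
    collect_bundles,
    parse_annotation_header,
    rank_bundle,
    read_summary_tsv,
    write_annotation_fasta,
    write_run_report,
    write_summary_tsv,
)
from metannot.core_io import SeqRecord
from metannot.evidence import BlastClass, PriamHit, TmhmmResult

from conftest import DATA_DIR, bundle_from_catalogue, make_blast_hit, make_hmm_hit


def bundle(**kw):
    defaults = dict(peptide_id="pep1", peptide_len=100)
    defaults.update(kw)
    return EvidenceBundle(**defaults)


class TestHierarchyTable:
    def test_matches_transcribed_fixture(self):
        rows = [
            tuple(line.split("\t"))
            for line in (DATA_DIR / "hierarchy_fixture.tsv").read_text().splitlines()
        ]
        fixture = tuple((int(r), t, c) for r, t, c in rows)
        assert HIERARCHY == fixture
        assert len(HIERARCHY) == 25

    def test_duplicate_class_resolves_to_best_rank(self):
        # "TIGRfam Domain" appears at ranks 5 and 18; items get rank 5
        b = bundle(hmm=[make_hmm_hit(isotype="domain", library="TIGRFAM")])
        assert rank_bundle(b)[0].rank == 5


class TestRankBundle:
    def test_equivalog_beats_pfam_domain_and_high_confidence_blast(self):
        b = bundle(
            hmm=[
                make_hmm_hit(model_id="TIGR1", library="TIGRFAM", isotype="equivalog"),
                make_hmm_hit(model_id="PF1", library="PFAM", isotype="domain"),
            ],
            blast=[(make_blast_hit(), BlastClass.HIGH_CONFIDENCE)],
        )
        ranked = rank_bundle(b)
        assert [r.rank for r in ranked] == [1, 17, 19, 25]
        assert ranked[0].payload.model.model_id == "TIGR1"

    def test_empty_bundle_yields_default_sentinel(self):
        (only,) = rank_bundle(bundle())
        assert only.rank == 25 and only.evidence_type == "DEFAULT"

    def test_within_rank_tiebreak_by_evalue(self):
        b = bundle(
            hmm=[
                make_hmm_hit(model_id="TIGRB", evalue=1e-20),
                make_hmm_hit(model_id="TIGRA", evalue=1e-40),
            ]
        )
        ranked = rank_bundle(b)
        assert ranked[0].payload.model.model_id == "TIGRA"

    def test_low_confidence_blast_and_zero_helix_tmhmm_excluded(self):
        b = bundle(
            blast=[(make_blast_hit(), BlastClass.LOW_CONFIDENCE)],
            tmhmm=TmhmmResult("pep1", 0, 0.0),
        )
        assert [r.rank for r in rank_bundle(b)] == [25]

    def test_head_always_has_minimal_rank_exhaustively(self, evidence_catalogue):
        # all bundles of <=4 distinct items from the 12-item catalogue
        for k in (1, 2, 3, 4):
            for combo in itertools.combinations(evidence_catalogue, k):
                ranked = rank_bundle(bundle_from_catalogue(combo))
                assert ranked[0].rank == min(r for r, _, _ in combo)

    def test_adding_weaker_evidence_never_changes_the_head(self, evidence_catalogue):
        strong = evidence_catalogue[0]  # rank 1
        for extra in evidence_catalogue[1:]:
            with_extra = rank_bundle(bundle_from_catalogue([strong, extra]))
            assert with_extra[0].rank == 1
            # removing the head promotes exactly the next item
            assert rank_bundle(bundle_from_catalogue([extra]))[0].rank == with_extra[1].rank


class TestAssignCommonName:
    def test_hmm_head_names_from_model(self):
        b = bundle(hmm=[make_hmm_hit(name="glutamine synthetase, catalytic domain", model_id="PF00120", library="PFAM")])
        assert assign_common_name(rank_bundle(b)) == (
            "glutamine synthetase, catalytic domain", "PF00120",
        )

    def test_priam_head_falls_through_to_next_eligible(self):
        b = bundle(
            priam=[PriamHit("pep1", "1.1.1.1", 1e-20, "pd1")],
            blast=[(make_blast_hit(name="putative widget", subject_id="S9"), BlastClass.HIGH_CONFIDENCE)],
        )
        assert rank_bundle(b)[0].evidence_type == "PRIAM"
        assert assign_common_name(rank_bundle(b)) == ("putative widget", "S9")

    def test_priam_only_bundle_is_hypothetical(self):
        b = bundle(priam=[PriamHit("pep1", "1.1.1.1", 1e-20, "pd1")])
        name, ev = assign_common_name(rank_bundle(b))
        assert name == "hypothetical protein"

    def test_motif_level_names(self):
        from metannot.evidence import LipoMotifHit

        b = bundle(tmhmm=TmhmmResult("pep1", 4, 80.0))
        assert assign_common_name(rank_bundle(b))[0] == "putative membrane protein"
        b = bundle(lipo=LipoMotifHit("pep1", 14, "LAAC"))
        assert assign_common_name(rank_bundle(b))[0] == "putative lipoprotein"

    def test_empty_bundle_hypothetical(self):
        assert assign_common_name(rank_bundle(bundle()))[0] == "hypothetical protein"


class TestAssignGeneSymbol:
    def test_curated_hit_supplies_symbol(self):
        b = bundle(blast=[(make_blast_hit(curated=True, symbol="glnT", subject_id="ACC1"), BlastClass.HIGH_CONFIDENCE)])
        assert assign_gene_symbol(b, rank_bundle(b)) == ("glnT", "ACC1")

    def test_hmm_head_symbol_has_primacy(self):
        b = bundle(
            hmm=[make_hmm_hit(symbol="abcZ", model_id="TIGR9")],
            blast=[(make_blast_hit(curated=True, symbol="glnT"), BlastClass.HIGH_CONFIDENCE)],
        )
        assert assign_gene_symbol(b, rank_bundle(b)) == ("abcZ", "TIGR9")

    def test_no_curated_hits_means_no_symbol(self):
        b = bundle(blast=[(make_blast_hit(symbol="x"), BlastClass.HIGH_CONFIDENCE)])
        assert assign_gene_symbol(b, rank_bundle(b)) == ("", "")

    def test_better_sorted_curated_hit_wins(self):
        b = bundle(
            blast=[
                (make_blast_hit(curated=True, symbol="aaaA", subject_id="A", evalue=1e-50), BlastClass.HIGH_CONFIDENCE),
                (make_blast_hit(curated=True, symbol="bbbB", subject_id="B", evalue=1e-20), BlastClass.HIGH_CONFIDENCE),
            ]
        )
        assert assign_gene_symbol(b, rank_bundle(b))[0] == "aaaA"


class TestAssignEcGoRole:
    def test_ec_precedence_tigrfam_over_priam_over_pfam(self):
        tigr = make_hmm_hit(model_id="TIGR5", library="TIGRFAM", ec=("1.1.1.1",))
        pfam = make_hmm_hit(model_id="PF5", library="PFAM", ec=("3.3.3.3",))
        priam = PriamHit("pep1", "2.2.2.2", 1e-15, "pd5")
        b = bundle(hmm=[tigr, pfam], priam=[priam])
        assert assign_ec(b) == ("1.1.1.1", "TIGR5")
        b = bundle(hmm=[pfam], priam=[priam])
        assert assign_ec(b) == ("2.2.2.2", "pd5")
        b = bundle(hmm=[pfam])
        assert assign_ec(b) == ("3.3.3.3", "PF5")

    def test_go_evidence_order(self):
        maps = MappingTables(ec_to_go={"2.2.2.2": ("GO:0000002",)})
        tigr = make_hmm_hit(model_id="TIGR5", library="TIGRFAM", go=("GO:0000001",))
        pfam = make_hmm_hit(model_id="PF5", library="PFAM", go=("GO:0000003",))
        cur = (make_blast_hit(curated=True, go=["GO:0000004"], subject_id="C1"), BlastClass.HIGH_CONFIDENCE)
        b = bundle(hmm=[tigr, pfam], priam=[PriamHit("pep1", "2.2.2.2", 1e-15, "pd")], blast=[cur])
        assert assign_go(b, maps) == (["GO:0000001"], ["TIGR5"])
        b = bundle(hmm=[pfam], priam=[PriamHit("pep1", "2.2.2.2", 1e-15, "pd")], blast=[cur])
        assert assign_go(b, maps) == (["GO:0000002"], ["2.2.2.2"])
        b = bundle(hmm=[pfam], blast=[cur])
        assert assign_go(b, maps) == (["GO:0000003"], ["PF5"])
        b = bundle(blast=[cur])
        assert assign_go(b, maps) == (["GO:0000004"], ["C1"])
        assert assign_go(bundle(), maps) == ([], [])

    def test_go_terms_deduplicated_evidence_parallel(self):
        pfam = make_hmm_hit(model_id="PF00120", library="PFAM", go=("GO:0004356", "GO:0006542", "GO:0004356"))
        terms, ev = assign_go(bundle(hmm=[pfam]), MappingTables())
        assert terms == ["GO:0004356", "GO:0006542"]
        assert ev == ["PF00120", "PF00120"]

    def test_role_precedence(self):
        tigr = make_hmm_hit(model_id="TIGR5", library="TIGRFAM", role_id=129)
        pfam = make_hmm_hit(model_id="PF00120", library="PFAM", role_id=73)
        assert assign_role(bundle(hmm=[tigr, pfam])) == ("129", "TIGR5")
        assert assign_role(bundle(hmm=[pfam])) == ("73", "PF00120")
        assert assign_role(bundle()) == ("", "")


def worked_example_bundle():
    """The documented worked example: a Pfam equivalog-class hit carrying
    name/EC/GO/role plus a curated BLAST hit supplying the symbol."""
    pfam = make_hmm_hit(
        query_id="PEP 5160785.1",
        model_id="PF00120",
        library="PFAM",
        isotype="equivalog",
        name="glutamine synthetase, catalytic domain",
        symbol=None,
        ec=("6.3.1.2",),
        go=("GO:0004356", "GO:0006542"),
        role_id=73,
    )
    cur = make_blast_hit(
        query_id="PEP 5160785.1",
        subject_id="RF|YP 266724.1|71084004|NC 007205",
        curated=True,
        symbol="glnT",
        name="glutamine synthetase",
    )
    return EvidenceBundle(
        peptide_id="PEP 5160785.1",
        peptide_len=100,
        hmm=[pfam],
        blast=[(cur, BlastClass.HIGH_CONFIDENCE)],
    )


WORKED_EXAMPLE_FIELDS = [
    "GCA1659448.b1",
    "PEP 5160785.1",
    "common_name",
    "glutamine synthetase, catalytic domain",
    "PF00120",
    "gene_symbol",
    "glnT",
    "RF|YP 266724.1|71084004|NC 007205",
    "GO",
    "GO:0004356 // GO:0006542",
    "PF00120 // PF00120",
    "EC",
    "6.3.1.2",
    "PF00120",
    "TIGR_role",
    "73",
    "PF00120",
]


class TestAnnotate:
    def test_worked_example_field_for_field(self):
        a = annotate(worked_example_bundle(), user_id="GCA1659448.b1")
        assert annotation_header_fields(a) == WORKED_EXAMPLE_FIELDS

    def test_empty_bundle_all_attributes_empty(self):
        a = annotate(bundle())
        assert a.common_name == "hypothetical protein"
        assert a.gene_symbol == "" and a.ec == "" and a.role_id == ""
        assert a.go_terms == [] and a.head_rank == 25

    def test_pure_function(self):
        b = worked_example_bundle()
        assert annotate(b) == annotate(b)

    def test_name_evidence_identifies_naming_item(self, evidence_catalogue):
        import itertools as it

        for combo in it.combinations(evidence_catalogue, 2):
            b = bundle_from_catalogue(combo)
            a = annotate(b)
            ranked = rank_bundle(b)
            head = next(r for r in ranked if r.name_eligible)
            from metannot.annotator import _evidence_string

            assert a.common_name_ev == _evidence_string(head)


class TestOutputFormats:
    def test_annotation_fasta_header_roundtrip(self, tmp_path):
        a = annotate(worked_example_bundle(), user_id="GCA1659448.b1")
        pep = SeqRecord(id="PEP 5160785.1", seq="MKTAYIAKQR")
        p = tmp_path / "ann.fasta"
        write_annotation_fasta([a], [pep], p)
        text = p.read_text()
        header = text.splitlines()[0][1:]
        assert header == "\t".join(WORKED_EXAMPLE_FIELDS)
        back = parse_annotation_header(header)
        assert annotation_header_fields(back) == WORKED_EXAMPLE_FIELDS

    def test_empty_attributes_keep_positional_fields(self, tmp_path):
        a = annotate(bundle())
        pep = SeqRecord(id="pep1", seq="MK")
        p = tmp_path / "ann.fasta"
        write_annotation_fasta([a], [pep], p)
        header = p.read_text().splitlines()[0]
        assert header.count("\t") == 16
        assert "\tGO\t\t\t" in header

    def test_unknown_peptide_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown peptide"):
            write_annotation_fasta([annotate(bundle())], [], tmp_path / "x.fasta")

    def test_summary_tsv_roundtrip_and_format(self, tmp_path):
        annos = [
            annotate(worked_example_bundle(), user_id="GCA1659448.b1"),
            annotate(bundle()),
            annotate(bundle(peptide_id="pep2")),
        ]
        p = tmp_path / "summary.tsv"
        write_summary_tsv(annos, p)
        raw = p.read_bytes().decode("utf-8")
        lines = raw.split("\n")
        assert len([l for l in lines if l]) == 4  # header + 3 rows
        assert not any(l.endswith("\t") and "GO" not in l for l in lines[:1])
        assert "\r" not in raw
        assert [annotation_header_fields(x) for x in read_summary_tsv(p)] == [
            annotation_header_fields(a) for a in annos
        ]

    def test_run_report_counts_by_rank(self, tmp_path):
        annos = [annotate(worked_example_bundle()), annotate(bundle()), annotate(bundle())]
        p = tmp_path / "report.txt"
        write_run_report(annos, p)
        text = p.read_text()
        assert "peptides annotated\t3" in text
        assert "hypothetical\t2" in text
        assert "rank 2\tHMM\tPfam Equivalog\t1" in text


class TestCollectBundles:
    def test_orphan_evidence_warns_not_errors(self, caplog):
        import logging

        peps = [SeqRecord(id="pep1", seq="MKLLIV" * 20)]
        with caplog.at_level(logging.WARNING):
            bundles = collect_bundles(peps, blast={"ghost": []})
        assert len(bundles) == 1
        assert "match no peptide" in caplog.text

    def test_blast_hits_classified_against_peptide_length(self):
        peps = [SeqRecord(id="pep1", seq="M" * 100)]
        hit = make_blast_hit(q_start=1, q_end=90)
        bundles = collect_bundles(peps, blast={"pep1": [hit]}, scan_lipoprotein=False)
        assert bundles[0].blast[0][1] is BlastClass.HIGH_CONFIDENCE
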