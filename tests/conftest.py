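import random
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests.oracles importable as `oracles`

from metannot.core_io import CodonTable
from metannot.evidence import BlastClass, BlastHit, HmmHit, HmmModelMeta, PriamHit, TmhmmResult

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def table11() -> CodonTable:
    return CodonTable.from_ncbi(11)


def make_hmm_hit(
    query_id="pep1",
    model_id="TIGR00001",
    library="TIGRFAM",
    isotype="equivalog",
    name="widget synthase",
    symbol=None,
    ec=(),
    go=(),
    role_id=None,
    score=100.0,
    evalue=1e-30,
    trusted_cutoff=25.0,
):
    meta = HmmModelMeta(
        model_id=model_id,
        library=library,
        isotype=isotype,
        trusted_cutoff=trusted_cutoff,
        name=name,
        symbol=symbol,
        ec=tuple(ec),
        go=tuple(go),
        role_id=role_id,
    )
    return HmmHit(query_id=query_id, model=meta, total_score=score, evalue=evalue)


def make_blast_hit(
    query_id="pep1",
    subject_id="SBJ1",
    pct_identity=90.0,
    q_start=1,
    q_end=95,
    evalue=1e-40,
    bitscore=300.0,
    curated=False,
    symbol=None,
    name=None,
    go=None,
):
    return BlastHit(
        query_id=query_id,
        subject_id=subject_id,
        pct_identity=pct_identity,
        aln_len=q_end - q_start + 1,
        q_start=q_start,
        q_end=q_end,
        s_start=1,
        s_end=q_end - q_start + 1,
        evalue=evalue,
        bitscore=bitscore,
        subject_is_curated=curated,
        subject_symbol=symbol,
        subject_name=name,
        subject_go=go,
    )


@pytest.fixture
def evidence_catalogue():
    """Twelve evidence items with known hierarchy ranks, for exhaustive
    bundle-ordering checks.  Each entry: (expected_rank, kind, item)."""
    cat = [
        (1, "hmm", make_hmm_hit(model_id="TIGR00001", library="TIGRFAM", isotype="equivalog")),
        (2, "hmm", make_hmm_hit(model_id="PF00001", library="PFAM", isotype="equivalog")),
        (3, "hmm", make_hmm_hit(model_id="TIGR00003", library="TIGRFAM", isotype="hypoth_equivalog")),
        (6, "priam", PriamHit(query_id="pep1", ec="1.1.1.1", evalue=1e-20, profile_id="pd1")),
        (7, "hmm", make_hmm_hit(model_id="TIGR00007", library="TIGRFAM", isotype="subfamily")),
        (9, "hmm", make_hmm_hit(model_id="TIGR00009", library="TIGRFAM", isotype="equivalog_domain")),
        (12, "hmm", make_hmm_hit(model_id="PF00012", library="PFAM", isotype="subfamily")),
        (17, "blast", (make_blast_hit(subject_id="HC1"), BlastClass.HIGH_CONFIDENCE)),
        (19, "hmm", make_hmm_hit(model_id="PF00019", library="PFAM", isotype="domain")),
        (21, "blast", (make_blast_hit(subject_id="PU1", pct_identity=30.0), BlastClass.PUTATIVE)),
        (22, "blast", (make_blast_hit(subject_id="CD1", q_end=40), BlastClass.CONSERVED_DOMAIN)),
        (23, "tmhmm", TmhmmResult(query_id="pep1", predicted_helices=3, exp_aa_in_membrane=66.0)),
    ]
    return cat


def bundle_from_catalogue(items):
    """Assemble an EvidenceBundle from catalogue entries."""
    from metannot.annotator import EvidenceBundle

    b = EvidenceBundle(peptide_id="pep1", peptide_len=100)
    for _rank, kind, item in items:
        if kind == "hmm":
            b.hmm.append(item)
        elif kind == "blast":
            b.blast.append(item)
        elif kind == "priam":
            b.priam.append(item)
        elif kind == "tmhmm":
            b.tmhmm = item
    return b


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choices("ACGT", k=n))
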