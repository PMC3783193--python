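"""Tests for ORF finding, hit annotation and database assembly."""

import numpy as np
import pytest

from tagkit import fixtures as fx
from tagkit import protein_db_builder as db
from tagkit.cloning_sim import reverse_complement
from tagkit.errors import TagkitError

STOPS = {"TAA", "TAG", "TGA"}
CODON_AA = fx._table.forward_table


def brute_force_orfs(seq: str, min_aa: int = 100) -> set[tuple[str, int, int, int]]:
    """Independent oracle: walk codons in all 6 frames, collect
    ATG-initiated, stop-terminated proteins >= min_aa with plus-strand
    coordinates (protein, frame, start, end)."""
    out = set()
    n = len(seq)
    for strand, work in (("+", seq), ("-", reverse_complement(seq))):
        for off in range(3):
            codons = [
                (i, work[i : i + 3])
                for i in range(off, len(work) - 2, 3)
            ]
            i = 0
            while i < len(codons):
                pos, codon = codons[i]
                if codon == "ATG":
                    prot = []
                    j = i
                    while j < len(codons) and codons[j][1] not in STOPS:
                        prot.append(CODON_AA[codons[j][1]])
                        j += 1
                    if j < len(codons) and len(prot) >= min_aa:
                        s_work = pos
                        e_work = pos + 3 * len(prot)
                        if strand == "+":
                            rec = ("".join(prot), off + 1, s_work, e_work)
                        else:
                            rec = ("".join(prot), -(off + 1), n - e_work, n - s_work)
                        out.add(rec)
                    i = j
                i += 1
    return out


def _random_transcript(rng, n=700):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# ---------------------------------------------------------------- find_orfs


def test_find_orfs_single_planted_orf():
    rng = np.random.default_rng(0)
    protein = "M" + "".join(rng.choice(sorted(set("ACDEFGHIKLNPQRSTVWY")), 149))
    cds = fx._encode(rng, protein) + "TAA"
    seq = "CCCTTT" + cds + "GGGAAA"
    t = db.TranscriptRecord("c1_g1_i1", "c1_g1", seq)
    orfs = db.find_orfs(t, min_aa=100)
    assert len(orfs) == 1
    orf = orfs[0]
    assert orf.protein == protein
    assert orf.frame == 1
    assert (orf.start, orf.end) == (6, 6 + 3 * 150)
    assert orf.orf_id == "c1_g1_i1.orf1"


def test_find_orfs_all_stops_empty():
    t = db.TranscriptRecord("c1_g1_i1", "c1_g1", "TAATAGTGA" * 40)
    assert db.find_orfs(t, min_aa=5) == []


def test_find_orfs_reverse_complement_mirrors_frames():
    rng = np.random.default_rng(1)
    seq = _random_transcript(rng, 900)
    fwd = db.find_orfs(db.TranscriptRecord("t_i1", "t", seq), min_aa=20)
    rev = db.find_orfs(
        db.TranscriptRecord("t_i1", "t", reverse_complement(seq)), min_aa=20
    )
    assert sorted(o.protein for o in fwd) == sorted(o.protein for o in rev)
    assert sorted(-o.frame for o in fwd) == sorted(o.frame for o in rev)


@pytest.mark.parametrize("min_aa", [20, 50])
def test_find_orfs_equals_brute_force_on_random_transcripts(min_aa):
    """Exhaustive 6-frame enumeration oracle over 200 random transcripts."""
    rng = np.random.default_rng(42)
    for k in range(200):
        seq = _random_transcript(rng, int(rng.integers(200, 900)))
        t = db.TranscriptRecord(f"t{k}_i1", f"t{k}", seq)
        ours = {
            (o.protein, o.frame, o.start, o.end) for o in db.find_orfs(t, min_aa=min_aa)
        }
        assert ours == brute_force_orfs(seq, min_aa)


def test_find_orfs_sorted_by_length_desc():
    rng = np.random.default_rng(3)
    seq = _random_transcript(rng, 2000)
    orfs = db.find_orfs(db.TranscriptRecord("t_i1", "t", seq), min_aa=10)
    lengths = [len(o.protein) for o in orfs]
    assert lengths == sorted(lengths, reverse=True)


# ---------------------------------------------------------------- annotate


def _orf(oid="c1_g1_i1.orf1", tid="c1_g1_i1", protein="M" + "A" * 120):
    rec = db.OrfRecord(tid, 1, 0, 3 * len(protein), protein)
    rec.orf_id = oid
    return rec


def _hit(query, subject, e, bit, species):
    return db.AlignmentHit(query, subject, 95.0, 100, 5, 0, 1, 100, 1, 100, e, bit,
                           subject_species=species)


def test_annotate_both_species_independently():
    orfs = [_orf()]
    hits = [
        _hit("c1_g1_i1.orf1", "GG_X", 1e-20, 90, "chicken"),
        _hit("c1_g1_i1.orf1", "HS_Y", 1e-15, 80, "human"),
    ]
    (ann,) = db.annotate(orfs, hits)
    assert ann.name_chicken == "GG_X"
    assert ann.name_human == "HS_Y"
    assert ann.group_id == "c1_g1"


def test_annotate_cutoff_discards_weak_hits():
    orfs = [_orf()]
    hits = [_hit("c1_g1_i1.orf1", "GG_X", 1e-5, 90, "chicken")]
    (ann,) = db.annotate(orfs, hits, e_cutoff=1e-10)
    assert ann.name_chicken is None


def test_annotate_tie_break_and_order_invariance():
    orfs = [_orf()]
    hits = [
        _hit("c1_g1_i1.orf1", "GG_A", 1e-20, 80, "chicken"),
        _hit("c1_g1_i1.orf1", "GG_B", 1e-20, 95, "chicken"),
    ]
    import itertools

    for perm in itertools.permutations(hits):
        (ann,) = db.annotate(orfs, list(perm))
        assert ann.name_chicken == "GG_B"  # higher bit score wins


def test_read_hits_skips_malformed_rows(tmp_path, caplog):
    path = tmp_path / "hits.tsv"
    path.write_text(
        "# comment\n"
        "q1\tGG_X\t95\t100\t5\t0\t1\t100\t1\t100\t1e-20\t90\n"
        "broken row\n"
        "q1\tHS_Y\t95\t100\t5\t0\t1\t100\t1\t100\tnot_a_number\t80\n"
    )
    hits = db.read_hits_tsv(path, species_map={"GG_": "chicken", "HS_": "human"})
    assert len(hits) == 1
    assert hits[0].subject_species == "chicken"


# ---------------------------------------------------------------- representatives


def test_select_representatives_longest_then_lex_id():
    group = [
        _orf("B", "g_i1", "M" + "A" * 199),
        _orf("A", "g_i2", "M" + "A" * 199),
        _orf("C", "g_i3", "M" + "A" * 119),
    ]
    annotated = [
        db.AnnotatedProtein(o.orf_id, o.protein, group_id="g1") for o in group
    ]
    reps = db.select_representatives(annotated)
    assert len(reps) == 1
    assert reps[0].id == "A"
    assert len(reps[0].protein) == 200


def test_select_representatives_one_per_group(cfg):
    transcripts, hits, manifest = fx.make_transcripts(cfg)
    orfs = [o for t in transcripts for o in db.find_orfs(t, min_aa=cfg.min_aa)]
    annotated = db.annotate(orfs, hits, species_map=fx.DEFAULT_SPECIES_MAP)
    reps = db.select_representatives(annotated)
    assert len(reps) == manifest["n_groups"]
    expected = {g["representative"] for g in manifest["groups"].values()}
    assert {r.id for r in reps} == expected


# ---------------------------------------------------------------- database


def test_build_fasta_db_counts_match_ground_truth(cfg, tmp_path):
    transcripts, hits, manifest = fx.make_transcripts(cfg)
    orfs = [o for t in transcripts for o in db.find_orfs(t, min_aa=cfg.min_aa)]
    annotated = db.annotate(orfs, hits, species_map=fx.DEFAULT_SPECIES_MAP)
    reps = db.select_representatives(annotated)
    records, report = db.build_fasta_db(reps, out_path=tmp_path / "db.fasta")
    assert report["from_transcripts"] == manifest["n_groups"]
    assert report["no_chicken_annotation"] == manifest["n_without_chicken"]
    assert report["total"] == manifest["n_groups"] + report["extras"]


def test_build_fasta_db_empty_input_plus_extras(tmp_path):
    records, report = db.build_fasta_db(
        [], extras=[("Quant_peptide", "LAADITSLYK"), ("TEV_synth", "M" + "A" * 50)],
        out_path=tmp_path / "db.fasta",
    )
    assert report["total"] == 2
    text = (tmp_path / "db.fasta").read_text()
    assert text.count(">") == 2


def test_build_fasta_db_deterministic(cfg, tmp_path):
    transcripts, hits, _ = fx.make_transcripts(cfg)
    orfs = [o for t in transcripts for o in db.find_orfs(t, min_aa=cfg.min_aa)]
    annotated = db.annotate(orfs, hits, species_map=fx.DEFAULT_SPECIES_MAP)
    reps = db.select_representatives(annotated)
    db.build_fasta_db(reps, out_path=tmp_path / "a.fasta")
    db.build_fasta_db(reps, out_path=tmp_path / "b.fasta")
    assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()


def test_build_fasta_db_duplicate_ids_error():
    recs = [db.AnnotatedProtein("X", "MAAA"), db.AnnotatedProtein("X", "MCCC")]
    with pytest.raises(TagkitError):
        db.build_fasta_db(recs)
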