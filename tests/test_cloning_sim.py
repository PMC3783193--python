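"""Unit and property tests for the in-silico cloning engine."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from tagkit import cloning_sim as cs
from tagkit.cloning_sim import (
    ENZYMES,
    WT_LOXP,
    Fragment,
    NucleotideSequence,
    Primer,
    reverse_complement,
)
from tagkit.errors import (
    AmbiguousAssemblyError,
    InsufficientHomologyError,
    LigationError,
    NonSpecificPrimingError,
    NoProductError,
    RecombinationError,
    SequenceError,
    TargetingError,
    UncutSequenceError,
)

NOTI = ENZYMES["NotI"]
HINDIII = ENZYMES["HindIII"]

dna = st.text(alphabet="ACGT", min_size=1)


def lin(seq, sid="s"):
    return NucleotideSequence(sid, seq, "linear")


def circ(seq, sid="s"):
    return NucleotideSequence(sid, seq, "circular")


# ---------------------------------------------------------------- sequences


def test_sequence_rejects_ambiguity_codes_and_empty():
    with pytest.raises(SequenceError):
        NucleotideSequence("x", "ACGTN")
    with pytest.raises(SequenceError):
        NucleotideSequence("x", "")


def test_reverse_complement_involution():
    s = "GATTACAGCGGCCGC"
    assert reverse_complement(reverse_complement(s)) == s


# ---------------------------------------------------------------- find_sites


def test_find_sites_embedded_linear():
    assert cs.find_sites(lin("AAGCGGCCGCTT"), NOTI) == [2]


def test_find_sites_spanning_circular_origin():
    # brute-force oracle: scan the doubled string of the rotation
    seq = "GGCCGCAAAAGC"
    doubled = seq + seq
    oracle = sorted(
        {i % len(seq) for i in range(len(seq)) if doubled[i : i + 8] == NOTI.recognition}
    )
    assert oracle == [10]
    assert cs.find_sites(circ(seq), NOTI) == [10]


def test_find_sites_absent():
    assert cs.find_sites(lin("ATATATATATAT"), NOTI) == []


@given(dna.filter(lambda s: len(s) >= 8))
def test_find_sites_rotation_invariant(seq):
    c = circ(seq)
    base = cs.find_sites(c, NOTI)
    rot = cs.find_sites(c.rotated(3), NOTI)
    assert len(base) == len(rot)


# ---------------------------------------------------------------- digest


def test_digest_circular_single_site_conserves_length():
    seq = "A" * 46 + NOTI.recognition + "T" * 46
    frags = cs.digest(circ(seq), NOTI)
    assert len(frags) == 1
    assert len(frags[0]) == 100
    assert frags[0].end5.compatible(frags[0].end3)


def test_digest_linear_two_sites_slicing_oracle():
    left, mid, right = "AT" * 10, "CA" * 15, "GT" * 12
    seq = left + NOTI.recognition + mid + NOTI.recognition + right
    frags = cs.digest(lin(seq), NOTI)
    assert len(frags) == 3
    # oracle: direct string slicing at top-strand cuts (offset 2 into site)
    c1 = len(left) + 2
    c2 = len(left) + 8 + len(mid) + 2
    assert [f.seq for f in frags] == [seq[:c1], seq[c1:c2], seq[c2:]]
    assert "".join(f.seq for f in frags) == seq


def test_digest_linear_no_sites_returns_blunt_input():
    frags = cs.digest(lin("ACGT" * 10), NOTI)
    assert len(frags) == 1
    assert frags[0].seq == "ACGT" * 10
    assert frags[0].end5.kind == "blunt"


def test_digest_uncut_circle_raises():
    with pytest.raises(UncutSequenceError):
        cs.digest(circ("ACGT" * 10), NOTI)


@given(dna, st.sampled_from(sorted(ENZYMES)))
def test_digest_partition_property_all_enzymes(seq, enzyme_name):
    """Digestion of a linear molecule exactly partitions it, for every
    enzyme in the bundled table."""
    enzyme = ENZYMES[enzyme_name]
    frags = cs.digest(lin(seq), enzyme)
    assert "".join(f.seq for f in frags) == seq


def test_digest_ligate_digest_round_trip():
    for name, enzyme in ENZYMES.items():
        seq = "ATGCAT" * 8 + enzyme.recognition + "CCATGG" * 8
        frags = cs.digest(lin(seq), enzyme)
        assert len(frags) == 2
        rejoined = cs.ligate(frags[0], frags[1])
        assert rejoined.seq == seq
        assert [f.seq for f in cs.digest(lin(rejoined.seq), enzyme)] == [f.seq for f in frags]


# ---------------------------------------------------------------- PCR


def _random_seq(seed, n):
    import numpy as np

    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def test_pcr_identity_case():
    seq = _random_seq(17, 1000)
    f = Primer("f", anneal=seq[:20])
    r = Primer("r", anneal=reverse_complement(seq[-20:]))
    assert cs.simulate_pcr(lin(seq), f, r).seq == seq


def test_pcr_overhangs_appended():
    seq = _random_seq(23, 120)
    f = Primer("f", anneal=seq[:18], overhang="CAGTGCGGCCGC")
    r = Primer("r", anneal=reverse_complement(seq[-18:]), overhang="CAGTGCGGCCGC")
    prod = cs.simulate_pcr(lin(seq), f, r)
    assert prod.seq == "CAGTGCGGCCGC" + seq + reverse_complement("CAGTGCGGCCGC")


def test_pcr_across_circular_origin_matches_rotation_oracle():
    import numpy as np

    rng = np.random.default_rng(11)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    c = circ(seq)
    # primers facing outward across the origin: amplicon wraps
    f = Primer("f", anneal=seq[250:270])
    r = Primer("r", anneal=reverse_complement(seq[30:50]))
    prod = cs.simulate_pcr(c, f, r)
    # oracle: rotate the circle so the amplicon is contiguous
    rotated = seq[250:] + seq[:250]
    assert prod.seq == rotated[: len(prod)]
    assert prod.seq == seq[250:] + seq[:50]


def test_pcr_strand_symmetry():
    import numpy as np

    rng = np.random.default_rng(5)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
    f = Primer("f", anneal=seq[10:30], overhang="GGCC")
    r = Primer("r", anneal=reverse_complement(seq[360:380]), overhang="TTAA")
    prod = cs.simulate_pcr(lin(seq), f, r)
    # swap primers on the reverse-complement template
    prod_rc = cs.simulate_pcr(lin(reverse_complement(seq)), r, f)
    assert prod_rc.seq == reverse_complement(prod.seq)


def test_pcr_nonspecific_and_facing_away_errors():
    seq = "ATGCATGCATGCATGCA" * 4  # repeated: primer binds 4x
    with pytest.raises(NonSpecificPrimingError):
        cs.simulate_pcr(lin(seq), Primer("f", anneal=seq[:17]),
                        Primer("r", anneal=reverse_complement(seq[-17:])))
    import numpy as np

    rng = np.random.default_rng(3)
    uniq = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
    with pytest.raises(NoProductError):
        cs.simulate_pcr(
            lin(uniq),
            Primer("f", anneal=uniq[150:170]),
            Primer("r", anneal=reverse_complement(uniq[20:40])),
        )


# ---------------------------------------------------------------- ligation


def test_self_circularize_round_trip():
    seq = "AT" * 20 + NOTI.recognition + "GC" * 20 + NOTI.recognition + "TA" * 20
    mid = cs.digest(lin(seq), NOTI)[1]
    circle = cs.self_circularize(mid)
    assert circle.is_circular
    assert len(circle) == len(mid)
    refrag = cs.digest(circle, NOTI)
    assert len(refrag) == 1
    assert refrag[0].seq == mid.seq


def test_self_circularize_blunt_and_mixed():
    blunt = Fragment("ACGT" * 10)
    assert len(cs.self_circularize(blunt)) == 40
    mixed = Fragment("ACGT" * 10, end5=cs.End("5ext", "GGCC"), end3=cs.BLUNT)
    with pytest.raises(LigationError):
        cs.self_circularize(mixed)


# ---------------------------------------------------------------- SLIC


def _slic_parts(seed=0):
    import numpy as np

    rng = np.random.default_rng(seed)
    mk = lambda n: "".join("ACGT"[i] for i in rng.integers(0, 4, n))
    a, b = mk(30), mk(30)
    vec = b + mk(400) + a  # vector: ...a at 3' end, b at 5' end
    ins = a + mk(300) + b
    return vec, ins, a, b


def test_slic_assemble_30bp_overlaps():
    vec, ins, a, b = _slic_parts()
    res = cs.slic_assemble(lin(vec, "v"), lin(ins, "i"), min_overlap=25)
    assert (res.overlap5, res.overlap3) == (30, 30)
    assert len(res.product) == len(vec) + len(ins) - 60
    assert res.product.is_circular


def test_slic_assemble_reverse_complement_insert_same_circle():
    vec, ins, _, _ = _slic_parts(1)
    fwd = cs.slic_assemble(lin(vec, "v"), lin(ins, "i"))
    rev = cs.slic_assemble(lin(vec, "v"), lin(reverse_complement(ins), "i"))
    assert fwd.product.seq == rev.product.seq
    assert rev.insert_flipped


def test_slic_assemble_short_overlap_rejected():
    import numpy as np

    rng = np.random.default_rng(2)
    mk = lambda n: "".join("ACGT"[i] for i in rng.integers(0, 4, n))
    a, b = mk(20), mk(20)
    vec, ins = b + mk(200) + a, a + mk(150) + b
    with pytest.raises(InsufficientHomologyError):
        cs.slic_assemble(lin(vec, "v"), lin(ins, "i"), min_overlap=25)


# ---------------------------------------------------------------- Cre/loxP


def test_cre_excise_definitional():
    a, b, c = "ACGT" * 5, "GGCCTTAA" * 4, "TTGGCCAA" * 3
    seq = a + WT_LOXP + b + WT_LOXP + c
    remaining, excised = cs.cre_excise(lin(seq))
    assert remaining.seq == a + WT_LOXP + c
    assert excised.is_circular
    assert excised.seq == WT_LOXP + b  # one loxP travels with the circle
    assert len(remaining) + len(excised) == len(seq)


@given(dna, dna, dna)
def test_cre_excise_length_conservation(a, b, c):
    seq = a + WT_LOXP + b + WT_LOXP + c
    if seq.count(WT_LOXP) != 2 or reverse_complement(WT_LOXP) in seq:
        return
    remaining, excised = cs.cre_excise(lin(seq))
    assert len(remaining) + len(excised) == len(seq)
    assert remaining.seq.count(WT_LOXP) == 1
    assert excised.seq.count(WT_LOXP) == 1


def test_cre_excise_errors():
    with pytest.raises(RecombinationError):
        cs.cre_excise(lin("AAAA" + WT_LOXP + "TTTT"))
    opposite = "AAAA" + WT_LOXP + "CCCC" + reverse_complement(WT_LOXP) + "TTTT"
    with pytest.raises(RecombinationError):
        cs.cre_excise(lin(opposite))


# ---------------------------------------------------------------- HR


def _hr_case(seed=0, min_arm=200):
    import numpy as np

    rng = np.random.default_rng(seed)
    mk = lambda n: "".join("ACGT"[i] for i in rng.integers(0, 4, n))
    genome = mk(6000)
    left = genome[2000:2000 + min_arm + 300]
    right = genome[2000 + min_arm + 300 : 2000 + 2 * (min_arm + 300)]
    cassette = mk(1500)
    construct = left + cassette + right
    expected = genome[: 2000 + len(left)] + cassette + genome[2000 + len(left) :]
    return lin(genome, "g"), lin(construct, "c"), expected


def test_hr_integration_matches_splice_oracle():
    genome, construct, expected = _hr_case()
    out = cs.simulate_hr_integration(genome, construct, min_arm=200)
    assert out.seq == expected


def test_hr_integration_tolerates_terminal_scar():
    genome, construct, expected = _hr_case(1)
    scarred = lin("GGCCGC" + construct.seq + "GC", "c")
    out = cs.simulate_hr_integration(genome, scarred, min_arm=200, end_trim=8)
    assert out.seq == expected


def test_hr_integration_scrambled_and_swapped_arms_fail():
    import numpy as np

    genome, construct, _ = _hr_case(2)
    rng = np.random.default_rng(0)
    scramble = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
    scrambled = lin(scramble + construct.seq[500:], "c2")
    with pytest.raises(TargetingError):
        cs.simulate_hr_integration(genome, scrambled, min_arm=200)
    # arms swapped: wrong relative order
    left, right = construct.seq[:500], construct.seq[-500:]
    swapped = lin(right + construct.seq[500:-500] + left, "c3")
    with pytest.raises(TargetingError):
        cs.simulate_hr_integration(genome, swapped, min_arm=200)


@given(st.integers(0, 99))
def test_hr_integration_random_loci_equal_string_splice(seed):
    """Three-way string-splice oracle over random synthetic loci."""
    genome, construct, expected = _hr_case(seed, min_arm=150)
    out = cs.simulate_hr_integration(genome, construct, min_arm=150)
    assert out.seq == expected
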