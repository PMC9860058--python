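"""Sequence design: GC, recoding, motif scanning, TSD detection, PFMs."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from isgarden.seq_design import (
    IUPAC_SETS,
    CodingSequence,
    NucleotideSequence,
    TargetMotif,
    build_pfm,
    find_tsd,
    flank_gc_asymmetry,
    gc_fraction,
    recode_to_gc,
    scan_motif,
    translate,
    available_sites,
)
from isgarden.simulate import make_insertion_allele, random_cds, random_sequence

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


def _random_cds_strategy(max_codons=50):
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[11]
    nonstop = sorted(table.forward_table)
    return st.lists(st.sampled_from(nonstop), min_size=2, max_size=max_codons).map(
        lambda codons: "ATG" + "".join(codons)
    )


# ---------------------------------------------------------------------------
# gc_fraction


@pytest.mark.parametrize(
    "seq,expected",
    [("ATGC", 0.5), ("GGCC", 1.0), ("AT", 0.0)],
)
def test_gc_fraction_simple(seq, expected):
    assert gc_fraction(seq) == expected


def test_gc_fraction_interval_and_errors():
    s = NucleotideSequence("x", "AAGGCCTT")
    assert gc_fraction(s, 3, 6) == 1.0
    with pytest.raises(ValueError):
        gc_fraction(s, 5, 4)  # empty interval
    with pytest.raises(ValueError):
        gc_fraction(s, 0, 3)
    with pytest.raises(ValueError):
        gc_fraction("ACGN")


def test_gc_fraction_matches_tally_on_recoded_gene():
    cds = random_cds(474, gc=0.388, seed=5)
    v = recode_to_gc(cds, target_gc=0.616)
    tally = sum(1 for c in v.residues if c in "GC") / len(v.residues)
    assert gc_fraction(v.residues) == pytest.approx(tally, abs=0)
    assert v.achieved_gc == pytest.approx(tally, abs=1e-12)


# ---------------------------------------------------------------------------
# translate


@pytest.mark.parametrize("cds,aa", [("ATGAAATAA", "MK*"), ("ATG", "M")])
def test_translate_simple(cds, aa):
    assert translate(cds) == aa


def test_translate_internal_stop_names_codon():
    with pytest.raises(ValueError, match="codon index 2"):
        translate("ATGTAAAAA")


@given(_random_cds_strategy(30))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_translate_matches_biopython(cds):
    mine = translate(cds)
    ref = str(Seq(cds).translate(table=11))
    assert mine == ref


# ---------------------------------------------------------------------------
# recode_to_gc


def test_recode_fixed_point():
    cds = CodingSequence("x", "ATGAAACCC")
    v = recode_to_gc(cds, target_gc=gc_fraction(cds.residues))
    assert v.n_substitutions == 0
    assert v.residues == cds.residues


def test_recode_maximize_two_lysines():
    # brute force over the 4 synonymous combinations of the two K codons
    v = recode_to_gc(CodingSequence("x", "ATGAAAAAA"), direction="maximize")
    assert v.residues == "ATGAAGAAG"
    assert v.achieved_gc == pytest.approx(3 / 9)


@given(_random_cds_strategy(50), st.floats(min_value=0.1, max_value=0.9))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_recode_preserves_translation(cds, target):
    parent = CodingSequence("p", cds)
    v = recode_to_gc(parent, target_gc=target)
    assert translate(v.residues) == translate(parent)


@given(_random_cds_strategy(7))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_recode_maximize_is_optimal_on_small_cds(cds):
    """Greedy maximization reaches the exhaustive synonymous-recoding optimum."""
    from isgarden.seq_design import _synonym_map

    parent = CodingSequence("p", cds)
    v = recode_to_gc(parent, direction="maximize")
    syn = _synonym_map(11)
    best = max(
        sum(1 for c in "".join(combo) if c in "GC")
        for combo in itertools.product(*(syn[c] for c in parent.codons))
    )
    assert round(v.achieved_gc * len(cds)) == best


def test_recode_unreachable_flag():
    # tryptophan-only CDS has no synonymous freedom
    v = recode_to_gc(CodingSequence("x", "ATGTGGTGG"), target_gc=0.9)
    assert v.unreachable
    assert v.n_substitutions == 0


# ---------------------------------------------------------------------------
# scan_motif


@pytest.mark.parametrize(
    "seq,motif,expected",
    [
        ("TATATA", "TA", [1, 3, 5]),
        ("TGACAA", "WNA", [1, 3]),
        ("AC", "ACGT", []),
    ],
)
def test_scan_motif_examples(seq, motif, expected):
    assert scan_motif(seq, motif) == expected


def test_scan_motif_both_strands():
    # 'AC' matches at 3; its reverse complement 'GT' matches at 1
    assert scan_motif("GTAC", "AC", strand="both") == [1, 3]


def test_scan_motif_invalid_code():
    with pytest.raises(ValueError, match="IUPAC"):
        scan_motif("ACGT", "A?A")


@given(dna, st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=5))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_scan_motif_equals_bruteforce(seq, motif):
    m = len(motif)
    expected = [
        i + 1
        for i in range(len(seq) - m + 1)
        if all(seq[i + j] in IUPAC_SETS[motif[j]] for j in range(m))
    ]
    assert scan_motif(seq, motif) == expected


def test_available_sites_table():
    seqs = [NucleotideSequence("a", "TATATA"), NucleotideSequence("b", "GGGGGG")]
    motifs = [TargetMotif("is1", "TA"), TargetMotif("is2", "GG")]
    t = available_sites(seqs, motifs)
    assert t.set_index(["variant_id", "motif"])["count"].to_dict() == {
        ("a", "TA"): 3,
        ("a", "GG"): 0,
        ("b", "TA"): 0,
        ("b", "GG"): 5,
    }
    assert available_sites(seqs, []).empty
    # determinism: same variant twice gives identical counts
    again = available_sites(seqs, motifs)
    assert t.equals(again)


# ---------------------------------------------------------------------------
# find_tsd / make_insertion_allele


def test_find_tsd_worked_example():
    ref = NucleotideSequence("r", "AAATTACCC")
    mut = NucleotideSequence("m", "AAATTAGGGGTTACCC")
    tsd, core, pos = find_tsd(ref, mut)
    assert (tsd.sequence, core, pos) == ("TTA", "GGGG", 6)
    assert (tsd.left_pos, tsd.right_pos) == (4, 11)


def test_find_tsd_no_duplication():
    ref = NucleotideSequence("r", "AAACCC")
    mut = make_insertion_allele(ref, 3, "GGGG", tsd_len=0)
    tsd, core, pos = find_tsd(ref, mut)
    assert tsd.length == 0
    assert core == "GGGG"


def test_find_tsd_long_element_roundtrip():
    # an element at the top of the realistic IS size range (1497 bp)
    rng = np.random.default_rng(7)
    ref = random_sequence(400, gc=0.4, seed=rng, id="ref")
    element = random_sequence(1497, gc=0.5, seed=rng, id="is").residues
    mut = make_insertion_allele(ref, 200, element, tsd_len=3)
    tsd, core, pos = find_tsd(ref, mut)
    assert len(core) == 1497


def test_find_tsd_rejects_non_insertions():
    ref = NucleotideSequence("r", "AAACCC")
    with pytest.raises(ValueError):
        find_tsd(ref, NucleotideSequence("m", "AAACC"))  # shorter
    with pytest.raises(ValueError):
        find_tsd(ref, NucleotideSequence("m", "TTTTTTTT"))  # unrelated


@given(
    st.integers(min_value=0, max_value=6),
    st.integers(min_value=10, max_value=40),
    st.integers(min_value=4, max_value=30),
    st.randoms(use_true_random=False),
)
@settings(max_examples=150, deadline=None, derandomize=True)
def test_tsd_roundtrip_reconstructs_allele(tsd_len, ref_len, ins_len, rnd):
    """find_tsd composed with make_insertion_allele reproduces the mutant.

    With degenerate flank homology the breakpoint can shift, but the
    recovered (position, element, TSD) must always regenerate the observed
    mutant allele exactly.
    """
    ref = NucleotideSequence("r", "".join(rnd.choice("ACGT") for _ in range(ref_len)))
    pos = rnd.randint(max(1, tsd_len), ref_len)
    ins = "".join(rnd.choice("ACGT") for _ in range(ins_len))
    mut = make_insertion_allele(ref, pos, ins, tsd_len=tsd_len)
    tsd, core, p = find_tsd(ref, mut, max_tsd=10)
    rebuilt = make_insertion_allele(ref, p, core, tsd_len=tsd.length)
    assert rebuilt.residues == mut.residues


def test_tsd_roundtrip_exact_on_nondegenerate_flanks():
    ref = NucleotideSequence("r", "AAACGTCCC")
    mut = make_insertion_allele(ref, 6, "TTTTT", tsd_len=2)
    assert mut.residues == "AAACGTTTTTTGTCCC"
    tsd, core, pos = find_tsd(ref, mut)
    assert (tsd.sequence, core, pos) == ("GT", "TTTTT", 6)


# ---------------------------------------------------------------------------
# PFM and flank asymmetry


def test_pfm_identical_windows_full_information():
    pfm = build_pfm(["TTAA", "TTAA"])
    assert np.allclose(pfm.information_content, 2.0)
    assert pfm.consensus() == "T-T-A-A"


def test_pfm_uniform_position_zero_information():
    pfm = build_pfm(["TA", "TT", "TC", "TG"])
    assert pfm.information_content == pytest.approx([2.0, 0.0])
    # 50/50 split at position 2 -> two-base consensus token
    assert build_pfm(["TA", "TT"]).consensus() == "T-A/T"


def test_pfm_column_sums_conserved_and_bounded():
    rng = np.random.default_rng(11)
    windows = ["".join(rng.choice(list("ACGT"), 6)) for _ in range(50)]
    pfm = build_pfm(windows, pseudocount=0.5)
    assert np.allclose(pfm.counts.sum(axis=0), 50)
    assert (pfm.information_content >= 0).all()
    assert (pfm.information_content <= 2).all()


def test_pfm_degenerate_consensus_label():
    # 70% T / 30% A at position 1 -> written as a two-base position
    pfm = build_pfm(["TA"] * 7 + ["AA"] * 3)
    assert pfm.consensus() == "T/A-A"


def test_pfm_rejects_ragged_windows():
    with pytest.raises(ValueError, match="ragged"):
        build_pfm(["TTA", "TT"])


def test_flank_gc_asymmetry():
    seq = NucleotideSequence("x", "ATATATATAT" + "T" + "GCGCGCGCGC")
    up, down, diff = flank_gc_asymmetry(seq, 11, window=10)
    assert (up, down, diff) == (0.0, 1.0, 100.0)
    sym = NucleotideSequence("y", "GCGCA" + "T" + "AGCGC")
    assert flank_gc_asymmetry(sym, 6, window=5)[2] == 0.0
    with pytest.raises(ValueError):
        flank_gc_asymmetry(seq, 3, window=10)
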