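"""5-class read-signature classification, signature gate, rescue,
novel-candidate filters and genomic context.  The library classifier is
checked against an independent oracle over a randomized grid that hits
every rule boundary."""

from __future__ import annotations

import random

import pytest

from mirnaome.classify import (
    MirnaCandidate,
    PrecursorAnnotation,
    classify_global,
    classify_library,
    genomic_context,
    novel_filters,
    rescue_by_mature,
    signature_gate,
)
from mirnaome.fold import FoldResult
from mirnaome.hairpin import PrecursorCandidate
from mirnaome.io_formats import FeatureRecord
from mirnaome.mapping import GenomeLocus, MappedRead
from mirnaome.reads import CollapsedRead

LIB = "lib1"
N = 120
MIR = (10, 31)
STAR = (60, 81)


def _annotation(placed, passed=True, fold=None):
    precursor = PrecursorCandidate(
        locus=GenomeLocus("c", 1000, 1000 + N, "+"),
        sequence="A" * N,
        fold=fold,
        mir_span=MIR,
        star_span=STAR,
        duplex=None,
    )
    seqs = set()
    reads = []
    k = 0
    for span, count in placed:
        # distinct sequences so counts collapse per read as intended
        while True:
            seq = format(k, "021b").replace("0", "A").replace("1", "C")
            k += 1
            if seq not in seqs:
                seqs.add(seq)
                break
        reads.append((CollapsedRead(seq, {LIB: count}), span))
    defining = MappedRead(
        reads[0][0] if reads else CollapsedRead("A" * 21, {LIB: 1}),
        (GenomeLocus("c", 1010, 1031, "+"),),
        passed_libraries=frozenset({LIB}) if passed else frozenset(),
    )
    return PrecursorAnnotation(precursor=precursor, defining=defining,
                               placed_reads=reads)


def _oracle(placed, passed=True):
    """Independent restatement of the classification contract."""
    if not passed:
        return "unclassified"
    regions = [
        (max(0, MIR[0] - 2), min(N, MIR[1] + 2)),
        (max(0, STAR[0] - 2), min(N, STAR[1] + 2)),
    ]
    star_region = regions[1]
    M = S = 0
    outside = []
    for (lo, hi), count in placed:
        if count <= 0:
            continue
        inside = any(lo >= a and hi <= b for a, b in regions)
        if inside:
            M += count
        else:
            outside.append(count)
        if lo < star_region[1] and hi > star_region[0]:
            S += count
    if M == 0:
        return "unclassified"
    if not outside:
        return 1 if S > 0 else 3
    if sum(outside) > M:
        return 5
    if sum(outside) / len(outside) <= M / 10:
        return 2 if S > 0 else 4
    return "unclassified"


def test_classify_library_matches_oracle_on_random_grid():
    rng = random.Random(17)
    spans = [
        MIR,                      # exact mature
        (MIR[0] - 2, MIR[1] + 2),  # still inside the widened region
        (MIR[0] - 3, MIR[1]),      # leaks outside
        STAR,                      # star
        (STAR[0] - 1, STAR[1] + 1),
        (STAR[0] - 10, STAR[0] + 5),  # overlaps star but not inside
        (35, 56),                  # loop / outside
        (90, 111),                 # downstream outside
        (0, 21),                   # upstream outside
    ]
    n_checked = 0
    for _ in range(1500):
        placed = []
        for span in spans:
            if rng.random() < 0.55:
                placed.append((span, rng.choice([0, 1, 2, 3, 9, 10, 11, 40, 100])))
        ann = _annotation(placed)
        assert classify_library(ann, LIB) == _oracle(placed)
        n_checked += 1
    assert n_checked == 1500


@pytest.mark.parametrize(
    "placed,expected",
    [
        # only mature + star reads, S > 0 -> class 1
        ([(MIR, 100), (STAR, 10)], 1),
        # mature reads only, nothing outside, no star signal -> class 3
        ([(MIR, 100)], 3),
        # outside mean exactly M/10 -> class 2 (boundary is inclusive)
        ([(MIR, 90), (STAR, 10), ((90, 111), 10)], 2),
        # same but without star coverage -> class 4
        ([(MIR, 100), ((90, 111), 10)], 4),
        # outside mean just above M/10 -> unclassified
        ([(MIR, 90), (STAR, 10), ((90, 111), 11)], "unclassified"),
        # outside sum exactly M -> not class 5; mean fails -> unclassified
        ([(MIR, 100), ((90, 111), 100)], "unclassified"),
        # outside sum exceeding M -> class 5
        ([(MIR, 100), ((90, 111), 101)], 5),
        # no reads in the duplex region at all -> unclassified
        ([((90, 111), 50)], "unclassified"),
        # read overlapping star without being inside counts toward S and O
        ([(MIR, 100), ((STAR[0] - 10, STAR[0] + 5), 5)], 2),
    ],
)
def test_classify_library_rule_boundaries(placed, expected):
    assert classify_library(_annotation(placed), LIB) == expected


def test_classify_library_requires_abundance_gate():
    ann = _annotation([(MIR, 100), (STAR, 10)], passed=False)
    assert classify_library(ann, LIB) == "unclassified"


def test_classify_global_takes_best_class():
    ann = _annotation([(MIR, 90), (STAR, 10), ((90, 111), 9)])
    # lib1: class 2.  lib2 unclassified (defining not gated there).
    assert classify_global(ann, ["lib1", "lib2"]) == 2
    assert ann.per_library_class["lib1"] == 2
    assert ann.per_library_class["lib2"] == "unclassified"
    ann2 = _annotation([], passed=False)
    assert classify_global(ann2, ["lib1"]) is None


def _folded_annotation(placed, structure):
    fold = FoldResult("A" * N, structure, -40.0)
    return _annotation(placed, fold=fold)


def _paired_structure(frac_mir_paired: float) -> str:
    """Structure string pairing the first k mature bases with the star arm."""
    s = ["."] * N
    k = round(frac_mir_paired * (MIR[1] - MIR[0]))
    for i in range(k):
        s[MIR[0] + i] = "("
        s[STAR[1] - 1 - i] = ")"
    return "".join(s)


def test_signature_gate_consistency_threshold():
    structure = _paired_structure(1.0)
    # 75 counts near-mature + 25 far outside: exactly 0.75 -> pass
    ann = _folded_annotation([(MIR, 75), ((90, 111), 25)], structure)
    assert signature_gate(ann) is True
    assert ann.signature_pass
    # 74/100 -> fail
    ann = _folded_annotation([(MIR, 74), ((90, 111), 26)], structure)
    assert signature_gate(ann) is False


def test_signature_gate_tolerance_and_loop():
    structure = _paired_structure(1.0)
    # shifted by exactly 3 nt counts as consistent; 4 nt does not
    ann = _folded_annotation([((MIR[0] + 3, MIR[1] + 3), 10)], structure)
    assert signature_gate(ann) is True
    ann = _folded_annotation([((MIR[0] + 4, MIR[1] + 4), 10)], structure)
    assert signature_gate(ann) is False
    # loop-only reads are consistent
    ann = _folded_annotation([((35, 56), 10)], structure)
    assert signature_gate(ann) is True


def test_signature_gate_min_mir_pairing():
    ann = _folded_annotation([(MIR, 100)], _paired_structure(0.60))
    assert signature_gate(ann) is True
    ann = _folded_annotation([(MIR, 100)], _paired_structure(0.5))
    assert signature_gate(ann) is False


def _candidate(mature, global_class, signature=True):
    ann = _annotation([(MIR, 10)])
    ann.global_class = global_class
    ann.signature_pass = signature
    return MirnaCandidate(mature=mature, defining=ann.defining,
                          precursors=[ann], n_loci=1)


def test_rescue_by_mature():
    bona = _candidate("TGGAGCTCCCTTCATTCCAAT", 1)
    near = _candidate("TGGAGCTCCCTTCATTCCTTT", 3)         # 3 mismatches
    far = _candidate("ACACACACACACACACACACA", 3)
    nosig = _candidate("TGGAGCTCCCTTCATTCCTTT"[:-1] + "A", 3, signature=False)
    rescue_by_mature([bona, near, far, nosig])
    assert bona.precursors[0].retained
    assert near.precursors[0].rescued and near.precursors[0].retained
    assert not far.precursors[0].rescued and not far.precursors[0].retained
    assert nosig.precursors[0].rescued and not nosig.precursors[0].retained


def test_novel_filters_statuses():
    known = {"TGGAGCTCCCTTCATTCCAAT"}
    exact = _candidate("TGGAGCTCCCTTCATTCCAAT", 1)
    assert novel_filters(exact, known) == "known_exact"
    variant = _candidate("TGGAGCTCCCTTCATTCCTTT", 1)
    assert novel_filters(variant, known) == "known_variant"
    novel = _candidate("ACACGTGTCACGTACGTACGT", 1)
    assert novel_filters(novel, known) == "novel_accepted"
    # hairpin fraction below 0.20 -> rejected even with a signature
    sparse = _candidate("ACACGTGTCACGTACGTACGT", 1)
    sparse.n_loci = 6  # 1/6 < 0.20
    assert novel_filters(sparse, known) == "rejected"
    # no signature-passing precursor -> rejected
    nosig = _candidate("ACACGTGTCACGTACGTACGT", 1, signature=False)
    assert novel_filters(nosig, known) == "rejected"


def test_genomic_context_precedence():
    feats = [
        FeatureRecord("c", "s", "gene", 0, 1000, "+", {}),
        FeatureRecord("c", "s", "exon", 0, 300, "+", {}),
        FeatureRecord("c", "s", "CDS", 50, 250, "+", {}),
        FeatureRecord("c", "s", "five_prime_UTR", 0, 50, "+", {}),
        FeatureRecord("c", "s", "gene", 2000, 2500, "-", {}),
        FeatureRecord("c", "s", "exon", 2000, 2500, "-", {}),
        FeatureRecord("c", "s", "CDS", 2000, 2500, "-", {}),
    ]
    assert genomic_context(GenomeLocus("c", 100, 121, "+"), feats) == "cds"
    assert genomic_context(GenomeLocus("c", 10, 31, "+"), feats) == "utr"
    assert genomic_context(GenomeLocus("c", 500, 521, "+"), feats) == "intron"
    assert genomic_context(GenomeLocus("c", 2100, 2121, "+"), feats) == "antisense"
    assert genomic_context(GenomeLocus("c", 5000, 5021, "+"), feats) == "intergenic"
    # one shared base pair counts as overlap
    assert genomic_context(GenomeLocus("c", 249, 270, "+"), feats) == "cds"
    assert genomic_context(GenomeLocus("c", 250, 271, "+"), feats) != "cds"
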