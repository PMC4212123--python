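"""Family clustering against a brute-force oracle, plus the
conservation scan against a naive mismatch counter."""

from __future__ import annotations

import random

import pytest

from mirnaome.families import (
    cluster_families,
    conservation_category,
    count_hamming_hits,
    family_compatible,
    mismatch_distance,
    offset_alignments,
)
from mirnaome.io_formats import revcomp


def _oracle_compatible(a: str, b: str, max_mm=3, min_id=0.842) -> bool:
    """Independent check: some ungapped offset has both few mismatches
    and high identity relative to the shorter sequence."""
    shorter = min(len(a), len(b))
    for off in range(-len(b) + 1, len(a)):
        match = mm = 0
        for i in range(len(a)):
            j = i - off
            if 0 <= j < len(b):
                if a[i] == b[j]:
                    match += 1
                else:
                    mm += 1
        if match + mm == 0:
            continue
        if mm <= max_mm and match / shorter >= min_id:
            return True
    return False


def _oracle_distance(a: str, b: str) -> int:
    shorter = min(len(a), len(b))
    best = None
    for off in range(-len(b) + 1, len(a)):
        match = mm = 0
        for i in range(len(a)):
            j = i - off
            if 0 <= j < len(b):
                if a[i] == b[j]:
                    match += 1
                else:
                    mm += 1
        overlap = match + mm
        if overlap == 0:
            continue
        d = mm + (shorter - overlap)
        best = d if best is None else min(best, d)
    return best


def _random_matures(rng, n):
    base = "".join(rng.choice("ACGT") for _ in range(21))
    out = {}
    while len(out) < n:
        if rng.random() < 0.6:
            # perturb the base: family structure emerges
            s = list(base)
            for _ in range(rng.randrange(0, 6)):
                s[rng.randrange(len(s))] = rng.choice("ACGT")
            seq = "".join(s)
            if rng.random() < 0.3:
                k = rng.choice([20, 22])
                seq = (seq + rng.choice("ACGT"))[:k]
        else:
            seq = "".join(rng.choice("ACGT") for _ in range(rng.choice([20, 21, 22])))
        if seq not in out:
            out[seq] = rng.randrange(1, 200)
    return list(out.items())


def test_family_compatible_matches_oracle():
    rng = random.Random(23)
    pairs_checked = 0
    matures = _random_matures(rng, 40)
    for i in range(len(matures)):
        for j in range(len(matures)):
            a, b = matures[i][0], matures[j][0]
            assert family_compatible(a, b) == _oracle_compatible(a, b), (a, b)
            pairs_checked += 1
    assert pairs_checked == 1600


def test_mismatch_distance_matches_oracle_and_is_symmetric():
    rng = random.Random(29)
    matures = _random_matures(rng, 25)
    for a, _ in matures:
        for b, _ in matures:
            d = mismatch_distance(a, b)
            assert d == _oracle_distance(a, b)
            assert d == mismatch_distance(b, a)
            if a == b:
                assert d == 0


def test_mismatch_distance_known_values():
    assert mismatch_distance("ACGTACGT", "ACGTACGT") == 0
    assert mismatch_distance("ACGTACGT", "ACGTACGA") == 1
    # a 1-nt 5' shift of identical content costs 1 uncovered base at best
    assert mismatch_distance("ACGTACGT", "CGTACGTA") <= 2
    # length difference alone: perfect substring costs the uncovered bases
    assert mismatch_distance("ACGTACGTACGTACGTACGTA", "ACGTACGTACGTACGTACGT") == 0


def test_identity_boundary_16_of_19():
    # 21-nt vs 19-nt overlap with 3 mismatches: 16/19 = 0.842... passes;
    # one more mismatch pushes identity to 15/19 < 0.842 -> fails
    a = "ACGTACGTACGTACGTACGTA"
    b = list(a[:19])
    for pos in (3, 8, 13):
        b[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[pos]]
    assert family_compatible(a, "".join(b))
    b[16] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[16]]
    assert not family_compatible(a, "".join(b))


def _oracle_cluster(matures, loci):
    ordered = sorted(matures, key=lambda t: (-t[1], t[0]))
    fams = []
    for seq, _ in ordered:
        for fam in fams:
            if _oracle_compatible(fam[0], seq):
                fam[1].append(seq)
                break
        else:
            fams.append((seq, [seq]))
    return [(rep, members, sum(loci.get(m, 1) for m in members)) for rep, members in fams]


def test_cluster_families_matches_greedy_oracle():
    rng = random.Random(31)
    matures = _random_matures(rng, 200)
    loci = {m: rng.randrange(1, 5) for m, _ in matures}
    got = cluster_families(matures, loci)
    expect = _oracle_cluster(matures, loci)
    assert [(f.representative, f.members, f.n_genes) for f in got] == expect
    # invariants: ids sequential, every member compatible with its centroid
    for k, fam in enumerate(got, start=1):
        assert fam.family_id == f"fam{k:03d}"
        for m in fam.members:
            assert family_compatible(fam.representative, m)
    assert sum(len(f.members) for f in got) == len(matures)


def test_cluster_families_rejects_duplicates():
    with pytest.raises(ValueError):
        cluster_families([("ACGTACGTACGTACGTACGTA", 3),
                          ("ACGTACGTACGTACGTACGTA", 1)])


def _oracle_hits(mature, genome, max_mm):
    n = len(mature)
    hits = 0
    for strand_seq in (genome, revcomp(genome)):
        for i in range(len(strand_seq) - n + 1):
            window = strand_seq[i : i + n]
            mm = sum(1 for x, y in zip(mature, window) if x != y or y == "N")
            if mm <= max_mm:
                hits += 1
    return hits


def test_count_hamming_hits_matches_naive_scan():
    rng = random.Random(37)
    genome = "".join(rng.choice("ACGT") for _ in range(4000))
    mature = genome[100:121]
    # plant a reverse-strand copy and a 3-mismatch copy
    mm3 = list(mature)
    for pos in (2, 9, 17):
        mm3[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mm3[pos]]
    genome = genome + revcomp(mature) + "".join(mm3) + "N" * 30
    for probe in (mature, "".join(mm3), "ACGT" * 5 + "A"):
        assert count_hamming_hits(probe, genome) == _oracle_hits(probe, genome, 3)


def test_count_hamming_hits_n_never_matches():
    mature = "ACGTACGTACGTACGTACGTA"
    genome = mature[:10] + "N" * 4 + mature[14:]
    # 4 N positions -> 4 effective mismatches -> no hit at threshold 3
    assert count_hamming_hits(mature, genome) == 0


def test_conservation_categories():
    rng = random.Random(41)
    mature = "".join(rng.choice("ACGT") for _ in range(21))
    bg = lambda: "".join(rng.choice("ACGT") for _ in range(2000))
    clade = {"sp1": bg() + mature + bg(), "sp2": bg()}
    outgroup_hit = {"og1": bg() + revcomp(mature) + bg()}
    outgroup_miss = {"og1": bg()}

    call = conservation_category(mature, clade, outgroup_hit)
    assert call.category == "widespread"
    assert call.hits_per_genome["sp1"] >= 1 and call.hits_per_genome["og1"] >= 1

    call = conservation_category(mature, clade, outgroup_miss)
    assert call.category == "clade_specific"

    call = conservation_category(mature, {"sp1": bg(), "sp2": bg()}, outgroup_miss)
    assert call.category == "species_specific"
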