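"""Target alignment scoring, site filtering, degradome validation and
the anticorrelation screen."""

from __future__ import annotations

import random

import numpy as np
import pytest

from mirnaome.io_formats import revcomp
from mirnaome.targets import (
    GAP_OPEN,
    GU_SCORE,
    MISMATCH_SCORE,
    WC_SCORE,
    TargetAlignment,
    align_mirna_target,
    anticorrelation_screen,
    degradome_validate,
    filter_targets,
    map_degradome_tags,
)

MIRNA = "TGGAGCTCCCTTTCATTCCAA"  # 21 nt
RNG = random.Random(51)


def _transcript_with(site: str, pad: int = 400) -> tuple[str, int]:
    flank = lambda n: "".join(RNG.choice("ACGT") for _ in range(n))
    left = flank(pad)
    return left + site + flank(pad), len(left)


def test_perfect_site_scores_exactly_140():
    """A perfect 21-nt complement scores 14 seed-weighted WC matches:
    7 positions at 2-8 double-weighted (7*10) plus 14 at weight 1 (14*5)."""
    site = revcomp(MIRNA)
    transcript, off = _transcript_with(site)
    hits = align_mirna_target(MIRNA, transcript, "t1")
    assert hits, "perfect site must be found"
    best = hits[0]
    assert best.alignment_score == pytest.approx(7 * 2 * WC_SCORE + 14 * WC_SCORE)
    assert best.alignment_score == pytest.approx(140.0)
    assert best.site == (off, off + 21)
    assert best.penalty_score == 0.0
    assert best.alignment_length == 21
    assert all(kind == "WC" for kind, *_ in best.columns)
    assert best.duplex_energy < -20.0
    kept = filter_targets(hits)
    assert best in kept


def test_gu_wobble_costs_half_point():
    # replace one non-seed transcript base to make a G:U pair against the
    # miRNA: in reverse-complement space C->T turns a WC column into GU
    # miRNA U:G wobble -> in reverse-complement space an A column becomes G;
    # pick a non-seed miRNA position (site index i pairs position 21-i)
    site = list(revcomp(MIRNA))
    idx = next(i for i in range(len(site))
               if site[i] == "A" and not 2 <= 21 - i <= 8)
    site[idx] = "G"
    transcript, _ = _transcript_with("".join(site))
    hits = align_mirna_target(MIRNA, transcript, "t1", min_score=100.0)
    best = hits[0]
    assert any(kind == "GU" for kind, *_ in best.columns)
    assert best.penalty_score == pytest.approx(0.5)
    weight_at_idx = 1  # miRNA position 21-idx is outside the 2-8 seed
    expected = 140.0 - weight_at_idx * WC_SCORE + weight_at_idx * GU_SCORE
    assert best.alignment_score == pytest.approx(expected)


def test_seed_mismatch_weighs_double():
    site = list(revcomp(MIRNA))
    # miRNA position p pairs transcript index 21-p: index 15 -> position 6
    pos = 15
    complement = {"A": "T", "C": "G", "G": "C", "T": "A"}
    mir_base = MIRNA[21 - pos - 1]
    bad = next(b for b in "ACGT"
               if b != site[pos] and b != complement[mir_base]
               and (mir_base, b) not in {("G", "T"), ("T", "G")})
    site[pos] = bad
    transcript, _ = _transcript_with("".join(site))
    hits = align_mirna_target(MIRNA, transcript, "t1", min_score=50.0)
    best = hits[0]
    mm_cols = [c for c in best.columns if c[0] == "mismatch"]
    assert len(mm_cols) == 1
    assert best.alignment_score == pytest.approx(
        140.0 - 2 * WC_SCORE + 2 * MISMATCH_SCORE
    )
    assert best.penalty_score == pytest.approx(1.0)


def test_poly_a_transcript_has_no_sites():
    assert align_mirna_target(MIRNA, "A" * 500, "t1") == []


def test_sites_do_not_overlap():
    site = revcomp(MIRNA)
    transcript = "ACGT" * 30 + site + "ACGT" * 10 + site + "ACGT" * 30
    hits = align_mirna_target(MIRNA, transcript, "t1")
    assert len(hits) == 2
    (a, b), (c, d) = sorted(h.site for h in hits)
    assert b <= c


def test_penalty_boundary_filters():
    cols_2mm = (
        [("WC", MIRNA[-(i + 1)], "N", 21 - i) for i in range(19)]
        + [("mismatch", "A", "A", 2), ("mismatch", "A", "A", 1)]
    )
    site = TargetAlignment(MIRNA, "t", (0, 21), cols_2mm, 150.0, -30.0)
    assert site.penalty_score == pytest.approx(2.0)
    assert filter_targets([site]) == [site]
    cols_over = cols_2mm[:-1] + [("GU", "G", "T", 1), ("mismatch", "A", "A", 1)]
    over = TargetAlignment(MIRNA, "t", (0, 21), cols_over, 150.0, -30.0)
    assert over.penalty_score == pytest.approx(2.5)
    assert filter_targets([over]) == []


def test_gap_penalty_counts_openings_not_length():
    wc = [("WC", "G", "C", i) for i in range(21, 2, -1)]
    one_gap2 = TargetAlignment(
        MIRNA, "t", (0, 21), wc + [("gap", "-", "A", 0), ("gap", "-", "A", 0)],
        150.0, -30.0,
    )
    assert one_gap2.penalty_score == pytest.approx(2.0)
    two_gaps = TargetAlignment(
        MIRNA, "t", (0, 21),
        wc + [("gap", "-", "A", 0), ("WC", "G", "C", 2), ("gap", "A", "-", 1)],
        150.0, -30.0,
    )
    assert two_gaps.penalty_score == pytest.approx(4.0)


def test_filter_targets_length_score_energy():
    good_cols = [("WC", "G", "C", i) for i in range(21, 3, -1)]
    short = TargetAlignment(MIRNA, "t", (0, 17), good_cols[:17], 150.0, -30.0)
    assert filter_targets([short]) == []
    weak = TargetAlignment(MIRNA, "t", (0, 21), good_cols, 139.9, -30.0)
    assert filter_targets([weak]) == []
    hot = TargetAlignment(MIRNA, "t", (0, 21), good_cols, 150.0, -19.9)
    assert filter_targets([hot]) == []


def test_map_degradome_tags_counts_5prime_ends():
    transcript = "".join(RNG.choice("ACGT") for _ in range(300))
    tags = [transcript[50:70]] * 3 + [transcript[120:140]] + ["G" * 20]
    profiles = map_degradome_tags(tags, {"t1": transcript})
    assert profiles["t1"][50] == 3
    assert profiles["t1"][120] == 1
    assert profiles["t1"].sum() == 4


def _site_at(start: int, transcript_id="t1"):
    cols = [("WC", "G", "C", i) for i in range(21, 0, -1)]
    return TargetAlignment(MIRNA, transcript_id, (start, start + 21), cols,
                           150.0, -30.0)


def test_degradome_categories_and_pvalue():
    profile = np.zeros(500, dtype=np.int64)
    cleavage = 100 + (21 - 10)
    profile[cleavage] = 30
    profile[7] = 5
    profile[400] = 2
    sup = degradome_validate(_site_at(100), {"t1": profile})
    assert sup.category == 0
    assert sup.tag_count_at_cleavage == 30
    assert sup.p_value == pytest.approx(1 / 500)
    assert sup.validated

    # tie for the maximum -> category 1
    profile2 = profile.copy()
    profile2[7] = 30
    assert degradome_validate(_site_at(100), {"t1": profile2}).category == 1

    # above the median but not maximal -> category 2
    sup2 = degradome_validate(_site_at(389), {"t1": profile})
    assert sup2.tag_count_at_cleavage == 2
    assert sup2.category == 2

    # count <= 1 -> category 4, p-value 1 at zero signal
    sup4 = degradome_validate(_site_at(200), {"t1": profile})
    assert sup4.category == 4 and not sup4.validated


def test_degradome_uniform_background_is_not_validated():
    profile = np.full(400, 3, dtype=np.int64)
    sup = degradome_validate(_site_at(100), {"t1": profile})
    assert sup.p_value == pytest.approx(1.0)
    assert not sup.validated


def test_degradome_missing_transcript():
    sup = degradome_validate(_site_at(100, "absent"), {})
    assert not sup.has_data and not sup.validated


def test_anticorrelation_screen():
    mirna_ab = {"m1": {"ctl": 10.0, "drought": 30.0, "cold": 10.0}}
    target_ab = {"t1": {"ctl": 90.0, "drought": 30.0, "cold": 90.0},
                 "t2": {"ctl": 0.0, "drought": 10.0}}
    flagged = anticorrelation_screen(
        mirna_ab, target_ab, [("m1", "t1"), ("m1", "t2")],
        [("drought", "ctl"), ("cold", "ctl")],
    )
    assert len(flagged) == 1
    hit = flagged[0]
    assert (hit["mirna"], hit["target"], hit["condition"]) == ("m1", "t1", "drought")
    assert hit["mirna_fold"] == pytest.approx(3.0)
    assert hit["target_fold"] == pytest.approx(1 / 3)
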