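"""SNP/indel partitioning around precursors, mature-position breakdown,
structural contexts and the permutation test."""

from __future__ import annotations

import numpy as np
import pytest

from mirnaome.fold import FoldResult
from mirnaome.io_formats import VariantRecord
from mirnaome.mapping import GenomeLocus
from mirnaome.polymorphism import (
    PrecursorRegions,
    assign_snps,
    mature_position_breakdown,
    permutation_test_rates,
    profile_precursor,
    region_windows,
    structural_context,
    summarize_polymorphism,
)


def _variant(pos, ref="A", alt="T", chrom="c"):
    return VariantRecord(chrom, pos, ref, alt, frozenset({"acc1"}),
                         VariantRecord.classify(ref, alt))


def _prec(start=10_000, end=10_120, strand="+", chrom_length=None):
    return PrecursorRegions(
        precursor_id="p1",
        locus=GenomeLocus("c", start, end, strand),
        mature_local=(10, 31),
        star_local=(80, 101),
        chrom_length=chrom_length,
    )


def test_region_windows_plus_strand_layout():
    w = region_windows(GenomeLocus("c", 10_000, 10_120, "+"))
    assert w["up_1"] == (9_500, 10_000)
    assert w["up_500"] == (9_000, 9_500)
    assert w["up_1000"] == (8_500, 9_000)
    assert w["dn_1"] == (10_120, 10_620)
    assert w["dn_500"] == (10_620, 11_120)
    assert w["dn_1000"] == (11_120, 11_620)


def test_region_windows_minus_strand_mirrors():
    plus = region_windows(GenomeLocus("c", 10_000, 10_120, "+"))
    minus = region_windows(GenomeLocus("c", 10_000, 10_120, "-"))
    assert minus["up_1"] == plus["dn_1"]
    assert minus["dn_1000"] == plus["up_1000"]


def test_region_windows_clamped_at_edges():
    w = region_windows(GenomeLocus("c", 1200, 1300, "+"), chrom_length=1500)
    assert w["up_1"] == (700, 1200)
    assert w["up_500"] == (200, 700)
    assert w["up_1000"] == (0, 200)  # truncated to 200 bp
    assert w["dn_1"] == (1300, 1500)
    assert w["dn_500"][1] - w["dn_500"][0] == 0  # fully beyond the end: empty


def test_region_windows_rejects_bad_flank():
    with pytest.raises(ValueError):
        region_windows(GenomeLocus("c", 0, 100, "+"), flank=1200)


def _oracle_region(prec, pos):
    """Independent single-position partition for a '+'-strand precursor."""
    s, e = prec.locus.start, prec.locus.end
    if s <= pos < e:
        return "hairpin"
    for key, (lo, hi) in region_windows(prec.locus, prec.chrom_length).items():
        if lo <= pos < hi:
            return key
    return None


def test_assign_snps_matches_position_scan_oracle():
    prec = _prec()
    variants = [_variant(p) for p in range(8_400, 11_700, 37)]
    # add boundary positions explicitly
    for p in (8_499, 8_500, 9_999, 10_000, 10_119, 10_120, 11_619, 11_620):
        variants.append(_variant(p))
    # non-counted classes and other chromosomes must be ignored
    variants.append(_variant(10_050, ref="ACGTT", alt="A"))
    variants.append(_variant(10_050, chrom="other"))

    regions = assign_snps(variants, [prec])["p1"]
    got = {}
    for key, vs in regions.items():
        if key == "mature":
            continue
        for v in vs:
            got[(v.pos, v.seq_id, v.ref_allele)] = key
    for v in variants:
        expect = None
        if v.seq_id == "c" and v.variant_class in ("snp", "indel_le_2bp"):
            expect = _oracle_region(prec, v.pos)
        assert got.get((v.pos, v.seq_id, v.ref_allele)) == expect, v
    # the mature list is the subset of hairpin variants inside the mature
    lo, hi = prec.mature_genomic()
    assert {v.pos for v in regions["mature"]} == {
        v.pos for v in regions["hairpin"] if lo <= v.pos < hi
    }


def test_assign_snps_example_offsets():
    prec = _prec()
    # 1200 bp upstream of the start -> up_1000; 1501 bp -> outside
    regions = assign_snps([_variant(10_000 - 1200), _variant(10_000 - 1501)],
                          [prec])["p1"]
    assert [v.pos for v in regions["up_1000"]] == [8_800]
    assert sum(len(v) for v in regions.values()) == 1


def test_mature_breakdown_plus_strand():
    offsets, flags = mature_position_breakdown((100, 121), "+", [100, 109, 110, 120])
    assert offsets == [1, 10, 11, 21]
    assert flags["snp_at_10_or_11"]
    assert flags["snp_in_1_7"] and flags["snp_in_8_12"] and flags["snp_in_13_21"]


def test_mature_breakdown_minus_strand():
    # on '-' the genomic end is the miRNA 5' end
    offsets, flags = mature_position_breakdown((100, 121), "-", [120, 100])
    assert offsets == [1, 21]
    assert not flags["snp_at_10_or_11"]


def test_mature_breakdown_ignores_outside_positions():
    offsets, _ = mature_position_breakdown((100, 121), "+", [99, 121, 500])
    assert offsets == []


def test_structural_context_cases():
    #            0123456789012345678901234567
    structure = "((((((..((((....))))..))))))"
    fold = FoldResult("A" * len(structure), structure, -20.0)
    loop = (12, 16)
    star = (22, 28)
    assert structural_context(fold, 13, loop, star) == ("loop", False)
    assert structural_context(fold, 6, loop, star) == ("bulge", False)
    # paired base adjacent to the internal bulge
    assert structural_context(fold, 5, loop, star)[0] == "near_bulge_1_2nt"
    assert structural_context(fold, 9, loop, star)[0] == "near_bulge_1_2nt"
    # deep stem base, 3+ nt from any unpaired stem base
    assert structural_context(fold, 2, loop, star)[0] == "stem"
    # paired base inside the star span disrupts the miR:miR* duplex
    assert structural_context(fold, 25, loop, star) == ("stem", True)
    with pytest.raises(ValueError):
        structural_context(fold, 99, loop, star)


def test_profile_precursor_rates_per_100bp():
    prec = _prec()
    variants = (
        [_variant(p) for p in (10_005, 10_015, 10_100)]  # hairpin (one in mature)
        + [_variant(9_700), _variant(9_800)]             # up_1
        + [_variant(10_050, ref="AT", alt="A")]          # hairpin indel
    )
    prof = profile_precursor(prec, assign_snps(variants, [prec])["p1"])
    assert prof.n_snps_hairpin == 3
    assert prof.n_indels_hairpin == 1
    assert prof.hairpin_rate == pytest.approx(3 / 120 * 100)
    assert prof.window_counts["up_1"] == 2
    assert prof.window_rates["up_1"] == pytest.approx(2 / 500 * 100)
    # local mature offset of genomic 10_015 on '+' with mature at +10..31
    assert prof.mature_snp_positions == [6]
    assert prof.flags["snp_in_1_7"]


def test_permutation_test_detects_shift_and_respects_null():
    rng = np.random.default_rng(0)
    a = rng.normal(5.0, 0.3, size=12)
    b = rng.normal(1.0, 0.3, size=12)
    res = permutation_test_rates(a, b, n_permutations=2000, seed=7)
    assert res["p_value"] < 0.01
    assert res["observed_diff"] == pytest.approx(a.mean() - b.mean())
    null = permutation_test_rates(a, a + rng.normal(0, 1e-6, size=12),
                                  n_permutations=500, seed=7)
    assert null["p_value"] > 0.2


def test_permutation_test_small_group_note():
    res = permutation_test_rates(np.array([1.0]), np.array([2.0, 3.0]))
    assert res["p_value"] is None and res["note"] == "group too small"


def test_permutation_test_deterministic_in_seed():
    rng = np.random.default_rng(3)
    a, b = rng.normal(2, 1, 10), rng.normal(2.5, 1, 10)
    r1 = permutation_test_rates(a, b, n_permutations=500, seed=11)
    r2 = permutation_test_rates(a, b, n_permutations=500, seed=11)
    assert r1 == r2


def test_summarize_polymorphism_tables():
    precs = []
    variants = []
    for i, (start, group) in enumerate(
        [(10_000, "conserved"), (40_000, "conserved"), (70_000, "novel"),
         (100_000, "novel"), (130_000, "novel")]
    ):
        precs.append(
            PrecursorRegions(
                precursor_id=f"p{i}",
                locus=GenomeLocus("c", start, start + 120, "+"),
                mature_local=(10, 31),
                star_local=(80, 101),
            )
        )
        # novel precursors get dense hairpin SNPs, conserved get none
        if group == "novel":
            variants += [_variant(start + k) for k in range(5, 115, 10)]
    group_of = {"p0": "conserved", "p1": "conserved", "p2": "novel",
                "p3": "novel", "p4": "novel"}
    chrom_of = {p.precursor_id: "c" for p in precs}
    profiles = [
        profile_precursor(p, assign_snps(variants, [p])[p.precursor_id])
        for p in precs
    ]
    out = summarize_polymorphism(profiles, group_of, chrom_of,
                                 n_permutations=300, seed=5)
    table = out["table"]
    # group x chromosome rows plus 'all' aggregations on both axes
    assert set(table["group"]) == {"conserved", "novel", "all"}
    assert set(table["chromosome"]) == {"c", "all"}
    all_row = table[(table["group"] == "all") & (table["chromosome"] == "all")]
    assert int(all_row["n_precursors"].iloc[0]) == 5
    comparison = out["comparison"]
    assert comparison["hairpin"]["p_value"] is not None
    # the planted novel group is strictly more polymorphic in the hairpin
    assert comparison["hairpin"]["observed_diff"] != 0.0
    rbw = out["rates_by_window"]
    assert {"hairpin", "up_1000", "up_500", "up_1",
            "dn_1", "dn_500", "dn_1000"} <= set(rbw.columns)
    novel_rate = rbw[rbw["group"] == "novel"]["hairpin"].mean()
    conserved_rate = rbw[rbw["group"] == "conserved"]["hairpin"].mean()
    assert novel_rate > conserved_rate


def test_summarize_polymorphism_deterministic():
    prec = _prec()
    profiles = [profile_precursor(prec, assign_snps([_variant(10_010)], [prec])["p1"])]
    kw = dict(group_of={"p1": "novel"}, chrom_of={"p1": "c"},
              n_permutations=100, seed=2)
    a = summarize_polymorphism(profiles, **kw)
    b = summarize_polymorphism(profiles, **kw)
    assert a["table"].equals(b["table"])
    assert a["rates_by_window"].equals(b["rates_by_window"])
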