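"""SNP/small-indel profiling of miRNA precursors, matures and flanks.

Each variant is assigned to exactly one region per precursor: the
hairpin itself or one of six 500-bp flanking windows covering 1.5 kb on
each side ("upstream" is 5' of the precursor on its own strand).
Variants inside the mature span are additionally broken down by 1-based
position from the mature 5' end, with flags for positions 10/11 (the
cleavage-guiding positions) and the 1-7 / 8-12 / 13-21 bins.  Hairpin
SNPs are placed in the secondary structure (bulge, near-bulge, stem,
loop) and checked for miR* pair disruption.

The conserved-versus-novel comparison of per-region SNP rates uses a
seeded label-permutation test on the group mean difference rather than
parametric count models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fold import FoldResult
from .io_formats import VariantRecord
from .mapping import GenomeLocus

FLANK_DEFAULT = 1500
WINDOW_DEFAULT = 500

# region keys, upstream windows named by their far boundary as in Fig-5 style
WINDOW_KEYS = ("up_1000", "up_500", "up_1", "dn_1", "dn_500", "dn_1000")
REGION_KEYS = ("hairpin",) + WINDOW_KEYS

COUNTED_CLASSES = {"snp", "indel_le_2bp"}


@dataclass
class PrecursorRegions:
    """Everything the profiler needs to know about one precursor."""

    precursor_id: str
    locus: GenomeLocus
    mature_local: tuple[int, int]
    star_local: tuple[int, int]
    fold: FoldResult | None = None
    loop_local: tuple[int, int] | None = None
    chrom_length: int | None = None

    def mature_genomic(self) -> tuple[int, int]:
        a, b = self.mature_local
        if self.locus.strand == "+":
            return (self.locus.start + a, self.locus.start + b)
        return (self.locus.end - b, self.locus.end - a)


@dataclass
class MirnaPolymorphism:
    precursor_id: str
    n_snps_hairpin: int = 0
    n_indels_hairpin: int = 0
    mature_snp_positions: list = field(default_factory=list)
    flags: dict = field(default_factory=dict)
    window_counts: dict = field(default_factory=dict)      # region -> n SNPs
    window_rates: dict = field(default_factory=dict)       # region -> SNP/100 bp
    window_lengths: dict = field(default_factory=dict)
    star_snp_count: int = 0
    structural_context: list = field(default_factory=list)  # (local pos, context, star_disrupt)
    hairpin_rate: float = 0.0


def region_windows(
    locus: GenomeLocus,
    chrom_length: int | None = None,
    flank: int = FLANK_DEFAULT,
    window: int = WINDOW_DEFAULT,
) -> dict[str, tuple[int, int]]:
    """Genomic half-open intervals of the six flank windows, oriented by
    the precursor strand and clamped at chromosome ends."""
    n_win = flank // window
    if n_win != 3 or flank % window:
        raise ValueError("flank must be three whole windows")
    upstream_left = locus.strand == "+"  # genomic left side is 5' on '+'

    def clamp(a: int, b: int) -> tuple[int, int]:
        lo = max(0, a)
        hi = min(chrom_length, b) if chrom_length is not None else b
        return (lo, max(lo, hi))

    out = {}
    for k in range(1, n_win + 1):
        left = clamp(locus.start - k * window, locus.start - (k - 1) * window)
        right = clamp(locus.end + (k - 1) * window, locus.end + k * window)
        label = ("up_1", "up_500", "up_1000")[k - 1]
        other = ("dn_1", "dn_500", "dn_1000")[k - 1]
        if upstream_left:
            out[label], out[other] = left, right
        else:
            out[label], out[other] = right, left
    return out


def assign_snps(
    variants: list[VariantRecord],
    precursors: list[PrecursorRegions],
    flank: int = FLANK_DEFAULT,
    window: int = WINDOW_DEFAULT,
) -> dict[str, dict[str, list[VariantRecord]]]:
    """Partition counted variants (SNPs and ≤2-bp indels) into the
    hairpin / six-window regions of each precursor; a variant overlapping
    several precursors is counted once per precursor."""
    out: dict[str, dict[str, list[VariantRecord]]] = {}
    for prec in precursors:
        windows = region_windows(prec.locus, prec.chrom_length, flank, window)
        regions = {key: [] for key in REGION_KEYS}
        regions["mature"] = []  # breakdown only; subset of hairpin
        mat_lo, mat_hi = prec.mature_genomic()
        for v in variants:
            if v.seq_id != prec.locus.seq_id or v.variant_class not in COUNTED_CLASSES:
                continue
            if prec.locus.start <= v.pos < prec.locus.end:
                regions["hairpin"].append(v)
                if mat_lo <= v.pos < mat_hi:
                    regions["mature"].append(v)
                continue
            for key in WINDOW_KEYS:
                lo, hi = windows[key]
                if lo <= v.pos < hi:
                    regions[key].append(v)
                    break
        out[prec.precursor_id] = regions
    return out


def mature_position_breakdown(
    mature_span: tuple[int, int], strand: str, snp_positions: list[int]
) -> tuple[list[int], dict[str, bool]]:
    """1-based offsets from the mature 5' end (miRNA strand) and the
    position flags used by the Table-1 summary."""
    lo, hi = mature_span
    offsets = []
    for pos in snp_positions:
        if not (lo <= pos < hi):
            continue
        offsets.append(pos - lo + 1 if strand == "+" else hi - pos)
    offsets.sort()
    flags = {
        "snp_at_10_or_11": any(o in (10, 11) for o in offsets),
        "snp_in_1_7": any(1 <= o <= 7 for o in offsets),
        "snp_in_8_12": any(8 <= o <= 12 for o in offsets),
        "snp_in_13_21": any(13 <= o <= 21 for o in offsets),
    }
    return offsets, flags


def structural_context(
    fold: FoldResult,
    position: int,
    loop_region: tuple[int, int] | None = None,
    star_span: tuple[int, int] | None = None,
    vicinity: int = 2,
) -> tuple[str, bool]:
    """Context of a hairpin SNP in the MFE structure.

    Returns (context, star_pair_disruption); context is ``loop`` for an
    unpaired base inside the terminal loop, ``bulge`` for any other
    unpaired base, ``near_bulge_1_2nt`` for a paired base within 1-2 nt
    of an unpaired stem base, else ``stem``.
    """
    pairs = fold.pair_table
    n = len(pairs)
    if not (0 <= position < n):
        raise ValueError("position outside the precursor")
    unpaired = pairs[position] < 0
    in_loop = loop_region is not None and loop_region[0] <= position < loop_region[1]
    star_disrupt = bool(
        star_span is not None
        and star_span[0] <= position < star_span[1]
        and not unpaired
    )
    if unpaired:
        return ("loop" if in_loop else "bulge"), star_disrupt
    for d in range(1, vicinity + 1):
        for q in (position - d, position + d):
            if 0 <= q < n and pairs[q] < 0:
                in_loop_q = loop_region is not None and loop_region[0] <= q < loop_region[1]
                if not in_loop_q:
                    return "near_bulge_1_2nt", star_disrupt
    return "stem", star_disrupt


def profile_precursor(
    prec: PrecursorRegions,
    regions: dict[str, list[VariantRecord]],
    flank: int = FLANK_DEFAULT,
    window: int = WINDOW_DEFAULT,
) -> MirnaPolymorphism:
    """Combine region assignment, mature breakdown and structural context
    into one per-precursor record with SNP/100 bp window rates."""
    windows = region_windows(prec.locus, prec.chrom_length, flank, window)
    hairpin_vars = regions["hairpin"]
    hairpin_snps = [v for v in hairpin_vars if v.variant_class == "snp"]
    mature_snps = [v.pos for v in regions["mature"] if v.variant_class == "snp"]
    offsets, flags = mature_position_breakdown(
        prec.mature_genomic(), prec.locus.strand, mature_snps
    )

    counts, rates, lengths = {}, {}, {}
    for key in WINDOW_KEYS:
        lo, hi = windows[key]
        length = hi - lo
        n = sum(1 for v in regions[key] if v.variant_class == "snp")
        counts[key] = n
        lengths[key] = length
        rates[key] = 100.0 * n / length if length else 0.0
    hp_len = len(prec.locus)

    star_count = 0
    contexts = []
    for v in hairpin_snps:
        if prec.locus.strand == "+":
            local = v.pos - prec.locus.start
        else:
            local = prec.locus.end - 1 - v.pos
        if prec.fold is not None:
            ctx, disrupt = structural_context(
                prec.fold, local, prec.loop_local, prec.star_local
            )
            contexts.append((local, ctx, disrupt))
        if prec.star_local[0] <= local < prec.star_local[1]:
            star_count += 1

    return MirnaPolymorphism(
        precursor_id=prec.precursor_id,
        n_snps_hairpin=len(hairpin_snps),
        n_indels_hairpin=sum(
            1 for v in hairpin_vars if v.variant_class == "indel_le_2bp"
        ),
        mature_snp_positions=offsets,
        flags=flags,
        window_counts=counts,
        window_rates=rates,
        window_lengths=lengths,
        star_snp_count=star_count,
        structural_context=contexts,
        hairpin_rate=100.0 * len(hairpin_snps) / hp_len if hp_len else 0.0,
    )


# ---------------------------------------------------------------------------
# summaries and the group comparison


def _table_rows(
    profiles: list[MirnaPolymorphism],
    group_of: dict[str, str],
    chrom_of: dict[str, str],
) -> pd.DataFrame:
    rows = []
    keys = sorted(
        {(group_of.get(p.precursor_id, "all"), chrom_of.get(p.precursor_id, "?"))
         for p in profiles}
    )
    groups = sorted({g for g, _ in keys})
    for group in groups + ["all"]:
        members = [
            p for p in profiles
            if group == "all" or group_of.get(p.precursor_id) == group
        ]
        chroms = sorted({chrom_of.get(p.precursor_id, "?") for p in members})
        for chrom in chroms + ["all"]:
            sel = [
                p for p in members
                if chrom == "all" or chrom_of.get(p.precursor_id) == chrom
            ]
            n = len(sel)
            if n == 0:
                continue
            with_snp = sum(
                1 for p in sel
                if p.n_snps_hairpin + sum(p.window_counts.values()) > 0
            )
            with_hairpin_snp = sum(1 for p in sel if p.n_snps_hairpin > 0)
            with_mature = sum(1 for p in sel if p.mature_snp_positions)
            with_10_11 = sum(1 for p in sel if p.flags.get("snp_at_10_or_11"))
            rows.append(
                {
                    "group": group,
                    "chromosome": chrom,
                    "n_precursors": n,
                    "n_with_any_snp": with_snp,
                    "pct_with_any_snp": 100.0 * with_snp / n,
                    "n_with_hairpin_snp": with_hairpin_snp,
                    "pct_with_hairpin_snp": 100.0 * with_hairpin_snp / n,
                    "n_with_mature_snp": with_mature,
                    "pct_with_mature_snp": 100.0 * with_mature / n,
                    "n_with_snp_10_11": with_10_11,
                    "pct_with_snp_10_11": 100.0 * with_10_11 / n,
                }
            )
    return pd.DataFrame(rows)


def permutation_test_rates(
    rates_a: np.ndarray,
    rates_b: np.ndarray,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Two-sided label-permutation p-value for the difference of group
    mean rates, with add-one smoothing."""
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return {"p_value": None, "observed_diff": None, "note": "group too small"}
    pooled = np.concatenate([a, b])
    na = len(a)
    observed = a.mean() - b.mean()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        diff = perm[:na].mean() - perm[na:].mean()
        if abs(diff) >= abs(observed) - 1e-12:
            hits += 1
    return {
        "p_value": (hits + 1) / (n_permutations + 1),
        "observed_diff": float(observed),
        "n_permutations": n_permutations,
    }


def summarize_polymorphism(
    profiles: list[MirnaPolymorphism],
    group_of: dict[str, str],
    chrom_of: dict[str, str],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Table-1-style summary, Fig-5-style window rates and the
    conserved-versus-novel permutation comparison per region."""
    table = _table_rows(profiles, group_of, chrom_of)

    rate_rows = []
    for p in profiles:
        row = {"precursor_id": p.precursor_id,
               "group": group_of.get(p.precursor_id, "all"),
               "hairpin": p.hairpin_rate}
        row.update({k: p.window_rates.get(k, 0.0) for k in WINDOW_KEYS})
        rate_rows.append(row)
    rates = pd.DataFrame(rate_rows)

    comparison = {}
    groups = sorted(set(group_of.values()))
    if len(groups) == 2:
        ga = rates[rates["group"] == groups[0]]
        gb = rates[rates["group"] == groups[1]]
        for i, region in enumerate(("hairpin",) + WINDOW_KEYS):
            comparison[region] = permutation_test_rates(
                ga[region].to_numpy(),
                gb[region].to_numpy(),
                n_permutations,
                seed=seed + i,
            )
    else:
        comparison["note"] = "need exactly two groups for the comparison"
    return {"table": table, "rates_by_window": rates, "comparison": comparison}
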