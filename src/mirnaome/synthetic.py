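"""Synthetic genome, sRNA libraries, variant panel, transcriptome and
degradome with the statistical structure the analysis assumes.

The generator emulates the study conditions at desk scale: a ~5-Mb
two-chromosome genome hosting 30 planted miRNA hairpin loci spanning all
five read-signature class regimes, repeat-siRNA families (one 21-mer
copied 35 times), rRNA/tRNA loci, four adaptor-bearing raw sRNA
libraries with negative-binomial read counts and ±1-nt end wobble, a
26-accession variant panel with region-dependent SNP rates, and
transcripts carrying complementary target sites cleaved in a synthetic
degradome.  Every planted feature is recorded in a truth ledger; each
planted hairpin is verified (and, for planted negatives, its recorded
violation verified) by running the discovery module's own fold and
acceptance predicates at construction time.

All randomness flows from one integer seed through per-stage
``numpy.random.Generator`` streams, so identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fold import fold_mfe, is_complementary
from .hairpin import (
    HairpinThresholds,
    LoopSpanningError,
    PrecursorCandidate,
    accept_precursor,
    locate_duplex,
)
from .io_formats import GenomeSequence, revcomp, write_fasta
from .mapping import GenomeLocus

_BASES = np.array(list("ACGT"))
_NONPAIRING = {  # bases that can pair neither Watson-Crick nor wobble
    "A": "ACG",
    "C": "ACT",
    "G": "AG",
    "T": "CT",
}
_SUBSTITUTE = {"A": "C", "C": "A", "G": "T", "T": "G"}  # non-pairing, non-identical


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimulationConfig:
    """Study-scale defaults for the synthetic dataset."""

    seed: int = 0
    genome_length: int = 5_000_000
    n_chromosomes: int = 2
    n_true_mirna_loci: int = 30
    class_mix: dict = field(default_factory=lambda: {1: 10, 2: 6, 3: 6, 4: 4, 5: 4})
    n_sirna_repeat_loci: int = 5
    sirna_copy_number: int = 35
    n_rrna_trna_loci: int = 4
    gc_background: float = 0.35
    # genomic context of planted precursors (study-wide proportions)
    context_proportions: dict = field(
        default_factory=lambda: {
            "intergenic": 0.43,
            "antisense": 0.17,
            "intron": 0.16,
            "utr": 0.08,
            "cds": 0.16,
        }
    )
    frac_5prime_u: float = 0.62
    mature_length_probs: dict = field(
        default_factory=lambda: {21: 0.92, 22: 0.06, 20: 0.02}
    )
    # libraries
    n_libraries: int = 4
    mir_mean_count: float = 150.0
    nb_dispersion: float = 5.0       # negative-binomial size parameter
    min_mir_count: int = 25
    star_ratio: float = 0.15
    background_ratio: float = 0.033  # per-read outside/miR count ratio, class 2/4
    end_wobble_freq: float = 0.10
    adaptor: str = "TGGAATTCTCGGGTGCCAAGG"
    raw_read_length: int = 50
    background_reads_per_length: dict = field(
        default_factory=lambda: {
            18: 60, 19: 60, 20: 60, 21: 1800, 22: 60, 23: 60, 24: 600, 25: 60,
        }
    )
    background_extra_count_mean: float = 0.15
    sirna_read_count: int = 80
    structural_fragments_per_library: int = 30
    no_adaptor_fraction: float = 0.01
    # known-mature catalogue
    n_known_exact: int = 6
    n_known_variant: int = 4
    n_catalog_decoys: int = 10
    # variant panel
    n_accessions: int = 26
    snp_rate_by_region: dict = field(
        default_factory=lambda: {
            "mature": 0.2,
            "hairpin": 1.0,
            "flank": 1.5,
            "background": 0.02,
        }
    )
    indel_fraction: float = 0.1
    flank: int = 1500
    # transcriptome / degradome
    n_transcripts: int = 30
    transcript_length: tuple = (500, 1500)
    n_planted_target_sites: int = 15
    n_decoy_target_sites: int = 5
    target_site_edits: int = 0
    degradome_depth: int = 100
    degradome_signal_fraction: float = 0.8
    degradome_background_tags: int = 300
    degradome_tag_length: int = 20
    # homolog genomes for conservation categories
    clade_genomes: tuple = ("clade_sp1", "clade_sp2")
    outgroup_genomes: tuple = ("outgroup_sp1", "outgroup_sp2")
    homolog_genome_length: int = 100_000

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class HairpinParams:
    """Geometry of one constructed stem-loop."""

    n_mismatches: int = 2
    n_gaps: int = 0
    max_consecutive_mm: int = 2
    loop_len: int = 8
    lower_stem_len: int = 20
    n_lower_mismatches: int = 0
    overhang: int = 2


@dataclass
class PlantedLocus:
    locus_id: str
    kind: str                     # mirna | sirna_repeat | structural_rna
    precursor_locus: GenomeLocus  # full planted hairpin extent (miRNA only)
    mature_locus: GenomeLocus | None
    mature_seq: str | None
    star_seq: str | None
    expected_class: int | None
    context: str | None
    known_status: str | None = None   # known_exact | known_variant | novel
    negative_reason: str | None = None
    copy_loci: tuple = ()             # siRNA repeat copies
    precursor_seq: str | None = None
    mir_span: tuple | None = None     # local offsets within precursor_seq
    star_span: tuple | None = None
    loop_span: tuple | None = None
    expected_conservation: str | None = None


@dataclass
class PlantedTarget:
    mirna_id: str
    mature_seq: str
    transcript_id: str
    site_start: int
    site_end: int
    cleavage_pos: int
    is_decoy: bool
    n_edits: int


@dataclass
class TruthLedger:
    loci: list = field(default_factory=list)
    targets: list = field(default_factory=list)

    def mirna_loci(self):
        return [p for p in self.loci if p.kind == "mirna"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.loci:
            rows.append(
                {
                    "locus_id": p.locus_id,
                    "kind": p.kind,
                    "seq_id": p.precursor_locus.seq_id if p.precursor_locus else "",
                    "start": p.precursor_locus.start if p.precursor_locus else -1,
                    "end": p.precursor_locus.end if p.precursor_locus else -1,
                    "strand": p.precursor_locus.strand if p.precursor_locus else ".",
                    "mature_seq": p.mature_seq or "",
                    "star_seq": p.star_seq or "",
                    "expected_class": p.expected_class or 0,
                    "context": p.context or "",
                    "known_status": p.known_status or "",
                    "expected_conservation": p.expected_conservation or "",
                    "n_copies": len(p.copy_loci) or 1,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: dict
    features: list
    truth: TruthLedger
    libraries: dict            # library_id -> list of raw read strings
    known_matures: list        # [(name, seq)]
    variants: list             # VariantRecord
    transcripts: list          # [(id, seq)]
    degradome_tags: list       # [(id, seq)]  (duplicates encode abundance)
    homolog_genomes: dict      # species -> dict[str, GenomeSequence]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def _random_seq(rng, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


# ---------------------------------------------------------------------------
# hairpin construction


def _mismatch_runs(n: int, max_run: int) -> list[int]:
    runs = []
    while n > 0:
        take = min(max_run, n)
        runs.append(take)
        n -= take
    return runs


def simulate_hairpin(
    mature: str, params: HairpinParams, rng: np.random.Generator
) -> tuple[str, tuple[int, int], tuple[int, int]]:
    """Construct a precursor whose 3' arm is the reverse complement of the
    mature with the requested mismatch/gap pattern, leaving 2-nt 3'
    overhangs; returns (precursor DNA, mir span, intended star span).

    Raises ValueError if the pattern is not geometrically placeable.
    """
    L = len(mature)
    usable_lo, usable_hi = 2, L - 4  # keep duplex ends anchored
    runs = _mismatch_runs(params.n_mismatches, params.max_consecutive_mm)
    span_needed = sum(runs) + 2 * max(0, len(runs) - 1) + 3 * params.n_gaps
    if span_needed > usable_hi - usable_lo:
        raise ValueError("mismatch/gap pattern not placeable on the stem")

    # lay out mismatch runs then gaps left to right with 2-nt paired spacers
    mm_positions: list[int] = []
    gap_positions: list[int] = []
    cursor = usable_lo
    for run in runs:
        mm_positions.extend(range(cursor, cursor + run))
        cursor += run + 2
    for _ in range(params.n_gaps):
        gap_positions.append(cursor)
        cursor += 3

    arm3 = list(revcomp(mature))  # arm3[L-1-k] pairs mature position k
    for k in mm_positions:
        choices = _NONPAIRING[mature[k]]
        arm3[L - 1 - k] = choices[rng.integers(len(choices))]
    for k in sorted(gap_positions, reverse=True):
        del arm3[L - 1 - k]

    lower5 = _random_seq(rng, params.lower_stem_len, gc=0.62)
    lower3 = list(revcomp(lower5))
    for k in rng.choice(
        np.arange(3, max(4, params.lower_stem_len - 3)),
        size=min(params.n_lower_mismatches, max(1, params.lower_stem_len - 6)),
        replace=False,
    ) if params.n_lower_mismatches else []:
        # lower-stem mismatch: breaks the perfect palindrome so loop/stem
        # reads stay unique in the genome
        base = lower5[params.lower_stem_len - 1 - int(k)]
        choices = _NONPAIRING[base]
        lower3[int(k)] = choices[rng.integers(len(choices))]

    loop = _random_seq(rng, params.loop_len, gc=0.3)
    precursor = lower5 + mature + loop + "".join(arm3) + "".join(lower3)
    mir_span = (params.lower_stem_len, params.lower_stem_len + L)

    # intended star span: partner region of the anchored mature positions,
    # plus the 2-nt 3' overhang
    arm3_start = mir_span[1] + params.loop_len
    deleted = sorted(L - 1 - k for k in gap_positions)
    partners = []
    for k in range(0, L - 2):
        if k in mm_positions or k in gap_positions:
            continue
        idx = L - 1 - k
        idx_mod = idx - sum(1 for d in deleted if d < idx)
        partners.append(arm3_start + idx_mod)
    star_span = (min(partners), max(partners) + 1 + params.overhang)
    return precursor, mir_span, star_span


def verify_hairpin(
    precursor: str,
    mir_span: tuple[int, int],
    thresholds: HairpinThresholds | None = None,
    backend: str = "bundled",
):
    """Run the discovery module's own predicates on a construct.

    Returns (accepted, reasons, candidate|None).
    """
    fold = fold_mfe(precursor, backend=backend)
    try:
        star_span, metrics = locate_duplex(fold, mir_span)
    except LoopSpanningError:
        return False, ["loop_spanning"], None
    candidate = PrecursorCandidate(
        locus=GenomeLocus("construct", 0, len(precursor), "+"),
        sequence=precursor,
        fold=fold,
        mir_span=mir_span,
        star_span=star_span,
        duplex=metrics,
    )
    ok, reasons = accept_precursor(candidate, thresholds)
    return ok, reasons, candidate


_NEGATIVE_RECIPES = {
    # duplex-criterion violations: params guaranteeing exactly one failure
    "consecutive_mismatches": HairpinParams(
        n_mismatches=4, n_gaps=0, max_consecutive_mm=4, loop_len=8, lower_stem_len=24
    ),
    "gaps": HairpinParams(
        n_mismatches=1, n_gaps=3, max_consecutive_mm=1, loop_len=8, lower_stem_len=24
    ),
    "total_mm_gap": HairpinParams(
        n_mismatches=6, n_gaps=2, max_consecutive_mm=2, loop_len=8, lower_stem_len=26
    ),
}


def simulate_criterion_negative(
    mature: str, criterion: str, rng: np.random.Generator, max_tries: int = 80
):
    """A planted negative violating exactly one duplex criterion.

    Returns (precursor, mir_span, candidate); the construct is verified
    with the discovery module's own predicates to fail with the recorded
    reason (and no other duplex reason).
    """
    recipe = _NEGATIVE_RECIPES[criterion]
    others = set(_NEGATIVE_RECIPES) - {criterion}
    for _ in range(max_tries):
        try:
            precursor, mir_span, _ = simulate_hairpin(mature, recipe, rng)
        except ValueError:
            raise
        ok, reasons, cand = verify_hairpin(precursor, mir_span)
        if ok or cand is None:
            continue
        if criterion in reasons and not others & set(reasons):
            return precursor, mir_span, cand
    raise RuntimeError(f"could not construct a clean negative for {criterion}")


# ---------------------------------------------------------------------------
# genome


def _class_params(cls: int, rng) -> HairpinParams:
    """Duplex geometry per class regime; >= 1 mismatch always, so the
    planted arms are never perfect palindromes (keeps read loci unique)."""
    long_loop = cls in (2, 4, 5)
    return HairpinParams(
        n_mismatches=int(rng.integers(1, 4)),
        n_gaps=int(rng.integers(0, 2)),
        max_consecutive_mm=2,
        loop_len=40 if long_loop else int(rng.integers(8, 16)),
        lower_stem_len=35 if long_loop else int(rng.integers(18, 26)),
        n_lower_mismatches=2 if long_loop else 1,
    )


def _draw_mature(cfg: SimulationConfig, rng, forbidden: set[str]) -> str:
    lengths = sorted(cfg.mature_length_probs)
    probs = np.array([cfg.mature_length_probs[k] for k in lengths])
    probs = probs / probs.sum()
    seed8 = cfg.adaptor[:8]
    while True:
        L = int(rng.choice(lengths, p=probs))
        seq = _random_seq(rng, L, gc=0.45)
        if rng.random() < cfg.frac_5prime_u:
            seq = "T" + seq[1:]
        elif seq[0] == "T":
            seq = rng.choice(list("ACG")) + seq[1:]
        if seed8 in seq or seq in forbidden:
            continue
        return seq


class _SlotPlanner:
    """Hands out non-overlapping genomic slots on a fixed grid."""

    def __init__(self, chrom_lengths: dict[str, int], spacing: int, rng):
        slots = []
        for seq_id in sorted(chrom_lengths):
            n = chrom_lengths[seq_id]
            for pos in range(spacing, n - spacing, spacing):
                slots.append((seq_id, pos))
        order = rng.permutation(len(slots))
        self._slots = [slots[i] for i in order]

    def take(self) -> tuple[str, int]:
        if not self._slots:
            raise ValueError("genome too small to host all planted loci")
        return self._slots.pop()


def simulate_genome(config: SimulationConfig):
    """Build the genome, its annotation and the truth ledger."""
    rng = _rng(config.seed, 1)
    cfg = config

    chrom_len = cfg.genome_length // cfg.n_chromosomes
    chrom_ids = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    arrays: dict[str, np.ndarray] = {}
    gc = cfg.gc_background
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    for cid in chrom_ids:
        arrays[cid] = rng.choice(_BASES, size=chrom_len, p=p)

    planner = _SlotPlanner({c: chrom_len for c in chrom_ids}, 6000, rng)
    features: list = []
    truth = TruthLedger()

    # class and context assignment
    classes = [c for c, n in sorted(cfg.class_mix.items()) for _ in range(n)]
    if len(classes) != cfg.n_true_mirna_loci:
        raise ValueError("class_mix must sum to n_true_mirna_loci")
    contexts = _allocate(cfg.context_proportions, cfg.n_true_mirna_loci)
    classes = [classes[i] for i in rng.permutation(len(classes))]
    contexts = [contexts[i] for i in rng.permutation(len(contexts))]

    from .io_formats import FeatureRecord

    used_matures: set[str] = set()
    thresholds = HairpinThresholds()
    for i, (cls, context) in enumerate(zip(classes, contexts)):
        locus_id = f"mir_{i + 1:03d}"
        strand = "+" if rng.random() < 0.67 else "-"
        seq_id, pos = planner.take()
        saved = arrays[seq_id][pos : pos + 220].copy()
        for _attempt in range(40):
            mature = _draw_mature(cfg, rng, used_matures)
            params = _class_params(cls, rng)
            try:
                precursor, mir_span, star_span = simulate_hairpin(mature, params, rng)
            except ValueError:
                continue
            if cfg.adaptor[:8] in precursor:
                continue
            ok, _reasons, cand = verify_hairpin(precursor, mir_span, thresholds)
            if not ok or abs(cand.star_span[0] - star_span[0]) > 2:
                continue
            # the realized miR* must itself be a placeable 20-24-nt read,
            # as real passenger strands are; otherwise redraw
            star_len = cand.star_span[1] - cand.star_span[0]
            if not 20 <= star_len <= 24:
                continue
            # embed, then re-verify in the padded genomic window the
            # discovery stage will actually fold (flanks can reshape the MFE)
            planted = precursor if strand == "+" else revcomp(precursor)
            arrays[seq_id][pos : pos + 220] = saved
            arrays[seq_id][pos : pos + len(precursor)] = list(planted)
            if strand == "+":
                m_start = pos + mir_span[0]
            else:
                m_start = pos + len(precursor) - mir_span[1]
            window = "".join(
                arrays[seq_id][m_start - 400 : m_start + len(mature) + 400]
            )
            if strand == "-":
                window = revcomp(window)
            win_cand = _verify_embedded(window, len(mature), thresholds)
            # the mature must occur exactly once in its window and never
            # as a reverse complement: an exact antisense copy on the
            # opposite arm would create a duplicate mapping locus
            if (
                win_cand is None
                or window.count(mature) != 1
                or revcomp(mature) in window
            ):
                arrays[seq_id][pos : pos + 220] = saved
                continue
            break
        else:
            raise RuntimeError(f"could not construct hairpin for {locus_id}")

        used_matures.add(mature)
        prec_locus = GenomeLocus(seq_id, pos, pos + len(precursor), strand)
        mature_locus = GenomeLocus(seq_id, m_start, m_start + len(mature), strand)
        loop_span = (mir_span[1], mir_span[1] + params.loop_len)
        truth.loci.append(
            PlantedLocus(
                locus_id=locus_id,
                kind="mirna",
                precursor_locus=prec_locus,
                mature_locus=mature_locus,
                mature_seq=mature,
                star_seq=precursor[cand.star_span[0] : cand.star_span[1]],
                expected_class=cls,
                context=context,
                precursor_seq=precursor,
                mir_span=mir_span,
                star_span=cand.star_span,
                loop_span=loop_span,
            )
        )
        features.extend(
            _context_features(FeatureRecord, locus_id, prec_locus, context, chrom_len)
        )

    # siRNA repeat families: one 21-mer copied sirna_copy_number times
    for s in range(cfg.n_sirna_repeat_loci):
        unit = _random_seq(rng, 21, gc=0.4)
        copies = []
        for _c in range(cfg.sirna_copy_number):
            seq_id, pos = planner.take()
            arrays[seq_id][pos : pos + 21] = list(unit)
            copies.append(GenomeLocus(seq_id, pos, pos + 21, "+"))
        truth.loci.append(
            PlantedLocus(
                locus_id=f"sirna_{s + 1:02d}",
                kind="sirna_repeat",
                precursor_locus=copies[0],
                mature_locus=None,
                mature_seq=unit,
                star_seq=None,
                expected_class=None,
                context=None,
                copy_loci=tuple(copies),
            )
        )

    # structural rRNA/tRNA loci
    for s in range(cfg.n_rrna_trna_loci):
        seq_id, pos = planner.take()
        seq = _random_seq(rng, 120, gc=0.55)
        arrays[seq_id][pos : pos + 120] = list(seq)
        ftype = "rRNA" if s % 2 == 0 else "tRNA"
        features.append(
            FeatureRecord(
                seq_id, "synthetic", ftype, pos, pos + 120, "+",
                {"ID": f"struct_{s + 1:02d}"},
            )
        )
        truth.loci.append(
            PlantedLocus(
                locus_id=f"struct_{s + 1:02d}",
                kind="structural_rna",
                precursor_locus=GenomeLocus(seq_id, pos, pos + 120, "+"),
                mature_locus=None,
                mature_seq=seq,
                star_seq=None,
                expected_class=None,
                context=None,
            )
        )

    genome = {
        cid: GenomeSequence(cid, "".join(arrays[cid])) for cid in chrom_ids
    }
    features.sort(key=lambda f: (f.seq_id, f.start, f.end, f.feature_type))
    return genome, features, truth


def _verify_embedded(window: str, mature_len: int, thresholds) -> object | None:
    """Fold the discovery-stage window around an embedded mature and run
    the full locate/accept/trim cascade; None if any step fails."""
    from .hairpin import ContextFrame, trim_precursor

    mir_span = (400, 400 + mature_len)
    fold = fold_mfe(window)
    try:
        star_span, metrics = locate_duplex(fold, mir_span)
    except LoopSpanningError:
        return None
    cand = PrecursorCandidate(
        locus=GenomeLocus("w", 0, len(window), "+"),
        sequence=window,
        fold=fold,
        mir_span=mir_span,
        star_span=star_span,
        duplex=metrics,
    )
    ok, _ = accept_precursor(cand, thresholds)
    if not ok:
        return None
    frame = ContextFrame("w", 0, len(window), "+")
    try:
        return trim_precursor(cand, frame, 15, thresholds)
    except ValueError:
        return None


def _allocate(proportions: dict, n: int) -> list[str]:
    keys = sorted(proportions)
    counts = {k: int(round(proportions[k] * n)) for k in keys}
    drift = n - sum(counts.values())
    counts[max(keys, key=lambda k: proportions[k])] += drift
    return [k for k in keys for _ in range(counts[k])]


def _context_features(FeatureRecord, locus_id, prec: GenomeLocus, context, chrom_len):
    """Gene models realising the requested genomic context of a precursor."""
    out = []
    pad = 300
    g_start = max(0, prec.start - pad)
    g_end = min(chrom_len, prec.end + pad)
    gid = f"gene_{locus_id}"
    if context == "intergenic":
        return out
    if context == "antisense":
        strand = "-" if prec.strand == "+" else "+"
        out.append(FeatureRecord(prec.seq_id, "synthetic", "gene", g_start, g_end, strand, {"ID": gid}))
        out.append(FeatureRecord(prec.seq_id, "synthetic", "mRNA", g_start, g_end, strand, {"ID": f"{gid}.t", "Parent": gid}))
        out.append(FeatureRecord(prec.seq_id, "synthetic", "exon", g_start, g_end, strand, {"Parent": f"{gid}.t"}))
        out.append(FeatureRecord(prec.seq_id, "synthetic", "CDS", g_start, g_end, strand, {"Parent": f"{gid}.t"}))
        return out
    strand = prec.strand
    out.append(FeatureRecord(prec.seq_id, "synthetic", "gene", g_start, g_end, strand, {"ID": gid}))
    out.append(FeatureRecord(prec.seq_id, "synthetic", "mRNA", g_start, g_end, strand, {"ID": f"{gid}.t", "Parent": gid}))
    if context == "intron":
        # two exons flanking the precursor; the precursor sits in the intron
        out.append(FeatureRecord(prec.seq_id, "synthetic", "exon", g_start, prec.start - 50, strand, {"Parent": f"{gid}.t"}))
        out.append(FeatureRecord(prec.seq_id, "synthetic", "exon", prec.end + 50, g_end, strand, {"Parent": f"{gid}.t"}))
        out.append(FeatureRecord(prec.seq_id, "synthetic", "CDS", g_start, prec.start - 50, strand, {"Parent": f"{gid}.t"}))
        out.append(FeatureRecord(prec.seq_id, "synthetic", "CDS", prec.end + 50, g_end, strand, {"Parent": f"{gid}.t"}))
    elif context == "utr":
        utr_type = "five_prime_UTR" if strand == "+" else "three_prime_UTR"
        out.append(FeatureRecord(prec.seq_id, "synthetic", "exon", g_start, g_end, strand, {"Parent": f"{gid}.t"}))
        out.append(FeatureRecord(prec.seq_id, "synthetic", utr_type, g_start, prec.end + 50, strand, {"Parent": f"{gid}.t"}))
        out.append(FeatureRecord(prec.seq_id, "synthetic", "CDS", prec.end + 60, g_end, strand, {"Parent": f"{gid}.t"}))
    elif context == "cds":
        out.append(FeatureRecord(prec.seq_id, "synthetic", "exon", g_start, g_end, strand, {"Parent": f"{gid}.t"}))
        out.append(FeatureRecord(prec.seq_id, "synthetic", "CDS", g_start, g_end, strand, {"Parent": f"{gid}.t"}))
    return out


# ---------------------------------------------------------------------------
# libraries


def _nb(rng, mean: float, size_param: float) -> int:
    p = size_param / (size_param + mean)
    return int(rng.negative_binomial(size_param, p))


def simulate_libraries(genome, truth: TruthLedger, config: SimulationConfig):
    """Raw (adaptor-bearing) reads per library.

    Per miRNA locus the miR count is negative-binomial, the miR* count a
    fixed ratio of it, outside reads follow the class regime, and 10% of
    miR reads carry ±1-nt end wobble.  Returns
    ``{library_id: [raw read strings]}`` plus the per-library truth of
    planted inserts (for tests).
    """
    cfg = config
    rng = _rng(cfg.seed, 2)
    occupied = _occupied_intervals(truth)
    libraries: dict[str, list[str]] = {}
    for li in range(cfg.n_libraries):
        lib = f"lib{li + 1}"
        inserts: list[str] = []

        for locus in truth.mirna_loci():
            m = max(cfg.min_mir_count, _nb(rng, cfg.mir_mean_count, cfg.nb_dispersion))
            prec = locus.precursor_seq
            p0, p1 = locus.mir_span
            n_wobble = int(round(m * cfg.end_wobble_freq))
            inserts += [locus.mature_seq] * (m - n_wobble)
            inserts += [prec[p0 - 1 : p1 - 1]] * (n_wobble // 2)
            inserts += [prec[p0 + 1 : p1 + 1]] * (n_wobble - n_wobble // 2)
            cls = locus.expected_class
            if cls in (1, 2, 5):
                inserts += [locus.star_seq] * max(1, int(round(m * cfg.star_ratio)))
            if cls in (2, 4):
                # rare additional smRNAs from the (long) terminal loop
                lo = locus.loop_span[0] + 2
                c = max(1, int(m * cfg.background_ratio))
                for off, ln in ((1, 23), (6, 24), (12, 23)):
                    inserts += [prec[lo + off : lo + off + ln]] * c
            elif cls == 5:
                # loop smRNAs dominating the precursor
                lo = locus.loop_span[0] + 2
                for off, ln in ((1, 23), (10, 24)):
                    inserts += [prec[lo + off : lo + off + ln]] * m

        for locus in truth.loci:
            if locus.kind == "sirna_repeat":
                inserts += [locus.mature_seq] * cfg.sirna_read_count
            elif locus.kind == "structural_rna":
                for _ in range(cfg.structural_fragments_per_library):
                    ln = int(rng.integers(18, 26))
                    off = int(rng.integers(0, 120 - ln))
                    inserts.append(locus.mature_seq[off : off + ln])

        # random degradation background drawn outside planted loci
        for length in sorted(cfg.background_reads_per_length):
            n_distinct = cfg.background_reads_per_length[length]
            for _ in range(n_distinct):
                seq = _draw_background_fragment(rng, genome, length, occupied)
                count = 1 + int(rng.poisson(cfg.background_extra_count_mean))
                inserts += [seq] * min(count, 8)

        raw = [_to_raw_read(s, cfg, rng) for s in inserts]
        n_junk = int(len(raw) * cfg.no_adaptor_fraction)
        raw += [_random_seq(rng, cfg.raw_read_length, gc=0.5) for _ in range(n_junk)]
        order = rng.permutation(len(raw))
        libraries[lib] = [raw[i] for i in order]
    return libraries


def _occupied_intervals(truth: TruthLedger):
    occ: dict[str, list] = {}
    for locus in truth.loci:
        spans = locus.copy_loci or (locus.precursor_locus,)
        for g in spans:
            occ.setdefault(g.seq_id, []).append((g.start - 60, g.end + 60))
    for v in occ.values():
        v.sort()
    return occ


def _draw_background_fragment(rng, genome, length, occupied):
    chrom_ids = sorted(genome)
    while True:
        cid = chrom_ids[int(rng.integers(len(chrom_ids)))]
        residues = genome[cid].residues
        pos = int(rng.integers(0, len(residues) - length))
        if any(s < pos + length and pos < e for s, e in occupied.get(cid, [])):
            continue
        seq = residues[pos : pos + length]
        if "N" in seq:
            continue
        return seq if rng.random() < 0.5 else revcomp(seq)


def _to_raw_read(insert: str, cfg: SimulationConfig, rng) -> str:
    raw = insert + cfg.adaptor
    if len(raw) < cfg.raw_read_length:
        raw += _random_seq(rng, cfg.raw_read_length - len(raw), gc=0.5)
    return raw[: cfg.raw_read_length]


# ---------------------------------------------------------------------------
# known-mature catalogue


def simulate_known_catalog(truth: TruthLedger, config: SimulationConfig):
    """Catalogue FASTA: some planted matures verbatim (known_exact), some
    2-mismatch variants of planted matures (-> known_variant), plus
    unrelated decoy entries; annotates expected status in the ledger."""
    rng = _rng(config.seed, 3)
    mirnas = truth.mirna_loci()
    order = rng.permutation(len(mirnas))
    catalog = []
    n_exact, n_var = config.n_known_exact, config.n_known_variant
    for rank, idx in enumerate(order):
        locus = mirnas[int(idx)]
        if rank < n_exact:
            locus.known_status = "known_exact"
            catalog.append((f"cat-{locus.locus_id}", locus.mature_seq))
        elif rank < n_exact + n_var:
            locus.known_status = "known_variant"
            variant = list(locus.mature_seq)
            for k in rng.choice(len(variant) - 2, size=2, replace=False):
                variant[int(k) + 1] = _SUBSTITUTE[variant[int(k) + 1]]
            catalog.append((f"cat-var-{locus.locus_id}", "".join(variant)))
        else:
            locus.known_status = "novel"
    for d in range(config.n_catalog_decoys):
        catalog.append((f"cat-decoy-{d + 1:02d}", _random_seq(rng, 21, gc=0.45)))
    return catalog


# ---------------------------------------------------------------------------
# variant panel


def simulate_variant_panel(genome, truth: TruthLedger, config: SimulationConfig):
    """Region-rate SNP/indel panel over the planted miRNA loci.

    SNP positions are Poisson-drawn per region at the configured per-100-bp
    rates (mature sub-region lowest by default, mirroring purifying
    selection on the mature); each variant is carried by a random
    non-empty subset of accessions.
    """
    from .io_formats import VariantRecord

    cfg = config
    rng = _rng(cfg.seed, 4)
    rates = cfg.snp_rate_by_region
    accessions = [f"acc{i + 1:02d}" for i in range(cfg.n_accessions)]
    chosen: dict[tuple, tuple] = {}

    def add_region(seq_id, start, end, rate):
        length = max(0, end - start)
        if length == 0 or rate <= 0:
            return
        n = rng.poisson(length * rate / 100.0)
        for _ in range(n):
            pos = start + int(rng.integers(0, length))
            chosen.setdefault((seq_id, pos), (seq_id, pos))

    for locus in truth.mirna_loci():
        g = locus.precursor_locus
        m = locus.mature_locus
        add_region(g.seq_id, m.start, m.end, rates["mature"])
        # hairpin outside the mature
        add_region(g.seq_id, g.start, m.start, rates["hairpin"])
        add_region(g.seq_id, m.end, g.end, rates["hairpin"])
        add_region(g.seq_id, max(0, g.start - cfg.flank), g.start, rates["flank"])
        chrom_len = len(genome[g.seq_id])
        add_region(g.seq_id, g.end, min(chrom_len, g.end + cfg.flank), rates["flank"])

    if rates.get("background", 0) > 0:
        for cid in sorted(genome):
            add_region(cid, 0, len(genome[cid]), rates["background"])

    records = []
    for (seq_id, pos) in sorted(chosen):
        ref = genome[seq_id].residues[pos]
        if ref == "N":
            continue
        if rng.random() < cfg.indel_fraction:
            dlen = int(rng.integers(1, 3))
            if rng.random() < 0.5 and pos + 1 + dlen <= len(genome[seq_id]):
                ref_a = genome[seq_id].residues[pos : pos + 1 + dlen]
                alt_a = ref_a[0]
            else:
                ref_a = ref
                alt_a = ref + _random_seq(rng, dlen, 0.5)
        else:
            ref_a = ref
            alt_a = str(rng.choice([b for b in "ACGT" if b != ref]))
        k = int(rng.integers(1, cfg.n_accessions + 1))
        carriers = frozenset(
            accessions[int(i)] for i in rng.choice(cfg.n_accessions, size=k, replace=False)
        )
        records.append(
            VariantRecord(seq_id, pos, ref_a, alt_a, carriers,
                          VariantRecord.classify(ref_a, alt_a))
        )
    return records


# ---------------------------------------------------------------------------
# transcriptome + degradome


def simulate_transcriptome_and_degradome(truth: TruthLedger, config: SimulationConfig):
    """Transcripts with planted complementary sites and a degradome whose
    signal tags start exactly opposite miRNA position 10."""
    cfg = config
    rng = _rng(cfg.seed, 5)
    mirnas = [p for p in truth.mirna_loci() if p.expected_class in (1, 2)]
    transcripts: list[tuple[str, str]] = []
    tags: list[tuple[str, str]] = []
    tag_no = 0

    n_sites = min(cfg.n_planted_target_sites, len(mirnas))
    site_mirnas = [mirnas[int(i)] for i in rng.choice(len(mirnas), size=n_sites, replace=False)]
    decoy_pool = truth.mirna_loci()

    for t in range(cfg.n_transcripts):
        tid = f"T{t + 1:04d}"
        tl = int(rng.integers(*cfg.transcript_length))
        seq = _random_seq(rng, tl, gc=0.42)
        if t < n_sites:
            locus = site_mirnas[t]
            site = _edited_site(locus.mature_seq, cfg.target_site_edits, rng)
            pos = int(rng.integers(100, tl - len(site) - 100))
            seq = seq[:pos] + site + seq[pos + len(site) :]
            cleavage = pos + len(locus.mature_seq) - 10
            truth.targets.append(
                PlantedTarget(locus.locus_id, locus.mature_seq, tid, pos,
                              pos + len(site), cleavage, False, cfg.target_site_edits)
            )
            n_signal = int(round(cfg.degradome_depth * cfg.degradome_signal_fraction))
            tag = seq[cleavage : cleavage + cfg.degradome_tag_length]
            for _ in range(n_signal):
                tags.append((f"tag{tag_no:06d}", tag))
                tag_no += 1
        elif t < n_sites + cfg.n_decoy_target_sites and decoy_pool:
            locus = decoy_pool[int(rng.integers(len(decoy_pool)))]
            site = _edited_site(locus.mature_seq, 3, rng)
            pos = int(rng.integers(100, tl - len(site) - 100))
            seq = seq[:pos] + site + seq[pos + len(site) :]
            truth.targets.append(
                PlantedTarget(locus.locus_id, locus.mature_seq, tid, pos,
                              pos + len(site), pos + len(locus.mature_seq) - 10,
                              True, 3)
            )
        transcripts.append((tid, seq))

    # uniform background degradome tags
    for _ in range(cfg.degradome_background_tags):
        tid, seq = transcripts[int(rng.integers(len(transcripts)))]
        pos = int(rng.integers(0, len(seq) - cfg.degradome_tag_length))
        tags.append((f"tag{tag_no:06d}", seq[pos : pos + cfg.degradome_tag_length]))
        tag_no += 1
    return transcripts, tags


def _edited_site(mature: str, n_edits: int, rng) -> str:
    """Reverse-complement target site with n mismatching edits (outside
    the 2-8 seed-pairing region so penalty maps 1:1 to edits)."""
    site = list(revcomp(mature))
    L = len(mature)
    if n_edits:
        # site position pairing miRNA position k (1-based) is L-k
        allowed = [L - k for k in range(10, L - 1)]
        for k in rng.choice(len(allowed), size=n_edits, replace=False):
            i = allowed[int(k)]
            base = site[i]
            # replace with a base that cannot pair the miRNA position
            mir_base = revcomp(base)  # original pairing partner (WC)
            site[i] = _NONPAIRING[mir_base][0]
    return "".join(site)


# ---------------------------------------------------------------------------
# homolog genomes for conservation calls


def simulate_homolog_genomes(truth: TruthLedger, config: SimulationConfig):
    """Small stand-in genomes for related (clade) and outgroup species,
    with matures planted (<=3 mismatches) according to an expected
    conservation category recorded in the ledger."""
    cfg = config
    rng = _rng(cfg.seed, 6)
    species = list(cfg.clade_genomes) + list(cfg.outgroup_genomes)
    arrays = {
        sp: rng.choice(_BASES, size=cfg.homolog_genome_length, p=[0.3, 0.2, 0.2, 0.3])
        for sp in species
    }
    positions = {}
    for sp in species:
        grid = list(range(500, cfg.homolog_genome_length - 500, 1000))
        positions[sp] = [grid[i] for i in rng.permutation(len(grid))]

    cats = ["widespread", "clade_specific", "species_specific"]
    for idx, locus in enumerate(truth.mirna_loci()):
        cat = cats[idx % 3]
        locus.expected_conservation = cat
        if cat == "species_specific":
            continue
        targets = list(cfg.clade_genomes)
        if cat == "widespread":
            targets.append(cfg.outgroup_genomes[idx % len(cfg.outgroup_genomes)])
        for sp in targets:
            seq = list(locus.mature_seq)
            for k in rng.choice(len(seq) - 4, size=int(rng.integers(0, 4)), replace=False):
                seq[int(k) + 2] = str(rng.choice([b for b in "ACGT" if b != seq[int(k) + 2]]))
            pos = positions[sp].pop()
            arrays[sp][pos : pos + len(seq)] = seq
    return {
        sp: {sp: GenomeSequence(sp, "".join(arrays[sp]))} for sp in species
    }


# ---------------------------------------------------------------------------
# one-call dataset


def simulate_all(config: SimulationConfig) -> SyntheticDataset:
    genome, features, truth = simulate_genome(config)
    known = simulate_known_catalog(truth, config)
    libraries = simulate_libraries(genome, truth, config)
    variants = simulate_variant_panel(genome, truth, config)
    transcripts, tags = simulate_transcriptome_and_degradome(truth, config)
    homologs = simulate_homolog_genomes(truth, config)
    return SyntheticDataset(
        config=config,
        genome=genome,
        features=features,
        truth=truth,
        libraries=libraries,
        known_matures=known,
        variants=variants,
        transcripts=transcripts,
        degradome_tags=tags,
        homolog_genomes=homologs,
    )


def write_dataset(data: SyntheticDataset, out_dir) -> None:
    """Emit the dataset as plain-text files (FASTA/FASTQ/GFF3/VCF/TSV)."""
    from .io_formats import write_gff3, write_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(((cid, g.residues) for cid, g in sorted(data.genome.items())),
                out / "genome.fa")
    write_gff3(data.features, out / "annotation.gff3", source="synthetic")
    for lib in sorted(data.libraries):
        with open(out / f"{lib}.fastq", "w") as fh:
            for i, read in enumerate(data.libraries[lib]):
                fh.write(f"@{lib}_{i}\n{read}\n+\n{'I' * len(read)}\n")
    write_fasta(data.known_matures, out / "known_matures.fa")
    write_fasta(data.transcripts, out / "transcripts.fa")
    write_fasta(data.degradome_tags, out / "degradome.fa")
    _write_vcf(data, out / "variants.vcf")
    for sp, genome in sorted(data.homolog_genomes.items()):
        write_fasta(((cid, g.residues) for cid, g in sorted(genome.items())),
                    out / f"homolog_{sp}.fa")
    write_table(data.truth.to_frame(), out / "truth.tsv")


def _write_vcf(data: SyntheticDataset, path) -> None:
    accessions = [f"acc{i + 1:02d}" for i in range(data.config.n_accessions)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for cid in sorted(data.genome):
            fh.write(f"##contig=<ID={cid},length={len(data.genome[cid])}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(accessions) + "\n")
        for v in sorted(data.variants, key=lambda r: (r.seq_id, r.pos, r.alt_allele)):
            gts = ["1/1" if a in v.accession_presence else "0/0" for a in accessions]
            fh.write(
                f"{v.seq_id}\t{v.pos + 1}\t.\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )
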