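"""Greedy defining-smRNA assignment, read-signature classification of
precursors, retention gates and genomic-context labelling.

The defining smRNA of a precursor is chosen greedily: candidate lengths
are processed 21, then 22, then 20 nt, within a length by descending
total read count (ties lexicographic).  Each accepted hairpin is
annotated with every 20-24-nt read placed inside it, and its reads are
withdrawn from the candidate list, so no read defines two precursors.

Per library, a precursor is classified only if its defining read sat in
that library's top-5% expression gate:

* class 1 — reads only from both strands of the miR:miR* region,
* class 2 — miR and miR* plus rare additional smRNAs (mean per-read
  count at most a tenth of the miR-region expression),
* class 3 / 4 — as 1 / 2 but without any miR* read,
* class 5 — reads outside the miR region out-sum the miR region.

The global class is the best (numerically smallest) class over
classified libraries; classes 1-2 are bona fide.  Classes 3-5 are
retained only when their read signature is Dicer-consistent and the
mature resembles a bona fide mature (the rescue rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .families import mismatch_distance
from .hairpin import PrecursorCandidate, discover_hairpin
from .io_formats import FeatureRecord
from .mapping import GenomeLocus, MappedRead
from .reads import CollapsedRead

DEFINING_LENGTH_ORDER = (21, 22, 20)
PLACED_MIN, PLACED_MAX = 20, 24
MIR_REGION_MARGIN = 2


@dataclass
class PrecursorAnnotation:
    precursor: PrecursorCandidate
    defining: MappedRead
    placed_reads: list = field(default_factory=list)  # (CollapsedRead, (lo, hi))
    per_library_class: dict = field(default_factory=dict)
    global_class: int | None = None
    signature_pass: bool = False
    rescued: bool = False
    retained: bool = False
    context: str | None = None

    @property
    def mir_region(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """(mature side, star side), each widened by ±2 nt."""
        n = self.precursor.length
        a, b = self.precursor.mir_span
        c, d = self.precursor.star_span
        m = MIR_REGION_MARGIN
        return (
            (max(0, a - m), min(n, b + m)),
            (max(0, c - m), min(n, d + m)),
        )

    @property
    def loop_region(self) -> tuple[int, int]:
        """Interval between the duplex arms (may be empty)."""
        spans = sorted([self.precursor.mir_span, self.precursor.star_span])
        return (spans[0][1], spans[1][0])


@dataclass
class MirnaCandidate:
    mature: str
    defining: MappedRead
    precursors: list = field(default_factory=list)  # PrecursorAnnotation
    n_loci: int = 0
    status: str = "candidate"

    @property
    def fraction_loci_with_hairpin(self) -> float:
        return len(self.precursors) / self.n_loci if self.n_loci else 0.0


# ---------------------------------------------------------------------------
# greedy defining-smRNA selection


def _locus_inside(locus: GenomeLocus, extent: GenomeLocus) -> bool:
    return (
        locus.seq_id == extent.seq_id
        and locus.start >= extent.start
        and locus.end <= extent.end
    )


def select_defining_smrnas(
    mapped: list[MappedRead],
    genome,
    pad: int = 400,
    margin: int = 15,
    thresholds=None,
    backend: str = "bundled",
) -> list[MirnaCandidate]:
    """Greedy assignment of defining smRNAs to hairpin precursors.

    ``mapped`` must already carry abundance-gate flags; only gated reads
    (or known matures) can define a precursor.  Returns one candidate per
    defining mature, holding every accepted precursor locus.
    """
    placeable = [
        m for m in mapped if PLACED_MIN <= m.read.length <= PLACED_MAX
    ]
    registered_extents: list[GenomeLocus] = []
    candidates: list[MirnaCandidate] = []

    for length in DEFINING_LENGTH_ORDER:
        queue = sorted(
            (m for m in mapped if m.read.length == length and m.passed_abundance_filter),
            key=lambda m: (-m.read.total_count, m.sequence),
        )
        for cand_read in queue:
            if any(
                _locus_inside(loc, ext)
                for loc in cand_read.loci
                for ext in registered_extents
            ):
                continue  # produced by an already-registered precursor
            annotations = []
            for locus in cand_read.loci:
                precursor, _reasons = discover_hairpin(
                    cand_read.read, locus, genome, pad=pad, margin=margin,
                    thresholds=thresholds, backend=backend,
                )
                if precursor is None:
                    continue
                ann = annotate_precursor(precursor, cand_read, placeable)
                annotations.append(ann)
                registered_extents.append(precursor.locus)
            if annotations:
                candidates.append(
                    MirnaCandidate(
                        mature=_reported_mature(annotations[0], cand_read),
                        defining=cand_read,
                        precursors=annotations,
                        n_loci=cand_read.n_loci,
                    )
                )
    return candidates


def _reported_mature(annotation: PrecursorAnnotation, defining: MappedRead) -> str:
    """The annotated mature is the most abundant 20-22-nt read lying in
    either duplex arm: when the defining read is the passenger strand
    (e.g. a 21-nt miR* seen before a 22-nt miR in the greedy order), the
    expressed guide strand is still the one reported."""
    mir_side, star_side = annotation.mir_region
    best = None
    for read, span in annotation.placed_reads:
        if not 20 <= read.length <= 22:
            continue
        if _span_inside(span, mir_side) or _span_inside(span, star_side):
            key = (-read.total_count, read.sequence)
            if best is None or key < best[0]:
                best = (key, read.sequence)
    return best[1] if best is not None else defining.sequence


def annotate_precursor(
    precursor: PrecursorCandidate,
    defining: MappedRead,
    mapped: list[MappedRead],
) -> PrecursorAnnotation:
    """Place every 20-24-nt read whose genomic match lies fully inside the
    precursor extent (same strand), with local offsets on the hairpin."""
    ext = precursor.locus
    placed = []
    for m in mapped:
        for locus in m.loci:
            if locus.strand != ext.strand or not _locus_inside(locus, ext):
                continue
            if ext.strand == "+":
                span = (locus.start - ext.start, locus.end - ext.start)
            else:
                span = (ext.end - locus.end, ext.end - locus.start)
            placed.append((m.read, span))
    placed.sort(key=lambda t: (t[1], t[0].sequence))
    return PrecursorAnnotation(precursor=precursor, defining=defining, placed_reads=placed)


# ---------------------------------------------------------------------------
# the 5-class scheme


def _span_inside(span, region) -> bool:
    return span[0] >= region[0] and span[1] <= region[1]


def _span_overlaps(span, region) -> bool:
    return span[0] < region[1] and region[0] < span[1]


def classify_library(
    annotation: PrecursorAnnotation,
    library: str,
    outside_statistic: str = "mean",
):
    """Class 1-5 in one library, or ``"unclassified"``.

    Requires the defining read to have passed the library's top-5% gate.
    M is the summed count of reads fully inside the miR:miR* region, S
    the count overlapping the star side, O the reads outside; class 2/4
    compare the mean (default; ``outside_statistic="sum"`` uses the sum
    contract) per-distinct-read outside count against M/10.
    """
    if library not in annotation.defining.passed_libraries:
        return "unclassified"
    mir_side, star_side = annotation.mir_region
    M = 0
    S = 0
    outside_counts = []
    for read, span in annotation.placed_reads:
        c = read.count_in(library)
        if c <= 0:
            continue
        if _span_inside(span, mir_side) or _span_inside(span, star_side):
            M += c
        else:
            outside_counts.append(c)
        if _span_overlaps(span, star_side):
            S += c
    if M == 0:
        return "unclassified"
    if not outside_counts:
        return 1 if S > 0 else 3
    sum_o = sum(outside_counts)
    if sum_o > M:
        return 5
    stat = (
        sum_o / len(outside_counts)
        if outside_statistic == "mean"
        else sum_o
    )
    if stat <= M / 10:
        return 2 if S > 0 else 4
    return "unclassified"


def classify_global(annotation: PrecursorAnnotation, libraries) -> int | None:
    """Best (smallest) class over classified libraries; None if none."""
    per_lib = {
        lib: classify_library(annotation, lib) for lib in sorted(libraries)
    }
    annotation.per_library_class = per_lib
    classes = [c for c in per_lib.values() if isinstance(c, int)]
    annotation.global_class = min(classes) if classes else None
    return annotation.global_class


# ---------------------------------------------------------------------------
# retention gates


def signature_gate(
    annotation: PrecursorAnnotation,
    consistency_threshold: float = 0.75,
    tolerance: int = 3,
    min_mir_paired: float = 0.60,
) -> bool:
    """Dicer-consistency of the read signature.

    Passes iff the fraction of placed-read counts whose spans align
    (within ±tolerance nt) with the miR span, the star span, or fall
    fully inside the terminal loop is at least the threshold, and at
    least ``min_mir_paired`` of miR bases are paired in the fold.
    """
    mir = annotation.precursor.mir_span
    star = annotation.precursor.star_span
    loop = annotation.loop_region
    total = 0
    consistent = 0
    for read, span in annotation.placed_reads:
        c = read.total_count
        total += c
        near_mir = abs(span[0] - mir[0]) <= tolerance and abs(span[1] - mir[1]) <= tolerance
        near_star = abs(span[0] - star[0]) <= tolerance and abs(span[1] - star[1]) <= tolerance
        in_loop = span[0] >= loop[0] and span[1] <= loop[1]
        if near_mir or near_star or in_loop:
            consistent += c
    frac = consistent / total if total else 0.0

    pairs = annotation.precursor.fold.pair_table
    a, b = mir
    paired = sum(1 for i in range(a, b) if pairs[i] >= 0)
    ok = frac >= consistency_threshold and paired / (b - a) >= min_mir_paired
    annotation.signature_pass = ok
    return ok


def rescue_by_mature(
    candidates: list[MirnaCandidate], max_mismatch: int = 3
) -> None:
    """Retain class-3/4/5 precursors whose defining mature lies within
    ``max_mismatch`` mismatches (no gaps) of a bona fide class-1/2
    mature; sets per-precursor ``rescued``/``retained`` flags."""
    bona_fide = {
        c.mature
        for c in candidates
        for ann in c.precursors
        if ann.global_class in (1, 2)
    }
    for cand in candidates:
        for ann in cand.precursors:
            if ann.global_class in (1, 2):
                ann.retained = True
                continue
            if ann.global_class is None:
                ann.retained = False
                continue
            ann.rescued = any(
                mismatch_distance(cand.mature, bf) <= max_mismatch
                for bf in bona_fide
            )
            ann.retained = ann.rescued and ann.signature_pass


def novel_filters(
    candidate: MirnaCandidate,
    known_matures: dict[str, str] | set[str],
    min_hairpin_fraction: float = 0.20,
    known_max_mismatch: int = 3,
) -> str:
    """Final status of a mature candidate against the known catalogue and
    the stem-loop-loci / signature filters for novel candidates."""
    known = (
        set(known_matures.values())
        if isinstance(known_matures, dict)
        else set(known_matures)
    )
    known = {k.upper().replace("U", "T") for k in known}
    if candidate.mature in known:
        candidate.status = "known_exact"
        return candidate.status
    if any(
        mismatch_distance(candidate.mature, k) <= known_max_mismatch for k in known
    ):
        candidate.status = "known_variant"
        return candidate.status
    has_signature = any(ann.signature_pass for ann in candidate.precursors)
    if (
        candidate.fraction_loci_with_hairpin >= min_hairpin_fraction
        and has_signature
    ):
        candidate.status = "novel_accepted"
    else:
        candidate.status = "rejected"
    return candidate.status


# ---------------------------------------------------------------------------
# genomic context


_SENSE_PRECEDENCE = ("CDS", "five_prime_UTR", "three_prime_UTR")


def genomic_context(locus: GenomeLocus, features: list[FeatureRecord]) -> str:
    """Label a precursor locus by overlap with the gene annotation.

    Same-strand precedence CDS > UTR > intron (inside a gene span with no
    exon overlap) > antisense (opposite-strand CDS/exon overlap) >
    intergenic; one shared base pair counts as overlap.
    """
    same = [
        f for f in features
        if f.strand == locus.strand and f.overlaps(locus.seq_id, locus.start, locus.end)
    ]
    opposite = [
        f for f in features
        if f.strand != locus.strand and f.overlaps(locus.seq_id, locus.start, locus.end)
    ]
    types_same = {f.feature_type for f in same}
    if "CDS" in types_same:
        return "cds"
    if "five_prime_UTR" in types_same or "three_prime_UTR" in types_same:
        return "utr"
    if "gene" in types_same and "exon" not in types_same:
        return "intron"
    if any(f.feature_type in ("CDS", "exon") for f in opposite):
        return "antisense"
    return "intergenic"


# ---------------------------------------------------------------------------
# summary


def summarize_matures(candidates: list[MirnaCandidate]) -> dict:
    """Headline composition statistics over accepted candidates."""
    accepted = [
        c for c in candidates
        if c.status in ("known_exact", "known_variant", "novel_accepted")
    ]
    matures = [c.mature for c in accepted]
    precursors = [
        ann.precursor
        for c in accepted
        for ann in c.precursors
        if ann.retained
    ]
    n = len(matures)
    length_hist: dict[int, int] = {}
    for m in matures:
        length_hist[len(m)] = length_hist.get(len(m), 0) + 1
    plen = [p.length for p in precursors]
    return {
        "n_matures": n,
        "n_precursors": len(precursors),
        "frac_5prime_u": sum(m.startswith("T") for m in matures) / n if n else 0.0,
        "length_hist": dict(sorted(length_hist.items())),
        "frac_len_21": length_hist.get(21, 0) / n if n else 0.0,
        "precursor_len_min": min(plen) if plen else 0,
        "precursor_len_max": max(plen) if plen else 0,
        "frac_precursor_100_300": (
            sum(100 <= v <= 300 for v in plen) / len(plen) if plen else 0.0
        ),
    }
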