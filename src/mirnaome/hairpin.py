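"""Stem-loop excision and pre-miRNA acceptance criteria.

A candidate read's genomic context (400 bp each side) is excised,
folded once, and the miR:miR* duplex implied by the MFE structure is
scored column-wise.  A hairpin is accepted as a putative plant
pre-miRNA iff

* folding energy < -30 kcal/mol (strict),
* folding energy density (-MFE / length) > 0.15 kcal/mol/nt,
* the duplex shows < 4 consecutive mismatches, < 3 gaps and < 8
  mismatches+gaps in total,
* the mature does not span the terminal loop.

After acceptance the precursor is trimmed to the outermost base pair
enclosing the miR and miR* plus a symmetric margin, re-folded and
re-checked.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .fold import FoldResult, fold_mfe
from .io_formats import GenomeSequence, revcomp
from .mapping import GenomeLocus
from .reads import CollapsedRead

PAD_DEFAULT = 400


class LoopSpanningError(ValueError):
    """The mature read lies across the terminal loop, not within one arm."""


@dataclass(frozen=True)
class HairpinThresholds:
    """Plant pre-miRNA acceptance thresholds (all boundaries strict)."""

    max_mfe: float = -30.0          # accept iff mfe < max_mfe
    min_density: float = 0.15       # accept iff -mfe/len > min_density
    max_consecutive_mm: int = 3     # "less than four consecutive mismatches"
    max_gaps: int = 2               # "less than three gaps"
    max_total_mm_gap: int = 7       # "in total less than eight mismatches/gaps"


@dataclass(frozen=True)
class DuplexMetrics:
    n_mismatch: int
    n_gap: int
    max_consecutive_mismatch: int
    overhang3p: int = 2

    @property
    def total_mm_gap(self) -> int:
        return self.n_mismatch + self.n_gap


@dataclass(frozen=True)
class PrecursorCandidate:
    locus: GenomeLocus             # genomic extent of the precursor
    sequence: str                  # DNA, precursor (read) strand
    fold: FoldResult
    mir_span: tuple[int, int]      # local offsets within the precursor
    star_span: tuple[int, int]
    duplex: DuplexMetrics
    defining_read: CollapsedRead | None = None

    @property
    def mfe_density(self) -> float:
        return -self.fold.mfe / len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ContextFrame:
    """Maps local offsets of an excised, strand-oriented window back to
    genome coordinates."""

    seq_id: str
    window_start: int   # genomic start of the window (0-based)
    window_end: int
    strand: str

    def to_genomic(self, local_start: int, local_end: int) -> tuple[int, int]:
        if self.strand == "+":
            return self.window_start + local_start, self.window_start + local_end
        return self.window_end - local_end, self.window_end - local_start

    def to_local(self, gstart: int, gend: int) -> tuple[int, int]:
        if self.strand == "+":
            return gstart - self.window_start, gend - self.window_start
        return self.window_end - gend, self.window_end - gstart


def extract_context(
    locus: GenomeLocus, genome: dict[str, GenomeSequence], pad: int = PAD_DEFAULT
) -> tuple[str, ContextFrame]:
    """Excise the padded genomic window around a locus, oriented so the
    read lies on the forward strand of the returned sequence."""
    chrom = genome[locus.seq_id]
    w_start = max(0, locus.start - pad)
    w_end = min(len(chrom), locus.end + pad)
    seq = chrom.residues[w_start:w_end]
    if locus.strand == "-":
        seq = revcomp(seq)
    return seq, ContextFrame(locus.seq_id, w_start, w_end, locus.strand)


def locate_duplex(
    fold: FoldResult, mir_span: tuple[int, int]
) -> tuple[tuple[int, int], DuplexMetrics]:
    """miR* span and duplex metrics implied by the MFE structure.

    The star span is the pairing partner region of the mature shifted to
    leave 2-nt 3' overhangs on both strands.  Metrics are counted
    column-wise over the miR:miR* alignment: unpaired-opposite-unpaired
    columns are mismatches, asymmetric bulges are gaps (one event for
    bulges up to 2 nt, length-counted beyond).

    Raises :class:`LoopSpanningError` if the mature crosses the terminal
    loop or pairs with itself.
    """
    a, b = mir_span
    pairs = fold.pair_table
    n = len(fold.structure)
    if not (0 <= a < b <= n):
        raise ValueError("mir_span outside the folded sequence")

    # the mature's designed 2-nt 3' overhang does not pair within the duplex
    anchors = [(i, int(pairs[i])) for i in range(a, b - 2) if pairs[i] >= 0]
    if not anchors:
        raise LoopSpanningError("mature entirely unpaired")
    partners = [j for _, j in anchors]
    if any(a <= j < b for j in partners):
        raise LoopSpanningError("mature pairs with itself across the loop")
    left = [j for j in partners if j < a]
    right = [j for j in partners if j >= b]
    if left and right:
        raise LoopSpanningError("mature spans the terminal loop")

    star_lo, star_hi = min(partners), max(partners) + 1
    star_span = (star_lo, min(star_hi + 2, n))  # 2-nt 3' overhang on the star
    overhang = star_span[1] - star_hi

    # column walk: anchors ordered 5'->3' on the mature pair with strictly
    # decreasing partners (nested structure)
    n_mismatch = 0
    n_gap = 0
    max_run = 0

    def add_mismatch_run(k: int):
        nonlocal n_mismatch, max_run
        n_mismatch += k
        max_run = max(max_run, k)

    add_mismatch_run(anchors[0][0] - a)           # leading unpaired mature bases
    for (i1, j1), (i2, j2) in zip(anchors, anchors[1:]):
        u_m = i2 - i1 - 1
        u_s = j1 - j2 - 1
        add_mismatch_run(min(u_m, u_s))
        d = abs(u_m - u_s)
        if d:
            n_gap += 1 if d <= 2 else d
    add_mismatch_run((b - 2 - 1) - anchors[-1][0])  # trailing, overhang excluded

    metrics = DuplexMetrics(n_mismatch, n_gap, max_run, overhang)
    return star_span, metrics


def accept_precursor(
    candidate: PrecursorCandidate, thresholds: HairpinThresholds | None = None
) -> tuple[bool, list[str]]:
    """Pure acceptance predicate; returns decision and failed-criterion codes."""
    t = thresholds or HairpinThresholds()
    reasons = []
    if not candidate.fold.mfe < t.max_mfe:
        reasons.append("mfe")
    if not candidate.mfe_density > t.min_density:
        reasons.append("density")
    if candidate.duplex.max_consecutive_mismatch > t.max_consecutive_mm:
        reasons.append("consecutive_mismatches")
    if candidate.duplex.n_gap > t.max_gaps:
        reasons.append("gaps")
    if candidate.duplex.total_mm_gap > t.max_total_mm_gap:
        reasons.append("total_mm_gap")
    return (not reasons), reasons


def trim_precursor(
    candidate: PrecursorCandidate,
    frame: ContextFrame,
    margin: int = 15,
    thresholds: HairpinThresholds | None = None,
    backend: str = "bundled",
) -> PrecursorCandidate:
    """Tighten the precursor to the outermost base pair enclosing the
    miR and miR* spans plus a symmetric margin; re-fold and re-check.

    Raises ValueError("trim-destabilized") if the trimmed hairpin no
    longer satisfies the acceptance criteria or loses its duplex.
    """
    pairs = candidate.fold.pair_table
    lo = min(candidate.mir_span[0], candidate.star_span[0])
    hi = max(candidate.mir_span[1], candidate.star_span[1])
    outer = None
    # innermost pair enclosing both spans = the base of the hairpin stem;
    # scanning outward would instead catch spurious long-range pairs
    # formed by the genomic flanks of the excision window
    for i in range(lo, -1, -1):
        j = int(pairs[i])
        if j >= hi - 1 and j > i:
            outer = (i, j)
            break
    if outer is None:
        # no single pair encloses both spans; fall back to the spans themselves
        outer = (lo, hi - 1)
    start = max(0, outer[0] - margin)
    end = min(len(candidate.sequence), outer[1] + 1 + margin)
    if (start, end) == (0, len(candidate.sequence)):
        return candidate  # already trimmed

    sub_seq = candidate.sequence[start:end]
    sub_fold = fold_mfe(sub_seq, backend=backend)
    mir_span = (candidate.mir_span[0] - start, candidate.mir_span[1] - start)
    try:
        star_span, metrics = locate_duplex(sub_fold, mir_span)
    except LoopSpanningError as exc:
        raise ValueError("trim-destabilized") from exc
    loc_start, loc_end = frame.to_local(candidate.locus.start, candidate.locus.end)
    new_gstart, new_gend = frame.to_genomic(loc_start + start, loc_start + end)
    trimmed = PrecursorCandidate(
        locus=GenomeLocus(frame.seq_id, new_gstart, new_gend, frame.strand),
        sequence=sub_seq,
        fold=sub_fold,
        mir_span=mir_span,
        star_span=star_span,
        duplex=metrics,
        defining_read=candidate.defining_read,
    )
    ok, _reasons = accept_precursor(trimmed, thresholds)
    if not ok:
        raise ValueError("trim-destabilized")
    return trimmed


def discover_hairpin(
    read: CollapsedRead,
    locus: GenomeLocus,
    genome: dict[str, GenomeSequence],
    pad: int = PAD_DEFAULT,
    margin: int = 15,
    thresholds: HairpinThresholds | None = None,
    backend: str = "bundled",
) -> tuple[PrecursorCandidate | None, list[str]]:
    """Full excise-fold-locate-accept-trim cascade for one read locus.

    Returns the trimmed accepted candidate, or ``(None, reasons)`` with
    the failed-criterion codes.
    """
    window, frame = extract_context(locus, genome, pad)
    fold = fold_mfe(window, backend=backend)
    mir_span = frame.to_local(locus.start, locus.end)
    try:
        star_span, metrics = locate_duplex(fold, mir_span)
    except LoopSpanningError:
        return None, ["loop_spanning"]
    candidate = PrecursorCandidate(
        locus=GenomeLocus(frame.seq_id, frame.window_start, frame.window_end, locus.strand),
        sequence=window,
        fold=fold,
        mir_span=mir_span,
        star_span=star_span,
        duplex=metrics,
        defining_read=read,
    )
    ok, reasons = accept_precursor(candidate, thresholds)
    if not ok:
        return None, reasons
    try:
        trimmed = trim_precursor(candidate, frame, margin, thresholds, backend)
    except ValueError:
        return None, ["trim_destabilized"]
    return trimmed, []
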