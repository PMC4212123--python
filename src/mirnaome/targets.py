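"""Plant-adapted miRNA target alignment, filtering and degradome support.

The aligner is a local (Smith-Waterman) affine-gap alignment of the
reverse-complemented miRNA against each transcript: Watson-Crick columns
score +5, G:U wobbles +2, mismatches -3, gap open -9, gap extend -4, and
any column pairing miRNA positions 2-8 (the seed) has its substitution
score doubled.  A perfectly complementary 21-mer therefore scores
14*5 + 7*10 = 140, which is exactly the acceptance score floor; the
biological penalty score (1 per mismatch, 2 per gap opening, 0.5 per
G:U) is counted over the reported columns and must stay at or below 2.

Degradome validation builds the 5'-end tag-count profile of each
transcript and inspects the base opposite miRNA position 10; the site
p-value is the fraction of transcript positions carrying at least the
observed cleavage count (an empirical positional null).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fold import duplex_energy
from .io_formats import revcomp

# substitution scores
WC_SCORE = 5.0
GU_SCORE = 2.0
MISMATCH_SCORE = -3.0
GAP_OPEN = -9.0
GAP_EXTEND = -4.0
SEED_START, SEED_END = 2, 8        # miRNA positions weighted x2 (1-based, incl.)

# biological penalty terms and acceptance thresholds
PENALTY_MISMATCH = 1.0
PENALTY_GAP = 2.0
PENALTY_GU = 0.5
MAX_PENALTY = 2.0
MIN_ALIGN_LENGTH = 18
MIN_SCORE = 140.0
MAX_ENERGY = -20.0

_GU_RC = {("C", "T"), ("A", "G")}  # (revcomp-miRNA base, target base) G:U wobbles
_GU_PARTNER = {"C": "T", "A": "G"}  # same map, keyed for the vectorized fill


@dataclass
class TargetAlignment:
    mirna: str
    transcript_id: str
    site: tuple[int, int]          # transcript interval, 0-based half-open
    columns: list = field(default_factory=list)
    # each column: (kind, mirna_base | "-", target_base | "-", mirna_position | 0)
    # kind in {"WC", "GU", "mismatch", "gap"}; mirna_position 1-based from 5'
    alignment_score: float = 0.0
    duplex_energy: float = 0.0

    @property
    def alignment_length(self) -> int:
        return len(self.columns)

    @property
    def penalty_score(self) -> float:
        n_mm = sum(1 for k, *_ in self.columns if k == "mismatch")
        n_gu = sum(1 for k, *_ in self.columns if k == "GU")
        n_gap = 0
        prev_gap = False
        for k, *_ in self.columns:
            if k == "gap":
                if not prev_gap:
                    n_gap += 1
                prev_gap = True
            else:
                prev_gap = False
        return PENALTY_MISMATCH * n_mm + PENALTY_GAP * n_gap + PENALTY_GU * n_gu


def _column_kind(rc_base: str, t_base: str) -> str:
    if rc_base == t_base:
        return "WC"
    if (rc_base, t_base) in _GU_RC:
        return "GU"
    return "mismatch"


def _substitution(rc_base: str, t_base: str, mir_pos: int) -> float:
    kind = _column_kind(rc_base, t_base)
    s = {"WC": WC_SCORE, "GU": GU_SCORE, "mismatch": MISMATCH_SCORE}[kind]
    if SEED_START <= mir_pos <= SEED_END:
        s *= 2.0
    return s


def _smith_waterman(rc: str, mir_positions: list[int], transcript: str):
    """One best local alignment of the reverse-complemented miRNA against
    the transcript; returns (score, columns, t_start, t_end) or None.

    The fill is vectorized per miRNA row; within a row the
    transcript-gap state Iy is a running maximum solved with a
    cumulative-maximum identity instead of a scalar scan.
    """
    m, n = len(rc), len(transcript)
    if n == 0:
        return None
    NEG = -1e9
    t_arr = np.frombuffer(transcript.encode(), dtype=np.uint8)
    M = np.zeros((m + 1, n + 1))
    Ix = np.full((m + 1, n + 1), NEG)   # gap in transcript (miRNA base unpaired)
    Iy = np.full((m + 1, n + 1), NEG)   # gap in miRNA (transcript base unpaired)
    js = np.arange(n + 1, dtype=float)
    for i in range(1, m + 1):
        rb = rc[i - 1]
        weight = 2.0 if SEED_START <= mir_positions[i - 1] <= SEED_END else 1.0
        sub = np.where(
            t_arr == ord(rb),
            WC_SCORE,
            np.where(t_arr == ord(_GU_PARTNER.get(rb, "?")), GU_SCORE, MISMATCH_SCORE),
        ) * weight
        diag = np.maximum(np.maximum(M[i - 1, :-1], Ix[i - 1, :-1]), Iy[i - 1, :-1])
        M[i, 1:] = np.maximum(0.0, diag + sub)
        Ix[i, 1:] = np.maximum(M[i - 1, 1:] + GAP_OPEN, Ix[i - 1, 1:] + GAP_EXTEND)
        # Iy[i, j] = max_{k <= j-1} M[i, k] + GAP_OPEN + GAP_EXTEND*(j-1-k)
        a = M[i] + GAP_OPEN - GAP_EXTEND * js
        Iy[i, 1:] = np.maximum.accumulate(a[:-1]) + GAP_EXTEND * (js[1:] - 1)
    bi, bj = np.unravel_index(int(M.argmax()), M.shape)
    score = float(M[bi, bj])
    if score <= 0:
        return None

    # traceback from the best M cell
    columns = []
    state = "M"
    i, j = bi, bj
    while i > 0 and j > 0:
        if state == "M":
            if M[i, j] == 0.0 and not columns:
                break
            sub = _substitution(rc[i - 1], transcript[j - 1], mir_positions[i - 1])
            kind = _column_kind(rc[i - 1], transcript[j - 1])
            columns.append((kind, rc[i - 1], transcript[j - 1], mir_positions[i - 1]))
            prev = M[i, j] - sub
            i, j = i - 1, j - 1
            if abs(prev) < 1e-9 and M[i, j] == 0.0:
                break
            for cand, mat in (("M", M), ("Ix", Ix), ("Iy", Iy)):
                if abs(mat[i, j] - prev) < 1e-9:
                    state = cand
                    break
        elif state == "Ix":
            columns.append(("gap", rc[i - 1], "-", mir_positions[i - 1]))
            if abs(Ix[i, j] - (M[i - 1, j] + GAP_OPEN)) < 1e-9:
                state = "M"
            i -= 1
        else:  # Iy
            columns.append(("gap", "-", transcript[j - 1], 0))
            if abs(Iy[i, j] - (M[i, j - 1] + GAP_OPEN)) < 1e-9:
                state = "M"
            j -= 1
    columns.reverse()
    t_start = j if columns else bj
    return score, columns, t_start, bj


def align_mirna_target(
    mirna: str,
    transcript: str,
    transcript_id: str = "",
    min_score: float = MIN_SCORE,
) -> list[TargetAlignment]:
    """All non-overlapping local alignment sites scoring at least
    ``min_score``, best first.  The miRNA is reverse-complemented and slid
    over the transcript; column kinds and the biological penalty are
    recorded per site, and the duplex hybridization energy is computed
    over the reported columns."""
    if not mirna or not transcript:
        raise ValueError("sequences must be nonempty")
    mirna = mirna.upper().replace("U", "T")
    transcript = transcript.upper().replace("U", "T")
    rc = revcomp(mirna)
    L = len(mirna)
    # rc column i (0-based) pairs miRNA position L - i (1-based from miRNA 5')
    mir_positions = [L - i for i in range(L)]

    sites: list[TargetAlignment] = []
    # non-overlap via segment splitting: each reported site removes its
    # transcript interval from further consideration
    segments = [(0, len(transcript))]
    while segments:
        seg_lo, seg_hi = segments.pop(0)
        hit = _smith_waterman(rc, mir_positions, transcript[seg_lo:seg_hi])
        if hit is None:
            continue
        score, columns, t_start, t_end = hit
        t_start, t_end = int(t_start) + seg_lo, int(t_end) + seg_lo
        if score < min_score:
            continue
        # energy columns run 5'->3' along the miRNA strand, with the
        # original miRNA base (not its reverse complement) on strand one
        energy_cols = [
            ("-" if mb == "-" else revcomp(mb), tb)
            for _k, mb, tb, _p in reversed(columns)
        ]
        ali = TargetAlignment(
            mirna=mirna,
            transcript_id=transcript_id,
            site=(t_start, t_end),
            columns=columns,
            alignment_score=float(score),
            duplex_energy=duplex_energy(energy_cols),
        )
        sites.append(ali)
        if t_start - seg_lo > 0:
            segments.append((seg_lo, t_start))
        if seg_hi - t_end > 0:
            segments.append((t_end, seg_hi))
    sites.sort(key=lambda a: (-a.alignment_score, a.site))
    return sites


def filter_targets(
    alignments: list[TargetAlignment],
    max_penalty: float = MAX_PENALTY,
    min_length: int = MIN_ALIGN_LENGTH,
    min_score: float = MIN_SCORE,
    max_energy: float = MAX_ENERGY,
) -> list[TargetAlignment]:
    """Plant-target acceptance: penalty ≤ 2, ≥ 18 aligned columns,
    score ≥ 140 and duplex energy ≤ -20 kcal/mol."""
    return [
        a
        for a in alignments
        if a.penalty_score <= max_penalty
        and a.alignment_length >= min_length
        and a.alignment_score >= min_score
        and a.duplex_energy <= max_energy
    ]


# ---------------------------------------------------------------------------
# degradome


@dataclass
class DegradomeSupport:
    transcript_id: str
    cleavage_position: int
    tag_count_at_cleavage: int
    category: int
    p_value: float
    has_data: bool = True

    @property
    def validated(self) -> bool:
        return self.has_data and self.p_value <= 0.05


def map_degradome_tags(
    tags: list[str], transcripts: dict[str, str], tag_len: int = 20
) -> dict[str, np.ndarray]:
    """Per-transcript 5'-end tag-count profiles from perfect-match tag
    placement (first ``tag_len`` bases of each tag)."""
    profiles = {tid: np.zeros(len(seq), dtype=np.int64) for tid, seq in transcripts.items()}
    index: dict[str, list[tuple[str, int]]] = {}
    for tid, seq in transcripts.items():
        for i in range(len(seq) - tag_len + 1):
            index.setdefault(seq[i : i + tag_len], []).append((tid, i))
    for tag in tags:
        key = tag[:tag_len].upper().replace("U", "T")
        for tid, pos in index.get(key, ()):
            profiles[tid][pos] += 1
    return profiles


def degradome_validate(
    site: TargetAlignment,
    profiles: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> DegradomeSupport:
    """CleaveLand-style category and empirical positional p-value for a
    predicted site.  The cleavage position is the transcript base paired
    with miRNA position 10 (cleavage between positions 10 and 11)."""
    cleavage = site.site[0] + (len(site.mirna) - 10)
    if site.transcript_id not in profiles:
        return DegradomeSupport(site.transcript_id, cleavage, 0, 4, 1.0, has_data=False)
    profile = profiles[site.transcript_id]
    if not (0 <= cleavage < len(profile)):
        return DegradomeSupport(site.transcript_id, cleavage, 0, 4, 1.0, has_data=False)
    c = int(profile[cleavage])
    maximum = int(profile.max()) if len(profile) else 0
    median = float(np.median(profile))
    if c <= 1:
        category = 4
    elif c == maximum:
        category = 0 if int((profile == maximum).sum()) == 1 else 1
    elif c > median:
        category = 2
    else:
        category = 3
    p = float((profile >= c).sum() / len(profile)) if c > 0 else 1.0
    return DegradomeSupport(site.transcript_id, cleavage, c, category, p)


def anticorrelation_screen(
    mirna_abundance: dict[str, dict[str, float]],
    target_abundance: dict[str, dict[str, float]],
    pairs: list[tuple[str, str]],
    contrasts: list[tuple[str, str]],
    fold: float = 1.5,
) -> list[dict]:
    """Flag miRNA-target pairs with ≥ ``fold``-change in opposite
    directions between a condition and its control; contrasts whose
    control value is missing or zero are skipped."""
    flagged = []
    for mirna, target in pairs:
        for condition, control in contrasts:
            ma = mirna_abundance.get(mirna, {})
            ta = target_abundance.get(target, {})
            if control not in ma or control not in ta:
                continue
            if condition not in ma or condition not in ta:
                continue
            if ma[control] <= 0 or ta[control] <= 0:
                continue
            mf = ma[condition] / ma[control]
            tf = ta[condition] / ta[control]
            up_down = mf >= fold and tf <= 1.0 / fold
            down_up = mf <= 1.0 / fold and tf >= fold
            if up_down or down_up:
                flagged.append(
                    {
                        "mirna": mirna,
                        "target": target,
                        "condition": condition,
                        "control": control,
                        "mirna_fold": mf,
                        "target_fold": tf,
                    }
                )
    return flagged
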