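"""Raw sRNA read cleaning and collapsing to distinct sequences.

Adaptor trimming keeps the insert preceding the leftmost exact match of
the adaptor's first ``seed_len`` bases (no trimmer tool names a mismatch
tolerance for this protocol, so the seed match is exact and its length
configurable).  Surviving 18-25-nt, N-free, non-structural reads are
collapsed to distinct sequences with per-library counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import revcomp

MIN_LEN = 18
MAX_LEN = 25


@dataclass(frozen=True)
class CollapsedRead:
    """A distinct 18-25-nt sequence with per-library read counts."""

    sequence: str
    counts: dict = field(hash=False)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    @property
    def length(self) -> int:
        return len(self.sequence)

    def count_in(self, library: str) -> int:
        return self.counts.get(library, 0)


def trim_adaptor(read: str, adaptor: str, seed_len: int = 8) -> str | None:
    """Insert preceding the leftmost adaptor-seed match, or None."""
    if not adaptor:
        raise ValueError("adaptor must be nonempty")
    seed = adaptor[:seed_len]
    idx = read.find(seed)
    if idx < 0:
        return None  # insert longer than the read; unusable
    return read[:idx]


def filter_and_collapse(
    reads_by_library: dict[str, list[str]],
    structural_sequences: list[str] | None = None,
) -> list[CollapsedRead]:
    """Length/N/structural-RNA filtering followed by redundancy collapsing.

    ``structural_sequences`` are annotated rRNA/tRNA locus sequences (or a
    user blacklist); a read matching any of them as a perfect substring on
    either strand is dropped.  Output is sorted by descending total count,
    ties broken lexicographically — downstream greedy selection depends on
    this order.
    """
    structural = structural_sequences or []
    structural_both = [s.upper() for s in structural]
    structural_both += [revcomp(s) for s in structural_both]

    counts: dict[str, dict[str, int]] = {}
    for library, reads in reads_by_library.items():
        for seq in reads:
            if not (MIN_LEN <= len(seq) <= MAX_LEN) or "N" in seq:
                continue
            per_lib = counts.setdefault(seq, {})
            per_lib[library] = per_lib.get(library, 0) + 1

    collapsed = []
    for seq, per_lib in counts.items():
        if any(seq in s for s in structural_both):
            continue
        collapsed.append(CollapsedRead(seq, dict(sorted(per_lib.items()))))
    collapsed.sort(key=lambda r: (-r.total_count, r.sequence))
    return collapsed
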