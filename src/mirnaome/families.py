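"""Greedy family clustering of matures and cross-species conservation.

Families follow greedy-centroid (CD-HIT-like) semantics: matures are
processed by descending total count and join the first family whose
*representative* is within 3 mismatches under the best ungapped offset
alignment and at least 84.2% identical over the shorter sequence.
Membership is representative-linked, not a transitive closure, so two
members of one family may be more than 3 mismatches apart.

Conservation is an exhaustive Hamming-distance scan (≤3 mismatches,
every offset, both strands) against a panel of related genomes:
*widespread* if the mature hits any outgroup genome, *clade_specific*
if it hits only genomes of the focal clade, *species_specific*
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import revcomp

FAMILY_MAX_MISMATCH = 3
FAMILY_MIN_IDENTITY = 0.842


def offset_alignments(a: str, b: str):
    """Yield (offset, n_match, n_mismatch, overlap) for every ungapped
    offset of ``a`` against ``b`` with at least one overlapping column."""
    for off in range(-(len(a) - 1), len(b)):
        match = mismatch = 0
        for i, ca in enumerate(a):
            j = i + off
            if 0 <= j < len(b):
                if ca == b[j]:
                    match += 1
                else:
                    mismatch += 1
        if match + mismatch:
            yield off, match, mismatch, match + mismatch


def family_compatible(
    representative: str,
    member: str,
    max_mismatch: int = FAMILY_MAX_MISMATCH,
    min_identity: float = FAMILY_MIN_IDENTITY,
) -> bool:
    """True iff some ungapped offset satisfies both the mismatch and the
    identity constraint (identity over the shorter sequence)."""
    shorter = min(len(representative), len(member))
    for _off, match, mismatch, _ov in offset_alignments(representative, member):
        if mismatch <= max_mismatch and match / shorter >= min_identity:
            return True
    return False


def mismatch_distance(a: str, b: str) -> int:
    """Mismatches at the best ungapped offset; bases of the shorter
    sequence left unaligned count as mismatches."""
    shorter = min(len(a), len(b))
    best = shorter
    for _off, match, mismatch, overlap in offset_alignments(a, b):
        best = min(best, mismatch + (shorter - overlap))
    return best


@dataclass
class MirnaFamily:
    family_id: str
    representative: str
    members: list = field(default_factory=list)
    n_genes: int = 0


def cluster_families(
    matures: list[tuple[str, int]],
    loci_per_mature: dict[str, int] | None = None,
    max_mismatch: int = FAMILY_MAX_MISMATCH,
    min_identity: float = FAMILY_MIN_IDENTITY,
) -> list[MirnaFamily]:
    """Greedy centroid clustering of (mature, total_count) pairs.

    Matures must be distinct; processing order is descending count with
    lexicographic tie-break, and a mature joins the first compatible
    family in foundation order.
    """
    seqs = [m for m, _ in matures]
    if len(set(seqs)) != len(seqs):
        raise ValueError("matures must be deduplicated")
    loci = loci_per_mature or {}
    ordered = sorted(matures, key=lambda t: (-t[1], t[0]))
    families: list[MirnaFamily] = []
    for seq, _count in ordered:
        for fam in families:
            if family_compatible(fam.representative, seq, max_mismatch, min_identity):
                fam.members.append(seq)
                fam.n_genes += loci.get(seq, 1)
                break
        else:
            families.append(
                MirnaFamily(
                    family_id=f"fam{len(families) + 1:03d}",
                    representative=seq,
                    members=[seq],
                    n_genes=loci.get(seq, 1),
                )
            )
    return families


# ---------------------------------------------------------------------------
# conservation


@dataclass
class ConservationCall:
    mature: str
    hits_per_genome: dict
    category: str


_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(
        seq.encode().translate(bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))),
        dtype=np.uint8,
    )


def count_hamming_hits(mature: str, genome_seq: str, max_mismatch: int = 3) -> int:
    """Number of genomic windows (both strands) within Hamming distance
    ``max_mismatch`` of the mature; exhaustive over all offsets."""
    L = len(mature)
    total = 0
    for query in (mature, revcomp(mature)):
        g = _encode(genome_seq)
        q = _encode(query)
        n = len(g) - L + 1
        if n <= 0:
            continue
        mism = np.zeros(n, dtype=np.int32)
        for k in range(L):
            mism += (g[k : k + n] != q[k]) | (g[k : k + n] == 4)
        total += int(np.count_nonzero(mism <= max_mismatch))
    return total


def conservation_category(
    mature: str,
    clade_genomes: dict[str, str],
    outgroup_genomes: dict[str, str],
    max_mismatch: int = 3,
) -> ConservationCall:
    """Classify a mature by its presence in related genomes.

    The focal genome is not part of either panel; a hit is any window at
    Hamming distance ≤ ``max_mismatch`` on either strand.
    """
    hits = {}
    for gid in sorted(clade_genomes):
        hits[gid] = count_hamming_hits(mature, clade_genomes[gid], max_mismatch)
    for gid in sorted(outgroup_genomes):
        hits[gid] = count_hamming_hits(mature, outgroup_genomes[gid], max_mismatch)
    if any(hits[gid] > 0 for gid in outgroup_genomes):
        category = "widespread"
    elif any(hits[gid] > 0 for gid in clade_genomes):
        category = "clade_specific"
    else:
        category = "species_specific"
    return ConservationCall(mature=mature, hits_per_genome=hits, category=category)
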