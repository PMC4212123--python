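"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions: everything in memory is 0-based half-open;
1-based inclusive coordinates exist only in on-disk GFF3/VCF, converted
at the I/O boundary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    pass


def revcomp(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One reference sequence (chromosome/scaffold), uppercase DNA."""

    seq_id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"{self.seq_id}: empty sequence")
        if set(self.residues) - set("ACGTN"):
            bad = sorted(set(self.residues) - set("ACGTN"))
            raise ValueError(f"{self.seq_id}: non-DNA characters {bad}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class FeatureRecord:
    """One GFF3 feature, coordinates 0-based half-open."""

    seq_id: str
    source: str
    feature_type: str
    start: int
    end: int
    strand: str
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.start > self.end:
            raise ParseError(
                f"feature {self.attributes.get('ID', '?')}: start > end"
            )
        if self.strand not in "+-":
            raise ParseError(f"bad strand {self.strand!r}")

    def overlaps(self, seq_id: str, start: int, end: int) -> bool:
        return self.seq_id == seq_id and self.start < end and start < self.end


@dataclass(frozen=True)
class VariantRecord:
    """One variant call, genome position 0-based."""

    seq_id: str
    pos: int
    ref_allele: str
    alt_allele: str
    accession_presence: frozenset
    variant_class: str  # snp | indel_le_2bp | other

    @staticmethod
    def classify(ref: str, alt: str) -> str:
        if len(ref) == 1 and len(alt) == 1:
            return "snp"
        if abs(len(ref) - len(alt)) in (1, 2):
            return "indel_le_2bp"
        return "other"


# ---------------------------------------------------------------------------
# sequences


def read_sequences(path, fmt: str = "fasta", alphabet: str = "dna"):
    """Read FASTA/FASTQ into ``[(id, sequence)]`` or ``[(id, seq, quals)]``.

    Sequences are uppercased; for ``alphabet="dna"`` U is converted to T,
    for ``alphabet="rna"`` T is converted to U.
    """
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}")
    out = []
    try:
        for rec in SeqIO.parse(str(path), fmt):
            seq = str(rec.seq).upper()
            if alphabet == "dna":
                seq = seq.replace("U", "T")
            else:
                seq = seq.replace("T", "U")
            if fmt == "fastq":
                out.append((rec.id, seq, rec.letter_annotations["phred_quality"]))
            else:
                out.append((rec.id, seq))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return out


def read_genome(path) -> dict[str, GenomeSequence]:
    return {
        seq_id: GenomeSequence(seq_id, seq)
        for seq_id, seq in read_sequences(path, "fasta")
    }


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# annotation

_GFF_CORE = {
    "Chromosome", "Source", "Feature", "Start", "End", "Score", "Strand", "Frame",
}


def read_annotation(path) -> list[FeatureRecord]:
    """Parse GFF3 into FeatureRecords (0-based half-open, sorted)."""
    import pyranges

    df = pyranges.read_gff3(str(path)).df
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        attributes = {
            k: v
            for k, v in d.items()
            if k not in _GFF_CORE and isinstance(v, str) and v
        }
        strand = str(d["Strand"])
        records.append(
            FeatureRecord(
                seq_id=str(d["Chromosome"]),
                source=str(d["Source"]),
                feature_type=str(d["Feature"]),
                start=int(d["Start"]),
                end=int(d["End"]),
                strand=strand if strand in "+-" else "+",
                attributes=attributes,
            )
        )
    records.sort(key=lambda f: (f.seq_id, f.start, f.end, f.feature_type))
    return records


def write_gff3(features, path, source: str = "mirnaome") -> None:
    """Write features (0-based half-open) as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items())
            fh.write(
                f"{f.seq_id}\t{source}\t{f.feature_type}\t{f.start + 1}\t{f.end}"
                f"\t.\t{f.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# variants


def read_variants(path) -> list[VariantRecord]:
    """Read a VCF (subset) or tab-separated variant table.

    The TSV dialect has columns chrom, pos (1-based), ref, alt,
    accessions (comma-separated accession ids carrying the alt allele).
    Multi-allelic rows are split; rows with alt == ref are dropped with a
    warning.
    """
    path = Path(path)
    if path.suffix == ".vcf" or _looks_like_vcf(path):
        rows = _iter_vcf_rows(path)
    else:
        rows = _iter_tsv_rows(path)
    records, n_rejected = [], 0
    for chrom, pos1, ref, alts, accessions_per_alt in rows:
        for alt, accs in zip(alts, accessions_per_alt):
            if alt == ref:
                n_rejected += 1
                continue
            records.append(
                VariantRecord(
                    seq_id=chrom,
                    pos=pos1 - 1,
                    ref_allele=ref,
                    alt_allele=alt,
                    accession_presence=frozenset(accs),
                    variant_class=VariantRecord.classify(ref, alt),
                )
            )
    if n_rejected:
        log.warning("%s: rejected %d rows with alt == ref", path, n_rejected)
    return records


def _looks_like_vcf(path: Path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return first.startswith("##fileformat=VCF") or first.startswith("#CHROM")


def _iter_vcf_rows(path: Path):
    samples: list[str] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            if len(fields) < 5:
                raise ParseError(f"{path}:{line_no}: truncated VCF row")
            chrom, pos1, _id, ref, alt = fields[:5]
            alts = alt.split(",")
            accessions_per_alt: list[set] = [set() for _ in alts]
            for sample, gt_field in zip(samples, fields[9:]):
                gt = gt_field.split(":")[0]
                for allele in gt.replace("|", "/").split("/"):
                    if allele.isdigit() and int(allele) > 0:
                        accessions_per_alt[int(allele) - 1].add(sample)
            yield chrom, int(pos1), ref, alts, accessions_per_alt


def _iter_tsv_rows(path: Path):
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    for row in df.itertuples(index=False):
        d = row._asdict()
        accs = d.get(cols.get("accessions", ""), "")
        acc_set = set(str(accs).split(",")) - {"", "nan"} if pd.notna(accs) else set()
        alts = str(d[cols["alt"]]).split(",")
        yield (
            str(d[cols["chrom"]]),
            int(d[cols["pos"]]),
            str(d[cols["ref"]]),
            alts,
            [acc_set for _ in alts],
        )


# ---------------------------------------------------------------------------
# outputs


def write_table(df: pd.DataFrame, path) -> None:
    """Deterministic UTF-8 TSV with one header row."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(path, config: dict, seed: int, stage_counts: dict) -> None:
    manifest = {
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
        "stage_counts": stage_counts,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
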