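"""End-to-end orchestration: read cleaning through polymorphism profiling.

``run_all`` executes the discovery funnel in order — trim/collapse,
perfect-match mapping, multi-locus and top-5% abundance filters, hairpin
discovery with the greedy defining-smRNA algorithm, 5-class read
signature classification with the signature and rescue retention gates,
family clustering and conservation, target prediction with degradome
validation, and SNP profiling — writing one TSV per stage plus a funnel
table and a JSON manifest.  Identical config and seed give byte-identical
outputs; all randomness flows from the single pipeline seed.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import classify as cls
from . import families as fam
from . import polymorphism as poly
from . import targets as tgt
from .hairpin import HairpinThresholds
from .io_formats import write_manifest, write_table
from .mapping import abundance_gate, extract_locus, filter_multilocus, map_perfect
from .reads import MAX_LEN, MIN_LEN, filter_and_collapse, trim_adaptor
from .synthetic import SimulationConfig, simulate_all

log = logging.getLogger("mirnaome")


@dataclass
class PipelineConfig:
    """Every stage threshold with its literature default, plus the seed."""

    seed: int = 0
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    # read processing
    adaptor: str = "TGGAATTCTCGGGTGCCAAGG"
    adaptor_seed_len: int = 8

    # mapping and expression filters
    max_loci: int = 30
    top_quantile: float = 0.05

    # hairpin discovery
    hairpin: HairpinThresholds = field(default_factory=HairpinThresholds)
    context_pad: int = 400
    trim_margin: int = 15
    fold_backend: str = "bundled"

    # classification and retention
    signature_threshold: float = 0.75
    signature_tolerance: int = 3
    min_mir_paired: float = 0.60
    rescue_max_mismatch: int = 3
    min_hairpin_fraction: float = 0.20

    # families and conservation
    family_max_mismatch: int = 3
    family_min_identity: float = 0.842
    conservation_max_mismatch: int = 3

    # targets
    target_max_penalty: float = 2.0
    target_min_length: int = 18
    target_min_score: float = 140.0
    target_max_energy: float = -20.0
    degradome_alpha: float = 0.05
    degradome_tag_length: int = 20

    # polymorphism
    flank: int = 1500
    window: int = 500
    n_permutations: int = 10_000

    log_level: str = "INFO"

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls_, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        # YAML has no tuple type: restore tuples where the defaults use them
        for key, default in (
            (f.name, f.default) for f in dataclasses.fields(SimulationConfig)
        ):
            if isinstance(default, tuple) and isinstance(sim_raw.get(key), list):
                sim_raw[key] = tuple(sim_raw[key])
        sim = SimulationConfig(**sim_raw)
        hp = HairpinThresholds(**raw.pop("hairpin", {}))
        return cls_(simulation=sim, hairpin=hp, **raw)


_ACCEPTED_STATUS = ("known_exact", "known_variant", "novel_accepted")


STAGES = ("process", "map", "classify", "cluster", "targets", "snp")


def run_all(config: PipelineConfig, out_dir, data=None, until: str = "snp") -> dict:
    """Run every stage on a dataset (simulated by default) and write the
    stage tables, funnel and manifest under ``out_dir``.

    ``until`` stops after the named stage (stages are pure functions of
    the inputs and the seed, so partial runs are simply prefixes).
    """
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; choose from {STAGES}")

    def reached(stage: str) -> bool:
        return STAGES.index(until) >= STAGES.index(stage)

    logging.basicConfig(level=config.log_level)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    funnel: list[tuple[str, str, int, bool]] = []  # stage, unit, count, in chain

    # ------------------------------------------------------------------ input
    if data is None:
        if not config.simulate:
            raise ValueError("no input data given and simulation disabled")
        sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
        data = simulate_all(sim_cfg)
    genome = data.genome
    features = data.features
    libraries = sorted(data.libraries)
    known_set = {s.upper().replace("U", "T") for _n, s in data.known_matures}

    # ---------------------------------------------------------------- process
    raw_total = sum(len(v) for v in data.libraries.values())
    funnel.append(("raw_reads", "reads", raw_total, True))
    inserts_by_lib: dict[str, list[str]] = {}
    n_trimmed = 0
    n_clean = 0
    for lib in libraries:
        inserts = []
        for read in data.libraries[lib]:
            insert = trim_adaptor(read, config.adaptor, config.adaptor_seed_len)
            if insert is None:
                continue
            n_trimmed += 1
            if MIN_LEN <= len(insert) <= MAX_LEN and "N" not in insert:
                n_clean += 1
                inserts.append(insert)
        inserts_by_lib[lib] = inserts
    funnel.append(("adaptor_trimmed", "reads", n_trimmed, True))
    funnel.append(("length_filtered", "reads", n_clean, True))

    structural = [
        extract_locus(genome, _feature_locus(f))
        for f in features
        if f.feature_type in ("rRNA", "tRNA")
    ]
    collapsed = filter_and_collapse(inserts_by_lib, structural)
    funnel.append(("distinct_smrnas", "distinct", len(collapsed), True))
    log.info("stage=process distinct=%d", len(collapsed))
    if not reached("map"):
        df = pd.DataFrame(
            [
                {"sequence": r.sequence, "length": r.length, "total_count": r.total_count,
                 **{f"count_{lib}": r.count_in(lib) for lib in libraries}}
                for r in collapsed
            ]
        )
        write_table(df, out / "smrnas.tsv")
        return _finish(out, config, funnel, t_start, {"data": data, "collapsed": collapsed})

    # -------------------------------------------------------------------- map
    mapped = map_perfect(collapsed, genome)
    funnel.append(("mapped_smrnas", "distinct", len(mapped), True))
    retained, n_multi = filter_multilocus(mapped, config.max_loci)
    funnel.append(("multilocus_retained", "distinct", len(retained), True))
    gated = abundance_gate(retained, known_set, config.top_quantile)
    n_gated = sum(1 for m in gated if m.passed_abundance_filter)
    funnel.append(("abundance_gated", "distinct", n_gated, True))
    log.info("stage=map mapped=%d retained=%d gated=%d", len(mapped), len(retained), n_gated)
    if not reached("classify"):
        df = pd.DataFrame(
            [
                {"sequence": m.sequence, "length": m.read.length,
                 "total_count": m.read.total_count, "n_loci": m.n_loci,
                 "is_known_mirna": m.is_known_mirna,
                 "passed_abundance_filter": m.passed_abundance_filter,
                 "passed_libraries": ",".join(sorted(m.passed_libraries))}
                for m in gated
            ]
        )
        write_table(df, out / "mapped_smrnas.tsv")
        return _finish(out, config, funnel, t_start, {"data": data, "gated": gated})

    # ------------------------------------------------- discovery + classify
    candidates = cls.select_defining_smrnas(
        gated,
        genome,
        pad=config.context_pad,
        margin=config.trim_margin,
        thresholds=config.hairpin,
        backend=config.fold_backend,
    )
    n_defining = sum(
        1
        for m in gated
        if m.passed_abundance_filter and m.read.length in cls.DEFINING_LENGTH_ORDER
    )
    funnel.append(("defining_candidates", "distinct", n_defining, True))
    funnel.append(("matures_with_precursor", "matures", len(candidates), True))

    for cand in candidates:
        for ann in cand.precursors:
            cls.classify_global(ann, libraries)
            cls.signature_gate(
                ann,
                config.signature_threshold,
                config.signature_tolerance,
                config.min_mir_paired,
            )
    cls.rescue_by_mature(candidates, config.rescue_max_mismatch)
    for cand in candidates:
        cls.novel_filters(
            cand,
            known_set,
            config.min_hairpin_fraction,
            config.rescue_max_mismatch,
        )
        if not any(ann.retained for ann in cand.precursors):
            cand.status = "rejected"
        for ann in cand.precursors:
            ann.context = cls.genomic_context(ann.precursor.locus, features)

    accepted = [c for c in candidates if c.status in _ACCEPTED_STATUS]
    n_class12 = sum(
        1 for c in candidates if any(a.global_class in (1, 2) for a in c.precursors)
    )
    n_rescued = sum(
        1 for c in candidates for a in c.precursors if a.retained and a.rescued
    )
    # composition row, not part of the monotone filter chain: rescue can
    # accept class-3/4/5 matures beyond the bona fide class-1/2 set
    funnel.append(("bona_fide_class12_matures", "matures", n_class12, False))
    funnel.append(("accepted_matures", "matures", len(accepted), True))
    funnel.append(("rescued_class345_precursors", "precursors", n_rescued, False))
    log.info("stage=classify candidates=%d accepted=%d", len(candidates), len(accepted))

    # ------------------------------------------------- families/conservation
    families: list = []
    family_of: dict[str, str] = {}
    conservation: dict = {}
    if reached("cluster"):
        # two independent loci may report the same mature; merge them before
        # clustering (counts summed, retained loci pooled)
        count_by_mature: dict[str, int] = {}
        loci_per_mature: dict[str, int] = {}
        for c in accepted:
            count_by_mature[c.mature] = (
                count_by_mature.get(c.mature, 0) + c.defining.read.total_count
            )
            loci_per_mature[c.mature] = loci_per_mature.get(c.mature, 0) + sum(
                1 for a in c.precursors if a.retained
            )
        mature_counts = sorted(count_by_mature.items())
        families = fam.cluster_families(
            mature_counts,
            loci_per_mature,
            config.family_max_mismatch,
            config.family_min_identity,
        )
        family_of = {m: f.family_id for f in families for m in f.members}

        clade = {
            sp: _flatten_genome(data.homolog_genomes[sp])
            for sp in data.config.clade_genomes
            if sp in data.homolog_genomes
        } if hasattr(data, "config") else {}
        outgroup = {
            sp: _flatten_genome(data.homolog_genomes[sp])
            for sp in getattr(data.config, "outgroup_genomes", ())
            if sp in data.homolog_genomes
        } if hasattr(data, "config") else {}
        conservation = {
            c.mature: fam.conservation_category(
                c.mature, clade, outgroup, config.conservation_max_mismatch
            )
            for c in accepted
        }
        log.info("stage=cluster families=%d", len(families))

    # ---------------------------------------------------------------- targets
    target_rows: list = []
    if reached("targets"):
        transcripts = dict(data.transcripts)
        profiles = tgt.map_degradome_tags(
            [s for _i, s in data.degradome_tags], transcripts, config.degradome_tag_length
        )
        for c in accepted:
            for tid in sorted(transcripts):
                sites = tgt.align_mirna_target(
                    c.mature, transcripts[tid], tid, config.target_min_score
                )
                for site in tgt.filter_targets(
                    sites,
                    config.target_max_penalty,
                    config.target_min_length,
                    config.target_min_score,
                    config.target_max_energy,
                ):
                    support = tgt.degradome_validate(site, profiles, config.degradome_alpha)
                    target_rows.append(
                        {
                            "mirna": c.mature,
                            "transcript_id": tid,
                            "site_start": site.site[0],
                            "site_end": site.site[1],
                            "alignment_score": site.alignment_score,
                            "penalty_score": site.penalty_score,
                            "alignment_length": site.alignment_length,
                            "duplex_energy": round(site.duplex_energy, 3),
                            "cleavage_position": support.cleavage_position,
                            "cleavage_tag_count": support.tag_count_at_cleavage,
                            "degradome_category": support.category,
                            "degradome_p": round(support.p_value, 6),
                            "validated": support.validated,
                        }
                    )
        log.info("stage=targets sites=%d", len(target_rows))

    # ----------------------------------------------------------- polymorphism
    group_of: dict[str, str] = {}
    chrom_of: dict[str, str] = {}
    regions_specs: list[poly.PrecursorRegions] = []
    precursor_meta: dict[str, tuple] = {}
    for ci, c in enumerate(accepted):
        group = "conserved" if c.status in ("known_exact", "known_variant") else "novel"
        for k, ann in enumerate(ann for ann in c.precursors if ann.retained):
            pid = f"prec_{ci + 1:03d}_{k + 1}"
            pc = ann.precursor
            regions_specs.append(
                poly.PrecursorRegions(
                    precursor_id=pid,
                    locus=pc.locus,
                    mature_local=pc.mir_span,
                    star_local=pc.star_span,
                    fold=pc.fold,
                    loop_local=ann.loop_region,
                    chrom_length=len(genome[pc.locus.seq_id]),
                )
            )
            precursor_meta[pid] = (c, ann)
            group_of[pid] = group
            chrom_of[pid] = pc.locus.seq_id
    snp_profiles: list = []
    snp_summary = {
        "table": pd.DataFrame(),
        "rates_by_window": pd.DataFrame(),
        "comparison": {},
    }
    if reached("snp"):
        assigned = poly.assign_snps(
            data.variants, regions_specs, config.flank, config.window
        )
        snp_profiles = [
            poly.profile_precursor(spec, assigned[spec.precursor_id], config.flank, config.window)
            for spec in regions_specs
        ]
        snp_summary = poly.summarize_polymorphism(
            snp_profiles, group_of, chrom_of, config.n_permutations, config.seed
        )
        log.info("stage=snp precursors=%d", len(snp_profiles))

    # ---------------------------------------------------------------- outputs
    mature_rows = []
    for c in sorted(candidates, key=lambda c: c.mature):
        mature_rows.append(
            {
                "mature": c.mature,
                "length": len(c.mature),
                "total_count": c.defining.read.total_count,
                "n_loci": c.n_loci,
                "n_precursors": len(c.precursors),
                "n_retained_precursors": sum(a.retained for a in c.precursors),
                "fraction_loci_with_hairpin": round(c.fraction_loci_with_hairpin, 4),
                "status": c.status,
                "family_id": family_of.get(c.mature, ""),
                "conservation": (
                    conservation[c.mature].category if c.mature in conservation else ""
                ),
            }
        )
    matures_df = pd.DataFrame(mature_rows)

    precursor_rows = []
    for pid in sorted(precursor_meta):
        c, ann = precursor_meta[pid]
        pc = ann.precursor
        precursor_rows.append(
            {
                "precursor_id": pid,
                "mature": c.mature,
                "seq_id": pc.locus.seq_id,
                "start": pc.locus.start,
                "end": pc.locus.end,
                "strand": pc.locus.strand,
                "length": pc.length,
                "mfe": round(pc.fold.mfe, 2),
                "mfe_density": round(pc.mfe_density, 4),
                "global_class": ann.global_class,
                "signature_pass": ann.signature_pass,
                "rescued": ann.rescued,
                "context": ann.context,
                "status": c.status,
            }
        )
    precursors_df = pd.DataFrame(precursor_rows)

    families_df = pd.DataFrame(
        [
            {
                "family_id": f.family_id,
                "representative": f.representative,
                "n_members": len(f.members),
                "n_genes": f.n_genes,
                "members": ",".join(f.members),
            }
            for f in families
        ]
    )
    conservation_df = pd.DataFrame(
        [
            {
                "mature": m,
                "category": call.category,
                **{f"hits_{g}": n for g, n in sorted(call.hits_per_genome.items())},
            }
            for m, call in sorted(conservation.items())
        ]
    )
    targets_df = pd.DataFrame(target_rows)

    poly_rows = []
    for p in snp_profiles:
        row = {
            "precursor_id": p.precursor_id,
            "group": group_of[p.precursor_id],
            "n_snps_hairpin": p.n_snps_hairpin,
            "n_indels_hairpin": p.n_indels_hairpin,
            "mature_snp_offsets": ",".join(map(str, p.mature_snp_positions)),
            "star_snp_count": p.star_snp_count,
            "hairpin_rate": round(p.hairpin_rate, 4),
            "n_bulge_snps": sum(1 for _p, ctx, _d in p.structural_context if ctx == "bulge"),
            "n_near_bulge_snps": sum(
                1 for _p, ctx, _d in p.structural_context if ctx == "near_bulge_1_2nt"
            ),
            "n_stem_snps": sum(1 for _p, ctx, _d in p.structural_context if ctx == "stem"),
            "n_loop_snps": sum(1 for _p, ctx, _d in p.structural_context if ctx == "loop"),
            "n_star_disrupting": sum(1 for _p, _c, d in p.structural_context if d),
        }
        row.update({f"flag_{k}": v for k, v in sorted(p.flags.items())})
        for key in poly.WINDOW_KEYS:
            row[f"snps_{key}"] = p.window_counts.get(key, 0)
            row[f"rate_{key}"] = round(p.window_rates.get(key, 0.0), 4)
        poly_rows.append(row)
    poly_df = pd.DataFrame(poly_rows).sort_values("precursor_id") if poly_rows else pd.DataFrame()

    funnel_df = pd.DataFrame(
        funnel, columns=["stage", "unit", "count", "monotone_chain"]
    )

    from .io_formats import FeatureRecord, write_fasta, write_gff3

    precursor_features = []
    for pid in sorted(precursor_meta):
        c, ann = precursor_meta[pid]
        pc = ann.precursor
        precursor_features.append(
            FeatureRecord(
                pc.locus.seq_id, "mirnaome", "miRNA_primary_transcript",
                pc.locus.start, pc.locus.end, pc.locus.strand,
                {
                    "ID": pid,
                    "class": str(ann.global_class),
                    "defining_smrna": ann.defining.sequence,
                    "mfe": f"{pc.fold.mfe:.2f}",
                    "density": f"{pc.mfe_density:.4f}",
                    "status": c.status,
                },
            )
        )
    write_gff3(precursor_features, out / "precursors.gff3", source="mirnaome")
    write_fasta(
        sorted({(f"mir_{i + 1:03d}", c.mature) for i, c in enumerate(accepted)}),
        out / "matures.fa",
    )

    write_table(funnel_df, out / "funnel.tsv")
    write_table(matures_df, out / "matures.tsv")
    write_table(precursors_df, out / "precursors.tsv")
    write_table(families_df, out / "families.tsv")
    write_table(conservation_df, out / "conservation.tsv")
    write_table(targets_df, out / "targets.tsv")
    write_table(poly_df, out / "polymorphism.tsv")
    write_table(snp_summary["table"], out / "summary_table.tsv")
    write_table(snp_summary["rates_by_window"], out / "rates_by_window.tsv")

    comparison_rows = [
        {"region": region, **{k: v for k, v in res.items()}}
        for region, res in snp_summary["comparison"].items()
        if isinstance(res, dict)
    ]
    write_table(pd.DataFrame(comparison_rows), out / "group_comparison.tsv")

    stage_counts = {stage: count for stage, _u, count, _c in funnel}
    stage_counts["n_families"] = len(families)
    stage_counts["n_target_sites"] = len(target_rows)
    stage_counts["n_validated_sites"] = int(
        sum(1 for r in target_rows if r["validated"])
    )
    stage_counts["runtime_s"] = round(time.time() - t_start, 1)
    write_manifest(out / "manifest.json", config.resolved(), config.seed, stage_counts)
    log.info("pipeline done in %.1f s", time.time() - t_start)

    return {
        "data": data,
        "candidates": candidates,
        "accepted": accepted,
        "families": families,
        "conservation": conservation,
        "targets": target_rows,
        "snp_profiles": snp_profiles,
        "snp_summary": snp_summary,
        "funnel": funnel_df,
        "summary": cls.summarize_matures(candidates),
        "out_dir": out,
    }


def _finish(out: Path, config: PipelineConfig, funnel, t_start, result: dict) -> dict:
    """Write the funnel and manifest for a partial (``until``) run."""
    funnel_df = pd.DataFrame(funnel, columns=["stage", "unit", "count", "monotone_chain"])
    write_table(funnel_df, out / "funnel.tsv")
    stage_counts = {stage: count for stage, _u, count, _c in funnel}
    stage_counts["runtime_s"] = round(time.time() - t_start, 1)
    write_manifest(out / "manifest.json", config.resolved(), config.seed, stage_counts)
    result["funnel"] = funnel_df
    result["out_dir"] = out
    return result


def _feature_locus(f):
    from .mapping import GenomeLocus

    return GenomeLocus(f.seq_id, f.start, f.end, f.strand)


def _flatten_genome(genome: dict) -> str:
    # concatenate chromosomes with an N spacer wide enough to block any
    # window (max 3 mismatches allowed) from spanning the junction
    return ("N" * 4).join(g.residues for _c, g in sorted(genome.items()))
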