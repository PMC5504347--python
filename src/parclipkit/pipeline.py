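"""End-to-end orchestration: simulate/load -> align/classify -> annotate ->
composition / metagene / tRNA enrichment / rRNA profile / codon census.

One global seed drives the simulator and every tie-breaking draw; per-stage
seeds are derived deterministically from it, so re-running a config
reproduces all outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate as sim
from .align import Aligner, class_ambiguous, classify, filter_for_analysis, TransitionClass
from .annotate import DEFAULT_PRIORITY, annotate_reads, composition
from .codons import census
from .metagene import MetageneConfig, build_metagene
from .reads import collapse_duplicates, read_fastq, write_fastq
from .references import ReferenceSet, load_references, write_references
from .rrna import call_hotspots, rrna_coverage
from .trna import (
    CountTable,
    conversion_map,
    count_unique,
    enrichment,
    positional_profile,
)

log = logging.getLogger("parclipkit")

STAGES = ("composition", "metagene", "trna", "rrna", "census")


@dataclass
class HotspotParams:
    frac_of_max: float = 0.25
    merge_gap: int = 5
    min_width: int = 10


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "parclip_run"
    references: str | None = None  # dir with references.fasta/regions.tsv/trna.tsv
    reads: str | None = None  # PAR-CLIP FASTQ; None -> simulate
    background_reads: str | None = None  # background FASTQ; None -> simulate
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    max_mismatches: int = 2
    min_read_len: int = 15
    category_priority: tuple = DEFAULT_PRIORITY
    use_copies: bool = True
    fdr: float = 0.05
    top_fraction: float = 0.85
    census_codon: str = "AAA"
    hotspot: HotspotParams = field(default_factory=HotspotParams)
    metagene: MetageneConfig = field(default_factory=MetageneConfig)
    sim: sim.SimConfig = field(default_factory=sim.default_config)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["category_priority"] = list(self.category_priority)
        return d


def _set_nested(obj, key: str, value, path: str):
    if not hasattr(obj, key):
        raise ValueError(f"unknown config key {path!r}")
    current = getattr(obj, key)
    if dataclasses.is_dataclass(current) and isinstance(value, dict):
        for k, v in value.items():
            _set_nested(current, k, v, f"{path}.{k}")
    else:
        setattr(obj, key, value)


def validate_config(source) -> RunConfig:
    """Normalize a YAML path / dict into a validated RunConfig.

    Unknown keys are rejected with their key path; out-of-range values are
    reported the same way.
    """
    if source is None:
        data = {}
    elif isinstance(source, dict):
        data = source
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")

    cfg = RunConfig()
    for key, value in data.items():
        if key == "stages":
            if not isinstance(value, dict):
                raise ValueError("stages must be a mapping of stage -> bool")
            for s, flag in value.items():
                if s not in STAGES:
                    raise ValueError(f"unknown config key 'stages.{s}'")
                cfg.stages[s] = bool(flag)
        elif key == "category_priority":
            cfg.category_priority = tuple(value)
        else:
            _set_nested(cfg, key, value, key)

    if not 0 < cfg.fdr <= 1:
        raise ValueError("fdr must be in (0,1]")
    if not 0 < cfg.top_fraction <= 1:
        raise ValueError("top_fraction must be in (0,1]")
    if cfg.min_read_len < 1:
        raise ValueError("min_read_len must be >= 1")
    if cfg.max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    cfg.metagene.validate()
    if isinstance(cfg.sim, dict):  # pragma: no cover - defensive
        cfg.sim = sim.SimConfig(**cfg.sim)
    cfg.sim.validate()
    return cfg


def _derived_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def _prepare_aligned(reads, cfg, aligner, label, accounting):
    accounting[f"{label}_reads_in"] = len(reads)
    kept = [r for r in reads if len(r.sequence) >= cfg.min_read_len]
    accounting[f"{label}_reads_min_len"] = len(kept)
    collapsed = collapse_duplicates(kept)
    accounting[f"{label}_unique_sequences"] = len(collapsed)
    aligned = aligner.align_many(collapsed)
    accounting[f"{label}_mapped_sequences"] = sum(1 for a in aligned if a.mapped)
    return aligned


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the run report.

    All stage tables are written under ``config.out_dir`` along with the
    normalized config echo and ``run_report.json``.  A stage failure leaves a
    ``FAILED`` marker naming the stage and re-raises.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    stage = "setup"
    try:
        seeds = _derived_seeds(config.seed, 4)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

        if config.references:
            rdir = Path(config.references)
            refset = load_references(
                rdir / "references.fasta", rdir / "regions.tsv", rdir / "trna.tsv"
            )
            log.info("loaded %d references from %s", len(refset), rdir)
        else:
            refset = sim.synthetic_references(seed=seeds[0])
            write_references(refset, out / "references")
            log.info("generated synthetic reference universe (%d sequences)", len(refset))

        sim_cfg = dataclasses.replace(config.sim, seed=seeds[1])
        if config.reads:
            par_reads = read_fastq(config.reads)
        else:
            par_reads, par_truth = sim.simulate_parclip(refset, sim_cfg)
            write_fastq(par_reads, out / "parclip.fastq")
            sim.write_truth(par_truth, out / "parclip_truth.tsv")
        log.info("PAR-CLIP library: %d reads", len(par_reads))

        aligner = Aligner(refset, max_mm=config.max_mismatches)
        accounting: dict = {}
        aligned = _prepare_aligned(par_reads, config, aligner, "parclip", accounting)
        annotated = annotate_reads(
            aligned, refset, priority=config.category_priority, seed=seeds[2]
        )
        accounting["parclip_annotated_sequences"] = len(annotated)

        report: dict = {
            "seed": config.seed,
            "stages": {},
            "read_accounting": accounting,
        }

        if config.stages.get("composition", True):
            stage = "composition"
            comp_reads = filter_for_analysis(annotated, "composition")
            accounting["composition_reads"] = len(comp_reads)
            comp = composition(comp_reads, use_copies=config.use_copies)
            comp.table.to_csv(out / "composition.tsv", sep="\t", index=False)
            report["stages"]["composition"] = {"ratio": comp.ratio, "total": comp.total}
            log.info("composition ratio (rRNA=1): %s", comp.ratio)
        else:
            report["stages"]["composition"] = "skipped"

        if config.stages.get("metagene", True):
            stage = "metagene"
            mg_reads = filter_for_analysis(
                [r for r in annotated if r.category == "mRNA"], "mrna"
            )
            accounting["metagene_reads"] = len(mg_reads)
            mg = build_metagene(mg_reads, refset, config.metagene, config.use_copies)
            mg.matrix.to_csv(out / "metagene_matrix.tsv", sep="\t")
            mg.aggregate.to_csv(out / "metagene_aggregate.tsv", sep="\t", index=False)
            report["stages"]["metagene"] = {
                "transcripts": int(mg.matrix.shape[0]),
                "region_shares": mg.region_shares(),
            }
        else:
            report["stages"]["metagene"] = "skipped"

        if config.stages.get("trna", True):
            stage = "trna"
            if config.background_reads:
                bg_reads = read_fastq(config.background_reads)
            else:
                bg_reads, bg_truth = sim.simulate_background(refset, sim_cfg)
                write_fastq(bg_reads, out / "background.fastq")
                sim.write_truth(bg_truth, out / "background_truth.tsv")
            bg_aligned = _prepare_aligned(bg_reads, config, aligner, "background", accounting)

            trna_ann = [r for r in annotated if r.category == "tRNA"]
            trna_d1tc = filter_for_analysis(trna_ann, "trna")
            accounting["trna_d1tc_reads"] = len(trna_d1tc)
            par_for_counts = [
                a
                for a in aligned
                if a.mapped
                and a.length >= 20
                and classify(a) == TransitionClass.D1TC
                and not class_ambiguous(a)
            ]
            table = count_unique(
                par_for_counts, bg_aligned, refset, use_copies=config.use_copies
            )
            gdf = table.genes.reset_index()
            gdf.to_csv(out / "trna_counts.tsv", sep="\t", index=False)
            enr = enrichment(table, fdr=config.fdr, top_fraction=config.top_fraction)
            combined = (
                enr.genes.reset_index()
                .rename(columns={"gene": "feature"})
                .assign(level="gene")
            )
            fam = (
                enr.families.reset_index()
                .rename(columns={"family": "feature"})
                .assign(level="family")
            )
            pd_all = pd.concat([combined, fam], ignore_index=True)
            pd_all.to_csv(out / "trna_enrichment.tsv", sep="\t", index=False)

            profile = positional_profile(
                trna_d1tc, refset, use_copies=config.use_copies
            ) if trna_d1tc else None
            cmap = conversion_map(trna_ann, refset, use_copies=config.use_copies)
            cmap.table.to_csv(out / "trna_conversion_profile.tsv", sep="\t", index=False)

            top = enr.families.sort_values("q").head(5)
            report["stages"]["trna"] = {
                "factors": enr.factors,
                "top_families": {
                    str(i): {
                        "log2fc": None if np.isnan(row.log2fc) else float(row.log2fc),
                        "q": None if np.isnan(row.q) else float(row.q),
                        "significant": bool(row.significant),
                    }
                    for i, row in top.iterrows()
                },
                "argmax_element": cmap.argmax_element,
                "positional_profile": None if profile is None else [float(x) for x in profile],
            }
        else:
            report["stages"]["trna"] = "skipped"

        if config.stages.get("rrna", True):
            stage = "rrna"
            rr_reads = filter_for_analysis(
                [r for r in annotated if r.category == "rRNA"], "rrna"
            )
            accounting["rrna_reads"] = len(rr_reads)
            profile = rrna_coverage(rr_reads, refset, use_copies=config.use_copies)
            profile.to_frame().to_csv(out / "rrna_coverage.tsv", sep="\t", index=False)
            profile.composition.to_csv(out / "rrna_composition.tsv", sep="\t", index=False)
            hs = call_hotspots(
                profile,
                frac_of_max=config.hotspot.frac_of_max,
                merge_gap=config.hotspot.merge_gap,
                min_width=config.hotspot.min_width,
            )
            hs.to_csv(out / "rrna_hotspots.tsv", sep="\t", index=False)
            report["stages"]["rrna"] = {
                "hotspots": hs.to_dict(orient="records"),
            }
        else:
            report["stages"]["rrna"] = "skipped"

        if config.stages.get("census", True):
            stage = "census"
            cds = {}
            for rid, reg in refset.mrna_regions.items():
                seq = refset.sequences[rid].sequence
                cds_seq = seq[reg.utr5_len : reg.utr5_len + reg.cds_len]
                cds[rid] = cds_seq[: len(cds_seq) - len(cds_seq) % 3]
            cen = census(cds, config.census_codon)
            pd.DataFrame(
                [{"k": k, "count": v} for k, v in cen.histogram.items()]
            ).to_csv(out / "census.tsv", sep="\t", index=False)
            pd.DataFrame(
                cen.runs, columns=["cds_id", "codon_index", "k"]
            ).to_csv(out / "runs.tsv", sep="\t", index=False)
            report["stages"]["census"] = {
                "codon": config.census_codon,
                "histogram": {str(k): v for k, v in cen.histogram.items()},
                "max_k": cen.max_k,
            }
        else:
            report["stages"]["census"] = "skipped"

        with open(out / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=float)
        log.info("run complete")
        return report
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\n{exc}\n")
        log.error("stage %s failed: %s", stage, exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
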