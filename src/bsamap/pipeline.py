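"""End-to-end orchestration: simulate → scan → annotate → prioritize → targets.

A run is a pure function of (inputs, config): identical config and seed
reproduce byte-identical outputs and report. Inputs come either from a
seeded simulation or from files on disk; all stage outputs are written in
the standard formats and a machine-readable JSON report collects stage
counts, the detected interval, the candidate ranking, and — when ground
truth is available — recovery metrics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import io as gio
from . import prioritize as pz
from . import scan as sc
from . import targets as tg
from .effects import annotate_all, genome_index
from .errors import ConfigError, ConsistencyError
from .simulate import CrossConfig, SimTruth, simulate_dataset, write_dataset

log = logging.getLogger(__name__)


@dataclass
class ScanParams:
    window_size: int = sc.DEFAULT_WINDOW_SIZE
    min_depth: int = sc.DEFAULT_MIN_DEPTH
    ems_only: bool = True
    threshold: float = sc.DEFAULT_THRESHOLD
    min_variants: int = sc.DEFAULT_MIN_VARIANTS


@dataclass
class CascadeParams:
    f_mut_min: float = pz.DEFAULT_F_MUT_MIN
    f_wt_max: float = pz.DEFAULT_F_WT_MAX
    fpkm_min: float = pz.DEFAULT_FPKM_MIN
    use_expression: bool = True


@dataclass
class TargetParams:
    max_dist: int = tg.DEFAULT_MAX_DIST
    shared_min: int = 2
    padj_max: float = tg.DEFAULT_PADJ_MAX
    lfc_min: float = tg.DEFAULT_LFC_MIN
    count_min: float | None = None


@dataclass
class InputPaths:
    vcf: str | None = None
    gff: str | None = None
    fasta: str | None = None
    panel: str | None = None
    expression: str | None = None
    peaks: str | None = None
    de: str | None = None
    truth: str | None = None
    sample_map: dict[str, str] = field(default_factory=lambda: dict(gio.DEFAULT_SAMPLE_MAP))


@dataclass
class RunConfig:
    """Full configuration of one pipeline run.

    Exactly one of ``simulate`` (a :class:`CrossConfig`) or ``inputs``
    (paths to existing files) must be provided. Unknown config keys are
    rejected so a typo cannot silently fall back to a default.
    """

    outdir: str = "bsamap_run"
    seed: int = 0
    log_level: str = "INFO"
    simulate: CrossConfig | None = None
    inputs: InputPaths | None = None
    scan: ScanParams = field(default_factory=ScanParams)
    cascade: CascadeParams = field(default_factory=CascadeParams)
    targets: TargetParams = field(default_factory=TargetParams)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        def build(dc_cls, payload, ctx):
            if payload is None:
                return None
            if not isinstance(payload, Mapping):
                raise ConfigError(f"{ctx}: expected a mapping, got {type(payload).__name__}")
            names = {f.name for f in dataclasses.fields(dc_cls)}
            unknown = set(payload) - names
            if unknown:
                raise ConfigError(f"{ctx}: unknown keys {sorted(unknown)}")
            return dc_cls(**payload)

        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ConfigError(f"run config: unknown keys {sorted(unknown)}")
        kwargs: dict[str, Any] = {
            k: d[k] for k in ("outdir", "seed", "log_level") if k in d
        }
        kwargs["simulate"] = build(CrossConfig, d.get("simulate"), "simulate")
        kwargs["inputs"] = build(InputPaths, d.get("inputs"), "inputs")
        for key, dc_cls in (
            ("scan", ScanParams),
            ("cascade", CascadeParams),
            ("targets", TargetParams),
        ):
            if key in d:
                kwargs[key] = build(dc_cls, d[key], key)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _variant_label(key: tuple[str, int, str, str]) -> str:
    chrom, pos, ref, alt = key
    return f"{chrom}:{pos}:{ref}>{alt}"


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> dict:
    """Execute the full mapping pipeline; returns the JSON-ready report.

    When ``write_outputs`` is true, stage outputs (scan.tsv, region.bed,
    ann.tsv, candidates.tsv, report.json, plus simulated inputs) land
    under ``config.outdir``.
    """
    if (config.simulate is None) == (config.inputs is None):
        raise ConfigError("provide exactly one of 'simulate' or 'inputs'")

    outdir = Path(config.outdir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)

    truth: SimTruth | None = None
    peaks = None
    de_table = None
    t0 = time.perf_counter()

    if config.simulate is not None:
        sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
        dataset = simulate_dataset(sim_cfg)
        if write_outputs:
            write_dataset(dataset, outdir / "inputs")
        genome = genome_index(dataset.genome)
        gene_models = dataset.gene_models
        variants = dataset.bulk_variants
        panel = dataset.panel_sites
        expression = dataset.expression
        peaks = dataset.peaks
        de_table = dataset.de_table
        truth = dataset.truth
        n_skipped = 0
    else:
        inp = config.inputs
        required = {"vcf": inp.vcf, "gff": inp.gff, "fasta": inp.fasta}
        missing = [k for k, v in required.items() if v is None]
        if missing:
            raise ConfigError(f"inputs missing required paths: {missing}")
        genome = genome_index(gio.read_genome(inp.fasta))
        gene_models = gio.read_gene_models(inp.gff)
        vlist = gio.read_variants(inp.vcf, inp.sample_map)
        variants, n_skipped = list(vlist), vlist.n_skipped
        panel = gio.read_panel_sites(inp.panel) if inp.panel else set()
        expression = gio.read_expression(inp.expression) if inp.expression else None
        peaks = gio.read_peaks(inp.peaks) if inp.peaks else None
        de_table = gio.read_de_table(inp.de) if inp.de else None
        if inp.truth:
            truth = SimTruth.from_json(Path(inp.truth).read_text())
    log.info("inputs ready: %d variants (%d skipped on read)", len(variants), n_skipped)

    # --- scan -------------------------------------------------------------
    records = sc.compute_records(variants, min_depth=config.scan.min_depth)
    scan_records = [r for r in records if r.is_ems_type] if config.scan.ems_only else records
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    windows = sc.windowed_scan(
        scan_records, config.scan.window_size, chrom_lengths=chrom_lengths
    )
    interval = sc.detect_interval(
        windows, threshold=config.scan.threshold, min_variants=config.scan.min_variants
    )
    log.info("scan: %d windows, interval %s", len(windows), interval)

    # --- annotate ---------------------------------------------------------
    annotations = annotate_all(variants, gene_models, genome)

    # --- prioritize -------------------------------------------------------
    expressed = None
    if config.cascade.use_expression and expression is not None:
        expressed = pz.expressed_genes(expression, config.cascade.fpkm_min)
    report_obj = pz.apply_cascade(
        records,
        annotations,
        interval,
        panel,
        expressed=expressed,
        f_mut_min=config.cascade.f_mut_min,
        f_wt_max=config.cascade.f_wt_max,
    )
    log.info("cascade: %s", report_obj.stage_counts())

    # --- targets ----------------------------------------------------------
    targets_section = None
    if peaks is not None:
        assignments = tg.assign_targets(peaks, gene_models, config.targets.max_dist)
        sets = tg.target_sets(assignments)
        targets_section = {
            "n_assignments": len(assignments),
            "factors": {f: len(g) for f, g in sorted(sets.items())},
        }
        if len(sets) >= 2:
            sh = tg.shared_fraction(sets, config.targets.shared_min)
            targets_section["union_size"] = sh.union_size
            targets_section["shared_size"] = sh.shared_size
            targets_section["shared_fraction"] = (
                None if sh.fraction is None else round(float(sh.fraction), 6)
            )
        if de_table is not None and sets:
            up, down = tg.filter_de(
                de_table,
                config.targets.padj_max,
                config.targets.lfc_min,
                config.targets.count_min,
            )
            union = set().union(*sets.values())
            ov = tg.overlap_targets_de(union, up, down)
            targets_section["de"] = {
                "n_up": len(up),
                "n_down": len(down),
                "up_target_fraction": None
                if ov.up_fraction is None
                else round(float(ov.up_fraction), 6),
                "down_target_fraction": None
                if ov.down_fraction is None
                else round(float(ov.down_fraction), 6),
            }

    report = {
        "schema": "bsamap-report-v1",
        "seed": config.seed,
        "n_variants": len(variants),
        "n_skipped_on_read": n_skipped,
        "interval": None
        if interval is None
        else {"chrom": interval.chrom, "start": interval.start, "end": interval.end},
        "cascade": {
            "stages": [
                {
                    "name": s.name,
                    "description": s.description,
                    "survivors": s.survivor_count,
                    "survivor_ids": [_variant_label(k) for k in s.survivors],
                }
                for s in report_obj.stages
            ],
        },
        "candidates": [
            {
                "rank": i + 1,
                "variant": _variant_label(c.variant.key),
                "gene_id": c.annotation.gene_id,
                "effect": c.annotation.effect_class.value,
                "impact": c.annotation.impact.value,
                "aa_change": c.annotation.aa_change,
                "distance": round(c.distance, 6),
                "gene_expressed": c.gene_expressed,
            }
            for i, c in enumerate(report_obj.final)
        ],
        "targets": targets_section,
    }
    if truth is not None:
        report["dataset_seed"] = truth.seed
        report["recovery"] = score_against_truth(report, truth)

    if write_outputs:
        gio.write_table(outdir / "scan.tsv", sc.scan_to_frame(windows))
        if interval is not None:
            (outdir / "region.bed").write_text(
                f"{interval.chrom}\t{interval.start}\t{interval.end}\tmapped_interval\n"
            )
        ann_rows = []
        for ann in annotations:
            v = ann.variant
            ann_rows.append(
                {
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "gene_id": ann.gene_id,
                    "effect": ann.effect_class.value,
                    "impact": ann.impact.value,
                    "codon_change": ann.codon_change,
                    "aa_change": ann.aa_change,
                }
            )
        import pandas as pd

        gio.write_table(outdir / "ann.tsv", pd.DataFrame(ann_rows))
        gio.write_table(outdir / "candidates.tsv", pz.report_to_frame(report_obj))
        (outdir / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True) + "\n"
        )
    log.info("pipeline finished in %.2f s", time.perf_counter() - t0)
    return report


def score_against_truth(report: Mapping[str, Any], truth: SimTruth) -> dict:
    """Recovery metrics of a report against the simulator's ground truth."""
    if "dataset_seed" in report and report["dataset_seed"] != truth.seed:
        raise ConsistencyError(
            f"report dataset seed {report['dataset_seed']} != truth seed {truth.seed}"
        )
    causal_label = _variant_label(truth.causal)
    chrom, pos = truth.causal[0], truth.causal[1]
    interval = report.get("interval")
    contains = bool(
        interval
        and interval["chrom"] == chrom
        and interval["start"] <= pos - 1 < interval["end"]
    )
    rank = None
    for c in report.get("candidates", []):
        if c["variant"] == causal_label:
            rank = c["rank"]
            break
    retention = [
        {
            "stage": s["name"],
            "causal_retained": causal_label in s.get("survivor_ids", []),
        }
        for s in report.get("cascade", {}).get("stages", [])
    ]
    return {
        "causal": causal_label,
        "causal_gene": truth.causal_gene,
        "interval_contains_causal": contains,
        "causal_in_final": rank is not None,
        "causal_rank": rank,
        "stage_retention": retention,
    }
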