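"""End-to-end orchestration: simulate -> align -> call -> classify -> anchor
-> design -> report, with per-stage artifacts and a reproducibility manifest.

Every stochastic stage draws from the single seed in the simulation config,
so re-running an identical configuration reproduces identical artifact
digests. Each stage writes its outputs under the configured directory and
drops a ``<stage>.partial`` marker while running; the marker is removed on
success, so a leftover marker identifies the stage that failed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import io as io_mod
from .alignment import build_contig_alignment
from .anchoring import (AnchorConfig, compute_anchors, read_psl,
                        resolve_best_hits, tally_by_chromosome, write_anchors)
from .assay import AssayCriteria, select_assayable, write_assay_table
from .ace import read_ace, write_ace
from .classify import summarize_catalog
from .discovery import CallerConfig, call_contigs, classify_candidates
from .errors import ConfigurationError, PipelineError
from .report import evaluate_against_truth, format_report
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger("tetrasnp")

STAGE_ORDER = ["simulate", "call", "classify", "anchor", "design", "report"]


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)
    anchor: AnchorConfig = field(default_factory=AnchorConfig)
    assay: AssayCriteria = field(default_factory=AssayCriteria)
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "call": True, "classify": True,
        "anchor": False, "design": True, "report": True,
    })
    inputs: dict = field(default_factory=dict)  # ace / reads / placements /
    # references / psl / snps
    outdir: str = "tetrasnp_out"
    log_level: str = "INFO"

    def __post_init__(self):
        self.validate()

    def validate(self):
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        stages = self.enabled_stages()
        if "call" in stages and "simulate" not in stages:
            has_ace = "ace" in self.inputs
            has_reads = {"reads", "placements", "references"} <= set(self.inputs)
            if not (has_ace or has_reads):
                raise ConfigurationError(
                    "call stage without simulation requires inputs.ace or "
                    "inputs.{reads,placements,references}")
        if "anchor" in stages and "psl" not in self.inputs:
            raise ConfigurationError(
                "anchor stage requires inputs.psl (a PSL alignment file)")
        if "classify" in stages and "call" not in stages and \
                "snps" not in self.inputs:
            raise ConfigurationError(
                "classify stage without the call stage requires inputs.snps")
        if "design" in stages and "call" not in stages and not \
                {"ace", "snps"} <= set(self.inputs):
            raise ConfigurationError(
                "design stage without the call stage requires inputs.ace "
                "and inputs.snps")
        for key, path in self.inputs.items():
            if not Path(path).exists():
                raise ConfigurationError(
                    f"inputs.{key}: file not found: {path}")

    def enabled_stages(self) -> list:
        return [s for s in STAGE_ORDER if self.stages.get(s, False)]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(
                f"unknown pipeline config keys: {sorted(unknown)}")
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "caller" in d and isinstance(d["caller"], dict):
            d["caller"] = CallerConfig.from_dict(d["caller"])
        if "anchor" in d and isinstance(d["anchor"], dict):
            d["anchor"] = AnchorConfig.from_dict(d["anchor"])
        if "assay" in d and isinstance(d["assay"], dict):
            d["assay"] = AssayCriteria.from_dict(d["assay"])
        return cls(**d)

    def snapshot(self) -> dict:
        return {
            "simulation": self.simulation.to_dict(),
            "caller": self.caller.to_dict(),
            "anchor": self.anchor.to_dict(),
            "assay": self.assay.to_dict(),
            "stages": dict(self.stages),
            "inputs": {k: str(v) for k, v in self.inputs.items()},
            "outdir": str(self.outdir),
            "log_level": self.log_level,
        }


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    return PipelineConfig.from_dict(data)


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stages: dict = field(default_factory=dict)  # name -> {seconds, outputs}

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "version": self.version,
             "seed": self.seed, "stages": self.stages},
            indent=2, sort_keys=True)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _setup_logging(outdir: Path, level: str):
    logger.setLevel(getattr(logging, level.upper(), logging.INFO))
    logger.handlers = [logging.StreamHandler()]
    try:
        logger.addHandler(logging.FileHandler(outdir / "run.log"))
    except OSError:
        pass
    for handler in logger.handlers:
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s"))


class _StageRunner:
    def __init__(self, outdir: Path, manifest: RunManifest):
        self.outdir = outdir
        self.manifest = manifest

    def run(self, name: str, func):
        marker = self.outdir / f"{name}.partial"
        marker.touch()
        start = time.monotonic()
        logger.info("stage %s: starting", name)
        try:
            outputs = func() or {}
        except Exception as exc:  # noqa: BLE001 - report stage and cause
            logger.error("stage %s failed: %s", name, exc)
            raise PipelineError(name, str(exc)) from exc
        marker.unlink(missing_ok=True)
        self.manifest.stages[name] = {
            "seconds": round(time.monotonic() - start, 3),
            "outputs": {key: _digest(Path(p)) for key, p in outputs.items()},
        }
        logger.info("stage %s: done (%.2fs)", name,
                    self.manifest.stages[name]["seconds"])


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in order and write a run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir, config.log_level)
    logger.info("seed: %d", config.simulation.seed)

    manifest = RunManifest(config=config.snapshot(), version=__version__,
                           seed=config.simulation.seed)
    runner = _StageRunner(outdir, manifest)
    stages = config.enabled_stages()

    state: dict = {}

    if "simulate" in stages:
        def stage_simulate():
            dataset = simulate_dataset(config.simulation)
            state["dataset"] = dataset
            return {k: str(p)
                    for k, p in io_mod.write_dataset(dataset, outdir).items()}
        runner.run("simulate", stage_simulate)

    if "call" in stages:
        def stage_call():
            genotype_map = None
            if "dataset" in state:
                dataset = state["dataset"]
                contigs = build_contig_alignment(
                    dataset.reads, dataset.transcripts)
            elif "ace" in config.inputs:
                sim = config.simulation
                genotype_map = dict(zip(sim.genotype_prefixes,
                                        sim.genotype_ids))
                contigs = read_ace(config.inputs["ace"],
                                   genotype_map=genotype_map)
            else:
                sequences = io_mod.read_fasta(config.inputs["reads"])
                reads = io_mod.read_placements(
                    config.inputs["placements"], sequences)
                references = io_mod.read_fasta(config.inputs["references"])
                contigs = build_contig_alignment(reads, references)
            state["contigs"] = contigs
            snps = call_contigs(contigs, config.caller)
            state["snps"] = snps
            ace_path = outdir / "contigs.ace"
            write_ace(contigs, ace_path)
            cons_path = outdir / "consensus.fasta"
            io_mod.write_fasta(
                ((c.contig_id, c.unpadded_consensus()) for c in contigs),
                cons_path)
            snp_path = outdir / "snps.tsv"
            io_mod.write_snp_table(snps, snp_path)
            logger.info("called %d candidate columns (%d passing)",
                        len(snps),
                        sum(1 for s in snps if s.status == "called"))
            return {"ace": str(ace_path), "consensus": str(cons_path),
                    "snps": str(snp_path)}
        runner.run("call", stage_call)

    if "classify" in stages:
        def stage_classify():
            snps = state.get("snps")
            if snps is None:
                snps = io_mod.read_snp_table(config.inputs["snps"])
                state["snps"] = snps
            order = list(config.simulation.genotype_ids)
            classify_candidates(snps, genotype_order=order)
            state["summary"] = summarize_catalog(snps)
            path = outdir / "snps_classified.tsv"
            io_mod.write_snp_table(snps, path)
            summary_path = outdir / "catalog_summary.tsv"
            state["summary"].to_frame().to_csv(
                summary_path, sep="\t", index=False)
            return {"snps_classified": str(path),
                    "catalog_summary": str(summary_path)}
        runner.run("classify", stage_classify)

    if "anchor" in stages:
        def stage_anchor():
            records = read_psl(config.inputs["psl"])
            anchors = compute_anchors(records, config.anchor)
            resolved = resolve_best_hits(
                anchors, policy=config.anchor.best_hit_policy)
            state["anchors"] = resolved
            anchors_path = outdir / "anchors.tsv"
            write_anchors(anchors, anchors_path)
            tally = tally_by_chromosome(resolved, state.get("snps"))
            state["chromosome_table"] = tally
            tally_path = outdir / "chromosome_tally.tsv"
            tally.to_csv(tally_path, sep="\t", index=False)
            return {"anchors": str(anchors_path), "tally": str(tally_path)}
        runner.run("anchor", stage_anchor)

    if "design" in stages:
        def stage_design():
            snps = state.get("snps")
            if snps is None:
                snps = io_mod.read_snp_table(config.inputs["snps"])
                state["snps"] = snps
            if "contigs" not in state and "ace" in config.inputs:
                sim = config.simulation
                state["contigs"] = read_ace(
                    config.inputs["ace"],
                    genotype_map=dict(zip(sim.genotype_prefixes,
                                          sim.genotype_ids)))
            contigs = {c.contig_id: c for c in state.get("contigs", [])}
            targets, rejections = select_assayable(
                snps, contigs, config.assay)
            state["targets"] = targets
            path = outdir / "assay_targets.tsv"
            write_assay_table(targets, rejections, path)
            logger.info("designed %d assays, rejected %d",
                        len(targets), len(rejections))
            return {"assay_targets": str(path)}
        runner.run("design", stage_design)

    if "report" in stages:
        def stage_report():
            dataset = state.get("dataset")
            contigs = state.get("contigs", [])
            evaluation = None
            read_lengths = None
            if dataset is not None:
                read_lengths = [len(r.sequence) for r in dataset.reads]
                if contigs and state.get("snps") is not None:
                    evaluation = evaluate_against_truth(
                        contigs, dataset.truth, state["snps"],
                        reads=dataset.reads,
                        min_reads=config.caller.min_reads_per_allele)
            text = format_report(
                read_lengths=read_lengths,
                contig_lengths=[len(c.unpadded_consensus())
                                for c in contigs] or None,
                summary=state.get("summary"),
                chromosome_table=state.get("chromosome_table"),
                evaluation=evaluation,
            )
            path = outdir / "report.txt"
            path.write_text(text)
            return {"report": str(path)}
        runner.run("report", stage_report)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(manifest.to_json() + "\n")
    return manifest
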