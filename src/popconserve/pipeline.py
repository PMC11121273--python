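"""End-to-end orchestration: input/simulate -> QC -> diversity -> ROH ->
relatedness -> NJ tree -> families, with TSV/Newick artifacts and a JSON
run report.

Every tabular artifact carries a commented provenance header (package
version, config hash, seed), so summary tables from different runs or
generations of a conservation herd can be diffed directly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .diversity import locus_stats, population_diversity
from .families import build_families
from .genotypes import GenotypeMatrix
from .io import read_plink_text, read_vcf, write_matrix_tsv
from .qc import QCConfig, QCError, apply_qc
from .relatedness import grm, ibs_distance, pca
from .roh import ROHParams, detect_roh_all, froh_all, roh_summaries, segments_frame
from .simulate import SimConfig, simulate_population
from .trees import nj_tree


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and artifacts written so far."""

    def __init__(self, stage: str, cause: Exception, manifest: list[str]):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.manifest = manifest


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Single configuration object for a full pipeline run.

    Exactly one of ``vcf`` / (``ped``, ``map``) / ``sim`` selects the
    genotype source. Omitted blocks take their documented defaults.
    """

    vcf: str | None = None
    ped: str | None = None
    map: str | None = None
    sim: SimConfig | None = None
    qc: QCConfig = field(default_factory=QCConfig)
    roh: ROHParams = field(default_factory=ROHParams)
    pn_threshold: float = 0.05
    family_threshold: float = 0.1
    pca_components: int = 2
    estimate_ne: bool = True
    outdir: str = "popconserve_out"
    seed: int = 0

    def validate(self) -> None:
        sources = sum([self.vcf is not None, self.ped is not None, self.sim is not None])
        if sources != 1:
            raise ConfigError(
                "exactly one genotype source (vcf / ped+map / sim) is required"
            )
        if self.ped is not None and self.map is None:
            raise ConfigError("PED input requires a MAP path")

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = SimConfig(**raw["sim"])
        if "qc" in raw and raw["qc"] is not None:
            raw["qc"] = QCConfig(**raw["qc"])
        if "roh" in raw and raw["roh"] is not None:
            raw["roh"] = ROHParams(**raw["roh"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        payload = _plain(dataclasses.asdict(self))
        payload.pop("outdir", None)
        blob = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _plain(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


@dataclass
class RunReport:
    """What a run produced: artifact paths plus headline numbers."""

    outdir: str
    provenance: dict[str, Any]
    qc_report: Any
    diversity: Any
    n_roh_segments: int
    mean_froh: float
    artifacts: dict[str, str]

    def to_json(self) -> str:
        # artifact paths are relative to outdir, so reports from runs
        # into different directories stay byte-comparable
        payload = {
            "provenance": self.provenance,
            "qc": dataclasses.asdict(self.qc_report),
            "diversity": dataclasses.asdict(self.diversity),
            "n_roh_segments": self.n_roh_segments,
            "mean_froh": self.mean_froh,
            "artifacts": self.artifacts,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def load_genotypes(cfg: RunConfig) -> GenotypeMatrix:
    if cfg.sim is not None:
        sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
        gm, _ = simulate_population(sim)
        return gm
    if cfg.vcf is not None:
        return read_vcf(cfg.vcf)
    return read_plink_text(cfg.ped, cfg.map)


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute every stage in order on the QC-passed matrix."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = [
        f"popconserve {__version__}",
        f"config_hash={cfg.config_hash()}",
        f"seed={cfg.seed}",
    ]
    manifest: list[str] = []

    def emit(name: str, df) -> str:
        path = outdir / name
        write_matrix_tsv(df.round(10), path, header)
        manifest.append(str(path))
        return name

    def stage(name: str, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, exc, manifest) from exc

    artifacts: dict[str, str] = {}

    gm = stage("input", lambda: load_genotypes(cfg))

    def _qc():
        retained, report = apply_qc(gm, cfg.qc)
        if retained.n_variants == 0:
            raise QCError("no SNPs survived quality control")
        artifacts["qc_report"] = emit("qc_report.tsv", report.to_frame())
        return retained, report

    clean, qc_report = stage("qc", _qc)

    def _diversity():
        per_locus = locus_stats(clean)
        summary = population_diversity(
            clean, pn_threshold=cfg.pn_threshold, estimate_ne=cfg.estimate_ne
        )
        artifacts["diversity_per_locus"] = emit("diversity_per_locus.tsv", per_locus)
        artifacts["diversity_summary"] = emit("diversity_summary.tsv", summary.to_frame())
        return summary

    diversity = stage("diversity", _diversity)

    def _roh():
        segments = detect_roh_all(clean, cfg.roh)
        artifacts["roh_segments"] = emit("roh_segments.tsv", segments_frame(segments))
        froh_table = froh_all(clean, cfg.roh, segments=segments)
        artifacts["froh"] = emit("froh.tsv", froh_table)
        summaries = roh_summaries(
            segments, sample_ids=clean.sample_ids, L_kb=cfg.roh.autosome_length_kb
        )
        artifacts["roh_length_bins"] = emit("roh_length_bins.tsv", summaries["length_bins"])
        artifacts["roh_per_chromosome"] = emit(
            "roh_per_chromosome.tsv", summaries["per_chromosome"]
        )
        return segments, float(froh_table["froh"].mean())

    segments, mean_froh = stage("roh", _roh)

    def _relate():
        g = grm(clean)
        ibs = ibs_distance(clean)
        pcs = pca(clean, k=min(cfg.pca_components, clean.n_samples - 1))
        artifacts["grm"] = emit("grm.tsv", g.to_frame().reset_index(names="sample_id"))
        artifacts["ibs"] = emit("ibs.tsv", ibs.to_frame().reset_index(names="sample_id"))
        artifacts["pca"] = emit("pca.tsv", pcs.to_frame())
        return g, ibs

    g, ibs = stage("relatedness", _relate)

    def _families():
        tree = nj_tree(ibs)
        tree_path = outdir / "nj_tree.nwk"
        with open(tree_path, "wt") as fh:
            fh.write(f"# {header[0]}; {header[1]}; arbitrary rooting at last join\n")
            fh.write(tree.to_newick() + "\n")
        manifest.append(str(tree_path))
        artifacts["nj_tree"] = tree_path.name
        males = clean.samples.loc[clean.samples["sex"] == "male", "id"].tolist()
        females = [s for s in clean.sample_ids if s not in set(males)]
        if males:
            fam = build_families(g, males, females, cfg.family_threshold)
            artifacts["families"] = emit("families.tsv", fam.to_frame())
        return None

    stage("trees_families", _families)

    report = RunReport(
        outdir=str(outdir),
        provenance={
            "version": __version__,
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
        },
        qc_report=qc_report,
        diversity=diversity,
        n_roh_segments=len(segments),
        mean_froh=mean_froh,
        artifacts=artifacts,
    )
    report_path = outdir / "run_report.json"
    report_path.write_text(report.to_json() + "\n")
    return report
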