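"""End-to-end orchestration: simulate -> filter -> SFS -> fit -> GOF.

A :class:`RunConfig` (single YAML file) fixes every input, the master seed
and the schedules; :func:`run_pipeline` executes the stages in order, writes
per-stage outputs plus a JSON manifest (inputs, seeds, config hash, output
checksums) and can resume: a stage whose outputs already exist under the same
config hash is skipped.  Every output embeds the master seed and config hash
in its header, so two runs differing only in seed differ only where
stochastic stages write.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import catalog, coalsim
from .fit import FitSchedule, ecm_fit, gof_residuals
from .models import DemographicModel, ModelError, TimeScale, load_model
from .sfs import FilterConfig, build_2d_msfs, filter_sites, read_vcf, write_sfs

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "filter", "sfs", "fit", "gof")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and a replayable command."""


@dataclass
class RunConfig:
    out_dir: str
    model: str | None = None  # YAML model path; None -> bundled e1
    vcf: str | None = None  # observed VCF; None -> simulate stage makes one
    popmap: str | None = None  # required with vcf
    n_sites: int = 5_000
    seed: int = 1
    generation_time_years: float = 5.0
    filter: dict = field(default_factory=dict)
    schedule: dict = field(default_factory=lambda: {"n_starts": 2, "n_cycles": 4, "n_sims": 2000})
    free_params: list[str] | None = None
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ModelError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.vcf is not None:
            if not Path(self.vcf).exists():
                raise ModelError(f"vcf not found: {self.vcf}")
            if self.popmap is None:
                raise ModelError("a popmap is required when a VCF is supplied")
            if not Path(self.popmap).exists():
                raise ModelError(f"popmap not found: {self.popmap}")
        if self.model is not None and not Path(self.model).exists():
            raise ModelError(f"model spec not found: {self.model}")
        FilterConfig(**self.filter)
        FitSchedule(seed=self.seed, **self.schedule)
        TimeScale(self.generation_time_years)

    def config_hash(self) -> str:
        # where outputs land does not change what is computed
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        d.pop("verbosity")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def load_demographic_model(self) -> DemographicModel:
        return load_model(self.model) if self.model else catalog.model_e1()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.verbosity.upper(), logging.INFO))

    chash = cfg.config_hash()
    manifest_path = out / "manifest.json"
    manifest = {"seed": cfg.seed, "config_hash": chash, "stages": {}}
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == chash:
            manifest = old

    model = cfg.load_demographic_model()
    header = [f"seed={cfg.seed}", f"config_hash={chash}"]
    state: dict = {}

    def done(stage: str) -> bool:
        info = manifest["stages"].get(stage)
        if not info:
            return False
        return all(Path(p).exists() and _sha256(Path(p)) == h
                   for p, h in info["outputs"].items())

    def record(stage: str, outputs: list[Path]) -> None:
        manifest["stages"][stage] = {
            "outputs": {str(p): _sha256(p) for p in outputs},
            "seed": cfg.seed,
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))

    def run_stage(stage: str, fn) -> None:
        if done(stage):
            logger.info("stage %s: up to date, skipping", stage)
            return
        try:
            outputs = fn()
        except Exception as exc:
            raise PipelineError(
                f"stage {stage!r} failed: {exc}\n"
                f"replay: demosfs run-all --config <config> --only {stage}"
            ) from exc
        record(stage, outputs)

    # -- simulate ---------------------------------------------------------
    def stage_simulate() -> list[Path]:
        vcf_path = out / "data.vcf"
        popmap_path = out / "popmap.tsv"
        if cfg.vcf is not None:
            state["vcf"], state["popmap"] = Path(cfg.vcf), Path(cfg.popmap)
            return []
        g = coalsim.simulate_genotypes(model, cfg.n_sites, seed=cfg.seed)
        coalsim.write_vcf(g, vcf_path, extra_header=[f"##demosfs_{h}" for h in header])
        coalsim.write_popmap(g, popmap_path)
        state["vcf"], state["popmap"] = vcf_path, popmap_path
        return [vcf_path, popmap_path]

    run_stage("simulate", stage_simulate)
    state.setdefault("vcf", Path(cfg.vcf) if cfg.vcf else out / "data.vcf")
    state.setdefault("popmap", Path(cfg.popmap) if cfg.popmap else out / "popmap.tsv")

    # -- filter -----------------------------------------------------------
    def stage_filter() -> list[Path]:
        g = read_vcf(state["vcf"], str(state["popmap"]))
        kept = filter_sites(g, FilterConfig(**cfg.filter))
        path = out / "filtered.vcf"
        coalsim.write_vcf(kept, path, extra_header=[f"##demosfs_{h}" for h in header])
        logger.info("filter: %d of %d sites kept", kept.n_sites, g.n_sites)
        return [path]

    run_stage("filter", stage_filter)

    # -- sfs --------------------------------------------------------------
    def stage_sfs() -> list[Path]:
        g = read_vcf(out / "filtered.vcf", str(state["popmap"]))
        names = model.pop_names
        outputs = []
        state["obs"] = {}
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                s = build_2d_msfs(g, a, b, seed=cfg.seed)
                path = out / f"sfs_{a}_{b}.tsv"
                write_sfs(s, path, extra_comments=header)
                state["obs"][(a, b)] = s
                outputs.append(path)
        return outputs

    run_stage("sfs", stage_sfs)
    if "obs" not in state:
        from .sfs import read_sfs

        names = model.pop_names
        state["obs"] = {}
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                state["obs"][(a, b)] = read_sfs(out / f"sfs_{a}_{b}.tsv")

    # -- fit --------------------------------------------------------------
    def stage_fit() -> list[Path]:
        m = model if cfg.free_params is None else model.restrict(cfg.free_params)
        sched = FitSchedule(seed=cfg.seed, **cfg.schedule)
        fit = ecm_fit(m, state["obs"], sched)
        state["fit"] = fit
        path = out / "fit.json"
        payload = {"seed": cfg.seed, "config_hash": chash, **fit.to_dict()}
        path.write_text(json.dumps(payload, indent=2))
        return [path]

    run_stage("fit", stage_fit)
    if "fit" not in state:
        from .fit import FitResult

        d = json.loads((out / "fit.json").read_text())
        state["fit"] = FitResult.make(
            d["model_id"], d["params"], d["lnL"], d["k"], d["trace"], d["converged"]
        )

    # -- gof --------------------------------------------------------------
    def stage_gof() -> list[Path]:
        fitted = model.with_params(
            {k: v for k, v in state["fit"].params.items()}
        )
        sched = FitSchedule(seed=cfg.seed, **cfg.schedule)
        exp = coalsim.expected_sfs_pairs(
            fitted, list(state["obs"]), n_sims=sched.n_sims, seed=cfg.seed
        )
        path = out / "gof.tsv"
        with open(path, "w") as fh:
            for h in header:
                fh.write(f"# {h}\n")
            fh.write("pairA\tpairB\trss\tn_sites\n")
            for pair, obs in state["obs"].items():
                _, rss = gof_residuals(obs, exp[pair])
                fh.write(f"{pair[0]}\t{pair[1]}\t{rss:.6g}\t{obs.total:g}\n")
        return [path]

    run_stage("gof", stage_gof)

    manifest["n_stages"] = len(STAGES)
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
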