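"""File-driven pipeline: simulate -> uhi -> policy -> hcdi -> gravity ->
network -> validate.

Each stage reads the tidy-CSV/JSON artifacts of its upstream stages from
the output directory and writes its own, so stages can be rerun
individually; a manifest records the config hash, seed and package
version. Reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .gravity import GravityParams, GravityTensor, compute_gravity_study, sensitivity_profile
from .hcdi import ahp_weights, build_hcdi_panel, compute_hcdi, default_judgment_matrix
from .indices import (compute_uhi, entropy_weights, standardize_panel,
                      uniform_weights)
from .network import (ClassifierThresholds, build_network, classify_structure)
from .policy import PolicyCorpus, aggregate_policy_intensity
from .synthetic import (AgglomerationSpec, StudyAreaSpec, SyntheticStudyArea,
                        generate_study_area, plant_structure, read_matrix,
                        read_panel, write_study_area)

log = logging.getLogger("healthnet")

STAGES = ("simulate", "uhi", "policy", "hcdi", "gravity", "network", "validate")


class PipelineError(RuntimeError):
    """A stage could not run; the message names the stage."""


@dataclass
class PipelineConfig:
    spec: StudyAreaSpec = field(default_factory=StudyAreaSpec)
    params: GravityParams = field(default_factory=GravityParams)
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    weighting: str = "entropy"          # entropy | uniform
    scope: str = "pooled"               # standardization scope
    archetype: str | None = None        # plant this archetype instead of generic
    out_dir: Path = Path("healthnet_out")
    seed: int | None = None             # overrides spec.seed when set
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.seed is not None:
            self.spec = dataclasses.replace(self.spec, seed=int(self.seed))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["spec"]["policy_pulse_years"] = sorted(self.spec.policy_pulse_years)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        spec_raw = dict(raw.get("spec", {}))
        if "agglomerations" in spec_raw:
            spec_raw["agglomerations"] = tuple(
                AgglomerationSpec(**a) for a in spec_raw["agglomerations"])
        if "years" in spec_raw:
            spec_raw["years"] = tuple(spec_raw["years"])
        if "policy_pulse_years" in spec_raw:
            spec_raw["policy_pulse_years"] = frozenset(spec_raw["policy_pulse_years"])
        return cls(
            spec=StudyAreaSpec(**spec_raw),
            params=GravityParams(**raw.get("gravity", {})),
            thresholds=ClassifierThresholds(**raw.get("network", {})),
            weighting=raw.get("weighting", "entropy"),
            scope=raw.get("scope", "pooled"),
            archetype=raw.get("archetype"),
            out_dir=Path(raw.get("out_dir", "healthnet_out")),
            seed=raw.get("seed"),
            log_level=raw.get("log_level", "INFO"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _require(path: Path, stage: str, upstream: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"stage '{stage}' requires artifact '{path.name}'; "
            f"run stage '{upstream}' first")
    return path


def _aggl_names(cfg: PipelineConfig) -> list[str]:
    return [a.name for a in cfg.spec.agglomerations]


def _load_study(cfg: PipelineConfig, stage: str) -> SyntheticStudyArea:
    out = cfg.out_dir
    panel = read_panel(_require(out / "panel.csv", stage, "simulate"))
    distances = {a: read_matrix(_require(out / f"distances_{a}.csv", stage, "simulate"))
                 for a in _aggl_names(cfg)}
    times = {a: read_matrix(_require(out / f"travel_times_{a}.csv", stage, "simulate"))
             for a in _aggl_names(cfg)}
    policies = PolicyCorpus.from_csv(_require(out / "policies.csv", stage, "simulate"))
    truth = json.loads(_require(out / "truth.json", stage, "simulate").read_text())
    ref_long = pd.read_csv(_require(out / "reference_gravity.csv", stage, "simulate"))
    reference = {
        a: GravityTensor.from_long_frame(g.drop(columns=["agglomeration"]))
        for a, g in ref_long.groupby("agglomeration")
    }
    return SyntheticStudyArea(spec=cfg.spec, panel=panel, distances=distances,
                              travel_times=times, policies=policies,
                              truth=truth, reference_gravity=reference)


def _weights(cfg: PipelineConfig, std_panel):
    if cfg.weighting == "entropy":
        return entropy_weights(std_panel)
    if cfg.weighting == "uniform":
        return uniform_weights(std_panel.indicators)
    raise PipelineError(f"stage 'uhi': unknown weighting method {cfg.weighting!r}")


# --------------------------------------------------------------------------
# stages

def stage_simulate(cfg: PipelineConfig) -> None:
    if cfg.archetype:
        study = plant_structure(cfg.spec, cfg.archetype, cfg.params)
    else:
        study = generate_study_area(cfg.spec, cfg.params)
    write_study_area(study, cfg.out_dir)
    log.info("simulate: %d cities, %d years", study.spec.n_cities_total,
             len(study.spec.year_list))


def stage_uhi(cfg: PipelineConfig) -> None:
    panel = read_panel(_require(cfg.out_dir / "panel.csv", "uhi", "simulate"))
    std = standardize_panel(panel, scope=cfg.scope)
    weights = _weights(cfg, std)
    uhi = compute_uhi(std, weights)
    uhi.reset_index().to_csv(cfg.out_dir / "uhi.csv", index=False)
    (cfg.out_dir / "uhi_weights.json").write_text(json.dumps(
        {"method": weights.method, "weights": weights.weights.round(12).to_dict()},
        indent=2, sort_keys=True))


def stage_policy(cfg: PipelineConfig) -> None:
    panel = read_panel(_require(cfg.out_dir / "panel.csv", "policy", "simulate"))
    corpus = PolicyCorpus.from_csv(
        _require(cfg.out_dir / "policies.csv", "policy", "simulate"))
    intensity = aggregate_policy_intensity(corpus, panel.cities, panel.years)
    tidy = intensity.stack().rename("policy_intensity").reset_index()
    tidy.to_csv(cfg.out_dir / "policy_intensity.csv", index=False)


def stage_hcdi(cfg: PipelineConfig) -> None:
    out = cfg.out_dir
    panel = read_panel(_require(out / "panel.csv", "hcdi", "simulate"))
    distances = {a: read_matrix(_require(out / f"distances_{a}.csv", "hcdi", "simulate"))
                 for a in _aggl_names(cfg)}
    times = {a: read_matrix(_require(out / f"travel_times_{a}.csv", "hcdi", "simulate"))
             for a in _aggl_names(cfg)}
    tidy = pd.read_csv(_require(out / "policy_intensity.csv", "hcdi", "policy"))
    intensity = tidy.pivot(index="city", columns="year", values="policy_intensity")
    hcdi_panel = build_hcdi_panel(panel, distances, times, intensity)
    std = standardize_panel(hcdi_panel, scope=cfg.scope)
    ahp = ahp_weights(default_judgment_matrix())
    hcdi = compute_hcdi(std, ahp)
    hcdi.reset_index().to_csv(out / "hcdi.csv", index=False)
    (out / "ahp.json").write_text(json.dumps({
        "weights": ahp.weights.weights.round(12).to_dict(),
        "lambda_max": ahp.lambda_max,
        "consistency_index": ahp.consistency_index,
        "consistency_ratio": ahp.consistency_ratio,
    }, indent=2, sort_keys=True))


def stage_gravity(cfg: PipelineConfig) -> None:
    out = cfg.out_dir
    uhi_frame = pd.read_csv(_require(out / "uhi.csv", "gravity", "uhi"))
    uhi = uhi_frame.set_index(["city", "year"])["uhi"]
    panel = read_panel(_require(out / "panel.csv", "gravity", "simulate"))
    distances = {a: read_matrix(_require(out / f"distances_{a}.csv", "gravity", "simulate"))
                 for a in _aggl_names(cfg)}
    times = {a: read_matrix(_require(out / f"travel_times_{a}.csv", "gravity", "simulate"))
             for a in _aggl_names(cfg)}
    tensors = compute_gravity_study(uhi, panel.membership, distances, times, cfg.params)
    for aggl, tensor in tensors.items():
        tensor.to_long_frame().to_csv(out / f"gravity_{aggl}.csv", index=False)


def stage_network(cfg: PipelineConfig) -> None:
    out = cfg.out_dir
    uhi_frame = pd.read_csv(_require(out / "uhi.csv", "network", "uhi"))
    uhi = uhi_frame.set_index(["city", "year"])["uhi"]
    last_year = int(uhi_frame["year"].max())
    for aggl in _aggl_names(cfg):
        long = pd.read_csv(
            _require(out / f"gravity_{aggl}.csv", "network", "gravity"))
        tensor = GravityTensor.from_long_frame(long)
        net = build_network(tensor, tau=cfg.thresholds.tau)
        uhi_last = uhi.xs(last_year, level="year").reindex(net.cities)
        net.structure_label = classify_structure(net, uhi_last, cfg.thresholds)
        net.r.to_csv(out / f"r_{aggl}.csv")
        report = {
            "agglomeration": aggl,
            "structure_label": net.structure_label,
            "centralization": net.centralization,
            "degree_centrality": net.degree_centrality.round(12).to_dict(),
            "tau": cfg.thresholds.tau,
        }
        (out / f"network_{aggl}.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))


def stage_validate(cfg: PipelineConfig) -> None:
    from .validation import loocv  # local import to avoid a cycle at import time

    study = _load_study(cfg, "validate")
    report = loocv(study, T=cfg.params.T)
    report.sensitivity = sensitivity_profile(study, cfg.params)
    report.to_json(cfg.out_dir / "validation.json")
    log.info("validate: worst rmse %.4f, worst r2 %.4f",
             report.worst_rmse, report.worst_r2)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "uhi": stage_uhi,
    "policy": stage_policy,
    "hcdi": stage_hcdi,
    "gravity": stage_gravity,
    "network": stage_network,
    "validate": stage_validate,
}


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] = STAGES) -> None:
    """Run the requested stages in canonical order and write the manifest."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    cfg.spec.validate()
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages {sorted(unknown)}")
    for stage in STAGES:
        if stage in stages:
            log.info("running stage %s", stage)
            _STAGE_FUNCS[stage](cfg)
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.spec.seed,
        "version": __version__,
        "stages": [s for s in STAGES if s in stages],
        "artifacts": sorted(p.name for p in cfg.out_dir.iterdir()
                            if p.is_file() and p.name != "manifest.json"),
    }
    (cfg.out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))
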