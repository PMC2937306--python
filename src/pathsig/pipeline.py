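"""End-to-end pipeline: simulate -> zero-transform -> filter -> fit ->
project -> stratify, driven by a single declarative YAML config.

The config has one block per stage plus a global seed and output directory;
unknown keys anywhere are rejected.  All stage randomness derives from the
global seed through numpy's ``SeedSequence`` spawning, so a rerun with the
same config reproduces every numeric output bit-identically.  Each run
writes the resolved config next to its outputs and a JSON ``RunReport``
with per-stage parameters, output digests, counts and wall time.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as psio
from .errors import ConfigurationError
from .preprocess import filter_fold_change, zero_transform
from .projection import project_signature
from .signature import SignaturePrior, fit_signature
from .simulate import (
    CohortConfig,
    InVitroConfig,
    config_from_dict,
    simulate_cohort,
    simulate_invitro,
    simulate_survival,
)
from .survival import optimal_stratify

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "load_config",
           "demo_config"]

_STAGE_KEYS = {
    "seed", "out_dir", "log_level",
    "invitro", "filter", "signature", "cohort", "survival", "stratify",
}


@dataclass
class PipelineConfig:
    """Resolved configuration of a full pipeline run."""

    seed: int = 0
    out_dir: str = "pathsig_run"
    log_level: str = "INFO"
    invitro: dict = field(default_factory=dict)
    filter: dict = field(default_factory=lambda: {"fold": 2.0, "min_obs": 2})
    signature: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    survival: dict = field(
        default_factory=lambda: {
            "log_hr": -1.0, "base_rate": 0.1, "censor_rate": 0.02,
        }
    )
    stratify: dict = field(default_factory=lambda: {"min_group_frac": 0.1})

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _STAGE_KEYS
        if unknown:
            raise ConfigurationError(
                f"unknown config key(s): {', '.join(sorted(unknown))}"
            )
        cfg = cls(**{k: v for k, v in raw.items() if k in _STAGE_KEYS})
        # validate stage blocks eagerly so errors name the offending field
        config_from_dict(InVitroConfig, {**cfg.invitro, "seed": 0})
        config_from_dict(CohortConfig, {**cfg.cohort, "seed": 0})
        known_filter = {"fold", "min_obs"}
        if set(cfg.filter) - known_filter:
            raise ConfigurationError(
                "unknown filter key(s): "
                f"{', '.join(sorted(set(cfg.filter) - known_filter))}"
            )
        known_surv = {"log_hr", "base_rate", "censor_rate"}
        if set(cfg.survival) - known_surv:
            raise ConfigurationError(
                "unknown survival key(s): "
                f"{', '.join(sorted(set(cfg.survival) - known_surv))}"
            )
        known_strat = {"min_group_frac"}
        if set(cfg.stratify) - known_strat:
            raise ConfigurationError(
                "unknown stratify key(s): "
                f"{', '.join(sorted(set(cfg.stratify) - known_strat))}"
            )
        SignaturePrior(**cfg.signature)
        return cfg


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return PipelineConfig.from_dict(raw)


def demo_config() -> PipelineConfig:
    """The small bundled demo configuration (runs in seconds)."""
    raw = yaml.safe_load(
        resources.files("pathsig").joinpath("data/demo.yaml").read_text()
    )
    return PipelineConfig.from_dict(raw)


@dataclass
class RunReport:
    """Per-stage record of a pipeline run: parameters, outputs, counts."""

    seed: int
    stages: dict = field(default_factory=dict)
    wall_time_s: float = 0.0

    def to_dict(self) -> dict:
        return {"seed": self.seed, "wall_time_s": self.wall_time_s,
                "stages": self.stages}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _child_seeds(seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def run_pipeline(config: PipelineConfig, out_dir=None) -> RunReport:
    """Execute all configured stages in dependency order.

    Writes every artifact (expression, annotation, truth, log2 ratios,
    retained probes, signature, cohort, activity, scores, survival table,
    stratification) plus the resolved config and the run report into
    ``out_dir``.
    """
    t0 = _time.perf_counter()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    seeds = _child_seeds(config.seed, 3)

    def record(stage: str, params: dict, outputs: list[Path], **counts):
        report.stages[stage] = {
            "params": params,
            "outputs": {p.name: _digest(p) for p in outputs},
            **counts,
        }

    # 1. in-vitro simulation
    iv_cfg = config_from_dict(
        InVitroConfig, {**config.invitro, "seed": seeds[0]}
    )
    expr, annot, truth = simulate_invitro(iv_cfg)
    p_expr = psio.write_expression(expr, out / "expression.tsv")
    p_annot = psio.write_annotation(annot, out / "annotation.tsv")
    truth_path = out / "truth.tsv"
    truth.to_csv(truth_path, sep="\t")
    record("invitro", asdict(iv_cfg), [p_expr, p_annot, truth_path],
           n_probes=int(expr.shape[0]), n_samples=int(expr.shape[1]))

    # 2. zero-transformation and fold-change filter
    ztm = zero_transform(expr, annot, match_time=True)
    p_ztm = psio.write_expression(ztm, out / "log2_ratios.tsv")
    fold = float(config.filter.get("fold", 2.0))
    min_obs = int(config.filter.get("min_obs", 2))
    retained = filter_fold_change(ztm, fold=fold, min_obs=min_obs)
    p_ret = out / "filtered_probes.txt"
    p_ret.write_text("\n".join(map(str, retained)) + "\n")
    record("filter", {"fold": fold, "min_obs": min_obs}, [p_ztm, p_ret],
           n_retained=int(len(retained)))

    # 3. signature estimation
    prior = SignaturePrior(**config.signature)
    model = fit_signature(expr, annot, treatment=iv_cfg.treatment_label,
                          prior=prior)
    p_sig = psio.write_signature(model, out / "signature.tsv")
    record("signature", vars(prior), [p_sig], n_probes=len(model))

    # 4. cohort simulation and projection
    co_cfg = config_from_dict(CohortConfig, {**config.cohort, "seed": seeds[1]})
    cohort, activity = simulate_cohort(model, co_cfg)
    p_cohort = psio.write_expression(cohort, out / "cohort.tsv")
    p_act = out / "activity.tsv"
    activity.rename_axis("sample_id").to_csv(p_act, sep="\t")
    sv = project_signature(model, cohort, center=True)
    p_scores = psio.write_scores(sv, out / "scores.tsv")
    record("projection", {"center": True, "weight": sv.weight},
           [p_cohort, p_act, p_scores],
           n_probes_used=len(sv.probes_used), n_dropped=sv.n_dropped)

    # 5. survival simulation and optimal stratification
    surv_tab = simulate_survival(
        activity,
        log_hr=float(config.survival.get("log_hr", -1.0)),
        base_rate=float(config.survival.get("base_rate", 0.1)),
        censor_rate=float(config.survival.get("censor_rate", 0.02)),
        seed=seeds[2],
    )
    p_surv = psio.write_survival(surv_tab, out / "survival.csv")
    strat = optimal_stratify(
        sv, surv_tab,
        min_group_frac=float(config.stratify.get("min_group_frac", 0.1)),
    )
    p_strat = out / "stratification.json"
    p_strat.write_text(json.dumps(strat.to_dict(), indent=1))
    record("stratify", dict(config.stratify), [p_surv, p_strat],
           n_samples=len(surv_tab),
           n_events=int(surv_tab["event"].sum()),
           threshold=strat.threshold,
           area_between_curves=strat.area,
           cox_group_p=strat.cox_group.p,
           cox_score_p=strat.cox_score.p)

    # resolved config + report
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(config)))
    report.wall_time_s = _time.perf_counter() - t0
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
    return report
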