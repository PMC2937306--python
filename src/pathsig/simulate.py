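"""Synthetic data with the statistical structure the analysis assumes.

Three generators cover the three kinds of input the pipeline consumes:

``simulate_invitro``
    A two-arm (control vs. treatment) log2-expression experiment with
    replicates at several time points, a sparse set of truly differential
    probes, and per-probe residual variances.  This is the testbed for
    zero-transformation, fold-change filtering and signature estimation.

``simulate_cohort``
    A tumor cohort whose expression embeds a latent per-sample pathway
    activity through a given signature: ``x[g, i] = m[g] + a[i] * pi[g] *
    beta[g] + eps[g, i]``.  The latent activity is returned so projection
    accuracy can be measured.

``simulate_survival``
    Right-censored exponential survival times whose log-hazard is linear in
    the latent activity — the proportional-hazards world the Cox model and
    the Kaplan-Meier stratification assume.

All randomness flows from a single integer seed per config; identical
configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "InVitroConfig",
    "CohortConfig",
    "simulate_invitro",
    "simulate_cohort",
    "simulate_survival",
]


@dataclass(frozen=True)
class InVitroConfig:
    """Design of a synthetic two-arm expression experiment.

    Parameters
    ----------
    n_probes:
        Number of probes (rows).
    n_reps:
        Replicates per arm per time point (the emulated design uses
        triplicates).
    time_points:
        Labels of the sampling times; one control and one treatment group of
        ``n_reps`` arrays is generated per label.
    frac_de:
        Fraction of probes with a true treatment effect, in [0, 1].
    effect_scale:
        Magnitude scale of true log2 effects; ``|beta|`` is drawn uniformly
        from ``[0.5 * effect_scale, effect_scale]`` with random sign.
    noise_scale:
        Scale of the residual standard deviation.  Per-probe variances are
        scaled inverse-chi-square with scale ``noise_scale**2`` and
        ``var_df`` degrees of freedom, giving the variance heterogeneity the
        per-probe weights downstream rely on.
    baseline_mean, baseline_sd:
        Normal distribution of per-probe baseline log2 means (the typical
        post-normalization range).
    var_df:
        Degrees of freedom of the inverse-chi-square variance distribution.
    treatment_label:
        Arm label for treated samples; controls are always ``"control"``.
    seed:
        Integer seed; identical seeds give bit-identical outputs.
    """

    n_probes: int = 2000
    n_reps: int = 3
    time_points: tuple[str, ...] = ("1h", "4h", "12h", "24h")
    frac_de: float = 0.1
    effect_scale: float = 2.0
    noise_scale: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    var_df: float = 8.0
    treatment_label: str = "treated"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ConfigurationError(f"n_probes must be >= 1, got {self.n_probes}")
        if self.n_reps < 1:
            raise ConfigurationError(f"n_reps must be >= 1, got {self.n_reps}")
        if len(self.time_points) < 1:
            raise ConfigurationError("time_points must be non-empty")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ConfigurationError(f"frac_de must be in [0, 1], got {self.frac_de}")
        if self.noise_scale <= 0:
            raise ConfigurationError(
                f"noise_scale must be > 0, got {self.noise_scale}"
            )
        if self.effect_scale < 0:
            raise ConfigurationError(
                f"effect_scale must be >= 0, got {self.effect_scale}"
            )
        if self.var_df <= 2:
            raise ConfigurationError(f"var_df must be > 2, got {self.var_df}")


@dataclass(frozen=True)
class CohortConfig:
    """Design of a synthetic tumor cohort with latent pathway activity."""

    n_tumors: int = 100
    activity_sd: float = 1.0
    noise_scale: float = 0.3
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumors < 2:
            raise ConfigurationError(f"n_tumors must be >= 2, got {self.n_tumors}")
        if self.activity_sd < 0:
            raise ConfigurationError(
                f"activity_sd must be >= 0, got {self.activity_sd}"
            )
        if self.noise_scale <= 0:
            raise ConfigurationError(
                f"noise_scale must be > 0, got {self.noise_scale}"
            )


def config_from_dict(cls, mapping: dict):
    """Build a config dataclass from a dict, rejecting unknown keys."""
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigurationError(
            f"unknown {cls.__name__} field(s): {', '.join(sorted(unknown))}"
        )
    kwargs = dict(mapping)
    if "time_points" in kwargs and isinstance(kwargs["time_points"], list):
        kwargs["time_points"] = tuple(str(t) for t in kwargs["time_points"])
    return cls(**kwargs)


def _draw_truth(config: InVitroConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_probes
    probe_ids = [f"P{i:06d}" for i in range(n)]
    n_de = int(round(config.frac_de * n))
    is_de = np.zeros(n, dtype=bool)
    if n_de > 0:
        de_idx = rng.choice(n, size=n_de, replace=False)
        is_de[de_idx] = True
    sign = rng.choice([-1.0, 1.0], size=n)
    magnitude = rng.uniform(0.5 * config.effect_scale, config.effect_scale, size=n)
    true_beta = np.where(is_de, sign * magnitude, 0.0)
    # scaled inverse-chi-square: sigma2 = df * s2 / chisq(df)
    chi = rng.chisquare(config.var_df, size=n)
    true_sigma2 = config.var_df * config.noise_scale**2 / chi
    return pd.DataFrame(
        {"is_de": is_de, "true_beta": true_beta, "true_sigma2": true_sigma2},
        index=pd.Index(probe_ids, name="probe_id"),
    )


def simulate_invitro(
    config: InVitroConfig, truth: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a two-arm log2 expression experiment.

    Parameters
    ----------
    config:
        Experiment design; see :class:`InVitroConfig`.
    truth:
        Optional pre-built truth table (columns ``is_de``, ``true_beta``,
        ``true_sigma2``) to reuse across runs, e.g. to generate two noisy
        replicate experiments of the same underlying response, or two
        treatments with opposite effects.  Must have ``n_probes`` rows.

    Returns
    -------
    (expression, annotation, truth):
        ``expression`` is a probes x samples DataFrame of log2 values;
        ``annotation`` is indexed by sample with columns ``arm``,
        ``time_point``, ``replicate``; ``truth`` records per-probe ground
        truth for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    if truth is None:
        truth = _draw_truth(config, rng)
    else:
        _draw_truth(config, rng)  # keep the noise stream aligned regardless
        required = {"is_de", "true_beta", "true_sigma2"}
        if not required.issubset(truth.columns):
            raise ConfigurationError(
                f"truth table must have columns {sorted(required)}"
            )
        if len(truth) != config.n_probes:
            raise ConfigurationError(
                f"truth table has {len(truth)} rows, config.n_probes is "
                f"{config.n_probes}"
            )

    n = config.n_probes
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)

    sample_ids: list[str] = []
    arms: list[str] = []
    tps: list[str] = []
    reps: list[int] = []
    for tp in config.time_points:
        for arm in ("control", config.treatment_label):
            for r in range(1, config.n_reps + 1):
                sample_ids.append(f"{arm}_{tp}_r{r}")
                arms.append(arm)
                tps.append(str(tp))
                reps.append(r)
    n_samples = len(sample_ids)

    treated = np.array([a != "control" for a in arms])
    sigma = np.sqrt(truth["true_sigma2"].to_numpy())
    values = (
        baseline[:, None]
        + np.outer(truth["true_beta"].to_numpy(), treated.astype(float))
        + rng.standard_normal((n, n_samples)) * sigma[:, None]
    )

    expr = pd.DataFrame(values, index=truth.index.copy(), columns=sample_ids)
    annot = pd.DataFrame(
        {"arm": arms, "time_point": tps, "replicate": reps},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return expr, annot, truth


def simulate_cohort(model, config: CohortConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a cohort whose expression embeds a latent pathway activity.

    For each signature probe g and tumor i,
    ``x[g, i] = m[g] + a[i] * pi[g] * beta[g] + eps[g, i]`` with
    ``a[i] ~ N(0, activity_sd^2)`` and ``eps ~ N(0, noise_scale^2)``.

    Returns the expression matrix and the latent activity vector ``a``.
    """
    if len(model) == 0:
        raise ConfigurationError("signature model is empty")
    rng = np.random.default_rng(config.seed)
    probes = model.table.index
    n_g = len(probes)
    sample_ids = [f"T{i:04d}" for i in range(config.n_tumors)]
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_g)
    activity = rng.normal(0.0, config.activity_sd, size=config.n_tumors)
    signal = model.table["pi"].to_numpy() * model.table["beta"].to_numpy()
    values = (
        baseline[:, None]
        + np.outer(signal, activity)
        + rng.standard_normal((n_g, config.n_tumors)) * config.noise_scale
    )
    expr = pd.DataFrame(values, index=probes.copy(), columns=sample_ids)
    return expr, pd.Series(activity, index=sample_ids, name="activity")


def simulate_survival(
    activity: pd.Series,
    log_hr: float,
    base_rate: float = 0.1,
    censor_rate: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate right-censored survival linked to a latent activity.

    Event times are exponential with per-sample rate
    ``base_rate * exp(log_hr * a[i])``; censoring times are exponential with
    rate ``censor_rate`` (``0`` disables censoring).  The observed time is
    the minimum, the event flag indicates the event preceded censoring.
    """
    if base_rate <= 0:
        raise ConfigurationError(f"base_rate must be > 0, got {base_rate}")
    if censor_rate < 0:
        raise ConfigurationError(f"censor_rate must be >= 0, got {censor_rate}")
    activity = pd.Series(activity)
    rng = np.random.default_rng(seed)
    rates = base_rate * np.exp(log_hr * activity.to_numpy(dtype=float))
    event_times = rng.exponential(1.0 / rates)
    if censor_rate > 0:
        censor_times = rng.exponential(1.0 / censor_rate, size=len(activity))
    else:
        censor_times = np.full(len(activity), np.inf)
    time = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)
    return pd.DataFrame(
        {"time": time, "event": event},
        index=pd.Index(activity.index, name="sample_id"),
    )
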