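"""Synthetic probe-level miRNA microarray cohorts.

Emulates a Geniom-style biochip in which every array carries 904 miRNA /
miRNA-star probes, each printed in 7 replicate spots.  The generative model
works on the glog (arsinh) scale, where the downstream variance-stabilised
analysis lives:

    g[p, s] = baseline[p] + effect[p] * 1{s is case}
              + bio[p, s] + array_offset[s]            (per-sample abundance)
    g_spot[p, k, s] = g[p, s] + spot_noise[p, k, s]    (per replicate spot)
    raw[p, k, s]    = sinh(g_spot[p, k, s]) + background[p, k, s]

so that after background subtraction, median summarisation over the 7 spots
and arsinh-based normalisation, a planted ``effect`` reappears as a shift of
that size in the feature space seen by the t-test and the classifier.

Two published replicate statistics pin the default noise level: biological
replicate profiles should show a Pearson correlation of about 0.85 and a
between-replicate variance of about 0.005 after preprocessing.  Under the
model above both statistics depend on the noise standard deviations only
through v = bio_sd**2 + c * spot_sd**2 (c = variance factor of the median of
the replicate spots), while the correlation additionally fixes the
across-probe baseline spread tau through rho = tau**2 / (tau**2 + v).  The
defaults below are the calibrated solution of that system; see
:func:`calibrate_noise`.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import CalibrationError, ConfigurationError

__all__ = [
    "ProbeRecord",
    "ProbeSet",
    "GeneratorConfig",
    "SampleSpec",
    "RawArraySet",
    "make_probe_set",
    "simulate_cohort",
    "simulate_from_config",
    "simulate_replicate_pair",
    "replicate_statistics",
    "calibrate_noise",
    "baseline_sd_for_targets",
    "NoiseCalibration",
]

# Replicate-quality targets of the emulated platform.
TARGET_REPLICATE_CORR = 0.85
TARGET_REPLICATE_VAR = 0.005

DEFAULT_N_PROBES = 904
DEFAULT_N_SPOTS = 7

# Across-probe baseline spread implied by the replicate targets:
# tau = sqrt(v * rho / (1 - rho)).
DEFAULT_BASELINE_GLOG_MEAN = 6.5
DEFAULT_BASELINE_GLOG_SD = math.sqrt(
    TARGET_REPLICATE_VAR * TARGET_REPLICATE_CORR / (1.0 - TARGET_REPLICATE_CORR)
)

# Calibrated noise defaults (50/50 split of the replicate variance between
# the biological and the median-summarised spot component; see
# calibrate_noise and docs/methods.md).
DEFAULT_BIO_NOISE_SD = 0.05
DEFAULT_SPOT_NOISE_SD = 0.1089

# Histological subtype frequencies among cases (21 serous, 2 endometrioid,
# 1 solid in a 24-patient cohort).
CASE_SUBTYPES = ("serous", "endometrioid", "solid")
CASE_SUBTYPE_PROBS = (21 / 24, 2 / 24, 1 / 24)

CASE_LABEL = "case"
CONTROL_LABEL = "control"


@dataclass(frozen=True)
class ProbeRecord:
    """One probe of the array: identity, planted effect and baseline."""

    probe_id: str
    is_star: bool
    planted_effect: float
    baseline_log_mean: float
    baseline_log_sd: float


@dataclass
class ProbeSet:
    """Ordered probe universe with planted ground truth."""

    probes: list[ProbeRecord]

    def __post_init__(self) -> None:
        ids = [p.probe_id for p in self.probes]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("probe_id values must be unique")

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    @property
    def planted_effects(self) -> np.ndarray:
        return np.array([p.planted_effect for p in self.probes])

    @property
    def baselines(self) -> np.ndarray:
        return np.array([p.baseline_log_mean for p in self.probes])

    @property
    def planted_probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes if p.planted_effect != 0.0]


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the cohort generator; one seed drives every stream."""

    n_probes: int = DEFAULT_N_PROBES
    n_replicate_spots: int = DEFAULT_N_SPOTS
    n_up: int = 0
    n_down: int = 0
    effect_size: float = 0.0
    spot_noise_sd: float = DEFAULT_SPOT_NOISE_SD
    bio_noise_sd: float = DEFAULT_BIO_NOISE_SD
    array_scale_sd: float = 0.05
    background_mean: float = 50.0
    background_sd: float = 10.0
    baseline_glog_mean: float = DEFAULT_BASELINE_GLOG_MEAN
    baseline_glog_sd: float = DEFAULT_BASELINE_GLOG_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes <= 0 or self.n_replicate_spots <= 0:
            raise ConfigurationError("n_probes and n_replicate_spots must be positive")
        if self.n_up < 0 or self.n_down < 0:
            raise ConfigurationError("n_up and n_down must be nonnegative")
        if self.n_up + self.n_down > self.n_probes:
            raise ConfigurationError("n_up + n_down must not exceed n_probes")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be nonnegative")
        for name in ("spot_noise_sd", "bio_noise_sd", "array_scale_sd",
                     "background_mean", "background_sd", "baseline_glog_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class SampleSpec:
    """One sample of the cohort (controls always carry subtype 'none')."""

    sample_id: str
    class_label: str
    subtype: str = "none"

    def __post_init__(self) -> None:
        if self.class_label not in (CASE_LABEL, CONTROL_LABEL):
            raise ConfigurationError(f"unknown class label {self.class_label!r}")
        if self.class_label == CONTROL_LABEL and self.subtype != "none":
            raise ConfigurationError("controls must have subtype 'none'")


@dataclass
class RawArraySet:
    """Probe-level spot intensities with per-spot background estimates.

    ``intensities`` and ``backgrounds`` are indexed (probe, replicate spot,
    sample) and are complete: exactly n_replicate_spots entries per probe
    per sample.
    """

    probe_ids: list[str]
    samples: list[SampleSpec]
    intensities: np.ndarray
    backgrounds: np.ndarray
    background_corrected: bool = False
    floor: float | None = None

    def __post_init__(self) -> None:
        expected = (len(self.probe_ids), self.intensities.shape[1], len(self.samples))
        if self.intensities.shape != expected or self.backgrounds.shape != expected:
            raise ConfigurationError(
                f"intensity table shape {self.intensities.shape} inconsistent "
                f"with {len(self.probe_ids)} probes / {len(self.samples)} samples"
            )
        if np.isnan(self.intensities).any() or np.isnan(self.backgrounds).any():
            raise ConfigurationError("intensity table must be complete (no NaN)")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_replicate_spots(self) -> int:
        return self.intensities.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.class_label for s in self.samples])


def make_probe_set(
    n_probes: int = DEFAULT_N_PROBES,
    n_up: int = 0,
    n_down: int = 0,
    effect_size: float = 0.0,
    seed: int = 0,
    *,
    baseline_glog_mean: float = DEFAULT_BASELINE_GLOG_MEAN,
    baseline_glog_sd: float = DEFAULT_BASELINE_GLOG_SD,
    star_fraction: float = 0.3,
) -> ProbeSet:
    """Build the probe universe with ``n_up`` / ``n_down`` planted probes.

    Planted probes receive ``planted_effect`` of +effect_size (up in cases)
    or -effect_size (down in cases); all other probes are null.  Baselines
    are drawn from the configured glog-scale hyperprior.  Deterministic in
    ``seed``.
    """
    if n_probes <= 0:
        raise ConfigurationError("n_probes must be positive")
    if n_up < 0 or n_down < 0:
        raise ConfigurationError("n_up and n_down must be nonnegative")
    if n_up + n_down > n_probes:
        raise ConfigurationError(
            f"n_up + n_down = {n_up + n_down} exceeds n_probes = {n_probes}"
        )
    if effect_size < 0:
        raise ConfigurationError("effect_size must be nonnegative")

    rng = np.random.default_rng(seed)
    baselines = rng.normal(baseline_glog_mean, baseline_glog_sd, n_probes)
    stars = rng.random(n_probes) < star_fraction
    effects = np.zeros(n_probes)
    planted = rng.choice(n_probes, size=n_up + n_down, replace=False)
    effects[planted[:n_up]] = effect_size
    effects[planted[n_up:]] = -effect_size

    probes = [
        ProbeRecord(
            probe_id=f"syn-miR-{i + 1:04d}" + ("*" if stars[i] else ""),
            is_star=bool(stars[i]),
            planted_effect=float(effects[i]),
            baseline_log_mean=float(baselines[i]),
            baseline_log_sd=baseline_glog_sd,
        )
        for i in range(n_probes)
    ]
    return ProbeSet(probes)


def _simulate_samples(
    probe_set: ProbeSet,
    class_labels: list[str],
    config: GeneratorConfig,
    rng: np.random.Generator,
    id_offset: tuple[int, int] = (0, 0),
) -> RawArraySet:
    """Core generator shared by cohorts and replicate pairs.

    Draw order is fixed (subtypes, array offsets, biological noise, spot
    noise, background) so output is bit-reproducible for a given stream.
    """
    n_p = len(probe_set)
    n_k = config.n_replicate_spots
    n_s = len(class_labels)
    if n_p != config.n_probes:
        raise ConfigurationError(
            f"probe set size {n_p} does not match config.n_probes {config.n_probes}"
        )

    is_case = np.array([lab == CASE_LABEL for lab in class_labels])
    n_case = int(is_case.sum())
    case_subtypes = rng.choice(CASE_SUBTYPES, size=n_case, p=CASE_SUBTYPE_PROBS)

    samples: list[SampleSpec] = []
    ci, gi = id_offset
    case_i = 0
    for lab in class_labels:
        if lab == CASE_LABEL:
            ci += 1
            samples.append(SampleSpec(f"OVCA-{ci:03d}", CASE_LABEL, str(case_subtypes[case_i])))
            case_i += 1
        else:
            gi += 1
            samples.append(SampleSpec(f"CTRL-{gi:03d}", CONTROL_LABEL, "none"))

    offsets = rng.normal(0.0, config.array_scale_sd, n_s)
    bio = rng.normal(0.0, config.bio_noise_sd, (n_p, n_s))
    g = (
        probe_set.baselines[:, None]
        + probe_set.planted_effects[:, None] * is_case[None, :]
        + bio
        + offsets[None, :]
    )
    spot = g[:, None, :] + rng.normal(0.0, config.spot_noise_sd, (n_p, n_k, n_s))
    backgrounds = np.clip(
        rng.normal(config.background_mean, config.background_sd, (n_p, n_k, n_s)),
        0.0,
        None,
    )
    intensities = np.sinh(spot) + backgrounds
    return RawArraySet(list(probe_set.probe_ids), samples, intensities, backgrounds)


def simulate_cohort(
    probe_set: ProbeSet,
    n_case: int,
    n_control: int,
    config: GeneratorConfig,
) -> RawArraySet:
    """Simulate a case/control cohort of probe-level arrays.

    Fully reproducible from ``config.seed``; the planted effects of
    ``probe_set`` shift the case group on the glog scale.
    """
    if n_case <= 0 or n_control <= 0:
        raise ConfigurationError("cohort sizes must be positive")
    rng = np.random.default_rng(config.seed)
    labels = [CASE_LABEL] * n_case + [CONTROL_LABEL] * n_control
    return _simulate_samples(probe_set, labels, config, rng)


def simulate_from_config(
    config: GeneratorConfig, n_case: int, n_control: int
) -> tuple[ProbeSet, RawArraySet]:
    """Convenience: build the probe set and the cohort from one config."""
    probe_set = make_probe_set(
        config.n_probes,
        config.n_up,
        config.n_down,
        config.effect_size,
        seed=config.seed,
        baseline_glog_mean=config.baseline_glog_mean,
        baseline_glog_sd=config.baseline_glog_sd,
    )
    return probe_set, simulate_cohort(probe_set, n_case, n_control, config)


def simulate_replicate_pair(config: GeneratorConfig, seed: int) -> RawArraySet:
    """Two biological replicates of one (control) subject.

    The pair shares the probe baselines and differs by biological noise,
    array effects, spot noise and background — the model's notion of a
    biological replicate.
    """
    rng = np.random.default_rng(seed)
    probe_set = make_probe_set(
        config.n_probes,
        seed=int(rng.integers(2**31)),
        baseline_glog_mean=config.baseline_glog_mean,
        baseline_glog_sd=config.baseline_glog_sd,
    )
    return _simulate_samples(probe_set, [CONTROL_LABEL, CONTROL_LABEL], config, rng)


def replicate_statistics(
    config: GeneratorConfig,
    n_pairs: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo replicate quality after the full preprocessing chain.

    Returns (mean Pearson correlation, mean between-replicate variance),
    where the variance of a pair is the per-probe two-point sample variance
    (x - y)**2 / 2 averaged over probes, both computed on background-
    corrected, median-summarised, normalised profiles.
    """
    from . import preprocess  # local import; preprocess depends on this module

    child_seeds = np.random.SeedSequence(seed).generate_state(n_pairs) % (2**31)
    corrs = np.empty(n_pairs)
    variances = np.empty(n_pairs)
    for i, s in enumerate(child_seeds):
        raw = simulate_replicate_pair(config, int(s))
        mat = preprocess.preprocess_raw(raw)
        x, y = mat.values[:, 0], mat.values[:, 1]
        corrs[i] = np.corrcoef(x, y)[0, 1]
        variances[i] = float(np.mean((x - y) ** 2) / 2.0)
    return float(corrs.mean()), float(variances.mean())


@functools.lru_cache(maxsize=None)
def median_variance_factor(n_spots: int, n_draws: int = 400_000) -> float:
    """Variance of the median of ``n_spots`` iid standard normals (MC)."""
    rng = np.random.default_rng(20_214_907)
    draws = rng.standard_normal((n_draws, n_spots))
    return float(np.median(draws, axis=1).var())


def baseline_sd_for_targets(target_corr: float, target_var: float) -> float:
    """Across-probe baseline sd implied by the two replicate targets."""
    if not 0.0 < target_corr < 1.0 or target_var <= 0.0:
        raise ConfigurationError("need 0 < corr < 1 and var > 0")
    return math.sqrt(target_var * target_corr / (1.0 - target_corr))


@dataclass(frozen=True)
class NoiseCalibration:
    """Calibrated noise sds plus the Monte-Carlo statistics they achieve."""

    spot_noise_sd: float
    bio_noise_sd: float
    achieved_corr: float
    achieved_var: float

    def __iter__(self):
        return iter((self.spot_noise_sd, self.bio_noise_sd))


def calibrate_noise(
    target_replicate_corr: float,
    target_replicate_var: float,
    config: GeneratorConfig | None = None,
    *,
    n_pairs: int = 200,
    max_iter: int = 8,
    corr_tol: float = 0.02,
    var_rel_tol: float = 0.05,
    seed: int = 0,
) -> NoiseCalibration:
    """Find (spot_noise_sd, bio_noise_sd) matching the replicate targets.

    The total replicate variance v = bio**2 + c * spot**2 (c the median-of-
    spots variance factor) is split 50/50 between the biological and the
    summarised spot component, and a common multiplier on both sds is
    iterated against Monte-Carlo measurements through the full
    preprocessing chain until the variance target is met.  The correlation
    target is then verified: it is controlled by ``config.baseline_glog_sd``
    (rho = tau**2 / (tau**2 + v)), not by the noise sds, so a config with an
    inconsistent baseline spread fails calibration with diagnostics.
    Deterministic in ``seed``.
    """
    if not 0.0 < target_replicate_corr < 1.0:
        raise ConfigurationError("target_replicate_corr must be in (0, 1)")
    if target_replicate_var <= 0.0:
        raise ConfigurationError("target_replicate_var must be positive")
    config = config or GeneratorConfig()

    c_med = median_variance_factor(config.n_replicate_spots)
    bio = math.sqrt(0.5 * target_replicate_var)
    spot = math.sqrt(0.5 * target_replicate_var / c_med)

    corr_hat = var_hat = float("nan")
    for it in range(max_iter):
        cfg = replace(config, bio_noise_sd=bio, spot_noise_sd=spot)
        corr_hat, var_hat = replicate_statistics(cfg, n_pairs=n_pairs, seed=seed + it)
        rel = var_hat / target_replicate_var - 1.0
        if abs(rel) <= var_rel_tol:
            break
        scale = math.sqrt(target_replicate_var / var_hat)
        bio *= scale
        spot *= scale
    else:
        raise CalibrationError(
            "variance calibration did not converge",
            {"achieved_var": var_hat, "target_var": target_replicate_var,
             "spot_noise_sd": spot, "bio_noise_sd": bio},
        )

    if abs(corr_hat - target_replicate_corr) > corr_tol:
        tau_needed = baseline_sd_for_targets(target_replicate_corr, target_replicate_var)
        raise CalibrationError(
            "replicate correlation off target; adjust baseline_glog_sd "
            f"(need about {tau_needed:.4f}, config has {config.baseline_glog_sd:.4f})",
            {"achieved_corr": corr_hat, "target_corr": target_replicate_corr,
             "achieved_var": var_hat},
        )
    return NoiseCalibration(spot, bio, corr_hat, var_hat)
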