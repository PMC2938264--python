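"""Probe-level preprocessing: background correction, replicate
summarisation and variance-stabilising normalisation.

The normalisation follows the VSN recipe in its essentials: every array is
calibrated to a robust across-array reference profile by an affine map
(offset, scale) fitted with a robust loss, and the calibrated intensities
are passed through the generalised logarithm arsinh(x / cofactor).  The
affine step removes array-to-array offset and scale effects; the arsinh
step makes measurement variance approximately intensity-independent —
log-like at high intensity, linear near zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .errors import (
    AlreadyCorrectedError,
    InsufficientDataError,
    SchemaError,
)
from .simulate import RawArraySet

__all__ = [
    "ExpressionMatrix",
    "NormalizationModel",
    "background_correct",
    "summarize_replicates",
    "fit_normalization",
    "apply_normalization",
    "normalize",
    "preprocess_raw",
]

STAGE_RAW = "raw-summarized"
STAGE_NORMALIZED = "normalized"


@dataclass
class ExpressionMatrix:
    """Feature x sample matrix with per-sample class labels.

    ``stage`` records where the matrix sits in the chain: "raw-summarized"
    (background-corrected medians on the intensity scale) or "normalized"
    (glog scale, unbounded reals).
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: np.ndarray
    stage: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise SchemaError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(self.labels) != len(self.sample_ids):
            raise SchemaError("one class label per sample required")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise SchemaError("duplicate probe ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SchemaError("duplicate sample ids")
        if not np.isfinite(self.values).all():
            raise SchemaError("expression values must be finite")
        if self.stage not in (STAGE_RAW, STAGE_NORMALIZED):
            raise SchemaError(f"unknown stage {self.stage!r}")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


def background_correct(raw: RawArraySet, floor: float | None = None) -> RawArraySet:
    """Subtract per-spot background estimates, flooring at a small positive
    constant so later glog transforms stay finite.

    The default floor is data-driven — the 1st percentile of the positive
    corrected intensities — but clamped to stay genuinely small: at least
    0.5, and at most 5% of the median positive intensity, so that arrays
    whose signals all sit well above background never have real low-end
    signal censored.  Applying the correction twice is an error, never a
    silent re-subtraction.
    """
    if raw.background_corrected:
        raise AlreadyCorrectedError("background already subtracted from this array set")
    corrected = raw.intensities - raw.backgrounds
    if floor is None:
        positive = corrected[corrected > 0]
        if positive.size:
            cap = 0.05 * float(np.median(positive))
            floor = max(0.5, min(float(np.percentile(positive, 1)), cap))
        else:
            floor = 0.5
    if floor <= 0:
        raise SchemaError("floor must be positive")
    corrected = np.maximum(corrected, floor)
    return RawArraySet(
        probe_ids=list(raw.probe_ids),
        samples=list(raw.samples),
        intensities=corrected,
        backgrounds=raw.backgrounds.copy(),
        background_corrected=True,
        floor=float(floor),
    )


def summarize_replicates(corrected: RawArraySet) -> ExpressionMatrix:
    """Median over the replicate spots: one value per (probe, sample)."""
    if not corrected.background_corrected:
        raise SchemaError("summarize_replicates expects background-corrected input")
    values = np.median(corrected.intensities, axis=1)
    return ExpressionMatrix(
        probe_ids=list(corrected.probe_ids),
        sample_ids=corrected.sample_ids,
        values=values,
        labels=corrected.labels,
        stage=STAGE_RAW,
    )


@dataclass
class NormalizationModel:
    """Fitted per-array affine calibration plus the glog cofactor.

    ``reference`` is the frozen glog-scale reference profile (probe-wise
    median across the training arrays).  Applying the model to its own
    training matrix reproduces ``training_normalized`` exactly.
    """

    probe_ids: list[str]
    reference: np.ndarray
    reference_raw: np.ndarray
    cofactor: float
    offsets: dict[str, float]
    scales: dict[str, float]
    trim: float
    training_normalized: ExpressionMatrix | None = field(default=None, repr=False)


def _glog(x: np.ndarray, cofactor: float) -> np.ndarray:
    return np.arcsinh(x / cofactor)


def _fit_affine(
    y: np.ndarray,
    ref_glog: np.ndarray,
    ref_raw: np.ndarray,
    cofactor: float,
    trim: float,
) -> tuple[float, float]:
    """Robust (offset, scale) calibrating one array to the reference.

    Minimises the profile log-likelihood of the transform-both-sides model,

        n * log( trimmed mean of r**2 ) - 2 * sum log h'(y),
        r = h(y) - ref,   h(y) = arsinh((s*y + o) / cofactor),

    a least-trimmed-squares fit so a minority of outlying probes (e.g.
    truly deregulated ones) cannot drive the calibration.  The Jacobian
    term log h' is essential: without it the flat (s down, o up) valley of
    the arsinh family lets the fit compress the glog scale to shrink
    residual noise, biasing replicate variances low.  Scale stays positive
    by optimising its log.
    """
    med_y = float(np.median(y))
    s0 = float(np.median(ref_raw)) / med_y if med_y > 0 else 1.0
    s0 = s0 if np.isfinite(s0) and s0 > 0 else 1.0
    n_keep = max(2, int(round((1.0 - trim) * y.size)))

    def objective(theta: np.ndarray) -> float:
        o, log_s = theta
        s = np.exp(log_s)
        u = s * y + o
        if np.any(u <= 0):  # keep the transform in its monotone range
            return np.inf
        r2 = (_glog(u, cofactor) - ref_glog) ** 2
        kept = np.partition(r2, n_keep - 1)[:n_keep]
        log_jac = log_s - 0.5 * np.log(cofactor**2 + u * u)
        # tiny epsilon keeps the log finite for exact-fit (zero residual) arrays
        return y.size * np.log(kept.mean() + 1e-30) - 2.0 * log_jac.sum()

    sol = optimize.minimize(
        objective,
        x0=np.array([0.0, np.log(s0)]),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 600},
    )
    o, log_s = sol.x
    return float(o), float(np.exp(log_s))


def fit_normalization(
    matrix: ExpressionMatrix,
    cofactor: float = 1.0,
    trim: float = 0.25,
) -> NormalizationModel:
    """Fit per-array affine calibrations against the probe-wise median
    reference, then store the arsinh transform parameters."""
    if matrix.stage != STAGE_RAW:
        raise SchemaError("fit_normalization expects a raw-summarized matrix")
    if matrix.n_samples < 2:
        raise InsufficientDataError("normalization needs at least two arrays")
    if cofactor <= 0:
        raise SchemaError("cofactor must be positive")

    ref_raw = np.median(matrix.values, axis=1)
    ref_glog = _glog(ref_raw, cofactor)

    offsets: dict[str, float] = {}
    scales: dict[str, float] = {}
    for j, sid in enumerate(matrix.sample_ids):
        o, s = _fit_affine(matrix.values[:, j], ref_glog, ref_raw, cofactor, trim)
        offsets[sid] = o
        scales[sid] = s

    model = NormalizationModel(
        probe_ids=list(matrix.probe_ids),
        reference=ref_glog,
        reference_raw=ref_raw,
        cofactor=cofactor,
        offsets=offsets,
        scales=scales,
        trim=trim,
    )
    model.training_normalized = apply_normalization(model, matrix)
    return model


def apply_normalization(
    model: NormalizationModel, matrix: ExpressionMatrix
) -> ExpressionMatrix:
    """Calibrate and glog-transform a raw-summarized matrix.

    Arrays seen at fit time reuse their stored affine parameters; unseen
    arrays are calibrated against the frozen reference profile.  Re-applying
    to normalized output is rejected, never silently repeated.
    """
    if matrix.stage == STAGE_NORMALIZED:
        raise AlreadyCorrectedError("matrix is already normalized")
    if list(matrix.probe_ids) != list(model.probe_ids):
        raise SchemaError("probe set of matrix does not match normalization model")

    out = np.empty_like(matrix.values)
    for j, sid in enumerate(matrix.sample_ids):
        y = matrix.values[:, j]
        if sid in model.offsets:
            o, s = model.offsets[sid], model.scales[sid]
        else:
            o, s = _fit_affine(
                y, model.reference, model.reference_raw, model.cofactor, model.trim
            )
        out[:, j] = _glog(s * y + o, model.cofactor)

    return ExpressionMatrix(
        probe_ids=list(matrix.probe_ids),
        sample_ids=list(matrix.sample_ids),
        values=out,
        labels=matrix.labels.copy(),
        stage=STAGE_NORMALIZED,
    )


def normalize(
    matrix: ExpressionMatrix, cofactor: float = 1.0, trim: float = 0.25
) -> ExpressionMatrix:
    """Fit-and-apply convenience wrapper."""
    return fit_normalization(matrix, cofactor, trim).training_normalized


def preprocess_raw(
    raw: RawArraySet,
    floor: float | None = None,
    cofactor: float = 1.0,
    trim: float = 0.25,
) -> ExpressionMatrix:
    """Full chain: background correction -> median summarisation -> VSN."""
    corrected = background_correct(raw, floor=floor)
    summarized = summarize_replicates(corrected)
    return normalize(summarized, cofactor=cofactor, trim=trim)
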