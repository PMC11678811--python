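"""Control-plasma noise model and ctDNA signal statistics.

The signal in a patient's plasma is summarized by ``AveVarDet`` — the
average VAF (or AD) over the filtered tumor variants in the patient's
plasma. The noise model is the same quantity measured in each control
plasma from tumor-free individuals: one summary value per control, whose
mean and sample standard deviation give ``mu_noise`` and ``sigma_noise``.
Two statistics compare signal to noise::

    S2N = AveVarDet / mu_noise
    z   = (AveVarDet - mu_noise) / sigma_noise

A *binary* variant replaces the VAF/AD values by the count of detected
variants (plasma AD at or above a detection threshold), with the noise
model built from the same counts per control. Significance is judged
one-sided against a Student-t critical value; the shipped default of 7
degrees of freedom at alpha = 0.05 gives the critical value 1.895.

By default the per-control summaries are per-sample *means* across the
kept variants — each control's mean is a natural null replicate of
AveVarDet, and sigma is then a between-sample standard deviation with
n_controls - 1 degrees of freedom. A pooled alternative (mu/sigma over
all variant x control values) is available via ``pooling="pooled"``.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, asdict, field
from typing import Literal

import numpy as np
from scipy import stats

from .errors import DegenerateNoiseError, NoiseModelError, UndefinedSignalError
from .filters import FilterConfig, PonSites, apply_method
from .variants import PatientTable

Metric = Literal["VAF", "AD", "binary"]
METRICS = ("VAF", "AD", "binary")

DEFAULT_ALPHA = 0.05
#: Degrees of freedom whose one-sided 5% t-quantile is 1.895 (3 decimals).
DEFAULT_DF = 7


@dataclass(frozen=True)
class NoiseModel:
    """Per-control noise summaries and their mean/sd."""

    metric: str
    per_control: tuple[float, ...]
    mu_noise: float
    sigma_noise: float
    n_controls: int
    pooling: str = "per_control"

    @classmethod
    def from_per_control(
        cls, metric: str, values, pooling: str = "per_control"
    ) -> "NoiseModel":
        values = tuple(float(v) for v in values)
        if len(values) < 2:
            raise NoiseModelError(f"need >= 2 control summaries, got {len(values)}")
        arr = np.asarray(values)
        return cls(metric, values, float(arr.mean()), float(arr.std(ddof=1)),
                   len(values), pooling)


@dataclass(frozen=True)
class SignalResult:
    """Signal statistics for one patient, one metric."""

    metric: str
    n_variants_used: int
    ave_var_det: float
    s2n: float
    z: float


def ave_var_det(
    kept: PatientTable,
    metric: str,
    *,
    detected_only: bool = False,
    detection_ad_min: int = 1,
) -> float:
    """Mean plasma VAF (or AD) over the kept variants.

    With ``detected_only`` the average runs only over variants with plasma
    AD >= ``detection_ad_min``; if none are detected the signal is 0.
    """
    if len(kept) == 0:
        raise UndefinedSignalError("no variants survive filtering; AveVarDet is undefined")
    if metric == "VAF":
        values = kept.plasma_vaf
    elif metric == "AD":
        values = kept.plasma_ad.astype(float)
    else:
        raise ValueError(f"metric must be 'VAF' or 'AD', got {metric!r}")
    if detected_only:
        mask = kept.plasma_ad >= detection_ad_min
        if not mask.any():
            return 0.0
        values = values[mask]
    return float(np.mean(values))


def build_noise_model(
    kept: PatientTable,
    metric: str,
    *,
    detection_ad_min: int = 1,
    pooling: str = "per_control",
) -> NoiseModel:
    """Noise model from the control plasmas over the kept variants.

    Per-control summaries: mean control VAF, mean control AD, or (binary)
    the count of variants with control AD >= ``detection_ad_min``.
    """
    if kept.n_controls < 2:
        raise NoiseModelError(f"need >= 2 control plasmas, got {kept.n_controls}")
    if len(kept) == 0:
        raise UndefinedSignalError("no variants survive filtering; noise model is undefined")
    if metric == "VAF":
        matrix = kept.control_vaf()
    elif metric == "AD":
        matrix = kept.control_ad().astype(float)
    elif metric == "binary":
        counts = (kept.control_ad() >= detection_ad_min).sum(axis=0)
        return NoiseModel.from_per_control("binary", counts)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    per_control = matrix.mean(axis=0)
    if pooling == "per_control":
        return NoiseModel.from_per_control(metric, per_control)
    if pooling == "pooled":
        flat = matrix.ravel()
        return NoiseModel(metric, tuple(float(v) for v in per_control),
                          float(flat.mean()), float(flat.std(ddof=1)),
                          kept.n_controls, "pooled")
    raise ValueError(f"pooling must be 'per_control' or 'pooled', got {pooling!r}")


def s2n(ave: float, noise: NoiseModel) -> float:
    """Signal-to-noise ratio AveVarDet / mu_noise (+inf sentinel at zero noise)."""
    if noise.mu_noise == 0:
        warnings.warn("mu_noise is zero; S2N reported as +inf", RuntimeWarning, stacklevel=2)
        return math.inf
    return ave / noise.mu_noise


def z_score(ave: float, noise: NoiseModel) -> float:
    """Standardized signal (AveVarDet - mu_noise) / sigma_noise."""
    if noise.sigma_noise == 0:
        raise DegenerateNoiseError("sigma_noise is zero; z-score is undefined")
    return (ave - noise.mu_noise) / noise.sigma_noise


def binary_z_score(kept: PatientTable, detection_ad_min: int = 1) -> SignalResult:
    """z-score on detected-variant *counts* (values of VAF/AD not used)."""
    if len(kept) == 0:
        raise UndefinedSignalError("no variants survive filtering")
    count = float((kept.plasma_ad >= detection_ad_min).sum())
    noise = build_noise_model(kept, "binary", detection_ad_min=detection_ad_min)
    return SignalResult(
        metric="binary",
        n_variants_used=len(kept),
        ave_var_det=count,
        s2n=s2n(count, noise),
        z=z_score(count, noise),
    )


def significance(
    z: float, alpha: float = DEFAULT_ALPHA, df: int = DEFAULT_DF
) -> tuple[float, bool]:
    """One-sided Student-t significance decision.

    Returns ``(critical_value, z > critical_value)`` where the critical
    value is the upper-``alpha`` quantile of t with ``df`` degrees of
    freedom (1.895 at alpha = 0.05, df = 7).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    critical = float(stats.t.ppf(1.0 - alpha, df))
    return critical, bool(z > critical)


def _config_hash(cfg: FilterConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True)
    return hashlib.md5(payload.encode()).hexdigest()[:12]


def evaluate_patient(
    table: PatientTable,
    method: int,
    cfg: FilterConfig = FilterConfig(),
    pon_1000g: PonSites | None = None,
    pon_self: PonSites | None = None,
    *,
    alpha: float = DEFAULT_ALPHA,
    df: int = DEFAULT_DF,
    detection_ad_min: int = 1,
    detected_only: bool = False,
    pooling: str = "per_control",
) -> dict:
    """Filter a patient table and compute the full statistic set.

    Returns a JSON-serializable bundle with, per metric (VAF, AD, binary),
    the noise model (mu, sigma), AveVarDet, S2N and z, plus the one-sided
    critical value and significance flags.
    """
    kept, verdicts = apply_method(table, method, cfg, pon_1000g, pon_self)
    if len(kept) == 0:
        raise UndefinedSignalError(
            f"patient {table.patient_id}: no variants survive Method {method} filtering"
        )
    critical, _ = significance(0.0, alpha, df)
    metrics: dict[str, dict] = {}
    for metric in ("VAF", "AD"):
        ave = ave_var_det(kept, metric, detected_only=detected_only,
                          detection_ad_min=detection_ad_min)
        noise = build_noise_model(kept, metric, pooling=pooling)
        zval = z_score(ave, noise)
        metrics[metric] = {
            "mu": noise.mu_noise,
            "sigma": noise.sigma_noise,
            "ave": ave,
            "s2n": s2n(ave, noise),
            "z": zval,
            "significant": bool(zval > critical),
        }
    bres = binary_z_score(kept, detection_ad_min)
    bnoise = build_noise_model(kept, "binary", detection_ad_min=detection_ad_min)
    metrics["binary"] = {
        "count": bres.ave_var_det,
        "mu": bnoise.mu_noise,
        "sigma": bnoise.sigma_noise,
        "s2n": bres.s2n,
        "z": bres.z,
        "significant": bool(bres.z > critical),
    }
    return {
        "patient_id": table.patient_id,
        "method": method,
        "n_variants_input": len(table),
        "n_variants_used": len(kept),
        "n_controls": kept.n_controls,
        "metrics": metrics,
        "alpha": alpha,
        "df": df,
        "critical": critical,
        "config_hash": _config_hash(cfg),
    }
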