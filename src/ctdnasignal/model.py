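"""Model/Results interface over the filter-and-score pipeline.

``CtDNASignalModel`` binds a patient's forced-call table to a filtering
method and its configuration; ``fit()`` applies the filters, builds the
control-plasma noise models, and returns a ``CtDNASignalResults`` object
carrying AveVarDet, S2N and z for the VAF, AD and binary metrics, together
with the one-sided significance decision and the per-variant filter
verdicts (for UpSet-style accounting). ``summary()`` renders a compact
text table.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import UndefinedSignalError
from .filters import FilterConfig, LABELS, PonSites, method_verdict_frame
from .signal import (
    DEFAULT_ALPHA,
    DEFAULT_DF,
    NoiseModel,
    SignalResult,
    ave_var_det,
    binary_z_score,
    build_noise_model,
    s2n,
    significance,
    z_score,
    _config_hash,
)
from .variants import PatientTable, read_patient_table


class CtDNASignalModel:
    """Tumor-informed ctDNA signal model for one patient.

    Parameters
    ----------
    table
        Forced-call variant table (tumor x all samples).
    method
        1 = basic + gnomAD + public PON; 2 = merged PON; 3 = merged PON +
        plasma-pool artefact filter.
    filter_config
        Thresholds; defaults are the shipped most-stringent rung
        (ADt >= 8, DPt >= 12, VAFt >= 0.2, ADn = 0, DPn >= 10).
    pon_1000g, pon_self
        Public and self-generated panels of normals (either may be None).
    detection_ad_min
        Plasma AD needed for a variant to count as detected (binary metric
        and ``detected_only`` averaging).
    detected_only
        Average AveVarDet only over detected variants.
    noise_pooling
        "per_control" (between-sample noise model, default) or "pooled".
    """

    def __init__(
        self,
        table: PatientTable,
        method: int = 3,
        filter_config: FilterConfig | None = None,
        pon_1000g: PonSites | None = None,
        pon_self: PonSites | None = None,
        *,
        detection_ad_min: int = 1,
        detected_only: bool = False,
        noise_pooling: str = "per_control",
    ) -> None:
        self.table = table
        self.method = method
        self.filter_config = filter_config or FilterConfig()
        self.pon_1000g = pon_1000g
        self.pon_self = pon_self
        self.detection_ad_min = detection_ad_min
        self.detected_only = detected_only
        self.noise_pooling = noise_pooling

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "CtDNASignalModel":
        return cls(read_patient_table(path), **kwargs)

    def fit(self, alpha: float = DEFAULT_ALPHA, df: int = DEFAULT_DF) -> "CtDNASignalResults":
        verdict_frame = method_verdict_frame(
            self.table, self.method, self.filter_config, self.pon_1000g, self.pon_self
        )
        kept = self.table.subset(~verdict_frame.to_numpy().any(axis=1))
        if len(kept) == 0:
            raise UndefinedSignalError(
                f"patient {self.table.patient_id}: no variants survive Method "
                f"{self.method} filtering"
            )
        noise: dict[str, NoiseModel] = {}
        signal: dict[str, SignalResult] = {}
        for metric in ("VAF", "AD"):
            ave = ave_var_det(
                kept, metric, detected_only=self.detected_only,
                detection_ad_min=self.detection_ad_min,
            )
            nm = build_noise_model(kept, metric, pooling=self.noise_pooling)
            noise[metric] = nm
            signal[metric] = SignalResult(metric, len(kept), ave, s2n(ave, nm), z_score(ave, nm))
        signal["binary"] = binary_z_score(kept, self.detection_ad_min)
        noise["binary"] = build_noise_model(kept, "binary",
                                            detection_ad_min=self.detection_ad_min)
        critical, _ = significance(0.0, alpha, df)
        return CtDNASignalResults(self, kept, verdict_frame, noise, signal, alpha, df, critical)


class CtDNASignalResults:
    """Fitted signal statistics for one patient and one filtering method."""

    def __init__(
        self,
        model: CtDNASignalModel,
        kept: PatientTable,
        verdict_frame: pd.DataFrame,
        noise: dict[str, NoiseModel],
        signal: dict[str, SignalResult],
        alpha: float,
        df: int,
        critical: float,
    ) -> None:
        self.model = model
        self.kept = kept
        self.verdict_frame = verdict_frame
        self.noise = noise
        self.signal = signal
        self.alpha = alpha
        self.df = df
        self.critical = critical

    @property
    def n_variants_input(self) -> int:
        return len(self.model.table)

    @property
    def n_variants_used(self) -> int:
        return len(self.kept)

    def significant(self, metric: str = "VAF") -> bool:
        return self.signal[metric].z > self.critical

    def removed_counts(self) -> dict[str, int]:
        """Marginal removed-variant count per filter label."""
        return {lab: int(self.verdict_frame[lab].sum()) for lab in LABELS}

    def to_dict(self) -> dict:
        return {
            "patient_id": self.model.table.patient_id,
            "method": self.model.method,
            "n_variants_input": self.n_variants_input,
            "n_variants_used": self.n_variants_used,
            "n_controls": self.kept.n_controls,
            "alpha": self.alpha,
            "df": self.df,
            "critical": self.critical,
            "config_hash": _config_hash(self.model.filter_config),
            "removed_by_filter": self.removed_counts(),
            "metrics": {
                m: {
                    "ave": r.ave_var_det,
                    "mu": self.noise[m].mu_noise,
                    "sigma": self.noise[m].sigma_noise,
                    "s2n": r.s2n,
                    "z": r.z,
                    "significant": bool(r.z > self.critical),
                }
                for m, r in self.signal.items()
            },
        }

    def save_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        """Plain-text summary table in the style of a regression results printout."""
        t = self.model.table
        lines = []
        w = 78
        lines.append("Tumor-informed ctDNA signal detection".center(w))
        lines.append("=" * w)
        lines.append(
            f"Patient: {t.patient_id:<20} Method: {self.model.method}"
            f"        Controls: {t.n_controls}   Pool: {t.n_pool}"
        )
        lines.append(
            f"Variants in: {self.n_variants_input:<16} kept: {self.n_variants_used:<10}"
            f" alpha (one-sided): {self.alpha:.3f}  df: {self.df}"
        )
        lines.append(f"Critical value (Student t): {self.critical:.3f}")
        lines.append("-" * w)
        hdr = f"{'metric':<8}{'AveVarDet':>12}{'mu_noise':>12}{'sigma_noise':>13}{'S2N':>10}{'z':>10}{'signif':>8}"
        lines.append(hdr)
        for metric in ("VAF", "AD", "binary"):
            r = self.signal[metric]
            nm = self.noise[metric]
            sig = "yes" if r.z > self.critical else "no"
            lines.append(
                f"{metric:<8}{r.ave_var_det:>12.6g}{nm.mu_noise:>12.6g}"
                f"{nm.sigma_noise:>13.6g}{r.s2n:>10.4g}{r.z:>10.4g}{sig:>8}"
            )
        lines.append("-" * w)
        removed = self.removed_counts()
        lines.append(
            "Removed by filter: "
            + "  ".join(f"{lab}={n}" for lab, n in removed.items() if n > 0 or lab == "pool")
        )
        lines.append("=" * w)
        return "\n".join(lines)

    def __repr__(self) -> str:
        zv = self.signal["VAF"].z
        return (
            f"<CtDNASignalResults patient={self.model.table.patient_id} "
            f"method={self.model.method} n_used={self.n_variants_used} z(VAF)={zv:.3g}>"
        )
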