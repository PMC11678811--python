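"""Synthetic cohort generator with ground truth.

Real forced-call tables from patients cannot be shared, so this module
generates cohorts with the statistical structure the detection method
assumes:

* per-variant tumor-tissue VAFs drawn from a high-purity spectrum
  (default uniform on [0.2, 0.8], consistent with tumors of at least 75%
  tumor cell fraction and a VAFt >= 0.2 calling regime);
* patient plasma whose per-site alternate probability is
  ``tumor_fraction * v_t`` plus a background term;
* a uniform per-base substitution error ``e`` split equally over the
  three non-reference bases (site background e/3);
* a small fraction of *artefact sites* with an elevated error rate shared
  by every plasma sample — patient, controls and pool alike. These are
  the recurrent outliers that the plasma-pool filter exists to remove;
* germline leakage: a fraction of tumor calls that are really germline
  variants, planted with heterozygous support in the matched normal (they
  are what the ADn = 0 filter removes);
* per-site depths drawn around the role means (Poisson by default,
  negative binomial behind a knob).

Every generated table passes the domain validation (AD <= DP always), and
the accompanying ``SimTruth`` records the flags needed for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .filters import FilterConfig, PonSites, pool_failed
from .model import CtDNASignalModel
from .signal import DEFAULT_ALPHA, DEFAULT_DF, significance
from .variants import PatientTable, VariantKey, write_patient_table

_BASE = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Cohort-generation parameters.

    Depth defaults mirror a WGS design with ~24x tumor, ~17x normal,
    ~52x patient plasma and ~49x control plasma; nine controls and nine
    pool plasmas mirror a nine-patient, nine-control study layout.
    ``tumor_fraction`` defaults to 0.01, a plausible pretreatment ctDNA
    burden for advanced high-grade serous disease.
    """

    n_variants: int = 2000
    tumor_depth: float = 24.0
    normal_depth: float = 17.0
    plasma_depth: float = 52.0
    control_depth: float = 49.0
    n_controls: int = 9
    n_pool: int = 9
    tumor_fraction: float = 0.01
    tumor_vaf_range: tuple[float, float] = (0.2, 0.8)
    error_rate: float = 1e-3
    artefact_fraction: float = 0.02
    artefact_vaf: float = 0.02
    germline_leak_fraction: float = 0.01
    germline_leak_vaf: float = 0.5
    depth_law: str = "poisson"
    depth_dispersion: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tumor_fraction", "error_rate", "artefact_fraction",
                     "artefact_vaf", "germline_leak_fraction", "germline_leak_vaf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("tumor_depth", "normal_depth", "plasma_depth", "control_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.n_controls < 2:
            raise ValueError("n_controls must be >= 2")
        if self.n_pool < 0:
            raise ValueError("n_pool must be >= 0")
        lo, hi = self.tumor_vaf_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"tumor_vaf_range must satisfy 0 <= lo <= hi <= 1, got {self.tumor_vaf_range}")
        if self.depth_law not in ("poisson", "negbin"):
            raise ValueError("depth_law must be 'poisson' or 'negbin'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "tumor_vaf_range" in data:
            data["tumor_vaf_range"] = tuple(data["tumor_vaf_range"])
        return cls(**data)


@dataclass
class SimTruth:
    """Ground truth for one simulated patient."""

    patient_id: str
    tumor_fraction: float
    v_t: np.ndarray
    is_artefact_site: np.ndarray
    is_germline_leak: np.ndarray

    def artefact_keys(self, table: PatientTable) -> set[VariantKey]:
        return {k for k, flag in zip(table.keys(), self.is_artefact_site) if flag}

    def to_jsonable(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "tumor_fraction": self.tumor_fraction,
            "v_t": [float(v) for v in self.v_t],
            "is_artefact_site": [bool(b) for b in self.is_artefact_site],
            "is_germline_leak": [bool(b) for b in self.is_germline_leak],
        }


def _draw_depth(rng: np.random.Generator, cfg: SimConfig, mean: float, n: int) -> np.ndarray:
    if cfg.depth_law == "poisson":
        return rng.poisson(mean, size=n)
    r = cfg.depth_dispersion
    return rng.negative_binomial(r, r / (r + mean), size=n)


def _binom_obs(rng, dp: np.ndarray, p: np.ndarray | float) -> np.ndarray:
    return rng.binomial(dp, np.clip(p, 0.0, 1.0))


def simulate_patient(
    cfg: SimConfig,
    rng: np.random.Generator | int | None = None,
    patient_id: str = "P1",
    control_ids=None,
    pool_ids=None,
    pos_offset: int = 0,
) -> tuple[PatientTable, SimTruth]:
    """Simulate one patient's forced-call table plus its ground truth."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n = cfg.n_variants
    control_ids = list(control_ids) if control_ids is not None else [
        f"C{j + 1:02d}" for j in range(cfg.n_controls)
    ]
    pool_ids = list(pool_ids) if pool_ids is not None else [
        f"POOL{j + 1:02d}" for j in range(cfg.n_pool)
    ]

    pos = pos_offset + np.cumsum(rng.integers(1, 1000, size=n))
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4

    lo, hi = cfg.tumor_vaf_range
    v_t = rng.uniform(lo, hi, size=n)
    is_artefact = rng.random(n) < cfg.artefact_fraction
    is_leak = rng.random(n) < cfg.germline_leak_fraction
    background = np.where(is_artefact, cfg.artefact_vaf, cfg.error_rate / 3.0)

    data = {
        "chrom": np.full(n, "1"),
        "pos": pos,
        "ref": _BASE[ref_idx],
        "alt": _BASE[alt_idx],
        "pop_af": np.full(n, np.nan),
    }
    tumor_dp = _draw_depth(rng, cfg, cfg.tumor_depth, n)
    data["tumor.DP"] = tumor_dp
    data["tumor.AD"] = _binom_obs(rng, tumor_dp, v_t)
    normal_dp = _draw_depth(rng, cfg, cfg.normal_depth, n)
    normal_p = np.where(is_leak, cfg.germline_leak_vaf, cfg.error_rate / 3.0)
    data["normal.DP"] = normal_dp
    data["normal.AD"] = _binom_obs(rng, normal_dp, normal_p)
    plasma_dp = _draw_depth(rng, cfg, cfg.plasma_depth, n)
    data["plasma.DP"] = plasma_dp
    data["plasma.AD"] = _binom_obs(rng, plasma_dp, cfg.tumor_fraction * v_t + background)
    for cid in control_ids:
        dp = _draw_depth(rng, cfg, cfg.control_depth, n)
        data[f"control:{cid}.DP"] = dp
        data[f"control:{cid}.AD"] = _binom_obs(rng, dp, background)
    for pid in pool_ids:
        dp = _draw_depth(rng, cfg, cfg.plasma_depth, n)
        data[f"pool:{pid}.DP"] = dp
        data[f"pool:{pid}.AD"] = _binom_obs(rng, dp, background)

    import pandas as pd

    table = PatientTable(patient_id, pd.DataFrame(data), control_ids, pool_ids, validate=False)
    truth = SimTruth(patient_id, cfg.tumor_fraction, v_t, is_artefact, is_leak)
    return table, truth


def simulate_cohort(
    cfg: SimConfig,
    n_patients: int,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> list[tuple[PatientTable, SimTruth]]:
    """Simulate a cohort of patients sharing one control/pool manifest.

    Patients occupy disjoint genomic position blocks; the cohort ground
    truth records each patient's artefact sites (within any one table the
    same artefact sites are elevated in the patient plasma, every control
    and every pool sample, which is the structure the pool filter
    exploits). With ``out_dir`` set, per-patient TSV tables, a manifest
    YAML and a ``truth.json`` are written; output is byte-reproducible
    for a given seed.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    master = np.random.SeedSequence(seed if seed is not None else cfg.seed)
    control_ids = [f"C{j + 1:02d}" for j in range(cfg.n_controls)]
    pool_ids = [f"POOL{j + 1:02d}" for j in range(cfg.n_pool)]
    block = cfg.n_variants * 1000
    cohort = []
    for i, ss in enumerate(master.spawn(n_patients)):
        table, truth = simulate_patient(
            cfg,
            np.random.default_rng(ss),
            patient_id=f"P{i + 1:02d}",
            control_ids=control_ids,
            pool_ids=pool_ids,
            pos_offset=i * block,
        )
        cohort.append((table, truth))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for table, _truth in cohort:
            write_patient_table(table, out_dir / f"{table.patient_id}.tsv")
        manifest = {
            "patients": [t.patient_id for t, _ in cohort],
            "controls": control_ids,
            "pool": pool_ids,
        }
        with open(out_dir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(
                {t.patient_id: tr.to_jsonable() for t, tr in cohort},
                fh, indent=2, sort_keys=True,
            )
    return cohort


def recovery_report(
    cohort: list[tuple[PatientTable, SimTruth]],
    filter_config: FilterConfig | None = None,
    pon_1000g: PonSites | None = None,
    pon_self: PonSites | None = None,
    *,
    alpha: float = DEFAULT_ALPHA,
    df: int = DEFAULT_DF,
    metric: str = "VAF",
    detection_ad_min: int = 1,
) -> dict:
    """Score a simulated cohort against its ground truth.

    Runs Methods 2 and 3 on every patient and reports per-patient S2N and
    z with detection flags, the pool filter's precision/recall against
    the true artefact sites, and the empirical type-I error over null
    (tumor_fraction = 0) patients under Method 3.
    """
    filter_config = filter_config or FilterConfig()
    critical, _ = significance(0.0, alpha, df)
    patients = []
    tp = fp = fn = 0
    null_flags = []
    for table, truth in cohort:
        if truth.patient_id != table.patient_id:
            raise ValueError(
                f"truth/table id mismatch: {truth.patient_id} vs {table.patient_id}"
            )
        entry: dict = {"patient_id": table.patient_id,
                       "tumor_fraction": truth.tumor_fraction, "methods": {}}
        for method in (2, 3):
            res = CtDNASignalModel(
                table, method, filter_config, pon_1000g, pon_self,
                detection_ad_min=detection_ad_min,
            ).fit(alpha=alpha, df=df)
            r = res.signal[metric]
            entry["methods"][method] = {
                "n_variants_used": res.n_variants_used,
                "s2n": r.s2n,
                "z": r.z,
                "detected": bool(r.z > critical),
            }
        patients.append(entry)
        removed = pool_failed(table, filter_config.pool_ad_gt)
        art = np.asarray(truth.is_artefact_site, dtype=bool)
        tp += int((removed & art).sum())
        fp += int((removed & ~art).sum())
        fn += int((~removed & art).sum())
        if truth.tumor_fraction == 0.0:
            null_flags.append(entry["methods"][3]["detected"])
    report = {
        "metric": metric,
        "critical": critical,
        "patients": patients,
        "pool_filter": {
            "true_positives": tp,
            "false_positives": fp,
            "false_negatives": fn,
            "precision": tp / (tp + fp) if tp + fp else None,
            "recall": tp / (tp + fn) if tp + fn else None,
        },
        "type_i_error": (sum(null_flags) / len(null_flags)) if null_flags else None,
        "n_null_patients": len(null_flags),
        "mean_z": {
            m: float(np.mean([p["methods"][m]["z"] for p in patients])) for m in (2, 3)
        },
    }
    return report
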