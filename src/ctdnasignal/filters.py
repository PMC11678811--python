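"""Noise filters for tumor-informed plasma variant sets.

Four families of filters are composed into three analysis methods:

* basic read-support thresholds on the tumor and matched normal
  (labels ``ADt``, ``DPt``, ``VAFt``, ``ADn``, ``DPn``);
* a population allele-frequency filter (``gnomAD``) removing likely
  germline/common variants;
* panel-of-normals (PON) site filters (``PON``) — a public PON, a
  self-generated PON built from the cohort's normal DNA, or their union;
* the plasma-pool artefact filter (``pool``), removing a tumor variant if
  any plasma sample from *other* patients shows alternate support AD > 1
  at that site — such recurrent cross-patient signal marks a
  position-specific sequencing artefact rather than ctDNA.

Method 1 = basic + gnomAD + public PON; Method 2 swaps in the merged PON;
Method 3 = Method 2 + the plasma-pool filter. Every filter is evaluated
per variant against the *original* table, so composition is commutative
and the verdicts record every reason a variant was removed (consumed by
:mod:`ctdnasignal.accounting`).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import TableFormatError
from .variants import BASES, Observation, PatientTable, VariantKey

#: Filter labels in canonical display order.
LABELS = ("ADt", "DPt", "VAFt", "ADn", "DPn", "gnomAD", "PON", "pool")
BASIC_LABELS = LABELS[:5]

METHODS = (1, 2, 3)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the filter ladder.

    Keep-side conventions: a variant is kept when tumor AD >= ``ad_t_min``,
    tumor DP >= ``dp_t_min``, tumor VAF >= ``vaf_t_min``, normal
    AD <= ``ad_n_max``, normal DP >= ``dp_n_min``, population
    AF <= ``pop_af_max`` (absent counts as kept), and no pool sample shows
    AD strictly greater than ``pool_ad_gt``.
    """

    ad_t_min: int = 8
    dp_t_min: int = 12
    vaf_t_min: float = 0.2
    ad_n_max: int = 0
    dp_n_min: int = 10
    pop_af_max: float = 1e-5
    pool_ad_gt: int = 1
    pon_min_samples: int = 2
    pon_min_ad: int = 1

    def __post_init__(self) -> None:
        for name in ("ad_t_min", "dp_t_min", "ad_n_max", "dp_n_min", "pool_ad_gt",
                     "pon_min_samples", "pon_min_ad"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.vaf_t_min <= 1.0:
            raise ValueError("vaf_t_min must be in [0, 1]")
        if not 0.0 <= self.pop_af_max <= 1.0:
            raise ValueError("pop_af_max must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def with_(self, **kwargs) -> "FilterConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PonSites:
    """A panel of normals as a set of recurrently artefactual sites."""

    sites: frozenset[VariantKey]
    label: str = "PON"

    @classmethod
    def empty(cls, label: str = "empty") -> "PonSites":
        return cls(frozenset(), label)

    def __len__(self) -> int:
        return len(self.sites)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.sites


@dataclass(frozen=True)
class FilterVerdict:
    """Per-variant outcome: the (possibly empty) set of failed filter labels."""

    key: VariantKey
    failed: frozenset[str]

    @property
    def passes(self) -> bool:
        return not self.failed


# ---------------------------------------------------------------------------
# Individual filters
# ---------------------------------------------------------------------------

def evaluate_basic_filters(record, cfg: FilterConfig) -> set[str]:
    """Failed basic-threshold labels for a single record (scalar reference path)."""
    failed = set()
    if record.tumor.ad < cfg.ad_t_min:
        failed.add("ADt")
    if record.tumor.dp < cfg.dp_t_min:
        failed.add("DPt")
    if record.tumor.vaf < cfg.vaf_t_min:
        failed.add("VAFt")
    if record.normal.ad > cfg.ad_n_max:
        failed.add("ADn")
    if record.normal.dp < cfg.dp_n_min:
        failed.add("DPn")
    return failed


def basic_failed_frame(table: PatientTable, cfg: FilterConfig) -> pd.DataFrame:
    """Vectorized basic filters: boolean DataFrame, one column per basic label."""
    return pd.DataFrame(
        {
            "ADt": table.tumor_ad < cfg.ad_t_min,
            "DPt": table.tumor_dp < cfg.dp_t_min,
            "VAFt": table.tumor_vaf < cfg.vaf_t_min,
            "ADn": table.normal_ad > cfg.ad_n_max,
            "DPn": table.normal_dp < cfg.dp_n_min,
        }
    )


def population_af_failed(table: PatientTable, pop_af_max: float) -> np.ndarray:
    """True where pop_af is present and exceeds the cutoff (missing AF is kept)."""
    af = table.pop_af
    return ~np.isnan(af) & (af > pop_af_max)


def pon_failed(table: PatientTable, pon: PonSites) -> np.ndarray:
    if not pon.sites:
        return np.zeros(len(table), dtype=bool)
    return np.fromiter((k in pon.sites for k in table.keys()), dtype=bool, count=len(table))


def pool_failed(table: PatientTable, pool_ad_gt: int = 1) -> np.ndarray:
    """True where any pool plasma shows AD strictly above ``pool_ad_gt``."""
    pool_ad = table.pool_ad()
    if pool_ad.shape[1] == 0:
        return np.zeros(len(table), dtype=bool)
    return (pool_ad > pool_ad_gt).any(axis=1)


def _as_verdicts(table: PatientTable, frame: pd.DataFrame) -> list[FilterVerdict]:
    keys = table.keys()
    labels = list(frame.columns)
    arr = frame.to_numpy()
    return [
        FilterVerdict(k, frozenset(lab for lab, f in zip(labels, row) if f))
        for k, row in zip(keys, arr)
    ]


def apply_population_af_filter(
    table: PatientTable, pop_af_max: float = 1e-5
) -> tuple[PatientTable, list[FilterVerdict]]:
    failed = population_af_failed(table, pop_af_max)
    verdicts = _as_verdicts(table, pd.DataFrame({"gnomAD": failed}))
    return table.subset(~failed), verdicts


def apply_pon_filter(table: PatientTable, pon: PonSites) -> tuple[PatientTable, list[FilterVerdict]]:
    failed = pon_failed(table, pon)
    verdicts = _as_verdicts(table, pd.DataFrame({"PON": failed}))
    return table.subset(~failed), verdicts


def apply_plasma_pool_filter(
    table: PatientTable, pool_ad_gt: int = 1
) -> tuple[PatientTable, list[FilterVerdict]]:
    """Remove variants with AD > ``pool_ad_gt`` in at least one pool plasma.

    Removal excludes the variant from *all* downstream computation — the
    patient-plasma signal and the control-plasma noise model alike.
    """
    failed = pool_failed(table, pool_ad_gt)
    verdicts = _as_verdicts(table, pd.DataFrame({"pool": failed}))
    return table.subset(~failed), verdicts


# ---------------------------------------------------------------------------
# Panels of normals
# ---------------------------------------------------------------------------

def build_pon(
    normals: Mapping[str, Iterable[tuple[VariantKey, Observation]]],
    cfg: FilterConfig = FilterConfig(),
    label: str = "self-PON",
) -> PonSites:
    """Build a panel of normals from per-sample normal-DNA observations.

    A site enters the panel when it carries alternate support
    (AD >= ``cfg.pon_min_ad``) in at least ``cfg.pon_min_samples`` distinct
    normal samples.
    """
    counts: Counter[VariantKey] = Counter()
    for _sample, obs_iter in normals.items():
        pairs = obs_iter.items() if hasattr(obs_iter, "items") else obs_iter
        seen = {key for key, obs in pairs if obs.ad >= cfg.pon_min_ad}
        counts.update(seen)
    sites = frozenset(k for k, c in counts.items() if c >= cfg.pon_min_samples)
    return PonSites(sites, label)


def build_pon_from_tables(
    tables: Sequence[PatientTable], cfg: FilterConfig = FilterConfig(), label: str = "self-PON"
) -> PonSites:
    """Build the self-generated PON from the matched-normal column of patient tables."""
    normals = {
        t.patient_id: list(zip(t.keys(), (Observation(int(d), int(a))
                                          for d, a in zip(t.normal_dp, t.normal_ad))))
        for t in tables
    }
    return build_pon(normals, cfg, label)


def merge_pons(a: PonSites, b: PonSites) -> PonSites:
    """Set union of two panels; provenance labels are concatenated."""
    return PonSites(a.sites | b.sites, f"{a.label}+{b.label}")


def read_pon(path: str | Path, label: str | None = None) -> PonSites:
    """Read a PON site list from a sites-only VCF or a 4-column TSV (chrom pos ref alt)."""
    path = Path(path)
    label = label or path.stem
    sites: set[VariantKey] = set()
    if path.suffix in (".vcf", ".bcf", ".gz"):
        import pysam

        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                for alt in rec.alts or ():
                    if len(rec.ref) == 1 and alt and len(alt) == 1 and \
                            rec.ref in BASES and alt in BASES:
                        sites.add(VariantKey(str(rec.chrom), int(rec.pos), rec.ref, alt))
        return PonSites(frozenset(sites), label)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[:4] == ["chrom", "pos", "ref", "alt"]:
                continue  # optional header
            if len(parts) < 4:
                raise TableFormatError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            sites.add(VariantKey(parts[0], int(parts[1]), parts[2], parts[3]))
    return PonSites(frozenset(sites), label)


def write_pon(pon: PonSites, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for k in sorted(pon.sites):
            fh.write(f"{k.chrom}\t{k.pos}\t{k.ref}\t{k.alt}\n")


# ---------------------------------------------------------------------------
# Method composition
# ---------------------------------------------------------------------------

def method_verdict_frame(
    table: PatientTable,
    method: int,
    cfg: FilterConfig = FilterConfig(),
    pon_1000g: PonSites | None = None,
    pon_self: PonSites | None = None,
) -> pd.DataFrame:
    """Boolean failed-filter matrix (columns = :data:`LABELS`) for one method.

    Every filter is evaluated independently against the original table; a
    variant survives iff its row is all-False. Methods: 1 uses the public
    PON alone, 2 the merged (public + self-generated) PON, 3 adds the
    plasma-pool filter.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    pon = pon_1000g or PonSites.empty("1000_g")
    if method >= 2:
        pon = merge_pons(pon, pon_self or PonSites.empty("self"))
    frame = basic_failed_frame(table, cfg)
    frame["gnomAD"] = population_af_failed(table, cfg.pop_af_max)
    frame["PON"] = pon_failed(table, pon)
    frame["pool"] = (
        pool_failed(table, cfg.pool_ad_gt) if method == 3 else np.zeros(len(table), dtype=bool)
    )
    return frame[list(LABELS)]


def apply_method(
    table: PatientTable,
    method: int,
    cfg: FilterConfig = FilterConfig(),
    pon_1000g: PonSites | None = None,
    pon_self: PonSites | None = None,
) -> tuple[PatientTable, list[FilterVerdict]]:
    """Apply one analysis method; returns (surviving table, full verdict list)."""
    frame = method_verdict_frame(table, method, cfg, pon_1000g, pon_self)
    kept = table.subset(~frame.to_numpy().any(axis=1))
    return kept, _as_verdicts(table, frame)


@dataclass(frozen=True)
class LadderRung:
    config: FilterConfig
    n_kept: int
    kept: PatientTable


def filter_ladder(
    table: PatientTable,
    ladder: Sequence[FilterConfig],
    pon_1000g: PonSites | None = None,
) -> list[LadderRung]:
    """Evaluate a progressive-stringency ladder of configs under Method 1."""
    if not ladder:
        raise ValueError("ladder must contain at least one FilterConfig")
    rungs = []
    for cfg in ladder:
        kept, _ = apply_method(table, 1, cfg, pon_1000g)
        rungs.append(LadderRung(cfg, len(kept), kept))
    return rungs
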