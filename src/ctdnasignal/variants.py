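"""Domain types and I/O for multi-sample forced-call SNV observations.

A tumor-informed ctDNA analysis starts from a per-patient table of somatic
SNVs called in the tumor and force-genotyped in every other sample: the
matched normal, the patient's own plasma, a set of control plasmas from
tumor-free individuals, and a pool of plasma samples from other patients.
Each cell of that table is an ``Observation`` — total read depth (DP) and
alternate allelic depth (AD) at one site in one sample; the variant allele
frequency is always AD/DP, recomputed, never trusted from file.

The table is stored column-wise in a :class:`pandas.DataFrame` so that the
downstream filters and statistics can operate on whole columns at once.
Two on-disk representations are supported: a multi-sample VCF (FORMAT
fields AD and DP) together with a sample-role manifest, and a plain TSV
dialect whose header names the per-sample DP/AD columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from .errors import ManifestError, TableFormatError, TableValidationError

logger = logging.getLogger(__name__)

BASES = frozenset("ACGT")

#: Sample roles a manifest may assign.
ROLES = ("tumor", "normal", "plasma", "control", "pool")

CORE_COLUMNS = ["chrom", "pos", "ref", "alt", "pop_af"]

#: INFO keys probed, in order, for a per-allele population allele frequency.
POP_AF_INFO_KEYS = ("POP_AF", "GNOMAD_AF", "AF")


@dataclass(frozen=True, order=True)
class VariantKey:
    """A single-nucleotide variant: chromosome, 1-based position, ref and alt base."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise TableValidationError(f"position must be >= 1, got {self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise TableValidationError(
                f"ref/alt must be single bases in ACGT, got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise TableValidationError(f"ref equals alt ({self.ref}) at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class Observation:
    """Read support at one site in one sample: depth (DP) and alt depth (AD)."""

    dp: int
    ad: int

    def __post_init__(self) -> None:
        if self.dp < 0 or self.ad < 0:
            raise TableValidationError(f"negative read counts: dp={self.dp}, ad={self.ad}")
        if self.ad > self.dp:
            raise TableValidationError(f"ad ({self.ad}) exceeds dp ({self.dp})")

    @property
    def vaf(self) -> float:
        """AD/DP, or 0 when depth is zero (no evidence either way)."""
        return self.ad / self.dp if self.dp > 0 else 0.0


def vaf_of(obs: Observation) -> float:
    """Variant allele frequency of an observation (0 at zero depth)."""
    return obs.vaf


@dataclass(frozen=True)
class PatientVariantRecord:
    """One tumor-called SNV with its observation in every sample of the design."""

    key: VariantKey
    tumor: Observation
    normal: Observation
    plasma: Observation
    controls: tuple[Observation, ...] = ()
    pool: tuple[Observation, ...] = ()
    pop_af: float | None = None


def _sample_columns(control_ids: Sequence[str], pool_ids: Sequence[str]) -> list[str]:
    cols = []
    for role in ("tumor", "normal", "plasma"):
        cols += [f"{role}.DP", f"{role}.AD"]
    for cid in control_ids:
        cols += [f"control:{cid}.DP", f"control:{cid}.AD"]
    for pid in pool_ids:
        cols += [f"pool:{pid}.DP", f"pool:{pid}.AD"]
    return cols


def _safe_vaf(ad: np.ndarray, dp: np.ndarray) -> np.ndarray:
    ad = np.asarray(ad, dtype=float)
    dp = np.asarray(dp, dtype=float)
    return np.divide(ad, dp, out=np.zeros_like(ad), where=dp > 0)


class PatientTable:
    """Per-patient forced-call matrix: tumor SNVs x {tumor, normal, plasma, controls, pool}.

    Parameters
    ----------
    patient_id
        Identifier of the patient whose tumor defined the variant set.
    df
        DataFrame with columns ``chrom pos ref alt pop_af`` followed by
        ``<role>.DP``/``<role>.AD`` pairs for tumor/normal/plasma and
        ``control:<id>``/``pool:<id>`` samples. ``pop_af`` is NaN when the
        variant is absent from the population resource.
    control_ids, pool_ids
        Ordered sample identifiers; they fix the column order and the
        orientation of the matrices returned by the accessors.
    """

    def __init__(
        self,
        patient_id: str,
        df: pd.DataFrame,
        control_ids: Sequence[str],
        pool_ids: Sequence[str] = (),
        validate: bool = True,
    ) -> None:
        self.patient_id = str(patient_id)
        self.control_ids = tuple(str(c) for c in control_ids)
        self.pool_ids = tuple(str(p) for p in pool_ids)
        expected = CORE_COLUMNS + _sample_columns(self.control_ids, self.pool_ids)
        missing = [c for c in expected if c not in df.columns]
        if missing:
            raise TableFormatError(f"missing columns: {missing}")
        df = df[expected].reset_index(drop=True).copy()
        for col in expected:
            if col in ("chrom", "ref", "alt"):
                df[col] = df[col].astype(str)
            elif col == "pop_af":
                df[col] = df[col].astype(float)
            else:
                df[col] = df[col].astype(np.int64)
        self._df = df
        if validate:
            self._validate()

    def _validate(self) -> None:
        df = self._df
        if len(df) == 0:
            return
        if (df["pos"] < 1).any():
            raise TableValidationError("positions must be 1-based (>= 1)")
        bad = ~(df["ref"].isin(BASES) & df["alt"].isin(BASES)) | (df["ref"] == df["alt"])
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise TableValidationError(f"row {i}: not a valid SNV ({df['ref'][i]}>{df['alt'][i]})")
        for col in self._df.columns:
            if col.endswith(".AD"):
                dp_col = col[:-3] + ".DP"
                over = df[col] > df[dp_col]
                if over.any():
                    i = int(np.flatnonzero(over)[0])
                    raise TableValidationError(
                        f"row {i}, sample {col[:-3]}: AD ({df[col][i]}) exceeds DP ({df[dp_col][i]})"
                    )
                if (df[col] < 0).any() or (df[dp_col] < 0).any():
                    raise TableValidationError(f"negative counts in sample {col[:-3]}")
        dup = df.duplicated(subset=["chrom", "pos", "ref", "alt"])
        if dup.any():
            i = int(np.flatnonzero(dup)[0])
            raise TableValidationError(
                f"duplicate variant {df['chrom'][i]}:{df['pos'][i]} {df['ref'][i]}>{df['alt'][i]}"
            )

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(
        cls,
        patient_id: str,
        records: Iterable[PatientVariantRecord],
        control_ids: Sequence[str],
        pool_ids: Sequence[str] = (),
    ) -> "PatientTable":
        control_ids = tuple(control_ids)
        pool_ids = tuple(pool_ids)
        rows = []
        for rec in records:
            if len(rec.controls) != len(control_ids) or len(rec.pool) != len(pool_ids):
                raise TableValidationError(
                    f"record {rec.key} has {len(rec.controls)} controls / {len(rec.pool)} pool "
                    f"observations; manifest expects {len(control_ids)} / {len(pool_ids)}"
                )
            row = {
                "chrom": rec.key.chrom,
                "pos": rec.key.pos,
                "ref": rec.key.ref,
                "alt": rec.key.alt,
                "pop_af": np.nan if rec.pop_af is None else float(rec.pop_af),
            }
            for role, obs in (("tumor", rec.tumor), ("normal", rec.normal), ("plasma", rec.plasma)):
                row[f"{role}.DP"] = obs.dp
                row[f"{role}.AD"] = obs.ad
            for cid, obs in zip(control_ids, rec.controls):
                row[f"control:{cid}.DP"] = obs.dp
                row[f"control:{cid}.AD"] = obs.ad
            for pid, obs in zip(pool_ids, rec.pool):
                row[f"pool:{pid}.DP"] = obs.dp
                row[f"pool:{pid}.AD"] = obs.ad
            rows.append(row)
        cols = CORE_COLUMNS + _sample_columns(control_ids, pool_ids)
        df = pd.DataFrame(rows, columns=cols)
        return cls(patient_id, df, control_ids, pool_ids)

    # -- basic protocol ---------------------------------------------------

    def __len__(self) -> int:
        return len(self._df)

    @property
    def n_variants(self) -> int:
        return len(self._df)

    @property
    def n_controls(self) -> int:
        return len(self.control_ids)

    @property
    def n_pool(self) -> int:
        return len(self.pool_ids)

    @property
    def df(self) -> pd.DataFrame:
        """The underlying DataFrame (treat as read-only)."""
        return self._df

    def keys(self) -> list[VariantKey]:
        d = self._df
        return [
            VariantKey(c, int(p), r, a)
            for c, p, r, a in zip(d["chrom"], d["pos"], d["ref"], d["alt"])
        ]

    def records(self) -> list[PatientVariantRecord]:
        d = self._df
        out = []
        for i in range(len(d)):
            out.append(
                PatientVariantRecord(
                    key=VariantKey(d["chrom"][i], int(d["pos"][i]), d["ref"][i], d["alt"][i]),
                    tumor=Observation(int(d["tumor.DP"][i]), int(d["tumor.AD"][i])),
                    normal=Observation(int(d["normal.DP"][i]), int(d["normal.AD"][i])),
                    plasma=Observation(int(d["plasma.DP"][i]), int(d["plasma.AD"][i])),
                    controls=tuple(
                        Observation(int(d[f"control:{c}.DP"][i]), int(d[f"control:{c}.AD"][i]))
                        for c in self.control_ids
                    ),
                    pool=tuple(
                        Observation(int(d[f"pool:{p}.DP"][i]), int(d[f"pool:{p}.AD"][i]))
                        for p in self.pool_ids
                    ),
                    pop_af=None if np.isnan(d["pop_af"][i]) else float(d["pop_af"][i]),
                )
            )
        return out

    def subset(self, mask: np.ndarray) -> "PatientTable":
        """New table containing the rows where ``mask`` is True (order kept)."""
        mask = np.asarray(mask, dtype=bool)
        sub = self._df.loc[mask].reset_index(drop=True)
        return PatientTable(self.patient_id, sub, self.control_ids, self.pool_ids, validate=False)

    def equals(self, other: "PatientTable") -> bool:
        return (
            isinstance(other, PatientTable)
            and self.patient_id == other.patient_id
            and self.control_ids == other.control_ids
            and self.pool_ids == other.pool_ids
            and self._df.equals(other._df)
        )

    def __eq__(self, other: object) -> bool:  # type: ignore[override]
        if not isinstance(other, PatientTable):
            return NotImplemented
        return self.equals(other)

    # -- columnar accessors ----------------------------------------------

    def _arr(self, col: str) -> np.ndarray:
        return self._df[col].to_numpy()

    @property
    def pop_af(self) -> np.ndarray:
        return self._arr("pop_af")

    @property
    def tumor_dp(self) -> np.ndarray:
        return self._arr("tumor.DP")

    @property
    def tumor_ad(self) -> np.ndarray:
        return self._arr("tumor.AD")

    @property
    def tumor_vaf(self) -> np.ndarray:
        return _safe_vaf(self.tumor_ad, self.tumor_dp)

    @property
    def normal_dp(self) -> np.ndarray:
        return self._arr("normal.DP")

    @property
    def normal_ad(self) -> np.ndarray:
        return self._arr("normal.AD")

    @property
    def plasma_dp(self) -> np.ndarray:
        return self._arr("plasma.DP")

    @property
    def plasma_ad(self) -> np.ndarray:
        return self._arr("plasma.AD")

    @property
    def plasma_vaf(self) -> np.ndarray:
        return _safe_vaf(self.plasma_ad, self.plasma_dp)

    def _matrix(self, prefix: str, ids: Sequence[str], fld: str) -> np.ndarray:
        if not ids:
            return np.zeros((len(self._df), 0), dtype=np.int64)
        return np.column_stack([self._arr(f"{prefix}:{i}.{fld}") for i in ids])

    def control_dp(self) -> np.ndarray:
        """(n_variants, n_controls) matrix of control DP."""
        return self._matrix("control", self.control_ids, "DP")

    def control_ad(self) -> np.ndarray:
        return self._matrix("control", self.control_ids, "AD")

    def control_vaf(self) -> np.ndarray:
        return _safe_vaf(self.control_ad(), self.control_dp())

    def pool_dp(self) -> np.ndarray:
        return self._matrix("pool", self.pool_ids, "DP")

    def pool_ad(self) -> np.ndarray:
        return self._matrix("pool", self.pool_ids, "AD")

    def pool_vaf(self) -> np.ndarray:
        return _safe_vaf(self.pool_ad(), self.pool_dp())


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def write_patient_table(table: PatientTable, tsv_path: str | Path) -> None:
    """Write a table in the package TSV dialect ("." marks a missing pop_af)."""
    df = table.df.copy()
    df["pop_af"] = [("." if np.isnan(v) else repr(float(v))) for v in df["pop_af"]]
    df.to_csv(tsv_path, sep="\t", index=False)


def read_patient_table(tsv_path: str | Path, patient_id: str | None = None) -> PatientTable:
    """Read a table written by :func:`write_patient_table`.

    The control and pool manifests are recovered from the header; the
    patient id defaults to the file stem. VAF never appears on disk — it is
    recomputed from AD/DP on access.
    """
    tsv_path = Path(tsv_path)
    if patient_id is None:
        patient_id = tsv_path.stem
    try:
        df = pd.read_csv(
            tsv_path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str},
            na_values=["."], keep_default_na=False,
        )
    except pd.errors.EmptyDataError as exc:
        raise TableFormatError(f"{tsv_path}: empty file (no header)") from exc
    cols = list(df.columns)
    if cols[:5] != CORE_COLUMNS:
        raise TableFormatError(f"{tsv_path}: header must start with {CORE_COLUMNS}, got {cols[:5]}")
    control_ids, pool_ids = [], []
    for col in cols[5:]:
        if col.startswith("control:") and col.endswith(".DP"):
            control_ids.append(col[len("control:"):-3])
        elif col.startswith("pool:") and col.endswith(".DP"):
            pool_ids.append(col[len("pool:"):-3])
    expected = CORE_COLUMNS + _sample_columns(control_ids, pool_ids)
    if cols != expected:
        raise TableFormatError(
            f"{tsv_path}: column layout does not match the header manifest; "
            f"expected {expected}, got {cols}"
        )
    count_cols = [c for c in cols if c.endswith(".DP") or c.endswith(".AD")]
    for col in count_cols:
        if df[col].isna().any():
            i = int(np.flatnonzero(df[col].isna())[0])
            raise TableFormatError(f"{tsv_path}: missing count in row {i}, column {col}")
    try:
        return PatientTable(patient_id, df, control_ids, pool_ids)
    except TableValidationError as exc:
        raise TableValidationError(f"{tsv_path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Multi-sample VCF + role manifest
# ---------------------------------------------------------------------------

def load_manifest(path: str | Path) -> dict[str, str]:
    """Load a ``{sample_name: role}`` manifest from YAML or JSON."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ManifestError(f"{path}: manifest must be a mapping of sample -> role")
    manifest = {str(k): str(v) for k, v in data.items()}
    bad = {r for r in manifest.values() if r not in ROLES}
    if bad:
        raise ManifestError(f"{path}: unknown roles {sorted(bad)}; expected one of {ROLES}")
    return manifest


def _check_manifest_roles(manifest: Mapping[str, str]) -> tuple[str, str, str, list[str], list[str]]:
    by_role: dict[str, list[str]] = {r: [] for r in ROLES}
    for sample, role in manifest.items():
        if role not in by_role:
            raise ManifestError(f"unknown role {role!r} for sample {sample!r}")
        by_role[role].append(sample)
    for role in ("tumor", "normal", "plasma"):
        if len(by_role[role]) != 1:
            raise ManifestError(
                f"manifest must assign exactly one {role} sample, got {by_role[role]}"
            )
    if len(by_role["control"]) < 1:
        raise ManifestError("manifest must assign at least one control plasma")
    return (
        by_role["tumor"][0],
        by_role["normal"][0],
        by_role["plasma"][0],
        by_role["control"],
        by_role["pool"],
    )


def _sample_obs(sample, allele_index: int) -> tuple[Observation, bool]:
    """(Observation, was_missing) for one VCF genotype entry and one alt allele."""
    ad = sample.get("AD")
    dp = sample.get("DP")
    ad_missing = ad is None or all(a is None for a in ad)
    if ad_missing and dp is None:
        return Observation(0, 0), True
    alt_ad = 0
    if not ad_missing and len(ad) > allele_index:
        alt_ad = int(ad[allele_index] or 0)
    if dp is None:
        dp = sum(int(a or 0) for a in ad)
    dp = max(int(dp), alt_ad)  # some callers emit DP < sum(AD); keep ad <= dp
    return Observation(dp, alt_ad), False


def _record_pop_af(rec, alt_pos: int) -> float:
    for key in POP_AF_INFO_KEYS:
        if key in rec.info:
            val = rec.info[key]
            if isinstance(val, (tuple, list)):
                val = val[alt_pos] if alt_pos < len(val) else None
            if val is not None:
                return float(val)
    return np.nan


def read_patient_vcf(
    vcf_path: str | Path,
    manifest: Mapping[str, str],
    patient_id: str | None = None,
) -> PatientTable:
    """Build a :class:`PatientTable` from a multi-sample forced-call VCF.

    ``manifest`` maps each VCF sample name to its role (tumor / normal /
    plasma / control / pool). Multiallelic lines are split per alternate
    allele; non-SNV alleles are skipped with a counted warning; a missing
    genotype (``./.``) yields ``Observation(dp=0, ad=0)``. A per-allele
    population allele frequency is taken from the first INFO key present
    among ``POP_AF``, ``GNOMAD_AF``, ``AF``.
    """
    vcf_path = Path(vcf_path)
    if patient_id is None:
        patient_id = vcf_path.stem.split(".")[0]
    tumor_s, normal_s, plasma_s, control_s, pool_s = _check_manifest_roles(manifest)
    with pysam.VariantFile(str(vcf_path)) as vf:
        fmts = set(vf.header.formats.keys())
        if "AD" not in fmts or "DP" not in fmts:
            raise TableFormatError(f"{vcf_path}: FORMAT fields AD and DP are required")
        header_samples = set(vf.header.samples)
        absent = [s for s in manifest if s not in header_samples]
        if absent:
            raise ManifestError(f"{vcf_path}: manifest samples not in VCF header: {absent}")
        records: list[PatientVariantRecord] = []
        n_skipped = n_missing = 0
        for rec in vf:
            alts = rec.alts or ()
            for alt_pos, alt in enumerate(alts):
                if len(rec.ref) != 1 or alt is None or len(alt) != 1 or \
                        rec.ref not in BASES or alt not in BASES:
                    n_skipped += 1
                    continue
                allele_index = alt_pos + 1  # AD is (ref, alt1, alt2, ...)

                def obs(sample_name: str) -> Observation:
                    nonlocal n_missing
                    o, was_missing = _sample_obs(rec.samples[sample_name], allele_index)
                    n_missing += was_missing
                    return o

                records.append(
                    PatientVariantRecord(
                        key=VariantKey(str(rec.chrom), int(rec.pos), rec.ref, alt),
                        tumor=obs(tumor_s),
                        normal=obs(normal_s),
                        plasma=obs(plasma_s),
                        controls=tuple(obs(s) for s in control_s),
                        pool=tuple(obs(s) for s in pool_s),
                        pop_af=(lambda v: None if np.isnan(v) else v)(_record_pop_af(rec, alt_pos)),
                    )
                )
    if n_skipped:
        logger.warning("%s: skipped %d non-SNV allele(s)", vcf_path, n_skipped)
    if n_missing:
        logger.warning("%s: %d missing genotype entr(ies) read as DP=0, AD=0", vcf_path, n_missing)
    return PatientTable.from_records(patient_id, records, control_s, pool_s)
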