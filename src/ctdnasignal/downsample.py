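"""Count-level emulation of read downsampling.

Sequencing a library to a fraction of its depth keeps each read
independently with that probability, so at a forced SNV site the kept
alternate reads are Binomial(AD, fraction) and the kept reference reads
Binomial(DP - AD, fraction). Thinning per-site counts this way matches
the marginal per-site behavior of BAM-level random downsampling for SNV
counts; read-pairing effects do not exist at the count level. By default
only the patient plasma is thinned — the controls keep their original
depth, so the noise model is untouched and any depth sensitivity shows up
purely on the signal side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .variants import Observation, PatientTable

_ROLE_ORDER = ("tumor", "normal", "plasma", "control", "pool")


@dataclass(frozen=True)
class ThinningSpec:
    """Keep-probability, seed, and the sample roles to thin."""

    fraction: float
    seed: int = 0
    scope: tuple[str, ...] = ("plasma",)

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction must be in [0, 1], got {self.fraction}")
        bad = set(self.scope) - set(_ROLE_ORDER)
        if bad:
            raise ValueError(f"unknown roles in scope: {sorted(bad)}")


def thin_observation(obs: Observation, fraction: float, rng: np.random.Generator) -> Observation:
    """Thin one observation: each alt and ref read kept i.i.d. with ``fraction``."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    kept_alt = int(rng.binomial(obs.ad, fraction))
    kept_ref = int(rng.binomial(obs.dp - obs.ad, fraction))
    return Observation(dp=kept_alt + kept_ref, ad=kept_alt)


def _scoped_columns(table: PatientTable, scope: tuple[str, ...]) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    for role in _ROLE_ORDER:
        if role not in scope:
            continue
        if role in ("tumor", "normal", "plasma"):
            pairs.append((f"{role}.DP", f"{role}.AD"))
        elif role == "control":
            pairs += [(f"control:{c}.DP", f"control:{c}.AD") for c in table.control_ids]
        else:
            pairs += [(f"pool:{p}.DP", f"pool:{p}.AD") for p in table.pool_ids]
    return pairs


def downsample_plasma(table: PatientTable, spec: ThinningSpec) -> PatientTable:
    """Thin every observation in the scoped roles (default: patient plasma only).

    Each scoped sample gets its own deterministic random stream derived
    from ``spec.seed``, running over variants in table order, so the
    output is bit-reproducible for a given seed and identical in all
    out-of-scope columns.
    """
    df = table.df.copy()
    pairs = _scoped_columns(table, spec.scope)
    streams = np.random.SeedSequence(spec.seed).spawn(len(pairs))
    for (dp_col, ad_col), ss in zip(pairs, streams):
        rng = np.random.default_rng(ss)
        ad = df[ad_col].to_numpy()
        ref = df[dp_col].to_numpy() - ad
        kept_alt = rng.binomial(ad, spec.fraction)
        kept_ref = rng.binomial(ref, spec.fraction)
        df[ad_col] = kept_alt
        df[dp_col] = kept_alt + kept_ref
    return PatientTable(table.patient_id, df, table.control_ids, table.pool_ids, validate=False)
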