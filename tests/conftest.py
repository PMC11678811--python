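"""Shared fixtures: hand-built and random patient tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ctdnasignal import Observation, PatientTable, PatientVariantRecord, VariantKey

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


def rec(
    pos,
    tumor=(24, 12),
    normal=(17, 0),
    plasma=(52, 0),
    controls=((49, 0), (49, 0)),
    pool=(),
    pop_af=None,
    ref="A",
    alt="C",
    chrom="1",
):
    """Shorthand record builder; sample tuples are (dp, ad)."""
    return PatientVariantRecord(
        key=VariantKey(chrom, pos, ref, alt),
        tumor=Observation(*tumor),
        normal=Observation(*normal),
        plasma=Observation(*plasma),
        controls=tuple(Observation(*c) for c in controls),
        pool=tuple(Observation(*p) for p in pool),
        pop_af=pop_af,
    )


def table_of(records, patient_id="P1", n_controls=2, n_pool=0):
    control_ids = [f"C{j+1:02d}" for j in range(n_controls)]
    pool_ids = [f"POOL{j+1:02d}" for j in range(n_pool)]
    return PatientTable.from_records(patient_id, records, control_ids, pool_ids)


def random_table(rng, n_variants=None, n_controls=None, n_pool=None, patient_id="R1"):
    """Random table whose counts straddle the default filter boundaries."""
    if n_variants is None:
        n_variants = int(rng.integers(1, 40))
    if n_controls is None:
        n_controls = int(rng.integers(2, 10))
    if n_pool is None:
        n_pool = int(rng.integers(0, 10))
    n = n_variants
    pos = np.cumsum(rng.integers(1, 50, size=n))
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    bases = np.array(list("ACGT"))

    def dp_ad(depth_lo, depth_hi, ad_hi):
        dp = rng.integers(depth_lo, depth_hi, size=n)
        ad = np.minimum(dp, rng.integers(0, ad_hi, size=n))
        return dp, ad

    data = {
        "chrom": np.full(n, "1"),
        "pos": pos,
        "ref": bases[ref_idx],
        "alt": bases[alt_idx],
        # straddle the 1e-5 population-AF boundary; mostly missing
        "pop_af": np.where(
            rng.random(n) < 0.3,
            rng.choice([1e-6, 1e-5, 2e-5, 1e-3], size=n),
            np.nan,
        ),
    }
    # tumor counts straddle ADt>=8 / DPt>=12 / VAFt>=0.2
    dp, ad = dp_ad(8, 30, 14)
    data["tumor.DP"], data["tumor.AD"] = dp, ad
    # normal counts straddle ADn=0 / DPn>=10
    dp, ad = dp_ad(6, 25, 3)
    data["normal.DP"], data["normal.AD"] = dp, ad
    dp, ad = dp_ad(20, 70, 4)
    data["plasma.DP"], data["plasma.AD"] = dp, ad
    for j in range(n_controls):
        dp, ad = dp_ad(20, 70, 3)
        data[f"control:C{j+1:02d}.DP"], data[f"control:C{j+1:02d}.AD"] = dp, ad
    for j in range(n_pool):
        dp, ad = dp_ad(20, 70, 4)  # pool AD straddles the >1 rule
        data[f"pool:POOL{j+1:02d}.DP"], data[f"pool:POOL{j+1:02d}.AD"] = dp, ad
    return PatientTable(
        patient_id,
        pd.DataFrame(data),
        [f"C{j+1:02d}" for j in range(n_controls)],
        [f"POOL{j+1:02d}" for j in range(n_pool)],
    )


@pytest.fixture
def toy_table():
    """Four variants with known filter outcomes under the default config."""
    return table_of(
        [
            # passes everything (boundary values on the keep side)
            rec(100, tumor=(12, 8), normal=(10, 0), plasma=(50, 2),
                controls=((49, 0), (49, 1)), pool=((50, 1), (50, 0))),
            # fails ADt only
            rec(200, tumor=(24, 7), normal=(17, 0), plasma=(50, 0),
                controls=((49, 0), (49, 0)), pool=((50, 0), (50, 0))),
            # fails ADn only
            rec(300, tumor=(24, 12), normal=(17, 1), plasma=(50, 1),
                controls=((49, 0), (49, 0)), pool=((50, 0), (50, 0))),
            # fails pool only (AD=2 in one pool sample)
            rec(400, tumor=(24, 12), normal=(17, 0), plasma=(50, 3),
                controls=((49, 2), (49, 3)), pool=((50, 2), (50, 0))),
        ],
        n_controls=2,
        n_pool=2,
    )
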