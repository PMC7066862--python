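"""Calculators for the two orthogonal validation assays.

* qRT-PCR relative quantification by the comparative-CT method: the target's
  threshold cycle is referenced to a spike-in plasmid transcript in the same
  sample and to the steady-state baseline,
  ``relative level = efficiency ** -((CT_target - CT_ref)_x - (CT_target - CT_ref)_0)``
  with perfect per-cycle doubling (efficiency 2) by default.

* Northern-blot band quantification: each target band's phosphor-imager
  intensity is divided by the spike-in transcript band in the same lane
  (cancelling loading and exposure), then expressed relative to the mean of
  the steady-state lanes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd


def _mean_ct(ct: float | Sequence[float], name: str) -> float:
    arr = np.atleast_1d(np.asarray(ct, dtype=float))
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"{name}: CT values must be finite and positive")
    return float(arr.mean())


def ddct_ratio(
    ct_target_x: float | Sequence[float],
    ct_ref_x: float | Sequence[float],
    ct_target_0: float | Sequence[float],
    ct_ref_0: float | Sequence[float],
    efficiency: float = 2.0,
) -> float:
    """Relative RNA level at condition x vs baseline 0 by the ddCT method.

    Replicate CTs are arithmetic-mean averaged before differencing.  The
    result is invariant to adding a constant to all four CTs (plate offset).
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    d_x = _mean_ct(ct_target_x, "ct_target_x") - _mean_ct(ct_ref_x, "ct_ref_x")
    d_0 = _mean_ct(ct_target_0, "ct_target_0") - _mean_ct(ct_ref_0, "ct_ref_0")
    return float(efficiency ** -(d_x - d_0))


def northern_relative(
    bands: pd.DataFrame,
    reference_band_id: str,
    steady_lanes: Sequence[str],
) -> pd.DataFrame:
    """Per-lane band intensities normalized to the in-lane reference band.

    ``bands`` is long-format with columns ``lane``, ``band_id``,
    ``intensity``.  For each target band the in-lane target/reference ratio
    is divided by the mean ratio over the steady-state lanes, so the steady
    lanes average to 1 by construction and the result is invariant to
    rescaling all intensities within a lane (exposure invariance).
    """
    required = {"lane", "band_id", "intensity"}
    missing = required - set(bands.columns)
    if missing:
        raise ValueError(f"bands table missing columns: {sorted(missing)}")
    if (bands["intensity"] < 0).any():
        raise ValueError("band intensities must be non-negative")
    wide = bands.pivot_table(
        index="lane", columns="band_id", values="intensity", aggfunc="sum"
    )
    if reference_band_id not in wide.columns:
        raise ValueError(f"reference band {reference_band_id!r} not present")
    ref = wide[reference_band_id]
    if ref.isna().any() or (ref == 0).any():
        bad = ref.index[ref.isna() | (ref == 0)].tolist()
        raise ValueError(f"missing or zero reference intensity in lane(s) {bad}")
    steady_lanes = list(steady_lanes)
    if not steady_lanes:
        raise ValueError("need at least one steady-state lane")
    missing_lanes = set(steady_lanes) - set(wide.index)
    if missing_lanes:
        raise ValueError(f"steady lanes absent from table: {sorted(missing_lanes)}")
    targets = [c for c in wide.columns if c != reference_band_id]
    ratios = wide[targets].div(ref, axis=0)
    baseline = ratios.loc[steady_lanes].mean(axis=0)
    if (baseline == 0).any():
        bad = baseline.index[baseline == 0].tolist()
        raise ValueError(f"zero steady-state signal for band(s) {bad}")
    return ratios.div(baseline, axis=1)
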