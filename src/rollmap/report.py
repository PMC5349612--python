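"""Summary statistics for the reporting stage."""

from __future__ import annotations

import numpy as np
import pandas as pd


def periodicity_prevalence(n_periodic: int, n_total: int) -> float:
    """Percentage of footprint tracks exhibiting periodicity."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_periodic <= n_total:
        raise ValueError("n_periodic must lie in [0, n_total]")
    return 100.0 * n_periodic / n_total


def summarize_tracks(per_track: pd.DataFrame) -> dict:
    """Aggregate a per-track table (period_um, width_um, area_um2, fraction_pct).

    Missing periods (aperiodic tracks) are excluded from the period mean but
    counted in the prevalence.
    """
    out: dict = {"n_tracks": int(len(per_track))}
    if "period_um" in per_track:
        periodic = per_track["period_um"].notna()
        out["n_periodic"] = int(periodic.sum())
        if len(per_track):
            out["prevalence_pct"] = periodicity_prevalence(
                out["n_periodic"], out["n_tracks"]
            )
        if periodic.any():
            out["period_um_mean"] = float(per_track.loc[periodic, "period_um"].mean())
            out["diameter_um_mean"] = float(
                (per_track.loc[periodic, "period_um"] / np.pi).mean()
            )
    for col in ("width_um", "area_um2", "fraction_pct"):
        if col in per_track and per_track[col].notna().any():
            out[f"{col}_mean"] = float(per_track[col].mean())
    return out
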