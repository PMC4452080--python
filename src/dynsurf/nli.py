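"""Zone-resolved nuclear labeling index (NLI).

NLI (%) is the ratio of BrdU-labeled (newly synthesized) nuclei to all
nuclei, a proxy for growth activity.  Nuclei are binned by migration
distance from the initial pattern; per zone, the headline estimate is the
*mean of per-chip ratios* over replicate substrate chips (not the pooled
ratio), with dispersion reported as the across-chip SEM — so each chip is
the experimental unit.  With a single chip, mean-of-chips and pooled
ratio coincide.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .geometry import PatternSpec, assign_zone, zone_band

__all__ = ["compute_nli", "nli_profile_table"]

_COLUMNS = [
    "zone",
    "zone_lo_um",
    "zone_hi_um",
    "n_total",
    "n_labeled",
    "nli_pct",
    "sem_pct",
    "n_chips",
]


def compute_nli(
    records: pd.DataFrame, pattern: PatternSpec, min_count: int = 5
) -> pd.DataFrame:
    """NLI per migration-distance zone with across-chip dispersion.

    ``records`` needs columns ``chip``, ``x_um``, ``y_um``, ``labeled``.
    Chips contributing fewer than ``min_count`` nuclei to a zone are
    excluded from that zone (0/1-count ratios are unstable); a zone with
    no qualifying chip is omitted with a warning.  Returns one row per
    zone with pooled counts, mean NLI (%), SEM (%) across chips (missing
    when only one chip qualifies), and the number of qualifying chips.
    """
    if len(records) == 0:
        raise ValueError("no nucleus records: cannot compute NLI")
    df = records.copy()
    df["zone"] = assign_zone(df[["x_um", "y_um"]].to_numpy(dtype=float), pattern)
    per_chip = (
        df.groupby(["zone", "chip"], sort=True)["labeled"]
        .agg(n_total="size", n_labeled="sum")
        .reset_index()
    )
    rows = []
    for zone, grp in per_chip.groupby("zone", sort=True):
        ok = grp[grp["n_total"] >= min_count]
        if ok.empty:
            warnings.warn(
                f"zone {zone}: no chip with >= {min_count} nuclei; zone omitted",
                stacklevel=2,
            )
            continue
        chip_nli = 100.0 * ok["n_labeled"] / ok["n_total"]
        n_chips = len(ok)
        # SEM = (population SD of per-chip NLIs) / sqrt(n_chips)
        sem = float(chip_nli.std(ddof=0) / np.sqrt(n_chips)) if n_chips >= 2 else np.nan
        lo, hi = zone_band(int(zone), pattern)
        rows.append(
            {
                "zone": int(zone),
                "zone_lo_um": lo,
                "zone_hi_um": hi,
                "n_total": int(ok["n_total"].sum()),
                "n_labeled": int(ok["n_labeled"].sum()),
                "nli_pct": float(chip_nli.mean()),
                "sem_pct": sem,
                "n_chips": n_chips,
            }
        )
    return pd.DataFrame(rows, columns=_COLUMNS)


def _band_label(row: pd.Series) -> str:
    if row["zone"] == 0:
        return "0 um (within pattern)"
    return f"({row['zone_lo_um']:g}–{row['zone_hi_um']:g}] um"


def nli_profile_table(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Tidy multi-condition NLI table for reporting.

    ``results`` maps condition label to the frame returned by
    :func:`compute_nli`.  Output columns: condition, zone, distance band
    string, nli_pct, sem_pct, n_total, n_labeled, n_chips; zones sorted
    increasing within each condition.
    """
    cols = ["condition", "zone", "distance_band", "nli_pct", "sem_pct", "n_total", "n_labeled", "n_chips"]
    frames = []
    for condition, res in results.items():
        if res.empty:
            continue
        out = res.sort_values("zone").copy()
        out["condition"] = condition
        out["distance_band"] = out.apply(_band_label, axis=1)
        frames.append(out[cols])
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)
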