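"""Per-fiber myosin energetics derived from DRX/SRX decay fits.

The resting ATP consumption of a fiber follows from the fitted state
proportions and lifetimes under the standard assumption that the myosin-head
concentration in a single fiber is 220 uM: each head population turns over
one ATP per lifetime, so

    ATP (uM / fiber / min) = (P1/100) * C * (60/T1) + (P2/100) * C * (60/T2)

with C = 220 uM, P1/P2 in percent and T1/T2 in seconds.  Temperature
sensitivity is summarized per matched animal as the ratio of its 20 C mean to
its 8 C mean (per fiber type), and condition contrasts as signed percent
change versus a named baseline group.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "atp_consumption",
    "add_atp_consumption",
    "temperature_ratios",
    "percent_difference",
]

logger = logging.getLogger(__name__)

DEFAULT_HEAD_CONCENTRATION_UM = 220.0


def atp_consumption(p1_pct, t1_s, p2_pct, t2_s, head_concentration_uM=DEFAULT_HEAD_CONCENTRATION_UM):
    """Myosin ATP consumption of one fiber, uM ATP per minute.

    ``(p1_pct/100)*C*(60/t1_s) + (p2_pct/100)*C*(60/t2_s)``, vectorized.
    Lifetimes must be positive.
    """
    t1_s = np.asarray(t1_s, float)
    t2_s = np.asarray(t2_s, float)
    if np.any(t1_s <= 0) or np.any(t2_s <= 0):
        raise ValueError("lifetimes must be positive to compute ATP consumption")
    c = head_concentration_uM
    out = (np.asarray(p1_pct, float) / 100.0) * c * (60.0 / t1_s) + (
        np.asarray(p2_pct, float) / 100.0
    ) * c * (60.0 / t2_s)
    return out if out.shape else float(out)


def add_atp_consumption(fits: pd.DataFrame, head_concentration_uM=DEFAULT_HEAD_CONCENTRATION_UM) -> pd.DataFrame:
    """Attach an ``atp_consumption_uM_per_min`` column to an accepted-fit table."""
    if not fits["converged"].all():
        raise ValueError("fiber records require accepted (converged) fits only")
    out = fits.copy()
    out["atp_consumption_uM_per_min"] = atp_consumption(
        out["p1_pct"].to_numpy(),
        out["t1_s"].to_numpy(),
        out["p2_pct"].to_numpy(),
        out["t2_s"].to_numpy(),
        head_concentration_uM,
    )
    return out


def temperature_ratios(
    records: pd.DataFrame,
    warm_C: float = 20.0,
    cold_C: float = 8.0,
    metrics=("t1_s", "t2_s", "atp_consumption_uM_per_min"),
) -> pd.DataFrame:
    """Warm/cold ratios of animal means, per animal x condition x fiber type.

    For every animal with accepted fibers at both temperatures for a given
    fiber type, computes (mean at ``warm_C``) / (mean at ``cold_C``) for each
    metric.  Animals missing one temperature are omitted with a logged
    warning.  Returns columns animal_id, condition, fiber_type and
    ``ratio_<metric>``.
    """
    keys = ["animal_id", "condition", "fiber_type"]
    means = (
        records.groupby(keys + ["temperature_C"], sort=True)[list(metrics)]
        .mean()
        .reset_index()
    )
    warm = means[means["temperature_C"] == warm_C].set_index(keys)
    cold = means[means["temperature_C"] == cold_C].set_index(keys)

    rows = []
    for key in warm.index.union(cold.index):
        if key not in warm.index or key not in cold.index:
            logger.warning(
                "animal %s (%s, type %s): fibers at only one temperature; "
                "no ratio computed",
                *key,
            )
            continue
        row = dict(zip(keys, key))
        for m in metrics:
            row[f"ratio_{m}"] = float(warm.loc[key, m] / cold.loc[key, m])
        rows.append(row)
    return pd.DataFrame(rows, columns=keys + [f"ratio_{m}" for m in metrics])


def percent_difference(mean_a, mean_b) -> float:
    """Signed percent change of group b versus baseline group a.

    ``100 * (mean_b - mean_a) / mean_a``; a value 35% *lower* than baseline
    is reported as -35.  Raises if the baseline mean is zero.
    """
    if mean_a == 0:
        raise ValueError("baseline mean is zero; percent difference undefined")
    return 100.0 * (mean_b - mean_a) / mean_a
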