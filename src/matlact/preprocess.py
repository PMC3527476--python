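"""Record filtering, 305-d standardization and maternal-circumstance coding.

The analysis unit is a first-lactation cow with a recorded dam.  This module
applies the record filters (abortion before first lactation, first-lactation
milk below 1,000 kg, unknown pedigree, unrecorded dam, missing conception
date), standardizes lactation yields to a 305-d basis, and assigns every
retained cow her three maternal exposures:

* ``lact_group``  -- 0 if no dam lactation was open on the conception date,
  else the parity of the open lactation collapsed to {1, 2, 3+};
* ``yield_group`` -- 0 for non-lactating dams, else the decile (1..10) of the
  dam's daily milk at conception against the population decile boundaries,
  with left-open/right-closed intervals;
* ``mastitis``    -- 1 if any dam somatic-cell test inside the exposure
  window (conception to 220 d of gestation) exceeds the threshold
  (default 400,000 cells/ml).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree


class PreprocessError(ValueError):
    pass


# ---------------------------------------------------------------------------
# record filters
# ---------------------------------------------------------------------------

def apply_filters(
    phenotypes: pd.DataFrame,
    testdays: pd.DataFrame,
    pedigree: Pedigree | None = None,
    min_milk_kg: float = 1000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the record filters; returns ``(retained, exclusion_log)``.

    The exclusion log has one row per dropped cow with columns
    ``cow_id, rule, value``.  Filtering is total (never raises) and
    order-stable; applying it twice is a no-op.
    """
    df = phenotypes
    log_rows: list[tuple[str, str, str]] = []
    drop = pd.Series(False, index=df.index)

    def mark(mask: pd.Series, rule: str, value: pd.Series | str) -> None:
        new = mask & ~drop
        for i in df.index[new]:
            v = value if isinstance(value, str) else str(value.loc[i])
            log_rows.append((df.at[i, "cow_id"], rule, v))
        drop[new] = True

    if "abortion_before_first" in df.columns:
        mark(df["abortion_before_first"].astype(bool), "abortion before first lactation", "1")
    milk = df["milk_cum_kg"] if "milk_cum_kg" in df.columns else df["MY"]
    mark(milk < min_milk_kg, f"below {min_milk_kg:.0f} kg", milk)
    if pedigree is not None:
        known = df["cow_id"].isin(pedigree.index.keys())
        mark(~known, "unknown pedigree", "not in pedigree")
        dam_known = df["dam_id"].isin(pedigree.index.keys())
        mark(~dam_known, "unknown pedigree", "dam not in pedigree")
    recorded_dams = set(testdays["dam_id"].unique()) if len(testdays) else set()
    mark(~df["dam_id"].isin(recorded_dams), "dam unrecorded", "no dam lactation records")
    if "conception_date" in df.columns:
        mark(df["conception_date"].isna(), "missing conception date", "NA")

    log = pd.DataFrame(log_rows, columns=["cow_id", "rule", "value"])
    return df[~drop].reset_index(drop=True), log


# ---------------------------------------------------------------------------
# 305-d standardization
# ---------------------------------------------------------------------------

def standardize_305(
    cumulative_yield, lactation_length, max_length: float = 400.0
):
    """Rescale a cumulative lactation yield to a 305-d basis.

    ``yield * 305 / length``; lengths above ``max_length`` are truncated to
    ``max_length`` before scaling (records beyond that are treated as
    recording artefacts rather than production).  Identity at 305 d.
    Raises on non-positive lengths.
    """
    y = np.asarray(cumulative_yield, dtype=float)
    length = np.asarray(lactation_length, dtype=float)
    if np.any(length <= 0):
        raise PreprocessError("non-positive lactation length")
    return y * 305.0 / np.minimum(length, max_length)


# ---------------------------------------------------------------------------
# maternal circumstance
# ---------------------------------------------------------------------------

def compute_decile_bounds(dam_daily_milk) -> np.ndarray:
    """Empirical 10th..90th percentile boundaries (linear interpolation).

    Groups are assigned left-open/right-closed, so boundaries need not split
    tied values into equal-sized groups.
    """
    v = np.asarray(dam_daily_milk, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 10:
        raise PreprocessError("need at least 10 lactating-dam values for decile bounds")
    return np.percentile(v, np.arange(10, 100, 10))


def yield_group_of(daily_milk, bounds: np.ndarray) -> np.ndarray:
    """Decile group 1..10 for a lactating dam's daily milk (right-closed)."""
    return np.searchsorted(np.asarray(bounds), np.asarray(daily_milk, dtype=float),
                           side="left") + 1


@dataclass
class CircumstanceConfig:
    scc_threshold: float = 400.0         # 1000 cells/ml
    gestation_window_d: float = 220.0    # mastitis exposure window length
    milk_at_conception: str = "nearest"  # or "interpolated"
    concurrence_rule: str = "open"       # or "first220": any overlap of the
                                         # lactation with the first 220 d of
                                         # pregnancy counts as concurrent


def assign_circumstance(
    cows: pd.DataFrame,
    testdays: pd.DataFrame,
    decile_bounds: np.ndarray | None = None,
    config: CircumstanceConfig | None = None,
) -> pd.DataFrame:
    """Maternal-circumstance row for every cow.

    ``cows`` needs ``cow_id, dam_id, conception_date``; ``testdays`` is the
    dam milk-recording table (``dam_id, parity, calving_date, dryoff_date,
    test_date, dim, milk_kg, scc_1000``).  When ``decile_bounds`` is None the
    boundaries are computed from the lactating dams of this data set.
    Raises when a conception date falls outside the dam's recorded lifetime.
    """
    config = config or CircumstanceConfig()
    td = testdays.sort_values(["dam_id", "parity", "dim"], kind="stable")
    day = pd.Timedelta(days=1)
    origin = pd.Timestamp("1970-01-01")

    # per-dam numpy views: (parity, calving, dryoff, test_day, dim, milk, scc)
    dam_data: dict[str, tuple] = {}
    for dam, g in td.groupby("dam_id", sort=False):
        dam_data[dam] = (
            g["parity"].to_numpy(dtype=np.int64),
            ((pd.to_datetime(g["calving_date"]) - origin) / day).to_numpy(),
            ((pd.to_datetime(g["dryoff_date"]) - origin) / day).to_numpy(),
            ((pd.to_datetime(g["test_date"]) - origin) / day).to_numpy(),
            g["dim"].to_numpy(dtype=float),
            g["milk_kg"].to_numpy(dtype=float),
            g["scc_1000"].to_numpy(dtype=float),
        )

    n = len(cows)
    lact_group = np.zeros(n, dtype=int)
    parity_open = np.zeros(n, dtype=int)
    daily = np.full(n, np.nan)
    mastitis = np.zeros(n, dtype=int)
    win = float(config.gestation_window_d)
    conc_days = ((pd.to_datetime(cows["conception_date"]) - origin) / day).to_numpy()

    for k, (cow, dam, conc) in enumerate(
        zip(cows["cow_id"], cows["dam_id"], conc_days)
    ):
        if dam not in dam_data:
            raise PreprocessError(f"dam {dam!r} of cow {cow!r} has no lactation records")
        parity, calving, dryoff, tdate, tdim, tmilk, tscc = dam_data[dam]
        if conc < calving.min() - 310.0 or conc > dryoff.max() + 420.0:
            raise PreprocessError(
                f"conception date of cow {cow!r} outside dam {dam!r}'s recorded lifetime"
            )
        if config.concurrence_rule == "open":
            open_m = (calving <= conc) & (conc < dryoff)
        else:  # lactation overlapping the first 220 d of pregnancy
            open_m = (calving <= conc + win) & (conc < dryoff)
        if open_m.any():
            j = int(np.argmax(open_m))
            p = int(parity[j])
            parity_open[k] = p
            lact_group[k] = min(p, 3)
            in_lact = parity == p
            dim_c = conc - calving[j]
            if config.milk_at_conception == "interpolated" and in_lact.sum() > 1:
                daily[k] = np.interp(dim_c, tdim[in_lact], tmilk[in_lact])
            else:
                dsel = tdim[in_lact]
                daily[k] = tmilk[in_lact][np.abs(dsel - dim_c).argmin()]
        # mastitis exposure: any high-SCC dam test inside the window
        in_win = (tdate >= conc) & (tdate <= conc + win)
        if np.any(tscc[in_win] > config.scc_threshold):
            mastitis[k] = 1

    lactating = lact_group > 0
    if decile_bounds is None:
        decile_bounds = compute_decile_bounds(daily[lactating])
    yield_group = np.zeros(n, dtype=int)
    yield_group[lactating] = yield_group_of(daily[lactating], decile_bounds)

    return pd.DataFrame(
        {
            "cow_id": cows["cow_id"].to_numpy(),
            "lact_group": lact_group,
            "parity_open": parity_open,
            "yield_group": yield_group,
            "dam_daily_milk": daily,
            "mastitis": mastitis,
        }
    )
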