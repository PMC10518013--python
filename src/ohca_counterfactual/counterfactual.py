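"""Minute-level counterfactual adjustment of EMS activity times.

For a factor pair — transport time crossed with defibrillation time, or
transport crossed with drug-administration time — every (δ_transport,
δ_intervention) cell of an integer grid shifts both times jointly across the
eligible test records, re-encodes them with the *fitted* schema, and averages
the model's predicted CPC1/2 probability.  Each cell is summarised as the
percent change of that mean against the unadjusted (0, 0) baseline; stratified
by prefecture, the surface shows which local time reductions are associated
with the largest predicted-outcome gains.

Eligibility mirrors the intervention's clinical applicability: the
defibrillation pair keeps only shockable initial rhythms (VF / pulseless VT),
the drug pair drops EMS-witnessed arrests.  The excluded records leave the
whole grid, baseline included, so every cell averages over the same
denominator.  Shifted times clip at 1 minute and absent interventions are
never shifted: a δ moves an existing time, it cannot create or remove an
intervention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import FeatureSchema, encode
from .synthetic import SHOCKABLE_RHYTHMS, TIME_FACTOR_COLUMNS

logger = logging.getLogger(__name__)

FACTOR_PAIRS = {
    "transport_defib": ("transport", "defib"),
    "transport_drug": ("transport", "drug"),
}


@dataclass(frozen=True)
class AdjustmentSpec:
    """Declarative description of one perturbation grid."""

    factor_pair: str = "transport_defib"
    delta_transport_range: tuple[int, int] = (-5, 10)
    delta_intervention_range: tuple[int, int] = (-5, 5)
    apply_eligibility: bool = True
    clip_floor: int = 1

    def __post_init__(self) -> None:
        if self.factor_pair not in FACTOR_PAIRS:
            raise ValueError(f"unknown factor pair {self.factor_pair!r}")
        for lo, hi in (self.delta_transport_range, self.delta_intervention_range):
            if not (lo <= 0 <= hi):
                raise ValueError("delta ranges must contain 0 (the baseline cell)")

    @property
    def transport_deltas(self) -> list[int]:
        lo, hi = self.delta_transport_range
        return list(range(lo, hi + 1))

    @property
    def intervention_deltas(self) -> list[int]:
        lo, hi = self.delta_intervention_range
        return list(range(lo, hi + 1))

    @property
    def intervention_factor(self) -> str:
        return FACTOR_PAIRS[self.factor_pair][1]


@dataclass
class CounterfactualGrid:
    """Evaluated percent-change surface for one stratum."""

    spec: AdjustmentSpec
    stratum: str  # "all" or "prefecture_<k>"
    n_eligible: int
    baseline_mean: float
    cells: pd.DataFrame  # delta_transport, delta_intervention, mean_pred, pct_change

    def pct_change(self, delta_transport: int, delta_intervention: int) -> float:
        m = self.cells[
            (self.cells["delta_transport"] == delta_transport)
            & (self.cells["delta_intervention"] == delta_intervention)
        ]
        if m.empty:
            raise KeyError((delta_transport, delta_intervention))
        return float(m["pct_change"].iloc[0])

    def to_matrix(self) -> pd.DataFrame:
        """Pivot: rows = δ_intervention, columns = δ_transport."""
        return self.cells.pivot(
            index="delta_intervention", columns="delta_transport", values="pct_change"
        )


def eligible_subset(test: pd.DataFrame, spec: AdjustmentSpec) -> pd.DataFrame:
    """Records to which the factor pair applies (used for every cell)."""
    if not spec.apply_eligibility:
        return test
    if spec.factor_pair == "transport_defib":
        subset = test[test["initial_rhythm"].isin(SHOCKABLE_RHYTHMS)]
    else:
        subset = test[test["ems_witnessed"] == "no"]
    if len(subset) == 0:
        raise ValueError(f"no eligible records for {spec.factor_pair}")
    return subset


def apply_time_adjustment(
    table: pd.DataFrame, factor: str, delta: int, clip_floor: int = 1
) -> pd.DataFrame:
    """Shift one activity time by ``delta`` minutes where it exists.

    Absent interventions (NaN times) stay absent; shifted times clip at
    ``clip_floor``.  Returns a copy; the input is not mutated.
    """
    if factor not in TIME_FACTOR_COLUMNS:
        raise ValueError(f"unknown time factor {factor!r}")
    col = TIME_FACTOR_COLUMNS[factor]
    out = table.copy()
    t = out[col].to_numpy(float)
    present = ~np.isnan(t)
    t[present] = np.maximum(clip_floor, t[present] + delta)
    out[col] = t
    return out


def simulate_grid(
    model,
    schema: FeatureSchema,
    test: pd.DataFrame,
    spec: AdjustmentSpec,
    stratum: str = "all",
    count_mode: str = "expected",
    threshold: float = 0.5,
) -> CounterfactualGrid:
    """Evaluate the full percent-change surface for one stratum.

    ``count_mode="expected"`` averages predicted probabilities (the expected
    CPC1/2 count per record); ``"thresholded"`` averages hard 0/1 calls at
    ``threshold``.  The baseline is the (0, 0) cell of the same eligible
    subset, so its percent change is exactly zero by construction.
    """
    if count_mode not in ("expected", "thresholded"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    if stratum != "all":
        k = int(stratum.split("_")[-1])
        test = test[test["prefecture"] == k]
    subset = eligible_subset(test, spec)
    if len(subset) == 0:
        raise ValueError(f"empty stratum {stratum!r} after eligibility")

    ifactor = spec.intervention_factor
    n_overflow = 0
    means: dict[tuple[int, int], float] = {}
    for dt in spec.transport_deltas:
        adj_t = apply_time_adjustment(subset, "transport", dt, spec.clip_floor)
        for di in spec.intervention_deltas:
            adj = apply_time_adjustment(adj_t, ifactor, di, spec.clip_floor)
            for fac in ("transport", ifactor):
                col = TIME_FACTOR_COLUMNS[fac]
                t_max = schema.time_specs[col].t_max
                n_overflow += int((adj[col] > t_max).sum())
            p = np.asarray(model.predict_proba(encode(adj, schema)), float)
            if count_mode == "thresholded":
                p = (p >= threshold).astype(float)
            means[(dt, di)] = float(p.mean())
    if n_overflow:
        logger.info("%d adjusted time(s) fell in an overflow bin", n_overflow)

    baseline = means[(0, 0)]
    rows = [
        {
            "delta_transport": dt,
            "delta_intervention": di,
            "mean_pred": m,
            "pct_change": 100.0 * (m - baseline) / baseline,
        }
        for (dt, di), m in means.items()
    ]
    return CounterfactualGrid(
        spec=spec,
        stratum=stratum,
        n_eligible=len(subset),
        baseline_mean=baseline,
        cells=pd.DataFrame(rows),
    )


def per_prefecture_grids(
    model,
    schema: FeatureSchema,
    test: pd.DataFrame,
    spec: AdjustmentSpec,
    n_min: int = 50,
    count_mode: str = "expected",
) -> list[CounterfactualGrid]:
    """One grid per prefecture with at least ``n_min`` eligible records."""
    grids = []
    for k in sorted(test["prefecture"].unique()):
        sub = test[test["prefecture"] == k]
        try:
            n_elig = len(eligible_subset(sub, spec))
        except ValueError:
            n_elig = 0
        if n_elig < n_min:
            logger.warning(
                "prefecture %d skipped: %d eligible records (< %d)", k, n_elig, n_min
            )
            continue
        grids.append(
            simulate_grid(model, schema, sub, spec, stratum=f"prefecture_{k}",
                          count_mode=count_mode)
        )
    return grids


def best_adjustment(grid: CounterfactualGrid) -> tuple[int, int, float]:
    """Cell with the largest percent change.

    Ties break toward the smallest total absolute adjustment, then toward
    transport reduction (more negative δ_transport first).
    """
    cells = grid.cells
    key = sorted(
        cells.itertuples(index=False),
        key=lambda r: (
            -r.pct_change,
            abs(r.delta_transport) + abs(r.delta_intervention),
            r.delta_transport,
            r.delta_intervention,
        ),
    )[0]
    return int(key.delta_transport), int(key.delta_intervention), float(key.pct_change)


def grids_to_long_frame(grids: list[CounterfactualGrid]) -> pd.DataFrame:
    """Long-format export: one row per (stratum, δ, δ) cell."""
    frames = []
    for g in grids:
        df = g.cells.copy()
        df.insert(0, "stratum", g.stratum)
        df.insert(1, "factor_pair", g.spec.factor_pair)
        df["n_eligible"] = g.n_eligible
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
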