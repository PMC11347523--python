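"""Synthetic morphometry cohorts with planted, known age-sensitivity.

Real regional-morphometry cohorts for brain-age work sit behind managed
access, so every downstream stage here is exercised on simulated tables
whose ground truth is known exactly. Each feature follows a deterministic
age trajectory plus independent Gaussian measurement noise:

    value = baseline + slope * age + quad * age^2 + sex_offset * [male] + N(0, sd)

truncated below at 1% of baseline to preserve positivity. The default
aging preset emulates the qualitative structure cross-sectional aging
studies report: declining GMV and cortical thickness, increasing CSF,
weakly non-monotone WMV (inverted-U peaking in midlife), region-specific
sensitivity, and a modest male offset on volumes.

The planted "truth" is the standardized effect size of each feature —
the range of its deterministic trajectory over the cohort age span,
divided by its noise sd — from which per-measure ground-truth region
rankings are derived for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .schema import (
    MEASURES,
    VOLUME_MEASURES,
    FeatureTable,
    RegionSchema,
    feature_name,
    parse_feature_name,
    write_results,
)

__all__ = ["TrajectoryParams", "SyntheticTruth", "simulate_cohort", "default_aging_preset"]

AGE_RANGE_DEFAULT = (18.0, 88.0)

# Per-measure generative settings for the default preset. Baselines and
# noise sds are order-of-magnitude plausible for regional cortical
# morphometry (mm^3 for volumes, mm for thickness); e_max/e_min are the
# standardized effect sizes (trajectory range over the age span, in noise-sd
# units) of the most and least age-sensitive region for that measure. The
# scales are set so the expected MI ordering across measures is
# GMV > CSF > CT > WMV and the planted top region of each measure is
# separated from its runner-up by several times the KSG sampling noise at
# cohort scale (see docs/methods.md for the calculation).
_PRESET_MEASURE = {
    "GMV": dict(baseline=12000.0, sd=900.0, e_max=4.5, e_min=0.40, sign=-1),
    "CSF": dict(baseline=2500.0, sd=350.0, e_max=3.4, e_min=0.35, sign=+1),
    "CT": dict(baseline=2.6, sd=0.13, e_max=2.8, e_min=0.30, sign=-1),
    "WMV": dict(baseline=9000.0, sd=500.0, e_max=2.8, e_min=0.50, sign=0),
}
_WMV_PEAK_AGE = 75.0  # weakly non-monotone: rises to 75 y, then declines
# effect-size fractions (of e_max) for the pinned front regions of each
# measure; the non-pinned tail then runs linearly from _TAIL_FRAC to e_min.
_FRONT_FRACS = {
    "GMV": (1.0, 0.93, 0.88),  # pre-central, superior frontal, cingulate
    "WMV": (1.0, 0.92),  # insula, superior frontal
    "CSF": (1.0,),  # cingulate
    "CT": (1.0,),  # superior temporal
}
_TAIL_FRAC = 0.75
_MALE_VOLUME_OFFSET_FRAC = 0.08  # +8% on volume baselines for males
_TRUNCATION_FLOOR_FRAC = 0.01  # positivity floor, fraction of baseline


@dataclass
class TrajectoryParams:
    """Per-feature trajectory coefficients plus cohort-level settings.

    ``per_feature`` is indexed by feature name with columns
    ``baseline, slope, quad, sex_offset, noise_sd``.
    """

    per_feature: pd.DataFrame
    age_range: tuple[float, float] = AGE_RANGE_DEFAULT
    sex_ratio: float = 0.5  # fraction of males
    n_subjects: int = 600
    seed: int = 0
    head_size_sd: float = 0.0  # optional shared log-normal scaling on volumes

    def __post_init__(self) -> None:
        req = {"baseline", "slope", "quad", "sex_offset", "noise_sd"}
        missing = req - set(self.per_feature.columns)
        if missing:
            raise ValueError(f"per_feature missing columns: {sorted(missing)}")
        if (self.per_feature["noise_sd"] < 0).any():
            raise ValueError("noise sd must be non-negative")
        if (self.per_feature["baseline"] <= 0).any():
            raise ValueError("baselines must be positive")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0, 1]")

    def trajectory(self, name: str, ages: np.ndarray) -> np.ndarray:
        """Deterministic (noise-free, female) trajectory of one feature."""
        row = self.per_feature.loc[name]
        return row["baseline"] + row["slope"] * ages + row["quad"] * ages**2


@dataclass
class SyntheticTruth:
    """Planted per-feature effect sizes and the region rankings they imply."""

    effect_sizes: dict[str, float]

    def region_effects(self, measure: str) -> dict[str, float]:
        """Per-region effect size for one measure, averaged over hemispheres."""
        acc: dict[str, list[float]] = {}
        for name, e in self.effect_sizes.items():
            region, _, m = parse_feature_name(name)
            if m == measure:
                acc.setdefault(region, []).append(e)
        return {r: float(np.mean(v)) for r, v in acc.items()}

    def ranking(self, measure: str) -> list[str]:
        """Regions ordered by descending effect size (ties by label)."""
        eff = self.region_effects(measure)
        return sorted(eff, key=lambda r: (-eff[r], r))

    def top_region(self, measure: str) -> str:
        return self.ranking(measure)[0]

    def to_dict(self) -> dict:
        return {"effect_sizes": {k: float(v) for k, v in self.effect_sizes.items()}}

    def write(self, path: str | Path) -> None:
        write_results(self, path)


def _effect_size(params: TrajectoryParams, name: str) -> float:
    """Range of the deterministic trajectory over the age span, in sd units."""
    lo, hi = params.age_range
    ages = np.linspace(lo, hi, 701)
    traj = params.trajectory(name, ages)
    rng_ = float(traj.max() - traj.min())
    sd = float(params.per_feature.loc[name, "noise_sd"])
    if sd == 0:
        return float("inf") if rng_ > 0 else 0.0
    return rng_ / sd


def planted_truth(params: TrajectoryParams) -> SyntheticTruth:
    return SyntheticTruth(
        {name: _effect_size(params, name) for name in params.per_feature.index}
    )


def simulate_cohort(
    params: TrajectoryParams,
    schema: RegionSchema,
    n: int | None = None,
    seed: int | None = None,
) -> tuple[FeatureTable, SyntheticTruth]:
    """Draw a cohort from *params* and return it with its planted truth.

    ``n`` and ``seed`` override the cohort-level values stored on *params*.
    Identical (params, n, seed) yield an identical table.
    """
    n = params.n_subjects if n is None else int(n)
    seed = params.seed if seed is None else int(seed)
    if n < 0:
        raise ValueError("number of subjects must be non-negative")
    names = schema.feature_names()
    missing = [x for x in names if x not in params.per_feature.index]
    if missing:
        raise ValueError(f"params lack trajectory for feature(s): {missing[:5]}")

    rng = np.random.default_rng(seed)
    lo, hi = params.age_range
    ages = rng.uniform(lo, hi, size=n)
    is_male = rng.random(n) < params.sex_ratio
    noise = rng.standard_normal((n, len(names)))

    p = params.per_feature.loc[names]
    baseline = p["baseline"].to_numpy()
    slope = p["slope"].to_numpy()
    quad = p["quad"].to_numpy()
    sex_off = p["sex_offset"].to_numpy()
    sd = p["noise_sd"].to_numpy()

    values = (
        baseline[None, :]
        + slope[None, :] * ages[:, None]
        + quad[None, :] * ages[:, None] ** 2
        + sex_off[None, :] * is_male[:, None]
        + noise * sd[None, :]
    )
    if params.head_size_sd > 0:
        factor = np.exp(rng.normal(0.0, params.head_size_sd, size=n))
        is_volume = np.array(
            [parse_feature_name(x)[2] in VOLUME_MEASURES for x in names]
        )
        values[:, is_volume] *= factor[:, None]
    values = np.maximum(values, _TRUNCATION_FLOOR_FRAC * baseline[None, :])

    df = pd.DataFrame(values, columns=names)
    df.insert(0, "sex", np.where(is_male, "male", "female"))
    df.insert(0, "age", ages)
    df.insert(0, "subject_id", [f"S{i:05d}" for i in range(n)])
    table = FeatureTable(df, schema).validate()
    return table, planted_truth(params)


_PLANTED = (
    "pre_central_gyrus",
    "superior_frontal_gyrus",
    "cingulate",
    "insula",
    "superior_temporal_gyrus",
)


def _preset_orders(
    regions: Sequence[str], rng: np.random.Generator
) -> dict[str, list[str]]:
    """Per-measure region sensitivity orders for the default preset.

    The five anchor regions are pinned explicitly per measure; all other
    regions share a single seeded sensitivity order used by every measure,
    emulating the empirical pattern that a region aging quickly in one
    morphometric measure tends to age quickly in the others. The shared
    order also gives the all-measure merged region profile a wide spread,
    so subgroup ranking comparisons are not noise-dominated.
    """
    present = set(regions)
    anchors = [r for r in _PLANTED if r in present]
    rest = [r for r in regions if r not in anchors]
    b = [rest[i] for i in rng.permutation(len(rest))]

    def keep(seq: Sequence[str]) -> list[str]:
        return [r for r in seq if r in present]

    orders = {
        "GMV": keep(["pre_central_gyrus", "superior_frontal_gyrus", "cingulate"])
        + b
        + keep(["superior_temporal_gyrus", "insula"]),
        "WMV": keep(["insula", "superior_frontal_gyrus"])
        + b
        + keep(["superior_temporal_gyrus", "cingulate", "pre_central_gyrus"]),
        "CSF": keep(["cingulate"])
        + b
        + keep(
            [
                "insula",
                "superior_temporal_gyrus",
                "pre_central_gyrus",
                "superior_frontal_gyrus",
            ]
        ),
        "CT": keep(["superior_temporal_gyrus"])
        + b
        + keep(
            [
                "pre_central_gyrus",
                "superior_frontal_gyrus",
                "insula",
                "cingulate",
            ]
        ),
    }
    return orders


def default_aging_preset(
    schema: RegionSchema | None = None, seed: int = 0
) -> TrajectoryParams:
    """The default aging cohort: documented trajectories with planted tops.

    The most age-sensitive region per measure is pinned: pre-central gyrus
    for GMV, cingulate for CSF, superior temporal gyrus for CT, insula for
    WMV; the superior frontal gyrus is planted high in both GMV and WMV so
    it tops the parenchyma (GMV+WMV) combination, and the cingulate's high
    CSF plus high GMV make it top intracranial volume. The planted top of
    each measure carries a deliberate effect-size margin over its
    runner-up; remaining regions get linearly spaced effect sizes in a
    seed-determined order, decorrelated across measures.
    """
    schema = schema or RegionSchema()
    rng = np.random.default_rng(seed)
    orders = _preset_orders(schema.regions, rng)

    rows = {}
    span = AGE_RANGE_DEFAULT[1] - AGE_RANGE_DEFAULT[0]
    for measure in schema.measures:
        cfg = _PRESET_MEASURE[measure]
        order = orders[measure]
        n_r = len(order)
        front_fracs = _FRONT_FRACS[measure][: n_r]
        n_front = len(front_fracs)
        n_tail = n_r - n_front
        for rank, region in enumerate(order):
            if rank < n_front:
                e = front_fracs[rank] * cfg["e_max"]
            else:
                frac = (rank - n_front) / (n_tail - 1) if n_tail > 1 else 0.0
                e = _TAIL_FRAC * cfg["e_max"] - (
                    _TAIL_FRAC * cfg["e_max"] - cfg["e_min"]
                ) * frac
            if measure == "WMV":
                # weakly non-monotone: vertex at _WMV_PEAK_AGE; the range
                # over the age span is |quad| * (peak - age_lo)^2 = e * sd
                depth = (_WMV_PEAK_AGE - AGE_RANGE_DEFAULT[0]) ** 2
                quad = -e * cfg["sd"] / depth
                slope = -2.0 * quad * _WMV_PEAK_AGE
            else:
                quad = 0.0
                slope = cfg["sign"] * e * cfg["sd"] / span
            sex_offset = (
                _MALE_VOLUME_OFFSET_FRAC * cfg["baseline"]
                if measure in VOLUME_MEASURES
                else 0.0
            )
            for hemi in schema.hemispheres:
                rows[feature_name(region, hemi, measure)] = dict(
                    baseline=cfg["baseline"],
                    slope=slope,
                    quad=quad,
                    sex_offset=sex_offset,
                    noise_sd=cfg["sd"],
                )

    per_feature = pd.DataFrame.from_dict(rows, orient="index").loc[
        schema.feature_names()
    ]
    return TrajectoryParams(per_feature=per_feature, seed=seed)


def null_preset(schema: RegionSchema | None = None) -> TrajectoryParams:
    """All slopes zero: features carry no age information at all."""
    schema = schema or RegionSchema()
    params = default_aging_preset(schema, seed=0)
    params.per_feature["slope"] = 0.0
    params.per_feature["quad"] = 0.0
    return params


def reversed_preset(schema: RegionSchema | None = None, seed: int = 0) -> TrajectoryParams:
    """Same trajectories, but the per-measure region sensitivity order is
    exactly reversed — used to plant opposite ground-truth rankings."""
    schema = schema or RegionSchema()
    base = default_aging_preset(schema, seed=seed)
    pf = base.per_feature.copy()
    for measure in schema.measures:
        truth = planted_truth(base)
        order = truth.ranking(measure)
        rev = list(reversed(order))
        remap = dict(zip(order, rev))
        for hemi in schema.hemispheres:
            src_rows = {
                r: pf.loc[feature_name(r, hemi, measure)].copy() for r in order
            }
            for r in order:
                pf.loc[feature_name(r, hemi, measure)] = src_rows[remap[r]]
    out = TrajectoryParams(
        per_feature=pf,
        age_range=base.age_range,
        sex_ratio=base.sex_ratio,
        n_subjects=base.n_subjects,
        seed=base.seed,
        head_size_sd=base.head_size_sd,
    )
    return out
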