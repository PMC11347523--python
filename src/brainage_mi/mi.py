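"""Kraskov (KSG) mutual information and its regional aggregation.

Mutual information I(x; y) = H(x) + H(y) - H(x, y) measures the
reduction in uncertainty about one variable given the other; it is
non-negative, symmetric, and invariant under invertible marginal
transforms, which makes it a model-agnostic score of how much each
morphometric feature "knows" about estimated brain age.

For continuous variables we use the first Kraskov-Stogbauer-Grassberger
k-nearest-neighbor estimator:

    I(X, Y) = psi(k) - < psi(n_x + 1) + psi(n_y + 1) > + psi(N)

where psi is the digamma function, the k-th neighbor distance of each
point is taken in the joint space under the Chebyshev (max-coordinate)
metric, and n_x, n_y count marginal points strictly within that
distance. Values are reported in nats; a raw estimate below zero is
clipped to 0 with the raw value retained.

Aggregation follows the decoding procedure: left and right hemisphere
MI values are summed per region, per-region measure combinations
(parenchyma = GMV+WMV, intracranial = GMV+WMV+CSF) and per-measure
totals are sums of those, and each 33-region ranking is split into
tertiles of 11.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from .schema import (
    MEASURE_COMBINATIONS,
    FeatureTable,
    MeasureCombination,
    RegionSchema,
    ValidationError,
    parse_feature_name,
)

__all__ = [
    "MIEstimate",
    "MIProfile",
    "ksg_mi",
    "plugin_discrete_mi",
    "mi_profile",
    "aggregate_hemispheres",
    "aggregate_measures",
    "rank_and_tertile",
]

LN2 = float(np.log(2.0))
_JITTER_AMPLITUDE = 1e-10  # x feature sd; breaks exact ties only

TERTILE_LABELS = ("highest", "middle", "lowest")


@dataclass(frozen=True)
class MIEstimate:
    """One KSG estimate: clipped value (nats), raw value, k and N used."""

    value: float
    raw: float
    k: int
    n: int

    def in_bits(self) -> float:
        return self.value / LN2

    def to_dict(self) -> dict:
        return {"value": self.value, "raw": self.raw, "k": self.k, "n": self.n}


def _jitter_for(v: np.ndarray, seed: int) -> np.ndarray:
    """Tie-breaking jitter derived from (seed, content) so that the same
    variable always receives the same jitter regardless of argument order
    — ksg_mi(x, y) and ksg_mi(y, x) are then exactly equal."""
    content = zlib.crc32(np.ascontiguousarray(v).tobytes())
    rng = np.random.default_rng([seed & 0x7FFFFFFF, content])
    sd = float(v.std())
    amp = _JITTER_AMPLITUDE * (sd if sd > 0 else 1.0)
    return rng.uniform(-amp, amp, size=v.shape)


def _marginal_counts(v: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """For each i, the number of j != i with |v_j - v_i| < eps_i.

    O(n log n) via a sorted copy and searchsorted, rather than a KD-tree
    per marginal. The k-th joint neighbor of i sits at distance exactly
    eps_i in one coordinate, so the strict inequality is decided at the
    rounding limit; shrinking the radius by a relative 1e-12 margin makes
    its exclusion robust to float rounding (real inter-point gaps are many
    orders of magnitude larger).
    """
    eps = eps * (1.0 - 1e-12)
    order = np.sort(v)
    lo = np.searchsorted(order, v - eps, side="right")
    hi = np.searchsorted(order, v + eps, side="left")
    return hi - lo - 1  # exclude the point itself


def ksg_mi(
    x: np.ndarray, y: np.ndarray, k: int = 3, seed: int = 0
) -> MIEstimate:
    """KSG (algorithm 1) mutual information between two scalar samples.

    The seed drives tie-breaking jitter only; the estimator is otherwise
    deterministic in the data.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k:
        raise ValueError(f"need more than k={k} samples, got n={n}")

    xj = x + _jitter_for(x, seed)
    yj = y + _jitter_for(y, seed)

    joint = np.column_stack([xj, yj])
    tree = cKDTree(joint)
    # distance to the k-th neighbor (excluding self) under the max norm
    dists, _ = tree.query(joint, k=k + 1, p=np.inf)
    eps = dists[:, k]

    n_x = _marginal_counts(xj, eps)
    n_y = _marginal_counts(yj, eps)

    raw = float(
        digamma(k) + digamma(n) - np.mean(digamma(n_x + 1) + digamma(n_y + 1))
    )
    return MIEstimate(value=max(raw, 0.0), raw=raw, k=k, n=n)


def plugin_discrete_mi(joint: np.ndarray) -> float:
    """Exact plug-in MI (nats) of a finite joint probability table.

    Computes H(x), H(y) and H(x, y) by direct entropy summation and
    returns H(x) + H(y) - H(x, y). Serves as a closed-form oracle for the
    continuous estimator on discretized data.
    """
    p = np.asarray(joint, dtype=float)
    if p.ndim != 2:
        raise ValueError("joint table must be 2-D")
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1, got {p.sum()!r}")

    def entropy(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-np.sum(q * np.log(q)))

    return entropy(p.sum(axis=1)) + entropy(p.sum(axis=0)) - entropy(p.ravel())


@dataclass
class MIProfile:
    """Per-feature MI against (corrected) brain age plus all aggregates."""

    feature_mi: dict[str, MIEstimate]
    region_measure: dict[str, dict[str, float]]  # measure -> region -> nats
    combinations: dict[str, dict[str, float]]  # combo name -> region -> nats
    measure_totals: dict[str, float]
    combination_totals: dict[str, float]
    total: float
    tertiles: dict[str, dict[str, str]] | None  # measure/combo -> region -> label
    top_regions: dict[str, list[str]]  # measure/combo -> descending region list
    k: int
    n: int
    seed: int
    units: str = "nats"

    def ranked(self, key: str) -> list[tuple[str, float]]:
        """Regions of one measure or combination, descending by MI."""
        vals = self.region_measure.get(key) or self.combinations.get(key)
        if vals is None:
            raise KeyError(key)
        return sorted(vals.items(), key=lambda kv: (-kv[1], kv[0]))

    def to_dict(self) -> dict:
        return {
            "units": self.units,
            "k": self.k,
            "n": self.n,
            "seed": self.seed,
            "total": self.total,
            "measure_totals": self.measure_totals,
            "combination_totals": self.combination_totals,
            "feature_mi": {k: v.to_dict() for k, v in self.feature_mi.items()},
            "region_measure": self.region_measure,
            "combinations": self.combinations,
            "tertiles": self.tertiles,
            "top_regions": self.top_regions,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MIProfile":
        return cls(
            feature_mi={
                k: MIEstimate(**v) for k, v in d["feature_mi"].items()
            },
            region_measure=d["region_measure"],
            combinations=d["combinations"],
            measure_totals=d["measure_totals"],
            combination_totals=d["combination_totals"],
            total=d["total"],
            tertiles=d["tertiles"],
            top_regions=d["top_regions"],
            k=d["k"],
            n=d["n"],
            seed=d["seed"],
            units=d["units"],
        )


def aggregate_hemispheres(
    feature_mi: Mapping[str, MIEstimate | float], schema: RegionSchema
) -> dict[str, dict[str, float]]:
    """Merge left+right MI per region: measure -> region -> summed nats."""
    out: dict[str, dict[str, float]] = {m: {} for m in schema.measures}
    for region in schema.regions:
        for measure in schema.measures:
            total = 0.0
            for hemi in schema.hemispheres:
                key = f"{region}__{hemi}__{measure}"
                if key not in feature_mi:
                    raise ValidationError(f"missing hemisphere entry {key}")
                v = feature_mi[key]
                total += v.value if isinstance(v, MIEstimate) else float(v)
            out[measure][region] = total
    return out


def aggregate_measures(
    region_measure: Mapping[str, Mapping[str, float]],
    combo: MeasureCombination,
) -> dict[str, float]:
    """Per-region combined MI: the sum of the member measures' region MI."""
    missing = [m for m in combo.members if m not in region_measure]
    if missing:
        raise ValidationError(
            f"combination {combo.name!r} needs measures {missing} not present"
        )
    regions = list(next(iter(region_measure.values())).keys())
    return {
        r: float(sum(region_measure[m][r] for m in combo.members)) for r in regions
    }


def rank_and_tertile(
    region_values: Mapping[str, float], top_k: int = 10
) -> tuple[list[tuple[str, float]], dict[str, str], list[str]]:
    """Descending ranking, tertile labels (thirds of the atlas), top-k list.

    Requires a region count divisible by 3 (the full atlas has 33 ->
    tertiles of 11); ties are broken by region label, ascending, stably.
    """
    n = len(region_values)
    if n == 0 or n % 3 != 0:
        raise ValidationError(
            f"tertile grouping needs a region count divisible by 3, got {n}"
        )
    ranked = sorted(region_values.items(), key=lambda kv: (-kv[1], kv[0]))
    third = n // 3
    tertiles = {}
    for i, (region, _) in enumerate(ranked):
        tertiles[region] = TERTILE_LABELS[min(i // third, 2)]
    top = [r for r, _ in ranked[:top_k]]
    return ranked, tertiles, top


def mi_profile(
    table: FeatureTable,
    corrected_age: np.ndarray,
    schema: RegionSchema | None = None,
    k: int = 3,
    seed: int = 0,
    combine_volumes: bool = False,
) -> MIProfile:
    """MI between each feature and (corrected) brain age, fully aggregated.

    With ``combine_volumes=True`` the parenchyma/intracranial entries are
    the MI of the summed volumes rather than the sum of member MI values
    (secondary mode; the primary decoding sums per-feature MI).
    """
    schema = schema or table.schema
    corrected_age = np.asarray(corrected_age, dtype=float).ravel()
    if len(corrected_age) != table.n_subjects:
        raise ValidationError(
            f"corrected_age has {len(corrected_age)} entries for "
            f"{table.n_subjects} subjects"
        )
    if table.n_subjects <= k:
        raise ValidationError(f"need n > k={k} subjects, got {table.n_subjects}")

    mat, names = table.feature_matrix()
    feature_mi = {
        name: ksg_mi(mat[:, j], corrected_age, k=k, seed=seed)
        for j, name in enumerate(names)
    }

    region_measure = aggregate_hemispheres(feature_mi, schema)
    combos: dict[str, dict[str, float]] = {}
    for cname, combo in MEASURE_COMBINATIONS.items():
        if not set(combo.members) <= set(schema.measures):
            continue
        if combine_volumes:
            vals: dict[str, float] = {}
            member_idx = {
                (r, h): [
                    names.index(f"{r}__{h}__{m}") for m in combo.members
                ]
                for r in schema.regions
                for h in schema.hemispheres
            }
            for r in schema.regions:
                total = 0.0
                for h in schema.hemispheres:
                    summed = mat[:, member_idx[(r, h)]].sum(axis=1)
                    total += ksg_mi(summed, corrected_age, k=k, seed=seed).value
                vals[r] = total
            combos[cname] = vals
        else:
            combos[cname] = aggregate_measures(region_measure, combo)

    measure_totals = {
        m: float(sum(region_measure[m].values())) for m in schema.measures
    }
    combination_totals = {c: float(sum(v.values())) for c, v in combos.items()}
    total = float(sum(measure_totals.values()))

    tertiles: dict[str, dict[str, str]] | None = None
    top_regions: dict[str, list[str]] = {}
    if len(schema.regions) % 3 == 0 and len(schema.regions) > 0:
        tertiles = {}
        for key, vals in {**region_measure, **combos}.items():
            _, tert, top = rank_and_tertile(vals)
            tertiles[key] = tert
            top_regions[key] = top
    else:
        for key, vals in {**region_measure, **combos}.items():
            ranked = sorted(vals.items(), key=lambda kv: (-kv[1], kv[0]))
            top_regions[key] = [r for r, _ in ranked[:10]]

    return MIProfile(
        feature_mi=feature_mi,
        region_measure=region_measure,
        combinations=combos,
        measure_totals=measure_totals,
        combination_totals=combination_totals,
        total=total,
        tertiles=tertiles,
        top_regions=top_regions,
        k=k,
        n=table.n_subjects,
        seed=seed,
    )
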