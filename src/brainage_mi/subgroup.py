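"""Sex-specific subgroup analysis of model performance and MI rankings.

The test cohort is split by sex, the trained model is evaluated per
subgroup (before and after age-bias correction, reusing the
training-set coefficients), the MI decoding is repeated per subgroup,
and the per-region MI rankings are compared between subgroups — and
against the full cohort — with Spearman rank correlation at the 0.05
significance level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .age_model import (
    BrainAgeModel,
    PerformanceMetrics,
    apply_bias_correction,
    evaluate,
    predict_age,
)
from .mi import MIProfile, mi_profile
from .schema import FeatureTable, ValidationError

__all__ = ["SubgroupComparison", "split_by_sex", "compare_mi_rankings", "subgroup_report"]

SIGNIFICANCE_LEVEL = 0.05
OVERALL_KEY = "all_measures"


def split_by_sex(table: FeatureTable) -> tuple[FeatureTable, FeatureTable]:
    """Disjoint, exhaustive (male, female) partition of the cohort."""
    sexes = table.df["sex"]
    missing = table.df.loc[sexes.isna() | ~sexes.isin(["male", "female"]), "subject_id"]
    if len(missing):
        raise ValidationError(
            f"subjects with missing/unknown sex: {missing.tolist()[:10]}"
        )
    male = table.subset_rows((sexes == "male").to_numpy())
    female = table.subset_rows((sexes == "female").to_numpy())
    return male, female


def compare_mi_rankings(
    profile_a: dict[str, float], profile_b: dict[str, float]
) -> tuple[float, float]:
    """Spearman rho and two-sided p between two per-region MI mappings.

    Average ranks are used for ties (scipy default); the p-value uses the
    t-distribution approximation.
    """
    if set(profile_a) != set(profile_b):
        raise ValidationError("region sets differ between profiles")
    regions = sorted(profile_a)
    a = np.array([profile_a[r] for r in regions], dtype=float)
    b = np.array([profile_b[r] for r in regions], dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        # a constant profile (e.g. every estimate clipped at 0) has no
        # ranking to correlate
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def _overall_region_mi(profile: MIProfile) -> dict[str, float]:
    """Per-region MI summed over all four measures (the merged profile)."""
    regions = list(next(iter(profile.region_measure.values())).keys())
    return {
        r: float(sum(profile.region_measure[m][r] for m in profile.region_measure))
        for r in regions
    }


@dataclass
class SubgroupComparison:
    """Per-sex metrics, MI profiles and the pairwise ranking correlations."""

    metrics: dict[str, dict[str, PerformanceMetrics]]  # group -> before/after
    profiles: dict[str, MIProfile]  # male / female / all
    totals: dict[str, float]
    comparisons: dict[str, dict[str, dict[str, float | bool]]]  # pair -> key -> rho/p
    n_subjects: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "metrics": {
                g: {phase: m.to_dict() for phase, m in d.items()}
                for g, d in self.metrics.items()
            },
            "totals": self.totals,
            "comparisons": self.comparisons,
            "profiles": {g: p.to_dict() for g, p in self.profiles.items()},
        }


def subgroup_report(
    test: FeatureTable,
    model: BrainAgeModel,
    k: int = 3,
    seed: int = 0,
) -> SubgroupComparison:
    """Full sex-subgroup analysis of a test cohort under a trained model.

    Bias-correction coefficients are those fitted on the training set —
    they are deliberately not refit per subgroup.
    """
    if model.bias is None:
        raise ValidationError("model has no fitted bias-correction coefficients")
    male, female = split_by_sex(test)
    groups = {"male": male, "female": female, "all": test}
    for name in ("male", "female"):
        if groups[name].n_subjects <= k:
            raise ValidationError(
                f"{name} subgroup has n={groups[name].n_subjects} <= k={k}; "
                "too small for MI estimation"
            )

    metrics: dict[str, dict[str, PerformanceMetrics]] = {}
    profiles: dict[str, MIProfile] = {}
    totals: dict[str, float] = {}
    for name, sub in groups.items():
        pred = predict_age(model, sub)
        corr = apply_bias_correction(pred, sub.ages, model.bias)
        metrics[name] = {
            "before_correction": evaluate(pred, sub.ages),
            "after_correction": evaluate(corr, sub.ages),
        }
        profiles[name] = mi_profile(sub, corr, model.schema, k=k, seed=seed)
        totals[name] = profiles[name].total

    comparisons: dict[str, dict[str, dict[str, float | bool]]] = {}
    for pair in (("male", "female"), ("male", "all"), ("female", "all")):
        pa, pb = profiles[pair[0]], profiles[pair[1]]
        block: dict[str, dict[str, float | bool]] = {}
        keys = list(pa.region_measure) + list(pa.combinations)
        for key in keys:
            va = pa.region_measure.get(key) or pa.combinations[key]
            vb = pb.region_measure.get(key) or pb.combinations[key]
            rho, p = compare_mi_rankings(va, vb)
            block[key] = {"rho": rho, "p": p, "significant": bool(p < SIGNIFICANCE_LEVEL)}
        rho, p = compare_mi_rankings(_overall_region_mi(pa), _overall_region_mi(pb))
        block[OVERALL_KEY] = {
            "rho": rho,
            "p": p,
            "significant": bool(p < SIGNIFICANCE_LEVEL),
        }
        comparisons["_vs_".join(pair)] = block

    return SubgroupComparison(
        metrics=metrics,
        profiles=profiles,
        totals=totals,
        comparisons=comparisons,
        n_subjects={g: t.n_subjects for g, t in groups.items()},
    )
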