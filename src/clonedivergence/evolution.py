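"""Trunk/branch partition of paired lesions and evolution-class calls.

With exactly two lesions per patient the phylogeny degenerates to a
shared trunk (mutations in both lesions) plus one private branch per
lesion.  The genomic distance between the lesions is summarised as the
shared proportion |trunk| / |union| over substitution/indel keys, and a
patient is called parallel (low sharing: early, independent
dissemination), linear (high sharing: late dissemination of an evolved
clone) or intermediate by thresholding that proportion.  Patients with
too few union mutations are unclassifiable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .association import Contingency2x2, test_2x2
from .variant_model import (
    AlterationClass,
    Cohort,
    PatientPair,
    mutation_key,
)


class EvolutionError(ValueError):
    """Unpaired input or invalid thresholds."""


@dataclass(frozen=True)
class PairPartition:
    """Trunk and lesion-private branch mutation keys of one patient."""

    patient_id: str
    trunk: frozenset[tuple]
    primary_branch: frozenset[tuple]
    metastasis_branch: frozenset[tuple]

    @property
    def n_union(self) -> int:
        return len(self.trunk) + len(self.primary_branch) + len(self.metastasis_branch)


@dataclass(frozen=True)
class EvolutionThresholds:
    """Shared-proportion cutoffs: parallel < t_low <= intermediate < t_high
    <= linear; below min_mutations union SNVs a patient is unclassifiable."""

    t_low: float = 0.30
    t_high: float = 0.50
    min_mutations: int = 10

    def __post_init__(self) -> None:
        if not (0 <= self.t_low < self.t_high <= 1):
            raise EvolutionError(
                f"need 0 <= t_low < t_high <= 1, got ({self.t_low}, {self.t_high})"
            )
        if self.min_mutations < 1:
            raise EvolutionError("min_mutations must be >= 1")


@dataclass(frozen=True)
class EvolutionCall:
    patient_id: str
    shared_proportion: float | None   # None when the union is empty
    n_union: int
    call: str                         # parallel | intermediate | linear | unclassifiable


#: Alteration classes entering the genomic distance by default; CNVs and
#: fusions are excluded because their cross-lesion concordance is low.
DISTANCE_CLASSES = frozenset({AlterationClass.SUBSTITUTION_INDEL})


def partition_pair(
    pair: PatientPair,
    key_level: str = "allele",
    classes: frozenset = DISTANCE_CLASSES,
) -> PairPartition:
    """Split the lesion key union into trunk and private branches."""
    if not pair.paired:
        raise EvolutionError(f"patient {pair.patient_id} is not paired")

    def keys(profile) -> set[tuple]:
        return {
            mutation_key(v, key_level)
            for v in profile.variants
            if v.alteration_class in classes
        }

    pk, mk = keys(pair.primary), keys(pair.metastasis)
    return PairPartition(
        patient_id=pair.patient_id,
        trunk=frozenset(pk & mk),
        primary_branch=frozenset(pk - mk),
        metastasis_branch=frozenset(mk - pk),
    )


def genomic_distance(partition: PairPartition) -> float | None:
    """Shared proportion |trunk| / |union|; None for an empty union."""
    if partition.n_union == 0:
        return None
    return len(partition.trunk) / partition.n_union


def classify_evolution(
    partition: PairPartition,
    thresholds: EvolutionThresholds = EvolutionThresholds(),
) -> EvolutionCall:
    """Call parallel / intermediate / linear from the shared proportion.

    Monotone in the shared proportion: parallel below t_low, linear at or
    above t_high, intermediate between.  Pairs with fewer than
    min_mutations union mutations are unclassifiable.
    """
    shared = genomic_distance(partition)
    n = partition.n_union
    if n < thresholds.min_mutations or shared is None:
        return EvolutionCall(partition.patient_id, shared, n, "unclassifiable")
    if shared < thresholds.t_low:
        call = "parallel"
    elif shared >= thresholds.t_high:
        call = "linear"
    else:
        call = "intermediate"
    return EvolutionCall(partition.patient_id, shared, n, call)


def cohort_evolution_calls(
    cohort: Cohort,
    thresholds: EvolutionThresholds = EvolutionThresholds(),
    key_level: str = "allele",
) -> pd.DataFrame:
    """Per-patient partition sizes, shared proportion and class call."""
    rows = []
    for pair in cohort.paired():
        part = partition_pair(pair, key_level)
        call = classify_evolution(part, thresholds)
        rows.append(
            {
                "patient_id": pair.patient_id,
                "n_trunk": len(part.trunk),
                "n_primary_branch": len(part.primary_branch),
                "n_metastasis_branch": len(part.metastasis_branch),
                "n_union": part.n_union,
                "shared_proportion": call.shared_proportion,
                "call": call.call,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "n_trunk", "n_primary_branch", "n_metastasis_branch",
            "n_union", "shared_proportion", "call",
        ],
    )


def cohort_evolution_summary(
    calls: pd.DataFrame,
    clinical: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class counts overall (and by metastasis subtype) with pairwise
    Fisher tests of class membership against subtype.

    ``clinical`` maps patient_id -> metastasis subtype.  Returns
    (summary, tests); unclassifiable patients are excluded from the
    summary and reported via ``summary.attrs['n_excluded']``.
    """
    classified = calls[calls["call"] != "unclassifiable"].copy()
    n_excluded = len(calls) - len(classified)
    order = ["parallel", "intermediate", "linear"]
    rows = []
    for cls in order:
        sub = classified[classified["call"] == cls]
        row = {"call": cls, "n": len(sub),
               "proportion": len(sub) / len(classified) if len(classified) else 0.0}
        if clinical is not None:
            for subtype in ("synchronous", "metachronous"):
                row[f"n_{subtype}"] = sum(
                    1 for pid in sub["patient_id"] if clinical.get(pid) == subtype
                )
        rows.append(row)
    summary = pd.DataFrame(rows)
    summary.attrs["n_excluded"] = n_excluded

    tests = []
    if clinical is not None and len(classified):
        subtype_of = {pid: clinical.get(pid) for pid in classified["patient_id"]}
        n_sync = sum(1 for s in subtype_of.values() if s == "synchronous")
        n_meta = sum(1 for s in subtype_of.values() if s == "metachronous")
        for cls in order:
            in_cls = set(classified[classified["call"] == cls]["patient_id"])
            a = sum(1 for pid in in_cls if subtype_of.get(pid) == "synchronous")
            c = sum(1 for pid in in_cls if subtype_of.get(pid) == "metachronous")
            if n_sync == 0 or n_meta == 0:
                continue
            res = test_2x2(Contingency2x2(a, n_sync - a, c, n_meta - c), method="fisher")
            tests.append(
                {"call": cls, "n_synchronous": a, "n_metachronous": c,
                 "method": res.method, "p_value": res.p_value}
            )
    return summary, pd.DataFrame(tests)


def pair_composition(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-patient (primary-only, metastasis-only, shared) proportions."""
    out = calls.copy()
    n = out["n_union"].replace(0, pd.NA)
    out["prop_primary_only"] = out["n_primary_branch"] / n
    out["prop_metastasis_only"] = out["n_metastasis_branch"] / n
    out["prop_shared"] = out["n_trunk"] / n
    return out


def compare_composition_anova(
    groups: Mapping[str, pd.DataFrame],
    components: Sequence[str] = ("prop_primary_only", "prop_metastasis_only", "prop_shared"),
) -> pd.DataFrame:
    """One-way ANOVA of each composition component across groups.

    ``groups`` maps a label (e.g. subtype) to a composition table from
    :func:`pair_composition`.  Classical F = MS_between / MS_within with
    (k-1, N-k) degrees of freedom; F is reported as NaN (with p NaN) when
    the within-group variance is zero and means are equal.
    """
    if len(groups) < 2:
        raise EvolutionError("ANOVA requires at least two groups")
    rows = []
    for comp in components:
        samples = []
        for label, df in groups.items():
            vals = pd.to_numeric(df[comp], errors="coerce").dropna().to_numpy()
            if len(vals) < 2:
                raise EvolutionError(f"group {label!r} has fewer than 2 patients")
            samples.append(vals)
        res = stats.f_oneway(*samples)
        rows.append(
            {"component": comp, "F": float(res.statistic), "p_value": float(res.pvalue),
             "df_between": len(samples) - 1,
             "df_within": sum(len(s) for s in samples) - len(samples)}
        )
    return pd.DataFrame(rows)
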