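"""Alteration-landscape summaries and lesion/group comparisons.

Shared-status labelling (S = shared, P = primary-only, M = metastasis-only),
per-gene alteration frequencies, group-versus-group 2x2 frequency screens,
paired-lesion Pearson correlations, CNV chromosome distributions and fusion
concordance.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import Contingency2x2, test_2x2
from .pathway_score import benjamini_hochberg
from .variant_model import (
    AlterationClass,
    Cohort,
    Lesion,
    PatientPair,
    SampleProfile,
    mutation_key,
)


class LandscapeError(ValueError):
    """Empty selection or unpaired input where a pair is required."""


class SharedStatus(str, enum.Enum):
    S = "S"  # shared by both lesions
    P = "P"  # primary only
    M = "M"  # metastasis only


def label_shared_status(
    pair: PatientPair, key_level: str = "allele"
) -> dict[tuple, SharedStatus]:
    """Label every mutation key in the lesion union as S, P or M."""
    if not pair.paired:
        raise LandscapeError(f"patient {pair.patient_id} is not paired")
    pk = pair.primary.keys(key_level)
    mk = pair.metastasis.keys(key_level)
    out: dict[tuple, SharedStatus] = {}
    for key in pk | mk:
        if key in pk and key in mk:
            out[key] = SharedStatus.S
        elif key in pk:
            out[key] = SharedStatus.P
        else:
            out[key] = SharedStatus.M
    return out


def gene_alteration_frequency(
    cohort: Cohort,
    lesion: Lesion | None = None,
    patients: Sequence[str] | None = None,
    shared_status: SharedStatus | None = None,
    key_level: str = "allele",
    group: str = "all",
) -> pd.DataFrame:
    """Per-gene mutated-patient counts and frequencies.

    A patient counts at most once per gene regardless of how many
    alterations hit it.  ``shared_status`` restricts to genes whose
    alterations carry that cross-lesion status (paired patients only),
    e.g. ``SharedStatus.S`` tabulates shared-alteration frequencies.
    """
    selected = [
        p for p in cohort.pairs if patients is None or p.patient_id in patients
    ]
    if shared_status is not None:
        selected = [p for p in selected if p.paired]
    if not selected:
        raise LandscapeError("empty patient selection")

    carriers: dict[str, set[str]] = {}
    for pair in selected:
        if shared_status is not None:
            labels = label_shared_status(pair, key_level)
            key_to_gene = {}
            for prof in (pair.primary, pair.metastasis):
                for v in prof.variants:
                    key_to_gene[mutation_key(v, key_level)] = v.gene
            for key, status in labels.items():
                if status == shared_status:
                    carriers.setdefault(key_to_gene[key], set()).add(pair.patient_id)
        else:
            for prof in (pair.primary, pair.metastasis):
                if prof is None or (lesion is not None and prof.lesion != lesion):
                    continue
                for v in prof.variants:
                    carriers.setdefault(v.gene, set()).add(pair.patient_id)

    n_patients = len(selected)
    df = pd.DataFrame(
        {
            "gene": sorted(carriers),
            "group": group,
            "n_mutated_patients": [len(carriers[g]) for g in sorted(carriers)],
            "n_patients": n_patients,
        }
    )
    df["frequency"] = df["n_mutated_patients"] / df["n_patients"]
    return df.sort_values(
        ["n_mutated_patients", "gene"], ascending=[False, True], ignore_index=True
    )


def compare_gene_frequencies(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    min_count: int = 3,
    method: str = "auto",
) -> pd.DataFrame:
    """Gene-by-gene 2x2 comparison of two disjoint patient groups.

    For each gene mutated in at least ``min_count`` patients overall, a
    mutated/unmutated 2x2 table is tested (Fisher when any expected count
    < 5, Pearson chi-squared otherwise, unless ``method`` forces one).
    Raw p-values are primary; BH q-values are appended.
    """
    a = table_a.set_index("gene")
    b = table_b.set_index("gene")
    na = int(a["n_patients"].iloc[0]) if len(a) else 0
    nb = int(b["n_patients"].iloc[0]) if len(b) else 0
    rows = []
    for gene in sorted(set(a.index) | set(b.index)):
        ka = int(a["n_mutated_patients"].get(gene, 0))
        kb = int(b["n_mutated_patients"].get(gene, 0))
        if ka + kb < min_count:
            continue
        res = test_2x2(Contingency2x2(ka, na - ka, kb, nb - kb), method=method)
        rows.append(
            {
                "gene": gene,
                "n_mutated_a": ka, "n_a": na,
                "n_mutated_b": kb, "n_b": nb,
                "freq_a": ka / na if na else 0.0,
                "freq_b": kb / nb if nb else 0.0,
                "method": res.method,
                "statistic": res.statistic,
                "p_value": res.p_value,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene", "n_mutated_a", "n_a", "n_mutated_b", "n_b",
            "freq_a", "freq_b", "method", "statistic", "p_value",
        ],
    )
    if len(df):
        df["q_value"] = benjamini_hochberg(df["p_value"].to_numpy())
        df = df.sort_values(["p_value", "gene"], ignore_index=True)
    return df


@dataclass(frozen=True)
class CorrelationResult:
    patient_id: str
    feature_kind: str            # SNV | CNV
    r: float | None              # Pearson r; None when undefined
    n_features: int
    reason: str = ""             # why undefined, when r is None
    used_vaf: bool = True        # False = presence/absence vectors


def paired_lesion_correlation(
    pair: PatientPair,
    feature_kind: str = "SNV",
    min_keys: int = 3,
    key_level: str = "allele",
) -> CorrelationResult:
    """Pearson correlation of lesion feature vectors over the key union.

    SNV vectors hold VAFs (0 where the key is absent from a lesion);
    when any VAF is missing, presence/absence vectors are used instead.
    CNV vectors hold per-gene event indicators signed by direction
    (+1 amplification, -1 homozygous deletion, 0 absent).  Undefined
    (with a reason) below ``min_keys`` union keys or at zero variance.
    """
    if not pair.paired:
        raise LandscapeError(f"patient {pair.patient_id} is not paired")
    if feature_kind not in {"SNV", "CNV"}:
        raise ValueError(f"feature_kind must be SNV or CNV, got {feature_kind!r}")

    def features(profile: SampleProfile) -> dict:
        out = {}
        for v in profile.variants:
            if feature_kind == "SNV":
                if v.alteration_class is AlterationClass.SUBSTITUTION_INDEL:
                    out[mutation_key(v, key_level)] = v.vaf
            else:
                if v.alteration_class is AlterationClass.AMPLIFICATION:
                    out[(v.gene, "cnv")] = 1.0
                elif v.alteration_class is AlterationClass.HOMOZYGOUS_DELETION:
                    out[(v.gene, "cnv")] = -1.0
        return out

    fp = features(pair.primary)
    fm = features(pair.metastasis)
    keys = sorted(set(fp) | set(fm))
    n = len(keys)
    used_vaf = feature_kind == "SNV" and all(
        v is not None for v in list(fp.values()) + list(fm.values())
    )
    if n < min_keys:
        return CorrelationResult(pair.patient_id, feature_kind, None, n,
                                 reason=f"fewer than {min_keys} union keys",
                                 used_vaf=used_vaf)

    def vec(f: dict) -> np.ndarray:
        if feature_kind == "SNV" and not used_vaf:
            return np.array([1.0 if k in f else 0.0 for k in keys])
        return np.array([f.get(k) or 0.0 for k in keys], dtype=float)

    x, y = vec(fp), vec(fm)
    if x.std() == 0 or y.std() == 0:
        return CorrelationResult(pair.patient_id, feature_kind, None, n,
                                 reason="zero variance in a lesion vector",
                                 used_vaf=used_vaf)
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationResult(pair.patient_id, feature_kind, r, n, used_vaf=used_vaf)


def cohort_correlations(cohort: Cohort, feature_kind: str = "SNV") -> pd.DataFrame:
    rows = []
    for pair in cohort.paired():
        res = paired_lesion_correlation(pair, feature_kind)
        rows.append(
            {
                "patient_id": res.patient_id,
                "feature_kind": res.feature_kind,
                "r": res.r,
                "n_features": res.n_features,
                "reason": res.reason,
                "used_vaf": res.used_vaf,
            }
        )
    return pd.DataFrame(rows)


_CNV_CLASSES = {
    AlterationClass.AMPLIFICATION: "amplification",
    AlterationClass.HOMOZYGOUS_DELETION: "deletion",
}


def cnv_chromosome_distribution(
    cohort: Cohort,
    compare_lesions: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-chromosome, per-lesion CNV counts split by direction.

    Returns (counts, tests): counts partition every amplification /
    homozygous-deletion event by chromosome, direction and lesion; tests
    compare, per chromosome and direction, that chromosome's share of CNV
    events between lesions with the standard 2x2 machinery.
    """
    rows = []
    for prof in cohort.profiles():
        for v in prof.variants:
            direction = _CNV_CLASSES.get(v.alteration_class)
            if direction:
                rows.append(
                    {"chrom": v.chrom, "direction": direction, "lesion": prof.lesion.value}
                )
    if not rows:
        return (
            pd.DataFrame(columns=["chrom", "direction", "lesion", "count"]),
            pd.DataFrame(columns=["chrom", "direction", "p_value"]),
        )
    counts = (
        pd.DataFrame(rows)
        .value_counts(["chrom", "direction", "lesion"])
        .rename("count")
        .reset_index()
        .sort_values(["chrom", "direction", "lesion"], ignore_index=True)
    )
    tests = []
    if compare_lesions:
        totals = counts.groupby("lesion")["count"].sum()
        for (chrom, direction), sub in counts.groupby(["chrom", "direction"]):
            by_lesion = sub.set_index("lesion")["count"]
            kp = int(by_lesion.get("primary", 0))
            km = int(by_lesion.get("metastasis", 0))
            np_, nm = int(totals.get("primary", 0)), int(totals.get("metastasis", 0))
            if np_ == 0 or nm == 0:
                continue
            res = test_2x2(Contingency2x2(kp, np_ - kp, km, nm - km), method="auto")
            tests.append(
                {"chrom": chrom, "direction": direction, "n_primary": kp,
                 "n_metastasis": km, "method": res.method, "p_value": res.p_value}
            )
    return counts, pd.DataFrame(tests)


def compare_fusions(cohort: Cohort) -> pd.DataFrame:
    """Per-patient fusion events labelled by cross-lesion concordance.

    A fusion is shared when the unordered gene pair occurs in both lesions
    of the same patient; otherwise it is primary-only or metastasis-only.
    """
    rows = []
    for pair in cohort.pairs:
        by_lesion: dict[str, set[tuple]] = {"primary": set(), "metastasis": set()}
        for prof in (pair.primary, pair.metastasis):
            if prof is None:
                continue
            for v in prof.variants:
                if v.alteration_class is AlterationClass.FUSION_REARRANGEMENT:
                    by_lesion[prof.lesion.value].add(
                        tuple(sorted((v.gene, v.fusion_partner or "")))
                    )
        for fusion in sorted(by_lesion["primary"] | by_lesion["metastasis"]):
            in_p = fusion in by_lesion["primary"]
            in_m = fusion in by_lesion["metastasis"]
            status = "shared" if in_p and in_m else ("primary_only" if in_p else "metastasis_only")
            rows.append(
                {
                    "patient_id": pair.patient_id,
                    "gene_a": fusion[0],
                    "gene_b": fusion[1],
                    "status": status,
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "gene_a", "gene_b", "status"])
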