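"""Somatic alteration and clinical data model.

Tab-separated alteration tables (one row per somatic event in one lesion of
one patient) and clinical tables are parsed into validated records and
assembled into a cohort of primary/metastasis pairs.  Coordinates are
1-based, inclusive (MAF convention).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


class VariantTableError(ValueError):
    """Malformed alteration or clinical table (missing column, bad row)."""


class CohortError(ValueError):
    """Inconsistent cohort assembly input (orphan or duplicate patients)."""


class AlterationClass(str, enum.Enum):
    SUBSTITUTION_INDEL = "substitution_indel"
    AMPLIFICATION = "amplification"
    TRUNCATION = "truncation"
    FUSION_REARRANGEMENT = "fusion_rearrangement"
    HOMOZYGOUS_DELETION = "homozygous_deletion"


class Lesion(str, enum.Enum):
    PRIMARY = "primary"
    METASTASIS = "metastasis"


#: MAF Variant_Classification strings mapped onto the five-class model.
MAF_CLASS_LOOKUP: Mapping[str, AlterationClass] = {
    "Missense_Mutation": AlterationClass.SUBSTITUTION_INDEL,
    "Silent": AlterationClass.SUBSTITUTION_INDEL,
    "Splice_Site": AlterationClass.SUBSTITUTION_INDEL,
    "In_Frame_Ins": AlterationClass.SUBSTITUTION_INDEL,
    "In_Frame_Del": AlterationClass.SUBSTITUTION_INDEL,
    "Frame_Shift_Ins": AlterationClass.SUBSTITUTION_INDEL,
    "Frame_Shift_Del": AlterationClass.SUBSTITUTION_INDEL,
    "Nonsense_Mutation": AlterationClass.TRUNCATION,
    "Nonstop_Mutation": AlterationClass.TRUNCATION,
    "Translation_Start_Site": AlterationClass.SUBSTITUTION_INDEL,
    "Amplification": AlterationClass.AMPLIFICATION,
    "Homozygous_Deletion": AlterationClass.HOMOZYGOUS_DELETION,
    "Fusion": AlterationClass.FUSION_REARRANGEMENT,
}

_DNA = set("ACGT")


@dataclass(frozen=True)
class Variant:
    """One somatic alteration in one lesion of one patient.

    ``pos`` is 1-based.  ``context`` is the 5'->3' trinucleotide around a
    single-base substitution on the forward strand; its middle base must
    match ``ref``.  ``fusion_partner`` is required for (and restricted to)
    fusion/rearrangement events.
    """

    patient_id: str
    lesion: Lesion
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    alteration_class: AlterationClass
    vaf: float | None = None
    context: str | None = None
    fusion_partner: str | None = None
    extra: Mapping[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantTableError(
                f"pos must be >= 1 (1-based convention), got {self.pos}"
            )
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise VariantTableError(f"vaf must be in [0, 1], got {self.vaf}")
        if self.context is not None:
            ctx = self.context.upper()
            if len(ctx) != 3 or not set(ctx) <= _DNA:
                raise VariantTableError(f"context must be a 3-mer over ACGT: {ctx!r}")
            if (
                self.alteration_class is AlterationClass.SUBSTITUTION_INDEL
                and len(self.ref) == 1
                and ctx[1] != self.ref.upper()
            ):
                raise VariantTableError(
                    f"context middle base {ctx[1]} != ref {self.ref}"
                )
        is_fusion = self.alteration_class is AlterationClass.FUSION_REARRANGEMENT
        if is_fusion and not self.fusion_partner:
            raise VariantTableError("fusion/rearrangement requires fusion_partner")
        if not is_fusion and self.fusion_partner:
            raise VariantTableError("fusion_partner only valid for fusions")

    @property
    def is_snv(self) -> bool:
        return (
            self.alteration_class is AlterationClass.SUBSTITUTION_INDEL
            and len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref.upper() in _DNA
            and self.alt.upper() in _DNA
            and self.ref.upper() != self.alt.upper()
        )


def mutation_key(variant: Variant, level: str = "allele") -> tuple:
    """Identity key used to match events across lesions.

    ``allele`` (default): substitutions/indels keyed by
    (gene, chrom, pos, ref, alt); CNV/fusion events by gene-level identity
    (gene, class[, partner]).  ``gene``: every event keyed by
    (gene, class[, partner]).
    """
    cls = variant.alteration_class
    if cls is AlterationClass.FUSION_REARRANGEMENT:
        pair = tuple(sorted((variant.gene, variant.fusion_partner or "")))
        return ("fusion", *pair)
    if cls is AlterationClass.SUBSTITUTION_INDEL and level == "allele":
        return (variant.gene, variant.chrom, variant.pos, variant.ref, variant.alt)
    return (variant.gene, cls.value)


class MetastasisSubtype(str, enum.Enum):
    SYNCHRONOUS = "synchronous"
    METACHRONOUS = "metachronous"


class Response(str, enum.Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"


#: CR/PR count as effective, SD/PD as ineffective (RECIST 1.1 dichotomy).
EFFECTIVE_RESPONSES = frozenset({Response.CR, Response.PR})


@dataclass(frozen=True)
class ClinicalRecord:
    patient_id: str
    metastasis_subtype: MetastasisSubtype
    extent: str = "unknown"          # local | diffuse | unknown
    laterality: str = "unknown"      # bilateral | unilateral | unknown
    lauren: str = "unknown"          # diffuse | intestinal | mixed | unknown
    pathology: str = "unknown"       # signet | non_signet | unknown
    response: Response | None = None
    os_months: float | None = None
    os_event: bool | None = None     # True = death observed, False = censored

    def __post_init__(self) -> None:
        allowed = {
            "extent": {"local", "diffuse", "unknown"},
            "laterality": {"bilateral", "unilateral", "unknown"},
            "lauren": {"diffuse", "intestinal", "mixed", "unknown"},
            "pathology": {"signet", "non_signet", "unknown"},
        }
        for name, values in allowed.items():
            if getattr(self, name) not in values:
                raise VariantTableError(
                    f"invalid {name} value {getattr(self, name)!r}; "
                    f"expected one of {sorted(values)}"
                )
        if self.os_months is not None and self.os_months < 0:
            raise VariantTableError("os_months must be nonnegative")

    @property
    def effective(self) -> bool | None:
        """Treatment-response dichotomy: CR/PR effective, SD/PD ineffective."""
        if self.response is None:
            return None
        return self.response in EFFECTIVE_RESPONSES


@dataclass(frozen=True)
class SampleProfile:
    """All alterations observed in one lesion of one patient."""

    patient_id: str
    lesion: Lesion
    variants: tuple[Variant, ...]

    def __post_init__(self) -> None:
        for v in self.variants:
            if v.patient_id != self.patient_id or v.lesion != self.lesion:
                raise CohortError(
                    f"variant ({v.patient_id}, {v.lesion.value}) does not belong "
                    f"to profile ({self.patient_id}, {self.lesion.value})"
                )

    def keys(self, level: str = "allele") -> set[tuple]:
        return {mutation_key(v, level) for v in self.variants}


@dataclass(frozen=True)
class PatientPair:
    patient_id: str
    clinical: ClinicalRecord
    primary: SampleProfile | None = None
    metastasis: SampleProfile | None = None

    def __post_init__(self) -> None:
        if self.primary is None and self.metastasis is None:
            raise CohortError(f"patient {self.patient_id}: no lesion profile")

    @property
    def paired(self) -> bool:
        return self.primary is not None and self.metastasis is not None


@dataclass(frozen=True)
class Cohort:
    pairs: tuple[PatientPair, ...]
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.pairs]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate patient ids in cohort: {dupes}")

    def paired(self) -> list[PatientPair]:
        return [p for p in self.pairs if p.paired]

    def profiles(self, lesion: Lesion | None = None) -> list[SampleProfile]:
        out: list[SampleProfile] = []
        for pair in self.pairs:
            for prof in (pair.primary, pair.metastasis):
                if prof is not None and (lesion is None or prof.lesion == lesion):
                    out.append(prof)
        return out

    def get(self, patient_id: str) -> PatientPair:
        for pair in self.pairs:
            if pair.patient_id == patient_id:
                return pair
        raise KeyError(patient_id)


# ---------------------------------------------------------------------------
# Readers / writers

_VARIANT_COLUMNS = [
    "patient_id", "lesion", "gene", "chrom", "pos", "ref", "alt",
    "alteration_class",
]
_VARIANT_OPTIONAL = ["vaf", "context", "fusion_partner"]

_MAF_RENAME = {
    "Hugo_Symbol": "gene",
    "Chromosome": "chrom",
    "Start_Position": "pos",
    "Reference_Allele": "ref",
    "Tumor_Seq_Allele2": "alt",
    "Variant_Classification": "alteration_class",
    "Tumor_Sample_Barcode": "patient_id",
    "t_vaf": "vaf",
}


def _opt(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s if s and s.lower() not in {"na", "nan", ".", ""} else None


def read_variant_table(path: str | Path, dialect: str = "tsv") -> list[Variant]:
    """Read a tab-separated alteration table into validated records.

    ``dialect='maf'`` accepts MAF-style column names, mapping
    Variant_Classification strings onto the five alteration classes.
    A ``lesion`` column is required in either dialect.  Row order is
    preserved; unrecognised columns are kept in ``Variant.extra``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if dialect == "maf":
        df = df.rename(columns=_MAF_RENAME)
    missing = [c for c in _VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise VariantTableError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    known = set(_VARIANT_COLUMNS) | set(_VARIANT_OPTIONAL)
    extra_cols = [c for c in df.columns if c not in known]
    out: list[Variant] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        try:
            cls_raw = str(rec["alteration_class"]).strip()
            if dialect == "maf":
                if cls_raw not in MAF_CLASS_LOOKUP:
                    raise VariantTableError(
                        f"unknown MAF Variant_Classification {cls_raw!r}"
                    )
                cls = MAF_CLASS_LOOKUP[cls_raw]
            else:
                cls = AlterationClass(cls_raw)
            pos = int(rec["pos"])
            vaf_raw = _opt(rec.get("vaf"))
            out.append(
                Variant(
                    patient_id=str(rec["patient_id"]).strip(),
                    lesion=Lesion(str(rec["lesion"]).strip()),
                    gene=str(rec["gene"]).strip(),
                    chrom=str(rec["chrom"]).strip(),
                    pos=pos,
                    ref=str(rec["ref"]).strip(),
                    alt=str(rec["alt"]).strip(),
                    alteration_class=cls,
                    vaf=float(vaf_raw) if vaf_raw is not None else None,
                    context=_opt(rec.get("context")),
                    fusion_partner=_opt(rec.get("fusion_partner")),
                    extra={c: rec[c] for c in extra_cols},
                )
            )
        except (ValueError, KeyError) as exc:
            raise VariantTableError(f"{path}: line {i}: {exc}") from exc
    return out


def write_variant_table(variants: Iterable[Variant], path: str | Path) -> None:
    rows = []
    for v in variants:
        rows.append(
            {
                "patient_id": v.patient_id,
                "lesion": v.lesion.value,
                "gene": v.gene,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "alteration_class": v.alteration_class.value,
                "vaf": "" if v.vaf is None else f"{v.vaf:.6g}",
                "context": v.context or "",
                "fusion_partner": v.fusion_partner or "",
            }
        )
    pd.DataFrame(rows, columns=_VARIANT_COLUMNS + _VARIANT_OPTIONAL).to_csv(
        path, sep="\t", index=False
    )


_CLINICAL_COLUMNS = ["patient_id", "metastasis_subtype"]


def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise VariantTableError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    out: list[ClinicalRecord] = []
    for i, rec in enumerate(df.to_dict("records"), start=2):
        try:
            resp = _opt(rec.get("response"))
            osm = _opt(rec.get("os_months"))
            osev = _opt(rec.get("os_event"))
            out.append(
                ClinicalRecord(
                    patient_id=str(rec["patient_id"]).strip(),
                    metastasis_subtype=MetastasisSubtype(
                        str(rec["metastasis_subtype"]).strip()
                    ),
                    extent=_opt(rec.get("extent")) or "unknown",
                    laterality=_opt(rec.get("laterality")) or "unknown",
                    lauren=_opt(rec.get("lauren")) or "unknown",
                    pathology=_opt(rec.get("pathology")) or "unknown",
                    response=Response(resp) if resp else None,
                    os_months=float(osm) if osm else None,
                    os_event={"death": True, "censored": False}.get(osev)
                    if osev
                    else None,
                )
            )
        except (ValueError, KeyError) as exc:
            raise VariantTableError(f"{path}: line {i}: {exc}") from exc
    return out


def write_clinical_table(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "metastasis_subtype": r.metastasis_subtype.value,
                "extent": r.extent,
                "laterality": r.laterality,
                "lauren": r.lauren,
                "pathology": r.pathology,
                "response": r.response.value if r.response else "",
                "os_months": "" if r.os_months is None else f"{r.os_months:.6g}",
                "os_event": {True: "death", False: "censored", None: ""}[r.os_event],
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def assemble_cohort(
    variants: Sequence[Variant],
    clinicals: Sequence[ClinicalRecord],
    metadata: Mapping[str, str] | None = None,
) -> Cohort:
    """Group per-row alterations into per-patient primary/metastasis pairs.

    Every variant's patient must appear in the clinical table; patients
    with a single lesion are kept as unpaired pairs.  Output is invariant
    to input row order (profiles sort variants deterministically).
    """
    clin_by_id: dict[str, ClinicalRecord] = {}
    for rec in clinicals:
        if rec.patient_id in clin_by_id:
            raise CohortError(f"duplicate patient in clinical table: {rec.patient_id}")
        clin_by_id[rec.patient_id] = rec
    orphans = sorted({v.patient_id for v in variants} - set(clin_by_id))
    if orphans:
        raise CohortError(f"variants for patients absent from clinical table: {orphans}")

    by_patient: dict[str, dict[Lesion, list[Variant]]] = {}
    for v in variants:
        by_patient.setdefault(v.patient_id, {}).setdefault(v.lesion, []).append(v)

    sort_key = lambda v: (v.chrom, v.pos, v.gene, v.ref, v.alt, v.alteration_class.value)
    pairs = []
    for pid, rec in clin_by_id.items():
        lesions = by_patient.get(pid, {})
        if not lesions:
            continue
        profs = {
            les: SampleProfile(pid, les, tuple(sorted(vs, key=sort_key)))
            for les, vs in lesions.items()
        }
        pairs.append(
            PatientPair(
                patient_id=pid,
                clinical=rec,
                primary=profs.get(Lesion.PRIMARY),
                metastasis=profs.get(Lesion.METASTASIS),
            )
        )
    pairs.sort(key=lambda p: p.patient_id)
    return Cohort(pairs=tuple(pairs), metadata=dict(metadata or {}))


def tally_alteration_classes(profiles: Sequence[SampleProfile]) -> pd.DataFrame:
    """Count alterations by class with percentages (one decimal).

    Returns one row per alteration class present, ordered by descending
    count, with columns ``count`` and ``percent`` where
    percent = 100 * count / total rounded to one decimal place.
    """
    if not profiles:
        raise VariantTableError("tally_alteration_classes: empty profile collection")
    counts: dict[str, int] = {}
    for prof in profiles:
        for v in prof.variants:
            counts[v.alteration_class.value] = counts.get(v.alteration_class.value, 0) + 1
    total = sum(counts.values())
    df = pd.DataFrame(
        {
            "alteration_class": list(counts),
            "count": list(counts.values()),
        }
    ).sort_values("count", ascending=False, kind="stable", ignore_index=True)
    df["percent"] = (100.0 * df["count"] / total).round(1)
    df.attrs["total"] = total
    return df
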