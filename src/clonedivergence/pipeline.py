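"""End-to-end orchestration: landscape -> signatures -> pathway scores ->
evolution -> association/survival, with a machine-readable run manifest.

Every threshold (cosine gate, FDR cutoff, evolution cutoffs, minimum
counts) lives in the config and is echoed into the manifest; outputs are
deterministic functions of the inputs, config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import association, evolution, landscape, signatures
from .pathway_score import (
    enrich_pathways,
    pathway_score_table,
    rank_and_cluster_scores,
    read_gmt,
    top_frequent_genes,
)
from .evolution import EvolutionThresholds
from .variant_model import (
    Cohort,
    Lesion,
    read_clinical_table,
    read_variant_table,
    assemble_cohort,
    tally_alteration_classes,
)

logger = logging.getLogger("clonedivergence")


class PipelineConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass(frozen=True)
class PipelineConfig:
    variants: str
    clinical: str
    gmt: str
    signature_matrix: str
    out_dir: str
    seed: int = 0
    variant_dialect: str = "tsv"
    key_level: str = "allele"
    cosine_threshold: float = 0.85
    fdr_threshold: float = 0.05
    top_k_genes: int = 100
    min_count: int = 3
    t_low: float = 0.30
    t_high: float = 0.50
    min_mutations: int = 10
    fit_level: str = "sample"      # sample | cohort
    dedup_per_patient: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise PipelineConfigError(str(exc)) from exc

    def validate(self) -> None:
        for name in ("variants", "clinical", "gmt", "signature_matrix"):
            p = getattr(self, name)
            if not Path(p).is_file():
                raise PipelineConfigError(f"{name} path does not exist: {p}")
        EvolutionThresholds(self.t_low, self.t_high, self.min_mutations)
        if not (0 < self.cosine_threshold <= 1):
            raise PipelineConfigError("cosine_threshold must be in (0, 1]")
        if self.fit_level not in {"sample", "cohort"}:
            raise PipelineConfigError("fit_level must be 'sample' or 'cohort'")

    def sha256(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and write TSV outputs plus manifest.json.

    Any stage failure is re-raised with the stage named.  Returns the
    manifest dictionary.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "clonedivergence",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_sha256": config.sha256(),
        "stages": [],
    }

    stage = "load"
    try:
        variants = read_variant_table(config.variants, dialect=config.variant_dialect)
        clinicals = read_clinical_table(config.clinical)
        cohort = assemble_cohort(variants, clinicals)
        collection = read_gmt(config.gmt)
        sig_matrix = signatures.read_signature_matrix(config.signature_matrix)
        logger.info("load: %d variants, %d clinical records, %d patients",
                    len(variants), len(clinicals), len(cohort.pairs))
        manifest["stages"].append({"stage": stage, "n_variants": len(variants),
                                   "n_patients": len(cohort.pairs)})

        stage = "landscape"
        _run_landscape(config, cohort, out, manifest)

        stage = "signatures"
        _run_signatures(config, cohort, sig_matrix, out, manifest)

        stage = "pathways"
        _run_pathways(config, cohort, collection, out, manifest)

        stage = "evolution"
        calls = _run_evolution(config, cohort, out, manifest)

        stage = "association_survival"
        _run_association(config, cohort, calls, out, manifest)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _run_landscape(config, cohort: Cohort, out: Path, manifest: dict) -> None:
    profiles = cohort.profiles()
    _write(tally_alteration_classes(profiles), out / "landscape_summary.tsv")
    freq_p = landscape.gene_alteration_frequency(cohort, lesion=Lesion.PRIMARY, group="primary")
    freq_m = landscape.gene_alteration_frequency(cohort, lesion=Lesion.METASTASIS, group="metastasis")
    _write(pd.concat([freq_p, freq_m], ignore_index=True), out / "gene_frequency.tsv")
    _write(
        landscape.compare_gene_frequencies(freq_p, freq_m, min_count=config.min_count),
        out / "gene_comparison.tsv",
    )
    _write(landscape.cohort_correlations(cohort, "SNV"), out / "correlations_snv.tsv")
    _write(landscape.cohort_correlations(cohort, "CNV"), out / "correlations_cnv.tsv")
    counts, tests = landscape.cnv_chromosome_distribution(cohort)
    _write(counts, out / "cnv_by_chrom.tsv")
    _write(tests, out / "cnv_by_chrom_tests.tsv")
    _write(landscape.compare_fusions(cohort), out / "fusions.tsv")
    manifest["stages"].append({"stage": "landscape", "n_profiles": len(profiles)})


def _run_signatures(config, cohort: Cohort, matrix: pd.DataFrame, out: Path,
                    manifest: dict) -> None:
    spectra = {}
    if config.fit_level == "cohort":
        all_vars = [v for prof in cohort.profiles() for v in prof.variants]
        spectra["cohort"] = signatures.build_spectrum96(all_vars)
    else:
        for prof in cohort.profiles():
            label = f"{prof.patient_id}:{prof.lesion.value}"
            spectra[label] = signatures.build_spectrum96(prof.variants)
    spectra_df = pd.DataFrame(spectra)
    spectra_df.insert(0, "channel", list(signatures.CHANNELS_96))
    _write(spectra_df, out / "spectra.tsv")

    fits = {label: signatures.fit_signatures(spec, matrix) for label, spec in spectra.items()}
    selected, table = signatures.select_signatures(fits, threshold=config.cosine_threshold)
    table = table.reset_index()
    _write(table, out / "exposures.tsv")
    quality = pd.DataFrame(
        {"sample": list(fits), "cosine": [f.cosine for f in fits.values()],
         "residual": [f.residual for f in fits.values()]}
    )
    _write(quality, out / "fit_quality.tsv")
    manifest["stages"].append(
        {"stage": "signatures", "n_samples_fit": len(fits), "selected": selected}
    )


def _run_pathways(config, cohort: Cohort, collection, out: Path, manifest: dict) -> None:
    sync = [p.patient_id for p in cohort.pairs
            if p.clinical.metastasis_subtype.value == "synchronous"]
    meta = [p.patient_id for p in cohort.pairs
            if p.clinical.metastasis_subtype.value == "metachronous"]
    groups = {
        "primary": (list(cohort.pairs), Lesion.PRIMARY),
        "metastasis": (list(cohort.pairs), Lesion.METASTASIS),
    }
    if sync:
        groups["synchronous"] = ([cohort.get(pid) for pid in sync], None)
    if meta:
        groups["metachronous"] = ([cohort.get(pid) for pid in meta], None)

    enrich_frames = []
    significant: set[str] = set()
    for label, (pairs, lesion) in groups.items():
        sub = Cohort(pairs=tuple(pairs))
        top = top_frequent_genes(sub, k=config.top_k_genes, lesion=lesion)
        enr = enrich_pathways(top, collection, config.fdr_threshold)
        enr.insert(0, "group", label)
        enrich_frames.append(enr)
        significant |= set(enr.loc[enr["significant"], "pathway"])
    _write(pd.concat(enrich_frames, ignore_index=True), out / "enrichment.tsv")

    scored = pathway_score_table(
        collection, groups,
        pathways=sorted(significant) if significant else None,
        dedup_per_patient=config.dedup_per_patient,
    )
    scored = rank_and_cluster_scores(scored)
    _write(scored, out / "pathway_scores.tsv")
    manifest["stages"].append(
        {"stage": "pathways", "n_significant_pathways": len(significant)}
    )


def _run_evolution(config, cohort: Cohort, out: Path, manifest: dict) -> pd.DataFrame:
    thresholds = EvolutionThresholds(config.t_low, config.t_high, config.min_mutations)
    calls = evolution.cohort_evolution_calls(cohort, thresholds, config.key_level)
    _write(calls, out / "evolution_calls.tsv")
    subtype = {p.patient_id: p.clinical.metastasis_subtype.value for p in cohort.pairs}
    summary, tests = evolution.cohort_evolution_summary(calls, subtype)
    _write(summary, out / "evolution_summary.tsv")
    _write(tests, out / "evolution_subtype_tests.tsv")

    comp = evolution.pair_composition(calls)
    by_subtype = {
        s: comp[comp["patient_id"].map(subtype) == s]
        for s in ("synchronous", "metachronous")
    }
    by_subtype = {s: df for s, df in by_subtype.items() if len(df) >= 2}
    if len(by_subtype) >= 2:
        _write(evolution.compare_composition_anova(by_subtype), out / "composition_anova.tsv")
    manifest["stages"].append(
        {"stage": "evolution", "thresholds": [config.t_low, config.t_high],
         "n_classified": int((calls["call"] != "unclassifiable").sum())}
    )
    return calls


def _run_association(config, cohort: Cohort, calls: pd.DataFrame, out: Path,
                     manifest: dict) -> None:
    screen = association.gene_response_screen(cohort, min_count=config.min_count)
    _write(screen, out / "association.tsv")

    call_of = dict(zip(calls["patient_id"], calls["call"]))
    rows, km_rows = [], []
    group_times: dict[str, list[float]] = {}
    group_events: dict[str, list[bool]] = {}
    for pair in cohort.pairs:
        cls = call_of.get(pair.patient_id)
        rec = pair.clinical
        if cls in ("parallel", "intermediate", "linear") and rec.os_months is not None \
                and rec.os_event is not None:
            group_times.setdefault(cls, []).append(rec.os_months)
            group_events.setdefault(cls, []).append(rec.os_event)
        if cls and rec.effective is not None:
            rows.append({"patient_id": pair.patient_id, "call": cls,
                         "effective": rec.effective})

    # pairwise Fisher of response between evolution groups
    resp = pd.DataFrame(rows)
    pairwise = []
    order = ["parallel", "intermediate", "linear"]
    for i, g1 in enumerate(order):
        for g2 in order[i + 1:]:
            s1 = resp[resp["call"] == g1] if len(resp) else resp
            s2 = resp[resp["call"] == g2] if len(resp) else resp
            if len(s1) == 0 or len(s2) == 0:
                continue
            tab = association.Contingency2x2(
                int(s1["effective"].sum()), int((~s1["effective"]).sum()),
                int(s2["effective"].sum()), int((~s2["effective"]).sum()),
            )
            res = association.test_2x2(tab, method="fisher")
            pairwise.append({"group_a": g1, "group_b": g2,
                             "effective_a": int(s1["effective"].sum()), "n_a": len(s1),
                             "effective_b": int(s2["effective"].sum()), "n_b": len(s2),
                             "p_value": res.p_value})
    _write(pd.DataFrame(pairwise), out / "response_by_evolution.tsv")

    for cls, times in group_times.items():
        curve = association.km_curve(times, group_events[cls])
        for t, s, r in zip(curve.times, curve.survival, curve.at_risk):
            km_rows.append({"group": cls, "time": t, "survival": s, "at_risk": r})
    _write(pd.DataFrame(km_rows, columns=["group", "time", "survival", "at_risk"]),
           out / "km_curves.tsv")

    if len(group_times) >= 2:
        lr = association.logrank_test(group_times, group_events)
        _write(pd.DataFrame([{"chi2": lr.chi2, "df": lr.df, "p_value": lr.p_value,
                              "note": lr.note}]), out / "logrank.tsv")
    manifest["stages"].append(
        {"stage": "association_survival", "n_genes_screened": len(screen),
         "n_response_excluded": screen.attrs.get("n_excluded", 0)}
    )
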