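"""Synthetic paired-lesion cohort generator.

Emulates the statistical structure the downstream analyses assume: each
patient carries a primary and a metastatic lesion sharing a trunk clone,
with lesion-private branch mutations; the trunk fraction of the mutation
union is drawn from a per-class Beta distribution (parallel / intermediate
/ linear evolution); substitution trinucleotide contexts are drawn from a
patient-specific mixture of reference signatures; treatment response and
overall survival depend on the evolution class.  A truth table records the
generating class, trunk fraction and signature exposures per patient so
recovery can be measured exactly.

Defaults emulate the printed summaries of a 64-pair gastric-cancer
ovarian-metastasis cohort: class mix 18/17/20 of 55 classifiable, per-class
trunk-fraction medians near 0.08 / 0.40 / 0.63, per-class effective-response
probabilities 0.722 / 0.647 / 0.40, and exponential survival calibrated to
5-year OS of about 25% / 30% / ~0%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .signatures import (
    CHANNELS_96,
    cosine_similarity,
    reverse_complement,
    write_signature_matrix,
)
from .variant_model import (
    AlterationClass,
    ClinicalRecord,
    Cohort,
    Lesion,
    MetastasisSubtype,
    Response,
    SampleProfile,
    Variant,
    assemble_cohort,
    write_clinical_table,
    write_variant_table,
)

EVOLUTION_CLASSES = ("parallel", "intermediate", "linear")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Recurrent gastric-cancer genes, weighted above the background pool.
_DRIVER_GENES: tuple[tuple[str, float], ...] = (
    ("TP53", 30.0), ("ARID1A", 18.0), ("CDH1", 14.0), ("TTN", 12.0),
    ("ERBB2", 9.0), ("TGFBR2", 9.0), ("PIK3CA", 8.0), ("MUC16", 8.0),
    ("LRP1B", 7.0), ("FAT4", 6.0), ("CTNNB1", 5.0), ("APC", 5.0),
    ("RNF43", 4.0), ("KRAS", 4.0), ("ERBB3", 4.0), ("RHOA", 3.0),
    ("CCNE1", 3.0), ("MYC", 3.0), ("CDKN2A", 3.0), ("PTEN", 3.0),
    ("AXIN1", 2.0), ("EGFR", 2.0), ("SALL4", 1.5), ("CCDC105", 1.5),
    ("CLDN18", 1.5), ("AFF2", 1.5), ("PIK3CD", 1.5), ("TAF1L", 1.5),
)


def default_gene_pool(n_background: int = 180) -> tuple[tuple[str, float], ...]:
    """Driver genes plus a uniform-weight background pool."""
    background = tuple((f"GENE{i:03d}", 1.0) for i in range(1, n_background + 1))
    return _DRIVER_GENES + background


class GeneratorError(ValueError):
    """Degenerate generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-simulation parameters; defaults are the study conditions."""

    n_patients: int = 64
    seed: int = 0
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"parallel": 18 / 55, "intermediate": 17 / 55, "linear": 20 / 55}
    )
    # Beta(alpha, beta) of the trunk fraction per class; means 0.08/0.40/0.63
    shared_fraction_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "parallel": (4.0, 46.0),
            "intermediate": (60.0, 90.0),
            "linear": (63.0, 37.0),
        }
    )
    # Negative-binomial union SNV burden (mean, dispersion r); min enforced
    burden_mean: float = 120.0
    burden_dispersion: float = 8.0
    burden_min: int = 12
    # Per-patient Dirichlet concentration over reference signatures
    exposure_concentration: tuple[float, ...] = (1.2, 1.0, 0.8)
    n_signatures: int = 3
    signature_cosine_cap: float = 0.7
    gene_pool: tuple[tuple[str, float], ...] = field(default_factory=default_gene_pool)
    # Probability of an effective (CR/PR) response by evolution class
    response_model: Mapping[str, float] = field(
        default_factory=lambda: {"parallel": 0.722, "intermediate": 0.647, "linear": 0.40}
    )
    # Exponential death hazard per month by class; calibrated to 5-year OS
    # S(60) = 0.249 / 0.302 for parallel/intermediate; linear median ~10 mo
    survival_hazard: Mapping[str, float] = field(
        default_factory=lambda: {
            "parallel": 0.02317,
            "intermediate": 0.01996,
            "linear": 0.0693,
        }
    )
    censoring_rate: float = 0.004       # random loss to follow-up per month
    censor_horizon: float = 60.0        # administrative censoring, months
    # Probability of metachronous subtype by class (linear disseminates late)
    subtype_model: Mapping[str, float] = field(
        default_factory=lambda: {"parallel": 0.15, "intermediate": 0.35, "linear": 0.45}
    )
    # Non-SNV event rates (per lesion unless noted)
    amp_rate: float = 0.10              # amplifications per union SNV
    trunc_rate: float = 0.07            # truncations per union SNV
    homdel_rate: float = 0.01           # gene deletions per union SNV
    fusion_rate: float = 0.2            # mean fusions per lesion
    fusion_shared_prob: float = 0.4     # primary fusion also in metastasis
    # CNV chromosome biases (emulating amp clusters and a metastasis-specific
    # deletion excess on chromosome 9)
    amp_chroms: tuple[str, ...] = ("7", "11", "16", "17")
    amp_chrom_weight: float = 5.0
    met_del_chrom: str = "9"
    met_del_chrom_weight: float = 8.0
    n_chromosomes: int = 22
    chrom_length: int = 1_000_000

    def validate(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise GeneratorError(f"class_proportions sum to {total}, expected 1")
        for cls in EVOLUTION_CLASSES:
            if cls not in self.class_proportions:
                raise GeneratorError(f"class_proportions missing {cls!r}")
            a, b = self.shared_fraction_params[cls]
            if a <= 0 or b <= 0:
                raise GeneratorError(f"Beta parameters for {cls!r} must be > 0")
        if len(self.exposure_concentration) != self.n_signatures:
            raise GeneratorError("exposure_concentration length != n_signatures")
        if any(a <= 0 for a in self.exposure_concentration):
            raise GeneratorError("Dirichlet concentration must be > 0")
        if self.burden_mean <= 0 or self.burden_dispersion <= 0:
            raise GeneratorError("burden parameters must be > 0")

    def target_shared_median(self) -> float:
        """Median of the configured Beta-mixture trunk-fraction distribution."""
        classes = list(self.class_proportions)
        w = np.array([self.class_proportions[c] for c in classes])
        dists = [stats.beta(*self.shared_fraction_params[c]) for c in classes]
        cdf = lambda x: float(sum(wi * d.cdf(x) for wi, d in zip(w, dists)) - 0.5)
        return float(optimize.brentq(cdf, 1e-9, 1 - 1e-9))


def generate_reference_signatures(
    n_signatures: int,
    seed: int | np.random.Generator = 0,
    cosine_cap: float = 0.7,
    n_focus: int = 8,
    max_tries: int = 200,
) -> pd.DataFrame:
    """Random sparse 96 x S column-stochastic reference matrix.

    Each signature concentrates mass on a few focus channels over a small
    uniform background, and columns are re-drawn until all pairwise cosine
    similarities fall below ``cosine_cap`` (keeps NNLS refitting
    identifiable).
    """
    if n_signatures < 1:
        raise GeneratorError("n_signatures must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols: list[np.ndarray] = []
    for _ in range(n_signatures):
        for attempt in range(max_tries):
            focus = rng.choice(96, size=n_focus, replace=False)
            col = np.full(96, 0.05 / 96)
            col[focus] += 0.95 * rng.dirichlet(np.full(n_focus, 0.6))
            col /= col.sum()
            if all(cosine_similarity(col, c) < cosine_cap for c in cols):
                cols.append(col)
                break
        else:
            raise GeneratorError(
                f"could not draw {n_signatures} signatures with pairwise "
                f"cosine < {cosine_cap} in {max_tries} tries"
            )
    labels = [f"S{i + 1}" for i in range(n_signatures)]
    return pd.DataFrame(np.column_stack(cols), index=list(CHANNELS_96), columns=labels)


def _parse_channel(channel: str) -> tuple[str, str, str]:
    """Channel label -> (ref, alt, forward-strand context), pyrimidine frame."""
    five, rest = channel[0], channel[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return ref, alt, five + ref + three


def _draw_snv(
    rng: np.random.Generator,
    config: GeneratorConfig,
    channel_probs: np.ndarray,
    genes: np.ndarray,
    gene_weights: np.ndarray,
    used_sites: set[tuple[str, int]],
    vaf_ab: tuple[float, float],
) -> Variant:
    channel = CHANNELS_96[rng.choice(96, p=channel_probs)]
    ref, alt, ctx = _parse_channel(channel)
    if rng.random() < 0.5:  # record on the purine strand half the time
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        ctx = reverse_complement(ctx)
    while True:
        chrom = str(rng.integers(1, config.n_chromosomes + 1))
        pos = int(rng.integers(2, config.chrom_length))
        if (chrom, pos) not in used_sites:
            used_sites.add((chrom, pos))
            break
    return Variant(
        patient_id="", lesion=Lesion.PRIMARY, gene=str(rng.choice(genes, p=gene_weights)),
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        alteration_class=AlterationClass.SUBSTITUTION_INDEL,
        vaf=float(np.clip(rng.beta(*vaf_ab), 0.01, 1.0)),
        context=ctx,
    )


def _place(v: Variant, patient_id: str, lesion: Lesion, vaf_jitter: float | None = None) -> Variant:
    vaf = v.vaf
    if vaf_jitter is not None and vaf is not None:
        vaf = float(np.clip(vaf + vaf_jitter, 0.01, 1.0))
    return replace(v, patient_id=patient_id, lesion=lesion, vaf=vaf)


def generate_cohort(
    config: GeneratorConfig,
    signature_matrix: pd.DataFrame | None = None,
) -> tuple[Cohort, pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; returns (cohort, truth table, signature matrix).

    Truth-table columns: patient_id, true_class, drawn_shared_fraction,
    realized_shared_fraction, n_union, and one ``exposure_<label>`` column
    per reference signature (fractions summing to 1).  Fixed seed gives
    bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if signature_matrix is None:
        signature_matrix = generate_reference_signatures(
            config.n_signatures, rng, config.signature_cosine_cap
        )
    sig_cols = signature_matrix.to_numpy(dtype=float)
    sig_labels = list(signature_matrix.columns)

    genes = np.array([g for g, _ in config.gene_pool])
    gene_w = np.array([w for _, w in config.gene_pool], dtype=float)
    gene_w /= gene_w.sum()

    classes = list(config.class_proportions)
    class_p = np.array([config.class_proportions[c] for c in classes])
    nb_r = config.burden_dispersion
    nb_p = nb_r / (nb_r + config.burden_mean)

    variants: list[Variant] = []
    clinicals: list[ClinicalRecord] = []
    truth_rows: list[dict] = []

    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        cls = classes[rng.choice(len(classes), p=class_p)]
        f = float(rng.beta(*config.shared_fraction_params[cls]))
        n_union = max(int(rng.negative_binomial(nb_r, nb_p)), config.burden_min)
        n_trunk = int(np.floor(f * n_union))
        n_branch = n_union - n_trunk
        n_pri_branch = int(rng.binomial(n_branch, 0.5))
        n_met_branch = n_branch - n_pri_branch

        exposures = rng.dirichlet(np.asarray(config.exposure_concentration))
        channel_probs = sig_cols @ exposures
        channel_probs /= channel_probs.sum()

        used_sites: set[tuple[str, int]] = set()
        draw = lambda vaf_ab: _draw_snv(
            rng, config, channel_probs, genes, gene_w, used_sites, vaf_ab
        )
        for _ in range(n_trunk):
            v = draw((16.0, 24.0))  # clonal trunk, VAF ~ 0.4
            variants.append(_place(v, pid, Lesion.PRIMARY))
            variants.append(
                _place(v, pid, Lesion.METASTASIS, vaf_jitter=float(rng.normal(0, 0.03)))
            )
        for _ in range(n_pri_branch):
            variants.append(_place(draw((6.0, 24.0)), pid, Lesion.PRIMARY))
        for _ in range(n_met_branch):
            variants.append(_place(draw((6.0, 24.0)), pid, Lesion.METASTASIS))

        variants.extend(_non_snv_events(rng, config, pid, n_union, genes, gene_w))

        metachronous = rng.random() < config.subtype_model[cls]
        effective = rng.random() < config.response_model[cls]
        response = Response(str(rng.choice(["CR", "PR"] if effective else ["SD", "PD"])))
        death_t = float(rng.exponential(1.0 / config.survival_hazard[cls]))
        cens_t = (
            float(rng.exponential(1.0 / config.censoring_rate))
            if config.censoring_rate > 0
            else np.inf
        )
        t = min(death_t, cens_t, config.censor_horizon)
        clinicals.append(
            ClinicalRecord(
                patient_id=pid,
                metastasis_subtype=(
                    MetastasisSubtype.METACHRONOUS if metachronous else MetastasisSubtype.SYNCHRONOUS
                ),
                extent=str(rng.choice(["local", "diffuse"], p=[0.34, 0.66])),
                laterality=str(rng.choice(["bilateral", "unilateral"], p=[0.76, 0.24])),
                lauren=str(rng.choice(["diffuse", "intestinal", "mixed"], p=[0.33, 0.28, 0.39])),
                pathology=str(rng.choice(["non_signet", "signet"], p=[0.92, 0.08])),
                response=response,
                os_months=round(t, 2),
                os_event=death_t <= min(cens_t, config.censor_horizon),
            )
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "true_class": cls,
                "drawn_shared_fraction": f,
                "realized_shared_fraction": n_trunk / n_union,
                "n_union": n_union,
                **{f"exposure_{s}": e for s, e in zip(sig_labels, exposures)},
            }
        )

    cohort = assemble_cohort(
        variants, clinicals, metadata={"generator": "clonedivergence.synthetic_cohort",
                                       "seed": str(config.seed)}
    )
    truth = pd.DataFrame(truth_rows)
    return cohort, truth, signature_matrix


def _non_snv_events(
    rng: np.random.Generator,
    config: GeneratorConfig,
    pid: str,
    n_union: int,
    genes: np.ndarray,
    gene_w: np.ndarray,
) -> list[Variant]:
    """Gene-level CNVs, truncations and fusions, independent per lesion."""
    out: list[Variant] = []
    n_chrom = config.n_chromosomes
    amp_w = np.ones(n_chrom)
    for c in config.amp_chroms:
        amp_w[int(c) - 1] = config.amp_chrom_weight
    amp_w /= amp_w.sum()

    for lesion in (Lesion.PRIMARY, Lesion.METASTASIS):
        del_w = np.ones(n_chrom)
        if lesion is Lesion.METASTASIS:
            del_w[int(config.met_del_chrom) - 1] = config.met_del_chrom_weight
        del_w /= del_w.sum()

        def event(cls: AlterationClass, chrom_w: np.ndarray) -> Variant:
            chrom = str(rng.choice(n_chrom, p=chrom_w) + 1)
            return Variant(
                patient_id=pid, lesion=lesion, gene=str(rng.choice(genes, p=gene_w)),
                chrom=chrom, pos=int(rng.integers(2, config.chrom_length)),
                ref="-", alt="-", alteration_class=cls,
            )

        for _ in range(rng.poisson(config.amp_rate * n_union)):
            out.append(event(AlterationClass.AMPLIFICATION, amp_w))
        for _ in range(rng.poisson(config.homdel_rate * n_union)):
            out.append(event(AlterationClass.HOMOZYGOUS_DELETION, del_w))
        for _ in range(rng.poisson(config.trunc_rate * n_union)):
            out.append(event(AlterationClass.TRUNCATION, np.full(n_chrom, 1 / n_chrom)))

    fusion_pairs = [("CLDN18", "ARHGAP26"), ("CLDN18", "ARHGAP42"), ("TCF3", "MBD3")]
    for _ in range(rng.poisson(config.fusion_rate)):
        if rng.random() < 0.5:
            gene, partner = fusion_pairs[rng.choice(len(fusion_pairs))]
        else:
            gene, partner = rng.choice(genes, size=2, replace=False)
        chrom = str(rng.integers(1, n_chrom + 1))
        pos = int(rng.integers(2, config.chrom_length))
        fus = Variant(
            patient_id=pid, lesion=Lesion.PRIMARY, gene=str(gene), chrom=chrom,
            pos=pos, ref="-", alt="-",
            alteration_class=AlterationClass.FUSION_REARRANGEMENT,
            fusion_partner=str(partner),
        )
        out.append(fus)
        if rng.random() < config.fusion_shared_prob:
            out.append(replace(fus, lesion=Lesion.METASTASIS))
    return out


def simulate_to_dir(config: GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the generator and write variants/clinical/truth/signature TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort, truth, sig = generate_cohort(config)
    paths = {
        "variants": outdir / "variants.tsv",
        "clinical": outdir / "clinical.tsv",
        "truth": outdir / "truth.tsv",
        "signatures": outdir / "signatures.tsv",
    }
    all_variants = [v for prof in cohort.profiles() for v in prof.variants]
    write_variant_table(all_variants, paths["variants"])
    write_clinical_table([p.clinical for p in cohort.pairs], paths["clinical"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    write_signature_matrix(sig, paths["signatures"])
    return paths
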