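"""Top-gene selection, hypergeometric gene-set enrichment, and the
group-level Pathway Score.

Enrichment of a selected gene list against a GMT collection is tested
with the one-sided (upper-tail) hypergeometric distribution and
Benjamini-Hochberg FDR control; pathways with FDR < 0.05 are significant.
The Pathway Score for a group of patients is

    score = (sum of mutations across the pathway's genes in the group)
            / (pathway gene count x patient cohort size)

counting alteration records by default (a per-patient deduplicated
variant is available).  Heatmap binning follows the 0.25 pivot: below is
the blue range, exactly 0.25 white, above red.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .variant_model import Cohort, Lesion, PatientPair


class PathwayError(ValueError):
    """Empty collection/pathway or invalid p-values."""


@dataclass(frozen=True)
class GeneSetCollection:
    """Pathway name -> member genes, with a background universe.

    The universe defaults to the union of all member genes; every set
    must be nonempty and contained in the universe.
    """

    sets: Mapping[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.sets:
            raise PathwayError("empty gene-set collection")
        for name, members in self.sets.items():
            if not members:
                raise PathwayError(f"empty gene set {name!r}")
            if not members <= self.universe:
                raise PathwayError(f"gene set {name!r} not contained in universe")

    @classmethod
    def from_sets(
        cls,
        sets: Mapping[str, Iterable[str]],
        universe: Iterable[str] | None = None,
    ) -> "GeneSetCollection":
        frozen = {name: frozenset(genes) for name, genes in sets.items()}
        uni = frozenset(universe) if universe is not None else frozenset().union(*frozen.values())
        return cls(sets=frozen, universe=uni)


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB gene TAB gene ...)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    if not sets:
        raise PathwayError(f"{path}: no gene sets parsed")
    return GeneSetCollection.from_sets(sets, universe)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")


def top_frequent_genes(
    cohort: Cohort,
    k: int = 100,
    lesion: Lesion | None = None,
    patients: Sequence[str] | None = None,
    tie_policy: str = "alphabetical",
) -> list[str]:
    """Top-k genes by mutated-patient frequency, descending.

    ``tie_policy='alphabetical'`` cuts ties at the rank-k boundary
    alphabetically; ``'keep-all'`` keeps every gene tied with rank k.
    """
    if k < 1:
        raise PathwayError("k must be >= 1")
    carriers: dict[str, set[str]] = {}
    selected = [p for p in cohort.pairs if patients is None or p.patient_id in patients]
    if not selected:
        raise PathwayError("empty patient selection")
    for pair in selected:
        for prof in (pair.primary, pair.metastasis):
            if prof is None or (lesion is not None and prof.lesion != lesion):
                continue
            for v in prof.variants:
                carriers.setdefault(v.gene, set()).add(pair.patient_id)
    if not carriers:
        raise PathwayError("no mutated genes in selection")
    ranked = sorted(carriers, key=lambda g: (-len(carriers[g]), g))
    if tie_policy == "keep-all" and len(ranked) > k:
        cutoff = len(carriers[ranked[k - 1]])
        while k < len(ranked) and len(carriers[ranked[k]]) == cutoff:
            k += 1
    return ranked[:k]


def hypergeom_enrichment_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric P(X >= k) for k hits of a K-gene pathway
    in an n-gene list drawn from an N-gene universe."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up q-values, mapped back to input order and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1) | np.isnan(p)).any():
        raise PathwayError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_pathways(
    gene_list: Iterable[str],
    collection: GeneSetCollection,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a gene list over every pathway.

    Genes outside the universe are dropped (count in
    ``attrs['n_dropped']``).  Columns: pathway, k, K, n, N, p_value, fdr,
    significant (fdr < threshold); sorted by p then name.
    """
    genes = set(gene_list)
    inside = genes & collection.universe
    n_dropped = len(genes) - len(inside)
    N = len(collection.universe)
    n = len(inside)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        k = len(inside & members)
        K = len(members)
        rows.append(
            {"pathway": name, "k": k, "K": K, "n": n, "N": N,
             "p_value": hypergeom_enrichment_p(k, K, n, N)}
        )
    df = pd.DataFrame(rows)
    df["fdr"] = benjamini_hochberg(df["p_value"].to_numpy())
    df["significant"] = df["fdr"] < fdr_threshold
    df = df.sort_values(["p_value", "pathway"], ignore_index=True)
    df.attrs["n_dropped"] = n_dropped
    return df


def pathway_score(
    pathway_genes: Iterable[str],
    pairs: Sequence[PatientPair],
    lesion: Lesion | None = None,
    dedup_per_patient: bool = False,
) -> float:
    """Group-level Pathway Score.

    score = mutation_sum / (gene_count x cohort_size), where mutation_sum
    counts every alteration record on the pathway's genes in the group's
    chosen lesion(s) (or at most one record per patient per gene with
    ``dedup_per_patient``).
    """
    genes = set(pathway_genes)
    if not genes:
        raise PathwayError("empty pathway")
    if not pairs:
        raise PathwayError("empty patient group")
    total = 0
    for pair in pairs:
        seen: set[str] = set()
        for prof in (pair.primary, pair.metastasis):
            if prof is None or (lesion is not None and prof.lesion != lesion):
                continue
            for v in prof.variants:
                if v.gene in genes:
                    if dedup_per_patient:
                        seen.add(v.gene)
                    else:
                        total += 1
        total += len(seen)
    return total / (len(genes) * len(pairs))


def pathway_score_table(
    collection: GeneSetCollection,
    groups: Mapping[str, tuple[Sequence[PatientPair], Lesion | None]],
    pathways: Iterable[str] | None = None,
    dedup_per_patient: bool = False,
) -> pd.DataFrame:
    """Pathway Score for every (pathway, group), with heatmap bins.

    ``groups`` maps a group label to (patient pairs, lesion filter).
    """
    names = sorted(pathways) if pathways is not None else sorted(collection.sets)
    rows = []
    for name in names:
        genes = collection.sets[name]
        for label, (pairs, lesion) in groups.items():
            score = pathway_score(genes, pairs, lesion, dedup_per_patient)
            rows.append(
                {
                    "pathway": name,
                    "group": label,
                    "gene_count": len(genes),
                    "cohort_size": len(pairs),
                    "score": score,
                }
            )
    return bin_scores(pd.DataFrame(rows))


def bin_scores(table: pd.DataFrame, pivot: float = 0.25) -> pd.DataFrame:
    """Heatmap bins: score < pivot blue, == pivot white, > pivot red."""
    def bin_one(s: float) -> str:
        if s < pivot:
            return "low_blue"
        if s == pivot:
            return "mid_white"
        return "high_red"

    out = table.copy()
    out["bin"] = [bin_one(s) for s in out["score"]]
    return out


def rank_and_cluster_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Order pathways by average-linkage hierarchical clustering of their
    score vectors (Euclidean), then by descending mean score within the
    leaf order."""
    wide = table.pivot(index="pathway", columns="group", values="score")
    if len(wide) > 2:
        link = hierarchy.linkage(wide.to_numpy(), method="average", metric="euclidean")
        leaves = hierarchy.leaves_list(link)
        wide = wide.iloc[leaves]
    order = wide.mean(axis=1).sort_values(ascending=False, kind="stable").index
    out = table.set_index("pathway").loc[order].reset_index()
    return out
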