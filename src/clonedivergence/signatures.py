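"""96-channel substitution spectra and reference-signature refitting.

Single-base substitutions are folded onto the six pyrimidine-centered
substitution types (C>A, C>G, C>T, T>A, T>C, T>G) and, with their
trinucleotide context, onto the standard 96 channels ordered
substitution-major with flanking bases alphabetical within each type
(A[C>A]A, A[C>A]C, ..., T[T>G]T).  Exposures to a fixed reference
signature matrix are refit by nonnegative least squares and a per-sample
fit is accepted when the cosine similarity between the observed spectrum
and its reconstruction exceeds a threshold (default 0.85).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .variant_model import Variant

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Pyrimidine-centered substitution types, canonical order.
SUBSTITUTION_TYPES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Six-channel labels with both strand representations spelled out.
SIX_CHANNEL_LABELS: tuple[str, ...] = (
    "C>A/G>T", "C>G/G>C", "C>T/G>A", "T>A/A>T", "T>C/A>G", "T>G/A>C",
)

_BASES = ("A", "C", "G", "T")

#: The 96 trinucleotide channels, e.g. "A[C>A]A", substitution-major order.
CHANNELS_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_TYPES
    for five in _BASES
    for three in _BASES
)

_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def fold_substitution(ref: str, alt: str) -> str:
    """Map a substitution onto its pyrimidine-centered type."""
    ref, alt = ref.upper(), alt.upper()
    if ref in "GA":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    sub = f"{ref}>{alt}"
    if sub not in SUBSTITUTION_TYPES:
        raise ValueError(f"not a substitution: {ref}>{alt}")
    return sub


def fold_context(ref: str, alt: str, context: str) -> str:
    """Map (ref, alt, 5'->3' context) onto its 96-channel label.

    Purine-reference substitutions are reverse-complemented onto the
    pyrimidine strand; folding is idempotent.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if context[1] != ref:
        raise ValueError(f"context middle base {context[1]} != ref {ref}")
    if ref in "GA":
        context = reverse_complement(context)
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def six_channel_profile(variants: Iterable[Variant]) -> pd.Series:
    """Counts over the six strand-folded substitution types.

    Non-SNV records are ignored (their count is reported via
    ``Series.attrs['n_skipped']``); the profile sums to the number of
    SNVs retained.
    """
    counts = pd.Series(0, index=list(SIX_CHANNEL_LABELS), dtype=int)
    skipped = 0
    for v in variants:
        if not v.is_snv:
            skipped += 1
            continue
        sub = fold_substitution(v.ref, v.alt)
        counts[SIX_CHANNEL_LABELS[SUBSTITUTION_TYPES.index(sub)]] += 1
    counts.attrs["n_skipped"] = skipped
    return counts


def build_spectrum96(
    variants: Iterable[Variant],
    fasta: str | Path | None = None,
) -> pd.Series:
    """96-channel spectrum from SNVs carrying a trinucleotide context.

    Context comes from each record; when absent and ``fasta`` is given,
    it is looked up as the forward-strand bases pos-1..pos+1 (1-based).
    SNVs whose context cannot be resolved, or whose context middle base
    contradicts the reference allele, are dropped and counted in
    ``attrs['n_skipped']``.  The spectrum sums to the SNVs retained.
    """
    lookup = _FastaContext(fasta) if fasta is not None else None
    counts = np.zeros(96, dtype=float)
    skipped = 0
    for v in variants:
        if not v.is_snv:
            skipped += 1
            continue
        ctx = v.context
        if ctx is None and lookup is not None:
            ctx = lookup.get(v.chrom, v.pos)
        if ctx is None:
            skipped += 1
            continue
        try:
            channel = fold_context(v.ref, v.alt, ctx)
        except ValueError:
            skipped += 1
            continue
        counts[_CHANNEL_INDEX[channel]] += 1
    out = pd.Series(counts, index=list(CHANNELS_96))
    out.attrs["n_skipped"] = skipped
    return out


class _FastaContext:
    """Forward-strand trinucleotide lookup from a FASTA reference."""

    def __init__(self, path: str | Path):
        self._seqs: dict[str, str] = {}
        name = None
        chunks: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if name is not None:
                        self._seqs[name] = "".join(chunks)
                    name = line[1:].split()[0]
                    chunks = []
                elif line:
                    chunks.append(line.upper())
        if name is not None:
            self._seqs[name] = "".join(chunks)

    def get(self, chrom: str, pos: int) -> str | None:
        seq = self._seqs.get(chrom)
        if seq is None or pos < 2 or pos + 1 > len(seq):
            return None
        ctx = seq[pos - 2 : pos + 1]
        return ctx if set(ctx) <= set("ACGT") else None


# ---------------------------------------------------------------------------
# Reference matrix and refitting


def read_signature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a COSMIC-style 96 x S TSV (first column: channel label).

    Rows are reindexed onto the canonical channel order; columns must be
    nonnegative and are renormalised to sum to one.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CHANNELS_96) - set(df.index)
    if missing:
        raise ValueError(f"signature matrix lacks {len(missing)} channels")
    df = df.loc[list(CHANNELS_96)].astype(float)
    if (df.values < 0).any():
        raise ValueError("signature matrix has negative entries")
    return df / df.sum(axis=0)


def write_signature_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="channel")


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    return float(np.dot(a, b) / (na * nb))


@dataclass(frozen=True)
class SignatureFit:
    """NNLS refit of a 96-channel spectrum against reference signatures."""

    exposures: pd.Series          # nonnegative, per reference signature
    reconstruction: np.ndarray    # matrix @ exposures, 96-vector
    cosine: float                 # observed vs reconstruction; NaN if zero spectrum
    residual: float               # 2-norm of the residual

    def exposure_fractions(self) -> pd.Series:
        total = self.exposures.sum()
        if total == 0:
            return self.exposures * 0.0
        return self.exposures / total


def fit_signatures(spectrum: pd.Series | np.ndarray, matrix: pd.DataFrame) -> SignatureFit:
    """Refit exposures: min ||spectrum - matrix @ e||_2 subject to e >= 0.

    A zero spectrum yields zero exposures with cosine NaN.
    """
    y = np.asarray(spectrum, dtype=float)
    if y.shape != (96,):
        raise ValueError(f"spectrum must have 96 channels, got {y.shape}")
    A = matrix.to_numpy(dtype=float)
    if y.sum() == 0:
        zeros = pd.Series(0.0, index=matrix.columns)
        return SignatureFit(zeros, np.zeros(96), float("nan"), 0.0)
    coefs, resid = nnls(A, y)
    recon = A @ coefs
    return SignatureFit(
        exposures=pd.Series(coefs, index=matrix.columns),
        reconstruction=recon,
        cosine=cosine_similarity(y, recon),
        residual=float(resid),
    )


def select_signatures(
    fits: Mapping[str, SignatureFit],
    threshold: float = 0.85,
) -> tuple[list[str], pd.DataFrame]:
    """Cohort-level signature selection by cosine-similarity gating.

    A signature is retained when it carries nonzero exposure in at least
    one sample whose fit cosine is strictly greater than ``threshold``.
    Returns the selected labels and a per-sample table of exposure
    fractions with the fit cosine.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    selected: set[str] = set()
    rows = []
    for sample, fit in fits.items():
        frac = fit.exposure_fractions()
        passed = bool(fit.cosine > threshold)  # NaN compares False
        if passed:
            selected |= set(fit.exposures.index[fit.exposures > 0])
        rows.append({"sample": sample, "cosine": fit.cosine, "passed": passed, **frac})
    table = pd.DataFrame(rows).set_index("sample")
    order = [s for s in fits[next(iter(fits))].exposures.index if s in selected] if fits else []
    return order, table
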