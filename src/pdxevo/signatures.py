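"""Mutational-signature refitting on the 96 trinucleotide contexts.

Samples with at least 20 somatic SNVs are refit against a supplied SBS
signature matrix (e.g. COSMIC v3.2) by nonnegative least squares on the
normalized spectrum, with the weights renormalized to sum to one. No
signature is excluded a priori and no exposure scaling is applied. For
display, a signature is retained when its weight reaches 0.25 in at least
one sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import DegenerateDataError, ValidationError

_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

#: Canonical order of the 96 pyrimidine-centered contexts, "A[C>A]A" style.
CONTEXTS_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in _SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)
_CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXTS_96)}


class SignatureMatrix:
    """96-context x signature probability matrix.

    Rows are reordered to the canonical context order; every column must be a
    probability vector (nonnegative, summing to 1 within 1e-6).
    """

    def __init__(self, data: pd.DataFrame):
        missing = set(CONTEXTS_96) - set(data.index)
        if missing:
            raise ValidationError(
                f"signature matrix missing {len(missing)} contexts, e.g. "
                f"{sorted(missing)[:3]}"
            )
        data = data.loc[list(CONTEXTS_96)].astype(float)
        if (data.to_numpy() < -1e-12).any():
            raise ValidationError("signature matrix has negative entries")
        colsums = data.sum(axis=0)
        bad = colsums[(colsums - 1.0).abs() > 1e-6]
        if len(bad):
            raise ValidationError(
                f"signature column(s) do not sum to 1: {dict(bad.round(6))}"
            )
        self.data = data

    @property
    def signatures(self) -> list[str]:
        return list(self.data.columns)

    def __getitem__(self, name: str) -> pd.Series:
        return self.data[name]


@dataclass
class SignatureFit:
    weights: dict[str, float]
    reconstruction_error: float  # L2 norm of the residual spectrum
    n_mutations: int
    eligible: bool  # n_mutations >= min_mutations


def count_contexts(contexts: Iterable[str]) -> pd.Series:
    """Tally SNV trinucleotide contexts into the canonical 96-vector."""
    counts = np.zeros(96, dtype=int)
    for label in contexts:
        try:
            counts[_CONTEXT_INDEX[label]] += 1
        except KeyError:
            raise ValidationError(f"malformed 96-context label {label!r}") from None
    return pd.Series(counts, index=list(CONTEXTS_96), name="count")


def refit(
    counts: pd.Series | np.ndarray,
    matrix: SignatureMatrix,
    min_mutations: int = 20,
) -> SignatureFit:
    """Refit a mutation spectrum against known signatures.

    Minimizes ``|| spectrum - M w ||_2`` over nonnegative ``w`` and
    renormalizes the weights to sum to 1. A fit is returned regardless of the
    mutation count, flagged ``eligible=False`` below ``min_mutations``.
    """
    if isinstance(counts, pd.Series):
        counts = counts.reindex(list(CONTEXTS_96)).fillna(0.0)
        vec = counts.to_numpy(float)
    else:
        vec = np.asarray(counts, float)
        if vec.shape != (96,):
            raise ValidationError(f"expected a 96-vector, got shape {vec.shape}")
    total = vec.sum()
    if total < 1:
        raise DegenerateDataError("cannot refit an empty mutation spectrum")
    spectrum = vec / total
    m = matrix.data.to_numpy(float)
    w, residual = nnls(m, spectrum)
    wsum = w.sum()
    if wsum > 0:
        w = w / wsum
    return SignatureFit(
        weights=dict(zip(matrix.signatures, w.tolist())),
        reconstruction_error=float(residual),
        n_mutations=int(round(total)),
        eligible=total >= min_mutations,
    )


def display_filter(
    fits: Mapping[str, SignatureFit], threshold: float = 0.25
) -> tuple[list[str], pd.DataFrame]:
    """Select signatures worth displaying across a cohort.

    A signature is retained iff its weight reaches ``threshold`` in at least
    one sample; the returned boolean frame flags the per-sample weights
    strictly above ``threshold`` (the asterisk rule).
    """
    if not fits:
        raise DegenerateDataError("no fits supplied")
    weights = pd.DataFrame({s: f.weights for s, f in fits.items()}).T.fillna(0.0)
    retained = [sig for sig in weights.columns if (weights[sig] >= threshold).any()]
    flags = weights[retained] > threshold
    return retained, flags
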