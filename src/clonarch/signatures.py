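"""Mutational signature refitting by non-negative least squares.

A 96-channel mutation spectrum is decomposed over a reference catalogue of
single-base-substitution (SBS) signatures by solving

    w = argmin || spectrum - S w ||_2   subject to  w >= 0

in counts space (no normalization of the observed spectrum before the fit).
Goodness of fit is the cosine similarity between the observed and the
reconstructed spectrum. Signature groups (e.g. the mismatch-repair-deficiency
signatures SBS6/14/15/21/26/44, or the POLE-deficiency group) can be
collapsed into summed contributions for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .variants import SPECTRUM_CHANNELS, MutationSpectrum

__all__ = [
    "SignatureSet",
    "SignatureFit",
    "CollapsedFit",
    "MMRD_SIGNATURES",
    "POLE_SIGNATURES",
    "DEFAULT_SIGNATURE_GROUPS",
    "fit_signatures",
    "collapse_signature_groups",
    "cosine_similarity",
]

#: Signature groups collapsed for reporting: mismatch-repair deficiency and
#: POLE (polymerase-epsilon) deficiency.
MMRD_SIGNATURES = ("SBS6", "SBS14", "SBS15", "SBS21", "SBS26", "SBS44")
POLE_SIGNATURES = ("SBS10a", "SBS10b", "SBS28", "SBS17b")
DEFAULT_SIGNATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "MMRd": MMRD_SIGNATURES,
    "POLE": POLE_SIGNATURES,
}

#: Catalogue subset of mutational processes active in colon and lung cancer
#: (tobacco smoking excluded), for use with an externally supplied catalogue.
COLON_LUNG_SIGNATURES = (
    "SBS1", "SBS5", "SBS6", "SBS10a", "SBS10b", "SBS14", "SBS15", "SBS17a",
    "SBS17b", "SBS18", "SBS21", "SBS26", "SBS28", "SBS37", "SBS40", "SBS44",
)


@dataclass(frozen=True)
class SignatureSet:
    """Reference signatures: a (96, k) matrix of per-channel probabilities."""

    names: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (96, len(self.names)):
            raise ValueError(f"matrix must be (96, {len(self.names)}), got {m.shape}")
        if np.any(m < 0):
            raise ValueError("signature probabilities must be non-negative")
        sums = m.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("each signature's channels must sum to 1 (+-1e-6)")

    @classmethod
    def from_tsv(cls, path) -> "SignatureSet":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.reindex(list(SPECTRUM_CHANNELS))
        if df.isna().any().any():
            raise ValueError("signature TSV is missing channels")
        return cls(names=tuple(df.columns), matrix=df.to_numpy())

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.matrix, index=list(SPECTRUM_CHANNELS), columns=list(self.names)
        ).to_csv(path, sep="\t")

    def subset(self, names: Sequence[str]) -> "SignatureSet":
        idx = [self.names.index(n) for n in names]
        return SignatureSet(names=tuple(names), matrix=self.matrix[:, idx])


@dataclass(frozen=True)
class SignatureFit:
    weights: Mapping[str, float]  # mutation counts attributed per signature
    reconstructed: np.ndarray
    cosine: float
    residual_norm: float

    @property
    def total_weight(self) -> float:
        return float(sum(self.weights.values()))

    @property
    def fractions(self) -> dict[str, float]:
        total = self.total_weight
        return {k: (w / total if total else 0.0) for k, w in self.weights.items()}


def cosine_similarity(a: Sequence[float], b: Sequence[float]) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("spectra must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def fit_signatures(
    spectrum: MutationSpectrum | np.ndarray, signatures: SignatureSet
) -> SignatureFit:
    """Non-negative least-squares refit of a spectrum on a signature catalogue."""
    obs = spectrum.counts if isinstance(spectrum, MutationSpectrum) else np.asarray(spectrum, float)
    if obs.shape != (96,):
        raise ValueError("spectrum must have 96 channels")
    if obs.sum() == 0:
        raise ValueError("cannot fit an all-zero spectrum")
    w, rnorm = optimize.nnls(signatures.matrix, obs)
    recon = signatures.matrix @ w
    return SignatureFit(
        weights=dict(zip(signatures.names, map(float, w))),
        reconstructed=recon,
        cosine=cosine_similarity(obs, recon) if recon.sum() > 0 else 0.0,
        residual_norm=float(rnorm),
    )


@dataclass(frozen=True)
class CollapsedFit:
    weights: Mapping[str, float]  # group or passthrough-signature -> summed weight
    fractions: Mapping[str, float]


def collapse_signature_groups(
    fit: SignatureFit, groups: Mapping[str, Sequence[str]] = DEFAULT_SIGNATURE_GROUPS
) -> CollapsedFit:
    """Sum fitted weights within signature groups; ungrouped signatures pass
    through individually. Reports both weights and fractions of the total."""
    grouped_members = set()
    for name, members in groups.items():
        for m in members:
            if m not in fit.weights:
                raise ValueError(f"group {name!r} references unknown signature {m!r}")
            grouped_members.add(m)
    weights = {
        name: float(sum(fit.weights[m] for m in members))
        for name, members in groups.items()
    }
    for sig, w in fit.weights.items():
        if sig not in grouped_members:
            weights[sig] = float(w)
    total = sum(weights.values())
    fractions = {k: (w / total if total else 0.0) for k, w in weights.items()}
    return CollapsedFit(weights=weights, fractions=fractions)
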