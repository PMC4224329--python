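"""Contamination estimation from diagnostic positions.

A diagnostic position is a site where the sample's base differs from the
near-unanimous base of a modern reference panel, so any read covering it
reveals its origin.  Each (molecule, covered diagnostic position)
observation is classified as clean (sample base), contaminating
(panel-consensus base) or other (any third base or N; excluded from the
denominator).  The contamination rate is the contaminating fraction with
a Wilson score confidence interval, whose upper endpoint serves as a
conservative bound — well-behaved even at zero observed contaminant reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.stats import norm

from .errors import ConfigError, UndefinedEstimateError
from .reads import AlignedRead
from .reference import GenomeRecord

__all__ = [
    "DiagnosticSite",
    "DiagnosticPanel",
    "ContaminationEstimate",
    "find_diagnostic_positions",
    "count_diagnostic_reads",
    "wilson_interval",
    "wilson_upper",
    "estimate_contamination",
]


@dataclass(frozen=True)
class DiagnosticSite:
    position: int  # 1-based
    sample_base: str
    contaminant_base: str
    panel_agreement: float

    def __post_init__(self) -> None:
        if self.sample_base == self.contaminant_base:
            raise ConfigError(
                f"diagnostic site {self.position}: sample and contaminant base identical"
            )


@dataclass
class DiagnosticPanel:
    """Sorted, unique diagnostic sites plus panel provenance."""

    sites: List[DiagnosticSite]
    panel_size: int
    agreement_threshold: float = 0.99

    def __post_init__(self) -> None:
        positions = [s.position for s in self.sites]
        if len(set(positions)) != len(positions):
            raise ConfigError("diagnostic positions must be unique")
        self.sites = sorted(self.sites, key=lambda s: s.position)
        for s in self.sites:
            if s.panel_agreement < self.agreement_threshold:
                raise ConfigError(
                    f"site {s.position}: agreement {s.panel_agreement:.4f} below "
                    f"threshold {self.agreement_threshold}"
                )

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites], dtype=np.int64)


def find_diagnostic_positions(
    sample: GenomeRecord,
    panel: Sequence[GenomeRecord],
    threshold: float = 0.99,
) -> DiagnosticPanel:
    """Sites where the panel is >= ``threshold`` unanimous on a base that
    differs from the sample's.

    Panel Ns are ignored per site (agreement is computed over non-N panel
    bases); sites where the sample itself is N are skipped rather than
    guessed.
    """
    if not panel:
        raise ConfigError("panel of modern genomes is empty")
    if not 0.5 < threshold <= 1.0:
        raise ConfigError(f"threshold={threshold} must be in (0.5, 1]")
    L = sample.length
    for g in panel:
        if g.length != L:
            raise ConfigError(f"panel genome {g.id} not in the sample's frame")

    sample_codes = sample.codes()
    stack = np.stack([g.codes() for g in panel])  # (P, L)
    base_counts = np.stack([(stack == b).sum(axis=0) for b in range(4)])  # (4, L)
    non_n = base_counts.sum(axis=0)
    majority = base_counts.argmax(axis=0)
    maj_count = base_counts.max(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        agreement = np.where(non_n > 0, maj_count / np.maximum(non_n, 1), 0.0)

    eligible = (
        (non_n > 0)
        & (agreement >= threshold)
        & (sample_codes < 4)
        & (majority != sample_codes)
    )
    sites = [
        DiagnosticSite(
            position=int(i) + 1,
            sample_base="ACGT"[sample_codes[i]],
            contaminant_base="ACGT"[majority[i]],
            panel_agreement=float(agreement[i]),
        )
        for i in np.flatnonzero(eligible)
    ]
    return DiagnosticPanel(sites=sites, panel_size=len(panel), agreement_threshold=threshold)


def count_diagnostic_reads(
    molecules: Sequence[AlignedRead], panel: DiagnosticPanel, frame_length: int
) -> Tuple[int, int, int]:
    """Classify every (molecule, covered diagnostic position) observation.

    A molecule covering k diagnostic positions contributes k observations.
    Returns ``(n_clean, n_contaminant, n_other)``; classification is
    exhaustive and exclusive.
    """
    if not len(panel):
        return (0, 0, 0)
    positions = panel.positions
    sample_bases = [s.sample_base for s in panel.sites]
    contam_bases = [s.contaminant_base for s in panel.sites]
    n_clean = n_contam = n_other = 0
    for mol in molecules:
        # offset of each diagnostic position within the circular span
        off = (positions - mol.ref_start) % frame_length
        covered = np.flatnonzero(off < mol.length)
        for j in covered:
            base = mol.bases[int(off[j])]
            if base == sample_bases[j]:
                n_clean += 1
            elif base == contam_bases[j]:
                n_contam += 1
            else:
                n_other += 1
    return n_clean, n_contam, n_other


def wilson_interval(k: int, n: int, confidence: float = 0.95) -> Tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion k/n.

    With p̂ = k/n and z the two-sided standard-normal quantile for the
    confidence level:

        (p̂ + z²/2n ± z·sqrt(p̂(1−p̂)/n + z²/4n²)) / (1 + z²/n)

    clipped to [0, 1].  The z quantile is computed from ``confidence``, so
    other levels than 95% are available.
    """
    if n < 1:
        raise UndefinedEstimateError("Wilson interval undefined for n = 0")
    if not 0 <= k <= n:
        raise UndefinedEstimateError(f"k={k} outside [0, n={n}]")
    if not 0.0 < confidence < 1.0:
        raise ConfigError(f"confidence={confidence} outside (0, 1)")
    z = norm.ppf((1.0 + confidence) / 2.0)
    p = k / n
    z2n = z * z / n
    center = p + z2n / 2.0
    half = z * np.sqrt(p * (1.0 - p) / n + z2n / (4.0 * n))
    denom = 1.0 + z2n
    low = max(0.0, (center - half) / denom)
    # k == n (and k == 0 for the lower bound) are exact boundary roots of
    # the score test; return them without floating-point dust
    high = 1.0 if k == n else min(1.0, (center + half) / denom)
    if k == 0:
        low = 0.0
    return low, high


def wilson_upper(k: int, n: int, confidence: float = 0.95) -> float:
    """Upper endpoint of the Wilson score interval (conservative bound)."""
    return wilson_interval(k, n, confidence)[1]


@dataclass
class ContaminationEstimate:
    """Observation counts with point estimate and Wilson bounds."""

    n_clean: int
    n_contaminant: int
    n_other: int
    point: float
    wilson_low: float
    wilson_high: float
    confidence: float = 0.95

    @property
    def n_informative(self) -> int:
        return self.n_clean + self.n_contaminant


def estimate_contamination(
    molecules: Sequence[AlignedRead],
    panel: DiagnosticPanel,
    frame_length: int,
    confidence: float = 0.95,
) -> ContaminationEstimate:
    """Count diagnostic observations and bound the contaminating fraction."""
    n_clean, n_contam, n_other = count_diagnostic_reads(molecules, panel, frame_length)
    n = n_clean + n_contam
    if n == 0:
        raise UndefinedEstimateError(
            "no informative observations at diagnostic positions"
        )
    low, high = wilson_interval(n_contam, n, confidence)
    return ContaminationEstimate(
        n_clean=n_clean,
        n_contaminant=n_contam,
        n_other=n_other,
        point=n_contam / n,
        wilson_low=low,
        wilson_high=high,
        confidence=confidence,
    )
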