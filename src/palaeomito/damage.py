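"""Substitution-frequency-by-position damage profiles.

For each aligned molecule, positions within a window of each molecule end
are tabulated as (reference base X, read base Y) observations indexed by
the distance from that end.  The frequency of a substitution X→Y at
distance d is the count of Y observations divided by the number of
reference-X opportunities at that distance.  Minus-strand molecules are
oriented read-wise before tabulation (their 5′ end is the right edge of
the alignment, and both bases are complemented), so the profile reflects
molecule ends rather than reference orientation.

Authentic ancient DNA shows elevated C→T at the 5′ end and G→A at the 3′
end, decaying into the molecule; all other ten substitution types stay at
the background error rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _seq
from .errors import ConfigError, InsufficientDataError, ParseError
from .reads import AlignedRead
from .reference import CircularReference

__all__ = [
    "DamageProfile",
    "damage_profile",
    "terminal_damage_summary",
    "TerminalDamageSummary",
    "write_profile_tsv",
    "read_profile_tsv",
    "plot_profile",
]

#: The 12 substitution types, ordered pairs over {A, C, G, T}.
SUBSTITUTION_TYPES = [
    (x, y) for x in "ACGT" for y in "ACGT" if x != y
]


@dataclass
class DamageProfile:
    """Counts and denominators per (end, substitution, distance) cell.

    ``counts5[x, y, d]`` is the number of (ref base x, read base y)
    observations at distance ``d + 1`` from the 5′ molecule end (codes
    A=0..T=3); ``denom5[x, d]`` the number of reference-x opportunities
    there.  Same from the 3′ end.  Cells with zero denominator have no
    defined frequency and are reported as NaN, not 0.
    """

    window: int
    counts5: np.ndarray  # (4, 4, window)
    denom5: np.ndarray  # (4, window)
    counts3: np.ndarray
    denom3: np.ndarray

    @classmethod
    def empty(cls, window: int) -> "DamageProfile":
        return cls(
            window=window,
            counts5=np.zeros((4, 4, window), dtype=np.int64),
            denom5=np.zeros((4, window), dtype=np.int64),
            counts3=np.zeros((4, 4, window), dtype=np.int64),
            denom3=np.zeros((4, window), dtype=np.int64),
        )

    def frequency(self, end: str, sub: str, distance: int) -> float:
        """Frequency of e.g. ``sub="C>T"`` at 1-based ``distance`` from ``end``
        ("5p" or "3p"); NaN if there were no reference-X opportunities."""
        x, y = sub.split(">")
        xi, yi = "ACGT".index(x), "ACGT".index(y)
        counts, denom = (
            (self.counts5, self.denom5) if end == "5p" else (self.counts3, self.denom3)
        )
        d = denom[xi, distance - 1]
        if d == 0:
            return float("nan")
        return counts[xi, yi, distance - 1] / d

    def merge(self, other: "DamageProfile") -> "DamageProfile":
        """Pool counts with another profile over the same window."""
        if other.window != self.window:
            raise ConfigError("cannot merge profiles with different windows")
        return DamageProfile(
            self.window,
            self.counts5 + other.counts5,
            self.denom5 + other.denom5,
            self.counts3 + other.counts3,
            self.denom3 + other.denom3,
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for end, counts, denom in (("5p", self.counts5, self.denom5), ("3p", self.counts3, self.denom3)):
            for x, y in SUBSTITUTION_TYPES:
                xi, yi = "ACGT".index(x), "ACGT".index(y)
                for d in range(self.window):
                    den = int(denom[xi, d])
                    cnt = int(counts[xi, yi, d])
                    rows.append(
                        {
                            "end": end,
                            "distance": d + 1,
                            "sub_type": f"{x}>{y}",
                            "count": cnt,
                            "denominator": den,
                            "frequency": cnt / den if den else float("nan"),
                        }
                    )
        return pd.DataFrame(rows)


def damage_profile(
    molecules: Sequence[AlignedRead],
    ref: CircularReference,
    window: int = 25,
) -> DamageProfile:
    """Tabulate read-wise substitution frequencies near molecule ends.

    ``ref`` is the sequence the observations are counted against — pass the
    final consensus so true variants do not inflate apparent damage, or the
    initial reference to mimic profiling raw alignments against it.
    """
    if window < 1:
        raise ConfigError(f"window={window} must be >= 1")
    prof = DamageProfile.empty(window)
    ref_codes = ref.codes()
    L = ref.length

    xs5, ys5, ds5 = [], [], []
    xs3, ys3, ds3 = [], [], []
    for mol in molecules:
        m = mol.length
        stored = _seq.encode(mol.bases)  # reference orientation
        pos0 = (mol.ref_start - 1 + np.arange(m)) % L
        refc = ref_codes[pos0]
        if mol.strand == "+":
            read_x, read_y = refc, stored
        else:
            # read-wise orientation: reverse and complement both
            read_x = _seq.revcomp_codes(refc)
            read_y = _seq.revcomp_codes(stored)
        valid = (read_x < 4) & (read_y < 4)
        idx = np.arange(m)
        in5 = (idx < window) & valid
        d3 = m - idx  # 1-based distance from 3' end
        in3 = (d3 <= window) & valid
        xs5.append(read_x[in5]); ys5.append(read_y[in5]); ds5.append(idx[in5])
        xs3.append(read_x[in3]); ys3.append(read_y[in3]); ds3.append(d3[in3] - 1)

    if xs5:
        x5 = np.concatenate(xs5); y5 = np.concatenate(ys5); d5 = np.concatenate(ds5)
        np.add.at(prof.counts5, (x5, y5, d5), 1)
        np.add.at(prof.denom5, (x5, d5), 1)
        x3 = np.concatenate(xs3); y3 = np.concatenate(ys3); d3c = np.concatenate(ds3)
        np.add.at(prof.counts3, (x3, y3, d3c), 1)
        np.add.at(prof.denom3, (x3, d3c), 1)
    # matches (X == Y) are part of the denominator but are not substitutions;
    # counts include them on the diagonal, which to_dataframe never reports
    return prof


@dataclass
class TerminalDamageSummary:
    """Deamination summary at the molecule termini."""

    ct_5p_d1: float
    ga_3p_d1: float
    ct_5p_mean_d1_3: float
    ga_3p_mean_d1_3: float
    adna_consistent: bool
    threshold: float


def terminal_damage_summary(
    profile: DamageProfile, threshold: float = 0.10
) -> TerminalDamageSummary:
    """Terminal C→T / G→A frequencies and an aDNA-consistency flag.

    The flag is true when both the distance-1 5′ C→T and 3′ G→A
    frequencies reach ``threshold``.  Distance 1–3 averages are also
    reported since "terminal" is sometimes read as the first few bases.
    """
    if profile.denom5["ACGT".index("C"), 0] == 0 or profile.denom3["ACGT".index("G"), 0] == 0:
        raise InsufficientDataError("no reference-C/G opportunities at distance 1")
    ct1 = profile.frequency("5p", "C>T", 1)
    ga1 = profile.frequency("3p", "G>A", 1)
    dmax = min(3, profile.window)
    ct_mean = float(np.nanmean([profile.frequency("5p", "C>T", d) for d in range(1, dmax + 1)]))
    ga_mean = float(np.nanmean([profile.frequency("3p", "G>A", d) for d in range(1, dmax + 1)]))
    return TerminalDamageSummary(
        ct_5p_d1=ct1,
        ga_3p_d1=ga1,
        ct_5p_mean_d1_3=ct_mean,
        ga_3p_mean_d1_3=ga_mean,
        adna_consistent=bool(ct1 >= threshold and ga1 >= threshold),
        threshold=threshold,
    )


def write_profile_tsv(profile: DamageProfile, path) -> None:
    profile.to_dataframe().to_csv(path, sep="\t", index=False)


def read_profile_tsv(path) -> DamageProfile:
    df = pd.read_csv(path, sep="\t")
    expected = {"end", "distance", "sub_type", "count", "denominator", "frequency"}
    if set(df.columns) != expected:
        raise ParseError(f"{path}: unexpected profile columns {sorted(df.columns)}")
    window = int(df["distance"].max())
    prof = DamageProfile.empty(window)
    for row in df.to_dict("records"):
        x, y = row["sub_type"].split(">")
        xi, yi = "ACGT".index(x), "ACGT".index(y)
        d = int(row["distance"]) - 1
        if row["end"] == "5p":
            prof.counts5[xi, yi, d] = int(row["count"])
            prof.denom5[xi, d] = int(row["denominator"])
        else:
            prof.counts3[xi, yi, d] = int(row["count"])
            prof.denom3[xi, d] = int(row["denominator"])
    return prof


def plot_profile(profile: DamageProfile, path) -> None:
    """Two-panel plot of the 12 substitution curves from each molecule end."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    dists = np.arange(1, profile.window + 1)
    for ax, end, title in ((axes[0], "5p", "from 5' end"), (axes[1], "3p", "from 3' end")):
        for x, y in SUBSTITUTION_TYPES:
            sub = f"{x}>{y}"
            freqs = [profile.frequency(end, sub, int(d)) for d in dists]
            highlight = (end == "5p" and sub == "C>T") or (end == "3p" and sub == "G>A")
            ax.plot(
                dists if end == "5p" else -dists,
                freqs,
                lw=2 if highlight else 0.8,
                label=sub if highlight else None,
                color="firebrick" if highlight else "grey",
                alpha=1.0 if highlight else 0.6,
            )
        ax.set_xlabel(f"distance {title} (nt)")
        ax.legend(loc="upper right" if end == "5p" else "upper left", frameon=False)
    axes[0].set_ylabel("substitution frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
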