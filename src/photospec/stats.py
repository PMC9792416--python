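"""Replicate statistics: one-way ANOVA, Tukey HSD and the compact letter
display used to annotate per-species comparisons."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "GroupedMeasurements",
    "TukeyComparison",
    "tukey_letters",
    "replicate_mean_se",
]


@dataclass(frozen=True)
class GroupedMeasurements:
    """Replicate values per group (e.g. lambda-max per species)."""

    groups: dict
    metric_name: str = ""
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        for name, values in self.groups.items():
            if len(values) < 2:
                raise ValueError(f"group {name!r} has fewer than 2 replicates")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class TukeyComparison:
    """ANOVA + Tukey HSD summary with compact letter display."""

    group_names: tuple[str, ...]
    means: np.ndarray
    se: np.ndarray
    letters: dict
    pairwise_p: pd.DataFrame
    anova_F: float
    anova_p: float
    alpha: float


def replicate_mean_se(values) -> tuple[float, float]:
    """Mean and standard error (sd / sqrt(n), ddof=1) of replicate values."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 replicates")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


def _insert_absorb_letters(names, nonsig: dict) -> dict:
    """Compact letter display by insert-and-absorb.

    Builds letter columns so that two groups share at least one letter iff
    their pair is non-significant; redundant columns absorbed into supersets.
    """
    columns: list[set] = [set(names)]
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if nonsig[(a, b)]:
                continue
            # significant pair: split every column containing both
            new_columns = []
            for col in columns:
                if a in col and b in col:
                    new_columns.append(col - {a})
                    new_columns.append(col - {b})
                else:
                    new_columns.append(col)
            # absorb columns that are subsets of another
            columns = []
            for col in new_columns:
                if any(col < other for other in new_columns if col is not other):
                    continue
                if col not in columns:
                    columns.append(col)
    letters = {name: "" for name in names}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for k, col in enumerate(columns):
        for name in names:
            if name in col:
                letters[name] += alphabet[k % len(alphabet)]
    return letters


def tukey_letters(data: GroupedMeasurements) -> TukeyComparison:
    """One-way ANOVA, all-pairs Tukey HSD and compact letters.

    Adjusted p-values come from the studentized-range distribution; groups
    share a letter iff their adjusted p >= alpha (a tie at exactly alpha
    counts as not significant, matching the strict ``p < alpha`` criterion).
    """
    names = tuple(sorted(data.groups))
    samples = [np.asarray(data.groups[n], float) for n in names]
    if all(np.ptp(s) == 0 for s in samples):
        raise ValueError("zero within-group variance in every group")
    F, p = sps.f_oneway(*samples)
    values = np.concatenate(samples)
    labels = np.concatenate([[n] * len(s) for n, s in zip(names, samples)])
    hsd = pairwise_tukeyhsd(values, labels, alpha=data.alpha)
    pmat = pd.DataFrame(np.ones((len(names), len(names))),
                        index=names, columns=names)
    nonsig = {}
    for (a, b), padj in zip(
            [(g1, g2) for i, g1 in enumerate(hsd.groupsunique)
             for g2 in hsd.groupsunique[i + 1:]],
            hsd.pvalues):
        pmat.loc[a, b] = pmat.loc[b, a] = padj
        nonsig[(a, b)] = nonsig[(b, a)] = bool(padj >= data.alpha)
    letters = _insert_absorb_letters(names, nonsig)
    means, ses = zip(*(replicate_mean_se(s) for s in samples))
    return TukeyComparison(names, np.asarray(means), np.asarray(ses),
                           letters, pmat, float(F), float(p), data.alpha)
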