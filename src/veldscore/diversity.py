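"""Species diversity indices: richness, Shannon-Wiener, Simpson, evenness.

All indices are plug-in estimators on occurrence counts, with natural
logarithms throughout.  Simpson's index is reported in its dominance form
D = sum(p_i^2): larger values mean stronger dominance by common species, with
D = 1 for a monoculture and D = 1/S for a perfectly even community of S
species.  Evenness is Pielou's E = H' / ln(S).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .survey_io import AbundanceMatrix

__all__ = [
    "DiversityResult",
    "shannon",
    "simpson",
    "evenness",
    "richness",
    "diversity_result",
    "diversity_table",
]


@dataclass(frozen=True)
class DiversityResult:
    richness: int
    shannon_H: float
    simpson_D: float
    evenness_E: float | None  # undefined for a single species


def _proportions(counts: Sequence[float]) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector")
    return counts[counts > 0] / total


def richness(counts: Sequence[float]) -> int:
    """Number of species with positive abundance."""
    counts = np.asarray(counts, dtype=float)
    return int(np.sum(counts > 0))


def shannon(counts: Sequence[float]) -> float:
    """Shannon-Wiener H' = -sum(p_i ln p_i), in nats."""
    p = _proportions(counts)
    return float(-np.sum(p * np.log(p)))


def simpson(counts: Sequence[float]) -> float:
    """Simpson dominance D = sum(p_i^2), in (0, 1]."""
    p = _proportions(counts)
    return float(np.sum(p**2))


def evenness(counts: Sequence[float]) -> float:
    """Pielou evenness E = H' / ln(S); requires at least two species."""
    S = richness(counts)
    if S < 2:
        raise ValueError(f"evenness undefined for richness {S} (ln 1 = 0)")
    return shannon(counts) / float(np.log(S))


def diversity_result(counts: Sequence[float]) -> DiversityResult:
    S = richness(counts)
    return DiversityResult(
        richness=S,
        shannon_H=shannon(counts),
        simpson_D=simpson(counts),
        evenness_E=evenness(counts) if S >= 2 else None,
    )


def diversity_table(
    matrix: AbundanceMatrix, by: str = "site"
) -> pd.DataFrame:
    """Diversity indices per site, or on counts pooled within location.

    ``by='site'`` (default) computes the indices for every transect;
    ``by='location'`` first pools counts across the sites of each location.
    The index of the returned frame says which was done.
    """
    if by == "site":
        rows = {
            site: diversity_result(matrix.counts[i])
            for i, site in enumerate(matrix.site_ids)
        }
    elif by == "location":
        if not matrix.locations:
            raise ValueError("matrix carries no location labels")
        labels = np.array(matrix.location_labels())
        rows = {}
        for loc in pd.unique(labels):
            pooled = matrix.counts[labels == loc].sum(axis=0)
            rows[loc] = diversity_result(pooled)
    else:
        raise ValueError(f"by must be 'site' or 'location', got {by!r}")
    df = pd.DataFrame(
        {
            name: {
                "richness": r.richness,
                "shannon_H": r.shannon_H,
                "simpson_D": r.simpson_D,
                "evenness_E": r.evenness_E,
            }
            for name, r in rows.items()
        }
    ).T
    df.index.name = by
    df["richness"] = df["richness"].astype(int)
    return df
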