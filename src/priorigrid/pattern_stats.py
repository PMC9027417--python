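"""Pairwise Pearson correlations among distribution patterns.

Ten patterns are compared: the five group richness ratios and the five
group components of the complementarity gains, each expressed as a vector
over all grid cells with absent cells zero-filled.  Correlation strength is
labelled on |r| with a seven-class taxonomy: perfect (|r| = 1), very strong
(0.8 <= |r| < 1), strong (0.6 <= |r| < 0.8), moderate (0.4 <= |r| < 0.6),
weak (0.2 <= |r| < 0.4), very weak (0 < |r| < 0.2), none (r = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import GridSpec
from .occurrences import GROUPS
from .prioritization import ComplementaritySolution, RichnessPattern

__all__ = [
    "PatternVector",
    "CorrelationReport",
    "pattern_vector",
    "pearson_r",
    "classify_r",
    "correlogram",
    "UndefinedCorrelationError",
]

# short group tags used in the report column order
_TAG = {
    "ALL": "All",
    "ENDEMIC": "EN",
    "THREATENED": "TH",
    "CITES": "CI",
    "NATIONAL_PROTECTED": "NP",
}
REPORT_ORDER = [f"R_{_TAG[g]}" for g in GROUPS] + [f"C_{_TAG[g]}" for g in GROUPS]


class UndefinedCorrelationError(ValueError):
    """Raised when Pearson r is undefined (a constant vector)."""


@dataclass
class PatternVector:
    """A cell-indexed numeric vector over all grid cells (zeros where absent)."""

    values: np.ndarray
    group: str
    algorithm: str  # "richness" | "complementarity"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("pattern vector has non-finite entries")

    @property
    def label(self) -> str:
        prefix = "R" if self.algorithm == "richness" else "C"
        return f"{prefix}_{_TAG[self.group]}"

    def __len__(self) -> int:
        return len(self.values)


def pattern_vector(
    source: RichnessPattern | ComplementaritySolution,
    group: str,
    grid: GridSpec,
) -> PatternVector:
    """Build a zero-filled per-cell vector for one group from either algorithm.

    Richness sources yield the group ratio r_gc; complementarity sources the
    group's component of the cell gain G_c (nonzero only on selected cells).
    """
    if group not in GROUPS:
        raise KeyError(f"unknown group {group!r}")
    if isinstance(source, RichnessPattern):
        if source.n_cells != grid.n_cells:
            raise ValueError("pattern computed on a different grid")
        return PatternVector(source.ratio_vector(group), group, "richness")
    if isinstance(source, ComplementaritySolution):
        if source.n_cells != grid.n_cells:
            raise ValueError("solution computed on a different grid")
        v = np.zeros(grid.n_cells)
        for cell, comp in source.gain_component(group).items():
            v[cell] = comp
        return PatternVector(v, group, "complementarity")
    raise TypeError(f"unsupported source type {type(source).__name__}")


def _normalize(v: np.ndarray, how: str) -> np.ndarray:
    if how == "none":
        return v
    if how == "zscore":
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else v - v.mean()
    if how == "minmax":
        lo, hi = v.min(), v.max()
        return (v - lo) / (hi - lo) if hi > lo else v - lo
    raise ValueError(f"unknown normalization {how!r}")


def pearson_r(x, y, normalize: str = "none") -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-test p-value.

    Pearson r is invariant under positive affine transforms, so the
    ``normalize`` switch (none|zscore|minmax) cannot change r; it exists to
    mirror a conventional pre-processing step.
    """
    xv = x.values if isinstance(x, PatternVector) else np.asarray(x, dtype=float)
    yv = y.values if isinstance(y, PatternVector) else np.asarray(y, dtype=float)
    if len(xv) != len(yv):
        raise ValueError(f"length mismatch: {len(xv)} vs {len(yv)}")
    if len(xv) < 3:
        raise ValueError("need at least 3 observations")
    if xv.std() == 0 or yv.std() == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    res = stats.pearsonr(_normalize(xv, normalize), _normalize(yv, normalize))
    return float(res.statistic), float(res.pvalue)


def classify_r(r: float, decimals: int | None = 2) -> str:
    """Seven-class correlation-strength label on |r|.

    r is rounded to ``decimals`` first (reported correlations carry two
    decimals, so classification operates on the printed value).
    """
    if not -1.0 - 1e-12 <= r <= 1.0 + 1e-12:
        raise ValueError(f"|r| > 1: {r}")
    a = abs(round(float(r), decimals) if decimals is not None else float(r))
    if a == 0:
        return "no correlation"
    if a < 0.2:
        return "very weak"
    if a < 0.4:
        return "weak"
    if a < 0.6:
        return "moderate"
    if a < 0.8:
        return "strong"
    if a < 1.0:
        return "very strong"
    return "perfect"


@dataclass
class CorrelationReport:
    r: pd.DataFrame  # symmetric, unit diagonal
    p: pd.DataFrame
    classes: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        rows = []
        labels = list(self.r.index)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                rows.append(
                    {
                        "x": a,
                        "y": b,
                        "r": self.r.loc[a, b],
                        "p": self.p.loc[a, b],
                        "class": self.classes.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path, form: str = "wide") -> None:
        if form == "wide":
            self.r.to_csv(path)
        elif form == "long":
            self.to_long().to_csv(path, index=False)
        else:
            raise ValueError(f"unknown form {form!r}")


def correlogram(vectors: list[PatternVector], normalize: str = "none") -> CorrelationReport:
    """Full pairwise correlation matrix with class labels.

    Output rows/columns follow the conventional order R_All..R_NP then
    C_All..C_NP where those labels are present; other labels append after.
    """
    if len(vectors) < 2:
        raise ValueError("need at least 2 vectors")
    n = len(vectors[0])
    if any(len(v) != n for v in vectors):
        raise ValueError("pattern vectors have mismatched lengths")
    labels = [v.label for v in vectors]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate pattern labels: {labels}")
    ordered = [l for l in REPORT_ORDER if l in labels] + [
        l for l in labels if l not in REPORT_ORDER
    ]
    by_label = {v.label: v for v in vectors}
    k = len(ordered)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            rij, pij = pearson_r(by_label[ordered[i]], by_label[ordered[j]], normalize)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    rdf = pd.DataFrame(r, index=ordered, columns=ordered)
    pdf = pd.DataFrame(p, index=ordered, columns=ordered)
    cdf = rdf.map(classify_r)
    return CorrelationReport(rdf, pdf, cdf)
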