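"""Inferential layer: Tukey HSD homogeneous groups, compact letter display,
Pearson dose correlation, and PCA of impact-factor matrices.

The post-hoc procedure follows the classical one-way layout: pairwise
studentized-range p-values from the ANOVA mean-square error (Tukey-Kramer
harmonic correction under unequal replication), then a compact letter display
so that two treatment levels share a letter iff they are not significantly
different at the chosen alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDataError,
    InsufficientReplicationError,
    ValidationError,
)
from .indices import IfMatrix
from .model import ActivityTable, TreatmentKey


# ---------------------------------------------------------------------------
# Tukey HSD + compact letter display


@dataclass
class HomogeneousGrouping:
    """Tukey HSD result with letter codes.

    Two labels share at least one letter iff their Tukey-adjusted p-value is
    >= ``alpha``.  Letters are assigned on labels ordered by descending group
    mean, so 'a' marks the highest-mean group (the common convention).
    """

    labels: list[str]
    means: dict[str, float]
    letters: dict[str, str]
    alpha: float
    pairwise_p: pd.DataFrame
    df_error: float = 0.0
    ms_error: float = 0.0

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "mean": [self.means[l] for l in self.labels],
                "letters": [self.letters[l] for l in self.labels],
            }
        )


def tukey_pairwise_pvalues(
    groups: Mapping[str, Sequence[float]],
) -> tuple[pd.DataFrame, dict[str, float], float, float]:
    """Tukey-Kramer adjusted p-values for all pairs of a one-way layout.

    Returns (p-value matrix, group means, error df, error mean square).
    Each group needs >= 2 replicates.  When the pooled within-group variance
    is exactly zero the comparison degenerates: pairs with equal means get
    p = 1 and pairs with different means p = 0 (every difference is infinitely
    many standard errors wide).
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups for Tukey HSD")
    data = {}
    for label in labels:
        values = np.asarray(groups[label], dtype=float)
        if values.size < 2:
            raise InsufficientReplicationError(
                f"group {label!r} has {values.size} replicate(s); Tukey HSD needs >= 2"
            )
        data[label] = values
    k = len(labels)
    n_total = sum(v.size for v in data.values())
    df_error = n_total - k
    sse = sum(float(np.sum((v - v.mean()) ** 2)) for v in data.values())
    mse = sse / df_error
    means = {l: float(v.mean()) for l, v in data.items()}

    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            li, lj = labels[i], labels[j]
            if mse == 0.0:
                p_ij = 1.0 if means[li] == means[lj] else 0.0
            else:
                # Tukey-Kramer: se^2 = MSE/2 * (1/ni + 1/nj)
                se = np.sqrt(mse / 2.0 * (1.0 / data[li].size + 1.0 / data[lj].size))
                q = abs(means[li] - means[lj]) / se
                p_ij = float(stats.studentized_range.sf(q, k, df_error))
            p[i, j] = p[j, i] = min(1.0, max(0.0, p_ij))
    frame = pd.DataFrame(p, index=labels, columns=labels)
    return frame, means, float(df_error), float(mse)


def _absorb(columns: list[set[int]]) -> list[set[int]]:
    """Drop empty columns, columns strictly contained in another, and duplicates."""
    kept: list[set[int]] = []
    for i, c in enumerate(columns):
        if not c:
            continue
        redundant = any(
            c < d or (c == d and j < i) for j, d in enumerate(columns) if j != i
        )
        if not redundant:
            kept.append(c)
    return kept


def compact_letter_display(
    significant: np.ndarray | pd.DataFrame,
    labels: Sequence[str] | None = None,
    order: Sequence[str] | None = None,
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``significant[i, j]`` is True iff labels i and j differ significantly.
    The result assigns each label a non-empty letter string such that two
    labels share a letter iff they are *not* significantly different.
    Absorbed (subset) letter groups are removed, and letters are issued in
    first-use order a, b, c, ... over ``order`` (default: input order).
    """
    if isinstance(significant, pd.DataFrame):
        if labels is None:
            labels = list(significant.index)
        significant = significant.to_numpy()
    significant = np.asarray(significant, dtype=bool)
    n = significant.shape[0]
    if significant.shape != (n, n):
        raise ValidationError("significance matrix must be square")
    if labels is None:
        labels = [str(i) for i in range(n)]
    labels = list(labels)
    if len(labels) != n:
        raise ValidationError("label count does not match matrix size")
    if np.any(significant != significant.T):
        raise ValidationError("significance matrix must be symmetric")
    if np.any(np.diag(significant)):
        raise ValidationError("diagonal must be False: a group does not differ from itself")

    pos = {l: i for i, l in enumerate(labels)}
    ordered = list(order) if order is not None else labels
    if sorted(ordered) != sorted(labels):
        raise ValidationError("order must be a permutation of labels")

    # columns are sets of matrix indices; start with one all-inclusive column
    columns: list[set[int]] = [set(range(n))]
    for a in range(n):
        for b in range(a + 1, n):
            if not significant[a, b]:
                continue
            for col in [c for c in columns if a in c and b in c]:
                columns.remove(col)
                columns.append(col - {a})
                columns.append(col - {b})
            columns = _absorb(columns)
    # order columns by the first (highest-priority) label they contain
    priority = {pos[l]: rank for rank, l in enumerate(ordered)}
    columns.sort(key=lambda c: min(priority[i] for i in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {l: "" for l in labels}
    for letter_index, col in enumerate(columns):
        letter = (
            alphabet[letter_index]
            if letter_index < len(alphabet)
            else f"({letter_index + 1})"
        )
        for i in sorted(col):
            letters[labels[i]] += letter
    if any(not s for s in letters.values()):
        raise ValidationError("internal error: a label received no letter")
    return letters


def tukey_hsd(
    table: ActivityTable,
    factor: str = "dose",
    alpha: float = 0.01,
    where: Mapping[str, object] | None = None,
) -> HomogeneousGrouping:
    """Tukey HSD homogeneous grouping of an activity table over one factor.

    ``factor`` is one of ``dose``, ``day``, ``biostimulant``; ``where``
    optionally fixes the remaining factors (e.g. ``{"day": 15,
    "biostimulant": False}``) so the comparison is a clean one-way layout.
    """
    if factor not in ("dose", "day", "biostimulant"):
        raise ValidationError(f"unknown factor {factor!r}")
    where = dict(where or {})
    attr = {"dose": "dose", "day": "time_day", "biostimulant": "biostimulant"}
    groups: dict[str, list[float]] = {}
    for key, values in table.records.items():
        if any(getattr(key, attr[f]) != v for f, v in where.items()):
            continue
        level = getattr(key, attr[factor])
        label = f"{level:g}" if isinstance(level, float) else str(level)
        groups.setdefault(label, []).extend(values)
    if len(groups) < 2:
        raise ValidationError(
            f"{table.response_name}: fewer than 2 levels of {factor!r} match {where}"
        )
    pairwise, means, df_error, mse = tukey_pairwise_pvalues(groups)
    ordered = sorted(groups, key=lambda l: -means[l])
    letters = compact_letter_display(
        pairwise.to_numpy() < alpha, labels=list(groups), order=ordered
    )
    return HomogeneousGrouping(
        labels=list(groups),
        means=means,
        letters=letters,
        alpha=alpha,
        pairwise_p=pairwise,
        df_error=df_error,
        ms_error=mse,
    )


# ---------------------------------------------------------------------------
# Pearson dose correlation


def pearson_dose_correlation(
    doses: Sequence[float], response: Sequence[float], alpha: float = 0.05
) -> tuple[float, bool, float]:
    """Pearson r between dose and response with a two-sided t-test flag.

    Returns ``(r, significant, p_value)``.  Requires >= 3 matched pairs and
    nonzero variance in both vectors (else :class:`DegenerateDataError`).
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("doses and response must be matched 1-d vectors")
    if x.size < 3:
        raise ValidationError(f"need >= 3 pairs for a correlation, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), bool(p < alpha), float(p)


# ---------------------------------------------------------------------------
# PCA of IF matrices


@dataclass
class PcaReport:
    """Principal components of an impact-factor matrix.

    Cases are treatment cells, variables are responses.  ``explained_pct``
    covers all components and sums to 100.  Loadings are unit-norm
    eigenvectors with the sign fixed so each component's largest-magnitude
    loading is positive; ``scores @ loadings.T`` reproduces the centered
    (and, if standardized, scaled) data.
    """

    explained_pct: np.ndarray
    loadings: pd.DataFrame  # variables x components
    scores: pd.DataFrame  # cases x components
    standardized: bool
    dropped_cases: list[str] = field(default_factory=list)


def pca_if(matrix: IfMatrix | pd.DataFrame, standardized: bool = True) -> PcaReport:
    """PCA of an IF matrix (or any responses-by-cells frame).

    The frame is transposed so treatment cells are cases and responses are
    variables, then centered (and scaled to unit variance when
    ``standardized``, i.e. correlation-matrix PCA).  Cases containing missing
    cells are dropped and reported in ``dropped_cases``.
    """
    frame = matrix.values if isinstance(matrix, IfMatrix) else matrix
    X = frame.T  # cases x variables
    case_labels = [
        ":".join(f"{v:g}" if isinstance(v, float) else str(v) for v in idx)
        if isinstance(idx, tuple)
        else str(idx)
        for idx in X.index
    ]
    var_labels = list(X.columns)
    values = X.to_numpy(dtype=float)
    keep = ~np.isnan(values).any(axis=1)
    dropped = [c for c, k in zip(case_labels, keep) if not k]
    values = values[keep]
    case_labels = [c for c, k in zip(case_labels, keep) if k]
    n, p = values.shape
    if n < 2 or p < 2:
        raise ValidationError(f"PCA needs >= 2 complete cases and >= 2 variables, got {n}x{p}")
    centered = values - values.mean(axis=0)
    if standardized:
        sd = values.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [v for v, s in zip(var_labels, sd) if s == 0]
            raise DegenerateDataError(f"constant variable(s) under standardization: {bad}")
        centered = centered / sd
    if not np.any(centered):
        raise DegenerateDataError("rank-0 input: all cases identical")

    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic orientation: largest-|loading| entry of each component positive
    for comp in range(s.size):
        pivot = np.argmax(np.abs(vt[comp]))
        if vt[comp, pivot] < 0:
            vt[comp] *= -1.0
            u[:, comp] *= -1.0
    explained = 100.0 * s**2 / float(np.sum(s**2))
    comps = [f"PC{i + 1}" for i in range(s.size)]
    return PcaReport(
        explained_pct=explained,
        loadings=pd.DataFrame(vt.T, index=var_labels, columns=comps),
        scores=pd.DataFrame(u * s, index=case_labels, columns=comps),
        standardized=standardized,
        dropped_cases=dropped,
    )
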