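"""Multi-class linear discriminant analysis with sequential gene removal.

The morph panel asks whether combined expression of a gene set separates
the three male morphs. LDA finds axes maximizing between-morph relative to
within-morph scatter: with pooled within-class covariance S_w and
prior-weighted between-class covariance S_b, the discriminants are the
leading eigenvectors of the symmetric-definite generalized eigenproblem
S_b w = lambda S_w w, and each eigenvalue's share of the eigenvalue sum is
the discriminant's "proportion of trace".

Two step-wise gene-removal procedures probe the robustness of morph
clustering: repeatedly dropping the heaviest-loading genes on LD1 (how
robust is separation to losing its strongest markers?) or the
lightest-loading genes (what minimal gene set still separates the morphs?).
Because cluster separation was traditionally judged from the LDA plot, a
formal criterion is used here: two morphs are "separated" when their LD1
projection intervals (1-D) or LD1/LD2 convex hulls (2-D) are disjoint;
hulls sharing even a boundary point count as overlapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg as _la
from shapely.geometry import MultiPoint

logger = logging.getLogger(__name__)


class LdaError(ValueError):
    pass


@dataclass(frozen=True)
class LdaModel:
    variables: tuple[str, ...]
    classes: tuple[str, ...]
    #: (n_variables, n_discriminants) coefficient matrix, columns LD1, LD2, ...
    coef: np.ndarray
    proportion_of_trace: np.ndarray
    #: (n_samples, n_discriminants) sample projections
    projections: np.ndarray
    labels: tuple[str, ...]
    class_means_proj: dict[str, np.ndarray]
    priors: dict[str, float]
    ridge_used: float = 0.0
    log2_input: bool = False

    @property
    def n_discriminants(self) -> int:
        return self.coef.shape[1]

    def coef_series(self, axis: int = 0) -> pd.Series:
        return pd.Series(self.coef[:, axis], index=list(self.variables))


@dataclass(frozen=True)
class RemovalStep:
    step: int
    removed: tuple[str, ...]
    remaining: tuple[str, ...]
    model: LdaModel
    separation_ld1: dict[tuple[str, str], bool]
    separation_ld12: dict[tuple[str, str], bool]


@dataclass(frozen=True)
class RemovalTrace:
    direction: str
    per_step: int
    floor: int
    steps: tuple[RemovalStep, ...] = field(default_factory=tuple)


def _scatter_matrices(
    X: np.ndarray, labels: np.ndarray, classes: Sequence[str], priors: dict[str, float]
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    n, p = X.shape
    k = len(classes)
    sw = np.zeros((p, p))
    means = {}
    for c in classes:
        xc = X[labels == c]
        mu = xc.mean(axis=0)
        means[c] = mu
        dev = xc - mu
        sw += dev.T @ dev
    sw /= n - k
    grand = np.sum([priors[c] * means[c] for c in classes], axis=0)
    sb = np.zeros((p, p))
    for c in classes:
        d = (means[c] - grand)[:, None]
        sb += priors[c] * (d @ d.T)
    return sw, sb, means


def fit_lda(
    X: pd.DataFrame,
    labels: Sequence[str],
    priors: str = "proportional",
    log2_input: bool = False,
    ridge: float = 0.0,
) -> LdaModel:
    """Fit a multi-class LDA on a samples x variables expression table.

    ``priors`` weight the between-class scatter: ``"proportional"`` to class
    sizes (the conventional default) or ``"equal"``. ``log2_input``
    transforms expression values before fitting. A singular within-class
    scatter triggers an automatic ridge fallback (logged).
    """
    if X.isna().any().any():
        raise LdaError("missing values present; apply listwise deletion first")
    y = np.asarray(list(labels))
    if len(y) != len(X):
        raise LdaError("labels length must match number of samples")
    classes = tuple(sorted(pd.unique(y)))
    if len(classes) < 2:
        raise LdaError("need >= 2 classes")
    if len(X) <= len(classes):
        raise LdaError("need more samples than classes")
    vals = X.to_numpy(dtype=float)
    if log2_input:
        if np.any(vals <= 0):
            raise LdaError("log2 transform requires strictly positive values")
        vals = np.log2(vals)
    n, p = vals.shape
    if priors == "proportional":
        pri = {c: float((y == c).sum()) / n for c in classes}
    elif priors == "equal":
        pri = {c: 1.0 / len(classes) for c in classes}
    else:
        raise LdaError("priors must be 'proportional' or 'equal'")
    sw, sb, means = _scatter_matrices(vals, y, classes, pri)
    ridge_used = ridge
    if ridge_used > 0:
        sw = sw + ridge_used * np.eye(p)
    sw_eigs = np.linalg.eigvalsh(sw)
    if sw_eigs[0] <= 1e-10 * max(sw_eigs[-1], 1e-300):
        ridge_used = max(ridge_used, 1e-8 * max(np.trace(sw) / p, 1.0))
        logger.warning(
            "within-class scatter (near-)singular; adding ridge %.3e", ridge_used
        )
        sw = sw + ridge_used * np.eye(p)
    for attempt in range(2):
        try:
            eigvals, eigvecs = _la.eigh(sb, sw)
            break
        except _la.LinAlgError:
            if attempt == 1:
                raise LdaError("within-class scatter singular even after ridge")
            ridge_used = 1e-8 * max(np.trace(sw) / p, 1.0)
            logger.warning(
                "singular within-class scatter; adding ridge %.3e", ridge_used
            )
            sw = sw + ridge_used * np.eye(p)
    order = np.argsort(eigvals)[::-1]
    r = min(len(classes) - 1, p)
    eigvals = np.clip(eigvals[order][:r], 0.0, None)
    W = eigvecs[:, order][:, :r]
    # scale each discriminant to unit pooled within-class variance, then fix
    # the sign so the largest-magnitude coefficient is positive
    for j in range(r):
        w = W[:, j]
        scale = float(w @ sw @ w)
        if scale > 0:
            W[:, j] = w / np.sqrt(scale)
        if W[np.argmax(np.abs(W[:, j])), j] < 0:
            W[:, j] = -W[:, j]
    total = eigvals.sum()
    if total > 0:
        proportions = eigvals / total
    else:
        proportions = np.zeros_like(eigvals)
        logger.warning("no between-class variation: proportions of trace all zero")
    grand = np.sum([pri[c] * means[c] for c in classes], axis=0)
    proj = (vals - grand) @ W
    class_means_proj = {c: proj[y == c].mean(axis=0) for c in classes}
    return LdaModel(
        variables=tuple(X.columns),
        classes=classes,
        coef=W,
        proportion_of_trace=proportions,
        projections=proj,
        labels=tuple(y),
        class_means_proj=class_means_proj,
        priors=pri,
        ridge_used=ridge_used,
        log2_input=log2_input,
    )


def separation(model: LdaModel, axis_set: str = "LD1") -> dict[tuple[str, str], bool]:
    """Disjointness of class projections, per class pair.

    ``axis_set="LD1"`` tests 1-D interval disjointness on the first
    discriminant; ``"LD1+LD2"`` tests disjointness of 2-D convex hulls
    (falling back to LD1 when only one discriminant exists). Touching
    hulls/intervals are not separated (closed-set convention).
    """
    if axis_set not in ("LD1", "LD1+LD2"):
        raise LdaError("axis_set must be 'LD1' or 'LD1+LD2'")
    y = np.asarray(model.labels)
    out: dict[tuple[str, str], bool] = {}
    use_2d = axis_set == "LD1+LD2" and model.n_discriminants >= 2
    for a, b in combinations(model.classes, 2):
        pa = model.projections[y == a]
        pb = model.projections[y == b]
        if use_2d:
            hull_a = MultiPoint(pa[:, :2]).convex_hull
            hull_b = MultiPoint(pb[:, :2]).convex_hull
            out[(a, b)] = not hull_a.intersects(hull_b)
        else:
            xa, xb = pa[:, 0], pb[:, 0]
            out[(a, b)] = bool(xa.max() < xb.min() or xb.max() < xa.min())
    return out


def _select_removals(coefs: pd.Series, direction: str, budget: int) -> list[str]:
    """Pick up to ``budget`` variables to drop, by LD1 loading.

    ``heaviest`` removes the most positive and most negative loadings,
    ``lightest`` the smallest-magnitude positive and smallest-magnitude
    negative loadings; when one sign is absent the pick falls back to the
    extreme (resp. smallest) magnitudes overall. Ties break by variable
    name.
    """
    s = coefs.copy()
    # deterministic tie-break: stable sort on (value, name)
    ordered = s.reindex(sorted(s.index)).sort_values(kind="mergesort")
    names_asc = list(ordered.index)  # most negative ... most positive
    if direction == "heaviest":
        pos_priority = names_asc[::-1]  # most positive first
        neg_priority = names_asc  # most negative first
    elif direction == "lightest":
        by_abs = ordered.abs().sort_values(kind="mergesort")
        pos_priority = [v for v in by_abs.index if ordered[v] > 0] or list(by_abs.index)
        neg_priority = [v for v in by_abs.index if ordered[v] < 0] or list(by_abs.index)
    else:
        raise LdaError("direction must be 'heaviest' or 'lightest'")
    picks: list[str] = []
    queues = [pos_priority, neg_priority]
    qi = 0
    while len(picks) < budget and any(queues):
        queue = queues[qi % 2]
        qi += 1
        while queue and queue[0] in picks:
            queue.pop(0)
        if queue:
            picks.append(queue.pop(0))
    return picks


def sequential_removal(
    X: pd.DataFrame,
    labels: Sequence[str],
    direction: str = "heaviest",
    per_step: int = 2,
    floor: int = 3,
    **lda_kwargs,
) -> RemovalTrace:
    """Iteratively refit LDA while removing genes by LD1 loading.

    Each step removes up to ``per_step`` variables (one from the positive
    and one from the negative loadings when ``per_step`` = 2), refits, and
    records separation flags; removal stops at ``floor`` remaining
    variables, taking a partial last step if needed.
    """
    if per_step < 1:
        raise LdaError("per_step must be >= 1")
    if len(X.columns) < 3:
        raise LdaError("need >= 3 variables to start removal")
    if floor < 2:
        raise LdaError("floor must be >= 2")
    remaining = list(X.columns)
    steps: list[RemovalStep] = []

    def record(step_idx: int, removed: tuple[str, ...]) -> LdaModel:
        model = fit_lda(X[remaining], labels, **lda_kwargs)
        steps.append(
            RemovalStep(
                step=step_idx,
                removed=removed,
                remaining=tuple(remaining),
                model=model,
                separation_ld1=separation(model, "LD1"),
                separation_ld12=separation(model, "LD1+LD2"),
            )
        )
        return model

    model = record(0, ())
    step_idx = 0
    while len(remaining) > floor:
        budget = min(per_step, len(remaining) - floor)
        picks = _select_removals(model.coef_series(0), direction, budget)
        if not picks:
            break
        remaining = [v for v in remaining if v not in picks]
        step_idx += 1
        model = record(step_idx, tuple(picks))
    return RemovalTrace(
        direction=direction, per_step=per_step, floor=floor, steps=tuple(steps)
    )
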