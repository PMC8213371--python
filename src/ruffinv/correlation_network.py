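"""Morph-stratified co-expression: pairwise correlations, FDR screen, Venn sets.

Within each morph, every unordered pair of panel variables (genes plus the
testosterone and GSI covariates) gets a Pearson correlation with its
two-sided p-value from the t transform (df = n - 2). The p-value family --
all v*(v-1)/2 pairs x morphs, 360 for a 16-variable panel over three
morphs -- is screened with Benjamini-Hochberg FDR at q = 0.10. Because
modest samples can leave biologically strong correlations short of
significance, pairs with |r| >= 0.8 are additionally listed per morph
regardless of p, and compared across morphs as Venn-style set
intersections.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _st

from .stats_core import bh_adjust

REPORT_COLUMNS = ["morph", "var_a", "var_b", "r", "n", "p_raw", "p_fdr", "strong"]


class CorrelationError(ValueError):
    pass


@dataclass(frozen=True)
class VennSets:
    """Per-morph strong-pair sets and their intersections."""

    per_morph: dict[str, frozenset[tuple[str, str]]]
    signs: dict[tuple[str, tuple[str, str]], int]
    threshold: float

    def intersection(self, *morphs: str) -> frozenset[tuple[str, str]]:
        sets = [self.per_morph[m] for m in morphs]
        out = sets[0]
        for s in sets[1:]:
            out = out & s
        return out

    def exclusive(self, *morphs: str) -> frozenset[tuple[str, str]]:
        """Pairs strong in exactly the given morphs and no others."""
        inside = self.intersection(*morphs)
        for other, s in self.per_morph.items():
            if other not in morphs:
                inside = inside - s
        return inside


def corr_matrix(
    X: pd.DataFrame,
    morph_col: str = "morph",
    variables: list[str] | None = None,
    min_n: int = 3,
) -> pd.DataFrame:
    """Long-format pairwise Pearson correlations, computed per morph.

    ``X`` holds one row per sample with a morph label column and numeric
    variable columns (expression plus covariates). Complete cases are used
    within each morph, so every pair of a morph shares the same n. Pairs
    involving a constant variable are reported with missing r/p.
    """
    if morph_col not in X.columns:
        raise CorrelationError(f"missing morph column {morph_col!r}")
    if variables is None:
        variables = [c for c in X.columns if c != morph_col and
                     pd.api.types.is_numeric_dtype(X[c])]
    if len(variables) < 2:
        raise CorrelationError("need >= 2 variables")
    rows = []
    for morph, grp in X.groupby(morph_col, sort=True):
        complete = grp[variables].dropna()
        n = len(complete)
        if n < min_n:
            raise CorrelationError(
                f"morph {morph!r} has {n} complete samples (< {min_n})"
            )
        arr = complete.to_numpy(dtype=float)
        sds = arr.std(axis=0)
        for ia, ib in combinations(range(len(variables)), 2):
            if sds[ia] == 0 or sds[ib] == 0:
                r, p = np.nan, np.nan
            else:
                r, p = _st.pearsonr(arr[:, ia], arr[:, ib])
            rows.append(
                {
                    "morph": morph,
                    "var_a": variables[ia],
                    "var_b": variables[ib],
                    "r": float(r),
                    "n": n,
                    "p_raw": float(p),
                }
            )
    return pd.DataFrame(rows, columns=["morph", "var_a", "var_b", "r", "n", "p_raw"])


def fdr_screen(
    reports: pd.DataFrame, q: float = 0.10, family: str = "pooled"
) -> pd.DataFrame:
    """Attach BH-adjusted p-values and a significance flag at level ``q``.

    ``family="pooled"`` adjusts all reports as one family (the default);
    ``"per_morph"`` adjusts within each morph separately.
    """
    if family not in ("pooled", "per_morph"):
        raise CorrelationError("family must be 'pooled' or 'per_morph'")
    out = reports.copy()
    out["p_fdr"] = np.nan
    if family == "pooled":
        groups = [out.index]
    else:
        groups = [idx for _, idx in out.groupby("morph").groups.items()]
    for idx in groups:
        mask = out.loc[idx, "p_raw"].notna()
        sel = out.loc[idx][mask]
        if len(sel):
            out.loc[sel.index, "p_fdr"] = bh_adjust(sel["p_raw"].to_numpy())
    out["significant"] = out["p_fdr"] <= q
    return out


def strong_pairs_venn(reports: pd.DataFrame, threshold: float = 0.8) -> VennSets:
    """Per-morph sets of strongly correlated pairs (|r| >= threshold), with signs."""
    per_morph: dict[str, frozenset[tuple[str, str]]] = {}
    signs: dict[tuple[str, tuple[str, str]], int] = {}
    for morph, grp in reports.groupby("morph", sort=True):
        pairs = set()
        for _, row in grp.iterrows():
            if np.isfinite(row["r"]) and abs(row["r"]) >= threshold:
                pair = tuple(sorted((row["var_a"], row["var_b"])))
                pairs.add(pair)
                signs[(morph, pair)] = 1 if row["r"] > 0 else -1
        per_morph[morph] = frozenset(pairs)
    return VennSets(per_morph=per_morph, signs=signs, threshold=threshold)


def venn_report(venn: VennSets) -> dict:
    """JSON-serializable summary: per-morph sets plus all 2- and 3-way intersections."""
    morphs = sorted(venn.per_morph)
    report: dict = {
        "threshold": venn.threshold,
        "per_morph": {
            m: sorted(["|".join(p) for p in venn.per_morph[m]]) for m in morphs
        },
        "intersections": {},
        "exclusive_regions": {},
    }
    for k in (2, 3):
        for combo in combinations(morphs, k):
            key = "&".join(combo)
            report["intersections"][key] = sorted(
                "|".join(p) for p in venn.intersection(*combo)
            )
            report["exclusive_regions"][key] = sorted(
                "|".join(p) for p in venn.exclusive(*combo)
            )
    return report
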