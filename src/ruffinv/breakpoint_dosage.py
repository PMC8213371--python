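"""Dosage analysis of a gene truncated by an inversion breakpoint.

A gene spanning the proximal breakpoint is intact on the ancestral allele
but truncated on the inverted allele. Two amplicons probe it: one entirely
*outside* the inverted region (templated by both alleles) and one *across*
the breakpoint (templated by the ancestral allele only). The per-sample
ratio RA_across / RA_outside therefore measures the ancestral-allele share
of transcription: ~1 in ancestral homozygotes, ~0.5 in inversion
heterozygotes with balanced allelic expression. Groups are tested against
the all-ancestral expectation of 1 with a one-sample t-test, and overall
non-truncated transcript abundance (the across amplicon) is compared
between groups with the exact Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .stats_core import TestResult, mann_whitney_exact, one_sample_t


@dataclass(frozen=True)
class DosageResult:
    sample_id: str
    tissue: str
    gene: str
    ratio: float
    morph: str | None = None
    #: 1.0 for ancestral homozygotes, 0.5 for inversion heterozygotes
    genotype_expectation: float | None = None
    undefined: bool = False


def dosage_ratio(
    ra: pd.DataFrame, sample_id: str, tissue: str, gene: str
) -> DosageResult:
    """Across/outside breakpoint expression ratio for one sample and tissue."""
    sel = ra[
        (ra["sample_id"] == sample_id)
        & (ra["tissue"] == tissue)
        & (ra["gene"] == gene)
    ]
    across = sel.loc[sel["amplicon_class"] == "across_breakpoint", "ra"]
    outside = sel.loc[sel["amplicon_class"] == "outside_breakpoint", "ra"]
    morph = sel["morph"].iloc[0] if len(sel) else None
    expectation = None
    if morph is not None:
        expectation = 1.0 if morph == "Independent" else 0.5
    if len(across) == 0 or len(outside) == 0:
        return DosageResult(sample_id, tissue, gene, np.nan, morph, expectation, True)
    a, o = float(across.iloc[0]), float(outside.iloc[0])
    if not np.isfinite(a) or not np.isfinite(o) or o == 0.0:
        return DosageResult(sample_id, tissue, gene, np.nan, morph, expectation, True)
    return DosageResult(sample_id, tissue, gene, a / o, morph, expectation, False)


def dosage_table(ra: pd.DataFrame, gene: str) -> pd.DataFrame:
    """All per-sample across/outside ratios for ``gene``, one row per sample x tissue."""
    sub = ra[ra["gene"] == gene]
    rows = []
    for (sample_id, tissue), _ in sub.groupby(["sample_id", "tissue"], sort=False):
        res = dosage_ratio(ra, sample_id, tissue, gene)
        rows.append(
            {
                "sample_id": res.sample_id,
                "morph": res.morph,
                "tissue": res.tissue,
                "gene": res.gene,
                "ratio": res.ratio,
                "genotype_expectation": res.genotype_expectation,
                "undefined": res.undefined,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "morph", "tissue", "gene",
            "ratio", "genotype_expectation", "undefined",
        ],
    )


def test_dosage_group(ratios: Sequence[float]) -> TestResult:
    """One-sample t of per-bird dosage ratios against the all-ancestral mean of 1.

    Ratios exactly at the null value carry no evidence against it, so a
    group of all-1 ratios reports t = 0, p = 1 instead of the zero-variance
    degenerate error.
    """
    arr = np.asarray(ratios, dtype=float)
    if arr.size >= 2 and np.ptp(arr) == 0 and np.all(arr == 1.0):
        return TestResult(statistic=0.0, df=float(arr.size - 1), p_two_sided=1.0,
                          method="one-sample t")
    return one_sample_t(arr, 1.0)


def compare_nontruncated(
    ra_across_group_a: Sequence[float], ra_across_group_b: Sequence[float]
) -> TestResult:
    """Mann-Whitney comparison of non-truncated transcript abundance between groups."""
    return mann_whitney_exact(ra_across_group_a, ra_across_group_b)
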