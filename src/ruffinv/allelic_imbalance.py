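"""Allelic imbalance of inversion genes in heterozygous individuals.

For genes with morph-specific variants, allele-specific primer pairs
quantify the ancestral-allele and inversion-allele transcripts separately.
Because both assays are efficiency-corrected before combination, the
inversion-allele share

    inv_percent = 100 * RA_inv / (RA_inv + RA_anc)

is not confounded by primer-efficiency differences. Departure from the
balanced 50% expectation is tested per gene x tissue cell with a one-sample
t-test over heterozygous individuals, with a Bonferroni-Dunn family-wise
correction over the gene x tissue grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qpcr_quant import INVERSION_MORPHS
from .stats_core import DegenerateInputError, bonferroni_dunn, one_sample_t


@dataclass(frozen=True)
class AIResult:
    sample_id: str
    tissue: str
    gene: str
    inv_percent: float
    anc_percent: float


def ai_percent(ra_inversion: float, ra_ancestral: float) -> float:
    """Percent of total expression contributed by the inversion allele."""
    if ra_inversion < 0 or ra_ancestral < 0:
        raise ValueError("relative abundances must be nonnegative")
    total = ra_inversion + ra_ancestral
    if total == 0 or not np.isfinite(total):
        return float("nan")
    return 100.0 * ra_inversion / total


def ai_table(ra: pd.DataFrame, genes: list[str] | None = None) -> pd.DataFrame:
    """Per heterozygote x tissue x gene inversion-allele percentages.

    Only inversion-morph (heterozygous) individuals are informative; rows
    lacking either allele-specific measurement become missing-data rows.
    """
    sub = ra[ra["morph"].isin(INVERSION_MORPHS)]
    if genes is not None:
        sub = sub[sub["gene"].isin(genes)]
    sub = sub[sub["amplicon_class"].isin(["ancestral_specific", "inversion_specific"])]
    rows = []
    for (sample_id, morph, tissue, gene), grp in sub.groupby(
        ["sample_id", "morph", "tissue", "gene"], sort=False
    ):
        anc = grp.loc[grp["amplicon_class"] == "ancestral_specific", "ra"]
        inv = grp.loc[grp["amplicon_class"] == "inversion_specific", "ra"]
        if len(anc) and len(inv) and np.isfinite(anc.iloc[0]) and np.isfinite(inv.iloc[0]):
            pct = ai_percent(float(inv.iloc[0]), float(anc.iloc[0]))
        else:
            pct = np.nan
        rows.append(
            {
                "sample_id": sample_id,
                "morph": morph,
                "tissue": tissue,
                "gene": gene,
                "inv_percent": pct,
                "anc_percent": 100.0 - pct if np.isfinite(pct) else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "morph", "tissue", "gene", "inv_percent", "anc_percent"],
    )


def ai_grid_test(
    ai: pd.DataFrame,
    m_mode: str = "testable",
    pool_morphs: bool = True,
) -> pd.DataFrame:
    """Test every gene x tissue cell for departure from 50% inversion share.

    ``m_mode`` sets the Bonferroni-Dunn multiplicity count: ``"testable"``
    uses the number of cells with >= 2 heterozygotes (the default),
    ``"grid"`` fixes m at #genes x #tissues regardless of missingness.
    ``pool_morphs=False`` tests Satellites and Faeders separately (and the
    family then spans gene x tissue x morph cells).
    """
    if m_mode not in ("testable", "grid"):
        raise ValueError("m_mode must be 'testable' or 'grid'")
    df = ai.dropna(subset=["inv_percent"]).copy()
    if pool_morphs:
        df["stratum"] = "pooled"
    else:
        df["stratum"] = df["morph"]
    cells = []
    for (gene, tissue, stratum), grp in df.groupby(["gene", "tissue", "stratum"], sort=True):
        values = grp["inv_percent"].to_numpy()
        cells.append((gene, tissue, stratum, values))
    def _is_testable(values: np.ndarray) -> bool:
        # a cell of identical values has no t statistic, except the exact
        # null case (everything at 50%), which is reported as p = 1
        return len(values) >= 2 and (np.ptp(values) > 0 or np.all(values == 50.0))

    testable = [c for c in cells if _is_testable(c[3])]
    if m_mode == "grid":
        n_strata = df["stratum"].nunique() if not pool_morphs else 1
        m = ai["gene"].nunique() * ai["tissue"].nunique() * max(1, n_strata)
    else:
        m = max(1, len(testable))
    rows = []
    for gene, tissue, stratum, values in cells:
        row = {
            "gene": gene,
            "tissue": tissue,
            "stratum": stratum,
            "n": len(values),
            "mean_inv_percent": float(np.mean(values)) if len(values) else np.nan,
            "m": m,
        }
        if len(values) >= 2 and np.ptp(values) == 0 and np.all(values == 50.0):
            row.update(statistic=0.0, df=float(len(values) - 1), p_raw=1.0,
                       p_adjusted=1.0, testable=True)
        else:
            try:
                res = one_sample_t(values, 50.0)
                row.update(
                    statistic=res.statistic,
                    df=res.df,
                    p_raw=res.p_two_sided,
                    p_adjusted=bonferroni_dunn(res.p_two_sided, m),
                    testable=True,
                )
            except DegenerateInputError:
                row.update(statistic=np.nan, df=np.nan, p_raw=np.nan,
                           p_adjusted=np.nan, testable=False)
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "tissue", "stratum", "n", "mean_inv_percent",
            "statistic", "df", "p_raw", "p_adjusted", "m", "testable",
        ],
    )
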