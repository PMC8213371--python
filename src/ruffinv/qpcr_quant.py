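"""Raw Cq measurements -> efficiency-corrected relative expression.

Quantification model
--------------------
A qPCR reaction with per-cycle amplification efficiency E crossing threshold
at cycle Cq started from a template quantity proportional to ``E**(-Cq)``.
Expression of a target is therefore reported as relative abundance

    RA = E_t**(-Cq_t) / geometric_mean_r( E_r**(-Cq_r) )

over the two reference genes r of the experiment. With all efficiencies
equal to 2 this reduces to the familiar ``2**-ddCt`` scheme; keeping the
per-assay efficiencies corrects allele-specific primer pairs whose measured
efficiencies differ from perfect doubling.

Efficiencies are estimated from standard curves (Cq regressed on log10
relative input over a serial dilution): ``E = 10**(-1/slope)``. Assays with
E below 1.9 fail QC for allele-specific use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MORPHS = ("Independent", "Satellite", "Faeder")
#: morphs heterozygous for the inversion (homozygotes are not viable)
INVERSION_MORPHS = ("Satellite", "Faeder")
TISSUES = ("gonad", "liver", "adrenal")
AMPLICON_CLASSES = (
    "common",
    "ancestral_specific",
    "inversion_specific",
    "across_breakpoint",
    "outside_breakpoint",
    "reference",
)
#: reactions are run for 40 cycles; a Cq at the cap is a non-detection
MAX_CYCLES = 40.0
#: default replicate Cq spread (cycles) above which a QC flag is raised
REPLICATE_SPREAD_THRESHOLD = 0.5
#: acceptance threshold for allele-specific assay efficiency
EFFICIENCY_QC_MIN = 1.9

CQ_COLUMNS = ["sample_id", "morph", "tissue", "gene", "amplicon_class", "replicate", "cq"]


class QuantError(ValueError):
    pass


@dataclass(frozen=True)
class AmpliconSpec:
    """Primer-pair metadata: what the amplicon templates and how it amplifies."""

    gene: str
    amplicon_class: str
    efficiency: float
    efficiency_source: str = "standard_curve"  # or "assumed_two"
    qc_pass: bool = True

    def __post_init__(self) -> None:
        if self.amplicon_class not in AMPLICON_CLASSES:
            raise QuantError(f"unknown amplicon class {self.amplicon_class!r}")
        if not (1.0 < self.efficiency <= 2.2):
            raise QuantError(
                f"{self.gene}/{self.amplicon_class}: efficiency {self.efficiency} outside (1, 2.2]"
            )
        if self.efficiency_source == "assumed_two" and self.efficiency != 2.0:
            raise QuantError("efficiency_source 'assumed_two' requires E = 2.0")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene, self.amplicon_class)


@dataclass(frozen=True)
class EfficiencyFit:
    """Standard-curve fit: slope of Cq vs log10 input, derived efficiency, r^2."""

    efficiency: float
    slope: float
    intercept: float
    r_squared: float
    qc_pass: bool


def collapse_replicates(
    records: pd.DataFrame,
    spread_threshold: float = REPLICATE_SPREAD_THRESHOLD,
    max_cycles: float = MAX_CYCLES,
) -> pd.DataFrame:
    """Average technical replicates to one mean Cq per (sample, tissue, gene, amplicon).

    Cq values at or above ``max_cycles`` are non-detections and are dropped
    before averaging; keys where every replicate failed to amplify are kept
    as missing-data rows (``mean_cq`` NaN) rather than silently removed.
    A ``spread_flag`` marks keys whose replicate range exceeds
    ``spread_threshold`` cycles.
    """
    df = records.copy()
    missing = [c for c in CQ_COLUMNS if c not in df.columns and c != "replicate"]
    if missing:
        raise QuantError(f"records missing columns: {missing}")
    df.loc[df["cq"] >= max_cycles, "cq"] = np.nan
    keys = ["sample_id", "morph", "tissue", "gene", "amplicon_class"]
    grouped = df.groupby(keys, sort=False, dropna=False)["cq"]
    out = grouped.agg(
        mean_cq="mean",
        n_replicates="count",
        spread=lambda s: float(np.ptp(s.dropna())) if s.notna().any() else np.nan,
    ).reset_index()
    out["spread_flag"] = out["spread"].fillna(0.0) > spread_threshold
    return out


def estimate_efficiency(
    dilution_factors: Sequence[float], cqs: Sequence[float]
) -> EfficiencyFit:
    """Estimate amplification efficiency from a serial-dilution standard curve.

    ``dilution_factors`` are fold dilutions (5 means 1:5), so relative input
    is ``1/factor``. Least squares of Cq on log10(relative input) gives the
    slope; ``E = 10**(-1/slope)``.
    """
    d = np.asarray(dilution_factors, dtype=float)
    c = np.asarray(cqs, dtype=float)
    if d.size != c.size:
        raise QuantError("dilution_factors and cqs must have equal length")
    if d.size < 3:
        raise QuantError("need >= 3 dilution points for a standard curve")
    if np.any(d <= 0):
        raise QuantError("dilution factors must be positive")
    x = np.log10(1.0 / d)
    if np.ptp(x) == 0.0:
        raise QuantError("dilution factors must be distinct")
    slope, intercept = np.polyfit(x, c, 1)
    resid = c - (slope * x + intercept)
    ss_tot = float(((c - c.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    if slope >= 0:
        raise QuantError("standard curve slope must be negative (Cq rises with dilution)")
    eff = 10.0 ** (-1.0 / slope)
    return EfficiencyFit(
        efficiency=float(eff),
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        qc_pass=bool(eff >= EFFICIENCY_QC_MIN),
    )


def relative_abundance(
    cq_target: float,
    spec_target: AmpliconSpec,
    ref_cqs: Iterable[tuple[float, AmpliconSpec]],
) -> float:
    """Efficiency-corrected expression relative to the reference-gene geometric mean."""
    refs = list(ref_cqs)
    if not refs:
        raise QuantError("at least one reference measurement is required")
    if not np.isfinite(cq_target):
        return float("nan")
    # work on the log scale: log RA = -Cq_t ln E_t + mean_r(Cq_r ln E_r)
    log_target = -cq_target * math.log(spec_target.efficiency)
    log_refs = [-cq * math.log(spec.efficiency) for cq, spec in refs]
    if any(not np.isfinite(v) for v in log_refs):
        return float("nan")
    return math.exp(log_target - sum(log_refs) / len(log_refs))


def relative_abundance_table(
    collapsed: pd.DataFrame,
    specs: Mapping[tuple[str, str], AmpliconSpec],
    reference_genes: Sequence[str],
) -> pd.DataFrame:
    """Build the RelAbundanceTable from collapsed Cq means.

    Every target amplicon of a (sample, tissue) is normalized by the
    geometric mean of the efficiency-corrected quantities of that sample's
    two reference genes. Rows whose references are missing are reported
    with NaN RA rather than dropped.
    """
    if len(reference_genes) == 0:
        raise QuantError("reference_genes must be nonempty")
    df = collapsed.copy()
    is_ref = df["gene"].isin(reference_genes)
    rows = []
    for (sample, tissue), sub in df.groupby(["sample_id", "tissue"], sort=False):
        refs = []
        for _, r in sub[is_ref.loc[sub.index]].iterrows():
            spec = specs.get((r["gene"], "reference")) or specs.get(
                (r["gene"], r["amplicon_class"])
            )
            if spec is None:
                raise QuantError(f"no AmpliconSpec for reference gene {r['gene']!r}")
            refs.append((r["mean_cq"], spec))
        ref_ok = len(refs) == len(reference_genes) and all(
            np.isfinite(cq) for cq, _ in refs
        )
        for _, r in sub[~is_ref.loc[sub.index]].iterrows():
            spec = specs.get((r["gene"], r["amplicon_class"]))
            if spec is None:
                raise QuantError(
                    f"no AmpliconSpec for {(r['gene'], r['amplicon_class'])!r}"
                )
            ra = (
                relative_abundance(r["mean_cq"], spec, refs) if ref_ok else float("nan")
            )
            rows.append(
                {
                    "sample_id": sample,
                    "morph": r["morph"],
                    "tissue": tissue,
                    "gene": r["gene"],
                    "amplicon_class": r["amplicon_class"],
                    "ra": ra,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "morph", "tissue", "gene", "amplicon_class", "ra"])


def log2_morph_foldchange(
    ra: pd.DataFrame,
    amplicon_class: str = "common",
    invert: bool = False,
) -> pd.DataFrame:
    """Per-individual log2 fold change of inversion-morph expression vs Independents.

    For each (gene, tissue) the Independent mean RA is the baseline; each
    Satellite/Faeder individual gets ``log2(RA_individual / baseline)``
    (0 = equal to the Independent mean, negative = reduced). ``invert=True``
    reports the reciprocal convention ``log2(baseline / RA_individual)``.
    Cells whose Independent baseline is zero or missing are flagged
    undefined.
    """
    sub = ra[ra["amplicon_class"] == amplicon_class]
    rows = []
    for (gene, tissue), grp in sub.groupby(["gene", "tissue"], sort=False):
        ind = grp.loc[grp["morph"] == "Independent", "ra"].dropna()
        baseline = ind.mean() if len(ind) else np.nan
        undefined = not np.isfinite(baseline) or baseline <= 0
        for _, r in grp[grp["morph"].isin(INVERSION_MORPHS)].iterrows():
            if undefined or not np.isfinite(r["ra"]) or r["ra"] <= 0:
                fc = np.nan
            else:
                fc = math.log2(r["ra"] / baseline)
                if invert:
                    fc = -fc
            rows.append(
                {
                    "gene": gene,
                    "tissue": tissue,
                    "sample_id": r["sample_id"],
                    "morph": r["morph"],
                    "log2_fc": fc,
                    "undefined": undefined or not np.isfinite(fc),
                }
            )
    return pd.DataFrame(
        rows, columns=["gene", "tissue", "sample_id", "morph", "log2_fc", "undefined"]
    )


def compute_gsi(gonad_mass: float, body_mass: float) -> float:
    """Gonadosomatic index in percent: gonad mass x 100 / body mass."""
    if gonad_mass <= 0 or body_mass <= 0:
        raise QuantError("masses must be positive")
    return gonad_mass * 100.0 / body_mass
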