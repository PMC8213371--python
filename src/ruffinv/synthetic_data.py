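"""Seeded generator of synthetic qPCR cohorts with inversion-morph structure.

The generator emulates the data layout of an allele-specific qPCR study of
three male morphs: an ancestral-homozygote morph (Independent) and two
inversion-heterozygote morphs (Satellite, Faeder; inversion homozygotes are
not viable and are never generated). It produces

* a tissue cohort (default 8/2/2 birds across gonad, liver and adrenal)
  measuring inversion genes: a breakpoint-truncated gene probed by an
  across-breakpoint amplicon (templated by the ancestral allele only, plus
  an optional read-through fraction of the inverted allele) and an
  outside-breakpoint amplicon (both alleles); allele-specific assays with a
  tunable inversion-allele expression fraction theta per gene x tissue; and
  two stable reference genes;
* a 14-gene expression panel (default 13/7/5 birds) with morph-specific
  mean shifts, designated correlated gene pairs per morph, and circulating
  testosterone (about an order of magnitude higher in the ancestral morph)
  and gonadosomatic-index covariates (highest in Faeders).

The measurement model is log-normal biology with Gaussian technical noise
on the cycle scale: a reaction starting from template q with efficiency E
crosses the common fluorescence threshold F_t at
Cq = (ln F_t - ln q)/ln E + N(0, sigma_cq) per replicate, censored at the
40-cycle cap (c0 parameterizes the threshold as F_t = 2**c0, so a perfect
doubling assay reads Cq = c0 - log2 q). All
randomness flows from one numpy Generator seeded explicitly, so a fixed
seed reproduces output byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .qpcr_quant import AmpliconSpec

logger = logging.getLogger(__name__)

MORPHS = ("Independent", "Satellite", "Faeder")
HET_MORPHS = ("Satellite", "Faeder")
TISSUES = ("gonad", "liver", "adrenal")

BREAKPOINT_GENE = "CENPN"
#: inversion genes probed with a single common amplicon (efficiency assumed 2)
COMMON_ONLY_GENES = ("BCO1", "SLC7A5", "PLCG2", "TERF2")
#: inversion genes with allele-specific assays (standard-curve efficiencies)
AI_GENES = ("ZFPM1", "ZDHHC7", "ZNF469", "SPATA2L")
TISSUE_REFERENCE_GENES = ("GAPDH", "RPL30")
PANEL_REFERENCE_GENES = ("HPRT1", "RPL32")

PANEL_GENES = (
    "STAR", "CYP11A1", "CYP17A1", "HSD3B2", "SRD5A1", "AROM", "HSD17B2",
    "SDR42E1", "AR", "ESR1", "ESR2", "LHR", "FSHR", "PRLR",
)


def _default_gene_baseline() -> dict[str, float]:
    # log2 relative template abundance; references high and stable
    base = {
        BREAKPOINT_GENE: 1.0,
        "BCO1": 0.5, "SLC7A5": 1.5, "PLCG2": 0.0, "TERF2": 1.0,
        "ZFPM1": 0.5, "ZDHHC7": 1.0, "ZNF469": 0.0, "SPATA2L": 0.5,
        "GAPDH": 6.0, "RPL30": 5.0,
    }
    return base


def _default_ai_theta() -> dict[str, dict[str, float]]:
    theta = {g: {t: 0.5 for t in TISSUES} for g in AI_GENES}
    # one gene with clear excess expression from the inversion allele
    theta["SPATA2L"] = {"gonad": 0.55, "liver": 0.72, "adrenal": 0.75}
    return theta


def _default_efficiencies() -> dict[tuple[str, str], tuple[float, str]]:
    eff: dict[tuple[str, str], tuple[float, str]] = {
        (BREAKPOINT_GENE, "across_breakpoint"): (2.0, "assumed_two"),
        (BREAKPOINT_GENE, "outside_breakpoint"): (2.0, "assumed_two"),
    }
    for g in COMMON_ONLY_GENES:
        eff[(g, "common")] = (2.0, "assumed_two")
    curve = {
        "ZFPM1": (1.95, 1.98), "ZDHHC7": (2.02, 1.96),
        "ZNF469": (1.93, 2.00), "SPATA2L": (1.97, 2.04),
    }
    for g, (e_anc, e_inv) in curve.items():
        eff[(g, "ancestral_specific")] = (e_anc, "standard_curve")
        eff[(g, "inversion_specific")] = (e_inv, "standard_curve")
        eff[(g, "common")] = (2.0, "assumed_two")
    for g in TISSUE_REFERENCE_GENES:
        eff[(g, "reference")] = (2.0, "assumed_two")
    return eff


def _default_panel_baseline() -> dict[str, float]:
    return {
        "STAR": 2.0, "CYP11A1": 1.5, "CYP17A1": 1.0, "HSD3B2": 0.5,
        "SRD5A1": 0.0, "AROM": -1.0, "HSD17B2": 0.0, "SDR42E1": -0.5,
        "AR": 1.0, "ESR1": 0.0, "ESR2": 0.5, "LHR": 1.0, "FSHR": 0.5,
        "PRLR": 0.0,
    }


def _default_panel_shifts() -> dict[str, dict[str, float]]:
    # log2 shifts vs the ancestral morph; with sigma_panel = 0.4 a shift of
    # 1.2 is three within-morph SDs
    return {
        "Satellite": {
            "HSD17B2": 1.2, "ESR2": -1.2, "STAR": 1.4, "CYP17A1": -1.4,
            "FSHR": 1.2, "PRLR": -1.2,
        },
        "Faeder": {
            "HSD17B2": 2.0, "SDR42E1": 1.6, "LHR": 1.4, "ESR2": -2.0,
            "SRD5A1": -1.6, "AR": -1.2,
        },
    }


def _default_correlated_pairs() -> list[tuple[str, str, dict[str, float]]]:
    # strong co-expression of the inversion gene SDR42E1 with aromatase in
    # Independents and Satellites but not Faeders
    return [
        ("SDR42E1", "AROM", {"Independent": 0.99, "Satellite": 0.99, "Faeder": 0.0}),
    ]


class ConfigError(ValueError):
    """Raised by GenerativeConfig.validate with the offending fields listed."""

    def __init__(self, issues: list[str]):
        self.issues = issues
        super().__init__("invalid GenerativeConfig: " + "; ".join(issues))


@dataclass
class GenerativeConfig:
    """All knobs of the synthetic study, with defaults set to the study design."""

    tissue_sizes: dict[str, int] = field(
        default_factory=lambda: {"Independent": 8, "Satellite": 2, "Faeder": 2}
    )
    panel_sizes: dict[str, int] = field(
        default_factory=lambda: {"Independent": 13, "Satellite": 7, "Faeder": 5}
    )
    tissues: tuple[str, ...] = TISSUES

    # --- tissue-cohort measurement model ---
    gene_baseline_log2: dict[str, float] = field(default_factory=_default_gene_baseline)
    tissue_offset_log2: dict[str, float] = field(
        default_factory=lambda: {"gonad": 0.0, "liver": -0.5, "adrenal": -1.0}
    )
    #: overall expression shift of inversion-region genes in heterozygous
    #: morphs (most pronounced in gonads)
    inversion_shift_log2: dict[str, float] = field(
        default_factory=lambda: {"gonad": -0.6, "liver": -0.2, "adrenal": -0.2}
    )
    sigma_bio_log2: float = 0.5
    sigma_ref_log2: float = 0.05
    sigma_cq: float = 0.2
    replicates: int = 2
    max_cycles: float = 40.0
    c0: float = 28.0
    #: ancestral-allele share of breakpoint-gene transcription in heterozygotes
    ancestral_fraction: dict[str, float] = field(
        default_factory=lambda: {"Satellite": 0.5, "Faeder": 0.5}
    )
    #: fraction of inverted-allele transcription continuing past the breakpoint
    read_through: float = 0.0
    ai_theta: dict[str, dict[str, float]] = field(default_factory=_default_ai_theta)
    efficiencies: dict[tuple[str, str], tuple[float, str]] = field(
        default_factory=_default_efficiencies
    )

    # --- expression panel ---
    panel_genes: tuple[str, ...] = PANEL_GENES
    panel_baseline_log2: dict[str, float] = field(default_factory=_default_panel_baseline)
    panel_shifts: dict[str, dict[str, float]] = field(default_factory=_default_panel_shifts)
    panel_sigma_log2: float = 0.4
    correlated_pairs: list[tuple[str, str, dict[str, float]]] = field(
        default_factory=_default_correlated_pairs
    )
    #: lognormal testosterone (ng/mL): ancestral morph about 10x higher
    testosterone_mean: dict[str, float] = field(
        default_factory=lambda: {"Independent": 2.0, "Satellite": 0.2, "Faeder": 0.2}
    )
    testosterone_sigma_log: float = 0.4
    #: GSI percent: Faeder > Satellite ~ Independent
    gsi_mean: dict[str, float] = field(
        default_factory=lambda: {"Independent": 2.0, "Satellite": 2.2, "Faeder": 3.3}
    )
    gsi_sigma: float = 0.6

    def validate(self) -> None:
        issues: list[str] = []
        for name, sizes in (("tissue_sizes", self.tissue_sizes),
                            ("panel_sizes", self.panel_sizes)):
            for morph, n in sizes.items():
                if morph not in MORPHS:
                    issues.append(f"{name}: unknown morph {morph!r}")
                if n < 0:
                    issues.append(f"{name}[{morph}] must be >= 0, got {n}")
        for name, sigma in (("sigma_bio_log2", self.sigma_bio_log2),
                            ("sigma_ref_log2", self.sigma_ref_log2),
                            ("sigma_cq", self.sigma_cq),
                            ("panel_sigma_log2", self.panel_sigma_log2),
                            ("testosterone_sigma_log", self.testosterone_sigma_log),
                            ("gsi_sigma", self.gsi_sigma)):
            if sigma < 0:
                issues.append(f"{name} must be >= 0, got {sigma}")
        if self.replicates < 1:
            issues.append(f"replicates must be >= 1, got {self.replicates}")
        if not (0.0 <= self.read_through <= 1.0):
            issues.append(f"read_through must be in [0,1], got {self.read_through}")
        for morph, a in self.ancestral_fraction.items():
            if not (0.0 <= a <= 1.0):
                issues.append(f"ancestral_fraction[{morph}] outside [0,1]: {a}")
        for gene, per_tissue in self.ai_theta.items():
            for tissue, th in per_tissue.items():
                if not (0.0 <= th <= 1.0):
                    issues.append(f"ai_theta[{gene}][{tissue}] outside [0,1]: {th}")
        for key, (e, _src) in self.efficiencies.items():
            if not (1.0 < e <= 2.2):
                issues.append(f"efficiency {key} outside (1, 2.2]: {e}")
        for a, b, rhos in self.correlated_pairs:
            for gene in (a, b):
                if gene not in self.panel_genes:
                    issues.append(f"correlated pair gene {gene!r} not in panel")
            for morph, rho in rhos.items():
                if not (-1.0 < rho < 1.0):
                    issues.append(f"rho for ({a},{b}) in {morph} outside (-1,1): {rho}")
        if issues:
            raise ConfigError(issues)

    # ------------------------------------------------------------------
    def amplicon_specs(self) -> dict[tuple[str, str], AmpliconSpec]:
        """AmpliconSpec per (gene, amplicon_class) used by the tissue cohort."""
        specs = {}
        for (gene, klass), (e, src) in self.efficiencies.items():
            allele_specific = klass in ("ancestral_specific", "inversion_specific")
            specs[(gene, klass)] = AmpliconSpec(
                gene=gene, amplicon_class=klass, efficiency=e,
                efficiency_source=src, qc_pass=not (allele_specific and e < 1.9),
            )
        return specs

    def amplicon_table(self) -> pd.DataFrame:
        rows = [
            {
                "gene": s.gene,
                "amplicon_class": s.amplicon_class,
                "efficiency": s.efficiency,
                "efficiency_source": s.efficiency_source,
                "qc_pass": s.qc_pass,
            }
            for s in self.amplicon_specs().values()
        ]
        return pd.DataFrame(rows).sort_values(["gene", "amplicon_class"]).reset_index(drop=True)


def _sample_ids(sizes: Mapping[str, int], prefix: str = "") -> list[tuple[str, str]]:
    out = []
    for morph in MORPHS:
        for i in range(sizes.get(morph, 0)):
            out.append((f"{prefix}{morph[0]}{i + 1:02d}", morph))
    return out


def simulate_qpcr_cohort(
    config: GenerativeConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the tissue cohort; returns (CqRecord table, truth table).

    The CqRecord table has one row per technical replicate with columns
    sample_id, morph, tissue, gene, amplicon_class, replicate, cq. The
    truth table records, per sample x tissue x gene, the generating total
    and per-allele abundances, the inversion-allele fraction and the dosage
    state, for parameter-recovery tests.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    samples = _sample_ids(config.tissue_sizes)
    genes = ([BREAKPOINT_GENE] + list(COMMON_ONLY_GENES) + list(AI_GENES)
             + list(TISSUE_REFERENCE_GENES))
    amplicons: dict[str, list[str]] = {BREAKPOINT_GENE: ["across_breakpoint", "outside_breakpoint"]}
    for g in COMMON_ONLY_GENES:
        amplicons[g] = ["common"]
    for g in AI_GENES:
        amplicons[g] = ["common", "ancestral_specific", "inversion_specific"]
    for g in TISSUE_REFERENCE_GENES:
        amplicons[g] = ["reference"]

    rec_rows: list[dict] = []
    truth_rows: list[dict] = []
    inversion_region = {BREAKPOINT_GENE, *COMMON_ONLY_GENES, *AI_GENES}
    for sample_id, morph in samples:
        het = morph in HET_MORPHS
        for tissue in config.tissues:
            for gene in genes:
                is_ref = gene in TISSUE_REFERENCE_GENES
                sigma = config.sigma_ref_log2 if is_ref else config.sigma_bio_log2
                log2_a = config.gene_baseline_log2[gene] + rng.normal(0.0, sigma)
                if not is_ref:
                    log2_a += config.tissue_offset_log2.get(tissue, 0.0)
                    if het and gene in inversion_region:
                        log2_a += config.inversion_shift_log2.get(tissue, 0.0)
                total = 2.0 ** log2_a
                # allele split
                if is_ref:
                    anc, inv, theta = total, 0.0, np.nan
                elif not het:
                    anc, inv, theta = total, 0.0, 0.0
                elif gene == BREAKPOINT_GENE:
                    a_frac = config.ancestral_fraction[morph]
                    anc, inv, theta = a_frac * total, (1 - a_frac) * total, 1 - a_frac
                elif gene in AI_GENES:
                    theta = config.ai_theta[gene][tissue]
                    anc, inv = (1 - theta) * total, theta * total
                else:
                    anc, inv, theta = 0.5 * total, 0.5 * total, 0.5
                truth_rows.append(
                    {
                        "sample_id": sample_id, "morph": morph, "tissue": tissue,
                        "gene": gene, "total_abundance": total,
                        "ancestral_abundance": anc, "inversion_abundance": inv,
                        "theta_inv": theta,
                        "dosage_state": "reference" if is_ref
                        else ("inversion_het" if het else "ancestral_hom"),
                    }
                )
                for klass in amplicons[gene]:
                    if klass == "common":
                        template = anc + inv
                    elif klass == "ancestral_specific":
                        template = anc
                    elif klass == "inversion_specific":
                        template = inv
                    elif klass == "across_breakpoint":
                        template = anc + config.read_through * inv
                    elif klass == "outside_breakpoint":
                        template = anc + inv
                    else:  # reference
                        template = total
                    e = config.efficiencies[(gene, klass)][0]
                    for rep in range(1, config.replicates + 1):
                        if template <= 0:
                            cq = config.max_cycles
                        else:
                            threshold_log = config.c0 * np.log(2.0)
                            cq = ((threshold_log - np.log(template)) / np.log(e)
                                  + rng.normal(0.0, config.sigma_cq))
                            cq = min(cq, config.max_cycles)
                        rec_rows.append(
                            {
                                "sample_id": sample_id, "morph": morph,
                                "tissue": tissue, "gene": gene,
                                "amplicon_class": klass, "replicate": rep,
                                "cq": float(cq),
                            }
                        )
    records = pd.DataFrame(
        rec_rows,
        columns=["sample_id", "morph", "tissue", "gene", "amplicon_class", "replicate", "cq"],
    )
    truth = pd.DataFrame(truth_rows)
    return records, truth


def _morph_covariance(config: GenerativeConfig, morph: str) -> np.ndarray:
    p = len(config.panel_genes)
    idx = {g: i for i, g in enumerate(config.panel_genes)}
    sig = config.panel_sigma_log2
    cov = np.eye(p) * sig**2
    for a, b, rhos in config.correlated_pairs:
        rho = rhos.get(morph, 0.0)
        cov[idx[a], idx[b]] = cov[idx[b], idx[a]] = rho * sig**2
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() < 1e-10:
        # nearest-PD repair: clip the spectrum and reassemble
        w, v = np.linalg.eigh(cov)
        cov = (v * np.clip(w, 1e-8, None)) @ v.T
        logger.warning("panel covariance for %s not PD; spectrum clipped", morph)
    return cov


def simulate_panel(config: GenerativeConfig, seed: int) -> pd.DataFrame:
    """Simulate the gene panel with testosterone and GSI covariates.

    Returns one row per bird: sample_id, morph, one positive expression
    column per panel gene (log-normal within morph, with the configured
    mean shifts and correlated pairs), plus testosterone (ng/mL) and GSI
    (percent).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for sample_id, morph in _sample_ids(config.panel_sizes, prefix="P"):
        shifts = config.panel_shifts.get(morph, {})
        mean = np.array(
            [config.panel_baseline_log2[g] + shifts.get(g, 0.0) for g in config.panel_genes]
        )
        cov = _morph_covariance(config, morph)
        z = rng.multivariate_normal(mean, cov, method="cholesky")
        t_mu = config.testosterone_mean[morph]
        testosterone = float(
            rng.lognormal(np.log(t_mu), config.testosterone_sigma_log)
        )
        gsi = float(max(0.1, rng.normal(config.gsi_mean[morph], config.gsi_sigma)))
        row = {"sample_id": sample_id, "morph": morph}
        row.update({g: float(2.0**zi) for g, zi in zip(config.panel_genes, z)})
        row["testosterone"] = testosterone
        row["gsi"] = gsi
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_dilution_series(
    e_true: float,
    n_points: int = 5,
    noise: float = 0.0,
    seed: int | None = None,
    dilution_range: tuple[float, float] = (5.0, 100.0),
    c0: float = 28.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Standard-curve data: fold-dilution factors and the Cqs they produce."""
    if not (1.0 < e_true <= 2.2):
        raise ConfigError([f"e_true outside (1, 2.2]: {e_true}"])
    if n_points < 3:
        raise ConfigError([f"n_points must be >= 3, got {n_points}"])
    rng = np.random.default_rng(seed)
    factors = np.geomspace(dilution_range[0], dilution_range[1], n_points)
    quantities = 1.0 / factors
    cqs = (c0 * np.log(2.0) - np.log(quantities)) / np.log(e_true)
    if noise > 0:
        cqs = cqs + rng.normal(0.0, noise, size=n_points)
    return factors, cqs
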