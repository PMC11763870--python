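"""Synthetic cohort generation with known ground truth.

Produces the four tables the pipeline consumes (variants, SNP allele
counts, clinical, survival) plus a ground-truth record that the pipeline
under test never sees.  Allele counts follow a purity-aware dosage model:
a heterozygous germline SNP has expected alt fraction 1/2 under disomy,
(1-p)/(2-p) or 1/(2-p) under monosomy (depending on which allele is
lost), and 1/(2+p) or (1+p)/(2+p) under a single-copy gain, where p is
tumor purity.  Somatic variants are clonal heterozygous events with
expected VAF p*ccf/2.  Depths are negative-binomial per amplicon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .panel_model import PanelDefinition, reference_panel

__all__ = ["SimConfig", "GroundTruth", "simulate_cohort", "simulate_balanced_reference"]

# default per-gene mutation frequencies (cohort rates); GNAQ and GNA11 are
# drawn from one categorical so they stay mutually exclusive
DEFAULT_GENE_FREQUENCIES: dict[str, float] = {
    "GNAQ": 0.591,
    "GNA11": 0.296,
    "BAP1": 0.41,
    "SF3B1": 0.182,
    "FOXO1": 0.136,
    "RPL5": 0.114,
    "EIF1AX": 0.114,
    "HIF1A": 0.091,
    "CENPE": 0.068,
    "SRSF2": 0.068,
    "PLCB4": 0.046,
    "TP53": 0.046,
    "BRAF": 0.023,
    "CDKN2A": 0.023,
    "CYSLTR2": 0.023,
}

DEFAULT_IMBALANCE_FREQUENCIES: dict[str, float] = {"1": 0.50, "3": 0.66, "8": 0.568}

# chromosome -> copy-state used when that chromosome is imbalanced
IMBALANCE_COPY_STATE: dict[str, str] = {"1": "monosomy", "3": "monosomy", "8": "gain"}

# one representative alteration per gene (hg19-like coordinates inside the
# bundled panel regions)
_VARIANT_TEMPLATES: dict[str, tuple[str, int, str, str, str, str]] = {
    "GNAQ": ("9", 80409488, "T", "G", "p.Q209P", "MISSENSE"),
    "GNA11": ("19", 3118942, "A", "T", "p.Q209L", "MISSENSE"),
    "CYSLTR2": ("13", 49280769, "G", "A", "p.L129Q", "MISSENSE"),
    "PLCB4": ("20", 9389601, "A", "G", "p.D630Y", "MISSENSE"),
    "BAP1": ("3", 52437422, "CT", "C", "p.L182fs", "FRAMESHIFT"),
    "EIF1AX": ("X", 20156677, "C", "T", "p.G9R", "MISSENSE"),
    "SF3B1": ("2", 198267371, "G", "A", "p.R625C", "MISSENSE"),
    "SRSF2": ("17", 74732959, "C", "T", "p.P95L", "MISSENSE"),
    "CDKN2A": ("9", 21971120, "G", "T", "p.E88*", "NONSENSE"),
    "CENPE": ("4", 104057515, "C", "T", "p.R1013W", "MISSENSE"),
    "FOXO1": ("13", 41134997, "G", "A", "p.S22L", "MISSENSE"),
    "HIF1A": ("14", 62201919, "C", "T", "p.P582S", "MISSENSE"),
    "RPL5": ("1", 93301200, "A", "G", "p.K46E", "MISSENSE"),
    "TP53": ("17", 7577538, "C", "T", "p.R248Q", "MISSENSE"),
    "BRAF": ("7", 140453154, "A", "T", "p.G469V", "MISSENSE"),
}


@dataclass
class SimConfig:
    n_patients: int = 44
    seed: int = 0
    purity_range: tuple[float, float] = (0.85, 0.95)
    depth_mean: float = 500.0
    depth_dispersion: float = 11.0  # negative-binomial size; CV ~ 0.3 at mean 500
    gene_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENE_FREQUENCIES)
    )
    imbalance_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IMBALANCE_FREQUENCIES)
    )
    hazard_ratios: dict[str, float] = field(
        default_factory=lambda: {"BAP1_MUT": 2.5, "IMB3": 2.5}
    )
    baseline_median_months: float = 72.0
    ccf: float = 1.0  # cancer-cell fraction of somatic drivers
    het_rate: float = 0.5  # germline heterozygosity per SNP locus
    hom_error: float = 0.002  # sequencing-error alt fraction at homozygous loci
    noise_variants: bool = True  # emit filter-fodder rows (never ground truth)

    def __post_init__(self) -> None:
        for g, f in self.gene_frequencies.items():
            if not 0 <= f <= 1:
                raise ValueError(f"frequency for {g} outside [0, 1]")
        for c, f in self.imbalance_frequencies.items():
            if not 0 <= f <= 1:
                raise ValueError(f"imbalance frequency for chr{c} outside [0, 1]")
        ga, gb = self.gene_frequencies.get("GNAQ", 0), self.gene_frequencies.get("GNA11", 0)
        if ga + gb > 1:
            raise ValueError("GNAQ + GNA11 frequencies exceed 1; exclusivity infeasible")
        lo, hi = self.purity_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("purity range must satisfy 0 < low <= high <= 1")


@dataclass
class GroundTruth:
    """Per-patient truth labels; never consumed by the pipeline under test."""

    mutations: dict[str, list[str]]
    copy_state: dict[str, dict[str, str]]
    purity: dict[str, float]
    hazard_multiplier: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "mutations": self.mutations,
            "copy_state": self.copy_state,
            "purity": self.purity,
            "hazard_multiplier": self.hazard_multiplier,
        }


def _draw_depth(rng: np.random.Generator, cfg: SimConfig, size: int) -> np.ndarray:
    r = cfg.depth_dispersion
    p = r / (r + cfg.depth_mean)
    return np.maximum(rng.negative_binomial(r, p, size=size), 1)


def _het_alt_prob(copy_state: str, purity: float, rng: np.random.Generator) -> float:
    if copy_state == "disomy":
        return 0.5
    if copy_state == "monosomy":
        # which allele is lost is a coin flip per locus
        return (1 - purity) / (2 - purity) if rng.random() < 0.5 else 1 / (2 - purity)
    if copy_state == "gain":
        return 1 / (2 + purity) if rng.random() < 0.5 else (1 + purity) / (2 + purity)
    raise ValueError(f"unknown copy state {copy_state!r}")


def _somatic_pvalue(alt: np.ndarray | int, depth: np.ndarray | int) -> np.ndarray:
    """One-sided binomial test of the alt count against a 1% error null."""
    return stats.binom.sf(np.asarray(alt) - 1, np.asarray(depth), 0.01)


def simulate_cohort(
    cfg: SimConfig, panel: Optional[PanelDefinition] = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate (variant, SNP, clinical, survival) tables plus ground truth.

    Fixed seed and config give byte-identical tables.
    """
    panel = panel or reference_panel()
    rng = np.random.default_rng(cfg.seed)
    ids = [f"UM{i + 1:05d}" for i in range(cfg.n_patients)]

    genes_other = [g for g in cfg.gene_frequencies if g not in ("GNAQ", "GNA11")]
    p_gnaq = cfg.gene_frequencies.get("GNAQ", 0.0)
    p_gna11 = cfg.gene_frequencies.get("GNA11", 0.0)

    var_rows: list[dict] = []
    snp_rows: list[dict] = []
    clin_rows: list[dict] = []
    surv_rows: list[dict] = []
    truth_mut: dict[str, list[str]] = {}
    truth_cn: dict[str, dict[str, str]] = {}
    truth_purity: dict[str, float] = {}
    truth_hr: dict[str, float] = {}

    lam0 = np.log(2) / cfg.baseline_median_months

    for pid in ids:
        purity = float(rng.uniform(*cfg.purity_range))
        truth_purity[pid] = purity

        # --- mutations ---
        mutated: list[str] = []
        u = rng.random()
        if u < p_gnaq:
            mutated.append("GNAQ")
        elif u < p_gnaq + p_gna11:
            mutated.append("GNA11")
        for g in genes_other:
            if rng.random() < cfg.gene_frequencies[g]:
                mutated.append(g)
        truth_mut[pid] = sorted(mutated)

        for gene in mutated:
            chrom, pos, ref, alt, hgvs_p, csq = _VARIANT_TEMPLATES[gene]
            depth = int(_draw_depth(rng, cfg, 1)[0])
            vaf_true = purity * cfg.ccf / 2
            alt_reads = int(rng.binomial(depth, vaf_true))
            var_rows.append(
                {
                    "patient_id": pid,
                    "gene": gene,
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "total_depth": depth,
                    "alt_depth": alt_reads,
                    "qual": float(np.round(rng.uniform(60, 99), 1)),
                    "pvalue": float(_somatic_pvalue(alt_reads, depth)),
                    "consequence": csq,
                    "clin_class": "PATHOGENIC" if gene in ("GNAQ", "GNA11", "BAP1") else "NOVEL",
                    "hgvs_p": hgvs_p,
                }
            )

        if cfg.noise_variants:
            var_rows.extend(_noise_variants(pid, purity, rng, cfg))

        # --- chromosomal copy states and SNP allele counts ---
        states: dict[str, str] = {}
        for chrom in ("1", "3", "8"):
            imbalanced = rng.random() < cfg.imbalance_frequencies.get(chrom, 0.0)
            states[chrom] = IMBALANCE_COPY_STATE[chrom] if imbalanced else "disomy"
        truth_cn[pid] = states

        for locus in panel.snps:
            depth = int(_draw_depth(rng, cfg, 1)[0])
            gt = rng.random()
            if gt < cfg.het_rate:
                p_alt = _het_alt_prob(states[locus.chrom], purity, rng)
            elif gt < cfg.het_rate + (1 - cfg.het_rate) / 2:
                p_alt = cfg.hom_error
            else:
                p_alt = 1 - cfg.hom_error
            snp_rows.append(
                {
                    "patient_id": pid,
                    "rsid": locus.rsid,
                    "chrom": locus.chrom,
                    "arm": locus.arm,
                    "pos": locus.pos,
                    "total_depth": depth,
                    "alt_depth": int(rng.binomial(depth, p_alt)),
                }
            )

        # --- clinical ---
        clin_rows.append(
            {
                "patient_id": pid,
                "sex": "M" if rng.random() < 0.523 else "F",
                "laterality": rng.choice(["L", "R", "NA"], p=[0.341, 0.614, 0.045]),
                "tumor_size_mm": float(np.round(rng.uniform(2, 30), 1)),
                "site": "CHOROID" if rng.random() < 0.977 else "CHOROID_CILIARY",
            }
        )

        # --- survival ---
        hr = 1.0
        if "BAP1" in mutated:
            hr *= cfg.hazard_ratios.get("BAP1_MUT", 1.0)
        if states["3"] != "disomy":
            hr *= cfg.hazard_ratios.get("IMB3", 1.0)
        truth_hr[pid] = hr
        t_event = rng.exponential(1.0 / (lam0 * hr))
        t_censor = rng.uniform(24, 120)
        event = int(t_event <= t_censor)
        surv_rows.append(
            {
                "patient_id": pid,
                "time_months": float(np.round(max(min(t_event, t_censor), 0.1), 2)),
                "event": event,
            }
        )

    variants = pd.DataFrame(
        var_rows,
        columns=[
            "patient_id", "gene", "chrom", "pos", "ref", "alt", "total_depth",
            "alt_depth", "qual", "pvalue", "consequence", "clin_class", "hgvs_p",
        ],
    )
    snps = pd.DataFrame(
        snp_rows,
        columns=["patient_id", "rsid", "chrom", "arm", "pos", "total_depth", "alt_depth"],
    )
    clinical = pd.DataFrame(
        clin_rows, columns=["patient_id", "sex", "laterality", "tumor_size_mm", "site"]
    )
    survival = pd.DataFrame(surv_rows, columns=["patient_id", "time_months", "event"])
    truth = GroundTruth(
        mutations=truth_mut,
        copy_state=truth_cn,
        purity=truth_purity,
        hazard_multiplier=truth_hr,
    )
    return variants, snps, clinical, survival, truth


def _noise_variants(
    pid: str, purity: float, rng: np.random.Generator, cfg: SimConfig
) -> list[dict]:
    """Rows the filter chain must reject; they carry no ground-truth signal."""
    rows = []
    if rng.random() < 0.4:  # synonymous passenger
        depth = int(_draw_depth(rng, cfg, 1)[0])
        alt = int(rng.binomial(depth, purity / 2))
        rows.append(
            {
                "patient_id": pid, "gene": "CENPE", "chrom": "4", "pos": 104061001,
                "ref": "G", "alt": "A", "total_depth": depth, "alt_depth": alt,
                "qual": float(np.round(rng.uniform(60, 99), 1)),
                "pvalue": float(_somatic_pvalue(alt, depth)),
                "consequence": "SYNONYMOUS", "clin_class": "NOVEL", "hgvs_p": "p.T700=",
            }
        )
    if rng.random() < 0.6:  # germline common polymorphism at ~50% VAF
        depth = int(_draw_depth(rng, cfg, 1)[0])
        alt = int(rng.binomial(depth, 0.5))
        rows.append(
            {
                "patient_id": pid, "gene": "TP53", "chrom": "17", "pos": 7579472,
                "ref": "G", "alt": "C", "total_depth": depth, "alt_depth": alt,
                "qual": float(np.round(rng.uniform(60, 99), 1)),
                "pvalue": float(_somatic_pvalue(alt, depth)),
                "consequence": "MISSENSE", "clin_class": "COMMON_SNP", "hgvs_p": "p.P72R",
            }
        )
    if rng.random() < 0.4:  # low-VAF artifact
        depth = int(_draw_depth(rng, cfg, 1)[0])
        alt = int(rng.binomial(depth, 0.03))
        rows.append(
            {
                "patient_id": pid, "gene": "HIF1A", "chrom": "14", "pos": 62207555,
                "ref": "C", "alt": "A", "total_depth": depth, "alt_depth": alt,
                "qual": float(np.round(rng.uniform(41, 60), 1)),
                "pvalue": float(_somatic_pvalue(alt, depth)),
                "consequence": "MISSENSE", "clin_class": "NOVEL", "hgvs_p": None,
            }
        )
    if rng.random() < 0.3:  # low-quality artifact
        depth = int(_draw_depth(rng, cfg, 1)[0])
        alt = int(rng.binomial(depth, 0.25))
        rows.append(
            {
                "patient_id": pid, "gene": "FOXO1", "chrom": "13", "pos": 41140001,
                "ref": "T", "alt": "C", "total_depth": depth, "alt_depth": alt,
                "qual": float(np.round(rng.uniform(5, 35), 1)),
                "pvalue": float(_somatic_pvalue(alt, depth)),
                "consequence": "MISSENSE", "clin_class": "NOVEL", "hgvs_p": None,
            }
        )
    return rows


def simulate_balanced_reference(
    cfg: SimConfig, panel: Optional[PanelDefinition] = None, sample_id: str = "REF001"
) -> pd.DataFrame:
    """SNP table for a diploid reference sample (negative control).

    Every locus is drawn homozygous or 50%-centred heterozygous, so the
    imbalance caller should report BALANCED (or NON_INFORMATIVE when no
    heterozygous loci were drawn) on all chromosomes.
    """
    panel = panel or reference_panel()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for locus in panel.snps:
        depth = int(_draw_depth(rng, cfg, 1)[0])
        gt = rng.random()
        if gt < cfg.het_rate:
            p_alt = 0.5
        elif gt < cfg.het_rate + (1 - cfg.het_rate) / 2:
            p_alt = cfg.hom_error
        else:
            p_alt = 1 - cfg.hom_error
        rows.append(
            {
                "patient_id": sample_id,
                "rsid": locus.rsid,
                "chrom": locus.chrom,
                "arm": locus.arm,
                "pos": locus.pos,
                "total_depth": depth,
                "alt_depth": int(rng.binomial(depth, p_alt)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "rsid", "chrom", "arm", "pos", "total_depth", "alt_depth"],
    )
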