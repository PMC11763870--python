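"""Per-patient molecular profiles, cohort summaries and risk strata."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

from .imbalance import CHROMOSOMES, ChromosomeImbalanceCall, ImbalanceStatus
from .panel_model import GeneCategory, PANEL_GENES, category_of
from .variant_filtering import VariantCall

__all__ = [
    "StratumLabel",
    "Scheme",
    "PatientProfile",
    "CohortSummary",
    "RiskStratum",
    "build_profile",
    "summarize_cohort",
    "stratify",
    "round_pct",
]


class Scheme(str, enum.Enum):
    BAP1 = "BAP1"
    CHR1 = "CHR1"
    CHR3 = "CHR3"
    CHR8 = "CHR8"


class StratumLabel(str, enum.Enum):
    BAP1_MUT = "BAP1_MUT"
    BAP1_WT = "BAP1_WT"
    D3 = "D3"
    IMB1 = "IMB1"
    IMB3 = "IMB3"
    IMB8 = "IMB8"


def round_pct(count: int, n: int) -> float:
    """Percentage with half-up rounding to one decimal."""
    pct = Decimal(100 * count) / Decimal(n)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class PatientProfile:
    patient_id: str
    mutations: list[VariantCall] = field(default_factory=list)
    imbalances: dict[str, ImbalanceStatus] = field(default_factory=dict)
    sex: str = "NA"
    laterality: str = "NA"
    tumor_size_mm: Optional[float] = None
    site: str = "NA"

    @property
    def mutated_genes(self) -> set[str]:
        return {v.gene for v in self.mutations}

    @property
    def category_hits(self) -> dict[GeneCategory, set[str]]:
        hits: dict[GeneCategory, set[str]] = {}
        for gene in self.mutated_genes:
            hits.setdefault(category_of(gene), set()).add(gene)
        return hits

    @property
    def bap1_status(self) -> str:
        return "MUTATED" if "BAP1" in self.mutated_genes else "WT"


@dataclass
class CohortSummary:
    n_patients: int
    gene_counts: dict[str, int]
    gene_pcts: dict[str, float]
    imbalance_counts: dict[str, int]
    imbalance_pcts: dict[str, float]
    mutually_exclusive: dict[tuple[str, str], bool]


@dataclass
class RiskStratum:
    label: StratumLabel
    patient_ids: list[str]

    def __len__(self) -> int:
        return len(self.patient_ids)


def build_profile(
    patient_id: str,
    kept_variants: Sequence[VariantCall],
    imbalance_calls: Mapping[str, ChromosomeImbalanceCall] | Mapping[str, ImbalanceStatus],
    clinical_row: Optional[Mapping[str, object]] = None,
) -> PatientProfile:
    """Assemble one patient's molecular profile.

    Missing clinical fields become NA placeholders; the patient is never
    dropped.  Chromosomes absent from the imbalance calls are recorded as
    NON_INFORMATIVE.
    """
    imbalances: dict[str, ImbalanceStatus] = {}
    for chrom in CHROMOSOMES:
        call = imbalance_calls.get(chrom)
        if call is None:
            imbalances[chrom] = ImbalanceStatus.NON_INFORMATIVE
        elif isinstance(call, ChromosomeImbalanceCall):
            imbalances[chrom] = call.status
        else:
            imbalances[chrom] = ImbalanceStatus(call)
    row = dict(clinical_row or {})
    size = row.get("tumor_size_mm")
    return PatientProfile(
        patient_id=patient_id,
        mutations=list(kept_variants),
        imbalances=imbalances,
        sex=str(row.get("sex", "NA") or "NA"),
        laterality=str(row.get("laterality", "NA") or "NA"),
        tumor_size_mm=float(size) if size not in (None, "", "NA") else None,
        site=str(row.get("site", "NA") or "NA"),
    )


def summarize_cohort(
    profiles: Sequence[PatientProfile],
    exclusive_pairs: Iterable[tuple[str, str]] = (("GNAQ", "GNA11"),),
) -> CohortSummary:
    """Cohort-level mutation and imbalance rates.

    A gene counts once per patient regardless of how many variants hit
    it; imbalance rates count IMBALANCED calls only.
    """
    if not profiles:
        raise ValueError("empty cohort")
    n = len(profiles)
    gene_counts = {g: 0 for g in sorted(PANEL_GENES)}
    for p in profiles:
        for g in p.mutated_genes:
            gene_counts.setdefault(g, 0)
            gene_counts[g] += 1
    imbalance_counts = {
        chrom: sum(
            1 for p in profiles if p.imbalances.get(chrom) is ImbalanceStatus.IMBALANCED
        )
        for chrom in CHROMOSOMES
    }
    mutually_exclusive = {
        (a, b): not any({a, b} <= p.mutated_genes for p in profiles)
        for a, b in exclusive_pairs
    }
    return CohortSummary(
        n_patients=n,
        gene_counts=gene_counts,
        gene_pcts={g: round_pct(c, n) for g, c in gene_counts.items()},
        imbalance_counts=imbalance_counts,
        imbalance_pcts={c: round_pct(k, n) for c, k in imbalance_counts.items()},
        mutually_exclusive=mutually_exclusive,
    )


_SCHEME_CHROM = {Scheme.CHR1: "1", Scheme.CHR3: "3", Scheme.CHR8: "8"}
_SCHEME_IMB = {Scheme.CHR1: StratumLabel.IMB1, Scheme.CHR3: StratumLabel.IMB3, Scheme.CHR8: StratumLabel.IMB8}


def stratify(
    profiles: Sequence[PatientProfile], scheme: Scheme | str
) -> tuple[RiskStratum, RiskStratum, list[str]]:
    """Split a cohort into the two comparison groups for a scheme.

    BAP1: mutated vs wild-type.  CHRk: patients IMBALANCED for chromosome
    k vs a disomy-3 baseline — BALANCED for chromosome 3 and, when k != 3,
    also BALANCED for chromosome k.  Patients fitting neither group (e.g.
    NON_INFORMATIVE for a required chromosome) are excluded and returned
    as the third element.
    """
    scheme = Scheme(scheme)
    excluded: list[str] = []
    if scheme is Scheme.BAP1:
        a = [p.patient_id for p in profiles if p.bap1_status == "MUTATED"]
        b = [p.patient_id for p in profiles if p.bap1_status == "WT"]
        groups = (
            RiskStratum(StratumLabel.BAP1_MUT, a),
            RiskStratum(StratumLabel.BAP1_WT, b),
        )
    else:
        chrom = _SCHEME_CHROM[scheme]
        a, b = [], []
        for p in profiles:
            status_k = p.imbalances.get(chrom, ImbalanceStatus.NON_INFORMATIVE)
            status_3 = p.imbalances.get("3", ImbalanceStatus.NON_INFORMATIVE)
            if status_k is ImbalanceStatus.IMBALANCED:
                a.append(p.patient_id)
            elif status_3 is ImbalanceStatus.BALANCED and (
                chrom == "3" or status_k is ImbalanceStatus.BALANCED
            ):
                b.append(p.patient_id)
            else:
                excluded.append(p.patient_id)
        groups = (
            RiskStratum(_SCHEME_IMB[scheme], a),
            RiskStratum(StratumLabel.D3, b),
        )
    overlap = set(groups[0].patient_ids) & set(groups[1].patient_ids)
    if overlap:
        raise RuntimeError(f"patients in both strata: {sorted(overlap)}")
    return groups[0], groups[1], excluded
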