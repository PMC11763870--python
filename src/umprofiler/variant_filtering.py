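"""Variant allele frequency computation, filter chain and clinical classing.

The filter chain keeps a call only if it clears, in order: VAF >= 10%
(inclusive), read depth > 100, Phred quality > 40, caller p-value < 0.01,
non-synonymous consequence, and a clinical class other than benign/common
polymorphism.  Rejections record the first failing rule.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

__all__ = [
    "Consequence",
    "ClinClass",
    "RejectReason",
    "VariantCall",
    "FilterConfig",
    "AnnotationTable",
    "RejectedVariant",
    "compute_vaf",
    "apply_filter_chain",
    "classify_variant",
]


class Consequence(str, enum.Enum):
    SYNONYMOUS = "SYNONYMOUS"
    MISSENSE = "MISSENSE"
    NONSENSE = "NONSENSE"
    FRAMESHIFT = "FRAMESHIFT"
    SPLICE = "SPLICE"
    OTHER = "OTHER"


class ClinClass(str, enum.Enum):
    PATHOGENIC = "PATHOGENIC"
    VUS = "VUS"
    CIP = "CIP"
    NOVEL = "NOVEL"
    BENIGN = "BENIGN"
    COMMON_SNP = "COMMON_SNP"


class RejectReason(str, enum.Enum):
    VAF_BELOW_CUTOFF = "VAF_BELOW_CUTOFF"
    LOW_DEPTH = "LOW_DEPTH"
    LOW_QUALITY = "LOW_QUALITY"
    HIGH_PVALUE = "HIGH_PVALUE"
    SYNONYMOUS = "SYNONYMOUS"
    BENIGN_OR_COMMON = "BENIGN_OR_COMMON"
    MALFORMED = "MALFORMED"


def compute_vaf(alt_depth: int, total_depth: int) -> float:
    """Variant allele frequency as a percent of reads.

    Raises ``ValueError`` when total depth is zero or the counts are
    inconsistent.
    """
    if total_depth <= 0:
        raise ValueError("VAF undefined: total depth must be positive")
    if not 0 <= alt_depth <= total_depth:
        raise ValueError(
            f"alt depth {alt_depth} outside [0, {total_depth}]"
        )
    return 100.0 * alt_depth / total_depth


@dataclass
class VariantCall:
    patient_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    total_depth: int
    alt_depth: int
    qual: float
    pvalue: float
    consequence: Consequence
    clin_class: ClinClass = ClinClass.NOVEL
    hgvs_p: Optional[str] = None
    vaf: float = field(default=math.nan)

    def __post_init__(self) -> None:
        self.consequence = Consequence(self.consequence)
        self.clin_class = ClinClass(self.clin_class)
        if math.isnan(self.vaf):
            self.vaf = compute_vaf(self.alt_depth, self.total_depth)

    @property
    def genomic_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def protein_key(self) -> Optional[tuple[str, str]]:
        return (self.gene, self.hgvs_p) if self.hgvs_p else None


@dataclass(frozen=True)
class FilterConfig:
    vaf_min: float = 10.0  # percent, inclusive
    depth_min: int = 100  # strict: depth must exceed this
    qual_min: float = 40.0  # strict
    p_max: float = 0.01  # strict


@dataclass(frozen=True)
class RejectedVariant:
    variant: VariantCall
    reason: RejectReason
    detail: str = ""


class AnnotationTable:
    """Offline clinical-significance lookup.

    Maps either a genomic key (chrom, pos, ref, alt) or a protein key
    (gene, hgvs_p) to a clinical class; variants absent from both maps
    classify as NOVEL.
    """

    def __init__(
        self,
        genomic: Mapping[tuple[str, int, str, str], ClinClass] | None = None,
        protein: Mapping[tuple[str, str], ClinClass] | None = None,
    ) -> None:
        self.genomic = dict(genomic or {})
        self.protein = dict(protein or {})

    def lookup(self, variant: VariantCall) -> ClinClass:
        hit = self.genomic.get(variant.genomic_key)
        if hit is not None:
            return hit
        if variant.protein_key is not None:
            hit = self.protein.get(variant.protein_key)
            if hit is not None:
                return hit
        return ClinClass.NOVEL

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationTable":
        """Read an annotation TSV with columns:
        chrom, pos, ref, alt, gene, hgvs_p, clin_class (empty fields allowed
        for whichever key is absent)."""
        genomic: dict[tuple[str, int, str, str], ClinClass] = {}
        protein: dict[tuple[str, str], ClinClass] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {name: i for i, name in enumerate(header)}
            for lineno, raw in enumerate(fh, start=2):
                if not raw.strip():
                    continue
                f = raw.rstrip("\n").split("\t")
                cls_ = ClinClass(f[idx["clin_class"]])
                if f[idx["chrom"]] and f[idx["pos"]]:
                    genomic[
                        (f[idx["chrom"]], int(f[idx["pos"]]), f[idx["ref"]], f[idx["alt"]])
                    ] = cls_
                if f[idx["gene"]] and f[idx["hgvs_p"]]:
                    protein[(f[idx["gene"]], f[idx["hgvs_p"]])] = cls_
        return cls(genomic, protein)


def classify_variant(variant: VariantCall, annotations: AnnotationTable) -> ClinClass:
    """Table lookup; unlisted variants are NOVEL."""
    return annotations.lookup(variant)


def _first_failure(v: VariantCall, cfg: FilterConfig) -> Optional[RejectReason]:
    # rule order is fixed so reason codes are deterministic and auditable
    if v.vaf < cfg.vaf_min:
        return RejectReason.VAF_BELOW_CUTOFF
    if not v.total_depth > cfg.depth_min:
        return RejectReason.LOW_DEPTH
    if not v.qual > cfg.qual_min:
        return RejectReason.LOW_QUALITY
    if not v.pvalue < cfg.p_max:
        return RejectReason.HIGH_PVALUE
    if v.consequence is Consequence.SYNONYMOUS:
        return RejectReason.SYNONYMOUS
    if v.clin_class in (ClinClass.BENIGN, ClinClass.COMMON_SNP):
        return RejectReason.BENIGN_OR_COMMON
    return None


def apply_filter_chain(
    variants: Iterable[VariantCall], cfg: FilterConfig = FilterConfig()
) -> tuple[list[VariantCall], list[RejectedVariant]]:
    """Partition variants into (kept, rejected-with-reason).

    Every input lands in exactly one of the two lists; malformed records
    (missing or inconsistent numeric fields) are rejected with reason
    MALFORMED rather than raising.
    """
    kept: list[VariantCall] = []
    rejected: list[RejectedVariant] = []
    for v in variants:
        try:
            for name in ("total_depth", "alt_depth", "qual", "pvalue", "vaf"):
                value = getattr(v, name)
                if value is None or (isinstance(value, float) and math.isnan(value)):
                    raise ValueError(f"missing field {name}")
            if not 0 <= v.alt_depth <= v.total_depth:
                raise ValueError("alt_depth outside [0, total_depth]")
        except (ValueError, TypeError) as exc:
            rejected.append(RejectedVariant(v, RejectReason.MALFORMED, str(exc)))
            continue
        reason = _first_failure(v, cfg)
        if reason is None:
            kept.append(v)
        else:
            rejected.append(RejectedVariant(v, reason))
    return kept, rejected
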