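"""Bi-allelic imbalance calling on chromosomes 1, 3 and 8 from SNP VAFs.

Heterozygous SNPs sit near 50% VAF and homozygous ones near 0%/100%; a
copy-number change on a chromosome shifts heterozygous loci out of the
heterozygosity band.  Each SNP is banded (homozygous 0-5% / 95-100%,
heterozygous 45-55%, inclusive bounds; anything else is deviant) and a
chromosome is called imbalanced when enough informative SNPs deviate.

Homozygous loci carry no dosage information (a copy loss cannot move a
0% or 100% VAF) and never count toward a call; informative loci are the
heterozygous plus deviant ones.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .panel_model import PanelDefinition, SnpLocus

logger = logging.getLogger(__name__)

__all__ = [
    "BandConfig",
    "ZygosityBand",
    "ImbalanceStatus",
    "SnpObservation",
    "ChromosomeImbalanceCall",
    "band_snp",
    "call_chromosome",
    "call_patient_imbalances",
    "CHROMOSOMES",
]

CHROMOSOMES = ("1", "3", "8")


class ZygosityBand(str, enum.Enum):
    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    DEVIANT = "DEVIANT"


class ImbalanceStatus(str, enum.Enum):
    BALANCED = "BALANCED"
    IMBALANCED = "IMBALANCED"
    NON_INFORMATIVE = "NON_INFORMATIVE"


@dataclass(frozen=True)
class BandConfig:
    hom_low: tuple[float, float] = (0.0, 5.0)
    het: tuple[float, float] = (45.0, 55.0)
    hom_high: tuple[float, float] = (95.0, 100.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.hom_low, self.het, self.hom_high):
            if lo > hi:
                raise ValueError(f"band [{lo}, {hi}] is empty")
        if not (self.hom_low[1] < self.het[0] and self.het[1] < self.hom_high[0]):
            raise ValueError("zygosity bands must be disjoint and ordered")


@dataclass(frozen=True)
class SnpObservation:
    patient_id: str
    locus: SnpLocus
    total_depth: int
    alt_depth: int

    def __post_init__(self) -> None:
        if self.total_depth <= 0:
            raise ValueError(f"SNP {self.locus.rsid}: total depth must be positive")
        if not 0 <= self.alt_depth <= self.total_depth:
            raise ValueError(f"SNP {self.locus.rsid}: alt depth out of range")

    @property
    def vaf(self) -> float:
        return 100.0 * self.alt_depth / self.total_depth


@dataclass(frozen=True)
class ChromosomeImbalanceCall:
    patient_id: str
    chrom: str
    n_snps: int
    n_homozygous: int
    n_het: int
    n_deviant: int
    status: ImbalanceStatus
    arm_status: Mapping[str, ImbalanceStatus] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_homozygous + self.n_het + self.n_deviant == self.n_snps


def band_snp(vaf: float, cfg: BandConfig = BandConfig()) -> ZygosityBand:
    """Assign a VAF (percent) to its zygosity band; bounds are inclusive."""
    if not 0.0 <= vaf <= 100.0:
        raise ValueError(f"VAF {vaf} outside [0, 100]")
    if cfg.hom_low[0] <= vaf <= cfg.hom_low[1]:
        return ZygosityBand.HOM_REF
    if cfg.het[0] <= vaf <= cfg.het[1]:
        return ZygosityBand.HET
    if cfg.hom_high[0] <= vaf <= cfg.hom_high[1]:
        return ZygosityBand.HOM_ALT
    return ZygosityBand.DEVIANT


def _aggregate(
    bands: Sequence[ZygosityBand], min_informative: int, deviant_fraction: float
) -> tuple[ImbalanceStatus, int, int, int]:
    counts = Counter(bands)
    n_hom = counts[ZygosityBand.HOM_REF] + counts[ZygosityBand.HOM_ALT]
    n_het = counts[ZygosityBand.HET]
    n_dev = counts[ZygosityBand.DEVIANT]
    informative = n_het + n_dev
    if informative < min_informative:
        status = ImbalanceStatus.NON_INFORMATIVE
    elif n_dev >= min_informative and n_dev / informative >= deviant_fraction:
        status = ImbalanceStatus.IMBALANCED
    else:
        status = ImbalanceStatus.BALANCED
    return status, n_hom, n_het, n_dev


def call_chromosome(
    snps: Sequence[SnpObservation],
    cfg: BandConfig = BandConfig(),
    min_informative: int = 2,
    deviant_fraction: float = 0.5,
    patient_id: Optional[str] = None,
    chrom: Optional[str] = None,
) -> ChromosomeImbalanceCall:
    """Call one chromosome for one patient from its SNP observations.

    A chromosome is NON_INFORMATIVE with fewer than ``min_informative``
    informative (het or deviant) loci, IMBALANCED when at least
    ``min_informative`` loci deviate and deviants make up at least
    ``deviant_fraction`` of the informative loci, else BALANCED.
    """
    if min_informative < 1:
        raise ValueError("min_informative must be >= 1")
    if not 0 < deviant_fraction <= 1:
        raise ValueError("deviant_fraction must be in (0, 1]")
    if snps:
        patients = {s.patient_id for s in snps}
        chroms = {s.locus.chrom for s in snps}
        if len(patients) > 1:
            raise ValueError(f"mixed patients in input: {sorted(patients)}")
        if len(chroms) > 1:
            raise ValueError(f"mixed chromosomes in input: {sorted(chroms)}")
        patient_id = patients.pop()
        chrom = chroms.pop()
    if patient_id is None or chrom is None:
        raise ValueError("empty input requires explicit patient_id and chrom")

    bands = [band_snp(s.vaf, cfg) for s in snps]
    status, n_hom, n_het, n_dev = _aggregate(bands, min_informative, deviant_fraction)

    arm_status: dict[str, ImbalanceStatus] = {}
    for arm in ("p", "q"):
        arm_bands = [b for b, s in zip(bands, snps) if s.locus.arm == arm]
        arm_status[arm] = _aggregate(arm_bands, min_informative, deviant_fraction)[0]

    return ChromosomeImbalanceCall(
        patient_id=patient_id,
        chrom=chrom,
        n_snps=len(snps),
        n_homozygous=n_hom,
        n_het=n_het,
        n_deviant=n_dev,
        status=status,
        arm_status=arm_status,
    )


def call_patient_imbalances(
    snps: Iterable[SnpObservation],
    panel: Optional[PanelDefinition] = None,
    cfg: BandConfig = BandConfig(),
    min_informative: int = 2,
    deviant_fraction: float = 0.5,
    patient_id: Optional[str] = None,
) -> dict[str, ChromosomeImbalanceCall]:
    """One imbalance call per chromosome in {1, 3, 8} for one patient.

    Loci not in the panel's SNP set are ignored with a warning; a
    chromosome with no observations is NON_INFORMATIVE with zero counts.
    """
    known = set(panel.snp_index()) if panel is not None else None
    by_chrom: dict[str, list[SnpObservation]] = {c: [] for c in CHROMOSOMES}
    for obs in snps:
        if known is not None and obs.locus.rsid not in known:
            logger.warning(
                "locus %s not in panel; ignored for patient %s",
                obs.locus.rsid,
                obs.patient_id,
            )
            continue
        if patient_id is None:
            patient_id = obs.patient_id
        elif obs.patient_id != patient_id:
            raise ValueError(
                f"mixed patients: {obs.patient_id!r} vs {patient_id!r}"
            )
        by_chrom[obs.locus.chrom].append(obs)
    if patient_id is None:
        raise ValueError("no observations and no explicit patient_id")
    return {
        chrom: call_chromosome(
            obs_list,
            cfg=cfg,
            min_informative=min_informative,
            deviant_fraction=deviant_fraction,
            patient_id=patient_id,
            chrom=chrom,
        )
        for chrom, obs_list in by_chrom.items()
    }
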