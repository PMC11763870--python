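"""Panel model: gene categories, target regions and SNP loci.

The reference panel targets 15 genes (full CDS or hotspot exons) plus 55
polymorphic SNP loci on both arms of chromosomes 1, 3 and 8, tiled by 418
amplicons in two primer pools.  Coordinates are hg19, 1-based inclusive;
BED input is converted at the boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "GeneCategory",
    "CoverageMode",
    "TargetRegion",
    "SnpLocus",
    "PanelDefinition",
    "PanelError",
    "GENE_CATEGORIES",
    "PANEL_GENES",
    "FULL_CDS_GENES",
    "HOTSPOT_GENES",
    "category_of",
    "load_panel",
    "write_panel",
    "reference_panel",
]


class PanelError(ValueError):
    """Raised for malformed or inconsistent panel definitions."""


class GeneCategory(str, enum.Enum):
    INITIATING = "INITIATING"
    PROGNOSTIC = "PROGNOSTIC"
    EMERGENT = "EMERGENT"
    CONTROL = "CONTROL"


class CoverageMode(str, enum.Enum):
    FULL_CDS = "FULL_CDS"
    HOTSPOT = "HOTSPOT"


GENE_CATEGORIES: Mapping[GeneCategory, frozenset[str]] = {
    GeneCategory.INITIATING: frozenset({"CYSLTR2", "GNA11", "GNAQ", "PLCB4"}),
    GeneCategory.PROGNOSTIC: frozenset({"BAP1", "EIF1AX", "SF3B1", "SRSF2"}),
    GeneCategory.EMERGENT: frozenset(
        {"CDKN2A", "CENPE", "FOXO1", "HIF1A", "RPL5", "TP53"}
    ),
    GeneCategory.CONTROL: frozenset({"BRAF"}),
}

PANEL_GENES: frozenset[str] = frozenset().union(*GENE_CATEGORIES.values())

FULL_CDS_GENES: frozenset[str] = frozenset(
    {"BAP1", "CDKN2A", "CENPE", "FOXO1", "HIF1A", "RPL5", "SRSF2", "TP53"}
)
HOTSPOT_GENES: frozenset[str] = PANEL_GENES - FULL_CDS_GENES

_CATEGORY_BY_GENE: dict[str, GeneCategory] = {
    gene: cat for cat, genes in GENE_CATEGORIES.items() for gene in genes
}


def category_of(gene: str) -> GeneCategory:
    """Return the category of a panel gene; raise for non-panel symbols."""
    try:
        return _CATEGORY_BY_GENE[gene]
    except KeyError:
        raise PanelError(f"unknown panel gene: {gene!r}") from None


@dataclass(frozen=True)
class TargetRegion:
    gene: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    pool: int
    coverage_mode: CoverageMode

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise PanelError(
                f"region {self.gene} {self.chrom}:{self.start}-{self.end}: "
                "start > end"
            )
        if self.pool not in (1, 2):
            raise PanelError(f"region {self.gene}: pool must be 1 or 2")
        category_of(self.gene)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SnpLocus:
    rsid: str
    chrom: str  # "1", "3" or "8"
    arm: str  # "p" or "q"
    pos: int  # 1-based

    def __post_init__(self) -> None:
        if self.chrom not in ("1", "3", "8"):
            raise PanelError(f"SNP {self.rsid}: chromosome must be 1, 3 or 8")
        if self.arm not in ("p", "q"):
            raise PanelError(f"SNP {self.rsid}: arm must be 'p' or 'q'")
        if self.pos < 1:
            raise PanelError(f"SNP {self.rsid}: position must be positive")


@dataclass
class PanelDefinition:
    regions: list[TargetRegion]
    snps: list[SnpLocus]
    amplicon_count: int = 418

    def __post_init__(self) -> None:
        for region in self.regions:
            category_of(region.gene)

    @property
    def genes(self) -> set[str]:
        return {r.gene for r in self.regions}

    def snp_index(self) -> dict[str, SnpLocus]:
        return {s.rsid: s for s in self.snps}

    def validate_reference(self) -> None:
        """Assert the invariants of the bundled reference panel."""
        if len(self.genes) != 15:
            raise PanelError(f"expected 15 genes, found {len(self.genes)}")
        if len(self.snps) != 55:
            raise PanelError(f"expected 55 SNP loci, found {len(self.snps)}")
        arms = {(s.chrom, s.arm) for s in self.snps}
        expected = {(c, a) for c in ("1", "3", "8") for a in ("p", "q")}
        if arms != expected:
            raise PanelError(f"SNP loci missing arms: {sorted(expected - arms)}")


_REGION_HEADER = "#regions\tchrom\tstart\tend\tgene\tpool\tmode"
_SNP_HEADER = "#snps\trsid\tchrom\tarm\tpos"


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def load_panel(path: str | Path, *, bed_coords: bool = False) -> PanelDefinition:
    """Load a panel-definition file.

    The file holds a region section (chrom, start, end, gene, pool, mode)
    and a SNP section (rsid, chrom, arm, pos), each introduced by a header
    line.  Region coordinates are 1-based inclusive unless ``bed_coords``
    asks for 0-based half-open conversion.
    """
    path = Path(path)
    regions: list[TargetRegion] = []
    snps: list[SnpLocus] = []
    amplicon_count = 418
    section = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#umprofiler-panel"):
                for tok in line.split()[1:]:
                    if tok.startswith("amplicon_count="):
                        amplicon_count = int(tok.split("=", 1)[1])
                continue
            if line.startswith("#regions"):
                section = "regions"
                continue
            if line.startswith("#snps"):
                section = "snps"
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if section == "regions":
                if len(fields) != 6:
                    raise PanelError(
                        f"{path}:{lineno}: expected 6 region columns, "
                        f"got {len(fields)}"
                    )
                chrom, start_s, end_s, gene, pool_s, mode = fields
                try:
                    start, end, pool = int(start_s), int(end_s), int(pool_s)
                except ValueError as exc:
                    raise PanelError(f"{path}:{lineno}: {exc}") from None
                if bed_coords:
                    start += 1  # 0-based half-open -> 1-based inclusive
                if gene not in PANEL_GENES:
                    raise PanelError(f"{path}:{lineno}: unknown gene symbol {gene!r}")
                if start > end:
                    raise PanelError(
                        f"{path}:{lineno}: coordinate error, start {start} > end {end}"
                    )
                regions.append(
                    TargetRegion(
                        gene=gene,
                        chrom=_norm_chrom(chrom),
                        start=start,
                        end=end,
                        pool=pool,
                        coverage_mode=CoverageMode(mode),
                    )
                )
            elif section == "snps":
                if len(fields) != 4:
                    raise PanelError(
                        f"{path}:{lineno}: expected 4 SNP columns, got {len(fields)}"
                    )
                rsid, chrom, arm, pos_s = fields
                try:
                    pos = int(pos_s)
                except ValueError as exc:
                    raise PanelError(f"{path}:{lineno}: {exc}") from None
                snps.append(SnpLocus(rsid=rsid, chrom=_norm_chrom(chrom), arm=arm, pos=pos))
            else:
                raise PanelError(f"{path}:{lineno}: data line before section header")
    return PanelDefinition(regions=regions, snps=snps, amplicon_count=amplicon_count)


def write_panel(panel: PanelDefinition, path: str | Path) -> None:
    """Write a panel definition in the format read by :func:`load_panel`."""
    path = Path(path)
    lines = [f"#umprofiler-panel\tamplicon_count={panel.amplicon_count}"]
    lines.append(_REGION_HEADER)
    for r in panel.regions:
        lines.append(
            f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}\t{r.pool}\t{r.coverage_mode.value}"
        )
    lines.append(_SNP_HEADER)
    for s in panel.snps:
        lines.append(f"{s.rsid}\t{s.chrom}\t{s.arm}\t{s.pos}")
    path.write_text("\n".join(lines) + "\n")


def reference_panel() -> PanelDefinition:
    """Load the bundled reference panel (15 genes, 55 SNP loci, 418 amplicons)."""
    with resources.as_file(
        resources.files("umprofiler.data") / "reference_panel.tsv"
    ) as p:
        panel = load_panel(p)
    panel.validate_reference()
    return panel
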