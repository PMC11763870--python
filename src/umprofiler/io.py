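"""Readers and writers for the interchange tables and VCF input.

All tables are plain TSV/CSV with documented columns; chromosome names
are accepted with or without a "chr" prefix and stored without it.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .imbalance import ChromosomeImbalanceCall, ImbalanceStatus, SnpObservation
from .panel_model import SnpLocus
from .survival import SurvivalRecord
from .variant_filtering import RejectedVariant, VariantCall

__all__ = [
    "read_variants_tsv",
    "write_variants_tsv",
    "write_rejections_tsv",
    "read_snps_tsv",
    "write_imbalance_tsv",
    "read_imbalance_tsv",
    "read_clinical",
    "read_survival",
    "read_vcf",
    "file_checksum",
    "write_manifest",
]

VARIANT_COLUMNS = [
    "patient_id", "gene", "chrom", "pos", "ref", "alt", "total_depth",
    "alt_depth", "vaf", "qual", "pvalue", "consequence", "clin_class", "hgvs_p",
]


def _norm_chrom(chrom: str) -> str:
    chrom = str(chrom)
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def read_variants_tsv(path: str | Path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "patient_id": str})
    required = {"patient_id", "gene", "chrom", "pos", "ref", "alt", "total_depth",
                "alt_depth", "qual", "pvalue", "consequence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing variant columns {sorted(missing)}")
    calls = []
    for row in df.itertuples(index=False):
        hgvs = getattr(row, "hgvs_p", None)
        if isinstance(hgvs, float) and math.isnan(hgvs):
            hgvs = None
        calls.append(
            VariantCall(
                patient_id=str(row.patient_id),
                gene=row.gene,
                chrom=_norm_chrom(row.chrom),
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                total_depth=int(row.total_depth),
                alt_depth=int(row.alt_depth),
                qual=float(row.qual),
                pvalue=float(row.pvalue),
                consequence=row.consequence,
                clin_class=getattr(row, "clin_class", "NOVEL"),
                hgvs_p=hgvs,
            )
        )
    return calls


def _variant_row(v: VariantCall) -> dict:
    return {
        "patient_id": v.patient_id, "gene": v.gene, "chrom": v.chrom, "pos": v.pos,
        "ref": v.ref, "alt": v.alt, "total_depth": v.total_depth,
        "alt_depth": v.alt_depth, "vaf": round(v.vaf, 4), "qual": v.qual,
        "pvalue": v.pvalue, "consequence": v.consequence.value,
        "clin_class": v.clin_class.value, "hgvs_p": v.hgvs_p or "",
    }


def write_variants_tsv(variants: Iterable[VariantCall], path: str | Path) -> None:
    pd.DataFrame([_variant_row(v) for v in variants], columns=VARIANT_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def write_rejections_tsv(rejections: Iterable[RejectedVariant], path: str | Path) -> None:
    rows = []
    for r in rejections:
        row = _variant_row(r.variant)
        row["reason"] = r.reason.value
        row["detail"] = r.detail
        rows.append(row)
    pd.DataFrame(rows, columns=VARIANT_COLUMNS + ["reason", "detail"]).to_csv(
        path, sep="\t", index=False
    )


def read_snps_tsv(path: str | Path) -> list[SnpObservation]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "patient_id": str})
    required = {"patient_id", "rsid", "chrom", "arm", "pos", "total_depth", "alt_depth"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing SNP columns {sorted(missing)}")
    return [
        SnpObservation(
            patient_id=str(row.patient_id),
            locus=SnpLocus(
                rsid=row.rsid,
                chrom=_norm_chrom(row.chrom),
                arm=row.arm,
                pos=int(row.pos),
            ),
            total_depth=int(row.total_depth),
            alt_depth=int(row.alt_depth),
        )
        for row in df.itertuples(index=False)
    ]


IMBALANCE_COLUMNS = [
    "patient_id", "chrom", "n_snps", "n_homozygous", "n_het", "n_deviant",
    "status", "p_arm_status", "q_arm_status",
]


def write_imbalance_tsv(calls: Iterable[ChromosomeImbalanceCall], path: str | Path) -> None:
    rows = [
        {
            "patient_id": c.patient_id, "chrom": c.chrom, "n_snps": c.n_snps,
            "n_homozygous": c.n_homozygous, "n_het": c.n_het,
            "n_deviant": c.n_deviant, "status": c.status.value,
            "p_arm_status": c.arm_status.get("p", ImbalanceStatus.NON_INFORMATIVE).value,
            "q_arm_status": c.arm_status.get("q", ImbalanceStatus.NON_INFORMATIVE).value,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=IMBALANCE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_imbalance_tsv(path: str | Path) -> dict[str, dict[str, ImbalanceStatus]]:
    """patient_id -> chrom -> status."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "patient_id": str})
    out: dict[str, dict[str, ImbalanceStatus]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.patient_id), {})[str(row.chrom)] = ImbalanceStatus(row.status)
    return out


def read_clinical(path: str | Path) -> dict[str, dict]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        raise ValueError(f"{path}: clinical table needs a patient_id column")
    return {
        str(row["patient_id"]): {k: v for k, v in row.items() if k != "patient_id"}
        for _, row in df.iterrows()
    }


def read_survival(path: str | Path) -> dict[str, SurvivalRecord]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "time_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing survival columns {sorted(missing)}")
    return {
        str(row.patient_id): SurvivalRecord(
            patient_id=str(row.patient_id),
            time=float(row.time_months),
            event=int(row.event),
        )
        for row in df.itertuples(index=False)
    }


def read_vcf(path: str | Path, patient_id: Optional[str] = None) -> list[VariantCall]:
    """Read small-variant calls from an (uncompressed) VCF 4.2 file.

    Depth comes from FORMAT/DP or INFO/DP; alt depth from FORMAT/AD
    (ref,alt), FORMAT/AO or INFO/AO.  Annotation keys GENE, CSQ, CLIN,
    HGVSP and PVAL are read from INFO when present.  A record missing a
    depth source raises a ``ValueError`` naming the key.
    """
    import pysam

    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        default_pid = patient_id or (samples[0] if samples else Path(path).stem)
        def safe_get(mapping, key):
            # pysam raises "Invalid header" for keys absent from the header
            if mapping is None:
                return None
            try:
                return mapping.get(key)
            except (KeyError, ValueError):
                return None

        for rec in vcf:
            sample = rec.samples[samples[0]] if samples else None
            dp = safe_get(sample, "DP")
            if dp is None:
                dp = safe_get(rec.info, "DP")
            if dp is None:
                raise ValueError(f"{path}: record {rec.chrom}:{rec.pos} lacks DP")
            dp = int(dp)
            ao = None
            ad = safe_get(sample, "AD")
            if ad is not None and len(ad) >= 2 and ad[1] is not None:
                ao = int(ad[1])
            if ao is None:
                raw = safe_get(sample, "AO")
                if raw is None:
                    raw = safe_get(rec.info, "AO")
                if raw is not None:
                    ao = int(raw[0] if isinstance(raw, tuple) else raw)
            if ao is None:
                raise ValueError(
                    f"{path}: record {rec.chrom}:{rec.pos} lacks AD/AO alt depth"
                )
            def info_get(key, default=None):
                # pysam raises on INFO keys absent from the header
                try:
                    value = rec.info.get(key, default)
                except (KeyError, ValueError):
                    return default
                return default if value is None else value
            calls.append(
                VariantCall(
                    patient_id=default_pid,
                    gene=str(info_get("GENE", "")),
                    chrom=_norm_chrom(rec.chrom),
                    pos=int(rec.pos),
                    ref=rec.ref,
                    alt=rec.alts[0] if rec.alts else "",
                    total_depth=dp,
                    alt_depth=ao,
                    qual=float(rec.qual) if rec.qual is not None else 0.0,
                    pvalue=float(info_get("PVAL", 1.0)),
                    consequence=str(info_get("CSQ", "OTHER")),
                    clin_class=str(info_get("CLIN", "NOVEL")),
                    hgvs_p=(str(info_get("HGVSP")) if info_get("HGVSP") else None),
                )
            )
    return calls


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path, artifacts: dict[str, str | Path], status: str = "complete",
    failed_stage: Optional[str] = None,
) -> Path:
    """Write a manifest JSON listing each artifact with its sha256."""
    out_dir = Path(out_dir)
    entries = {
        name: {"path": str(Path(p).name), "sha256": file_checksum(p)}
        for name, p in artifacts.items()
        if Path(p).exists()
    }
    manifest = {"status": status, "artifacts": entries}
    if failed_stage:
        manifest["failed_stage"] = failed_stage
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
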