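"""End-to-end orchestration: filter -> imbalance -> profile -> summarize
-> stratify -> survive, with a checksum manifest for reproducibility."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import io as uio
from .imbalance import BandConfig, call_patient_imbalances
from .panel_model import PanelDefinition, reference_panel
from .profiles import Scheme, build_profile, summarize_cohort
from .survival import compare_strata
from .variant_filtering import AnnotationTable, FilterConfig, apply_filter_chain, classify_variant

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    variants_path: Path
    snps_path: Path
    out_dir: Path
    clinical_path: Optional[Path] = None
    survival_path: Optional[Path] = None
    annotations_path: Optional[Path] = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    band_config: BandConfig = field(default_factory=BandConfig)
    min_informative: int = 2
    deviant_fraction: float = 0.5

    def __post_init__(self) -> None:
        self.variants_path = Path(self.variants_path)
        self.snps_path = Path(self.snps_path)
        self.out_dir = Path(self.out_dir)


def run_pipeline(cfg: RunConfig, panel: Optional[PanelDefinition] = None) -> Path:
    """Run every stage, writing one artifact per stage plus a manifest.

    Identical inputs and configuration produce identical checksums.  A
    stage failure raises :class:`PipelineError` after flagging the
    partially written manifest.
    """
    panel = panel or reference_panel()
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "filter"
    try:
        # --- filter ---
        if not cfg.variants_path.exists():
            raise PipelineError(stage, f"missing variants file {cfg.variants_path}")
        if cfg.variants_path.suffix == ".vcf":
            variants = uio.read_vcf(cfg.variants_path)
        else:
            variants = uio.read_variants_tsv(cfg.variants_path)
        if cfg.annotations_path:
            ann = AnnotationTable.from_tsv(cfg.annotations_path)
            for v in variants:
                v.clin_class = classify_variant(v, ann)
        kept, rejected = apply_filter_chain(variants, cfg.filter_config)
        logger.info("filter: %d in, %d kept, %d rejected", len(variants), len(kept), len(rejected))
        artifacts["filtered_variants"] = out / "filtered_variants.tsv"
        uio.write_variants_tsv(kept, artifacts["filtered_variants"])
        artifacts["rejected_variants"] = out / "rejected_variants.tsv"
        uio.write_rejections_tsv(rejected, artifacts["rejected_variants"])

        # --- imbalance ---
        stage = "imbalance"
        if not cfg.snps_path.exists():
            raise PipelineError(stage, f"missing SNP file {cfg.snps_path}")
        snps = uio.read_snps_tsv(cfg.snps_path)
        by_patient: dict[str, list] = {}
        for obs in snps:
            by_patient.setdefault(obs.patient_id, []).append(obs)
        imbalance_calls = {
            pid: call_patient_imbalances(
                obs_list, panel, cfg.band_config,
                cfg.min_informative, cfg.deviant_fraction,
            )
            for pid, obs_list in sorted(by_patient.items())
        }
        artifacts["imbalance_calls"] = out / "imbalance_calls.tsv"
        uio.write_imbalance_tsv(
            [c for calls in imbalance_calls.values() for c in calls.values()],
            artifacts["imbalance_calls"],
        )

        # --- profile ---
        stage = "profile"
        clinical = uio.read_clinical(cfg.clinical_path) if cfg.clinical_path else {}
        patient_ids = sorted(
            {v.patient_id for v in kept} | set(imbalance_calls) | set(clinical)
        )
        profiles = [
            build_profile(
                pid,
                [v for v in kept if v.patient_id == pid],
                imbalance_calls.get(pid, {}),
                clinical.get(pid),
            )
            for pid in patient_ids
        ]
        artifacts["profiles"] = out / "profiles.json"
        artifacts["profiles"].write_text(
            json.dumps(
                {
                    p.patient_id: {
                        "mutated_genes": sorted(p.mutated_genes),
                        "category_hits": {
                            cat.value: sorted(genes)
                            for cat, genes in sorted(p.category_hits.items(), key=lambda kv: kv[0].value)
                        },
                        "imbalances": {c: s.value for c, s in sorted(p.imbalances.items())},
                        "bap1_status": p.bap1_status,
                        "sex": p.sex,
                        "laterality": p.laterality,
                        "tumor_size_mm": p.tumor_size_mm,
                        "site": p.site,
                    }
                    for p in profiles
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )

        # --- summarize ---
        stage = "summarize"
        summary = summarize_cohort(profiles)
        lines = ["metric\tkey\tcount\tpercent"]
        for g in sorted(summary.gene_counts):
            lines.append(f"gene\t{g}\t{summary.gene_counts[g]}\t{summary.gene_pcts[g]}")
        for c in sorted(summary.imbalance_counts):
            lines.append(
                f"imbalance\tchr{c}\t{summary.imbalance_counts[c]}\t{summary.imbalance_pcts[c]}"
            )
        for (a, b), flag in summary.mutually_exclusive.items():
            lines.append(f"mutually_exclusive\t{a}/{b}\t{int(flag)}\t")
        artifacts["cohort_summary"] = out / "cohort_summary.tsv"
        artifacts["cohort_summary"].write_text("\n".join(lines) + "\n")

        # --- stratify + survive ---
        stage = "survive"
        if cfg.survival_path:
            survival = uio.read_survival(cfg.survival_path)
            report = {}
            for scheme in Scheme:
                cmp = compare_strata(profiles, survival, scheme)
                report[scheme.value] = {
                    "group_a": {"label": cmp.group_a.label.value, "n": len(cmp.group_a)},
                    "group_b": {"label": cmp.group_b.label.value, "n": len(cmp.group_b)},
                    "chi_square": cmp.chi_square,
                    "p_value": cmp.p_value,
                    "excluded": sorted(cmp.excluded),
                    "flags": cmp.flags,
                }
            artifacts["survival_comparisons"] = out / "survival_comparisons.json"
            artifacts["survival_comparisons"].write_text(
                json.dumps(report, indent=2, sort_keys=True) + "\n"
            )

        return uio.write_manifest(out, artifacts)
    except PipelineError:
        uio.write_manifest(out, artifacts, status="partial", failed_stage=stage)
        raise
    except Exception as exc:
        uio.write_manifest(out, artifacts, status="partial", failed_stage=stage)
        raise PipelineError(stage, str(exc)) from exc
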