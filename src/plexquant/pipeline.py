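"""End-to-end orchestration: quantify → QC → differential → pathway
statistics → summary artifacts.

A single :class:`RunConfig` (YAML file or constructed in code) drives the
whole run.  Every stage writes its table as TSV into the output directory
and the final machine-readable ``summary.json`` is *re-derived from those
TSVs* by :func:`summarize`, so no number in the summary exists that a user
could not recompute from the stage outputs.  A plain-text run log records
versions, thresholds and the tie rule — the gating parameters are exactly
the knobs reasonable analysts disagree about, so their provenance is
written down every run.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import design as dio
from .design import ValidationError
from .differential import (
    Thresholds,
    correlation_matrix,
    differential_table,
    heatmap_scale,
    significant_set,
    volcano_table,
)
from .pathways import (
    classify_functional,
    dysregulation_wide,
    enrichment_table,
    pathway_dysregulation,
    top_enriched,
)
from .quantify import merge_common, pooled_cv, relative_abundance

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths, thresholds and gate choices for one pipeline run."""

    design: str
    tables: list[str]
    gmt: str
    localization: str
    out_dir: str
    classes: str | None = None
    control: str = "DMSO"
    alpha: float = 0.05
    beta: float = 0.2
    fc_mode: str = "symmetric015"
    p_cutoff: float = 0.05
    counts_gate: str = "p_fc"  # gate for headline changed-protein counts
    pathway_gate: str = "power"  # gate feeding pathway statistics
    tie: str = "ge"
    cv_threshold_pct: float = 5.0
    volcano_floor_mito: float = 0.15
    volcano_floor_other: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"{path}: unknown config key(s) {sorted(unknown)}")
        missing = [
            k for k in ("design", "tables", "gmt", "localization", "out_dir")
            if k not in doc
        ]
        if missing:
            raise ValidationError(f"{path}: missing config key(s) {missing}")
        return cls(**doc)

    def thresholds(self) -> Thresholds:
        return Thresholds(
            alpha=self.alpha,
            beta=self.beta,
            fc_mode=self.fc_mode,
            p_cutoff=self.p_cutoff,
        )

    def validate_paths(self) -> None:
        paths = [self.design, *self.tables, self.gmt, self.localization]
        if self.classes:
            paths.append(self.classes)
        for p in paths:
            if not Path(p).exists():
                raise ValidationError(f"input path does not exist: {p}")


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g", na_rep="NA")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return the summary dict.

    Stage order: read/validate inputs → per-plex relative abundance →
    cross-plex merge → pooled-reference CV QC → differential table →
    mitochondrial split and correlations → heat-map / volcano exports →
    pathway dysregulation → enrichment (both backgrounds) → functional
    classes → summary.  Any stage error aborts with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return deco

    config.validate_paths()
    thr = config.thresholds()

    @stage("read_inputs")
    def inputs():
        designs = dio.read_design(config.design)
        if len(config.tables) != len(designs):
            raise ValidationError(
                f"{len(config.tables)} intensity table(s) for {len(designs)} plex(es)"
            )
        tables = [
            dio.read_intensity_table(p, d) for p, d in zip(config.tables, designs)
        ]
        pathways = dio.read_gmt(config.gmt)
        loc_map = dio.read_localization(config.localization)
        class_map = dio.read_class_map(config.classes) if config.classes else {}
        return designs, tables, pathways, loc_map, class_map

    designs, tables, pathway_sets, loc_map, class_map = inputs

    @stage("quantify")
    def merged():
        mats = [relative_abundance(t, d) for t, d in zip(tables, designs)]
        return merge_common(mats)

    loc = dio.apply_localization(merged.proteins, loc_map)
    merged.annotations["localization"] = loc

    @stage("cv_qc")
    def cv():
        return pooled_cv(merged, threshold_pct=config.cv_threshold_pct)

    @stage("differential")
    def diff():
        return differential_table(merged, config.control, thr)

    treatments = [g for g in merged.groups() if g != config.control]
    mito_set = set(loc[loc == dio.MITOCHONDRIAL].index)

    changed_counts = {t: significant_set(diff, t, config.counts_gate) for t in treatments}
    changed_power = {t: significant_set(diff, t, config.pathway_gate) for t in treatments}
    mito_changed_any = set().union(*changed_counts.values()) & mito_set
    nonmito_changed_any = set().union(*changed_counts.values()) - mito_set

    @stage("correlation")
    def correlations():
        out_c = {}
        for label, subset in (
            ("mito", mito_changed_any),
            ("nonmito", nonmito_changed_any),
        ):
            if len(subset) >= 3:
                out_c[label] = correlation_matrix(diff, subset)
            else:
                out_c[label] = pd.DataFrame(
                    np.nan, index=treatments, columns=treatments
                )
        return out_c

    @stage("exports")
    def exports():
        heat = heatmap_scale(merged, mito_changed_any) if mito_changed_any else pd.DataFrame()
        volc_m = volcano_table(
            diff[diff["protein"].isin(mito_set)], config.volcano_floor_mito
        )
        volc_n = volcano_table(
            diff[~diff["protein"].isin(mito_set)], config.volcano_floor_other
        )
        return heat, volc_m, volc_n

    heat, volc_m, volc_n = exports

    detected = set(merged.proteins)

    @stage("pathway_dysregulation")
    def dysreg():
        return pathway_dysregulation(pathway_sets, detected, changed_power, tie=config.tie)

    @stage("enrichment")
    def enrichment():
        global_bg = detected | set().union(*(p.members for p in pathway_sets))
        user = enrichment_table(pathway_sets, changed_power, detected, "user_dataset")
        glob = enrichment_table(pathway_sets, changed_power, global_bg, "global_annotation")
        return user, glob

    enr_user, enr_global = enrichment

    @stage("functional_classes")
    def classes():
        per_treatment = {t: changed_counts[t] & mito_set for t in treatments}
        return classify_functional(per_treatment, class_map)

    @stage("write_outputs")
    def write():
        merged_out = merged.annotations.join(merged.values)
        merged_out.insert(0, "accession", merged_out.index)
        _write_tsv(merged_out, out / "merged.tsv")
        ref_out = merged.reference_ratios.copy()
        ref_out.insert(0, "accession", ref_out.index)
        _write_tsv(ref_out, out / "reference_ratios.tsv")
        cv_out = cv.per_protein.copy()
        cv_out.insert(0, "accession", cv_out.index)
        _write_tsv(cv_out, out / "cv_report.tsv")
        counts = pd.DataFrame(
            {
                "metric": [
                    "n_total_detected",
                    "n_overlap",
                    "n_dropped_reference",
                    "n_samples",
                ],
                "value": [
                    merged.n_total_detected,
                    merged.n_detected,
                    merged.n_dropped_reference,
                    len(merged.samples),
                ],
            }
        )
        _write_tsv(counts, out / "counts.tsv")
        _write_tsv(diff, out / "differential.tsv")
        _write_tsv(correlations["mito"], out / "correlation_mito.tsv", index=True)
        _write_tsv(correlations["nonmito"], out / "correlation_nonmito.tsv", index=True)
        if not heat.empty:
            h = heat.copy()
            h.insert(0, "accession", h.index)
            _write_tsv(h, out / "heatmap_mito.tsv")
        _write_tsv(volc_m, out / "volcano_mito.tsv")
        _write_tsv(volc_n, out / "volcano_nonmito.tsv")
        _write_tsv(dysregulation_wide(dysreg), out / "pathway_dysregulation.tsv")
        _write_tsv(enr_user, out / "enrichment_user.tsv")
        _write_tsv(enr_global, out / "enrichment_global.tsv")
        _write_tsv(classes, out / "functional_classes.tsv")

    @stage("run_log")
    def log():
        lines = [
            f"plexquant {__version__}",
            f"python {sys.version.split()[0]}  numpy {np.__version__}  pandas {pd.__version__}",
            "",
            "configuration:",
        ]
        for k, v in asdict(config).items():
            lines.append(f"  {k}: {v}")
        lines += [
            "",
            f"thresholds: alpha={thr.alpha} beta={thr.beta} "
            f"power_cutoff={thr.power_cutoff} p_cutoff={thr.p_cutoff} "
            f"fc_bounds={thr.fc_bounds} (fc_mode={thr.fc_mode})",
            f"tie rule for dysregulation flags: {config.tie} "
            "(percent_change vs percent_coverage)",
            f"gates: counts={config.counts_gate}, pathways={config.pathway_gate}",
            f"seed: {config.seed}",
        ]
        (out / "run_log.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")

    summary = summarize(out)
    logger.info("pipeline complete; outputs in %s", out)
    return summary


def summarize(out_dir: str | Path) -> dict:
    """Build (and write) ``summary.json`` from the stage TSVs.

    Reads only the pipeline's own output tables, so every headline number
    is re-derivable — and re-running is idempotent.
    """
    out = Path(out_dir)
    for fname in ("counts.tsv", "differential.tsv", "merged.tsv", "cv_report.tsv"):
        if not (out / fname).exists():
            raise ValidationError(f"summarize: missing output file {out / fname}")
    counts = pd.read_csv(out / "counts.tsv", sep="\t").set_index("metric")["value"]
    diff = pd.read_csv(out / "differential.tsv", sep="\t")
    merged = pd.read_csv(out / "merged.tsv", sep="\t")
    cv = pd.read_csv(out / "cv_report.tsv", sep="\t")
    dysreg = pd.read_csv(out / "pathway_dysregulation.tsv", sep="\t")
    enr_user = pd.read_csv(out / "enrichment_user.tsv", sep="\t")
    enr_global = pd.read_csv(out / "enrichment_global.tsv", sep="\t")

    mito = set(merged.loc[merged["localization"] == dio.MITOCHONDRIAL, "accession"])
    n_overlap = int(counts["n_overlap"])
    treatments = list(dict.fromkeys(diff["treatment"]))

    per_treatment = {}
    changed_any: set[str] = set()
    for t in treatments:
        sub = diff[diff["treatment"] == t]
        ch = set(sub.loc[sub["pass_p"] & sub["pass_fc"], "protein"])
        changed_any |= ch
        flags = dysreg[f"flag_{t}"] if f"flag_{t}" in dysreg.columns else pd.Series(dtype=bool)
        per_treatment[t] = {
            "n_changed": len(ch),
            "frac_changed": len(ch) / n_overlap if n_overlap else float("nan"),
            "n_changed_mito": len(ch & mito),
            "n_changed_nonmito": len(ch - mito),
            "n_power_gate": int(sub["pass_power"].sum()),
            "n_flagged_pathways": int(flags.sum()),
            "flagged_pathways": sorted(
                dysreg.loc[flags.astype(bool), "pathway_id"].tolist()
            ) if len(flags) else [],
        }

    summary = {
        "plexquant_version": __version__,
        "n_total_detected": int(counts["n_total_detected"]),
        "n_overlap": n_overlap,
        "n_dropped_reference": int(counts["n_dropped_reference"]),
        "n_samples": int(counts["n_samples"]),
        "cv": {
            "median_cv_combined_pct": float(cv["cv_combined"].median()),
            "frac_below_5pct": float((cv["cv_combined"] < 5.0).mean()),
        },
        "n_changed_any": len(changed_any),
        "n_changed_any_mito": len(changed_any & mito),
        "n_changed_any_nonmito": len(changed_any - mito),
        "per_treatment": per_treatment,
        "top_enrichment": {
            "user_dataset": top_enriched(enr_user),
            "global_annotation": top_enriched(enr_global),
        },
    }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary
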