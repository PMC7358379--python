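"""Pooled-reference relative quantification and cross-plex merging.

Each protein's relative abundance in a sample is its summed reporter-ion
intensity divided by the plex's pooled-reference abundance (the arithmetic
mean of that plex's pooled channels).  Because the pooled reference is the
same mixture in every plex, the ratio cancels plex-level batch scale — the
bridging property that makes merging two plexes into one matrix valid.

The merged "user dataset" keeps only proteins quantified in every sample
of every plex (complete cases), mirroring the overlap set a multi-batch
study reports.  Pooled-channel ratios are retained for the CV-based
reproducibility QC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import PlexDesign, ReporterIntensityTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RelativeAbundanceMatrix:
    """Protein × sample ratios to the pooled reference.

    ``values``: DataFrame indexed by accession, one column per sample_id,
    strictly positive where present (NaN = missing before merge).
    ``samples``: per-sample metadata (sample_id, plex_id, group, replicate).
    ``reference_ratios``: retained per-plex pooled-channel ratios
    (columns named ``plex_id/channel``) for QC.
    ``n_detected``: proteins detected (quantifiable) before any merging.
    ``n_dropped_reference``: proteins dropped for missing/zero reference.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    reference_ratios: pd.DataFrame
    annotations: pd.DataFrame
    n_detected: int
    n_dropped_reference: int = 0
    n_total_detected: int | None = None

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    def sample_ids(self, group: str | None = None) -> list[str]:
        df = self.samples
        if group is not None:
            df = df[df["group"] == group]
        return df["sample_id"].tolist()

    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.samples["group"]))


@dataclass
class CVReport:
    """Per-protein coefficient of variation of pooled-reference ratios.

    CV = sample standard deviation / mean (unitless), reported in percent,
    computed across pooled-channel ratio columns — combined across plexes
    and, where a plex contributes at least two pooled channels, per plex.
    """

    per_protein: pd.DataFrame  # columns: cv_combined + cv_<plex_id>...
    summary: dict[str, float]  # fraction of proteins with CV < 5%, median CV


def relative_abundance(
    table: ReporterIntensityTable, design: PlexDesign
) -> RelativeAbundanceMatrix:
    """Convert one plex's reporter intensities to ratios vs the pooled reference.

    The per-protein reference abundance is the arithmetic mean of the
    plex's pooled-reference channel intensities (over the channels present
    for that protein).  Proteins whose reference is entirely missing or
    zero are dropped and counted.  Individual pooled-channel ratios are
    retained in ``reference_ratios``.
    """
    table.validate(design)
    ref_cols = design.reference_channels
    ref = table.data[ref_cols].mean(axis=1, skipna=True)
    quantifiable = ref.notna() & (ref > 0)
    n_dropped = int((~quantifiable).sum())
    if quantifiable.sum() == 0:
        raise ValidationError(
            f"plex {design.plex_id!r}: no quantifiable proteins "
            "(all reference channels zero or missing)"
        )
    if n_dropped:
        logger.info(
            "plex %s: dropped %d protein(s) with missing/zero reference",
            design.plex_id,
            n_dropped,
        )
    data = table.data.loc[quantifiable]
    ref = ref.loc[quantifiable]

    sample_chs = design.sample_channels
    values = data[[ch.channel for ch in sample_chs]].div(ref, axis=0)
    values.columns = [ch.sample_id for ch in sample_chs]
    reference_ratios = data[ref_cols].div(ref, axis=0)
    reference_ratios.columns = [f"{design.plex_id}/{c}" for c in ref_cols]

    samples = pd.DataFrame(
        {
            "sample_id": [ch.sample_id for ch in sample_chs],
            "plex_id": design.plex_id,
            "group": [ch.group for ch in sample_chs],
            "replicate": [ch.replicate for ch in sample_chs],
        }
    )
    return RelativeAbundanceMatrix(
        values=values,
        samples=samples,
        reference_ratios=reference_ratios,
        annotations=table.annotations.loc[quantifiable].copy(),
        n_detected=int(quantifiable.sum()),
        n_dropped_reference=n_dropped,
    )


def merge_common(
    matrices: list[RelativeAbundanceMatrix],
) -> RelativeAbundanceMatrix:
    """Merge per-plex matrices on their commonly-quantified protein set.

    Only proteins with a present (non-missing) ratio in every sample of
    every plex are retained; columns are concatenated.  The result carries
    both the total number of distinct proteins detected anywhere
    (``n_total_detected``) and the overlap count (``n_detected``).
    """
    if not matrices:
        raise ValidationError("merge_common: no matrices given")
    all_samples = pd.concat([m.samples for m in matrices], ignore_index=True)
    if all_samples["sample_id"].duplicated().any():
        raise ValidationError("merge_common: sample_ids not disjoint across plexes")

    common = matrices[0].values.dropna().index
    union: set[str] = set()
    for m in matrices:
        complete = m.values.dropna().index
        common = common.intersection(complete)
        union |= set(m.proteins)
    if len(common) == 0:
        raise ValidationError(
            "merge_common: no protein is quantified in every sample of every "
            "plex; inspect per-plex missingness"
        )
    common = matrices[0].values.dropna().index
    for m in matrices[1:]:
        common = common.intersection(m.values.dropna().index)
    # preserve first-matrix protein order
    common = [p for p in matrices[0].proteins if p in set(common)]

    values = pd.concat([m.values.loc[common] for m in matrices], axis=1)
    reference_ratios = pd.concat(
        [m.reference_ratios.reindex(common) for m in matrices], axis=1
    )
    annotations = matrices[0].annotations.reindex(common)
    for m in matrices[1:]:
        annotations = annotations.combine_first(m.annotations.reindex(common))
    logger.info(
        "merged %d plex(es): %d proteins detected in total, %d overlap",
        len(matrices),
        len(union),
        len(common),
    )
    return RelativeAbundanceMatrix(
        values=values,
        samples=all_samples,
        reference_ratios=reference_ratios,
        annotations=annotations,
        n_detected=len(common),
        n_dropped_reference=sum(m.n_dropped_reference for m in matrices),
        n_total_detected=len(union),
    )


def pooled_cv(merged: RelativeAbundanceMatrix, threshold_pct: float = 5.0) -> CVReport:
    """Reproducibility QC: CV of each protein's pooled-channel ratios.

    Uses the sample standard deviation (n−1 denominator) over all retained
    pooled-reference ratio columns, expressed in percent.  Requires at
    least two pooled columns overall; per-plex CVs are reported for plexes
    contributing at least two pooled channels.
    """
    ref = merged.reference_ratios
    if ref.shape[1] < 2:
        raise ValidationError(
            f"pooled_cv: need at least 2 pooled-reference columns, have {ref.shape[1]}"
        )

    def _cv(df: pd.DataFrame) -> pd.Series:
        return 100.0 * df.std(axis=1, ddof=1) / df.mean(axis=1)

    per = pd.DataFrame({"cv_combined": _cv(ref)})
    plexes = sorted({c.split("/", 1)[0] for c in ref.columns})
    for plex in plexes:
        cols = [c for c in ref.columns if c.split("/", 1)[0] == plex]
        if len(cols) >= 2:
            per[f"cv_{plex}"] = _cv(ref[cols])

    summary: dict[str, float] = {
        "median_cv_combined_pct": float(per["cv_combined"].median()),
        "frac_below_threshold_combined": float(
            (per["cv_combined"] < threshold_pct).mean()
        ),
        "threshold_pct": threshold_pct,
    }
    for col in per.columns:
        if col == "cv_combined":
            continue
        summary[f"frac_below_threshold_{col[3:]}"] = float(
            (per[col] < threshold_pct).mean()
        )
    logger.info(
        "pooled CV: median %.2f%%, %.1f%% of proteins below %.0f%%",
        summary["median_cv_combined_pct"],
        100 * summary["frac_below_threshold_combined"],
        threshold_pct,
    )
    return CVReport(per_protein=per, summary=summary)
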