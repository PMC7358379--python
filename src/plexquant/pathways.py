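"""Pathway-level statistics: coverage-vs-change dysregulation, Fisher
enrichment, and the mitochondrial functional-class breakdown.

The central statistic compares, for each pathway,

* **percent coverage** — detected members among all annotated members of
  the pathway, 100·n_detected/n_annotated; a property of the dataset, the
  same for every treatment; and
* **percent change** — significantly changed members among detected
  members under one treatment, 100·n_changed/n_detected.

A pathway is flagged *treatment-specific* for a treatment when its percent
change meets or exceeds its percent coverage (ties flag true by default; a
strict ``gt`` rule is available).  The intuition: coverage is the share of
the pathway the instrument could see at all, so a treatment that perturbs
at least that share of what was seen stands out against detection depth.

Enrichment uses the right-tailed hypergeometric (Fisher exact) test with a
selectable background: the full annotation universe, or the user dataset
of commonly-detected proteins (which removes detection bias).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .design import PathwayAnnotation, ValidationError

logger = logging.getLogger(__name__)

#: functional classes used for the mitochondrial breakdown
FUNCTIONAL_CLASSES = (
    "OXPHOS",
    "TCA cycle",
    "lipid metabolism",
    "redox",
    "transport",
    "cell death/defense",
    "signaling",
    "protease",
    "protein targeting",
    "RNA/DNA/protein synthesis",
    "nucleotide metabolism",
    "carbohydrate metabolism",
)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class EnrichmentResult:
    """Right-tailed hypergeometric over-representation result.

    k changed members in the pathway, out of K pathway members in the
    background, with n changed overall drawn from a background of size N.
    """

    pathway_id: str
    background_mode: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    overlap: frozenset[str]


def pathway_dysregulation(
    pathways: Iterable[PathwayAnnotation],
    detected: set[str],
    changed_by_treatment: Mapping[str, set[str]],
    tie: str = "ge",
) -> pd.DataFrame:
    """Coverage-vs-change statistic for every (pathway, treatment) pair.

    Returns a tidy frame with one row per pathway per treatment:
    pathway_id, n_annotated, n_detected, percent_coverage, treatment,
    n_changed, percent_change, flag.  Pathways with no detected member get
    percent_coverage 0, undefined (NaN) percent_change and no flag.
    Changed sets are intersected with the detected set, so proteins
    outside it cannot influence the statistic.
    """
    if tie not in ("ge", "gt"):
        raise ValueError(f"tie rule must be 'ge' or 'gt', got {tie!r}")
    detected = set(detected)
    for t, s in changed_by_treatment.items():
        extra = set(s) - detected
        if extra:
            logger.warning(
                "treatment %s: %d changed protein(s) outside the detected set "
                "are ignored",
                t,
                len(extra),
            )
    rows = []
    n_degenerate = 0
    for pw in pathways:
        members_detected = pw.members & detected
        n_annot = len(pw.members)
        n_det = len(members_detected)
        coverage = 100.0 * n_det / n_annot
        if n_det == 0:
            n_degenerate += 1
        for treatment, changed in changed_by_treatment.items():
            n_changed = len(members_detected & set(changed))
            if n_det == 0:
                change = float("nan")
                flag = False
            else:
                change = 100.0 * n_changed / n_det
                flag = change >= coverage if tie == "ge" else change > coverage
            rows.append(
                (pw.pathway_id, n_annot, n_det, coverage, treatment, n_changed, change, flag)
            )
    if n_degenerate:
        logger.info(
            "%d pathway(s) with no detected member (coverage 0, no flags)",
            n_degenerate,
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pathway_id",
            "n_annotated",
            "n_detected",
            "percent_coverage",
            "treatment",
            "n_changed",
            "percent_change",
            "flag",
        ],
    )


def dysregulation_wide(tidy: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy dysregulation frame to one row per pathway
    (coverage plus per-treatment change/flag columns)."""
    base = tidy.drop_duplicates("pathway_id").set_index("pathway_id")[
        ["n_annotated", "n_detected", "percent_coverage"]
    ]
    for treatment, sub in tidy.groupby("treatment", sort=False):
        sub = sub.set_index("pathway_id")
        base[f"n_changed_{treatment}"] = sub["n_changed"]
        base[f"percent_change_{treatment}"] = sub["percent_change"]
        base[f"flag_{treatment}"] = sub["flag"]
    return base.reset_index()


def fisher_enrichment(
    pathway: PathwayAnnotation,
    changed: set[str],
    background: set[str],
    mode: str = "user_dataset",
) -> EnrichmentResult:
    """Right-tailed hypergeometric p-value P(X ≥ k) for one pathway.

    ``background`` defines the sampling universe N; pathway members are
    intersected with it to give K, and ``changed`` must be a subset of the
    background (n = |changed|).  ``mode`` records which background
    convention produced the numbers (``user_dataset`` = commonly-detected
    proteins; ``global_annotation`` = full annotation universe).
    """
    background = set(background)
    if not background:
        raise ValidationError("fisher_enrichment: empty background")
    changed = set(changed)
    if not changed <= background:
        raise ValidationError(
            "fisher_enrichment: changed set is not a subset of the background"
        )
    members = pathway.members & background
    overlap = members & changed
    k, K, n, N = len(overlap), len(members), len(changed), len(background)
    # P(X >= k); sf(k-1) is the right tail including k
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(
        pathway_id=pathway.pathway_id,
        background_mode=mode,
        k=k,
        K=K,
        n=n,
        N=N,
        p_value=p,
        overlap=frozenset(overlap),
    )


def enrichment_table(
    pathways: Iterable[PathwayAnnotation],
    changed_by_treatment: Mapping[str, set[str]],
    background: set[str],
    mode: str = "user_dataset",
) -> pd.DataFrame:
    """Enrichment of every (pathway, treatment) pair against one background.

    Changed sets are intersected with the background first (a changed
    protein outside the chosen universe cannot count as drawn from it).
    """
    background = set(background)
    rows = []
    for treatment, changed in changed_by_treatment.items():
        ch = set(changed) & background
        for pw in pathways:
            res = fisher_enrichment(pw, ch, background, mode)
            rows.append(
                (
                    treatment,
                    res.pathway_id,
                    res.background_mode,
                    res.k,
                    res.K,
                    res.n,
                    res.N,
                    res.p_value,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["treatment", "pathway_id", "background_mode", "k", "K", "n", "N", "p_value"],
    )


def top_enriched(table: pd.DataFrame, n_top: int = 5) -> dict[str, list[dict]]:
    """Top-``n_top`` pathways per treatment, ascending p-value."""
    out: dict[str, list[dict]] = {}
    for treatment, sub in table.groupby("treatment", sort=False):
        top = sub.sort_values(["p_value", "pathway_id"]).head(n_top)
        out[str(treatment)] = [
            {"pathway_id": r.pathway_id, "p_value": float(r.p_value), "k": int(r.k)}
            for r in top.itertuples()
        ]
    return out


def classify_functional(
    changed_by_treatment: Mapping[str, set[str]],
    class_map: Mapping[str, str],
) -> pd.DataFrame:
    """Functional-class counts of changed (mitochondrial) proteins.

    Each protein belongs to exactly one class; unmapped proteins fall into
    ``unassigned`` with a logged count.  Returns one row per class with an
    ``all`` column (union over treatments) plus one column per treatment.
    """
    union: set[str] = set()
    for s in changed_by_treatment.values():
        union |= set(s)
    unmapped = {p for p in union if p not in class_map}
    if unmapped:
        logger.warning(
            "%d changed protein(s) without functional class; counted as %r",
            len(unmapped),
            UNASSIGNED,
        )
    classes = list(FUNCTIONAL_CLASSES) + [UNASSIGNED]

    def _counts(proteins: set[str]) -> dict[str, int]:
        c = dict.fromkeys(classes, 0)
        for p in proteins:
            cls = class_map.get(p, UNASSIGNED)
            if cls not in c:
                c[cls] = 0  # tolerate classes beyond the standard list
            c[cls] += 1
        return c

    data = {"all": _counts(union)}
    for treatment, proteins in changed_by_treatment.items():
        data[treatment] = _counts(set(proteins) & union)
    out = pd.DataFrame(data).fillna(0).astype(int)
    out.index.name = "functional_class"
    return out.reset_index()
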