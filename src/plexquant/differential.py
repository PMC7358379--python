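"""Per-protein differential statistics against the vehicle control.

For each protein and each treatment the pipeline computes the ratio of
group means (treatment / control, on relative abundances), a two-sided
pooled-variance Student t-test p-value, and the post-hoc power of that
test at the observed effect size (Cohen's d, noncentral-t formula).  Two
significance gates are exposed because small-replicate designs use them
for different purposes:

* the *p-gate* (p < 0.05) crossed with a fold-change bound, used for
  headline changed-protein counts;
* the *power-gate* (power > 0.8, i.e. β < 0.2), used to feed pathway-level
  statistics where both error types matter.

Tests operate on natural-scale ratios by default, matching threshold
conventions of 1.15 / 0.85; a log2 transform is available via
``Thresholds.log_transform`` for users who prefer it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import ValidationError
from .quantify import RelativeAbundanceMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """Significance and fold-change gating configuration.

    ``fc_mode`` selects the fold-change bounds: ``symmetric015`` flags
    ratios > 1.15 or < 0.85 (a symmetric 0.15-fold change), ``ipa`` flags
    ratios > 1.15 or < 0.8 (the asymmetric variant used for
    enrichment-style uploads).
    """

    alpha: float = 0.05
    beta: float = 0.2
    fc_mode: str = "symmetric015"
    p_cutoff: float = 0.05
    log_transform: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0 < self.beta < 1:
            raise ValueError(f"beta must be in (0,1), got {self.beta}")
        if self.fc_mode not in ("symmetric015", "ipa"):
            raise ValueError(f"unknown fc_mode {self.fc_mode!r}")

    @property
    def power_cutoff(self) -> float:
        return 1.0 - self.beta

    @property
    def fc_bounds(self) -> tuple[float, float]:
        """(lower, upper) ratio bounds; outside either bound passes."""
        return (0.85, 1.15) if self.fc_mode == "symmetric015" else (0.8, 1.15)


# ---------------------------------------------------------------------------
# elementary statistics


def student_ttest(x, y) -> float:
    """Two-sided pooled-variance (Student) two-sample t-test p-value.

    Degenerate zero-variance input yields p = 1 when the means are equal
    and p = 0 (logged) when they differ, rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("student_ttest: need at least 2 values per group")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("student_ttest: non-finite input")
    p = _ttest_p(x[None, :], y[None, :])[0]
    return float(p)


def _pooled_sd(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    n1, n2 = x.shape[1], y.shape[1]
    ss = (x.var(axis=1, ddof=1) * (n1 - 1)) + (y.var(axis=1, ddof=1) * (n2 - 1))
    return np.sqrt(ss / (n1 + n2 - 2))


def _ttest_p(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorised pooled t-test over rows with zero-variance edge handling."""
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(x, y, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    sp = _pooled_sd(x, y)
    degen = sp == 0
    if degen.any():
        equal = np.isclose(x.mean(axis=1), y.mean(axis=1))
        p = np.where(degen & equal, 1.0, p)
        p = np.where(degen & ~equal, 0.0, p)
        n_sep = int((degen & ~equal).sum())
        if n_sep:
            logger.warning(
                "%d test(s) with zero pooled variance but unequal means; p set to 0",
                n_sep,
            )
    return p


def power_from_d(
    d: float | np.ndarray, n1: int, n2: int, alpha: float = 0.05
) -> float | np.ndarray:
    """Power of the two-sided two-sample t-test at effect size ``d``.

    Uses the noncentral t distribution: with noncentrality
    δ = d·sqrt(n1·n2/(n1+n2)) and df = n1+n2−2, power = P(|T| > t_crit).
    At d = 0 this reduces exactly to the test size α.
    """
    d = np.abs(np.asarray(d, dtype=float))
    df = n1 + n2 - 2
    delta = d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    upper = stats.nct.sf(tcrit, df, delta)
    # the opposite-sign tail; scipy's nct.cdf can return NaN at large
    # noncentrality, where this term is vanishingly small anyway
    lower = stats.nct.cdf(-tcrit, df, delta)
    lower = np.where(np.isnan(lower), 0.0, lower)
    power = np.clip(upper + lower, 0.0, 1.0)
    return power if power.ndim else float(power)


def posthoc_power(x, y, alpha: float = 0.05) -> float:
    """Post-hoc power at the observed Cohen's d of two replicate groups.

    With zero pooled sd, power is defined as 1 when the means differ and
    α when they are equal (logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("posthoc_power: need at least 2 values per group")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("posthoc_power: non-finite input")
    return float(
        _power_rows(x[None, :], y[None, :], alpha)[0]
    )


def _power_rows(x: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    sp = _pooled_sd(x, y)
    diff = np.abs(x.mean(axis=1) - y.mean(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(sp > 0, diff / np.where(sp > 0, sp, 1.0), 0.0)
    power = np.asarray(power_from_d(d, x.shape[1], y.shape[1], alpha))
    degen = sp == 0
    if degen.any():
        equal = np.isclose(x.mean(axis=1), y.mean(axis=1))
        power = np.where(degen & equal, alpha, power)
        power = np.where(degen & ~equal, 1.0, power)
        n_sep = int((degen & ~equal).sum())
        if n_sep:
            logger.warning(
                "%d power computation(s) with zero pooled sd but unequal "
                "means; power set to 1",
                n_sep,
            )
    return power


# ---------------------------------------------------------------------------
# tables


def differential_table(
    merged: RelativeAbundanceMatrix,
    control: str,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """One record per (protein, non-control group) with all gate flags.

    Columns: protein, treatment, ratio, p_value, power, pass_power,
    pass_p, pass_fc, direction, degenerate.  ``ratio`` is
    mean(treatment replicate ratios) / mean(control replicate ratios).
    Zero-variance (degenerate) proteins keep their edge-case p/power
    values but are excluded from all gates.
    """
    thr = thresholds or Thresholds()
    groups = merged.groups()
    if control not in groups:
        raise ValidationError(f"control group {control!r} not in matrix")
    for g in groups:
        n = len(merged.sample_ids(g))
        if n < 2:
            raise ValidationError(
                f"group {g!r} has only {n} replicate; at least 2 required"
            )

    yc = merged.values[merged.sample_ids(control)].to_numpy(dtype=float)
    lo, hi = thr.fc_bounds
    records = []
    for g in groups:
        if g == control:
            continue
        x = merged.values[merged.sample_ids(g)].to_numpy(dtype=float)
        ratio = x.mean(axis=1) / yc.mean(axis=1)
        if thr.log_transform:
            xt, yt = np.log2(x), np.log2(yc)
        else:
            xt, yt = x, yc
        p = _ttest_p(xt, yt)
        power = _power_rows(xt, yt, thr.alpha)
        degen = _pooled_sd(xt, yt) == 0
        df = pd.DataFrame(
            {
                "protein": merged.proteins,
                "treatment": g,
                "ratio": ratio,
                "p_value": p,
                "power": power,
                "degenerate": degen,
            }
        )
        df["pass_power"] = (df["power"] > thr.power_cutoff) & ~degen
        df["pass_p"] = (df["p_value"] < thr.p_cutoff) & ~degen
        df["pass_fc"] = (df["ratio"] > hi) | (df["ratio"] < lo)
        df["direction"] = np.where(df["ratio"] >= 1.0, "up", "down")
        records.append(df)
    out = pd.concat(records, ignore_index=True)
    return out


def significant_set(
    table: pd.DataFrame, treatment: str, gate: str = "p_fc"
) -> set[str]:
    """Proteins passing a named gate for one treatment.

    Gates: ``p`` (p-value only), ``power`` (power only), ``p_fc``
    (p-value and fold change), ``power_fc`` (power and fold change).
    """
    sub = table[table["treatment"] == treatment]
    masks = {
        "p": sub["pass_p"],
        "power": sub["pass_power"],
        "p_fc": sub["pass_p"] & sub["pass_fc"],
        "power_fc": sub["pass_power"] & sub["pass_fc"],
    }
    if gate not in masks:
        raise ValueError(f"unknown gate {gate!r}; one of {sorted(masks)}")
    return set(sub.loc[masks[gate], "protein"])


def treatment_correlation(
    table: pd.DataFrame, subset: set[str], a: str, b: str
) -> float:
    """Pearson correlation of two treatments' ratio vectors over ``subset``.

    Returns NaN when either vector has zero variance.
    """
    subset = set(subset)
    if len(subset) < 3:
        raise ValidationError(
            f"treatment_correlation: need at least 3 proteins, got {len(subset)}"
        )
    pivot = (
        table[table["protein"].isin(subset)]
        .pivot(index="protein", columns="treatment", values="ratio")
    )
    for g in (a, b):
        if g not in pivot.columns:
            raise ValidationError(f"treatment {g!r} not present in table")
    va, vb = pivot[a].to_numpy(), pivot[b].to_numpy()
    if np.std(va) == 0 or np.std(vb) == 0:
        return float("nan")
    return float(np.corrcoef(va, vb)[0, 1])


def correlation_matrix(table: pd.DataFrame, subset: set[str]) -> pd.DataFrame:
    """Pairwise Pearson correlations of treatment ratio profiles."""
    treatments = list(dict.fromkeys(table["treatment"]))
    out = pd.DataFrame(
        np.eye(len(treatments)), index=treatments, columns=treatments
    )
    for i, a in enumerate(treatments):
        for b in treatments[i + 1 :]:
            r = treatment_correlation(table, subset, a, b)
            out.loc[a, b] = out.loc[b, a] = r
    return out


def heatmap_scale(
    merged: RelativeAbundanceMatrix, subset: set[str] | None = None
) -> pd.DataFrame:
    """Scale each protein row so the highest-expressing sample equals 1."""
    values = merged.values
    if subset is not None:
        missing = set(subset) - set(values.index)
        if missing:
            raise ValidationError(
                f"heatmap_scale: proteins not in matrix: {sorted(missing)[:5]}"
            )
        values = values.loc[[p for p in values.index if p in set(subset)]]
    return values.div(values.max(axis=1), axis=0)


def volcano_table(table: pd.DataFrame, fc_floor: float = 0.15) -> pd.DataFrame:
    """Volcano-plot data: significant records with log2 ratio and −log10 p.

    Keeps records with p < 0.05 and |ratio − 1| ≥ ``fc_floor`` (0.15 for
    the mitochondrial view, 0.5 for the top non-mitochondrial view).  The
    conventional significance line sits at −log10 p = 1.3.
    """
    if fc_floor < 0:
        raise ValueError("fc_floor must be non-negative")
    keep = (table["p_value"] < 0.05) & (
        (table["ratio"] >= 1 + fc_floor) | (table["ratio"] <= 1 - fc_floor)
    )
    out = table.loc[keep, ["protein", "treatment", "ratio", "p_value"]].copy()
    with np.errstate(divide="ignore"):
        out["log2_ratio"] = np.log2(out["ratio"])
        out["neg_log10_p"] = -np.log10(out["p_value"])
    return out.reset_index(drop=True)
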