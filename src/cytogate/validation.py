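"""Method-comparison statistics for automated vs. manual gating.

The battery used to decide whether an automated gating template can
replace a manual gold standard for a given population: Pearson
correlation with Fisher-z confidence interval, percent bias with a
bootstrap interval, signed/absolute mean difference, event-level
F-measure of membership agreement, a 3-SD outlier-removal sensitivity
analysis, the strict r > 0.75 template-optimization gate, and inter- vs
intra-technician variance components (with their intraclass
correlation) from a REML linear mixed model on replicated controls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class StatError(ValueError):
    pass


def _paired(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, pd.DataFrame):
        a = pairs.iloc[:, -2].to_numpy(dtype=float)
        b = pairs.iloc[:, -1].to_numpy(dtype=float)
    else:
        arr = np.asarray(pairs, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise StatError("pairs must be an (n, 2) array or a DataFrame")
        a, b = arr[:, 0], arr[:, 1]
    if a.shape != b.shape:
        raise StatError("paired columns differ in length")
    return a, b


def pearson_ci(pairs, conf: float = 0.95) -> tuple[float, float, float]:
    """Sample Pearson r with a Fisher-z confidence interval.

    The interval uses z = atanh(r), SE = 1/sqrt(n-3).  Requires n >= 4
    and non-constant columns.
    """
    a, b = _paired(pairs)
    n = a.size
    if n < 4:
        raise StatError(f"need at least 4 pairs for a correlation CI, got {n}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise StatError("correlation undefined: a column is constant")
    r = float(stats.pearsonr(a, b).statistic)
    if abs(r) >= 1.0:
        return r, r, r
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + conf / 2) / np.sqrt(n - 3)
    return r, float(np.tanh(z - half)), float(np.tanh(z + half))


def percent_bias(pairs, n_boot: int = 2000, seed: int = 0,
                 per_sample: bool = False) -> tuple[float, float, float]:
    """Percent bias of the automated method relative to the manual one.

    ``pairs`` columns are (automated, manual).  Default definition is
    the ratio of means, 100 * (mean(auto) - mean(manual)) / mean(manual);
    positive values mean the automated analysis over-calls.  With
    ``per_sample=True`` the mean of per-sample relative differences is
    used instead (rows with manual == 0 excluded).  The 95% interval is
    a nonparametric bootstrap over paired rows (2000 resamples, seeded).
    """
    a, b = _paired(pairs)

    def bias_of(aa, bb):
        if per_sample:
            ok = bb != 0
            if not ok.any():
                return np.nan
            return 100.0 * float(np.mean((aa[ok] - bb[ok]) / bb[ok]))
        mb = float(np.mean(bb))
        if mb == 0:
            return np.nan
        return 100.0 * (float(np.mean(aa)) - mb) / mb

    est = bias_of(a, b)
    if np.isnan(est):
        raise StatError("percent bias undefined: manual mean is zero")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, a.size, size=(n_boot, a.size))
    boot = np.array([bias_of(a[i], b[i]) for i in idx])
    boot = boot[~np.isnan(boot)]
    lo, hi = np.percentile(boot, [2.5, 97.5]) if boot.size else (est, est)
    return est, float(lo), float(hi)


def absolute_difference(pairs) -> tuple[float, float]:
    """Mean signed difference and mean absolute difference (input units)."""
    a, b = _paired(pairs)
    if a.size < 1:
        raise StatError("need at least one pair")
    d = a - b
    return float(np.mean(d)), float(np.mean(np.abs(d)))


def f_measure(membership_a: np.ndarray, membership_b: np.ndarray) -> float:
    """Event-level F-measure of two population masks, B being the truth.

    F = 2TP / (2TP + FP + FN), the harmonic mean of precision and
    recall over event membership agreement.  Both masks empty is taken
    as perfect agreement (F = 1, logged).
    """
    a = np.asarray(membership_a, dtype=bool)
    b = np.asarray(membership_b, dtype=bool)
    if a.shape != b.shape:
        raise StatError(f"mask length mismatch: {a.shape} vs {b.shape}")
    tp = int((a & b).sum())
    fp = int((a & ~b).sum())
    fn = int((~a & b).sum())
    if tp + fp + fn == 0:
        logger.info("f_measure: both masks empty; returning 1 by convention")
        return 1.0
    return 2 * tp / (2 * tp + fp + fn)


def remove_outliers(pairs, k: float = 3.0):
    """Drop rows where either method's value is > k SD from that method's mean.

    Single pass (means/SDs are not re-estimated after removal).
    Returns ``(filtered_pairs, n_removed)`` in the input's type.
    """
    a, b = _paired(pairs)
    if a.size < 10:
        raise StatError(f"need at least 10 pairs for outlier screening, got {a.size}")

    def keep_mask(v):
        sd = v.std(ddof=1)
        if sd == 0:
            return np.ones(v.size, dtype=bool)
        return np.abs(v - v.mean()) <= k * sd

    keep = keep_mask(a) & keep_mask(b)
    n_removed = int((~keep).sum())
    if isinstance(pairs, pd.DataFrame):
        return pairs.loc[keep], n_removed
    return np.column_stack([a[keep], b[keep]]), n_removed


def optimization_gate(r: float) -> bool:
    """Template-optimization pass rule: strictly r > 0.75 passes.

    r <= 0.75 counts as a failure of the automated analysis for that
    population, sending it back for iterative template refinement.
    """
    if not np.isfinite(r):
        raise StatError("correlation must be finite")
    return bool(r > 0.75)


def icc_mixed_model(design: pd.DataFrame, population: str | None = None,
                    ) -> tuple[float, float, float]:
    """Technician variance components and ICC from a REML mixed model.

    Fits ``value ~ C(control_id)`` with a random technician intercept by
    restricted maximum likelihood: controls are fixed effects, the
    technician effect is the inter-technician variance, the residual the
    intra-technician variance.  Returns ``(icc, var_inter, var_intra)``
    with variances floored at 0 and
    ICC = var_inter / (var_inter + var_intra) — the share of
    non-control variance attributable to technician batch effects.

    ``design`` needs columns ``control_id, technician_id, value`` (and
    ``population`` when ``population`` is given).
    """
    import statsmodels.formula.api as smf

    df = design
    if population is not None:
        df = df[df["population"] == population]
    df = df.dropna(subset=["value"])
    required = {"control_id", "technician_id", "value"}
    if missing := required - set(df.columns):
        raise StatError(f"design missing columns: {sorted(missing)}")
    if df["technician_id"].nunique() < 2:
        raise StatError("ICC not identifiable with fewer than 2 technicians")
    if len(df) <= df["control_id"].nunique() + 1:
        raise StatError("too few observations to separate variance components")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("value ~ C(control_id)", data=df,
                            groups=df["technician_id"])
        fit = model.fit(reml=True)
    var_inter = max(0.0, float(np.asarray(fit.cov_re)[0, 0]))
    var_intra = max(0.0, float(fit.scale))
    total = var_inter + var_intra
    icc = var_inter / total if total > 0 else 0.0
    return icc, var_inter, var_intra


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "population", "n", "r", "r_lo", "r_hi", "percent_bias", "bias_lo",
    "bias_hi", "mean_diff", "mean_abs_diff", "f_measure",
    "n_outliers_removed", "r_after_outlier_removal", "optimization_pass",
    "icc", "var_inter", "var_intra", "reason",
]


@dataclass
class ComparisonReport:
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_markdown(self, path=None) -> str:
        lines = ["# Automated vs. manual gating comparison", ""]
        lines.append("| population | n | r (95% CI) | percent bias (95% CI) | "
                     "mean |diff| | F | outliers removed | r after removal | "
                     "pass r>0.75 | ICC |")
        lines.append("|---|---|---|---|---|---|---|---|---|---|")
        for row in self.table.itertuples(index=False):
            if row.reason:
                lines.append(f"| {row.population} | {row.n} | — | — | — | — | — "
                             f"| — | — | — | ({row.reason}) |"[:-2] + "|")
                continue

            def fmt(v, d=3):
                return "—" if v is None or (isinstance(v, float) and np.isnan(v)) \
                    else f"{v:.{d}f}"

            lines.append(
                f"| {row.population} | {row.n} "
                f"| {fmt(row.r)} ({fmt(row.r_lo)}, {fmt(row.r_hi)}) "
                f"| {fmt(row.percent_bias, 2)} ({fmt(row.bias_lo, 2)}, {fmt(row.bias_hi, 2)}) "
                f"| {fmt(row.mean_abs_diff)} | {fmt(row.f_measure)} "
                f"| {int(row.n_outliers_removed) if not np.isnan(row.n_outliers_removed) else '—'} "
                f"| {fmt(row.r_after_outlier_removal)} "
                f"| {'pass' if row.optimization_pass else 'FAIL'} "
                f"| {fmt(row.icc)} |")
        text = "\n".join(lines) + "\n"
        if path is not None:
            from pathlib import Path
            Path(path).write_text(text)
        return text


def build_report(
    paired: pd.DataFrame,
    masks: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    design: pd.DataFrame | None = None,
    seed: int = 0,
) -> ComparisonReport:
    """Run the full comparison battery per population.

    ``paired`` has columns ``sample_id, population, hybrid, manual``.
    ``masks`` optionally maps population -> (automated mask, manual
    mask) on a shared event index for the F-measure.  ``design``
    optionally provides the replicated-control table for the ICC.
    Populations whose statistics are undefined (too few pairs, constant
    columns) are reported with a reason code, never dropped.
    """
    required = {"sample_id", "population", "hybrid", "manual"}
    if missing := required - set(paired.columns):
        raise StatError(f"paired counts missing columns: {sorted(missing)}")
    rows = []
    for pop, grp in paired.groupby("population", sort=True):
        pairs = grp[["hybrid", "manual"]].to_numpy(dtype=float)
        row = dict.fromkeys(REPORT_COLUMNS, np.nan)
        row.update(population=pop, n=len(grp), reason="")
        try:
            r, rlo, rhi = pearson_ci(pairs)
            bias, blo, bhi = percent_bias(pairs, seed=seed)
            md, mad = absolute_difference(pairs)
            row.update(r=r, r_lo=rlo, r_hi=rhi, percent_bias=bias,
                       bias_lo=blo, bias_hi=bhi, mean_diff=md,
                       mean_abs_diff=mad, optimization_pass=optimization_gate(r))
            try:
                trimmed, n_rm = remove_outliers(pairs)
                row["n_outliers_removed"] = n_rm
                row["r_after_outlier_removal"] = pearson_ci(trimmed)[0]
            except StatError:
                row["n_outliers_removed"] = 0
                row["r_after_outlier_removal"] = r
        except StatError as exc:
            row["reason"] = str(exc)
        if masks and pop in masks:
            row["f_measure"] = f_measure(*masks[pop])
        if design is not None and "population" in design.columns \
                and (design["population"] == pop).any():
            try:
                icc, vi, ve = icc_mixed_model(design, pop)
                row.update(icc=icc, var_inter=vi, var_intra=ve)
            except StatError as exc:
                row["reason"] = (row["reason"] + "; " if row["reason"] else "") \
                    + f"icc: {exc}"
        rows.append(row)
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return ComparisonReport(table)
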