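"""Protein-level relative quantitation and differential-expression calls.

Peptide reporter-area ratios (test channel / reference channel) are
aggregated to a weighted average of log10 ratios per protein.  Three
statistics drive the inference:

* an *error factor* ``10^(S_MW x t_crit(0.975, n-1))`` where ``S_MW`` is
  the weighted standard deviation of the weighted average of log ratios --
  the multiplicative 95 % uncertainty bound of the protein ratio;
* a Student t on the bias-corrected weighted mean,
  ``t = (weighted mean - log bias) / S_MW`` with n-1 degrees of freedom;
* a two-cell likelihood-ratio G-test on the summed reporter areas of the
  reference and test groups, referred to chi-square with 1 df and
  corrected across proteins with the Benjamini-Hochberg step-up.

Regulation calls combine a fold-change cutoff (>1.5 up, <0.67 down) with
BH-significance of the G-test; gender-differential proteins are those
whose female-vs-control and male-vs-control ratios differ by >= 0.2.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, DpmQuantError
from .psm_io import GroupDesign, PsmRecord


@dataclass
class RatioStats:
    """Weighted log-ratio of one protein in one group vs the reference."""

    protein_acc: str | None
    group: str | None
    weighted_log_ratio: float
    s_mw: float
    n_peptides: int
    error_factor: float
    t_stat: float
    p_value: float

    @property
    def ratio(self) -> float:
        return 10.0 ** self.weighted_log_ratio


@dataclass
class GTestResult:
    """Area-based G statistic for one protein (reference vs dementia group)."""

    protein_acc: str | None
    ctrl_area: float
    dem_area: float
    g_value: float
    p_raw: float
    p_bh: float = math.nan


@dataclass
class RegulationCall:
    """Per-protein regulation and gender-difference call."""

    protein_acc: str | None
    female_ratio: float
    male_ratio: float
    call_vs_control: dict[str, str] = field(default_factory=dict)
    modulated: dict[str, bool] = field(default_factory=dict)
    gender_difference: float = math.nan
    gender_quotient: float = math.nan
    is_gender_differential: bool = False
    significance_tier: str = "none"


def _weighted_stats(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted mean and S_MW (weighted SD of the weighted mean).

    Uses reliability weights: the unbiased weighted variance divided by the
    effective number of observations (sum w)^2 / sum w^2.  With equal
    weights this reduces to the ordinary standard error s/sqrt(n).
    """
    v1 = w.sum()
    v2 = (w * w).sum()
    mean = float((w * x).sum() / v1)
    n = len(x)
    if n < 2:
        return mean, math.nan
    denom = v1 - v2 / v1
    if denom <= 0:
        return mean, math.nan
    var = float((w * (x - mean) ** 2).sum() / denom)
    n_eff = v1 * v1 / v2
    return mean, math.sqrt(max(var, 0.0) / n_eff)


def weighted_ratio_stats(
    log_ratios: Sequence[float],
    weights: Sequence[float] | None = None,
    log_bias: float = 0.0,
    protein_acc: str | None = None,
    group: str | None = None,
) -> RatioStats:
    """Weighted log-ratio statistics from per-peptide log10 ratios."""
    x = np.asarray(log_ratios, dtype=float)
    if x.size == 0:
        raise DpmQuantError("at least one peptide log ratio is required")
    w = (
        np.ones_like(x)
        if weights is None
        else np.asarray(weights, dtype=float)
    )
    if w.shape != x.shape or (w <= 0).any():
        raise DpmQuantError("weights must be positive and match the ratios")
    mean, s_mw = _weighted_stats(x, w)
    n = x.size
    if n < 2 or math.isnan(s_mw):
        return RatioStats(protein_acc, group, mean, math.nan, n, math.nan, math.nan, math.nan)
    delta = mean - log_bias
    if s_mw == 0.0:
        t = 0.0 if delta == 0.0 else math.copysign(math.inf, delta)
        p = 1.0 if delta == 0.0 else 0.0
    else:
        t = delta / s_mw
        p = 2.0 * stats.t.sf(abs(t), n - 1)
    t_crit = stats.t.ppf(0.975, n - 1)
    error_factor = 10.0 ** (s_mw * t_crit)
    return RatioStats(protein_acc, group, mean, s_mw, n, error_factor, t, p)


def protein_log_ratio(
    peptide_areas: Iterable[tuple],
    log_bias: float = 0.0,
    protein_acc: str | None = None,
    group: str | None = None,
) -> RatioStats:
    """Protein ratio statistics from peptide (group_area, ref_area[, weight]).

    The default weight is the summed reporter area of the peptide across
    the two channels, a precision proxy for more intense peptides.
    """
    log_ratios, weights = [], []
    for entry in peptide_areas:
        if len(entry) == 2:
            g_area, r_area = entry
            weight = g_area + r_area
        else:
            g_area, r_area, weight = entry
        if g_area <= 0 or r_area <= 0:
            raise DpmQuantError("reporter areas must be positive for ratio peptides")
        log_ratios.append(math.log10(g_area / r_area))
        weights.append(weight)
    return weighted_ratio_stats(
        log_ratios, weights, log_bias=log_bias, protein_acc=protein_acc, group=group
    )


def estimate_log_bias(all_peptide_log_ratios: Sequence[float]) -> float:
    """Global normalization offset: the median peptide log10 ratio.

    Assumes the bulk of proteins are unchanged so the ratio distribution
    should center at 1 (log ratio 0).
    """
    x = np.asarray(all_peptide_log_ratios, dtype=float)
    if x.size == 0:
        raise DpmQuantError("cannot estimate log bias from an empty set")
    return float(np.median(x))


def g_test(
    ctrl_area: float, dem_area: float, protein_acc: str | None = None
) -> GTestResult:
    """Two-cell likelihood-ratio G on summed reporter areas.

    G = 2 (Ctrl ln[Ctrl / m] + Dem ln[Dem / m]) with m = (Ctrl + Dem)/2,
    with the x ln x convention that a zero cell contributes 0; the p-value
    is the chi-square(1 df) upper tail.
    """
    if ctrl_area < 0 or dem_area < 0:
        raise DpmQuantError("areas must be non-negative")
    if ctrl_area == 0 and dem_area == 0:
        raise DpmQuantError("G-test undefined when both areas are zero")
    m = (ctrl_area + dem_area) / 2.0

    def cell(x: float) -> float:
        if x == 0:
            return 0.0
        ratio = x / m
        if ratio > 0:
            return x * math.log(ratio)
        # x/m underflowed to zero for a subnormal cell
        return x * (math.log(x) - math.log(m))

    g = 2.0 * (cell(ctrl_area) + cell(dem_area))
    g = max(float(g), 0.0)
    p = float(stats.chi2.sf(g, df=1))
    return GTestResult(protein_acc, ctrl_area, dem_area, g, p)


def bh_correct(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up adjustment.

    Returns the adjusted p-values and the data-driven significance
    threshold: the largest raw p still declared significant at ``alpha``
    (NaN when nothing is).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), math.nan
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DpmQuantError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    threshold = float(p[reject].max()) if reject.any() else math.nan
    return p_adj, threshold


def call_regulation(
    ratio_stats: Mapping[str, RatioStats],
    gtests: Mapping[str, GTestResult],
    up_cut: float = 1.5,
    alpha: float = 0.05,
    diff_cut: float = 0.2,
    strong_diff: float = 0.9,
    female: str = "female",
    male: str = "male",
) -> RegulationCall:
    """Combine ratio cutoffs, BH-corrected G-tests and gender difference.

    A group is called up when its ratio exceeds ``up_cut`` and down below
    ``round(1/up_cut, 2)`` (0.67 for the default 1.5); it is *modulated*
    only when additionally its BH-corrected G-test p is below ``alpha``.
    The gender call uses the absolute female-male ratio difference with
    tiers matching p<0.05 & diff>=0.2 and p<0.001 & diff>=0.9.
    """
    for group in (female, male):
        if group not in ratio_stats:
            raise DesignError(f"group {group!r} missing from ratio stats")
    down_cut = round(1.0 / up_cut, 2)
    acc = next(iter(ratio_stats.values())).protein_acc
    calls: dict[str, str] = {}
    modulated: dict[str, bool] = {}
    for group, rs in ratio_stats.items():
        ratio = rs.ratio
        call = "up" if ratio > up_cut else ("down" if ratio < down_cut else "unchanged")
        calls[group] = call
        g = gtests.get(group)
        sig = g is not None and not math.isnan(g.p_bh) and g.p_bh < alpha
        modulated[group] = bool(sig and call != "unchanged")

    f_ratio = ratio_stats[female].ratio
    m_ratio = ratio_stats[male].ratio
    diff = abs(f_ratio - m_ratio)
    quotient = f_ratio / m_ratio if m_ratio > 0 else math.nan
    p_bh_values = [
        g.p_bh for g in gtests.values() if g is not None and not math.isnan(g.p_bh)
    ]
    p_min = min(p_bh_values) if p_bh_values else math.nan
    if not math.isnan(p_min) and p_min < 0.001 and diff >= strong_diff:
        tier = "p<0.001 & diff>=0.9"
    elif not math.isnan(p_min) and p_min < 0.05 and diff >= diff_cut:
        tier = "p<0.05 & diff>=0.2"
    else:
        tier = "none"
    return RegulationCall(
        protein_acc=acc,
        female_ratio=f_ratio,
        male_ratio=m_ratio,
        call_vs_control=calls,
        modulated=modulated,
        gender_difference=diff,
        gender_quotient=quotient,
        is_gender_differential=diff >= diff_cut,
        significance_tier=tier,
    )


def ratio_cv_profile(
    per_replicate_ratios: Mapping, cutoffs: Sequence[float] = (20.0, 50.0)
) -> tuple[pd.DataFrame, dict]:
    """Percent CV of replicate-level protein ratios and its distribution.

    %CV = 100 x SD / mean over the replicate ratios of each protein; the
    summary reports the fraction of proteins under each requested cutoff.
    Proteins with fewer than two replicates or zero mean get NaN.
    """
    rows = []
    for key, ratios in per_replicate_ratios.items():
        r = np.asarray(list(ratios), dtype=float)
        if r.size < 2 or r.mean() == 0:
            cv = math.nan
        else:
            cv = 100.0 * r.std(ddof=1) / r.mean()
        rows.append({"key": key, "n_replicates": int(r.size),
                     "mean_ratio": float(r.mean()) if r.size else math.nan,
                     "cv_pct": cv})
    df = pd.DataFrame(rows)
    cv = df["cv_pct"].dropna() if not df.empty else pd.Series(dtype=float)
    summary = {
        "n": int(len(df)),
        "median_cv_pct": float(cv.median()) if len(cv) else math.nan,
        "frac_below": {
            float(c): float((cv < c).mean()) if len(cv) else math.nan for c in cutoffs
        },
    }
    return df, summary


@dataclass
class ProteinQuantResult:
    """Protein-level statistics table plus per-protein calls."""

    stats: pd.DataFrame
    calls: dict[str, RegulationCall]
    per_replicate_ratios: dict[tuple[str, str], list[float]]
    bh_thresholds: dict[str, float]


def quantify_proteins(
    records: Sequence[PsmRecord],
    design: GroupDesign,
    accessions: set[str] | None = None,
    up_cut: float = 1.5,
    alpha: float = 0.05,
    diff_cut: float = 0.2,
    strong_diff: float = 0.9,
    normalize: bool = True,
) -> ProteinQuantResult:
    """Run the full protein-level inference over qualified records.

    Per test group: peptide log10 ratios (group channel over reference
    channel, both areas > 0) are bias-corrected by the per-replicate
    median (``normalize=True``; the correction assumes most proteins are
    unchanged), pooled across replicates into weighted ratio statistics,
    and the per-protein summed areas (rounded to integer, treating areas
    as counts) feed the G-test whose p-values are BH-corrected per group.
    """
    records = [r for r in records if not r.is_decoy]
    if accessions is not None:
        records = [r for r in records if r.protein_acc in accessions]
    ref_ch = design.channel_of(design.reference_group)

    all_rows: list[dict] = []
    per_rep: dict[tuple[str, str], dict[str, float]] = defaultdict(dict)
    stats_by_acc: dict[str, dict[str, RatioStats]] = defaultdict(dict)
    gtests_by_acc: dict[str, dict[str, GTestResult]] = defaultdict(dict)
    bh_thresholds: dict[str, float] = {}

    for group in design.test_groups:
        ch = design.channel_of(group)
        entries = []  # (acc, run, log_ratio, weight, g_area, ref_area)
        for r in records:
            g_area, r_area = r.area(ch), r.area(ref_ch)
            if g_area > 0 and r_area > 0:
                entries.append(
                    (r.protein_acc, r.run_id, math.log10(g_area / r_area),
                     g_area + r_area, g_area, r_area)
                )
        if not entries:
            continue
        bias_by_run: dict[str, float] = {}
        if normalize:
            by_run: dict[str, list[float]] = defaultdict(list)
            for _, run, x, *_ in entries:
                by_run[run].append(x)
            bias_by_run = {run: estimate_log_bias(xs) for run, xs in by_run.items()}

        by_acc: dict[str, list[tuple]] = defaultdict(list)
        for acc, run, x, w, ga, ra in entries:
            by_acc[acc].append((run, x - bias_by_run.get(run, 0.0), w, ga, ra))

        group_gtests: list[GTestResult] = []
        for acc, items in by_acc.items():
            xs = [x for _, x, _, _, _ in items]
            ws = [w for _, _, w, _, _ in items]
            rs = weighted_ratio_stats(xs, ws, log_bias=0.0, protein_acc=acc, group=group)
            stats_by_acc[acc][group] = rs
            ctrl_a = round(sum(ra for *_, ra in items))
            dem_a = round(sum(ga for *_, ga, _ in items))
            if ctrl_a == 0 and dem_a == 0:
                continue
            gt = g_test(ctrl_a, dem_a, protein_acc=acc)
            gtests_by_acc[acc][group] = gt
            group_gtests.append(gt)
            runs: dict[str, list[tuple[float, float]]] = defaultdict(list)
            for run, x, w, *_ in items:
                runs[run].append((x, w))
            for run, xw in runs.items():
                xa = np.array([x for x, _ in xw])
                wa = np.array([w for _, w in xw])
                per_rep[(acc, group)][run] = 10.0 ** float((wa * xa).sum() / wa.sum())

        if group_gtests:
            p_adj, threshold = bh_correct([g.p_raw for g in group_gtests], alpha=alpha)
            for g, adj in zip(group_gtests, p_adj):
                g.p_bh = float(adj)
            bh_thresholds[group] = threshold

    calls: dict[str, RegulationCall] = {}
    female, male = "female", "male"
    for acc, group_stats in stats_by_acc.items():
        if female in group_stats and male in group_stats:
            calls[acc] = call_regulation(
                group_stats, gtests_by_acc.get(acc, {}),
                up_cut=up_cut, alpha=alpha, diff_cut=diff_cut,
                strong_diff=strong_diff, female=female, male=male,
            )
        for group, rs in group_stats.items():
            gt = gtests_by_acc.get(acc, {}).get(group)
            ratio = rs.ratio
            down_cut = round(1.0 / up_cut, 2)
            call = (
                "up" if ratio > up_cut else ("down" if ratio < down_cut else "unchanged")
            )
            sig = gt is not None and not math.isnan(gt.p_bh) and gt.p_bh < alpha
            all_rows.append(
                {
                    "protein_acc": acc,
                    "group": group,
                    "n_peptides": rs.n_peptides,
                    "weighted_log_ratio": rs.weighted_log_ratio,
                    "ratio": ratio,
                    "s_mw": rs.s_mw,
                    "error_factor": rs.error_factor,
                    "t_stat": rs.t_stat,
                    "p_value": rs.p_value,
                    "ctrl_area": gt.ctrl_area if gt else math.nan,
                    "dem_area": gt.dem_area if gt else math.nan,
                    "g_value": gt.g_value if gt else math.nan,
                    "p_raw": gt.p_raw if gt else math.nan,
                    "p_bh": gt.p_bh if gt else math.nan,
                    "call": call,
                    "modulated": bool(sig and call != "unchanged"),
                }
            )

    stats_df = pd.DataFrame(all_rows)
    if not stats_df.empty:
        stats_df = stats_df.sort_values(["protein_acc", "group"]).reset_index(drop=True)
    rep_ratios = {
        key: [run_map[r] for r in sorted(run_map)] for key, run_map in per_rep.items()
    }
    return ProteinQuantResult(stats_df, calls, rep_ratios, bh_thresholds)


def heatmap_matrix(result: ProteinQuantResult, design: GroupDesign) -> pd.DataFrame:
    """Ratio matrix (proteins x groups) with the reference column fixed at 1."""
    if result.stats.empty:
        return pd.DataFrame()
    mat = result.stats.pivot(index="protein_acc", columns="group", values="ratio")
    mat.insert(0, design.reference_group, 1.0)
    return mat
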