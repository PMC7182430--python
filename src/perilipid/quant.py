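"""Quantification: calibration curves, standard addition, and derived biology.

Absolute amounts come from external standard curves (peak area regressed on
known concentration) or, for complex matrices, from the method of standard
addition (spiking known amounts of the analyte into the sample and reading
the endogenous concentration off the x-intercept of the response line).
Sphingolipids lack synthetic standards, so they are reported strictly as
peak-area ratios to ergosterol — an internal control whose signal is stable
across membrane domains — never as molar amounts.

Derived summaries: class mol% over absolutely quantified species,
IPC/ergosterol and MIPC/ergosterol ratio statistics between membrane
domains (group means ± SEM, fold change, Student's t), and the
lipids-per-SMALP stoichiometry assuming one protein per nanodisc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StandardSeries",
    "CurveFit",
    "RatioReport",
    "fit_external_curve",
    "quantify_by_curve",
    "standard_addition",
    "conversion_factor",
    "class_composition",
    "two_sample_ttest",
    "sphingolipid_ratio_report",
    "lipids_per_smalp",
]

#: spike grids used with the HPLC-MS method (pmol/µl)
PHOSPHOLIPID_SPIKE_GRID = (0.0, 0.5, 1.0, 1.5, 2.0)
ERGOSTEROL_SPIKE_GRID = (0.0, 1.0, 3.0, 5.0)


@dataclass(frozen=True)
class StandardSeries:
    """Concentration/peak-area points for one analyte.

    ``kind`` is ``"external"`` (pure standards) or ``"addition"`` (standard
    spiked into the sample, so every point carries the endogenous signal).
    """

    analyte: str
    concentrations: tuple[float, ...]
    areas: tuple[float, ...]
    kind: str = "external"

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.areas):
            raise ValueError("concentrations and areas differ in length")
        if len(self.concentrations) < 3:
            raise ValueError("a standard series needs at least 3 points")
        conc = np.asarray(self.concentrations)
        if (conc < 0).any():
            raise ValueError("concentrations must be non-negative")
        if not (np.diff(conc) > 0).all():
            raise ValueError("concentrations must be strictly increasing")
        if self.kind not in ("external", "addition"):
            raise ValueError(f"unknown series kind {self.kind!r}")
        if self.kind == "external" and conc[0] != 0:
            raise ValueError("external series must include a blank (0) point")


@dataclass
class CurveFit:
    """Ordinary-least-squares line of peak area on concentration."""

    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    intercept_se: float
    flags: list[str] = field(default_factory=list)


def _ols(x: np.ndarray, y: np.ndarray) -> CurveFit:
    if np.ptp(x) == 0:
        raise ValueError("zero concentration variance")
    res = stats.linregress(x, y)
    fit = CurveFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
    )
    return fit


def fit_external_curve(series: StandardSeries, r2_warn: float = 0.98) -> CurveFit:
    """Fit an external calibration line; flag poor linearity or zero response."""
    if series.kind != "external":
        raise ValueError("fit_external_curve expects an external series")
    fit = _ols(np.asarray(series.concentrations), np.asarray(series.areas))
    if fit.slope <= 0:
        fit.flags.append("nonpositive_slope")
    if fit.r_squared < r2_warn:
        fit.flags.append("poor_linearity")
    return fit


def quantify_by_curve(area: float, fit: CurveFit) -> float:
    """Concentration (pmol/µl) from a peak area and an external curve."""
    if fit.slope <= 0:
        raise ValueError("calibration slope must be positive")
    conc = (area - fit.intercept) / fit.slope
    if conc < 0:
        warnings.warn("peak area below calibration intercept; clipping to 0")
        return 0.0
    return conc


def standard_addition(series: StandardSeries) -> tuple[float, float]:
    """Endogenous concentration ± SE from a standard-addition series.

    The response line ``area = slope × spike + intercept`` crosses zero at
    ``spike = −intercept/slope``; the magnitude of that x-intercept is the
    endogenous concentration.  The standard error follows from first-order
    propagation of the OLS slope/intercept errors including their covariance.
    """
    if series.kind != "addition":
        raise ValueError("standard_addition expects an addition series")
    x = np.asarray(series.concentrations)
    y = np.asarray(series.areas)
    fit = _ols(x, y)
    if fit.slope <= 0:
        raise ValueError("non-positive response slope in standard addition")
    if fit.intercept < 0:
        warnings.warn("negative intercept: endogenous concentration reported as 0")
        return 0.0, float("nan")
    est = fit.intercept / fit.slope
    # cov(slope, intercept) = −x̄ × var(slope) for OLS
    cov_ab = -float(np.mean(x)) * fit.slope_se**2
    var = (
        (fit.intercept_se / fit.slope) ** 2
        + (fit.intercept * fit.slope_se / fit.slope**2) ** 2
        - 2 * fit.intercept / fit.slope**3 * cov_ab
    )
    se = float(np.sqrt(max(var, 0.0)))
    return float(est), se


def conversion_factor(external_fit: CurveFit, addition_series: StandardSeries) -> float:
    """Per-analyte correction relating the two calibration strategies.

    Standard addition sees the analyte in the true sample matrix, so the
    ratio of the standard-addition estimate to the external-curve estimate of
    the same sample (the zero-spike point) calibrates matrix effects; the
    factor then corrects external-curve results for other samples of the
    same analyte.
    """
    endogenous, _ = standard_addition(addition_series)
    zero_spike_area = addition_series.areas[addition_series.concentrations.index(0.0)]
    external_est = quantify_by_curve(zero_spike_area, external_fit)
    if external_est <= 0:
        raise ValueError("external-curve estimate non-positive; cannot calibrate")
    return endogenous / external_est


def class_composition(
    quantities: Mapping[str, float],
    relative_only: Sequence[str] = (),
) -> dict[str, float]:
    """mol% per class over absolutely quantified classes (sums to 100).

    Classes listed in ``relative_only`` (sphingolipids, which have no
    standards) are excluded from the denominator and the output.
    """
    absolute = {
        k: v for k, v in quantities.items() if k not in set(relative_only)
    }
    total = sum(absolute.values())
    if total <= 0:
        raise ValueError("no absolutely quantified material")
    return {k: 100.0 * v / total for k, v in absolute.items()}


def two_sample_ttest(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> tuple[float, float, float]:
    """Two-tailed two-sample t-test; pooled variance (Student) by default.

    Returns (t, df, p).  ``welch=True`` drops the equal-variance assumption.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    df = len(a) + len(b) - 2
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate replicates: equal means are indistinguishable (p = 1),
        # unequal means are separated with certainty
        if np.mean(a) == np.mean(b):
            return 0.0, float(df), 1.0
        return float(np.inf * np.sign(np.mean(a) - np.mean(b))), float(df), 0.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    if welch:
        df = res.df
    return float(res.statistic), float(df), float(res.pvalue)


def _significance_label(p: float) -> str:
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class RatioReport:
    """Sphingolipid/ergosterol ratio comparison between two domains."""

    analyte: str
    mcp_ratios: list[float]
    mcc_ratios: list[float]
    mcp_mean: float
    mcp_sem: float
    mcc_mean: float
    mcc_sem: float
    fold_change: float
    t_statistic: float
    df: float
    p_value: float
    label: str


def sphingolipid_ratio_report(
    mcp_samples: Sequence[Mapping[str, float]],
    mcc_samples: Sequence[Mapping[str, float]],
    analyte: str = "IPC",
    welch: bool = False,
) -> RatioReport:
    """Compare analyte/ergosterol peak-area ratios between membrane domains.

    Each sample mapping provides the analyte peak area under its name (e.g.
    ``"IPC"``) and the ergosterol area under ``"ERG"``.  The fold change is
    mean(MCP)/mean(MCC); significance labels follow p < 0.05 (*) and
    p < 0.005 (**).
    """

    def ratios(samples: Sequence[Mapping[str, float]]) -> list[float]:
        out = []
        for s in samples:
            erg = s["ERG"]
            if erg <= 0:
                raise ValueError("zero or negative ergosterol area in a replicate")
            out.append(s[analyte] / erg)
        return out

    mcp = ratios(mcp_samples)
    mcc = ratios(mcc_samples)
    if len(mcp) < 2 or len(mcc) < 2:
        raise ValueError("each group needs at least 2 replicates")
    t, df, p = two_sample_ttest(mcp, mcc, welch=welch)
    mcc_mean = float(np.mean(mcc))
    mcp_mean = float(np.mean(mcp))
    return RatioReport(
        analyte=analyte,
        mcp_ratios=mcp,
        mcc_ratios=mcc,
        mcp_mean=mcp_mean,
        mcp_sem=float(np.std(mcp, ddof=1) / np.sqrt(len(mcp))),
        mcc_mean=mcc_mean,
        mcc_sem=float(np.std(mcc, ddof=1) / np.sqrt(len(mcc))),
        fold_change=mcp_mean / mcc_mean if mcc_mean > 0 else float("inf"),
        t_statistic=t,
        df=df,
        p_value=p,
        label=_significance_label(p),
    )


def lipids_per_smalp(total_lipid_pmol: float, protein_pmol: float) -> int:
    """Lipids per nanodisc, assuming one protein per SMALP.

    The molar ratio of total (phospholipid + ergosterol) lipid to protein,
    rounded to an integer for reporting.
    """
    if protein_pmol <= 0:
        raise ValueError("protein amount must be positive")
    if total_lipid_pmol < 0:
        raise ValueError("lipid amount must be non-negative")
    return int(round(total_lipid_pmol / protein_pmol))
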