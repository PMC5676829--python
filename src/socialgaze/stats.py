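"""Correlational statistics for the trait-attention analysis.

The analysis relates two eye-tracking measures (latency to orient to the
eyes; first-pass dwell before reorienting) to two trait dimensions
(autistic traits via SRS raw scores; social anxiety via SPAI-C raw
scores) within a single sample, so the central tool is the comparison of
*dependent* correlations: Steiger's Z for two correlations that share a
variable,

    Z = (z(r12) - z(r13)) * sqrt((n - 3) / (2 * (1 - s_bar)))

with z the Fisher transform, and s_bar the pooled estimate of the
covariance between the two correlations built from r23 and
rbar = (r12 + r13) / 2.  Supporting pieces: Pearson and first-order
partial correlations with exact t tests, Cook's-distance screening for
bivariate outliers in each measure-trait pair, a Shapiro-Wilk normality
screen, and the paired cued/silent latency contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class InsufficientDataError(ValueError):
    """Raised when a test's minimal sample-size precondition fails."""


class DegenerateInputError(ValueError):
    """Raised for inputs on which the statistic is undefined."""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t_stat: float
    df: int
    p_two_tailed: float
    controlled_for: str | None = None


@dataclass(frozen=True)
class DependentCorrComparison:
    """All quantities of Steiger's test for two correlations sharing a variable."""

    r12: float
    r13: float
    r23: float
    n: int
    rbar: float
    psi_bar: float
    s_bar: float
    z: float
    p_two_tailed: float


@dataclass(frozen=True)
class InfluenceDiagnostics:
    residuals: np.ndarray
    leverage: np.ndarray
    cooks_d: np.ndarray
    threshold: float
    flagged: np.ndarray  # indices with cooks_d > threshold


def _complete(*cols: np.ndarray) -> tuple[np.ndarray, ...]:
    arrs = [np.asarray(c, dtype=float) for c in cols]
    mask = np.ones(len(arrs[0]), dtype=bool)
    for a in arrs:
        mask &= np.isfinite(a)
    return tuple(a[mask] for a in arrs)


def fisher_z(r: float) -> float:
    """Variance-stabilizing Fisher transform z = atanh(r)."""
    return math.atanh(r)


def _t_test_r(r: float, df: int) -> tuple[float, float]:
    if abs(r) >= 1.0:
        return math.copysign(math.inf, r), 0.0
    t = r * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df)
    return t, float(p)


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with its exact two-tailed t test.

    Missing values are removed pairwise; the complete-case n is recorded
    in the result.
    """
    x, y = _complete(x, y)
    n = len(x)
    if n < 4:
        raise InsufficientDataError(f"need at least 4 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("correlation undefined for a constant variable")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    t, p = _t_test_r(r, n - 2)
    return CorrelationResult(r=r, n=n, t_stat=t, df=n - 2, p_two_tailed=p)


def partial_corr_from_r(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation from the three pairwise correlations."""
    # 1e-9 slack: a numerically computed r of an exactly collinear pair
    # comes back a few ulp under 1
    if abs(r_xz) >= 1.0 - 1e-9 or abs(r_yz) >= 1.0 - 1e-9:
        raise DegenerateInputError("control variable collinear with an input")
    return (r_xy - r_xz * r_yz) / math.sqrt((1 - r_xz**2) * (1 - r_yz**2))


def partial_corr(
    x: Sequence[float],
    y: Sequence[float],
    z: Sequence[float],
    controlled_for: str | None = None,
) -> CorrelationResult:
    """Correlation of x and y with z partialled out, tested on n-3 df.

    Equals the Pearson correlation of the residuals of x and y after
    least-squares regression on z.
    """
    x, y, z = _complete(x, y, z)
    n = len(x)
    if n < 5:
        raise InsufficientDataError(f"need at least 5 complete triples, got {n}")
    for v, name in ((x, "x"), (y, "y"), (z, "z")):
        if np.std(v) == 0:
            raise DegenerateInputError(f"variable {name} is constant")
    r_xy = float(np.corrcoef(x, y)[0, 1])
    r_xz = float(np.corrcoef(x, z)[0, 1])
    r_yz = float(np.corrcoef(y, z)[0, 1])
    r = partial_corr_from_r(r_xy, r_xz, r_yz)
    r = max(-1.0, min(1.0, r))
    t, p = _t_test_r(r, n - 3)
    return CorrelationResult(
        r=r, n=n, t_stat=t, df=n - 3, p_two_tailed=p, controlled_for=controlled_for
    )


def steiger_z(r12: float, r13: float, r23: float, n: int) -> DependentCorrComparison:
    """Steiger's Z for comparing two dependent correlations.

    r12 and r13 are the correlations of the shared variable (1) with
    each of the other two; r23 is the correlation between the non-shared
    variables.  Z is referred to the standard normal, two-tailed.
    Swapping r12 and r13 negates Z exactly; r12 == r13 gives Z = 0.
    """
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not -1.0 < r < 1.0:
            raise DegenerateInputError(f"{name} must lie in (-1, 1), got {r}")
    if n < 10:
        raise InsufficientDataError(f"need n >= 10, got {n}")
    rbar = (r12 + r13) / 2.0
    psi_bar = r23 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r23**2)
    s_bar = psi_bar / (1 - rbar**2) ** 2
    if s_bar >= 1.0:
        raise DegenerateInputError(
            f"degenerate correlation configuration (s_bar = {s_bar:.4f} >= 1)"
        )
    z = (fisher_z(r12) - fisher_z(r13)) * math.sqrt((n - 3) / (2.0 * (1.0 - s_bar)))
    p = 2.0 * sps.norm.sf(abs(z))
    return DependentCorrComparison(
        r12=r12, r13=r13, r23=r23, n=n, rbar=rbar, psi_bar=psi_bar, s_bar=s_bar,
        z=z, p_two_tailed=float(p),
    )


def cooks_distance(
    x: Sequence[float], y: Sequence[float], threshold: float | None = None
) -> InfluenceDiagnostics:
    """Cook's distance for the simple regression of y on x.

    Uses the closed-form leverages of the one-predictor design,
    h_ii = 1/n + (x_i - xbar)^2 / sum((x_j - xbar)^2), and
    D_i = e_i^2 h_ii / (p s^2 (1 - h_ii)^2) with p = 2 parameters and
    s^2 the residual mean square.  Observations with D_i above the
    threshold (default 4/n) are flagged.
    """
    x, y = _complete(x, y)
    n = len(x)
    if n < 5:
        raise InsufficientDataError(f"need at least 5 complete pairs, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise DegenerateInputError("constant predictor: regression design is singular")
    slope = float(np.sum((x - x.mean()) * (y - y.mean()))) / sxx
    intercept = y.mean() - slope * x.mean()
    e = y - (intercept + slope * x)
    h = 1.0 / n + (x - x.mean()) ** 2 / sxx
    p_params = 2
    s2 = float(np.sum(e**2)) / (n - p_params)
    if s2 == 0:
        d = np.zeros(n)
    else:
        d = e**2 * h / (p_params * s2 * (1 - h) ** 2)
    thr = 4.0 / n if threshold is None else threshold
    return InfluenceDiagnostics(
        residuals=e, leverage=h, cooks_d=d, threshold=thr,
        flagged=np.flatnonzero(d > thr),
    )


def paired_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, int, float]:
    """Paired-samples t test on complete pairs; returns (t, df, p)."""
    a, b = _complete(a, b)
    n = len(a)
    if n < 2:
        raise InsufficientDataError(f"need at least 2 complete pairs, got {n}")
    d = a - b
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        if float(np.mean(d)) == 0:
            return 0.0, n - 1, 1.0
        raise DegenerateInputError("zero variance of nonzero differences")
    t = float(np.mean(d)) / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return t, n - 1, float(p)


def shapiro_wilk(x: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality statistic W and p; a screen, never a gate."""
    (x,) = _complete(x)
    n = len(x)
    if not 3 <= n <= 5000:
        raise InsufficientDataError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("Shapiro-Wilk undefined for a constant vector")
    w, p = sps.shapiro(x)
    return float(w), float(p)


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StatsConfig:
    cooks_screening: bool = True
    cooks_threshold: float | None = None  # None -> 4/n
    subscale_analysis: bool = True
    min_participants: int = 10


MEASURES = {
    "latency_to_eyes": "mean_latency_ms",
    "first_pass_dwell": "mean_dwell_ms",
}

TRAITS = {"srs": "srs_total", "spaic": "spaic_total"}

SUBSCALE_COLUMNS = (
    "srs_social_awareness",
    "srs_social_communication",
    "srs_social_cognition",
    "srs_social_motivation",
    "srs_rrb",
)


@dataclass
class AnalysisResults:
    """Tabular results plus the normality screen and the condition contrast."""

    tests: pd.DataFrame
    shapiro: pd.DataFrame
    contrast: dict | None
    n_participants: int
    notes: list[str] = field(default_factory=list)

    def report(self) -> str:
        lines = [
            f"Association analysis over {self.n_participants} participants",
            "",
            "Normality screen (Shapiro-Wilk):",
        ]
        for row in self.shapiro.itertuples(index=False):
            lines.append(f"  {row.variable}: W = {row.W:.3f}, p = {row.p:.3f}")
        if self.contrast is not None:
            c = self.contrast
            lines += [
                "",
                (
                    f"Cued vs silent latency (paired, n = {c['n']}): silent "
                    f"M = {c['mean_silent']:.0f}, SD = {c['sd_silent']:.0f}; cued "
                    f"M = {c['mean_cued']:.0f}, SD = {c['sd_cued']:.0f}; "
                    f"t({c['df']}) = {c['t']:.2f}, p = {c['p']:.3f}"
                ),
            ]
        lines += ["", "Correlations:"]
        for row in self.tests.itertuples(index=False):
            cov = f" | {row.covariate}" if isinstance(row.covariate, str) and row.covariate else ""
            extra = f", removed {row.n_removed_outliers}" if row.n_removed_outliers else ""
            if row.analysis == "steiger":
                lines.append(
                    f"  {row.measure}: {row.predictor} vs {row.covariate}: "
                    f"Z = {row.estimate:.3f}, p = {row.p:.3f} (n = {row.n})"
                )
            else:
                lines.append(
                    f"  {row.measure} ~ {row.predictor}{cov}: r = {row.estimate:.3f}, "
                    f"t({row.df:.0f}) = {row.statistic:.2f}, p = {row.p:.3f} "
                    f"(n = {row.n}{extra})"
                )
        if self.notes:
            lines += ["", "Notes:"] + [f"  {n}" for n in self.notes]
        return "\n".join(lines) + "\n"


def _screen_pair(
    x: np.ndarray, y: np.ndarray, config: StatsConfig
) -> tuple[np.ndarray, np.ndarray, int]:
    """Apply Cook's-distance screening to one measure-trait pair."""
    if not config.cooks_screening:
        return x, y, 0
    diag = cooks_distance(x, y, threshold=config.cooks_threshold)
    if len(diag.flagged) == 0:
        return x, y, 0
    keep = np.ones(len(x), dtype=bool)
    keep[diag.flagged] = False
    return x[keep], y[keep], int(len(diag.flagged))


def run_association_analysis(
    summaries: pd.DataFrame,
    traits: pd.DataFrame,
    config: StatsConfig = StatsConfig(),
) -> AnalysisResults:
    """The full correlational analysis of attention measures against traits.

    For each measure x trait pair: Cook's-distance screening (per pair),
    zero-order Pearson r, and the partial r controlling the other trait;
    per measure, Steiger's comparison of the two traits' correlations;
    the trait intercorrelation; optionally SRS-subscale correlations with
    latency (zero-order and SPAI-C-partialled); and a Shapiro-Wilk screen
    of all analysis variables.
    """
    notes: list[str] = []
    data = summaries.merge(traits, on="participant_id", how="inner")
    core = data[list(MEASURES.values()) + list(TRAITS.values())]
    n_complete = int(core.notna().all(axis=1).sum())
    if n_complete < config.min_participants:
        raise InsufficientDataError(
            f"analysis requires >= {config.min_participants} participants with both "
            f"measures and both trait scores, got {n_complete}"
        )

    rows = []

    def _add(analysis, measure, predictor, covariate, res, n_removed=0):
        if isinstance(res, DependentCorrComparison):
            rows.append(
                (analysis, measure, predictor, covariate, res.n, res.z, res.z,
                 np.nan, res.p_two_tailed, n_removed)
            )
        else:
            rows.append(
                (analysis, measure, predictor, covariate, res.n, res.r, res.t_stat,
                 res.df, res.p_two_tailed, n_removed)
            )

    # measure-trait pairs
    for m_name, m_col in MEASURES.items():
        for t_name, t_col in TRAITS.items():
            other_name, other_col = next(
                (k, v) for k, v in TRAITS.items() if k != t_name
            )
            x, y = _complete(data[t_col], data[m_col])
            x2, y2, n_rm = _screen_pair(x, y, config)
            if n_rm:
                notes.append(
                    f"{n_rm} observation(s) removed from {m_name} ~ {t_name} by "
                    f"Cook's distance screening"
                )
            _add("pearson", m_name, t_name, None, pearson_corr(x2, y2), n_rm)
            xt, yt, zt = _complete(data[t_col], data[m_col], data[other_col])
            _add(
                "partial", m_name, t_name, other_name,
                partial_corr(xt, yt, zt, controlled_for=other_name),
            )

        # Steiger comparison of the two traits' correlations with this measure
        m, a, b = _complete(data[m_col], data[TRAITS["srs"]], data[TRAITS["spaic"]])
        r12 = float(np.corrcoef(m, a)[0, 1])
        r13 = float(np.corrcoef(m, b)[0, 1])
        r23 = float(np.corrcoef(a, b)[0, 1])
        _add("steiger", m_name, "srs", "spaic", steiger_z(r12, r13, r23, len(m)))

    # trait intercorrelation
    ta, tb = _complete(data[TRAITS["srs"]], data[TRAITS["spaic"]])
    _add("pearson", "spaic", "srs", None, pearson_corr(ta, tb))

    # SRS subscales vs latency
    if config.subscale_analysis:
        for sub in SUBSCALE_COLUMNS:
            if sub not in data.columns:
                continue
            x, y = _complete(data[sub], data[MEASURES["latency_to_eyes"]])
            _add("pearson", "latency_to_eyes", sub, None, pearson_corr(x, y))
            xs, ys, zs = _complete(
                data[sub], data[MEASURES["latency_to_eyes"]], data[TRAITS["spaic"]]
            )
            _add(
                "partial", "latency_to_eyes", sub, "spaic",
                partial_corr(xs, ys, zs, controlled_for="spaic"),
            )

    tests = pd.DataFrame(
        rows,
        columns=[
            "analysis", "measure", "predictor", "covariate", "n", "estimate",
            "statistic", "df", "p", "n_removed_outliers",
        ],
    )

    shapiro_rows = []
    for label, col in {**MEASURES, **TRAITS}.items():
        vals = data[col].dropna().to_numpy()
        try:
            w, p = shapiro_wilk(vals)
        except (InsufficientDataError, DegenerateInputError):
            w, p = float("nan"), float("nan")
        shapiro_rows.append((label, w, p))
    shapiro = pd.DataFrame(shapiro_rows, columns=["variable", "W", "p"])

    contrast = cued_silent_contrast(data)
    return AnalysisResults(
        tests=tests, shapiro=shapiro, contrast=contrast,
        n_participants=n_complete, notes=notes,
    )


def cued_silent_contrast(summaries: pd.DataFrame) -> dict | None:
    """Paired cued/silent latency contrast over eligible participants.

    Only participants with at least half their trials valid in each
    condition (``contrast_eligible``) enter; returns None when fewer
    than two qualify.
    """
    if "contrast_eligible" not in summaries.columns:
        return None
    elig = summaries[
        summaries["contrast_eligible"].astype(bool)
        & summaries["mean_latency_silent_ms"].notna()
        & summaries["mean_latency_cued_ms"].notna()
    ]
    if len(elig) < 2:
        return None
    silent = elig["mean_latency_silent_ms"].to_numpy()
    cued = elig["mean_latency_cued_ms"].to_numpy()
    try:
        t, df, p = paired_t(silent, cued)
    except DegenerateInputError:
        return None
    return {
        "n": len(elig),
        "mean_silent": float(silent.mean()),
        "sd_silent": float(silent.std(ddof=1)),
        "mean_cued": float(cued.mean()),
        "sd_cued": float(cued.std(ddof=1)),
        "t": t,
        "df": df,
        "p": p,
    }
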