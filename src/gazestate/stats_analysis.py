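"""Repeated-measures statistical battery for the three-state design.

Implements the analyses applied to each subjective scale and eye-tracking
aggregate: one-way within-subject (repeated-measures) ANOVA with Mauchly's
sphericity test and the Greenhouse-Geisser correction, partial eta
squared, Bonferroni-corrected paired post hoc t-tests with Cohen's d
(root-mean-square pooled SD convention) and a normal-approximation 95% CI,
and Pearson correlations between eye-tracking metrics and scale scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from gazestate import reference_tables as ref


class IncompleteDesignError(ValueError):
    pass


class DegenerateDataError(ValueError):
    pass


@dataclass(frozen=True)
class RmAnovaResult:
    measure: str
    F: float
    df1: int
    df2: int
    eps_gg: float
    p_uncorrected: float
    p_gg: float
    eta_p2: float
    sphericity_W: float
    sphericity_p: float


@dataclass(frozen=True)
class PosthocResult:
    measure: str
    pair: tuple[int, int]
    t: float
    df: int
    p_bonf: float
    d: float
    ci95: tuple[float, float]
    degenerate: bool = False


@dataclass(frozen=True)
class CorrResult:
    x: str
    y: str
    r: float
    p: float
    n: int


def _wide(table: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Pivot the long table to participants x states for one measure."""
    sub = table[table["measure"] == measure]
    if sub.empty:
        raise IncompleteDesignError(f"no rows for measure {measure!r}")
    wide = sub.pivot(index="participant_id", columns="state", values="value")
    if wide.isna().any().any():
        raise IncompleteDesignError(f"missing cells for measure {measure!r}")
    if wide.shape[1] != 3:
        raise IncompleteDesignError(f"expected 3 states, got {wide.shape[1]}")
    return wide.sort_index(axis=1)


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon-hat from the condition covariance matrix.

    Computed on an orthonormal contrast of the k conditions:
    eps = tr(M)^2 / ((k-1) tr(M^2)) with M = C S C'.  Bounded in
    [1/(k-1), 1]; equals 1 under compound symmetry.
    """
    S = np.asarray(cov, dtype=float)
    k = S.shape[0]
    if S.shape != (k, k) or k < 2:
        raise DegenerateDataError("covariance must be k x k with k >= 2")
    # orthonormal basis of the contrast space (complement of the unit vector)
    C = np.linalg.svd(np.eye(k) - np.ones((k, k)) / k)[0][:, : k - 1].T
    M = C @ S @ C.T
    tr = np.trace(M)
    tr2 = np.trace(M @ M)
    if tr2 <= 0 or tr <= 0:
        raise DegenerateDataError("degenerate condition covariance")
    eps = tr * tr / ((k - 1) * tr2)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def mauchly_w(cov: np.ndarray, n: int) -> tuple[float, float]:
    """Mauchly's sphericity statistic W and its chi-square p-value."""
    S = np.asarray(cov, dtype=float)
    k = S.shape[0]
    C = np.linalg.svd(np.eye(k) - np.ones((k, k)) / k)[0][:, : k - 1].T
    M = C @ S @ C.T
    d = k - 1
    eig = np.linalg.eigvalsh(M)
    if np.any(eig <= 0):
        raise DegenerateDataError("singular condition covariance")
    W = float(np.prod(eig) / (eig.mean() ** d))
    f = 1.0 - (2 * d * d + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f * np.log(W)
    ddof = d * (d + 1) // 2 - 1
    p = float(sps.chi2.sf(chi2, ddof))
    return W, p


def rm_anova(table: pd.DataFrame, measure: str) -> RmAnovaResult:
    """One-way within-subject ANOVA with GG correction for one measure.

    F = MS_state / MS_error from the two-way (subject x state) sum-of-
    squares decomposition; df = (k-1, (k-1)(n-1)); partial eta squared =
    SS_state / (SS_state + SS_error).  The GG-corrected p is always
    reported alongside the uncorrected p.
    """
    wide = _wide(table, measure)
    Y = wide.to_numpy(dtype=float)
    n, k = Y.shape
    grand = Y.mean()
    ss_state = n * np.sum((Y.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((Y.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((Y - grand) ** 2)
    ss_err = ss_total - ss_state - ss_subj
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_state = ss_state / df1
    ms_err = ss_err / df2
    scale = max(ss_total, 1.0)
    if ms_err <= 1e-12 * scale:
        if ms_state <= 1e-12 * scale:
            # all condition columns identical: no effect, no error variance
            return RmAnovaResult(
                measure=measure, F=0.0, df1=df1, df2=df2, eps_gg=1.0,
                p_uncorrected=1.0, p_gg=1.0, eta_p2=0.0,
                sphericity_W=1.0, sphericity_p=1.0,
            )
        raise DegenerateDataError(f"zero error variance for {measure!r}")
    F = ms_state / ms_err
    eta_p2 = ss_state / (ss_state + ss_err)
    cov = np.cov(Y, rowvar=False)
    eps = gg_epsilon(cov)
    W, p_sph = mauchly_w(cov, n)
    p_unc = float(sps.f.sf(F, df1, df2))
    p_gg = float(sps.f.sf(F, df1 * eps, df2 * eps))
    return RmAnovaResult(
        measure=measure,
        F=float(F),
        df1=df1,
        df2=df2,
        eps_gg=eps,
        p_uncorrected=p_unc,
        p_gg=p_gg,
        eta_p2=float(eta_p2),
        sphericity_W=W,
        sphericity_p=p_sph,
    )


def cohens_d(m1: float, s1: float, m2: float, s2: float) -> float:
    """Cohen's d with root-mean-square pooled SD, reported as |d|.

    d = |m1 - m2| / sqrt((s1^2 + s2^2) / 2).  This convention reproduces
    the published post hoc effect sizes from the published per-state
    means/SDs.
    """
    if s1 <= 0 or s2 <= 0:
        raise DegenerateDataError("standard deviations must be positive")
    return float(abs(m1 - m2) / np.sqrt((s1 * s1 + s2 * s2) / 2.0))


def _d_ci(d: float, n: int) -> tuple[float, float]:
    # normal approximation for a within-subject standardized difference:
    # Var(d) ~ 1/n + d^2 / (2 n)
    se = np.sqrt(1.0 / n + d * d / (2.0 * n))
    return (float(d - 1.96 * se), float(d + 1.96 * se))


def posthoc_bonferroni(table: pd.DataFrame, measure: str) -> list[PosthocResult]:
    """Bonferroni-corrected paired t-tests for all three state pairs.

    p is multiplied by the number of comparisons (3) and capped at 1;
    Cohen's d uses the per-state SDs (rms-pooled, absolute value).  A
    zero-variance difference vector yields a degenerate-test flag instead
    of a t statistic.
    """
    wide = _wide(table, measure)
    Y = wide.to_numpy(dtype=float)
    n = Y.shape[0]
    states = list(wide.columns)
    out = []
    m = Y.mean(axis=0)
    s = Y.std(axis=0, ddof=1)
    n_pairs = len(list(combinations(range(len(states)), 2)))
    for i, j in combinations(range(len(states)), 2):
        diff = Y[:, i] - Y[:, j]
        if np.allclose(diff.std(ddof=1), 0.0):
            out.append(
                PosthocResult(
                    measure=measure,
                    pair=(states[i], states[j]),
                    t=np.nan,
                    df=n - 1,
                    p_bonf=1.0,
                    d=0.0 if np.allclose(diff, 0) else np.inf,
                    ci95=(np.nan, np.nan),
                    degenerate=True,
                )
            )
            continue
        t, p = sps.ttest_rel(Y[:, i], Y[:, j])
        d = cohens_d(m[i], s[i], m[j], s[j])
        out.append(
            PosthocResult(
                measure=measure,
                pair=(states[i], states[j]),
                t=float(t),
                df=n - 1,
                p_bonf=float(min(1.0, n_pairs * p)),
                d=d,
                ci95=_d_ci(d, n),
            )
        )
    return out


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> CorrResult:
    """Pearson product-moment correlation with a two-tailed t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DegenerateDataError("need paired vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DegenerateDataError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return CorrResult(x="x", y="y", r=float(r), p=float(p), n=int(x.size))


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_table(
    long: pd.DataFrame,
    metric_names=ref.METRIC_NAMES,
    scale_names=ref.SCALE_NAMES,
) -> pd.DataFrame:
    """Pearson r between each scale and each metric, pooling all sessions.

    Observations are participant x state sessions (n = 78 at study scale).
    """
    wide = long.pivot_table(
        index=["participant_id", "state"], columns="measure", values="value"
    )
    rows = []
    for s in scale_names:
        for m in metric_names:
            res = pearson_with_p(wide[s].to_numpy(), wide[m].to_numpy())
            rows.append(
                {"scale": s, "metric": m, "r": res.r, "p": res.p, "n": res.n,
                 "sig": stars(res.p)}
            )
    return pd.DataFrame(rows)


def run_battery(long: pd.DataFrame, out_dir: str | Path | None = None) -> dict:
    """Full statistical report: ANOVA + post hocs per measure, correlations.

    Returns dict of DataFrames (``anova``, ``posthoc``, ``correlations``);
    writes CSVs plus a human-readable report if ``out_dir`` is given.
    """
    measures = sorted(long["measure"].unique())
    anova_rows, post_rows = [], []
    for meas in measures:
        res = rm_anova(long, meas)
        anova_rows.append(
            {
                "measure": meas,
                "F": res.F,
                "df1": res.df1,
                "df2": res.df2,
                "eps_gg": res.eps_gg,
                "p_uncorrected": res.p_uncorrected,
                "p_gg": res.p_gg,
                "eta_p2": res.eta_p2,
                "sphericity_W": res.sphericity_W,
                "sphericity_p": res.sphericity_p,
                "sig": stars(res.p_gg),
            }
        )
        for ph in posthoc_bonferroni(long, meas):
            post_rows.append(
                {
                    "measure": meas,
                    "state_a": ph.pair[0],
                    "state_b": ph.pair[1],
                    "t": ph.t,
                    "df": ph.df,
                    "p_bonf": ph.p_bonf,
                    "d": ph.d,
                    "ci_low": ph.ci95[0],
                    "ci_high": ph.ci95[1],
                    "sig": stars(ph.p_bonf),
                }
            )
    present = set(long["measure"].unique())
    metrics = [m for m in ref.METRIC_NAMES if m in present]
    scales = [s for s in ref.SCALE_NAMES if s in present]
    tables = {
        "anova": pd.DataFrame(anova_rows),
        "posthoc": pd.DataFrame(post_rows),
    }
    if metrics and scales:
        tables["correlations"] = correlation_table(long, metrics, scales)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False, float_format="%.6f")
        with open(out / "report.txt", "w") as fh:
            for name, df in tables.items():
                fh.write(f"== {name} ==\n{df.to_string(index=False)}\n\n")
    return tables
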