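"""Variance-component statistics for replicated multi-scan trait tables.

Each trait Y is analyzed with the linear mixed model

    Y = mu + Genotype + Rep + Col + Row + E,

where Rep is the scan (each scan is one replicate) and Row/Col are the
spatial position of the well inside the scan.  Variance components are
estimated by REML; components that collapse to the zero boundary (the
constrained analogue of a negative estimate) are pruned smallest-first and
the model refit.  With genotype random the fit yields EBLUPs, variance
components, R^2 = 1 - sigma2_e / var(Y), and the entry-mean repeatability

    R = sigma2_g / (sigma2_g + sigma2_e / r),

with r the number of replicate scans.  With genotype fixed the fit yields
BLUEs, compared pairwise by the Tukey-Kramer HSD with a compact letter
display.  Residual normality is checked by the Anderson-Darling test at
alpha = 0.05, with a log10 refit for non-normal, strictly positive traits.
Pearson correlations (significance flagged at p < 0.01) relate EBLUPs of
CT traits to each other and to external reference measurements.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

DEFAULT_EFFECTS = ("genotype", "rep", "col", "row")

#: A variance component below this fraction of the response variance is
#: treated as a zero-boundary (would-be-negative) estimate and pruned.
BOUNDARY_TOL = 1e-6

AD_ALPHA = 0.05


@dataclass
class ModelFit:
    """One trait's fitted mixed model and derived summaries."""

    response: str
    components: dict[str, float]
    sigma2_e: float
    dropped: list[str]
    r_squared: float
    n_reps: int
    residuals: np.ndarray
    df_resid: int
    transform: str = "none"
    repeatability: float | None = None
    eblups: pd.Series | None = None
    blues: pd.Series | None = None
    ad_statistic: float | None = None
    ad_critical: float | None = None
    ad_normal: bool | None = None
    genotype_reps: pd.Series | None = None
    hsd: float | None = None
    letters: pd.Series | None = None
    prune_trace: list[str] = dc_field(default_factory=list)

    def summary_dict(self) -> dict:
        out = {
            "response": self.response,
            "transform": self.transform,
            "sigma2_e": self.sigma2_e,
            "r_squared": self.r_squared,
            "repeatability": self.repeatability,
            "dropped": list(self.dropped),
            "hsd": self.hsd,
            "ad_statistic": self.ad_statistic,
            "ad_normal": self.ad_normal,
        }
        out.update({f"sigma2_{k}": v for k, v in self.components.items()})
        return out


def repeatability(sigma2_g: float, sigma2_e: float, r: int) -> float:
    """Entry-mean repeatability ``sigma2_g / (sigma2_g + sigma2_e / r)``.

    Monotone increasing in both ``sigma2_g`` and ``r``; NaN when both
    variances are zero.
    """
    if sigma2_g < 0 or sigma2_e < 0:
        raise ValueError("variance components must be non-negative")
    if r < 1:
        raise ValueError("r must be >= 1")
    if sigma2_g == 0 and sigma2_e == 0:
        return float("nan")
    return sigma2_g / (sigma2_g + sigma2_e / r)


def _clean(table: pd.DataFrame, response: str, effects) -> pd.DataFrame:
    cols = [response] + [e for e in effects]
    df = table[cols].dropna().copy()
    if len(df) < 3:
        raise ValueError(f"too few complete observations for {response}")
    return df


@dataclass
class _RemlResult:
    """One profile-REML fit of ``y = X beta + sum_i Z_i u_i + e``."""

    beta: pd.Series
    components: dict[str, float]  # per random effect
    sigma2_e: float
    blups: dict[str, pd.Series]
    resid: np.ndarray  # conditional residuals
    loglik: float
    converged: bool


def _dummies(col: pd.Series) -> tuple[np.ndarray, list]:
    levels = sorted(col.unique())
    lut = {lv: i for i, lv in enumerate(levels)}
    Z = np.zeros((len(col), len(levels)))
    Z[np.arange(len(col)), col.map(lut).to_numpy()] = 1.0
    return Z, levels


def _reml_fit(df, response, effects, fixed_effect=None) -> _RemlResult:
    """Profile REML over variance ratios gamma_i = sigma2_i / sigma2_e.

    ``fixed_effect`` names a column modeled as fixed cell means (no
    intercept); with ``None`` the fixed part is the grand mean.  The
    ratios are optimized under a non-negativity bound, so a would-be
    negative component comes back exactly at the zero boundary.
    """
    y = df[response].to_numpy(dtype=float)
    n = len(y)
    if fixed_effect is None:
        X = np.ones((n, 1))
        beta_index = ["(mean)"]
    else:
        X, beta_index = _dummies(df[fixed_effect])
    p = X.shape[1]
    Zs = [_dummies(df[e]) for e in effects]

    def profile(gammas):
        """Negative REML log-likelihood profiled over beta and sigma2_e."""
        V0 = np.eye(n)
        for g, (Z, _) in zip(gammas, Zs):
            V0 += g * (Z @ Z.T)
        sign, logdet_v = np.linalg.slogdet(V0)
        Vi = np.linalg.inv(V0)
        XtVi = X.T @ Vi
        A = XtVi @ X
        beta = np.linalg.solve(A, XtVi @ y)
        r = y - X @ beta
        quad = float(r @ Vi @ r)
        sigma2 = quad / (n - p)
        _, logdet_a = np.linalg.slogdet(A)
        nll = 0.5 * (
            (n - p) * np.log(max(sigma2, 1e-300)) + logdet_v + logdet_a + (n - p)
        )
        return nll, beta, r, Vi, sigma2

    if effects:
        from scipy.optimize import minimize

        best = None
        for start in (0.1, 1.0, 10.0):
            res = minimize(
                lambda g: profile(g)[0],
                x0=np.full(len(effects), start),
                method="L-BFGS-B",
                bounds=[(0.0, 1e6)] * len(effects),
            )
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        gammas = best.x
        converged = bool(best.success)
    else:
        gammas = np.array([])
        converged = True

    nll, beta, r, Vi, sigma2 = profile(gammas)
    comps = {e: float(g * sigma2) for e, (g, _) in zip(effects, zip(gammas, Zs))}
    blups, cond = {}, np.zeros(n)
    for e, g, (Z, levels) in zip(effects, gammas, Zs):
        u = g * (Z.T @ (Vi @ r))
        blups[e] = pd.Series(u, index=levels, name=e)
        cond += Z @ u
    return _RemlResult(
        beta=pd.Series(beta, index=beta_index, name="beta"),
        components=comps,
        sigma2_e=float(sigma2),
        blups=blups,
        resid=r - cond,
        loglik=-nll,
        converged=converged,
    )


def _prune_and_fit(df, response, effects, fixed_effect=None):
    """Iteratively drop zero-boundary components (smallest first) and refit."""
    var_y = float(np.var(df[response], ddof=1))
    tol = BOUNDARY_TOL * max(var_y, np.finfo(float).tiny)
    effects = list(effects)
    trace: list[str] = []
    dropped: list[str] = []
    while True:
        res = _reml_fit(df, response, effects, fixed_effect)
        boundary = sorted(
            (e for e in effects if res.components[e] <= tol),
            key=lambda e: res.components[e],
        )
        if not boundary:
            return res, res.components, dropped, trace
        worst = boundary[0]
        trace.append(
            f"dropped {worst} (component {res.components[worst]:.3g} at zero boundary)"
        )
        dropped.append(worst)
        effects.remove(worst)


def _df_resid(df: pd.DataFrame, response: str, effects: list[str]) -> int:
    """Residual df of the all-factors-fixed analogue of the final model."""
    X = np.ones((len(df), 1))
    for e in effects:
        X = np.hstack([X, pd.get_dummies(df[e]).to_numpy(dtype=float)])
    return len(df) - int(np.linalg.matrix_rank(X))


def _anderson_normal(resid):
    """Anderson-Darling normality statistic and its 5% critical value."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        ad = sps.anderson(resid, dist="norm")
    crit = float(ad.critical_values[list(ad.significance_level).index(AD_ALPHA * 100)])
    return ad, crit


def _maybe_log10(table, response, effects, fit_fn):
    """Anderson-Darling gate: refit on log10 response when residuals fail."""
    fit = fit_fn(table, response)
    resid = fit.residuals
    if np.allclose(resid, resid[0]):
        log.warning("constant residuals for %s; normality check skipped", response)
        return fit
    ad, crit = _anderson_normal(resid)
    fit.ad_statistic = float(ad.statistic)
    fit.ad_critical = crit
    fit.ad_normal = bool(ad.statistic < crit)
    if fit.ad_normal:
        return fit
    if (table[response] <= 0).any():
        raise ValueError(
            f"{response} fails the normality check but has non-positive values; "
            "cannot apply the log10 transform"
        )
    logged = table.copy()
    logged[response] = np.log10(logged[response])
    refit = fit_fn(logged, response)
    refit.transform = "log10"
    resid = refit.residuals
    if not np.allclose(resid, resid[0]):
        ad, crit = _anderson_normal(resid)
        refit.ad_statistic = float(ad.statistic)
        refit.ad_critical = crit
        refit.ad_normal = bool(ad.statistic < crit)
    return refit


def fit_random_model(
    table: pd.DataFrame,
    response: str,
    effects=DEFAULT_EFFECTS,
    check_normality: bool = True,
) -> ModelFit:
    """All-random REML fit: variance components, EBLUPs, R^2, repeatability."""

    def _fit(tab, resp):
        df = _clean(tab, resp, list(dict.fromkeys(["rep", *effects])))
        if df["rep"].nunique() < 2:
            raise ValueError("need at least two replicates (scans)")
        res, comps, dropped, trace = _prune_and_fit(df, resp, effects, None)
        sigma2_e = res.sigma2_e
        var_y = float(np.var(df[resp], ddof=1))
        genos = sorted(df["genotype"].unique())
        eblups = res.blups.get(
            "genotype", pd.Series(0.0, index=genos)
        ).rename("eblup")
        n_reps = int(df["rep"].nunique())
        s2g = comps.get("genotype", 0.0)
        fit = ModelFit(
            response=resp,
            components=comps,
            sigma2_e=sigma2_e,
            dropped=dropped,
            r_squared=(1.0 - sigma2_e / var_y) if var_y > 0 else float("nan"),
            n_reps=n_reps,
            residuals=np.asarray(res.resid),
            df_resid=_df_resid(df, resp, [e for e in effects if e not in dropped]),
            repeatability=(
                repeatability(s2g, sigma2_e, n_reps)
                if (s2g > 0 or sigma2_e > 0)
                else float("nan")
            ),
            eblups=eblups,
            prune_trace=trace,
        )
        return fit

    if not check_normality:
        return _fit(table, response)
    return _maybe_log10(table, response, effects, _fit)


def fit_fixed_model(
    table: pd.DataFrame,
    response: str,
    effects=DEFAULT_EFFECTS,
    check_normality: bool = True,
) -> ModelFit:
    """Genotype-fixed fit: BLUEs plus the random nuisance components.

    In a fully balanced design with no missing values the BLUEs equal the
    genotype raw means.
    """
    rand = [e for e in effects if e != "genotype"]

    def _fit(tab, resp):
        df = _clean(tab, resp, list(dict.fromkeys(["genotype", "rep", *effects])))
        res, comps, dropped, trace = _prune_and_fit(df, resp, rand, "genotype")
        sigma2_e = res.sigma2_e
        var_y = float(np.var(df[resp], ddof=1))
        blues = res.beta.rename("blue").sort_index()
        kept = ["genotype"] + [e for e in rand if e not in dropped]
        fit = ModelFit(
            response=resp,
            components=comps,
            sigma2_e=sigma2_e,
            dropped=dropped,
            r_squared=(1.0 - sigma2_e / var_y) if var_y > 0 else float("nan"),
            n_reps=int(df["rep"].nunique()),
            residuals=np.asarray(res.resid),
            df_resid=_df_resid(df, resp, kept),
            blues=blues,
            genotype_reps=df.groupby("genotype").size(),
            prune_trace=trace,
        )
        return fit

    if not check_normality:
        return _fit(table, response)
    return _maybe_log10(table, response, effects, _fit)


def tukey_hsd(fit: ModelFit, alpha: float = 0.05):
    """Tukey-Kramer HSD on the BLUEs of a genotype-fixed fit.

    Returns ``(hsd, pairwise, letters)``: the least significant difference
    at the harmonic-mean replication, a boolean significance matrix using
    the Tukey-Kramer unequal-replication standard errors, and a compact
    letter display.  The fit's HSD fields are filled in place.
    """
    if fit.blues is None:
        raise ValueError("tukey_hsd requires a genotype-fixed fit with BLUEs")
    if fit.df_resid <= 0:
        raise ValueError("no residual degrees of freedom for the HSD test")
    means = fit.blues
    reps = fit.genotype_reps.reindex(means.index)
    k = len(means)
    q = sps.studentized_range.ppf(1 - alpha, k, fit.df_resid)
    r_harm = k / (1.0 / reps).sum()
    hsd = float(q * np.sqrt(fit.sigma2_e / r_harm))
    diff = np.abs(means.to_numpy()[:, None] - means.to_numpy()[None, :])
    se = np.sqrt(
        fit.sigma2_e / 2.0 * (1.0 / reps.to_numpy()[:, None] + 1.0 / reps.to_numpy()[None, :])
    )
    signif = pd.DataFrame(
        diff > q * se, index=means.index, columns=means.index
    )
    np.fill_diagonal(signif.values, False)
    letters = _compact_letters(means, signif)
    fit.hsd = hsd
    fit.letters = letters
    return hsd, signif, letters


def _compact_letters(means: pd.Series, signif: pd.DataFrame) -> pd.Series:
    """Insert-and-absorb compact letter display (highest mean gets 'a')."""
    order = means.sort_values(ascending=False).index.tolist()
    columns: list[set] = [set(order)]
    for i, gi in enumerate(order):
        for gj in order[i + 1 :]:
            if not signif.loc[gi, gj]:
                continue
            for col in [c for c in columns if gi in c and gj in c]:
                columns.remove(col)
                for drop in (gi, gj):
                    new = col - {drop}
                    if new and not any(new <= other for other in columns):
                        columns.append(new)
        # absorb: remove columns that became subsets
        columns = [
            c for c in columns if not any(c < other for other in columns)
        ]
    columns.sort(key=lambda c: min(order.index(g) for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in order}
    for letter, col in zip(alphabet, columns):
        for g in order:
            if g in col:
                out[g] += letter
    return pd.Series(out, name="letters").reindex(means.index)


def correlation_matrix(
    table: pd.DataFrame, external: pd.DataFrame | None = None, p_threshold: float = 0.01
):
    """Pairwise Pearson correlations of genotype-level trait estimates.

    ``table`` has one row per genotype with numeric trait columns (EBLUPs
    or BLUEs), indexed or keyed by ``genotype``; ``external`` optionally
    adds reference columns (joined on genotype).  Returns ``(r, p, flag)``
    DataFrames, with zero-variance columns reported as NaN.
    """
    df = table.copy()
    if "genotype" in df.columns:
        df = df.set_index("genotype")
    if external is not None:
        ext = external.copy()
        if "genotype" in ext.columns:
            ext = ext.set_index("genotype")
        df = df.join(ext, how="inner")
    df = df.select_dtypes(include=[np.number])
    if len(df) < 3:
        raise ValueError("need at least 3 genotypes for correlations")
    cols = df.columns
    n = len(cols)
    r = np.full((n, n), np.nan)
    p = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            x, y = df.iloc[:, i], df.iloc[:, j]
            ok = x.notna() & y.notna()
            if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
                continue
            rr, pp = sps.pearsonr(x[ok], y[ok])
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    return r_df, p_df, p_df < p_threshold


def analyze_trait_table(
    table: pd.DataFrame,
    traits: list[str] | None = None,
    effects=DEFAULT_EFFECTS,
    alpha: float = 0.05,
) -> dict:
    """Full per-trait analysis: random fit, fixed fit, HSD, correlations."""
    from .traits import TRAIT_COLUMNS

    if traits is None:
        traits = [t for t in TRAIT_COLUMNS if t in table.columns]
    random_fits, fixed_fits = {}, {}
    for t in traits:
        random_fits[t] = fit_random_model(table, t, effects)
        fx = fit_fixed_model(table, t, effects)
        tukey_hsd(fx, alpha)
        fixed_fits[t] = fx
    eblup_table = pd.DataFrame(
        {t: random_fits[t].eblups for t in traits}
    )
    r, p, flags = correlation_matrix(eblup_table)
    return {
        "random": random_fits,
        "fixed": fixed_fits,
        "eblups": eblup_table,
        "correlations": {"r": r, "p": p, "significant": flags},
    }


def simulate_trait_table(
    n_genotypes: int = 19,
    n_reps: int = 3,
    n_rows: int = 3,
    n_cols: int = 7,
    n_check_wells: int = 3,
    mean: float = 20.0,
    sigma2_g: float = 4.0,
    sigma2_e: float = 1.0,
    sigma2_rep: float = 0.5,
    sigma2_row: float = 0.1,
    sigma2_col: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a trait table directly from the mixed model.

    Mirrors the scanned design: a rows-by-cols well grid per scan, each
    scan one replicate, every genotype once per scan except the first
    (check) genotype which fills the spare wells.  Returns the table and
    the true genotype effects (for EBLUP validation).
    """
    rng = np.random.default_rng(seed)
    genos = [f"G{i:02d}" for i in range(1, n_genotypes + 1)]
    n_wells = n_rows * n_cols
    entries = genos + [genos[0]] * (n_check_wells - 1)
    if len(entries) != n_wells:
        raise ValueError("genotypes + check wells must fill the well grid")
    g_eff = pd.Series(rng.normal(0, np.sqrt(sigma2_g), n_genotypes), index=genos)
    rows = []
    for rep in range(1, n_reps + 1):
        rep_eff = rng.normal(0, np.sqrt(sigma2_rep))
        row_eff = rng.normal(0, np.sqrt(sigma2_row), n_rows)
        col_eff = rng.normal(0, np.sqrt(sigma2_col), n_cols)
        perm = rng.permutation(n_wells)
        for w, gi in enumerate(perm):
            g = entries[gi]
            r_i, c_i = w // n_cols, w % n_cols
            y = (
                mean
                + g_eff[g]
                + rep_eff
                + row_eff[r_i]
                + col_eff[c_i]
                + rng.normal(0, np.sqrt(sigma2_e))
            )
            rows.append(
                {"genotype": g, "rep": rep, "row": r_i + 1, "col": c_i + 1, "y": y}
            )
    return pd.DataFrame(rows), g_eff
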