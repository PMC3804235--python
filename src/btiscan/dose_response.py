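"""Log-probit bioassay analysis.

Mortality data from larval bioassays are modelled as

    probit(p) = alpha + beta * log10(dose)

fitted by binomial maximum likelihood (IRLS).  Natural (control) mortality is
removed beforehand with Abbott's formula.  Lethal concentrations LC50/LC95
come from inverting the fitted line, with 95% fiducial limits from Fieller's
theorem on the ratio (probit(q) - alpha) / beta.  When replicate heterogeneity
is detected (Pearson chi-square significant at 5% and h = chi2/df > 1), the
variance-covariance matrix is inflated by h and a t multiplier replaces the
normal one — the classic heterogeneity adjustment of probit practice.

Resistance ratios divide a population's LC by the susceptible reference's LC;
their confidence interval takes the widest ("extreme") ratio of the fiducial
bounds, and a ratio is flagged significant only when the two fiducial
intervals do not overlap AND the ratio's CI excludes 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "BioassayTable",
    "DoseResponseFit",
    "ResistanceRatio",
    "abbott_correct",
    "fit_probit",
    "lethal_concentration",
    "resistance_ratio",
]


@dataclass
class BioassayTable:
    """Dose-mortality records for one population.

    ``records`` is a DataFrame with columns concentration (0 allowed for
    controls), n_exposed, n_dead, replicate.
    """

    population: str
    records: pd.DataFrame

    def __post_init__(self):
        req = {"concentration", "n_exposed", "n_dead", "replicate"}
        missing = req - set(self.records.columns)
        if missing:
            raise ValueError(f"bioassay table missing columns {sorted(missing)}")
        r = self.records
        if (r["concentration"] < 0).any():
            raise ValueError("concentrations must be >= 0 (0 = control)")
        if ((r["n_dead"] < 0) | (r["n_dead"] > r["n_exposed"])).any():
            raise ValueError("need 0 <= n_dead <= n_exposed")
        n_conc = r.loc[r["concentration"] > 0, "concentration"].nunique()
        if n_conc < 5:
            warnings.warn(
                f"{self.population}: only {n_conc} distinct concentrations; "
                "at least five are recommended",
                stacklevel=2,
            )

    @property
    def doses(self) -> np.ndarray:
        return np.sort(
            self.records.loc[self.records["concentration"] > 0, "concentration"]
            .unique()
        )


@dataclass
class DoseResponseFit:
    population: str
    alpha: float
    beta: float
    cov: np.ndarray  # 2x2 vcov of (alpha, beta), heterogeneity-adjusted
    heterogeneity: float  # h = Pearson chi2 / df
    heterogeneity_significant: bool
    df_resid: int
    converged: bool
    n_total: int

    @property
    def multiplier(self) -> float:
        """95% two-sided critical value: t when heterogeneity was flagged."""
        if self.heterogeneity_significant:
            return float(stats.t.ppf(0.975, self.df_resid))
        return float(stats.norm.ppf(0.975))


@dataclass
class ResistanceRatio:
    quantile: float
    ratio: float
    ci_low: float
    ci_high: float
    significant: bool


def abbott_correct(observed_mortality: float, control_mortality: float) -> float:
    """Abbott's correction (obs - ctrl) / (1 - ctrl), clamped to [0, 1]."""
    if not (0.0 <= observed_mortality <= 1.0):
        raise ValueError("observed mortality must lie in [0, 1]")
    if not (0.0 <= control_mortality < 1.0):
        raise ValueError("control mortality must lie in [0, 1)")
    corrected = (observed_mortality - control_mortality) / (1.0 - control_mortality)
    if corrected < 0.0:
        warnings.warn(
            "observed mortality below control mortality; corrected value clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return float(min(1.0, corrected))


def _control_mortality(records: pd.DataFrame, per_replicate: bool) -> dict:
    """Control mortality per replicate id (or a single pooled value)."""
    ctrl = records[records["concentration"] == 0]
    if ctrl.empty:
        return {}
    if per_replicate:
        grouped = ctrl.groupby("replicate").agg(
            dead=("n_dead", "sum"), n=("n_exposed", "sum")
        )
        return {rep: row.dead / row.n for rep, row in grouped.iterrows()}
    pooled = ctrl["n_dead"].sum() / ctrl["n_exposed"].sum()
    return {None: pooled}


def fit_probit(
    table: BioassayTable,
    abbott_per_replicate: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> DoseResponseFit:
    """Maximum-likelihood probit fit of mortality on log10(dose).

    Control rows (concentration 0) supply Abbott's correction, applied per
    replicate by default (pooled across replicates otherwise).  Doses with 0%
    or 100% mortality stay in the likelihood.
    """
    rec = table.records
    ctrl = _control_mortality(rec, abbott_per_replicate)
    rows = rec[rec["concentration"] > 0].copy()
    if rows.empty:
        raise ValueError(f"{table.population}: no positive-dose records")

    obs = rows["n_dead"] / rows["n_exposed"]
    if ctrl:
        def _c(rep):
            if None in ctrl:
                return ctrl[None]
            return ctrl.get(rep, 0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corrected = np.array(
                [abbott_correct(o, _c(rep)) for o, rep in zip(obs, rows["replicate"])]
            )
    else:
        corrected = obs.to_numpy(dtype=float)

    # identifiability: need some partial mortality across dose levels
    by_dose = pd.DataFrame(
        {"dose": rows["concentration"], "p": corrected, "n": rows["n_exposed"]}
    ).groupby("dose").apply(lambda d: np.average(d["p"], weights=d["n"]),
                            include_groups=False)
    if np.all((by_dose <= 0.0) | (by_dose >= 1.0)):
        raise ValueError(
            f"{table.population}: slope unidentifiable (all-or-nothing "
            "mortality at every dose)"
        )

    x = np.log10(rows["concentration"].to_numpy(dtype=float))
    X = sm.add_constant(x)
    n = rows["n_exposed"].to_numpy(dtype=float)
    model = sm.GLM(
        corrected, X, family=sm.families.Binomial(sm.families.links.Probit()),
        var_weights=n,
    )
    res = model.fit(maxiter=max_iter, tol=tol)
    alpha, beta = float(res.params[0]), float(res.params[1])
    cov = np.asarray(res.cov_params())

    df = int(res.df_resid)
    chi2 = float(res.pearson_chi2)
    h = chi2 / df if df > 0 else np.nan
    significant = bool(
        df > 0 and h > 1.0 and stats.chi2.sf(chi2, df) < 0.05
    )
    if significant:
        cov = cov * h

    return DoseResponseFit(
        population=table.population,
        alpha=alpha,
        beta=beta,
        cov=cov,
        heterogeneity=h,
        heterogeneity_significant=significant,
        df_resid=df,
        converged=bool(res.converged),
        n_total=int(n.sum()),
    )


def lethal_concentration(fit: DoseResponseFit, quantile: float = 0.5):
    """LC at the given mortality quantile with 95% fiducial limits.

    The point estimate is 10**((probit(q) - alpha)/beta); limits solve
    Fieller's quadratic for the ratio using the fit's (possibly
    heterogeneity-adjusted) covariance and multiplier.
    """
    if not (0.0 < quantile < 1.0):
        raise ValueError("quantile must lie in (0, 1)")
    if fit.beta <= 0:
        raise ValueError("invalid fit: slope must be positive")
    y0 = stats.norm.ppf(quantile)
    a = y0 - fit.alpha  # numerator of the log10-LC ratio
    b = fit.beta
    var_a = fit.cov[0, 0]
    var_b = fit.cov[1, 1]
    cov_ab = -fit.cov[0, 1]
    m = a / b
    z = fit.multiplier

    if var_a == 0.0 and var_b == 0.0:
        return 10.0**m, 10.0**m, 10.0**m

    g = z**2 * var_b / b**2
    if g >= 1.0:
        raise ValueError("fiducial limits undefined (slope too imprecise, g >= 1)")
    # Fieller: (b^2 - z^2 var_b) m^2 - 2(ab - z^2 cov) m + (a^2 - z^2 var_a) <= 0
    A = b**2 - z**2 * var_b
    B = a * b - z**2 * cov_ab
    C = a**2 - z**2 * var_a
    disc = B**2 - A * C
    if disc < 0:
        raise ValueError("fiducial limits undefined (negative discriminant)")
    root = np.sqrt(disc)
    m_lo, m_hi = (B - root) / A, (B + root) / A
    return float(10.0**m), float(10.0**m_lo), float(10.0**m_hi)


def resistance_ratio(
    pop_fit: DoseResponseFit,
    ref_fit: DoseResponseFit,
    quantile: float = 0.5,
) -> ResistanceRatio:
    """RR = LC_pop / LC_ref with the extreme-bounds CI and the dual
    significance rule (non-overlapping fiducial intervals AND CI > 1)."""
    lc_p, lo_p, hi_p = lethal_concentration(pop_fit, quantile)
    lc_r, lo_r, hi_r = lethal_concentration(ref_fit, quantile)
    if lc_r <= 0:
        raise ValueError("reference LC must be positive")
    rr = lc_p / lc_r
    ci_low = lo_p / hi_r
    ci_high = hi_p / lo_r
    no_overlap = (lo_p > hi_r) or (hi_p < lo_r)
    significant = bool(no_overlap and ci_low > 1.0)
    return ResistanceRatio(
        quantile=quantile, ratio=float(rr),
        ci_low=float(ci_low), ci_high=float(ci_high),
        significant=significant,
    )
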