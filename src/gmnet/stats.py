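"""Statistical layer: z-scoring, adjusted associations, mediation, group tests.

Network measures are z-scored to the control group so slopes are comparable
across measures.  Associations between tau burden and network measures are
ordinary least squares adjusted for age, sex and total intracranial volume
(plus connectivity density for the higher-order measures, and local volume /
degree for regional measures), with false-discovery-rate correction across
global outcomes and Bonferroni correction across regions.  The mediation of
the tau -> cognition effect through network topology uses the linear
product-of-coefficients decomposition with nonparametric percentile
bootstrap confidence intervals: in nested linear models on the same sample
the total effect decomposes exactly as c = c' + a*b, so the average causal
mediation effect (ACME) is a*b and the proportion mediated is a*b / c.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "MediationResult",
    "GroupComparison",
    "zscore_to_reference",
    "fit_linear_association",
    "adjust_pvalues",
    "run_association_suite",
    "mediation_analysis",
    "compare_groups",
    "LinearMediation",
]


@dataclass
class AssociationResult:
    """One covariate-adjusted linear association (one model row)."""

    outcome: str
    predictor: str
    beta: float
    se: float
    t: float
    p: float
    covariates: tuple[str, ...]
    n: int
    group: str | None = None
    p_adjusted: float | None = None
    adjust_method: str | None = None

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["covariates"] = ",".join(self.covariates)
        return d


@dataclass
class MediationResult:
    """Linear product-of-coefficients mediation with bootstrap CIs.

    Paths: a (treatment -> mediator), b (mediator -> outcome, treatment-
    adjusted), c (total effect), c_prime (direct effect), acme = a*b,
    prop_mediated = acme / c.  ``prop_mediated`` is reported even outside
    [0, 1]; ``prop_flagged`` marks a near-zero total effect making the
    proportion unstable.  ``ci`` maps each quantity to a percentile
    bootstrap interval; ``bootstrap_samples`` keeps the replicate draws.
    """

    a: float
    b: float
    c: float
    c_prime: float
    acme: float
    prop_mediated: float
    ci: dict[str, tuple[float, float]]
    n_boot: int
    seed: int | None
    n: int
    treatment: str
    mediator: str
    outcome: str
    covariates: tuple[str, ...]
    prop_flagged: bool = False
    bootstrap_samples: dict[str, np.ndarray] | None = field(default=None, repr=False)


@dataclass
class GroupComparison:
    """Omnibus group test for one variable (ANOVA or chi-squared)."""

    variable: str
    test: str  # "anova" | "chi-squared"
    statistic: float
    p: float
    group_summaries: dict


def zscore_to_reference(values, reference_mask) -> np.ndarray:
    """Standardise values by the reference (control) group's mean and sd."""
    x = np.asarray(values, dtype=float)
    mask = np.asarray(reference_mask, dtype=bool)
    if mask.shape != x.shape:
        raise ValueError("reference_mask must align with values")
    ref = x[mask]
    ref = ref[np.isfinite(ref)]
    if len(ref) < 2:
        raise ValueError("reference group must contain at least 2 observations")
    sd = float(np.std(ref, ddof=1))
    if sd == 0.0:
        raise ValueError("reference group has zero standard deviation")
    return (x - float(np.mean(ref))) / sd


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Names of design columns beyond the numerical rank (QR with pivoting)."""
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diagonal(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [names[i] for i in piv[rank:]]


def fit_linear_association(
    table: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: Sequence[str] = (),
    interaction_with: str | None = None,
) -> AssociationResult:
    """OLS of ``outcome`` on ``predictor`` adjusted for ``covariates``.

    Complete cases only.  With ``interaction_with``, the model adds that
    column and the product term, and the reported coefficient/test is the
    product term's.  Outcomes are used as passed; z-score them first (see
    :func:`zscore_to_reference`) to obtain control-referenced slopes.
    """
    cols = [outcome, predictor, *covariates]
    if interaction_with is not None:
        cols.append(interaction_with)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"columns not in table: {', '.join(missing)}")
    data = table[cols].apply(pd.to_numeric).dropna()

    y = data[outcome].to_numpy(dtype=float)
    names = [predictor, *covariates]
    X = data[names].to_numpy(dtype=float)
    term = predictor
    if interaction_with is not None:
        names.append(interaction_with)
        X = np.column_stack([X, data[interaction_with].to_numpy(dtype=float)])
        term = f"{predictor}:{interaction_with}"
        names.append(term)
        X = np.column_stack(
            [X, data[predictor].to_numpy(float) * data[interaction_with].to_numpy(float)]
        )
    names = ["const", *names]
    X = sm.add_constant(X, has_constant="add")

    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    dof = len(y) - X.shape[1]
    if dof < 10:
        raise ValueError(f"only {dof} residual degrees of freedom (need >= 10)")

    fit = sm.OLS(y, X).fit()
    idx = names.index(term)
    return AssociationResult(
        outcome=outcome,
        predictor=term,
        beta=float(fit.params[idx]),
        se=float(fit.bse[idx]),
        t=float(fit.tvalues[idx]),
        p=float(fit.pvalues[idx]),
        covariates=tuple(covariates),
        n=len(y),
    )


def adjust_pvalues(pvals, method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjustment: Benjamini-Hochberg or Bonferroni."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("fdr_bh", "bonferroni"):
        raise ValueError(f"unknown method {method!r}")
    return multipletests(p, method=method)[1]


def run_association_suite(
    table: pd.DataFrame,
    outcomes: Sequence[str],
    predictor: str,
    covariate_policy: Mapping[str, Sequence[str]] | Callable[[str], Sequence[str]],
    adjust_method: str = "fdr_bh",
    reference_mask=None,
    group_col: str | None = None,
    zscore_outcomes: bool = True,
) -> list[AssociationResult]:
    """One adjusted model per outcome, multiplicity-corrected within tiers.

    Outcomes are z-scored to the reference group (or the whole sample when
    ``reference_mask`` is None).  P-values are adjusted across outcomes
    within each tier: the whole-sample analyses form one tier, and, when
    ``group_col`` is given, each diagnostic group's stratified analyses form
    their own tier.
    """
    policy = covariate_policy if callable(covariate_policy) else covariate_policy.get
    work = table.copy()
    if zscore_outcomes:
        mask = (
            np.ones(len(work), dtype=bool)
            if reference_mask is None
            else np.asarray(reference_mask, dtype=bool)
        )
        for out in outcomes:
            work[out] = zscore_to_reference(work[out].to_numpy(float), mask)

    def _tier(sub: pd.DataFrame, group: str | None) -> list[AssociationResult]:
        results = []
        for out in outcomes:
            covs = policy(out) or ()
            res = fit_linear_association(sub, out, predictor, covariates=covs)
            res.group = group
            results.append(res)
        adjusted = adjust_pvalues([r.p for r in results], method=adjust_method)
        for r, pa in zip(results, adjusted):
            r.p_adjusted = float(pa)
            r.adjust_method = adjust_method
        return results

    all_results = _tier(work, None)
    if group_col is not None:
        for g, sub in work.groupby(group_col, sort=True):
            all_results.extend(_tier(sub, str(g)))
    return all_results


def filter_zscoreable_outcomes(
    table: pd.DataFrame, outcomes: Sequence[str], reference_mask=None
) -> tuple[list[str], list[str]]:
    """Split outcomes into (usable, degenerate) for control-referenced z-scoring.

    An outcome is degenerate when it has non-finite values or when the
    reference group offers fewer than 2 observations or zero variance.
    """
    usable, degenerate = [], []
    for outcome in outcomes:
        vals = table[outcome].to_numpy(dtype=float)
        ref = vals if reference_mask is None else vals[np.asarray(reference_mask, bool)]
        ref = ref[np.isfinite(ref)]
        if len(ref) < 2 or np.std(ref, ddof=1) == 0.0 or not np.isfinite(vals).all():
            degenerate.append(outcome)
        else:
            usable.append(outcome)
    return usable, degenerate


def _lstsq_coefs(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, y, rcond=None)[0]


def mediation_analysis(
    table: pd.DataFrame,
    treatment: str,
    mediator: str,
    outcome: str,
    covariates: Sequence[str] = (),
    n_boot: int = 1000,
    seed: int | None = None,
) -> MediationResult:
    """Linear mediation with nonparametric percentile bootstrap CIs.

    Fits mediator ~ treatment + covariates (path a), outcome ~ treatment +
    mediator + covariates (paths c', b) and outcome ~ treatment + covariates
    (path c) on complete cases; ACME = a*b and proportion mediated =
    ACME / c.  Subjects are resampled with replacement ``n_boot`` times;
    intervals are the 2.5/97.5 percentiles.  Deterministic given ``seed``.
    """
    if n_boot < 500:
        raise ValueError("n_boot must be at least 500")
    cols = [treatment, mediator, outcome, *covariates]
    data = table[cols].apply(pd.to_numeric).dropna()
    n = len(data)
    if n < len(cols) + 3:
        raise ValueError(f"too few complete cases (n={n}) for mediation")

    t = data[treatment].to_numpy(float)
    m = data[mediator].to_numpy(float)
    y = data[outcome].to_numpy(float)
    C = data[list(covariates)].to_numpy(float) if covariates else np.empty((n, 0))
    ones = np.ones((n, 1))

    def paths(idx: np.ndarray) -> tuple[float, float, float, float]:
        Xa = np.column_stack([ones[idx], t[idx], C[idx]])
        a = _lstsq_coefs(Xa, m[idx])[1]
        Xb = np.column_stack([ones[idx], t[idx], m[idx], C[idx]])
        coefs = _lstsq_coefs(Xb, y[idx])
        c_prime, b = coefs[1], coefs[2]
        c = _lstsq_coefs(Xa, y[idx])[1]
        return float(a), float(b), float(c), float(c_prime)

    full = np.arange(n)
    a, b, c, c_prime = paths(full)
    acme = a * b
    prop_flagged = abs(c) < 1e-12
    prop = float("nan") if prop_flagged else acme / c

    rng = np.random.default_rng(seed)
    boot = {k: np.empty(n_boot) for k in ("a", "b", "c", "c_prime", "acme", "prop_mediated")}
    for rep in range(n_boot):
        idx = rng.integers(0, n, size=n)
        ar, br, cr, cpr = paths(idx)
        boot["a"][rep] = ar
        boot["b"][rep] = br
        boot["c"][rep] = cr
        boot["c_prime"][rep] = cpr
        boot["acme"][rep] = ar * br
        boot["prop_mediated"][rep] = (ar * br) / cr if abs(cr) > 1e-12 else np.nan

    ci = {}
    for key, sample in boot.items():
        finite = sample[np.isfinite(sample)]
        if len(finite):
            lo, hi = np.percentile(finite, [2.5, 97.5])
        else:  # pragma: no cover - fully degenerate
            lo = hi = float("nan")
        ci[key] = (float(lo), float(hi))

    return MediationResult(
        a=a,
        b=b,
        c=c,
        c_prime=c_prime,
        acme=acme,
        prop_mediated=prop,
        ci=ci,
        n_boot=n_boot,
        seed=seed,
        n=n,
        treatment=treatment,
        mediator=mediator,
        outcome=outcome,
        covariates=tuple(covariates),
        prop_flagged=prop_flagged,
        bootstrap_samples=boot,
    )


class LinearMediation(BaseEstimator):
    """Estimator wrapper around :func:`mediation_analysis`.

    Parameters name the table columns; :meth:`fit` accepts the subject
    table and exposes ``acme_``, ``prop_mediated_`` and the full
    ``result_``.
    """

    def __init__(
        self,
        treatment: str = "tau",
        mediator: str = "sigma",
        outcome: str = "cognition",
        covariates: tuple[str, ...] = (),
        n_boot: int = 1000,
        random_state: int | None = None,
    ):
        self.treatment = treatment
        self.mediator = mediator
        self.outcome = outcome
        self.covariates = covariates
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, table: pd.DataFrame, y=None):
        self.result_ = mediation_analysis(
            table,
            self.treatment,
            self.mediator,
            self.outcome,
            covariates=self.covariates,
            n_boot=self.n_boot,
            seed=self.random_state,
        )
        self.a_ = self.result_.a
        self.b_ = self.result_.b
        self.c_ = self.result_.c
        self.c_prime_ = self.result_.c_prime
        self.acme_ = self.result_.acme
        self.prop_mediated_ = self.result_.prop_mediated
        return self


def compare_groups(
    table: pd.DataFrame, variable: str, group: str, kind: str | None = None
) -> GroupComparison:
    """One-way ANOVA (continuous) or Pearson chi-squared (categorical).

    ``kind`` may force "anova" or "chi-squared"; by default numeric columns
    get ANOVA.
    """
    data = table[[variable, group]].dropna()
    groups = [g for _, g in data.groupby(group, sort=True)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if kind is None:
        kind = "anova" if pd.api.types.is_numeric_dtype(data[variable]) else "chi-squared"
    if kind == "anova":
        samples = [g[variable].to_numpy(float) for g in groups]
        if any(len(s) < 2 for s in samples):
            raise ValueError("every group needs at least 2 observations for ANOVA")
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            stat, p = scipy.stats.f_oneway(*samples)
        if not np.isfinite(stat):  # zero variance everywhere: no group effect
            stat, p = 0.0, 1.0
        summaries = {
            str(g[group].iloc[0]): {
                "n": int(len(g)),
                "mean": float(g[variable].mean()),
                "sd": float(g[variable].std(ddof=1)),
            }
            for g in groups
        }
    elif kind == "chi-squared":
        crosstab = pd.crosstab(data[group], data[variable])
        stat, p, _, _ = scipy.stats.chi2_contingency(crosstab, correction=False)
        summaries = {str(k): v for k, v in crosstab.T.to_dict().items()}
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    return GroupComparison(
        variable=variable,
        test=kind,
        statistic=float(stat),
        p=float(p),
        group_summaries=summaries,
    )
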