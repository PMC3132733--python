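"""Per-SNP case-control association and genomic control.

Each SNP is tested by the Wald test on its coefficient in an additive-coded
logistic regression

    logit P(case) = b0 + beta * dosage + b_age * age + b_sex * sex,

where dosage counts minor alleles (0/1/2), so ``exp(beta)`` is the
per-allele odds ratio.  Subjects with a missing genotype are dropped for
that SNP only.  SNPs with constant dosage, too few subjects per status, or
evidence of (quasi-)separation are flagged rather than reported with an
unstable OR; flagged SNPs are excluded from downstream gene statistics.

:func:`wald_test` fits one SNP through statsmodels.  :func:`association_scan`
fits all SNPs at once with a vectorised Newton (IRLS) solver: the design
differs across SNPs only in the dosage column, so the per-SNP gradient and
Hessian assemble from a handful of matrix products over a shared covariate
block.  The permutation null refits the whole scan per permutation, which
is what makes this batch path necessary; it agrees with statsmodels to
solver tolerance (see the test suite).

Genomic control estimates the inflation factor λ as the median per-SNP
1-df chi-square statistic divided by 0.4549364 (the chi-square(1) median)
and, when λ > 1, deflates every statistic by λ before recomputing p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .containers import GenotypeMatrix, MonomorphicError

__all__ = [
    "AssociationResult",
    "GenomicControlResult",
    "wald_test",
    "association_scan",
    "genomic_control",
    "CHI2_1_MEDIAN",
]

CHI2_1_MEDIAN = 0.4549364
Z_975 = 1.959964  # standard-normal 97.5% quantile, fixed for CI reproducibility
_BETA_BOUND = 12.0  # |log OR| beyond this is treated as separation


@dataclass(frozen=True)
class AssociationResult:
    """Wald-test output for one SNP.

    ``ci_low``/``ci_high`` are ``exp(beta ∓ 1.959964·se)``.  A flagged
    result (monomorphic, separated, non-converged or under-populated SNP)
    carries ``nan`` statistics and must not enter gene-level statistics.
    """

    snp_id: str
    beta: float
    se: float
    wald_z: float
    p: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    maf: float
    n_used: int
    flagged: bool = False
    flag_reason: str = ""


@dataclass(frozen=True)
class GenomicControlResult:
    """λ estimate plus per-SNP λ-adjusted p-values (= raw p when λ ≤ 1)."""

    lambda_gc: float
    adjusted_p: np.ndarray
    chi2: np.ndarray


def _as_covariate_array(covariates, subject_ids=None) -> np.ndarray | None:
    if covariates is None:
        return None
    if isinstance(covariates, pd.DataFrame):
        if subject_ids is not None:
            if len(covariates) != len(subject_ids) or not np.array_equal(
                covariates.index.to_numpy(dtype=object), np.asarray(subject_ids, dtype=object)
            ):
                raise ValueError("covariate subject ids do not match the genotype matrix")
        cols = {c.lower(): c for c in covariates.columns}
        if "age" in cols and "sex" in cols:
            return covariates[[cols["age"], cols["sex"]]].to_numpy(dtype=float)
        return covariates.select_dtypes("number").to_numpy(dtype=float)
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def _maf_of(dosage: np.ndarray) -> float:
    d = dosage[np.isfinite(dosage)]
    if d.size == 0:
        return np.nan
    f = d.sum() / (2 * d.size)
    return float(min(f, 1.0 - f))


def _flagged(snp_id: str, maf: float, n_used: int, reason: str) -> AssociationResult:
    nan = float("nan")
    return AssociationResult(
        snp_id, nan, nan, nan, nan, nan, nan, nan, maf, n_used, flagged=True, flag_reason=reason
    )


def wald_test(
    dosages: np.ndarray,
    status: np.ndarray,
    covariates=None,
    snp_id: str = "snp",
) -> AssociationResult:
    """Wald test for a single SNP via maximum-likelihood logistic regression.

    ``dosages`` may contain ``nan`` (those subjects are dropped); ``status``
    is 0/1.  Raises :class:`MonomorphicError` for constant dosage and
    ``ValueError`` for constant status or fewer than two subjects in either
    status group among non-missing subjects.  Separation or non-convergence
    yields a flagged result instead of an unreliable p-value.
    """
    dosages = np.asarray(dosages, dtype=float)
    status = np.asarray(status, dtype=float)
    cov = _as_covariate_array(covariates)
    keep = np.isfinite(dosages)
    d, y = dosages[keep], status[keep]
    maf = _maf_of(d)
    n_used = int(keep.sum())
    if np.unique(y).size < 2:
        raise ValueError("status is constant; association is undefined")
    if np.unique(d).size < 2:
        raise MonomorphicError(f"SNP {snp_id} has constant dosage among typed subjects")
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 subjects per status among non-missing")

    X = d[:, None] if cov is None else np.column_stack([d, cov[keep]])
    X = sm.add_constant(X, prepend=True, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200, method="newton", tol=1e-10)
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            return _flagged(snp_id, maf, n_used, "separation")
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if (
        not fit.mle_retvals.get("converged", False)
        or not np.isfinite(beta)
        or not np.isfinite(se)
        or abs(beta) > _BETA_BOUND
    ):
        return _flagged(snp_id, maf, n_used, "separation")
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return AssociationResult(
        snp_id=snp_id,
        beta=beta,
        se=se,
        wald_z=float(z),
        p=float(p),
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z_975 * se)),
        ci_high=float(np.exp(beta + Z_975 * se)),
        maf=maf,
        n_used=n_used,
    )


# ---------------------------------------------------------------------------
# batch scan
# ---------------------------------------------------------------------------

def _batch_logistic_wald(
    dosage_sn: np.ndarray,
    y: np.ndarray,
    cov: np.ndarray | None,
    *,
    tol: float = 1e-9,
    max_iter: int = 40,
):
    """Vectorised Newton fit of one logistic model per SNP.

    ``dosage_sn``: (S, n) with nan for missing; ``y``: (n,) 0/1;
    ``cov``: (n, c) shared covariates or None.  Returns arrays
    (beta, se, n_used, ok) where ``ok`` marks clean converged fits.

    The design is [1, cov..., dosage]; only the dosage column varies by SNP,
    so every gradient/Hessian block is a (S, n) x (n, k) product.  Missing
    subjects enter with weight 0 and residual 0.
    """
    S, n = dosage_sn.shape
    C = np.ones((n, 1)) if cov is None else np.column_stack([np.ones(n), cov])
    k = C.shape[1]
    full_mask = np.isfinite(dosage_sn)
    g_full = np.where(full_mask, dosage_sn, 0.0)
    iu, ju = np.triu_indices(k)
    P = C[:, iu] * C[:, ju]  # (n, k(k+1)/2) shared-block products

    beta_C = np.zeros((S, k))
    ybar = min(max(float(y.mean()), 1e-6), 1 - 1e-6)
    beta_C[:, 0] = np.log(ybar / (1 - ybar))
    beta_g = np.zeros(S)
    H_final = np.zeros((S, k + 1, k + 1))  # each row's Hessian at its last update
    converged = np.zeros(S, dtype=bool)
    active = np.arange(S)

    for _ in range(max_iter):
        g = g_full[active]
        mask = full_mask[active]
        eta = beta_C[active] @ C.T + beta_g[active, None] * g
        np.clip(eta, -30.0, 30.0, out=eta)
        mu = expit(eta)
        w = mu * (1.0 - mu)
        w *= mask
        r = (y[None, :] - mu) * mask
        a = active.size
        grad = np.empty((a, k + 1))
        grad[:, :k] = r @ C
        grad[:, k] = np.einsum("sn,sn->s", r, g)
        wg = w * g
        Hu = w @ P  # (a, pairs)
        H = np.zeros((a, k + 1, k + 1))
        H[:, iu, ju] = Hu
        H[:, ju, iu] = Hu
        b = wg @ C
        H[:, :k, k] = b
        H[:, k, :k] = b
        H[:, k, k] = np.einsum("sn,sn->s", wg, g)
        H[:, np.arange(k + 1), np.arange(k + 1)] += 1e-12
        try:
            delta = np.linalg.solve(H, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover - ridge makes this rare
            H[:, np.arange(k + 1), np.arange(k + 1)] += 1e-8
            delta = np.linalg.solve(H, grad[..., None])[..., 0]
        H_final[active] = H
        beta_C[active] += delta[:, :k]
        beta_g[active] += delta[:, k]
        done = np.max(np.abs(delta), axis=1) < tol
        converged[active[done]] = True
        active = active[~done]
        if active.size == 0:
            break

    # H_final holds each row's Hessian within `tol` of the final estimate,
    # accurate enough for standard errors without a full rebuild
    e_last = np.zeros(k + 1)
    e_last[k] = 1.0
    with np.errstate(all="ignore"):
        try:
            rhs = np.broadcast_to(e_last[:, None], (S, k + 1, 1)).copy()
            var_g = np.linalg.solve(H_final, rhs)[:, k, 0]
        except np.linalg.LinAlgError:  # pragma: no cover
            var_g = np.array([np.linalg.pinv(h)[k, k] for h in H_final])
        se = np.sqrt(var_g)
    n_used = full_mask.sum(axis=1)
    ok = (
        converged
        & np.isfinite(beta_g)
        & np.isfinite(se)
        & (np.abs(beta_g) <= _BETA_BOUND)
        & (se > 0)
    )
    return beta_g, se, n_used, ok


def association_scan(
    genotypes: GenotypeMatrix,
    status: np.ndarray,
    covariates=None,
) -> pd.DataFrame:
    """Wald-test every SNP; return one row per SNP in input order.

    Columns: snp_id, beta, se, wald_z, p, odds_ratio, ci_low, ci_high, maf,
    n_used, flagged, flag_reason.  Monomorphic, under-populated, separated
    and non-converged SNPs are flagged with nan statistics.
    """
    status = np.asarray(status, dtype=float)
    if len(status) != genotypes.n_subjects:
        raise ValueError("status length does not match the genotype matrix")
    cov = _as_covariate_array(covariates, subject_ids=genotypes.subject_ids)
    if genotypes.n_snps == 0:
        return _empty_scan_frame()
    if np.unique(status).size < 2:
        raise ValueError("status is constant; association is undefined")

    D = genotypes.dosages.T  # (S, n)
    mask = np.isfinite(D)
    n_used = mask.sum(axis=1)
    # per-SNP pre-checks
    with np.errstate(invalid="ignore"):
        mono = np.array(
            [np.unique(D[j][mask[j]]).size < 2 if mask[j].any() else True for j in range(D.shape[0])]
        )
    cases = status == 1
    n_case = (mask & cases[None, :]).sum(axis=1)
    n_ctrl = (mask & ~cases[None, :]).sum(axis=1)
    sparse = (n_case < 2) | (n_ctrl < 2)
    fit_mask = ~(mono | sparse)

    beta = np.full(D.shape[0], np.nan)
    se = np.full(D.shape[0], np.nan)
    ok = np.zeros(D.shape[0], dtype=bool)
    if fit_mask.any():
        b, s, _, o = _batch_logistic_wald(D[fit_mask], status, cov)
        beta[fit_mask] = b
        se[fit_mask] = s
        ok[fit_mask] = o

    with np.errstate(invalid="ignore", over="ignore"):
        z = beta / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        or_ = np.exp(beta)
        lo = np.exp(beta - Z_975 * se)
        hi = np.exp(beta + Z_975 * se)
    maf = np.array([_maf_of(D[j]) for j in range(D.shape[0])])

    reason = np.where(mono, "monomorphic", np.where(sparse, "insufficient_subjects", ""))
    reason = np.where(fit_mask & ~ok, "separation", reason)
    flagged = ~ok
    for arr in (beta, se, z, p, or_, lo, hi):
        arr[flagged] = np.nan
    return pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids,
            "beta": beta,
            "se": se,
            "wald_z": z,
            "p": p,
            "odds_ratio": or_,
            "ci_low": lo,
            "ci_high": hi,
            "maf": maf,
            "n_used": n_used.astype(int),
            "flagged": flagged,
            "flag_reason": reason,
        }
    )


def _empty_scan_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": pd.Series(dtype=object),
            "beta": pd.Series(dtype=float),
            "se": pd.Series(dtype=float),
            "wald_z": pd.Series(dtype=float),
            "p": pd.Series(dtype=float),
            "odds_ratio": pd.Series(dtype=float),
            "ci_low": pd.Series(dtype=float),
            "ci_high": pd.Series(dtype=float),
            "maf": pd.Series(dtype=float),
            "n_used": pd.Series(dtype=int),
            "flagged": pd.Series(dtype=bool),
            "flag_reason": pd.Series(dtype=object),
        }
    )


def scan_pvalues(
    dosage_sn: np.ndarray,
    status: np.ndarray,
    cov: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """P-values and validity mask for a pre-masked (S, n) dosage block.

    Lean inner loop for the permutation null: skips OR/CI bookkeeping and
    assumes monomorphic/sparse screening was done by the caller on the
    observed data (dosages do not change across permutations).  Solver
    tolerance is relaxed to 1e-6 — far below the resolution the permuted
    ES ranking can perceive.
    """
    beta, se, _, ok = _batch_logistic_wald(
        dosage_sn, np.asarray(status, float), cov, tol=1e-6, max_iter=30
    )
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return p, ok


def genomic_control(pvalues) -> GenomicControlResult:
    """Estimate inflation λ from p-values and λ-adjust them.

    Each p maps to the chi-square(1) quantile it would have as a 1-df test
    statistic; λ is the median statistic over the chi-square(1) median
    0.4549364.  When λ > 1 every statistic is divided by λ and p recomputed
    from the chi-square(1) tail; when λ ≤ 1 p-values pass through unchanged.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("genomic control needs at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    if lam > 1.0:
        adjusted = stats.chi2.sf(chi2 / lam, df=1)
    else:
        adjusted = p.copy()
    return GenomicControlResult(lambda_gc=lam, adjusted_p=adjusted, chi2=chi2)
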