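"""Matched-set construction and conditional logistic association testing.

The central test contrasts each proband (case) with within-family matched
controls: the three retained pseudo siblings (default design), the two
parents (parent-control design), or the single non-transmitted pseudo
sibling (one-sibling design).  For a matched set with case exposure x_p and
control exposures x_s1..x_sK the conditional likelihood contribution is

    exp(x_p b) / (exp(x_p b) + exp(x_s1 b) + ... + exp(x_sK b))

and the product over families is maximized by Newton-Raphson.  The fitted b
is interpreted as transmission disequilibrium of imputed expression (per SD
when exposures are standardized).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import expression_models as em
from . import trio_genotypes as tg

__all__ = [
    "MatchedSet", "CLRFit", "select_controls", "fit_conditional_logistic",
    "score_test", "run_twas", "run_trio_gwas", "fit_one_sibling",
    "fit_parent_control", "stratified_twas", "conditional_fine_mapping",
    "TwasConfig",
]


@dataclass
class MatchedSet:
    """Exposures for one case and K matched controls (vectors of length q)."""

    family_id: str
    case: np.ndarray
    controls: list[np.ndarray]

    def stack(self) -> np.ndarray:
        return np.vstack([np.atleast_1d(self.case)] + [np.atleast_1d(c) for c in self.controls])


@dataclass
class CLRFit:
    """Result of a conditional logistic fit.

    ``beta``/``se``/``z``/``p`` are scalars for a single exposure and arrays
    for the multivariate (fine-mapping) case.  Under complete separation the
    reported p-value comes from the score test at beta = 0 and ``beta`` is
    capped; ``method`` records which p-value was used.
    """

    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: float | np.ndarray
    loglik: float
    n_families_total: int
    n_families_informative: int
    converged: bool
    separation_flag: bool
    method: str = "wald"  # "wald" | "score" | "none"
    n_iter: int = 0
    collinearity_flag: bool = False

    def scalar(self) -> "CLRFit":
        """Collapse length-1 arrays to floats for the univariate case."""
        for name in ("beta", "se", "z", "p"):
            v = getattr(self, name)
            if np.ndim(v) > 0 and np.size(v) == 1:
                setattr(self, name, float(np.asarray(v).ravel()[0]))
        return self


def select_controls(
    proband_value, config_values, mode: str = "single"
) -> tuple[np.ndarray, int]:
    """Drop the configuration closest to the proband, keep the other three.

    ``mode="single"``: closeness is |value - proband|; ``mode="multivariate"``:
    closeness is the sum of squared differences across genes.  Exactly one
    configuration is removed (the identical one when phasing is exact); ties
    go to the lowest configuration index.  Returns (controls, excluded index).
    """
    cfg = np.asarray(config_values, dtype=float)
    if cfg.shape[0] != 4:
        raise ValueError("expected exactly 4 configuration values")
    pv = np.asarray(proband_value, dtype=float)
    if mode == "single":
        dist = np.abs(cfg - pv)
    elif mode == "multivariate":
        dist = ((cfg - pv[None, :]) ** 2).sum(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    excl = int(np.argmin(dist))  # argmin takes the first minimum: lowest index
    keep = np.ones(4, dtype=bool)
    keep[excl] = False
    return cfg[keep], excl


def _select_controls_batch(proband: np.ndarray, configs: np.ndarray) -> np.ndarray:
    """Vectorized single-exposure control selection over families.

    ``proband``: (N,), ``configs``: (N, 4).  Returns the (N, 4) matched
    exposure matrix with the case in column 0.
    """
    dist = np.abs(configs - proband[:, None])
    excl = dist.argmin(axis=1)
    keep = np.ones_like(configs, dtype=bool)
    keep[np.arange(len(excl)), excl] = False
    controls = configs[keep].reshape(len(proband), 3)
    return np.column_stack([proband, controls])


# ---------------------------------------------------------------------------
# conditional logistic likelihood


def _prepare(exposures: np.ndarray) -> np.ndarray:
    X = np.asarray(exposures, dtype=float)
    if X.ndim == 2:
        X = X[:, :, None]
    if X.ndim != 3:
        raise ValueError("exposures must be (N, K+1) or (N, K+1, q)")
    return X


def _informative_mask(X: np.ndarray) -> np.ndarray:
    """A set is informative iff its K+1 exposure vectors are not all identical."""
    return ~np.all(X == X[:, :1, :], axis=(1, 2))


def _ll_grad_hess(X: np.ndarray, beta: np.ndarray):
    eta = X @ beta  # (N, M)
    etamax = eta.max(axis=1, keepdims=True)
    w = np.exp(eta - etamax)
    denom = w.sum(axis=1, keepdims=True)
    prob = w / denom
    ll = float((eta[:, 0] - (np.log(denom[:, 0]) + etamax[:, 0])).sum())
    mean = np.einsum("nm,nmq->nq", prob, X)
    grad = (X[:, 0, :] - mean).sum(axis=0)
    exx = np.einsum("nm,nmq,nmr->qr", prob, X, X)
    hess = -(exx - np.einsum("nq,nr->qr", mean, mean))
    return ll, grad, hess


def _loglik(X: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    etamax = eta.max(axis=1, keepdims=True)
    denom = np.exp(eta - etamax).sum(axis=1)
    return float((eta[:, 0] - (np.log(denom) + etamax[:, 0])).sum())


def score_test(exposures: np.ndarray) -> tuple[float, float]:
    """Score test of beta = 0 for the conditional likelihood.

    Returns (z, two-sided p) for a single exposure, or (nan, chi-square p)
    for multivariate exposures.  Valid under separation, where the Wald test
    degenerates.
    """
    X = _prepare(exposures)
    X = X[_informative_mask(X)]
    if X.shape[0] == 0:
        return np.nan, np.nan
    m = X.shape[1]
    mean = X.mean(axis=1)  # uniform membership probabilities at beta=0
    u = (X[:, 0, :] - mean).sum(axis=0)
    exx = np.einsum("nmq,nmr->qr", X, X) / m
    info = exx - np.einsum("nq,nr->qr", mean, mean)
    if X.shape[2] == 1:
        z = float(u[0] / np.sqrt(info[0, 0]))
        return z, float(2 * stats.norm.sf(abs(z)))
    chi2 = float(u @ np.linalg.solve(info, u))
    return np.nan, float(stats.chi2.sf(chi2, df=X.shape[2]))


def _detect_separation_1d(X: np.ndarray) -> bool:
    """Case exposure a strict extremum in every informative set (scalar q=1)."""
    case = X[:, 0, 0]
    others = X[:, 1:, 0]
    return bool(np.all(case > others.max(axis=1)) or np.all(case < others.min(axis=1)))


def fit_conditional_logistic(
    exposures: np.ndarray,
    max_iter: int = 50,
    score_tol: float = 1e-8,
    beta_cap: float = 15.0,
    ridge: Optional[float] = None,
) -> CLRFit:
    """Maximize the conditional likelihood by Newton-Raphson with step-halving.

    ``exposures`` is (N, K+1) or (N, K+1, q) with the case in column 0.
    Uninformative sets (all members identical) contribute a constant and are
    dropped; both counts are reported.  Convergence is max |score| <
    ``score_tol``.  Complete separation (the case is the strict extremum in
    every informative set, or |beta| exceeds ``beta_cap`` on the fitted
    scale) is flagged: beta is capped and the p-value falls back to the
    score test at beta = 0.  A near-singular information matrix triggers a
    collinearity warning and a ridge-stabilized step.
    """
    X = _prepare(exposures)
    n_total = X.shape[0]
    mask = _informative_mask(X)
    Xi = X[mask]
    n_info = Xi.shape[0]
    q = X.shape[2]

    if n_info == 0:
        nan = np.full(q, np.nan)
        return CLRFit(nan, nan, nan, np.nan, np.nan, n_total, 0,
                      False, False, method="none").scalar()

    separated = q == 1 and _detect_separation_1d(Xi)
    beta = np.zeros(q)
    ll, grad, hess = _ll_grad_hess(Xi, beta)
    converged = False
    collinear = False
    it = 0
    if not separated:
        for it in range(1, max_iter + 1):
            if np.max(np.abs(grad)) < score_tol:
                converged = True
                break
            neg_hess = -hess
            cond = np.linalg.cond(neg_hess) if q > 1 else 1.0
            if (q > 1 and cond > 1e8) or ridge:
                lam = ridge if ridge else 1e-6 * np.trace(neg_hess) / q
                if q > 1 and cond > 1e8 and not collinear:
                    warnings.warn("near-singular information matrix; "
                                  "ridge-stabilized Newton step used")
                    collinear = True
                neg_hess = neg_hess + lam * np.eye(q)
            try:
                step = np.linalg.solve(neg_hess, grad)
            except np.linalg.LinAlgError:
                collinear = True
                step = np.linalg.lstsq(neg_hess, grad, rcond=None)[0]
            # step-halving: never accept a likelihood decrease
            scale = 1.0
            for _ in range(30):
                cand = beta + scale * step
                ll_new = _loglik(Xi, cand)
                if ll_new >= ll - 1e-12:
                    break
                scale /= 2
            beta = beta + scale * step
            ll, grad, hess = _ll_grad_hess(Xi, beta)
            if np.max(np.abs(beta)) > beta_cap:
                separated = True
                break
        else:
            converged = np.max(np.abs(grad)) < score_tol
        if not separated and not converged and np.max(np.abs(grad)) < score_tol:
            converged = True

    if separated:
        _, grad0, _ = _ll_grad_hess(Xi, np.zeros(q))
        beta = np.clip(np.sign(grad0) * beta_cap if np.all(beta == 0) else np.clip(beta, -beta_cap, beta_cap), -beta_cap, beta_cap)
        warnings.warn("complete separation detected; beta capped and p-value "
                      "taken from the score test at beta=0")
        z_s, p_s = score_test(Xi)
        nanq = np.full(q, np.nan)
        return CLRFit(beta, nanq, np.full(q, z_s), p_s, _loglik(Xi, beta),
                      n_total, n_info, False, True, method="score",
                      n_iter=it).scalar()

    neg_hess = -hess
    if collinear:
        neg_hess = neg_hess + (ridge or 1e-6 * np.trace(neg_hess) / q) * np.eye(q)
    cov = np.linalg.inv(neg_hess)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    fit = CLRFit(beta, se, z, p if q > 1 else float(p[0]), ll, n_total, n_info,
                 converged, False, method="wald", n_iter=it,
                 collinearity_flag=collinear)
    return fit.scalar()


def fit_matched_sets(sets: Sequence[MatchedSet], **kwargs) -> CLRFit:
    """Fit the conditional logistic model on a list of MatchedSet objects."""
    X = np.stack([s.stack() for s in sets])
    return fit_conditional_logistic(X, **kwargs)


# ---------------------------------------------------------------------------
# pipelines


@dataclass
class TwasConfig:
    """Options for the trio TWAS pipeline."""

    standardize: bool = True
    keep_ambiguous: bool = False
    max_weight_loss: float = 0.5  # gene skipped if > this fraction of sum|w| lost
    beta_cap: float = 15.0


def _member_exposures(
    aligned: em.AlignedModel,
    matrix: tg.PhasedGenotypeMatrix,
    trios: Sequence[tg.Trio],
):
    """Imputed expression for probands, parents and the 4 configurations.

    Returns (proband (N,), configs (N, 4), father (N,), mother (N,)) with
    configuration columns ordered as CONFIG_LABELS.  Vectorized across
    families; relies on linearity: a configuration's value is the sum of one
    paternal and one maternal per-haplotype contribution.
    """
    cols = aligned.col_idx
    f_idx = np.array([matrix.sample_index(t.father_id) for t in trios])
    m_idx = np.array([matrix.sample_index(t.mother_id) for t in trios])
    p_idx = np.array([matrix.sample_index(t.proband_id) for t in trios])
    H = matrix.haplotypes
    xF = em.haplotype_values(aligned, H[f_idx][:, cols, :])  # (N, 2)
    xM = em.haplotype_values(aligned, H[m_idx][:, cols, :])
    xP = em.haplotype_values(aligned, H[p_idx][:, cols, :]).sum(axis=1)
    configs = np.stack(
        [xF[:, f - 1] + xM[:, m - 1] for f, m in tg.CONFIG_LABELS], axis=1
    )
    return xP, configs, xF.sum(axis=1), xM.sum(axis=1)


_NA_COLS = ["beta", "se", "z", "p"]


def _fit_row(ident: dict, fit: Optional[CLRFit], reason: str = "") -> dict:
    row = dict(ident)
    if fit is None:
        row.update({c: np.nan for c in _NA_COLS})
        row.update(n_total=0, n_informative=0, converged=False,
                   separation=False, reason=reason)
    else:
        row.update(beta=fit.beta, se=fit.se, z=fit.z, p=fit.p,
                   n_total=fit.n_families_total,
                   n_informative=fit.n_families_informative,
                   converged=fit.converged, separation=fit.separation_flag,
                   reason=reason)
    return row


def run_twas(
    matrix: tg.PhasedGenotypeMatrix,
    trios: Sequence[tg.Trio],
    models: Sequence[em.ExpressionModel],
    config: TwasConfig = TwasConfig(),
) -> pd.DataFrame:
    """Trio TWAS: one conditional logistic fit per gene/tissue model.

    Per model: harmonize -> impute proband and the four pseudo-offspring
    configurations -> drop the configuration with imputed expression closest
    to the proband's -> standardize exposures -> fit.  Genes skipped for
    quality reasons appear as NA rows with the reason; errors never abort
    the run.
    """
    rows = []
    for model in models:
        ident = dict(gene=model.gene, tissue=model.tissue,
                     feature=model.feature_type, cluster=model.cluster)
        try:
            aligned = em.harmonize(model, matrix, keep_ambiguous=config.keep_ambiguous)
            if aligned.n_predictors == 0:
                rows.append(_fit_row(ident, None, "no_predictors_in_matrix"))
                continue
            if aligned.weight_mass_retained < 1.0 - config.max_weight_loss:
                rows.append(_fit_row(ident, None, "excess_weight_loss"))
                continue
            xP, configs, _, _ = _member_exposures(aligned, matrix, trios)
            X = _select_controls_batch(xP, configs)
            if config.standardize:
                X, ok = em.standardize_exposures(X)
                if not ok:
                    rows.append(_fit_row(ident, None, "uninformative"))
                    continue
            fit = fit_conditional_logistic(X, beta_cap=config.beta_cap)
            if fit.n_families_informative == 0:
                rows.append(_fit_row(ident, None, "uninformative"))
                continue
            rows.append(_fit_row(ident, fit))
        except Exception as exc:  # keep going; report per-gene failure
            rows.append(_fit_row(ident, None, f"error: {exc}"))
    return pd.DataFrame(rows)


def run_trio_gwas(
    matrix: tg.PhasedGenotypeMatrix,
    trios: Sequence[tg.Trio],
    config: TwasConfig = TwasConfig(standardize=False),
) -> pd.DataFrame:
    """Trio GWAS: conditional logistic test of each SNP's A1 count.

    For each variant the four recombined genotypes are enumerated from the
    parental haplotypes, one configuration identical to the proband's count
    is excluded, and the proband is contrasted with the remaining three.
    Families where no configuration matches the proband (phasing error) are
    excluded from that variant; variants monomorphic in parents are reported
    uninformative.
    """
    f_idx = np.array([matrix.sample_index(t.father_id) for t in trios])
    m_idx = np.array([matrix.sample_index(t.mother_id) for t in trios])
    p_idx = np.array([matrix.sample_index(t.proband_id) for t in trios])
    H = matrix.haplotypes
    rows = []
    for v, variant in enumerate(matrix.variants):
        ident = dict(chrom=variant.chrom, pos=variant.pos, id=variant.id,
                     ref=variant.ref, alt=variant.alt)
        fh, mh, ph = H[f_idx, v, :], H[m_idx, v, :], H[p_idx, v, :]
        configs = np.stack(
            [fh[:, f - 1] + mh[:, m - 1] for f, m in tg.CONFIG_LABELS], axis=1
        )  # (N, 4)
        pc = ph.sum(axis=1)
        match = configs == pc[:, None]
        has_match = match.any(axis=1)
        n_flagged = int((~has_match).sum())
        configs, pc2 = configs[has_match], pc[has_match]
        if len(pc2) == 0:
            rows.append(_fit_row(ident, None, "no_consistent_families"))
            continue
        drop = match[has_match].argmax(axis=1)  # first (lowest-index) match
        keep = np.ones_like(configs, dtype=bool)
        keep[np.arange(len(drop)), drop] = False
        X = np.column_stack([pc2, configs[keep].reshape(len(pc2), 3)]).astype(float)
        fit = fit_conditional_logistic(X, beta_cap=config.beta_cap)
        if fit.n_families_informative == 0:
            rows.append(_fit_row(ident, None, "monomorphic_in_parents"))
            continue
        row = _fit_row(ident, fit, f"{n_flagged}_families_flagged" if n_flagged else "")
        rows.append(row)
    return pd.DataFrame(rows)


def fit_one_sibling(
    proband_values: np.ndarray,
    sibling_values: np.ndarray,
    regression_mode: str = "unconditional",
) -> CLRFit:
    """One-sibling design: proband vs the non-transmitted pseudo sibling.

    The sibling exposure is father + mother - proband (the two
    non-transmitted haplotypes).  Default is plain logistic regression of
    status (1 = proband, 0 = pseudo sibling) on exposure with an intercept,
    reporting the Wald test of the fitted slope; under quasi-separation the
    Wald SE inflates and the test loses power, which is the behavior of a
    standard GLM fit and is reported as-is (flagged).
    ``regression_mode="conditional"`` fits a 1:1 matched conditional model
    instead (that path uses the score-test fallback under separation).
    """
    xp = np.asarray(proband_values, dtype=float)
    xs = np.asarray(sibling_values, dtype=float)
    if regression_mode == "conditional":
        return fit_conditional_logistic(np.column_stack([xp, xs]))
    if regression_mode != "unconditional":
        raise ValueError(f"unknown regression_mode {regression_mode!r}")
    import statsmodels.api as sm

    y = np.concatenate([np.ones_like(xp), np.zeros_like(xs)])
    x = np.concatenate([xp, xs])
    n = len(xp)
    if np.ptp(x) == 0:
        nan = np.nan
        return CLRFit(nan, nan, nan, np.nan, np.nan, n, 0, False, False, "none")
    design = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=False, maxiter=100)
        except Exception:
            return CLRFit(np.nan, np.nan, np.nan, np.nan, np.nan, n, n,
                          False, True, "none")
    beta, se = float(res.params[1]), float(res.bse[1])
    separated = not res.mle_retvals.get("converged", True) or abs(beta) > 15
    if not np.isfinite(se) or se == 0:
        return CLRFit(beta, np.nan, np.nan, np.nan, float(res.llf), n, n,
                      False, True, "none")
    z = beta / se
    return CLRFit(beta, se, z, float(2 * stats.norm.sf(abs(z))), float(res.llf),
                  n, n, not separated, separated, "wald")


def fit_parent_control(
    proband_values: np.ndarray,
    father_values: np.ndarray,
    mother_values: np.ndarray,
    **kwargs,
) -> CLRFit:
    """Parent-control design: proband matched with its two parents (K = 2)."""
    X = np.column_stack([proband_values, father_values, mother_values])
    return fit_conditional_logistic(X, **kwargs)


def stratified_twas(
    exposures: np.ndarray,
    group_labels: np.ndarray,
    n_permutations: int = 10_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """Two-group stratified fit with a permutation p-value on the effect ratio.

    ``exposures`` is the matched (N, K+1) exposure matrix for one gene;
    ``group_labels`` assigns each family to one of two groups.  The ratio
    statistic beta_group1 / beta_group2 is compared with its null
    distribution from shuffling the group labels across families; the
    one-sided p-value is (r + 1) / (B + 1) for r replicates with ratio >=
    observed.  Groups with fewer than two informative families yield NA.
    """
    if n_permutations < 1:
        raise ValueError("need >= 1 permutation")
    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(uniq)}")
    X = np.asarray(exposures, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)

    def group_betas(lab):
        betas = {}
        for g in uniq:
            Xg = X[lab == g]
            fit = fit_conditional_logistic(Xg) if len(Xg) else None
            if fit is None or fit.n_families_informative < 2:
                betas[g] = (np.nan, None)
            else:
                betas[g] = (fit.beta, fit)
        return betas

    obs = group_betas(labels)
    fits = {g: obs[g][1] for g in uniq}
    b1, b2 = obs[uniq[0]][0], obs[uniq[1]][0]
    ratio = b1 / b2 if np.isfinite(b1) and np.isfinite(b2) and b2 != 0 else np.nan
    r = 0
    if np.isfinite(ratio):
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            pb = group_betas(perm)
            p1, p2 = pb[uniq[0]][0], pb[uniq[1]][0]
            if np.isfinite(p1) and np.isfinite(p2) and p2 != 0 and p1 / p2 >= ratio:
                r += 1
        p_perm = (r + 1) / (n_permutations + 1)
    else:
        p_perm = np.nan
    return {"fits": fits, "ratio": ratio, "permutation_p": p_perm,
            "n_permutations": n_permutations}


def conditional_fine_mapping(
    matrix: tg.PhasedGenotypeMatrix,
    trios: Sequence[tg.Trio],
    models: Sequence[em.ExpressionModel],
    config: TwasConfig = TwasConfig(),
) -> tuple[CLRFit, pd.DataFrame]:
    """Joint conditional analysis of co-localized genes in one tissue.

    All genes' imputed expressions enter one multivariate conditional
    logistic model over a shared pseudo-sibling window; the excluded
    configuration per family is the one with the lowest sum of squared
    differences (on standardized values) to the proband across genes.
    Returns the joint fit and a per-gene table of conditional effects.
    A rank-deficient exposure matrix triggers a collinearity warning and a
    ridge-stabilized fit, flagged on the result.
    """
    if len(models) < 1:
        raise ValueError("need at least one model")
    tissues = {m.tissue for m in models}
    if len(tissues) != 1:
        raise ValueError(f"fine-mapping requires one tissue, got {sorted(tissues)}")

    pvals, cvals = [], []
    for model in models:
        aligned = em.harmonize(model, matrix, keep_ambiguous=config.keep_ambiguous)
        if aligned.n_predictors == 0:
            raise ValueError(f"model {model.gene}: no predictors in matrix")
        xP, cfgs, _, _ = _member_exposures(aligned, matrix, trios)
        pvals.append(xP)
        cvals.append(cfgs)
    P = np.stack(pvals, axis=1)        # (N, q)
    C = np.stack(cvals, axis=2)        # (N, 4, q)

    # exclusion distance on per-gene normalized values so no gene dominates
    # the sum of squares; for one gene this reduces to |value - proband|
    scale = np.where(C.std(axis=(0, 1)) > 0, C.std(axis=(0, 1)), 1.0)
    dist = (((C - P[:, None, :]) / scale) ** 2).sum(axis=2)
    excl = dist.argmin(axis=1)
    keep = np.ones(dist.shape, dtype=bool)
    keep[np.arange(len(excl)), excl] = False
    controls = C[keep].reshape(len(P), 3, len(models))
    X = np.concatenate([P[:, None, :], controls], axis=1)  # (N, 4, q)
    if config.standardize:
        # per-gene z-scoring over case + retained controls, as in run_twas
        for g in range(X.shape[2]):
            std, ok = em.standardize_exposures(X[:, :, g])
            if ok:
                X[:, :, g] = std
    fit = fit_conditional_logistic(X)
    table = pd.DataFrame({
        "gene": [m.gene for m in models],
        "tissue": [m.tissue for m in models],
        "beta": np.atleast_1d(fit.beta),
        "se": np.atleast_1d(fit.se),
        "z": np.atleast_1d(fit.z),
        "p": 2 * stats.norm.sf(np.abs(np.atleast_1d(fit.z))),
    })
    return fit, table
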