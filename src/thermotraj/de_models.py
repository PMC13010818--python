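"""Per-gene count GLMMs, AIC family selection, term tests, and candidate calling.

Each gene's normalized expression is modelled with a log link as

    Expression ~ <fixed terms> + (1 | AP)

where the fixed terms follow one of four factorial designs (all factors are
two-level: Generation G9/G23, Selection Control/Warming, History PT/NL) and
AP is a random intercept for the ancestral replicate population, shared by a
control lineage and its warming descendant. The response family is negative
binomial (variance = mu + phi * mu^2) or Poisson; because the response is a
median-of-ratios normalized count and may be fractional, likelihoods are
evaluated with gamma-function generalizations of the factorial terms. The
random intercept is integrated out by a Laplace approximation with a 1-D
Newton inner optimization per AP level.

Per-term p-values come from likelihood-ratio tests against the model with
the term's column removed, computed under sum-to-zero contrasts so that main
effects remain interpretable when their interactions are retained. The
family (NB vs Poisson) used for all genes is chosen by a per-gene AIC vote.
Candidates are genes whose term p-value falls below alpha / H_n, the nominal
level divided by the harmonic number of the number of genes tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from . import _fast
from .io_core import CountMatrix, SampleDesign, logger

# ---------------------------------------------------------------------------
# Model designs
# ---------------------------------------------------------------------------

#: Fixed-term lists of the four model designs. M1 is the all-sample model,
#: M2 drops Generation (fit per generation), M3 keeps only Selection (fit per
#: generation and history), M4 drops History (fit per history, both
#: generations). The AP random intercept is always present.
MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "M1": (
        "Generation",
        "Selection",
        "History",
        "Generation:Selection",
        "Generation:History",
        "Selection:History",
        "Generation:Selection:History",
    ),
    "M2": ("Selection", "History", "Selection:History"),
    "M3": ("Selection",),
    "M4": ("Generation", "Selection", "Generation:Selection"),
}

FAMILIES = ("negative_binomial", "poisson")

_PHI_MIN, _PHI_MAX = 1e-8, 1e3
_SIGMA_MIN, _SIGMA_MAX = 1e-4, 10.0
_ETA_CLIP = 30.0


@dataclass(frozen=True)
class ModelSpec:
    """One of the four factorial designs plus a response family."""

    design_id: str
    family: str = "negative_binomial"

    def __post_init__(self) -> None:
        if self.design_id not in MODEL_TERMS:
            raise ValueError(f"unknown design {self.design_id!r}; allowed: {sorted(MODEL_TERMS)}")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; allowed: {FAMILIES}")

    @property
    def fixed_terms(self) -> tuple[str, ...]:
        return MODEL_TERMS[self.design_id]

    @property
    def n_fixed(self) -> int:
        return 1 + len(self.fixed_terms)

    @property
    def n_params(self) -> int:
        # fixed coefficients + dispersion (NB) + random-intercept variance
        return self.n_fixed + (1 if self.family == "negative_binomial" else 0) + 1


@dataclass
class FdrSpec:
    """Nominal FDR level and the number of genes tested in the analysis."""

    alpha: float = 0.01
    n_genes: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


@dataclass
class GeneFitResult:
    """Maximum-likelihood fit of one gene under one ModelSpec.

    Coefficients are on the natural-log scale with treatment coding
    (reference levels G9, Control, PT). ``dispersion`` is None for Poisson.
    ``fallback_used`` marks genes refitted without the random intercept after
    the random-intercept variance collapsed or the mixed fit failed.
    """

    gene_id: str
    family: str
    coefficients: dict[str, float]
    dispersion: float | None
    random_intercept_sd: float
    log_likelihood: float
    aic: float
    p_values: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    fallback_used: bool = False


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

_FACTOR_LEVELS = {
    "Generation": ("G9", "G23"),
    "Selection": ("Control", "Warming"),
    "History": ("PT", "NL"),
}


def _factor_column(designs: Sequence[SampleDesign], factor: str, coding: str) -> np.ndarray:
    ref, alt = _FACTOR_LEVELS[factor]
    values = {
        "Generation": [d.generation for d in designs],
        "Selection": [d.selection for d in designs],
        "History": [d.history for d in designs],
    }[factor]
    ind = np.array([v == alt for v in values], dtype=float)
    if coding == "treatment":
        return ind
    # sum-to-zero: reference level -1, alternative +1
    return 2.0 * ind - 1.0


def build_design_matrix(
    designs: Sequence[SampleDesign], terms: Sequence[str], coding: str = "treatment"
) -> tuple[np.ndarray, list[str]]:
    """Intercept + one column per term; interactions are products of mains."""
    if coding not in ("treatment", "sum"):
        raise ValueError("coding must be 'treatment' or 'sum'")
    cols = [np.ones(len(designs))]
    names = ["Intercept"]
    for term in terms:
        col = np.ones(len(designs))
        for factor in term.split(":"):
            col = col * _factor_column(designs, factor, coding)
        cols.append(col)
        names.append(term)
    return np.column_stack(cols), names


def _check_factor_levels(designs: Sequence[SampleDesign], terms: Sequence[str]) -> None:
    factors = {f for t in terms for f in t.split(":")}
    for factor in factors:
        col = _factor_column(designs, factor, "treatment")
        if len(np.unique(col)) < 2:
            raise ValueError(f"factor {factor!r} has fewer than 2 levels in this subset")


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------


def _nb_loglik(y: np.ndarray, mu: np.ndarray, r: float) -> np.ndarray:
    """NB log-likelihood valid for non-integer y >= 0 (gamma generalization)."""
    return (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        - r * np.log1p(mu / r)
        + special.xlogy(y, mu / (r + mu))
    )


def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    return special.xlogy(y, mu) - mu - special.gammaln(y + 1.0)


def _loglik(y: np.ndarray, mu: np.ndarray, family: str, r: float) -> np.ndarray:
    if family == "poisson":
        return _poisson_loglik(y, mu)
    return _nb_loglik(y, mu, r)


def _deriv_eta(y: np.ndarray, mu: np.ndarray, family: str, r: float):
    """First and second derivatives of the log-likelihood wrt eta = log mu."""
    if family == "poisson":
        return y - mu, -mu
    d1 = r * (y - mu) / (r + mu)
    d2 = -r * mu * (r + y) / (r + mu) ** 2
    return d1, d2


# ---------------------------------------------------------------------------
# Laplace marginal likelihood
# ---------------------------------------------------------------------------


def _inner_modes(
    y: np.ndarray,
    eta0: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
    sigma2: float,
    family: str,
    r: float,
    b_start: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior modes of the per-group random intercepts (damped 1-D Newton).

    Returns (b_hat, W) with W_k = -sum of d2 loglik / d eta2 over group k at
    the mode. The penalized objective is strictly concave in each b_k, so
    damped Newton converges monotonically.
    """
    b = b_start.copy()
    for _ in range(100):
        eta = np.clip(eta0 + b[group_idx], -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        d1, d2 = _deriv_eta(y, mu, family, r)
        score = np.bincount(group_idx, weights=d1, minlength=n_groups) - b / sigma2
        hess = np.bincount(group_idx, weights=d2, minlength=n_groups) - 1.0 / sigma2
        step = score / hess
        np.clip(step, -3.0, 3.0, out=step)
        b -= step
        if np.max(np.abs(step)) < 1e-11:
            break
    eta = np.clip(eta0 + b[group_idx], -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    _, d2 = _deriv_eta(y, mu, family, r)
    W = -np.bincount(group_idx, weights=d2, minlength=n_groups)
    return b, W


class _Objective:
    """Negative Laplace-approximated marginal log-likelihood in theta.

    theta = [beta..., log phi (NB only), log sigma (if random)]. Inner modes
    are warm-started from the previous evaluation; with the tight inner
    tolerance the objective value is start-independent.
    """

    def __init__(self, y, X, group_idx, n_groups, family, random_intercept):
        self.y = y
        self.X = X
        self.group_idx = group_idx
        self.n_groups = n_groups
        self.family = family
        self.random = random_intercept
        self.p = X.shape[1]
        self._b = np.zeros(n_groups)

    def split(self, theta: np.ndarray):
        beta = theta[: self.p]
        i = self.p
        r = np.inf
        if self.family == "negative_binomial":
            r = 1.0 / math.exp(theta[i])
            i += 1
        sigma = math.exp(theta[i]) if self.random else 0.0
        return beta, r, sigma

    def __call__(self, theta: np.ndarray) -> float:
        beta, r, sigma = self.split(theta)
        eta0 = np.clip(self.X @ beta, -_ETA_CLIP, _ETA_CLIP)
        if not self.random:
            mu = np.exp(eta0)
            ll = float(np.sum(_loglik(self.y, mu, self.family, r)))
            return -ll if np.isfinite(ll) else 1e12
        sigma2 = sigma * sigma
        b, W = _inner_modes(
            self.y, eta0, self.group_idx, self.n_groups, sigma2,
            self.family, r, self._b,
        )
        self._b = b
        eta = np.clip(eta0 + b[self.group_idx], -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        ll = (
            float(np.sum(_loglik(self.y, mu, self.family, r)))
            - float(np.sum(b * b)) / (2.0 * sigma2)
            - 0.5 * float(np.sum(np.log1p(sigma2 * np.maximum(W, 0.0))))
        )
        return -ll if np.isfinite(ll) else 1e12


def _start_values(y, X, family, random_intercept):
    z = np.log(y + 0.5)
    beta0, *_ = np.linalg.lstsq(X, z, rcond=None)
    theta = list(beta0)
    if family == "negative_binomial":
        mu0 = np.exp(np.clip(X @ beta0, -_ETA_CLIP, _ETA_CLIP))
        denom = float(np.sum(mu0 * mu0))
        phi0 = float(np.sum((y - mu0) ** 2 - mu0)) / denom if denom > 0 else 0.1
        theta.append(math.log(min(max(phi0, 1e-3), 50.0)))
    if random_intercept:
        theta.append(math.log(0.1))
    return np.array(theta)


def _maximize(y, X, group_idx, n_groups, family, random_intercept):
    """Fit one (family, structure) combination; returns a raw fit dict."""
    obj = _Objective(y, X, group_idx, n_groups, family, random_intercept)
    if _fast.AVAILABLE:
        yc = np.ascontiguousarray(y, dtype=np.float64)
        Xc = np.ascontiguousarray(X, dtype=np.float64)
        gc = np.ascontiguousarray(group_idx, dtype=np.int64)
        is_nb = family == "negative_binomial"
        p = X.shape[1]

        def fun(theta, _y=yc, _X=Xc, _g=gc):
            return _fast.negll(
                np.asarray(theta, dtype=np.float64), _y, _X, _g,
                n_groups, p, is_nb, random_intercept,
            )
    else:  # pragma: no cover - numba is a hard dependency in practice
        fun = obj
    theta0 = _start_values(y, X, family, random_intercept)
    p = X.shape[1]
    bounds = [(-_ETA_CLIP, _ETA_CLIP)] * p
    if family == "negative_binomial":
        bounds.append((math.log(_PHI_MIN), math.log(_PHI_MAX)))
    if random_intercept:
        bounds.append((math.log(_SIGMA_MIN), math.log(_SIGMA_MAX)))
    opts = {"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500, "maxfun": 5000}
    res = optimize.minimize(fun, theta0, method="L-BFGS-B", bounds=bounds, options=opts)
    converged = bool(res.success) and np.isfinite(res.fun)
    if not converged and np.isfinite(res.fun):
        # line searches on finite-difference gradients occasionally stall at
        # the optimum; a restart with a fresh Hessian either confirms
        # stationarity (no further decrease) or escapes a genuine stall
        res2 = optimize.minimize(
            fun, res.x, method="L-BFGS-B", bounds=bounds, options=opts
        )
        if res2.fun <= res.fun + 1e-9:
            converged = bool(res2.success) or (res.fun - res2.fun) < 1e-6
            res = res2
    beta, r, sigma = obj.split(res.x)
    return {
        "beta": np.asarray(beta, dtype=float),
        "phi": (1.0 / r) if family == "negative_binomial" else None,
        "sigma": sigma,
        "ll": -float(res.fun),
        "converged": converged and np.isfinite(res.fun),
    }


def _fit_ml(y, X, group_idx, n_groups, family, random_intercept=True):
    """Fit with the random intercept, falling back to fixed effects only when
    the variance collapses to its bound or the mixed fit fails."""
    fallback = False
    fit = None
    if random_intercept and n_groups >= 2:
        fit = _maximize(y, X, group_idx, n_groups, family, True)
        at_bound = fit["sigma"] <= _SIGMA_MIN * 2.0
        if not fit["converged"] or at_bound:
            fallback = True
    else:
        fallback = True
    if fallback:
        fixed = _maximize(y, X, group_idx, n_groups, family, False)
        fixed["sigma"] = 0.0
        # keep the mixed fit only if it is valid and strictly better
        if fit is not None and fit["converged"] and fit["ll"] > fixed["ll"] + 1e-8:
            fit["fallback"] = False
            return fit
        fixed["fallback"] = True
        return fixed
    fit["fallback"] = False
    return fit


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def _prepare(designs: Sequence[SampleDesign], spec: ModelSpec, coding: str = "treatment"):
    X, names = build_design_matrix(designs, spec.fixed_terms, coding)
    ap_levels = sorted({d.ap for d in designs})
    ap_index = {a: i for i, a in enumerate(ap_levels)}
    group_idx = np.array([ap_index[d.ap] for d in designs])
    return X, names, group_idx, len(ap_levels)


def _validate_response(y: np.ndarray, n_design: int, n_fixed: int) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) != n_design:
        raise ValueError(f"response length {len(y)} does not match design ({n_design})")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite expression values")
    if np.any(y < 0):
        raise ValueError("negative expression values")
    if len(y) < n_fixed:
        raise ValueError(
            f"{len(y)} observations cannot identify {n_fixed} fixed parameters"
        )
    return y


def fit_gene(
    y: np.ndarray,
    designs: Sequence[SampleDesign],
    spec: ModelSpec,
    gene_id: str = "gene",
) -> GeneFitResult:
    """Maximum-likelihood fit of one gene's expression under ``spec``.

    The random AP intercept is integrated by a Laplace approximation; if its
    variance collapses to the lower bound or the mixed fit fails, the gene is
    refitted without the random term and flagged via ``fallback_used``. AIC
    counts the random-intercept variance (and the NB dispersion) as estimated
    parameters even when the fallback pinned them, so AICs stay comparable
    across genes.
    """
    _check_factor_levels(designs, spec.fixed_terms)
    y = _validate_response(y, len(designs), spec.n_fixed)
    X, names, group_idx, n_groups = _prepare(designs, spec)
    fit = _fit_ml(y, X, group_idx, n_groups, spec.family)
    k = spec.n_params
    return GeneFitResult(
        gene_id=gene_id,
        family=spec.family,
        coefficients=dict(zip(names, fit["beta"])),
        dispersion=fit["phi"],
        random_intercept_sd=float(fit["sigma"]),
        log_likelihood=fit["ll"],
        aic=2.0 * k - 2.0 * fit["ll"],
        converged=fit["converged"],
        fallback_used=fit["fallback"],
    )


def test_term(
    full: GeneFitResult,
    term: str,
    y: np.ndarray,
    designs: Sequence[SampleDesign],
    spec: ModelSpec,
) -> float:
    """Likelihood-ratio p-value for one fixed term.

    The reduced model removes the term's single column from the sum-to-zero
    coded design while retaining all other terms (including interactions that
    contain it), so main effects are tested as average effects across the
    levels of the interacting factors. The statistic is referred to a 1-df
    chi-square; the full model's maximized likelihood is coding-invariant, so
    the treatment-coded fit is reused.
    """
    if term not in spec.fixed_terms:
        raise ValueError(f"term {term!r} not in design {spec.design_id} ({spec.fixed_terms})")
    y = np.asarray(y, dtype=float)
    reduced_terms = [t for t in spec.fixed_terms if t != term]
    X_red, _ = build_design_matrix(designs, reduced_terms, coding="sum")
    ap_levels = sorted({d.ap for d in designs})
    ap_index = {a: i for i, a in enumerate(ap_levels)}
    group_idx = np.array([ap_index[d.ap] for d in designs])
    use_random = not full.fallback_used
    fit_red = _fit_ml(
        y, X_red, group_idx, len(ap_levels), spec.family, random_intercept=use_random
    )
    lrt = max(0.0, 2.0 * (full.log_likelihood - fit_red["ll"]))
    return float(stats.chi2.sf(lrt, df=1))


def fit_genes(
    counts: CountMatrix,
    designs: Sequence[SampleDesign],
    spec: ModelSpec,
    terms_to_test: Sequence[str] | None = None,
) -> list[GeneFitResult]:
    """Fit every gene in ``counts`` and (optionally) LRT-test the given terms.

    ``terms_to_test=None`` tests every fixed term; pass an empty list to skip
    testing (e.g. for AIC-only passes).
    """
    if [d.sample_id for d in designs] != counts.sample_ids:
        raise ValueError("designs must be ordered to match counts.sample_ids")
    if terms_to_test is None:
        terms_to_test = spec.fixed_terms
    for t in terms_to_test:
        if t not in spec.fixed_terms:
            raise ValueError(f"cannot test {t!r}: not a term of {spec.design_id}")
    results = []
    for g, gene_id in enumerate(counts.gene_ids):
        y = counts.counts[g, :]
        res = fit_gene(y, designs, spec, gene_id=gene_id)
        for term in terms_to_test:
            res.p_values[term] = test_term(res, term, y, designs, spec)
        results.append(res)
    n_fallback = sum(r.fallback_used for r in results)
    n_failed = sum(not r.converged for r in results)
    logger.info(
        "fit_genes: %d genes, design %s, family %s (%d fallback, %d non-converged)",
        len(results), spec.design_id, spec.family, n_fallback, n_failed,
    )
    return results


def select_family_and_structure(
    counts: CountMatrix,
    designs: Sequence[SampleDesign],
    spec_candidates: Sequence[ModelSpec],
) -> ModelSpec:
    """AIC majority vote across genes between candidate family/structure pairs.

    Every candidate is fitted to every gene; each gene votes for its
    lowest-AIC candidate (ties toward fewer parameters), and the candidate
    with the most votes wins (global ties again toward fewer parameters).
    Genes for which every candidate fit fails are excluded from the vote.
    """
    if len(spec_candidates) == 0:
        raise ValueError("need at least one candidate")
    if len({s.design_id for s in spec_candidates}) != 1:
        raise ValueError("candidates must share a design_id")
    if len(spec_candidates) == 1:
        return spec_candidates[0]
    order = np.argsort([s.n_params for s in spec_candidates], kind="stable")
    ranked = [spec_candidates[i] for i in order]
    votes = np.zeros(len(ranked), dtype=int)
    n_excluded = 0
    if [d.sample_id for d in designs] != counts.sample_ids:
        raise ValueError("designs must be ordered to match counts.sample_ids")
    for g, gene_id in enumerate(counts.gene_ids):
        y = counts.counts[g, :]
        aics = []
        for spec in ranked:
            try:
                res = fit_gene(y, designs, spec, gene_id=gene_id)
                aics.append(res.aic if res.converged else np.inf)
            except (ValueError, FloatingPointError):
                aics.append(np.inf)
        aics = np.asarray(aics)
        if not np.any(np.isfinite(aics)):
            n_excluded += 1
            logger.warning("select_family: all fits failed for %s; excluded", gene_id)
            continue
        # first index achieving the minimum within tolerance = simplest winner
        best = np.flatnonzero(aics <= aics.min() + 1e-9)[0]
        votes[best] += 1
    winner = ranked[int(np.argmax(votes))]
    logger.info(
        "select_family: votes %s -> %s (%d genes excluded)",
        {s.family: int(v) for s, v in zip(ranked, votes)}, winner.family, n_excluded,
    )
    return winner


def fdr_threshold(spec: FdrSpec) -> float:
    """Per-gene p-value cutoff alpha / H_n with H_n the n-th harmonic number,
    computed by direct summation."""
    h_n = float(np.sum(1.0 / np.arange(1, spec.n_genes + 1)))
    return spec.alpha / h_n


def detect_candidates(
    results: Sequence[GeneFitResult], term: str, spec: FdrSpec
) -> set[str]:
    """Gene ids whose ``term`` p-value falls below the harmonic-series cutoff.

    Non-converged fits are excluded from calling (and logged). ``spec.n_genes``
    should be the number of genes actually tested in this analysis.
    """
    cutoff = fdr_threshold(spec)
    candidates = set()
    n_skipped = 0
    for res in results:
        if term not in res.p_values:
            raise ValueError(f"gene {res.gene_id!r} has no p-value for term {term!r}")
        if not res.converged:
            n_skipped += 1
            continue
        if res.p_values[term] < cutoff:
            candidates.add(res.gene_id)
    if n_skipped:
        logger.info("detect_candidates: %d non-converged genes excluded", n_skipped)
    return candidates


def results_to_records(results: Sequence[GeneFitResult]) -> list[dict]:
    """Flatten fit results into TSV-ready records (p-values as p_<term>)."""
    records = []
    for r in results:
        rec: dict = {"gene_id": r.gene_id, "family": r.family}
        for name, value in r.coefficients.items():
            rec[f"coef_{name}"] = value
        rec["dispersion"] = r.dispersion
        rec["random_intercept_sd"] = r.random_intercept_sd
        rec["log_likelihood"] = r.log_likelihood
        rec["aic"] = r.aic
        for term, p in r.p_values.items():
            rec[f"p_{term}"] = p
        rec["converged"] = r.converged
        rec["fallback_used"] = r.fallback_used
        records.append(rec)
    return records
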