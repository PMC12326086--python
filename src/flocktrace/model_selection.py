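"""Habitat-conditioned linear mixed-model selection.

For each response (flap frequency, absolute flock spread, distance to
centroid, group size, flight speed, front-back and left-right distance) the
procedure is:

1. transform the response where needed (square root for the two
   right-skewed spread measures);
2. prune multicollinear fixed terms by (generalised) variance inflation
   factor, iteratively dropping the worst offender while the maximum exceeds
   the threshold;
3. enumerate every subset of the surviving fixed terms that respects
   marginality (an interaction enters only with both parents present) — the
   "all-subsets" search, including the intercept-only model;
4. fit each candidate as a linear mixed model with random intercepts for
   loft and for bird nested in loft, by maximum likelihood so AICs compare
   fixed structures;
5. among fits within 2 AIC units of the minimum, select the highest marginal
   r-squared; r-squared ties at the fifth decimal place go to the model with
   the fewest fixed terms, residual ties to the lowest AIC;
6. compute Cook's distances from the fixed-effects projection, drop
   observations above 4/n once, and refit the selected structure by REML for
   the reported coefficient table.

Singular fits (any random-effect variance at the boundary) and
non-convergent fits are flagged and excluded from selection.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import DegenerateInputError, ParameterError, SelectionError

logger = logging.getLogger(__name__)

DEFAULT_VIF_THRESHOLD = 5.0
#: random-effect variance below this fraction of residual variance is
#: unambiguously at the boundary
SINGULARITY_TOL = 1e-8
#: variance ratios below this trigger the likelihood-flatness check
SINGULARITY_SCREEN = 0.02
#: log-likelihood gain below this means the component is indistinguishable
#: from zero variance
SINGULARITY_LLF_TOL = 1e-4
#: refuse exhaustive searches beyond this many candidate specifications
MAX_SPECS = 2 ** 14

#: patsy fragment per fixed-term name; habitat is a 3-level factor whose
#: reference level is substituted at formula-build time.
TERM_FORMULAS = {
    "habitat": "C(habitat, Treatment('{ref}'))",
    "flight_time": "flight_time",
    "iteration": "iteration",
    "flap_frequency": "flap_frequency",
    "absolute_spread": "absolute_spread",
    "distance_to_centroid": "distance_to_centroid",
    "group_size": "group_size",
    "speed": "speed",
    "front_back": "front_back",
    "left_right": "left_right",
    "position": "C(position, Treatment('back'))",
    "habitat:flight_time": "C(habitat, Treatment('{ref}')):flight_time",
    "habitat:iteration": "C(habitat, Treatment('{ref}')):iteration",
}

#: columns a term needs in the data frame
TERM_COLUMNS = {
    "habitat:flight_time": ("habitat", "flight_time"),
    "habitat:iteration": ("habitat", "iteration"),
}


def term_columns(term: str) -> tuple[str, ...]:
    return TERM_COLUMNS.get(term, (term,))


def interaction_parents(term: str) -> tuple[str, ...] | None:
    return tuple(term.split(":")) if ":" in term else None


@dataclass(frozen=True)
class ModelSpec:
    """One candidate fixed-effect structure (random structure is fixed)."""

    response: str
    fixed_terms: tuple[str, ...]
    transform: str = "identity"
    habitat_ref: str = "open"

    def __post_init__(self):
        for term in self.fixed_terms:
            parents = interaction_parents(term)
            if parents and not all(p in self.fixed_terms for p in parents):
                raise ParameterError(
                    f"interaction {term} requires both parents in the spec")

    def formula(self) -> str:
        rhs = " + ".join(
            TERM_FORMULAS[t].format(ref=self.habitat_ref)
            for t in self.fixed_terms) or "1"
        lhs = (f"np.sqrt({self.response})" if self.transform == "sqrt"
               else self.response)
        return f"{lhs} ~ {rhs}"


@dataclass
class ModelFit:
    """A fitted mixed model with its selection metadata."""

    spec: ModelSpec
    aic: float
    r2: float
    n_obs: int
    singular: bool
    converged: bool
    coefficients: pd.DataFrame = field(repr=False)
    random_variances: dict[str, float] = field(default_factory=dict)
    result: object = field(default=None, repr=False)
    used_index: pd.Index = field(default=None, repr=False)

    @property
    def eligible(self) -> bool:
        return self.converged and not self.singular and np.isfinite(self.aic)


def apply_transform(values, transform: str) -> np.ndarray:
    """Elementwise identity or square root (non-negative domain enforced)."""
    x = np.asarray(values, dtype=float)
    if transform == "identity":
        return x
    if transform == "sqrt":
        if np.nanmin(x) < 0:
            raise ParameterError("sqrt transform requires non-negative values")
        return np.sqrt(x)
    raise ParameterError(f"unknown transform {transform!r}")


# ---------------------------------------------------------------------------
# collinearity pruning


def _design_by_term(data: pd.DataFrame, terms, habitat_ref: str = "open"):
    """Column blocks of the main-effects design matrix, one per term.

    Built with an intercept so factors get reduced (treatment) coding —
    full dummy coding would make the centred factor columns exactly
    collinear and every VIF infinite — then the intercept column is dropped.
    """
    rhs = " + ".join(TERM_FORMULAS[t].format(ref=habitat_ref) for t in terms)
    mat = patsy.dmatrix("1 + " + rhs, data, return_type="dataframe")
    info = mat.design_info
    blocks = {}
    for term in terms:
        frag = TERM_FORMULAS[term].format(ref=habitat_ref)
        cols = []
        for t_name, slc in info.term_name_slices.items():
            if t_name.replace(" ", "") == frag.replace(" ", ""):
                cols = [i - 1 for i in range(slc.start, slc.stop)]
        if not cols:
            raise ParameterError(f"could not locate design columns for {term}")
        blocks[term] = cols
    return mat.to_numpy()[:, 1:], blocks


def generalized_vif(X: np.ndarray, blocks: dict[str, list[int]]) -> dict[str, float]:
    """Scaled generalised VIF per term: GVIF^(1/df), comparable to an
    ordinary VIF threshold.

    Computed through the conditional-covariance identity
    ``GVIF_j = det(S_jj) / det(S_jj - S_jo S_oo^+ S_oj)`` — how much the
    term's (standardised) covariance shrinks once the other terms are
    partialled out.  For a one-column term this is exactly 1/(1-R2) of that
    column regressed on the rest, and a term that is an exact linear
    function of the others (and only such a term) yields +inf.
    """
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = 1.0
    Z = Xc / sd
    n = Z.shape[0]
    out = {}
    idx_all = np.arange(Z.shape[1])
    for term, cols in blocks.items():
        others = np.setdiff1d(idx_all, cols)
        Zj = Z[:, cols]
        Sjj = Zj.T @ Zj / n
        if len(others) == 0:
            out[term] = 1.0
            continue
        Zo = Z[:, others]
        beta, *_ = np.linalg.lstsq(Zo, Zj, rcond=None)
        resid = Zj - Zo @ beta
        Scond = resid.T @ resid / n
        d_full = float(np.linalg.det(Sjj))
        d_cond = float(np.linalg.det(Scond))
        if d_cond <= 1e-12 * max(d_full, 1e-300):
            out[term] = float("inf")
            continue
        out[term] = float((d_full / d_cond) ** (1.0 / len(cols)))
    return out


def vif_prune(data: pd.DataFrame, fixed_terms,
              threshold: float = DEFAULT_VIF_THRESHOLD,
              habitat_ref: str = "open"):
    """Iteratively drop the highest-VIF main-effect term while max > threshold.

    Interaction terms are never VIF-tested against their own parents: they
    are set aside and reattached afterwards (dropped if a parent was pruned).
    Returns ``(retained_terms, removal_log)``.
    """
    mains = [t for t in fixed_terms if interaction_parents(t) is None]
    interactions = [t for t in fixed_terms if interaction_parents(t) is not None]
    removed = []
    current = list(mains)
    while len(current) >= 2:
        cols = set(c for t in current for c in term_columns(t))
        X, blocks = _design_by_term(data.dropna(subset=sorted(cols)), current,
                                    habitat_ref)
        vifs = generalized_vif(X, blocks)
        worst = max(vifs.values())
        if worst <= threshold:
            break
        # drop the later-ordered among maximal offenders (handles exact ties)
        offender = [t for t in current if vifs[t] == worst][-1]
        current.remove(offender)
        removed.append((offender, worst))
        logger.info("vif_prune: removed %s (VIF %.3g)", offender, worst)
    kept_interactions = [
        t for t in interactions
        if all(p in current for p in interaction_parents(t))]
    dropped_int = [t for t in interactions if t not in kept_interactions]
    removed.extend((t, float("nan")) for t in dropped_int)
    return current + kept_interactions, removed


# ---------------------------------------------------------------------------
# exhaustive enumeration


def enumerate_subsets(fixed_terms, response: str, transform: str = "identity",
                      habitat_ref: str = "open") -> list[ModelSpec]:
    """All fixed-term subsets respecting marginality, incl. intercept-only."""
    mains = [t for t in fixed_terms if interaction_parents(t) is None]
    interactions = [t for t in fixed_terms if interaction_parents(t) is not None]
    specs = []
    for r in range(len(mains) + 1):
        for main_subset in itertools.combinations(mains, r):
            allowed = [t for t in interactions
                       if all(p in main_subset for p in interaction_parents(t))]
            for k in range(len(allowed) + 1):
                for int_subset in itertools.combinations(allowed, k):
                    specs.append(ModelSpec(
                        response=response,
                        fixed_terms=tuple(main_subset) + tuple(int_subset),
                        transform=transform, habitat_ref=habitat_ref))
                    if len(specs) > MAX_SPECS:
                        raise ParameterError(
                            f"candidate space exceeds {MAX_SPECS} specs; "
                            "reduce the term list")
    return specs


# ---------------------------------------------------------------------------
# fitting


def _complete_cases(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    cols = {spec.response, "loft_id", "bird_id"}
    for t in spec.fixed_terms:
        cols.update(term_columns(t))
    return data.dropna(subset=sorted(cols))


def _fit_mixed(formula: str, df: pd.DataFrame, reml: bool,
               with_loft: bool = True, with_bird: bool = True):
    """One MixedLM fit with the pipeline's random structure (or a reduced
    structure for the singularity probe).

    Dropping the loft intercept keeps bird intercepts by regrouping on
    bird; dropping the bird component keeps the plain loft intercept.
    """
    if with_loft and with_bird:
        model = smf.mixedlm(formula, df, groups=df["loft_id"],
                            re_formula="1",
                            vc_formula={"bird": "0 + C(bird_id)"})
    elif with_bird:
        model = smf.mixedlm(formula, df, groups=df["bird_id"], re_formula="1")
    else:
        model = smf.mixedlm(formula, df, groups=df["loft_id"], re_formula="1")
    result = model.fit(reml=reml, method=["lbfgs", "bfgs", "cg"], maxiter=200)
    if not (bool(getattr(result, "converged", True))
            and np.isfinite(result.llf)):
        retry = model.fit(reml=reml, method="powell", maxiter=1000)
        if bool(getattr(retry, "converged", False)) and np.isfinite(retry.llf):
            result = retry
    return model, result


def _is_singular(formula, df, reml, result, variances, scale) -> bool:
    """Boundary detection for the random-effect variances.

    A variance below ``SINGULARITY_TOL`` x residual is at the boundary
    outright.  Optimisers often stall at small positive values instead of
    descending to an exact zero, so any component whose ratio falls below
    ``SINGULARITY_SCREEN`` is probed by refitting without it: if the ML
    log-likelihood barely moves, the component is indistinguishable from
    zero variance and the fit is singular.
    """
    llf = float(result.llf)
    for comp, var in variances.items():
        ratio = var / scale if scale > 0 else 0.0
        if ratio < SINGULARITY_TOL:
            return True
        if ratio >= SINGULARITY_SCREEN:
            continue
        try:
            _, reduced = _fit_mixed(formula, df, reml,
                                    with_loft=(comp != "loft"),
                                    with_bird=(comp != "bird"))
        except (np.linalg.LinAlgError, ValueError):
            continue
        if not np.isfinite(reduced.llf):
            continue
        if llf - float(reduced.llf) < SINGULARITY_LLF_TOL:
            return True
    return False


def fit_lmm(spec: ModelSpec, data: pd.DataFrame, reml: bool = False) -> ModelFit:
    """Fit one candidate as a linear mixed model.

    Random structure: intercept for loft (grouping factor) and a variance
    component for bird within loft.  ML by default so AIC compares fixed
    structures; the final reported refit uses REML.  The fit is flagged
    singular when any random-effect variance falls below ``SINGULARITY_TOL``
    times the residual variance, and non-convergent fits are excluded from
    selection by the caller.
    """
    df = _complete_cases(data, spec).copy()
    n = len(df)
    formula = spec.formula()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model, result = _fit_mixed(formula, df, reml)
            converged = (bool(getattr(result, "converged", True))
                         and np.isfinite(result.llf))
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.info("fit_lmm: %s failed to fit (%s)", spec.fixed_terms, exc)
            return ModelFit(spec, np.nan, np.nan, n, False, False,
                            pd.DataFrame(), {}, None, df.index)

        scale = float(result.scale)
        loft_var = float(np.asarray(result.cov_re).ravel()[0]) if result.cov_re.size else 0.0
        bird_var = float(result.vcomp[0]) if len(result.vcomp) else 0.0
        singular = _is_singular(formula, df, reml, result,
                                {"loft": loft_var, "bird": bird_var}, scale)

    fe = result.fe_params
    fitted_fixed = np.asarray(model.exog) @ np.asarray(fe)
    var_f = float(np.var(fitted_fixed))
    total = var_f + loft_var + bird_var + scale
    r2 = var_f / total if total > 0 else 0.0

    k_params = len(fe) + 2 + 1  # fixed + two variance params + residual
    aic = float(-2.0 * result.llf + 2.0 * k_params)

    coeffs = _coefficient_table(spec, model, result, n)
    return ModelFit(spec, aic, r2, n, singular, converged, coeffs,
                    {"loft": loft_var, "bird": bird_var, "residual": scale},
                    result, df.index)


def _coefficient_table(spec: ModelSpec, model, result, n: int) -> pd.DataFrame:
    """Per-coefficient estimates/SE plus per-term joint Wald F and p."""
    fe = result.fe_params
    se = result.bse_fe
    names = list(fe.index)
    cov = np.asarray(result.cov_params())[:len(names), :len(names)]
    info = model.data.design_info
    rows = []
    p_total = len(names)
    for term_name, slc in info.term_name_slices.items():
        idx = list(range(slc.start, slc.stop))
        if term_name == "Intercept":
            f_stat, p_val = np.nan, np.nan
        else:
            b = np.asarray(fe)[idx]
            V = cov[np.ix_(idx, idx)]
            q = len(idx)
            try:
                w = float(b @ np.linalg.solve(V, b))
                f_stat = w / q
                p_val = float(stats.f.sf(f_stat, q, max(n - p_total, 1)))
            except np.linalg.LinAlgError:
                f_stat, p_val = np.nan, np.nan
        for i in idx:
            rows.append({"term": term_name, "coefficient": names[i],
                         "estimate": float(np.asarray(fe)[i]),
                         "se": float(np.asarray(se)[i]),
                         "F": f_stat, "p": p_val})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# selection


def select_best(fits) -> ModelFit:
    """Apply the dAIC<2 -> max r2 -> fewest-terms -> lowest-AIC rule.

    Order-invariant over the candidate list; ineligible (singular or
    non-convergent) fits never enter selection.
    """
    eligible = [f for f in fits if f.eligible]
    if not eligible:
        raise SelectionError("no converged, non-singular candidate model")
    amin = min(f.aic for f in eligible)
    window = [f for f in eligible if f.aic - amin < 2.0]
    best_r2 = max(round(f.r2, 5) for f in window)
    tied = [f for f in window if round(f.r2, 5) == best_r2]
    fewest = min(len(f.spec.fixed_terms) for f in tied)
    tied = [f for f in tied if len(f.spec.fixed_terms) == fewest]
    tied.sort(key=lambda f: (f.aic, f.spec.fixed_terms))
    return tied[0]


# ---------------------------------------------------------------------------
# influence


def cooks_distances(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Closed-form Cook's distances of an OLS fit of y on X.

    ``D_i = r_i^2 h_i / (p (1 - h_i))`` with ``r_i`` the internally
    standardised residual and ``h_i`` the leverage — algebraically the
    classic ``e_i^2 h_i / (p s^2 (1-h_i)^2)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    Q, _ = np.linalg.qr(X)
    h = np.einsum("ij,ij->i", Q, Q)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    e = y - X @ beta
    s2 = float(e @ e) / (n - p)
    denom = np.clip(1.0 - h, 1e-12, None)
    return (e ** 2) * h / (p * s2 * denom ** 2)


def cooks_refit(fit: ModelFit, data: pd.DataFrame,
                threshold: float | None = None) -> tuple[ModelFit, int]:
    """Drop observations with Cook's D above 4/n once and refit by REML.

    Influence is approximated through the fixed-effects projection of the
    marginal model (the design matrix of the selected fixed structure).
    Refusal with a diagnostic if removal empties a habitat level used by the
    model.
    """
    spec = fit.spec
    df = _complete_cases(data, spec).copy()
    n = len(df)
    threshold = 4.0 / n if threshold is None else threshold
    y = apply_transform(df[spec.response].to_numpy(), spec.transform)
    rhs = " + ".join(TERM_FORMULAS[t].format(ref=spec.habitat_ref)
                     for t in spec.fixed_terms) or "1"
    X = patsy.dmatrix(rhs, df, return_type="dataframe").to_numpy()
    D = cooks_distances(X, y)
    keep = D <= threshold
    removed = int((~keep).sum())
    kept = df.loc[keep]
    if "habitat" in [c for t in spec.fixed_terms for c in term_columns(t)]:
        if kept["habitat"].nunique() < df["habitat"].nunique():
            raise DegenerateInputError(
                "outlier removal emptied a habitat level; refit aborted")
    refit = fit_lmm(spec, kept, reml=True)
    return refit, removed


# ---------------------------------------------------------------------------
# design diagnostic


def layer_independence_check(data: pd.DataFrame, factor: str = "bird_id"):
    """Likelihood-ratio test that habitat is independent of bird (or loft).

    Multinomial logistic regression of the habitat category on the identity
    factor versus an intercept-only model.  Returns ``(deviance, df, p)``.
    """
    df = data.dropna(subset=["habitat", factor])
    levels = df["habitat"].unique()
    if len(levels) < 2:
        raise DegenerateInputError("need >= 2 habitat levels")
    y, X_full = patsy.dmatrices(f"C(habitat) ~ C({factor})", df)
    y = np.asarray(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.MNLogit(y, np.asarray(X_full)).fit(disp=False, maxiter=200,
                                                     method="bfgs")
        null = sm.MNLogit(y, np.ones((len(df), 1))).fit(disp=False)
    deviance = 2.0 * (full.llf - null.llf)
    dof = (len(levels) - 1) * (df[factor].nunique() - 1)
    p = float(stats.chi2.sf(deviance, dof))
    return float(deviance), int(dof), p
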