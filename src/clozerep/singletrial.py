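"""Single-trial analysis route: crossed random-effects model ladders on ROI
window means.

Cloze probability is z-scored and entered as a continuous predictor;
laboratory is a deviation-coded nuisance predictor (sum-to-zero contrasts,
last lab as implicit reference); word type and grammaticality are deviation
coded as +-0.5 so their coefficients are directly condition differences in
microvolts.  All models are fitted by maximum likelihood (so that
likelihood-ratio tests of fixed effects are valid) with random intercepts
and slopes for subjects and items crossed.  Cloze coefficients and Wald
confidence intervals are transformed back from the z scale to the 0-100%
cloze range:  beta_raw = beta_z * 100 / sd(cloze in percent).

Model ladders
-------------
Per word type (response = N400 ROI window mean):

    Model 1:  ~ cloze * lab   + (cloze | subject) + (cloze | item)
    Model 2:  ~ cloze + lab   + (cloze | subject) + (cloze | item)
    Model 3:  ~ cloze         + (cloze | subject) + (cloze | item)
    Model 4:  ~ 1             + (cloze | subject) + (cloze | item)

with LRTs 1v2 (cloze x lab, df = #labs-1), 2v3 (lab), 3v4 (cloze, df 1);
the reported coefficient comes from Model 3.  The word-type interaction
uses uncorrelated random effects (the double-bar form); accuracy moderation
and the P600 grammaticality contrast follow the same pattern (docstrings of
the individual functions).

Non-convergent fits fall back along a documented simplification ladder:
drop random correlations, then the item slope, then the subject slope; the
actually-fitted specification is recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from clozerep.mixedlm import MixedLMFit, RandomTerm, fit_mixed_lm

__all__ = [
    "LmmResult",
    "LrtResult",
    "zscore_cloze",
    "fit_model",
    "lrt",
    "run_ladder",
    "wordtype_interaction",
    "accuracy_moderation",
    "prearticle_analysis",
    "p600_control",
]

#: Two-tailed 95% normal quantile used for every Wald interval.
Z95 = float(stats.norm.ppf(0.975))


@dataclass
class LmmResult:
    """Cloze (or contrast) coefficient with scale transforms and fit info."""

    term: str
    response: str
    beta_z: float | None
    se_z: float | None
    ci_z: tuple[float, float] | None
    beta_raw: float | None
    ci_raw: tuple[float, float] | None
    sd_cloze_percent: float | None
    loglik: float
    n_obs: int
    converged: bool
    fitted_random: str
    fallback_steps: tuple[str, ...]
    fit: MixedLMFit = field(repr=False)


@dataclass
class LrtResult:
    """Likelihood-ratio test between nested ML fits."""

    name: str
    chi2: float
    df: int
    p: float


# ------------------------------------------------------------------ z-scores

def zscore_cloze(table: pd.DataFrame, scope: str = "per_wordtype"):
    """Add ``cloze_z`` and return (table, scale dict).

    ``scope`` is ``per_wordtype`` (z within each word type, for the separate
    article/noun models) or ``combined`` (one z over all modelled rows, for
    the word-type interaction model).  The sample standard deviation
    (ddof=1) is used; the scale dict maps scope keys to ``(mean, sd)`` in
    cloze percent for back-transformation.  Raises on constant cloze.
    """
    out = table.copy()
    scale: dict[str, tuple[float, float]] = {}
    if scope == "combined":
        groups = [("combined", out.index)]
    elif scope == "per_wordtype":
        groups = [(wt, out.index[out["word_type"] == wt]) for wt in out["word_type"].unique()]
    else:
        raise ValueError(f"unknown z-scoring scope {scope!r}")
    out["cloze_z"] = np.nan
    for key, idx in groups:
        vals = out.loc[idx, "cloze"].to_numpy(dtype=float)
        mu, sd = vals.mean(), vals.std(ddof=1)
        if sd <= 1e-12 * max(1.0, abs(mu)):
            raise ValueError(f"cloze is constant for {key!r}; cannot z-score")
        out.loc[idx, "cloze_z"] = (vals - mu) / sd
        scale[key] = (float(mu), float(sd))
    return out, scale


def zscore_accuracy(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``accuracy_z``: z of each subject's accuracy, over subjects.

    Accuracy is a per-subject quantity, so the z-transform uses one value
    per subject (not per trial).  Raises if accuracy does not vary.
    """
    per_subj = table.drop_duplicates("subject_id")[["subject_id", "subject_accuracy"]]
    vals = per_subj["subject_accuracy"].to_numpy(dtype=float)
    sd = vals.std(ddof=1)
    if sd <= 1e-12 * max(1.0, abs(vals.mean())):
        raise ValueError("subject accuracy is constant; cannot z-score")
    z = (per_subj["subject_accuracy"] - vals.mean()) / sd
    out = table.copy()
    out["accuracy_z"] = out["subject_id"].map(
        dict(zip(per_subj["subject_id"], z))
    )
    return out


# ------------------------------------------------------------ design coding

def _lab_contrasts(table: pd.DataFrame) -> pd.DataFrame:
    """Sum-to-zero contrasts for laboratory: k-1 columns for k labs."""
    levels = sorted(table["lab_id"].unique())
    cols = {}
    for lev in levels[:-1]:
        x = np.where(table["lab_id"] == lev, 1.0, 0.0)
        x[table["lab_id"] == levels[-1]] = -1.0
        cols[f"lab[{lev}]"] = x
    return pd.DataFrame(cols, index=table.index)


def _encode(table: pd.DataFrame) -> pd.DataFrame:
    """Working copy with the deviation-coded helper columns attached."""
    out = table.copy()
    if "word_type" in out.columns:
        out["wordtype_dev"] = np.where(out["word_type"] == "noun", 0.5, -0.5)
    if "grammatical" in out.columns:
        out["gram_dev"] = np.where(out["grammatical"], -0.5, 0.5)
    if "cloze_z" in out.columns and "wordtype_dev" in out.columns:
        out["cloze_x_wordtype"] = out["cloze_z"] * out["wordtype_dev"]
    if "cloze_z" in out.columns and "accuracy_z" in out.columns:
        out["cloze_x_accuracy"] = out["cloze_z"] * out["accuracy_z"]
    return out


def _fixed_design(table: pd.DataFrame, fixed) -> pd.DataFrame:
    """Fixed-effects design matrix for a list of term names.

    Recognised terms: ``cloze_z``, ``accuracy_z``, ``wordtype``,
    ``grammaticality``, ``lab``, ``cloze_z:lab``, ``cloze_z:wordtype``,
    ``accuracy_z:cloze_z``.  An intercept is always included.
    """
    X = pd.DataFrame({"(Intercept)": np.ones(len(table))}, index=table.index)
    for term in fixed:
        if term in ("cloze_z", "accuracy_z"):
            X[term] = table[term].to_numpy(dtype=float)
        elif term == "wordtype":
            X["wordtype"] = table["wordtype_dev"].to_numpy()
        elif term == "grammaticality":
            X["grammaticality"] = table["gram_dev"].to_numpy()
        elif term == "lab":
            X = pd.concat([X, _lab_contrasts(table)], axis=1)
        elif term == "cloze_z:lab":
            labs = _lab_contrasts(table)
            for c in labs.columns:
                X[f"cloze_z:{c}"] = table["cloze_z"].to_numpy() * labs[c].to_numpy()
        elif term == "cloze_z:wordtype":
            X["cloze_z:wordtype"] = table["cloze_x_wordtype"].to_numpy()
        elif term == "accuracy_z:cloze_z":
            X["accuracy_z:cloze_z"] = table["cloze_x_accuracy"].to_numpy()
        else:
            raise ValueError(f"unknown fixed term {term!r}")
    return X


# ------------------------------------------------------------------- fitting

def _simplify(terms):
    """One fallback ladder step: correlations, then item slope, then subject."""
    terms = list(terms)
    if any(t.correlated and len(t.variables) > 1 for t in terms):
        return [
            RandomTerm(t.factor, t.variables, correlated=False) for t in terms
        ], "uncorrelated random effects"
    for factor in ("item_id", "subject_id"):
        for i, t in enumerate(terms):
            if t.factor == factor and len(t.variables) > 1:
                terms[i] = RandomTerm(t.factor, ("1",), correlated=False)
                return terms, f"intercept-only for {factor}"
    return None, None


def fit_model(
    table: pd.DataFrame,
    fixed,
    terms,
    response: str = "roi_n400",
    cloze_term: str | None = "cloze_z",
    sd_cloze_percent: float | None = None,
    theta0=None,
) -> LmmResult:
    """Fit one mixed model with the convergence fallback ladder.

    ``fixed`` is a list of fixed-term names (see :func:`_fixed_design`);
    ``terms`` the random-effect terms.  ``cloze_term`` names the reported
    coefficient (None for intercept-only models); if ``sd_cloze_percent``
    is given, the coefficient and its Wald CI are also back-transformed to
    the 0-100% cloze scale.  ``theta0`` warm-starts the covariance
    parameters (useful when comparing fixed-effects-nested models that
    share a random structure).
    """
    work = _encode(table)
    X = _fixed_design(work, fixed)
    y = work[response].to_numpy(dtype=float)

    steps: list[str] = []
    current = list(terms)
    while True:
        fit = fit_mixed_lm(y, X, work, current, theta0=theta0)
        if fit.converged:
            break
        simpler, step = _simplify(current)
        if simpler is None:
            break
        current = simpler
        steps.append(step)

    beta_z = se_z = ci_z = beta_raw = ci_raw = None
    if cloze_term is not None and cloze_term in fit.beta.index:
        beta_z = float(fit.beta[cloze_term])
        se_z = float(fit.se[cloze_term])
        ci_z = (beta_z - Z95 * se_z, beta_z + Z95 * se_z)
        if sd_cloze_percent is not None:
            f = 100.0 / sd_cloze_percent
            beta_raw = beta_z * f
            ci_raw = (ci_z[0] * f, ci_z[1] * f)
    return LmmResult(
        term=cloze_term or "",
        response=response,
        beta_z=beta_z,
        se_z=se_z,
        ci_z=ci_z,
        beta_raw=beta_raw,
        ci_raw=ci_raw,
        sd_cloze_percent=sd_cloze_percent,
        loglik=fit.loglik,
        n_obs=fit.n_obs,
        converged=fit.converged,
        fitted_random=" + ".join(t.describe() for t in fit.terms),
        fallback_steps=tuple(steps),
        fit=fit,
    )


def ensure_nested(full: LmmResult, reduced: LmmResult, refit) -> LmmResult:
    """Guarantee the nesting inequality loglik(full) >= loglik(reduced).

    A full model can come out marginally below its nested reduction when the
    covariance optimiser stalls near a boundary.  ``refit`` is called with
    ``theta0=reduced.fit.theta`` to restart the full fit from the reduced
    model's optimum (a feasible point for the shared random structure); the
    better of the two fits is returned.
    """
    if full.loglik >= reduced.loglik - 1e-9:
        return full
    again = refit(theta0=reduced.fit.theta)
    return again if again.loglik > full.loglik else full


def lrt(full: LmmResult, reduced: LmmResult, name: str = "") -> LrtResult:
    """Likelihood-ratio test of nested ML fits on identical rows.

    chi2 = 2 (loglik_full - loglik_reduced), clamped at 0; df is the
    difference in fixed-effect parameter counts.
    """
    if full.n_obs != reduced.n_obs:
        raise ValueError("LRT requires identical observation sets")
    df = full.fit.n_fixed - reduced.fit.n_fixed
    if df < 0:
        raise ValueError("models are not nested (reduced has more parameters)")
    chi2 = 2.0 * (full.loglik - reduced.loglik)
    if chi2 < -1e-6:
        raise ValueError(f"full model fits worse than reduced (chi2={chi2:.3g}); "
                         "check convergence")
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 and chi2 > 0 else 1.0
    return LrtResult(name=name, chi2=float(chi2), df=int(df), p=p)


# -------------------------------------------------------------- the ladders

_CLOZE_RANDOM = (
    RandomTerm("subject_id", ("1", "cloze_z")),
    RandomTerm("item_id", ("1", "cloze_z")),
)


def run_ladder(
    table: pd.DataFrame,
    word_type: str,
    response: str = "roi_n400",
) -> dict:
    """Model ladder 1-4 for a single word type.

    Returns a dict with ``interaction_lrt`` (cloze x lab), ``lab_lrt``,
    ``cloze_lrt`` and ``best`` (the Model-3 coefficient on both scales).
    With a single laboratory the two lab comparisons are skipped (None).
    """
    sub = table[table["word_type"] == word_type]
    if "experiment" in sub.columns:
        sub = sub[sub["experiment"] == "main"]
    if sub.empty:
        raise ValueError(f"no rows for word type {word_type!r}")
    sub, scale = zscore_cloze(sub, scope="per_wordtype")
    sd = scale[word_type][1]
    n_labs = sub["lab_id"].nunique()

    def _fit(fixed, term, **kw):
        return fit_model(sub, fixed, _CLOZE_RANDOM, response, term, sd, **kw)

    m3 = _fit(["cloze_z"], "cloze_z")
    warm = m3.fit.theta
    m4 = fit_model(sub, [], _CLOZE_RANDOM, response, None, sd, theta0=warm)
    m3 = ensure_nested(m3, m4, lambda **kw: _fit(["cloze_z"], "cloze_z", **kw))
    out = {
        "interaction_lrt": None,
        "lab_lrt": None,
        "cloze_lrt": lrt(m3, m4, "cloze"),
        "best": m3,
        "model4": m4,
    }
    if n_labs > 1:
        m2 = _fit(["cloze_z", "lab"], "cloze_z", theta0=warm)
        m2 = ensure_nested(m2, m3,
                           lambda **kw: _fit(["cloze_z", "lab"], "cloze_z", **kw))
        m1 = _fit(["cloze_z", "lab", "cloze_z:lab"], "cloze_z",
                  theta0=m2.fit.theta)
        m1 = ensure_nested(
            m1, m2,
            lambda **kw: _fit(["cloze_z", "lab", "cloze_z:lab"], "cloze_z", **kw),
        )
        out["interaction_lrt"] = lrt(m1, m2, "cloze_x_lab")
        out["lab_lrt"] = lrt(m2, m3, "lab")
    return out


def wordtype_interaction(table: pd.DataFrame, response: str = "roi_n400"):
    """Does the cloze effect differ between articles and nouns?

    ~ cloze * wordtype with uncorrelated random intercepts and slopes for
    cloze, wordtype and their product by subject and by item (the
    double-bar form, which is what lets these richer models converge).
    Returns ``(LrtResult, full-model LmmResult)``; the interaction df is 1.
    """
    sub = table
    if "experiment" in sub.columns:
        sub = sub[sub["experiment"] == "main"]
    if sub["word_type"].nunique() < 2:
        raise ValueError("need both word types for the interaction model")
    sub, scale = zscore_cloze(sub, scope="combined")
    sd = scale["combined"][1]
    terms = (
        RandomTerm("subject_id", ("1", "cloze_z", "wordtype_dev", "cloze_x_wordtype"),
                   correlated=False),
        RandomTerm("item_id", ("1", "cloze_z", "wordtype_dev", "cloze_x_wordtype"),
                   correlated=False),
    )
    m1 = fit_model(sub, ["cloze_z", "wordtype", "cloze_z:wordtype"], terms,
                   response, "cloze_z:wordtype", sd)
    m2 = fit_model(sub, ["cloze_z", "wordtype"], terms, response, "cloze_z", sd,
                   theta0=m1.fit.theta)
    m1 = ensure_nested(
        m1, m2,
        lambda **kw: fit_model(sub, ["cloze_z", "wordtype", "cloze_z:wordtype"],
                               terms, response, "cloze_z:wordtype", sd, **kw),
    )
    return lrt(m1, m2, "cloze_x_wordtype"), m1


def accuracy_moderation(table: pd.DataFrame, word_type: str = "article",
                        response: str = "roi_n400") -> dict:
    """Accuracy-moderation ladder for one word type.

        Model 1: ~ accuracy * cloze + (cloze | subject) + (cloze | item)
        Model 2: ~ accuracy + cloze + ...
        Model 3: ~ accuracy + ...

    1v2 tests whether the cloze effect depends on the subject's
    comprehension accuracy; 2v3 tests cloze with accuracy in the model.
    Both LRTs have df 1.
    """
    sub = table[table["word_type"] == word_type]
    if "experiment" in sub.columns:
        sub = sub[sub["experiment"] == "main"]
    sub, scale = zscore_cloze(sub, scope="per_wordtype")
    sd = scale[word_type][1]
    sub = zscore_accuracy(sub)
    m1 = fit_model(sub, ["accuracy_z", "cloze_z", "accuracy_z:cloze_z"],
                   _CLOZE_RANDOM, response, "cloze_z", sd)
    m2 = fit_model(sub, ["accuracy_z", "cloze_z"], _CLOZE_RANDOM, response,
                   "cloze_z", sd, theta0=m1.fit.theta)
    m3 = fit_model(sub, ["accuracy_z"], _CLOZE_RANDOM, response, None, sd,
                   theta0=m2.fit.theta)
    m2 = ensure_nested(
        m2, m3,
        lambda **kw: fit_model(sub, ["accuracy_z", "cloze_z"], _CLOZE_RANDOM,
                               response, "cloze_z", sd, **kw),
    )
    m1 = ensure_nested(
        m1, m2,
        lambda **kw: fit_model(sub, ["accuracy_z", "cloze_z", "accuracy_z:cloze_z"],
                               _CLOZE_RANDOM, response, "cloze_z", sd, **kw),
    )
    return {
        "acc_x_cloze_lrt": lrt(m1, m2, "accuracy_x_cloze"),
        "cloze_given_acc_lrt": lrt(m2, m3, "cloze_given_accuracy"),
        "model2": m2,
    }


def prearticle_analysis(table: pd.DataFrame) -> dict:
    """Models 3 vs 4 on the pre-article (-500..-100 ms) window, articles.

    A sanity control: the sentence context is identical before the article,
    so a cloze effect in this window cannot be caused by the article and
    indexes residual pre-stimulus differences instead.  The input table
    must carry ``roi_prearticle`` computed from the 100 ms-baselined data.
    """
    out = run_ladder(table, "article", response="roi_prearticle")
    return {"cloze_lrt": out["cloze_lrt"], "best": out["best"]}


def p600_control(table: pd.DataFrame):
    """Grammaticality contrast on the P600 window (500-800 ms), control trials.

        Model 1: ~ grammaticality + (grammaticality | subject) + (gram | item)
        Model 2: ~ 1              + same random effects

    Grammaticality is deviation coded +-0.5, so the coefficient is the
    ungrammatical-minus-grammatical difference in uV.  Returns
    ``(LrtResult, LmmResult)``; df is 1.
    """
    sub = table[table["experiment"] == "control"] if "experiment" in table.columns else table
    if sub.empty:
        raise ValueError("no control-experiment trials in the table")
    if sub["grammatical"].nunique() < 2:
        raise ValueError("control trials must include both grammaticality levels")
    sub = _encode(sub)
    terms = (
        RandomTerm("subject_id", ("1", "gram_dev")),
        RandomTerm("item_id", ("1", "gram_dev")),
    )
    m1 = fit_model(sub, ["grammaticality"], terms, "roi_p600", "grammaticality")
    m2 = fit_model(sub, [], terms, "roi_p600", None, theta0=m1.fit.theta)
    m1 = ensure_nested(
        m1, m2,
        lambda **kw: fit_model(sub, ["grammaticality"], terms, "roi_p600",
                               "grammaticality", **kw),
    )
    return lrt(m1, m2, "grammaticality"), m1
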