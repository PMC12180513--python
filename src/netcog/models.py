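"""Two-stage knowledge models.

Stage 1 (subject level): each subject's binary friendship guesses from the
knowledge task are regressed, by maximum-likelihood logistic regression, on
two binary predictors derived from the veridical network —

    friend guess ~ b0 + b1 * true_friendship + b2 * true_community

``b1`` measures micro-level knowledge (reliance on specific pairwise
friendships) and ``b2`` meso-level knowledge (reliance on shared consensus
community membership).  Subjects whose coefficients or standard errors are
group outliers (beyond 3 SD), or whose fits do not converge, are excluded.

Stage 2 (group level): the subject-level coefficients become predictors in
ordinary least-squares regressions of network centrality — change scores,
contemporaneous centrality, or late influence with early-meso x late-micro
interactions — with optional friend-count and extroversion controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .communities import MesoTieMatrix

#: Wald-SE threshold beyond which a subject-level logistic fit is treated as
#: non-converged (quasi-separation inflates SEs by orders of magnitude).
SE_BLOWUP = 50.0


@dataclass
class SubjectKnowledge:
    """Per-subject micro/meso knowledge estimates from the stage-1 logistic fit."""

    subject: Hashable
    wave: int | None
    beta0: float
    beta_micro: float
    beta_meso: float
    se_micro: float
    se_meso: float
    converged: bool
    excluded: bool = False
    reason: str | None = None


@dataclass
class TermResult:
    name: str
    beta: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class GroupModelResult:
    """One fitted group-level OLS model (coefficients, 95% CIs, p-values)."""

    model_id: str
    outcome: str
    terms: list[TermResult]
    n_subjects: int
    #: column means of the design (for marginal predictions over a focal term)
    design_means: dict[str, float] = field(default_factory=dict)
    _fit: object | None = field(default=None, repr=False, compare=False)

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"term {name!r} not in model {self.model_id}")


def build_design(
    responses: pd.DataFrame,
    net: nx.Graph,
    meso: MesoTieMatrix,
) -> pd.DataFrame:
    """Per-trial design rows: guess, true_friendship, true_community.

    ``responses`` must have columns subject, block_target, probe, guess.  The
    ground truth is looked up in the friendship network and consensus meso-tie
    matrix of the immediately preceding friendship survey.  Pairs involving an
    unassigned subject have true_community = 0.
    """
    required = {"subject", "block_target", "probe", "guess"}
    missing = required - set(responses.columns)
    if missing:
        raise ValueError(f"responses missing columns: {sorted(missing)}")
    known = set(net.nodes())
    rows = []
    for rec in responses.itertuples(index=False):
        if rec.block_target not in known or rec.probe not in known:
            bad = rec.block_target if rec.block_target not in known else rec.probe
            raise ValueError(f"trial references unknown subject {bad!r}")
        rows.append(
            {
                "subject": rec.subject,
                "guess": int(rec.guess),
                "true_friendship": int(net.has_edge(rec.block_target, rec.probe)),
                "true_community": meso.tie(rec.block_target, rec.probe),
            }
        )
    return pd.DataFrame(rows, columns=["subject", "guess", "true_friendship", "true_community"])


def fit_subject_knowledge(
    rows: pd.DataFrame,
    subject: Hashable | None = None,
    wave: int | None = None,
    min_trials: int = 870,
) -> SubjectKnowledge:
    """Stage-1 logistic fit for one subject.

    Trials are aggregated into the four (true_friendship, true_community)
    cells and fit as a binomial GLM with logit link — the MLE and standard
    errors are identical to the Bernoulli-trial fit.  Degenerate inputs
    (constant predictor, separation, SE blow-up) yield ``converged=False``
    rather than an exception.
    """
    if subject is None and "subject" in rows.columns:
        uniq = rows["subject"].unique()
        if len(uniq) != 1:
            raise ValueError("rows for exactly one subject expected")
        subject = uniq[0]
    if len(rows) < min_trials:
        raise ValueError(
            f"subject {subject!r}: {len(rows)} trials < required minimum {min_trials}"
        )

    def _failed() -> SubjectKnowledge:
        return SubjectKnowledge(
            subject=subject, wave=wave, beta0=np.nan, beta_micro=np.nan,
            beta_meso=np.nan, se_micro=np.nan, se_meso=np.nan,
            converged=False, excluded=True, reason="nonconvergence",
        )

    if rows["true_friendship"].nunique() < 2 or rows["true_community"].nunique() < 2:
        return _failed()

    cells = (
        rows.groupby(["true_friendship", "true_community"])["guess"]
        .agg(successes="sum", n="count")
        .reset_index()
    )
    endog = np.column_stack([cells["successes"], cells["n"] - cells["successes"]])
    exog = sm.add_constant(cells[["true_friendship", "true_community"]].to_numpy(float))
    try:
        # separation / saturated-cell degeneracies surface as warnings here and
        # are converted to the converged=False flag below
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(maxiter=100)
    except Exception:
        return _failed()
    params = np.asarray(fit.params, float)
    ses = np.asarray(fit.bse, float)
    ok = (
        bool(getattr(fit, "converged", True))
        and np.all(np.isfinite(params))
        and np.all(np.isfinite(ses))
        and np.all(ses < SE_BLOWUP)
    )
    if not ok:
        return _failed()
    return SubjectKnowledge(
        subject=subject, wave=wave,
        beta0=float(params[0]), beta_micro=float(params[1]), beta_meso=float(params[2]),
        se_micro=float(ses[1]), se_meso=float(ses[2]),
        converged=True,
    )


def exclude_outliers(
    estimates: Sequence[SubjectKnowledge],
    n_sd: float = 3.0,
) -> list[SubjectKnowledge]:
    """Apply the group-level 3-SD exclusion rules, per coefficient.

    A subject is excluded when either knowledge coefficient lies more than
    ``n_sd`` group SDs from the group mean (reason ``beta_outlier``), or when
    either standard error lies more than ``n_sd`` SDs from the mean standard
    error (reason ``se_outlier``).  Non-converged fits are already excluded.
    Group means/SDs are computed over converged subjects; if a SD is zero that
    rule excludes nobody.  The operator is idempotent: flags are recomputed
    from the same converged pool each time.
    """
    if len(estimates) < 3:
        raise ValueError("need at least 3 subjects to apply group exclusion rules")
    pool = [e for e in estimates if e.converged]
    stats_for: dict[str, tuple[float, float]] = {}
    for attr in ("beta_micro", "beta_meso", "se_micro", "se_meso"):
        values = np.array([getattr(e, attr) for e in pool], float)
        stats_for[attr] = (values.mean(), values.std(ddof=0)) if len(values) else (0.0, 0.0)

    def _outlier(value: float, attr: str) -> bool:
        mean, sd = stats_for[attr]
        return sd > 0 and abs(value - mean) > n_sd * sd

    out = []
    for e in estimates:
        if not e.converged:
            out.append(replace(e, excluded=True, reason="nonconvergence"))
        elif _outlier(e.beta_micro, "beta_micro") or _outlier(e.beta_meso, "beta_meso"):
            out.append(replace(e, excluded=True, reason="beta_outlier"))
        elif _outlier(e.se_micro, "se_micro") or _outlier(e.se_meso, "se_meso"):
            out.append(replace(e, excluded=True, reason="se_outlier"))
        else:
            out.append(replace(e, excluded=False, reason=None))
    return out


def knowledge_frame(estimates: Iterable[SubjectKnowledge]) -> pd.DataFrame:
    """Tabular view of subject-knowledge estimates (one row per subject)."""
    return pd.DataFrame(
        [
            {
                "subject": e.subject, "wave": e.wave, "beta0": e.beta0,
                "beta_micro": e.beta_micro, "beta_meso": e.beta_meso,
                "se_micro": e.se_micro, "se_meso": e.se_meso,
                "converged": e.converged, "excluded": e.excluded, "reason": e.reason,
            }
            for e in estimates
        ]
    )


def _check_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        degenerate = [c for c in design.columns if design[c].nunique() <= 1 and c != "const"]
        raise ValueError(
            "rank-deficient design"
            + (f"; collinear/constant terms: {degenerate}" if degenerate else "")
        )


def _fit_ols(
    design: pd.DataFrame,
    outcome: pd.Series,
    model_id: str,
    outcome_name: str,
    min_n: int = 10,
) -> GroupModelResult:
    if len(design) < min_n:
        raise ValueError(f"{model_id}: only {len(design)} subjects; need >= {min_n}")
    design = sm.add_constant(design, has_constant="add")
    _check_rank(design)
    fit = sm.OLS(outcome.to_numpy(float), design).fit()
    ci = fit.conf_int(alpha=0.05)
    terms = [
        TermResult(
            name=name,
            beta=float(fit.params[name]),
            ci_low=float(ci.loc[name, 0]),
            ci_high=float(ci.loc[name, 1]),
            p_value=float(fit.pvalues[name]),
        )
        for name in design.columns
    ]
    return GroupModelResult(
        model_id=model_id,
        outcome=outcome_name,
        terms=terms,
        n_subjects=len(design),
        design_means={c: float(design[c].mean()) for c in design.columns},
        _fit=fit,
    )


def _merge_knowledge(
    knowledge: Iterable[SubjectKnowledge],
    prefix: str,
) -> pd.DataFrame:
    rows = [
        {
            "subject": e.subject,
            f"{prefix}_micro": e.beta_micro,
            f"{prefix}_meso": e.beta_meso,
        }
        for e in knowledge
        if e.converged and not e.excluded
    ]
    return pd.DataFrame(rows).set_index("subject")


def fit_change_model(
    knowledge: Sequence[SubjectKnowledge],
    deltas: Mapping[Hashable, float],
    outcome_name: str = "delta_influence",
    controls: pd.DataFrame | None = None,
) -> GroupModelResult:
    """Early knowledge predicting centrality change (late minus early).

    ``controls`` may carry additional numeric columns (e.g. early friend
    count and extroversion) indexed by subject; with controls the model is
    the M2 variant, without it M1.
    """
    know = _merge_knowledge(knowledge, "fall")
    df = know.join(pd.Series(deltas, name="outcome"), how="inner")
    if controls is not None:
        df = df.join(controls, how="inner")
    df = df.dropna()
    model_id = "change_M2" if controls is not None else "change_M1"
    return _fit_ols(df.drop(columns="outcome"), df["outcome"], model_id, outcome_name)


def fit_current_model(
    knowledge: Sequence[SubjectKnowledge],
    centrality: Mapping[Hashable, float],
    outcome_name: str,
    season: str = "fall",
    model_id: str | None = None,
) -> GroupModelResult:
    """Contemporaneous knowledge predicting current centrality."""
    know = _merge_knowledge(knowledge, season)
    df = know.join(pd.Series(centrality, name="outcome"), how="inner").dropna()
    return _fit_ols(
        df.drop(columns="outcome"), df["outcome"],
        model_id or f"current_{season}_{outcome_name}", outcome_name,
    )


def fit_interaction_model(
    fall_knowledge: Sequence[SubjectKnowledge],
    spring_knowledge: Sequence[SubjectKnowledge],
    spring_influence: Mapping[Hashable, float],
    full: bool = False,
) -> GroupModelResult:
    """Late influence from the early-meso x late-micro knowledge interaction.

    The parsimonious model (``full=False``) has fall-meso and spring-micro
    main effects plus their product.  ``full=True`` adds both waves' other
    main effects and all four early-by-late products.
    """
    fall = _merge_knowledge(fall_knowledge, "fall")
    spring = _merge_knowledge(spring_knowledge, "spring")
    df = fall.join(spring, how="inner").join(
        pd.Series(spring_influence, name="outcome"), how="inner"
    ).dropna()
    if full:
        design = df[["fall_micro", "fall_meso", "spring_micro", "spring_meso"]].copy()
        for early in ("fall_meso", "fall_micro"):
            for late in ("spring_micro", "spring_meso"):
                design[f"{early}_x_{late}"] = df[early] * df[late]
        model_id = "interaction_M2"
    else:
        design = df[["fall_meso", "spring_micro"]].copy()
        design["fall_meso_x_spring_micro"] = df["fall_meso"] * df["spring_micro"]
        model_id = "interaction_M1"
    return _fit_ols(design, df["outcome"], model_id, "spring_influence")


def marginal_predictions(
    result: GroupModelResult,
    focal: str,
    grid: Sequence[float],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Model predictions over a grid of one focal predictor.

    Non-focal terms (including any interaction columns) are held at their
    sample means; the confidence ribbon comes from the coefficient
    covariance via the t distribution.
    """
    fit = result._fit
    if fit is None:
        raise ValueError("model result does not carry a stored fit")
    names = list(result.design_means)
    if focal not in names:
        raise KeyError(f"focal term {focal!r} not in model {result.model_id}")
    x = np.tile([result.design_means[c] for c in names], (len(grid), 1))
    x[:, names.index(focal)] = np.asarray(grid, float)
    beta = np.asarray(fit.params, float)
    cov = np.asarray(fit.cov_params(), float)
    pred = x @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", x, cov, x))
    tcrit = stats.t.ppf(1 - alpha / 2, fit.df_resid)
    return pd.DataFrame(
        {
            focal: grid,
            "predicted": pred,
            "ci_low": pred - tcrit * se,
            "ci_high": pred + tcrit * se,
        }
    )
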