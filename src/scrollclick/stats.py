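"""Within-participant statistics and the motor-hysteresis mixed model.

``rm_anova_gg`` implements a fully within-participant factorial ANOVA of
arbitrary order on participant x cell mean tables: classical
sums-of-squares decomposition with subjects as a random factor, F tests of
each effect against its effect-by-subject interaction, Greenhouse-Geisser
sphericity correction of the degrees of freedom, and generalized eta
squared with all subject-related variance components in the denominator
(the standard definition for fully within designs).

``build_hysteresis_predictors`` and ``fit_mixed_model`` implement the
carry-over analysis: trial-level click positions regressed on the current
scroll's signed amplitude and direction, the start position or inducer
eccentricity, and the previous trial's click position and (direction-
signed, centered) click eccentricity, with by-participant random slopes
for all predictors.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert

import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "AnovaEffect",
    "ContrastResult",
    "FixedEffect",
    "MixedModelResult",
    "rm_anova_gg",
    "rm_anova_cube",
    "consecutive_contrasts",
    "build_hysteresis_predictors",
    "fit_mixed_model",
    "INDUCER_ECCENTRICITY_CODES",
    "ECCENTRICITY_CENTER",
]

#: predictor coding of the Exp 2 inducer eccentricity conditions
#: (distance of the inducer targets from the screen center)
INDUCER_ECCENTRICITY_CODES = {"low": 0.14, "medium": 0.43, "high": 0.71}

#: centering constant for click eccentricity (half its [0, 0.5] range)
ECCENTRICITY_CENTER = 0.25


@dataclass(frozen=True)
class AnovaEffect:
    effect: str
    F: float
    df_num: float
    df_den: float
    p: float
    eta_g: float
    epsilon: float
    ss_effect: float = np.nan
    ss_error: float = np.nan


@dataclass(frozen=True)
class ContrastResult:
    pair: tuple
    t: float
    df: int
    p: float
    d_z: float
    degenerate: bool = False


@dataclass(frozen=True)
class FixedEffect:
    name: str
    beta_hat: float
    se: float
    F: float
    df_num: float
    df_den: float
    p: float
    vif: float


@dataclass(frozen=True)
class MixedModelResult:
    fixed: List[FixedEffect]
    r2_marginal: float
    r2_conditional: float
    cov_struct: str
    converged: bool
    notes: tuple = ()

    def summary(self) -> str:
        lines = ["Linear mixed model (by-participant random slopes for all "
                 "predictors)",
                 f"covariance structure: {self.cov_struct}   "
                 f"converged: {self.converged}",
                 f"marginal R2 = {self.r2_marginal:.3f}   "
                 f"conditional R2 = {self.r2_conditional:.3f}",
                 "",
                 f"{'fixed effect':<26}{'beta':>9}{'SE':>8}{'F':>10}"
                 f"{'df':>14}{'p':>10}{'VIF':>7}"]
        for fe in self.fixed:
            df = f"(1,{fe.df_den:.1f})"
            lines.append(f"{fe.name:<26}{fe.beta_hat:>9.3f}{fe.se:>8.3f}"
                         f"{fe.F:>10.2f}{df:>14}{fe.p:>10.4f}{fe.vif:>7.2f}")
        for n in self.notes:
            lines.append(f"note: {n}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _effect_decomposition(Y: np.ndarray) -> Dict[frozenset, float]:
    """Classical SS decomposition of a complete balanced cube.

    Axis 0 is the subject; remaining axes are within factors. Returns the
    sum of squares of every effect term (every non-empty subset of axes),
    computed by inclusion-exclusion on marginal means.
    """
    n_axes = Y.ndim
    all_axes = tuple(range(n_axes))
    sizes = Y.shape
    terms: Dict[frozenset, np.ndarray] = {}
    grand = Y.mean(keepdims=True)
    terms[frozenset()] = grand
    for r in range(1, n_axes + 1):
        for T in itertools.combinations(all_axes, r):
            Ts = frozenset(T)
            M = Y.mean(axis=tuple(a for a in all_axes if a not in Ts),
                       keepdims=True)
            eff = M.copy()
            for U in terms:
                if U < Ts:
                    eff = eff - terms[U]
            terms[Ts] = eff
    ss = {}
    for Ts, eff in terms.items():
        if not Ts:
            continue
        mult = int(np.prod([sizes[a] for a in all_axes if a not in Ts]))
        ss[Ts] = float(np.sum(eff ** 2)) * mult
    return ss


def _gg_epsilon(Y: np.ndarray, effect_axes: Tuple[int, ...]) -> float:
    """Greenhouse-Geisser epsilon for one within effect.

    Cells are averaged over factors outside the effect; epsilon is computed
    from the covariance of orthonormal (Helmert) contrast scores:
    eps = tr(S)^2 / (d * tr(S @ S)).
    """
    n_axes = Y.ndim
    other = tuple(a for a in range(1, n_axes) if a not in effect_axes)
    Z = Y.mean(axis=other) if other else Y
    # flatten effect axes in order
    n = Z.shape[0]
    Z = Z.reshape(n, -1)
    C = np.ones((1, 1))
    for a in effect_axes:
        k = Y.shape[a]
        C = np.kron(C, helmert(k, full=False))
    d = C.shape[0]
    if d <= 1:
        return 1.0
    W = Z @ C.T
    S = np.cov(W, rowvar=False)
    tr = np.trace(S)
    denom = d * float(np.sum(S * S))
    if denom <= 0:
        return 1.0
    eps = tr * tr / denom
    return float(min(max(eps, 1.0 / d), 1.0))


def rm_anova_cube(Y: np.ndarray, factor_names: Sequence[str],
                  correction: str = "gg") -> List[AnovaEffect]:
    """Fully within-participant factorial ANOVA on a cell-mean cube.

    Parameters
    ----------
    Y : ndarray, shape (n_participants, k1, ..., km)
        One cell mean per participant per factor combination.
    factor_names : sequence of str
        Names of the m within factors, in axis order.
    correction : {"gg", "none"}
        Whether to apply the Greenhouse-Geisser correction to the degrees
        of freedom used for the p value.

    Returns one :class:`AnovaEffect` per main effect and interaction.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != len(factor_names) + 1:
        raise ValueError("cube rank does not match number of factors")
    n = Y.shape[0]
    if n < 2:
        raise ValueError("at least two participants are required")
    ss = _effect_decomposition(Y)
    factor_axes = tuple(range(1, Y.ndim))
    # all subject-related variance components (subject main effect and every
    # effect-by-subject interaction) enter the generalized eta denominator
    subj_terms = sum(v for T, v in ss.items() if 0 in T)
    results = []
    for r in range(1, len(factor_axes) + 1):
        for E in itertools.combinations(factor_axes, r):
            Es = frozenset(E)
            err = Es | {0}
            df_num = float(np.prod([Y.shape[a] - 1 for a in E]))
            df_den = df_num * (n - 1)
            ms_e = ss[Es] / df_num
            ms_err = ss[err] / df_den
            F = ms_e / ms_err if ms_err > 0 else (0.0 if ss[Es] == 0 else np.inf)
            eps = _gg_epsilon(Y, E) if correction == "gg" else 1.0
            p = float(sps.f.sf(F, df_num * eps, df_den * eps)) if np.isfinite(F) else 0.0
            eta_g = ss[Es] / (ss[Es] + subj_terms) if (ss[Es] + subj_terms) > 0 else 0.0
            results.append(AnovaEffect(
                effect=":".join(factor_names[a - 1] for a in E),
                F=float(F), df_num=df_num * eps, df_den=df_den * eps,
                p=p, eta_g=float(eta_g), epsilon=float(eps),
                ss_effect=ss[Es], ss_error=ss[err]))
    return results


def _table_to_cube(cell_means: pd.DataFrame, factors: Sequence[str],
                   dv: str, participant: str) -> Tuple[np.ndarray, list]:
    levels = [sorted(cell_means[f].unique()) for f in factors]
    participants = sorted(cell_means[participant].unique())
    pivot = cell_means.set_index([participant, *factors])[dv]
    if pivot.index.has_duplicates:
        raise ValueError("more than one value per participant x cell; "
                         "aggregate to cell means first")
    shape = (len(participants), *map(len, levels))
    Y = np.full(shape, np.nan)
    idx = {p: i for i, p in enumerate(participants)}
    lidx = [{l: i for i, l in enumerate(ls)} for ls in levels]
    for key, val in pivot.items():
        p, *cell = key if isinstance(key, tuple) else (key,)
        Y[(idx[p], *[lidx[j][c] for j, c in enumerate(cell)])] = val
    if np.isnan(Y).any():
        missing = [(participants[t[0]],
                    *[levels[j][t[j + 1]] for j in range(len(factors))])
                   for t in zip(*np.nonzero(np.isnan(Y)))]
        raise ValueError(f"missing cells (participant, {', '.join(factors)}): "
                         f"{missing[:20]}{' ...' if len(missing) > 20 else ''}")
    return Y, levels


def rm_anova_gg(cell_means: pd.DataFrame, factors: Sequence[str],
                dv: str = "initial_click_y",
                participant: str = "participant") -> List[AnovaEffect]:
    """GG-corrected within-participant ANOVA on a long cell-mean table.

    ``cell_means`` must hold exactly one row per participant x factor cell
    (as produced by :func:`scrollclick.reduction.summarize_conditions`);
    missing cells raise an error listing them.
    """
    Y, _ = _table_to_cube(cell_means, factors, dv, participant)
    return rm_anova_cube(Y, list(factors))


def consecutive_contrasts(cell_means: pd.DataFrame, factor: str,
                          dv: str = "initial_click_y",
                          participant: str = "participant",
                          levels: Optional[Sequence] = None) -> List[ContrastResult]:
    """Paired t tests between adjacent levels of an ordered within factor.

    Cell values are averaged over any other factors per participant first.
    ``d_z = t / sqrt(n)``. A zero-variance difference is flagged degenerate
    rather than reported as an unbounded t.
    """
    means = (cell_means.groupby([participant, factor], sort=True)[dv]
             .mean().unstack(factor))
    if levels is None:
        levels = list(means.columns)
    if len(levels) < 2:
        raise ValueError("need at least two factor levels")
    if len(means) < 2:
        raise ValueError("need at least two participants")
    out = []
    n = len(means)
    for a, b in zip(levels[:-1], levels[1:]):
        diff = (means[a] - means[b]).to_numpy(float)
        sd = diff.std(ddof=1)
        if sd == 0:
            mean_d = float(diff.mean())
            out.append(ContrastResult((a, b), t=0.0 if mean_d == 0 else np.inf,
                                      df=n - 1, p=np.nan if mean_d else 1.0,
                                      d_z=0.0 if mean_d == 0 else np.inf,
                                      degenerate=mean_d != 0))
            continue
        t, p = sps.ttest_rel(means[a], means[b])
        out.append(ContrastResult((a, b), t=float(t), df=n - 1, p=float(p),
                                  d_z=float(t / np.sqrt(n))))
    return out


# ---------------------------------------------------------------------------
# hysteresis predictors and mixed model
# ---------------------------------------------------------------------------

def build_hysteresis_predictors(trial_table: pd.DataFrame,
                                experiment: str) -> pd.DataFrame:
    """Build the trial-level predictor table for the carry-over analysis.

    Expects a tidy trial table (one row per trial) with columns
    ``participant``, ``block``, ``trial_index``, ``displacement``,
    ``initial_click_y``, ``trial_duration`` and, per experiment,
    ``start_vertical`` (exp1) or ``eccentricity_condition`` (exp2). Trials
    must be ordered within participant; the first trial of each block is
    dropped, as is any trial whose own or preceding trial duration exceeds
    10 s.

    Predictor coding:

    * ``amplitude`` — signed displacement of the current scroll.
    * ``direction`` — -0.5 for downward, +0.5 for upward scrolls.
    * ``prev_click_y`` — previous trial's initial click position.
    * ``prev_ecc_signed`` — previous click eccentricity |y - 0.5| centered
      on 0.25, multiplied by +1 when the current trial scrolls downward
      and -1 when upward (a click at the top of the screen yields +0.25
      before a downward scroll and -0.25 before an upward one).
    * ``start_position`` (exp1) — vertical start offset (-0.4, 0, 0.4).
    * ``inducer_eccentricity`` (exp2) — 0.14 / 0.43 / 0.71 for low /
      medium / high blocks.
    """
    df = trial_table.copy()
    for col in ("participant", "block", "trial_index", "displacement",
                "initial_click_y", "trial_duration"):
        if col not in df.columns:
            raise ValueError(f"trial table lacks required column {col!r}")
    order_keys = ["participant", "block"]
    if "subblock" in df.columns and df["subblock"].notna().any():
        order_keys.append("subblock")
    order_keys.append("trial_index")
    sorted_df = df.sort_values(order_keys, kind="stable")
    if not (sorted_df.index.to_numpy() == df.index.to_numpy()).all():
        raise ValueError("trial table must be ordered within participant "
                         "(participant, block, subblock, trial_index)")

    g = df.groupby(["participant", "block"], sort=False)
    df["prev_click_y"] = g["initial_click_y"].shift(1)
    df["prev_duration"] = g["trial_duration"].shift(1)
    df["_first_of_block"] = df["prev_click_y"].isna()

    keep = (~df["_first_of_block"]
            & (df["trial_duration"] <= EXCLUSION_SECONDS_LMM)
            & (df["prev_duration"] <= EXCLUSION_SECONDS_LMM))
    df = df.loc[keep].copy()

    d = df["displacement"].to_numpy(float)
    down_sign = np.where(d < 0, 1.0, -1.0)  # +1 when current scroll is downward
    prev_ecc = np.abs(df["prev_click_y"].to_numpy(float) - 0.5)
    df["prev_ecc_signed"] = (prev_ecc - ECCENTRICITY_CENTER) * down_sign
    df["amplitude"] = d
    df["direction"] = np.where(d > 0, 0.5, -0.5)

    predictors = ["amplitude", "direction", "prev_click_y", "prev_ecc_signed"]
    if experiment == "exp1":
        df["start_position"] = df["start_vertical"].astype(float)
        predictors.insert(2, "start_position")
    elif experiment == "exp2":
        df["inducer_eccentricity"] = df["eccentricity_condition"].map(
            INDUCER_ECCENTRICITY_CODES)
        predictors.insert(2, "inducer_eccentricity")
    else:
        raise ValueError(f"unknown experiment {experiment!r}")
    df.attrs["predictors"] = predictors
    return df.drop(columns=["prev_duration", "_first_of_block"])


EXCLUSION_SECONDS_LMM = 10.0


def _vifs(X: np.ndarray) -> np.ndarray:
    """Variance inflation factors of centered predictor columns."""
    Xc = X - X.mean(axis=0)
    R = np.corrcoef(Xc, rowvar=False)
    R = np.atleast_2d(R)
    try:
        return np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        return np.full(X.shape[1], np.inf)


def fit_mixed_model(predictor_table: pd.DataFrame,
                    dv: str = "initial_click_y",
                    predictors: Optional[Sequence[str]] = None,
                    group: str = "participant",
                    cov_struct: str = "unstructured",
                    reml: bool = True) -> MixedModelResult:
    """Fit the hysteresis mixed model with by-participant random slopes.

    Estimation uses statsmodels' MixedLM (REML by default). The random
    effects (intercept plus one slope per predictor) have an unstructured
    covariance by default, falling back to a diagonal structure when the
    unstructured fit fails to converge or is singular. Per-predictor F
    statistics are Wald squares of t ratios with one numerator df; the
    denominator df uses a group-count approximation (n_participants - 1),
    appropriate for within-participant predictors carrying random slopes.
    Marginal and conditional R2 follow the variance-partition formulation.
    """
    predictors = list(predictors or predictor_table.attrs.get("predictors") or [])
    if not predictors:
        raise ValueError("no predictors given and none recorded on the table")
    groups = predictor_table[group].to_numpy()
    n_groups = len(np.unique(groups))
    if n_groups < 2:
        raise ValueError("at least two participants are required")
    counts = predictor_table.groupby(group).size()
    if (counts < 2).any():
        raise ValueError("every participant needs at least two trials")

    Xp = predictor_table[predictors].to_numpy(float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(Xp)), Xp])) < len(predictors) + 1:
        corr = np.corrcoef(Xp, rowvar=False)
        bad = [(predictors[i], predictors[j])
               for i in range(len(predictors)) for j in range(i + 1, len(predictors))
               if abs(corr[i, j]) > 0.999]
        raise ValueError(f"rank-deficient fixed design; collinear columns: {bad}")

    y = predictor_table[dv].to_numpy(float)
    X = np.column_stack([np.ones(len(Xp)), Xp])
    exog_names = ["intercept", *predictors]
    notes: List[str] = []

    def _fit(struct: str):
        model = MixedLM(y, X, groups=groups, exog_re=X)
        free = None
        if struct == "diagonal":
            free = MixedLMParams.from_components(
                fe_params=np.ones(X.shape[1]),
                cov_re=np.eye(X.shape[1]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = model.fit(reml=reml, free=free, method="lbfgs", maxiter=500)
        return model, res

    struct_used = cov_struct
    model, res = _fit(cov_struct)
    singular = False
    try:
        eigvals = np.linalg.eigvalsh(res.cov_re)
        singular = eigvals.min() < 1e-10 * max(eigvals.max(), 1e-12)
    except np.linalg.LinAlgError:
        singular = True
    if cov_struct == "unstructured" and (not res.converged or singular):
        notes.append("unstructured random-effect covariance singular or "
                     "non-convergent; refit with diagonal structure")
        struct_used = "diagonal"
        model, res = _fit("diagonal")

    vifs = _vifs(Xp)
    ddf = float(n_groups - 1)
    fixed = []
    for j, name in enumerate(exog_names):
        if name == "intercept":
            continue
        b = float(res.fe_params[j])
        se = float(res.bse_fe[j])
        F = (b / se) ** 2 if se > 0 else np.inf
        p = float(sps.f.sf(F, 1, ddf))
        fixed.append(FixedEffect(name=name, beta_hat=b, se=se, F=float(F),
                                 df_num=1.0, df_den=ddf, p=p,
                                 vif=float(vifs[j - 1])))

    # variance partition R2
    var_fixed = float(np.var(X @ res.fe_params))
    var_random = float(np.mean(np.einsum("ij,jk,ik->i", X, res.cov_re, X)))
    var_resid = float(res.scale)
    total = var_fixed + var_random + var_resid
    r2m = var_fixed / total if total > 0 else 0.0
    r2c = (var_fixed + var_random) / total if total > 0 else 0.0

    return MixedModelResult(fixed=fixed, r2_marginal=r2m, r2_conditional=r2c,
                            cov_struct=struct_used, converged=bool(res.converged),
                            notes=tuple(notes))
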