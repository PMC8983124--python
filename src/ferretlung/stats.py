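"""Statistical stages: longitudinal mixed models, paired log-ratio tests,
and inhibition-capacity AUC.

The longitudinal model for repeated lung-function measures is

    value_ij = sex intercept + beta_genotype * age_ij + u_i + e_ij

with a random intercept ``u_i ~ N(0, sigma_u^2)`` per animal and
residuals ``e_ij ~ N(0, sigma^2)``, fitted by REML through statsmodels
MixedLM.  Genotype-specific age slopes come from a cell-means
interaction coding (no main age term), so each genotype's slope is a
directly interpretable fixed effect; slope contrasts are Wald tests on
the fitted covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import InputError, DegenerateAnalysisError
from .synthetic import CohortPreset, make_cohort


@dataclass
class MixedModelFit:
    """Fixed and random effects of the longitudinal model."""

    slopes: dict  # genotype -> age slope (response units per day)
    slope_se: dict
    sex_intercepts: dict  # sex -> fitted intercept (reference-coded)
    random_intercept_sd: float
    residual_sd: float
    slope_contrasts: pd.DataFrame | None = None  # genotype pair tests
    n_animals: int = 0
    n_obs: int = 0
    converged: bool = True


@dataclass
class PairedRatioResult:
    """One-sample location test of log(case/control) against zero."""

    ratios: np.ndarray
    mean_log_ratio: float
    geometric_mean: float
    t_statistic: float
    p_value: float
    n: int


def fit_longitudinal(
    cohort: pd.DataFrame,
    response: str = "ic_per_ln",
    reml: bool = True,
) -> MixedModelFit:
    """Fit the random-intercept model with genotype-specific age slopes.

    Expects tidy columns ``animal, genotype, sex, age_days`` plus the
    response.  Raises :class:`DegenerateAnalysisError` when every animal
    has a single observation (random intercept unidentifiable).  A
    zero-residual cohort (noise-free synthetic data) is detected and
    resolved by an exact per-animal least-squares fit, since the REML
    likelihood degenerates there.
    """
    required = {"animal", "genotype", "sex", "age_days", response}
    missing = required - set(cohort.columns)
    if missing:
        raise InputError(f"cohort table missing columns: {sorted(missing)}")
    if cohort["animal"].nunique() < 2:
        raise DegenerateAnalysisError("need at least 2 animals")
    if (cohort.groupby("animal").size() < 2).all():
        raise DegenerateAnalysisError(
            "every animal has a single observation - random intercept unidentifiable"
        )

    df = cohort.copy()
    genotypes = sorted(df["genotype"].unique())
    sexes = sorted(df["sex"].unique())

    # Exact path for noise-free data: animal dummies absorb sex + random
    # intercepts; slopes are recovered exactly by OLS.
    exact = _exact_fit_if_noise_free(df, response, genotypes)
    if exact is not None:
        return exact

    formula = f"{response} ~ C(sex) + age_days:C(genotype)"
    with warnings.catch_warnings():
        # variance components may legitimately hit the zero boundary on
        # small cohorts; the fixed-effect estimates remain valid
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, df, groups=df["animal"])
        result = model.fit(reml=reml, method="lbfgs")

    slopes, slope_se = {}, {}
    for g in genotypes:
        name = f"age_days:C(genotype)[{g}]"
        slopes[g] = float(result.params[name])
        slope_se[g] = float(result.bse[name])
    sex_intercepts = {sexes[0]: float(result.params["Intercept"])}
    for s in sexes[1:]:
        sex_intercepts[s] = float(
            result.params["Intercept"] + result.params[f"C(sex)[T.{s}]"]
        )

    contrasts = None
    if len(genotypes) > 1:
        rows = []
        cov = result.cov_params()
        for i, g1 in enumerate(genotypes):
            for g2 in genotypes[i + 1 :]:
                n1, n2 = f"age_days:C(genotype)[{g1}]", f"age_days:C(genotype)[{g2}]"
                diff = slopes[g1] - slopes[g2]
                var = cov.loc[n1, n1] + cov.loc[n2, n2] - 2 * cov.loc[n1, n2]
                z = diff / np.sqrt(var) if var > 0 else np.nan
                rows.append(
                    {
                        "genotype_1": g1,
                        "genotype_2": g2,
                        "slope_difference": diff,
                        "z": z,
                        "p_value": 2 * sps.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                    }
                )
        contrasts = pd.DataFrame(rows)

    return MixedModelFit(
        slopes=slopes,
        slope_se=slope_se,
        sex_intercepts=sex_intercepts,
        random_intercept_sd=float(np.sqrt(max(result.cov_re.iloc[0, 0], 0.0))),
        residual_sd=float(np.sqrt(max(result.scale, 0.0))),
        slope_contrasts=contrasts,
        n_animals=int(df["animal"].nunique()),
        n_obs=len(df),
        converged=bool(result.converged),
    )


def _exact_fit_if_noise_free(df, response, genotypes, tol=1e-10):
    """Noise-free cohorts: per-animal intercept + genotype slope OLS.

    Returns a MixedModelFit if the fit is exact (zero residual), else None.
    """
    animals = pd.get_dummies(df["animal"], dtype=float)
    X = animals.to_numpy()
    for g in genotypes:
        X = np.column_stack([X, (df["genotype"] == g).to_numpy() * df["age_days"].to_numpy()])
    y = df[response].to_numpy(dtype=float)
    coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    ssr = float(np.sum((y - fitted) ** 2))
    scale = float(np.sum(y**2)) or 1.0
    if ssr / scale > tol:
        return None
    k = animals.shape[1]
    slopes = {g: float(coef[k + i]) for i, g in enumerate(genotypes)}
    intercepts = pd.Series(coef[:k], index=animals.columns)
    sex_of = df.drop_duplicates("animal").set_index("animal")["sex"]
    sex_intercepts = {
        s: float(intercepts[sex_of[sex_of == s].index].mean())
        for s in sorted(sex_of.unique())
    }
    per_sex_dev = intercepts - sex_of.map(sex_intercepts).astype(float)
    return MixedModelFit(
        slopes=slopes,
        slope_se={g: 0.0 for g in genotypes},
        sex_intercepts=sex_intercepts,
        random_intercept_sd=float(per_sex_dev.std(ddof=0)),
        residual_sd=0.0,
        slope_contrasts=None,
        n_animals=k,
        n_obs=len(df),
        converged=True,
    )


def simulate_slope_recovery(
    preset: CohortPreset,
    n_reps: int = 200,
    seed: int = 0,
    response: str = "ic_per_ln",
) -> pd.DataFrame:
    """Monte-Carlo parameter recovery for one cohort preset.

    Generates ``n_reps`` independent cohorts from the preset and fits the
    mixed model to each; returns one row per replicate with the estimated
    genotype slope.  The mean estimate should match the preset's
    generating slope within Monte-Carlo error if the estimator is
    unbiased.
    """
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    rows = []
    for r, s in enumerate(rep_seeds):
        cohort = make_cohort(preset, seed=int(s))
        fit = fit_longitudinal(cohort, response=response)
        rows.append(
            {
                "replicate": r,
                "seed": int(s),
                "slope": fit.slopes[preset.genotype],
                "slope_se": fit.slope_se[preset.genotype],
            }
        )
    return pd.DataFrame(rows)


def paired_ratio_vs_unity(pairs) -> PairedRatioResult:
    """Test whether case/control ratios differ from 1 on the log scale.

    ``pairs`` is an iterable of ``(case_value, control_value)``; repeated
    measures should be collapsed to per-animal means first.  Reports the
    geometric-mean ratio and a two-sided one-sample t-test of the mean
    log ratio against zero.
    """
    pairs = np.asarray(list(pairs), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise InputError("pairs must be (case, control) tuples")
    if pairs.shape[0] < 2:
        raise InputError(f"need at least 2 pairs, got {pairs.shape[0]}")
    if np.any(pairs <= 0):
        raise InputError("all paired values must be positive for log ratios")
    ratios = pairs[:, 0] / pairs[:, 1]
    logs = np.log(ratios)
    if np.allclose(logs, 0.0):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = sps.ttest_1samp(logs, 0.0)
    return PairedRatioResult(
        ratios=ratios,
        mean_log_ratio=float(logs.mean()),
        geometric_mean=float(np.exp(logs.mean())),
        t_statistic=float(t_stat),
        p_value=float(p),
        n=len(ratios),
    )


def inhibition_auc(curve: pd.DataFrame) -> float:
    """Trapezoidal AUC of residual activity over sample volume (uL).

    Lower AUC means greater inhibitory capacity.  The curve must include
    the zero-volume normalisation point; unsorted rows are sorted,
    duplicate volumes are an error.
    """
    required = {"volume_ul", "activity"}
    if not required <= set(curve.columns):
        raise InputError(f"inhibition curve needs columns {sorted(required)}")
    df = curve.sort_values("volume_ul")
    v = df["volume_ul"].to_numpy(dtype=float)
    a = df["activity"].to_numpy(dtype=float)
    if len(np.unique(v)) != len(v):
        raise InputError("duplicate volumes in inhibition curve")
    if v.size < 2:
        raise InputError("need at least 2 points")
    if v[0] != 0:
        raise InputError("curve must include the zero-volume control point")
    return float(np.trapezoid(a, v))


def compare_inhibition_groups(curves_case, curves_control):
    """Ratio of mean AUCs between groups with a two-sample t-test.

    Returns ``(ratio, t_statistic, p_value)`` where ratio > 1 means the
    case group has less inhibitory capacity (larger residual activity).
    """
    auc_case = np.array([inhibition_auc(c) for c in curves_case])
    auc_ctrl = np.array([inhibition_auc(c) for c in curves_control])
    if auc_case.size < 2 or auc_ctrl.size < 2:
        raise InputError("each group needs at least 2 curves")
    t_stat, p = sps.ttest_ind(auc_case, auc_ctrl)
    return float(auc_case.mean() / auc_ctrl.mean()), float(t_stat), float(p)
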