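"""Per-window age models and tRNA-level summaries.

Each 500 bp window's quantile-normalised score is regressed on age with one
of four fixed-effect covariate sets used on the discovery cohort:

1. no covariates;
2. batch;
3. blood cell-type counts (lymphocytes, monocytes, neutrophils,
   eosinophils);
4. batch and blood cell counts.

The reported p-value is always the partial F-test for the age-methylation
association term (for model 1 this is exactly the simple-regression F).
Additional model surfaces: a longitudinal model restricted to participants
sampled >=5 years apart with participant identity as a fixed effect, and a
mixed-model likelihood-ratio test with family/zygosity random effects.

Both regression orientations are supported: ``meth_response`` fits
``methylation ~ age + covariates`` (slope in score units per year);
``age_response`` fits ``age ~ methylation + covariates``. By the
Frisch-Waugh-Lovell theorem the partial F p-value for the association is
identical either way; only the slope's units differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .window_methylome import MethylationMatrix, WindowFeatureMap

__all__ = [
    "AgeModelSpec",
    "WindowAgeResult",
    "TRNAAgeSummary",
    "MODEL_COVARIATES",
    "CELL_COUNT_COLUMNS",
    "fit_age_model",
    "fit_all_windows",
    "fit_longitudinal",
    "mixed_model_lrt",
    "bonferroni_threshold",
    "summarize_by_trna",
    "build_design",
]

logger = logging.getLogger(__name__)

CELL_COUNT_COLUMNS = ["lymphocytes", "monocytes", "neutrophils", "eosinophils"]

#: Covariate sets of the four cross-sectional models.
MODEL_COVARIATES: dict[object, list[str]] = {
    1: [],
    2: ["batch"],
    3: CELL_COUNT_COLUMNS.copy(),
    4: ["batch"] + CELL_COUNT_COLUMNS,
    "longitudinal": ["batch"] + CELL_COUNT_COLUMNS + ["participant_id"],
}

_CATEGORICAL = {"batch", "participant_id", "zygosity", "sex"}


@dataclass(frozen=True)
class AgeModelSpec:
    """Which covariates and regression orientation to use."""

    model_id: object = 4
    direction: str = "meth_response"
    covariates: tuple[str, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.direction not in {"meth_response", "age_response"}:
            raise ValueError("direction must be meth_response or age_response")
        if self.covariates is None:
            if self.model_id not in MODEL_COVARIATES:
                raise ValueError(f"unknown model_id {self.model_id!r}")
            object.__setattr__(
                self, "covariates", tuple(MODEL_COVARIATES[self.model_id])
            )


@dataclass
class WindowAgeResult:
    """Slope, standard error and partial-F p for one window's age model."""

    window: str
    slope: float
    se: float
    p_value: float
    model_id: object = 4
    flag: str = ""  # "", "zero_variance"


@dataclass
class TRNAAgeSummary:
    """Best-window summary for one tRNA gene.

    A tRNA is called significant at a threshold if *any* overlapping window
    passes it; the best window is the one with minimal p (ties broken by
    larger |slope|, then lexicographic window name).
    """

    trna: str
    best_window: str
    min_p: float
    slope: float
    significant_study_wide: bool
    significant_genome_wide: bool
    direction: str  # "hyper" / "hypo"
    flag: str = ""  # "", "no_coverage"


def build_design(
    samples: pd.DataFrame, covariates: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariate design matrix (categoricals one-hot, first level
    as reference). Raises on rank deficiency, naming the collinear columns."""
    cols: list[np.ndarray] = [np.ones(len(samples))]
    names = ["intercept"]
    for cov in covariates:
        if cov not in samples.columns:
            raise ValueError(f"missing covariate column {cov!r}")
        if samples[cov].isna().any():
            raise ValueError(f"missing values in covariate {cov!r}")
        if cov in _CATEGORICAL or samples[cov].dtype == object:
            dummies = pd.get_dummies(samples[cov], prefix=cov, drop_first=True)
            for name in dummies.columns:
                cols.append(dummies[name].to_numpy(dtype=float))
                names.append(name)
        else:
            cols.append(samples[cov].to_numpy(dtype=float))
            names.append(cov)
    Z = np.column_stack(cols)
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        collinear = _find_collinear(Z, names)
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    return Z, names


def _find_collinear(Z: np.ndarray, names: list[str]) -> list[str]:
    keep: list[int] = []
    bad: list[str] = []
    for j in range(Z.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(Z[:, trial]) == len(trial):
            keep.append(j)
        else:
            bad.append(names[j])
    return bad


def _partial_regression(
    Y: np.ndarray, age: np.ndarray, Z: np.ndarray, direction: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised partial (FWL) regression of each row of Y against age.

    Residualises both age and methylation on Z (which includes the
    intercept), then regresses one residual on the other. Returns
    (slope, se, p, zero_variance_mask); p is the partial F(1, df) p-value,
    identical for both orientations.
    """
    n = Z.shape[0]
    df = n - Z.shape[1] - 1
    if df < 1:
        raise ValueError(f"not enough samples ({n}) for {Z.shape[1] + 1} parameters")
    Q, _ = np.linalg.qr(Z)
    age_r = age - Q @ (Q.T @ age)
    Y_r = Y - (Y @ Q) @ Q.T

    aa = float(age_r @ age_r)
    yy = np.einsum("ij,ij->i", Y_r, Y_r)
    xy = Y_r @ age_r

    # zero residual variance, relative to the raw scale (rounding-safe)
    yy0 = np.einsum("ij,ij->i", Y, Y)
    zero_var = yy <= 1e-20 * np.maximum(yy0, 1.0)
    if aa <= 1e-20 * max(float(age @ age), 1.0):
        # age has no residual variance: nothing is estimable
        k = Y.shape[0]
        return np.zeros(k), np.zeros(k), np.ones(k), np.ones(k, dtype=bool)

    with np.errstate(divide="ignore", invalid="ignore"):
        if direction == "meth_response":
            slope = xy / aa
            rss = yy - xy**2 / aa
            se = np.sqrt(np.maximum(rss, 0) / df / aa)
        else:  # age ~ methylation: slope per score unit
            slope = np.where(zero_var, 0.0, xy / np.where(zero_var, 1.0, yy))
            rss = aa - np.where(zero_var, 0.0, xy**2 / np.where(zero_var, 1.0, yy))
            se = np.where(
                zero_var, 0.0, np.sqrt(np.maximum(rss, 0) / df / np.where(zero_var, 1.0, yy))
            )
        t2 = np.where(se > 0, (slope / np.where(se > 0, se, 1.0)) ** 2, np.inf)
    p = stats.f.sf(t2, 1, df)
    # perfect fits (se -> 0) can underflow; keep p in (0, 1]
    p = np.maximum(p, np.nextafter(0, 1))
    slope = np.where(zero_var, 0.0, slope)
    se = np.where(zero_var, 0.0, se)
    p = np.where(zero_var, 1.0, p)
    return slope, se, p, zero_var


def fit_all_windows(
    matrix: MethylationMatrix,
    samples: pd.DataFrame,
    spec: AgeModelSpec = AgeModelSpec(),
) -> list[WindowAgeResult]:
    """Fit the age model at every window of the matrix (vectorised OLS).

    Windows with zero score variance are flagged (slope 0, p = 1) rather
    than dropped, keeping output aligned to input. Sample order must match
    the matrix columns.
    """
    if list(matrix.scores.columns) != samples["sample_id"].to_list():
        samples = samples.set_index("sample_id").loc[list(matrix.scores.columns)].reset_index()
    if matrix.n_windows == 0:
        return []
    Z, _ = build_design(samples, spec.covariates)
    age = samples["age"].to_numpy(dtype=float)
    Y = matrix.scores.to_numpy(dtype=float)
    slope, se, p, zero_var = _partial_regression(Y, age, Z, spec.direction)
    results = []
    for i, w in enumerate(matrix.windows):
        flag = "zero_variance" if zero_var[i] else ""
        if flag:
            logger.warning("window %s has zero variance; p set to 1", w.name)
        results.append(
            WindowAgeResult(
                window=w.name,
                slope=float(slope[i]),
                se=float(se[i]),
                p_value=float(p[i]),
                model_id=spec.model_id,
                flag=flag,
            )
        )
    return results


def fit_age_model(
    meth: np.ndarray | Sequence[float],
    samples: pd.DataFrame,
    spec: AgeModelSpec = AgeModelSpec(),
    window: str = "window",
) -> WindowAgeResult:
    """Fit the age model for a single window's methylation vector."""
    meth = np.asarray(meth, dtype=float).reshape(1, -1)
    if meth.shape[1] != len(samples):
        raise ValueError("methylation vector length must match sample table")
    Z, _ = build_design(samples, spec.covariates)
    age = samples["age"].to_numpy(dtype=float)
    slope, se, p, zero_var = _partial_regression(meth, age, Z, spec.direction)
    flag = "zero_variance" if zero_var[0] else ""
    if flag:
        logger.warning("window %s has zero variance; p set to 1", window)
    return WindowAgeResult(
        window=window,
        slope=float(slope[0]),
        se=float(se[0]),
        p_value=float(p[0]),
        model_id=spec.model_id,
        flag=flag,
    )


def fit_longitudinal(
    matrix: MethylationMatrix,
    samples: pd.DataFrame,
    min_gap_years: float = 5.0,
) -> list[WindowAgeResult]:
    """Within-person age models on the longitudinal subset.

    Keeps participants with >=2 samples whose age span is at least
    ``min_gap_years``, then fits models with participant identity as a fixed
    effect alongside batch and blood cell counts, so the age slope is
    identified from within-person change.
    """
    span = samples.groupby("participant_id")["age"].agg(["count", "min", "max"])
    ok = span[(span["count"] >= 2) & (span["max"] - span["min"] >= min_gap_years)].index
    keep = samples["participant_id"].isin(ok)
    if ok.empty or keep.sum() < 4:
        raise ValueError("no qualifying longitudinal participants")
    sub_samples = samples[keep].reset_index(drop=True)
    sub_scores = matrix.scores.loc[:, sub_samples["sample_id"].to_list()]
    sub_matrix = MethylationMatrix(list(matrix.windows), sub_scores)
    spec = AgeModelSpec(model_id="longitudinal")
    return fit_all_windows(sub_matrix, sub_samples, spec)


def mixed_model_lrt(
    meth: np.ndarray | Sequence[float], samples: pd.DataFrame
) -> tuple[float, float]:
    """Likelihood-ratio test for the methylation term in a twin mixed model.

    The null model regresses age on batch and the four blood cell counts
    (fixed effects) with a random intercept per family plus an extra
    variance component shared within monozygotic families (the zygosity
    random effect); the alternative adds the quantile-normalised methylation
    score. Both are fitted by maximum likelihood and compared with a
    chi-square(1) LRT. A singular random-effects fit falls back to the
    fixed-effects partial F-test with a logged warning.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    meth = np.asarray(meth, dtype=float)
    if "family_id" not in samples.columns:
        raise ValueError("family_id required for the mixed model")
    if samples["family_id"].nunique() < 10:
        raise ValueError("need >=10 families for the mixed model")

    data = samples[["family_id"] + MODEL_COVARIATES[4] + ["age"]].copy()
    data["meth"] = meth
    data["is_mz"] = (samples["zygosity"] == "MZ").astype(float)
    Z, _ = build_design(samples, MODEL_COVARIATES[4])
    age = samples["age"].to_numpy(dtype=float)
    fixed = "age ~ C(batch) + " + " + ".join(CELL_COUNT_COLUMNS)
    vc = {"mz": "0 + is_mz"}

    def _fit(formula):
        model = MixedLM.from_formula(
            formula, data, groups="family_id", re_formula="1", vc_formula=vc
        )
        return model.fit(reml=False, method="lbfgs", maxiter=200, disp=False)

    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res_null = _fit(fixed)
            res_alt = _fit(fixed + " + meth")
        lrt = 2.0 * (res_alt.llf - res_null.llf)
        if not np.isfinite(lrt):
            raise np.linalg.LinAlgError("non-finite likelihood")
        lrt = max(lrt, 0.0)
        return float(lrt), float(stats.chi2.sf(lrt, 1))
    except (np.linalg.LinAlgError, ValueError) as exc:
        logger.warning("mixed model failed (%s); using fixed-effects partial F", exc)
        slope, se, p, _ = _partial_regression(
            meth.reshape(1, -1), age, Z, "age_response"
        )
        t2 = (slope[0] / se[0]) ** 2 if se[0] > 0 else np.inf
        return float(t2), float(p[0])


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Bonferroni-corrected per-test threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def summarize_by_trna(
    results: Sequence[WindowAgeResult],
    feature_map: WindowFeatureMap,
    thresholds: Mapping[str, float],
    trna_names: Sequence[str] | None = None,
) -> list[TRNAAgeSummary]:
    """Summarise window results to tRNA level via the any-overlap rule.

    ``thresholds`` supplies ``study_wide`` and ``genome_wide`` cutoffs. A
    tRNA with no overlapping window gets a ``no_coverage`` flag. Note that
    one window may overlap two neighbouring tRNAs, in which case a single
    significant window calls both.
    """
    study = thresholds["study_wide"]
    genome = thresholds["genome_wide"]
    names = list(trna_names) if trna_names is not None else feature_map.feature_names
    summaries = []
    for trna in names:
        idxs = feature_map.windows_for(trna)
        hits = [results[i] for i in idxs if i < len(results)]
        if not hits:
            summaries.append(
                TRNAAgeSummary(trna, "", 1.0, 0.0, False, False, "hyper", flag="no_coverage")
            )
            continue
        best = min(hits, key=lambda r: (r.p_value, -abs(r.slope), r.window))
        summaries.append(
            TRNAAgeSummary(
                trna=trna,
                best_window=best.window,
                min_p=best.p_value,
                slope=best.slope,
                significant_study_wide=best.p_value < study,
                significant_genome_wide=best.p_value < genome,
                direction="hyper" if best.slope >= 0 else "hypo",
            )
        )
    return summaries


def results_to_frame(results: Sequence[WindowAgeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "window": [r.window for r in results],
            "slope": [r.slope for r in results],
            "se": [r.se for r in results],
            "p": [r.p_value for r in results],
            "model_id": [r.model_id for r in results],
            "flag": [r.flag for r in results],
        }
    )


def summaries_to_frame(summaries: Sequence[TRNAAgeSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trna": [s.trna for s in summaries],
            "best_window": [s.best_window for s in summaries],
            "min_p": [s.min_p for s in summaries],
            "slope": [s.slope for s in summaries],
            "significant_study_wide": [s.significant_study_wide for s in summaries],
            "significant_genome_wide": [s.significant_genome_wide for s in summaries],
            "direction": [s.direction for s in summaries],
            "flag": [s.flag for s in summaries],
        }
    )
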