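"""Outcome prediction from the probabilistic map.

The predictor for a subject is its interference histogram: the counts of
heatmap (signed-p) values sampled under the subject's two mirrored VTAs,
binned over the heatmap's [-1, +1] range. To keep training data independent
of the predicted subject, histograms are built in a leave-one-out (LOO)
fashion — the heatmap for subject i is recomputed from the other n-1
subjects before sampling. A multivariate ordinary-least-squares model with
one coefficient per bin maps histograms to percentage improvements, and
LOO cross-validation (refitting the model per fold) measures predictive
validity as the Pearson correlation between predicted and empirical
outcomes. Simpler baselines (distance-to-sweetspot regression, stimulation
parameter regression, mean-R prediction from a rank-correlation map) are
provided for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import Cohort, Subject
from .mapping import RMap, SignedPMap, rmap_spearman, voxelwise_heatmap
from .vta import VTAMask, efield_magnitude, ensure_left

__all__ = [
    "InterferenceHistogram",
    "OutcomeModel",
    "CVResult",
    "interference_histogram",
    "loo_histograms",
    "fit_outcome_model",
    "loocv_predict",
    "cog_distance_regression",
    "stimparams_regression",
    "subject_efield_magnitudes",
    "mean_r_prediction",
]


@dataclass(frozen=True)
class InterferenceHistogram:
    """Binned counts of heatmap values under one subject's VTA pair."""

    subject_id: str
    n_bins: int
    bin_edges: np.ndarray
    counts: np.ndarray  # non-negative ints, one per bin
    fold_id: int | None = None

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _bin_edges(n_bins: int) -> np.ndarray:
    return np.linspace(-1.0, 1.0, n_bins + 1)


def interference_histogram(
    heatmap: SignedPMap,
    vta_pair,
    n_bins: int = 15,
    subject_id: str = "",
    fold_id: int | None = None,
    undefined: str = "zero",
) -> InterferenceHistogram:
    """Histogram of heatmap values sampled under a pair of VTAs.

    Each VTA is sampled independently and the counts summed, so a voxel
    covered by both volumes of the pair contributes twice (multiplicity
    pooling). Bins are half-open [edge_k, edge_{k+1}) with the last bin
    closed at +1. Heatmap voxels without defined statistics are sampled as
    0 by default (``undefined="zero"``) or dropped (``undefined="exclude"``).
    """
    if n_bins < 2:
        raise ValueError(f"need at least 2 bins, got {n_bins}")
    values = []
    for mask in vta_pair:
        if len(mask) == 0:
            raise ValueError(f"subject {subject_id!r}: empty VTA in the pair")
        flat = mask.flat_indices
        if undefined == "exclude":
            keep = heatmap.defined_mask.ravel()[flat]
            flat = flat[keep]
        values.append(heatmap.sample_flat(flat))
    sampled = np.concatenate(values)
    edges = _bin_edges(n_bins)
    counts, _ = np.histogram(sampled, bins=edges)
    return InterferenceHistogram(
        subject_id=subject_id,
        n_bins=n_bins,
        bin_edges=edges,
        counts=counts.astype(int),
        fold_id=fold_id,
    )


def loo_histograms(
    cohort: Cohort,
    outcome_column: str = "pct_improvement",
    n_bins: int = 15,
    min_coverage: int = 2,
) -> list[InterferenceHistogram]:
    """One interference histogram per subject, each sampled on the heatmap
    recomputed from the other n-1 subjects (leave-one-out)."""
    n = len(cohort)
    if n < 5:
        raise ValueError(f"leave-one-out mapping needs at least 5 subjects, got {n}")
    histograms = []
    for fold, subject in enumerate(cohort.subjects):
        fold_map = voxelwise_heatmap(
            cohort, outcome_column, min_coverage=min_coverage, exclude={subject.subject_id}
        )
        if not fold_map.defined_mask.any():
            raise ValueError(
                f"fold {fold} (leaving out {subject.subject_id}): reduced heatmap has no defined voxels"
            )
        histograms.append(
            interference_histogram(
                fold_map, subject.vta_pair(), n_bins, subject.subject_id, fold_id=fold
            )
        )
    return histograms


@dataclass(frozen=True)
class OutcomeModel:
    """OLS model: percentage improvement ~ intercept + one term per bin."""

    intercept: float
    coefficients: np.ndarray
    r_squared: float
    f_pvalue: float
    n: int
    n_predictors: int

    def predict(self, histograms) -> np.ndarray:
        X = _design(histograms, self.n_predictors)
        return self.intercept + X @ self.coefficients

    def predict_one(self, histogram: InterferenceHistogram) -> float:
        return float(self.predict([histogram])[0])


def _design(histograms, n_bins: int) -> np.ndarray:
    X = np.array([h.counts for h in histograms], dtype=float)
    if X.shape[1] != n_bins:
        raise ValueError(f"histograms have {X.shape[1]} bins, model expects {n_bins}")
    return X


def fit_outcome_model(histograms, outcomes) -> OutcomeModel:
    """Fit the multivariate linear histogram model by least squares.

    A rank-deficient design (possible by construction: 15 predictors on a
    cohort of ~40 is near-saturated) falls back to the minimum-norm
    solution with a logged warning listing the deficient bins. Reports the
    in-sample R-squared and the overall F-test p-value; with no residual
    degrees of freedom (n <= n_bins + 1, a saturated fit) the F p-value is
    NaN but the coefficients remain usable for prediction.
    """
    y = np.asarray(outcomes, dtype=float)
    n_bins = histograms[0].n_bins
    n = y.size
    if len(histograms) != n:
        raise ValueError("one outcome per histogram is required")
    if n < 2:
        raise ValueError(f"need at least 2 subjects to fit, got {n}")
    X = np.column_stack([np.ones(n), _design(histograms, n_bins)])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        # identify directions with (numerically) no support
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        null_mask = s <= s[0] * max(X.shape) * np.finfo(float).eps
        deficient = sorted(set(np.argmax(np.abs(vt[null_mask]), axis=1).tolist()))
        warnings.warn(
            f"rank-deficient histogram design (rank {rank} of {X.shape[1]}); "
            f"minimum-norm fit used; affected columns (0 = intercept): {deficient}",
            stacklevel=2,
        )
    fitted = X @ beta
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    df_model = max(rank - 1, 1)
    df_resid = n - rank
    if df_resid <= 0:
        f_p = float("nan")  # saturated fit: no residual degrees of freedom
    elif ss_res > 0 and r2 < 1.0:
        f_stat = (r2 / df_model) / ((1.0 - r2) / df_resid)
        f_p = float(stats.f.sf(f_stat, df_model, df_resid))
    else:
        f_p = 0.0 if r2 > 0 else 1.0
    return OutcomeModel(
        intercept=float(beta[0]),
        coefficients=beta[1:],
        r_squared=r2,
        f_pvalue=f_p,
        n=n,
        n_predictors=n_bins,
    )


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the exact t-transform p-value (n - 2 df)."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: one of the vectors is constant")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class CVResult:
    """Per-subject predictions and their correlation with empirical outcomes."""

    subject_ids: list[str]
    predicted: np.ndarray
    empirical: np.ndarray
    pearson_r: float
    p_value: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "predicted": self.predicted,
                "empirical": self.empirical,
            }
        )


def loocv_predict(histograms, outcomes) -> CVResult:
    """Leave-one-out cross-validation of the histogram model.

    Fold i refits the OLS model on the other n-1 (histogram, outcome)
    pairs — subject i's outcome never enters its own fold — and predicts
    the held-out histogram. Validity is the Pearson correlation between
    the n predictions and the empirical improvements.
    """
    y = np.asarray(outcomes, dtype=float)
    n = y.size
    n_bins = histograms[0].n_bins
    if n < n_bins + 2:
        raise ValueError(f"LOOCV needs n >= n_bins + 2 (= {n_bins + 2}), got {n}")
    preds = np.empty(n)
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        model = fit_outcome_model([histograms[j] for j in keep], y[keep])
        preds[i] = model.predict_one(histograms[i])
    r, p = _pearson_with_p(preds, y)
    return CVResult(
        subject_ids=[h.subject_id for h in histograms],
        predicted=preds,
        empirical=y,
        pearson_r=r,
        p_value=p,
    )


# ----------------------------------------------------------------------
# simpler baselines


def _active_contact_coords(subject: Subject) -> np.ndarray:
    """World coordinates of the active contacts, mirrored to the left."""
    coords = []
    for side, setting in subject.settings.items():
        c = subject.lead_geometry[side].contact_centres[setting.contact_index]
        coords.append(ensure_left(c, side))
    return np.asarray(coords)


def cog_distance_regression(cohort: Cohort, sweetspot_cog, outcome_column: str = "pct_improvement"):
    """Univariate OLS: improvement ~ mean distance of active contacts to the
    sweetspot centre of gravity. Returns (R^2, p, slope)."""
    cog = np.asarray(sweetspot_cog, dtype=float)
    dist = np.array(
        [np.linalg.norm(_active_contact_coords(s) - cog, axis=1).mean() for s in cohort.subjects]
    )
    if np.ptp(dist) == 0:
        raise ValueError("zero variance in contact-to-sweetspot distances")
    y = cohort.outcomes(outcome_column)
    model = sm.OLS(y, sm.add_constant(dist)).fit()
    return float(model.rsquared), float(model.f_pvalue), float(model.params[1])


def stimparams_regression(cohort: Cohort, outcome_column: str = "pct_improvement"):
    """Multivariate OLS of improvement on amplitude, pulse width and
    frequency (each averaged over the two sides). Returns (R^2, p)."""
    rows = []
    for s in cohort.subjects:
        settings = list(s.settings.values())
        rows.append(
            {
                "amplitude": np.mean([st.amplitude for st in settings]),
                "pulse_width_us": np.mean([st.pulse_width_us for st in settings]),
                "frequency_hz": np.mean([st.frequency_hz for st in settings]),
            }
        )
    X = pd.DataFrame(rows)
    constant = [c for c in X.columns if X[c].nunique() == 1]
    if constant:
        warnings.warn(f"dropping constant stimulation-parameter columns: {constant}", stacklevel=2)
        X = X.drop(columns=constant)
    if X.shape[1] == 0:
        raise ValueError("all stimulation parameters are constant across the cohort")
    y = cohort.outcomes(outcome_column)
    model = sm.OLS(y, sm.add_constant(X.to_numpy(dtype=float))).fit()
    return float(model.rsquared), float(model.f_pvalue)


def subject_efield_magnitudes(cohort: Cohort, sigma: float = 2e-4) -> np.ndarray:
    """Per-subject bilateral point-source field magnitudes on the grid.

    Each subject's field is the voxelwise maximum over the two sides'
    point sources (active contact mirrored to the left, source current =
    amplitude). Returns an (n_subjects, *grid.shape) array.
    """
    fields = []
    for s in cohort.subjects:
        per_side = []
        for side, setting in s.settings.items():
            centre = ensure_left(
                s.lead_geometry[side].contact_centres[setting.contact_index], side
            )
            per_side.append(
                efield_magnitude(cohort.grid, centre, setting.amplitude, sigma).magnitude
            )
        fields.append(np.maximum.reduce(per_side))
    return np.asarray(fields)


def mean_r_prediction(
    cohort: Cohort,
    efield_magnitudes: np.ndarray | None = None,
    outcome_column: str = "pct_improvement",
    sigma: float = 2e-4,
) -> CVResult:
    """Leave-one-out validation of the Spearman R-map.

    Fold i builds the R-map from the other n-1 subjects' field magnitudes
    and predicts subject i as the mean R value over its VTA pair's voxels
    (multiplicity pooling over the two volumes; undefined voxels excluded,
    a fully undefined sample scores 0). Returns the Pearson correlation
    between the scores and the empirical improvements.
    """
    if efield_magnitudes is None:
        efield_magnitudes = subject_efield_magnitudes(cohort, sigma)
    y = cohort.outcomes(outcome_column)
    n = len(cohort)
    scores = np.empty(n)
    for i, subject in enumerate(cohort.subjects):
        keep = [j for j in range(n) if j != i]
        rmap = rmap_spearman(efield_magnitudes[keep], y[keep], cohort.grid)
        flat = np.concatenate([m.flat_indices for m in subject.vta_pair()])
        defined = rmap.defined_mask.ravel()[flat]
        if not defined.any():
            warnings.warn(
                f"fold {i}: no defined R values under the VTA pair; score set to 0", stacklevel=2
            )
            scores[i] = 0.0
        else:
            scores[i] = float(rmap.sample_flat(flat[defined]).mean())
    r, p = _pearson_with_p(scores, y)
    return CVResult(
        subject_ids=[s.subject_id for s in cohort.subjects],
        predicted=scores,
        empirical=y,
        pearson_r=r,
        p_value=p,
    )
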