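"""Scoring of decompositions against ground truth or against each other.

Estimated modes have no intrinsic order or sign, so sets of modes are first
matched by the Hungarian algorithm on the sum of spatial and temporal
similarity scores, with each candidate pair scored at its better joint sign
(one flip applied to a mode's map *and* time course together).  Similarity is
an uncentered Pearson correlation: the factorisation is ambiguous in scale
but not in mean offsets, so means are deliberately not removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import norm
from scipy.stats import t as t_dist

__all__ = [
    "MatchResult",
    "ScoreReport",
    "uncentered_correlation",
    "match_modes",
    "score_decomposition",
    "netmat_rmse",
    "test_retest",
    "fisher_group_zstats",
    "partial_correlations",
    "dual_regression",
    "pca_dual_regression_baseline",
]


class UndefinedScoreError(ValueError):
    """Raised when a correlation against an all-zero vector is requested."""


def uncentered_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """sum(x y) / sqrt(sum(x^2) sum(y^2)); means are *not* removed."""
    x = np.ravel(np.asarray(x, dtype=float))
    y = np.ravel(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    nx = float(x @ x)
    ny = float(y @ y)
    if nx == 0.0 or ny == 0.0:
        raise UndefinedScoreError("uncentered correlation with a zero vector is undefined")
    return float(np.clip((x @ y) / np.sqrt(nx * ny), -1.0, 1.0))


def _safe_uncorr(x, y) -> float:
    try:
        return uncentered_correlation(x, y)
    except UndefinedScoreError:
        return np.nan


def _nanmean_or_nan(values) -> float:
    """nanmean that returns NaN (quietly) when every value is missing."""
    arr = np.asarray(values, dtype=float)
    good = arr[np.isfinite(arr)]
    return float(good.mean()) if good.size else np.nan


@dataclass
class MatchResult:
    """Assignment of estimated modes to reference modes.

    permutation maps estimated index -> reference index for the matched
    pairs; sign_flips holds the joint map/time-course sign per matched
    estimated mode.  Unmatched modes (when counts differ) are listed
    separately and excluded from score averages.
    """

    permutation: dict[int, int]
    sign_flips: dict[int, int]
    pair_scores: dict[int, tuple[float, float]]
    unmatched_est: list[int] = field(default_factory=list)
    unmatched_ref: list[int] = field(default_factory=list)


@dataclass
class ScoreReport:
    spatial_accuracy: dict[int, float]
    temporal_accuracy: dict[int, float]
    spatial_netmat_rmse: float = np.nan
    temporal_netmat_rmse: float = np.nan

    def mean_spatial(self) -> float:
        return _nanmean_or_nan(list(self.spatial_accuracy.values()))

    def mean_temporal(self) -> float:
        return _nanmean_or_nan(list(self.temporal_accuracy.values()))

    def to_dict(self) -> dict:
        return {
            "spatial_accuracy": {str(k): v for k, v in self.spatial_accuracy.items()},
            "temporal_accuracy": {str(k): v for k, v in self.temporal_accuracy.items()},
            "spatial_netmat_rmse": self.spatial_netmat_rmse,
            "temporal_netmat_rmse": self.temporal_netmat_rmse,
            "mean_spatial_accuracy": self.mean_spatial(),
            "mean_temporal_accuracy": self.mean_temporal(),
        }


def match_modes(
    est_maps: np.ndarray,
    ref_maps: np.ndarray,
    est_tc: np.ndarray | None = None,
    ref_tc: np.ndarray | None = None,
) -> MatchResult:
    """Hungarian matching of estimated to reference modes.

    Maps are V x M (columns are modes); time courses, if given, are M x T.
    The assignment maximises the summed |spatial + temporal| score over
    pairs; the sign achieving each pair's score is recorded.
    """
    est_maps = np.asarray(est_maps, dtype=float)
    ref_maps = np.asarray(ref_maps, dtype=float)
    if est_maps.size == 0 or ref_maps.size == 0:
        raise ValueError("cannot match empty mode sets")
    if est_maps.shape[0] != ref_maps.shape[0]:
        raise ValueError("estimated and reference maps must share V")
    m_est, m_ref = est_maps.shape[1], ref_maps.shape[1]

    score = np.zeros((m_est, m_ref))
    for i in range(m_est):
        for j in range(m_ref):
            s = _safe_uncorr(est_maps[:, i], ref_maps[:, j])
            if est_tc is not None and ref_tc is not None:
                s = s + _safe_uncorr(est_tc[i], ref_tc[j])
            score[i, j] = 0.0 if np.isnan(s) else s

    rows, cols = linear_sum_assignment(-np.abs(score))
    permutation: dict[int, int] = {}
    signs: dict[int, int] = {}
    pair_scores: dict[int, tuple[float, float]] = {}
    for i, j in zip(rows, cols):
        permutation[int(i)] = int(j)
        signs[int(i)] = 1 if score[i, j] >= 0 else -1
        sp = _safe_uncorr(signs[i] * est_maps[:, i], ref_maps[:, j])
        tp = np.nan
        if est_tc is not None and ref_tc is not None:
            tp = _safe_uncorr(signs[i] * est_tc[i], ref_tc[j])
        pair_scores[int(i)] = (sp, tp)
    unmatched_est = sorted(set(range(m_est)) - set(permutation))
    unmatched_ref = sorted(set(range(m_ref)) - set(permutation.values()))
    return MatchResult(
        permutation=permutation,
        sign_flips=signs,
        pair_scores=pair_scores,
        unmatched_est=unmatched_est,
        unmatched_ref=unmatched_ref,
    )


def score_decomposition(
    est_subject_maps: dict[str, np.ndarray],
    est_timecourses: dict[tuple[str, str], np.ndarray],
    truth_subject_maps: dict[str, np.ndarray],
    truth_timecourses: dict[tuple[str, str], np.ndarray],
    match: MatchResult,
) -> ScoreReport:
    """Per-mode accuracies: mean over subjects of subject-map correlations and
    mean over runs of time-course correlations, at the matched pairing.

    Group-level methods without subject maps are scored under the convention
    of supplying the group map for every subject.
    """
    spatial: dict[int, float] = {}
    temporal: dict[int, float] = {}
    for i, j in match.permutation.items():
        sign = match.sign_flips[i]
        sp = [
            _safe_uncorr(sign * est_subject_maps[s][:, i], truth_subject_maps[s][:, j])
            for s in truth_subject_maps
            if s in est_subject_maps
        ]
        spatial[j] = _nanmean_or_nan(sp)
        tp = [
            _safe_uncorr(sign * est_timecourses[k][i], truth_timecourses[k][j])
            for k in truth_timecourses
            if k in est_timecourses
        ]
        temporal[j] = _nanmean_or_nan(tp)
    sp_rmse, tp_rmse = netmat_rmse(
        est_subject_maps, est_timecourses, truth_subject_maps, truth_timecourses, match
    )
    return ScoreReport(
        spatial_accuracy=spatial,
        temporal_accuracy=temporal,
        spatial_netmat_rmse=sp_rmse,
        temporal_netmat_rmse=tp_rmse,
    )


def _mode_correlations(columns: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix between columns (modes)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.corrcoef(columns, rowvar=False)


def netmat_rmse(
    est_subject_maps: dict[str, np.ndarray],
    est_timecourses: dict[tuple[str, str], np.ndarray],
    truth_subject_maps: dict[str, np.ndarray],
    truth_timecourses: dict[tuple[str, str], np.ndarray],
    match: MatchResult,
) -> tuple[float, float]:
    """RMS error of inter-mode correlation matrices, spatial and temporal.

    Per subject the mode-by-mode correlation matrices are computed (spatial
    from the subject maps, temporal from the concatenated run time courses);
    the elementwise error is averaged over subjects first, then the RMS is
    taken over off-diagonal elements, respecting the permutation and sign
    flips.
    """
    est_idx = sorted(match.permutation)
    ref_idx = [match.permutation[i] for i in est_idx]
    signs = np.array([match.sign_flips[i] for i in est_idx], dtype=float)

    def _subject_netmats(subject: str):
        est = est_subject_maps[subject][:, est_idx] * signs[None, :]
        ref = truth_subject_maps[subject][:, ref_idx]
        sp_err = _mode_correlations(est) - _mode_correlations(ref)
        est_cat = np.concatenate(
            [est_timecourses[k] for k in sorted(est_timecourses) if k[0] == subject],
            axis=1,
        )
        ref_cat = np.concatenate(
            [truth_timecourses[k] for k in sorted(truth_timecourses) if k[0] == subject],
            axis=1,
        )
        tp_err = _mode_correlations(
            (est_cat[est_idx] * signs[:, None]).T
        ) - _mode_correlations(ref_cat[ref_idx].T)
        return sp_err, tp_err

    subjects = [s for s in truth_subject_maps if s in est_subject_maps]
    sp_errs, tp_errs = zip(*(_subject_netmats(s) for s in subjects))
    off = ~np.eye(len(est_idx), dtype=bool)

    def _rms(errs):
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            mean_err = np.nanmean(np.stack(errs), axis=0)
            return float(np.sqrt(np.nanmean(mean_err[off] ** 2)))

    return _rms(sp_errs), _rms(tp_errs)


def test_retest(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    strength_threshold: float = 0.05,
) -> dict:
    """Agreement between two decompositions of the same data.

    The two sets of group maps are matched, per-pair map correlations are
    reported, and each pair carries a normalised strength statistic: the map
    standard deviations normalised by the strongest ('global') mode within
    each analysis, taking the maximum over the pair.  Pairs whose normalised
    strength is close to zero have been eliminated by the model
    regularisation and are flagged.
    """
    match = match_modes(maps_a, maps_b)
    sd_a = maps_a.std(axis=0)
    sd_b = maps_b.std(axis=0)
    norm_a = sd_a / sd_a.max() if sd_a.max() > 0 else sd_a
    norm_b = sd_b / sd_b.max() if sd_b.max() > 0 else sd_b
    scores = {}
    strengths = {}
    for i, j in match.permutation.items():
        scores[i] = match.pair_scores[i][0]
        strengths[i] = float(max(norm_a[i], norm_b[j]))
    eliminated = [i for i, v in strengths.items() if v < strength_threshold]
    return {
        "match": match,
        "scores": scores,
        "strengths": strengths,
        "eliminated_pairs": eliminated,
    }


test_retest.__test__ = False  # a retest metric, not a pytest test, despite the name


def fisher_group_zstats(per_subject_corr: np.ndarray) -> np.ndarray:
    """Group z-statistics from per-subject mode-by-mode correlation matrices.

    Each off-diagonal element is Fisher (atanh) transformed, tested against
    zero with a one-sample t-test pooling across subjects, and the t value
    (S - 1 degrees of freedom) converted to a standard-normal-equivalent z by
    two-sided tail matching, preserving sign.  Requires at least 3 subjects.
    """
    mats = np.asarray(per_subject_corr, dtype=float)
    if mats.ndim != 3 or mats.shape[1] != mats.shape[2]:
        raise ValueError("expected an (S, M, M) stack of correlation matrices")
    S, M, _ = mats.shape
    if S < 3:
        raise ValueError("need at least 3 subjects")
    clipped = np.clip(mats, -1.0 + 1e-12, 1.0 - 1e-12)
    fz = np.arctanh(clipped)
    mean = fz.mean(axis=0)
    sd = fz.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(S))
        t = np.where(sd == 0, np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)
    p_two = 2.0 * t_dist.sf(np.abs(t), df=S - 1)
    with np.errstate(divide="ignore"):
        z = np.sign(t) * norm.isf(np.clip(p_two / 2.0, 1e-300, 1.0))
    z = np.where(t == 0, 0.0, z)
    np.fill_diagonal(z, 0.0)
    return z


def partial_correlations(
    series: np.ndarray, subset: np.ndarray | list[int] | None = None,
    cond_threshold: float = 1e8,
) -> np.ndarray:
    """Partial correlations among modes, optionally returning a subset block.

    ``series`` is M x T (rows are mode time courses or map weight vectors).
    The full partial correlation matrix is obtained from the inverse of the
    full correlation matrix — so the subset block is conditioned on *all*
    remaining modes — and the requested block is returned with unit diagonal.
    """
    series = np.asarray(series, dtype=float)
    C = np.corrcoef(series)
    cond = np.linalg.cond(C)
    if cond > cond_threshold:
        import warnings

        warnings.warn(
            f"correlation matrix poorly conditioned (cond={cond:.2e}); regularising",
            RuntimeWarning,
            stacklevel=2,
        )
        C = C + (np.trace(C) / C.shape[0] / cond_threshold) * np.eye(C.shape[0])
    P = np.linalg.inv(C)
    d = np.sqrt(np.diag(P))
    partial = -P / np.outer(d, d)
    np.fill_diagonal(partial, 1.0)
    if subset is not None:
        subset = np.asarray(subset, dtype=int)
        partial = partial[np.ix_(subset, subset)]
    return partial


def dual_regression(
    group_maps: np.ndarray, run_data: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage least squares: group maps -> time courses -> subject maps."""
    G = np.asarray(group_maps, dtype=float)
    D = np.asarray(run_data, dtype=float)
    if G.ndim != 2 or D.shape[0] != G.shape[0]:
        raise ValueError("group maps and data must share V")
    rank = np.linalg.matrix_rank(G)
    if rank < G.shape[1]:
        sv = np.linalg.svd(G, compute_uv=False)
        bad = np.flatnonzero(sv < sv[0] * 1e-10)
        raise ValueError(f"group maps rank deficient (singular values {bad.tolist()} ~ 0)")
    tc, *_ = np.linalg.lstsq(G, D, rcond=None)
    maps_t, *_ = np.linalg.lstsq(tc.T, D.T, rcond=None)
    return tc, maps_t.T


def pca_dual_regression_baseline(
    data, M: int
) -> tuple[np.ndarray, dict[str, np.ndarray], dict[tuple[str, str], np.ndarray]]:
    """Group-PCA maps followed by per-subject dual regression.

    The baseline a practitioner would run: top-M left singular vectors of the
    concatenated demeaned data as group maps, then dual regression on each
    subject's concatenated runs.  Returns (group_maps, subject_maps,
    run_timecourses).
    """
    concat = np.concatenate(
        [D - D.mean(axis=1, keepdims=True) for D in data.runs.values()], axis=1
    )
    U, svals, _ = np.linalg.svd(concat, full_matrices=False)
    group_maps = U[:, :M] * svals[:M] / np.sqrt(concat.shape[1])
    subject_maps: dict[str, np.ndarray] = {}
    timecourses: dict[tuple[str, str], np.ndarray] = {}
    for s in data.subjects:
        keys = data.runs_of(s)
        cat = np.concatenate([data.runs[k] for k in keys], axis=1)
        cat = cat - cat.mean(axis=1, keepdims=True)
        tc_cat, maps = dual_regression(group_maps, cat)
        subject_maps[s] = maps
        offset = 0
        for k in keys:
            T = data.runs[k].shape[1]
            timecourses[k] = tc_cat[:, offset : offset + T]
            offset += T
    return group_maps, subject_maps, timecourses
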