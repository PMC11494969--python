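"""Linear time-warp alignment of subjects to a data-selected reference.

Different hosts traverse the same underlying biological process at different
speeds, so each subject's clock is mapped onto a common reference clock by a
linear transformation t -> slope * t + offset.  The warp for a subject is
fitted on one designated omic layer (taxa by default) by minimizing the mean
squared difference between the subject's spline-smoothed series, evaluated in
warped time, and the reference subject's splines, averaged over shared
entities on the overlapping interval.  The reference is the subject whose
choice minimizes the total alignment error over all other subjects, and the
fitted transformation is then applied to every omic layer of the subject.

The optimizer is a grid search over slope in [0.5, 2.0] at 0.01 resolution
and offset in [-30, 30] days at 1-day resolution (hierarchical: a coarse pass
followed by a fine pass around the best cell), finished with Nelder-Mead
refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import AlignmentError
from .preprocess import OmicsDataset, fit_series_spline

#: (times, values) arrays per entity name; the unit alignment operates on.
SubjectSeries = dict[str, tuple[np.ndarray, np.ndarray]]

#: Spline bundle per entity: (t_min, t_max, fitted spline).
_Bundle = dict[str, tuple[float, float, object]]


@dataclass(frozen=True)
class WarpParams:
    """A per-subject linear time transformation and its goodness of fit.

    ``slope`` is unitless and strictly positive (time order preserved);
    ``offset`` is in days; ``alignment_error`` is the minimized mean squared
    difference on the overlapping warped interval.
    """

    slope: float
    offset: float
    alignment_error: float = 0.0

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError(f"warp slope must be > 0, got {self.slope}")
        if self.alignment_error < 0:
            raise ValueError("alignment_error must be >= 0")


def subject_series(ds: OmicsDataset, subject: str, omic_type: str | None = "taxon") -> SubjectSeries:
    """Extract one subject's per-entity series, optionally restricted to one omic layer."""
    df = ds.subject_frame(subject)
    if omic_type is not None:
        df = df[df["omic_type"] == omic_type]
    out: SubjectSeries = {}
    for entity, series in df.groupby("entity", sort=True):
        s = series.sort_values("time")
        out[entity] = (s["time"].to_numpy(float), s["value"].to_numpy(float))
    return out


SLOPE_RANGE = (0.5, 2.0)
OFFSET_RANGE = (-30.0, 30.0)
_SLOPE_STEP = 0.01
_OFFSET_STEP = 1.0
_COARSE_FACTOR = 5  # coarse pass at 5x the final step
_N_EVAL = 25  # sample points per entity on the overlap when computing the error


def _warp_error(
    slopes: np.ndarray,
    offsets: np.ndarray,
    series: list[tuple[float, float, object]],
    ref: list[tuple[float, float, object]],
) -> np.ndarray:
    """Mean squared alignment error for arrays of candidate (slope, offset).

    ``series``/``ref`` hold (t_min, t_max, spline) per shared entity, in
    matching order.  The error for a candidate is the mean over entities of
    the mean squared difference between subject values at t and reference
    values at slope*t + offset, sampled on the interval of t where the warped
    time falls inside the reference's observed range.  Candidates with an
    empty overlap get infinite error.
    """
    slopes = np.atleast_1d(np.asarray(slopes, float))
    offsets = np.atleast_1d(np.asarray(offsets, float))
    total = np.zeros(slopes.shape, float)
    n_ok = np.zeros(slopes.shape, int)
    for (s_lo, s_hi, s_spl), (r_lo, r_hi, r_spl) in zip(series, ref):
        # overlap in subject time: slope*t+offset must lie in [r_lo, r_hi]
        lo = np.maximum(s_lo, (r_lo - offsets) / slopes)
        hi = np.minimum(s_hi, (r_hi - offsets) / slopes)
        ok = hi > lo
        frac = np.linspace(0.0, 1.0, _N_EVAL)
        t = lo[..., None] + (hi - lo)[..., None] * frac  # (n_cand, _N_EVAL)
        sub_vals = s_spl(t)
        ref_vals = r_spl(slopes[..., None] * t + offsets[..., None])
        mse = np.mean((sub_vals - ref_vals) ** 2, axis=-1)
        total = np.where(ok, total + mse, total)
        n_ok = n_ok + ok.astype(int)
    with np.errstate(invalid="ignore"):
        err = np.where(n_ok == len(series), total / max(len(series), 1), np.inf)
    return err


def _spline_bundle(series: SubjectSeries) -> _Bundle:
    out: _Bundle = {}
    for name in sorted(series):
        t, v = series[name]
        out[name] = (float(np.min(t)), float(np.max(t)), fit_series_spline(t, v))
    return out


def _grid_minimum(sub, ref, slopes, offsets):
    """Best (slope, offset, error) on a grid; exact ties go toward identity."""
    grid_s, grid_o = np.meshgrid(slopes, offsets, indexing="ij")
    errs = _warp_error(grid_s.ravel(), grid_o.ravel(), sub, ref)
    if not np.isfinite(errs).any():
        raise AlignmentError("no candidate warp yields an overlapping interval")
    best = float(np.min(errs))
    tied = np.flatnonzero(errs <= best + 1e-15)
    s_cand, o_cand = grid_s.ravel()[tied], grid_o.ravel()[tied]
    pick = int(np.lexsort((np.abs(o_cand), np.abs(s_cand - 1.0)))[0])
    return float(s_cand[pick]), float(o_cand[pick]), float(errs[tied[pick]])


def _fit_warp_bundles(sub: list, ref: list) -> WarpParams:
    coarse_s = np.round(
        np.arange(SLOPE_RANGE[0], SLOPE_RANGE[1] + 1e-9, _SLOPE_STEP * _COARSE_FACTOR), 10
    )
    coarse_o = np.arange(OFFSET_RANGE[0], OFFSET_RANGE[1] + 1e-9, _OFFSET_STEP * _COARSE_FACTOR)
    s0, o0, e0 = _grid_minimum(sub, ref, coarse_s, coarse_o)

    fine_s = np.round(
        np.arange(
            max(SLOPE_RANGE[0], s0 - _SLOPE_STEP * (_COARSE_FACTOR + 1)),
            min(SLOPE_RANGE[1], s0 + _SLOPE_STEP * (_COARSE_FACTOR + 1)) + 1e-9,
            _SLOPE_STEP,
        ),
        10,
    )
    fine_o = np.arange(
        max(OFFSET_RANGE[0], o0 - _OFFSET_STEP * (_COARSE_FACTOR + 1)),
        min(OFFSET_RANGE[1], o0 + _OFFSET_STEP * (_COARSE_FACTOR + 1)) + 1e-9,
        _OFFSET_STEP,
    )
    s1, o1, e1 = _grid_minimum(sub, ref, fine_s, fine_o)
    if (abs(s0 - 1.0), abs(o0)) < (abs(s1 - 1.0), abs(o1)) and e0 <= e1 + 1e-15:
        s1, o1, e1 = s0, o0, e0  # keep identity preference on flat landscapes

    def objective(x):
        s, o = x
        if s <= 0:
            return np.inf
        return float(_warp_error(np.array([s]), np.array([o]), sub, ref)[0])

    res = minimize(
        objective, x0=[s1, o1], method="Nelder-Mead", options={"xatol": 1e-4, "fatol": 1e-12}
    )
    # accept the polish only inside the trusted search box
    if (
        np.isfinite(res.fun)
        and res.fun < e1
        and SLOPE_RANGE[0] <= res.x[0] <= SLOPE_RANGE[1]
        and OFFSET_RANGE[0] <= res.x[1] <= OFFSET_RANGE[1]
    ):
        s1, o1, e1 = float(res.x[0]), float(res.x[1]), float(res.fun)
    return WarpParams(slope=s1, offset=o1, alignment_error=max(e1, 0.0))


def _shared_bundles(sub: _Bundle, ref: _Bundle):
    shared = sorted(set(sub) & set(ref))
    if not shared:
        raise AlignmentError("subjects share no entities; cannot align")
    return [sub[n] for n in shared], [ref[n] for n in shared]


def fit_linear_warp(series: SubjectSeries, reference: SubjectSeries) -> WarpParams:
    """Fit the linear warp of one subject onto a reference subject."""
    sub, ref = _shared_bundles(_spline_bundle(series), _spline_bundle(reference))
    return _fit_warp_bundles(sub, ref)


def select_reference(cohort: dict[str, SubjectSeries]) -> str:
    """Pick the subject minimizing the total alignment error of all others onto it.

    Ties are broken by lexicographic subject id.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    ids = sorted(cohort)
    if len(ids) == 1:
        return ids[0]
    bundles = {i: _spline_bundle(cohort[i]) for i in ids}
    totals: dict[str, float] = {}
    for ref_id in ids:
        total = 0.0
        for sub_id in ids:
            if sub_id == ref_id:
                continue
            sub, ref = _shared_bundles(bundles[sub_id], bundles[ref_id])
            total += _fit_warp_bundles(sub, ref).alignment_error
        totals[ref_id] = total
    return min(ids, key=lambda i: (totals[i], i))


def apply_warp_all_omics(subject_data: pd.DataFrame, warp: WarpParams) -> pd.DataFrame:
    """Map the time axis of every omic series of one subject by t -> slope*t + offset.

    Values are untouched; only time stamps change.
    """
    out = subject_data.copy()
    out["time"] = warp.slope * out["time"].astype(float) + warp.offset
    return out


@dataclass(frozen=True)
class SubjectAlignment:
    subject: str
    warp: WarpParams
    kept: bool


def align_cohort(
    ds: OmicsDataset,
    align_on: str = "taxon",
    reference: str | None = None,
    drop_outliers: bool = True,
) -> tuple[OmicsDataset, list[SubjectAlignment]]:
    """Warp every subject onto a reference selected from the cohort.

    The warp is fitted on the ``align_on`` omic layer and applied to all of
    the subject's omics.  Subjects whose alignment error exceeds
    median + 2*IQR of the cohort's errors are treated as abnormal/noisy and
    dropped when ``drop_outliers`` is set.  Returns the aligned dataset and
    the per-subject warp parameters.
    """
    subjects = ds.subjects()
    if not subjects:
        return ds, []
    cohort = {s: subject_series(ds, s, align_on) for s in subjects}
    if reference is not None:
        ref_id = reference
    else:
        ref_id = select_reference(cohort)
    bundles = {s: _spline_bundle(cohort[s]) for s in subjects}
    warps: dict[str, WarpParams] = {}
    for s in subjects:
        if s == ref_id:
            warps[s] = WarpParams(1.0, 0.0, 0.0)
        else:
            sub, ref = _shared_bundles(bundles[s], bundles[ref_id])
            warps[s] = _fit_warp_bundles(sub, ref)
    errors = np.array([warps[s].alignment_error for s in subjects])
    if drop_outliers and len(subjects) >= 4:
        med = float(np.median(errors))
        q1, q3 = np.percentile(errors, [25, 75])
        cutoff = med + 2.0 * (q3 - q1)
        kept = {s for s, e in zip(subjects, errors) if e <= cutoff or s == ref_id}
    else:
        kept = set(subjects)
    frames = [
        apply_warp_all_omics(ds.subject_frame(s), warps[s]) for s in subjects if s in kept
    ]
    aligned = OmicsDataset(pd.concat(frames, ignore_index=True))
    report = [SubjectAlignment(s, warps[s], s in kept) for s in subjects]
    return aligned, report
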