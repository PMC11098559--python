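"""Mant-ATP chase analysis: ROI extraction, normalization and decay fitting.

The loaded Mant-ATP chase assay reports the nucleotide turnover of resting
myosin in a permeabilized single muscle fiber.  Fluorescent Mant-ATP bound to
myosin heads is chased with dark ATP while frames are acquired (every 5 s for
5 min by default); the fluorescence decay is background-corrected, normalized
to the final pre-washout frame (t = 0) and fit with an unconstrained double
exponential

    F(t) = 1 - P1*(1 - exp(-t/T1)) - P2*(1 - exp(-t/T2))

where (P1, T1) describe the fast, disordered-relaxed (DRX) population and
(P2, T2) the slow, super-relaxed (SRX) population.  Amplitudes are fractions
internally and reported in percent; the faster lifetime is always labelled
DRX.  The non-exchanging plateau 1 - P1 - P2 is left free.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .types import DecayFit, FluorescenceTrace, NormalizedDecay

__all__ = [
    "decay_model",
    "extract_roi_traces",
    "normalize",
    "fit_decay",
    "fit_traces",
    "qc_filter",
    "QCThresholds",
    "plot_decay_fit",
]

# Multi-start grid over lifetimes (s); amplitudes are initialized by a linear
# solve at each lifetime pair, so only the nonlinear coordinates need a grid.
_T1_STARTS = (2.0, 10.0, 30.0)
_T2_STARTS = (100.0, 200.0, 400.0)

# Loose default box: amplitudes in [-0.1, 1.2], lifetimes in [0.1, 5000] s.
# Wide enough not to bind on physiological fibers, tight enough to keep the
# optimizer off pathological plateaus on noisy traces.
_DEFAULT_BOUNDS = (
    np.array([-0.1, 0.1, -0.1, 0.1]),
    np.array([1.2, 5000.0, 1.2, 5000.0]),
)


def decay_model(t, p1, t1, p2, t2):
    """Normalized double-exponential decay; equals 1 at t = 0 identically.

    Parameters are amplitude *fractions* ``p1``, ``p2`` and lifetimes
    ``t1``, ``t2`` in seconds.
    """
    t = np.asarray(t, dtype=float)
    return 1.0 - p1 * (1.0 - np.exp(-t / t1)) - p2 * (1.0 - np.exp(-t / t2))


def _model_jacobian(t, p1, t1, p2, t2):
    e1 = np.exp(-t / t1)
    e2 = np.exp(-t / t2)
    return np.column_stack(
        [
            -(1.0 - e1),
            p1 * e1 * t / t1**2,
            -(1.0 - e2),
            p2 * e2 * t / t2**2,
        ]
    )


def extract_roi_traces(stack, fiber_masks, background_masks):
    """Average an image stack over fiber and background ROIs, frame by frame.

    ``stack`` is (n_frames, ny, nx).  The fiber trace is the per-frame mean of
    the individual fiber-ROI means (the conventional three sampled regions per
    fiber are averaged before any fitting); the background trace is the mean
    over the background ROI(s).

    Returns ``(fiber_trace, background_trace)`` as float arrays of length
    n_frames.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError(f"stack must be 3-D (frames, y, x); got shape {stack.shape}")
    if not fiber_masks:
        raise ValueError("at least one fiber ROI mask is required")
    if not background_masks:
        raise ValueError("at least one background ROI mask is required")

    bad = np.argwhere(~np.isfinite(stack))
    if bad.size:
        raise ValueError(f"stack contains a non-finite pixel in frame {int(bad[0, 0])}")

    def roi_mean(mask):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != stack.shape[1:]:
            raise ValueError(
                f"mask shape {mask.shape} does not match frame shape {stack.shape[1:]}"
            )
        if not mask.any():
            raise ValueError("empty ROI mask")
        return stack[:, mask].mean(axis=1)

    fiber = np.mean([roi_mean(m) for m in fiber_masks], axis=0)
    background = np.mean([roi_mean(m) for m in background_masks], axis=0)
    return fiber, background


def normalize(trace: FluorescenceTrace) -> NormalizedDecay:
    """Background-correct and normalize a raw fluorescence trace.

    The mean background intensity is subtracted frame-wise from the fiber
    intensity, and every frame is divided by the corrected intensity of the
    final pre-washout frame (t = 0), so the output starts at exactly 1.

    Raises ``ValueError`` if the corrected t = 0 intensity is not positive
    (such a fiber is unusable).
    """
    trace.validate()
    corrected = np.asarray(trace.raw_fluor, float) - np.asarray(
        trace.background_fluor, float
    )
    c0 = corrected[0]
    if not c0 > 0:
        raise ValueError(
            f"fiber {trace.fiber_id}: background-corrected intensity at t=0 is "
            f"{c0:g}; must be > 0"
        )
    return NormalizedDecay(time_s=np.asarray(trace.time_s, float), norm_fluor=corrected / c0)


def _init_amplitudes(t, y, t1_0, t2_0):
    # The model is linear in (p1, p2) at fixed lifetimes: solve
    # 1 - y = p1*(1-exp(-t/t1)) + p2*(1-exp(-t/t2)) by least squares.
    b = np.column_stack([1.0 - np.exp(-t / t1_0), 1.0 - np.exp(-t / t2_0)])
    sol, *_ = np.linalg.lstsq(b, 1.0 - y, rcond=None)
    return np.clip(sol, -0.05, 1.1)


@dataclass
class QCThresholds:
    """Per-fiber quality-control thresholds for accepting a decay fit."""

    require_converged: bool = True
    max_rel_se_t2: float = 1.0  # reject if SE(T2)/T2 exceeds this
    max_rel_se_t1: float = 1.0
    reject_amplitude_sum_gt_100: bool = False
    reject_lifetimes_close: bool = False


def fit_decay(
    decay: NormalizedDecay,
    *,
    unconstrained: bool = False,
    rel_tol: float = 1e-10,
    max_nfev: int = 10_000,
) -> DecayFit:
    """Fit the double-exponential decay model by multi-start least squares.

    Starts span a lifetime grid T1 in {2, 10, 30} s x T2 in {100, 200, 400} s
    with amplitudes initialized by a linear solve at each pair; the best
    residual sum of squares wins.  The fit uses loose box constraints by
    default (``unconstrained=True`` removes them).  After fitting, components
    are relabelled so the faster lifetime is reported as (P1, T1) = DRX and
    amplitudes are converted to percent.  Standard errors come from the local
    curvature (Gauss-Newton approximation) at the optimum.

    QC flags raised here:

    - ``NONCONVERGED``: no start converged; parameters are NaN and the fit
      must not be used downstream.
    - ``LIFETIMES_CLOSE``: fitted lifetimes differ by < 5x and their 95%
      confidence intervals overlap — the two components are weakly
      identifiable.
    - ``AMPLITUDE_SUM_GT_100``: P1 + P2 exceeds 100% (negative plateau).
    - ``COMPONENT_NEGLIGIBLE``: an amplitude below 0.5%, e.g. a decay that is
      effectively single-exponential or flat.
    """
    t = np.asarray(decay.time_s, float)
    y = np.asarray(decay.norm_fluor, float)
    if t.size < 8:
        raise ValueError(f"need at least 8 time points to fit; got {t.size}")
    if not np.isfinite(y).all():
        raise ValueError("decay contains non-finite values")

    # A flat trace (no exchanging heads) is an exact model solution with both
    # amplitudes zero but makes the Jacobian singular; handle it directly.
    rss_flat = float(np.sum((y - 1.0) ** 2))
    if rss_flat < 1e-12 * t.size:
        return DecayFit(
            p1_pct=0.0, t1_s=_T1_STARTS[1], p2_pct=0.0, t2_s=_T2_STARTS[1],
            p1_pct_se=np.nan, t1_s_se=np.nan, p2_pct_se=np.nan, t2_s_se=np.nan,
            rss=rss_flat, n_points=t.size, converged=True,
            qc_flags=frozenset({"COMPONENT_NEGLIGIBLE"}),
        )

    if unconstrained:
        bounds = (-np.inf, np.inf)
    else:
        bounds = _DEFAULT_BOUNDS

    def residuals(theta):
        return decay_model(t, *theta) - y

    def jac(theta):
        return _model_jacobian(t, *theta)

    best = None
    for t1_0, t2_0 in itertools.product(_T1_STARTS, _T2_STARTS):
        p1_0, p2_0 = _init_amplitudes(t, y, t1_0, t2_0)
        x0 = np.array([p1_0, t1_0, p2_0, t2_0])
        if not unconstrained:
            x0 = np.clip(x0, bounds[0], bounds[1])
        try:
            res = least_squares(
                residuals,
                x0,
                jac=jac,
                bounds=bounds,
                xtol=rel_tol,
                ftol=rel_tol,
                gtol=None,
                max_nfev=max_nfev,
            )
        except Exception:
            continue
        if res.status <= 0 or not np.isfinite(res.x).all():
            continue
        rss = float(2.0 * res.cost)
        if best is None or rss < best[0]:
            best = (rss, res)
        if rss < 1e-18 * t.size:  # numerically exact; later starts cannot win
            break

    if best is None:
        return DecayFit(
            p1_pct=np.nan, t1_s=np.nan, p2_pct=np.nan, t2_s=np.nan,
            p1_pct_se=np.nan, t1_s_se=np.nan, p2_pct_se=np.nan, t2_s_se=np.nan,
            rss=np.nan, n_points=t.size, converged=False,
            qc_flags=frozenset({"NONCONVERGED"}),
        )

    rss, res = best
    p1, t1, p2, t2 = res.x
    # Gauss-Newton covariance; guard the rank-deficient case.
    jtj = res.jac.T @ res.jac
    dof = max(t.size - 4, 1)
    try:
        cov = np.linalg.inv(jtj) * rss / dof
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(4, np.nan)

    # Label by speed: the faster component is DRX, by convention, always.
    if t1 > t2:
        p1, t1, p2, t2 = p2, t2, p1, t1
        se = se[[2, 3, 0, 1]]

    flags = set()
    if p1 + p2 > 1.0:
        flags.add("AMPLITUDE_SUM_GT_100")
    if min(p1, p2) < 0.005:
        flags.add("COMPONENT_NEGLIGIBLE")
    if t1 > 0 and t2 / t1 < 5.0:
        tol = 1e-6 * t2  # guard exactly-coincident lifetimes with zero SE
        lo1, hi1 = t1 - 1.96 * se[1] - tol, t1 + 1.96 * se[1] + tol
        lo2, hi2 = t2 - 1.96 * se[3] - tol, t2 + 1.96 * se[3] + tol
        if not np.isfinite(se[[1, 3]]).all() or (hi1 >= lo2 and hi2 >= lo1):
            flags.add("LIFETIMES_CLOSE")

    return DecayFit(
        p1_pct=100.0 * p1, t1_s=t1, p2_pct=100.0 * p2, t2_s=t2,
        p1_pct_se=100.0 * se[0], t1_s_se=se[1],
        p2_pct_se=100.0 * se[2], t2_s_se=se[3],
        rss=rss, n_points=t.size, converged=True, qc_flags=frozenset(flags),
    )


def fit_traces(traces, **fit_kwargs):
    """Normalize and fit every fiber in a tidy trace table.

    ``traces`` is a pandas DataFrame with columns fiber_id, animal_id,
    condition, fiber_type, temperature_C, time_s, raw_fluor,
    background_fluor (one row per frame).  Returns one row per fiber with all
    DecayFit fields plus the labels.  Fibers whose normalization fails are
    returned non-converged with flag ``NORMALIZATION_FAILED``.
    """
    import pandas as pd

    required = {
        "fiber_id", "animal_id", "condition", "fiber_type",
        "temperature_C", "time_s", "raw_fluor", "background_fluor",
    }
    missing = required - set(traces.columns)
    if missing:
        raise ValueError(f"trace table is missing columns: {sorted(missing)}")

    rows = []
    for fiber_id, grp in traces.groupby("fiber_id", sort=True):
        grp = grp.sort_values("time_s")
        trace = FluorescenceTrace(
            fiber_id=str(fiber_id),
            time_s=grp["time_s"].to_numpy(float),
            raw_fluor=grp["raw_fluor"].to_numpy(float),
            background_fluor=grp["background_fluor"].to_numpy(float),
            animal_id=str(grp["animal_id"].iloc[0]),
            condition=str(grp["condition"].iloc[0]),
            fiber_type=str(grp["fiber_type"].iloc[0]),
            temperature_C=float(grp["temperature_C"].iloc[0]),
        )
        try:
            fit = fit_decay(normalize(trace), **fit_kwargs)
        except ValueError:
            fit = DecayFit(
                p1_pct=np.nan, t1_s=np.nan, p2_pct=np.nan, t2_s=np.nan,
                p1_pct_se=np.nan, t1_s_se=np.nan, p2_pct_se=np.nan,
                t2_s_se=np.nan, rss=np.nan, n_points=len(grp),
                converged=False, qc_flags=frozenset({"NORMALIZATION_FAILED"}),
            )
        row = {
            "fiber_id": trace.fiber_id,
            "animal_id": trace.animal_id,
            "condition": trace.condition,
            "fiber_type": trace.fiber_type,
            "temperature_C": trace.temperature_C,
        }
        row.update(fit.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def qc_filter(fits, thresholds: QCThresholds | None = None):
    """Partition a fit table into accepted and rejected fibers.

    Every rejected row carries a machine-readable, semicolon-joined
    ``reject_reason``.  The partition is deterministic given the thresholds.
    Returns ``(accepted, rejected)`` DataFrames.
    """
    thresholds = thresholds or QCThresholds()
    fits = fits.copy()

    reasons = []
    for _, row in fits.iterrows():
        why = []
        flags = set(str(row.get("qc_flags", "")).split("|")) - {""}
        if thresholds.require_converged and not row["converged"]:
            why.append("NONCONVERGED")
        if row["converged"]:
            if (
                np.isfinite(row["t2_s_se"])
                and row["t2_s"] > 0
                and row["t2_s_se"] / row["t2_s"] > thresholds.max_rel_se_t2
            ):
                why.append("REL_SE_T2")
            if (
                np.isfinite(row["t1_s_se"])
                and row["t1_s"] > 0
                and row["t1_s_se"] / row["t1_s"] > thresholds.max_rel_se_t1
            ):
                why.append("REL_SE_T1")
            if thresholds.reject_amplitude_sum_gt_100 and "AMPLITUDE_SUM_GT_100" in flags:
                why.append("AMPLITUDE_SUM_GT_100")
            if thresholds.reject_lifetimes_close and "LIFETIMES_CLOSE" in flags:
                why.append("LIFETIMES_CLOSE")
        reasons.append(";".join(why))

    fits["reject_reason"] = reasons
    accepted = fits[fits["reject_reason"] == ""].drop(columns="reject_reason")
    rejected = fits[fits["reject_reason"] != ""]
    return accepted.reset_index(drop=True), rejected.reset_index(drop=True)


def plot_decay_fit(decay: NormalizedDecay, fit: DecayFit, path):
    """Write a per-fiber diagnostic plot (data, fitted curve, residuals)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(decay.time_s, decay.norm_fluor, "o", ms=3, label="data")
    if fit.converged:
        tt = np.linspace(decay.time_s[0], decay.time_s[-1], 300)
        ax.plot(
            tt,
            decay_model(tt, fit.p1_pct / 100, fit.t1_s, fit.p2_pct / 100, fit.t2_s),
            "-",
            label=(
                f"P1={fit.p1_pct:.1f}% T1={fit.t1_s:.1f}s "
                f"P2={fit.p2_pct:.1f}% T2={fit.t2_s:.0f}s"
            ),
        )
    ax.set_xlabel("time after ATP chase (s)")
    ax.set_ylabel("normalized fluorescence")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
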