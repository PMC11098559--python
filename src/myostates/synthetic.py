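"""Synthetic data generation for every stage of the pipeline.

No per-fiber fluorescence recordings or diffraction profiles accompany the
hibernation study this package analyzes (only proteomics raw files are
deposited), so this module generates inputs with the statistical structure
the analysis assumes:

- double-exponential Mant-ATP chase decays with additive Gaussian noise on
  the normalized scale, rescaled to raw counts over a drawn background;
- a hierarchical study layout (condition -> animal -> fiber) with
  between-animal and within-animal variation, fiber types I/II and one or
  two assay temperatures;
- small image stacks whose fiber-ROI means reproduce a tabular trace;
- 1-D diffraction profiles with Gaussian reflections placed by the exact
  Bragg relation on a smooth monotone background;
- log-normal protein/PTM abundance matrices with designated differential
  features and left-censored (intensity-dependent) missingness.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mant_atp import decay_model
from .types import (
    BeamGeometry,
    ConditionEffects,
    DecayTruth,
    DiffractionProfile,
    FluorescenceTrace,
    StudyDesign,
)
from .xray import spacing_to_detector

__all__ = [
    "simulate_decay",
    "simulate_study",
    "simulate_image_stack",
    "default_roi_geometry",
    "simulate_diffraction_profile",
    "simulate_abundance_matrix",
    "write_image_stack",
    "read_image_stack",
]


def simulate_decay(
    truth: DecayTruth,
    grid,
    noise_sd: float = 0.01,
    seed=0,
    *,
    baseline_intensity: float = 500.0,
    background_level: float = 50.0,
    background_drift_per_s: float = 0.0,
    fiber_id: str = "fiber",
    **labels,
) -> FluorescenceTrace:
    """Simulate one fiber's raw Mant-ATP chase trace from known truth.

    The normalized decay model is evaluated on ``grid`` (seconds, starting at
    0), i.i.d. Gaussian noise of standard deviation ``noise_sd`` is added on
    the normalized scale, and the result is rescaled by ``baseline_intensity``
    and offset by ``background_level`` so that downstream background
    subtraction and t=0 normalization are non-trivial:

        raw(t) = background(t) + baseline * (model(t) + noise)

    The paired background trace is ``background_level`` plus the optional
    linear drift.  ``labels`` (animal_id, condition, fiber_type,
    temperature_C) are attached to the returned trace.
    """
    truth.validate()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or grid[0] != 0:
        raise ValueError("time grid must start at 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)

    model = decay_model(grid, truth.p1_frac, truth.t1_s, truth.p2_frac, truth.t2_s)
    noisy = model + rng.normal(0.0, noise_sd, size=grid.size) if noise_sd > 0 else model
    background = background_level + background_drift_per_s * grid
    raw = background + baseline_intensity * noisy
    return FluorescenceTrace(
        fiber_id=fiber_id,
        time_s=grid,
        raw_fluor=raw,
        background_fluor=background,
        animal_id=str(labels.get("animal_id", "")),
        condition=str(labels.get("condition", "")),
        fiber_type=str(labels.get("fiber_type", "")),
        temperature_C=float(labels.get("temperature_C", 20.0)),
    ).validate()


def _draw_truth(rng, effects: ConditionEffects, condition, fiber_type, temperature_C,
                animal_lt_mult, animal_p1_shift, max_tries: int = 200) -> DecayTruth:
    """Draw one fiber's DecayTruth; resample until its invariants hold."""
    base = effects.baseline
    key = (condition, fiber_type)
    m1 = effects.t1_multipliers.get(key, 1.0)
    m2 = effects.t2_multipliers.get(key, 1.0)
    shift = effects.p1_shifts.get(key, 0.0)
    mt1, mt2 = effects.temperature_multipliers.get(temperature_C, (1.0, 1.0))

    for _ in range(max_tries):
        fiber_lt = rng.lognormal(0.0, effects.fiber_cv, size=2) if effects.fiber_cv > 0 else np.ones(2)
        p1 = (
            base.p1_frac + shift + animal_p1_shift
            + (rng.normal(0.0, effects.fiber_amp_sd) if effects.fiber_amp_sd > 0 else 0.0)
        )
        p2 = base.p2_frac
        truth = DecayTruth(
            p1_frac=p1,
            t1_s=base.t1_s * m1 * mt1 * animal_lt_mult[0] * fiber_lt[0],
            p2_frac=p2,
            t2_s=base.t2_s * m2 * mt2 * animal_lt_mult[1] * fiber_lt[1],
        )
        try:
            return truth.validate()
        except ValueError:
            continue
    raise RuntimeError(
        f"could not draw a valid DecayTruth for {condition}/{fiber_type} in "
        f"{max_tries} tries; check the configured effects"
    )


def simulate_study(design: StudyDesign, effects: ConditionEffects | None = None):
    """Simulate a full hierarchical study of Mant-ATP chase traces.

    Draws condition -> animal -> fiber, labels every trace, and returns
    ``(traces, truth)``: a tidy frame with one row per fiber per frame
    (fiber_id, animal_id, condition, fiber_type, temperature_C, time_s,
    raw_fluor, background_fluor) and a truth table with one row per fiber
    holding the generating parameters.  Fibers at each configured assay
    temperature are distinct (separate fibers from the same animals, as in a
    matched-animal two-temperature protocol).  Identical (design, effects)
    and seed give byte-identical tables.
    """
    design.validate()
    effects = (effects or ConditionEffects()).validate()
    rng = np.random.default_rng(design.seed)
    grid = design.time_grid()
    low, high = design.fibers_per_animal

    trace_frames = []
    truth_rows = []
    n_traces = 0
    for condition in design.conditions:
        for a in range(design.animals_per_condition):
            animal_id = f"{condition}_a{a + 1}"
            animal_lt = (
                rng.lognormal(0.0, effects.animal_cv, size=2)
                if effects.animal_cv > 0
                else np.ones(2)
            )
            animal_p1 = (
                rng.normal(0.0, effects.animal_amp_sd)
                if effects.animal_amp_sd > 0
                else 0.0
            )
            for temperature_C in design.temperatures_C:
                n_fibers = int(rng.integers(low, high + 1))
                for f in range(n_fibers):
                    fiber_type = "II" if rng.random() < design.fiber_type_proportion else "I"
                    truth = _draw_truth(
                        rng, effects, condition, fiber_type, temperature_C,
                        animal_lt, animal_p1,
                    )
                    baseline = rng.uniform(*effects.baseline_intensity)
                    background = rng.uniform(*effects.background_level)
                    fiber_id = f"{animal_id}_{temperature_C:g}C_f{f + 1}"
                    trace = simulate_decay(
                        truth,
                        grid,
                        noise_sd=effects.noise_sd,
                        seed=rng.integers(0, 2**31 - 1),
                        baseline_intensity=baseline,
                        background_level=background,
                        background_drift_per_s=effects.background_drift_per_s,
                        fiber_id=fiber_id,
                        animal_id=animal_id,
                        condition=condition,
                        fiber_type=fiber_type,
                        temperature_C=temperature_C,
                    )
                    trace_frames.append(
                        pd.DataFrame(
                            {
                                "fiber_id": fiber_id,
                                "animal_id": animal_id,
                                "condition": condition,
                                "fiber_type": fiber_type,
                                "temperature_C": temperature_C,
                                "time_s": grid,
                                "raw_fluor": trace.raw_fluor,
                                "background_fluor": trace.background_fluor,
                            }
                        )
                    )
                    truth_rows.append(
                        {
                            "fiber_id": fiber_id,
                            "animal_id": animal_id,
                            "condition": condition,
                            "fiber_type": fiber_type,
                            "temperature_C": temperature_C,
                            "p1_frac": truth.p1_frac,
                            "t1_s": truth.t1_s,
                            "p2_frac": truth.p2_frac,
                            "t2_s": truth.t2_s,
                            "baseline_intensity": baseline,
                            "background_level": background,
                        }
                    )
                    n_traces += 1
    if n_traces == 0:
        raise ValueError("design produced zero fibers")
    traces = pd.concat(trace_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return traces, truth


def default_roi_geometry(frame_shape=(64, 64)):
    """Three disjoint fiber ROIs along a horizontal fiber plus one background ROI.

    Returns ``(fiber_masks, background_masks)`` as lists of boolean arrays.
    """
    ny, nx = frame_shape
    fiber_rows = slice(ny // 2 - ny // 8, ny // 2 + ny // 8)
    thirds = np.array_split(np.arange(nx // 8, nx - nx // 8), 3)
    fiber_masks = []
    for cols in thirds:
        m = np.zeros(frame_shape, dtype=bool)
        m[fiber_rows, cols[0] : cols[-1]] = True  # leave a 1-px gap between ROIs
        fiber_masks.append(m)
    bg = np.zeros(frame_shape, dtype=bool)
    bg[: ny // 8, : nx // 2] = True
    return fiber_masks, [bg]


def simulate_image_stack(
    trace: FluorescenceTrace,
    frame_shape=(64, 64),
    roi_geometry=None,
    noise: str = "none",
    noise_sd: float = 1.0,
    seed=0,
):
    """Render a trace as a synthetic fluorescence image stack with ROI masks.

    Per frame, pixels inside the fiber ROIs take the trace's raw value and all
    other pixels take the background value (both before pixel noise), so the
    ROI-mean extraction round-trips the tabular trace.  ``noise`` is one of
    ``"none"``, ``"gaussian"`` (additive, ``noise_sd``) or ``"poisson"``.

    Returns ``(stack, fiber_masks, background_masks)``; the stack has shape
    ``(n_frames, *frame_shape)``.
    """
    trace.validate()
    if roi_geometry is None:
        roi_geometry = default_roi_geometry(frame_shape)
    fiber_masks, background_masks = roi_geometry

    union = np.zeros(frame_shape, dtype=int)
    for m in list(fiber_masks) + list(background_masks):
        if m.shape != tuple(frame_shape):
            raise ValueError("ROI mask shape does not match frame shape")
        union += m.astype(int)
    if (union > 1).any():
        raise ValueError("ROI masks overlap; fiber and background ROIs must be disjoint")

    n_frames = len(trace.time_s)
    stack = np.empty((n_frames,) + tuple(frame_shape), dtype=float)
    fiber_any = np.zeros(frame_shape, dtype=bool)
    for m in fiber_masks:
        fiber_any |= m
    for i in range(n_frames):
        frame = np.full(frame_shape, trace.background_fluor[i], dtype=float)
        frame[fiber_any] = trace.raw_fluor[i]
        stack[i] = frame

    rng = np.random.default_rng(seed)
    if noise == "gaussian":
        stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)
    elif noise == "poisson":
        stack = rng.poisson(np.clip(stack, 0.0, None)).astype(float)
    elif noise != "none":
        raise ValueError(f"unknown noise model {noise!r}; use none|gaussian|poisson")
    return stack, fiber_masks, background_masks


def write_image_stack(stack, fiber_masks, background_masks, path_prefix):
    """Write a stack as multi-page TIFF with ROI masks as run-length JSON.

    Produces ``<prefix>.tiff`` and ``<prefix>_rois.json`` (row-wise run
    lengths per mask).  Returns the two paths.
    """
    import json
    from pathlib import Path

    import tifffile

    path_prefix = Path(path_prefix)
    tiff_path = path_prefix.with_suffix(".tiff")
    roi_path = path_prefix.parent / f"{path_prefix.name}_rois.json"
    tifffile.imwrite(tiff_path, np.asarray(stack, dtype=np.float32))

    def runs(mask):
        out = []
        for row in np.asarray(mask, dtype=bool):
            edges = np.flatnonzero(np.diff(np.concatenate([[0], row, [0]])))
            out.append([[int(s), int(e)] for s, e in zip(edges[::2], edges[1::2])])
        return out

    roi_path.write_text(
        json.dumps(
            {
                "frame_shape": list(np.asarray(fiber_masks[0]).shape),
                "fiber": [runs(m) for m in fiber_masks],
                "background": [runs(m) for m in background_masks],
            }
        )
    )
    return tiff_path, roi_path


def read_image_stack(path_prefix):
    """Inverse of :func:`write_image_stack`.

    Returns ``(stack, fiber_masks, background_masks)``.
    """
    import json
    from pathlib import Path

    import tifffile

    path_prefix = Path(path_prefix)
    stack = tifffile.imread(path_prefix.with_suffix(".tiff")).astype(float)
    spec = json.loads(
        (path_prefix.parent / f"{path_prefix.name}_rois.json").read_text()
    )
    shape = tuple(spec["frame_shape"])

    def unruns(rows):
        mask = np.zeros(shape, dtype=bool)
        for i, row_runs in enumerate(rows):
            for start, end in row_runs:
                mask[i, start:end] = True
        return mask

    fiber = [unruns(m) for m in spec["fiber"]]
    background = [unruns(m) for m in spec["background"]]
    return stack, fiber, background


def simulate_diffraction_profile(
    peaks,
    geometry: BeamGeometry | None = None,
    r_range_mm=(2.0, 60.0),
    n_points: int = 2000,
    background=(10.0, 200.0, 15.0),
    noise_sd: float = 0.0,
    seed=0,
    axis: str = "meridional",
    **labels,
) -> DiffractionProfile:
    """Simulate a 1-D diffraction profile from a list of reflections.

    ``peaks`` is a list of ``(d_spacing_nm, integrated_intensity, width_mm)``;
    each Gaussian is centered at the detector radius implied by its d-spacing
    under the exact Bragg relation for the given geometry and normalized so
    its area equals the requested intensity.  The background is the smooth
    monotone-decreasing curve ``b0 + b1*exp(-r/r_decay)`` (the three
    ``background`` parameters), plus additive Gaussian noise of ``noise_sd``.
    A peak whose center falls outside ``r_range_mm`` raises a ValueError
    naming the peak.
    """
    geometry = (geometry or BeamGeometry()).validate()
    rng = np.random.default_rng(seed)
    r = np.linspace(r_range_mm[0], r_range_mm[1], n_points)
    b0, b1, r_decay = background
    intensity = b0 + b1 * np.exp(-r / r_decay)
    for d_nm, area, width_mm in peaks:
        if not d_nm > 0:
            raise ValueError(f"d-spacing must be positive; got {d_nm}")
        center = spacing_to_detector(d_nm, geometry)
        if not r_range_mm[0] <= center <= r_range_mm[1]:
            raise ValueError(
                f"peak at d={d_nm} nm maps to radius {center:.2f} mm, outside "
                f"the simulated range {r_range_mm}"
            )
        intensity = intensity + (
            area / (width_mm * np.sqrt(2.0 * np.pi))
        ) * np.exp(-0.5 * ((r - center) / width_mm) ** 2)
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=r.size)
    return DiffractionProfile(
        radius_mm=r,
        intensity=intensity,
        axis=axis,
        condition=str(labels.get("condition", "")),
        bundle_id=str(labels.get("bundle_id", "")),
    ).validate()


def simulate_abundance_matrix(
    n_features: int = 1000,
    groups=None,
    de_fraction: float = 0.1,
    log2_fc: float = 2.0,
    feature_sd: float = 0.5,
    missingness: str = "left-censored",
    missing_rate: float = 0.0,
    seed=0,
):
    """Simulate a log2 protein/PTM-site abundance matrix with known truth.

    Feature baseline abundances are log-normal (normal on the log2 scale,
    mean 16, SD 2 — typical of reporter-ion intensities); sample values vary
    around their feature baseline with ``feature_sd``.  A ``de_fraction`` of
    features is shifted by ``log2_fc`` in every non-reference group (the
    first group listed is the reference).  With ``missingness
    ="left-censored"`` and ``missing_rate > 0``, cells go missing with a
    probability that increases as abundance decreases (values below the
    low-abundance tail are preferentially censored, the regime MinProb-style
    imputation targets); ``missingness="off"`` yields a complete matrix.

    Returns ``(matrix, sample_groups, truth)``: a features x samples
    DataFrame (log2 scale, NaN for missing), a Series mapping sample -> group
    label, and a truth table with ``is_de`` and the applied shift.
    """
    if groups is None:
        groups = {"SA": 5, "torpor": 5}
    if any(n < 2 for n in groups.values()):
        raise ValueError("every group needs >= 2 samples")
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    features = [f"prot{i:05d}" for i in range(n_features)]
    samples, labels = [], []
    for g, n in groups.items():
        for j in range(n):
            samples.append(f"{g}_{j + 1}")
            labels.append(g)
    sample_groups = pd.Series(labels, index=samples, name="group")
    reference = next(iter(groups))

    base = rng.normal(16.0, 2.0, size=n_features)
    n_de = int(round(de_fraction * n_features))
    de_idx = rng.choice(n_features, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)

    data = np.empty((n_features, len(samples)))
    for j, g in enumerate(labels):
        shift = np.zeros(n_features)
        if g != reference:
            shift[de_idx] = signs * log2_fc
        data[:, j] = base + shift + rng.normal(0.0, feature_sd, size=n_features)

    if missingness == "left-censored" and missing_rate > 0:
        # Logistic in abundance, centered below the grand mean so censoring is
        # concentrated in the low-intensity tail; scaled to hit the requested
        # overall rate.
        mu, sd = data.mean(), data.std()
        propensity = 1.0 / (1.0 + np.exp((data - (mu - 1.0 * sd)) / (0.5 * sd)))
        p_miss = np.minimum(1.0, propensity * missing_rate / propensity.mean())
        data = np.where(rng.random(data.shape) < p_miss, np.nan, data)
    elif missingness not in ("left-censored", "off"):
        raise ValueError(f"unknown missingness model {missingness!r}")

    matrix = pd.DataFrame(data, index=features, columns=samples)
    truth = pd.DataFrame(
        {"feature": features, "is_de": False, "log2_fc": 0.0}
    ).set_index("feature")
    truth.iloc[de_idx, truth.columns.get_loc("is_de")] = True
    truth.iloc[de_idx, truth.columns.get_loc("log2_fc")] = signs * log2_fc
    return matrix, sample_groups, truth
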