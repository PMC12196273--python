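"""Synthetic surface-dissolution imaging studies with linked plasma profiles.

A study emulates a flow-cell UV imaging experiment on a single tablet:
three dissolution media (pH 1.2 buffer, water, pH 6.8 buffer), two capture
wavelengths (255 nm UV, 520 nm visible), giving six video captures per
tablet.  Release kinetics are first-order for immediate-release (IR)
tablets and Weibull for extended-release (XR) tablets; each medium applies
a rate multiplier.  The rendered frame model is deliberately simple — a
centred anti-aliased tablet rectangle whose area tracks remaining drug
mass, an optional gel annulus for swelling XR matrices, and a smooth
dissolved-drug plume above the tablet whose pixel integral equals
``drug_absorptivity * dose * fraction_dissolved(t)`` exactly.  The integral,
not the plume shape, carries the quantitative signal.

The linked in vivo plasma profile is generated by convolving the
time-derivative of the in vitro release in a designated reference medium
with a one-compartment first-order elimination kernel (Bateman-type
response), so the image -> concentration mapping has a known ground truth.

Everything is a pure function of (specs, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from ivivr.pk import PlasmaProfile

MEDIUM_IDS = ("1_2", "Wa", "6_8")
WAVELENGTHS = (255, 520)

#: manual sampling plan for IR tablets (minutes); capture runs to 75 min
IR_SAMPLING_TIMES = (0, 5, 10, 15, 30, 45, 60, 75)
#: automated sampling plan for XR tablets (minutes); capture runs to 720 min
XR_SAMPLING_TIMES = (
    0, 5, 10, 15, 30, 45, 60, 120, 180, 240, 300, 360, 420, 480, 540, 600,
    660, 720,
)

IR_DURATION_MIN = 75.0
XR_DURATION_MIN = 720.0


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class MediumSpec:
    """A dissolution medium and its kinetic rate multiplier."""

    id: str
    rate_multiplier: float

    def __post_init__(self) -> None:
        if self.id not in MEDIUM_IDS:
            raise ValueError(f"unknown medium id {self.id!r}; expected one of {MEDIUM_IDS}")
        if not self.rate_multiplier > 0:
            raise ValueError("rate_multiplier must be > 0")


@dataclass(frozen=True)
class FormulationSpec:
    """A tablet formulation: geometry plus base release kinetics.

    ``dissolution_params`` holds the base kinetics to which each medium's
    rate multiplier is applied: ``{"k": ...}`` (1/min) for IR,
    ``{"tau": ..., "beta": ...}`` (min, dimensionless) for XR.
    ``swelling_gain`` scales gel-annulus growth and must be 0 for IR.
    """

    id: str
    release_type: str  # "IR" | "XR"
    dose: float  # mg
    tablet_height_px: int
    tablet_width_px: int
    dissolution_params: Mapping[str, float]
    swelling_gain: float = 0.0

    def __post_init__(self) -> None:
        if self.release_type not in ("IR", "XR"):
            raise ValueError("release_type must be 'IR' or 'XR'")
        if not self.dose > 0:
            raise ValueError("dose must be > 0")
        if self.release_type == "IR":
            if self.dissolution_params.get("k", 0.0) <= 0:
                raise ValueError("IR formulation requires first-order rate k > 0")
            if self.swelling_gain != 0.0:
                raise ValueError("swelling_gain must be 0 for IR")
        else:
            if self.dissolution_params.get("tau", 0.0) <= 0:
                raise ValueError("XR formulation requires Weibull scale tau > 0")
            if self.dissolution_params.get("beta", 0.0) <= 0:
                raise ValueError("XR formulation requires Weibull shape beta > 0")


@dataclass(frozen=True)
class AcquisitionSpec:
    """One capture wavelength and its rendering constants.

    ``drug_absorptivity`` is absorbance-integral per unit dissolved mass
    (AU*px/mg); ``tablet_opacity`` the per-pixel absorbance of intact tablet;
    ``noise_sd`` the additive Gaussian noise level (AU).
    """

    wavelength: int
    drug_absorptivity: float
    tablet_opacity: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.wavelength not in WAVELENGTHS:
            raise ValueError(f"wavelength must be one of {WAVELENGTHS}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class PKParams:
    """One-compartment PK link: first-order elimination, absorption driven
    by the reference medium's in vitro release derivative."""

    ke: float  # 1/min
    V: float  # apparent volume (scaling constant)
    F: float  # bioavailable fraction
    reference_medium: str = "1_2"

    def __post_init__(self) -> None:
        if not self.ke > 0:
            raise ValueError("ke must be > 0")
        if not self.V > 0:
            raise ValueError("V must be > 0")
        if not 0 < self.F <= 1:
            raise ValueError("F must be in (0, 1]")
        if self.reference_medium not in MEDIUM_IDS:
            raise ValueError("unknown reference_medium")


@dataclass
class DissolutionVideo:
    """One (formulation, medium, wavelength) capture.

    ``frames`` is a (T, H, W) nonnegative array of absorbance maps.  The
    generator also records its ground truth per frame: dissolved fraction
    and the (float, half-open) core and outer tablet boxes, which tests use
    for mass-balance and geometry oracles.
    """

    formulation_id: str
    medium_id: str
    wavelength: int
    times: np.ndarray  # (T,) minutes
    frames: np.ndarray  # (T, H, W)
    fraction: np.ndarray  # (T,) ground-truth dissolved fraction
    core_boxes: np.ndarray  # (T, 4) rows y0, y1, x0, x1 (float, half-open)
    outer_boxes: np.ndarray  # (T, 4) core plus gel annulus (== core for IR)
    acquisition: AcquisitionSpec | None = None
    formulation: FormulationSpec | None = None

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def frame_at(self, t: float) -> np.ndarray:
        """Return the frame at time ``t`` (exact match required)."""
        idx = np.flatnonzero(np.isclose(self.times, t))
        if idx.size == 0:
            raise KeyError(f"no frame at t={t} min in video "
                           f"{self.formulation_id}/{self.medium_id}_{self.wavelength}")
        return self.frames[idx[0]]

    def absorbance_frame(self, t: float):
        from ivivr.imaging import AbsorbanceFrame

        return AbsorbanceFrame(pixels=self.frame_at(t), medium_id=self.medium_id,
                               wavelength=self.wavelength, time=float(t))


@dataclass
class SimulatedStudy:
    """Six dissolution videos plus the linked plasma profile."""

    formulation: FormulationSpec
    videos: dict[tuple[str, int], DissolutionVideo]
    true_fraction_dissolved: dict[str, Callable[[np.ndarray], np.ndarray]]
    plasma_profile: PlasmaProfile
    sampling_times: tuple[float, ...]
    seed: int

    def video(self, medium_id: str, wavelength: int) -> DissolutionVideo:
        return self.videos[(medium_id, wavelength)]


# ---------------------------------------------------------------------------
# release kinetics


def fraction_dissolved(formulation: FormulationSpec, medium: MediumSpec,
                       t: float | np.ndarray) -> float | np.ndarray:
    """Fraction of dose dissolved at time ``t`` (minutes) in ``medium``.

    IR: ``1 - exp(-k m t)``; XR: ``1 - exp(-((t / (tau/m))**beta))`` with
    ``m`` the medium rate multiplier.  Nondecreasing in t, -> 1 as t -> inf.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    m = medium.rate_multiplier
    if formulation.release_type == "IR":
        k = formulation.dissolution_params["k"]
        out = 1.0 - np.exp(-k * m * t_arr)
    else:
        tau = formulation.dissolution_params["tau"] / m
        beta = formulation.dissolution_params["beta"]
        out = 1.0 - np.exp(-np.power(t_arr / tau, beta))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def release_rate(formulation: FormulationSpec, medium: MediumSpec,
                 t: np.ndarray) -> np.ndarray:
    """Analytic time-derivative of :func:`fraction_dissolved` (1/min)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    m = medium.rate_multiplier
    if formulation.release_type == "IR":
        k = formulation.dissolution_params["k"] * m
        return k * np.exp(-k * t)
    tau = formulation.dissolution_params["tau"] / m
    beta = formulation.dissolution_params["beta"]
    with np.errstate(divide="ignore", invalid="ignore"):
        x = t / tau
        rate = (beta / tau) * np.power(x, beta - 1.0) * np.exp(-np.power(x, beta))
    # Weibull with beta > 1 has zero initial rate; beta < 1 diverges at 0,
    # where we report the (finite) right-limit of the cumulative via 0.
    return np.where(t > 0, rate, 0.0)


# ---------------------------------------------------------------------------
# frame rendering

FRAME_HEIGHT_PX = 112  #: default frame height, preserving a 28x24 mm field
FRAME_WIDTH_PX = 96
MIN_MARGIN_PX = 4
GEL_OPACITY_FACTOR = 0.3  # gel annulus absorbance relative to intact core


def _interval_coverage(n: int, lo: float, hi: float) -> np.ndarray:
    """Per-cell overlap of [lo, hi) with unit cells [i, i+1); sums to hi-lo."""
    edges = np.arange(n + 1, dtype=float)
    return np.clip(np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo), 0.0, None)


def _aa_rect(shape: tuple[int, int], box: tuple[float, float, float, float]) -> np.ndarray:
    """Anti-aliased axis-aligned rectangle; pixel sum equals the exact area."""
    h, w = shape
    y0, y1, x0, x1 = box
    return np.outer(_interval_coverage(h, y0, y1), _interval_coverage(w, x0, x1))


def _tablet_geometry(formulation: FormulationSpec, frac: float,
                     shape: tuple[int, int]) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Core and outer (core + gel) boxes at dissolved fraction ``frac``.

    The core rectangle keeps its aspect ratio and shrinks so that its area
    is proportional to remaining fraction (1 - frac); for XR a gel annulus
    grows with ``swelling_gain``, capped one pixel inside the frame margin.
    """
    H, W = shape
    cy, cx = H / 2.0, W / 2.0
    scale = math.sqrt(max(0.0, 1.0 - frac))
    h = formulation.tablet_height_px * scale
    w = formulation.tablet_width_px * scale
    core = (cy - h / 2.0, cy + h / 2.0, cx - w / 2.0, cx + w / 2.0)
    if formulation.release_type == "XR" and formulation.swelling_gain > 0:
        margin = min(
            (H - formulation.tablet_height_px) / 2.0,
            (W - formulation.tablet_width_px) / 2.0,
        )
        g = min(formulation.swelling_gain * frac * (margin - 1.0), margin - 1.0)
        g = max(g, 0.0)
        outer = (core[0] - g, core[1] + g, core[2] - g, core[3] + g)
    else:
        outer = core
    return core, outer


def _check_margins(formulation: FormulationSpec, shape: tuple[int, int]) -> None:
    H, W = shape
    if (H - formulation.tablet_height_px) / 2.0 < MIN_MARGIN_PX or \
            (W - formulation.tablet_width_px) / 2.0 < MIN_MARGIN_PX:
        raise ValueError(
            f"tablet {formulation.tablet_height_px}x{formulation.tablet_width_px} px "
            f"does not fit a {H}x{W} frame with a {MIN_MARGIN_PX} px margin")


def render_frame(formulation: FormulationSpec, medium: MediumSpec,
                 acq: AcquisitionSpec, t: float,
                 shape: tuple[int, int] = (FRAME_HEIGHT_PX, FRAME_WIDTH_PX),
                 ) -> tuple[np.ndarray, float, tuple, tuple]:
    """Render one noise-free frame; returns (pixels, fraction, core, outer).

    The plume is an exponentially decaying ridge above the tablet's top
    edge, normalised so its pixel sum is exactly
    ``drug_absorptivity * dose * fraction_dissolved(t)``.
    """
    _check_margins(formulation, shape)
    frac = float(fraction_dissolved(formulation, medium, t))
    core, outer = _tablet_geometry(formulation, frac, shape)
    H, W = shape
    img = acq.tablet_opacity * _aa_rect(shape, core)
    if outer != core:
        gel = _aa_rect(shape, outer) - _aa_rect(shape, core)
        img += GEL_OPACITY_FACTOR * acq.tablet_opacity * np.clip(gel, 0.0, None)
    target = acq.drug_absorptivity * formulation.dose * frac
    if target > 0:
        n_rows = int(math.floor(outer[0]))  # rows strictly above the tablet
        if n_rows < 1:
            raise ValueError("no room above the tablet for the dissolved-drug plume")
        rows = np.arange(n_rows, dtype=float) + 0.5
        depth = outer[0] - rows  # distance below the tablet top edge
        w_row = np.exp(-depth / (0.35 * H))
        cols = np.arange(W, dtype=float) + 0.5
        sigma = 0.35 * formulation.tablet_width_px
        w_col = np.exp(-0.5 * ((cols - W / 2.0) / sigma) ** 2)
        plume = np.outer(w_row, w_col)
        plume *= target / plume.sum()
        img[:n_rows] += plume
    return img, frac, core, outer


def simulate_dissolution_video(formulation: FormulationSpec, medium: MediumSpec,
                               acq: AcquisitionSpec, duration: float,
                               frame_interval: float, seed: int,
                               shape: tuple[int, int] = (FRAME_HEIGHT_PX, FRAME_WIDTH_PX),
                               extra_times: Sequence[float] = (),
                               ) -> DissolutionVideo:
    """Simulate one capture: frames at a regular grid (plus ``extra_times``),
    first frame at t = 0, additive Gaussian noise clipped at zero."""
    if not duration > 0:
        raise ValueError("duration must be > 0")
    if not frame_interval > 0:
        raise ValueError("frame_interval must be > 0")
    _check_margins(formulation, shape)
    grid = np.arange(0.0, duration + 1e-9, frame_interval)
    times = np.union1d(np.round(grid, 6), np.round(np.asarray(extra_times, float), 6))
    if np.any(times < 0) or np.any(times > duration + 1e-9):
        raise ValueError("extra_times must lie within [0, duration]")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), MEDIUM_IDS.index(medium.id),
                                int(acq.wavelength)]))
    T = times.size
    frames = np.empty((T, *shape), dtype=float)
    fracs = np.empty(T)
    cores = np.empty((T, 4))
    outers = np.empty((T, 4))
    for i, t in enumerate(times):
        img, frac, core, outer = render_frame(formulation, medium, acq, float(t), shape)
        if acq.noise_sd > 0:
            img = np.clip(img + rng.normal(0.0, acq.noise_sd, size=shape), 0.0, None)
        frames[i] = img
        fracs[i] = frac
        cores[i] = core
        outers[i] = outer
    return DissolutionVideo(
        formulation_id=formulation.id, medium_id=medium.id,
        wavelength=acq.wavelength, times=times, frames=frames, fraction=fracs,
        core_boxes=cores, outer_boxes=outers, acquisition=acq,
        formulation=formulation)


# ---------------------------------------------------------------------------
# pharmacokinetics


def simulate_plasma_profile(formulation: FormulationSpec, pk: PKParams,
                            t_grid: Sequence[float],
                            media: Mapping[str, MediumSpec] | None = None,
                            fine_step: float = 0.25) -> PlasmaProfile:
    """Plasma concentration by convolution of the reference-medium release
    rate with a first-order elimination kernel.

    ``C(t) = (F dose / V) * int_0^t rdot(u) exp(-ke (t-u)) du``, evaluated
    by trapezoidal quadrature on a fine grid (step <= 1 min) using the
    exact recursion ``I(t+h) = I(t) e^{-ke h} + h/2 (rdot(t) e^{-ke h} +
    rdot(t+h))``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D sequence")
    if t_grid[0] != 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be sorted, strictly increasing, starting at 0")
    if not 0 < fine_step <= 1.0:
        raise ValueError("fine_step must be in (0, 1] min")
    if media is None:
        media = default_media()
    medium = media[pk.reference_medium]
    fine = np.union1d(np.arange(0.0, t_grid[-1] + fine_step, fine_step), t_grid)
    fine = fine[fine <= t_grid[-1] + 1e-12]
    rdot = release_rate(formulation, medium, fine)
    integral = np.zeros_like(fine)
    dt = np.diff(fine)
    decay = np.exp(-pk.ke * dt)
    for i in range(1, fine.size):
        integral[i] = integral[i - 1] * decay[i - 1] + 0.5 * dt[i - 1] * (
            rdot[i - 1] * decay[i - 1] + rdot[i])
    conc = (pk.F * formulation.dose / pk.V) * integral
    idx = np.searchsorted(fine, t_grid)
    return PlasmaProfile(formulation_id=formulation.id, times=t_grid,
                         concentrations=np.maximum(conc[idx], 0.0),
                         source="simulated")


def bateman_tmax(ka: float, ke: float) -> float:
    """Closed-form time of peak for first-order absorption/elimination."""
    if ka == ke:
        return 1.0 / ka
    return math.log(ka / ke) / (ka - ke)


# ---------------------------------------------------------------------------
# study assembly


def generate_study(formulation: FormulationSpec,
                   media: Mapping[str, MediumSpec],
                   acquisitions: Mapping[int, AcquisitionSpec],
                   pk: PKParams,
                   sampling_plan: Sequence[float],
                   seed: int,
                   shape: tuple[int, int] = (FRAME_HEIGHT_PX, FRAME_WIDTH_PX),
                   frame_interval: float | None = None,
                   pk_grid_end: float = 1440.0,
                   pk_grid_step: float = 5.0) -> SimulatedStudy:
    """Generate six videos (3 media x 2 wavelengths) plus the linked plasma
    profile, all from one seed.  Frame times are the union of a regular grid
    and the sampling plan."""
    plan = tuple(sorted(float(t) for t in sampling_plan))
    if len(plan) == 0:
        raise ValueError("empty sampling plan")
    limit = IR_DURATION_MIN if formulation.release_type == "IR" else XR_DURATION_MIN
    if plan[-1] > limit:
        raise ValueError(
            f"sampling plan extends to {plan[-1]} min, beyond the {limit} min "
            f"capture window of a {formulation.release_type} study")
    if set(media) != set(MEDIUM_IDS):
        raise ValueError(f"media must cover exactly {MEDIUM_IDS}")
    if set(acquisitions) != set(WAVELENGTHS):
        raise ValueError(f"acquisitions must cover exactly {WAVELENGTHS}")
    if acquisitions[255].drug_absorptivity <= acquisitions[520].drug_absorptivity:
        raise ValueError("drug_absorptivity at 255 nm must exceed that at 520 nm")
    duration = limit
    if frame_interval is None:
        frame_interval = 5.0 if formulation.release_type == "IR" else 30.0
    videos: dict[tuple[str, int], DissolutionVideo] = {}
    for mid in MEDIUM_IDS:
        for wl in WAVELENGTHS:
            videos[(mid, wl)] = simulate_dissolution_video(
                formulation, media[mid], acquisitions[wl], duration,
                frame_interval, seed, shape=shape, extra_times=plan)
    profile = simulate_plasma_profile(
        formulation, pk,
        np.arange(0.0, pk_grid_end + 1e-9, pk_grid_step), media=media)
    fractions = {
        mid: (lambda t, _m=media[mid]: fraction_dissolved(formulation, _m, t))
        for mid in MEDIUM_IDS
    }
    return SimulatedStudy(formulation=formulation, videos=videos,
                          true_fraction_dissolved=fractions,
                          plasma_profile=profile, sampling_times=plan,
                          seed=int(seed))


# ---------------------------------------------------------------------------
# metformin-like study defaults
#
# These constants define the emulated study conditions: an IR 500 mg and an
# IR 850 mg tablet dissolving within 75 min in the faster media, an XR
# 750 mg tablet releasing over ~12 h, and plasma profiles with
# Cmax ~ 1000-1150 ng/mL near tmax ~ 120 min (IR).  The pH 1.2 medium is
# the slowest (rate multiplier 0.5) and drives absorption.


def default_media() -> dict[str, MediumSpec]:
    return {
        "1_2": MediumSpec("1_2", 0.5),
        "Wa": MediumSpec("Wa", 1.0),
        "6_8": MediumSpec("6_8", 1.2),
    }


def default_acquisitions(noise_fraction: float = 0.01) -> dict[int, AcquisitionSpec]:
    """UV channel sees dissolved drug; visible channel mainly the tablet.

    Default noise is 1% of the tablet opacity at each wavelength."""
    return {
        255: AcquisitionSpec(255, drug_absorptivity=0.02, tablet_opacity=1.2,
                             noise_sd=noise_fraction * 1.2),
        520: AcquisitionSpec(520, drug_absorptivity=0.002, tablet_opacity=2.0,
                             noise_sd=noise_fraction * 2.0),
    }


def default_formulations() -> dict[str, FormulationSpec]:
    return {
        "IR500": FormulationSpec("IR500", "IR", 500.0, 32, 72, {"k": 0.03}),
        "IR850": FormulationSpec("IR850", "IR", 850.0, 36, 76, {"k": 0.026}),
        "XR750": FormulationSpec("XR750", "XR", 750.0, 16, 80,
                                 {"tau": 240.0, "beta": 1.2},
                                 swelling_gain=0.5),
    }


def default_pk_params() -> dict[str, PKParams]:
    # ke/ka chosen so the IR Bateman peak falls near 120 min; V tuned once
    # so Cmax lands in the 1000-1150 ng/mL range at the given F and dose.
    return {
        "IR500": PKParams(ke=0.004, V=0.147, F=0.5, reference_medium="1_2"),
        "IR850": PKParams(ke=0.004, V=0.231, F=0.5, reference_medium="1_2"),
        "XR750": PKParams(ke=0.004, V=0.091, F=0.5, reference_medium="1_2"),
    }


def default_sampling_plan(release_type: str) -> tuple[float, ...]:
    return tuple(float(t) for t in
                 (IR_SAMPLING_TIMES if release_type == "IR" else XR_SAMPLING_TIMES))


def generate_default_study(formulation_id: str, seed: int,
                           shape: tuple[int, int] = (FRAME_HEIGHT_PX, FRAME_WIDTH_PX),
                           noise_fraction: float = 0.01) -> SimulatedStudy:
    """Convenience wrapper: one of the three default formulations, default
    media/acquisitions/PK, the matching sampling plan, one seed."""
    form = default_formulations()[formulation_id]
    # scale tablet geometry with non-default frame sizes
    H, W = shape
    if (H, W) != (FRAME_HEIGHT_PX, FRAME_WIDTH_PX):
        sy, sx = H / FRAME_HEIGHT_PX, W / FRAME_WIDTH_PX
        form = replace(form,
                       tablet_height_px=max(4, int(round(form.tablet_height_px * sy))),
                       tablet_width_px=max(4, int(round(form.tablet_width_px * sx))))
    return generate_study(
        form, default_media(), default_acquisitions(noise_fraction),
        default_pk_params()[formulation_id],
        default_sampling_plan(form.release_type), seed, shape=shape)


# ---------------------------------------------------------------------------
# on-disk layout: <formulation>/<medium>_<wavelength>/t<minutes>.png


PNG_SCALE_KEY = "absorbance_per_count"


def write_study(study: SimulatedStudy, outdir: str | Path) -> Path:
    """Write frames as 16-bit grayscale PNGs plus a YAML manifest and the
    plasma profile as a 2-column CSV."""
    import imageio.v3 as iio
    import yaml

    outdir = Path(outdir)
    root = outdir / study.formulation.id
    manifest: dict = {
        "formulation": study.formulation.id,
        "release_type": study.formulation.release_type,
        "dose_mg": study.formulation.dose,
        "seed": study.seed,
        "sampling_times_min": list(study.sampling_times),
        "captures": {},
    }
    for (mid, wl), video in study.videos.items():
        cap_dir = root / f"{mid}_{wl}"
        cap_dir.mkdir(parents=True, exist_ok=True)
        vmax = float(video.frames.max())
        scale = vmax / 65535.0 if vmax > 0 else 1.0
        for t, frame in zip(video.times, video.frames):
            counts = np.round(frame / scale).astype(np.uint16)
            iio.imwrite(cap_dir / f"t{_fmt_time(t)}.png", counts)
        manifest["captures"][f"{mid}_{wl}"] = {
            PNG_SCALE_KEY: scale,
            "times_min": [float(t) for t in video.times],
        }
    prof = study.plasma_profile
    csv_path = root / "plasma_profile.csv"
    np.savetxt(csv_path, np.column_stack([prof.times, prof.concentrations]),
               delimiter=",", header="time_min,conc", comments="")
    with open(root / "study.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return root


def read_study_frames(root: str | Path) -> dict[tuple[str, int], DissolutionVideo]:
    """Read a written study directory back into per-capture videos (the
    inverse of :func:`write_study` up to 16-bit quantisation)."""
    import imageio.v3 as iio
    import yaml

    root = Path(root)
    with open(root / "study.yaml") as fh:
        manifest = yaml.safe_load(fh)
    videos: dict[tuple[str, int], DissolutionVideo] = {}
    for cap, meta in manifest["captures"].items():
        mid, wl = cap.rsplit("_", 1)
        wl = int(wl)
        times = np.asarray(meta["times_min"], dtype=float)
        frames = np.stack([
            iio.imread(root / cap / f"t{_fmt_time(t)}.png").astype(float)
            * meta[PNG_SCALE_KEY]
            for t in times
        ])
        videos[(mid, wl)] = DissolutionVideo(
            formulation_id=manifest["formulation"], medium_id=mid, wavelength=wl,
            times=times, frames=frames,
            fraction=np.full(times.size, np.nan),
            core_boxes=np.full((times.size, 4), np.nan),
            outer_boxes=np.full((times.size, 4), np.nan))
    return videos


def _fmt_time(t: float) -> str:
    return f"{t:g}".replace(".", "p")
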