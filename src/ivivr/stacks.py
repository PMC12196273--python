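"""CNN input representations of a dissolution study.

Two layouts are supported:

* **Timepoint stacks** — one stack per sampling time, six co-registered
  channels (3 media x 2 wavelengths) captured at that time, paired with
  the spline-interpolated plasma concentration.
* **Process stacks** — one stack per point of a fixed 53-point timepoint
  grid.  Every stack of a formulation shares the same 108 frame planes
  (6 captures x 18 frame-slot times), a whole-process snapshot; only a
  constant-valued timepoint layer (t / 1440) and the target differ
  between stacks.  Capture windows shorter than the frame-slot span (IR
  runs 75 min, XR 720 min) are padded with zero frames.

Channel order is canonical and fixed: media ["1_2", "Wa", "6_8"] x
wavelengths [255, 520], lexicographic in that token order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ivivr.pk import PlasmaProfile, cubic_spline_interpolate

MEDIUM_IDS = ("1_2", "Wa", "6_8")
WAVELENGTHS = (255, 520)

#: canonical channel order for timepoint stacks
CHANNEL_ORDER: tuple[tuple[str, int], ...] = tuple(
    (m, wl) for m in MEDIUM_IDS for wl in WAVELENGTHS)

#: frame-slot times of a process stack: t = 0 plus the 17-point XR sampling
#: plan; 6 captures x 18 slots = 108 frame planes
PROCESS_FRAME_TIMES: tuple[float, ...] = (
    0.0, 5.0, 10.0, 15.0, 30.0, 45.0, 60.0, 120.0, 180.0, 240.0, 300.0,
    360.0, 420.0, 480.0, 540.0, 600.0, 660.0, 720.0,
)

TIME_SCALE_MIN = 1440.0  #: timepoint layer encodes t / 1440

CAPTURE_WINDOW_MIN = {"IR": 75.0, "XR": 720.0}


def timepoint_grid() -> np.ndarray:
    """The 53-point process-stack grid: 7 early points (0, 5, 10, 15, 30,
    45, 60 min) then 46 points spaced 30 min apart up to 1440 min."""
    return np.concatenate([
        np.array([0.0, 5.0, 10.0, 15.0, 30.0, 45.0, 60.0]),
        np.arange(90.0, 1441.0, 30.0),
    ])


@dataclass
class TimepointStack:
    """Six same-time frames plus the interpolated concentration target."""

    formulation_id: str
    time: float
    channels: np.ndarray  # (6, H, W) in CHANNEL_ORDER
    target: float  # ng/mL (raw; scaling is applied by the harness)
    channel_order: tuple[tuple[str, int], ...] = CHANNEL_ORDER

    def __post_init__(self) -> None:
        if self.channels.ndim != 3 or self.channels.shape[0] != len(CHANNEL_ORDER):
            raise ValueError("channels must be a (6, H, W) array")

    @property
    def tensor(self) -> np.ndarray:
        return self.channels


@dataclass
class ProcessStack:
    """Whole-process frames plus a timepoint layer and the target.

    ``frames`` (108, H, W) is shared (by reference) between all stacks of
    one formulation; ``tensor`` appends the constant timepoint plane as a
    109th input plane.
    """

    formulation_id: str
    time: float
    frames: np.ndarray  # (108, H, W), shared across the formulation's stacks
    target: float  # ng/mL
    frame_slot_times: tuple[float, ...] = PROCESS_FRAME_TIMES
    time_scale: float = TIME_SCALE_MIN

    @property
    def timepoint_value(self) -> float:
        return self.time / self.time_scale

    @property
    def tensor(self) -> np.ndarray:
        tp = np.full((1, *self.frames.shape[1:]), self.timepoint_value,
                     dtype=self.frames.dtype)
        return np.concatenate([self.frames, tp], axis=0)


@dataclass
class DatasetSplit:
    train: list
    test: list
    rule: str

    def __post_init__(self) -> None:
        train_keys = {(s.formulation_id, s.time) for s in self.train}
        test_keys = {(s.formulation_id, s.time) for s in self.test}
        if train_keys & test_keys:
            raise ValueError("train/test overlap detected")


# ---------------------------------------------------------------------------
# builders


def build_timepoint_stacks(videos: Mapping[tuple[str, int], "object"],
                           profile: PlasmaProfile,
                           sampling_times: Sequence[float],
                           ) -> list[TimepointStack]:
    """One six-channel stack per sampling time, target = natural-cubic-
    spline-interpolated concentration at that time."""
    _require_six(videos)
    times = [float(t) for t in sampling_times]
    targets = cubic_spline_interpolate(profile, times).concentrations
    formulation_id = next(iter(videos.values())).formulation_id
    out = []
    for t, y in zip(times, targets):
        channels = np.stack([
            np.asarray(videos[key].frame_at(t), dtype=np.float32)
            for key in CHANNEL_ORDER
        ])
        out.append(TimepointStack(formulation_id=formulation_id, time=t,
                                  channels=channels, target=float(y)))
    return out


def build_process_stacks(videos: Mapping[tuple[str, int], "object"],
                         profile: PlasmaProfile,
                         release_type: str,
                         grid: np.ndarray | None = None,
                         ) -> list[ProcessStack]:
    """The 53 whole-process stacks of one formulation.

    Frame planes are laid out capture-major: for each (medium, wavelength)
    in canonical order, the 18 frame-slot times in order.  Slots beyond
    the formulation's capture window (75 min for IR, 720 min for XR) are
    zero-filled.
    """
    _require_six(videos)
    if release_type not in CAPTURE_WINDOW_MIN:
        raise ValueError("release_type must be 'IR' or 'XR'")
    if grid is None:
        grid = timepoint_grid()
    grid = np.asarray(grid, dtype=float)
    lo, hi = profile.span
    if grid[0] < lo or grid[-1] > hi:
        raise ValueError("timepoint grid extends beyond the plasma profile span")
    window = CAPTURE_WINDOW_MIN[release_type]
    first = next(iter(videos.values()))
    H, W = np.asarray(first.frame_at(0.0)).shape
    planes = np.zeros((len(CHANNEL_ORDER) * len(PROCESS_FRAME_TIMES), H, W),
                      dtype=np.float32)
    i = 0
    for key in CHANNEL_ORDER:
        for t in PROCESS_FRAME_TIMES:
            if t <= window:
                planes[i] = np.asarray(videos[key].frame_at(t), dtype=np.float32)
            i += 1
    targets = cubic_spline_interpolate(profile, grid).concentrations
    formulation_id = first.formulation_id
    return [
        ProcessStack(formulation_id=formulation_id, time=float(t),
                     frames=planes, target=float(y))
        for t, y in zip(grid, targets)
    ]


def extrapolation_split(stacks: Sequence[ProcessStack],
                        n_test: int = 6) -> DatasetSplit:
    """Withhold the final ``n_test`` records of each formulation as the
    extrapolation test set."""
    by_form: dict[str, list[ProcessStack]] = {}
    for s in stacks:
        by_form.setdefault(s.formulation_id, []).append(s)
    train: list[ProcessStack] = []
    test: list[ProcessStack] = []
    for fid, group in by_form.items():
        group = sorted(group, key=lambda s: s.time)
        if len(group) < n_test + 1:
            raise ValueError(f"formulation {fid} has too few stacks for the split")
        train.extend(group[:-n_test])
        test.extend(group[-n_test:])
    return DatasetSplit(train=train, test=test,
                        rule=f"final {n_test} records per formulation withheld")


def _require_six(videos: Mapping) -> None:
    if set(videos) != set(CHANNEL_ORDER):
        raise ValueError("need exactly the six (medium, wavelength) captures")


# ---------------------------------------------------------------------------
# serialization: one binary array container per stack + JSON sidecar

LAYOUT_VERSION = 1


def save_stack(stack: TimepointStack | ProcessStack, path: str | Path) -> None:
    """Persist a stack as <path>.npy plus a <path>.json sidecar."""
    path = Path(path)
    if isinstance(stack, TimepointStack):
        np.save(path.with_suffix(".npy"), stack.channels)
        meta = {"kind": "timepoint", "formulation_id": stack.formulation_id,
                "time": stack.time, "target": stack.target,
                "channel_order": [list(c) for c in stack.channel_order],
                "layout_version": LAYOUT_VERSION}
    else:
        np.save(path.with_suffix(".npy"), stack.frames)
        meta = {"kind": "process", "formulation_id": stack.formulation_id,
                "time": stack.time, "target": stack.target,
                "frame_slot_times": list(stack.frame_slot_times),
                "time_scale": stack.time_scale,
                "layout_version": LAYOUT_VERSION}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_stack(path: str | Path) -> TimepointStack | ProcessStack:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    arr = np.load(path.with_suffix(".npy"))
    if meta["kind"] == "timepoint":
        return TimepointStack(
            formulation_id=meta["formulation_id"], time=meta["time"],
            channels=arr, target=meta["target"],
            channel_order=tuple((m, int(wl)) for m, wl in meta["channel_order"]))
    return ProcessStack(
        formulation_id=meta["formulation_id"], time=meta["time"], frames=arr,
        target=meta["target"],
        frame_slot_times=tuple(meta["frame_slot_times"]),
        time_scale=meta["time_scale"])


def dataset_tensor(stacks: Sequence[TimepointStack | ProcessStack]) -> np.ndarray:
    """Stack tensors into an (N, planes, H, W) float32 training array."""
    return np.stack([np.asarray(s.tensor, dtype=np.float32) for s in stacks])


def dataset_hash(stacks: Sequence[TimepointStack | ProcessStack]) -> str:
    h = hashlib.sha256()
    for s in stacks:
        h.update(np.ascontiguousarray(s.tensor, dtype=np.float32).tobytes())
        h.update(np.float64(s.target).tobytes())
    return h.hexdigest()[:16]
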