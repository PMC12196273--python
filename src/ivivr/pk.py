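"""Plasma concentration-time profiles: containers, cubic-spline
interpolation, target scaling, and the packaged reference tables."""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

PROFILE_SOURCES = ("observed", "interpolated", "predicted", "simulated")


@dataclass
class PlasmaProfile:
    """A concentration-time series (minutes, ng/mL).

    Times are strictly increasing and start at 0.  Concentrations may be
    negative for ``predicted`` profiles (model outputs are reported as-is,
    never clipped).
    """

    formulation_id: str
    times: np.ndarray
    concentrations: np.ndarray
    source: str = "observed"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape or self.times.ndim != 1:
            raise ValueError("times and concentrations must be equal-length 1-D arrays")
        if self.times.size == 0:
            raise ValueError("empty profile")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        # full-profile invariants apply to measured/simulated series;
        # interpolated/predicted slices may cover any query window
        if self.source in ("observed", "simulated"):
            if self.times.size < 2:
                raise ValueError("a profile needs at least two points")
            if self.times[0] != 0:
                raise ValueError("profile must start at t = 0")
        if self.source not in PROFILE_SOURCES:
            raise ValueError(f"source must be one of {PROFILE_SOURCES}")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.times, "conc": self.concentrations})

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, formulation_id: str = "",
                 source: str = "observed") -> "PlasmaProfile":
        df = pd.read_csv(path, comment="#")
        return cls(formulation_id=formulation_id,
                   times=df.iloc[:, 0].to_numpy(),
                   concentrations=df.iloc[:, 1].to_numpy(), source=source)


def cubic_spline(profile: PlasmaProfile) -> CubicSpline:
    """Natural cubic spline through the profile's knots."""
    return CubicSpline(profile.times, profile.concentrations, bc_type="natural")


def cubic_spline_interpolate(profile: PlasmaProfile,
                             query_times: Sequence[float]) -> PlasmaProfile:
    """Interpolate onto ``query_times`` with a natural cubic spline.

    Queries must lie within the observed span — no extrapolation.  Exact at
    the knots; C2-continuous in between (overshoot is possible and allowed).
    """
    q = np.asarray(query_times, dtype=float)
    lo, hi = profile.span
    if np.any(q < lo) or np.any(q > hi):
        raise ValueError(f"query times must lie within [{lo}, {hi}] min")
    values = cubic_spline(profile)(q)
    return PlasmaProfile(formulation_id=profile.formulation_id, times=q,
                         concentrations=values, source="interpolated")


# ---------------------------------------------------------------------------
# target scaling


@dataclass(frozen=True)
class ScaledTarget:
    """A dimensionless training target: concentration / scale_constant."""

    value: float
    scale_constant: float

    def __post_init__(self) -> None:
        if not self.scale_constant > 0:
            raise ValueError("scale_constant must be > 0")

    @property
    def concentration(self) -> float:
        return self.value * self.scale_constant


def scale_targets(profiles: Sequence[PlasmaProfile],
                  ) -> tuple[list[list[ScaledTarget]], float]:
    """Scale concentrations by the global maximum across training profiles.

    Returns one list of :class:`ScaledTarget` per profile plus the shared
    scale constant; every scaled value lies in (-inf, 1] with the global
    maximum mapping to exactly 1.  The inverse transform is
    ``value * scale_constant``.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    scale = max(float(p.concentrations.max()) for p in profiles)
    if scale <= 0:
        raise ValueError("scaling requires at least one positive concentration")
    return [[ScaledTarget(float(c) / scale, scale) for c in p.concentrations]
            for p in profiles], scale


# ---------------------------------------------------------------------------
# packaged reference tables


def _read_packaged(name: str) -> pd.DataFrame:
    text = resources.files("ivivr.data").joinpath(name).read_text()
    return pd.read_csv(io.StringIO(text), comment="#")


def load_fixture_profiles() -> dict[str, pd.DataFrame]:
    """The packaged reference tables, verbatim.

    ``extrapolation``: 12 rows of (time_min, formulation, predicted,
    observed) for the six held-out tail timepoints of each formulation.
    ``validation``: 11 rows of observed/predicted pairs for the IR 500 mg
    (training) and IR 850 mg (validation) tablets.
    """
    return {
        "extrapolation": _read_packaged("extrapolation_reference.csv"),
        "validation": _read_packaged("validation_reference.csv"),
    }


def fixture_profile(formulation_id: str, kind: str = "observed") -> PlasmaProfile:
    """One head-to-head series from the validation table as a profile.

    ``formulation_id`` is "IR500" or "IR850"; ``kind`` "observed" or
    "predicted"."""
    df = load_fixture_profiles()["validation"]
    col = f"{formulation_id.lower()}_{kind}"
    if col not in df.columns:
        raise KeyError(f"no packaged series {col!r}")
    return PlasmaProfile(formulation_id=formulation_id,
                         times=df["time_min"].to_numpy(),
                         concentrations=df[col].to_numpy(), source=kind)
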