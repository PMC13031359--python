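"""FRET quantification from three-channel flow cytometry and acceptor photobleaching.

The sensitized-emission route works on per-sample channel summaries measured in
three channels of a flow cytometer:

* ``I1`` — donor channel (445 nm excitation, 470 nm emission),
* ``I2`` — FRET channel (445 nm excitation, 520 nm emission),
* ``I3`` — acceptor channel (488 nm excitation, 520 nm emission).

After background subtraction, the FRET efficiency of a 1:1 donor–acceptor
fusion is

    E = (I2 - S2*I3 - S1*I1) / (I2 - S2*I3 + (alpha - S1)*I1) * 100%

where ``S1 = I2/I1`` of a donor-only sample corrects donor bleed-through into
the FRET channel, ``S2 = I2/I3`` of an acceptor-only sample corrects direct
acceptor excitation, and ``alpha`` relates the brightness of an acceptor
molecule in the FRET channel to that of a donor molecule in the donor channel.
``alpha`` is calibrated from one-to-one fusion samples of varying efficiency by
an ordinary least-squares line of y = 1/(R_F - 1) against x = 1/R_1, whose
slope/intercept ratio equals alpha.

The acceptor-photobleaching route compares donor fluorescence before and after
destroying the acceptor: E = (F_AB - F_BB)/F_AB * 100%, with both levels read
off straight-line fits of the pre- and post-bleach time series extrapolated to
the bleach instant, which corrects for donor photobleaching during acquisition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import CalibrationError, DegenerateSignalError

#: Calibration factor for the mTurquoise2-mNeonGreen pair used as a fallback
#: when no calibration sample set is available.
DEFAULT_ALPHA = 0.739

#: Relative tolerance below which a denominator/intercept counts as zero.
ZERO_TOL = 1e-12

_CHANNELS = ("m1", "m2", "m3")


@dataclass(frozen=True)
class EventTable:
    """Per-cell intensities of one cytometry sample in the three FRET channels."""

    sample_id: str
    events: np.ndarray  # shape (n_events, 3): columns I1, I2, I3
    channel_meta: tuple[str, str, str] = (
        "I1 donor 445ex/470em",
        "I2 FRET 445ex/520em",
        "I3 acceptor 488ex/520em",
    )

    def __post_init__(self) -> None:
        ev = np.asarray(self.events, dtype=float)
        if ev.ndim != 2 or ev.shape[1] != 3:
            raise ValueError("events must be an (n, 3) array of I1, I2, I3")
        if ev.shape[0] < 1:
            raise ValueError("event table is empty")
        if not np.all(np.isfinite(ev)):
            raise ValueError("event intensities must be finite")
        object.__setattr__(self, "events", ev)

    @property
    def n_events(self) -> int:
        return self.events.shape[0]


@dataclass(frozen=True)
class ChannelSummary:
    """Per-channel summary intensities (median by default) of one sample."""

    sample_id: str
    m1: float
    m2: float
    m3: float
    n_events: int
    background_subtracted: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.m1, self.m2, self.m3])


@dataclass(frozen=True)
class BleedthroughFactors:
    """Spectral bleed-through corrections.

    ``S1``: donor emission leaking into the FRET channel (I2/I1, donor-only).
    ``S2``: directly excited acceptor signal in the FRET channel (I2/I3,
    acceptor-only).
    """

    S1: float
    S2: float

    def __post_init__(self) -> None:
        if not (self.S1 > 0 and self.S2 > 0):
            raise ValueError("bleed-through factors must be positive")


@dataclass(frozen=True)
class SpectralCalibration:
    """Bleed-through factors plus the alpha calibration line diagnostics."""

    factors: BleedthroughFactors
    alpha: float
    slope: float
    intercept: float
    n_samples: int
    r_squared: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    @classmethod
    def from_constants(
        cls, s1: float, s2: float, alpha: float = DEFAULT_ALPHA
    ) -> "SpectralCalibration":
        """Calibration with a fixed alpha (no fit performed)."""
        return cls(
            factors=BleedthroughFactors(S1=s1, S2=s2),
            alpha=alpha,
            slope=alpha,
            intercept=1.0,
            n_samples=0,
            r_squared=float("nan"),
        )


@dataclass(frozen=True)
class FretEfficiency:
    """FRET efficiency of one sample, in percent.

    ``F_sen`` is the sensitized emission, the fully corrected acceptor signal
    attributable to energy transfer.  Negative efficiencies (possible for
    negative controls and noise around zero) are reported unclamped and
    carry the ``negative_E`` flag.
    """

    sample_id: str
    E: float
    F_sen: float
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.E > 100.0:
            raise ValueError("FRET efficiency cannot exceed 100%")
        if self.E < 0 and "negative_E" not in self.flags:
            raise ValueError("negative efficiency must carry the negative_E flag")


@dataclass(frozen=True)
class BleachSeries:
    """Background-corrected donor fluorescence time series around a bleach event."""

    time: np.ndarray
    donor_fluorescence: np.ndarray
    phase: str  # "pre" or "post"
    bleach_time: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.donor_fluorescence, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("time and fluorescence must be matching 1-D sequences")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.phase not in ("pre", "post"):
            raise ValueError("phase must be 'pre' or 'post'")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "donor_fluorescence", f)


def summarize_events(events: EventTable, statistic: str = "median") -> ChannelSummary:
    """Collapse an event table to per-channel summary intensities.

    The median is the default and the recommended statistic; the mean is
    offered for diagnostics only.
    """
    if statistic == "median":
        m = np.median(events.events, axis=0)
    elif statistic == "mean":
        m = np.mean(events.events, axis=0)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return ChannelSummary(
        sample_id=events.sample_id,
        m1=float(m[0]),
        m2=float(m[1]),
        m3=float(m[2]),
        n_events=events.n_events,
        background_subtracted=False,
    )


def subtract_background(
    sample: ChannelSummary,
    background: ChannelSummary,
    require_positive: tuple[str, ...] = _CHANNELS,
) -> ChannelSummary:
    """Subtract autofluorescence background medians channel by channel.

    The background summary comes from an empty-vector (no biosensor) sample.
    A non-positive corrected median in a channel listed in ``require_positive``
    raises :class:`DegenerateSignalError` — the biosensor signal is supposed to
    dominate the background by far.  Samples that legitimately lack signal in
    one channel (donor-only lacks I3, acceptor-only lacks I1) should restrict
    ``require_positive`` to the channels they actually use.
    """
    corrected = sample.as_array() - background.as_array()
    for name, value in zip(_CHANNELS, corrected):
        if name in require_positive and value <= 0:
            raise DegenerateSignalError(
                f"corrected median {name} = {value:g} is not positive for "
                f"sample {sample.sample_id!r}"
            )
    return replace(
        sample,
        m1=float(corrected[0]),
        m2=float(corrected[1]),
        m3=float(corrected[2]),
        background_subtracted=True,
    )


def estimate_bleedthrough(
    donor_only: ChannelSummary, acceptor_only: ChannelSummary
) -> BleedthroughFactors:
    """S1 = I2/I1 of a donor-only sample; S2 = I2/I3 of an acceptor-only sample."""
    for s in (donor_only, acceptor_only):
        if not s.background_subtracted:
            raise ValueError(f"summary {s.sample_id!r} is not background-subtracted")
    if donor_only.m1 <= 0:
        raise DegenerateSignalError("donor-only sample has non-positive donor signal")
    if acceptor_only.m3 <= 0:
        raise DegenerateSignalError(
            "acceptor-only sample has non-positive acceptor signal"
        )
    return BleedthroughFactors(
        S1=donor_only.m2 / donor_only.m1, S2=acceptor_only.m2 / acceptor_only.m3
    )


def calibrate_alpha(
    samples: list[ChannelSummary], factors: BleedthroughFactors
) -> SpectralCalibration:
    """Fit the alpha calibration factor from one-to-one donor:acceptor samples.

    For each background-subtracted sample the two intermediate ratios are

        R_1 = (m2 - S2*m3 - S1*m1) / m1      (sensitized emission per donor)
        R_F = (m2 - S1*m1) / (S2*m3)         (acceptor enhancement factor)

    Samples with R_1 <= 0 or R_F <= 1 carry no usable sensitized emission and
    are dropped with a warning.  An unweighted ordinary least-squares line
    through (1/R_1, 1/(R_F - 1)) then gives alpha = slope/intercept.
    """
    s1, s2 = factors.S1, factors.S2
    xs, ys = [], []
    for s in samples:
        if not s.background_subtracted:
            raise ValueError(f"summary {s.sample_id!r} is not background-subtracted")
        if s.m1 <= 0 or s.m3 <= 0:
            warnings.warn(
                f"sample {s.sample_id!r} lacks donor or acceptor signal; skipped",
                stacklevel=2,
            )
            continue
        r1 = (s.m2 - s2 * s.m3 - s1 * s.m1) / s.m1
        rf = (s.m2 - s1 * s.m1) / (s2 * s.m3)
        if r1 <= 0 or rf <= 1:
            warnings.warn(
                f"sample {s.sample_id!r} has no usable sensitized emission "
                f"(R1={r1:.3g}, RF={rf:.3g}); excluded from alpha fit",
                stacklevel=2,
            )
            continue
        xs.append(1.0 / r1)
        ys.append(1.0 / (rf - 1.0))
    x = np.array(xs)
    y = np.array(ys)
    if len(x) < 2:
        raise CalibrationError(
            f"alpha calibration needs >= 2 usable samples, got {len(x)}"
        )
    if np.unique(x).size < 2:
        raise CalibrationError("all calibration samples have identical 1/R1")
    # OLS y = slope*x + intercept
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), res, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ np.array([slope, intercept])
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if abs(intercept) <= ZERO_TOL * max(abs(slope) * float(np.max(np.abs(x))), 1e-300):
        raise CalibrationError("calibration line intercept is ~0; alpha undefined")
    alpha = float(slope / intercept)
    if alpha <= 0:
        raise CalibrationError(f"calibration produced non-positive alpha ({alpha:g})")
    return SpectralCalibration(
        factors=factors,
        alpha=alpha,
        slope=float(slope),
        intercept=float(intercept),
        n_samples=len(x),
        r_squared=r_squared,
    )


def fret_efficiency(
    sample: ChannelSummary, calib: SpectralCalibration
) -> FretEfficiency:
    """Calibrated FRET efficiency (percent) from a background-subtracted summary."""
    if not sample.background_subtracted:
        raise ValueError(f"summary {sample.sample_id!r} is not background-subtracted")
    s1, s2 = calib.factors.S1, calib.factors.S2
    f_sen = sample.m2 - s2 * sample.m3 - s1 * sample.m1
    denom = f_sen + calib.alpha * sample.m1
    leading = max(abs(sample.m2), abs(s2 * sample.m3), abs(s1 * sample.m1))
    if denom <= ZERO_TOL * leading:
        raise DegenerateSignalError(
            f"Eq. denominator {denom:g} is not positive for {sample.sample_id!r}"
        )
    e = f_sen / denom * 100.0
    flags = frozenset({"negative_E"}) if f_sen < 0 else frozenset()
    return FretEfficiency(sample_id=sample.sample_id, E=float(e), F_sen=float(f_sen), flags=flags)


def fret_ratio(sample: ChannelSummary) -> float:
    """Raw FRET ratio m2/m1 (FRET channel over donor channel, donor excitation).

    A proxy for efficiency that needs no calibration but, unlike the corrected
    efficiency, shifts with expression level when background is present.
    """
    if sample.m1 <= 0:
        raise DegenerateSignalError(
            f"zero/negative donor signal for {sample.sample_id!r}"
        )
    return sample.m2 / sample.m1


def calibrate_from_event_tables(
    fusion: list[EventTable],
    donor_only: EventTable,
    acceptor_only: EventTable,
    background: EventTable,
    statistic: str = "median",
) -> SpectralCalibration:
    """Full spectral calibration from raw event tables.

    Summarizes every sample, subtracts the background sample's medians,
    estimates S1/S2 from the single-fluorophore controls and fits alpha on the
    one-to-one fusion samples.
    """
    bg = summarize_events(background, statistic)
    donor = subtract_background(
        summarize_events(donor_only, statistic), bg, require_positive=("m1", "m2")
    )
    acceptor = subtract_background(
        summarize_events(acceptor_only, statistic), bg, require_positive=("m2", "m3")
    )
    factors = estimate_bleedthrough(donor, acceptor)
    summaries = [
        subtract_background(summarize_events(t, statistic), bg) for t in fusion
    ]
    return calibrate_alpha(summaries, factors)


def efficiency_from_events(
    table: EventTable,
    background: EventTable | ChannelSummary,
    calib: SpectralCalibration,
    statistic: str = "median",
) -> tuple[ChannelSummary, float, FretEfficiency]:
    """Summarize one sample and return (summary, fret_ratio, efficiency)."""
    bg = (
        background
        if isinstance(background, ChannelSummary)
        else summarize_events(background, statistic)
    )
    summary = subtract_background(summarize_events(table, statistic), bg)
    return summary, fret_ratio(summary), fret_efficiency(summary, calib)


def _line_at(series: BleachSeries, t: float) -> float:
    if len(series.time) < 2:
        raise ValueError("bleach series needs >= 2 points for a linear fit")
    slope, intercept = np.polyfit(series.time, series.donor_fluorescence, 1)
    return float(slope * t + intercept)


def photobleach_efficiency(
    pre_series: BleachSeries, post_series: BleachSeries
) -> FretEfficiency:
    """FRET efficiency from donor dequenching after acceptor photobleaching.

    Both series are fit by straight lines against time (correcting for donor
    photobleaching during acquisition) and extrapolated to the bleach instant:
    F_BB from the pre-bleach fit, F_AB from the post-bleach fit, then
    E = (F_AB - F_BB)/F_AB * 100%.
    """
    if pre_series.phase != "pre" or post_series.phase != "post":
        raise ValueError("expected one 'pre' and one 'post' series, in that order")
    if pre_series.bleach_time != post_series.bleach_time:
        raise ValueError("pre and post series disagree on the bleach time")
    t_bleach = pre_series.bleach_time
    f_bb = _line_at(pre_series, t_bleach)
    f_ab = _line_at(post_series, t_bleach)
    if f_ab <= 0:
        raise DegenerateSignalError(f"non-positive post-bleach donor level ({f_ab:g})")
    e = (f_ab - f_bb) / f_ab * 100.0
    flags = frozenset({"negative_E"}) if f_ab <= f_bb else frozenset()
    return FretEfficiency(
        sample_id="photobleach", E=float(e), F_sen=float(f_ab - f_bb), flags=flags
    )
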