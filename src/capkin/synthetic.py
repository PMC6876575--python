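"""Ground-truth single-filament kinetics and synthetic imaging data.

This module emulates the three single-filament experiments that the rest of
the package analyzes:

* pointed-end depolymerization of surface-anchored filaments observed in a
  microfluidics chamber (rendered as kymographs / TIFF movies),
* two-state binding of a GFP-tagged depolymerase (CAP) to the filament
  pointed end, observed as a fluorescence stream acquisition at both
  filament ends,
* severing of a field of filaments, observed as an event log plus a
  per-frame length table.

Every simulation is event-driven (exact exponential waiting times from a
single seeded generator) and then sampled on the imaging frame grid, so the
ground truth is free of time-discretization bias and is bit-reproducible
for a given (parameters, seed) pair.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .kymo import Kymograph
from .severing import SeveringRecord

CONDITIONS = ("bare-ADP", "cofilin", "cofilin+NCAP")

#: filament length change per subunit gained/lost (standard actin geometry)
DEFAULT_SUBUNIT_RISE_NM = 2.7


@dataclass(frozen=True)
class KineticParams:
    """Ground-truth kinetic constants used by the generator and recovered by fits.

    Rates are pointed-end depolymerization rates in subunits/s:
    ``v_bare`` for bare ADP-actin, ``v_cof`` for cofilin-decorated filaments,
    and ``v_sat`` for cofilin-decorated filaments with saturating CAP.  The
    CAP concentration dependence is first-order saturation with dissociation
    constant ``Kd`` (µM).  Pointed-end binding of CAP is a two-state process
    with pseudo-first-order association rate ``kon_eff`` (kon·[CAP], 1/s) and
    unbinding rate ``koff`` (1/s).  ``lambda_sev`` is the severing rate per µm
    of filament per second, and ``subunit_rise`` converts subunits to nm.
    """

    v_bare: float = 0.13
    v_cof: float = 13.0 / 30.0
    v_sat: float = 13.0
    Kd: float = 0.978
    kon_eff: float = 0.512
    koff: float = 2.5
    lambda_sev: float = 0.005
    subunit_rise: float = DEFAULT_SUBUNIT_RISE_NM

    def __post_init__(self) -> None:
        for name in ("v_bare", "v_cof", "v_sat", "kon_eff", "koff", "lambda_sev"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.Kd <= 0:
            raise ValueError("Kd must be > 0")
        if not (self.v_sat >= self.v_cof >= self.v_bare):
            raise ValueError("expected v_sat >= v_cof >= v_bare")
        if self.subunit_rise <= 0:
            raise ValueError("subunit_rise must be > 0")

    def depol_rate(self, condition: str, cap_conc_uM: float | None = None) -> float:
        """Pointed-end depolymerization rate (subunits/s) for a condition.

        For ``cofilin+NCAP`` the rate follows the first-order saturation
        curve v(C) = v_cof + (v_sat - v_cof) * C / (Kd + C).
        """
        if condition == "bare-ADP":
            return self.v_bare
        if condition == "cofilin":
            return self.v_cof
        if condition == "cofilin+NCAP":
            if cap_conc_uM is None or cap_conc_uM < 0:
                raise ValueError("cofilin+NCAP requires cap_conc_uM >= 0")
            c = float(cap_conc_uM)
            return self.v_cof + (self.v_sat - self.v_cof) * c / (self.Kd + c)
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")


@dataclass(frozen=True)
class ImagingParams:
    """Forward imaging model parameters.

    ``pixel_size`` (nm), ``frame_interval`` (s), ``psf_sigma`` (nm),
    ``label_fraction`` (fraction of subunits carrying a fluorophore, in
    (0, 1]), Gaussian camera background (mean/SD in camera counts),
    ``signal_amplitude`` (counts per fluorophore, or per bound molecule for
    end-binding traces) and number of frames.
    """

    pixel_size: float = 100.0
    frame_interval: float = 1.0
    psf_sigma: float = 130.0
    label_fraction: float = 0.1
    background_mean: float = 100.0
    background_sd: float = 5.0
    signal_amplitude: float = 50.0
    n_frames: int = 100

    def __post_init__(self) -> None:
        if min(self.pixel_size, self.frame_interval, self.psf_sigma) <= 0:
            raise ValueError("pixel_size, frame_interval, psf_sigma must be > 0")
        if not (0.0 < self.label_fraction <= 1.0):
            raise ValueError("label_fraction must be in (0, 1]")
        if self.background_sd < 0 or self.n_frames < 1:
            raise ValueError("background_sd >= 0 and n_frames >= 1 required")


#: stream-acquisition imaging defaults (5 frames/second over 12 s)
STREAM_IMAGING = ImagingParams(frame_interval=0.2, n_frames=60)


@dataclass
class FilamentTruth:
    """Per-frame ground truth for one simulated filament.

    ``end_position`` is the pointed-end coordinate in nm with the (capped)
    barbed end anchored at 0, so it decreases by ``subunit_rise`` per lost
    subunit and equals the filament ``length``.  ``event_times`` holds the
    exact (continuous-time) subunit-loss times.
    """

    times: np.ndarray
    end_position: np.ndarray
    length: np.ndarray
    bound_state: np.ndarray | None
    sever_events: list[tuple[float, float]]
    event_times: np.ndarray
    condition: str
    rate_true: float
    params: KineticParams
    seed: int

    def to_frame(self) -> pd.DataFrame:
        d = {
            "time_s": self.times,
            "end_position_nm": self.end_position,
            "length_nm": self.length,
        }
        if self.bound_state is not None:
            d["bound"] = self.bound_state.astype(int)
        return pd.DataFrame(d)


def _poisson_event_times(rate: float, duration: float, rng: np.random.Generator) -> np.ndarray:
    """Exact homogeneous Poisson event times on [0, duration)."""
    if rate <= 0:
        return np.empty(0)
    # draw in blocks of exponential gaps until the horizon is passed
    times: list[np.ndarray] = []
    t = 0.0
    block = max(16, int(rate * duration * 1.2) + 1)
    while t < duration:
        gaps = rng.exponential(1.0 / rate, size=block)
        cum = t + np.cumsum(gaps)
        times.append(cum)
        t = cum[-1]
    all_t = np.concatenate(times)
    return all_t[all_t < duration]


def simulate_depolymerizing_filament(
    params: KineticParams,
    condition: str,
    duration: float,
    seed: int,
    *,
    cap_conc_uM: float | None = None,
    frame_interval: float = 1.0,
    initial_length_nm: float | None = None,
) -> FilamentTruth:
    """Simulate pointed-end depolymerization as a Poisson subunit-loss process.

    Subunit-loss events are drawn with exact exponential waiting times at the
    condition rate; the pointed-end coordinate decreases by ``subunit_rise``
    per event and the truth is sampled every ``frame_interval`` seconds
    (frame 0 at t = 0).  Identical (params, seed) give identical output.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rate = params.depol_rate(condition, cap_conc_uM)
    rng = np.random.default_rng(seed)
    events = _poisson_event_times(rate, duration, rng)

    n_frames = int(np.floor(duration / frame_interval)) + 1
    times = np.arange(n_frames) * frame_interval
    lost = np.searchsorted(events, times, side="right")

    if initial_length_nm is None:
        initial_length_nm = rate * duration * params.subunit_rise * 1.3 + 2000.0
    end = np.maximum(initial_length_nm - lost * params.subunit_rise, 0.0)
    return FilamentTruth(
        times=times,
        end_position=end,
        length=end.copy(),
        bound_state=None,
        sever_events=[],
        event_times=events,
        condition=condition,
        rate_true=rate,
        params=params,
        seed=seed,
    )


@dataclass
class BindingSim:
    """Simulated two-end fluorescence stream acquisition.

    The pointed end carries the two-state binding signal; the barbed end is
    capped and shows background only.  Which physical trace (A or B) is the
    pointed end is randomized per filament and recorded in ``pointed_end``.
    ``bound`` is the exact state at each frame time; ``switch_times`` are the
    continuous-time state-change instants (starting from unbound at t = 0).
    """

    times: np.ndarray
    bound: np.ndarray
    intensity_endA: np.ndarray
    intensity_endB: np.ndarray
    pointed_end: str
    switch_times: np.ndarray
    params: KineticParams
    imaging: ImagingParams
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "intensityA": self.intensity_endA,
                "intensityB": self.intensity_endB,
                "bound_true": self.bound.astype(int),
            }
        )


def simulate_binding_trace(
    params: KineticParams, imaging: ImagingParams = STREAM_IMAGING, seed: int = 0
) -> BindingSim:
    """Simulate CAP binding at the pointed end as a two-state Markov chain.

    The unbound<->bound chain is simulated with exact exponential waiting
    times (rates ``kon_eff`` and ``koff``) and sampled at the frame interval.
    Equilibrium occupancy is kon_eff / (kon_eff + koff).
    """
    if params.kon_eff <= 0 and params.koff <= 0:
        raise ValueError("kon_eff and koff cannot both be zero")
    if params.kon_eff < 0 or params.koff < 0:
        raise ValueError("binding rates must be >= 0")
    rng = np.random.default_rng(seed)
    horizon = imaging.n_frames * imaging.frame_interval

    # the chamber equilibrates before the stream acquisition starts, so the
    # initial state is drawn from the stationary distribution
    occ = params.kon_eff / (params.kon_eff + params.koff) if params.koff > 0 else 1.0
    state0 = int(rng.random() < occ)
    switches: list[float] = []
    t, state = 0.0, state0
    while t < horizon:
        rate = params.kon_eff if state == 0 else params.koff
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        if t < horizon:
            switches.append(t)
        state ^= 1
    switch_times = np.asarray(switches)

    times = np.arange(imaging.n_frames) * imaging.frame_interval
    # state at time t = initial state flipped once per preceding switch
    n_sw = np.searchsorted(switch_times, times, side="right")
    bound = ((n_sw + state0) % 2).astype(bool)

    sig = imaging.background_mean + bound * imaging.signal_amplitude
    noise = rng.normal(0.0, imaging.background_sd, size=(2, imaging.n_frames))
    pointed_first = bool(rng.integers(2))
    pointed_trace = sig + noise[0]
    barbed_trace = imaging.background_mean + noise[1]
    if pointed_first:
        int_a, int_b, pointed = pointed_trace, barbed_trace, "A"
    else:
        int_a, int_b, pointed = barbed_trace, pointed_trace, "B"
    return BindingSim(
        times=times,
        bound=bound,
        intensity_endA=int_a,
        intensity_endB=int_b,
        pointed_end=pointed,
        switch_times=switch_times,
        params=params,
        imaging=imaging,
        seed=seed,
    )


def simulate_severing_field(
    filament_lengths_um: Sequence[float],
    lambda_sev: float,
    depol_rate: float,
    duration: float,
    seed: int,
    *,
    frame_interval: float = 1.0,
    subunit_rise_nm: float = DEFAULT_SUBUNIT_RISE_NM,
) -> SeveringRecord:
    """Simulate severing of a field of shrinking filaments.

    Per frame, each filament severs with probability lambda_sev*length*dt at
    a uniform position; both fragments remain in the field.  Lengths shrink
    deterministically at the depolymerization speed.  Returns the event log
    and the per-frame length table that the cumulative events/µm statistic
    consumes.
    """
    if lambda_sev < 0:
        raise ValueError("lambda_sev must be >= 0")
    lengths = np.asarray(filament_lengths_um, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("filament lengths must be > 0")
    rng = np.random.default_rng(seed)
    shrink_per_frame = depol_rate * subunit_rise_nm * frame_interval / 1000.0  # µm

    live: dict[int, float] = {i: float(l) for i, l in enumerate(lengths)}
    next_id = len(live)
    events = []
    length_rows = []
    n_frames = int(np.floor(duration / frame_interval)) + 1
    for k in range(n_frames):
        t = k * frame_interval
        for fid in sorted(live):
            length_rows.append((t, fid, live[fid]))
        if k == n_frames - 1:
            break
        # severing decisions for this frame interval
        for fid in sorted(live):
            l = live[fid]
            p = min(lambda_sev * l * frame_interval, 1.0)
            if rng.random() < p:
                pos = rng.uniform(0.0, l)
                events.append((t + frame_interval, fid, pos))
                live[fid] = pos
                live[next_id] = l - pos
                next_id += 1
        # depolymerization shrink
        for fid in list(live):
            live[fid] = live[fid] - shrink_per_frame
            if live[fid] <= 0:
                del live[fid]

    events_df = pd.DataFrame(events, columns=["time_s", "filament_id", "position_um"])
    lengths_df = pd.DataFrame(length_rows, columns=["time_s", "filament_id", "length_um"])
    return SeveringRecord(events=events_df, lengths=lengths_df)


# ---------------------------------------------------------------------------
# Forward imaging model


def _labeled_subunits(n_subunits: int, label_fraction: float, rng: np.random.Generator) -> np.ndarray:
    return np.flatnonzero(rng.random(n_subunits) < label_fraction)


def _profile_rows(
    truth: FilamentTruth, imaging: ImagingParams, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Noise-free fluorophore count per pixel for each frame (before PSF blur)."""
    from scipy.ndimage import gaussian_filter1d

    rise = truth.params.subunit_rise
    n0 = int(np.round(truth.end_position[0] / rise))
    labeled = _labeled_subunits(n0, imaging.label_fraction, rng)
    # subunit i sits at (i + 0.5) * rise from the anchored barbed end
    pos_nm = (labeled + 0.5) * rise
    margin = 4.0 * imaging.psf_sigma + 5.0 * imaging.pixel_size
    n_px = int(np.ceil((truth.end_position[0] + margin) / imaging.pixel_size))
    px_idx = np.minimum((pos_nm / imaging.pixel_size).astype(int), n_px - 1)

    n_frames = len(truth.times)
    rows = np.zeros((n_frames, n_px))
    sigma_px = imaging.psf_sigma / imaging.pixel_size
    for k in range(n_frames):
        n_rem = int(np.round(truth.end_position[k] / rise))
        m = np.searchsorted(labeled, n_rem)
        counts = np.bincount(px_idx[:m], minlength=n_px).astype(float)
        rows[k] = gaussian_filter1d(
            counts * imaging.signal_amplitude, sigma_px, mode="constant"
        )
    return rows, n_px


def render_kymograph(truth: FilamentTruth, imaging: ImagingParams, seed: int) -> Kymograph:
    """Render ground truth as a kymograph (rows = frames, columns = position).

    Labeled subunits are drawn once (fraction ``label_fraction``), convolved
    with a Gaussian PSF, and Gaussian camera background is added per pixel.
    """
    if len(truth.times) < 1:
        raise ValueError("truth covers no frames")
    rng = np.random.default_rng(seed)
    rows, n_px = _profile_rows(truth, imaging, rng)
    noise = rng.normal(imaging.background_mean, imaging.background_sd, size=rows.shape)
    dt = float(truth.times[1] - truth.times[0]) if len(truth.times) > 1 else imaging.frame_interval
    return Kymograph(intensity=rows + noise, pixel_size=imaging.pixel_size, frame_interval=dt)


def render_movie(
    truth: FilamentTruth,
    imaging: ImagingParams,
    seed: int,
    *,
    height_px: int = 11,
) -> np.ndarray:
    """Render a TIFF-ready movie (frames, height, width) of a straight filament.

    The filament lies along the central row (microfluidics-aligned geometry);
    the PSF is applied in both axes.
    """
    rng = np.random.default_rng(seed)
    rows, n_px = _profile_rows(truth, imaging, rng)
    sigma_px = imaging.psf_sigma / imaging.pixel_size
    y = np.arange(height_px) - (height_px - 1) / 2.0
    psf_y = np.exp(-0.5 * (y / sigma_px) ** 2)
    psf_y /= psf_y.max()  # central row keeps the 1-D profile scale
    movie = psf_y[None, :, None] * rows[:, None, :]
    movie += rng.normal(imaging.background_mean, imaging.background_sd, size=movie.shape)
    return movie


def write_movie(
    path: str | Path,
    movie: np.ndarray,
    imaging: ImagingParams,
    seed: int,
    params: KineticParams | None = None,
) -> None:
    """Write a multi-page TIFF plus a JSON sidecar with imaging metadata."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, movie.astype(np.float32))
    meta = {
        "pixel_size_nm": imaging.pixel_size,
        "frame_interval_s": imaging.frame_interval,
        "seed": seed,
        "imaging": dataclasses.asdict(imaging),
    }
    if params is not None:
        meta["params"] = dataclasses.asdict(params)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def write_truth(path: str | Path, truth: FilamentTruth) -> None:
    """Write per-frame ground truth as CSV and events/params as JSON."""
    path = Path(path)
    truth.to_frame().to_csv(path.with_suffix(".csv"), index=False)
    meta = {
        "condition": truth.condition,
        "rate_true_subunits_s": truth.rate_true,
        "seed": truth.seed,
        "params": dataclasses.asdict(truth.params),
        "event_times_s": truth.event_times.tolist(),
        "sever_events": truth.sever_events,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
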