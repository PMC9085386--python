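"""Locomotion speed-trace analysis and a synthetic trace generator.

Freely moving worms alternate between a long-lived forward state and brief
backward excursions (plus a small pause component).  The signed centroid
speed (um/s, positive = forward) is segmented by sign, summarized per event,
and its distribution fitted by a two-component Gaussian whose centers are the
forward and backward speed modes.

The generator emulates exactly that structure: a semi-Markov state sequence
with exponential dwell times tuned to target occupancy fractions, and
per-frame Gaussian speed noise around each state's mean.  It stands in for
recorded traces in tests; it reproduces the stationary statistics
(occupancies, speed distributions, mean dwell times) but none of the
kinematic structure of real crawling (no speed autocorrelation within a
state, no smooth reversals, no turning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "SpeedTrace",
    "LocomotionEvents",
    "BimodalFitResult",
    "SyntheticBehaviorConfig",
    "synthesize_speed_trace",
    "segment_locomotion",
    "fit_speed_distribution",
    "locomotion_summary",
]

# Reported two-component fit of the local-search speed distribution and the
# forward/backward time split used as generator defaults.
FORWARD_MU = 259.8
FORWARD_SIGMA = 77.79164
BACKWARD_MU = -308.03
BACKWARD_SIGMA = 62.79239
FORWARD_OCCUPANCY = 0.9336
BACKWARD_OCCUPANCY = 0.0664


@dataclass
class SpeedTrace:
    """Uniformly sampled signed centroid speed (um/s; positive = forward)."""

    times: np.ndarray
    speeds: np.ndarray
    frame_rate: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.speeds = np.asarray(self.speeds, dtype=float)
        if self.times.shape != self.speeds.shape or self.times.ndim != 1:
            raise InvalidInputError("times and speeds must be 1-D and equally long")
        if not np.all(np.isfinite(self.speeds)):
            raise InvalidInputError("speeds must be finite")
        if self.frame_rate <= 0:
            raise InvalidParameterError("frame_rate must be > 0")

    def __len__(self):
        return self.speeds.size

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("time_s,speed_um_per_s\n")
            for t, v in zip(self.times, self.speeds):
                fh.write(f"{t:.6g},{v:.6g}\n")

    @classmethod
    def from_csv(cls, path) -> "SpeedTrace":
        data = np.genfromtxt(path, delimiter=",", names=True)
        t = np.atleast_1d(data["time_s"])
        dt = np.diff(t)
        if t.size > 1 and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise InvalidInputError("trace is not uniformly sampled")
        rate = 1.0 / dt[0] if t.size > 1 else 1.0
        return cls(times=t, speeds=np.atleast_1d(data["speed_um_per_s"]), frame_rate=rate)


@dataclass
class Segment:
    state: str  # "forward" | "backward" | "pause"
    start: int  # frame index, inclusive
    stop: int  # frame index, exclusive
    duration: float  # seconds
    mean_speed: float  # um/s (signed)


@dataclass
class LocomotionEvents:
    """Maximal same-state runs tiling a trace without overlap."""

    segments: list[Segment]
    frame_rate: float

    def __len__(self):
        return len(self.segments)

    def by_state(self, state: str) -> list[Segment]:
        return [s for s in self.segments if s.state == state]

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)


@dataclass
class SyntheticBehaviorConfig:
    """Generator settings: per-state speed statistics, dwell times, occupancy.

    Occupancy fractions must sum to 1; dwell means are in seconds.  When
    ``occupancy`` is given, the embedded switching chain is chosen so the
    stationary time fractions match it (for two states this reduces to strict
    alternation with dwell means in the occupancy ratio).
    """

    states: tuple[str, ...] = ("forward", "backward")
    speed_mean: dict[str, float] = field(
        default_factory=lambda: {"forward": FORWARD_MU, "backward": BACKWARD_MU}
    )
    speed_sd: dict[str, float] = field(
        default_factory=lambda: {"forward": FORWARD_SIGMA, "backward": BACKWARD_SIGMA}
    )
    dwell_mean: dict[str, float] = field(
        default_factory=lambda: {
            "forward": 2.0 * FORWARD_OCCUPANCY / BACKWARD_OCCUPANCY,
            "backward": 2.0,
        }
    )
    occupancy: dict[str, float] | None = field(
        default_factory=lambda: {
            "forward": FORWARD_OCCUPANCY,
            "backward": BACKWARD_OCCUPANCY,
        }
    )
    frame_rate: float = 10.0
    n_frames: int = 100_000
    seed: int = 0

    def __post_init__(self):
        self.states = tuple(self.states)
        if len(self.states) < 1:
            raise InvalidParameterError("need at least one state")
        for s in self.states:
            if s not in self.speed_mean or s not in self.speed_sd:
                raise InvalidParameterError(f"state {s!r} lacks speed statistics")
            if self.dwell_mean.get(s, 0.0) <= 0.0:
                raise InvalidParameterError(f"state {s!r} needs a positive dwell time")
        if self.occupancy is not None and len(self.states) > 1:
            total = sum(self.occupancy[s] for s in self.states)
            if abs(total - 1.0) > 1e-9:
                raise InvalidParameterError("occupancy fractions must sum to 1")
            if any(self.occupancy[s] <= 0 for s in self.states):
                raise InvalidParameterError("occupancy fractions must be positive")


def synthesize_speed_trace(config: SyntheticBehaviorConfig) -> SpeedTrace:
    """Draw a semi-Markov speed trace; reproducible for a given seed.

    Dwell times are exponential.  With a target occupancy, the probability of
    switching into state ``j`` is proportional to ``occupancy_j / dwell_j``,
    which makes the stationary time fraction of ``j`` proportional to its
    occupancy (exact for two states, where the chain strictly alternates).
    """
    rng = np.random.default_rng(config.seed)
    states = config.states
    n = config.n_frames
    dt = 1.0 / config.frame_rate

    if len(states) == 1:
        labels = np.zeros(n, dtype=int)
    else:
        if config.occupancy is not None:
            rates = np.array(
                [config.occupancy[s] / config.dwell_mean[s] for s in states]
            )
        else:
            rates = np.array([1.0 / config.dwell_mean[s] for s in states])
        labels = np.empty(n, dtype=int)
        pos = 0
        current = int(np.argmax(rates))  # start in the dominant state
        while pos < n:
            dwell = rng.exponential(config.dwell_mean[states[current]])
            frames = max(1, int(round(dwell / dt)))
            labels[pos : pos + frames] = current
            pos += frames
            probs = rates.copy()
            probs[current] = 0.0
            probs /= probs.sum()
            current = int(rng.choice(len(states), p=probs))

    means = np.array([config.speed_mean[s] for s in states])
    sds = np.array([config.speed_sd[s] for s in states])
    speeds = means[labels] + sds[labels] * rng.standard_normal(n)
    times = np.arange(n) * dt
    return SpeedTrace(times=times, speeds=speeds, frame_rate=config.frame_rate)


def segment_locomotion(trace: SpeedTrace, dead_band: float = 0.0) -> LocomotionEvents:
    """Classify frames by speed sign and merge runs into events.

    forward: speed > dead_band; backward: speed < -dead_band; pause otherwise.
    A dead band of 0 reproduces pure sign classification (the pause mass of a
    real distribution is then split between the two moving states).
    """
    if dead_band < 0:
        raise InvalidParameterError("dead_band must be >= 0")
    if len(trace) == 0:
        raise InvalidInputError("empty trace")
    v = trace.speeds
    cls = np.where(v > dead_band, 0, np.where(v < -dead_band, 1, 2))
    names = ("forward", "backward", "pause")
    boundaries = np.flatnonzero(np.diff(cls)) + 1
    starts = np.concatenate([[0], boundaries])
    stops = np.concatenate([boundaries, [v.size]])
    segments = [
        Segment(
            state=names[cls[a]],
            start=int(a),
            stop=int(b),
            duration=(b - a) / trace.frame_rate,
            mean_speed=float(v[a:b].mean()),
        )
        for a, b in zip(starts, stops)
    ]
    return LocomotionEvents(segments=segments, frame_rate=trace.frame_rate)


@dataclass
class BimodalFitResult:
    """Two-component Gaussian description of a signed speed distribution."""

    mu_forward: float
    sigma_forward: float
    mu_backward: float
    sigma_backward: float
    weight_forward: float
    weight_backward: float
    log_likelihood: float
    method: str
    n_components: int = 2


def _gauss_loglik(x, mu, sd):
    return float(
        np.sum(-0.5 * ((x - mu) / sd) ** 2 - np.log(sd * np.sqrt(2.0 * np.pi)))
    )


def fit_speed_distribution(
    speeds,
    init: tuple[float, float] | None = None,
    method: str = "sign-split",
) -> BimodalFitResult:
    """Fit forward/backward Gaussian components to a signed speed sample.

    Default "sign-split" anchors the components to the positive and negative
    samples and fits each Gaussian by maximum likelihood independently
    (matching the convention of reporting separate forward/backward
    parameters).  method="em" runs a 2-component mixture EM instead
    (scikit-learn), initialized at ``init`` or at the sign-split means.
    One-signed samples fall back to a single-Gaussian fit with a warning.
    """
    speeds = np.asarray(speeds, dtype=float)
    if speeds.size < 100:
        raise InvalidInputError("need at least 100 samples")
    pos = speeds[speeds > 0]
    neg = speeds[speeds < 0]
    if pos.size == 0 or neg.size == 0:
        warnings.warn(
            "speed sample is one-signed; falling back to a single-Gaussian fit",
            stacklevel=2,
        )
        mu, sd = float(speeds.mean()), float(speeds.std(ddof=0))
        ll = _gauss_loglik(speeds, mu, sd)
        fwd = mu > 0
        return BimodalFitResult(
            mu_forward=mu if fwd else np.nan,
            sigma_forward=sd if fwd else np.nan,
            mu_backward=mu if not fwd else np.nan,
            sigma_backward=sd if not fwd else np.nan,
            weight_forward=1.0 if fwd else 0.0,
            weight_backward=0.0 if fwd else 1.0,
            log_likelihood=ll,
            method="single",
            n_components=1,
        )
    if method == "sign-split":
        mu_f, sd_f = float(pos.mean()), float(pos.std(ddof=0))
        mu_b, sd_b = float(neg.mean()), float(neg.std(ddof=0))
        ll = _gauss_loglik(pos, mu_f, sd_f) + _gauss_loglik(neg, mu_b, sd_b)
        return BimodalFitResult(
            mu_forward=mu_f,
            sigma_forward=sd_f,
            mu_backward=mu_b,
            sigma_backward=sd_b,
            weight_forward=pos.size / speeds.size,
            weight_backward=neg.size / speeds.size,
            log_likelihood=ll,
            method="sign-split",
        )
    if method == "em":
        from sklearn.mixture import GaussianMixture

        if init is None:
            init = (float(pos.mean()), float(neg.mean()))
        gm = GaussianMixture(
            n_components=2,
            means_init=np.array(init, dtype=float).reshape(2, 1),
            random_state=0,
        )
        gm.fit(speeds.reshape(-1, 1))
        mus = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())
        ws = gm.weights_.ravel()
        order = np.argsort(-mus)  # forward (larger mean) first
        i_f, i_b = order[0], order[1]
        return BimodalFitResult(
            mu_forward=float(mus[i_f]),
            sigma_forward=float(sds[i_f]),
            mu_backward=float(mus[i_b]),
            sigma_backward=float(sds[i_b]),
            weight_forward=float(ws[i_f]),
            weight_backward=float(ws[i_b]),
            log_likelihood=float(gm.score(speeds.reshape(-1, 1)) * speeds.size),
            method="em",
        )
    raise InvalidParameterError(f"unknown fit method {method!r}")


def locomotion_summary(
    events: LocomotionEvents,
    duration_bin: float = 1.0,
    speed_bin: float = 44.0,
) -> dict:
    """Per-state time fractions, event counts, dwell and speed statistics.

    Histogram bin sizes are configurable (seconds for durations, um/s for
    event mean speeds).
    """
    if len(events) == 0:
        raise InvalidInputError("no events")
    total = events.total_duration
    out = {"total_duration_s": total, "states": {}}
    for state in ("forward", "backward", "pause"):
        segs = events.by_state(state)
        if not segs:
            continue
        durs = np.array([s.duration for s in segs])
        spd = np.array([s.mean_speed for s in segs])
        d_edges = np.arange(0.0, durs.max() + duration_bin, duration_bin)
        lo = np.floor(spd.min() / speed_bin) * speed_bin
        hi = np.ceil(spd.max() / speed_bin) * speed_bin + speed_bin
        s_edges = np.arange(lo, hi, speed_bin)
        out["states"][state] = {
            "time_fraction": float(durs.sum() / total),
            "event_count": len(segs),
            "mean_duration_s": float(durs.mean()),
            "median_duration_s": float(np.median(durs)),
            "mean_abs_speed": float(np.abs(spd).mean()),
            "duration_hist": {
                "bin_s": duration_bin,
                "edges": d_edges.tolist(),
                "counts": np.histogram(durs, bins=d_edges)[0].tolist(),
            },
            "speed_hist": {
                "bin_um_per_s": speed_bin,
                "edges": s_edges.tolist(),
                "counts": np.histogram(spd, bins=s_edges)[0].tolist(),
            },
        }
    return out
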