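"""Zero-crossing echolocation call streams.

A zero-crossing bat detector records one time-frequency point per N signal
cycles (division ratio N; here N = 8, so the sampling interval at frequency f
is 8/f).  A detector-night's data is a stream of such points partitioned into
calls; calls separated by more than a fixed silence gap (5 s by default) are
grouped into distinct *passes*, the unit in which bat activity is counted.

This module provides the stream container and plain-text interchange format,
pass segmentation, extraction of the 11 call-shape features used for quality
filtering and species classification, and the quality filter itself.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "DIVISION_RATIO",
    "FEATURE_NAMES",
    "Call",
    "CallFeatures",
    "DegenerateCallError",
    "Pass",
    "QualityThresholds",
    "ZCCallStream",
    "drop_empty_passes",
    "dumps_zc",
    "extract_features",
    "loads_zc",
    "nightly_counts",
    "quality_filter",
    "read_zc",
    "segment_passes",
    "write_zc",
]

DIVISION_RATIO = 8

#: Default silence gap separating passes (seconds).  A gap of exactly this
#: length still merges ("no more than" reads as <=).
DEFAULT_GAP_S = 5.0

# Time span (s) of the local linear regression window used for slope
# estimates; a fixed time span (rather than point count) keeps slope noise
# comparable across call frequencies, since the zero-crossing sampling
# interval is 8/f.  Bounds are in points.
_SLOPE_WINDOW_S = 1.2e-3
_SLOPE_WINDOW_MIN = 5
_SLOPE_WINDOW_MAX = 15

# Absolute floor (octaves/s) added to the 20%-relative body slope band, so
# that calls with a near-zero terminal slope retain a well-defined body.
_BODY_SLOPE_FLOOR = 2.0

# |d slope/dt| (octaves/s^2) above which a call is considered to have a knee;
# below it the knee frequency falls back to the characteristic frequency.
_KNEE_CURVATURE_MIN = 5.0e3

# Exponent grid for the smooth power-law sweep fit behind the Qual index.
_QUAL_EXPONENTS = np.geomspace(0.3, 5.0, 24)


class DegenerateCallError(ValueError):
    """Raised when a call has too few points for feature extraction."""


@dataclass
class CallFeatures:
    """The 11 shape descriptors of a single call.

    Frequencies in kHz, durations/times in ms, slopes in octaves per second.
    """

    fc_khz: float      # characteristic frequency: flattest point, final half
    fmax_khz: float
    fmin_khz: float
    fmean_khz: float   # time-weighted mean frequency
    dur_ms: float
    body_ms: float     # extent of the near-linear body around the fc point
    qual: float        # RMS relative deviation from a smooth sweep fit
    s1_okps: float     # initial slope
    sc_okps: float     # slope at the characteristic point
    tc_ms: float       # time from call start to the characteristic point
    fk_khz: float      # knee frequency (maximum-curvature point)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)


FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in fields(CallFeatures))


@dataclass
class Call:
    """One call: strictly increasing times (s) with frequencies (kHz)."""

    times_s: np.ndarray
    freqs_khz: np.ndarray
    species: str | None = None          # true label, when synthetic
    features: CallFeatures | None = None
    is_quality: bool | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.freqs_khz = np.asarray(self.freqs_khz, dtype=float)
        if self.times_s.ndim != 1 or self.times_s.shape != self.freqs_khz.shape:
            raise ValueError("times and frequencies must be matching 1-d arrays")
        if self.times_s.size == 0:
            raise ValueError("empty call")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("call times must be strictly increasing")
        if np.any(self.freqs_khz <= 0):
            raise ValueError("frequencies must be positive")

    @property
    def start_s(self) -> float:
        return float(self.times_s[0])

    @property
    def end_s(self) -> float:
        return float(self.times_s[-1])

    @property
    def n_points(self) -> int:
        return int(self.times_s.size)


@dataclass
class ZCCallStream:
    """All calls recorded by one detector during one night."""

    detector_night_id: str
    calls: list[Call] = field(default_factory=list)

    def __post_init__(self) -> None:
        starts = [c.start_s for c in self.calls]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise ValueError("calls must be ordered by start time")

    @property
    def n_calls(self) -> int:
        return len(self.calls)

    @property
    def points(self) -> np.ndarray:
        """All points as an (n, 2) array of (time_s, freq_khz)."""
        if not self.calls:
            return np.empty((0, 2))
        return np.concatenate(
            [np.column_stack([c.times_s, c.freqs_khz]) for c in self.calls]
        )

    @property
    def call_breaks(self) -> list[int]:
        """Start index of each call within :attr:`points`."""
        breaks, i = [], 0
        for c in self.calls:
            breaks.append(i)
            i += c.n_points
        return breaks


@dataclass
class Pass:
    """A temporally contiguous group of calls from (presumably) one bat."""

    pass_id: str
    calls: list[Call]
    detector_night_id: str | None = None
    species: str | None = None          # assigned or true label

    @property
    def start_s(self) -> float:
        return self.calls[0].start_s

    @property
    def end_s(self) -> float:
        return self.calls[-1].end_s

    @property
    def n_calls(self) -> int:
        return len(self.calls)

    @property
    def n_quality_calls(self) -> int:
        return sum(1 for c in self.calls if c.is_quality)

    @property
    def quality_calls(self) -> list[Call]:
        return [c for c in self.calls if c.is_quality]


# ---------------------------------------------------------------------------
# plain-text interchange format


def dumps_zc(stream: ZCCallStream) -> str:
    """Serialize a stream to the plain-text zero-crossing format.

    Header lines carry the detector-night id and division ratio; every
    subsequent line is one ``time_s freq_khz`` pair, with a blank line
    between calls.  Floats use the shortest round-trip representation so
    that write -> read -> write is byte-identical.
    """
    buf = io.StringIO()
    buf.write(f"# detector_night_id {stream.detector_night_id}\n")
    buf.write(f"# division_ratio {DIVISION_RATIO}\n")
    for k, call in enumerate(stream.calls):
        if k:
            buf.write("\n")
        for t, f in zip(call.times_s, call.freqs_khz):
            buf.write(f"{float(t)!r} {float(f)!r}\n")
    return buf.getvalue()


def loads_zc(text: str) -> ZCCallStream:
    """Parse the plain-text zero-crossing format."""
    night_id = None
    calls: list[Call] = []
    cur_t: list[float] = []
    cur_f: list[float] = []

    def flush() -> None:
        if cur_t:
            calls.append(Call(np.array(cur_t), np.array(cur_f)))
            cur_t.clear()
            cur_f.clear()

    for line in text.splitlines():
        line = line.strip()
        if line.startswith("#"):
            parts = line[1:].split()
            if parts and parts[0] == "detector_night_id":
                night_id = " ".join(parts[1:])
        elif not line:
            flush()
        else:
            t_s, f_s = line.split()
            cur_t.append(float(t_s))
            cur_f.append(float(f_s))
    flush()
    if night_id is None:
        raise ValueError("missing '# detector_night_id' header")
    return ZCCallStream(night_id, calls)


def write_zc(stream: ZCCallStream, path) -> None:
    with open(path, "w") as fh:
        fh.write(dumps_zc(stream))


def read_zc(path) -> ZCCallStream:
    with open(path) as fh:
        return loads_zc(fh.read())


# ---------------------------------------------------------------------------
# pass segmentation


def segment_passes(stream: ZCCallStream, gap_s: float = DEFAULT_GAP_S) -> list[Pass]:
    """Group a stream's calls into passes.

    Consecutive calls whose silent interval (end of one call to start of the
    next) is at most ``gap_s`` seconds belong to the same pass; a longer gap
    starts a new pass.  An empty stream yields an empty list.
    """
    if gap_s < 0:
        raise ValueError("gap_s must be non-negative")
    passes: list[Pass] = []
    group: list[Call] = []

    def flush() -> None:
        if group:
            passes.append(
                Pass(
                    pass_id=f"{stream.detector_night_id}:p{len(passes)}",
                    calls=list(group),
                    detector_night_id=stream.detector_night_id,
                )
            )
            group.clear()

    for call in stream.calls:
        if group and call.start_s - group[-1].end_s > gap_s:
            flush()
        group.append(call)
    flush()
    return passes


# ---------------------------------------------------------------------------
# feature extraction


def _local_slopes(t: np.ndarray, logf: np.ndarray, window: int) -> np.ndarray:
    """Per-point slope of logf vs t by centered local linear regression."""
    n = t.size
    w = min(window, n)
    h = w // 2
    idx = np.arange(n)
    lo = np.maximum(0, idx - h)
    hi = np.minimum(n, idx + h + 1)

    def csum(a):
        out = np.empty(a.size + 1)
        out[0] = 0.0
        np.cumsum(a, out=out[1:])
        return out

    s1, st = csum(np.ones(n)), csum(t)
    stt, sf, stf = csum(t * t), csum(logf), csum(t * logf)
    m = s1[hi] - s1[lo]
    mt = st[hi] - st[lo]
    cov = (stf[hi] - stf[lo]) - mt * (sf[hi] - sf[lo]) / m
    var = (stt[hi] - stt[lo]) - mt * mt / m
    return cov / np.maximum(var, 1e-300)


def _qual_index(t_rel: np.ndarray, f: np.ndarray) -> float:
    """RMS relative deviation from the best-fitting smooth power-law sweep.

    The smooth family is f(t) = a + b * (1 - t/T)^gamma with gamma searched
    over a fixed grid; (a, b) solved per gamma by linear least squares.  Flat
    calls and exact linear sweeps fit perfectly and score 0.
    """
    T = t_rel[-1]
    x = 1.0 - t_rel / T
    best = np.inf
    n = f.size
    fm = f.mean()
    for gamma in _QUAL_EXPONENTS:
        g = x**gamma
        gm = g.mean()
        varg = np.dot(g, g) / n - gm * gm
        if varg < 1e-12:
            resid = f - fm
        else:
            b = (np.dot(g, f) / n - gm * fm) / varg
            a = fm - b * gm
            resid = f - (a + b * g)
        rms = float(np.sqrt(np.mean((resid / f) ** 2)))
        best = min(best, rms)
    return best


def extract_features(times_s, freqs_khz) -> CallFeatures:
    """Extract the 11 shape features from one call's point sequence.

    ``times_s``/``freqs_khz`` are the call's zero-crossing points.  All
    features are invariant to a global time offset.  Fewer than 3 points
    raises :class:`DegenerateCallError`.

    Feature definitions (the vendor software the thresholds originate from
    never published exact formulas; these are fixed, documented stand-ins):

    * ``fc``: frequency at the minimum-|slope| point within the final half
      of the call; slope ties resolved to the latest such point.
    * ``body``: time extent of the longest contiguous run of points whose
      slope lies within 20% (plus a small absolute floor) of the slope at
      the fc point.
    * ``qual``: RMS relative residual from a least-squares power-law sweep
      fit (0 = perfectly smooth).
    * ``fk``: frequency at the maximum-|curvature| point of the log-frequency
      track; curvature-free calls report fk = fc.
    * slopes (``s1``, ``sc``): octaves/s from local linear regression of
      log2 f on t.
    """
    t = np.asarray(times_s, dtype=float)
    f = np.asarray(freqs_khz, dtype=float)
    if t.size < 3:
        raise DegenerateCallError(f"call has {t.size} point(s); need >= 3")
    if np.any(np.diff(t) <= 0):
        raise ValueError("call times must be strictly increasing")
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")

    t_rel = t - t[0]
    dur_s = t_rel[-1]
    dur_ms = dur_s * 1e3
    fmax = float(f.max())
    fmin = float(f.min())
    fmean = float(np.trapezoid(f, t_rel) / dur_s)

    logf = np.log2(f)
    dt_med = float(np.median(np.diff(t_rel)))
    window = int(np.clip(round(_SLOPE_WINDOW_S / dt_med) | 1,
                         _SLOPE_WINDOW_MIN, _SLOPE_WINDOW_MAX))
    slopes = _local_slopes(t_rel, logf, window)

    # characteristic point: flattest point in the final half, ties -> latest
    half = np.nonzero(t_rel >= dur_s / 2)[0]
    a = np.abs(slopes[half])
    amin = a.min()
    ic = int(half[np.nonzero(a <= amin * (1 + 1e-12) + 1e-15)[0][-1]])
    fc = float(f[ic])
    tc_ms = float(t_rel[ic] * 1e3)
    sc = float(slopes[ic])
    s1 = float(slopes[0])

    qual = _qual_index(t_rel, f)

    # body: longest run of points with slope close to sc.  The band is 20%
    # relative with an absolute floor that adapts to the slope-track noise
    # (per-point jitter, estimated by the qual residual, propagated through
    # the local regression), since the flattest-point slope is
    # selection-biased low on noisy tracks.
    sigma_logf = qual / np.log(2)
    slope_noise = sigma_logf * np.sqrt(12.0 / (window**3 - window)) / dt_med
    tol = 0.2 * abs(sc) + max(_BODY_SLOPE_FLOOR, 3.0 * slope_noise)
    ok = np.abs(slopes - sc) <= tol
    body_ms = 0.0
    run_start = None
    edges = np.flatnonzero(np.diff(np.concatenate(([0], ok.view(np.int8), [0]))))
    for lo, hi in zip(edges[::2], edges[1::2]):
        span = (t_rel[hi - 1] - t_rel[lo]) * 1e3
        if span > body_ms:
            body_ms = float(span)
            run_start = lo

    # knee: maximum curvature of the log-frequency track
    curv = np.gradient(slopes, t_rel)
    ik = int(np.argmax(np.abs(curv)))
    fk = float(f[ik]) if np.abs(curv[ik]) >= _KNEE_CURVATURE_MIN else fc

    return CallFeatures(
        fc_khz=fc,
        fmax_khz=fmax,
        fmin_khz=fmin,
        fmean_khz=fmean,
        dur_ms=float(dur_ms),
        body_ms=body_ms,
        qual=qual,
        s1_okps=s1,
        sc_okps=sc,
        tc_ms=tc_ms,
        fk_khz=fk,
    )


def featurize_call(call: Call) -> Call:
    """Attach extracted features to a call (marking degenerate calls)."""
    if call.features is None:
        try:
            call.features = extract_features(call.times_s, call.freqs_khz)
        except DegenerateCallError:
            call.features = None
            call.is_quality = False
    return call


# ---------------------------------------------------------------------------
# quality filtering and counting


@dataclass(frozen=True)
class QualityThresholds:
    """Acceptance window for high-quality calls."""

    fc_min_khz: float = 5.0
    fc_max_khz: float = 60.0
    dur_min_ms: float = 2.0
    dur_max_ms: float = 50.0
    body_min_ms: float = 1.0
    qual_max: float = 0.3

    def accepts(self, ft: CallFeatures) -> bool:
        return (
            self.fc_min_khz <= ft.fc_khz <= self.fc_max_khz
            and self.dur_min_ms <= ft.dur_ms <= self.dur_max_ms
            and ft.body_ms > self.body_min_ms
            and ft.qual < self.qual_max
        )


def quality_filter(pass_: Pass, thresholds: QualityThresholds | None = None) -> Pass:
    """Mark each call in a pass as high-quality or not (idempotent).

    Features are extracted on demand; calls too short to featurize are
    rejected.  Returns the same pass with ``is_quality`` flags set.
    """
    thr = thresholds or QualityThresholds()
    for call in pass_.calls:
        featurize_call(call)
        call.is_quality = call.features is not None and thr.accepts(call.features)
    return pass_


def drop_empty_passes(passes: list[Pass]) -> list[Pass]:
    """Retain only passes containing at least one high-quality call."""
    return [p for p in passes if p.n_quality_calls >= 1]


def nightly_counts(
    passes: list[Pass],
    night_ids: list[str] | None = None,
    by_species: bool = False,
):
    """Count passes per detector-night (optionally per species).

    Returns a :class:`pandas.DataFrame` with columns ``detector_night_id``,
    optionally ``species``, and ``n_passes``.  When ``night_ids`` is given,
    nights without passes appear with an explicit zero and a pass referencing
    an unlisted night is an error.
    """
    import pandas as pd

    for p in passes:
        if p.detector_night_id is None:
            raise ValueError(f"pass {p.pass_id} has no detector_night_id")
    if night_ids is not None:
        known = set(night_ids)
        for p in passes:
            if p.detector_night_id not in known:
                raise ValueError(
                    f"pass {p.pass_id} references unknown detector-night "
                    f"{p.detector_night_id!r}"
                )
    nights = list(night_ids) if night_ids is not None else sorted(
        {p.detector_night_id for p in passes}
    )

    if not by_species:
        tally = {n: 0 for n in nights}
        for p in passes:
            tally[p.detector_night_id] += 1
        return pd.DataFrame(
            {"detector_night_id": nights, "n_passes": [tally[n] for n in nights]}
        )

    species = sorted({p.species for p in passes if p.species is not None})
    tally = {(n, s): 0 for n in nights for s in species}
    for p in passes:
        if p.species is None:
            raise ValueError(f"pass {p.pass_id} has no species label")
        tally[(p.detector_night_id, p.species)] += 1
    rows = [
        {"detector_night_id": n, "species": s, "n_passes": tally[(n, s)]}
        for n in nights
        for s in species
    ]
    return pd.DataFrame(rows)
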