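"""Synthetic echolocation call streams and survey datasets.

Everything downstream of a bat detector is testable without field data:
this module generates (a) species call-shape profiles and labeled reference
call libraries for the classifier, and (b) full survey datasets -- design
covariates, NB1 nightly pass counts with crossed night/transect random
effects, and per-night zero-crossing call streams whose 5-second-gap
segmentation recovers exactly the simulated passes.

Call synthesis uses a two-phase frequency sweep: a steep curved onset
(power exponent 1 + curvature over the first 30% of the call, covering 65%
of the log-frequency range) followed by a near-linear terminal body with
constant octave slope, the characteristic shape of FM bat calls.  A
curvature of zero degenerates to a single linear sweep.  Points are placed
where a division-ratio-8 zero-crossing detector would record them
(t_{k+1} = t_k + 8 / f(t_k)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import zc
from .design import DESIGN_COLUMNS, ModelSpec, build_design
from .glmm import rnb1
from .studydata import default_species_mix

__all__ = [
    "SpeciesProfile",
    "SurveyConfig",
    "SurveyData",
    "TrueModel",
    "generate_call",
    "make_species_profiles",
    "read_survey_csv",
    "simulate_reference_library",
    "simulate_survey",
    "write_survey_csv",
]

#: Fraction of the call duration spent in the curved onset phase.
_ONSET_TIME_FRAC = 0.3
#: Fraction of the log-frequency range covered by the onset phase.
_ONSET_LOG_FRAC = 0.65
#: Per-point frequency jitter, as a fraction of the profile's feature_sd.
_POINT_JITTER_FRAC = 0.1
#: Log-scale point jitter applied to corrupted (low-quality) calls.
_CORRUPT_JITTER = 0.5


@dataclass(frozen=True)
class SpeciesProfile:
    """Mean call-shape parameters of one synthetic species."""

    species_code: str
    f_start_khz: float
    f_end_khz: float
    duration_ms: float
    curvature: float            # 0 = linear sweep; larger = steeper onset
    feature_sd: float           # relative call-to-call jitter (fraction)
    calls_per_pass_mean: float

    def __post_init__(self) -> None:
        if not (self.f_start_khz >= self.f_end_khz > 0):
            raise ValueError("require f_start_khz >= f_end_khz > 0")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.curvature < 0:
            raise ValueError("curvature must be non-negative")
        if self.feature_sd < 0:
            raise ValueError("feature_sd must be non-negative")
        if self.calls_per_pass_mean < 1:
            raise ValueError("calls_per_pass_mean must be >= 1")


@dataclass(frozen=True)
class TrueModel:
    """Generating truth for nightly counts: eta = x'beta + u_night + v_transect."""

    beta: tuple[float, ...]
    sigma_night: float = 0.3
    sigma_transect: float = 0.3
    phi: float = 3.0            # NB1 dispersion: var = phi * mean

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))
        if len(self.beta) != len(DESIGN_COLUMNS):
            raise ValueError(f"beta must have {len(DESIGN_COLUMNS)} entries")
        if self.sigma_night < 0 or self.sigma_transect < 0:
            raise ValueError("random-effect SDs must be non-negative")
        if self.phi < 1:
            raise ValueError("phi must be >= 1 (NB1 dispersion)")

    @property
    def beta_array(self) -> np.ndarray:
        return np.asarray(self.beta, dtype=float)


@dataclass(frozen=True)
class SurveyConfig:
    """Layout and environment of a synthetic survey.

    Defaults reproduce the scale of the motivating field study: 3 sites
    with 4/2/4 transects, detectors at 0/100/300 m, 30 sampled points of
    which 4 are lit, 3-10 nights per point totalling 174 detector-nights
    drawn from a 34-night calendar split over two seasons, and daily
    maximum temperatures ~ N(23, 4.9^2) truncated to [17, 37] C.
    """

    site_transects: tuple[tuple[str, int], ...] = (
        ("DOED", 4), ("HAYW", 2), ("SAPA", 4)
    )
    distances_m: tuple[int, ...] = (0, 100, 300)
    total_nights: int = 174
    nights_per_point_range: tuple[int, int] = (3, 10)
    n_calendar_nights: int = 34
    years: tuple[int, int] = (2010, 2011)
    n_light_points: int = 4
    temp_mean_c: float = 23.0
    temp_sd_c: float = 4.9
    temp_range_c: tuple[float, float] = (17.0, 37.0)
    night_hours: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.nights_per_point_range
        n_points = self.n_points
        if not (1 <= lo <= hi):
            raise ValueError("invalid nights_per_point_range")
        n_tr = sum(n for _, n in self.site_transects)
        n_dist = len(self.distances_m)
        if self.total_nights % n_dist:
            raise ValueError(
                "total_nights must be divisible by the number of distances"
            )
        deployments = self.total_nights // n_dist
        if not (n_tr * lo <= deployments <= n_tr * hi):
            raise ValueError(
                f"total_nights={self.total_nights} unreachable with "
                f"{n_tr} transects and {lo}-{hi} nights each"
            )
        if self.n_light_points > n_points:
            raise ValueError("more lit points than points")
        if self.n_calendar_nights < hi:
            raise ValueError("calendar too short for nights_per_point_range")

    @property
    def n_points(self) -> int:
        return sum(n for _, n in self.site_transects) * len(self.distances_m)


@dataclass
class SurveyData:
    """A simulated survey: records, truth, and (optionally) call streams."""

    records: pd.DataFrame            # one row per detector-night, total counts
    species_counts: pd.DataFrame | None
    streams: list[zc.ZCCallStream]
    u_night: np.ndarray
    v_transect: np.ndarray
    config: SurveyConfig
    model: TrueModel


# ---------------------------------------------------------------------------
# species profiles and single calls


def make_species_profiles(
    n_species: int, seed: int | np.random.Generator = 0,
    feature_sd: float = 0.05,
) -> list[SpeciesProfile]:
    """Generate pairwise-distinct species call-shape profiles.

    Terminal frequencies are spread over 12-50 kHz with seeded jitter so
    that species occupy distinct regions of feature space; all other shape
    parameters are drawn per species.  Deterministic for a fixed seed.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    f_end = np.linspace(12.0, 50.0, n_species)
    spacing = (f_end[1] - f_end[0]) if n_species > 1 else 1.0
    f_end = f_end + rng.uniform(-0.3, 0.3, n_species) * spacing
    ratio = rng.uniform(1.2, 1.9, n_species)
    duration = rng.uniform(3.5, 12.0, n_species)
    curvature = rng.uniform(0.3, 1.8, n_species)
    cpp = rng.uniform(3.0, 8.0, n_species)
    return [
        SpeciesProfile(
            species_code=f"SP{i + 1:02d}",
            f_start_khz=float(f_end[i] * ratio[i]),
            f_end_khz=float(f_end[i]),
            duration_ms=float(duration[i]),
            curvature=float(curvature[i]),
            feature_sd=feature_sd,
            calls_per_pass_mean=float(cpp[i]),
        )
        for i in range(n_species)
    ]


def _sweep_function(fs: float, fe: float, dur_s: float, curvature: float):
    """Instantaneous frequency (kHz) as a function of time since call start."""
    if curvature == 0.0 or fs == fe:
        def f(t):
            return fs + (fe - fs) * (t / dur_s)
        return f
    t_knee = _ONSET_TIME_FRAC * dur_s
    log_range = math.log(fs / fe)
    fk = fe * math.exp((1.0 - _ONSET_LOG_FRAC) * log_range)
    expo = 1.0 + curvature
    log_fk = math.log(fk)
    log_fe = math.log(fe)

    def f(t):
        if t < t_knee:
            return fk + (fs - fk) * (1.0 - t / t_knee) ** expo
        frac = (t - t_knee) / (dur_s - t_knee)
        return math.exp(log_fk + (log_fe - log_fk) * frac)

    return f


def generate_call(
    profile: SpeciesProfile,
    seed: int | np.random.Generator = 0,
    *,
    start_s: float = 0.0,
    corrupt: bool = False,
):
    """Generate one call's zero-crossing points for a species profile.

    Returns ``(times_s, freqs_khz)``.  Call-level shape jitter (duration and
    endpoint frequencies) and per-point frequency jitter both scale with the
    profile's ``feature_sd``; a zero ``feature_sd`` yields identical calls.
    ``corrupt=True`` adds heavy point noise, producing a call the quality
    filter should reject.
    """
    rng = np.random.default_rng(seed)
    sd = profile.feature_sd
    dur_ms = profile.duration_ms * math.exp(rng.normal(0.0, sd))
    fs = profile.f_start_khz * math.exp(rng.normal(0.0, sd))
    fe = profile.f_end_khz * math.exp(rng.normal(0.0, sd))
    fe = min(fe, fs)
    dur_s = dur_ms / 1e3
    f_of_t = _sweep_function(fs, fe, dur_s, profile.curvature)

    times = []
    t = 0.0
    while t <= dur_s:
        times.append(t)
        t += zc.DIVISION_RATIO / (f_of_t(t) * 1e3)
    times = np.array(times)
    freqs = np.array([f_of_t(tt) for tt in times])
    jitter_sd = _POINT_JITTER_FRAC * sd + (_CORRUPT_JITTER if corrupt else 0.0)
    if jitter_sd > 0:
        freqs = freqs * np.exp(rng.normal(0.0, jitter_sd, freqs.size))
    return times + start_s, freqs


# ---------------------------------------------------------------------------
# reference library


def simulate_reference_library(
    profiles: list[SpeciesProfile],
    n_per_species,
    seed: int | np.random.Generator = 0,
    quality_rate: float = 0.97,
):
    """Simulate a labeled reference call library.

    ``n_per_species`` is a single count or one per profile (each >= 10).
    A fraction ``1 - quality_rate`` of calls is corrupted with heavy point
    noise so the library exercises the quality filter.  Returns a
    :class:`batpass.classify.ReferenceLibrary`.
    """
    from .classify import LabeledCall, ReferenceLibrary

    if not profiles:
        raise ValueError("no species profiles supplied")
    if np.isscalar(n_per_species):
        counts = [int(n_per_species)] * len(profiles)
    else:
        counts = [int(n) for n in n_per_species]
        if len(counts) != len(profiles):
            raise ValueError("n_per_species length must match profiles")
    if any(n < 10 for n in counts):
        raise ValueError("need at least 10 calls per species")
    if not (0.0 < quality_rate <= 1.0):
        raise ValueError("quality_rate must be in (0, 1]")

    rng = np.random.default_rng(seed)
    entries: list[LabeledCall] = []
    for profile, n in zip(profiles, counts):
        for _ in range(n):
            corrupt = bool(rng.random() > quality_rate)
            times, freqs = generate_call(profile, rng, corrupt=corrupt)
            call = zc.Call(times, freqs, species=profile.species_code)
            zc.featurize_call(call)
            entries.append(
                LabeledCall(species=profile.species_code, call=call)
            )
    return ReferenceLibrary(
        entries=entries,
        species_list=tuple(p.species_code for p in profiles),
    )


# ---------------------------------------------------------------------------
# survey simulation


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _nights_per_point(rng, n_points, lo, hi, total):
    n = rng.integers(lo, hi + 1, n_points)
    while n.sum() > total:
        idx = rng.choice(np.flatnonzero(n > lo))
        n[idx] -= 1
    while n.sum() < total:
        idx = rng.choice(np.flatnonzero(n < hi))
        n[idx] += 1
    return n


def _calendar(config: SurveyConfig):
    """Calendar-night ids, years and dates (two late-summer seasons)."""
    n = config.n_calendar_nights
    first = (n + 1) // 2
    ids, years, dates = [], [], []
    for i in range(n):
        year = config.years[0] if i < first else config.years[1]
        day_index = i if i < first else i - first
        month = 8 + day_index // 28
        day = 1 + (day_index * 2) % 28
        ids.append(f"{year}-{month:02d}-{day:02d}")
        years.append(year)
        dates.append(ids[-1])
    return ids, years, dates


def simulate_survey(
    config: SurveyConfig,
    model: TrueModel,
    profiles: list[SpeciesProfile] | None = None,
    species_mix: dict[str, float] | None = None,
    *,
    seed: int | np.random.Generator | None = None,
    emit_streams: bool = True,
) -> SurveyData:
    """Simulate a full survey from the generating count model.

    For every detector-night the generator forms eta = x'beta + u_night +
    v_transect (transect effects shared across nights), draws the nightly
    pass count from NB1(exp(eta), phi), allocates passes to species by
    ``species_mix``, and (when ``emit_streams``) lays the passes out over a
    10-hour night with >= 6 s of silence between passes so the 5-second-gap
    segmentation recovers them exactly.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if emit_streams and profiles is None:
        profiles = make_species_profiles(15, seed=rng.integers(2**31))
    if profiles is not None:
        codes = [p.species_code for p in profiles]
        if species_mix is None:
            species_mix = default_species_mix(codes)
        missing = set(species_mix) - set(codes)
        if missing:
            raise ValueError(f"species_mix references unknown codes: {missing}")
        mix = np.array([species_mix.get(c, 0.0) for c in codes])
        if abs(mix.sum() - 1.0) > 1e-8:
            raise ValueError("species_mix must sum to 1")
    else:
        codes, mix = [], None

    # --- design layout -----------------------------------------------------
    # Detectors are deployed a whole transect at a time (all distances the
    # same nights), a few transects per calendar night, so each combination
    # of transect and distance accumulates 3-10 nights.
    transects = []
    for site, n_tr in config.site_transects:
        for k in range(n_tr):
            transects.append((site, f"{site}-T{k + 1}"))
    n_dist = len(config.distances_m)
    points = [
        (site, tr, dist)
        for site, tr in transects
        for dist in config.distances_m
    ]
    n_points = len(points)
    if config.total_nights % n_dist:
        raise ValueError(
            "total_nights must be divisible by the number of distances "
            "(transect-level deployment)"
        )
    lo, hi = config.nights_per_point_range
    nights_per_transect = _nights_per_point(
        rng, len(transects), lo, hi, config.total_nights // n_dist
    )
    lit = set(rng.choice(n_points, config.n_light_points, replace=False))

    cal_ids, cal_years, _ = _calendar(config)
    n_cal = config.n_calendar_nights
    temps = _truncated_normal(
        rng, config.temp_mean_c, config.temp_sd_c,
        config.temp_range_c[0], config.temp_range_c[1], n_cal,
    )

    rows = []
    for t_idx, (site, transect) in enumerate(transects):
        chosen = rng.choice(n_cal, int(nights_per_transect[t_idx]),
                            replace=False)
        for c in sorted(chosen):
            for dist in config.distances_m:
                p_idx = points.index((site, transect, dist))
                rows.append(
                    {
                        "detector_night_id": f"{transect}:{dist}:{cal_ids[c]}",
                        "site": site,
                        "transect": transect,
                        "dist_road": dist,
                        "night_id": cal_ids[c],
                        "date": cal_ids[c],
                        "year": cal_years[c],
                        "temp_max": float(temps[c]),
                        "light_100": p_idx in lit,
                    }
                )
    records = pd.DataFrame(rows)

    # --- counts ------------------------------------------------------------
    design = build_design(records, ModelSpec())
    u = rng.normal(0.0, model.sigma_night, design.n_nights)
    v = rng.normal(0.0, model.sigma_transect, design.n_transects)
    eta = (
        design.X @ model.beta_array
        + u[design.night_index]
        + v[design.transect_index]
    )
    mu = np.exp(np.clip(eta, -30, 30))
    counts = rnb1(mu, model.phi, rng)
    records["count"] = counts.astype(int)
    records["species"] = "all"

    # --- species allocation and call streams -------------------------------
    species_counts = None
    streams: list[zc.ZCCallStream] = []
    if mix is not None:
        alloc = np.stack(
            [rng.multinomial(int(c), mix) for c in counts]
        )  # (n_records, n_species)
        species_counts = pd.DataFrame(
            alloc, columns=codes, index=records.index
        )
        species_counts.insert(
            0, "detector_night_id", records["detector_night_id"]
        )
    if emit_streams:
        prof_by_code = {p.species_code: p for p in profiles}
        night_len = config.night_hours * 3600.0
        min_sep = 10.0  # start-to-start; passes are < 4 s long
        for i, row in records.iterrows():
            y_i = int(row["count"])
            calls: list[zc.Call] = []
            if y_i > 0:
                span = night_len - (y_i - 1) * min_sep
                if span <= 0:
                    raise ValueError(
                        f"{y_i} passes do not fit in a "
                        f"{config.night_hours}-hour night"
                    )
                starts = np.sort(rng.uniform(0.0, span, y_i))
                starts = starts + np.arange(y_i) * min_sep
                labels = np.repeat(codes, alloc[i])
                rng.shuffle(labels)
                for start, code in zip(starts, labels):
                    profile = prof_by_code[code]
                    n_calls = 1 + min(int(rng.poisson(
                        max(profile.calls_per_pass_mean - 1.0, 0.0)
                    )), 11)
                    t = float(start)
                    for _ in range(n_calls):
                        times, freqs = generate_call(profile, rng, start_s=t)
                        calls.append(
                            zc.Call(times, freqs, species=code)
                        )
                        t = float(times[-1]) + rng.uniform(0.05, 0.3)
            streams.append(
                zc.ZCCallStream(str(row["detector_night_id"]), calls)
            )

    return SurveyData(
        records=records,
        species_counts=species_counts,
        streams=streams,
        u_night=u,
        v_transect=v,
        config=config,
        model=model,
    )


# ---------------------------------------------------------------------------
# survey CSV interchange (summary-table layout)


def write_survey_csv(survey: SurveyData, path) -> None:
    """Write nightly counts in the summary layout: one row per
    detector-night and species (total activity under species "all")."""
    frames = [
        survey.records[
            ["site", "transect", "dist_road", "date", "year",
             "temp_max", "light_100", "species", "count"]
        ].rename(
            columns={
                "dist_road": "distance_m",
                "temp_max": "temp_max_c",
                "count": "n_passes",
            }
        )
    ]
    if survey.species_counts is not None:
        base = survey.records[
            ["site", "transect", "dist_road", "date", "year",
             "temp_max", "light_100"]
        ].rename(columns={"dist_road": "distance_m", "temp_max": "temp_max_c"})
        for code in survey.species_counts.columns.drop("detector_night_id"):
            f = base.copy()
            f["species"] = code
            f["n_passes"] = survey.species_counts[code].to_numpy()
            frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_survey_csv(path) -> pd.DataFrame:
    """Read a survey summary CSV back into a records DataFrame."""
    df = pd.read_csv(path)
    df = df.rename(
        columns={
            "distance_m": "dist_road",
            "temp_max_c": "temp_max",
            "n_passes": "count",
        }
    )
    df["night_id"] = df["date"].astype(str)
    df["light_100"] = df["light_100"].astype(bool)
    return df
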