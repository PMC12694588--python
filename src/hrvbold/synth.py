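"""Synthetic cohorts with planted HRV / age / SD_BOLD structure.

Emulates, at desk scale, the statistical structure the analysis
pipeline assumes: a cohort of subjects with demographic covariates and
log HRV measures that decline with age; per-subject RR tachograms with
controllable LF/HF sinusoidal modulation, white inter-beat jitter and
artifact dropout; and 4D BOLD runs on a small voxel grid (12^3 by
default, all-true mask, 240 volumes at TR = 2 s) whose per-voxel
temporal SD carries planted couplings:

* between subjects, affected voxels' SD scales with the subject's
  z-scored log SDNN (slope ``hrv_sd_slope``) and z-scored age
  (``age_sd_slope``);
* within subjects, noise amplitude is modulated across the scan so that
  each sliding window's mean SD_BOLD shifts by ``within_coupling`` per
  z-unit of that window's (person-centered) HRV.

All generators are pure functions of their arguments including the
seed.  The within-window plant uses piecewise-constant amplitude
segments aligned with the downstream window grid; for 50%-overlapping
windows the segment variances are solved exactly so that every window's
average noise variance hits its target.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hrv import NNIntervalSeries
from .sdbold import BoldRun
from .windows import WindowSpec, make_windows

__all__ = [
    "CohortSpec",
    "CohortData",
    "gen_cohort",
    "gen_rr_series",
    "gen_bold_run",
    "inject_artifacts",
    "affected_voxel_mask",
    "simulate_study",
]

# log-scale baselines for a middle-aged resting cohort: SDNN ~ 45 ms,
# RMSSD ~ 35 ms, LF ~ 600 ms^2, HF ~ 300 ms^2
_LOG_BASE = {"log_sdnn": np.log(45.0), "log_rmssd": np.log(35.0),
             "log_lf": np.log(600.0), "log_hf": np.log(300.0)}


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of a synthetic cohort and its planted effects.

    Between-subject effects: ``age_hrv_slope`` is the change in log HRV
    per year of age; ``hrv_sd_slope`` scales affected voxels' temporal
    SD per z-unit of log SDNN; ``age_sd_slope`` does the same per
    z-unit of age.  ``within_coupling`` is the change in window mean
    SD_BOLD (in SD_BOLD units) per z-unit of person-centered log HRV.
    ``affected_fraction`` of voxels carry the between-subject plant.

    Defaults follow the study conditions the pipeline targets: 60
    subjects aged 26-76, 240 volumes at TR 2 s on a 12^3 grid, HRV
    declining ~1%/year, and positive HRV -> SD_BOLD coupling both
    between and within subjects.
    """

    n_subjects: int = 60
    seed: int = 0
    age_range: tuple[float, float] = (26.0, 76.0)
    age_hrv_slope: float = -0.01
    hrv_sd_slope: float = 0.2
    within_coupling: float = 0.01
    grid_dims: tuple[int, int, int] = (12, 12, 12)
    n_volumes: int = 240
    tr: float = 2.0
    noise_sd: float = 10.0
    affected_fraction: float = 0.7
    # --- extensions required to realize the plants ---
    age_sd_slope: float = -0.05
    offset: float = 1000.0
    hrv_noise_sd: float = 0.2
    shared_noise_sd: float = 0.0
    within_hrv_mod: float = 0.2
    sex_male_prop: float = 0.47
    race_white_prop: float = 0.69
    block_len: int = 10
    window_length_s: float = 240.0
    window_overlap: float = 0.5

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError(
                f"n_subjects must be >= 2, got {self.n_subjects}"
            )
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError(f"age_range low must be < high, got ({lo}, {hi})")
        if any(d < 1 for d in self.grid_dims):
            raise ValueError(f"grid_dims must all be >= 1, got {self.grid_dims}")
        if self.n_volumes < self.block_len:
            raise ValueError(
                f"n_volumes ({self.n_volumes}) must be >= block length "
                f"({self.block_len})"
            )
        if not 0 <= self.affected_fraction <= 1:
            raise ValueError(
                f"affected_fraction must be in [0, 1], got {self.affected_fraction}"
            )
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.offset <= 0:
            raise ValueError(f"offset must be positive, got {self.offset}")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_dims))

    @property
    def scan_duration(self) -> float:
        return self.n_volumes * self.tr

    def window_spec(self) -> WindowSpec:
        return WindowSpec(
            scan_duration=self.scan_duration,
            window_length=self.window_length_s,
            overlap_fraction=self.window_overlap,
        )

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["age_range"] = list(d["age_range"])
        d["grid_dims"] = list(d["grid_dims"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        d = yaml.safe_load(Path(path).read_text())
        d["age_range"] = tuple(d["age_range"])
        d["grid_dims"] = tuple(d["grid_dims"])
        return cls(**d)


def gen_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate the subject table: demographics and log HRV measures.

    Ages are uniform over ``age_range``; sex (1 = male) and race
    (1 = white) are Bernoulli with the configured proportions.  Each log
    HRV measure is a baseline plus a linear age trend of slope
    ``age_hrv_slope`` (doubled for the power measures LF/HF, which live
    on a squared-amplitude scale) plus a shared subject deviation and
    measure-specific noise, giving the realistic positive correlation
    among HRV indices.  The shared deviation is truncated at +/-3 SD —
    physiological QC excludes the extreme outliers, and the bound keeps
    the multiplicative SD plant of :func:`gen_bold_run` positive for
    every subject at the default slopes.  Adds z-scored helper columns
    ``z_log_sdnn`` and ``z_age`` used by the BOLD generator.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    lo, hi = spec.age_range
    mid = 0.5 * (lo + hi)
    age = rng.uniform(lo, hi, n)
    sex = (rng.random(n) < spec.sex_male_prop).astype(int)
    race = (rng.random(n) < spec.race_white_prop).astype(int)
    s = spec.hrv_noise_sd
    dev = np.clip(rng.normal(0.0, s, n), -3 * s, 3 * s)
    extra = {
        "log_rmssd": rng.normal(0.0, 0.5 * spec.hrv_noise_sd, n),
        "log_lf": rng.normal(0.0, spec.hrv_noise_sd, n),
        "log_hf": rng.normal(0.0, spec.hrv_noise_sd, n),
    }
    trend = spec.age_hrv_slope * (age - mid)
    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:03d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "race": race,
            "log_sdnn": _LOG_BASE["log_sdnn"] + trend + dev,
            "log_rmssd": _LOG_BASE["log_rmssd"] + trend + 0.9 * dev
            + extra["log_rmssd"],
            "log_lf": _LOG_BASE["log_lf"] + 2 * trend + 1.8 * dev
            + extra["log_lf"],
            "log_hf": _LOG_BASE["log_hf"] + 2 * trend + 1.6 * dev
            + extra["log_hf"],
        }
    )

    def _z(col: np.ndarray) -> np.ndarray:
        sd = col.std(ddof=1)
        return (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)

    table["z_log_sdnn"] = _z(table["log_sdnn"].to_numpy())
    table["z_age"] = _z(table["age"].to_numpy())
    return table


def gen_rr_series(
    mean_rr: float,
    duration: float,
    lf_amp: float = 0.0,
    hf_amp: float = 0.0,
    lf_freq: float = 0.10,
    hf_freq: float = 0.25,
    jitter_sd: float = 0.0,
    seed: int = 0,
    segment_bounds: np.ndarray | None = None,
    segment_jitter_factors: np.ndarray | None = None,
) -> NNIntervalSeries:
    """Generate an RR tachogram with LF/HF sinusoidal modulation.

    Each interval (ms) is ``mean_rr + lf_amp sin(2 pi lf_freq t) +
    hf_amp sin(2 pi hf_freq t) + jitter`` evaluated at the beat's onset
    ``t``; beats accumulate until ``duration`` (s) is filled.  Intervals
    are floored at 1% of ``mean_rr`` so the series stays strictly
    positive even under heavy jitter.

    ``segment_bounds`` / ``segment_jitter_factors`` optionally scale the
    jitter SD piecewise over time (used to plant within-scan HRV
    modulation aligned with the sliding-window grid).
    """
    if mean_rr <= 0:
        raise ValueError(f"mean_rr must be positive, got {mean_rr}")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if not 0.04 <= lf_freq <= 0.15:
        raise ValueError(f"lf_freq must lie in the LF band 0.04-0.15 Hz, got {lf_freq}")
    if not 0.15 <= hf_freq <= 0.40:
        raise ValueError(f"hf_freq must lie in the HF band 0.15-0.40 Hz, got {hf_freq}")
    rng = np.random.default_rng(seed)
    onsets: list[float] = []
    intervals: list[float] = []
    t = 0.0
    floor = 0.01 * mean_rr
    while True:
        jit = jitter_sd
        if segment_bounds is not None:
            j = int(np.clip(
                np.searchsorted(segment_bounds, t, side="right") - 1,
                0, len(segment_jitter_factors) - 1,
            ))
            jit = jitter_sd * float(segment_jitter_factors[j])
        nn = (
            mean_rr
            + lf_amp * np.sin(2 * np.pi * lf_freq * t)
            + hf_amp * np.sin(2 * np.pi * hf_freq * t)
            + (rng.normal(0.0, jit) if jit > 0 else 0.0)
        )
        nn = max(nn, floor)
        if t + nn / 1000.0 > duration:
            break
        onsets.append(t)
        intervals.append(nn)
        t += nn / 1000.0
    return NNIntervalSeries(
        np.asarray(onsets), np.asarray(intervals), np.ones(len(onsets), bool)
    )


def affected_voxel_mask(spec: CohortSpec) -> np.ndarray:
    """Flat boolean mask of voxels carrying the between-subject plant.

    Derived from ``spec.seed`` only, so the affected set is identical
    for every subject of a cohort — a shared spatial pattern is what
    the multivariate analysis is meant to recover.
    """
    n_aff = int(round(spec.affected_fraction * spec.n_voxels))
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xAFFEC]))
    mask = np.zeros(spec.n_voxels, dtype=bool)
    mask[rng.permutation(spec.n_voxels)[:n_aff]] = True
    return mask


def _window_segment_variances(
    window_factors: np.ndarray, spec: CohortSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Segment boundaries and variances hitting per-window variance targets.

    Windows at 50% overlap each span two equal segments, so window w's
    average variance is ``(v_w + v_{w+1}) / 2``; the recursion
    ``v_0 = f_0^2, v_{w+1} = 2 f_w^2 - v_w`` solves the system exactly.
    Non-overlapping windows are their own segments.  Other overlaps are
    not supported for planting.
    """
    ws = spec.window_spec()
    windows = make_windows(ws)
    f2 = np.asarray(window_factors, dtype=float) ** 2
    if len(f2) != len(windows):
        raise ValueError(
            f"profile length {len(f2)} != number of windows {len(windows)}"
        )
    step = ws.step
    if spec.window_overlap == 0.5:
        # window w spans segments w and w+1, so (v_w + v_{w+1})/2 = f_w^2;
        # the system is linear in the free parameter v_0 with alternating
        # signs (v_j = c_j +/- v_0); pick v_0 mid-interval for robustness
        n_seg = len(windows) + 1
        c = np.zeros(n_seg)
        s = np.ones(n_seg)
        for w in range(len(windows)):
            c[w + 1] = 2 * f2[w] - c[w]
            s[w + 1] = -s[w]
        lower = max([0.0] + [-c[j] for j in range(n_seg) if s[j] > 0])
        uppers = [c[j] for j in range(n_seg) if s[j] < 0]
        upper = min(uppers) if uppers else 2.0 * lower + 1.0
        if lower >= upper:
            raise ValueError(
                "window profile implies a non-positive segment variance; "
                "reduce the within-person modulation amplitude"
            )
        v0 = 0.5 * (lower + upper)
        v = c + s * v0
        bounds = np.append(np.arange(n_seg) * step, ws.scan_duration)
    elif spec.window_overlap == 0.0:
        v = f2.copy()
        bounds = np.append(
            np.asarray([w0 for w0, _ in windows]), ws.scan_duration
        )
    else:
        raise ValueError(
            "within-window planting supports only 0 or 0.5 window overlap"
        )
    if np.any(v <= 0):
        raise ValueError(
            "window profile implies a non-positive segment variance; "
            "reduce the within-person modulation amplitude"
        )
    return np.asarray(bounds, dtype=float), v


def _expected_base_sd(spec: CohortSpec, sigma_mean: float) -> float:
    """Expected mean SD_BOLD (scaled units) for noise of SD ``sigma_mean``.

    Block scaling divides by ~``offset/100`` and within-block demeaning
    of L points shrinks the SD by sqrt((L-1)/L) (population divisor).
    """
    L = spec.block_len
    return sigma_mean * (100.0 / spec.offset) * np.sqrt((L - 1) / L)


def gen_bold_run(
    subject_row: pd.Series,
    spec: CohortSpec,
    window_hrv_profile: np.ndarray | None = None,
    seed: int | np.random.SeedSequence = 0,
    dtype=np.float32,
) -> BoldRun:
    """Generate one subject's 4D BOLD run with planted SD structure.

    Every voxel's series is ``offset + sigma_v * g(t) * noise`` with
    Gaussian noise independent across voxels (plus an optional shared
    global component).  For affected voxels,
    ``sigma_v = noise_sd * (1 + hrv_sd_slope * z(log SDNN) +
    age_sd_slope * z(age))``; others keep the baseline SD.  When a
    window HRV profile is given, ``g(t)`` is piecewise constant on the
    sliding-window segment grid, solved so window w's mean SD_BOLD
    shifts by ``within_coupling * profile_w``.
    """
    rng = np.random.default_rng(seed)
    nv, nt = spec.n_voxels, spec.n_volumes
    z_sdnn = float(subject_row["z_log_sdnn"])
    z_age = float(subject_row["z_age"])
    sigma = np.full(nv, spec.noise_sd)
    aff = affected_voxel_mask(spec)
    factor = 1.0 + spec.hrv_sd_slope * z_sdnn + spec.age_sd_slope * z_age
    if factor < 0:
        raise ValueError(
            f"implied voxel SD is negative for subject "
            f"{subject_row.get('subject_id', '?')}: factor={factor:.3f}"
        )
    sigma[aff] *= factor
    g = np.ones(nt)
    if window_hrv_profile is not None:
        base_sd = _expected_base_sd(spec, float(sigma.mean()))
        f_w = 1.0 + spec.within_coupling * np.asarray(window_hrv_profile) / base_sd
        if np.any(f_w <= 0):
            raise ValueError("window profile implies non-positive SD factor")
        bounds, v = _window_segment_variances(f_w, spec)
        times = np.arange(nt) * spec.tr
        j = np.clip(np.searchsorted(bounds, times, side="right") - 1, 0, len(v) - 1)
        g = np.sqrt(v[j])
    noise = rng.standard_normal((nv, nt), dtype=dtype)
    noise *= (sigma[:, None] * g[None, :]).astype(dtype)
    if spec.shared_noise_sd > 0:
        noise += (spec.shared_noise_sd * rng.standard_normal(nt)).astype(dtype)
    data = (noise + dtype(spec.offset)).reshape(*spec.grid_dims, nt)
    mask = np.ones(spec.grid_dims, dtype=bool)
    return BoldRun(data=data, tr=spec.tr, mask=mask)


def inject_artifacts(
    nn: NNIntervalSeries, segments: list[tuple[float, float]]
) -> NNIntervalSeries:
    """Mark intervals overlapping any artifact segment as invalid.

    Segments are ``(start_s, end_s)`` on the series clock; they must be
    non-overlapping, non-inverted and within the series duration.  The
    temporal structure of the remaining valid intervals is preserved.
    """
    segs = sorted(segments)
    for s0, s1 in segs:
        if s1 <= s0:
            raise ValueError(f"inverted artifact segment ({s0}, {s1})")
        if s0 < 0 or s1 > nn.duration + 1e-9:
            raise ValueError(
                f"artifact segment ({s0}, {s1}) outside series duration "
                f"{nn.duration:.1f} s"
            )
    for (a0, a1), (b0, b1) in zip(segs, segs[1:]):
        if a1 > b0:
            raise ValueError(f"overlapping artifact segments {(a0, a1)}, {(b0, b1)}")
    if not segs:
        return nn
    ends = nn.onset_times + nn.intervals / 1000.0
    bad = np.zeros(len(nn), dtype=bool)
    for s0, s1 in segs:
        bad |= (nn.onset_times < s1) & (ends > s0)
    return NNIntervalSeries(nn.onset_times, nn.intervals, nn.valid & ~bad)


@dataclass
class CohortData:
    """One simulated cohort: covariates, tachograms, runs, plants."""

    spec: CohortSpec
    subjects: pd.DataFrame
    nn_series: dict[str, NNIntervalSeries] = field(default_factory=dict)
    runs: dict[str, BoldRun] = field(default_factory=dict)
    window_profiles: dict[str, np.ndarray] = field(default_factory=dict)
    artifact_segments: dict[str, list[tuple[float, float]]] = field(
        default_factory=dict
    )


def _standardized_profile(rng: np.random.Generator, n_windows: int) -> np.ndarray:
    """Per-subject window profile, z-scored across windows (ddof=1)."""
    while True:
        raw = rng.standard_normal(n_windows)
        sd = raw.std(ddof=1)
        if sd > 0:
            return (raw - raw.mean()) / sd


def simulate_study(
    spec: CohortSpec,
    with_tachograms: bool = True,
    with_bold: bool = True,
    dtype=np.float32,
) -> CohortData:
    """Simulate a full cohort ready for the end-to-end pipeline.

    Per subject: a window HRV profile (z-scored across windows) drives
    both the tachogram's within-scan jitter modulation (amplitude
    ``within_hrv_mod``) and, scaled by ``within_coupling``, the BOLD
    noise amplitude, so windows with higher measured HRV have higher
    mean SD_BOLD by construction.  Tachogram LF/HF sinusoid amplitudes
    are set from the subject's target band powers and the jitter from
    the remaining SDNN budget, so measured log HRV tracks the subject
    table.
    """
    subjects = gen_cohort(spec)
    data = CohortData(spec=spec, subjects=subjects)
    n_windows = len(make_windows(spec.window_spec()))
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_subjects)
    modulate = spec.within_hrv_mod > 0 and n_windows >= 2
    for i, row in subjects.iterrows():
        sid = row["subject_id"]
        child = children[i]
        s_prof, s_rr, s_bold, s_misc = child.spawn(4)
        profile = None
        if modulate:
            profile = _standardized_profile(
                np.random.default_rng(s_prof), n_windows
            )
            data.window_profiles[sid] = profile
        if with_tachograms:
            rng_misc = np.random.default_rng(s_misc)
            mean_rr = float(np.clip(rng_misc.normal(900.0, 80.0), 600.0, 1200.0))
            sdnn_t = np.exp(row["log_sdnn"])
            lf_p = np.exp(row["log_lf"])
            hf_p = np.exp(row["log_hf"])
            jitter_var = sdnn_t**2 - lf_p - hf_p
            if jitter_var <= 0:  # shrink band power so jitter keeps >= half the budget
                scale = 0.5 * sdnn_t**2 / (lf_p + hf_p)
                lf_p *= scale
                hf_p *= scale
                jitter_var = sdnn_t**2 - lf_p - hf_p
            seg_kw: dict = {}
            if modulate:
                bounds, v = _window_segment_variances(
                    1.0 + spec.within_hrv_mod * profile, spec
                )
                seg_kw = {
                    "segment_bounds": bounds,
                    "segment_jitter_factors": np.sqrt(v),
                }
            data.nn_series[sid] = gen_rr_series(
                mean_rr=mean_rr,
                duration=spec.scan_duration,
                lf_amp=float(np.sqrt(2 * lf_p)),
                hf_amp=float(np.sqrt(2 * hf_p)),
                lf_freq=0.10,
                hf_freq=0.25,
                jitter_sd=float(np.sqrt(jitter_var)),
                seed=s_rr,
                **seg_kw,
            )
        if with_bold:
            bold_profile = profile if spec.within_coupling != 0 else None
            data.runs[sid] = gen_bold_run(
                row, spec, window_hrv_profile=bold_profile, seed=s_bold,
                dtype=dtype,
            )
    return data


def null_spec(spec: CohortSpec | None = None, **overrides) -> CohortSpec:
    """A copy of ``spec`` with every planted coupling set to zero."""
    base = spec if spec is not None else CohortSpec()
    return replace(
        base,
        hrv_sd_slope=0.0,
        age_sd_slope=0.0,
        within_coupling=0.0,
        **overrides,
    )
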