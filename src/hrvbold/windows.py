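"""Sliding-window within-person analysis of HRV–SD_BOLD coupling.

The resting-state scan is cut into overlapping windows (three 4-minute
windows at 50% overlap for an 8-minute scan).  Per window and subject we
compute HRV measures from the tachogram and mean SD_BOLD from the
window's volumes (blocks formed within the window, so each window is a
self-contained observation).  Windows holding more than a configurable
amount of artifact time are excluded.

Within-person HRV is isolated by person-centering: per subject and HRV
measure, subtract the subject mean and divide by the subject SD across
valid windows (sample divisor).  A linear mixed model of window mean
SD_BOLD on the person-centered and person-mean HRV terms (plus age, sex,
race) with a per-subject random intercept and a random slope on the
person-centered term separates within-person coupling from stable
between-person differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .hrv import NNIntervalSeries, UndefinedMeasureError, hrv_measures
from .sdbold import BoldRun, mean_sd, sd_bold_map

__all__ = [
    "WindowSpec",
    "MixedModelFit",
    "make_windows",
    "window_validity",
    "per_window_metrics",
    "person_center",
    "fit_within_model",
    "fit_age_model",
]

HRV_LOG_COLUMNS = ("log_sdnn", "log_rmssd", "log_lf", "log_hf")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry.

    ``overlap_fraction`` is the fraction of a window shared with its
    successor (0.5 for the standard three-window configuration).
    """

    scan_duration: float = 480.0
    window_length: float = 240.0
    overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError(
                f"overlap_fraction must be in [0, 1), got {self.overlap_fraction}"
            )
        if self.window_length > self.scan_duration:
            raise ValueError(
                f"window_length {self.window_length} s exceeds scan duration "
                f"{self.scan_duration} s"
            )
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")

    @property
    def step(self) -> float:
        return self.window_length * (1 - self.overlap_fraction)


def make_windows(spec: WindowSpec) -> list[tuple[float, float]]:
    """Ordered ``[start, end)`` window intervals.

    Windows start at multiples of ``window_length * (1 - overlap)``;
    the count is ``floor((scan - window) / step) + 1``.
    """
    step = spec.step
    n = int(np.floor((spec.scan_duration - spec.window_length) / step + 1e-9)) + 1
    return [(i * step, i * step + spec.window_length) for i in range(n)]


def window_validity(
    segments: list[tuple[float, float]],
    window: tuple[float, float],
    max_bad: float = 120.0,
) -> bool:
    """True unless artifact time intersecting the window exceeds ``max_bad`` s."""
    segs = sorted(segments)
    for (a0, a1), (b0, b1) in zip(segs, segs[1:]):
        if a1 > b0:
            raise ValueError(f"artifact segments overlap: {(a0, a1)} and {(b0, b1)}")
    w0, w1 = window
    bad = sum(max(0.0, min(s1, w1) - max(s0, w0)) for s0, s1 in segs)
    return bad <= max_bad


def per_window_metrics(
    run: BoldRun,
    nn: NNIntervalSeries,
    windows: list[tuple[float, float]],
    subject_id: str = "sub-0",
    artifact_segments: list[tuple[float, float]] | None = None,
    max_bad: float = 120.0,
    block_len: int = 10,
    divisor: str = "population",
) -> pd.DataFrame:
    """Per-window HRV and mean SD_BOLD for one subject.

    HRV intervals belong to the window containing their onset;
    overlapping windows share intervals by design.  SD_BOLD is computed
    from the window's volumes using only full blocks inside the window.
    Uncomputable windows (excess artifact, too few valid intervals, or
    fewer volumes than one block) are kept as rows flagged invalid with
    a reason code.
    """
    rows = []
    for w_idx, (start, end) in enumerate(windows):
        row: dict = {
            "subject_id": subject_id,
            "window_index": w_idx,
            "window_start_s": start,
            "window_end_s": end,
            "valid": True,
            "reason": "",
            "mean_sd_bold": np.nan,
        }
        for c in HRV_LOG_COLUMNS:
            row[c] = np.nan
        if artifact_segments and not window_validity(
            artifact_segments, (start, end), max_bad
        ):
            row["valid"] = False
            row["reason"] = "excess_artifact"
            rows.append(row)
            continue
        try:
            hm = hrv_measures(nn.slice_window(start, end))
            for c in HRV_LOG_COLUMNS:
                row[c] = getattr(hm, c)
        except UndefinedMeasureError as e:
            row["valid"] = False
            row["reason"] = f"hrv_undefined: {e}"
            rows.append(row)
            continue
        try:
            sub = run.restrict_to_times(start, end)
            smap = sd_bold_map(sub, block_len=block_len, divisor=divisor)
            row["mean_sd_bold"] = mean_sd(smap)
        except ValueError as e:
            row["valid"] = False
            row["reason"] = f"sdbold_undefined: {e}"
        rows.append(row)
    return pd.DataFrame(rows)


def person_center(
    table: pd.DataFrame,
    measure: str,
    min_windows: int = 2,
) -> pd.DataFrame:
    """Add person-centered and person-mean columns for one HRV measure.

    Per subject, over valid windows: ``{measure}_pm`` is the subject
    mean and ``{measure}_pc = (value - mean) / SD`` (sample divisor),
    a within-subject z-score.  Subjects with fewer than ``min_windows``
    valid windows, or zero within-subject variance, are dropped.
    """
    if measure not in table.columns:
        raise ValueError(f"unknown measure column {measure!r}")
    out = table[table["valid"] & table[measure].notna()].copy()
    dropped: list[str] = []
    pc, pm = f"{measure}_pc", f"{measure}_pm"
    out[pc] = np.nan
    out[pm] = np.nan
    for sid, grp in out.groupby("subject_id", sort=False):
        vals = grp[measure].to_numpy(float)
        if len(vals) < min_windows:
            dropped.append(str(sid))
            continue
        sd = np.std(vals, ddof=1)
        if sd == 0:
            dropped.append(str(sid))
            continue
        out.loc[grp.index, pm] = vals.mean()
        out.loc[grp.index, pc] = (vals - vals.mean()) / sd
    out = out[out[pc].notna()]
    if dropped:
        warnings.warn(
            f"person_center({measure}): dropped {len(dropped)} subject(s) "
            f"with < {min_windows} valid windows or zero within-subject "
            f"variance: {', '.join(dropped[:5])}"
            + ("..." if len(dropped) > 5 else "")
        )
    if len(out) == 0:
        raise ValueError(f"person_center({measure}): all subjects dropped")
    return out


@dataclass
class MixedModelFit:
    """Fixed-effect estimates from a within-person coupling model."""

    response: str
    fixed_effects: dict[str, dict[str, float]]  # name -> beta/se/t/p
    random_structure: str
    converged: bool
    fallback_used: bool
    n_obs: int
    n_subjects: int

    def effect(self, name: str) -> dict[str, float]:
        return self.fixed_effects[name]


def _collect_fit(result, response, structure, fallback) -> MixedModelFit:
    fe = {}
    for name in result.fe_params.index:
        fe[name] = {
            "beta": float(result.fe_params[name]),
            "se": float(result.bse_fe[name]),
            "t": float(result.tvalues[name]),
            "p": float(result.pvalues[name]),
        }
    return MixedModelFit(
        response=response,
        fixed_effects=fe,
        random_structure=structure,
        converged=bool(result.converged),
        fallback_used=fallback,
        n_obs=int(result.nobs),
        n_subjects=len(result.model.group_labels),
    )


def fit_within_model(
    table: pd.DataFrame,
    measure: str,
    covariates: tuple[str, ...] = ("age", "sex", "race"),
    min_subjects: int = 10,
) -> MixedModelFit:
    """Mixed model of window mean SD_BOLD on person-centered + mean HRV.

    Random intercept per subject and random slope on the person-centered
    term, fitted by REML.  If that structure fails to converge (three
    windows per subject often cannot identify a slope variance), the
    model is refitted with a random intercept only and flagged.
    """
    pc, pm = f"{measure}_pc", f"{measure}_pm"
    for col in (pc, pm, "mean_sd_bold", *covariates):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}; run person_center first")
    n_subj = table["subject_id"].nunique()
    if n_subj < min_subjects:
        raise ValueError(
            f"need >= {min_subjects} subjects with valid windows, got {n_subj}"
        )
    rhs = " + ".join([pc, pm, *covariates])
    formula = f"mean_sd_bold ~ {rhs}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = smf.mixedlm(
                formula, table, groups=table["subject_id"], re_formula=f"~{pc}"
            ).fit(reml=True)
            if res.converged and np.all(np.isfinite(res.fe_params)):
                return _collect_fit(
                    res, "mean_sd_bold",
                    f"random intercept + random slope({pc})", fallback=False,
                )
        except (np.linalg.LinAlgError, ValueError):
            pass
        res = smf.mixedlm(
            formula, table, groups=table["subject_id"], re_formula="~1"
        ).fit(reml=True)
    return _collect_fit(res, "mean_sd_bold", "random intercept", fallback=True)


def fit_age_model(
    table: pd.DataFrame,
    covariates: tuple[str, ...] = ("sex", "race"),
) -> MixedModelFit:
    """Mixed model of window mean SD_BOLD on age (random intercept only).

    Age is constant within subject, so no within-person term or random
    slope applies.
    """
    rhs = " + ".join(["age", *covariates])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = smf.mixedlm(
            f"mean_sd_bold ~ {rhs}",
            table[table["valid"]],
            groups=table[table["valid"]]["subject_id"],
            re_formula="~1",
        ).fit(reml=True)
    return _collect_fit(res, "mean_sd_bold", "random intercept", fallback=False)


def within_model_table(fits: dict[str, MixedModelFit]) -> pd.DataFrame:
    """Summary table: per HRV measure, person-centered and mean rows."""
    rows = []
    for measure, fit in fits.items():
        for label, term in (
            ("intercept", "Intercept"),
            ("person_centered", f"{measure}_pc"),
            ("person_mean", f"{measure}_pm"),
            ("age", "age"),
        ):
            if term not in fit.fixed_effects:
                continue
            eff = fit.fixed_effects[term]
            rows.append(
                {
                    "measure": measure,
                    "term": label,
                    "beta": eff["beta"],
                    "se": eff["se"],
                    "t": eff["t"],
                    "p": eff["p"],
                    "converged": fit.converged,
                    "fallback_used": fit.fallback_used,
                    "n_obs": fit.n_obs,
                    "n_subjects": fit.n_subjects,
                }
            )
    return pd.DataFrame(rows)
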