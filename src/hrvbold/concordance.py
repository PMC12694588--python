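"""Spatial concordance of age-model and HRV-model effects.

Each voxel is classified by the directions of its age and HRV
associations with SD_BOLD: concordant positive (both increase),
concordant negative (both decrease), opposite, or negligible.  Two
classification modes are supported, because the direction of an
association can be read either from the signed effect direction
(salience sign x brain-score slope sign) or from the raw salience sign
of each model's first latent variable; both are reported and the mode
is recorded on the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConcordanceMap", "classify_concordance", "CATEGORY_CODES"]

CATEGORY_CODES = {
    "concordant_positive": 1,
    "concordant_negative": 2,
    "opposite": 3,
    "negligible": 0,
}


@dataclass(frozen=True)
class ConcordanceMap:
    """Per-voxel concordance categories and their percentages."""

    category: np.ndarray          # int codes per CATEGORY_CODES
    percentages: dict[str, float]  # per category, of all voxels
    mode: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"mode": self.mode, **self.percentages}])


def classify_concordance(
    age_effects: np.ndarray,
    hrv_effects: np.ndarray,
    age_bsr: np.ndarray | None = None,
    hrv_bsr: np.ndarray | None = None,
    negligible_cutoff: float | None = None,
    mode: str = "effect_direction",
) -> ConcordanceMap:
    """Classify voxels by the agreement of two signed direction maps.

    ``age_effects`` and ``hrv_effects`` are per-voxel signed directions
    (+1 / -1 / 0) on a common voxel set.  Voxels where either direction
    is 0 are negligible; when ``negligible_cutoff`` is given, voxels
    whose |bootstrap ratio| falls below the cutoff in either map are
    negligible as well.  Percentages over the four categories sum to
    100.
    """
    a = np.sign(np.asarray(age_effects, dtype=float))
    h = np.sign(np.asarray(hrv_effects, dtype=float))
    if a.shape != h.shape:
        raise ValueError(
            f"direction maps must share a voxel set: {a.shape} vs {h.shape}"
        )
    negligible = (a == 0) | (h == 0)
    if negligible_cutoff is not None:
        if age_bsr is None or hrv_bsr is None:
            raise ValueError("negligible_cutoff requires both BSR maps")
        negligible |= (np.abs(age_bsr) <= negligible_cutoff) | (
            np.abs(hrv_bsr) <= negligible_cutoff
        )
    cat = np.full(a.shape, CATEGORY_CODES["negligible"], dtype=int)
    both_pos = ~negligible & (a > 0) & (h > 0)
    both_neg = ~negligible & (a < 0) & (h < 0)
    mixed = ~negligible & (a * h < 0)
    cat[both_pos] = CATEGORY_CODES["concordant_positive"]
    cat[both_neg] = CATEGORY_CODES["concordant_negative"]
    cat[mixed] = CATEGORY_CODES["opposite"]
    n = cat.size
    pct = {
        name: 100.0 * float(np.sum(cat == code)) / n
        for name, code in CATEGORY_CODES.items()
    }
    return ConcordanceMap(category=cat, percentages=pct, mode=mode)
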