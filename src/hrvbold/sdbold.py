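"""Voxelwise BOLD signal variability (SD_BOLD).

SD_BOLD quantifies the temporal variability of the BOLD signal at each
voxel while suppressing slow scanner drift:

1. the (drift-corrected) time series is cut into fixed-length temporal
   blocks (10 volumes by default);
2. each block is rescaled so that its 4D mean over in-mask voxels and
   block time points equals 100 (multiplying by ``100 / block 4D mean``),
   which removes multiplicative gain and slow intensity drift;
3. each voxel's within-block temporal mean is subtracted, the demeaned
   blocks are concatenated, and the standard deviation of the
   concatenated residual series is the voxel's SD_BOLD.

Any signal component that is constant within every block — including an
arbitrary step drift at block boundaries — contributes nothing, and the
map is invariant to a global intensity gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "BoldRun",
    "SdBoldMap",
    "drop_initial_volumes",
    "block_scale",
    "block_demean_concat",
    "sd_map",
    "sd_bold_map",
    "mean_sd",
    "load_bold_run",
    "save_bold_run",
    "save_sd_map",
    "sd_maps_to_frame",
]


@dataclass(frozen=True)
class BoldRun:
    """A 4D BOLD run: intensity lattice (x, y, z, t), TR and brain mask.

    ``t_offset`` carries the time of the first retained volume relative
    to scan start, so windows stay aligned with a simultaneously
    recorded tachogram after initial volumes are dropped.
    """

    data: np.ndarray
    tr: float
    mask: np.ndarray
    t_offset: float = 0.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        mask = np.asarray(self.mask, dtype=bool)
        if data.ndim != 4:
            raise ValueError(f"data must be 4-D (x,y,z,t), got shape {data.shape}")
        if data.shape[3] < 1:
            raise ValueError("run must contain at least one volume")
        if mask.shape != data.shape[:3]:
            raise ValueError(
                f"mask shape {mask.shape} does not match spatial dims "
                f"{data.shape[:3]}"
            )
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if not np.all(np.isfinite(data)):
            raise ValueError("run intensities must be finite")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "mask", mask)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def volume_times(self) -> np.ndarray:
        """Acquisition time of each volume (s, scan clock)."""
        return self.t_offset + np.arange(self.n_volumes) * self.tr

    def restrict_to_times(self, start_s: float, end_s: float) -> "BoldRun":
        """Volumes acquired in ``[start_s, end_s)`` as a new run."""
        sel = (self.volume_times >= start_s) & (self.volume_times < end_s)
        if not sel.any():
            raise ValueError(f"no volumes in window [{start_s}, {end_s}) s")
        first = int(np.flatnonzero(sel)[0])
        return BoldRun(
            self.data[..., sel], self.tr, self.mask,
            t_offset=float(self.volume_times[first]),
        )


@dataclass(frozen=True)
class SdBoldMap:
    """Per-voxel SD_BOLD values over the in-mask voxels of a run.

    ``values[i]`` belongs to the voxel at ``voxel_index[:, i]`` in the
    source lattice; ``n_blocks_used`` records how many full blocks
    entered the computation (trailing partial blocks are dropped).
    """

    values: np.ndarray
    mask: np.ndarray
    n_blocks_used: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if values.ndim != 1 or len(values) != int(mask.sum()):
            raise ValueError("values must be 1-D with one entry per masked voxel")
        if np.any(values < 0):
            raise ValueError("SD values must be non-negative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)

    @property
    def voxel_index(self) -> np.ndarray:
        """3 x n array of (x, y, z) indices for each value."""
        return np.asarray(np.nonzero(self.mask))

    def to_volume(self, background: float = 0.0) -> np.ndarray:
        """Render as a 3D array (``background`` outside the mask)."""
        vol = np.full(self.mask.shape, background, dtype=float)
        vol[self.mask] = self.values
        return vol


def drop_initial_volumes(run: BoldRun, k: int = 5) -> BoldRun:
    """Remove the first ``k`` volumes (T1 saturation transients)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if run.n_volumes <= k:
        raise ValueError(
            f"cannot drop {k} volumes from a run of {run.n_volumes}"
        )
    if k == 0:
        return run
    return BoldRun(
        run.data[..., k:], run.tr, run.mask, t_offset=run.t_offset + k * run.tr
    )


def _masked_2d(run: BoldRun) -> np.ndarray:
    """In-mask voxels as a (voxels, time) float64 matrix."""
    return run.data[run.mask].astype(np.float64, copy=False)


def block_scale(
    run: BoldRun,
    block_len: int = 10,
    use_mask: bool = True,
) -> tuple[np.ndarray, int]:
    """Scale each full block to a 4D mean of 100.

    The 4D mean is taken over in-mask voxels and the block's time points
    (over the whole field of view if ``use_mask`` is False).  Trailing
    volumes not filling a complete block are dropped.

    Returns ``(scaled, n_blocks)`` where ``scaled`` is a
    ``(n_masked_voxels, n_blocks * block_len)`` matrix.
    """
    if block_len < 1:
        raise ValueError("block_len must be >= 1")
    n_blocks = run.n_volumes // block_len
    if n_blocks < 1:
        raise ValueError(
            f"run of {run.n_volumes} volumes is shorter than one block "
            f"({block_len} volumes)"
        )
    t_used = n_blocks * block_len
    ts = _masked_2d(run)[:, :t_used]
    full = run.data.reshape(-1, run.n_volumes)[:, :t_used].astype(np.float64)
    scaled = ts.copy()
    for b in range(n_blocks):
        sl = slice(b * block_len, (b + 1) * block_len)
        m = ts[:, sl].mean() if use_mask else full[:, sl].mean()
        if m <= 0:
            raise ValueError(f"non-positive 4D mean in block {b}: {m}")
        scaled[:, sl] *= 100.0 / m
    return scaled, n_blocks


def block_demean_concat(scaled: np.ndarray, block_len: int = 10) -> np.ndarray:
    """Subtract each voxel's within-block temporal mean; concatenate.

    Input and output are (voxels, time) with time a whole number of
    blocks; the per-voxel per-block mean of the output is 0.
    """
    v, t = scaled.shape
    if t % block_len != 0 or t == 0:
        raise ValueError(
            f"time dimension {t} is not a whole number of {block_len}-volume blocks"
        )
    blocks = scaled.reshape(v, t // block_len, block_len)
    resid = blocks - blocks.mean(axis=2, keepdims=True)
    return resid.reshape(v, t)


def sd_map(
    residuals: np.ndarray,
    mask: np.ndarray,
    n_blocks_used: int,
    divisor: str = "population",
) -> SdBoldMap:
    """Per-voxel SD of the concatenated residual series.

    ``divisor`` is "population" (n, the default) or "sample" (n-1).
    """
    if residuals.shape[1] < 2:
        raise ValueError("concatenated series must have length >= 2")
    ddof = {"population": 0, "sample": 1}.get(divisor)
    if ddof is None:
        raise ValueError(f"divisor must be 'population' or 'sample', got {divisor!r}")
    values = residuals.std(axis=1, ddof=ddof)
    return SdBoldMap(values=values, mask=mask, n_blocks_used=n_blocks_used)


def sd_bold_map(
    run: BoldRun,
    block_len: int = 10,
    divisor: str = "population",
    use_mask_for_scaling: bool = True,
) -> SdBoldMap:
    """Full SD_BOLD pipeline: block-scale, block-demean, SD per voxel."""
    scaled, n_blocks = block_scale(run, block_len, use_mask=use_mask_for_scaling)
    resid = block_demean_concat(scaled, block_len)
    return sd_map(resid, run.mask, n_blocks, divisor=divisor)


def mean_sd(sdmap: SdBoldMap, subset: np.ndarray | None = None) -> float:
    """Mean SD_BOLD over a voxel subset (all in-mask voxels by default).

    ``subset`` is a boolean vector over the map's in-mask voxels.
    """
    if subset is None:
        vals = sdmap.values
    else:
        subset = np.asarray(subset, dtype=bool)
        if subset.shape != sdmap.values.shape:
            raise ValueError("subset must be a boolean vector over masked voxels")
        vals = sdmap.values[subset]
    if len(vals) == 0:
        raise ValueError("voxel subset is empty")
    return float(vals.mean())


# ---------------------------------------------------------------------------
# NIfTI / CSV I/O


def load_bold_run(bold_path: str | Path, mask_path: str | Path) -> BoldRun:
    """Load a 4D NIfTI run and 3D mask; TR is read from the header."""
    img = nib.load(str(bold_path))
    mask_img = nib.load(str(mask_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    mask = np.asarray(mask_img.dataobj) > 0
    tr = float(img.header.get_zooms()[3])
    return BoldRun(data=data, tr=tr, mask=mask)


def save_bold_run(run: BoldRun, bold_path: str | Path, mask_path: str | Path) -> None:
    """Write the run as 4D NIfTI-1 (TR in the header) plus a 3D mask."""
    img = nib.Nifti1Image(np.asarray(run.data, dtype=np.float32), affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, run.tr))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(bold_path))
    mimg = nib.Nifti1Image(run.mask.astype(np.uint8), affine=np.eye(4))
    nib.save(mimg, str(mask_path))


def save_sd_map(sdmap: SdBoldMap, nifti_path: str | Path | None = None,
                csv_path: str | Path | None = None) -> None:
    """Write a map as 3D NIfTI-1 (0 outside mask) and/or voxel-index CSV."""
    if nifti_path is not None:
        img = nib.Nifti1Image(sdmap.to_volume().astype(np.float32), np.eye(4))
        nib.save(img, str(nifti_path))
    if csv_path is not None:
        idx = sdmap.voxel_index
        pd.DataFrame(
            {"x": idx[0], "y": idx[1], "z": idx[2], "sd_bold": sdmap.values}
        ).to_csv(csv_path, index=False)


def sd_maps_to_frame(maps: dict[str, SdBoldMap]) -> pd.DataFrame:
    """Stack subjects' maps into a (subject x voxel) DataFrame."""
    masks = [m.mask for m in maps.values()]
    for m in masks[1:]:
        if not np.array_equal(m, masks[0]):
            raise ValueError("all maps must share the same mask")
    return pd.DataFrame(
        {sid: m.values for sid, m in maps.items()}
    ).T
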