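"""Tissue-contrast measures and regional aggregation.

Implements the image-quality and contrast formulas used to compare field
strengths and patient groups:

* contrast-to-noise ratio, ``CNR = |mW - mG| / sqrt(Wvar + Gvar)``, from
  labeled GM/WM intensity samples (volume voxels, or surface-mapped for
  the surface variant sCNR);
* gray-to-white percent contrast, ``GWc = 100 (W - G) / (0.5 (W + G))``,
  where W is white-matter intensity sampled just below the white surface
  and G gray-matter intensity sampled at fractional cortical depth;
* global SNR as mean brain-tissue intensity over the background noise SD;
* averaging vertex-wise values into the 68 atlas regions;
* background-noise masking of a quantitative T1 map by a PD-weighted image.

Intensity-sample collections are plain :class:`pandas.DataFrame` objects
with columns ``intensity`` (arbitrary units), ``tissue`` (``GM`` / ``WM``
/ ``background``) and optionally ``surface_sampled`` (bool), ``vertex_id``
and ``region``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import UNKNOWN_LABEL, desikan_killiany_labels

TISSUE_CLASSES = ("GM", "WM", "background")

MEASURES = ("CT", "GWc")


class DegenerateContrastError(ValueError):
    """Raised when a contrast formula hits a zero denominator."""


@dataclass
class RegionalMorphometryTable:
    """Per-subject regional values of one morphometric measure.

    Parameters
    ----------
    values
        Wide table, one row per subject (index = subject_id), one column
        per atlas region. Complete-case: no missing entries.
    measure
        ``"CT"`` (cortical thickness, mm) or ``"GWc"`` (percent contrast).
    group, field
        Cohort cell this table belongs to, e.g. ``("MS", "7T")``.
    """

    values: pd.DataFrame
    measure: str
    group: str | None = None
    field: str | None = None

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}; expected one of {MEASURES}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate subject ids: {dupes}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate region columns")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            bad = self.values.columns[~np.isfinite(arr).all(axis=0)].tolist()
            raise ValueError(f"missing or non-finite values in regions {bad}")
        if self.measure == "CT" and (arr <= 0).any():
            raise ValueError("cortical thickness values must be strictly positive")

    @property
    def regions(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    @property
    def cell(self) -> tuple[str | None, str | None]:
        return (self.group, self.field)


@dataclass(frozen=True)
class TissueIntensitySample:
    """One labeled intensity sample feeding the contrast formulas."""

    intensity: float
    tissue: str
    surface_sampled: bool = False
    vertex_id: int | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        if self.tissue not in TISSUE_CLASSES:
            raise ValueError(f"tissue must be one of {TISSUE_CLASSES}, got {self.tissue!r}")
        if not np.isfinite(self.intensity):
            raise ValueError("intensity must be finite")


def _as_frame(samples) -> pd.DataFrame:
    if isinstance(samples, pd.DataFrame):
        return samples
    return pd.DataFrame([
        {
            "intensity": s.intensity,
            "tissue": s.tissue,
            "surface_sampled": s.surface_sampled,
        }
        for s in samples
    ])


def _tissue_values(frame: pd.DataFrame, tissue: str) -> np.ndarray:
    return frame.loc[frame["tissue"] == tissue, "intensity"].to_numpy(dtype=float)


def compute_cnr(samples, denominator: str = "variance") -> float:
    """Contrast-to-noise ratio between WM and GM intensities.

    ``|mW - mG| / sqrt(Wvar + Gvar)`` where mG/mW are tissue means and
    Wvar/Gvar tissue variances (``denominator="variance"``, the default)
    or tissue standard deviations summed under the square root
    (``denominator="sd"``, an alternative convention).

    The statistic is invariant under adding a constant to all intensities
    and under multiplying all intensities by a positive constant.
    """
    if denominator not in ("variance", "sd"):
        raise ValueError("denominator must be 'variance' or 'sd'")
    frame = _as_frame(samples)
    gm = _tissue_values(frame, "GM")
    wm = _tissue_values(frame, "WM")
    if gm.size < 2 or wm.size < 2:
        raise ValueError(
            f"need at least 2 GM and 2 WM samples (got {gm.size} GM, {wm.size} WM)")
    g_var = float(np.var(gm, ddof=1))
    w_var = float(np.var(wm, ddof=1))
    if g_var == 0.0 and w_var == 0.0:
        raise DegenerateContrastError(
            "both tissue classes have zero variance: CNR denominator is zero")
    if denominator == "variance":
        denom = np.sqrt(w_var + g_var)
    else:
        denom = np.sqrt(np.sqrt(w_var) + np.sqrt(g_var))
    return float(abs(wm.mean() - gm.mean()) / denom)


def compute_scnr(samples, denominator: str = "variance") -> float:
    """Surface-based CNR: the CNR formula on surface-mapped samples only."""
    frame = _as_frame(samples)
    if "surface_sampled" not in frame.columns:
        raise ValueError("samples carry no 'surface_sampled' flag")
    surface = frame.loc[frame["surface_sampled"].astype(bool)]
    if surface.empty:
        raise ValueError("no surface-sampled intensities available for sCNR")
    return compute_cnr(surface, denominator=denominator)


def compute_snr(samples) -> float:
    """Global SNR: mean brain-tissue (GM+WM) intensity / background SD.

    No closed-form SNR convention accompanies the contrast formulas, so
    the standard mean-signal-over-noise-SD definition is used; see the
    methods note.
    """
    frame = _as_frame(samples)
    brain = frame.loc[frame["tissue"].isin(["GM", "WM"]), "intensity"].to_numpy(dtype=float)
    noise = _tissue_values(frame, "background")
    if brain.size == 0 or noise.size < 2:
        raise ValueError("SNR needs brain-tissue samples and >= 2 background samples")
    noise_sd = float(np.std(noise, ddof=1))
    if noise_sd == 0.0:
        raise DegenerateContrastError("background noise has zero variance")
    return float(brain.mean() / noise_sd)


def compute_gwc(w_intensity, g_intensity):
    """Gray-to-white percent contrast ``100 (W - G) / (0.5 (W + G))``.

    Positive when WM is brighter than GM; scale-invariant under a common
    positive rescaling of both intensities (but not under a common
    additive offset). Accepts scalars or arrays (elementwise).
    """
    w = np.asarray(w_intensity, dtype=float)
    g = np.asarray(g_intensity, dtype=float)
    denom = 0.5 * (w + g)
    if np.any(denom == 0.0):
        raise DegenerateContrastError("W + G = 0: percent-contrast denominator is zero")
    out = 100.0 * (w - g) / denom
    if out.ndim == 0:
        return float(out)
    return out


def aggregate_regional(
    vertex_values: pd.DataFrame,
    region_labels: list[str] | None = None,
    value_column: str = "value",
) -> pd.Series:
    """Average vertex-wise values into atlas regions.

    Parameters
    ----------
    vertex_values
        One row per vertex with columns ``region`` and `value_column`.
        Vertices labeled ``"unknown"`` (medial wall) are excluded.
    region_labels
        Expected atlas regions (default: the 68 Desikan-Killiany labels).
        A region with no labeled vertex is an error.

    Returns
    -------
    pandas.Series of regional means, indexed by `region_labels` in order.
    """
    if region_labels is None:
        region_labels = desikan_killiany_labels()
    if "region" not in vertex_values.columns or value_column not in vertex_values.columns:
        raise ValueError(f"vertex table needs 'region' and {value_column!r} columns")
    labeled = vertex_values.loc[vertex_values["region"] != UNKNOWN_LABEL]
    means = labeled.groupby("region")[value_column].mean()
    missing = [r for r in region_labels if r not in means.index]
    if missing:
        raise ValueError(f"regions with zero labeled vertices: {missing}")
    return means.reindex(region_labels)


def mask_background(
    t1_map: np.ndarray,
    pd_image: np.ndarray,
    threshold: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mask amplified background noise in a quantitative T1 map.

    The T1 map (whose reconstruction amplifies noise outside the head) is
    multiplied voxel-wise by a PD-weighted image that is dark in the
    background; voxels where the product exceeds `threshold` form the
    brain mask. Returns ``(masked_t1, mask)`` where the masked map equals
    the T1 map inside the mask and 0 outside.
    """
    t1 = np.asarray(t1_map, dtype=float)
    pd_img = np.asarray(pd_image, dtype=float)
    if t1.shape != pd_img.shape:
        raise ValueError(f"shape mismatch: T1 {t1.shape} vs PD {pd_img.shape}")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    mask = (t1 * pd_img) > threshold
    return np.where(mask, t1, 0.0), mask
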