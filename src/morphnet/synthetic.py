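"""Synthetic cohorts with modular structural-covariance structure.

The generator emulates the statistical features the downstream analysis
assumes, so that every stage — contrast formulas, covariance networks,
null-normalized graph metrics, group statistics — can be exercised
without any scan data:

* a 2x2 design (group HC/MS x field 3T/7T) over 68 Desikan-Killiany
  regions, with cortical thickness (CT, mm) lower and gray-white contrast
  (GWc, percent) higher at 7T than 3T, and the MS-like group showing
  lower CT and higher GWc than controls;
* an inter-regional block-correlation structure induced by a latent
  factor model: one shared factor, one factor per module, and
  idiosyncratic noise, giving within-module correlation ``w`` and
  between-module correlation ``b`` by construction (positive
  semi-definite for any 0 <= b <= w < 1);
* subject demographics (age, sex) and group-shifted lesion-load /
  brain-volume columns so the demographics tests have inputs.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
import pandas as pd

from .atlas import desikan_killiany_labels
from .morphometry import RegionalMorphometryTable

GROUPS = ("HC", "MS")
FIELDS = ("3T", "7T")
#: Fixed cell order so the random stream is independent of dict ordering.
CELLS = (("HC", "3T"), ("HC", "7T"), ("MS", "3T"), ("MS", "7T"))


def _default_n_per_cell() -> dict[tuple[str, str], int]:
    # Mirrors the study cells: 30 + 7 controls at 3T, 40 + 7 at 7T,
    # 7 patients per field.
    return {("HC", "3T"): 37, ("HC", "7T"): 47, ("MS", "3T"): 7, ("MS", "7T"): 7}


def _default_baseline(n_regions: int, center: float, spread: float) -> np.ndarray:
    """Deterministic per-region baseline with a plausible regional spread.

    A fixed-seed draw (independent of the cohort seed) so that regional
    profiles vary across the cortex — which the 3T/7T correspondence
    regression needs — while remaining identical across cohorts.
    """
    rng = np.random.default_rng(8675309)
    return center + spread * rng.uniform(-1.0, 1.0, size=n_regions)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic four-cell cohort.

    Effects are additive shifts in measure units applied on top of the
    per-region baselines; the latent block-correlation structure is
    parameterized per group so the MS-like cell can be made more
    segregated (higher within-module correlation) than controls.
    """

    n_subjects_per_cell: Mapping[tuple[str, str], int] | int = dc_field(
        default_factory=_default_n_per_cell)
    n_regions: int = 68
    region_labels: tuple[str, ...] | None = None
    ct_baseline: float | np.ndarray | None = None    # mm per region
    gwc_baseline: float | np.ndarray | None = None   # percent per region
    field_effect_ct: float = -0.20     # mm, applied at 7T
    field_effect_gwc: float = 2.0      # percent, applied at 7T
    disease_effect_ct: float = -0.12   # mm, applied in MS
    disease_effect_gwc: float = 1.0    # percent, applied in MS
    n_modules: int = 4
    within_module_corr: Mapping[str, float] = dc_field(
        default_factory=lambda: {"HC": 0.45, "MS": 0.60})
    between_module_corr: Mapping[str, float] = dc_field(
        default_factory=lambda: {"HC": 0.15, "MS": 0.15})
    subject_sd_ct: float = 0.15        # mm, total per-subject SD around the cell mean
    subject_sd_gwc: float = 1.5        # percent
    age_range: tuple[float, float] = (19.0, 60.0)
    sex_ratio: float = 0.5             # fraction female
    seed: int = 0

    def __post_init__(self) -> None:
        labels = self.region_labels
        if labels is None:
            labels = tuple(desikan_killiany_labels()) if self.n_regions == 68 else tuple(
                f"region_{i:03d}" for i in range(self.n_regions))
            object.__setattr__(self, "region_labels", labels)
        if len(labels) != self.n_regions:
            raise ValueError(
                f"n_regions={self.n_regions} but {len(labels)} region labels given")
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        if self.n_modules < 1 or self.n_modules > self.n_regions:
            raise ValueError("n_modules must be in [1, n_regions]")
        for group in GROUPS:
            w = self.within_module_corr[group]
            b = self.between_module_corr[group]
            if not (0.0 <= b <= w < 1.0):
                raise ValueError(
                    "latent correlation block for group "
                    f"{group!r} is not realizable by the factor model "
                    f"(need 0 <= between <= within < 1, got within={w}, between={b})")
            if b >= w and not (w == b == 0.0):
                raise ValueError(
                    f"within_module_corr must exceed between_module_corr for group {group!r}")
        if isinstance(self.n_subjects_per_cell, int):
            if self.n_subjects_per_cell <= 0:
                raise ValueError("n_subjects_per_cell must be positive")
        else:
            for cell in CELLS:
                if self.n_subjects_per_cell.get(cell, 0) <= 0:
                    raise ValueError(f"n_subjects_per_cell missing or <= 0 for cell {cell}")
        if self.subject_sd_ct < 0 or self.subject_sd_gwc < 0:
            raise ValueError("subject SDs must be >= 0")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ValueError("sex_ratio must be in [0, 1]")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be (low, high)")

    def n_in_cell(self, cell: tuple[str, str]) -> int:
        if isinstance(self.n_subjects_per_cell, int):
            return self.n_subjects_per_cell
        return self.n_subjects_per_cell[cell]

    def module_of(self) -> np.ndarray:
        """Region index -> module index (contiguous blocks over the label list)."""
        return np.repeat(
            np.arange(self.n_modules),
            np.diff(np.round(np.linspace(0, self.n_regions, self.n_modules + 1)).astype(int)),
        )

    def baseline(self, measure: str) -> np.ndarray:
        if measure == "CT":
            base = self.ct_baseline
            default = _default_baseline(self.n_regions, 2.5, 0.4)
        else:
            base = self.gwc_baseline
            default = _default_baseline(self.n_regions, 20.0, 3.0)
        if base is None:
            return default
        return np.broadcast_to(np.asarray(base, dtype=float), (self.n_regions,)).copy()


@dataclass
class Cohort:
    """Generated cohort: regional tables per (measure, group, field) plus metadata."""

    config: CohortConfig
    tables: dict[tuple[str, str, str], RegionalMorphometryTable]
    subjects: pd.DataFrame

    def table(self, measure: str, group: str, field: str) -> RegionalMorphometryTable:
        return self.tables[(measure, group, field)]

    def to_long(self) -> pd.DataFrame:
        """Long format: subject_id, group, field, measure, region, value."""
        rows = []
        for (measure, group, field), table in self.tables.items():
            long = table.values.stack().rename("value").reset_index()
            long.columns = ["subject_id", "region", "value"]
            long.insert(1, "group", group)
            long.insert(2, "field", field)
            long.insert(3, "measure", measure)
            rows.append(long)
        return pd.concat(rows, ignore_index=True)


def _latent_block_signal(
    rng: np.random.Generator,
    n_subjects: int,
    module_of: np.ndarray,
    within: float,
    between: float,
) -> np.ndarray:
    """Unit-variance signal with corr `within` inside modules, `between` across.

    z_r = sqrt(b) g + sqrt(w-b) f_{m(r)} + sqrt(1-w) e_r with independent
    standard-normal g (shared), f (per module) and e (per region).
    """
    n_modules = int(module_of.max()) + 1 if module_of.size else 0
    shared = rng.standard_normal((n_subjects, 1))
    module = rng.standard_normal((n_subjects, n_modules))
    idio = rng.standard_normal((n_subjects, module_of.size))
    return (np.sqrt(between) * shared
            + np.sqrt(within - between) * module[:, module_of]
            + np.sqrt(1.0 - within) * idio)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the four-cell cohort for both measures.

    Subject values = per-region baseline + field effect (7T cells) +
    disease effect (MS cells) + subject_sd * latent block signal. The
    latent signal induces the configured within/between-module
    correlations; CT and GWc draw independent latents. Identical config
    (including seed) gives bit-identical output.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(len(CELLS) + 1)
    module_of = config.module_of()
    tables: dict[tuple[str, str, str], RegionalMorphometryTable] = {}
    subject_rows = []

    for cell_idx, (group, field) in enumerate(CELLS):
        rng = np.random.default_rng(seeds[cell_idx])
        n = config.n_in_cell((group, field))
        ids = [f"{group}{field}_{i:03d}" for i in range(n)]
        w = config.within_module_corr[group]
        b = config.between_module_corr[group]
        for measure, sd, base, f_eff, d_eff in (
            ("CT", config.subject_sd_ct, config.baseline("CT"),
             config.field_effect_ct, config.disease_effect_ct),
            ("GWc", config.subject_sd_gwc, config.baseline("GWc"),
             config.field_effect_gwc, config.disease_effect_gwc),
        ):
            z = _latent_block_signal(rng, n, module_of, w, b)
            shift = (f_eff if field == "7T" else 0.0) + (d_eff if group == "MS" else 0.0)
            values = base[None, :] + shift + sd * z
            frame = pd.DataFrame(values, index=pd.Index(ids, name="subject_id"),
                                 columns=list(config.region_labels))
            tables[(measure, group, field)] = RegionalMorphometryTable(
                values=frame, measure=measure, group=group, field=field)

        ages = rng.uniform(config.age_range[0], config.age_range[1], size=n)
        sexes = np.where(rng.random(n) < config.sex_ratio, "F", "M")
        if group == "MS":
            wml = np.clip(rng.normal(4.2, 3.0, size=n), 0.1, None)
            bpv = rng.normal(975_000.0, 65_000.0, size=n)
        else:
            wml = np.clip(rng.normal(1.3, 0.5, size=n), 0.1, None)
            bpv = rng.normal(1_050_000.0, 100_000.0, size=n)
        for i, sid in enumerate(ids):
            subject_rows.append({
                "subject_id": sid, "group": group, "field": field,
                "age": ages[i], "sex": sexes[i],
                "wml_volume": wml[i], "bpv": bpv[i],
            })

    subjects = pd.DataFrame(subject_rows)
    return Cohort(config=config, tables=tables, subjects=subjects)


def generate_intensity_fixture(
    n_samples: int,
    mean_gm: float = 90.0,
    mean_wm: float = 110.0,
    sd_gm: float = 10.0,
    sd_wm: float = 10.0,
    background_fraction: float = 0.2,
    seed: int = 0,
    surface_offset_gm: float = 0.0,
    surface_offset_wm: float = 0.0,
) -> pd.DataFrame:
    """Labeled Gaussian intensity samples for the contrast formulas.

    Draws `n_samples` GM and `n_samples` WM intensities per sampling mode
    (volume and surface-mapped), plus background-noise samples making up
    `background_fraction` of the volume draw. Surface samples take the
    same tissue moments shifted by the ``surface_offset_*`` arguments
    (the white-surface WM sample sits 1 mm below the boundary and the GM
    sample 30% into the cortical depth, so their intensities need not
    match the volume averages). Deterministic under `seed`.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    if sd_gm < 0 or sd_wm < 0:
        raise ValueError("tissue SDs must be >= 0")
    if not (0.0 <= background_fraction < 1.0):
        raise ValueError("background_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_bg = int(round(2 * n_samples * background_fraction / (1.0 - background_fraction)))

    parts = []
    for surface, off_g, off_w in ((False, 0.0, 0.0),
                                  (True, surface_offset_gm, surface_offset_wm)):
        for tissue, mean, sd, off in (("GM", mean_gm, sd_gm, off_g),
                                      ("WM", mean_wm, sd_wm, off_w)):
            vals = mean + off + sd * rng.standard_normal(n_samples)
            parts.append(pd.DataFrame({
                "intensity": vals, "tissue": tissue, "surface_sampled": surface}))
    if n_bg > 0:
        noise_scale = 0.05 * max(abs(mean_gm), abs(mean_wm), 1.0)
        bg = np.abs(rng.normal(0.0, noise_scale, size=n_bg))
        parts.append(pd.DataFrame({
            "intensity": bg, "tissue": "background", "surface_sampled": False}))
    return pd.concat(parts, ignore_index=True)
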