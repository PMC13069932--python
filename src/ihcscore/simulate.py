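"""Synthetic data generators.

The original patient images and cohort are not public, so every
downstream stage is exercised on synthetic inputs with known ground
truth:

* field images — a membrane-ring (or blob) stain pattern painted at a
  known gray level on a near-white background, with optional Gaussian
  acquisition noise; the realized stained fraction and mean stained gray
  value are recorded alongside the image and never consulted by the
  analysis code;
* cohorts — per-case (mean intensity, percent area) pairs drawn
  independently from normal distributions truncated to the published
  per-group ranges for FISH-negative and FISH-positive 2+ disease, plus
  optional IHC 0/1+/3+ control groups drawn directly at the HScore
  level;
* raw enrollment tables with completeness flags, to drive the
  exclusion-accounting stage.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Mapping, Optional

import numpy as np
import pandas as pd
from PIL import Image
from scipy import stats
from skimage import draw


# --------------------------------------------------------------------------
# distributional building block
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TruncNormal:
    """Normal distribution truncated to [lower, upper].

    Published summaries give only mean, SD and range per group;
    truncating to the printed range keeps draws physically possible
    (no negative areas, no gray values past white).
    """

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"sd must be > 0, got {self.sd}")
        if not self.lower < self.upper:
            raise ValueError(f"empty range [{self.lower}, {self.upper}]")
        if not self.lower <= self.mean <= self.upper:
            raise ValueError(
                f"truncation range [{self.lower}, {self.upper}] excludes mean {self.mean}"
            )

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                   size=n, random_state=rng)


# --------------------------------------------------------------------------
# field images
# --------------------------------------------------------------------------

Pattern = Literal["membrane-rings", "blobs"]


@dataclass(frozen=True)
class ImageSpec:
    """Parameters of one synthetic brightfield field."""

    width: int = 256
    height: int = 256
    background_level: int = 245
    stain_level: int = 103
    target_area_fraction: float = 0.068
    noise_sd: float = 3.0
    pattern: Pattern = "membrane-rings"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be positive")
        if not 0 <= self.stain_level <= 255 or not 0 <= self.background_level <= 255:
            raise ValueError("gray levels must lie in [0, 255]")
        if self.stain_level >= self.background_level:
            raise ValueError(
                f"stain_level ({self.stain_level}) must be darker than "
                f"background_level ({self.background_level})"
            )
        if not 0.0 <= self.target_area_fraction <= 1.0:
            raise ValueError("target_area_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class FieldGroundTruth:
    """Realized truth recorded next to each generated image."""

    stain_fraction: float
    stain_mean_intensity: float
    seed: int


def _paint_pattern(spec: ImageSpec, rng: np.random.Generator) -> np.ndarray:
    """Boolean stain mask with exactly round(f * N) true pixels."""
    h, w = spec.height, spec.width
    n_target = int(round(spec.target_area_fraction * h * w))
    mask = np.zeros((h, w), dtype=bool)
    if n_target == 0:
        return mask
    # membrane staining shows as annuli around cell outlines; blobs are
    # filled ellipses for robustness checks
    for _ in range(10_000):
        if mask.sum() >= n_target:
            break
        r0 = rng.integers(0, h)
        c0 = rng.integers(0, w)
        r_out = rng.integers(6, max(7, min(h, w) // 8))
        rr, cc = draw.ellipse(r0, c0, r_out, r_out, shape=(h, w))
        if spec.pattern == "membrane-rings":
            ring = np.zeros((h, w), dtype=bool)
            ring[rr, cc] = True
            r_in = max(1, r_out - 2)
            ri, ci = draw.ellipse(r0, c0, r_in, r_in, shape=(h, w))
            ring[ri, ci] = False
            mask |= ring
        else:
            mask[rr, cc] = True
    # land exactly on the target count: trim surplus / back-fill deficit
    excess = int(mask.sum()) - n_target
    if excess > 0:
        on = np.flatnonzero(mask.ravel())
        off_idx = rng.choice(on, size=excess, replace=False)
        mask.ravel()[off_idx] = False
    elif excess < 0:
        off = np.flatnonzero(~mask.ravel())
        on_idx = rng.choice(off, size=-excess, replace=False)
        mask.ravel()[on_idx] = True
    return mask


def generate_field_image(spec: ImageSpec) -> tuple[np.ndarray, FieldGroundTruth]:
    """Render one synthetic field and its ground truth.

    Returns an 8-bit gray image plus the realized stained fraction and
    the realized mean gray value over stained pixels (equal to the
    painted ``stain_level`` when ``noise_sd`` is zero).
    """
    rng = np.random.default_rng(spec.seed)
    mask = _paint_pattern(spec, rng)
    img = np.full((spec.height, spec.width), float(spec.background_level))
    img[mask] = float(spec.stain_level)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    n_stained = int(mask.sum())
    truth = FieldGroundTruth(
        stain_fraction=n_stained / img.size,
        stain_mean_intensity=float(img[mask].mean()) if n_stained else float("nan"),
        seed=spec.seed,
    )
    return img, truth


def write_field_images(
    specs: Mapping[str, ImageSpec],
    out_dir: str | Path,
) -> pd.DataFrame:
    """Write PNG images plus a ground-truth sidecar CSV; returns the sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for field_id, spec in specs.items():
        img, truth = generate_field_image(spec)
        Image.fromarray(img, mode="L").save(out_dir / f"{field_id}.png")
        rows.append({
            "field_id": field_id,
            "stain_fraction": truth.stain_fraction,
            "stain_mean_intensity": truth.stain_mean_intensity,
            "seed": truth.seed,
        })
    sidecar = pd.DataFrame(rows)
    sidecar.to_csv(out_dir / "ground_truth.csv", index=False)
    return sidecar


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FishGroupSpec:
    """Slide-level measurement distributions for one FISH group."""

    intensity: TruncNormal
    area: TruncNormal


@dataclass(frozen=True)
class ControlGroupSpec:
    """Score-level distribution for an IHC 0/1+/3+ control group."""

    hscore: TruncNormal
    n: int


# Published per-group moments of the 182-case equivocal (IHC 2+) cohort:
# mean intensity and percent stained area, as mean / SD / range.
NEGATIVE_DEFAULT = FishGroupSpec(
    intensity=TruncNormal(113.3, 13.9, 66.4, 142.8),
    area=TruncNormal(6.3, 1.9, 2.6, 13.8),
)
POSITIVE_DEFAULT = FishGroupSpec(
    intensity=TruncNormal(103.82, 20.8, 59.1, 126.4),
    area=TruncNormal(6.8, 2.1, 3.6, 11.9),
)

# Published HScore moments of the IHC expression-level groups
# (mean / SD / range, n=10 controls per non-equivocal category).
CONTROL_DEFAULTS: dict[int, ControlGroupSpec] = {
    0: ControlGroupSpec(TruncNormal(3.35, 0.74, 2.10, 4.51), n=10),
    1: ControlGroupSpec(TruncNormal(2.56, 0.97, 1.51, 4.55), n=10),
    3: ControlGroupSpec(TruncNormal(4.02, 1.43, 2.46, 6.75), n=10),
}

# Published HScore moments of the 2+ cohort itself (score-level), used by
# tests that compare expression categories on a common score scale.
TWO_PLUS_HSCORE = TruncNormal(2.65, 0.88, 1.16, 6.43)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full cohort-generator parameterization.

    Defaults reproduce the published study conditions: 182 equivocal
    cases of which 13 are FISH positive, with per-group truncated-normal
    intensity and area distributions at the printed moments.
    """

    negative: FishGroupSpec = NEGATIVE_DEFAULT
    positive: FishGroupSpec = POSITIVE_DEFAULT
    n_negative: int = 169
    n_positive: int = 13
    controls: Optional[Mapping[int, ControlGroupSpec]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_negative < 1 or self.n_positive < 1:
            raise ValueError("need at least one case per FISH group")
        if self.controls is not None:
            bad = set(self.controls) - {0, 1, 3}
            if bad:
                raise ValueError(f"control groups must be IHC 0/1/3, got {sorted(bad)}")

    def with_controls(self) -> "SyntheticSpec":
        """Copy of this spec with the published control groups attached."""
        return replace(self, controls=dict(CONTROL_DEFAULTS))


def generate_cohort(spec: SyntheticSpec) -> pd.DataFrame:
    """Draw one synthetic cohort as a tidy case table.

    Columns: case_id, ihc_category, fish_status, mean_intensity,
    pct_area, hscore (NaN for 2+ cases — recomputed downstream; drawn
    directly for score-level control groups), age (placeholder
    covariate). Intensity and area are drawn independently, consistent
    with the reported lack of correlation between them.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for status, group, n in (
        ("negative", spec.negative, spec.n_negative),
        ("positive", spec.positive, spec.n_positive),
    ):
        frames.append(pd.DataFrame({
            "ihc_category": 2,
            "fish_status": status,
            "mean_intensity": group.intensity.draw(rng, n),
            "pct_area": group.area.draw(rng, n),
            "hscore": np.nan,
        }))
    if spec.controls:
        for cat in sorted(spec.controls):
            ctrl = spec.controls[cat]
            frames.append(pd.DataFrame({
                "ihc_category": cat,
                "fish_status": "unavailable",
                "mean_intensity": np.nan,
                "pct_area": np.nan,
                "hscore": ctrl.hscore.draw(rng, ctrl.n),
            }))
    cohort = pd.concat(frames, ignore_index=True)
    cohort.insert(0, "case_id", [f"case-{i:04d}" for i in range(len(cohort))])
    cohort["age"] = rng.integers(30, 81, size=len(cohort))
    return cohort


def generate_raw_enrollment(
    n_total: int,
    n_incomplete: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Enrollment table with completeness flags.

    Exactly ``n_incomplete`` records carry at least one of the two
    exclusion flags (missing clinical data, unavailable slide); which
    records and which flag(s) are pseudo-random by seed.
    """
    if n_total < 0 or n_incomplete < 0:
        raise ValueError("counts must be non-negative")
    if n_incomplete > n_total:
        raise ValueError(f"n_incomplete ({n_incomplete}) exceeds n_total ({n_total})")
    rng = np.random.default_rng(seed)
    missing_clinical = np.zeros(n_total, dtype=bool)
    missing_slide = np.zeros(n_total, dtype=bool)
    flagged = rng.choice(n_total, size=n_incomplete, replace=False) if n_incomplete else []
    for i in flagged:
        reason = rng.integers(0, 3)  # 0: clinical, 1: slide, 2: both
        missing_clinical[i] = reason in (0, 2)
        missing_slide[i] = reason in (1, 2)
    return pd.DataFrame({
        "case_id": [f"enroll-{i:04d}" for i in range(n_total)],
        "missing_clinical": missing_clinical,
        "missing_slide": missing_slide,
    })
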