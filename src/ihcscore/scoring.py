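"""Optical-density HScore.

The score combines the two field measurements into one number per case:

    OD     = log10(255 / mean_intensity)
    HScore = OD * (pct_area + 1)

with ``pct_area`` in percent units. Darker staining (lower mean
intensity) and a larger stained area both raise the score; a pure-white
field (mean intensity 255) scores exactly zero. The log base and the
percent-unit convention are pinned down numerically by the unit tests:
no other common reading reproduces the published group means.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .imaging import WHITE_REF

logger = logging.getLogger(__name__)

#: Floor applied to mean intensity before the log transform; a literal
#: 0 gray value would send the optical density to infinity.
MIN_INTENSITY = 1.0


class HScoreValidationError(ValueError):
    """A precomputed hscore column disagrees with recomputation."""


def optical_density(mean_intensity: float) -> float:
    """log10(255 / mean_intensity); 0 for reference white."""
    if mean_intensity <= 0:
        raise ValueError(f"mean intensity must be positive, got {mean_intensity}")
    if mean_intensity < MIN_INTENSITY:
        logger.warning("mean intensity %g clamped to %g", mean_intensity, MIN_INTENSITY)
        mean_intensity = MIN_INTENSITY
    return math.log10(WHITE_REF / mean_intensity)


def hscore(mean_intensity: float, pct_area: float) -> float:
    """Optical density times (percent area stained + 1)."""
    if not 0.0 <= pct_area <= 100.0:
        raise ValueError(f"pct_area must be a percentage in [0, 100], got {pct_area}")
    return optical_density(mean_intensity) * (pct_area + 1.0)


def score_cohort(
    cohort: pd.DataFrame,
    validate: bool = True,
    atol: float = 1e-9,
) -> pd.DataFrame:
    """Fill (or validate) per-case ``od`` and ``hscore`` columns.

    Cases missing ``mean_intensity`` or ``pct_area`` keep any hscore
    they arrived with (the synthetic IHC 0/1+/3+ controls are generated
    at the score level) or get NaN; they are flagged in a boolean
    ``score_missing`` column and logged.

    If a precomputed ``hscore`` column is present and ``validate`` is
    true, it is checked against recomputation to ``atol``; disagreement
    raises :class:`HScoreValidationError` naming the offending cases.
    """
    out = cohort.copy()
    mi = pd.to_numeric(out["mean_intensity"], errors="coerce")
    pa = pd.to_numeric(out["pct_area"], errors="coerce")
    computable = mi.notna() & pa.notna()
    if ((mi[computable] <= 0) | (pa[computable] < 0) | (pa[computable] > 100)).any():
        raise ValueError("mean_intensity must be > 0 and pct_area in [0, 100]")

    od = np.full(len(out), np.nan)
    hs = np.full(len(out), np.nan)
    mi_c = np.maximum(mi[computable].to_numpy(float), MIN_INTENSITY)
    od[computable.to_numpy()] = np.log10(WHITE_REF / mi_c)
    hs[computable.to_numpy()] = od[computable.to_numpy()] * (
        pa[computable].to_numpy(float) + 1.0
    )

    had_hscore = "hscore" in out.columns
    if had_hscore and validate:
        prior = pd.to_numeric(out["hscore"], errors="coerce")
        check = computable & prior.notna()
        bad = check & (np.abs(prior - hs) > atol)
        if bad.any():
            ids = out.loc[bad, "case_id"].tolist() if "case_id" in out else list(out.index[bad])
            raise HScoreValidationError(
                f"precomputed hscore disagrees with recomputation for cases: {ids}"
            )
    if had_hscore:
        # keep arriving scores where inputs are absent (score-level controls)
        hs = np.where(computable, hs, pd.to_numeric(out["hscore"], errors="coerce"))

    out["od"] = od
    out["hscore"] = hs
    out["score_missing"] = ~np.isfinite(out["hscore"].to_numpy(float))
    n_missing = int(out["score_missing"].sum())
    if n_missing:
        logger.warning("%d case(s) lack scoreable inputs; flagged score_missing", n_missing)
    return out
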