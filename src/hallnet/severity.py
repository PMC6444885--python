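"""Composite hallucination severity score (HSS) and demographic correlations.

The HSS is the sum of the two z-scored severity components: the percentage
of misperceptions on the bistable-percept task and the hallucination
questionnaire total. Standardization uses the cohort mean and the sample
(n-1) standard deviation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortManifest, OPTIONAL_MANIFEST_COLS

logger = logging.getLogger(__name__)

NORMALITY_ALPHA = 0.05


class DegenerateInputError(ValueError):
    """Input without the variance the computation requires."""


def compute_hss(manifest: CohortManifest) -> pd.DataFrame:
    """Per-subject z-scores of both components and their sum (the HSS).

    Requires at least 3 subjects and nonzero variance in both components.
    """
    df = manifest.frame
    if len(df) < 3:
        raise DegenerateInputError("need >= 3 subjects to standardize")
    out = pd.DataFrame({"subject_id": df["subject_id"].astype(str)})
    for col, zcol in (("bpp_pct", "z_bpp"), ("psychq_a", "z_psychq")):
        x = df[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise DegenerateInputError(f"zero variance in component {col!r}")
        out[zcol] = (x - x.mean()) / sd
    out["hss"] = out["z_bpp"] + out["z_psychq"]
    return out


def correlate_demographics(severity: pd.DataFrame, manifest: CohortManifest,
                           variables: tuple[str, ...] = OPTIONAL_MANIFEST_COLS,
                           ) -> pd.DataFrame:
    """Correlate the HSS with demographic variables.

    Pearson when both the HSS and the variable pass a Shapiro-Wilk
    normality screen at alpha=0.05, Spearman otherwise; two-sided p.
    Variables with fewer than 4 complete pairs are skipped with a warning.
    """
    hss = severity["hss"].to_numpy(dtype=float)
    rows = []
    for var in variables:
        if var not in manifest.frame.columns:
            continue
        x = manifest.frame[var].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(hss)
        if ok.sum() < 4:
            logger.warning("variable %r skipped: <4 complete pairs", var)
            continue
        xv, hv = x[ok], hss[ok]
        if xv.std() == 0:
            logger.warning("variable %r skipped: constant", var)
            continue
        normal = (stats.shapiro(xv).pvalue > NORMALITY_ALPHA
                  and stats.shapiro(hv).pvalue > NORMALITY_ALPHA)
        if normal:
            r, p = stats.pearsonr(xv, hv)
            method = "pearson"
        else:
            r, p = stats.spearmanr(xv, hv)
            method = "spearman"
        rows.append({"variable": var, "r": float(r), "p": float(p),
                     "method": method, "n": int(ok.sum())})
    return pd.DataFrame(rows, columns=["variable", "r", "p", "method", "n"])
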