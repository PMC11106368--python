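"""Regional imaging variables and the Bonferroni-corrected correlation scan.

Regional means are taken under the estimated LC mask after propagating the
soft mask to each map's grid (linear resampling, then binarization), e.g.
from the (0.7 mm)^3 anatomical grid to a (1.25 mm)^3 diffusion grid.  The
exploratory scan correlates every imaging variable with every non-imaging
variable, multiplying each Pearson p-value by the number of imaging and
non-imaging variables (p_B = p * N_imaging * N_external, capped at 1).
ICV adjustment is a partial correlation: both variables are residualized
on intracranial volume and the degrees of freedom reduced by one.
Instead of a manual visual inspection for outlier-driven hits, each pair
carries a leverage diagnostic (the largest leave-one-out change in r);
pairs are flagged, never auto-excluded.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .io_core import BinaryMask, Volume, resample_to_grid

LEVERAGE_FLAG_THRESHOLD = 0.2  # LOO |delta r| above this flags a pair


def propagate_mask(mask: Volume, target: Volume, threshold: float = 0.5
                   ) -> BinaryMask:
    """Carry a (soft or binary) mask onto another grid: linear resampling
    of the soft values, then binarization."""
    soft = Volume(np.asarray(mask.data, dtype=float), mask.affine)
    res = resample_to_grid(soft, target, mode="linear")
    return BinaryMask((res.data > threshold).astype(np.uint8), res.affine)


def regional_means(mask: Volume, maps: Dict[str, Volume],
                   threshold: float = 0.5) -> Dict[str, float]:
    """Mean map value inside the mask, per named map.

    Maps on a different grid receive a propagated copy of the mask first.
    An empty propagated mask yields NaN for that map (missing value).
    """
    out = {}
    for name, vol in maps.items():
        if mask.same_grid(vol):
            m = np.asarray(mask.data) > 0.5
        else:
            m = propagate_mask(mask, vol, threshold).data > 0
        out[name] = float(np.asarray(vol.data)[m].mean()) if m.any() \
            else float("nan")
    return out


def _pearson_with_df(x: np.ndarray, y: np.ndarray, df: int):
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if df <= 0 or abs(r) == 1.0:
        return r, 0.0 if abs(r) == 1.0 else float("nan")
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * sstats.t.sf(abs(t), df)
    return r, float(p)


def _residualize(y: np.ndarray, covar: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(covar), covar])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _loo_max_delta_r(x: np.ndarray, y: np.ndarray, r: float) -> float:
    """Largest leave-one-out change in r (vectorized via sum updates)."""
    n = len(x)
    if n <= 3:
        return 0.0
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    m = n - 1
    mx = (sx - x) / m
    my = (sy - y) / m
    cov = sxy - x * y - m * mx * my
    vx = sxx - x * x - m * mx * mx
    vy = syy - y * y - m * my * my
    denom = np.sqrt(np.clip(vx * vy, 0.0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        ri = cov / denom
    ri = np.where(denom > 0, ri, r)
    return float(np.max(np.abs(ri - r)))


def correlation_scan(imaging: pd.DataFrame, external: pd.DataFrame,
                     adjust_icv: bool = False, icv_col: str = "ICV",
                     alpha: float = 0.05) -> pd.DataFrame:
    """Scan all (imaging, external) variable pairs with Pearson correlation
    and Bonferroni correction by the two variable counts.

    Both frames are subject-indexed; complete cases are used per pair (no
    imputation).  Returns one row per pair with columns
    ``imaging_var, external_var, n, r, p, p_B, significant, flag``, sorted
    by ``p_B``.  Zero-variance pairs are flagged, not dropped.
    """
    common = imaging.index.intersection(external.index)
    if len(common) < 3:
        raise ValueError("need at least 3 common subjects")
    imaging = imaging.loc[common]
    external = external.loc[common]
    icv = None
    if adjust_icv:
        if icv_col not in external.columns and icv_col not in imaging.columns:
            raise ValueError(f"ICV column {icv_col!r} not found")
        icv = (external[icv_col] if icv_col in external.columns
               else imaging[icv_col]).astype(float)
        external = external.drop(columns=[icv_col], errors="ignore")
    img_vars = list(imaging.columns)
    ext_vars = list(external.columns)
    n_tests = len(img_vars) * len(ext_vars)

    rows = []
    for iv in img_vars:
        xv = imaging[iv].astype(float)
        for ev in ext_vars:
            yv = external[ev].astype(float)
            sel = xv.notna() & yv.notna()
            if icv is not None:
                sel &= icv.notna()
            x = xv[sel].to_numpy()
            y = yv[sel].to_numpy()
            n = len(x)
            flag = ""
            if n < 3:
                rows.append(dict(imaging_var=iv, external_var=ev, n=n,
                                 r=np.nan, p=np.nan, p_B=np.nan,
                                 significant=False, flag="insufficient_n"))
                continue
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append(dict(imaging_var=iv, external_var=ev, n=n,
                                 r=np.nan, p=np.nan, p_B=np.nan,
                                 significant=False, flag="zero_variance"))
                continue
            if icv is not None:
                c = icv[sel].to_numpy()
                if np.std(c) == 0:
                    rows.append(dict(imaging_var=iv, external_var=ev, n=n,
                                     r=np.nan, p=np.nan, p_B=np.nan,
                                     significant=False,
                                     flag="zero_variance_icv"))
                    continue
                x = _residualize(x, c)
                y = _residualize(y, c)
                df = n - 3  # one more parameter than the plain correlation
            else:
                df = n - 2
            r, p = _pearson_with_df(x, y, df)
            p_b = min(1.0, p * n_tests) if np.isfinite(p) else np.nan
            lev = _loo_max_delta_r(x, y, r)
            if lev > LEVERAGE_FLAG_THRESHOLD:
                flag = "high_leverage"
            rows.append(dict(imaging_var=iv, external_var=ev, n=n, r=r, p=p,
                             p_B=p_b, significant=bool(p_b < alpha),
                             flag=flag, max_loo_delta_r=lev))
    out = pd.DataFrame(rows)
    return out.sort_values("p_B", kind="stable").reset_index(drop=True)


def bonferroni(p: float, n_imaging: int, n_external: int) -> float:
    """p_B = min(1, p * N_imaging * N_external)."""
    if p < 0 or p > 1:
        raise ValueError("p must lie in [0, 1]")
    return min(1.0, p * n_imaging * n_external)
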