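"""Image-fidelity metrics (PSNR, SSIM) and their per-cohort aggregation.

PSNR uses a fixed data range R equal to the width of the normalized
intensity scale (256), not the per-image dynamic range, so values are
comparable across cases.  SSIM follows Wang et al. (2004): an 11-tap
Gaussian window (sigma 1.5, truncated at 3.5 sigma, reflect boundary),
population moments, C1 = (K1 R)^2, C2 = (K2 R)^2 with K1 = 0.01,
K2 = 0.03; border positions narrower than the window radius are excluded
from the average.  Rank-3 volumes are scored slice-wise in the axial plane
and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .model import PairedPrediction
from .phantom import PairedCase

__all__ = ["QualityReport", "psnr", "ssim", "evaluate_pairs", "DATA_RANGE"]

DATA_RANGE = 256.0
_K1, _K2 = 0.01, 0.03
_SIGMA, _TRUNCATE = 1.5, 3.5


def psnr(pred: np.ndarray, ref: np.ndarray, data_range: float = DATA_RANGE) -> float:
    """Peak signal-to-noise ratio 10*log10(R^2 / MSE) in decibels.

    Identical inputs give +inf.
    """
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {ref.shape}")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((np.asarray(pred, dtype=np.float64) - ref) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(data_range ** 2 / mse))


def _ssim_2d(pred: np.ndarray, ref: np.ndarray, data_range: float) -> float:
    x = np.asarray(pred, dtype=np.float64)
    y = np.asarray(ref, dtype=np.float64)
    radius = int(_TRUNCATE * _SIGMA + 0.5)
    win = 2 * radius + 1
    if min(x.shape) < win:
        raise ValueError(f"image {x.shape} smaller than the {win}-tap window")
    filt = dict(sigma=_SIGMA, truncate=_TRUNCATE, mode="reflect")
    ux = gaussian_filter(x, **filt)
    uy = gaussian_filter(y, **filt)
    uxx = gaussian_filter(x * x, **filt)
    uyy = gaussian_filter(y * y, **filt)
    uxy = gaussian_filter(x * y, **filt)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    c1 = (_K1 * data_range) ** 2
    c2 = (_K2 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)
         / ((ux * ux + uy * uy + c1) * (vx + vy + c2)))
    interior = s[radius:-radius, radius:-radius]
    return float(interior.mean())


def ssim(pred: np.ndarray, ref: np.ndarray, data_range: float = DATA_RANGE) -> float:
    """Mean structural similarity in [-1, 1]; slice-wise for rank-3 input."""
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {ref.shape}")
    if pred.ndim == 2:
        return _ssim_2d(pred, ref, data_range)
    if pred.ndim == 3:
        return float(np.mean([_ssim_2d(pred[..., z], ref[..., z], data_range)
                              for z in range(pred.shape[-1])]))
    raise ValueError("ssim expects a 2D image or 3D volume")


@dataclass
class QualityReport:
    """Per-case PSNR/SSIM rows plus mean ± sd aggregates for sVNC and sIOM."""

    per_case: pd.DataFrame
    data_range: float = DATA_RANGE
    ssim_constants: tuple[float, float] = (_K1, _K2)

    @property
    def aggregates(self) -> pd.DataFrame:
        metrics = ["psnr_vnc", "ssim_vnc", "psnr_iom", "ssim_iom"]
        return pd.DataFrame({
            "mean": self.per_case[metrics].mean(),
            "sd": self.per_case[metrics].std(ddof=1).fillna(0.0),
        })

    def to_text(self) -> str:
        """Mean ± sd table, SSIM as percentages (presentation convention)."""
        agg = self.aggregates
        lines = ["          sVNC                    sIOM",
                 "          PSNR (dB)   SSIM (%)    PSNR (dB)   SSIM (%)"]
        row = ("this run  {pv:.2f} ± {pvs:.2f}  {sv:.2f} ± {svs:.2f}  "
               "{pi:.2f} ± {pis:.2f}  {si:.2f} ± {sis:.2f}")
        lines.append(row.format(
            pv=agg.loc["psnr_vnc", "mean"], pvs=agg.loc["psnr_vnc", "sd"],
            sv=100 * agg.loc["ssim_vnc", "mean"], svs=100 * agg.loc["ssim_vnc", "sd"],
            pi=agg.loc["psnr_iom", "mean"], pis=agg.loc["psnr_iom", "sd"],
            si=100 * agg.loc["ssim_iom", "mean"], sis=100 * agg.loc["ssim_iom", "sd"]))
        return "\n".join(lines)


def evaluate_pairs(predictions: list[PairedPrediction],
                   cases: list[PairedCase],
                   data_range: float = DATA_RANGE) -> QualityReport:
    """Score generated (sVNC, sIOM) against their ground-truth cases by id."""
    by_id = {c.case_id: c for c in cases}
    rows = []
    for pred in predictions:
        case = by_id.get(pred.case_id)
        if case is None:
            raise KeyError(f"no ground-truth case for prediction "
                           f"{pred.case_id!r}")
        rows.append({
            "case_id": pred.case_id,
            "psnr_vnc": psnr(pred.svnc, case.vnc, data_range),
            "ssim_vnc": ssim(pred.svnc, case.vnc, data_range),
            "psnr_iom": psnr(pred.siom, case.iom, data_range),
            "ssim_iom": ssim(pred.siom, case.iom, data_range),
        })
    if not rows:
        raise ValueError("no predictions to evaluate")
    return QualityReport(per_case=pd.DataFrame(rows), data_range=data_range)
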