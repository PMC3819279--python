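"""Full-reference image quality metrics and Table-style aggregation.

SNR and PSNR follow the standard signal-power / error-power definitions in
dB; identical image pairs score ``inf`` and are excluded from mean/std
aggregation (and serialized as the string ``"inf"`` in CSV).  SSIM uses the
canonical construction (11x11 Gaussian window, sigma 1.5, K1=0.01,
K2=0.03).  Mutual information is computed from the joint intensity
histogram in bits.  TC (time consumption) is a wall-clock measurement
supplied by the caller and never asserted against.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .image import GrayImage

__all__ = ["MetricReport", "snr", "psnr", "ssim", "mutual_information", "evaluate"]

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ("snr_db", "psnr_db", "ssim", "mi_bits", "tc_seconds")


def _check_dims(ref: GrayImage, test: GrayImage) -> None:
    if ref.shape != test.shape:
        raise ValueError(f"dimension mismatch: {ref.shape} vs {test.shape}")


def snr(ref: GrayImage, test: GrayImage) -> float:
    """Signal-to-noise ratio ``10*log10(sum ref^2 / sum (ref-test)^2)`` in dB."""
    _check_dims(ref, test)
    err = np.sum((ref.pixels - test.pixels) ** 2)
    if err == 0.0:
        return float("inf")
    sig = np.sum(ref.pixels**2)
    return float(10.0 * np.log10(sig / err))


def psnr(ref: GrayImage, test: GrayImage, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio ``10*log10(peak^2 / MSE)`` in dB."""
    _check_dims(ref, test)
    if peak <= 0:
        raise ValueError("peak must be positive")
    mse = np.mean((ref.pixels - test.pixels) ** 2)
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / mse))


def ssim(ref: GrayImage, test: GrayImage) -> float:
    """Mean local structural similarity with the canonical parameters."""
    _check_dims(ref, test)
    if min(ref.shape) < 11:
        raise ValueError("SSIM requires images of at least 11x11")
    return float(
        structural_similarity(
            ref.pixels,
            test.pixels,
            data_range=1.0,
            gaussian_weights=True,
            sigma=1.5,
            win_size=11,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def mutual_information(ref: GrayImage, test: GrayImage, bins: int = 256) -> float:
    """Mutual information of the joint intensity histogram, in bits.

    Intensities are binned with ``bins`` equal-width bins on [0, 1];
    ``mutual_information(x, x)`` equals the marginal entropy of ``x`` at
    the same binning.
    """
    _check_dims(ref, test)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    joint, _, _ = np.histogram2d(
        ref.pixels.ravel(), test.pixels.ravel(), bins=bins, range=[[0.0, 1.0], [0.0, 1.0]]
    )
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    outer = np.outer(px, py)
    return float(np.sum(pxy[nz] * np.log2(pxy[nz] / outer[nz])))


def evaluate(
    ref: GrayImage,
    test: GrayImage,
    method_name: str,
    image_id: str,
    elapsed: float = 0.0,
    mi_bins: int = 256,
) -> dict:
    """Assemble one report row with all four quality metrics plus TC."""
    if elapsed < 0:
        raise ValueError("elapsed must be >= 0")
    return {
        "method": method_name,
        "image_id": image_id,
        "snr_db": snr(ref, test),
        "psnr_db": psnr(ref, test),
        "ssim": ssim(ref, test),
        "mi_bits": mutual_information(ref, test, bins=mi_bins),
        "tc_seconds": float(elapsed),
    }


@dataclasses.dataclass
class MetricReport:
    """Per-image metric rows plus per-method mean +/- std aggregates.

    Aggregation uses the sample standard deviation (ddof=1; 0.0 for a
    single row) and drops non-finite values — identical-pair rows score
    ``inf`` on SNR/PSNR and would otherwise poison the means.
    """

    rows: list[dict] = dataclasses.field(default_factory=list)

    def append(self, row: dict) -> None:
        self.rows.append(dict(row))

    def extend(self, rows: Iterable[dict]) -> None:
        for row in rows:
            self.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["method", "image_id", *METRIC_COLUMNS])

    def aggregate(self) -> pd.DataFrame:
        """Per-method mean/std for every metric, recomputable from rows."""
        frame = self.to_frame()
        records = []
        for method, grp in frame.groupby("method", sort=False):
            rec: dict = {"method": method}
            for col in METRIC_COLUMNS:
                vals = grp[col].to_numpy(dtype=float)
                finite = vals[np.isfinite(vals)]
                if finite.size < vals.size:
                    logger.info(
                        "%s/%s: dropped %d non-finite value(s) from aggregation",
                        method, col, vals.size - finite.size,
                    )
                if finite.size == 0:
                    rec[f"{col}_mean"] = float("nan")
                    rec[f"{col}_std"] = float("nan")
                else:
                    rec[f"{col}_mean"] = float(finite.mean())
                    rec[f"{col}_std"] = float(finite.std(ddof=1)) if finite.size > 1 else 0.0
            records.append(rec)
        return pd.DataFrame(records)

    def summary_table(self) -> pd.DataFrame:
        """Metrics-as-rows, methods-as-columns table of ``mean ± std`` cells."""
        agg = self.aggregate()
        table: dict[str, list[str]] = {}
        for _, rec in agg.iterrows():
            table[rec["method"]] = [
                f"{rec[f'{col}_mean']:.4f} ± {rec[f'{col}_std']:.4f}" for col in METRIC_COLUMNS
            ]
        return pd.DataFrame(table, index=list(METRIC_COLUMNS))

    def write_csv(self, rows_path, summary_path=None) -> None:
        frame = self.to_frame()
        # Serialize infinities explicitly so the CSV round-trips losslessly.
        frame.to_csv(rows_path, index=False, na_rep="nan")
        if summary_path is not None:
            self.summary_table().to_csv(summary_path, index_label="metric")
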