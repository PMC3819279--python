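"""Seeded synthetic test images and the degrade protocol.

The benchmark images this package was designed around are confidential
clinical scans, so every pipeline stage is exercised on deterministic
phantoms instead: oriented step edges, disks, rings, gratings, checkers,
smooth blob fields, and a curved bright band on a dark background that
mimics a spine-like structure.  Identical specs always produce
bit-identical images.
"""

from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np

from .image import GrayImage, resample

__all__ = ["PhantomSpec", "PHANTOM_KINDS", "make_phantom", "degrade", "make_corpus"]

PHANTOM_KINDS = (
    "oriented_step",
    "disk",
    "ring",
    "grating",
    "checker",
    "blob_field",
    "spine_band",
)


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Deterministic description of one synthetic image."""

    kind: str
    size: tuple[int, int] = (256, 256)
    params: dict[str, Any] = dataclasses.field(default_factory=dict)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; choose from {PHANTOM_KINDS}")
        if min(self.size) < 16:
            raise ValueError("phantom size must be at least 16x16")
        if not (0.0 <= self.noise_sigma < 0.5):
            raise ValueError("noise_sigma must lie in [0, 0.5)")


def _grids(size: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = size
    return np.meshgrid(np.arange(h, dtype=np.float64), np.arange(w, dtype=np.float64), indexing="ij")


def _soft_step(signed_dist: np.ndarray, lo: float, hi: float, soft: bool = True) -> np.ndarray:
    """Two-level image from a signed distance field, 1-px linear transition."""
    if soft:
        t = np.clip(signed_dist + 0.5, 0.0, 1.0)
    else:
        t = (signed_dist >= 0).astype(np.float64)
    return lo + (hi - lo) * t


def _oriented_step(size, angle=90.0, lo=0.2, hi=0.8, antialias=True, **_):
    # Boundary line through the center at `angle` degrees from horizontal;
    # angle 90 gives a vertical boundary with the low level on the left.
    rr, cc = _grids(size)
    rc, cv = (size[0] - 1) / 2.0, (size[1] - 1) / 2.0
    theta = np.deg2rad(angle)
    signed = (cc - cv) * np.sin(theta) - (rr - rc) * np.cos(theta)
    return _soft_step(signed, lo, hi, soft=antialias)


def _disk(size, radius=40.0, center=None, lo=0.1, hi=0.9, **_):
    rr, cc = _grids(size)
    if center is None:
        center = ((size[0] - 1) / 2.0, (size[1] - 1) / 2.0)
    dist = np.hypot(rr - center[0], cc - center[1])
    return _soft_step(radius - dist, lo, hi)


def _ring(size, radius=60.0, thickness=12.0, lo=0.1, hi=0.9, **_):
    rr, cc = _grids(size)
    rc, cv = (size[0] - 1) / 2.0, (size[1] - 1) / 2.0
    dist = np.hypot(rr - rc, cc - cv)
    return _soft_step(thickness / 2.0 - np.abs(dist - radius), lo, hi)


def _grating(size, frequency=0.08, angle=30.0, lo=0.2, hi=0.8, **_):
    rr, cc = _grids(size)
    theta = np.deg2rad(angle)
    phase = 2.0 * np.pi * frequency * (cc * np.cos(theta) + rr * np.sin(theta))
    return lo + (hi - lo) * 0.5 * (1.0 + np.sin(phase))


def _checker(size, block=16, lo=0.15, hi=0.85, **_):
    rr, cc = _grids(size)
    parity = ((rr // block) + (cc // block)) % 2
    return lo + (hi - lo) * parity


def _blob_field(size, n_blobs=6, sigma_px=14.0, rng=None, **_):
    rng = rng or np.random.default_rng(0)
    rr, cc = _grids(size)
    img = np.zeros(size, dtype=np.float64)
    for _i in range(int(n_blobs)):
        r0 = rng.uniform(0.15, 0.85) * (size[0] - 1)
        c0 = rng.uniform(0.15, 0.85) * (size[1] - 1)
        amp = rng.uniform(0.3, 0.9)
        img += amp * np.exp(-(((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma_px**2)))
    peak = img.max()
    return img / peak * 0.9 if peak > 0 else img


def _spine_band(size, curvature=0.25, half_width=None, lo=0.05, hi=0.95, **_):
    """Curved bright band on dark background, brightness fading along it."""
    rr, cc = _grids(size)
    h, w = size
    half_width = half_width or max(4.0, w / 18.0)
    # Parabolic centerline running top to bottom, bowing with `curvature`.
    t = rr / max(h - 1, 1)
    center_col = (0.5 + curvature * (t - 0.5) ** 2 * 4.0 - curvature) * (w - 1)
    dist = np.abs(cc - center_col)
    profile = np.exp(-0.5 * (dist / half_width) ** 2)
    brightness = hi - (hi - lo) * 0.6 * t  # bright end fading toward dark end
    return lo + (brightness - lo) * profile


_GENERATORS = {
    "oriented_step": _oriented_step,
    "disk": _disk,
    "ring": _ring,
    "grating": _grating,
    "checker": _checker,
    "blob_field": _blob_field,
    "spine_band": _spine_band,
}


def make_phantom(spec: PhantomSpec) -> GrayImage:
    """Render a phantom image; a pure function of its spec."""
    rng = np.random.default_rng(spec.seed)
    try:
        img = _GENERATORS[spec.kind](spec.size, rng=rng, **spec.params)
    except TypeError as exc:
        raise ValueError(f"invalid params for kind {spec.kind!r}: {exc}") from exc
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return GrayImage(np.clip(img, 0.0, 1.0))


def degrade(img: GrayImage) -> GrayImage:
    """Nearest-neighbor 0.5 downscale (the benchmark degradation step).

    Keeps the top-left sample of every 2x2 block; odd dimensions are
    floor-rounded by the resampler's size rule.
    """
    out = resample(img, 0.5, "nearest")
    if min(out.shape) < 8:
        raise ValueError(f"degraded image {out.shape} is smaller than 8x8")
    return out


def make_corpus(n: int, size: tuple[int, int] = (256, 256), seed: int = 0) -> list[GrayImage]:
    """Generate ``n`` phantoms cycling through the kinds with seeded jitter.

    Image ``i`` uses kind ``PHANTOM_KINDS[i % len(PHANTOM_KINDS)]``; all
    parameter jitter derives from ``seed`` so identical arguments always
    reproduce the identical corpus.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    corpus = []
    for i in range(n):
        kind = PHANTOM_KINDS[i % len(PHANTOM_KINDS)]
        params: dict[str, Any]
        if kind == "oriented_step":
            params = {"angle": float(rng.uniform(0.0, 180.0))}
        elif kind == "disk":
            params = {"radius": float(rng.uniform(0.15, 0.35) * min(size))}
        elif kind == "ring":
            params = {
                "radius": float(rng.uniform(0.2, 0.35) * min(size)),
                "thickness": float(rng.uniform(6.0, 16.0)),
            }
        elif kind == "grating":
            params = {
                "frequency": float(rng.uniform(0.02, 0.08)),
                "angle": float(rng.uniform(0.0, 180.0)),
            }
        elif kind == "checker":
            params = {"block": int(rng.integers(12, 33))}
        elif kind == "blob_field":
            params = {"n_blobs": int(rng.integers(4, 9))}
        else:  # spine_band
            params = {"curvature": float(rng.uniform(0.1, 0.35))}
        sub_seed = int(rng.integers(0, 2**31 - 1))
        corpus.append(make_phantom(PhantomSpec(kind, size, params, seed=sub_seed)))
    return corpus
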