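"""Image output: PFM (float radiance) and PNG (tone-mapped display)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_pfm", "read_pfm", "tone_map", "write_png"]


def write_pfm(path, image: np.ndarray) -> Path:
    """Write an HDR image as little-endian PFM (rows stored bottom-up)."""
    path = Path(path)
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("PFM writer expects an (H, W, 3) image")
    h, w = img.shape[:2]
    with open(path, "wb") as fh:
        fh.write(b"PF\n")
        fh.write(f"{w} {h}\n".encode())
        fh.write(b"-1.0\n")  # negative scale marks little-endian
        fh.write(img[::-1].astype("<f4").tobytes())
    return path


def read_pfm(path) -> np.ndarray:
    with open(path, "rb") as fh:
        header = fh.readline().strip()
        if header not in (b"PF", b"Pf"):
            raise ValueError("not a PFM file")
        w, h = map(int, fh.readline().split())
        scale = float(fh.readline())
        count = w * h * (3 if header == b"PF" else 1)
        data = np.frombuffer(fh.read(count * 4),
                             dtype="<f4" if scale < 0 else ">f4")
    img = data.reshape(h, w, -1)[::-1]
    if img.shape[2] == 1:
        img = np.repeat(img, 3, axis=2)
    return np.ascontiguousarray(img, dtype=np.float32)


def tone_map(hdr: np.ndarray, exposure: float = 1.0) -> np.ndarray:
    """Reinhard x/(1+x) on exposure-scaled radiance, then gamma 2.2 -> uint8.

    Monotone per channel; large inputs approach 255 without overflow.
    """
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    x = np.maximum(np.asarray(hdr, dtype=np.float64) * exposure, 0.0)
    y = (x / (1.0 + x)) ** (1.0 / 2.2)
    return np.clip(np.rint(y * 255.0), 0, 255).astype(np.uint8)


def write_png(path, image: np.ndarray) -> Path:
    import imageio.v3 as iio
    path = Path(path)
    img = np.asarray(image)
    if img.dtype != np.uint8:
        img = tone_map(img)
    iio.imwrite(path, img)
    return path
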