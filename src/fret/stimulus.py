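"""Headless visual-stimulus model.

Stimulus elements (gratings and patches) expose their parameters as
fields that may hold either a plain constant or a signal: assigning a
signal makes the element track its emissions, and a listener marks the
element dirty so a renderer can skip frames in which nothing changed.

Coordinates use a linear small-angle viewing model: positions and sizes
are in visual degrees, with the screen center at (azimuth, altitude) =
(0, 0), azimuth increasing rightward and altitude upward, and a single
``px_per_deg`` conversion factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .network import Signal

__all__ = [
    "VisualElement",
    "ScreenModel",
    "Renderer",
    "make_grating",
    "make_patch",
    "render_frame",
    "estimate_grating_orientation",
    "save_png",
]

_GRATING_FIELDS = ("show", "orientation", "phase", "spatialFreq", "azimuth",
                   "altitude", "dims", "color", "contrast", "sigma")
_PATCH_FIELDS = ("show", "azimuth", "altitude", "dims", "color",
                 "orientation")


class VisualElement:
    """A stimulus element whose fields are signals or constants.

    Field units: orientation in degrees, phase in radians, spatialFreq in
    cycles/degree, azimuth/altitude/dims/sigma in visual degrees, color
    as RGB in [0, 1], contrast in [0, 1].
    """

    def __init__(self, kind: str, shape: str, fields: tuple[str, ...],
                 defaults: dict[str, Any]):
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "_allowed", fields)
        object.__setattr__(self, "_fields", dict(defaults))
        object.__setattr__(self, "dirty", True)
        object.__setattr__(self, "_listeners", [])

    def __setattr__(self, key: str, value: Any) -> None:
        if key == "dirty":
            object.__setattr__(self, key, value)
            return
        if key not in self._allowed:
            raise AttributeError(
                f"{self.kind} element has no field {key!r}; "
                f"fields are {self._allowed}")
        self._fields[key] = value
        if isinstance(value, Signal):
            self._listeners.append(
                value.on_value(lambda v, el=self: setattr(el, "dirty", True)))
        object.__setattr__(self, "dirty", True)

    def __getattr__(self, key: str) -> Any:
        if key.startswith("_"):
            raise AttributeError(key)
        try:
            return self._fields[key]
        except KeyError:
            raise AttributeError(key) from None

    def current(self, key: str, default: Any = None) -> Any:
        """The field's current value: a constant as-is; a signal's
        committed value, or ``default`` if it has none yet."""
        v = self._fields.get(key, default)
        if isinstance(v, Signal):
            return v.value if v.has_value else default
        return v

    @property
    def visible(self) -> bool:
        from .network import truthy
        return truthy(self.current("show", False))


@dataclass
class ScreenModel:
    """Headless screen: pixel raster plus degrees-to-pixels conversion."""

    width_px: int = 160
    height_px: int = 120
    px_per_deg: float = 4.0
    background: float = 0.5

    def grids_deg(self) -> tuple[np.ndarray, np.ndarray]:
        """(azimuth, altitude) meshgrids in degrees, center at (0, 0)."""
        x = (np.arange(self.width_px) - (self.width_px - 1) / 2) / self.px_per_deg
        y = ((self.height_px - 1) / 2 - np.arange(self.height_px)) / self.px_per_deg
        return np.meshgrid(x, y)


def make_grating(t: Signal, carrier: str = "sinusoid",
                 window: str = "Gaussian") -> VisualElement:
    """A sinusoidal grating, optionally under a Gaussian window (Gabor)."""
    if carrier not in ("sinusoid",):
        raise ValueError(f"unknown carrier {carrier!r}")
    if window.lower() not in ("gaussian", "none"):
        raise ValueError(f"unknown window {window!r}")
    defaults = dict(show=False, orientation=0.0, phase=0.0, spatialFreq=0.1,
                    azimuth=0.0, altitude=0.0, dims=(10.0, 10.0),
                    color=(1.0, 1.0, 1.0), contrast=1.0,
                    sigma=5.0 if window.lower() == "gaussian" else None)
    return VisualElement("grating", carrier, _GRATING_FIELDS, defaults)


def make_patch(t: Signal, shape: str = "rectangle") -> VisualElement:
    """A solid patch: rectangle (dims = [w, h] deg) or circle
    (dims[0] = diameter in deg)."""
    if shape not in ("rectangle", "circle"):
        raise ValueError(f"unknown patch shape {shape!r}")
    defaults = dict(show=True, azimuth=0.0, altitude=0.0, dims=(4.0, 4.0),
                    color=(1.0, 1.0, 1.0), orientation=0.0)
    return VisualElement("patch", shape, _PATCH_FIELDS, defaults)


def _render_grating(el: VisualElement, X: np.ndarray, Y: np.ndarray,
                    frame: np.ndarray) -> None:
    theta = np.deg2rad(float(el.current("orientation", 0.0)))
    phase = float(el.current("phase", 0.0))
    sf = float(el.current("spatialFreq", 0.1))
    contrast = float(el.current("contrast", 1.0))
    color = np.asarray(el.current("color", (1.0, 1.0, 1.0)), dtype=float)
    az = float(el.current("azimuth", 0.0))
    alt = float(el.current("altitude", 0.0))
    sigma = el.current("sigma", None)
    x, y = X - az, Y - alt
    carrier = np.cos(2 * np.pi * sf * (x * np.cos(theta) + y * np.sin(theta))
                     + phase)
    w = np.exp(-(x ** 2 + y ** 2) / (2 * float(sigma) ** 2)) \
        if sigma is not None else 1.0
    mod = 0.5 * contrast * w * carrier
    for ch in range(3):
        frame[:, :, ch] = 0.5 + color[ch] * mod


def _render_patch(el: VisualElement, X: np.ndarray, Y: np.ndarray,
                  frame: np.ndarray) -> None:
    az = float(el.current("azimuth", 0.0))
    alt = float(el.current("altitude", 0.0))
    dims = np.atleast_1d(np.asarray(el.current("dims", (4.0, 4.0)),
                                    dtype=float))
    color = np.asarray(el.current("color", (1.0, 1.0, 1.0)), dtype=float)
    if el.shape == "rectangle":
        w = dims[0]
        h = dims[1] if dims.size > 1 else dims[0]
        mask = (np.abs(X - az) <= w / 2) & (np.abs(Y - alt) <= h / 2)
    else:  # circle
        r = dims[0] / 2
        mask = (X - az) ** 2 + (Y - alt) ** 2 <= r ** 2
    frame[mask] = color


def render_frame(elements: dict[str, VisualElement],
                 screen: ScreenModel) -> np.ndarray:
    """Rasterize visible elements over the background, in registration
    order, returning an (H, W, 3) float image in [0, 1]."""
    frame = np.full((screen.height_px, screen.width_px, 3),
                    screen.background, dtype=float)
    X, Y = screen.grids_deg()
    for el in elements.values():
        if not isinstance(el, VisualElement) or not el.visible:
            continue
        if el.kind == "grating":
            _render_grating(el, X, Y, frame)
        else:
            _render_patch(el, X, Y, frame)
    np.clip(frame, 0.0, 1.0, out=frame)
    return frame


class Renderer:
    """Caches the last frame; re-rasterizes only when an element is dirty."""

    def __init__(self, screen: ScreenModel):
        self.screen = screen
        self._frame: np.ndarray | None = None

    def render(self, elements: dict[str, VisualElement]) -> np.ndarray:
        dirty = any(getattr(el, "dirty", False) for el in elements.values())
        if self._frame is None or dirty:
            self._frame = render_frame(elements, self.screen)
            for el in elements.values():
                if isinstance(el, VisualElement):
                    el.dirty = False
        return self._frame


def estimate_grating_orientation(img: np.ndarray) -> float:
    """Dominant spatial orientation of a grating image, in degrees
    modulo 180, estimated from the structure tensor of the luminance
    gradient (the dominant gradient direction is the carrier's wave
    vector)."""
    lum = img.mean(axis=2) if img.ndim == 3 else img
    gy, gx = np.gradient(lum)
    gy = -gy  # row index increases downward; altitude increases upward
    j11 = np.sum(gx * gx)
    j22 = np.sum(gy * gy)
    j12 = np.sum(gx * gy)
    ang = 0.5 * np.arctan2(2 * j12, j11 - j22)
    return float(np.rad2deg(ang) % 180.0)


def save_png(frame: np.ndarray, path) -> None:
    """Write a rendered frame as an 8-bit PNG."""
    from PIL import Image
    img = (np.clip(frame, 0, 1) * 255).round().astype(np.uint8)
    Image.fromarray(img).save(path)
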