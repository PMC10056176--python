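"""Per-pixel structure-tensor orientation and coherency fields.

The local structure tensor of an intensity field f(x1, x2) is the
Gaussian-window-weighted matrix of gradient products

    J = [[<fx1|fx1>_w, <fx1|fx2>_w],
         [<fx1|fx2>_w, <fx2|fx2>_w]]

whose dominant eigenvector gives the local gradient direction.  The structure
orientation (direction of the isolines, i.e. of the visible stripes/fibres)
is perpendicular to it and is obtained in closed form as

    theta = 1/2 * atan2(2 Jxy, Jyy - Jxx)        (degrees, [0, 180))

with the coherency index

    C = sqrt((Jyy - Jxx)^2 + 4 Jxy^2) / (Jxx + Jyy)  in [0, 1]

equal to the normalized eigenvalue contrast (l1 - l2)/(l1 + l2): 1 for a
perfectly oriented neighbourhood, 0 for an isotropic one.

Gradient operators: central finite differences, derivative-of-Gaussian, and
the first-order Riesz transform (frequency-domain multipliers -i w_k / |w|),
a translation-, rotation- and scale-invariant derivative operator that does
not amplify high frequencies; it is the default.

Axis/angle convention: x = columns, y = rows (increasing downward); theta is
measured counter-clockwise from +x, so a grating whose stripes run along the
image rows has theta = 0 and vertical stripes have theta = 90.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "GradientField",
    "StructureTensorField",
    "OrientationField",
    "gradient",
    "structure_tensor",
    "orientation_and_coherency",
    "orientation_field",
    "render_hsb",
    "render_coherency",
    "GRADIENT_OPERATORS",
]

GRADIENT_OPERATORS = ("finite_difference", "gaussian", "riesz")


@dataclass
class GradientField:
    fx1: np.ndarray  # d/dx (columns)
    fx2: np.ndarray  # d/dy (rows)
    operator: str


@dataclass
class StructureTensorField:
    jxx: np.ndarray  # <fx1|fx1>_w
    jxy: np.ndarray  # <fx1|fx2>_w
    jyy: np.ndarray  # <fx2|fx2>_w
    window_sigma: float


@dataclass
class OrientationField:
    """theta in degrees [0, 180) (NaN where undefined), coherency in [0, 1],
    energy = tensor trace."""

    theta: np.ndarray
    coherency: np.ndarray
    energy: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.theta)


def _riesz_gradient(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    h, w = img.shape
    spec = np.fft.fft2(img)
    u = np.fft.fftfreq(w)[None, :]
    v = np.fft.fftfreq(h)[:, None]
    norm = np.hypot(u, v)
    norm[0, 0] = 1.0  # DC multiplier forced to zero below
    hx = -1j * u / norm
    hy = -1j * v / norm
    hx[0, 0] = 0.0
    hy[0, 0] = 0.0
    fx = np.fft.ifft2(spec * hx).real
    fy = np.fft.ifft2(spec * hy).real
    return fx, fy


def gradient(image: np.ndarray, operator: str = "riesz",
             sigma_d: float = 1.0) -> GradientField:
    """Image gradient with the selected operator.

    finite_difference: central differences (one-sided at the borders);
    gaussian: derivative-of-Gaussian at scale ``sigma_d``;
    riesz: first-order Riesz transform (see module docstring).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("image must be 2-D and at least 3x3")
    if operator == "finite_difference":
        fy, fx = np.gradient(img)
    elif operator == "gaussian":
        fx = ndimage.gaussian_filter(img, sigma_d, order=(0, 1), mode="reflect")
        fy = ndimage.gaussian_filter(img, sigma_d, order=(1, 0), mode="reflect")
    elif operator == "riesz":
        fx, fy = _riesz_gradient(img)
    else:
        raise ValueError(
            f"unknown operator {operator!r}; valid: {', '.join(GRADIENT_OPERATORS)}")
    return GradientField(fx1=fx, fx2=fy, operator=operator)


def structure_tensor(grad: GradientField,
                     window_sigma: float = 8.0) -> StructureTensorField:
    """Gaussian-windowed products of the gradient components.

    Each product image (fx1^2, fx1 fx2, fx2^2) is smoothed with a normalized
    Gaussian of the given sigma, reflective boundaries.
    """
    if not window_sigma > 0:
        raise ValueError("window_sigma must be positive")
    smooth = lambda a: ndimage.gaussian_filter(a, window_sigma, mode="reflect")
    return StructureTensorField(
        jxx=smooth(grad.fx1 * grad.fx1),
        jxy=smooth(grad.fx1 * grad.fx2),
        jyy=smooth(grad.fx2 * grad.fx2),
        window_sigma=window_sigma,
    )


def orientation_and_coherency(tensor: StructureTensorField) -> OrientationField:
    """Closed-form orientation and coherency from the 2x2 tensor field.

    Pixels whose energy (tensor trace) is below 1e-12 of the field maximum
    get coherency 0 and undefined (NaN) theta rather than raising.
    """
    jxx, jxy, jyy = tensor.jxx, tensor.jxy, tensor.jyy
    energy = jxx + jyy
    eps = 1e-12 * max(float(energy.max()), 1e-300)
    ok = energy > eps

    theta = 0.5 * np.arctan2(2.0 * jxy, jyy - jxx)
    theta_deg = np.rad2deg(theta) % 180.0
    theta_deg[~ok] = np.nan

    coherency = np.zeros_like(energy)
    num = np.sqrt((jyy - jxx) ** 2 + 4.0 * jxy ** 2)
    coherency[ok] = num[ok] / energy[ok]
    np.clip(coherency, 0.0, 1.0, out=coherency)
    return OrientationField(theta=theta_deg, coherency=coherency, energy=energy)


def orientation_field(image: np.ndarray, operator: str = "riesz",
                      window_sigma: float = 8.0, sigma_d: float = 1.0,
                      ) -> tuple[OrientationField, StructureTensorField]:
    """Convenience: gradient -> structure tensor -> orientation/coherency."""
    grad = gradient(image, operator=operator, sigma_d=sigma_d)
    tensor = structure_tensor(grad, window_sigma=window_sigma)
    return orientation_and_coherency(tensor), tensor


# --------------------------------------------------------------------------
# renders
# --------------------------------------------------------------------------

def render_hsb(orientation: OrientationField, image: np.ndarray) -> np.ndarray:
    """Hue-saturation-brightness composite as a uint8 RGB array.

    hue encodes theta (full wheel = 180 deg), saturation the coherency and
    brightness the normalized input image; undefined-theta pixels are gray.
    """
    from matplotlib.colors import hsv_to_rgb

    img = np.asarray(image, dtype=float)
    if img.shape != orientation.theta.shape:
        raise ValueError("image and orientation field shapes differ")
    lo, hi = img.min(), img.max()
    bright = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    hue = np.nan_to_num(orientation.theta, nan=0.0) / 180.0
    sat = np.where(orientation.defined, orientation.coherency, 0.0)
    rgb = hsv_to_rgb(np.dstack([hue, sat, bright]))
    return (rgb * 255.0 + 0.5).astype(np.uint8)


def render_coherency(orientation: OrientationField) -> np.ndarray:
    """Coherency map as 8-bit grayscale: bright = locally oriented."""
    return (np.clip(orientation.coherency, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
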