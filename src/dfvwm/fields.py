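"""Dynamic neural field engine.

Implements the Amari-style field dynamics used throughout the package:

    tau * du/dt = -u + h + s + [k * g(u)] + q * xi

where ``u`` is activation over one or two circular feature dimensions,
``h`` the resting level, ``s`` external input, ``k`` a
difference-of-Gaussians lateral-interaction kernel (optionally with a
constant global-inhibition offset), ``g`` a logistic output function and
``xi`` spatiotemporal Gaussian white noise scaled by amplitude ``q``.

Fields are integrated with fixed-step Euler-Maruyama.  Lateral
interactions are computed by circular (FFT) convolution of the field
output with the kernel, scaled by the grid spacing so that tuned
parameters are approximately resolution invariant.

Scalar dynamic nodes (zero-dimensional fields with optional
self-excitation) share the same relaxation contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from scipy import fft as sp_fft
from scipy.special import expit

__all__ = [
    "SigmoidSpec",
    "InteractionKernel",
    "Field",
    "DynamicNode",
    "sigmoid",
    "circular_distance",
    "lateral_input",
    "euler_step",
    "detect_peaks",
    "node_step",
]

EXTENT = 360.0  # every field dimension spans the full circle, in degrees


@dataclass(frozen=True)
class SigmoidSpec:
    """Logistic output nonlinearity g(u) = 1 / (1 + exp(-beta*(u - theta)))."""

    beta: float = 4.0
    theta: float = 0.0


def sigmoid(u, spec: SigmoidSpec = SigmoidSpec()):
    """Elementwise logistic output function; strictly increasing, in (0, 1)."""
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite activation passed to sigmoid")
    return expit(spec.beta * (u - spec.theta))


@dataclass(frozen=True)
class InteractionKernel:
    """Difference-of-Gaussians lateral kernel with optional global inhibition.

    Evaluated at circular distance d (degrees):

        k(d) = c_exc * exp(-d^2 / (2 sigma_exc^2))
             - c_inh * exp(-d^2 / (2 sigma_inh^2))
             - g_inh

    For 2D fields the excitatory and inhibitory Gaussians are separable
    products over the two dimensions; pass 2-tuples for the sigmas.
    Amplitudes are per-degree weights: the convolution multiplies by the
    grid spacing, so the same parameters produce the same dynamics at
    any sampling resolution.
    """

    c_exc: float = 0.0
    sigma_exc: float | tuple = 5.0
    c_inh: float = 0.0
    sigma_inh: float | tuple = 10.0
    g_inh: float = 0.0

    def __post_init__(self):
        if self.g_inh < 0:
            raise ValueError("g_inh must be >= 0")
        if self.c_exc != 0.0 and self.c_inh != 0.0:
            se = np.max(np.atleast_1d(self.sigma_exc))
            si = np.max(np.atleast_1d(self.sigma_inh))
            if not si > se:
                raise ValueError(
                    "surround structure requires sigma_inh > sigma_exc"
                )

    def profile(self, shape: Sequence[int]) -> np.ndarray:
        """Kernel sampled on the (circular) grid, centered at index 0.

        The constant global-inhibition offset is *excluded*; it is applied
        separately in :func:`lateral_input`.
        """
        ndim = len(shape)
        se = _sigmas(self.sigma_exc, ndim)
        si = _sigmas(self.sigma_inh, ndim)
        for s in se + si:
            if s >= EXTENT:
                raise ValueError("kernel width exceeds field extent")
        exc = _sep_gaussian(shape, se)
        inh = _sep_gaussian(shape, si)
        return self.c_exc * exc - self.c_inh * inh


def _sigmas(sigma, ndim: int) -> tuple:
    if np.isscalar(sigma):
        return (float(sigma),) * ndim
    sigma = tuple(float(s) for s in sigma)
    if len(sigma) != ndim:
        raise ValueError("sigma tuple length does not match field dims")
    return sigma


def _sep_gaussian(shape: Sequence[int], sigmas: tuple) -> np.ndarray:
    out = np.array(1.0)
    for n, s in zip(shape, sigmas):
        d = circular_distance(np.arange(n) * (EXTENT / n), 0.0)
        g = np.exp(-0.5 * (d / s) ** 2)
        out = np.multiply.outer(out, g)
    return out


def circular_distance(a, b):
    """Unsigned circular distance in degrees, in [0, 180]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % EXTENT
    return np.minimum(d, EXTENT - d)


def circular_diff(a, b):
    """Signed circular difference a - b, wrapped into (-180, 180]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % EXTENT
    return np.where(d > 180.0, d - EXTENT, d)


@dataclass
class Field:
    """Activation field over one or two circular dimensions of 360 degrees."""

    label: str
    shape: tuple
    h: float = -5.0
    tau: float = 20.0
    q: float = 0.0
    kernel: Optional[InteractionKernel] = None
    sigmoid: SigmoidSpec = dc_field(default_factory=SigmoidSpec)
    u: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.shape = tuple(int(n) for n in np.atleast_1d(self.shape))
        if len(self.shape) not in (1, 2):
            raise ValueError("fields must have 1 or 2 dimensions")
        if self.u is None:
            self.u = np.full(self.shape, self.h, dtype=float)
        else:
            self.u = np.asarray(self.u, dtype=float).reshape(self.shape)
        self._kernel_fft = None
        self._kernel_key = None

    @property
    def spacing(self) -> tuple:
        """Grid spacing per dimension, degrees per site."""
        return tuple(EXTENT / n for n in self.shape)

    @property
    def cell(self) -> float:
        """Volume element (product of spacings) used to scale integrals."""
        return float(np.prod(self.spacing))

    def coords(self, dim: int = 0) -> np.ndarray:
        """Site coordinates (degrees) along a dimension."""
        n = self.shape[dim]
        return np.arange(n) * (EXTENT / n)

    def output(self) -> np.ndarray:
        # hot path: expit directly (validity is enforced at construction
        # and by euler_step's arithmetic staying finite)
        return expit(self.sigmoid.beta * (self.u - self.sigmoid.theta))

    def _kernel_transfer(self):
        key = (self.shape, self.kernel)
        if self._kernel_key != key:
            prof = self.kernel.profile(self.shape)
            if len(self.shape) == 1:
                # small 1D fields: a dense circulant matrix beats FFT
                n = self.shape[0]
                idx = (np.arange(n)[:, None] - np.arange(n)[None, :]) % n
                self._kernel_fft = prof[idx]
            else:
                self._kernel_fft = sp_fft.rfftn(prof)
            self._kernel_key = key
        return self._kernel_fft


def lateral_input(field: Field, output: Optional[np.ndarray] = None) -> np.ndarray:
    """Circular convolution of the field output with its interaction kernel.

    Scaled by the grid volume element so it approximates the continuous
    integral; the constant global-inhibition offset subtracts
    ``g_inh * integral of g(u)`` uniformly.
    """
    if field.kernel is None:
        raise ValueError(f"field {field.label!r} has no interaction kernel")
    g = field.output() if output is None else output
    kf = field._kernel_transfer()
    if len(field.shape) == 1:
        conv = kf @ g
    else:
        conv = sp_fft.irfftn(sp_fft.rfftn(g) * kf, s=field.shape)
    out = conv * field.cell
    if field.kernel.g_inh:
        out = out - field.kernel.g_inh * g.sum() * field.cell
    return out


def euler_step(
    field: Field,
    external_input,
    dt: float,
    rng: Optional[np.random.Generator] = None,
    output: Optional[np.ndarray] = None,
) -> Field:
    """Advance the field by one Euler-Maruyama step of size dt (ms), in place.

    du = (dt/tau) * (-u + h + s + lateral) + q * sqrt(dt) * xi
    with xi i.i.d. standard normal per site.  Deterministic when q == 0.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    if dt >= field.tau:
        raise ValueError(
            f"dt={dt} >= tau={field.tau} for field {field.label!r}: "
            "Euler integration unstable"
        )
    s = np.zeros(field.shape) if external_input is None else np.asarray(external_input)
    drive = -field.u + field.h + s
    if field.kernel is not None:
        drive = drive + lateral_input(field, output)
    field.u = field.u + (dt / field.tau) * drive
    if field.q:
        if rng is None:
            raise ValueError("rng required when noise amplitude q > 0")
        field.u = field.u + field.q * np.sqrt(dt) * rng.standard_normal(field.shape)
    return field


def detect_peaks(field_or_u, threshold: float, coords: Optional[np.ndarray] = None):
    """Circular local maxima above threshold in a 1D activation profile.

    Returns a list of (location_degrees, activation) sorted by descending
    activation.  Locations are refined by three-point parabolic
    interpolation around each maximum; ties broken by lowest site index.
    """
    if isinstance(field_or_u, Field):
        if len(field_or_u.shape) != 1:
            raise ValueError("detect_peaks expects a 1D field or profile")
        u = field_or_u.u
        coords = field_or_u.coords()
    else:
        u = np.asarray(field_or_u, dtype=float)
        if coords is None:
            coords = np.arange(u.size) * (EXTENT / u.size)
    n = u.size
    left = np.roll(u, 1)
    right = np.roll(u, -1)
    is_peak = (u > threshold) & (u >= left) & (u > right)
    idx = np.nonzero(is_peak)[0]
    step = EXTENT / n
    peaks = []
    for i in idx:
        um, u0, up = u[(i - 1) % n], u[i], u[(i + 1) % n]
        denom = um - 2.0 * u0 + up
        delta = 0.0 if denom == 0 else 0.5 * (um - up) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
        loc = (coords[i] + delta * step) % EXTENT
        peaks.append((float(loc), float(u0)))
    # descending activation, ties -> lowest original index (stable sort)
    order = sorted(range(len(idx)), key=lambda j: (-peaks[j][1], idx[j]))
    return [peaks[j] for j in order]


@dataclass
class DynamicNode:
    """Scalar dynamic unit: a zero-dimensional field with self-excitation."""

    label: str
    h: float = -5.0
    tau: float = 20.0
    self_exc: float = 0.0
    q: float = 0.0
    sigmoid: SigmoidSpec = dc_field(default_factory=SigmoidSpec)
    u: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.u is None:
            self.u = float(self.h)

    def output(self) -> float:
        return float(sigmoid(np.array(self.u), self.sigmoid))


def node_step(
    node: DynamicNode,
    drive: float,
    dt: float,
    rng: Optional[np.random.Generator] = None,
) -> DynamicNode:
    """One Euler step of a scalar node; self-excitation acts on its output."""
    if not dt > 0:
        raise ValueError("dt must be positive")
    if dt >= node.tau:
        raise ValueError(f"dt={dt} >= tau={node.tau} for node {node.label!r}")
    lat = node.self_exc * node.output()
    node.u = node.u + (dt / node.tau) * (-node.u + node.h + drive + lat)
    if node.q:
        if rng is None:
            raise ValueError("rng required when noise amplitude q > 0")
        node.u = node.u + node.q * np.sqrt(dt) * float(rng.standard_normal())
    return node
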