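"""Forward simulation of multi-echo magnitude acquisitions.

Each voxel's noiseless signal follows the mono-exponential decay with a
constant offset, S(t) = A + S0 * exp(-t/T), evaluated at the protocol's
echo times.  Magnitude MRI noise is Rician: independent Gaussian noise of
standard deviation sigma is added to the real and imaginary channels and
the magnitude is taken, which biases low-SNR voxels upward (background
voxels converge to the Rayleigh mean sigma*sqrt(pi/2)).  SNR is defined as
mean tumor S0 divided by the per-channel sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .phantom import LABEL_TUMOR, PhantomVolume
from .protocols import Protocol

__all__ = ["EchoSeries", "simulate_acquisition", "rician"]


@dataclass
class EchoSeries:
    """An observed 4-D multi-echo magnitude image.

    ``voxels`` has shape (x, y, slice, echo) with the echo axis matching
    ``protocol.echo_times``; values are non-negative (magnitude data).
    The remaining fields are provenance metadata.
    """

    voxels: np.ndarray
    protocol: Protocol
    subject_id: str = "subject0"
    acquisition_index: int = 1
    contrast_state: str = "pre"
    seed: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=float)
        if v.ndim != 4:
            raise ValueError(f"voxels must be 4-D (x, y, slice, echo), got shape {v.shape}")
        if v.shape[3] != self.protocol.n_echoes:
            raise ValueError(
                f"echo axis length {v.shape[3]} != protocol echo count {self.protocol.n_echoes}"
            )
        if np.any(v < 0):
            raise ValueError("magnitude data must be non-negative")
        self.voxels = v

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape[:3])

    @property
    def echo_times_ms(self) -> np.ndarray:
        return self.protocol.echo_times_ms


def rician(noiseless: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Apply Rician noise: magnitude of (signal + complex Gaussian noise)."""
    if sigma < 0:
        raise ConfigError("sigma must be >= 0")
    if sigma == 0:
        return np.asarray(noiseless, dtype=float).copy()
    re = noiseless + rng.normal(0.0, sigma, noiseless.shape)
    im = rng.normal(0.0, sigma, noiseless.shape)
    return np.hypot(re, im)


def forward_signal(phantom: PhantomVolume, echo_times_ms: np.ndarray) -> np.ndarray:
    """Noiseless (x, y, z, echo) signal from the phantom's latent truth."""
    te = np.asarray(echo_times_ms, dtype=float)
    T = phantom.true_T
    with np.errstate(divide="ignore", invalid="ignore"):
        decay = np.exp(-te[None, None, None, :] / np.where(T > 0, T, np.inf)[..., None])
    decay[T <= 0] = 0.0  # background: no transverse signal
    return phantom.true_A[..., None] + phantom.true_S0[..., None] * decay


def simulate_acquisition(
    phantom: PhantomVolume,
    protocol: Protocol,
    snr: float | None,
    seed: int,
    *,
    noise_model: str = "rician",
    subject_id: str = "subject0",
    acquisition_index: int = 1,
) -> EchoSeries:
    """Simulate one multi-echo acquisition of the phantom.

    Parameters
    ----------
    snr : float or None
        Mean tumor S0 divided by per-channel noise sigma.  ``None`` (or
        ``inf``) disables noise, returning the forward model exactly.
    seed : int
        Seeds the noise realization only; two seeds on one phantom are the
        paired acquisitions of a test-retest design.
    noise_model : {"rician", "gaussian"}
        Gaussian adds real-channel noise only (analytic convenience);
        Rician is the physical model for magnitude MRI.
    """
    clean = forward_signal(phantom, protocol.echo_times_ms)
    if snr is None or np.isinf(snr):
        voxels = clean
    else:
        if snr <= 0:
            raise ConfigError("snr must be > 0 (or None for noiseless)")
        tumor = phantom.labels == LABEL_TUMOR
        s0_ref = float(phantom.true_S0[tumor].mean()) if tumor.any() else float(
            phantom.true_S0[phantom.labels > 0].mean()
        )
        sigma = s0_ref / snr
        rng = np.random.default_rng(seed)
        if noise_model == "rician":
            voxels = rician(clean, sigma, rng)
        elif noise_model == "gaussian":
            voxels = np.clip(clean + rng.normal(0.0, sigma, clean.shape), 0.0, None)
        else:
            raise ConfigError(f"unknown noise_model {noise_model!r}")
    return EchoSeries(
        voxels=voxels,
        protocol=protocol,
        subject_id=subject_id,
        acquisition_index=acquisition_index,
        contrast_state=phantom.contrast_state,
        seed=seed,
    )
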