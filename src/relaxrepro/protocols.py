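"""Multi-echo acquisition protocols.

A :class:`Protocol` describes one echo-train acquisition: field strength,
weighting (gradient-echo T2* or spin-echo T2), the explicit echo-time
vector, the sampling matrix and the slice geometry.  The four presets are
the multislice gradient-echo / spin-echo protocols used for T2* and T2
mapping of murine osteosarcomas at 3 T and 7 T; their echo trains are
expanded from minimum TE + echo spacing x echo-train-length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UnsupportedProtocolError

__all__ = ["Protocol", "protocol_preset", "PRESET_PARAMETERS"]


@dataclass(frozen=True)
class Protocol:
    """An echo-train acquisition description.

    Parameters
    ----------
    name : str
        Human-readable label, e.g. ``"7T_T2star"``.
    field_strength : float
        Static field in tesla.
    weighting : str
        ``"T2star"`` (multi-gradient-echo) or ``"T2"`` (multi-spin-echo).
    echo_times : tuple of float
        Echo times in milliseconds, strictly increasing, all positive,
        at least three (the decay model has three parameters).
    matrix : tuple of int
        In-plane sampling matrix (pixels x pixels).
    n_slices : int
        Number of slices.
    slice_thickness : float
        Slice thickness in millimeters.
    """

    name: str
    field_strength: float
    weighting: str
    echo_times: tuple[float, ...]
    matrix: tuple[int, int] = (64, 64)
    n_slices: int = 3
    slice_thickness: float = 1.0

    def __post_init__(self) -> None:
        if self.weighting not in ("T2star", "T2"):
            raise ValueError(f"weighting must be 'T2star' or 'T2', got {self.weighting!r}")
        te = np.asarray(self.echo_times, dtype=float)
        if te.size < 3:
            raise ValueError("echo_times must contain at least 3 echoes")
        if np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("echo_times must be positive and strictly increasing")
        object.__setattr__(self, "echo_times", tuple(float(t) for t in te))

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times)

    @property
    def echo_times_ms(self) -> np.ndarray:
        """Echo times as a float array (ms)."""
        return np.asarray(self.echo_times, dtype=float)


def _expand_train(min_te: float, spacing: float, etl: int) -> tuple[float, ...]:
    return tuple(min_te + k * spacing for k in range(etl))


# (field_strength, weighting) -> printed acquisition parameters:
# minimum TE (ms), echo spacing (ms), echo train length, matrix, slice thickness (mm)
PRESET_PARAMETERS: dict[tuple[int, str], dict] = {
    (3, "T2star"): dict(min_te=3.0, spacing=4.0, etl=12, matrix=(160, 160), slice_thickness=1.0),
    (3, "T2"): dict(min_te=12.0, spacing=12.0, etl=10, matrix=(160, 160), slice_thickness=1.0),
    (7, "T2star"): dict(min_te=3.5, spacing=5.0, etl=10, matrix=(256, 256), slice_thickness=1.0),
    (7, "T2"): dict(min_te=7.5, spacing=7.5, etl=13, matrix=(192, 192), slice_thickness=0.8),
}


def protocol_preset(
    field_strength: float,
    weighting: str,
    *,
    matrix: tuple[int, int] | None = None,
    n_slices: int = 3,
) -> Protocol:
    """Return one of the four preset mapping protocols.

    Parameters
    ----------
    field_strength : {3, 7}
        Scanner field in tesla.
    weighting : {"T2star", "T2"}
        Which relaxation time the echo train probes.
    matrix, n_slices : optional
        Override the in-plane matrix / slice count (the simulator works on
        smaller grids than the scanner matrix; echo timing is unchanged).

    Raises
    ------
    UnsupportedProtocolError
        If (field_strength, weighting) is not one of the four presets.
    """
    key = (int(field_strength), weighting)
    if float(field_strength) not in (3.0, 7.0) or key not in PRESET_PARAMETERS:
        raise UnsupportedProtocolError(
            f"no preset for field_strength={field_strength}, weighting={weighting!r}; "
            "supported: (3|7, 'T2star'|'T2')"
        )
    p = PRESET_PARAMETERS[key]
    return Protocol(
        name=f"{key[0]}T_{weighting}",
        field_strength=float(key[0]),
        weighting=weighting,
        echo_times=_expand_train(p["min_te"], p["spacing"], p["etl"]),
        matrix=tuple(matrix) if matrix is not None else p["matrix"],
        n_slices=n_slices,
        slice_thickness=p["slice_thickness"],
    )
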