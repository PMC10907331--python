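"""2-D geometry of an implanted cochlea.

The cochlear spiral is unrolled onto a straight longitudinal axis running
from the base (0 mm) to the apex (``cochlear_length`` mm, default 33.9 mm,
corresponding to an angular span of 0-900 degrees).  Auditory nerve fibers
(ANFs) lie equidistantly on the neural axis at height 0; each fiber stands
for a single site of excitation.  The electrode array lies on the lateral
wall above that axis, so the height of the scala tympani at an electrode's
longitudinal position is its electrode-neuron distance.  Two cubic height
profiles (10 % and 90 % quantiles of scala-tympani height across temporal
bones, labelled ``short`` and ``long``) provide the two electrode-neuron
distance conditions.  Every electrode contact is treated as a point source;
orientation and size of the contacts are ignored.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

# Greenwood frequency-position map for the human cochlea,
# F(x) = A (10^(a x) - k) with x the relative position from the apex.
GREENWOOD_A = 165.4
GREENWOOD_ALPHA = 2.1
GREENWOOD_K = 0.88

#: Default cubic scala-tympani height profiles, mm height as a function of
#: longitudinal position (mm from base), coefficients in increasing order.
#: ``short`` tracks the 10 % height quantile, ``long`` the 90 % quantile;
#: both decrease from base to apex and stay within the anatomically
#: plausible 0.4-1.4 mm band.  The exact coefficients are configurable
#: defaults (the quantile curves themselves are not tabulated anywhere);
#: every export records the coefficients actually used.
DEFAULT_HEIGHT_POLYNOMIALS: dict[str, tuple[float, float, float, float]] = {
    "short": (0.75, -0.018, 3.2e-4, -2.5e-6),
    "long": (1.33, -0.020, 3.2e-4, -2.5e-6),
}


def greenwood(position_mm: float | np.ndarray, length: float = 33.9) -> float | np.ndarray:
    """Characteristic frequency (Hz) at ``position_mm`` from the base."""
    x_rel = 1.0 - np.asarray(position_mm, dtype=float) / length  # rel. pos. from apex
    out = GREENWOOD_A * (10.0 ** (GREENWOOD_ALPHA * x_rel) - GREENWOOD_K)
    return float(out) if np.isscalar(position_mm) else out


def inverse_greenwood(frequency: float | np.ndarray, length: float = 33.9) -> float | np.ndarray:
    """Map a characteristic frequency (Hz) to its position in mm from the base.

    The highest mapped frequency (~20.6 kHz) sits at the base (0 mm), the
    lowest (~19.9 Hz) at the apex (``length`` mm); the returned position is
    monotonically decreasing in frequency.

    Raises
    ------
    ValueError
        If ``frequency`` falls outside the range covered by the map.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    f = np.asarray(frequency, dtype=float)
    arg = f / GREENWOOD_A + GREENWOOD_K
    with np.errstate(invalid="ignore"):
        x_rel = np.log10(arg) / GREENWOOD_ALPHA
    if np.any(~np.isfinite(x_rel)) or np.any(x_rel < -1e-12) or np.any(x_rel > 1 + 1e-12):
        raise ValueError(
            f"frequency {frequency!r} Hz outside the Greenwood map's valid range "
            f"({greenwood(length, length):.1f}-{greenwood(0.0, length):.0f} Hz)"
        )
    pos = length * (1.0 - np.clip(x_rel, 0.0, 1.0))
    return float(pos) if np.isscalar(frequency) else pos


def evaluate_height(coeffs, position_mm):
    """Evaluate a cubic height profile (coefficients in increasing order)."""
    c = np.asarray(coeffs, dtype=float)
    if c.shape != (4,):
        raise ValueError("height polynomial needs exactly 4 coefficients")
    return np.polynomial.polynomial.polyval(np.asarray(position_mm, dtype=float), c)


@dataclass
class GeometryConfig:
    """Configuration of the unrolled 2-D cochlea.

    ``apical_contact_position`` is the longitudinal position (mm from base)
    of contact #1, the most apical one; contacts are numbered apical to
    basal and spaced ``electrode_spacing`` mm apart, which puts contact #6
    of the default 12-contact array at mid-cochlear depth (14 mm).  The
    insertion depth is not prescribed anywhere, so it is configurable, and
    user-supplied per-contact characteristic frequencies
    (``electrode_cfs``, Hz, apical to basal) may replace the uniform
    spacing via the inverse Greenwood map.
    """

    cochlear_length: float = 33.9
    angular_span: float = 900.0
    n_electrodes: int = 12
    electrode_spacing: float = 2.0
    n_fibers: int = 2000
    height_profile: str = "short"
    apical_contact_position: float = 24.0
    electrode_cfs: tuple[float, ...] | None = None
    height_polynomials: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_HEIGHT_POLYNOMIALS)
    )

    def __post_init__(self) -> None:
        if self.cochlear_length <= 0:
            raise ValueError("cochlear_length must be positive")
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        if self.n_electrodes < 2:
            raise ValueError("n_electrodes must be >= 2")
        if self.height_profile not in self.height_polynomials:
            raise ValueError(
                f"unknown height_profile {self.height_profile!r}; "
                f"available: {sorted(self.height_polynomials)}"
            )
        x = np.linspace(0.0, self.cochlear_length, 512)
        for name, coeffs in self.height_polynomials.items():
            h = evaluate_height(coeffs, x)
            if np.any(h <= 0):
                raise ValueError(f"height profile {name!r} not strictly positive")
        if {"short", "long"} <= set(self.height_polynomials):
            xe = self.electrode_positions_longitudinal()
            h_short = evaluate_height(self.height_polynomials["short"], xe)
            h_long = evaluate_height(self.height_polynomials["long"], xe)
            if np.any(h_long < h_short):
                raise ValueError("'long' profile must lie at or above 'short' at every electrode")

    def electrode_positions_longitudinal(self) -> np.ndarray:
        """Longitudinal positions (mm from base) of contacts #1..#n (apical to basal)."""
        if self.electrode_cfs is not None:
            if len(self.electrode_cfs) != self.n_electrodes:
                raise ValueError("electrode_cfs length must equal n_electrodes")
            pos = np.asarray(
                [inverse_greenwood(f, self.cochlear_length) for f in self.electrode_cfs]
            )
        else:
            pos = self.apical_contact_position - self.electrode_spacing * np.arange(
                self.n_electrodes, dtype=float
            )
        if np.any(pos < 0) or np.any(pos > self.cochlear_length):
            raise ValueError("electrode array does not fit inside the cochlea")
        return pos


@dataclass
class CochlearGeometry:
    """Realised geometry: contact and fiber positions plus distance matrix."""

    config: GeometryConfig
    electrode_positions: np.ndarray  # (n_electrodes, 2): longitudinal mm, height mm
    fiber_positions: np.ndarray  # (n_fibers, 2): longitudinal mm, 0
    distances: np.ndarray  # (n_electrodes, n_fibers) Euclidean distances, mm

    @property
    def n_electrodes(self) -> int:
        return self.electrode_positions.shape[0]

    @property
    def n_fibers(self) -> int:
        return self.fiber_positions.shape[0]

    def electrode_index(self, electrode_id: int) -> int:
        if not 1 <= electrode_id <= self.n_electrodes:
            raise ValueError(f"electrode id {electrode_id} out of range 1..{self.n_electrodes}")
        return electrode_id - 1

    def distances_from(self, electrode_id: int) -> np.ndarray:
        """Distance vector (mm) from one contact to every fiber (r_s or r_r)."""
        return self.distances[self.electrode_index(electrode_id)]

    def electrode_fiber_distance(self, electrode_id: int) -> float:
        """Distance from a contact to the nearest fiber (~ local scala height)."""
        return float(self.distances_from(electrode_id).min())

    def export_csv(self) -> tuple[str, str]:
        """Return (electrodes CSV, fibers CSV) as text."""
        buf_e = io.StringIO()
        buf_e.write("electrode_id,x_mm,height_mm\n")
        for i, (x, h) in enumerate(self.electrode_positions, start=1):
            buf_e.write(f"{i},{x:.6f},{h:.6f}\n")
        buf_f = io.StringIO()
        buf_f.write("fiber_id,x_mm\n")
        for i, (x, _h) in enumerate(self.fiber_positions):
            buf_f.write(f"{i},{x:.6f}\n")
        return buf_e.getvalue(), buf_f.getvalue()


def euclidean_distances(points_a: np.ndarray, points_b: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances (mm) between two 2-D point sets."""
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("point sets must be non-empty")
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt(np.sum(diff**2, axis=-1))


def build_geometry(config: GeometryConfig) -> CochlearGeometry:
    """Place contacts on the selected height profile, fibers on the neural axis."""
    xe = config.electrode_positions_longitudinal()
    he = evaluate_height(config.height_polynomials[config.height_profile], xe)
    electrode_positions = np.column_stack([xe, he])

    if config.n_fibers == 1:
        xf = np.array([config.cochlear_length / 2.0])
    else:
        xf = np.linspace(0.0, config.cochlear_length, config.n_fibers)
    fiber_positions = np.column_stack([xf, np.zeros_like(xf)])

    distances = euclidean_distances(electrode_positions, fiber_positions)
    return CochlearGeometry(config, electrode_positions, fiber_positions, distances)
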