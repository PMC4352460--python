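"""Two-dimensional phase congruency from a log-Gabor filter bank.

Phase congruency marks image points where the Fourier components are
maximally in phase — edges and line features — and, because it is a
normalized quantity, it is largely invariant to uneven illumination and
contrast.  That makes it an attractive front end for *global*
thresholding of retinal vessels, whose raw intensities drift across the
fundus.

The map is computed orientation by orientation from quadrature pairs of
log-Gabor filters::

    PC(x, y) = sum_theta sum_t  W_theta * max(A_{t,theta} * dphi_{t,theta} - T_theta, 0)
               -----------------------------------------------------------------------
                          sum_theta sum_t  A_{t,theta}(x, y)  +  eps

where ``A_{t,theta}`` is the filter-response amplitude at scale ``t``,
``dphi`` measures the deviation of the local phase from the amplitude-
weighted mean phase, ``T_theta`` is a noise floor estimated from the
smallest-scale amplitude distribution (assumed Rayleigh), and
``W_theta`` is a sigmoid weight that penalizes narrow frequency spread.
The result lies in ``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PhaseCongParams", "log_gabor_bank", "phase_congruency_map"]

# guard for the amplitude normalisation inside each orientation; kept
# fixed (not user-facing) so the user-facing eps acts purely as the
# final-denominator regularizer
_NORM_GUARD = 1e-12


@dataclass(frozen=True)
class PhaseCongParams:
    """Tuning constants of the phase-congruency model.

    n_scale, n_orient
        Number of wavelet scales and of filter orientations.
    min_wavelength
        Wavelength (pixels) of the smallest-scale filter.
    mult
        Scaling factor between successive filter wavelengths.
    sigma_on_f
        Ratio of the log-Gabor radial Gaussian's standard deviation to
        the filter center frequency (bandwidth control).
    d_theta_on_sigma
        Ratio of the angular interval between orientations to the
        angular Gaussian's standard deviation.
    k
        Number of noise standard deviations above the mean noise energy
        at which the noise floor ``T`` is set; ``k = 0`` disables noise
        suppression.
    cut_off, g
        Fractional frequency spread below which congruency is
        penalized, and the sharpness of that sigmoid penalty.
    epsilon
        Regularizer added to the energy-sum denominator.
    phase_measure
        ``"cos_minus_abs_sin"`` (default): ``cos(dphi) - |sin(dphi)|``,
        the sensitive deviation measure; ``"cos"``: plain ``cos(dphi)``.
    """

    n_scale: int = 4
    n_orient: int = 6
    min_wavelength: float = 3.0
    mult: float = 2.1
    sigma_on_f: float = 0.55
    d_theta_on_sigma: float = 1.2
    k: float = 2.3
    cut_off: float = 0.5
    g: float = 10.0
    epsilon: float = 1e-4
    phase_measure: str = "cos_minus_abs_sin"

    def __post_init__(self) -> None:
        if self.n_scale < 1 or self.n_orient < 1:
            raise ValueError("n_scale and n_orient must be >= 1")
        if self.mult <= 1.0:
            raise ValueError("mult must exceed 1")
        if not 0.0 < self.cut_off < 1.0:
            raise ValueError("cut_off must lie in (0, 1)")
        if self.epsilon <= 0.0:
            raise ValueError("epsilon must be positive")
        if self.phase_measure not in ("cos", "cos_minus_abs_sin"):
            raise ValueError("phase_measure must be 'cos' or 'cos_minus_abs_sin'")

    # tuned parameter sets for the two standard fundus databases
    @classmethod
    def drive(cls) -> "PhaseCongParams":
        """Settings tuned for DRIVE-resolution (565x584) images."""
        return cls()

    @classmethod
    def stare(cls) -> "PhaseCongParams":
        """Settings tuned for STARE-resolution (700x605) images."""
        return cls(
            n_scale=3, n_orient=5, min_wavelength=2.5, mult=2.9,
            sigma_on_f=1.5, d_theta_on_sigma=1.7, k=3.0, cut_off=0.5, g=14.0,
        )

    _ALIASES = {
        "nscale": "n_scale",
        "norient": "n_orient",
        "minwavelength": "min_wavelength",
        "mult": "mult",
        "sigmaonf": "sigma_on_f",
        "dthetaonsigma": "d_theta_on_sigma",
        "k": "k",
        "cutoff": "cut_off",
        "g": "g",
        "epsilon": "epsilon",
        "phase_measure": "phase_measure",
    }

    @classmethod
    def from_config(cls, mapping: dict) -> "PhaseCongParams":
        """Build params from a config dict; the conventional camelCase
        names (nscale, norient, minWaveLength, sigmaOnf, dThetaOnSigma,
        cutOff, ...) are accepted verbatim alongside the field names."""
        kwargs = {}
        fields = {f for f in cls.__dataclass_fields__}
        for key, value in mapping.items():
            low = key.lower()
            if key in fields:
                kwargs[key] = value
            elif low in cls._ALIASES:
                kwargs[cls._ALIASES[low]] = value
            else:
                raise ValueError(f"unknown phase-congruency parameter {key!r}")
        return cls(**kwargs)


def _frequency_grids(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized radius and unit direction grids in FFT layout."""
    rows, cols = shape
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    radius = np.hypot(fx, fy)
    radius[0, 0] = 1.0  # avoid log(0); DC is zeroed explicitly later
    theta = np.arctan2(-fy, fx)  # +y up so angles follow math convention
    return radius, np.sin(theta), np.cos(theta)


def _radial_filters(radius: np.ndarray, params: PhaseCongParams) -> list[np.ndarray]:
    # ideal-ish lowpass keeps the largest-scale filters from wrapping
    # at the Nyquist corners
    lowpass = 1.0 / (1.0 + (radius / 0.45) ** 30)
    out = []
    log_sig = 2.0 * np.log(params.sigma_on_f) ** 2
    for t in range(params.n_scale):
        wavelength = params.min_wavelength * params.mult**t
        f0 = 1.0 / wavelength
        lg = np.exp(-(np.log(radius / f0) ** 2) / log_sig) * lowpass
        lg[0, 0] = 0.0
        out.append(lg)
    return out


def _angular_spreads(
    sin_t: np.ndarray, cos_t: np.ndarray, params: PhaseCongParams
) -> list[np.ndarray]:
    sigma_theta = (np.pi / params.n_orient) / params.d_theta_on_sigma
    out = []
    for j in range(params.n_orient):
        angle = j * np.pi / params.n_orient
        ds = sin_t * np.cos(angle) - cos_t * np.sin(angle)
        dc = cos_t * np.cos(angle) + sin_t * np.sin(angle)
        dtheta = np.abs(np.arctan2(ds, dc))
        out.append(np.exp(-(dtheta**2) / (2.0 * sigma_theta**2)))
    return out


def log_gabor_bank(
    shape: tuple[int, int], params: PhaseCongParams | None = None
) -> np.ndarray:
    """Frequency-domain log-Gabor transfer functions.

    Returns an array of shape ``(n_scale, n_orient, H, W)`` in FFT
    (unshifted) layout.  Each filter has unit peak along its center
    frequency ``f_t = 1 / (min_wavelength * mult**t)`` and exactly zero
    response at DC.
    """
    params = params or PhaseCongParams()
    radius, sin_t, cos_t = _frequency_grids(shape)
    radials = _radial_filters(radius, params)
    spreads = _angular_spreads(sin_t, cos_t, params)
    bank = np.empty((params.n_scale, params.n_orient) + tuple(shape))
    for t, rad in enumerate(radials):
        for j, spr in enumerate(spreads):
            bank[t, j] = rad * spr
    return bank


def phase_congruency_map(
    img: np.ndarray, params: PhaseCongParams | None = None
) -> np.ndarray:
    """Phase-congruency map of a 2-D image, values in [0, 1].

    The image is extended even-symmetrically (mirrored to twice its
    size) before the frequency-domain filtering so that the implicit
    periodicity of the FFT introduces no boundary discontinuities.
    A constant image yields an all-zero map.
    """
    params = params or PhaseCongParams()
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("phase_congruency_map expects a 2-D gray image")
    H, W = img.shape

    padded = np.pad(img, ((0, H), (0, W)), mode="symmetric")
    IM = np.fft.fft2(padded)

    radius, sin_t, cos_t = _frequency_grids(padded.shape)
    radials = _radial_filters(radius, params)
    spreads = _angular_spreads(sin_t, cos_t, params)

    total_energy = np.zeros_like(padded)
    total_sum_an = np.zeros_like(padded)

    for spread in spreads:
        sum_e = np.zeros_like(padded)
        sum_o = np.zeros_like(padded)
        sum_an = np.zeros_like(padded)
        max_an = np.zeros_like(padded)
        eo_list = []
        tau = 0.0
        for t, rad in enumerate(radials):
            eo = np.fft.ifft2(IM * (rad * spread))
            e, o = eo.real, eo.imag
            an = np.abs(eo)
            eo_list.append((e, o))
            sum_e += e
            sum_o += o
            sum_an += an
            np.maximum(max_an, an, out=max_an)
            if t == 0:
                # Rayleigh scale from the median of the smallest-scale
                # amplitudes: median = tau * sqrt(ln 4)
                tau = np.median(an) / np.sqrt(np.log(4.0))

        x_energy = np.hypot(sum_e, sum_o) + _NORM_GUARD
        mean_e = sum_e / x_energy
        mean_o = sum_o / x_energy

        energy = np.zeros_like(padded)
        for e, o in eo_list:
            if params.phase_measure == "cos_minus_abs_sin":
                energy += e * mean_e + o * mean_o - np.abs(e * mean_o - o * mean_e)
            else:
                energy += e * mean_e + o * mean_o

        if params.k > 0.0:
            # total noise amplitude over scales assuming geometric decay
            # of the filter gains, then Rayleigh mean + k sigma
            inv_m = 1.0 / params.mult
            total_tau = tau * (1.0 - inv_m**params.n_scale) / (1.0 - inv_m)
            noise_mean = total_tau * np.sqrt(np.pi / 2.0)
            noise_sigma = total_tau * np.sqrt((4.0 - np.pi) / 2.0)
            T = noise_mean + params.k * noise_sigma
            energy = np.maximum(energy - T, 0.0)
        else:
            energy = np.maximum(energy, 0.0)

        spread_frac = (sum_an / (max_an + _NORM_GUARD)) / params.n_scale
        weight = 1.0 / (1.0 + np.exp(params.g * (params.cut_off - spread_frac)))

        total_energy += weight * energy
        total_sum_an += sum_an

    pc = total_energy / (total_sum_an + params.epsilon)
    return pc[:H, :W]
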