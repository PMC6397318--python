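"""Standard OCT intensity composition and the depth-resolved attenuation coefficient.

Standard B-scans are obtained by coherent composition of the repeated
acquisitions: each repeat is phase-aligned to the first (one global phase
per repeat per A-line, estimated from the complex inner product over depth)
and the aligned channel fields are averaged before taking the intensity.
Coherent averaging of N independent noise realizations reduces the noise
power by 1/N while leaving static signal untouched.

The attenuation coefficient is estimated depth-resolved from the composed
linear intensity under the assumptions of the Vermeer-style model (all
light attenuated within the recorded depth range, backscatter proportional
to attenuation).  With ``S[i] = sum_{j>i} I[j]``:

* ``method="log"`` (default): ``mu[i] = ln(1 + I[i]/S[i]) / (2 dz)`` —
  exact on sampled exponentials for any ``mu * dz``;
* ``method="linear"``: ``mu[i] = I[i] / (2 dz S[i])`` — the small-step
  limit of the same estimator, biased by ``(e^{2 mu dz} - 1)/(2 mu dz)``.

The truncated tail sum inflates ``mu`` near the bottom of the A-line;
``tail_policy="trim"`` (default) marks the deepest fraction invalid and
``"extrapolate"`` extends the sum with a geometric tail whose rate is fit
to the deepest valid samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IntensityVolume",
    "AttenuationVolume",
    "compose_standard_oct",
    "attenuation_coefficient",
]


@dataclass
class IntensityVolume:
    """Linear composed intensity per voxel, grid ``(nb, nz, nx)``."""

    linear: np.ndarray
    dz: float
    n_repeats: int = 1
    phase_aligned: bool = True
    meta: dict = field(default_factory=dict)

    def db(self, eps: float = 1e-12) -> np.ndarray:
        """Decibel view ``10 log10(linear + eps)``."""
        return 10.0 * np.log10(self.linear + eps)

    @property
    def shape(self):
        return self.linear.shape


@dataclass
class AttenuationVolume:
    """Depth-resolved attenuation ``mu`` (mm^-1) and its log10.

    ``a_log = log10(mu)`` is the quantity entering F_RPE; it is deliberately
    *not* clamped at zero — ``mu < 1`` gives negative values that the
    downstream F_RPE threshold rejects naturally.  ``a_log`` is NaN where
    invalid or ``mu <= 0``.
    """

    mu: np.ndarray
    a_log: np.ndarray
    valid: np.ndarray
    tail_policy: str
    meta: dict = field(default_factory=dict)


def compose_standard_oct(volume) -> IntensityVolume:
    """Coherently compose repeated B-scans into one standard OCT volume."""
    nrep = volume.n_repeats
    h0, v0 = volume.h[0], volume.v[0]
    h_acc = h0.astype(np.complex128).copy()
    v_acc = v0.astype(np.complex128).copy()
    for r in range(1, nrep):
        # one global phase per repeat per A-line, from the depth inner product
        inner = np.sum(
            volume.h[r] * np.conj(h0) + volume.v[r] * np.conj(v0),
            axis=1,
            dtype=np.complex128,
        )  # (nb, nx)
        mag = np.abs(inner)
        phase = np.where(mag > 0, inner / np.where(mag > 0, mag, 1.0), 1.0)
        align = np.conj(phase)[:, None, :]
        h_acc += volume.h[r] * align
        v_acc += volume.v[r] * align
    h_mean = h_acc / nrep
    v_mean = v_acc / nrep
    linear = np.abs(h_mean) ** 2 + np.abs(v_mean) ** 2
    return IntensityVolume(
        linear=linear,
        dz=volume.dz,
        n_repeats=nrep,
        phase_aligned=True,
        meta={"composition": "coherent"},
    )


def _fit_tail_mu(linear: np.ndarray, dz: float, n_fit: int = 10) -> np.ndarray:
    """Per-A-line attenuation rate fit to the log-intensity of the deepest samples."""
    tail = linear[:, -n_fit:, :]
    with np.errstate(divide="ignore"):
        logs = np.log(np.where(tail > 0, tail, np.nan))
    z = np.arange(n_fit, dtype=np.float64)[None, :, None]
    zbar = np.nanmean(np.where(np.isnan(logs), np.nan, z), axis=1)
    lbar = np.nanmean(logs, axis=1)
    cov = np.nansum((z - zbar[:, None, :]) * (logs - lbar[:, None, :]), axis=1)
    var = np.nansum((z - zbar[:, None, :]) ** 2 * ~np.isnan(logs), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = cov / var
    mu = -slope / (2.0 * dz)
    return np.where(np.isfinite(mu) & (mu > 0), mu, 0.0)  # (nb, nx)


def attenuation_coefficient(
    intensity: IntensityVolume,
    dz: float | None = None,
    tail_policy: str = "trim",
    *,
    trim_fraction: float = 0.1,
    method: str = "log",
) -> AttenuationVolume:
    """Depth-resolved attenuation coefficient of a composed intensity volume."""
    dz = intensity.dz if dz is None else dz
    if not dz > 0:
        raise ValueError("dz must be > 0")
    if tail_policy not in ("trim", "extrapolate"):
        raise ValueError(f"unknown tail_policy {tail_policy!r}")
    if method not in ("log", "linear"):
        raise ValueError(f"unknown method {method!r}")

    linear = np.asarray(intensity.linear, dtype=np.float64)
    nb, nz, nx = linear.shape
    # S[i] = sum of intensities strictly deeper than i
    rev_cum = np.cumsum(linear[:, ::-1, :], axis=1)[:, ::-1, :]
    tail_sum = rev_cum - linear

    if tail_policy == "extrapolate":
        mu_tail = _fit_tail_mu(linear, dz)  # (nb, nx)
        q = np.exp(-2.0 * mu_tail * dz)
        with np.errstate(divide="ignore", invalid="ignore"):
            geo = np.where(mu_tail > 0, q / (1.0 - q), 0.0)
        tail_sum = tail_sum + (linear[:, -1, :] * geo)[:, None, :]

    valid = tail_sum > 0
    mu = np.zeros_like(linear)
    if method == "log":
        ratio = np.divide(linear, tail_sum, out=np.zeros_like(linear), where=valid)
        mu = np.log1p(ratio) / (2.0 * dz)
    else:
        np.divide(linear, 2.0 * dz * tail_sum, out=mu, where=valid)
    mu[~valid] = 0.0

    if tail_policy == "trim":
        n_trim = int(np.ceil(trim_fraction * nz))
        if n_trim > 0:
            valid = valid.copy()
            valid[:, nz - n_trim :, :] = False

    with np.errstate(divide="ignore", invalid="ignore"):
        a_log = np.where(valid & (mu > 0), np.log10(np.where(mu > 0, mu, 1.0)), np.nan)
    return AttenuationVolume(
        mu=mu,
        a_log=a_log,
        valid=valid,
        tail_policy=tail_policy,
        meta={"method": method, "trim_fraction": trim_fraction, "dz": dz},
    )
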