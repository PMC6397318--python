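"""The RPE-melanin-specific contrast F_RPE.

Melanin in both the RPE and the choroidal stroma depolarizes light, so DOPU
alone cannot separate the two when they abut (e.g. at the margin of a PED).
F_RPE multiplies three co-registered contrasts so that only static,
strongly attenuating, depolarizing tissue — RPE melanin — survives:

    F_RPE = a_log * (1 - DOPU) * (1 - OCTA_b)

with ``a_log`` the log10 attenuation coefficient (mm^-1), DOPU the degree
of polarization uniformity, and ``OCTA_b`` the binarized angiography mask
(1 on vasculature).  Choroidal melanin is removed by the flow term, weakly
attenuating tissue by ``a_log`` (negative below 1 mm^-1), and
polarization-preserving tissue by the DOPU term.  The melanin mask applies
the fixed inclusive threshold F_RPE >= 0.15.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .angiography import BinaryMask, OctaImage
from .intensity import AttenuationVolume
from .polarimetry import DopuImage

__all__ = ["FrpeVolume", "MelaninMask", "compute_frpe", "binarize_frpe", "enface_max_frpe"]


@dataclass
class FrpeVolume:
    """F_RPE per voxel with a conjunctive invalid mask."""

    values: np.ndarray
    valid: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.values.shape


@dataclass
class MelaninMask:
    """Binarized RPE-melanin volume (F_RPE >= threshold, valid voxels only)."""

    values: np.ndarray
    threshold: float


def compute_frpe(
    a_log: AttenuationVolume, dopu: DopuImage, octa_b: BinaryMask
) -> FrpeVolume:
    """Voxel-wise F_RPE from the three co-registered component contrasts.

    A voxel is invalid if any component is invalid; vasculature (OCTA_b)
    and fully polarization-preserving voxels (DOPU = 1) map exactly to 0.
    """
    shapes = {
        "a_log": a_log.a_log.shape,
        "dopu": dopu.values.shape,
        "octa_b": octa_b.values.shape,
    }
    if len({s for s in shapes.values()}) != 1:
        raise ValueError(f"component grids differ: {shapes}")
    flow = octa_b.values.astype(np.float64)
    valid = a_log.valid & np.isfinite(a_log.a_log) & dopu.valid
    if octa_b.valid is not None:
        valid &= octa_b.valid
    values = np.zeros(a_log.a_log.shape, dtype=np.float64)
    np.multiply(
        np.where(valid, a_log.a_log, 0.0),
        (1.0 - dopu.values) * (1.0 - flow),
        out=values,
    )
    values[~valid] = 0.0
    return FrpeVolume(
        values=values,
        valid=valid,
        meta={
            "dopu_kernel": dopu.kernel,
            "octa_threshold": octa_b.threshold,
            "attenuation": dict(a_log.meta),
        },
    )


def binarize_frpe(frpe: FrpeVolume, threshold: float = 0.15) -> MelaninMask:
    """RPE-melanin mask: valid voxels with F_RPE >= threshold (inclusive)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return MelaninMask(
        values=(frpe.values >= threshold) & frpe.valid,
        threshold=float(threshold),
    )


def enface_max_frpe(frpe: FrpeVolume) -> tuple[np.ndarray, np.ndarray]:
    """En face map of the maximum valid F_RPE along depth.

    Returns ``(map, has_valid)`` on the (B-scan, A-line) grid; columns
    without any valid voxel carry NaN in the map and False in the flag.
    """
    masked = np.where(frpe.valid, frpe.values, -np.inf)
    out = masked.max(axis=1)  # depth is axis 1 of (nb, nz, nx)
    has_valid = frpe.valid.any(axis=1)
    out = np.where(has_valid, out, np.nan)
    return out, has_valid
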