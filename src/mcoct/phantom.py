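"""Synthetic MC-OCT phantoms with voxel-level ground truth.

The generator emulates the statistical structure the downstream pipeline
relies on, layer by layer along each A-line:

* fully developed speckle — the complex backscattered amplitude of every
  voxel is circular complex Gaussian, so linear intensity is exponentially
  distributed around the Beer–Lambert expectation
  ``backscatter * exp(-2 * sum(mu * dz))``;
* melanin-induced polarization scrambling — melanin voxels (RPE band,
  choroidal stroma) carry an independent random pure polarization state,
  uniform on the Poincaré sphere, while all other tissue preserves the
  incident state; kernel averaging downstream turns this into low DOPU;
* flow decorrelation — choroidal flow voxels redraw independent speckle for
  every repeat, static voxels share one draw across repeats up to a global
  per-repeat phase (axial bulk motion surrogate, constant within a B-scan);
* additive circular complex detector noise of variance ``sigma2`` per
  polarization channel per repeat.

Lesion anatomy: a serous PED lifts the retina/RPE complex into a dome above
Bruch's membrane, the sub-RPE space fills with weakly scattering fluid,
focal RPE defects remove melanin (and most attenuation) from rectangular
lateral footprints of the band, and hyper-reflective foci are bright
ellipsoid blobs inside the PED fluid.

Axis convention: volumes are indexed ``(bscan, depth, aline)``; the raw
repeats carry a leading repeat axis.  Depth index 0 is the vitreous side.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = [
    "LayerSpec",
    "PedSpec",
    "DefectSpec",
    "HrfBlobSpec",
    "PhantomSpec",
    "GroundTruth",
    "MCOCTVolume",
    "LABELS",
    "PRESETS",
    "default_spec",
    "build_phantom",
]

#: ground-truth label codes, vitreous → sclera direction
LABELS = {
    "vitreous": 0,
    "inner_retina": 1,
    "elm": 2,
    "ez": 3,
    "outer_segments": 4,
    "rpe_bruchs": 5,
    "fluid": 6,
    "choroid": 7,
    "hrf": 8,
}


class PhantomValidationError(ValueError):
    """A :class:`PhantomSpec` violates one of its invariants."""


@dataclass(frozen=True)
class LayerSpec:
    """One tissue layer: geometry plus optical and contrast properties.

    ``backscatter`` is the expected linear backscattered intensity at the
    layer top before attenuation (arbitrary units); ``mu`` the attenuation
    coefficient in mm^-1; ``melanin_fraction`` the probability that a voxel
    scrambles polarization; ``flow_fraction`` the probability that a voxel
    decorrelates between repeats.
    """

    name: str
    thickness_px: int
    backscatter: float
    mu: float
    melanin_fraction: float = 0.0
    flow_fraction: float = 0.0


@dataclass(frozen=True)
class PedSpec:
    """Serous PED dome: half-ellipsoid elevation of the RPE above Bruch's.

    ``center`` is (bscan, aline); ``radii`` are the lateral half-axes in
    (B-scans, A-lines); ``apex_px`` the apex elevation in depth pixels.
    """

    center: tuple[int, int]
    radii: tuple[float, float]
    apex_px: float


@dataclass(frozen=True)
class DefectSpec:
    """Rectangular lateral footprint where RPE melanin is removed.

    Half-open index ranges ``bscan_range=(b0, b1)``, ``aline_range=(x0, x1)``.
    Within the footprint the band keeps a weakly scattering, weakly
    attenuating remnant (``residual_backscatter``, ``residual_mu``) so the
    hyper-transmission motif emerges in the intensity image.
    """

    bscan_range: tuple[int, int]
    aline_range: tuple[int, int]
    residual_backscatter: float = 0.05
    residual_mu: float = 0.3


@dataclass(frozen=True)
class HrfBlobSpec:
    """Bright ellipsoid hyper-reflective focus inside the PED fluid."""

    center: tuple[int, int, int]  # (bscan, depth, aline)
    radii: tuple[float, float, float]
    backscatter: float = 0.9
    mu: float = 8.0


@dataclass(frozen=True)
class PhantomSpec:
    """Complete description of one synthetic MC-OCT acquisition."""

    n_alines: int = 128
    n_bscans: int = 64
    n_depth: int = 200
    n_repeats: int = 4
    dx: float = 6.0 / 128
    dy: float = 6.0 / 64
    dz: float = 0.006
    vitreous_px: int = 35
    layers: tuple[LayerSpec, ...] = (
        LayerSpec("inner_retina", 50, 0.35, 1.5),
        LayerSpec("elm", 2, 0.25, 2.0),
        LayerSpec("ez", 3, 0.60, 3.0),
        LayerSpec("outer_segments", 5, 0.08, 0.8),
        LayerSpec("rpe_bruchs", 5, 1.00, 25.0, melanin_fraction=0.9),
    )
    choroid: LayerSpec = LayerSpec(
        "choroid", 0, 0.8, 4.0, melanin_fraction=0.5, flow_fraction=0.9
    )
    fluid_backscatter: float = 0.02
    fluid_mu: float = 0.3
    ped: Optional[PedSpec] = None
    defects: tuple[DefectSpec, ...] = ()
    hrf_blobs: tuple[HrfBlobSpec, ...] = ()
    noise_variance: float = 2e-5
    seed: int = 0

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`PhantomValidationError` naming the offending field."""
        for name in ("n_alines", "n_bscans", "n_depth", "n_repeats"):
            if int(getattr(self, name)) < 1:
                raise PhantomValidationError(f"{name} must be >= 1")
        for name in ("dx", "dy", "dz"):
            if not getattr(self, name) > 0:
                raise PhantomValidationError(f"{name} must be > 0")
        if self.noise_variance < 0:
            raise PhantomValidationError("noise_variance must be >= 0")
        for lay in (*self.layers, self.choroid):
            if lay.mu < 0:
                raise PhantomValidationError(f"layers[{lay.name}].mu must be >= 0")
            for frac in ("melanin_fraction", "flow_fraction"):
                if not 0.0 <= getattr(lay, frac) <= 1.0:
                    raise PhantomValidationError(
                        f"layers[{lay.name}].{frac} must be in [0, 1]"
                    )
        names = [lay.name for lay in self.layers]
        if "rpe_bruchs" not in names:
            raise PhantomValidationError("layers must contain an 'rpe_bruchs' band")
        stack_bottom = self.vitreous_px + sum(l.thickness_px for l in self.layers)
        if stack_bottom >= self.n_depth:
            raise PhantomValidationError("layers: retinal stack exceeds n_depth")
        if self.ped is not None:
            if self.ped.apex_px < 0:
                raise PhantomValidationError("ped.apex_px must be >= 0")
            retina_top = self.vitreous_px - self.ped.apex_px
            if retina_top < 0:
                raise PhantomValidationError(
                    "ped.apex_px lifts the retina out of the frame"
                )
        for i, d in enumerate(self.defects):
            b0, b1 = d.bscan_range
            x0, x1 = d.aline_range
            if not (0 <= b0 < b1 <= self.n_bscans and 0 <= x0 < x1 <= self.n_alines):
                raise PhantomValidationError(
                    f"defects[{i}]: footprint outside the lateral grid"
                )
        if self.hrf_blobs and self.ped is None:
            raise PhantomValidationError("hrf_blobs require a ped region")

    # -- convenience --------------------------------------------------
    @property
    def band_top_base(self) -> int:
        """Baseline (no dome) depth of the top of the RPE–Bruch's band."""
        z = self.vitreous_px
        for lay in self.layers:
            if lay.name == "rpe_bruchs":
                return z
            z += lay.thickness_px
        raise PhantomValidationError("layers must contain an 'rpe_bruchs' band")

    @property
    def band_thickness(self) -> int:
        return next(l.thickness_px for l in self.layers if l.name == "rpe_bruchs")

    def spec_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class GroundTruth:
    """Phantom-only truth channels for parameter-recovery testing."""

    layer_label: np.ndarray  # (nb, nz, nx) uint8, codes in LABELS
    melanin: np.ndarray  # (nb, nz, nx) bool
    flow: np.ndarray  # (nb, nz, nx) bool
    mu: np.ndarray  # (nb, nz, nx) float32, mm^-1
    band_center: np.ndarray  # (nb, nx) float32, depth px of band centre
    band_half_thickness: int
    ped_mask: np.ndarray  # (nb, nz, nx) bool (sub-RPE cavity incl. HRF)
    defect_footprint: np.ndarray  # (nb, nx) bool
    hrf_mask: np.ndarray  # (nb, nz, nx) bool


@dataclass
class MCOCTVolume:
    """Raw multi-repeat two-channel complex MC-OCT volume.

    ``h``/``v`` have shape ``(n_repeats, n_bscans, n_depth, n_alines)``.
    """

    h: np.ndarray
    v: np.ndarray
    dx: float
    dy: float
    dz: float
    noise_variance: float
    meta: dict = field(default_factory=dict)

    @property
    def n_repeats(self) -> int:
        return self.h.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        """Grid shape ``(n_bscans, n_depth, n_alines)``."""
        return self.h.shape[1:]

    def intensity(self, repeat: int = 0) -> np.ndarray:
        g = (self.h[repeat], self.v[repeat])
        return (np.abs(g[0]) ** 2 + np.abs(g[1]) ** 2).astype(np.float64)


# ----------------------------------------------------------------------
# presets
# ----------------------------------------------------------------------

def _reduced(**over) -> PhantomSpec:
    return PhantomSpec(**over)


def _ped(apex=25.0) -> PedSpec:
    return PedSpec(center=(32, 64), radii=(22.0, 42.0), apex_px=apex)


PRESETS = {
    "healthy": lambda: _reduced(),
    "ped_with_defect": lambda: _reduced(
        ped=_ped(),
        defects=(DefectSpec(bscan_range=(28, 36), aline_range=(56, 68)),),
    ),
    "ped_with_hrf": lambda: _reduced(
        ped=_ped(),
        hrf_blobs=(
            HrfBlobSpec(center=(32, 85, 64), radii=(2.5, 5.0, 5.0)),
            HrfBlobSpec(center=(28, 88, 50), radii=(2.0, 4.0, 4.0)),
        ),
    ),
    "defect_at_ped_margin": lambda: _reduced(
        ped=_ped(),
        defects=(DefectSpec(bscan_range=(28, 36), aline_range=(96, 104)),),
    ),
}


def default_spec(preset: str, *, seed: int = 0, full_grid: bool = False) -> PhantomSpec:
    """Return a fully populated :class:`PhantomSpec` for a named scenario.

    Presets use a reduced 128 × 64 × 200 grid (same 6 × 6 mm field of view)
    so full pipelines run in seconds; ``full_grid=True`` scales the lateral
    grid to the clinical 512 × 256 raster.
    """
    if preset not in PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; valid presets: {sorted(PRESETS)}"
        )
    spec = PRESETS[preset]()
    if full_grid:
        fb, fx = 256 // spec.n_bscans, 512 // spec.n_alines
        scale = dict(
            n_alines=512,
            n_bscans=256,
            n_depth=2 * spec.n_depth,
            dx=6.0 / 512,
            dy=6.0 / 256,
        )
        # lateral features scale with the raster; axial geometry is kept
        if spec.ped is not None:
            p = spec.ped
            scale["ped"] = PedSpec(
                (p.center[0] * fb, p.center[1] * fx),
                (p.radii[0] * fb, p.radii[1] * fx),
                p.apex_px,
            )
        if spec.defects:
            scale["defects"] = tuple(
                DefectSpec(
                    (d.bscan_range[0] * fb, d.bscan_range[1] * fb),
                    (d.aline_range[0] * fx, d.aline_range[1] * fx),
                    d.residual_backscatter,
                    d.residual_mu,
                )
                for d in spec.defects
            )
        if spec.hrf_blobs:
            scale["hrf_blobs"] = tuple(
                HrfBlobSpec(
                    (b.center[0] * fb, b.center[1], b.center[2] * fx),
                    (b.radii[0] * fb, b.radii[1], b.radii[2] * fx),
                    b.backscatter,
                    b.mu,
                )
                for b in spec.hrf_blobs
            )
        spec = PhantomSpec(**{**asdict_spec(spec), **scale})
    if seed != spec.seed:
        spec = PhantomSpec(**{**asdict_spec(spec), "seed": seed})
    return spec


def asdict_spec(spec: PhantomSpec) -> dict:
    """Shallow field dict keeping nested dataclasses intact."""
    return {k: getattr(spec, k) for k in spec.__dataclass_fields__}


# ----------------------------------------------------------------------
# construction
# ----------------------------------------------------------------------

def _dome_height(spec: PhantomSpec) -> np.ndarray:
    """PED elevation in pixels per (bscan, aline); zeros without a PED."""
    nb, nx = spec.n_bscans, spec.n_alines
    if spec.ped is None:
        return np.zeros((nb, nx), dtype=np.float64)
    cb, cx = spec.ped.center
    rb, rx = spec.ped.radii
    b = (np.arange(nb)[:, None] - cb) / rb
    x = (np.arange(nx)[None, :] - cx) / rx
    r2 = b * b + x * x
    h = np.zeros((nb, nx))
    inside = r2 < 1.0
    h[inside] = spec.ped.apex_px * np.sqrt(1.0 - r2[inside])
    return h


def _build_truth(spec: PhantomSpec) -> GroundTruth:
    nb, nz, nx = spec.n_bscans, spec.n_depth, spec.n_alines
    z = np.arange(nz, dtype=np.float64)[None, :, None]  # (1, nz, 1)
    h = _dome_height(spec)[:, None, :]  # (nb, 1, nx)

    label = np.zeros((nb, nz, nx), dtype=np.uint8)
    top = spec.vitreous_px - h
    for lay in spec.layers:
        bottom = top + lay.thickness_px
        label[(z >= top) & (z < bottom)] = LABELS[lay.name]
        top = bottom
    # `top` is now the (elevated) band bottom; Bruch's line is its baseline
    bruchs = spec.band_top_base + spec.band_thickness
    fluid = (z >= top) & (z < bruchs)
    label[fluid] = LABELS["fluid"]
    label[z >= np.maximum(top, bruchs)] = LABELS["choroid"]

    band_center = (spec.band_top_base - h[:, 0, :]) + (spec.band_thickness - 1) / 2.0

    hrf_mask = np.zeros((nb, nz, nx), dtype=bool)
    zb = np.arange(nb)[:, None, None]
    zz = np.arange(nz)[None, :, None]
    zx = np.arange(nx)[None, None, :]
    for i, blob in enumerate(spec.hrf_blobs):
        (cb, cz, cx), (rb, rz, rx) = blob.center, blob.radii
        inside = (
            ((zb - cb) / rb) ** 2 + ((zz - cz) / rz) ** 2 + ((zx - cx) / rx) ** 2
        ) <= 1.0
        if not np.all(label[inside] == LABELS["fluid"]):
            raise PhantomValidationError(
                f"hrf_blobs[{i}]: blob extends outside the PED fluid interior"
            )
        hrf_mask |= inside
    label[hrf_mask] = LABELS["hrf"]

    defect_fp = np.zeros((nb, nx), dtype=bool)
    for d in spec.defects:
        defect_fp[d.bscan_range[0] : d.bscan_range[1],
                  d.aline_range[0] : d.aline_range[1]] = True

    # per-voxel optical properties from labels
    back = np.empty(9)
    mu = np.empty(9)
    mel = np.zeros(9)
    flow = np.zeros(9)
    back[LABELS["vitreous"]], mu[LABELS["vitreous"]] = 0.0, 0.0
    for lay in (*spec.layers, spec.choroid):
        code = LABELS[lay.name]
        back[code], mu[code] = lay.backscatter, lay.mu
        mel[code], flow[code] = lay.melanin_fraction, lay.flow_fraction
    back[LABELS["fluid"]], mu[LABELS["fluid"]] = spec.fluid_backscatter, spec.fluid_mu
    back[LABELS["hrf"]], mu[LABELS["hrf"]] = 0.0, 0.0  # overridden per blob

    backscatter = back[label]
    mu_vol = mu[label].astype(np.float32)
    for blob in spec.hrf_blobs:
        (cb, cz, cx), (rb, rz, rx) = blob.center, blob.radii
        inside = (
            ((zb - cb) / rb) ** 2 + ((zz - cz) / rz) ** 2 + ((zx - cx) / rx) ** 2
        ) <= 1.0
        backscatter[inside] = blob.backscatter
        mu_vol[inside] = blob.mu

    # focal defect: remove melanin, leave a weak band remnant
    band = label == LABELS["rpe_bruchs"]
    in_defect = band & defect_fp[:, None, :]
    for d in spec.defects:
        dsel = np.zeros((nb, nx), dtype=bool)
        dsel[d.bscan_range[0] : d.bscan_range[1],
             d.aline_range[0] : d.aline_range[1]] = True
        sel = band & dsel[:, None, :]
        backscatter[sel] = d.residual_backscatter
        mu_vol[sel] = d.residual_mu

    melanin_p = mel[label]
    melanin_p[in_defect] = 0.0
    flow_p = flow[label]

    truth = GroundTruth(
        layer_label=label,
        melanin=melanin_p,  # probabilities for now; realized in build_phantom
        flow=flow_p,
        mu=mu_vol,
        band_center=band_center.astype(np.float32),
        band_half_thickness=spec.band_thickness // 2,
        ped_mask=(label == LABELS["fluid"]) | (label == LABELS["hrf"]),
        defect_footprint=defect_fp,
        hrf_mask=hrf_mask,
    )
    truth._backscatter = backscatter  # transient, consumed by build_phantom
    return truth


def _random_jones(rng: np.random.Generator, n: int) -> np.ndarray:
    """n unit Jones vectors Haar-uniform on CP^1 (uniform on the Poincaré sphere)."""
    g = rng.standard_normal((n, 4))
    j = g[:, 0] + 1j * g[:, 1], g[:, 2] + 1j * g[:, 3]
    norm = np.sqrt(np.abs(j[0]) ** 2 + np.abs(j[1]) ** 2)
    return np.stack([j[0] / norm, j[1] / norm], axis=0)


def build_phantom(spec: PhantomSpec) -> tuple[MCOCTVolume, GroundTruth]:
    """Simulate one MC-OCT acquisition. Same spec (incl. seed) → bit-identical output."""
    spec.validate()
    truth = _build_truth(spec)
    nb, nz, nx = spec.n_bscans, spec.n_depth, spec.n_alines
    nrep = spec.n_repeats
    rng = np.random.default_rng(spec.seed)

    backscatter = truth._backscatter
    del truth._backscatter
    mu_vol = truth.mu.astype(np.float64)

    # two-way Beer–Lambert transmission down to the *top* of each voxel
    od = np.cumsum(mu_vol, axis=1) - mu_vol  # exclusive cumulative sum along depth
    expected = backscatter * np.exp(-2.0 * spec.dz * od)

    # realize Bernoulli melanin / flow masks from the stored probabilities
    melanin = rng.random((nb, nz, nx)) < truth.melanin
    flow = rng.random((nb, nz, nx)) < truth.flow
    truth.melanin = melanin
    truth.flow = flow

    # polarization state per voxel
    jones_h = np.ones((nb, nz, nx), dtype=np.complex64)
    jones_v = np.zeros((nb, nz, nx), dtype=np.complex64)
    n_mel = int(melanin.sum())
    if n_mel:
        jh, jv = _random_jones(rng, n_mel)
        jones_h[melanin] = jh.astype(np.complex64)
        jones_v[melanin] = jv.astype(np.complex64)

    sigma_amp = np.sqrt(expected / 2.0).astype(np.float64)

    def _speckle(shape):
        re = rng.standard_normal(shape, dtype=np.float32)
        im = rng.standard_normal(shape, dtype=np.float32)
        return re + 1j * im

    amp_static = (_speckle((nb, nz, nx)) * sigma_amp).astype(np.complex64)
    phases = np.exp(1j * rng.uniform(0.0, 2 * np.pi, size=(nrep, nb))).astype(
        np.complex64
    )
    phases[0] = 1.0  # first repeat is the phase reference

    h = np.empty((nrep, nb, nz, nx), dtype=np.complex64)
    v = np.empty_like(h)
    n_flow = int(flow.sum())
    sig_flow = sigma_amp[flow]
    jh_f, jv_f = jones_h[flow], jones_v[flow]
    noise_sd = np.sqrt(spec.noise_variance / 2.0)
    for r in range(nrep):
        amp = amp_static.copy()
        if n_flow:
            amp[flow] = (_speckle(n_flow) * sig_flow).astype(np.complex64)
        ph = phases[r][:, None, None]
        h[r] = amp * jones_h * ph
        v[r] = amp * jones_v * ph
        if spec.noise_variance > 0:
            h[r] += (noise_sd * _speckle((nb, nz, nx))).astype(np.complex64)
            v[r] += (noise_sd * _speckle((nb, nz, nx))).astype(np.complex64)

    vol = MCOCTVolume(
        h=h,
        v=v,
        dx=spec.dx,
        dy=spec.dy,
        dz=spec.dz,
        noise_variance=spec.noise_variance,
        meta={"spec_hash": spec.spec_hash(), "seed": spec.seed},
    )
    return vol, truth
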