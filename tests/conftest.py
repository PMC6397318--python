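"""Shared fixtures: small phantoms and manually built volumes."""

import numpy as np
import pytest

from mcoct import LayerSpec, MCOCTVolume, PhantomSpec, build_phantom


def slab_spec(
    mu=0.0,
    backscatter=1.0,
    melanin=0.0,
    flow=0.0,
    noise=0.0,
    n_depth=64,
    n_bscans=4,
    n_alines=64,
    seed=0,
):
    """Homogeneous single-layer slab filling (almost) the whole depth range."""
    thickness = n_depth - 1
    lay = LayerSpec("rpe_bruchs", thickness, backscatter, mu, melanin, flow)
    return PhantomSpec(
        n_alines=n_alines,
        n_bscans=n_bscans,
        n_depth=n_depth,
        vitreous_px=0,
        layers=(lay,),
        choroid=LayerSpec("choroid", 0, backscatter, mu, melanin, flow),
        ped=None,
        defects=(),
        hrf_blobs=(),
        noise_variance=noise,
        seed=seed,
    )


def manual_volume(h, v, dx=0.01, dy=0.02, dz=0.006, noise_variance=0.0):
    """Wrap explicit per-repeat channel arrays into an MCOCTVolume."""
    h = np.asarray(h, dtype=np.complex128)
    v = np.asarray(v, dtype=np.complex128)
    return MCOCTVolume(h=h, v=v, dx=dx, dy=dy, dz=dz, noise_variance=noise_variance)


@pytest.fixture(scope="session")
def healthy_phantom():
    import mcoct

    spec = mcoct.default_spec("healthy", seed=0)
    return build_phantom(spec) + (spec,)


@pytest.fixture(scope="session")
def defect_phantom():
    import mcoct

    spec = mcoct.default_spec("ped_with_defect", seed=0)
    return build_phantom(spec) + (spec,)


@pytest.fixture(scope="session")
def defect_result():
    import mcoct

    return mcoct.run_pipeline(mcoct.RunConfig(preset="ped_with_defect", seed=0))
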