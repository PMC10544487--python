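"""Shared fixtures: desk-scale phantoms, protocols and reconstructed series.

Expensive simulation products are session-scoped so the suite simulates each
configuration once.
"""

import numpy as np
import pytest

from rttag.phantom import PhantomConfig, build_phantom
from rttag.recon import cs_recon, zero_filled_recon, zero_pad_enhance
from rttag.sampling import full_sampling_plan, make_sampling_plan
from rttag.sequence import SequenceProtocol, acquire_series, timing_summary


DESK_N = 96


@pytest.fixture(scope="session")
def desk_phantom():
    cfg = PhantomConfig(matrix=DESK_N, pixel_spacing=2.0)
    tissue, motion = build_phantom(cfg)
    return cfg, tissue, motion


@pytest.fixture(scope="session")
def desk_protocols():
    kw = dict(matrix=DESK_N, fov=DESK_N * 2.0, window_ms=700.0)
    return (SequenceProtocol(tag_axis="col", **kw),
            SequenceProtocol(tag_axis="row", **kw))


@pytest.fixture(scope="session")
def desk_snapshot_series(desk_phantom, desk_protocols):
    """Fully sampled snapshot reference series, both tag orientations."""
    _, tissue, motion = desk_phantom
    prot_x, prot_y = desk_protocols
    frames = timing_summary(prot_x).frames_per_window
    plan = full_sampling_plan(DESK_N, frames)
    ks_x = acquire_series(tissue, motion, prot_x, plan, snapshot=True)
    ks_y = acquire_series(tissue, motion, prot_y, plan, snapshot=True)
    return zero_filled_recon(ks_x, plan), zero_filled_recon(ks_y, plan)


@pytest.fixture(scope="session")
def static_tagged_kspace():
    """Static tagged phantom, 12-fold plan + fully sampled snapshot
    reference — the recon-quality fixture."""
    cfg = PhantomConfig(matrix=DESK_N, pixel_spacing=2.0, gcs_peak=0.0)
    tissue, motion = build_phantom(cfg)
    prot = SequenceProtocol(matrix=DESK_N, fov=DESK_N * 2.0, window_ms=500.0)
    frames = timing_summary(prot).frames_per_window
    plan = make_sampling_plan(DESK_N, 2, 6, frames, seed=5)
    ks = acquire_series(tissue, motion, prot, plan)
    plan_full = full_sampling_plan(DESK_N, frames)
    ks_ref = acquire_series(tissue, motion, prot, plan_full, snapshot=True)
    return ks, plan, ks_ref, plan_full


@pytest.fixture(scope="session")
def static_recons(static_tagged_kspace):
    ks, plan, ks_ref, plan_full = static_tagged_kspace
    ref = zero_filled_recon(ks_ref, plan_full)
    zf = zero_filled_recon(ks, plan)
    cs = cs_recon(ks, plan, iterations=40)
    cs_zp = zero_pad_enhance(cs, DESK_N)
    return {"ref": ref, "zf": zf, "cs": cs, "cs_zp": cs_zp}


def norm_mag(x):
    m = np.abs(x)
    return m / m.max()
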