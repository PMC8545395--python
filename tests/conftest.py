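"""Shared fixtures: scaled-down synthetic sessions (generated at test time).

Sessions use fewer trials/units and shorter ITIs than the full task
defaults so the suite stays fast; effect sizes are the generator
defaults.
"""

import numpy as np
import pytest

from condpipe.synthetic import (AssemblyDef, SessionSpec, default_assemblies,
                                generate_session, null_spec)


def small_spec(seed=1, **kw):
    kw.setdefault("stage", "post")
    kw.setdefault("n_units_ca1", 30)
    kw.setdefault("n_units_pfc", 40)
    kw.setdefault("n_trials_csplus", 20)
    kw.setdefault("n_trials_csminus", 20)
    kw.setdefault("iti_range_s", (8.0, 12.0))
    kw.setdefault("with_lfp", False)
    return SessionSpec(seed=seed, **kw)


@pytest.fixture(scope="session")
def post_session():
    """Post-learning session with planted response classes and assemblies."""
    spec = small_spec(seed=1, assembly_defs=default_assemblies(30, 40),
                      ripple_rate_hz=0.15)
    bundle, truth = generate_session(spec)
    return spec, bundle, truth


@pytest.fixture(scope="session")
def null_session():
    """Effect-free session for false-positive calibration."""
    spec = null_spec(seed=11, n_units_ca1=30, n_units_pfc=40,
                     n_trials_csplus=20, n_trials_csminus=20,
                     iti_range_s=(8.0, 12.0))
    bundle, truth = generate_session(spec)
    return spec, bundle, truth


@pytest.fixture(scope="session")
def lfp_session():
    """Small session with full LFP (ripples, artifacts, coherent PFC)."""
    spec = SessionSpec(seed=5, stage="post", n_units_ca1=8, n_units_pfc=8,
                       n_trials_csplus=10, n_trials_csminus=10,
                       iti_range_s=(8.0, 12.0), ripple_rate_hz=0.15,
                       n_artifacts=3, baseline_rate_hz=3.0)
    bundle, truth = generate_session(spec)
    return spec, bundle, truth


@pytest.fixture(scope="session")
def classified(post_session):
    from condpipe.single_cell import classify_cells
    _, bundle, _ = post_session
    return classify_cells(bundle)
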