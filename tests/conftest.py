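"""Shared fixtures: small synthetic scenes and the heavy standard-scene
pipeline (computed once per session and reused by the acceptance tests)."""

import warnings

import numpy as np
import pytest

import decimix as dx
from decimix import pearson


@pytest.fixture(scope="session")
def small_scene():
    """A quick 48x48 scene with 8 well-separated neurons and mild noise."""
    spec = dx.SceneSpec(H=48, W=48, N=8, T=400, rate=20.0, radius=2.5,
                        min_separation=12.0, spike_rate=0.02, noise_sigma=0.3,
                        min_spikes=3, seed=3)
    return dx.make_scene(spec)


@pytest.fixture(scope="session")
def noiseless_scene():
    """Exact low-rank scene (no noise) for identifiability checks."""
    spec = dx.SceneSpec(H=32, W=32, N=6, T=200, radius=2.5, min_separation=9.0,
                        noise="none", min_spikes=2, seed=5)
    return dx.make_scene(spec)


@pytest.fixture(scope="session")
def standard_bundle():
    return dx.standard_scene()


@pytest.fixture(scope="session")
def standard_fit(standard_bundle):
    """Phase-1 multi-scale fit of the standard scene plus AR estimates and
    the component-to-truth matching."""
    b = standard_bundle
    init = dx.InitConfig(n_components=40, expected_radius=3.0, patch_half_width=8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model, trace = dx.fit_multiscale(b.noisy, dx.FitSchedule(), init)
        model.normalize()
        gamma = np.vstack([dx.estimate_ar(model.C[n]) for n in range(model.N)])
    perm = [int(np.argmax([pearson(b.C_true[n], model.C[m])
                           for m in range(model.N)]))
            for n in range(b.spec.N)]
    assert len(set(perm)) == len(perm), "phase-1 fit failed to separate components"
    return {"model": model, "trace": trace, "ar": dx.ARModel(gamma), "perm": perm,
            "init": init}


@pytest.fixture(scope="session")
def standard_demix(standard_bundle, standard_fit):
    """Two-phase demixing of the standard scene at l = 1, 2, 4, 8."""
    b = standard_bundle
    Y = dx.flatten(b.noisy)
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for l in (1, 2, 4, 8):
            ml = dx.decimate_model(standard_fit["model"], l, l)
            Yl, _ = dx.decimate_spatial(Y, l, l, grid=(b.spec.H, b.spec.W))
            res = dx.demix_lowres(Yl, ml, standard_fit["ar"])
            out[l] = {"result": res, "model_l": ml}
    return out


def corr_to_truth(bundle, C, perm):
    return np.array([pearson(bundle.C_true[n], C[perm[n]])
                     for n in range(bundle.spec.N)])
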