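import numpy as np
import pytest

from nirhsi.hypercube import WavelengthGrid
from nirhsi.synth import (
    BarSpec,
    ParticleSpec,
    SceneSpec,
    make_reference_library,
    synth_cube,
)


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid.default()


@pytest.fixture(scope="session")
def library():
    """Synthetic reference library at the default sensor-noise level."""
    return make_reference_library(seed=1)


@pytest.fixture(scope="session")
def noiseless_library():
    return make_reference_library(noise_sd=0.0, seed=1)


FIVE_DISK_MATERIALS = ("HDPE", "PP", "PS", "pumice", "LDPE")


@pytest.fixture(scope="session")
def five_disk_scene():
    """Five well-separated disks of known material plus a 500-px scale bar."""
    particles = tuple(
        ParticleSpec(
            shape="disk",
            size=(12,),
            center=(60 + 20 * (i % 2), 80 + 110 * i),
            material=FIVE_DISK_MATERIALS[i],
        )
        for i in range(5)
    )
    scene = SceneSpec(
        shape=(200, 640),
        particles=particles,
        bar=BarSpec(length_px=500),
        noise_sd=0.005,
        seed=3,
    )
    cube, truth_labels, truth = synth_cube(scene)
    return scene, cube, truth_labels, truth


def match_regions(truth_labels, seg_labels):
    """Map planted particle id -> (best seg label, Jaccard overlap)."""
    out = {}
    for pid in np.unique(truth_labels):
        if pid == 0:
            continue
        tm = truth_labels == pid
        ids, counts = np.unique(seg_labels[tm], return_counts=True)
        ids, counts = ids[ids != 0], counts[ids != 0]
        if ids.size == 0:
            out[int(pid)] = (0, 0.0)
            continue
        best = ids[np.argmax(counts)]
        sm = seg_labels == best
        out[int(pid)] = (int(best), float((tm & sm).sum() / (tm | sm).sum()))
    return out
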