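import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_hist(spec, barcode="BC", l_max=1000):
    """Histogram from {length: count} or an iterable of lengths."""
    from fldqc.fragments import FLDHistogram

    counts = np.zeros(l_max + 1, dtype=np.int64)
    if isinstance(spec, dict):
        for length, c in spec.items():
            counts[length] = c
    else:
        counts = np.bincount(np.asarray(spec), minlength=l_max + 1)[: l_max + 1].astype(
            np.int64
        )
    return FLDHistogram(barcode, counts)


@pytest.fixture
def hist_factory():
    return make_hist


@pytest.fixture(scope="session")
def small_library(tmp_path_factory):
    """Small mixed-theta synthetic library emitted as BED, shared across tests."""
    from fldqc import simulate as sim
    from fldqc.fragments import BarcodeUniverse

    outdir = tmp_path_factory.mktemp("lib")
    lib = sim.make_library(
        6, theta=[0.0, 0.2, 0.4, 0.6, 0.8, 1.0], depth=400, seed=11,
        fraction_in_peaks=0.5,
    )
    bed = sim.emit_fragments(lib, "bed", outdir / "fragments.bed")
    universe = BarcodeUniverse(bc for bc, _ in lib.cells)
    return {"lib": lib, "bed": bed, "universe": universe, "outdir": outdir}
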