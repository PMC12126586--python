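import numpy as np
import pytest

from wetlandscape.grids_io import RasterLayer, SYNTHETIC_CRS, Transform
from wetlandscape.pipeline import PipelineConfig, run_pipeline


def make_layer(values, cell_size=50.0, nodata=None, crs=SYNTHETIC_CRS):
    values = np.asarray(values)
    transform = Transform(0.0, values.shape[0] * cell_size, cell_size, cell_size)
    return RasterLayer(values, transform, crs, nodata)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run under the default synthetic study conditions.

    Session-scoped: the accuracy, fragmentation and WFPI checks all read
    from this single run.
    """
    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = PipelineConfig(outdir=str(outdir), seed=11)
    manifest = run_pipeline(cfg)
    return cfg, manifest
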