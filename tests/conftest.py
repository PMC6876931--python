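import numpy as np
import pytest

from ecgdigitize import cli, synthetic
from ecgdigitize.types import RasterImage
from ecgdigitize.validation import overlap_pair, pearson, resample


@pytest.fixture(scope="session")
def default_spec():
    return synthetic.SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def rendered_page(default_spec):
    """One default 13-lead page plus its ground truth (rendered once)."""
    img, truth = synthetic.render(default_spec)
    return img, truth


@pytest.fixture(scope="session")
def digitized_page(rendered_page):
    img, truth = rendered_page
    result = cli.digitize_page(img)
    return img, truth, result


@pytest.fixture(scope="session")
def noiseless_page():
    spec = synthetic.SyntheticSpec(seed=7, noise_sd=0.0, n_glyphs=0)
    img, truth = synthetic.render(spec)
    return img, truth


def roundtrip_rhos(truth, result, n_resample: int = 1000) -> dict[str, float]:
    """Per-lead Pearson correlation between truth and recovered signals,
    both resampled to ``n_resample`` points over their column overlap."""
    rhos = {}
    for label, lr in result.leads.items():
        ref = truth.signals[label]
        ref_start = truth.trace_cols[label][0]
        a, b = overlap_pair(ref, lr.signal, ref_start, lr.start_col)
        rhos[label] = pearson(resample(a, n_resample).v, resample(b, n_resample).v)
    return rhos


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_image(rng, n_rows: int, n_cols: int) -> RasterImage:
    return RasterImage(rng.uniform(0.0, 1.0, size=(n_rows, n_cols)))
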