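import numpy as np
import pytest
from hypothesis import settings

from ftirlcm import classify as clf
from ftirlcm import preprocess as pp
from ftirlcm import synthetic as syn
from ftirlcm.hyperspec_io import WavenumberAxis

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def axis() -> WavenumberAxis:
    return WavenumberAxis.acquisition_default()


@pytest.fixture(scope="session")
def signatures():
    return syn.default_signatures()


def preprocess_phantom(seed: int, size: int = 48, **spec_kwargs):
    """Phantom -> QC -> EMSC; returns (corrected image, truth map, report)."""
    spec = syn.PhantomSpec(shape=(size, size), seed=seed, **spec_kwargs)
    image, truth, conc, meta = syn.generate_phantom(spec)
    _, report = pp.quality_control(image)
    flat = image.cube.reshape(-1, image.cube.shape[2])
    reference = flat[image.qc_mask.reshape(-1)].mean(axis=0)
    model = pp.EMSCModel(
        reference=reference, axis=image.axis, mie_basis=pp.build_mie_basis(image.axis)
    )
    corrected, _ = pp.emsc_correct_image(image, model)
    return corrected, truth, report


def train_on_phantom(corrected, truth, seed: int, n_trees: int = 200):
    """Single-level three-class cascade fitted on one corrected phantom."""
    features, back_map = clf.extract_features(corrected)
    names = np.array(
        [truth.legend[l][0] if l > 0 else "" for l in truth.labels.reshape(-1)[back_map]],
        dtype=object,
    )
    keep = names != ""
    spec = clf.CascadeSpec(
        levels=(
            clf.CascadeLevel("tissue", ("epithelioid", "sarcomatoid", "stroma"), n_trees=n_trees),
        )
    )
    grid = corrected.axis.values[corrected.axis.window_indices(*spec.feature_range)]
    return clf.train_cascade([(features[keep], names[keep])], spec, grid, seed=seed)


def leaf_accuracy(pred_map, truth_map) -> float:
    """Per-pixel accuracy over pixels labelled in both maps."""
    mask = (truth_map.labels > 0) & (pred_map.labels > 0)
    pred = np.array([pred_map.legend[l][0] for l in pred_map.labels[mask]])
    true = np.array([truth_map.legend[l][0] for l in truth_map.labels[mask]])
    return float((pred == true).mean())


@pytest.fixture(scope="session")
def trained_phantom_cascade():
    """One corrected training phantom, its cascade, and a held-out phantom."""
    corrected, truth, _ = preprocess_phantom(seed=1)
    cascade = train_on_phantom(corrected, truth, seed=7)
    held_out, held_truth, _ = preprocess_phantom(seed=2)
    return cascade, held_out, held_truth
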