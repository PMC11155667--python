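import json

import numpy as np
import pytest

from peakfit.config import (ComponentSpec, FitProject, ParameterSpec,
                            Settings, Spectrum, parse_input)


@pytest.fixture
def single_gaussian_doc() -> str:
    """Declarative input in the canonical JSON layout: one Gaussian with
    amplitude/center/fwhmg parameter specs under fitting.peaks."1"."""
    return json.dumps({
        "settings": {"x_column": "Energy", "y_column": "Norm"},
        "fitting": {
            "description": {"project_name": "unit test"},
            "peaks": {
                "1": {"gaussian": {
                    "amplitude": {"min": 0, "max": 10, "vary": True, "value": 2},
                    "center": {"min": 0, "max": 10, "vary": True, "value": 5},
                    "fwhmg": {"min": 0.1, "max": 5, "vary": True, "value": 1.5},
                }}
            },
        },
    })


@pytest.fixture
def single_gaussian_project(single_gaussian_doc) -> FitProject:
    return parse_input(single_gaussian_doc, format="json")


def gaussian_project(truth: list[dict], lo=0.0, hi=10.0) -> FitProject:
    """Project of free Gaussians initialized at the given attribute values."""
    comps = []
    for i, attrs in enumerate(truth, start=1):
        comps.append(ComponentSpec(index=str(i), kind="gaussian", attributes={
            "amplitude": ParameterSpec(value=attrs["amplitude"], min=0, max=100),
            "center": ParameterSpec(value=attrs["center"], min=lo, max=hi),
            "fwhmg": ParameterSpec(value=attrs["fwhmg"], min=0.05, max=20),
        }))
    return FitProject(settings=Settings(), components=comps)


@pytest.fixture
def noisy_gaussian_spectrum() -> tuple[Spectrum, dict]:
    """One noisy Gaussian with known truth on a fixed grid."""
    truth = {"amplitude": 2.0, "center": 5.0, "fwhmg": 1.5}
    rng = np.random.default_rng(11)
    x = np.linspace(0, 10, 201)
    sigma = truth["fwhmg"] / (2 * np.sqrt(2 * np.log(2)))
    clean = truth["amplitude"] / (sigma * np.sqrt(2 * np.pi)) * np.exp(
        -((x - truth["center"]) ** 2) / (2 * sigma**2))
    y = clean + rng.normal(0, 0.005, x.size)
    return Spectrum(x=x, y=y), truth
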