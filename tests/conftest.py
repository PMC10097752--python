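import numpy as np
import pytest

from carfundus import DiseaseHead, FindingHead, ModelBundle


def random_bundle(rng: np.random.Generator, n_findings: int = 4,
                  n_diseases: int = 2, channels: int = 8,
                  coupling_scale: float = 0.3) -> ModelBundle:
    """A random two-stage model with well-conditioned heads."""
    findings = [
        FindingHead(f"f{i}", rng.normal(size=channels), float(rng.normal()))
        for i in range(n_findings)
    ]
    diseases = [
        DiseaseHead(
            f"d{j}",
            [coupling_scale * rng.normal(size=channels) for _ in range(n_findings)],
            float(rng.normal()),
        )
        for j in range(n_diseases)
    ]
    return ModelBundle(findings, diseases)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def bundle(rng) -> ModelBundle:
    return random_bundle(rng)


@pytest.fixture
def latents(rng, bundle):
    return [rng.normal(size=bundle.channels) for _ in bundle.findings]
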