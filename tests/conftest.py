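import numpy as np
import pytest

from otomorph.efd import Contour
from otomorph.synthdata import ContourParams, generate_contour


@pytest.fixture(scope="session")
def notched_contour() -> Contour:
    """A representative asymmetric otolith-like outline."""
    return generate_contour(
        ContourParams(s=1.0, h=0.8, d=0.2, t0=2.2, w=0.3, K=512), specimen_id="notched"
    )


@pytest.fixture(scope="session")
def circle_contour() -> Contour:
    t = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
    return Contour(points=np.column_stack([np.cos(t), np.sin(t)]), specimen_id="circle")


@pytest.fixture(scope="session")
def ellipse_contour() -> Contour:
    """Axis-aligned 2:1 ellipse sampled at equal parameter angles."""
    t = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
    return Contour(
        points=np.column_stack([2.0 * np.cos(t), np.sin(t)]), specimen_id="ellipse"
    )
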