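import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lungrpn import synthdata

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.RandomState(1234)


@pytest.fixture
def phantom_spec():
    """A small thorax phantom: 160 px at 0.7 mm/px, one rib-like bone arc."""
    return synthdata.PhantomSpec(
        image_size=160,
        spacing=0.7,
        bone_arcs=(synthdata.BoneArc(cx=80, cy=80, r0=66, r1=70, theta0=-0.6, theta1=0.6),),
    )


@pytest.fixture
def phantom_nodules(phantom_spec):
    """Two nodules, one per lung, comfortably inside the lung ellipses."""
    sp = phantom_spec.spacing
    left = phantom_spec.left_lung_ellipse
    right = phantom_spec.right_lung_ellipse
    return [
        synthdata.NoduleSpec(center=(left.cx * sp, left.cy * sp), diameter=8.0),
        synthdata.NoduleSpec(
            center=((right.cx + 5) * sp, (right.cy - 8) * sp), diameter=6.0
        ),
    ]


@pytest.fixture
def phantom_slice(phantom_spec, phantom_nodules):
    return synthdata.make_phantom_slice(phantom_spec, phantom_nodules)
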