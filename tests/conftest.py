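import numpy as np
import pytest

import meshstrain as ms

PIX = 1.0
MARGIN = 10.0   # explicit render margin so ground-truth node positions are known


@pytest.fixture(scope="session")
def mesh5():
    """5x5-line lattice, 40 um pitch, 4 um lines (fast to render at 1 um/px)."""
    return ms.MeshSpec(pitch=40, line_width=4, rows=5, cols=5)


@pytest.fixture(scope="session")
def identity_render(mesh5):
    """Noiseless render of the undeformed lattice on a pinned pixel grid."""
    img = ms.render_frame(mesh5, ms.IdentityField(), 0, pixel_size=PIX,
                          origin_um=(-MARGIN, -MARGIN), shape=(181, 181))
    return img


@pytest.fixture(scope="session")
def segmented(mesh5, identity_render):
    mm = ms.skeletonize(ms.binarize(identity_render))
    ns = ms.detect_nodes(mm, identity_render, pixel_size=PIX,
                         pitch_hint=mesh5.pitch, line_width=mesh5.line_width)
    return mm, ns


@pytest.fixture(scope="session")
def true_nodes(mesh5):
    """Ground-truth node positions matching identity_render's pixel grid."""
    return mesh5.node_grid() + MARGIN


@pytest.fixture(scope="session")
def small_series(mesh5):
    """Noiseless incompressible uniaxial series, 6 frames to 45 % strain."""
    return ms.make_uniaxial_series(mesh5, 0.45, 0.09, mode="incompressible",
                                   pixel_size=PIX)


@pytest.fixture(scope="session")
def small_result(small_series, mesh5):
    series, _ = small_series
    return ms.analyze_series(series, pitch=mesh5.pitch,
                             line_width=mesh5.line_width)


def tracks_from_positions(positions, reference=0):
    """NodeTracks with every node tracked, from a (T, N, dim) array."""
    positions = np.asarray(positions, float)
    status = np.full(positions.shape[:2], ms.TRACKED, np.int8)
    return ms.NodeTracks(positions, status, reference=reference)
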