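import numpy as np
import pytest

import woolscale as ws


@pytest.fixture(scope="session")
def coronal_image():
    """Fine fibre (22 µm, 6 scales/100 µm) with its ground truth."""
    spec = ws.ImageSpec(
        diameter_um=22.0,
        length_um=520.0,
        pattern=ws.ScalePattern.CORONAL,
        scales_per_100um=6.0,
        seed=11,
    )
    return ws.generate_fibre_image(spec)


@pytest.fixture(scope="session")
def reticulate_image():
    """Coarse fibre (72 µm, 16 scales/100 µm) with its ground truth."""
    spec = ws.ImageSpec(
        diameter_um=72.0,
        length_um=1020.0,
        pattern=ws.ScalePattern.RETICULATE,
        scales_per_100um=16.0,
        seed=5,
    )
    return ws.generate_fibre_image(spec)


def chain_code_oracle(skel: np.ndarray) -> float:
    """Brute-force O(n^2) pixel-walk length: 1 per 4-connected step, sqrt(2)
    per diagonal step, skipping diagonals that shortcut a 4-connected corner.
    Deliberately naive — an independent check of the vectorized estimator."""
    pts = list(zip(*np.nonzero(skel)))
    on = set(pts)
    total = 0.0
    for i, (r1, c1) in enumerate(pts):
        for r2, c2 in pts[i + 1 :]:
            dr, dc = abs(r1 - r2), abs(c1 - c2)
            if dr + dc == 1:
                total += 1.0
            elif dr == 1 and dc == 1:
                if (r1, c2) not in on and (r2, c1) not in on:
                    total += np.sqrt(2.0)
    return total
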