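import numpy as np
import pytest

import heterodont as hd


@pytest.fixture(scope="session")
def small_assemblage():
    """12 specimens, half caniniform, half homodont; noisy outlines."""
    return hd.simulate_assemblage(12, mix=0.5, seed=7)


@pytest.fixture(scope="session")
def small_aligned(small_assemblage):
    configs = [hd.resample_to_configuration(o) for o in small_assemblage.all_outlines()]
    return hd.gpa(configs)


@pytest.fixture(scope="session")
def small_space(small_aligned):
    return hd.fit_pca(small_aligned)


@pytest.fixture(scope="session")
def aspect_contrast_space():
    """Joint shape space over tall (aspect 3) and stout (aspect 0.8) teeth."""
    tall = hd.ToothParams(height=3.0, base_width=1.0)
    stout = hd.ToothParams(height=0.8, base_width=1.0)
    configs = []
    for i in range(12):
        for j, params in enumerate((tall, stout)):
            o = hd.make_tooth_outline(
                params, 61, seed=100 * i + j, specimen_id=f"S{i}", tooth_position=j + 1
            )
            configs.append(hd.resample_to_configuration(o))
    aligned = hd.gpa(configs)
    aspects = []
    for c in configs:
        w = np.ptp(c.points[:, 0])
        h = np.ptp(c.points[:, 1])
        aspects.append(h / w)
    return hd.fit_pca(aligned), np.array(aspects)
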