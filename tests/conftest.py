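import numpy as np
import pytest

from seedmorph.synthetic_seeds import SpeciesTemplate, generate_population, paper_like_panel

#: canonical seed for the reference panel used throughout the suite
PANEL_SEED = 1


@pytest.fixture(scope="session")
def panel():
    """The full calibrated 1625-seed reference panel (shared, read-only)."""
    return paper_like_panel(seed=PANEL_SEED)


def small_templates():
    return [
        SpeciesTemplate(
            name="rounded",
            status="wild_reference",
            n_accessions=3,
            seeds_per_accession=15,
            size_means=(1.0, 0.7, 0.6),
            size_cv=(0.10, 0.09, 0.09),
            mode_scores=np.array([-1.5, 0.5, 0.0, 0.0, 0.0, 0.0]),
        ),
        SpeciesTemplate(
            name="elongated",
            status="cultivated",
            role="cultivar",
            n_accessions=3,
            seeds_per_accession=15,
            size_means=(2.0, 0.85, 0.75),
            size_cv=(0.18, 0.10, 0.10),
            mode_scores=np.array([2.5, 1.2, -0.5, 0.5, 0.0, 0.0]),
        ),
        SpeciesTemplate(
            name="middling",
            status="wild_reference",
            n_accessions=2,
            seeds_per_accession=15,
            size_means=(1.4, 0.8, 0.7),
            size_cv=(0.12, 0.09, 0.09),
            mode_scores=np.array([0.5, -0.8, 0.8, 0.0, 0.3, 0.0]),
        ),
    ]


@pytest.fixture(scope="module")
def small_panel():
    """A 120-seed three-species population for fast unit tests."""
    return generate_population(small_templates(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def smooth_outline(rng, n_points=96, n_extra=4, amp=0.15, aspect=1.6):
    """A random smooth closed outline: ellipse plus a few low harmonics."""
    t = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    x = aspect * np.cos(t)
    y = np.sin(t)
    for n in range(2, 2 + n_extra):
        ax, bx, cy, dy = rng.normal(0, amp / n**2, 4)
        x += ax * np.cos(n * t) + bx * np.sin(n * t)
        y += cy * np.cos(n * t) + dy * np.sin(n * t)
    return np.column_stack([x, y])
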