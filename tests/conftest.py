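import numpy as np
import pytest

from alphaqar.coreg import Section
from alphaqar.listmode import AcquisitionSchedule
from alphaqar.quantify import AC225, ActivityImage
from alphaqar.synthetic import (
    KidneyPhantomSpec,
    TumorStackSpec,
    generate_kidney_phantom,
    generate_tumor_stack,
)
from alphaqar.warp import PhantomSpec

HOUR = 3600.0
DAY = 86400.0


@pytest.fixture(scope="session")
def dots_spec() -> PhantomSpec:
    return PhantomSpec(
        kind="dots",
        element_size=80.0,
        spacing=300.0,
        grid_rows=7,
        grid_cols=7,
        image_shape=(256, 256),
        pixel_spacing=13.25,
    )


@pytest.fixture(scope="session")
def small_activity() -> ActivityImage:
    rng = np.random.default_rng(0)
    return ActivityImage(rng.uniform(0.02, 0.08, (16, 16)), pixel_spacing=26.5, isotope=AC225)


@pytest.fixture(scope="session")
def schedule_60h() -> AcquisitionSchedule:
    return AcquisitionSchedule.from_pairs([(0.0, 60 * HOUR)])


@pytest.fixture(scope="session")
def kidney_enriched():
    """Kidney phantom with a 2x annular enrichment 50-100 um around glomeruli."""
    spec = KidneyPhantomSpec(seed=5, enrichment_amplitude=2.0, noise_level=0.05)
    anatomy, activity, truth = generate_kidney_phantom(spec)
    return spec, anatomy, activity, truth


@pytest.fixture(scope="session")
def kidney_flat():
    spec = KidneyPhantomSpec(seed=6, enrichment_amplitude=1.0, noise_level=0.0)
    anatomy, activity, truth = generate_kidney_phantom(spec)
    return spec, anatomy, activity, truth


def sections_from_stack(raw_sections) -> list[Section]:
    return [
        Section(
            activity=s["activity"],
            anatomy=s["anatomy"],
            activity_spacing=s["pixel_spacing_um"],
            anatomy_spacing=s["pixel_spacing_um"],
            landmarks_activity=s["landmarks"],
            landmarks_anatomy=s["landmarks"],
        )
        for s in raw_sections
    ]


@pytest.fixture(scope="session")
def tumor_stack_warped():
    spec = TumorStackSpec(seed=3, warp_amplitude_um=40.0, image_shape=(128, 128))
    raw, truth = generate_tumor_stack(spec)
    return spec, sections_from_stack(raw), truth
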