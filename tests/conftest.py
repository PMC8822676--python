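import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from autocontour.dicom_io import CTVolume, StructureSet


def make_volume(shape=(6, 64, 64), spacing=(1.0, 1.0), thickness=2.5,
                fill=0.0, patient_id="test") -> CTVolume:
    """In-memory axial CT grid for geometry tests (no files involved)."""
    nz, ny, nx = shape
    return CTVolume(
        voxels=np.full(shape, fill, dtype=np.float32),
        pixel_spacing=spacing,
        slice_thickness=thickness,
        slice_positions=np.arange(nz) * thickness,
        origin=(0.0, 0.0, 0.0),
        orientation=(1, 0, 0, 0, 1, 0),
        sop_instance_uids=[f"1.2.3.{k}" for k in range(nz)],
        series_uid="1.2.3",
        frame_of_reference_uid="1.2.4",
        patient_id=patient_id,
    )


@pytest.fixture
def volume_64():
    return make_volume()


@pytest.fixture(scope="session")
def small_phantom():
    """One small phantom (128x128, 8 slices) shared across DICOM tests."""
    from autocontour.synthetic_data import OrganShape, PhantomSpec, generate_phantom

    spec = PhantomSpec(
        matrix=(128, 128), n_slices=8, body_semi_axes=(50.0, 58.0),
        organs=[
            OrganShape("brainstem", "cylinder", (0.0, 10.0, 10.0), (8.0, 8.0, 6.0), 160.0),
            OrganShape("parotid_l", "ellipsoid", (-28.0, 0.0, 10.0), (10.0, 8.0, 6.0), 320.0),
        ],
        seed=7,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_phantom_dir(small_phantom, tmp_path_factory):
    from autocontour.synthetic_data import write_phantom_dicom

    volume, structs = small_phantom
    out = tmp_path_factory.mktemp("phantom_dicom")
    write_phantom_dicom(volume, structs, out)
    return out
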