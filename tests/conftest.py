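import numpy as np
import pytest
import trimesh

from pahemo.mesh import Region, SurfaceMesh


def make_labelled_cylinder(radius: float, length: float, sections: int = 96,
                           label: Region = Region.MPA) -> SurfaceMesh:
    """Capped cylinder along z, centred at the origin, caps labelled."""
    m = trimesh.creation.cylinder(radius=radius, height=length, sections=sections)
    sm = SurfaceMesh.from_trimesh(m)
    nrm = sm.face_normals
    labels = np.full(len(sm.faces), label, dtype=object)
    labels[nrm[:, 2] > 0.99] = Region.CAP_OUTLET
    labels[nrm[:, 2] < -0.99] = Region.CAP_INLET
    sm.labels = labels
    return sm


@pytest.fixture(scope="session")
def cylinder_r5_l80() -> SurfaceMesh:
    return make_labelled_cylinder(5.0, 80.0)


@pytest.fixture(scope="session")
def cylinder_r12_l60() -> SurfaceMesh:
    return make_labelled_cylinder(12.0, 60.0)


@pytest.fixture(scope="session")
def sensor_body():
    from pahemo.implantation import make_sensor_body

    return make_sensor_body()


@pytest.fixture(scope="session")
def synthetic_pa():
    from pahemo.synthetic import generate_synthetic_pa

    return generate_synthetic_pa(seed=7)


@pytest.fixture(scope="session")
def case01_waveform():
    from pahemo.boundary import synthesize_waveform

    return synthesize_waveform(99.0, 4.7, 245.0)


@pytest.fixture(scope="session")
def viscosity():
    from pahemo.boundary import ViscosityModel

    return ViscosityModel()
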