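import numpy as np
import pytest

from capkin.structure import AtomFrame
from capkin.synthetic import ImagingParams, KineticParams


@pytest.fixture
def params() -> KineticParams:
    return KineticParams()


@pytest.fixture
def imaging() -> ImagingParams:
    return ImagingParams()


@pytest.fixture
def stream_imaging() -> ImagingParams:
    return ImagingParams(frame_interval=0.2, n_frames=60)


def make_frame(
    xyz: np.ndarray,
    chain: str | list = "A",
    resnum: np.ndarray | None = None,
    element: str | list = "C",
    atom: str | list = "CA",
    resname: str | list = "ALA",
) -> AtomFrame:
    """Construct an AtomFrame from coordinates and (broadcastable) labels."""
    xyz = np.asarray(xyz, dtype=float)
    n = len(xyz)

    def arr(v, dtype=None):
        if isinstance(v, (list, np.ndarray)):
            return np.asarray(v)
        return np.full(n, v)

    return AtomFrame(
        chain=arr(chain),
        resnum=np.arange(1, n + 1) if resnum is None else np.asarray(resnum, dtype=int),
        resname=arr(resname),
        atom=arr(atom),
        element=arr(element),
        xyz=xyz,
        altloc=np.full(n, ""),
        occupancy=np.ones(n),
    )
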