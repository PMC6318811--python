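"""Shared fixtures and helpers for the pwstherm test suite."""

from __future__ import annotations

import numpy as np
import pytest

from pwstherm.geometry import TissueModel
from pwstherm.optics import OpticalProperties

LABEL_EPIDERMIS = 1
LABEL_BASAL = 2
LABEL_DERMIS = 3
LABEL_VESSEL = 4


def uniform_model(
    mu_a: float,
    mu_s: float,
    g: float,
    nz: int = 50,
    nx: int = 40,
    dx: float = 50.0,
    dz: float = 20.0,
    label: int = LABEL_DERMIS,
    ny: int | None = None,
    dy: float | None = None,
) -> TissueModel:
    """Homogeneous medium with a single label and prescribed optical properties."""
    shape = (nz, nx) if ny is None else (nz, ny, nx)
    labels = np.full(shape, label, dtype=np.int8)
    props = {label: OpticalProperties(mu_a, mu_s, g)}
    return TissueModel(labels=labels, dx=dx, dz=dz, dy=dy, optical_by_label=props)


@pytest.fixture(scope="session")
def default_plexus():
    """One default-parameter synthetic plexus volume, shared across tests."""
    from pwstherm.synthetic import make_plexus_volume

    return make_plexus_volume(seed=0)
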