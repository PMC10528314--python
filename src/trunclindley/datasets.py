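"""Packaged example datasets.

Two classical positive-valued samples ship as plain-text fixtures, one value
per line:

* ``temperatures`` - 130 average July temperatures (degrees C) recorded at
  Neuenburg, Switzerland, 1864-1993 (Barakat et al., 2014).
* ``carbon_fibers`` - breaking stress (GPa) of 64 single carbon fibers of
  gauge length 10 mm (Cheng & Traylor, 1970).

Each load re-validates the value count, range and a SHA-256 checksum of the
canonical 4-decimal rendering, so silent fixture corruption cannot pass.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Dict

import numpy as np

__all__ = ["FixtureManifest", "MANIFEST", "load_dataset"]


@dataclass(frozen=True)
class FixtureManifest:
    name: str
    filename: str
    n: int
    vmin: float
    vmax: float
    sha256: str
    source: str


MANIFEST: Dict[str, FixtureManifest] = {
    "temperatures": FixtureManifest(
        name="temperatures",
        filename="neuenburg_july_temperatures.txt",
        n=130,
        vmin=15.3,
        vmax=23.4,
        sha256="84b253595831f8843b86d88d00df18defdfe86ab5aafe2f0dec81b498685ba44",
        source="Barakat, Nigm, El-Adll & Yusuf (2014): average July "
               "temperatures, Neuenburg, Switzerland, 1864-1993",
    ),
    "carbon_fibers": FixtureManifest(
        name="carbon_fibers",
        filename="carbon_fiber_breaking_stress.txt",
        n=64,
        vmin=1.901,
        vmax=5.02,
        sha256="0dd114eed474262f682ce6cddf2463f1abe4f6dcf029dacbb7c0e3a5a1dd302d",
        source="Cheng & Traylor (1970): breaking stress of 64 single carbon "
               "fibers, gauge length 10 mm",
    ),
}


def load_dataset(name: str) -> np.ndarray:
    """Load a packaged dataset by name, validating its manifest."""
    if name not in MANIFEST:
        raise KeyError(
            f"unknown dataset {name!r}; available: {sorted(MANIFEST)}"
        )
    m = MANIFEST[name]
    text = resources.files("trunclindley.data").joinpath(m.filename).read_text()
    vals = np.array([float(line) for line in text.splitlines()
                     if line.strip() and not line.startswith("#")])
    canon = "\n".join(f"{v:.4f}" for v in vals)
    digest = hashlib.sha256(canon.encode()).hexdigest()
    if (vals.size != m.n or not np.isclose(vals.min(), m.vmin)
            or not np.isclose(vals.max(), m.vmax) or digest != m.sha256):
        raise RuntimeError(f"fixture {name!r} failed manifest validation")
    return vals
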