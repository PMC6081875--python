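"""Phantom configuration loading.

Phantom masses and S values are inputs, not constants of the method: public
tabulations differ by phantom family and are licensed per source, so the
package reads them from a YAML/JSON file keyed by sex.  A clearly-labelled
illustrative synthetic set ships with the package for tests and examples.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import yaml

from .dosimetry import PhantomReference
from .errors import ConfigurationError

__all__ = ["load_phantom", "load_illustrative_phantom"]

#: Organ models per therapy: kidneys are main accumulating organs for both;
#: liver and spleen are additionally modelled for octreotate.
DEFAULT_ORGAN_MODEL = {
    "octreotate": ["kidneys", "liver", "spleen"],
    "psma617": ["kidneys"],
}


def load_phantom(path: str | Path, sex: str = "male") -> PhantomReference:
    """Load one sex's phantom reference from a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if sex not in data:
        raise ConfigurationError(f"phantom config {path} has no entry for sex '{sex}'")
    return PhantomReference.from_dict(data[sex])


def load_illustrative_phantom(sex: str = "male") -> PhantomReference:
    """The packaged illustrative (synthetic) phantom — for tests and examples."""
    ref = resources.files("marrowdose.data").joinpath("phantom_illustrative.yaml")
    data = yaml.safe_load(ref.read_text())
    if sex not in data:
        raise ConfigurationError(f"no illustrative phantom for sex '{sex}'")
    return PhantomReference.from_dict(data[sex])
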