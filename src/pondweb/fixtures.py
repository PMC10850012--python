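"""The two canonical grass-carp pond models, packaged as CSV model
directories.

``monoculture_fixture`` is the 16-group single-species pond (grass carp
plus silver carp as a service species); ``polyculture_fixture`` is the
18-group 80:20 pond that adds bighead carp and crucian carp.  Both webs
run on a 300-day culture season and are import-fed through formulated
feed and precipitation pools.  Parameter provenance (including the
resolved bacteria production rate and the fitted detritus routing) is
annotated inline in the CSV files.
"""

from __future__ import annotations

from importlib import resources

from .model import EcopathModel, load_model


def _load(name: str) -> EcopathModel:
    root = resources.files("pondweb").joinpath("data", name)
    with resources.as_file(root) as path:
        return load_model(str(path), format="csv")


def monoculture_fixture() -> EcopathModel:
    """16-group monoculture grass-carp pond model."""
    return _load("monoculture")


def polyculture_fixture() -> EcopathModel:
    """18-group 80:20 polyculture grass-carp pond model."""
    return _load("polyculture")
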