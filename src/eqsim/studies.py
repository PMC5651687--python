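"""Canonical protocol fixtures for the four replicated simulations.

Fixtures ship as YAML files under ``eqsim/protocols/`` and are loaded
through :func:`make_protocol`.  Supported (study, variant) combinations:

======================  ==========================  =====================================
study                   variant                     protocol
======================  ==========================  =====================================
``sim1``                --                          3-member class, 30 AB/BC epochs
``sidman1982``          --                          3 classes x 4 members, staged AB/AC/DC
``devany1986``          ``typical`` (default)       2 classes x 3 members, beta=0.2, theta=0.7
``devany1986``          ``learning_disability``     same stages, beta=0.1, theta=0.72
``devany1986``          ``interference_avoidance``  AB solo (45 trials) then 30 mixed AB/AC
``spencer1996``         ``staged`` (default)        linear series, Table-of-stages counts
``spencer1996``         ``equal_trials``            65 trials per relation set, interleaved
======================  ==========================  =====================================
"""

from __future__ import annotations

from importlib import resources

from .errors import ConfigurationError
from .protocol import ProtocolSpec, protocol_from_yaml

_REGISTRY: dict[tuple[str, str], str] = {
    ("sim1", ""): "sim1.yaml",
    ("sidman1982", ""): "sidman1982.yaml",
    ("devany1986", ""): "devany1986.yaml",
    ("devany1986", "typical"): "devany1986.yaml",
    ("devany1986", "learning_disability"): "devany1986_learning_disability.yaml",
    (
        "devany1986",
        "interference_avoidance",
    ): "devany1986_interference_avoidance.yaml",
    ("spencer1996", ""): "spencer1996.yaml",
    ("spencer1996", "staged"): "spencer1996.yaml",
    ("spencer1996", "equal_trials"): "spencer1996_equal_trials.yaml",
}


def available_protocols() -> list[str]:
    """Names of all shipped fixtures (``study`` or ``study:variant``)."""
    names = []
    for (study, variant), _ in _REGISTRY.items():
        names.append(f"{study}:{variant}" if variant else study)
    return sorted(names)


def load_protocol_text(study: str, variant: str = "") -> str:
    key = (study, variant or "")
    if key not in _REGISTRY:
        known = ", ".join(available_protocols())
        raise ConfigurationError(
            f"unknown study/variant {study!r}/{variant!r}; available: {known}"
        )
    path = resources.files("eqsim").joinpath("protocols", _REGISTRY[key])
    return path.read_text(encoding="utf-8")


def make_protocol(study: str, variant: str = "") -> ProtocolSpec:
    """Load one of the shipped study protocols as a :class:`ProtocolSpec`."""
    return protocol_from_yaml(load_protocol_text(study, variant))
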