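"""Parcellation label sets used to define network nodes.

Two atlases are supported: the 116-region AAL parcellation (volume-based
metrics) and the 68-region Desikan-Killiany cortical parcellation
(surface-based metrics).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

AAL116 = "AAL116"
DK68 = "DK68"

ATLASES = (AAL116, DK68)

#: metric name -> atlas it is parcellated with
METRIC_ATLAS = {
    "GMV": AAL116,
    "CT": DK68,
    "SD": DK68,
    "FD": DK68,
    "GI": DK68,
}

METRICS = tuple(METRIC_ATLAS)

_RESOURCE_FILES = {
    AAL116: "aal116_labels.txt",
    DK68: "dk68_labels.txt",
}

_EXPECTED_SIZE = {AAL116: 116, DK68: 68}


@lru_cache(maxsize=None)
def atlas_labels(atlas: str) -> tuple[str, ...]:
    """Return the ordered ROI label tuple for *atlas*."""
    if atlas not in _RESOURCE_FILES:
        raise ValueError(f"unknown atlas {atlas!r}; expected one of {ATLASES}")
    text = (
        resources.files("klsnet.resources")
        .joinpath(_RESOURCE_FILES[atlas])
        .read_text(encoding="utf-8")
    )
    labels = tuple(line.strip() for line in text.splitlines() if line.strip())
    n = _EXPECTED_SIZE[atlas]
    if len(labels) != n:
        raise RuntimeError(f"{atlas} resource has {len(labels)} labels, expected {n}")
    return labels


def atlas_size(atlas: str) -> int:
    return len(atlas_labels(atlas))


def atlas_for_metric(metric: str) -> str:
    if metric not in METRIC_ATLAS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    return METRIC_ATLAS[metric]
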