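"""Region-of-interest definitions and the Braak-stage approximation map.

The tau feature space is the 36 bilateral Desikan-Killiany ROIs used for
regional tau-PET SUVR extraction: the 34 cortical parcels of the atlas with
left/right hemispheres averaged, plus hippocampus and amygdala.  The Braak
map groups these ROIs into the six neuropathological tau stages (I-VI); it
ships as an editable YAML config because the grouping is an approximation
taken from the staging literature, not something this package derives.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

BRAAK_STAGES = ("I", "II", "III", "IV", "V", "VI")

#: temporal / parietal ROIs that accumulate tau early in AD; the synthetic
#: generator gives these a positive progression->rate slope by default.
HIGH_SLOPE_ROIS = (
    "fusiform",
    "inferiortemporal",
    "supramarginal",
    "inferiorparietal",
    "superiorparietal",
    "precuneus",
    "bankssts",
)


def load_braak_map(path: str | Path | None = None) -> dict[str, str]:
    """Load a Braak map as ``{roi: stage}`` from YAML.

    The YAML schema is ``stage -> [roi, ...]``.  With ``path=None`` the
    packaged default map is used.  Every ROI must be assigned exactly one
    stage and every stage label must be one of I..VI.
    """
    if path is None:
        text = (resources.files("tautraj") / "data" / "braak_dk.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    mapping: dict[str, str] = {}
    for stage, rois in raw.items():
        if stage not in BRAAK_STAGES:
            raise ValueError(f"unknown Braak stage {stage!r}; expected one of {BRAAK_STAGES}")
        for roi in rois:
            if roi in mapping:
                raise ValueError(f"ROI {roi!r} assigned to more than one Braak stage")
            mapping[str(roi)] = stage
    return mapping


def default_roi_list() -> list[str]:
    """The 36 bilateral Desikan-Killiany ROI names, in Braak-stage order."""
    return list(load_braak_map().keys())


def validate_braak_map(mapping: dict[str, str], rois: list[str]) -> None:
    """Check that *mapping* covers exactly the configured ROI list."""
    missing = sorted(set(rois) - set(mapping))
    if missing:
        raise ValueError(f"Braak map missing ROIs: {missing}")
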