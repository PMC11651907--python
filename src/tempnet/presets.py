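"""Named analysis presets for the published proximity-sensor deployments.

Each preset bundles the recording resolution, the contact-validity
threshold (the deployment's median contact duration) and the time-step
length (its median delay between contacts) for one of the classic
sensor-study settings, plus whether the device records directed
(face-to-face) or undirected (omnidirectional radius) contacts.  The
``fixed15min`` and ``fixed1h`` presets standardise the step across
settings for sensitivity analyses; ``daily`` uses one-day steps for the
top-contributor persistence sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["AnalysisPreset", "PRESETS", "get_preset"]


@dataclass(frozen=True)
class AnalysisPreset:
    name: str
    resolution: int  # recording interval, seconds
    duration_threshold: int  # median contact duration, seconds
    step_length: int  # median delay in contact, seconds
    directed: bool
    description: str


PRESETS: dict[str, AnalysisPreset] = {
    p.name: p
    for p in [
        AnalysisPreset(
            "cruise", 15, 900, 900, False,
            "cruise sailings, omnidirectional sensors (undirected)",
        ),
        AnalysisPreset(
            "community", 300, 300, 600, True,
            "community study via mobile app, 5 min reporting",
        ),
        AnalysisPreset(
            "highschool", 20, 20, 140, True,
            "high school face-to-face badges (per-school delays 100-140 s)",
        ),
        AnalysisPreset(
            "hospital", 20, 20, 140, True,
            "hospital ward face-to-face badges",
        ),
        AnalysisPreset(
            "workplace", 20, 20, 220, True,
            "office buildings face-to-face badges (per-site delays 120-220 s)",
        ),
    ]
}


def get_preset(name: str, step_override: int | None = None) -> AnalysisPreset:
    """Look up a preset, optionally replacing the step length.

    ``step_override`` supports the fixed-step sensitivity analyses
    (e.g. 900 for 15 min, 3600 for 1 h, 86400 for daily steps).
    """
    try:
        preset = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    if step_override is not None:
        preset = AnalysisPreset(
            preset.name, preset.resolution, preset.duration_threshold,
            step_override, preset.directed, preset.description,
        )
    return preset
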