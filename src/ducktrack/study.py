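"""Study-design constants of the tagging campaign and derived desk rates.

The deployment metadata are inputs to the analysis (cohort sizes for the
synthetic generator, tag burden sanity checks), not outputs of it.
"""

from __future__ import annotations

STUDY_DESIGN = {
    "n_deployed": 48,            # females tagged on the breeding island
    "n_recaptured": 19,          # loggers physically recovered
    "n_resighted_not_recaptured": 9,
    "logger_mass_g": 3.3,
    "body_mass_min_g": 580.0,    # lightest tagged female
    "deployment_days_mean": 364,
    "capture_site": (48.848, 69.138),   # lon, lat
}


def recapture_rate_pct(design: dict | None = None) -> float:
    d = design or STUDY_DESIGN
    return 100.0 * d["n_recaptured"] / d["n_deployed"]


def resighted_rate_pct(design: dict | None = None) -> float:
    """Recaptured plus resighted-only birds, as a share of those tagged."""
    d = design or STUDY_DESIGN
    seen = d["n_recaptured"] + d["n_resighted_not_recaptured"]
    return 100.0 * seen / d["n_deployed"]


def max_logger_mass_fraction_pct(design: dict | None = None) -> float:
    """Tag mass as a share of the lightest bird's body mass."""
    d = design or STUDY_DESIGN
    return 100.0 * d["logger_mass_g"] / d["body_mass_min_g"]
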