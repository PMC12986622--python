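"""Reported summary statistics of the double-cropping rice panel.

These are inputs to derived-statistic checks and to the worked examples:
per-trait phenotype means (± SD) in the early (ES) and late (LS) season for
the 217-accession core set, and the published genomic heritabilities. Units:
internode lengths and plant height in cm, bending resistance in Newtons,
length/height ratios dimensionless.
"""

from __future__ import annotations

__all__ = ["SEASONAL_TRAIT_MEANS", "GENOMIC_HERITABILITY",
           "CORE_SET_SIZE", "SEASON_TOTALS", "PANEL_SIZE", "percent_change"]

# trait -> (ES mean, LS mean) over the core set
SEASONAL_TRAIT_MEANS: dict[str, tuple[float, float]] = {
    "IL3": (11.23, 8.13),
    "BR3": (8.09, 16.14),
    "IL4": (19.17, 15.90),
    "BR4": (4.84, 10.97),
    "IL3_PH": (0.09, 0.08),
    "IL4_PH": (0.16, 0.15),
    "PH": (116.30, 107.70),
}

# published single-value genomic heritability per trait
GENOMIC_HERITABILITY: dict[str, float] = {
    "IL3": 0.5054, "BR3": 0.3477, "IL4": 0.6257, "BR4": 0.2297,
    "IL3_PH": 0.2462, "IL4_PH": 0.3724, "PH": 0.7687,
}

PANEL_SIZE = 438          # unique accessions genotyped
CORE_SET_SIZE = 217       # complete phenotypes in both seasons
SEASON_TOTALS = {"ES": 315, "LS": 340}  # complete phenotypes per season


def percent_change(before: float, after: float) -> float:
    """Relative change from ``before`` to ``after`` in percent."""
    if before == 0:
        raise ZeroDivisionError("percent change undefined from zero")
    return 100.0 * (after - before) / before
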