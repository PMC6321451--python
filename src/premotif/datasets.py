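"""Small packaged example datasets.

Only curated text lists live here; precursor sequence databases (e.g.
miRBase releases) are never bundled and must be supplied by the user.
"""

from __future__ import annotations

from importlib import resources


def ddx1_interacting_precursors() -> list[str]:
    """The 25-entry list of human pre-miRNAs reported to co-purify with
    the DEAD-box helicase DDX1, in the nomenclature of the original
    immunoprecipitation study (some names are legacy and no longer
    resolve against current miRBase releases)."""
    text = (
        resources.files("premotif")
        .joinpath("data/ddx1_clip_precursors.txt")
        .read_text()
    )
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
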