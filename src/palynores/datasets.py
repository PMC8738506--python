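"""Bundled example data.

The packaged indicator harmonization table is a *synthetic emulation*: it
encodes the worked Plantago / cereal / Brassicaceae / Cyperaceae /
Rumex-Oxyria merges and the independent indicator taxa discussed in the
palynological literature, plus a neutral arboreal background and aquatics.
It is not a transcription of any published supplementary table; it exists so
the harmonization and downgrade logic can be exercised on realistic names.
"""

from __future__ import annotations

from importlib import resources

from .harmonization import HarmonizationTable, load_harmonization_table

__all__ = ["synthetic_indicator_table"]


def synthetic_indicator_table() -> HarmonizationTable:
    """Load the bundled synthetic indicator harmonization table."""
    ref = resources.files("palynores.data").joinpath(
        "indicator_harmonization_synthetic.csv"
    )
    with resources.as_file(ref) as path:
        return load_harmonization_table(path)
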